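import numpy as np
import pytest
import biotite.structure as struc

from neuroquant.structure import StructureModel


@pytest.fixture
def make_model():
    """Factory for tiny synthetic structures from raw coordinates."""

    def _make(
        coords,
        elements=None,
        chain_ids=None,
        res_ids=None,
        res_names=None,
        atom_names=None,
    ) -> StructureModel:
        n = len(coords)
        arr = struc.AtomArray(n)
        arr.coord = np.asarray(coords, dtype=float)
        arr.element = np.asarray(elements if elements is not None else ["C"] * n)
        arr.chain_id = np.asarray(chain_ids if chain_ids is not None else ["A"] * n)
        arr.res_id = np.asarray(
            res_ids if res_ids is not None else np.arange(1, n + 1)
        )
        arr.res_name = np.asarray(res_names if res_names is not None else ["ALA"] * n)
        arr.atom_name = np.asarray(atom_names if atom_names is not None else ["CA"] * n)
        arr.occupancy = np.ones(n)
        return StructureModel(arr, np.asarray(coords, dtype=float))

    return _make
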