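"""Structure geometry: termini distance, solvent accessibility, burial, hydrophobic runs.

Three geometric readouts used to reason about how a protein partitions
between binding partners:

* the Euclidean distance between the C-alpha atoms of the first and last
  resolved residues of a chain (an extended, planar conformation of CYFIP1
  puts its termini ~12.8 nm apart; a compact one ~7 nm, within Förster range
  of a ~5 nm R0);
* Shrake-Rupley solvent-accessible surface area (SASA) and the burial of a
  residue by a partner chain (a residue essential for one interaction can be
  occluded when the protein sits in the other complex);
* maximal runs of consecutive hydrophobic residues in a sequence (candidate
  hydrophobic interface patches).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import biotite.structure as struc
import biotite.structure.io.pdb as pdb_io
import biotite.structure.io.pdbx as pdbx_io

logger = logging.getLogger(__name__)

__all__ = [
    "StructureModel",
    "SasaResult",
    "HydrophobicRun",
    "VDW_RADII",
    "DEFAULT_HYDROPHOBIC",
    "MAX_RESIDUE_SASA",
    "read_structure",
    "termini_distance",
    "shrake_rupley_sasa",
    "residue_burial",
    "find_hydrophobic_runs",
    "fibonacci_sphere",
]

#: van der Waals radii (Angstrom) used for SASA; unknown elements fall back
#: to the carbon radius with a warning.
VDW_RADII: dict[str, float] = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "H": 1.20,
    "P": 1.80,
}
DEFAULT_VDW_RADIUS = 1.70

#: Default hydrophobic residue set (one-letter codes).
DEFAULT_HYDROPHOBIC: frozenset[str] = frozenset("AVLIMFWC")

#: Maximal per-residue SASA (Angstrom^2) of Gly-X-Gly tripeptides
#: (theoretical values of Tien et al. 2013, PLoS ONE 8:e80635), used as the
#: denominator of relative accessibility.
MAX_RESIDUE_SASA: dict[str, float] = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLN": 225.0, "GLU": 223.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
}


@dataclass
class StructureModel:
    """Atoms of a macromolecular model (thin wrapper over a biotite AtomArray).

    ``coord`` is kept as an authoritative float64 array so that geometric
    readouts are exact to double precision regardless of the container's
    internal storage; it defaults to the AtomArray coordinates.
    """

    atoms: struc.AtomArray
    coord: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.coord is None:
            self.coord = np.asarray(self.atoms.coord, dtype=np.float64)
        else:
            self.coord = np.asarray(self.coord, dtype=np.float64)
            if self.coord.shape != (self.atoms.array_length(), 3):
                raise ValueError("coord must be (n_atoms, 3)")

    @property
    def n_atoms(self) -> int:
        return self.atoms.array_length()

    @property
    def chains(self) -> list[str]:
        return list(np.unique(self.atoms.chain_id))

    def chain(self, chain_id: str) -> "StructureModel":
        sel = self.atoms.chain_id == chain_id
        if not sel.any():
            raise KeyError(f"no chain {chain_id!r}; have {self.chains}")
        return StructureModel(self.atoms[sel], self.coord[sel])

    def subset(self, chain_ids: Iterable[str]) -> "StructureModel":
        ids = list(chain_ids)
        sel = np.isin(self.atoms.chain_id, ids)
        if not sel.any():
            raise KeyError(f"no atoms in chains {ids}")
        return StructureModel(self.atoms[sel], self.coord[sel])

    def sequence(self, chain_id: str) -> tuple[str, np.ndarray]:
        """One-letter sequence of a chain and its residue numbers."""
        from biotite.sequence import ProteinSequence

        ch = self.chain(chain_id).atoms
        res_ids = []
        letters = []
        for res_id, res_name in zip(*struc.get_residues(ch)):
            try:
                letters.append(ProteinSequence.convert_letter_3to1(res_name))
            except KeyError:
                letters.append("X")
            res_ids.append(res_id)
        return "".join(letters), np.asarray(res_ids)


@dataclass(frozen=True)
class SasaResult:
    """Shrake-Rupley output: per-atom SASA plus residue aggregation keys."""

    atom_sasa: np.ndarray            # Angstrom^2 per atom
    chain_ids: np.ndarray
    res_ids: np.ndarray
    res_names: np.ndarray
    probe_radius: float
    n_points: int

    @property
    def total(self) -> float:
        return float(self.atom_sasa.sum())

    def residue_sasa(self, chain_id: str, res_id: int) -> float:
        sel = (self.chain_ids == chain_id) & (self.res_ids == res_id)
        if not sel.any():
            raise KeyError(f"residue {chain_id}/{res_id} not found")
        return float(self.atom_sasa[sel].sum())


@dataclass(frozen=True)
class HydrophobicRun:
    """A maximal stretch of consecutive hydrophobic residues."""

    chain_id: str
    start: int
    end: int          # inclusive
    residues: str

    @property
    def length(self) -> int:
        return self.end - self.start + 1


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------


def read_structure(
    path: str | Path,
    format: str | None = None,
    *,
    strip_waters: bool = True,
) -> StructureModel:
    """Read a PDB or mmCIF file into a :class:`StructureModel`.

    The format is inferred from the file suffix unless given.  Of alternate
    locations the highest-occupancy one is kept; waters are stripped unless
    ``strip_waters=False``; multi-model files yield the first model.
    """
    path = Path(path)
    fmt = format or ("pdb" if path.suffix.lower() in {".pdb", ".ent"} else "mmcif")
    if fmt == "pdb":
        f = pdb_io.PDBFile.read(str(path))
        atoms = pdb_io.get_structure(f, model=1, altloc="occupancy")
    elif fmt in {"mmcif", "cif"}:
        f = pdbx_io.CIFFile.read(str(path))
        atoms = pdbx_io.get_structure(f, model=1, altloc="occupancy")
    else:
        raise ValueError(f"unknown structure format {fmt!r}")
    if strip_waters:
        atoms = atoms[~struc.filter_solvent(atoms)]
    if atoms.array_length() == 0:
        raise ValueError(f"no atoms parsed from {path}")
    if not np.isfinite(atoms.coord).all():
        raise ValueError(f"non-finite coordinates in {path}")
    return StructureModel(atoms)


def write_pdb(model: StructureModel, path: str | Path) -> None:
    f = pdb_io.PDBFile()
    pdb_io.set_structure(f, model.atoms)
    f.write(str(path))


# ---------------------------------------------------------------------------
# Termini distance
# ---------------------------------------------------------------------------


def termini_distance(model: StructureModel, chain_id: str) -> float:
    """C-alpha to C-alpha distance (nm) between the first and last resolved
    residues of a chain.

    Residues lacking a C-alpha at either end are skipped with a log message
    (the nearest resolved residue is used instead).
    """
    ch = model.chain(chain_id)
    is_ca = ch.atoms.atom_name == "CA"
    if is_ca.sum() < 2:
        raise ValueError(f"chain {chain_id!r} has fewer than 2 C-alpha atoms")
    ca_res = ch.atoms.res_id[is_ca]
    ca_coord = ch.coord[is_ca]
    order = np.argsort(ca_res, kind="stable")
    first, last = order[0], order[-1]
    res_ids = ch.atoms.res_id
    if ca_res[first] != res_ids.min() or ca_res[last] != res_ids.max():
        logger.info(
            "chain %s: terminal residue lacks C-alpha; using nearest resolved "
            "residues %d-%d", chain_id, ca_res[first], ca_res[last],
        )
    d_angstrom = float(np.linalg.norm(ca_coord[first] - ca_coord[last]))
    return d_angstrom / 10.0


# ---------------------------------------------------------------------------
# Shrake-Rupley SASA
# ---------------------------------------------------------------------------


def fibonacci_sphere(n: int) -> np.ndarray:
    """``n`` quasi-uniform points on the unit sphere (deterministic lattice)."""
    i = np.arange(n, dtype=float)
    golden = (1.0 + 5.0**0.5) / 2.0
    z = 1.0 - (2.0 * i + 1.0) / n
    theta = 2.0 * np.pi * i / golden
    rho = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([rho * np.cos(theta), rho * np.sin(theta), z])


def _atom_radii(elements: Sequence[str]) -> np.ndarray:
    radii = np.empty(len(elements))
    unknown = set()
    for i, el in enumerate(elements):
        el = el.capitalize()
        r = VDW_RADII.get(el)
        if r is None:
            unknown.add(el)
            r = DEFAULT_VDW_RADIUS
        radii[i] = r
    if unknown:
        logger.warning(
            "unknown elements %s: using default van der Waals radius %.2f A",
            sorted(unknown), DEFAULT_VDW_RADIUS,
        )
    return radii


def shrake_rupley_sasa(
    model: StructureModel,
    probe_radius: float = 1.4,
    n_points: int = 960,
) -> SasaResult:
    """Solvent-accessible surface area by the Shrake-Rupley method.

    Each atom's van der Waals sphere is inflated by the probe radius and
    sampled with a deterministic Fibonacci lattice of ``n_points``; the SASA
    of the atom is the unoccluded fraction of sample points times the area of
    the inflated sphere.  Hydrogens participate only if present in the model.
    """
    if probe_radius < 0:
        raise ValueError("probe_radius must be >= 0")
    if n_points < 10:
        raise ValueError("n_points too small for a meaningful quadrature")
    atoms = model.atoms
    coords = model.coord
    radii = _atom_radii(list(atoms.element)) + probe_radius
    n = coords.shape[0]
    sphere = fibonacci_sphere(n_points)

    # Neighbour search: grid-based via cell lists from biotite would also do,
    # but a KD-tree keeps the dependency surface minimal.
    from scipy.spatial import cKDTree

    tree = cKDTree(coords)
    max_r = radii.max()
    sasa = np.zeros(n)
    for i in range(n):
        pts = coords[i] + radii[i] * sphere
        neigh = tree.query_ball_point(coords[i], r=radii[i] + max_r)
        neigh = [j for j in neigh if j != i]
        accessible = np.ones(n_points, dtype=bool)
        for j in neigh:
            d2 = ((pts - coords[j]) ** 2).sum(axis=1)
            accessible &= d2 > radii[j] ** 2
            if not accessible.any():
                break
        sasa[i] = accessible.mean() * 4.0 * np.pi * radii[i] ** 2
    return SasaResult(
        atom_sasa=sasa,
        chain_ids=np.asarray(atoms.chain_id),
        res_ids=np.asarray(atoms.res_id),
        res_names=np.asarray(atoms.res_name),
        probe_radius=probe_radius,
        n_points=n_points,
    )


def residue_burial(
    model: StructureModel,
    chain_id: str,
    res_id: int,
    partner_chains: Iterable[str] = (),
    probe_radius: float = 1.4,
    n_points: int = 960,
) -> dict[str, float]:
    """Accessibility of one residue with and without partner chains.

    SASA is computed twice — for the chain together with ``partner_chains``
    (the complex) and for the chain alone — and reported as absolute values,
    their difference ``delta_sasa`` (burial by the partners), and relative
    accessibilities against the residue type's maximal SASA.
    """
    partner_chains = [c for c in partner_chains if c != chain_id]
    complex_model = model.subset([chain_id, *partner_chains]) if partner_chains else model.chain(chain_id)
    alone_model = model.chain(chain_id)

    res_sel = (alone_model.atoms.chain_id == chain_id) & (alone_model.atoms.res_id == res_id)
    if not res_sel.any():
        raise KeyError(f"residue {res_id} not found in chain {chain_id}")
    res_name = str(alone_model.atoms.res_name[res_sel][0])

    sasa_complex = shrake_rupley_sasa(complex_model, probe_radius, n_points)
    sasa_alone = shrake_rupley_sasa(alone_model, probe_radius, n_points)
    in_complex = sasa_complex.residue_sasa(chain_id, res_id)
    alone = sasa_alone.residue_sasa(chain_id, res_id)

    max_sasa = MAX_RESIDUE_SASA.get(res_name)
    rel_complex = in_complex / max_sasa if max_sasa else float("nan")
    rel_alone = alone / max_sasa if max_sasa else float("nan")
    return {
        "sasa_complex": in_complex,
        "sasa_alone": alone,
        "delta_sasa": alone - in_complex,
        "relative_complex": rel_complex,
        "relative_alone": rel_alone,
    }


# ---------------------------------------------------------------------------
# Hydrophobic runs
# ---------------------------------------------------------------------------


def find_hydrophobic_runs(
    sequence: str,
    min_len: int = 8,
    hydrophobic_set: frozenset[str] | set[str] = DEFAULT_HYDROPHOBIC,
    *,
    chain_id: str = "",
    numbering: Sequence[int] | None = None,
) -> list[HydrophobicRun]:
    """Maximal runs of >= ``min_len`` consecutive hydrophobic residues.

    ``numbering`` maps sequence positions to residue numbers (defaults to
    1-based positions).  ``X`` is tolerated as an unknown residue and is never
    hydrophobic; other non-standard letters are rejected.
    """
    sequence = sequence.upper()
    allowed = set("ACDEFGHIKLMNPQRSTVWYX")
    bad = set(sequence) - allowed
    if bad:
        raise ValueError(f"non-standard residue letters: {sorted(bad)}")
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    if numbering is None:
        numbering = list(range(1, len(sequence) + 1))
    elif len(numbering) != len(sequence):
        raise ValueError("numbering must match sequence length")

    runs: list[HydrophobicRun] = []
    start = None
    for i, aa in enumerate(sequence + "$"):  # sentinel terminates the last run
        if aa in hydrophobic_set:
            if start is None:
                start = i
        else:
            if start is not None and i - start >= min_len:
                runs.append(
                    HydrophobicRun(
                        chain_id=chain_id,
                        start=int(numbering[start]),
                        end=int(numbering[i - 1]),
                        residues=sequence[start:i],
                    )
                )
            start = None
    return runs
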