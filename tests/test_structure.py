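"""Structure parsing, termini distances, Shrake-Rupley SASA and hydrophobic runs."""

import numpy as np
import pytest

from neuroquant.structure import (
    DEFAULT_HYDROPHOBIC,
    VDW_RADII,
    fibonacci_sphere,
    find_hydrophobic_runs,
    read_structure,
    residue_burial,
    shrake_rupley_sasa,
    termini_distance,
    write_pdb,
)

TWO_ATOM_PDB = """\
ATOM      1  CA  ALA A   1      11.000  12.500  13.250  1.00 20.00           C
ATOM      2  CA  GLY A   2      14.000  12.500  13.250  1.00 20.00           C
END
"""

ALTLOC_PDB = """\
ATOM      1  CA AALA A   1       1.000   0.000   0.000  0.60 20.00           C
ATOM      2  CA BALA A   1       9.000   0.000   0.000  0.40 20.00           C
END
"""


class TestReadStructure:
    def test_two_atom_fixture(self, tmp_path):
        p = tmp_path / "two.pdb"
        p.write_text(TWO_ATOM_PDB)
        m = read_structure(p)
        assert m.n_atoms == 2
        np.testing.assert_allclose(m.atoms.coord[0], [11.0, 12.5, 13.25])
        np.testing.assert_allclose(m.atoms.coord[1], [14.0, 12.5, 13.25])

    def test_highest_occupancy_altloc_kept(self, tmp_path):
        p = tmp_path / "alt.pdb"
        p.write_text(ALTLOC_PDB)
        m = read_structure(p)
        assert m.n_atoms == 1
        np.testing.assert_allclose(m.atoms.coord[0], [1.0, 0.0, 0.0])

    def test_round_trip_preserves_coordinates(self, tmp_path, make_model):
        m = make_model([[1.234, -5.678, 9.012], [0.0, 0.0, 0.0]])
        out = tmp_path / "rt.pdb"
        write_pdb(m, out)
        m2 = read_structure(out)
        np.testing.assert_allclose(m2.atoms.coord, m.atoms.coord, atol=1e-3)

    def test_malformed_file_rejected(self, tmp_path):
        p = tmp_path / "bad.pdb"
        p.write_text("ATOM garbage record\n")
        with pytest.raises(Exception):
            read_structure(p)


class TestTerminiDistance:
    def test_axis_aligned_128_angstrom(self, make_model):
        m = make_model([[0, 0, 0], [0, 0, 128.0]], res_ids=[1, 100])
        assert termini_distance(m, "A") == pytest.approx(12.8)

    def test_identical_coordinates(self, make_model):
        m = make_model([[3, 3, 3], [3, 3, 3]], res_ids=[1, 2])
        assert termini_distance(m, "A") == pytest.approx(0.0)

    def test_rigid_motion_invariance(self, make_model):
        rng = np.random.default_rng(0)
        coords = rng.normal(scale=20, size=(5, 3))
        m = make_model(coords, res_ids=[1, 2, 3, 4, 5])
        d0 = termini_distance(m, "A")
        # random rotation + translation
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        m2 = make_model(coords @ q.T + np.array([10.0, -4.0, 7.0]), res_ids=[1, 2, 3, 4, 5])
        assert termini_distance(m2, "A") == pytest.approx(d0, abs=1e-9)

    def test_missing_terminal_ca_falls_back(self, make_model):
        # residue 1 has no CA; nearest resolved residues are used
        m = make_model(
            [[0, 0, 0], [0, 0, 50.0], [0, 0, 90.0]],
            res_ids=[1, 2, 3],
            atom_names=["CB", "CA", "CA"],
        )
        assert termini_distance(m, "A") == pytest.approx(4.0)

    def test_single_residue_rejected(self, make_model):
        m = make_model([[0, 0, 0]])
        with pytest.raises(ValueError):
            termini_distance(m, "A")


def grid_sasa(coords, elements, probe=1.4, n_theta=400):
    """Dense latitude/longitude quadrature oracle, independent of the
    Fibonacci lattice used by the implementation."""
    coords = np.asarray(coords, float)
    radii = np.array([VDW_RADII[e] for e in elements]) + probe
    total = np.zeros(len(coords))
    # area-weighted lat-long grid on each sphere
    theta = (np.arange(n_theta) + 0.5) * np.pi / n_theta
    for i, (c, r) in enumerate(zip(coords, radii)):
        area_i = 0.0
        for t in theta:
            n_phi = max(8, int(round(2 * n_theta * np.sin(t))))
            phi = (np.arange(n_phi) + 0.5) * 2 * np.pi / n_phi
            pts = c + r * np.column_stack(
                [np.sin(t) * np.cos(phi), np.sin(t) * np.sin(phi),
                 np.full(n_phi, np.cos(t))]
            )
            cell_area = r**2 * np.sin(t) * (np.pi / n_theta) * (2 * np.pi / n_phi)
            free = np.ones(n_phi, bool)
            for j, (cj, rj) in enumerate(zip(coords, radii)):
                if j == i:
                    continue
                free &= ((pts - cj) ** 2).sum(1) > rj**2
            area_i += cell_area * free.sum()
        total[i] = area_i
    return total


class TestShrakeRupley:
    def test_isolated_atom_closed_form(self, make_model):
        m = make_model([[0, 0, 0]], elements=["C"])
        r = shrake_rupley_sasa(m)
        exact = 4 * np.pi * (1.7 + 1.4) ** 2
        assert r.total == pytest.approx(exact, rel=0.02)

    def test_pair_against_grid_oracle(self, make_model):
        coords = [[0, 0, 0], [2.0, 0, 0]]
        m = make_model(coords, elements=["C", "C"])
        mine = shrake_rupley_sasa(m).atom_sasa
        oracle = grid_sasa(coords, ["C", "C"])
        np.testing.assert_allclose(mine, oracle, rtol=0.03)

    def test_cluster_against_grid_oracle(self, make_model):
        rng = np.random.default_rng(1)
        coords = rng.uniform(0, 6, size=(8, 3))
        elements = ["C", "N", "O", "S", "C", "N", "O", "C"]
        m = make_model(coords, elements=elements)
        mine = shrake_rupley_sasa(m).atom_sasa
        oracle = grid_sasa(coords, elements)
        # compare totals (per-atom values can be tiny and noisy)
        assert mine.sum() == pytest.approx(oracle.sum(), rel=0.03)

    def test_occlusion_monotone_in_distance(self, make_model):
        prev = -np.inf
        for d in (2.0, 4.0, 6.0, 8.0, 10.0):
            m = make_model([[0, 0, 0], [d, 0, 0]], elements=["C", "C"])
            s = shrake_rupley_sasa(m).atom_sasa[0]
            assert s >= prev
            prev = s

    def test_quadrature_convergence(self, make_model):
        rng = np.random.default_rng(2)
        m = make_model(rng.uniform(0, 5, size=(6, 3)))
        coarse = shrake_rupley_sasa(m, n_points=960).total
        fine = shrake_rupley_sasa(m, n_points=3840).total
        assert abs(coarse - fine) / fine <= 0.01

    def test_unknown_element_gets_default_radius(self, make_model, caplog):
        import logging

        m = make_model([[0, 0, 0]], elements=["ZZ"])
        with caplog.at_level(logging.WARNING, logger="neuroquant.structure"):
            r = shrake_rupley_sasa(m)
        assert r.total == pytest.approx(4 * np.pi * 3.1**2, rel=0.02)
        assert any("unknown element" in rec.message.lower() for rec in caplog.records)

    def test_matches_independent_implementation(self, make_model):
        # cross-check against biotite's Shrake-Rupley on a random cluster
        import biotite.structure as bs

        rng = np.random.default_rng(3)
        m = make_model(rng.uniform(0, 8, size=(10, 3)))
        mine = shrake_rupley_sasa(m, n_points=960).atom_sasa
        ref = bs.sasa(m.atoms, probe_radius=1.4, point_number=960, vdw_radii="Single")
        # different quadrature point sets: agree within a few percent
        np.testing.assert_allclose(mine, ref, rtol=0.06, atol=1.0)
        assert mine.sum() == pytest.approx(ref.sum(), rel=0.01)

    def test_fibonacci_lattice_on_unit_sphere(self):
        pts = fibonacci_sphere(500)
        np.testing.assert_allclose(np.linalg.norm(pts, axis=1), 1.0, atol=1e-12)
        # quasi-uniform: centroid near origin
        assert np.linalg.norm(pts.mean(0)) < 0.01


class TestResidueBurial:
    def test_no_partners_no_burial(self, make_model):
        m = make_model([[0, 0, 0], [4, 0, 0]], res_ids=[1, 2])
        out = residue_burial(m, "A", 1, partner_chains=[])
        assert out["delta_sasa"] == pytest.approx(0.0, abs=1e-9)

    def test_caged_residue_is_buried(self, make_model):
        # a single "ALA" atom surrounded by a dense cage of partner atoms
        cage = []
        n_shell = 60
        pts = fibonacci_sphere(n_shell) * 4.0
        coords = [[0.0, 0.0, 0.0]] + pts.tolist()
        chains = ["A"] + ["B"] * n_shell
        res_ids = [1] + list(range(1, n_shell + 1))
        m = make_model(coords, chain_ids=chains, res_ids=res_ids)
        out = residue_burial(m, "A", 1, partner_chains=["B"])
        assert out["relative_complex"] < 0.05
        assert out["relative_alone"] > 0.5
        assert out["delta_sasa"] > 0

    def test_interface_delta_additivity(self, make_model):
        # chain-level SASA difference equals the sum of per-residue burials
        rng = np.random.default_rng(4)
        a_coords = rng.uniform(0, 6, size=(6, 3))
        b_coords = rng.uniform(3, 9, size=(6, 3))
        coords = np.vstack([a_coords, b_coords])
        chains = ["A"] * 6 + ["B"] * 6
        res_ids = list(range(1, 7)) + list(range(1, 7))
        m = make_model(coords, chain_ids=chains, res_ids=res_ids)
        per_res = sum(
            residue_burial(m, "A", rid, ["B"])["delta_sasa"] for rid in range(1, 7)
        )
        sasa_alone = shrake_rupley_sasa(m.chain("A")).total
        full = shrake_rupley_sasa(m)
        sel = full.chain_ids == "A"
        sasa_complex = full.atom_sasa[sel].sum()
        assert per_res == pytest.approx(sasa_alone - sasa_complex, rel=0.01, abs=0.5)

    def test_missing_residue_rejected(self, make_model):
        m = make_model([[0, 0, 0]])
        with pytest.raises(KeyError):
            residue_burial(m, "A", 99)


class TestHydrophobicRuns:
    def test_embedded_run(self):
        runs = find_hydrophobic_runs("KKAVLLIMFVKK", min_len=8)
        assert len(runs) == 1
        (run,) = runs
        assert (run.start, run.end, run.length) == (3, 10, 8)
        assert run.residues == "AVLLIMFV"

    def test_eight_residue_interface_motif(self):
        # an A...I stretch of eight consecutive hydrophobics is detected with
        # its sequence numbering preserved
        seq = "G" * 10 + "AVLILMVI" + "G" * 10
        numbering = list(range(996, 996 + len(seq)))
        runs = find_hydrophobic_runs(seq, min_len=8, numbering=numbering)
        assert [(r.start, r.end) for r in runs] == [(1006, 1013)]

    def test_no_runs_in_polar_sequence(self):
        assert find_hydrophobic_runs("K" * 30, min_len=8) == []

    def test_min_len_one(self):
        runs = find_hydrophobic_runs("A", min_len=1)
        assert len(runs) == 1 and runs[0].length == 1

    def test_runs_are_maximal(self):
        runs = find_hydrophobic_runs("AVLIMFWCAVLI", min_len=4)
        assert len(runs) == 1
        assert runs[0].length == 12

    def test_x_never_hydrophobic(self):
        runs = find_hydrophobic_runs("AVLIXAVLI", min_len=4)
        assert [(r.start, r.end) for r in runs] == [(1, 4), (6, 9)]

    def test_nonstandard_letters_rejected(self):
        with pytest.raises(ValueError):
            find_hydrophobic_runs("AVLIB")

    def test_default_set(self):
        assert DEFAULT_HYDROPHOBIC == frozenset("AVLIMFWC")
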