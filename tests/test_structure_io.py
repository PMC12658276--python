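import math

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.transform import Rotation

from membpka.errors import ParseError
from membpka.structure_io import (
    ProtonationAssignment,
    StructureFrame,
    apply_assignment,
    export_table,
    identify_titratable_sites,
    min_sidechain_distance,
    read_structure,
    write_pqr,
)
from conftest import make_atom

TOY_PQR = """\
ATOM 1 CB GLU A 10 0.000 0.000 0.000 0.0000 1.7000
ATOM 2 CD GLU A 10 1.500 0.000 0.000 -1.0000 1.5000
ATOM 3 NZ LYS A 20 6.000 0.000 0.000 1.0000 1.5000
END
"""


@pytest.fixture
def toy_pqr(tmp_path):
    p = tmp_path / "toy.pqr"
    p.write_text(TOY_PQR)
    return p


class TestPqrReading:
    def test_roundtrip_identity(self, toy_pqr, tmp_path):
        frame = read_structure(toy_pqr, "pqr")
        assert len(frame) == 3
        assert frame.atoms[1].partial_charge == -1.0
        assert frame.atoms[1].radius == 1.5
        out = tmp_path / "out.pqr"
        write_pqr(frame, out)
        again = read_structure(out, "pqr")
        np.testing.assert_allclose(again.positions, frame.positions, atol=1e-3)
        np.testing.assert_allclose(again.charges, frame.charges, atol=1e-4)
        np.testing.assert_allclose(again.radii, frame.radii, atol=1e-4)
        assert again.atom_keys() == frame.atom_keys()

    def test_total_charge_is_column_sum(self, tmp_path):
        lines = ["ATOM 1 Q1 DUM A 1 0 0 0 1.5 1.0",
                 "ATOM 2 Q2 DUM A 2 3 0 0 0.5 1.0"]
        p = tmp_path / "q.pqr"
        p.write_text("\n".join(lines) + "\n")
        assert read_structure(p, "pqr").total_charge == pytest.approx(2.0)

    def test_malformed_record_names_line(self, tmp_path):
        p = tmp_path / "bad.pqr"
        p.write_text("ATOM 1 CB GLU A ten 0 0 0 0 1\n")
        with pytest.raises(ParseError, match="bad.pqr:1"):
            read_structure(p, "pqr")

    def test_chainless_pqr_gets_default_chain(self, tmp_path):
        p = tmp_path / "nochain.pqr"
        p.write_text("ATOM 1 CB GLU 10 0 0 0 -1.0 1.5\n")
        frame = read_structure(p, "pqr")
        assert frame.atoms[0].chain_id == "A"


class TestPdbReading:
    def test_glu_is_titratable_downstream(self, tmp_path):
        pdb = tmp_path / "glu.pdb"
        pdb.write_text(
            "ATOM      1  CB  GLU A  10       0.000   0.000   0.000  1.00  0.00           C\n"
            "ATOM      2  CD  GLU A  10       1.500   0.000   0.000  1.00  0.00           C\n"
            "END\n"
        )
        frame = read_structure(pdb, "pdb")
        sites = identify_titratable_sites(frame)
        assert [s.residue_name for s in sites] == ["GLU"]
        # charge assigned from the parameter table (default deprotonated form)
        assert frame.total_charge == pytest.approx(-1.0)


class TestTitratableSites:
    def test_non_titratable_residues_excluded(self):
        atoms = [
            make_atom("CD", resname="GLU", resid=1, pos=(0, 0, 0)),
            make_atom("CD", resname="GLU", resid=2, pos=(5, 0, 0)),
            make_atom("CZ", resname="ARG", resid=3, pos=(10, 0, 0)),
        ]
        sites = identify_titratable_sites(StructureFrame(atoms))
        assert len(sites) == 2
        assert all(s.residue_name == "GLU" for s in sites)

    def test_empty_include_set(self):
        frame = StructureFrame([make_atom("CD", resname="GLU")])
        assert identify_titratable_sites(frame, include=()) == []

    def test_homotrimer_counts_by_chain(self):
        atoms = [
            make_atom("NZ", "N", "LYS", 5, chain, pos=(i * 8.0, 0, 0))
            for i, chain in enumerate("ABC")
        ]
        sites = identify_titratable_sites(StructureFrame(atoms))
        assert len(sites) == 3
        assert len(sites) % 3 == 0
        assert [s.chain_id for s in sites] == ["A", "B", "C"]

    def test_missing_functional_atom_skipped_with_warning(self):
        frame = StructureFrame([make_atom("CB", resname="GLU", resid=7)])
        with pytest.warns(UserWarning, match="GLU7"):
            assert identify_titratable_sites(frame) == []

    def test_reference_pkas(self):
        atoms = [
            make_atom("CG", resname="ASP", resid=1, pos=(0, 0, 0)),
            make_atom("CD", resname="GLU", resid=2, pos=(5, 0, 0)),
            make_atom("NE2", "N", "HIS", 3, pos=(10, 0, 0)),
            make_atom("ND1", "N", "HIS", 3, pos=(11.3, 0, 0)),
            make_atom("NZ", "N", "LYS", 4, pos=(15, 0, 0)),
        ]
        sites = identify_titratable_sites(StructureFrame(atoms))
        refs = {s.residue_name: s.reference_pka for s in sites}
        assert refs == {"ASP": 3.90, "GLU": 4.07, "HIS": 6.04, "LYS": 10.54}

    def test_charge_sets_differ_by_one_proton(self):
        frame = StructureFrame([make_atom("CD", resname="GLU")])
        (site,) = identify_titratable_sites(frame)
        dq = sum(site.charge_sets["protonated"].values()) - sum(
            site.charge_sets["deprotonated"].values()
        )
        assert dq == pytest.approx(1.0)


class TestAssignment:
    def test_apply_assignment_sets_functional_charges(self):
        frame = StructureFrame(
            [make_atom("CB", resname="GLU", pos=(0, 0, 1.5), charge=0.0),
             make_atom("CD", resname="GLU", pos=(0, 0, 0), charge=-1.0)]
        )
        sites = identify_titratable_sites(frame)
        protonated = ProtonationAssignment(states={sites[0].site_id: "protonated"})
        out = apply_assignment(frame, sites, protonated)
        assert out.total_charge == pytest.approx(0.0)
        deprot = ProtonationAssignment(states={sites[0].site_id: "deprotonated"})
        assert apply_assignment(frame, sites, deprot).total_charge == pytest.approx(-1.0)


class TestMinSidechainDistance:
    def test_single_atom_pair(self):
        frame = StructureFrame(
            [make_atom("CG", resname="ASP", resid=1, pos=(0, 0, 0)),
             make_atom("CG", resname="ASP", resid=2, pos=(0, 0, 3.1))]
        )
        assert min_sidechain_distance(frame, ("A", 1), ("A", 2)) == pytest.approx(3.1)

    def test_self_distance_zero(self):
        frame = StructureFrame([make_atom("CG", resname="ASP", resid=1)])
        assert min_sidechain_distance(frame, ("A", 1), ("A", 1)) == 0.0

    def test_matches_bruteforce_and_symmetry(self):
        rng = np.random.default_rng(7)
        pa = rng.normal(0, 3, (5, 3))
        pb = rng.normal(8, 3, (5, 3))
        atoms = [make_atom(f"S{i}", resname="TRP", resid=1, pos=p) for i, p in enumerate(pa)]
        atoms += [make_atom(f"S{i}", resname="TRP", resid=2, pos=p) for i, p in enumerate(pb)]
        frame = StructureFrame(atoms)
        brute = min(np.linalg.norm(a - b) for a in pa for b in pb)
        d12 = min_sidechain_distance(frame, ("A", 1), ("A", 2))
        d21 = min_sidechain_distance(frame, ("A", 2), ("A", 1))
        assert d12 == pytest.approx(brute)
        assert d12 == d21

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(11)
        pa = rng.normal(0, 2, (4, 3))
        pb = rng.normal(6, 2, (4, 3))
        rot = Rotation.from_rotvec([0.3, -0.7, 1.1]).as_matrix()
        shift = np.array([5.0, -3.0, 2.0])

        def build(pts_a, pts_b):
            atoms = [make_atom(f"S{i}", resname="PHE", resid=1, pos=p) for i, p in enumerate(pts_a)]
            atoms += [make_atom(f"S{i}", resname="PHE", resid=2, pos=p) for i, p in enumerate(pts_b)]
            return StructureFrame(atoms)

        d0 = min_sidechain_distance(build(pa, pb), ("A", 1), ("A", 2))
        d1 = min_sidechain_distance(build(pa @ rot.T + shift, pb @ rot.T + shift), ("A", 1), ("A", 2))
        assert d1 == pytest.approx(d0, abs=1e-9)

    def test_no_sidechain_is_an_error(self):
        frame = StructureFrame(
            [make_atom("CA", resname="GLY", resid=1),
             make_atom("CG", resname="ASP", resid=2, pos=(3, 0, 0))]
        )
        with pytest.raises(ValueError, match="no heavy side-chain atoms"):
            min_sidechain_distance(frame, ("A", 1), ("A", 2))


class TestExportTable:
    def test_row_counts_and_roundtrip(self, tmp_path):
        df = pd.DataFrame({"site": [f"A:GLU{i}" for i in range(15)],
                           "mean_pka": np.linspace(2, 9, 15)})
        out = tmp_path / "pka.csv"
        export_table(df, out)
        back = pd.read_csv(out)
        assert len(back) == 15
        np.testing.assert_allclose(back["mean_pka"], df["mean_pka"], atol=1e-6)

    def test_empty_table_refused(self, tmp_path):
        with pytest.raises(ValueError):
            export_table(pd.DataFrame(), tmp_path / "x.csv")
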