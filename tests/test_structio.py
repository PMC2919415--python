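"""Structure reading, mass accounting and sphere-model round trips."""
import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from ccsbuild.models import Sphere, SphereModel
from ccsbuild.structio import (
    ConsistencyError,
    StructureError,
    WATER_MASS,
    mass_account,
    read_sphere_pdb,
    read_structure,
    residue_mass,
    sequence_mass,
    write_sphere_pdb,
)
from ccsbuild.synthetic import FixtureSpec, make_unit_pdb

GAPPED_PDB = """\
SEQRES   1 A    5  ALA GLY ALA GLY ALA
ATOM      1  CA  ALA A   1      10.000  10.000  10.000  1.00 20.00           C
ATOM      2  CA  GLY A   2      13.500  10.000  10.000  1.00 20.00           C
ATOM      3  CA  ALA A   3      17.000  10.000  10.000  1.00 20.00           C
END
"""

NO_SEQRES_PDB = """\
ATOM      1  CA  ALA A   1      10.000  10.000  10.000  1.00 20.00           C
ATOM      2  CA  GLY A   2      13.500  10.000  10.000  1.00 20.00           C
END
"""

ALTLOC_PDB = """\
ATOM      1  CA AALA A   1      10.000  10.000  10.000  0.40 20.00           C
ATOM      2  CA BALA A   1      12.000  10.000  10.000  0.60 20.00           C
END
"""

TWO_CHAIN_PDB = """\
SEQRES   1 A    2  ALA GLY
SEQRES   1 B    3  ALA ALA ALA
ATOM      1  CA  ALA A   1      10.000  10.000  10.000  1.00 20.00           C
ATOM      2  CA  GLY A   2      13.500  10.000  10.000  1.00 20.00           C
ATOM      3  CA  ALA B   1      30.000  10.000  10.000  1.00 20.00           C
ATOM      4  CA  ALA B   2      33.500  10.000  10.000  1.00 20.00           C
END
"""


def _write(tmp_path, text, name="t.pdb"):
    p = tmp_path / name
    p.write_text(text)
    return p


def test_seqres_declares_absent_residues(tmp_path):
    st = read_structure(_write(tmp_path, GAPPED_PDB))
    assert st.chains["A"] == "AGAGA"
    observed = st.residue_keys()
    assert len(observed) == 3
    acc = mass_account(st)
    assert acc.missing_segments == (("A", 4, 5),)
    expected_f = (residue_mass("G") + residue_mass("A")) / sequence_mass("AGAGA")
    assert acc.f_missing == pytest.approx(expected_f, abs=1e-9)


def test_no_seqres_falls_back_to_observed_sequence(tmp_path):
    st = read_structure(_write(tmp_path, NO_SEQRES_PDB))
    assert st.chains["A"] == "AG"
    acc = mass_account(st)
    assert acc.f_missing == 0.0
    assert acc.m_present == acc.m_full


def test_remark290_operators_parsed_with_identity():
    spec = FixtureSpec(seed=1, n_residues=40, operators="orthorhombic4")
    import tempfile
    from pathlib import Path

    with tempfile.TemporaryDirectory() as d:
        p = Path(d) / "u.pdb"
        p.write_text(make_unit_pdb(spec))
        st = read_structure(p)
    assert st.sym_ops is not None and len(st.sym_ops) == 4
    assert any(op.is_identity() for op in st.sym_ops)
    assert st.cell is not None


def test_altloc_keeps_highest_occupancy(tmp_path):
    st = read_structure(_write(tmp_path, ALTLOC_PDB))
    assert st.n_atoms == 1
    assert st.coords[0, 0] == pytest.approx(12.0)


def test_missing_file_and_empty_structure(tmp_path):
    with pytest.raises(StructureError):
        read_structure(tmp_path / "nonexistent.pdb")
    with pytest.raises(StructureError):
        read_structure(_write(tmp_path, "REMARK no atoms here\nEND\n"))


def test_fasta_full_sequence_overrides_seqres(tmp_path):
    st = read_structure(_write(tmp_path, GAPPED_PDB))
    acc = mass_account(st, full_sequence={"A": "AGAGAGGGGG"})
    assert acc.m_full == pytest.approx(sequence_mass("AGAGAGGGGG"))
    assert acc.f_missing > mass_account(st).f_missing


def test_mass_account_is_additive_over_chains(tmp_path):
    lines = TWO_CHAIN_PDB.splitlines()
    a_text = "\n".join(ln for ln in lines if " B " not in ln) + "\n"
    b_text = "\n".join(ln for ln in lines if " A " not in ln) + "\n"
    both = mass_account(read_structure(_write(tmp_path, TWO_CHAIN_PDB, "ab.pdb")))
    only_a = mass_account(read_structure(_write(tmp_path, a_text, "a.pdb")))
    only_b = mass_account(read_structure(_write(tmp_path, b_text, "b.pdb")))
    assert both.m_full == pytest.approx(only_a.m_full + only_b.m_full, abs=1e-6)
    assert both.m_present == pytest.approx(
        only_a.m_present + only_b.m_present, abs=1e-6
    )


def test_f_missing_invariant_under_rigid_motion(tmp_path):
    st = read_structure(_write(tmp_path, GAPPED_PDB))
    R = Rotation.from_euler("xyz", [0.3, -1.1, 2.0]).as_matrix()
    moved = st.transformed(R, np.array([5.0, -3.0, 12.0]))
    assert mass_account(moved).f_missing == mass_account(st).f_missing


def test_observed_residue_outside_declared_sequence_errors(tmp_path):
    bad = GAPPED_PDB.replace("ALA A   3", "ALA A   9")
    st = read_structure(_write(tmp_path, bad))
    with pytest.raises(ConsistencyError):
        mass_account(st)


def test_observed_residue_type_mismatch_errors(tmp_path):
    bad = GAPPED_PDB.replace("GLY A   2", "TRP A   2")
    st = read_structure(_write(tmp_path, bad))
    with pytest.raises(ConsistencyError):
        mass_account(st)


def test_sequence_mass_matches_residue_table():
    assert sequence_mass("AAAAA") == pytest.approx(
        5 * residue_mass("A") + WATER_MASS, abs=1e-6
    )
    # monoisotopic option stays self-consistent
    assert sequence_mass("AG", monoisotopic=True) == pytest.approx(
        residue_mass("A", True) + residue_mass("G", True) + 18.010565, abs=1e-5
    )


class TestSpherePdb:
    def _model(self):
        return SphereModel(
            spheres=[
                Sphere("domain1", (1.234, -5.678, 9.012), 14.25, 8123.4, "domain"),
                Sphere("domain2", (20.001, 3.5, -2.25), 11.0, 6200.0, "domain"),
                Sphere("missing", (0.0, 0.0, 30.125), 7.94, 3100.75, "missing"),
            ],
            provenance="unit-test",
        )

    def test_round_trip_preserves_everything(self, tmp_path):
        model = self._model()
        p = tmp_path / "spheres.pdb"
        write_sphere_pdb(model, p)
        lines = p.read_text().splitlines()
        assert sum(1 for ln in lines if ln.startswith("HETATM")) == 3
        back = read_sphere_pdb(p)
        assert len(back) == 3
        assert back.provenance == "unit-test"
        for a, b in zip(model.spheres, back.spheres):
            assert a.label == b.label and a.kind == b.kind
            assert np.allclose(a.center, b.center, atol=1.5e-3)
            assert b.radius == pytest.approx(a.radius, abs=5e-3)
            assert b.mass == pytest.approx(a.mass, abs=1e-3)

    def test_empty_model_errors(self, tmp_path):
        with pytest.raises(ValueError):
            write_sphere_pdb(SphereModel(spheres=[]), tmp_path / "x.pdb")

    def test_radius_beyond_column_precision_errors(self, tmp_path):
        big = SphereModel(spheres=[Sphere("x", (0, 0, 0), 1234.5, 1.0)])
        with pytest.raises(ValueError):
            write_sphere_pdb(big, tmp_path / "x.pdb")
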