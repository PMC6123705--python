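"""Structure reading, atom-name normalization and tabular I/O."""

import numpy as np
import pytest

from enoe.errors import ENOEError, FormatError, NameNormalizationError
from enoe.restraints import DistanceRestraint, restraints_from_bounds
from enoe.spin_system_io import (
    AtomId,
    Ensemble,
    make_spin_system,
    normalize_atom_name,
    parse_atom_token,
    read_buildup_table,
    read_ensemble,
    read_restraint_table,
    write_buildup_table,
    write_restraints,
)

from conftest import ensemble_to_pdb


# An independently written dialect mapping (PDB v2 / XPLOR / asterisk
# conventions), used as a cross-check oracle for the normalization table.
INDEPENDENT_DIALECTS = [
    ("H5*", "A", "H5'"),
    ("H5''", "G", "H5''"),
    ('H5"', "G", "H5''"),
    ("1H5'", "C", "H5'"),
    ("2H5'", "C", "H5''"),
    ("H5'1", "U", "H5'"),
    ("H5'2", "U", "H5''"),
    ("H2*", "A", "H2'"),
    ("1H2'", "A", "H2'"),
    ("1H2", "G", "H21"),
    ("2H2", "G", "H22"),
    ("1H4", "C", "H41"),
    ("2H4", "C", "H42"),
    ("1H6", "A", "H61"),
    ("2H6", "A", "H62"),
    ("HO2'", "U", "HO2'"),
    ("HO'2", "U", "HO2'"),
    ("2HO'", "U", "HO2'"),
    ("H1'", "G", "H1'"),
    ("H8", "G", "H8"),
]


class TestNormalizeAtomName:
    @pytest.mark.parametrize("raw,res,expected", INDEPENDENT_DIALECTS)
    def test_dialect_table(self, raw, res, expected):
        assert normalize_atom_name(raw, res) == expected

    @pytest.mark.parametrize("raw,res,expected", INDEPENDENT_DIALECTS)
    def test_idempotent(self, raw, res, expected):
        once = normalize_atom_name(raw, res)
        assert normalize_atom_name(once, res) == once

    def test_non_hydrogen_unchanged(self):
        for name in ("C1'", "N9", "OP1", "P"):
            assert normalize_atom_name(name, "G") == name

    def test_unmappable_dialect_raises(self):
        with pytest.raises(NameNormalizationError, match="HQ9"):
            normalize_atom_name("HQ9", "G")

    def test_wrong_residue_proton_raises(self):
        # H8 is a purine proton; uracil has none
        with pytest.raises(NameNormalizationError):
            normalize_atom_name("H8", "U")

    def test_empty_raises(self):
        with pytest.raises(NameNormalizationError):
            normalize_atom_name("  ", "G")


def _toy_ensemble(n_conformers=1, n_atoms=5):
    names = ["H1'", "H2'", "H8", "C1'", "N9"][:n_atoms]
    atoms = [AtomId(1, "G", n) for n in names]
    rng = np.random.default_rng(0)
    base = rng.uniform(0, 8, size=(n_atoms, 3))
    coords = np.array([base + 0.1 * c for c in range(n_conformers)])
    return Ensemble(atoms=atoms, coordinates=coords)


class TestReadEnsemble:
    def test_single_model_identity(self):
        e = _toy_ensemble()
        out = read_ensemble(ensemble_to_pdb(e))
        assert out.n_conformers == 1
        assert out.atoms == e.atoms
        assert np.allclose(out.coordinates, e.coordinates, atol=1e-3)

    def test_twenty_models(self):
        e = _toy_ensemble(n_conformers=20)
        out = read_ensemble(ensemble_to_pdb(e))
        assert out.n_conformers == 20
        assert np.allclose(out.coordinates, e.coordinates, atol=1e-3)

    def test_atom_missing_in_one_model_dropped_with_warning(self):
        e = _toy_ensemble(n_conformers=2)
        text = ensemble_to_pdb(e)
        # remove one atom line from model 2 only
        lines = text.splitlines()
        idx = [i for i, ln in enumerate(lines) if "H2'" in ln][1]
        del lines[idx]
        with pytest.warns(UserWarning, match="not present in every model"):
            out = read_ensemble("\n".join(lines))
        assert AtomId(1, "G", "H2'") not in out.atoms
        assert out.n_atoms == e.n_atoms - 1

    def test_no_atoms_raises(self):
        with pytest.raises(FormatError):
            read_ensemble("HEADER  nothing\nEND\n")

    def test_inconsistent_residue_numbering_raises(self):
        e = _toy_ensemble(n_conformers=2)
        text = ensemble_to_pdb(e).replace("G A   1", "A A   1", 2)  # model 2 differs
        # the replacement hits model 1's first lines; swap so models disagree
        lines = text.splitlines()
        changed = 0
        for i, ln in enumerate(lines):
            if ln.startswith("ATOM") and "  G A" in ln and changed < 2:
                lines[i] = ln.replace("  G A", "  A A")
                changed += 1
        with pytest.raises(FormatError, match="inconsistent residue"):
            read_ensemble("\n".join(lines))


class TestMakeSpinSystem:
    def _cytosine(self):
        names = ["H41", "H42", "H5", "H6", "H1'", "H5'", "H5''", "C1'"]
        atoms = [AtomId(2, "C", n) for n in names]
        rng = np.random.default_rng(1)
        coords = rng.uniform(0, 9, size=(1, len(atoms), 3))
        return Ensemble(atoms=atoms, coordinates=coords)

    def test_cytosine_classification(self):
        s = make_spin_system(self._cytosine())
        cls = dict(zip([a.atom_name for a in s.protons], s.group_class))
        assert cls["H41"] == cls["H42"] == "amino"
        assert cls["H5"] == cls["H6"] == "other"

    def test_methylene_geminal_pairing(self):
        s = make_spin_system(self._cytosine())
        i5 = next(k for k, a in enumerate(s.protons) if a.atom_name == "H5'")
        i5p = next(k for k, a in enumerate(s.protons) if a.atom_name == "H5''")
        assert s.group_class[i5] == s.group_class[i5p] == "methylene"
        assert s.geminal_partner[i5] == i5p
        assert s.geminal_partner[i5p] == i5

    def test_exclude_exchangeable_filters_and_subsets(self):
        e = self._cytosine()
        s_all = make_spin_system(e, include_exchangeable=True)
        s_d2o = make_spin_system(e, include_exchangeable=False)
        assert s_all.n_protons == 7
        assert s_d2o.n_protons == 5  # two amino protons excluded
        assert set(s_d2o.protons) <= set(s_all.protons)

    def test_no_hydrogens_raises(self):
        atoms = [AtomId(1, "G", "C1'"), AtomId(1, "G", "N9")]
        e = Ensemble(atoms=atoms, coordinates=np.zeros((1, 2, 3)) + [[0, 0, 0], [2, 0, 0]])
        with pytest.raises(ENOEError, match="protonated"):
            make_spin_system(e)


def _table(rows, header="peak_id\tatom_i\tatom_j\tmixing_time_s\tintensity"):
    return header + "\n" + "\n".join("\t".join(str(x) for x in r) for r in rows) + "\n"


class TestBuildupTable:
    def test_two_peaks_eight_mixing_times(self):
        taus = [0.04, 0.08, 0.12, 0.16, 0.20, 0.24, 0.28, 0.32]
        rows = []
        for t in taus:
            rows.append(["p1", "G1.H8", "G1.H8", t, np.exp(-3 * t)])
            rows.append(["p2", "G1.H8", "C2.H5", t, 0.1 * t])
        b = read_buildup_table(_table(rows))
        assert len(b.series) == 2
        for s in b.series.values():
            assert s.mixing_times.size == 8
            assert np.all(np.diff(s.mixing_times) > 0)

    def test_empty_table_warns(self):
        with pytest.warns(UserWarning, match="empty"):
            b = read_buildup_table("# just a comment\n")
        assert len(b.series) == 0

    def test_ms_unit_round_trip(self):
        rows_s = [["p", "G1.H8", "C2.H5", 0.04, 1.0], ["p", "G1.H8", "C2.H5", 0.08, 2.0]]
        rows_ms = [["p", "G1.H8", "C2.H5", 40, 1.0], ["p", "G1.H8", "C2.H5", 80, 2.0]]
        b_s = read_buildup_table(_table(rows_s))
        b_ms = read_buildup_table(_table(rows_ms), time_unit="ms")
        k = next(iter(b_s.series))
        assert np.allclose(b_s.series[k].mixing_times, b_ms.series[k].mixing_times)
        assert np.allclose(b_s.series[k].intensities, b_ms.series[k].intensities)

    def test_duplicate_measurement_raises(self):
        rows = [["p", "G1.H8", "C2.H5", 0.04, 1.0], ["p", "G1.H8", "C2.H5", 0.04, 1.1]]
        with pytest.raises(FormatError, match="duplicate"):
            read_buildup_table(_table(rows))

    def test_missing_column_raises(self):
        with pytest.raises(FormatError, match="intensity"):
            read_buildup_table("peak_id\tatom_i\tatom_j\tmixing_time_s\np\ta\tb\t0.04\n")

    def test_non_numeric_raises(self):
        rows = [["p", "G1.H8", "C2.H5", 0.04, "oops"]]
        with pytest.raises(FormatError):
            read_buildup_table(_table(rows))

    def test_write_read_round_trip(self):
        rows = [["p", "G1.H8", "C2.H5", 0.04, 1.25], ["p", "G1.H8", "C2.H5", 0.08, 2.5],
                ["d", "G1.H8", "G1.H8", 0.04, 9.0], ["d", "G1.H8", "G1.H8", 0.08, 7.0]]
        b = read_buildup_table(_table(rows))
        b2 = read_buildup_table(write_buildup_table(b))
        assert set(b2.series) == set(b.series)
        for k in b.series:
            assert np.allclose(b2.series[k].intensities, b.series[k].intensities)

    def test_atom_token_round_trip(self):
        a = AtomId(10, "G", "H5''")
        assert parse_atom_token(str(a)) == a


def _restraint(i, j, r, cls):
    a, b = AtomId(i, "G", "H8"), AtomId(j, "C", "H5")
    upper = r if cls == "bidirectional" else 1.1 * r
    lower = {"bidirectional": r, "unidirectional": 0.9 * r, "gn": None}[cls]
    return DistanceRestraint((a, b), r, cls, upper, lower)


class TestRestraintFiles:
    def test_bidirectional_same_value_both_files(self):
        r = [_restraint(1, 2, 3.50, "bidirectional")]
        upl = write_restraints(r, "upper")
        lol = write_restraints(r, "lower")
        assert "3.50" in upl and "3.50" in lol

    def test_gn_upper_only(self):
        r = [_restraint(1, 2, 4.00, "gn")]
        assert "4.40" in write_restraints(r, "upper")
        with pytest.raises(ENOEError):
            write_restraints(r, "lower")

    def test_mixed_set_skips_gn_in_lol_with_warning(self):
        rs = [_restraint(1, 2, 3.5, "bidirectional"), _restraint(1, 3, 4.0, "gn")]
        with pytest.warns(UserWarning, match="skipped"):
            lol = write_restraints(rs, "lower")
        assert len(lol.strip().splitlines()) == 1

    def test_round_trip(self):
        rs = [_restraint(1, 2, 3.5, "bidirectional"),
              _restraint(1, 3, 4.0, "unidirectional"),
              _restraint(2, 3, 4.0, "gn")]
        upl = read_restraint_table(write_restraints(rs, "upper"))
        with pytest.warns(UserWarning):
            lol = read_restraint_table(write_restraints(rs, "lower"))
        back = restraints_from_bounds(upl, lol)
        by_pair = {frozenset(r.pair): r for r in back}
        for r in rs:
            b = by_pair[frozenset(r.pair)]
            assert b.restraint_class == r.restraint_class
            assert b.upper == pytest.approx(r.upper, abs=0.01)
            if r.lower is not None:
                assert b.lower == pytest.approx(r.lower, abs=0.01)
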