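"""Distance conversion, restraint classes, validation and pruning."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from enoe.errors import ENOEError, FitError
from enoe.fitting import CrossFit
from enoe.relaxation import pair_rates
from enoe.restraints import (
    DistanceRestraint,
    compare_distances,
    ensemble_distance,
    jackknife,
    make_restraint,
    prune_peaks,
    sigma_to_distance,
    violation_tf,
)
from enoe.spin_system_io import AtomId, Ensemble


def _aid(i, name="H8", res="G"):
    return AtomId(i, res, name)


class TestSigmaToDistance:
    @pytest.mark.parametrize("r", [1.8, 2.5, 3.0, 3.97, 5.0, 6.0])
    def test_round_trip_identity(self, cond, r):
        sigma, _ = pair_rates(r, cond)
        assert sigma_to_distance(sigma, cond) == pytest.approx(r, rel=1e-10)

    def test_halving_sigma_scales_by_sixth_root_of_two(self, cond):
        sigma, _ = pair_rates(3.0, cond)
        r1 = sigma_to_distance(sigma, cond)
        r2 = sigma_to_distance(sigma / 2, cond)
        assert r2 / r1 == pytest.approx(2 ** (1 / 6), rel=1e-12)

    def test_bidirectional_mean_before_conversion(self, cond):
        sigma, _ = pair_rates(3.5, cond)
        r = sigma_to_distance([0.9 * sigma, 1.1 * sigma], cond)
        assert r == pytest.approx(3.5, rel=1e-10)

    def test_wrong_sign_raises(self, cond):
        with pytest.raises(ENOEError, match="sign"):
            sigma_to_distance(0.5, cond)  # positive sigma in slow tumbling


class TestMakeRestraint:
    def _fit(self, cond, r, both=True):
        sigma, _ = pair_rates(r, cond)
        return CrossFit(pair=(_aid(1), _aid(2, "H5", "C")), sigma_ij=sigma,
                        sigma_ji=sigma if both else None,
                        sigma_ij_rel_stderr=0.01, n_points=4)

    def test_bidirectional_equal_bounds(self, cond):
        r = make_restraint(self._fit(cond, 3.50), cond)
        assert r.restraint_class == "bidirectional"
        assert r.upper == r.lower == pytest.approx(3.50, rel=1e-9)

    def test_unidirectional_ten_percent(self, cond):
        r = make_restraint(self._fit(cond, 4.00, both=False), cond)
        assert r.restraint_class == "unidirectional"
        assert r.upper == pytest.approx(4.40, rel=1e-9)
        assert r.lower == pytest.approx(3.60, rel=1e-9)

    def test_gn_upper_only(self, cond):
        r = make_restraint(self._fit(cond, 4.00, both=False), cond,
                           restraint_class="gn")
        assert r.upper == pytest.approx(4.40, rel=1e-9)
        assert r.lower is None

    def test_rejected_fit_raises(self, cond):
        fit = self._fit(cond, 3.0)
        fit.flags = ("rejected",)
        with pytest.raises(FitError):
            make_restraint(fit, cond)


def _ensemble(dists_by_conformer):
    """Two-atom ensemble with prescribed per-conformer distances."""
    atoms = [_aid(1), _aid(2, "H5", "C")]
    coords = np.array([[[0, 0, 0], [d, 0, 0]] for d in dists_by_conformer],
                      dtype=float)
    return Ensemble(atoms=atoms, coordinates=coords)


class TestEnsembleDistance:
    def test_single_conformer_both_modes_equal(self):
        e = _ensemble([3.3])
        pair = (e.atoms[0], e.atoms[1])
        assert ensemble_distance(e, pair, "r6") == pytest.approx(3.3)
        assert ensemble_distance(e, pair, "linear") == pytest.approx(3.3)

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(1.5, 8.0), min_size=2, max_size=10))
    def test_r6_never_exceeds_linear(self, dists):
        e = _ensemble(dists)
        pair = (e.atoms[0], e.atoms[1])
        r6 = ensemble_distance(e, pair, "r6")
        lin = ensemble_distance(e, pair, "linear")
        assert r6 <= lin + 1e-12
        if np.ptp(dists) > 1e-6:
            assert r6 < lin

    def test_missing_atom_raises(self):
        e = _ensemble([3.0])
        with pytest.raises(KeyError):
            ensemble_distance(e, (e.atoms[0], _aid(99)), "r6")


class TestCompareDistances:
    def _sets(self, scale=1.0):
        pairs = [(_aid(i), _aid(i + 1)) for i in range(1, 6)]
        a = {p: 2.0 + 0.5 * k for k, p in enumerate(pairs)}
        b = {p: scale * v for p, v in a.items()}
        return a, b

    def test_identical_sets(self):
        a, b = self._sets()
        st_ = compare_distances(a, b)
        assert st_.slope_through_origin == pytest.approx(1.0)
        assert st_.pearson_r == pytest.approx(1.0)
        assert st_.n_pairs == 5

    def test_doubled_set(self):
        a, b = self._sets(scale=2.0)
        st_ = compare_distances(a, b)
        assert st_.slope_through_origin == pytest.approx(2.0)
        assert st_.pearson_r == pytest.approx(1.0)

    def test_too_few_shared_pairs(self):
        a = {(_aid(1), _aid(2)): 3.0}
        with pytest.raises(ENOEError):
            compare_distances(a, a)

    def test_subgroup_breakdown(self):
        a, b = self._sets()
        classes = {p: ("methylene", "other") for p in a}
        st_ = compare_distances(a, b, classes=classes)
        assert "mixed" in st_.subgroups
        assert st_.subgroups["mixed"].n_pairs == 5


def _restraint(pair, r, cls="bidirectional"):
    upper = r if cls == "bidirectional" else 1.1 * r
    lower = {"bidirectional": r, "unidirectional": 0.9 * r, "gn": None}[cls]
    return DistanceRestraint(pair, r, cls, upper, lower)


class TestViolationTF:
    def test_satisfied_restraints_zero_tf(self):
        e = _ensemble([4.0])
        pair = (e.atoms[0], e.atoms[1])
        rep = violation_tf([_restraint(pair, 4.0)], e)
        assert rep.tf == 0.0
        assert rep.n_violated == 0

    def test_single_violation_squared(self):
        e = _ensemble([4.5])
        pair = (e.atoms[0], e.atoms[1])
        rep = violation_tf([_restraint(pair, 4.0)], e)
        assert rep.tf == pytest.approx(0.25)
        assert rep.highlighted == [pair]

    def test_two_state_consistent_only_on_r6_average(self):
        """A mobile proton whose restraint matches the r^-6 average is
        violated by every individual conformer but satisfied by the
        two-state ensemble."""
        e = _ensemble([3.0, 5.0])
        pair = (e.atoms[0], e.atoms[1])
        r_eff = ensemble_distance(e, pair, "r6")
        restraints = [_restraint(pair, r_eff)]
        assert violation_tf(restraints, e, "r6_over_states").tf == pytest.approx(0.0)
        for c in (0, 1):
            rep = violation_tf(restraints, e, "per_conformer", conformer=c)
            assert rep.tf > 0.01

    def test_order_invariance_and_bound_relaxation(self):
        e = _ensemble([4.5])
        pair = (e.atoms[0], e.atoms[1])
        r1, r2 = _restraint(pair, 4.0), _restraint(pair, 4.2, "unidirectional")
        tf_a = violation_tf([r1, r2], e).tf
        tf_b = violation_tf([r2, r1], e).tf
        assert tf_a == tf_b
        relaxed = DistanceRestraint(pair, 4.1, "bidirectional", 4.1, 4.1)
        assert violation_tf([relaxed, r2], e).tf < tf_a

    def test_unresolvable_atoms_skipped_with_warning(self):
        e = _ensemble([4.0])
        bad = _restraint((_aid(98), _aid(99)), 3.0)
        with pytest.warns(UserWarning, match="unresolvable"):
            rep = violation_tf([bad], e)
        assert rep.skipped == [bad.pair]
        assert rep.tf == 0.0


def _restraint_set(n, violated_every=3):
    e = _ensemble([4.0])
    pair = (e.atoms[0], e.atoms[1])
    rs = []
    for k in range(n):
        r = 4.0 if k % violated_every else 3.6
        rs.append(_restraint(pair, r))
    return e, rs


class TestJackknife:
    def test_partition_covers_every_restraint_once(self):
        e, rs = _restraint_set(23)
        rep = jackknife(rs, e, k=10, seed=1)
        assert len(rep.partials) == 10
        assert sum(len(rep.violations) for _ in [0]) <= len(rs)

    def test_k_equal_one_is_full_tf(self):
        e, rs = _restraint_set(12)
        full = violation_tf(rs, e).tf
        assert jackknife(rs, e, k=1, seed=0).tf == pytest.approx(full)

    def test_partials_sum_to_total(self):
        e, rs = _restraint_set(20)
        rep = jackknife(rs, e, k=10, seed=3)
        assert rep.tf == pytest.approx(sum(rep.partials))
        # additivity of sum v^2: fold-wise evaluation equals full evaluation
        assert rep.tf == pytest.approx(violation_tf(rs, e).tf)

    def test_k_larger_than_n_raises(self):
        e, rs = _restraint_set(5)
        with pytest.raises(ValueError):
            jackknife(rs, e, k=10, seed=0)

    def test_seed_reproducibility(self):
        e, rs = _restraint_set(20)
        a = jackknife(rs, e, k=10, seed=7)
        b = jackknife(rs, e, k=10, seed=7)
        assert a.partials == b.partials


class TestPrunePeaks:
    def _ids(self, n_diag=20, n_cross=40):
        diag = [_aid(i) for i in range(1, n_diag + 1)]
        rng = np.random.default_rng(0)
        cross = []
        seen = set()
        while len(cross) < n_cross:
            i, j = rng.choice(n_diag, 2, replace=False) + 1
            if (i, j) not in seen:
                seen.add((i, j))
                cross.append((_aid(int(i)), _aid(int(j))))
        return diag, cross

    def test_zero_fraction_is_identity(self):
        diag, cross = self._ids()
        res = prune_peaks(diag, cross, 0.0, seed=1)
        assert res.kept_diagonals == diag
        assert res.kept_cross == cross
        assert all(c == "bidirectional" for c in res.classification.values())

    def test_two_to_one_deletion_arithmetic(self):
        diag, cross = self._ids(20, 40)
        res = prune_peaks(diag, cross, 0.35, seed=1)
        assert len(res.kept_diagonals) == 20 - int(0.7 * 20)
        assert len(res.kept_cross) == 40 - int(0.35 * 40)

    def test_out_of_range_fraction(self):
        diag, cross = self._ids()
        with pytest.raises(ValueError):
            prune_peaks(diag, cross, 0.6, seed=0)

    def test_reproducible_bit_for_bit(self):
        diag, cross = self._ids()
        a = prune_peaks(diag, cross, 0.3, seed=11)
        b = prune_peaks(diag, cross, 0.3, seed=11)
        assert a.kept_diagonals == b.kept_diagonals
        assert a.classification == b.classification

    @settings(max_examples=30, deadline=None)
    @given(seed=st.integers(0, 10_000), f=st.floats(0.0, 0.5))
    def test_demotion_chain_consistency(self, seed, f):
        """Classes only come from the demotion chain and depend exactly on
        the surviving diagonals: no restraint ever gains a class."""
        diag, cross = self._ids(12, 20)
        res = prune_peaks(diag, cross, f, seed=seed)
        kept = set(res.kept_diagonals)
        for pair, cls in res.classification.items():
            if cls is None:
                continue
            n = sum(1 for a in pair if a in kept)
            assert cls == ("gn", "unidirectional", "bidirectional")[n]
            assert cls in ("bidirectional", "unidirectional", "gn")
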