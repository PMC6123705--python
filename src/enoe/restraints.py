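"""Distance restraints from cross-relaxation rates, and ensemble validation.

The cross-relaxation rate of a rigid pair scales as sigma ~ r^-6, so a
fitted sigma inverts to an effective distance

    r = ( K [6 J(2 w0) - J(0)] / sigma )^(1/6)

using the same rate convention as :mod:`enoe.relaxation`.  Restraint bounds
follow the direction class: bidirectional pairs (both cross peaks fitted)
get upper = lower = r; unidirectional pairs get +-10%; gn (generic
normalized) pairs get an upper limit of 1.1 r and no lower bound.

Ensemble validation compares restraints with conformer bundles via r^-6 or
linear distance averaging, a target function TF = sum of squared violations
(A^2), jack-knife cross-validation over restraint folds, and the
peak-pruning experiment that emulates the growing spectral overlap of
larger RNAs (diagonal peaks are lost twice as fast as cross peaks).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import ENOEError, FitError
from .fitting import CrossFit
from .relaxation import ExperimentConditions, K_DIPOLAR, spectral_density, _ANG
from .spin_system_io import AtomId, Ensemble

__all__ = [
    "DistanceRestraint",
    "ComparisonStats",
    "ValidationReport",
    "sigma_to_distance",
    "make_restraint",
    "ensemble_distance",
    "compare_distances",
    "violation_tf",
    "jackknife",
    "prune_peaks",
    "restraints_from_bounds",
]

#: fractional tolerance applied to uni-directional and gn restraints
TOLERANCE = 0.10
#: violations at least this large (A) are highlighted separately
HIGHLIGHT_THRESHOLD = 0.2


@dataclass(frozen=True)
class DistanceRestraint:
    """An eNOE-derived distance restraint.

    bidirectional: upper = lower = r_eff (no tolerance);
    unidirectional: upper = 1.1 r_eff, lower = 0.9 r_eff;
    gn: upper = 1.1 r_eff, no lower bound.
    """

    pair: tuple[AtomId, AtomId]
    r_eff: float
    restraint_class: str  # bidirectional | unidirectional | gn
    upper: float
    lower: float | None
    source: CrossFit | None = None

    def __post_init__(self) -> None:
        if self.restraint_class not in ("bidirectional", "unidirectional", "gn"):
            raise ValueError(f"unknown restraint class {self.restraint_class!r}")


@dataclass
class ComparisonStats:
    """Through-origin regression statistics between two distance sets."""

    slope_through_origin: float
    pearson_r: float
    n_pairs: int
    subgroups: dict[str, "ComparisonStats"] = field(default_factory=dict)


@dataclass
class ValidationReport:
    """Restraint-violation summary against an ensemble.

    ``violations`` is per restraint (a pair may carry several restraints):
    a list of ``(pair, violation in A)`` in evaluation order.
    """

    tf: float  # A^2, sum of squared violations
    violations: list[tuple[tuple[AtomId, AtomId], float]]
    effective_distances: dict[tuple[AtomId, AtomId], float]
    highlighted: list[tuple[AtomId, AtomId]]  # violation >= 0.2 A
    skipped: list[tuple[AtomId, AtomId]]
    partials: list[float] = field(default_factory=list)

    @property
    def n_violated(self) -> int:
        return sum(1 for _, v in self.violations if v > 0)


def _sigma_per_r6(cond: ExperimentConditions) -> float:
    """sigma * r^6 (in s^-1 A^6) at the given conditions."""
    w0 = cond.omega0
    j0 = spectral_density(0.0, cond.tau_c)
    j2 = spectral_density(2.0 * w0, cond.tau_c)
    return K_DIPOLAR * (6.0 * j2 - j0) / _ANG**6


def sigma_to_distance(sigma, cond: ExperimentConditions) -> float:
    """Convert a cross-relaxation rate (s^-1) to an effective distance (A).

    ``sigma`` may be a scalar or an iterable of the two directions' rates,
    which are averaged before conversion (bidirectional pairs). The sign of
    sigma must match the tumbling regime (negative for slow tumbling); a
    wrong sign usually indicates a mis-set tau_c.
    """
    s = float(np.mean(np.asarray(sigma, dtype=float)))
    c = _sigma_per_r6(cond)
    if s == 0 or np.sign(s) != np.sign(c):
        raise ENOEError(
            f"sigma = {s:g} s^-1 has the wrong sign for these conditions "
            f"(expected sign {int(np.sign(c))}); check tau_c"
        )
    return float((c / s) ** (1.0 / 6.0))


def make_restraint(
    fit: CrossFit,
    cond: ExperimentConditions,
    restraint_class: str | None = None,
) -> DistanceRestraint:
    """Build the classed restraint for a (non-rejected) cross fit.

    The class defaults to the fit's direction class; pass ``"gn"`` for
    fits normalized with group upper-limit parameters.
    """
    if "rejected" in fit.flags:
        raise FitError(f"cross fit {fit.pair} was rejected by quality filtering")
    cls = restraint_class or fit.direction_class
    r = sigma_to_distance([s for s in (fit.sigma_ij, fit.sigma_ji) if s is not None],
                          cond)
    if cls == "bidirectional":
        upper = lower = r
    elif cls == "unidirectional":
        upper, lower = (1 + TOLERANCE) * r, (1 - TOLERANCE) * r
    elif cls == "gn":
        upper, lower = (1 + TOLERANCE) * r, None
    else:
        raise ValueError(f"unknown restraint class {cls!r}")
    return DistanceRestraint(pair=fit.pair, r_eff=r, restraint_class=cls,
                             upper=upper, lower=lower, source=fit)


def ensemble_distance(e: Ensemble, pair, mode: str = "r6") -> float:
    """Effective distance of an atom pair over an ensemble (A).

    ``mode="r6"`` returns <r^-6>^(-1/6), the average the NOE physically
    reports; ``mode="linear"`` returns <r>.
    """
    i, j = e.index(pair[0]), e.index(pair[1])
    r = np.linalg.norm(e.coordinates[:, i, :] - e.coordinates[:, j, :], axis=1)
    if mode == "r6":
        return float(np.mean(r**-6.0) ** (-1.0 / 6.0))
    if mode == "linear":
        return float(np.mean(r))
    raise ValueError("mode must be 'r6' or 'linear'")


def _pair_group(classes: tuple[str, str] | None) -> str:
    """Subgroup label: within amino/methylene pairs, mixed, or neither."""
    if classes is None:
        return "unclassified"
    special = {"amino", "methylene"}
    n = sum(1 for c in classes if c in special)
    return ("within_amino_methylene", "mixed", "non_amino_methylene")[2 - n]


def compare_distances(a: dict, b: dict, classes: dict | None = None) -> ComparisonStats:
    """Compare two distance sets over their shared pairs.

    ``a`` and ``b`` map pairs to distances (A); the through-origin slope
    sum(xy)/sum(x^2) regresses b on a, with a Pearson correlation alongside.
    ``classes`` optionally maps each pair to its two protons' group classes
    for the three-way subgroup breakdown (non-amino/methylene pairs, mixed,
    within amino/methylene).
    """
    shared = sorted(set(a) & set(b))
    if len(shared) < 3:
        raise ENOEError(f"only {len(shared)} shared pair(s); need at least 3")
    stats = _regress([a[p] for p in shared], [b[p] for p in shared])
    if classes is not None:
        groups: dict[str, list] = {}
        for p in shared:
            groups.setdefault(_pair_group(classes.get(p)), []).append(p)
        for name, pairs in groups.items():
            if len(pairs) >= 3:
                stats.subgroups[name] = _regress(
                    [a[p] for p in pairs], [b[p] for p in pairs]
                )
    return stats


def _regress(x, y) -> ComparisonStats:
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    slope = float(np.sum(x * y) / np.sum(x * x))
    if np.std(x) == 0 or np.std(y) == 0:
        r = 1.0 if np.allclose(y, slope * x) else float("nan")
    else:
        r = float(np.corrcoef(x, y)[0, 1])
    return ComparisonStats(slope_through_origin=slope, pearson_r=r, n_pairs=len(x))


def _effective_distance(e: Ensemble, pair, averaging: str, conformer=None) -> float:
    if averaging == "r6_over_states":
        return ensemble_distance(e, pair, mode="r6")
    if averaging == "per_conformer":
        i, j = e.index(pair[0]), e.index(pair[1])
        return float(np.linalg.norm(
            e.coordinates[conformer, i, :] - e.coordinates[conformer, j, :]
        ))
    raise ValueError("averaging must be 'per_conformer' or 'r6_over_states'")


def violation_tf(
    restraints,
    e: Ensemble,
    averaging: str = "r6_over_states",
    conformer: int = 0,
    highlight: float = HIGHLIGHT_THRESHOLD,
) -> ValidationReport:
    """Evaluate restraint violations against an ensemble.

    With ``averaging="r6_over_states"`` the restraint is tested against the
    r^-6-averaged distance across all states (the multi-state logic: the
    states must satisfy the restraint on average, not individually); with
    ``"per_conformer"`` it is tested against the single conformer
    ``conformer``. The target function is TF = sum of squared violations
    (A^2); violations of at least ``highlight`` (0.2 A by default) are
    listed separately. Restraints whose atoms are not resolvable in the
    ensemble are skipped with a warning.
    """
    violations = []
    distances = {}
    highlighted = []
    skipped = []
    for r in restraints:
        try:
            d = _effective_distance(e, r.pair, averaging, conformer)
        except KeyError:
            skipped.append(r.pair)
            continue
        v = max(0.0, d - r.upper)
        if r.lower is not None:
            v += max(0.0, r.lower - d)
        if v < 1e-9:  # numerical dust is not a violation
            v = 0.0
        violations.append((r.pair, v))
        distances[r.pair] = d
        if v >= highlight:
            highlighted.append(r.pair)
    if skipped:
        warnings.warn(
            f"skipped {len(skipped)} restraint(s) with unresolvable atoms",
            stacklevel=2,
        )
    tf = float(sum(v**2 for _, v in violations))
    return ValidationReport(tf=tf, violations=violations,
                            effective_distances=distances,
                            highlighted=highlighted, skipped=skipped)


def jackknife(
    restraints,
    e: Ensemble,
    k: int = 10,
    seed: int = 0,
    averaging: str = "r6_over_states",
) -> ValidationReport:
    """k-fold jack-knife cross-validation of a restraint set.

    The restraints are randomly partitioned (seeded) into ``k`` folds, each
    restraint held out exactly once; each fold's held-out partial TF is
    evaluated against the supplied ensemble, and the cross-validation TF is
    the sum of the partials. (This evaluates a given bundle; it does not
    recompute structures.)
    """
    restraints = list(restraints)
    if k < 1 or k > len(restraints):
        raise ValueError(f"k = {k} must be between 1 and {len(restraints)}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(restraints))
    folds = np.array_split(perm, k)
    partials = []
    violations = []
    distances = {}
    highlighted = []
    skipped = []
    for fold in folds:
        rep = violation_tf([restraints[i] for i in fold], e, averaging=averaging)
        partials.append(rep.tf)
        violations.extend(rep.violations)
        distances.update(rep.effective_distances)
        highlighted.extend(rep.highlighted)
        skipped.extend(rep.skipped)
    return ValidationReport(tf=float(sum(partials)), violations=violations,
                            effective_distances=distances,
                            highlighted=highlighted, skipped=skipped,
                            partials=partials)


def restraints_from_bounds(upper_entries, lower_entries=None) -> list[DistanceRestraint]:
    """Reconstruct classed restraints from parsed .upl/.lol entries.

    Entries are ``(atom_a, atom_b, bound)`` triples as returned by
    :func:`enoe.spin_system_io.read_restraint_table`.  A pair with equal
    upper and lower bound is bidirectional; unequal bounds mean
    unidirectional (+-10% around r_eff); an upper bound without a lower one
    is a gn restraint (upper = 1.1 r_eff).
    """
    lowers = {}
    for a, b, v in (lower_entries or []):
        lowers[frozenset((a, b))] = v
    out = []
    for a, b, up in upper_entries:
        lo = lowers.get(frozenset((a, b)))
        if lo is None:
            out.append(DistanceRestraint((a, b), up / (1 + TOLERANCE), "gn", up, None))
        elif np.isclose(lo, up):
            out.append(DistanceRestraint((a, b), up, "bidirectional", up, lo))
        else:
            out.append(DistanceRestraint((a, b), up / (1 + TOLERANCE),
                                         "unidirectional", up, lo))
    return out


@dataclass
class PruneResult:
    """Outcome of the overlap-emulating peak-deletion experiment."""

    kept_diagonals: list
    kept_cross: list
    classification: dict  # cross pair -> class or None (restraint lost)


def prune_peaks(diagonal_ids, cross_ids, fraction_cross: float, seed: int = 0) -> PruneResult:
    """Delete diagonal and cross peaks in a 2:1 ratio and reclassify.

    ``fraction_cross`` of the cross peaks (and twice that fraction of the
    diagonal peaks — diagonal overlap grows faster, since only one
    resonance needs to coincide) are deleted uniformly at random, seeded.
    Each surviving cross peak is reclassified by its surviving diagonals:
    both -> bidirectional, one -> unidirectional, none -> gn; deleted cross
    peaks lose their restraint (class ``None``).
    """
    if not 0.0 <= fraction_cross <= 0.5:
        raise ValueError("fraction_cross must be within [0, 0.5]")
    diagonal_ids = list(diagonal_ids)
    cross_ids = list(cross_ids)
    rng = np.random.default_rng(seed)
    n_del_diag = int(np.floor(2.0 * fraction_cross * len(diagonal_ids)))
    n_del_cross = int(np.floor(fraction_cross * len(cross_ids)))
    del_diag = set(rng.choice(len(diagonal_ids), size=n_del_diag, replace=False).tolist()) if n_del_diag else set()
    del_cross = set(rng.choice(len(cross_ids), size=n_del_cross, replace=False).tolist()) if n_del_cross else set()
    kept_diag = [d for i, d in enumerate(diagonal_ids) if i not in del_diag]
    kept_diag_set = set(kept_diag)
    kept_cross = [c for i, c in enumerate(cross_ids) if i not in del_cross]
    classification = {}
    for i, pair in enumerate(cross_ids):
        if i in del_cross:
            classification[pair] = None
            continue
        n_diag = sum(1 for a in pair if a in kept_diag_set)
        classification[pair] = ("gn", "unidirectional", "bidirectional")[n_diag]
    return PruneResult(kept_diagonals=kept_diag, kept_cross=kept_cross,
                       classification=classification)
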