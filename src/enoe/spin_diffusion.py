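"""Full-matrix spin-diffusion corrections for NOESY buildups.

Indirect (relayed) magnetization transfer through intermediate protons
inflates or deflates measured cross peaks relative to the isolated-pair
behavior that buildup fitting assumes.  The correction for a pair (i, j) at
mixing time tau_m is the ratio of the simulated isolated two-spin intensity
to the simulated full-matrix intensity, both computed from a reference
structure (or averaged over a reference ensemble's conformers) with uniform
initial magnetization.  Multiplying a measured intensity by its factor
restores an effective isolated-pair buildup.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .relaxation import (
    ExperimentConditions,
    build_relaxation_matrix,
    transfer_matrices,
    two_spin_closed_form,
)
from .spin_system_io import BuildupSeries, BuildupSet, SpinSystem
from .errors import ENOEError

__all__ = ["CorrectionSet", "correction_factors", "apply_corrections"]

#: simulated full-matrix intensities below this are considered vanished
_INTENSITY_FLOOR = 1e-12


@dataclass
class CorrectionSet:
    """Per-pair, per-mixing-time spin-diffusion correction factors.

    ``factors[(i, j)][k]`` multiplies the measured intensity of cross peak
    (i, j) at ``mixing_times[k]``; NaN marks a (pair, time) whose simulated
    full-matrix intensity vanished and which must be excluded from fitting.
    Diagonal pairs (i, i) may carry factors too (ratio of the pure
    monoexponential decay exp(-rho_i tau) to the full-matrix diagonal).
    """

    mixing_times: np.ndarray
    factors: dict[tuple, np.ndarray]
    reference_label: str = ""

    def __post_init__(self) -> None:
        self.mixing_times = np.asarray(self.mixing_times, dtype=float)

    def usable(self, pair) -> np.ndarray:
        return np.isfinite(self.factors[pair])


def correction_factors(
    s: SpinSystem,
    cond: ExperimentConditions,
    mixing_times,
    pairs,
    cutoff: float | None = None,
) -> CorrectionSet:
    """Compute spin-diffusion correction factors from a reference structure.

    For every conformer of ``s`` the full relaxation matrix is propagated
    and the isolated two-spin system of each requested pair (same rho_i,
    rho_j, sigma_ij, uniform initial magnetization) is solved analytically;
    intensities are averaged over conformers *before* taking the ratio
    factor = <two-spin> / <full-matrix>, so that the factor corrects the
    conformer-averaged observable.
    """
    taus = np.asarray(mixing_times, dtype=float)
    if np.any(taus <= 0):
        raise ValueError("mixing times must be positive")
    pairs = list(pairs)
    idx = {}
    for pair in pairs:
        i, j = s.index(pair[0]), s.index(pair[1])
        idx[pair] = (i, j)

    n_conf = s.n_conformers
    full = {p: np.zeros_like(taus) for p in pairs}
    iso = {p: np.zeros_like(taus) for p in pairs}
    for c in range(n_conf):
        R = build_relaxation_matrix(s, c, cond, cutoff=cutoff)
        A = transfer_matrices(R, taus)  # (n_tau, n, n)
        for p, (i, j) in idx.items():
            full[p] += A[:, i, j]
            if i == j:
                iso[p] += np.exp(-R.rates[i, i] * taus)
            else:
                _, _, I_ij, _ = two_spin_closed_form(
                    R.rates[i, i], R.rates[j, j], R.rates[i, j], 1.0, 1.0, taus
                )
                iso[p] += I_ij
    flagged = 0
    factors = {}
    for p in pairs:
        fm = full[p] / n_conf
        tw = iso[p] / n_conf
        f = np.full_like(taus, np.nan)
        ok = np.abs(fm) > _INTENSITY_FLOOR
        f[ok] = tw[ok] / fm[ok]
        flagged += int(np.sum(~ok))
        factors[p] = f
    if flagged:
        warnings.warn(
            f"{flagged} (pair, mixing-time) point(s) have vanishing simulated "
            "intensity; marked unusable",
            stacklevel=2,
        )
    return CorrectionSet(mixing_times=taus, factors=factors,
                         reference_label=s.source_label)


def apply_corrections(
    b: BuildupSet,
    c: CorrectionSet,
    correct_diagonals: bool = False,
) -> BuildupSet:
    """Multiply measured cross-peak intensities by their correction factors.

    Diagonal series are left unchanged unless ``correct_diagonals`` is set
    and diagonal factors are present.  Points whose factor is marked
    unusable are dropped with a warning.  Applying corrections twice is an
    error (the flag on the returned BuildupSet guards multiplicativity).
    """
    if b.corrected:
        raise ENOEError("BuildupSet is already corrected")
    out = {}
    dropped = 0
    for key, ser in b.series.items():
        if ser.is_diagonal and not correct_diagonals:
            out[key] = ser
            continue
        if key not in c.factors:
            if ser.is_diagonal:
                out[key] = ser
                continue
            raise ENOEError(f"no correction factors for cross peak {key[0]}-{key[1]}")
        f = _factors_at(c, key, ser.mixing_times)
        ok = np.isfinite(f)
        dropped += int(np.sum(~ok))
        out[key] = BuildupSeries(
            pair=ser.pair,
            mixing_times=ser.mixing_times[ok],
            intensities=ser.intensities[ok] * f[ok],
            noise=None if ser.noise is None else ser.noise[ok] * f[ok],
            peak_id=ser.peak_id,
        )
    if dropped:
        warnings.warn(f"dropped {dropped} uncorrectable point(s)", stacklevel=2)
    return BuildupSet(series=out, corrected=True)


def _factors_at(c: CorrectionSet, pair, times: np.ndarray) -> np.ndarray:
    out = np.empty_like(times)
    for k, t in enumerate(times):
        hit = np.flatnonzero(np.isclose(c.mixing_times, t, rtol=1e-9, atol=1e-12))
        if hit.size == 0:
            raise ENOEError(
                f"no correction factor for {pair[0]}-{pair[1]} at tau_m = {t:g} s"
            )
        out[k] = c.factors[pair][hit[0]]
    return out
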