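"""Model/Results facade over the eNOE extraction pipeline.

:class:`NOESYBuildupModel` bundles the experimental observables (a
:class:`~enoe.spin_system_io.BuildupSet`), the proton network used for
spin-diffusion simulation, and the experiment conditions; ``fit()`` runs
the full protocol — correct, fit diagonals, fit cross peaks, classify,
convert to distances — and returns a :class:`NOESYBuildupResults` carrying
rates, distances, restraints and quality diagnostics, with ``summary()``
and ``to_frame()`` for reporting and ``validate()`` for checking conformer
bundles against the extracted restraints.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ENOEError
from .fitting import (
    CrossFit,
    DecayFit,
    DEFAULT_FIT_RANGE,
    FitThresholds,
    fit_cross,
    fit_diagonal,
    gn_parameters,
    quality_filter,
)
from .relaxation import ExperimentConditions
from .restraints import make_restraint, violation_tf
from .spin_diffusion import apply_corrections, correction_factors
from .spin_system_io import (
    BuildupSet,
    SpinSystem,
    make_spin_system,
    read_buildup_table,
    read_ensemble,
    write_restraints,
)

__all__ = ["NOESYBuildupModel", "NOESYBuildupResults"]


class NOESYBuildupModel:
    """Exact-NOE extraction from a NOESY buildup series.

    Parameters
    ----------
    buildups : BuildupSet
        Diagonal and cross-peak intensity series.
    spin_system : SpinSystem
        Proton network of the reference structure (or ensemble) used for
        the full-matrix spin-diffusion simulation.
    conditions : ExperimentConditions
        tau_c, spectrometer frequency, fallback auto-relaxation rate.
    fit_range : (float, float)
        Mixing-time window (s) used for all fits; default 40-160 ms.
    thresholds : FitThresholds
        Numeric stand-in for visual fit evaluation.
    """

    def __init__(
        self,
        buildups: BuildupSet,
        spin_system: SpinSystem,
        conditions: ExperimentConditions,
        fit_range: tuple[float, float] = DEFAULT_FIT_RANGE,
        thresholds: FitThresholds = FitThresholds(),
    ) -> None:
        self.buildups = buildups
        self.spin_system = spin_system
        self.conditions = conditions
        self.fit_range = fit_range
        self.thresholds = thresholds

    @classmethod
    def from_files(
        cls,
        peaks_text: str,
        pdb_text: str,
        tau_c_ns: float,
        field_mhz: float,
        include_exchangeable: bool = True,
        time_unit: str = "s",
        **kwargs,
    ) -> "NOESYBuildupModel":
        """Build a model from a buildup table and a (multi-model) PDB text."""
        buildups = read_buildup_table(peaks_text, time_unit=time_unit)
        ensemble = read_ensemble(pdb_text)
        spins = make_spin_system(ensemble, include_exchangeable=include_exchangeable)
        cond = ExperimentConditions(tau_c=tau_c_ns * 1e-9, larmor_frequency=field_mhz)
        return cls(buildups, spins, cond, **kwargs)

    # -- fitting ----------------------------------------------------------

    def fit(
        self,
        correct: bool = True,
        correct_diagonals: bool = True,
        use_gn: bool = True,
    ) -> "NOESYBuildupResults":
        """Run the extraction protocol and return the results object.

        ``correct_diagonals`` extends the spin-diffusion correction to the
        diagonal decays (restoring monoexponential behavior before the
        rho/DM0 fits), which is how the corrections make the whole protocol
        self-consistent; switch it off to correct cross peaks only.
        """
        b = self.buildups
        correction = None
        if correct and not b.corrected:
            taus = _union_mixing_times(b, self.fit_range)
            pairs = [k for k in b.series
                     if k[0] in self.spin_system and k[1] in self.spin_system
                     and (correct_diagonals or k[0] != k[1])]
            correction = correction_factors(self.spin_system, self.conditions,
                                            taus, pairs)
            b = apply_corrections(b, correction, correct_diagonals=correct_diagonals)

        decays: dict = {}
        for atom, ser in b.diagonals().items():
            decays[atom] = fit_diagonal(ser, self.fit_range, self.conditions,
                                        min_r2=self.thresholds.min_diagonal_r2)
        decays = {a: f for a, f in
                  zip(decays, quality_filter(decays.values(), self.thresholds))}

        gn_params = self._gn_parameters(decays) if use_gn else {}
        cross_fits = self._fit_cross_peaks(b, decays, gn_params)
        cross_fits = quality_filter(cross_fits, self.thresholds)

        restraints = []
        for cf in cross_fits:
            if "rejected" in cf.flags or "sigma_precision" in cf.flags:
                continue
            cls = "gn" if "gn" in cf.flags else None
            restraints.append(make_restraint(cf, self.conditions, restraint_class=cls))

        return NOESYBuildupResults(
            model=self, buildups=b, decay_fits=decays, cross_fits=cross_fits,
            restraints=restraints, correction=correction, gn_params=gn_params,
        )

    def _gn_parameters(self, decays: dict) -> dict:
        """Group upper-limit (dM0, rho) from the successfully fitted decays."""
        groups: dict[str, list[DecayFit]] = {}
        for atom, d in decays.items():
            if d.fallback_used:
                continue
            cls = self.spin_system.group_class[self.spin_system.index(atom)] \
                if atom in self.spin_system else "other"
            groups.setdefault(cls, []).append(d)
        return {g: gn_parameters(g, ds) for g, ds in groups.items()}

    def _fit_cross_peaks(self, b: BuildupSet, decays: dict, gn_params: dict):
        thresholds = self.thresholds
        seen = set()
        fits = []
        for (ai, aj) in list(b.cross_peaks()):
            if frozenset((ai, aj)) in seen:
                continue
            seen.add(frozenset((ai, aj)))
            s_ij = b.series.get((ai, aj))
            s_ji = b.series.get((aj, ai))
            d_i, d_j = decays.get(ai), decays.get(aj)
            ok_i = d_i is not None and d_i.passes(thresholds)
            ok_j = d_j is not None and d_j.passes(thresholds)
            try:
                if ok_i and ok_j and s_ij is not None and s_ji is not None:
                    fits.append(fit_cross(s_ij, d_i, d_j, self.fit_range,
                                          series_reverse=s_ji))
                elif ok_i and s_ij is not None:
                    fits.append(fit_cross(s_ij, d_i, d_j or d_i, self.fit_range))
                elif ok_j and s_ji is not None:
                    fits.append(fit_cross(s_ji, d_j, d_i or d_j, self.fit_range))
                elif ok_j and s_ij is not None:
                    # destination normalization: the origin's diagonal is
                    # unusable but the destination's is clean
                    cf = fit_cross(s_ij, d_j, d_j, self.fit_range)
                    fits.append(
                        CrossFit(pair=(ai, aj), sigma_ij=cf.sigma_ij,
                                 sigma_ij_rel_stderr=cf.sigma_ij_rel_stderr,
                                 r_squared_ij=cf.r_squared_ij,
                                 normalization="destination",
                                 n_points=cf.n_points)
                    )
                elif gn_params and (s_ij is not None or s_ji is not None):
                    ser = s_ij if s_ij is not None else s_ji
                    origin = ser.pair[0]
                    cls = self.spin_system.group_class[self.spin_system.index(origin)] \
                        if origin in self.spin_system else "other"
                    if cls not in gn_params:
                        continue
                    dm0_up, rho_up = gn_params[cls]
                    gn_decay = DecayFit(atom=origin, rho=rho_up, dM0=dm0_up,
                                        fit_range=self.fit_range, fallback_used=True)
                    dest = decays.get(ser.pair[1]) or gn_decay
                    cf = fit_cross(ser, gn_decay, dest, self.fit_range)
                    fits.append(CrossFit(pair=ser.pair, sigma_ij=cf.sigma_ij,
                                         sigma_ij_rel_stderr=cf.sigma_ij_rel_stderr,
                                         r_squared_ij=cf.r_squared_ij,
                                         n_points=cf.n_points, flags=("gn",)))
                else:
                    fits.append(CrossFit(pair=(ai, aj), sigma_ij=None,
                                         flags=("rejected",)))
            except ENOEError:
                fits.append(CrossFit(pair=(ai, aj), sigma_ij=None,
                                     flags=("rejected",)))
        return fits


@dataclass
class NOESYBuildupResults:
    """Fitted rates, distances and restraints from a NOESY buildup series."""

    model: NOESYBuildupModel
    buildups: BuildupSet
    decay_fits: dict
    cross_fits: list
    restraints: list
    correction: object | None = None
    gn_params: dict = field(default_factory=dict)

    @property
    def conditions(self) -> ExperimentConditions:
        return self.model.conditions

    def distances(self) -> dict:
        """Pair -> effective eNOE distance (A) for all accepted fits."""
        out = {}
        for r in self.restraints:
            out[r.pair] = r.r_eff
        return out

    def to_frame(self) -> pd.DataFrame:
        """One row per restraint with rates, class and bounds."""
        rows = []
        for r in self.restraints:
            cf = r.source
            rows.append({
                "atom_i": str(r.pair[0]), "atom_j": str(r.pair[1]),
                "class": r.restraint_class,
                "sigma_ij": None if cf is None else cf.sigma_ij,
                "sigma_ji": None if cf is None else cf.sigma_ji,
                "r_eff": r.r_eff, "upper": r.upper, "lower": r.lower,
            })
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Human-readable fit report."""
        n_diag = len(self.decay_fits)
        n_fb = sum(d.fallback_used for d in self.decay_fits.values())
        classes = {}
        for r in self.restraints:
            classes[r.restraint_class] = classes.get(r.restraint_class, 0) + 1
        n_rej = sum(1 for c in self.cross_fits
                    if "rejected" in c.flags or "sigma_precision" in c.flags)
        cond = self.conditions
        lines = [
            "eNOE buildup fit results",
            "=" * 60,
            f"conditions:       tau_c = {cond.tau_c * 1e9:.2f} ns, "
            f"{cond.larmor_frequency:.0f} MHz",
            f"fit range:        {self.model.fit_range[0] * 1e3:.0f}-"
            f"{self.model.fit_range[1] * 1e3:.0f} ms",
            f"corrected:        {self.buildups.corrected}",
            f"diagonal decays:  {n_diag} fitted ({n_fb} fallback rho = "
            f"{cond.rho_fallback:g} 1/s)",
            f"cross fits:       {len(self.cross_fits)} ({n_rej} rejected/flagged)",
            "restraints:       "
            + ", ".join(f"{v} {k}" for k, v in sorted(classes.items()))
            + (f" ({len(self.restraints)} total)" if classes else "none"),
        ]
        df = self.to_frame()
        if not df.empty:
            lines += ["-" * 60, df.to_string(index=False, float_format="%.3f")]
        return "\n".join(lines)

    # -- downstream conveniences -----------------------------------------

    def write_restraints(self, dialect: str) -> str:
        """CYANA-style .upl / .lol text for the accepted restraints."""
        return write_restraints(self.restraints, dialect)

    def validate(self, ensemble, averaging: str = "r6_over_states"):
        """Violation report of the extracted restraints against a bundle."""
        return violation_tf(self.restraints, ensemble, averaging=averaging)

    def plot_buildup(self, pair, ax=None):
        """Plot one (corrected) buildup with its fitted curve."""
        import matplotlib.pyplot as plt

        from .relaxation import two_spin_closed_form

        if ax is None:
            _, ax = plt.subplots()
        ser = self.buildups.series[pair]
        ax.plot(ser.mixing_times * 1e3, ser.intensities, "o", label="data")
        cf = next((c for c in self.cross_fits if set(c.pair) == set(pair)), None)
        d_i, d_j = self.decay_fits.get(pair[0]), self.decay_fits.get(pair[1])
        if cf is not None and cf.sigma_ij is not None and d_i and d_j:
            t = np.linspace(0, ser.mixing_times[-1], 200)
            _, _, I_ij, _ = two_spin_closed_form(
                d_i.rho, d_j.rho, cf.sigma_ij, d_i.dM0, d_j.dM0, t)
            ax.plot(t * 1e3, I_ij, "-", label="fit")
        ax.set_xlabel("mixing time (ms)")
        ax.set_ylabel("intensity")
        ax.set_title(f"{pair[0]} - {pair[1]}")
        ax.legend()
        return ax


def _union_mixing_times(b: BuildupSet, fit_range) -> np.ndarray:
    taus = sorted({round(float(t), 9) for s in b.series.values()
                   for t in s.mixing_times})
    if not taus:
        raise ENOEError("empty buildup set")
    return np.array(taus)
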