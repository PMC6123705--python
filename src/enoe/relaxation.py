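"""Homonuclear dipolar relaxation rates and NOESY magnetization transfer.

The magnetization deviations DM(t) of a network of protons obey the Solomon
equations dDM/dt = -R DM, with auto-relaxation rates rho_i on the diagonal
of R and cross-relaxation rates sigma_ij off the diagonal.  For rigid
isotropic tumbling with correlation time tau_c the rates of a proton pair at
distance r are

    sigma    = K r^-6 [6 J(2 w0) - J(0)]
    rho_pair = K r^-6 [J(0) + 3 J(w0) + 6 J(2 w0)]

with the Lorentzian spectral density J(w) = tau_c / (1 + (w tau_c)^2) and
K = (1/10) ((mu0/4pi) hbar gammaH^2)^2.  The NOESY transfer matrix over a
mixing time tau_m is A(tau_m) = exp(-R tau_m); its entries are normalized
peak intensities per unit initial magnetization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .errors import GeometryError

__all__ = [
    "GAMMA_H",
    "K_DIPOLAR",
    "ExperimentConditions",
    "RelaxationMatrix",
    "spectral_density",
    "pair_rates",
    "build_relaxation_matrix",
    "propagate",
    "two_spin_closed_form",
]

#: proton gyromagnetic ratio, rad s^-1 T^-1
GAMMA_H = 2.6752218744e8
_HBAR = 1.054571817e-34  # J s
_MU0_4PI = 1.0e-7  # T^2 m^3 J^-1

#: dipolar rate constant K, in m^6 s^-2 (divide by r^6 in meters)
K_DIPOLAR = 0.1 * (_MU0_4PI * _HBAR * GAMMA_H**2) ** 2

_ANG = 1.0e-10  # m per Angstrom
_MIN_R = 0.5  # Angstrom; below this two "protons" are considered overlapping


@dataclass
class ExperimentConditions:
    """NOESY experiment conditions.

    Parameters
    ----------
    tau_c : float
        Overall rotational correlation time in seconds (e.g. 2.23e-9 for the
        UUCG 14-mer in H2O).
    larmor_frequency : float
        Proton Larmor frequency in MHz (e.g. 900.0).
    rho_external : float
        Additive per-proton auto-relaxation in s^-1 (external leakage, e.g.
        solvent exchange); added to every diagonal entry. Default 0.
    rho_fallback : float
        Auto-relaxation rate in s^-1 used when a diagonal decay cannot be
        fitted. Default 2.9.
    """

    tau_c: float
    larmor_frequency: float
    rho_external: float = 0.0
    rho_fallback: float = 2.9

    def __post_init__(self) -> None:
        if self.tau_c <= 0:
            raise ValueError("tau_c must be positive")
        if self.larmor_frequency <= 0:
            raise ValueError("larmor_frequency must be positive")
        if self.rho_external < 0:
            raise ValueError("rho_external must be non-negative")

    @property
    def omega0(self) -> float:
        """Angular Larmor frequency in rad/s."""
        return 2.0 * np.pi * self.larmor_frequency * 1.0e6


def spectral_density(omega, tau_c: float):
    """Rigid isotropic Lorentzian J(w) = tau_c / (1 + (w tau_c)^2), in s."""
    if tau_c <= 0:
        raise ValueError("tau_c must be positive")
    omega = np.asarray(omega, dtype=float)
    out = tau_c / (1.0 + (omega * tau_c) ** 2)
    return out if out.ndim else float(out)


def pair_rates(r: float, cond: ExperimentConditions) -> tuple[float, float]:
    """Cross- and pairwise auto-relaxation rates (s^-1) for distance r (A).

    Returns ``(sigma, rho_pair)``.  In the slow-tumbling regime
    (w0 tau_c > ~1.12) sigma is negative.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= _MIN_R):
        raise GeometryError(f"interproton distance {np.min(r):g} A is below {_MIN_R} A")
    k = K_DIPOLAR / (r * _ANG) ** 6
    w0 = cond.omega0
    j0 = spectral_density(0.0, cond.tau_c)
    j1 = spectral_density(w0, cond.tau_c)
    j2 = spectral_density(2.0 * w0, cond.tau_c)
    sigma = k * (6.0 * j2 - j0)
    rho_pair = k * (j0 + 3.0 * j1 + 6.0 * j2)
    if sigma.ndim:
        return sigma, rho_pair
    return float(sigma), float(rho_pair)


@dataclass
class RelaxationMatrix:
    """Full relaxation matrix over a spin system's protons (s^-1).

    ``rates[i, i]`` is the total auto-relaxation of proton i (sum of its
    pairwise contributions plus any external rate); ``rates[i, j]`` is
    sigma_ij. The off-diagonal part is symmetric by construction.
    """

    rates: np.ndarray
    protons: list = field(default_factory=list)
    conditions: ExperimentConditions | None = None

    def __post_init__(self) -> None:
        self.rates = np.asarray(self.rates, dtype=float)
        n = self.rates.shape[0]
        if self.rates.shape != (n, n):
            raise ValueError("rates must be square")
        if not np.all(np.isfinite(self.rates)):
            raise ValueError("non-finite relaxation rate")


def build_relaxation_matrix(
    s,
    conformer_index: int,
    cond: ExperimentConditions,
    cutoff: float | None = None,
) -> RelaxationMatrix:
    """Assemble the full homonuclear relaxation matrix for one conformer.

    All proton pairs contribute by default; ``cutoff`` (A) restricts the
    network to pairs closer than the cutoff (a scalability affordance for
    large systems — the diagonal still accumulates every pair's rho).
    """
    xyz = s.coordinates[conformer_index]
    n = xyz.shape[0]
    if n < 2:
        raise ValueError("need at least two protons")
    diff = xyz[:, None, :] - xyz[None, :, :]
    r = np.sqrt((diff**2).sum(axis=-1))
    iu = np.triu_indices(n, k=1)
    too_close = r[iu] < _MIN_R
    if np.any(too_close):
        i, j = iu[0][too_close][0], iu[1][too_close][0]
        raise GeometryError(
            f"protons {s.protons[i]} and {s.protons[j]} overlap "
            f"(r = {r[i, j]:.3f} A < {_MIN_R} A)"
        )
    sigma, rho_pair = pair_rates(r[iu], cond)
    R = np.zeros((n, n))
    R[iu] = sigma
    R = R + R.T
    rho_tot = np.zeros(n)
    tmp = np.zeros((n, n))
    tmp[iu] = rho_pair
    tmp = tmp + tmp.T
    rho_tot = tmp.sum(axis=1) + cond.rho_external
    if cutoff is not None:
        mask = r > cutoff
        np.fill_diagonal(mask, False)
        R[mask] = 0.0
    np.fill_diagonal(R, rho_tot)
    return RelaxationMatrix(rates=R, protons=list(s.protons), conditions=cond)


def propagate(R: RelaxationMatrix, tau_m: float) -> np.ndarray:
    """NOESY transfer matrix A(tau_m) = exp(-R tau_m).

    Entry (i, j) is the normalized intensity contribution from spin j to
    peak i; A(0) is the identity.
    """
    if tau_m < 0:
        raise ValueError("tau_m must be non-negative")
    return scipy.linalg.expm(-R.rates * tau_m)


def transfer_matrices(R: RelaxationMatrix, mixing_times) -> np.ndarray:
    """A(tau) for several mixing times at once, shape (n_times, n, n).

    Uses the symmetric eigendecomposition of R (R is symmetric for any
    physical matrix built here).
    """
    w, v = scipy.linalg.eigh(R.rates)
    taus = np.asarray(mixing_times, dtype=float)
    return np.einsum("ik,tk,jk->tij", v, np.exp(-np.outer(taus, w)), v)


def two_spin_closed_form(rho_i, rho_j, sigma, dM_ii0, dM_jj0, tau_m):
    """Analytic Solomon solution for an isolated two-spin system.

    Returns ``(I_ii, I_jj, I_ij, I_ji)`` at mixing time(s) ``tau_m``, where
    ``I_ij`` is the cross peak fed by the initial magnetization of spin i
    (so I_ij(0) = 0 and I_ii(0) = dM_ii0).
    """
    tau = np.asarray(tau_m, dtype=float)
    if np.any(tau < 0):
        raise ValueError("tau_m must be non-negative")
    rbar = 0.5 * (rho_i + rho_j)
    delta = 0.5 * (rho_i - rho_j)
    lam = np.hypot(delta, sigma)
    x = lam * tau
    ch = np.cosh(x)
    # sinh(lam*tau)/lam, stable at lam -> 0
    with np.errstate(invalid="ignore", divide="ignore"):
        sh = np.where(x > 1e-8, np.sinh(x) / np.where(lam > 0, lam, 1.0), tau)
    damp = np.exp(-rbar * tau)
    a_ii = damp * (ch - delta * sh)
    a_jj = damp * (ch + delta * sh)
    a_cross = damp * (-sigma * sh)
    I_ii = dM_ii0 * a_ii
    I_jj = dM_jj0 * a_jj
    I_ij = dM_ii0 * a_cross
    I_ji = dM_jj0 * a_cross
    return I_ii, I_jj, I_ij, I_ji
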