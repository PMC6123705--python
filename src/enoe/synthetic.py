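"""Synthetic spin systems and NOESY buildups with known ground truth.

The fixture geometry is a deterministic parametric helix (an A-form-like
proton lattice): each residue contributes five protons including a geminal
methylene pair at ~1.78 A, with interproton distances spanning roughly
1.8-6 A. Buildups are simulated with the full relaxation matrix, so every
downstream stage (correction, fitting, distance conversion) can be tested
against exact truth without any experimental input.

Also houses the experiment-design helpers: Stokes-Einstein scaling of the
rotational correlation time with solvent viscosity, and the empirical
maximal NOESY mixing time tau_max = 4e-10 s^2 / tau_c for RNA
(2.5e-10 s^2 / tau_c for proteins).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .relaxation import ExperimentConditions, build_relaxation_matrix, transfer_matrices
from .spin_system_io import AtomId, BuildupSeries, BuildupSet, SpinSystem

__all__ = [
    "SyntheticTruth",
    "make_helix_spin_system",
    "simulate_noesy",
    "heterogeneous_dm0",
    "stokes_einstein_tau",
    "max_mixing_time",
    "snap_to_grid",
    "DEFAULT_MIXING_TIMES",
]

#: the eight-point NOESY mixing-time grid, seconds
DEFAULT_MIXING_TIMES = (0.04, 0.08, 0.12, 0.16, 0.20, 0.24, 0.28, 0.32)

_MIN_DISTANCE = 1.7  # A, construction constraint

# helix parameters: twist (deg), rise (A)
_TWIST = 32.0
_RISE = 2.70
# local proton offsets per residue: name -> (radial, tangential, axial), A
_PROTON_OFFSETS = {
    "H1'": (5.20, 0.00, 0.00),
    "H2'": (4.20, 1.20, 0.80),
    "H3'": (3.00, -0.50, 1.10),
    "H5'": (4.90, -1.50, 2.00),
    "H5''": (5.43, -0.61, 3.44),  # geminal partner of H5', ~1.78 A away
}
_RESIDUE_CYCLE = ("G", "C", "A", "U")


@dataclass
class SyntheticTruth:
    """Ground truth accompanying a synthetic spin system."""

    spin_system: SpinSystem
    distances: dict  # ordered pair (i < j by index) -> r^-6-averaged distance, A
    conditions: ExperimentConditions | None = None
    noise_sd_relative: float = 0.0
    seed: int = 0

    def distance(self, a: AtomId, b: AtomId) -> float:
        key = (a, b) if (a, b) in self.distances else (b, a)
        return self.distances[key]


def _base_coordinates(n_residues: int) -> tuple[list[AtomId], np.ndarray]:
    atoms = []
    xyz = []
    twist = np.radians(_TWIST)
    for k in range(n_residues):
        phi = k * twist
        u = np.array([np.cos(phi), np.sin(phi), 0.0])
        v = np.array([-np.sin(phi), np.cos(phi), 0.0])
        w = np.array([0.0, 0.0, 1.0])
        resname = _RESIDUE_CYCLE[k % len(_RESIDUE_CYCLE)]
        for name, (ru, tv, az) in _PROTON_OFFSETS.items():
            atoms.append(AtomId(k + 1, resname, name))
            xyz.append(ru * u + tv * v + (k * _RISE + az) * w)
    return atoms, np.array(xyz)


def _min_pair_distance(xyz: np.ndarray) -> float:
    d = np.linalg.norm(xyz[:, None, :] - xyz[None, :, :], axis=-1)
    iu = np.triu_indices(len(xyz), k=1)
    return float(d[iu].min())


def make_helix_spin_system(
    n_residues: int,
    conformers: int = 1,
    displacement: float = 0.0,
    seed: int = 0,
) -> tuple[SpinSystem, SyntheticTruth]:
    """Deterministic parametric helix of protons with known distances.

    Five protons per residue (including the geminal H5'/H5'' pair at
    ~1.78 A); ``displacement`` adds per-conformer Gaussian jitter of that
    RMS amplitude (seeded), applied rigidly per residue so covalent
    geometry is preserved, and redrawn if it would push any pair below
    1.7 A. The returned truth carries the r^-6-averaged pair distances of
    the generated coordinates.
    """
    if n_residues < 2:
        raise ValueError("need at least 2 residues")
    atoms, base = _base_coordinates(n_residues)
    rng = np.random.default_rng(seed)
    n_per_res = len(_PROTON_OFFSETS)
    coords = []
    for _ in range(conformers):
        if displacement > 0:
            for _attempt in range(200):
                jitter = rng.normal(scale=displacement / np.sqrt(3.0),
                                    size=(n_residues, 3))
                xyz = base + np.repeat(jitter, n_per_res, axis=0)
                if _min_pair_distance(xyz) >= _MIN_DISTANCE:
                    break
            else:
                raise RuntimeError(
                    f"could not jitter by {displacement} A without clashes"
                )
        else:
            xyz = base.copy()
        coords.append(xyz)
    coords = np.array(coords)

    classes = []
    exch = []
    geminal: list[int | None] = []
    for i, a in enumerate(atoms):
        if a.atom_name in ("H5'", "H5''"):
            classes.append("methylene")
            partner = "H5''" if a.atom_name == "H5'" else "H5'"
            geminal.append(next(
                k for k, b in enumerate(atoms)
                if b.residue_number == a.residue_number and b.atom_name == partner
            ))
        else:
            classes.append("other")
            geminal.append(None)
        exch.append(False)
    s = SpinSystem(protons=atoms, coordinates=coords, group_class=classes,
                   exchangeable=exch, geminal_partner=geminal,
                   source_label=f"helix(n={n_residues},seed={seed})")
    n = len(atoms)
    distances = {}
    for i in range(n):
        for j in range(i + 1, n):
            r = np.linalg.norm(coords[:, i, :] - coords[:, j, :], axis=1)
            distances[(atoms[i], atoms[j])] = float(np.mean(r**-6.0) ** (-1 / 6))
    truth = SyntheticTruth(spin_system=s, distances=distances, seed=seed)
    return s, truth


def heterogeneous_dm0(s: SpinSystem, seed: int = 0, spread: float = 0.3) -> np.ndarray:
    """Per-spin initial-magnetization factors with class-dependent scale.

    Methylene protons get a larger base level than the rest (as their
    recovery differs in practice), and each spin is scattered downward by up
    to ``spread`` below its class base, so group maxima genuinely exceed
    individual members — the situation gn normalization is designed for.
    """
    base = {"amino": 1.4, "methylene": 1.25, "hydroxyl": 1.0, "other": 1.0}
    rng = np.random.default_rng(seed)
    scale = rng.uniform(1.0 - spread, 1.0, size=s.n_protons)
    return np.array([base[c] for c in s.group_class]) * scale


def simulate_noesy(
    s: SpinSystem,
    cond: ExperimentConditions,
    mixing_times=DEFAULT_MIXING_TIMES,
    noise_sd_relative: float = 0.0,
    seed: int = 0,
    dM0=None,
    max_pair_distance: float | None = None,
) -> BuildupSet:
    """Simulate a NOESY buildup series with the full relaxation matrix.

    Emits one diagonal series per proton and both directions of every cross
    pair (optionally restricted to pairs closer than ``max_pair_distance``
    in the first conformer). Intensities are conformer-averaged transfer
    amplitudes scaled by the origin spin's initial magnetization
    (``dM0``: scalar or per-proton array, default uniform 1). Additive
    Gaussian noise has standard deviation ``noise_sd_relative`` times the
    largest first-mixing-time diagonal.
    """
    taus = np.asarray(mixing_times, dtype=float)
    if np.any(taus <= 0):
        raise ValueError("mixing times must be positive")
    n = s.n_protons
    if dM0 is None:
        dm0 = np.ones(n)
    else:
        dm0 = np.broadcast_to(np.asarray(dM0, dtype=float), (n,)).copy()

    A = np.zeros((taus.size, n, n))
    for c in range(s.n_conformers):
        R = build_relaxation_matrix(s, c, cond)
        A += transfer_matrices(R, taus)
    A /= s.n_conformers

    pairs = []
    xyz0 = s.coordinates[0]
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            if max_pair_distance is not None:
                if np.linalg.norm(xyz0[i] - xyz0[j]) > max_pair_distance:
                    continue
            pairs.append((i, j))

    rng = np.random.default_rng(seed)
    sd = noise_sd_relative * float(np.max(A[0].diagonal() * dm0))

    series = {}
    for i in range(n):
        y = A[:, i, i] * dm0[i]
        if noise_sd_relative > 0:
            y = y + rng.normal(0.0, sd, size=y.shape)
        key = (s.protons[i], s.protons[i])
        series[key] = BuildupSeries(pair=key, mixing_times=taus, intensities=y,
                                    peak_id=f"d{i}")
    for i, j in pairs:
        y = A[:, i, j] * dm0[i]
        if noise_sd_relative > 0:
            y = y + rng.normal(0.0, sd, size=y.shape)
        key = (s.protons[i], s.protons[j])
        series[key] = BuildupSeries(pair=key, mixing_times=taus, intensities=y,
                                    peak_id=f"c{i}-{j}")
    return BuildupSet(series=series)


def stokes_einstein_tau(tau_ref: float, viscosity_ratio: float) -> float:
    """Scale a correlation time with solvent viscosity (Stokes-Einstein:
    tau_c is proportional to viscosity at fixed radius and temperature)."""
    if tau_ref <= 0 or viscosity_ratio <= 0:
        raise ValueError("tau_ref and viscosity_ratio must be positive")
    return tau_ref * viscosity_ratio


def max_mixing_time(tau_c: float, constant: float = 4.0e-10) -> float:
    """Maximal useful NOESY mixing time, tau_max = constant / tau_c.

    The default constant 4e-10 s^2 applies to RNA; 2.5e-10 s^2 is the
    corresponding recommendation for proteins.
    """
    if tau_c <= 0:
        raise ValueError("tau_c must be positive")
    return constant / tau_c


def snap_to_grid(tau_max: float, grid=DEFAULT_MIXING_TIMES) -> float:
    """Round tau_max down to the nearest acquired mixing time."""
    grid = sorted(grid)
    below = [g for g in grid if g <= tau_max + 1e-12]
    return below[-1] if below else grid[0]
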