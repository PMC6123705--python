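"""Conformer-bundle metrics: order parameters, RMSD, nucleic-acid torsions.

Order parameters follow the ensemble definition
S^2 = (3 sum_ab <mu_a mu_b>^2 - 1) / 2 over the unit bond vector mu with
equal conformer weights: 1 for a rigid bond, 0 for complete angular
freedom. RMSD is the mean RMSD-to-mean after optimal superposition onto the
iteratively refined mean coordinates. Torsions use the standard IUPAC
nucleic-acid definitions (alpha..zeta backbone, chi glycosidic, nu1/nu2
sugar ring, eta2 = C1'-C2'-O2'-HO2' for the 2'-hydroxyl).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation
from scipy.stats import circmean, circstd

from .errors import ENOEError
from .spin_system_io import AtomId, Ensemble, is_hydrogen_name

__all__ = [
    "OrderParameterResult",
    "TorsionResult",
    "order_parameter",
    "heavy_atom_rmsd",
    "torsion_angles",
    "dihedral",
    "bond_partners",
]


@dataclass
class OrderParameterResult:
    bond: tuple[AtomId, AtomId]
    s2: float


@dataclass
class TorsionResult:
    residue_number: int
    angle_name: str
    values: np.ndarray  # degrees, one per conformer, in (-180, 180]
    circular_mean: float
    circular_std: float


def order_parameter(e: Ensemble, bond) -> OrderParameterResult:
    """Ensemble order parameter S^2 of a bond vector.

    S^2 = (3 sum_ab <mu_a mu_b>^2 - 1) / 2 with mu the unit bond vector and
    <.> the equal-weight conformer average; lies in [0, 1] and equals 1 for
    any single-conformer ensemble.
    """
    i, j = e.index(bond[0]), e.index(bond[1])
    vec = e.coordinates[:, j, :] - e.coordinates[:, i, :]
    norms = np.linalg.norm(vec, axis=1)
    if np.any(norms < 1e-8):
        raise ENOEError(f"coincident atoms in bond {bond[0]}-{bond[1]}")
    mu = vec / norms[:, None]
    M = np.einsum("ca,cb->ab", mu, mu) / mu.shape[0]
    s2 = 0.5 * (3.0 * float(np.sum(M * M)) - 1.0)
    return OrderParameterResult(bond=(bond[0], bond[1]), s2=s2)


def _kabsch(mobile: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Optimally superpose mobile onto ref (both pre-centered externally)."""
    mc = mobile - mobile.mean(axis=0)
    rc = ref - ref.mean(axis=0)
    rot, _ = Rotation.align_vectors(rc, mc)
    return rot.apply(mc) + ref.mean(axis=0)


def heavy_atom_rmsd(
    e: Ensemble,
    residues=None,
    atoms: str = "heavy",
    max_iter: int = 50,
    tol: float = 1e-8,
) -> float:
    """Mean RMSD of the conformers to their iteratively refined mean (A).

    ``residues`` restricts the superposition/RMSD subset (iterable of
    residue numbers; default all); ``atoms`` is ``"heavy"`` or ``"all"``.
    """
    if e.n_conformers < 2:
        raise ENOEError("need at least two conformers for a bundle RMSD")
    sel = []
    residues = None if residues is None else set(residues)
    for k, a in enumerate(e.atoms):
        if residues is not None and a.residue_number not in residues:
            continue
        if atoms == "heavy" and is_hydrogen_name(a.atom_name):
            continue
        sel.append(k)
    if not sel:
        raise ENOEError("atom subset selects no atoms")
    coords = e.coordinates[:, sel, :].copy()
    coords -= coords.mean(axis=1, keepdims=True)
    mean = coords[0].copy()
    for _ in range(max_iter):
        aligned = np.array([_kabsch(c, mean) for c in coords])
        new_mean = aligned.mean(axis=0)
        shift = float(np.abs(new_mean - mean).max())
        mean = new_mean
        coords = aligned
        if shift < tol:
            break
    rmsds = np.sqrt(np.mean(np.sum((coords - mean) ** 2, axis=2), axis=1))
    return float(rmsds.mean())


def dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral angle (degrees, in (-180, 180]) of four positions."""
    b0 = np.asarray(p1) - np.asarray(p0)
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x = float(n1 @ n2)
    y = float(m1 @ n2)
    ang = np.degrees(np.arctan2(y, x))
    return 180.0 if np.isclose(ang, -180.0) else float(ang)


def bond_partners(e: Ensemble, kinds=("CH", "NH")) -> list[tuple[AtomId, AtomId]]:
    """Covalent bond vectors for order-parameter analysis.

    ``kinds`` selects bond types: ``"CH"`` / ``"NH"`` / ``"OH"`` pair each
    proton with its nearest heavy atom (within 1.3 A in the first
    conformer); ``"POP1"`` selects the backbone P-OP1 bond of each residue.
    """
    kinds = set(kinds)
    bonds: list[tuple[AtomId, AtomId]] = []
    xyz = e.coordinates[0]
    heavy_idx = [k for k, a in enumerate(e.atoms) if not is_hydrogen_name(a.atom_name)]
    if {"CH", "NH", "OH"} & kinds and heavy_idx:
        hx = xyz[heavy_idx]
        for k, a in enumerate(e.atoms):
            if not is_hydrogen_name(a.atom_name):
                continue
            d = np.linalg.norm(hx - xyz[k], axis=1)
            j = int(np.argmin(d))
            if d[j] > 1.3:
                continue
            heavy = e.atoms[heavy_idx[j]]
            kind = heavy.atom_name[0] + "H"
            if kind in kinds:
                bonds.append((heavy, a))
    if "POP1" in kinds:
        by_res: dict[int, dict[str, AtomId]] = {}
        for a in e.atoms:
            if a.atom_name in ("P", "OP1"):
                by_res.setdefault(a.residue_number, {})[a.atom_name] = a
        for res in sorted(by_res):
            if {"P", "OP1"} <= set(by_res[res]):
                bonds.append((by_res[res]["P"], by_res[res]["OP1"]))
    return bonds


# IUPAC torsion definitions: (atom, residue offset) quadruples
_TORSION_DEFS = {
    "alpha": (("O3'", -1), ("P", 0), ("O5'", 0), ("C5'", 0)),
    "beta": (("P", 0), ("O5'", 0), ("C5'", 0), ("C4'", 0)),
    "gamma": (("O5'", 0), ("C5'", 0), ("C4'", 0), ("C3'", 0)),
    "delta": (("C5'", 0), ("C4'", 0), ("C3'", 0), ("O3'", 0)),
    "epsilon": (("C4'", 0), ("C3'", 0), ("O3'", 0), ("P", 1)),
    "zeta": (("C3'", 0), ("O3'", 0), ("P", 1), ("O5'", 1)),
    "nu1": (("O4'", 0), ("C1'", 0), ("C2'", 0), ("C3'", 0)),
    "nu2": (("C1'", 0), ("C2'", 0), ("C3'", 0), ("C4'", 0)),
    "eta2": (("C1'", 0), ("C2'", 0), ("O2'", 0), ("HO2'", 0)),
}
_PURINES = {"A", "G"}


def _chi_def(residue_name: str):
    if residue_name in _PURINES:
        return (("O4'", 0), ("C1'", 0), ("N9", 0), ("C4", 0))
    return (("O4'", 0), ("C1'", 0), ("N1", 0), ("C2", 0))


def torsion_angles(e: Ensemble, residues=None, angles=None) -> list[TorsionResult]:
    """Backbone, glycosidic, sugar and 2'-hydroxyl torsions of an ensemble.

    Angles with missing atoms (chain termini lacking a neighboring
    phosphate, absent HO2' protons for eta2, ...) are skipped with a
    warning.  Circular mean and circular standard deviation are reported
    across conformers.
    """
    lookup: dict[tuple[int, str], int] = {}
    residue_numbers = sorted({a.residue_number for a in e.atoms})
    names = {a.residue_number: a.residue_name for a in e.atoms}
    for k, a in enumerate(e.atoms):
        lookup[(a.residue_number, a.atom_name)] = k
    if residues is not None:
        residue_numbers = [r for r in residue_numbers if r in set(residues)]
    wanted = list(_TORSION_DEFS) + ["chi"] if angles is None else list(angles)

    results = []
    skipped = []
    for res in residue_numbers:
        for name in wanted:
            defn = _chi_def(names[res]) if name == "chi" else _TORSION_DEFS[name]
            try:
                idx = [lookup[(res + off, atom)] for atom, off in defn]
            except KeyError:
                skipped.append((res, name))
                continue
            vals = np.array([
                dihedral(*(e.coordinates[c, k, :] for k in idx))
                for c in range(e.n_conformers)
            ])
            rad = np.radians(vals)
            results.append(TorsionResult(
                residue_number=res, angle_name=name, values=vals,
                circular_mean=float(np.degrees(circmean(rad, high=np.pi, low=-np.pi))),
                circular_std=float(np.degrees(circstd(rad, high=np.pi, low=-np.pi))),
            ))
    if skipped:
        warnings.warn(
            f"skipped {len(skipped)} torsion(s) with missing atoms", stacklevel=2
        )
    return results
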