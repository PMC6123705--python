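"""Structure and table I/O for eNOE analysis.

Reads multi-conformer PDB files into :class:`Ensemble` objects, normalizes
nucleic-acid proton naming to PDB v3, builds :class:`SpinSystem` objects
(the nodes of the relaxation network), and reads/writes the package's
plain-text tabular formats: NOESY buildup tables and CYANA-style ``.upl`` /
``.lol`` distance-restraint files.

Atom tokens in tabular files use the compact form ``G10.H8`` (residue name,
residue number, atom name).
"""

from __future__ import annotations

import io
import re
import warnings
from dataclasses import dataclass, field

import gemmi
import numpy as np
import pandas as pd

from .errors import FormatError, NameNormalizationError, ENOEError

__all__ = [
    "AtomId",
    "Ensemble",
    "SpinSystem",
    "BuildupSeries",
    "BuildupSet",
    "read_ensemble",
    "normalize_atom_name",
    "make_spin_system",
    "read_buildup_table",
    "write_buildup_table",
    "write_restraints",
    "read_restraint_table",
    "parse_atom_token",
    "format_atom_token",
    "is_hydrogen_name",
]


# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class AtomId:
    """A single atom, identified by residue number, residue name and the
    canonical PDB-v3 atom name (H5'/H5'' style)."""

    residue_number: int
    residue_name: str
    atom_name: str

    def __str__(self) -> str:
        return format_atom_token(self)


@dataclass
class Ensemble:
    """An ordered set of conformers sharing one atom list.

    ``coordinates`` has shape ``(n_conformers, n_atoms, 3)`` in Angstrom.
    """

    atoms: list[AtomId]
    coordinates: np.ndarray
    source_label: str = ""

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise ValueError("coordinates must have shape (n_conformers, n_atoms, 3)")
        if self.coordinates.shape[0] < 1:
            raise ValueError("an Ensemble needs at least one conformer")
        if self.coordinates.shape[1] != len(self.atoms):
            raise ValueError("coordinate/atom count mismatch")
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("non-finite coordinates")
        self._index = {a: i for i, a in enumerate(self.atoms)}

    @property
    def n_conformers(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def index(self, atom: AtomId) -> int:
        try:
            return self._index[atom]
        except KeyError:
            raise KeyError(f"atom {atom} not in ensemble") from None

    def __contains__(self, atom: AtomId) -> bool:
        return atom in self._index


GROUP_CLASSES = ("amino", "methylene", "hydroxyl", "other")


@dataclass
class SpinSystem:
    """The proton network of an :class:`Ensemble`.

    ``coordinates`` has shape ``(n_conformers, n_protons, 3)``;
    ``group_class[k]`` is one of :data:`GROUP_CLASSES`;
    ``geminal_partner[k]`` is the index of the geminal methylene partner or
    ``None``.
    """

    protons: list[AtomId]
    coordinates: np.ndarray
    group_class: list[str]
    exchangeable: list[bool]
    geminal_partner: list[int | None] = field(default_factory=list)
    source_label: str = ""

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        n = len(self.protons)
        if not all(is_hydrogen_name(a.atom_name) for a in self.protons):
            raise ValueError("SpinSystem atoms must all be protons")
        if len(self.group_class) != n or len(self.exchangeable) != n:
            raise ValueError("per-proton annotation length mismatch")
        for g in self.group_class:
            if g not in GROUP_CLASSES:
                raise ValueError(f"unknown group class {g!r}")
        if not self.geminal_partner:
            self.geminal_partner = [None] * n
        self._index = {a: i for i, a in enumerate(self.protons)}

    @property
    def n_protons(self) -> int:
        return len(self.protons)

    @property
    def n_conformers(self) -> int:
        return self.coordinates.shape[0]

    def index(self, atom: AtomId) -> int:
        try:
            return self._index[atom]
        except KeyError:
            raise KeyError(f"proton {atom} not in spin system") from None

    def __contains__(self, atom: AtomId) -> bool:
        return atom in self._index


@dataclass
class BuildupSeries:
    """One peak's intensities over the mixing-time series."""

    pair: tuple[AtomId, AtomId]
    mixing_times: np.ndarray  # s, strictly increasing
    intensities: np.ndarray
    noise: np.ndarray | None = None
    peak_id: str = ""

    def __post_init__(self) -> None:
        self.mixing_times = np.asarray(self.mixing_times, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.noise is not None:
            self.noise = np.asarray(self.noise, dtype=float)
        if self.mixing_times.shape != self.intensities.shape:
            raise ValueError("mixing_times/intensities length mismatch")
        if np.any(np.diff(self.mixing_times) <= 0):
            raise ValueError("mixing times must be strictly increasing")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("non-finite intensity")

    @property
    def is_diagonal(self) -> bool:
        return self.pair[0] == self.pair[1]


@dataclass
class BuildupSet:
    """Diagonal and cross-peak buildup series keyed by ordered atom pair.

    ``corrected`` records whether spin-diffusion corrections have been
    applied (they are multiplicative and must not be applied twice).
    """

    series: dict[tuple[AtomId, AtomId], BuildupSeries]
    corrected: bool = False

    def __len__(self) -> int:
        return len(self.series)

    def diagonals(self) -> dict[AtomId, BuildupSeries]:
        return {k[0]: s for k, s in self.series.items() if s.is_diagonal}

    def cross_peaks(self) -> dict[tuple[AtomId, AtomId], BuildupSeries]:
        return {k: s for k, s in self.series.items() if not s.is_diagonal}


# --------------------------------------------------------------------------
# Atom-name normalization (PDB v3 canonical forms)
# --------------------------------------------------------------------------

_RESIDUE_ALIASES = {
    "A": "A", "G": "G", "C": "C", "U": "U",
    "RA": "A", "RG": "G", "RC": "C", "RU": "U",
    "ADE": "A", "GUA": "G", "CYT": "C", "URA": "U", "URI": "U",
    "A5": "A", "G5": "G", "C5": "C", "U5": "U",
    "A3": "A", "G3": "G", "C3": "C", "U3": "U",
}

_SUGAR_H = ["H1'", "H2'", "H3'", "H4'", "H5'", "H5''", "HO2'", "HO3'", "HO5'"]

#: canonical hydrogen names per ribonucleotide
CANONICAL_PROTONS = {
    "A": set(_SUGAR_H) | {"H2", "H8", "H61", "H62"},
    "G": set(_SUGAR_H) | {"H8", "H1", "H21", "H22"},
    "C": set(_SUGAR_H) | {"H5", "H6", "H41", "H42"},
    "U": set(_SUGAR_H) | {"H5", "H6", "H3"},
}
_ALL_CANONICAL = set().union(*CANONICAL_PROTONS.values())

# amino protons (exchangeable, attached to the base amino nitrogen)
_AMINO = {"H21", "H22", "H41", "H42", "H61", "H62"}
# imino protons, exchangeable
_IMINO = {"H1", "H3"}
_HYDROXYL = {"HO2'", "HO3'", "HO5'"}
_METHYLENE = {"H5'", "H5''"}

# explicit one-off dialect entries that the generic rules do not cover
_SPECIAL_DIALECTS = {
    "HO'2": "HO2'", "2HO'": "HO2'", "O2'H": "HO2'", "HO2": "HO2'",
    "HO'3": "HO3'", "3HO'": "HO3'", "O3'H": "HO3'",
    "HO'5": "HO5'", "5HO'": "HO5'", "O5'H": "HO5'",
}


def is_hydrogen_name(name: str) -> bool:
    """True for atom names that denote hydrogens in any common PDB dialect."""
    return bool(re.match(r"^[123]?H", name.strip()))


def _canonical_residue(residue_name: str) -> str | None:
    return _RESIDUE_ALIASES.get(residue_name.strip().upper())


def normalize_atom_name(raw: str, residue_name: str) -> str:
    """Map a proton-name dialect onto the canonical PDB-v3 form.

    Handles asterisk/quote/unicode prime variants (``H5*``, ``H5"``),
    leading-digit forms (``1H5'`` -> ``H5'``, ``2H6`` -> ``H62``) and
    trailing-digit forms (``H5'1`` -> ``H5'``, ``H5'2`` -> ``H5''``).
    Non-hydrogen names are returned unchanged; an unmappable hydrogen
    dialect raises :class:`NameNormalizationError`.
    """
    if not raw or not raw.strip():
        raise NameNormalizationError("empty atom name")
    name = raw.strip()
    # prime dialects
    name = name.replace("′", "'").replace("″", "''")
    name = name.replace("*", "'").replace('"', "''")

    if not is_hydrogen_name(name):
        return name

    resolved = _resolve_hydrogen(name)
    if resolved is None:
        raise NameNormalizationError(
            f"cannot map hydrogen name {raw!r} (residue {residue_name!r}) to PDB v3"
        )
    res = _canonical_residue(residue_name)
    allowed = CANONICAL_PROTONS.get(res, _ALL_CANONICAL) if res else _ALL_CANONICAL
    if resolved not in allowed:
        raise NameNormalizationError(
            f"hydrogen name {raw!r} maps to {resolved!r}, which is not a "
            f"known proton of residue {residue_name!r}"
        )
    return resolved


def _resolve_hydrogen(name: str) -> str | None:
    if name in _ALL_CANONICAL:
        return name
    if name in _SPECIAL_DIALECTS:
        return _SPECIAL_DIALECTS[name]
    # leading digit: 1H5' -> H5', 2H5' -> H5''; 1H2 -> H21, 2H4 -> H42
    m = re.match(r"^([123])H(.*)$", name)
    if m:
        digit, rest = m.group(1), m.group(2)
        if rest.endswith("'"):
            return "H" + rest if digit == "1" else "H" + rest + "'"
        return f"H{rest}{digit}"
    # trailing digit after prime: H5'1 -> H5', H5'2 -> H5''
    m = re.match(r"^H(\w*')([12])$", name)
    if m:
        core, digit = m.group(1), m.group(2)
        return "H" + core if digit == "1" else "H" + core + "'"
    return None


def classify_proton(atom: AtomId) -> tuple[str, bool]:
    """Return ``(group_class, exchangeable)`` for a canonical proton name."""
    name = atom.atom_name
    if name in _AMINO:
        return "amino", True
    if name in _METHYLENE:
        return "methylene", False
    if name in _HYDROXYL:
        return "hydroxyl", True
    if name in _IMINO:
        res = _canonical_residue(atom.residue_name)
        # G H1 and U H3 are ring NH protons; A H2 / C,U H5 etc. are carbon-bound
        if (res == "G" and name == "H1") or (res == "U" and name == "H3"):
            return "other", True
        return "other", False
    return "other", False


# --------------------------------------------------------------------------
# PDB reading
# --------------------------------------------------------------------------

def read_ensemble(pdb_text: str, source_label: str = "") -> Ensemble:
    """Parse a (possibly multi-model) PDB character stream into an Ensemble.

    MODEL/ENDMDL records delimit conformers; a single implicit model is
    accepted. Atoms present in only some models are dropped with a warning.
    Atom names are normalized to PDB v3.
    """
    structure = gemmi.read_pdb_string(pdb_text)
    models = list(structure)
    if not models:
        raise FormatError("no ATOM records found in PDB stream")

    per_model: list[dict[AtomId, np.ndarray]] = []
    order: list[AtomId] = []
    resname_by_number: dict[tuple[str, int], str] = {}
    for model in models:
        coords: dict[AtomId, np.ndarray] = {}
        for chain in model:
            for residue in chain:
                num = residue.seqid.num
                key = (chain.name, num)
                if key in resname_by_number and resname_by_number[key] != residue.name:
                    raise FormatError(
                        f"inconsistent residue numbering across models: residue "
                        f"{num} is {resname_by_number[key]!r} in one model and "
                        f"{residue.name!r} in another"
                    )
                resname_by_number[key] = residue.name
                res = _canonical_residue(residue.name) or residue.name
                for atom in residue:
                    if atom.altloc not in ("", "A", "\x00"):
                        continue
                    name = normalize_atom_name(atom.name, residue.name)
                    aid = AtomId(num, res, name)
                    if aid in coords:
                        continue
                    coords[aid] = np.array([atom.pos.x, atom.pos.y, atom.pos.z])
                    if len(per_model) == 0:
                        order.append(aid)
        if not coords:
            raise FormatError("model without ATOM records in PDB stream")
        per_model.append(coords)

    shared = [a for a in order if all(a in m for m in per_model)]
    extra = set().union(*(set(m) for m in per_model)) - set(shared)
    if extra:
        warnings.warn(
            f"dropping {len(extra)} atom(s) not present in every model: "
            + ", ".join(sorted(str(a) for a in extra)),
            stacklevel=2,
        )
    if not shared:
        raise FormatError("no atom is present in every model")
    xyz = np.array([[m[a] for a in shared] for m in per_model])
    return Ensemble(atoms=shared, coordinates=xyz, source_label=source_label)


def make_spin_system(e: Ensemble, include_exchangeable: bool = True) -> SpinSystem:
    """Select the protons of an ensemble and classify them.

    Protons are classed as amino / methylene / hydroxyl / other; exchangeable
    protons (amino, imino, hydroxyl) are excluded when
    ``include_exchangeable`` is off, emulating the D2O sample condition.
    """
    sel: list[tuple[int, AtomId, str, bool]] = []
    for i, a in enumerate(e.atoms):
        if not is_hydrogen_name(a.atom_name):
            continue
        cls, exch = classify_proton(a)
        if exch and not include_exchangeable:
            continue
        sel.append((i, a, cls, exch))
    if not sel:
        raise ENOEError(
            "ensemble contains no (selected) hydrogens; protonated coordinates "
            "are required for eNOE analysis"
        )
    idx = [i for i, *_ in sel]
    protons = [a for _, a, *_ in sel]
    classes = [c for *_, c, _ in sel]
    exch = [x for *_, x in sel]
    geminal: list[int | None] = [None] * len(protons)
    by_key = {(a.residue_number, a.atom_name): k for k, a in enumerate(protons)}
    for k, a in enumerate(protons):
        if a.atom_name == "H5'":
            partner = by_key.get((a.residue_number, "H5''"))
        elif a.atom_name == "H5''":
            partner = by_key.get((a.residue_number, "H5'"))
        else:
            partner = None
        geminal[k] = partner
    return SpinSystem(
        protons=protons,
        coordinates=e.coordinates[:, idx, :],
        group_class=classes,
        exchangeable=exch,
        geminal_partner=geminal,
        source_label=e.source_label,
    )


# --------------------------------------------------------------------------
# Buildup tables
# --------------------------------------------------------------------------

_ATOM_TOKEN_RE = re.compile(r"^([A-Za-z]{1,3})(\d+)\.(\S+)$")


def format_atom_token(atom: AtomId) -> str:
    return f"{atom.residue_name}{atom.residue_number}.{atom.atom_name}"


def parse_atom_token(token: str) -> AtomId:
    m = _ATOM_TOKEN_RE.match(token.strip())
    if not m:
        raise FormatError(f"cannot parse atom token {token!r} (expected e.g. G10.H8)")
    return AtomId(int(m.group(2)), m.group(1), m.group(3))


def read_buildup_table(text: str, time_unit: str = "s") -> BuildupSet:
    """Read a long-format NOESY buildup table.

    Tab-separated columns ``peak_id  atom_i  atom_j  mixing_time_s
    intensity`` (optional ``noise``); ``#`` starts a comment line; diagonal
    peaks have ``atom_i == atom_j``. ``time_unit`` may be ``"s"`` or
    ``"ms"``.
    """
    if time_unit not in ("s", "ms"):
        raise ValueError("time_unit must be 's' or 'ms'")
    try:
        df = pd.read_csv(io.StringIO(text), sep="\t", comment="#",
                         skip_blank_lines=True, dtype=str)
    except pd.errors.EmptyDataError:
        df = pd.DataFrame()
    if df.empty:
        warnings.warn("empty buildup table", stacklevel=2)
        return BuildupSet(series={})
    cols = list(df.columns)
    time_col = "mixing_time_s" if "mixing_time_s" in cols else "mixing_time"
    required = ["peak_id", "atom_i", "atom_j", time_col, "intensity"]
    missing = [c for c in required if c not in cols]
    if missing:
        raise FormatError(f"buildup table missing column(s): {', '.join(missing)}")
    try:
        times = df[time_col].astype(float).to_numpy()
        inten = df["intensity"].astype(float).to_numpy()
        noise = df["noise"].astype(float).to_numpy() if "noise" in cols else None
    except ValueError as exc:
        raise FormatError(f"non-numeric value in buildup table: {exc}") from exc
    if time_unit == "ms":
        times = times / 1000.0

    rows: dict[tuple[AtomId, AtomId], list[tuple[float, float, float | None, str]]] = {}
    seen: set[tuple[AtomId, AtomId, float]] = set()
    for k in range(len(df)):
        ai = parse_atom_token(df["atom_i"].iloc[k])
        aj = parse_atom_token(df["atom_j"].iloc[k])
        key = (ai, aj)
        tkey = (ai, aj, round(float(times[k]), 9))
        if tkey in seen:
            raise FormatError(
                f"duplicate measurement for peak {format_atom_token(ai)}-"
                f"{format_atom_token(aj)} at mixing time {times[k]:g} s"
            )
        seen.add(tkey)
        rows.setdefault(key, []).append(
            (times[k], inten[k], None if noise is None else noise[k],
             str(df["peak_id"].iloc[k]))
        )
    series = {}
    for key, pts in rows.items():
        pts.sort(key=lambda p: p[0])
        t = np.array([p[0] for p in pts])
        ii = np.array([p[1] for p in pts])
        nn = None
        if all(p[2] is not None for p in pts):
            nn = np.array([p[2] for p in pts])
        series[key] = BuildupSeries(pair=key, mixing_times=t, intensities=ii,
                                    noise=nn, peak_id=pts[0][3])
    return BuildupSet(series=series)


def write_buildup_table(b: BuildupSet) -> str:
    """Inverse of :func:`read_buildup_table` (times in seconds)."""
    lines = ["peak_id\tatom_i\tatom_j\tmixing_time_s\tintensity"]
    for key in sorted(b.series, key=lambda k: (k[0], k[1])):
        s = b.series[key]
        for t, v in zip(s.mixing_times, s.intensities):
            lines.append(
                f"{s.peak_id or format_atom_token(key[0]) + '-' + format_atom_token(key[1])}"
                f"\t{format_atom_token(key[0])}\t{format_atom_token(key[1])}"
                f"\t{t:.6g}\t{v:.10g}"
            )
    return "\n".join(lines) + "\n"


# --------------------------------------------------------------------------
# CYANA-style restraint files
# --------------------------------------------------------------------------

def write_restraints(restraints, dialect: str) -> str:
    """Write CYANA-style ``.upl`` (``dialect="upper"``) or ``.lol``
    (``dialect="lower"``) lines.

    One line per restraint: residue number, residue name, atom name for both
    partners, then the bound in Angstrom with two decimals. Restraints
    lacking the requested bound (gn restraints have no lower limit) are
    skipped with a warning. Ordering is by first then second atom.
    """
    if dialect not in ("upper", "lower"):
        raise ValueError("dialect must be 'upper' or 'lower'")
    written = []
    skipped = 0
    for r in sorted(restraints, key=lambda r: (r.pair[0], r.pair[1])):
        bound = r.upper if dialect == "upper" else r.lower
        if bound is None:
            skipped += 1
            continue
        a, b = r.pair
        written.append(
            f"{a.residue_number:4d} {a.residue_name:<4s} {a.atom_name:<6s}"
            f"{b.residue_number:4d} {b.residue_name:<4s} {b.atom_name:<6s}"
            f"{bound:8.2f}"
        )
    if skipped:
        warnings.warn(
            f"skipped {skipped} restraint(s) without a {dialect} bound",
            stacklevel=2,
        )
    if not written:
        raise ENOEError(f"no restraint carries a {dialect} bound")
    return "\n".join(written) + "\n"


def read_restraint_table(text: str) -> list[tuple[AtomId, AtomId, float]]:
    """Parse lines written by :func:`write_restraints`."""
    out = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 7:
            raise FormatError(f"malformed restraint line: {line!r}")
        a = AtomId(int(parts[0]), parts[1], parts[2])
        b = AtomId(int(parts[3]), parts[4], parts[5])
        out.append((a, b, float(parts[6])))
    return out
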