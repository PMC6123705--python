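import numpy as np
import pytest

from enoe.relaxation import ExperimentConditions
from enoe.spin_system_io import AtomId, Ensemble, is_hydrogen_name
from enoe.synthetic import make_helix_spin_system


@pytest.fixture
def cond() -> ExperimentConditions:
    """The 14-mer's H2O conditions: tau_c = 2.23 ns on a 900 MHz magnet."""
    return ExperimentConditions(tau_c=2.23e-9, larmor_frequency=900.0)


@pytest.fixture
def helix():
    """20-proton helix fixture with ground truth (seeded)."""
    return make_helix_spin_system(4, seed=1, displacement=0.3)


def _pdb_atom_line(serial, atom: AtomId, xyz, element=None) -> str:
    name = atom.atom_name
    if element is None:
        element = "H" if is_hydrogen_name(name) else name[0]
    nm = name if len(name) == 4 else f" {name:<3s}"
    return (
        f"ATOM  {serial:5d} {nm:<4s}{atom.residue_name:>3s} A{atom.residue_number:4d}"
        f"    {xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}  1.00  0.00          {element:>2s}"
    )


def ensemble_to_pdb(e: Ensemble) -> str:
    """Minimal multi-model PDB writer (test oracle for the reader)."""
    lines = []
    for m in range(e.n_conformers):
        lines.append(f"MODEL     {m + 1}")
        for k, atom in enumerate(e.atoms):
            lines.append(_pdb_atom_line(k + 1, atom, e.coordinates[m, k]))
        lines.append("ENDMDL")
    lines.append("END")
    return "\n".join(lines) + "\n"


def spin_system_to_pdb(s) -> str:
    e = Ensemble(atoms=list(s.protons), coordinates=s.coordinates)
    return ensemble_to_pdb(e)


def random_spin_system(n: int, seed: int, min_dist: float = 1.8, box: float = 6.0):
    """Random n-proton geometry with a minimum-distance constraint."""
    rng = np.random.default_rng(seed)
    pts = []
    while len(pts) < n:
        p = rng.uniform(0, box, size=3)
        if all(np.linalg.norm(p - q) >= min_dist for q in pts):
            pts.append(p)
    atoms = [AtomId(i + 1, "G", "H8") for i in range(n)]
    from enoe.spin_system_io import SpinSystem

    return SpinSystem(
        protons=atoms,
        coordinates=np.asarray(pts)[None, :, :],
        group_class=["other"] * n,
        exchangeable=[False] * n,
    )
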