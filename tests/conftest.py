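"""Shared fixtures: tiny hand-built topologies and ensembles."""

from __future__ import annotations

import numpy as np
import pytest

from eemcc.frames import FrameEnsemble
from eemcc.topology import Topology


def make_topology(
    atoms: list[dict],
    bonds: list[tuple[int, int]],
    species: dict[int, str],
    formal_charge: dict[int, float] | None = None,
    monomer_class: dict[int, str] | None = None,
    dihedrals: list[tuple[int, tuple[int, int, int, int]]] | None = None,
) -> Topology:
    """Build a Topology from per-atom dicts (element, mass, charge, ua,
    monomer, molecule; name optional)."""
    n = len(atoms)
    mons = sorted({a["monomer"] for a in atoms})
    mols = sorted({a["molecule"] for a in atoms})
    top = Topology(
        element=np.array([a["element"] for a in atoms], dtype=object),
        name=np.array([a.get("name", a["element"]) for a in atoms], dtype=object),
        mass=np.array([a["mass"] for a in atoms], dtype=float),
        charge=np.array([a["charge"] for a in atoms], dtype=float),
        ua_id=np.array([a["ua"] for a in atoms], dtype=int),
        monomer_id=np.array([a["monomer"] for a in atoms], dtype=int),
        molecule_id=np.array([a["molecule"] for a in atoms], dtype=int),
        bonds=(np.array(bonds, dtype=int) if bonds
               else np.empty((0, 2), dtype=int)),
        monomer_class={m: "n/a" for m in mons},
        species=dict(species),
        formal_charge={m: 0.0 for m in mols},
        dihedrals=list(dihedrals or []),
    )
    if monomer_class:
        top.monomer_class.update(monomer_class)
    if formal_charge:
        top.formal_charge.update(formal_charge)
    top.validate()
    return top


def water_atoms(mol: int, ua: int, mon: int) -> list[dict]:
    return [
        {"element": "O", "name": "OW", "mass": 16.0, "charge": -0.834,
         "ua": ua, "monomer": mon, "molecule": mol},
        {"element": "H", "name": "HW1", "mass": 1.0, "charge": 0.417,
         "ua": ua, "monomer": mon, "molecule": mol},
        {"element": "H", "name": "HW2", "mass": 1.0, "charge": 0.417,
         "ua": ua, "monomer": mon, "molecule": mol},
    ]


def static_ensemble(
    positions: np.ndarray,
    box: float = 100.0,
    n_frames: int = 1,
    forces: np.ndarray | None = None,
) -> FrameEnsemble:
    """Frames with fixed positions and zero (or given) forces/energies."""
    positions = np.asarray(positions, dtype=float)
    n = len(positions)
    pos = np.tile(positions, (n_frames, 1, 1))
    frc = (np.tile(forces, (n_frames, 1, 1)) if forces is not None
           else np.zeros_like(pos))
    return FrameEnsemble(
        times=np.arange(n_frames, dtype=float),
        box=np.full((n_frames, 3), float(box)),
        positions=pos,
        forces=frc,
        pe=np.zeros((n_frames, n)),
        ke=np.zeros((n_frames, n)),
    )


@pytest.fixture
def single_water():
    """One water molecule plus a bonded-H bookkeeping check."""
    top = make_topology(
        water_atoms(0, 0, 0), [(0, 1), (0, 2)], species={0: "water"}
    )
    pos = np.array([[5.0, 5.0, 5.0], [5.76, 5.59, 5.0], [4.24, 5.59, 5.0]])
    return top, pos
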