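"""Enthalpy bookkeeping from per-atom kinetic and potential energies.

The trajectory producer is trusted to decompose many-body and mesh
energy terms evenly over the atoms involved, so the enthalpy of any
unit is simply H = sum_i (K_i + U_i) over its atoms; the negligible
pressure-volume term is ignored.  Per-unit enthalpies therefore sum
exactly over any complete partition of the system.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .frames import FrameEnsemble
from .topology import Topology


def unit_enthalpy(
    pe: np.ndarray,
    ke: np.ndarray,
    atoms: np.ndarray,
) -> float:
    """H = sum(K + U) over a unit's atoms for one frame, kJ mol^-1."""
    return float(np.sum(pe[atoms] + ke[atoms]))


@dataclass
class EnergyLedger:
    """Weighted-mean enthalpies aggregated over the labelling hierarchy."""

    per_molecule: dict[int, float] = field(default_factory=dict)
    per_species: dict[str, float] = field(default_factory=dict)
    per_monomer: dict[int, float] = field(default_factory=dict)
    per_monomer_class: dict[str, float] = field(default_factory=dict)
    per_water_environment: dict[str, float] = field(default_factory=dict)
    #: per-water weighted samples for distribution export: label -> values/weights
    water_samples: dict[str, tuple[np.ndarray, np.ndarray]] = field(
        default_factory=dict
    )
    total: float = 0.0


def aggregate_energy(
    ens: FrameEnsemble,
    top: Topology,
    water_labels: list[dict[int, str]] | None = None,
    weights: np.ndarray | None = None,
) -> EnergyLedger:
    """Weighted mean enthalpy per molecule, species, monomer class and
    water environment.

    Water-environment labels are frame-local: a water contributes to an
    environment's statistics only in the frames it carries that label.
    """
    if weights is None:
        weights = np.ones(ens.n_frames)
    weights = np.asarray(weights, dtype=float)
    wsum = weights.sum()
    if wsum <= 0:
        raise ValueError("total frame weight must be positive")

    etot = ens.pe + ens.ke  # (nf, n)
    ledger = EnergyLedger()
    w_mean_atom = (etot * weights[:, None]).sum(axis=0) / wsum
    ledger.total = float(w_mean_atom.sum())
    for mol in (int(m) for m in top.units("molecule")):
        ledger.per_molecule[mol] = float(
            w_mean_atom[top.atoms_of("molecule", mol)].sum()
        )
    for mol, h in ledger.per_molecule.items():
        role = top.species[mol]
        ledger.per_species[role] = ledger.per_species.get(role, 0.0) + h
    for mon in (int(m) for m in top.units("monomer")):
        ledger.per_monomer[mon] = float(
            w_mean_atom[top.atoms_of("monomer", mon)].sum()
        )
        cls = top.monomer_class[mon]
        ledger.per_monomer_class[cls] = (
            ledger.per_monomer_class.get(cls, 0.0) + ledger.per_monomer[mon]
        )

    if water_labels is not None:
        acc: dict[str, list[tuple[float, float]]] = {}
        mol_atoms = {
            int(m): top.atoms_of("molecule", int(m))
            for m in top.molecules_of_species("water")
        }
        for f, labels_f in enumerate(water_labels):
            for m, lab in labels_f.items():
                h = float(etot[f][mol_atoms[int(m)]].sum())
                acc.setdefault(lab, []).append((h, float(weights[f])))
        for lab, rows in acc.items():
            vals = np.array([r[0] for r in rows])
            ws = np.array([r[1] for r in rows])
            ledger.per_water_environment[lab] = float(
                np.average(vals, weights=ws)
            )
            ledger.water_samples[lab] = (vals, ws)
    return ledger


def water_energy_histograms(
    ledger: EnergyLedger,
    bins: int = 30,
) -> pd.DataFrame:
    """Weighted per-water enthalpy histograms by environment (long form)."""
    rows = []
    for lab, (vals, ws) in sorted(ledger.water_samples.items()):
        hist, edges = np.histogram(vals, bins=bins, weights=ws)
        for k in range(len(hist)):
            rows.append((lab, edges[k], edges[k + 1], hist[k]))
    return pd.DataFrame(
        rows, columns=["environment", "bin_lo", "bin_hi", "weighted_count"]
    )
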