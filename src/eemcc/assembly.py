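"""Entropy ledger, free-energy tables and the excipient-binding ΔG.

The total entropy is a sum of components S_ijkl over molecule/species
i, level j (united atom, monomer, polymer), type k (vibrational or
topographical) and motion l (translation or rotation).  Combined with
per-species enthalpies this gives G = H - T*S per species in each
state, and the binding free energy of moving a set of excipients (with
counterions) from dilute solution onto a buffered protein system:

    dG = sum_X [ G_X,bnd N_X + G_W,bnd N_WX,bnd
                 + G_W,bulk (N_WX,dil - N_WX,bnd) ]
               - [ G_X,dil N_X + G_W,dil N_WX,dil ]

where N_WX counts the hydration-shell waters of species X and waters
released to bulk are priced at the pure-water reference free energy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import DEFAULT_CONSTANTS, PhysicalConstants
from .topology import Topology

LEVELS_ORDER = ("UA", "M", "P")
TYPES = ("vibrational", "topographical")
MOTIONS = ("translation", "rotation")


class LedgerError(ValueError):
    pass


@dataclass
class EntropyLedger:
    """Entropy components keyed (species, level, type, motion), J K^-1 mol^-1.

    Values are per molecule of the species (averaged over the species'
    molecules), the convention used for free-energy tables.
    """

    components: dict[tuple[str, str, str, str], float] = field(
        default_factory=dict
    )
    declared_levels: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def total(self, species: str | None = None) -> float:
        return sum(
            v for (sp, *_), v in self.components.items()
            if species is None or sp == species
        )


def declared_components(
    species: str,
    levels: tuple[str, ...],
    rotor: bool = True,
    has_dihedrals: bool = False,
) -> set[tuple[str, str, str, str]]:
    """The component keys a species must provide.

    Every declared level carries vibrational translation, plus
    vibrational rotation for non-monatomic units; water carries UA
    topographical rotation (orientational) and dihedral-bearing species
    UA topographical translation (conformational).
    """
    keys = set()
    for lv in levels:
        keys.add((species, lv, "vibrational", "translation"))
        if rotor:
            keys.add((species, lv, "vibrational", "rotation"))
    if species == "water" or (rotor and species == "water"):
        keys.add((species, "UA", "topographical", "rotation"))
    if has_dihedrals:
        keys.add((species, "UA", "topographical", "translation"))
    return keys


def assemble_ledger(
    vib: dict[tuple[int, str, str], float],
    topo: dict[tuple[str, str, str], float],
    top: Topology,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
) -> EntropyLedger:
    """Slot per-molecule vibrational and topographical entropies.

    ``vib`` maps (molecule, level, motion) to entropy; ``topo`` maps
    (species, "conformational"|"orientational", motion-free) —
    concretely keys (species, level, kind) with kind in
    {"conformational", "orientational"}.  Vibrational components are
    averaged over the species' molecules.  Missing declared components
    and components at undeclared levels are hard errors.
    """
    ledger = EntropyLedger()
    species_mols: dict[str, list[int]] = {}
    for mol, role in top.species.items():
        species_mols.setdefault(role, []).append(mol)

    for role, mols in species_mols.items():
        levels = top.levels_of_molecule(mols[0])
        ledger.declared_levels[role] = levels
        rotor = any(
            len(top.atoms_of("ua", int(u))) > 1
            or len(top.atoms_of("molecule", mols[0])) > 1
            for u in np.unique(top.ua_id[top.atoms_of("molecule", mols[0])])
        )
        has_dih = any(mon_id in {m for m, _ in top.dihedrals}
                      for mon_id in np.unique(
                          top.monomer_id[top.atoms_of("molecule", mols[0])]))
        required = declared_components(role, levels, rotor, has_dih)

        for mol in mols:
            for (m, lv, motion), s in vib.items():
                if m != mol:
                    continue
                if lv not in levels:
                    raise LedgerError(
                        f"molecule {mol} ({role}) reports level {lv} "
                        f"outside its declared levels {levels}"
                    )
                key = (role, lv, "vibrational", motion)
                ledger.components[key] = (
                    ledger.components.get(key, 0.0) + s / len(mols)
                )
        for (sp, lv, kind), s in topo.items():
            if sp != role:
                continue
            if lv not in levels:
                raise LedgerError(
                    f"species {role} topographical entropy at undeclared "
                    f"level {lv}"
                )
            motion = "rotation" if kind == "orientational" else "translation"
            ledger.components[(role, lv, "topographical", motion)] = s

        present = {k for k in ledger.components if k[0] == role}
        missing = {k for k in required if k not in present
                   and not (k[3] == "rotation" and not rotor)}
        if missing:
            raise LedgerError(
                f"species {role} is missing declared entropy components: "
                f"{sorted(missing)}"
            )
    return ledger


@dataclass
class SpeciesState:
    """Per-molecule thermodynamics of one species in one state.

    ``g``/``h``/``ts`` are kJ mol^-1 per molecule; ``n`` the molecule
    count; ``n_w`` the hydration-shell water count of the species and
    ``gw/hw/tsw`` the per-molecule thermodynamics of those waters.
    """

    g: float
    h: float
    ts: float
    n: float
    n_w: float = 0.0
    gw: float = 0.0
    hw: float = 0.0
    tsw: float = 0.0


def binding_delta_g(
    bound: dict[str, SpeciesState],
    dilute: dict[str, SpeciesState],
    bulk_water: SpeciesState,
) -> pd.DataFrame:
    """Binding decomposition table: one row per species X and per W_X.

    Released waters (N_WX,dil - N_WX,bnd) are priced at the bulk-water
    reference.  Returns columns dG, dH, TdS (kJ mol^-1) with a Total
    row; dG = dH - TdS holds row-wise by construction.
    """
    rows = {}
    for X in sorted(set(bound) | set(dilute)):
        b = bound.get(X)
        d = dilute.get(X)
        if b is None or d is None:
            raise LedgerError(f"species {X} missing from one state")
        if b.n_w < 0 or d.n_w < 0:
            raise LedgerError(f"negative hydration water count for {X}")
        rows[X] = (
            b.g * b.n - d.g * d.n,
            b.h * b.n - d.h * d.n,
            b.ts * b.n - d.ts * d.n,
        )
        dn_w = d.n_w - b.n_w  # waters released to bulk
        rows[f"W_{X}"] = (
            b.gw * b.n_w + bulk_water.g * dn_w - d.gw * d.n_w,
            b.hw * b.n_w + bulk_water.h * dn_w - d.hw * d.n_w,
            b.tsw * b.n_w + bulk_water.ts * dn_w - d.tsw * d.n_w,
        )
    df = pd.DataFrame.from_dict(
        rows, orient="index", columns=["dG", "dH", "TdS"]
    )
    df.loc["Total"] = df.sum(axis=0)
    return df


def classwise_decomposition(
    per_monomer: dict[int, tuple[float, float, float]],
    top: Topology,
) -> pd.DataFrame:
    """Group per-monomer (dG, dH, TdS) values by monomer class."""
    rows: dict[str, np.ndarray] = {}
    for mon, vals in per_monomer.items():
        cls = top.monomer_class[int(mon)]
        rows[cls] = rows.get(cls, np.zeros(3)) + np.asarray(vals, float)
    df = pd.DataFrame.from_dict(
        rows, orient="index", columns=["dG", "dH", "TdS"]
    ).sort_index()
    df.loc["Total"] = df.sum(axis=0)
    return df


def group_standard_error(
    values: np.ndarray,
    groups: np.ndarray,
) -> float:
    """Standard error over group means: std(means, ddof=1)/sqrt(n_groups).

    Used for multi-walker estimates analysed in groups of starting
    poses.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups for a standard error")
    means = np.array([values[groups == g].mean() for g in labels])
    return float(means.std(ddof=1) / np.sqrt(len(labels)))


def average_formal_charge(top: Topology, role: str) -> float:
    """Mean formal charge over the molecules of one species role."""
    mols = top.molecules_of_species(role)
    if len(mols) == 0:
        raise ValueError(f"no molecules with role {role!r}")
    return float(np.mean([top.formal_charge[int(m)] for m in mols]))


def check_free_energy_table(
    df: pd.DataFrame,
    decimals: int = 0,
    slack: float = 1.0,
) -> None:
    """Printed-precision consistency of an exported decomposition table.

    At export rounding, component rows must sum to the Total row within
    ``slack`` (one unit in the last printed place absorbs rounding of
    individual rows), and dG = dH - TdS must hold per row to the same
    slack (independently rounded columns can disagree by one unit).
    """
    if "Total" not in df.index:
        raise LedgerError("table has no Total row")
    body = df.drop(index="Total").round(decimals)
    total = df.loc["Total"].round(decimals)
    if np.any(np.abs(body.sum(axis=0) - total) > slack):
        raise LedgerError("component rows do not sum to Total at printed precision")
    resid = (df["dG"] - (df["dH"] - df["TdS"])).abs()
    if np.any(resid > slack + 1e-9):
        raise LedgerError("dG = dH - TdS violated beyond rounding")


def export_free_energy_table(df: pd.DataFrame, path) -> None:
    """Write a decomposition table rounded to whole kJ mol^-1."""
    check_free_energy_table(df)
    df.round(0).astype(int).to_csv(path)
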