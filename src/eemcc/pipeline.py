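"""High-level pipeline stages used by the CLI and the worked examples.

Each stage is a plain function from in-memory objects to in-memory
objects or DataFrames; the CLI wires file I/O and logging around them.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .assembly import SpeciesState, assemble_ledger, binding_delta_g
from .constants import DEFAULT_CONSTANTS, PhysicalConstants
from .energy import aggregate_energy
from .frames import FrameEnsemble
from .neighbourhood import (
    assign_hbonds,
    build_shells,
    classify_water,
    contact_table,
    donor_acceptor_probabilities,
    water_environment_counts,
)
from .reweighting import frame_weights
from .topographical import build_conformer_distribution, conformational_entropy, orientational_entropy
from .topology import Topology
from .vibrational import vibrational_entropies

log = logging.getLogger("eemcc")


def species_thermodynamics(
    ens: FrameEnsemble,
    top: Topology,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
    cutoff: float = 8.0,
    weights: np.ndarray | None = None,
    weight_protein: bool = False,
) -> dict:
    """Per-species G, H, T*S (kJ mol^-1 per molecule) for one ensemble.

    Frame weights (from a metadynamics bias) apply to water/excipient
    statistics, energies and contacts; protein entropy terms stay
    unweighted unless ``weight_protein`` is set.
    """
    if ens.bias is not None and weights is None:
        weights = frame_weights(ens.bias, constants).w
    shells = build_shells(ens, top, cutoff=cutoff)
    log.info("built shells for %d frames, %d united atoms",
             shells.n_frames, len(top.units('ua')))
    hbonds = assign_hbonds(ens, shells, top)
    labels = classify_water(shells, top)
    env_counts = water_environment_counts(labels, weights)
    log.info("water environments (mean counts): %s",
             env_counts.round(2).to_dict())

    ledger_energy = aggregate_energy(ens, top, water_labels=labels,
                                     weights=weights)
    contacts = contact_table(ens, shells, top, weights=weights)

    # entropies: protein terms unweighted by convention
    w_nonprot = weights
    vib_w = {}
    vib_unw = vibrational_entropies(ens, top, constants, weights=None)
    if w_nonprot is not None:
        vib_biased = vibrational_entropies(ens, top, constants, weights=w_nonprot)
    else:
        vib_biased = vib_unw
    for key, s in vib_unw.items():
        mol = key[0]
        use_unweighted = (top.species[mol] == "protein") and not weight_protein
        vib_w[key] = s if use_unweighted else vib_biased[key]

    topo: dict[tuple[str, str, str], float] = {}
    waters = top.molecules_of_species("water")
    if len(waters):
        stats = donor_acceptor_probabilities(
            ens, shells, hbonds, top, weights=w_nonprot
        )
        topo[("water", "UA", "orientational")] = orientational_entropy(
            stats, constants
        )
    # conformational entropy per species with registered dihedrals
    by_species: dict[str, list[float]] = {}
    for mon, quad in top.dihedrals:
        atoms = np.array(quad)
        mol = int(top.molecule_id[atoms[0]])
        role = top.species[mol]
        series = _dihedral_series(ens, atoms)
        dist = build_conformer_distribution(
            series[None, :],
            None if (role == "protein" and not weight_protein) else w_nonprot,
        )
        by_species.setdefault(role, []).append(
            conformational_entropy(dist, constants)
        )
    for role, vals in by_species.items():
        n_mol = len(top.molecules_of_species(role))
        topo[(role, "UA", "conformational")] = float(np.sum(vals)) / n_mol

    ledger = assemble_ledger(vib_w, topo, top, constants)
    out: dict[str, SpeciesState] = {}
    for role in sorted(set(top.species.values())):
        n_mol = len(top.molecules_of_species(role))
        h = ledger_energy.per_species.get(role, 0.0) / n_mol
        ts = constants.T * ledger.total(role) / 1000.0
        out[role] = SpeciesState(g=h - ts, h=h, ts=ts, n=n_mol)
    return {
        "species": out,
        "ledger": ledger,
        "energy": ledger_energy,
        "contacts": contacts,
        "water_environments": env_counts,
        "water_labels": labels,
        "shells": shells,
    }


def _dihedral_series(ens: FrameEnsemble, atoms: np.ndarray) -> np.ndarray:
    """Signed dihedral angle (deg) of an atom quadruple over all frames."""
    p = ens.positions[:, atoms, :]
    b1 = p[:, 1] - p[:, 0]
    b2 = p[:, 2] - p[:, 1]
    b3 = p[:, 3] - p[:, 2]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2, axis=1, keepdims=True))
    x = np.einsum("ij,ij->i", n1, n2)
    y = np.einsum("ij,ij->i", m1, n2)
    ang = np.degrees(np.arctan2(y, x))
    return (ang + 180.0) % 360.0 - 180.0


def binding_table(
    bound: dict,
    dilute: dict,
    bulk_water: SpeciesState,
    hydration_counts_bound: dict[str, float],
    hydration_counts_dilute: dict[str, float],
) -> pd.DataFrame:
    """Assemble the binding decomposition from two pipeline results."""
    b_states = {}
    d_states = {}
    for role in bound["species"]:
        if role == "water":
            continue
        b = bound["species"][role]
        d = dilute["species"][role]
        wb = bound["species"].get("water")
        wd = dilute["species"].get("water")
        b_states[role] = SpeciesState(
            g=b.g, h=b.h, ts=b.ts, n=b.n,
            n_w=hydration_counts_bound.get(role, 0.0),
            gw=wb.g if wb else 0.0, hw=wb.h if wb else 0.0,
            tsw=wb.ts if wb else 0.0,
        )
        d_states[role] = SpeciesState(
            g=d.g, h=d.h, ts=d.ts, n=d.n,
            n_w=hydration_counts_dilute.get(role, 0.0),
            gw=wd.g if wd else 0.0, hw=wd.h if wd else 0.0,
            tsw=wd.ts if wd else 0.0,
        )
    return binding_delta_g(b_states, d_states, bulk_water)
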