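"""Solvent-structure layer: coordination shells, hydrogen bonds, contacts.

Coordination shells are parameter-free relative-angular-distance (RAD)
shells built on united-atom (heavy-atom) positions: a candidate
neighbour j of centre i is rejected if any closer candidate k "blocks"
it, i.e. if ``1/r_ij^2 < (1/r_ik^2) * cos(theta_jik)``.  Hydrogen bonds
are topological: each donor hydrogen is assigned to the shell acceptor
with the most negative ``q_D * q_A / r^2``.  Water environments are
classified by which species roles appear in the water's shell.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .frames import FrameEnsemble, minimum_image
from .topology import Topology

EXCIPIENT_ROLES = frozenset({"polyanion", "buffer", "cation", "anion"})
WATER_LABELS = ("bulk", "WP", "WPP", "WEP", "WEPP", "WE")


@dataclass
class CoordinationShellMap:
    """RAD shells per frame: ``shells[frame][ua] = [(neigh_ua, r), ...]``."""

    shells: list[dict[int, list[tuple[int, float]]]]
    cutoff: float

    @property
    def n_frames(self) -> int:
        return len(self.shells)

    def neighbours(self, frame: int, ua: int) -> list[int]:
        return [n for n, _ in self.shells[frame].get(ua, [])]


@dataclass
class HBondAssignment:
    """Per frame, donor hydrogen atom index -> acceptor united atom."""

    assignments: list[dict[int, int]]


@dataclass
class ShellObservation:
    """One water molecule in one frame, reduced to labelled events.

    ``shell_labels`` is the multiset of neighbour-type labels in the
    water's coordination shell; ``donated``/``accepted`` are the
    neighbour-type labels of this water's donation and acceptance
    events in that frame.
    """

    shell_labels: tuple[str, ...]
    donated: tuple[str, ...]
    accepted: tuple[str, ...]
    weight: float = 1.0
    water: int = -1
    frame: int = -1


def rad_shell(
    center_pos: np.ndarray,
    candidate_pos: np.ndarray,
    box: np.ndarray | None = None,
) -> list[tuple[int, float]]:
    """RAD-retained candidates around one centre.

    Returns ``(candidate_index, distance)`` pairs.  Candidates are
    processed in order of increasing distance; j is retained iff no
    strictly closer candidate k satisfies the blocking inequality
    ``1/r_j^2 < (1/r_k^2) * cos(theta_jik)``.
    """
    if len(candidate_pos) == 0:
        return []
    vec = candidate_pos - center_pos
    if box is not None:
        vec = minimum_image(vec, box)
    r = np.linalg.norm(vec, axis=1)
    if np.any(r < 1e-9):
        raise ValueError("coincident atom positions: RAD angle undefined")
    order = np.argsort(r, kind="stable")
    retained: list[tuple[int, float]] = []
    for pos_j in range(len(order)):
        j = order[pos_j]
        blocked = False
        for pos_k in range(pos_j):
            k = order[pos_k]
            if r[k] >= r[j]:
                continue  # equal distances do not block
            cos_t = float(vec[j] @ vec[k] / (r[j] * r[k]))
            if 1.0 / r[j] ** 2 < cos_t / r[k] ** 2:
                blocked = True
                break
        if not blocked:
            retained.append((int(j), float(r[j])))
    return retained


def ua_positions(top: Topology, positions: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Heavy-atom position of each united atom.

    Returns (ua ids sorted, positions (n_ua, 3)).
    """
    uas = top.units("ua")
    pos = np.array([positions[top.heavy_atom_of_ua(int(u))] for u in uas])
    return uas, pos


def build_shells(
    ens: FrameEnsemble,
    top: Topology,
    cutoff: float = 8.0,
) -> CoordinationShellMap:
    """RAD coordination shells of every united atom in every frame.

    Candidates are united atoms within ``cutoff`` (minimum image); the
    centre's own UA is excluded.
    """
    uas = top.units("ua")
    heavy = np.array([top.heavy_atom_of_ua(int(u)) for u in uas])
    frames = []
    for f in range(ens.n_frames):
        pos = ens.positions[f][heavy]
        box = ens.box[f]
        shell_f: dict[int, list[tuple[int, float]]] = {}
        vec_all = minimum_image(pos[None, :, :] - pos[:, None, :], box)
        dist = np.linalg.norm(vec_all, axis=2)
        for ci in range(len(uas)):
            cand = np.flatnonzero((dist[ci] <= cutoff) & (np.arange(len(uas)) != ci))
            kept = rad_shell(pos[ci], pos[ci] + vec_all[ci, cand], box=None)
            shell_f[int(uas[ci])] = [
                (int(uas[cand[j]]), r) for j, r in kept
            ]
        frames.append(shell_f)
    return CoordinationShellMap(shells=frames, cutoff=cutoff)


def assign_hbonds(
    ens: FrameEnsemble,
    shells: CoordinationShellMap,
    top: Topology,
) -> HBondAssignment:
    """Topological hydrogen bonds: argmin over shell acceptors of qD*qA/r^2.

    Donors are hydrogens bonded to N or O; acceptor candidates are the
    heavy atoms of the donor united atom's shell members.  A donor with
    no negative-product candidate is left unassigned.
    """
    donors = top.donor_hydrogens()
    out = []
    for f in range(ens.n_frames):
        box = ens.box[f]
        assign: dict[int, int] = {}
        for h, het in donors:
            ua = int(top.ua_id[het])
            qd = top.charge[h]
            best_score, best_ua = 0.0, None
            for nua, _ in shells.shells[f].get(ua, []):
                acc = top.heavy_atom_of_ua(nua)
                qa = top.charge[acc]
                dvec = minimum_image(ens.positions[f, acc] - ens.positions[f, h], box)
                r2 = float(dvec @ dvec)
                score = qd * qa / r2
                if score < best_score:
                    best_score, best_ua = score, nua
            if best_ua is not None:
                assign[h] = best_ua
        out.append(assign)
    return HBondAssignment(assignments=out)


def _neighbour_label(
    ua: int,
    top: Topology,
    shell_f: dict[int, list[tuple[int, float]]],
) -> str:
    """Neighbour-type label for orientational statistics.

    Non-water neighbours are labelled by their species role.  A water
    neighbour takes the role of the nearest solute whose coordination
    shell it sits in, and is ``bulk`` otherwise.
    """
    role = top.species_of_ua(ua)
    if role != "water":
        return role
    best: tuple[float, str] | None = None
    for solute_ua, members in shell_f.items():
        srole = top.species_of_ua(solute_ua)
        if srole == "water":
            continue
        for n, r in members:
            if n == ua and (best is None or r < best[0]):
                best = (r, srole)
    return f"near-{best[1]}" if best is not None else "bulk"


def water_observations(
    ens: FrameEnsemble,
    shells: CoordinationShellMap,
    hbonds: HBondAssignment,
    top: Topology,
    waters: np.ndarray | None = None,
    weights: np.ndarray | None = None,
) -> tuple[list[ShellObservation], int]:
    """Reduce geometry to per-(water, frame) labelled shell/HB events.

    Returns the observations plus a tally of waters excluded for having
    an empty coordination shell.
    """
    if waters is None:
        waters = top.molecules_of_species("water")
    if weights is None:
        weights = np.ones(ens.n_frames)
    water_ua = {int(m): int(top.ua_id[top.atoms_of("molecule", int(m))[0]])
                for m in waters}
    ua_to_water = {u: m for m, u in water_ua.items()}
    obs: list[ShellObservation] = []
    empty = 0
    for f in range(ens.n_frames):
        shell_f = shells.shells[f]
        assign = hbonds.assignments[f]
        # donor events grouped by acceptor UA for acceptance lookups
        donors_by_acceptor: dict[int, list[int]] = defaultdict(list)
        for h, acc_ua in assign.items():
            donors_by_acceptor[acc_ua].append(h)
        for m in waters:
            ua = water_ua[int(m)]
            members = shell_f.get(ua, [])
            if not members:
                empty += 1
                continue
            labels = tuple(sorted(_neighbour_label(n, top, shell_f)
                                  for n, _ in members))
            label_of = {n: _neighbour_label(n, top, shell_f) for n, _ in members}
            donated = tuple(
                label_of[assign[h]]
                for h in np.flatnonzero(top.ua_id == ua)
                if top.element[h] == "H" and h in assign and assign[h] in label_of
            )
            accepted = []
            for h in donors_by_acceptor.get(ua, []):
                donor_ua = int(top.ua_id[h])
                if donor_ua in label_of:
                    accepted.append(label_of[donor_ua])
            obs.append(ShellObservation(
                shell_labels=labels,
                donated=donated,
                accepted=tuple(accepted),
                weight=float(weights[f]),
                water=int(m),
                frame=f,
            ))
    return obs, empty


@dataclass
class OrientationalStats:
    """Per-shell-type inputs to the water orientational entropy.

    For each shell type ``c`` (a sorted multiset of neighbour labels):
    ``p_c`` its weighted probability, ``N_i`` mean neighbour counts per
    label, and ``p_D``/``p_A`` donation/acceptance event fractions per
    label (both equal to 1 in the single-type bulk limit).
    """

    p_c: dict[tuple[str, ...], float] = field(default_factory=dict)
    N_i: dict[tuple[str, ...], dict[str, float]] = field(default_factory=dict)
    p_D: dict[tuple[str, ...], dict[str, float]] = field(default_factory=dict)
    p_A: dict[tuple[str, ...], dict[str, float]] = field(default_factory=dict)
    excluded_empty: int = 0

    def N_c(self, c: tuple[str, ...]) -> float:
        return sum(self.N_i[c].values())


def accumulate_orientational_stats(
    obs: list[ShellObservation],
    excluded_empty: int = 0,
) -> OrientationalStats:
    """Pool labelled observations into per-shell-type statistics."""
    if not obs:
        raise ValueError("no shell observations to accumulate")
    w_c: dict[tuple[str, ...], float] = defaultdict(float)
    n_i: dict[tuple[str, ...], Counter] = defaultdict(Counter)
    don: dict[tuple[str, ...], Counter] = defaultdict(Counter)
    acc: dict[tuple[str, ...], Counter] = defaultdict(Counter)
    for o in obs:
        c = o.shell_labels
        w_c[c] += o.weight
        for lab, k in Counter(o.shell_labels).items():
            n_i[c][lab] += o.weight * k
        for lab in o.donated:
            don[c][lab] += o.weight
        for lab in o.accepted:
            acc[c][lab] += o.weight
    total_w = sum(w_c.values())
    stats = OrientationalStats(excluded_empty=excluded_empty)
    for c, w in w_c.items():
        stats.p_c[c] = w / total_w
        stats.N_i[c] = {lab: cnt / w for lab, cnt in n_i[c].items()}
        labels = sorted(stats.N_i[c])
        dtot = sum(don[c].values())
        atot = sum(acc[c].values())
        stats.p_D[c] = {
            lab: (don[c][lab] / dtot if dtot > 0 else 0.0) for lab in labels
        }
        stats.p_A[c] = {
            lab: (acc[c][lab] / atot if atot > 0 else 0.0) for lab in labels
        }
    return stats


def donor_acceptor_probabilities(
    ens: FrameEnsemble,
    shells: CoordinationShellMap,
    hbonds: HBondAssignment,
    top: Topology,
    waters: np.ndarray | None = None,
    weights: np.ndarray | None = None,
) -> OrientationalStats:
    """Donation/acceptance fractions per neighbour type per shell type."""
    obs, empty = water_observations(ens, shells, hbonds, top, waters, weights)
    return accumulate_orientational_stats(obs, excluded_empty=empty)


def classify_water(
    shells: CoordinationShellMap,
    top: Topology,
) -> list[dict[int, str]]:
    """Water environment label per water molecule per frame.

    Labels follow the shell's species content: one protein (WP), two
    proteins (WPP), protein(s) plus any excipient/counterion (WEP /
    WEPP), excipient/counterion only (WE), otherwise bulk.  Neighbour
    waters never trigger a solute category.
    """
    waters = top.molecules_of_species("water")
    water_ua = {int(m): int(top.ua_id[top.atoms_of("molecule", int(m))[0]])
                for m in waters}
    out = []
    for f in range(shells.n_frames):
        labels: dict[int, str] = {}
        for m, ua in water_ua.items():
            prot_mols = set()
            has_exc = False
            for n, _ in shells.shells[f].get(ua, []):
                mol = top.molecule_of_ua(n)
                role = top.species[mol]
                if role == "protein":
                    prot_mols.add(mol)
                elif role in EXCIPIENT_ROLES:
                    has_exc = True
            np_ = len(prot_mols)
            if np_ >= 2:
                labels[m] = "WEPP" if has_exc else "WPP"
            elif np_ == 1:
                labels[m] = "WEP" if has_exc else "WP"
            else:
                labels[m] = "WE" if has_exc else "bulk"
        out.append(labels)
    return out


def water_environment_counts(
    labels: list[dict[int, str]],
    weights: np.ndarray | None = None,
) -> pd.Series:
    """Weighted mean number of waters in each environment per frame."""
    if weights is None:
        weights = np.ones(len(labels))
    counts = {lab: 0.0 for lab in WATER_LABELS}
    for f, lab_f in enumerate(labels):
        for lab in lab_f.values():
            counts[lab] += weights[f]
    tot_w = float(np.sum(weights))
    return pd.Series({k: v / tot_w for k, v in counts.items()})


def switching_contacts(
    distances: np.ndarray,
    d0: float,
    r0: float,
) -> float:
    """Continuous contact count with the rational switching function.

    ``s(r) = (1 - x^6) / (1 - x^12)`` with ``x = (r - d0)/r0``, which
    simplifies to ``1/(1 + x^6)`` including the removable singularity
    at x = 1 (value 1/2).  Distances below d0 count as full contacts.
    """
    if d0 < 0 or r0 <= 0:
        raise ValueError("d0 must be >= 0 and r0 > 0")
    x = np.maximum(np.asarray(distances, dtype=float) - d0, 0.0) / r0
    return float(np.sum(1.0 / (1.0 + x**6)))


def contact_table(
    ens: FrameEnsemble,
    shells: CoordinationShellMap,
    top: Topology,
    weights: np.ndarray | None = None,
) -> pd.DataFrame:
    """Ensemble-average intermolecular UA contact counts by species role.

    A contact between united atoms a and b (different molecules) exists
    in a frame if either RAD shell contains the other; each unordered
    pair counts once and is added symmetrically to the role matrix.
    """
    if weights is None:
        weights = np.ones(ens.n_frames)
    roles = sorted(set(top.species.values()))
    table = pd.DataFrame(0.0, index=roles, columns=roles)
    mol_of = {int(u): top.molecule_of_ua(int(u)) for u in top.units("ua")}
    role_of = {u: top.species[m] for u, m in mol_of.items()}
    for f in range(ens.n_frames):
        pairs = set()
        for ua, members in shells.shells[f].items():
            for n, _ in members:
                if mol_of[ua] != mol_of[n]:
                    pairs.add((min(ua, n), max(ua, n)))
        w = weights[f]
        for a, b in pairs:
            ra, rb = role_of[a], role_of[b]
            table.loc[ra, rb] += w
            if ra != rb:
                table.loc[rb, ra] += w
    return table / np.sum(weights)


def per_molecule_contacts(
    table: pd.DataFrame,
    top: Topology | None = None,
    counts: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Row-normalised contact table: contacts per molecule of the row species."""
    if counts is None:
        if top is None:
            raise ValueError("need a topology or explicit molecule counts")
        counts = {r: len(top.molecules_of_species(r)) for r in table.index}
    out = table.copy()
    for r in out.index:
        n = counts.get(r, 0)
        if n > 0:
            out.loc[r] = out.loc[r] / n
    return out
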