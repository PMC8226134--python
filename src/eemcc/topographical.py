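"""Topographical entropy: dihedral conformers and water orientations.

Conformational entropy discretises each dihedral series into 30-degree
bins; conformers sit on histogram peaks (bins more populated than both
circular neighbours, no two peaks closer than 60 degrees) and the joint
state over a monomer's dihedrals gives a Shannon entropy -kB sum p ln p.

Orientational entropy of a water molecule scores how biased its
hydrogen bonding is towards particular neighbour types:

    S = kB * sum_c p(c) ln[ (Neff * pi)^(3/2) * p(HBav) / sigma ]

with p(HBi) = pD*pA/(pD+pA)^2 per neighbour type (0.25 when unbiased),
p(HBav) its shell average and Neff = sum_i p(HBi) Ni / 0.25 the
effective number of hydrogen-bonding neighbours.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .constants import R_GAS, DEFAULT_CONSTANTS, PhysicalConstants
from .neighbourhood import OrientationalStats

N_BINS = 12
BIN_WIDTH = 360.0 / N_BINS
BIN_CENTERS = -180.0 + BIN_WIDTH * (np.arange(N_BINS) + 0.5)


def _circular_distance(a: np.ndarray, b: float) -> np.ndarray:
    d = np.abs(np.asarray(a) - b) % 360.0
    return np.minimum(d, 360.0 - d)


def find_conformers(
    angles: np.ndarray,
    weights: np.ndarray | None = None,
) -> np.ndarray:
    """Peak centres (deg) of a dihedral distribution on 30-degree bins.

    A peak bin is strictly more populated than both circular
    neighbours; of two peaks closer than 60 degrees the more populated
    survives (ties to the lower bin index).  A flat distribution with
    no peak collapses to a single conformer at the most populated bin,
    with a warning.
    """
    angles = np.asarray(angles, dtype=float)
    if angles.size == 0:
        raise ValueError("empty dihedral series")
    if np.any(angles < -180.0) or np.any(angles >= 180.0):
        raise ValueError("angles must lie in [-180, 180)")
    idx = np.floor((angles + 180.0) / BIN_WIDTH).astype(int)
    hist = np.bincount(idx, weights=weights, minlength=N_BINS).astype(float)
    peaks = [
        b for b in range(N_BINS)
        if hist[b] > hist[(b - 1) % N_BINS] and hist[b] > hist[(b + 1) % N_BINS]
    ]
    # enforce minimum 60-degree separation, keeping the more populated
    peaks.sort(key=lambda b: (-hist[b], b))
    kept: list[int] = []
    for b in peaks:
        if all(_circular_distance(BIN_CENTERS[b], BIN_CENTERS[o]) >= 60.0 - 1e-9
               for o in kept):
            kept.append(b)
    if not kept:
        warnings.warn(
            "no dihedral histogram peak; collapsing to a single conformer",
            stacklevel=2,
        )
        kept = [int(np.argmax(hist))]
    return BIN_CENTERS[np.sort(kept)]


def assign_conformers(angles: np.ndarray, peaks: np.ndarray) -> np.ndarray:
    """Index of the nearest peak (periodic distance) for each angle."""
    d = np.stack([_circular_distance(angles, p) for p in peaks])
    return np.argmin(d, axis=0)


@dataclass
class ConformerDistribution:
    """Joint conformer-state probabilities over a monomer's dihedrals."""

    peaks: list[np.ndarray]  # peak centres per dihedral
    state_probs: dict[tuple[int, ...], float]

    @property
    def n_conf(self) -> int:
        return len(self.state_probs)


def build_conformer_distribution(
    angle_series: np.ndarray,
    weights: np.ndarray | None = None,
) -> ConformerDistribution:
    """Discretise (n_dihedrals, n_frames) angle series into joint states."""
    angle_series = np.atleast_2d(np.asarray(angle_series, dtype=float))
    nd, nf = angle_series.shape
    if nf == 0:
        raise ValueError("empty dihedral series")
    if weights is None:
        weights = np.ones(nf)
    peaks = [find_conformers(angle_series[d], weights) for d in range(nd)]
    states = np.stack(
        [assign_conformers(angle_series[d], peaks[d]) for d in range(nd)]
    )  # (nd, nf)
    probs: dict[tuple[int, ...], float] = {}
    for f in range(nf):
        key = tuple(int(s) for s in states[:, f])
        probs[key] = probs.get(key, 0.0) + float(weights[f])
    tot = sum(probs.values())
    return ConformerDistribution(
        peaks=peaks, state_probs={k: v / tot for k, v in probs.items()}
    )


def conformational_entropy(
    dist: ConformerDistribution,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
) -> float:
    """Shannon entropy -kB sum p ln p of the joint states, J K^-1 mol^-1."""
    p = np.array([v for v in dist.state_probs.values() if v > 0])
    return float(-R_GAS * np.sum(p * np.log(p)))


def hb_bias(p_d: float, p_a: float) -> float:
    """Hydrogen-bond bias p(HBi); 0.25 when donating and accepting equally."""
    s = p_d + p_a
    if s == 0:
        return 0.0
    return (p_d / s) * (p_a / s)


@dataclass
class ShellTypeTerm:
    """Per-shell-type quantities entering the orientational sum."""

    p_c: float
    N_c: float
    p_HBav: float
    Neff: float
    entropy_term: float  # ln argument contribution, in kB units


def orientational_entropy(
    stats: OrientationalStats,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
    exponent: str = "neff_pi_3_2",
    return_terms: bool = False,
):
    """Water orientational entropy from donor/acceptor statistics.

    ``exponent`` selects the grouping of the orientational phase-space
    factor: ``"neff_pi_3_2"`` uses (Neff*pi)^(3/2) (default),
    ``"neff_3_2_pi_1_2"`` uses Neff^(3/2)*pi^(1/2); the two differ by a
    constant per shell type and must be pinned before comparing
    absolute numbers.  Shell types whose Neff*p(HBav) vanishes carry no
    orientational freedom; they are dropped and p(c) renormalised, with
    the dropped weight tallied.
    """
    sigma = constants.sigma_water
    terms: dict[tuple[str, ...], ShellTypeTerm] = {}
    dropped = 0.0
    for c, pc in stats.p_c.items():
        ni = stats.N_i[c]
        nc = sum(ni.values())
        phb = {lab: hb_bias(stats.p_D[c].get(lab, 0.0),
                            stats.p_A[c].get(lab, 0.0)) for lab in ni}
        p_hbav = sum(phb[lab] * ni[lab] for lab in ni) / nc
        neff = sum(phb[lab] * ni[lab] for lab in ni) / 0.25
        if neff * p_hbav <= 0:
            dropped += pc
            continue
        if exponent == "neff_pi_3_2":
            arg = (neff * np.pi) ** 1.5 * p_hbav / sigma
        elif exponent == "neff_3_2_pi_1_2":
            arg = neff**1.5 * np.sqrt(np.pi) * p_hbav / sigma
        else:
            raise ValueError(f"unknown exponent grouping {exponent!r}")
        terms[c] = ShellTypeTerm(
            p_c=pc, N_c=nc, p_HBav=p_hbav, Neff=neff,
            entropy_term=float(np.log(arg)),
        )
    live = sum(t.p_c for t in terms.values())
    if live == 0:
        s = 0.0
    else:
        s = float(R_GAS * sum(t.p_c / live * t.entropy_term
                              for t in terms.values()))
    if return_terms:
        return s, terms, dropped
    return s
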