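"""Quasi-harmonic vibrational entropy from force/torque covariances.

For each molecule and length scale (united atom, monomer, polymer) the
forces on each unit are summed, rotated into the unit's body frame and
mass-weighted (F / sqrt(M)); torques about the unit's centre of mass are
inertia-weighted (tau / sqrt(I)) along instantaneous principal axes.
Eigenvalues lambda_i of the covariance matrices give mode frequencies

    nu_i = (1 / 2 pi) * sqrt(lambda_i / (kB T))

and each retained mode contributes the quantum harmonic oscillator
entropy.  In the mean-field approximation polymer-level forces and
torques at every level are halved.  At every level below a molecule's
highest, the six lowest force-covariance modes duplicate the rigid-body
motion resolved at the level above and are removed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .constants import (
    AMU_TO_KG,
    FORCE_TO_SI,
    INERTIA_TO_SI,
    R_GAS,
    TORQUE_TO_SI,
    DEFAULT_CONSTANTS,
    PhysicalConstants,
)
from .frames import FrameEnsemble
from .topology import Topology

LEVELS = ("UA", "M", "P")
#: inertia eigenvalue ratio below which an axis is treated as degenerate
LINEAR_TOL = 1e-8


class CovarianceError(ValueError):
    pass


@dataclass
class CovarianceSet:
    """Force and torque covariances for one molecule at one level."""

    molecule: int
    level: str
    force_cov: np.ndarray  # (3N, 3N), SI (s^-2 after / kBT)
    torque_cov: np.ndarray | None  # (Nrot, Nrot) or None if no rotors
    n_frames: int
    weight_sum: float


@dataclass
class ModeSpectrum:
    """Sorted mode frequencies (s^-1) with removal flags."""

    molecule: int
    level: str
    freq_trans: np.ndarray
    freq_rot: np.ndarray
    removed_trans: np.ndarray = field(default=None)  # bool mask

    def __post_init__(self):
        if self.removed_trans is None:
            self.removed_trans = np.zeros(len(self.freq_trans), dtype=bool)

    def retained(self, motion: str) -> np.ndarray:
        if motion == "translation":
            return self.freq_trans[~self.removed_trans]
        return self.freq_rot


def _units_at_level(top: Topology, mol: int, level: str) -> list[np.ndarray]:
    """Atom-index groups of the molecule's units at the given level."""
    atoms = top.atoms_of("molecule", mol)
    if level == "P":
        return [atoms]
    key = {"UA": top.ua_id, "M": top.monomer_id}[level]
    return [atoms[key[atoms] == u] for u in np.unique(key[atoms])]


def _principal_frame(pos: np.ndarray, mass: np.ndarray):
    """Principal inertia axes (rows) and moments about the COM.

    Axes are sign-fixed (largest-magnitude component positive) and made
    right-handed so the body frame is deterministic.
    """
    com = np.average(pos, axis=0, weights=mass)
    d = pos - com
    inertia = np.zeros((3, 3))
    for m, r in zip(mass, d):
        inertia += m * ((r @ r) * np.eye(3) - np.outer(r, r))
    moments, axes = np.linalg.eigh(inertia)
    axes = axes.T  # rows are axes
    for i in range(3):
        j = int(np.argmax(np.abs(axes[i])))
        if axes[i, j] < 0:
            axes[i] = -axes[i]
    if np.linalg.det(axes) < 0:
        axes[2] = -axes[2]
    return com, axes, moments


def _ua_frame(top: Topology, pos_frame: np.ndarray, atoms: np.ndarray) -> np.ndarray:
    """Body frame of a united atom from its covalent geometry.

    One axis points along the bond to the first bonded atom (heavy
    preferred), a second bonded atom fixes the plane; UAs without two
    usable bonds fall back to principal inertia axes, and single atoms
    to the lab frame.
    """
    if len(atoms) == 1 and len(top.bonded_to(int(atoms[0]))) == 0:
        return np.eye(3)
    heavy = atoms[top.element[atoms] != "H"][0]
    partners = sorted(
        top.bonded_to(int(heavy)),
        key=lambda a: (top.element[a] == "H", a),
    )
    vecs = []
    for p in partners:
        v = pos_frame[p] - pos_frame[heavy]
        n = np.linalg.norm(v)
        if n > 1e-9:
            vecs.append(v / n)
        if len(vecs) == 2:
            break
    if len(vecs) == 0:
        return np.eye(3)
    e1 = vecs[0]
    if len(vecs) == 2 and abs(vecs[1] @ e1) < 1 - 1e-6:
        e2 = vecs[1] - (vecs[1] @ e1) * e1
    else:
        trial = np.eye(3)[int(np.argmin(np.abs(e1)))]
        e2 = trial - (trial @ e1) * e1
    e2 /= np.linalg.norm(e2)
    e3 = np.cross(e1, e2)
    return np.stack([e1, e2, e3])


def build_covariances(
    ens: FrameEnsemble,
    top: Topology,
    level: str,
    weights: np.ndarray | None = None,
) -> list[CovarianceSet]:
    """Accumulate mass-weighted force / inertia-weighted torque covariances.

    One :class:`CovarianceSet` per molecule carrying the given level.
    Covariances are central (mean subtracted) and weighted if frame
    weights are supplied.  Accumulated quantities are in SI so that the
    eigenvalues divide directly by kB*T.
    """
    if level not in LEVELS:
        raise ValueError(f"unknown level {level!r}")
    if ens.n_frames < 2:
        raise CovarianceError("covariance undefined for a single frame")
    if weights is None:
        weights = np.ones(ens.n_frames)
    weights = np.asarray(weights, dtype=float)
    out = []
    for mol in (int(m) for m in top.units("molecule")):
        if level not in top.levels_of_molecule(mol):
            continue
        units = _units_at_level(top, mol, level)
        f_rows, t_rows = [], []
        for f in range(ens.n_frames):
            pos, frc = ens.positions[f], ens.forces[f]
            fvec, tvec = [], []
            for atoms in units:
                mass = top.mass[atoms]
                M = mass.sum()
                if level == "UA":
                    axes = _ua_frame(top, pos, atoms)
                    com = np.average(pos[atoms], axis=0, weights=mass)
                    moments = None
                else:
                    com, axes, moments = _principal_frame(pos[atoms], mass)
                F = frc[atoms].sum(axis=0)
                if level == "P":
                    F = F / 2.0  # mean-field halving of polymer forces
                fvec.append(axes @ F * FORCE_TO_SI / np.sqrt(M * AMU_TO_KG))
                if len(atoms) >= 2:
                    if moments is None:
                        _, axes_t, moments = _principal_frame(pos[atoms], mass)
                    else:
                        axes_t = axes
                    tau = np.zeros(3)
                    for a in atoms:
                        tau += np.cross(pos[a] - com, frc[a])
                    tau = (axes_t @ tau) / 2.0  # torques halved at all levels
                    keep = moments > LINEAR_TOL * moments.max()
                    ti = (tau[keep] * TORQUE_TO_SI
                          / np.sqrt(moments[keep] * INERTIA_TO_SI))
                    tvec.append(ti)
            f_rows.append(np.concatenate(fvec))
            t_rows.append(np.concatenate(tvec) if tvec else np.empty(0))
        F_mat = np.array(f_rows)
        wsum = weights.sum()
        Fc = F_mat - np.average(F_mat, axis=0, weights=weights)
        force_cov = (Fc * weights[:, None]).T @ Fc / wsum
        torque_cov = None
        if t_rows[0].size:
            T_mat = np.array(t_rows)
            Tc = T_mat - np.average(T_mat, axis=0, weights=weights)
            torque_cov = (Tc * weights[:, None]).T @ Tc / wsum
        out.append(CovarianceSet(
            molecule=mol, level=level, force_cov=force_cov,
            torque_cov=torque_cov, n_frames=ens.n_frames,
            weight_sum=float(wsum),
        ))
    return out


def frequencies(
    cov: CovarianceSet,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
    tol: float = 1e-8,
) -> ModeSpectrum:
    """Mode frequencies from covariance eigenvalues.

    Eigenvalues in [-tol*max, 0) are clamped to zero; more negative
    values indicate a broken covariance and are a hard error.
    """
    kBT = constants.kBT_si

    def _freqs(mat: np.ndarray) -> np.ndarray:
        if mat.size == 0:
            return np.empty(0)
        lam = np.linalg.eigvalsh((mat + mat.T) / 2)
        floor = -tol * max(abs(lam).max(), 1.0)
        if np.any(lam < floor):
            raise CovarianceError(
                f"covariance of molecule {cov.molecule} level {cov.level} "
                f"has eigenvalue {lam.min():.3e} below tolerance"
            )
        lam = np.clip(lam, 0.0, None)
        return np.sort(np.sqrt(lam / kBT) / (2 * np.pi))

    return ModeSpectrum(
        molecule=cov.molecule,
        level=cov.level,
        freq_trans=_freqs(cov.force_cov),
        freq_rot=(_freqs(cov.torque_cov)
                  if cov.torque_cov is not None else np.empty(0)),
    )


def remove_lowest_modes(
    spec: ModeSpectrum,
    highest_level: str,
) -> ModeSpectrum:
    """Flag the six lowest force modes as removed below the highest level.

    These duplicate the rigid-body translation/rotation resolved at the
    next level up.  At the molecule's highest level nothing is removed.
    """
    if spec.level == highest_level:
        return spec
    n = len(spec.freq_trans)
    if n < 7:
        raise CovarianceError(
            f"molecule {spec.molecule} level {spec.level} has only {n} "
            "translational modes; six-mode removal is ill-posed"
        )
    removed = np.zeros(n, dtype=bool)
    removed[:6] = True  # frequencies are sorted ascending
    return ModeSpectrum(
        molecule=spec.molecule, level=spec.level,
        freq_trans=spec.freq_trans, freq_rot=spec.freq_rot,
        removed_trans=removed,
    )


def svib_modes(
    freqs: np.ndarray,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
) -> float:
    """Quantum harmonic oscillator entropy of a set of modes, J K^-1 mol^-1.

    Zero-frequency modes contribute nothing (they are rigid-body modes
    that should have been removed) and trigger a warning.
    """
    freqs = np.asarray(freqs, dtype=float)
    if np.any(freqs == 0):
        warnings.warn(
            "zero-frequency mode survives removal; contributing zero entropy",
            stacklevel=2,
        )
    x = constants.h * freqs[freqs > 0] / constants.kBT_si
    with np.errstate(over="ignore"):  # x/expm1(x) -> 0 for huge x
        return float(R_GAS * np.sum(x / np.expm1(x) - np.log1p(-np.exp(-x))))


def svib(
    spec: ModeSpectrum,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
) -> dict[str, float]:
    """Vibrational entropy per motion for one molecule/level, J K^-1 mol^-1."""
    return {
        "translation": svib_modes(spec.retained("translation"), constants),
        "rotation": svib_modes(spec.retained("rotation"), constants),
    }


def vibrational_entropies(
    ens: FrameEnsemble,
    top: Topology,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
    weights: np.ndarray | None = None,
) -> dict[tuple[int, str, str], float]:
    """Full pipeline: {(molecule, level, motion): S} over declared levels."""
    out: dict[tuple[int, str, str], float] = {}
    highest = {int(m): top.levels_of_molecule(int(m))[-1]
               for m in top.units("molecule")}
    for level in LEVELS:
        for cov in build_covariances(ens, top, level, weights):
            spec = frequencies(cov, constants)
            spec = remove_lowest_modes(spec, highest_level=highest[cov.molecule])
            for motion, s in svib(spec, constants).items():
                out[(cov.molecule, level, motion)] = s
    return out
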