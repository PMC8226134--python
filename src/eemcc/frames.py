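"""Trajectory frames and the columnar dump / bias-file dialects.

Frames carry per-atom positions (A), forces (kJ mol^-1 A^-1) and per-atom
potential and kinetic energies (kJ mol^-1) together with the orthorhombic
box, as produced by engines that decompose many-body energy terms evenly
over the atoms involved.  The text dialect mirrors a LAMMPS dump with
``ITEM:`` section headers and a declared atom-column layout.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

ROLES = ("id", "x", "y", "z", "fx", "fy", "fz", "pe", "ke")
DEFAULT_COLUMNS = {
    "id": "id", "x": "x", "y": "y", "z": "z",
    "fx": "fx", "fy": "fy", "fz": "fz", "pe": "c_pe", "ke": "c_ke",
}


class FrameError(ValueError):
    """Raised on malformed or inconsistent trajectory input."""


@dataclass
class FrameEnsemble:
    """Time-ordered frames with constant atom count.

    ``bias`` is the metadynamics bias V(s, t) per frame in kJ mol^-1,
    or ``None`` for unbiased ensembles.
    """

    times: np.ndarray  # (nf,)
    box: np.ndarray  # (nf, 3) orthorhombic edge lengths, A
    positions: np.ndarray  # (nf, n, 3) A
    forces: np.ndarray  # (nf, n, 3) kJ mol^-1 A^-1
    pe: np.ndarray  # (nf, n) kJ mol^-1
    ke: np.ndarray  # (nf, n) kJ mol^-1
    bias: np.ndarray | None = None  # (nf,) kJ mol^-1

    @property
    def n_frames(self) -> int:
        return len(self.times)

    @property
    def n_atoms(self) -> int:
        return self.positions.shape[1]

    def validate(self) -> None:
        nf, n = self.positions.shape[:2]
        for name, arr, shape in (
            ("times", self.times, (nf,)),
            ("box", self.box, (nf, 3)),
            ("forces", self.forces, (nf, n, 3)),
            ("pe", self.pe, (nf, n)),
            ("ke", self.ke, (nf, n)),
        ):
            if arr.shape != shape:
                raise FrameError(f"{name} has shape {arr.shape}, expected {shape}")
        if np.any(self.box <= 0):
            raise FrameError("box edge lengths must be positive")
        if nf > 1 and np.any(np.diff(self.times) < 0):
            raise FrameError("frames are not time-ordered")
        if self.bias is not None and self.bias.shape != (nf,):
            raise FrameError("bias length does not match frame count")


def minimum_image(vec: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Minimum-image displacement vectors in an orthorhombic box."""
    return vec - box * np.round(vec / box)


def read_frames(
    path: str | Path,
    columns: dict[str, str] | None = None,
    scales: dict[str, float] | None = None,
) -> FrameEnsemble:
    """Parse the columnar dump dialect into a :class:`FrameEnsemble`.

    ``columns`` maps the roles ``id/x/y/z/fx/fy/fz/pe/ke`` to column
    names in the file's ``ITEM: ATOMS`` header; ``scales`` gives
    per-role multiplicative factors converting the file's units to the
    package convention (default 1.0, i.e. the file already uses A and
    kJ mol^-1).
    """
    columns = dict(DEFAULT_COLUMNS if columns is None else columns)
    missing = [r for r in ROLES if r not in columns]
    if missing:
        raise FrameError(f"column map missing roles {missing}")
    scales = scales or {}

    lines = [ln for ln in Path(path).read_text().splitlines()
             if not ln.startswith("#")]
    i = 0
    times, boxes, pos, frc, pes, kes = [], [], [], [], [], []
    n_atoms_ref: int | None = None
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        if not lines[i].startswith("ITEM: TIMESTEP"):
            raise FrameError(f"expected 'ITEM: TIMESTEP' at line {i + 1}")
        t = float(lines[i + 1])
        if not lines[i + 2].startswith("ITEM: NUMBER OF ATOMS"):
            raise FrameError("missing 'ITEM: NUMBER OF ATOMS' section")
        n = int(lines[i + 3])
        if n_atoms_ref is None:
            n_atoms_ref = n
        elif n != n_atoms_ref:
            raise FrameError(
                f"atom count changed from {n_atoms_ref} to {n} at t={t}"
            )
        if not lines[i + 4].startswith("ITEM: BOX BOUNDS"):
            raise FrameError("missing 'ITEM: BOX BOUNDS' section")
        edges = []
        for k in range(3):
            lo, hi = (float(v) for v in lines[i + 5 + k].split()[:2])
            edges.append(hi - lo)
        header = lines[i + 8]
        if not header.startswith("ITEM: ATOMS"):
            raise FrameError("missing 'ITEM: ATOMS' section")
        names = header.split()[2:]
        try:
            cols = {role: names.index(columns[role]) for role in ROLES}
        except ValueError as exc:
            raise FrameError(f"declared column not in file: {exc}") from exc
        block = np.array(
            [ln.split() for ln in lines[i + 9:i + 9 + n]], dtype=float
        )
        if block.shape[0] != n:
            raise FrameError(f"frame at t={t} is truncated")
        order = np.argsort(block[:, cols["id"]], kind="stable")
        block = block[order]
        get = lambda r: block[:, cols[r]] * scales.get(r, 1.0)  # noqa: E731
        times.append(t)
        boxes.append(edges)
        pos.append(np.stack([get("x"), get("y"), get("z")], axis=1))
        frc.append(np.stack([get("fx"), get("fy"), get("fz")], axis=1))
        pes.append(get("pe"))
        kes.append(get("ke"))
        i += 9 + n

    ens = FrameEnsemble(
        times=np.array(times),
        box=np.array(boxes),
        positions=np.array(pos),
        forces=np.array(frc),
        pe=np.array(pes),
        ke=np.array(kes),
    )
    ens.validate()
    return ens


def write_frames(ens: FrameEnsemble, path: str | Path) -> None:
    """Write the dump dialect with the default column layout."""
    with open(path, "w") as fh:
        for f in range(ens.n_frames):
            fh.write("ITEM: TIMESTEP\n")
            fh.write(f"{ens.times[f]:.10g}\n")
            fh.write("ITEM: NUMBER OF ATOMS\n")
            fh.write(f"{ens.n_atoms}\n")
            fh.write("ITEM: BOX BOUNDS pp pp pp\n")
            for k in range(3):
                fh.write(f"0.0 {ens.box[f, k]:.10g}\n")
            fh.write("ITEM: ATOMS id x y z fx fy fz c_pe c_ke\n")
            for a in range(ens.n_atoms):
                x, y, z = ens.positions[f, a]
                fx, fy, fz = ens.forces[f, a]
                fh.write(
                    f"{a + 1} {x:.10g} {y:.10g} {z:.10g} "
                    f"{fx:.10g} {fy:.10g} {fz:.10g} "
                    f"{ens.pe[f, a]:.10g} {ens.ke[f, a]:.10g}\n"
                )


def read_bias(
    path: str | Path,
    frame_times: np.ndarray,
    tol: float = 1e-6,
) -> np.ndarray:
    """Match a two-column (time, bias) file to trajectory frame times.

    Each frame takes the bias value at the nearest file time within
    ``tol`` of half the local sampling interval; a frame not covered by
    the file, or a non-monotonic time column, is a hard error.
    """
    rows = []
    for ln in Path(path).read_text().splitlines():
        ln = ln.strip()
        if not ln or ln.startswith("#"):
            continue
        parts = ln.split()
        rows.append((float(parts[0]), float(parts[1])))
    if not rows:
        raise FrameError(f"empty bias file {path}")
    data = np.array(rows)
    t_bias, v_bias = data[:, 0], data[:, 1]
    if np.any(np.diff(t_bias) <= 0):
        raise FrameError("bias file times are not strictly increasing")
    dt = np.median(np.diff(t_bias)) if len(t_bias) > 1 else np.inf
    out = np.empty(len(frame_times))
    for i, t in enumerate(frame_times):
        j = int(np.argmin(np.abs(t_bias - t)))
        if abs(t_bias[j] - t) > max(dt / 2, tol):
            raise FrameError(
                f"frame time {t} not covered by bias file "
                f"(nearest bias time {t_bias[j]})"
            )
        out[i] = v_bias[j]
    return out


def write_bias(times: np.ndarray, bias: np.ndarray, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# time bias\n")
        for t, v in zip(times, bias):
            fh.write(f"{t:.10g} {v:.10g}\n")
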