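"""Trajectory containers and text-format I/O.

The on-disk formats are deliberately plain text: extended XYZ for
trajectories (atom-count line, ``key=value`` comment line carrying ``Time``
and orthorhombic ``Lattice``, then ``element x y z [vx vy vz]`` rows) and
two-column TSV for 1D potential scans and spectra.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "Frame",
    "Trajectory",
    "read_xyz",
    "write_xyz",
    "read_potential_scan",
    "write_table",
]


class ParseError(ValueError):
    """Malformed trajectory or scan file."""


@dataclass
class Frame:
    """One trajectory frame: positions (Å), optional velocities (Å/fs), time (fs)."""

    positions: np.ndarray
    velocities: np.ndarray | None = None
    time: float = 0.0

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must have shape (n_atoms, 3)")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("non-finite coordinates")
        if self.velocities is not None:
            self.velocities = np.asarray(self.velocities, dtype=float)
            if self.velocities.shape != self.positions.shape:
                raise ValueError("velocities must match positions in shape")


@dataclass
class Trajectory:
    """Ordered frames with shared element labels, frame spacing and cell.

    Attributes
    ----------
    positions : (n_frames, n_atoms, 3) array, Å
    velocities : optional matching array, Å/fs
    elements : per-atom chemical symbols
    dt : frame spacing, fs
    cell : optional orthorhombic box lengths (3,), Å
    comment : free-form metadata echoed into output files
    """

    positions: np.ndarray
    elements: list[str]
    dt: float
    velocities: np.ndarray | None = None
    cell: np.ndarray | None = None
    comment: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 3 or self.positions.shape[2] != 3:
            raise ValueError("positions must have shape (n_frames, n_atoms, 3)")
        if self.positions.shape[1] != len(self.elements):
            raise ValueError("elements length must match atom count")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.velocities is not None:
            self.velocities = np.asarray(self.velocities, dtype=float)
            if self.velocities.shape != self.positions.shape:
                raise ValueError("velocities must match positions in shape")
        if self.cell is not None:
            self.cell = np.asarray(self.cell, dtype=float).reshape(3)
            if np.any(self.cell <= 0):
                raise ValueError("cell lengths must be positive")

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.positions.shape[1]

    @property
    def duration(self) -> float:
        """Trajectory duration in fs (last frame time, frame 0 at t=0)."""
        return (self.n_frames - 1) * self.dt

    @property
    def times(self) -> np.ndarray:
        """Frame times in fs."""
        return np.arange(self.n_frames) * self.dt

    def frame(self, i: int) -> Frame:
        vel = None if self.velocities is None else self.velocities[i]
        return Frame(self.positions[i], vel, time=i * self.dt)


def _format_lattice(cell: np.ndarray) -> str:
    a, b, c = cell
    return f'Lattice="{a:.10g} 0 0 0 {b:.10g} 0 0 0 {c:.10g}"'


def _parse_comment(line: str) -> dict:
    """Parse key=value pairs from an extended-XYZ comment line."""
    out: dict = {}
    i = 0
    n = len(line)
    while i < n:
        eq = line.find("=", i)
        if eq < 0:
            break
        key = line[line.rfind(" ", 0, eq) + 1 : eq]
        j = eq + 1
        if j < n and line[j] == '"':
            end = line.find('"', j + 1)
            out[key] = line[j + 1 : end]
            i = end + 1
        else:
            end = line.find(" ", j)
            end = n if end < 0 else end
            out[key] = line[j:end]
            i = end + 1
    return out


def write_xyz(traj: Trajectory, path: str | Path) -> None:
    """Write a trajectory as extended XYZ; velocities written iff present."""
    path = Path(path)
    if traj.n_frames == 0:
        warnings.warn("writing empty trajectory", stacklevel=2)
        path.write_text("")
        return
    lines: list[str] = []
    for i in range(traj.n_frames):
        lines.append(str(traj.n_atoms))
        parts = [f"Time={i * traj.dt:.6f}"]
        if traj.cell is not None:
            parts.append(_format_lattice(traj.cell))
        for k, v in traj.comment.items():
            parts.append(f'{k}="{v}"' if " " in str(v) else f"{k}={v}")
        lines.append(" ".join(parts))
        for a in range(traj.n_atoms):
            x, y, z = traj.positions[i, a]
            row = f"{traj.elements[a]:<2s} {x:18.10f} {y:18.10f} {z:18.10f}"
            if traj.velocities is not None:
                vx, vy, vz = traj.velocities[i, a]
                row += f" {vx:18.10f} {vy:18.10f} {vz:18.10f}"
            lines.append(row)
    path.write_text("\n".join(lines) + "\n")


def read_xyz(path: str | Path) -> Trajectory:
    """Read an extended-XYZ trajectory written by :func:`write_xyz` or peers."""
    path = Path(path)
    text = path.read_text().splitlines()
    frames_pos: list[np.ndarray] = []
    frames_vel: list[np.ndarray] = []
    times: list[float] = []
    elements: list[str] | None = None
    cell = None
    i = 0
    frame_idx = 0
    have_vel: bool | None = None
    while i < len(text):
        if not text[i].strip():
            i += 1
            continue
        try:
            n_atoms = int(text[i].strip())
        except ValueError as exc:
            raise ParseError(
                f"frame {frame_idx}: expected atom count at line {i + 1}"
            ) from exc
        meta = _parse_comment(text[i + 1] if i + 1 < len(text) else "")
        if "Lattice" in meta:
            vals = np.fromstring(meta["Lattice"], sep=" ")
            if vals.size == 9:
                cell = vals.reshape(3, 3).diagonal().copy()
            else:
                cell = vals[:3]
        times.append(float(meta.get("Time", frame_idx)))
        rows = text[i + 2 : i + 2 + n_atoms]
        if len(rows) < n_atoms or any(
            not r.strip() or r.strip().isdigit() for r in rows
        ):
            raise ParseError(f"frame {frame_idx}: fewer atoms than declared")
        syms: list[str] = []
        pos = np.empty((n_atoms, 3))
        vel = np.empty((n_atoms, 3))
        frame_has_vel = None
        for a, row in enumerate(rows):
            cols = row.split()
            syms.append(cols[0])
            try:
                nums = [float(c) for c in cols[1:]]
            except ValueError as exc:
                raise ParseError(
                    f"non-numeric coordinate at line {i + 2 + a + 1}"
                ) from exc
            if len(nums) not in (3, 6):
                raise ParseError(
                    f"frame {frame_idx}: expected 3 or 6 numeric columns "
                    f"at line {i + 2 + a + 1}"
                )
            pos[a] = nums[:3]
            this_has_vel = len(nums) == 6
            if frame_has_vel is None:
                frame_has_vel = this_has_vel
            elif frame_has_vel != this_has_vel:
                raise ParseError(
                    f"frame {frame_idx}: mixed velocity/no-velocity rows"
                )
            if this_has_vel:
                vel[a] = nums[3:]
        if elements is None:
            elements = syms
        elif syms != elements or n_atoms != len(elements):
            raise ParseError(
                f"frame {frame_idx}: atom count or element order differs "
                "from frame 0"
            )
        if have_vel is None:
            have_vel = bool(frame_has_vel)
        elif have_vel != frame_has_vel:
            raise ParseError(f"frame {frame_idx}: velocity columns inconsistent")
        frames_pos.append(pos)
        if have_vel:
            frames_vel.append(vel)
        i += 2 + n_atoms
        frame_idx += 1
    if elements is None:
        raise ParseError("no frames found")
    if len(times) > 1:
        dt = times[1] - times[0]
        if dt <= 0:
            dt = 1.0
    else:
        dt = 1.0
    return Trajectory(
        positions=np.array(frames_pos),
        elements=elements,
        dt=dt,
        velocities=np.array(frames_vel) if frames_vel else None,
        cell=cell,
    )


def read_potential_scan(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a two-column TSV rigid-scan file: displacement (Å), energy (hartree).

    Energies are shifted so the minimum is zero — only energy differences
    enter the vibrational solve, so the gauge is fixed on read.

    Returns
    -------
    x, V : arrays of equal length, x strictly increasing, min(V) = 0.
    """
    data = np.loadtxt(path, ndmin=2)
    if data.shape[1] < 2:
        raise ParseError("scan file needs two columns: displacement, energy")
    x, v = data[:, 0], data[:, 1]
    if len(x) < 5:
        raise ParseError(f"scan needs >= 5 points, got {len(x)}")
    if np.any(np.diff(x) <= 0):
        raise ParseError("scan displacement grid must be strictly increasing")
    return x, v - v.min()


def write_table(
    path: str | Path, columns: dict[str, np.ndarray], meta: dict | None = None
) -> None:
    """Write named columns as a TSV with a '#'-prefixed header row.

    ``meta`` key=value pairs (e.g. the run's config hash) are prepended as
    extra comment lines.
    """
    names = list(columns)
    arr = np.column_stack([np.asarray(columns[k], dtype=float) for k in names])
    header = "".join(f"{k}={v}\n" for k, v in (meta or {}).items())
    header += "\t".join(names)
    np.savetxt(path, arr, delimiter="\t", header=header, fmt="%.10g")


def write_metadata(path: str | Path, meta: dict) -> None:
    """JSON metadata sidecar (seeds, parameters, config hash)."""
    Path(path).write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
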