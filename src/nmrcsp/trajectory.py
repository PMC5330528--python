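"""Trajectories: ordered sequences of same-topology P1 frames.

Frames are stored as full :class:`~nmrcsp.crystio.Crystal` objects so cell
fluctuations can be carried per frame. I/O uses the extended-XYZ convention
(per-frame ``Lattice="ax ay az bx by bz cx cy cz"`` in the comment line,
Cartesian positions, fixed atom order).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

import numpy as np

from .crystio import AtomSite, Crystal, UnitCell
from .errors import TrajectoryError

__all__ = ["Trajectory", "read_extxyz", "write_extxyz", "cell_from_matrix"]

_LATTICE_RE = re.compile(r'Lattice\s*=\s*"([^"]+)"')
_TIME_RE = re.compile(r"Time\s*=\s*([-\d.eE+]+)")


def cell_from_matrix(m: np.ndarray) -> UnitCell:
    """Unit-cell parameters (lengths/angles) from a row-vector lattice matrix."""
    m = np.asarray(m, dtype=float)
    a, b, c = (np.linalg.norm(m[i]) for i in range(3))

    def angle(u, v):
        cosang = float(np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)))
        return math.degrees(math.acos(max(-1.0, min(1.0, cosang))))

    return UnitCell(a, b, c, angle(m[1], m[2]), angle(m[0], m[2]), angle(m[0], m[1]))


@dataclass
class Trajectory:
    """Same-topology P1 frames with an optional time step in ps."""

    frames: list[Crystal]
    timestep_ps: float | None = None
    name: str = ""
    times_ps: list[float] | None = field(default=None)

    def __post_init__(self) -> None:
        if not self.frames:
            raise TrajectoryError("trajectory has no frames")
        ref = self.frames[0]
        for i, fr in enumerate(self.frames):
            if len(fr.sites) != len(ref.sites):
                raise TrajectoryError(
                    f"frame {i} has {len(fr.sites)} atoms, frame 0 has {len(ref.sites)}"
                )
            if fr.labels != ref.labels:
                raise TrajectoryError(f"frame {i} atom ordering differs from frame 0")
            if not fr.is_p1():
                raise TrajectoryError(f"frame {i} is not P1")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def labels(self) -> list[str]:
        return self.frames[0].labels

    def frac_stack(self) -> np.ndarray:
        """(n_frames, n_atoms, 3) array of fractional coordinates."""
        return np.array([fr.frac_coords() for fr in self.frames])


def read_extxyz(text: str, labels: list[str] | None = None) -> Trajectory:
    """Read an extended-XYZ multi-frame string.

    Atom labels are not part of the format; they default to element+ordinal
    (C1, C2, H1, ...) assigned on frame 0, or can be supplied explicitly in
    atom order.
    """
    lines = text.splitlines()
    pos = 0
    frames: list[Crystal] = []
    times: list[float] = []
    frame_labels = labels
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        try:
            natoms = int(lines[pos].strip())
        except ValueError:
            raise TrajectoryError(f"line {pos + 1}: expected atom count, got {lines[pos]!r}")
        comment = lines[pos + 1] if pos + 1 < len(lines) else ""
        m = _LATTICE_RE.search(comment)
        if not m:
            raise TrajectoryError(f"frame at line {pos + 1}: missing Lattice field")
        vals = [float(x) for x in m.group(1).split()]
        if len(vals) != 9:
            raise TrajectoryError(f"frame at line {pos + 1}: Lattice needs 9 numbers")
        lattice = np.array(vals).reshape(3, 3)
        tm = _TIME_RE.search(comment)
        if tm:
            times.append(float(tm.group(1)))
        body = lines[pos + 2 : pos + 2 + natoms]
        if len(body) < natoms:
            raise TrajectoryError(f"frame at line {pos + 1}: truncated ({len(body)}/{natoms} atoms)")
        elements, cart = [], []
        for ln in body:
            parts = ln.split()
            elements.append(parts[0])
            cart.append([float(x) for x in parts[1:4]])
        cart = np.array(cart)
        frac = cart @ np.linalg.inv(lattice)
        if frame_labels is None:
            counts: dict[str, int] = {}
            frame_labels = []
            for el in elements:
                counts[el] = counts.get(el, 0) + 1
                frame_labels.append(f"{el}{counts[el]}")
        sites = [
            AtomSite(label=l, element=e, frac=f)
            for l, e, f in zip(frame_labels, elements, frac)
        ]
        frames.append(Crystal(cell=cell_from_matrix(lattice), sites=sites, name=f"frame_{len(frames)}"))
        pos += 2 + natoms
    if not frames:
        raise TrajectoryError("no frames found")
    timestep = None
    if len(times) == len(frames) and len(times) > 1:
        timestep = times[1] - times[0]
    return Trajectory(frames=frames, timestep_ps=timestep, times_ps=times or None)


def write_extxyz(traj: Trajectory) -> str:
    """Serialize a trajectory to an extended-XYZ string (Cartesian positions)."""
    out = []
    for i, fr in enumerate(traj.frames):
        m = fr.cell.matrix
        lat = " ".join(f"{x:.8f}" for x in m.ravel())
        if traj.times_ps is not None:
            t = traj.times_ps[i]
        else:
            t = i * (traj.timestep_ps or 1.0)
        out.append(str(len(fr.sites)))
        out.append(f'Lattice="{lat}" Properties=species:S:1:pos:R:3 Time={t:.6f}')
        cart = fr.cart_coords()
        for s, xyz in zip(fr.sites, cart):
            out.append(f"{s.element} {xyz[0]:.8f} {xyz[1]:.8f} {xyz[2]:.8f}")
    return "\n".join(out) + "\n"
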