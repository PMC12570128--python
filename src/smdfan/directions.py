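"""Pulling-direction fans over a hemisphere anchored on the principal axis.

Each direction is parameterized by a polar angle *theta* (measured from the
principal axis, i.e. the fixed-to-pulled center-of-mass vector) and an azimuth
*phi* in the transverse plane:

    v(theta, phi) = cos(theta) axis + sin(theta) (cos(phi) e1 + sin(phi) e2)

where (e1, e2, axis) is a deterministic right-handed orthonormal frame.  The
default grid, theta in {0, 45, 90} deg crossed with phi in {0, 90, 180, 270}
deg, collapses the fourfold-degenerate pole and yields nine distinct pulling
directions covering the hemisphere on the pulled side of the complex.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import ConfigurationError, DegenerateAxisError

#: two directions closer than this (rad) are the same grid point
DEDUP_TOL_RAD = 1e-6


@dataclass(frozen=True)
class Direction:
    """A single labeled unit pulling vector."""

    theta: float  # deg, polar angle from the principal axis
    phi: float    # deg, azimuth in the transverse plane
    vector: np.ndarray  # unit 3-vector
    label: str

    def __post_init__(self):
        object.__setattr__(self, "vector", np.asarray(self.vector, dtype=float))


@dataclass
class DirectionSet:
    """Deduplicated, ordered fan of pulling directions around one axis."""

    axis: np.ndarray
    frame: tuple[np.ndarray, np.ndarray, np.ndarray]  # (e1, e2, axis)
    thetas: list[float]
    phis: list[float]
    directions: list[Direction] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.directions)

    def __iter__(self):
        return iter(self.directions)

    def labels(self) -> list[str]:
        return [d.label for d in self.directions]

    def to_table(self) -> str:
        """Plain-text table: label, theta, phi, vx, vy, vz (6 decimals)."""
        lines = ["label\ttheta\tphi\tvx\tvy\tvz"]
        for d in self.directions:
            vx, vy, vz = d.vector
            lines.append(
                f"{d.label}\t{_fmt_angle(d.theta)}\t{_fmt_angle(d.phi)}"
                f"\t{vx:.6f}\t{vy:.6f}\t{vz:.6f}")
        return "\n".join(lines) + "\n"


def _fmt_angle(a: float) -> str:
    return str(int(round(a))) if abs(a - round(a)) < 1e-9 else f"{a:.1f}"


def direction_label(theta: float, phi: float) -> str:
    return f"theta_{_fmt_angle(theta)}_phi_{_fmt_angle(phi)}"


def build_frame(axis: Sequence[float]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Deterministic right-handed orthonormal frame (e1, e2, axis).

    The phi = 0 reference e1 is normalize(z x axis); when the axis is within
    ~2.6 deg of +-z that cross product degenerates and e1 falls back to the
    unit projection of x into the transverse plane, so axis = +z gives the
    canonical frame e1 = x, e2 = y.
    """
    axis = np.asarray(axis, dtype=float)
    norm = float(np.linalg.norm(axis))
    if norm < 1e-12:
        raise DegenerateAxisError("cannot build a frame around a zero vector")
    axis = axis / norm
    z = np.array([0.0, 0.0, 1.0])
    if abs(float(axis @ z)) > 0.999:
        x = np.array([1.0, 0.0, 0.0])
        e1 = x - (x @ axis) * axis
    else:
        e1 = np.cross(z, axis)
    e1 = e1 / np.linalg.norm(e1)
    e2 = np.cross(axis, e1)  # e1 x e2 = axis: right-handed
    return e1, e2, axis


def direction_vector(
    frame: tuple[np.ndarray, np.ndarray, np.ndarray],
    theta: float,
    phi: float,
) -> np.ndarray:
    """Unit vector at polar angle theta and azimuth phi (both degrees)."""
    if not 0.0 <= theta <= 180.0:
        raise ConfigurationError(f"theta must lie in [0, 180] deg, got {theta}")
    e1, e2, axis = frame
    th, ph = np.deg2rad(theta), np.deg2rad(phi)
    v = np.cos(th) * axis + np.sin(th) * (np.cos(ph) * e1 + np.sin(ph) * e2)
    return v / np.linalg.norm(v)


def generate_directions(
    axis: Sequence[float],
    thetas: Iterable[float] = (0.0, 45.0, 90.0),
    phis: Iterable[float] = (0.0, 90.0, 180.0, 270.0),
) -> DirectionSet:
    """Cartesian (theta, phi) grid with duplicate vectors collapsed.

    Ordering is theta ascending then phi ascending; the theta = 0 pole keeps
    a single direction labeled ``theta_0_phi_0``.  With the defaults this
    produces nine distinct pulling directions.
    """
    thetas = sorted(float(t) for t in thetas)
    phis = sorted(float(p) for p in phis)
    if not thetas or not phis:
        raise ConfigurationError("theta and phi lists must be non-empty")
    if not all(np.isfinite(thetas)) or not all(np.isfinite(phis)):
        raise ConfigurationError("angles must be finite")
    frame = build_frame(axis)
    directions: list[Direction] = []
    for th in thetas:
        for ph in phis:
            v = direction_vector(frame, th, ph)
            dup = any(
                float(np.arccos(np.clip(v @ d.vector, -1.0, 1.0))) < DEDUP_TOL_RAD
                for d in directions)
            if not dup:
                directions.append(Direction(th, ph, v, direction_label(th, ph)))
    return DirectionSet(axis=frame[2], frame=frame, thetas=thetas, phis=phis,
                        directions=directions)


def render_vmd_arrows(
    dset: DirectionSet,
    origin: Sequence[float],
    scale: float = 20.0,
    color: str = "yellow",
) -> str:
    """Tcl script drawing one arrow per pulling direction in VMD.

    Each arrow (cylinder shaft + cone tip) runs from ``origin`` (typically the
    pulled group's center of mass) to ``origin + scale * vector``.
    """
    if len(dset) == 0:
        raise ConfigurationError("cannot render an empty direction set")
    o = np.asarray(origin, dtype=float)
    shaft_r = max(scale * 0.015, 0.2)
    lines = [
        "# pulling-direction arrows (VMD Tcl)",
        "draw delete all",
        f"draw color {color}",
    ]
    for d in dset:
        tip = o + scale * d.vector
        neck = o + 0.8 * scale * d.vector
        lines += [
            f"# {d.label}",
            "draw cylinder {%.3f %.3f %.3f} {%.3f %.3f %.3f} radius %.3f resolution 20"
            % (*o, *neck, shaft_r),
            "draw cone {%.3f %.3f %.3f} {%.3f %.3f %.3f} radius %.3f resolution 20"
            % (*neck, *tip, 2.5 * shaft_r),
            'draw text {%.3f %.3f %.3f} "%s" size 0.8' % (*tip, d.label),
        ]
    return "\n".join(lines) + "\n"


def write_vmd_arrows(dset: DirectionSet, origin, path: str | Path, scale: float = 20.0) -> None:
    Path(path).write_text(render_vmd_arrows(dset, origin, scale))
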