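"""Parse SMD engine output into force traces.

Two dialects are understood: NAMD log files, whose SMD-tagged lines carry the
step number, the pulled-group COM (A) and the applied force vector
(kcal mol^-1 A^-1); and GROMACS pull ``.xvg`` files (xmgrace dialect) with
time (ps) against force (kJ mol^-1 nm^-1) or position (nm).  All forces are
converted to pN; the primary force coordinate is the projection of the force
vector on the pulling direction (the magnitude is available as an option).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import FormatError, InputError
from .units import KCAL_PER_MOL_ANGSTROM_TO_PN, KJ_PER_MOL_NM_TO_PN

log = logging.getLogger(__name__)


@dataclass
class ForceTrace:
    """Time series of the pulling force, in ps / pN.

    ``position`` (optional) holds the pulled-group COM per sample, in A.
    """

    time: np.ndarray
    force: np.ndarray
    direction: np.ndarray
    source: str  # "namd_log" | "gromacs_xvg" | "toysim"
    replica_id: int = 0
    position: np.ndarray | None = None
    label: str = ""

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        self.direction = np.asarray(self.direction, dtype=float)
        if self.time.shape != self.force.shape:
            raise FormatError("time and force series differ in length")
        if self.position is not None:
            self.position = np.asarray(self.position, dtype=float)
            if len(self.position) != len(self.time):
                raise FormatError("position series length mismatch")
        if len(self.time) > 1 and not np.all(np.diff(self.time) > 0):
            raise FormatError("time series must be strictly increasing")

    def __len__(self) -> int:
        return len(self.time)


@dataclass
class DistanceTrace:
    """Pull-coordinate position over time (ps / A), from a pullx .xvg."""

    time: np.ndarray
    distance: np.ndarray

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.distance = np.asarray(self.distance, dtype=float)


def parse_namd_smd_log(
    path: str | Path,
    timestep: float,
    direction: Sequence[float],
    replica_id: int = 0,
    use_magnitude: bool = False,
) -> ForceTrace:
    """Extract the SMD series from a NAMD log.

    Parameters
    ----------
    timestep : fs per MD step (converts step numbers to ps).
    direction : unit pulling vector the force is projected on.
    use_magnitude : report |F| instead of the projection F . direction.
    """
    path = Path(path)
    if not path.is_file():
        raise InputError(f"NAMD log not found: {path}")
    direction = np.asarray(direction, dtype=float)
    steps: list[int] = []
    pos: list[list[float]] = []
    forces: list[list[float]] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        parts = line.split()
        if len(parts) < 8 or parts[0] != "SMD":
            continue
        try:
            step = int(parts[1])
            vals = [float(p) for p in parts[2:8]]
        except ValueError:
            raise FormatError(
                f"malformed SMD line {lineno} in {path.name}") from None
        if steps and step < steps[-1]:
            raise FormatError(
                f"non-monotone SMD step at line {lineno} in {path.name} "
                f"({step} after {steps[-1]})")
        if steps and step == steps[-1]:
            # restart overlap: last occurrence wins
            log.warning("duplicate SMD step %d at line %d in %s: keeping last",
                        step, lineno, path.name)
            steps.pop(); pos.pop(); forces.pop()
        steps.append(step)
        pos.append(vals[0:3])
        forces.append(vals[3:6])
    if not steps:
        raise FormatError(f"no SMD lines found in {path}")
    fvec = np.array(forces)
    proj = (np.linalg.norm(fvec, axis=1) if use_magnitude
            else fvec @ direction)
    return ForceTrace(
        time=np.array(steps, dtype=float) * timestep * 1e-3,
        force=proj * KCAL_PER_MOL_ANGSTROM_TO_PN,
        position=np.array(pos),
        direction=direction,
        source="namd_log",
        replica_id=replica_id,
    )


def _read_xvg_rows(path: Path) -> np.ndarray:
    rows: list[list[float]] = []
    width = None
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        s = line.strip()
        if not s or s.startswith("#") or s.startswith("@"):
            continue
        try:
            vals = [float(tok) for tok in s.split()]
        except ValueError:
            raise FormatError(
                f"non-numeric row at line {lineno} in {path.name}") from None
        if width is None:
            width = len(vals)
        elif len(vals) != width:
            raise FormatError(
                f"ragged row at line {lineno} in {path.name} "
                f"({len(vals)} columns, expected {width})")
        rows.append(vals)
    if not rows:
        raise FormatError(f"no numeric rows in {path}")
    return np.array(rows)


def parse_xvg(
    path: str | Path,
    kind: str = "pullf",
    direction: Sequence[float] | None = None,
    replica_id: int = 0,
) -> ForceTrace | DistanceTrace:
    """Parse a GROMACS pull .xvg file.

    ``kind="pullf"`` yields a :class:`ForceTrace` (force converted to pN);
    ``kind="pullx"`` yields a :class:`DistanceTrace` with the pull-coordinate
    position converted from nm to A.
    """
    path = Path(path)
    if not path.is_file():
        raise InputError(f".xvg file not found: {path}")
    if kind not in ("pullf", "pullx"):
        raise InputError(f"unknown xvg kind {kind!r}")
    data = _read_xvg_rows(path)
    if data.shape[1] < 2:
        raise FormatError(f"{path.name}: expected at least 2 columns")
    if kind == "pullx":
        return DistanceTrace(time=data[:, 0], distance=data[:, 1] * 10.0)
    return ForceTrace(
        time=data[:, 0],
        force=data[:, 1] * KJ_PER_MOL_NM_TO_PN,
        direction=(np.zeros(3) if direction is None
                   else np.asarray(direction, dtype=float)),
        source="gromacs_xvg",
        replica_id=replica_id,
    )


def com_distance_series(
    frames: Sequence[np.ndarray],
    fixed_idx: Sequence[int],
    pulled_idx: Sequence[int],
    masses: Sequence[float],
) -> np.ndarray:
    """Per-frame |COM_pulled - COM_fixed| in A over a trajectory."""
    fixed_idx = np.asarray(list(fixed_idx), dtype=int)
    pulled_idx = np.asarray(list(pulled_idx), dtype=int)
    if fixed_idx.size == 0 or pulled_idx.size == 0:
        raise InputError("com_distance_series: empty selection")
    masses = np.asarray(masses, dtype=float)
    mf = masses[fixed_idx]
    mp = masses[pulled_idx]
    out = np.empty(len(frames))
    for k, frame in enumerate(frames):
        frame = np.asarray(frame, dtype=float)
        if frame.shape[0] <= max(fixed_idx.max(), pulled_idx.max()):
            raise InputError(
                f"frame {k} has {frame.shape[0]} atoms; selection exceeds it")
        com_f = (frame[fixed_idx] * mf[:, None]).sum(axis=0) / mf.sum()
        com_p = (frame[pulled_idx] * mp[:, None]).sum(axis=0) / mp.sum()
        out[k] = np.linalg.norm(com_p - com_f)
    return out
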