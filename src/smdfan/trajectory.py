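"""Lightweight trajectory readers/writers: multi-model PDB and XYZ.

These cover the plain-text formats the toy simulator emits and the H-bond
analysis consumes.  Binary trajectory formats (DCD/XTC) are out of core
scope; MDAnalysis can be used upstream to convert them to multi-model PDB.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import FormatError, InputError
from .structure import Structure, _parse_atom_line, format_atom_line


def read_pdb_models(path: str | Path) -> list[np.ndarray]:
    """All MODEL blocks of a PDB as a list of (n_atoms, 3) coordinate arrays.

    A file without MODEL records yields a single frame.
    """
    path = Path(path)
    if not path.is_file():
        raise InputError(f"trajectory PDB not found: {path}")
    frames: list[np.ndarray] = []
    current: list[list[float]] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        rec = line[:6].strip()
        if rec in ("ATOM", "HETATM"):
            a = _parse_atom_line(line, lineno)
            current.append([a.x, a.y, a.z])
        elif rec == "ENDMDL":
            frames.append(np.array(current))
            current = []
    if current:
        frames.append(np.array(current))
    if not frames or frames[0].size == 0:
        raise FormatError(f"no coordinates parsed from {path}")
    n = frames[0].shape[0]
    if any(f.shape[0] != n for f in frames):
        raise FormatError(f"{path.name}: models differ in atom count")
    return frames


def write_pdb_models(structure: Structure, frames: Sequence[np.ndarray],
                     path: str | Path) -> None:
    """Write frames as a multi-model PDB using ``structure`` for atom metadata."""
    lines: list[str] = []
    for m, frame in enumerate(frames, start=1):
        frame = np.asarray(frame, dtype=float)
        if frame.shape[0] != len(structure):
            raise InputError(f"frame {m - 1} atom count mismatch")
        lines.append(f"MODEL     {m:>4}")
        for a, (x, y, z) in zip(structure.atoms, frame):
            rec = type(a)(**{**a.__dict__, "x": x, "y": y, "z": z})
            lines.append(format_atom_line(rec))
        lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def read_xyz(path: str | Path) -> list[np.ndarray]:
    """Multi-frame XYZ file -> list of (n_atoms, 3) arrays (A)."""
    path = Path(path)
    if not path.is_file():
        raise InputError(f"XYZ file not found: {path}")
    lines = path.read_text().splitlines()
    frames: list[np.ndarray] = []
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError:
            raise FormatError(
                f"{path.name}: expected atom count at line {i + 1}") from None
        block = lines[i + 2:i + 2 + n]
        if len(block) < n:
            raise FormatError(f"{path.name}: truncated frame at line {i + 1}")
        coords = []
        for j, row in enumerate(block):
            parts = row.split()
            if len(parts) < 4:
                raise FormatError(
                    f"{path.name}: short XYZ row at line {i + 3 + j}")
            coords.append([float(parts[1]), float(parts[2]), float(parts[3])])
        frames.append(np.array(coords))
        i += 2 + n
    if not frames:
        raise FormatError(f"no frames parsed from {path}")
    return frames


def write_xyz(names: Sequence[str], frames: Sequence[np.ndarray],
              path: str | Path) -> None:
    lines: list[str] = []
    for frame in frames:
        frame = np.asarray(frame, dtype=float)
        lines.append(str(len(names)))
        lines.append("frame")
        for name, (x, y, z) in zip(names, frame):
            lines.append(f"{name} {x:.6f} {y:.6f} {z:.6f}")
    Path(path).write_text("\n".join(lines) + "\n")
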