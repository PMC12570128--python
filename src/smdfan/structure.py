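"""PDB structures, atom selections, centers of mass and the principal pulling axis.

The setup stage of a multidirectional pulling campaign needs very little
structural information: ordered atom records with coordinates and masses, two
atom selections (the immobilized and the pulled group), and the unit vector
joining their centers of mass.  That vector is the *principal axis* from which
every pulling direction is measured.

PDB handling is deliberately self-contained: records are read and written with
wwPDB v3.3 fixed columns so that a read -> write -> read round trip preserves
every parsed field, and so that the occupancy / B-factor columns (which NAMD
uses to flag SMD and fixed atoms) are under exact control.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .errors import DegenerateAxisError, FormatError, InputError, SelectionError

log = logging.getLogger(__name__)

# masses in amu; enough for proteins, nucleic acids and common ions
ATOMIC_MASSES = {
    "H": 1.008, "D": 2.014, "C": 12.011, "N": 14.007, "O": 15.999,
    "F": 18.998, "NA": 22.990, "MG": 24.305, "P": 30.974, "S": 32.06,
    "CL": 35.45, "K": 39.098, "CA": 40.078, "MN": 54.938, "FE": 55.845,
    "CO": 58.933, "NI": 58.693, "CU": 63.546, "ZN": 65.38, "SE": 78.971,
    "BR": 79.904, "I": 126.904,
}

#: fallback mass (amu) for unknown / absent element symbols
DEFAULT_MASS = 12.011

#: two centers of mass closer than this (A) give no usable axis
DEGENERATE_AXIS_TOL = 1e-6


@dataclass
class AtomRecord:
    """One ATOM/HETATM record; coordinates in A, mass in amu."""

    serial: int
    name: str
    resname: str
    chain: str
    resseq: int
    x: float
    y: float
    z: float
    occupancy: float = 1.0
    beta: float = 0.0
    element: str = ""
    mass: float = DEFAULT_MASS
    record: str = "ATOM"
    altloc: str = ""
    icode: str = ""
    segid: str = ""

    @property
    def position(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)


@dataclass
class Structure:
    """Ordered atom table; atom order is exactly the input-file order."""

    atoms: list[AtomRecord] = field(default_factory=list)
    title: str = ""

    def __len__(self) -> int:
        return len(self.atoms)

    def __iter__(self):
        return iter(self.atoms)

    def coordinates(self) -> np.ndarray:
        """(n_atoms, 3) array of coordinates in A."""
        return np.array([[a.x, a.y, a.z] for a in self.atoms], dtype=float)

    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.atoms], dtype=float)

    def copy(self) -> "Structure":
        return Structure(atoms=[replace(a) for a in self.atoms], title=self.title)


def infer_element(name: str, record: str = "ATOM") -> str:
    """Guess the element from an atom name when columns 77-78 are blank.

    For ATOM (polymer) records the first alphabetic character wins, so "CA"
    is an alpha carbon; for HETATM a two-letter symbol ("FE", "ZN") is tried
    first, since ions commonly carry element-like names.
    """
    letters = re.sub(r"[^A-Za-z]", "", name).upper()
    if not letters:
        return ""
    if record == "HETATM" and letters[:2] in ATOMIC_MASSES:
        return letters[:2]
    return letters[0]


def mass_of(element: str) -> float:
    m = ATOMIC_MASSES.get(element.upper())
    if m is None:
        log.warning("unknown element %r: using fallback mass %.3f amu",
                    element, DEFAULT_MASS)
        return DEFAULT_MASS
    return m


def _parse_atom_line(line: str, lineno: int) -> AtomRecord:
    line = line.rstrip("\n").ljust(80)
    try:
        serial = int(line[6:11])
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except ValueError as exc:
        raise FormatError(
            f"malformed numeric field in ATOM record at line {lineno}: {exc}"
        ) from None
    occ_s, beta_s = line[54:60].strip(), line[60:66].strip()
    occupancy = float(occ_s) if occ_s else 1.0
    beta = float(beta_s) if beta_s else 0.0
    record = line[0:6].strip()
    name = line[12:16].strip()
    element = line[76:78].strip()
    if not element:
        element = infer_element(name, record)
    resseq_s = line[22:26].strip()
    return AtomRecord(
        serial=serial,
        name=name,
        resname=line[17:20].strip(),
        chain=line[21].strip(),
        resseq=int(resseq_s) if resseq_s else 0,
        x=x, y=y, z=z,
        occupancy=occupancy,
        beta=beta,
        element=element,
        mass=mass_of(element),
        record=record,
        altloc=line[16].strip(),
        icode=line[26].strip(),
        segid=line[72:76].strip(),
    )


def read_pdb(path: str | Path) -> Structure:
    """Read a PDB file into a :class:`Structure`.

    Only the first MODEL defines the structure (setup needs one topology);
    use :func:`smdfan.trajectory.read_pdb_models` for multi-model trajectories.
    """
    path = Path(path)
    if not path.is_file():
        raise InputError(f"PDB file not found: {path}")
    atoms: list[AtomRecord] = []
    title = ""
    in_model = 0
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        rec = line[:6].strip()
        if rec == "TITLE":
            title = (title + " " + line[10:].strip()).strip()
        elif rec == "MODEL":
            in_model += 1
            if in_model > 1:
                break
        elif rec == "ENDMDL" and in_model >= 1:
            break
        elif rec in ("ATOM", "HETATM"):
            atoms.append(_parse_atom_line(line, lineno))
    if not atoms:
        raise FormatError(f"no ATOM/HETATM records parsed from {path}")
    return Structure(atoms=atoms, title=title)


def format_atom_line(a: AtomRecord) -> str:
    """Render one record with wwPDB v3.3 fixed columns."""
    # element-aligned atom name: 1-letter elements start in column 14
    if len(a.name) >= 4:
        name_f = a.name[:4]
    elif len(a.element) == 2 and a.name.upper().startswith(a.element.upper()):
        name_f = a.name.ljust(4)
    else:
        name_f = (" " + a.name).ljust(4)
    return (
        f"{a.record:<6}{a.serial:>5} {name_f}{a.altloc or ' ':1}"
        f"{a.resname:>3} {a.chain or ' ':1}{a.resseq:>4}{a.icode or ' ':1}   "
        f"{a.x:8.3f}{a.y:8.3f}{a.z:8.3f}{a.occupancy:6.2f}{a.beta:6.2f}"
        f"      {a.segid:<4}{a.element:>2}"
    )


def write_pdb(
    structure: Structure,
    path: str | Path,
    beta_override: Mapping[int, float] | None = None,
    occupancy_override: Mapping[int, float] | None = None,
) -> None:
    """Write a fixed-column PDB; overrides replace occupancy / B-factor per atom index."""
    if len(structure) == 0:
        raise InputError("refusing to write an empty structure")
    lines = []
    if structure.title:
        lines.append(f"TITLE     {structure.title}")
    for i, a in enumerate(structure.atoms):
        if beta_override is not None and i in beta_override:
            a = replace(a, beta=beta_override[i])
        if occupancy_override is not None and i in occupancy_override:
            a = replace(a, occupancy=occupancy_override[i])
        lines.append(format_atom_line(a))
    lines.append("END")
    try:
        Path(path).write_text("\n".join(lines) + "\n")
    except OSError as exc:
        raise InputError(f"cannot write PDB to {path}: {exc}") from None


# ---------------------------------------------------------------------------
# selection grammar:  chain A | resid 1-30 | name CA | segid PROA,
# combined with and / or / not and parentheses; keywords case-insensitive
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(r"\s*(\(|\)|[^\s()]+)")


@dataclass(frozen=True)
class SelectionSpec:
    """A selection expression, e.g. ``"chain A and resid 1-30"``."""

    expression: str

    def resolve(self, structure: Structure) -> list[int]:
        return select(structure, self)


def _tokenize(expr: str) -> list[tuple[str, int]]:
    tokens, pos = [], 0
    while pos < len(expr):
        m = _TOKEN_RE.match(expr, pos)
        if not m:
            break
        tokens.append((m.group(1), m.start(1)))
        pos = m.end()
    return tokens


class _SelParser:
    """Recursive-descent parser producing a boolean mask over atoms."""

    def __init__(self, tokens: list[tuple[str, int]], structure: Structure):
        self.tokens = tokens
        self.i = 0
        self.s = structure

    def _peek(self) -> str | None:
        return self.tokens[self.i][0] if self.i < len(self.tokens) else None

    def _pos(self) -> int:
        return self.tokens[self.i][1] if self.i < len(self.tokens) else -1

    def _next(self) -> str:
        tok = self._peek()
        if tok is None:
            raise SelectionError("unexpected end of selection expression")
        self.i += 1
        return tok

    def parse(self) -> np.ndarray:
        mask = self._expr()
        if self._peek() is not None:
            raise SelectionError(
                f"unexpected token {self._peek()!r} at position {self._pos()}")
        return mask

    def _expr(self) -> np.ndarray:
        mask = self._term()
        while self._peek() is not None and self._peek().lower() == "or":
            self._next()
            mask = mask | self._term()
        return mask

    def _term(self) -> np.ndarray:
        mask = self._factor()
        while self._peek() is not None and self._peek().lower() == "and":
            self._next()
            mask = mask & self._factor()
        return mask

    def _factor(self) -> np.ndarray:
        tok = self._peek()
        if tok is None:
            raise SelectionError("unexpected end of selection expression")
        if tok.lower() == "not":
            self._next()
            return ~self._factor()
        if tok == "(":
            self._next()
            mask = self._expr()
            if self._peek() != ")":
                raise SelectionError(
                    f"missing ')' at position {self._pos()}")
            self._next()
            return mask
        return self._primary()

    def _primary(self) -> np.ndarray:
        pos = self._pos()
        kw = self._next().lower()
        if kw == "all":
            return np.ones(len(self.s), dtype=bool)
        if kw not in ("chain", "resid", "name", "segid"):
            raise SelectionError(
                f"unknown selection keyword {kw!r} at position {pos}")
        vpos = self._pos()
        value = self._next()
        atoms = self.s.atoms
        if kw == "chain":
            return np.array([a.chain == value for a in atoms])
        if kw == "name":
            return np.array([a.name == value.upper() for a in atoms])
        if kw == "segid":
            return np.array([a.segid == value for a in atoms])
        # resid: single number or inclusive range a-b
        m = re.fullmatch(r"(-?\d+)(?:-(-?\d+))?", value)
        if not m:
            raise SelectionError(
                f"bad resid value {value!r} at position {vpos}")
        lo = int(m.group(1))
        hi = int(m.group(2)) if m.group(2) is not None else lo
        return np.array([lo <= a.resseq <= hi for a in atoms])


def select(structure: Structure, spec: SelectionSpec | str) -> list[int]:
    """Resolve a selection to an ordered list of atom indices (input order)."""
    expr = spec.expression if isinstance(spec, SelectionSpec) else spec
    tokens = _tokenize(expr)
    if not tokens:
        raise SelectionError("empty selection expression")
    mask = _SelParser(tokens, structure).parse()
    idx = [i for i, keep in enumerate(mask) if keep]
    if not idx:
        log.warning("selection %r matched no atoms", expr)
    return idx


def center_of_mass(
    structure: Structure,
    indices: Sequence[int],
    geometric: bool = False,
) -> np.ndarray:
    """Mass-weighted (default) or geometric center of the selected atoms, in A."""
    idx = list(indices)
    if not idx:
        raise InputError("center_of_mass: empty selection")
    coords = structure.coordinates()[idx]
    if geometric:
        return coords.mean(axis=0)
    m = structure.masses()[idx]
    return (coords * m[:, None]).sum(axis=0) / m.sum()


def principal_axis(
    structure: Structure,
    fixed: SelectionSpec | str | Sequence[int],
    pulled: SelectionSpec | str | Sequence[int],
    geometric: bool = False,
) -> np.ndarray:
    """Unit vector from the fixed group's COM toward the pulled group's COM."""
    def _resolve(sel) -> list[int]:
        if isinstance(sel, (SelectionSpec, str)):
            return select(structure, sel)
        return list(sel)

    fixed_idx, pulled_idx = _resolve(fixed), _resolve(pulled)
    if not fixed_idx or not pulled_idx:
        raise InputError("principal_axis: empty fixed or pulled selection")
    delta = (center_of_mass(structure, pulled_idx, geometric)
             - center_of_mass(structure, fixed_idx, geometric))
    norm = float(np.linalg.norm(delta))
    if norm < DEGENERATE_AXIS_TOL:
        raise DegenerateAxisError(
            f"fixed and pulled centers of mass coincide (|d| = {norm:.2e} A)")
    return delta / norm
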