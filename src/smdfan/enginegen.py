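"""Render per-direction NAMD / GROMACS constant-velocity pulling inputs.

For every pulling direction a run subdirectory is scaffolded with the engine
input file(s), the auxiliary reference/index file the engine needs, and a
``run.sh`` that loops over replicas.  Conventions:

* NAMD: fixed atoms are flagged in the B-factor column of a reference PDB
  (``fixedAtomsCol B``), SMD-pulled atoms in the occupancy column.  The
  replica index enters the config through the ``SMDFAN_REPLICA`` environment
  variable (the NAMD config is a Tcl script), giving each replica a distinct
  random seed and output name.
* GROMACS: pulling uses the pull code with ``pull-coord1-geometry =
  direction``; the fixed group is immobilized with freeze groups, which
  requires no topology edit (trade-off: frozen atoms are excluded from
  pressure coupling).  One .mdp per replica differs only in ``gen-seed``.

Replica r uses seed ``base_seed + r``; the base seed is recorded in the
manifest.
"""

from __future__ import annotations

import os
import shutil
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .directions import Direction, DirectionSet
from .errors import ConfigurationError, InputError, SelectionError
from .structure import SelectionSpec, Structure, select, write_pdb


def fmt_num(x: float) -> str:
    """Format a float with >= 6 decimals that parses back to the same double.

    Uses fixed 6 decimals when that representation is exact (so grid-aligned
    values render as e.g. ``1.000000``), otherwise the shortest repr.
    """
    s = f"{x:.6f}"
    return s if float(s) == x else repr(float(x))


@dataclass
class PullPlan:
    """Engine-facing description of one constant-velocity pulling campaign.

    Units are engine-native and never silently converted: for NAMD spring_k is
    kcal mol^-1 A^-2 and pull_velocity is A per timestep-unit as the SMDVel
    keyword requires; for GROMACS they are kJ mol^-1 nm^-2 and nm ps^-1.
    """

    engine: str  # "namd" | "gromacs"
    spring_k: float
    pull_velocity: float
    timestep: float  # fs
    n_steps: int
    fixed: SelectionSpec
    pulled: SelectionSpec
    n_replicas: int = 1
    output_root: Path | str = "smd_runs"
    base_seed: int = 12345
    engine_passthrough: dict[str, str] = field(default_factory=dict)
    engine_binary: str | None = None  # default namd3 / gmx

    def __post_init__(self):
        if self.engine not in ("namd", "gromacs"):
            raise ConfigurationError(f"unknown engine {self.engine!r}")
        if self.spring_k <= 0 or self.pull_velocity <= 0 or self.n_steps <= 0:
            raise ConfigurationError(
                "spring_k, pull_velocity and n_steps must be positive")
        if self.n_replicas < 1:
            raise ConfigurationError("n_replicas must be >= 1")
        if isinstance(self.fixed, str):
            self.fixed = SelectionSpec(self.fixed)
        if isinstance(self.pulled, str):
            self.pulled = SelectionSpec(self.pulled)


@dataclass
class RunTree:
    """Scaffolded campaign layout: one subdirectory per pulling direction."""

    root: Path
    directories: dict[str, Path]  # direction label -> subdirectory
    manifest: Path


def _check_unit(direction: Direction) -> np.ndarray:
    v = np.asarray(direction.vector, dtype=float)
    if abs(np.linalg.norm(v) - 1.0) > 1e-9:
        raise ConfigurationError(
            f"direction {direction.label} is not a unit vector")
    return v


def render_namd_config(plan: PullPlan, direction: Direction,
                       ref_pdb: str = "ref.pdb") -> str:
    """NAMD configuration text for one pulling direction."""
    if plan.engine != "namd":
        raise ConfigurationError("render_namd_config requires engine = namd")
    v = _check_unit(direction)
    lines = [
        f"# constant-velocity SMD, direction {direction.label}",
        "set replica $env(SMDFAN_REPLICA)",
        f"seed [expr {{{plan.base_seed} + $replica}}]",
        "outputname smd_r${replica}",
        f"timestep {fmt_num(plan.timestep)}",
        "",
        "SMD on",
        f"SMDk {fmt_num(plan.spring_k)}",
        f"SMDVel {fmt_num(plan.pull_velocity)}",
        f"SMDDir {fmt_num(v[0])} {fmt_num(v[1])} {fmt_num(v[2])}",
        f"SMDFile {ref_pdb}",
        "SMDOutputFreq 100",
        "",
        "fixedAtoms on",
        f"fixedAtomsFile {ref_pdb}",
        "fixedAtomsCol B",
        "",
    ]
    for k, val in plan.engine_passthrough.items():
        lines.append(f"{k} {val}")
    lines.append(f"run {plan.n_steps}")
    return "\n".join(lines) + "\n"


def parse_namd_config(text: str) -> dict:
    """Recover (spring_k, pull_velocity, direction, timestep, n_steps) from rendered text."""
    out: dict = {}
    for line in text.splitlines():
        parts = line.split()
        if not parts:
            continue
        key = parts[0]
        if key == "SMDk":
            out["spring_k"] = float(parts[1])
        elif key == "SMDVel":
            out["pull_velocity"] = float(parts[1])
        elif key == "SMDDir":
            out["direction"] = np.array([float(p) for p in parts[1:4]])
        elif key == "timestep":
            out["timestep"] = float(parts[1])
        elif key == "run":
            out["n_steps"] = int(parts[1])
    return out


def render_namd_reference_pdb(
    structure: Structure,
    fixed_idx: Sequence[int],
    pulled_idx: Sequence[int],
) -> Structure:
    """Annotated copy: B = 1.00 on fixed atoms, occupancy = 1.00 on pulled atoms.

    Matches ``fixedAtomsCol B`` and the SMD occupancy-column convention; all
    other atoms carry 0.00 in both columns.
    """
    fixed_set, pulled_set = set(fixed_idx), set(pulled_idx)
    if not fixed_set or not pulled_set:
        raise InputError("fixed and pulled selections must be non-empty")
    overlap = fixed_set & pulled_set
    if overlap:
        raise SelectionError(
            f"fixed and pulled selections overlap on {len(overlap)} atoms "
            f"(first: index {min(overlap)})")
    out = structure.copy()
    for i, a in enumerate(out.atoms):
        a.beta = 1.0 if i in fixed_set else 0.0
        a.occupancy = 1.0 if i in pulled_set else 0.0
    return out


def render_gromacs_mdp(plan: PullPlan, direction: Direction,
                       gen_seed: int | None = None) -> str:
    """GROMACS .mdp text for one pulling direction (pull code, freeze groups)."""
    if plan.engine != "gromacs":
        raise ConfigurationError("render_gromacs_mdp requires engine = gromacs")
    v = _check_unit(direction)
    dt_ps = plan.timestep * 1e-3
    seed = plan.base_seed if gen_seed is None else gen_seed
    lines = [
        f"; constant-velocity pulling, direction {direction.label}",
        "integrator = md",
        f"dt = {fmt_num(dt_ps)}",
        f"nsteps = {plan.n_steps}",
        f"gen-seed = {seed}",
        "",
        "pull = yes",
        "pull-ngroups = 2",
        "pull-ncoords = 1",
        "pull-group1-name = fixed",
        "pull-group2-name = pulled",
        "pull-coord1-groups = 1 2",
        "pull-coord1-type = umbrella",
        "pull-coord1-geometry = direction",
        f"pull-coord1-vec = {fmt_num(v[0])} {fmt_num(v[1])} {fmt_num(v[2])}",
        f"pull-coord1-rate = {fmt_num(plan.pull_velocity)}",
        f"pull-coord1-k = {fmt_num(plan.spring_k)}",
        "pull-coord1-start = yes",
        "",
        "freezegrps = fixed",
        "freezedim = Y Y Y",
        "",
    ]
    for k, val in plan.engine_passthrough.items():
        lines.append(f"{k} = {val}")
    return "\n".join(lines) + "\n"


def parse_gromacs_mdp(text: str) -> dict:
    """Recover (spring_k, pull_velocity, direction, dt, n_steps, gen_seed)."""
    out: dict = {}
    for line in text.splitlines():
        line = line.split(";")[0]
        if "=" not in line:
            continue
        key, _, val = line.partition("=")
        key, val = key.strip(), val.strip()
        if key == "pull-coord1-k":
            out["spring_k"] = float(val)
        elif key == "pull-coord1-rate":
            out["pull_velocity"] = float(val)
        elif key == "pull-coord1-vec":
            out["direction"] = np.array([float(p) for p in val.split()])
        elif key == "dt":
            out["dt"] = float(val)
        elif key == "nsteps":
            out["n_steps"] = int(val)
        elif key == "gen-seed":
            out["gen_seed"] = int(val)
    return out


def render_ndx(structure: Structure, groups: Mapping[str, Sequence[int]]) -> str:
    """GROMACS .ndx text: 1-based atom numbers, at most 15 per line."""
    if not groups:
        raise ConfigurationError("ndx rendering needs at least one group")
    names = list(groups)
    if len(set(names)) != len(names):
        raise ConfigurationError("duplicate index-group names")
    n = len(structure)
    lines = []
    for name, indices in groups.items():
        idx = list(indices)
        if any(i < 0 or i >= n for i in idx):
            raise InputError(f"group {name!r} has out-of-range atom indices")
        lines.append(f"[ {name} ]")
        serials = [str(i + 1) for i in idx]
        for start in range(0, len(serials), 15):
            lines.append(" ".join(serials[start:start + 15]))
    return "\n".join(lines) + "\n"


def parse_ndx(text: str) -> dict[str, list[int]]:
    """Parse .ndx text back to 0-based index lists."""
    groups: dict[str, list[int]] = {}
    current: list[int] | None = None
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("[") and line.endswith("]"):
            name = line[1:-1].strip()
            current = groups.setdefault(name, [])
        elif current is not None:
            current.extend(int(tok) - 1 for tok in line.split())
    return groups


def _run_script_namd(plan: PullPlan) -> str:
    binary = plan.engine_binary or "namd3"
    return "\n".join([
        "#!/bin/bash",
        "# run all replicas of this pulling direction",
        "set -e",
        f"for r in $(seq 1 {plan.n_replicas}); do",
        f'    SMDFAN_REPLICA=$r {binary} smd.namd > smd_r${{r}}.log',
        "done",
    ]) + "\n"


def _run_script_gromacs(plan: PullPlan) -> str:
    binary = plan.engine_binary or "gmx"
    return "\n".join([
        "#!/bin/bash",
        "# run all replicas of this pulling direction",
        "set -e",
        "TOP=${TOP:-../topol.top}",
        "GRO=${GRO:-../conf.gro}",
        f"for r in $(seq 1 {plan.n_replicas}); do",
        f'    {binary} grompp -f smd_r${{r}}.mdp -c "$GRO" -p "$TOP" '
        f'-n index.ndx -o smd_r${{r}}.tpr',
        f'    {binary} mdrun -deffnm smd_r${{r}} '
        f'-pf pullf_r${{r}}.xvg -px pullx_r${{r}}.xvg',
        "done",
    ]) + "\n"


def scaffold(
    plan: PullPlan,
    dset: DirectionSet,
    structure: Structure,
    overwrite: bool = False,
) -> RunTree:
    """Create the campaign tree: one subdirectory per direction plus a manifest."""
    root = Path(plan.output_root)
    if root.exists() and any(root.iterdir()):
        if not overwrite:
            raise InputError(
                f"output root {root} exists and is not empty "
                "(pass overwrite=True to replace it)")
        shutil.rmtree(root)
    root.mkdir(parents=True, exist_ok=True)

    fixed_idx = select(structure, plan.fixed)
    pulled_idx = select(structure, plan.pulled)
    if not fixed_idx or not pulled_idx:
        raise InputError("fixed or pulled selection resolved to zero atoms")

    dirs: dict[str, Path] = {}
    for d in dset:
        sub = root / d.label
        sub.mkdir()
        if plan.engine == "namd":
            ref = render_namd_reference_pdb(structure, fixed_idx, pulled_idx)
            write_pdb(ref, sub / "ref.pdb")
            (sub / "smd.namd").write_text(render_namd_config(plan, d))
            script = _run_script_namd(plan)
        else:
            (sub / "index.ndx").write_text(
                render_ndx(structure, {"fixed": fixed_idx, "pulled": pulled_idx}))
            for r in range(1, plan.n_replicas + 1):
                (sub / f"smd_r{r}.mdp").write_text(
                    render_gromacs_mdp(plan, d, gen_seed=plan.base_seed + r))
            script = _run_script_gromacs(plan)
        run_sh = sub / "run.sh"
        run_sh.write_text(script)
        os.chmod(run_sh, 0o755)
        dirs[d.label] = sub

    manifest = root / "manifest.tsv"
    header = (f"# engine = {plan.engine}\n"
              f"# base_seed = {plan.base_seed}\n"
              f"# n_replicas = {plan.n_replicas}\n")
    manifest.write_text(header + dset.to_table())
    return RunTree(root=root, directories=dirs, manifest=manifest)


def read_manifest(root: str | Path) -> tuple[dict[str, str], list[dict]]:
    """Read a campaign manifest: ({meta}, [rows with label/theta/phi/vector])."""
    path = Path(root) / "manifest.tsv"
    if not path.is_file():
        raise InputError(f"no manifest.tsv under {root}")
    meta: dict[str, str] = {}
    rows: list[dict] = []
    header: list[str] | None = None
    for line in path.read_text().splitlines():
        if line.startswith("#"):
            k, _, v = line[1:].partition("=")
            meta[k.strip()] = v.strip()
        elif header is None:
            header = line.split("\t")
        elif line.strip():
            vals = dict(zip(header, line.split("\t")))
            rows.append({
                "label": vals["label"],
                "theta": float(vals["theta"]),
                "phi": float(vals["phi"]),
                "vector": np.array([float(vals["vx"]), float(vals["vy"]),
                                    float(vals["vz"])]),
            })
    return meta, rows
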