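"""Desk-scale steered Brownian-dynamics engine for bead-spring complexes.

The simulator plays the role of an MD engine at toy scale: a bead-spring
complex with breakable interface bonds is pulled by the standard
constant-velocity SMD spring

    F(t) = k_spring (v_pull t - (COM_pulled(t) - COM_pulled(0)) . direction)

applied along a unit direction and distributed over the pulled beads in
proportion to their mass.  Free beads follow overdamped (inertialess)
Langevin dynamics integrated with Euler-Maruyama,

    dr = (F_total / gamma) dt + sqrt(2 kB T dt / gamma) xi,

fixed beads never move, and a breakable bond is removed permanently the first
step its length exceeds its rupture length.  Internal units are pN / A / ps;
the emitted log uses NAMD's SMD line dialect (positions in A, forces in
kcal mol^-1 A^-1) so the downstream parser consumes it unchanged.

The module also provides the built-in anisotropic two-cluster complex used
for end-to-end pipeline checks, and a rigid quasi-static displacement scan
that serves as a brute-force rupture-force oracle for it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import ConfigurationError, InputError, StabilityError
from .structure import AtomRecord, Structure
from .units import KB_PN_ANGSTROM_PER_K, pn_to_namd_force


@dataclass
class Bond:
    """Harmonic bond; breakable bonds snap irreversibly past r_break."""

    i: int
    j: int
    k: float      # pN / A
    r0: float     # A
    breakable: bool = False
    r_break: float = np.inf  # A

    def __post_init__(self):
        if self.breakable and self.r_break <= self.r0:
            raise ConfigurationError("r_break must exceed r0 for breakable bonds")


@dataclass
class ToyModel:
    """Bead-spring complex with an immobilized and a pulled bead group."""

    positions: np.ndarray       # (n, 3) A
    masses: np.ndarray          # (n,) amu
    gamma: np.ndarray           # (n,) pN ps / A
    bonds: list[Bond]
    temperature: float          # K
    fixed_idx: np.ndarray
    pulled_idx: np.ndarray

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        self.masses = np.asarray(self.masses, dtype=float)
        self.gamma = np.asarray(self.gamma, dtype=float)
        self.fixed_idx = np.asarray(self.fixed_idx, dtype=int)
        self.pulled_idx = np.asarray(self.pulled_idx, dtype=int)
        if np.any(self.gamma <= 0):
            raise ConfigurationError("friction gamma must be positive")
        if np.any(self.masses <= 0):
            raise ConfigurationError("masses must be positive")
        if set(self.fixed_idx) & set(self.pulled_idx):
            raise ConfigurationError("fixed and pulled bead sets overlap")

    @property
    def n_beads(self) -> int:
        return self.positions.shape[0]


@dataclass
class SMDProtocol:
    """Constant-velocity pulling protocol for the toy engine."""

    direction: np.ndarray   # unit 3-vector
    k_spring: float         # pN / A
    v_pull: float           # A / ps
    dt: float               # ps
    n_steps: int
    seed: int = 0
    log_stride: int = 10

    def __post_init__(self):
        self.direction = np.asarray(self.direction, dtype=float)
        nrm = float(np.linalg.norm(self.direction))
        if nrm < 1e-12:
            raise ConfigurationError("pulling direction must be non-zero")
        self.direction = self.direction / nrm
        if self.dt <= 0 or self.n_steps <= 0 or self.log_stride < 1:
            raise ConfigurationError("dt, n_steps > 0 and log_stride >= 1 required")


def smd_force(t: float, com_pulled: np.ndarray, com0: np.ndarray,
              proto: SMDProtocol) -> tuple[float, np.ndarray]:
    """SMD spring force: scalar along the direction and the force vector (pN)."""
    ext = proto.v_pull * t - float(
        (np.asarray(com_pulled) - np.asarray(com0)) @ proto.direction)
    f = proto.k_spring * ext
    return f, f * proto.direction


@dataclass
class ToyRun:
    """Output of one steered toy simulation."""

    frames: list[np.ndarray]        # logged coordinates, (n, 3) A
    log_text: str                   # NAMD-dialect SMD log
    times: np.ndarray               # logged times, ps
    forces_pn: np.ndarray           # logged scalar spring force, pN
    com_positions: np.ndarray       # logged pulled-group COM, A
    broken_bonds: list[int]         # indices into model.bonds, in break order

    def __iter__(self):  # allows `frames, log = run_toy_smd(...)`
        return iter((self.frames, self.log_text))


def run_toy_smd(model: ToyModel, proto: SMDProtocol) -> ToyRun:
    """Integrate the steered overdamped dynamics and emit a NAMD-style log.

    Every ``log_stride`` steps (including step 0) one ``SMD`` line records the
    step, the pulled-group COM (A) and the applied SMD force vector converted
    to kcal mol^-1 A^-1.
    """
    rng = np.random.default_rng(proto.seed)
    r = model.positions.copy()
    n = model.n_beads
    free = np.ones(n, dtype=bool)
    free[model.fixed_idx] = False

    bonds = model.bonds
    bi = np.array([b.i for b in bonds], dtype=int) if bonds else np.empty(0, int)
    bj = np.array([b.j for b in bonds], dtype=int) if bonds else np.empty(0, int)
    bk = np.array([b.k for b in bonds]) if bonds else np.empty(0)
    br0 = np.array([b.r0 for b in bonds]) if bonds else np.empty(0)
    b_breakable = np.array([b.breakable for b in bonds], dtype=bool) \
        if bonds else np.empty(0, bool)
    b_rbreak = np.array([b.r_break for b in bonds]) if bonds else np.empty(0)
    alive = np.ones(len(bonds), dtype=bool)
    broken_order: list[int] = []

    mp = model.masses[model.pulled_idx]
    mp_frac = mp / mp.sum()
    com0 = (r[model.pulled_idx] * mp[:, None]).sum(axis=0) / mp.sum()

    gamma = model.gamma[:, None]
    noise_amp = np.sqrt(2.0 * KB_PN_ANGSTROM_PER_K * model.temperature
                        * proto.dt / model.gamma)[:, None]
    use_noise = model.temperature > 0

    frames: list[np.ndarray] = []
    log_lines: list[str] = []
    times: list[float] = []
    forces: list[float] = []
    coms: list[np.ndarray] = []

    def _log(step: int, com: np.ndarray, fvec_pn: np.ndarray, f_pn: float,
             t: float) -> None:
        f_namd = pn_to_namd_force(1.0) * fvec_pn
        log_lines.append(
            "SMD %d %.10g %.10g %.10g %.10g %.10g %.10g"
            % (step, com[0], com[1], com[2], f_namd[0], f_namd[1], f_namd[2]))
        frames.append(r.copy())
        times.append(t)
        forces.append(f_pn)
        coms.append(com.copy())

    for step in range(proto.n_steps + 1):
        t = step * proto.dt
        force = np.zeros((n, 3))
        if len(bonds) and alive.any():
            ai = bi[alive]
            aj = bj[alive]
            rij = r[aj] - r[ai]
            d = np.linalg.norm(rij, axis=1)
            # snap over-stretched breakable bonds before computing their force
            snap = alive.copy()
            snap[alive] = b_breakable[alive] & (d > b_rbreak[alive])
            if snap.any():
                broken_order.extend(int(x) for x in np.flatnonzero(snap))
                alive &= ~snap
                ai, aj = bi[alive], bj[alive]
                rij = r[aj] - r[ai]
                d = np.linalg.norm(rij, axis=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                u = np.where(d[:, None] > 0, rij / d[:, None], 0.0)
            fb = (bk[alive] * (d - br0[alive]))[:, None] * u
            np.add.at(force, ai, fb)
            np.add.at(force, aj, -fb)

        com = (r[model.pulled_idx] * mp[:, None]).sum(axis=0) / mp.sum()
        f_scalar, fvec = smd_force(t, com, com0, proto)
        force[model.pulled_idx] += mp_frac[:, None] * fvec[None, :]

        if step % proto.log_stride == 0:
            _log(step, com, fvec, f_scalar, t)
        if step == proto.n_steps:
            break

        dr = force / gamma * proto.dt
        if use_noise:
            dr = dr + noise_amp * rng.standard_normal((n, 3))
        r[free] += dr[free]
        if not np.isfinite(r).all():
            raise StabilityError(
                f"non-finite coordinates at step {step + 1}; "
                "reduce dt or spring stiffness")

    return ToyRun(frames=frames, log_text="\n".join(log_lines) + "\n",
                  times=np.array(times), forces_pn=np.array(forces),
                  com_positions=np.array(coms), broken_bonds=broken_order)


# ---------------------------------------------------------------------------
# built-in anisotropic test complex
# ---------------------------------------------------------------------------

#: default protocol parameters for campaigns on the built-in complex
DEFAULT_TOY_PROTOCOL = dict(k_spring=20.0, v_pull=0.05, dt=0.005,
                            n_steps=88000, log_stride=40)


def make_anisotropic_complex(seed: int = 0) -> tuple[ToyModel, Structure]:
    """Synthetic two-cluster complex whose rupture force is direction-dependent.

    A pulled four-bead tetrahedron (chain B) sits above a fixed "socket":
    a five-bead ring plus center bead (chain A).  Breakable bonds anchor the
    tetrahedron to distinct ring positions with very unequal stiffnesses, so
    each pulling direction loads a different bond combination: the nine
    default directions rupture at quasi-static forces spanning roughly
    64-143 pN with no two closer than ~6 pN.  Bonds are tilted on purpose —
    bonds parallel to the inter-COM axis would respond identically to every
    transverse pull of a rigid cluster and the azimuthal anisotropy would
    vanish.  ``seed`` jitters the bead positions slightly (0.02 A) so
    independently generated fixtures differ.

    Returns the model together with its rendering as a PDB structure so the
    whole setup pipeline (selections, axis, scaffolding) runs on it.
    """
    rng = np.random.default_rng(seed)
    ring_angles = np.deg2rad([0, 72, 144, 216, 288])
    fixed_pts = np.array([[5 * np.cos(a), 5 * np.sin(a), 0.0]
                          for a in ring_angles] + [[0.0, 0.0, 0.0]])
    tetra = np.array([[1.8, 0.0, 0.0], [-0.9, 1.56, 0.0],
                      [-0.9, -1.56, 0.0], [0.0, 0.0, 1.8]])
    pulled_pts = tetra + np.array([0.0, 0.0, 5.0])
    positions = np.vstack([fixed_pts, pulled_pts])
    positions += rng.normal(scale=0.02, size=positions.shape)
    n_f = len(fixed_pts)
    n = len(positions)

    bonds: list[Bond] = []
    for group in (range(n_f), range(n_f, n)):
        idx = list(group)
        for a in range(len(idx)):
            for b in range(a + 1, len(idx)):
                d = float(np.linalg.norm(positions[idx[b]] - positions[idx[a]]))
                bonds.append(Bond(idx[a], idx[b], k=100.0, r0=d))

    # breakable anchors: (ring bead, tetrahedron bead, stiffness pN/A,
    # rupture extension A); stiffness spans ~3.5x so different directions
    # rupture at well-separated forces
    interface = [
        (3, 0, 6.0, 2.2),
        (3, 3, 5.8, 2.2),
        (0, 2, 8.0, 2.8),
        (0, 0, 17.3, 3.2),
        (1, 2, 20.0, 3.1),
        (4, 3, 17.8, 2.5),
    ]
    for fi, pi, kb, ext in interface:
        i, j = fi, n_f + pi
        d = float(np.linalg.norm(positions[j] - positions[i]))
        bonds.append(Bond(i, j, k=kb, r0=d, breakable=True, r_break=d + ext))

    model = ToyModel(
        positions=positions,
        masses=np.full(n, 12.011),
        gamma=np.full(n, 5.0),
        bonds=bonds,
        temperature=10.0,
        fixed_idx=np.arange(n_f),
        pulled_idx=np.arange(n_f, n),
    )

    atoms = [
        AtomRecord(serial=i + 1, name="CA", resname="TOY",
                   chain=("A" if i < n_f else "B"),
                   resseq=(i if i < n_f else i - n_f) + 1,
                   x=round(positions[i, 0], 3), y=round(positions[i, 1], 3),
                   z=round(positions[i, 2], 3),
                   occupancy=1.0, beta=0.0, element="C", mass=12.011)
        for i in range(n)
    ]
    return model, Structure(atoms=atoms, title="synthetic two-cluster toy complex")


def run_toy_campaign(
    model: ToyModel,
    dset,
    n_replicas: int = 5,
    base_seed: int = 0,
    out_root=None,
    structure: Structure | None = None,
    write_trajectories: bool = False,
    **proto_kwargs,
) -> dict[str, list[ToyRun]]:
    """Run the toy engine for every direction x replica of a DirectionSet.

    Replica r of any direction uses seed ``base_seed + r`` (replicas differ
    only in their noise realization, mirroring the engine-input convention).
    When ``out_root`` is given the runs are written in the same tree layout
    the analysis stage expects: ``<root>/<label>/smd_r<r>.log`` plus a
    manifest, and optionally multi-model PDB trajectories.
    """
    from pathlib import Path

    from .trajectory import write_pdb_models

    params = {**DEFAULT_TOY_PROTOCOL, **proto_kwargs}
    results: dict[str, list[ToyRun]] = {}
    root = Path(out_root) if out_root is not None else None
    if root is not None:
        root.mkdir(parents=True, exist_ok=True)
        (root / "manifest.tsv").write_text(
            "# engine = toysim\n"
            f"# base_seed = {base_seed}\n"
            f"# n_replicas = {n_replicas}\n"
            f"# timestep_fs = {params['dt'] * 1000.0}\n" + dset.to_table())
    for d in dset:
        runs = []
        for rep in range(1, n_replicas + 1):
            proto = SMDProtocol(direction=d.vector, seed=base_seed + rep,
                                **params)
            run = run_toy_smd(model, proto)
            runs.append(run)
            if root is not None:
                sub = root / d.label
                sub.mkdir(exist_ok=True)
                (sub / f"smd_r{rep}.log").write_text(run.log_text)
                if write_trajectories and structure is not None:
                    write_pdb_models(structure, run.frames,
                                     sub / f"traj_r{rep}.pdb")
        results[d.label] = runs
    return results


def quasistatic_rupture_scan(
    model: ToyModel,
    direction: Sequence[float],
    s_max: float = 22.0,
    ds: float = 0.05,
    k_spring: float = 50.0,
) -> tuple[float, float]:
    """Brute-force rupture oracle: quasi-static energy scan along a direction.

    The scan is the zero-velocity, zero-temperature limit of the pulling
    protocol: the spring anchor is displaced by s along the direction on a
    fine grid, and at every s the total energy (harmonic bonds plus the COM
    spring) is minimized over all mobile bead coordinates, warm-starting
    from the previous minimum so the system follows the adiabatic branch.
    Breakable bonds found over-stretched at a minimum are removed permanently
    and the configuration re-relaxed.  The restoring force is the spring
    tension k_spring (s - u) at the minimum, with u the projected COM
    displacement.  Returns (F_max in pN, anchor displacement s at F_max, A).
    """
    from scipy.optimize import minimize

    direction = np.asarray(direction, dtype=float)
    direction = direction / np.linalg.norm(direction)
    bonds = model.bonds
    if not any(b.breakable for b in bonds):
        raise InputError("model has no breakable bonds to rupture")

    n = model.n_beads
    mobile = np.ones(n, dtype=bool)
    mobile[model.fixed_idx] = False
    mob_idx = np.flatnonzero(mobile)
    pulled = model.pulled_idx
    mp = model.masses[pulled]
    w = mp / mp.sum()
    r_full = model.positions.copy()
    com0 = (r_full[pulled] * mp[:, None]).sum(axis=0) / mp.sum()

    bi = np.array([b.i for b in bonds], dtype=int)
    bj = np.array([b.j for b in bonds], dtype=int)
    bk = np.array([b.k for b in bonds])
    br0 = np.array([b.r0 for b in bonds])
    b_breakable = np.array([b.breakable for b in bonds], dtype=bool)
    b_rbreak = np.array([b.r_break for b in bonds])
    alive = np.ones(len(bonds), dtype=bool)

    def energy_grad(x: np.ndarray, s: float) -> tuple[float, np.ndarray]:
        r = r_full.copy()
        r[mob_idx] = x.reshape(-1, 3)
        grad = np.zeros_like(r)
        ai, aj = bi[alive], bj[alive]
        rij = r[aj] - r[ai]
        d = np.linalg.norm(rij, axis=1)
        d = np.where(d > 1e-12, d, 1e-12)
        stretch = d - br0[alive]
        e = 0.5 * float(bk[alive] @ stretch**2)
        fb = (bk[alive] * stretch / d)[:, None] * rij
        np.add.at(grad, ai, -fb)
        np.add.at(grad, aj, fb)
        com = (r[pulled] * mp[:, None]).sum(axis=0) / mp.sum()
        u = float((com - com0) @ direction)
        e += 0.5 * k_spring * (s - u) ** 2
        grad[pulled] += (-k_spring * (s - u)) * w[:, None] * direction[None, :]
        return e, grad[mob_idx].ravel()

    x = r_full[mob_idx].ravel()
    f_max, s_at = 0.0, 0.0
    for s in np.arange(0.0, s_max + ds / 2, ds):
        while True:
            res = minimize(energy_grad, x, args=(s,), jac=True,
                           method="L-BFGS-B",
                           options={"maxiter": 500, "ftol": 1e-12,
                                    "gtol": 1e-8})
            x = res.x
            r = r_full.copy()
            r[mob_idx] = x.reshape(-1, 3)
            d = np.linalg.norm(r[bj] - r[bi], axis=1)
            snap = alive & b_breakable & (d > b_rbreak)
            if not snap.any():
                break
            alive &= ~snap
        com = (r[pulled] * mp[:, None]).sum(axis=0) / mp.sum()
        u = float((com - com0) @ direction)
        f = k_spring * (s - u)
        if f > f_max:
            f_max, s_at = f, float(s)
        if not (alive & b_breakable).any() and f < 0.2 * f_max:
            break  # interface fully ruptured and force relaxed
    return f_max, s_at
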