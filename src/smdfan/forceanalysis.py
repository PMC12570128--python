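"""Rupture-force and hydrogen-bond analysis of pulling campaigns.

The quantities of interest per pulling direction are: the force-time curve,
the force against the center-of-mass distance of the two groups, the maximum
(rupture) force interpreted as the mechanical stability along that direction,
replica mean +- SD curves, and the count of inter-fragment hydrogen bonds per
trajectory frame under a geometric criterion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import AlignmentError, InputError
from .smdparse import ForceTrace


def running_mean(y: np.ndarray, window: int) -> np.ndarray:
    """Centered running mean with edge truncation; window <= 1 is a no-op."""
    y = np.asarray(y, dtype=float)
    if window <= 1:
        return y
    half = window // 2
    csum = np.cumsum(np.concatenate(([0.0], y)))
    n = len(y)
    lo = np.maximum(np.arange(n) - half, 0)
    hi = np.minimum(np.arange(n) + half + 1, n)
    return (csum[hi] - csum[lo]) / (hi - lo)


def max_rupture_force(trace: ForceTrace, smooth_window: int = 0) -> tuple[float, float]:
    """Global maximum of the force series and the time it occurs.

    Ties report the earliest time.  The maximum is taken on the raw series by
    default; ``smooth_window`` > 1 applies a centered running mean first
    (opt-in, intended for visual summaries).
    """
    if len(trace) == 0:
        raise InputError("max_rupture_force: empty trace")
    f = running_mean(trace.force, smooth_window)
    i = int(np.argmax(f))  # argmax returns the first maximum
    return float(f[i]), float(trace.time[i])


def force_vs_distance(trace: ForceTrace, distances: Sequence[float]) -> np.ndarray:
    """(distance, force) pairs ordered by time; distance may be non-monotone."""
    d = np.asarray(distances, dtype=float)
    if d.shape[0] != len(trace):
        raise AlignmentError(
            f"distance series length {d.shape[0]} != trace length {len(trace)}")
    return np.column_stack([d, trace.force])


@dataclass
class ReplicaEnsemble:
    """Replica traces of one direction resampled onto a common time grid."""

    traces: list[ForceTrace]
    common_time: np.ndarray
    mean_force: np.ndarray
    sd_force: np.ndarray
    label: str = ""


def aggregate_replicas(traces: Sequence[ForceTrace],
                       grid_dt: float | None = None) -> ReplicaEnsemble:
    """Pointwise mean and sample SD over replicas on a shared uniform grid.

    Each trace is linearly interpolated onto a grid spanning the intersection
    of the replica time ranges, so no values are fabricated outside any
    trace's span.  The default grid step is the smallest native sampling
    interval among the replicas.  SD uses the n-1 denominator and is zero for
    a single replica.
    """
    traces = list(traces)
    if not traces:
        raise InputError("aggregate_replicas: no traces")
    t0 = max(tr.time[0] for tr in traces)
    t1 = min(tr.time[-1] for tr in traces)
    if t1 < t0:
        raise AlignmentError("replica time ranges do not overlap")
    if grid_dt is None:
        steps = [np.diff(tr.time).min() for tr in traces if len(tr) > 1]
        grid_dt = float(min(steps)) if steps else 1.0
    n = max(int(np.floor((t1 - t0) / grid_dt + 1e-9)) + 1, 1)
    grid = t0 + grid_dt * np.arange(n)
    ys = np.array([np.interp(grid, tr.time, tr.force) for tr in traces])
    mean = ys.mean(axis=0)
    sd = (ys.std(axis=0, ddof=1) if len(traces) > 1
          else np.zeros_like(mean))
    return ReplicaEnsemble(traces=traces, common_time=grid,
                           mean_force=mean, sd_force=sd,
                           label=traces[0].label)


@dataclass
class HBondCriterion:
    """Geometric hydrogen-bond definition.

    d_max : donor-acceptor distance cutoff, A (default 3.5, the de facto
        standard geometric criterion).
    angle_min : D-H...A angle cutoff at the hydrogen, degrees (default 150).
    """

    d_max: float = 3.5
    angle_min: float = 150.0

    def __post_init__(self):
        if self.d_max <= 0:
            raise InputError("d_max must be positive")
        if not 0 < self.angle_min <= 180:
            raise InputError("angle_min must lie in (0, 180]")


def count_hbonds(
    frame: np.ndarray,
    donors: Sequence[tuple[int, int]],
    acceptors: Sequence[int],
    crit: HBondCriterion = HBondCriterion(),
    fragment_of: Mapping[int, int] | None = None,
) -> int:
    """Count hydrogen bonds in one frame.

    A (D, H, A) triple is a bond when |D - A| <= d_max and the D-H...A angle
    (at the hydrogen) >= angle_min, with A != D.  ``fragment_of`` (atom index
    -> fragment id) restricts counting to inter-fragment pairs, the relevant
    set when monitoring interface rupture.
    """
    frame = np.asarray(frame, dtype=float)
    n = frame.shape[0]
    donors = list(donors)
    acc = np.asarray(list(acceptors), dtype=int)
    if donors and (max(max(d, h) for d, h in donors) >= n
                   or min(min(d, h) for d, h in donors) < 0):
        raise InputError("donor index out of range")
    if acc.size and (acc.max() >= n or acc.min() < 0):
        raise InputError("acceptor index out of range")
    if not donors or acc.size == 0:
        return 0
    d_idx = np.array([d for d, _ in donors], dtype=int)
    h_idx = np.array([h for _, h in donors], dtype=int)
    # pairwise donor-acceptor distances
    dvec = frame[acc][None, :, :] - frame[d_idx][:, None, :]  # (nd, na, 3)
    dist = np.linalg.norm(dvec, axis=2)
    ok = dist <= crit.d_max
    ok &= acc[None, :] != d_idx[:, None]
    if fragment_of is not None:
        frag_d = np.array([fragment_of[i] for i in d_idx])
        frag_a = np.array([fragment_of[i] for i in acc])
        ok &= frag_d[:, None] != frag_a[None, :]
    if not ok.any():
        return 0
    # angle at H between H->D and H->A
    hd = frame[d_idx] - frame[h_idx]  # (nd, 3)
    ha = frame[acc][None, :, :] - frame[h_idx][:, None, :]  # (nd, na, 3)
    num = np.einsum("ij,ikj->ik", hd, ha)
    den = (np.linalg.norm(hd, axis=1)[:, None]
           * np.linalg.norm(ha, axis=2))
    with np.errstate(invalid="ignore", divide="ignore"):
        cosang = np.clip(np.where(den > 0, num / den, 1.0), -1.0, 1.0)
    angle = np.degrees(np.arccos(cosang))
    ok &= angle >= crit.angle_min
    return int(ok.sum())


def hbond_series(
    frames: Sequence[np.ndarray],
    donors: Sequence[tuple[int, int]],
    acceptors: Sequence[int],
    crit: HBondCriterion = HBondCriterion(),
    fragment_of: Mapping[int, int] | None = None,
) -> np.ndarray:
    """Per-frame hydrogen-bond counts, frame order preserved."""
    out = np.empty(len(frames), dtype=int)
    for k, frame in enumerate(frames):
        try:
            out[k] = count_hbonds(frame, donors, acceptors, crit, fragment_of)
        except InputError as exc:
            raise InputError(f"frame {k}: {exc}") from None
    return out


@dataclass
class RuptureSummary:
    """Per-direction rupture statistics across replicas."""

    label: str
    theta: float
    phi: float
    replicas: list[dict] = field(default_factory=list)
    # each replica dict: {"replica_id", "f_max", "t_at_max", "distance_at_max"}

    @property
    def f_max_values(self) -> np.ndarray:
        return np.array([r["f_max"] for r in self.replicas])

    @property
    def mean_f_max(self) -> float:
        return float(self.f_max_values.mean())

    @property
    def sd_f_max(self) -> float:
        v = self.f_max_values
        return float(v.std(ddof=1)) if len(v) > 1 else 0.0


def summarize_ruptures(
    label: str,
    theta: float,
    phi: float,
    traces: Sequence[ForceTrace],
    distances: Sequence[np.ndarray] | None = None,
    smooth_window: int = 0,
) -> RuptureSummary:
    """Build a :class:`RuptureSummary` from one direction's replica traces."""
    summ = RuptureSummary(label=label, theta=theta, phi=phi)
    for k, tr in enumerate(traces):
        f_max, t_at = max_rupture_force(tr, smooth_window)
        dist_at = None
        if distances is not None:
            d = np.asarray(distances[k], dtype=float)
            if d.shape[0] == len(tr):
                dist_at = float(d[int(np.argmax(running_mean(tr.force, smooth_window)))])
        summ.replicas.append({
            "replica_id": tr.replica_id,
            "f_max": f_max,
            "t_at_max": t_at,
            "distance_at_max": dist_at,
        })
    return summ


def anisotropy_table(summaries: Sequence[RuptureSummary]) -> pd.DataFrame:
    """One row per pulling direction: mean and SD of the rupture force (pN)."""
    summaries = list(summaries)
    if not summaries:
        raise InputError("anisotropy_table: no summaries")
    labels = [s.label for s in summaries]
    if len(set(labels)) != len(labels):
        raise InputError("duplicate direction labels in anisotropy table")
    return pd.DataFrame({
        "label": labels,
        "theta": [s.theta for s in summaries],
        "phi": [s.phi for s in summaries],
        "mean_f_max_pN": [s.mean_f_max for s in summaries],
        "sd_f_max_pN": [s.sd_f_max for s in summaries],
        "n_replicas": [len(s.replicas) for s in summaries],
    })
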