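"""Chemotaxis trajectory metrics and wound-closure planimetry.

Per-cell metrics from horizontal-chemotaxis (TAXIScan-style) tracks:

* velocity — curvilinear speed, total path length over elapsed time
  (μm/min);
* directionality — a signed chemotactic index: the net displacement
  projected onto the gradient axis, divided by the total path length.
  It is bounded in [−1, 1]: +1 means a straight run toward the
  chemoattractant source, 0 an aimless or closed path. The alternative
  convention (forward migration per unit time, μm/min, unbounded) is
  available via ``directionality_mode="fmi_per_time"``.

Wound closure expresses each day's wound area as a percentage of the
day-0 area (day 0 ≡ 100%).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DomainError
from .types import ChemotaxisMetrics, Trajectory, WoundSeries

__all__ = ["track_metrics", "cohort_summary", "recenter", "wound_closure"]


def track_metrics(
    traj: Trajectory, directionality_mode: str = "chemotactic_index"
) -> ChemotaxisMetrics:
    """Compute velocity, directionality, path length and net displacement.

    A stationary cell has velocity 0 and directionality defined as 0.
    Duplicate timestamps are rejected at :class:`Trajectory` construction.
    """
    if directionality_mode not in ("chemotactic_index", "fmi_per_time"):
        raise DomainError(f"unknown directionality_mode {directionality_mode!r}")
    dx = np.diff(traj.xs)
    dy = np.diff(traj.ys)
    path = float(np.sum(np.hypot(dx, dy)))
    elapsed_min = float(traj.times[-1] - traj.times[0]) / 60.0
    net_vec = np.array([traj.xs[-1] - traj.xs[0], traj.ys[-1] - traj.ys[0]])
    net = float(np.hypot(*net_vec))
    proj = float(net_vec @ np.asarray(traj.gradient_axis))
    velocity = path / elapsed_min
    if directionality_mode == "chemotactic_index":
        directionality = proj / path if path > 0 else 0.0
    else:
        directionality = proj / elapsed_min
    return ChemotaxisMetrics(
        velocity=velocity,
        directionality=directionality,
        path_length=path,
        net_displacement=net,
    )


def recenter(trajs: Sequence[Trajectory]) -> list:
    """Translate each track so it starts at the origin (for rose/spider plots).

    A pure translation: shapes, step lengths and pairwise distances are
    unchanged, and the operation is idempotent.
    """
    out = []
    for t in trajs:
        out.append(
            Trajectory(
                cell_id=t.cell_id,
                times=t.times.copy(),
                xs=t.xs - t.xs[0],
                ys=t.ys - t.ys[0],
                gradient_axis=t.gradient_axis,
            )
        )
    return out


def cohort_summary(
    trajs: Sequence[Trajectory],
    group_labels: Sequence[str],
    min_frames: int = 5,
    directionality_mode: str = "chemotactic_index",
) -> pd.DataFrame:
    """Per-group mean ± SEM of velocity and directionality.

    Tracks shorter than ``min_frames`` samples are excluded (counted in
    ``n_excluded``) — very short tracks make both metrics unstable. Row
    order follows first appearance of each label; the summary is fully
    deterministic and invariant to permuting the input.
    """
    if len(trajs) != len(group_labels):
        raise DomainError("trajs and group_labels must have equal length")
    order = list(dict.fromkeys(group_labels))
    per_group = {g: [] for g in order}
    excluded = {g: 0 for g in order}
    for t, g in zip(trajs, group_labels):
        if len(t) < min_frames:
            excluded[g] += 1
            continue
        per_group[g].append(track_metrics(t, directionality_mode=directionality_mode))
    rows = []
    for g in order:
        ms = per_group[g]
        n = len(ms)
        # sorted before summing so the output is exactly permutation-invariant
        vel = np.sort([m.velocity for m in ms])
        dire = np.sort([m.directionality for m in ms])
        rows.append({
            "group": g,
            "n": n,
            "n_excluded": excluded[g],
            "velocity_mean": float(vel.mean()) if n else np.nan,
            "velocity_sem": float(vel.std(ddof=1) / np.sqrt(n)) if n > 1 else np.nan,
            "directionality_mean": float(dire.mean()) if n else np.nan,
            "directionality_sem": float(dire.std(ddof=1) / np.sqrt(n)) if n > 1 else np.nan,
        })
    return pd.DataFrame(rows)


def wound_closure(series: WoundSeries) -> np.ndarray:
    """Wound area as a percentage of the day-0 area; first value exactly 100.

    >>> import numpy as np
    >>> from cellmech import WoundSeries, wound_closure
    >>> wound_closure(WoundSeries(days=[0, 3, 6], areas=[78.5, 39.25, 0.0]))
    array([100.,  50.,   0.])
    """
    # ratio first so day 0 is exactly 100 in floating point
    return 100.0 * (series.areas / series.areas[0])
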