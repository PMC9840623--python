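"""Single-particle tracking: trajectory linking and step-size fitting.

For long-exposure acquisitions (one excitation pulse per frame),
localizations in consecutive frames are linked into trajectories when the
match is unambiguous, and the pooled step-size distribution is fit to a
mixture of 2D random-walk (Rayleigh) components

    P(r) = sum_i f_i (2 r / (4 D_i dt)) exp(-r^2 / (4 D_i dt)),

with no background term and no truncation normalization — ambiguous
pairings are discarded at the linking stage instead of being modeled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .smdm import FitResult, _fit_mixture

__all__ = ["Trajectory", "link_trajectories", "fit_trajectory_displacements"]

MIN_POOLED_STEPS = 200


@dataclass
class Trajectory:
    """One linked molecule track: consecutive frames, positions in nm."""

    frames: np.ndarray
    x_nm: np.ndarray
    y_nm: np.ndarray
    gap_policy: str = "none"

    def __post_init__(self):
        self.frames = np.asarray(self.frames, int)
        self.x_nm = np.asarray(self.x_nm, float)
        self.y_nm = np.asarray(self.y_nm, float)
        if np.any(np.diff(self.frames) != 1):
            raise ValueError("trajectory frames must be consecutive")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def steps_nm(self) -> np.ndarray:
        return np.hypot(np.diff(self.x_nm), np.diff(self.y_nm))


def link_trajectories(
    table: pd.DataFrame,
    link_radius_nm: float = 800.0,
    min_len: int = 5,
    max_len: int = 30,
) -> list[Trajectory]:
    """Greedy unambiguous frame-to-frame linking.

    A link between a localization in frame t and one in frame t+1 is made
    only when each is the other's *unique* candidate within
    ``link_radius_nm`` (bidirectional uniqueness); any multiplicity cuts the
    affected tracks at that frame, and the resulting segments are
    re-qualified against the length window. A missed frame ends the track
    (no gap closing). Tracks shorter than ``min_len`` frames or longer than
    ``max_len`` are dropped.
    """
    if len(table) == 0:
        return []
    frames = table["frame"].to_numpy(int)
    x = table["x_nm"].to_numpy(float)
    y = table["y_nm"].to_numpy(float)

    by_frame: dict[int, np.ndarray] = {}
    for f in np.unique(frames):
        by_frame[int(f)] = np.nonzero(frames == f)[0]

    next_of = np.full(len(table), -1, int)
    has_prev = np.zeros(len(table), bool)
    for f in sorted(by_frame):
        i0 = by_frame[f]
        i1 = by_frame.get(f + 1)
        if i1 is None:
            continue
        t0 = cKDTree(np.column_stack([x[i0], y[i0]]))
        t1 = cKDTree(np.column_stack([x[i1], y[i1]]))
        fwd = t0.query_ball_tree(t1, link_radius_nm)
        bwd = t1.query_ball_tree(t0, link_radius_nm)
        for a_local, cands in enumerate(fwd):
            if len(cands) != 1:
                continue
            b_local = cands[0]
            if len(bwd[b_local]) != 1:
                continue
            a, b = i0[a_local], i1[b_local]
            next_of[a] = b
            has_prev[b] = True

    trajs: list[Trajectory] = []
    for start in np.nonzero((next_of >= 0) & ~has_prev)[0]:
        chain = [start]
        cur = start
        while next_of[cur] >= 0:
            cur = next_of[cur]
            chain.append(cur)
        if min_len <= len(chain) <= max_len:
            idx = np.asarray(chain)
            trajs.append(Trajectory(frames[idx], x[idx], y[idx]))
    return trajs


def fit_trajectory_displacements(
    trajs: list[Trajectory],
    dt_ms: float,
    n_components: int = 1,
) -> FitResult:
    """MLE of the pooled step-size distribution across trajectories.

    ``dt_ms`` is the frame-to-frame time of the tracking acquisition
    (exposure plus camera dead time). Requires at least 200 pooled steps.
    """
    if n_components not in (1, 2, 3):
        raise ValueError("n_components must be 1, 2 or 3")
    steps = np.concatenate([t.steps_nm for t in trajs]) if trajs else np.empty(0)
    if steps.size < MIN_POOLED_STEPS:
        raise ValueError(
            f"refusing to fit {steps.size} pooled steps "
            f"(need >= {MIN_POOLED_STEPS}); pool more trajectories")
    return _fit_mixture(steps, dt_ms, np.inf, n_components, fix_b=0.0)
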