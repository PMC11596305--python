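"""Two-channel single-molecule co-tracking and diffusion analysis.

Starting from per-channel localization tables, tracks are linked by
greedy nearest-neighbor assignment, immobile emitters are removed by a
positional-spread filter, receptor dimerization is quantified as the
fraction of particles co-diffusing within a 100 nm radius for at least
10 frames, and diffusion constants come from a linear regression of the
pooled mean squared displacement over the first lags (D = slope / 4 in
two dimensions).  Group comparisons use the two-sample
Kolmogorov-Smirnov test, enumerated exactly for small samples.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .errors import InsufficientDataError

__all__ = [
    "Trajectory",
    "CoTrajectory",
    "CoTrackingResult",
    "DiffusionEstimate",
    "link_tracks",
    "filter_immobile",
    "cotrack",
    "msd_diffusion",
    "ks_two_sample",
]

#: Co-localization cutoff radius (um) — 100 nm.
DEFAULT_RADIUS = 0.1
#: Minimum number of co-diffusing frames for a dimer call.
DEFAULT_MIN_FRAMES = 10
#: Imaging frame interval (s) — 32 ms.
DEFAULT_FRAME_INTERVAL = 0.032


@dataclass(frozen=True)
class Trajectory:
    """Ordered localizations of one emitter in one channel."""

    track_id: int
    frames: np.ndarray
    xy: np.ndarray
    channel: str = "A"

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames, dtype=int)
        xy = np.asarray(self.xy, dtype=float)
        if frames.ndim != 1 or xy.shape != (frames.size, 2):
            raise ValueError("frames must be 1-D and xy of shape (n, 2)")
        if frames.size and np.any(np.diff(frames) <= 0):
            raise ValueError("frames must be strictly increasing")
        object.__setattr__(self, "frames", frames)
        object.__setattr__(self, "xy", xy)

    @property
    def lifetime(self) -> int:
        return int(self.frames.size)

    def positional_sd(self) -> float:
        """Total positional spread sqrt(var_x + var_y)."""
        return float(np.sqrt(self.xy.var(axis=0).sum()))


@dataclass(frozen=True)
class CoTrajectory:
    """A run of frames in which one A-track and one B-track co-diffuse."""

    track_a: int
    track_b: int
    frames: tuple[int, ...]

    @property
    def n_frames(self) -> int:
        return len(self.frames)


@dataclass(frozen=True)
class CoTrackingResult:
    co_trajectories: tuple[CoTrajectory, ...]
    fraction: float
    radius: float
    min_frames: int
    n_tracks_a: int
    n_tracks_b: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError("fraction must lie in [0, 1]")


@dataclass(frozen=True)
class DiffusionEstimate:
    """D (um^2/s) from MSD regression; intercept absorbs static noise."""

    d: float
    intercept: float
    n_lags: int
    n_trajectories: int


def link_tracks(
    localizations: pd.DataFrame,
    max_step: float,
    max_gap: int = 0,
    channel: str = "A",
) -> list[Trajectory]:
    """Greedy nearest-neighbor frame-to-frame linking.

    ``localizations`` needs columns ``frame, x_um, y_um``.  Active tracks
    claim the closest new localization within ``max_step`` um per elapsed
    frame (gaps up to ``max_gap`` frames are bridged); pairs are resolved
    globally by increasing distance.  Unlinkable localizations seed new
    tracks.
    """
    df = localizations.sort_values("frame", kind="stable")
    tracks: list[dict] = []  # {"frames": [...], "xy": [...]}
    active: list[int] = []
    for frame, group in df.groupby("frame", sort=True):
        frame = int(frame)
        pts = group[["x_um", "y_um"]].to_numpy(dtype=float)
        active = [
            i for i in active if frame - tracks[i]["frames"][-1] <= max_gap + 1
        ]
        candidates: list[tuple[float, int, int]] = []
        for i in active:
            last_xy = tracks[i]["xy"][-1]
            elapsed = frame - tracks[i]["frames"][-1]
            allowed = max_step * elapsed
            dist = np.linalg.norm(pts - last_xy, axis=1)
            for j in np.nonzero(dist <= allowed)[0]:
                candidates.append((float(dist[j]), i, int(j)))
        candidates.sort()
        taken_tracks: set[int] = set()
        taken_pts: set[int] = set()
        for dist, i, j in candidates:
            if i in taken_tracks or j in taken_pts:
                continue
            tracks[i]["frames"].append(frame)
            tracks[i]["xy"].append(pts[j])
            taken_tracks.add(i)
            taken_pts.add(j)
        for j in range(len(pts)):
            if j not in taken_pts:
                tracks.append({"frames": [frame], "xy": [pts[j]]})
                active.append(len(tracks) - 1)
    return [
        Trajectory(
            track_id=i,
            frames=np.array(t["frames"]),
            xy=np.array(t["xy"]),
            channel=channel,
        )
        for i, t in enumerate(tracks)
    ]


def filter_immobile(
    trajectories: Sequence[Trajectory],
    precision: float,
    sd_multiple: float = 2.0,
) -> list[Trajectory]:
    """Drop trajectories whose positional spread is noise-like.

    A trajectory is immobile when its total positional SD falls below
    ``sd_multiple`` times the localization precision.
    """
    threshold = sd_multiple * precision
    return [t for t in trajectories if t.positional_sd() >= threshold]


def _positions_by_frame(trajectories: Sequence[Trajectory]) -> dict[int, list[tuple[int, np.ndarray]]]:
    by_frame: dict[int, list[tuple[int, np.ndarray]]] = {}
    for t in trajectories:
        for f, xy in zip(t.frames, t.xy):
            by_frame.setdefault(int(f), []).append((t.track_id, xy))
    return by_frame


def cotrack(
    trajectories_a: Sequence[Trajectory],
    trajectories_b: Sequence[Trajectory],
    radius: float = DEFAULT_RADIUS,
    min_frames: int = DEFAULT_MIN_FRAMES,
) -> CoTrackingResult:
    """Frame-by-frame co-localization followed by co-trajectory calling.

    Within each frame, A-B localization pairs inside ``radius`` are
    matched greedily by increasing distance (one partner each).  Runs of
    consecutive frames in which the same A/B track pair stays matched
    for at least ``min_frames`` frames become co-trajectories.  The
    co-tracked fraction is the number of participating tracks over the
    total track count, averaged over the two channels.
    """
    n_a, n_b = len(trajectories_a), len(trajectories_b)
    if n_a == 0 or n_b == 0:
        return CoTrackingResult(
            co_trajectories=(), fraction=0.0, radius=radius,
            min_frames=min_frames, n_tracks_a=n_a, n_tracks_b=n_b,
        )
    by_frame_a = _positions_by_frame(trajectories_a)
    by_frame_b = _positions_by_frame(trajectories_b)

    paired_frames: dict[tuple[int, int], list[int]] = {}
    for frame in sorted(set(by_frame_a) & set(by_frame_b)):
        locs_a = by_frame_a[frame]
        locs_b = by_frame_b[frame]
        cand: list[tuple[float, int, int]] = []
        for ia, (ta, xa) in enumerate(locs_a):
            for ib, (tb, xb) in enumerate(locs_b):
                d = float(np.hypot(*(xa - xb)))
                if d <= radius:
                    cand.append((d, ia, ib))
        cand.sort()
        used_a: set[int] = set()
        used_b: set[int] = set()
        for d, ia, ib in cand:
            if ia in used_a or ib in used_b:
                continue
            used_a.add(ia)
            used_b.add(ib)
            key = (locs_a[ia][0], locs_b[ib][0])
            paired_frames.setdefault(key, []).append(frame)

    co_trajs: list[CoTrajectory] = []
    for (ta, tb), frames in paired_frames.items():
        run: list[int] = []
        for f in frames:
            if run and f != run[-1] + 1:
                if len(run) >= min_frames:
                    co_trajs.append(CoTrajectory(ta, tb, tuple(run)))
                run = []
            run.append(f)
        if len(run) >= min_frames:
            co_trajs.append(CoTrajectory(ta, tb, tuple(run)))

    co_a = {c.track_a for c in co_trajs}
    co_b = {c.track_b for c in co_trajs}
    fraction = (len(co_a) + len(co_b)) / (n_a + n_b)
    return CoTrackingResult(
        co_trajectories=tuple(co_trajs),
        fraction=float(fraction),
        radius=radius,
        min_frames=min_frames,
        n_tracks_a=n_a,
        n_tracks_b=n_b,
    )


def msd_diffusion(
    trajectories: Sequence[Trajectory],
    n_lags: int = 4,
    frame_interval: float = DEFAULT_FRAME_INTERVAL,
    min_lifetime: int = 11,
) -> DiffusionEstimate:
    """Diffusion constant from pooled MSD linear regression.

    Only trajectories with a lifetime strictly greater than 10 frames
    (i.e. >= ``min_lifetime`` localizations) qualify.  MSD is pooled
    over all qualifying trajectories at lags ``1..n_lags`` and regressed
    against lag time; ``D = slope / 4``.
    """
    qualifying = [t for t in trajectories if t.lifetime >= min_lifetime]
    if not qualifying:
        raise InsufficientDataError(
            f"no trajectory with >= {min_lifetime} localizations"
        )
    msd = np.zeros(n_lags)
    for lag in range(1, n_lags + 1):
        sq: list[float] = []
        for t in qualifying:
            # only displacements spanning exactly `lag` frames
            idx = {int(f): k for k, f in enumerate(t.frames)}
            for f, k in idx.items():
                k2 = idx.get(f + lag)
                if k2 is not None:
                    diff = t.xy[k2] - t.xy[k]
                    sq.append(float(diff @ diff))
        if not sq:
            raise InsufficientDataError(f"no displacement at lag {lag}")
        msd[lag - 1] = np.mean(sq)
    tau = frame_interval * np.arange(1, n_lags + 1)
    slope, intercept = np.polyfit(tau, msd, 1)
    return DiffusionEstimate(
        d=float(slope / 4.0),
        intercept=float(intercept),
        n_lags=n_lags,
        n_trajectories=len(qualifying),
    )


def _ks_statistic(a: np.ndarray, b: np.ndarray) -> float:
    pooled = np.concatenate([a, b])
    grid = np.unique(pooled)
    fa = np.searchsorted(np.sort(a), grid, side="right") / a.size
    fb = np.searchsorted(np.sort(b), grid, side="right") / b.size
    return float(np.max(np.abs(fa - fb)))


def ks_two_sample(
    sample_a: Sequence[float],
    sample_b: Sequence[float],
    exact_limit: int = 8,
    max_enumeration: int = 200_000,
) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test.

    Returns the sup-norm ECDF distance and a p-value: for
    ``min(n, m) <= exact_limit`` (and a tractable number of label
    assignments) the permutation-exact p-value is enumerated over all
    ways to label the pooled sample; otherwise the asymptotic
    approximation is used.
    """
    a = np.asarray(list(sample_a), dtype=float)
    b = np.asarray(list(sample_b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    d_obs = _ks_statistic(a, b)

    n, m = a.size, b.size
    if min(n, m) <= exact_limit and math.comb(n + m, n) <= max_enumeration:
        pooled = np.sort(np.concatenate([a, b]))
        total = 0
        hits = 0
        indices = range(n + m)
        for combo in itertools.combinations(indices, n):
            mask = np.zeros(n + m, dtype=bool)
            mask[list(combo)] = True
            d = _ks_statistic(pooled[mask], pooled[~mask])
            total += 1
            if d >= d_obs - 1e-12:
                hits += 1
        return d_obs, hits / total
    res = _stats.ks_2samp(a, b, method="asymp")
    return d_obs, float(res.pvalue)
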