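"""Growth-cone alignment, velocity-vs-distance profiles, and regressions.

A raw flow kymograph is expressed in lab-frame coordinates while the growth
cone advances, so velocity structure (P-domain retrograde flow, the T-zone,
axonal bulk flow) drifts across columns over time.  ``shear_align``
translates each row so the growth cone occupies a fixed column; velocities
are moved, never rescaled.  Column-wise averaging of the sheared map then
gives a velocity-vs-distance profile, which is zeroed at the T-zone — the
retrograde→anterograde transition — so profiles from different cells can be
averaged on a common axis.

Distance convention: 0 at the T-zone, positive toward the axon (proximal),
negative into the P-domain (distal).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage, stats

from .kymio import Kymograph


class DetectionError(RuntimeError):
    """Growth-cone detection failed (too many gap frames)."""


class AlignmentError(ValueError):
    """No retrograde-to-anterograde transition found in a profile."""


@dataclass
class GrowthConeTrack:
    position: np.ndarray      # per-frame column of the reference point
    velocity: float           # μm/h from the least-squares slope of the track

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        if self.position.ndim != 1:
            raise ValueError("track position must be one value per frame")


@dataclass
class VelocityProfile:
    distance: np.ndarray       # μm, strictly increasing
    mean_velocity: np.ndarray  # μm/h
    ci95: np.ndarray           # μm/h
    n: np.ndarray              # samples per bin
    aligned: bool = False      # True once the T-zone sits at distance 0

    def __post_init__(self):
        for name in ("distance", "mean_velocity", "ci95", "n"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if not np.all(np.diff(self.distance) > 0):
            raise ValueError("profile distances must be strictly increasing")
        if np.any(self.ci95 < 0):
            raise ValueError("ci95 must be non-negative")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "distance_um": self.distance,
                "mean_umh": self.mean_velocity,
                "ci95_umh": self.ci95,
                "n": self.n.astype(int),
            }
        )


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    slope_ci95: float
    intercept: float
    r_squared: float
    p_value: float
    n: int


# ---------------------------------------------------------------------------


def estimate_gc_track(
    kymo: Kymograph,
    method: str = "edge",
    trace: np.ndarray | None = None,
    median_size: int = 5,
) -> GrowthConeTrack:
    """Locate the growth cone in every frame.

    ``edge``: per frame, the most distal column whose intensity exceeds an
    Otsu threshold, median-filtered; frames with no supra-threshold pixel
    are interpolated (a detection error is raised if more than half the
    frames are gaps).  ``trace``: a supplied (frame, position) polyline is
    interpolated to every frame.  Velocity is the calibrated least-squares
    slope of position against time.
    """
    n_rows = kymo.shape[0]
    if method == "trace":
        if trace is None:
            raise ValueError("method='trace' needs a (frame, position) polyline")
        trace = np.asarray(trace, dtype=float)
        pos = np.interp(np.arange(n_rows), trace[:, 0], trace[:, 1])
    elif method == "edge":
        from skimage.filters import threshold_otsu

        thr = threshold_otsu(kymo.grid)
        above = kymo.grid > thr
        pos = np.full(n_rows, np.nan)
        for t in range(n_rows):
            cols = np.nonzero(above[t])[0]
            if cols.size:
                pos[t] = cols.max()
        gaps = np.isnan(pos)
        if gaps.mean() > 0.5:
            raise DetectionError(f"{gaps.sum()}/{n_rows} frames without signal")
        if gaps.any():
            ok = ~gaps
            pos = np.interp(np.arange(n_rows), np.nonzero(ok)[0], pos[ok])
        pos = ndimage.median_filter(pos, size=median_size, mode="nearest")
    else:
        raise ValueError("method must be 'edge' or 'trace'")
    slope_pf = np.polyfit(np.arange(n_rows), pos, 1)[0]
    return GrowthConeTrack(position=pos, velocity=slope_pf * kymo.pf_to_umh)


def shear_align(flow_umh: np.ndarray, track: GrowthConeTrack) -> np.ndarray:
    """Shear a velocity grid so the growth-cone column is constant over time.

    Row t is translated by −(position[t] − position[0]) with linear
    interpolation; pixels shifted in from outside the grid, or interpolated
    across an invalid (NaN) neighbour, are NaN.  Values are moved, never
    rescaled, so the multiset of finite velocities is preserved up to
    interpolation.
    """
    flow_umh = np.asarray(flow_umh, dtype=float)
    n_rows, n_cols = flow_umh.shape
    if len(track.position) != n_rows:
        raise ValueError("track must cover every row of the grid")
    out = np.full_like(flow_umh, np.nan)
    cols = np.arange(n_cols, dtype=float)
    for t in range(n_rows):
        src = cols + (track.position[t] - track.position[0])
        i0 = np.floor(src).astype(int)
        frac = src - i0
        ok = (i0 >= 0) & (i0 + 1 <= n_cols - 1)
        # integer shifts need no right neighbour
        exact = ok | ((frac == 0) & (i0 >= 0) & (i0 <= n_cols - 1))
        i0c = np.clip(i0, 0, n_cols - 1)
        i1c = np.clip(i0 + 1, 0, n_cols - 1)
        left = flow_umh[t, i0c]
        right = flow_umh[t, i1c]
        vals = np.where(frac == 0, left, left * (1 - frac) + right * frac)
        vals[~exact] = np.nan
        out[t] = vals
    return out


def mask_beyond_edge(
    sheared_umh: np.ndarray, track: GrowthConeTrack, margin_px: float = 0.0
) -> np.ndarray:
    """NaN out columns distal of the (sheared) growth-cone column.

    After shear alignment the growth cone sits at ``track.position[0]`` in
    every row; anything further distal is substrate background, not cell,
    and must not enter velocity profiles.
    """
    out = np.asarray(sheared_umh, dtype=float).copy()
    cutoff = int(np.ceil(track.position[0] + margin_px))
    if cutoff + 1 < out.shape[1]:
        out[:, cutoff + 1:] = np.nan
    return out


def profile_from_flow(sheared_umh: np.ndarray, kymo: Kymograph) -> VelocityProfile:
    """Column-wise mean velocity vs distance (μm), with per-column 95% CI.

    The distal edge of the grid is distance 0 and distance increases toward
    the axon (leftward in grid coordinates); the profile is unaligned until
    :func:`align_tzone` re-zeroes it at the T-zone.  Columns without a valid
    pixel are dropped.
    """
    px, _ = kymo.calibration
    grid = np.asarray(sheared_umh, dtype=float)
    finite = np.isfinite(grid)
    n = finite.sum(axis=0)
    filled = np.where(finite, grid, 0.0)
    nsafe = np.maximum(n, 1)
    mean = filled.sum(axis=0) / nsafe
    sd = np.sqrt((np.where(finite, (grid - mean) ** 2, 0.0)).sum(axis=0) / nsafe)
    keep = n >= 1
    cols = np.nonzero(keep)[0]
    dist = (grid.shape[1] - 1 - cols) * px
    order = np.argsort(dist)
    ci = 1.96 * sd[keep] / np.sqrt(n[keep])
    return VelocityProfile(
        distance=dist[order],
        mean_velocity=mean[keep][order],
        ci95=ci[order],
        n=n[keep][order],
        aligned=False,
    )


def find_tzone(profile: VelocityProfile, smooth_bins: int = 5) -> float:
    """Distance (μm) of the retrograde→anterograde transition.

    Candidate crossings are sign changes of the raw profile scanning from
    the distal end; a median filter over ``smooth_bins`` bins (robust to
    single outlier bins) is used only to disambiguate between several raw
    crossings — the raw crossing nearest the filtered one wins, ties toward
    the distal end.  The returned position is linearly interpolated between
    the raw bracketing bins; reported profile values are never smoothed.
    """
    v = profile.mean_velocity
    d = profile.distance
    neg_to_pos = np.nonzero((v[:-1] < 0) & (v[1:] >= 0))[0]
    if neg_to_pos.size == 0:
        raise AlignmentError("profile has no retrograde-to-anterograde transition")
    pick = neg_to_pos[0]
    if neg_to_pos.size > 1:
        vs = ndimage.median_filter(v, size=smooth_bins, mode="nearest")
        sm = np.nonzero((vs[:-1] < 0) & (vs[1:] >= 0))[0]
        if sm.size:
            target = sm[0]
            pick = neg_to_pos[np.argmin(np.abs(neg_to_pos - target))]
    i = pick
    frac = -v[i] / (v[i + 1] - v[i])
    return float(d[i] + frac * (d[i + 1] - d[i]))


def align_tzone(profile: VelocityProfile, on_missing: str = "raise") -> VelocityProfile:
    """Shift a profile's distance axis so the T-zone sits at 0.

    Bin spacing is untouched (pure translation).  Without a sign change the
    profile is either returned unaligned (``on_missing='flag'``) or an
    :class:`AlignmentError` is raised.
    """
    try:
        zero = find_tzone(profile)
    except AlignmentError:
        if on_missing == "flag":
            return replace(profile, aligned=False)
        raise
    return VelocityProfile(
        distance=profile.distance - zero,
        mean_velocity=profile.mean_velocity,
        ci95=profile.ci95,
        n=profile.n,
        aligned=True,
    )


def average_profiles(
    profiles: list[VelocityProfile], grid_step: float = 1.0
) -> VelocityProfile:
    """Across-cell mean profile on a shared distance grid.

    Profiles are linearly interpolated onto a ``grid_step``-μm grid spanning
    the intersection of their supports; the CI is the across-cell 95%
    interval and ``n`` counts cells per bin.
    """
    if len(profiles) < 2:
        raise ValueError("need at least 2 profiles to average")
    lo = max(p.distance[0] for p in profiles)
    hi = min(p.distance[-1] for p in profiles)
    if hi <= lo:
        raise ValueError("profiles have disjoint distance supports")
    grid = np.arange(np.ceil(lo / grid_step), np.floor(hi / grid_step) + 1) * grid_step
    if grid.size == 0:
        raise ValueError("no shared distance bins at this grid step")
    vals = np.vstack([np.interp(grid, p.distance, p.mean_velocity) for p in profiles])
    m = len(profiles)
    mean = vals.mean(axis=0)
    ci = 1.96 * vals.std(axis=0, ddof=0) / np.sqrt(m)
    return VelocityProfile(
        distance=grid,
        mean_velocity=mean,
        ci95=ci,
        n=np.full(grid.size, m),
        aligned=all(p.aligned for p in profiles),
    )


def linregress(x, y) -> RegressionResult:
    """Ordinary least squares with a t-based 95% CI on the slope."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("regression needs matched x, y with n >= 3")
    if np.ptp(x) == 0:
        raise ValueError("x has zero variance")
    n = x.size
    if np.ptp(y) == 0:
        # flat response: slope exactly 0, no explained variance
        return RegressionResult(
            slope=0.0, slope_ci95=0.0, intercept=float(y[0]),
            r_squared=0.0, p_value=1.0, n=n,
        )
    res = stats.linregress(x, y)
    tcrit = stats.t.ppf(0.975, n - 2)
    return RegressionResult(
        slope=float(res.slope),
        slope_ci95=float(tcrit * res.stderr),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue),
        n=n,
    )


def endpoint_velocity(trace: np.ndarray, pixel_size: float, frame_interval: float) -> float:
    """Endpoint-slope velocity (μm/h): net displacement over elapsed time.

    This is the classic measure used when motion is scored by connecting a
    feature's initial and final kymograph positions with a straight line.
    """
    trace = np.asarray(trace, dtype=float)
    dt = trace[-1, 0] - trace[0, 0]
    if dt <= 0:
        raise ValueError("trace must span at least one frame interval")
    slope_pf = (trace[-1, 1] - trace[0, 1]) / dt
    return slope_pf * pixel_size / frame_interval * 3600.0
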