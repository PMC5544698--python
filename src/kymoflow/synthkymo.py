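"""Synthetic ground-truth kymographs.

Two generators:

* the single-line rotation benchmark — one straight anti-aliased line per
  kymograph, swept from 0° (horizontal, infinitely fast) to −90° (vertical,
  stationary) in 1° steps, whose true velocity is cot|angle| in pixels/frame;
* a neurite scenario emulating fluorescent speckle microscopy of a growing
  axon: speckles advect with a bulk velocity field (slow anterograde flow
  along the axon, rapid retrograde flow in the growth-cone P-domain, a
  discontinuity at the T-zone that advances with the growth cone), with
  Poisson-generated fast transport events superimposed.

Angle convention: angles are measured from the distance (column) axis and are
negative for lines sloping down-right, i.e. anterograde motion at later
times.  −45° is 1 p/f; −1° is 57.3 p/f; −89° is 0.0175 p/f.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .kymio import Kymograph

DEFAULT_ANGLES = tuple(float(-a) for a in range(0, 91))  # 0° .. −90°, 91 entries


@dataclass(frozen=True)
class LineBenchmarkSpec:
    """Parameters of the rotated-line benchmark set."""

    angles: tuple[float, ...] = DEFAULT_ANGLES
    size: tuple[int, int] = (128, 128)
    line_width: float = 2.0
    intensity: float = 1.0
    noise_sd: float = 0.0
    bit_depth: int | None = 8  # quantize like an exported 8-bit raster; None = float
    seed: int = 0

    def __post_init__(self):
        if any(a < -90 or a > 0 for a in self.angles):
            raise ValueError("benchmark angles must lie in [-90, 0] degrees")
        if self.size[0] < 16 or self.size[1] < 16:
            raise ValueError("benchmark grid must be at least 16x16")


@dataclass
class NeuriteSimSpec:
    """Study conditions for the simulated growing neurite.

    Units: velocities in μm/h unless noted; event rates in events/min; fast
    speeds in μm/s; geometry in μm.  Defaults emulate a chick sensory neuron
    elongating at ~24 μm/h with P-domain retrograde flow near −97 μm/h and
    fast transport events at 0.1 ± 0.05 μm/s.
    """

    gc_velocity: float = 24.0
    axon_profile: Callable[[np.ndarray], np.ndarray] | None = None
    decay_length: float = 150.0  # μm; friction-like decay of bulk flow if no profile given
    retro_velocity: float = -97.0
    p_domain_width: float = 5.0
    fast_event_rate_antero: float = 0.5
    fast_event_rate_retro: float = 0.38
    fast_speed_mean: float = 0.1
    fast_speed_sd: float = 0.05
    speckle_density: float = 2.0  # speckles/μm
    noise_sd: float = 0.05
    duration: float = 25.0  # min; keeps a 24 μm/h growth cone inside the default field
    n_cols: int = 256
    pixel_size: float = 0.1   # μm
    frame_interval: float = 5.0  # s
    initial_edge_col: float | None = None
    seed: int = 0

    def __post_init__(self):
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.p_domain_width < 0:
            raise ValueError("p_domain_width must be >= 0")
        if min(self.fast_event_rate_antero, self.fast_event_rate_retro) < 0:
            raise ValueError("event rates must be >= 0")

    @property
    def n_rows(self) -> int:
        return int(round(self.duration * 60.0 / self.frame_interval))

    @property
    def umh_to_pf(self) -> float:
        """μm/h → pixels/frame."""
        return self.frame_interval / (3600.0 * self.pixel_size)

    def bulk_velocity(self, distance_um):
        """Bulk anterograde velocity (μm/h) at a distance (μm) behind the T-zone."""
        d = np.asarray(distance_um, dtype=float)
        if self.axon_profile is not None:
            return np.asarray(self.axon_profile(d), dtype=float)
        return self.gc_velocity * np.exp(-d / self.decay_length)


@dataclass
class GroundTruth:
    """True per-pixel flow (p/f, NaN where undefined), fast events, gc track."""

    flow: np.ndarray
    events: list = field(default_factory=list)
    gc_track: np.ndarray | None = None


@dataclass(frozen=True)
class FastEvent:
    direction: int          # +1 anterograde, −1 retrograde
    velocity: float         # μm/s, signed
    crossing_frame: float   # frame at which the path crosses the centre column


def angle_to_velocity(angle_deg: float) -> float:
    """True velocity (p/f) of a benchmark line: cot|angle|; −90° → 0, 0° → inf."""
    a = abs(angle_deg)
    if a == 0:
        return math.inf
    if a == 90:
        return 0.0
    return 1.0 / math.tan(math.radians(a))


def make_line_kymograph(
    angle: float, spec: LineBenchmarkSpec | None = None
) -> tuple[Kymograph, GroundTruth]:
    """One benchmark kymograph: an anti-aliased line through the grid centre.

    The ground-truth flow equals cot|angle| p/f on line-support pixels and is
    NaN elsewhere.
    """
    spec = spec or LineBenchmarkSpec()
    if angle < -90 or angle > 0:
        raise ValueError(f"angle {angle} outside [-90, 0] degrees")
    rows, cols = spec.size
    r = np.arange(rows, dtype=float)[:, None] - (rows - 1) / 2.0
    x = np.arange(cols, dtype=float)[None, :] - (cols - 1) / 2.0
    th = math.radians(angle)
    # line direction in (x, t): (cos th, −sin th); normal: (sin th, cos th)
    dist = np.abs(x * math.sin(th) + r * math.cos(th))
    grid = spec.intensity * np.clip(spec.line_width / 2.0 + 0.5 - dist, 0.0, 1.0)
    support = dist <= spec.line_width / 2.0 + 0.5
    if spec.noise_sd > 0:
        rng = np.random.default_rng(
            np.random.SeedSequence([spec.seed, int(round(abs(angle) * 1000))])
        )
        grid = grid + rng.normal(0.0, spec.noise_sd, grid.shape)
    if spec.bit_depth is not None:
        levels = 2**spec.bit_depth - 1
        peak = max(abs(spec.intensity), 1e-12)
        grid = np.round(np.clip(grid / peak, -1, 1) * levels) / levels * peak
    flow = np.full((rows, cols), np.nan)
    flow[support] = angle_to_velocity(angle)
    kymo = Kymograph(grid=grid, pixel_size=0.1, frame_interval=5.0)
    return kymo, GroundTruth(flow=flow)


def make_benchmark_set(
    spec: LineBenchmarkSpec | None = None,
) -> list[tuple[float, Kymograph, GroundTruth]]:
    """The full rotated-line set: one (angle, kymograph, truth) per spec angle."""
    spec = spec or LineBenchmarkSpec()
    return [(a, *make_line_kymograph(a, spec)) for a in spec.angles]


# ---------------------------------------------------------------------------
# neurite simulation


def _field_velocity_umh(x_px: np.ndarray, edge_px: float, spec: NeuriteSimSpec) -> np.ndarray:
    """Lab-frame bulk velocity (μm/h) at columns x_px given the leading edge."""
    tz_px = edge_px - spec.p_domain_width / spec.pixel_size
    v = np.zeros_like(np.asarray(x_px, dtype=float))
    in_p = (x_px > tz_px) & (x_px <= edge_px)
    in_axon = x_px <= tz_px
    v[in_p] = spec.retro_velocity
    d_um = (tz_px - np.asarray(x_px, dtype=float)) * spec.pixel_size
    v[in_axon] = spec.bulk_velocity(d_um[in_axon])
    return v


def simulate_neurite_kymograph(
    spec: NeuriteSimSpec | None = None,
) -> tuple[Kymograph, GroundTruth]:
    """Simulate an FSM kymograph of a growing neurite.

    Speckles are seeded at ``speckle_density`` and advected with the bulk
    field; material appearing at the advancing leading edge and entering at
    the proximal end is replenished so the density stays roughly stationary.
    Fast transport events are Poisson-generated per direction and rendered as
    brighter streaks that cross the paths of the slow speckles, passing
    through the centre column at a uniformly random frame.
    """
    spec = spec or NeuriteSimSpec()
    rng = np.random.default_rng(spec.seed)
    n_rows, n_cols = spec.n_rows, spec.n_cols
    dt_frames = 1.0
    v_gc_pf = spec.gc_velocity * spec.umh_to_pf
    e0 = spec.initial_edge_col
    if e0 is None:
        e0 = 0.55 * n_cols if spec.gc_velocity >= 0 else 0.8 * n_cols
    edge = e0 + v_gc_pf * np.arange(n_rows)

    dens_px = spec.speckle_density * spec.pixel_size  # speckles per pixel
    # initial speckles fill [0, e0]
    n0 = rng.poisson(dens_px * e0)
    pos = rng.uniform(0.0, e0, n0)
    amp = rng.uniform(0.5, 1.0, n0)

    grid = np.zeros((n_rows, n_cols))
    flow = np.full((n_rows, n_cols), np.nan)
    cols = np.arange(n_cols, dtype=float)
    sigma = 0.8
    offs = np.arange(-3, 4)

    def render(row, xs, amps, gain=1.0):
        keep = (xs > -3) & (xs < n_cols + 3)
        xs, amps = xs[keep], amps[keep]
        base = np.round(xs).astype(int)
        for o in offs:
            idx = base + o
            ok = (idx >= 0) & (idx < n_cols)
            w = np.exp(-((idx - xs) ** 2) / (2 * sigma**2))
            np.add.at(grid[row], idx[ok], gain * (amps * w)[ok])

    # --- fast events ------------------------------------------------------
    events: list[FastEvent] = []
    ev_paths = []  # (t0, x0, v_pf, amp)
    center = (n_cols - 1) / 2.0
    for direction, rate in ((+1, spec.fast_event_rate_antero), (-1, spec.fast_event_rate_retro)):
        n_ev = rng.poisson(rate * spec.duration)
        for _ in range(n_ev):
            s = -1.0
            while s <= 0:
                s = rng.normal(spec.fast_speed_mean, spec.fast_speed_sd)
            v_pf = direction * s * spec.frame_interval / spec.pixel_size
            t_cross = rng.uniform(0, n_rows - 1)
            events.append(FastEvent(direction, direction * s, t_cross))
            ev_paths.append((t_cross, center, v_pf, rng.uniform(1.0, 1.4)))

    spawn_edge = dens_px * max(v_gc_pf - spec.retro_velocity * spec.umh_to_pf, 0.0)
    spawn_prox = dens_px * max(float(spec.bulk_velocity(0.0)) * spec.umh_to_pf, 0.0)

    for t in range(n_rows):
        e_t = edge[t]
        # true bulk flow on occupied columns
        occ = cols <= e_t
        flow[t, occ] = _field_velocity_umh(cols[occ], e_t, spec) * spec.umh_to_pf
        render(t, pos, amp)
        for t0, x0, v_pf, a in ev_paths:
            x_t = x0 + v_pf * (t - t0)
            if 0 <= x_t <= e_t:
                render(t, np.array([x_t]), np.array([a]))
        # advect; P-domain speckles disassemble at the T-zone instead of
        # piling up behind it
        tz_t = e_t - spec.p_domain_width / spec.pixel_size
        in_p = pos > tz_t
        v = _field_velocity_umh(pos, e_t, spec) * spec.umh_to_pf
        pos = pos + v * dt_frames
        tz_next = edge[min(t + 1, n_rows - 1)] - spec.p_domain_width / spec.pixel_size
        absorbed = in_p & (pos <= tz_next)
        pos, amp = pos[~absorbed], amp[~absorbed]
        # respawn at leading edge and proximal end
        for lam, lo, hi in ((spawn_edge, max(edge[min(t + 1, n_rows - 1)] - 1.0, 0), edge[min(t + 1, n_rows - 1)]),
                            (spawn_prox, 0.0, 1.0)):
            k = rng.poisson(lam)
            if k:
                pos = np.concatenate([pos, rng.uniform(lo, hi, k)])
                amp = np.concatenate([amp, rng.uniform(0.5, 1.0, k)])
        keep = (pos >= 0) & (pos <= e_t + 1)
        pos, amp = pos[keep], amp[keep]

    if spec.noise_sd > 0:
        grid = grid + rng.normal(0.0, spec.noise_sd, grid.shape)

    kymo = Kymograph(grid=grid, pixel_size=spec.pixel_size, frame_interval=spec.frame_interval)
    return kymo, GroundTruth(flow=flow, events=events, gc_track=edge)


def event_traces(truth: GroundTruth, spec: NeuriteSimSpec):
    """TraceSet of straight polylines, one per fast event (for flux counting)."""
    from .kymio import TraceSet

    n_rows, n_cols = spec.n_rows, spec.n_cols
    center = (n_cols - 1) / 2.0
    traces = []
    for ev in truth.events:
        v_pf = ev.velocity * spec.frame_interval / spec.pixel_size
        # extend from the crossing point until leaving the grid
        ts = []
        for x_target in (0.0, n_cols - 1.0):
            ts.append(ev.crossing_frame + (x_target - center) / v_pf)
        t0, t1 = sorted(ts)
        t0 = max(t0, 0.0)
        t1 = min(t1, n_rows - 1.0)
        if t1 - t0 < 1.0:
            continue
        x0 = center + v_pf * (t0 - ev.crossing_frame)
        x1 = center + v_pf * (t1 - ev.crossing_frame)
        traces.append(np.array([[t0, x0], [t1, x1]]))
    return TraceSet(traces, label="fast events")
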