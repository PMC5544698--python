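"""Fast-speckle velocities, directional flux, and the microtubule mass budget.

Fast transport is scored from hand-traced speckle paths: a trace whose
least-squares velocity exceeds a motor-scale threshold (default 0.05 μm/s,
the lower edge of the microtubule-motor range) counts toward the flux of
the direction it moves in, once, if it crosses the kymograph's reference
column.  The mass budget converts directional fluxes (MT/min) into the
length of polymer delivered per hour and, divided by the number of
microtubules in an axonal cross-section, into the equivalent rate of axon
growth that rapid transport alone could sustain.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .kymio import TraceSet

FAST_THRESHOLD_UMS = 0.05  # μm/s; motor-driven transport is ~0.05–5 μm/s


@dataclass(frozen=True)
class SpeckleEvent:
    velocity: float        # μm/s, signed (positive anterograde)
    crosses_center: bool
    trace_id: int


@dataclass(frozen=True)
class FluxBudget:
    """Microtubule transport mass budget.

    All fields are stored unrounded; :meth:`rounded` renders them at the
    conventional table precision (fluxes 2 d.p., MT/h 1 d.p., lengths to
    the μm when ≥ 10, growth 1 d.p.).
    """

    antero_flux: float            # MT/min
    retro_flux: float             # MT/min
    net_flux: float               # MT/min
    net_flux_h: float             # MT/h
    mt_length: float              # μm
    mt_per_cross_section: float
    transported_length: float     # μm of MT polymer per hour
    net_axonal_growth: float      # μm/h
    mean_interval: float          # min between net anterograde MTs (inf if net <= 0)

    def rounded(self) -> dict:
        tl = self.transported_length
        return {
            "antero_flux_mt_min": round(self.antero_flux, 2),
            "retro_flux_mt_min": round(self.retro_flux, 2),
            "net_flux_mt_min": round(self.net_flux, 2),
            "net_flux_mt_h": round(self.net_flux_h, 1),
            "mt_length_um": round(self.mt_length, 2),
            "transported_um_h": round(tl) if abs(tl) >= 10 else round(tl, 1),
            "mt_per_cross_section": self.mt_per_cross_section,
            "net_axonal_growth_um_h": round(self.net_axonal_growth, 1),
            "mean_interval_min": round(self.mean_interval, 1)
            if math.isfinite(self.mean_interval)
            else None,
        }


def speckle_velocity(trace: np.ndarray, pixel_size: float, frame_interval: float) -> float:
    """Signed speckle velocity in μm/s from the least-squares slope of a trace."""
    trace = np.asarray(trace, dtype=float)
    if trace.shape[0] < 2 or trace[-1, 0] == trace[0, 0]:
        raise ValueError("trace must span at least 2 distinct frames")
    slope_pf = np.polyfit(trace[:, 0], trace[:, 1], 1)[0]
    return slope_pf * pixel_size / frame_interval


def classify_fast(velocity_ums: float, threshold: float = FAST_THRESHOLD_UMS) -> bool:
    """True if |v| reaches the motor-transport threshold (inclusive)."""
    return abs(velocity_ums) >= threshold


def _crosses(trace: np.ndarray, center_col: float) -> bool:
    p = np.asarray(trace, dtype=float)[:, 1] - center_col
    return bool(np.any(p[:-1] * p[1:] <= 0) and (p.min() <= 0 <= p.max()))


def count_flux(
    traces: TraceSet,
    center_col: float,
    duration_min: float,
    pixel_size: float,
    frame_interval: float,
    threshold: float = FAST_THRESHOLD_UMS,
) -> tuple[float, float]:
    """Directional fast-speckle flux (MT/min) past the centre column.

    Each trace counts at most once regardless of how often it re-crosses
    the column; direction follows the sign of its least-squares velocity.
    """
    if duration_min <= 0:
        raise ValueError("duration_min must be positive")
    antero = retro = 0
    for tr in traces:
        if not _crosses(tr, center_col):
            continue
        v = speckle_velocity(tr, pixel_size, frame_interval)
        if not classify_fast(v, threshold):
            continue
        if v > 0:
            antero += 1
        else:
            retro += 1
    return antero / duration_min, retro / duration_min


def classify_events(
    traces: TraceSet,
    center_col: float,
    pixel_size: float,
    frame_interval: float,
    threshold: float = FAST_THRESHOLD_UMS,
) -> list[SpeckleEvent]:
    """Per-trace velocity/crossing classification (fast traces only)."""
    out = []
    for i, tr in enumerate(traces):
        v = speckle_velocity(tr, pixel_size, frame_interval)
        if classify_fast(v, threshold):
            out.append(SpeckleEvent(velocity=v, crosses_center=_crosses(tr, center_col), trace_id=i))
    return out


def mass_budget(
    antero_flux: float,
    retro_flux: float,
    mt_length: float,
    mt_per_cross_section: float,
) -> FluxBudget:
    """Fill the transport mass budget from directional fluxes.

    net = antero − retro (MT/min); per hour × 60; transported polymer
    length = net/h × mean MT length; net axonal growth = transported length
    ÷ MTs per cross-section; mean interval between net anterograde MTs =
    1/net (min), infinite when net ≤ 0.
    """
    if mt_length <= 0 or mt_per_cross_section <= 0:
        raise ValueError("mt_length and mt_per_cross_section must be positive")
    net = antero_flux - retro_flux
    net_h = 60.0 * net
    transported = net_h * mt_length
    growth = transported / mt_per_cross_section
    interval = 1.0 / net if net > 0 else math.inf
    return FluxBudget(
        antero_flux=antero_flux,
        retro_flux=retro_flux,
        net_flux=net,
        net_flux_h=net_h,
        mt_length=mt_length,
        mt_per_cross_section=mt_per_cross_section,
        transported_length=transported,
        net_axonal_growth=growth,
        mean_interval=interval,
    )


def net_flux_from_rate_fraction(event_interval_min: float, antero_fraction: float) -> float:
    """Net flux (MT/min) from a mean inter-event interval and the anterograde share.

    With one event every ``event_interval_min`` minutes of which a fraction
    f moves anterogradely, net flux = (2f − 1) / interval.
    """
    if event_interval_min <= 0:
        raise ValueError("event_interval_min must be positive")
    if not 0.0 <= antero_fraction <= 1.0:
        raise ValueError("antero_fraction must lie in [0, 1]")
    return (2.0 * antero_fraction - 1.0) / event_interval_min
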