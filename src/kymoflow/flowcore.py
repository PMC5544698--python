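"""Optical flow on kymographs.

On a kymograph, motion is one-dimensional: a feature translating at v
pixels/frame draws a streak of slope v (columns per row).  ``lk_flow``
estimates v per pixel from the brightness-constancy equation
``I_x v + I_t = 0`` solved by least squares over a local window — the
classic Lucas–Kanade scheme restricted to one spatial dimension.  Gradient
methods of this kind are only trustworthy for sub-pixel displacements.

``kymoflow`` extends the reliable range by exploiting a geometric fact: when
the time and distance axes of a kymograph are swapped, a streak of slope v
becomes a streak of slope 1/v, so fast motion (e.g. 10 p/f) turns into slow
motion (0.1 p/f) that the same estimator measures well.  The estimator is
run on the original and the axis-swapped kymograph, the swapped branch is
back-transformed (v ← 1/v, coordinates mapped back), and the two branches
are merged per pixel: the unrotated estimate where motion is sub-pixel, the
rotated one where it is fast, and their average in a hysteresis band around
the 1 p/f symmetry point.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .kymio import CalibrationError, Kymograph


@dataclass(frozen=True)
class FlowParams:
    """Estimator parameters.

    window
        side of the square least-squares neighbourhood, pixels (odd, ≥ 3).
    smoothing_sigma
        Gaussian pre-smoothing applied before differentiation, pixels.
    rotations
        rotation branches in degrees; must contain 0, and 90 whenever more
        than one branch is combined.  Only multiples of 90° are accepted
        here (the lossless axis swap); arbitrary-angle grids can be made
        with :func:`rotate_kymo` but are not merged.
    switch_threshold
        |v| (p/f) above which the combined map prefers the rotated branch.
    hysteresis
        relative half-width of the band around the threshold in which both
        branches are averaged.
    min_gradient
        absolute floor on windowed spatial-gradient energy below which a
        pixel is invalid.
    rel_gradient
        relative validity floor as a fraction of the image's maximum
        windowed gradient energy; rejects noise-only background.
    max_velocity
        |v| (p/f) beyond which an estimate is marked invalid instead of
        reported; a kymograph cannot resolve motion much faster than its
        own width per frame, and near-reciprocal blow-ups would otherwise
        poison column means.
    derivative_order
        accuracy order of the central-difference derivative stencil (2 or
        4).  The 4th-order stencil largely removes the orientation-dependent
        discretization bias of plain central differences.
    """

    window: int = 9
    smoothing_sigma: float = 2.5
    derivative_order: int = 4
    rotations: tuple[float, ...] = (0.0, 90.0)
    switch_threshold: float = 1.0
    hysteresis: float = 0.2
    min_gradient: float = 1e-6
    rel_gradient: float = 5e-3
    max_velocity: float = 100.0

    def __post_init__(self):
        if self.window < 3 or self.window % 2 == 0:
            raise ValueError("window must be odd and >= 3")
        if self.switch_threshold <= 0:
            raise ValueError("switch_threshold must be positive")
        if len(self.rotations) > 1 and not any(r % 360 == 90 for r in self.rotations):
            raise ValueError("rotation set must include 90 when combining branches")
        if self.derivative_order not in (2, 4):
            raise ValueError("derivative_order must be 2 or 4")


@dataclass
class FlowMap:
    """Per-pixel signed velocity in p/f (positive = anterograde) with validity mask."""

    velocity: np.ndarray
    valid: np.ndarray
    window: int
    source: str = "baseline"

    def __post_init__(self):
        if self.velocity.shape != self.valid.shape:
            raise ValueError("velocity and valid mask must share a shape")

    @property
    def shape(self):
        return self.velocity.shape

    def masked(self) -> np.ndarray:
        """Velocity with invalid pixels set to NaN."""
        out = self.velocity.copy()
        out[~self.valid] = np.nan
        return out


_EPS_BACKTRANSFORM = 1e-6  # |v_rot| below this is invalid rather than ~1/0


def _anti_transpose(a: np.ndarray) -> np.ndarray:
    """The lossless 90° axis swap: transpose with both axes reversed.

    An involution that maps a streak of slope v to slope 1/v with the sign
    preserved.
    """
    return a.T[::-1, ::-1]


def rotate_kymo(kymo: Kymograph, degrees: float) -> Kymograph:
    """Rotate a kymograph's time/distance axes.

    Odd multiples of 90° use the exact axis swap (no interpolation); 180°
    reverses both axes; other angles fall back to bicubic resampling.  The
    returned kymograph records its cumulative rotation.
    """
    from dataclasses import replace

    deg = degrees % 360
    if deg == 0:
        grid = kymo.grid.copy()
    elif deg in (90, 270):
        grid = _anti_transpose(kymo.grid)
    elif deg == 180:
        grid = kymo.grid[::-1, ::-1].copy()
    else:
        from skimage.transform import rotate as _sk_rotate

        grid = _sk_rotate(kymo.grid, angle=degrees, resize=True, order=3, mode="constant")
    return replace(kymo, grid=grid, rotation=(kymo.rotation + degrees) % 360)


def lk_flow(kymo: Kymograph | np.ndarray, params: FlowParams | None = None) -> FlowMap:
    """One-dimensional Lucas–Kanade flow on a kymograph.

    Solves ``v = −Σ w I_x I_t / Σ w I_x²`` over a ``window``-sized
    neighbourhood of Gaussian-smoothed central-difference derivatives.
    Pixels with insufficient spatial-gradient energy, or within the
    border margin where derivatives are unreliable, are invalid.
    """
    params = params or FlowParams()
    grid = kymo.grid if isinstance(kymo, Kymograph) else np.asarray(kymo, dtype=float)
    if min(grid.shape) < params.window:
        raise ValueError(f"kymograph {grid.shape} smaller than window {params.window}")
    sm = ndimage.gaussian_filter(grid, params.smoothing_sigma, mode="nearest")
    if params.derivative_order == 4:
        kern = np.array([1.0, -8.0, 0.0, 8.0, -1.0]) / 12.0
        it = ndimage.correlate1d(sm, kern, axis=0, mode="nearest")
        ix = ndimage.correlate1d(sm, kern, axis=1, mode="nearest")
    else:
        it, ix = np.gradient(sm)
    sxx = ndimage.uniform_filter(ix * ix, params.window, mode="nearest")
    sxt = ndimage.uniform_filter(ix * it, params.window, mode="nearest")
    floor = max(params.min_gradient, params.rel_gradient * float(sxx.max()))
    valid = sxx > floor
    margin = params.window // 2 + int(math.ceil(2 * params.smoothing_sigma)) + 1
    if margin > 0 and min(grid.shape) > 2 * margin:
        border = np.zeros_like(valid)
        border[margin:-margin, margin:-margin] = True
        valid &= border
    with np.errstate(divide="ignore", invalid="ignore"):
        v = np.where(valid, -sxt / np.where(sxx > 0, sxx, 1.0), 0.0)
    valid &= np.isfinite(v) & (np.abs(v) <= params.max_velocity)
    return FlowMap(velocity=v, valid=valid, window=params.window, source="baseline")


def kymoflow(kymo: Kymograph, params: FlowParams | None = None) -> FlowMap:
    """Rotation-augmented flow: merge unrotated and axis-swapped estimates.

    Per pixel the combined map takes the unrotated estimate where
    |v| < switch_threshold, the back-transformed rotated estimate where it
    is larger, and the average of both inside the hysteresis band; validity
    is the union of the contributing branches.
    """
    params = params or FlowParams()
    for r in params.rotations:
        if r % 90 != 0:
            raise NotImplementedError(
                "kymoflow combines only multiples of 90 deg; use rotate_kymo for other angles"
            )
    base = lk_flow(kymo, params)
    if all(r % 360 == 0 for r in params.rotations):
        return base

    rot = lk_flow(rotate_kymo(kymo, 90), params)
    with np.errstate(divide="ignore"):
        v_bt = np.where(np.abs(rot.velocity) > _EPS_BACKTRANSFORM, 1.0 / rot.velocity, np.nan)
    ok_bt = rot.valid & np.isfinite(v_bt)
    # the axis swap is an involution: applying it again maps back
    v_rot = _anti_transpose(np.where(ok_bt, v_bt, 0.0))
    ok_rot = _anti_transpose(ok_bt)

    lo = params.switch_threshold * (1.0 - params.hysteresis)
    hi = params.switch_threshold * (1.0 + params.hysteresis)
    vb, okb = base.velocity, base.valid
    both = okb & ok_rot
    v = np.zeros_like(vb)
    # a lone branch is trusted only inside its own reliable half-range:
    # sub-threshold motion for the unrotated branch, supra-threshold for the
    # back-transformed rotated branch
    only_b = okb & ~ok_rot & (np.abs(vb) <= hi)
    only_r = ok_rot & ~okb & (np.abs(v_rot) >= lo)
    v[only_b] = vb[only_b]
    v[only_r] = v_rot[only_r]
    slow = both & (np.abs(vb) < lo)
    fast = both & (np.abs(vb) > hi)
    band = both & ~slow & ~fast
    v[slow] = vb[slow]
    v[fast] = v_rot[fast]
    v[band] = 0.5 * (vb[band] + v_rot[band])
    valid = (only_b | only_r | both) & (np.abs(v) <= params.max_velocity)
    return FlowMap(velocity=v, valid=valid, window=params.window, source="combined")


def calibrate_flow(flow: FlowMap, kymo: Kymograph) -> np.ndarray:
    """Convert a p/f flow map to μm/h (NaN where invalid).

    v[μm/h] = v[p/f] × pixel_size[μm] / frame_interval[s] × 3600.
    """
    if kymo.pixel_size is None or kymo.frame_interval is None:
        raise CalibrationError("flow calibration requires pixel_size and frame_interval")
    out = flow.velocity * kymo.pf_to_umh
    out[~flow.valid] = np.nan
    return out
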