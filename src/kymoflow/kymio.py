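"""Movie, kymograph and trace I/O.

A kymograph is a space-time image: rows are frames (time increases downward)
and columns are positions along a sampling line, with distance increasing
toward the growth cone so that anterograde motion has positive slope
(pixels per frame, "p/f").  All readers normalise to this convention; the
``flip_x`` / ``flip_t`` flags handle source images recorded the other way.

Calibration (``pixel_size`` in μm/px, ``frame_interval`` in s/frame) is never
defaulted silently: explicit arguments win over TIFF/ImageJ metadata, and a
kymograph without calibration refuses to produce physical units.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile
from scipy import ndimage
from skimage.draw import line_aa
from skimage.morphology import skeletonize


class FormatError(ValueError):
    """Input file or array does not have the expected structure."""


class CalibrationError(ValueError):
    """Physical units requested but pixel size / frame interval unknown."""


@dataclass(frozen=True)
class ImageStack:
    """An ordered time-lapse: ``frames`` has shape (n_frames, height, width)."""

    frames: np.ndarray
    frame_interval: float | None = None  # seconds per frame
    pixel_size: float | None = None      # μm per pixel

    def __post_init__(self):
        frames = np.asarray(self.frames, dtype=float)
        if frames.ndim != 3:
            raise FormatError(f"expected (t, y, x) stack, got shape {frames.shape}")
        object.__setattr__(self, "frames", frames)
        for name in ("frame_interval", "pixel_size"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be positive, got {v}")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


@dataclass(frozen=True)
class Kymograph:
    """Space-time image; rows = frames, columns = distance (anterograde = +x)."""

    grid: np.ndarray
    frame_interval: float | None = None
    pixel_size: float | None = None
    origin_label: str = "distal"
    rotation: float = 0.0  # degrees by which the grid has been rotated

    def __post_init__(self):
        grid = np.asarray(self.grid, dtype=float)
        if grid.ndim != 2 or grid.shape[0] < 2 or grid.shape[1] < 2:
            raise FormatError(f"kymograph grid must be 2-D and at least 2x2, got {grid.shape}")
        object.__setattr__(self, "grid", grid)
        for name in ("frame_interval", "pixel_size"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be positive, got {v}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape

    @property
    def calibration(self) -> tuple[float, float]:
        """(pixel_size μm, frame_interval s); raises if either is missing."""
        if self.pixel_size is None or self.frame_interval is None:
            raise CalibrationError(
                "kymograph has no calibration; supply pixel_size (μm) and frame_interval (s)"
            )
        return self.pixel_size, self.frame_interval

    @property
    def pf_to_umh(self) -> float:
        """Factor converting pixels/frame to μm/h."""
        px, dt = self.calibration
        return px / dt * 3600.0

    def with_calibration(self, pixel_size: float, frame_interval: float) -> "Kymograph":
        return replace(self, pixel_size=pixel_size, frame_interval=frame_interval)


@dataclass
class TraceSet:
    """Hand-drawn motion traces as polylines in (frame, position) coordinates.

    Each trace is an (n, 2) float array of (frame_index, position) vertices
    with strictly increasing frame indices.
    """

    traces: list[np.ndarray] = field(default_factory=list)
    label: str = ""

    def __post_init__(self):
        clean = []
        for tr in self.traces:
            tr = np.asarray(tr, dtype=float)
            if tr.ndim != 2 or tr.shape[1] != 2 or tr.shape[0] < 2:
                raise FormatError("each trace needs >= 2 (frame, position) vertices")
            if not np.all(np.diff(tr[:, 0]) > 0):
                raise FormatError("trace frame indices must be strictly increasing")
            clean.append(tr)
        self.traces = clean

    def __len__(self) -> int:
        return len(self.traces)

    def __iter__(self):
        return iter(self.traces)


# ---------------------------------------------------------------------------
# calibration plumbing


def load_calibration(path: str | Path) -> dict:
    """Read a JSON sidecar with pixel_size_um and frame_interval_s."""
    with open(path) as fh:
        cfg = json.load(fh)
    out = {}
    if "pixel_size_um" in cfg:
        out["pixel_size"] = float(cfg["pixel_size_um"])
    if "frame_interval_s" in cfg:
        out["frame_interval"] = float(cfg["frame_interval_s"])
    return out


def _calibration_from_tiff(tif: tifffile.TiffFile) -> dict:
    out: dict[str, float] = {}
    meta = tif.imagej_metadata or {}
    if meta.get("finterval"):
        out["frame_interval"] = float(meta["finterval"])
    page = tif.pages[0]
    res = page.tags.get("XResolution")
    unit = page.tags.get("ResolutionUnit")
    if res is not None:
        num, den = res.value
        if num:
            px = den / num  # units per pixel
            # ImageJ writes resolution in its own 'unit'; honour μm only
            if meta.get("unit") in ("um", "micron", "µm"):
                out["pixel_size"] = px
            elif unit is not None and getattr(unit.value, "name", "") == "NONE":
                pass
    return out


# ---------------------------------------------------------------------------
# readers / writers


def read_movie(
    path: str | Path,
    pixel_size: float | None = None,
    frame_interval: float | None = None,
) -> ImageStack:
    """Read a multi-page TIFF time-lapse into an :class:`ImageStack`.

    Explicit calibration arguments take precedence over TIFF/ImageJ tags.
    """
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tif:
            frames = tif.asarray()
            tags = _calibration_from_tiff(tif)
    except (OSError, tifffile.TiffFileError, IndexError, ValueError) as exc:
        raise OSError(f"cannot read TIFF movie {path}: {exc}") from exc
    if frames.ndim == 2:
        frames = frames[None]
    if frames.ndim != 3:
        raise FormatError(f"{path}: expected a single-channel multi-page TIFF, got shape {frames.shape}")
    return ImageStack(
        frames=frames.astype(float),
        pixel_size=pixel_size if pixel_size is not None else tags.get("pixel_size"),
        frame_interval=frame_interval if frame_interval is not None else tags.get("frame_interval"),
    )


def write_movie(path: str | Path, stack: ImageStack) -> None:
    tifffile.imwrite(path, stack.frames.astype(np.float32))


def read_kymograph(
    path: str | Path,
    pixel_size: float | None = None,
    frame_interval: float | None = None,
    flip_x: bool = False,
    flip_t: bool = False,
) -> Kymograph:
    """Read a single-page TIFF (or first page) as a kymograph.

    ``flip_x`` / ``flip_t`` normalise source images whose distance or time
    axis runs opposite to the internal convention.
    """
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tif:
            grid = tif.pages[0].asarray()
            tags = _calibration_from_tiff(tif)
    except (OSError, tifffile.TiffFileError, IndexError, ValueError) as exc:
        raise OSError(f"cannot read TIFF kymograph {path}: {exc}") from exc
    if grid.ndim != 2:
        raise FormatError(f"{path}: kymograph page must be 2-D, got shape {grid.shape}")
    grid = grid.astype(float)
    if flip_x:
        grid = grid[:, ::-1]
    if flip_t:
        grid = grid[::-1, :]
    return Kymograph(
        grid=grid,
        pixel_size=pixel_size if pixel_size is not None else tags.get("pixel_size"),
        frame_interval=frame_interval if frame_interval is not None else tags.get("frame_interval"),
    )


def write_kymograph(path: str | Path, kymo: Kymograph) -> None:
    meta = {}
    if kymo.frame_interval is not None:
        meta["finterval"] = kymo.frame_interval
    if kymo.pixel_size is not None:
        meta["unit"] = "um"
    res = None
    if kymo.pixel_size is not None:
        res = (1.0 / kymo.pixel_size, 1.0 / kymo.pixel_size)
    tifffile.imwrite(
        path,
        kymo.grid.astype(np.float32),
        imagej=True,
        resolution=res,
        metadata=meta or None,
    )


# ---------------------------------------------------------------------------
# kymograph construction


def _sample_roi(roi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Resample a polyline at 1-px arc-length steps; return points and unit normals."""
    roi = np.asarray(roi, dtype=float)
    if roi.ndim != 2 or roi.shape[1] != 2 or roi.shape[0] < 2:
        raise ValueError("roi must be an (n >= 2, 2) array of (x, y) points")
    seg = np.diff(roi, axis=0)
    seglen = np.hypot(seg[:, 0], seg[:, 1])
    if np.any(seglen == 0):
        roi = roi[np.concatenate(([True], seglen > 0))]
        seg = np.diff(roi, axis=0)
        seglen = np.hypot(seg[:, 0], seg[:, 1])
    arclen = np.concatenate(([0.0], np.cumsum(seglen)))
    s = np.arange(0.0, arclen[-1] + 1e-9, 1.0)
    x = np.interp(s, arclen, roi[:, 0])
    y = np.interp(s, arclen, roi[:, 1])
    pts = np.column_stack([x, y])
    # tangent by central differences, normal is its 90° rotation
    tang = np.gradient(pts, axis=0)
    norm = np.column_stack([-tang[:, 1], tang[:, 0]])
    norm /= np.maximum(np.hypot(norm[:, 0], norm[:, 1]), 1e-12)[:, None]
    return pts, norm


def build_kymograph(
    stack: ImageStack,
    roi: Sequence[Sequence[float]],
    width: int = 1,
    projection: str = "max",
) -> Kymograph:
    """Reslice a movie along a polyline and z-project across its width.

    One row per frame; one column per 1-px arc-length step along ``roi``;
    each pixel is the max (or mean) of ``width`` samples taken perpendicular
    to the line at that arc position.
    """
    if width < 1:
        raise ValueError("width must be >= 1")
    if projection not in ("max", "mean"):
        raise ValueError("projection must be 'max' or 'mean'")
    pts, normals = _sample_roi(np.asarray(roi, dtype=float))
    h, w = stack.frames.shape[1:]
    if (pts[:, 0].min() < -0.5 or pts[:, 0].max() > w - 0.5
            or pts[:, 1].min() < -0.5 or pts[:, 1].max() > h - 0.5):
        raise ValueError("roi lies outside frame bounds")
    offsets = np.arange(width, dtype=float) - (width - 1) / 2.0
    # sample coordinates: (n_cols, width) each for x and y
    xs = pts[:, 0][:, None] + offsets[None, :] * normals[:, 0][:, None]
    ys = pts[:, 1][:, None] + offsets[None, :] * normals[:, 1][:, None]
    coords = np.stack([ys.ravel(), xs.ravel()])  # map_coordinates wants (row, col)
    rows = []
    for frame in stack.frames:
        samp = ndimage.map_coordinates(frame, coords, order=1, mode="nearest")
        samp = samp.reshape(len(pts), width)
        rows.append(samp.max(axis=1) if projection == "max" else samp.mean(axis=1))
    return Kymograph(
        grid=np.asarray(rows),
        frame_interval=stack.frame_interval,
        pixel_size=stack.pixel_size,
    )


# ---------------------------------------------------------------------------
# traces


def read_trace_image(path_or_array, kymo: Kymograph) -> TraceSet:
    """Convert a drawn trace layer (image of thin curves) into polylines.

    Any nonzero pixel is foreground.  Each connected component is
    skeletonized and reduced to one polyline ordered by frame (row) index,
    taking the mean column where the skeleton occupies several pixels in a
    row.  Components spanning fewer than 2 rows are dropped.
    """
    if isinstance(path_or_array, (str, Path)):
        img = tifffile.imread(path_or_array)
    else:
        img = np.asarray(path_or_array)
    if img.shape != kymo.shape:
        raise FormatError(
            f"trace image shape {img.shape} does not match kymograph {kymo.shape}"
        )
    fg = img != 0
    if not fg.any():
        return TraceSet([])
    skel = skeletonize(fg)
    labels, n = ndimage.label(skel, structure=np.ones((3, 3), dtype=int))
    traces = []
    for lab in range(1, n + 1):
        rr, cc = np.nonzero(labels == lab)
        order = np.argsort(rr)
        rr, cc = rr[order], cc[order]
        frames = np.unique(rr)
        if len(frames) < 2:
            continue
        pos = ndimage.mean(cc.astype(float), labels=rr, index=frames)
        traces.append(np.column_stack([frames.astype(float), pos]))
    return TraceSet(traces)


def traces_to_flow_input(traces: TraceSet, kymo_shape: tuple[int, int]) -> np.ndarray:
    """Rasterize traces onto a grid with anti-aliased 1-px strokes (max-composited)."""
    h, w = kymo_shape
    out = np.zeros((h, w), dtype=float)
    for tr in traces:
        if tr[:, 0].max() > h - 1 + 1e-9 or tr[:, 1].min() < -1e-9 or tr[:, 1].max() > w - 1 + 1e-9:
            raise ValueError("trace vertex outside kymograph bounds")
        for (f0, p0), (f1, p1) in zip(tr[:-1], tr[1:]):
            rr, cc, val = line_aa(int(round(f0)), int(round(p0)), int(round(f1)), int(round(p1)))
            keep = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
            np.maximum.at(out, (rr[keep], cc[keep]), val[keep])
    return out


def read_traces_csv(path: str | Path) -> TraceSet:
    """Read traces from CSV with columns trace_id, frame, position."""
    import pandas as pd

    df = pd.read_csv(path)
    required = {"trace_id", "frame", "position"}
    if not required.issubset(df.columns):
        raise FormatError(f"trace CSV needs columns {sorted(required)}")
    traces = []
    for _, grp in df.groupby("trace_id", sort=True):
        grp = grp.sort_values("frame")
        traces.append(grp[["frame", "position"]].to_numpy(dtype=float))
    return TraceSet(traces)


def write_traces_csv(path: str | Path, traces: TraceSet) -> None:
    import pandas as pd

    rows = []
    for i, tr in enumerate(traces):
        for f, p in tr:
            rows.append((i, f, p))
    pd.DataFrame(rows, columns=["trace_id", "frame", "position"]).to_csv(path, index=False)
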