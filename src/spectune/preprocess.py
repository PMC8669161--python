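"""Pre-processing: detrend/resample, IPL detection, per-pixel quality maps,
ROI placement, z-scoring and quality filtering.

The quality index (QI) of a T x R response matrix C (time x stimulus
repetitions) is Var_t[mean_r C] / mean_r[Var_t C]: 0 for random traces,
1 when all repetitions are identical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal

__all__ = [
    "ROIRecord",
    "ROISegment",
    "QualityMap",
    "NoIPLError",
    "compute_qi",
    "detrend_and_resample",
    "detect_ipl",
    "qi_image",
    "place_rois",
    "zscore_trace",
    "filter_rois",
    "extract_roi_records",
]

DEFAULT_QI_MIN = 0.4


class NoIPLError(RuntimeError):
    """No pixels passed the IPL amplitude threshold."""


@dataclass
class ROIRecord:
    """One terminal: trial-resolved trace plus quality and position metadata."""

    id: int
    trace_repeats: np.ndarray            # (T, R)
    trace_mean: np.ndarray               # (T,)
    qi: float
    ipl_depth: float = float("nan")
    region: str = "AZ"
    scan_id: str = "sim"
    fish_id: str = "sim"
    pixel_coords: np.ndarray | None = None
    area_um2: float | None = None
    plane: int = 0


@dataclass
class ROISegment:
    """A filled, disjoint pixel set from ROI placement (single plane)."""

    pixel_coords: np.ndarray             # (n_px, 2) row, col
    area_um2: float

    @property
    def center(self) -> np.ndarray:
        return self.pixel_coords.mean(axis=0)


@dataclass
class QualityMap:
    """Per-pixel QI image(s); values in [0, 1]."""

    qi: np.ndarray                       # (ny, nx) or (ny, nx, n_planes)
    pixel_size_um: float = 1.0


def compute_qi(C: np.ndarray) -> float:
    """Quality index of a T x R response matrix.

    Raises ``ValueError`` when every repetition is constant (0/0).
    """
    C = np.asarray(C, float)
    if C.ndim != 2 or C.shape[1] < 2:
        raise ValueError("C must be T x R with R >= 2")
    if not np.all(np.isfinite(C)):
        raise ValueError("C must be finite")
    within = C.var(axis=0).mean()
    if within == 0.0:
        raise ValueError("undefined QI: all repetitions are constant")
    return float(C.mean(axis=1).var() / within)


def detrend_and_resample(
    trace: np.ndarray, native_rate_hz: float, target_rate_hz: float = 42.0
) -> np.ndarray:
    """Remove the best-fit line, then linearly interpolate to the target rate.

    Output length is ``ceil(duration * target_rate)`` with the edge value held
    beyond the last native sample.
    """
    trace = np.asarray(trace, float)
    if trace.ndim != 1 or len(trace) < 2:
        raise ValueError("trace must be 1-D with at least 2 samples")
    if native_rate_hz <= 0 or target_rate_hz <= 0:
        raise ValueError("rates must be positive")
    detrended = signal.detrend(trace, type="linear")
    duration = len(trace) / native_rate_hz
    n_out = math.ceil(duration * target_rate_hz)
    t_in = np.arange(len(trace)) / native_rate_hz
    t_out = np.arange(n_out) / target_rate_hz
    return np.interp(t_out, t_in, detrended)


def detect_ipl(
    stack: np.ndarray,
    smooth_px: float = 3.0,
    threshold_frac: float = 0.35,
    smoother: str = "gaussian",
):
    """Detect the IPL band from the time-SD image of each plane.

    The SD image is smoothed (Gaussian sigma derived from a 3 px kernel, or a
    3 px median filter with ``smoother='median'``) and thresholded at
    ``min + threshold_frac * (max - min)`` per image. Returns ``(mask,
    borders)`` where ``borders[p]`` is an ``(outer, inner)`` pair of per-column
    row coordinates (NaN where the column is empty); the outer border is the
    low-row side, taken as the INL-adjacent edge (depth 0).
    """
    stack = np.asarray(stack, float)
    if stack.ndim == 3:
        stack = stack[..., None]
    if stack.shape[0] < 2:
        raise ValueError("stack needs >= 2 time points")
    n_planes = stack.shape[3]
    mask = np.zeros(stack.shape[1:], bool)
    borders = []
    for p in range(n_planes):
        sd = stack[:, :, :, p].std(axis=0)
        if smoother == "median":
            sm = ndimage.median_filter(sd, size=int(round(smooth_px)))
        else:
            sm = ndimage.gaussian_filter(sd, sigma=smooth_px / 2.0)
        lo, hi = sm.min(), sm.max()
        m = sm > lo + threshold_frac * (hi - lo)
        mask[:, :, p] = m
        ny, nx = m.shape
        outer = np.full(nx, np.nan)
        inner = np.full(nx, np.nan)
        for c in range(nx):
            rows = np.flatnonzero(m[:, c])
            if rows.size:
                outer[c], inner[c] = rows[0], rows[-1]
        borders.append((outer, inner))
    if not mask.any():
        raise NoIPLError("no pixels passed the IPL amplitude threshold")
    return mask, borders


def qi_image(
    stack: np.ndarray,
    n_repeats: int,
    n_baseline_frames: int = 0,
    pixel_size_um: float = 1.0,
) -> QualityMap:
    """Per-pixel QI after folding the (baseline-stripped) time axis into
    stimulus repetitions; fractional-repeat remainders are truncated."""
    stack = np.asarray(stack, float)
    if n_repeats < 2:
        raise ValueError("need >= 2 repetitions")
    sub = stack[n_baseline_frames:]
    t_rep = sub.shape[0] // n_repeats
    if t_rep < 2:
        raise ValueError("too few frames per repetition")
    folded = sub[: t_rep * n_repeats].reshape((n_repeats, t_rep) + sub.shape[1:])
    # per-pixel QI, vectorized: repeats axis 0, time axis 1
    within = folded.var(axis=1).mean(axis=0)
    between = folded.mean(axis=0).var(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        qi = np.where(within > 0, between / np.where(within > 0, within, 1.0), 0.0)
    return QualityMap(qi=np.clip(qi, 0.0, 1.0), pixel_size_um=pixel_size_um)


def place_rois(
    qmap: QualityMap | np.ndarray,
    pixel_size_um: float | None = None,
    block_size: int = 5,
    shrink_distance_px: float = 1.0,
    min_area_px: int = 3,
    min_distance_px: int = 3,
) -> list[ROISegment]:
    """Segment terminal-sized ROIs from a 2-D QI image.

    Adaptive (local-mean, ``block_size`` px) threshold, hole filling, a
    distance-transform shrink to cores, then watershed expansion back to the
    thresholded mask; components smaller than ``min_area_px`` are dropped.
    """
    from skimage.feature import peak_local_max
    from skimage.filters import threshold_local
    from skimage.measure import label
    from skimage.segmentation import watershed

    if isinstance(qmap, QualityMap):
        img = np.asarray(qmap.qi, float)
        pixel_size_um = qmap.pixel_size_um if pixel_size_um is None else pixel_size_um
    else:
        img = np.asarray(qmap, float)
        pixel_size_um = 1.0 if pixel_size_um is None else pixel_size_um
    if img.ndim != 2:
        raise ValueError("place_rois operates on a single 2-D plane")
    if not np.all(np.isfinite(img)):
        raise ValueError("QI map must be finite")
    if img.max() <= 0:
        return []

    local = threshold_local(img, block_size=block_size, method="mean")
    mask = img > local
    mask = ndimage.binary_fill_holes(mask)
    dist = ndimage.distance_transform_edt(mask)
    cores = dist > shrink_distance_px
    if not cores.any():
        return []
    peaks = peak_local_max(
        dist, min_distance=min_distance_px, labels=label(cores), exclude_border=False
    )
    markers = np.zeros_like(img, dtype=int)
    for i, (r, c) in enumerate(peaks, start=1):
        markers[r, c] = i
    labels = watershed(-dist, markers, mask=mask)

    rois = []
    for lab in range(1, labels.max() + 1):
        coords = np.argwhere(labels == lab)
        if len(coords) < min_area_px:
            continue
        rois.append(
            ROISegment(pixel_coords=coords, area_um2=len(coords) * pixel_size_um**2)
        )
    return rois


def zscore_trace(trace: np.ndarray, n_baseline: int) -> np.ndarray:
    """Z-score a trace by the mean/SD of its first ``n_baseline`` samples
    (the pre-stimulus window)."""
    trace = np.asarray(trace, float)
    if not 2 <= n_baseline <= len(trace):
        raise ValueError("baseline window must contain >= 2 samples")
    base = trace[:n_baseline]
    sd = base.std()
    if sd == 0.0:
        raise ValueError("zero baseline SD")
    return (trace - base.mean()) / sd


def filter_rois(rois: list[ROIRecord], qi_min: float = DEFAULT_QI_MIN) -> list[ROIRecord]:
    """Keep ROIs with QI >= qi_min (strictly smaller values are excluded)."""
    return [r for r in rois if np.isfinite(r.qi) and r.qi >= qi_min]


def extract_roi_records(
    stack: np.ndarray,
    rois: list[ROISegment],
    *,
    plane: int,
    frame_rate_hz: float,
    n_repeats: int,
    n_baseline_frames: int,
    resample_rate_hz: float = 42.0,
    ipl_borders=None,
    scan_id: str = "sim",
    fish_id: str = "sim",
    id_offset: int = 0,
) -> list[ROIRecord]:
    """Turn segmented ROIs on one plane of a stack into quality-scored,
    z-scored, trial-resolved records.

    Per ROI: average the pixel time courses, detrend and resample to the
    analysis rate, z-score against the pre-stimulus baseline, fold the
    stimulus window into repetitions and compute the QI. IPL depth is the
    ROI center-of-mass position between the detected borders.
    """
    stack = np.asarray(stack, float)
    if stack.ndim == 3:
        stack = stack[..., None]
    records = []
    for j, roi in enumerate(rois):
        rr, cc = roi.pixel_coords[:, 0], roi.pixel_coords[:, 1]
        raw = stack[:, rr, cc, plane].mean(axis=1)
        trace = detrend_and_resample(raw, frame_rate_hz, resample_rate_hz)
        nb = int(round(n_baseline_frames / frame_rate_hz * resample_rate_hz))
        try:
            trace = zscore_trace(trace, max(nb, 2))
        except ValueError:
            pass  # flat baseline: keep detrended trace
        stim = trace[nb:]
        t_rep = len(stim) // n_repeats
        reps = stim[: t_rep * n_repeats].reshape(n_repeats, t_rep).T
        try:
            qi = compute_qi(reps)
        except ValueError:
            qi = 0.0
        depth = float("nan")
        if ipl_borders is not None:
            outer, inner = ipl_borders[plane]
            r0, c0 = roi.center
            col = int(round(np.clip(c0, 0, len(outer) - 1)))
            if np.isfinite(outer[col]) and inner[col] > outer[col]:
                depth = float(
                    np.clip((r0 - outer[col]) / (inner[col] - outer[col]), 0.0, 1.0)
                )
        records.append(
            ROIRecord(
                id=id_offset + j,
                trace_repeats=reps,
                trace_mean=reps.mean(axis=1),
                qi=qi,
                ipl_depth=depth,
                region="AZ",
                scan_id=scan_id,
                fish_id=fish_id,
                pixel_coords=roi.pixel_coords,
                area_um2=roi.area_um2,
                plane=plane,
            )
        )
    return records
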