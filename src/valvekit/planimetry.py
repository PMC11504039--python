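"""Geometric orifice area (GOA) by planimetry of peak-systole video frames.

The measurement chain mirrors standard bench practice: pick the frame nearest
the flow peak, enhance it (CLAHE + Gaussian blur), segment the bright open
orifice inside a region of interest (threshold seed refined by an edge-based
morphological active contour), and convert the mask pixel count to cm² using
the pixel calibration. Calibration can be recovered from the visible valve
holder rim (26 mm base diameter) by a Hough circle fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import binary_fill_holes
from skimage import exposure, feature, filters, measure, segmentation, transform

from .errors import CalibrationError, DataError, SegmentationError
from .hydrodynamics import PressureFlowWaveform

__all__ = [
    "OrificeFrame",
    "GOAResult",
    "select_peak_frame",
    "preprocess_frame",
    "segment_orifice",
    "compute_goa",
    "calibrate_from_holder",
    "measure_goa",
    "HOLDER_DIAMETER_MM",
]

HOLDER_DIAMETER_MM = 26.0


@dataclass
class OrificeFrame:
    """Calibrated grayscale frame: 8-bit pixels, mm/px scale, timestamp (s)."""

    pixels: np.ndarray
    mm_per_px: float
    timestamp: float = 0.0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise DataError("frame must be a nonempty 2-D grayscale image")
        if self.mm_per_px <= 0:
            raise DataError("mm_per_px must be positive")


@dataclass
class GOAResult:
    area: float  # cm²
    contour: np.ndarray  # (L, 2) row/col polygon
    mask: np.ndarray  # bool


def select_peak_frame(frames: list, w: PressureFlowWaveform) -> int:
    """Index of the frame nearest in time to the flow peak (ties -> earlier)."""
    if not frames:
        raise DataError("empty frame list")
    t_peak = float(w.time[int(np.argmax(w.q))])
    stamps = np.array([f.timestamp for f in frames], dtype=float)
    return int(np.argmin(np.abs(stamps - t_peak)))


def preprocess_frame(
    frame: OrificeFrame,
    clahe_clip: float = 0.01,
    clahe_tiles: int = 8,
    blur_sigma: float = 1.5,
) -> np.ndarray:
    """CLAHE-equalize then Gaussian-blur; returns an 8-bit image of same shape."""
    img = frame.pixels.astype(float) / 255.0
    if np.ptp(img) > 0:
        kernel = max(frame.pixels.shape[0] // clahe_tiles, 1)
        img = exposure.equalize_adapthist(img, kernel_size=kernel, clip_limit=clahe_clip)
    img = filters.gaussian(img, sigma=blur_sigma)
    return np.clip(np.rint(img * 255.0), 0, 255).astype(np.uint8)


def _largest_component(mask: np.ndarray) -> np.ndarray:
    labels = measure.label(mask)
    if labels.max() == 0:
        raise SegmentationError("empty segmentation")
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    return labels == int(np.argmax(counts))


def segment_orifice(
    enhanced: np.ndarray,
    roi_hint: tuple | None = None,
    n_iter: int = 30,
    smoothing: int = 1,
) -> np.ndarray:
    """Segment the bright orifice; returns a single-component boolean mask.

    ``roi_hint`` is an inclusive (row0, col0, row1, col1) rectangle prior; the
    default is the central 80% of the frame. An Otsu threshold inside the ROI
    seeds the mask, which an edge-based (geodesic) morphological active
    contour then refines.
    """
    img = np.asarray(enhanced, dtype=float)
    h, wd = img.shape
    if roi_hint is None:
        roi_hint = (int(0.1 * h), int(0.1 * wd), int(0.9 * h), int(0.9 * wd))
    r0, c0, r1, c1 = roi_hint
    if not (0 <= r0 < r1 <= h and 0 <= c0 < c1 <= wd):
        raise DataError("roi_hint must be a rectangle inside the image")
    roi = img[r0:r1, c0:c1]
    if np.ptp(roi) < 1.0:
        raise SegmentationError("region of interest has no contrast")
    thr = filters.threshold_otsu(roi)
    seed = np.zeros(img.shape, dtype=bool)
    seed[r0:r1, c0:c1] = roi > thr
    if not seed.any():
        raise SegmentationError("no foreground above threshold in ROI")
    seed = binary_fill_holes(_largest_component(seed))

    if n_iter > 0:
        gimage = segmentation.inverse_gaussian_gradient(img / 255.0)
        refined = segmentation.morphological_geodesic_active_contour(
            gimage,
            num_iter=n_iter,
            init_level_set=seed,
            smoothing=smoothing,
            balloon=0,
        ).astype(bool)
        if refined.any():
            seed = binary_fill_holes(_largest_component(refined))
    if not seed.any():
        raise SegmentationError("active contour collapsed to empty mask")
    return seed


def compute_goa(mask: np.ndarray, mm_per_px: float) -> GOAResult:
    """Planimetric area of a binary mask: count × (mm/px)² / 100 cm²."""
    mask = np.asarray(mask, dtype=bool)
    count = int(mask.sum())
    if count == 0:
        raise DataError("empty mask; no orifice area")
    area = count * mm_per_px**2 / 100.0
    contours = measure.find_contours(mask.astype(float), 0.5)
    contour = max(contours, key=len) if contours else np.empty((0, 2))
    return GOAResult(area=area, contour=contour, mask=mask)


def calibrate_from_holder(
    frame: OrificeFrame,
    holder_diameter_mm: float = HOLDER_DIAMETER_MM,
    accumulator_threshold: float = 0.35,
) -> float:
    """mm/px from the bright holder rim: Hough-circle fit + sub-pixel refine.

    The rim is taken as the outermost strong circle (the orifice itself can be
    near-circular but always lies inside the holder); its radius is refined to
    sub-pixel precision as the brightness-weighted mean radius of the bright
    band around the Hough estimate.
    """
    img = frame.pixels.astype(float) / 255.0
    edges = feature.canny(img, sigma=1.5)
    max_r = min(img.shape) // 2
    radii = np.arange(max(8, max_r // 3), max_r, 1)
    accum = transform.hough_circle(edges, radii)
    accums, cxs, cys, rads = transform.hough_circle_peaks(accum, radii, num_peaks=8)
    strong = [i for i in range(len(rads)) if accums[i] >= accumulator_threshold]
    if not strong:
        raise CalibrationError("no holder rim circle detected")
    i = max(strong, key=lambda j: rads[j])
    cx, cy, r0 = float(cxs[i]), float(cys[i]), float(rads[i])
    yy, xx = np.mgrid[0 : img.shape[0], 0 : img.shape[1]]
    rr = np.hypot(yy - cy, xx - cx)
    band = (rr > r0 - 6.0) & (rr < r0 + 6.0)
    weights = np.clip(img[band] - 0.5, 0.0, None)  # rim pixels only
    if weights.sum() <= 0:
        raise CalibrationError("holder rim band is not bright enough to refine")
    r_rim = float(np.sum(weights * rr[band]) / weights.sum())
    return holder_diameter_mm / (2.0 * r_rim)


def measure_goa(
    frame: OrificeFrame,
    roi_hint: tuple | None = None,
    auto_calibrate: bool = False,
    **preprocess_kwargs,
) -> GOAResult:
    """End-to-end single-frame pipeline: preprocess, segment, measure."""
    mm_per_px = calibrate_from_holder(frame) if auto_calibrate else frame.mm_per_px
    enhanced = preprocess_frame(frame, **preprocess_kwargs)
    mask = segment_orifice(enhanced, roi_hint=roi_hint)
    return compute_goa(mask, mm_per_px)
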