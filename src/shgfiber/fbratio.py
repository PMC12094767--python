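"""Censored forward/backward (FB) SHG ratio maps and fiber-segment statistics.

The FB ratio compares transmitted (forward) and reflected (backward) SHG
signal per pixel; it reports on fibril packing within a collagen bundle.  The
map is stored on an 8-bit axis with explicit censoring: value 0 means no
measurable ratio (zero forward signal or a ratio rounding to zero) and 255
means saturation (zero backward signal, or a ratio off the top of the axis).
Only values strictly between 0 and 255 are "measured".

The map is restricted to detected fibers, each fiber contour becomes a
region of interest (ROI), and per-sample distributions of per-segment mean
ratios are summarised by mean / median / SD / IQR plus the pixel-censoring
counts N_measured / N_zeros / N_255 / total N.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .morphometrics import (
    AveragedImage,
    FiberMask,
    MaskParams,
    _path_length,
    contrast_saturate,
    detect_ridges,
    skeleton_paths,
)

__all__ = [
    "CENSOR_EXCLUDED",
    "CENSOR_MEASURED",
    "CENSOR_ZERO",
    "CENSOR_SATURATED",
    "FBRatioMap",
    "FiberSegmentMeasure",
    "FBDistributionSummary",
    "compute_fb_map",
    "mask_fb",
    "extract_segments",
    "measure_segments",
    "summarize_sample",
]

# per-pixel censor codes
CENSOR_EXCLUDED = 0  # off-fiber, not counted at all
CENSOR_MEASURED = 1
CENSOR_ZERO = 2
CENSOR_SATURATED = 3

# calibration constant of the detection bench (mean FB of a balanced
# beamsplitter measured over 100 frames); optional correction, default off
BENCH_FB_CALIBRATION = 1.079


@dataclass
class FBRatioMap:
    """8-bit FB ratio map with per-pixel censor flags."""

    values: np.ndarray  # uint8
    censor: np.ndarray  # uint8 censor codes

    def __post_init__(self) -> None:
        if self.values.shape != self.censor.shape:
            raise ValueError("values and censor shapes differ")

    def censor_counts(self) -> tuple[int, int, int]:
        """(n_measured, n_zeros, n_255) over non-excluded pixels."""
        return (
            int(np.sum(self.censor == CENSOR_MEASURED)),
            int(np.sum(self.censor == CENSOR_ZERO)),
            int(np.sum(self.censor == CENSOR_SATURATED)),
        )


@dataclass
class FiberSegmentMeasure:
    """ROI statistics of one detected fiber contour."""

    segment_id: int
    area: int  # ROI pixel count
    mean: float  # mean FB value over measured pixels (NaN if none)
    stddev: float  # sample SD over measured pixels
    contour_length: float  # polyline length, px


@dataclass
class FBDistributionSummary:
    """Per-sample summary of the distribution of per-segment mean FB ratios."""

    mean: float
    median: float
    stddev: float
    iqr: float
    n_measured: int
    n_zeros: int
    n_255: int

    @property
    def total_n(self) -> int:
        return self.n_measured + self.n_zeros + self.n_255

    def as_row(self) -> dict[str, float]:
        return {
            "fb_mean": self.mean,
            "fb_median": self.median,
            "fb_stddev": self.stddev,
            "fb_iqr": self.iqr,
            "n_measured": self.n_measured,
            "n_zeros": self.n_zeros,
            "n_255": self.n_255,
            "total_n": self.total_n,
        }


def compute_fb_map(
    forward_avg: AveragedImage,
    backward_avg: AveragedImage,
    scale: float = 1.0,
    apply_bench_calibration: bool = False,
) -> FBRatioMap:
    """Per-pixel censored forward/backward ratio on an 8-bit axis.

    ``r = forward / backward`` where backward > 0; the stored value is
    ``round(scale * r)`` clipped to [0, 255].  Zero forward signal stores 0;
    positive forward over zero backward stores 255.  Censor flags follow the
    stored value: 0 -> zero-censored, 255 -> saturated, else measured.
    ``apply_bench_calibration`` divides ratios by the bench constant 1.079.
    """
    f = forward_avg.pixels
    b = backward_avg.pixels
    if f.shape != b.shape:
        raise ValueError("channel shapes differ")
    if scale <= 0:
        raise ValueError("scale must be positive")
    eff_scale = scale / BENCH_FB_CALIBRATION if apply_bench_calibration else scale
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(b > 0, f / np.where(b > 0, b, 1.0), np.inf)
    values = np.clip(np.round(eff_scale * r), 0, 255)
    values[f == 0] = 0
    values[(b == 0) & (f > 0)] = 255
    values = values.astype(np.uint8)
    censor = np.full(values.shape, CENSOR_MEASURED, dtype=np.uint8)
    censor[values == 0] = CENSOR_ZERO
    censor[values == 255] = CENSOR_SATURATED
    return FBRatioMap(values, censor)


def mask_fb(fb: FBRatioMap, fiber_mask: FiberMask) -> FBRatioMap:
    """Restrict the map to fiber pixels; off-mask pixels leave all counts."""
    if fb.values.shape != fiber_mask.mask.shape:
        raise ValueError("map and mask shapes differ")
    on = fiber_mask.mask
    values = np.where(on, fb.values, 0).astype(np.uint8)
    censor = np.where(on, fb.censor, CENSOR_EXCLUDED).astype(np.uint8)
    return FBRatioMap(values, censor)


def extract_segments(
    masked_fb: FBRatioMap, params: MaskParams | None = None
) -> list[np.ndarray]:
    """Detect individual fiber contours on the masked FB map.

    The same ridge operator used for mask generation runs on the masked map
    (contrast-stretched first; hysteresis thresholds relaxed because the
    background is exactly zero), and each branch-free centerline path becomes
    one ordered (row, col) contour.  Contours shorter than
    ``min_branch_length`` are discarded.
    """
    params = params or MaskParams()
    img = AveragedImage(masked_fb.values.astype(float))
    if not np.any(masked_fb.values):
        return []
    stretched = contrast_saturate(img, 0.0)
    seg_params = MaskParams(
        contrast_saturation=params.contrast_saturation,
        line_width=params.line_width,
        min_branch_length=params.min_branch_length,
        max_display_hdm=params.max_display_hdm,
        min_gap_diameter=params.min_gap_diameter,
        curvature_window=params.curvature_window,
        ridge_low=2.0,
        ridge_high=5.0,
    )
    fm = detect_ridges(stretched, seg_params)
    paths = skeleton_paths(fm.skeleton)
    return [p for p in paths if _path_length(p) >= params.min_branch_length]


def _dilate_contour(
    contour: np.ndarray, radius: int, shape: tuple[int, int]
) -> tuple[np.ndarray, np.ndarray]:
    """ROI pixel coordinates of a contour dilated by ``radius`` (Chebyshev disk)."""
    rr, cc = contour[:, 0], contour[:, 1]
    r0 = max(int(rr.min()) - radius, 0)
    r1 = min(int(rr.max()) + radius + 1, shape[0])
    c0 = max(int(cc.min()) - radius, 0)
    c1 = min(int(cc.max()) + radius + 1, shape[1])
    roi = np.zeros((r1 - r0, c1 - c0), dtype=bool)
    roi[rr - r0, cc - c0] = True
    if radius > 0:
        from scipy.ndimage import distance_transform_edt

        roi = distance_transform_edt(~roi) <= radius
    out_r, out_c = np.nonzero(roi)
    return out_r + r0, out_c + c0


def measure_segments(
    contours: Sequence[np.ndarray],
    fb: FBRatioMap,
    dilation_px: int | None = None,
    line_width: float = 15.0,
) -> list[FiberSegmentMeasure]:
    """ROI statistics per contour.

    Each contour is dilated by ``dilation_px`` (default: half the line width)
    to an ROI; mean and sample SD (n-1) are computed over measured pixels
    only.  An ROI with no measured pixel gets NaN statistics but keeps its
    area and censored pixels counted.
    """
    if dilation_px is None:
        dilation_px = int(round(line_width / 2))
    out = []
    for i, contour in enumerate(contours):
        rr, cc = _dilate_contour(contour, dilation_px, fb.values.shape)
        vals = fb.values[rr, cc]
        cens = fb.censor[rr, cc]
        measured = vals[cens == CENSOR_MEASURED].astype(float)
        if measured.size:
            mean = float(measured.mean())
            sd = float(measured.std(ddof=1)) if measured.size > 1 else 0.0
        else:
            mean, sd = float("nan"), float("nan")
        out.append(
            FiberSegmentMeasure(
                segment_id=i,
                area=int(len(vals)),
                mean=mean,
                stddev=sd,
                contour_length=_path_length(contour),
            )
        )
    return out


def summarize_sample(
    measures: Iterable[FiberSegmentMeasure],
    fb_maps: Iterable[FBRatioMap] = (),
) -> FBDistributionSummary:
    """Distribution summary of per-segment means plus pixel censor counts.

    The four distribution statistics run over segments with a measured mean
    (NaN if none); censor counts accumulate over all the sample's masked
    maps.  IQR uses linear interpolation between order statistics.
    """
    means = np.array([m.mean for m in measures], dtype=float)
    means = means[np.isfinite(means)]
    if means.size:
        q1, q3 = np.percentile(means, [25, 75])
        stats = (
            float(means.mean()),
            float(np.median(means)),
            float(means.std(ddof=1)) if means.size > 1 else 0.0,
            float(q3 - q1),
        )
    else:
        stats = (float("nan"),) * 4
    n_meas = n_zero = n_sat = 0
    for fb in fb_maps:
        m, z, s = fb.censor_counts()
        n_meas += m
        n_zero += z
        n_sat += s
    return FBDistributionSummary(*stats, n_meas, n_zero, n_sat)
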