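"""Scratch-assay (wound-healing) quantification.

The wound is the large smooth vertical band inside an otherwise textured
cell lawn.  A local-variance map separates the two: lawn pixels have high
variance in any small window, wound pixels almost none.  The largest
low-variance component spanning most of the image height is the wound;
its mean width is its area divided by its vertical extent.  Closure at
24 h is expressed as a percentage of the 1-h width and then normalised so
that the scrambled control is 1.0 per experiment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu

__all__ = [
    "ScratchParams",
    "WoundMeasurement",
    "ScratchRecord",
    "detect_wound",
    "closure_and_normalize",
]


@dataclass
class ScratchParams:
    """Wound-detector knobs.

    ``window_px`` is the side of the square local-variance window;
    ``min_height_frac`` is the fraction of image height a candidate wound
    component must span; ``max_width_frac`` rejects components as wide as
    the image itself (blank/degenerate inputs).  ``contrast_ratio_max``
    requires the low-variance class to be genuinely smooth relative to
    the lawn (mean low/high variance ratio); a fully textured image has a
    unimodal variance map whose automatic split fails this test, which is
    how complete closure is recognised.  ``edge_correction`` adds back the
    ``window_px - 1`` columns lost where the sliding window starts to
    overlap the lawn on either side of the wound.  ``horizontal=True``
    rotates the analysis for horizontal scratches.
    """

    window_px: int = 15
    min_height_frac: float = 0.8
    max_width_frac: float = 0.95
    contrast_ratio_max: float = 0.2
    edge_correction: bool = True
    horizontal: bool = False

    def __post_init__(self) -> None:
        if self.window_px < 3:
            raise ValueError("window_px must be >= 3")
        if not 0 < self.min_height_frac <= 1:
            raise ValueError("min_height_frac must be in (0, 1]")
        if not 0 < self.max_width_frac <= 1:
            raise ValueError("max_width_frac must be in (0, 1]")
        if not 0 < self.contrast_ratio_max < 1:
            raise ValueError("contrast_ratio_max must be in (0, 1)")


@dataclass
class WoundMeasurement:
    width_px: float
    closed: bool
    degenerate: bool
    variance_threshold: float
    mask: np.ndarray | None = None


@dataclass
class ScratchRecord:
    condition: str
    experiment: int
    width_t1_px: float
    width_t24_px: float
    closure_percent: float = float("nan")
    normalized_width: float = float("nan")


def _local_variance(image: np.ndarray, window: int) -> np.ndarray:
    img = np.asarray(image, dtype=float)
    mean = ndi.uniform_filter(img, size=window, mode="reflect")
    mean_sq = ndi.uniform_filter(img * img, size=window, mode="reflect")
    return np.clip(mean_sq - mean * mean, 0.0, None)


def detect_wound(image: np.ndarray,
                 params: ScratchParams | None = None) -> WoundMeasurement:
    """Measure the cell-free band width of one scratch image.

    Returns width 0 with ``closed=True`` when no qualifying low-variance
    component exists (fully textured image), and ``degenerate=True`` when
    the image carries no texture signal at all (e.g. uniform blank) or
    the low-variance region is as wide as the image.

    The variance map scales quadratically with any global intensity
    factor, and its automatic threshold scales along with it, so the
    measurement is invariant to intensity rescaling.
    """
    params = params or ScratchParams()
    img = np.asarray(image)
    if params.horizontal:
        img = img.T
    var = _local_variance(img, params.window_px)
    vmax = float(var.max())
    if vmax <= 0 or var.min() == vmax:
        return WoundMeasurement(0.0, closed=False, degenerate=True,
                                variance_threshold=float("nan"))
    thr = float(threshold_otsu(var))
    low = var < thr
    if not low.any() or low.all():
        return WoundMeasurement(0.0, closed=low.all(), degenerate=not low.all(),
                                variance_threshold=thr)
    mean_low = float(var[low].mean())
    mean_high = float(var[~low].mean())
    if mean_high <= 0 or mean_low / mean_high > params.contrast_ratio_max:
        # unimodal texture: no genuinely smooth region -> wound closed
        return WoundMeasurement(0.0, closed=True, degenerate=False,
                                variance_threshold=thr)
    h, w = low.shape
    labels, n = ndi.label(low)
    best_width = 0.0
    best_area = 0
    best_mask = None
    degenerate = False
    for lab in range(1, n + 1):
        component = labels == lab
        rows = np.nonzero(component.any(axis=1))[0]
        height = rows.max() - rows.min() + 1
        if height < params.min_height_frac * h:
            continue
        area = int(component.sum())
        width = area / height
        if width > params.max_width_frac * w:
            degenerate = True
            continue
        if area > best_area:
            best_area = area
            best_width = width
            best_mask = component
    if best_mask is None:
        return WoundMeasurement(0.0, closed=not degenerate,
                                degenerate=degenerate,
                                variance_threshold=thr)
    if params.edge_correction:
        best_width = min(best_width + params.window_px - 1.0, float(w))
    return WoundMeasurement(float(best_width), closed=False, degenerate=False,
                            variance_threshold=thr, mask=best_mask)


def closure_and_normalize(records: pd.DataFrame,
                          control_label: str = "Scrambled"
                          ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Percent closure and control-normalised width per record.

    ``records`` needs columns condition, experiment, width_t1_px,
    width_t24_px.  Returns (per-record table, per-condition summary with
    mean +/- SEM across experiments).  The control's normalised width is
    exactly 1.0 in every experiment.
    """
    required = {"condition", "experiment", "width_t1_px", "width_t24_px"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"records lack columns: {sorted(missing)}")
    out = records.copy()
    if (out["width_t1_px"] <= 0).any():
        bad = out.loc[out["width_t1_px"] <= 0, "condition"].tolist()
        raise ValueError(f"invalid scratch (width_t1 <= 0) for {bad}")
    out["closure_percent"] = (100.0 * out["width_t24_px"].astype(float)
                              / out["width_t1_px"].astype(float))
    ctrl = out.loc[out["condition"] == control_label]
    missing_exp = set(out["experiment"].unique()) - set(ctrl["experiment"])
    if missing_exp:
        raise ValueError(f"control {control_label!r} missing from "
                         f"experiment(s) {sorted(missing_exp)}")
    ctrl_closure = ctrl.groupby("experiment")["closure_percent"].mean()
    denom = out["experiment"].map(ctrl_closure).to_numpy(dtype=float)
    if (denom <= 0).any():
        raise ValueError("control closure is zero; cannot normalize")
    out["normalized_width"] = out["closure_percent"].to_numpy() / denom

    summary = (out.groupby("condition")["normalized_width"]
               .agg(mean="mean", sem=lambda v: v.std(ddof=1) / np.sqrt(len(v)),
                    n="size")
               .reset_index())
    return out, summary
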