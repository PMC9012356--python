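"""The standardized T1w/T2w (sT1w/T2w) ratio pipeline for the MCP.

Core computation, in pipeline order:

1. **Scaling factor** ``s`` = median gray-matter T1w intensity / median
   gray-matter T2w intensity (white-matter medians are recorded for QC but do
   not enter ``s``).
2. **Ratio map**: the T2w image is scaled, ``sT2 = s * T2w``, and the
   standardized ratio is ``(T1w - sT2) / (T1w + sT2)``, bounded in (-1, 1)
   wherever the denominator is positive; nonpositive denominators are flagged
   invalid, never silently zeroed.  Because ``s`` rescales with the inputs,
   the map is invariant to independent global rescaling of T1w and T2w — the
   property that makes the ratio comparable across subjects and scanners.
3. **Smoothing**: separable Gaussian, 8-mm FWHM by default
   (``sigma = FWHM / (2 sqrt(2 ln 2))`` per axis in voxel units), computed as
   a mask-normalized convolution so invalid voxels neither contribute nor
   bleed zeros into their neighbours.
4. **ROI extraction**: the probabilistic MCP atlas is thresholded at 90%
   membership probability; the subject's MCP value is the mean of the left
   and right ROI medians of the smoothed map.
5. **MCP volume**: thresholded atlas voxel count x voxel volume, averaged
   over sides, divided by the intracranial volume (brain-mask volume) and
   reported as ratio x 10^3.

In this phantom world the common-space transform between subject space and
the atlas space is the identity; :func:`process_subject` keeps the stage
order (ratio map -> common space -> smooth -> ROI medians) with a hook where
a real spatial normalization would slot in.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .preprocess import (GM, WM, PreprocessError, Volume, brain_mask,
                         correct_bias, estimate_bias_field,
                         estimate_bias_field_multiclass, segment_tissues)
from .synthetic import ProbAtlas, SubjectPhantom

#: FWHM-to-sigma conversion for a Gaussian kernel.
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

DEFAULT_FWHM_MM = 8.0
DEFAULT_ATLAS_THRESHOLD = 0.90


class RatioError(ValueError):
    """Raised when a ratio-pipeline contract is violated."""


# ---------------------------------------------------------------------------
# Scaling factor
# ---------------------------------------------------------------------------

@dataclass
class ScalingFactor:
    """Gray-matter-median scaling factor with QC medians."""

    s: float
    gm_median_t1w: float
    gm_median_t2w: float
    wm_median_t1w: float
    wm_median_t2w: float


def scaling_factor(t1w: Volume, t2w: Volume, gm_mask: np.ndarray,
                   wm_mask: np.ndarray) -> ScalingFactor:
    """Compute ``s = median(T1w | GM) / median(T2w | GM)``."""
    gm_mask = np.asarray(gm_mask, dtype=bool)
    wm_mask = np.asarray(wm_mask, dtype=bool)
    if not gm_mask.any():
        raise RatioError("gray-matter mask is empty")
    gm1 = float(np.median(t1w.values[gm_mask]))
    gm2 = float(np.median(t2w.values[gm_mask]))
    if gm2 <= 0:
        raise RatioError("gray-matter T2w median must be positive")
    wm1 = float(np.median(t1w.values[wm_mask])) if wm_mask.any() else float("nan")
    wm2 = float(np.median(t2w.values[wm_mask])) if wm_mask.any() else float("nan")
    return ScalingFactor(s=gm1 / gm2, gm_median_t1w=gm1, gm_median_t2w=gm2,
                         wm_median_t1w=wm1, wm_median_t2w=wm2)


# ---------------------------------------------------------------------------
# Ratio map
# ---------------------------------------------------------------------------

@dataclass
class RatioMap:
    """sT1w/T2w ratio values with an explicit validity mask.

    Valid voxels carry values strictly inside (-1, 1); invalid voxels
    (nonpositive T1w or sT2) are NaN.
    """

    values: np.ndarray
    valid: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)


def ratio_map(t1w: Volume, t2w: Volume, s: ScalingFactor | float) -> RatioMap:
    """Standardized ratio map ``(T1w - sT2) / (T1w + sT2)``.

    A voxel is valid only where both T1w and sT2 are positive (which implies
    a positive denominator and bounds the ratio in (-1, 1)); other voxels —
    background, or noise-dominated intensities — are flagged invalid and
    carry NaN, never a silent zero.
    """
    if not t1w.same_grid(t2w):
        raise RatioError("T1w and T2w must be registered on the same grid")
    s_val = s.s if isinstance(s, ScalingFactor) else float(s)
    st2 = s_val * t2w.values
    denom = t1w.values + st2
    valid = (t1w.values > 0) & (st2 > 0)
    values = np.full(t1w.shape, np.nan)
    np.divide(t1w.values - st2, denom, out=values, where=valid)
    return RatioMap(values, valid, t1w.affine.copy())


def smooth(rmap: RatioMap, fwhm_mm: float = DEFAULT_FWHM_MM,
           voxel_size_mm: np.ndarray | None = None) -> RatioMap:
    """Mask-normalized separable Gaussian smoothing of a ratio map.

    Invalid voxels are excluded: the map (with invalid voxels zeroed) and the
    validity mask are smoothed separately and their quotient is taken where
    the smoothed mask has support, so a constant valid map stays constant.
    ``fwhm_mm = 0`` is the identity.
    """
    if fwhm_mm < 0:
        raise RatioError("FWHM must be nonnegative")
    if fwhm_mm == 0:
        return RatioMap(rmap.values.copy(), rmap.valid.copy(), rmap.affine.copy())
    if voxel_size_mm is None:
        voxel_size_mm = np.sqrt((rmap.affine[:3, :3] ** 2).sum(axis=0))
    sigma_vox = fwhm_mm * FWHM_TO_SIGMA / np.asarray(voxel_size_mm, dtype=float)
    filled = np.where(rmap.valid, rmap.values, 0.0)
    num = ndimage.gaussian_filter(filled, sigma_vox, mode="constant")
    den = ndimage.gaussian_filter(rmap.valid.astype(float), sigma_vox,
                                  mode="constant")
    support = den > 1e-12
    values = np.full(rmap.values.shape, np.nan)
    np.divide(num, den, out=values, where=support)
    return RatioMap(values, support, rmap.affine.copy())


# ---------------------------------------------------------------------------
# MCP measurement
# ---------------------------------------------------------------------------

@dataclass
class McpMeasurement:
    """Per-subject MCP summary: ratio part and/or volume part."""

    left_median: float = float("nan")
    right_median: float = float("nan")
    mcp_value: float = float("nan")
    mcp_volume_mm3: float = float("nan")
    icv_mm3: float = float("nan")
    mcp_volume_norm: float = float("nan")


def mcp_value(rmap: RatioMap, atlas: ProbAtlas,
              threshold: float = DEFAULT_ATLAS_THRESHOLD) -> McpMeasurement:
    """Mean of the left/right ROI medians at the atlas probability threshold.

    The threshold is inclusive (probability >= threshold) and only valid
    voxels enter the medians.
    """
    medians = []
    for prob in (atlas.left, atlas.right):
        sel = (prob >= threshold) & rmap.valid
        if not sel.any():
            raise RatioError("thresholded ROI contains no valid voxels")
        medians.append(float(np.median(rmap.values[sel])))
    left, right = medians
    return McpMeasurement(left_median=left, right_median=right,
                          mcp_value=(left + right) / 2.0)


def mcp_volume(atlas: ProbAtlas, threshold: float, brain: np.ndarray,
               voxel_volume_mm3: float) -> McpMeasurement:
    """Thresholded-atlas MCP volume normalized by the intracranial volume.

    The per-side voxel counts at the probability threshold are converted to
    mm^3, averaged over sides, and divided by the ICV (brain-mask volume);
    the normalized value is reported as ratio x 10^3.
    """
    brain = np.asarray(brain, dtype=bool)
    if not brain.any():
        raise RatioError("brain mask is empty")
    sides = []
    for prob in (atlas.left, atlas.right):
        count = int((prob >= threshold).sum())
        if count == 0:
            raise RatioError("thresholded ROI is empty")
        sides.append(count * voxel_volume_mm3)
    vol = float(np.mean(sides))
    icv = float(brain.sum() * voxel_volume_mm3)
    return McpMeasurement(mcp_volume_mm3=vol, icv_mm3=icv,
                          mcp_volume_norm=vol / icv * 1e3)


def measure_mcp(rmap: RatioMap, atlas: ProbAtlas, brain: np.ndarray,
                voxel_volume_mm3: float,
                threshold: float = DEFAULT_ATLAS_THRESHOLD) -> McpMeasurement:
    """Combine :func:`mcp_value` and :func:`mcp_volume` into one record."""
    ratio_part = mcp_value(rmap, atlas, threshold)
    vol_part = mcp_volume(atlas, threshold, brain, voxel_volume_mm3)
    return McpMeasurement(
        left_median=ratio_part.left_median,
        right_median=ratio_part.right_median,
        mcp_value=ratio_part.mcp_value,
        mcp_volume_mm3=vol_part.mcp_volume_mm3,
        icv_mm3=vol_part.icv_mm3,
        mcp_volume_norm=vol_part.mcp_volume_norm,
    )


# ---------------------------------------------------------------------------
# End-to-end subject processing
# ---------------------------------------------------------------------------

def preprocess_estimate(t1w: Volume, t2w: Volume):
    """Estimated preprocessing chain for a co-registered T1w/T2w pair.

    Skull-strip, rough segmentation, per-class robust polynomial bias fit for
    each contrast, correction, final segmentation.  Returns
    ``(t1_corrected, t2_corrected, labels, brain_mask)``.
    """
    brain = brain_mask(t1w)
    rough = segment_tissues(t1w, brain)
    # per-class residual fit with outlier trimming: robust to the focal
    # T2w signal change in the MCP region, with full-brain support
    fld1 = estimate_bias_field_multiclass(t1w, rough)
    fld2 = estimate_bias_field_multiclass(t2w, rough)
    t1c = correct_bias(t1w, fld1, brain)
    t2c = correct_bias(t2w, fld2, brain)
    labels = segment_tissues(t1c, brain)
    return t1c, t2c, labels, brain


def process_volumes(t1w: Volume, t2w: Volume, atlas: ProbAtlas,
                    fwhm_mm: float = DEFAULT_FWHM_MM,
                    threshold: float = DEFAULT_ATLAS_THRESHOLD,
                    return_map: bool = False):
    """Full estimated pipeline on raw volumes (the file-input entry point).

    Returns the per-subject record, plus the smoothed ratio map when
    ``return_map`` is set.
    """
    t1c, t2c, labels, brain = preprocess_estimate(t1w, t2w)
    row, smoothed = _measure(t1c, t2c, labels, brain, atlas, fwhm_mm, threshold)
    return (row, smoothed) if return_map else row


def _measure(t1c: Volume, t2c: Volume, labels, brain: np.ndarray,
             atlas: ProbAtlas, fwhm_mm: float, threshold: float):
    s = scaling_factor(t1c, t2c, labels.mask(GM), labels.mask(WM))
    rmap = ratio_map(t1c, t2c, s)
    # subject -> common space: identity in the phantom world (hook for a
    # real spatial normalization), then smoothing and ROI extraction
    smoothed = smooth(rmap, fwhm_mm)
    meas = measure_mcp(smoothed, atlas, brain, t1c.voxel_volume_mm3, threshold)
    return {
        "s": s.s,
        "gm_median_t1w": s.gm_median_t1w,
        "gm_median_t2w": s.gm_median_t2w,
        "wm_median_t1w": s.wm_median_t1w,
        "wm_median_t2w": s.wm_median_t2w,
        "mcp_left": meas.left_median,
        "mcp_right": meas.right_median,
        "mcp_value": meas.mcp_value,
        "mcp_volume_mm3": meas.mcp_volume_mm3,
        "icv_mm3": meas.icv_mm3,
        "mcp_volume_norm": meas.mcp_volume_norm,
    }, smoothed


def process_subject(phantom: SubjectPhantom, atlas: ProbAtlas,
                    mode: str = "oracle",
                    fwhm_mm: float = DEFAULT_FWHM_MM,
                    threshold: float = DEFAULT_ATLAS_THRESHOLD) -> dict:
    """Run the full per-subject pipeline on a phantom.

    ``mode="oracle"`` takes masks and the bias field from the generator's
    ground truth, isolating the ratio computation from segmentation error;
    ``mode="estimate"`` runs the preprocessing estimators (brain mask,
    rough segmentation, WM-fit bias field, correction, re-segmentation).
    Returns a flat record suitable for one CSV row.
    """
    t1w, t2w = phantom.t1w, phantom.t2w
    if not t1w.same_grid(t2w):
        raise RatioError(
            "subject processing expects co-registered same-grid volumes; "
            "run register_rigid first")

    if mode == "oracle":
        labels = phantom.truth_labels
        brain = labels.brain
        fld = phantom.truth_bias_field
        t1c = correct_bias(t1w, fld, brain)
        t2c = correct_bias(t2w, fld, brain)
    elif mode == "estimate":
        t1c, t2c, labels, brain = preprocess_estimate(t1w, t2w)
    else:
        raise RatioError(f"unknown preprocessing mode {mode!r}")

    row, _ = _measure(t1c, t2c, labels, brain, atlas, fwhm_mm, threshold)
    return row
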