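"""Desk-scale preprocessing for the sT1w/T2w ratio pipeline.

The original pipeline delegates four preprocessing steps to external
neuroimaging tools: intensity-inhomogeneity (bias-field) correction, rigid
co-registration of the T1w and T2w volumes, skull-stripping, and tissue
segmentation into CSF / gray matter / white matter.  Downstream, only their
*outputs* matter (masks and in-mask medians), so each step is reimplemented
here with the simplest algorithm honoring that contract:

* bias field   -- least-squares polynomial fit to log-intensity, exponentiated;
* registration -- 6-parameter rigid search minimizing mean-squared intensity
  difference, with trilinear resampling through the volume affines;
* brain mask   -- Otsu threshold + largest connected component + closing
  (the mask volume defines the intracranial volume, ICV);
* segmentation -- deterministic 1-D k-means on in-mask intensity, classes
  relabeled by ascending mean so CSF < GM < WM in T1w.

Coordinate convention: voxel indices are 0-based; world coordinates are
RAS millimetres through the 4x4 affine; resampling outside the source grid
yields zero together with an out-of-field mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize
from skimage.filters import threshold_otsu

#: Tissue label codes shared across the package.
BACKGROUND, CSF, GM, WM = 0, 1, 2, 3


class PreprocessError(ValueError):
    """Raised when a preprocessing contract is violated."""


# ---------------------------------------------------------------------------
# Volume containers
# ---------------------------------------------------------------------------

@dataclass
class Volume:
    """A 3-D intensity grid with a voxel-to-world (RAS mm) affine."""

    values: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.values.ndim != 3:
            raise PreprocessError("volume values must be a 3-D array")
        if self.affine.shape != (4, 4):
            raise PreprocessError("affine must be 4x4")
        if not np.isfinite(self.values).all():
            raise PreprocessError("volume contains non-finite values")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise PreprocessError("affine is not invertible")
        if (self.voxel_size_mm <= 0).any():
            raise PreprocessError("voxel spacings must be positive")

    @property
    def voxel_size_mm(self) -> np.ndarray:
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    @property
    def shape(self) -> tuple[int, ...]:
        return self.values.shape

    def with_values(self, values: np.ndarray) -> "Volume":
        return Volume(values, self.affine.copy())

    def same_grid(self, other: "Volume") -> bool:
        return self.shape == other.shape and np.allclose(self.affine, other.affine)

    def world_center_mm(self) -> np.ndarray:
        """World coordinates of the geometric center of the grid."""
        center_vox = (np.asarray(self.shape, dtype=float) - 1.0) / 2.0
        return self.affine[:3, :3] @ center_vox + self.affine[:3, 3]


@dataclass
class LabelVolume:
    """Integer tissue/ROI labels on a :class:`Volume` grid."""

    values: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    VALID_LABELS = (BACKGROUND, CSF, GM, WM)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int16)
        self.affine = np.asarray(self.affine, dtype=float)
        if not np.isin(self.values, self.VALID_LABELS).all():
            raise PreprocessError(
                f"labels must be drawn from {self.VALID_LABELS}")

    def mask(self, label: int) -> np.ndarray:
        return self.values == label

    @property
    def brain(self) -> np.ndarray:
        return self.values != BACKGROUND


# ---------------------------------------------------------------------------
# Rigid transforms and resampling
# ---------------------------------------------------------------------------

@dataclass
class RigidTransform:
    """Rigid-body transform: rotations in degrees, translations in mm.

    The transform maps *fixed-image* world coordinates to *moving-image*
    world coordinates; the rotation is applied about ``center_mm`` (usually
    the fixed volume's geometric center) in the order R = Rz @ Ry @ Rx.
    """

    rotation_deg: np.ndarray = field(default_factory=lambda: np.zeros(3))
    translation_mm: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.rotation_deg = np.asarray(self.rotation_deg, dtype=float).reshape(3)
        self.translation_mm = np.asarray(self.translation_mm, dtype=float).reshape(3)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls()

    @classmethod
    def from_params(cls, params: np.ndarray) -> "RigidTransform":
        params = np.asarray(params, dtype=float).reshape(6)
        return cls(params[:3], params[3:])

    def as_params(self) -> np.ndarray:
        return np.concatenate([self.rotation_deg, self.translation_mm])

    def rotation_matrix(self) -> np.ndarray:
        rx, ry, rz = np.deg2rad(self.rotation_deg)
        cx, sx = np.cos(rx), np.sin(rx)
        cy, sy = np.cos(ry), np.sin(ry)
        cz, sz = np.cos(rz), np.sin(rz)
        Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
        Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
        Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
        return Rz @ Ry @ Rx

    def matrix(self, center_mm: np.ndarray) -> np.ndarray:
        """Homogeneous 4x4 world-coordinate matrix about ``center_mm``."""
        center_mm = np.asarray(center_mm, dtype=float)
        R = self.rotation_matrix()
        M = np.eye(4)
        M[:3, :3] = R
        M[:3, 3] = center_mm - R @ center_mm + self.translation_mm
        return M


def resample(moving: Volume, fixed: Volume,
             transform: "RigidTransform | np.ndarray | None" = None,
             order: int = 1) -> tuple[Volume, np.ndarray]:
    """Resample ``moving`` onto the grid of ``fixed``.

    ``transform`` may be a :class:`RigidTransform` (applied about the fixed
    volume's center) or a raw homogeneous 4x4 world-coordinate matrix.
    Returns the resampled volume and a boolean in-field mask; voxels mapping
    outside the source grid are zero and flagged out-of-field.
    """
    if transform is None:
        transform = RigidTransform.identity()
    if isinstance(transform, np.ndarray):
        M = transform
    else:
        M = transform.matrix(fixed.world_center_mm())
    # fixed voxel -> fixed world -> moving world -> moving voxel
    A = np.linalg.inv(moving.affine) @ M @ fixed.affine
    idx = np.indices(fixed.shape, dtype=float).reshape(3, -1)
    src = A[:3, :3] @ idx + A[:3, 3:4]
    vals = ndimage.map_coordinates(moving.values, src, order=order,
                                   mode="constant", cval=0.0)
    upper = np.asarray(moving.shape, dtype=float).reshape(3, 1) - 1.0
    infield = ((src >= -0.5) & (src <= upper + 0.5)).all(axis=0)
    return (fixed.with_values(vals.reshape(fixed.shape)),
            infield.reshape(fixed.shape))


# ---------------------------------------------------------------------------
# Bias-field estimation and correction
# ---------------------------------------------------------------------------

def _polynomial_design(shape: tuple[int, ...], order: int) -> np.ndarray:
    """Monomial design matrix (total degree <= order) on [-1, 1]^3 coords."""
    axes = [np.linspace(-1.0, 1.0, n) if n > 1 else np.zeros(n) for n in shape]
    x, y, z = np.meshgrid(*axes, indexing="ij")
    cols = []
    for a in range(order + 1):
        for b in range(order + 1 - a):
            for c in range(order + 1 - a - b):
                cols.append((x ** a) * (y ** b) * (z ** c))
    return np.stack([col.ravel() for col in cols], axis=1)


def estimate_bias_field(volume: Volume, mask: np.ndarray, order: int = 2) -> Volume:
    """Estimate a smooth multiplicative intensity-inhomogeneity field.

    A polynomial of total degree ``order`` is fit by least squares to the
    log-intensity inside ``mask``, exponentiated over the whole grid, and
    normalized to in-mask mean 1.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise PreprocessError("bias estimation requires a nonempty mask")
    vals = volume.values[mask]
    if (vals <= 0).any():
        raise PreprocessError("bias estimation requires positive in-mask intensities")
    design = _polynomial_design(volume.shape, order)
    flat_mask = mask.ravel()
    coef, *_ = np.linalg.lstsq(design[flat_mask], np.log(vals), rcond=None)
    log_field = (design @ coef).reshape(volume.shape)
    log_field -= log_field[mask].mean()  # keeps exp() well-scaled
    fld = np.exp(log_field)
    fld /= fld[mask].mean()
    return volume.with_values(fld)


def estimate_bias_field_multiclass(volume: Volume, labels: "LabelVolume",
                                   order: int = 2, trim: float = 2.5) -> Volume:
    """Bias estimation from per-tissue log-intensity residuals.

    For each tissue class the median log-intensity is subtracted, giving
    residuals that reflect the bias field regardless of tissue contrast;
    voxels whose residual exceeds ``trim`` robust SDs of their class (e.g.
    focal signal change such as a degenerated tract) are excluded before the
    polynomial fit.  This gives full-brain spatial support, unlike a
    single-tissue fit.
    """
    lab = labels.values
    brain = lab != BACKGROUND
    if not brain.any():
        raise PreprocessError("bias estimation requires a nonempty brain")
    vals = volume.values
    positive = brain & (vals > 0)   # noise-dominated voxels cannot enter the log
    if not positive.any():
        raise PreprocessError("bias estimation requires positive in-mask intensities")
    logv = np.zeros_like(vals)
    logv[positive] = np.log(vals[positive])
    resid = np.zeros_like(vals)
    keep = np.zeros(vals.shape, dtype=bool)
    for c in (CSF, GM, WM):
        sel = (lab == c) & positive
        if not sel.any():
            continue
        med = np.median(logv[sel])
        r = logv[sel] - med
        mad = np.median(np.abs(r - np.median(r)))
        scale = max(1.4826 * mad, 1e-6)
        ok = np.abs(r) <= trim * scale
        resid[sel] = r
        keep_c = np.zeros(vals.shape, dtype=bool)
        keep_c[sel] = ok
        keep |= keep_c
    design = _polynomial_design(volume.shape, order)
    coef, *_ = np.linalg.lstsq(design[keep.ravel()], resid[keep], rcond=None)
    log_field = (design @ coef).reshape(volume.shape)
    log_field -= log_field[brain].mean()
    fld = np.exp(log_field)
    fld /= fld[brain].mean()
    return volume.with_values(fld)


def correct_bias(volume: Volume, bias_field: Volume,
                 mask: np.ndarray | None = None) -> Volume:
    """Divide out a multiplicative bias field."""
    f = bias_field.values
    if mask is not None and (f[np.asarray(mask, dtype=bool)] == 0).any():
        raise PreprocessError("bias field is zero inside the mask")
    out = np.divide(volume.values, f, out=np.zeros_like(volume.values),
                    where=f != 0)
    return volume.with_values(out)


# ---------------------------------------------------------------------------
# Rigid registration
# ---------------------------------------------------------------------------

def _mse_cost_factory(moving: Volume, fixed: Volume, smooth_sigma_vox: float,
                      stride: int):
    """Mean-squared-difference cost over a (subsampled) fixed grid."""
    mov_s = ndimage.gaussian_filter(moving.values, smooth_sigma_vox)
    fix_s = ndimage.gaussian_filter(fixed.values, smooth_sigma_vox)
    sub = fix_s[::stride, ::stride, ::stride]
    sub_idx = np.indices(sub.shape, dtype=float).reshape(3, -1) * stride
    center = fixed.world_center_mm()
    inv_mov = np.linalg.inv(moving.affine)
    upper = np.asarray(moving.shape, dtype=float).reshape(3, 1) - 1.0

    def cost(params: np.ndarray) -> float:
        M = RigidTransform.from_params(params).matrix(center)
        A = inv_mov @ M @ fixed.affine
        src = A[:3, :3] @ sub_idx + A[:3, 3:4]
        infield = ((src >= 0) & (src <= upper)).all(axis=0)
        if infield.mean() < 0.25:
            return np.inf
        vals = ndimage.map_coordinates(mov_s, src[:, infield], order=1)
        diff = vals - sub.ravel()[infield]
        return float(np.mean(diff ** 2))

    return cost


def register_rigid(moving: Volume, fixed: Volume, mode: str = "identity",
                   smooth_sigma_vox: float = 2.0,
                   coarse_translations_mm: tuple[float, ...] = (-6.0, -3.0, 0.0, 3.0, 6.0),
                   ) -> tuple[RigidTransform, Volume]:
    """Rigidly align ``moving`` to ``fixed``.

    ``mode="identity"`` trusts the affines (the default when both images live
    on the same grid, as generated phantoms do) and only resamples.
    ``mode="optimize"`` minimizes the mean-squared intensity difference over
    the 6 rigid parameters by derivative-free multi-start search: a coarse
    translation scan seeds a Powell pass on a 2x-subsampled grid, refined by
    a second Powell pass at full resolution.  Both passes run on smoothed
    volumes, which keeps the cost surface free of interpolation ripple.
    Intended for same-contrast pairs (MSE is not a cross-contrast metric).
    """
    if mode == "identity":
        transform = RigidTransform.identity()
        resampled, _ = resample(moving, fixed, transform)
        return transform, resampled
    if mode != "optimize":
        raise PreprocessError(f"unknown registration mode {mode!r}")

    coarse = _mse_cost_factory(moving, fixed, smooth_sigma_vox, stride=2)
    best, best_cost = np.zeros(6), np.inf
    for tx in coarse_translations_mm:
        for ty in coarse_translations_mm:
            for tz in coarse_translations_mm:
                p = np.array([0.0, 0.0, 0.0, tx, ty, tz])
                c = coarse(p)
                if c < best_cost:
                    best, best_cost = p, c
    if not np.isfinite(best_cost):
        raise PreprocessError("no overlap between volumes during registration")

    res = optimize.minimize(coarse, best, method="Powell",
                            options={"xtol": 1e-4, "ftol": 1e-8, "maxiter": 300})
    fine = _mse_cost_factory(moving, fixed, smooth_sigma_vox, stride=1)
    res = optimize.minimize(fine, res.x, method="Powell",
                            options={"xtol": 1e-5, "ftol": 1e-10, "maxiter": 300})
    transform = RigidTransform.from_params(res.x)
    resampled, _ = resample(moving, fixed, transform)
    return transform, resampled


# ---------------------------------------------------------------------------
# Brain masking and tissue segmentation
# ---------------------------------------------------------------------------

def brain_mask(t1w: Volume) -> np.ndarray:
    """Skull-strip: Otsu threshold, largest component, morphological closing.

    The resulting mask volume defines the intracranial volume (ICV) used to
    normalize MCP volumes downstream.
    """
    v = t1w.values
    if not np.any(v != 0):
        raise PreprocessError("cannot skull-strip an all-zero volume")
    thr = threshold_otsu(v)
    rough = v > thr
    labels, n = ndimage.label(rough)
    if n == 0:
        raise PreprocessError("no foreground found above the Otsu threshold")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, np.arange(1, n + 1))
    largest = labels == (1 + int(np.argmax(sizes)))
    closed = ndimage.binary_closing(largest, structure=np.ones((3, 3, 3)),
                                    iterations=2)
    return ndimage.binary_fill_holes(closed)


def _kmeans_1d(x: np.ndarray, k: int, max_iter: int = 100) -> np.ndarray:
    """Deterministic 1-D k-means; centers start on a quantile-bracketed grid."""
    lo, hi = np.percentile(x, [2.0, 98.0])
    if lo == hi:
        lo, hi = x.min(), x.max()
    centers = np.linspace(lo, hi, k)
    assign = np.zeros(x.shape, dtype=np.int64)
    for _ in range(max_iter):
        new_assign = np.argmin(np.abs(x[:, None] - centers[None, :]), axis=1)
        if np.array_equal(new_assign, assign) and _ > 0:
            break
        assign = new_assign
        for j in range(k):
            sel = assign == j
            if sel.any():
                centers[j] = x[sel].mean()
    return assign


def segment_tissues(t1w: Volume, mask: np.ndarray, k: int = 3) -> LabelVolume:
    """Segment in-mask T1w intensities into ``k`` tissue classes.

    Classes are relabeled by ascending mean intensity, so on T1w the output
    labels are CSF (1) < GM (2) < WM (3); voxels outside the mask are
    background (0).  Deterministic: no randomized initialization.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise PreprocessError("segmentation requires a nonempty mask")
    x = t1w.values[mask]
    if np.unique(x).size < k:
        raise PreprocessError(
            f"need at least {k} distinct intensities to fit {k} classes")
    assign = _kmeans_1d(x, k)
    means = np.array([x[assign == j].mean() if (assign == j).any() else np.inf
                      for j in range(k)])
    order = np.argsort(means)
    relabel = np.empty(k, dtype=np.int64)
    relabel[order] = np.arange(1, k + 1)
    out = np.zeros(t1w.shape, dtype=np.int16)
    out[mask] = relabel[assign]
    return LabelVolume(out, t1w.affine.copy())
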