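"""Synthetic data: brain phantoms, a probabilistic MCP atlas, value-level
cohorts, and simulated reviewer ratings.

No imaging data are deposited for the MSA-C / SCA cohort the MCP sT1w/T2w
biomarker was evaluated on, so every downstream stage of this package is
exercised on synthetic inputs whose statistical structure mirrors the
published summary (:mod:`mcpratio.reference`):

* :func:`make_phantom` builds a stylized ellipsoidal brain (CSF shell, GM
  ribbon, WM core) with a brainstem/cerebellum block containing left and
  right MCP regions.  Inside that block the T2w intensity is back-solved from
  the T1w intensity and the intended gray-matter scaling factor so that the
  noiseless ratio pipeline returns exactly ``mcp_target_ratio``.  A smooth
  multiplicative bias field and additive noise are layered on top.
* :func:`make_atlas` builds the probabilistic left/right MCP atlas used for
  ROI parcellation (probability 1 at each ROI center, smooth decay to 0).
* :func:`simulate_value_cohort` draws per-subject biomarker values
  (ratio, ICV-normalized volume, ordinal hyperintensity extent, demographics)
  from the published group moments.
* :func:`simulate_ratings` emulates reviewers with controllable
  sensitivity/specificity for binary signs and transition noise for the
  ordinal hot-cross-bun grade.

The phantom geometry is deliberately not anatomical: the ratio pipeline is
geometry-agnostic given masks and an atlas, so a stylized shape with known
ground truth is the stronger test fixture.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy import ndimage

from . import reference
from .preprocess import (BACKGROUND, CSF, GM, WM, LabelVolume, PreprocessError,
                         RigidTransform, Volume, resample)


class SyntheticError(ValueError):
    """Raised on invalid generator specifications."""


# ---------------------------------------------------------------------------
# Geometry (fractions of the half field of view, per axis)
# ---------------------------------------------------------------------------

_BRAIN_RADII_FRAC = np.array([0.94, 0.82, 0.82])
_CSF_INNER = 0.93      # normalized radius of the CSF/GM interface
_GM_INNER = 0.86       # normalized radius of the GM/WM interface
_STEM_CENTER_FRAC = np.array([0.0, 0.0, -0.20])   # offset from grid center
_STEM_RADII_FRAC = np.array([0.60, 0.34, 0.34])
_MCP_LATERAL_FRAC = 0.25
#: sized so the 90%-probability core over the default grid yields an
#: ICV-normalized MCP volume near the healthy-control value (~0.34 x 10^-3)
_MCP_RADII_FRAC = np.array([0.210, 0.175, 0.175])


@dataclass
class RoiGeometry:
    """Two lateral ellipsoids (voxel units) defining the left/right MCP."""

    center_left_vox: np.ndarray
    center_right_vox: np.ndarray
    radii_vox: np.ndarray

    def __post_init__(self) -> None:
        self.center_left_vox = np.asarray(self.center_left_vox, dtype=float)
        self.center_right_vox = np.asarray(self.center_right_vox, dtype=float)
        self.radii_vox = np.asarray(self.radii_vox, dtype=float)
        if (self.radii_vox <= 0).any():
            raise SyntheticError("ROI radii must be positive")


def default_mcp_geometry(grid_shape: tuple[int, int, int]) -> RoiGeometry:
    half = (np.asarray(grid_shape, dtype=float) - 1.0) / 2.0
    center = half.copy()
    stem_center = center + _STEM_CENTER_FRAC * half
    offset = np.array([_MCP_LATERAL_FRAC * half[0], 0.0, 0.0])
    return RoiGeometry(center_left_vox=stem_center - offset,
                       center_right_vox=stem_center + offset,
                       radii_vox=_MCP_RADII_FRAC * half)


# ---------------------------------------------------------------------------
# Probabilistic atlas
# ---------------------------------------------------------------------------

@dataclass
class ProbAtlas:
    """Per-voxel left/right MCP membership probabilities on a common grid."""

    left: np.ndarray
    right: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.left = np.asarray(self.left, dtype=float)
        self.right = np.asarray(self.right, dtype=float)
        for p in (self.left, self.right):
            if ((p < 0) | (p > 1)).any():
                raise SyntheticError("atlas probabilities must lie in [0, 1]")


def _ellipsoid_d2(shape: tuple[int, ...], center_vox: np.ndarray,
                  radii_vox: np.ndarray) -> np.ndarray:
    """Squared normalized ellipsoidal distance at every voxel."""
    grids = np.ogrid[tuple(slice(n) for n in shape)]
    d2 = np.zeros(shape, dtype=float)
    for g, c, r in zip(grids, center_vox, radii_vox):
        d2 = d2 + ((g - c) / r) ** 2
    return d2


def _affine_from_spacing(voxel_size_mm: np.ndarray) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] = np.diag(voxel_size_mm)
    return aff


def make_atlas(grid_shape: tuple[int, int, int],
               voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 2.0),
               roi_geometry: RoiGeometry | None = None) -> ProbAtlas:
    """Build the probabilistic left/right MCP atlas.

    The membership probability is 1 at each ROI center and decays smoothly
    (quadratically in the normalized ellipsoidal radius, ``p = 1 - d^2``) to 0
    at the ellipsoid surface and beyond.  Deterministic for fixed inputs.
    """
    geo = roi_geometry or default_mcp_geometry(grid_shape)
    upper = np.asarray(grid_shape, dtype=float) - 1.0
    for c in (geo.center_left_vox, geo.center_right_vox):
        if ((c - geo.radii_vox) < 0).any() or ((c + geo.radii_vox) > upper).any():
            raise SyntheticError("ROI ellipsoid extends beyond the grid")
    left = np.clip(1.0 - _ellipsoid_d2(grid_shape, geo.center_left_vox,
                                       geo.radii_vox), 0.0, 1.0)
    right = np.clip(1.0 - _ellipsoid_d2(grid_shape, geo.center_right_vox,
                                        geo.radii_vox), 0.0, 1.0)
    return ProbAtlas(left, right,
                     _affine_from_spacing(np.asarray(voxel_size_mm, float)))


# ---------------------------------------------------------------------------
# Phantom generation
# ---------------------------------------------------------------------------

@dataclass
class PhantomSpec:
    """Parameters of one synthetic multi-contrast subject."""

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    #: per-tissue intensity (arbitrary units); chosen so that a bimodal
    #: background/brain split dominates the Otsu histogram on T1w
    tissue_means_t1w: dict = dc_field(
        default_factory=lambda: {"csf": 100.0, "gm": 140.0, "wm": 180.0})
    tissue_means_t2w: dict = dc_field(
        default_factory=lambda: {"csf": 180.0, "gm": 100.0, "wm": 60.0})
    #: intended post-pipeline sT1w/T2w value inside the MCP ROIs
    mcp_target_ratio: float = 0.07
    #: peak fractional deviation of the multiplicative bias field
    bias_amplitude: float = 0.1
    #: additive noise SD (intensity units)
    noise_sigma: float = 4.0
    noise_model: str = "gaussian"   # or "rician"
    #: optional rigid motion (rotation deg + translation mm) of the T2w grid
    rigid_offset: RigidTransform | None = None
    #: optional thick-slice T2w acquisition (slab thickness along z, mm)
    t2_slice_thickness_mm: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for means in (self.tissue_means_t1w, self.tissue_means_t2w):
            if any(v <= 0 for v in means.values()):
                raise SyntheticError("tissue intensities must be positive")
        if not 0.0 <= self.bias_amplitude < 1.0:
            raise SyntheticError("bias_amplitude must lie in [0, 1)")
        if self.noise_sigma < 0:
            raise SyntheticError("noise_sigma must be nonnegative")
        if not abs(self.mcp_target_ratio) < 1.0:
            raise SyntheticError("|mcp_target_ratio| must be < 1")
        if self.noise_model not in ("gaussian", "rician"):
            raise SyntheticError(f"unknown noise model {self.noise_model!r}")


@dataclass
class SubjectPhantom:
    """One synthetic subject with full ground truth."""

    t1w: Volume
    t2w: Volume
    truth_labels: LabelVolume
    truth_mcp_left: np.ndarray
    truth_mcp_right: np.ndarray
    truth_stem: np.ndarray
    truth_bias_field: Volume
    truth_transform: RigidTransform
    truth_mcp_ratio: float
    spec: PhantomSpec


def _bias_field(shape: tuple[int, ...], brain: np.ndarray, amplitude: float,
                rng: np.random.Generator) -> np.ndarray:
    """exp(random order-2 polynomial), in-brain mean 1, peak dev ~ amplitude."""
    if amplitude == 0.0:
        return np.ones(shape)
    axes = [np.linspace(-1.0, 1.0, n) for n in shape]
    x, y, z = np.meshgrid(*axes, indexing="ij")
    terms = [x, y, z, x * y, x * z, y * z, x ** 2, y ** 2, z ** 2]
    coef = rng.normal(size=len(terms))
    q = sum(c * t for c, t in zip(coef, terms))
    q -= q[brain].mean()
    peak = np.abs(q[brain]).max()
    if peak > 0:
        q /= peak
    fld = np.exp(np.log1p(amplitude) * q)
    return fld / fld[brain].mean()


def make_phantom(spec: PhantomSpec) -> SubjectPhantom:
    """Generate one phantom subject; identical seeds give identical output."""
    rng = np.random.default_rng(spec.seed)
    shape = tuple(spec.grid_shape)
    half = (np.asarray(shape, dtype=float) - 1.0) / 2.0
    center = half.copy()

    rho2 = _ellipsoid_d2(shape, center, _BRAIN_RADII_FRAC * half)
    labels = np.zeros(shape, dtype=np.int16)
    labels[rho2 <= 1.0] = CSF
    labels[rho2 <= _CSF_INNER ** 2] = GM
    labels[rho2 <= _GM_INNER ** 2] = WM

    stem = _ellipsoid_d2(shape, center + _STEM_CENTER_FRAC * half,
                         _STEM_RADII_FRAC * half) <= 1.0
    labels[stem] = WM  # the stem/cerebellum block is white matter

    geo = default_mcp_geometry(shape)
    mcp_left = _ellipsoid_d2(shape, geo.center_left_vox, geo.radii_vox) <= 1.0
    mcp_right = _ellipsoid_d2(shape, geo.center_right_vox, geo.radii_vox) <= 1.0

    m1, m2 = spec.tissue_means_t1w, spec.tissue_means_t2w
    lut1 = np.array([0.0, m1["csf"], m1["gm"], m1["wm"]])
    lut2 = np.array([0.0, m2["csf"], m2["gm"], m2["wm"]])
    t1 = lut1[labels]
    t2 = lut2[labels]

    # Back-solve T2w in the calibrated block so the noiseless pipeline value
    # equals mcp_target_ratio: with s = GM_T1 / GM_T2 and r* the target,
    # (T1 - s T2) / (T1 + s T2) = r*  =>  T2 = T1 (1 - r*) / (1 + r*) / s.
    # The whole stem block (not just the MCP ellipsoids) is calibrated so the
    # smoothing kernel's full support around the 90%-probability core sees a
    # homogeneous ratio value.
    s_intended = m1["gm"] / m2["gm"]
    r = spec.mcp_target_ratio
    t2[stem] = t1[stem] * (1.0 - r) / (1.0 + r) / s_intended

    brain = labels != BACKGROUND
    fld = _bias_field(shape, brain, spec.bias_amplitude, rng)
    t1 = t1 * fld
    t2 = t2 * fld

    affine = _affine_from_spacing(np.asarray(spec.voxel_size_mm, float))
    t1_vol = Volume(t1, affine)
    t2_vol = Volume(t2, affine)

    truth_transform = spec.rigid_offset or RigidTransform.identity()
    if spec.rigid_offset is not None:
        # Move the T2w grid so that registration with the recorded transform
        # maps it back onto the T1w grid.
        M = truth_transform.matrix(t2_vol.world_center_mm())
        moved, _ = resample(t2_vol, t2_vol, np.linalg.inv(M))
        t2_vol = moved
    if spec.t2_slice_thickness_mm is not None:
        t2_vol = _slab_average_z(t2_vol, spec.t2_slice_thickness_mm)

    t1_noisy = _add_noise(t1_vol.values, spec, rng)
    t2_noisy = _add_noise(t2_vol.values, spec, rng)

    return SubjectPhantom(
        t1w=Volume(t1_noisy, affine),
        t2w=Volume(t2_noisy, t2_vol.affine),
        truth_labels=LabelVolume(labels, affine),
        truth_mcp_left=mcp_left,
        truth_mcp_right=mcp_right,
        truth_stem=stem,
        truth_bias_field=Volume(fld, affine),
        truth_transform=truth_transform,
        truth_mcp_ratio=r,
        spec=spec,
    )


def _add_noise(values: np.ndarray, spec: PhantomSpec,
               rng: np.random.Generator) -> np.ndarray:
    if spec.noise_sigma == 0.0:
        return values.copy()
    if spec.noise_model == "gaussian":
        return values + rng.normal(0.0, spec.noise_sigma, values.shape)
    n1 = rng.normal(0.0, spec.noise_sigma, values.shape)
    n2 = rng.normal(0.0, spec.noise_sigma, values.shape)
    return np.sqrt((values + n1) ** 2 + n2 ** 2)


def _slab_average_z(vol: Volume, thickness_mm: float) -> Volume:
    """Thick-slice acquisition surrogate: box-average along the z axis."""
    dz = vol.voxel_size_mm[2]
    factor = max(1, int(round(thickness_mm / dz)))
    if factor == 1:
        return vol
    nz = vol.shape[2] // factor
    v = vol.values[:, :, :nz * factor]
    slabs = v.reshape(v.shape[0], v.shape[1], nz, factor).mean(axis=3)
    aff = vol.affine.copy()
    shift = aff[:3, 2] * (factor - 1) / 2.0
    aff[:3, 2] *= factor
    aff[:3, 3] += shift
    return Volume(slabs, aff)


# ---------------------------------------------------------------------------
# Value-level cohort simulation
# ---------------------------------------------------------------------------

@dataclass
class GroupParams:
    n: int
    ratio_mean: float
    ratio_sd: float
    volume_mean: float
    volume_sd: float
    age_mean: float = 60.0
    age_sd: float = 10.0
    male_frac: float = 0.5
    duration_median: float | None = None

    def __post_init__(self) -> None:
        if self.n < 1:
            raise SyntheticError("group size must be >= 1")
        if min(self.ratio_sd, self.volume_sd, self.age_sd) < 0:
            raise SyntheticError("SDs must be nonnegative")


def default_group_params() -> dict[str, GroupParams]:
    """Group parameters from the published cohort summary."""
    out = {}
    for g in reference.GROUPS:
        rm, rs = reference.RATIO_MOMENTS[g]
        vm, vs = reference.VOLUME_MOMENTS[g]
        am, asd = reference.AGE_MOMENTS[g]
        males, females = reference.SEX_COUNTS[g]
        out[g] = GroupParams(
            n=reference.GROUP_SIZES[g],
            ratio_mean=rm, ratio_sd=rs,
            volume_mean=vm, volume_sd=vs,
            age_mean=am, age_sd=asd,
            male_frac=males / (males + females),
            duration_median=reference.DURATION_MEDIANS.get(g),
        )
    return out


@dataclass
class CohortSpec:
    """Specification of a value-level cohort draw."""

    groups: dict[str, GroupParams] = dc_field(default_factory=default_group_params)
    #: correlation between the ratio value and the normalized volume
    ratio_volume_corr: float = 0.6
    #: strength of the (inverse, monotone-noisy) link between the ratio and
    #: the ordinal 0-3 hyperintensity-extent score
    extent_corr: float = 0.8
    #: log-scale SD of the disease-duration draw
    duration_log_sd: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        for rho in (self.ratio_volume_corr, self.extent_corr):
            if not -1.0 <= rho <= 1.0:
                raise SyntheticError("correlations must lie in [-1, 1]")


#: standard-normal quartile cuts mapping a latent severity to scores 0-3
_EXTENT_CUTS = (-0.6745, 0.0, 0.6745)


def simulate_value_cohort(spec: CohortSpec | None = None) -> pd.DataFrame:
    """Draw one subject table from Gaussian group distributions.

    One row per subject: group, MCP sT1w/T2w ratio, ICV-normalized MCP
    volume (correlated with the ratio), ordinal 0-3 hyperintensity-extent
    score inversely and noisily linked to the ratio, plus age, sex and
    disease duration.  Reproducible under ``spec.seed``.
    """
    spec = spec or CohortSpec()
    rng = np.random.default_rng(spec.seed)
    rho_v, rho_e = spec.ratio_volume_corr, spec.extent_corr
    rows = []
    sid = 0
    for group, gp in spec.groups.items():
        z1 = rng.standard_normal(gp.n)
        z2 = rng.standard_normal(gp.n)
        z3 = rng.standard_normal(gp.n)
        ratio = gp.ratio_mean + gp.ratio_sd * z1
        volume = gp.volume_mean + gp.volume_sd * (
            rho_v * z1 + np.sqrt(1.0 - rho_v ** 2) * z2)
        latent = -rho_e * z1 + np.sqrt(1.0 - rho_e ** 2) * z3
        extent = np.digitize(latent, _EXTENT_CUTS)
        age = gp.age_mean + gp.age_sd * rng.standard_normal(gp.n)
        sex = np.where(rng.random(gp.n) < gp.male_frac, "M", "F")
        if gp.duration_median is not None:
            duration = np.exp(np.log(gp.duration_median)
                              + spec.duration_log_sd * rng.standard_normal(gp.n))
        else:
            duration = np.full(gp.n, np.nan)
        for i in range(gp.n):
            rows.append({
                "subject_id": f"S{sid:04d}", "group": group,
                "mcp_ratio": ratio[i], "mcp_volume_norm": volume[i],
                "extent_score": int(extent[i]), "age": age[i],
                "sex": sex[i], "disease_duration": duration[i],
            })
            sid += 1
    return pd.DataFrame(rows)


def phantom_cohort_specs(n_per_group: dict[str, int], seed: int = 0,
                         **phantom_kwargs) -> list[tuple[str, str, PhantomSpec]]:
    """Per-subject phantom specs with MCP targets drawn from group moments.

    Returns (subject_id, group, PhantomSpec) triples; each subject's
    ``mcp_target_ratio`` is a Normal draw from the published per-group ratio
    moments and each phantom gets an independent child seed.
    """
    rng = np.random.default_rng(seed)
    out = []
    sid = 0
    for group, n in n_per_group.items():
        mean, sd = reference.RATIO_MOMENTS[group]
        for _ in range(n):
            target = float(np.clip(rng.normal(mean, sd), -0.9, 0.9))
            child_seed = int(rng.integers(0, 2 ** 31 - 1))
            out.append((f"S{sid:04d}", group,
                        PhantomSpec(mcp_target_ratio=target, seed=child_seed,
                                    **phantom_kwargs)))
            sid += 1
    return out


# ---------------------------------------------------------------------------
# Reviewer-rating simulation
# ---------------------------------------------------------------------------

@dataclass
class RaterModel:
    """Per-reviewer error model for visual sign ratings.

    ``sensitivity[sign][j]`` / ``specificity[sign][j]`` give reviewer ``j``'s
    probability of calling a truly positive subject positive and a truly
    negative subject negative; ordinal hot-cross-bun grades are perturbed to
    an adjacent grade with probability ``grade_noise``.
    """

    sensitivity: dict[str, tuple[float, ...]] = dc_field(
        default_factory=lambda: {"mcp_hyper": (0.906, 0.969, 0.844)})
    specificity: dict[str, tuple[float, ...]] = dc_field(
        default_factory=lambda: {"mcp_hyper": (0.750, 0.125, 0.875)})
    grade_noise: float = 0.1

    def __post_init__(self) -> None:
        for table in (self.sensitivity, self.specificity):
            for vals in table.values():
                if any(not 0.0 <= v <= 1.0 for v in vals):
                    raise SyntheticError(
                        "sensitivity/specificity must lie in [0, 1]")
        if not 0.0 <= self.grade_noise <= 1.0:
            raise SyntheticError("grade_noise must lie in [0, 1]")

    @property
    def n_raters(self) -> int:
        return len(next(iter(self.sensitivity.values())))


def simulate_ratings(truth: pd.DataFrame, model: RaterModel,
                     seed: int = 0) -> pd.DataFrame:
    """Simulate reviewer ratings from per-subject truth.

    ``truth`` holds one column of 0/1 truth per binary sign named in the
    model, and optionally an integer ``hcb_grade`` column (0/1/2) for the
    ordinal sign.  Output columns are ``{sign}_rater{j}``; flips are
    independent Bernoulli draws governed by the model and reproducible
    under ``seed``.
    """
    rng = np.random.default_rng(seed)
    out = pd.DataFrame(index=truth.index)
    for sign, sens in model.sensitivity.items():
        spec = model.specificity[sign]
        t = truth[sign].to_numpy().astype(bool)
        for j in range(len(sens)):
            u = rng.random(t.size)
            call_pos = np.where(t, u < sens[j], u < 1.0 - spec[j])
            out[f"{sign}_rater{j + 1}"] = call_pos.astype(int)
    if "hcb_grade" in truth.columns:
        g = truth["hcb_grade"].to_numpy().astype(int)
        for j in range(model.n_raters):
            flip = rng.random(g.size) < model.grade_noise
            step = np.where(rng.random(g.size) < 0.5, -1, 1)
            rated = np.clip(g + np.where(flip, step, 0), 0, 2)
            out[f"hcb_grade_rater{j + 1}"] = rated
    return out
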