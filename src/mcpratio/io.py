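"""Formats, configuration, and the end-to-end pipeline composition.

NIfTI-1 volumes (plain or gzipped) are read and written through nibabel with
lossless round-trip of data and affine; cohorts, ratings and evaluation
tables are CSV with a header row; run configuration is a flat ``key = value``
text format whose unknown keys are rejected.  :func:`run_all` ties the stages
together: phantom simulation -> preprocessing -> ratio pipeline -> value-level
cohort -> reviewer simulation -> diagnostic evaluation, all deterministic
under a single seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from . import diagnostics, reference, synthetic
from .preprocess import Volume
from .ratio import process_subject
from .synthetic import (CohortSpec, ProbAtlas, RaterModel, make_atlas,
                        make_phantom, phantom_cohort_specs,
                        simulate_ratings, simulate_value_cohort)

logger = logging.getLogger("mcpratio")


class VolumeFormatError(IOError):
    """Raised when a volume file is missing, truncated, or malformed."""


class ConfigError(ValueError):
    """Raised on unknown or ill-typed configuration keys."""


# ---------------------------------------------------------------------------
# NIfTI IO
# ---------------------------------------------------------------------------

def read_volume(path) -> Volume:
    """Load a NIfTI-1 volume (plain ``.nii`` or gzipped ``.nii.gz``)."""
    path = Path(path)
    if not path.exists():
        raise VolumeFormatError(f"no such file: {path}")
    try:
        img = nib.load(str(path))
        data = np.asarray(img.get_fdata(dtype=np.float64))
        affine = np.asarray(img.affine, dtype=float)
    except VolumeFormatError:
        raise
    except Exception as exc:  # nibabel raises several unrelated types here
        raise VolumeFormatError(f"cannot read NIfTI volume {path}: {exc}") from exc
    if data.ndim != 3:
        raise VolumeFormatError(f"{path} is not a 3-D volume (ndim={data.ndim})")
    return Volume(data, affine)


def write_volume(volume: Volume, path) -> None:
    """Write a volume as NIfTI-1; float64 data are preserved bit-exactly."""
    img = nib.Nifti1Image(volume.values.astype(np.float64), volume.affine)
    img.header.set_data_dtype(np.float64)
    img.to_filename(str(path))


def read_atlas(path) -> ProbAtlas:
    """Load a two-channel (left/right) probabilistic atlas from 4-D NIfTI."""
    path = Path(path)
    try:
        img = nib.load(str(path))
        data = np.asarray(img.get_fdata(dtype=np.float64))
    except Exception as exc:
        raise VolumeFormatError(f"cannot read atlas {path}: {exc}") from exc
    if data.ndim != 4 or data.shape[3] != 2:
        raise VolumeFormatError("atlas must be 4-D with two channels (left, right)")
    return ProbAtlas(data[..., 0], data[..., 1], np.asarray(img.affine, float))


def write_atlas(atlas: ProbAtlas, path) -> None:
    data = np.stack([atlas.left, atlas.right], axis=-1)
    img = nib.Nifti1Image(data.astype(np.float64), atlas.affine)
    img.header.set_data_dtype(np.float64)
    img.to_filename(str(path))


def write_transform(transform, path) -> None:
    """Serialize a rigid transform as a 6-number text record."""
    np.savetxt(path, transform.as_params().reshape(1, 6),
               header="rx_deg ry_deg rz_deg tx_mm ty_mm tz_mm")


def read_transform(path):
    from .preprocess import RigidTransform
    params = np.loadtxt(path).reshape(6)
    return RigidTransform.from_params(params)


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Fully resolved parameters of one end-to-end run."""

    seed: int = 0
    #: phantom subjects simulated per diagnostic group (imaging arm)
    subjects_per_group: int = 2
    #: preprocessing mode: generator truth masks ("oracle") or estimated
    mode: str = "oracle"
    fwhm_mm: float = 8.0
    atlas_threshold: float = 0.90
    noise_sigma: float = 4.0
    bias_amplitude: float = 0.1
    grid_size: int = 64
    voxel_mm: float = 2.0
    #: correlation between ratio and volume in the value-level cohort
    ratio_volume_corr: float = 0.6
    extent_corr: float = 0.8

    def __post_init__(self) -> None:
        if self.mode not in ("oracle", "estimate"):
            raise ConfigError(f"unknown preprocessing mode {self.mode!r}")
        if self.subjects_per_group < 1:
            raise ConfigError("subjects_per_group must be >= 1")


def read_config(path) -> RunConfig:
    """Parse a flat ``key = value`` configuration file."""
    fields = {f.name: f for f in dataclasses.fields(RunConfig)}
    kwargs = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ConfigError(f"{path}:{lineno}: expected 'key = value'")
        key, value = (part.strip() for part in line.split("=", 1))
        if key not in fields:
            raise ConfigError(f"{path}:{lineno}: unknown key {key!r}")
        ftype = fields[key].type
        try:
            if ftype == "int":
                kwargs[key] = int(value)
            elif ftype == "float":
                kwargs[key] = float(value)
            else:
                kwargs[key] = value
        except ValueError as exc:
            raise ConfigError(f"{path}:{lineno}: bad value for {key}") from exc
    return RunConfig(**kwargs)


def write_config(config: RunConfig, path) -> None:
    lines = [f"{f.name} = {getattr(config, f.name)}"
             for f in dataclasses.fields(RunConfig)]
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Reviewer-rating truth and evaluation
# ---------------------------------------------------------------------------

def rating_truth(cohort: pd.DataFrame) -> pd.DataFrame:
    """Ground-truth visual signs for the rating simulator.

    MCP hyperintensity is truly present in MSA-C; the hot-cross-bun grade is
    2 in MSA-C, 1 in SCA3 (where a vertical pontine hyperintensity occurs)
    and 0 elsewhere.  Controls are not rated (excluded by the caller).
    """
    truth = pd.DataFrame(index=cohort.index)
    truth["mcp_hyper"] = (cohort["group"] == "MSA-C").astype(int)
    truth["hcb_grade"] = np.select(
        [cohort["group"] == "MSA-C", cohort["group"] == "SCA3"], [2, 1], 0)
    return truth


def _summary_row(sign, comparison, rater, name, est):
    return {"sign": sign, "comparison": f"{comparison[0]} vs {comparison[1]}",
            "rater": rater, "metric": name,
            "pct": None if est is None else est.pct,
            "ci_lo_pct": None if est is None else est.ci_lo_pct,
            "ci_hi_pct": None if est is None else est.ci_hi_pct}


def evaluate_cohort(cohort: pd.DataFrame, ratings: pd.DataFrame | None = None
                    ) -> dict:
    """Diagnostic evaluation of a value-level cohort.

    Produces ROC/AUC (DeLong SE and CI) and the closest-to-corner cutoff for
    the ratio and the normalized volume on every pairwise group comparison,
    the group-comparison suite, per-group Grubbs outlier screening, and —
    when ratings are supplied — per-reviewer confusion metrics and the ICC.
    """
    roc_rows = []
    for marker, col in (("ratio", "mcp_ratio"), ("volume", "mcp_volume_norm")):
        for pos, neg in reference.COMPARISONS:
            sub = cohort[cohort["group"].isin([pos, neg])]
            labels = (sub["group"] == pos).to_numpy()
            roc = diagnostics.roc_auc(sub[col].to_numpy(), labels,
                                      direction="lower")
            cut = diagnostics.optimal_cutoff(roc)
            roc_rows.append({
                "marker": marker, "comparison": f"{pos} vs {neg}",
                "auc": roc.auc, "auc_se": roc.auc_se,
                "ci_lo": roc.ci95[0], "ci_hi": roc.ci95[1],
                "cutoff": cut.threshold, "sensitivity": cut.sensitivity,
                "specificity": cut.specificity,
            })
    report: dict = {"roc": pd.DataFrame(roc_rows)}

    report["group_comparisons"] = diagnostics.group_comparisons(cohort)

    grubbs_rows = []
    for group, sub in cohort.groupby("group"):
        res = diagnostics.grubbs(sub["mcp_ratio"].to_numpy())
        grubbs_rows.append({"group": group, "G": res.g_statistic,
                            "critical": res.critical_value,
                            "outlier_flagged": res.flagged_index is not None})
    report["grubbs"] = pd.DataFrame(grubbs_rows)

    if ratings is not None:
        rated = cohort["group"] != "Control"
        summary_rows = []
        for pos, neg in (("MSA-C", "SCA3"), ("MSA-C", "SCA6"), ("SCA3", "SCA6")):
            in_comp = cohort["group"].isin([pos, neg]) & rated
            truth_pos = (cohort.loc[in_comp, "group"] == pos).to_numpy()
            for sign in ("mcp_hyper", "hcb_grade2", "hcb_grade12"):
                for rater in (1, 2, 3):
                    if sign == "mcp_hyper":
                        col = f"mcp_hyper_rater{rater}"
                        if col not in ratings:
                            continue
                        called = ratings.loc[in_comp, col].to_numpy() == 1
                    else:
                        col = f"hcb_grade_rater{rater}"
                        if col not in ratings:
                            continue
                        grade = ratings.loc[in_comp, col].to_numpy()
                        called = (grade >= 2 if sign == "hcb_grade2"
                                  else grade >= 1)
                    table = diagnostics.ConfusionTable(
                        tp=int((called & truth_pos).sum()),
                        fn=int((~called & truth_pos).sum()),
                        fp=int((called & ~truth_pos).sum()),
                        tn=int((~called & ~truth_pos).sum()))
                    summary = diagnostics.confusion_metrics(table)
                    for name in ("sensitivity", "specificity", "ppv", "npv",
                                 "accuracy"):
                        summary_rows.append(_summary_row(
                            sign, (pos, neg), rater, name,
                            getattr(summary, name)))
        report["reviewer_summary"] = pd.DataFrame(summary_rows)

        icc_rows = []
        for sign, cols in (("mcp_hyper", [f"mcp_hyper_rater{j}" for j in (1, 2, 3)]),
                           ("hcb_grade", [f"hcb_grade_rater{j}" for j in (1, 2, 3)])):
            if all(c in ratings for c in cols):
                mat = ratings.loc[rated, cols].to_numpy()
                res = diagnostics.icc(mat)
                icc_rows.append({"sign": sign, "icc": res.icc,
                                 "variant": res.variant,
                                 "n_subjects": res.n_subjects,
                                 "n_raters": res.n_raters})
        report["icc"] = pd.DataFrame(icc_rows)
    return report


# ---------------------------------------------------------------------------
# End-to-end run
# ---------------------------------------------------------------------------

def run_all(config: RunConfig, out_dir=None) -> dict:
    """Simulation -> preprocessing -> ratio -> evaluation, one seed.

    Returns the in-memory results (DataFrames and the evaluation report);
    when ``out_dir`` is given, also writes cohort_images.csv,
    cohort_values.csv, ratings.csv, roc_summary.csv, reviewer_summary.csv,
    icc.csv, grubbs.csv, report.json and the resolved config.
    """
    root = np.random.default_rng(config.seed)
    image_seed = int(root.integers(0, 2 ** 31 - 1))
    cohort_seed = int(root.integers(0, 2 ** 31 - 1))
    rating_seed = int(root.integers(0, 2 ** 31 - 1))

    logger.info("run_all: seed=%d mode=%s grid=%d", config.seed, config.mode,
                config.grid_size)

    # --- imaging arm: phantoms through the full ratio pipeline
    shape = (config.grid_size,) * 3
    voxel = (config.voxel_mm,) * 3
    atlas = make_atlas(shape, voxel)
    n_per_group = {g: config.subjects_per_group for g in reference.GROUPS}
    specs = phantom_cohort_specs(
        n_per_group, seed=image_seed, grid_shape=shape, voxel_size_mm=voxel,
        noise_sigma=config.noise_sigma, bias_amplitude=config.bias_amplitude)
    image_rows = []
    for subject_id, group, spec in specs:
        phantom = make_phantom(spec)
        try:
            row = process_subject(phantom, atlas, mode=config.mode,
                                  fwhm_mm=config.fwhm_mm,
                                  threshold=config.atlas_threshold)
        except Exception as exc:
            raise RuntimeError(
                f"pipeline failed at subject {subject_id} "
                f"(stage: ratio pipeline): {exc}") from exc
        row.update(subject_id=subject_id, group=group,
                   target_ratio=spec.mcp_target_ratio)
        image_rows.append(row)
        logger.info("subject %s (%s): mcp_value=%.4f (target %.4f)",
                    subject_id, group, row["mcp_value"], spec.mcp_target_ratio)
    images = pd.DataFrame(image_rows)

    # --- value arm: published-moment cohort, ratings, evaluation
    cohort = simulate_value_cohort(CohortSpec(
        ratio_volume_corr=config.ratio_volume_corr,
        extent_corr=config.extent_corr, seed=cohort_seed))
    truth = rating_truth(cohort)
    rated = cohort["group"] != "Control"
    ratings = simulate_ratings(truth[rated], RaterModel(), seed=rating_seed)
    ratings = ratings.reindex(cohort.index)

    evaluation = evaluate_cohort(cohort, ratings)

    results = {"images": images, "cohort": cohort, "ratings": ratings,
               "evaluation": evaluation, "config": config}
    if out_dir is not None:
        _write_outputs(results, out_dir)
    return results


def _json_safe(obj):
    if isinstance(obj, dict):
        return {k: _json_safe(v) for k, v in obj.items()}
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    return obj


def _write_outputs(results: dict, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    float_fmt = "%.10g"
    results["images"].to_csv(out / "cohort_images.csv", index=False,
                             float_format=float_fmt)
    results["cohort"].to_csv(out / "cohort_values.csv", index=False,
                             float_format=float_fmt)
    results["ratings"].to_csv(out / "ratings.csv", index=False)
    ev = results["evaluation"]
    ev["roc"].to_csv(out / "roc_summary.csv", index=False, float_format=float_fmt)
    ev["grubbs"].to_csv(out / "grubbs.csv", index=False, float_format=float_fmt)
    if "reviewer_summary" in ev:
        ev["reviewer_summary"].to_csv(out / "reviewer_summary.csv", index=False,
                                      float_format=float_fmt)
    if "icc" in ev:
        ev["icc"].to_csv(out / "icc.csv", index=False, float_format=float_fmt)
    with open(out / "report.json", "w") as fh:
        json.dump(_json_safe(ev), fh, indent=2)
    write_config(results["config"], out / "resolved_config.txt")
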