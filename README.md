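# mcpratio

Standardized T1w/T2w ratio biomarker for the **middle cerebellar peduncle
(MCP)**: a quantitative MRI pipeline plus the full diagnostic-evaluation
statistics, exercised on synthetic multi-contrast phantoms so that every
stage is testable without patient data.

## The problem

The cerebellar subtype of multiple system atrophy (MSA-C) and the
spinocerebellar ataxias SCA3 and SCA6 all present with cerebellar ataxia,
but MSA-C degenerates the pontocerebellar fibers of the MCP early and
severely. Visual signs on T2-weighted MRI (MCP hyperintensities, the
"hot cross bun" sign) capture this but are qualitative and rater-dependent.
The standardized T1w/T2w ratio turns the two routine clinical contrasts into
a quantitative, scanner-comparable marker of that degeneration.

## The method

For each subject, with `s` the gray-matter-median scaling factor

```
s   = median(T1w | GM) / median(T2w | GM)
sT2 = s · T2w
sT1w/T2w = (T1w − sT2) / (T1w + sT2)        ∈ (−1, 1)
```

the ratio map is smoothed with an 8-mm FWHM Gaussian kernel and the left and
right MCP are parcellated from a probabilistic atlas at a 90% probability
threshold; the subject's **MCP sT1w/T2w value** is the mean of the two ROI
medians. Because `s` rescales with the inputs, the map is invariant to
independent global rescaling of T1w and T2w — the property that makes values
comparable across subjects and scanners. The **MCP volume** is the
thresholded-atlas volume divided by the intracranial volume (reported as
m × 10⁻³). Myelin loss and gliosis drive the MCP value *down*, so lower
values indicate disease.

The package contains five parts:

| module | contents |
|---|---|
| `mcpratio.synthetic` | brain phantoms with exact ground truth, the probabilistic MCP atlas, value-level cohort simulation from published group moments, reviewer-rating simulation |
| `mcpratio.preprocess` | bias-field estimation/correction, rigid registration, skull-stripping, tissue segmentation (desk-scale stand-ins for the usual external tools) |
| `mcpratio.ratio` | scaling factor, ratio map, smoothing, atlas-ROI medians, ICV-normalized volume, end-to-end subject processing |
| `mcpratio.diagnostics` | ROC/AUC with DeLong variance and test, closest-to-corner cutoff, Clopper–Pearson CIs, exact binomial comparisons, ICC, Smirnov–Grubbs, ANCOVA/Kruskal–Wallis/chi-square suite |
| `mcpratio.io` / `mcpratio.cli` | NIfTI-1 and CSV formats, flat key=value configs, `mcpratio` command line |

## Worked example

```python
import mcpratio as m

spec = m.PhantomSpec(mcp_target_ratio=0.07, seed=42)   # an MSA-C-like subject
phantom = m.make_phantom(spec)
atlas = m.make_atlas(spec.grid_shape, spec.voxel_size_mm)
row = m.process_subject(phantom, atlas, mode="estimate")
print(f"scaling factor s        : {row['s']:.3f}")
print(f"MCP medians (L, R)      : {row['mcp_left']:.4f}, {row['mcp_right']:.4f}")
print(f"MCP sT1w/T2w value      : {row['mcp_value']:.4f}")
print(f"normalized MCP volume   : {row['mcp_volume_norm']:.3f}")
```

prints

```
scaling factor s        : 1.411
MCP medians (L, R)      : 0.0580, 0.0579
MCP sT1w/T2w value      : 0.0579
normalized MCP volume   : 0.338
```

The phantom was built so that a noise-free run returns exactly 0.07; with
the default noise and bias field and fully *estimated* preprocessing the
pipeline lands within 0.02 of it (here 0.058), and in `mode="oracle"`
(generator truth masks) within a few thousandths. A value near 0.06 sits in
the MSA-C range, far below the ≈0.17–0.19 typical of SCA3/SCA6/controls; the
normalized volume 0.338 matches healthy anatomy (≈0.34).

The same run is available from the shell:

```bash
mcpratio phantom --out ph --seed 3 --target-ratio 0.17     # an SCA3-like subject
mcpratio ratio run --t1w ph/t1w.nii.gz --t2w ph/t2w.nii.gz \
    --atlas ph/atlas.nii.gz --out sub1
# subject: MCP sT1w/T2w = 0.1576 (left 0.1567, right 0.1585)

mcpratio run-all --out results --seed 5    # phantoms + cohort + full evaluation
mcpratio ratio evaluate --cohort results/cohort_values.csv \
    --simulate-ratings --out eval
#  ratio MSA-C vs SCA3      AUC 0.996 (95% CI 0.985-1.000) cutoff 0.138 ...
```

`run-all` writes per-subject imaging measurements, a value-level cohort
drawn from the published group moments (32 MSA-C / 8 SCA3 / 16 SCA6 /
17 controls), simulated reviewer ratings, and the evaluation tables
(ROC summaries, per-reviewer diagnostic metrics with exact CIs, ICC,
outlier screening).

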