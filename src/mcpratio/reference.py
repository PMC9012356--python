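"""Published cohort summary used as simulation inputs and evaluation fixtures.

The study cohort behind the MCP sT1w/T2w biomarker (32 MSA-C, 8 SCA3,
16 SCA6 patients and 17 controls) is private; what is public is its summary:
group sizes and demographics, per-group moments of the MCP sT1w/T2w ratio and
of the ICV-normalized MCP volume, and the per-reviewer visual-rating
performance table for MCP hyperintensities and the hot-cross-bun (HCB) sign.
These numbers are the inputs the synthetic cohort generator and the
diagnostic-evaluation checks run from.

Percent cells with a zero denominator (e.g. PPV when a reviewer made no
positive call) are stored as ``None``: no point estimate is defined there.
"""

from __future__ import annotations

GROUPS = ("MSA-C", "SCA3", "SCA6", "Control")

GROUP_SIZES = {"MSA-C": 32, "SCA3": 8, "SCA6": 16, "Control": 17}

#: Mean and SD of the MCP sT1w/T2w ratio per group (dimensionless).
RATIO_MOMENTS = {
    "MSA-C": (0.07, 0.06),
    "SCA3": (0.17, 0.03),
    "SCA6": (0.18, 0.03),
    "Control": (0.19, 0.03),
}

#: Mean and SD of the ICV-normalized MCP volume per group (ratio x 10^3).
VOLUME_MOMENTS = {
    "MSA-C": (0.20, 0.06),
    "SCA3": (0.23, 0.04),
    "SCA6": (0.31, 0.05),
    "Control": (0.34, 0.05),
}

#: Age at MRI, mean and SD in years.
AGE_MOMENTS = {
    "MSA-C": (62.8, 9.4),
    "SCA3": (51.4, 16.7),
    "SCA6": (58.3, 13.7),
    "Control": (62.4, 10.8),
}

#: Male / female counts.
SEX_COUNTS = {
    "MSA-C": (19, 13),
    "SCA3": (2, 6),
    "SCA6": (10, 6),
    "Control": (9, 8),
}

#: Median disease duration in years (patients only).
DURATION_MEDIANS = {"MSA-C": 2.3, "SCA3": 4.5, "SCA6": 3.5}

#: Pairwise group comparisons evaluated with ROC analysis; the first group
#: is the "diseased" (positive) class and carries the lower biomarker value.
COMPARISONS = (
    ("MSA-C", "SCA3"),
    ("MSA-C", "SCA6"),
    ("MSA-C", "Control"),
    ("SCA3", "SCA6"),
)

#: Reported whole-cohort AUCs of the ratio and the normalized volume.
REPORTED_AUC = {
    "ratio": {
        ("MSA-C", "SCA3"): 0.934,
        ("MSA-C", "SCA6"): 0.965,
        ("MSA-C", "Control"): 0.980,
        ("SCA3", "SCA6"): 0.633,
    },
    "volume": {
        ("MSA-C", "SCA3"): 0.664,
        ("MSA-C", "SCA6"): 0.924,
        ("MSA-C", "Control"): 0.967,
        ("SCA3", "SCA6"): 0.914,
    },
}

VISUAL_SIGNS = ("mcp_hyper", "hcb_grade2", "hcb_grade12")

#: Reviewer performance: {sign: {(pos_group, neg_group): {reviewer: row}}}
#: with row = (sensitivity, specificity, ppv, npv, accuracy) in percent.
#: ``None`` marks an undefined (zero-denominator) cell.
REVIEWER_PERFORMANCE = {
    "mcp_hyper": {
        ("MSA-C", "SCA3"): {
            1: (90.6, 75.0, 93.5, 66.7, 87.5),
            2: (96.9, 12.5, 81.6, 50.0, 80.0),
            3: (84.4, 87.5, 96.4, 58.3, 85.0),
        },
        ("MSA-C", "SCA6"): {
            1: (90.6, 100.0, 100.0, 84.2, 93.8),
            2: (96.9, 100.0, 100.0, 94.1, 97.9),
            3: (84.4, 100.0, 100.0, 76.2, 89.6),
        },
        ("SCA3", "SCA6"): {
            1: (25.0, 100.0, 100.0, 72.7, 75.0),
            2: (87.5, 100.0, 100.0, 94.1, 95.8),
            3: (12.5, 100.0, 100.0, 69.6, 70.8),
        },
    },
    "hcb_grade2": {
        ("MSA-C", "SCA3"): {
            1: (59.4, 100.0, 100.0, 38.1, 67.5),
            2: (81.2, 100.0, 100.0, 57.1, 85.0),
            3: (75.0, 87.5, 96.0, 46.7, 77.5),
        },
        ("MSA-C", "SCA6"): {
            1: (59.4, 100.0, 100.0, 55.2, 72.9),
            2: (81.2, 100.0, 100.0, 72.7, 87.5),
            3: (75.0, 100.0, 100.0, 66.7, 83.3),
        },
        ("SCA3", "SCA6"): {
            1: (0.0, 100.0, None, 66.7, 66.7),
            2: (0.0, 100.0, None, 66.7, 66.7),
            3: (12.5, 100.0, 100.0, 69.6, 70.8),
        },
    },
    "hcb_grade12": {
        ("MSA-C", "SCA3"): {
            1: (87.5, 12.5, 80.0, 20.0, 72.5),
            2: (93.8, 0.0, 78.9, 0.0, 75.0),
            3: (100.0, 0.0, 80.0, None, 80.0),
        },
        ("MSA-C", "SCA6"): {
            1: (87.5, 93.8, 96.6, 78.9, 89.6),
            2: (93.8, 93.8, 96.8, 88.2, 93.8),
            3: (100.0, 31.2, 74.4, 100.0, 77.1),
        },
        ("SCA3", "SCA6"): {
            1: (87.5, 93.8, 87.5, 93.8, 91.7),
            2: (100.0, 93.8, 88.9, 100.0, 95.8),
            3: (100.0, 31.2, 42.1, 100.0, 54.2),
        },
    },
}

#: Reported reviewer-1 operating point of the ratio ROC (MSA-C vs SCA3).
REPORTED_RATIO_OPERATING_POINT = {"sensitivity": 0.906, "specificity": 0.875}

#: Multiple-comparison correction used for post-hoc pairwise tests.
PAIRWISE_ALPHA = 0.05
N_PAIRWISE = 3


def reconstruct_counts(sensitivity_pct: float, specificity_pct: float,
                       n_pos: int, n_neg: int) -> tuple[int, int, int, int]:
    """Back out (tp, fn, fp, tn) from percent sensitivity/specificity.

    With the published group sizes the mapping is unique: the true-positive
    count is the integer in [0, n_pos] whose percentage rounds back to the
    printed value (and likewise for true negatives).
    """
    tp = round(sensitivity_pct / 100.0 * n_pos)
    tn = round(specificity_pct / 100.0 * n_neg)
    return tp, n_pos - tp, n_neg - tn, tn
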