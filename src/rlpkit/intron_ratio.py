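"""Detained-intron quantification.

For a constitutive intron k of a gene's designated transcript, the per-cell
intron ratio is the intron's mean read coverage normalized by the average
of the mean coverages of the two flanking exons (exon k and exon k+1 in
transcript order):

    ratio = mean_cov(intron_k) / ((mean_cov(exon_k) + mean_cov(exon_k+1)) / 2)

The ratio is invariant to per-cell sequencing depth, so cross-cell depth
normalization is unnecessary. Group contrasts (e.g. S vs G2/M phase) use a
two-sided Mann-Whitney U test on per-cell ratios.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .transcript_io import TranscriptModel

COVERAGE_COLUMNS = ["cell_id", "gene_id", "feature", "mean_coverage"]


def intron_ratio(
    coverage: pd.DataFrame,
    model: TranscriptModel,
    intron_index: int,
) -> tuple[pd.Series, list[str]]:
    """Per-cell detained-intron ratio for intron ``intron_index`` (1-based,
    transcript order).

    ``coverage`` is a FeatureCoverage table with columns
    cell_id, gene_id, feature, mean_coverage where feature names follow
    ``intron_k`` / ``exon_k`` (1-based, transcript order). Cells where both
    flanking exon means are zero are undefined: excluded from the returned
    series and listed separately.
    """
    n_introns = len(model.exons) - 1
    if not 1 <= intron_index <= n_introns:
        raise IndexError(
            f"intron {intron_index} out of range for "
            f"{model.transcript_id} ({n_introns} introns)"
        )
    missing = [c for c in COVERAGE_COLUMNS if c not in coverage.columns]
    if missing:
        raise ValueError(f"coverage table missing columns {missing}")
    sub = coverage[coverage["gene_id"] == model.gene_id]
    if np.any(sub["mean_coverage"] < 0):
        raise ValueError("mean_coverage must be nonnegative")
    wide = sub.pivot_table(
        index="cell_id", columns="feature", values="mean_coverage"
    )
    needed = [f"intron_{intron_index}", f"exon_{intron_index}",
              f"exon_{intron_index + 1}"]
    for feat in needed:
        if feat not in wide.columns:
            raise KeyError(f"feature {feat} absent for gene {model.gene_id}")
    intron = wide[needed[0]]
    flank = (wide[needed[1]] + wide[needed[2]]) / 2.0
    defined = flank > 0
    ratios = (intron[defined] / flank[defined]).rename(
        f"{model.gene_id}:intron_{intron_index}"
    )
    undefined = list(wide.index[~defined])
    return ratios, undefined


def compare_groups(
    ratios: pd.Series,
    labels: pd.Series,
    pseudocount: float = 0.01,
) -> dict:
    """Two-sided Mann-Whitney U between the two label groups.

    Returns the U statistic, p value and the fold change of group medians
    (first label group over second, in sorted label order). When either
    median is zero, ``pseudocount`` is added to both medians and the result
    is flagged.
    """
    common = ratios.index.intersection(labels.index)
    r = ratios.loc[common]
    lab = labels.loc[common]
    groups = sorted(lab.unique())
    if len(groups) != 2:
        raise ValueError(f"need exactly two groups, got {groups}")
    a = r[lab == groups[0]].dropna().to_numpy(dtype=float)
    b = r[lab == groups[1]].dropna().to_numpy(dtype=float)
    if min(len(a), len(b)) < 3:
        raise ValueError("need >= 3 cells with defined ratios per group")
    u, p = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    med_a, med_b = float(np.median(a)), float(np.median(b))
    guarded = med_a == 0 or med_b == 0
    if guarded:
        fold = (med_a + pseudocount) / (med_b + pseudocount)
    else:
        fold = med_a / med_b
    return {
        "group_a": groups[0], "group_b": groups[1],
        "n_a": len(a), "n_b": len(b),
        "median_a": med_a, "median_b": med_b,
        "fold_change": float(fold), "pseudocount_used": guarded,
        "U": float(u), "pvalue": float(p),
    }
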