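"""Per-gene differential expression between single-infected and mixed
cultures, with Benjamini-Hochberg FDR control.

The default per-gene test is the two-sided Mann-Whitney, consistent with
the nonparametric tests used elsewhere in the pipeline; a Welch t-test on
log counts is available as an option.  Effect size is a pseudocount-
stabilized log2 fold change of group means on standardized counts.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .dataio import CountMatrix


def log2_fold_change(mean_a, mean_b, pseudocount: float = 0.5) -> np.ndarray:
    """log2((mean_b + c) / (mean_a + c)); b is conventionally "mixed"."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    a = np.asarray(mean_a, dtype=float)
    b = np.asarray(mean_b, dtype=float)
    return np.log2((b + pseudocount) / (a + pseudocount))


def de_test(
    matrix: CountMatrix,
    groups: pd.Series,
    alpha: float = 0.05,
    method: str = "mannwhitney",
    pseudocount: float = 0.5,
    reference: str | None = None,
) -> pd.DataFrame:
    """Per-gene two-group test with BH adjustment across the organism.

    ``groups`` maps sample ids to two labels; ``reference`` names the
    baseline label (group A of the fold change), defaulting to the first
    label in ``groups`` order.  Returns a DataFrame indexed by gene with
    columns log2fc, p, q, class ('up'/'down'/'ns'): class is non-'ns' iff
    q < alpha, with the sign taken from log2fc.
    """
    labels = groups.loc[matrix.sample_ids]
    levels = list(pd.unique(labels))
    if len(levels) != 2:
        raise ValueError(f"expected 2 groups, got {levels}")
    if reference is None:
        reference = levels[0]
    other = levels[1] if levels[0] == reference else levels[0]
    samples_a = [s for s in matrix.sample_ids if labels[s] == reference]
    samples_b = [s for s in matrix.sample_ids if labels[s] == other]
    if len(samples_a) < 3 or len(samples_b) < 3:
        raise ValueError("each group needs n >= 3")
    A = matrix.counts[samples_a].to_numpy(dtype=float)
    B = matrix.counts[samples_b].to_numpy(dtype=float)
    lfc = log2_fold_change(A.mean(axis=1), B.mean(axis=1), pseudocount)

    pvals = np.ones(len(lfc))
    for i in range(A.shape[0]):
        a, b = A[i], B[i]
        if np.ptp(np.concatenate([a, b])) == 0:
            pvals[i] = 1.0
        elif method == "mannwhitney":
            pvals[i] = stats.mannwhitneyu(a, b, alternative="two-sided").pvalue
        elif method == "welch":
            pvals[i] = stats.ttest_ind(
                np.log2(a + pseudocount), np.log2(b + pseudocount), equal_var=False
            ).pvalue
        else:
            raise ValueError(f"unknown method {method!r}")
    q = bh_adjust(pvals)
    cls = np.where(q < alpha, np.where(lfc > 0, "up", "down"), "ns")
    return pd.DataFrame(
        {"log2fc": lfc, "p": pvals, "q": q, "class": cls}, index=matrix.gene_ids
    )


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    return multipletests(np.asarray(pvals, dtype=float), method="fdr_bh")[1]


def volcano_table(results: pd.DataFrame, path: str | Path) -> Path:
    """Write a volcano-plot table (gene, log2fc, -log10 q, class) sorted by
    q, with up/down counts in a header comment."""
    path = Path(path)
    out = results.sort_values("q").copy()
    with np.errstate(divide="ignore"):
        out["neg_log10_q"] = -np.log10(out["q"])
    n_up = int((results["class"] == "up").sum())
    n_down = int((results["class"] == "down").sum())
    with open(path, "w") as fh:
        fh.write(f"# up={n_up}\tdown={n_down}\tns={len(results) - n_up - n_down}\n")
        out[["log2fc", "neg_log10_q", "class"]].rename_axis("gene_id").to_csv(
            fh, sep="\t"
        )
    return path
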