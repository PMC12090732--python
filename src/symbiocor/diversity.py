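"""Shannon diversity of gene expression per sample, group comparisons, and
the diversity-diversity regression.

The Shannon index is computed on each sample's gene-count distribution:
H = -sum p_i ln p_i over genes with nonzero counts, natural log by default.
Used here as a per-sample measure of how evenly an organism spreads its
transcription across its genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .dataio import CountMatrix
from .standardize import TestResult, mann_whitney


def shannon(counts, base: float | None = None) -> float:
    """Shannon index of a nonnegative count vector.

    ``base=None`` means natural log (nats).  Zero entries carry no weight;
    an all-zero vector is an error.
    """
    arr = np.asarray(counts, dtype=float)
    if arr.ndim != 1:
        raise ValueError("counts must be a 1-D vector")
    if (arr < 0).any():
        raise ValueError("counts must be nonnegative")
    if arr.sum() == 0:
        raise ValueError("all-zero count vector has undefined diversity")
    return float(stats.entropy(arr, base=base))


def sample_diversity(matrix: CountMatrix, base: float | None = None) -> pd.Series:
    """Per-sample Shannon index over the organism's gene-count distribution."""
    return pd.Series(
        {s: shannon(matrix.counts[s].to_numpy(), base=base) for s in matrix.sample_ids},
        name=f"H_{matrix.organism}",
    )


def compare_diversity(values: pd.Series, groups: pd.Series) -> TestResult:
    """Mann-Whitney for two groups, tie-corrected Kruskal-Wallis for >= 3."""
    labels = groups.loc[values.index]
    groupvals = [values[labels == g].to_numpy() for g in pd.unique(labels)]
    if len(groupvals) < 2:
        raise ValueError("need at least 2 groups")
    for g, v in zip(pd.unique(labels), groupvals):
        if len(v) < 2:
            raise ValueError(f"group {g!r} has n < 2")
    if len(groupvals) == 2:
        return mann_whitney(groupvals[0], groupvals[1])
    if np.ptp(np.concatenate(groupvals)) == 0:  # scipy rejects all-tied input
        return TestResult("kruskal-wallis", 0.0, 1.0)
    h, p = stats.kruskal(*groupvals)
    return TestResult("kruskal-wallis", float(h), float(p))


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r2: float
    f: float
    df: tuple[int, int]
    p: float
    x: np.ndarray
    fitted: np.ndarray
    ci_low: np.ndarray  # 95% confidence band for the mean
    ci_high: np.ndarray
    pi_low: np.ndarray  # 95% prediction band
    pi_high: np.ndarray


def regress_diversity(x, y, alpha: float = 0.05) -> RegressionResult:
    """OLS of one organism's Shannon index on another's, with F-test and
    95% confidence and prediction bands evaluated at the observed x."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need >= 3 paired values")
    if np.ptp(x) == 0:
        raise ValueError("x has zero variance")
    X = sm.add_constant(x)
    fit = sm.OLS(y, X).fit()
    pred = fit.get_prediction(X)
    frame = pred.summary_frame(alpha=alpha)
    return RegressionResult(
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        r2=float(fit.rsquared),
        f=float(fit.fvalue),
        df=(int(fit.df_model), int(fit.df_resid)),
        p=float(fit.f_pvalue),
        x=x,
        fitted=np.asarray(frame["mean"]),
        ci_low=np.asarray(frame["mean_ci_lower"]),
        ci_high=np.asarray(frame["mean_ci_upper"]),
        pi_low=np.asarray(frame["obs_ci_lower"]),
        pi_high=np.asarray(frame["obs_ci_upper"]),
    )
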