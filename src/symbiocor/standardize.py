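"""Library-size standardization and symbiont/host read proportions.

Standardization is rarefaction: every sample is subsampled without
replacement (multivariate hypergeometric) to the smallest sample total, so
counts stay integers and the zero pattern can only grow, never shrink.
Read proportions are computed on UNstandardized counts, as ratios of
organism read totals per sample.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

from .dataio import CountMatrix, SampleTable


@dataclass
class TestResult:
    """Outcome of a rank-based two-group (or k-group) comparison."""

    test: str  # "mann-whitney" | "kruskal-wallis"
    statistic: float  # U (min convention) or Kruskal-Wallis H
    p: float
    z: float | None = None  # normal-approximation z where applicable
    exact: bool = False


def downsample_to_min(matrix: CountMatrix, seed: int) -> CountMatrix:
    """Rarefy every sample to the minimum sample total.

    Each sample's counts are drawn without replacement from its own reads
    (multivariate hypergeometric), so the expected downsampled count is
    ``count * min_total / sample_total``.  A sample already at the minimum
    is returned unchanged.  Deterministic per seed.
    """
    totals = matrix.sample_totals()
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(
            f"cannot downsample: sample(s) with zero total reads: {list(zero.index)}"
        )
    min_total = int(totals.min())
    rng = np.random.default_rng(seed)
    out = {}
    for sample in matrix.sample_ids:
        col = matrix.counts[sample].to_numpy()
        if col.sum() == min_total:
            out[sample] = col
        else:
            out[sample] = rng.multivariate_hypergeometric(col, min_total)
    return CountMatrix(
        matrix.organism,
        pd.DataFrame(out, index=matrix.gene_ids, columns=matrix.sample_ids),
    )


def symbiont_host_proportion(sym: CountMatrix, host: CountMatrix) -> pd.Series:
    """Per-sample ratio of symbiont read total to host read total.

    Computed on unstandardized counts; samples must be aligned.
    """
    if list(sym.sample_ids) != list(host.sample_ids):
        raise ValueError("symbiont and host matrices must share aligned samples")
    host_tot = host.sample_totals()
    zero = host_tot[host_tot == 0]
    if len(zero):
        raise ValueError(f"host total is zero for sample(s): {list(zero.index)}")
    return sym.sample_totals() / host_tot


def _mannwhitney_exact(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided exact Mann-Whitney by full enumeration of group
    assignments; handles ties.  Returns (U_min, p)."""
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    n1, n2 = len(x), len(y)
    n = n1 + n2

    def u_min(idx: tuple[int, ...]) -> float:
        r1 = ranks[list(idx)].sum()
        u1 = r1 - n1 * (n1 + 1) / 2
        return min(u1, n1 * n2 - u1)

    observed = u_min(tuple(range(n1)))
    count = sum(
        1 for idx in combinations(range(n), n1) if u_min(idx) <= observed + 1e-12
    )
    return observed, count / comb(n, n1)


def mann_whitney(x, y) -> TestResult:
    """Two-sided Mann-Whitney U.

    Exact by full enumeration when both groups have n <= 8, else the
    tie-corrected normal approximation.  The reported U follows the
    min(U1, U2) convention.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs n >= 2")
    u1 = stats.mannwhitneyu(x, y, method="asymptotic", alternative="two-sided")
    u_min = min(u1.statistic, len(x) * len(y) - u1.statistic)
    mu = len(x) * len(y) / 2
    # tie-corrected variance for the z report
    pooled = np.concatenate([x, y])
    n = len(pooled)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (n * (n - 1))
    var = len(x) * len(y) / 12 * (n + 1 - tie_term)
    z = (u1.statistic - mu) / np.sqrt(var) if var > 0 else 0.0
    if len(x) <= 8 and len(y) <= 8:
        u_exact, p = _mannwhitney_exact(x, y)
        return TestResult("mann-whitney", u_exact, min(p, 1.0), z=z, exact=True)
    return TestResult("mann-whitney", u_min, float(u1.pvalue), z=z, exact=False)


def compare_proportions(props: pd.Series, groups: pd.Series) -> TestResult:
    """Compare symbiont/host read proportions between two sample groups."""
    labels = groups.loc[props.index] if hasattr(groups, "loc") else pd.Series(groups)
    levels = pd.unique(labels)
    if len(levels) != 2:
        raise ValueError(f"expected exactly 2 groups, got {list(levels)}")
    a = props[labels == levels[0]].to_numpy()
    b = props[labels == levels[1]].to_numpy()
    if len(a) == 0 or len(b) == 0:
        raise ValueError("a group is empty")
    return mann_whitney(a, b)
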