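"""All-pairs Spearman correlation networks between gene sets with
permutation p-values.

Rho uses average ranks on ties (Pearson on ranks).  Significance is by
permuting sample labels of one gene set: exact enumeration of all n!
permutations when n <= 7, otherwise Monte Carlo with the +1-corrected
estimator p = (1 + #{|rho_b| >= |rho_obs|}) / (B + 1).  A whole network
shares one permutation index stream, so results are reproducible per seed
and all pairs are evaluated against the same null draws.

Edges with p < alpha are split by the sign of rho into per-gene profiles;
genes with extreme edge counts are flagged by Tukey fences; profiles can be
clustered hierarchically (Ward or UPGMA) and networks reduced to edge lists
at a |rho| quantile cutoff.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import permutations as iter_permutations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

logger = logging.getLogger("symbiocor")

EXACT_MAX_N = 7  # n! <= 5040: enumerate instead of sampling


def _rank_rows(mat: np.ndarray) -> np.ndarray:
    return np.apply_along_axis(stats.rankdata, 1, mat)


def _standardize_rows(ranks: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Center/scale rank rows; returns (standardized, constant-row mask)."""
    centered = ranks - ranks.mean(axis=1, keepdims=True)
    norms = np.sqrt((centered**2).sum(axis=1))
    constant = norms == 0
    norms[constant] = 1.0
    return centered / norms[:, None], constant


def spearman_rho(x, y) -> float:
    """Spearman correlation with average ranks on ties."""
    rx = stats.rankdata(np.asarray(x, dtype=float))
    ry = stats.rankdata(np.asarray(y, dtype=float))
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        raise ValueError("constant vector: correlation undefined")
    return float(np.corrcoef(rx, ry)[0, 1])


def _permutation_set(
    n: int, B: int, rng: np.random.Generator
) -> tuple[np.ndarray, bool]:
    """All n! permutations when n <= EXACT_MAX_N, else B random ones."""
    if n <= EXACT_MAX_N:
        return np.array(list(iter_permutations(range(n)))), True
    return np.array([rng.permutation(n) for _ in range(B)]), False


def correlate_pair(
    x, y, B: int = 9999, seed: int = 0
) -> tuple[float, float]:
    """Spearman rho and two-sided permutation p for one gene pair.

    Exact over all n! permutations of y when n <= 7 (p = k / n!, the
    identity permutation included); Monte Carlo with the +1 correction
    otherwise, so p >= 1/(B+1).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n != len(y) or n < 4:
        raise ValueError("need equal-length vectors with n >= 4")
    rho = spearman_rho(x, y)
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    perms, exact = _permutation_set(n, B, np.random.default_rng(seed))
    rx_std = (rx - rx.mean()) / np.sqrt(((rx - rx.mean()) ** 2).sum())
    ry_std = (ry - ry.mean()) / np.sqrt(((ry - ry.mean()) ** 2).sum())
    null = ry_std[perms] @ rx_std
    hits = int((np.abs(null) >= abs(rho) - 1e-12).sum())
    if exact:
        return rho, hits / len(perms)
    return rho, (1 + hits) / (len(perms) + 1)


@dataclass
class CorrelationNetwork:
    """Spearman rho and permutation p between two gene sets."""

    rho: pd.DataFrame  # rows = set 1 genes, cols = set 2 genes
    p: pd.DataFrame
    alpha: float
    B: int
    seed: int
    condition: str = ""
    exact: bool = False
    excluded_rows: list[str] = field(default_factory=list)
    excluded_cols: list[str] = field(default_factory=list)

    def significant(self) -> pd.DataFrame:
        return self.p < self.alpha

    def transpose(self) -> "CorrelationNetwork":
        return CorrelationNetwork(
            self.rho.T, self.p.T, self.alpha, self.B, self.seed, self.condition,
            self.exact, self.excluded_cols, self.excluded_rows,
        )


def cross_network(
    matA,
    matB,
    B: int = 9999,
    alpha: float = 0.05,
    seed: int = 0,
    condition: str = "",
) -> CorrelationNetwork:
    """All row-gene x col-gene Spearman correlations with permutation p.

    ``matA`` and ``matB`` are genes x samples DataFrames (or CountMatrix)
    over the same aligned samples.  Genes constant across samples are
    excluded and logged.  One shared permutation stream drives every pair.
    """
    dfA = matA.counts if hasattr(matA, "counts") else pd.DataFrame(matA)
    dfB = matB.counts if hasattr(matB, "counts") else pd.DataFrame(matB)
    if list(dfA.columns) != list(dfB.columns):
        raise ValueError("matrices must share aligned samples")
    n = dfA.shape[1]
    if n < 4:
        raise ValueError(f"need >= 4 shared samples, got {n}")

    ranksA = _rank_rows(dfA.to_numpy(dtype=float))
    ranksB = _rank_rows(dfB.to_numpy(dtype=float))
    stdA, constA = _standardize_rows(ranksA)
    stdB, constB = _standardize_rows(ranksB)
    rowsA = dfA.index[~constA]
    rowsB = dfB.index[~constB]
    if constA.any():
        logger.warning("excluding %d constant gene(s) in %s", constA.sum(), condition or "set1")
    if constB.any():
        logger.warning("excluding %d constant gene(s) in %s", constB.sum(), condition or "set2")
    stdA = stdA[~constA]
    stdB = stdB[~constB]

    rho = stdA @ stdB.T
    perms, exact = _permutation_set(n, B, np.random.default_rng(seed))
    hits = np.zeros_like(rho, dtype=np.int64)
    thresh = np.abs(rho) - 1e-12
    for perm in perms:
        null = stdA @ stdB[:, perm].T
        hits += np.abs(null) >= thresh
    if exact:
        p = hits / len(perms)
    else:
        p = (1 + hits) / (len(perms) + 1)
    return CorrelationNetwork(
        rho=pd.DataFrame(rho, index=rowsA, columns=rowsB),
        p=pd.DataFrame(p, index=rowsA, columns=rowsB),
        alpha=alpha,
        B=len(perms) if not exact else B,
        seed=seed,
        condition=condition,
        exact=exact,
        excluded_rows=list(dfA.index[constA]),
        excluded_cols=list(dfB.index[constB]),
    )


def signed_counts(
    net: CorrelationNetwork,
) -> tuple[int, int, pd.DataFrame]:
    """Totals and per-row-gene counts of significant positive/negative edges.

    Edges with rho == 0 count in neither class.
    """
    sig = net.significant().to_numpy()
    rho = net.rho.to_numpy()
    pos = sig & (rho > 0)
    neg = sig & (rho < 0)
    profiles = pd.DataFrame(
        {
            "n_pos": pos.sum(axis=1),
            "n_neg": neg.sum(axis=1),
        },
        index=net.rho.index,
    )
    if net.condition:
        profiles["condition"] = net.condition
    return int(pos.sum()), int(neg.sum()), profiles


def detect_outliers(
    profiles: pd.DataFrame, fence_factor: float = 1.5
) -> pd.DataFrame:
    """Flag genes whose edge counts exceed the Tukey upper fence.

    ``profiles``: genes x numeric count columns (one per count type /
    condition).  A gene is an outlier if any column value exceeds
    Q3 + fence_factor * IQR of that column.  Returns the input with
    ``outlier`` and ``triggered_by`` columns appended.
    """
    numeric = profiles.select_dtypes(include=[np.number])
    if len(numeric) < 5:
        raise ValueError("need at least 5 profiles")
    out = profiles.copy()
    triggers = pd.Series([[] for _ in range(len(out))], index=out.index, dtype=object)
    for col in numeric.columns:
        q1, q3 = np.percentile(numeric[col], [25, 75])
        fence = q3 + fence_factor * (q3 - q1)
        for g in numeric.index[numeric[col] > fence]:
            triggers[g] = triggers[g] + [col]
    out["outlier"] = triggers.map(bool)
    out["triggered_by"] = triggers.map(",".join)
    return out


def cluster_profiles(
    profiles: pd.DataFrame,
    method: str = "ward",
    distance: str = "euclidean",
    k: int = 2,
) -> tuple[pd.Series, np.ndarray]:
    """Agglomerative clustering of gene edge-count profiles.

    method: 'ward' or 'upgma' (average linkage); distance: 'euclidean' or
    'bray_curtis'.  Returns (labels in 1..k, scipy linkage matrix).
    """
    numeric = profiles.select_dtypes(include=[np.number])
    n = len(numeric)
    if k > n:
        raise ValueError(f"k={k} exceeds number of profiles n={n}")
    metric = {"euclidean": "euclidean", "bray_curtis": "braycurtis"}[distance]
    scipy_method = {"ward": "ward", "upgma": "average"}[method]
    d = pdist(numeric.to_numpy(dtype=float), metric=metric)
    Z = linkage(d, method=scipy_method)
    labels = fcluster(Z, t=k, criterion="maxclust")
    return pd.Series(labels, index=numeric.index, name="cluster"), Z


def edge_list(net: CorrelationNetwork, cutoff_quantile: float = 0.75) -> pd.DataFrame:
    """Significant edges with |rho| at or above the given quantile of the
    significant |rho| distribution.  Empty networks give an empty list."""
    sig = net.significant()
    rows = []
    abs_sig = np.abs(net.rho.to_numpy()[sig.to_numpy()])
    if abs_sig.size == 0:
        return pd.DataFrame(columns=["gene1", "gene2", "rho", "p", "sign"])
    threshold = np.quantile(abs_sig, cutoff_quantile)
    for g1 in net.rho.index:
        for g2 in net.rho.columns:
            if sig.at[g1, g2] and abs(net.rho.at[g1, g2]) >= threshold - 1e-12:
                r = net.rho.at[g1, g2]
                rows.append((g1, g2, r, net.p.at[g1, g2], "+" if r > 0 else "-"))
    return pd.DataFrame(rows, columns=["gene1", "gene2", "rho", "p", "sign"])
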