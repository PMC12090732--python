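"""Per-pathway partial dbRDA effect profiles and K-means clustering.

For every host pathway, a distance-based redundancy model asks how much of
the pathway's expression variation (Bray-Curtis distance over the pathway's
host genes) is explained by forward-selected symbiont genes, separately for
each model condition: symbiont A or B in single-infected cultures, symbiont
A or B in mixed cultures, and both symbionts together in mixed cultures.
The resulting pathways x conditions matrix of explained variability (R2)
is then clustered by K-means to group pathways with similar symbiont
control profiles.
"""

from __future__ import annotations

from dataclasses import dataclass
import logging

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_samples

from .dataio import AnnotationMap, CountMatrix, SampleTable
from .ordination import bray_curtis, forward_select

logger = logging.getLogger("symbiocor")

# condition -> (statuses of samples used, symbiont organisms providing predictors)
MODEL_CONDITIONS: dict[str, tuple[tuple[str, ...], tuple[str, ...]]] = {
    "symA_single": (("singleA",), ("symA",)),
    "symB_single": (("singleB",), ("symB",)),
    "symA_mixed": (("mixed",), ("symA",)),
    "symB_mixed": (("mixed",), ("symB",)),
    "both": (("mixed",), ("symA", "symB")),
}


@dataclass
class PathwayEffectMatrix:
    r2: pd.DataFrame  # pathways x model conditions
    selected: dict[tuple[str, str], list[str]]  # (pathway, condition) -> genes
    skipped: list[str]  # pathways with < 2 mapped genes


@dataclass
class PathwayClustering:
    labels: pd.Series  # pathway -> 1..k
    silhouettes: pd.Series
    wgss: float
    pseudo_f: float
    pct_variance: float
    avg_silhouette: float
    k: int


def pathway_effects(
    host: CountMatrix,
    annotation: AnnotationMap,
    symbionts: dict[str, CountMatrix],
    meta: SampleTable,
    pathways: list[str] | None = None,
    B: int = 199,
    alpha: float = 0.01,
    seed: int = 0,
    max_predictors: int = 4,
) -> PathwayEffectMatrix:
    """Build the pathways x conditions explained-variability matrix.

    For each cell: response = Bray-Curtis distances over the pathway's host
    genes in the condition's samples; candidate predictors = the stated
    symbiont organism(s)' gene expression in those samples; predictors are
    reduced by forward selection (permutation p < alpha, at most
    ``max_predictors``); the cell holds the final model's R2, 0.0 when no
    predictor enters.  The default entry threshold is stricter than the
    usual 0.05 because each model screens the symbiont's whole gene set;
    without it, spurious single-gene fits inflate noise pathways.
    Pathways mapping to < 2 host genes are skipped with a warning.
    """
    if pathways is None:
        pathways = annotation.pathway_ids
    if not pathways:
        raise ValueError("empty pathway list")
    rng = np.random.default_rng(seed)
    cells: dict[str, dict[str, float]] = {}
    selected: dict[tuple[str, str], list[str]] = {}
    skipped: list[str] = []
    for pw in pathways:
        genes = annotation.genes_in_pathway(pw, host.gene_ids)
        if len(genes) < 2:
            logger.warning("pathway %s maps to %d gene(s); skipped", pw, len(genes))
            skipped.append(pw)
            continue
        cells[pw] = {}
        for cond, (statuses, orgs) in MODEL_CONDITIONS.items():
            samples = meta.samples_with_status(*statuses)
            if len(samples) < 4:  # no usable model for this condition
                cells[pw][cond] = float("nan")
                continue
            sub_host = host.counts.loc[genes, samples]
            if (sub_host.sum(axis=0) == 0).any():
                cells[pw][cond] = float("nan")
                continue
            D = bray_curtis(sub_host.T)
            pred_frames = []
            for org in orgs:
                sym = symbionts[org].counts.loc[:, samples].T
                sym = sym.loc[:, sym.std(axis=0) > 0]
                pred_frames.append(sym.add_prefix(f"{org}:"))
            candidates = pd.concat(pred_frames, axis=1)
            # rank candidates by marginal Spearman link to the pathway's
            # first distance axis to bound the forward-selection search
            if candidates.shape[1] > 3 * max_predictors:
                from .ordination import pcoa

                axis1 = pcoa(D).coordinates[:, 0]
                score = candidates.apply(
                    lambda col: abs(pd.Series(col.values).corr(pd.Series(axis1), method="spearman"))
                )
                candidates = candidates[score.nlargest(3 * max_predictors).index]
            fs = forward_select(
                D,
                candidates,
                alpha=alpha,
                B=B,
                seed=int(rng.integers(2**31 - 1)),
                use_adjr2_guard=False,
                max_terms=max_predictors,
            )
            if fs.final is None:
                cells[pw][cond] = 0.0
                selected[(pw, cond)] = []
            else:
                cells[pw][cond] = fs.final.r2
                selected[(pw, cond)] = fs.selected
    r2 = pd.DataFrame.from_dict(cells, orient="index").reindex(
        columns=list(MODEL_CONDITIONS)
    )
    return PathwayEffectMatrix(r2, selected, skipped)


def cluster_pathways(
    effects: pd.DataFrame | PathwayEffectMatrix,
    k: int | None = None,
    seed: int = 0,
    n_init: int = 10,
    k_range: tuple[int, int] = (2, 8),
) -> PathwayClustering:
    """K-means on pathway R2 profiles with silhouette-based diagnostics.

    When ``k`` is None, it is chosen to maximize the average silhouette
    over ``k_range`` (bounded by the number of pathways).  Reports
    within-group sum of squares (WGSS), pseudo-F, percent variance
    explained and average silhouette.
    """
    X = effects.r2 if isinstance(effects, PathwayEffectMatrix) else effects
    X = X.dropna(axis=1, how="all").dropna()
    n = len(X)
    arr = X.to_numpy(dtype=float)
    if k is not None and (k < 2 or k > n):
        raise ValueError(f"k must be in [2, {n}], got {k}")
    if n < 2:
        raise ValueError("need >= 2 pathways")

    def fit(kk: int) -> tuple[KMeans, np.ndarray]:
        km = KMeans(n_clusters=kk, n_init=n_init, random_state=seed).fit(arr)
        sil = silhouette_samples(arr, km.labels_)
        return km, sil

    if k is None:
        best = None
        for kk in range(k_range[0], min(k_range[1], n - 1) + 1):
            km, sil = fit(kk)
            if best is None or sil.mean() > best[2].mean():
                best = (kk, km, sil)
        k, km, sil = best
    else:
        km, sil = fit(k)

    wgss = float(km.inertia_)
    tss = float(((arr - arr.mean(axis=0)) ** 2).sum())
    bgss = tss - wgss
    pseudo_f = (bgss / (k - 1)) / (wgss / (n - k)) if wgss > 0 and n > k else float("inf")
    return PathwayClustering(
        labels=pd.Series(km.labels_ + 1, index=X.index, name="cluster"),
        silhouettes=pd.Series(sil, index=X.index, name="silhouette"),
        wgss=wgss,
        pseudo_f=pseudo_f,
        pct_variance=100 * bgss / tss if tss > 0 else 0.0,
        avg_silhouette=float(sil.mean()),
        k=k,
    )
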