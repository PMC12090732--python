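"""Distance matrices and distance-based multivariate models.

Implements the beta-diversity toolkit used to relate gene-expression
profiles to experimental factors:

* Bray-Curtis dissimilarity for standardized counts and robust Aitchison
  distance (robust centered log-ratio with zeros treated as missing) for
  unstandardized counts;
* principal coordinates analysis (Gower double-centering); axes with
  negative eigenvalues are reported but discarded, without correction;
* distance-based redundancy analysis (dbRDA): PCoA coordinates regressed
  on predictor columns, optionally after partialling out conditioning
  variables; explained variability R2 = constrained / total inertia;
  significance by a permutation pseudo-F (rows of the response permuted
  freely, or residuals permuted under the conditioning model);
* forward selection of predictors by permutation p, with an adjusted-R2
  stopping guard;
* ANOSIM on rank-transformed distances with pairwise Bonferroni tests;
* SIMPER decomposition of the average between-group Bray-Curtis
  dissimilarity into per-variable contributions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations, permutations as iter_permutations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

EIG_TOL = 1e-10


@dataclass
class DistanceMatrix:
    sample_ids: list[str]
    d: np.ndarray  # symmetric, zero diagonal
    metric: str

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        if d.shape != (len(self.sample_ids), len(self.sample_ids)):
            raise ValueError("distance matrix shape does not match sample ids")
        if not np.allclose(d, d.T):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(d), 0):
            raise ValueError("distance matrix diagonal is not zero")
        if (d < -1e-12).any():
            raise ValueError("negative distances")
        self.d = d

    @property
    def n(self) -> int:
        return len(self.sample_ids)


def _as_samples_by_features(matrix) -> tuple[np.ndarray, list[str]]:
    """Accept CountMatrix (genes x samples) or DataFrame/array of samples x
    features; return (samples x features array, sample ids)."""
    if hasattr(matrix, "counts"):  # CountMatrix
        return matrix.counts.to_numpy(dtype=float).T, list(matrix.counts.columns)
    df = pd.DataFrame(matrix)
    return df.to_numpy(dtype=float), [str(i) for i in df.index]


def bray_curtis(matrix) -> DistanceMatrix:
    """Bray-Curtis dissimilarity between samples.

    d(j,k) = sum_i |y_ij - y_ik| / sum_i (y_ij + y_ik).
    """
    y, ids = _as_samples_by_features(matrix)
    if (y < 0).any():
        raise ValueError("Bray-Curtis requires nonnegative values")
    totals = y.sum(axis=1)
    if (totals == 0).any():
        bad = [ids[i] for i in np.flatnonzero(totals == 0)]
        raise ValueError(f"all-zero sample(s): {bad}")
    d = squareform(pdist(y, metric="braycurtis"))
    return DistanceMatrix(ids, d, "bray_curtis")


def robust_aitchison(matrix) -> DistanceMatrix:
    """Robust Aitchison distance on unstandardized counts.

    Each sample gets a robust centered log-ratio: log of its positive
    counts minus the mean log over its positive counts, zeros treated as
    missing.  Pairwise distance is Euclidean over features positive in both
    samples, scaled by sqrt(n_features / n_shared) to stay comparable
    across pairs with different overlap.  Reduces to classical CLR +
    Euclidean on zero-free data.
    """
    y, ids = _as_samples_by_features(matrix)
    if (y < 0).any():
        raise ValueError("counts must be nonnegative")
    n, m = y.shape
    if (y.sum(axis=1) == 0).any():
        bad = [ids[i] for i in np.flatnonzero(y.sum(axis=1) == 0)]
        raise ValueError(f"sample(s) with no positive feature: {bad}")
    logs = np.full_like(y, np.nan, dtype=float)
    np.log(y, out=logs, where=y > 0)
    rclr = logs - np.nanmean(logs, axis=1, keepdims=True)
    pos = y > 0
    d = np.zeros((n, n))
    for j in range(n):
        for k in range(j + 1, n):
            shared = pos[j] & pos[k]
            ns = int(shared.sum())
            if ns == 0:
                raise ValueError(
                    f"samples {ids[j]!r} and {ids[k]!r} share no positive feature"
                )
            diff = rclr[j, shared] - rclr[k, shared]
            d[j, k] = d[k, j] = math.sqrt((diff**2).sum() * m / ns)
    return DistanceMatrix(ids, d, "robust_aitchison")


def euclidean(matrix) -> DistanceMatrix:
    y, ids = _as_samples_by_features(matrix)
    return DistanceMatrix(ids, squareform(pdist(y)), "euclidean")


@dataclass
class PCoAResult:
    sample_ids: list[str]
    coordinates: np.ndarray  # samples x retained axes, scaled by sqrt(eigval)
    eigenvalues: np.ndarray  # retained (positive) eigenvalues, descending
    negative_eigenvalues: np.ndarray
    total_inertia: float  # sum of retained positive eigenvalues


def pcoa(D: DistanceMatrix) -> PCoAResult:
    """Principal coordinates: Gower double-centering + eigendecomposition.

    Axes with eigenvalue <= EIG_TOL are dropped; negative eigenvalues are
    reported for diagnostics.  Total inertia is the positive-eigenvalue sum
    and is what dbRDA partitions downstream.
    """
    n = D.n
    A = -0.5 * D.d**2
    J = np.eye(n) - np.ones((n, n)) / n
    G = J @ A @ J
    G = (G + G.T) / 2
    eigval, eigvec = np.linalg.eigh(G)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    keep = eigval > EIG_TOL
    coords = eigvec[:, keep] * np.sqrt(eigval[keep])
    return PCoAResult(
        sample_ids=list(D.sample_ids),
        coordinates=coords,
        eigenvalues=eigval[keep],
        negative_eigenvalues=eigval[eigval < -EIG_TOL],
        total_inertia=float(eigval[keep].sum()),
    )


@dataclass
class OrdinationResult:
    """dbRDA output: inertia partition and permutation test."""

    total_inertia: float
    constrained_inertia: float
    conditioned_inertia: float
    r2: float  # constrained / total (the "explained variability R")
    adjusted_r2: float
    f: float
    p: float
    df: int  # number of constraining columns
    eigenvalues_constrained: np.ndarray = field(default_factory=lambda: np.empty(0))
    site_scores: np.ndarray | None = None
    biplot_scores: np.ndarray | None = None
    predictors: list[str] = field(default_factory=list)
    conditions: list[str] = field(default_factory=list)
    B: int = 0
    seed: int = 0


def _design(X) -> tuple[np.ndarray, list[str]]:
    if X is None:
        return np.empty((0, 0)), []
    df = pd.DataFrame(X)
    return df.to_numpy(dtype=float), [str(c) for c in df.columns]


def _qr_basis(M: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    """Orthonormal basis of the column space (rank-revealing)."""
    if M.size == 0:
        return np.empty((M.shape[0], 0))
    q, r = np.linalg.qr(M)
    diag = np.abs(np.diag(r)) if r.size else np.empty(0)
    keep = diag > tol * max(1.0, diag.max() if diag.size else 1.0)
    return q[:, keep]


def _fstat(
    U: np.ndarray, Qx: np.ndarray, q: int, c: int, total_after_cond: float
) -> tuple[float, float]:
    """Constrained inertia and pseudo-F for (already conditioned) responses
    U against an orthonormal predictor basis Qx."""
    fitted = Qx @ (Qx.T @ U)
    constrained = float((fitted**2).sum())
    n = U.shape[0]
    resid = total_after_cond - constrained
    df_resid = n - q - c - 1
    if df_resid <= 0 or resid <= 0:
        return constrained, math.inf
    return constrained, (constrained / q) / (resid / df_resid)


def dbrda(
    D: DistanceMatrix,
    X,
    condition=None,
    B: int = 999,
    seed: int = 0,
    compute_scores: bool = False,
) -> OrdinationResult:
    """Distance-based redundancy analysis with a permutation pseudo-F test.

    ``X`` (samples x predictors) is regressed against the PCoA coordinates
    of ``D``; ``condition`` columns are partialled out of both first.  The
    permutation scheme permutes response rows freely, or residual rows
    under the conditioning model when ``condition`` is given.
    """
    pc = pcoa(D)
    U = pc.coordinates
    n = U.shape[0]
    Xmat, xnames = _design(X)
    if Xmat.shape[0] != n:
        raise ValueError("X rows must align with samples")
    Zmat, znames = _design(condition)

    ones = np.ones((n, 1))
    Qz = _qr_basis(np.hstack([ones] + ([Zmat] if Zmat.size else [])))
    c = Qz.shape[1] - 1  # conditioning df beyond the intercept
    U_res = U - Qz @ (Qz.T @ U)
    X_res = Xmat - Qz @ (Qz.T @ Xmat)
    Qx = _qr_basis(X_res)
    q = Qx.shape[1]
    if q < Xmat.shape[1]:
        raise ValueError(
            f"rank-deficient predictors: {Xmat.shape[1]} column(s) span only "
            f"{q} dimension(s) after conditioning ({xnames})"
        )
    if q == 0:
        raise ValueError("empty predictor matrix")
    if n <= q + c + 1:
        raise ValueError("not enough samples for the requested model")

    total = pc.total_inertia
    conditioned = total - float((U_res**2).sum())
    total_after_cond = float((U_res**2).sum())
    constrained, f_obs = _fstat(U_res, Qx, q, c, total_after_cond)

    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(B):
        perm = rng.permutation(n)
        _, f_b = _fstat(U_res[perm], Qx, q, c, total_after_cond)
        if f_b >= f_obs - 1e-12:
            hits += 1
    p = (1 + hits) / (B + 1)

    r2 = constrained / total if total > 0 else 0.0
    df_resid = n - q - c - 1
    adj = 1 - (1 - r2) * (n - 1 - c) / df_resid if df_resid > 0 else float("nan")

    eig_c = np.empty(0)
    site = biplot = None
    if compute_scores:
        fitted = Qx @ (Qx.T @ U_res)
        u_svd, s_svd, _ = np.linalg.svd(fitted, full_matrices=False)
        keep = s_svd**2 > EIG_TOL
        eig_c = (s_svd**2)[keep]
        site = u_svd[:, keep] * s_svd[keep]
        if site.shape[1]:
            with np.errstate(invalid="ignore"):
                biplot = np.array(
                    [
                        [
                            np.corrcoef(Xmat[:, j], site[:, a])[0, 1]
                            for a in range(site.shape[1])
                        ]
                        for j in range(Xmat.shape[1])
                    ]
                )
    return OrdinationResult(
        total_inertia=total,
        constrained_inertia=constrained,
        conditioned_inertia=conditioned,
        r2=r2,
        adjusted_r2=adj,
        f=f_obs,
        p=p,
        df=q,
        eigenvalues_constrained=eig_c,
        site_scores=site,
        biplot_scores=biplot,
        predictors=xnames,
        conditions=znames,
        B=B,
        seed=seed,
    )


@dataclass
class ForwardSelectionResult:
    selected: list[str]
    step_p: list[float]
    final: OrdinationResult | None


def forward_select(
    D: DistanceMatrix,
    candidates: pd.DataFrame,
    alpha: float = 0.05,
    B: int = 199,
    seed: int = 0,
    condition=None,
    use_adjr2_guard: bool = True,
    max_terms: int | None = None,
) -> ForwardSelectionResult:
    """Stepwise forward selection of predictor columns by permutation p.

    At each step the candidate with the lowest marginal permutation p
    enters (ties broken by larger marginal R2, then column order);
    selection stops when the best p >= alpha or, with the guard on, when
    the adjusted R2 of the selected model would exceed that of the
    full-candidate model.
    """
    candidates = pd.DataFrame(candidates)
    rng = np.random.default_rng(seed)
    guard = -np.inf
    if use_adjr2_guard and len(candidates.columns) > 1:
        try:
            full = dbrda(D, candidates, condition=condition, B=0, seed=0)
            guard = full.adjusted_r2
        except ValueError:  # full model unfittable (e.g. saturated): no guard
            guard = np.inf
    selected: list[str] = []
    step_p: list[float] = []
    final: OrdinationResult | None = None
    remaining = list(candidates.columns)
    while remaining and (max_terms is None or len(selected) < max_terms):
        best = None
        for col in remaining:
            trial_cols = selected + [col]
            try:
                res = dbrda(
                    D,
                    candidates[trial_cols],
                    condition=condition,
                    B=B,
                    seed=int(rng.integers(2**31 - 1)),
                )
            except ValueError:  # collinear with already-selected: skip
                continue
            key = (res.p, -res.r2)
            if best is None or key < best[0]:
                best = (key, col, res)
        if best is None:
            break
        (p_best, _), col_best, res_best = best
        if p_best >= alpha:
            break
        if use_adjr2_guard and np.isfinite(guard) and res_best.adjusted_r2 > guard:
            break
        selected.append(col_best)
        step_p.append(p_best)
        remaining.remove(col_best)
        final = res_best
    return ForwardSelectionResult(selected, step_p, final)


@dataclass
class AnosimResult:
    R: float
    p: float
    B: int
    exact: bool
    pairwise: pd.DataFrame | None = None  # groups, R, p, p_bonferroni


def _anosim_R(rank_d: np.ndarray, groups: np.ndarray) -> float:
    """R from a condensed vector of distance ranks and group labels."""
    n = len(groups)
    iu = np.triu_indices(n, k=1)
    within = groups[iu[0]] == groups[iu[1]]
    rb = rank_d[~within].mean()
    rw = rank_d[within].mean()
    return (rb - rw) / (n * (n - 1) / 4)


ANOSIM_EXACT_MAX_N = 8


def anosim(
    D: DistanceMatrix,
    groups,
    B: int = 999,
    seed: int = 0,
    pairwise: bool = True,
) -> AnosimResult:
    """Analysis of similarities on rank-transformed distances.

    R = (mean between-group rank - mean within-group rank) / (N(N-1)/4).
    One-sided p by label permutation; full enumeration when N <= 8.
    With more than two groups, pairwise two-group tests are Bonferroni
    adjusted.
    """
    groups = np.asarray(groups)
    if len(groups) != D.n:
        raise ValueError("group labels must align with samples")
    levels, counts = np.unique(groups, return_counts=True)
    if len(levels) < 2:
        raise ValueError("need >= 2 groups")
    if (counts < 2).any():
        bad = levels[counts < 2]
        raise ValueError(f"singleton group(s): {list(bad)}")
    n = D.n
    iu = np.triu_indices(n, k=1)
    rank_d = stats.rankdata(D.d[iu])
    r_obs = _anosim_R(rank_d, groups)

    if n <= ANOSIM_EXACT_MAX_N:
        perms = iter_permutations(range(n))
        hits = total = 0
        for perm in perms:
            total += 1
            if _anosim_R(rank_d, groups[list(perm)]) >= r_obs - 1e-12:
                hits += 1
        p, exact, b_used = hits / total, True, total
    else:
        rng = np.random.default_rng(seed)
        hits = 0
        for _ in range(B):
            if _anosim_R(rank_d, groups[rng.permutation(n)]) >= r_obs - 1e-12:
                hits += 1
        p, exact, b_used = (1 + hits) / (B + 1), False, B

    pw = None
    if pairwise and len(levels) > 2:
        n_pairs = len(levels) * (len(levels) - 1) // 2
        rows = []
        for i, (a, b) in enumerate(combinations(levels, 2)):
            mask = np.isin(groups, [a, b])
            sub = DistanceMatrix(
                [s for s, m in zip(D.sample_ids, mask) if m],
                D.d[np.ix_(mask, mask)],
                D.metric,
            )
            res = anosim(sub, groups[mask], B=B, seed=seed + 1 + i, pairwise=False)
            rows.append((a, b, res.R, res.p, min(1.0, res.p * n_pairs)))
        pw = pd.DataFrame(rows, columns=["group1", "group2", "R", "p", "p_bonferroni"])
    return AnosimResult(float(r_obs), float(p), b_used, exact, pw)


@dataclass
class SimperResult:
    contributions: pd.DataFrame  # variable, contribution, pct, cumulative_pct
    overall_dissimilarity: float


def simper(matrix, groups) -> SimperResult:
    """Per-variable contributions to average between-group Bray-Curtis
    dissimilarity, sorted descending with cumulative percentages.

    Contribution of variable i = mean over between-group sample pairs of
    |y_ij - y_ik| / sum_m (y_mj + y_mk); contributions sum to the average
    between-group dissimilarity.
    """
    y, ids = _as_samples_by_features(matrix)
    if hasattr(matrix, "counts"):
        varnames = list(matrix.counts.index)
    else:
        varnames = list(pd.DataFrame(matrix).columns)
    groups = np.asarray(groups)
    levels = np.unique(groups)
    if len(levels) != 2:
        raise ValueError(f"SIMPER needs exactly 2 groups, got {len(levels)}")
    idx_a = np.flatnonzero(groups == levels[0])
    idx_b = np.flatnonzero(groups == levels[1])
    contrib = np.zeros(y.shape[1])
    n_pairs = 0
    for j in idx_a:
        for k in idx_b:
            denom = (y[j] + y[k]).sum()
            if denom == 0:
                raise ValueError("a between-group pair has zero total")
            contrib += np.abs(y[j] - y[k]) / denom
            n_pairs += 1
    contrib /= n_pairs
    overall = float(contrib.sum())
    df = pd.DataFrame({"variable": varnames, "contribution": contrib})
    df = df.sort_values("contribution", ascending=False, kind="mergesort").reset_index(
        drop=True
    )
    df["pct"] = 100 * df["contribution"] / overall if overall > 0 else 0.0
    df["cumulative_pct"] = df["pct"].cumsum()
    return SimperResult(df, overall)
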