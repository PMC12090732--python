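"""Synthetic tripartite meta-transcriptome generator.

Emulates the study design of two intracellular symbionts (A, Cardinium-like;
B, Wolbachia-like) in a shared arthropod host: two A-single cultures, two
B-single cultures, four mixed cultures, seven replicate flasks each.  Counts
are negative binomial (gamma-Poisson).  Planted structure, all recorded in
:class:`GroundTruth`:

* read proportions: symbiont/host read ratios per culture, with a
  configurable drop of symbiont B in mixed cultures (default 10-fold);
* inter-organism correlations: shared per-sample latent factors acting on
  a "responder" subset of each organism's genes.  Responders carry strong
  positive loadings but are rescaled to a small share of the organism's
  read mass, so the compensating (closure) response of the remaining genes
  stays weak; in mixed samples the latent contribution of a configurable
  fraction of symbiont-B responders is sign-flipped, planting a
  negative-dominated A<->B correlation structure that survives
  library-size standardization;
* differential expression: a set of genes per organism shifted up or down
  (log2 scale) in mixed cultures, with the baseline masses of up and down
  genes balanced so non-shifted genes keep their expected share;
* culture-type composition shifts: per-gene log-normal shifts applied in
  mixed samples, with a larger spread for symbiont A than B by default,
  planting the directional asymmetry in which A's expression responds more
  strongly to B's presence than vice versa;
* pathway structure: host genes in a "linked" subset of pathways carry
  latent loadings (so symbiont expression explains them), the rest are
  noise, planting a two-cluster pathway effect profile.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .dataio import (
    AnnotationMap,
    CountMatrix,
    SampleTable,
    write_annotation,
    write_counts,
    write_sample_table,
)

DEFAULT_CULTURES: tuple[tuple[str, str], ...] = (
    ("5L", "singleA"),
    ("5S", "singleA"),
    ("5N", "singleB"),
    ("5P", "singleB"),
    ("5LN", "mixed"),
    ("5LP", "mixed"),
    ("5SN", "mixed"),
    ("5SP", "mixed"),
)


class ConfigError(ValueError):
    """Invalid generator configuration; the message names the field."""


@dataclass
class SynthConfig:
    """Parameters of the synthetic study.

    Defaults are a desk-scale version of the study design: 8 cultures x 7
    replicate flasks, symbiont read proportions of a few percent of host
    reads, and a 10-fold drop of symbiont B in mixed cultures.
    """

    n_genes_host: int = 60
    n_genes_symA: int = 30
    n_genes_symB: int = 30
    cultures: tuple[tuple[str, str], ...] = DEFAULT_CULTURES
    n_replicates: int = 7
    lib_size_mean: float = 5_000_000.0
    dispersion: float = 0.3
    prop_symA_single: float = 0.05
    prop_symB_single: float = 0.05
    prop_symB_mixed_factor: float = 0.1
    n_latent: int = 1
    latent_sign_mix: float = 0.9
    loading_scale: float = 1.0
    latent_responder_frac: float = 0.75
    latent_responder_mass: float = 0.03
    mixed_shift_sd_symA: float = 1.0
    mixed_shift_sd_symB: float = 0.0
    n_de_genes: int = 6
    de_log2fc: float = 2.0
    depth_sigma: float = 0.1
    n_pathways: int = 8
    pathway_frac_linked: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_genes_host", "n_genes_symA", "n_genes_symB", "n_replicates"):
            if int(getattr(self, name)) < 1:
                raise ConfigError(f"{name} must be >= 1")
        for name in ("lib_size_mean", "dispersion", "loading_scale"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")
        for name in ("prop_symA_single", "prop_symB_single", "prop_symB_mixed_factor"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ConfigError(f"{name} must be in (0, 1]")
        if not 0 <= self.latent_sign_mix <= 1:
            raise ConfigError("latent_sign_mix must be in [0, 1]")
        if self.n_latent < 0:
            raise ConfigError("n_latent must be >= 0")
        if self.n_de_genes < 0:
            raise ConfigError("n_de_genes must be >= 0")
        if self.mixed_shift_sd_symA < 0 or self.mixed_shift_sd_symB < 0:
            raise ConfigError("mixed_shift_sd_* must be >= 0")
        if not 0 <= self.pathway_frac_linked <= 1:
            raise ConfigError("pathway_frac_linked must be in [0, 1]")
        if not 0 < self.latent_responder_frac <= 1:
            raise ConfigError("latent_responder_frac must be in (0, 1]")
        if not 0 < self.latent_responder_mass < 1:
            raise ConfigError("latent_responder_mass must be in (0, 1)")
        statuses = {s for _, s in self.cultures}
        bad = statuses - {"singleA", "singleB", "mixed"}
        if bad:
            raise ConfigError(f"cultures: unknown status values {sorted(bad)}")
        ids = [c for c, _ in self.cultures]
        if len(ids) != len(set(ids)):
            raise ConfigError("cultures: duplicate culture ids")


@dataclass
class GroundTruth:
    """Everything planted by the generator, for downstream recovery checks."""

    de_genes: dict[str, dict[str, int]]  # organism -> gene_id -> +1 / -1
    loadings: dict[str, np.ndarray]  # organism -> (n_genes, n_latent)
    sign_flipped_symB: list[str]  # symB genes with negated latent effect in mixed
    expected_proportions: dict[str, dict[str, float]]  # culture -> {symA, symB}
    pathway_clusters: dict[str, int] = field(default_factory=dict)  # pathway -> 1|2


def _sample_frame(config: SynthConfig) -> pd.DataFrame:
    rows = []
    for culture, status in config.cultures:
        for rep in range(1, config.n_replicates + 1):
            rows.append((f"{culture}_r{rep}", culture, status, rep))
    return pd.DataFrame(rows, columns=["sample_id", "culture", "status", "replicate"])


def _balanced_de_factors(
    rng: np.random.Generator,
    gene_ids: Sequence[str],
    baseline: np.ndarray,
    n_de: int,
    log2fc: float,
    eligible: np.ndarray | None = None,
) -> tuple[np.ndarray, dict[str, int]]:
    """Pick DE genes (half up, half down) and return per-gene fold factors
    applied in mixed samples.  The baselines of the down set are rescaled so
    the expected total mass of the organism is unchanged, which keeps
    non-DE genes' expected shares intact."""
    n_genes = len(gene_ids)
    factors = np.ones(n_genes)
    signs: dict[str, int] = {}
    if n_de == 0 or log2fc == 0:
        return factors, signs
    pool = np.arange(n_genes) if eligible is None or not len(eligible) else eligible
    if n_de > len(pool):
        raise ConfigError(
            "n_de_genes exceeds the genes available outside the latent responder set"
        )
    idx = rng.choice(pool, size=n_de, replace=False)
    up, down = idx[: (n_de + 1) // 2], idx[(n_de + 1) // 2 :]
    factors[up] = 2.0 ** log2fc
    factors[down] = 2.0 ** (-log2fc)
    gain = baseline[up].sum() * (2.0 ** log2fc - 1.0)
    loss_per_unit = 1.0 - 2.0 ** (-log2fc)
    if len(down) and loss_per_unit > 0 and baseline[down].sum() > 0:
        baseline[down] *= gain / (loss_per_unit * baseline[down].sum())
    for i in up:
        signs[gene_ids[i]] = 1
    for i in down:
        signs[gene_ids[i]] = -1
    return factors, signs


def _nb_counts(
    rng: np.random.Generator, mu: np.ndarray, dispersion: float
) -> np.ndarray:
    """Gamma-Poisson draw with var = mu + dispersion * mu^2."""
    if dispersion <= 0:
        return rng.poisson(mu)
    lam = rng.gamma(1.0 / dispersion, dispersion * mu)
    return rng.poisson(lam)


def _build_annotation(
    config: SynthConfig, host_genes: Sequence[str], linked_mask: np.ndarray
) -> tuple[AnnotationMap, dict[str, int]]:
    """Assign host genes to pathways: linked pathways draw from
    latent-loaded genes, the rest from noise genes."""
    if config.n_pathways == 0:
        return AnnotationMap({}, {}, {}), {}
    n_linked_pw = round(config.n_pathways * config.pathway_frac_linked)
    pathway_ids = [f"pw{i:03d}" for i in range(1, config.n_pathways + 1)]
    clusters = {
        pw: (1 if i < n_linked_pw else 2) for i, pw in enumerate(pathway_ids)
    }
    linked_genes = [g for g, m in zip(host_genes, linked_mask) if m]
    noise_genes = [g for g, m in zip(host_genes, linked_mask) if not m]
    gene_to_ko: dict[str, str] = {}
    ko_to_pathways: dict[str, frozenset[str]] = {}
    pathway_names = {pw: f"pathway {pw[2:]}" for pw in pathway_ids}

    def assign(genes: list[str], pws: list[str]) -> None:
        if not pws:
            return
        for i, g in enumerate(genes):
            ko = f"K{len(gene_to_ko):05d}"
            gene_to_ko[g] = ko
            ko_to_pathways[ko] = frozenset({pws[i % len(pws)]})

    assign(linked_genes, [pw for pw in pathway_ids if clusters[pw] == 1])
    assign(noise_genes, [pw for pw in pathway_ids if clusters[pw] == 2])
    return AnnotationMap(gene_to_ko, ko_to_pathways, pathway_names), clusters


def generate_dataset(
    config: SynthConfig,
) -> tuple[dict[str, CountMatrix], SampleTable, AnnotationMap, GroundTruth]:
    """Generate count matrices, metadata, annotation and ground truth.

    Deterministic for a fixed ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    meta_df = _sample_frame(config)
    n_samples = len(meta_df)
    status = meta_df["status"].to_numpy()
    is_mixed = status == "mixed"
    has_A = (status == "singleA") | is_mixed
    has_B = (status == "singleB") | is_mixed

    gene_ids = {
        "host": [f"mite{i:05d}" for i in range(1, config.n_genes_host + 1)],
        "symA": [f"cA{i:04d}" for i in range(1, config.n_genes_symA + 1)],
        "symB": [f"wB{i:04d}" for i in range(1, config.n_genes_symB + 1)],
    }
    n_genes = {o: len(g) for o, g in gene_ids.items()}

    # shared per-sample latent variates driving inter-organism correlation
    # bounded latent variates (mean 0, variance 1): heavy Gaussian tails
    # would let the responders' read-mass swing imprint a detectable
    # closure signal on every non-responder gene
    z = rng.uniform(-math.sqrt(3.0), math.sqrt(3.0), (n_samples, config.n_latent))

    # host genes split once into latent-linked and noise halves; the linked
    # half also seeds the "linked" pathway cluster
    linked_mask_host = np.zeros(n_genes["host"], dtype=bool)
    linked_mask_host[: n_genes["host"] // 2] = True

    baseline = {
        org: rng.lognormal(0.0, 1.0, n_genes[org]) for org in gene_ids
    }

    # responders: strongly loaded genes, later rescaled to a small
    # read-mass share so closure-induced compensation in the other genes
    # stays weak
    loadings: dict[str, np.ndarray] = {}
    responder_idx: dict[str, np.ndarray] = {}
    for org in ("host", "symA", "symB"):
        ng = n_genes[org]
        L = np.zeros((ng, config.n_latent))
        responders = np.empty(0, dtype=int)
        if config.n_latent > 0:
            if org == "host":
                responders = np.flatnonzero(linked_mask_host)
            else:
                n_resp = max(1, round(config.latent_responder_frac * ng))
                responders = rng.choice(ng, size=n_resp, replace=False)
            factor_of = rng.integers(config.n_latent, size=len(responders))
            magnitude = config.loading_scale * rng.uniform(0.7, 1.3, len(responders))
            L[responders, factor_of] = magnitude
        loadings[org] = L
        responder_idx[org] = responders

    # flip exactly the configured fraction of symbiont-B responders so the
    # planted negative:positive balance is not at the mercy of Bernoulli noise
    flip_B = np.zeros(n_genes["symB"], dtype=bool)
    resp_B = np.flatnonzero(loadings["symB"].any(axis=1))
    if len(resp_B):
        n_flip = round(config.latent_sign_mix * len(resp_B))
        flip_B[rng.choice(resp_B, size=n_flip, replace=False)] = True

    # DE genes are drawn among non-responders: the mass-balancing rescale
    # must not touch responder baselines, whose small mass share is what
    # keeps the closure compensation below detectability
    de_factors: dict[str, np.ndarray] = {}
    de_signs: dict[str, dict[str, int]] = {}
    for org in gene_ids:
        eligible = np.flatnonzero(~loadings[org].any(axis=1))
        f, s = _balanced_de_factors(
            rng, gene_ids[org], baseline[org], config.n_de_genes,
            config.de_log2fc, eligible,
        )
        de_factors[org] = f
        de_signs[org] = s

    # fix the responder pool to its configured share of baseline read mass
    # AFTER DE balancing, so neither planting dilutes the other
    for org in gene_ids:
        responders = responder_idx[org]
        if len(responders) == 0 or len(responders) == n_genes[org]:
            continue
        w = baseline[org]
        s_resp = w[responders].sum()
        s_other = w.sum() - s_resp
        if s_other > 0 and s_resp > 0:
            m = config.latent_responder_mass
            w[responders] *= m * s_other / ((1 - m) * s_resp)

    mixed_shift = {
        "host": np.zeros(n_genes["host"]),
        "symA": rng.normal(0.0, config.mixed_shift_sd_symA, n_genes["symA"]),
        "symB": rng.normal(0.0, config.mixed_shift_sd_symB, n_genes["symB"]),
    }

    depth = np.exp(rng.normal(0.0, config.depth_sigma, n_samples))
    host_target = config.lib_size_mean * depth
    target = {
        "host": host_target,
        "symA": np.where(has_A, config.prop_symA_single * host_target, 0.0),
        "symB": np.where(
            has_B,
            config.prop_symB_single
            * host_target
            * np.where(is_mixed, config.prop_symB_mixed_factor, 1.0),
            0.0,
        ),
    }

    matrices: dict[str, CountMatrix] = {}
    for org in ("host", "symA", "symB"):
        L = loadings[org]
        log_mod = z @ L.T  # samples x genes
        if org == "symB":
            log_mod[np.ix_(is_mixed, flip_B)] *= -1.0
        log_mod[is_mixed] += mixed_shift[org][None, :]
        weights = baseline[org][None, :] * np.exp(log_mod)
        weights = np.where(is_mixed[:, None], weights * de_factors[org][None, :], weights)
        weights /= weights.sum(axis=1, keepdims=True)
        mu = weights * target[org][:, None]
        counts = _nb_counts(rng, mu, config.dispersion).T  # genes x samples
        matrices[org] = CountMatrix(
            org,
            pd.DataFrame(counts, index=gene_ids[org], columns=meta_df["sample_id"]),
        )

    annotation, pw_clusters = _build_annotation(
        config, gene_ids["host"], linked_mask_host
    )

    expected_props: dict[str, dict[str, float]] = {}
    for culture, st in config.cultures:
        pa = config.prop_symA_single if st in ("singleA", "mixed") else 0.0
        pb = config.prop_symB_single if st in ("singleB", "mixed") else 0.0
        if st == "mixed":
            pb *= config.prop_symB_mixed_factor
        expected_props[culture] = {"symA": pa, "symB": pb}

    truth = GroundTruth(
        de_genes=de_signs,
        loadings=loadings,
        sign_flipped_symB=[g for g, f in zip(gene_ids["symB"], flip_B) if f],
        expected_proportions=expected_props,
        pathway_clusters=pw_clusters,
    )
    return matrices, SampleTable(meta_df), annotation, truth


def write_dataset(
    dataset: tuple[dict[str, CountMatrix], SampleTable, AnnotationMap, GroundTruth],
    directory: str | Path,
) -> dict[str, Path]:
    """Write the dataset as TSV files plus a JSON ground-truth manifest."""
    matrices, meta, annotation, truth = dataset
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for org, mat in matrices.items():
        paths[f"counts_{org}"] = write_counts(mat, directory / f"counts_{org}.tsv")
    paths["metadata"] = write_sample_table(meta, directory / "metadata.tsv")
    paths["annotation"] = write_annotation(annotation, directory / "annotation.tsv")
    manifest = {
        "de_genes": truth.de_genes,
        "loadings": {o: L.tolist() for o, L in truth.loadings.items()},
        "sign_flipped_symB": truth.sign_flipped_symB,
        "expected_proportions": truth.expected_proportions,
        "pathway_clusters": truth.pathway_clusters,
    }
    p = directory / "ground_truth.json"
    p.write_text(json.dumps(manifest, indent=1))
    paths["ground_truth"] = p
    return paths


def read_ground_truth(path: str | Path) -> GroundTruth:
    d = json.loads(Path(path).read_text())
    return GroundTruth(
        de_genes={o: {g: int(s) for g, s in v.items()} for o, v in d["de_genes"].items()},
        loadings={o: np.asarray(L) for o, L in d["loadings"].items()},
        sign_flipped_symB=list(d["sign_flipped_symB"]),
        expected_proportions=d["expected_proportions"],
        pathway_clusters={k: int(v) for k, v in d["pathway_clusters"].items()},
    )
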