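"""End-to-end orchestration: simulate or ingest, standardize, diversity,
correlation networks, ordination models, differential expression, pathway
effect models — one report directory with a machine-readable manifest.

A single global seed is expanded into independent per-stage substreams, so
reruns with the same config and seed are bit-identical for deterministic
stages, and stages stay reproducible in isolation.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import corrnet as cn
from . import diffexpr as de
from . import diversity as dv
from . import ordination as od
from . import pathmodels as pm
from . import standardize as st
from .dataio import (
    CountMatrix,
    SampleTable,
    align_samples,
    read_annotation,
    read_counts,
    read_sample_table,
)
from .synthgen import SynthConfig, generate_dataset, write_dataset

logger = logging.getLogger("symbiocor")


@dataclass
class PipelineConfig:
    """Run-level parameters; synthetic generation and stage knobs."""

    out_dir: str = "report"
    seed: int = 0
    input_dir: str | None = None  # read an existing dataset instead of simulating
    synth: SynthConfig = field(default_factory=SynthConfig)
    alpha: float = 0.05
    B_corr: int = 999  # permutations for correlation networks
    B_ord: int = 199  # permutations for ordination tests
    with_host_networks: bool = True
    pathway_k: int | None = 2
    edge_cutoff_quantile: float = 0.75


def _stage_seeds(seed: int, names: list[str]) -> dict[str, int]:
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {
        n: int(np.random.default_rng(c).integers(2**31 - 1))
        for n, c in zip(names, children)
    }


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write(df: pd.DataFrame, path: Path, index_label: str | None = None) -> None:
    df.to_csv(path, sep="\t", index=index_label is not None, index_label=index_label)


def run_all(config: PipelineConfig) -> Path:
    """Run every stage; returns the report directory.

    On a stage failure, partial outputs are kept and a ``FAILED_<stage>``
    marker is written before the error propagates.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = [
        "simulate", "standardize", "diversity", "corrnet",
        "ordination", "diffexpr", "pathways",
    ]
    seeds = _stage_seeds(config.seed, stages)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "stage_seeds": seeds,
        "parameters": {
            "alpha": config.alpha,
            "B_corr": config.B_corr,
            "B_ord": config.B_ord,
            "edge_cutoff_quantile": config.edge_cutoff_quantile,
            "synth": None if config.input_dir else asdict(config.synth),
        },
        "stages": {},
        "results": {},
    }
    current = "simulate"
    try:
        # ---- ingest / simulate -------------------------------------------
        if config.input_dir:
            d = Path(config.input_dir)
            matrices = {
                org: read_counts(d / f"counts_{org}.tsv", org)
                for org in ("host", "symA", "symB")
            }
            meta = read_sample_table(d / "metadata.tsv")
            ann_path = d / "annotation.tsv"
            annotation = read_annotation(ann_path) if ann_path.exists() else None
            truth = None
        else:
            synth = SynthConfig(**{**asdict(config.synth), "seed": seeds["simulate"]})
            matrices, meta, annotation, truth = generate_dataset(synth)
            write_dataset((matrices, meta, annotation, truth), out / "dataset")
        mats, meta = align_samples(
            [matrices["host"], matrices["symA"], matrices["symB"]], meta
        )
        host_raw, symA_raw, symB_raw = mats
        manifest["stages"]["simulate"] = {
            "n_samples": len(meta.sample_ids),
            "input_hashes": {
                p.name: _sha256(p)
                for p in sorted((out / "dataset").glob("*.tsv"))
            } if not config.input_dir else {
                p.name: _sha256(p)
                for p in sorted(Path(config.input_dir).glob("*.tsv"))
            },
        }

        status = meta.table.set_index("sample_id")["status"]
        a_samples = meta.samples_with_status("singleA", "mixed")
        b_samples = meta.samples_with_status("singleB", "mixed")
        mixed = meta.samples_with_status("mixed")

        # ---- standardize: proportions on raw counts, then rarefaction ----
        current = "standardize"
        props = pd.DataFrame(
            {
                "symA_host": st.symbiont_host_proportion(
                    symA_raw.restrict_samples(a_samples),
                    host_raw.restrict_samples(a_samples),
                ),
                "symB_host": st.symbiont_host_proportion(
                    symB_raw.restrict_samples(b_samples),
                    host_raw.restrict_samples(b_samples),
                ),
            }
        )
        _write(props, out / "proportions.tsv", index_label="sample_id")
        prop_tests = []
        for col, single in (("symA_host", "singleA"), ("symB_host", "singleB")):
            series = props[col].dropna()
            grp = status.loc[series.index].map(
                lambda s: "single" if s == single else "mixed"
            )
            res = st.compare_proportions(series, grp)
            ratio = series[grp == "mixed"].mean() / series[grp == "single"].mean()
            prop_tests.append((col, res.statistic, res.p, res.exact, ratio))
        prop_df = pd.DataFrame(
            prop_tests, columns=["proportion", "U", "p", "exact", "mixed_over_single"]
        )
        _write(prop_df, out / "proportion_tests.tsv")
        manifest["results"]["proportions"] = prop_df.to_dict("records")

        std = {
            org: st.downsample_to_min(
                m.restrict_samples(s), seed=seeds["standardize"]
            )
            for org, m, s in (
                ("host", host_raw, meta.sample_ids),
                ("symA", symA_raw, a_samples),
                ("symB", symB_raw, b_samples),
            )
        }
        manifest["stages"]["standardize"] = {
            "min_totals": {o: int(m.sample_totals().min()) for o, m in std.items()}
        }

        # ---- diversity ---------------------------------------------------
        current = "diversity"
        div = pd.DataFrame(
            {f"H_{org}": dv.sample_diversity(m) for org, m in std.items()}
        )
        _write(div, out / "diversity.tsv", index_label="sample_id")
        div_tests = []
        for org, single in (("symA", "singleA"), ("symB", "singleB")):
            h = div[f"H_{org}"].dropna()
            grp = status.loc[h.index].map(
                lambda s: "single" if s == single else "mixed"
            )
            r = dv.compare_diversity(h, grp)
            div_tests.append((org, r.test, r.statistic, r.z, r.p))
        h_host = div["H_host"]
        r = dv.compare_diversity(h_host, status.loc[h_host.index])
        div_tests.append(("host", r.test, r.statistic, r.z, r.p))
        div_df = pd.DataFrame(div_tests, columns=["organism", "test", "stat", "z", "p"])
        _write(div_df, out / "diversity_tests.tsv")

        common_b = [s for s in b_samples if s in div.index]
        reg = dv.regress_diversity(
            div.loc[common_b, "H_symB"], div.loc[common_b, "H_host"]
        )
        manifest["results"]["diversity_regression"] = {
            "slope": reg.slope, "r2": reg.r2, "f": reg.f, "p": reg.p, "df": reg.df,
        }

        # ---- correlation networks ---------------------------------------
        current = "corrnet"
        rng_corr = np.random.default_rng(seeds["corrnet"])
        nets: dict[str, cn.CorrelationNetwork] = {}
        pairs = [("symA", "symB", mixed, "mixed")]
        if config.with_host_networks:
            for org, singles in (("symA", "singleA"), ("symB", "singleB")):
                pairs.append((org, "host", meta.samples_with_status(singles), "single"))
                pairs.append((org, "host", mixed, "mixed"))
        edge_rows = []
        for o1, o2, samples, cond in pairs:
            m1 = std[o1].counts.loc[:, samples]
            m2 = std[o2].counts.loc[:, samples]
            net = cn.cross_network(
                m1, m2, B=config.B_corr, alpha=config.alpha,
                seed=int(rng_corr.integers(2**31 - 1)), condition=f"{o1}-{o2}:{cond}",
            )
            nets[f"{o1}-{o2}:{cond}"] = net
            pos, neg, prof = cn.signed_counts(net)
            edge_rows.append((o1, o2, cond, pos, neg))
            prof.rename_axis("gene_id").to_csv(
                out / f"profiles_{o1}-{o2}_{cond}.tsv", sep="\t"
            )
        counts_df = pd.DataFrame(
            edge_rows, columns=["set1", "set2", "condition", "n_pos", "n_neg"]
        )
        _write(counts_df, out / "signed_edge_counts.tsv")
        manifest["results"]["signed_edges"] = counts_df.to_dict("records")

        ab = nets["symA-symB:mixed"]
        edges = cn.edge_list(ab, config.edge_cutoff_quantile)
        _write(edges, out / "edges_symA-symB_mixed.tsv")

        if config.with_host_networks:
            # host-gene profiles across the four host-facing networks
            prof_cols = {}
            for key in nets:
                if not key.endswith("host:single") and "host" not in key:
                    continue
                net_t = nets[key].transpose()  # host genes as rows
                _, _, prof = cn.signed_counts(net_t)
                tag = key.replace("-host", "").replace(":", "_")
                prof_cols[f"n_pos_{tag}"] = prof["n_pos"]
                prof_cols[f"n_neg_{tag}"] = prof["n_neg"]
            host_prof = pd.DataFrame(prof_cols).fillna(0).astype(int)
            if len(host_prof) >= 5:
                flagged = cn.detect_outliers(host_prof)
                flagged.rename_axis("gene_id").to_csv(
                    out / "host_outliers.tsv", sep="\t"
                )
                manifest["results"]["n_host_outliers"] = int(flagged["outlier"].sum())

        # ---- ordination models ------------------------------------------
        current = "ordination"
        rng_ord = np.random.default_rng(seeds["ordination"])
        model_rows = []
        for org, samples, single in (
            ("symA", a_samples, "singleA"),
            ("symB", b_samples, "singleB"),
        ):
            sub = std[org].counts.loc[:, samples]
            D = od.bray_curtis(sub.T)
            grp = status.loc[samples].map(lambda s: "single" if s == single else "mixed")
            an = od.anosim(
                D, grp.to_numpy(), B=config.B_ord,
                seed=int(rng_ord.integers(2**31 - 1)),
            )
            model_rows.append((f"anosim_{org}", org, "culture type", np.nan,
                               an.R, np.nan, an.p))
            other = "symB" if org == "symA" else "symA"
            presence = (status.loc[samples] == "mixed").astype(float).to_frame(
                f"{other}_present"
            )
            db = od.dbrda(
                D, presence, B=config.B_ord, seed=int(rng_ord.integers(2**31 - 1)),
            )
            model_rows.append((f"dbrda_{org}_vs_{other}_presence", org,
                               f"{other} presence", db.df, db.f, db.r2, db.p))
        host_D = od.bray_curtis(std["host"].counts.T)
        grp_host = status.loc[std["host"].sample_ids]
        an_host = od.anosim(
            host_D, grp_host.to_numpy(), B=config.B_ord,
            seed=int(rng_ord.integers(2**31 - 1)),
        )
        model_rows.append(("anosim_host", "host", "status", np.nan,
                           an_host.R, np.nan, an_host.p))
        X_host = pd.get_dummies(grp_host, drop_first=True).astype(float)
        db_host = od.dbrda(
            host_D, X_host, B=config.B_ord, seed=int(rng_ord.integers(2**31 - 1)),
        )
        model_rows.append(("dbrda_host_vs_status", "host", "status",
                           db_host.df, db_host.f, db_host.r2, db_host.p))
        models_df = pd.DataFrame(
            model_rows,
            columns=["model", "dependent", "independent", "df", "F", "R2", "p"],
        )
        _write(models_df, out / "ordination_models.tsv")
        manifest["results"]["ordination_models"] = models_df.to_dict("records")
        if an_host.pairwise is not None:
            _write(an_host.pairwise, out / "anosim_host_pairwise.tsv")

        # SIMPER per organism, single vs mixed
        for org, samples, single in (
            ("symA", a_samples, "singleA"),
            ("symB", b_samples, "singleB"),
        ):
            sub = std[org].counts.loc[:, samples]
            grp = status.loc[samples].map(lambda s: "single" if s == single else "mixed")
            sim = od.simper(sub.T, grp.to_numpy())
            _write(sim.contributions, out / f"simper_{org}.tsv")

        # ---- differential expression ------------------------------------
        current = "diffexpr"
        de_summary = {}
        for org, samples, single in (
            ("symA", a_samples, "singleA"),
            ("symB", b_samples, "singleB"),
            ("host", list(meta.sample_ids), None),
        ):
            sub = std[org].restrict_samples(samples)
            if single is None:
                grp = status.loc[samples].map(
                    lambda s: "mixed" if s == "mixed" else "single"
                )
            else:
                grp = status.loc[samples].map(
                    lambda s: "single" if s == single else "mixed"
                )
            res = de.de_test(sub, grp, alpha=config.alpha, reference="single")
            res.rename_axis("gene_id").to_csv(out / f"de_{org}.tsv", sep="\t")
            de.volcano_table(res, out / f"volcano_{org}.tsv")
            de_summary[org] = {
                "up": int((res["class"] == "up").sum()),
                "down": int((res["class"] == "down").sum()),
            }
        manifest["results"]["differential_expression"] = de_summary

        # ---- pathway models ---------------------------------------------
        current = "pathways"
        if annotation is None or not annotation.pathway_names:
            logger.warning("no annotation available; pathway stage skipped")
            manifest["stages"]["pathways"] = "skipped: no annotation"
        else:
            eff = pm.pathway_effects(
                std["host"], annotation, {"symA": std["symA"], "symB": std["symB"]},
                meta, seed=seeds["pathways"],
            )
            clus = pm.cluster_pathways(eff, k=config.pathway_k, seed=seeds["pathways"])
            table = eff.r2.copy()
            table.insert(0, "cluster", clus.labels)
            table.insert(1, "silhouette", clus.silhouettes)
            table.rename_axis("pathway").to_csv(out / "pathway_effects.tsv", sep="\t")
            manifest["results"]["pathway_clustering"] = {
                "k": clus.k, "wgss": clus.wgss, "pseudo_f": clus.pseudo_f,
                "pct_variance": clus.pct_variance,
                "avg_silhouette": clus.avg_silhouette,
            }
    except Exception as exc:
        (out / f"FAILED_{current}").write_text(f"{type(exc).__name__}: {exc}\n")
        raise RuntimeError(f"pipeline stage {current!r} failed: {exc}") from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return out
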