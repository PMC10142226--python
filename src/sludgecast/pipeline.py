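"""End-to-end orchestration: simulate/load -> preprocess -> diversity ->
predict -> interpret -> neutral model -> community analyses.

`run_pipeline` sequences the whole analysis from one config, writes every
artifact as TSV/JSON under the output directory, and returns a
machine-readable report. All randomness is routed through named seeds
derived from the config's master seed, so a rerun with the same config is
byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as scio
from .ann import TrainConfig, predict, repeated_experiment
from .community import (
    aggregate_groups,
    classify_core,
    intra_inter_similarity,
    linear_fit,
    summary_stats,
    t_test_two_sample,
)
from .diversity import alpha_diversity, weighted_unifrac
from .importance import cluster_factor_weights, garson_weights, rank_factors
from .neutral import fit_ncm, refit_partitions
from .preprocess import (
    dedup_samples,
    encode_binary,
    filter_taxa,
    impute_2nn,
    normalize_1_100,
    rarefy,
    relative_abundance,
)
from .synthetic import (
    assign_functional_groups,
    generate_env_table,
    generate_neutral_counts,
    generate_tree,
    inject_env_responses,
)

log = logging.getLogger("sludgecast.pipeline")


@dataclass
class SimulationBlock:
    """Synthetic study conditions when no input paths are given."""

    n_samples: int = 120
    n_taxa: int = 150
    n_numeric: int = 46
    n_binary: int = 2
    missing_rate: float = 0.05
    m: float = 0.1
    reads_per_sample: int = 4000
    lognormal_sigma: float = 2.0
    n_driven: int = 20
    effect_size: float = 2.0
    link: str = "logistic"
    group_fraction: float = 0.3


@dataclass
class PipelineConfig:
    """Everything one run needs; either input paths or a simulation block."""

    outdir: str = "sludgecast_run"
    seed: int = 0
    env_path: str | None = None
    env_meta_path: str | None = None
    counts_path: str | None = None
    tree_path: str | None = None
    group_map_path: str | None = None
    simulation: SimulationBlock | None = field(default_factory=SimulationBlock)
    dedup: bool = True
    rarefy_depth: int | None = None
    min_occurrence_frac: float = 0.1
    ncm_depth: int = 2000
    n_asv_targets: int = 6
    alpha_targets: tuple[str, ...] = ("shannon", "pielou", "richness", "faith_pd")
    train: TrainConfig | None = None
    mantel_permutations: int = 199

    def validate(self) -> None:
        paths = [self.env_path, self.counts_path]
        if self.simulation is None and any(p is None for p in paths):
            raise ValueError("provide either input paths or a simulation block")
        if self.train is not None:
            # TrainConfig validates itself on construction; re-check here so a
            # config edited after construction still fails before any stage runs
            TrainConfig(**dataclasses.asdict(self.train))

    def config_hash(self) -> str:
        def enc(o):
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            raise TypeError

        return hashlib.sha256(
            json.dumps(dataclasses.asdict(self), sort_keys=True, default=enc).encode()
        ).hexdigest()[:16]


def _load_or_simulate(config: PipelineConfig):
    sim = config.simulation
    if config.env_path is not None:
        env = scio.read_env(config.env_path, config.env_meta_path)
        counts = scio.read_counts(config.counts_path)
        tree = scio.read_tree(config.tree_path) if config.tree_path else None
        group_map = (
            scio.read_group_map(config.group_map_path) if config.group_map_path else {}
        )
        return env, counts, tree, group_map, None
    env = generate_env_table(
        sim.n_samples, sim.n_numeric, sim.n_binary, sim.missing_rate, seed=config.seed
    )
    counts, truth = generate_neutral_counts(
        sim.n_samples,
        sim.n_taxa,
        m=sim.m,
        reads_per_sample=sim.reads_per_sample,
        lognormal_sigma=sim.lognormal_sigma,
        seed=config.seed + 1,
    )
    counts, drive_truth = inject_env_responses(
        counts, env, sim.n_driven, sim.effect_size, sim.link, seed=config.seed + 2
    )
    truth.driver_map = drive_truth.driver_map
    tree = generate_tree(list(counts.columns), seed=config.seed + 3)
    group_map = assign_functional_groups(
        list(counts.columns), fraction_assigned=sim.group_fraction, seed=config.seed + 4
    )
    truth.group_map = group_map
    return env, counts, tree, group_map, truth


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write artifacts under ``config.outdir``."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "seeds": {},
        "stages": [],
    }

    def stage(name):
        log.info("stage: %s", name)
        report["stages"].append(name)

    try:
        stage("inputs")
        env, counts, tree, group_map, truth = _load_or_simulate(config)
        if truth is not None:
            scio.write_truth(truth, outdir / "truth.json")
        scio.write_counts(counts, outdir / "counts_raw.tsv")

        stage("preprocess_env")
        env = normalize_1_100(impute_2nn(encode_binary(env)))
        scio.write_env(env, outdir / "env_normalized.csv", outdir / "env_meta.csv")

        stage("dedup")
        if config.dedup and tree is not None:
            abund_full = relative_abundance(counts)
            wuf = weighted_unifrac(abund_full, tree)
            keep = dedup_samples(env, wuf)
            env = env.copy_with(values=env.values.loc[keep])
            counts = counts.loc[keep]
            report["n_samples_after_dedup"] = len(keep)

        stage("feature_table")
        if config.rarefy_depth:
            counts = rarefy(counts, config.rarefy_depth, seed=config.seed + 10)
            env = env.copy_with(values=env.values.loc[counts.index])
        filtered = filter_taxa(
            counts, min_occurrence_frac=config.min_occurrence_frac, drop_singletons=True
        )
        abund = relative_abundance(filtered)
        scio.write_counts(filtered, outdir / "counts_filtered.tsv")

        stage("alpha_diversity")
        alpha = alpha_diversity(filtered, tree)
        alpha.to_csv(outdir / "alpha_diversity.tsv", sep="\t")

        stage("train")
        tcfg = config.train or TrainConfig(
            n_inputs=env.values.shape[1], n_iterations=300, n_seeds=3
        )
        X = env.values
        targets: dict[str, np.ndarray] = {}
        for a in config.alpha_targets:
            if a in alpha.columns and not alpha[a].isna().any():
                targets[f"alpha:{a}"] = alpha[a].to_numpy(dtype=float)
        mra_order = abund.mean(axis=0).sort_values(ascending=False)
        asv_targets = list(mra_order.index[: config.n_asv_targets])
        for t in asv_targets:
            targets[f"asv:{t}"] = abund[t].to_numpy(dtype=float)
        group_abund = aggregate_groups(abund, {k: v for k, v in group_map.items()})
        for g in group_abund.columns:
            targets[f"group:{g}"] = group_abund[g].to_numpy(dtype=float)

        results = {}
        for tid, y in targets.items():
            results[tid] = repeated_experiment(
                X, y, tcfg, seeds=list(range(tcfg.n_seeds)), target_id=tid
            )
        report["seeds"]["train"] = list(range(tcfg.n_seeds))
        eval_rows = [
            {
                "target": tid,
                "r2_1to1": r.mean("r2_1to1"),
                "r2_bestfit": r.mean("r2_bestfit"),
                "mse": r.mean("mse"),
            }
            for tid, r in results.items()
        ]
        eval_table = pd.DataFrame(eval_rows).set_index("target")
        eval_table.to_csv(outdir / "evaluation.tsv", sep="\t")
        report["evaluation"] = eval_table["r2_1to1"].to_dict()

        stage("importance")
        imp = pd.DataFrame(
            {
                tid: pd.concat(
                    [garson_weights(m, list(X.columns)) for m in r.models], axis=1
                ).mean(axis=1)
                for tid, r in results.items()
            }
        ).T
        imp.to_csv(outdir / "importance.tsv", sep="\t")
        clusters = cluster_factor_weights(imp, k=3, seed=config.seed + 20)
        clusters.to_csv(outdir / "importance_clusters.tsv", sep="\t")
        report["factor_ranking"] = rank_factors(imp, "median")[:10]

        stage("neutral_model")
        ncm_counts = rarefy(
            counts, min(config.ncm_depth, int(counts.sum(axis=1).min())),
            seed=config.seed + 30,
        )
        ncm_abund = relative_abundance(ncm_counts)
        fit = fit_ncm(ncm_abund, N_T=float(ncm_counts.sum(axis=1).iloc[0]))
        fit.table.to_csv(outdir / "ncm_partitions.tsv", sep="\t")
        report["ncm"] = {
            "m": fit.m,
            "r2_fit": fit.r2_fit,
            "partitions": fit.partition_counts().to_dict(),
        }
        refit = refit_partitions(fit)
        report["ncm"]["refit_m"] = refit.to_dict()

        stage("community")
        core = classify_core(abund)
        core.to_csv(outdir / "core_labels.tsv", sep="\t")
        report["n_core"] = int(core["core"].sum())
        stats_table = summary_stats(abund)
        stats_table.to_csv(outdir / "asv_summary.tsv", sep="\t")

        stage("cross_analyses")
        cross: dict = {}
        asv_r2 = pd.Series(
            {t: results[f"asv:{t}"].mean("r2_1to1") for t in asv_targets}
        )
        feats = stats_table.loc[asv_targets]
        if len(asv_targets) >= 3 and feats["mra"].std() > 0:
            cross["r2_vs_mra"] = linear_fit(feats["mra"], asv_r2)
        if len(asv_targets) >= 3 and feats["occurrence_frequency"].std() > 0:
            cross["r2_vs_frequency"] = linear_fit(feats["occurrence_frequency"], asv_r2)
        if len(asv_targets) >= 3 and feats["cv"].std() > 0:
            cross["r2_vs_cv"] = linear_fit(feats["cv"], asv_r2)
        if len(refit) >= 3 and asv_r2.std() > 0:
            part_r2 = {}
            for label in refit.index:
                taxa = [
                    t
                    for t in asv_targets
                    if t in fit.table.index and fit.table.loc[t, "partition"] == label
                ]
                if taxa:
                    part_r2[label] = float(asv_r2[taxa].mean())
            common = [l for l in refit.index if l in part_r2]
            if len(common) >= 3:
                cross["r2_vs_migration"] = linear_fit(
                    refit[common], [part_r2[l] for l in common]
                )
        core_ids = [t for t in asv_targets if core.loc[t, "core"]]
        noncore_ids = [t for t in asv_targets if not core.loc[t, "core"]]
        if len(core_ids) >= 2 and len(noncore_ids) >= 2:
            t, df, p = t_test_two_sample(asv_r2[core_ids], asv_r2[noncore_ids])
            cross["core_vs_noncore"] = {"t": t, "df": df, "p": p}

        observed_sub = abund[asv_targets].div(abund[asv_targets].sum(axis=1), axis=0)
        pred_cols = {
            t: np.clip(predict(results[f"asv:{t}"].models[0], X), 1e-12, None)
            for t in asv_targets
        }
        predicted_sub = pd.DataFrame(pred_cols, index=abund.index)
        intra, inter, test = intra_inter_similarity(observed_sub, predicted_sub)
        cross["intra_inter"] = {
            "intra_mean": float(intra.mean()),
            "inter_mean": float(inter.mean()),
            "t": test[0],
            "p": test[2],
        }
        report["cross_analyses"] = cross

        manifest = json.dumps(report, indent=1, default=str)
        (outdir / "report.json").write_text(manifest)
        return report
    except Exception as exc:
        failed = report["stages"][-1] if report["stages"] else "validate"
        raise RuntimeError(f"pipeline stage {failed!r} failed: {exc}") from exc
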