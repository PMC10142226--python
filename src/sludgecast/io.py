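"""Plain-text readers and writers for every pipeline artifact.

Environmental tables are CSV (samples as rows) with a CSV sidecar of factor
annotations; count/abundance tables are TSV in feature-table orientation
(samples x ASVs); trees are newick; ground truth and reports are JSON;
trained models are a plain-text matrix dump that round-trips bit-exactly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import TreeNode

from .ann import PredictiveModel
from .tables import EnvTable, SyntheticTruth


def write_env(env: EnvTable, values_path, meta_path) -> None:
    env.values.to_csv(values_path, index_label="sample_id")
    meta = env.meta.copy()
    meta["normalized"] = env.normalized
    meta.to_csv(meta_path, index_label="factor")


def read_env(values_path, meta_path) -> EnvTable:
    values = pd.read_csv(values_path, index_col="sample_id").rename_axis(None)
    meta = pd.read_csv(meta_path, index_col="factor")
    normalized = bool(meta["normalized"].iloc[0]) if "normalized" in meta else False
    return EnvTable(
        values=values,
        meta=meta[["category", "is_binary"]],
        normalized=normalized,
    )


def write_counts(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index_label="sample_id")


def read_counts(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample_id").rename_axis(None)


def write_tree(tree: TreeNode, path) -> None:
    tree.write(str(path), format="newick")


def read_tree(path) -> TreeNode:
    return TreeNode.read(str(path), format="newick")


def write_truth(truth: SyntheticTruth, path) -> None:
    payload = {
        "seed": truth.seed,
        "migration_rate": truth.migration_rate,
        "metacommunity_abundance": (
            None
            if truth.metacommunity_abundance is None
            else truth.metacommunity_abundance.to_dict()
        ),
        "driver_map": truth.driver_map,
        "group_map": truth.group_map,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_truth(path) -> SyntheticTruth:
    payload = json.loads(Path(path).read_text())
    meta = payload["metacommunity_abundance"]
    return SyntheticTruth(
        seed=payload["seed"],
        migration_rate=payload["migration_rate"],
        metacommunity_abundance=None if meta is None else pd.Series(meta),
        driver_map={
            k: [tuple(d) for d in v] for k, v in payload["driver_map"].items()
        },
        group_map=payload["group_map"],
    )


def write_group_map(group_map: dict[str, str], path) -> None:
    pd.Series(group_map, name="group").rename_axis("taxon").to_csv(path, sep="\t")


def read_group_map(path) -> dict[str, str]:
    s = pd.read_csv(path, sep="\t", index_col="taxon")["group"]
    return {str(k): str(v) for k, v in s.items()}


def write_distance(dist: pd.DataFrame, path) -> None:
    dist.to_csv(path, sep="\t", index_label="sample_id")


def read_distance(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample_id").rename_axis(None)


def write_model(model: PredictiveModel, path) -> None:
    """Plain-text dump: shape header, scaler line, then weights at full precision."""
    n, h = model.W.shape
    lines = [f"# sludgecast model n_inputs={n} hidden={h}"]
    lines.append(f"scaler\t{model.target_min!r}\t{model.target_max!r}")
    lines.append("columns\t" + ("\t".join(model.columns) if model.columns else ""))
    for name, arr in (
        ("W", model.W.ravel()),
        ("b_h", model.b_h),
        ("v", model.v),
        ("b_o", np.array([model.b_o])),
    ):
        lines.append(name + "\t" + "\t".join(repr(float(x)) for x in arr))
    Path(path).write_text("\n".join(lines) + "\n")


def read_model(path) -> PredictiveModel:
    lines = Path(path).read_text().splitlines()
    header = lines[0].split()
    n = int(header[3].split("=")[1])
    h = int(header[4].split("=")[1])
    fields: dict[str, list[str]] = {}
    for line in lines[1:]:
        parts = line.split("\t")
        fields[parts[0]] = parts[1:]
    cols = [c for c in fields["columns"] if c] or None
    return PredictiveModel(
        W=np.array([float(x) for x in fields["W"]]).reshape(n, h),
        b_h=np.array([float(x) for x in fields["b_h"]]),
        v=np.array([float(x) for x in fields["v"]]),
        b_o=float(fields["b_o"][0]),
        target_min=float(fields["scaler"][0]),
        target_max=float(fields["scaler"][1]),
        columns=cols,
    )
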