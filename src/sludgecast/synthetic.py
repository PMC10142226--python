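"""Synthetic wastewater-treatment-plant community and metadata generators.

The generators invert the analysis pipeline's own assumptions so every
downstream step can be tested against known ground truth:

* environmental metadata tables with numeric and binary factors spread over
  the five factor categories (climate, design/operation, inflow, effluent,
  physicochemical), with completely-at-random missing cells;
* neutral ASV count tables where each sample's latent relative abundance of
  taxon *i* follows Sloan's Beta(N_T*m*p_i, N_T*m*(1-p_i)) around a lognormal
  metacommunity, then a multinomial read draw at fixed depth;
* deterministic environment->abundance responses injected into a chosen
  subset of taxa, which the neural predictor is later asked to recover;
* random rooted binary trees and functional-group assignments.
"""

from __future__ import annotations

import io

import numpy as np
import pandas as pd
from scipy.special import expit
from skbio import TreeNode

from .tables import FACTOR_CATEGORIES, EnvTable, SyntheticTruth, check_counts

DEFAULT_GROUPS = ("nitrifiers", "denitrifiers", "PAOs", "GAOs", "filamentous")

# per-column distribution menu for numeric factors; varied shapes so that the
# skewness/kurtosis analysis downstream has signal to work with
_NUMERIC_FAMILIES = ("normal", "lognormal", "uniform", "gamma")


def generate_env_table(
    n_samples: int,
    n_numeric: int = 46,
    n_binary: int = 2,
    missing_rate: float = 0.0,
    seed: int = 0,
) -> EnvTable:
    """Generate a samples x factors environmental metadata table.

    Numeric factors are drawn from a rotating menu of distribution families;
    binary factors hold ``"yes"``/``"no"`` tokens so the encoder is
    exercised. ``missing_rate`` of the numeric cells (rounded to the nearest
    cell) are blanked completely at random.
    """
    if n_samples <= 0:
        raise ValueError("n_samples must be positive")
    if n_numeric + n_binary < 1:
        raise ValueError("need at least one factor")
    if not 0 <= missing_rate < 1:
        raise ValueError("missing_rate must be in [0, 1)")

    rng = np.random.default_rng(seed)
    samples = [f"S{i:04d}" for i in range(n_samples)]
    data: dict[str, np.ndarray | list[str]] = {}
    meta_rows = []

    for j in range(n_numeric):
        fam = _NUMERIC_FAMILIES[j % len(_NUMERIC_FAMILIES)]
        if fam == "normal":
            col = rng.normal(rng.uniform(-5, 30), rng.uniform(0.5, 10), n_samples)
        elif fam == "lognormal":
            col = rng.lognormal(rng.uniform(0, 2), rng.uniform(0.3, 1.2), n_samples)
        elif fam == "uniform":
            lo = rng.uniform(0, 50)
            col = rng.uniform(lo, lo + rng.uniform(1, 100), n_samples)
        else:
            col = rng.gamma(rng.uniform(1, 6), rng.uniform(0.5, 5), n_samples)
        data[f"env{j:02d}"] = col
    for j in range(n_binary):
        data[f"flag{j:02d}"] = list(rng.choice(["yes", "no"], size=n_samples))

    values = pd.DataFrame(data, index=samples)
    for i, fid in enumerate(values.columns):
        meta_rows.append(
            {
                "factor": fid,
                "category": FACTOR_CATEGORIES[i % len(FACTOR_CATEGORIES)],
                "is_binary": fid.startswith("flag"),
            }
        )
    meta = pd.DataFrame(meta_rows).set_index("factor")

    if missing_rate > 0 and n_numeric > 0:
        n_cells = n_samples * n_numeric
        n_missing = int(round(missing_rate * n_cells))
        flat = rng.choice(n_cells, size=n_missing, replace=False)
        numeric_cols = [f"env{j:02d}" for j in range(n_numeric)]
        arr = values[numeric_cols].to_numpy(dtype=float)
        arr[np.unravel_index(flat, arr.shape)] = np.nan
        values[numeric_cols] = arr

    return EnvTable(values=values, meta=meta)


def generate_neutral_counts(
    n_samples: int,
    n_taxa: int,
    m: float = 0.1,
    reads_per_sample: int = 2000,
    lognormal_sigma: float = 2.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Generate neutral ASV counts under Sloan's model.

    Metacommunity relative abundances ``p`` are normalised lognormal(0,
    ``lognormal_sigma``) draws; each sample's latent relative abundance of
    taxon *i* is Beta(N_T*m*p_i, N_T*m*(1-p_i)) with N_T =
    ``reads_per_sample``; the latent vector is renormalised and a single
    multinomial draw produces integer counts at exactly the stated depth.
    """
    if not 0 < m <= 1:
        raise ValueError("m must be in (0, 1]")
    if reads_per_sample < 1:
        raise ValueError("reads_per_sample must be >= 1")
    if n_samples < 1 or n_taxa < 1:
        raise ValueError("n_samples and n_taxa must be positive")

    rng = np.random.default_rng(seed)
    p = rng.lognormal(0.0, lognormal_sigma, n_taxa)
    p /= p.sum()
    taxa = [f"ASV{i:05d}" for i in range(n_taxa)]
    samples = [f"S{i:04d}" for i in range(n_samples)]

    nm = reads_per_sample * m
    x = rng.beta(nm * p, nm * (1.0 - p), size=(n_samples, n_taxa))
    row_sums = x.sum(axis=1, keepdims=True)
    # all-zero latent rows are a measure-zero event; guard with the metacommunity
    zero = row_sums[:, 0] == 0
    if zero.any():
        x[zero] = p
        row_sums = x.sum(axis=1, keepdims=True)
    x /= row_sums

    counts = np.empty((n_samples, n_taxa), dtype=np.int64)
    for s in range(n_samples):
        counts[s] = rng.multinomial(reads_per_sample, x[s])

    table = pd.DataFrame(counts, index=samples, columns=taxa)
    truth = SyntheticTruth(
        seed=seed,
        migration_rate=m,
        metacommunity_abundance=pd.Series(p, index=taxa),
    )
    return check_counts(table), truth


def inject_env_responses(
    counts: pd.DataFrame,
    env: EnvTable,
    n_driven: int,
    effect_size: float,
    link: str = "logistic",
    seed: int = 0,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Inject deterministic environment->abundance responses into taxa.

    ``n_driven`` taxa are each tied to one numeric environmental factor; the
    taxon's expected relative abundance is multiplied by a monotone function
    of the standardised driver value (``linear``: ``max(1 + beta*z, 0.05)``;
    ``logistic``: ``2*sigmoid(beta*z)``, both mean ~1 under a symmetric
    driver), rows are renormalised, and counts are redrawn at the original
    per-row depth.
    """
    if link not in ("linear", "logistic"):
        raise ValueError(f"unknown link {link!r}")
    if n_driven > counts.shape[1]:
        raise ValueError("n_driven exceeds the number of taxa")
    if effect_size < 0:
        raise ValueError("effect_size must be non-negative")
    if list(counts.index) != list(env.values.index):
        raise ValueError("counts and env must share sample ids in order")

    rng = np.random.default_rng(seed)
    numeric = [f for f in env.factor_ids if f not in env.binary_factors()]
    if not numeric:
        raise ValueError("env table has no numeric factors to use as drivers")

    driven = rng.choice(counts.columns.to_numpy(), size=n_driven, replace=False)
    drivers = rng.choice(np.asarray(numeric), size=n_driven, replace=True)

    depth = counts.sum(axis=1).to_numpy()
    base = counts.to_numpy(dtype=float)
    base = base / base.sum(axis=1, keepdims=True)

    driver_map: dict[str, list[tuple[str, float, str]]] = {}
    expected = base.copy()
    for taxon, factor in zip(driven, drivers):
        col = env.values[factor].astype(float)
        col = col.fillna(col.mean())
        sd = col.std(ddof=0)
        z = np.zeros(len(col)) if sd == 0 else ((col - col.mean()) / sd).to_numpy()
        if link == "linear":
            mult = np.clip(1.0 + effect_size * z, 0.05, None)
        else:
            mult = 2.0 * expit(effect_size * z)
        jt = counts.columns.get_loc(taxon)
        expected[:, jt] = expected[:, jt] * mult
        driver_map[str(taxon)] = [(str(factor), float(effect_size), link)]

    expected /= expected.sum(axis=1, keepdims=True)
    out = np.empty_like(counts.to_numpy())
    for s in range(expected.shape[0]):
        out[s] = rng.multinomial(int(depth[s]), expected[s])

    table = pd.DataFrame(out, index=counts.index, columns=counts.columns)
    truth = SyntheticTruth(seed=seed, driver_map=driver_map)
    return check_counts(table), truth


def generate_tree(taxa_ids: list[str], seed: int = 0) -> TreeNode:
    """Random rooted binary tree with the given leaves.

    Built by iteratively joining two random subtrees (a random coalescent
    topology) with exponential branch lengths; deterministic per seed.
    """
    ids = list(taxa_ids)
    if len(ids) < 2:
        raise ValueError("need at least 2 taxa")
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate taxa ids")

    rng = np.random.default_rng(seed)
    nodes = [TreeNode(name=t, length=float(rng.exponential(0.5)) + 1e-3) for t in ids]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        right = nodes.pop(j)
        left = nodes.pop(i)
        parent = TreeNode(length=float(rng.exponential(0.5)) + 1e-3)
        parent.extend([left, right])
        nodes.append(parent)
    root = nodes[0]
    root.length = None
    return root


def tree_to_newick(tree: TreeNode) -> str:
    buf = io.StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue()


def tree_from_newick(text: str) -> TreeNode:
    return TreeNode.read(io.StringIO(text), format="newick")


def assign_functional_groups(
    taxa_ids: list[str],
    groups: tuple[str, ...] = DEFAULT_GROUPS,
    fraction_assigned: float = 0.2,
    seed: int = 0,
) -> dict[str, str]:
    """Assign a random subset of taxa to functional groups.

    A ``fraction_assigned`` share of taxa (rounded) is drawn at random and
    labels are allocated in a balanced round-robin over ``groups``.
    """
    if not groups:
        raise ValueError("groups must be non-empty")
    if not 0 <= fraction_assigned <= 1:
        raise ValueError("fraction_assigned must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_assigned = int(round(fraction_assigned * len(taxa_ids)))
    chosen = rng.choice(np.asarray(taxa_ids, dtype=object), size=n_assigned, replace=False)
    return {str(t): groups[i % len(groups)] for i, t in enumerate(chosen)}
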