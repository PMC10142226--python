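"""Metadata and feature-table preprocessing.

Environmental metadata goes through binary label-encoding, two-nearest-
neighbour imputation and 1-100 min-max normalisation; near-duplicate samples
(identical metadata rows whose community distance falls under a Q1 - 3*IQR
fence on the weighted-UniFrac distribution) are merged. Feature tables are
rarefied without replacement, cleaned of singletons, filtered by occurrence,
and converted to relative abundances.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .tables import EnvTable, check_counts


def encode_binary(env: EnvTable) -> EnvTable:
    """Map flagged binary columns to {0, 1} by sorted token order.

    Tokens are ranked lexicographically among the observed tokens (label-
    encoder semantics), e.g. ``{"no", "yes"} -> {0, 1}``. Numeric columns are
    untouched. More than two distinct tokens in a flagged column is a
    data-format error.
    """
    values = env.values.copy()
    for col in env.binary_factors():
        observed = values[col].dropna()
        tokens = sorted(set(observed.astype(str)))
        if len(tokens) > 2:
            raise ValueError(f"binary column {col!r} has {len(tokens)} tokens")
        mapping = {tok: float(i) for i, tok in enumerate(tokens)}
        values[col] = observed.astype(str).map(mapping).reindex(values.index)
    return env.copy_with(values=values.astype(float))


def _sample_distances(arr: np.ndarray) -> np.ndarray:
    """Pairwise distances over mutually observed columns, averaged per column.

    d(s, t) = sqrt(mean over shared columns of squared differences); NaN when
    two samples share no observed column.
    """
    mask = ~np.isnan(arr)
    filled = np.where(mask, arr, 0.0)
    shared = mask.astype(float) @ mask.T.astype(float)
    sq = filled**2
    # sum over shared columns of (x - y)^2, computed with masked products
    cross = filled @ filled.T
    xx = sq @ mask.T.astype(float)
    d2 = xx + xx.T - 2 * cross
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.sqrt(np.maximum(d2, 0.0) / shared)
    out[shared == 0] = np.nan
    return out


def impute_2nn(env: EnvTable) -> EnvTable:
    """Fill missing cells by the mean of the 2 nearest samples' values.

    Distance between two samples is the root-mean-square difference over the
    columns observed in both. For each missing cell the 2 nearest samples
    (ties broken by sample order) that observe the factor donate the
    unweighted mean of their values. Binary columns must be encoded first.
    """
    values = env.values
    if values.dtypes.apply(lambda d: d == object).any():
        raise ValueError("encode binary columns before imputation")
    arr = values.to_numpy(dtype=float)
    if not np.isnan(arr).any():
        return env

    obs_per_col = (~np.isnan(arr)).sum(axis=0)
    if (obs_per_col < 2).any():
        bad = values.columns[obs_per_col < 2]
        raise ValueError(f"columns with <2 observed values: {list(bad)}")

    dist = _sample_distances(arr)
    np.fill_diagonal(dist, np.inf)
    out = arr.copy()
    for s, f in zip(*np.where(np.isnan(arr))):
        donors = np.where(~np.isnan(arr[:, f]))[0]
        d = dist[s, donors]
        if np.all(np.isnan(d)):
            raise ValueError(
                f"sample {values.index[s]!r} shares no observed columns with any donor"
            )
        order = np.lexsort((donors, np.where(np.isnan(d), np.inf, d)))
        nearest = donors[order[:2]]
        out[s, f] = arr[nearest, f].mean()
    return env.copy_with(values=pd.DataFrame(out, index=values.index, columns=values.columns))


def normalize_1_100(env: EnvTable, columns_stats: pd.DataFrame | None = None) -> EnvTable:
    """Min-max normalise every factor onto [1, 100].

    x' = 1 + 99*(x - min)/(max - min); constant columns map to the range
    midpoint 50.5. ``columns_stats`` (a DataFrame with ``min``/``max`` rows)
    allows fitting the scaling on a training subset only, for leakage-free
    evaluation; by default the full table is used.
    """
    arr = env.values.to_numpy(dtype=float)
    if np.isnan(arr).any():
        raise ValueError("impute missing cells before normalization")
    if columns_stats is None:
        lo, hi = arr.min(axis=0), arr.max(axis=0)
    else:
        lo = columns_stats.loc["min", env.values.columns].to_numpy(dtype=float)
        hi = columns_stats.loc["max", env.values.columns].to_numpy(dtype=float)
    span = hi - lo
    with np.errstate(invalid="ignore", divide="ignore"):
        scaled = 1.0 + 99.0 * (arr - lo) / span
    # pin the endpoints exactly: roundoff must not leave max at 99.999...
    scaled = np.where(arr == lo, 1.0, scaled)
    scaled = np.where(arr == hi, 100.0, scaled)
    scaled[:, span == 0] = 50.5
    scaled = np.clip(scaled, 1.0, 100.0)
    values = pd.DataFrame(scaled, index=env.values.index, columns=env.values.columns)
    return env.copy_with(values=values, normalized=True)


def duplicate_distance_fence(dist: pd.DataFrame) -> float:
    """Q1 - 3*IQR of all pairwise distances, clamped at 0.

    For typical distance distributions this is negative, so after clamping
    only (near-)identical communities can be merged.
    """
    vals = dist.to_numpy()[np.triu_indices(len(dist), k=1)]
    q1, q3 = np.percentile(vals, [25, 75])
    return max(0.0, q1 - 3.0 * (q3 - q1))


def dedup_samples(env: EnvTable, dist: pd.DataFrame) -> list[str]:
    """Drop near-duplicate samples.

    Samples with byte-identical environmental rows whose pairwise community
    distance is no more than the Q1 - 3*IQR fence are merged transitively;
    the lexicographically smallest id of each merged component is retained.
    Returns the sorted retained id list, independent of input row order.
    """
    ids = list(env.values.index)
    if set(dist.index) != set(ids) or set(dist.columns) != set(ids):
        raise ValueError("distance matrix ids do not match env sample ids")
    dist = dist.loc[ids, ids]
    if not np.allclose(dist.to_numpy(), dist.to_numpy().T):
        raise ValueError("distance matrix must be symmetric")

    fence = duplicate_distance_fence(dist)

    # group samples by identical env rows (NaN compares equal to NaN)
    keys: dict[tuple, list[str]] = {}
    for sid, row in env.values.iterrows():
        key = tuple("<NA>" if pd.isna(v) else v for v in row)
        keys.setdefault(key, []).append(sid)

    dropped: set[str] = set()
    for group in keys.values():
        if len(group) < 2:
            continue
        group = sorted(group)
        parent = {g: g for g in group}

        def find(a: str) -> str:
            while parent[a] != a:
                parent[a] = parent[parent[a]]
                a = parent[a]
            return a

        for i, a in enumerate(group):
            for b in group[i + 1 :]:
                if dist.loc[a, b] <= fence:
                    parent[find(b)] = find(a)
        comps: dict[str, list[str]] = {}
        for g in group:
            comps.setdefault(find(g), []).append(g)
        for members in comps.values():
            for sid in sorted(members)[1:]:
                dropped.add(sid)
    return sorted(s for s in ids if s not in dropped)


def rarefy(
    counts: pd.DataFrame,
    depth: int,
    seed: int = 0,
    drop_short: bool = True,
) -> pd.DataFrame:
    """Subsample each sample to ``depth`` reads without replacement.

    Rows already at exactly ``depth`` are returned unchanged; rows below
    ``depth`` are dropped when ``drop_short`` else raise. The draw is
    multivariate hypergeometric, deterministic per seed.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    check_counts(counts)
    rng = np.random.default_rng(seed)
    totals = counts.sum(axis=1)
    short = totals < depth
    if short.any() and not drop_short:
        raise ValueError(
            f"{int(short.sum())} samples have fewer than {depth} reads"
        )
    rows = []
    kept = []
    for sid, row in counts.iterrows():
        total = int(totals[sid])
        if total < depth:
            continue
        if total == depth:
            rows.append(row.to_numpy())
        else:
            rows.append(rng.multivariate_hypergeometric(row.to_numpy(), depth))
        kept.append(sid)
    if not kept:
        raise ValueError("no sample reaches the rarefaction depth")
    return pd.DataFrame(np.vstack(rows), index=kept, columns=counts.columns)


def filter_taxa(
    counts: pd.DataFrame,
    min_occurrence_frac: float = 0.0,
    drop_singletons: bool = True,
) -> pd.DataFrame:
    """Remove singleton ASVs, then ASVs below the occurrence threshold.

    Singletons are ASVs with a single read summed over all samples. The
    occurrence rule keeps ASVs detected (count > 0) in at least
    ``ceil(min_occurrence_frac * n_samples)`` samples ("at least 10%" read
    inclusively).
    """
    if not 0 <= min_occurrence_frac <= 1:
        raise ValueError("min_occurrence_frac must be in [0, 1]")
    check_counts(counts)
    out = counts
    if drop_singletons:
        out = out.loc[:, out.sum(axis=0) != 1]
    if min_occurrence_frac > 0:
        need = int(np.ceil(min_occurrence_frac * out.shape[0]))
        occ = (out > 0).sum(axis=0)
        out = out.loc[:, occ >= need]
    return out


def relative_abundance(counts: pd.DataFrame) -> pd.DataFrame:
    """Row-normalise counts to relative abundances."""
    totals = counts.sum(axis=1)
    if (totals <= 0).any():
        bad = list(totals.index[totals <= 0][:5])
        raise ValueError(f"zero-total samples: {bad}")
    return counts.div(totals, axis=0)
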