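"""Community-level classification and the study's statistical toolbox.

Core taxa are ASVs that are simultaneously overall abundant (top 1% by mean
relative abundance), ubiquitous (detected in more than 20% of samples) and
frequently abundant (inside the per-sample top-80%-of-reads set in at least
10% of samples). Functional-group abundances are per-sample sums over a
taxon -> group map. The statistics cover the cross-analyses: Mantel tests,
ordinary least-squares fits, two-sample t-tests, per-taxon summary features
(mean relative abundance, occurrence frequency, coefficient of variation)
and the intra- vs inter-sample Bray-Curtis comparison of observed and
predicted communities.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import cdist

from .tables import check_abundance


def classify_core(
    abund: pd.DataFrame,
    top_frac: float = 0.01,
    ubiquity_threshold: float = 0.2,
    dominance_share: float = 0.8,
    freq_abundant_frac: float = 0.1,
) -> pd.DataFrame:
    """Flag overall-abundant, ubiquitous, frequently-abundant and core ASVs.

    * overall abundant: the ceil(top_frac * n_asvs) ASVs of highest mean
      relative abundance (ties broken by id);
    * ubiquitous: occurrence frequency strictly greater than
      ``ubiquity_threshold``;
    * per-sample abundant set: the smallest prefix of that sample's
      descending abundance ranking (ties by id) whose cumulative share
      reaches ``dominance_share`` — the crossing ASV is included;
    * frequently abundant: abundant in at least ``freq_abundant_frac`` of
      samples;
    * core: all three at once.
    """
    check_abundance(abund)
    if abund.shape[1] == 0:
        raise ValueError("empty abundance table")
    n_samples, n_asvs = abund.shape

    mra = abund.mean(axis=0)
    freq = (abund > 0).mean(axis=0)

    n_top = int(np.ceil(top_frac * n_asvs))
    by_rank = sorted(abund.columns, key=lambda t: (-mra[t], t))
    overall = pd.Series(False, index=abund.columns)
    overall[by_rank[:n_top]] = True

    ubiquitous = freq > ubiquity_threshold

    dominant_count = pd.Series(0, index=abund.columns)
    for _, row in abund.iterrows():
        order = sorted(abund.columns, key=lambda t: (-row[t], t))
        cum = 0.0
        for t in order:
            dominant_count[t] += 1
            cum += row[t]
            if cum >= dominance_share:
                break
    freq_abundant = dominant_count / n_samples >= freq_abundant_frac

    return pd.DataFrame(
        {
            "mra": mra,
            "occurrence_frequency": freq,
            "overall_abundant": overall,
            "ubiquitous": ubiquitous,
            "frequently_abundant": freq_abundant,
            "core": overall & ubiquitous & freq_abundant,
        }
    )


def aggregate_groups(abund: pd.DataFrame, group_map: dict[str, str]) -> pd.DataFrame:
    """Per-sample summed relative abundance of each functional group.

    Taxa absent from the map are ignored; a taxon may carry only one group.
    Returns samples x groups (all mapped groups as columns, zero-filled).
    """
    check_abundance(abund)
    groups = sorted(set(group_map.values()))
    out = pd.DataFrame(0.0, index=abund.index, columns=groups)
    for taxon, group in group_map.items():
        if taxon in abund.columns:
            out[group] += abund[taxon]
    return out


def _upper_triangle(d: pd.DataFrame) -> np.ndarray:
    arr = d.to_numpy(dtype=float)
    return arr[np.triu_indices(arr.shape[0], k=1)]


def mantel_test(
    dist1: pd.DataFrame,
    dist2: pd.DataFrame,
    n_permutations: int = 999,
    seed: int = 0,
) -> tuple[float, float]:
    """Mantel test between two distance matrices.

    r is the Pearson correlation of the off-diagonal upper triangles; the
    one-sided p-value is (1 + #{permuted r >= observed r}) / (1 + n_perm),
    permuting rows and columns of ``dist2`` jointly.
    """
    ids = list(dist1.index)
    if len(ids) < 4:
        raise ValueError("need at least 4 samples")
    if set(dist2.index) != set(ids):
        raise ValueError("distance matrices must share ids")
    d2 = dist2.loc[ids, ids].to_numpy(dtype=float)
    v1 = _upper_triangle(dist1)
    v2 = d2[np.triu_indices(len(ids), k=1)]
    if np.std(v1) == 0 or np.std(v2) == 0:
        raise ValueError("constant distance matrix; correlation undefined")
    r_obs = float(stats.pearsonr(v1, v2)[0])

    rng = np.random.default_rng(seed)
    iu = np.triu_indices(len(ids), k=1)
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(len(ids))
        v2p = d2[np.ix_(perm, perm)][iu]
        if np.corrcoef(v1, v2p)[0, 1] >= r_obs:
            count += 1
    p = (1 + count) / (1 + n_permutations)
    return r_obs, p


def linear_fit(x, y) -> dict:
    """Ordinary least squares of y on x: slope, intercept, r2, p (slope t-test)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    if np.std(x) == 0:
        raise ValueError("constant x")
    res = stats.linregress(x, y)
    return {
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "r2": float(res.rvalue**2),
        "p": float(res.pvalue),
    }


def t_test_two_sample(a, b, variant: str = "student") -> tuple[float, float, float]:
    """Unpaired two-tailed two-sample t-test.

    ``student`` pools variances; ``welch`` uses the Satterthwaite df.
    Returns (t, df, p).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    if variant not in ("student", "welch"):
        raise ValueError(f"unknown variant {variant!r}")
    equal_var = variant == "student"
    if equal_var:
        df = len(a) + len(b) - 2
        pooled = ((len(a) - 1) * np.var(a, ddof=1) + (len(b) - 1) * np.var(b, ddof=1)) / df
        if pooled == 0:
            raise ValueError("zero pooled variance")
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    df = float(res.df) if hasattr(res, "df") else float(len(a) + len(b) - 2)
    return float(res.statistic), df, float(res.pvalue)


def summary_stats(
    abund: pd.DataFrame,
    abundance_thresholds: tuple[float, float] = (1e-4, 1e-3),
    frequency_thresholds: tuple[float, float] = (0.2, 0.5),
) -> pd.DataFrame:
    """Per-ASV distribution features and abundance/frequency group labels.

    CV is sd/mean of the relative abundance across all samples, zeros
    included, with the n-1 sd. Group labels use configurable thresholds:
    abundance low < 0.01%, high >= 0.1% mean relative abundance; frequency
    low < 0.2, high >= 0.5 (defaults, not study-fixed values).
    """
    check_abundance(abund)
    mra = abund.mean(axis=0)
    freq = (abund > 0).mean(axis=0)
    sd = abund.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cv = sd / mra
    lo_a, hi_a = abundance_thresholds
    lo_f, hi_f = frequency_thresholds
    a_group = np.where(mra >= hi_a, "high", np.where(mra < lo_a, "low", "medium"))
    f_group = np.where(freq >= hi_f, "high", np.where(freq < lo_f, "low", "medium"))
    return pd.DataFrame(
        {
            "mra": mra,
            "occurrence_frequency": freq,
            "cv": cv,
            "abundance_group": a_group,
            "frequency_group": f_group,
        }
    )


def intra_inter_similarity(
    observed: pd.DataFrame, predicted: pd.DataFrame, variant: str = "student"
) -> tuple[np.ndarray, np.ndarray, tuple[float, float, float]]:
    """Compare observed and predicted communities sample-wise.

    Bray-Curtis similarity between every observed row and every predicted
    row; intra = same sample (diagonal), inter = different samples
    (off-diagonal). Returns (intra, inter, t-test result). Predicted rows
    are re-normalised to sum to 1.
    """
    if list(observed.index) != list(predicted.index) or list(observed.columns) != list(
        predicted.columns
    ):
        raise ValueError("observed and predicted must share sample and taxon ids")
    check_abundance(observed)
    pred = predicted.div(predicted.sum(axis=1), axis=0)
    sim = 1.0 - cdist(observed.to_numpy(), pred.to_numpy(), metric="braycurtis")
    intra = np.diag(sim)
    inter = sim[~np.eye(sim.shape[0], dtype=bool)]
    test = t_test_two_sample(intra, inter, variant=variant)
    return intra, inter, test
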