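"""Alpha- and beta-diversity metrics used by the pipeline.

Alpha diversity per sample: Shannon-Wiener H (natural log), Pielou's
evenness J = H/ln(S), richness S, and Faith's phylogenetic diversity
(including the path to the root, the QIIME convention). Beta metrics:
weighted UniFrac (raw or normalised) and Bray-Curtis similarity.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import TreeNode
from skbio.diversity import beta_diversity
from skbio.diversity.alpha import faith_pd

from .tables import check_abundance, check_counts


def alpha_diversity(counts: pd.DataFrame, tree: TreeNode | None = None) -> pd.DataFrame:
    """Per-sample alpha diversity from a count table.

    Returns a DataFrame indexed by sample with columns ``shannon`` (nats),
    ``pielou`` (NaN when S = 1), ``richness`` and, when a tree is supplied,
    ``faith_pd``. A sample with no reads is an error.
    """
    check_counts(counts)
    arr = counts.to_numpy(dtype=float)
    totals = arr.sum(axis=1)
    if (totals == 0).any():
        bad = list(counts.index[totals == 0][:5])
        raise ValueError(f"samples with zero reads have undefined diversity: {bad}")

    p = arr / totals[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    shannon = -plogp.sum(axis=1)
    richness = (arr > 0).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        pielou = np.where(richness > 1, shannon / np.log(richness), np.nan)

    out = pd.DataFrame(
        {"shannon": shannon, "pielou": pielou, "richness": richness},
        index=counts.index,
    )
    if tree is not None:
        taxa = list(counts.columns)
        out["faith_pd"] = [
            faith_pd(arr[i], taxa=taxa, tree=tree) for i in range(arr.shape[0])
        ]
    return out


def weighted_unifrac(
    abund: pd.DataFrame, tree: TreeNode, normalized: bool = False
) -> pd.DataFrame:
    """Pairwise weighted UniFrac distances between samples.

    Raw form: sum over branches b of l_b * |A_b - B_b| where A_b, B_b are the
    relative abundances descending from b in the two samples; the normalised
    form divides by sum(l_b * (A_b + B_b)).
    """
    check_abundance(abund)
    leaf_names = {t.name for t in tree.tips()}
    missing = [t for t in abund.columns if t not in leaf_names]
    if missing:
        raise ValueError(f"taxa missing from the tree: {missing[:5]}")
    dm = beta_diversity(
        "weighted_unifrac",
        abund.to_numpy(),
        ids=list(abund.index),
        taxa=list(abund.columns),
        tree=tree,
        normalized=normalized,
    )
    return pd.DataFrame(dm.data, index=list(abund.index), columns=list(abund.index))


def bray_curtis_similarity(abund: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Bray-Curtis similarity, 1 - sum|x-y| / sum(x+y)."""
    check_abundance(abund)
    sim = 1.0 - squareform(pdist(abund.to_numpy(), metric="braycurtis"))
    np.fill_diagonal(sim, 1.0)
    return pd.DataFrame(sim, index=abund.index, columns=abund.index)
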