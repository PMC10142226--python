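"""Metadata preprocessing and diversity: encoding, imputation, 1-100
normalisation, weighted-UniFrac near-duplicate removal, rarefaction,
occurrence filtering, and alpha diversity.

Run examples/01_simulate_dataset.py first.
"""

from pathlib import Path

from sludgecast import io as scio
from sludgecast.diversity import alpha_diversity, weighted_unifrac
from sludgecast.preprocess import (
    dedup_samples,
    encode_binary,
    filter_taxa,
    impute_2nn,
    normalize_1_100,
    rarefy,
    relative_abundance,
)

indir = Path("example_output/simulated")
env = scio.read_env(indir / "env.csv", indir / "env_meta.csv")
counts = scio.read_counts(indir / "counts.tsv")
tree = scio.read_tree(indir / "tree.nwk")

env = normalize_1_100(impute_2nn(encode_binary(env)))
print(f"after normalisation every factor spans [{env.values.min().min()}, "
      f"{env.values.max().max()}]")

# near-duplicate removal: identical metadata rows whose community distance
# falls under the Q1 - 3*IQR fence of the weighted-UniFrac distribution
wuf = weighted_unifrac(relative_abundance(counts), tree)
keep = dedup_samples(env, wuf)
print(f"samples retained after duplicate merge: {len(keep)} / {len(counts)}")
counts = counts.loc[keep]

counts = rarefy(counts, depth=1500, seed=0)
filtered = filter_taxa(counts, min_occurrence_frac=0.10, drop_singletons=True)
print(f"ASVs present in >=10% of samples: {filtered.shape[1]} / {counts.shape[1]}")

alpha = alpha_diversity(filtered, tree)
print(alpha.describe().loc[["min", "mean", "max"]].round(3))
# shannon is in nats, pielou in [0,1], faith_pd in branch-length units; the
# ranges above are the spread across samples of the rarefied community.
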