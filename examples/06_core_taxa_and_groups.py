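"""Core-taxa classification, functional-group abundances, and per-taxon
distribution features.

Run examples/01_simulate_dataset.py first.
"""

from pathlib import Path

from sludgecast import io as scio
from sludgecast.community import aggregate_groups, classify_core, summary_stats
from sludgecast.preprocess import filter_taxa, relative_abundance

indir = Path("example_output/simulated")
counts = scio.read_counts(indir / "counts.tsv")
group_map = scio.read_group_map(indir / "groups.tsv")

abund = relative_abundance(filter_taxa(counts, min_occurrence_frac=0.10))

core = classify_core(abund)
print(f"{int(core['core'].sum())} core ASVs out of {len(core)} "
      "(top-1% abundance AND >20% occurrence AND top-80% of reads in >=10% of samples)")
print(core[core["core"]][["mra", "occurrence_frequency"]].round(4))

groups = aggregate_groups(abund, group_map)
print("\nmean summed relative abundance per functional group:")
print(groups.mean().round(4).to_string())

stats = summary_stats(abund)
print("\nper-ASV features (first 3):")
print(stats.head(3).round(4))
# mra is the mean relative abundance over samples; cv (sd/mean, zeros
# included) measures how variable a taxon is across plants -- highly
# variable taxa are typically the hardest to predict.
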