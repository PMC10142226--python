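# sludgecast

Predicting activated-sludge microbial community structure from environmental
metadata, and asking *which* taxa are predictable and *why*.

Activated sludge — the microbial biomass in a wastewater treatment plant's
aeration tank — hosts communities whose composition responds to climate,
design/operation, inflow, effluent and physicochemical conditions, but is
also shaped by stochastic dispersal. `sludgecast` is a Python library for
the full analysis chain around that question:

* **Prediction.** One shallow neural network per community feature (an
  alpha-diversity index, a single ASV's relative abundance, a functional
  group's summed abundance): n environmental factors → a hidden layer of
  2n+1 relu units → one sigmoid output, trained with Adam (batch 256,
  learning rate 1e-5, weight decay 0.01, 10,000 steps) on min–max-scaled
  targets. Accuracy is **R²₁:₁ = 1 − SS_res/SS_tot**, the coefficient of
  determination against the identity (observed = predicted) line — it can
  be negative — averaged over a 20-seed repetition of the 80/20 split.
* **Interpretation.** Garson's connection-weight importance
  (c_ij = |w_ij|·|v_j|, normalised per hidden unit, summed over units, then
  over inputs), k-means clustering of factor-importance profiles, median
  ranking, and the relation of importance to each factor's skewness and
  kurtosis.
* **Assembly.** The Sloan neutral community model: a taxon with
  metacommunity mean relative abundance p has local relative abundance
  ~ Beta(N_T·m·p, N_T·m·(1−p)); the migration rate m is least-squares
  fitted to the occurrence-frequency vs abundance relation, a 95% Wilson
  band partitions taxa into above / neutral / below, and m is re-estimated
  per partition.
* **Community analysis.** Core-taxa classification (top-1% mean relative
  abundance ∧ present in >20% of samples ∧ in the per-sample top-80%-of-
  reads set in ≥10% of samples), functional-group aggregation
  (nitrifiers, denitrifiers, PAOs, GAOs, filamentous), Mantel tests, OLS
  fits, t-tests, per-taxon distribution features.
* **Preprocessing and diversity.** Binary label-encoding, two-nearest-
  neighbour imputation, 1–100 normalisation, weighted-UniFrac
  near-duplicate sample removal (Q1 − 3·IQR fence), rarefaction without
  replacement, singleton/occurrence filtering; Shannon, Pielou, richness,
  Faith's PD, weighted UniFrac, Bray–Curtis.
* **Synthetic surveys.** A first-class generator producing metadata tables,
  neutral count tables at a *known* migration rate, taxa with injected
  monotone environment responses, random phylogenies and functional-group
  maps — with full ground truth, so every method above can be tested by
  parameter recovery.

## Worked example

`examples/04_factor_importance.py` builds a 400-sample survey whose target
depends on three known factors among 48, runs the repeated-seed protocol,
and interprets the trained networks:

```text
mean R2_1:1 over 5 seeds: 0.925
top-5 factors by mean Garson importance (true drivers were ['env00', 'env09', 'env22']):
env22    0.0336
env09    0.0318
env00    0.0292
env26    0.0239
env34    0.0235
importance ~ skewness: slope -9.59e-04 (p=0.018); ~ kurtosis: slope -1.58e-04 (p=0.031)
```

The network explains 92.5% of held-out variance about the 1:1 line, and all
three true drivers head the importance ranking. `examples/05_neutral_model.py`
fits the neutral model to a simulated survey (true m = 0.1 with 20
environment-driven taxa):

```text
true m = 0.1, fitted m = 0.0667, fit R2 = 0.991
partition counts: {'neutral': 249, 'above': 25, 'below': 17}
per-partition refit of m:
above      0.1027
neutral    0.0674
below      0.0495
```

Stochastic assembly explains 99% of the frequency–abundance relation in this
(mostly neutral) simulation, most taxa sit inside the 95% band, and the
above partition refits to a higher migration rate than the below partition —
the deterministic environmental filtering on the driven taxa also depresses
the community-wide m̂ below the neutral truth, which is the expected
signature of selection.

Run `examples/01_simulate_dataset.py` first; every script prints what its
numbers mean.

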