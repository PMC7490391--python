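# muskin

A desk-scale analysis pipeline for wild-vs-laboratory mouse **skin
microbiota** 16S amplicon studies with paired DNA ("standing") and RNA
("active") community profiles. The package implements:

- **Contaminant screening** (`muskin.decontam`) — the frequency method:
  per feature, a constrained-slope model (log frequency = b − log
  concentration) is compared against a constant-frequency model via an
  F-CDF score; features scoring below 0.1 in *either* the DNA or RNA
  dataset are removed from *both* tables. Negative extraction controls
  with ≥ 40 processed reads are included.
- **Repeated-rarefaction normalization** (`muskin.normalize`) — per
  sample, 1000 independent draws of equal depth (default 4000 reads,
  without replacement); features whose occurrence frequency across draws
  falls below the 10% quantile of that sample's present features are
  discarded, then one final equal-depth draw is taken from the selected
  features only.
- **Core-community partitioning** (`muskin.core`) — taxonomic collapsing,
  top-5-taxa summaries, core sets (present in ≥ 25% of a group's
  individuals), shared/unique/partial partitioning, and per-individual
  core-abundance fractions per category.
- **Diversity** (`muskin.diversity`) — Shannon, bias-corrected Chao1,
  Faith's PD (root-inclusive), Bray–Curtis, Jaccard,
  unweighted/normalized-weighted UniFrac by explicit branch enumeration,
  PCoA (Gower double-centering), and sequential (Type-I) PERMANOVA with
  free label permutation.
- **Indicator statistics** (`muskin.indicators`) — the group-equalized
  point-biserial correlation (per-sample weights 1/n_group), one-sided
  permutation p-values, and Benjamini–Hochberg step-up adjustment.
- **Distance decay & genetics** (`muskin.genetics`) — p-distance with
  pairwise deletion, individual-level Cavalli-Sforza chord distance,
  planar Euclidean geographic distance, and Spearman-based Mantel /
  partial Mantel tests (1000 permutations).
- **Variance partitioning** (`muskin.mixed`) — random-intercept Gaussian
  mixed models fit by profiled REML (1-D optimization over the variance
  ratio), marginal R², and drop-one factor shares.
- **Species matching** (`muskin.match`) — global affine-gap alignment
  identity against labeled references with a 0.05 near-tie multi-match
  rule.
- **Synthetic data** (`muskin.simulate`) — a generator that plants all of
  the structure the analyses assume (contaminants with frequency ∝
  1/concentration, shared/group-specific core taxa, a wild-enriched rare
  biosphere, DNA-only carry-over taxa, spatially autocorrelated farm
  effects producing distance decay, and spatially clustered
  microsatellite/D-loop genetics) and returns machine-readable truth
  labels for recovery testing.

Bundles are plain-text directories (TSV tables and metadata, Newick tree,
FASTA sequences); see `muskin/io.py` for the exact dialects.

## Test

```sh
python -m pytest tests/
```

The suite includes `tests/test_acceptance.py`, one test per acceptance
criterion (hypergeometric oracles, normalization contracts, planted-truth
recovery, 2000-replicate permutation calibrations, REML closed-form
equalities, species-match truth). One test,
`test_criterion3_null_calibration_range`, is intentionally red: the
specified null-calibration bracket is unattainable for the fixed
contaminant-score definition, which is conservative (not uniform) under
the null — see the module docstring; the accompanying conservativeness
test passes.

## CLI

```sh
muskin --seed 1 --out-dir bundle simulate               # synthetic bundle + truth tables
muskin --out-dir clean decontam bundle                  # frequency screen, union removal
muskin --out-dir norm normalize clean --depth 4000      # reliability filter + final draw
muskin --out-dir core core norm --level genus           # core sets and partition
muskin --out-dir div diversity norm --metrics shannon,chao1,bray_curtis
muskin --out-dir drv drivers mantel --main geo.tsv --response bray.tsv \
       --conditions cas.tsv,pdist.tsv --nperm 1000
muskin --out-dir drv drivers mixed bundle --response-set alpha,beta-axes
muskin --out-dir sp match-species --queries asvs.fasta --refs clones.fasta \
       --labels species.tsv --delta 0.05
```

`simulate` accepts a `key = value` config file (`--config sim.toml`) whose
keys mirror `muskin.simulate.SimulationConfig`; the desk-scale defaults
run the whole pipeline in seconds, and `SimulationConfig.paper_scale()`
restores study-scale group sizes.

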