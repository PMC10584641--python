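# barcodegap

Evaluation of DNA barcode markers for species identification, aimed at
mitochondrial fragments (COI, Cytb, D-loop) pulled from public sequence
repositories — where mislabeled records, cryptic lineages and saturated
markers routinely corrupt barcode reference libraries. The package is for
researchers who need to ask, before trusting a marker or a reference
library: *does this marker separate species at all, and which records
cannot be trusted?*

It provides, as a library plus a `barcodegap` command-line tool:

* **Distance-based evaluation** — Kimura 2-parameter divergence
  `d = -½·ln[(1-2P-Q)·√(1-2Q)]` with pairwise deletion, the
  nearest-neighbor identification test, the per-sequence *barcoding gap*
  (minimum interspecific minus maximum intraspecific divergence),
  per-species divergence summaries, and Kruskal-Wallis + Dunn/Bonferroni
  comparison of gap distributions between markers.
* **Repository audit** — classification of records into group 1 (consistent
  with their name), group 2 (ambiguous) and group 3 (all conspecific
  distances beyond an outlier threshold: probable mislabels).
* **Tree-based evaluation** — monophyly fractions per species, a class-1/2/3
  clustering audit, neighbor joining and simple clock projections (UPGMA,
  mean path length) as plumbing.
* **Substitution-saturation testing** — the entropy index
  `Iss = H̄ / H_FSS` with OTU resampling, codon-position partitions, and
  Monte-Carlo critical values `Iss.c` for symmetric and asymmetric
  reference topologies.
* **Species delimitation** — single-threshold GMYC on ultrametric trees and
  PTP (maximum likelihood + MCMC co-assignment supports) on substitution
  trees, both as model classes with `fit()` → results objects carrying
  likelihoods, estimates and `summary()`.
* **A synthetic barcode generator** — Yule species trees, grafted
  within-species coalescents, K2P sequence evolution, terminal gap runs and
  planted mislabels, all reproducible from one seed, so every stage is
  testable against known truth.

See `docs/methods.md` for the models, assumptions and numerical choices.

## Worked example

Generate a well-separated ten-species dataset (100 sequences, 600 bp) and
run the identification tests:

```bash
barcodegap simulate --scenario well_separated --seed 42 --out demo/data
barcodegap nn-test --fasta demo/data/alignment.fasta --out demo/nn.tsv
# percent correct: 100.00%
head -3 demo/nn.tsv
# query_id  neighbor_ids        min_distance           conspecific
# SEQ0001   SEQ0004             0.0016891907958136532  true
# SEQ0002   SEQ0008             0.0                    true
```

Every query's nearest neighbor carries its own species label, so 100% of
records are correctly identified. The barcoding gap confirms the regime:

```bash
barcodegap gap --fasta demo/data/alignment.fasta --out demo/gaps.tsv
head -2 demo/gaps.tsv
# query_id  max_intra             min_inter           gap
# SEQ0001   0.008728480321161325  0.138851138621167   0.13012265830000566
```

SEQ0001's farthest conspecific sits at 0.87% divergence while its closest
heterospecific sits at 13.9% — a positive gap of ~0.13 substitutions/site,
and in this dataset every record's gap is positive (unambiguous
identification). Species delimitation on the true gene tree:

```bash
barcodegap delimit --tree demo/data/gene_tree.nwk --method gmyc --seed 1 \
    --out demo/gmyc.tsv
# GMYC single-threshold model
# ===========================
# n tips                 100
# n species (clusters)   11
# threshold (time b.p.)  0.0123953
# lnL null (1 coalescent) 855.8248
# lnL GMYC               862.9854
# LR statistic           14.3211
# LR p (chi2, df=3)      0.002499
```

GMYC places the Yule/coalescent threshold at 0.0124 substitutions/site
before the present and finds 11 clusters for the 10 simulated species (one
species split in two — within the ±1 resolution expected at this
coalescent depth), decisively rejecting the one-population null
(p ≈ 0.0025).

The whole pipeline — QC, distances, nearest neighbor, gaps, summaries,
audit, trees, monophyly, classes, saturation, delimitation, and (with
several markers) the cross-marker comparison — runs as one command:

```bash
barcodegap evaluate --fasta demo/data/alignment.fasta --marker Cytb \
    --seed 1 --out demo/results
```

writing one TSV per result table plus `manifest.json`; identical inputs,
configuration and seed reproduce every output byte for byte.

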