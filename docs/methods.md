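# Methods

`barcodegap` evaluates how well a DNA barcode marker (a short mitochondrial
fragment such as COI, Cytb or the non-coding D-loop) discriminates species,
and delimits putative species directly from trees. This note documents the
models, the estimators, the synthetic-data generator used to validate them,
and the numerical choices that matter.

## Sequence QC

Repository barcode fragments arrive in several lengths; only records whose
ungapped length equals the modal length are retained (`select_modal_length`),
with length ties broken toward the longer fragment (it carries more signal;
configurable). Protein-coding markers are scanned codon-by-codon for internal
stop codons under the vertebrate mitochondrial code (NCBI table 2, the
appropriate code for fish mitochondria; table id configurable). Codons
containing a gap or ambiguity code are skipped rather than flagged, because
gapped sequences are deliberately retained upstream — excluding them would
mask the nuclear-copy contamination the stop-codon check exists to catch.
Alignment columns are 1-based everywhere.

## Divergence

The Kimura 2-parameter model separates transitions (A↔G, C↔T; proportion P
of comparable sites) from transversions (proportion Q):

    d = -1/2 · ln[(1 - 2P - Q) · sqrt(1 - 2Q)]

Sites are compared under *pairwise deletion*: a column counts for a pair only
when both sequences carry an unambiguous A/C/G/T. Ambiguity codes are treated
as missing, not fractionally matched. Pairs with fewer than 50 comparable
sites (configurable) are flagged `too_few_sites`; pairs whose corrected
divergence is undefined (the logarithm's argument is non-positive, which
happens for saturated non-coding fragments) are flagged `undefined`. Flagged
cells are never silently dropped: they are excluded from downstream minima
and maxima with a logged warning. Internally divergences are dimensionless
substitutions/site; reports print them ×100 as percent, so values above 100%
simply mean d > 1 — expected for deeply saturated D-loop-type comparisons.

## Distance-based evaluation

* **Nearest-neighbor test.** Every query's neighbors at the minimum defined
  distance are retained (ties kept, relative tolerance 1e−12). A query is
  correctly identified only when *all* tied neighbors are conspecific;
  `ambiguous` when the tie mixes species. Strict tie handling is the
  conservative choice, and configurable in the sense that ambiguous calls are
  tracked separately from failures.
* **Percent correct** = 100 × (#conspecific) / denominator. Singleton
  species can never have a conspecific neighbor, so they leave the
  denominator by default (`exclude`); `count_incorrect` keeps them as
  failures.
* **Barcoding gap** is computed per sequence: minimum heterospecific
  distance minus maximum conspecific distance. Positive gaps mean the record
  is unambiguously identifiable; the per-record distribution (not one value
  per species) is what the gap histograms summarize.
* **Marker comparison.** Gap distributions across markers are compared with
  the Kruskal-Wallis test (tie-corrected, via scipy) and Dunn's rank-sum
  post-hoc test with Bonferroni correction (implemented here; the Z
  statistic uses the pooled-rank variance with the tie correction
  Σ(t³−t)/(12(N−1))).
* **Repository audit.** Non-singleton records are classified: group 1 when
  the nearest neighbor is conspecific and the closest conspecific lies
  within `intra_threshold` (default 0.03, the conventional teleost
  intraspecific bound); group 3 when *every* conspecific distance exceeds
  `outlier_threshold` (default 0.10) — the record sits far from everything
  sharing its name, the signature of a mislabel or a deeply divergent
  cryptic lineage; group 2 otherwise. Both thresholds are exposed because no
  universal values exist.

## Tree-based evaluation

Trees are dendropy objects; newick I/O preserves branch lengths and
internal-node support labels (values > 1 are read as percentages). When no
externally inferred tree is supplied, the pipeline builds a neighbor-joining
tree from the distance matrix (falling back to p-distances when K2P cells
are undefined). The NJ implementation clamps negative branch-length
estimates to zero and moves the deficit to the sister branch, which
preserves path lengths and recovers additive matrices exactly. Rooting uses
the outgroup edge midpoint when an outgroup is given, midpoint rooting (with
a log note) otherwise.

A species is **monophyletic** when the MRCA of its tips contains no other
species' tips. Singletons count as monophyletic by default (they cannot be
paraphyletic) or can be excluded — both policies are reported because
published monophyly percentages rarely state which was used.

The **class audit** mirrors the repository audit on the tree: class 1 =
monophyletic with MRCA support ≥ 0.90 (missing supports do not block class
1, so NJ trees without bootstrap values remain classifiable); class 3 = a
non-monophyletic species whose enclosing minimal clade wholly contains two
or more species (cohesive mixing — the clade must be a proper subclade of
the tree, otherwise mere scattering would qualify); class 2 = everything
else (no intraspecific clustering).

**Clock projection.** GMYC needs an ultrametric tree. Two simple projections
are provided: UPGMA from the distance matrix (scipy average linkage;
cophenetic heights halved into node ages) and mean-path-length smoothing of
an existing rooted tree (each node's age is the mean path length to its
descendant tips, monotonized so parents stay older than children). Penalized
-likelihood dating is deliberately out of scope; for the shallow, clock-like
simulated data these projections feed GMYC adequately, and real analyses can
import an externally dated tree instead.

## Substitution saturation (entropy index)

Saturation — multiple hits erasing signal — is tested by comparing the mean
per-site entropy of the alignment with the entropy expected at full
saturation. For a column with n unambiguous residues, H = −Σ p_b log2 p_b.
Under full saturation every cell is an iid draw from the global base
frequencies; the expected column entropy H_FSS is computed *exactly* by
enumerating all multinomial count compositions of n among the four bases
(≤ 6,545 compositions at n = 32; cached). The index is

    Iss = H_mean / H_FSS

which is 0 for invariant alignments and ≈1 for random ones (slightly above
1 is possible because H_FSS is an expectation). The observed Iss is
resampled: each replicate draws `n_otu` sequences without replacement
(defaults 4/8/16/32 OTUs, 1,000 replicates, seeded); the mean and the
standard error across replicates are reported. Columns keep their usable
cells (gapped/ambiguous cells are dropped per column; columns with fewer
than two usable residues are skipped).

**Critical values.** Iss.c is the index value at which tree reconstruction
stops working. It is estimated by Monte-Carlo simulation, not copied from
external tables: alignments evolve (Jukes-Cantor) on two reference
topologies over a grid of root-to-tip depths (geometric, 0.05–8
substitutions/site, 14 points, 12 replicates each, 600 bp); at each depth
the whole-topology recovery rate of p-distance NJ is recorded, normalized
against the random-alignment floor, and Iss.c is the interpolated mean Iss
where recovery crosses 50%. The reference geometries are chosen to probe the
reconstruction-hostile regime the test guards against: both topologies place
short internodes (depth / 2·log2 n) under long terminal branches; the
symmetric tree is a clock-like balanced tree, the asymmetric tree is a
pectinate ladder whose terminals alternate long/short — a long-branch-
attraction geometry that is systematically harder. Two qualitative
properties follow and are verified by the acceptance suite: Iss.c(sym) >
Iss.c(asym) at every OTU count, and Iss.c falls as OTUs are added (more
bipartitions must all be recovered). The absolute values depend on this
simulation design and are not comparable to other programs' tables.

**The test.** Observed Iss is compared to each critical value with a
one-sample t test across resampling replicates, df = usable columns − 1
(the convention of the source test). Verdicts: `no saturation` when Iss is
significantly below Iss.c, `saturated` when significantly above,
`inconclusive` otherwise; the headline verdict uses the symmetric critical
value and both are reported. For coding markers the test runs on the whole
alignment, codon positions 1+2, and codon position 3 separately.

## GMYC (single threshold)

The general mixed Yule-coalescent model locates a time threshold on an
ultrametric tree separating interspecific (Yule) branching from
intraspecific (coalescent) branching. Branching events are ordered from the
root; candidate thresholds place the j oldest events in the speciation class
(j = 0 … n−1; the partition into clusters is the set of branches crossing
the threshold, so the fitted species count is j+1, singletons included).

The likelihood is assembled over the *same* set of inter-event waiting times
for every threshold (conditioned on the root event): during an interval
above the threshold the branching rate is λ₁·m^p₁ (m = lineages present);
below the threshold it is λ₁·(j+1)^p₁ + λ₂·σ^p₂, where σ = Σ_c k_c(k_c−1)
pools the within-cluster lineage-pair counts and the first term is the
diversification background of the j+1 persisting species lineages. Each
interval contributes ln b − b·x. The scaling exponents p allow the rate to
deviate from the strict Yule/Kingman forms, as in the source model. For each
j the four parameters are maximized jointly (L-BFGS-B on log-rates, p
bounded in (0, 3], initialized from closed-form single-class profile fits);
the best j wins. The null model is a single coalescent class λ·(k(k−1))^p
fitted to the same intervals; the j=0 model nests it as λ₁ → 0, so
lnL(GMYC) ≥ lnL(null) by construction. The likelihood-ratio test uses
χ² with df = 3 (two extra rate parameters plus the threshold), the
convention of the original single-threshold method; measured type-I error
on 100 simulated single-population coalescent trees is ~0.05 at the nominal
0.05 level.

Numerical details: node ages must be strictly decreasing, so tied heights
are perturbed by a relative 1e−9 ladder; waits smaller than 1e−8 × tree
height are masked out of the likelihood for every threshold and the null
alike (a zero wait carries no waiting-time information, and its perturbed
exponential density would otherwise reward whichever class absorbs it).
Input must be rooted and ultrametric within a relative 1e−6 spread; ≥ 4
tips.

## PTP (Poisson tree processes)

PTP works on substitution branch lengths directly: within-species and
between-species branches are two exponential classes. A candidate
delimitation is an antichain of subtree roots covering all tips; edges
strictly inside those subtrees are within-species, all others
between-species. Rates are profiled out (λ̂ = E/S per class), so the
partition log-likelihood is E_w·(ln(E_w/S_w)−1) + E_b·(ln(E_b/S_b)−1).
Zero-length branches are floored at 1e−9 to keep the likelihood finite.

The ML search is greedy hill-climbing over split (replace a species root by
its children) and merge (replace sibling species roots by their parent)
moves, from deterministic starts (single species; every tip a species) plus
seeded random antichains (10 restarts by default). Both move types have
O(1) likelihood deltas via precomputed subtree sums. The two-class fit is
compared to the one-rate null by AIC; a homogeneous (star-like) tree
therefore returns one species rather than an arbitrary split.

The Bayesian-flavored variant (`fit_mcmc`, defaults 100,000 steps, 10%
burn-in, thinning 50, seed required) runs Metropolis-Hastings over the same
move set, with the Hastings ratio given by the move-count asymmetry,
targeting the profile likelihood — a documented simplification relative to
a full treatment with rate priors. It reports per-tip-pair co-assignment
frequencies and the posterior-mode species count; a fixed seed reproduces
the chain exactly.

## Synthetic data generator

The generator produces the repository-like datasets every stage is tested
against, with full ground truth:

1. **Species tree**: Yule (pure birth), forward-simulated to n species with
   a trailing Exp(nλ) interval, then scaled to the requested root-to-tip
   depth (expected substitutions/site).
2. **Gene tree**: independent Kingman coalescents per species — with k
   lineages the waiting time is Exp(k(k−1)/θ), making θ the expected
   intraspecific pairwise divergence — grafted onto the species-tree tips
   (rescaled with a log note in the rare case a coalescent outreaches its
   stem). Tips at the present; the gene tree is ultrametric.
3. **Sequences**: K2P substitution along branches with transition/
   transversion rate ratio κ (default 4, typical of fish mitochondrial
   fragments), root drawn from the base frequencies, optional per-site rate
   multipliers (used to emulate elevated third codon positions). The
   generator deliberately matches the analysis model so that
   distance-estimator consistency is testable in isolation.
4. **Partial reads**: terminal truncations replaced by gaps; each record
   loses Uniform(0, 2·gap_rate) of its columns split between the two ends.
5. **Mislabels**: a seeded Bernoulli(rate) draw per record; hits receive a
   uniformly chosen *different* species label; the truth table records
   true species, assigned label and the flag.

One master seed drives everything; rerunning a scenario reproduces every
output byte.

### Scenario presets and what they represent

| scenario | geometry | regime |
|---|---|---|
| `well_separated` | 10 sp × 10, depth 0.2, θ 0.005 | positive-gap marker (Cytb-like) |
| `overlapping` | 10 sp × 10, depth 0.02, θ 0.02 | negative-gap marker (COI/D-loop-like) |
| `saturated` | 10 sp × 4, depth 5.0 | saturated non-coding marker |
| `singleton_rich` | 20 sp, 30% singletons | sparse repository coverage |
| `mislabeled` | 20 sp × 20, depth 0.5, 5% mislabels | repository-audit calibration |

`well_separated` additionally rejection-samples the Yule tree until the
youngest speciation is ≥ 0.15 × depth (`singleton_rich`: 0.10). This
conditioning is the preset's *definition*: an unconditioned Yule tree
routinely places its youngest split inside the coalescent scale, which
contradicts what "well separated" is supposed to exercise. The same logic
applies to the GMYC strong-separation validation (youngest split ≥ 0.05 ×
depth, i.e. ≥ 5× the coalescent depth). Fractions of runs meeting a target
in these regimes therefore speak to performance *under the stated regime*,
not on arbitrary Yule draws — and not on real data, where rate variation,
non-clock evolution, selection, indel processes and alignment error (all
deliberately excluded here) make every task harder.

## Problem sizes

Validation runs use desk-scale sizes chosen to keep the full suite
reproducible on a laptop: 100–400 sequences per synthetic dataset, 20-seed
replicate batches for regime checks, 100 null trees for the GMYC type-I
measurement, 12-replicate × 14-depth grids for saturation critical values,
and 10–20k MCMC steps in tests (the library default remains 100k).

## Known limitations

* Distance variance estimators and substitution models beyond K2P/p are out
  of scope, as are alignment itself, Bayesian/ML tree inference and
  bootstrap support.
* Iss.c values are tied to this package's simulation design; only their
  orderings (symmetric > asymmetric; decreasing in OTU count) are
  design-independent.
* The GMYC clock inputs produced by UPGMA/MPL are crude relative to proper
  dating; thresholds on real data should come from externally dated trees.
* bPTP support values are profile-likelihood MCMC frequencies, not a full
  posterior.
* The audit thresholds (3% / 10%) are field conventions, not estimates; on
  markers whose intraspecific divergence exceeds them the audit will
  over-assign group 3, which is visible in the `saturated` scenario.
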