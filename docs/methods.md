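# Methods

## Scope and model

`cernet` screens for lncRNA–mRNA pairs that behave as competing endogenous
RNAs with respect to a shared miRNA pool, in a two-group (CC vs GC), 3-vs-3
replicate bulk RNA-seq design. The screen is deliberately the classic
cascade — differential expression → seed-match target prediction →
shared-miRNA hypergeometric overlap → correlation filters — rather than a
model-based estimator: each stage is an independently testable primitive
with an exact or brute-force oracle.

### Normalization

mRNA/lncRNA: FPKM_is = 1e9·C_is/(N_s·L_i), with N_s the per-sample column
total of counts; miRNA: tags-per-million TPM_is = 1e6·C_is/N_s (small-RNA
tags are sequenced whole, so no length correction). A length-normalized TPM
variant for long transcripts is provided for completeness; every TPM column
sums to 1e6 by construction. No library-size factor estimation beyond
column totals, no batch correction.

### Differential expression

Welch's two-sample t on log2(normalized value + pseudocount), pseudocount
default 1. Gates: |log2FC| ≥ 1 and BH FDR < 0.05 for mRNA/lncRNA;
|log2FC| ≥ 1 and raw p < 0.05 for miRNA (the small-RNA convention of gating
on the unadjusted p). Fold change is oriented as group B relative to group
A, A being the first group in column order (CC here). Zero variance in both
groups with equal means yields p = 1 by convention; zero variance with
different means yields p = 0. This is a documented stand-in for a dedicated
count model (dispersion shrinkage is out of scope); the downstream stages
accept externally computed (p, log2FC) tables so that output of such a tool
can be substituted. At n = 3 per group the Welch test has limited power —
see *Generator calibration* below for the consequences.

### Target prediction

Canonical seed grammar on the transcript sense strand, DNA alphabet,
no G:U wobble: 6mer = revcomp(miRNA nt 2–7), 7mer-m8 = revcomp(nt 2–8),
7mer-A1 = 6mer + site A, 8mer = 7mer-m8 + site A. Each seed-core position is
reported once as its strongest matching type (8mer > 7mer-m8 > 7mer-A1 >
6mer); coordinates are 1-based inclusive. Default interaction gate:
≥ 1 site of type 7mer-A1 or better (bare 6mers carry little repression
signal). Full transcript sequences are scanned because lncRNAs have no UTR
annotation; free-energy alignment, conservation and context scores are out
of scope. The whole-pair site sets are verified against a naive substring
oracle in the tests.

### Competing-pair scoring

For each (DE lncRNA, DE mRNA) pair sharing ≥ 1 DE miRNA regulator:
upper-tail hypergeometric p for k shared regulators out of targeting-set
sizes K and n in a universe of N miRNAs, BH-adjusted across all scored
pairs. The universe is, by default, the DE miRNAs with ≥ 1 predicted
interaction among DE transcripts (the smallest defensible choice);
`universe="all_de"` counts every DE miRNA instead and is preferable when
few miRNAs have predicted targets, since with K = n = k = 1 the p-value is
exactly 1/N. A shared miRNA counts as screening evidence only when its
Spearman correlation with *both* partners is ≤ the regime threshold
(either-arm semantics available by flag). A pair passes when hypergeom p <
p_max, Pearson r(lncRNA, mRNA) ≥ r_min, and ≥ 1 screening miRNA exists.

Two named regimes: **lenient** (ρ ≤ −0.7, r ≥ 0.9, p < 0.05; the default
for network construction) and **strict** (ρ ≤ −0.95, r ≥ 0.95, p < 0.01
plus hypergeometric FDR < 0.01; for reporting high-confidence pairs).
Strict output is a subset of lenient output by construction. Correlations
are computed on normalized values pooled over all six samples; with n = 6
this is fragile and is the main reason the generator defaults to clean,
well-expressed planted transcripts. Constant vectors yield NaN (flagged
missing, never silently 0), and NaN fails every gate.

### Network

Tripartite typed graph: lnc_mi and mi_m interaction edges for every shared
miRNA of a passing pair, plus an explicit ceRNA (lncRNA–mRNA) edge carrying
the pair statistics. Type constraints are asserted on every build. Exports:
SIF, GraphML (with the circle/triangle/diamond shape convention and DE
calls as node attributes, thresholds as graph provenance) and edge TSV;
GraphML round-trips losslessly. Subnetwork extraction reports the focus
node's miRNA/lncRNA neighbour counts.

### qPCR validation

Pure Livak 2^−ΔΔCt (100% amplification efficiency; no Pfaffl correction).
Technical replicates are averaged on the Ct scale before ΔCt. The
concordance report gives per-target sign agreement between RNA-seq log2FC
and log2 of the qPCR fold change, plus Spearman ρ across shared targets.

## Synthetic-data generator

The generator emulates the study design: three replicates per group for
three libraries (mRNA, lncRNA, miRNA), negative-binomial counts with
per-transcript log-normal baselines (log-mean 4.0, log-sd 1.2, natural
log), per-sample library-size factors (log-normal, CV 0.1 — library sizes
are a free parameter of the design), and a planted fold change of 4 for DE
transcripts (symmetric split between groups, direction random). Planted
sponge triples additionally share a per-sample latent factor on the
log-mean scale, amplitude 0.12 × `planted_corr_strength` (natural log),
entering both ceRNAs positively and the miRNA negatively; each triple's
miRNA seed site (8mer) is written verbatim into both partner transcripts at
a recorded position.

Defaults that required genuine design choices, and why:

- **nb_dispersion = 0.002, planted/DE expression floors 1500/50 counts.**
  The screening cascade must survive an n = 3 Welch test *and* rank
  correlations over 6 samples. The latent sponge factor is within-group
  variance for the DE test, so its amplitude must stay well below the fold
  change while dominating counting noise for the rank screens; that forces
  low dispersion (clean cultured-cell replicates) and well-expressed
  planted transcripts. Real tissue data are noisier — passing recovery
  tests here demonstrates correctness of the screens, not power on noisy
  designs.
- **Sequence composition: transcripts 12% GC, miRNAs 70% GC with ≥ 5 G/C in
  the seed.** With uniform composition the incidental seed-match rate is
  heavy-tailed (AT-rich seeds match almost every transcript), which
  inflates hypergeometric targeting sets until a single shared planted
  miRNA is no longer significant, and floods the pair search with spurious
  co-DE candidates. The composition skew keeps incidental matches rare but
  nonzero; they occur, are absent from the truth table, and count against
  precision when recovered.
- **Decoy DE fractions 0.15/0.20/0.20** (mRNA/lncRNA/miRNA): enough
  non-sponge DE background for the BH family and the miRNA universe to be
  realistic at this scale without overwhelming the pair search.

What the generator does *not* emulate: read-level data, multi-site and
multi-miRNA regulation (each planted triple shares exactly one miRNA, so
k = K = n = 1 for clean planted pairs), dispersion trends with expression,
UTR structure, G:U wobble sites, and correlated DE across transcripts.
Recovery metrics are defined strictly against the truth table.

## Numerical choices

- Hypergeometric tails via `scipy.stats.hypergeom.sf(k-1, N, K, n)`;
  k = 0 returns exactly 1. Verified against exhaustive subset enumeration
  for every valid (N ≤ 12, K, n, k) at 1e-12 relative tolerance.
- BH step-up is order-preserving, capped at 1, stable under ties
  (mergesort), and matches a literal step-up implementation on random
  vectors.
- Spearman uses average ranks for ties (rank then product-moment).
- Determinism: every stochastic step draws from
  `numpy.random.default_rng([seed, stream])`; identical seeds give
  byte-identical FASTA/TSV/JSON outputs.
- Test problem sizes: module tests use a scaled-down design (400/120/150
  transcripts, 10 triples); the recovery acceptance test runs the full
  design (2000/500/300, 50 triples) over a fixed 20-seed panel, which
  pilot runs place at recall ≈ 0.95 and precision ≈ 0.90 against the
  ≥ 0.8 acceptance bounds.

## Known limitations

- The Welch DE stand-in is anticonservative/underpowered relative to
  shrinkage-based count models at n = 3; it is a pluggable default, not a
  recommendation.
- Correlation screens on six pooled samples conflate group separation with
  within-group co-variation; strongly DE but unrelated transcript pairs can
  pass the Pearson gate and are filtered mainly by the shared-miRNA
  requirement.
- With single-miRNA planted triples the strict regime (p < 0.01) passes
  only when the miRNA universe exceeds 100, so strict networks on synthetic
  defaults are nearly empty; on real data with larger shared-regulator sets
  this does not apply.
- Seed matching ignores site accessibility, conservation and 3'
  supplementary pairing; predicted interactions are an upper bound.
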