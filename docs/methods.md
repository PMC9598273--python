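# Methods

## Study design and data model

The pipeline operates on a fully crossed grouped design: a set of
tissues × a set of sexes, each group with the same number of replicate
samples. The default is 4 tissues (brain B, gonad G, liver L, muscle M)
× 3 sexes (female F, male M, pseudo-male PM) × 3 replicates — 36
samples named `<sex><tissue><rep>` (FB1…PMM3). Pairwise differential
expression compares sexes within a tissue (12 comparisons by default);
network correlations are computed across the 12 group-mean profiles.

All genomic coordinates are 0-based half-open (BED convention); GFF3 is
converted on read/write. Sequences are held in DNA space with U→T
normalisation at FASTA ingest, so seed matching is alphabet-agnostic.

## Differential expression

**Normalisation.** TMM-style factors: per sample, the trimmed mean of
per-feature log2 ratios to a reference sample (the one with the most
typical upper quartile), after removing the raw library-size effect and
trimming 30% of M-values and 5% of A-values at each end. Factors are
rescaled to geometric mean 1; effective library size = raw total ×
factor.

**Test.** The classic conditional negative-binomial exact test for
two-group counts. For one feature with group sums (S_a, S_b), replicate
counts are modelled NB(μ, φ) with a common dispersion φ
(variance = μ + φμ²); group sums are NB with size n/φ and means
proportional to the groups' summed effective library sizes. The
p-value sums the conditional probabilities P(k | S_a + S_b) of all
outcomes no more likely than the observed S_a (the "minlike" two-sided
rule). At φ = 0 the conditional law is binomial on the library-size
proportions, recovering the Poisson-conditional (binomial exact) test.

Unequal library sizes are handled inside the null distribution rather
than by rescaling counts: scaling NB counts by a constant changes their
mean–variance relation and measurably inflates the type-I error when
group library sizes are imbalanced, which is why the implementation
passes raw counts plus effective library sizes to the test.

**Dispersion.** Common φ per comparison by pooled method of moments:
from E[s² − m] = φμ² within each group, φ̂ = Σ(s² − m) / Σm² over
features with mean ≥ 1 (ratio of sums, not mean of ratios — far less
biased at n = 3). Floor 1e-6 for numerical stability. Under a simulated
NB null (φ = 0.1, 10,000 features, 3 vs 3) the realised fraction of
p < 0.05 sits at ≈ 0.05 across seeds.

**Calling.** A feature is significant iff |log2FC| ≥ 1 and p < 0.05
(raw p; BH adjustment available but off by default, matching the
threshold convention the pipeline targets). log2FC is computed on
normalised group means with pseudo-count 0.5 to avoid infinities.
Exact replication of edgeR's numbers is a non-goal; the test is the
same conditional construction with a simpler dispersion estimator.

## circRNA classification

Classes are assigned by precedence with a ±2 nt boundary tolerance
(absorbing off-by-one dialects between callers):

1. `annot_exon` — same strand; both back-splice ends within tolerance of
   exon boundaries of one gene; body segments (exon blocks if present)
   covered by that gene's exons.
2. `exon_intron` — same-strand overlap of one gene touching both exonic
   and intronic sequence.
3. `antisense` — gene overlap on the opposite strand only.
4. `intergenic` — no gene overlap.
5. `other` — anything else (sub-exonic intervals off the boundaries,
   intron-only circles).

The precedence makes classes mutually exclusive; multi-exon circles are
judged on their exon blocks so the genomic span's introns do not defeat
the coverage check. Length bins are edge-inclusive: [100, 2500],
[2501, 10000], other.

## Seed-match target prediction

Seed = mature miRNA nucleotides 2–8. The scanner anchors on the 6mer
core (reverse complement of positions 2–7), then upgrades by the m8
match one base 5′ on the transcript and the A anchor one base 3′:
8mer (m8 + A), 7mer-m8, 7mer-A1, 6mer. One site per core position, the
strongest satisfied class. Context scoring, conservation and
non-canonical sites are deliberately out of scope: seed classes are the
reproducible core of canonical target prediction, and the downstream
correlation filters do the specificity work. miRNAs shorter than 8 nt
are rejected rather than padded.

## ceRNA network

For each transcript t (DE circRNA or DE mRNA), the candidate-regulator
set is the DE miRNAs with predicted sites on t whose expression
anti-correlates with t (Spearman < −0.7 on group means). A triplet
(c, m, g) is retained iff m is a candidate regulator of both c and g,
Pearson(c, g) > 0.9, and the shared-sponge test on the two candidate
sets gives p < 0.05. All threshold inequalities are strict; undefined
correlations (constant profiles) count as filter failures, not errors.

**Shared-sponge test.** With K = |candidates of c| and n = |candidates
of g| drawn from a universe of N DE miRNAs, p = P[X ≥ shared] for
X ~ Hypergeom(N, K, n), one-sided (enrichment of sharing), no
multiple-testing correction by default (BH available). The universe
defaults to the DE miRNA count and is configurable. Defining the
candidate sets after the anti-correlation filter keeps chance seed
matches (a 6mer occurs every ~4 kb of random sequence) from swamping
the sharing signal in the small universes that desk-scale data sets
produce; the test then asks exactly whether the regulators the network
logic actually uses are shared more than chance allows.

**Group means, not replicates.** Correlations span tissues and sexes,
so the 12 group-mean profiles are the natural unit; a replicate-level
mode exists behind a flag.

**Exports.** nodes.tsv / edges.tsv / triplets.tsv round-trip
losslessly; sankey.tsv holds one circRNA→miRNA or miRNA→mRNA link per
network edge; heatmap_matrix.tsv is the circRNA group-mean matrix
row-standardised (zero mean, unit variance; zero-variance rows are left
centred).

## Enrichment

Standard one-sided hypergeometric over-representation against
user-supplied (term_id, term_name, gene_id) tables with BH adjustment
across tested terms. Query genes outside the background are dropped
with a warning; empty terms are skipped. No live database queries, so
results are database-version independent.

## qPCR

Livak relative quantification: per replicate ΔCt = Ct_target −
Ct_reference; per group ΔΔCt = mean ΔCt(group) − mean ΔCt(calibrator);
fold = 2^−ΔΔCt. Replicates are averaged within group before the ΔΔCt
step (the common Livak usage); a per-replicate mode is available. The
calibrator's own fold is exactly 1 and whole-sample plate offsets
cancel. Concordance against RNA-seq reports the sign-agreement fraction
and Spearman correlation between log2(fold) and the RNA-seq log2FC over
shared targets. Amplification-efficiency correction and ANOVA are out
of scope; junction-spanning (divergent) primer pairs are tracked only
as a boolean bookkeeping flag per circRNA target.

## Synthetic data generator

The generator's defaults are the study conditions the test suite and
acceptance script measure under; they are not tuning knobs.

- **Annotation**: multi-exon genes (2–6 exons of 120–400 nt, introns
  200–1500 nt) laid out without overlap on either strand — stronger
  than biologically necessary, but it keeps planted circRNA classes
  unambiguous. The last chromosome ("W") receives ~10% of the mean
  genes per chromosome, emulating a degenerate female-specific sex
  chromosome.
- **circRNAs**: planted per class by construction (see classification
  rules above); the default class mix is {annot_exon 0.67, exon_intron
  0.16, antisense 0.06, intergenic 0.04, other 0.07} with lengths in
  [100, 2500] nt; largest-remainder apportionment keeps realised
  fractions within 1/n of the mix.
- **Counts**: NB with a single user-set dispersion per matrix
  (default 0.1), lognormal baseline abundances (median 50), per-sample
  relative library factors uniform in [0.7, 1.3]. DE features
  (default 10%) get a 2^±lfc effect (default lfc 2) in one random
  (sex, tissue) group; the truth ledger records them under the two
  within-tissue comparisons involving that sex. Pooling of individuals
  into replicate samples is not modelled explicitly — dispersion is the
  single knob for biological + technical variance.
- **ceRNA triplets**: planted in (circRNA, mRNA) pairs sharing two
  sponge miRNAs, so the hypergeometric sharing is significant whenever
  the DE-miRNA universe has ≥ 7 members; a lone shared miRNA would need
  a universe > 20, which small bundles cannot guarantee. Each pair gets
  a geometric ladder of group means (adjacent groups two-fold apart,
  base ~20), shared by circRNA and mRNA and reversed for its miRNAs, so
  true-mean correlations are ±1 and every within-tissue comparison has
  |log2FC| ≥ 1. Planted rows are re-drawn at dispersion 0.05 and
  checked against the correlation targets (bounded retries), and an
  8mer site for each sponge miRNA is written at non-overlapping
  positions into both partner sequences. Default: 8 triplets.
- **Sequences**: random uniform A/C/G/T (miRNAs 22 nt, 3′UTRs 500 nt,
  circRNAs at their spliced length, capped to [100, 2500]); random
  term maps of 20 terms with 5–25 genes.

What the generator does *not* emulate — read-level errors, GC and
length biases, correlated dispersion trends, isoform ambiguity, shared
miRNA family seeds — bounds what passing tests show: recovery results
demonstrate the statistical machinery is correct and calibrated under
the stated model, not that real libraries meet the model.

## Determinism and numerics

Every stochastic step takes an explicit seed; bundle generation derives
per-stage seeds from one master seed via a seed sequence, and two runs
of the pipeline with the same config produce byte-identical outputs
(verified via per-file SHA-256 in the manifest, which records no
timestamps). Two-sided exact p-values use a 1e-10 relative slack when
collecting outcomes "no more likely than observed" to absorb log-pmf
rounding; correlation ties get average ranks; dispersion floor 1e-6;
log2FC pseudo-count 0.5.

## Problem sizes

Default bundle: 8 chromosomes, 200 genes, 200 circRNAs, 60 miRNAs,
150 mRNAs, 8 planted triplets. Calibration checks use 10,000 features;
classification recovery uses 2,000 planted circRNAs over 300 genes;
the permutation negative control averages 20 label permutations. These
sizes give stable Monte-Carlo estimates (binomial SE ≤ 0.005 on the
calibration rates) while keeping a full verification run in well under
a minute per stage.
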