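# Methods

`repsig` analyses paired tumor / adjacent non-tumor adaptive immune
repertoires (AIRR-seq clonotype tables) the way they are analysed in
tumor-immunology cohort studies: per-sample diversity, paired-sample
overlap, BCR somatic-hypermutation structure, gene-usage ordination, rank
statistics across clinical groups, and survival stratification by
repertoire features. This note records the model choices, their defaults,
and what a green test does and does not establish.

## Productive-clonotype QC

A clonotype is retained iff all three hold:

1. CDR3 amino-acid length >= 4;
2. CDR3 nucleotide length is a multiple of 3;
3. the CDR3 contains no stop codon.

Stop detection uses the amino-acid string when present (`*` or `_`, the
frameshift/stop markers emitted by common clonotype callers); when only
nucleotides are available, the frame-0 translation is checked. Filtering
acts on clonotype records, each carrying its duplicate/read count; counts
are never redistributed. The filter is idempotent and order-preserving.
Counts are read weights, not cell counts, and all downstream metrics use
them as-is — no depth normalization or rarefaction is applied.

Gene calls are truncated to gene level (allele suffix after `*` dropped);
multi-hit lists keep the first, top-scoring call.

## Feature levels

Every repertoire feature is computed at two levels:

* **CDR3aa** — clones identified by the CDR3 amino-acid sequence;
* **VDJ** — clones identified by the joint (V, D, J) gene-segment
  combination, empty D for chains without a D segment. Gene-combination
  identity (not nucleotide-level rearrangement identity) is the working
  definition here.

## Diversity

For clone frequencies $p_i = x_i / \sum_j x_j$:

* richness $S$ = number of distinct clone labels;
* Shannon entropy $H = -\sum_i p_i \ln p_i$ (nats);
* evenness $\mathrm{NSDE} = H / \ln S$ (Pielou's $J$), defined as 0 when
  $S = 1$ (a monoclonal repertoire is maximally uneven; this avoids 0/0).

The log base cancels in NSDE, so the choice of nats is cosmetic. No Hill
numbers beyond these are computed.

## Morisita–Horn similarity

For two profiles with counts $x_i, y_i$, totals $X, Y$ and concentrations
$d_x = \sum x_i^2 / X^2$, $d_y = \sum y_i^2 / Y^2$:

$$\mathrm{MHSI} = \frac{2 \sum_i x_i y_i}{(d_x + d_y)\, X Y}$$

MHSI is symmetric, invariant to scaling either profile, bounded in
[0, 1], 1 for identical relative abundances and 0 iff the supports are
disjoint. It is computed on abundances (the index's definition), not on
presence/absence, and is exposed at both feature levels because either is
defensible for paired-tissue overlap.

## SHM clone networks

An IgH clone with >= 1 V-region nucleotide mismatch to germline is
*mutated*; 0 mismatches is *original*; missing mismatch counts are
*unknown* and excluded from percentage denominators only (such clones
still count toward diversity). Percentages are clone-based, not
count-weighted, because the quantity of interest is the fraction of
distinct clones carrying mutations; a count-weighted variant would answer
a different question.

Mutated clones of one sample (per isotype and combined) form a network.
The edge rule — identical V gene, identical J gene, equal CDR3aa length,
CDR3aa Hamming distance <= 1 — is the standard clonal-lineage grouping
convention in BCR network analysis; the distance threshold is a parameter.
Statistics:

* **average degree** = (sum of node degrees) / (number of nodes) = 2E/N,
  0 for an empty network;
* **EXd1** = average degree after removing, in one simultaneous pass, every
  node whose degree is exactly 1 (degree-0 nodes are retained). The
  single-pass rule is a literal reading of "exclude nodes with only one
  connection"; an iterative 2-core variant would be stricter and is not
  the default.

## Gene-usage ordination

Per-sample count-weighted segment frequencies (V, J, or joint V-D-J) form
a compositional matrix (rows sum to 1). PCA runs on column-centered,
unscaled frequencies — rows are already on a common scale, so variance
scaling would inflate rare segments. MDS is classical (Torgerson) metric
MDS on Euclidean row distances, which on such input reproduces PCA scores
up to per-axis sign; signs are fixed deterministically (largest-magnitude
loading, respectively coordinate, made positive).

## Cohort statistics

* Paired comparisons: Wilcoxon signed-rank, zero differences dropped,
  midranks for tied |differences|. Exact two-sided p by full enumeration
  of the $2^n$ sign assignments for $n \le 12$; otherwise normal
  approximation with tie correction and 0.5 continuity correction.
* Independent groups: Mann–Whitney U with midranks; exact p by
  enumeration of rank splits for $n_a + n_b \le 12$, else tie-corrected
  normal approximation with continuity correction.
* Two-sided p everywhere ("significant" means p < 0.05); the exact and
  approximate branches share the midrank treatment so the dispatch
  threshold does not change how ties are handled.
* Correlations: Spearman (Pearson on midranks, t-approximation).
* Categorical tables: Fisher's exact test (2x2, two-sided by the
  point-probability rule — the R convention; SPSS may differ slightly in
  edge cases) when any expected cell < 5, else Pearson chi-square without
  continuity correction.
* No multiplicity correction by default, matching common practice of
  reporting raw p; Benjamini–Hochberg q-values are available via a flag.
* Missing values: pairwise deletion per test; every result reports the n
  actually used.

## Survival

Features are dichotomized at the cohort median (ties to "low" — a
deterministic, assumption-free cut; the threshold is configurable).
Kaplan–Meier product-limit curves per group, two-group log-rank test, for
PFS, RFS and OS endpoints. With every subject censored the curves are
returned (identically 1) and the test is reported as undefined rather
than p = 1. No Cox or multivariable modelling: the package reports
stratified curves only.

## Synthetic cohort generator

The generator provides the paired-design data the analyses assume, with
enough ground truth to predict every expected value in the tests.

* **Cohort size**: 64 patients by default (the emulated study design),
  paired tumor/non-tumor libraries for TRA, TRB, TRG, TRD and IGH.
* **Clone abundances**: Zipf law — rank-i clone gets
  `max(1, round(N_max / i**alpha))` reads, `N_max = 1000`,
  `alpha = 1.2` (tumor) vs `1.0` (non-tumor), making tumors more clonal.
  The power law is the canonical repertoire clone-size model; the
  deterministic rank counts make evenness strictly monotone in alpha,
  which the recovery tests exploit. A side effect is that CDR3aa richness
  equals the configured clone budget exactly — real repertoires vary in
  richness; recovery tests that need richness variation get it from the
  SHM lineage machinery or per-sample configs.
* **Clone labels**: V/D/J segments from per-chain pools (sizes mirroring
  the human loci) with rank-skewed usage; CDR3aa = 'C' + uniform letters
  at a length drawn from a peaked 8–20 distribution; nucleotides are a
  random synonymous codon spelling, so generated clones are productive by
  construction.
* **Sharing**: `shared_fraction` (default 0.2 — paired-tissue repertoire
  overlap is weak, on the order of a few percent to tens of percent) of
  tumor clones copy non-tumor labels at matched abundance rank; the rest
  are rejection-sampled to be disjoint from the paired sample. Hence MHSI
  is exactly 0 at zero sharing and ~1 at full sharing with equal alpha.
* **Nonproductive spike-in**: 5% extra clones violating exactly one QC
  rule each, ids recorded in the manifest, so the filter contract is
  checkable exactly.
* **SHM**: each IgH clone mutates with probability 0.5; mutated founders
  spawn `Geometric(0.5)`-size star lineages (members differ from the
  founder at exactly one distinct CDR3aa position, share V/J/isotype,
  carry >= 1 mismatch). Stars give closed-form degrees (2k/(k+1)) for
  network tests. Because descendants are themselves mutated clones,
  lineage growth inflates the clone-level mutated fraction above the
  founder mutation probability; recovery tests of the mutation
  probability therefore run with lineage size pinned to 1, where the
  binomial model holds.
* **Clinical cohort**: sex/stage/recurrence frequencies default to the
  emulated 64-patient cohort's proportions; survival times are
  exponential with hazard `rate * HR^high`, where `high` marks patients
  above the cohort median of tumor IgH evenness and `HR = 0.4` (the
  injected protective effect), censoring independent exponential.
* **Determinism**: every stream is keyed by (seed, patient, tissue,
  chain, purpose), so identical configs are byte-identical on disk and
  adding patients never perturbs existing samples.

What the generator does **not** emulate: sequencing error and PCR
amplification noise, read-depth variation between libraries, isotype
class-switch dynamics, tree-shaped (non-star) lineages, and biological
correlation structure between chains of one patient. A green recovery
test therefore establishes that the analysis recovers the generator's
stated effects, not that it would behave identically on real AIRR-seq
data.

## Numerical conventions

* Exact-test tie handling uses a 1e-9 comparison tolerance on midrank
  sums (midranks are half-integers; the tolerance guards float error).
* Ordination signs are fixed per axis as above; eigenvalues of the MDS
  Gram matrix are clipped at 0 before the square root.
* Empty repertoires propagate as missing metric values, never as zeros;
  undefined tests raise (library use) or are skipped with the reason
  recorded (pipeline use).
* Percentages in frequency tables are rounded to 1 decimal; per-variable
  sums may differ from 100 by rounding (tested to ±0.2).

## Limitations

* Mutation status is taken from the caller-reported V-mismatch count; no
  germline reconstruction or lineage-tree inference is performed.
* The edge rule for clone networks is a convention, not an inference;
  results at Hamming threshold 1 should be read as lower bounds on
  lineage connectivity.
* Exact tests enumerate up to n = 12; beyond that the corrected normal
  approximation is used, which is standard but approximate in the
  presence of heavy ties.
* The pipeline's survival screen fits no multivariable model and makes no
  multiplicity adjustment unless asked; p-values from many median-split
  screens should be treated as exploratory.
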