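# Methods

## Scope and model of the data

`pepqc` treats an immunopeptidomics sample as a *set* of peptide
sequences over the 20 canonical amino acids, together with an MHC class
and 1–6 allele names.  Duplicates are collapsed before any analysis
because every downstream quantity (length fractions, set intersections,
motif groups) is defined on sequence sets.  Preprocessing removes
flanking residues (a single residue or `-` separated by dots on each
side of the sequence), bracketed/parenthesized modification annotations
plus inline digits and `+ - . *` symbols, and any sequence containing a
non-canonical character.  The modification syntax is deliberately
permissive — search engines disagree on notation, and the cost of
stripping an annotation that was not a modification is bounded by the
canonical-alphabet filter behind it.

## QC scores

* **LF** = (peptides with length 8–12 for class I, 9–22 for class II) /
  (all peptides).  The length histogram shown in reports truncates at
  30-mers for display, but the LF denominator always counts every
  peptide.
* **BF** = (in-range peptides whose aggregate call is SB or WB) /
  (in-range peptides).  Aggregate call = best call over the sample's
  alleles.  BF is undefined (rendered as a dash) when no peptide is in
  range.

Scores are stored at full precision and displayed rounded to two
decimals, half away from zero (computed in decimal arithmetic, so
0.285 → 0.29 regardless of binary representation).

Binder calls per class: class I SB ≤ 0.5 %rank, WB ≤ 2.0, NB above;
class II SB ≤ 2.0, WB ≤ 10, NB above.  Heatmaps cap %rank at 2.5
(class I) / 12 (class II) before sorting rows lexicographically by
allele column, so that hopeless non-binders cannot dominate the
ordering; the red→blue→yellow colormap is anchored at the SB/WB
thresholds.

## Mock %rank predictor

Eluted-ligand percent ranks from neural-network predictors are
percentiles of a peptide's score among random natural peptides.  The
mock predictor reproduces exactly that construction with a transparent
scoring model so the pipeline is testable end to end:

* score = best log₂-odds of the peptide against the allele's 20×9
  probability matrix over natural background frequencies;
* peptides longer than 9 residues score their best contiguous 9-mer
  window; 8-mers try a single matrix-column gap at every position (the
  gapped column contributes 0 bits);
* %rank = 100 × (fraction of a seeded background of uniform-random
  peptides, lengths spanning the class range, scoring at least as
  high), floored at 100/|background|.

The default background is 10,000 peptides; the 152-sample batch in the
acceptance script uses 2,000 to keep a single-CPU run short (ranks at
the SB/WB boundaries shift by well under the threshold spacing at that
size).  Backgrounds are cached per allele matrix, so batches pay the
scoring cost once.

One consequence of mixing lengths in the background: longer background
peptides get a best-window advantage, so short random peptides rank
pessimistically (near 100).  This is conservative in the direction QC
needs — contaminants never look like binders.

## Gibbs motif deconvolution

The sampler maintains, for each peptide, a group assignment (or trash)
and a core placement: a sliding 9-mer window for peptides at or above
the core length, or a contiguous block of matrix gaps for shorter
peptides.  Class I parameter sets allow these indels (up to 4 deletions
/ 1 insertion, which covers the 8–12-mer subset); class II sets align
by sliding offset only.

Each sweep visits peptides in random order, removes the peptide from
its group's counts, scores every (group, placement) as the sum of
log₂(p′/q) over non-gap core columns — p′ the group's
pseudocount-corrected column probabilities (α = group size − 1,
β = 50, BLOSUM62-conditional pseudocounts), q a flat 1/20 background —
and resamples from a Boltzmann distribution at the current temperature.
The temperature anneals geometrically from 1.5 to 0.1 over 100 sweeps
(50 in the recovery experiments below; the statistic plateaus well
before).  A peptide whose *best* placement scores below −2 bits goes to
trash and is excluded from counts and KLD.  The threshold sits below
the score noise of motif-free data (±~0.5 bits) but far above the
penalty of a genuine anchor mismatch (~−3 bits per anchor), so trash
collects outliers without self-selecting survivors from noise — a
threshold at 0 bits (the noise mean) measurably drives random data to
~2.7 bits of spurious KLD through exactly that feedback.  After
sampling, a deterministic refinement pass repeatedly applies the best
single-peptide move while it increases the raw weighted KLD.

**Model selection.**  The grouping quality is the size-weighted mean
KLD of the group matrices from background, in bits per peptide.  The
plug-in estimate of that quantity is biased upward, for two reasons: a
finite sample inflates any frequency estimate (~19·L/(2 ln 2 · n) bits
per group), and — much larger in practice — the sampler is free to sort
peptides into whichever groups their noise happens to match (~1.4 bits
at n = 500, five groups).  Both effects grow with the number of groups,
so uncorrected KLD-max systematically over-selects group counts.  The
engine therefore calibrates each run against a matched null: the same
sampler, same parameters, run once on a copy of the data whose residues
were globally reshuffled (preserving composition and lengths,
destroying positional structure).  The reported `total_kld` is the raw
value minus the null, clamped at zero; `total_kld_raw` and `null_kld`
are kept on the solution.  On motif-free data the corrected statistic
sits at 0 across group counts; on two-motif mixtures it peaks sharply at
two groups.  The standalone `total_kld()` function computes the plain
uncorrected formula, which is what the hand-arithmetic oracle tests
check.  Ties in model selection break toward fewer groups.

Restarts: 2 per group count for class I, 1 for class II, best kept by
KLD.  All randomness flows from a single integer seed; results are
independent of worker counts because work units (one group count per
job) are merged deterministically.

The *unsupervised* routine runs group counts 1–6 and annotates each
final group with the percentage of members whose best (lowest-rank)
binder call points at each allele.  The *allele-specific* routine
clusters each allele's SB/WB subset as a single group (a peptide
binding two alleles appears in both subsets) and the everybody-NB
subset with 1–5 groups; subsets under 20 peptides are discarded as too
small to align reliably.

For users with a local GibbsCluster-2.0 installation,
`external_flag_string()` emits the canonical parameter strings
(`-g 1-6 -T -j 2 -C -D 4 -I 1` for class I, `-g 1-6 -k 1 -T -j 2` for
class II, with `-g` fixed per job when scheduling one group count at a
time).

## Sequence logos

Probability matrices come from Hobohm-1 clustering (greedy scan in
input order; a sequence joins the first cluster whose *founding*
sequence shares ≥ 63 % identical positions; weight = 1/cluster size)
followed by pseudocount correction
p′ = (α·p_obs + β·g)/(α + β) with α = n_clusters − 1, β = 200 and
g(b) = Σₐ p_obs(a)·q(b|a).  The conditional substitution probabilities
q(b|a) are reconstructed from the published BLOSUM62 log-odds scores as
q(b|a) ∝ q(b)·2^(s(a,b)/2), row-normalized — exact up to the integer
rounding of the published matrix.  Background frequencies q(b) are the
standard natural amino-acid composition shipped with the package.

Shannon logos: column information R = log₂20 − H, letter height
p·R (non-negative, ≤ log₂20).  KLD logos: column total
D = Σ p·log₂(p/q); enriched letters (p ≥ q) stack above the axis,
depleted letters hang below with their signed contribution.  Under a
uniform background the two conventions coincide exactly.  Alignments
may contain `-` gaps (from short-peptide core placements); gaps
contribute no counts and no identity.

Rendering is deterministic (fixed SVG hash salt, no timestamps in
SVG/PDF metadata), so re-rendering a matrix is byte-identical.

## Synthetic data generator

The generator emulates the two populations that dominate real samples:

* **binders** — 9-mer cores drawn column-independently from an allele
  PSSM, trimmed at the C terminus (8-mers) or extended with
  background-frequency residues (10–12-mers); default length profile
  0.10/0.60/0.15/0.10/0.05 over 8–12, matching typical class I eluted
  ligand data;
* **contaminants** — uniform-random residue strings with a configurable
  length profile, defaulting to mass above 12-mers (tryptic-fragment
  like), which depresses LF exactly as real proteolytic background
  does.

The built-in motifs `SYN-A`/`SYN-B` carry four anchors each (primary
P2/P9 plus auxiliary P3/P7, anchor probability 0.85, disjoint residues
between the two motifs).  Two anchors alone make a poor model-selection
test case: Σ p·log₂(p/q) is nearly linear in p in this regime, so
merging two 2-anchor motifs costs almost no KLD and no statistic could
separate the hypotheses; four anchors mirror the primary-plus-auxiliary
architecture of real class I motifs and make ground truth unambiguous.

What the generator does *not* emulate: real allele preference
structure beyond anchors, peptide abundance/intensity, modified or
spliced peptides, MS identification error, and shared-peptide structure
beyond simple random resampling between samples.  Tests passing on this
generator therefore demonstrate that the pipeline's arithmetic,
thresholds, clustering and reporting behave correctly — not that any
predictor or clustering would annotate real biology at a given
accuracy.

Every sampled peptide's origin (allele, contaminant, shared) is written
to a manifest, and all randomness flows through one recorded seed, so
ground-truth assertions (LF vs. injected contaminant fraction, BF vs.
population, cluster recovery vs. generating motif) are exact.

## Numerical and degenerate-input conventions

* `0·log 0 = 0` throughout; log-ratios are floored via a 1e-30 clamp on
  probabilities so β = 0 (no pseudocounts) stays finite.
* PSSM columns must sum to 1 within 1e-6 on input; outputs are
  renormalized after pseudocount mixing.
* Empty groups fall back to a uniform observed distribution (their
  weight in any reported statistic is zero).
* LF on an empty peptide set and BF on an empty call list are errors,
  not zeros; the report renders the undefined BF case as a dash.
* Heatmap row sorting is stable: ties keep input order.  Displays with
  more than 5,000 rows are binned for rendering only; data files always
  carry every row.
* Percent-rank values must be strictly positive; the mock predictor
  floors at 100/|background|.

## Problem sizes in the validation suite

The test suite and acceptance script run entirely on synthetic data at
sizes chosen to exercise every code path on a single CPU in minutes:
motif recovery uses two 100-peptide motifs over five seeds with group
counts 1–6 and 50 sampler sweeps; the LF-recovery cohort uses 2,000
peptides; BF separation uses 500 peptides per population against a
10,000-peptide background; the batch demonstration runs 152 small
samples (8 binders each — deliberately below the 20-peptide clustering
minimum, exercising the skip path) with a 2,000-peptide background.

## Known limitations

* The Gibbs engine is this package's own implementation of the
  published method family; its update rules, trash criterion and
  null-calibrated model selection are documented above but are not a
  re-implementation of any specific external binary, and group-level
  results on real data will differ in detail from GibbsCluster-2.0.
* The mock predictor is a scoring stand-in with percent-rank
  *semantics*; it shares no weights with NetMHCpan/NetMHCIIpan and must
  not be used to annotate real samples — use the external adapter for
  that.
* The Hobohm-1 variant compares against cluster founders only (the
  common fast variant), not all members.
* Class II core handling uses the same 9-residue core with sliding
  offsets; no position-specific insertion modeling.
* The HTML report embeds static SVG; there is no interactivity.
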