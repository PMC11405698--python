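# Methods

This note records the models, conventions and numerical choices behind each
stage, what the synthetic generators do and do not emulate, and the known
limits of what the tests demonstrate.

## Alignments, trimming and windowed similarity

Alignments are equal-length rows over the 20 standard amino acids plus `X`
(unknown) and `-` (gap). Columns are 0-based internally and reported 1-based
in human-readable output; reference residue positions are 1-based.

**Gap-threshold trimming** keeps exactly the columns whose non-gap fraction
is at least the threshold gt (ties retained), the common semantics of
gap-threshold trimmers. Retained-column sets are therefore nested as gt
rises, which the tests assert over random alignments. Rows left with no
residues after trimming are kept — with a warning — because downstream
pairwise matrices need row correspondence, not maximal rows. The typical
working range for protein phylogenetics inputs is gt 0.6–0.95, and
`sweep_trim` tabulates that range in one call.

**Windowed similarity** scores a column as the mean substitution-matrix
score over all unordered row pairs, with any pair involving `-` or `X`
contributing 0 while remaining in the denominator; the track value at a
window centre is the mean column score across an odd-width window (default
11). This gap rule is a documented approximation: published similarity-plot
tools do not all treat gaps identically, so profiles computed here match
such figures qualitatively, not bit-exactly. The default matrix is BLOSUM62
(the EMBOSS EBLOSUM62 scores are identical); custom matrices load from the
standard NCBI/EMBOSS text layout.

## Identity matrices and shared-specificity calls

Percent identity over a column set counts only positions where neither
residue is `-` or `X` — excluded positions leave both numerator and
denominator, because counting unknowns as mismatches would silently dilute
identity for partial sequences. A pair with no comparable position is
reported missing (NaN), never 0, and a pair with at most half the subset's
positions comparable carries a low-coverage flag.

Shared-specificity classification applies inclusive thresholds: subset
identity ≥ 70% over the specificity-determining residues (for Mint PDZ
domains, 17 positions in the β2/β3 strands and α2 helix) and ≥ 50% over the
full domain. Ties count as shared; the choice is documented and tested
rather than left to float comparison accidents. The position set itself is
configuration — a labelled, reference-anchored list of 1-based residue
indices — because such sets are defined graphically in the literature and
depend on the aligner; no hard-coded column list would survive realignment.

## C-terminal ligand classes

Positions are labelled −(k−1)…0 with 0 the protein's final residue.
Classification precedence is fixed: (1) `DDWC_like` iff W at −1 and C at 0;
(2) `type_I` iff S/T at −2 and a hydrophobic residue at 0; (3)
`W_minus1_other` iff W at −1; (4) `other`. The precedence puts ETWC — which
satisfies both the W/C and the S/T features — in the W/C group, matching how
such non-canonical cnidarian channel termini behave experimentally. The
hydrophobe set Φ defaults to {V, I, L, M, F, W, A, C} and is configurable;
the default covers the common type-I position-0 residues including the
valine of CTAV. Peptides shorter than 4 residues fall to `other` with a
truncation flag. Consensus motifs break majority ties alphabetically and
flag them; invariant positions are exactly those with a single observed
residue.

## Screen statistics

Hit-table statistics are colony-weighted by default — each recovered colony
counts one unit — because screen totals in this kind of assay are colony
sums, not unique-prey counts; unweighted mode supports unique-prey
statements. Prey ranking sorts by colonies descending with alphabetical
C-terminus tie-breaks for determinism. The packaged fixtures are transcribed
TSVs (8 records for the tandem-bait screen, 13 for the PDZ-1 screen) with
annotation columns passed through verbatim and a missing prey id stored as
the explicit sentinel `Not found`.

## Peptide-library logos

The library register is fixed-length (default hexamers: screens of
PDZ-peptide specificity rarely enrich anything at −6, so a 6-mer register
samples the informative positions more deeply). Frequencies use an additive
pseudocount of 0.01 per residue — enough to avoid −∞ entropies from sampling
zeros without visibly distorting strong signals. Information content is
IC = log2(20) − H against a uniform 20-residue background, with no
small-sample correction and no compositional correction; the inputs are
selected-pool frequencies, and any enrichment-vs-input normalization is
upstream of this package. Signatures render positions with IC ≥ 1 bit,
listing residues with frequency ≥ 0.2 ('/'-joined, descending), `x`
elsewhere, with leading `x` runs trimmed; both thresholds are configurable,
and the defaults reproduce `WV` / `GxWV`-style renderings on the synthetic
libraries. Exact letter heights of published logos are not reproduction
targets (the underlying selection reads are not available in
machine-readable form); logo rendering here is a minimal matplotlib letter
stack for inspection.

## Co-expression

Expression calls are strict: a unit expresses a gene when its value is
greater than the threshold (default 0). The strictness and the default are
explicit because public atlases rarely publish their call rule; the
threshold is a config knob and is recorded in output metadata. All counts,
Venn partitions and conditional percentages operate on the calls, optionally
filtered by a cell-type annotation. Percentages are reported to 1 decimal
with full precision retained internally. The calibration comparison runs a
set of candidate partners and a positive-control gene (one biologically
required to co-occur with the reference, such as an obligate channel
subunit) through the same conditional-rate computation and flags candidates
within a 1.5× factor of the control — the control's rate estimates the
ceiling the data can show, so a candidate near it is as co-expressed as the
data can demonstrate. Atlas-derived metacell counts (hundreds of neuronal
metacells, dozens co-expressing) depend on the external atlas's own
construction and call rule and are anchored here only in direction, via the
synthetic designs.

## Reporter assays

Activity is 1000·A420/(t·V·OD600); the constant is cosmetic and cancels
under normalization, and the formula is homogeneous of degree −1 in each of
time, volume and density (tested). Normalization divides every well's
activity by the control condition's mean, so the control reports mean 1
exactly; summaries are mean ± sample SD (ddof = 1) with every well row
treated as one replicate. The two-sample test defaults to Welch's
unequal-variance statistic with Welch–Satterthwaite degrees of freedom,
since equal-variance pooling is an extra assumption nothing here licenses; a
pooled mode exists. Paired mode tests the per-pair differences. No
multiple-testing correction is applied by default (per-comparison reporting
is the norm for these assays); a Bonferroni option exists.

## Synthetic generators

Each generator is a pure function of its parameters and seed and returns a
ground-truth record sufficient to compute the expected value of the
downstream estimate.

- **Alignment families** use a per-column star model: a row keeps the
  column's consensus residue with probability p, else draws uniformly from
  the other 19, giving pairwise identity q = p² + (1−p)²/19, solved as
  p = (1 + √(380q − 19))/20. Identities below the 0.05 random-matching floor
  are infeasible and raise. Gaps are inserted only outside designated
  columns.
- **C-termini** plant unambiguous class instances in the last four residues;
  a dual-feature flag generates ETWC-style peptides (W/C ending plus T at
  −2) to exercise precedence.
- **Peptide libraries** draw the planted residue at `enrichment_factor`
  times its uniform background frequency (probability f/20, capped at 20);
  a factor of 10 plants the residue in half the reads (IC ≈ 1.2 bits),
  comfortably above the 1-bit signature threshold at the default library
  weight of 5000.
- **Hit tables** plant terminal-residue composition and suffixes, redrawing
  non-planted prey that would collide with a planted suffix so that the
  planted weight sums are exact bookkeeping identities.
- **Metacell matrices** draw reference genes at their marginal prevalence
  and dependent genes at the designed conditional rate on reference-positive
  units, solving the reference-negative rate to preserve the dependent
  gene's marginal prevalence (unsatisfiable designs raise). Called entries
  receive unit-mean exponential values, since only the binary call matters
  downstream. The acceptance design uses 4000 metacells with reference
  prevalence 0.11 and conditional rates 0.18/0.19/0.012, emulating an
  atlas-scale neuronal compartment (~400 reference-positive units).
- **Assay wells** encode ratio·1000·(1 + Gaussian noise) activities
  back-converted to plausible A420/OD600/t/V tuples.

What the generators do **not** emulate: phylogenetic correlation between
rows (alignment rows are exchangeable), selection chemistry and sequencing
error in libraries, dropout and depth effects in single-cell data, and
technical-vs-biological replicate structure in assays. Passing recovery
tests therefore show estimator correctness under the designed sampling
models, not robustness to those real-data effects.

## Problem sizes and determinism

The test suite and the acceptance script use desk-scale sizes chosen for
tight statistical bounds at interactive runtimes: 200 random instances per
oracle-equivalence check (tolerance 1e−9), 120 two-row replicates of the
17-column identity recovery, 4000-metacell co-expression designs, and 200
repeats of the 6-replicate assay recovery. All randomness flows through
explicit integer seeds; repeated runs are bit-identical.

## Known limitations

Published figure values that depend on external resources are out of reach
at desk scale and are deliberately not asserted anywhere: specificity-matrix
percentages from any particular aligner's output and chevron-marked position
set, atlas metacell counts, manually counted in situ co-expression
percentages, and selection-logo letter heights. The package anchors these
qualitatively — the direction of classification and calibration — and keeps
every such threshold configurable so real inputs can be swapped in.
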