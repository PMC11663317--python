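# Methods

This document records the models, conventions and numerical choices behind
`c9meth`: what each metric means, how the synthetic cohort generator works,
what it deliberately does not emulate, and the package's limitations.

## Coordinates and units

Internally all coordinates are 0-based half-open. CpG calls are anchored on
the C of a CG dinucleotide (`read_pos_0based`). Methylation scores are
integers 0–255, interpreted as scaled 5mC probabilities. Repeat lengths are
in motif units (6 bp per GGGGCC unit).

## Read QC

Two profiles, run as parallel branches (each feeds its own allele
assignment and metrics; nothing is shared downstream of filtering):

| profile              | min full passes | min predicted accuracy | length      | flanks |
|----------------------|-----------------|------------------------|-------------|--------|
| `methylation_purity` | 7               | 0.99                   | 10 bp–100 kb | both   |
| `length`             | 1               | 0.80                   | 10 bp–100 kb | both   |

All thresholds are inclusive. Requiring both flanks guarantees the read
contains the complete repeat tract, which is a precondition for every
length, purity and tract-methylation measurement. Missing metadata in any
required column is a hard, read-naming error — silently passing such reads
could bias every downstream summary.

## Allele assignment

Each carrier has two alleles, one short wild-type (2–30 units) and one
expansion. Reads are assigned by k-means with k=2 (Euclidean, `n_init=10`,
fixed `random_state`) on **raw** overlapping 6-mer counts of the
inter-anchor segment. Raw counts (not frequencies) are deliberate: the
dominant signal separating the alleles is tract length, and raw counts keep
it in the feature space. The cluster with the larger mean GGGGCC-hexamer
count is labelled expanded; an exact tie falls back to mean read length.

Clustering is applied per sample. Pooling individuals whose expansions
differ by thousands of units can make k-means split large-vs-small
*expansions* rather than wild-type-vs-expanded, so the per-sample unit is
the well-posed one. A degenerate sample (all feature vectors identical,
e.g. a single spanning molecule amplified into identical reads) raises in
`assign_alleles`; the per-sample wrapper falls back to labelling by motif
count against the wild-type upper bound (> 30 copies ⇒ expanded).

## Methylation metrics

Per read: median CpG score, and proportion of CpGs "likely methylated" with
the main rule **score ≥ 128** (top half of the scale). The alternate rule
used for sensitivity analysis is **strictly greater than 75 % of the
scale**, i.e. score ≥ 192. Per sample × allele: median of per-read medians,
median of per-read proportions, and min/max/range of the proportion. The
even-count median is the mean of the two middle values. Reads with zero CpG
calls are excluded (and logged), not errors.

Waterfall matrices (reads × CpG ordinal, rows sorted by descending CpG
count) use NaN for cells beyond a read's CpG count — explicitly distinct
from a score of 0.

## Repeat length and purity

The tract is delimited by the **first and last exact** GGGGCC occurrence in
the read; length = floor(span / 6), so interrupted interior units still
count toward length. Reads without a single exact motif copy are flagged
motif-free and excluded from repeat metrics. Per sample × allele, the
**maximum** per-read count is the primary length estimate (the longest
molecule is what a Southern blot's upper band tracks), with median, min and
range also reported; the range measures somatic mosaicism.

Purity is computed over the tract only: GC fraction of tract bases
(a pure tract is 100 % GC since every base of GGGGCC is G or C; deletions
and substitutions introduce A/T or shift the frame), and motif fraction =
6 × (number of non-overlapping exact matches, greedy left-to-right) / span.

## Statistics

* Spearman rank correlation (average ranks for ties; two-sided p). Fewer
  than 3 finite pairs or a constant margin returns a status-flagged
  undefined result rather than raising.
* Paired Wilcoxon signed-rank: zero differences dropped; exact null
  distribution when ≤ 25 non-zero differences without tied absolute values,
  otherwise normal approximation with continuity correction.
* Unpaired rank-sum (Mann–Whitney U, two-sided).
* Age adjustment: OLS `y ~ intercept + group + age` with two-sided t-tests
  per coefficient; a singular design raises.
* Longitudinal rule: **stable** iff within-individual max − min change
  < 0.10 (absolute proportion units). Transmission rule: **decrease** iff
  parent − child ≥ 0.10 (symmetric for increase). Comparisons against the
  0.10 boundary allow 1e-9 absolute slack because a decimal change of
  exactly 0.10 is not representable in binary floating point
  (0.50 − 0.40 = 0.09999999999999998).
* p-values are reported raw; a Benjamini–Hochberg helper exists but is off
  by default.

## Synthetic cohort generator

### Reads

Each read is `left flank + repeat tract + right flank`. The flanks are
fixed synthetic 120 bp sequences (not the human reference): CpG-rich like
the real locus (9 CpGs each), free of GGGGCC, with junctions that create no
CG across a boundary, and with 20 bp tract-proximal termini serving as span
anchors. Per-read expansion size is `modal × (1 + |N(0, dispersion)|)` — a
half-normal right tail emulating somatic mosaicism. Interruptions hit each
unit with probability `clip(rate × n_units / 100, 0, 0.5)` (longer tracts
are less pure, matching the observed negative purity–length relation) and
are single-base substitutions or deletions (50/50). With probability
`truncation_rate` a read loses one flank and up to half the tract from that
side. Pass counts are `1 + Poisson(mean − 1)`; predicted accuracy is
`1 − 0.3·exp(−0.5·passes)·U(0.5, 1.5)`.

### Methylation scores

Every CG in the read gets a score. The mean methylation fraction is: for
expanded-allele tract CpGs, `clip(intercept + slope × n_units + individual
jitter)`; for wild-type tract CpGs, a low constant; for flank CpGs inside
the terminal `flank_end_window` (default 30 bp) of an intact flank, a high
constant (0.8) — locus methylation extends into the flank interior, whose
CpGs follow the allele's tract level. Two score models:

* `bernoulli` (default): each CpG draws a methylated state at its mean
  fraction; score = 235 (methylated) or 20 (unmethylated) + N(0, 25),
  rounded and clipped to 0–255. This produces realistic per-read
  *proportions* in the 13–66 % band.
* `mean`: score = 255 × fraction + N(0, noise). Useful for noise-free
  limit checks (e.g. fraction 0.2 ⇒ every score exactly 51).

### Cohort structure (defaults = study conditions)

27 individuals: 15 ALS, 1 FTD, 11 presymptomatic. Ages N(62, 7) clipped
45–78 for symptomatic, N(39, 8) clipped 25–55 for presymptomatic. Expanded
modal length is age-linked: `clip(60 × (age − 22) + N(0, 250), 300, 3400)`
— this single coupling generates the methylation–age and length–age
correlations and the age-confounded group difference. Expansion methylation
fraction = `clip(0.22 + 1e-4 × n_units + jitter)`. Promoter methylation
percentage is log-normal background plus a term that rises with the
individual's expansion methylation; the hypermethylation flag is a 5 %
cutoff. Southern-style external length estimates add 25 % multiplicative
noise. 34 blood samples: 13 longitudinal timepoints across 6 individuals
(4 designed stable with modal shifts within ±60 units, 2 variable with a
+1400-unit shift); 4 pedigrees with 7 father→offspring transmissions, each
carrying a 1800–2200-unit contraction; one cerebellum sample per individual
(shorter: ×0.7, less methylated: −0.12, purer: ×0.5 interruption rate, less
mosaic: ×0.6 dispersion).

### What the simulator does **not** emulate

Sequencing error in the base calls (reads are error-free outside the
modelled interruptions), strand effects and hemimethylation, non-CpG
methylation, alignment artifacts, guide-RNA enrichment biases, per-CpG
positional methylation structure within the tract (CpGs are i.i.d. given
the read-level fraction), repeat-priming artifacts, and coverage depth
dynamics beyond a uniform 6–12 reads per allele. Modification calls are
always complete (every CG scored), whereas real callers can emit gaps.

## Determinism

All randomness flows from a single integer seed through
`numpy.random.default_rng`; the pipeline writes byte-identical outputs for
a fixed seed (manifests exclude path fields; PNGs are written with fixed
dpi and no embedded software metadata).

## Limitations

The generator is calibrated to reproduce the *qualitative* structure of a
real blood cohort (directions, orderings, significance patterns), not its
exact numbers; headline values drift with the seed. The purity–length
coupling is built in by the interruption model, so the associated
correlation validates plumbing, not biology. Allele assignment assumes two
alleles per sample and at least one spanning read from each; homozygous
non-expanded samples need the single-allele fallback. The 0.10 stability
threshold is a convention, not an inferred quantity.
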