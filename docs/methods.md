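# Methods

## Overview

`methyltf` screens a PWM collection against one cell type's promoter
methylation and expression profile to find transcription factors whose
binding is attenuated by DNA methylation in a way that *sharpens* the
statistical link between their predicted binding and gene expression.
The pipeline has four stages: promoter scanning, a sigmoid
methylation-effect model per binding site, a threshold-swept Z statistic,
and a grid search over the model parameters with a two-standard activity
call.

## Promoter scanning

Promoters are TSS-relative windows (default 1200 bp upstream, 300 bp
downstream, matching common promoter-array designs), stored 5'→3' on the
gene's sense strand; minus-strand windows are reverse-complemented so
index 0 is always the most-upstream base.  All coordinates are 0-based
half-open.  A promoter of length N scanned with a motif of length L
yields N − L + 1 sites per strand; by default both strands are scanned
(TFs bind double-stranded DNA) and a `strands="sense"` switch restores
single-strand scanning.  PWM weights are used exactly as read — counts,
frequencies or scores — but must be nonnegative, because the binding
score multiplies match values by an attenuation in (0, 1) and a negative
weight would invert the attenuation's meaning; log-odds matrices must be
shifted or exponentiated first (`PWM.normalized()` converts counts to
frequencies).  `N` bases contribute weight 0; other IUPAC ambiguity codes
are collapsed to N with a warning.  Ties at the maximum break toward the
smallest site index, sense strand first, so the argmax site that
methylation lookup depends on is deterministic.  Genes shorter than a
motif are excluded from that TF's analysis rather than given a sentinel
score, which would distort the threshold sweep.

## Methylation-effect model

Site methylation is the mean of present per-base values over the L-bp
site window, on the MeDIP log2-ratio scale (test/reference; 0 means no
enrichment, roughly [−2, 2] in practice).  Users with beta-value (0–1)
tracks should rescale them or adjust the C grid accordingly.

The attenuation of a site's match value is logistic with center `C` (the
methylation level at which half the binding ability is lost) and
steepness `S > 0` (transition width; S = 0.01 is nearly a step on the
log2-ratio scale):

* sense: `E = expit(−(M − C)/S)` — decreasing in M;
* antisense: `E = expit(+(M − C)/S)` — the exact mirror, so
  sense + antisense = 1 identically.

The published rendering of the antisense form is typographically
ambiguous; the mirror convention is adopted because it preserves both the
documented qualitative behavior (high methylation matters less) and the
sum-to-one identity.  Equivalently, only the parameterization — not the
family of curves — is pinned down by the source; the C grid is symmetric
about zero, so the search space is identical under either sign
convention.  Sigmoids are evaluated with `scipy.special.expit`, which is
branch-safe for exponents of ±400 (S = 0.01 with |M − C| up to 4).

The binding score takes the maximum of A × E over *all* retained sites,
not just each gene's best sequence match — the optimal site under
attenuation may differ from the optimal site by sequence.  Per gene and
TF the top-K sites by match value are retained (default K = 50); K below
the full site count is an approximation, logged when it bites.  Missing
site methylation defaults to the neutral policy (E = 1, no attenuation):
absence of evidence should not suppress a site.  A `skip` policy drops
such sites instead.

## Z statistic and threshold sweep

For a target set of size k with mean log expression m, against a cohort
background with mean μ and SD σ (SD uses ddof = 1),
`Z = (m − μ)/(σ/√k)` — the one-sample Z of the target mean.  Candidate
thresholds are the sorted unique score values; target sets use a strict
cut (score > t).  Thresholds leaving fewer than `k_min = 10` or more than
`k_max_frac = 0.5` of the universe are excluded: the normal approximation
needs a reasonably sized set, and near-total sets carry no contrast.  The
reported Z_m is the Z of maximal absolute value with its sign preserved;
ties on |Z| break toward larger k (the less extreme-tail cut), then the
smaller threshold.  The gene universe is the intersection of scored and
expression-profiled genes; μ and σ stay fixed at the cohort values.

The low-expression filter drops genes below the 0.10 quantile of the
(optionally log2-transformed) expression distribution — an explicit,
reproducible stand-in for the usual removal of unreliably measured genes.

## Grid search and the activity call

For each TF and orientation, every (C, S) on the grid (C ∈ −2…2 step
0.05, S ∈ {0.01, 0.05, 0.1}) gets a binding-score sweep and a Z_m; the
grid extreme maximizes |Z_m| with ties broken toward smaller |C| then
smaller S — the weakest model achieving the same statistic.  A TF is
active iff

1. |Z_m-p| ≥ (1 + margin) · |Z_m-o|, and
2. no antisense cell's |Z_m-q| strictly exceeds |Z_m-o|.

Equality in standard 2 is deliberately tolerated: grid corners where the
antisense sigmoid saturates to E ≡ 1 degenerate to the no-effect limit
and reproduce the match-score analysis bit-for-bit, and reproducing the
baseline is no evidence for the wrong-signed model.  Two genuinely
different target sets tying in Z at float precision is a measure-zero
coincidence.

The margin defaults to the fixed 10% figure.  A percentile mode
(margin = 90th percentile of the cohort's |Z_m-p|/|Z_m-o| ratios − 1,
linear interpolation, floored at 0) is available for large compendia; it
is not the default because in small or null-heavy cohorts TFs with
near-zero |Z_m-o| denominators dominate the upper percentiles and the
derived margin loses meaning.  With fewer than 10 ratios the percentile
mode falls back to the fixed default with a warning.

Both standards operate on absolute values; the sign of Z_m-o is carried
as a direction label (activator/repressor), and a sign disagreement
between Z_m-o and the extreme Z_m-p is flagged `sign_flip` for review
without changing the call.  Ranked reports list positive-direction TFs by
extreme Z_m-p descending and negative-direction TFs separately; optional
deduplication keeps, per TF name, the matrix with the largest |Z_m-p|.
The cohort-level shift between Z_m-o and extreme Z_m-p distributions is
tested with a paired two-sided Wilcoxon signed-rank test.

## Synthetic cohorts

The generator emulates the screen's four inputs with a known planted
mechanism, so every stage is testable without external data.  Defaults
(one cohort = the package's study conditions):

| parameter | default | why |
|---|---|---|
| n_genes | 500 | large enough for stable Z, small enough for seconds-scale screens |
| promoter_length | 1500 bp | the 1200 + 300 TSS window |
| n_tfs / n_active_tfs | 10 / 1 | one planted activator, nine decoys |
| motif_length | 10 bp | the site size methylation is quantified over |
| planted_C / planted_S | 0.25 / 0.01 | mid-grid center, near-step attenuation |
| effect_size β | 2.0 | expression shift per unit effective binding |
| noise_sd | 0.5 | log-scale expression noise |
| methylation mixture | modes ±0.75, SD 0.75, clipped to [−2, 2] | hypo/hyper modes with density across the whole C search range |
| target_fraction | 0.3 | 150 targets per TF |
| baseline_expression | 8.0 | microarray-like log2 scale |

Promoters are i.i.d. uniform sequences on a synthetic contig (alternating
strands, so the strand-aware extraction and projection paths are
exercised by the fixture round trip).  Planted site sequences are
*sampled from the TF's frequency matrix* rather than fixed at the
consensus: real sites vary in strength, and with identical site scores
the threshold sweep can absorb any over-large center C by cutting inside
the sigmoid transition, leaving Z(C) flat above the true center and the
parameter unidentifiable.  Methylation is block-wise (50 bp) from the
mixture, overridden at each active-TF site by one constant site-level
value drawn from the hypo mode for expressed targets and the hyper mode
for silenced ones.  Expression is
`baseline + β · E_sense(M_site; planted_C, planted_S) + N(0, noise_sd)`;
decoy TFs get planted sites but no expression term.  A per-gene truth
table records the deterministic expression component; a per-site table
records every planted site and its realized methylation.

What the generator does *not* emulate: co-binding and TF modules,
sequence composition bias (GC/CpG islands), regionally smooth methylation
gradients, probe-level noise in either assay, and any correlation between
motif content and expression beyond the planted mechanism.  Passing tests
therefore demonstrate the statistical machinery and its calibration under
the planted model, not performance on real chromatin.

## Validation harness and problem sizes

The acceptance tests run the full screen on 20 seeded planted cohorts
(true centers cycling −0.5, 0, 0.5) and 20 null cohorts (β = 0),
checking: center recovery within one grid step on the fixed-steepness
calibration sweep (S held at the planted 0.01, as in the standard display
of the search — the full-grid arg-extreme systematically trades a larger
S for a shifted C, with C* − 2S tracking the true center); the planted
TF's activity call; decoy and null false-positive rates; the
no-methylation reduction (zero methylation plus a saturating sense model
reproduces the match-score analysis to 10⁻⁶ and calls nothing active);
and exhaustive-enumeration oracles for the scanner and the sweep.
`scripts/acceptance.py` repeats the study at 10 + 10 replicates from a
user-supplied seed.

## Numerical and degenerate-input choices

* All-equal score columns admit no informative threshold: the TF is
  excluded with a reason rather than scored.
* Empty site lists return a −inf score with a null argmax at the
  operation level; matrix assembly stores NaN and excludes the gene.
* Overlapping methylation intervals resolve last-record-wins with a
  warning; WIG input is converted from 1-based to 0-based on read.
* PWM writing (JASPAR, minimal-MEME) emits full-precision floats so a
  write/read round trip is bit-exact.
* Everything is deterministic: reruns of scanning, sweeping and the grid
  search are bit-identical, and fixtures are byte-reproducible per seed.

## Limitations

* The sigmoid family assumes a monotone, saturating methylation effect
  with one center per TF; bimodal or context-dependent effects are out of
  scope.
* Site retention (top-K by match value) can in principle miss a weak site
  that would dominate after attenuation; K = 50 makes this negligible at
  promoter scale but it remains an approximation.
* The extreme-over-grid statistics are selection-biased upward by
  construction; they are meaningful relative to each other (the two
  standards compare like with like), not as calibrated p-values.
* Percentile-derived margins need a large, signal-rich TF compendium;
  see above for why the default margin is fixed.
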