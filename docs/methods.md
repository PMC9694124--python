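# Methods

## The design being modelled

Eleven adult unilateral cochlear-implant users are tested with two sound
processor programs that differ only in the instantaneous input dynamic range
(IIDR): the default T-SPL/C-SPL of 25/65 dB SPL (width 40 dB) and a wide
25/80 dB SPL (width 55 dB). Subjects had previously self-selected one
program after a blinded trial, defining two preference groups: `preCSPL65`
(5 subjects) and `preCSPL80` (6 subjects). Each subject is scored with both
programs on 8 conditions — {word, sentence} × {quiet, noise at +10 dB SNR} ×
{65, 80 dB SPL} — using one 25-word list or one 15-sentence list (60
morphemes) per cell. Scores are percent-correct items; every item is a
binary outcome and the analysis operates at item level throughout, which is
why the canonical interchange format is a long CSV with one row per item.

## The permutation test

Each comparison takes two binary item vectors: within-program comparisons
concatenate, per selected subject in stable order, the default-program items
as side *a* and the wide-program items as side *b* at a fixed condition;
between-group comparisons fix the condition and the program and put the
`preCSPL65` items in *a* and the `preCSPL80` items in *b*. The statistic is
`D = 100·(mean(b) − mean(a))` in percentage points. The null is assessed by
resampling without replacement: each of `n_resamples` independent iterations
draws a pseudo-*b* of size |b| from the pooled items (the remainder is
pseudo-*a*) and the p-value is `extreme_count / n_resamples`, where a
resample is extreme when its difference is `≥ D` (one-sided `greater`, the
default: improvements are reported in the wide-minus-default direction) or
`|D'| ≥ |D|` (two-sided). The rule is inclusive, there is no +1 continuity
correction, and constant pooled data return `D = 0, p = 1` rather than an
error. A Monte Carlo p of exactly 0 is therefore possible; reports annotate
it as `< 1/n_resamples`.

Two implementation notes:

* **Hypergeometric resampling.** For binary items, a without-replacement
  split is completely characterised by the number of correct items that land
  in pseudo-*b*, which follows a hypergeometric law. `mc_permutation_test`
  draws that count directly (`rng.hypergeometric`) instead of materialising
  index permutations. This is the identical resampling distribution — not an
  approximation — and makes a 100,000-resample test run in ~30 ms, which is
  what keeps the 2,000-null calibration study and the 50-replicate stability
  checks tractable. Tie handling is exact: the permuted difference at the
  observed count is computed by the same floating expression as the observed
  difference, so ties register as extreme.
* **Exact oracle.** `exact_permutation_test` enumerates assignments by the
  ones-count with exact integer multiplicities (`math.comb`), returning an
  exact rational p as `extreme_count / C(n, |b|)`. Its contract caps the
  enumeration at `C(n, |b|) ≤ 10^7` assignments and directs larger inputs to
  the Monte Carlo mode. On one-sided binary inputs it equals the closed-form
  hypergeometric upper tail; the tests assert agreement to 1e-12 relative
  error against `scipy.stats.hypergeom` and against
  `scipy.stats.permutation_test` in exact mode, keeping implementation and
  oracle on separate routes.

Pooling across subjects (rather than permuting within each subject's paired
lists) is the reading under which the stated resample units — 25 words, 60
morphemes, and their multiples at group level — are meaningful; the
per-subject paired variant is deliberately not implemented. No
multiple-testing correction is applied across the 40-comparison matrix, and
significance is flagged at the two conventional thresholds (0.05, 0.01) with
strict inequality.

## The synthetic cohort generator

The study's item-level data are not available, so the generator emulates the
design: for group *g*, condition *c* and program *r*, the base success
probability `p[g,c,r]` is the published group mean score divided by 100
(the `figure3` preset; 32 cells). Each subject receives one random effect
`u_s ~ Normal(0, subject_sd)` on the logit scale, shared across all 16 of
their cells, and the effective cell probability is
`invlogit(logit(p) + u_s)`; base probabilities of exactly 0 or 1 bypass the
transform so floor/ceiling cells stay degenerate. Items are independent
Bernoulli draws. Every draw comes from a dedicated stream keyed by
`(seed, stream, subject, condition facets)`, so cohorts are bitwise
reproducible and adding a condition or subject does not perturb existing
cells.

Parameter defaults and why:

| parameter    | default           | rationale                                            |
|--------------|-------------------|------------------------------------------------------|
| `n_per_group`| 5 / 6             | the study's group sizes                              |
| `accuracy`   | published means/100 | calibration target of the preset                   |
| `subject_sd` | 0.2 (logit units) | no subject-level dispersion was published; 0.2 gives per-subject score SDs of a few percentage points at mid-range accuracies, enough to make subjects visibly heterogeneous while preserving the published complete separation of the two groups' noise scores at 65 dB |
| `n_resamples`| 100,000           | the study's stated resample count                    |

What the generator does **not** emulate: item-difficulty structure (the real
lists vary in difficulty across items and subjects; items here are
exchangeable within a cell), learning/order effects (lists were rotated in
the study), and any psychometric link from presentation level, SNR or C-SPL
to accuracy (probabilities are configured per cell, not derived). Passing
tests therefore demonstrate that the pipeline is correct and that the
published significance structure is reproducible under a binomial
item model calibrated to the published means — not that it would be
reproduced on the real items, whose within-list dependence could widen the
permutation null.

## Calibration and power properties the tests measure

* With `subject_sd = 0`, pooled per-cell means over 200 generated cohorts
  match the configured means within 3 binomial standard errors.
* Under the preset (`subject_sd = 0.2`), the per-subject default-program
  noise scores at 65 dB of the two groups are completely separated in ≥ 95%
  of cohorts (measured rate is printed by the test; it is ~1.0).
* Type-I error: with both sides drawn from one Bernoulli(0.5) at the pooled
  sizes the study actually uses (275 word items, 660 morpheme items per
  side), the two-sided rejection rate at α = 0.05 over 2,000 nulls lies in
  the 99% binomial band around 0.05. The one-sided test is valid but
  measurably conservative at n = 275: its true size is ≈ 0.039 (computable
  exactly from the binomial-hypergeometric mixture) because the inclusive
  rule on a discrete statistic cannot attain 0.05 exactly; the test asserts
  it never exceeds the band's upper edge and prints the measured rates.
* Stability of the headline contrast: on a calibrated cohort, the
  all-subjects words-in-noise comparison at 65 dB (pooled means ≈ 41% vs
  58%, 275 items per side) yields one-sided p < 0.01 in ≥ 95% of 50 seeded
  100,000-resample runs. Across *regenerated* cohorts the same event has
  probability ≈ 0.96 (measured over 1,000 cohorts with the exact p): the
  ≈ 16.5 pp mean improvement sits ≈ 1.7 cohort-level SDs above the ≈ 9.9 pp
  rejection threshold, so occasional cohorts fall short — a genuine power
  statement about an 11-subject design, which is why the stability check
  fixes the cohort and varies the resampling stream.
* The full 8-cell all-subjects significance pattern at α = 0.05 is matched
  in only a moderate fraction of replicate studies (the rate is printed by
  the pipeline test): the two quiet-word contrasts (≈ 6.9 and ≈ 9.4 pp) are
  near-threshold at these sample sizes, with single-cell power around
  0.7–0.8. The structurally large contrasts — both noise conditions at both
  levels and sentences in quiet at 80 dB — are each reproduced in ≥ 90% of
  replicates and are asserted.

## Numerical and degenerate-input choices

* Percent scores are floats on the 0–100 scale; item counts stay integers.
* `item_index` is 0-based and purely positional; readers reject cells whose
  index run is not a contiguous 0-based sequence of the material's length,
  non-binary outcomes (with the offending row number), conflicting group
  labels for a subject, and cohorts that are not fully crossed (naming the
  missing cells). Missing data are an error, never imputed.
* Exact two-sided extremity uses an absolute-value comparison with a 1e-12
  slack toward inclusion so symmetric counterparts of the observed split are
  never lost to rounding.
* Per-comparison Monte Carlo seeds are spawned from the run seed via
  `numpy.random.SeedSequence`, and reports embed seed, resample count,
  alternative and (for synthetic cohorts) the generator-config hash, so any
  report line can be regenerated bit-exactly.

## Problem sizes used by the shipped checks

The calibration and separation checks use 200 generated cohorts; the
pattern-rate check uses 50 replicate studies at 20,000 resamples over the 8
all-subjects comparisons; the type-I study uses 2,000 nulls per
(size, sidedness) cell at 100,000 resamples; the acceptance script uses one
cohort and 50 runs at 100,000 resamples. These sizes put every Monte Carlo
assertion's sampling error well inside its stated tolerance band.
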