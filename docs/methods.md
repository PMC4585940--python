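# Methods

This note documents the models, defaults and numerical policies behind
`kinarray`, and what the synthetic data can and cannot establish.

## Data model

A study is an array **layout** (peptide substrates with grid positions and
signal-category annotations) plus one **quantification** per reaction:
per-spot foreground and local background densities in arbitrary
phosphor-imager units, with an optional `bad_spot` flag. The layout file's
row order is the pipeline's canonical peptide order; all readers realign
to it and all writers emit it, so shuffling input rows changes nothing
downstream and reruns are byte-identical. Grid coordinates are 0-based
`(block, row, col)` triples; the layout file is the single source of truth
for array geometry (the shipped default layout uses 4 blocks of 16 × 16
spots as a documented convention, not a physical constraint). Category
labels are free-form case-sensitive strings, so any annotation scheme can
be encoded as data.

`bad_spot` spots are carried through but never called (`no_call`): they
are excluded from QC correlations, from mixture fitting, and shrink the
per-peptide usable-reaction count `n_called` rather than the score.

## Replicate QC

Within each condition, every reaction pair is scored by the Pearson
product-moment correlation of `log1p(foreground)` over spots usable in
both members. QC precedes background correction and calling deliberately:
it measures raw run concordance, and `log1p` keeps zero-intensity spots
finite while behaving as `log` at phosphor-imager magnitudes. Whether raw,
corrected or log densities are the "right" basis is an assumption; it is
exposed here as the documented convention. Pairs sharing a biological
replicate are averaged into `mean_technical_r`, the rest into
`mean_biological_r`; the gate passes when both reach the threshold
(default 0.85). The gate is advisory-with-override: the pipeline stops on
failure unless `override_qc` is set, because a failed run is more often a
sample-handling problem than a statistical one. Pairs with fewer than 3
shared usable spots have undefined correlation and are excluded with a
warning; if every pair is undefined the report is an error.

## Phosphorylation-state calling

Each reaction is reduced to a binary latent state per peptide: background
vs phosphorylated. Reactions are fitted independently — no pooling across
replicates before scoring — so technical artifacts in one reaction cannot
leak into another.

**Feature.** `x_p = log1p(max(fg_p − bg_p, 0))`. Per-spot local background
subtraction (rather than a global background distribution) is the chosen
interpretation of separately-quantified spot and background densities;
flooring at zero acknowledges that negative incorporated radioactivity is
unphysical.

**Model.** A two-component Gaussian mixture on `x` with **tied component
variances**, fitted by EM. Tying the variances is a deliberate departure
from the fully free two-component fit, forced by data shape: background
subtraction leaves the inactive population left-skewed (low-SNR spots fall
toward and onto the zero floor), and with free variances the maximum-
likelihood solution places one narrow component inside the inactive bulk
and one wide component over everything else — the labels stop meaning
"background" and "phosphorylated" and false-positive calls jump to tens of
percent. With tied variances the bright component must be a genuinely
shifted subpopulation. For the same reason the fit (not the calling)
excludes the smallest 2.5% of values (count-based trim): the subtraction
tail otherwise inflates the shared variance. Benchmarked on synthetic
studies with known truth, tied+trim calling achieves ~85% per-reaction
sensitivity at ~1.7% false-positive rate with call-fraction bias under 1%,
where the free-variance fit is unusable.

**Fitting policy.** Deterministic initialization (means at the 25th/75th
percentiles, equal weights, pooled SD), convergence at relative
log-likelihood change < 1e-8, at most 500 iterations, variance floored at
1e-6. The log-likelihood trace is kept on the model object and checked to
be non-decreasing on every fit (EM guarantee; a decrease beyond
floating-point slack raises). Components are relabeled after fitting so
`mu0 < mu1`. Degenerate input (no spread at all) yields a single-state
fallback in which every peptide is background; under 20 usable spots the
fit refuses.

**Decision.** `state = phosphorylated` iff the posterior probability of
the bright component is ≥ the threshold (default 0.5); a tie at exactly
the threshold goes to the active state, a one-line rule that makes the
pipeline fully deterministic. With tied variances the posterior is
monotone in intensity, so calls are equivalent to an intensity cutoff that
adapts per reaction. A robust non-probabilistic fallback
(`corrected > median + k·MAD`, k = 3) is available via
`--method zscore` for data where no mixture structure exists.

## Markov scores and category collapse

The per-peptide **Markov score** is the count of reactions (out of R = 6
in the default 2 biological × 3 technical design) in which the peptide was
called phosphorylated: an integer 0..R summarizing reproducibility of the
call, robust to any single aberrant reaction. Peptides scored in fewer
than half the design's reactions (all-bad spots) are dropped from category
summaries — a fraction computed from 2 of 6 reactions is not comparable to
one from 6 — but remain in the profile with their `n_called`.

A category's value in one condition is the fraction of its members with
`M_p ≥ τ`. τ = 4 of 6 ("phosphorylated in a majority of reactions") is the
default reading of "number of peptides phosphorylated"; it is
configuration, and τ = 1 reproduces the any-reaction-positive reading.
Uncategorized peptides are scored but excluded from the collapse.

## Differential comparison

Per category, the observed statistic is `|Δ_c|`, `Δ_c = f_c(B) − f_c(A)`
computed over peptides eligible in both conditions (shared denominator).
The null reshuffles category membership labels across all categorized
eligible peptides, preserving category sizes, with one joint shuffle per
iteration serving every category; this conditions on the overall set of
per-peptide call changes and asks whether their concentration in a
category is surprising. p-values use the add-one estimator
`(1 + #{|Δ*| ≥ |Δ|}) / (1 + n_perm)` (never zero), with BH adjustment
across categories. n_perm defaults to 10 000; below 100 a warning is
issued. Everything is deterministic given the seed.

**Calibration.** Because calls are binary and categories finite, `|Δ_c|`
is discrete (multiples of 1/n_c). Under a no-effect generator most
categories show no net call change, the observed statistic ties with the
bulk of the permutation distribution, and the p-values concentrate at
large values — on 500 null studies of 64 peptides, ~85% of p-values are
exactly 1. Such discrete permutation p-values are *valid but
conservative*: P(p ≤ α) ≤ α at every α (measured P(p ≤ 0.05) ≈ 0.003),
while their distribution is far from uniform in the two-sided sense. Users
should read borderline q-values as conservative, and should not expect a
uniform p histogram from null data. The permutation test and BH layer are
additions of this package — the underlying category contrast is
traditionally presented qualitatively as a grey-scale matrix, which
`compare` also emits.

## Synthetic studies

The generator emulates the two-condition MEF design on the log scale:

    log fg[p,c,b,t] = a_p + log m(p,c) + B[p,c,b] + T[p,c,b,t]

with per-peptide affinity `a_p ~ N(baseline_log_mean, baseline_log_sd²)`
shared by both conditions, activity multiplier `m`, biological noise `B`
shared across the technical replicates of one lysate, technical noise `T`
per reaction, and i.i.d. lognormal per-spot background. Defaults (all
arbitrary-unit choices documented as calibration, not measured values):
baseline ≈ exp(6.4) ≈ 600 over background ≈ exp(4.6) ≈ 100;
`baseline_log_sd` 0.4 (≈ 5-fold 95% range of substrate affinity);
`sigma_bio` 0.15 > `sigma_tech` 0.10, which reproduces the observed QC
regime (technical r ≈ 0.97, biological r ≈ 0.91, both "well in excess of
0.85") and the ordering technical > biological concordance; knockout-side
multiplier 4.0 on the five planted categories (mTOR, p70S6K, AMPK,
Chk1/Chk2, PAK) of 20 peptides each; ten 20-peptide neutral categories so
specificity is measurable; 15% of uncategorized peptides constitutively
active in both conditions (so the within-reaction mixture always has two
populations). A single integer seed drives four documented substreams
(layout, truth, signal, background); identical configurations give
byte-identical files.

What the generator does **not** emulate: spatial artifacts (scratches,
gradients, edge effects), intensity-dependent (heteroscedastic or
saturating) noise, correlated backgrounds, cross-reactive substrates
shared between categories, or image-level segmentation error. Passing
tests therefore establish the pipeline's statistical behavior under a
clean multiplicative noise model, not robustness to spatially structured
artifacts; real arrays need the QC gate and `bad_spot` flags to carry that
weight.

## Problem sizes used in the test suite

Unit and property tests run on desk-scale instances (tens of peptides,
hundreds of randomized cases per oracle check). Study-level checks use the
full default scale: 20 seeds for the QC regime, 10 seeds × 12 reactions ×
1024 peptides with n_perm = 10 000 for planted-category recovery, and 500
null studies at 64 peptides / n_perm = 200 for calibration. These sizes
give stable averages (recovery and false-report rates are assessed per
category across seeds) while keeping the whole suite in a few minutes.

## Known limitations

- The two-state caller assumes some phosphorylated population exists per
  reaction; arrays with essentially no active spots are better served by
  the z-score fallback (the mixture may otherwise split noise).
- Tied variances trade a little sensitivity at the bright end for label
  stability; strongly heteroscedastic actives would be under-called.
- Membership permutation treats peptides as exchangeable units; if
  categories differ systematically in substrate affinity, the null is
  approximate.
- Pairwise-only condition comparison; multi-condition designs require
  repeated pairwise runs with their own multiplicity handling.
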