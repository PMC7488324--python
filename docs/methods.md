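# Methods

This note documents the statistical machinery behind `dconet`, the defaults
it ships with, the design choices that were genuinely open, and what the
synthetic-cohort tests do and do not demonstrate.

## Response calling

Caliper measurements convert to volumes with the ellipsoid approximation
`V = l·w²·π/6` (`l` = major axis, `w` = minor axis; the axis order is
enforced, not silently swapped).  Percent change from baseline is
`ΔVol_t = (V_t − V_i)/V_i · 100` with `V_i` the earliest observation.
BestResponse is the minimum `ΔVol_t` over observations at/after `min_day`
(default 10 days); BestAverageResponse is the minimum over the same
evaluation times of the running mean of `ΔVol` across *all* post-baseline
observations up to that time.  Two windowing choices were open and are fixed
as follows: the running mean starts at the first post-baseline observation
(the baseline's ΔVol = 0 is excluded from the mean), and observations before
`min_day` contribute to later running means but are never candidate minima
themselves — "after 10 or more days" qualifies the evaluation time, not the
data that feed it.

Classes are applied in order: CR (best < −95 and avg < −40), PR (best < −50
and avg < −20), SD (best < 35 and avg < 30), with PD the fall-through.  A
pair such as (40, 20) matches neither SD nor the literal PD conjunction; as
the last rule in an ordered cascade, PD absorbs it.  Binary labels are
responder = CR/PR/SD, non-responder = PD.  Classification is scale-invariant
in the volumes and total on finite inputs.  Note that
BestAverageResponse ≥ BestResponse is *not* an invariant (early deep
shrinkage followed by regrowth breaks it); the test suite constructs the
counterexample.

Arms with fewer than 5 samples in either response group are ineligible: with
less inter-individual heterogeneity there is nothing to model.

## Differential drivers

Group alteration rates get independent beta posteriors
`Beta(k + a, n − k + b)`.  The default prior is uniform (`a = b = 1`) and
exposed as a knob, since the appropriate prior strength is
cohort-dependent.  The inequality probability
`P(p₁ > p₂) = ∫₀¹ f_Beta(a₁,b₁)(x) · F_Beta(a₂,b₂)(x) dx` is computed by
adaptive quadrature with the density evaluated in log space and the
integrable endpoint singularities (when a shape parameter is < 1 the
integrand diverges at 0 or 1) handled by the quadrature's break-point list;
absolute tolerance ≤ 1e−8, verified against a Monte-Carlo oracle.
Symmetric evidence short-circuits to exactly 0.5, which also guarantees
`P(p₁>p₂) + P(p₂>p₁) = 1` at machine precision in the symmetric case and to
the quadrature tolerance otherwise.

Selection: Resp_DiffD requires `P(p_resp > p_nonresp) > 0.95` plus ≥ 2
altered responders and a responder rate ≥ 5%; NonResp_DiffD is the mirror
image.  General_DiffD uses the two-sided rule `max(P, 1−P) > 0.95` with the
count/rate filters applied in whichever group is enriched.  No
multiple-testing correction is applied at this stage — the method is a
fixed-probability filter, not a hypothesis-testing procedure, and the
permutation null downstream carries the error control for pairs.

## Co-occurring pairs and the rewiring null

The null preserves both marginals of the binary matrix exactly: repeated
checkerboard swaps pick two 1-entries `(s₁,g₁)`, `(s₂,g₂)` with
`(s₁,g₂) = (s₂,g₁) = 0` and exchange them.  Each permutation performs
10 × (number of 1s) successful swaps (configurable), comfortably above the
usual mixing budgets for bipartite degree-preserving randomization; the swap
loop is JIT-compiled, so 1000 permutations of an 80 × 120 matrix take about
a second.  Degenerate matrices with no valid checkerboard (e.g. all ones)
are returned unchanged with a warning.

Permutations rewire the *full* arm matrix once and are reused for the
responder and non-responder views by row restriction — this keeps the three
views of each permutation mutually consistent and is what "permutations of
the alteration matrix" implies; since row sums are preserved exactly, the
restriction also preserves every per-sample alteration count.  Candidate
pairs are restricted to genes altered ≥ 2 times in the arm, because a pair
failing the count filter can never be selected.

Per pair: the *tendency* is the mean over permutations of
`P(co-rate_obs > co-rate_perm)` (beta-inequality on co-alteration counts
over the same subset); the *differential co-occurrence* probability is
`P(co-rate_resp > co-rate_nonresp)`, and its permutation-null distribution
is obtained by splitting each permuted matrix by the true labels.
General_Ps needs tendency > 0.95 over the arm plus count/rate filters;
Resp_Ps needs responder tendency > 0.95, differential probability > 0.95
*and* above the null's 95th percentile, plus filters in responders;
NonResp_Ps mirrors with the complement probability and the 5th percentile.
Probabilities over integer count pairs are memoized, which is what makes
1000-permutation runs cheap (a few seconds per arm at desk scale).

## Networks

Per arm, three networks (General / Resp / NonResp): nodes are the flavor's
DiffD genes plus genes in flavor-selected pairs (source attribute `DiffD`,
`DiP`, or `both`), edges the selected pairs with their statistics.  When
gene coordinates are supplied, an edge gets `linked = True` if both genes
map to the same chromosome arm, plus the bp gap between gene bodies —
genomically linked pairs co-occur for structural reasons (co-amplification,
co-deletion) and deserve separate interpretation from *trans* pairs.  "Same
chromosome arm" rather than "same chromosome" is the operative definition;
distance is reported so users can draw their own line.  Nodes whose mean
LOOCV feature importance is ≤ 0 can be pruned (idempotent; incident edges
go with them).  Export is GraphML (typed attributes, round-trips exactly)
or SIF with the interaction label `co` for network viewers.

## Classifiers and score combination

The backend contract is any decision-tree gradient-boosting implementation
with class probabilities, per-feature importances, per-sample additive
explanations, and at least pairwise interaction modeling; `dconet` uses
xgboost (binary logistic objective, `base_score` fixed at 0.5, exact tree
method, single thread, explicit seed — LOOCV is bit-reproducible given seed
and library version).  Features are the network genes only, columns sorted
lexicographically; edges are deliberately not features.

Hyperparameters: 100 trees always; the tuning grid discretizes the ranges
as depth {1..7} × learning rate {0.2, 0.4, 0.6, 0.8, 1.0} × L2
{1, 3, 5, 10}, scored by mean AUC over 30 repeats of stratified 5-fold CV,
ties broken toward the simpler model (smaller depth, smaller learning rate,
larger L2).  Tuning happens once per arm with the LOOCV as the external
evaluation loop; fully nested tuning is available but not the default —
with arms of 29–246 samples the inner CV is already the dominant cost, and
per-fold re-tuning mostly adds variance.  Pipeline entry points accept
fixed hyperparameters (default depth 3, learning rate 0.4, L2 = 3) for
runs where tuning is not the point; the worked examples and the synthetic
benchmark use those.

`wComb` combines the three flavor classifiers with their LOOCV balanced
accuracies as weights; the general model contributes with both signs, the
responder model only positive response votes, the non-responder model only
negative non-response votes.  `P_s`/`P_r` are read as the general model's
class probabilities for response and non-response — the symbol pair is not
otherwise pinned down, and this is the only reading that makes the general
term change sign with the predicted class.  A missing or untrainable flavor
contributes 0; if every flavor is untrainable the arm yields no-calls.
`|wComb| ≤ BAcc_Gen + max(BAcc_Resp, BAcc_NonResp)` by construction.
The biomarker baseline (`wComb_bmk`) deduplicates catalog records, scores
each gene by its naive-rule balanced accuracy computed on the full arm (the
biomarker is a fixed comparator, not a fitted model), and flags samples
with no altered biomarker as not-applicable rather than confidently zero.

## Interpretation

Per-sample additive contributions come from the ensemble's native TreeSHAP
(`pred_contribs`); base value + contributions equals the margin (log-odds)
output.  The identity is exact in real arithmetic; in float32 the fast
margin prediction accumulates ~100 leaf values, so additivity checks at the
1e−6 level compare against `margin_float64`, an independent double-precision
evaluation of the dumped trees.  Pairwise interaction strengths use the
SHAP interaction decomposition (`pred_interactions`), ranked by mean
absolute off-diagonal value, ties broken lexicographically.  For a pair
(A, B) the four status categories A∧B, A∧¬B, ¬A∧B, ¬A∧¬B get each gene's
mean contribution and the category sizes; empty categories report NaN.
The exhaustive oracle in the test suite recomputes Shapley values by subset
enumeration over the cover-weighted conditional-expectation value function,
which is exactly what TreeSHAP computes in its path-dependent form.

The biomarker-overlap test builds the 2×2 table (overlap, network-only,
catalog-only, remainder) over the universe of eligible drug–gene pairs and
reports Fisher's exact two-sided p with both the sample odds ratio (ad/bc)
and the conditional-MLE odds ratio — sources differ in which they print, so
both are available.

## Clinical adaptation

Patients are sorted by treatment duration and split into equal thirds:
shortest = non-responders, longest = responders, middle unlabeled.  Cutoffs
are the boundary order statistics; duration values tied across a boundary
are resolved toward the middle group, and a fully tied cohort leaves
everyone unlabeled with a warning.  Patients whose biopsy postdates therapy
start by more than 60 days can be excluded upstream via an optional offset
column.  The standard pipeline runs on the extremes only; middle-third
patients never appear in network inference or training folds and are scored
at prediction time.

Confidence thresholds scan the labeled LOOCV scores per side independently
(the two sides need not be symmetric).  Candidates stay on the natural side
of the `wComb` decision boundary — response thresholds positive,
non-response negative — so a confident call always agrees with the score's
sign; within that constraint the least extreme threshold whose labeled FDR
is within the bound (default 30%) is chosen, maximizing coverage.  Raising
the bound never shrinks the number of confident calls.  If no threshold
qualifies on either side, an explicit "no confident calls" sentinel is
returned instead of a degraded threshold.  Unlabeled patients are excluded
from FDR bookkeeping but counted in coverage.

Survival evaluation: Kaplan–Meier median per predicted group (infinite when
a group never reaches 50% events), two-group log-rank test, and a Cox
proportional-hazards fit of the event hazard on the continuous score (both
raw-duration and censored modes are supported; censored is the default for
evaluation).

## Synthetic cohorts

The generator emulates the statistical structure the pipeline assumes:

* background alterations i.i.d. Bernoulli per gene with gene-specific rates
  drawn from Beta(1.5, 20) (mean ≈ 7%, the typical per-gene driver
  frequency in targeted-panel cohorts);
* planted differential genes with group-specific rates (default 0.6 vs
  0.05, two responder-enriched and one non-responder-enriched gene);
* planted pairs via a shared latent Bernoulli factor (default 0.35) in the
  designated group plus independent 2% background — the latent-factor
  construction inflates co-occurrence while keeping marginals controllable,
  which is precisely the quantity the pair test measures;
* tumor volumes `V(t) = V₀ · exp((g − e·z)·t) · lognormal noise` with
  growth 0.06/day, treatment effect 0.12/day for carriers `z = 1` of any
  planted responder feature, baseline 200 mm³, observations twice weekly to
  day 28, σ = 0.1 — so carriers regress (PR/SD) and non-carriers progress
  (PD);
* progression times Weibull with shape 2, non-carrier scale 5.5 months and
  carrier hazard ratio 6.25 (a 2.5× median ratio, mirroring reported
  metastatic-setting splits of ~5 vs ~13.5 months), independent exponential
  censoring at a 15% marginal rate.

Default cohort size is 80 samples × 120 genes; the full pipeline (1000
permutations plus LOOCV) runs in well under a minute per arm on one CPU.

What passing these tests shows: the selection machinery recovers effects of
the planted size at the stated thresholds, controls false selection on null
cohorts, and the classifier/combination stack turns recovered features into
accurate, explainable predictions.  What it does not show: robustness to
mutational-signature structure, copy-number segment correlation (planted
pairs are *trans*-like; real linked pairs share segments), tumor-type
confounding, panel-coverage mismatch, or any property of real PDX or
patient cohorts.

## Numerical and degenerate-input conventions

* Beta quadrature: `scipy.integrate.quad`, break points at the density mode,
  absolute/relative tolerance 1e−10, hard failure (not silent) if the error
  estimate exceeds 1e−6.
* Rewiring: swap attempts capped at 200 × target; falling short warns and
  returns the partially mixed matrix.
* LOOCV folds that lose a class (only possible in pathological arms)
  predict the training base rate.
* Balanced accuracy is `None`, never a number, when a class is absent;
  arms with undefined BAcc are excluded from macro-averages with a log line.
* Tertile cutoffs with massive ties degrade to "all unlabeled", not to an
  arbitrary split.
* All stochastic steps take explicit seeds; derived sub-seeds come from
  `numpy.random.SeedSequence` spawning.

## Benchmark problem sizes

The shipped acceptance benchmark uses 20 synthetic cohorts per recovery
condition (each 80 × 120 at 1000 permutations), a 51-point grid for the
Monte-Carlo comparison at 10⁶ draws per point, 1000 rewirings for the
marginal-preservation check, 20 cohorts per LOOCV condition, 40 score sets
for the FDR bound, and 50 survival cohorts of 50 + 50 patients at hazard
ratio 2.5 — sizes chosen so the whole benchmark completes in a few minutes
on a single CPU while keeping the binomial uncertainty on every reported
rate a few percent.
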