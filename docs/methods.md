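# Methods

`psychoscreen` implements a screening workflow for identifying gut microbes
whose abundance trajectories track mood in small, densely sampled
longitudinal cohorts (the "psychobiotic candidate" setting: ~8 subjects
observed at ~13 timepoints each, a 19-factor POMS + SCL-90 mood panel, and
compositional taxon profiles from shotgun metagenomics, optionally LFQ
protein-group or metabolite-peak matrices). This note records the model,
the defaults, the numerical choices, and what the synthetic validation
does and does not establish.

## Pipeline

1. **Normalization.** Each feature column x is transformed to
   `log2(x + c)` and divided by the magnitude of its across-sample mean
   log value (the "quotient" step). The pseudocount c defaults to half
   the smallest nonzero value of the matrix — standard compositional
   practice for zero handling; `fixed(ε)` is available. Two orders are
   implemented (`log_then_quotient`, default, and `quotient_then_log`);
   log-first is the default because a quotient on raw compositional
   values is already scale-free and the log-first form has a clean
   covariance property (doubling a feature shifts its pre-quotient column
   by exactly +1). Dividing by the *magnitude* of the mean rather than
   the signed mean is deliberate: on relative-abundance data every mean
   log2 value is negative, and a signed quotient would invert each
   feature's orientation and with it the sign of every downstream
   correlation, detaching the final sign classification from the data's
   actual direction. Features whose mean log is ~0 are divided by 1.
2. **Prevalence filter** (sparse LFQ/metabolite data): a feature is kept
   iff it is detected (> 0) in at least `min_fraction` (default 50%) of
   samples in *every* group (e.g. each crew rotation).
3. **Stationarity gate.** Correlating two time series is only meaningful
   if both look stationary. Per subject and per variable we compute the
   sample ACF (common-denominator estimator, r0 = 1), the white-noise
   band ±z_{1−α/2}/√n (α = 0.05, the conventional "blue lines"), and the
   Ljung-Box Q over lags 1..L with its chi-square(h) upper-tail p. A
   series is flagged stationary iff all lag-1..L autocorrelations sit
   inside the band AND the Ljung-Box p exceeds α. L defaults to
   min(10, ⌊n/2⌋−1); series shorter than 4 points (or constant) are
   flagged `insufficient` rather than raising. Sampling days are treated
   as an ordered, effectively equally spaced index; the day numbers are
   carried through for the user but not modelled.
4. **Ordination.** PCA by SVD of the centered matrix; a one-way MANOVA on
   the top-k scores (k configurable, default 2 — the dimensionality one
   plots) tests subject and gender separation via Wilks'
   Λ = det(W)/det(W+B). The p-value uses Rao's F transformation of Λ,
   which is exact whenever the score dimension is ≤ 2 or there are ≤ 3
   groups — every configuration the package's own checks exercise —
   and reduces to the ordinary F test in the univariate two-group case;
   Bartlett's chi-square approximation is reported alongside for
   reference. Group distances are Mahalanobis distances between group
   means under the pooled within-group covariance, clustered by average
   linkage with groups pre-sorted lexicographically (the deterministic
   tie-break), exported as Newick.
5. **PLS engine.** One NIPALS PLS1 model per mood factor (19 separate
   single-response models, matching the per-factor reporting convention;
   PLS2 is not used). Predictors are autoscaled by default — standard
   for VIP-based screening across features of very different variance —
   and centering/scaling are recomputed inside every leave-one-out fold
   to avoid leakage. Model size A is chosen per factor by maximizing
   LOO-Q² over 1..max_A (default max_A = min(10, n−2, p)), ties toward
   the smaller A. Evaluation reports PRESS, RMSECV = √(PRESS/n),
   Q² = 1 − PRESS/Σ(y−ȳ)², and the Spearman R/P between cross-validated
   predictions and observations. VIP uses the Wold formulation
   VIP_j = √(p·Σ_a SS_a (w_ja/‖w_a‖)² / Σ_a SS_a) with
   SS_a = q_a²(t_aᵀt_a), so Σ_j VIP_j² = p exactly. Folds in which a
   feature loses all variance drop that feature within the fold (logged).
6. **Two-stage screen.** Stage 1: a feature is *key* iff VIP ≥ 1 in a
   strict majority ("more than 50%", i.e. ⌊f/2⌋+1 = 10 of 19 factors) of
   the panel. Stage 2: key features only — Spearman against every
   factor; *candidate* iff |R| ≥ 0.5 (0.35 for protein-group data) with
   P < 0.001 in a strict majority of factors. Computing stage 2 on all
   features instead provably cannot change the candidate set (candidates
   must pass both stages) and is available for reporting. Stage 3:
   candidates are classified `positive_mood_associated` iff R > 0 with
   P < 0.05 on **every** positive-polarity factor (there are only two:
   vigour-activity and self-esteem) and R < 0 with P < 0.05 on a strict
   majority of the 17 negative-polarity factors; the mirror condition
   gives `negative_mood_associated`, anything else `inconsistent`.
   Requiring unanimity over 17 negative factors would be stricter than
   the evidence pattern such panels actually show, so majority was
   chosen for the long arm and unanimity for the short one. P-values use
   the t approximation by default; an exact n!-enumeration is available
   for n ≤ 8. No multiple-testing correction is applied across
   features or factors — the screen's thresholds are raw-P by design;
   a Benjamini–Hochberg option can be layered on by the user.
7. **Inverted metabolite screen.** One PLS model per candidate taxon
   (metabolites → taxon abundance); a metabolite is key iff VIP ≥ 1 in
   **all** taxon models (a conjunction, not a majority — with a single
   candidate taxon it degenerates to the single-model rule). A curated
   allowlist (e.g. nervous-system metabolites) restricts only the
   reported table, never the fitting. KO and protein-group matrices are
   screened by refitting per matrix; component counts are never reused
   across matrices.

Mood scores are not normalized before PLS by default (PLS centers, and
autoscaling the response is a no-op for Q² and VIP); a config switch
(`normalize_mood`) applies the log-quotient transform to the panel too.

## Synthetic cohorts

The generator produces the structure the screen assumes, with ground
truth for recovery testing:

- latent mood state m: independent stationary AR(1) per subject,
  φ = 0.3, unit innovations (marginal variance 1/(1−φ²) ≈ 1.10) —
  persistence mild enough that per-subject series pass the ACF gate, as
  the real panel's series did;
- mood factors: ±λ·m + noise (λ = 1, noise sd 0.5), sign from the
  factor's polarity; affinely mapped to questionnaire-like ranges
  (POMS-like ≈ mean 10 sd 4, SCL-like ≈ mean 1.5 sd 0.4) using the
  theoretical sd, so the map is deterministic and cosmetic (Spearman and
  autoscaled PLS are unaffected);
- taxa: log2 abundance = base (sd 1.5, giving a realistic rank-abundance
  spread) + per-subject offset (sd 0.5) + per-taxon gender effect
  (sd 0.5) + planted effect (β·sign·m, β = 1, default 5 of 200 taxa,
  all signs +1 unless configured) + noise (sd 0.5), closed to relative
  abundances per sample (logistic-normal composition);
- defaults 8 subjects (4 female / 4 male) × 13 timepoints = 104 samples;
- metabolites: one linked metabolite per planted taxon
  (α·log2 abundance + noise), the rest iid log-normal;
- the null generator zeroes the planted effect and empties the truth,
  leaving every other stream identical.

The offset and noise sds (0.5 on the log2 scale) are the package's
realism choice: individual signatures comparable in magnitude to
within-subject dynamics, which is what dense longitudinal gut-microbiome
studies report qualitatively. Under these conditions a planted taxon's
expected pooled Spearman |R| against a factor is ≈ 0.75, comfortably
above the 0.5 gate at n ≈ 104, so recovery failures indicate pipeline
defects rather than an underpowered design.

What passing the synthetic suite shows: the screen recovers taxa whose
log-abundance genuinely tracks a shared latent state, with correct sign,
and almost never promotes unrelated taxa even in the presence of
subject/gender structure. What it does not show: robustness to real
microbiome dynamics (blooms, interactions, diet shifts), irregular
sampling, sequencing noise, or compositional artifacts stronger than the
logistic-normal model induces.

## Numerical choices and degenerate inputs

- ACF uses the biased (common-denominator) estimator, matching standard
  ACF-plot conventions; constant series raise in `sample_acf` and are
  flagged (not raised) in the panel assessment.
- Spearman uses midranks under ties; in the tie-free case the classical
  d² formula is used so that perfectly monotone data yields R = ±1
  exactly. Constant vectors are signalled as errors.
- NIPALS stops early if the residual becomes orthogonal to y; a
  zero-variance column under autoscaling is an error naming the column
  at fit time, and a logged within-fold drop during cross-validation.
- Wilks' Λ is computed from slogdet; a singular within-group SSCP raises
  with the suggestion to reduce k.
- Screen report reals are serialized with 17 significant digits, so
  write→read round trips are exact to well below 1e-12.
- All randomness flows through `numpy.random.default_rng` seeds;
  identical inputs, config and seed reproduce byte-identical reports.

## Problem sizes used in validation

The validation suite exercises: 50 random 20×5 problems for the PLS/OLS
oracle; 20 random 15×4 problems for the LOO/refit-loop oracle; 100 random
n=6 pairs for the exact-vs-approximate Spearman comparison; 2,000
white-noise series of length 50 for Ljung-Box calibration; 1,000
two-group null replicates for MANOVA calibration; and 50 signal + 50 null
default cohorts (104 samples, 200 taxa) for end-to-end recovery and
false-positive calibration.

Known limitation: the Ljung-Box chi-square reference is intrinsically
liberal for h large relative to n (at n = 50, h = 10 its true type-I rate
is ≈ 0.07 at nominal 0.05, indistinguishable from statsmodels'
implementation), so its white-noise rejection-rate estimate sits at the
edge of a 0.05 ± 0.02 calibration band.
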