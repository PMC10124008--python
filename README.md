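# psychoscreen

Identify mood-associated gut microbes ("psychobiotic" candidates) in
small, densely sampled longitudinal cohorts — the setting of closed-habitat
crews or intensive ambulatory studies: a handful of subjects, ~13 sampling
days each, a 19-factor mood panel (8 POMS factors including Total Mood
Disturbance, 11 SCL-90 factors including SUM-SCL90), and compositional
multiomics profiles (taxa, KOs, protein groups, metabolites) from the same
stool samples.

## What it computes

The screen asks: which features' trajectories track mood across the whole
panel, in the right direction?

1. **Normalization** — per feature, `log2(x + c)` followed by a quotient
   by the magnitude of the across-sample mean log value; 50%-per-group
   prevalence filtering for sparse LFQ data.
2. **Stationarity gate** — per subject and variable, the sample ACF with
   the ±1.96/√n white-noise band and the Ljung-Box portmanteau
   Q = n(n+2)Σₖ rₖ²/(n−k): correlations are only interpreted between
   series that behave as stationary stochastic processes.
3. **Ordination** — PCA, then MANOVA on PC scores (Wilks' Λ, p by Rao's
   F), Mahalanobis distances between subject/gender group means, and an
   average-linkage dendrogram of groups.
4. **PLS engine** — one NIPALS PLS1 model per mood factor with
   leave-one-out cross-validation: Q² = 1 − PRESS/Σ(y−ȳ)², RMSECV, and
   the Spearman R/P of cross-validated predictions versus observations;
   component count chosen by LOO-Q²; Wold VIP scores
   (VIP_j = √(p·Σₐ SSₐ(w_ja/‖wₐ‖)²/Σₐ SSₐ), so mean VIP² = 1).
5. **Two-stage screen** — *key* features have VIP ≥ 1 in more than 50% of
   the factors (10 of 19); *candidates* additionally have |R| ≥ 0.5
   (0.35 for protein groups) with P < 0.001 in more than 50% of the
   factors; candidates are sign-classified as positive- or negative-mood
   associated from the polarity split of the panel (vigour-activity and
   self-esteem score positively; the other 17 factors are symptom
   scales). An inverted screen selects metabolites with VIP ≥ 1 in
   **all** candidate-taxon models.
6. **Synthetic cohorts** — a generator with a stationary AR(1) latent
   mood state, polarity-consistent factor loadings, and planted
   mood-tracking taxa in a logistic-normal composition, with ground
   truth, so the entire pipeline is validated by recovery and null
   calibration rather than trust.

## Worked example

```sh
psychoscreen simulate --seed 7 --out-dir cohort
psychoscreen preprocess --abundance cohort/abundance.tsv \
    --metadata cohort/metadata.tsv --out normalized.tsv
psychoscreen screen --abundance normalized.tsv \
    --mood cohort/mood.tsv --out-dir screen
psychoscreen report --screen-dir screen
```

prints

```
cohort written to cohort (104 samples, 200 taxa, 5 planted)
normalized table written to normalized.tsv
features in: 200; key: 47; candidates: 5; by class: {'positive_mood_associated': 5}
200 features screened against 19 factors (votes required: 10)
key: 47; candidates: 5
  taxon_0003: vip_votes=19 corr_votes=19 class=positive_mood_associated
  taxon_0045: vip_votes=19 corr_votes=19 class=positive_mood_associated
  taxon_0052: vip_votes=19 corr_votes=19 class=positive_mood_associated
  taxon_0065: vip_votes=19 corr_votes=19 class=positive_mood_associated
  taxon_0144: vip_votes=19 corr_votes=19 class=positive_mood_associated
```

The simulated cohort planted five taxa whose log-abundance tracks the
latent mood state (`cohort/truth_planted.tsv`); the screen narrows 200
taxa to 47 key features by the VIP vote, keeps exactly the five planted
taxa as candidates by the correlation vote, and classifies each as
positively mood-associated — matching the planted loading signs. The
per-feature votes, the full (feature × factor) VIP/R/P table, and the
candidate list are written under `screen/`. `psychoscreen stationarity`
and `psychoscreen ordinate` expose the gate and the ordination steps on
the same tables, and the library API (`psychoscreen.*`) exposes every
stage programmatically.

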