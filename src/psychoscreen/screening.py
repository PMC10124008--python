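"""Candidate selection: VIP majority vote, Spearman magnitude/significance
vote, and sign-consistency classification.

Stage 1 fits one PLS1 model per mood factor and counts, per feature, the
factors in which its VIP reaches the threshold; features voted in by a
strict majority are "key". Stage 2 computes Spearman correlations of the
key features against every factor and requires |R| and P thresholds in a
strict majority of factors. Stage 3 classifies surviving candidates as
positive- or negative-mood associated from the signs of their significant
correlations against the panel's polarity split.

The inverted screen (metabolites predicting candidate taxa, with the "VIP
>= 1 in ALL taxa" conjunction) lives here too.
"""

from __future__ import annotations

import logging
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import pls
from .config import RunConfig
from .types import AbundanceMatrix, MoodPanel, ScreenResult

logger = logging.getLogger(__name__)


def _strict_majority_threshold(n: int, fraction: float) -> int:
    import math

    return math.floor(n * fraction) + 1


def classify_sign(
    r_by_factor: Mapping[str, float],
    p_by_factor: Mapping[str, float],
    polarity: Mapping[str, str],
    alpha: float = 0.05,
) -> str:
    """Sign-consistency class of one feature.

    ``positive_mood_associated``: significantly (P < alpha) positive R on
    EVERY positive-polarity factor and significantly negative R on a strict
    majority of negative-polarity factors. ``negative_mood_associated`` is
    the mirror image; anything else is ``inconsistent``.
    """
    positives = [f for f, pol in polarity.items() if pol == "positive"]
    negatives = [f for f, pol in polarity.items() if pol == "negative"]
    missing = [f for f in polarity if f not in r_by_factor]
    if missing:
        raise ValueError(f"R missing for factors: {missing}")

    def sig(f: str, sign: int) -> bool:
        r, p = r_by_factor[f], p_by_factor[f]
        return np.isfinite(r) and p < alpha and (r > 0 if sign > 0 else r < 0)

    need_neg = _strict_majority_threshold(len(negatives), 0.5) if negatives else 0
    pos_up = all(sig(f, +1) for f in positives)
    neg_down = sum(sig(f, -1) for f in negatives) >= need_neg
    if pos_up and neg_down:
        return "positive_mood_associated"
    pos_down = all(sig(f, -1) for f in positives)
    neg_up = sum(sig(f, +1) for f in negatives) >= need_neg
    if pos_down and neg_up:
        return "negative_mood_associated"
    return "inconsistent"


def _factor_vip(x: np.ndarray, y: np.ndarray, cfg: RunConfig) -> np.ndarray:
    a_star, _ = pls.select_components(x, y, cfg.max_components, scale=cfg.scale)
    model = pls.fit_pls(x, y, a_star, scale=cfg.scale)
    return pls.vip(model)


def screen_features_vs_panel(
    matrix: AbundanceMatrix,
    panel: MoodPanel,
    cfg: Optional[RunConfig] = None,
    stage2_all_features: bool = False,
) -> ScreenResult:
    """Two-stage screen of features against the mood panel.

    ``matrix`` must already be normalized and sample-aligned with the
    panel. ``stage2_all_features=True`` computes Spearman statistics for
    every feature rather than only stage-1 survivors (the candidate set is
    unaffected; useful for reporting).
    """
    cfg = cfg or RunConfig()
    if list(matrix.values.index) != list(panel.scores.index):
        if set(matrix.values.index) != set(panel.scores.index):
            raise ValueError("sample ids of matrix and mood panel do not match")
        panel = MoodPanel(panel.scores.loc[matrix.values.index], panel.polarity)
    n = matrix.n_samples
    if n < 10:
        raise ValueError(f"need at least 10 aligned samples; got {n}")

    x = matrix.values.to_numpy(dtype=float)
    factors = []
    for f in panel.factor_names:
        if np.ptp(panel.scores[f].to_numpy(dtype=float)) == 0.0:
            logger.warning("factor %r has zero variance; excluded from the vote", f)
            continue
        factors.append(f)
    n_factors = len(factors)
    if n_factors == 0:
        raise ValueError("no non-degenerate factors to screen against")
    votes_required = cfg.votes_required(n_factors)

    feature_ids = matrix.feature_ids
    p = len(feature_ids)

    # Stage 1: per-factor PLS + VIP votes
    vip_table = pd.DataFrame(index=feature_ids, columns=factors, dtype=float)
    for f in factors:
        y = panel.scores[f].to_numpy(dtype=float)
        vip_table[f] = _factor_vip(x, y, cfg)
    vip_votes = (vip_table >= cfg.vip_threshold).sum(axis=1)
    key = vip_votes >= votes_required
    logger.info("stage 1: %d features in, %d key (VIP>=%.3g in >=%d of %d factors)",
                p, int(key.sum()), cfg.vip_threshold, votes_required, n_factors)

    # Stage 2: Spearman for key features (optionally all)
    stage2 = list(feature_ids) if stage2_all_features else list(vip_votes.index[key])
    r_table = pd.DataFrame(np.nan, index=feature_ids, columns=factors)
    p_table = pd.DataFrame(np.nan, index=feature_ids, columns=factors)
    for feat in stage2:
        xi = matrix.values[feat].to_numpy(dtype=float)
        for f in factors:
            r, pv = pls.spearman(xi, panel.scores[f].to_numpy(dtype=float))
            r_table.loc[feat, f] = r
            p_table.loc[feat, f] = pv
    passing = (r_table.abs() >= cfg.r_threshold) & (p_table < cfg.p_threshold)
    corr_votes = passing.sum(axis=1)
    candidate = key & (corr_votes >= votes_required)
    logger.info("stage 2: %d key in, %d candidates (|R|>=%.3g, P<%.3g in >=%d factors)",
                int(key.sum()), int(candidate.sum()), cfg.r_threshold,
                cfg.p_threshold, votes_required)

    # Stage 3: sign classification of candidates
    polarity = {f: panel.polarity[f] for f in factors}
    sign_class = pd.Series("none", index=feature_ids, dtype=object)
    for feat in feature_ids:
        if candidate[feat]:
            sign_class[feat] = classify_sign(
                r_table.loc[feat].to_dict(), p_table.loc[feat].to_dict(),
                polarity, alpha=cfg.sign_alpha,
            )

    features = pd.DataFrame({
        "vip_votes": vip_votes.astype(int),
        "corr_votes": corr_votes.astype(int),
        "key": key,
        "candidate": candidate,
        "sign_class": sign_class,
    })
    features.index.name = "feature"
    long = pd.concat(
        {
            "vip": vip_table.stack(future_stack=True),
            "spearman_r": r_table.stack(future_stack=True),
            "spearman_p": p_table.stack(future_stack=True),
        },
        axis=1,
    ).reset_index()
    long.columns = ["feature", "factor", "vip", "spearman_r", "spearman_p"]
    return ScreenResult(features=features, per_factor=long,
                        n_factors=n_factors, votes_required=votes_required)


def screen_metabolites_vs_taxa(
    metabolites: AbundanceMatrix,
    taxa: pd.DataFrame,
    cfg: Optional[RunConfig] = None,
    allowlist: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Inverted screen: PLS models predicting each candidate taxon's
    (normalized) abundance from all metabolites; a metabolite is *key* iff
    its VIP reaches the threshold in EVERY taxon model. Spearman R/P are
    then reported for each (key metabolite, taxon) pair.

    ``taxa`` is a samples x candidate-taxa table aligned with the
    metabolite matrix. ``allowlist`` (e.g. a curated set of nervous-system
    metabolites) restricts the *reported* table only, never the fitting.
    Returns a long table: metabolite, taxon, vip, spearman_r, spearman_p, key.
    """
    cfg = cfg or RunConfig()
    if taxa.shape[1] < 1:
        raise ValueError("need at least one candidate taxon")
    if list(metabolites.values.index) != list(taxa.index):
        if set(metabolites.values.index) != set(taxa.index):
            raise ValueError("sample ids of metabolite matrix and taxa table differ")
        taxa = taxa.loc[metabolites.values.index]

    x = metabolites.values.to_numpy(dtype=float)
    met_ids = metabolites.feature_ids
    vip_table = pd.DataFrame(index=met_ids, columns=taxa.columns, dtype=float)
    for taxon in taxa.columns:
        y = taxa[taxon].to_numpy(dtype=float)
        vip_table[taxon] = _factor_vip(x, y, cfg)
    key = (vip_table >= cfg.vip_threshold).all(axis=1)
    logger.info("metabolite screen: %d metabolites, %d key (VIP>=%.3g in all %d taxa)",
                len(met_ids), int(key.sum()), cfg.vip_threshold, taxa.shape[1])

    rows = []
    for met in met_ids:
        if not key[met]:
            continue
        xm = metabolites.values[met].to_numpy(dtype=float)
        for taxon in taxa.columns:
            r, pv = pls.spearman(xm, taxa[taxon].to_numpy(dtype=float))
            rows.append({"metabolite": met, "taxon": taxon,
                         "vip": float(vip_table.loc[met, taxon]),
                         "spearman_r": r, "spearman_p": pv, "key": True})
    table = pd.DataFrame(rows, columns=["metabolite", "taxon", "vip",
                                        "spearman_r", "spearman_p", "key"])
    if allowlist is not None:
        table = table[table["metabolite"].isin(set(allowlist))].reset_index(drop=True)
    return table
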