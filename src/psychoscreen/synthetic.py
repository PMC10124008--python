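"""Synthetic longitudinal cohorts with planted mood-tracking taxa.

The generator emulates the statistical structure the screen assumes: a
small closed cohort (8 subjects, half female, ~13 sampling days each), a
latent per-subject mood state following a stationary AR(1) process, a
19-factor mood panel whose factors load on that state with a
positive/negative polarity split, and a compositional taxon table in which
a handful of planted taxa track the latent state on the log scale while
everything else is subject/gender-structured noise. An optional metabolite
layer reads out planted taxa. Ground truth (planted identities, loading
signs, the latent state) is returned for recovery testing.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
import pandas as pd

from .types import (
    AbundanceMatrix,
    CohortTruth,
    DEFAULT_FACTORS,
    MoodPanel,
    POMS_FACTORS,
    default_polarity_map,
)


@dataclass
class CohortConfig:
    """Study-design and effect-size knobs of the simulator.

    Defaults mirror the cohort the screen targets: 8 subjects (4 female /
    4 male) x 13 timepoints = 104 samples, 200 taxa with 5 planted at
    loading ``effect_size`` on the latent state, AR(1) persistence 0.3
    (innovation sd 1, so the latent state has marginal sd ~1.05), and
    moderate noise/offset scales (sd 0.5 on the log2 scale) for individual
    and gender structure.
    """

    n_subjects: int = 8
    timepoints_per_subject: int = 13
    n_taxa: int = 200
    n_planted: int = 5
    effect_size: float = 1.0  # loading of planted log2-abundance on the latent state
    ar_phi: float = 0.3
    factor_loading: float = 1.0
    factor_noise_sd: float = 0.5
    taxon_noise_sd: float = 0.5
    subject_offset_sd: float = 0.5
    gender_offset_sd: float = 0.5
    base_log_abundance_sd: float = 1.5
    n_metabolites: int = 60
    metabolite_alpha: float = 1.0
    metabolite_noise_sd: float = 0.5
    planted_signs: Optional[tuple[int, ...]] = None  # default: all +1
    seed: int = 0

    def __post_init__(self) -> None:
        if not (-1.0 < self.ar_phi < 1.0):
            raise ValueError("ar_phi must lie strictly in (-1, 1)")
        if self.n_planted >= self.n_taxa:
            raise ValueError("n_planted must be < n_taxa")
        for name in ("factor_noise_sd", "taxon_noise_sd", "subject_offset_sd",
                     "gender_offset_sd", "metabolite_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.planted_signs is not None:
            if len(self.planted_signs) != self.n_planted:
                raise ValueError("planted_signs must have length n_planted")
            if any(s not in (-1, 1) for s in self.planted_signs):
                raise ValueError("planted_signs entries must be +1 or -1")


def _ar1(rng: np.random.Generator, n: int, phi: float) -> np.ndarray:
    """Stationary AR(1) path: x_0 ~ N(0, 1/(1-phi^2)), unit innovations."""
    x = np.empty(n)
    x[0] = rng.normal(0.0, 1.0 / np.sqrt(1.0 - phi ** 2))
    eps = rng.normal(size=n - 1)
    for t in range(1, n):
        x[t] = phi * x[t - 1] + eps[t - 1]
    return x


def generate_cohort(
    cfg: CohortConfig,
) -> tuple[AbundanceMatrix, MoodPanel, pd.DataFrame, CohortTruth]:
    """Generate (taxa AbundanceMatrix, MoodPanel, metadata, CohortTruth).

    Latent state: independent stationary AR(1) per subject. Factors:
    ``polarity_sign * factor_loading * m + noise``, affinely mapped to
    plausible questionnaire ranges (POMS-like ~ mean 10 sd 4, SCL-like ~
    mean 1.5 sd 0.4) using the theoretical series sd, so the mapping is
    deterministic and scale-only. Taxa: log2 abundance = base + subject
    offset + gender offset + (planted: effect_size * sign * m) + noise,
    closed to relative abundances per sample.
    """
    rng = np.random.default_rng(cfg.seed)
    n_sub, n_tp = cfg.n_subjects, cfg.timepoints_per_subject
    subjects = [chr(ord("A") + i) if i < 26 else f"S{i}" for i in range(n_sub)]
    genders = ["female" if i < (n_sub + 1) // 2 else "male" for i in range(n_sub)]

    latent = np.vstack([_ar1(rng, n_tp, cfg.ar_phi) for _ in range(n_sub)])
    sample_ids = [f"{s}_t{t:02d}" for s in subjects for t in range(1, n_tp + 1)]
    metadata = pd.DataFrame(
        {
            "subject_id": np.repeat(subjects, n_tp),
            "gender": np.repeat(genders, n_tp),
            "timepoint": np.tile(np.arange(1, n_tp + 1), n_sub),
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    m = latent.ravel()  # sample-aligned latent state
    n_samples = m.size

    # --- mood panel ---------------------------------------------------
    polarity = default_polarity_map()
    factor_sd = np.sqrt(
        cfg.factor_loading ** 2 / (1.0 - cfg.ar_phi ** 2) + cfg.factor_noise_sd ** 2
    )
    scores = {}
    for f in DEFAULT_FACTORS:
        sgn = 1.0 if polarity[f] == "positive" else -1.0
        raw = sgn * cfg.factor_loading * m + rng.normal(0, cfg.factor_noise_sd, n_samples)
        if f in POMS_FACTORS:
            scores[f] = 10.0 + 4.0 * raw / factor_sd
        else:
            scores[f] = 1.5 + 0.4 * raw / factor_sd
    panel = MoodPanel(pd.DataFrame(scores, index=metadata.index), polarity)

    # --- taxa ---------------------------------------------------------
    taxa_ids = [f"taxon_{j:04d}" for j in range(cfg.n_taxa)]
    planted_idx = rng.choice(cfg.n_taxa, size=cfg.n_planted, replace=False)
    planted_idx.sort()
    signs = (np.ones(cfg.n_planted, dtype=int) if cfg.planted_signs is None
             else np.asarray(cfg.planted_signs, dtype=int))

    base = rng.normal(0.0, cfg.base_log_abundance_sd, cfg.n_taxa)
    subj_offsets = rng.normal(0.0, cfg.subject_offset_sd, (n_sub, cfg.n_taxa))
    gender_effect = rng.normal(0.0, cfg.gender_offset_sd, cfg.n_taxa)
    is_male = (metadata["gender"] == "male").to_numpy(dtype=float)
    subj_index = np.repeat(np.arange(n_sub), n_tp)

    log2_abund = (
        base[None, :]
        + subj_offsets[subj_index]
        + np.outer(is_male, gender_effect)
        + rng.normal(0.0, cfg.taxon_noise_sd, (n_samples, cfg.n_taxa))
    )
    log2_abund[:, planted_idx] += cfg.effect_size * np.outer(m, np.ones(cfg.n_planted)) * signs

    raw = np.exp2(log2_abund)
    rel = raw / raw.sum(axis=1, keepdims=True)
    taxa = AbundanceMatrix(
        pd.DataFrame(rel, index=metadata.index, columns=taxa_ids),
        mode="relative_abundance",
        metadata=metadata,
    )

    truth = CohortTruth(
        planted=pd.DataFrame(
            {"sign": signs.astype(float) * (1.0 if cfg.effect_size != 0 else 0.0)},
            index=pd.Index([taxa_ids[j] for j in planted_idx], name="taxon_id"),
        ) if cfg.effect_size != 0 else pd.DataFrame(
            {"sign": pd.Series(dtype=float)},
            index=pd.Index([], name="taxon_id"),
        ),
        latent_state=pd.DataFrame(latent, index=subjects,
                                  columns=[f"t{t:02d}" for t in range(1, n_tp + 1)]),
    )
    return taxa, panel, metadata, truth


def make_null_cohort(
    cfg: CohortConfig,
) -> tuple[AbundanceMatrix, MoodPanel, pd.DataFrame, CohortTruth]:
    """Same generative process with all planted loadings zeroed; the truth
    records an empty planted set. The panel's polarity structure (and the
    random stream layout) is unchanged, so null and signal cohorts differ
    only in the planted effect."""
    return generate_cohort(replace(cfg, effect_size=0.0))


def generate_metabolites(cfg: CohortConfig, taxa: AbundanceMatrix,
                         truth: CohortTruth) -> tuple[AbundanceMatrix, CohortTruth]:
    """Metabolite layer: one linked metabolite per planted taxon
    (``alpha * log2 relative abundance + noise`` on the log2 scale, sign
    recorded), remaining metabolites iid log-normal with the same noise sd.
    Returns the metabolite matrix and the truth updated with the links.
    """
    if truth.latent_state is None:
        raise ValueError("generate a cohort first")
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 7151]))
    n_samples = taxa.n_samples
    n_met = cfg.n_metabolites
    planted = truth.planted_ids
    if n_met < len(planted):
        raise ValueError("n_metabolites smaller than the planted set")
    met_ids = [f"met_{j:03d}" for j in range(n_met)]

    log2_met = rng.normal(0.0, cfg.metabolite_noise_sd, (n_samples, n_met))
    links = []
    for j, taxon in enumerate(planted):
        tax_log = np.log2(taxa.values[taxon].to_numpy(dtype=float))
        log2_met[:, j] += cfg.metabolite_alpha * tax_log
        links.append({"metabolite": met_ids[j], "taxon": taxon,
                      "sign": float(np.sign(cfg.metabolite_alpha) or 1.0)})
    values = pd.DataFrame(np.exp2(log2_met), index=taxa.values.index, columns=met_ids)
    matrix = AbundanceMatrix(values, mode="metabolite_peak", metadata=taxa.metadata)
    link_frame = pd.DataFrame(links, columns=["metabolite", "taxon", "sign"])
    updated = CohortTruth(planted=truth.planted, latent_state=truth.latent_state,
                          metabolite_links=link_frame.set_index("metabolite")
                          if len(link_frame) else link_frame)
    return matrix, updated
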