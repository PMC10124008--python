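"""Core in-memory containers shared across the pipeline.

All tabular data rides on :class:`pandas.DataFrame`; the dataclasses here add
the domain invariants (compositional bounds, polarity bookkeeping, sample
alignment) that a bare frame cannot express.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

# ---------------------------------------------------------------------------
# Mood-panel factor vocabulary
# ---------------------------------------------------------------------------

#: POMS: seven mood factors plus the Total Mood Disturbance composite.
POMS_FACTORS: tuple[str, ...] = (
    "Total mood disturbance",
    "Tension-anxiety",
    "Anger-hostility",
    "Fatigue-inertia",
    "Depression-dejection",
    "Confusion-bewilderment",
    "Vigour-activity",
    "Self-esteem",
)

#: SCL-90: ten symptom factors plus the SUM-SCL90 composite.
SCL_FACTORS: tuple[str, ...] = (
    "SUM-SCL90",
    "Somatization",
    "Obsessive-compulsive",
    "Interpersonal sensitivity",
    "Depression",
    "Anxiety",
    "Hostility",
    "Phobic anxiety",
    "Paranoid ideation",
    "Psychoticism",
    "Additional items",
)

#: The default 19-factor panel: 8 POMS + 11 SCL-90 columns.
DEFAULT_FACTORS: tuple[str, ...] = POMS_FACTORS + SCL_FACTORS

#: Factors scored in the positive direction (higher score = better mood);
#: everything else on the default panel is a symptom-burden (negative) scale.
DEFAULT_POSITIVE_FACTORS: tuple[str, ...] = ("Vigour-activity", "Self-esteem")

_DASHES = {"–": "-", "—": "-", "−": "-"}


def normalize_factor_name(name: str) -> str:
    """Canonical factor key: trimmed, case-folded, all dash variants unified.

    "Vigour–activity" (en dash) and "vigour-activity" map to the same key.
    """
    out = name.strip()
    for bad, good in _DASHES.items():
        out = out.replace(bad, good)
    return out.casefold()


def default_polarity_map() -> dict[str, str]:
    """Polarity for the default 19-factor panel (2 positive, 17 negative)."""
    positive = {normalize_factor_name(f) for f in DEFAULT_POSITIVE_FACTORS}
    return {
        f: ("positive" if normalize_factor_name(f) in positive else "negative")
        for f in DEFAULT_FACTORS
    }


# ---------------------------------------------------------------------------
# Sample metadata
# ---------------------------------------------------------------------------

METADATA_COLUMNS = ("subject_id", "gender", "timepoint")
GENDERS = ("female", "male")


def validate_metadata(metadata: pd.DataFrame) -> pd.DataFrame:
    """Validate a sample-metadata frame (index = sample_id).

    Requires unique sample ids, gender in {female, male}, integer timepoints
    strictly increasing within each subject (row order).
    """
    missing = [c for c in METADATA_COLUMNS if c not in metadata.columns]
    if missing:
        raise ValueError(f"metadata missing columns: {missing}")
    if metadata.index.duplicated().any():
        dup = metadata.index[metadata.index.duplicated()].tolist()
        raise ValueError(f"duplicate sample ids in metadata: {dup}")
    bad_gender = set(metadata["gender"]) - set(GENDERS)
    if bad_gender:
        raise ValueError(f"gender must be one of {GENDERS}; got {sorted(bad_gender)}")
    tp = pd.to_numeric(metadata["timepoint"], errors="raise")
    for subject, sub in metadata.assign(timepoint=tp).groupby("subject_id", sort=False):
        t = sub["timepoint"].to_numpy()
        if not np.all(np.diff(t) > 0):
            raise ValueError(
                f"timepoints not strictly increasing within subject {subject!r}"
            )
    return metadata


# ---------------------------------------------------------------------------
# Abundance matrix
# ---------------------------------------------------------------------------

ABUNDANCE_MODES = ("relative_abundance", "lfq_intensity", "metabolite_peak", "normalized")


@dataclass
class AbundanceMatrix:
    """A samples x features numeric matrix with optional per-sample metadata.

    ``mode`` states the measurement scale: relative abundance (compositional,
    each row sums to <= 1), LFQ intensity or metabolite peak area (both
    non-negative, 0 = not detected), or ``normalized`` (output of
    :func:`psychoscreen.preprocess.normalize`, unconstrained reals).
    """

    values: pd.DataFrame
    mode: str = "relative_abundance"
    metadata: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        if self.mode not in ABUNDANCE_MODES:
            raise ValueError(f"unknown mode {self.mode!r}; expected one of {ABUNDANCE_MODES}")
        if self.values.index.duplicated().any():
            raise ValueError("duplicate sample ids in abundance matrix")
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate feature ids in abundance matrix")
        vals = self.values.to_numpy(dtype=float)
        if not np.isfinite(vals).all():
            raise ValueError("abundance matrix contains non-finite values")
        if self.mode == "relative_abundance":
            if (vals < 0).any() or (vals > 1).any():
                raise ValueError("relative abundances must lie in [0, 1]")
            sums = vals.sum(axis=1)
            if (sums > 1 + 1e-6).any():
                bad = self.values.index[sums > 1 + 1e-6].tolist()
                raise ValueError(f"per-sample relative abundances exceed 1: {bad}")
        elif self.mode in ("lfq_intensity", "metabolite_peak"):
            if (vals < 0).any():
                raise ValueError(f"{self.mode} values must be non-negative")
        if self.metadata is not None:
            validate_metadata(self.metadata)
            missing = self.values.index.difference(self.metadata.index)
            if len(missing):
                raise ValueError(f"samples without metadata: {missing.tolist()}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def with_metadata(self, metadata: pd.DataFrame) -> "AbundanceMatrix":
        return AbundanceMatrix(self.values, self.mode, metadata)


# ---------------------------------------------------------------------------
# Mood panel
# ---------------------------------------------------------------------------

@dataclass
class MoodPanel:
    """Samples x factors mood scores with a positive/negative polarity tag."""

    scores: pd.DataFrame
    polarity: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.scores.index.duplicated().any():
            raise ValueError("duplicate sample ids in mood panel")
        if self.scores.columns.duplicated().any():
            raise ValueError("duplicate factor names in mood panel")
        pol = {normalize_factor_name(k): v for k, v in dict(self.polarity).items()}
        resolved: dict[str, str] = {}
        for factor in self.scores.columns:
            key = normalize_factor_name(factor)
            if key not in pol:
                raise ValueError(f"no polarity defined for factor {factor!r}")
            if pol[key] not in ("positive", "negative"):
                raise ValueError(f"polarity for {factor!r} must be positive/negative")
            resolved[factor] = pol[key]
        self.polarity = resolved

    @property
    def factor_names(self) -> list[str]:
        return list(self.scores.columns)

    @property
    def positive_factors(self) -> list[str]:
        return [f for f, p in self.polarity.items() if p == "positive"]

    @property
    def negative_factors(self) -> list[str]:
        return [f for f, p in self.polarity.items() if p == "negative"]

    @property
    def n_factors(self) -> int:
        return self.scores.shape[1]


# ---------------------------------------------------------------------------
# Screening result
# ---------------------------------------------------------------------------

SIGN_CLASSES = (
    "positive_mood_associated",
    "negative_mood_associated",
    "inconsistent",
    "none",
)


@dataclass
class ScreenResult:
    """Outcome of the two-stage VIP-vote + Spearman screen.

    ``features``: one row per screened feature with columns
    ``vip_votes, corr_votes, key, candidate, sign_class``.
    ``per_factor``: long table (feature, factor) with ``vip, spearman_r,
    spearman_p`` (Spearman entries are NaN for features that never reached
    stage 2). ``n_factors`` is the vote denominator actually used.
    """

    features: pd.DataFrame
    per_factor: pd.DataFrame
    n_factors: int
    votes_required: int

    def __post_init__(self) -> None:
        feat = self.features
        if ((feat["candidate"]) & (~feat["key"])).any():
            raise ValueError("candidate features must also be key features")
        if (feat["vip_votes"] > self.n_factors).any() or (
            feat["corr_votes"] > self.n_factors
        ).any():
            raise ValueError("votes cannot exceed the number of factors")
        bad = set(feat["sign_class"]) - set(SIGN_CLASSES)
        if bad:
            raise ValueError(f"unknown sign classes: {sorted(bad)}")
        if ((feat["sign_class"] != "none") & (~feat["candidate"])).any():
            raise ValueError("only candidates may carry a sign class")

    @property
    def key_features(self) -> list[str]:
        return list(self.features.index[self.features["key"]])

    @property
    def candidates(self) -> list[str]:
        return list(self.features.index[self.features["candidate"]])


# ---------------------------------------------------------------------------
# Synthetic-cohort ground truth
# ---------------------------------------------------------------------------

@dataclass
class CohortTruth:
    """Ground truth of a simulated cohort: which taxa were planted to track
    the latent mood state, with what loading sign, and the latent state
    itself (subjects x timepoints)."""

    planted: pd.DataFrame  # index taxon_id, column "sign" (+1 / -1 float loadings sign)
    latent_state: pd.DataFrame  # subjects x timepoints
    metabolite_links: Optional[pd.DataFrame] = None  # index metabolite_id, cols taxon_id, sign

    @property
    def planted_ids(self) -> list[str]:
        return list(self.planted.index)
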