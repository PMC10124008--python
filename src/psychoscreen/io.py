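"""TSV readers and writers for every table the pipeline consumes or emits.

Conventions: UTF-8 TSV with one header row, "." decimal, sample ids in the
first column. Reals are serialized with 17 significant digits so a
write-then-read round trip is exact to well below 1e-12.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .types import (
    AbundanceMatrix,
    MoodPanel,
    ScreenResult,
    default_polarity_map,
    normalize_factor_name,
    validate_metadata,
)

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.17g"


def _read_tsv(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    if frame.index.duplicated().any():
        dup = frame.index[frame.index.duplicated()].tolist()
        raise ValueError(f"{path}: duplicate row ids {dup}")
    if frame.columns.duplicated().any():
        dup = frame.columns[frame.columns.duplicated()].tolist()
        raise ValueError(f"{path}: duplicate column ids {dup}")
    return frame


def _require_numeric(frame: pd.DataFrame, path) -> pd.DataFrame:
    try:
        return frame.astype(float)
    except (TypeError, ValueError):
        for col in frame.columns:
            coerced = pd.to_numeric(frame[col], errors="coerce")
            bad = frame.index[coerced.isna() & frame[col].notna()]
            if len(bad):
                raise ValueError(
                    f"{path}: non-numeric value at row {bad[0]!r}, column {col!r}"
                ) from None
        raise


def write_tsv(frame: pd.DataFrame, path: str | Path, index_label: str = "sample_id") -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, sep="\t", float_format=_FLOAT_FMT, index_label=index_label)


def read_feature_table(
    path: str | Path,
    orientation: str = "samples_in_rows",
    mode: str = "relative_abundance",
    metadata: Optional[pd.DataFrame] = None,
) -> AbundanceMatrix:
    """Read a feature-abundance TSV into an :class:`AbundanceMatrix`.

    ``orientation`` says whether rows are samples or features; the returned
    matrix is always samples x features with the on-disk feature order
    preserved.
    """
    if orientation not in ("samples_in_rows", "samples_in_cols"):
        raise ValueError("orientation must be samples_in_rows or samples_in_cols")
    frame = _require_numeric(_read_tsv(path), path)
    if orientation == "samples_in_cols":
        frame = frame.T
    logger.info("read %s: %d samples x %d features (%s)", path, *frame.shape, mode)
    return AbundanceMatrix(frame, mode=mode, metadata=metadata)


def write_feature_table(matrix: AbundanceMatrix, path: str | Path) -> None:
    write_tsv(matrix.values, path)


def read_mood_panel(
    path: str | Path,
    polarity_map: Optional[Mapping[str, str]] = None,
) -> MoodPanel:
    """Read a mood-panel TSV (samples x factors).

    ``polarity_map`` maps factor name -> "positive"/"negative"; by default
    the standard 19-factor POMS + SCL-90 panel. Every factor in the map
    must be present (matched after name normalization); extra columns are
    an error only if they lack a polarity.
    """
    polarity_map = dict(polarity_map) if polarity_map is not None else default_polarity_map()
    frame = _require_numeric(_read_tsv(path), path)
    wanted = {normalize_factor_name(k): v for k, v in polarity_map.items()}
    present = {normalize_factor_name(c): c for c in frame.columns}
    missing = [k for k in wanted if k not in present]
    if missing:
        raise ValueError(f"{path}: missing mood factors: {sorted(missing)}")
    columns = [present[k] for k in wanted]
    scores = frame[columns]
    polarity = {present[k]: v for k, v in wanted.items()}
    logger.info("read %s: %d samples x %d factors", path, *scores.shape)
    return MoodPanel(scores, polarity)


def write_mood_panel(panel: MoodPanel, path: str | Path) -> None:
    write_tsv(panel.scores, path)


def read_sample_metadata(path: str | Path) -> pd.DataFrame:
    frame = _read_tsv(path)
    frame["timepoint"] = frame["timepoint"].astype(int)
    return validate_metadata(frame)


def write_sample_metadata(metadata: pd.DataFrame, path: str | Path) -> None:
    write_tsv(metadata, path)


# ---------------------------------------------------------------------------
# Screen result serialization
# ---------------------------------------------------------------------------

_FEATURES_FILE = "screen_features.tsv"
_LONG_FILE = "screen_factor_long.tsv"
_CANDIDATES_FILE = "screen_candidates.tsv"


def write_screen_report(result: ScreenResult, out_dir: str | Path) -> dict[str, Path]:
    """Write the screen surface as three TSVs under ``out_dir``:
    per-feature votes/flags, the (feature, factor) long table of VIP and
    Spearman statistics, and the candidate list with sign class."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "features": out / _FEATURES_FILE,
        "long": out / _LONG_FILE,
        "candidates": out / _CANDIDATES_FILE,
    }
    feat = result.features.copy()
    feat.insert(0, "n_factors", result.n_factors)
    feat.insert(1, "votes_required", result.votes_required)
    write_tsv(feat, paths["features"], index_label="feature")
    long = result.per_factor
    long.to_csv(paths["long"], sep="\t", float_format=_FLOAT_FMT, index=False)
    cand = result.features.loc[result.features["candidate"], ["sign_class"]]
    write_tsv(cand, paths["candidates"], index_label="feature")
    logger.info("wrote screen report to %s (%d features, %d candidates)",
                out, len(feat), len(cand))
    return paths


def read_screen_report(out_dir: str | Path) -> ScreenResult:
    out = Path(out_dir)
    feat = _read_tsv(out / _FEATURES_FILE)
    n_factors = int(feat["n_factors"].iloc[0])
    votes_required = int(feat["votes_required"].iloc[0])
    feat = feat.drop(columns=["n_factors", "votes_required"])
    feat["key"] = feat["key"].astype(bool)
    feat["candidate"] = feat["candidate"].astype(bool)
    feat["vip_votes"] = feat["vip_votes"].astype(int)
    feat["corr_votes"] = feat["corr_votes"].astype(int)
    feat.index = feat.index.astype(str)
    feat.index.name = "feature"
    long = pd.read_csv(out / _LONG_FILE, sep="\t",
                       dtype={"feature": str, "factor": str})
    return ScreenResult(features=feat, per_factor=long,
                        n_factors=n_factors, votes_required=votes_required)
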