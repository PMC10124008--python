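"""Normalization and filtering applied before any modelling step.

``normalize`` implements the log2 + quotient transform used throughout the
pipeline; ``prevalence_filter`` the per-group >0 detection rule for sparse
LFQ data; ``horizon_transform`` the median-centering / MAD-banding used to
display factor time series as horizon graphs.
"""

from __future__ import annotations

import logging
from typing import Hashable, Mapping, Sequence

import numpy as np
import pandas as pd

from .types import AbundanceMatrix

logger = logging.getLogger(__name__)

_MEAN_GUARD = 1e-12


def _resolve_pseudocount(values: np.ndarray, policy: str, value: float) -> float:
    if policy == "fixed":
        return float(value)
    if policy == "half_min_nonzero":
        nonzero = values[values > 0]
        if nonzero.size == 0:
            raise ValueError("matrix has no nonzero entries; cannot derive pseudocount")
        return float(nonzero.min() / 2.0)
    raise ValueError(f"unknown pseudocount policy {policy!r}")


def normalize(
    matrix: AbundanceMatrix,
    pseudocount_policy: str = "half_min_nonzero",
    pseudocount_value: float = 0.0,
    order: str = "log_then_quotient",
) -> AbundanceMatrix:
    """log2 + per-feature quotient normalization.

    With the default order, each feature column x is mapped to
    ``log2(x + c)`` and then divided by the magnitude of its across-sample
    mean log value (features whose mean log is ~0 are divided by 1).
    Dividing by the magnitude rather than the signed mean keeps each
    feature's orientation: on compositional data every mean log is negative
    and a signed quotient would invert all downstream correlation signs.

    ``order="quotient_then_log"`` instead divides each raw feature by its
    across-sample mean and then takes log2(. + c).

    Raises if any feature is all-zero (run ``prevalence_filter`` first) or
    if the result would be non-finite (e.g. zeros with pseudocount 0).
    """
    values = matrix.values.to_numpy(dtype=float)
    if (values < 0).any():
        raise ValueError("normalize requires a non-negative matrix")
    all_zero = ~(values > 0).any(axis=0)
    if all_zero.any():
        bad = [c for c, z in zip(matrix.values.columns, all_zero) if z]
        raise ValueError(
            f"all-zero features {bad[:5]}{'...' if len(bad) > 5 else ''}: "
            "apply prevalence_filter before normalize"
        )
    c = _resolve_pseudocount(values, pseudocount_policy, pseudocount_value)

    if order == "log_then_quotient":
        with np.errstate(divide="ignore"):
            logs = np.log2(values + c)
        if not np.isfinite(logs).all():
            raise ValueError(
                "log2 produced non-finite values; zeros present with pseudocount 0"
            )
        means = logs.mean(axis=0)
        denom = np.where(np.abs(means) > _MEAN_GUARD, np.abs(means), 1.0)
        out = logs / denom
    elif order == "quotient_then_log":
        means = values.mean(axis=0)
        denom = np.where(np.abs(means) > _MEAN_GUARD, means, 1.0)
        with np.errstate(divide="ignore"):
            out = np.log2(values / denom + c)
        if not np.isfinite(out).all():
            raise ValueError(
                "log2 produced non-finite values; zeros present with pseudocount 0"
            )
    else:
        raise ValueError("order must be 'log_then_quotient' or 'quotient_then_log'")

    frame = pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns)
    return AbundanceMatrix(frame, mode="normalized", metadata=matrix.metadata)


def prevalence_filter(
    matrix: AbundanceMatrix,
    groups: Mapping[Hashable, Hashable] | pd.Series,
    min_fraction: float = 0.5,
) -> tuple[AbundanceMatrix, list[str], list[str]]:
    """Keep a feature iff, in EVERY group, it is detected (> 0) in at least
    ``min_fraction`` of that group's samples.

    ``groups`` maps sample id -> group label (e.g. subject or crew group).
    Returns (filtered matrix, kept feature ids, dropped feature ids).
    """
    if not (0.0 < min_fraction <= 1.0):
        raise ValueError("min_fraction must lie in (0, 1]")
    groups = pd.Series(groups)
    missing = matrix.values.index.difference(groups.index)
    if len(missing):
        raise ValueError(f"samples without a group assignment: {missing.tolist()}")
    labels = groups.loc[matrix.values.index]
    detected = matrix.values > 0
    keep = pd.Series(True, index=matrix.values.columns)
    for label, idx in detected.groupby(labels.to_numpy()).groups.items():
        sub = detected.loc[idx]
        if sub.shape[0] == 0:
            raise ValueError(f"empty group {label!r}")
        keep &= sub.mean(axis=0) >= min_fraction
    kept = [c for c in matrix.values.columns if keep[c]]
    dropped = [c for c in matrix.values.columns if not keep[c]]
    logger.info(
        "prevalence_filter: %d features in, %d kept, %d dropped (min_fraction=%.2f)",
        matrix.n_features, len(kept), len(dropped), min_fraction,
    )
    filtered = AbundanceMatrix(matrix.values[kept], matrix.mode, matrix.metadata)
    return filtered, kept, dropped


def horizon_transform(series: Sequence[float] | pd.Series) -> tuple[np.ndarray, float]:
    """Median-center a factor time series and return its MAD band width.

    Returns ``(series - median, median(|series - median|))`` — the transform
    behind horizon-graph displays of mood trajectories.
    """
    arr = np.asarray(series, dtype=float)
    if arr.ndim != 1:
        raise ValueError("horizon_transform expects a 1-D series")
    if arr.size < 2:
        raise ValueError("series must have length >= 2")
    centered = arr - np.median(arr)
    band_width = float(np.median(np.abs(centered)))
    return centered, band_width
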