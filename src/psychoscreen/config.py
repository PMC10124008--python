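"""Run configuration: the screening thresholds and their documented defaults.

Defaults encode the published selection rule: VIP >= 1 in more than 50% of
the psychological factors, then |R| >= 0.5 (0.35 for protein-group data) with
P < 0.001 in more than 50% of the factors.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Sequence

import yaml

from .types import DEFAULT_POSITIVE_FACTORS


@dataclass
class RunConfig:
    vip_threshold: float = 1.0
    r_threshold: float = 0.5  # 0.35 for protein-group (LFQ) screening
    p_threshold: float = 0.001
    factor_vote_fraction: float = 0.5  # "more than 50%", strictly
    sign_alpha: float = 0.05
    max_components: int = 10
    pseudocount_policy: str = "half_min_nonzero"  # or "fixed"
    pseudocount_value: float = 0.0  # used when policy == "fixed"
    scale: bool = True  # autoscale predictors inside PLS
    normalize_mood: bool = False  # log2+quotient normalize mood scores before PLS
    seed: int = 0
    positive_factors: tuple[str, ...] = DEFAULT_POSITIVE_FACTORS

    def __post_init__(self) -> None:
        if not (0.0 < self.factor_vote_fraction < 1.0):
            raise ValueError("factor_vote_fraction must lie strictly in (0, 1)")
        for name in ("vip_threshold", "r_threshold", "p_threshold", "sign_alpha"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.max_components < 1:
            raise ValueError("max_components must be >= 1")
        if self.pseudocount_policy not in ("half_min_nonzero", "fixed"):
            raise ValueError("pseudocount_policy must be 'half_min_nonzero' or 'fixed'")
        self.positive_factors = tuple(self.positive_factors)

    def votes_required(self, n_factors: int) -> int:
        """Smallest vote count that is *strictly* more than
        ``factor_vote_fraction`` of ``n_factors`` (10 of 19 at defaults)."""
        import math

        return math.floor(n_factors * self.factor_vote_fraction) + 1

    def with_overrides(self, **kwargs) -> "RunConfig":
        return replace(self, **kwargs)


def load_config(path: str | Path) -> RunConfig:
    """Read a flat key:value YAML document into a :class:`RunConfig`."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config file {path} must be a flat mapping")
    known = {f.name for f in fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "positive_factors" in raw and isinstance(raw["positive_factors"], list):
        raw["positive_factors"] = tuple(raw["positive_factors"])
    return RunConfig(**raw)


def save_config(cfg: RunConfig, path: str | Path) -> None:
    data = {
        f.name: (list(v) if isinstance(v := getattr(cfg, f.name), tuple) else v)
        for f in fields(RunConfig)
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
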