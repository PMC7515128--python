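"""Bayes-rule combination of the two branch scores.

Each branch was trained on class-balanced data, so its output is read as a
posterior under a 0.5 prior. Assuming branch independence, the combined
posterior odds are the product of per-branch odds times the prior odds:

    odds = (pi/(1-pi)) * (o1/(1-o1)) * (o2/(1-o2)),  fused = odds/(1+odds)

which at pi = 0.5 reduces to o1*o2 / (o1*o2 + (1-o1)(1-o2)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError

CLIP_EPS = 1e-7


@dataclass(frozen=True)
class FusionConfig:
    prior: float = 0.5
    threshold: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 < self.prior < 1.0):
            raise ConfigurationError("fusion prior must be in (0, 1)")
        if not (0.0 < self.threshold < 1.0):
            raise ConfigurationError("call threshold must be in (0, 1)")


def fuse(o1, o2, config: FusionConfig | None = None) -> np.ndarray | float:
    """Combine two branch scores into one posterior. Symmetric in (o1, o2)."""
    config = config or FusionConfig()
    scalar = np.isscalar(o1) and np.isscalar(o2)
    o1 = np.clip(np.asarray(o1, dtype=float), CLIP_EPS, 1.0 - CLIP_EPS)
    o2 = np.clip(np.asarray(o2, dtype=float), CLIP_EPS, 1.0 - CLIP_EPS)
    log_odds = (np.log(config.prior) - np.log1p(-config.prior)
                + np.log(o1) - np.log1p(-o1)
                + np.log(o2) - np.log1p(-o2))
    fused = 1.0 / (1.0 + np.exp(-log_odds))
    return float(fused) if scalar else fused


def call(scores, threshold: float = 0.5) -> np.ndarray:
    """Binary calls: 1 where score >= threshold."""
    return (np.asarray(scores, dtype=float) >= threshold).astype(np.int8)
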