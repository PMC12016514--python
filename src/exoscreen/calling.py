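"""Target-gene calling: window mean versus 2.5x the all-gene background.

A gene is called a target of a TF in a condition when its TSS-window mean
signal strictly exceeds ``threshold_factor`` times the background, where
the background is the unweighted mean of the window means over *all*
annotated genes (targets included).  The universe of genes is whatever
the annotation file provides; nothing is hard-coded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import pandas as pd

from .windows import WindowProfile, WindowSpec

__all__ = [
    "CallParameters",
    "TargetCallResult",
    "compute_background",
    "call_targets",
    "mean_reads_per_target",
]


@dataclass(frozen=True)
class CallParameters:
    """Threshold factor over background (default 2.5) and window extent."""

    threshold_factor: float = 2.5
    window: WindowSpec = field(default_factory=WindowSpec)

    def __post_init__(self) -> None:
        if self.threshold_factor <= 0:
            raise ValueError("threshold_factor must be positive")


@dataclass
class TargetCallResult:
    tf: str
    condition: str
    per_gene_mean: dict[str, float]
    background: float
    threshold_factor: float
    threshold: float
    targets: set[str]
    mean_reads_per_target: Optional[float]

    def to_frame(self) -> pd.DataFrame:
        """Per-gene table: window mean, background, threshold, is_target."""
        rows = [
            (g, m, self.background, self.threshold, g in self.targets)
            for g, m in sorted(self.per_gene_mean.items())
        ]
        return pd.DataFrame(
            rows, columns=["gene_id", "window_mean", "background", "threshold", "is_target"]
        )


def compute_background(per_gene_mean: Mapping[str, float]) -> float:
    """Unweighted mean of window means over all annotated genes."""
    if not per_gene_mean:
        raise ValueError("cannot compute background from an empty gene set")
    return float(sum(per_gene_mean.values()) / len(per_gene_mean))


def call_targets(
    profiles: Iterable[WindowProfile],
    params: CallParameters | None = None,
    tf: str = "",
    condition: str = "",
) -> TargetCallResult:
    """Call targets from per-gene window profiles.

    Strict inequality: a gene is a target iff its window mean is
    ``> threshold_factor * background``.  With an all-zero track the rule
    is applied literally (every positive mean would pass ``> 0``) and a
    degenerate-input warning is emitted.
    """
    params = params or CallParameters()
    profiles = list(profiles)
    if not profiles:
        raise ValueError("call_targets needs at least one profile")
    per_gene_mean = {p.gene_id: p.window_mean for p in profiles}
    if len(per_gene_mean) != len(profiles):
        raise ValueError("duplicate gene_id among profiles")
    background = compute_background(per_gene_mean)
    if background == 0:
        warnings.warn(
            "background is zero: every gene with positive signal will be called",
            RuntimeWarning,
            stacklevel=2,
        )
    threshold = params.threshold_factor * background
    targets = {g for g, m in per_gene_mean.items() if m > threshold}
    mrpt = (
        float(sum(per_gene_mean[g] for g in targets) / len(targets)) if targets else None
    )
    return TargetCallResult(
        tf=tf,
        condition=condition,
        per_gene_mean=per_gene_mean,
        background=background,
        threshold_factor=params.threshold_factor,
        threshold=threshold,
        targets=targets,
        mean_reads_per_target=mrpt,
    )


def mean_reads_per_target(result: TargetCallResult) -> float:
    """Mean window signal over the called targets only.

    Exceeds the background whenever ``threshold_factor >= 1`` and targets
    exist; raises ``ValueError`` when the target set is empty, where the
    statistic is undefined.
    """
    if not result.targets:
        raise ValueError("mean reads per target is undefined for an empty target set")
    return float(sum(result.per_gene_mean[g] for g in result.targets) / len(result.targets))
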