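"""Set algebra over target sets: condition contrasts and cross-TF overlap."""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import AbstractSet, Optional

__all__ = [
    "ConditionComparison",
    "CrossTFComparison",
    "compare_conditions",
    "fold_increase",
    "cross_tf_overlap",
    "annotate_known",
]


def _round_half_away(x: float, decimals: int = 1) -> float:
    """Round half away from zero (reporting convention for fold changes)."""
    factor = 10**decimals
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


@dataclass
class ConditionComparison:
    """Partition of one TF's targets across a control/stress pair."""

    set_control: frozenset[str]
    set_stress: frozenset[str]
    shared: frozenset[str]
    control_only: frozenset[str]
    stress_only: frozenset[str]
    fold_increase: Optional[float]  # rounded to 1 decimal; None when n_control == 0
    raw_ratio: Optional[float]

    @property
    def n_control(self) -> int:
        return len(self.set_control)

    @property
    def n_stress(self) -> int:
        return len(self.set_stress)

    def counts(self) -> dict[str, int]:
        return {
            "n_control": self.n_control,
            "n_stress": self.n_stress,
            "shared": len(self.shared),
            "control_only": len(self.control_only),
            "stress_only": len(self.stress_only),
        }


def compare_conditions(
    set_control: AbstractSet[str], set_stress: AbstractSet[str]
) -> ConditionComparison:
    control = frozenset(set_control)
    stress = frozenset(set_stress)
    shared = control & stress
    ratio = len(stress) / len(control) if control else None
    return ConditionComparison(
        set_control=control,
        set_stress=stress,
        shared=shared,
        control_only=control - stress,
        stress_only=stress - control,
        fold_increase=_round_half_away(ratio) if ratio is not None else None,
        raw_ratio=ratio,
    )


def fold_increase(n_control: int, n_stress: int) -> float:
    """Stress/control target-count ratio, rounded half-away-from-zero to 1 dp."""
    if n_control <= 0:
        raise ValueError("fold increase is undefined when the control count is zero")
    return _round_half_away(n_stress / n_control)


@dataclass
class CrossTFComparison:
    """Overlap of two TFs' target sets across two media."""

    both_tfs_stress: frozenset[str]
    both_tfs_control: frozenset[str]
    both_tfs_both_media: frozenset[str]
    both_tfs_stress_only: frozenset[str]

    def counts(self) -> dict[str, int]:
        return {
            "both_tfs_stress": len(self.both_tfs_stress),
            "both_tfs_control": len(self.both_tfs_control),
            "both_tfs_both_media": len(self.both_tfs_both_media),
            "both_tfs_stress_only": len(self.both_tfs_stress_only),
        }


def cross_tf_overlap(
    tf1_control: AbstractSet[str],
    tf1_stress: AbstractSet[str],
    tf2_control: AbstractSet[str],
    tf2_stress: AbstractSet[str],
) -> CrossTFComparison:
    """Two-TF overlap: shared targets per medium, in both media, stress-exclusive.

    ``both_tfs_stress_only`` removes genes targeted by *either* TF in the
    control medium from the stress-shared set.
    """
    both_stress = frozenset(tf1_stress) & frozenset(tf2_stress)
    both_control = frozenset(tf1_control) & frozenset(tf2_control)
    return CrossTFComparison(
        both_tfs_stress=both_stress,
        both_tfs_control=both_control,
        both_tfs_both_media=both_stress & both_control,
        both_tfs_stress_only=both_stress - (frozenset(tf1_control) | frozenset(tf2_control)),
    )


def annotate_known(
    targets: AbstractSet[str], known: AbstractSet[str]
) -> tuple[int, float]:
    """How many called targets are in a user-supplied known-target table."""
    targets = frozenset(targets)
    count = len(targets & frozenset(known))
    fraction = count / len(targets) if targets else 0.0
    return count, fraction
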