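"""Strand-oriented TSS windows and metagene aggregation.

The binding statistic of the pipeline is the mean per-base signal in a
window around each gene's TSS (default 1,000 bp upstream to 1,000 bp
downstream, both endpoints and the TSS included, 2,001 positions).
Windows are read 5'->3' in the gene's own orientation, so position
``-250`` always means 250 bp upstream of the TSS regardless of strand.
Positions that fall off a chromosome end are clipped and excluded from
the mean rather than zero-padded, which would deflate telomeric genes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .annotation import GeneAnnotation
from .signal import SignalTrack

__all__ = ["WindowSpec", "WindowProfile", "extract_window", "metagene_profile"]


@dataclass(frozen=True)
class WindowSpec:
    """Window extent in bp on either side of the TSS (gene orientation)."""

    upstream_bp: int = 1000
    downstream_bp: int = 1000

    def __post_init__(self) -> None:
        if self.upstream_bp < 0 or self.downstream_bp < 0:
            raise ValueError("window extents must be non-negative")
        if self.upstream_bp == 0 and self.downstream_bp == 0:
            raise ValueError("window cannot be empty")

    @property
    def length(self) -> int:
        return self.upstream_bp + self.downstream_bp + 1

    def offsets(self) -> np.ndarray:
        """Relative positions -upstream..downstream (0 = TSS)."""
        return np.arange(-self.upstream_bp, self.downstream_bp + 1)


@dataclass
class WindowProfile:
    """Signal over one gene's TSS window, after chromosome-end clipping.

    ``values[i]`` is the signal at relative position ``offsets[i]``;
    ``window_mean`` is the arithmetic mean over the covered positions.
    """

    gene_id: str
    offsets: np.ndarray
    values: np.ndarray
    window_mean: float


def extract_window(track: SignalTrack, gene: GeneAnnotation, spec: WindowSpec) -> WindowProfile:
    """Extract the per-base window profile for one gene.

    For ``-`` strand genes the genomic slice is reversed so that the
    profile runs 5'->3' relative to the gene.  Raises ``KeyError`` if the
    gene's chromosome is absent from the track.
    """
    if gene.chrom not in track.counts:
        raise KeyError(f"chromosome {gene.chrom!r} absent from signal track")
    vec = track.counts[gene.chrom]
    tss0 = gene.tss - 1  # to 0-based
    rel = spec.offsets()
    genomic = tss0 + rel if gene.strand == "+" else tss0 - rel
    keep = (genomic >= 0) & (genomic < len(vec))
    offsets = rel[keep]
    values = vec[genomic[keep]]
    if len(values) == 0:
        raise ValueError(f"{gene.gene_id}: window entirely outside chromosome")
    return WindowProfile(
        gene_id=gene.gene_id,
        offsets=offsets,
        values=values,
        window_mean=float(values.mean()),
    )


def extract_all_windows(
    track: SignalTrack, genes: Sequence[GeneAnnotation], spec: WindowSpec
) -> list[WindowProfile]:
    return [extract_window(track, g, spec) for g in genes]


def metagene_profile(profiles: Iterable[WindowProfile], spec: WindowSpec) -> np.ndarray:
    """Position-wise mean of window profiles across genes.

    Clipped positions are excluded position-wise: a relative position
    contributes only the genes that actually cover it.  Positions covered
    by no gene are NaN.  Raises ``ValueError`` on empty input.
    """
    profiles = list(profiles)
    if not profiles:
        raise ValueError("metagene_profile needs at least one profile")
    total = np.zeros(spec.length)
    n = np.zeros(spec.length)
    for p in profiles:
        idx = p.offsets + spec.upstream_bp
        total[idx] += p.values
        n[idx] += 1
    with np.errstate(invalid="ignore"):
        return np.where(n > 0, total / np.maximum(n, 1), np.nan)
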