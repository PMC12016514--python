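"""Per-base binding-signal tracks for one TF in one condition.

ChIP-exo coverage arrives as bedGraph (0-based, half-open intervals).  A
:class:`SignalTrack` holds one dense non-negative vector per chromosome;
uncovered bases are zero.  Overlapping bedGraph intervals are rejected
rather than summed: the dialect is ambiguous and silent guessing hides
upstream errors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = ["SignalTrack", "read_signal_track", "average_tracks"]


@dataclass
class SignalTrack:
    """Dense per-base counts (non-negative reals) keyed by chromosome."""

    tf: str = ""
    condition: str = ""
    counts: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for chrom, vec in self.counts.items():
            vec = np.asarray(vec, dtype=float)
            if (vec < 0).any():
                raise ValueError(f"negative counts on {chrom}")
            self.counts[chrom] = vec

    def chrom_length(self, chrom: str) -> int:
        return len(self.counts[chrom])


def read_signal_track(
    path: str,
    chrom_sizes: Mapping[str, int],
    tf: str = "",
    condition: str = "",
) -> SignalTrack:
    """Expand a bedGraph file into a dense per-base :class:`SignalTrack`.

    Intervals are 0-based half-open per the bedGraph standard.  Intervals
    beyond the chromosome end, negative values, unknown chromosomes and
    overlapping intervals all raise ``ValueError``.
    """
    counts = {chrom: np.zeros(int(size), dtype=float) for chrom, size in chrom_sizes.items()}
    try:
        df = pd.read_csv(
            path,
            sep=r"\s+",
            header=None,
            comment="#",
            names=["chrom", "start", "end", "value"],
            dtype={"chrom": str},
        )
    except pd.errors.EmptyDataError:
        return SignalTrack(tf=tf, condition=condition, counts=counts)
    df = df[~df["chrom"].str.startswith("track")]
    covered = {chrom: np.zeros(int(size), dtype=bool) for chrom, size in chrom_sizes.items()}
    for chrom, start, end, value in df.itertuples(index=False):
        if chrom not in counts:
            raise ValueError(f"{path}: unknown chromosome {chrom!r}")
        start, end, value = int(start), int(end), float(value)
        if value < 0:
            raise ValueError(f"{path}: negative value {value} at {chrom}:{start}-{end}")
        if start < 0 or end > len(counts[chrom]) or start >= end:
            raise ValueError(f"{path}: interval {chrom}:{start}-{end} outside chromosome bounds")
        if covered[chrom][start:end].any():
            raise ValueError(f"{path}: overlapping bedGraph intervals at {chrom}:{start}-{end}")
        covered[chrom][start:end] = True
        counts[chrom][start:end] = value
    return SignalTrack(tf=tf, condition=condition, counts=counts)


def average_tracks(tracks: Iterable[SignalTrack]) -> SignalTrack:
    """Base-wise mean of replicate tracks (same TF x condition)."""
    tracks = list(tracks)
    if not tracks:
        raise ValueError("no tracks to average")
    first = tracks[0]
    for t in tracks[1:]:
        if set(t.counts) != set(first.counts):
            raise ValueError("replicate tracks cover different chromosomes")
        for chrom in first.counts:
            if len(t.counts[chrom]) != len(first.counts[chrom]):
                raise ValueError(f"replicate tracks disagree on length of {chrom}")
    counts = {
        chrom: np.mean([t.counts[chrom] for t in tracks], axis=0) for chrom in first.counts
    }
    return SignalTrack(tf=first.tf, condition=first.condition, counts=counts)


def write_bedgraph(track: SignalTrack, path: str) -> None:
    """Write a track as bedGraph, merging constant runs; zeros are omitted."""
    with open(path, "w") as fh:
        for chrom in sorted(track.counts):
            vec = track.counts[chrom]
            if len(vec) == 0:
                continue
            # boundaries where the value changes
            change = np.flatnonzero(np.diff(vec) != 0) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [len(vec)]))
            for s, e in zip(starts, ends):
                v = vec[s]
                if v != 0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")
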