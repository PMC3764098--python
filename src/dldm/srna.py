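"""Strand-specific small-RNA window densities.

Mapped small-RNA reads (collapsed, with multiplicities) are tallied into
100-nt non-overlapping windows per strand of each chromosome. Before
cross-library comparison, reads whose 5' ends fall in rDNA intervals are
removed (ribosomal degradation products dominate raw counts), and each
library is rescaled to a common size — by default the smallest filtered
library.

Window assignment is by the read's 5' end: `start` for a plus-strand read,
`start + length - 1` for a minus-strand read. With 20–25-nt reads in 100-nt
windows this is unambiguous; no fractional-overlap splitting is attempted.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

__all__ = [
    "MappedRead",
    "WindowTrack",
    "five_prime_end",
    "merge_intervals",
    "filter_rdna",
    "compute_scaling",
    "window_counts",
    "normalize",
]


@dataclass(frozen=True)
class MappedRead:
    """One collapsed mapped small-RNA read.

    ``count`` is the collapsed multiplicity (identical reads mapped to the
    same position); it is taken at face value, with no multimapper weighting.
    """

    chrom: str
    start: int  # 0-based leftmost mapped position
    length: int
    strand: str  # '+' or '-'
    count: int = 1

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"read start must be >= 0, got {self.start}")
        if self.length < 1:
            raise ValueError(f"read length must be >= 1, got {self.length}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.count < 1:
            raise ValueError(f"count must be >= 1, got {self.count}")


def five_prime_end(read: MappedRead) -> int:
    """0-based genomic position of the read's 5' end."""
    return read.start if read.strand == "+" else read.start + read.length - 1


@dataclass
class WindowTrack:
    """Per-(chromosome, strand) window counts with a library scaling factor.

    ``raw`` maps window start (a multiple of ``window_size``) to the summed
    read multiplicity; ``factor`` is the cumulative library-size scaling, so
    the scaled density of a window is ``raw * factor``. Raw counts are never
    overwritten by normalization.
    """

    chrom: str
    strand: str
    window_size: int = 100
    raw: dict[int, int] = field(default_factory=dict)
    factor: float = 1.0
    library_label: str = ""

    def density(self, window_start: int) -> float:
        return self.raw.get(window_start, 0) * self.factor

    def densities(self) -> dict[int, float]:
        return {w: c * self.factor for w, c in self.raw.items()}

    def total_raw(self) -> int:
        return sum(self.raw.values())


def merge_intervals(intervals: Iterable[tuple]) -> dict[str, tuple[list[int], list[int]]]:
    """Merge per-chromosome 0-based half-open intervals into sorted disjoint
    (starts, ends) lists for fast containment lookup."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        chrom, start, end = iv[0], int(iv[1]), int(iv[2])
        if start >= end:
            raise ValueError(f"empty interval {chrom}:{start}-{end}")
        by_chrom.setdefault(chrom, []).append((start, end))
    merged: dict[str, tuple[list[int], list[int]]] = {}
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        out: list[list[int]] = []
        for s, e in ivs:
            if out and s <= out[-1][1]:
                out[-1][1] = max(out[-1][1], e)
            else:
                out.append([s, e])
        merged[chrom] = ([s for s, _ in out], [e for _, e in out])
    return merged


def _in_intervals(pos: int, starts: list[int], ends: list[int]) -> bool:
    i = bisect.bisect_right(starts, pos) - 1
    return i >= 0 and pos < ends[i]


def filter_rdna(
    reads: Sequence[MappedRead], rdna_intervals: Iterable[tuple]
) -> tuple[list[MappedRead], int]:
    """Drop reads whose 5' end lies in an rDNA interval (strand-agnostic).

    Returns the kept reads (multiplicities untouched) and the total removed
    multiplicity.
    """
    merged = merge_intervals(rdna_intervals)
    kept: list[MappedRead] = []
    removed = 0
    for read in reads:
        iv = merged.get(read.chrom)
        if iv is not None and _in_intervals(five_prime_end(read), *iv):
            removed += read.count
        else:
            kept.append(read)
    return kept, removed


def compute_scaling(
    filtered_totals: Mapping[str, float], target_size: float | None = None
) -> dict[str, float]:
    """Per-library scaling factors bringing filtered totals to a common size.

    ``target_size`` defaults to the smallest filtered library, so the
    smallest library gets factor 1.0 and larger ones are scaled down.
    """
    if not filtered_totals:
        raise ValueError("no libraries given")
    for label, total in filtered_totals.items():
        if total <= 0:
            raise ValueError(f"library {label!r} has non-positive filtered total {total}")
    if target_size is None:
        target_size = min(filtered_totals.values())
    return {label: target_size / total for label, total in filtered_totals.items()}


def window_counts(
    reads: Sequence[MappedRead], window: int = 100, library_label: str = ""
) -> dict[tuple[str, str], WindowTrack]:
    """Tally read multiplicities into non-overlapping windows by 5' end.

    Each read lands in exactly one window per its 5'-end position, so window
    counts conserve total read mass per (chromosome, strand).
    """
    if window < 1:
        raise ValueError(f"window must be >= 1, got {window}")
    tracks: dict[tuple[str, str], WindowTrack] = {}
    for read in reads:
        key = (read.chrom, read.strand)
        track = tracks.get(key)
        if track is None:
            track = tracks[key] = WindowTrack(
                chrom=read.chrom,
                strand=read.strand,
                window_size=window,
                library_label=library_label,
            )
        w = (five_prime_end(read) // window) * window
        track.raw[w] = track.raw.get(w, 0) + read.count
    return tracks


def normalize(track: WindowTrack, factor: float) -> WindowTrack:
    """Apply a library scaling factor; raw counts are retained and factors
    compose multiplicatively."""
    if factor <= 0:
        raise ValueError(f"scaling factor must be positive, got {factor}")
    return replace(track, raw=dict(track.raw), factor=track.factor * factor)
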