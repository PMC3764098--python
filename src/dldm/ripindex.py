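"""Sliding-window RIP-index scan.

Repeat-induced point mutation (RIP) converts C to T preferentially at CpA
dinucleotides, on both strands, leaving duplicated fungal DNA depleted of
CpA/TpG relative to ApC/GpT. The RIP index of a window is

    (n_CpA + n_TpG) / (n_ApC + n_GpT)

computed over overlapping dinucleotides; values below 0.7 mark RIP'd DNA,
while unmutated sequence sits near 1. The scanner uses a 500-bp window
sliding every 100 bp by default and operates on the given (top) strand only
— the index is not strand-symmetric in general.

Windows whose denominator is zero get an undefined (NaN) index; they are
flagged and excluded from summaries, never treated as 0.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import product

import numpy as np

__all__ = [
    "RipWindow",
    "RipScanResult",
    "count_dinucleotides",
    "rip_index_value",
    "scan",
    "classify_windows",
    "merge_ripd_segments",
    "locus_stats",
]

DEFAULT_WINDOW = 500
DEFAULT_STEP = 100
DEFAULT_THRESHOLD = 0.7

_DINUCS = ["".join(p) for p in product("ACGT", repeat=2)]


@dataclass(frozen=True)
class RipWindow:
    chrom: str
    start: int
    end: int
    n_CpA: int
    n_TpG: int
    n_ApC: int
    n_GpT: int
    index: float  # NaN when the denominator is zero

    @property
    def defined(self) -> bool:
        return not math.isnan(self.index)


@dataclass
class RipScanResult:
    chrom: str
    window_size: int
    step: int
    windows: list[RipWindow] = field(default_factory=list)


def count_dinucleotides(seq: str) -> dict[str, int]:
    """Counts of the 16 overlapping dinucleotides; pairs containing a
    non-ACGT base (e.g. N) are skipped entirely."""
    counts = dict.fromkeys(_DINUCS, 0)
    seq = seq.upper()
    for i in range(len(seq) - 1):
        pair = seq[i : i + 2]
        if pair in counts:
            counts[pair] += 1
    return counts


def rip_index_value(counts: dict[str, int]) -> float:
    """(CpA + TpG) / (ApC + GpT); NaN when the denominator is zero."""
    denom = counts["AC"] + counts["GT"]
    if denom == 0:
        return math.nan
    return (counts["CA"] + counts["TG"]) / denom


def scan(
    sequence: str,
    window: int = DEFAULT_WINDOW,
    step: int = DEFAULT_STEP,
    chrom: str = "seq",
) -> RipScanResult:
    """Slide a fixed-size window along the top strand and index each one.

    Windows start at 0, step, 2*step, ...; only full-length windows are
    emitted (a trailing partial window is dropped so all indices are
    comparable at the same window size).
    """
    if window < 2:
        raise ValueError(f"window must be >= 2, got {window}")
    if step < 1:
        raise ValueError(f"step must be >= 1, got {step}")
    result = RipScanResult(chrom=chrom, window_size=window, step=step)
    if len(sequence) < window:
        warnings.warn(
            f"sequence {chrom!r} ({len(sequence)} bp) shorter than window "
            f"({window} bp); empty scan",
            stacklevel=2,
        )
        return result
    for start in range(0, len(sequence) - window + 1, step):
        counts = count_dinucleotides(sequence[start : start + window])
        result.windows.append(
            RipWindow(
                chrom=chrom,
                start=start,
                end=start + window,
                n_CpA=counts["CA"],
                n_TpG=counts["TG"],
                n_ApC=counts["AC"],
                n_GpT=counts["GT"],
                index=rip_index_value(counts),
            )
        )
    return result


def classify_windows(
    result: RipScanResult, threshold: float = DEFAULT_THRESHOLD
) -> list[str]:
    """Label each window 'ripd' (index strictly below threshold), 'normal'
    (at or above), or 'undefined' (NaN index). A window exactly at the
    threshold is 'normal': RIP'd DNA lies below the line."""
    labels = []
    for w in result.windows:
        if not w.defined:
            labels.append("undefined")
        elif w.index < threshold:
            labels.append("ripd")
        else:
            labels.append("normal")
    return labels


def merge_ripd_segments(
    result: RipScanResult, threshold: float = DEFAULT_THRESHOLD
) -> list[tuple[str, int, int]]:
    """Merge overlapping/adjacent 'ripd' windows into maximal segments."""
    labels = classify_windows(result, threshold)
    segments: list[list] = []
    for w, lab in zip(result.windows, labels):
        if lab != "ripd":
            continue
        if segments and w.start <= segments[-1][2]:
            segments[-1][2] = max(segments[-1][2], w.end)
        else:
            segments.append([w.chrom, w.start, w.end])
    return [tuple(s) for s in segments]


def locus_stats(result: RipScanResult, interval: tuple[int, int]) -> dict:
    """Mean / sd / min of defined indices over windows overlapping a locus.

    Returns a dict with mean, sd (population, so a single window gives 0),
    min, n_windows and n_undefined; all-NaN loci come back flagged with
    ``defined=False`` rather than raising.
    """
    start, end = interval
    overlapping = [w for w in result.windows if w.start < end and w.end > start]
    values = np.array([w.index for w in overlapping if w.defined])
    n_undef = sum(1 for w in overlapping if not w.defined)
    if values.size == 0:
        return {
            "defined": False,
            "mean": math.nan,
            "sd": math.nan,
            "min": math.nan,
            "n_windows": len(overlapping),
            "n_undefined": n_undef,
        }
    return {
        "defined": True,
        "mean": float(values.mean()),
        "sd": float(values.std(ddof=0)),
        "min": float(values.min()),
        "n_windows": len(overlapping),
        "n_undefined": n_undef,
    }
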