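"""Per-clone bisulfite methylation calling and clone classification.

A sequenced clone is compared base-by-base against its reference amplicon
(bisulfite conversion is length-preserving, so no gapped alignment is
attempted — indels are rejected, keeping calls positionally exact). At each
reference cytosine, a clone C means the cytosine resisted conversion
(methylated), a clone T means it converted, and any other base is an
ambiguous sequencing artifact, excluded from every rate's numerator and
denominator.

Two clone-classification strategies mirror a restriction-protection readout
on post-bisulfite PCR products:

* Strategy 1 digests the PCR product of each subcloned fragment with DpnII.
  A GATC site survives bisulfite as "GATC" only if its C was methylated
  (5mC resists conversion), so a digestible ("cut") clone carried 5mC at a
  recognition site; an undigestible clone reads "GATT" everywhere.
* Strategy 2 digests genomic DNA with BfuCI *before* bisulfite treatment,
  destroying alleles with any unmethylated GATC site and enriching the
  template pool for methylated alleles.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

from .sim import Epiallele, digest_alleles

__all__ = [
    "METHYLATED",
    "CONVERTED",
    "AMBIGUOUS",
    "CloneCallVector",
    "CloneSummary",
    "align_clone",
    "call_methylation",
    "cytosine_contexts",
    "conversion_rate",
    "average_methylation_rate",
    "strategy1_classify",
    "strategy2_enrich",
    "summarize_clone",
    "lollipop_text",
    "lollipop_plot",
]

METHYLATED = "methylated"
CONVERTED = "converted"
AMBIGUOUS = "ambiguous"

_SYMBOL = {METHYLATED: "●", CONVERTED: "○", AMBIGUOUS: "?"}


@dataclass
class CloneCallVector:
    """Per-reference-cytosine calls for one sequenced clone."""

    clone_id: str
    positions: tuple[int, ...]  # reference C positions, ascending
    calls: tuple[str, ...]  # methylated / converted / ambiguous
    contexts: tuple[str, ...] = ()  # CpG / CHG / CHH per position (reported only)

    def __post_init__(self) -> None:
        if len(self.positions) != len(self.calls):
            raise ValueError("positions and calls must align")

    @property
    def n_methylated(self) -> int:
        return sum(c == METHYLATED for c in self.calls)

    @property
    def n_converted(self) -> int:
        return sum(c == CONVERTED for c in self.calls)

    @property
    def n_ambiguous(self) -> int:
        return sum(c == AMBIGUOUS for c in self.calls)


@dataclass
class CloneSummary:
    clone_id: str
    n_cytosines: int  # assessable (non-ambiguous)
    n_methylated: int
    methylation_fraction: float
    strategy1_class: str = "n/a"  # cut / noncut / n/a


def align_clone(reference_amplicon: str, clone: str) -> list[tuple[int, str, str]]:
    """Positional pairing of a clone against its reference amplicon.

    Raises on length mismatch naming both lengths; no gapped alignment is
    attempted.
    """
    if len(reference_amplicon) != len(clone):
        raise ValueError(
            f"clone length {len(clone)} does not match reference amplicon "
            f"length {len(reference_amplicon)}; indel-containing clones are rejected"
        )
    ref = reference_amplicon.upper()
    cln = clone.upper()
    return [(i, ref[i], cln[i]) for i in range(len(ref))]


def cytosine_contexts(reference: str, positions: Sequence[int]) -> tuple[str, ...]:
    """CpG/CHG/CHH context of each reference cytosine (H = A, C or T).

    Context is annotated and reported per call but is not used by any
    classification rule here. Cytosines too close to the sequence end for
    their context to be determined are labelled 'CNN'.
    """
    ref = reference.upper()
    out = []
    for pos in positions:
        if pos + 1 < len(ref) and ref[pos + 1] == "G":
            out.append("CpG")
        elif pos + 2 < len(ref):
            out.append("CHG" if ref[pos + 2] == "G" else "CHH")
        else:
            out.append("CNN")
    return tuple(out)


def call_methylation(
    pairs: Sequence[tuple[int, str, str]], clone_id: str = "clone"
) -> CloneCallVector:
    """Call each reference cytosine from aligned base pairs.

    Clone C at a reference C = methylated (resisted conversion); clone T =
    converted; anything else = ambiguous. Non-cytosine reference positions
    are ignored.
    """
    positions, calls = [], []
    for pos, ref_base, clone_base in pairs:
        if ref_base.upper() != "C":
            continue
        positions.append(pos)
        b = clone_base.upper()
        if b == "C":
            calls.append(METHYLATED)
        elif b == "T":
            calls.append(CONVERTED)
        else:
            calls.append(AMBIGUOUS)
    ref_seq = _reference_from_pairs(pairs)
    return CloneCallVector(
        clone_id=clone_id,
        positions=tuple(positions),
        calls=tuple(calls),
        contexts=cytosine_contexts(ref_seq, positions),
    )


def _reference_from_pairs(pairs: Sequence[tuple[int, str, str]]) -> str:
    return "".join(ref for _, ref, _ in pairs)


def conversion_rate(clones: Sequence[CloneCallVector]) -> float:
    """Bisulfite conversion-rate QC on a known-unmethylated control locus.

    Pooled converted / (converted + methylated) over all clones, ambiguous
    calls excluded from both sides. NaN (with a warning) when nothing is
    assessable.
    """
    conv = sum(c.n_converted for c in clones)
    meth = sum(c.n_methylated for c in clones)
    if conv + meth == 0:
        warnings.warn("no assessable cytosines; conversion rate undefined", stacklevel=2)
        return math.nan
    return conv / (conv + meth)


def average_methylation_rate(clones: Sequence[CloneCallVector]) -> float:
    """Pooled methylation frequency: total 5mC over total assessable
    cytosines across all clones."""
    meth = sum(c.n_methylated for c in clones)
    total = sum(c.n_methylated + c.n_converted for c in clones)
    if total == 0:
        warnings.warn("no assessable cytosines; methylation rate undefined", stacklevel=2)
        return math.nan
    return meth / total


def strategy1_classify(clone: str, gatc_sites: Sequence[int]) -> str:
    """Would DpnII digest the post-bisulfite PCR product of this clone?

    "cut" iff at least one reference GATC site still reads exactly "GATC"
    in the clone (the site C was retained, i.e. it was methylated in the
    genomic template); "noncut" otherwise; "n/a" when the reference carries
    no GATC site. One intact site suffices: digestion at any site destroys
    the full-length band.
    """
    if not gatc_sites:
        return "n/a"
    clone = clone.upper()
    return "cut" if any(clone[g : g + 4] == "GATC" for g in gatc_sites) else "noncut"


def strategy2_enrich(
    alleles: Sequence[Epiallele], enzyme: str = "BfuCI"
) -> list[Epiallele]:
    """Pre-bisulfite enrichment for methylated alleles.

    Returns the alleles surviving digestion (BfuCI spares only alleles whose
    every GATC-site C is methylated) — the enriched template pool that then
    goes into bisulfite treatment, PCR and cloning.
    """
    survivors = digest_alleles(alleles, enzyme).survivors
    if alleles and not survivors:
        warnings.warn("no alleles survive digestion; enriched pool is empty", stacklevel=2)
    return survivors


def summarize_clone(
    vector: CloneCallVector,
    clone_sequence: str | None = None,
    gatc_sites: Sequence[int] = (),
) -> CloneSummary:
    """Per-clone summary with methylation fraction over assessable
    cytosines, plus the Strategy-1 class if the clone sequence is given."""
    assessable = vector.n_methylated + vector.n_converted
    frac = vector.n_methylated / assessable if assessable else math.nan
    s1 = (
        strategy1_classify(clone_sequence, gatc_sites)
        if clone_sequence is not None
        else "n/a"
    )
    return CloneSummary(
        clone_id=vector.clone_id,
        n_cytosines=assessable,
        n_methylated=vector.n_methylated,
        methylation_fraction=frac,
        strategy1_class=s1,
    )


def lollipop_text(clones: Sequence[CloneCallVector]) -> str:
    """Text lollipop rendering: one row per clone, cytosines in reference
    order; ● methylated, ○ converted, ? ambiguous. Rows are sorted by
    clone_id for a deterministic report."""
    rows = []
    for c in sorted(clones, key=lambda c: c.clone_id):
        rows.append(f"{c.clone_id}\t" + "".join(_SYMBOL[call] for call in c.calls))
    return "\n".join(rows)


def lollipop_plot(clones: Sequence[CloneCallVector], path: str) -> None:
    """Lollipop plot of per-clone calls (filled = methylated, open =
    converted, grey cross = ambiguous), one row per clone."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ordered = sorted(clones, key=lambda c: c.clone_id)
    fig, ax = plt.subplots(figsize=(8, 0.3 * max(len(ordered), 4) + 1))
    for row, clone in enumerate(ordered):
        for col, call in enumerate(clone.calls):
            y = len(ordered) - 1 - row
            if call == METHYLATED:
                ax.plot(col, y, "o", color="black", ms=5)
            elif call == CONVERTED:
                ax.plot(col, y, "o", mfc="white", mec="black", ms=5)
            else:
                ax.plot(col, y, "x", color="grey", ms=5)
    ax.set_yticks(range(len(ordered)))
    ax.set_yticklabels([c.clone_id for c in reversed(ordered)], fontsize=6)
    ax.set_xlabel("cytosine (reference order)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
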