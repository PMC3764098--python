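"""Synthetic data generator for on/off epiallele methylation studies.

Everything the analysis pipeline consumes can be generated here with the
statistical structure the downstream methods assume: a haploid population of
alleles in which a fraction ``f_on`` is densely methylated (per-cytosine
density ``d_on``) and the rest essentially unmethylated, bisulfite
conversion with realistic efficiency (~99.5–99.8% of unmethylated cytosines
deaminated), methylation-sensitive GATC digestion, RIP'd sequence
composition, strand-specific small-RNA pileups, and qPCR Ct values.

Only the top strand is modelled for methylation and bisulfite conversion:
the clone-sequencing readout this emulates reads one strand. Methylation
state lives in each allele's 0/1 vector aligned to the reference cytosine
positions — never in the sequence alphabet.

All coordinates are 0-based, half-open.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .srna import MappedRead

__all__ = [
    "SimulatedLocus",
    "Epiallele",
    "SimParams",
    "DigestionResult",
    "generate_reference",
    "apply_rip",
    "assign_epialleles",
    "bisulfite_convert",
    "digest_alleles",
    "simulate_reads",
    "simulate_qpcr",
    "truth_table",
]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimulatedLocus:
    """A reference sequence with indexed cytosines and GATC sites.

    ``cytosine_positions`` are 0-based top-strand indices of every 'C';
    ``gatc_sites`` are 0-based start indices of every "GATC" occurrence.
    Both are strictly increasing.
    """

    name: str
    sequence: str
    cytosine_positions: tuple[int, ...]
    gatc_sites: tuple[int, ...]

    @classmethod
    def from_sequence(cls, name: str, sequence: str) -> "SimulatedLocus":
        sequence = sequence.upper()
        bad = set(sequence) - set("ACGTN")
        if bad:
            raise ValueError(f"illegal characters in sequence {name!r}: {sorted(bad)}")
        cs = tuple(i for i, b in enumerate(sequence) if b == "C")
        gatc = []
        i = sequence.find("GATC")
        while i != -1:
            gatc.append(i)
            i = sequence.find("GATC", i + 1)
        return cls(name, sequence, cs, tuple(gatc))

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class Epiallele:
    """One haploid allele's per-cytosine methylation state.

    ``state[i]`` is 1 iff the cytosine at ``locus.cytosine_positions[i]``
    carries 5mC. ``label`` records how the allele was generated ("on" = drawn
    from the dense component).
    """

    locus: SimulatedLocus
    state: np.ndarray  # uint8 vector of 0/1, aligned to cytosine_positions
    label: str  # "on" or "off"
    allele_id: str = ""

    def __post_init__(self) -> None:
        self.state = np.asarray(self.state, dtype=np.uint8)
        if self.state.shape != (len(self.locus.cytosine_positions),):
            raise ValueError(
                f"state length {self.state.shape} does not match "
                f"{len(self.locus.cytosine_positions)} reference cytosines"
            )
        if self.label not in ("on", "off"):
            raise ValueError(f"label must be 'on' or 'off', got {self.label!r}")

    @property
    def n_methylated(self) -> int:
        return int(self.state.sum())


@dataclass(frozen=True)
class SimParams:
    """Parameters of the on/off epiallele population model.

    f_on      fraction of alleles in the methylated ("on") component
    d_on      per-cytosine 5mC density of "on" alleles
    d_off     per-cytosine 5mC density of "off" alleles (0 = strictly off)
    conv_eff  bisulfite conversion efficiency for unmethylated C
    mC_conv   inappropriate conversion probability for 5mC
    """

    n_alleles: int
    f_on: float
    d_on: float
    d_off: float = 0.0
    conv_eff: float = 0.995
    mC_conv: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_alleles < 0:
            raise ValueError("n_alleles must be non-negative")
        for name in ("f_on", "d_on", "d_off", "conv_eff", "mC_conv"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability in [0,1], got {v}")


@dataclass
class DigestionResult:
    """Per-allele digestion outcomes plus the surviving (intact) subset."""

    enzyme: str
    outcomes: list[str]  # "cleaved" or "intact", aligned to input order
    survivors: list[Epiallele]


def generate_reference(
    length: int,
    gc_fraction: float = 0.5,
    planted_gatc: Sequence[int] = (),
    seed: int = 0,
    name: str = "locus",
) -> SimulatedLocus:
    """Random reference sequence with GATC motifs planted at given positions.

    Bases are iid with the requested GC fraction (G and C equally likely
    within the GC mass, A and T within the AT mass); planted motifs overwrite
    the random bases. Planted positions must fit within the sequence and must
    not overlap each other.
    """
    if length < 0:
        raise ValueError("length must be non-negative")
    if not 0.0 <= gc_fraction <= 1.0:
        raise ValueError(f"gc_fraction must be in [0,1], got {gc_fraction}")
    planted = sorted(planted_gatc)
    for p in planted:
        if p < 0 or p + 4 > length:
            raise ValueError(f"planted GATC at {p} does not fit in length {length}")
    for a, b in zip(planted, planted[1:]):
        if b < a + 4:
            raise ValueError(f"planted GATC motifs at {a} and {b} overlap")
    rng = np.random.default_rng(seed)
    probs = np.array(
        [(1 - gc_fraction) / 2, gc_fraction / 2, gc_fraction / 2, (1 - gc_fraction) / 2]
    )
    seq = rng.choice(_BASES, size=length, p=probs)
    for p in planted:
        seq[p : p + 4] = list("GATC")
    return SimulatedLocus.from_sequence(name, "".join(seq))


def apply_rip(
    locus: SimulatedLocus,
    interval: tuple[int, int],
    p_mut: float,
    seed: int = 0,
) -> SimulatedLocus:
    """Mutate a region the way repeat-induced point mutation (RIP) does.

    RIP converts C to T preferentially in CpA context, on both strands.
    Within the half-open ``interval``, each top-strand C followed by A is
    mutated to T with probability ``p_mut``, and each top-strand G preceded
    by T (the bottom-strand CpA event seen from the top strand as TpG) is
    mutated to A with the same probability. Dinucleotide contexts are read
    from the unmutated sequence, so the two event classes do not feed each
    other within a single application.
    """
    start, end = interval
    if not (0 <= start <= end <= len(locus.sequence)):
        raise ValueError(f"interval {interval} outside sequence of length {len(locus)}")
    if not 0.0 <= p_mut <= 1.0:
        raise ValueError(f"p_mut must be in [0,1], got {p_mut}")
    rng = np.random.default_rng(seed)
    original = locus.sequence
    out = list(original)
    for i in range(start, end):
        b = original[i]
        if b == "C" and i + 1 < len(original) and original[i + 1] == "A":
            if rng.random() < p_mut:
                out[i] = "T"
        elif b == "G" and i >= 1 and original[i - 1] == "T":
            if rng.random() < p_mut:
                out[i] = "A"
    return SimulatedLocus.from_sequence(locus.name, "".join(out))


def assign_epialleles(locus: SimulatedLocus, params: SimParams) -> list[Epiallele]:
    """Draw a haploid population of epialleles under the on/off model.

    Each allele is independently "on" with probability ``f_on`` (a Bernoulli
    draw per allele, not a fixed count — each nucleus switches
    independently); its per-cytosine states are then iid Bernoulli with
    density ``d_on`` or ``d_off``.
    """
    rng = np.random.default_rng(params.seed)
    n_c = len(locus.cytosine_positions)
    on = rng.random(params.n_alleles) < params.f_on
    alleles = []
    for i in range(params.n_alleles):
        d = params.d_on if on[i] else params.d_off
        state = (rng.random(n_c) < d).astype(np.uint8)
        alleles.append(
            Epiallele(
                locus=locus,
                state=state,
                label="on" if on[i] else "off",
                allele_id=f"allele_{i:05d}",
            )
        )
    return alleles


def bisulfite_convert(
    allele: Epiallele,
    conv_eff: float = 0.995,
    mC_conv: float = 0.0,
    seed: int = 0,
) -> str:
    """In-silico bisulfite conversion of one allele's top strand.

    Unmethylated C deaminates to uracil — read as T after PCR — with
    probability ``conv_eff``; 5mC resists, converting only with probability
    ``mC_conv``. Output has the reference length (conversion is
    length-preserving), so converted clones align positionally.
    """
    if not 0.0 <= conv_eff <= 1.0 or not 0.0 <= mC_conv <= 1.0:
        raise ValueError("conv_eff and mC_conv must be probabilities")
    rng = np.random.default_rng(seed)
    seq = list(allele.locus.sequence)
    for idx, pos in enumerate(allele.locus.cytosine_positions):
        p_convert = mC_conv if allele.state[idx] else conv_eff
        if rng.random() < p_convert:
            seq[pos] = "T"
    return "".join(seq)


def _gatc_c_state_index(locus: SimulatedLocus) -> dict[int, int]:
    # the recognition-site cytosine is the top-strand C at offset 3 of GATC
    pos_to_idx = {pos: i for i, pos in enumerate(locus.cytosine_positions)}
    return {g: pos_to_idx[g + 3] for g in locus.gatc_sites}


def digest_alleles(alleles: Sequence[Epiallele], enzyme: str) -> DigestionResult:
    """Methylation-sensitive digestion of a population at its GATC sites.

    The isoschizomers share the GATC recognition sequence but differ in
    methylation sensitivity: both digest unmethylated GATC sites, but only
    DpnII cuts when the site C is methylated. So DpnII cleaves any allele
    with at least one GATC site, while BfuCI cleaves only alleles with at
    least one GATC site whose C is unmethylated — an allele with every
    GATC-site C methylated survives BfuCI and is what a methylated-allele
    enrichment selects for.
    """
    if enzyme not in ("DpnII", "BfuCI"):
        raise ValueError(f"enzyme must be 'DpnII' or 'BfuCI', got {enzyme!r}")
    outcomes: list[str] = []
    survivors: list[Epiallele] = []
    warned = False
    for allele in alleles:
        sites = allele.locus.gatc_sites
        if not sites:
            if not warned:
                warnings.warn(
                    f"locus {allele.locus.name!r} has no GATC sites; "
                    "all alleles remain intact",
                    stacklevel=2,
                )
                warned = True
            outcomes.append("intact")
            survivors.append(allele)
            continue
        site_idx = _gatc_c_state_index(allele.locus)
        if enzyme == "DpnII":
            cleaved = True
        else:
            cleaved = any(allele.state[site_idx[g]] == 0 for g in sites)
        outcomes.append("cleaved" if cleaved else "intact")
        if not cleaved:
            survivors.append(allele)
    return DigestionResult(enzyme=enzyme, outcomes=outcomes, survivors=survivors)


def simulate_reads(
    locus: SimulatedLocus,
    strand_profiles: dict[str, Sequence[float]],
    n_reads: int,
    read_length: int = 22,
    rdna_intervals: Iterable[tuple] = (),
    rdna_fraction: float = 0.0,
    seed: int = 0,
    window: int = 100,
) -> list[MappedRead]:
    """Simulate mapped small-RNA reads from per-strand window intensities.

    ``strand_profiles`` maps '+' / '-' to a non-negative intensity per
    ``window``-nt window along the locus; read 5'-end positions are drawn
    multinomially proportional to those intensities, uniform within a
    window. A ``rdna_fraction`` of reads is instead placed with 5' ends
    uniform over ``rdna_intervals`` (random strand) to exercise rDNA
    filtering downstream.
    """
    if n_reads < 0:
        raise ValueError("n_reads must be non-negative")
    if n_reads == 0:
        return []
    if not 0.0 <= rdna_fraction <= 1.0:
        raise ValueError("rdna_fraction must be in [0,1]")
    rng = np.random.default_rng(seed)
    keys: list[tuple[str, int]] = []
    weights: list[float] = []
    for strand, profile in strand_profiles.items():
        if strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {strand!r}")
        arr = np.asarray(profile, dtype=float)
        if (arr < 0).any():
            raise ValueError("window intensities must be non-negative")
        for w, val in enumerate(arr):
            if val > 0:
                keys.append((strand, w))
                weights.append(val)
    if not weights:
        raise ValueError("all window intensities are zero")
    probs = np.asarray(weights) / sum(weights)

    rdna = [(iv[0], int(iv[1]), int(iv[2])) for iv in rdna_intervals]
    n_rdna = rng.binomial(n_reads, rdna_fraction) if rdna else 0
    n_locus = n_reads - n_rdna

    reads: list[MappedRead] = []
    counts = rng.multinomial(n_locus, probs)
    seq_len = len(locus.sequence)
    for (strand, w), k in zip(keys, counts):
        if k == 0:
            continue
        lo = w * window
        hi = min(lo + window, seq_len)
        # keep the whole read on the locus without moving its 5' end
        # out of the sampled window
        if strand == "+":
            hi = min(hi, seq_len - read_length + 1)
        else:
            lo = max(lo, read_length - 1)
        if lo >= hi:
            raise ValueError(
                f"window [{w * window},{w * window + window}) cannot hold a "
                f"{read_length}-nt read on strand {strand}"
            )
        for p5 in rng.integers(lo, hi, size=k):
            start = int(p5) if strand == "+" else int(p5) - read_length + 1
            reads.append(MappedRead(locus.name, start, read_length, strand, 1))

    if n_rdna:
        lens = np.array([e - s for _, s, e in rdna], dtype=float)
        which = rng.choice(len(rdna), size=n_rdna, p=lens / lens.sum())
        strands = rng.choice(["+", "-"], size=n_rdna)
        for j, strand in zip(which, strands):
            chrom, s, e = rdna[j]
            p5 = int(rng.integers(s, e))
            start = p5 if strand == "+" else max(0, p5 - read_length + 1)
            # for '-' reads keep the 5' end inside the interval exactly
            if strand == "-":
                start = p5 - read_length + 1
                if start < 0:
                    start, strand = p5, "+"
            reads.append(MappedRead(chrom, start, read_length, strand, 1))
    reads.sort(key=lambda r: (r.chrom, r.strand, r.start))
    return reads


def simulate_qpcr(
    relative_quantity: float,
    efficiency: float = 2.0,
    ct_noise_sd: float = 0.0,
    seed: int = 0,
    reference_ct: float = 20.0,
) -> float:
    """Ct value for a template at the given quantity relative to reference.

    Ct = reference_ct - log(quantity)/log(efficiency) + N(0, ct_noise_sd):
    halving the template with perfect doubling (efficiency 2) costs exactly
    one extra cycle.
    """
    if relative_quantity <= 0:
        raise ValueError(f"relative_quantity must be positive, got {relative_quantity}")
    if efficiency <= 1:
        raise ValueError(f"efficiency must exceed 1, got {efficiency}")
    if ct_noise_sd < 0:
        raise ValueError("ct_noise_sd must be non-negative")
    ct = reference_ct - math.log(relative_quantity) / math.log(efficiency)
    if ct_noise_sd > 0:
        ct += float(np.random.default_rng(seed).normal(0.0, ct_noise_sd))
    return ct


def truth_table(alleles: Sequence[Epiallele]):
    """Ground-truth table (allele_id, label, n_meth) as a pandas DataFrame."""
    import pandas as pd

    return pd.DataFrame(
        {
            "allele_id": [a.allele_id for a in alleles],
            "label": [a.label for a in alleles],
            "n_meth": [a.n_methylated for a in alleles],
        }
    )
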