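"""Shared readers and writers: FASTA, BED, bedGraph, tabular reads, manifests.

Coordinates in every file are 0-based half-open (BED convention); 1-based
coordinates appear only in labelled human-readable reports. FASTA parsing
goes through Biopython with case-insensitive input canonicalized to
uppercase; duplicate names and illegal characters are rejected.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .srna import MappedRead, WindowTrack

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_bed",
    "write_bed",
    "write_bedgraph",
    "read_reads_tsv",
    "write_reads_tsv",
    "write_manifest",
    "read_manifest",
]

_ALLOWED_BASES = set("ACGTN")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Named sequences in file order, uppercased and validated.

    Duplicate record names and characters outside {A,C,G,T,N} are errors.
    """
    seqs: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in seqs:
            raise ValueError(f"{path}: duplicate sequence name {record.id!r}")
        seq = str(record.seq).upper()
        bad = set(seq) - _ALLOWED_BASES
        if bad:
            raise ValueError(
                f"{path}: illegal characters {sorted(bad)} in record {record.id!r}"
            )
        seqs[record.id] = seq
    return seqs


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    records = [
        SeqRecord(Seq(seq.upper()), id=name, description="") for name, seq in seqs.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def read_bed(path: str | Path) -> list[tuple[str, int, int, str]]:
    """BED intervals (chrom, start, end, name) with validation.

    Raises with the 1-based line number on malformed lines or start >= end;
    the name column defaults to "" when absent.
    """
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 BED columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start < 0:
                raise ValueError(f"{path}:{lineno}: negative start {start}")
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start {start} >= end {end}")
            name = fields[3] if len(fields) > 3 else ""
            intervals.append((chrom, start, end, name))
    return intervals


def write_bed(intervals: Iterable[tuple], path: str | Path) -> None:
    """Sorted BED output; rows may be (chrom, start, end[, name...])."""
    rows = sorted(intervals, key=lambda iv: (iv[0], int(iv[1]), int(iv[2])))
    with open(path, "w") as fh:
        for iv in rows:
            fh.write("\t".join(str(x) for x in iv) + "\n")


def write_bedgraph(
    values: Iterable[tuple[str, int, int, float]], path: str | Path
) -> None:
    rows = sorted(values, key=lambda v: (v[0], v[1]))
    with open(path, "w") as fh:
        for chrom, start, end, value in rows:
            fh.write(f"{chrom}\t{start}\t{end}\t{value:.6g}\n")


def track_to_bedgraph_rows(track: WindowTrack) -> list[tuple[str, int, int, float]]:
    return [
        (track.chrom, w, w + track.window_size, track.density(w))
        for w in sorted(track.raw)
    ]


_READ_COLUMNS = ("chrom", "start", "length", "strand", "count")


def read_reads_tsv(path: str | Path) -> list[MappedRead]:
    """Tabular mapped reads: chrom, start, length, strand, count (with or
    without a header line)."""
    reads = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[:5] == list(_READ_COLUMNS):
                continue
            if len(fields) < 5:
                raise ValueError(f"{path}:{lineno}: expected 5 columns")
            try:
                reads.append(
                    MappedRead(
                        chrom=fields[0],
                        start=int(fields[1]),
                        length=int(fields[2]),
                        strand=fields[3],
                        count=int(fields[4]),
                    )
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return reads


def write_reads_tsv(reads: Sequence[MappedRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_READ_COLUMNS) + "\n")
        for r in reads:
            fh.write(f"{r.chrom}\t{r.start}\t{r.length}\t{r.strand}\t{r.count}\n")


def parameter_hash(params: Mapping) -> str:
    """Stable hash of a parameter mapping for run manifests."""
    canon = json.dumps(params, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def write_manifest(params: Mapping, path: str | Path) -> None:
    """YAML run manifest: parameters, seed, and a parameter hash.

    Deliberately timestamp-free so repeated runs with one seed are
    byte-identical.
    """
    from . import __version__

    doc = {
        "package_version": __version__,
        "parameters": dict(params),
        "parameter_hash": parameter_hash(params),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


def read_manifest(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)
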