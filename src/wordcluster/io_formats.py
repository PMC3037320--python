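"""FASTA/BED input, contig segmentation, and cluster report output.

All coordinates are 0-based half-open, both in memory and on disk (native
BED convention).  The 1-based inclusive arithmetic used for inter-copy
distances is confined to :func:`wordcluster.distance_model.distances`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

__all__ = [
    "Contig",
    "Interval",
    "read_fasta",
    "segment_contigs",
    "read_bed",
    "read_seq_lengths",
    "write_clusters",
]

_ACGT_RUN = re.compile(r"[ACGT]+")


@dataclass(frozen=True)
class Contig:
    """A maximal N-free segment of a sequence, in absolute coordinates.

    Scanning, inter-copy distances and clusters are all defined strictly
    within a contig; any non-ACGT character breaks the sequence.
    """

    seq_id: str
    start: int
    end: int
    bases: str

    def __post_init__(self) -> None:
        if self.end - self.start != len(self.bases):
            raise ValueError("contig span does not match its bases")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Interval:
    """A genomic interval (BED record, cluster span, gene region...)."""

    seq_id: str
    start: int
    end: int
    label: str = ""

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.seq_id}:{self.start}-{self.end}"
            )

    def __len__(self) -> int:
        return self.end - self.start


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a (multi-record) FASTA file.

    Sequences are uppercased; the ID is the first whitespace-delimited
    token of the header.  Empty files and duplicate IDs are hard errors.
    """
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA ID {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append((rec.id, str(rec.seq).upper()))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def segment_contigs(seq_id: str, sequence: str) -> list[Contig]:
    """Split an uppercase sequence into maximal A/C/G/T runs.

    Every non-ACGT character (N or any other ambiguity code) acts as a
    separator; an all-N sequence yields no contigs.
    """
    return [
        Contig(seq_id, m.start(), m.end(), m.group())
        for m in _ACGT_RUN.finditer(sequence)
    ]


def read_bed(path: str | Path) -> list[Interval]:
    """Read BED3+ records, returning intervals sorted by (seq_id, start, end).

    Lines starting with ``#``, ``track`` or ``browser`` are skipped.  The
    name column (4th), when present, is kept as the interval label.
    Malformed coordinates raise with the offending line number.
    """
    intervals: list[Interval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: fewer than 3 BED columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: non-numeric BED coordinates"
                ) from exc
            if start >= end:
                raise ValueError(
                    f"{path}:{lineno}: start {start} >= end {end}"
                )
            label = fields[3] if len(fields) > 3 else ""
            intervals.append(Interval(fields[0], start, end, label))
    intervals.sort(key=lambda iv: (iv.seq_id, iv.start, iv.end))
    return intervals


def read_seq_lengths(path: str | Path) -> dict[str, int]:
    """Read a two-column TSV of sequence name and length (chrom.sizes)."""
    lengths: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected 'name<TAB>length'")
            try:
                length = int(fields[1])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric length") from exc
            if fields[0] in lengths:
                raise ValueError(f"{path}:{lineno}: duplicate sequence {fields[0]!r}")
            lengths[fields[0]] = length
    if not lengths:
        raise ValueError(f"no sequence lengths found in {path}")
    return lengths


def write_clusters(clusters: Sequence, path: str | Path, *,
                   n_tested: int | None = None,
                   extra_header: Iterable[str] = ()) -> None:
    """Write clusters as BED-compatible TSV with a summary header.

    Columns: seq_id, start (0-based), end (exclusive), name, n, p-value.
    The ``#``-prefixed summary block reports the cluster count, mean
    length, total genome coverage and — so that users can apply a
    Bonferroni correction externally — the number of clusters tested.
    """
    lengths = [c.end - c.start for c in clusters]
    coverage = sum(lengths)
    mean_len = coverage / len(lengths) if lengths else 0.0
    with open(path, "w") as fh:
        fh.write(f"# clusters: {len(clusters)}\n")
        fh.write(f"# mean_length: {mean_len:.1f}\n")
        fh.write(f"# coverage_bp: {coverage}\n")
        if n_tested is not None:
            fh.write(f"# clusters_tested: {n_tested}\n")
        for line in extra_header:
            fh.write(f"# {line}\n")
        fh.write("# seq_id\tstart\tend\tname\tn\tp_value\n")
        for i, c in enumerate(clusters, start=1):
            pval = "NA" if c.p_value is None else f"{c.p_value:.1e}"
            fh.write(
                f"{c.seq_id}\t{c.start}\t{c.end}\tcluster_{i}\t{c.n}\t{pval}\n"
            )
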