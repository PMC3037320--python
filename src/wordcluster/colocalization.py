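"""Co-localization of clusters with gene regions.

Gene models come from refFlat-style TSV (UCSC convention).  From each
gene the strand-aware regions are derived: the 1-bp TSS, a 201-bp
TSS +/- 100 bp window, the promoter window R13 = [TSS-1500 bp, TSS+500 bp]
in transcription orientation (both ends inclusive), the UTRs, exons and
introns.  A cluster co-localizes with a region label when it shares at
least one bp with at least one interval of that label; each cluster is
counted once per label however many genes it touches.
"""

from __future__ import annotations

import logging
from bisect import bisect_right
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .io_formats import Interval

__all__ = [
    "GeneModel",
    "REGION_LABELS",
    "read_refflat",
    "derive_regions",
    "overlap_counts",
]

logger = logging.getLogger(__name__)

REGION_LABELS = ("TSS", "TSS_100", "R13", "5UTR", "exons", "introns", "3UTR")

R13_UP = 1500    # bp upstream of the TSS, in transcription orientation
R13_DOWN = 500   # bp downstream
TSS_FLANK = 100  # half-width of the TSS window


@dataclass(frozen=True)
class GeneModel:
    """One transcript in refFlat coordinates (0-based half-open)."""

    gene_id: str
    seq_id: str
    strand: str
    tx_start: int
    tx_end: int
    cds_start: int
    cds_end: int
    exons: tuple[tuple[int, int], ...]

    @property
    def coding(self) -> bool:
        return self.cds_end > self.cds_start


def read_refflat(path: str | Path) -> list[GeneModel]:
    """Parse refFlat-style TSV gene models.

    Accepts the 11-column UCSC refFlat layout (geneName, name, chrom, ...)
    or the 10-column variant without the transcript name.  Genes whose
    CDS falls outside the transcript span are rejected with a warning.
    """
    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) >= 11:
                f = [f[0]] + f[2:11]  # drop the transcript-name column
            if len(f) < 10:
                raise ValueError(f"{path}:{lineno}: expected >= 10 refFlat columns")
            try:
                tx_start, tx_end = int(f[3]), int(f[4])
                cds_start, cds_end = int(f[5]), int(f[6])
                n_exons = int(f[7])
                exon_starts = [int(x) for x in f[8].rstrip(",").split(",")]
                exon_ends = [int(x) for x in f[9].rstrip(",").split(",")]
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed refFlat fields") from exc
            if f[2] not in "+-":
                raise ValueError(f"{path}:{lineno}: strand must be + or -")
            if len(exon_starts) != n_exons or len(exon_ends) != n_exons:
                raise ValueError(f"{path}:{lineno}: exon count mismatch")
            if cds_end > cds_start and not (tx_start <= cds_start and cds_end <= tx_end):
                logger.warning("%s:%d: CDS outside transcript for %s; gene skipped",
                               path, lineno, f[0])
                continue
            genes.append(GeneModel(
                gene_id=f[0], seq_id=f[1], strand=f[2],
                tx_start=tx_start, tx_end=tx_end,
                cds_start=cds_start, cds_end=cds_end,
                exons=tuple(zip(exon_starts, exon_ends)),
            ))
    return genes


def derive_regions(genes: Sequence[GeneModel],
                   seq_lengths: Mapping[str, int] | None = None,
                   ) -> dict[str, list[Interval]]:
    """Strand-aware region intervals per label, clipped to sequence bounds."""
    regions: dict[str, list[Interval]] = {lab: [] for lab in REGION_LABELS}
    for g in genes:
        limit = seq_lengths.get(g.seq_id) if seq_lengths else None
        tss = g.tx_start if g.strand == "+" else g.tx_end - 1

        def add(label: str, start: int, end: int) -> None:
            start = max(0, start)
            if limit is not None:
                end = min(end, limit)
            if end > start:
                regions[label].append(Interval(g.seq_id, start, end, g.gene_id))

        add("TSS", tss, tss + 1)
        add("TSS_100", tss - TSS_FLANK, tss + TSS_FLANK + 1)
        if g.strand == "+":
            add("R13", tss - R13_UP, tss + R13_DOWN + 1)
        else:
            add("R13", tss - R13_DOWN, tss + R13_UP + 1)
        for s, e in g.exons:
            add("exons", s, e)
        cursor = g.tx_start
        for s, e in g.exons:
            if s > cursor:
                add("introns", cursor, s)
            cursor = max(cursor, e)
        if g.coding:
            # UTRs: exonic bases outside the CDS; 5' side depends on strand
            for s, e in g.exons:
                left = (max(s, g.tx_start), min(e, g.cds_start))
                right = (max(s, g.cds_end), min(e, g.tx_end))
                if left[1] > left[0]:
                    add("5UTR" if g.strand == "+" else "3UTR", *left)
                if right[1] > right[0]:
                    add("3UTR" if g.strand == "+" else "5UTR", *right)
    for lab in regions:
        regions[lab].sort(key=lambda iv: (iv.seq_id, iv.start, iv.end))
    return regions


def _merge(intervals: Iterable[Interval]) -> dict[str, tuple[list[int], list[int]]]:
    """Per-seq merged (union) interval bounds as parallel sorted lists."""
    by_seq: dict[str, list[Interval]] = {}
    for iv in intervals:
        by_seq.setdefault(iv.seq_id, []).append(iv)
    merged: dict[str, tuple[list[int], list[int]]] = {}
    for sid, ivs in by_seq.items():
        ivs.sort(key=lambda x: (x.start, x.end))
        starts: list[int] = []
        ends: list[int] = []
        for iv in ivs:
            if starts and iv.start <= ends[-1]:
                ends[-1] = max(ends[-1], iv.end)
            else:
                starts.append(iv.start)
                ends.append(iv.end)
        merged[sid] = (starts, ends)
    return merged


def overlaps_any(cluster, merged: Mapping[str, tuple[list[int], list[int]]]) -> bool:
    """Whether a cluster shares >= 1 bp with any merged region interval."""
    if cluster.seq_id not in merged:
        return False
    starts, ends = merged[cluster.seq_id]
    i = bisect_right(starts, cluster.end - 1) - 1  # last region starting before cluster end
    return i >= 0 and ends[i] > cluster.start


def overlap_counts(clusters: Sequence,
                   regions: Mapping[str, Sequence[Interval]]) -> dict[str, int]:
    """Number of clusters overlapping (>= 1 bp) each region label."""
    counts: dict[str, int] = {}
    for label, ivs in regions.items():
        merged = _merge(ivs)
        counts[label] = sum(1 for c in clusters if overlaps_any(c, merged))
    return counts
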