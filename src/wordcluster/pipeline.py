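"""End-to-end analyses: k-mer mode and genomic-element mode.

This is the library surface behind the command line: read the inputs,
resolve the maximum distance under the chosen model, assemble clusters,
assign negative-binomial p-values, filter, and report.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from . import cluster_core, distance_model, io_formats, kmer_scan
from .cluster_core import Cluster, DegenerateInputError, ElementSet, SequenceStats
from .distance_model import DistanceModelSpec
from .io_formats import Contig, Interval
from .kmer_scan import Occurrence, WordSet

__all__ = ["KmerResult", "ElementResult", "run_kmer_analysis",
           "run_element_analysis", "cluster_composition"]

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 1e-5
DEFAULT_MODEL = DistanceModelSpec("chrom_intersection")


@dataclass
class KmerResult:
    """Everything a k-mer run produces."""

    clusters: list[Cluster]              # all clusters (n >= 2), with p-values
    significant: list[Cluster]
    stats: dict[str, SequenceStats]      # per sequence
    genome_stats: SequenceStats | None
    thresholds: dict[str, tuple[int, float]]   # seq_id -> (d_max, p) used
    occurrences: dict[str, list[Occurrence]] = field(repr=False, default_factory=dict)
    contigs: dict[str, list[Contig]] = field(repr=False, default_factory=dict)


@dataclass
class ElementResult:
    clusters: list[Cluster]
    significant: list[Cluster]
    stats: dict[str, SequenceStats]
    genome_stats: SequenceStats | None
    thresholds: dict[str, tuple[int, float]]


def run_kmer_analysis(
    sequences: Sequence[tuple[str, str]],
    words: WordSet,
    model: DistanceModelSpec = DEFAULT_MODEL,
    alpha: float = DEFAULT_ALPHA,
) -> KmerResult:
    """Detect significant clusters of the target words in the sequences.

    Scanning, distances and clusters are confined to N-free contigs.
    Success probabilities are per sequence, except under the
    genome_intersection model where one genome-wide probability (N and
    the slot counts summed over sequences) is applied everywhere.
    """
    k = words.k
    contigs: dict[str, list[Contig]] = {}
    occs: dict[str, list[list[Occurrence]]] = {}     # per sequence, per contig
    for seq_id, seq in sequences:
        ctgs = io_formats.segment_contigs(seq_id, seq)
        contigs[seq_id] = ctgs
        occs[seq_id] = [kmer_scan.scan(c, words) for c in ctgs]

    stats: dict[str, SequenceStats] = {}
    seq_dists: dict[str, list[int]] = {}
    for seq_id in contigs:
        flat = [o for per_contig in occs[seq_id] for o in per_contig]
        if not flat:
            logger.info("%s: no target occurrences; skipped", seq_id)
            continue
        stats[seq_id] = kmer_scan.count_stats(flat, contigs[seq_id], k)
        dists: list[int] = []
        for per_contig in occs[seq_id]:
            dists.extend(distance_model.distances(per_contig))
        seq_dists[seq_id] = dists

    genome_stats = _genome_stats_kmer(stats, contigs, k) if stats else None
    clusterable = {sid: d for sid, d in seq_dists.items() if d}
    thresholds = distance_model.resolve_dmax(
        model,
        clusterable,
        {sid: stats[sid].p for sid in clusterable},
        genome_p=genome_stats.p if genome_stats else None,
    )
    for sid, (d_max, p) in thresholds.items():
        logger.info("%s: d_max=%d p=%.4g", sid, d_max, p)

    clusters: list[Cluster] = []
    for seq_id, per_contig in occs.items():
        if seq_id not in thresholds:
            continue
        d_max, p = thresholds[seq_id]
        for contig_occs in per_contig:
            for c in cluster_core.build_clusters(contig_occs, d_max):
                c.n_f = cluster_core.failures_kmer(c, k)
                c.p_value = cluster_core.negbin_pvalue(c.n, c.n_f, p)
                clusters.append(c)
    significant = cluster_core.filter_significant(clusters, alpha)
    return KmerResult(
        clusters=clusters,
        significant=significant,
        stats=stats,
        genome_stats=genome_stats,
        thresholds=thresholds,
        occurrences={sid: [o for pc in occs[sid] for o in pc] for sid in occs},
        contigs=contigs,
    )


def _genome_stats_kmer(stats: Mapping[str, SequenceStats],
                       contigs: Mapping[str, list[Contig]], k: int) -> SequenceStats:
    """Genome-wide N, L_s and p from the summed per-sequence totals."""
    all_contigs = [c for sid in stats for c in contigs[sid]]
    N = sum(s.N for s in stats.values())
    L_s = sum(s.L_s for s in stats.values())
    slots = sum(max(0, len(c) - k + 1) for c in all_contigs)
    denom = slots - N * (k - 1)
    if denom <= 0 or not 0 < N / denom < 1:
        raise DegenerateInputError("degenerate genome-wide success probability")
    return SequenceStats(N=N, L_s=L_s, p=N / denom)


def run_element_analysis(
    elements: Sequence[Interval],
    seq_lengths: Mapping[str, int],
    model: DistanceModelSpec = DEFAULT_MODEL,
    alpha: float = DEFAULT_ALPHA,
) -> ElementResult:
    """Detect significant clusters of genomic elements.

    Elements are grouped per sequence; L_s is the full declared sequence
    length (annotations refer to complete assemblies).  Under the
    per-sequence models, N, L_mean and p are per sequence; under
    genome_intersection they are pooled over all sequences.
    """
    by_seq: dict[str, list[Interval]] = {}
    for iv in elements:
        if iv.seq_id not in seq_lengths:
            raise ValueError(f"no length given for sequence {iv.seq_id!r}")
        if iv.end > seq_lengths[iv.seq_id]:
            raise ValueError(
                f"element {iv.seq_id}:{iv.start}-{iv.end} exceeds declared length"
            )
        by_seq.setdefault(iv.seq_id, []).append(iv)
    for ivs in by_seq.values():
        ivs.sort(key=lambda x: (x.start, x.end))

    stats: dict[str, SequenceStats] = {}
    elem_sets: dict[str, ElementSet] = {}
    seq_dists: dict[str, list[int]] = {}
    for sid, ivs in by_seq.items():
        es = ElementSet(ivs)
        p = cluster_core.success_prob_element(es, seq_lengths[sid])
        elem_sets[sid] = es
        stats[sid] = SequenceStats(N=es.N, L_s=seq_lengths[sid], p=p,
                                   L_mean=es.L_mean)
        seq_dists[sid] = distance_model.distances(ivs)

    genome_set = ElementSet([iv for ivs in by_seq.values() for iv in ivs])
    genome_L_s = sum(seq_lengths[sid] for sid in by_seq)
    genome_p = cluster_core.success_prob_element(genome_set, genome_L_s)
    genome_stats = SequenceStats(N=genome_set.N, L_s=genome_L_s, p=genome_p,
                                 L_mean=genome_set.L_mean)

    clusterable = {sid: d for sid, d in seq_dists.items() if d}
    if model.model == "genome_intersection":
        thresholds = distance_model.resolve_dmax(
            model,
            clusterable,
            {sid: stats[sid].p for sid in clusterable},
            genome_p=genome_p,
            unit=genome_set.L_mean,
        )
    else:
        # per-sequence scope: each sequence uses its own L_mean unit
        thresholds = {}
        for sid, dists in clusterable.items():
            thresholds.update(distance_model.resolve_dmax(
                model, {sid: dists}, {sid: stats[sid].p},
                unit=elem_sets[sid].L_mean,
            ))
    for sid, (d_max, p) in thresholds.items():
        logger.info("%s: d_max=%d p=%.4g", sid, d_max, p)

    clusters: list[Cluster] = []
    for sid, ivs in by_seq.items():
        if sid not in thresholds:
            continue
        d_max, p = thresholds[sid]
        scope_set = genome_set if model.model == "genome_intersection" else elem_sets[sid]
        for c in cluster_core.build_clusters(ivs, d_max):
            c.n_f = cluster_core.failures_element(c, scope_set)
            c.p_value = cluster_core.negbin_pvalue(c.n, c.n_f, p)
            clusters.append(c)
    significant = cluster_core.filter_significant(clusters, alpha)
    return ElementResult(
        clusters=clusters,
        significant=significant,
        stats=stats,
        genome_stats=genome_stats,
        thresholds=thresholds,
    )


def cluster_composition(cluster: Cluster, sequence: str) -> dict[str, float]:
    """Base composition of one cluster: GC fraction and CpG observed/expected.

    GC = (C+G)/L_c; O/E = (#CpG * L_c) / (#C * #G), the standard
    CpG-island quantities.  O/E is NaN when the cluster lacks C or G.
    """
    bases = sequence[cluster.start:cluster.end]
    c, g = bases.count("C"), bases.count("G")
    cpg = bases.count("CG")
    L = len(bases)
    gc = (c + g) / L if L else float("nan")
    oe = (cpg * L) / (c * g) if c and g else float("nan")
    return {"gc": gc, "cpg_oe": oe}
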