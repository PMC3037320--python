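"""Cluster assembly and negative-binomial significance.

A cluster is a maximal run of occurrences (word copies or genomic
elements) in which every consecutive inter-copy distance is <= d_max.
Its significance is the cumulative probability, under a Bernoulli null,
of observing at most n_f failures (no-target content) before the
(n-1)-th success: the first copy merely anchors the cluster, so only the
n-1 subsequent arrivals are informative.

For a k-mer cluster the failures are the intervening bases read as
no-target k-mers, n_f = L_c - n*k.  For genomic elements the uncovered
bases are counted in units of the mean element length,
n_f = ceiling(L_no / L_mean).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import gammaln, logsumexp

__all__ = [
    "Cluster",
    "SequenceStats",
    "ElementSet",
    "build_clusters",
    "failures_kmer",
    "failures_element",
    "success_prob_element",
    "negbin_pvalue",
    "filter_significant",
]


class DegenerateInputError(ValueError):
    """Raised when an input is too small/dense for a valid null model."""


@dataclass
class SequenceStats:
    """Per-scope totals feeding the null model.

    N is the number of occurrences (or elements), L_s the effective
    sequence length in bp, p the success probability, and L_mean the mean
    element length (element mode only).
    """

    N: int
    L_s: int
    p: float
    L_mean: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.p < 1.0:
            raise DegenerateInputError(
                f"success probability {self.p} outside (0,1)"
            )


@dataclass
class Cluster:
    """A maximal run of occurrences with all gaps <= d_max."""

    seq_id: str
    start: int
    end: int
    n: int
    members: tuple = field(repr=False, default=())
    n_f: int | None = None
    p_value: float | None = None

    @property
    def length(self) -> int:
        """Cluster length L_c in bp (end - start)."""
        return self.end - self.start


@dataclass
class ElementSet:
    """The genomic elements of one analysis scope, sorted by position."""

    intervals: Sequence
    L_mean: float = field(init=False)

    def __post_init__(self) -> None:
        if not self.intervals:
            raise DegenerateInputError("element set is empty")
        self.L_mean = float(
            np.mean([iv.end - iv.start for iv in self.intervals])
        )

    @property
    def N(self) -> int:
        return len(self.intervals)


def build_clusters(occurrences: Sequence, d_max: int) -> list[Cluster]:
    """Assemble maximal runs of occurrences with consecutive gaps <= d_max.

    ``occurrences`` must be sorted and lie within one contig (clusters
    never span contig boundaries).  A tie at distance == d_max is inside
    the cluster.  Runs of a single occurrence are discarded: with n = 1
    the test statistic is degenerate (zero informative arrivals).
    """
    if d_max < 1:
        raise ValueError("d_max must be >= 1")
    from .distance_model import distances  # local import to avoid cycle

    clusters: list[Cluster] = []
    run: list = []
    for occ in occurrences:
        if run:
            d = distances([run[-1], occ])[0]
            if d > d_max:
                _flush(run, clusters)
                run = []
        run.append(occ)
    _flush(run, clusters)
    return clusters


def _flush(run: list, clusters: list[Cluster]) -> None:
    if len(run) >= 2:
        clusters.append(
            Cluster(
                seq_id=run[0].seq_id,
                start=run[0].start,
                end=run[-1].end,
                n=len(run),
                members=tuple(run),
            )
        )


def failures_kmer(cluster: Cluster, k: int) -> int:
    """Number of no-target k-mers in a k-mer-mode cluster: L_c - n*k."""
    n_f = cluster.length - cluster.n * k
    if n_f < 0:
        raise RuntimeError(
            "negative failure count: overlapping occurrences in cluster "
            f"{cluster.seq_id}:{cluster.start}-{cluster.end}"
        )
    return n_f


def failures_element(cluster: Cluster, elements: ElementSet) -> int:
    """Element-mode failures: ceiling(L_no / L_mean).

    L_no is the number of cluster bases not covered by any member
    element; L_mean the mean element length of the analysis scope.
    """
    if elements.L_mean <= 0:
        raise DegenerateInputError("mean element length must be positive")
    covered = _union_coverage(cluster.members, cluster.start, cluster.end)
    l_no = cluster.length - covered
    assert l_no >= 0
    return math.ceil(l_no / elements.L_mean)


def _union_coverage(intervals: Sequence, lo: int, hi: int) -> int:
    """Total bases of [lo,hi) covered by the union of intervals."""
    covered = 0
    cursor = lo
    for iv in sorted(intervals, key=lambda x: x.start):
        s, e = max(iv.start, cursor), min(iv.end, hi)
        if e > s:
            covered += e - s
            cursor = e
    return covered


def success_prob_element(elements: ElementSet, L_s: int) -> float:
    """Element-mode success probability p = N * L_mean / L_s."""
    p = elements.N * elements.L_mean / L_s
    if p >= 1.0:
        raise DegenerateInputError(
            f"element success probability {p:.3g} >= 1: elements cover the "
            "sequence; no meaningful null model exists"
        )
    if p <= 0.0:
        raise DegenerateInputError("element success probability is zero")
    return p


def negbin_pvalue(n: int, n_f: int, p: float) -> float:
    """P(X <= n_f) for X ~ NegBin(r = n-1 successes, success prob p).

    pmf(x) = C(x + r - 1, r - 1) * p^r * (1-p)^x.  Evaluated in log
    space with log-gamma and logsumexp so that clusters with hundreds of
    members do not underflow.  Result lies in (0, 1]; values below the
    smallest positive double are floored at 5e-324.
    """
    if n < 2:
        raise ValueError("a cluster needs n >= 2 occurrences")
    if n_f < 0:
        raise ValueError("failure count must be >= 0")
    if not 0.0 < p < 1.0:
        raise ValueError(f"success probability {p} outside (0,1)")
    r = n - 1
    x = np.arange(n_f + 1)
    log_terms = (
        gammaln(x + r)
        - gammaln(r)
        - gammaln(x + 1)
        + r * math.log(p)
        + x * math.log1p(-p)
    )
    return float(min(1.0, max(math.exp(logsumexp(log_terms)), 5e-324)))


def filter_significant(clusters: Sequence[Cluster], alpha: float) -> list[Cluster]:
    """Keep clusters with p_value <= alpha, preserving order."""
    if not 0.0 < alpha <= 1.0:
        raise ValueError(f"alpha {alpha} outside (0,1]")
    return [c for c in clusters if c.p_value is not None and c.p_value <= alpha]
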