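"""Inter-copy distances, observed vs expected distributions, and d_max.

The distance between consecutive copies is "start of the downstream copy
minus end of the upstream copy" in 1-based inclusive arithmetic, so two
abutting copies are at distance 1.  Under the internal 0-based half-open
convention this is start_down - end_up + 1.

The expected inter-copy distance law is geometric, p*(1-p)^(d-1): the
unique memoryless inter-arrival distribution consistent with a Bernoulli
success probability p per candidate slot.  The maximum distance d_max
separating intra- from inter-cluster gaps can be taken as a percentile
of the observed distribution, as the crossing point between the observed
and expected curves (per chromosome or genome-wide), or fixed by the
user.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

__all__ = [
    "DistanceDistribution",
    "DistanceModelSpec",
    "MODELS",
    "distances",
    "expected_pmf",
    "percentile_distance",
    "intersection_distance",
    "resolve_dmax",
]

logger = logging.getLogger(__name__)

MODELS = ("percentile", "chrom_intersection", "genome_intersection", "fixed")


@dataclass
class DistanceDistribution:
    """Histogram of inter-copy distances with its matched expected curve."""

    counts: dict[int, int]
    total: int
    p_success: float | None = None

    @classmethod
    def from_distances(cls, dists: Sequence[int],
                       p_success: float | None = None) -> "DistanceDistribution":
        if any(d < 1 for d in dists):
            raise ValueError("distances must be >= 1")
        counts = dict(Counter(dists))
        return cls(counts=counts, total=len(dists), p_success=p_success)

    def observed_freq(self, d: int) -> float:
        return self.counts.get(d, 0) / self.total

    def merged_with(self, other: "DistanceDistribution") -> "DistanceDistribution":
        """Union of two distance multisets (sum of counts)."""
        counts = Counter(self.counts)
        counts.update(other.counts)
        return DistanceDistribution(dict(counts), self.total + other.total)


@dataclass
class DistanceModelSpec:
    """Which of the four maximum-distance models to apply."""

    model: str
    percentile_value: float | None = None
    fixed_distance: int | None = None

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ValueError(f"unknown distance model {self.model!r}")
        if self.model == "percentile":
            if self.percentile_value is None:
                raise ValueError("percentile model needs percentile_value")
            if not 0.0 < self.percentile_value <= 100.0:
                raise ValueError("percentile must lie in (0, 100]")
        if self.model == "fixed" and self.fixed_distance is None:
            raise ValueError("fixed model needs fixed_distance")


def distances(occurrences: Sequence) -> list[int]:
    """Distances between consecutive occurrences of one contig.

    Abutting copies give 1; for genomic elements that overlap (possible
    in real annotations) the distance is clamped to that minimum, so
    overlapping elements always co-cluster.
    """
    out = []
    for up, down in zip(occurrences, occurrences[1:]):
        out.append(max(1, down.start - up.end + 1))
    return out


def expected_pmf(d: int, p_success: float) -> float:
    """Geometric inter-arrival probability p*(1-p)^(d-1) at distance d >= 1."""
    if not 0.0 < p_success < 1.0:
        raise ValueError(f"success probability {p_success} outside (0,1)")
    if d < 1:
        raise ValueError("distance must be >= 1")
    return p_success * (1.0 - p_success) ** (d - 1)


def percentile_distance(dist: DistanceDistribution, q: float) -> int:
    """Nearest-rank percentile: smallest d with cumulative freq >= q/100."""
    if dist.total < 1:
        raise ValueError("empty distance distribution")
    if not 0.0 < q <= 100.0:
        raise ValueError("percentile must lie in (0, 100]")
    cum = 0
    for d in sorted(dist.counts):
        cum += dist.counts[d]
        if cum * 100.0 >= q * dist.total:
            return d
    return max(dist.counts)  # unreachable for valid q


def intersection_distance(dist: DistanceDistribution) -> int:
    """Crossing point of the observed and expected distance distributions.

    Scanning d = 1, 2, ... over the observed support, returns the first d
    where the normalized observed frequency drops below the expected
    geometric pmf after at least one occupied d where the observed curve
    lay strictly above the expected one — the reversal point beyond which
    copies are no longer clustered.  Exact equality does not count as
    enrichment (coinciding curves carry no cluster signal).  Degenerate
    data with no strict exceedance falls back to the median (the
    classical approximation to the intersection), with a logged warning.
    """
    if dist.total < 1:
        raise ValueError("empty distance distribution")
    if dist.p_success is None:
        raise ValueError("distribution carries no success probability")
    armed = False
    for d in range(1, max(dist.counts) + 2):
        obs = dist.observed_freq(d)
        exp = expected_pmf(d, dist.p_success)
        if dist.counts.get(d, 0) > 0 and obs > exp:
            armed = True
        elif armed and obs < exp:
            return d
    fallback = percentile_distance(dist, 50.0)
    logger.warning(
        "no observed/expected crossing found (no short-distance enrichment); "
        "falling back to the median d_max=%d", fallback,
    )
    return fallback


def resolve_dmax(
    spec: DistanceModelSpec,
    seq_distances: Mapping[str, Sequence[int]],
    seq_p: Mapping[str, float],
    genome_p: float | None = None,
    unit: float = 1.0,
) -> dict[str, tuple[int, float]]:
    """Resolve (d_max, p) for every sequence under the chosen model.

    percentile / chrom_intersection / fixed use each sequence's own
    distance distribution and success probability; genome_intersection
    merges all distance multisets and applies one genome-wide threshold
    and probability (``genome_p``, computed from summed N and L_s).

    ``unit`` is 1 for k-mer mode.  In element mode it is L_mean: for the
    intersection models, distances are first converted to failure units
    ceiling(d/L_mean), the crossing u is found on the unit histogram, and
    the bp threshold is floor(u*L_mean) — the largest distance whose unit
    count does not exceed u.
    """
    out: dict[str, tuple[int, float]] = {}
    if spec.model == "fixed":
        for sid in seq_distances:
            out[sid] = (int(spec.fixed_distance), seq_p[sid])
        return out
    if spec.model == "percentile":
        for sid, dists in seq_distances.items():
            dd = DistanceDistribution.from_distances(dists)
            out[sid] = (percentile_distance(dd, spec.percentile_value), seq_p[sid])
        return out
    if spec.model == "chrom_intersection":
        for sid, dists in seq_distances.items():
            d_max = _intersection_bp(dists, seq_p[sid], unit)
            out[sid] = (d_max, seq_p[sid])
        return out
    # genome_intersection
    if genome_p is None:
        raise ValueError("genome_intersection model needs a genome-wide p")
    merged = [d for dists in seq_distances.values() for d in dists]
    d_max = _intersection_bp(merged, genome_p, unit)
    for sid in seq_distances:
        out[sid] = (d_max, genome_p)
    return out


def _intersection_bp(dists: Sequence[int], p: float, unit: float) -> int:
    if unit <= 1.0:
        dd = DistanceDistribution.from_distances(dists, p_success=p)
        return intersection_distance(dd)
    units = [math.ceil(d / unit) for d in dists]
    dd = DistanceDistribution.from_distances(units, p_success=p)
    u_cross = intersection_distance(dd)
    return max(1, math.floor(u_cross * unit))
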