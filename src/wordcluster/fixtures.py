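"""Synthetic FASTA/BED inputs with known (planted) cluster structure.

make_sequence plants dense blocks of target-word copies inside chosen
windows over a random background in which the same words appear at a
controlled Bernoulli rate, so that the whole pipeline can be exercised
and its recovery measured without any real genome.  All randomness comes
from one numpy Generator seeded per call; identical seeds give identical
bytes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io_formats import Contig, Interval
from .kmer_scan import Occurrence, WordSet, scan

__all__ = ["PlantSpec", "SimulatedSequence", "make_sequence", "make_elements"]

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class PlantSpec:
    """Layout of one synthetic sequence.

    background_rate is the expected number of target-word copies per kb
    outside the planted windows; inside each (start, end, copies) window
    the copies are laid down left to right with uniform gaps of at most
    max_gap intervening bases (inter-copy distances <= max_gap + 1).
    """

    seq_length: int
    words: WordSet
    cluster_windows: tuple[tuple[int, int, int], ...] = ()
    background_rate: float = 0.5
    max_gap: int = 5
    seq_id: str = "sim"

    def __post_init__(self) -> None:
        prev_end = 0
        for start, end, copies in sorted(self.cluster_windows):
            if start < prev_end:
                raise ValueError("cluster windows must be disjoint")
            if end > self.seq_length:
                raise ValueError("window extends past the sequence")
            if copies * self.words.k > end - start:
                raise ValueError(
                    f"window [{start},{end}) too short for {copies} copies"
                )
            prev_end = end


@dataclass
class SimulatedSequence:
    """A synthetic sequence, its planted windows, and the realized truth."""

    seq_id: str
    sequence: str
    windows: list[Interval]
    occurrences: list[Occurrence] = field(repr=False, default_factory=list)


def make_sequence(spec: PlantSpec, seed: int) -> SimulatedSequence:
    """Generate one sequence with planted word clusters.

    The filler is uniform random ACGT; a repair pass mutates any
    accidental target match outside the intended placements so that the
    realized background stays at the requested rate.  The truth recorded
    is the actual post-repair occurrence set found by the scanner.
    """
    rng = np.random.default_rng(seed)
    k = spec.words.k
    seq = rng.choice(_BASES, size=spec.seq_length)
    intended = np.zeros(spec.seq_length, dtype=bool)

    def plant(pos: int) -> None:
        word = spec.words.words[rng.integers(len(spec.words.words))]
        seq[pos:pos + k] = np.frombuffer(word.encode(), dtype="S1")
        intended[pos:pos + k] = True

    windows = []
    in_window = np.zeros(spec.seq_length, dtype=bool)
    for start, end, copies in sorted(spec.cluster_windows):
        in_window[start:end] = True
        windows.append(Interval(spec.seq_id, start, end, f"planted_{copies}"))
        slack = (end - start) - copies * k
        pos = start
        for i in range(copies):
            plant(pos)
            pos += k
            if i < copies - 1:
                gap = int(rng.integers(0, min(spec.max_gap, slack) + 1))
                pos += gap
                slack -= gap

    # Bernoulli background outside the windows
    p_bg = spec.background_rate / 1000.0
    if p_bg > 0:
        hits = np.flatnonzero(rng.random(spec.seq_length) < p_bg)
        for pos in hits:
            if pos + k > spec.seq_length:
                continue
            if in_window[pos:pos + k].any() or intended[max(0, pos - k + 1):pos + k].any():
                continue
            plant(int(pos))

    _repair(seq, intended, spec.words, rng)

    sequence = seq.tobytes().decode()
    contig = Contig(spec.seq_id, 0, spec.seq_length, sequence)
    return SimulatedSequence(
        seq_id=spec.seq_id,
        sequence=sequence,
        windows=windows,
        occurrences=scan(contig, spec.words),
    )


def _repair(seq: np.ndarray, intended: np.ndarray, words: WordSet,
            rng: np.random.Generator, max_rounds: int = 20) -> None:
    """Mutate accidental target matches that touch no intended placement."""
    k = words.k
    targets = {w.encode() for w in words.words}
    for _ in range(max_rounds):
        dirty = False
        text = seq.tobytes()
        for pos in range(len(text) - k + 1):
            if text[pos:pos + k] in targets and not intended[pos:pos + k].any():
                j = pos + k // 2
                old = seq[j]
                choices = _BASES[_BASES != old]
                seq[j] = rng.choice(choices)
                dirty = True
        if not dirty:
            return


def make_elements(
    n_elements: int,
    L_mean: int,
    cluster_layout: Sequence[tuple[int, int, int]],
    seq_length: int,
    seed: int,
    seq_id: str = "sim",
    background_gap: int | None = None,
) -> tuple[list[Interval], list[Interval]]:
    """Genomic elements with controlled inter-element distances.

    cluster_layout is a list of (start, n_in_block, gap_bp) blocks: each
    block holds n_in_block elements of exactly L_mean bp separated by
    gap_bp intervening bases, so its span is n*L_mean + (n-1)*gap_bp.
    The remaining elements are scattered outside the blocks at random
    positions at least ``background_gap`` (default 10*L_mean) apart.
    Returns (elements, truth block spans).
    """
    rng = np.random.default_rng(seed)
    elements: list[Interval] = []
    truth: list[Interval] = []
    occupied: list[tuple[int, int]] = []
    placed = 0
    for start, n_block, gap in sorted(cluster_layout):
        span = n_block * L_mean + (n_block - 1) * gap
        if start + span > seq_length:
            raise ValueError(f"block at {start} (span {span}) exceeds sequence")
        if any(s < start + span and start < e for s, e in occupied):
            raise ValueError("cluster blocks overlap")
        pos = start
        for _ in range(n_block):
            elements.append(Interval(seq_id, pos, pos + L_mean, "elem"))
            pos += L_mean + gap
        occupied.append((start, start + span))
        truth.append(Interval(seq_id, start, start + span, f"block_{n_block}"))
        placed += n_block
    if placed > n_elements:
        raise ValueError("cluster_layout places more elements than n_elements")

    min_gap = background_gap if background_gap is not None else 10 * L_mean
    remaining = n_elements - placed
    attempts = 0
    while remaining > 0:
        attempts += 1
        if attempts > 1000 * n_elements:
            raise ValueError("could not place background elements; layout infeasible")
        pos = int(rng.integers(0, seq_length - L_mean + 1))
        lo, hi = pos - min_gap, pos + L_mean + min_gap
        if any(s < hi and lo < e for s, e in occupied):
            continue
        elements.append(Interval(seq_id, pos, pos + L_mean, "elem"))
        occupied.append((pos, pos + L_mean))
        remaining -= 1
    elements.sort(key=lambda iv: (iv.start, iv.end))
    return elements, truth
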