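"""Non-overlapping detection of target words within contigs.

The scan is greedy and left-to-right: once a copy is found, the search
resumes at the end of the word, so copies never overlap.  All target
words must share one length k; degenerate IUPAC patterns (e.g. CWG) are
expanded to their concrete A/C/G/T word set first.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Sequence

from .cluster_core import DegenerateInputError, SequenceStats
from .io_formats import Contig

__all__ = ["WordSet", "Occurrence", "expand_iupac", "make_wordset", "scan",
           "count_stats"]

IUPAC_CODES: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


@dataclass(frozen=True)
class WordSet:
    """A set of equal-length concrete target words."""

    words: tuple[str, ...]
    k: int


@dataclass(frozen=True)
class Occurrence:
    """One non-overlapping match of a target word."""

    seq_id: str
    start: int
    end: int
    word: str


def expand_iupac(pattern: str) -> WordSet:
    """Expand a degenerate IUPAC pattern into its concrete word set.

    "CWG" -> {CAG, CTG}; a plain A/C/G/T word expands to itself.
    """
    pattern = pattern.upper()
    try:
        choices = [IUPAC_CODES[c] for c in pattern]
    except KeyError as exc:
        raise ValueError(
            f"invalid IUPAC character {exc.args[0]!r} in pattern {pattern!r}"
        ) from None
    if not pattern:
        raise ValueError("empty pattern")
    words = sorted({"".join(w) for w in itertools.product(*choices)})
    return WordSet(tuple(words), len(pattern))


def make_wordset(words: Iterable[str]) -> WordSet:
    """Validate and deduplicate explicit target words (all of one length).

    Target words of unequal length are rejected: the failure count
    n_f = L_c - n*k and the slot arithmetic of the success probability
    are only defined for a single k.
    """
    cleaned = sorted({w.upper() for w in words})
    if not cleaned:
        raise ValueError("no target words given")
    lengths = {len(w) for w in cleaned}
    if len(lengths) != 1:
        raise ValueError(f"target words must share one length, got {sorted(lengths)}")
    k = lengths.pop()
    if k < 1:
        raise ValueError("empty target word")
    bad = [w for w in cleaned if set(w) - set("ACGT")]
    if bad:
        raise ValueError(
            f"words {bad} contain non-ACGT characters; expand IUPAC patterns "
            "with expand_iupac first"
        )
    return WordSet(tuple(cleaned), k)


def scan(contig: Contig, words: WordSet) -> list[Occurrence]:
    """Greedy left-to-right non-overlapping scan of one contig.

    At position i: if the window of k bases matches any target word, an
    occurrence is emitted and the scan resumes at i+k, else at i+1.
    """
    k = words.k
    targets = set(words.words)
    bases = contig.bases
    out: list[Occurrence] = []
    i, limit = 0, len(bases) - k
    while i <= limit:
        window = bases[i:i + k]
        if window in targets:
            out.append(
                Occurrence(contig.seq_id, contig.start + i, contig.start + i + k, window)
            )
            i += k
        else:
            i += 1
    return out


def count_stats(occurrences: Sequence[Occurrence], contigs: Sequence[Contig],
                k: int) -> SequenceStats:
    """Per-scope totals N, L_s and success probability p for k-mer mode.

    p = N / ((L_s - k + 1) - N*(k - 1)): the number of target copies over
    the number of candidate k-mer slots, with the k-1 positions consumed
    by each non-overlapping copy removed from the denominator.  Slots are
    counted within contigs (sum of max(0, len - k + 1) per contig): Ns
    are never candidate positions, so counting them would bias p down.
    """
    N = len(occurrences)
    L_s = sum(len(c) for c in contigs)
    slots = sum(max(0, len(c) - k + 1) for c in contigs)
    denom = slots - N * (k - 1)
    if denom <= 0:
        raise DegenerateInputError(
            f"no free k-mer slots (slots={slots}, N={N}, k={k}): sequence too "
            "short or saturated with target words"
        )
    p = N / denom
    if p >= 1.0:
        raise DegenerateInputError(
            f"k-mer success probability {p:.3g} >= 1: sequence saturated with "
            "target words; no meaningful null model exists"
        )
    if p <= 0.0:
        raise DegenerateInputError("no target occurrences found")
    return SequenceStats(N=N, L_s=L_s, p=p)
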