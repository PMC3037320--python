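"""Shared helpers: independent brute-force references for scan and clustering."""

from __future__ import annotations

import pytest


def brute_force_scan(seq: str, words: list[str]) -> list[tuple[int, int]]:
    """Greedy non-overlapping matching by explicit per-window comparison."""
    k = len(words[0])
    out: list[tuple[int, int]] = []
    last_end = 0
    for i in range(len(seq) - k + 1):
        if i >= last_end and any(seq[i:i + k] == w for w in words):
            out.append((i, i + k))
            last_end = i + k
    return out


def brute_force_clusters(spans: list[tuple[int, int]], d_max: int
                         ) -> list[tuple[int, int, int]]:
    """All maximal runs with every consecutive gap distance <= d_max.

    Enumerates every contiguous subrange and keeps those that qualify and
    cannot be extended.  Returns (start, end, n) triples for runs of >= 2.
    """
    m = len(spans)
    dist = [spans[i + 1][0] - spans[i][1] + 1 for i in range(m - 1)]
    out = []
    for i in range(m):
        for j in range(i + 1, m):
            if all(d <= d_max for d in dist[i:j]):
                left_max = i == 0 or dist[i - 1] > d_max
                right_max = j == m - 1 or dist[j] > d_max
                if left_max and right_max:
                    out.append((spans[i][0], spans[j][1], j - i + 1))
    return out


@pytest.fixture
def write_fasta(tmp_path):
    def _write(records, name="test.fa"):
        path = tmp_path / name
        with open(path, "w") as fh:
            for seq_id, seq in records:
                fh.write(f">{seq_id}\n{seq}\n")
        return path
    return _write
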