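"""Difficulty Predictor (DP): minimal-cost segmentation of a binary string.

A string is partitioned into contiguous segments of two kinds:

* **uniform** — a constant block of one symbol (any length >= 1), cost 1;
* **alternating** — a block whose adjacent symbols all differ, length >= 3,
  cost 2.

DP is the minimum total cost over all such partitions: the number of runs
kept as runs, plus twice the number of alternating blocks.  A length-2
"alternation" would cost exactly the same as its two runs, so admitting it
only creates ties; requiring length >= 3 makes the minimal partition
canonical without changing any score.

``dp_score`` solves this by dynamic programming over cut points; the
exponential ``dp_bruteforce`` enumerates every valid partition directly and
serves as an independent oracle for short strings.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

from .binseq import BinarySequence

__all__ = ["Segment", "Segmentation", "dp_score", "dp_bruteforce"]

MIN_ALTERNATING_LEN = 3
_UNIFORM_COST = 1
_ALTERNATING_COST = 2


@dataclass(frozen=True)
class Segment:
    start: int
    end: int  # exclusive
    kind: Literal["uniform", "alternating"]

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Segmentation:
    """A contiguous partition of [0, n) with its total cost."""

    segments: tuple[Segment, ...]
    cost: int

    def __post_init__(self) -> None:
        pos = 0
        for seg in self.segments:
            if seg.start != pos or seg.end <= seg.start:
                raise ValueError("segments must partition the string contiguously")
            pos = seg.end


def _extent_tables(bits: tuple[int, ...]) -> tuple[list[int], list[int]]:
    """Per end-position i (1-based prefix length): the longest uniform and the
    longest alternating block ending exactly at i."""
    n = len(bits)
    uni = [1] * (n + 1)
    alt = [1] * (n + 1)
    for i in range(2, n + 1):
        if bits[i - 1] == bits[i - 2]:
            uni[i] = uni[i - 1] + 1
        if bits[i - 1] != bits[i - 2]:
            alt[i] = alt[i - 1] + 1
    return uni, alt


def dp_score(seq: BinarySequence) -> tuple[int, Segmentation]:
    """Minimal segmentation cost and one partition achieving it, in O(n²).

    The score is unique; among minimal partitions the reported one prefers
    fewer alternating blocks, then longer (earlier-starting) segments.
    """
    bits = seq.bits
    n = len(bits)
    uni, alt = _extent_tables(bits)

    INF = (n + 10, n + 10)
    # best[i] = (cost, #alternating blocks) of the optimal prefix partition
    best: list[tuple[int, int]] = [INF] * (n + 1)
    best[0] = (0, 0)
    # parent[i] = (j, kind) of the chosen last segment [j, i)
    parent: list[tuple[int, str] | None] = [None] * (n + 1)

    for i in range(1, n + 1):
        choice = INF
        pick: tuple[int, str] | None = None
        # uniform last segment, longest first so ties keep the longest
        for length in range(uni[i], 0, -1):
            j = i - length
            cand = (best[j][0] + _UNIFORM_COST, best[j][1])
            if cand < choice:
                choice, pick = cand, (j, "uniform")
        # alternating last segment, length >= 3, longest first
        for length in range(alt[i], MIN_ALTERNATING_LEN - 1, -1):
            j = i - length
            cand = (best[j][0] + _ALTERNATING_COST, best[j][1] + 1)
            if cand < choice:
                choice, pick = cand, (j, "alternating")
        best[i] = choice
        parent[i] = pick

    segments: list[Segment] = []
    i = n
    while i > 0:
        j, kind = parent[i]  # type: ignore[misc]
        segments.append(Segment(j, i, kind))  # type: ignore[arg-type]
        i = j
    segments.reverse()
    score = best[n][0]
    return score, Segmentation(tuple(segments), score)


def dp_bruteforce(seq: BinarySequence) -> int:
    """Exhaustive minimum cost over every valid partition (oracle, n <= 16).

    Recursively tries every admissible first segment and enumerates all
    partitions explicitly — no memoization, so it is independent of the
    dynamic program it checks.
    """
    bits = seq.bits
    n = len(bits)
    if n > 16:
        raise ValueError("brute-force oracle is limited to n <= 16")

    def longest_uniform_from(i: int) -> int:
        j = i + 1
        while j < n and bits[j] == bits[i]:
            j += 1
        return j - i

    def longest_alternating_from(i: int) -> int:
        j = i + 1
        while j < n and bits[j] != bits[j - 1]:
            j += 1
        return j - i

    def rec(i: int) -> int:
        if i == n:
            return 0
        out = n + 10
        for length in range(1, longest_uniform_from(i) + 1):
            out = min(out, _UNIFORM_COST + rec(i + length))
        max_alt = longest_alternating_from(i)
        for length in range(MIN_ALTERNATING_LEN, max_alt + 1):
            out = min(out, _ALTERNATING_COST + rec(i + length))
        return out

    return rec(0)
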