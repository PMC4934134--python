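"""Binary sequences and their run/digram statistics.

The central object is :class:`BinarySequence`, an immutable string over a
two-letter alphabet (canonically ``X``/``O``; ``H``/``T`` is a common alias
for coin-flip data).  Everything downstream — the entropy scores, the
Difficulty Predictor, the curve fitting — consumes either a sequence or one
of the probability vectors derived here.

Digrams are the overlapping ordered pairs of adjacent symbols: a length-*n*
sequence has exactly *n − 1* of them, falling into the four categories
XX, OO (uniform) and XO, OX (alternating).  The probability of alternation

    P(A) = (r − 1) / (n − 1)

with *r* the number of runs, equals the fraction of digrams that alternate.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np

__all__ = [
    "DEFAULT_ALPHABET",
    "DIGRAM_ORDER",
    "BinarySequence",
    "DigramTable",
    "parse_sequence",
    "prob_alternation",
    "digram_counts",
    "digram_dist",
    "first_order_dist",
    "expected_digram_dist",
    "complement",
    "reverse",
    "canonicalize",
    "read_sequences",
    "write_sequences",
]

DEFAULT_ALPHABET: tuple[str, str] = ("X", "O")

#: Canonical ordering of the four digram categories used by every
#: 4-component probability or weight vector in this package:
#: uniform pairs first (XX, OO), alternating pairs second (XO, OX).
DIGRAM_ORDER: tuple[str, str, str, str] = ("XX", "OO", "XO", "OX")


@dataclass(frozen=True)
class BinarySequence:
    """An ordered string of symbols over a two-letter alphabet.

    Symbols are stored as bits: 0 for the first alphabet letter, 1 for the
    second.  Instances are immutable and hashable.
    """

    bits: tuple[int, ...]
    alphabet: tuple[str, str] = DEFAULT_ALPHABET

    def __post_init__(self) -> None:
        if len(self.bits) < 1:
            raise ValueError("empty sequence")
        if any(b not in (0, 1) for b in self.bits):
            raise ValueError("bits must be 0 or 1")
        a, b = self.alphabet
        if a == b:
            raise ValueError("alphabet letters must be distinct")

    # -- basic views ---------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.bits)

    def __len__(self) -> int:
        return len(self.bits)

    @property
    def text(self) -> str:
        return "".join(self.alphabet[b] for b in self.bits)

    def __str__(self) -> str:
        return self.text

    @property
    def runs(self) -> int:
        """Number of runs r (maximal unbroken blocks of one symbol), 1 <= r <= n."""
        b = self.bits
        return 1 + sum(b[i] != b[i + 1] for i in range(len(b) - 1))

    def counts(self) -> tuple[int, int]:
        """Occurrences of (first letter, second letter)."""
        ones = sum(self.bits)
        return len(self.bits) - ones, ones

    # -- transforms ----------------------------------------------------
    def complement(self) -> "BinarySequence":
        """Swap the two symbols everywhere."""
        return BinarySequence(tuple(1 - b for b in self.bits), self.alphabet)

    def reverse(self) -> "BinarySequence":
        return BinarySequence(self.bits[::-1], self.alphabet)

    def relabel(self, alphabet: tuple[str, str]) -> "BinarySequence":
        """Same bit pattern under a different alphabet (positional mapping)."""
        return BinarySequence(self.bits, tuple(alphabet))  # type: ignore[arg-type]


@dataclass(frozen=True)
class DigramTable:
    """Counts of the four overlapping ordered symbol pairs of one sequence.

    Attribute names use the canonical X/O roles: ``xx`` counts first-letter
    pairs, ``ox`` counts (second letter, first letter) transitions, etc.
    For a length-n sequence the counts total n − 1, and xo + ox = r − 1.
    """

    xx: int
    oo: int
    xo: int
    ox: int

    def __post_init__(self) -> None:
        if min(self.xx, self.oo, self.xo, self.ox) < 0:
            raise ValueError("digram counts must be non-negative")

    @property
    def total(self) -> int:
        return self.xx + self.oo + self.xo + self.ox

    @property
    def n_alternating(self) -> int:
        return self.xo + self.ox

    def as_array(self) -> np.ndarray:
        """Counts in :data:`DIGRAM_ORDER`, i.e. (XX, OO, XO, OX)."""
        return np.array([self.xx, self.oo, self.xo, self.ox], dtype=float)


# ---------------------------------------------------------------------------
# parsing and IO
# ---------------------------------------------------------------------------

def parse_sequence(
    text: str,
    alphabet: tuple[str, str] = DEFAULT_ALPHABET,
    *,
    case_insensitive: bool = True,
) -> BinarySequence:
    """Parse a symbol string into a :class:`BinarySequence`.

    Whitespace (including internal separators) is stripped; matching is
    case-insensitive by default.  A foreign character raises ``ValueError``
    naming its 1-based position within the cleaned string.
    """
    cleaned = "".join(text.split())
    if case_insensitive:
        cleaned = cleaned.upper()
        lookup = {alphabet[0].upper(): 0, alphabet[1].upper(): 1}
    else:
        lookup = {alphabet[0]: 0, alphabet[1]: 1}
    if not cleaned:
        raise ValueError("empty sequence")
    bits = []
    for pos, ch in enumerate(cleaned, start=1):
        if ch not in lookup:
            raise ValueError(
                f"foreign symbol {ch!r} at position {pos} "
                f"(alphabet is {alphabet[0]}/{alphabet[1]})"
            )
        bits.append(lookup[ch])
    return BinarySequence(tuple(bits), tuple(alphabet))  # type: ignore[arg-type]


def read_sequences(
    path: str | Path,
    alphabet: tuple[str, str] = DEFAULT_ALPHABET,
    *,
    relabel_to: tuple[str, str] | None = None,
) -> list[BinarySequence]:
    """Read one sequence per line; blank lines and ``#`` comments are skipped.

    ``relabel_to`` positionally maps the file's alphabet onto another one
    (e.g. read H/T files and store them as X/O).
    """
    seqs = []
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        seq = parse_sequence(line, alphabet)
        if relabel_to is not None:
            seq = seq.relabel(relabel_to)
        seqs.append(seq)
    return seqs


def write_sequences(path: str | Path, seqs: Iterable[BinarySequence],
                    header: str | None = None) -> None:
    lines = []
    if header:
        lines.extend("# " + h for h in header.splitlines())
    lines.extend(s.text for s in seqs)
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------

def prob_alternation(seq: BinarySequence) -> float:
    """Probability of alternation P(A) = (r − 1)/(n − 1); needs n >= 2."""
    if seq.n < 2:
        raise ValueError("probability of alternation is undefined for length < 2")
    return (seq.runs - 1) / (seq.n - 1)


def digram_counts(seq: BinarySequence) -> DigramTable:
    """Counts of the n − 1 overlapping ordered pairs; needs n >= 2."""
    if seq.n < 2:
        raise ValueError("digram counts are undefined for length < 2")
    b = seq.bits
    c = [0, 0, 0, 0]  # indexed by 2*first + second
    for i in range(len(b) - 1):
        c[2 * b[i] + b[i + 1]] += 1
    # bit pairs: (0,0)=XX, (0,1)=XO, (1,0)=OX, (1,1)=OO
    return DigramTable(xx=c[0], oo=c[3], xo=c[1], ox=c[2])


def first_order_dist(seq: BinarySequence) -> np.ndarray:
    """Relative frequencies of (first letter, second letter); sums to 1."""
    n0, n1 = seq.counts()
    return np.array([n0, n1], dtype=float) / seq.n


def digram_dist(seq: BinarySequence) -> np.ndarray:
    """Digram probabilities in :data:`DIGRAM_ORDER`; sums to 1; needs n >= 2."""
    table = digram_counts(seq)
    return table.as_array() / table.total


def expected_digram_dist(pa: float, n_first: int = 11, n_second: int = 10) -> np.ndarray:
    """Analytic digram distribution of a stimulus level with alternation rate ``pa``.

    The alternating mass ``pa`` is split equally between XO and OX, the
    uniform mass ``1 − pa`` equally between XX and OO — within any single
    linear sequence the XO and OX counts differ by at most one, so the
    symmetric split is the natural stimulus-level idealization.  Returned in
    :data:`DIGRAM_ORDER`.
    """
    if not 0.0 <= pa <= 1.0:
        raise ValueError(f"probability of alternation must lie in [0, 1], got {pa}")
    if n_first + n_second < 2:
        raise ValueError("stimulus length must be at least 2")
    u = (1.0 - pa) / 2.0
    a = pa / 2.0
    return np.array([u, u, a, a])


# ---------------------------------------------------------------------------
# canonical forms
# ---------------------------------------------------------------------------

def complement(seq: BinarySequence) -> BinarySequence:
    return seq.complement()


def reverse(seq: BinarySequence) -> BinarySequence:
    return seq.reverse()


def canonicalize(seq: BinarySequence) -> BinarySequence:
    """The lexicographically smaller of a sequence and its symbol complement.

    Idempotent, and invariant under complementation: a pattern and its
    symbol-swapped twin (e.g. TTTTTTTT vs HHHHHHHH) map to the same
    representative.
    """
    comp = seq.complement()
    return comp if comp.text < seq.text else seq
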