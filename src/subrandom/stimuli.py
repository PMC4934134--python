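"""Stimulus generators: alternation-controlled string sets, the 128 canonical
octograms, and synthetic rating curves for parameter-recovery studies.

The classic randomness-perception design uses 21-symbol strings with a
near-even symbol split (11/10) whose probability of alternation is swept
over ten levels, 0.1 to 1.0 in steps of 0.1.  Each level fixes the exact
number of runs r = P(A)·(n − 1) + 1, so the generator samples uniformly
among strings with exactly that run count and symbol split (random
compositions of each symbol's count into its runs, interleaved).

``synth_rating_curve`` turns any entropy configuration into a fake observed
rating curve (model curve rescaled to the rating scale plus Gaussian
noise), giving the fitter a ground truth to recover.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Sequence

import numpy as np
import pandas as pd

from .binseq import (
    DEFAULT_ALPHABET,
    BinarySequence,
    canonicalize,
    prob_alternation,
)
from .defit import DEFAULT_PA_LEVELS, TargetCurve, model_curve, _minmax
from .entropy import EntropyConfig

__all__ = [
    "StimulusSet",
    "generate_fk_set",
    "enumerate_octograms",
    "synth_rating_curve",
]


@dataclass(frozen=True)
class StimulusSet:
    """A batch of generated sequences with their design metadata."""

    sequences: tuple[BinarySequence, ...]
    pa: tuple[float, ...]              # requested alternation level per sequence
    set_index: tuple[int, ...]         # which replicate set each sequence belongs to
    design: tuple[int, int, int]       # (length, majority count, minority count)
    seed: int | None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "set": self.set_index,
                "pa": self.pa,
                "sequence": [s.text for s in self.sequences],
            }
        )


def _composition(rng: np.random.Generator, total: int, parts: int) -> list[int]:
    """A uniform random composition of ``total`` into ``parts`` parts >= 1."""
    if parts == total:
        return [1] * parts
    cuts = np.sort(rng.choice(total - 1, size=parts - 1, replace=False)) + 1
    edges = np.concatenate(([0], cuts, [total]))
    return list(np.diff(edges))


def _build_sequence(
    rng: np.random.Generator,
    r: int,
    count_start: int,
    count_other: int,
    start_bit: int,
    alphabet: tuple[str, str],
) -> BinarySequence:
    runs_start = (r + 1) // 2
    runs_other = r // 2
    lens_start = _composition(rng, count_start, runs_start)
    lens_other = _composition(rng, count_other, runs_other) if runs_other else []
    bits: list[int] = []
    for k in range(r):
        if k % 2 == 0:
            bits.extend([start_bit] * lens_start[k // 2])
        else:
            bits.extend([1 - start_bit] * lens_other[k // 2])
    return BinarySequence(tuple(bits), alphabet)


def generate_fk_set(
    n_sets: int = 4,
    *,
    seed: int | np.random.SeedSequence | None = None,
    length: int = 21,
    split: tuple[int, int] = (11, 10),
    pa_levels: Sequence[float] | None = None,
    alphabet: tuple[str, str] = DEFAULT_ALPHABET,
) -> StimulusSet:
    """Generate ``n_sets`` replicate sets of alternation-controlled strings.

    Each set holds one sequence per P(A) level (default 0.1 … 1.0), of the
    given length, with an exact run count r = P(A)·(length − 1) + 1 and the
    majority/minority symbol split alternating across levels (11 X / 10 O
    at even levels, 10 X / 11 O at odd ones, by default).  The starting
    symbol also alternates across levels and sets where the run structure
    permits it.
    """
    if n_sets < 1:
        raise ValueError("n_sets must be >= 1")
    n_major, n_minor = split
    if n_major + n_minor != length:
        raise ValueError("symbol split must sum to the sequence length")
    levels = [float(pa) for pa in (pa_levels if pa_levels is not None else DEFAULT_PA_LEVELS)]
    rng = np.random.default_rng(seed)

    sequences: list[BinarySequence] = []
    pa_out: list[float] = []
    set_out: list[int] = []
    for s in range(n_sets):
        for k, pa in enumerate(levels):
            r_exact = pa * (length - 1) + 1
            r = round(r_exact)
            if abs(r_exact - r) > 1e-9 or not 1 <= r <= length:
                raise ValueError(
                    f"level P(A)={pa} needs a non-integer run count r={r_exact}"
                )
            # majority symbol alternates across levels; start alternates too,
            # falling back to the majority symbol when the run split demands it
            major_bit = k % 2
            counts = {major_bit: n_major, 1 - major_bit: n_minor}
            start_bit = (k + s) % 2
            runs_start = (r + 1) // 2
            if counts[start_bit] < runs_start or counts[1 - start_bit] < r // 2:
                start_bit = 1 - start_bit
            if counts[start_bit] < runs_start or counts[1 - start_bit] < r // 2:
                raise ValueError(
                    f"level P(A)={pa}: run count r={r} is infeasible for split {split}"
                )
            seq = _build_sequence(
                rng, r, counts[start_bit], counts[1 - start_bit], start_bit, alphabet
            )
            assert seq.n == length and seq.runs == r
            sequences.append(seq)
            pa_out.append(pa)
            set_out.append(s)

    return StimulusSet(
        sequences=tuple(sequences),
        pa=tuple(pa_out),
        set_index=tuple(set_out),
        design=(length, n_major, n_minor),
        seed=seed if isinstance(seed, (int, type(None))) else None,
    )


def enumerate_octograms(alphabet: tuple[str, str] = DEFAULT_ALPHABET) -> list[BinarySequence]:
    """All 128 canonical 8-symbol sequences, one per complement pair.

    The full space of length-8 binary strings has 256 members; each pattern
    and its symbol complement are perceptually equivalent, so only the
    canonical representative of each pair is kept.  Deterministic
    enumeration order (no randomness involved).
    """
    out = []
    for bits in product((0, 1), repeat=8):
        seq = BinarySequence(bits, alphabet)
        if canonicalize(seq) == seq:
            out.append(seq)
    return out


def synth_rating_curve(
    config: EntropyConfig,
    pa_levels: Sequence[float] | None = None,
    *,
    noise_sd: float = 0.0,
    rating_scale_max: float = 10.0,
    seed: int | None = None,
    stimulus_design: tuple[int, int, int] = (21, 11, 10),
) -> TargetCurve:
    """A synthetic observed rating curve drawn from a known entropy model.

    The model curve is min–max rescaled to [0, ``rating_scale_max``], then
    i.i.d. Gaussian noise of standard deviation ``noise_sd`` (rating units)
    is added and the result clipped back to the rating scale.  With
    ``noise_sd=0`` the curve is exactly the rescaled model prediction.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    levels = [float(pa) for pa in (pa_levels if pa_levels is not None else DEFAULT_PA_LEVELS)]
    curve = model_curve(config, levels, stimulus_design)
    ratings = _minmax(curve) * rating_scale_max
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        ratings = ratings + rng.normal(0.0, noise_sd, size=ratings.size)
        ratings = np.clip(ratings, 0.0, rating_scale_max)
    return TargetCurve(tuple(levels), tuple(float(x) for x in ratings), rating_scale_max)
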