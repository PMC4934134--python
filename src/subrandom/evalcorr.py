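"""Validation stage: score sequence inventories and correlate with behavior.

Given a table of sequences with an observed value each (a mean rating, or
the proportion of participants classifying the string as random), this
module computes one score column per configured measure — any entropy
configuration, plus optionally the Difficulty Predictor and P(A) — and the
Pearson product-moment correlation of each column with the observations.

Sequences too short for a measure (second-order entropy and P(A) need at
least two symbols) get a missing score and are dropped pairwise from that
column's correlation, with the usable count reported alongside r.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .binseq import BinarySequence, canonicalize, parse_sequence, prob_alternation
from .dpscore import dp_score
from .entropy import EntropyConfig, second_order

__all__ = ["RatingTable", "pearson_r", "score_table", "correlate"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RatingTable:
    """Sequences paired with an observed behavioral value each.

    Sequences must be unique up to complementation (a pattern and its
    symbol-swapped twin count as the same stimulus).
    """

    sequences: tuple[BinarySequence, ...]
    observed: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.sequences) != len(self.observed):
            raise ValueError("sequences and observed values must align")
        if len(self.sequences) == 0:
            raise ValueError("rating table is empty")
        if not np.all(np.isfinite(self.observed)):
            raise ValueError("observed values must be finite")
        seen: dict[str, str] = {}
        for seq in self.sequences:
            canon = canonicalize(seq).text
            if canon in seen:
                raise ValueError(
                    f"duplicate sequence after canonicalization: {seq.text} "
                    f"collides with {seen[canon]}"
                )
            seen[canon] = seq.text

    @classmethod
    def from_csv(
        cls,
        path: str | Path,
        alphabet: tuple[str, str] = ("X", "O"),
        *,
        relabel_to: tuple[str, str] | None = None,
    ) -> "RatingTable":
        """Read a CSV with columns ``sequence`` and ``observed``."""
        df = pd.read_csv(path, comment="#")
        missing = {"sequence", "observed"} - set(df.columns)
        if missing:
            raise ValueError(f"rating CSV is missing columns: {sorted(missing)}")
        seqs = []
        for text in df["sequence"]:
            seq = parse_sequence(str(text), alphabet)
            if relabel_to is not None:
                seq = seq.relabel(relabel_to)
            seqs.append(seq)
        return cls(tuple(seqs), tuple(float(v) for v in df["observed"]))


def pearson_r(x: Sequence[float] | np.ndarray, y: Sequence[float] | np.ndarray) -> float:
    """Pearson product-moment correlation; needs length >= 3 and variance."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1:
        raise ValueError("inputs must be 1-d vectors of equal length")
    if xa.size < 3:
        raise ValueError("correlation needs at least 3 points")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise ValueError("undefined correlation: an input has zero variance")
    return float(stats.pearsonr(xa, ya).statistic)


def score_table(
    table: RatingTable,
    configs: Mapping[str, EntropyConfig],
    *,
    include_dp: bool = True,
    include_pa: bool = True,
) -> pd.DataFrame:
    """One row per sequence: the observed value plus every configured score.

    Entropy and P(A) columns hold NaN for sequences shorter than 2 symbols;
    the Difficulty Predictor is defined down to length 1.
    """
    rows = []
    for seq, obs in zip(table.sequences, table.observed):
        row: dict = {"sequence": seq.text, "observed": obs}
        if include_pa:
            row["pa"] = prob_alternation(seq) if seq.n >= 2 else np.nan
        for name, config in configs.items():
            row[name] = second_order(seq, config) if seq.n >= 2 else np.nan
        if include_dp:
            row["dp"] = dp_score(seq)[0]
        rows.append(row)
    return pd.DataFrame(rows)


def correlate(scores: pd.DataFrame, observed_column: str = "observed") -> pd.DataFrame:
    """Pearson r of every score column against the observed column.

    Rows with a missing score are dropped pairwise per column (the count
    actually used is reported as ``n_used``).
    """
    measure_cols = [c for c in scores.columns if c not in ("sequence", observed_column)]
    obs = scores[observed_column].to_numpy(dtype=float)
    rows = []
    for col in measure_cols:
        vals = scores[col].to_numpy(dtype=float)
        mask = np.isfinite(vals) & np.isfinite(obs)
        dropped = int((~mask).sum())
        if dropped:
            logger.info("measure %s: dropped %d rows with undefined scores", col, dropped)
        try:
            r = pearson_r(vals[mask], obs[mask])
        except ValueError:
            r = float("nan")  # fewer than 3 usable rows, or zero variance
        rows.append({"measure": col, "r": r, "n_used": int(mask.sum())})
    return pd.DataFrame(rows)
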