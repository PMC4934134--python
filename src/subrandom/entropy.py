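"""Entropy measures: Shannon, Rényi order-α, and Marcellin's asymmetric entropy.

All logarithms are base 2, so Shannon and Rényi values are in bits.
Marcellin's measure

    H_W(P) = Σ_i  p_i (1 − p_i) / ((1 − 2 w_i) p_i + w_i²)

is parameterized by a *worst distribution* W = (w_1, …, w_N), each w_i
strictly inside (0, 1): the measure attains its maximum when P sits at W
rather than at the uniform distribution, which is exactly what makes it
suitable for modeling the overalternating bias — people judge binary
strings with alternation rates around 0.6–0.7, not 0.5, as maximally
random.  W is a parameter vector and is not required to sum to 1.

The second-order entropy of a sequence is the digram entropy minus the
first-order (single-symbol) entropy; for Shannon this equals the
conditional entropy of the next symbol given the current one (chain rule),
for the other families the `difference` and `conditional` formulations
genuinely differ and both are provided.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .binseq import (
    DIGRAM_ORDER,
    BinarySequence,
    digram_dist,
    first_order_dist,
)

__all__ = [
    "RENYI_INF",
    "shannon_entropy",
    "renyi_entropy",
    "marcellin_entropy",
    "EntropyConfig",
    "second_order",
]

#: Sentinel for the α → ∞ (min-entropy) limit of the Rényi family.
RENYI_INF = math.inf

_DIST_TOL = 1e-9


def _as_dist(p: Sequence[float] | np.ndarray) -> np.ndarray:
    arr = np.asarray(p, dtype=float)
    if arr.ndim != 1 or arr.size < 1:
        raise ValueError("probability vector must be 1-dimensional and non-empty")
    if np.any(arr < -_DIST_TOL):
        raise ValueError("probability vector has negative mass")
    total = arr.sum()
    if abs(total - 1.0) > max(_DIST_TOL, 1e-9 * arr.size):
        raise ValueError(f"probability vector must sum to 1, got {total!r}")
    return np.clip(arr, 0.0, None)


def _as_worst(w: Sequence[float] | np.ndarray, n: int) -> np.ndarray:
    arr = np.asarray(w, dtype=float)
    if arr.shape != (n,):
        raise ValueError(f"worst distribution must have length {n}, got shape {arr.shape}")
    if np.any(arr <= 0.0) or np.any(arr >= 1.0):
        raise ValueError("worst-distribution weights must lie strictly inside (0, 1)")
    return arr


def shannon_entropy(p: Sequence[float] | np.ndarray) -> float:
    """Shannon entropy in bits, with the 0·log(1/0) := 0 convention."""
    arr = _as_dist(p)
    nz = arr[arr > 0.0]
    return float(-(nz * np.log2(nz)).sum())


def renyi_entropy(p: Sequence[float] | np.ndarray, alpha: float) -> float:
    """Rényi entropy of order α in bits.

    α = 0 gives Hartley entropy log2 of the support size, α → 1 the Shannon
    limit, α = 2 the collision entropy, and ``alpha=math.inf`` (an explicit
    sentinel, never inferred from magnitude) the min-entropy −log2 max p_i.
    """
    if alpha < 0:
        raise ValueError(f"Renyi order alpha must be non-negative, got {alpha}")
    arr = _as_dist(p)
    if alpha == RENYI_INF:
        return float(-np.log2(arr.max()))
    if alpha == 0.0:
        return float(np.log2(np.count_nonzero(arr > 0.0)))
    if abs(alpha - 1.0) < 1e-12:
        return shannon_entropy(arr)
    nz = arr[arr > 0.0]
    return float(np.log2((nz ** alpha).sum()) / (1.0 - alpha))


def marcellin_entropy(
    p: Sequence[float] | np.ndarray, w: Sequence[float] | np.ndarray
) -> float:
    """Marcellin's asymmetric entropy of P with worst distribution W.

    Non-negative on the whole simplex (the denominator is linear in p_i and
    positive at both endpoints: w_i² at p_i = 0 and (1 − w_i)² at p_i = 1),
    zero at any point mass, and equal to N when P = W.
    """
    arr = _as_dist(p)
    weights = _as_worst(w, arr.size)
    den = (1.0 - 2.0 * weights) * arr + weights**2
    return float((arr * (1.0 - arr) / den).sum())


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

_FAMILIES = ("shannon", "renyi", "marcellin")
_FORMULATIONS = ("difference", "conditional")


@dataclass(frozen=True)
class EntropyConfig:
    """Which entropy family to apply, with its parameters.

    ``weights`` is the Marcellin worst distribution over the four digram
    categories in the canonical order (XX, OO, XO, OX);
    ``first_order_weights`` is its 2-symbol counterpart used by the
    `difference` formulation's first-order term (default symmetric).
    """

    family: str
    alpha: float | None = None
    weights: tuple[float, float, float, float] | None = None
    first_order_weights: tuple[float, float] = (0.5, 0.5)
    formulation: str = "difference"

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown entropy family {self.family!r}")
        if self.formulation not in _FORMULATIONS:
            raise ValueError(f"unknown formulation {self.formulation!r}")
        if self.family == "renyi":
            if self.alpha is None:
                raise ValueError("renyi family requires alpha")
            if self.alpha < 0:
                raise ValueError("alpha must be non-negative")
        elif self.alpha is not None:
            raise ValueError(f"alpha is not a parameter of the {self.family} family")
        if self.family == "marcellin":
            if self.weights is None:
                raise ValueError("marcellin family requires the four digram weights")
            if len(self.weights) != 4:
                raise ValueError("marcellin digram weights must have length 4")
        elif self.weights is not None:
            raise ValueError(f"weights are not a parameter of the {self.family} family")

    # -- family dispatch ----------------------------------------------
    def evaluate(self, p: np.ndarray, w: Sequence[float] | None = None) -> float:
        """Apply the configured family to one probability vector.

        ``w`` is the worst distribution to use for this term (Marcellin
        only); Shannon and Rényi ignore it.
        """
        if self.family == "shannon":
            return shannon_entropy(p)
        if self.family == "renyi":
            return renyi_entropy(p, self.alpha)  # type: ignore[arg-type]
        assert w is not None
        return marcellin_entropy(p, w)

    # -- JSON interop (key names fixed for interoperability) ----------
    def to_dict(self) -> dict:
        out: dict = {"family": self.family, "formulation": self.formulation}
        if self.family == "renyi":
            out["alpha"] = self.alpha
        if self.family == "marcellin":
            out["weights"] = dict(zip(DIGRAM_ORDER, self.weights))  # type: ignore[arg-type]
            out["first_order_weights"] = list(self.first_order_weights)
        return out

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, **kwargs)

    @classmethod
    def from_dict(cls, d: dict) -> "EntropyConfig":
        weights = d.get("weights")
        if isinstance(weights, dict):
            weights = tuple(weights[k] for k in DIGRAM_ORDER)
        elif weights is not None:
            weights = tuple(weights)
        fow = d.get("first_order_weights", (0.5, 0.5))
        return cls(
            family=d["family"],
            alpha=d.get("alpha"),
            weights=weights,
            first_order_weights=tuple(fow),  # type: ignore[arg-type]
            formulation=d.get("formulation", "difference"),
        )

    @classmethod
    def from_json(cls, text: str) -> "EntropyConfig":
        return cls.from_dict(json.loads(text))


# ---------------------------------------------------------------------------
# second-order entropy
# ---------------------------------------------------------------------------

def _digram_first_marginal(digram: np.ndarray) -> np.ndarray:
    """Marginal of the first symbol under a digram distribution (XX,OO,XO,OX)."""
    return np.array([digram[0] + digram[2], digram[1] + digram[3]])


def second_order(
    seq_or_dists: BinarySequence | tuple[np.ndarray, np.ndarray],
    config: EntropyConfig,
) -> float:
    """Second-order entropy H2 of a sequence or a (digram, first-order) pair.

    ``difference``:  F(digram distribution) − F(first-order distribution),
    where F is the configured family (Marcellin applies ``weights`` to the
    digram term and ``first_order_weights`` to the symbol term).

    ``conditional``: Σ_s p(s) · F(next-symbol distribution | s), weighting
    by the digram first-symbol marginal; Marcellin uses the conditional
    worst distributions (w_XX, w_XO) given X and (w_OO, w_OX) given O.
    For Shannon the two formulations coincide by the chain rule whenever
    the supplied first-order distribution is the digram marginal.
    """
    if isinstance(seq_or_dists, BinarySequence):
        if seq_or_dists.n < 2:
            raise ValueError("second-order entropy needs a sequence of length >= 2")
        digram = digram_dist(seq_or_dists)
        first = first_order_dist(seq_or_dists)
    else:
        digram, first = seq_or_dists
        digram = _as_dist(digram)
        first = _as_dist(first)
        if digram.size != 4 or first.size != 2:
            raise ValueError("expected a 4-category digram and 2-category symbol distribution")

    if config.formulation == "difference":
        h_digram = config.evaluate(digram, config.weights)
        h_first = config.evaluate(first, config.first_order_weights)
        return h_digram - h_first

    # conditional formulation
    marginal = _digram_first_marginal(digram)
    total = 0.0
    cond_specs = (
        # (marginal index, digram indices (next=X, next=O), Marcellin worst pair)
        (0, (0, 2), None if config.weights is None else (config.weights[0], config.weights[2])),
        (1, (1, 3), None if config.weights is None else (config.weights[1], config.weights[3])),
    )
    for m_idx, (i_same, i_alt), w_pair in cond_specs:
        mass = marginal[m_idx]
        if mass <= 0.0:
            continue
        cond = np.array([digram[i_same], digram[i_alt]]) / mass
        total += mass * config.evaluate(cond, w_pair)
    return total
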