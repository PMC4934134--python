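"""Constrained Differential Evolution fitting of entropy models to rating curves.

The fitting target is a mean randomness-rating curve: ten P(A) levels, each
with a mean rating on a 0–10 scale.  An entropy model predicts, per level,
the second-order entropy of the analytic digram distribution at that level;
the fitness is the Euclidean distance between the (normalized) model curve
and the (normalized) target curve — lower is better.

The optimizer is classic DE/rand/1/bin: population of N vectors, mutant
v_m = v_1 + F·(v_2 − v_3), binomial crossover at rate CR with one forced
mutant component, greedy one-to-one selection.  Feasibility constraints
(relative-distance bounds tying psychologically equivalent digram weights
together, e.g. w_OO ≈ w_XX) are enforced by regenerating infeasible trial
vectors rather than by penalties.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .binseq import expected_digram_dist
from .entropy import EntropyConfig, second_order

__all__ = [
    "DEConfig",
    "ConstraintSpec",
    "MARCELLIN_CONSTRAINTS",
    "TargetCurve",
    "FitResult",
    "model_curve",
    "euclidean_fitness",
    "check_constraints",
    "convergence_check",
    "de_optimize",
    "tune_parameters",
    "fit_entropy",
]

DEFAULT_PA_LEVELS = tuple(np.round(np.arange(0.1, 1.01, 0.1), 10))
DEFAULT_STIMULUS_DESIGN = (21, 11, 10)  # (length, majority count, minority count)

NORMALIZATION_MODES = ("minmax_both", "ratings_div_scale", "none")


# ---------------------------------------------------------------------------
# configuration and result containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DEConfig:
    """Differential Evolution settings.

    Defaults follow the tuned operating point of the F × CR grid search
    (F = 0.6, CR = 0.9) with a population of 20 run for 100 generations.
    """

    pop_size: int = 20
    F: float = 0.6
    CR: float = 0.9
    generations: int = 100
    seed: int | np.random.SeedSequence | None = None
    max_retries: int = 100
    clip_to_bounds: bool = True
    force_crossover: bool = True

    def __post_init__(self) -> None:
        if self.pop_size < 4:
            raise ValueError("pop_size must be >= 4 (mutation needs target + 3 others)")
        if not 0.0 <= self.F <= 2.0:
            raise ValueError("differential weight F must lie in [0, 2]")
        if not 0.0 <= self.CR <= 1.0:
            raise ValueError("crossover rate CR must lie in [0, 1]")
        if self.generations < 1:
            raise ValueError("generations must be >= 1")


@dataclass(frozen=True)
class ConstraintSpec:
    """Pairwise relative-distance feasibility constraints.

    Each entry (i, j, tol) requires 2·|x_i − x_j| / (x_i + x_j) <= tol.
    A non-positive pair sum is treated as infeasible.
    """

    pairs: tuple[tuple[int, int, float], ...]

    def __post_init__(self) -> None:
        for i, j, tol in self.pairs:
            if tol <= 0:
                raise ValueError("constraint tolerance must be positive")

    def check(self, params: np.ndarray) -> bool:
        for i, j, tol in self.pairs:
            a, b = params[i], params[j]
            s = a + b
            if s <= 0.0 or 2.0 * abs(a - b) / s > tol:
                return False
        return True


#: Default Marcellin feasibility: uniform weights (w_XX, w_OO) within 10%
#: relative distance of each other, likewise the alternating pair (w_XO, w_OX).
#: Indices refer to the canonical digram order (XX, OO, XO, OX).
MARCELLIN_CONSTRAINTS = ConstraintSpec(((0, 1, 0.1), (2, 3, 0.1)))


def check_constraints(params: Sequence[float] | np.ndarray,
                      spec: ConstraintSpec | None) -> bool:
    """True iff every pairwise relative-distance constraint is satisfied."""
    if spec is None:
        return True
    return spec.check(np.asarray(params, dtype=float))


def convergence_check(run_best: float, global_best: float) -> bool:
    """A run converged if its best fitness is below the overall best plus 1%."""
    if run_best < 0 or global_best < 0:
        raise ValueError("fitness values must be non-negative")
    return run_best < global_best * 1.01


@dataclass(frozen=True)
class TargetCurve:
    """Mean rating per P(A) level — the curve an entropy model is fitted to."""

    pa_levels: tuple[float, ...]
    ratings: tuple[float, ...]
    rating_scale_max: float = 10.0

    def __post_init__(self) -> None:
        if len(self.pa_levels) != len(self.ratings):
            raise ValueError("pa_levels and ratings must have equal length")
        if len(self.pa_levels) < 2:
            raise ValueError("a target curve needs at least 2 points")
        levels = np.asarray(self.pa_levels, dtype=float)
        if np.any(levels < 0) or np.any(levels > 1):
            raise ValueError("P(A) levels must lie in [0, 1]")
        if np.any(np.diff(levels) <= 0):
            raise ValueError("P(A) levels must be strictly increasing")
        if not np.all(np.isfinite(self.ratings)):
            raise ValueError("ratings must be finite")

    @classmethod
    def from_csv(cls, path: str | Path, rating_scale_max: float = 10.0) -> "TargetCurve":
        """Read a curve from a CSV with columns ``pa`` and ``rating``."""
        df = pd.read_csv(path, comment="#")
        missing = {"pa", "rating"} - set(df.columns)
        if missing:
            raise ValueError(f"target CSV is missing columns: {sorted(missing)}")
        df = df.sort_values("pa")
        return cls(tuple(df["pa"]), tuple(df["rating"]), rating_scale_max)

    def to_csv(self, path: str | Path, header: str | None = None) -> None:
        lines = [f"# {h}" for h in (header.splitlines() if header else [])]
        lines.append("pa,rating")
        lines.extend(f"{pa:.10g},{r:.10g}" for pa, r in zip(self.pa_levels, self.ratings))
        Path(path).write_text("\n".join(lines) + "\n")


@dataclass(frozen=True)
class FitResult:
    """Outcome of one DE run: best member, its fitness, and diagnostics."""

    params: tuple[float, ...]
    fitness: float
    converged: bool | None
    generations_used: int
    history: tuple[float, ...]  # best population fitness after each generation
    config: DEConfig
    entropy_config: EntropyConfig | None = None

    def to_dict(self) -> dict:
        out = {
            "params": list(self.params),
            "fitness": self.fitness,
            "converged": self.converged,
            "generations_used": self.generations_used,
            "pop_size": self.config.pop_size,
            "F": self.config.F,
            "CR": self.config.CR,
            "seed": self.config.seed if not isinstance(self.config.seed, np.random.SeedSequence) else None,
        }
        if self.entropy_config is not None:
            out["entropy_config"] = self.entropy_config.to_dict()
        return out


# ---------------------------------------------------------------------------
# model curve and fitness
# ---------------------------------------------------------------------------

def _minmax(v: np.ndarray) -> np.ndarray:
    lo, hi = v.min(), v.max()
    if hi - lo <= 0:
        raise ValueError("cannot min–max normalize a constant vector")
    return (v - lo) / (hi - lo)


def model_curve(
    config: EntropyConfig,
    pa_levels: Sequence[float] = DEFAULT_PA_LEVELS,
    stimulus_design: tuple[int, int, int] = DEFAULT_STIMULUS_DESIGN,
    *,
    evaluation: str = "analytic",
    n_sets: int = 4,
    seed: int | None = None,
) -> np.ndarray:
    """Model-predicted second-order entropy at each P(A) level (raw units).

    ``evaluation="analytic"`` (default, deterministic) scores the idealized
    digram distribution of each level with a symmetric (0.5, 0.5) symbol
    marginal.  ``evaluation="stimuli"`` instead generates concrete stimulus
    sets and averages the per-sequence second-order entropy at each level.
    """
    n, n_first, n_second = stimulus_design
    levels = [float(pa) for pa in pa_levels]
    if evaluation == "analytic":
        first = np.array([0.5, 0.5])
        return np.array(
            [
                second_order((expected_digram_dist(pa, n_first, n_second), first), config)
                for pa in levels
            ]
        )
    if evaluation == "stimuli":
        from .stimuli import generate_fk_set  # local import: stimuli depends on this module

        stim = generate_fk_set(
            n_sets, seed=seed, length=n, split=(n_first, n_second), pa_levels=levels
        )
        values = np.zeros(len(levels))
        counts = np.zeros(len(levels))
        index = {pa: k for k, pa in enumerate(levels)}
        for seq, pa in zip(stim.sequences, stim.pa):
            k = index[float(pa)]
            values[k] += second_order(seq, config)
            counts[k] += 1
        return values / counts
    raise ValueError(f"unknown evaluation mode {evaluation!r}")


def euclidean_fitness(
    model: Sequence[float] | np.ndarray,
    target: Sequence[float] | np.ndarray,
    *,
    normalization: str = "minmax_both",
    rating_scale_max: float = 10.0,
) -> float:
    """Euclidean distance between a model curve and target ratings.

    Normalization modes (ratings are on an arbitrary 0–scale axis while
    entropies are in bits, so some alignment is required):

    * ``minmax_both`` (default): min–max normalize both vectors to [0, 1]
      over the evaluated levels — a pure shape comparison;
    * ``ratings_div_scale``: divide ratings by ``rating_scale_max`` and the
      model curve by its maximum;
    * ``none``: compare raw values.
    """
    m = np.asarray(model, dtype=float)
    t = np.asarray(target, dtype=float)
    if m.shape != t.shape:
        raise ValueError(f"length mismatch: model {m.shape} vs target {t.shape}")
    if normalization == "minmax_both":
        m, t = _minmax(m), _minmax(t)
    elif normalization == "ratings_div_scale":
        t = t / rating_scale_max
        peak = np.abs(m).max()
        if peak <= 0:
            raise ValueError("cannot scale an all-zero model curve")
        m = m / peak
    elif normalization != "none":
        raise ValueError(f"unknown normalization mode {normalization!r}")
    return float(np.linalg.norm(m - t))


# ---------------------------------------------------------------------------
# the optimizer
# ---------------------------------------------------------------------------

def _feasible_uniform(rng: np.random.Generator, lo: np.ndarray, hi: np.ndarray,
                      constraints: ConstraintSpec | None, cap: int = 100_000) -> np.ndarray:
    for _ in range(cap):
        v = rng.uniform(lo, hi)
        if check_constraints(v, constraints):
            return v
    raise RuntimeError("could not sample a feasible initial member; constraints too tight")


def de_optimize(
    objective: Callable[[np.ndarray], float],
    bounds: Sequence[tuple[float, float]],
    constraints: ConstraintSpec | None = None,
    config: DEConfig | None = None,
    *,
    reference_best: float | None = None,
) -> FitResult:
    """Minimize ``objective`` over a box with DE/rand/1/bin.

    Infeasible trial vectors are discarded and regenerated (fresh donor
    picks and crossover) up to ``config.max_retries`` times, after which
    the target member survives unchallenged.  Fully deterministic given
    ``config.seed``.  ``reference_best`` (e.g. the best fitness over a batch
    of runs) enables the ``converged`` flag via the +1% criterion.
    """
    config = config or DEConfig()
    lo = np.array([b[0] for b in bounds], dtype=float)
    hi = np.array([b[1] for b in bounds], dtype=float)
    if lo.size == 0 or np.any(~np.isfinite(lo)) or np.any(~np.isfinite(hi)) or np.any(hi <= lo):
        raise ValueError("bounds must be finite (low, high) pairs with high > low")
    dim = lo.size
    rng = np.random.default_rng(config.seed)

    pop = np.array(
        [_feasible_uniform(rng, lo, hi, constraints) for _ in range(config.pop_size)]
    )
    fit = np.array([objective(v) for v in pop], dtype=float)

    history: list[float] = []
    indices = np.arange(config.pop_size)
    for _ in range(config.generations):
        for t in range(config.pop_size):
            others = indices[indices != t]
            trial = None
            for _attempt in range(config.max_retries):
                i1, i2, i3 = rng.choice(others, size=3, replace=False)
                mutant = pop[i1] + config.F * (pop[i2] - pop[i3])
                if config.clip_to_bounds:
                    mutant = np.clip(mutant, lo, hi)
                cross = rng.random(dim) < config.CR
                if config.force_crossover:
                    cross[rng.integers(dim)] = True
                candidate = np.where(cross, mutant, pop[t])
                if check_constraints(candidate, constraints):
                    trial = candidate
                    break
            if trial is None:
                continue  # retries exhausted: the target survives the duel
            f_trial = objective(trial)
            if f_trial <= fit[t]:
                pop[t] = trial
                fit[t] = f_trial
        history.append(float(fit.min()))

    best_idx = int(np.argmin(fit))
    best_fitness = float(fit[best_idx])
    converged = None if reference_best is None else convergence_check(best_fitness, reference_best)
    return FitResult(
        params=tuple(float(x) for x in pop[best_idx]),
        fitness=best_fitness,
        converged=converged,
        generations_used=len(history),
        history=tuple(history),
        config=config,
    )


# ---------------------------------------------------------------------------
# F × CR tuning grid
# ---------------------------------------------------------------------------

F_GRID = tuple(np.round(np.arange(0.1, 2.01, 0.1), 10))   # 20 values
CR_GRID = tuple(np.round(np.arange(0.1, 0.91, 0.1), 10))  # 9 values


def tune_parameters(
    objective: Callable[[np.ndarray], float],
    bounds: Sequence[tuple[float, float]],
    constraints: ConstraintSpec | None = None,
    *,
    runs_per_cell: int = 10,
    generations: int = 100,
    pop_size: int = 20,
    seed: int = 0,
) -> tuple[pd.DataFrame, tuple[float, float]]:
    """Grid-search F × CR (20 × 9 = 180 cells), ``runs_per_cell`` runs each.

    A run counts as converged at the first generation whose best population
    fitness drops below the best fitness over *all* runs plus 1%.  Returns
    the grid as a DataFrame (columns F, CR, converge_pct, mean_generations)
    and the selected (F, CR): highest convergence rate, ties broken by
    fewest mean generations.
    """
    if runs_per_cell < 1:
        raise ValueError("runs_per_cell must be >= 1")
    ss = np.random.SeedSequence(seed)
    children = iter(ss.spawn(len(F_GRID) * len(CR_GRID) * runs_per_cell))
    runs: list[tuple[float, float, tuple[float, ...]]] = []
    for F in F_GRID:
        for CR in CR_GRID:
            for _ in range(runs_per_cell):
                cfg = DEConfig(pop_size=pop_size, F=F, CR=CR,
                               generations=generations, seed=next(children))
                res = de_optimize(objective, bounds, constraints, cfg)
                runs.append((F, CR, res.history))

    global_best = min(min(h) for _, _, h in runs)
    threshold = global_best * 1.01
    rows = []
    for F in F_GRID:
        for CR in CR_GRID:
            cell = [h for f, cr, h in runs if (f, cr) == (F, CR)]
            gens_needed = []
            for h in cell:
                hit = next((g + 1 for g, v in enumerate(h) if v < threshold), None)
                if hit is not None:
                    gens_needed.append(hit)
            pct = 100.0 * len(gens_needed) / len(cell)
            mean_g = float(np.mean(gens_needed)) if gens_needed else float("nan")
            rows.append({"F": F, "CR": CR, "converge_pct": pct, "mean_generations": mean_g})
    grid = pd.DataFrame(rows)
    ranked = grid.sort_values(
        ["converge_pct", "mean_generations"], ascending=[False, True], kind="mergesort"
    )
    best_row = ranked.iloc[0]
    return grid, (float(best_row["F"]), float(best_row["CR"]))


# ---------------------------------------------------------------------------
# entropy-model fitting front ends
# ---------------------------------------------------------------------------

MARCELLIN_BOUNDS = ((1e-3, 1 - 1e-3),) * 4


def _objective_for(
    family: str,
    target: TargetCurve,
    *,
    normalization: str,
    formulation: str,
    stimulus_design: tuple[int, int, int],
    alpha_max: float,
) -> tuple[Callable[[np.ndarray], float], tuple, ConstraintSpec | None,
           Callable[[np.ndarray], EntropyConfig]]:
    ratings = np.asarray(target.ratings, dtype=float)

    if family == "marcellin":
        def make_config(params: np.ndarray) -> EntropyConfig:
            return EntropyConfig(
                family="marcellin",
                weights=tuple(float(w) for w in params),
                formulation=formulation,
            )
        bounds: tuple = MARCELLIN_BOUNDS
        constraints: ConstraintSpec | None = MARCELLIN_CONSTRAINTS
    elif family == "renyi":
        def make_config(params: np.ndarray) -> EntropyConfig:
            return EntropyConfig(family="renyi", alpha=float(params[0]),
                                 formulation=formulation)
        bounds = ((1e-6, alpha_max),)
        constraints = None
    else:
        raise ValueError(
            f"family {family!r} has no free parameters to fit; "
            "use model_curve directly" if family == "shannon"
            else f"unknown entropy family {family!r}"
        )

    def objective(params: np.ndarray) -> float:
        curve = model_curve(make_config(params), target.pa_levels, stimulus_design)
        return euclidean_fitness(
            curve, ratings,
            normalization=normalization, rating_scale_max=target.rating_scale_max,
        )

    return objective, bounds, constraints, make_config


def fit_entropy(
    family: str,
    target: TargetCurve,
    config: DEConfig | None = None,
    *,
    normalization: str = "minmax_both",
    formulation: str = "difference",
    stimulus_design: tuple[int, int, int] = DEFAULT_STIMULUS_DESIGN,
    alpha_max: float = 10.0,
    n_runs: int = 1,
) -> FitResult:
    """Fit Rényi's α or Marcellin's four digram weights to a target curve.

    Marcellin searches (0, 1)^4 under the paired relative-distance
    constraints; Rényi searches (0, ``alpha_max``] unconstrained.  With
    ``n_runs > 1`` the run seeds are derived from ``config.seed`` and the
    best run is returned, its ``converged`` flag evaluated against the
    batch-best fitness by the +1% criterion.
    """
    config = config or DEConfig()
    objective, bounds, constraints, make_config = _objective_for(
        family, target,
        normalization=normalization, formulation=formulation,
        stimulus_design=stimulus_design, alpha_max=alpha_max,
    )

    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    if n_runs == 1:
        seeds: list = [config.seed]
    else:
        base = config.seed if isinstance(config.seed, np.random.SeedSequence) \
            else np.random.SeedSequence(config.seed)
        seeds = list(base.spawn(n_runs))

    results = [
        de_optimize(objective, bounds, constraints, replace(config, seed=s))
        for s in seeds
    ]
    batch_best = min(r.fitness for r in results)
    best = min(results, key=lambda r: r.fitness)
    return replace(
        best,
        converged=convergence_check(best.fitness, batch_best),
        entropy_config=make_config(np.asarray(best.params)),
    )
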