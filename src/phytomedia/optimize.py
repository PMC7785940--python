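"""Desirability-weighted genetic-algorithm search over medium composition.

Each response model supplies predictions; a one-sided linear desirability
ramp maps each prediction to d in [0, 1] (0 at/below the lower anchor, 1
at/above the target) and the weighted geometric mean aggregates them into
an overall desirability D, reported as an agreement percentage 100 D.
Genes are the five xMS factor levels by default, so candidate media stay
inside the salt groupings the models were trained on; a free-salt mode
optimizes all 14 salt concentrations independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datasets import ms_recipe, standard_recipe
from .doe import load_factor_specs
from .stoichiometry import (FACTOR_NAMES, MS_SALTS, FactorLevels,
                            factors_to_recipe, recipe_to_ion_profile)

#: The study's optimization goals: weight, lower anchor sentinel, target.
DEFAULT_WEIGHTS = {"SQ": 10.0, "SN": 9.0, "SL": 8.0, "LA": 7.0}
DEFAULT_TARGETS = {"SQ": 4.00, "SN": 4.4, "SL": 1.6, "LA": 28.0}


@dataclass(frozen=True)
class DesirabilityChannel:
    lower_anchor: float
    target: float
    weight: float

    def __post_init__(self):
        if not self.lower_anchor < self.target:
            raise ValueError("lower_anchor must be below target")
        if self.weight < 0:
            raise ValueError("weight must be >= 0")


@dataclass
class DesirabilitySpec:
    channels: dict[str, DesirabilityChannel]

    def __post_init__(self):
        if not any(c.weight > 0 for c in self.channels.values()):
            raise ValueError("at least one positive weight required")

    @classmethod
    def from_training_minima(cls, y_min: dict[str, float],
                             targets: dict[str, float] | None = None,
                             weights: dict[str, float] | None = None):
        """Anchors at each output's training minimum (the default policy)."""
        targets = targets or DEFAULT_TARGETS
        weights = weights or DEFAULT_WEIGHTS
        return cls({
            out: DesirabilityChannel(float(y_min[out]), float(targets[out]),
                                     float(weights[out]))
            for out in targets
        })


def partial_desirability(yhat, lower_anchor: float, target: float):
    """One-sided maximize ramp: 0 below anchor, linear to 1 at the target."""
    yhat = np.asarray(yhat, float)
    d = (yhat - lower_anchor) / (target - lower_anchor)
    return np.clip(d, 0.0, 1.0)


def overall_desirability(d, weights):
    """Weighted geometric mean; any zero channel vetoes the candidate."""
    d = np.asarray(d, float)
    w = np.asarray(weights, float)
    if w.sum() <= 0:
        raise ValueError("weights must sum to > 0")
    if (d == 0).any():
        return 0.0
    return float(np.exp(np.sum(w * np.log(d)) / w.sum()))


@dataclass
class GAConfig:
    population: int = 100
    generations: int = 200
    crossover_rate: float = 0.9
    mutation_rate: float = 0.1
    elitism: int = 2
    tournament: int = 3
    blx_alpha: float = 0.5
    mutation_scale: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.population < 10:
            raise ValueError("population must be >= 10")
        if self.elitism < 1:
            raise ValueError("elitism must be >= 1")


@dataclass
class OptimizationResult:
    recipe: dict[str, float]
    factor_levels: dict[str, float] | None
    ion_profile: dict[str, float]
    predicted: dict[str, float]
    desirabilities: dict[str, float]
    agreement: float
    best_trace: list[float] = field(default_factory=list)


def _salt_vector(recipe) -> pd.DataFrame:
    return pd.DataFrame([[recipe.concentrations.get(s, 0.0) for s in MS_SALTS]],
                        columns=list(MS_SALTS))


def _gene_bounds(mode: str) -> tuple[np.ndarray, np.ndarray, list[str]]:
    specs = load_factor_specs()
    if mode == "factors":
        names = [f.name for f in specs]
        lo = np.array([f.low for f in specs])
        hi = np.array([f.high for f in specs])
        return lo, hi, names
    base = ms_recipe().concentrations
    by_salt = {s: f for f in specs for s in f.salts}
    lo = np.array([base[s] * by_salt[s].low for s in MS_SALTS])
    hi = np.array([base[s] * by_salt[s].high for s in MS_SALTS])
    return lo, hi, list(MS_SALTS)


def _decode(gene: np.ndarray, mode: str):
    if mode == "factors":
        levels = FactorLevels(**dict(zip(FACTOR_NAMES, map(float, gene))))
        recipe = factors_to_recipe(levels, ms_recipe())
        return recipe, levels
    from .stoichiometry import MediumRecipe

    return MediumRecipe(dict(zip(MS_SALTS, map(float, gene))),
                        label="candidate"), None


def ga_optimize(models: dict, spec: DesirabilitySpec,
                config: GAConfig | None = None,
                mode: str = "factors") -> OptimizationResult:
    """Real-coded GA (tournament, blend crossover, Gaussian mutation).

    ``models`` maps each weighted output to a predictor over the 14-salt
    representation (mg/L).  Elitism makes the best-so-far fitness
    non-decreasing across generations; the run is deterministic per seed.
    """
    config = config or GAConfig()
    missing = [o for o in spec.channels if o not in models]
    if missing:
        raise ValueError(f"no model for weighted outputs {missing}")
    lo, hi, gene_names = _gene_bounds(mode)
    if not np.all(np.isfinite(lo)) or not np.all(lo < hi):
        raise ValueError("infeasible gene bounds")
    rng = np.random.default_rng(config.seed)
    outputs = list(spec.channels)
    weights = np.array([spec.channels[o].weight for o in outputs])

    def fitness(gene):
        recipe, _ = _decode(gene, mode)
        salts = _salt_vector(recipe)
        d = []
        for o in outputs:
            ch = spec.channels[o]
            pred = float(np.asarray(models[o].predict(salts)).ravel()[0])
            d.append(float(partial_desirability(pred, ch.lower_anchor,
                                                ch.target)))
        return overall_desirability(d, weights)

    pop = rng.uniform(lo, hi, size=(config.population, len(lo)))
    fit = np.array([fitness(g) for g in pop])
    trace = [float(fit.max())]
    for _ in range(config.generations):
        order = np.argsort(fit)[::-1]
        elite = pop[order[: config.elitism]].copy()
        children = list(elite)
        while len(children) < config.population:
            picks = rng.integers(0, config.population, size=(2, config.tournament))
            pa = pop[picks[0][np.argmax(fit[picks[0]])]]
            pb = pop[picks[1][np.argmax(fit[picks[1]])]]
            if rng.random() < config.crossover_rate:
                span = np.abs(pa - pb)
                c_lo = np.minimum(pa, pb) - config.blx_alpha * span
                c_hi = np.maximum(pa, pb) + config.blx_alpha * span
                child = rng.uniform(c_lo, c_hi)
            else:
                child = pa.copy()
            mask = rng.random(len(lo)) < config.mutation_rate
            child = np.where(mask,
                             child + rng.normal(0, config.mutation_scale *
                                                (hi - lo), len(lo)),
                             child)
            children.append(np.clip(child, lo, hi))
        pop = np.array(children[: config.population])
        fit = np.array([fitness(g) for g in pop])
        trace.append(max(trace[-1], float(fit.max())))

    best_gene = pop[int(np.argmax(fit))]
    recipe, levels = _decode(best_gene, mode)
    salts = _salt_vector(recipe)
    predicted = {o: float(np.asarray(models[o].predict(salts)).ravel()[0])
                 for o in outputs}
    desir = {o: float(partial_desirability(predicted[o],
                                           spec.channels[o].lower_anchor,
                                           spec.channels[o].target))
             for o in outputs}
    D = overall_desirability([desir[o] for o in outputs], weights)
    return OptimizationResult(
        recipe={s: float(c) for s, c in recipe.concentrations.items()},
        factor_levels=None if levels is None else levels.as_dict(),
        ion_profile=recipe_to_ion_profile(recipe).mM,
        predicted=predicted,
        desirabilities=desir,
        agreement=100.0 * D,
        best_trace=trace,
    )


def desirability_of_recipe(recipe, models: dict, spec: DesirabilitySpec) -> float:
    """Overall desirability of an arbitrary recipe under the same models."""
    salts = _salt_vector(recipe)
    d, w = [], []
    for o, ch in spec.channels.items():
        pred = float(np.asarray(models[o].predict(salts)).ravel()[0])
        d.append(float(partial_desirability(pred, ch.lower_anchor, ch.target)))
        w.append(ch.weight)
    return overall_desirability(d, w)


def result_report(result: OptimizationResult) -> pd.DataFrame:
    """Optimized recipe side by side with the standard media (mg/L)."""
    media = ["MS", "B5", "St", "Ha"]
    cols = {"optimized": pd.Series(result.recipe)}
    for m in media:
        cols[m] = pd.Series(standard_recipe(m).concentrations)
    out = pd.DataFrame(cols).fillna(0.0)
    return out
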