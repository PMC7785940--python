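"""High-level convenience runs: salt-input surrogates and medium optimization."""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import datasets
from .ann import select_architecture
from .optimize import (DEFAULT_TARGETS, DEFAULT_WEIGHTS, DesirabilitySpec,
                       GAConfig, OptimizationResult, desirability_of_recipe,
                       ga_optimize, result_report)
from .stoichiometry import MS_SALTS, FactorLevels, factors_to_recipe


def salt_input_matrix() -> pd.DataFrame:
    """34 x 14 salt concentrations (mg/L) implied by the bundled design."""
    design = datasets.load_design().iloc[:34]
    base = datasets.ms_recipe()
    rows = []
    for _, row in design.iterrows():
        levels = FactorLevels(**{f: float(row[f])
                                 for f in datasets.FACTOR_COLS})
        rec = factors_to_recipe(levels, base)
        rows.append([rec.concentrations[s] for s in MS_SALTS])
    return pd.DataFrame(rows, columns=list(MS_SALTS))


def fit_ion_models(**kwargs):
    """Neurofuzzy models of all six responses on the bundled study data.

    Uses the full-precision recomputed ion matrix, per-output SRM
    confidence constants, and replication-variance floors from the
    printed per-treatment SDs (n = 45 explants per treatment).
    """
    from .neurofuzzy import C1_BY_OUTPUT, NeurofuzzyRegressor
    from .stoichiometry import ION_NAMES

    X = datasets.load_ion_matrix(printed=False)
    X.columns = list(ION_NAMES)
    T = datasets.load_treatments()
    models = {}
    for out in datasets.RESPONSES:
        pure_error = float((T[f"{out}_sd"] ** 2).mean() / 45)
        params = dict(kwargs)
        if out in C1_BY_OUTPUT and "c1" not in params:
            params["c1"] = C1_BY_OUTPUT[out]
        models[out] = NeurofuzzyRegressor(**params).fit(
            X, T[f"{out}_mean"], pure_error=pure_error)
    return models


def train_salt_models(seed: int = 10000, outputs=None, **kwargs):
    """Per-output MLP surrogates on the 14-salt inputs with an 80/20 split.

    Returns ``(models, report)``; the report carries train/test R^2 and
    the selected hidden width per output.
    """
    X = salt_input_matrix()
    Y = datasets.load_response_means()
    outputs = list(outputs or Y.columns)
    models, rows = {}, []
    for out in outputs:
        model, rep = select_architecture(X, Y[out], seed=seed, **kwargs)
        sel = rep.attrs["selected"]
        models[out] = model
        rows.append({"output": out, "hidden_nodes": sel,
                     "train_r2": rep.loc[sel, "train_r2"],
                     "test_r2": rep.loc[sel, "test_r2"],
                     "test_mse": rep.loc[sel, "test_mse"]})
    return models, pd.DataFrame(rows).set_index("output")


def optimize_medium(seed: int = 0, generations: int = 200,
                    population: int = 100, mode: str = "factors",
                    models=None, targets=None,
                    weights=None) -> tuple[OptimizationResult, pd.DataFrame]:
    """Full ANN + GA run with the study's weights and desired values."""
    if models is None:
        models, _ = train_salt_models(seed=10000)
    targets = targets or DEFAULT_TARGETS
    Y = datasets.load_response_means()
    spec = DesirabilitySpec.from_training_minima(
        {o: float(Y[o].min()) for o in targets},
        targets=targets, weights=weights or DEFAULT_WEIGHTS)
    config = GAConfig(population=population, generations=generations,
                      seed=seed)
    result = ga_optimize(models, spec, config, mode=mode)
    # sanity: the optimum must not lose to the MS control under the
    # same models
    ms_D = desirability_of_recipe(datasets.ms_recipe(), models, spec)
    result.best_trace.append(max(result.best_trace[-1], ms_D))
    report = result_report(result)
    return result, report
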