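"""D-optimal experimental designs over the five-factor medium space.

A candidate grid is enumerated over the factor ranges (xMS multipliers)
and a Fedorov exchange search picks the ``n_runs`` rows maximizing
``det(X'X)`` of the model matrix on coded [-1, 1] factors.  Replicate
pairs and control (1x MS) runs are appended afterwards, mirroring how the
study's 33 generated runs were augmented with three MS controls.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

MODEL_ORDERS = ("linear", "interaction", "quadratic")


@dataclass(frozen=True)
class FactorSpec:
    name: str
    low: float
    high: float
    salts: tuple[str, ...] = ()

    def __post_init__(self):
        if not 0 < self.low < self.high:
            raise ValueError(f"{self.name}: need 0 < low < high")


def load_factor_specs() -> list[FactorSpec]:
    """The study's five factors and their xMS ranges."""
    with resources.files("phytomedia.data").joinpath("factors.csv").open("r") as fh:
        df = pd.read_csv(fh)
    return [
        FactorSpec(r["name"], float(r["low"]), float(r["high"]),
                   tuple(r["salts"].split(";")))
        for _, r in df.iterrows()
    ]


@dataclass
class DesignSpec:
    factors: list[FactorSpec]
    model_order: str = "quadratic"
    n_runs: int = 33
    n_replicate_pairs: int = 3
    n_controls: int = 3
    grid_points_per_factor: int = 5
    seed: int = 0
    max_candidates: int = 200_000

    def __post_init__(self):
        if self.model_order not in MODEL_ORDERS:
            raise ValueError(f"model_order must be one of {MODEL_ORDERS}")
        p = n_model_terms(len(self.factors), self.model_order)
        if self.n_runs < p:
            raise ValueError(f"n_runs={self.n_runs} < {p} model terms")


@dataclass
class Design:
    """Run x factor matrix of xMS levels plus replicate/control flags."""

    runs: pd.DataFrame
    replicate_of: list[int | None] = field(default_factory=list)
    is_control: list[bool] = field(default_factory=list)
    log_det_trace: list[float] = field(default_factory=list)

    def __post_init__(self):
        n = len(self.runs)
        if not self.replicate_of:
            self.replicate_of = [None] * n
        if not self.is_control:
            self.is_control = [False] * n

    def to_frame(self) -> pd.DataFrame:
        df = self.runs.reset_index(drop=True).copy()
        df["replicate_of"] = pd.array(
            [(-1 if r is None else r) for r in self.replicate_of], dtype="Int64"
        )
        df["replicate_of"] = df["replicate_of"].replace(-1, pd.NA)
        df["is_control"] = np.asarray(self.is_control, dtype=int)
        return df


def n_model_terms(k: int, model_order: str) -> int:
    if model_order == "linear":
        return 1 + k
    if model_order == "interaction":
        return 1 + k + k * (k - 1) // 2
    return 1 + 2 * k + k * (k - 1) // 2  # full quadratic


def code_levels(X: np.ndarray, factors: list[FactorSpec]) -> np.ndarray:
    """Affine map of each factor to [-1, 1] over its design range."""
    lo = np.array([f.low for f in factors])
    hi = np.array([f.high for f in factors])
    return 2.0 * (X - lo) / (hi - lo) - 1.0


def model_matrix(X_coded: np.ndarray, model_order: str) -> np.ndarray:
    """Columns: 1, x_i, (x_i x_j), (x_i^2) depending on the model order."""
    n, k = X_coded.shape
    cols = [np.ones(n)]
    cols += [X_coded[:, i] for i in range(k)]
    if model_order in ("interaction", "quadratic"):
        for i, j in itertools.combinations(range(k), 2):
            cols.append(X_coded[:, i] * X_coded[:, j])
    if model_order == "quadratic":
        cols += [X_coded[:, i] ** 2 for i in range(k)]
    return np.column_stack(cols)


def build_candidates(spec: DesignSpec) -> np.ndarray:
    """Full-factorial uniform grid over the factor ranges, endpoints included."""
    g = spec.grid_points_per_factor
    if g < 2:
        raise ValueError("grid_points_per_factor must be >= 2")
    total = g ** len(spec.factors)
    if total > spec.max_candidates:
        raise ValueError(f"candidate grid of {total} points exceeds cap "
                         f"{spec.max_candidates}")
    axes = [np.linspace(f.low, f.high, g) for f in spec.factors]
    return np.array(list(itertools.product(*axes)))


def _logdet(M: np.ndarray) -> float:
    sign, ld = np.linalg.slogdet(M)
    return ld if sign > 0 else -np.inf


def d_optimal(candidates: np.ndarray, factors: list[FactorSpec],
              model_order: str, n_runs: int, seed: int = 0,
              max_iter: int = 50, max_restarts: int = 10) -> tuple[np.ndarray, list[float]]:
    """Fedorov exchange: swap design rows for candidates to grow det(X'X).

    First-improvement scan in candidate index order; the seed only controls
    the random start.  Returns the chosen rows (original units) and the
    log-determinant trace, which is non-decreasing by construction.
    """
    p = n_model_terms(len(factors), model_order)
    if n_runs < p:
        raise ValueError(f"n_runs={n_runs} < {p} model terms")
    F = model_matrix(code_levels(candidates, factors), model_order)
    rng = np.random.default_rng(seed)
    for _ in range(max_restarts):
        idx = list(rng.choice(len(candidates), size=n_runs, replace=False))
        M = F[idx].T @ F[idx]
        best = _logdet(M)
        if np.isfinite(best):
            break
    else:
        raise RuntimeError("could not find a non-singular starting design")

    trace = [best]
    for _ in range(max_iter):
        improved = False
        for pos in range(n_runs):
            current = best
            for cand in range(len(F)):
                trial = idx.copy()
                trial[pos] = cand
                ld = _logdet(F[trial].T @ F[trial])
                if ld > current + 1e-10:
                    idx = trial
                    best = current = ld
                    improved = True
                    break  # first improvement for this position
        trace.append(best)
        if not improved:
            break
    return candidates[idx], trace


def d_efficiency(runs: np.ndarray, factors: list[FactorSpec],
                 model_order: str) -> float:
    """100 * det(X'X / n)^(1/p) on coded factors (1.0-scaled information).

    100% is attained by an orthogonal two-level factorial under a linear
    model; rank-deficient designs report 0 with a warning.
    """
    X = model_matrix(code_levels(np.asarray(runs, float), factors), model_order)
    n, p = X.shape
    sign, ld = np.linalg.slogdet(X.T @ X / n)
    if sign <= 0 or np.linalg.matrix_rank(X) < p:
        import warnings

        warnings.warn("rank-deficient design; D-efficiency reported as 0")
        return 0.0
    return 100.0 * float(np.exp(ld / p))


def augment(runs: np.ndarray, factors: list[FactorSpec],
            n_replicate_pairs: int = 0, control_point: np.ndarray | None = None,
            n_controls: int = 0, seed: int = 0) -> Design:
    """Append exact-copy replicate rows and flagged control rows."""
    rng = np.random.default_rng(seed)
    runs = np.asarray(runs, float)
    names = [f.name for f in factors]
    rows = [runs]
    replicate_of: list[int | None] = [None] * len(runs)
    if n_replicate_pairs:
        sources = rng.choice(len(runs), size=n_replicate_pairs, replace=False)
        for s in sorted(sources):
            rows.append(runs[[s]])
            replicate_of.append(int(s))
    is_control = [False] * len(replicate_of)
    if n_controls:
        if control_point is None:
            raise ValueError("control_point required when n_controls > 0")
        rows.append(np.tile(np.asarray(control_point, float), (n_controls, 1)))
        replicate_of += [None] * n_controls
        is_control += [True] * n_controls
    df = pd.DataFrame(np.vstack(rows), columns=names)
    return Design(df, replicate_of, is_control)


def generate_design(spec: DesignSpec) -> Design:
    """Candidate grid -> exchange search -> replicate/control augmentation.

    Replicate pairs count toward ``n_runs`` (the study's 33 runs include
    its three replicate pairs); controls are appended on top.
    """
    candidates = build_candidates(spec)
    n_unique = spec.n_runs - spec.n_replicate_pairs
    runs, trace = d_optimal(candidates, spec.factors, spec.model_order,
                            n_unique, seed=spec.seed)
    control = np.ones(len(spec.factors))
    design = augment(runs, spec.factors, spec.n_replicate_pairs,
                     control_point=control, n_controls=spec.n_controls,
                     seed=spec.seed)
    design.log_det_trace = trace
    return design
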