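"""Neurofuzzy additive tensor B-spline models with IF-THEN rule extraction.

Each response is modeled as an additive sum of low-order tensor-product
B-spline submodels over small ion subsets (ASMOD-style construction):

    y(x) = intercept + sum_s  B_s(x_{I_s}) beta_s

where each input carries a triangular (order-2 B-spline) partition with 2
or 3 uniformly spaced apexes over its empirical domain.  Those basis
functions double as fuzzy membership functions ("Low", "Mid", "High"), so
a fitted submodel reads directly as IF-THEN rules: at every apex
combination the tensor basis is one-hot, making each coefficient the
submodel's prediction for that linguistic cell.

Structure search is two-phase: a growth phase forces the best
complexity-increasing move (add ion, add pair, tensor-expand, merge,
raise density) along a refinement path, then a structural-risk score
selects the best path element and a refinement pass (including drop,
contract and lower-density moves) polishes it.  The response is min-max
scaled to [0, 1] during training so mean-squared errors and the
complexity penalty are comparable across outputs.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

LABELS = {2: ("Low", "High"), 3: ("Low", "Mid", "High")}


# ---------------------------------------------------------------------------
# fuzzification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FuzzyPartition:
    """Triangular membership partition of one input's empirical domain.

    Apexes sit at ``domain_min``, (midpoint,) ``domain_max``; memberships
    are order-2 B-splines and sum to one everywhere on the domain.
    """

    ion: str
    domain_min: float
    domain_max: float
    density: int

    def __post_init__(self):
        if self.density not in (2, 3):
            raise ValueError("density must be 2 or 3")
        if not self.domain_min < self.domain_max:
            raise ValueError(f"{self.ion}: domain_min must be < domain_max")

    @property
    def labels(self) -> tuple[str, ...]:
        return LABELS[self.density]

    @property
    def apexes(self) -> np.ndarray:
        return np.linspace(self.domain_min, self.domain_max, self.density)

    def membership(self, x) -> np.ndarray:
        """(n, density) membership degrees; x is clamped to the domain."""
        x = np.clip(np.asarray(x, dtype=float), self.domain_min, self.domain_max)
        apex = self.apexes
        out = np.zeros(x.shape + (self.density,))
        for j, a in enumerate(apex):
            left = apex[j - 1] if j > 0 else a
            right = apex[j + 1] if j + 1 < self.density else a
            mu = np.zeros_like(x)
            if j > 0:
                up = (x - left) / (a - left)
                mu = np.where((x >= left) & (x <= a), up, mu)
            else:
                mu = np.where(x <= a, 1.0, mu)
            if j + 1 < self.density:
                down = (right - x) / (right - a)
                mu = np.where((x > a) & (x <= right), down, mu)
            out[..., j] = mu
        return out

    def boundaries(self) -> np.ndarray:
        """Label crossover points (where adjacent memberships are equal)."""
        apex = self.apexes
        return (apex[:-1] + apex[1:]) / 2.0

    def dominance_ranges(self) -> list[tuple[str, float, float]]:
        """Per label, the interval where it dominates all other labels."""
        edges = [self.domain_min, *self.boundaries(), self.domain_max]
        return [(lab, edges[i], edges[i + 1]) for i, lab in enumerate(self.labels)]


def fuzzify(domain_min: float, domain_max: float, density: int,
            ion: str = "") -> FuzzyPartition:
    """Build the uniform triangular partition over [domain_min, domain_max]."""
    return FuzzyPartition(ion, float(domain_min), float(domain_max), int(density))


# ---------------------------------------------------------------------------
# submodel bases and fitting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SubModelStructure:
    """An ion subset (<= 4) with a set density per ion."""

    inputs: tuple[str, ...]
    densities: tuple[int, ...]

    def __post_init__(self):
        if not 1 <= len(self.inputs) <= 4:
            raise ValueError("submodel size must be 1..4")
        if len(self.inputs) != len(self.densities):
            raise ValueError("one density per input required")

    @property
    def n_cells(self) -> int:
        return int(np.prod(self.densities))


def submodel_design_matrix(X: pd.DataFrame, structure: SubModelStructure,
                           partitions: dict[tuple[str, int], FuzzyPartition]) -> np.ndarray:
    """Tensor-product membership basis; each row sums to one."""
    B = None
    for ion, dens in zip(structure.inputs, structure.densities):
        M = partitions[(ion, dens)].membership(X[ion].to_numpy())
        B = M if B is None else np.einsum("ni,nj->nij", B.reshape(len(M), -1),
                                          M).reshape(len(M), -1)
    return B


def ridge_fit(B: np.ndarray, y: np.ndarray, ridge: float) -> np.ndarray:
    """Solve min ||y - B beta||^2 + ridge ||beta||^2 (always solvable)."""
    p = B.shape[1]
    return np.linalg.solve(B.T @ B + ridge * np.eye(p), B.T @ y)


def srm_score(mse: float, p: int, n: int, c1: float, c2: float) -> float:
    """Structural-risk penalty: inflate mse by a capacity-dependent factor.

    score = mse * exp(-ln(1-c1) * c2 * p / (3n)).

    c1 plays the role of the confidence level of a guaranteed-risk bound
    (the penalty grows with -ln(1 - c1), so lowering c1 deliberately
    relaxes the penalty, which is how the per-output confidence constants
    are meant to be used) and c2 scales the capacity charge per sample;
    the fixed 1/3 constant anchors the per-parameter charge so that the
    study's stated (c1, c2) reproduce the complexity of its reported
    models at its sample size.  The score is strictly increasing in both
    mse and p, zero at mse = 0, and p >= n is inadmissible (+inf).
    """
    if not 0 < c1 < 1 or c2 <= 0:
        raise ValueError("need 0 < c1 < 1 and c2 > 0")
    if p < 1:
        raise ValueError("p must be >= 1")
    if p >= n:
        return np.inf
    return float(mse * np.exp(-np.log(1 - c1) * c2 * p / (3 * n)))


def train_r2(y, yhat) -> float:
    """Training R^2 in percent: (1 - SSE/SST) * 100."""
    y = np.asarray(y, float)
    yhat = np.asarray(yhat, float)
    if len(y) < 2:
        raise ValueError("need at least two observations")
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0:
        raise ValueError("R^2 undefined for constant response")
    return float((1.0 - np.sum((y - yhat) ** 2) / sst) * 100.0)


def model_anova(y, yhat, df1: int, df2: int, alpha: float = 0.05,
                convention: str = "residual"):
    """Model-accuracy ANOVA comparing predictions with observations.

    f_ratio = (SSR/df1) / (SSE/(df2-df1)) with df1 = effective model terms
    and df2 = total observations - 1.  ``convention`` picks the critical
    value: "residual" (textbook) uses the upper-``alpha`` quantile of
    F(df1, df2 - df1); "study" reproduces the published critical values,
    which are the upper 0.1% quantile of F(df1, df2) with df2 the *total*
    df (e.g. 3.558 at (16, 33)) despite being labeled alpha = 0.05.
    ``pass`` means f_ratio > f_critical.
    """
    if df1 < 1 or df2 <= df1:
        raise ValueError("need df1 >= 1 and df2 > df1")
    y = np.asarray(y, float)
    yhat = np.asarray(yhat, float)
    sse = float(np.sum((y - yhat) ** 2))
    ssr = float(np.sum((yhat - y.mean()) ** 2))
    f_ratio = (ssr / df1) / (sse / (df2 - df1)) if sse > 0 else np.inf
    if convention == "study":
        f_critical = float(sps.f.ppf(1 - 0.001, df1, df2))
    elif convention == "residual":
        f_critical = float(sps.f.ppf(1 - alpha, df1, df2 - df1))
    else:
        raise ValueError("convention must be 'residual' or 'study'")
    return f_ratio, f_critical, bool(f_ratio > f_critical)


# ---------------------------------------------------------------------------
# the estimator
# ---------------------------------------------------------------------------

class NeurofuzzyRegressor(RegressorMixin, BaseEstimator):
    """ASMOD-style additive spline model with fuzzy rule extraction.

    Parameters
    ----------
    c1, c2 : float
        Structural-risk-minimization constants (confidence / capacity).
    ridge : float
        Ridge factor of the least-squares fits.
    densities : tuple of int
        Candidate set densities per input (2 and/or 3).
    max_inputs : int
        Maximum ions per tensor submodel.
    max_nodes_per_input : int
        Cap on apexes per input (the uniform partitions here use 2-3).

    Attributes
    ----------
    submodels_ : list of (SubModelStructure, ndarray)
        Selected structures with their coefficient vectors (scaled units).
    intercept_ : float
        Additive offset in scaled units.
    partitions_ : dict
        (ion, density) -> FuzzyPartition over the training domain.
    active_ions_ : tuple of str
        Union of ions used by the selected submodels.
    r2_ : float
        Training R^2 in percent (original units).
    """

    def __init__(self, c1: float = 0.868, c2: float = 4.8, ridge: float = 1e-6,
                 densities: tuple[int, ...] = (2, 3), max_inputs: int = 4,
                 max_nodes_per_input: int = 15, adapt_nodes: bool = True,
                 target_mse: float = 1e-4):
        self.c1 = c1
        self.c2 = c2
        self.ridge = ridge
        self.densities = densities
        self.max_inputs = max_inputs
        self.max_nodes_per_input = max_nodes_per_input
        self.adapt_nodes = adapt_nodes
        self.target_mse = target_mse

    # -- internal helpers ---------------------------------------------------

    def _as_frame(self, X) -> pd.DataFrame:
        if isinstance(X, pd.DataFrame):
            return X
        X = np.asarray(X, float)
        names = getattr(self, "feature_names_in_", None)
        if names is None:
            names = [f"x{i}" for i in range(X.shape[1])]
        return pd.DataFrame(X, columns=list(names))

    def _effective_params(self, structures) -> int:
        # Partition of unity makes one direction per submodel redundant
        # with the intercept; count distinct directions only.
        if not structures:
            return 1
        return sum(s.n_cells for s in structures) - len(structures) + 1

    def _fit_structures(self, X, ys, structures):
        """Joint ridge fit of a set of submodels on the scaled response."""
        if not structures:
            return 0.0 + ys.mean(), [], float(np.mean((ys - ys.mean()) ** 2))
        blocks = [submodel_design_matrix(X, s, self.partitions_)
                  for s in structures]
        B = np.hstack(blocks)
        yc = ys - ys.mean()
        beta = ridge_fit(B, yc, self.ridge)
        coefs, k = [], 0
        for s, blk in zip(structures, blocks):
            coefs.append(beta[k:k + blk.shape[1]])
            k += blk.shape[1]
        resid = yc - B @ beta
        mse = float(np.mean(resid ** 2))
        return float(ys.mean()), list(zip(structures, coefs)), mse

    def _score(self, mse, structures, n) -> float:
        # below the error floor, accuracy differences are noise: charge
        # only for complexity so the smallest floor-reaching model wins
        return srm_score(max(mse, self._mse_floor),
                         self._effective_params(structures), n,
                         self.c1, self.c2)

    def _candidate_moves(self, structures, grow_only: bool = False):
        used = {ion for s in structures for ion in s.inputs}
        free = [ion for ion in self.feature_names_in_ if ion not in used]
        moves = []
        # add a univariate submodel at the lowest candidate density
        d0 = min(self.densities)
        for ion in free:
            moves.append(structures + [SubModelStructure((ion,), (d0,))])
        # add a bivariate tensor directly (interactions with weak marginal
        # effects are invisible to one-ion additions)
        if self.max_inputs >= 2:
            for a, b in itertools.combinations(free, 2):
                moves.append(structures
                             + [SubModelStructure((a, b), (d0, d0))])
        # tensor-expand an existing submodel with a fresh input
        for i, s in enumerate(structures):
            if len(s.inputs) < self.max_inputs:
                for ion in free:
                    new = SubModelStructure(s.inputs + (ion,),
                                            s.densities + (d0,))
                    moves.append(structures[:i] + [new] + structures[i + 1:])
        # tensor-merge two submodels
        for i, j in itertools.combinations(range(len(structures)), 2):
            si, sj = structures[i], structures[j]
            if len(si.inputs) + len(sj.inputs) <= self.max_inputs:
                merged = SubModelStructure(si.inputs + sj.inputs,
                                           si.densities + sj.densities)
                rest = [s for k, s in enumerate(structures) if k not in (i, j)]
                moves.append(rest + [merged])
        # raise one input's density
        hi = max(self.densities)
        for i, s in enumerate(structures):
            for k, d in enumerate(s.densities):
                if d < hi:
                    dens = s.densities[:k] + (hi,) + s.densities[k + 1:]
                    new = SubModelStructure(s.inputs, dens)
                    moves.append(structures[:i] + [new] + structures[i + 1:])
        if not grow_only:
            # drop a submodel
            for i in range(len(structures)):
                moves.append(structures[:i] + structures[i + 1:])
            # contract a tensor: remove one input from a submodel
            for i, s in enumerate(structures):
                if len(s.inputs) >= 2:
                    for k in range(len(s.inputs)):
                        new = SubModelStructure(
                            s.inputs[:k] + s.inputs[k + 1:],
                            s.densities[:k] + s.densities[k + 1:])
                        moves.append(structures[:i] + [new]
                                     + structures[i + 1:])
            # lower one input's density
            lo_d = min(self.densities)
            for i, s in enumerate(structures):
                for k, d in enumerate(s.densities):
                    if d > lo_d:
                        dens = s.densities[:k] + (lo_d,) + s.densities[k + 1:]
                        new = SubModelStructure(s.inputs, dens)
                        moves.append(structures[:i] + [new]
                                     + structures[i + 1:])
        return moves

    # -- sklearn API --------------------------------------------------------

    def fit(self, X, y, pure_error: float | None = None):
        """Fit the additive spline model.

        ``pure_error`` optionally supplies the replication variance of the
        response values (e.g. mean squared standard error of treatment
        means), in original units; residual improvements below this floor
        are treated as noise during structure selection.
        """
        X = self._as_frame(X)
        y = np.asarray(y, float).ravel()
        if len(X) < 8:
            raise ValueError("need at least 8 training runs")
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        self.n_features_in_ = X.shape[1]

        # empirical domains; constant columns cannot carry a partition
        self.domains_ = {}
        for ion in X.columns:
            lo, hi = float(X[ion].min()), float(X[ion].max())
            if lo < hi:
                self.domains_[ion] = (lo, hi)
        self.partitions_ = {
            (ion, d): fuzzify(lo, hi, d, ion=ion)
            for ion, (lo, hi) in self.domains_.items()
            for d in self.densities
        }
        self._usable = [c for c in X.columns if c in self.domains_]

        # response scaled to [0, 1] so mse and the SRM penalty are
        # comparable across outputs
        self._y_lo, self._y_hi = float(y.min()), float(y.max())
        if self._y_hi == self._y_lo:
            raise ValueError("constant response")
        ys = (y - self._y_lo) / (self._y_hi - self._y_lo)
        self._mse_floor = self.target_mse
        if pure_error is not None:
            # one-sided 90% allowance for the sampling spread of a purely
            # replication-noise-level residual around the floor
            q = sps.chi2.ppf(0.9, len(y) - 1) / (len(y) - 1)
            self._mse_floor = max(
                self._mse_floor,
                q * float(pure_error) / (self._y_hi - self._y_lo) ** 2)

        Xu = X[self._usable]
        n = len(ys)

        # Phase 1 (grow): force the refinement path forward, always taking
        # the complexity-increasing move with the best penalized score,
        # until the parameter budget (half the observations) or the
        # training-error floor is reached.  Phase 2 (select): pick the
        # path element minimizing the SRM score globally, then let the
        # full move set (including drops and merges) refine it under the
        # same criterion.
        structures: list[SubModelStructure] = []
        intercept, submodels, mse = self._fit_structures(Xu, ys, structures)
        path = [(structures, intercept, submodels, mse)]
        p_cap = max(2, min(n - 2, n // 2))
        while (self._effective_params(structures) < p_cap
               and mse > self._mse_floor):
            best_move = None
            best_sc = np.inf
            p0 = self._effective_params(structures)
            for cand in self._candidate_moves(structures, grow_only=True):
                if not p0 < self._effective_params(cand) <= p_cap:
                    continue
                ic, sm, m = self._fit_structures(Xu, ys, cand)
                sc = self._score(m, cand, n)
                if sc < best_sc - 1e-12:
                    best_sc = sc
                    best_move = (cand, ic, sm, m)
            if best_move is None:
                break
            structures, intercept, submodels, mse = best_move
            path.append((structures, intercept, submodels, mse))

        scores = [self._score(m, st, n) for st, _, _, m in path]
        best_i = int(np.argmin(scores))
        structures, intercept, submodels, mse = path[best_i]
        best_score = scores[best_i]

        while True:
            best_move = None
            for cand in self._candidate_moves(structures):
                if self._effective_params(cand) > p_cap:
                    continue
                ic, sm, m = self._fit_structures(Xu, ys, cand)
                sc = self._score(m, cand, n)
                better = sc < best_score - 1e-12
                tie = (abs(sc - best_score) <= 1e-12 and best_move is not None
                       and self._effective_params(cand)
                       < self._effective_params(best_move[2]))
                if better or tie:
                    best_score = sc
                    best_move = (ic, sm, cand, m)
            if best_move is None:
                break
            intercept, submodels, structures, mse = best_move

        if not submodels:
            warnings.warn("no admissible submodel; intercept-only model")
        self.intercept_ = intercept
        self.submodels_ = submodels
        self.structures_ = structures
        self.mse_ = mse
        self.n_params_ = self._effective_params(structures)
        self.active_ions_ = tuple(
            ion for ion in self.feature_names_in_
            if any(ion in s.inputs for s in structures)
        )
        yhat = self.predict(X)
        self.fitted_values_ = yhat
        self.residuals_ = y - yhat
        self.r2_ = train_r2(y, yhat) if np.ptp(y) > 0 else np.nan
        return self

    def _predict_scaled(self, X: pd.DataFrame) -> np.ndarray:
        out = np.full(len(X), self.intercept_)
        for s, coef in self.submodels_:
            out += submodel_design_matrix(X, s, self.partitions_) @ coef
        return out

    def predict(self, X):
        check_is_fitted(self, "submodels_")
        X = self._as_frame(X)
        ys = self._predict_scaled(X)
        return self._y_lo + ys * (self._y_hi - self._y_lo)

    # -- interpretation -----------------------------------------------------

    def extract_rules(self) -> pd.DataFrame:
        """One IF-THEN rule per linguistic cell of each submodel.

        The consequent label and membership degree come from min-max
        normalizing the submodel's cell predictions (its coefficients) to
        s in [0, 1]: High with MD = s when s >= 0.5, else Low with
        MD = 1 - s.  Constant submodels are flagged degenerate (MD 0.5).
        """
        check_is_fitted(self, "submodels_")
        rows = []
        for s_idx, (s, coef) in enumerate(self.submodels_):
            lo, hi = float(coef.min()), float(coef.max())
            degenerate = np.isclose(hi, lo)
            cells = itertools.product(
                *[LABELS[d] for d in s.densities])
            for labels, pred in zip(cells, coef):
                if degenerate:
                    cons, md = "High", 0.5
                else:
                    t = (float(pred) - lo) / (hi - lo)
                    cons, md = ("High", t) if t >= 0.5 else ("Low", 1.0 - t)
                rows.append({
                    "submodel": s_idx,
                    "antecedent": dict(zip(s.inputs, labels)),
                    "consequent": cons,
                    "MD": md,
                    "cell_prediction": float(pred),
                    "degenerate": degenerate,
                })
        return pd.DataFrame(rows)

    def dominance_ranges(self) -> pd.DataFrame:
        """Low/Mid/High dominance intervals for every ion the model uses."""
        check_is_fitted(self, "submodels_")
        rows = []
        for s in self.structures_:
            for ion, dens in zip(s.inputs, s.densities):
                part = self.partitions_[(ion, dens)]
                for lab, lo, hi in part.dominance_ranges():
                    rows.append({"ion": ion, "density": dens, "label": lab,
                                 "lower": lo, "upper": hi})
        return pd.DataFrame(rows).drop_duplicates(ignore_index=True)

    def anova(self, X, y, alpha: float = 0.05):
        """Model-accuracy ANOVA at the study's df convention."""
        yhat = self.predict(X)
        return model_anova(y, yhat, self.n_params_, len(np.asarray(y)) - 1,
                           alpha=alpha)


def fit_all_outputs(X: pd.DataFrame, Y: pd.DataFrame,
                    c1_overrides: dict[str, float] | None = None,
                    **kwargs) -> dict[str, NeurofuzzyRegressor]:
    """Fit one neurofuzzy model per response column.

    ``c1_overrides`` supplies per-output SRM confidence constants (the
    study used 0.8 for shoot number and 0.868 elsewhere).
    """
    c1_overrides = dict(c1_overrides or {})
    models = {}
    for col in Y.columns:
        params = dict(kwargs)
        if col in c1_overrides:
            params["c1"] = c1_overrides[col]
        models[col] = NeurofuzzyRegressor(**params).fit(X, Y[col])
    return models


#: The study's per-output SRM confidence constants.
C1_BY_OUTPUT = {"SN": 0.8}
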