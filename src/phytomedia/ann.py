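"""Small multilayer perceptrons trained with resilient backpropagation.

One network per response, 14 salt concentrations in, one hidden layer of
2-4 sigmoid nodes, linear output.  Training is full-batch RPROP on
min-max-scaled data with an early-stopping rule that watches a blend of
train and held-out error (0.9 train + 0.1 test by default) so the tiny
data set is not overfitted.  Everything is deterministic given the seed.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted


def sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -500, 500)))


def split_data(X, y, fraction: float = 0.8, seed: int = 10000):
    """Deterministic shuffled split into ceil(f*n) train / rest test rows."""
    n = len(X)
    if n < 5:
        raise ValueError("need at least 5 samples to split")
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = int(round(fraction * n))
    tr, te = perm[:n_train], perm[n_train:]
    take = (lambda a, i: a.iloc[i] if hasattr(a, "iloc") else np.asarray(a)[i])
    return take(X, tr), take(X, te), take(y, tr), take(y, te)


class _MinMax:
    def fit(self, A):
        A = np.asarray(A, float)
        self.lo = A.min(axis=0)
        self.hi = A.max(axis=0)
        self.span = np.where(self.hi > self.lo, self.hi - self.lo, 1.0)
        return self

    def transform(self, A):
        return (np.asarray(A, float) - self.lo) / self.span

    def inverse(self, A):
        return np.asarray(A, float) * self.span + self.lo


class RpropMLPRegressor(RegressorMixin, BaseEstimator):
    """1-hidden-layer MLP with RPROP training and blended-error early stop.

    Parameters mirror the training protocol of the study's ANN software:
    ``max_iterations`` caps training epochs, ``target_mse`` stops on a
    scaled train error, ``min_iterations`` must elapse before the smart
    stop may fire, and ``test_error_weighting`` sets the held-out share of
    the blended stopping criterion.  RPROP step constants (eta+, eta-,
    initial and bounding step sizes) are the usual defaults.
    """

    def __init__(self, hidden_nodes: int = 3, eta_plus: float = 1.2,
                 eta_minus: float = 0.5, delta0: float = 0.1,
                 delta_min: float = 1e-6, delta_max: float = 50.0,
                 max_iterations: int = 1000, target_mse: float = 1e-4,
                 min_iterations: int = 20, test_error_weighting: float = 0.1,
                 patience: int = 80, seed: int = 10000, max_retries: int = 3):
        self.hidden_nodes = hidden_nodes
        self.eta_plus = eta_plus
        self.eta_minus = eta_minus
        self.delta0 = delta0
        self.delta_min = delta_min
        self.delta_max = delta_max
        self.max_iterations = max_iterations
        self.target_mse = target_mse
        self.min_iterations = min_iterations
        self.test_error_weighting = test_error_weighting
        self.patience = patience
        self.seed = seed
        self.max_retries = max_retries

    def _forward(self, X, params):
        W1, b1, W2, b2 = params
        Z = sigmoid(X @ W1 + b1)
        return Z, Z @ W2 + b2

    def _grads(self, X, y, params):
        W1, b1, W2, b2 = params
        Z, yhat = self._forward(X, params)
        e = (yhat - y)[:, None]
        n = len(y)
        gW2 = 2.0 / n * (Z.T @ e).ravel()
        gb2 = 2.0 / n * e.sum()
        dZ = 2.0 / n * e * W2[None, :] * Z * (1 - Z)
        gW1 = X.T @ dZ
        gb1 = dZ.sum(axis=0)
        return [gW1, gb1, gW2, np.atleast_1d(gb2)], float(np.mean(e ** 2))

    def fit(self, X, y, X_val=None, y_val=None):
        if isinstance(X, pd.DataFrame):
            self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        X = np.asarray(X, float)
        y = np.asarray(y, float).ravel()
        self.n_features_in_ = X.shape[1]
        self.x_scaler_ = _MinMax().fit(X)
        self.y_scaler_ = _MinMax().fit(y)
        Xs = self.x_scaler_.transform(X)
        ys = self.y_scaler_.transform(y)
        if X_val is not None:
            Xv = self.x_scaler_.transform(np.asarray(X_val, float))
            yv = self.y_scaler_.transform(np.asarray(y_val, float).ravel())
        else:
            Xv = yv = None

        h, m = self.hidden_nodes, X.shape[1]
        rng = np.random.default_rng(self.seed)
        for attempt in range(self.max_retries + 1):
            params = [rng.uniform(-0.5, 0.5, (m, h)), rng.uniform(-0.5, 0.5, h),
                      rng.uniform(-0.5, 0.5, h), rng.uniform(-0.5, 0.5, 1)]
            result = self._rprop(Xs, ys, Xv, yv, params)
            if result is not None:
                break
        else:
            raise RuntimeError("training diverged in every retry")
        self.params_, self.history_, self.n_iter_ = result
        _, yhat = self._forward(Xs, self.params_)
        self.fitted_values_ = self.y_scaler_.inverse(yhat)
        return self

    def _rprop(self, Xs, ys, Xv, yv, params):
        deltas = [np.full_like(p, self.delta0) for p in params]
        prev = [np.zeros_like(p) for p in params]
        history = []
        best = (np.inf, [p.copy() for p in params], 0)
        w = self.test_error_weighting
        for it in range(1, self.max_iterations + 1):
            grads, train_mse = self._grads(Xs, ys, params)
            if not np.isfinite(train_mse):
                return None
            if Xv is not None and len(Xv):
                _, yvh = self._forward(Xv, params)
                test_mse = float(np.mean((yvh - yv) ** 2))
                blended = (1 - w) * train_mse + w * test_mse
            else:
                test_mse = np.nan
                blended = train_mse
            history.append((train_mse, test_mse))
            if blended < best[0]:
                best = (blended, [p.copy() for p in params], it)
            if train_mse <= self.target_mse and it >= self.min_iterations:
                break
            if it >= self.min_iterations and it - best[2] >= self.patience:
                break
            for k, (g, gp) in enumerate(zip(grads, prev)):
                sign = g * gp
                deltas[k] = np.where(sign > 0,
                                     np.minimum(deltas[k] * self.eta_plus,
                                                self.delta_max),
                                     np.where(sign < 0,
                                              np.maximum(deltas[k] * self.eta_minus,
                                                         self.delta_min),
                                              deltas[k]))
                g = np.where(sign < 0, 0.0, g)  # iRPROP-: forget flipped grads
                params[k] = params[k] - np.sign(g) * deltas[k]
                prev[k] = g
        return best[1], history, len(history)

    def predict(self, X):
        check_is_fitted(self, "params_")
        X = np.asarray(X, float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("feature count mismatch")
        Xs = self.x_scaler_.transform(X)
        if ((Xs < -1e-9) | (Xs > 1 + 1e-9)).any():
            warnings.warn("inputs outside the training hull were clamped")
            Xs = np.clip(Xs, 0.0, 1.0)
        _, yhat = self._forward(Xs, self.params_)
        return self.y_scaler_.inverse(yhat)


def train_mlp(X, y, X_val=None, y_val=None, **kwargs) -> RpropMLPRegressor:
    return RpropMLPRegressor(**kwargs).fit(X, y, X_val=X_val, y_val=y_val)


def select_architecture(X, y, hidden_range=(2, 3, 4), fraction: float = 0.8,
                        seed: int = 10000, **kwargs):
    """Train over the candidate hidden sizes; keep the lowest test MSE.

    Returns ``(model, report)`` where report holds train/test R^2 and MSE
    per candidate width plus the selected width.
    """
    from .neurofuzzy import train_r2

    X_tr, X_te, y_tr, y_te = split_data(X, y, fraction=fraction, seed=seed)
    y_te_arr = np.asarray(y_te, float)
    # out-of-sample R^2 benchmarks against the *training* mean: with only
    # ~7 test rows, the within-test mean is too unstable a baseline
    sst_te = float(np.sum((y_te_arr - np.asarray(y_tr, float).mean()) ** 2))
    rows, fitted = [], {}
    for h in hidden_range:
        model = RpropMLPRegressor(hidden_nodes=h, seed=seed, **kwargs)
        model.fit(X_tr, y_tr, X_val=X_te, y_val=y_te)
        pred_tr = model.predict(np.asarray(X_tr, float))
        pred_te = model.predict(np.asarray(X_te, float))
        test_mse = float(np.mean((pred_te - y_te_arr) ** 2))
        sse_te = float(np.sum((pred_te - y_te_arr) ** 2))
        rows.append({
            "hidden_nodes": h,
            "test_mse": test_mse,
            "train_r2": train_r2(y_tr, pred_tr),
            "test_r2": 100.0 * (1.0 - sse_te / sst_te) if sst_te > 0
                       else np.nan,
        })
        fitted[h] = model
    report = pd.DataFrame(rows).set_index("hidden_nodes")
    best = int(report["test_mse"].idxmin())
    report.attrs["selected"] = best
    return fitted[best], report
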