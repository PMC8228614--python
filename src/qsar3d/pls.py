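"""Partial least squares regression with leave-one-out model selection.

A deterministic PLS1 (single response) implementation: columns are centered
by the training mean (block scaling is done upstream), the response is
centered but not scaled. With as many components as the rank of X the fit
coincides with ordinary least squares, which the test suite checks against a
normal-equations oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "PLSModel",
    "PLSError",
    "fit_pls",
    "predict",
    "loo_q2",
    "select_components",
    "model_stats",
    "field_contributions",
]


class PLSError(RuntimeError):
    pass


@dataclass
class PLSModel:
    """Fitted latent-variable regression.

    ``coef``/``intercept`` act on raw (uncentered) descriptor rows.
    ``x_rotation`` maps centered rows to latent scores:
    ``T = (X - x_mean) @ x_rotation``.
    """

    n_components: int
    x_mean: np.ndarray  # (p,)
    y_mean: float
    x_weights: np.ndarray  # W, (p, c)
    x_loadings: np.ndarray  # P, (p, c)
    y_loadings: np.ndarray  # q, (c,)
    x_rotation: np.ndarray  # W (P^T W)^-1, (p, c)
    coef: np.ndarray  # (p,)
    intercept: float
    scores: np.ndarray  # training T, (n, c)
    x_sd: np.ndarray  # training column SD (ddof=0), (p,)
    stats: dict = field(default_factory=dict)
    index_map: list[tuple[str, int]] | None = None

    @property
    def n_columns(self) -> int:
        return self.coef.shape[0]

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Latent scores for new rows."""
        X = np.asarray(X, dtype=float)
        return (X - self.x_mean) @ self.x_rotation

    def to_dict(self) -> dict:
        return {
            "n_components": self.n_components,
            "x_mean": self.x_mean.tolist(),
            "y_mean": self.y_mean,
            "x_weights": self.x_weights.tolist(),
            "x_loadings": self.x_loadings.tolist(),
            "y_loadings": self.y_loadings.tolist(),
            "x_rotation": self.x_rotation.tolist(),
            "coef": self.coef.tolist(),
            "intercept": self.intercept,
            "x_sd": self.x_sd.tolist(),
            "stats": self.stats,
            "index_map": self.index_map,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PLSModel":
        return cls(
            n_components=int(d["n_components"]),
            x_mean=np.asarray(d["x_mean"], dtype=float),
            y_mean=float(d["y_mean"]),
            x_weights=np.asarray(d["x_weights"], dtype=float),
            x_loadings=np.asarray(d["x_loadings"], dtype=float),
            y_loadings=np.asarray(d["y_loadings"], dtype=float),
            x_rotation=np.asarray(d["x_rotation"], dtype=float),
            coef=np.asarray(d["coef"], dtype=float),
            intercept=float(d["intercept"]),
            scores=np.empty((0, int(d["n_components"]))),
            x_sd=np.asarray(d["x_sd"], dtype=float),
            stats=dict(d.get("stats", {})),
            index_map=[tuple(t) for t in d["index_map"]] if d.get("index_map") else None,
        )


def _validate_xy(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise PLSError(f"shape mismatch: X {X.shape}, y {y.shape}")
    if X.shape[0] < 3:
        raise PLSError("PLS requires at least 3 samples")
    if np.ptp(y) == 0:
        raise PLSError("response has zero variance")
    return X, y


def fit_pls(
    X: np.ndarray,
    y: np.ndarray,
    n_components: int,
    index_map: list[tuple[str, int]] | None = None,
) -> PLSModel:
    """Fit a PLS1 model by sequential component extraction.

    ``n_components`` is capped at min(n - 1, p) and at the effective rank
    encountered during deflation. For a univariate response the NIPALS
    weight vector is available in closed form per component (w = X'y
    normalized), so the fit is exactly deterministic.
    """
    X, y = _validate_xy(X, y)
    if n_components < 1:
        raise PLSError("n_components must be >= 1")
    n, p = X.shape
    cap = min(n_components, n - 1, p)
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    Xd = X - x_mean
    x_sd = X.std(axis=0, ddof=0)
    yd = y - y_mean
    W, P, Q, T = [], [], [], []
    for _ in range(cap):
        w = Xd.T @ yd
        norm_w = float(np.linalg.norm(w))
        if norm_w < 1e-12:
            break
        w = w / norm_w
        t = Xd @ w
        tt = float(t @ t)
        if tt < 1e-24:
            break
        p_vec = Xd.T @ t / tt
        q = float(yd @ t) / tt
        Xd = Xd - np.outer(t, p_vec)
        yd = yd - q * t
        W.append(w)
        P.append(p_vec)
        Q.append(q)
        T.append(t)
    if not W:
        raise PLSError("no PLS component could be extracted (X'y is zero)")
    Wm = np.column_stack(W)
    Pm = np.column_stack(P)
    qv = np.asarray(Q, dtype=float)
    rotation = Wm @ np.linalg.solve(Pm.T @ Wm, np.eye(len(Q)))
    coef = rotation @ qv
    intercept = y_mean - float(x_mean @ coef)
    return PLSModel(
        n_components=len(Q),
        x_mean=x_mean,
        y_mean=y_mean,
        x_weights=Wm,
        x_loadings=Pm,
        y_loadings=qv,
        x_rotation=rotation,
        coef=coef,
        intercept=intercept,
        scores=np.column_stack(T),
        x_sd=x_sd,
        index_map=index_map,
    )


def predict(model: PLSModel, X_new: np.ndarray) -> np.ndarray:
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if X_new.shape[1] != model.n_columns:
        raise PLSError(
            f"column mismatch: model has {model.n_columns}, input has {X_new.shape[1]}"
        )
    return X_new @ model.coef + model.intercept


def loo_q2(X: np.ndarray, y: np.ndarray, n_components: int) -> float:
    """Leave-one-out cross-validated q2 = 1 - PRESS/SS.

    Each fold refits the full pipeline step (centering included) on the
    retained samples; SS is taken about the mean of the retained training
    responses of each fold.
    """
    X, y = _validate_xy(X, y)
    n = X.shape[0]
    press = 0.0
    ss = 0.0
    for i in range(n):
        keep = np.ones(n, dtype=bool)
        keep[i] = False
        y_keep = y[keep]
        if np.ptp(y_keep) == 0:
            raise PLSError(f"fold {i}: retained response has zero variance")
        fold = fit_pls(X[keep], y_keep, n_components)
        y_hat = float(predict(fold, X[i : i + 1])[0])
        press += (y[i] - y_hat) ** 2
        ss += (y[i] - float(y_keep.mean())) ** 2
    return 1.0 - press / ss


def select_components(X: np.ndarray, y: np.ndarray, max_components: int = 5) -> int:
    """Number of latent variables maximizing LOO q2 (ties -> smallest)."""
    X, y = _validate_xy(X, y)
    if max_components < 1:
        raise PLSError("max_components must be >= 1")
    n, p = X.shape
    upper = min(max_components, n - 2, p)
    if upper < 1:
        raise PLSError("too few samples to cross-validate any component count")
    best_c, best_q2 = 1, -np.inf
    for c in range(1, upper + 1):
        q2 = loo_q2(X, y, c)
        if q2 > best_q2:
            best_c, best_q2 = c, q2
    return best_c


def model_stats(model: PLSModel, X: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Training-set (r2, SEE, F) for a fitted model.

    r2 = 1 - SSE/SST, SEE = sqrt(SSE/(n - c - 1)),
    F = [(SST - SSE)/c] / [SSE/(n - c - 1)] with c latent variables.
    """
    y = np.asarray(y, dtype=float).ravel()
    n = y.shape[0]
    c = model.n_components
    if n - c - 1 <= 0:
        raise PLSError(f"cannot compute SEE/F with n={n}, components={c}")
    y_hat = predict(model, X)
    sse = float(np.sum((y - y_hat) ** 2))
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0:
        raise PLSError("response has zero variance")
    r2 = 1.0 - sse / sst
    see = float(np.sqrt(sse / (n - c - 1)))
    f = ((sst - sse) / c) / (sse / (n - c - 1)) if sse > 0 else np.inf
    model.stats.update({"r2": r2, "see": see, "f": f, "n": n, "n_components": c})
    return r2, see, f


def field_contributions(
    model: PLSModel, index_map: Sequence[tuple[str, int]] | None = None
) -> dict[str, float]:
    """Percent contribution per field kind: sum_j |b_j| * sd(X_j), normalized
    to 100 over the field kinds present in the index map."""
    index_map = index_map if index_map is not None else model.index_map
    if index_map is None:
        raise PLSError("no column index map available")
    if len(index_map) != model.n_columns:
        raise PLSError("index map length does not match model columns")
    raw: dict[str, float] = {}
    for j, (kind, _) in enumerate(index_map):
        raw[kind] = raw.get(kind, 0.0) + abs(float(model.coef[j])) * float(model.x_sd[j])
    total = sum(raw.values())
    if total == 0:
        return {k: 0.0 for k in raw}
    out = {k: 100.0 * v / total for k, v in raw.items()}
    model.stats["field_contributions"] = out
    return out
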