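"""Leverage-based applicability domain and Williams-plot classification.

Leverage is computed in the model's latent-score space (the raw descriptor
matrix has far more columns than compounds, so X'X there is singular):
h = x (X'X)^-1 x'. The warning threshold is h* = 3k/n; compounds whose
standardized residual magnitude exceeds 2.5 are response outliers.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["ADResult", "ADError", "leverage", "h_star", "williams_classify", "plot_williams"]


class ADError(RuntimeError):
    pass


@dataclass
class ADResult:
    """Per-compound leverage, standardized residual and domain class."""

    frame: pd.DataFrame  # abbrev, leverage, std_residual, class
    h_star: float
    y_bound: float
    k: int | None = None
    n: int | None = None

    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False)

    @property
    def outliers(self) -> pd.DataFrame:
        return self.frame[self.frame["class"] != "in_domain"].reset_index(drop=True)


def leverage(
    scores: np.ndarray,
    queries: np.ndarray | None = None,
    intercept: bool = True,
) -> np.ndarray:
    """Hat-diagonal leverages h = x (X'X)^-1 x'.

    ``scores`` defines the reference matrix X; ``queries`` defaults to the
    reference rows themselves. With ``intercept`` a constant column is
    prepended to both, so the training leverages sum to k + 1.
    """
    X = np.atleast_2d(np.asarray(scores, dtype=float))
    Q = X if queries is None else np.atleast_2d(np.asarray(queries, dtype=float))
    if Q.shape[1] != X.shape[1]:
        raise ADError("query and reference score dimensions differ")
    if intercept:
        X = np.hstack([np.ones((X.shape[0], 1)), X])
        Q = np.hstack([np.ones((Q.shape[0], 1)), Q])
    gram = X.T @ X
    if np.linalg.matrix_rank(gram) < gram.shape[0]:
        raise ADError("X'X is rank-deficient; use fewer latent components")
    inv = np.linalg.inv(gram)
    return np.einsum("ij,jk,ik->i", Q, inv, Q)


def h_star(k: int, n: int) -> float:
    """Leverage warning threshold 3k/n (k variables, n samples)."""
    if k < 1 or n < 1:
        raise ADError("h_star requires k >= 1 and n >= 1")
    return 3.0 * k / n


def williams_classify(
    leverages: np.ndarray,
    residuals: np.ndarray,
    h_star_value: float,
    y_bound: float = 2.5,
    abbrevs: list[str] | None = None,
    k: int | None = None,
) -> ADResult:
    """Classify compounds for a Williams plot.

    Standardized residuals divide by the population (n-denominator) SD of
    the residuals. X outliers have leverage strictly above h*; Y outliers
    have |standardized residual| strictly above ``y_bound``.
    """
    lev = np.asarray(leverages, dtype=float).ravel()
    res = np.asarray(residuals, dtype=float).ravel()
    if lev.shape != res.shape:
        raise ADError("leverages and residuals must have equal length")
    sd = float(res.std(ddof=0))
    if sd == 0:
        raise ADError("residual SD is zero; standardized residuals undefined")
    std_res = res / sd
    x_out = lev > h_star_value
    y_out = np.abs(std_res) > y_bound
    labels = np.where(
        x_out & y_out, "both",
        np.where(x_out, "X_outlier", np.where(y_out, "Y_outlier", "in_domain")),
    )
    frame = pd.DataFrame(
        {
            "abbrev": abbrevs if abbrevs is not None else [f"c{i}" for i in range(len(lev))],
            "leverage": lev,
            "std_residual": std_res,
            "class": labels,
        }
    )
    return ADResult(frame=frame, h_star=h_star_value, y_bound=y_bound, k=k, n=len(lev))


def plot_williams(result: ADResult, path: str | Path) -> None:
    """Render the Williams diagram with dashed lines at h* and +/-y_bound."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4.5))
    for label, marker in [("in_domain", "o"), ("X_outlier", "s"), ("Y_outlier", "^"), ("both", "D")]:
        sub = result.frame[result.frame["class"] == label]
        if len(sub):
            ax.scatter(sub["leverage"], sub["std_residual"], marker=marker, label=label)
    ax.axvline(result.h_star, linestyle="--", color="gray")
    ax.axhline(result.y_bound, linestyle="--", color="gray")
    ax.axhline(-result.y_bound, linestyle="--", color="gray")
    ax.set_xlabel("leverage h")
    ax.set_ylabel("standardized residual")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
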