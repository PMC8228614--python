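"""External-set acceptance statistics and permutation controls.

Implements the seven-condition model-acceptance battery over observed vs
predicted test-set activities (squared correlation, external cross-validated
R2, through-origin regressions in both orientations and their slopes),
the external Q2 (F1 convention, denominator about the training mean), and a
seeded Y-randomization check.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from . import pls as _pls

__all__ = [
    "TropshaReport",
    "YRandomizationResult",
    "ValidationError",
    "tropsha_criteria",
    "external_q2",
    "y_randomization",
]


class ValidationError(RuntimeError):
    pass


@dataclass
class TropshaReport:
    """The acceptance-battery statistics with per-criterion booleans.

    Criteria (strict inequalities as published):
    R2 > 0.6; Rcvext2 > 0.5; (R2-R02)/R2 < 0.1; (R2-R0p2)/R2 < 0.1;
    |R02-R0p2| < 0.3; 0.85 <= k <= 1.15; 0.85 <= kp <= 1.15.
    """

    r2: float
    rcvext2: float
    r02: float
    r0p2: float
    k_slope: float
    kp_slope: float
    criteria: dict[str, bool]
    passed: bool

    def to_dict(self) -> dict:
        return {
            "R2": self.r2,
            "Rcvext2": self.rcvext2,
            "R02": self.r02,
            "R0p2": self.r0p2,
            "k": self.k_slope,
            "kp": self.kp_slope,
            "criteria": self.criteria,
            "passed": self.passed,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)


@dataclass
class YRandomizationResult:
    real_q2: float
    real_r2: float
    perm_q2: np.ndarray
    perm_r2: np.ndarray
    p_value: float  # fraction of permutations with q2 >= real q2 (add-one)


def _through_origin(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Slope and R2 of the no-intercept regression of y on x.

    R2 is 1 - SS(residual about the origin line)/SS(y about its mean)."""
    denom = float(np.sum(x * x))
    if denom == 0:
        raise ValidationError("through-origin slope undefined: regressor is zero")
    slope = float(np.sum(x * y)) / denom
    ss_res = float(np.sum((y - slope * x) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        raise ValidationError("through-origin R2 undefined: zero variance")
    return slope, 1.0 - ss_res / ss_tot


def tropsha_criteria(
    y_obs_test: np.ndarray, y_pred_test: np.ndarray, y_train_mean: float
) -> TropshaReport:
    """Evaluate the seven-condition acceptance battery on external pairs."""
    yo = np.asarray(y_obs_test, dtype=float).ravel()
    yp = np.asarray(y_pred_test, dtype=float).ravel()
    if yo.shape != yp.shape or yo.size < 2:
        raise ValidationError("need >= 2 matched observed/predicted pairs")
    if not (np.all(np.isfinite(yo)) and np.all(np.isfinite(yp))):
        raise ValidationError("non-finite values in observed/predicted input")
    if np.ptp(yo) == 0 or np.ptp(yp) == 0:
        raise ValidationError("zero variance: correlation undefined")
    r2 = float(np.corrcoef(yo, yp)[0, 1] ** 2)
    # predicted-vs-observed through origin -> (k, R0^2); swapped -> (k', R'0^2)
    k_slope, r02 = _through_origin(yo, yp)
    kp_slope, r0p2 = _through_origin(yp, yo)
    rcvext2 = external_q2(yo, yp, y_train_mean)
    criteria = {
        "R2_gt_0.6": r2 > 0.6,
        "Rcvext2_gt_0.5": rcvext2 > 0.5,
        "rel_R02_lt_0.1": (r2 - r02) / r2 < 0.1,
        "rel_R0p2_lt_0.1": (r2 - r0p2) / r2 < 0.1,
        "abs_R02_diff_lt_0.3": abs(r02 - r0p2) < 0.3,
        "k_in_0.85_1.15": 0.85 <= k_slope <= 1.15,
        "kp_in_0.85_1.15": 0.85 <= kp_slope <= 1.15,
    }
    return TropshaReport(
        r2=r2,
        rcvext2=rcvext2,
        r02=r02,
        r0p2=r0p2,
        k_slope=k_slope,
        kp_slope=kp_slope,
        criteria=criteria,
        passed=all(criteria.values()),
    )


def external_q2(
    y_obs_test: np.ndarray, y_pred_test: np.ndarray, y_train_mean: float
) -> float:
    """External Q2 (F1 convention): 1 - PRESS / SS about the training mean."""
    yo = np.asarray(y_obs_test, dtype=float).ravel()
    yp = np.asarray(y_pred_test, dtype=float).ravel()
    if yo.size < 1 or yo.shape != yp.shape:
        raise ValidationError("need >= 1 matched observed/predicted pair")
    denom = float(np.sum((yo - y_train_mean) ** 2))
    if denom == 0:
        raise ValidationError("test values all equal the training mean")
    return 1.0 - float(np.sum((yo - yp) ** 2)) / denom


def y_randomization(
    X: np.ndarray,
    y: np.ndarray,
    n_perm: int,
    seed: int,
    n_components: int | None = None,
    max_components: int = 5,
) -> YRandomizationResult:
    """Permute the response ``n_perm`` times and refit.

    The component count is chosen once on the real response (unless given)
    and held fixed across permutations. The p-value is the add-one estimate
    of P(permuted q2 >= real q2).
    """
    if n_perm < 10:
        raise ValidationError("y_randomization requires n_perm >= 10")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    c = n_components or _pls.select_components(X, y, max_components)
    real_q2 = _pls.loo_q2(X, y, c)
    real_model = _pls.fit_pls(X, y, c)
    real_r2, _, _ = _pls.model_stats(real_model, X, y)
    rng = np.random.default_rng(seed)
    perm_q2 = np.empty(n_perm)
    perm_r2 = np.empty(n_perm)
    for i in range(n_perm):
        yp = rng.permutation(y)
        perm_q2[i] = _pls.loo_q2(X, yp, c)
        m = _pls.fit_pls(X, yp, c)
        perm_r2[i], _, _ = _pls.model_stats(m, X, yp)
    p_value = (1.0 + float(np.sum(perm_q2 >= real_q2))) / (n_perm + 1.0)
    return YRandomizationResult(
        real_q2=real_q2, real_r2=real_r2, perm_q2=perm_q2, perm_r2=perm_r2, p_value=p_value
    )
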