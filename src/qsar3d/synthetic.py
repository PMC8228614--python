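"""Seeded synthetic generators for pipeline testing without chemistry.

Three generators mirror the statistical assumptions of the analysis:
low-rank latent descriptor matrices with Gaussian noise (for PLS and
permutation tests), homologous dialkyl diester series with a chain-length-
monotone endpoint (for the end-to-end structural pipeline), and score/
residual sets with planted leverage or response outliers (for the
applicability-domain stage).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ad import h_star, leverage

__all__ = [
    "SyntheticSpec",
    "LatentTruth",
    "ADFixture",
    "gen_latent_pls_data",
    "gen_homologous_series",
    "gen_ad_fixture",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the latent-structure generator.

    X = T P' + noise_sd * N(0,1); y = T c + e with var(e) set so that
    var(Tc)/var(e) = snr. Loadings P are orthonormal; factor scales decay
    linearly so component order is identifiable.
    """

    n_samples: int = 50
    n_columns: int = 30
    n_factors: int = 3
    noise_sd: float = 0.1
    snr: float = 10.0
    seed: int = 0
    factor_scales: tuple[float, ...] | None = None

    def scales(self) -> np.ndarray:
        if self.factor_scales is not None:
            if len(self.factor_scales) != self.n_factors:
                raise ValueError("factor_scales length must equal n_factors")
            return np.asarray(self.factor_scales, dtype=float)
        return np.linspace(3.0, 1.0, self.n_factors)


@dataclass
class LatentTruth:
    """Ground truth of one generated dataset."""

    scores: np.ndarray  # T, (n, k)
    loadings: np.ndarray  # P, (p, k), orthonormal columns
    y_coef: np.ndarray  # c, (k,)
    beta: np.ndarray  # implied coefficient vector P c, (p,)
    noise_sd_y: float


@dataclass
class ADFixture:
    scores: np.ndarray
    residuals: np.ndarray
    x_outlier_idx: list[int] = field(default_factory=list)
    y_outlier_idx: list[int] = field(default_factory=list)
    h_star: float = 0.0


def gen_latent_pls_data(spec: SyntheticSpec) -> tuple[np.ndarray, np.ndarray, LatentTruth]:
    """Draw one (X, y) dataset with known low-rank latent structure."""
    if spec.n_factors < 1 or spec.n_samples <= spec.n_factors:
        raise ValueError("need n_samples > n_factors >= 1")
    if spec.n_columns < spec.n_factors:
        raise ValueError("need n_columns >= n_factors")
    rng = np.random.default_rng(spec.seed)
    T = rng.standard_normal((spec.n_samples, spec.n_factors)) * spec.scales()
    P, _ = np.linalg.qr(rng.standard_normal((spec.n_columns, spec.n_factors)))
    c = np.ones(spec.n_factors)
    signal = T @ c
    sd_y = float(signal.std(ddof=0) / np.sqrt(spec.snr)) if spec.snr > 0 else 0.0
    X = T @ P.T + spec.noise_sd * rng.standard_normal((spec.n_samples, spec.n_columns))
    y = signal + sd_y * rng.standard_normal(spec.n_samples)
    truth = LatentTruth(scores=T, loadings=P, y_coef=c, beta=P @ c, noise_sd_y=sd_y)
    return X, y, truth


def gen_homologous_series(
    min_chain: int = 1,
    max_chain: int = 8,
    intercept: float = 3.5,
    slope: float = 0.1,
) -> tuple[list[str], np.ndarray, list[str]]:
    """Linear-chain dialkyl benzene-1,2-dicarboxylate series.

    Chain length 1 is the dimethyl diester. The synthetic endpoint is
    ``intercept + slope * chain_length`` (strictly increasing for positive
    slope, matching the chain-length trend of the packaged LD50 data).
    Returns (smiles, endpoints, names).
    """
    if not (1 <= min_chain <= max_chain <= 12):
        raise ValueError("need 1 <= min_chain <= max_chain <= 12")
    smiles, names = [], []
    lengths = range(min_chain, max_chain + 1)
    for k in lengths:
        chain = "C" * k
        smiles.append(f"{chain}OC(=O)c1ccccc1C(=O)O{chain}")
        names.append(f"C{k}")
    endpoints = intercept + slope * np.arange(min_chain, max_chain + 1, dtype=float)
    return smiles, endpoints, names


def gen_ad_fixture(
    n: int, k: int, n_outliers: int = 0, seed: int = 0, kind: str = "x"
) -> ADFixture:
    """Score matrix + residuals with planted outliers.

    ``kind`` selects what is planted: "x" (high-leverage rows), "y" (large
    residuals) or "both". Planted points exceed the h* = 3k/n threshold or
    the +/-2.5 standardized-residual bound by at least a 20% margin.
    """
    if n <= k:
        raise ValueError("need n > k")
    if kind not in ("x", "y", "both"):
        raise ValueError("kind must be 'x', 'y' or 'both'")
    rng = np.random.default_rng(seed)
    scores = rng.standard_normal((n, k))
    residuals = rng.standard_normal(n)
    hs = h_star(k, n)
    # keep the natural points strictly inside both bounds before planting
    for _ in range(20):
        lev = leverage(scores)
        high = np.flatnonzero(lev > 0.9 * hs)
        if high.size == 0:
            break
        scores[high] *= 0.5
    for _ in range(20):
        ratio = np.abs(residuals / residuals.std(ddof=0))
        high = np.flatnonzero(ratio > 2.0)
        if high.size == 0:
            break
        residuals[high] *= 0.5
    fixture = ADFixture(scores=scores, residuals=residuals, h_star=hs)
    if n_outliers == 0:
        return fixture
    idx = list(range(n - n_outliers, n))
    if kind in ("x", "both"):
        direction = np.ones(k) / np.sqrt(k)
        for i in idx:
            scale = 1.0
            for _ in range(60):
                scores[i] = direction * scale
                if leverage(scores)[i] >= 1.2 * hs:
                    break
                scale *= 1.5
            else:
                raise RuntimeError("could not plant a leverage outlier")
        fixture.x_outlier_idx = idx
    if kind in ("y", "both"):
        for i in idx:
            target = 1.2 * 2.5
            mag = target * residuals.std(ddof=0)
            for _ in range(60):
                residuals[i] = mag
                if abs(residuals[i]) / residuals.std(ddof=0) >= target:
                    break
                mag *= 1.5
            else:
                raise RuntimeError("could not plant a residual outlier")
        fixture.y_outlier_idx = idx
    return fixture
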