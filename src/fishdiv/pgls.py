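"""Phylogenetic generalized least squares with bootstrap confidence intervals.

The model is ``y = X b + e`` with ``e ~ N(0, V s2)`` where V is the
Brownian shared-ancestry covariance from the rank tree. Categorical models
use cell-means coding (one indicator per level, no intercept) so each
coefficient is that level's taxonomically corrected mean; continuous models
use intercept plus slope and report the slope.

Uncertainty comes from a nonparametric species bootstrap on the whitened
model: with ``V = L L'`` the rows of ``(L^-1 X, L^-1 y)`` are exchangeable
under the model, so resampling them with replacement and refitting by OLS
is the pairs bootstrap of the GLS estimator. At ``V = I`` this is exactly
the classical i.i.d. pairs bootstrap. (Rebuilding V per resample with
duplicated species at covariance 1 is not an option: a cluster of k
identical copies at correlation ~1 carries the GLS weight of one
observation, so resample multiplicities would be discarded and intervals
systematically narrowed.) Percentile intervals are read off the resampled
coefficient distribution. Group differences are judged by
confidence-interval overlap:
an interval excluding zero marks a nonzero coefficient, and two groups
differ when their intervals do not overlap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg

from .config import PGLSConfig
from .taxonomy import BrownianCovariance

logger = logging.getLogger(__name__)


class SingularDesignError(ValueError):
    """Design matrix is rank deficient on the fitted subset."""


@dataclass(frozen=True)
class DesignMatrix:
    """Model matrix with labelled columns.

    ``factor`` marks cell-means indicator columns: a bootstrap resample that
    zeroes one of them has emptied a level and is redrawn.
    """

    X: np.ndarray
    labels: tuple[str, ...]
    factor: bool


def cell_means_design(levels: pd.Series | np.ndarray) -> DesignMatrix:
    """One indicator column per factor level, no intercept.

    Column order follows first appearance so the design is deterministic in
    input order.
    """
    values = np.asarray(levels, dtype=object)
    seen: list[str] = []
    for v in values:
        if v not in seen:
            seen.append(str(v))
    X = np.column_stack([(values == lvl).astype(float) for lvl in seen])
    return DesignMatrix(X=X, labels=tuple(seen), factor=True)


def slope_design(x: np.ndarray, label: str = "slope") -> DesignMatrix:
    """Intercept plus a single continuous predictor."""
    x = np.asarray(x, dtype=float)
    X = np.column_stack([np.ones_like(x), x])
    return DesignMatrix(X=X, labels=("intercept", label), factor=False)


@dataclass(frozen=True)
class PGLSFit:
    coefficients: dict[str, float]
    sigma2: float
    n: int
    p: int
    loglik: float

    def coef(self, label: str) -> float:
        return self.coefficients[label]


def _whitening_factor(V: np.ndarray, nugget: float) -> np.ndarray:
    """Lower Cholesky factor of V (+nugget), with eigenvalue-clip fallback."""
    Vn = V + nugget * np.eye(V.shape[0])
    try:
        return linalg.cholesky(Vn, lower=True)
    except linalg.LinAlgError:
        w, Q = linalg.eigh(Vn)
        w = np.clip(w, 1e-10, None)
        logger.warning("V not positive definite; eigenvalues clipped at 1e-10")
        return linalg.cholesky((Q * w) @ Q.T, lower=True)


def gls_fit(
    design: DesignMatrix,
    y: np.ndarray,
    V: BrownianCovariance | np.ndarray,
    nugget: float = 1e-8,
) -> PGLSFit:
    """Closed-form GLS fit via Cholesky whitening.

    Solves ``b = (X' V^-1 X)^-1 X' V^-1 y`` by ordinary least squares on the
    whitened system ``L^-1 X, L^-1 y`` with ``V = L L'``; the residual scale
    is ``s2 = r' V^-1 r / (n - p)``. With V the identity this reduces
    exactly to OLS.
    """
    Vm = V.matrix if isinstance(V, BrownianCovariance) else np.asarray(V, float)
    X, y = np.asarray(design.X, float), np.asarray(y, float)
    n, p = X.shape
    if Vm.shape != (n, n) or y.shape[0] != n:
        raise ValueError("X, y and V dimensions are not aligned")
    if np.linalg.matrix_rank(X) < p:
        col_norm = np.linalg.norm(X, axis=0)
        aliased = [design.labels[j] for j in np.where(col_norm == 0)[0]] or list(
            design.labels
        )
        raise SingularDesignError(f"rank-deficient design; check columns {aliased}")
    L = _whitening_factor(Vm, nugget)
    Xw = linalg.solve_triangular(L, X, lower=True)
    yw = linalg.solve_triangular(L, y, lower=True)
    beta, _, _, _ = np.linalg.lstsq(Xw, yw, rcond=None)
    rw = yw - Xw @ beta
    rss = float(rw @ rw)
    sigma2 = rss / (n - p) if n > p else float("nan")
    logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
    loglik = -0.5 * (n * np.log(2.0 * np.pi * max(rss / n, 1e-300)) + logdet + n)
    return PGLSFit(
        coefficients=dict(zip(design.labels, map(float, beta))),
        sigma2=sigma2,
        n=n,
        p=p,
        loglik=loglik,
    )


@dataclass(frozen=True)
class BootstrapCI:
    """Percentile bootstrap intervals per coefficient.

    ``draws`` keeps the raw resampled coefficients (B x p) so that derived
    quantities — notably percentile intervals of coefficient differences,
    which cancel variance components shared between groups — can be read
    off the joint distribution rather than from the marginal intervals.
    """

    estimates: dict[str, float]
    lower: dict[str, float]
    upper: dict[str, float]
    iterations: int
    seed: int
    n_redrawn: int = 0
    draws: np.ndarray | None = None

    def interval(self, label: str) -> tuple[float, float]:
        return (self.lower[label], self.upper[label])

    def difference_interval(
        self, label_a: str, label_b: str, level: float = 0.95
    ) -> tuple[float, float]:
        """Percentile CI of coefficient ``a - b`` from the joint draws."""
        if self.draws is None:
            raise ValueError("bootstrap draws were not retained")
        labels = list(self.estimates)
        diff = (self.draws[:, labels.index(label_a)]
                - self.draws[:, labels.index(label_b)])
        alpha = 1.0 - level
        lo, hi = np.percentile(diff, [100 * alpha / 2, 100 * (1 - alpha / 2)])
        return float(lo), float(hi)


def bootstrap_ci(
    design: DesignMatrix,
    y: np.ndarray,
    V: BrownianCovariance,
    cfg: PGLSConfig | None = None,
    seed: int = 0,
) -> BootstrapCI:
    """Species bootstrap of GLS coefficients via whitened-pairs resampling.

    The model is whitened once with the Cholesky factor of V; each of
    ``cfg.bootstrap_iterations`` resamples then draws whitened rows with
    replacement and refits by OLS. A resample that leaves a factor level
    empty (judged on the original indicator columns) is redrawn and logged.
    Point estimates come from the full-data fit.
    """
    cfg = cfg or PGLSConfig()
    if cfg.bootstrap_iterations < 100:
        raise ValueError("bootstrap_iterations must be >= 100")
    rng = np.random.default_rng(seed)
    X, y = np.asarray(design.X, float), np.asarray(y, float)
    n, p = X.shape
    full = gls_fit(design, y, V, cfg.nugget)
    Vm = V.matrix if isinstance(V, BrownianCovariance) else np.asarray(V, float)
    L = _whitening_factor(Vm, cfg.nugget)
    Xw = linalg.solve_triangular(L, X, lower=True)
    yw = linalg.solve_triangular(L, y, lower=True)
    draws = np.empty((cfg.bootstrap_iterations, p))
    n_redrawn = 0
    for b in range(cfg.bootstrap_iterations):
        for _ in range(cfg.max_redraws):
            idx = rng.integers(0, n, size=n)
            if design.factor and np.any(X[idx].sum(axis=0) == 0):
                n_redrawn += 1
                continue
            break
        else:
            raise RuntimeError("could not draw a resample with all factor levels")
        draws[b], _, _, _ = np.linalg.lstsq(Xw[idx], yw[idx], rcond=None)
    if n_redrawn:
        logger.info("bootstrap: redrew %d resamples with empty factor levels",
                    n_redrawn)
    alpha = 1.0 - cfg.ci_level
    lo = np.percentile(draws, 100 * alpha / 2, axis=0)
    hi = np.percentile(draws, 100 * (1 - alpha / 2), axis=0)
    return BootstrapCI(
        estimates={k: full.coefficients[k] for k in design.labels},
        lower=dict(zip(design.labels, map(float, lo))),
        upper=dict(zip(design.labels, map(float, hi))),
        iterations=cfg.bootstrap_iterations,
        seed=seed,
        n_redrawn=n_redrawn,
        draws=draws,
    )


def significant_nonzero(interval: tuple[float, float]) -> bool:
    """True when a closed confidence interval excludes zero."""
    lo, hi = interval
    return not (lo <= 0.0 <= hi)


def compare_groups(
    interval_a: tuple[float, float], interval_b: tuple[float, float]
) -> bool:
    """True when two closed intervals do not overlap (groups differ)."""
    return max(interval_a[0], interval_b[0]) > min(interval_a[1], interval_b[1])
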