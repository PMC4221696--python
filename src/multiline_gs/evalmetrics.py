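"""Evaluation machinery: hatch-week pre-correction, predictive correlation
with its approximate standard error, and the bias regression with a
bootstrap SE and the |b1 - 1| < 2 SE compatibility rule.

The predictive correlation is the Pearson correlation between validation
phenotypes and GEBV; its approximate SE is (1 - rho^2) / sqrt(N - 2) with
N the number of validation animals. The bias coefficient b1 is the OLS
slope of phenotype on GEBV (1 = unbiased scale); its SE is the standard
deviation of the slope over B bootstrap resamples of the validation
animals.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

__all__ = [
    "EvaluationReport",
    "precorrect",
    "predictive_correlation",
    "correlation_se",
    "bias_regression",
    "evaluate_predictions",
    "round_half_up",
]


def round_half_up(x: float, ndigits: int = 3) -> float:
    """Decimal half-up rounding, matching tabular reporting conventions."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class EvaluationReport:
    rho: float
    se_rho: float
    n_validation: int
    b1: float
    se_b1: float
    b1_compatible_with_1: bool
    n_bootstrap: int
    seed: int
    n_redrawn: int = 0

    def to_dict(self) -> dict:
        return {
            "rho": self.rho,
            "se_rho": self.se_rho,
            "n_validation": self.n_validation,
            "b1": self.b1,
            "se_b1": self.se_b1,
            "b1_compatible_with_1": self.b1_compatible_with_1,
            "n_bootstrap": self.n_bootstrap,
            "seed": self.seed,
            "n_redrawn": self.n_redrawn,
        }


def precorrect(
    phenotypes: np.ndarray,
    factor_levels: np.ndarray,
    train_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Subtract per-level means of a one-way fixed effect (hatch week).

    Level means are least-squares estimates from the training animals
    (`train_mask`, default: all); every animal is corrected with the
    training estimate of its level. A level present outside training but
    absent from it is an error.
    """
    y = np.asarray(phenotypes, dtype=float)
    levels = np.asarray(factor_levels)
    if len(y) != len(levels):
        raise ValueError("phenotypes and factor levels must align")
    if train_mask is None:
        train_mask = np.ones(len(y), dtype=bool)
    train_mask = np.asarray(train_mask, dtype=bool)
    if not train_mask.any():
        raise ValueError("no training observations to estimate level means")
    means = {}
    for lev in np.unique(levels[train_mask]):
        means[lev] = y[train_mask & (levels == lev)].mean()
    unseen = set(np.unique(levels)) - set(means)
    if unseen:
        raise ValueError(f"factor levels unseen in training: {sorted(unseen)}")
    return y - np.array([means[lev] for lev in levels])


def predictive_correlation(y_valid: np.ndarray, gebv: np.ndarray) -> float:
    y = np.asarray(y_valid, dtype=float)
    g = np.asarray(gebv, dtype=float)
    if len(y) != len(g):
        raise ValueError("phenotypes and GEBV must align")
    if len(y) < 3:
        raise ValueError("need at least 3 validation animals")
    if np.std(g) == 0:
        raise ValueError("GEBV have zero variance; correlation undefined")
    if np.std(y) == 0:
        raise ValueError("phenotypes have zero variance; correlation undefined")
    return float(np.corrcoef(y, g)[0, 1])


def correlation_se(rho: float, N: int) -> float:
    """Approximate sampling SE of a correlation: (1 - rho^2)/sqrt(N - 2)."""
    if N < 3:
        raise ValueError("N must be >= 3")
    if not -1.0 <= rho <= 1.0:
        raise ValueError("rho must be in [-1, 1]")
    return float((1.0 - rho**2) / np.sqrt(N - 2))


def _ols_slope(y: np.ndarray, x: np.ndarray) -> float:
    xc = x - x.mean()
    return float((xc @ y) / (xc @ xc))


def bias_regression(
    y_valid: np.ndarray,
    gebv: np.ndarray,
    B: int = 10_000,
    seed: int = 0,
) -> tuple[float, float, bool, int]:
    """OLS slope of phenotype on GEBV with a bootstrap SE.

    Animals are resampled with replacement B times; a resample whose GEBV
    are constant (slope undefined) is redrawn and counted. Returns
    (b1, se_b1, compatible_with_1, n_redrawn) with the compatibility flag
    true iff |b1 - 1| < 2 se_b1.
    """
    y = np.asarray(y_valid, dtype=float)
    g = np.asarray(gebv, dtype=float)
    N = len(y)
    if B < 100:
        raise ValueError("B must be >= 100")
    if N < 10:
        raise ValueError("need at least 10 validation animals")
    if np.std(g) == 0:
        raise ValueError("GEBV have zero variance; slope undefined")
    b1 = _ols_slope(y, g)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, N, size=(B, N))
    gx = g[idx]
    gy = y[idx]
    var = gx.var(axis=1)
    n_redrawn = 0
    bad = np.flatnonzero(var <= 0)
    while bad.size:
        n_redrawn += bad.size
        idx_new = rng.integers(0, N, size=(bad.size, N))
        gx[bad] = g[idx_new]
        gy[bad] = y[idx_new]
        var[bad] = gx[bad].var(axis=1)
        bad = np.flatnonzero(var <= 0)
    cov = (gx * gy).mean(axis=1) - gx.mean(axis=1) * gy.mean(axis=1)
    slopes = cov / var
    se_b1 = float(slopes.std(ddof=1))
    # the tiny absolute slack keeps the exact-identity case (se_b1 = 0 to
    # machine precision) flagged as unbiased
    flag = bool(abs(b1 - 1.0) < 2.0 * se_b1 + 1e-12)
    return b1, se_b1, flag, n_redrawn


def evaluate_predictions(
    y_valid: np.ndarray,
    gebv: np.ndarray,
    B: int = 10_000,
    seed: int = 0,
) -> EvaluationReport:
    """Full validation report: rho, approximate SE, bias regression."""
    rho = predictive_correlation(y_valid, gebv)
    N = len(np.asarray(y_valid))
    b1, se_b1, flag, n_redrawn = bias_regression(y_valid, gebv, B=B, seed=seed)
    return EvaluationReport(
        rho=rho,
        se_rho=correlation_se(rho, N),
        n_validation=N,
        b1=b1,
        se_b1=se_b1,
        b1_compatible_with_1=flag,
        n_bootstrap=B,
        seed=seed,
        n_redrawn=n_redrawn,
    )
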