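"""Model blending and complementarity.

Two models' predictions are combined as a_hat = beta a1 + (1 - beta) a2
with beta in [0, 1]; a sweep over beta traces the predictive correlation of
the blend, and the complementarity of a model set is summarized by the
correlation matrix of their predictions on common validation animals.

The beta sweep is evaluated on the validation data itself (no inner
holdout), which is an optimistic reading of blending benefit; it mirrors
how such curves are usually presented and is documented as such.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .evalmetrics import predictive_correlation

__all__ = ["BlendResult", "combine", "beta_sweep", "complementarity_matrix"]


@dataclass
class BlendResult:
    beta_grid: np.ndarray
    rho: np.ndarray
    argmax_beta: float
    labels: tuple[str, str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"beta": self.beta_grid, "rho": self.rho,
             "pair": f"{self.labels[0]}+{self.labels[1]}"}
        )


def combine(a1: np.ndarray, a2: np.ndarray, beta: float) -> np.ndarray:
    """Element-wise convex combination beta*a1 + (1-beta)*a2."""
    a1 = np.asarray(a1, dtype=float)
    a2 = np.asarray(a2, dtype=float)
    if a1.shape != a2.shape:
        raise ValueError("predictions must align")
    if not 0.0 <= beta <= 1.0:
        raise ValueError("beta must be in [0, 1]")
    return beta * a1 + (1.0 - beta) * a2


def beta_sweep(
    a1: np.ndarray,
    a2: np.ndarray,
    y_valid: np.ndarray,
    grid_step: float = 0.05,
    labels: tuple[str, str] = ("model1", "model2"),
) -> BlendResult:
    """Predictive correlation of the blend over beta = 0, step, ..., 1.

    Endpoints equal the two single-model predictive correlations exactly.
    """
    n_steps = round(1.0 / grid_step)
    if abs(n_steps * grid_step - 1.0) > 1e-9:
        raise ValueError("grid_step must divide 1 evenly")
    grid = np.linspace(0.0, 1.0, n_steps + 1)
    rho = np.array(
        [predictive_correlation(y_valid, combine(a1, a2, b)) for b in grid]
    )
    return BlendResult(
        beta_grid=grid,
        rho=rho,
        argmax_beta=float(grid[int(np.argmax(rho))]),
        labels=labels,
    )


def complementarity_matrix(predictions: dict[str, np.ndarray]) -> pd.DataFrame:
    """Pearson correlation matrix between the models' predictions."""
    names = list(predictions)
    arrs = [np.asarray(predictions[k], dtype=float) for k in names]
    n = {a.shape for a in arrs}
    if len(n) != 1:
        raise ValueError("all predictions must cover the same animals")
    C = np.eye(len(names))
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            C[i, j] = C[j, i] = float(np.corrcoef(arrs[i], arrs[j])[0, 1])
    return pd.DataFrame(C, index=names, columns=names)
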