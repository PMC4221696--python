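"""Reported validation results from the multi-line layer-hen study this
package re-implements, kept as plain data for cross-checks.

`B1_PREDICTIVE_CORRELATIONS` holds the predictive correlations reported for
the B1 validation line: seven models (rows) by seven training sets
(columns). The study quotes, alongside this table, a range of approximate
standard errors of these correlations (0.058 to 0.065 after rounding to
three decimals), obtained from se = (1 - rho^2) / sqrt(N - 2) with N = 240
validation animals; :func:`se_range` recomputes that range from the table.

`GENETIC_CORRELATIONS` holds the reported between-line genetic correlations
of the trait (with their standard errors), which the synthetic-data
generator uses as its default architecture.
"""

from __future__ import annotations

import numpy as np

from .evalmetrics import correlation_se, round_half_up

__all__ = [
    "B1_PREDICTIVE_CORRELATIONS",
    "MODELS",
    "TRAINING_SETS",
    "GENETIC_CORRELATIONS",
    "N_VALIDATION",
    "se_range",
]

MODELS = ("GBLUP", "RRPCA", "MTGBLUP", "Poly", "PolyPCA", "RBF", "RBFPCA")
TRAINING_SETS = ("B1", "B2", "W1", "B1+B2", "B1+W1", "B2+W1", "B1+B2+W1")
N_VALIDATION = 240

B1_PREDICTIVE_CORRELATIONS = np.array(
    [
        [0.322, 0.182, -0.033, 0.316, 0.306, 0.149, 0.304],  # GBLUP
        [0.286, 0.147, 0.064, 0.280, 0.279, 0.156, 0.276],   # RRPCA
        [0.282, 0.194, -0.037, 0.293, 0.274, 0.190, 0.292],  # MTGBLUP
        [0.281, -0.026, 0.013, 0.281, 0.283, 0.008, 0.283],  # Poly
        [0.280, -0.046, 0.013, 0.280, 0.282, 0.007, 0.282],  # PolyPCA
        [0.315, 0.206, 0.006, 0.321, 0.315, 0.204, 0.321],   # RBF
        [0.281, 0.128, 0.029, 0.285, 0.281, 0.129, 0.285],   # RBFPCA
    ]
)

#: Between-line genetic correlations (lower triangle) with SEs in brackets:
#: r(B1,B2)=0.63 (0.14), r(B1,W1)=-0.26 (0.37), r(B2,W1)=-0.55 (0.37).
GENETIC_CORRELATIONS = {
    ("B1", "B2"): (0.63, 0.14),
    ("B1", "W1"): (-0.26, 0.37),
    ("B2", "W1"): (-0.55, 0.37),
}


def se_range(
    correlations: np.ndarray = B1_PREDICTIVE_CORRELATIONS,
    n_validation: int = N_VALIDATION,
) -> tuple[float, float]:
    """Approximate-SE range over a table of predictive correlations,
    rounded to three decimals (the precision at which it is reported)."""
    ses = [
        round_half_up(correlation_se(float(r), n_validation), 3)
        for r in np.asarray(correlations).ravel()
    ]
    return min(ses), max(ses)
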