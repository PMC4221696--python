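"""Genomic REML variance components.

Single-trait and bivariate (two-line) restricted maximum likelihood on a
genomic relationship matrix, by expectation-maximization updates. EM is
monotone in the REML log-likelihood, which is asserted on every accepted
iterate; an extrapolated (SQUAREM-style) step is attempted each cycle and
kept only when it does not decrease the likelihood, so the recorded trace
stays monotone while convergence is much faster than plain EM. Standard
errors come from the inverse average-information matrix at the optimum.

In the bivariate model the same trait measured in two lines is treated as
two traits observed on disjoint animals: y = Xb + u + e with
u ~ N(0, Sigma_g x G) (Kronecker) and a diagonal, per-trait residual.
The genetic correlation r = sigma_g12 / sqrt(sigma_g1^2 sigma_g2^2) is the
quantity MTGBLUP consumes.

Three-line correlation matrices are assembled from the three pairwise runs
(no trivariate joint REML); a non-PSD assembly is bent by eigenvalue
flooring and flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

from .simdata import bend_correlation

__all__ = [
    "VarianceComponents",
    "UnivariateREMLResult",
    "reml_univariate",
    "reml_bivariate",
    "pairwise_components",
]

_MONOTONE_SLACK = 1e-6


@dataclass
class UnivariateREMLResult:
    genetic_variance: float
    residual_variance: float
    heritability: float
    se_genetic: float
    se_residual: float
    se_heritability: float
    log_likelihood_trace: list
    converged: bool
    boundary: bool


@dataclass
class VarianceComponents:
    """Per-line variances and the between-line genetic correlation matrix."""

    line_names: tuple
    genetic_variance: np.ndarray
    residual_variance: np.ndarray
    genetic_correlation: np.ndarray
    standard_errors: dict = field(default_factory=dict)
    log_likelihood_trace: list = field(default_factory=list)
    converged: bool = True
    boundary: bool = False
    bent: bool = False

    def __post_init__(self) -> None:
        self.genetic_variance = np.atleast_1d(np.asarray(self.genetic_variance, float))
        self.residual_variance = np.atleast_1d(np.asarray(self.residual_variance, float))
        self.genetic_correlation = np.asarray(self.genetic_correlation, float)
        if (self.genetic_variance <= 0).any() or (self.residual_variance <= 0).any():
            raise ValueError("variances must be positive")
        C = self.genetic_correlation
        if not np.allclose(C, C.T, atol=1e-8) or not np.allclose(np.diag(C), 1.0):
            raise ValueError("correlation matrix must be symmetric unit-diagonal")
        if np.abs(C).max() > 1.0 + 1e-8:
            raise ValueError("correlations must lie in [-1, 1]")

    @property
    def heritability(self) -> np.ndarray:
        return self.genetic_variance / (self.genetic_variance + self.residual_variance)

    def to_yaml(self, path) -> None:
        raw = {
            "line_names": list(self.line_names),
            "genetic_variance": self.genetic_variance.tolist(),
            "residual_variance": self.residual_variance.tolist(),
            "genetic_correlation": self.genetic_correlation.tolist(),
            "converged": bool(self.converged),
            "boundary": bool(self.boundary),
            "bent": bool(self.bent),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "VarianceComponents":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(
            line_names=tuple(raw["line_names"]),
            genetic_variance=np.asarray(raw["genetic_variance"], float),
            residual_variance=np.asarray(raw["residual_variance"], float),
            genetic_correlation=np.asarray(raw["genetic_correlation"], float),
            converged=raw.get("converged", True),
            boundary=raw.get("boundary", False),
            bent=raw.get("bent", False),
        )


def _check_monotone(trace: list, new: float) -> None:
    if trace and new < trace[-1] - _MONOTONE_SLACK * (1.0 + abs(trace[-1])):
        raise RuntimeError(
            f"REML log-likelihood decreased: {trace[-1]:.6f} -> {new:.6f}"
        )


# ---------------------------------------------------------------------------
# univariate


def reml_univariate(
    G: np.ndarray,
    y: np.ndarray,
    init: tuple[float, float] | None = None,
    tol: float = 1e-6,
    max_iter: int = 2000,
) -> UnivariateREMLResult:
    """EM-REML for one trait: y = mu + u + e, u ~ N(0, sigma_g^2 G).

    G is eigendecomposed once so each EM iteration is O(n).
    """
    G = np.asarray(G, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if G.shape != (n, n):
        raise ValueError("G and y dimensions disagree")
    if n < 5:
        raise ValueError("too few records for REML")
    lam, U = np.linalg.eigh((G + G.T) / 2.0)
    lam = np.maximum(lam, 0.0)
    yt = U.T @ y
    xt = U.T @ np.ones(n)

    vary = float(np.var(y))
    floor = 1e-8 * vary
    if init is None:
        sg, se = vary / 2.0, vary / 2.0
    else:
        sg, se = (float(v) for v in init)

    def stats(sg, se):
        d = 1.0 / (sg * lam + se)
        xdx = float(np.sum(d * xt * xt))
        xdy = float(np.sum(d * xt * yt))
        Py = d * yt - d * xt * (xdy / xdx)
        trP = float(np.sum(d) - np.sum(d * d * xt * xt) / xdx)
        trLP = float(np.sum(lam * d) - np.sum(lam * d * d * xt * xt) / xdx)
        logl = -0.5 * (
            float(np.sum(np.log(sg * lam + se))) + np.log(xdx) + float(yt @ Py)
        )
        return Py, trP, trLP, logl

    def em(sg, se):
        Py, trP, trLP, logl = stats(sg, se)
        sg_new = sg + sg * sg * (float(np.sum(lam * Py * Py)) - trLP) / n
        se_new = se + se * se * (float(np.sum(Py * Py)) - trP) / n
        return max(sg_new, floor), max(se_new, floor), logl

    trace: list[float] = []
    converged = False
    it = 0
    while it < max_iter:
        sg1, se1, logl0 = em(sg, se)
        _check_monotone(trace, logl0)
        trace.append(logl0)
        sg2, se2, logl1 = em(sg1, se1)
        # Aitken-style extrapolation with likelihood safeguard
        r = np.array([sg1 - sg, se1 - se])
        v = np.array([sg2 - sg1, se2 - se1]) - r
        accepted = (sg2, se2)
        if np.linalg.norm(v) > 1e-14:
            a = -np.linalg.norm(r) / np.linalg.norm(v)
            cand = np.array([sg, se]) - 2 * a * r + a * a * v
            if (cand > floor).all():
                _, _, _, logl_cand = stats(*cand)
                _, _, _, logl2 = stats(sg2, se2)
                if logl_cand >= logl2:
                    accepted = tuple(cand)
        delta = max(abs(accepted[0] - sg), abs(accepted[1] - se))
        rel = delta / max(vary, 1e-12)
        prev_logl = trace[-1]
        sg, se = accepted
        it += 2
        _, _, _, cur = stats(sg, se)
        if abs(cur - prev_logl) < tol or rel < 1e-8:
            converged = True
            trace.append(cur)
            break
    else:
        _, _, _, cur = stats(sg, se)
        trace.append(cur)

    boundary = sg <= floor * 1.5 or se <= floor * 1.5
    # average-information SEs
    Py, trP, trLP, _ = stats(sg, se)
    d = 1.0 / (sg * lam + se)
    xdx = float(np.sum(d * xt * xt))

    def P_apply(v):
        return d * v - d * xt * (float(np.sum(d * xt * v)) / xdx)

    v1 = lam * Py
    v2 = Py
    AI = 0.5 * np.array(
        [
            [float(v1 @ P_apply(v1)), float(v1 @ P_apply(v2))],
            [float(v2 @ P_apply(v1)), float(v2 @ P_apply(v2))],
        ]
    )
    cov = np.linalg.pinv(AI)
    se_g = float(np.sqrt(max(cov[0, 0], 0.0)))
    se_e = float(np.sqrt(max(cov[1, 1], 0.0)))
    s = sg + se
    grad = np.array([se / s**2, -sg / s**2])
    se_h2 = float(np.sqrt(max(grad @ cov @ grad, 0.0)))
    return UnivariateREMLResult(
        genetic_variance=float(sg),
        residual_variance=float(se),
        heritability=float(sg / s),
        se_genetic=se_g,
        se_residual=se_e,
        se_heritability=se_h2,
        log_likelihood_trace=trace,
        converged=converged,
        boundary=boundary,
    )


# ---------------------------------------------------------------------------
# bivariate


class _BivariateData:
    def __init__(self, G, y1, y2):
        G = np.asarray(G, dtype=float)
        self.y1 = np.asarray(y1, dtype=float)
        self.y2 = np.asarray(y2, dtype=float)
        self.n1, self.n2 = len(self.y1), len(self.y2)
        self.n = self.n1 + self.n2
        if G.shape != (self.n, self.n):
            raise ValueError(
                "G must cover the line-1 then line-2 animals "
                f"({self.n} total), got {G.shape}"
            )
        self.G = (G + G.T) / 2.0
        self.G11 = self.G[: self.n1, : self.n1]
        self.G12 = self.G[: self.n1, self.n1 :]
        self.G22 = self.G[self.n1 :, self.n1 :]
        self.y = np.concatenate([self.y1, self.y2])
        X = np.zeros((self.n, 2))
        X[: self.n1, 0] = 1.0
        X[self.n1 :, 1] = 1.0
        self.X = X


def _biv_core(theta, data: _BivariateData):
    """Projection quantities shared by the EM step and the likelihood."""
    from scipy.linalg import lapack

    g11, g12, g22, e1, e2 = theta
    n1 = data.n1
    V = np.empty((data.n, data.n))
    V[:n1, :n1] = g11 * data.G11 + e1 * np.eye(n1)
    V[:n1, n1:] = g12 * data.G12
    V[n1:, :n1] = g12 * data.G12.T
    V[n1:, n1:] = g22 * data.G22 + e2 * np.eye(data.n2)
    c, info = lapack.dpotrf(V, lower=1, overwrite_a=False)
    if info != 0:
        jitter = 1e-10 * np.trace(V) / data.n
        c, info = lapack.dpotrf(V + jitter * np.eye(data.n), lower=1)
        if info != 0:
            raise np.linalg.LinAlgError("V is not positive definite")
    logdetV = 2.0 * float(np.sum(np.log(np.diag(c))))
    inv, info = lapack.dpotri(c, lower=1)
    if info != 0:
        raise np.linalg.LinAlgError("inversion of V failed")
    Vinv = np.tril(inv) + np.tril(inv, -1).T
    VX = Vinv @ data.X
    XVX = data.X.T @ VX
    XVX_inv = np.linalg.inv(XVX)
    P = Vinv - VX @ XVX_inv @ VX.T
    Py = P @ data.y
    logl = -0.5 * (
        logdetV + float(np.log(np.linalg.det(XVX))) + float(data.y @ Py)
    )
    return P, Py, logl


def _biv_loglik(theta, data):
    return _biv_core(theta, data)[2]


def _biv_em_step(theta, data: _BivariateData):
    g11, g12, g22, e1, e2 = theta
    n1, n2, n = data.n1, data.n2, data.n
    P, Py, logl = _biv_core(theta, data)
    Sigma = np.array([[g11, g12], [g12, g22]])

    S = np.zeros((n, 2))
    S[:n1, 0] = Py[:n1]
    S[n1:, 1] = Py[n1:]
    Q = S.T @ data.G @ S
    E = P * data.G
    T = np.array(
        [
            [E[:n1, :n1].sum(), E[:n1, n1:].sum()],
            [E[n1:, :n1].sum(), E[n1:, n1:].sum()],
        ]
    )
    Sigma_new = Sigma + Sigma @ (Q - T) @ Sigma / n

    trP11 = float(np.trace(P[:n1, :n1]))
    trP22 = float(np.trace(P[n1:, n1:]))
    e1_new = e1 + e1 * e1 * (float(Py[:n1] @ Py[:n1]) - trP11) / n1
    e2_new = e2 + e2 * e2 * (float(Py[n1:] @ Py[n1:]) - trP22) / n2
    theta_new = np.array(
        [Sigma_new[0, 0], Sigma_new[0, 1], Sigma_new[1, 1], e1_new, e2_new]
    )
    return theta_new, logl


def _biv_valid(theta, floor):
    g11, g12, g22, e1, e2 = theta
    return (
        g11 > floor
        and g22 > floor
        and e1 > floor
        and e2 > floor
        and g12 * g12 < g11 * g22 * (1.0 - 1e-10)
    )


def reml_bivariate(
    G: np.ndarray,
    y_line1: np.ndarray,
    y_line2: np.ndarray,
    init: np.ndarray | None = None,
    tol: float = 1e-4,
    max_iter: int = 500,
    line_names: tuple = ("line1", "line2"),
) -> VarianceComponents:
    """Bivariate EM-REML over two lines' phenotyped animals.

    `G` covers the line-1 animals first, then the line-2 animals. Each
    animal is phenotyped for its own line's trait only. Returns per-line
    genetic and residual variances, the genetic correlation with its
    average-information SE, the log-likelihood trace and convergence flags.
    """
    if len(np.atleast_1d(y_line2)) == 0 or len(np.atleast_1d(y_line1)) == 0:
        raise ValueError("both lines need records; use reml_univariate for one trait")
    data = _BivariateData(G, y_line1, y_line2)
    v1, v2 = float(np.var(data.y1)), float(np.var(data.y2))
    floor = 1e-8 * max(v1, v2)
    if init is None:
        theta = np.array([v1 / 2.0, 0.0, v2 / 2.0, v1 / 2.0, v2 / 2.0])
    else:
        theta = np.asarray(init, dtype=float).copy()

    trace: list[float] = []
    converged = False
    it = 0
    while it < max_iter and not converged:
        # two plain EM steps; each returns the likelihood at its input
        theta1, logl0 = _biv_em_step(theta, data)
        theta1 = _clip_biv(theta1, floor)
        _check_monotone(trace, logl0)
        trace.append(logl0)
        if len(trace) >= 2 and abs(trace[-1] - trace[-2]) < tol:
            theta = theta1
            converged = True
            break
        theta2, logl1 = _biv_em_step(theta1, data)
        theta2 = _clip_biv(theta2, floor)
        _check_monotone(trace, logl1)
        trace.append(logl1)
        if abs(trace[-1] - trace[-2]) < tol:
            theta = theta2
            converged = True
            break
        # extrapolated step, kept only if it does not lose likelihood
        r = theta1 - theta
        v = (theta2 - theta1) - r
        accepted = theta2  # logL(theta2) >= logl1 by EM monotonicity
        if np.linalg.norm(v) > 1e-14:
            a = -np.linalg.norm(r) / np.linalg.norm(v)
            cand = theta - 2 * a * r + a * a * v
            if _biv_valid(cand, floor):
                logl_cand = _biv_loglik(cand, data)
                if logl_cand >= logl1:
                    accepted = cand
        delta = np.max(np.abs(accepted - theta)) / max(v1, v2)
        theta = accepted
        it += 2
        if delta < 1e-6:
            converged = True
            trace.append(_biv_loglik(theta, data))
    if not converged:
        trace.append(_biv_loglik(theta, data))

    g11, g12, g22, e1, e2 = theta
    boundary = min(g11, g22, e1, e2) <= floor * 1.5
    r_hat = g12 / np.sqrt(g11 * g22)
    if abs(r_hat) > 0.999:
        r_hat = float(np.clip(r_hat, -0.999, 0.999))
        boundary = True

    # average-information SEs at the optimum
    P, Py, _ = _biv_core(theta, data)
    n1 = data.n1
    vs = []
    v = np.zeros(data.n); v[:n1] = data.G11 @ Py[:n1]; vs.append(v)
    v = np.zeros(data.n)
    v[:n1] = data.G12 @ Py[n1:]
    v[n1:] = data.G12.T @ Py[:n1]
    vs.append(v)
    v = np.zeros(data.n); v[n1:] = data.G22 @ Py[n1:]; vs.append(v)
    v = np.zeros(data.n); v[:n1] = Py[:n1]; vs.append(v)
    v = np.zeros(data.n); v[n1:] = Py[n1:]; vs.append(v)
    Pv = [P @ x for x in vs]
    AI = 0.5 * np.array([[float(a @ b) for b in Pv] for a in vs])
    cov = np.linalg.pinv(AI)
    grad_r = np.array([-r_hat / (2 * g11), 1.0 / np.sqrt(g11 * g22), -r_hat / (2 * g22)])
    se_r = float(np.sqrt(max(grad_r @ cov[:3, :3] @ grad_r, 0.0)))
    se_g = np.sqrt(np.maximum(np.diag(cov)[:3], 0.0))
    se_e = np.sqrt(np.maximum(np.diag(cov)[3:], 0.0))

    corr = np.array([[1.0, r_hat], [r_hat, 1.0]])
    return VarianceComponents(
        line_names=tuple(line_names),
        genetic_variance=np.array([g11, g22]),
        residual_variance=np.array([e1, e2]),
        genetic_correlation=corr,
        standard_errors={
            "genetic_variance": np.array([se_g[0], se_g[2]]),
            "genetic_covariance": float(se_g[1]),
            "residual_variance": se_e,
            "genetic_correlation": se_r,
        },
        log_likelihood_trace=trace,
        converged=converged,
        boundary=boundary,
    )


def _clip_biv(theta, floor):
    theta = theta.copy()
    theta[0] = max(theta[0], floor)
    theta[2] = max(theta[2], floor)
    theta[3] = max(theta[3], floor)
    theta[4] = max(theta[4], floor)
    lim = np.sqrt(theta[0] * theta[2]) * (1.0 - 1e-8)
    theta[1] = float(np.clip(theta[1], -lim, lim))
    return theta


# ---------------------------------------------------------------------------
# multi-line assembly


def pairwise_components(
    G: np.ndarray,
    y: np.ndarray,
    lines: np.ndarray,
    line_names: tuple,
    tol: float = 1e-4,
    max_iter: int = 500,
) -> VarianceComponents:
    """Assemble an L-line VarianceComponents from all pairwise bivariate
    REML runs; per-line variances are averaged over the pairs that include
    the line, and a non-PSD correlation assembly is bent and flagged."""
    G = np.asarray(G, dtype=float)
    y = np.asarray(y, dtype=float)
    lines = np.asarray(lines, dtype=str)
    L = len(line_names)
    corr = np.eye(L)
    gv = np.zeros((L, L))
    ev = np.zeros((L, L))
    counts = np.zeros(L)
    converged = True
    boundary = False
    traces = []
    for i in range(L):
        for j in range(i + 1, L):
            idx_i = np.flatnonzero(lines == line_names[i])
            idx_j = np.flatnonzero(lines == line_names[j])
            sel = np.concatenate([idx_i, idx_j])
            vc = reml_bivariate(
                G[np.ix_(sel, sel)],
                y[idx_i],
                y[idx_j],
                tol=tol,
                max_iter=max_iter,
                line_names=(line_names[i], line_names[j]),
            )
            corr[i, j] = corr[j, i] = vc.genetic_correlation[0, 1]
            gv[i, j], gv[j, i] = vc.genetic_variance
            ev[i, j], ev[j, i] = vc.residual_variance
            counts[i] += 1
            counts[j] += 1
            converged &= vc.converged
            boundary |= vc.boundary
            traces.append(vc.log_likelihood_trace)
    genetic = np.array([gv[i][gv[i] > 0].mean() if counts[i] else np.nan for i in range(L)])
    residual = np.array([ev[i][ev[i] > 0].mean() if counts[i] else np.nan for i in range(L)])
    bent_corr = bend_correlation(corr)
    bent = not np.allclose(bent_corr, corr, atol=1e-10)
    return VarianceComponents(
        line_names=tuple(line_names),
        genetic_variance=genetic,
        residual_variance=residual,
        genetic_correlation=bent_corr,
        log_likelihood_trace=traces,
        converged=converged,
        boundary=boundary,
        bent=bent,
    )
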