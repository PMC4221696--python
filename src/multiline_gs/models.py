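"""Prediction models: ridge regression (primal and dual), kernel ridge,
GBLUP, multi-trait GBLUP, and PCA reduction.

Everything is exposed twice: as scikit-learn-style estimators
(:class:`RidgeGenomic`, :class:`KernelRidgePredictor`,
:class:`GBLUPRegressor`, :class:`MTGBLUPRegressor`) that handle centering
and compose with sklearn tooling, and as thin module-level functions
operating on pre-centered arrays (the raw mixed-model / ridge algebra).

The dual ridge solution alpha = (XX' + gamma I)^-1 y and the primal
w = (X'X + gamma I)^-1 X'y give identical predictions (Woodbury identity);
kernel ridge generalizes the dual form by replacing XX' with any Gram
matrix K. GBLUP is ridge on frequency-centered dosages with
gamma = lambda * 2 sum f(1-f), lambda the residual-to-genetic variance
ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .kernels import GramMatrix, KernelSpec, cross, gram, resolve_bandwidth
from .simdata import bend_correlation

__all__ = [
    "RidgeFit",
    "GenomicRelationship",
    "MultiTraitFit",
    "PCAReduction",
    "fit_ridge_primal",
    "fit_ridge_dual",
    "predict_ridge",
    "fit_kernel_ridge",
    "predict_kernel",
    "build_G",
    "gblup_predict",
    "mtgblup_predict",
    "reduce_pca",
    "project",
    "select_gamma",
    "RidgeGenomic",
    "KernelRidgePredictor",
    "GBLUPRegressor",
    "MTGBLUPRegressor",
]


# ---------------------------------------------------------------------------
# functional core (pre-centered inputs)


@dataclass
class RidgeFit:
    """Solution of a ridge / kernel-ridge system.

    Exactly one of `weights` (primal) and `dual_coef` is populated.
    """

    gamma: float
    weights: np.ndarray | None = None
    dual_coef: np.ndarray | None = None
    X_train: np.ndarray | None = None  # needed for dual prediction
    marker_means: np.ndarray | None = None
    spec: KernelSpec | str = "linear-primal"

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if (self.weights is None) == (self.dual_coef is None):
            raise ValueError("exactly one of primal/dual must be populated")


def _solve_spd(A: np.ndarray, b: np.ndarray, what: str = "system") -> np.ndarray:
    try:
        c, low = cho_factor(A, lower=True)
    except np.linalg.LinAlgError as exc:
        cond = float(np.linalg.cond(A))
        raise np.linalg.LinAlgError(
            f"{what} is numerically singular (condition estimate {cond:.3e})"
        ) from exc
    return cho_solve((c, low), b)


def fit_ridge_primal(X_centered: np.ndarray, y: np.ndarray, gamma: float) -> RidgeFit:
    """Solve (X'X + gamma I) w = X'y."""
    X = np.asarray(X_centered, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(y) != X.shape[0]:
        raise ValueError("y length must match rows of X")
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    m = X.shape[1]
    w = _solve_spd(X.T @ X + gamma * np.eye(m), X.T @ y, "primal ridge system")
    return RidgeFit(gamma=gamma, weights=w)


def fit_ridge_dual(X_centered: np.ndarray, y: np.ndarray, gamma: float) -> RidgeFit:
    """Solve alpha = (XX' + gamma I)^-1 y; predictions are alpha' X x_t."""
    X = np.asarray(X_centered, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(y) != X.shape[0]:
        raise ValueError("y length must match rows of X")
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    n = X.shape[0]
    alpha = _solve_spd(X @ X.T + gamma * np.eye(n), y, "dual ridge system")
    return RidgeFit(gamma=gamma, dual_coef=alpha, X_train=X)


def predict_ridge(fit: RidgeFit, X_test: np.ndarray) -> np.ndarray:
    X_test = np.asarray(X_test, dtype=float)
    if fit.weights is not None:
        return X_test @ fit.weights
    return (X_test @ fit.X_train.T) @ fit.dual_coef


def fit_kernel_ridge(K, y: np.ndarray, gamma: float) -> RidgeFit:
    """Solve (K + gamma I) alpha = y for a Gram matrix K."""
    Kv = K.values if isinstance(K, GramMatrix) else np.asarray(K, dtype=float)
    y = np.asarray(y, dtype=float)
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    if Kv.shape[0] != len(y):
        raise ValueError("K and y dimensions disagree")
    alpha = _solve_spd(Kv + gamma * np.eye(len(y)), y, "kernel ridge system")
    spec = K.spec if isinstance(K, GramMatrix) else "kernel"
    return RidgeFit(gamma=gamma, dual_coef=alpha, spec=spec)


def predict_kernel(fit: RidgeFit, k_cross: np.ndarray) -> np.ndarray:
    """Predictions alpha' k per test animal; k_cross is n_train x n_test."""
    k_cross = np.asarray(k_cross, dtype=float)
    return k_cross.T @ fit.dual_coef


@dataclass
class GenomicRelationship:
    """Marker-based relationship matrix G = ZZ' / (2 sum f(1-f))."""

    G: np.ndarray
    scale: float
    freqs: np.ndarray

    def __post_init__(self) -> None:
        G = np.asarray(self.G, dtype=float)
        if not np.allclose(G, G.T, atol=1e-8):
            raise ValueError("G must be symmetric")
        self.G = (G + G.T) / 2.0


def build_G(X: np.ndarray, freqs: np.ndarray | None = None) -> GenomicRelationship:
    """Genomic relationship matrix from 0/1/2 dosages.

    `freqs` are per-marker allele frequencies (training-derived when the
    matrix must cover validation animals); defaults to column means / 2.
    """
    X = np.asarray(X, dtype=float)
    if freqs is None:
        freqs = X.mean(axis=0) / 2.0
    freqs = np.asarray(freqs, dtype=float)
    Z = X - 2.0 * freqs[None, :]
    scale = float(2.0 * np.sum(freqs * (1.0 - freqs)))
    if scale <= 0:
        raise ValueError("all markers fixed; cannot scale G")
    return GenomicRelationship(Z @ Z.T / scale, scale, freqs)


def gblup_predict(
    G: np.ndarray | GenomicRelationship,
    y_train: np.ndarray,
    lam: float,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
) -> np.ndarray:
    """GEBV for test animals from training records only.

    lam is the residual-to-genetic variance ratio; y is centered by its
    training mean internally and GEBV are returned as deviations.
    """
    if lam <= 0:
        raise ValueError("lambda must be positive")
    Gm = G.G if isinstance(G, GenomicRelationship) else np.asarray(G, dtype=float)
    y = np.asarray(y_train, dtype=float)
    train_idx = np.asarray(train_idx)
    test_idx = np.asarray(test_idx)
    if len(y) != len(train_idx):
        raise ValueError("y_train must align with train_idx")
    yc = y - y.mean()
    Gtt = Gm[np.ix_(train_idx, train_idx)]
    w = _solve_spd(Gtt + lam * np.eye(len(train_idx)), yc, "GBLUP system")
    return Gm[np.ix_(test_idx, train_idx)] @ w


@dataclass
class MultiTraitFit:
    """Multi-trait GBLUP solution: every animal gets a GEBV per line-trait."""

    gebv: np.ndarray  # n_animals x n_lines
    fixed_effects: np.ndarray  # per-trait means
    genetic_covariance: np.ndarray
    residual_variances: np.ndarray
    condition_estimate: float = np.nan

    def __post_init__(self) -> None:
        if not np.isfinite(self.gebv).all():
            raise ValueError("non-finite GEBV")


def mtgblup_predict(
    G: np.ndarray | GenomicRelationship,
    records: list[tuple[np.ndarray, np.ndarray]],
    genetic_variances: np.ndarray,
    genetic_correlation: np.ndarray,
    residual_variances: np.ndarray,
) -> MultiTraitFit:
    """Multi-trait GBLUP treating the same trait in each line as separate,
    genetically correlated traits.

    Parameters
    ----------
    G : relationship matrix over *all* animals (training and validation).
    records : per line-trait, a pair (animal indices into G, phenotypes).
        Traits are observed on disjoint animals (each animal records its
        own line's trait only).
    genetic_variances, genetic_correlation, residual_variances :
        per-line variance components; the genetic covariance is the
        correlation scaled by per-line genetic standard deviations.

    Returns GEBV for every animal and every line-trait, from the
    observed-data form of the mixed-model solution
    u_hat = (Sigma_g kron G) Z' V^-1 (y - Xb_hat).
    """
    Gm = G.G if isinstance(G, GenomicRelationship) else np.asarray(G, dtype=float)
    L = len(records)
    sg = np.asarray(genetic_variances, dtype=float)
    se = np.asarray(residual_variances, dtype=float)
    C = bend_correlation(np.asarray(genetic_correlation, dtype=float))
    if np.linalg.eigvalsh(C).min() < -1e-8:
        raise ValueError("genetic correlation matrix not PSD after bending")
    if (sg <= 0).any() or (se <= 0).any():
        raise ValueError("variance components must be positive")
    D = np.sqrt(sg)
    Sigma = C * np.outer(D, D)

    idxs = [np.asarray(ix, dtype=int) for ix, _ in records]
    ys = [np.asarray(yv, dtype=float) for _, yv in records]
    seen = np.concatenate(idxs) if idxs else np.array([], dtype=int)
    if len(np.unique(seen)) != len(seen):
        raise ValueError("each animal may be phenotyped for one trait only")
    observed = [a for a in range(L) if len(idxs[a]) > 0]
    if not observed:
        raise ValueError("no phenotype records supplied")
    sizes = [len(idxs[a]) for a in observed]
    n_obs = sum(sizes)
    offs = np.cumsum([0] + sizes)

    V = np.empty((n_obs, n_obs))
    for ai, a in enumerate(observed):
        for bi, b in enumerate(observed):
            blk = Sigma[a, b] * Gm[np.ix_(idxs[a], idxs[b])]
            if a == b:
                blk = blk + se[a] * np.eye(sizes[ai])
            V[offs[ai]:offs[ai + 1], offs[bi]:offs[bi + 1]] = blk
    V = (V + V.T) / 2.0

    X = np.zeros((n_obs, len(observed)))
    for ai in range(len(observed)):
        X[offs[ai]:offs[ai + 1], ai] = 1.0
    y = np.concatenate([ys[a] for a in observed])

    try:
        cf = cho_factor(V, lower=True)
    except np.linalg.LinAlgError:
        jitter = 1e-8 * np.trace(V) / n_obs
        cf = cho_factor(V + jitter * np.eye(n_obs), lower=True)
    diag = np.abs(np.diag(cf[0]))
    cond_est = float((diag.max() / diag.min()) ** 2)

    # per-trait means are absorbed by simple centering (phenotypes reach
    # this model pre-corrected, so only a trait-level mean remains)
    beta_obs = np.array([ys[a].mean() for a in observed])
    beta = np.zeros(L)
    beta[observed] = beta_obs
    w = cho_solve(cf, y - X @ beta_obs)

    n = Gm.shape[0]
    Gw = np.zeros((n, L))  # Gw[:, b] = G[:, idx_b] @ w_b
    for bi, b in enumerate(observed):
        Gw[:, b] = Gm[:, idxs[b]] @ w[offs[bi]:offs[bi + 1]]
    gebv = Gw @ Sigma.T  # gebv[:, a] = sum_b Sigma[a,b] * Gw[:, b]
    return MultiTraitFit(
        gebv=gebv,
        fixed_effects=beta,
        genetic_covariance=Sigma,
        residual_variances=se,
        condition_estimate=cond_est,
    )


# ---------------------------------------------------------------------------
# PCA reduction


@dataclass
class PCAReduction:
    mean: np.ndarray
    components: np.ndarray  # r x m, orthonormal rows
    explained_variance_ratio: np.ndarray
    rank: int


def reduce_pca(X_fit: np.ndarray, var_threshold: float) -> PCAReduction:
    """Principal components of the fitting matrix retaining the smallest
    rank whose cumulative explained variance reaches `var_threshold`."""
    if not (0.0 < var_threshold <= 1.0):
        raise ValueError("var_threshold must be in (0, 1]")
    X = np.asarray(X_fit, dtype=float)
    mean = X.mean(axis=0)
    Xc = X - mean
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    var = s ** 2
    total = var.sum()
    if total == 0:
        raise ValueError("fitting matrix has zero variance")
    ratio = var / total
    cum = np.cumsum(ratio)
    r = int(np.searchsorted(cum, var_threshold - 1e-12) + 1)
    r = min(r, len(s))
    return PCAReduction(mean=mean, components=Vt[:r], explained_variance_ratio=ratio[:r], rank=r)


def project(X: np.ndarray, reduction: PCAReduction) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    return (X - reduction.mean) @ reduction.components.T


# ---------------------------------------------------------------------------
# hyperparameter selection


def default_gamma_grid(n_train: int, n_points: int = 10) -> np.ndarray:
    """Log grid 1e-3 n ... 1e3 n around the training size."""
    return np.geomspace(1e-3 * n_train, 1e3 * n_train, n_points)


def _fold_assignment(n, n_folds, seed, lines=None):
    rng = np.random.default_rng(seed)
    folds = np.empty(n, dtype=int)
    if lines is None:
        groups = [np.arange(n)]
    else:
        lines = np.asarray(lines)
        groups = [np.flatnonzero(lines == g) for g in np.unique(lines)]
    for idx in groups:
        perm = rng.permutation(idx)
        folds[perm] = np.arange(len(perm)) % n_folds
    return folds


def select_gamma(
    K_or_X: np.ndarray,
    y: np.ndarray,
    grid: np.ndarray | None = None,
    n_folds: int = 5,
    seed: int = 0,
    lines: np.ndarray | None = None,
) -> float:
    """Pick the ridge penalty by seeded k-fold CV on held-out predictive
    correlation, with the one-standard-error rule: among penalties whose
    mean fold score is within one SE of the best, the largest (most
    shrunken) wins. Exact ties likewise break toward heavier shrinkage.

    Accepts either a square symmetric kernel matrix or a feature matrix
    (then the linear kernel of the centered features is used). Each fold's
    system is eigendecomposed once so the whole grid costs one
    decomposition per fold.
    """
    A = np.asarray(K_or_X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    if A.shape == (n, n) and np.allclose(A, A.T, atol=1e-8):
        K = A
    else:
        Xc = A - A.mean(axis=0)
        K = Xc @ Xc.T
    if grid is None:
        grid = default_gamma_grid(n)
    grid = np.sort(np.asarray(grid, dtype=float))
    if (grid <= 0).any():
        raise ValueError("gamma grid must be positive")

    folds = _fold_assignment(n, n_folds, seed, lines)
    scores = np.full((len(grid), n_folds), np.nan)
    for f in range(n_folds):
        te = folds == f
        tr = ~te
        ytr = y[tr]
        yc = ytr - ytr.mean()
        w, V = np.linalg.eigh(K[np.ix_(tr, tr)])
        Vty = V.T @ yc
        Kcross = K[np.ix_(te, tr)] @ V
        yte = y[te]
        if np.std(yte) == 0:
            continue
        for gi, g in enumerate(grid):
            pred = Kcross @ (Vty / (w + g))
            if np.std(pred) == 0:
                continue
            scores[gi, f] = np.corrcoef(pred, yte)[0, 1]
    with np.errstate(invalid="ignore"):
        mean_scores = np.nanmean(scores, axis=1)
        se_scores = np.nanstd(scores, axis=1) / np.sqrt(
            np.maximum(np.sum(~np.isnan(scores), axis=1), 1)
        )
    mean_scores = np.where(np.isnan(mean_scores), -np.inf, mean_scores)
    best = int(np.argmax(mean_scores))
    threshold = mean_scores[best] - se_scores[best]
    return float(grid[np.flatnonzero(mean_scores >= threshold - 1e-12)][-1])


# ---------------------------------------------------------------------------
# estimators


class _CenteredRegressor(RegressorMixin, BaseEstimator):
    def _center_fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        self.x_mean_ = X.mean(axis=0)
        self.y_mean_ = float(y.mean())
        return X - self.x_mean_, y - self.y_mean_


class RidgeGenomic(_CenteredRegressor):
    """Ridge regression on centered marker dosages.

    solver='primal' solves the m x m normal equations, 'dual' the n x n
    system; 'auto' picks whichever is smaller. Both give identical
    predictions.
    """

    def __init__(self, gamma: float = 1.0, solver: str = "auto"):
        self.gamma = gamma
        self.solver = solver

    def fit(self, X, y):
        Xc, yc = self._center_fit(X, y)
        n, m = Xc.shape
        solver = self.solver
        if solver == "auto":
            solver = "primal" if m <= n else "dual"
        if solver == "primal":
            self.fit_ = fit_ridge_primal(Xc, yc, self.gamma)
        elif solver == "dual":
            self.fit_ = fit_ridge_dual(Xc, yc, self.gamma)
        else:
            raise ValueError(f"unknown solver {solver!r}")
        return self

    def predict(self, X):
        check_is_fitted(self, "fit_")
        Xc = np.asarray(X, dtype=float) - self.x_mean_
        return predict_ridge(self.fit_, Xc) + self.y_mean_


class KernelRidgePredictor(_CenteredRegressor):
    """Kernel ridge on centered dosages with the package's kernel families.

    gamma may be a number or 'cv' (seeded k-fold selection on the training
    Gram matrix).
    """

    def __init__(
        self,
        family: str = "distance",
        degree: int = 2,
        shift: float = 1.0,
        p: float = 2.0,
        q: int = 1,
        bandwidth: float | str = "auto",
        gamma: float | str = 1.0,
        cv_seed: int = 0,
        gamma_grid=None,
    ):
        self.family = family
        self.degree = degree
        self.shift = shift
        self.p = p
        self.q = q
        self.bandwidth = bandwidth
        self.gamma = gamma
        self.cv_seed = cv_seed
        self.gamma_grid = gamma_grid

    def _spec(self) -> KernelSpec:
        return KernelSpec(
            family=self.family, degree=self.degree, shift=self.shift,
            p=self.p, q=self.q, bandwidth=self.bandwidth,
        )

    def fit(self, X, y, lines=None):
        Xc, yc = self._center_fit(X, y)
        spec = self._spec()
        bw = resolve_bandwidth(Xc, spec) if spec.family == "distance" else None
        K = gram(Xc, spec, bandwidth=bw)
        if self.gamma == "cv":
            grid = self.gamma_grid
            if grid is None:
                # n-scaled log grid; the mean Gram diagonal makes it
                # comparable across kernel families (1 for distance kernels)
                scale = max(float(np.trace(K.values) / K.n), 1e-12)
                grid = np.geomspace(1e-3, 1e3, 10) * K.n * scale
            gamma = select_gamma(K.values, yc, grid=grid, seed=self.cv_seed, lines=lines)
        else:
            gamma = float(self.gamma)
        self.bandwidth_ = bw
        self.gamma_ = gamma
        self.X_fit_ = Xc
        self.ridge_ = fit_kernel_ridge(K, yc, gamma)
        return self

    def predict(self, X):
        check_is_fitted(self, "ridge_")
        Xc = np.asarray(X, dtype=float) - self.x_mean_
        k = cross(self.X_fit_, Xc, self._spec(), bandwidth=self.bandwidth_)
        return predict_kernel(self.ridge_, k) + self.y_mean_


class GBLUPRegressor(_CenteredRegressor):
    """Single-trait GBLUP from training dosages.

    The shrinkage is the residual-to-genetic variance ratio `lambda_ratio`;
    alternatively pass `heritability` (lambda = (1-h2)/h2) or leave both
    None to select gamma = lambda * scale by CV on the centered dosages.
    """

    def __init__(
        self,
        lambda_ratio: float | None = None,
        heritability: float | None = None,
        cv_seed: int = 0,
        gamma_grid=None,
    ):
        self.lambda_ratio = lambda_ratio
        self.heritability = heritability
        self.cv_seed = cv_seed
        self.gamma_grid = gamma_grid

    def fit(self, X, y, lines=None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        self.freqs_ = X.mean(axis=0) / 2.0
        self.y_mean_ = float(y.mean())
        Z = X - 2.0 * self.freqs_[None, :]
        self.scale_ = float(2.0 * np.sum(self.freqs_ * (1.0 - self.freqs_)))
        if self.lambda_ratio is not None:
            lam = float(self.lambda_ratio)
        elif self.heritability is not None:
            h2 = float(self.heritability)
            if not (0.0 < h2 < 1.0):
                raise ValueError("heritability must be in (0, 1)")
            lam = (1.0 - h2) / h2
        else:
            gamma = select_gamma(
                Z, y, grid=self.gamma_grid, seed=self.cv_seed, lines=lines
            )
            lam = gamma / self.scale_
        if lam <= 0:
            raise ValueError("lambda must be positive")
        self.lambda_ = lam
        yc = y - self.y_mean_
        G_tt = Z @ Z.T / self.scale_
        self.w_ = _solve_spd(G_tt + lam * np.eye(len(y)), yc, "GBLUP system")
        self.Z_ = Z
        return self

    def predict(self, X):
        check_is_fitted(self, "w_")
        Zt = np.asarray(X, dtype=float) - 2.0 * self.freqs_[None, :]
        G_ts = Zt @ self.Z_.T / self.scale_
        return G_ts @ self.w_ + self.y_mean_


class MTGBLUPRegressor(BaseEstimator):
    """Multi-trait GBLUP estimator over line-labelled animals.

    Variance components (per-line genetic and residual variances and the
    between-line genetic correlation matrix) are supplied at construction,
    e.g. from bivariate genomic REML. `fit` takes the training dosages,
    phenotypes and line labels; `predict` returns, for each test animal,
    its own line's GEBV plus that trait's fixed-effect mean.
    """

    def __init__(self, genetic_variances, genetic_correlation, residual_variances, line_names):
        self.genetic_variances = genetic_variances
        self.genetic_correlation = genetic_correlation
        self.residual_variances = residual_variances
        self.line_names = line_names

    def fit(self, X, y, lines):
        X = np.asarray(X, dtype=float)
        self.X_train_ = X
        self.y_train_ = np.asarray(y, dtype=float)
        self.lines_train_ = np.asarray(lines, dtype=str)
        self.freqs_ = X.mean(axis=0) / 2.0
        return self

    def predict(self, X, lines):
        check_is_fitted(self, "X_train_")
        X = np.asarray(X, dtype=float)
        lines = np.asarray(lines, dtype=str)
        names = list(self.line_names)
        stacked = np.vstack([self.X_train_, X])
        G = build_G(stacked, freqs=self.freqs_)
        n_train = self.X_train_.shape[0]
        records = []
        for li, name in enumerate(names):
            mask = self.lines_train_ == name
            records.append((np.flatnonzero(mask), self.y_train_[mask]))
        fitres = mtgblup_predict(
            G,
            records,
            self.genetic_variances,
            self.genetic_correlation,
            self.residual_variances,
        )
        self.fit_result_ = fitres
        out = np.empty(X.shape[0])
        for li, name in enumerate(names):
            mask = lines == name
            out[mask] = (
                fitres.gebv[n_train:, li][mask] + fitres.fixed_effects[li]
            )
        unknown = ~np.isin(lines, names)
        if unknown.any():
            raise ValueError(f"unknown line labels {np.unique(lines[unknown])}")
        return out
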