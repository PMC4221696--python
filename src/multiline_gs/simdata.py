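"""Synthetic multi-line layer-hen genotype/phenotype simulator.

The generator emulates the statistical structure of a three-line layer
breeding program: two closely related brown lines (B1, B2) and one
distantly related white line (W1). Line allele frequencies diverge from a
shared ancestral frequency by Balding–Nichols drift along a two-level tree
((B1, B2), W1); local linkage disequilibrium arises from a first-order
haplotype copying process; a trait with line-specific, between-line
correlated QTL effects is overlaid with a hatch-week fixed effect and
residual noise.

Units: phenotypic variance within a line (excluding the hatch-week effect)
is 1, so the per-line genetic variance equals the configured heritability.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import yaml

__all__ = [
    "SimulationConfig",
    "GenotypePanel",
    "TruthSet",
    "DEFAULT_QTL_CORRELATION",
    "DEFAULT_DRIFT_TREE",
    "draw_line_frequencies",
    "simulate_genotypes",
    "assign_qtl_effects",
    "simulate_phenotypes",
    "simulate",
    "nei_fst",
    "bend_correlation",
]

#: Between-line genetic correlations of the emulated trait (egg number):
#: the two brown lines are strongly positively correlated, both are
#: negatively correlated with the white line.
DEFAULT_QTL_CORRELATION = np.array(
    [
        [1.00, 0.63, -0.26],
        [0.63, 1.00, -0.55],
        [-0.26, -0.55, 1.00],
    ]
)

#: Wright drift coefficients per branch of the ((B1,B2),W1) tree: a short
#: shared brown branch, short brown-split branches, and a long white branch.
DEFAULT_DRIFT_TREE = {
    "brown_ancestor": 0.05,
    "b1": 0.05,
    "b2": 0.05,
    "white": 0.20,
}

_FREQ_CLIP = 1e-3  # keep line frequencies strictly inside (0, 1)


def bend_correlation(C: np.ndarray, floor: float = 1e-6) -> np.ndarray:
    """Return the nearest-in-spirit valid correlation matrix.

    Eigenvalues are floored at `floor` and the result is rescaled to unit
    diagonal. A symmetric PSD input is returned unchanged (up to symmetry).
    """
    C = np.asarray(C, dtype=float)
    C = (C + C.T) / 2.0
    w, V = np.linalg.eigh(C)
    if w.min() >= -1e-12:  # PSD (possibly singular) matrices pass through
        return C
    w = np.maximum(w, floor)
    B = (V * w) @ V.T
    d = np.sqrt(np.diag(B))
    B = B / np.outer(d, d)
    np.fill_diagonal(B, 1.0)
    return (B + B.T) / 2.0


def _line_names(n_lines: int) -> tuple[str, ...]:
    if n_lines == 3:
        return ("B1", "B2", "W1")
    if n_lines == 2:
        return ("B1", "B2")
    raise ValueError(f"n_lines must be 2 or 3, got {n_lines}")


@dataclass(kw_only=True)
class SimulationConfig:
    """Parameters of one synthetic multi-line dataset.

    The defaults reproduce the study regime at desk scale: three lines,
    1000 training + 240 validation animals per line, 5000 markers, 300 QTL,
    h2 = 0.3 per line, the default between-line QTL-effect correlations and
    drift tree above, and strong local LD (ld_rho = 0.8).
    """

    seed: int
    n_lines: int = 3
    n_train_per_line: int = 1000
    n_valid_per_line: int = 240
    n_markers: int = 5000
    n_qtl: int = 300
    ancestral_freq_range: tuple[float, float] = (0.1, 0.9)
    drift_tree: dict = field(default_factory=lambda: dict(DEFAULT_DRIFT_TREE))
    ld_rho: float = 0.8
    qtl_correlation: np.ndarray = field(
        default_factory=lambda: DEFAULT_QTL_CORRELATION.copy()
    )
    heritability_per_line: tuple[float, ...] = (0.3, 0.3, 0.3)
    n_hatch_weeks: int = 10
    hatch_effect_sd: float = 0.25

    def __post_init__(self) -> None:
        self.qtl_correlation = np.asarray(self.qtl_correlation, dtype=float)
        self.heritability_per_line = tuple(
            float(h) for h in self.heritability_per_line
        )[: self.n_lines]
        self.validate()

    @property
    def line_names(self) -> tuple[str, ...]:
        return _line_names(self.n_lines)

    def validate(self) -> None:
        if self.n_qtl > self.n_markers:
            raise ValueError("n_qtl must not exceed n_markers")
        lo, hi = self.ancestral_freq_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError("ancestral_freq_range must lie inside (0, 1)")
        C = self.qtl_correlation[: self.n_lines, : self.n_lines]
        if C.shape != (self.n_lines, self.n_lines):
            raise ValueError("qtl_correlation must be n_lines x n_lines")
        if not np.allclose(C, C.T, atol=1e-10):
            raise ValueError("qtl_correlation must be symmetric")
        if not np.allclose(np.diag(C), 1.0, atol=1e-10):
            raise ValueError("qtl_correlation must have unit diagonal")
        if np.linalg.eigvalsh(C).min() < -1e-8:
            # bent later in assign_qtl_effects; reject only the grossly bad
            pass
        if len(self.heritability_per_line) != self.n_lines:
            raise ValueError("need one heritability per line")
        for h in self.heritability_per_line:
            if not (0.0 <= h < 1.0):
                raise ValueError("heritabilities must be in [0, 1)")
        for name, F in self.drift_tree.items():
            if not (0.0 <= F < 1.0):
                raise ValueError(f"drift F for branch {name!r} must be in [0, 1)")
        if not (0.0 <= self.ld_rho < 1.0):
            raise ValueError("ld_rho must be in [0, 1)")
        if not isinstance(self.seed, (int, np.integer)):
            raise ValueError("seed is mandatory and must be an integer")

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "seed" not in raw:
            raise ValueError("simulation config must set a seed")
        for key in ("ancestral_freq_range", "heritability_per_line"):
            if key in raw:
                raw[key] = tuple(raw[key])
        if "qtl_correlation" in raw:
            raw["qtl_correlation"] = np.asarray(raw["qtl_correlation"], float)
        return cls(**raw)

    def to_yaml(self, path) -> None:
        raw = {
            "seed": int(self.seed),
            "n_lines": self.n_lines,
            "n_train_per_line": self.n_train_per_line,
            "n_valid_per_line": self.n_valid_per_line,
            "n_markers": self.n_markers,
            "n_qtl": self.n_qtl,
            "ancestral_freq_range": list(self.ancestral_freq_range),
            "drift_tree": {k: float(v) for k, v in self.drift_tree.items()},
            "ld_rho": self.ld_rho,
            "qtl_correlation": self.qtl_correlation.tolist(),
            "heritability_per_line": list(self.heritability_per_line),
            "n_hatch_weeks": self.n_hatch_weeks,
            "hatch_effect_sd": self.hatch_effect_sd,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=int(seed))


@dataclass
class GenotypePanel:
    """Animals x markers dosage matrix with line and cohort labels."""

    animal_ids: np.ndarray  # str array, n
    line_labels: np.ndarray  # str array, n
    generation: np.ndarray  # 'train' | 'valid', n
    markers: np.ndarray  # str array, m
    genotypes: np.ndarray  # int8 array, n x m, entries in {0,1,2}

    def __post_init__(self) -> None:
        self.animal_ids = np.asarray(self.animal_ids, dtype=str)
        self.line_labels = np.asarray(self.line_labels, dtype=str)
        self.generation = np.asarray(self.generation, dtype=str)
        self.markers = np.asarray(self.markers, dtype=str)
        self.genotypes = np.asarray(self.genotypes)
        n, m = self.genotypes.shape
        if not (len(self.animal_ids) == len(self.line_labels) == len(self.generation) == n):
            raise ValueError("inconsistent animal dimension")
        if len(self.markers) != m:
            raise ValueError("inconsistent marker dimension")
        if self.genotypes.size and not np.isin(self.genotypes, (0, 1, 2)).all():
            raise ValueError("genotypes must be 0/1/2 dosages")

    @property
    def n_animals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_markers(self) -> int:
        return self.genotypes.shape[1]

    def mask(self, lines: Sequence[str] | None = None, generation: str | None = None) -> np.ndarray:
        m = np.ones(self.n_animals, dtype=bool)
        if lines is not None:
            m &= np.isin(self.line_labels, list(lines))
        if generation is not None:
            m &= self.generation == generation
        return m

    def subset_animals(self, mask: np.ndarray) -> "GenotypePanel":
        return GenotypePanel(
            self.animal_ids[mask],
            self.line_labels[mask],
            self.generation[mask],
            self.markers.copy(),
            self.genotypes[mask],
        )

    def subset_markers(self, mask: np.ndarray) -> "GenotypePanel":
        return GenotypePanel(
            self.animal_ids.copy(),
            self.line_labels.copy(),
            self.generation.copy(),
            self.markers[mask],
            self.genotypes[:, mask],
        )


@dataclass
class TruthSet:
    """Simulated trait architecture and phenotypes, aligned with a panel."""

    qtl_indices: np.ndarray  # marker indices, q
    qtl_effects: np.ndarray  # n_lines x q, line-specific allele effects
    line_names: tuple[str, ...]
    true_breeding_values: np.ndarray  # n
    hatch_week: np.ndarray  # int, n
    phenotypes: np.ndarray  # n

    def to_frame(self, panel: GenotypePanel):
        import pandas as pd

        return pd.DataFrame(
            {
                "animal_id": panel.animal_ids,
                "line": panel.line_labels,
                "generation": panel.generation,
                "hatch_week": self.hatch_week,
                "phenotype": self.phenotypes,
                "tbv": self.true_breeding_values,
            }
        )


def _balding_nichols(p: np.ndarray, F: float, rng: np.random.Generator) -> np.ndarray:
    """One drift step: Beta(p(1-F)/F, (1-p)(1-F)/F) around the parent p."""
    if F < 0 or F >= 1:
        raise ValueError("drift coefficient F must be in [0, 1)")
    if F == 0:
        return p.copy()
    a = p * (1.0 - F) / F
    b = (1.0 - p) * (1.0 - F) / F
    return rng.beta(a, b)


def draw_line_frequencies(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Draw per-line allele frequencies along the ((B1,B2),W1) drift tree.

    Returns a (n_lines, n_markers) matrix strictly inside (0, 1). With all
    drift coefficients zero every line carries the ancestral frequencies.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    lo, hi = config.ancestral_freq_range
    p_anc = rng.uniform(lo, hi, size=config.n_markers)
    tree = config.drift_tree
    p_brown = _balding_nichols(p_anc, tree.get("brown_ancestor", 0.0), rng)
    rows = [
        _balding_nichols(p_brown, tree.get("b1", 0.0), rng),
        _balding_nichols(p_brown, tree.get("b2", 0.0), rng),
    ]
    if config.n_lines == 3:
        rows.append(_balding_nichols(p_anc, tree.get("white", 0.0), rng))
    freqs = np.vstack(rows)
    return np.clip(freqs, _FREQ_CLIP, 1.0 - _FREQ_CLIP)


def _haplotypes(
    freqs_line: np.ndarray, n_hap: int, ld_rho: float, rng: np.random.Generator
) -> np.ndarray:
    """First-order copying haplotypes with exact per-marker marginals.

    Each haplotype carries a latent uniform per marker; with probability
    ld_rho the uniform is copied from the previous marker (same draw, hence
    correlated alleles), otherwise a fresh uniform is used. The allele is
    the indicator u < f_j, so the marginal frequency is exactly f_j at every
    marker while adjacent markers are positively associated.
    """
    m = len(freqs_line)
    fresh_u = rng.uniform(size=(n_hap, m))
    if ld_rho == 0.0:
        u = fresh_u
    else:
        fresh = rng.uniform(size=(n_hap, m)) >= ld_rho
        fresh[:, 0] = True
        idx = np.where(fresh, np.arange(m)[None, :], 0)
        last_fresh = np.maximum.accumulate(idx, axis=1)
        u = np.take_along_axis(fresh_u, last_fresh, axis=1)
    return (u < freqs_line[None, :]).astype(np.int8)


def simulate_genotypes(
    freqs: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> GenotypePanel:
    """Simulate training+validation genotypes for every line.

    Each animal is the sum of two copying-model haplotypes drawn at its
    line's frequencies; the validation cohort is an independent draw from
    the same line frequencies (an i.i.d. stand-in for a youngest
    generation).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    freqs = np.asarray(freqs, dtype=float)
    if freqs.shape != (config.n_lines, config.n_markers):
        raise ValueError("freqs must be n_lines x n_markers")
    if not ((freqs > 0) & (freqs < 1)).all():
        raise ValueError("line frequencies must lie strictly in (0, 1)")
    n_per = config.n_train_per_line + config.n_valid_per_line
    ids, lines, gens, blocks = [], [], [], []
    for li, line in enumerate(config.line_names):
        hap = _haplotypes(freqs[li], 2 * n_per, config.ld_rho, rng)
        geno = hap[0::2] + hap[1::2]
        blocks.append(geno)
        ids.extend(f"{line}_{i:04d}" for i in range(n_per))
        lines.extend([line] * n_per)
        gens.extend(
            ["train"] * config.n_train_per_line + ["valid"] * config.n_valid_per_line
        )
    markers = np.array([f"m{j + 1}" for j in range(config.n_markers)])
    return GenotypePanel(
        np.array(ids), np.array(lines), np.array(gens), markers,
        np.vstack(blocks).astype(np.int8),
    )


def assign_qtl_effects(
    config: SimulationConfig,
    freqs_at_qtl: np.ndarray,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Draw line x QTL allele effects with the configured between-line
    correlation, scaled per line so the expected genetic variance equals the
    line's heritability (phenotypic variance is 1 by construction).

    The per-QTL effect vector across lines is multivariate normal with the
    (bent, if necessary) qtl_correlation; per-line rescaling leaves the
    between-line correlations untouched.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    C = bend_correlation(config.qtl_correlation[: config.n_lines, : config.n_lines])
    w, V = np.linalg.eigh(C)
    if w.min() < -1e-8:
        raise ValueError("qtl_correlation is not PSD even after bending")
    L = V * np.sqrt(np.maximum(w, 0.0))  # exact factor, valid for singular C
    raw = L @ rng.standard_normal((config.n_lines, config.n_qtl))
    freqs_at_qtl = np.asarray(freqs_at_qtl, dtype=float)
    if freqs_at_qtl.shape != (config.n_lines, config.n_qtl):
        raise ValueError("freqs_at_qtl must be n_lines x n_qtl")
    het = 2.0 * freqs_at_qtl * (1.0 - freqs_at_qtl)  # per-QTL genotype variance
    effects = np.empty_like(raw)
    for li, h2 in enumerate(config.heritability_per_line):
        expected_var = float(np.sum(raw[li] ** 2 * het[li]))
        scale = 0.0 if h2 == 0.0 else np.sqrt(h2 / expected_var)
        effects[li] = raw[li] * scale
    return effects


def simulate_phenotypes(
    panel: GenotypePanel,
    qtl_indices: np.ndarray,
    qtl_effects: np.ndarray,
    freqs: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> TruthSet:
    """Build true breeding values and phenotypes on top of a panel.

    TBV_i = sum_q a(line_i, q) * (g_iq - 2 f_line,q); the residual standard
    deviation per line is sqrt(1 - h2) so phenotypic variance (before the
    hatch-week effect) is 1. Hatch weeks are uniform; week effects are
    i.i.d. normal with sd hatch_effect_sd, shared across lines.

    Effects are rescaled per line by the realized TBV variance (which the
    frequency-based scaling in assign_qtl_effects cannot fully anticipate
    because LD between QTL contributes covariance), so the per-line genetic
    variance equals h2 on the sampled animals; the rescaled effects are the
    ones stored in the returned TruthSet.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    for h in config.heritability_per_line:
        if h >= 1.0:
            raise ValueError("heritability must be < 1")
    qtl_indices = np.asarray(qtl_indices)
    G_qtl = panel.genotypes[:, qtl_indices].astype(float)
    n = panel.n_animals
    tbv = np.empty(n)
    resid = np.empty(n)
    qtl_effects = np.array(qtl_effects, dtype=float, copy=True)
    line_order = {name: i for i, name in enumerate(config.line_names)}
    for line, li in line_order.items():
        mask = panel.line_labels == line
        centred = G_qtl[mask] - 2.0 * freqs[li, qtl_indices][None, :]
        raw_tbv = centred @ qtl_effects[li]
        h2 = config.heritability_per_line[li]
        realized = float(raw_tbv.var())
        if h2 > 0 and realized > 0:
            factor = np.sqrt(h2 / realized)
            qtl_effects[li] *= factor
            raw_tbv = raw_tbv * factor
        elif h2 == 0:
            qtl_effects[li] = 0.0
            raw_tbv = np.zeros_like(raw_tbv)
        tbv[mask] = raw_tbv
        resid[mask] = rng.standard_normal(mask.sum()) * np.sqrt(1.0 - h2)
    week = rng.integers(0, config.n_hatch_weeks, size=n)
    week_effects = rng.standard_normal(config.n_hatch_weeks) * config.hatch_effect_sd
    phen = tbv + week_effects[week] + resid
    return TruthSet(
        qtl_indices=qtl_indices,
        qtl_effects=qtl_effects,
        line_names=config.line_names,
        true_breeding_values=tbv,
        hatch_week=week,
        phenotypes=phen,
    )


def simulate(config: SimulationConfig) -> tuple[GenotypePanel, TruthSet]:
    """Run the full generator deterministically from config.seed."""
    ss = np.random.SeedSequence(config.seed)
    r_freq, r_geno, r_qtl, r_phen = (np.random.default_rng(s) for s in ss.spawn(4))
    freqs = draw_line_frequencies(config, r_freq)
    panel = simulate_genotypes(freqs, config, r_geno)
    qtl_indices = np.sort(
        r_qtl.choice(config.n_markers, size=config.n_qtl, replace=False)
    )
    effects = assign_qtl_effects(config, freqs[:, qtl_indices], r_qtl)
    truth = simulate_phenotypes(panel, qtl_indices, effects, freqs, config, r_phen)
    return panel, truth


def nei_fst(freq_a: np.ndarray, freq_b: np.ndarray) -> float:
    """Nei-style fixation index between two populations from their
    per-marker allele frequencies: mean squared frequency difference over
    twice the mean heterozygosity at the average frequency."""
    pa, pb = np.asarray(freq_a, float), np.asarray(freq_b, float)
    pbar = (pa + pb) / 2.0
    num = np.mean((pa - pb) ** 2) / 2.0
    den = np.mean(pbar * (1.0 - pbar))
    return float(num / den)
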