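"""Study orchestration: the seven training sets per validation line, the
per-scenario pipeline (segregation filter, hatch-week pre-correction,
optional PCA, fit, predict, evaluate), and result tables.

For three lines the training sets are the seven non-empty line subsets
{B1}, {B2}, {W1}, {B1,B2}, {B1,W1}, {B2,W1}, {B1,B2,W1}; validation is
always the validation cohort of the evaluated line and never enters any
training computation. PCA loadings, kernel bandwidths and ridge penalties
are re-derived per scenario from that scenario's training animals only.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import evalmetrics, genio, models
from .simdata import GenotypePanel, SimulationConfig, TruthSet
from .varcomp import VarianceComponents, pairwise_components

logger = logging.getLogger("multiline_gs")

__all__ = [
    "ScenarioSpec",
    "RunConfig",
    "MODEL_NAMES",
    "build_training_sets",
    "run_scenario",
    "run_grid",
    "result_tables",
]

MODEL_NAMES = ("GBLUP", "RRPCA", "MTGBLUP", "Poly", "PolyPCA", "RBF", "RBFPCA")


@dataclass(frozen=True)
class ScenarioSpec:
    training_lines: tuple[str, ...]
    validation_line: str
    model: str
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.training_lines:
            raise ValueError("training_lines must be non-empty")
        if self.model not in MODEL_NAMES:
            raise ValueError(f"unknown model {self.model!r}")

    @property
    def training_label(self) -> str:
        return "+".join(self.training_lines)


@dataclass
class RunConfig:
    """Knobs of one grid run, consumable from YAML."""

    seed: int = 0
    models: tuple[str, ...] = MODEL_NAMES
    pca_threshold: float = 0.97
    poly_degree: int = 2
    poly_shift: float = 1.0
    rbf_p: float = 2.0
    rbf_q: int = 1
    rbf_bandwidth: float | str = "auto"
    gamma: float | str = "cv"  # kernel-ridge penalty or 'cv'
    gblup_lambda: float | str = "cv"  # 'cv', 'h2', or a number
    heritability: float = 0.3  # used when gblup_lambda == 'h2'
    n_bootstrap: int = 10_000
    variance_components: str = "reml"  # 'reml' or path to a YAML file

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "models" in raw:
            raw["models"] = tuple(raw["models"])
        return cls(**raw)


def training_line_sets(line_names) -> list[tuple[str, ...]]:
    """All non-empty subsets of the lines, singletons first (7 for 3 lines)."""
    names = list(line_names)
    out = []
    for r in range(1, len(names) + 1):
        out.extend(itertools.combinations(names, r))
    return out


def build_training_sets(panel: GenotypePanel) -> list[tuple[str, ...]]:
    """Training-line subsets available in a panel; requires train and
    validation cohorts for every line."""
    lines = [str(l) for l in pd.unique(panel.line_labels)]
    for line in lines:
        if not (panel.mask(lines=[line], generation="train")).any():
            raise ValueError(f"line {line} has no training cohort")
        if not (panel.mask(lines=[line], generation="valid")).any():
            raise ValueError(f"line {line} has no validation cohort")
    return training_line_sets(lines)


def _make_estimator(spec: ScenarioSpec, cfg: RunConfig, vc: VarianceComponents | None,
                    line_names):
    name = spec.model
    if name == "GBLUP":
        if cfg.gblup_lambda == "cv":
            return models.GBLUPRegressor(cv_seed=cfg.seed)
        if cfg.gblup_lambda == "h2":
            return models.GBLUPRegressor(heritability=cfg.heritability)
        return models.GBLUPRegressor(lambda_ratio=float(cfg.gblup_lambda))
    if name in ("RRPCA",):
        # ridge on PCA scores == kernel ridge with the linear kernel of the
        # reduced features; handled in run_scenario via the PCA flag
        return models.KernelRidgePredictor(
            family="linear", gamma=cfg.gamma, cv_seed=cfg.seed
        )
    if name in ("Poly", "PolyPCA"):
        return models.KernelRidgePredictor(
            family="polynomial", degree=cfg.poly_degree, shift=cfg.poly_shift,
            gamma=cfg.gamma, cv_seed=cfg.seed,
        )
    if name in ("RBF", "RBFPCA"):
        return models.KernelRidgePredictor(
            family="distance", p=cfg.rbf_p, q=cfg.rbf_q,
            bandwidth=cfg.rbf_bandwidth, gamma=cfg.gamma, cv_seed=cfg.seed,
        )
    if name == "MTGBLUP":
        if vc is None:
            raise ValueError("MTGBLUP needs variance components")
        return models.MTGBLUPRegressor(
            genetic_variances=vc.genetic_variance,
            genetic_correlation=vc.genetic_correlation,
            residual_variances=vc.residual_variance,
            line_names=vc.line_names,
        )
    raise ValueError(f"unknown model {name!r}")


def run_scenario(
    panel: GenotypePanel,
    truth: TruthSet,
    spec: ScenarioSpec,
    cfg: RunConfig,
    vc: VarianceComponents | None = None,
) -> dict:
    """One cell of the grid: returns the evaluation report, predictions and
    per-scenario diagnostics (filter counts, PCA rank, bandwidth, penalty)."""
    train_mask_full = panel.mask(lines=spec.training_lines, generation="train")
    valid_mask_full = panel.mask(lines=[spec.validation_line], generation="valid")
    if not valid_mask_full.any():
        raise ValueError(f"no validation cohort for line {spec.validation_line}")
    keep = train_mask_full | valid_mask_full
    sub = panel.subset_animals(keep)
    week = truth.hatch_week[keep]
    phen = truth.phenotypes[keep]
    is_train = sub.generation == "train"
    if np.intersect1d(sub.animal_ids[is_train], panel.animal_ids[valid_mask_full]).size:
        raise RuntimeError("leakage: validation animals in training set")

    filtered, report = genio.filter_nonsegregating(sub, sub.animal_ids[is_train])
    y_corr = evalmetrics.precorrect(phen, week, train_mask=is_train)

    X_train = filtered.genotypes[is_train].astype(float)
    X_valid = filtered.genotypes[~is_train].astype(float)
    y_train = y_corr[is_train]
    y_valid = y_corr[~is_train]
    lines_train = filtered.line_labels[is_train]
    lines_valid = filtered.line_labels[~is_train]

    diagnostics = {
        "n_train": int(is_train.sum()),
        "n_valid": int((~is_train).sum()),
        "n_markers": filtered.n_markers,
        "n_removed_markers": report.n_markers_in - report.n_segregating,
    }

    use_pca = spec.model.endswith("PCA")
    if use_pca:
        red = models.reduce_pca(X_train, cfg.pca_threshold)
        X_train = models.project(X_train, red)
        X_valid = models.project(X_valid, red)
        diagnostics["pca_rank"] = red.rank

    est = _make_estimator(spec, cfg, vc, panel.line_labels)
    if spec.model == "MTGBLUP":
        est.fit(X_train, y_train, lines=lines_train)
        preds = est.predict(X_valid, lines=lines_valid)
    else:
        try:
            est.fit(X_train, y_train, lines=lines_train)
        except TypeError:
            est.fit(X_train, y_train)
        preds = est.predict(X_valid)
    for attr, key in (("gamma_", "gamma"), ("lambda_", "lambda"), ("bandwidth_", "bandwidth")):
        val = getattr(est, attr, None)
        if val is not None:
            diagnostics[key] = float(val)

    rep = evalmetrics.evaluate_predictions(
        y_valid, preds, B=cfg.n_bootstrap, seed=cfg.seed
    )
    return {
        "spec": spec,
        "report": rep,
        "predictions": preds,
        "y_valid": y_valid,
        "validation_ids": filtered.animal_ids[~is_train],
        "diagnostics": diagnostics,
    }


def run_grid(
    panel: GenotypePanel,
    truth: TruthSet,
    cfg: RunConfig,
    vc: VarianceComponents | None = None,
) -> dict:
    """Run every (validation line, training set, model) cell.

    Returns a dict with the tidy results frame, per-cell predictions, and
    the variance components used for MTGBLUP (estimated by pairwise genomic
    REML on the full training cohorts when not supplied). Scenario failures
    become explicit error rows, never silent gaps.
    """
    line_names = [str(l) for l in pd.unique(panel.line_labels)]
    sets = build_training_sets(panel)
    if vc is None and "MTGBLUP" in cfg.models:
        vc = _estimate_vc(panel, truth, line_names)
    rows = []
    predictions = {}
    errors = []
    for vline in line_names:
        for tset in sets:
            for model in cfg.models:
                spec = ScenarioSpec(tset, vline, model, seed=cfg.seed)
                try:
                    out = run_scenario(panel, truth, spec, cfg, vc=vc)
                except Exception as exc:  # explicit error cell
                    logger.error("scenario %s failed: %s", spec, exc)
                    errors.append({"spec": spec, "error": str(exc)})
                    rows.append(
                        _tidy_row(vline, spec.training_label, model, "error", np.nan)
                    )
                    continue
                rep = out["report"]
                predictions[(vline, spec.training_label, model)] = (
                    out["validation_ids"],
                    out["predictions"],
                    out["y_valid"],
                )
                for metric, value in (
                    ("rho", rep.rho),
                    ("se_rho", rep.se_rho),
                    ("b1", rep.b1),
                    ("se_b1", rep.se_b1),
                    ("b1_compatible_with_1", float(rep.b1_compatible_with_1)),
                ):
                    rows.append(
                        _tidy_row(vline, spec.training_label, model, metric, value)
                    )
                logger.info(
                    "%s | %s | %s: rho=%.3f diagnostics=%s",
                    vline, spec.training_label, model, rep.rho, out["diagnostics"],
                )
    results = pd.DataFrame(rows)
    return {
        "results": results,
        "predictions": predictions,
        "variance_components": vc,
        "errors": errors,
    }


def _estimate_vc(panel, truth, line_names) -> VarianceComponents:
    train = panel.mask(generation="train")
    y = evalmetrics.precorrect(
        truth.phenotypes[train], truth.hatch_week[train]
    )
    X = panel.genotypes[train].astype(float)
    G = models.build_G(X).G
    return pairwise_components(G, y, panel.line_labels[train], tuple(line_names))


def _tidy_row(vline, tlabel, model, metric, value):
    return {
        "validation_line": vline,
        "training_set": tlabel,
        "model": model,
        "metric": metric,
        "value": value,
    }


def result_tables(results: pd.DataFrame, metric: str = "rho") -> dict[str, pd.DataFrame]:
    """Pivot the tidy frame into one models x training-sets table per
    validation line (the shape in which such comparisons are reported)."""
    sub = results[results["metric"] == metric]
    out = {}
    for vline, grp in sub.groupby("validation_line"):
        out[vline] = grp.pivot_table(
            index="model", columns="training_set", values="value", sort=False
        )
    return out


def simulate_and_run(
    sim_config: SimulationConfig, run_config: RunConfig
) -> dict:
    from .simdata import simulate

    panel, truth = simulate(sim_config)
    return run_grid(panel, truth, run_config)
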