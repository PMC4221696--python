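# multiline-gs

Genomic prediction across multiple breeding lines, for quantitative
geneticists studying whether pooling training data from related and
unrelated lines helps or hurts marker-based selection. The package
implements the full comparison machinery for a three-line layer-hen
setting — two closely related brown lines (B1, B2) and one distantly
related white line (W1) — together with a synthetic multi-line data
generator, so every result is reproducible without access to proprietary
breeding data.

## Models

All predictors are ridge-type regressions of hatch-week-corrected
phenotypes **y** on centered marker dosages **X** (n animals × m markers,
n ≪ m):

- **Ridge / SNP-BLUP** — w\* = (XᵀX + γI)⁻¹Xᵀy, or equivalently (Woodbury)
  w\* = Xᵀ(XXᵀ + γI)⁻¹y, so predictions cost O(n³) rather than O(m³).
- **Kernel ridge** — y\* = yᵀ(K + γI)⁻¹k with K the training Gram matrix:
  polynomial kernels (xᵀt + c)ˡ and distance kernels exp(−(‖x−t‖ₚ/h)^q)
  (p = 2 RBF, p = 1 Laplacian; bandwidth h from the median heuristic).
- **GBLUP** — the mixed model with G = ZZᵀ/(2Σf(1−f)); algebraically
  identical to dual ridge on frequency-centered dosages.
- **MTGBLUP** — the same trait in different lines treated as separate,
  correlated traits: u ~ N(0, Σ_g ⊗ G), with the between-line genetic
  correlation matrix estimated by bivariate genomic REML (EM updates,
  average-information standard errors).
- **PCA variants** (RRPCA, PolyPCA, RBFPCA) retaining 97% of genotype
  variance.

Evaluation follows the study design the package emulates: seven training
sets per validation line ({B1}, {B2}, {W1}, pairs, all three), predictive
correlation ρ̂ with approximate SE (1−ρ̂²)/√(N−2), bias slope b₁ of
phenotype on GEBV with a 10 000-sample bootstrap SE and the
|b₁−1| < 2·SE rule, plus convex blending of two models' predictions and a
between-model prediction-correlation (complementarity) matrix.

## Worked example

```python
import multiline_gs as mgs
from multiline_gs.scenarios import RunConfig, ScenarioSpec, run_scenario
from multiline_gs.blendscan import beta_sweep

cfg = mgs.SimulationConfig(
    seed=42, n_train_per_line=400, n_valid_per_line=120,
    n_markers=1500, n_qtl=150,
)
panel, truth = mgs.simulate(cfg)
run_cfg = RunConfig(seed=42, gblup_lambda="h2", heritability=0.3,
                    n_bootstrap=10_000)

preds = {}
for model in ("GBLUP", "RBF"):
    out = run_scenario(panel, truth,
                       ScenarioSpec(("B1", "B2", "W1"), "B1", model), run_cfg)
    rep = out["report"]
    preds[model] = (out["predictions"], out["y_valid"])
    print(f"{model:6s} rho = {rep.rho:.3f} (SE {rep.se_rho:.3f}), "
          f"b1 = {rep.b1:.2f} (SE {rep.se_b1:.2f}), "
          f"unbiased: {rep.b1_compatible_with_1}")

blend = beta_sweep(preds["GBLUP"][0], preds["RBF"][0], preds["GBLUP"][1],
                   labels=("GBLUP", "RBF"))
print(f"best blend beta = {blend.argmax_beta:.2f}, rho = {blend.rho.max():.3f}")
```

prints

```
GBLUP  rho = 0.238 (SE 0.087), b1 = 0.98 (SE 0.36), unbiased: True
RBF    rho = 0.290 (SE 0.084), b1 = 8.05 (SE 2.41), unbiased: False
best blend beta = 0.00, rho = 0.290
```

Read: training on all three lines and validating on B1, both models
predict with similar accuracy (ρ̂ ≈ 0.24–0.29, against an SE of ≈ 0.09 at
120 validation animals). GBLUP's slope of phenotype on GEBV is
compatible with 1 (unbiased scale), while the RBF predictions are far too
uniform — a slope of 8 means their spread understates true differences —
which is exactly why the bias diagnostic is reported alongside the
correlation. At this seed the best convex blend puts all weight on the
RBF model.

The same pipeline is scriptable from the shell:

```sh
multiline-gs simulate -c sim.yaml -o data/
multiline-gs run -c sim.yaml -r run.yaml -o results/
multiline-gs blend -r results/ --pair GBLUP,RBF --line B1
```

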