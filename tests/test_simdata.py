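"""Generator checks: drift moments, line divergence, LD, trait architecture."""

import numpy as np
import pytest

from multiline_gs.simdata import (
    SimulationConfig,
    assign_qtl_effects,
    bend_correlation,
    draw_line_frequencies,
    nei_fst,
    simulate,
    simulate_genotypes,
    simulate_phenotypes,
)


def cfg(**kw):
    base = dict(
        seed=0,
        n_train_per_line=60,
        n_valid_per_line=20,
        n_markers=200,
        n_qtl=30,
        ld_rho=0.5,
    )
    base.update(kw)
    return SimulationConfig(**base)


class TestLineFrequencies:
    def test_zero_drift_copies_ancestral_frequencies(self):
        c = cfg(drift_tree={"brown_ancestor": 0, "b1": 0, "b2": 0, "white": 0})
        f = draw_line_frequencies(c)
        assert np.array_equal(f[0], f[1])
        assert np.array_equal(f[0], f[2])
        assert ((f > 0.05) & (f < 0.95)).all()

    def test_drift_one_rejected(self):
        c = cfg(drift_tree={"brown_ancestor": 0, "b1": 0, "b2": 0, "white": 0})
        c.drift_tree["white"] = 1.0
        with pytest.raises(ValueError):
            draw_line_frequencies(c)

    def test_balding_nichols_moments(self):
        # one drift step at F=0.5 from p=0.5: mean 0.5, variance p(1-p)F=0.125
        c = cfg(
            n_markers=20000,
            ancestral_freq_range=(0.5, 0.5),
            drift_tree={"brown_ancestor": 0.0, "b1": 0.5, "b2": 0.0, "white": 0.0},
        )
        f = draw_line_frequencies(c)
        assert f[0].mean() == pytest.approx(0.5, abs=0.01)
        assert f[0].var() == pytest.approx(0.125, abs=0.005)
        # the undrifted sibling keeps the ancestral frequency exactly
        assert np.allclose(f[1], 0.5)

    def test_fst_ordering_follows_drift_tree(self):
        # brown split F=0.05 < white branch F=0.20 => B1-B2 less diverged
        fst_bb, fst_bw, fst_b2w = [], [], []
        for seed in range(30):
            c = cfg(
                seed=seed,
                n_markers=2000,
                drift_tree={"brown_ancestor": 0.05, "b1": 0.05, "b2": 0.05, "white": 0.20},
            )
            f = draw_line_frequencies(c)
            fst_bb.append(nei_fst(f[0], f[1]))
            fst_bw.append(nei_fst(f[0], f[2]))
            fst_b2w.append(nei_fst(f[1], f[2]))
        fst_bb, fst_bw, fst_b2w = map(np.array, (fst_bb, fst_bw, fst_b2w))
        assert fst_bb.mean() < fst_bw.mean()
        assert fst_bb.mean() < fst_b2w.mean()
        assert np.mean(fst_bb < fst_bw) >= 0.9
        assert np.mean(fst_bb < fst_b2w) >= 0.9


class TestGenotypes:
    def test_independent_marker_moments(self):
        c = cfg(
            n_train_per_line=1500,
            n_valid_per_line=0,
            n_markers=400,
            ld_rho=0.0,
            ancestral_freq_range=(0.5, 0.5),
            drift_tree={"brown_ancestor": 0, "b1": 0, "b2": 0, "white": 0},
        )
        f = draw_line_frequencies(c)
        panel = simulate_genotypes(f, c)
        g = panel.genotypes[panel.line_labels == "B1"].astype(float)
        assert g.mean() == pytest.approx(1.0, abs=0.03)
        assert g.var(axis=0).mean() == pytest.approx(0.5, abs=0.03)
        # adjacent markers uncorrelated
        r = [np.corrcoef(g[:, j], g[:, j + 1])[0, 1] for j in range(g.shape[1] - 1)]
        assert abs(np.mean(r)) < 0.01

    def test_sample_frequency_tracks_line_frequency(self):
        c = cfg(seed=21, n_train_per_line=400, n_valid_per_line=0, n_markers=500)
        f = draw_line_frequencies(c, np.random.default_rng(3))
        panel = simulate_genotypes(f, c, np.random.default_rng(4))
        n_hap = 2 * 400
        for li, line in enumerate(c.line_names):
            g = panel.genotypes[panel.line_labels == line]
            phat = g.mean(axis=0) / 2.0
            se = np.sqrt(f[li] * (1 - f[li]) / n_hap)
            within = np.abs(phat - f[li]) <= 4 * se
            assert within.mean() >= 0.99

    def test_ld_increases_with_copying_rate(self):
        def mean_adjacent_r2(rho, seed):
            c = cfg(seed=seed, n_train_per_line=150, n_valid_per_line=0,
                    n_markers=120, ld_rho=rho)
            f = draw_line_frequencies(c)
            panel = simulate_genotypes(f, c, np.random.default_rng(seed + 1))
            g = panel.genotypes[panel.line_labels == "B1"].astype(float)
            keep = g.std(axis=0) > 0
            g = g[:, keep]
            r2 = [
                np.corrcoef(g[:, j], g[:, j + 1])[0, 1] ** 2
                for j in range(g.shape[1] - 1)
            ]
            return np.mean(r2)

        high = np.mean([mean_adjacent_r2(0.9, s) for s in range(30)])
        low = np.mean([mean_adjacent_r2(0.2, s) for s in range(30)])
        assert high > low

    def test_genotypes_are_dosages(self, small_dataset):
        panel, _ = small_dataset
        assert np.isin(panel.genotypes, (0, 1, 2)).all()


class TestQtlEffects:
    def _freqs(self, c, rng):
        return np.clip(rng.uniform(0.1, 0.9, size=(c.n_lines, c.n_qtl)), 0.01, 0.99)

    def test_identity_correlation_gives_uncorrelated_effects(self):
        c = cfg(n_qtl=1000, n_markers=1000, qtl_correlation=np.eye(3))
        rng = np.random.default_rng(5)
        eff = assign_qtl_effects(c, self._freqs(c, rng), rng)
        r = np.corrcoef(eff)
        assert abs(r[0, 1]) < 0.1 and abs(r[0, 2]) < 0.1

    def test_configured_correlation_recovered(self):
        # r(B1,B2)=0.63 with 1000 QTL: within 3 MC SE, (1-r^2)/sqrt(q)
        c = cfg(n_qtl=1000, n_markers=1000)
        rng = np.random.default_rng(7)
        eff = assign_qtl_effects(c, self._freqs(c, rng), rng)
        r = np.corrcoef(eff[0], eff[1])[0, 1]
        tol = 3 * (1 - 0.63**2) / np.sqrt(1000)
        assert abs(r - 0.63) < tol

    def test_unit_correlation_gives_proportional_effects(self):
        c = cfg(qtl_correlation=np.ones((3, 3)))
        rng = np.random.default_rng(9)
        eff = assign_qtl_effects(c, self._freqs(c, rng), rng)
        for li in range(1, 3):
            ratio = eff[li] / eff[0]
            assert np.allclose(ratio, ratio[0], rtol=1e-6)

    def test_bend_correlation_fixes_non_psd(self):
        C = np.array([[1.0, 0.95, -0.95], [0.95, 1.0, 0.9], [-0.95, 0.9, 1.0]])
        B = bend_correlation(C)
        assert np.linalg.eigvalsh(B).min() >= -1e-10
        assert np.allclose(np.diag(B), 1.0)


class TestPhenotypes:
    def test_heritability_definition(self):
        # corr(TBV, phenotype) ~= sqrt(h2) once the hatch effect is absent
        c = cfg(seed=2, n_lines=2, n_train_per_line=2000, n_valid_per_line=0,
                n_markers=500, n_qtl=100, hatch_effect_sd=0.0,
                heritability_per_line=(0.3, 0.3),
                qtl_correlation=np.array([[1.0, 0.63], [0.63, 1.0]]))
        panel, truth = simulate(c)
        m = panel.line_labels == "B1"
        r = np.corrcoef(truth.true_breeding_values[m], truth.phenotypes[m])[0, 1]
        tol = 3 * (1 - 0.3) / np.sqrt(m.sum())
        assert abs(r - np.sqrt(0.3)) < tol

    def test_realized_genetic_variance_on_target(self, small_dataset, small_config):
        panel, truth = small_dataset
        for li, line in enumerate(small_config.line_names):
            m = panel.line_labels == line
            v = truth.true_breeding_values[m].var()
            assert v == pytest.approx(small_config.heritability_per_line[li], rel=0.2)

    def test_phenotype_decomposition(self, small_dataset, small_config):
        panel, truth = small_dataset
        # slope of phenotype on TBV is ~1 by construction
        x = truth.true_breeding_values
        y = truth.phenotypes
        slope = np.cov(x, y)[0, 1] / x.var()
        assert slope == pytest.approx(1.0, abs=0.15)

    def test_h2_one_rejected(self):
        with pytest.raises(ValueError):
            c = cfg(heritability_per_line=(1.0, 0.3, 0.3))

    def test_h2_zero_gives_pure_noise(self):
        c = cfg(seed=4, heritability_per_line=(0.0, 0.3, 0.3))
        panel, truth = simulate(c)
        m = panel.line_labels == "B1"
        assert np.allclose(truth.true_breeding_values[m], 0.0)


class TestDeterminism:
    def test_same_seed_bit_identical(self):
        c1 = cfg(seed=99)
        c2 = cfg(seed=99)
        p1, t1 = simulate(c1)
        p2, t2 = simulate(c2)
        assert np.array_equal(p1.genotypes, p2.genotypes)
        assert np.array_equal(t1.phenotypes, t2.phenotypes)
        assert np.array_equal(t1.qtl_indices, t2.qtl_indices)

    def test_different_seed_differs(self):
        p1, _ = simulate(cfg(seed=1))
        p2, _ = simulate(cfg(seed=2))
        assert not np.array_equal(p1.genotypes, p2.genotypes)


def test_yaml_roundtrip(tmp_path):
    c = cfg(seed=42)
    path = tmp_path / "config.yaml"
    c.to_yaml(path)
    c2 = SimulationConfig.from_yaml(path)
    assert c2.seed == 42
    assert c2.n_markers == c.n_markers
    assert np.allclose(c2.qtl_correlation, c.qtl_correlation)


def test_seed_mandatory_in_yaml(tmp_path):
    path = tmp_path / "bad.yaml"
    path.write_text("n_markers: 100\n")
    with pytest.raises(ValueError, match="seed"):
        SimulationConfig.from_yaml(path)
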