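import math

import numpy as np
import pytest
from scipy.special import expit, logit

from poolfreq.calibration import (CalibrationData, MONO_A, MONO_B, PoolDesign,
                                  STANDARD_PROPORTIONS,
                                  classify_configuration,
                                  expected_pool_frequency,
                                  expected_pool_percent, fit_logistic,
                                  predict_frequency, select_calibration_snps,
                                  standard_pool_designs)
from poolfreq.simulate import SignalModel, simulate_controlled_pools

import pandas as pd

# printed whole-percent grid for the nine standard pools x six parental
# genotype configurations (columns keyed by allele-B dosage triples)
EXPECTED_PERCENTS = {
    (0, 0, 0): [0, 0, 0, 0, 0, 0, 0, 0, 0],
    (1, 0, 0): [1, 2, 3, 5, 7, 10, 15, 20, 33],
    (0, 0, 1): [50, 49, 49, 48, 47, 45, 43, 40, 33],
    (0, 1, 0): [50, 49, 49, 48, 47, 45, 43, 40, 33],
    (1, 0, 1): [51, 51, 52, 53, 54, 55, 58, 60, 67],
    (1, 1, 0): [51, 51, 52, 53, 54, 55, 58, 60, 67],
    (0, 1, 1): [99, 98, 97, 95, 93, 90, 85, 80, 67],
    (1, 1, 1): [100, 100, 100, 100, 100, 100, 100, 100, 100],
}


class TestPoolDesign:
    def test_nine_standard_pools(self):
        designs = standard_pool_designs("S1")
        assert len(designs) == 9
        assert all(abs(sum(d.proportions) - 1) < 1e-9 for d in designs)

    def test_invalid_proportions_rejected(self):
        with pytest.raises(ValueError):
            PoolDesign("#x", (0.5, 0.5, 0.5), "S1")

    @pytest.mark.parametrize("genotypes,expected",
                             sorted(EXPECTED_PERCENTS.items()))
    def test_expected_percent_grid(self, genotypes, expected):
        got = [expected_pool_percent(genotypes, props)
               for props in STANDARD_PROPORTIONS]
        assert got == expected

    def test_worked_examples(self):
        assert expected_pool_frequency((1, 0, 1), (0.15, 0.425, 0.425)) \
            == pytest.approx(0.575)
        assert expected_pool_percent((1, 0, 1), (0.15, 0.425, 0.425)) == 58
        assert expected_pool_frequency((1, 0, 0), (0.2, 0.4, 0.4)) \
            == pytest.approx(0.2)
        assert expected_pool_frequency((0, 0, 0), (0.1, 0.45, 0.45)) == 0.0

    def test_heterozygous_dosage_rejected(self):
        with pytest.raises(ValueError):
            expected_pool_frequency((1, 0.5, 0), (0.2, 0.4, 0.4))


class TestConfigurationClass:
    @pytest.mark.parametrize("dosages,cls", [
        ((0, 0, 0), MONO_A), ((1, 1, 1), MONO_B),
        ((1, 0, 0), "R1"), ((0, 0, 1), "R2"), ((0, 1, 0), "R2"),
        ((1, 0, 1), "R3"), ((1, 1, 0), "R3"), ((0, 1, 1), "R4"),
    ])
    def test_mapping(self, dosages, cls):
        assert classify_configuration(dosages) == cls

    def test_invalid_dosage(self):
        with pytest.raises(ValueError):
            classify_configuration((0, 2, 1))


class TestCalibrationSample:
    @staticmethod
    def _configs(n_per_class=30):
        configs = {}
        i = 0
        for cls_dosage in ((1, 0, 0), (0, 0, 1), (1, 0, 1), (0, 1, 1)):
            for _ in range(n_per_class + 10):
                configs[f"snp{i:04d}"] = (
                    classify_configuration(cls_dosage), MONO_A)
                i += 1
        return configs

    def test_counts_and_uniqueness(self):
        sel = select_calibration_snps(self._configs(), 30, seed=0)
        assert len(sel) == 120
        assert len(set(sel)) == 120

    def test_determinism(self):
        cfg = self._configs()
        a = select_calibration_snps(cfg, 30, seed=5)
        b = select_calibration_snps(cfg, 30, seed=5)
        c = select_calibration_snps(cfg, 30, seed=6)
        assert a == b
        assert a != c

    def test_priority_assignment_unique(self):
        # a SNP that is R1 in one series and R4 in the other counts once,
        # and under the R1-first priority it counts as R1
        configs = {f"r1r4_{i}": ("R1", "R4") for i in range(10)}
        configs.update({f"r4_{i}": (MONO_A, "R4") for i in range(10)})
        configs.update({f"r2_{i}": ("R2", "R2") for i in range(10)})
        configs.update({f"r3_{i}": ("R3", MONO_B) for i in range(10)})
        sel = select_calibration_snps(configs, 10, seed=0)
        assert len(sel) == 40 and len(set(sel)) == 40
        assert {s for s in sel if s.startswith("r1r4")} == \
            {f"r1r4_{i}" for i in range(10)}

    def test_insufficient_class_named(self):
        configs = {"a": ("R1", MONO_A), "b": ("R1", "R2"), "c": ("R4", "R4"),
                   "d": ("R4", MONO_B), "e": ("R2", "R2"), "f": ("R3", "R3")}
        with pytest.raises(ValueError, match="R2"):
            select_calibration_snps(configs, 2, seed=0)


class TestFitLogistic:
    def test_zero_noise_identifiability(self):
        x = np.linspace(0.05, 0.95, 40)
        y = expit(-5 + 10 * x)
        fit = fit_logistic(x, y)
        assert fit.converged
        assert fit.alpha == pytest.approx(-5.0, abs=1e-6)
        assert fit.beta == pytest.approx(10.0, abs=1e-6)

    def test_two_point_closed_form(self):
        fit = fit_logistic([0.2, 0.8], [0.25, 0.75])
        beta = (logit(0.75) - logit(0.25)) / 0.6
        assert fit.beta == pytest.approx(beta, abs=1e-8)
        assert fit.alpha == pytest.approx(logit(0.25) - beta * 0.2, abs=1e-8)

    def test_constant_response_rejected(self):
        with pytest.raises(ValueError):
            fit_logistic([0.1, 0.5, 0.9], [0.4, 0.4, 0.4])

    def test_matches_statsmodels_glm(self):
        # independent IRLS oracle on noisy fractional responses
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(4)
        x = rng.uniform(0, 1, 200)
        y = np.clip(expit(-4 + 8 * x) + rng.normal(0, 0.05, 200), 0.001, 0.999)
        fit = fit_logistic(x, y)
        glm = sm.GLM(y, np.column_stack([np.ones_like(x), x]),
                     family=sm.families.Binomial()).fit()
        assert fit.alpha == pytest.approx(glm.params[0], abs=1e-6)
        assert fit.beta == pytest.approx(glm.params[1], abs=1e-6)
        assert fit.deviance == pytest.approx(glm.deviance, rel=1e-6)

    def test_allele_relabel_equivariance(self):
        rng = np.random.default_rng(8)
        x = rng.uniform(0, 1, 100)
        y = np.clip(expit(-3 + 6 * x) + rng.normal(0, 0.04, 100), 0.01, 0.99)
        fit = fit_logistic(x, y)
        flipped = fit_logistic(1 - x, 1 - y)
        assert flipped.beta == pytest.approx(fit.beta, abs=1e-6)
        assert flipped.alpha == pytest.approx(-fit.alpha - fit.beta, abs=1e-6)

    def test_parameter_recovery_from_controlled_pools(self):
        """A noise-free two-series design whose pools are all polymorphic
        (R1 + R4) identifies the generating curve to high precision."""
        model = SignalModel(noise_sd=0.0, mean_jitter_sd=0.0)
        snps = [f"s{i}" for i in range(50)]
        parents = {
            "S1": pd.DataFrame([[1, 0, 0]] * 50, index=snps),
            "S2": pd.DataFrame([[0, 1, 1]] * 50, index=snps),
        }
        fir, expected, _, pools = simulate_controlled_pools(
            parents, model, include_parents=False)
        data = CalibrationData(fir.values, expected, pools)
        fit = fit_logistic(*data.pairs())
        assert fit.alpha == pytest.approx(model.alpha0, abs=1e-3)
        assert fit.beta == pytest.approx(model.beta0, abs=1e-3)


class TestPredict:
    FIT = fit_logistic(np.linspace(0.05, 0.95, 20),
                       expit(-5 + 10 * np.linspace(0.05, 0.95, 20)))

    def test_symmetry_point(self):
        assert predict_frequency(0.5, self.FIT) == pytest.approx(0.5, abs=1e-9)

    def test_direct_evaluation(self):
        assert predict_frequency(0.92, self.FIT) == \
            pytest.approx(expit(4.2), abs=1e-6)
        assert expit(4.2) == pytest.approx(0.9852, abs=1e-4)

    def test_strictly_increasing_and_interior(self):
        grid = np.linspace(-0.5, 1.5, 200)
        p = predict_frequency(grid, self.FIT)
        assert np.all(np.diff(p) > 0)
        assert np.all((p > 0) & (p < 1))
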