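import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

import homingchains as hc
from homingchains.stats import dunnett_adjust, shrink_unit_interval


def beta_table(rng, logit_shift, n_per_group=500, phi=50.0):
    """Two datasets across generations 2-5 with a known logit mean shift."""
    g = np.tile([2, 3, 4, 5], n_per_group // 4)
    mu_ref = expit(-0.5 + 0.1 * g)
    mu_b = expit(-0.5 + 0.1 * g + logit_shift)
    y_ref = rng.beta(mu_ref * phi, (1 - mu_ref) * phi)
    y_b = rng.beta(mu_b * phi, (1 - mu_b) * phi)
    return pd.DataFrame(
        {
            "dataset": ["ref"] * g.size + ["b"] * g.size,
            "generation": np.concatenate([g, g]),
            "efficiency": np.concatenate([y_ref, y_b]),
        }
    )


class TestBetaRegression:
    def test_coefficient_recovery_within_3se(self):
        rng = np.random.default_rng(0)
        table = beta_table(rng, logit_shift=0.4)
        model = hc.fit_beta_regression(table, reference="ref")
        name = [p for p in model.params.index if "dataset" in p and ":" not in p][0]
        est = model.params[name]
        se = np.sqrt(np.diag(model.results.cov_params()))[
            list(model.params.index).index(name)
        ]
        # dataset effect plus the interaction at the mean generation
        inter = [p for p in model.params.index if "dataset" in p and ":" in p][0]
        total = est + model.params[inter] * 3.5
        assert abs(total - 0.4) < 3.0 * se + 0.05

    def test_constant_half_data_gives_zero_logit_intercept(self):
        table = pd.DataFrame(
            {"dataset": "a", "generation": np.tile([2, 3, 4, 5], 25), "efficiency": 0.5}
        )
        model = hc.fit_beta_regression(table)
        assert model.params["Intercept"] == pytest.approx(0.0, abs=1e-6)
        assert model.params["generation"] == pytest.approx(0.0, abs=1e-6)

    def test_single_dataset_reduces_to_generation_model(self):
        rng = np.random.default_rng(1)
        table = beta_table(rng, 0.0).query("dataset == 'ref'")
        model = hc.fit_beta_regression(table)
        assert not any("dataset" in p for p in model.params.index)

    def test_boundary_values_are_shrunk_with_warning(self):
        rng = np.random.default_rng(2)
        table = beta_table(rng, 0.0, n_per_group=100)
        table.loc[table.index[0], "efficiency"] = 1.0
        with pytest.warns(UserWarning, match="shrink"):
            hc.fit_beta_regression(table, reference="ref")

    def test_shrinkage_transform_definition(self):
        y = np.array([0.0, 0.5, 1.0])
        np.testing.assert_allclose(
            shrink_unit_interval(y), [0.5 / 3, (0.5 * 2 + 0.5) / 3, 2.5 / 3]
        )

    def test_missing_reference_rejected(self):
        rng = np.random.default_rng(3)
        with pytest.raises(ValueError):
            hc.fit_beta_regression(beta_table(rng, 0.0), reference="nope")


class TestOddsRatioContrasts:
    def test_dataset_against_itself_gives_unit_odds_ratio(self):
        rng = np.random.default_rng(4)
        table = beta_table(rng, 0.0, n_per_group=400)
        half = table.query("dataset == 'ref'").copy()
        half["dataset"] = "copy"
        model = hc.fit_beta_regression(
            pd.concat([table.query("dataset == 'ref'"), half]), reference="ref"
        )
        (contrast,) = hc.contrast_odds_ratios(model)
        assert contrast.estimate == pytest.approx(1.0, abs=1e-5)
        assert contrast.ci_lo <= 1.0 <= contrast.ci_hi

    def test_known_logit_shift_recovered_as_odds_ratio(self):
        rng = np.random.default_rng(5)
        table = beta_table(rng, np.log(1.5), n_per_group=2000)
        model = hc.fit_beta_regression(table, reference="ref")
        (contrast,) = hc.contrast_odds_ratios(model)
        assert contrast.estimate == pytest.approx(1.5, abs=0.12)
        assert contrast.scale == "odds_ratio"

    def test_weight_model_mean_difference_identity_is_zero(self):
        rng = np.random.default_rng(6)
        vals = rng.normal(0.5, 0.05, 200)
        table = pd.DataFrame(
            {
                "dataset": ["ref"] * 200 + ["copy"] * 200,
                "generation": np.tile(np.tile([2, 3, 4, 5], 50), 2),
                "weight": np.concatenate([vals, vals]),
            }
        )
        model = hc.fit_weight_model(table, reference="ref")
        (contrast,) = hc.contrast_mean_differences(model)
        assert contrast.estimate == pytest.approx(0.0, abs=1e-10)


class TestBootstrap:
    def _table(self, rng, shift=0.0, n=60):
        return pd.DataFrame(
            {
                "dataset": ["ref"] * n + ["b"] * n,
                "generation": 2,
                "bird": list(range(n)) * 2,
                "efficiency": np.concatenate(
                    [rng.beta(6, 2, n), np.clip(rng.beta(6, 2, n) + shift, 0.01, 0.99)]
                ),
            }
        )

    def test_fixed_seed_is_bit_identical(self):
        rng = np.random.default_rng(7)
        table = self._table(rng)
        a, _ = hc.bootstrap_contrasts(table, "efficiency", reference="ref", n_boot=200, seed=5)
        b, _ = hc.bootstrap_contrasts(table, "efficiency", reference="ref", n_boot=200, seed=5)
        assert a[0].ci_lo == b[0].ci_lo and a[0].ci_hi == b[0].ci_hi

    def test_single_draw_bootstrap_warns(self):
        rng = np.random.default_rng(8)
        with pytest.warns(UserWarning, match="degenerate"):
            hc.bootstrap_contrasts(self._table(rng), "efficiency", reference="ref",
                                   n_boot=1, seed=0)

    def test_null_coverage_of_percentile_intervals(self):
        # identical distributions: the 95% OR interval should contain 1 in at
        # least 94% of repetitions
        rng = np.random.default_rng(9)
        cover = 0
        reps = 2500
        for r in range(reps):
            res, _ = hc.bootstrap_contrasts(
                self._table(rng), "efficiency", reference="ref", n_boot=600,
                seed=10_000 + r,
            )
            cover += res[0].ci_lo <= 1.0 <= res[0].ci_hi
        assert cover / reps >= 0.94

    def test_real_shift_is_detected(self):
        rng = np.random.default_rng(10)
        res, reps = hc.bootstrap_contrasts(
            self._table(rng, shift=0.15), "efficiency", reference="ref",
            n_boot=2000, seed=1,
        )
        adj = hc.dunnett_adjust(res, reps)
        assert adj[0].estimate > 1.0
        assert adj[0].p_value < 0.05


class TestDunnett:
    def _fake_family(self, rng, k, n=30, n_boot=400):
        contrasts, replicates = [], {}
        for j in range(k):
            x = rng.normal(0, 1, n)
            theta = x[rng.integers(0, n, size=(n_boot, n))].mean(axis=1)
            obs = float(x.mean())
            lo, hi = np.quantile(theta, [0.025, 0.975])
            p = 2.0 * min(np.mean(theta <= 0), np.mean(theta >= 0))
            c = hc.ContrastResult(
                label=f"s{j}", generation=2, estimate=obs,
                ci_lo=min(lo, obs), ci_hi=max(hi, obs),
                p_value=float(max(p, 1 / n_boot)), scale="difference", df=n - 1,
            )
            contrasts.append(c)
            replicates[(c.label, 2)] = theta
        return contrasts, replicates

    def test_single_contrast_is_returned_unadjusted(self):
        rng = np.random.default_rng(11)
        contrasts, reps = self._fake_family(rng, 1)
        (adj,) = dunnett_adjust(contrasts, reps)
        assert adj.p_value == contrasts[0].p_value

    def test_bonferroni_multiplies_raw_p(self):
        rng = np.random.default_rng(12)
        contrasts, _ = self._fake_family(rng, 4)
        adjusted = dunnett_adjust(contrasts, method="bonferroni")
        for raw, adj in zip(contrasts, adjusted):
            assert adj.p_value == pytest.approx(min(1.0, 4 * raw.p_value))

    def test_adjusted_p_never_below_raw(self):
        rng = np.random.default_rng(13)
        contrasts, reps = self._fake_family(rng, 6)
        for raw, adj in zip(contrasts, dunnett_adjust(contrasts, reps)):
            assert adj.p_value >= raw.p_value - 1e-12

    def test_familywise_error_near_nominal_for_independent_nulls(self):
        # k = 6 independent null contrasts, 2000 repetitions: the probability
        # of any adjusted p < 0.05 should sit near 0.05
        rng = np.random.default_rng(14)
        hits = 0
        reps = 2000
        for _ in range(reps):
            contrasts, replicates = self._fake_family(rng, 6, n=30, n_boot=300)
            adj = dunnett_adjust(contrasts, replicates)
            hits += any(c.p_value < 0.05 for c in adj)
        assert 0.02 <= hits / reps <= 0.08
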