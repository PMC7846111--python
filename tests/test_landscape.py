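"""Mixture fitting, aero-type assignment, stepwise regression, complexity,
flux PCA and the feasibility envelope."""

import numpy as np
import pandas as pd
import pytest

from fluxscape.landscape import (
    AEROTYPE_LABELS,
    ComplexityMetrics,
    FitError,
    MixtureFit,
    assign_aerotype,
    component_silhouette,
    feasibility_envelope,
    fit_fatps_mixture,
    flux_pca,
    preferred_component_count,
    proteome_complexity,
    stepwise_regression,
)
from fluxscape.model import Condition, FluxSolution, InputError
from fluxscape.synth import make_fatps_samples


class TestMixtureFit:
    def test_recovers_generating_parameters(self):
        v = make_fatps_samples(
            means=(0.37, 0.53, 0.64, 0.71), sds=0.02, zero_weight=0.0,
            n=2000, seed=42,
        )
        fit = fit_fatps_mixture(v)
        for got, want in zip(fit.means, (0.37, 0.53, 0.64, 0.71)):
            assert got == pytest.approx(want, abs=0.01)
        assert fit.zero_peak_weight == 0.0
        assert fit.converged

    def test_all_zero_values_collapse_to_point_mass(self):
        fit = fit_fatps_mixture(np.zeros(500))
        assert fit.zero_peak_weight == 1.0
        assert fit.n_components == 0

    def test_weights_sum_to_one(self):
        v = make_fatps_samples(n=1500, zero_weight=0.2, seed=3)
        fit = fit_fatps_mixture(v)
        assert fit.zero_peak_weight + sum(fit.weights) == pytest.approx(1.0, abs=1e-9)
        assert all(b > a for a, b in zip(fit.means, fit.means[1:]))

    def test_duplicated_input_gives_identical_parameters(self):
        v = make_fatps_samples(n=800, seed=9)
        a = fit_fatps_mixture(v)
        b = fit_fatps_mixture(np.concatenate([v, v]))
        assert np.allclose(a.means, b.means, atol=1e-6)
        assert np.allclose(a.weights, b.weights, atol=1e-6)

    def test_too_few_values_rejected(self):
        with pytest.raises(FitError):
            fit_fatps_mixture(np.full(30, 0.5))

    def test_bic_prefers_the_generating_component_count(self):
        v = make_fatps_samples(n=2000, seed=5)
        assert preferred_component_count(v) >= 3

    def test_silhouette_high_for_separated_modes(self):
        v = make_fatps_samples(means=(0.2, 0.5, 0.8), sds=0.01, n=900, seed=2)
        fit = fit_fatps_mixture(v, n_components=3)
        assert component_silhouette(v, fit) > 0.8


def _fit(means, sds=0.02, zero=0.1):
    k = len(means)
    w = (1.0 - zero) / k
    return MixtureFit(
        zero_peak_weight=zero,
        means=tuple(means),
        sds=(sds,) * k if np.isscalar(sds) else tuple(sds),
        weights=(w,) * k,
        loglik=0.0, converged=True, n_used=100,
    )


class TestAssignAerotype:
    FIT = _fit((0.37, 0.53, 0.64, 0.71))

    def test_zero_is_fermentative_type(self):
        assert assign_aerotype(0.0, self.FIT) == "i"

    def test_top_peak_is_type_v(self):
        assert assign_aerotype(0.71, self.FIT) == "v"

    def test_posterior_tie_breaks_to_lower_label(self):
        # equidistant between two equal-weight, equal-sd components
        fit = _fit((0.4, 0.6, 0.7, 0.8))
        assert assign_aerotype(0.5, fit) == "ii"

    def test_out_of_range_rejected(self):
        with pytest.raises(InputError):
            assign_aerotype(1.5, self.FIT)

    def test_total_and_deterministic(self):
        labels = [assign_aerotype(f, self.FIT) for f in np.linspace(0, 1, 101)]
        assert set(labels) <= set(AEROTYPE_LABELS)
        assert labels == [assign_aerotype(f, self.FIT) for f in np.linspace(0, 1, 101)]


class TestStepwiseRegression:
    COLS = ["f_ATPS", "f_PGK", "f_PYK", "f_ACKr", "f_PPKr", "f_PPK2r",
            "f_SUCOAS", "f_PRPPS"]

    def _predictors(self, n, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(rng.random((n, 8)), columns=self.COLS)

    def test_exact_linear_response_selected_first(self):
        X = self._predictors(200)
        y = 3.0 * X["f_ATPS"] - 1.0
        rep = stepwise_regression(X, y)
        assert rep.selected[0] == "f_ATPS"
        assert rep.final_r2 == pytest.approx(1.0, abs=1e-9)

    def test_pure_noise_predictor_never_selected(self):
        rng = np.random.default_rng(1)
        X = self._predictors(1000, seed=1)
        y = 2.0 * X["f_PGK"] + 0.5 * X["f_ACKr"] + rng.normal(0, 0.05, 1000)
        noise = rng.normal(size=1000)
        X = X.assign(noise=noise - np.polyval(np.polyfit(y, noise, 1), y))
        rep = stepwise_regression(X, y)
        assert "noise" not in rep.selected

    def test_cumulative_r2_nondecreasing(self):
        rng = np.random.default_rng(2)
        X = self._predictors(300, seed=2)
        y = X.to_numpy() @ rng.random(8) + rng.normal(0, 0.1, 300)
        rep = stepwise_regression(X, y)
        assert all(b >= a - 1e-12 for a, b in zip(rep.cumulative_r2,
                                                  rep.cumulative_r2[1:]))
        assert all(0.0 <= r <= 1.0 + 1e-12 for r in rep.cumulative_r2)

    def test_duplicated_predictor_skipped_with_warning(self):
        X = self._predictors(100, seed=3)
        X["f_PGK"] = X["f_ATPS"]  # collinear pair
        y = X["f_ATPS"] * 2.0
        rep = stepwise_regression(X, y)
        assert rep.final_r2 == pytest.approx(1.0, abs=1e-9)
        assert any("rank-deficient" in w for w in rep.warnings)

    def test_too_few_rows_rejected(self):
        X = self._predictors(10)
        with pytest.raises(InputError):
            stepwise_regression(X, X["f_ATPS"])


class TestProteomeComplexity:
    def _solution(self, phi):
        return FluxSolution(
            mu=0.5, fluxes={}, enzyme_phi=phi, feasible=True,
            condition=Condition(temperature=37.0),
        )

    def test_nothing_expressed(self, model):
        out = proteome_complexity(self._solution({}), model)
        assert out == ComplexityMetrics(0, 0.0)

    def test_single_thirteen_subunit_complex(self, model):
        out = proteome_complexity(self._solution({"Nuo": 0.01}), model)
        assert out.n_genes_expressed == 13
        assert out.avg_subunits == 13.0

    def test_threshold_excludes_trace_expression(self, model):
        out = proteome_complexity(self._solution({"Nuo": 1e-8}), model)
        assert out.n_genes_expressed == 0

    def test_shared_genes_counted_once(self, model):
        phi = {"Pgk": 0.01, "EnoL": 0.01}
        out = proteome_complexity(self._solution(phi), model)
        assert out.n_genes_expressed == 3  # pgk + gpmA + eno
        assert out.avg_subunits == pytest.approx(1.5)


class TestFluxPCA:
    def _table(self, n=40, seed=0):
        rng = np.random.default_rng(seed)
        base = rng.normal(size=(n, 1))
        cols = {
            "GLCpts": base[:, 0] * 2 + rng.normal(0, 0.1, n),
            "ATPS4rpp": -base[:, 0] * 3 + rng.normal(0, 0.1, n),
            "PGK": base[:, 0] + rng.normal(0, 0.1, n),
            "PYK": rng.normal(0, 1, n),
        }
        return pd.DataFrame(cols)

    def test_variance_fractions_sum_to_one(self):
        _, var, _ = flux_pca(self._table(), ["GLCpts", "ATPS4rpp", "PGK", "PYK"])
        assert var.sum() == pytest.approx(1.0, abs=1e-9)

    def test_row_duplication_leaves_loadings_unchanged_up_to_sign(self):
        t = self._table()
        cols = ["GLCpts", "ATPS4rpp", "PGK", "PYK"]
        l1, _, _ = flux_pca(t, cols)
        l2, _, _ = flux_pca(pd.concat([t, t], ignore_index=True), cols)
        for c in l1.columns[:2]:
            same = np.allclose(l1[c], l2[c], atol=1e-8)
            flipped = np.allclose(l1[c], -l2[c], atol=1e-8)
            assert same or flipped

    def test_zero_variance_column_dropped_with_warning(self):
        t = self._table()
        t["PYK"] = 1.0
        with pytest.warns(UserWarning, match="zero-variance"):
            loadings, _, _ = flux_pca(t, ["GLCpts", "ATPS4rpp", "PGK", "PYK"])
        assert "PYK" not in loadings.index

    def test_too_few_samples_rejected(self):
        with pytest.raises(InputError):
            flux_pca(self._table(n=2), ["GLCpts", "PGK"])


class TestFeasibilityEnvelope:
    def _isocline(self, mu, slope_y, slope_q, n=30, seed=0):
        rng = np.random.default_rng(seed)
        f = rng.uniform(0.1, 0.8, n)
        return pd.DataFrame(
            {
                "feasible": True,
                "f_ATPS": f,
                "Y": 0.2 + slope_y * f,
                "q_glc": 12.0 + slope_q * f,
            }
        )

    def test_perfect_lines_reproduced_exactly(self):
        tables = {
            0.3: self._isocline(0.3, 0.4, -6.0, seed=1),
            0.5: self._isocline(0.5, 0.5, -7.0, seed=2),
        }
        env = feasibility_envelope(tables)
        row = env[env["mu"] == 0.3].iloc[0]
        assert row["Y_at_fmin"] == pytest.approx(0.2, abs=1e-9)
        assert row["Y_at_fmax"] == pytest.approx(0.2 + 0.4 * 0.83, abs=1e-9)
        assert row["q_at_fmax"] == pytest.approx(12.0 - 6.0 * 0.83, abs=1e-9)
        assert (env["Y_at_fmax"] > env["Y_at_fmin"]).all()

    def test_sparse_isocline_skipped_with_warning(self):
        tables = {
            0.3: self._isocline(0.3, 0.4, -6.0),
            0.5: self._isocline(0.5, 0.4, -6.0, n=3),
        }
        with pytest.warns(UserWarning, match="skipped"):
            env = feasibility_envelope(tables)
        assert set(env["mu"]) == {0.3}

    def test_single_isocline_rejected(self):
        with pytest.raises(InputError):
            feasibility_envelope({0.3: self._isocline(0.3, 0.4, -6.0)})
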