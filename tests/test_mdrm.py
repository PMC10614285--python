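"""M-DRM quadrature, design construction, moments and indices."""

import numpy as np
import pytest

from kinesens import distributions as dist
from kinesens import mdrm
from kinesens.distributions import ParameterSpec
from kinesens.mdrm import DesignError, MDRMSensitivity


def std_normal_spec(name="x"):
    return ParameterSpec(name=name, family="normal", params=(0.0, 1.0))


class TestQuadratureRule:
    def test_five_point_hermite_nodes_and_weights(self):
        rule = mdrm.quadrature_rule(std_normal_spec(), 5)
        # roots of the 5th probabilists' Hermite polynomial x^5-10x^3+15x
        expect = np.array([-2.8569700139, -1.3556261800, 0.0, 1.3556261800, 2.8569700139])
        assert np.allclose(rule.nodes, expect, atol=1e-9)
        assert np.allclose(
            rule.weights,
            [0.011257411328, 0.222075922006, 0.533333333333, 0.222075922006, 0.011257411328],
            atol=1e-10,
        )
        # non-extreme off-center nodes sit at 1.3 SD (one decimal)
        assert np.trunc(abs(rule.nodes[1]) * 10) / 10 == 1.3

    def test_hermite_nodes_are_polynomial_roots(self):
        rule = mdrm.quadrature_rule(std_normal_spec(), 5)
        p = rule.nodes**5 - 10 * rule.nodes**3 + 15 * rule.nodes
        assert np.allclose(p, 0.0, atol=1e-8)

    def test_uniform_first_moment_exact(self):
        spec = ParameterSpec(name="u", family="uniform", params=(0.0, 1.0))
        for n in (2, 3, 5, 7):
            rule = mdrm.quadrature_rule(spec, n)
            assert np.dot(rule.weights, rule.nodes) == pytest.approx(0.5, abs=1e-14)

    def test_normal_low_moments_exact(self):
        spec = ParameterSpec(name="n", family="normal", params=(3.0, 2.0))
        rule = mdrm.quadrature_rule(spec, 5)
        assert np.dot(rule.weights, rule.nodes) == pytest.approx(3.0, abs=1e-12)
        assert np.dot(rule.weights, (rule.nodes - 3.0) ** 2) == pytest.approx(4.0, abs=1e-12)

    @pytest.mark.parametrize("family,params", [
        ("normal", (1.0, 0.5)),
        ("uniform", (2.0, 5.0)),
        ("lognormal", (-1.45, 0.45)),
    ])
    @pytest.mark.parametrize("n_points", [3, 5])
    def test_moment_exactness_to_order_2n_minus_1(self, family, params, n_points):
        """Raw moments of the transformed variable match to degree 2N-1."""
        from scipy import stats

        spec = ParameterSpec(name="p", family=family, params=params)
        rule = mdrm.quadrature_rule(spec, n_points)
        if family == "normal":
            z = (rule.nodes - params[0]) / params[1]
            ref = stats.norm()
        elif family == "uniform":
            z = (rule.nodes - params[0]) / (params[1] - params[0])
            ref = stats.uniform()
        else:
            z = (np.log(rule.nodes) - params[0]) / params[1]
            ref = stats.norm()
        for k in range(2 * n_points):
            exact = ref.moment(k)
            approx = float(np.dot(rule.weights, z**k))
            assert approx == pytest.approx(exact, abs=1e-10 * max(1.0, abs(exact)))

    def test_center_node_is_nominal_for_all_defaults(self, param_specs, rules5):
        for p, r in zip(param_specs, rules5):
            assert r.nodes[r.center_index] == pytest.approx(p.nominal, rel=1e-12)

    def test_lognormal_center_is_median(self):
        spec = ParameterSpec(name="ln", family="lognormal", params=(-1.45, 0.45))
        rule = mdrm.quadrature_rule(spec, 5)
        assert rule.nodes[rule.center_index] == pytest.approx(np.exp(-1.45), rel=1e-14)


class TestBuildDesign:
    def test_seven_parameters_five_points_gives_29_runs(self, design5):
        assert design5.n_runs == 29

    def test_single_parameter_five_points_gives_5_runs(self):
        design = mdrm.build_design([std_normal_spec()], 5)
        assert design.n_runs == 5

    def test_three_points_gives_15_runs(self, param_specs):
        design = mdrm.build_design(param_specs, 3)
        assert design.n_runs == 7 * 2 + 1

    def test_each_run_differs_from_nominal_in_one_parameter(self, design5, param_specs):
        nominal = design5.runs[design5.runs.label == "nominal"].iloc[0]
        for _, row in design5.runs.iterrows():
            if row.label == "nominal":
                continue
            diffs = [
                p.name for p in param_specs if row[p.name] != nominal[p.name]
            ]
            assert len(diffs) == 1
            assert row.label.startswith(diffs[0] + ":")

    def test_even_point_count_cannot_share_nominal(self):
        with pytest.raises(DesignError):
            mdrm.build_design([std_normal_spec()], 4)

    def test_shifted_nominal_rejected(self):
        spec = ParameterSpec(name="x", family="normal", params=(0.0, 1.0), nominal=0.5)
        with pytest.raises(DesignError, match="impossible"):
            mdrm.build_design([spec], 5)

    def test_csv_round_trip(self, design5, tmp_path):
        p = tmp_path / "design.csv"
        design5.to_csv(p)
        back = mdrm.DesignMatrix.from_csv(p, 5)
        assert back.n_runs == design5.n_runs
        assert back.parameters == design5.parameters


def evaluate_design(design, func):
    X = design.runs[list(design.parameters)].to_numpy(dtype=float)
    return dict(zip(design.runs["run_id"], func(X)))


class TestMoments:
    def test_constant_function(self, design5, rules5):
        outputs = evaluate_design(design5, lambda X: np.full(len(X), 7.5))
        mom = mdrm.mdrm_moments(outputs, design5, rules5)
        assert np.allclose(mom["rho"], 7.5, atol=1e-12)
        assert np.allclose(mom["theta"], 7.5**2, atol=1e-12)

    def test_linear_in_one_standard_normal(self):
        specs = [std_normal_spec("x1"), std_normal_spec("x2")]
        # shift by 10 to keep rho nonzero
        design = mdrm.build_design(specs, 5)
        rules = [mdrm.quadrature_rule(s, 5) for s in specs]
        outputs = evaluate_design(design, lambda X: 10.0 + X[:, 0])
        mom = mdrm.mdrm_moments(outputs, design, rules)
        # E[10+x] = 10, E[(10+x)^2] = 100 + 1 (degree-2, quadrature-exact)
        assert mom.loc["x1", "rho"] == pytest.approx(10.0, abs=1e-12)
        assert mom.loc["x1", "theta"] == pytest.approx(101.0, abs=1e-11)
        assert mom.loc["x2", "rho"] == pytest.approx(10.0, abs=1e-12)
        assert mom.loc["x2", "theta"] == pytest.approx(100.0, abs=1e-11)

    def test_product_on_uniforms_matches_1d_integrals(self):
        specs = [
            ParameterSpec(name=f"u{i}", family="uniform", params=(1.0, 2.0))
            for i in range(3)
        ]
        design = mdrm.build_design(specs, 5)
        rules = [mdrm.quadrature_rule(s, 5) for s in specs]
        outputs = evaluate_design(design, lambda X: X.prod(axis=1))
        mom = mdrm.mdrm_moments(outputs, design, rules)
        # along the cut of u_i the others sit at 1.5:
        # rho_i = E[u] * 1.5^2, theta_i = E[u^2] * 1.5^4
        for i in range(3):
            assert mom.iloc[i]["rho"] == pytest.approx(1.5 * 1.5**2, rel=1e-12)
            assert mom.iloc[i]["theta"] == pytest.approx((7.0 / 3.0) * 1.5**4, rel=1e-12)

    def test_jensen_inequality_holds(self, design5, rules5, design_metrics):
        for metric, outputs in design_metrics.items():
            mom = mdrm.mdrm_moments(outputs, design5, rules5)
            assert np.all(mom["theta"] >= mom["rho"] ** 2 * (1 - 1e-12))

    def test_missing_run_output_raises(self, design5, rules5):
        outputs = evaluate_design(design5, lambda X: X[:, 0] + 5)
        outputs.pop("run_003")
        with pytest.raises(KeyError):
            mdrm.mdrm_moments(outputs, design5, rules5)

    def test_shared_nominal_equals_explicit_full_design(self, param_specs, rules5):
        """Reusing the nominal run at every centre node is identical to
        evaluating an explicit nN design of the same function."""
        func = lambda X: 50.0 + X[:, 2] * X[:, 3] + 0.3 * X[:, 0]
        design = mdrm.build_design(param_specs, 5, rules5)
        outputs = evaluate_design(design, func)
        mom_shared = mdrm.mdrm_moments(outputs, design, rules5)
        nominal = np.array([p.nominal for p in param_specs])
        for i, (p, rule) in enumerate(zip(param_specs, rules5)):
            X = np.tile(nominal, (rule.n_points, 1))
            X[:, i] = rule.nodes
            h = func(X)
            assert mom_shared.loc[p.name, "rho"] == pytest.approx(
                float(rule.weights @ h), rel=1e-12
            )
            assert mom_shared.loc[p.name, "theta"] == pytest.approx(
                float(rule.weights @ h**2), rel=1e-12
            )


class TestSensitivityIndices:
    def test_symmetric_function_gives_equal_sevenths(self):
        """Seven exchangeable parameters entering identically -> each 1/7."""
        specs = [std_normal_spec(f"x{i}") for i in range(7)]
        design = mdrm.build_design(specs, 5)
        rules = [mdrm.quadrature_rule(s, 5) for s in specs]
        outputs = evaluate_design(
            design, lambda X: np.prod(1.0 + 0.1 * X, axis=1)
        )
        mom = mdrm.mdrm_moments(outputs, design, rules)
        res = mdrm.sensitivity_indices(mom, 1.0)
        assert np.allclose(res.S, 1.0 / 7.0, atol=1e-12)
        assert res.S.sum() == pytest.approx(1.0, abs=1e-9)

    def test_single_active_parameter_gets_full_index(self):
        specs = [std_normal_spec(f"x{i}") for i in range(3)]
        design = mdrm.build_design(specs, 5)
        rules = [mdrm.quadrature_rule(s, 5) for s in specs]
        outputs = evaluate_design(design, lambda X: 5.0 + X[:, 0])
        mom = mdrm.mdrm_moments(outputs, design, rules)
        res = mdrm.sensitivity_indices(mom, 5.0)
        assert res.S[0] == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(res.S[1:], 0.0, atol=1e-12)

    def test_indices_sum_to_one_for_all_surrogate_metrics(
        self, design5, rules5, design_metrics
    ):
        for metric, outputs in design_metrics.items():
            mom = mdrm.mdrm_moments(outputs, design5, rules5)
            res = mdrm.sensitivity_indices(mom, outputs["run_000"], metric)
            assert np.nansum(res.S) == pytest.approx(1.0, abs=1e-9)
            assert np.all(res.S >= 0)

    def test_zero_rho_fails_loudly(self):
        specs = [std_normal_spec("x0"), std_normal_spec("x1")]
        design = mdrm.build_design(specs, 5)
        rules = [mdrm.quadrature_rule(s, 5) for s in specs]
        outputs = evaluate_design(design, lambda X: X[:, 0])  # odd: rho = 0
        mom = mdrm.mdrm_moments(outputs, design, rules)
        with pytest.raises(ZeroDivisionError):
            mdrm.sensitivity_indices(mom, 0.0)

    def test_all_zero_contributions_warn_and_nan(self, design5, rules5):
        outputs = evaluate_design(design5, lambda X: np.full(len(X), 3.0))
        mom = mdrm.mdrm_moments(outputs, design5, rules5)
        with pytest.warns(RuntimeWarning):
            res = mdrm.sensitivity_indices(mom, 3.0)
        assert np.all(np.isnan(res.S))

    def test_multiplicative_function_matches_monte_carlo_sobol(self, param_specs, rules5):
        """M-DRM indices vs a 1e5-sample pick-freeze Sobol oracle on a
        separable multiplicative function over the 7 default
        distributions: agreement within 0.02."""
        coeffs = np.array([0.05, 0.2, 0.1, 0.15, 0.08, 0.12, 0.18])

        def standardize(X):
            Z = np.empty_like(X)
            for i, p in enumerate(param_specs):
                a, b = p.params
                if p.family == "normal":
                    Z[:, i] = (X[:, i] - a) / b
                elif p.family == "uniform":
                    Z[:, i] = (X[:, i] - (a + b) / 2) / ((b - a) / 2)
                else:
                    Z[:, i] = (np.log(X[:, i]) - a) / b
            return Z

        def func(X):
            return np.prod(1.0 + coeffs * standardize(X), axis=1)

        design = mdrm.build_design(param_specs, 5, rules5)
        outputs = evaluate_design(design, func)
        mom = mdrm.mdrm_moments(outputs, design, rules5)
        res = mdrm.sensitivity_indices(mom, outputs["run_000"])

        rng = np.random.default_rng(42)
        n = 100_000
        A = np.column_stack(
            [p.frozen().rvs(size=n, random_state=rng) for p in param_specs]
        )
        B = np.column_stack(
            [p.frozen().rvs(size=n, random_state=rng) for p in param_specs]
        )
        fA, fB = func(A), func(B)
        mu = np.concatenate([fA, fB]).mean()
        var = np.concatenate([fA, fB]).var(ddof=1)
        for i, p in enumerate(param_specs):
            C = A.copy()
            C[:, i] = B[:, i]
            fC = func(C)
            S_mc = np.mean((fB - mu) * (fC - fA)) / var
            assert abs(res.S[i] - S_mc) < 0.02, p.name


class TestApproximateSurrogate:
    def test_exact_at_cut_point(self, param_specs, rules5):
        design = mdrm.build_design(param_specs, 5, rules5)
        outputs = evaluate_design(design, lambda X: 10.0 + X[:, 2])
        h0 = outputs["run_000"]
        hhat = mdrm.mdrm_approximate(h0, design, rules5, outputs)
        c = np.array([p.nominal for p in param_specs])
        assert hhat(c) == pytest.approx(h0, rel=1e-12)

    def test_reproduces_multiplicative_function_at_design_points(
        self, param_specs, rules5
    ):
        def func(X):
            return np.prod(1.0 + 0.05 * (X - X.mean(0)), axis=1) + 1.0

        # truly multiplicative in each coordinate separately
        nominal = np.array([p.nominal for p in param_specs])

        def mult(X):
            out = np.ones(len(X))
            for i in range(7):
                out *= 1.0 + 0.1 * (X[:, i] - nominal[i])
            return 2.0 * out

        design = mdrm.build_design(param_specs, 5, rules5)
        outputs = evaluate_design(design, mult)
        hhat = mdrm.mdrm_approximate(outputs["run_000"], design, rules5, outputs)
        X = design.runs[list(design.parameters)].to_numpy(dtype=float)
        expect = mult(X)
        got = hhat(X)
        assert np.allclose(got, expect, rtol=1e-9)

    def test_additive_function_has_finite_model_error(self):
        specs = [std_normal_spec("x0"), std_normal_spec("x1")]
        design = mdrm.build_design(specs, 5)
        rules = [mdrm.quadrature_rule(s, 5) for s in specs]
        outputs = evaluate_design(design, lambda X: 10.0 + X[:, 0] + X[:, 1])
        hhat = mdrm.mdrm_approximate(outputs["run_000"], design, rules, outputs)
        g = np.linspace(-2, 2, 9)
        XX = np.array([(a, b) for a in g for b in g])
        err = np.abs(hhat(XX) - (10.0 + XX.sum(1))) / np.abs(10.0 + XX.sum(1))
        assert np.isfinite(err).all()
        assert err.max() > 0  # the multiplicative form is not exact off-axis

    def test_zero_h0_rejected(self, design5, rules5, design_metrics):
        outputs = design_metrics["head_peak_fwd"]
        with pytest.raises(ZeroDivisionError):
            mdrm.mdrm_approximate(0.0, design5, rules5, outputs)


class TestModelResultsInterface:
    def test_fit_returns_per_metric_results_with_summary(
        self, design5, rules5, design_metrics
    ):
        import pandas as pd

        outputs = pd.DataFrame(design_metrics)
        res = MDRMSensitivity(outputs, design5, rules5).fit()
        assert set(res.metrics) == set(design_metrics)
        ind = res.indices
        assert ind.shape == (7, 4)
        assert np.allclose(ind.sum(axis=0), 1.0, atol=1e-9)
        text = res.summary()
        assert "runs: 29" in text
        for p in design5.parameters:
            assert p in text

    def test_json_export(self, design5, rules5, design_metrics, tmp_path):
        import json
        import pandas as pd

        res = MDRMSensitivity(pd.DataFrame(design_metrics), design5, rules5).fit()
        p = tmp_path / "sens.json"
        res.to_json(p)
        payload = json.loads(p.read_text())
        assert set(payload) == set(design_metrics)
        for m in payload:
            assert set(payload[m]) == set(design5.parameters)
            total = sum(v["S"] for v in payload[m].values())
            assert total == pytest.approx(1.0, abs=1e-9)
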