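"""Regression model definitions: means, noise, likelihood, priors, IO."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats
from scipy.integrate import quad

from cellallometry.data import AllometryDataset, read_dataset, write_dataset
from cellallometry.fitness import ClosedFormCoefficients, capacity
from cellallometry.models import (
    ModelSpec,
    PRIORS,
    log_posterior,
    log_prior,
    mean_diminishing_returns,
    mean_double_power_law,
    params_from_json,
    params_to_json,
    pointwise_log_likelihood,
    sd_function,
)

DPL = dict(k0=-0.20, s_small=0.21, n_bp=4.82, s_large=0.07)


class TestModelSpec:
    def test_names_round_trip(self):
        for name in ("dpl_const", "dpl_var", "dr_const", "dr_var"):
            assert ModelSpec.from_name(name).name == name

    def test_param_ordering(self):
        assert ModelSpec("double_power_law", "variable").param_names == (
            "k0", "s_small", "n_bp", "s_large", "Sigma0", "s_Sigma",
        )

    def test_unknown_names_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec.from_name("power_law")
        with pytest.raises(ValueError):
            ModelSpec(mean_kind="cubic")


class TestMeanFunctions:
    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        k0=st.floats(-0.5, 0.5),
        s_small=st.floats(-5, 5),
        n_bp=st.floats(0, 14),
        s_large=st.floats(-5, 5),
    )
    def test_continuity_at_breakpoint(self, k0, s_small, n_bp, s_large):
        p = dict(k0=k0, s_small=s_small, n_bp=n_bp, s_large=s_large)
        below = p["k0"] + p["s_small"] * n_bp
        above = (p["k0"] + p["s_small"] * p["n_bp"]
                 + p["s_large"] * (n_bp - p["n_bp"]))
        assert below == pytest.approx(above, abs=1e-12)
        assert mean_double_power_law(n_bp, p) == pytest.approx(below, abs=1e-12)

    def test_equal_slopes_collapse_to_line(self):
        p = dict(k0=0.1, s_small=0.3, n_bp=5.0, s_large=0.3)
        n = np.linspace(-2, 14, 33)
        assert np.allclose(mean_double_power_law(n, p), 0.1 + 0.3 * n)

    def test_breakpoint_value_from_posterior_means(self):
        # at n = n_bp the fitted curve is k0 + s_small * n_bp
        assert mean_double_power_law(4.82, DPL) == \
            pytest.approx(-0.20 + 0.21 * 4.82, rel=1e-12)

    def test_diminishing_returns_values(self):
        assert mean_diminishing_returns(2.0, dict(A=-1.0, B=1.0)) == 0.0
        assert mean_diminishing_returns(2.0, dict(A=0.0, B=1.0)) == \
            pytest.approx(math.log10(2.0), rel=1e-15)
        assert mean_diminishing_returns(4.0, dict(A=-0.29, B=1.29)) == \
            pytest.approx(math.log10(-0.29 + 1.29 * 4.0), rel=1e-14)

    def test_domain_violation_is_nan(self):
        assert math.isnan(mean_diminishing_returns(0.1, dict(A=-1.0, B=1.0)))

    def test_matches_fitness_capacity(self):
        # regression mean == log10 of the fitness model's capacity line
        co = ClosedFormCoefficients(A=-0.29, B=1.29)
        n = np.linspace(1.0, 13.0, 25)
        assert np.allclose(
            mean_diminishing_returns(n, dict(A=co.A, B=co.B)),
            np.log10(capacity(10.0**n, co)),
        )


class TestSdFunction:
    def test_constant(self):
        assert sd_function(0.0, dict(Sigma=0.33)) == 0.33
        assert np.allclose(sd_function(np.arange(5.0), dict(Sigma=0.33)), 0.33)

    def test_linear(self):
        noise = dict(Sigma0=0.12, s_Sigma=0.03)
        assert sd_function(0.0, noise) == pytest.approx(0.12)
        assert sd_function(10.0, noise) == pytest.approx(0.42)


class TestLikelihood:
    def test_point_on_curve_standard_normal_mode(self, ):
        ds = AllometryDataset(N=np.array([100.0]), K=np.array([10.0]))
        # mean passes exactly through k=1 at n=2
        ll = pointwise_log_likelihood(
            ds, ModelSpec("diminishing_returns", "constant"),
            dict(A=0.0, B=5.0, Sigma=1.0),
        )
        assert ll[0] == pytest.approx(-0.5 * math.log(2 * math.pi), rel=1e-14)

    def test_duplicated_observation_doubles(self):
        ds1 = AllometryDataset(N=np.array([1e3, 1e6]), K=np.array([5.0, 20.0]))
        ds2 = AllometryDataset(
            N=np.array([1e3, 1e6, 1e6]), K=np.array([5.0, 20.0, 20.0])
        )
        p = dict(A=-0.3, B=1.3, Sigma=0.4)
        spec = ModelSpec("diminishing_returns", "constant")
        l1 = pointwise_log_likelihood(ds1, spec, p)
        l2 = pointwise_log_likelihood(ds2, spec, p)
        assert l2[2] == l2[1] == l1[1]
        assert l2.sum() == pytest.approx(l1.sum() + l1[1], rel=1e-14)

    def test_against_scipy_per_point_oracle(self, tiny_dataset):
        spec = ModelSpec("double_power_law", "variable")
        p = dict(k0=-0.2, s_small=0.25, n_bp=5.0, s_large=0.08,
                 Sigma0=0.12, s_Sigma=0.03)
        got = pointwise_log_likelihood(tiny_dataset, spec, p)
        for i, (n, k) in enumerate(zip(tiny_dataset.n, tiny_dataset.k)):
            mu = (p["k0"] + p["s_small"] * n if n < p["n_bp"]
                  else p["k0"] + p["s_small"] * p["n_bp"]
                  + p["s_large"] * (n - p["n_bp"]))
            sd = p["Sigma0"] + p["s_Sigma"] * n
            assert got[i] == pytest.approx(stats.norm.logpdf(k, mu, sd),
                                           rel=1e-12)
        assert got.sum() == pytest.approx(
            sum(float(x) for x in got), rel=1e-14
        )

    def test_domain_violation_gives_minus_inf(self, tiny_dataset):
        spec = ModelSpec("diminishing_returns", "constant")
        ll = pointwise_log_likelihood(
            tiny_dataset, spec, dict(A=-5.0, B=1.0, Sigma=0.3)
        )
        assert np.isneginf(ll[0])  # A + B*n < 0 at the smallest organism
        ll2 = pointwise_log_likelihood(
            tiny_dataset, spec, dict(A=0.5, B=1.0, Sigma=-0.1)
        )
        assert np.all(np.isneginf(ll2))

    def test_permutation_equivariance(self, tiny_dataset):
        spec = ModelSpec("diminishing_returns", "constant")
        p = dict(A=-0.3, B=1.3, Sigma=0.33)
        perm = np.array([4, 2, 0, 1, 3])
        shuffled = AllometryDataset(
            N=tiny_dataset.N[perm], K=tiny_dataset.K[perm]
        )
        l0 = pointwise_log_likelihood(tiny_dataset, spec, p)
        l1 = pointwise_log_likelihood(shuffled, spec, p)
        assert np.allclose(l1, l0[perm])
        assert l1.sum() == pytest.approx(l0.sum(), rel=1e-13)


class TestPrior:
    def test_outside_support_minus_inf(self):
        spec = ModelSpec("double_power_law", "constant")
        good = dict(k0=0.0, s_small=0.2, n_bp=5.0, s_large=0.1, Sigma=0.3)
        assert math.isfinite(log_prior(spec, good))
        assert log_prior(spec, {**good, "k0": 0.7}) == -np.inf
        assert log_prior(spec, {**good, "Sigma": -0.1}) == -np.inf

    def test_half_cauchy_closed_form(self):
        # half-Cauchy at its scale point: log(2) + Cauchy(0, 10) density at 10
        expected = math.log(2) + stats.cauchy(0, 10).logpdf(10.0)
        assert PRIORS["Sigma"].logpdf(10.0) == pytest.approx(expected, rel=1e-12)
        # and log_prior uses exactly that factor
        spec = ModelSpec("diminishing_returns", "constant")
        base = dict(A=0.0, B=1.0)
        lp = log_prior(spec, {**base, "Sigma": 10.0})
        assert lp == pytest.approx(
            PRIORS["A"].logpdf(0.0) + PRIORS["B"].logpdf(1.0) + expected,
            rel=1e-12,
        )

    def test_sum_of_mode_densities(self):
        spec = ModelSpec("double_power_law", "variable")
        point = dict(k0=0.0, s_small=0.0, n_bp=5.0, s_large=0.0,
                     Sigma0=0.01, s_Sigma=0.01)
        expected = sum(
            PRIORS[name].logpdf(point[name]) for name in spec.param_names
        )
        assert log_prior(spec, point) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("name,support", [
        ("k0", (-0.5, 0.5)),
        ("s_small", (-np.inf, np.inf)),
        ("n_bp", (-np.inf, np.inf)),
        ("Sigma", (0, np.inf)),
        ("Sigma0", (0, np.inf)),
    ])
    def test_each_prior_integrates_to_one(self, name, support):
        val, _ = quad(PRIORS[name].pdf, *support, limit=200)
        assert val == pytest.approx(1.0, abs=1e-6)


class TestPosterior:
    def test_additivity(self, tiny_dataset):
        spec = ModelSpec("diminishing_returns", "constant")
        p = dict(A=-0.3, B=1.3, Sigma=0.33)
        lp = log_posterior(tiny_dataset, spec, p)
        assert lp == pytest.approx(
            log_prior(spec, p)
            + pointwise_log_likelihood(tiny_dataset, spec, p).sum(),
            rel=1e-12,
        )

    def test_prior_violation_propagates(self, tiny_dataset):
        spec = ModelSpec("diminishing_returns", "constant")
        assert log_posterior(
            tiny_dataset, spec, dict(A=-0.3, B=1.3, Sigma=-1.0)
        ) == -np.inf

    def test_params_json_round_trip(self):
        p = dict(A=-0.29, B=1.29, Sigma=0.33)
        assert params_from_json(params_to_json(p)) == p


class TestDatasetIO:
    def test_constraints_enforced(self):
        with pytest.raises(ValueError, match="1 <= K <= N"):
            AllometryDataset(N=np.array([10.0]), K=np.array([20.0]))
        with pytest.raises(ValueError, match="1 <= K <= N"):
            AllometryDataset(N=np.array([10.0]), K=np.array([0.5]))

    def test_round_trip_and_autodetect(self, tmp_path, tiny_dataset):
        path = tmp_path / "data.csv"
        write_dataset(tiny_dataset, path)
        back = read_dataset(path)
        assert np.allclose(back.N, tiny_dataset.N, rtol=1e-12)
        assert np.allclose(back.k, tiny_dataset.k, rtol=1e-12)
        assert back.labels == list(tiny_dataset.labels)

        # nonstandard headers found by case-insensitive substring match
        txt = path.read_text().replace("cells", "Number of Cells").replace(
            "cell_types", "Cell TYPES"
        )
        path2 = tmp_path / "odd.csv"
        path2.write_text(txt)
        odd = read_dataset(path2)
        assert np.allclose(odd.N, tiny_dataset.N)

    def test_missing_columns_named_in_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("x,y\n1,2\n")
        with pytest.raises(ValueError, match="auto-detect"):
            read_dataset(path)
        with pytest.raises(ValueError, match="not found"):
            read_dataset(path, cells_col="cells", types_col="cell_types")

    def test_scientific_notation(self, tmp_path):
        path = tmp_path / "sci.csv"
        path.write_text("cells,cell_types\n1.0e6,4.2e1\n3e12,2.1e2\n")
        ds = read_dataset(path)
        assert ds.N[1] == 3e12 and ds.K[0] == 42.0
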