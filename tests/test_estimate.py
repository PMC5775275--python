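import numpy as np
import pandas as pd
import pytest

from asnkin import asn_model, assay_synth, estimate
from asnkin.estimate import (
    FitConfig,
    FittingError,
    fit_timecourse,
    hooke_jeeves,
    recovery_experiment,
    sse_objective,
)
from asnkin.netcore import Place, Reaction, ReactionNetwork


def make_dataset(rows, enzyme="TaASN1", time_points=None):
    df = pd.DataFrame(rows)
    return assay_synth.AssayDataset(
        enzyme=enzyme,
        time_points=np.sort(df["time_s"].unique().astype(float))
        if time_points is None
        else np.asarray(time_points, float),
        measurements=df,
        n_replicates=int(df["replicate"].nunique()),
    )


class TestHookeJeeves:
    def test_univariate_parabola(self):
        res = hooke_jeeves(lambda x: (x[0] - 3.0) ** 2, [0.0], [(-10, 10)],
                           initial_step=1.0)
        assert res.converged
        assert abs(res.estimates["0"] - 3.0) < 1e-4

    def test_anisotropic_quadratic_beats_grid(self):
        calls = {"n": 0}

        def f(x):
            calls["n"] += 1
            return x[0] ** 2 + 10.0 * x[1] ** 2

        res = hooke_jeeves(f, [5.0, 5.0], [(-10, 10)] * 2, initial_step=1.0,
                           stop_step=1e-5)
        assert abs(res.estimates["0"]) < 1e-3 and abs(res.estimates["1"]) < 1e-3
        # exhaustive grid at 1e-3 resolution over the same box would need
        # (20/1e-3)^2 = 4e8 evaluations
        assert calls["n"] < 4e8 and calls["n"] < 5000

    def test_monotone_function_pins_lower_bound(self):
        res = hooke_jeeves(lambda x: x[0], [1.5], [(1.0, 2.0)], initial_step=0.5)
        assert res.estimates["0"] == pytest.approx(1.0, abs=1e-4)

    def test_random_quadratics_reach_analytic_minimum(self):
        """Property: the pattern search solves PD quadratics to 1e-3."""
        rng = np.random.default_rng(2024)
        for _ in range(20):
            dim = rng.integers(1, 5)
            M = rng.normal(size=(dim, dim))
            A = M @ M.T + dim * np.eye(dim)
            b = rng.normal(size=dim)
            x_star = np.linalg.solve(A, -b)
            x_star = np.clip(x_star, -5, 5)

            def f(x, A=A, b=b):
                return 0.5 * x @ A @ x + b @ x

            res = hooke_jeeves(f, rng.uniform(-5, 5, dim).tolist(),
                               [(-10, 10)] * dim, initial_step=1.0,
                               stop_step=1e-6)
            got = np.array([res.estimates[str(i)] for i in range(dim)])
            assert np.max(np.abs(got - x_star)) < 1e-3

    def test_trace_best_so_far_non_increasing(self):
        res = hooke_jeeves(lambda x: (x[0] - 3.0) ** 2 + (x[1] + 1) ** 2,
                           [0.0, 0.0], [(-10, 10)] * 2, initial_step=1.0)
        values = [v for _, _, v in res.trace]
        assert all(a >= b for a, b in zip(values, values[1:]))

    def test_non_finite_at_start_raises(self):
        with pytest.raises(FittingError):
            hooke_jeeves(lambda x: np.nan, [0.0], [(-1, 1)])

    def test_non_finite_during_search_treated_as_inf(self):
        def f(x):
            return np.inf if x[0] > 0.5 else (x[0] - 0.4) ** 2

        res = hooke_jeeves(f, [0.0], [(-1, 1)], initial_step=0.3)
        assert abs(res.estimates["0"] - 0.4) < 1e-4

    def test_start_outside_bounds_rejected(self):
        with pytest.raises(ValueError):
            hooke_jeeves(lambda x: x[0] ** 2, [5.0], [(-1, 1)])

    def test_deterministic(self):
        f = lambda x: (x[0] - 1.234) ** 2
        a = hooke_jeeves(f, [0.0], [(-10, 10)])
        b = hooke_jeeves(f, [0.0], [(-10, 10)])
        assert a.estimates == b.estimates and a.n_evaluations == b.n_evaluations


class TestSseObjective:
    def test_toy_residual(self):
        """One time point, one species, model 2.0 vs observed 0.5 twice: 4.5."""
        net = ReactionNetwork(places=[Place("A", 2.0)], reactions=[])
        rows = [
            {"replicate": 1, "time_s": 10.0, "species": "A", "concentration": 0.5},
            {"replicate": 2, "time_s": 10.0, "species": "A", "concentration": 0.5},
        ]
        sse = sse_objective(net, {}, {"A": 2.0}, make_dataset(rows), n_grid=11)
        assert sse == pytest.approx(4.5)

    def test_self_data_near_zero(self, asn_net, taasn1):
        data = assay_synth.generate_assay_dataset("TaASN1", noise_cv=0.0, seed=0)
        state0 = asn_model.default_initial_state("TaASN1")
        sse = sse_objective(asn_net, taasn1.params.as_dict(), state0, data)
        assert sse < 1e-10

    def test_perturbing_k1_increases_sse(self, asn_net, taasn1):
        data = assay_synth.generate_assay_dataset("TaASN1", noise_cv=0.0, seed=0)
        state0 = asn_model.default_initial_state("TaASN1")
        base = sse_objective(asn_net, taasn1.params.as_dict(), state0, data)
        perturbed = dict(taasn1.params.as_dict())
        perturbed["k1"] *= 2.0
        assert sse_objective(asn_net, perturbed, state0, data) > base + 1e-4

    def test_empty_dataset_rejected(self, asn_net, taasn1):
        data = make_dataset(
            [{"replicate": 1, "time_s": 1.0, "species": "Asn", "concentration": 0.0}]
        )
        data.measurements = data.measurements.iloc[:0]
        with pytest.raises(ValueError):
            sse_objective(asn_net, taasn1.params.as_dict(),
                          asn_model.default_initial_state("TaASN1"), data)


class TestFitConfig:
    def test_overlapping_free_and_fixed(self):
        with pytest.raises(ValueError):
            FitConfig(free=("k1",), fixed={"k1": 1.0}, start={"k1": 1.0})

    def test_start_outside_bounds(self):
        with pytest.raises(ValueError):
            FitConfig(free=("k1",), fixed={}, start={"k1": 1e7})

    def test_no_free_parameters(self):
        with pytest.raises(ValueError):
            FitConfig(free=(), fixed={}, start={})


class TestRecovery:
    @pytest.mark.parametrize(
        "enzyme, truth",
        [("TaASN1", {"k1": 0.016, "kD": 700.0}),
         ("TaASN2", {"k1": 0.02, "kD": 400.0})],
    )
    def test_noiseless_recovery_of_fitted_constants(self, enzyme, truth):
        """Refitting noiseless self-simulated data returns the generating
        k1 and kD within 5% for both enzymes."""
        report = recovery_experiment(enzyme, noise_cv=0.0, seed=0)
        for name, value in truth.items():
            row = report["parameters"][name]
            assert row["true"] == value
            assert row["relative_error"] < 0.05

    def test_start_at_truth_stays_at_truth(self, asn_net, taasn1):
        data = assay_synth.generate_assay_dataset("TaASN1", noise_cv=0.0, seed=1)
        truth = taasn1.params.as_dict()
        config = FitConfig(
            free=("k1", "kD"),
            fixed={k: v for k, v in truth.items() if k not in ("k1", "kD")},
            start={"k1": truth["k1"], "kD": truth["kD"]},
        )
        result = fit_timecourse(data, asn_net, taasn1, config)
        assert result.estimates["k1"] == pytest.approx(truth["k1"], rel=1e-12)
        assert result.estimates["kD"] == pytest.approx(truth["kD"], rel=1e-12)

    def test_result_beats_start(self, asn_net, taasn1):
        data = assay_synth.generate_assay_dataset("TaASN1", noise_cv=0.0, seed=2,
                                                  time_points=np.linspace(100, 2100, 20))
        truth = taasn1.params.as_dict()
        config = FitConfig(
            free=("k1", "kD"),
            fixed={k: v for k, v in truth.items() if k not in ("k1", "kD")},
            start={"k1": truth["k1"] * 3, "kD": truth["kD"] * 3},
        )
        result = fit_timecourse(data, asn_net, taasn1, config)
        state0 = asn_model.default_initial_state("TaASN1")
        start_params = dict(config.fixed)
        start_params.update(config.start)
        start_sse = sse_objective(asn_net, start_params, state0, data)
        assert result.objective <= start_sse
        values = [v for _, _, v in result.trace]
        assert all(a >= b for a, b in zip(values, values[1:]))

    def test_same_seed_identical_report(self):
        a = recovery_experiment("TaASN1", n_points=20, noise_cv=0.02, seed=7)
        b = recovery_experiment("TaASN1", n_points=20, noise_cv=0.02, seed=7)
        assert a == b

    def test_noise_degrades_recovery_gracefully(self):
        """Median k1 relative error grows with 5% measurement noise but
        stays below 25%."""
        noiseless = recovery_experiment("TaASN1", n_points=20, noise_cv=0.0, seed=0)
        errors = []
        for seed in range(10):
            rep = recovery_experiment("TaASN1", n_points=20, noise_cv=0.05,
                                      seed=seed)
            errors.append(rep["parameters"]["k1"]["relative_error"])
        median = float(np.median(errors))
        assert median > noiseless["parameters"]["k1"]["relative_error"]
        assert median < 0.25
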