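"""Kinetic fitters: exactness on noise-free data, recovery under noise,
row-order invariance, and agreement with a refined grid-search oracle."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gatekin.kinetics import (
    ModelMismatchError,
    fit_michaelis_menten,
    fit_ph_profile,
    fit_saturation,
    fit_transient,
    read_concentration_table,
)
from gatekin.synthetic import (
    SyntheticKineticsSpec,
    exponential_trace,
    generate_kinetic_dataset,
    hyperbolic_kobs,
    michaelis_menten_rate,
    ph_profile_value,
)


def grid_search(loss, bounds, n=15, refinements=2):
    """Coarse grid over parameter boxes, refined around the best point."""
    bounds = [list(b) for b in bounds]
    best = None
    for _ in range(refinements + 1):
        axes = [np.linspace(lo, hi, n) for lo, hi in bounds]
        mesh = np.meshgrid(*axes, indexing="ij")
        flat = np.stack([m.ravel() for m in mesh], axis=1)
        losses = np.array([loss(p) for p in flat])
        best = flat[np.argmin(losses)]
        bounds = [
            (max(lo, b - (hi - lo) / n), min(hi, b + (hi - lo) / n))
            for (lo, hi), b in zip(bounds, best)
        ]
    return best


class TestTransient:
    def test_exact_on_noise_free_trace(self):
        spec = SyntheticKineticsSpec(noise_sd=0.0, kobs=50.0, amplitude=0.1, offset=0.05)
        fit = fit_transient(generate_kinetic_dataset(spec, "trace"))
        assert fit.kobs == pytest.approx(50.0, rel=1e-6)
        assert fit.amplitude == pytest.approx(0.1, rel=1e-6)
        assert fit.offset == pytest.approx(0.05, rel=1e-6)

    def test_mean_kobs_within_two_percent_at_five_percent_noise(self):
        recovered = []
        for seed in range(20):
            spec = SyntheticKineticsSpec(noise_sd=0.05, seed=seed)
            recovered.append(fit_transient(generate_kinetic_dataset(spec, "trace")).kobs)
        assert np.mean(recovered) == pytest.approx(50.0, rel=0.02)

    def test_constant_trace_rejected(self):
        df = pd.DataFrame({"time_s": np.linspace(0, 1, 50), "A445": np.full(50, 0.2)})
        with pytest.raises(ModelMismatchError):
            fit_transient(df)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        kobs=st.floats(1.0, 500.0),
        B=st.floats(0.01, 0.5),
        C=st.floats(0.0, 0.2),
    )
    def test_exact_recovery_over_parameter_sweep(self, kobs, B, C):
        t = np.linspace(0, 5.0 / kobs, 60)
        df = pd.DataFrame({"time_s": t, "A445": exponential_trace(t, kobs, B, C)})
        fit = fit_transient(df)
        assert fit.kobs == pytest.approx(kobs, rel=1e-6)


class TestSaturation:
    def test_exact_recovery_and_krev_dropped(self):
        spec = SyntheticKineticsSpec(noise_sd=0.0, kred=32.0, Kd=8e-4, krev=0.0)
        fit = fit_saturation(generate_kinetic_dataset(spec, "saturation"))
        assert fit.kred == pytest.approx(32.0, rel=1e-6)
        assert fit.Kd == pytest.approx(8e-4, rel=1e-4)
        assert not fit.krev_retained

    def test_significant_intercept_retained(self):
        S = np.array([1e-4, 3e-4, 8e-4, 2e-3, 5e-3, 1e-2])
        rng = np.random.default_rng(0)
        kobs = hyperbolic_kobs(S, 30.0, 8e-4, 5.0) * (1 + rng.normal(0, 0.01, S.size))
        fit = fit_saturation(pd.DataFrame({"S": S, "kobs": kobs}))
        assert fit.krev_retained
        assert fit.krev == pytest.approx(5.0, rel=0.2)

    def test_half_saturation_point(self):
        fit = fit_saturation(
            generate_kinetic_dataset(SyntheticKineticsSpec(noise_sd=0.0), "saturation")
        )
        assert fit.predict(fit.Kd) == pytest.approx(fit.kred / 2 + fit.krev)

    def test_mean_kred_within_five_percent_at_five_percent_noise(self):
        recovered = [
            fit_saturation(
                generate_kinetic_dataset(
                    SyntheticKineticsSpec(noise_sd=0.05, seed=s), "saturation"
                )
            ).kred
            for s in range(20)
        ]
        assert np.mean(recovered) == pytest.approx(32.0, rel=0.05)

    def test_row_order_invariance(self):
        df = generate_kinetic_dataset(
            SyntheticKineticsSpec(noise_sd=0.05, seed=1), "saturation"
        )
        shuffled = df.sample(frac=1.0, random_state=3).reset_index(drop=True)
        a, b = fit_saturation(df), fit_saturation(shuffled)
        assert a.kred == pytest.approx(b.kred, rel=1e-9)
        assert a.Kd == pytest.approx(b.Kd, rel=1e-9)

    def test_kd_outside_range_flagged(self):
        S = np.array([1e-5, 2e-5, 3e-5, 4e-5])  # far below Kd: no curvature
        kobs = hyperbolic_kobs(S, 32.0, 8e-4)
        fit = fit_saturation(pd.DataFrame({"S": S, "kobs": kobs}))
        assert not fit.Kd_reliable

    def test_grid_search_oracle_agreement(self):
        rng = np.random.default_rng(8)
        for _ in range(5):
            kred, Kd = rng.uniform(10, 100), 10 ** rng.uniform(-4, -2.5)
            S = Kd * np.array([0.25, 0.5, 1, 2, 4, 8])
            df = pd.DataFrame({"S": S, "kobs": hyperbolic_kobs(S, kred, Kd)})
            fit = fit_saturation(df, allow_intercept=False)

            def loss(p):
                return np.sum((hyperbolic_kobs(S, p[0], p[1]) - df["kobs"]) ** 2)

            best = grid_search(loss, [(1.0, 200.0), (Kd / 10, Kd * 10)], n=25)
            # grid resolution: oracle optimum within a few percent
            assert fit.kred == pytest.approx(best[0], rel=0.05)
            assert fit.Kd == pytest.approx(best[1], rel=0.15)


class TestPHProfile:
    def test_exact_one_pka_recovery(self):
        spec = SyntheticKineticsSpec(noise_sd=0.0, ph_limit=32.0, pKa=9.5)
        fit = fit_ph_profile(generate_kinetic_dataset(spec, "ph_profile"))
        assert fit.pKa == pytest.approx(9.5, abs=1e-6)
        assert fit.limit == pytest.approx(32.0, rel=1e-6)

    def test_value_at_pka_is_half_limit(self):
        fit = fit_ph_profile(
            generate_kinetic_dataset(
                SyntheticKineticsSpec(noise_sd=0.0), "ph_profile"
            )
        )
        assert fit.predict(fit.pKa) == pytest.approx(fit.limit / 2)

    def test_two_pka_model_recovery(self):
        pH = np.linspace(6.0, 9.5, 12)
        y = ph_profile_value(pH, 500_000.0, 7.4, 2)
        fit = fit_ph_profile(pd.DataFrame({"pH": pH, "value": y}), model="two_pka")
        assert fit.pKa == pytest.approx(7.4, abs=1e-6)
        assert fit.limit == pytest.approx(500_000.0, rel=1e-6)

    def test_noisy_two_pka_within_interval(self):
        rng = np.random.default_rng(5)
        pH = np.linspace(6.0, 9.5, 12)
        y = ph_profile_value(pH, 500_000.0, 7.4, 2) * (1 + rng.normal(0, 0.05, pH.size))
        fit = fit_ph_profile(pd.DataFrame({"pH": pH, "value": y}), model="two_pka")
        assert abs(fit.pKa - 7.4) < 3 * max(fit.stderr["pKa"], 0.02)

    def test_slope_plus_one_and_plus_two_limbs(self):
        # rising limb slope in log10 space distinguishes the two models
        pH = np.array([5.0, 5.5, 6.0])  # far below pKa = 9
        one = np.diff(np.log10(ph_profile_value(pH, 10.0, 9.0, 1))) / 0.5
        two = np.diff(np.log10(ph_profile_value(pH, 10.0, 9.0, 2))) / 0.5
        assert np.allclose(one, 1.0, atol=1e-3)
        assert np.allclose(two, 2.0, atol=1e-3)


class TestMichaelisMenten:
    def test_exact_recovery(self):
        spec = SyntheticKineticsSpec(noise_sd=0.0, kcat=11.0, Km=11.0 / 2900.0)
        fit = fit_michaelis_menten(generate_kinetic_dataset(spec, "initial_rates"))
        assert fit.kcat == pytest.approx(11.0, rel=1e-6)
        assert fit.kcat_over_Km == pytest.approx(2900.0, rel=1e-6)

    def test_rate_at_km_is_half_kcat(self):
        fit = fit_michaelis_menten(
            generate_kinetic_dataset(
                SyntheticKineticsSpec(noise_sd=0.0), "initial_rates"
            )
        )
        assert fit.predict(fit.Km) == pytest.approx(fit.kcat / 2)

    def test_mean_kcat_within_five_percent_at_five_percent_noise(self):
        recovered = [
            fit_michaelis_menten(
                generate_kinetic_dataset(
                    SyntheticKineticsSpec(noise_sd=0.05, seed=s), "initial_rates"
                )
            ).kcat
            for s in range(20)
        ]
        assert np.mean(recovered) == pytest.approx(11.0, rel=0.05)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(kcat=st.floats(0.5, 500.0), km_exp=st.floats(-4.5, -2.0))
    def test_exact_recovery_over_parameter_sweep(self, kcat, km_exp):
        Km = 10.0**km_exp
        S = Km * np.array([0.2, 0.5, 1.0, 2.0, 5.0, 10.0])
        df = pd.DataFrame({"S": S, "v_over_E": michaelis_menten_rate(S, kcat, Km)})
        fit = fit_michaelis_menten(df)
        assert fit.kcat == pytest.approx(kcat, rel=1e-6)
        assert fit.Km == pytest.approx(Km, rel=1e-5)


class TestUnits:
    def test_mM_column_converted(self):
        df = pd.DataFrame({"S": [0.2, 0.4], "S_unit": ["mM", "mM"], "kobs": [1.0, 2.0]})
        out = read_concentration_table(df, "kobs")
        assert np.allclose(out["S"], [2e-4, 4e-4])

    def test_explicit_unit_flag(self):
        df = pd.DataFrame({"S": [100.0], "v_over_E": [3.0]})
        out = read_concentration_table(df, "v_over_E", unit="uM")
        assert out["S"].iloc[0] == pytest.approx(1e-4)

    def test_unknown_unit_rejected(self):
        df = pd.DataFrame({"S": [1.0], "S_unit": ["furlongs"], "kobs": [1.0]})
        with pytest.raises(ValueError):
            read_concentration_table(df, "kobs")
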