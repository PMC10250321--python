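"""Hertz spherical indentation: reduction, contact detection, modulus fit."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import optimize

from cellmech import (
    DomainError,
    HertzContactModel,
    IndentationCurve,
    InstrumentConfig,
    InsufficientDataError,
    NoContactError,
    NoiseSpec,
    aggregate_moduli,
    detect_contact_point,
    fit_hertz,
    hertz_force,
    reduce_raw,
    simulate_indentation,
    young_from_reduced,
)


class TestHertzForce:
    def test_hand_computed_value(self):
        # (4/3)*1000*sqrt(4.5e-6)*(2e-6)^{3/2} = 8.0 nN
        assert hertz_force(1000.0, 4.5e-6, 2e-6) == pytest.approx(8.0e-9, rel=1e-12)

    def test_zero_depth_zero_force(self):
        assert hertz_force(1721.0, 9e-6, 0.0) == 0.0

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        e=st.floats(min_value=10, max_value=1e5),
        r=st.floats(min_value=1e-7, max_value=1e-4),
        d=st.floats(min_value=1e-9, max_value=1e-5),
    )
    def test_three_halves_power_scaling(self, e, r, d):
        assert hertz_force(e, r, 2 * d) == pytest.approx(
            2 ** 1.5 * hertz_force(e, r, d), rel=1e-12
        )

    def test_negative_depth_rejected(self):
        with pytest.raises(DomainError):
            hertz_force(1000.0, 9e-6, -1e-7)


class TestReduceRaw:
    def test_zero_deflection_baseline(self):
        z = np.linspace(0, 5e-6, 50)
        raw = IndentationCurve(mode="raw", x=z, y=np.zeros(50))
        red = reduce_raw(raw)
        assert np.all(red.y == 0)
        assert np.allclose(red.x, z)

    def test_spring_constant_scaling(self):
        # d = 100 nm at k = 0.048 N/m -> F = 4.8 nN
        z = np.linspace(0, 5e-6, 30)
        d = np.full(30, 100e-9)
        red = reduce_raw(IndentationCurve(mode="raw", x=z, y=d))
        assert red.y[0] == pytest.approx(4.8e-9, rel=1e-12)

    def test_round_trip_from_synthetic_raw(self):
        reduced = simulate_indentation(1721.0)
        raw = simulate_indentation(1721.0, as_raw=True)
        again = reduce_raw(raw)
        assert np.allclose(again.x, reduced.x, atol=1e-18)
        assert np.allclose(again.y, reduced.y, atol=1e-24)

    def test_idempotent_on_reduced(self):
        red = simulate_indentation(1721.0)
        with warnings.catch_warnings(record=True) as w:
            warnings.simplefilter("always")
            again = reduce_raw(red)
        assert len(w) == 1
        assert again is red


class TestContactDetection:
    def test_exact_index_on_noiseless_curve(self, noiseless_curve):
        c, b = detect_contact_point(noiseless_curve)
        assert c == noiseless_curve.meta["contact_index"]
        assert b == pytest.approx(0.0, abs=1e-18)

    def test_pure_noise_raises_no_contact(self):
        rng = np.random.default_rng(11)
        curve = IndentationCurve(
            mode="reduced",
            x=np.linspace(0, 5e-6, 120),
            y=rng.normal(0, 1e-9, 120),
        )
        with pytest.raises(NoContactError):
            detect_contact_point(curve)

    def test_noisy_localisation_rate(self):
        """2% load noise (multiplicative, the module's load-noise protocol):
        detected index within +/-2 samples of truth in >= 95% of 100 seeded
        replicates."""
        rng = np.random.default_rng(314)
        noise = NoiseSpec(kind="multiplicative_gaussian", scale=0.02)
        hits = 0
        for _ in range(100):
            curve = simulate_indentation(1721.0, noise=noise, rng=rng)
            c, _ = detect_contact_point(curve)
            if abs(c - curve.meta["contact_index"]) <= 2:
                hits += 1
        assert hits >= 95


class TestHertzFitting:
    def test_noiseless_round_trip_at_control_modulus(self, noiseless_curve):
        fit = fit_hertz(noiseless_curve)
        assert fit.converged
        assert fit.e_reduced == pytest.approx(1721.0, rel=1e-3)

    def test_linearised_fit_matches_nonlinear_oracle(self, noiseless_curve):
        fit = fit_hertz(noiseless_curve)
        c = fit.contact_index
        depth = noiseless_curve.x[c:] - noiseless_curve.x[c]
        load = noiseless_curve.y[c:] - fit.baseline_force

        def model(d, e):
            return (4.0 / 3.0) * e * np.sqrt(9e-6) * d ** 1.5

        popt, _ = optimize.curve_fit(model, depth, load, p0=[500.0])
        assert fit.e_reduced == pytest.approx(popt[0], rel=1e-9)

    def test_load_scaling_linearity(self, noiseless_curve):
        doubled = IndentationCurve(
            mode="reduced", x=noiseless_curve.x, y=2 * noiseless_curve.y,
            instrument=noiseless_curve.instrument,
        )
        assert fit_hertz(doubled).e_reduced == pytest.approx(
            2 * fit_hertz(noiseless_curve).e_reduced, rel=1e-9
        )

    def test_depth_scaling_power_law(self):
        # scaling depths x2 at fixed loads divides E by 2^{3/2}
        base = simulate_indentation(1721.0, baseline_points=0, contact_offset=0.0)
        stretched = IndentationCurve(
            mode="reduced", x=2 * base.x, y=base.y, instrument=base.instrument
        )
        f0 = fit_hertz(base, contact=(0, 0.0))
        f1 = fit_hertz(stretched, contact=(0, 0.0))
        assert f1.e_reduced == pytest.approx(f0.e_reduced / 2 ** 1.5, rel=1e-9)

    def test_insufficient_post_contact_points(self):
        x = np.linspace(0, 5e-6, 40)
        y = np.concatenate([np.zeros(37), np.array([1e-9, 2e-9, 3e-9])])
        curve = IndentationCurve(mode="reduced", x=x, y=y)
        with pytest.raises(InsufficientDataError):
            fit_hertz(curve, contact=(37, 0.0))

    def test_contact_mislocation_bias_is_monotone(self, noiseless_curve):
        """Shifting the assumed contact later by s samples on a noiseless
        curve biases the modulus upward, monotonically in s."""
        truth = noiseless_curve.meta["contact_index"]
        mods = [
            fit_hertz(noiseless_curve, contact=(truth + s, 0.0)).e_reduced
            for s in (0, 2, 4, 8)
        ]
        assert all(b > a for a, b in zip(mods, mods[1:]))

    def test_full_pipeline_recovery_under_noise(self):
        """simulate -> detect -> fit recovers the modulus within 5% at 3%
        load noise (median over 100 seeded curves)."""
        rng = np.random.default_rng(99)
        noise = NoiseSpec(kind="multiplicative_gaussian", scale=0.03)
        errs = []
        for _ in range(100):
            curve = simulate_indentation(1721.0, noise=noise, rng=rng)
            fit = fit_hertz(curve)
            errs.append(abs(fit.e_reduced / 1721.0 - 1))
        assert np.median(errs) < 0.05

    def test_estimator_interface(self, noiseless_curve):
        m = HertzContactModel(tip_radius=9e-6).fit(noiseless_curve.x, noiseless_curve.y)
        assert m.e_reduced_ == pytest.approx(1721.0, rel=1e-3)
        pred = m.predict(noiseless_curve.x)
        assert np.allclose(pred, noiseless_curve.y, atol=1e-12)
        assert m.get_params()["tip_radius"] == 9e-6


class TestYoungConversion:
    def test_incompressible_default(self):
        assert young_from_reduced(1000.0) == pytest.approx(750.0)


class TestAggregation:
    def _fits(self, values, converged=True):
        from cellmech import HertzFit

        return [
            HertzFit(e_reduced=v, contact_index=0, baseline_force=0.0,
                     residual_rms=0.0, converged=converged)
            for v in values
        ]

    def test_single_fit_sem_flagged(self):
        out = aggregate_moduli(self._fits([1721.0]), ["a"])
        assert out.loc[0, "mean_pa"] == 1721.0
        assert np.isnan(out.loc[0, "sem_pa"])

    def test_sampled_cohort_mean_near_truth(self):
        rng = np.random.default_rng(1)
        vals = 1721.0 * rng.lognormal(-0.005, 0.1, 25)
        out = aggregate_moduli(self._fits(list(vals)), ["g"] * 25)
        sem = out.loc[0, "sem_pa"]
        assert abs(out.loc[0, "mean_pa"] - 1721.0) < 2 * sem

    def test_identical_groups_identical_rows(self):
        fits = self._fits([1000.0, 1100.0]) * 2
        labels = ["a", "a", "b", "b"]
        out = aggregate_moduli(fits, labels)
        assert out.loc[0, ["n", "mean_pa", "sem_pa"]].tolist() == \
            out.loc[1, ["n", "mean_pa", "sem_pa"]].tolist()

    def test_non_converged_excluded_and_counted(self):
        fits = self._fits([1000.0]) + self._fits([9999.0], converged=False)
        out = aggregate_moduli(fits, ["a", "a"])
        assert out.loc[0, "n"] == 1
        assert out.loc[0, "n_excluded"] == 1
        assert out.loc[0, "mean_pa"] == 1000.0
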