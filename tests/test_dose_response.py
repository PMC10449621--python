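"""Hill model: forward/inverse algebra, fitting, titers, yield conversions."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from guvquant import (
    AssayConfig,
    HillParams,
    estimate_titer,
    fit_curve,
    hill_forward,
    hill_inverse,
    simulate_dose_response,
    simulate_unknown_titer,
    yield_per_inner_solution,
)
from guvquant.dose_response import FitError, TiterRangeError

TRUTH = HillParams(a=3.6, b=1.0, ec50=1.0e-9, h=1.38)


class TestHillForward:
    def test_midpoint_is_half_maximal(self):
        params = HillParams(a=100.0, b=10.0, ec50=3e-9, h=2.2)
        assert hill_forward(params, 3e-9) == pytest.approx(55.0)

    def test_zero_concentration_gives_basal(self):
        assert hill_forward(TRUTH, 0.0) == TRUTH.b

    def test_standard_hill_point(self):
        """a=1, b=0, EC50=1 nM, h=1 at 10 nM -> 10/11."""
        params = HillParams(a=1.0, b=0.0, ec50=1e-9, h=1.0)
        assert hill_forward(params, 10e-9) == pytest.approx(10.0 / 11.0, rel=1e-9)

    def test_saturation_approaches_maximum(self):
        assert hill_forward(TRUTH, 1.0) == pytest.approx(TRUTH.a, rel=1e-6)

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            hill_forward(TRUTH, -1e-9)


class TestHillInverse:
    def test_midpoint_inverts_to_ec50(self):
        assert hill_inverse(TRUTH, (TRUTH.a + TRUTH.b) / 2) == pytest.approx(TRUTH.ec50)

    def test_worked_inverse_point(self):
        params = HillParams(a=1.0, b=0.0, ec50=1e-9, h=1.0)
        assert hill_inverse(params, 10.0 / 11.0) == pytest.approx(10e-9, rel=1e-9)

    def test_out_of_range_fluorescence_rejected(self):
        with pytest.raises(ValueError):
            hill_inverse(TRUTH, TRUTH.b)
        with pytest.raises(ValueError):
            hill_inverse(TRUTH, TRUTH.a * 1.01)

    @given(frac=st.floats(min_value=1e-6, max_value=1 - 1e-6))
    def test_roundtrip_identity(self, frac):
        y = TRUTH.b + frac * (TRUTH.a - TRUTH.b)
        x = hill_inverse(TRUTH, y)
        assert hill_forward(TRUTH, x) == pytest.approx(y, rel=1e-9)


class TestFitCurve:
    def test_noise_free_recovery_to_1e_4(self):
        cfg = AssayConfig(true_params=TRUTH, noise_cv=0.0, rng_seed=0)
        plate, _ = simulate_dose_response(cfg)
        params = fit_curve(plate).mean_params
        assert params.a == pytest.approx(TRUTH.a, rel=1e-4)
        assert params.b == pytest.approx(TRUTH.b, rel=1e-4)
        assert params.ec50 == pytest.approx(TRUTH.ec50, rel=1e-4)
        assert params.h == pytest.approx(TRUTH.h, rel=1e-4)

    def test_recovered_hill_coefficient_ordering(self):
        """Noise-free fits preserve the 1.38 vs 1.41 steepness ordering."""
        fits = {}
        for h in (1.38, 1.41):
            truth = HillParams(a=3.6, b=1.0, ec50=1e-9, h=h)
            plate, _ = simulate_dose_response(
                AssayConfig(true_params=truth, noise_cv=0.0, rng_seed=0)
            )
            fits[h] = fit_curve(plate).summary["h_mean"]
        assert fits[1.38] == pytest.approx(1.38, rel=1e-6)
        assert fits[1.41] == pytest.approx(1.41, rel=1e-6)
        assert fits[1.38] < fits[1.41]

    def test_per_replicate_summary_structure(self):
        cfg = AssayConfig(true_params=TRUTH, noise_cv=0.05, rng_seed=3)
        curve = fit_curve(simulate_dose_response(cfg)[0])
        assert len(curve.per_replicate) == 3
        assert curve.summary["n_replicates"] == 3
        assert curve.summary["ec50_sd"] >= 0
        assert all(f.converged for f in curve.per_replicate)

    def test_flat_data_rejected(self):
        import pandas as pd

        plate = pd.DataFrame(
            {
                "concentration_molar": [1e-9 * 10**k for k in range(6)],
                "fluorescence": [2.0] * 6,
                "replicate": [1] * 6,
            }
        )
        with pytest.raises(FitError, match="flat|unidentifiable"):
            fit_curve(plate)

    def test_too_few_concentrations_rejected(self):
        import pandas as pd

        plate = pd.DataFrame(
            {
                "concentration_molar": [1e-9, 1e-8, 1e-7] * 2,
                "fluorescence": [1.1, 2.0, 3.3, 1.0, 2.1, 3.4],
                "replicate": [1] * 6,
            }
        )
        with pytest.raises(FitError, match="5 distinct"):
            fit_curve(plate)


class TestEstimateTiter:
    def test_noise_free_roundtrip_recovers_stock(self):
        stock = 458.5e-9
        plate, _ = simulate_unknown_titer(stock, [200, 2000], TRUTH, noise_cv=0.0)
        est = estimate_titer(plate, TRUTH)
        assert est.stock_geomean == pytest.approx(stock, rel=1e-6)
        assert est.n_usable == len(plate)

    def test_estimate_invariant_to_choice_of_in_range_dilution(self):
        stock = 458.5e-9
        plate, _ = simulate_unknown_titer(stock, [200, 2000], TRUTH, noise_cv=0.0)
        per_dilution = [
            estimate_titer(plate[plate.dilution_factor == d], TRUTH).stock_geomean
            for d in (200.0, 2000.0)
        ]
        assert per_dilution[0] == pytest.approx(per_dilution[1], rel=1e-6)

    def test_all_saturated_raises_with_flags(self):
        plate, _ = simulate_unknown_titer(63.2e-6, [200, 2000], TRUTH, noise_cv=0.0)
        with pytest.raises(TiterRangeError, match="saturated"):
            estimate_titer(plate, TRUTH)

    def test_scale_equivariance(self):
        """Halving stock and dilution factors together keeps each well's
        assay concentration (hence fluorescence) fixed while the pooled
        stock estimate halves."""
        stock = 400e-9
        a, _ = simulate_unknown_titer(stock, [200, 2000], TRUTH, noise_cv=0.0)
        b, _ = simulate_unknown_titer(stock / 2, [100, 1000], TRUTH, noise_cv=0.0)
        np.testing.assert_allclose(a.fluorescence, b.fluorescence)
        est_a = estimate_titer(a, TRUTH).stock_geomean
        est_b = estimate_titer(b, TRUTH).stock_geomean
        assert est_b == pytest.approx(est_a / 2, rel=1e-9)

    def test_below_range_wells_flagged(self):
        plate, _ = simulate_unknown_titer(1e-12, [200, 2000], TRUTH, noise_cv=0.0)
        with pytest.raises(TiterRangeError, match="below"):
            estimate_titer(plate, TRUTH)


class TestYieldConversion:
    def test_vesicle_sample_yield(self):
        """458.5 nM in 25 ul with 5 ul inner solution -> ~2.29 pmol/ul."""
        value = yield_per_inner_solution(458.5, 25.0, 5.0)
        assert value == pytest.approx(2.2925)
        assert abs(round(value, 2) - 2.28) <= 0.01 + 1e-12

    def test_reduced_osmolarity_yield(self):
        assert round(yield_per_inner_solution(32.5, 25.0, 5.0), 2) == 0.16

    def test_bulk_micromolar_identity(self):
        """Equal volumes: 17.9 uM == 17.9 pmol/ul."""
        assert yield_per_inner_solution(17.9e3, 25.0, 25.0) == pytest.approx(17.9)

    def test_zero_concentration_gives_zero(self):
        assert yield_per_inner_solution(0.0, 25.0, 5.0) == 0.0

    def test_nonpositive_volume_rejected(self):
        with pytest.raises(ValueError):
            yield_per_inner_solution(10.0, 0.0, 5.0)
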