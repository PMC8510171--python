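"""Headspace mole balance, cumulative decoding and per-vial metrics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bmpkit.gas_kinetics import (
    GAS_CONSTANT,
    MOLAR_VOLUME_NTP_ML,
    HeadspaceObservation,
    MethaneProductionSeries,
    VialSpec,
    cod_removal_efficiency,
    cumulative_methane,
    interval_methane_moles,
    latency_phase,
    methane_production_rate,
    methane_yield,
    theoretical_bmp,
)
from bmpkit.simulate import default_vial, encode_headspace


def vent_oracle_moles(p_atm, p_hs, v_hs, temp, x_prev, x_curr):
    """Independent mole-balance oracle: track total and CH4 moles explicitly
    through the vent event (headspace returns to p_atm at composition x_prev)."""
    rt = GAS_CONSTANT * temp
    ch4_after_vent = x_prev * p_atm * v_hs / rt
    total_now = (p_atm + p_hs) * v_hs / rt
    ch4_now = x_curr * total_now
    return ch4_now - ch4_after_vent


class TestIntervalMoles:
    @pytest.mark.parametrize(
        "p_hs, x_prev, x_curr",
        [
            (20_000.0, 0.0, 0.0),  # no methane present at either time
            (0.0, 0.3, 0.3),  # zero overpressure, unchanged fraction
            (20_000.0, 0.40, 0.50),  # production against a vented baseline
            (5_000.0, 0.6, 0.55),  # apparent consumption (noise) -> negative
        ],
    )
    def test_matches_vent_oracle(self, vial, p_hs, x_prev, x_curr):
        prev = HeadspaceObservation(0.0, 0.0, x_prev)
        curr = HeadspaceObservation(1.0, p_hs, x_curr)
        expected = vent_oracle_moles(
            vial.atmospheric_pressure, p_hs, vial.headspace_volume, vial.temperature, x_prev, x_curr
        )
        assert interval_methane_moles(prev, curr, vial) == pytest.approx(expected, abs=1e-18)

    def test_trivial_cases_are_zero(self, vial):
        zero = interval_methane_moles(
            HeadspaceObservation(0.0, 0.0, 0.0), HeadspaceObservation(1.0, 20_000.0, 0.0), vial
        )
        assert zero == 0.0
        flat = interval_methane_moles(
            HeadspaceObservation(0.0, 0.0, 0.3), HeadspaceObservation(1.0, 0.0, 0.3), vial
        )
        assert flat == pytest.approx(0.0, abs=1e-18)

    def test_reference_magnitude(self, vial):
        # 20 kPa overpressure, fraction 0.40 -> 0.50 in a 28.6 ml headspace at 37 degC
        moles = interval_methane_moles(
            HeadspaceObservation(0.0, 0.0, 0.40),
            HeadspaceObservation(1.0, 20_000.0, 0.50),
            vial,
        )
        assert moles == pytest.approx(2.233e-4, rel=1e-3)

    def test_rejects_bad_inputs(self, vial):
        good = HeadspaceObservation(1.0, 0.0, 0.1)
        with pytest.raises(ValueError, match="time-ordered"):
            interval_methane_moles(good, HeadspaceObservation(0.5, 0.0, 0.1), vial)
        with pytest.raises(ValueError, match="belongs to vial"):
            interval_methane_moles(
                HeadspaceObservation(0.0, 0.0, 0.1, vial_id="other"), good, vial
            )
        with pytest.raises(ValueError, match="non-finite"):
            HeadspaceObservation(0.0, float("nan"), 0.1)


class TestCumulative:
    def test_zero_state_series(self, vial):
        obs = [HeadspaceObservation(0.0, 0.0, 0.0), HeadspaceObservation(1.0, 0.0, 0.0)]
        series = cumulative_methane(obs, vial)
        assert series.cumulative_ntp_ml == pytest.approx([0.0, 0.0])
        assert series.interval_moles[0] == 0.0

    def test_one_mol_is_ntp_molar_volume(self):
        # R * 273 / 101325 m^3/mol = 22,400.4 ml/mol
        assert MOLAR_VOLUME_NTP_ML == pytest.approx(22_400.4, abs=1.0)

    def test_requires_two_sorted_observations(self, vial):
        with pytest.raises(ValueError, match="at least 2"):
            cumulative_methane([HeadspaceObservation(0.0, 0.0, 0.0)], vial)
        obs = [HeadspaceObservation(t, 0.0, 0.0) for t in (0.0, 2.0)]
        with pytest.raises(ValueError, match="strictly increasing"):
            cumulative_methane([obs[1], obs[0], obs[1]], vial)

    def test_roundtrip_recovers_true_curve(self, vial, clean_encoding):
        series = cumulative_methane(clean_encoding["observations"], vial)
        true = clean_encoding["true_cumulative"]
        scale = max(true.max(), 1.0)
        assert np.max(np.abs(series.cumulative_ntp_ml - true)) / scale < 1e-9

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_conservation_against_explicit_vent_simulator(self, vial, seed):
        """Decoding equals an independent simulator that tracks headspace moles
        and explicit vent removals for arbitrary nondecreasing production."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 12))
        times = np.arange(n, dtype=float)
        produced_ml = np.concatenate([[0.0], np.cumsum(rng.uniform(0.0, 8.0, size=n - 1))])
        bg_ratio = float(rng.uniform(0.0, 1.5))
        obs = encode_headspace(times, produced_ml, vial, background_gas_ratio=bg_ratio)
        decoded = cumulative_methane(obs, vial).cumulative_ntp_ml
        assert np.allclose(decoded, produced_ml, atol=1e-9)


def make_series(times, cumulative, vial_id="v1"):
    moles = np.concatenate([[0.0], np.diff(cumulative)]) / MOLAR_VOLUME_NTP_ML
    return MethaneProductionSeries(vial_id, np.asarray(times, float), moles, np.asarray(cumulative, float))


def brute_force_mpr(times, values, sizes=(4, 5, 6)):
    best = -np.inf
    for w in sizes:
        for s in range(len(times) - w + 1):
            slope = np.polyfit(times[s : s + w], values[s : s + w], 1)[0]
            best = max(best, slope)
    return max(best, 0.0)


class TestMPR:
    def test_constant_series_is_zero(self, vial):
        series = make_series(np.arange(6.0), np.full(6, 10.0))
        assert methane_production_rate(series, vial)[0] == 0.0

    def test_exact_linear_series(self, vial):
        times = np.arange(8.0)
        series = make_series(times, 100.0 * times)
        mpr, meta = methane_production_rate(series, vial)
        assert mpr == pytest.approx(100.0 / vial.inoculum_vs)  # VS = 0.5 g -> 200

    def test_piecewise_rising_limb(self, vial):
        slope = 42.0
        times = np.arange(16.0)
        values = np.concatenate([np.zeros(5), slope * np.arange(1.0, 8.0), np.full(4, slope * 7)])
        mpr, meta = methane_production_rate(make_series(times, values), vial)
        assert mpr == pytest.approx(slope / vial.inoculum_vs, rel=1e-9)
        assert brute_force_mpr(times, values) == pytest.approx(slope, rel=1e-9)

    def test_matches_bruteforce_enumeration(self, vial):
        rng = np.random.default_rng(42)
        for _ in range(50):
            n = int(rng.integers(6, 15))
            times = np.cumsum(rng.uniform(0.5, 1.5, size=n))
            values = np.cumsum(rng.normal(5.0, 10.0, size=n))
            values[0] = 0.0
            mpr, _ = methane_production_rate(make_series(times, values), vial)
            assert mpr == pytest.approx(
                brute_force_mpr(times, values) / vial.inoculum_vs, rel=1e-9, abs=1e-12
            )

    def test_too_few_points(self, vial):
        with pytest.raises(ValueError, match="at least 4"):
            methane_production_rate(make_series(np.arange(3.0), np.arange(3.0)), vial)


class TestLatency:
    def test_immediate_onset_is_zero(self, vial):
        series = make_series(np.arange(6.0), np.array([0.0, 5, 20, 60, 100, 120]))
        result = latency_phase(series)
        assert result.days == 0.0 and result.onset

    def test_flat_then_jump(self, vial):
        times = np.arange(15.0)
        floor_level = 1.0
        values = np.where(times <= 10, floor_level / 2, floor_level * 5)
        result = latency_phase(make_series(times, values), baseline_floor=floor_level)
        assert result.days == 10.0 and result.onset

    def test_flat_series_flagged_no_onset(self, vial):
        series = make_series(np.arange(5.0), np.full(5, 3.0))
        result = latency_phase(series)
        assert result.days == 4.0 and not result.onset


class TestYieldAndRemoval:
    def test_yield_arithmetic(self, vial):
        times = np.arange(5.0)
        assert methane_yield(make_series(times, np.zeros(5)), vial) == 0.0
        series = make_series(times, np.array([0.0, 50, 100, 150, 150]))
        assert methane_yield(series, vial) == pytest.approx(150.0 / vial.fed_scod)  # 300

    def test_zero_fed_scod_rejected_at_spec(self):
        with pytest.raises(ValueError, match="sCOD"):
            VialSpec(
                vial_id="bad",
                total_volume=57.2e-6,
                headspace_volume=28.6e-6,
                temperature=310.15,
                atmospheric_pressure=101_325.0,
                inoculum_vs=0.5,
                fed_scod=0.0,
                ammonium_level=1.7,
            )

    @pytest.mark.parametrize(
        "fed, residual, expected",
        [(17.5, 1.7, 90.3), (17.5, 17.5, 0.0), (17.5, 0.0, 100.0)],
    )
    def test_removal_examples(self, fed, residual, expected):
        assert cod_removal_efficiency(fed, residual) == pytest.approx(expected, abs=0.05)

    def test_removal_clamps_and_warns(self):
        with pytest.warns(UserWarning, match="exceeds fed"):
            assert cod_removal_efficiency(10.0, 12.0) == 0.0
        with pytest.raises(ValueError):
            cod_removal_efficiency(0.0, 1.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.floats(min_value=0.1, max_value=100.0),
        st.floats(min_value=0.0, max_value=1.0),
        st.floats(min_value=0.0, max_value=1.0),
        st.floats(min_value=0.01, max_value=50.0),
    )
    def test_removal_antitone_and_scale_invariant(self, fed, frac_a, frac_b, scale):
        lo, hi = sorted((frac_a * fed, frac_b * fed))
        assert cod_removal_efficiency(fed, lo) >= cod_removal_efficiency(fed, hi)
        assert cod_removal_efficiency(fed, lo) == pytest.approx(
            cod_removal_efficiency(fed * scale, lo * scale), rel=1e-9
        )


class TestTheoreticalBMP:
    def test_derived_constant(self):
        value = theoretical_bmp()
        assert round(value) == 350
        assert abs(value - 350.0) < 0.5

    def test_efficiency_helper(self):
        # a 299.6 ml/g COD yield is ~85.6 % of the stoichiometric potential
        assert 100 * 299.6 / theoretical_bmp() == pytest.approx(85.6, abs=0.05)
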