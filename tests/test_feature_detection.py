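"""Salient-point detection: recovery of ground-truth trapezoid features,
acceptance-band arithmetic, spurious-point classification and cycle pairing."""

import dataclasses


import numpy as np
import pytest
from scipy import stats

from slopesync import (
    AcceptanceBands,
    CycleTemplate,
    DegenerateInputError,
    DetectionParams,
    InvalidInputError,
    SalientPoint,
    SmoothingSpec,
    Trace,
    analyse_trace,
    classify_points,
    default_bands,
    detect_cycles,
    features_frame,
    generate_trace,
    max_slope_point,
    min_slope_point,
    plateau_bounds,
    slope_series,
)


def bands_for(zero=0.05):
    return AcceptanceBands(
        max_slope_band=(0.5, np.inf),
        min_slope_band=(-np.inf, -0.5),
        zero_range=(-zero, zero),
    )


class TestExtremumPoints:
    def test_rising_ramp_steepest_sample(self):
        # sigmoid-like onset: unique steepest point at the inflection
        t = np.arange(60.0)
        values = 1.0 / (1.0 + np.exp(-(t - 30) / 4))
        slopes = slope_series(Trace(values), tau=5)
        pt = max_slope_point(slopes, 10, 50)
        assert pt.kind == "max_slope"
        assert pt.t == 30
        assert pt.valid is None

    def test_constant_trace_yields_zero_slope_point(self):
        slopes = slope_series(Trace(np.full(40, 3.0)), tau=4)
        pt = max_slope_point(slopes, 4, 35)
        assert pt.slope_value == pytest.approx(0.0)
        (classified,) = classify_points([pt], bands_for())
        assert classified.valid is False  # spurious

    def test_min_point_mirrors_max(self):
        t = np.arange(60.0)
        values = -1.0 / (1.0 + np.exp(-(t - 25) / 4))
        slopes = slope_series(Trace(values), tau=5)
        pt = min_slope_point(slopes, 10, 50)
        assert pt.t == 25
        assert pt.slope_value < 0

    def test_invalid_interval_errors(self):
        slopes = slope_series(Trace(np.arange(30.0)), tau=4)
        with pytest.raises(InvalidInputError):
            max_slope_point(slopes, 10, 10)
        with pytest.raises(InvalidInputError):
            max_slope_point(slopes, 0, 20)  # T1 outside valid range
        with pytest.raises(InvalidInputError):
            min_slope_point(slopes, 20, 29)  # T2 outside valid range

    def test_tie_broken_by_earliest_index(self):
        from slopesync import SlopeSeries

        centered = np.full(30, np.nan)
        centered[3:27] = 1.0  # exactly tied slope values
        slopes = SlopeSeries(tau=3, n=30, centered=centered)
        assert max_slope_point(slopes, 3, 26).t == 3
        assert min_slope_point(slopes, 3, 26).t == 3


class TestDefaultBands:
    def test_stated_arithmetic(self):
        values = np.concatenate([np.zeros(5), np.arange(0, 20, 2.0), np.arange(18, -2, -2.0), np.zeros(5)])
        slopes = slope_series(Trace(values), tau=2)
        smax = np.nanmax(slopes.centered)
        smin = np.nanmin(slopes.centered)
        assert smax == pytest.approx(2.0) and smin == pytest.approx(-2.0)
        bands = default_bands(slopes, epsilon=0.1, fraction=0.5)
        assert bands.max_slope_band[0] == pytest.approx(1.0)
        assert np.isinf(bands.max_slope_band[1])
        assert bands.min_slope_band[1] == pytest.approx(-1.0)
        assert bands.zero_range == pytest.approx((-0.2, 0.2))

    def test_epsilon_default(self):
        assert AcceptanceBands((1, 2), (-2, -1), (-0.1, 0.1)).epsilon == 0.1

    def test_sign_flip_swaps_and_negates_bands(self):
        rng = np.random.default_rng(7)
        values = np.cumsum(rng.normal(size=200))
        slopes = slope_series(Trace(values), tau=5)
        flipped = slope_series(Trace(-values), tau=5)
        b1 = default_bands(slopes, fraction=0.4)
        b2 = default_bands(flipped, fraction=0.4)
        assert b2.min_slope_band[1] == pytest.approx(-b1.max_slope_band[0])
        assert b2.max_slope_band[0] == pytest.approx(-b1.min_slope_band[1])

    def test_all_zero_slopes_degenerate(self):
        slopes = slope_series(Trace(np.full(30, 1.0)), tau=3)
        with pytest.raises(DegenerateInputError):
            default_bands(slopes)

    def test_band_invariants_enforced(self):
        with pytest.raises(InvalidInputError):
            AcceptanceBands((-1, 2), (-2, -1), (-0.1, 0.1))
        with pytest.raises(InvalidInputError):
            AcceptanceBands((1, 2), (-2, 1), (-0.1, 0.1))
        with pytest.raises(InvalidInputError):
            AcceptanceBands((1, 2), (-2, -1), (-0.2, 0.1))


class TestTrapezoidRecovery:
    def test_noise_free_recovery_within_tolerances(self, trapezoid_template):
        trace, truth = generate_trace(trapezoid_template, n_cycles=5, seed=0)
        feats = analyse_trace(trace, DetectionParams(tau=40))
        assert len(feats.cycles) == 5
        for cycle, row in zip(feats.cycles, truth.itertuples()):
            assert abs(cycle.max_slope_point.t - row.t_ramp_up_mid) <= 1
            assert abs(cycle.min_slope_point.t - row.t_ramp_down_mid) <= 1
            assert not cycle.plateau_undetermined
            assert abs(cycle.plateau_begin.t - row.t_plateau_begin) <= 40
            assert abs(cycle.plateau_end.t - row.t_plateau_end) <= 40

    def test_ordering_invariant(self, trapezoid_template):
        trace, _ = generate_trace(trapezoid_template, n_cycles=5, noise_sigma=0.05, seed=3)
        feats = analyse_trace(trace, DetectionParams(tau=40))
        for cycle in feats.cycles:
            if cycle.plateau_begin is None:
                continue
            assert (
                cycle.max_slope_point.t
                < cycle.plateau_begin.t
                <= cycle.plateau_end.t
                < cycle.min_slope_point.t
            )

    def test_determinism(self, trapezoid_template):
        trace, _ = generate_trace(trapezoid_template, n_cycles=4, noise_sigma=0.08, seed=9)
        a = analyse_trace(trace, DetectionParams(tau=40))
        b = analyse_trace(trace, DetectionParams(tau=40))
        assert a.cycles == b.cycles


class TestDetectCycles:
    def test_constant_trace_empty(self):
        slopes = slope_series(Trace(np.full(60, 2.0)), tau=4)
        assert detect_cycles(slopes, bands_for()) == []

    def test_trace_starting_mid_plateau_drops_leading_min(self, trapezoid_template):
        trace, truth = generate_trace(trapezoid_template, n_cycles=4, seed=0)
        # cut in the middle of the first plateau: first event is a ramp-down
        start = int(truth.t_plateau_begin.iloc[0]) + 60
        cut = Trace(trace.values[start:], sampling_interval=trace.sampling_interval)
        feats = analyse_trace(cut, DetectionParams(tau=40))
        assert len(feats.cycles) == 3  # complete max->min pairs only
        first = feats.cycles[0].max_slope_point.t
        # first retained max is from the second original cycle
        assert abs((first + start) - truth.t_ramp_up_mid.iloc[1]) <= 1

    def test_five_cycle_train_counts(self, trapezoid_template):
        trace, truth = generate_trace(trapezoid_template, n_cycles=5, seed=0)
        slopes = slope_series(Trace(trace.values), tau=40)
        cycles = detect_cycles(slopes, default_bands(slopes))
        assert len(cycles) == 5
        for cycle, row in zip(cycles, truth.itertuples()):
            assert abs(cycle.max_slope_point.t - row.t_ramp_up_mid) <= 1
            assert abs(cycle.min_slope_point.t - row.t_ramp_down_mid) <= 1


class TestPlateauBounds:
    def test_triangle_wave_is_undetermined(self):
        tri = CycleTemplate(period=900.0, ramp_up=300.0, plateau=1.5, ramp_down=300.0)
        trace, _ = generate_trace(tri, n_cycles=3, seed=0)
        slopes = slope_series(trace, tau=40)
        bands = default_bands(slopes, epsilon=0.01)  # tight zero range
        cycles = detect_cycles(slopes, bands)
        assert cycles
        for cycle in cycles:
            bounded = plateau_bounds(slopes, slopes, cycle, bands)
            assert bounded.plateau_undetermined
            assert bounded.plateau_begin is None and bounded.plateau_end is None

    def test_misordered_cycle_errors(self):
        from slopesync import ActivityCycle

        slopes = slope_series(Trace(np.arange(40.0)), tau=3)
        max_pt = SalientPoint("max_slope", 20, 1.0, True)
        min_pt = SalientPoint("min_slope", 10, -1.0, True)
        with pytest.raises(InvalidInputError):
            plateau_bounds(slopes, slopes, ActivityCycle(max_pt, min_pt), bands_for())


class TestSpikeDominantRegime:
    def test_valid_max_points_equal_true_bursts(self):
        """With a narrow band bracketing the ramp-slope magnitude (taken from
        the spike-free slope distribution), spike-induced slope extrema are
        excluded and exactly one valid max-slope point per burst remains."""
        template = CycleTemplate.spike_dominant()
        trace, truth = generate_trace(template, n_cycles=6, seed=11)
        quiet, _ = generate_trace(
            dataclasses.replace(template, spike_amplitude=0.0), n_cycles=6, seed=11
        )
        from slopesync import slope_series as _ss, smooth_trace as _sm

        ramp_slope = float(np.nanmax(_ss(_sm(quiet), 40).centered))
        bands = AcceptanceBands(
            max_slope_band=(0.8 * ramp_slope, 1.2 * ramp_slope),
            min_slope_band=(-1.2 * ramp_slope, -0.8 * ramp_slope),
            zero_range=(-0.1 * ramp_slope, 0.1 * ramp_slope),
        )
        feats = analyse_trace(trace, DetectionParams(tau=40, bands=bands))
        assert len(feats.cycles) == len(truth)
        # one-to-one: each valid max point sits inside its own burst's ramp region
        for cycle, row in zip(feats.cycles, truth.itertuples()):
            assert abs(cycle.max_slope_point.t - row.t_ramp_up_mid) < 100


class TestNoiseDegradation:
    def test_graceful_degradation_over_sigma_grid(self, trapezoid_template):
        """Detection survives noise up to 10% of plateau height and timing
        scatter grows monotonically with noise."""
        sigmas = [0.01, 0.03, 0.06, 0.10]
        per_sigma_sd = []
        detected = 0
        expected = 0
        for si, sigma in enumerate(sigmas):
            errors = []
            for rep in range(12):
                trace, truth = generate_trace(
                    trapezoid_template, n_cycles=5, noise_sigma=sigma,
                    seed=1000 * si + rep, lead_in=450.0,
                )
                feats = analyse_trace(trace, DetectionParams(tau=40))
                expected += len(truth)
                detected += len(feats.cycles)
                true_mids = truth.t_ramp_up_mid.to_numpy()
                for cycle in feats.cycles:
                    nearest = true_mids[np.argmin(np.abs(true_mids - cycle.max_slope_point.t))]
                    errors.append(cycle.max_slope_point.t - nearest)
            per_sigma_sd.append(np.std(errors))
        assert detected / expected >= 0.95
        rho, _ = stats.spearmanr(sigmas, per_sigma_sd)
        assert rho > 0


def test_features_frame_schema(trapezoid_template):
    trace, _ = generate_trace(trapezoid_template, n_cycles=3, seed=0, neuron_id="PY1")
    frame = features_frame(analyse_trace(trace, DetectionParams(tau=40)))
    assert list(frame.columns) == [
        "neuron_id", "cycle_index", "kind", "t_samples", "t_ms", "slope_value", "valid",
    ]
    assert set(frame.kind) == {"max_slope", "min_slope", "plateau_begin", "plateau_end"}
    assert (frame.t_ms == frame.t_samples * 1.5).all()
    assert frame.valid.all()
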