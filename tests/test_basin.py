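"""Outcome classification, return probabilities, basin scans, regimes."""

import numpy as np
import pytest

from spikewave import (
    ModelParameters,
    classify_attractor_regime,
    classify_outcome,
    estimate_return_probability,
    scan_basin,
    scan_parameter_1d,
    slice_along_attractor,
)
from spikewave.basin import BasinGrid, ClassificationRule, SliceSpec
from spikewave.model import Trajectory


def _constant_traj(x, span=4.0, fs=100.0):
    n = int(span * fs) + 1
    return Trajectory(np.arange(n) / fs, np.tile(np.asarray(x, float), (n, 1)))


class TestClassifyOutcome:
    @pytest.mark.parametrize("mode", ["eeg_threshold", "fp_vicinity", "sw_termination"])
    def test_fixed_point_is_background(self, det_params, det_fp, mode):
        rule = ClassificationRule.for_model(det_params, mode=mode)
        assert classify_outcome(_constant_traj(det_fp), rule, 0.0) == "background"

    @pytest.mark.parametrize("mode", ["eeg_threshold", "fp_vicinity", "sw_termination"])
    def test_sw_cycle_is_seizure(self, det_params, cycle, mode):
        from spikewave import integrate_deterministic

        rule = ClassificationRule.for_model(det_params, mode=mode)
        long = integrate_deterministic(det_params, cycle.states[0], 4.0,
                                       sample_rate=500.0)
        assert classify_outcome(long, rule, 0.0) == "seizure"

    def test_single_sample_exceedance_is_seizure(self, threshold_rule, det_fp):
        traj = _constant_traj(det_fp)
        states = traj.states.copy()
        states[150, 0] = 5.0  # one sample above threshold
        assert classify_outcome(Trajectory(traj.times, states),
                                threshold_rule, 0.0) == "seizure"

    def test_short_trajectory_raises(self, threshold_rule, det_fp):
        with pytest.raises(ValueError):
            classify_outcome(_constant_traj(det_fp, span=1.0),
                             threshold_rule, 0.0)

    def test_termination_mode_tolerates_early_exceedance(self, det_params):
        # activity that ends within the horizon counts as background
        rule = ClassificationRule.for_model(det_params, mode="sw_termination")
        traj = _constant_traj(rule.fixed_point)
        states = traj.states.copy()
        states[:100, 0] = 5.0  # first second above threshold, then quiet
        t = Trajectory(traj.times, states)
        assert classify_outcome(t, rule, 0.0) == "background"
        strict = ClassificationRule.for_model(det_params, mode="eeg_threshold")
        assert classify_outcome(t, strict, 0.0) == "seizure"


class TestReturnProbability:
    def test_fixed_point_returns_certainly(self, det_params, det_fp, threshold_rule):
        assert estimate_return_probability(det_params, det_fp, threshold_rule) == 1.0

    def test_attractor_persists_without_noise(self, det_params, cycle, threshold_rule):
        # deterministic bistability: SW never terminates spontaneously
        p = estimate_return_probability(det_params, cycle.states[10], threshold_rule)
        assert p == 0.0

    def test_granularity_matches_trial_count(self, noise_params, noise_fp):
        rule = ClassificationRule.for_model(noise_params)
        x0 = noise_fp + np.array([-0.25, -0.25, 0.0, 0.0])  # near the boundary
        p = estimate_return_probability(noise_params, x0, rule,
                                        n_trials=20, base_seed=3)
        assert round(p * 20) == pytest.approx(p * 20, abs=1e-12)

    def test_deep_core_retains_high_return_probability(self, noise_params,
                                                       noise_fp):
        """The core of the deterministic basin keeps a near-certain
        return probability under noise. (Exactly 1.0 is not a robust
        invariant: a spontaneous seizure can ignite within the horizon
        with small positive probability, ~1% per 3-s trial.)"""
        rule = ClassificationRule.for_model(noise_params)
        assert estimate_return_probability(
            noise_params, noise_fp, rule, n_trials=20, base_seed=0
        ) >= 0.95
        ball = 0
        rng = np.random.default_rng(7)
        for k in range(5):
            x0 = noise_fp + rng.uniform(-0.03, 0.03, size=4)
            ball += estimate_return_probability(
                noise_params, x0, rule, n_trials=20, base_seed=k
            )
        assert ball / 5 >= 0.9


class TestSliceSpecAndGrid:
    def test_partition_enforced(self):
        with pytest.raises(ValueError):
            SliceSpec(fixed_axes={"py": 0.0}, free_axes={"tc": (0, 1, 5)})
        with pytest.raises(ValueError):
            SliceSpec(fixed_axes={"py": 0.0, "inh": 0.0, "tc": 0.0},
                      free_axes={"re": (0, 1, 5)})

    def test_long_format_export(self, tmp_path):
        spec = SliceSpec(fixed_axes={"inh": 0.1, "re": 0.2},
                         free_axes={"py": (0, 1, 3), "tc": (0, 1, 2)})
        grid = BasinGrid(spec, np.arange(6, dtype=float).reshape(3, 2))
        df = grid.to_frame()
        assert len(df) == 6
        assert set(df.columns) == {"py", "inh", "tc", "re", "value"}
        grid.to_csv(tmp_path / "g.csv")
        assert (tmp_path / "g.csv").exists()


@pytest.fixture(scope="module")
def plane(det_params, det_fp, threshold_rule):
    spec = SliceSpec(
        fixed_axes={"inh": float(det_fp[1]), "re": float(det_fp[3])},
        free_axes={"py": (float(det_fp[0]) - 0.3, float(det_fp[0]) + 0.3, 5),
                   "tc": (float(det_fp[2]) - 0.3, float(det_fp[2]) + 0.3, 5)},
    )
    return spec, scan_basin(det_params, spec, threshold_rule, n_trials=1)


class TestScanBasin:
    def test_cell_at_fixed_point_is_background(self, plane):
        spec, grid = plane
        assert grid.values[2, 2] == 1.0  # grid center = fixed point

    def test_deterministic_values_are_binary(self, plane):
        _, grid = plane
        assert set(np.unique(grid.values)) <= {0.0, 1.0}

    def test_rescan_is_identical(self, det_params, threshold_rule, plane):
        spec, grid = plane
        again = scan_basin(det_params, spec, threshold_rule, n_trials=1)
        assert np.array_equal(grid.values, again.values)

    def test_attractor_points_labelled_seizure(self, det_params, cycle,
                                               threshold_rule):
        for idx in (0, len(cycle) // 2):
            x = cycle.states[idx]
            assert estimate_return_probability(
                det_params, x, threshold_rule
            ) == 0.0


class TestSliceAlongAttractor:
    def test_basic_and_empty(self, det_params, cycle, threshold_rule):
        template = {"py": (-0.1, 0.5, 3), "inh": (-0.1, 0.5, 3),
                    "tc": (-0.5, 0.3, 3)}
        assert slice_along_attractor(det_params, cycle, [], template,
                                     threshold_rule) == []
        grids = slice_along_attractor(det_params, cycle, [0.0, 0.15],
                                      template, threshold_rule)
        assert len(grids) == 2
        assert grids[0].metadata["slice_time"] == 0.0

    def test_identical_slice_values_give_identical_grids(self, det_params, cycle,
                                                         threshold_rule):
        template = {"py": (-0.1, 0.5, 3), "inh": (-0.1, 0.5, 3),
                    "tc": (-0.5, 0.3, 3)}
        grids = slice_along_attractor(det_params, cycle, [0.05, 0.05],
                                      template, threshold_rule)
        assert np.array_equal(grids[0].values, grids[1].values)

    def test_slice_time_outside_cycle_raises(self, det_params, cycle,
                                             threshold_rule):
        with pytest.raises(ValueError):
            slice_along_attractor(det_params, cycle, [99.0],
                                  {"py": (-0.1, 0.5, 3), "inh": (-0.1, 0.5, 3),
                                   "tc": (-0.5, 0.3, 3)}, threshold_rule)


class TestRegimes:
    def test_table_presets_are_bistable(self, det_params):
        assert classify_attractor_regime(det_params) == "bistable"
        p = ModelParameters.noise(alpha=0.0)
        assert classify_attractor_regime(p) == "bistable"

    def test_requires_zero_noise(self, noise_params):
        with pytest.raises(ValueError):
            classify_attractor_regime(noise_params)

    def test_far_shift_is_monostable(self, det_params):
        regime = classify_attractor_regime(det_params.replace(h_tc=-2.6))
        assert regime == "monostable_background"

    def test_label_invariant_to_kick_magnitude(self, det_params):
        # both probe signs are tried internally, so stronger standard
        # kicks give the same label
        for mag in (0.6, 0.9):
            assert classify_attractor_regime(
                det_params, kick_magnitude=mag
            ) == "bistable"

    def test_scan_finds_bistable_interval_around_default(self, det_params):
        values, regimes, intervals = scan_parameter_1d(
            det_params, "h_tc", (-2.15, -1.95), 5
        )
        by_value = dict(zip(np.round(values, 3), regimes))
        assert by_value[-2.05] == "bistable"
        assert intervals and any(lo <= -2.05 <= hi for lo, hi in intervals)
        # the bistable interval spans more than one grid value
        widths = [hi - lo for lo, hi in intervals]
        assert max(widths) > 0

    def test_degenerate_range(self, det_params):
        values, regimes, _ = scan_parameter_1d(det_params, "h_tc",
                                               (-2.0, -2.0), 1)
        assert len(values) == len(regimes) == 1

    def test_unknown_parameter_rejected(self, det_params):
        with pytest.raises(ValueError):
            scan_parameter_1d(det_params, "h_zz", (-1, 1), 3)
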