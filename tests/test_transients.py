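"""Transient IO, duplicate averaging and cardinal-point extraction."""

import dataclasses

import numpy as np
import pytest

from ojip import (
    GeneratorConfig,
    GridMismatchError,
    DegenerateCurveError,
    FormatError,
    OutOfRangeError,
    ValidationError,
    average_duplicates,
    extract_cardinal_points,
    phase_shape,
    read_transients,
    relative_variable_fluorescence,
    solve_amplitude,
    write_transients,
)
from ojip.transients import T_O, T_300US, T_J, T_I

from conftest import WORKED_ANCHORS, log_grid, make_transient


class TestValidation:
    def test_decreasing_time_rejected(self):
        grid = log_grid()
        bad = grid.copy()
        bad[10], bad[11] = bad[11], bad[10]
        with pytest.raises(ValidationError, match="strictly increasing"):
            make_transient(bad, np.full_like(bad, 100.0))

    @pytest.mark.parametrize(
        "tweak, message",
        [
            (dict(t_min=1e-4), "O-step mark"),
            (dict(t_max=0.2), "ends before"),
            (dict(n=20), "at least 40"),
        ],
    )
    def test_range_and_length_bounds(self, tweak, message):
        grid = log_grid(**tweak)
        with pytest.raises(ValidationError, match=message):
            make_transient(grid, np.full_like(grid, 100.0))

    def test_negative_fluorescence_rejected(self):
        grid = log_grid()
        fl = np.full_like(grid, 100.0)
        fl[5] = -1.0
        with pytest.raises(ValidationError, match="non-negative"):
            make_transient(grid, fl)


class TestCSVRoundTrip:
    def test_write_read_identity(self, tmp_path, worked_curve):
        path = tmp_path / "t.csv"
        write_transients([worked_curve], path)
        (back,) = read_transients(path)
        np.testing.assert_allclose(back.time_s, worked_curve.time_s, rtol=1e-11)
        np.testing.assert_allclose(back.fluorescence, worked_curve.fluorescence, rtol=1e-11)
        assert back.meta == dataclasses.replace(worked_curve.meta)

    def test_seventy_point_file_gives_one_transient(self, tmp_path):
        grid = np.geomspace(2e-5, 1.0, 70)
        t = make_transient(grid, 1000.0 + np.arange(70.0))
        path = tmp_path / "t.csv"
        write_transients([t], path)
        result = read_transients(path)
        assert len(result) == 1 and len(result[0]) == 70

    def test_missing_column_is_format_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("plant_id,time_s\nA,0.001\n")
        with pytest.raises(FormatError, match="missing required column"):
            read_transients(path)

    def test_malformed_rows_reported_with_line_numbers(self, tmp_path, worked_curve):
        path = tmp_path / "t.csv"
        write_transients([worked_curve], path)
        lines = path.read_text().splitlines()
        lines[3] = lines[3].rsplit(",", 1)[0] + ",not-a-number"
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(FormatError, match=r"line\(s\) \[4\]"):
            read_transients(path)

    def test_nonmonotone_record_named(self, tmp_path, worked_curve):
        path = tmp_path / "t.csv"
        scrambled = make_transient(worked_curve.time_s, worked_curve.fluorescence)
        write_transients([scrambled], path)
        txt = path.read_text().splitlines()
        txt[1], txt[2] = txt[2], txt[1]  # swap first two data rows -> time decreases
        path.write_text("\n".join(txt) + "\n")
        with pytest.raises(ValidationError, match="record"):
            read_transients(path)


class TestAveraging:
    def test_identity_and_linearity(self):
        grid = log_grid()
        a = 100.0 + 10.0 * np.arange(grid.size)
        t1 = make_transient(grid, a, meas=1)
        same = average_duplicates(t1, make_transient(grid, a, meas=2))
        np.testing.assert_array_equal(same.fluorescence, a)
        assert same.meta.measurement_index is None
        tripled = average_duplicates(t1, make_transient(grid, 3.0 * a, meas=2))
        np.testing.assert_allclose(tripled.fluorescence, 2.0 * a, rtol=1e-15)

    def test_mean_matches_pointwise_oracle(self):
        cfg = GeneratorConfig(seed=1)
        grid = cfg.time_grid()
        rng1, rng2 = np.random.default_rng(1), np.random.default_rng(2)
        f1 = 500.0 * np.exp(rng1.normal(0, 0.05, grid.size)) + 1000 * phase_shape(
            grid, cfg.weights, cfg.tau_s, cfg.sigma_decades
        )
        f2 = 500.0 * np.exp(rng2.normal(0, 0.05, grid.size)) + 1000 * phase_shape(
            grid, cfg.weights, cfg.tau_s, cfg.sigma_decades
        )
        out = average_duplicates(
            make_transient(grid, f1, meas=1), make_transient(grid, f2, meas=2)
        )
        expected = np.array([(x + y) / 2.0 for x, y in zip(f1, f2)])
        np.testing.assert_allclose(out.fluorescence, expected, rtol=0, atol=0)

    def test_mismatched_grid_is_error_not_resampled(self):
        g1, g2 = log_grid(), log_grid() * 0.999
        t1 = make_transient(g1, np.full(g1.size, 100.0), meas=1)
        t2 = make_transient(g2, np.full(g2.size, 100.0), meas=2)
        with pytest.raises(GridMismatchError):
            average_duplicates(t1, t2)

    def test_different_leaves_rejected(self):
        grid = log_grid()
        t1 = make_transient(grid, np.full(grid.size, 1.0), rep=1, meas=1)
        t2 = make_transient(grid, np.full(grid.size, 1.0), rep=2, meas=2)
        with pytest.raises(ValidationError):
            average_duplicates(t1, t2)


class TestCardinalPoints:
    def test_flat_curve_flagged(self):
        grid = log_grid()
        cp = extract_cardinal_points(make_transient(grid, np.full(grid.size, 1000.0)))
        assert cp.f0 == cp.fj == cp.fi == cp.fm == 1000.0
        assert cp.is_flat

    def test_grid_coincident_values_exact(self, worked_curve):
        cp = extract_cardinal_points(worked_curve)
        assert cp.f0 == WORKED_ANCHORS[T_O]
        assert cp.f300 == WORKED_ANCHORS[T_300US]
        assert cp.fj == WORKED_ANCHORS[T_J]
        assert cp.fi == WORKED_ANCHORS[T_I]
        assert cp.fm == WORKED_ANCHORS[1.0]
        assert not cp.is_flat

    def test_phase_model_closed_form_oracle(self):
        """Extraction on a sampled phase-model curve matches the analytic values."""
        cfg = GeneratorConfig()
        grid = cfg.time_grid()
        g = phase_shape(grid, cfg.weights, cfg.tau_s, cfg.sigma_decades)
        amp = solve_amplitude(g, cfg.fv_fm_target)
        t = make_transient(grid, cfg.f0_base * (1.0 + amp * g))
        cp = extract_cardinal_points(t)
        for mark, got in [(T_O, cp.f0), (T_300US, cp.f300), (T_J, cp.fj), (T_I, cp.fi)]:
            exact = cfg.f0_base * (
                1.0 + amp * phase_shape(np.array([mark]), cfg.weights, cfg.tau_s, cfg.sigma_decades)[0]
            )
            assert got == pytest.approx(exact, rel=1e-3)
        assert cp.fm == t.fluorescence.max()

    def test_scale_invariance_of_extraction(self, worked_curve):
        c = 3.7
        scaled = make_transient(worked_curve.time_s, c * worked_curve.fluorescence)
        cp0 = extract_cardinal_points(worked_curve)
        cp1 = extract_cardinal_points(scaled)
        for name in ("f0", "f300", "fj", "fi", "fm"):
            assert getattr(cp1, name) == pytest.approx(c * getattr(cp0, name), rel=1e-12)
        assert cp0.is_flat == cp1.is_flat

    def test_interpolated_value_within_bracket(self):
        rng = np.random.default_rng(5)
        grid = log_grid(n=55)
        fl = np.cumsum(rng.uniform(0, 30, grid.size)) + 400.0
        t = make_transient(grid, fl)
        cp = extract_cardinal_points(t)
        i = np.searchsorted(grid, T_300US)
        lo, hi = sorted((fl[i - 1], fl[i]))
        assert lo <= cp.f300 <= hi

    def test_mark_outside_range_is_error(self, worked_curve):
        from ojip.transients import _interp_log_time

        with pytest.raises(OutOfRangeError):
            _interp_log_time(worked_curve, 5.0)


class TestRelativeVariableFluorescence:
    def test_definition_and_endpoints(self, worked_curve):
        cp = extract_cardinal_points(worked_curve)
        v = relative_variable_fluorescence(worked_curve, cp)
        np.testing.assert_allclose(
            v, (worked_curve.fluorescence - cp.f0) / (cp.fm - cp.f0), rtol=0
        )
        assert v[np.argmax(worked_curve.fluorescence)] == pytest.approx(1.0)
        assert v[0] == pytest.approx(0.0, abs=1e-12)

    def test_step_curve(self):
        grid = log_grid()
        fl = np.full(grid.size, 500.0)
        fl[-1] = 2500.0
        t = make_transient(grid, fl)
        cp = extract_cardinal_points(t)
        v = relative_variable_fluorescence(t, cp)
        np.testing.assert_array_equal(v[:-1], 0.0)
        assert v[-1] == 1.0

    def test_flat_curve_is_degenerate(self):
        grid = log_grid()
        t = make_transient(grid, np.full(grid.size, 900.0))
        cp = extract_cardinal_points(t)
        with pytest.raises(DegenerateCurveError):
            relative_variable_fluorescence(t, cp)
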