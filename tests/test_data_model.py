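"""Data containers, table round trips, windowed means and protocol checks."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gasxkit.data_model import (
    AnatomyRecord,
    Constants,
    GasxSeries,
    LIGHT_CURVE_LEVELS,
    Protocol,
    ProtocolWarning,
    read_gasx_table,
    validate_protocol,
    window_mean,
    write_gasx_table,
)
from gasxkit.synthetic_data import GeneratorConfig, sample_panel, simulate_panel, write_dataset

from conftest import make_series


class TestGasxSeries:
    def test_rejects_duplicate_timestamp_naming_row(self):
        with pytest.raises(ValueError, match="row 2"):
            make_series([0, 10, 10, 30], [100] * 4, [5] * 4, [0.1] * 4)

    def test_rejects_length_mismatch(self):
        with pytest.raises(ValueError, match="length"):
            make_series([0, 10, 20], [100] * 3, [5] * 2, [0.1] * 3)

    def test_warns_on_offprotocol_ca(self):
        with pytest.warns(ProtocolWarning):
            make_series([0, 10], [100] * 2, [5] * 2, [0.1] * 2, Ca=[500.0, 500.0])

    def test_rejects_negative_conductance(self):
        with pytest.raises(ValueError, match="conductance"):
            make_series([0, 10], [100, 100], [5, 5], [0.1, -0.1])

    def test_subset_preserves_fields(self):
        s = make_series(np.arange(0, 100, 10), [100] * 10, np.arange(10), [0.1] * 10)
        sub = s.subset(s.t >= 50)
        assert len(sub) == 5
        np.testing.assert_array_equal(sub.A, np.arange(5, 10))
        assert sub.plant_id == s.plant_id


class TestConstants:
    def test_defaults_are_standard_25c_values(self):
        c = Constants()
        assert c.d == pytest.approx(24.6e-6)
        assert c.v == pytest.approx(24.4e-3)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            Constants(d=-1.0)


class TestAnatomyRecord:
    def test_pore_must_be_shorter_than_guard_cell(self):
        with pytest.raises(ValueError, match="pore_length"):
            AnatomyRecord("P1", "A", "abaxial", 10, 0.29,
                          guard_cell_length=30.0, pore_length=35.0)

    def test_rejects_unknown_surface(self):
        with pytest.raises(ValueError, match="surface"):
            AnatomyRecord("P1", "A", "upper", 10, 0.29)


class TestReadWrite:
    def test_single_plant_step_file_reads_through(self, tmp_path, noiseless_truth):
        from gasxkit.synthetic_data import simulate_step_response

        series = simulate_step_response(noiseless_truth, seed=1, plant_id="P9")
        path = tmp_path / "step.csv"
        write_gasx_table(series, path, sep=",")
        back = read_gasx_table(path)
        assert len(back) == 1
        got = back[0]
        assert got.protocol is Protocol.STEP_CHANGE
        assert len(got) == 211
        np.testing.assert_allclose(got.A, series.A, rtol=0, atol=0)

    def test_roundtrip_preserves_full_precision(self, tmp_path, truth):
        panel = simulate_panel([truth], n_plants=2, seed=3,
                               config=GeneratorConfig(n_accessions=1, n_plants=2))
        write_dataset(panel, tmp_path)
        for orig in panel.light + panel.step:
            sub = "light" if orig.protocol is Protocol.LIGHT_CURVE else "step"
            back = read_gasx_table(tmp_path / "gasx" / sub / f"{orig.plant_id}.csv")[0]
            for fld in ("t", "Q", "A", "gs", "Ci", "Ca"):
                np.testing.assert_array_equal(getattr(back, fld), getattr(orig, fld))
            assert back.accession == orig.accession

    def test_instrument_dialect_headers_and_extras(self, tmp_path):
        path = tmp_path / "licor.csv"
        path.write_text(
            "obs,Elapsed,PARi,Photo,Cond,Ci,CO2S,Tleaf\n"
            "1,0,2000,30.1,0.2,120,400,26.0\n"
            "2,10,2000,30.2,0.21,121,400,26.1\n"
        )
        series = read_gasx_table(path, plant_id="P1", protocol="light_curve")[0]
        np.testing.assert_array_equal(series.Q, [2000, 2000])
        np.testing.assert_array_equal(series.gs, [0.2, 0.21])
        assert "Tleaf" in series.extra.columns  # unknown columns carried through

    def test_missing_column_is_format_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("t,Q,A,gs,Ci\n0,100,5,0.1,120\n10,100,5,0.1,120\n")
        with pytest.raises(ValueError, match="Ca"):
            read_gasx_table(path, plant_id="P1", protocol="step_change")

    def test_nonnumeric_cell_names_row(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("t,Q,A,gs,Ci,Ca\n0,100,5,0.1,120,400\n10,100,oops,0.1,120,400\n")
        with pytest.raises(ValueError, match="row 1"):
            read_gasx_table(path, plant_id="P1", protocol="step_change")


class TestWindowMean:
    def test_constant_signal(self):
        s = make_series(np.arange(0, 100, 10), [100] * 10, [10.0] * 10, [0.1] * 10)
        assert window_mean(s, "A", 0, 90) == (10.0, 10)

    def test_linear_signal_inclusive_endpoints(self):
        t = np.arange(0, 101, 10)
        s = make_series(t, [100] * 11, t.astype(float), [0.1] * 11)
        mean, n = window_mean(s, "A", 0, 100)
        assert n == 11  # closed window includes both endpoints
        assert mean == pytest.approx(50.0)

    def test_empty_window_errors(self):
        s = make_series([0, 10, 20], [100] * 3, [5] * 3, [0.1] * 3)
        with pytest.raises(ValueError, match="no samples"):
            window_mean(s, "A", 100, 200)

    def test_matches_naive_loop_on_noisy_fixture(self):
        rng = np.random.default_rng(42)
        t = np.arange(0, 2000, 10.0)
        A = 20 + rng.normal(0, 1, len(t))
        s = make_series(t, [1000] * len(t), A, [0.1] * len(t))
        mean, n = window_mean(s, "A", 1500, 1800)
        # independent spreadsheet-style accumulation
        total, count = 0.0, 0
        for ti, ai in zip(t, A):
            if 1500 <= ti <= 1800:
                total += ai
                count += 1
        assert n == count
        assert mean == pytest.approx(total / count, rel=1e-12)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        values=st.lists(st.floats(-50, 50), min_size=2, max_size=40),
        lo=st.integers(0, 20),
        span=st.integers(1, 30),
    )
    def test_equals_naive_mean_property(self, values, lo, span):
        n = len(values)
        t = np.arange(n) * 10.0
        s = make_series(t, [100] * n, values, [0.1] * n)
        t0, t1 = lo * 10.0, (lo + span) * 10.0
        in_win = [v for ti, v in zip(t, values) if t0 <= ti <= t1]
        if not in_win:
            with pytest.raises(ValueError):
                window_mean(s, "A", t0, t1)
        else:
            mean, cnt = window_mean(s, "A", t0, t1)
            assert cnt == len(in_win)
            assert mean == pytest.approx(float(np.mean(in_win)), rel=1e-12, abs=1e-12)


class TestValidateProtocol:
    def test_canonical_twelve_step_curve_passes(self, noiseless_truth):
        from gasxkit.synthetic_data import simulate_light_curve

        series = simulate_light_curve(noiseless_truth, seed=0)
        report = validate_protocol(series)
        assert report.ok, str(report)

    def test_canonical_step_series_passes(self, noiseless_truth):
        from gasxkit.synthetic_data import simulate_step_response

        series = simulate_step_response(noiseless_truth, seed=0)
        report = validate_protocol(series)
        assert report.ok, str(report)
        assert series.t[np.argmax(series.Q > 500)] == 300.0

    def test_incomplete_curve_warns(self):
        t, Q = [], []
        for i, level in enumerate(LIGHT_CURVE_LEVELS[:5]):
            t += [i * 60.0, i * 60.0 + 10]
            Q += [level, level]
        s = make_series(t, Q, [5.0] * len(t), [0.1] * len(t), protocol=Protocol.LIGHT_CURVE)
        report = validate_protocol(s)
        assert not report.ok
        assert any("incomplete protocol" in c.message for c in report.warnings)
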