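"""Packaged scenarios, synthetic stream generation and the monitoring
runner."""

import numpy as np
import pandas as pd
import pytest

from vpcharts import ShiftSpec, generate_phase2_stream, load_scenario, \
    monitor_stream
from vpcharts.scenarios import available_scenarios, required_next_n


def test_benchmark_scenario_values(p2):
    m = p2.model
    np.testing.assert_array_equal(m.B, [[3, 2], [2, 1], [1, 1]])
    np.testing.assert_array_equal(m.Sigma, [[1, 0.5], [0.5, 1]])
    assert set(m.designs) == {4, 8}
    np.testing.assert_array_equal(m.design(4)[:, 1], [2, 4, 6, 8])
    np.testing.assert_array_equal(m.design(8)[:, 2], [1, 2, 3, 2, 3, 1, 2, 1])
    assert p2.vp_design.t1 == pytest.approx(1.9)


def test_stroke_scenario_values():
    s = load_scenario("stroke")
    assert s.model.Sigma[0, 1] == pytest.approx(0.0207)
    assert s.model.B[0, 0] == pytest.approx(2.0457)
    assert s.model.B[1, 1] == pytest.approx(-0.00079)
    assert s.model.q == 3
    assert s.vp_design.t1 == pytest.approx(3.0)  # E(t)=2, t2=1 months
    assert "synthetic" in s.notes


def test_p6_scenario_has_no_designs():
    s = load_scenario("p6")
    assert s.model.p == 6 and s.model.q == 6
    assert s.model.designs == {}
    assert "supply" in s.notes


def test_unknown_scenario_lists_available():
    with pytest.raises(ValueError, match="paper_p2"):
        load_scenario("nope")
    assert available_scenarios() == ["p6", "paper_p2", "stroke"]


def test_stream_generation_reproducible(p2):
    sched = [(4, ShiftSpec())] * 5 + [(8, ShiftSpec(tau=1.5))] * 3
    a = generate_phase2_stream(p2, sched, np.random.default_rng(1))
    b = generate_phase2_stream(p2, sched, np.random.default_rng(1))
    pd.testing.assert_frame_equal(a, b)
    assert a["sample_id"].nunique() == 8
    assert (a.groupby("sample_id").size().values == [4] * 5 + [8] * 3).all()
    assert list(a.columns) == ["sample_id", "x1", "x2", "y1", "y2"]


def test_stroke_stream_log_scale_columns():
    s = load_scenario("stroke")
    stream = generate_phase2_stream(
        s, [(4, ShiftSpec())] * 3, np.random.default_rng(2),
        random_covariates=True, inverse_log10=True,
    )
    np.testing.assert_allclose(stream["y1_orig"], 10.0 ** stream["y1"])
    assert stream["x1"].between(18, 100).all()     # age truncation
    assert set(stream["x2"]) <= {0.0, 1.0}          # sex binary
    assert stream["x3"].between(0, 42).all()        # severity truncation


def _fp_table(p2, stream, ucl, **kw):
    return monitor_stream(stream, p2, "max_mewma", scheme="fp", UCL=ucl, **kw)


def test_monitor_records_consistent(p2, mewma_fp_ucl):
    rng = np.random.default_rng(3)
    sched = [(4, ShiftSpec())] * 30 + [(4, ShiftSpec(delta_B=np.array(
        [[2.0, 2.0], [0, 0], [0, 0]])))] * 20
    stream = generate_phase2_stream(p2, sched, rng)
    tab = _fp_table(p2, stream, mewma_fp_ucl.UCL, stop_at_signal=True)
    # status column is forced by the statistic/UCL comparison
    assert ((tab["stat"] > tab["UCL_k"]) ==
            (tab["status"] == "out-of-control")).all()
    # cumulative columns are running sums of the per-sample columns
    np.testing.assert_array_equal(tab["cum_n"], tab["n_k"].cumsum())
    np.testing.assert_allclose(tab["cum_t"], tab["t_k"].cumsum())
    # FP never changes n or t
    assert tab["n_k"].nunique() == 1
    assert tab["t_k"].iloc[0] == 0.0
    assert tab["t_k"].iloc[1:].nunique() == 1
    # the injected sustained shift is eventually caught
    assert (tab["status"] == "out-of-control").any()
    # replay is exact
    pd.testing.assert_frame_equal(
        tab, _fp_table(p2, stream, mewma_fp_ucl.UCL, stop_at_signal=True))


def test_monitor_vp_follows_zones(p2, mewma_vp_design):
    """The VP runner's sample sizes follow the previous sample's zone, and
    a statistic exactly at the UCL stays in-control (warning zone)."""
    design = mewma_vp_design
    rng = np.random.default_rng(4)
    # build the stream interactively so the sizes match the prescription
    from vpcharts import DualTracker, make_chart, simulate_sample

    probe = DualTracker(lambda: make_chart("max_mewma", p2.model), design)
    frames = []
    for sid in range(1, 41):
        n = probe.required_n()
        s = simulate_sample(p2.model, ShiftSpec(tau=1.4), n=n, rng=rng)
        df = pd.DataFrame(s.X[:, 1:], columns=["x1", "x2"])
        df[["y1", "y2"]] = s.Y
        df.insert(0, "sample_id", sid)
        frames.append(df)
        _, zone = probe.step(s)
        if zone.value == "signal":
            break
    stream = pd.concat(frames, ignore_index=True)
    tab = monitor_stream(stream, p2, "max_mewma", scheme="vp", design=design)
    sizes = {1: design.n1, 2: design.n2}
    for i in range(1, len(tab)):
        prev = tab.iloc[i - 1]
        expect_region = 1 if prev["stat"] <= prev["UWL_k"] else 2
        assert tab.iloc[i]["region"] == expect_region
        assert tab.iloc[i]["n_k"] == sizes[expect_region]
    at_limit = tab.iloc[0]
    assert (at_limit["status"] == "out-of-control") == \
        (at_limit["stat"] > at_limit["UCL_k"])


def test_monitor_false_alarm_rate_in_control(p2, mewma_fp_ucl):
    """Monitoring a long in-control stream with restart-after-signal yields
    a signal count compatible with the calibrated false-alarm rate."""
    rng = np.random.default_rng(6)
    stream = generate_phase2_stream(p2, [(4, ShiftSpec())] * 4000, rng)
    tab = _fp_table(p2, stream, mewma_fp_ucl.UCL, stop_at_signal=False,
                    reset_after_signal=True)
    signals = int((tab["status"] == "out-of-control").sum())
    # ~ 4000/200 = 20 expected; very loose Poisson-style bounds
    assert 5 <= signals <= 45


def test_required_next_n(p2, mewma_vp_design):
    tab = pd.DataFrame([{"stat": 0.5, "UWL_k": 1.0, "UCL_k": 3.0}])
    assert required_next_n(tab, mewma_vp_design) == mewma_vp_design.n1
    tab2 = pd.DataFrame([{"stat": 2.0, "UWL_k": 1.0, "UCL_k": 3.0}])
    assert required_next_n(tab2, mewma_vp_design) == mewma_vp_design.n2
    assert required_next_n(pd.DataFrame(), mewma_vp_design) == mewma_vp_design.n1
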