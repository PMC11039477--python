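"""Packaged scenarios, a synthetic Phase-II stream generator and the
Phase-II monitoring runner.

Three scenarios ship with the package:

* ``paper_p2`` — the two-response benchmark: y1 = 3 + 2 x1 + x2, y2 = 2 + x1
  + x2 with unit error variances and correlation 0.5, fixed design matrices
  for n = 4 and n = 8, and the VP design n1=4, n2=8, E(n)=6, t2=0.1 hr,
  E(t)=1 hr, alpha1=0.004, E(alpha)=0.005 (so t1 = 1.9 hrs).
* ``stroke`` — a stroke-care thrombolysis-delay profile: log10 onset-to-
  needle and door-to-needle times regressed on age, sex and stroke severity,
  with the fitted coefficients and residual covariance of the register
  model.  The patient-level register data are restricted, so the shipped
  design matrices are synthetic stand-ins drawn once from documented
  covariate distributions.
* ``p6`` — the six-response benchmark coefficient matrix; its design
  matrices are not published, so the user must supply X before simulating.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .charts import ChartConfig, make_chart
from .model import ProfileModel, Sample, ShiftSpec
from .vp import DualTracker, VPDesign, Zone, classify_zone, solve_design

PAPER_P2_X4 = np.array(
    [[1, 2, 1], [1, 4, 2], [1, 6, 3], [1, 8, 2]], dtype=float
)
PAPER_P2_X8 = np.array(
    [
        [1, 2, 1], [1, 4, 2], [1, 6, 3], [1, 8, 2],
        [1, 9, 3], [1, 10, 1], [1, 9, 2], [1, 11, 1],
    ],
    dtype=float,
)

# Default covariate distributions for the synthetic stroke streams:
# age ~ Normal(72, 10^2) truncated to [18, 100]; sex ~ Bernoulli(0.5);
# severity (NIHSS) ~ Gamma(shape 2, scale 4) truncated to [0, 42].
STROKE_COVARIATES = {
    "age": {"dist": "truncnorm", "mean": 72.0, "sd": 10.0, "lo": 18.0, "hi": 100.0},
    "sex": {"dist": "bernoulli", "p": 0.5},
    "severity": {"dist": "truncgamma", "shape": 2.0, "scale": 4.0, "lo": 0.0,
                 "hi": 42.0},
}


@dataclass(frozen=True)
class Scenario:
    """A named profile model plus default chart and VP design settings."""

    name: str
    model: ProfileModel
    chart_config: ChartConfig = field(default_factory=ChartConfig)
    vp_design: VPDesign | None = None
    fp_n: int | None = None
    fp_t: float = 1.0
    notes: str = ""


def _paper_p2() -> Scenario:
    model = ProfileModel(
        B=np.array([[3.0, 2.0], [2.0, 1.0], [1.0, 1.0]]),
        Sigma=np.array([[1.0, 0.5], [0.5, 1.0]]),
        designs={4: PAPER_P2_X4, 8: PAPER_P2_X8},
    )
    design = solve_design(4, 8, 6.0, 0.1, 1.0, 0.004, 0.005)
    return Scenario(
        name="paper_p2",
        model=model,
        vp_design=design,
        fp_n=4,
        fp_t=1.0,
        notes="Two-profile benchmark with printed designs for n=4 and n=8.",
    )


def _draw_stroke_covariates(n: int, rng: np.random.Generator) -> np.ndarray:
    spec = STROKE_COVARIATES
    a = spec["age"]
    age = np.empty(n)
    for i in range(n):  # rejection sampling keeps the truncation exact
        while True:
            v = rng.normal(a["mean"], a["sd"])
            if a["lo"] <= v <= a["hi"]:
                age[i] = v
                break
    sex = rng.binomial(1, spec["sex"]["p"], size=n).astype(float)
    g = spec["severity"]
    sev = np.empty(n)
    for i in range(n):
        while True:
            v = rng.gamma(g["shape"], g["scale"])
            if g["lo"] <= v <= g["hi"]:
                sev[i] = v
                break
    return np.column_stack([np.ones(n), age, sex, sev])


def _stroke() -> Scenario:
    # Fitted log10-scale profiles: responses are log10 of the onset-to-needle
    # and door-to-needle times (minutes); covariates age, sex (1=female),
    # NIHSS severity.
    B = np.array(
        [
            [2.0457, 1.6797],
            [0.00084, -0.00079],
            [0.01597, 0.01558],
            [-0.0045, -0.0032],
        ]
    )
    Sigma = np.array([[0.0399, 0.0207], [0.0207, 0.0743]])
    # Synthetic stand-in designs (register data restricted): one fixed draw
    # per sample size from the documented covariate distributions.
    rng = np.random.default_rng(20160101)
    designs = {n: _draw_stroke_covariates(n, rng) for n in (4, 8)}
    model = ProfileModel(B=B, Sigma=Sigma, designs=designs)
    design = solve_design(4, 8, 6.0, 1.0, 2.0, 0.004, 0.005)  # months
    return Scenario(
        name="stroke",
        model=model,
        vp_design=design,
        fp_n=4,
        fp_t=2.0,
        notes=(
            "Stroke thrombolysis-delay profiles on the log10 scale; design "
            "matrices are synthetic stand-ins for the restricted register "
            "covariates."
        ),
    )


def _p6() -> Scenario:
    B = np.array(
        [
            [-0.05, 0.48, 0.37, 0.04, 0.09, 0.09],
            [10.0, 0.24, 0.09, 0.0, -0.021, 0.04],
            [-0.01, 21.01, 0.01, 0.0, 0.0, 0.0],
            [-0.03, -0.09, 6.81, 0.0, 0.01, -0.01],
            [0.26, 0.03, 0.04, 10.53, 0.02, 0.18],
            [0.0, -0.12, 0.02, -0.47, 7.0, -0.34],
            [0.03, 0.01, -0.03, 0.21, -0.34, 11.46],
        ]
    )
    rho = 0.5
    Sigma = np.full((6, 6), rho) + (1 - rho) * np.eye(6)
    model = ProfileModel(B=B, Sigma=Sigma, designs={})
    return Scenario(
        name="p6",
        model=model,
        notes=(
            "Six-profile benchmark coefficients; no design matrices are "
            "published for n=8/n=16 — the user must supply X."
        ),
    )


_BUILTIN = {"paper_p2": _paper_p2, "stroke": _stroke, "p6": _p6}


def load_scenario(name: str) -> Scenario:
    """Load a packaged scenario by name."""
    try:
        return _BUILTIN[name]()
    except KeyError:
        raise ValueError(
            f"unknown scenario {name!r}; available: {sorted(_BUILTIN)}"
        ) from None


def available_scenarios() -> list[str]:
    return sorted(_BUILTIN)


# ---------------------------------------------------------------------------
# Synthetic Phase-II streams


def generate_phase2_stream(
    scenario: Scenario,
    schedule: list[tuple[int, ShiftSpec]],
    rng: np.random.Generator,
    *,
    random_covariates: bool = False,
    inverse_log10: bool = False,
) -> pd.DataFrame:
    """Simulate a Phase-II sample stream.

    ``schedule`` lists one ``(n, shift)`` pair per sample.  Covariates come
    from the scenario's fixed design for that sample size, or (for the
    stroke scenario with ``random_covariates``) are redrawn per sample from
    the documented distributions.  Returns a tidy frame with one row per
    observation: sample_id, x1..xq, y1..yp (plus ``y*_orig = 10**y*`` when
    ``inverse_log10`` is set, convenient for log10-scale profiles).
    """
    model = scenario.model
    rows = []
    for sample_id, (n, shift) in enumerate(schedule, start=1):
        if random_covariates:
            if scenario.name != "stroke":
                raise ValueError("random covariates are defined for the stroke "
                                 "scenario only")
            X = _draw_stroke_covariates(n, rng)
        else:
            X = model.design(n)
        Bs = shift.shifted_B(model.B)
        chol = np.linalg.cholesky(shift.tau * model.Sigma)
        E = rng.standard_normal((n, model.p)) @ chol.T
        Y = X @ Bs + E
        for i in range(n):
            row = {"sample_id": sample_id}
            for j in range(model.q):
                row[f"x{j + 1}"] = X[i, j + 1]
            for j in range(model.p):
                row[f"y{j + 1}"] = Y[i, j]
                if inverse_log10:
                    row[f"y{j + 1}_orig"] = 10.0 ** Y[i, j]
            rows.append(row)
    return pd.DataFrame(rows)


def stream_samples(stream: pd.DataFrame, model: ProfileModel):
    """Iterate (sample_id, Sample) over a tidy observation stream."""
    xcols = [f"x{j + 1}" for j in range(model.q)]
    ycols = [f"y{j + 1}" for j in range(model.p)]
    for sample_id, grp in stream.groupby("sample_id", sort=True):
        X = np.column_stack([np.ones(len(grp)), grp[xcols].to_numpy(dtype=float)])
        Y = grp[ycols].to_numpy(dtype=float)
        yield int(sample_id), Sample(Y=Y, X=X, design_key=len(grp))


# ---------------------------------------------------------------------------
# Phase-II monitoring runner


@dataclass(frozen=True)
class MonitorRecord:
    """One row of a monitoring decision table."""

    k: int
    n_k: int
    cum_n: int
    t_k: float
    cum_t: float
    ybar: tuple
    mean_stat: float
    var_stat: float
    stat: float
    UWL_k: float
    UCL_k: float
    region: int
    status: str


def _records_frame(records: list[MonitorRecord], p: int) -> pd.DataFrame:
    out = []
    for r in records:
        row = {
            "k": r.k, "n_k": r.n_k, "cum_n": r.cum_n,
            "t_k": r.t_k, "cum_t": r.cum_t,
        }
        for j in range(p):
            row[f"ybar{j + 1}"] = r.ybar[j]
        row.update(
            mean_stat=r.mean_stat, var_stat=r.var_stat, stat=r.stat,
            UWL_k=r.UWL_k, UCL_k=r.UCL_k, region=r.region, status=r.status,
        )
        out.append(row)
    return pd.DataFrame(out)


def monitor_stream(
    stream: pd.DataFrame,
    scenario: Scenario,
    chart_name: str,
    *,
    scheme: str = "vp",
    design: VPDesign | None = None,
    UCL: float | None = None,
    UWL: float | None = None,
    stop_at_signal: bool = True,
    reset_after_signal: bool = True,
) -> pd.DataFrame:
    """Run a chart over a recorded sample stream, producing a decision table.

    VP scheme: sample sizes must follow the region prescription (the runner
    raises on a mismatch); FP scheme: constant n and t.  A statistic above
    the active UCL marks the sample out-of-control; by default monitoring
    stops there, otherwise the memory state is reset (or kept, with
    ``reset_after_signal=False``) and monitoring continues.
    """
    model = scenario.model
    cfg = scenario.chart_config
    records: list[MonitorRecord] = []
    cum_n = 0
    cum_t = 0.0

    if scheme == "vp":
        if design is None:
            design = scenario.vp_design
        if design is None:
            raise ValueError("a calibrated VPDesign is required for scheme='vp'")
        tracker = DualTracker(lambda: make_chart(chart_name, model, cfg), design)
        for k, sample in stream_samples(stream, model):
            region = tracker.region
            n_req, t_k, UCL_k, UWL_k = design.region_params(region)
            if not records:  # the clock starts at the first sample
                t_k = 0.0
            if sample.n != n_req:
                raise ValueError(
                    f"sample {k}: region {region} requires n={n_req}, "
                    f"stream has n={sample.n}"
                )
            stat, zone = tracker.step(sample)
            chart = tracker.tracks[region]
            cum_n += sample.n
            cum_t += t_k
            records.append(MonitorRecord(
                k=k, n_k=sample.n, cum_n=cum_n, t_k=t_k, cum_t=cum_t,
                ybar=tuple(sample.Y.mean(axis=0)),
                mean_stat=chart.last_mean_stat, var_stat=chart.last_var_stat,
                stat=stat, UWL_k=UWL_k, UCL_k=UCL_k, region=region,
                status="out-of-control" if zone is Zone.SIGNAL else "in-control",
            ))
            if zone is Zone.SIGNAL:
                if stop_at_signal:
                    break
                tracker = DualTracker(
                    lambda: make_chart(chart_name, model, cfg), design
                ) if reset_after_signal else tracker
                if not reset_after_signal:
                    tracker.region = 1
    elif scheme == "fp":
        if UCL is None:
            raise ValueError("UCL is required for scheme='fp'")
        uwl = UWL if UWL is not None else UCL
        chart = make_chart(chart_name, model, cfg)
        for k, sample in stream_samples(stream, model):
            t_k = scenario.fp_t if records else 0.0
            stat = chart.update(sample)
            cum_n += sample.n
            cum_t += t_k
            signal = stat > UCL
            records.append(MonitorRecord(
                k=k, n_k=sample.n, cum_n=cum_n, t_k=t_k, cum_t=cum_t,
                ybar=tuple(sample.Y.mean(axis=0)),
                mean_stat=chart.last_mean_stat, var_stat=chart.last_var_stat,
                stat=stat, UWL_k=uwl, UCL_k=UCL, region=1,
                status="out-of-control" if signal else "in-control",
            ))
            if signal:
                if stop_at_signal:
                    break
                if reset_after_signal:
                    chart.reset()
    else:
        raise ValueError("scheme must be 'fp' or 'vp'")
    return _records_frame(records, model.p)


def required_next_n(records: pd.DataFrame, design: VPDesign) -> int:
    """Sample size the VP scheme prescribes after the last recorded sample."""
    if records.empty:
        return design.n1
    last = records.iloc[-1]
    zone = classify_zone(last["stat"], last["UWL_k"], last["UCL_k"])
    if zone is Zone.SIGNAL:
        raise ValueError("process signalled; no next sample is prescribed")
    return design.n1 if zone is Zone.SAFE else design.n2
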