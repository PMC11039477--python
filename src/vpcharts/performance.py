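"""Run-length and time-to-signal performance of FP and VP schemes.

Zero-state convention: shifts are present from the first monitored sample
and all memory statistics start at zero.  For an FP scheme with sampling
interval ``t`` the time to signal is exactly ``t`` times the run length; a
VP scheme accrues the interval chosen after each sample, so ATS and ARL are
reported separately.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from . import _engine
from .charts import ChartConfig
from .model import IN_CONTROL, ProfileModel, ShiftSpec
from .calibration import CalibrationSettings
from .vp import VPDesign

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PerfSummary:
    """ARL/SDRL (samples) and ATS/SDTS (time units) over ``reps`` runs."""

    ARL: float
    SDRL: float
    ATS: float
    SDTS: float
    reps: int
    mc_se_arl: float
    mc_se_ats: float
    truncated: int = 0


def summarize(rl, ts, truncated: int = 0) -> PerfSummary:
    """Sample means/SDs (ddof=1) and Monte-Carlo standard errors."""
    rl = np.asarray(rl, dtype=float)
    ts = np.asarray(ts, dtype=float)
    if rl.size == 0 or ts.size == 0:
        raise ValueError("empty run-length input")
    if (rl < 1).any() or (ts <= 0).any():
        raise ValueError("run lengths must be >= 1 and times positive")
    reps = rl.size
    sdrl = float(rl.std(ddof=1)) if reps > 1 else 0.0
    sdts = float(ts.std(ddof=1)) if reps > 1 else 0.0
    return PerfSummary(
        ARL=float(rl.mean()),
        SDRL=sdrl,
        ATS=float(ts.mean()),
        SDTS=sdts,
        reps=reps,
        mc_se_arl=sdrl / np.sqrt(reps),
        mc_se_ats=sdts / np.sqrt(reps),
        truncated=truncated,
    )


def _warn_truncation(truncated: int, reps: int, cap: int) -> None:
    if truncated > 0.01 * reps:
        logger.warning("%d/%d runs hit the cap of %d samples", truncated, reps, cap)


def run_length_fp(
    chart: str,
    model: ProfileModel,
    cfg: ChartConfig | None = None,
    shift: ShiftSpec = IN_CONTROL,
    *,
    UCL: float,
    n: int,
    t: float = 1.0,
    settings: CalibrationSettings | None = None,
    cap: int | None = None,
    seed=None,
) -> PerfSummary:
    """Zero-state FP run-length distribution against a calibrated UCL."""
    cfg = cfg or ChartConfig()
    settings = settings or CalibrationSettings()
    cap = cap if cap is not None else settings.rl_cap or 10000
    seed = settings.seed if seed is None else seed
    rl, _ = _engine.fp_run_lengths(
        chart, model, cfg, shift, n=n, ucls=[UCL],
        reps=settings.reps, cap=cap, seed=seed,
    )
    rl = rl[:, 0]
    truncated = int((rl >= cap).sum())
    _warn_truncation(truncated, settings.reps, cap)
    return summarize(rl, t * rl, truncated)


def run_length_vp(
    chart: str,
    model: ProfileModel,
    design: VPDesign,
    cfg: ChartConfig | None = None,
    shift: ShiftSpec = IN_CONTROL,
    *,
    settings: CalibrationSettings | None = None,
    cap: int | None = None,
    seed=None,
    collect_occupancy: bool = False,
    initial_region: str = "relaxed",
    first_interval: str = "expected",
):
    """Zero-state VP run-length/time-to-signal distribution.

    Requires a fully calibrated design (UCL1, UCL2, UWL1, UWL2).  Runs
    start relaxed (region 1, both tracks zero) and the first sample is
    preceded by the expected interval E(t) — no zone information exists
    before it; both conventions can be overridden.  Returns a
    :class:`PerfSummary`, or ``(PerfSummary, occupancy)`` when
    ``collect_occupancy`` is set.
    """
    cfg = cfg or ChartConfig()
    settings = settings or CalibrationSettings()
    cap = cap if cap is not None else settings.rl_cap or 10000
    seed = settings.seed if seed is None else seed
    rl, ts, occ = _engine.vp_run_lengths(
        chart, model, cfg, shift, design,
        reps=settings.reps, cap=cap, seed=seed,
        collect_occupancy=collect_occupancy, initial_region=initial_region,
        first_interval=first_interval,
    )
    truncated = int((rl >= cap).sum())
    _warn_truncation(truncated, settings.reps, cap)
    summary = summarize(rl, ts, truncated)
    return (summary, occ) if collect_occupancy else summary
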