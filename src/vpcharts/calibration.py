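"""Monte-Carlo calibration of control and warning limits.

The control limit of each chart is set by stochastic search so that the
simulated zero-state in-control ARL equals ``1/alpha``; the warning limit is
then the P0-quantile of the in-control non-signal statistic stream (the
VSI-style construction, one warning limit per control limit).

The search exploits a structural fact: with a common random seed the chart
trajectories do not depend on the candidate limit, so the run length of each
replication — the first index at which the running maximum exceeds the limit
— is exactly nondecreasing in the limit.  One vectorized simulation pass
therefore evaluates a whole grid of candidate limits at once, and bracketing
grid refinement converges without Monte-Carlo jitter between iterations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import _engine
from .charts import ChartConfig
from .model import IN_CONTROL, ProfileModel
from .vp import VPDesign

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CalibrationSettings:
    """Knobs for the limit search.

    reps : replications per evaluation (default 10000).
    rl_cap : run-length truncation cap; default 50/alpha at use time.
    tol : relative tolerance on the achieved in-control ARL (default 0.02).
    max_iter : maximum bracketing/refinement passes.
    seed : base seed; every evaluation derives its stream from it.
    grid : candidate limits evaluated per pass.
    """

    reps: int = 10000
    rl_cap: int | None = None
    tol: float = 0.02
    max_iter: int = 40
    seed: int = 0
    grid: int = 25
    search_cap_factor: float = 10.0

    def __post_init__(self):
        if self.reps < 100:
            raise ValueError("reps must be >= 100")
        if not 0 < self.tol < 0.2:
            raise ValueError("tol must be in (0, 0.2)")

    def cap_for(self, alpha: float) -> int:
        return self.rl_cap if self.rl_cap is not None else int(round(50 / alpha))


@dataclass
class CalibrationResult:
    UCL: float
    achieved_arl: float
    target_arl: float
    reps: int
    iterations: int
    truncated: int
    converged: bool
    mc_se_arl: float = field(default=np.nan)


def initial_ucl(
    chart: str,
    model: ProfileModel,
    cfg: ChartConfig | None,
    *,
    alpha: float,
    n: int,
    reps: int = 10000,
    seed=0,
) -> float:
    """Order-statistic starting value for the UCL search.

    Simulates ``reps`` independent first-update statistics from fresh
    in-control chart states, sorts them increasingly and returns the
    ceil(reps*(1-alpha))-th value.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    cfg = cfg or ChartConfig()
    stats = np.sort(
        _engine.first_update_stats(chart, model, cfg, n=n, reps=reps, seed=seed)
    )
    k = int(np.ceil(reps * (1.0 - alpha)))
    return float(stats[k - 1])


def calibrate_ucl(
    chart: str,
    model: ProfileModel,
    cfg: ChartConfig | None = None,
    *,
    alpha: float,
    n: int,
    settings: CalibrationSettings | None = None,
) -> CalibrationResult:
    """Search for the UCL giving simulated in-control ARL = 1/alpha.

    Starts from the first-update order statistic, brackets the target with a
    geometric expansion, then refines the bracket with common-random-number
    grid passes until the achieved ARL is within ``settings.tol`` of target.
    """
    cfg = cfg or ChartConfig()
    settings = settings or CalibrationSettings()
    target = 1.0 / alpha
    # Search passes truncate at ~10x the target ARL: P(RL > cap) ~ e^-10 at
    # the returned limit, so the bias on the achieved ARL is negligible,
    # while candidates far above target stop early.
    cap = min(settings.cap_for(alpha),
              int(np.ceil(settings.search_cap_factor * target)))

    def evaluate(ucls):
        rl, _ = _engine.fp_run_lengths(
            chart, model, cfg, IN_CONTROL,
            n=n, ucls=ucls, reps=settings.reps, cap=cap, seed=settings.seed,
        )
        return rl

    u0 = initial_ucl(
        chart, model, cfg, alpha=alpha, n=n, reps=settings.reps, seed=settings.seed
    )
    u0 = max(u0, 1e-6)
    lo, hi = 0.75 * u0, 1.35 * u0
    best = None
    for it in range(1, settings.max_iter + 1):
        grid = np.linspace(lo, hi, settings.grid)
        rl = evaluate(grid)
        arls = rl.mean(axis=0)
        if arls[-1] < target:  # bracket too low
            lo, hi = hi, hi * 1.5
            continue
        if arls[0] > target:  # bracket too high
            lo, hi = lo * 0.6, lo
            continue
        j = int(np.searchsorted(arls, target, side="left"))
        j = min(max(j, 1), grid.size - 1)
        cand = j if abs(arls[j] - target) < abs(arls[j - 1] - target) else j - 1
        sd = rl[:, cand].std(ddof=1)
        se = sd / np.sqrt(settings.reps)
        # Converge relative to the Monte-Carlo SE when that is tighter than
        # the relative tolerance (near-deterministic run lengths allow — and
        # verification expects — much finer placement than tol*target).
        conv_tol = min(settings.tol * target, max(se, 1e-3 * target))
        best = CalibrationResult(
            UCL=float(grid[cand]),
            achieved_arl=float(arls[cand]),
            target_arl=target,
            reps=settings.reps,
            iterations=it,
            truncated=int((rl[:, cand] >= cap).sum()),
            converged=abs(arls[cand] - target) <= conv_tol,
            mc_se_arl=float(se),
        )
        if best.converged or (hi - lo) < 1e-9 * u0:
            break
        lo, hi = float(grid[j - 1]), float(grid[j])
    if best is None:
        raise RuntimeError(
            f"failed to bracket ARL={target} within {settings.max_iter} passes "
            f"(last bracket [{lo:.4g}, {hi:.4g}])"
        )
    if best.truncated:
        logger.warning("%d/%d runs truncated at cap=%d", best.truncated,
                       settings.reps, cap)
    if not best.converged:
        logger.warning(
            "UCL search stopped at ARL=%.2f (target %.2f) after %d passes",
            best.achieved_arl, target, best.iterations,
        )
    return best


def calibrate_uwl(
    chart: str,
    model: ProfileModel,
    cfg: ChartConfig | None = None,
    *,
    alpha: float,
    n: int,
    UCL: float,
    P0: float,
    settings: CalibrationSettings | None = None,
) -> float:
    """Warning limit: P0-quantile of the in-control non-signal statistics.

    Simulates in-control runs against the calibrated UCL, pools every
    plotting statistic at or below the UCL, and returns the empirical
    P0-quantile of the pool, so the safe-zone fraction among non-signal
    samples equals P0 (the VSI-style condition of the warning-limit design).
    """
    if not 0 < P0 < 1:
        raise ValueError("P0 must be in (0, 1)")
    cfg = cfg or ChartConfig()
    settings = settings or CalibrationSettings()
    cap = settings.cap_for(alpha)
    _, stats = _engine.fp_run_lengths(
        chart, model, cfg, IN_CONTROL,
        n=n, ucls=[UCL], reps=settings.reps, cap=cap,
        seed=settings.seed, collect_stats=True,
    )
    if stats.size == 0:
        raise RuntimeError("no in-control statistics collected below the UCL")
    uwl = float(np.quantile(stats, P0))
    return min(uwl, np.nextafter(UCL, -np.inf))


def calibrate_vp_limits(
    chart: str,
    model: ProfileModel,
    design: VPDesign,
    cfg: ChartConfig | None = None,
    *,
    settings: CalibrationSettings | None = None,
) -> tuple[VPDesign, dict]:
    """Calibrate (UCL1, UWL1) at (alpha1, n1) and (UCL2, UWL2) at
    (alpha2, n2) and return the design with limits attached plus the
    achieved in-control ARLs."""
    cfg = cfg or ChartConfig()
    settings = settings or CalibrationSettings()
    res1 = calibrate_ucl(chart, model, cfg, alpha=design.alpha1, n=design.n1,
                         settings=settings)
    res2 = calibrate_ucl(chart, model, cfg, alpha=design.alpha2, n=design.n2,
                         settings=settings)
    uwl1 = calibrate_uwl(chart, model, cfg, alpha=design.alpha1, n=design.n1,
                         UCL=res1.UCL, P0=design.P0, settings=settings)
    uwl2 = calibrate_uwl(chart, model, cfg, alpha=design.alpha2, n=design.n2,
                         UCL=res2.UCL, P0=design.P0, settings=settings)
    diag = {"ucl1": res1, "ucl2": res2}
    return design.with_limits(res1.UCL, res2.UCL, uwl1, uwl2), diag
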