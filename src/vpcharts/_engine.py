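"""Vectorized Monte-Carlo kernels for run-length simulation.

The public chart classes in :mod:`vpcharts.charts` are scalar, one-sample
recursions.  Calibrating limits and estimating run-length distributions
needs millions of chart updates, so this module re-implements the same
recursions vectorized across replications.  Tests replay the engine's random
draws through the scalar charts to pin the two routes together.

Random-number convention: one ``standard_normal((n_alive, n, p))`` draw per
simulation step for the replications still running (two draws per step for
VP runs, region-1 sizes first).  Run lengths are therefore reproducible from
the seed, and with a shared seed the run length of every replication is
nondecreasing in the control limit (the trajectories are identical until the
largest candidate limit is crossed).
"""

from __future__ import annotations

import numpy as np
from scipy import linalg, special

from .charts import ChartConfig, default_beta_b
from .model import IN_CONTROL, ProfileModel, ShiftSpec
from .vp import VPDesign


def _pit(x: np.ndarray, df: int, eps: float) -> np.ndarray:
    """Vectorized chi-square -> standard-normal probability integral
    transform with clamping (matches charts.normal_chisq_transform)."""
    u = np.clip(special.chdtr(df, x), eps, 1.0 - eps)
    return special.ndtri(u)


class _DesignEntry:
    """Per-design precomputation: projector, coefficient covariance, means."""

    def __init__(self, model: ProfileModel, n: int, shift: ShiftSpec):
        X = model.design(n)
        self.n = n
        self.X = X
        XtX_inv = linalg.inv(X.T @ X)
        self.pinv = XtX_inv @ X.T  # (q+1, n)
        self.Sbinv = linalg.inv(np.kron(model.Sigma, XtX_inv))
        self.df_w = n * model.p
        self.XB0 = X @ model.B
        self.XBs = X @ shift.shifted_B(model.B)


class _StepInputs:
    """Derived quantities for a batch of samples under one design."""

    __slots__ = ("dev_vec", "W", "ebar")

    def __init__(self, E: np.ndarray, entry: _DesignEntry, model: ProfileModel,
                 Sigma_inv: np.ndarray):
        Y = entry.XBs + E
        Bhat = np.einsum("an,rnp->rap", entry.pinv, Y)
        self.dev_vec = (Bhat - model.B).transpose(0, 2, 1).reshape(E.shape[0], model.m)
        resid = Y - entry.XB0
        self.W = np.einsum("rnp,pq,rnq->r", resid, Sigma_inv, resid)
        self.ebar = resid.mean(axis=1)


class _VecMaxMEWMA:
    def __init__(self, model, cfg, R):
        self.model, self.cfg = model, cfg
        self.z = np.zeros((R, model.m))
        self.g = np.zeros(R)

    def update(self, idx, inp: _StepInputs, entry: _DesignEntry) -> np.ndarray:
        lam, eps = self.cfg.lam, self.cfg.clamp_eps
        z = lam * inp.dev_vec + (1 - lam) * self.z[idx]
        self.z[idx] = z
        quad = (2 - lam) / lam * np.einsum("rm,mn,rn->r", z, entry.Sbinv, z)
        C = _pit(quad, self.model.m, eps)
        g = (1 - lam) * self.g[idx] + lam * _pit(inp.W, entry.df_w, eps)
        self.g[idx] = g
        S = np.sqrt((2 - lam) / lam) * g
        return np.maximum(np.abs(C), np.abs(S))


class _VecMaxMCUSUM:
    def __init__(self, model, cfg, R):
        self.model, self.cfg = model, cfg
        self.U = np.zeros(R)
        self.L = np.zeros(R)
        self.beta_b = cfg.beta_b if cfg.beta_b is not None else default_beta_b(model)
        self._dir = {}

    def _direction(self, entry: _DesignEntry):
        key = entry.n
        if key not in self._dir:
            diff = self.beta_b - self.model.beta_vec
            D2 = float(diff @ entry.Sbinv @ diff)
            if D2 <= 0:
                raise ValueError("beta_b must differ from the in-control vector")
            D = np.sqrt(D2)
            self._dir[key] = ((diff @ entry.Sbinv) / D, D)
        return self._dir[key]

    def update(self, idx, inp: _StepInputs, entry: _DesignEntry) -> np.ndarray:
        a, D = self._direction(entry)
        Z = inp.dev_vec @ a
        quad = np.einsum("rm,mn,rn->r", inp.dev_vec, entry.Sbinv, inp.dev_vec)
        U = np.maximum(0.0, self.U[idx] + Z - 0.5 * D)
        L = np.maximum(0.0, self.L[idx] + quad - self.cfg.cusum_v)
        self.U[idx], self.L[idx] = U, L
        return np.maximum(U, L)


class _VecSSBase:
    """Shared mean/variability transforms for the SS-type charts."""

    def __init__(self, model, cfg, R, Sigma_inv):
        self.model, self.cfg = model, cfg
        self.Sigma_inv = Sigma_inv
        self.z = np.zeros((R, model.p))

    def transformed(self, idx, inp: _StepInputs, entry: _DesignEntry):
        lam, eps = self.cfg.lam, self.cfg.clamp_eps
        z = lam * inp.ebar + (1 - lam) * self.z[idx]
        self.z[idx] = z
        quad = (2 - lam) / lam * entry.n * np.einsum(
            "rp,pq,rq->r", z, self.Sigma_inv, z
        )
        T = _pit(quad, self.model.p, eps)
        F = _pit(inp.W, entry.df_w, eps)
        return T, F


class _VecSSEWMAe(_VecSSBase):
    def __init__(self, model, cfg, R, Sigma_inv):
        super().__init__(model, cfg, R, Sigma_inv)
        self.P = np.zeros(R)
        self.V = np.zeros(R)

    def update(self, idx, inp, entry):
        lam = self.cfg.lam
        T, F = self.transformed(idx, inp, entry)
        P = lam * T + (1 - lam) * self.P[idx]
        V = lam * F + (1 - lam) * self.V[idx]
        self.P[idx], self.V[idx] = P, V
        return P**2 + V**2


class _VecSSCUSUMe(_VecSSBase):
    def __init__(self, model, cfg, R, Sigma_inv):
        super().__init__(model, cfg, R, Sigma_inv)
        self.Dm = np.zeros(R)
        self.Dp = np.zeros(R)
        self.Bm = np.zeros(R)
        self.Bp = np.zeros(R)

    def update(self, idx, inp, entry):
        k1, k2 = self.cfg.k1, self.cfg.k2
        T, F = self.transformed(idx, inp, entry)
        Dm = np.maximum(0.0, -T - k1 + self.Dm[idx])
        Dp = np.maximum(0.0, T - k1 + self.Dp[idx])
        Bm = np.maximum(0.0, -F - k2 + self.Bm[idx])
        Bp = np.maximum(0.0, F - k2 + self.Bp[idx])
        self.Dm[idx], self.Dp[idx] = Dm, Dp
        self.Bm[idx], self.Bp[idx] = Bm, Bp
        M = np.maximum(Dm, Dp)
        N = np.maximum(Bm, Bp)
        return M**2 + N**2


def _make_vec_chart(name, model, cfg, R, Sigma_inv):
    if name == "max_mewma":
        return _VecMaxMEWMA(model, cfg, R)
    if name == "max_mcusum":
        return _VecMaxMCUSUM(model, cfg, R)
    if name == "ss_ewmae":
        return _VecSSEWMAe(model, cfg, R, Sigma_inv)
    if name == "ss_cusume":
        return _VecSSCUSUMe(model, cfg, R, Sigma_inv)
    raise ValueError(f"unknown chart {name!r}")


def first_update_stats(
    chart: str,
    model: ProfileModel,
    cfg: ChartConfig,
    *,
    n: int,
    reps: int,
    seed,
) -> np.ndarray:
    """First-update plotting statistics of ``reps`` fresh in-control charts."""
    rng = np.random.default_rng(seed)
    cholT = linalg.cholesky(model.Sigma, lower=True).T
    Sigma_inv = linalg.inv(model.Sigma)
    entry = _DesignEntry(model, n, IN_CONTROL)
    state = _make_vec_chart(chart, model, cfg, reps, Sigma_inv)
    E = rng.standard_normal((reps, n, model.p)) @ cholT
    inp = _StepInputs(E, entry, model, Sigma_inv)
    return state.update(np.arange(reps), inp, entry)


def fp_run_lengths(
    chart: str,
    model: ProfileModel,
    cfg: ChartConfig,
    shift: ShiftSpec,
    *,
    n: int,
    ucls,
    reps: int,
    cap: int,
    seed,
    collect_stats: bool = False,
):
    """Zero-state run lengths of an FP chart for one or more candidate UCLs.

    Returns ``(rl, stats)`` where ``rl`` has shape (reps, len(ucls)) with
    truncated runs counted at ``cap``; ``stats`` pools the non-signal
    statistics (relative to ``ucls[0]``) when ``collect_stats`` is set.
    """
    cfg = cfg or ChartConfig()
    rng = np.random.default_rng(seed)
    cholT = linalg.cholesky(shift.tau * model.Sigma, lower=True).T
    Sigma_inv = linalg.inv(model.Sigma)
    entry = _DesignEntry(model, n, shift)
    state = _make_vec_chart(chart, model, cfg, reps, Sigma_inv)
    ucls = np.atleast_1d(np.asarray(ucls, dtype=float))
    ucl_max = ucls.max()
    runmax = np.full(reps, -np.inf)
    rl = np.full((reps, ucls.size), cap, dtype=np.int64)
    crossed = np.zeros((reps, ucls.size), dtype=bool)
    alive = np.ones(reps, dtype=bool)
    pooled = [] if collect_stats else None
    for k in range(1, cap + 1):
        idx = np.nonzero(alive)[0]
        if idx.size == 0:
            break
        E = rng.standard_normal((idx.size, n, model.p)) @ cholT
        inp = _StepInputs(E, entry, model, Sigma_inv)
        s = state.update(idx, inp, entry)
        rm = np.maximum(runmax[idx], s)
        runmax[idx] = rm
        sub = crossed[idx]
        newly = (~sub) & (rm[:, None] > ucls[None, :])
        if newly.any():
            rlsub = rl[idx]
            rlsub[newly] = k
            rl[idx] = rlsub
            crossed[idx] = sub | newly
        if pooled is not None:
            keep = s <= ucls[0]
            if keep.any():
                pooled.append(s[keep])
        alive[idx] = rm <= ucl_max
    stats = np.concatenate(pooled) if pooled else (np.empty(0) if collect_stats else None)
    return rl, stats


def fp_statistics(
    chart: str,
    model: ProfileModel,
    cfg: ChartConfig,
    shift: ShiftSpec,
    *,
    n: int,
    reps: int,
    steps: int,
    seed,
) -> np.ndarray:
    """Full (steps, reps) matrix of plotting statistics (no stopping).

    Uses the same draw order as :func:`fp_run_lengths` with all replications
    kept alive, so scalar-chart replays can reproduce it exactly.
    """
    rng = np.random.default_rng(seed)
    cholT = linalg.cholesky(shift.tau * model.Sigma, lower=True).T
    Sigma_inv = linalg.inv(model.Sigma)
    entry = _DesignEntry(model, n, shift)
    state = _make_vec_chart(chart, model, cfg, reps, Sigma_inv)
    idx = np.arange(reps)
    out = np.empty((steps, reps))
    for k in range(steps):
        E = rng.standard_normal((reps, n, model.p)) @ cholT
        out[k] = state.update(idx, _StepInputs(E, entry, model, Sigma_inv), entry)
    return out


def vp_run_lengths(
    chart: str,
    model: ProfileModel,
    cfg: ChartConfig,
    shift: ShiftSpec,
    design: VPDesign,
    *,
    reps: int,
    cap: int,
    seed,
    collect_occupancy: bool = False,
    initial_region: str = "relaxed",
    first_interval: str = "expected",
):
    """Zero-state run lengths and times to signal of a VP chart.

    Memory tracks start at zero and the interval chosen after sample k-1
    elapses before sample k.  No zone information exists before the first
    sample, so its preceding interval defaults to the design's expected
    interval E(t) (``first_interval="region"`` charges the starting
    region's interval instead).  ``initial_region``: "relaxed" starts every
    replication in region 1; "random" draws region 1 with probability P0.
    Returns ``(rl, ts, occupancy)`` where ``occupancy`` counts safe/warning
    classifications and accumulates sample sizes and intervals over
    non-signal samples when requested.
    """
    cfg = cfg or ChartConfig()
    if not np.isfinite([design.UCL1, design.UCL2, design.UWL1, design.UWL2]).all():
        raise ValueError("design limits must be calibrated before simulation")
    rng = np.random.default_rng(seed)
    cholT = linalg.cholesky(shift.tau * model.Sigma, lower=True).T
    Sigma_inv = linalg.inv(model.Sigma)
    entries = {
        1: _DesignEntry(model, design.n1, shift),
        2: _DesignEntry(model, design.n2, shift),
    }
    tracks = {
        1: _make_vec_chart(chart, model, cfg, reps, Sigma_inv),
        2: _make_vec_chart(chart, model, cfg, reps, Sigma_inv),
    }
    if initial_region == "random":
        region = np.where(rng.random(reps) < design.P0, 1, 2).astype(np.int8)
    elif initial_region == "relaxed":
        region = np.ones(reps, dtype=np.int8)
    else:
        raise ValueError("initial_region must be 'random' or 'relaxed'")
    if first_interval == "expected":
        t_elapsed = np.full(reps, float(design.Et))
    elif first_interval == "region":
        t_elapsed = np.where(region == 1, design.t1, design.t2).astype(float)
    else:
        raise ValueError("first_interval must be 'expected' or 'region'")
    rl = np.full(reps, cap, dtype=np.int64)
    ts = np.zeros(reps)
    alive = np.ones(reps, dtype=bool)
    occ = {"safe": 0, "warning": 0, "total_n": 0, "total_time": 0.0} \
        if collect_occupancy else None
    for k in range(1, cap + 1):
        if not alive.any():
            break
        cur_region = region.copy()
        cur_alive = alive.copy()
        for r in (1, 2):
            idx = np.nonzero(cur_alive & (cur_region == r))[0]
            if idx.size == 0:
                continue
            n_r, t_r, UCL_r, UWL_r = design.region_params(r)
            entry = entries[r]
            E = rng.standard_normal((idx.size, n_r, model.p)) @ cholT
            if k > 1:  # the first sample's interval is pre-charged
                t_elapsed[idx] += t_r
            s = tracks[r].update(idx, _StepInputs(E, entry, model, Sigma_inv), entry)
            sig = s > UCL_r
            sidx = idx[sig]
            rl[sidx] = k
            ts[sidx] = t_elapsed[sidx]
            alive[sidx] = False
            ok = idx[~sig]
            safe = s[~sig] <= UWL_r
            region[ok] = np.where(safe, 1, 2)
            if occ is not None:
                occ["safe"] += int(safe.sum())
                occ["warning"] += int((~safe).sum())
                occ["total_n"] += int(n_r) * int(ok.size)
                occ["total_time"] += t_r * int(ok.size)
    ts[alive] = t_elapsed[alive]
    return rl, ts, occ
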