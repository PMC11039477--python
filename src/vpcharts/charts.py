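"""Memory-type chart statistics for simultaneous mean/variability monitoring.

Four single-statistic charts are provided, each a stateful one-sample
recursion yielding a nonnegative plotting statistic:

* ``MaxMEWMA`` — EWMA of the vectorized coefficient deviation plus an EWMA of
  the probability-integral-transformed residual variability, combined with a
  max operator: ``ME = max(|C|, |S|)``.
* ``MaxMCUSUM`` — a directional CUSUM for the coefficient vector and a
  Mahalanobis-deviation CUSUM, combined as ``MC = max(U, L)``.
* ``SSEWMAe`` — EWMAs of the transformed mean-residual and residual-variance
  statistics, combined as a squared sum ``EWe = P^2 + V^2``.
* ``SSCUSUMe`` — two-sided CUSUMs of the same transformed statistics,
  combined as ``CUe = M^2 + N^2``.

All four use the chi-square-to-normal probability integral transform
``x -> Phi^-1(H_df(x))`` so that in-control inputs are (asymptotically)
standard normal.  Updates take the sample's own design matrix, so variable
sample sizes (n1 != n2 in a VP scheme) are handled per sample.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, stats

from .model import ProfileModel, Sample, estimate_coefficients, residual_summary

CHART_NAMES = ("max_mewma", "max_mcusum", "ss_ewmae", "ss_cusume")


def default_beta_b(model: ProfileModel) -> np.ndarray:
    """Default out-of-control reference vector for Max-MCUSUM: the in-control
    coefficient vector with every intercept shifted up by one unit."""
    delta = np.zeros_like(model.B)
    delta[0, :] = 1.0
    return model.beta_vec + delta.T.ravel()


@dataclass(frozen=True)
class ChartConfig:
    """Tuning constants shared by the chart recursions.

    lam : EWMA smoothing weight on the newest sample (default 0.2).
    k1, k2 : CUSUM reference values (allowances) for the SS-CUSUMe mean and
        variability accumulators (defaults 1 and 1.5).
    tau_design : variance multiplier embedded in the Max-MCUSUM allowance
        ``v = ln(tau) * tau/(tau-1)`` (default 1.1).
    beta_b : out-of-control reference coefficient vector for Max-MCUSUM;
        if None a unit intercept shift from the in-control vector is used.
    clamp_eps : probability clamp keeping the normal quantile finite.
    """

    lam: float = 0.2
    k1: float = 1.0
    k2: float = 1.5
    tau_design: float = 1.1
    beta_b: np.ndarray | None = None
    clamp_eps: float = 1e-12

    def __post_init__(self):
        if not 0 < self.lam <= 1:
            raise ValueError("lam must be in (0, 1]")
        if self.k1 <= 0 or self.k2 <= 0:
            raise ValueError("k1 and k2 must be > 0")
        if self.tau_design <= 1:
            raise ValueError("tau_design must be > 1")
        if not 0 < self.clamp_eps < 0.5:
            raise ValueError("clamp_eps must be in (0, 0.5)")
        if self.beta_b is not None:
            object.__setattr__(
                self, "beta_b", np.asarray(self.beta_b, dtype=float).ravel()
            )

    @property
    def cusum_v(self) -> float:
        """Max-MCUSUM variability allowance, v = ln(tau) * tau/(tau-1)."""
        t = self.tau_design
        return float(np.log(t) * t / (t - 1.0))


def normal_chisq_transform(
    x: float | np.ndarray, df: int, clamp_eps: float = 1e-12
) -> float | np.ndarray:
    """Probability integral transform Phi^-1(H_df(x)) with clamping.

    H_df is the chi-square CDF with ``df`` degrees of freedom.  The CDF value
    is clamped to [clamp_eps, 1 - clamp_eps] so the result is finite for all
    nonnegative inputs (x = 0 maps to a large negative number).
    """
    u = stats.chi2.cdf(x, df)
    u = np.clip(u, clamp_eps, 1.0 - clamp_eps)
    out = stats.norm.ppf(u)
    return float(out) if np.isscalar(x) else out


class _PerSizeCache:
    """Per-sample-size precomputation shared by the chart classes."""

    def __init__(self, model: ProfileModel):
        self.model = model
        self.Sigma_inv = linalg.inv(model.Sigma)
        self._by_n: dict[int, dict] = {}

    def for_design(self, X: np.ndarray) -> dict:
        n = X.shape[0]
        key = self._by_n.get(n)
        if key is not None and key["X"].shape == X.shape and np.array_equal(key["X"], X):
            return key
        XtX_inv = linalg.inv(X.T @ X)
        Sigma_beta = np.kron(self.model.Sigma, XtX_inv)
        entry = {
            "X": X.copy(),
            "Sigma_beta_inv": linalg.inv(Sigma_beta),
            "n": n,
        }
        self._by_n[n] = entry
        return entry


class _BaseChart:
    """Common reset/update plumbing for the four chart recursions."""

    name: str = ""

    def __init__(self, model: ProfileModel, config: ChartConfig | None = None):
        self.model = model
        self.config = config or ChartConfig()
        self._cache = _PerSizeCache(model)
        self.reset()

    def reset(self) -> None:
        self.k = 0
        self.last_mean_stat = np.nan
        self.last_var_stat = np.nan
        self._reset_state()

    def update(self, sample: Sample) -> float:
        """Consume one sample and return the plotting statistic."""
        stat = self._update(sample)
        self.k += 1
        return stat

    def clone_state(self):
        """Deep copy of the mutable state (for dual-track bookkeeping)."""
        return copy.deepcopy(self.__dict__)

    def _reset_state(self) -> None:  # pragma: no cover - abstract
        raise NotImplementedError

    def _update(self, sample: Sample) -> float:  # pragma: no cover - abstract
        raise NotImplementedError


class MaxMEWMA(_BaseChart):
    """Max-MEWMA chart: ME_k = max(|C_k|, |S_k|).

    C_k transforms the Mahalanobis norm of the EWMA'd coefficient deviation
    (df p(q+1)); S_k is sqrt((2-lam)/lam) times the EWMA of the transformed
    residual variability statistic W_k (chi-square np in control).
    """

    name = "max_mewma"

    def _reset_state(self) -> None:
        self.z = np.zeros(self.model.m)
        self.g = 0.0

    def _update(self, sample: Sample) -> float:
        cfg = self.config
        lam = cfg.lam
        entry = self._cache.for_design(sample.X)
        bh = estimate_coefficients(sample)
        dev = bh.beta_vec - self.model.beta_vec
        self.z = lam * dev + (1 - lam) * self.z
        quad = (2 - lam) / lam * float(self.z @ entry["Sigma_beta_inv"] @ self.z)
        C = normal_chisq_transform(quad, self.model.m, cfg.clamp_eps)
        W = residual_summary(sample, self.model).W
        self.g = (1 - lam) * self.g + lam * normal_chisq_transform(
            W, sample.n * self.model.p, cfg.clamp_eps
        )
        S = np.sqrt((2 - lam) / lam) * self.g
        self.last_mean_stat, self.last_var_stat = C, S
        return combine_max(C, S)


class MaxMCUSUM(_BaseChart):
    """Max-MCUSUM chart: MC_k = max(U_k, L_k).

    U is a one-sided CUSUM along the direction from the in-control to the
    reference out-of-control coefficient vector; L accumulates the
    coefficient-vector Mahalanobis deviation less the allowance v.
    """

    name = "max_mcusum"

    def _reset_state(self) -> None:
        self.U = 0.0
        self.L = 0.0

    def _update(self, sample: Sample) -> float:
        cfg = self.config
        entry = self._cache.for_design(sample.X)
        Sbi = entry["Sigma_beta_inv"]
        beta_g = self.model.beta_vec
        beta_b = cfg.beta_b if cfg.beta_b is not None else default_beta_b(self.model)
        diff = beta_b - beta_g
        D2 = float(diff @ Sbi @ diff)
        if D2 <= 0:
            raise ValueError("beta_b must differ from the in-control vector")
        D = np.sqrt(D2)
        a = (diff @ Sbi) / D
        dev = estimate_coefficients(sample).beta_vec - beta_g
        Z = float(a @ dev)
        self.U = max(0.0, self.U + Z - 0.5 * D)
        self.L = max(0.0, self.L + float(dev @ Sbi @ dev) - cfg.cusum_v)
        self.last_mean_stat, self.last_var_stat = self.U, self.L
        return combine_max(self.U, self.L)


class SSEWMAe(_BaseChart):
    """SS-EWMAe chart on the residuals: EWe_k = P_k^2 + V_k^2.

    The mean track EWMAs the average residual vector and transforms its
    Mahalanobis norm under the asymptotic EWMA covariance
    (lam/(2-lam)) * Sigma/n (chi-square p in control); the variability track
    EWMAs the transformed f_k (chi-square np in control).
    """

    name = "ss_ewmae"

    def _reset_state(self) -> None:
        self.z = np.zeros(self.model.p)
        self.P = 0.0
        self.V = 0.0

    def _update(self, sample: Sample) -> float:
        cfg = self.config
        lam = cfg.lam
        rs = residual_summary(sample, self.model)
        self.z = lam * rs.ebar + (1 - lam) * self.z
        quad = (
            (2 - lam) / lam * sample.n * float(self.z @ self._cache.Sigma_inv @ self.z)
        )
        T = normal_chisq_transform(quad, self.model.p, cfg.clamp_eps)
        self.P = lam * T + (1 - lam) * self.P
        F = normal_chisq_transform(rs.f, sample.n * self.model.p, cfg.clamp_eps)
        self.V = lam * F + (1 - lam) * self.V
        self.last_mean_stat, self.last_var_stat = self.P, self.V
        return combine_ss(self.P, self.V)


class SSCUSUMe(_BaseChart):
    """SS-CUSUMe chart on the residuals: CUe_k = M_k^2 + N_k^2 with
    M = max(D-, D+) and N = max(B-, B+), two-sided CUSUMs of the transformed
    statistics T_k and F_k with reference values k1 and k2."""

    name = "ss_cusume"

    def _reset_state(self) -> None:
        self.Dminus = 0.0
        self.Dplus = 0.0
        self.Bminus = 0.0
        self.Bplus = 0.0
        self.z = np.zeros(self.model.p)

    def _transformed(self, sample: Sample) -> tuple[float, float]:
        cfg = self.config
        lam = cfg.lam
        rs = residual_summary(sample, self.model)
        self.z = lam * rs.ebar + (1 - lam) * self.z
        quad = (
            (2 - lam) / lam * sample.n * float(self.z @ self._cache.Sigma_inv @ self.z)
        )
        T = normal_chisq_transform(quad, self.model.p, cfg.clamp_eps)
        F = normal_chisq_transform(rs.f, sample.n * self.model.p, cfg.clamp_eps)
        return T, F

    def step_transformed(self, T: float, F: float) -> float:
        """Advance the four accumulators given already-transformed T, F."""
        cfg = self.config
        self.Dminus = max(0.0, -T - cfg.k1 + self.Dminus)
        self.Dplus = max(0.0, T - cfg.k1 + self.Dplus)
        self.Bminus = max(0.0, -F - cfg.k2 + self.Bminus)
        self.Bplus = max(0.0, F - cfg.k2 + self.Bplus)
        M = max(self.Dminus, self.Dplus)
        N = max(self.Bminus, self.Bplus)
        self.last_mean_stat, self.last_var_stat = M, N
        return combine_ss(M, N)

    def _update(self, sample: Sample) -> float:
        T, F = self._transformed(sample)
        return self.step_transformed(T, F)


def combine_max(mean_stat: float, var_stat: float) -> float:
    """Max-operator combination, max(|mean|, |variability|) >= 0."""
    return max(abs(mean_stat), abs(var_stat))


def combine_ss(mean_stat: float, var_stat: float) -> float:
    """Squared-sum combination, mean^2 + variability^2 >= 0."""
    return mean_stat**2 + var_stat**2


_CHART_CLASSES = {
    "max_mewma": MaxMEWMA,
    "max_mcusum": MaxMCUSUM,
    "ss_ewmae": SSEWMAe,
    "ss_cusume": SSCUSUMe,
}


def make_chart(name: str, model: ProfileModel, config: ChartConfig | None = None):
    """Instantiate a chart by name (one of CHART_NAMES)."""
    try:
        cls = _CHART_CLASSES[name]
    except KeyError:
        raise ValueError(f"unknown chart {name!r}; choose from {CHART_NAMES}") from None
    return cls(model, config)


# Thin functional wrappers over the stateful classes -------------------------

def update_max_mewma(chart: MaxMEWMA, sample: Sample) -> float:
    return chart.update(sample)


def update_max_mcusum(chart: MaxMCUSUM, sample: Sample) -> float:
    return chart.update(sample)


def update_ss_ewmae(chart: SSEWMAe, sample: Sample) -> float:
    return chart.update(sample)


def update_ss_cusume(chart: SSCUSUMe, T: float, F: float) -> float:
    return chart.step_transformed(T, F)
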