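"""Variable-parameters (VP) scheme: design solver and zone state machine.

A VP scheme alternates between two parameter settings.  After a sample whose
statistic falls in the safe zone [0, UWL] the next sample uses the relaxed
setting (n1, t1, UCL1, UWL1, region 1); after a warning-zone sample
(UWL, UCL] the tightened setting (n2, t2, UCL2, UWL2, region 2) is used; a
statistic above the UCL is a signal.  The free design parameters are tied to
their in-control expectations through the safe-zone probability P0:

    E(n) = n1*P0 + n2*(1-P0),  E(t) = t1*P0 + t2*(1-P0),
    E(alpha) = alpha1*P0 + alpha2*(1-P0).

Memory statistics are kept in two region tracks: only the track matching the
active region advances at each sample, the other is frozen, so statistics
accumulated in one region never leak into the other.
"""

from __future__ import annotations

import enum
import hashlib
import pickle
from dataclasses import dataclass, replace

import numpy as np

from .model import Sample


class Zone(enum.Enum):
    SAFE = "safe"
    WARNING = "warning"
    SIGNAL = "signal"


@dataclass(frozen=True)
class VPDesign:
    """Full VP design: free parameters, derived parameters and limits."""

    n1: int
    n2: int
    t1: float
    t2: float
    alpha1: float
    alpha2: float
    P0: float
    En: float
    Et: float
    Ealpha: float
    UCL1: float = np.inf
    UCL2: float = np.inf
    UWL1: float = np.inf
    UWL2: float = np.inf

    def __post_init__(self):
        # equalities are allowed so a degenerate design can emulate FP
        if not self.n1 <= self.n2:
            raise ValueError("need n1 <= n2")
        if not self.t2 <= self.t1:
            raise ValueError("need t2 <= t1")
        if not self.alpha1 <= self.alpha2:
            raise ValueError("need alpha1 <= alpha2")
        if not 0 < self.P0 < 1:
            raise ValueError("P0 must be in (0, 1)")

    def with_limits(self, UCL1, UCL2, UWL1, UWL2) -> "VPDesign":
        if not UCL2 <= UCL1:
            raise ValueError("need UCL2 <= UCL1")
        if not (UWL1 < UCL1 and UWL2 < UCL2):
            raise ValueError("warning limits must lie below their control limits")
        return replace(self, UCL1=UCL1, UCL2=UCL2, UWL1=UWL1, UWL2=UWL2)

    def region_params(self, region: int) -> tuple[int, float, float, float]:
        """(n, t, UCL, UWL) for region 1 (relaxed) or 2 (tightened)."""
        if region == 1:
            return self.n1, self.t1, self.UCL1, self.UWL1
        if region == 2:
            return self.n2, self.t2, self.UCL2, self.UWL2
        raise ValueError("region must be 1 or 2")


def solve_design(
    n1: int,
    n2: int,
    En: float,
    t2: float,
    Et: float,
    alpha1: float,
    Ealpha: float,
) -> VPDesign:
    """Solve the three VP constraints for P0, t1 and alpha2.

    P0 = (E(n) - n2)/(n1 - n2);
    t1 = (E(t)(n1 - n2) - t2(n1 - E(n))) / (E(n) - n2);
    alpha2 = (E(alpha)(n1 - n2) - alpha1(E(n) - n2)) / (n1 - E(n)).
    """
    if n1 == n2:
        raise ValueError("n1 and n2 must differ")
    if not (min(n1, n2) < En < max(n1, n2)):
        raise ValueError("E(n) must lie strictly between n1 and n2")
    P0 = (En - n2) / (n1 - n2)
    t1 = (Et * (n1 - n2) - t2 * (n1 - En)) / (En - n2)
    alpha2 = (Ealpha * (n1 - n2) - alpha1 * (En - n2)) / (n1 - En)
    if not alpha1 < alpha2 < 1:
        raise ValueError(f"derived alpha2={alpha2} violates alpha1 < alpha2 < 1")
    if not t2 < t1:
        raise ValueError(f"derived t1={t1} is not above t2={t2}")
    return VPDesign(
        n1=int(n1), n2=int(n2), t1=t1, t2=t2, alpha1=alpha1, alpha2=alpha2,
        P0=P0, En=En, Et=Et, Ealpha=Ealpha,
    )


def classify_zone(stat: float, UWL: float, UCL: float) -> Zone:
    """Safe iff stat <= UWL, warning iff UWL < stat <= UCL, else signal."""
    if UWL >= UCL:
        raise ValueError("need UWL < UCL")
    if stat <= UWL:
        return Zone.SAFE
    if stat <= UCL:
        return Zone.WARNING
    return Zone.SIGNAL


def next_parameters(zone: Zone, design: VPDesign) -> tuple[int, float, float, float, int]:
    """Parameters (n, t, UCL, UWL, region) for the next sample after ``zone``."""
    if zone is Zone.SAFE:
        return (*design.region_params(1), 1)
    if zone is Zone.WARNING:
        return (*design.region_params(2), 2)
    raise ValueError("no next sample after a signal; handle the alarm")


def _digest(chart) -> str:
    """Stable digest of a chart's mutable state (frozen-track integrity)."""
    return hashlib.sha256(pickle.dumps(chart.clone_state())).hexdigest()


class DualTracker:
    """Region-split memory tracking for a VP monitoring run.

    Holds two independent chart instances (one per region); each incoming
    sample advances only the track of the current region, classifies its
    statistic against that region's limits and selects the next region.
    Runs start in region 1 (relaxed parameters) with both tracks at zero;
    pass ``initial_region=2`` or randomize externally to override.
    """

    def __init__(self, chart_factory, design: VPDesign, *, initial_region: int = 1):
        self.tracks = {1: chart_factory(), 2: chart_factory()}
        self.design = design
        self.region = initial_region
        self.elapsed_time = 0.0
        self.samples_taken = 0
        self.cumulative_n = 0

    @property
    def active_track(self):
        return self.tracks[self.region]

    def required_n(self) -> int:
        return self.design.region_params(self.region)[0]

    def pending_interval(self) -> float:
        """Sampling interval elapsing before the next sample."""
        return self.design.region_params(self.region)[1]

    def step(self, sample: Sample) -> tuple[float, Zone]:
        """Advance the active track with ``sample``; returns (stat, zone).

        The interval preceding the sample is added to ``elapsed_time``
        before the update; the monitoring clock starts at the first sample,
        whose preceding interval is zero.  The inactive track is untouched.
        """
        n_req, t, UCL, UWL = self.design.region_params(self.region)
        if sample.n != n_req:
            raise ValueError(
                f"region {self.region} requires n={n_req}, got sample of n={sample.n}"
            )
        self.elapsed_time += t if self.samples_taken > 0 else 0.0
        self.samples_taken += 1
        self.cumulative_n += sample.n
        stat = self.tracks[self.region].update(sample)
        zone = classify_zone(stat, UWL, UCL)
        if zone is not Zone.SIGNAL:
            self.region = 1 if zone is Zone.SAFE else 2
        return stat, zone

    def frozen_track_digest(self) -> str:
        """Digest of the currently inactive track's state."""
        other = 2 if self.region == 1 else 1
        return _digest(self.tracks[other])
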