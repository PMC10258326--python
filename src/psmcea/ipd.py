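"""Pseudo individual-patient data (IPD) for partitioned survival modelling.

Two routes produce per-subject ``(time, event)`` records for one trial arm
and endpoint:

* :func:`reconstruct_ipd` — deterministic reconstruction from digitized
  Kaplan–Meier coordinates, for when published curves have been read off
  with a graph digitizer.  No number-at-risk table is assumed: events are
  allocated per digitized interval by rounding against the current risk
  set, and subjects still at risk after the last coordinate are censored
  administratively.
* :func:`generate_synthetic_trial` — a seeded generator emulating a
  two-arm randomized trial (2:1 allocation, log-normal PFS/OS with
  configurable medians, staggered accrual with a fixed data cutoff), for
  development and testing when no digitized curves are supplied.  Defaults
  follow the CHOICE-01 trial of toripalimab + chemotherapy in advanced
  NSCLC (n=465 at 2:1; median PFS 8.3 vs 5.6 months; control-arm median
  OS 17.1 months; 16.2 months median follow-up).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

ARMS = ("TC", "PC")
ENDPOINTS = ("PFS", "OS")

__all__ = [
    "ARMS",
    "ENDPOINTS",
    "CurveValidationError",
    "DigitizedCurve",
    "PseudoIPD",
    "SyntheticTrialSpec",
    "reconstruct_ipd",
    "generate_synthetic_trial",
    "simulate_censored_lognormal",
    "simulate_two_arm_exponential",
    "accrual_censoring_times",
]


class CurveValidationError(ValueError):
    """A digitized curve violates monotonicity or range constraints."""


@dataclass(frozen=True)
class DigitizedCurve:
    """Ordered (time, survival) coordinates read off a published KM curve.

    A leading ``(0, 1.0)`` anchor is prepended automatically if absent.
    Times must be strictly increasing and survival non-increasing in
    ``[0, 1]``; violations raise :class:`CurveValidationError` naming the
    offending point.
    """

    endpoint: str
    arm: str
    points: tuple[tuple[float, float], ...]
    n_at_risk_start: int

    def __post_init__(self) -> None:
        pts = [(float(t), float(s)) for t, s in self.points]
        if not pts or pts[0][0] > 0.0:
            pts.insert(0, (0.0, 1.0))
        if pts[0] != (0.0, 1.0):
            raise CurveValidationError(
                f"first point must be (0, 1.0), got {pts[0]}"
            )
        for i, (t, s) in enumerate(pts):
            if not 0.0 <= s <= 1.0:
                raise CurveValidationError(
                    f"survival out of [0,1] at point {i}: ({t}, {s})"
                )
            if i > 0:
                tp, sp = pts[i - 1]
                if t <= tp:
                    raise CurveValidationError(
                        f"times not strictly increasing at point {i}: ({t}, {s})"
                    )
                if s > sp + 1e-12:
                    raise CurveValidationError(
                        f"survival increases at point {i}: ({t}, {s}) after ({tp}, {sp})"
                    )
        if self.n_at_risk_start <= 0:
            raise CurveValidationError("n_at_risk_start must be positive")
        object.__setattr__(self, "points", tuple(pts))

    @classmethod
    def from_csv(cls, path: str | Path, endpoint: str, arm: str,
                 n_at_risk_start: int) -> "DigitizedCurve":
        """Read a ``time_months,survival`` CSV produced by a digitizer."""
        df = pd.read_csv(path)
        pts = tuple(zip(df["time_months"].astype(float), df["survival"].astype(float)))
        return cls(endpoint=endpoint, arm=arm, points=pts,
                   n_at_risk_start=int(n_at_risk_start))


@dataclass(frozen=True)
class PseudoIPD:
    """Per-subject right-censored records for one arm and endpoint."""

    endpoint: str
    arm: str
    times: np.ndarray  # months, > 0
    events: np.ndarray  # 1 = event, 0 = censored

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        e = np.asarray(self.events, dtype=int)
        if t.shape != e.shape:
            raise ValueError("times and events must have equal length")
        if np.any(t <= 0):
            raise ValueError("all record times must be positive")
        if not np.isin(e, (0, 1)).all():
            raise ValueError("events must be 0/1")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "events", e)

    @property
    def n(self) -> int:
        return int(self.times.size)

    @property
    def n_events(self) -> int:
        return int(self.events.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_months": self.times, "event": self.events})

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, endpoint: str, arm: str) -> "PseudoIPD":
        df = pd.read_csv(path)
        return cls(endpoint=endpoint, arm=arm,
                   times=df["time_months"].to_numpy(dtype=float),
                   events=df["event"].to_numpy(dtype=int))


def reconstruct_ipd(curve: DigitizedCurve, censor_time: float) -> PseudoIPD:
    """Reconstruct pseudo-IPD from digitized KM coordinates.

    Events in interval ``(t_{i-1}, t_i]`` are allocated as
    ``k_i = round(n_i * (1 - S_i / S_hat_{i-1}))`` against the running
    risk set ``n_i`` and the *reconstructed* survival ``S_hat`` (so
    rounding errors do not accumulate), placed at the interval midpoint.
    Subjects implied still at risk past the last coordinate are censored
    at ``censor_time``.  The Kaplan–Meier estimator recomputed from the
    output reproduces each digitized survival value within the rounding
    resolution ``0.5 / n`` of the current risk set.
    """
    pts = curve.points
    if censor_time < pts[-1][0]:
        raise ValueError(
            f"censor_time {censor_time} precedes last curve time {pts[-1][0]}"
        )
    n_rem = curve.n_at_risk_start
    s_hat = 1.0
    times: list[float] = []
    events: list[int] = []
    for (t0, _s0), (t1, s1) in zip(pts[:-1], pts[1:]):
        if n_rem == 0 or s_hat <= 0.0:
            break
        k = int(round(n_rem * (1.0 - s1 / s_hat)))
        k = max(0, min(k, n_rem))
        if k:
            mid = 0.5 * (t0 + t1)
            times.extend([mid] * k)
            events.extend([1] * k)
            s_hat *= (n_rem - k) / n_rem
            n_rem -= k
    if n_rem:
        times.extend([float(censor_time)] * n_rem)
        events.extend([0] * n_rem)
    return PseudoIPD(endpoint=curve.endpoint, arm=curve.arm,
                     times=np.asarray(times), events=np.asarray(events))


@dataclass(frozen=True)
class SyntheticTrialSpec:
    """Parameters of the synthetic two-arm trial generator.

    Defaults emulate CHOICE-01: 465 subjects randomized 2:1 (TC:PC),
    median PFS 8.3 vs 5.6 months, control median OS 17.1 months, median
    follow-up 16.2 months.  ``os_median_tc`` was not reached in the trial
    (95% CI lower bound 21.7 months); the default of 28 months is a
    documented placeholder, not a trial estimate.
    """

    n_total: int = 465
    allocation_ratio: tuple[int, int] = (2, 1)  # TC : PC
    pfs_median_tc: float = 8.3
    pfs_median_pc: float = 5.6
    os_median_tc: float = 28.0  # placeholder: not reached in the trial
    os_median_pc: float = 17.1
    log_sd_pfs: float = 0.9
    log_sd_os: float = 0.9
    followup_median: float = 16.2
    copula_rho: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("pfs_median_tc", "pfs_median_pc", "os_median_tc",
                     "os_median_pc", "log_sd_pfs", "log_sd_os",
                     "followup_median"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_total < 10:
            raise ValueError("n_total must be >= 10")
        if min(self.allocation_ratio) <= 0:
            raise ValueError("allocation parts must be positive")
        if not -1.0 <= self.copula_rho <= 1.0:
            raise ValueError("copula_rho must be in [-1, 1]")

    @property
    def arm_sizes(self) -> dict[str, int]:
        a, b = self.allocation_ratio
        n_tc = int(round(self.n_total * a / (a + b)))
        return {"TC": n_tc, "PC": self.n_total - n_tc}


def accrual_censoring_times(n: int, followup_median: float,
                            rng: np.random.Generator) -> np.ndarray:
    """Administrative censoring times under staggered uniform accrual.

    Subjects accrue uniformly over a window of ``followup_median / 2``
    and data are cut at ``followup_median + window / 2`` after the first
    enrolment, so potential follow-up is Uniform(3m/4, 5m/4) with median
    exactly ``followup_median`` — no tuning needed.
    """
    window = followup_median / 2.0
    cutoff = followup_median + window / 2.0
    entry = rng.uniform(0.0, window, size=n)
    return cutoff - entry


def simulate_censored_lognormal(median: float, log_sd: float, n: int,
                                followup_median: float,
                                rng: np.random.Generator
                                ) -> tuple[np.ndarray, np.ndarray]:
    """Draw log-normal event times (median ``median``) with accrual censoring.

    Returns ``(observed_times, events)``; the single-endpoint building
    block of the trial generator, also used stand-alone for
    parameter-recovery studies.
    """
    t = np.exp(np.log(median) + log_sd * rng.standard_normal(n))
    c = accrual_censoring_times(n, followup_median, rng)
    obs = np.minimum(t, c)
    return obs, (t <= c).astype(int)


def generate_synthetic_trial(spec: SyntheticTrialSpec
                             ) -> dict[tuple[str, str], PseudoIPD]:
    """Generate pseudo-IPD for TC/PC x PFS/OS under a synthetic trial.

    OS is log-normal with the arm's OS median; PFS has an exactly
    log-normal marginal with the arm's PFS median, coupled to OS through
    a Gaussian copula (correlation ``copula_rho``) and clamped to
    ``PFS <= OS`` — the structural assumption of the partitioned survival
    model.  Both endpoints share the subject's administrative censoring
    time (one data cutoff).  Identical spec (including seed) gives
    identical output.
    """
    rng = np.random.default_rng(spec.seed)
    medians = {
        "TC": {"PFS": spec.pfs_median_tc, "OS": spec.os_median_tc},
        "PC": {"PFS": spec.pfs_median_pc, "OS": spec.os_median_pc},
    }
    out: dict[tuple[str, str], PseudoIPD] = {}
    rho = spec.copula_rho
    for arm in ARMS:
        n = spec.arm_sizes[arm]
        z_os = rng.standard_normal(n)
        z_ind = rng.standard_normal(n)
        z_pfs = rho * z_os + np.sqrt(1.0 - rho * rho) * z_ind
        t_os = np.exp(np.log(medians[arm]["OS"]) + spec.log_sd_os * z_os)
        t_pfs = np.exp(np.log(medians[arm]["PFS"]) + spec.log_sd_pfs * z_pfs)
        t_pfs = np.minimum(t_pfs, t_os)
        c = accrual_censoring_times(n, spec.followup_median, rng)
        for endpoint, t in (("PFS", t_pfs), ("OS", t_os)):
            out[(arm, endpoint)] = PseudoIPD(
                endpoint=endpoint, arm=arm,
                times=np.minimum(t, c), events=(t <= c).astype(int))
    return out


def simulate_two_arm_exponential(hazard_ratio: float, control_median: float,
                                 n_total: int, allocation_ratio: tuple[int, int],
                                 censor_time: float, rng: np.random.Generator
                                 ) -> pd.DataFrame:
    """Two-arm exponential trial with fixed administrative censoring.

    Control-arm rate is ``ln 2 / control_median``; the treated arm's rate
    is that times ``hazard_ratio``.  Returns a tidy frame with columns
    ``time_months``, ``event``, ``treated`` suitable for a Cox fit.
    """
    a, b = allocation_ratio
    n_trt = int(round(n_total * a / (a + b)))
    n_ctl = n_total - n_trt
    rate_ctl = np.log(2.0) / control_median
    t_trt = rng.exponential(1.0 / (rate_ctl * hazard_ratio), size=n_trt)
    t_ctl = rng.exponential(1.0 / rate_ctl, size=n_ctl)
    t = np.concatenate([t_trt, t_ctl])
    treated = np.concatenate([np.ones(n_trt, dtype=int), np.zeros(n_ctl, dtype=int)])
    obs = np.minimum(t, censor_time)
    return pd.DataFrame({
        "time_months": obs,
        "event": (t <= censor_time).astype(int),
        "treated": treated,
    })
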