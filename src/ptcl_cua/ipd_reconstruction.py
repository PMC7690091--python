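"""Pseudo individual-patient data (IPD) from digitized Kaplan-Meier curves.

Published survival evidence usually comes as a figure, not as patient-level
data. Following the standard practice for survival extrapolation in economic
models, this module inverts digitized KM survival coordinates back into a
pseudo-IPD sample (Guyot-style reconstruction), re-estimates the KM curve,
and provides the validation statistics used to check the reconstruction
against published summaries: median OS, Cox hazard ratio, and a
Grambsch-Therneau proportional-hazards test.

Two reconstruction modes are supported:

* **risk-table mode** — numbers-at-risk at stated times constrain both the
  event and the censoring counts per interval (the full Guyot inversion);
* **total-n mode** — only the starting sample size is known; events are
  allocated from successive survival ratios assuming no censoring before
  the last follow-up time, and all remaining subjects are censored there.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import proportional_hazard_test

__all__ = [
    "DigitizedCurve",
    "IPDSample",
    "StepSurvival",
    "CoxHRResult",
    "PHTestResult",
    "reconstruct_ipd",
    "km_estimator",
    "median_survival",
    "cox_hr",
    "ph_test",
]


@dataclass
class IPDSample:
    """(time, event) records for one treatment arm; times in weeks."""

    time: np.ndarray
    event: np.ndarray
    arm_label: str = ""

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=bool)
        if self.time.size == 0:
            raise ValueError("IPD sample must contain at least one record")
        if self.time.shape != self.event.shape:
            raise ValueError("time and event arrays must have equal length")
        if np.any(self.time <= 0):
            raise ValueError("all follow-up times must be positive")

    @property
    def n(self) -> int:
        return int(self.time.size)

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_weeks": self.time,
                "event": self.event.astype(int),
                "arm": self.arm_label,
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "IPDSample":
        df = pd.read_csv(path)
        label = str(df["arm"].iloc[0]) if "arm" in df else ""
        return cls(df["time_weeks"].to_numpy(), df["event"].to_numpy(dtype=bool), label)


@dataclass
class DigitizedCurve:
    """Digitized KM coordinates for one arm, plus optional numbers at risk.

    ``risk_table`` rows are (time, n at risk), where n counts subjects with
    observed time >= that time point.
    """

    times: np.ndarray
    survival: np.ndarray
    total_n: int
    risk_table: Optional[pd.DataFrame] = None  # columns time_weeks, n_at_risk
    arm_label: str = ""

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.survival = np.asarray(self.survival, dtype=float)
        if self.times.size < 1:
            raise ValueError("curve needs at least the (0, 1.0) coordinate")
        if self.times[0] != 0.0 or abs(self.survival[0] - 1.0) > 1e-12:
            raise ValueError("first coordinate must be (0, 1.0)")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("coordinate times must be strictly increasing")
        if np.any(np.diff(self.survival) > 1e-12):
            raise ValueError("survival coordinates must be non-increasing")
        if np.any((self.survival < -1e-12) | (self.survival > 1 + 1e-12)):
            raise ValueError("survival coordinates must lie in [0, 1]")
        if self.total_n < 1:
            raise ValueError("total_n must be >= 1")
        if self.risk_table is not None:
            rt = self.risk_table
            if np.any(np.diff(rt["n_at_risk"].to_numpy()) > 0):
                raise ValueError("numbers at risk must be non-increasing")

    def to_csv(self, path, risk_path=None) -> None:
        pd.DataFrame({"time_weeks": self.times, "survival": self.survival}).to_csv(
            path, index=False
        )
        if risk_path is not None and self.risk_table is not None:
            self.risk_table.to_csv(risk_path, index=False)

    @classmethod
    def from_csv(cls, path, total_n, risk_path=None, arm_label="") -> "DigitizedCurve":
        df = pd.read_csv(path)
        rt = pd.read_csv(risk_path) if risk_path is not None else None
        return cls(
            df["time_weeks"].to_numpy(),
            df["survival"].to_numpy(),
            total_n=int(total_n),
            risk_table=rt,
            arm_label=arm_label,
        )


@dataclass
class StepSurvival:
    """A Kaplan-Meier step function summarized at its drop (event) times."""

    drop_times: np.ndarray
    survival_after: np.ndarray
    n_at_risk: np.ndarray
    deaths: np.ndarray
    censored: np.ndarray
    n_total: int

    def survival_at(self, t: float) -> float:
        """S(t); right-continuous step evaluation."""
        idx = np.searchsorted(self.drop_times, t, side="right")
        return 1.0 if idx == 0 else float(self.survival_after[idx - 1])


@dataclass
class CoxHRResult:
    hr: float
    ci_low: float
    ci_high: float
    p_value: float


@dataclass
class PHTestResult:
    p_value: float
    reject_ph: bool
    alpha: float = 0.05


def km_estimator(ipd: IPDSample) -> StepSurvival:
    """Product-limit estimate.

    Ties at equal times follow the standard convention: events are
    processed before censorings, so subjects censored at a drop time are
    still at risk for that drop.
    """
    kmf = KaplanMeierFitter()
    kmf.fit(ipd.time, event_observed=ipd.event)
    tab = kmf.event_table
    drops = tab[tab["observed"] > 0]
    surv = kmf.survival_function_["KM_estimate"]
    s_after = surv.loc[drops.index].to_numpy()
    return StepSurvival(
        drop_times=drops.index.to_numpy(dtype=float),
        survival_after=s_after,
        n_at_risk=drops["at_risk"].to_numpy(dtype=int),
        deaths=drops["observed"].to_numpy(dtype=int),
        censored=drops["censored"].to_numpy(dtype=int),
        n_total=ipd.n,
    )


def median_survival(surv: StepSurvival) -> Optional[float]:
    """Smallest time with S(t) <= 0.5, or None when the curve never gets
    there (the undefined-median flag is explicit, never a sentinel)."""
    below = surv.survival_after <= 0.5 + 1e-12
    if not below.any():
        return None
    return float(surv.drop_times[np.argmax(below)])


def _allocate_events(n_at_risk: int, s_model: float, s_target: float) -> int:
    """Integer event count at one drop minimizing |S_model' - S_target|.

    Rounding the continuous solution n*(1 - s_target/s_model) is exactly the
    integer minimizer because the reconstructed survival is linear in the
    event count.
    """
    if n_at_risk <= 0 or s_model <= 0:
        return 0
    d = int(round(n_at_risk * (1.0 - s_target / s_model)))
    return min(max(d, 0), n_at_risk)


def reconstruct_ipd(curve: DigitizedCurve, arm_label: Optional[str] = None) -> IPDSample:
    """Invert digitized KM coordinates into a pseudo-IPD sample.

    With a risk table the censoring count per risk interval is pinned down
    by the drop in numbers at risk net of allocated events (infeasible
    tables raise, naming the interval). Without one, no censoring is
    assumed before the last coordinate, where every remaining subject is
    censored. Events + censorings always total ``curve.total_n``.
    """
    label = curve.arm_label if arm_label is None else arm_label
    times: list[float] = []
    events: list[bool] = []

    coords = list(zip(curve.times[1:], curve.survival[1:]))

    def _emit(t, n_events=0, n_censored=0):
        times.extend([t] * (n_events + n_censored))
        events.extend([True] * n_events + [False] * n_censored)

    if curve.risk_table is None:
        n = curve.total_n
        s_model = 1.0
        last_t = curve.times[-1] if len(coords) else 1.0
        for t, s in coords:
            d = _allocate_events(n, s_model, s)
            if d > 0:
                _emit(t, n_events=d)
                s_model *= 1.0 - d / n
                n -= d
        if n > 0:
            _emit(max(last_t, np.finfo(float).tiny), n_censored=n)
    else:
        rt_t = curve.risk_table["time_weeks"].to_numpy(dtype=float)
        rt_n = curve.risk_table["n_at_risk"].to_numpy(dtype=int)
        if rt_n[0] > curve.total_n:
            raise ValueError("risk table exceeds total_n at its first entry")
        s_model = 1.0
        ci = 0  # coordinate cursor
        for j in range(len(rt_t)):
            n_cur = int(rt_n[j])
            upper = rt_t[j + 1] if j + 1 < len(rt_t) else np.inf
            last_coord_t = None
            while ci < len(coords) and coords[ci][0] < upper:
                t, s = coords[ci]
                d = _allocate_events(n_cur, s_model, s)
                if d > 0:
                    _emit(t, n_events=d)
                    s_model *= 1.0 - d / n_cur
                    n_cur -= d
                last_coord_t = t
                ci += 1
            n_next = int(rt_n[j + 1]) if j + 1 < len(rt_t) else 0
            c = n_cur - n_next
            if c < 0:
                raise ValueError(
                    f"risk table infeasible in interval {j} "
                    f"[{rt_t[j]}, {upper}): needs {-c} extra subjects"
                )
            if c > 0:
                # censor after the interval's last event; KM at drop times
                # is invariant to the exact within-interval censor time
                t_cens = last_coord_t
                if t_cens is None:
                    t_cens = rt_t[j] if rt_t[j] > 0 else 0.5 * min(upper, 1.0)
                _emit(t_cens, n_censored=c)
        missing = curve.total_n - len(times)
        if missing > 0:  # subjects the risk table never saw leave the study
            _emit(curve.times[-1], n_censored=missing)

    return IPDSample(np.array(times), np.array(events), arm_label=label)


def _two_arm_frame(ipd_a: IPDSample, ipd_b: IPDSample) -> pd.DataFrame:
    if ipd_a.n_events == 0 and ipd_b.n_events == 0:
        raise ValueError("no events in either arm")
    return pd.DataFrame(
        {
            "time": np.concatenate([ipd_a.time, ipd_b.time]),
            "event": np.concatenate([ipd_a.event, ipd_b.event]).astype(int),
            "arm": np.concatenate([np.ones(ipd_a.n), np.zeros(ipd_b.n)]),
        }
    )


def cox_hr(ipd_a: IPDSample, ipd_b: IPDSample) -> CoxHRResult:
    """Cox partial-likelihood hazard ratio of arm A vs arm B (Breslow tie
    handling, Wald 95% CI)."""
    df = _two_arm_frame(ipd_a, ipd_b)
    cph = CoxPHFitter()
    cph.fit(df, duration_col="time", event_col="event")
    row = cph.summary.loc["arm"]
    return CoxHRResult(
        hr=float(row["exp(coef)"]),
        ci_low=float(row["exp(coef) lower 95%"]),
        ci_high=float(row["exp(coef) upper 95%"]),
        p_value=float(row["p"]),
    )


def ph_test(ipd_a: IPDSample, ipd_b: IPDSample, alpha: float = 0.05) -> PHTestResult:
    """Grambsch-Therneau test of proportional hazards for the arm covariate
    (correlation of scaled Schoenfeld residuals with ranked event time)."""
    df = _two_arm_frame(ipd_a, ipd_b)
    cph = CoxPHFitter()
    cph.fit(df, duration_col="time", event_col="event")
    res = proportional_hazard_test(cph, df, time_transform="rank")
    p = float(np.asarray(res.p_value).ravel()[0])
    return PHTestResult(p_value=p, reject_ph=p < alpha, alpha=alpha)
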