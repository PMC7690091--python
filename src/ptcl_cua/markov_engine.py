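"""Weekly-cycle Markov cohort simulation of the treatment pathway.

Five health states — initial treatment, treatment pause, subsequent
treatment, SCT success, death — with the three treatment states split into
nested response compartments (CR/PR/SD/PD). Both arms share one timeline:

* weeks 1-14: initial treatment (the cohort enters split by the arm's
  initial response rates);
* weeks 15-22: treatment pause; at week 20 a fraction of surviving CR+PR
  patients receives a stem-cell transplant, and the successful fraction
  moves to "SCT success" where general-population (life-table) mortality
  and utility apply; CR patients who are not transplanted or whose
  transplant fails stay in the pause state for good;
* weeks 23-35: subsequent chemotherapy for the remaining PR/SD/PD mass;
* week 36 onward: second pause; the cohort re-splits by the
  post-subsequent response rates on entry, a second transplant happens at
  week 42, and everyone else remains in the pause state until death or the
  horizon (782 weeks = 15 years at 365/7 weeks per year).

Arm-specific overall-survival mortality (from the fitted curve) applies
uniformly to every living non-transplanted compartment; within a cycle the
order is death first, then transplant transfer, then the phase transition
at the cycle boundary, so transplant candidates must survive the
transplant week. No half-cycle correction is applied; occupancy is
recorded at cycle boundaries and downstream accounting accrues on
start-of-cycle occupancy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .synthetic_data import ARMS, RESPONSES, LifeTable, ModelParameters

__all__ = ["PhaseSchedule", "CohortTrace", "build_schedule", "run_cohort", "trace_survival"]

_LEAK_TOL = 1e-9


@dataclass
class PhaseSchedule:
    """Deterministic week-by-week phase labels and event weeks for one arm."""

    arm: str
    cycles: int
    initial_tx_end: int        # last week of initial treatment (14)
    subsequent_start: int      # first week of subsequent treatment (23)
    subsequent_end: int        # last week of subsequent treatment (35)
    sct_week_initial: int      # 20
    sct_week_subsequent: int   # 42
    initial_cycle_weeks: int   # regimen cycle length during initial tx
    subsequent_cycle_weeks: int = 3  # subsequent chemo is a 3-week regimen

    def phase_of(self, week: int) -> str:
        """Phase of calendar week ``week`` (1-based)."""
        if not 1 <= week <= self.cycles:
            raise ValueError(f"week {week} outside 1..{self.cycles}")
        if week <= self.initial_tx_end:
            return "initial_tx"
        if week < self.subsequent_start or week > self.subsequent_end:
            return "pause"
        return "subsequent_tx"

    def in_first_initial_cycle(self, week: int) -> bool:
        return 1 <= week <= self.initial_cycle_weeks

    def in_first_subsequent_cycle(self, week: int) -> bool:
        return (
            self.subsequent_start
            <= week
            < self.subsequent_start + self.subsequent_cycle_weeks
        )

    def to_dict(self) -> dict:
        return {
            "arm": self.arm,
            "cycles": self.cycles,
            "initial_tx_end": self.initial_tx_end,
            "subsequent_start": self.subsequent_start,
            "subsequent_end": self.subsequent_end,
            "sct_week_initial": self.sct_week_initial,
            "sct_week_subsequent": self.sct_week_subsequent,
            "initial_cycle_weeks": self.initial_cycle_weeks,
            "subsequent_cycle_weeks": self.subsequent_cycle_weeks,
        }


def build_schedule(arm: str, params: ModelParameters) -> PhaseSchedule:
    """Validate the parameter timeline and derive the arm's schedule.

    Arm differences are limited to drug identity and costs; both arms share
    the 14/8/13-week phase skeleton (two 7-week pralatrexate cycles or 4.67
    three-week chemo cycles both round to 14 weeks; 4.33 three-week cycles
    round to 13)."""
    if arm not in ARMS:
        raise ValueError(f"unknown arm {arm!r}; expected one of {ARMS}")
    params.validate()
    initial_end = params.initial_tx_weeks
    sub_start = params.subsequent_start_week
    sub_end = params.pause2_start_week - 1
    problems = []
    if sub_start != initial_end + params.pause_weeks + 1:
        problems.append("subsequent_start_week != initial_tx_weeks + pause_weeks + 1")
    if sub_end - sub_start + 1 != params.subsequent_tx_weeks:
        problems.append("pause2_start_week inconsistent with subsequent_tx_weeks")
    if not initial_end < params.sct_week_post_initial < sub_start:
        problems.append("sct_week_post_initial outside the first pause window")
    if not params.sct_week_post_subsequent >= params.pause2_start_week:
        problems.append("sct_week_post_subsequent before the second pause")
    if params.sct_week_post_subsequent > params.cycles:
        problems.append("sct_week_post_subsequent beyond the horizon")
    if problems:
        raise ValueError("inconsistent schedule parameters: " + "; ".join(problems))
    return PhaseSchedule(
        arm=arm,
        cycles=params.cycles,
        initial_tx_end=initial_end,
        subsequent_start=sub_start,
        subsequent_end=sub_end,
        sct_week_initial=params.sct_week_post_initial,
        sct_week_subsequent=params.sct_week_post_subsequent,
        initial_cycle_weeks=int(round(params.tx_cycle_weeks[
            "pralatrexate" if arm == "pralatrexate" else "cc"
        ])),
    )


#: exported compartment order: phase x response, then the two plain states
TRACE_COLUMNS = (
    [f"initial_tx_{r}" for r in RESPONSES]
    + [f"pause_{r}" for r in RESPONSES]
    + [f"subsequent_tx_{r}" for r in RESPONSES]
    + ["sct_success", "dead"]
)


@dataclass
class CohortTrace:
    """Occupancy by week (rows 0..cycles) and compartment.

    ``occupancy`` holds the exported 14-column view (pause pools merged);
    the post-initial and post-subsequent pause pools are kept separately in
    ``pause1``/``pause2`` because only the post-subsequent pool is eligible
    for the second transplant. ``sct_transplants`` records the transplanted
    mass (successes and failures) at each transplant week for one-off cost
    accrual."""

    arm: str
    occupancy: np.ndarray          # (cycles+1, 14)
    pause1: np.ndarray             # (cycles+1, 4)
    pause2: np.ndarray             # (cycles+1, 4)
    ages: np.ndarray               # cohort age at each row
    sct_transplants: dict          # week -> transplanted mass

    @property
    def cycles(self) -> int:
        return self.occupancy.shape[0] - 1

    @property
    def dead(self) -> np.ndarray:
        return self.occupancy[:, -1]

    @property
    def sct_success(self) -> np.ndarray:
        return self.occupancy[:, -2]

    def column(self, name: str) -> np.ndarray:
        return self.occupancy[:, TRACE_COLUMNS.index(name)]

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.occupancy, columns=TRACE_COLUMNS)
        df.insert(0, "week", np.arange(self.occupancy.shape[0]))
        df["age"] = self.ages
        return df

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def run_cohort(
    arm: str,
    params: ModelParameters,
    death_prob_fn: Callable[[int], float],
    life_table: LifeTable,
) -> CohortTrace:
    """Run the cohort through the full horizon.

    ``death_prob_fn(w)`` is the arm's probability of dying during week
    ``w + 1`` (from the extrapolated OS curve); life-table mortality at the
    current cohort age applies to the SCT-success state instead. Raises if
    a death probability leaves [0, 1] or if probability mass leaks."""
    sched = build_schedule(arm, params)
    n_resp = len(RESPONSES)
    iCR, iPR, iSD, iPD = range(n_resp)

    split0 = np.array([params.response_split_initial[arm][r] for r in RESPONSES])
    split_sub = np.array([params.response_split_subsequent[r] for r in RESPONSES])

    it = split0.copy()          # initial treatment
    p1 = np.zeros(n_resp)       # pause, post-initial
    st = np.zeros(n_resp)       # subsequent treatment
    p2 = np.zeros(n_resp)       # pause, post-subsequent
    sct = 0.0
    dead = 0.0

    rows = np.zeros((sched.cycles + 1, len(TRACE_COLUMNS)))
    p1_rows = np.zeros((sched.cycles + 1, n_resp))
    p2_rows = np.zeros((sched.cycles + 1, n_resp))
    ages = params.start_age + np.arange(sched.cycles + 1) / params.weeks_per_year
    transplants: dict = {}

    def record(w):
        rows[w, :n_resp] = it
        rows[w, n_resp : 2 * n_resp] = p1 + p2
        rows[w, 2 * n_resp : 3 * n_resp] = st
        rows[w, -2] = sct
        rows[w, -1] = dead
        p1_rows[w] = p1
        p2_rows[w] = p2
        total = rows[w].sum()
        if abs(total - 1.0) > _LEAK_TOL:
            raise AssertionError(f"probability mass leak at week {w}: sum={total!r}")

    record(0)
    for w in range(1, sched.cycles + 1):
        p_arm = float(death_prob_fn(w - 1))
        if not 0.0 <= p_arm <= 1.0:
            raise ValueError(f"death probability {p_arm} outside [0, 1] at week {w}")
        p_gen = life_table.weekly_prob(ages[w - 1])

        # (i) mortality: arm hazard everywhere except SCT success (life table)
        alive_mass = it.sum() + p1.sum() + st.sum() + p2.sum()
        dead += alive_mass * p_arm + sct * p_gen
        it *= 1.0 - p_arm
        p1 *= 1.0 - p_arm
        st *= 1.0 - p_arm
        p2 *= 1.0 - p_arm
        sct *= 1.0 - p_gen

        # (ii) transplant events among surviving CR/PR
        if w == sched.sct_week_initial:
            eligible = p1[iCR] + p1[iPR]
            moved = eligible * params.sct_prob_initial
            transplants[w] = moved
            success_frac = params.sct_prob_initial * params.sct_success
            sct += eligible * success_frac
            p1[iCR] *= 1.0 - success_frac
            p1[iPR] *= 1.0 - success_frac
        if w == sched.sct_week_subsequent:
            eligible = p2[iCR] + p2[iPR]
            moved = eligible * params.sct_prob_subsequent
            transplants[w] = moved
            success_frac = params.sct_prob_subsequent * params.sct_success
            sct += eligible * success_frac
            p2[iCR] *= 1.0 - success_frac
            p2[iPR] *= 1.0 - success_frac

        # (iii) phase transitions at the cycle boundary
        if w == sched.initial_tx_end:
            p1 += it
            it[:] = 0.0
        if w == sched.subsequent_start - 1:
            # CR stays in pause for good; PR remainder, SD and PD move on
            st[iPR] += p1[iPR]
            st[iSD] += p1[iSD]
            st[iPD] += p1[iPD]
            p1[iPR] = p1[iSD] = p1[iPD] = 0.0
        if w == sched.subsequent_end:
            p2 += st.sum() * split_sub  # re-split on entry to the 2nd pause
            st[:] = 0.0

        record(w)

    return CohortTrace(
        arm=arm,
        occupancy=rows,
        pause1=p1_rows,
        pause2=p2_rows,
        ages=ages,
        sct_transplants=transplants,
    )


def trace_survival(trace: CohortTrace) -> np.ndarray:
    """Model overall survival: per-week alive fraction 1 - dead(t)."""
    return 1.0 - trace.dead
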