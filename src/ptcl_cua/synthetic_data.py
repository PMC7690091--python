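"""Seeded synthetic stand-ins for every external input of the analysis.

The real evaluation rests on three inputs that cannot be redistributed:
the matched-control overall-survival curves (published only as figures),
the Korean general-population life table, and the model-parameter table
assembled from tariffs, claims data and a clinician panel. This module
generates all three from known truth so the downstream pipeline —
digitization, pseudo-IPD reconstruction, parametric fitting, cohort
simulation, accounting — is testable end to end against that truth.

* :func:`generate_ipd` draws right-censored survival data from a named
  parametric family (the matched-control evidence had 80 subjects per arm;
  truths are calibrated to the published medians, 15.24 and 4.07 months).
* :func:`digitize_emulate` turns an IPD sample into the kind of coordinate
  list a curve-digitizer produces: the KM step function sampled on a grid,
  optionally perturbed by extraction noise, with a numbers-at-risk table.
* :func:`make_life_table` builds a stylized Gompertz-Makeham life table
  (explicitly *not* the Korean national table, whose values are not
  reproducible here) converted to weekly death probabilities.
* :func:`default_parameters` returns the packaged parameter fixture:
  treatment timings, response splits, transplant probabilities, weekly
  costs in 2019 USD, adverse-event rates/costs/disutilities and health
  utilities.
"""

from __future__ import annotations

import copy
import json
import math
from dataclasses import asdict, dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import distributions as dist
from .ipd_reconstruction import DigitizedCurve, IPDSample, km_estimator

__all__ = [
    "TrueSurvivalSpec",
    "LifeTable",
    "AEItem",
    "ModelParameters",
    "generate_ipd",
    "digitize_emulate",
    "make_life_table",
    "default_parameters",
    "weighted_regimen_cost",
    "MONTHS_TO_WEEKS",
]

#: 1 month = 365.25 / 12 / 7 weeks (so 15.24 mo = 66.27 wk, 4.07 mo = 17.70 wk)
MONTHS_TO_WEEKS = 365.25 / 12.0 / 7.0

#: follow-up horizon of the source comparative study, ~52 months
DEFAULT_MAX_FOLLOWUP_WEEKS = 52.0 * MONTHS_TO_WEEKS


@dataclass
class TrueSurvivalSpec:
    """Known parametric truth for one synthetic trial arm."""

    family: str
    params: tuple
    n_subjects: int = 80
    max_followup: float = DEFAULT_MAX_FOLLOWUP_WEEKS
    censor_rate: float = 0.2
    seed: int = 0

    def __post_init__(self):
        dist.validate_params(self.family, self.params)
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if not (0.0 <= self.censor_rate < 1.0):
            raise ValueError("censor_rate must be in [0, 1)")
        if not self.max_followup > 0:
            raise ValueError("max_followup must be positive")


def generate_ipd(spec: TrueSurvivalSpec, arm_label: str = "") -> IPDSample:
    """Draw a right-censored survival sample from the spec's truth.

    Each subject is independently at risk of random censoring with
    probability ``censor_rate`` (censor time uniform on (0, max_followup));
    everyone still at risk at ``max_followup`` is administratively censored
    there. Observed time = min(event, censor, max_followup). Deterministic
    under a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    t_event = dist.rvs(spec.family, spec.params, spec.n_subjects, rng)
    censor = np.full(spec.n_subjects, np.inf)
    if spec.censor_rate > 0:
        is_cens = rng.random(spec.n_subjects) < spec.censor_rate
        if np.isinf(spec.max_followup):
            raise ValueError("uniform censoring needs a finite max_followup")
        censor[is_cens] = rng.uniform(0.0, spec.max_followup, is_cens.sum())
    limit = np.minimum(censor, spec.max_followup)
    time = np.minimum(t_event, limit)
    event = t_event <= limit
    time = np.maximum(time, 1e-9)  # guard the open-at-zero invariant
    return IPDSample(time, event, arm_label=arm_label)


def digitize_emulate(
    ipd: IPDSample,
    grid_step: float = 1.0,
    jitter_sd: float = 0.005,
    seed: int = 0,
    include_risk_table: bool = True,
) -> DigitizedCurve:
    """Emulate manual curve digitization of the KM plot of ``ipd``.

    The exact KM step function is sampled at every drop time plus a
    regular grid; Gaussian jitter of scale ``jitter_sd`` (survival units)
    mimics extraction error and is followed by a monotone non-increasing
    clip and a clamp to [0, 1], so the output is always a valid survival
    curve starting at (0, 1.0). The risk table reports, at each sampled
    time, the number of subjects with observed time >= that time.
    """
    if grid_step <= 0:
        raise ValueError("grid_step must be positive")
    if jitter_sd < 0:
        raise ValueError("jitter_sd must be non-negative")
    surv = km_estimator(ipd)
    t_max = float(ipd.time.max())
    grid = np.arange(0.0, t_max + grid_step, grid_step)
    t_samp = np.unique(np.concatenate([[0.0], grid, surv.drop_times]))
    t_samp = t_samp[t_samp <= t_max + 1e-12]
    s = np.array([surv.survival_at(t) for t in t_samp])

    if jitter_sd > 0:
        rng = np.random.default_rng(seed)
        s = s + rng.normal(0.0, jitter_sd, s.size)
        s[0] = 1.0
        s = np.minimum.accumulate(np.clip(s, 0.0, 1.0))

    risk = None
    if include_risk_table:
        n_at_risk = np.array([(ipd.time >= t - 1e-12).sum() for t in t_samp])
        risk = pd.DataFrame({"time_weeks": t_samp, "n_at_risk": n_at_risk})
    return DigitizedCurve(
        times=t_samp,
        survival=s,
        total_n=ipd.n,
        risk_table=risk,
        arm_label=ipd.arm_label,
    )


@dataclass
class LifeTable:
    """Weekly general-population death probabilities by single year of age."""

    age_years: np.ndarray
    weekly_death_prob: np.ndarray

    def __post_init__(self):
        self.age_years = np.asarray(self.age_years, dtype=int)
        self.weekly_death_prob = np.asarray(self.weekly_death_prob, dtype=float)
        if np.any((self.weekly_death_prob < 0) | (self.weekly_death_prob >= 1)):
            raise ValueError("weekly death probabilities must lie in [0, 1)")

    def weekly_prob(self, age: float) -> float:
        """Weekly death probability at (fractional) age; clamped to the
        table's age range."""
        idx = int(np.clip(math.floor(age), self.age_years[0], self.age_years[-1]))
        return float(self.weekly_death_prob[idx - int(self.age_years[0])])

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"age_years": self.age_years, "weekly_death_prob": self.weekly_death_prob}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "LifeTable":
        df = pd.read_csv(path)
        return cls(df["age_years"].to_numpy(), df["weekly_death_prob"].to_numpy())


def make_life_table(
    makeham_a: float = 5e-4,
    gompertz_b: float = 3e-5,
    gompertz_c: float = 0.09,
    weeks_per_year: float = 52.1,
) -> LifeTable:
    """Stylized Gompertz-Makeham life table over ages 0-100.

    Annual hazard h(age) = A + B*exp(C*age); annual death probability
    1 - exp(-h); weekly probability 1 - (1 - p_year)^(1/weeks_per_year).
    The defaults give adult mortality of a plausible high-income-country
    magnitude (~0.3% per year at 48, ~4% at 80); they are configuration,
    not a reproduction of any national table.
    """
    ages = np.arange(0, 101)
    hazard = makeham_a + gompertz_b * np.exp(gompertz_c * ages)
    p_year = 1.0 - np.exp(-hazard)
    if np.any(p_year >= 1.0):
        raise ValueError("life-table shape parameters give probabilities >= 1")
    p_week = 1.0 - (1.0 - p_year) ** (1.0 / weeks_per_year)
    return LifeTable(ages, p_week)


@dataclass
class AEItem:
    """One grade>=3 adverse event: weekly incidence per arm/phase, cost per
    hospitalized episode (2019 USD), and utility decrement while present."""

    name: str
    weekly_prob: dict  # keys: pralatrexate_initial, cc_initial, cc_subsequent
    cost: float
    disutility: float


RESPONSES = ("CR", "PR", "SD", "PD")
ARMS = ("pralatrexate", "cc")


@dataclass
class ModelParameters:
    """Full parameter payload of the cost-utility model.

    All money fields are weekly 2019 USD from a societal perspective unless
    flagged one-off (``sct_cost``, AE episode costs). The treatment
    timeline is shared by both arms: initial treatment weeks 1-14, pause
    weeks 15-22 with transplant at week 20, subsequent treatment weeks
    23-35, second pause from week 36 with transplant at week 42.
    """

    start_age: float = 48.0
    horizon_years: float = 15.0
    weeks_per_year: float = 52.1
    discount_annual: float = 0.05
    months_to_weeks: float = MONTHS_TO_WEEKS

    initial_tx_weeks: int = 14
    pause_weeks: int = 8
    subsequent_tx_weeks: int = 13
    sct_week_post_initial: int = 20
    subsequent_start_week: int = 23
    pause2_start_week: int = 36
    sct_week_post_subsequent: int = 42

    tx_cycle_weeks: dict = field(
        default_factory=lambda: {"pralatrexate": 7.0, "cc": 3.0}
    )
    tx_n_cycles: dict = field(
        default_factory=lambda: {
            "pralatrexate_initial": 2.0,
            "cc_initial": 4.67,
            "cc_subsequent": 4.33,
        }
    )

    response_split_initial: dict = field(
        default_factory=lambda: {
            "pralatrexate": {"CR": 0.126, "PR": 0.211, "SD": 0.221, "PD": 0.442},
            "cc": {"CR": 0.198, "PR": 0.214, "SD": 0.032, "PD": 0.556},
        }
    )
    # both arms receive conventional chemotherapy subsequently
    response_split_subsequent: dict = field(
        default_factory=lambda: {"CR": 0.123, "PR": 0.158, "SD": 0.035, "PD": 0.684}
    )

    sct_prob_initial: float = 0.529
    sct_prob_subsequent: float = 0.458
    sct_success: float = 0.663

    medication_weekly: dict = field(
        default_factory=lambda: {
            "pralatrexate_initial": 2465.0,
            "cc_initial": 240.0,
            "cc_subsequent": 238.0,
        }
    )
    concomitant_weekly: dict = field(
        default_factory=lambda: {
            "pralatrexate_initial_first_cycle": 4.0,
            "pralatrexate_initial_last_cycle": 3.0,
            "cc_initial": 207.0,
            "cc_subsequent": 198.0,
        }
    )
    monitoring_weekly: dict = field(
        default_factory=lambda: {
            "pralatrexate_initial_first_cycle": 106.0,
            "pralatrexate_initial_other_cycles": 17.0,
            "cc_initial_first_cycle": 129.0,
            "cc_initial_other_cycles": 40.0,
            "cc_subsequent_first_cycle": 123.0,
            "cc_subsequent_other_cycles": 38.0,
        }
    )
    sct_cost: float = 27343.0  # one-off per transplant
    ae_prob_mode: str = "per_week"  # per_week | per_cycle | per_course

    ae_items: list = field(
        default_factory=lambda: [
            AEItem(
                "mucositis",
                {
                    "pralatrexate_initial": 0.0172,
                    "cc_initial": 0.0365,
                    "cc_subsequent": 0.0393,
                },
                1288.0,
                -0.075,
            ),
            AEItem(
                "thrombocytopenia",
                {
                    "pralatrexate_initial": 0.0267,
                    "cc_initial": 0.1122,
                    "cc_subsequent": 0.0839,
                },
                2859.0,
                -0.095,
            ),
            AEItem(
                "anemia",
                {
                    "pralatrexate_initial": 0.0118,
                    "cc_initial": 0.0257,
                    "cc_subsequent": 0.0279,
                },
                2877.0,
                -0.085,
            ),
            AEItem(
                "neutropenia",
                {
                    "pralatrexate_initial": 0.0172,
                    "cc_initial": 0.1250,
                    "cc_subsequent": 0.1011,
                },
                2760.0,
                -0.107,
            ),
            AEItem(
                "nausea_vomiting",
                {
                    "pralatrexate_initial": 0.0026,
                    "cc_initial": 0.0053,
                    "cc_subsequent": 0.0070,
                },
                707.0,
                -0.059,
            ),
            AEItem(
                "peripheral_neuropathy",
                {
                    "pralatrexate_initial": 0.0000,
                    "cc_initial": 0.0063,
                    "cc_subsequent": 0.0053,
                },
                643.0,
                -0.42,
            ),
        ]
    )

    utilities: dict = field(
        default_factory=lambda: {"CR": 0.885, "PR": 0.784, "SD": 0.746, "PD": 0.567}
    )
    # (age_low, age_high, utility); general-population utility post-transplant
    sct_success_utility_bands: list = field(
        default_factory=lambda: [
            (45, 49, 0.976),
            (50, 54, 0.971),
            (55, 59, 0.966),
            (60, 64, 0.936),
        ]
    )

    # provenance of the comparator weekly aggregates: regimen usage mix and
    # per-regimen weekly drug costs (the base case consumes the aggregates
    # above directly; see weighted_regimen_cost)
    comparator_regimen_mix: dict = field(
        default_factory=lambda: {
            "initial": {"DHAP": 0.153, "ESHAP": 0.099, "ICE": 0.748},
            "subsequent": {"DHAP": 0.339, "ESHAP": 0.162, "ICE": 0.455, "BSC": 0.044},
        }
    )
    regimen_weekly_drug_cost: dict = field(
        default_factory=lambda: {
            "pralatrexate": 2279.0,
            "DHAP": 54.0,
            "ESHAP": 64.0,
            "ICE": 100.0,
        }
    )

    @property
    def cycles(self) -> int:
        """Number of weekly cycles in the horizon (365 d / 7 d x years)."""
        return int(365.0 * self.horizon_years / 7.0)

    def sct_success_utility(self, age: float) -> float:
        """Age-band general-population utility; clamped to the outer bands."""
        bands = self.sct_success_utility_bands
        if age < bands[0][0]:
            return bands[0][2]
        for lo, hi, u in bands:
            if lo <= age < hi + 1:  # band covers whole years lo..hi
                return u
        return bands[-1][2]

    def ae_expected_weekly_cost(self, key: str) -> float:
        """Expected weekly AE treatment cost per occupant of arm/phase ``key``
        (one of pralatrexate_initial, cc_initial, cc_subsequent)."""
        return sum(it.weekly_prob[key] * it.cost for it in self.ae_items)

    def ae_expected_weekly_disutility(self, key: str) -> float:
        return sum(it.weekly_prob[key] * it.disutility for it in self.ae_items)

    def validate(self) -> None:
        for arm, split in self.response_split_initial.items():
            if abs(sum(split.values()) - 1.0) > 1e-9:
                raise ValueError(f"initial response split for {arm} does not sum to 1")
        if abs(sum(self.response_split_subsequent.values()) - 1.0) > 1e-9:
            raise ValueError("subsequent response split does not sum to 1")
        probs = [self.sct_prob_initial, self.sct_prob_subsequent, self.sct_success]
        probs += [p for it in self.ae_items for p in it.weekly_prob.values()]
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ValueError("a probability parameter lies outside [0, 1]")
        costs = (
            list(self.medication_weekly.values())
            + list(self.concomitant_weekly.values())
            + list(self.monitoring_weekly.values())
            + [self.sct_cost]
            + [it.cost for it in self.ae_items]
        )
        if any(c < 0 for c in costs):
            raise ValueError("costs must be non-negative")
        utils = list(self.utilities.values()) + [
            b[2] for b in self.sct_success_utility_bands
        ]
        if any(not (0.0 <= u <= 1.0) for u in utils):
            raise ValueError("utilities must lie in [0, 1]")
        if any(it.disutility > 0 for it in self.ae_items):
            raise ValueError("disutilities must be <= 0")
        if self.ae_prob_mode not in ("per_week", "per_cycle", "per_course"):
            raise ValueError(f"unknown ae_prob_mode {self.ae_prob_mode!r}")
        if not (
            1
            <= self.sct_week_post_initial
            < self.subsequent_start_week
            <= self.pause2_start_week
            < self.sct_week_post_subsequent
            <= self.cycles
        ):
            raise ValueError("treatment timeline weeks are inconsistent")

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["sct_success_utility_bands"] = [list(b) for b in d["sct_success_utility_bands"]]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParameters":
        d = copy.deepcopy(d)
        d["ae_items"] = [
            it if isinstance(it, AEItem) else AEItem(**it) for it in d.get("ae_items", [])
        ]
        if "sct_success_utility_bands" in d:
            d["sct_success_utility_bands"] = [
                tuple(b) for b in d["sct_success_utility_bands"]
            ]
        p = cls(**d)
        p.validate()
        return p

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ModelParameters":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def copy(self) -> "ModelParameters":
        return copy.deepcopy(self)


def default_parameters() -> ModelParameters:
    """The packaged base-case parameter fixture (weekly costs, 2019 USD)."""
    p = ModelParameters()
    p.validate()
    return p


def weighted_regimen_cost(mix: dict, per_regimen_cost: dict) -> float:
    """Usage-weighted mean weekly cost across chemotherapy regimens.

    Provenance helper for the comparator aggregates: the base case uses the
    packaged weekly aggregates directly, but when per-regimen costs are
    available this recomputes the weighted mean (weights renormalized over
    the regimens actually priced).
    """
    items = [(w, per_regimen_cost[r]) for r, w in mix.items() if r in per_regimen_cost]
    if not items:
        raise ValueError("no priced regimen appears in the mix")
    wsum = sum(w for w, _ in items)
    return sum(w * c for w, c in items) / wsum
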