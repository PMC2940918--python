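"""Disease consequences and annual costs by risk group.

Given the hypertensive population decomposed into risk groups k = 0..4
additional MetS components, this module attributes incident cardiovascular
events, attributable mortality, prevalent type 2 diabetes and
treatment-related new-onset diabetes to the groups, and aggregates the four
annual cost components (antihypertensive drugs, physician management,
cardiovascular events, type 2 diabetes) from quantities x unit prices.

Group-specific rates are anchored to sourced overall rates: a national
overall rate per 1,000 hypertensives is spread over the groups by relative
risks rr_k (rr_0 = 1, non-decreasing in k) with a scale factor chosen so the
population-weighted mean reproduces the overall rate exactly.  This is a
static annual snapshot on a population initially free of cardiovascular
disease: no event history or within-year competing mortality is modelled.
Drug and physician costs are distributed evenly across the five risk groups
(per treated patient); the continuation (adherence) rate scales drug spend
and treatment-dependent new-onset diabetes, not physician visits.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "CV_EVENT_OUTCOMES",
    "DrugClass",
    "TreatmentMix",
    "OutcomeRates",
    "UnitCosts",
    "CostBreakdown",
    "calibrate_group_rates",
    "expected_events",
    "event_rate_per_1000",
    "prevalent_t2d",
    "treatment_attributable_new_onset_t2d",
    "annual_costs",
    "per_patient_cost",
    "cost_shares",
    "mets_cost_share",
    "round_half_away",
]

#: Cardiovascular event outcomes (death counted as an event for event totals,
#: but carrying no downstream management cost).
CV_EVENT_OUTCOMES = ("ami", "chf", "unstable_angina", "stroke", "cv_death")
DRUG_CLASSES = ("arb", "ace_inhibitor", "ccb", "diuretic", "beta_blocker", "combination")


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round half away from zero (the convention used in the reports)."""
    scale = 10.0**ndigits
    return np.sign(x) * np.floor(abs(x) * scale + 0.5) / scale


@dataclass(frozen=True)
class DrugClass:
    """One antihypertensive drug class in the treatment mix."""

    name: str
    share: float  # share of treated patients on this class
    annual_cost_eur: float  # drug acquisition cost per treated patient-year
    continuation: float  # fraction persisting on therapy through the year
    rr_new_onset_diabetes: float  # relative risk of new-onset T2D vs baseline

    def __post_init__(self) -> None:
        if not 0.0 <= self.share <= 1.0:
            raise ValueError(f"{self.name}: share must be in [0,1]")
        if self.annual_cost_eur < 0:
            raise ValueError(f"{self.name}: annual_cost_eur must be >= 0")
        if not 0.0 <= self.continuation <= 1.0:
            raise ValueError(f"{self.name}: continuation must be in [0,1]")
        if self.rr_new_onset_diabetes < 0:
            raise ValueError(f"{self.name}: rr_new_onset_diabetes must be >= 0")


@dataclass(frozen=True)
class TreatmentMix:
    """Treated/untreated split, drug-class mix and physician contacts."""

    proportion_treated: float
    classes: tuple[DrugClass, ...]
    visits_per_year: float  # primary-care visits per treated patient-year
    visit_cost_eur: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.proportion_treated <= 1.0:
            raise ValueError("proportion_treated must be in [0,1]")
        if self.visits_per_year < 0 or self.visit_cost_eur < 0:
            raise ValueError("visit frequency and unit cost must be >= 0")
        total = sum(c.share for c in self.classes)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"drug-class shares must sum to 1 (got {total:.6f})")

    @property
    def drug_cost_per_treated(self) -> float:
        """Expected dispensed drug cost per treated patient-year (EUR)."""
        return sum(c.share * c.annual_cost_eur * c.continuation for c in self.classes)


@dataclass(frozen=True)
class OutcomeRates:
    """Overall rate per 1,000 hypertensives plus relative risks by group."""

    name: str
    overall_per_1000: float
    rr_by_k: tuple[float, float, float, float, float]

    def __post_init__(self) -> None:
        if self.overall_per_1000 < 0:
            raise ValueError(f"{self.name}: overall rate must be >= 0")
        rr = np.asarray(self.rr_by_k, dtype=float)
        if rr.shape != (5,):
            raise ValueError(f"{self.name}: rr_by_k needs 5 entries (k = 0..4)")
        if (rr < 0).any():
            raise ValueError(f"{self.name}: relative risks must be >= 0")
        if abs(rr[0] - 1.0) > 1e-12:
            raise ValueError(f"{self.name}: rr for k=0 must be 1 (reference group)")
        if (np.diff(rr) < -1e-12).any():
            raise ValueError(
                f"{self.name}: rr_by_k must be non-decreasing in k "
                "(risk rises with the number of MetS components)"
            )


@dataclass(frozen=True)
class UnitCosts:
    """Unit prices (EUR, base-year prices) for events and diabetes care."""

    event_cost_eur: Mapping[str, float]  # acute cost per CV event, by outcome
    t2d_annual_cost_eur: float  # annual management cost per diabetes patient

    def __post_init__(self) -> None:
        for k, v in self.event_cost_eur.items():
            if v < 0:
                raise ValueError(f"event cost for {k!r} must be >= 0")
        if self.t2d_annual_cost_eur < 0:
            raise ValueError("t2d_annual_cost_eur must be >= 0")

    def scaled(self, target: str, factor: float) -> "UnitCosts":
        if target == "cvd":
            return replace(
                self, event_cost_eur={k: v * factor for k, v in self.event_cost_eur.items()}
            )
        if target == "t2d":
            return replace(self, t2d_annual_cost_eur=self.t2d_annual_cost_eur * factor)
        raise ValueError(f"unknown unit-cost target {target!r}")


@dataclass(frozen=True)
class CostBreakdown:
    """Annual costs in EUR millions for one population slice.

    ``total`` is always the exact (unrounded) sum of the four components;
    rounding happens only at report serialisation.
    """

    drug: float
    physician: float
    cvd: float
    t2d: float
    label: str = ""

    @property
    def total(self) -> float:
        return self.drug + self.physician + self.cvd + self.t2d

    def __add__(self, other: "CostBreakdown") -> "CostBreakdown":
        return CostBreakdown(
            self.drug + other.drug,
            self.physician + other.physician,
            self.cvd + other.cvd,
            self.t2d + other.t2d,
            label=self.label or other.label,
        )


# ---------------------------------------------------------------------------
# consequences of disease
# ---------------------------------------------------------------------------

def calibrate_group_rates(
    overall_per_1000: float, weights: Sequence[float], rr_by_k: Sequence[float]
) -> np.ndarray:
    """Per-group rates b*rr_k whose weighted mean is the overall rate.

    ``weights`` are the population shares of groups k = 0..4 (sum to 1).
    Solves overall = b * sum_k w_k rr_k for the baseline rate b, so the
    calibration identity sum_k w_k rate_k = overall holds exactly.
    """
    w = np.asarray(weights, dtype=float)
    rr = np.asarray(rr_by_k, dtype=float)
    if abs(w.sum() - 1.0) > 1e-9:
        raise ValueError("group weights must sum to 1")
    if (rr < 0).any():
        raise ValueError("relative risks must be >= 0")
    denom = float(w @ rr)
    if denom == 0.0:
        raise ValueError("sum of weight x relative-risk is zero; rates are unidentifiable")
    return overall_per_1000 / denom * rr


def expected_events(persons_by_k: Sequence[float], rates_by_k: Sequence[float]) -> np.ndarray:
    """Annual event counts per group: persons_k x rate_k / 1,000."""
    persons = np.asarray(persons_by_k, dtype=float)
    rates = np.asarray(rates_by_k, dtype=float)
    if (persons < 0).any() or (rates < 0).any():
        raise ValueError("persons and rates must be non-negative")
    return persons * rates / 1000.0


def event_rate_per_1000(events: float, persons: float) -> float:
    """Reported event rate; NaN for an empty group rather than 0."""
    if persons == 0:
        return float("nan")
    return 1000.0 * events / persons


def prevalent_t2d(persons_by_k: Sequence[float], rates_by_k: Sequence[float]) -> np.ndarray:
    """Prevalent type 2 diabetes cases per group (a pool, not a flow).

    Arithmetically identical to :func:`expected_events` applied to a
    prevalence per 1,000; kept separate because prevalent cases feed the
    annual diabetes-management cost while events feed acute event costs.
    """
    return expected_events(persons_by_k, rates_by_k)


def treatment_attributable_new_onset_t2d(
    persons_by_k: Sequence[float],
    mix: TreatmentMix,
    baseline_incidence_by_k: Sequence[float],
) -> np.ndarray:
    """New-onset T2D cases attributable to antihypertensive class, per group.

    Per class: treated_k x share x continuation x baseline incidence x
    (rr_class - 1) / 1,000, floored at zero (protective classes do not
    generate negative cases), summed over classes.
    """
    persons = np.asarray(persons_by_k, dtype=float)
    base = np.asarray(baseline_incidence_by_k, dtype=float)
    treated = persons * mix.proportion_treated
    out = np.zeros_like(treated)
    for c in mix.classes:
        excess = max(c.rr_new_onset_diabetes - 1.0, 0.0)
        out += treated * c.share * c.continuation * base / 1000.0 * excess
    return out


# ---------------------------------------------------------------------------
# costs
# ---------------------------------------------------------------------------

def annual_costs(
    persons_by_k: Sequence[float],
    events_by_outcome: Mapping[str, Sequence[float]],
    t2d_cases_by_k: Sequence[float],
    mix: TreatmentMix,
    costs: UnitCosts,
    label: str = "",
) -> list[CostBreakdown]:
    """Annual cost breakdown (EUR millions) for each risk group k = 0..4.

    drug      = treated_k x sum_class(share x cost x continuation)
    physician = treated_k x visits x unit cost
    cvd       = sum over event outcomes of events_k x acute event cost
    t2d       = diabetes cases_k x annual management cost
    """
    persons = np.asarray(persons_by_k, dtype=float)
    if (persons < 0).any():
        raise ValueError("persons must be non-negative")
    treated = persons * mix.proportion_treated
    drug = treated * mix.drug_cost_per_treated
    physician = treated * mix.visits_per_year * mix.visit_cost_eur
    cvd = np.zeros_like(persons)
    for outcome, ev in events_by_outcome.items():
        cvd += np.asarray(ev, dtype=float) * costs.event_cost_eur.get(outcome, 0.0)
    t2d = np.asarray(t2d_cases_by_k, dtype=float) * costs.t2d_annual_cost_eur
    return [
        CostBreakdown(
            drug[k] / 1e6, physician[k] / 1e6, cvd[k] / 1e6, t2d[k] / 1e6,
            label=f"{label}k={k}" if label else f"k={k}",
        )
        for k in range(len(persons))
    ]


def per_patient_cost(
    breakdowns_by_k: Sequence[CostBreakdown], persons_by_k: Sequence[float]
) -> np.ndarray:
    """Mean annual cost in EUR per hypertensive patient, by group.

    Empty groups report NaN rather than zero: a mean over nobody is
    undefined, and zero would fake a free group.
    """
    persons = np.asarray(persons_by_k, dtype=float)
    totals = np.array([b.total for b in breakdowns_by_k])
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(persons > 0, totals * 1e6 / persons, np.nan)
    return out


def cost_shares(breakdown: CostBreakdown) -> dict[str, float]:
    """Percentage of the slice total contributed by each component (0-100)."""
    if breakdown.total <= 0:
        raise ValueError("cost shares are undefined for a zero total")
    t = breakdown.total
    return {
        "drug": 100.0 * breakdown.drug / t,
        "physician": 100.0 * breakdown.physician / t,
        "cvd": 100.0 * breakdown.cvd / t,
        "t2d": 100.0 * breakdown.t2d / t,
    }


def mets_cost_share(total_mets: float, total_non_mets: float) -> float:
    """MetS share (%) of the overall hypertension cost."""
    denom = total_mets + total_non_mets
    if denom <= 0:
        raise ValueError("MetS cost share is undefined for a zero overall total")
    return 100.0 * total_mets / denom
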