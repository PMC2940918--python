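"""Country parameter packs: loading, validation and illustrative defaults.

A parameter pack bundles everything the burden model needs for one country:
adult demography and hypertension prevalence per age/sex stratum, target
marginal prevalences of the four non-BP MetS components among hypertensives,
outcome rates with relative risks by risk group, the antihypertensive
treatment mix, unit costs, and growth assumptions for the projection year.

Packs are plain CSV/JSON files in a directory (schema below) so national
inputs can be swapped in without touching code.  The packs shipped by
:func:`demo_pack` are *illustrative*: they are shaped like the three modelled
countries (a high-clustering "DE" style and two lower-prevalence "ES"/"IT"
styles) but are not sourced national data.

Pack directory schema
---------------------
``pack.json``            country, currency, years, treated share, visits
``demography.csv``       age_band, sex, population, population_horizon, htn_prevalence
``component_targets.csv`` age_band, sex, obesity, low_hdl, high_tg, impaired_glucose
``rates.csv``            outcome, overall_per_1000, rr_k0..rr_k4
``treatment.csv``        class, share, annual_cost_eur, continuation, rr_nod
``unit_costs.csv``       item, cost_eur
``growth.csv``           component, cagr
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .atp3 import NON_BP_COMPONENTS
from .burden import (
    CV_EVENT_OUTCOMES,
    DrugClass,
    OutcomeRates,
    TreatmentMix,
    UnitCosts,
)
from .microdata import AGE_BANDS, SEXES
from .projection import GrowthAssumptions

__all__ = [
    "ParameterPack",
    "PackValidationError",
    "load_pack",
    "save_pack",
    "validate_parameter_pack",
    "demo_pack",
    "DEMO_STYLES",
]

OUTCOMES = CV_EVENT_OUTCOMES + ("attributable_mortality", "t2d_prevalent", "t2d_incident")
GROWTH_COMPONENTS = NON_BP_COMPONENTS + ("hypertension",)


class PackValidationError(ValueError):
    """Raised with the complete list of schema/cross-field violations."""

    def __init__(self, violations: list[str]):
        self.violations = violations
        super().__init__(
            "parameter pack failed validation:\n  - " + "\n  - ".join(violations)
        )


@dataclass
class ParameterPack:
    """A validated country parameter bundle (see module docstring)."""

    country: str
    demography: pd.DataFrame  # index (age_band, sex): population, population_horizon, htn_prevalence
    component_targets: pd.DataFrame  # index (age_band, sex): four non-BP components
    rates: dict[str, OutcomeRates]
    mix: TreatmentMix
    unit_costs: UnitCosts
    growth: GrowthAssumptions
    currency: str = "EUR"
    base_year: int = 2008
    horizon_year: int = 2020
    #: sensitivity toggle: cost T2D from incident (+ treatment-attributable
    #: new-onset) cases instead of the prevalence pool
    t2d_incident_only: bool = False
    #: optional annual rate for discounting horizon-year costs to base year
    discount_rate: float | None = None

    @property
    def strata(self) -> list[tuple[str, str]]:
        return list(self.demography.index)

    @property
    def htn_counts(self) -> pd.Series:
        """Base-year hypertensive head-counts per stratum."""
        return self.demography["population"] * self.demography["htn_prevalence"]

    def copy(self) -> "ParameterPack":
        return replace(
            self,
            demography=self.demography.copy(),
            component_targets=self.component_targets.copy(),
            rates=dict(self.rates),
            growth=self.growth.copy(),
        )


# ---------------------------------------------------------------------------
# validation (on raw frames, collecting every violation)
# ---------------------------------------------------------------------------

def _validate_raw(
    meta: dict,
    demography: pd.DataFrame,
    targets: pd.DataFrame,
    rates: pd.DataFrame,
    treatment: pd.DataFrame,
    unit_costs: pd.DataFrame,
    growth: pd.DataFrame,
) -> list[str]:
    v: list[str] = []

    for key in ("country", "currency", "base_year", "horizon_year",
                "proportion_treated", "visits_per_year", "visit_cost_eur"):
        if key not in meta:
            v.append(f"pack.json: missing field {key!r}")
    if meta.get("currency", "EUR") != "EUR":
        v.append(f"pack.json: currency must be EUR, got {meta.get('currency')!r}")
    if meta.get("horizon_year", 1) <= meta.get("base_year", 0):
        v.append("pack.json: horizon_year must be after base_year")
    pt = meta.get("proportion_treated", 0.0)
    if not 0.0 <= pt <= 1.0:
        v.append(f"pack.json: proportion_treated must be in [0,1], got {pt}")

    for col in ("population", "population_horizon", "htn_prevalence"):
        if col not in demography.columns:
            v.append(f"demography.csv: missing column {col!r}")
        elif (demography[col] < 0).any():
            v.append(f"demography.csv: column {col!r} has negative values")
    if "htn_prevalence" in demography.columns and (demography["htn_prevalence"] > 1).any():
        v.append("demography.csv: htn_prevalence above 1")

    for c in NON_BP_COMPONENTS:
        if c not in targets.columns:
            v.append(f"component_targets.csv: missing column {c!r}")
        elif ((targets[c] <= 0) | (targets[c] >= 1)).any():
            v.append(f"component_targets.csv: {c!r} targets must lie strictly in (0,1)")
    if not demography.index.equals(targets.index):
        v.append("component_targets.csv: strata do not match demography.csv")

    rates_ix = rates.set_index("outcome") if "outcome" in rates.columns else pd.DataFrame()
    for o in OUTCOMES:
        if o not in rates_ix.index:
            v.append(f"rates.csv: missing outcome {o!r}")
            continue
        row = rates_ix.loc[o]
        if row["overall_per_1000"] < 0:
            v.append(f"rates.csv: {o}: overall rate negative")
        rr = row[[f"rr_k{k}" for k in range(5)]].to_numpy(dtype=float)
        if abs(rr[0] - 1.0) > 1e-12:
            v.append(f"rates.csv: {o}: rr_k0 must be 1 (reference group)")
        if (np.diff(rr) < -1e-12).any():
            v.append(
                f"rates.csv: {o}: rr_k must be non-decreasing in k "
                "(risk rises with the number of MetS components)"
            )
        if (rr < 0).any():
            v.append(f"rates.csv: {o}: negative relative risk")
    if {"t2d_prevalent", "t2d_incident"} <= set(rates_ix.index):
        if (
            rates_ix.loc["t2d_incident", "overall_per_1000"]
            > rates_ix.loc["t2d_prevalent", "overall_per_1000"]
        ):
            v.append("rates.csv: t2d incidence exceeds t2d prevalence")

    share_sum = treatment["share"].sum() if "share" in treatment.columns else float("nan")
    if not abs(share_sum - 1.0) <= 1e-9:
        v.append(f"treatment.csv: drug-class shares must sum to 1, got {share_sum:.6f}")
    for col, lo, hi in (("continuation", 0.0, 1.0), ("rr_nod", 0.0, np.inf),
                        ("annual_cost_eur", 0.0, np.inf)):
        if col in treatment.columns and ((treatment[col] < lo) | (treatment[col] > hi)).any():
            v.append(f"treatment.csv: column {col!r} out of range [{lo},{hi}]")

    if "cost_eur" in unit_costs.columns and (unit_costs["cost_eur"] < 0).any():
        v.append("unit_costs.csv: negative unit cost")
    items = set(unit_costs.get("item", []))
    for needed in CV_EVENT_OUTCOMES + ("t2d_annual",):
        if needed not in items:
            v.append(f"unit_costs.csv: missing item {needed!r}")

    g_comps = set(growth.get("component", []))
    for c in GROWTH_COMPONENTS:
        if c not in g_comps:
            v.append(f"growth.csv: missing CAGR for component {c!r}")
    if "cagr" in growth.columns and (growth["cagr"] <= -1).any():
        v.append("growth.csv: CAGR must be > -1")

    return v


def _build_pack(
    meta: dict,
    demography: pd.DataFrame,
    targets: pd.DataFrame,
    rates: pd.DataFrame,
    treatment: pd.DataFrame,
    unit_costs: pd.DataFrame,
    growth: pd.DataFrame,
) -> ParameterPack:
    rates_ix = rates.set_index("outcome")
    rate_objs = {
        o: OutcomeRates(
            name=o,
            overall_per_1000=float(rates_ix.loc[o, "overall_per_1000"]),
            rr_by_k=tuple(float(rates_ix.loc[o, f"rr_k{k}"]) for k in range(5)),
        )
        for o in OUTCOMES
    }
    classes = tuple(
        DrugClass(
            name=str(r["class"]),
            share=float(r["share"]),
            annual_cost_eur=float(r["annual_cost_eur"]),
            continuation=float(r["continuation"]),
            rr_new_onset_diabetes=float(r["rr_nod"]),
        )
        for _, r in treatment.iterrows()
    )
    mix = TreatmentMix(
        proportion_treated=float(meta["proportion_treated"]),
        classes=classes,
        visits_per_year=float(meta["visits_per_year"]),
        visit_cost_eur=float(meta["visit_cost_eur"]),
    )
    uc = unit_costs.set_index("item")["cost_eur"]
    costs = UnitCosts(
        event_cost_eur={o: float(uc[o]) for o in CV_EVENT_OUTCOMES},
        t2d_annual_cost_eur=float(uc["t2d_annual"]),
    )
    cagr = growth.set_index("component")["cagr"].astype(float).to_dict()
    ga = GrowthAssumptions(
        cagr=cagr,
        base_year=int(meta["base_year"]),
        horizon_year=int(meta["horizon_year"]),
    )
    return ParameterPack(
        country=str(meta["country"]),
        demography=demography,
        component_targets=targets[list(NON_BP_COMPONENTS)].astype(float),
        rates=rate_objs,
        mix=mix,
        unit_costs=costs,
        growth=ga,
        currency=str(meta["currency"]),
        base_year=int(meta["base_year"]),
        horizon_year=int(meta["horizon_year"]),
    )


def _read_stratum_csv(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"age_band": str, "sex": str})
    df = df.set_index(["age_band", "sex"])
    df.index = pd.MultiIndex.from_tuples([tuple(t) for t in df.index])
    return df


def validate_parameter_pack(directory: str | Path) -> ParameterPack:
    """Load a pack directory, reporting *all* violations on failure."""
    d = Path(directory)
    missing = [
        f
        for f in (
            "pack.json", "demography.csv", "component_targets.csv",
            "rates.csv", "treatment.csv", "unit_costs.csv", "growth.csv",
        )
        if not (d / f).exists()
    ]
    if missing:
        raise PackValidationError([f"missing file {f!r}" for f in missing])
    meta = json.loads((d / "pack.json").read_text())
    demography = _read_stratum_csv(d / "demography.csv")
    targets = _read_stratum_csv(d / "component_targets.csv")
    rates = pd.read_csv(d / "rates.csv")
    treatment = pd.read_csv(d / "treatment.csv")
    unit_costs = pd.read_csv(d / "unit_costs.csv")
    growth = pd.read_csv(d / "growth.csv")
    violations = _validate_raw(meta, demography, targets, rates, treatment, unit_costs, growth)
    if violations:
        raise PackValidationError(violations)
    return _build_pack(meta, demography, targets, rates, treatment, unit_costs, growth)


#: alias matching the pipeline's vocabulary
load_pack = validate_parameter_pack


def save_pack(pack: ParameterPack, directory: str | Path) -> None:
    """Write a pack back out in the directory schema."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    meta = {
        "country": pack.country,
        "currency": pack.currency,
        "base_year": pack.base_year,
        "horizon_year": pack.horizon_year,
        "proportion_treated": pack.mix.proportion_treated,
        "visits_per_year": pack.mix.visits_per_year,
        "visit_cost_eur": pack.mix.visit_cost_eur,
    }
    (d / "pack.json").write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")

    def _write_stratum(df: pd.DataFrame, name: str) -> None:
        out = df.copy()
        out.insert(0, "sex", [s for _, s in out.index])
        out.insert(0, "age_band", [b for b, _ in out.index])
        out.to_csv(d / name, index=False)

    _write_stratum(pack.demography, "demography.csv")
    _write_stratum(pack.component_targets, "component_targets.csv")
    pd.DataFrame(
        [
            {"outcome": o, "overall_per_1000": r.overall_per_1000}
            | {f"rr_k{k}": r.rr_by_k[k] for k in range(5)}
            for o, r in pack.rates.items()
        ]
    ).to_csv(d / "rates.csv", index=False)
    pd.DataFrame(
        [
            {
                "class": c.name,
                "share": c.share,
                "annual_cost_eur": c.annual_cost_eur,
                "continuation": c.continuation,
                "rr_nod": c.rr_new_onset_diabetes,
            }
            for c in pack.mix.classes
        ]
    ).to_csv(d / "treatment.csv", index=False)
    pd.DataFrame(
        [{"item": o, "cost_eur": c} for o, c in pack.unit_costs.event_cost_eur.items()]
        + [{"item": "t2d_annual", "cost_eur": pack.unit_costs.t2d_annual_cost_eur}]
    ).to_csv(d / "unit_costs.csv", index=False)
    pd.DataFrame(
        [{"component": c, "cagr": g} for c, g in pack.growth.cagr.items()]
    ).to_csv(d / "growth.csv", index=False)


# ---------------------------------------------------------------------------
# illustrative demo packs
# ---------------------------------------------------------------------------

DEMO_STYLES = ("DE", "ES", "IT")

# adult (20+) population in millions, split over the seven bands x two sexes
_BAND_SHARES = np.array([0.16, 0.17, 0.19, 0.17, 0.14, 0.11, 0.06])
_POP_MILLIONS = {"DE": 68.0, "ES": 37.0, "IT": 49.0}

# hypertension prevalence by age band (both sexes; male slightly higher)
_HTN_BY_BAND = {
    "DE": (0.14, 0.25, 0.42, 0.60, 0.74, 0.82, 0.86),
    "ES": (0.11, 0.20, 0.36, 0.54, 0.69, 0.78, 0.82),
    "IT": (0.10, 0.19, 0.35, 0.53, 0.68, 0.77, 0.82),
}

# non-BP component prevalence among hypertensives at the middle band (50-59);
# a gentle age gradient is applied around these anchors
_TARGET_ANCHORS = {
    "DE": {"obesity": 0.62, "low_hdl": 0.34, "high_tg": 0.45, "impaired_glucose": 0.42},
    "ES": {"obesity": 0.40, "low_hdl": 0.15, "high_tg": 0.20, "impaired_glucose": 0.15},
    "IT": {"obesity": 0.44, "low_hdl": 0.15, "high_tg": 0.21, "impaired_glucose": 0.16},
}
_AGE_GRADIENT = np.array([-0.06, -0.04, -0.02, 0.0, 0.02, 0.03, 0.03])

_PROPORTION_TREATED = {"DE": 0.74, "ES": 0.66, "IT": 0.70}
_VISITS = {"DE": (4.4, 28.0), "ES": (3.4, 18.0), "IT": (3.6, 21.0)}

# relative risks by k: events/mortality roughly double and T2D prevalence is
# roughly six-fold in the MetS aggregate under the DE-style decomposition
_RR_EVENTS = (1.0, 1.45, 2.1, 2.9, 3.8)
_RR_T2D = (1.0, 3.0, 9.0, 16.0, 24.0)

_OVERALL_RATES = {
    # per 1,000 hypertensives: cv events split, mortality, T2D pool/flow
    "DE": {"ami": 4.4, "chf": 5.6, "unstable_angina": 3.2, "stroke": 5.6, "cv_death": 3.2,
           "attributable_mortality": 2.4, "t2d_prevalent": 168.0, "t2d_incident": 9.0},
    "ES": {"ami": 3.6, "chf": 4.4, "unstable_angina": 2.6, "stroke": 4.6, "cv_death": 2.6,
           "attributable_mortality": 2.0, "t2d_prevalent": 102.0, "t2d_incident": 7.0},
    "IT": {"ami": 3.4, "chf": 4.2, "unstable_angina": 2.6, "stroke": 4.6, "cv_death": 2.4,
           "attributable_mortality": 1.9, "t2d_prevalent": 106.0, "t2d_incident": 7.0},
}

_EVENT_COSTS = {
    "DE": {"ami": 6800.0, "chf": 5400.0, "unstable_angina": 4300.0, "stroke": 9200.0,
           "cv_death": 0.0},
    "ES": {"ami": 5600.0, "chf": 4300.0, "unstable_angina": 3500.0, "stroke": 7300.0,
           "cv_death": 0.0},
    "IT": {"ami": 6100.0, "chf": 4700.0, "unstable_angina": 3900.0, "stroke": 8100.0,
           "cv_death": 0.0},
}
_T2D_ANNUAL = {"DE": 2750.0, "ES": 1650.0, "IT": 2250.0}

_CLASSES = (
    # name, share, annual cost EUR, continuation, rr new-onset diabetes
    ("arb", 0.14, 340.0, 0.80, 0.75),
    ("ace_inhibitor", 0.24, 190.0, 0.72, 0.85),
    ("ccb", 0.16, 210.0, 0.66, 1.00),
    ("diuretic", 0.16, 95.0, 0.55, 1.30),
    ("beta_blocker", 0.18, 130.0, 0.60, 1.25),
    ("combination", 0.12, 420.0, 0.76, 1.05),
)

_CAGR = {
    "DE": {"obesity": 0.018, "low_hdl": 0.004, "high_tg": 0.009,
           "impaired_glucose": 0.024, "hypertension": 0.004},
    "ES": {"obesity": 0.030, "low_hdl": 0.010, "high_tg": 0.020,
           "impaired_glucose": 0.045, "hypertension": 0.008},
    "IT": {"obesity": 0.028, "low_hdl": 0.010, "high_tg": 0.019,
           "impaired_glucose": 0.042, "hypertension": 0.008},
}
# horizon/base population ratio by band: population ages into the older bands
_POP_GROWTH_BY_BAND = np.array([0.93, 0.96, 0.98, 1.05, 1.18, 1.28, 1.42])


def demo_pack(style: str = "DE") -> ParameterPack:
    """Build an illustrative parameter pack of the given country style."""
    if style not in DEMO_STYLES:
        raise ValueError(f"unknown demo style {style!r}; choose from {DEMO_STYLES}")
    strata = [(band, sex) for band in AGE_BANDS for sex in SEXES]
    idx = pd.MultiIndex.from_tuples(strata)
    pop = np.array(
        [
            _POP_MILLIONS[style] * 1e6 * _BAND_SHARES[AGE_BANDS.index(band)] / 2.0
            for band, _ in strata
        ]
    )
    htn = np.array(
        [
            _HTN_BY_BAND[style][AGE_BANDS.index(band)] * (1.04 if sex == "male" else 0.96)
            for band, sex in strata
        ]
    )
    demography = pd.DataFrame(
        {
            "population": pop,
            "population_horizon": pop
            * np.array([_POP_GROWTH_BY_BAND[AGE_BANDS.index(b)] for b, _ in strata]),
            "htn_prevalence": htn,
        },
        index=idx,
    )
    anchors = _TARGET_ANCHORS[style]
    targets = pd.DataFrame(
        {
            c: np.clip(
                [anchors[c] + _AGE_GRADIENT[AGE_BANDS.index(b)] for b, _ in strata],
                0.02,
                0.95,
            )
            for c in NON_BP_COMPONENTS
        },
        index=idx,
    )
    rates = {
        o: OutcomeRates(
            name=o,
            overall_per_1000=_OVERALL_RATES[style][o],
            rr_by_k=_RR_T2D if o.startswith("t2d") else _RR_EVENTS,
        )
        for o in OUTCOMES
    }
    visits, visit_cost = _VISITS[style]
    mix = TreatmentMix(
        proportion_treated=_PROPORTION_TREATED[style],
        classes=tuple(DrugClass(*c) for c in _CLASSES),
        visits_per_year=visits,
        visit_cost_eur=visit_cost,
    )
    costs = UnitCosts(event_cost_eur=_EVENT_COSTS[style], t2d_annual_cost_eur=_T2D_ANNUAL[style])
    growth = GrowthAssumptions(cagr=dict(_CAGR[style]), base_year=2008, horizon_year=2020)
    return ParameterPack(
        country=style,
        demography=demography,
        component_targets=targets,
        rates=rates,
        mix=mix,
        unit_costs=costs,
        growth=growth,
    )
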