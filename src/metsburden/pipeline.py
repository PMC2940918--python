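"""End-to-end pipeline: conditional structure -> decomposition -> burden.

``run_year`` executes one annual snapshot (base or horizon year) for one
country pack; ``run_pipeline`` wires microdata generation / loading,
reference estimation, both snapshot years and report serialisation into a
single deterministic, provenance-stamped run.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
import yaml

from .atp3 import NON_BP_COMPONENTS
from .burden import (
    CV_EVENT_OUTCOMES,
    CostBreakdown,
    annual_costs,
    calibrate_group_rates,
    cost_shares,
    event_rate_per_1000,
    expected_events,
    mets_cost_share,
    per_patient_cost,
    round_half_away,
    treatment_attributable_new_onset_t2d,
)
from .conditional import (
    RISK_GROUPS,
    ConditionalMatrix,
    calibrate_to_marginals,
    decompose_population,
    estimate_conditional_matrix,
)
from .microdata import DEFAULT_SEED, default_generator_spec, generate_microdata
from .packs import ParameterPack, demo_pack, load_pack
from .projection import discount, project_marginal

__all__ = ["YearResult", "RunConfig", "BurdenReport", "run_year", "run_pipeline"]

logger = logging.getLogger(__name__)


def _pkg_version() -> str:
    try:
        return version("metsburden")
    except PackageNotFoundError:  # pragma: no cover
        return "unknown"


@dataclass
class YearResult:
    """All unrounded results of one annual snapshot for one country."""

    country: str
    year: int
    matrix: ConditionalMatrix
    risk_table: pd.DataFrame  # per-stratum persons in k0..k4
    persons_by_k: np.ndarray  # pooled persons per group
    events_by_outcome: dict[str, np.ndarray]  # per-k annual counts
    t2d_prevalent_by_k: np.ndarray
    t2d_incident_by_k: np.ndarray
    t2d_new_onset_by_k: np.ndarray  # treatment-attributable new-onset cases
    breakdown_by_k: list[CostBreakdown]
    breakdown_mets: CostBreakdown
    breakdown_non_mets: CostBreakdown
    discount_rate: float | None = None
    discount_years: int = 0

    # -- aggregates -------------------------------------------------------
    @property
    def total_hypertensives(self) -> float:
        return float(self.persons_by_k.sum())

    @property
    def mets_persons(self) -> float:
        return float(self.persons_by_k[2:].sum())

    @property
    def non_mets_persons(self) -> float:
        return float(self.persons_by_k[:2].sum())

    @property
    def mets_share_of_hypertensives(self) -> float:
        return self.mets_persons / self.total_hypertensives

    @property
    def breakdown_total(self) -> CostBreakdown:
        return self.breakdown_mets + self.breakdown_non_mets

    def _split(self, by_k: np.ndarray) -> tuple[float, float]:
        return float(by_k[2:].sum()), float(by_k[:2].sum())

    def cv_events_by_k(self) -> np.ndarray:
        return sum(self.events_by_outcome[o] for o in CV_EVENT_OUTCOMES)

    def epidemiology(self) -> pd.DataFrame:
        """Cases and rates per 1,000 by MetS split (events/mortality/T2D)."""
        rows = []
        for name, by_k in (
            ("cv_events", self.cv_events_by_k()),
            ("mortality", self.events_by_outcome["attributable_mortality"]),
            ("t2d_prevalent", self.t2d_prevalent_by_k),
        ):
            mets, non = self._split(by_k)
            rows.append(
                {
                    "outcome": name,
                    "mets_cases": mets,
                    "mets_rate_per_1000": event_rate_per_1000(mets, self.mets_persons),
                    "non_mets_cases": non,
                    "non_mets_rate_per_1000": event_rate_per_1000(non, self.non_mets_persons),
                }
            )
        return pd.DataFrame(rows).set_index("outcome")

    def per_patient_by_k(self) -> np.ndarray:
        return per_patient_cost(self.breakdown_by_k, self.persons_by_k)

    def discounted(self, breakdown: CostBreakdown) -> CostBreakdown:
        """Cost breakdown discounted back to the base year, if a rate is set."""
        if self.discount_rate is None:
            return breakdown
        f = discount(1.0, self.discount_rate, self.discount_years)
        return CostBreakdown(
            breakdown.drug * f, breakdown.physician * f, breakdown.cvd * f,
            breakdown.t2d * f, label=breakdown.label,
        )

    def summary(self) -> dict:
        """Unrounded headline numbers for the JSON summary."""
        epi = self.epidemiology()
        shares = cost_shares(self.breakdown_mets)
        out = {
            "country": self.country,
            "year": self.year,
            "total_hypertensives": self.total_hypertensives,
            "persons_by_k": self.persons_by_k.tolist(),
            "mets_share_of_hypertensives": self.mets_share_of_hypertensives,
            "costs_meur": {
                split: {
                    "drug": b.drug, "physician": b.physician,
                    "cvd": b.cvd, "t2d": b.t2d, "total": b.total,
                }
                for split, b in (
                    ("mets", self.breakdown_mets),
                    ("non_mets", self.breakdown_non_mets),
                    ("all", self.breakdown_total),
                )
            },
            "mets_cost_share_pct": mets_cost_share(
                self.breakdown_mets.total, self.breakdown_non_mets.total
            ),
            "mets_component_shares_pct": shares,
            "per_patient_eur_by_k": [
                None if np.isnan(x) else float(x) for x in self.per_patient_by_k()
            ],
            "epidemiology": epi.reset_index().to_dict(orient="records"),
        }
        if self.discount_rate is not None:
            out["discounted_total_meur"] = self.discounted(self.breakdown_total).total
            out["discount_rate"] = self.discount_rate
        return out


def run_year(
    pack: ParameterPack,
    reference: ConditionalMatrix,
    year: Literal["base", "horizon"] = "base",
    discount_rate: float | None = None,
) -> YearResult:
    """One annual snapshot: calibrate, decompose, attribute, cost.

    For the horizon year the component and hypertension prevalences are
    projected by their CAGRs, horizon demography is used, and prices stay at
    base-year level; ``discount_rate`` (or the pack's ``discount_rate``)
    additionally enables discounting of the horizon costs to the base year.
    """
    t0 = time.perf_counter()
    if year == "base":
        targets = pack.component_targets
        htn_prev = pack.demography["htn_prevalence"]
        population = pack.demography["population"]
        year_label = pack.base_year
        discount_rate = None
    elif year == "horizon":
        missing = [c for c in NON_BP_COMPONENTS + ("hypertension",) if c not in pack.growth.cagr]
        if missing:
            raise ValueError(f"growth assumptions missing CAGR for: {missing}")
        n_years = pack.growth.years
        targets = pack.component_targets.copy()
        for c in NON_BP_COMPONENTS:
            g = pack.growth.cagr[c]
            targets[c] = [project_marginal(p, g, n_years) for p in targets[c]]
        g_htn = pack.growth.cagr["hypertension"]
        htn_prev = pd.Series(
            [project_marginal(p, g_htn, n_years) for p in pack.demography["htn_prevalence"]],
            index=pack.demography.index,
        )
        population = pack.demography["population_horizon"]
        year_label = pack.horizon_year
        if discount_rate is None:
            discount_rate = pack.discount_rate
    else:
        raise ValueError(f"year must be 'base' or 'horizon', got {year!r}")

    # IPF targets must sit strictly inside (0,1); projection may have capped at 1
    targets = targets.clip(1e-9, 1.0 - 1e-9)
    matrix = calibrate_to_marginals(reference, targets)
    htn_counts = population * htn_prev
    risk_table = decompose_population(htn_counts, matrix)
    persons = risk_table.sum(axis=0).to_numpy(dtype=float)
    weights = persons / persons.sum()

    events: dict[str, np.ndarray] = {}
    for o in CV_EVENT_OUTCOMES + ("attributable_mortality",):
        r = pack.rates[o]
        rates_k = calibrate_group_rates(r.overall_per_1000, weights, r.rr_by_k)
        events[o] = expected_events(persons, rates_k)

    prev_rates = calibrate_group_rates(
        pack.rates["t2d_prevalent"].overall_per_1000, weights,
        pack.rates["t2d_prevalent"].rr_by_k,
    )
    inc_rates = calibrate_group_rates(
        pack.rates["t2d_incident"].overall_per_1000, weights,
        pack.rates["t2d_incident"].rr_by_k,
    )
    t2d_prev = expected_events(persons, prev_rates)
    t2d_inc = expected_events(persons, inc_rates)
    t2d_nod = treatment_attributable_new_onset_t2d(persons, pack.mix, inc_rates)

    t2d_costed = (t2d_inc + t2d_nod) if pack.t2d_incident_only else t2d_prev
    by_k = annual_costs(
        persons,
        {o: events[o] for o in CV_EVENT_OUTCOMES},
        t2d_costed,
        pack.mix,
        pack.unit_costs,
        label=f"{pack.country}/{year_label}/",
    )
    mets = CostBreakdown(0, 0, 0, 0, label=f"{pack.country}/{year_label}/mets")
    non = CostBreakdown(0, 0, 0, 0, label=f"{pack.country}/{year_label}/non_mets")
    for k, b in enumerate(by_k):
        if k >= 2:
            mets = mets + b
        else:
            non = non + b
    mets = CostBreakdown(mets.drug, mets.physician, mets.cvd, mets.t2d,
                         label=f"{pack.country}/{year_label}/mets")
    non = CostBreakdown(non.drug, non.physician, non.cvd, non.t2d,
                        label=f"{pack.country}/{year_label}/non_mets")
    result = YearResult(
        country=pack.country,
        year=year_label,
        matrix=matrix,
        risk_table=risk_table,
        persons_by_k=persons,
        events_by_outcome=events,
        t2d_prevalent_by_k=t2d_prev,
        t2d_incident_by_k=t2d_inc,
        t2d_new_onset_by_k=t2d_nod,
        breakdown_by_k=by_k,
        breakdown_mets=mets,
        breakdown_non_mets=non,
        discount_rate=discount_rate,
        discount_years=pack.growth.years if year == "horizon" else 0,
    )
    logger.info(
        "run_year %s/%s: %.0f hypertensives, MetS share %.1f%%, total %.0f MEUR (%.2fs)",
        pack.country, year_label, result.total_hypertensives,
        100 * result.mets_share_of_hypertensives, result.breakdown_total.total,
        time.perf_counter() - t0,
    )
    return result


# ---------------------------------------------------------------------------
# full configured runs
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Configuration of a reproducible pipeline run.

    Exactly one of ``pack_dir`` / ``demo_style`` selects the country pack;
    the conditional-structure reference comes from ``reference_csv``,
    ``microdata_csv``, or (default) freshly generated synthetic microdata of
    size ``n_subjects`` under ``seed``.
    """

    pack_dir: str | None = None
    demo_style: str | None = "DE"
    reference_csv: str | None = None
    microdata_csv: str | None = None
    n_subjects: int = 50_000
    seed: int = DEFAULT_SEED
    include_horizon: bool = True
    discount_rate: float | None = None
    output_dir: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**raw)

    def provenance_hash(self) -> str:
        blob = json.dumps(self.__dict__, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()


@dataclass
class BurdenReport:
    """Rounded report tables plus the unrounded summary and provenance."""

    base: YearResult
    horizon: YearResult | None
    tables: dict[str, pd.DataFrame]
    summary: dict
    provenance: dict

    def write(self, directory: str | Path) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        for name, df in self.tables.items():
            df.to_csv(d / f"{name}.csv", index=False)
        (d / "summary.json").write_text(
            json.dumps(self.summary, indent=2, sort_keys=True) + "\n"
        )
        (d / "provenance.json").write_text(
            json.dumps(self.provenance, indent=2, sort_keys=True) + "\n"
        )


def _table1(results: list[YearResult]) -> pd.DataFrame:
    rows = []
    for res in results:
        epi = res.epidemiology()
        for outcome, r in epi.iterrows():
            for split in ("mets", "non_mets"):
                rows.append(
                    {
                        "country": res.country,
                        "year": res.year,
                        "outcome": outcome,
                        "split": split,
                        # cases rounded to the nearest 100, rates to 2 dp
                        "cases": round_half_away(r[f"{split}_cases"], -2),
                        "rate_per_1000": round_half_away(r[f"{split}_rate_per_1000"], 2),
                    }
                )
    return pd.DataFrame(rows)


def _table2(results: list[YearResult]) -> pd.DataFrame:
    rows = []
    for res in results:
        for split, b in (("mets", res.breakdown_mets), ("non_mets", res.breakdown_non_mets)):
            rows.append(
                {
                    "country": res.country,
                    "year": res.year,
                    "split": split,
                    "drug": round_half_away(b.drug),
                    "physician": round_half_away(b.physician),
                    "cvd": round_half_away(b.cvd),
                    "t2d": round_half_away(b.t2d),
                    "total": round_half_away(b.total),
                }
            )
    return pd.DataFrame(rows)


def _per_patient_table(results: list[YearResult]) -> pd.DataFrame:
    rows = []
    for res in results:
        pp = res.per_patient_by_k()
        for k, group in enumerate(RISK_GROUPS):
            rows.append(
                {
                    "country": res.country,
                    "year": res.year,
                    "group": group,
                    "per_patient_eur": (
                        float("nan") if np.isnan(pp[k]) else round_half_away(pp[k])
                    ),
                }
            )
    return pd.DataFrame(rows)


def build_reference(config: RunConfig) -> ConditionalMatrix:
    """Obtain the conditional-structure reference per the run config."""
    if config.reference_csv:
        return ConditionalMatrix.from_csv(config.reference_csv)
    if config.microdata_csv:
        records = pd.read_csv(config.microdata_csv, dtype={"age_band": str, "sex": str})
    else:
        logger.info(
            "generating %d synthetic microdata records (seed %d)",
            config.n_subjects, config.seed,
        )
        records = generate_microdata(default_generator_spec(config.n_subjects, config.seed))
    return estimate_conditional_matrix(records)


def run_pipeline(config: RunConfig) -> BurdenReport:
    """Execute the full pipeline for one country pack.

    Deterministic given the config (including the seed): running the same
    config twice yields byte-identical output files.
    """
    if (config.pack_dir is None) == (config.demo_style is None):
        raise ValueError("exactly one of pack_dir / demo_style must be set")
    pack = load_pack(config.pack_dir) if config.pack_dir else demo_pack(config.demo_style)
    reference = build_reference(config)

    base = run_year(pack, reference, "base")
    results = [base]
    horizon = None
    if config.include_horizon:
        horizon = run_year(pack, reference, "horizon", discount_rate=config.discount_rate)
        results.append(horizon)

    summary: dict = {"base": base.summary()}
    if horizon is not None:
        summary["horizon"] = horizon.summary()
        summary["mets_cost_rise_pct"] = 100.0 * (
            horizon.breakdown_mets.total / base.breakdown_mets.total - 1.0
        )
    tables = {
        "table1": _table1(results),
        "table2": _table2(results),
        "per_patient": _per_patient_table(results),
    }
    provenance = {
        "config_hash": config.provenance_hash(),
        "seed": config.seed,
        "package_version": _pkg_version(),
        "country": pack.country,
        "ipf_iterations": {
            f"{res.year}": {f"{b}/{s}": n for (b, s), n in res.matrix.ipf_iterations.items()}
            for res in results
        },
    }
    report = BurdenReport(
        base=base, horizon=horizon, tables=tables, summary=summary, provenance=provenance
    )
    if config.output_dir:
        report.write(config.output_dir)
    return report
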