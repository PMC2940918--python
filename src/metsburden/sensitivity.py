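"""Univariate (one-at-a-time) sensitivity analysis.

Each scenario perturbs exactly one model input — a unit-cost family scaled
by a factor, the continuation rate, the treated share, the
incident-instead-of-prevalent diabetes toggle, or the discount rate — while
every other parameter stays bit-identical to the baseline.  The engine
reruns the full burden computation per scenario and tabulates total annual
costs for the MetS presence/absence splits, ordered tornado-style by the
absolute spread of the presence totals.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import pandas as pd

from .burden import round_half_away
from .conditional import ConditionalMatrix
from .packs import ParameterPack
from .pipeline import YearResult, run_year

__all__ = ["Scenario", "apply_scenario", "run_univariate", "default_scenarios"]

_KINDS = (
    "scale_unit_cost",
    "scale_continuation",
    "t2d_incident_only",
    "set_proportion_treated",
    "discount",
)


@dataclass(frozen=True)
class Scenario:
    """One univariate perturbation of the baseline parameter set."""

    name: str
    kind: str
    target: str | None = None  # for scale_unit_cost: drug | cvd | t2d
    factor: float | None = None  # for the scaling kinds
    value: float | None = None  # for set_proportion_treated
    rate: float | None = None  # for discount

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown scenario kind {self.kind!r}; expected one of {_KINDS}")
        if self.kind == "scale_unit_cost":
            if self.target not in ("drug", "cvd", "t2d"):
                raise ValueError(f"unknown unit-cost target {self.target!r}")
            if self.factor is None or self.factor < 0:
                raise ValueError("scale_unit_cost needs a non-negative factor")
        elif self.kind == "scale_continuation" and (self.factor is None or self.factor < 0):
            raise ValueError("scale_continuation needs a non-negative factor")
        elif self.kind == "set_proportion_treated" and not (
            self.value is not None and 0.0 <= self.value <= 1.0
        ):
            raise ValueError("set_proportion_treated needs a value in [0,1]")
        elif self.kind == "discount" and (self.rate is None or self.rate <= -1):
            raise ValueError("discount needs a rate > -1")


def apply_scenario(pack: ParameterPack, scenario: Scenario) -> ParameterPack:
    """Return a deep copy of the pack with only the named factor changed."""
    out = pack.copy()
    if scenario.kind == "scale_unit_cost":
        if scenario.target == "drug":
            classes = tuple(
                replace(c, annual_cost_eur=c.annual_cost_eur * scenario.factor)
                for c in out.mix.classes
            )
            out.mix = replace(out.mix, classes=classes)
        else:
            out.unit_costs = out.unit_costs.scaled(scenario.target, scenario.factor)
    elif scenario.kind == "scale_continuation":
        classes = tuple(
            replace(c, continuation=min(1.0, c.continuation * scenario.factor))
            for c in out.mix.classes
        )
        out.mix = replace(out.mix, classes=classes)
    elif scenario.kind == "t2d_incident_only":
        out.t2d_incident_only = True
    elif scenario.kind == "set_proportion_treated":
        out.mix = replace(out.mix, proportion_treated=scenario.value)
    elif scenario.kind == "discount":
        out.discount_rate = scenario.rate
    return out


def default_scenarios(
    treated_share_override: float | None = None, discount_rate: float = 0.03
) -> list[Scenario]:
    """The standard univariate set: incident-only T2D, +/-20% continuation
    and unit costs, an optional treated-share override, and discounting."""
    scenarios = [Scenario("t2d_incident_only", "t2d_incident_only")]
    for factor, tag in ((1.2, "+20%"), (0.8, "-20%")):
        scenarios.append(Scenario(f"continuation {tag}", "scale_continuation", factor=factor))
    for target in ("drug", "cvd", "t2d"):
        for factor, tag in ((1.2, "+20%"), (0.8, "-20%")):
            scenarios.append(
                Scenario(f"{target} cost {tag}", "scale_unit_cost", target=target, factor=factor)
            )
    if treated_share_override is not None:
        scenarios.append(
            Scenario(
                f"proportion treated {treated_share_override:.0%}",
                "set_proportion_treated",
                value=treated_share_override,
            )
        )
    scenarios.append(Scenario(f"discount {discount_rate:.0%}", "discount", rate=discount_rate))
    return scenarios


def run_univariate(
    pack: ParameterPack,
    reference: ConditionalMatrix,
    scenarios: Sequence[Scenario],
    year: str = "base",
) -> pd.DataFrame:
    """Baseline plus one row per scenario with presence/absence totals.

    Totals are in EUR millions, unrounded; ``rounded_table`` serialises
    them.  Discount scenarios only change horizon-year runs (there is
    nothing to discount in the base year).  Scenario rows are ordered by the
    absolute spread of their presence totals around the baseline, largest
    first (tornado ordering); the baseline row stays on top.
    """
    def _totals(res: YearResult) -> tuple[float, float]:
        return (
            res.discounted(res.breakdown_mets).total,
            res.discounted(res.breakdown_non_mets).total,
        )

    base_res = run_year(pack, reference, year)
    rows = [{"scenario": "baseline", "presence": _totals(base_res)[0],
             "absence": _totals(base_res)[1]}]
    for sc in scenarios:
        res = run_year(apply_scenario(pack, sc), reference, year)
        presence, absence = _totals(res)
        rows.append({"scenario": sc.name, "presence": presence, "absence": absence})
    df = pd.DataFrame(rows)
    spread = (df["presence"] - df.loc[0, "presence"]).abs()
    order = [0] + list(spread.iloc[1:].sort_values(ascending=False).index)
    return df.loc[order].reset_index(drop=True)


def rounded_table(table: pd.DataFrame) -> pd.DataFrame:
    out = table.copy()
    for col in ("presence", "absence"):
        out[col] = [round_half_away(x) for x in out[col]]
    return out
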