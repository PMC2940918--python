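"""Projection of prevalences to a horizon year and cost discounting.

Component prevalences grow by compound annual growth rates (CAGRs) applied
multiplicatively and capped at 1; demographic change enters only through the
horizon-year population counts carried by the parameter pack.  Horizon costs
stay at base-year prices.  Discounting follows a single-snapshot convention:
the horizon-year annual cost is discounted back over (horizon - base) years
at an annual compound rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Mapping

if TYPE_CHECKING:  # pragma: no cover
    from .conditional import ConditionalMatrix
    from .packs import ParameterPack
    from .pipeline import YearResult

__all__ = ["GrowthAssumptions", "project_marginal", "project_burden", "discount"]


@dataclass
class GrowthAssumptions:
    """CAGRs per component plus the projection window.

    ``cagr`` maps each of the four non-BP components and ``"hypertension"``
    to a fractional annual growth rate (0.02 = +2 %/year).  The horizon-year
    population counts live in the pack's demography table.
    """

    cagr: Mapping[str, float] = field(default_factory=dict)
    base_year: int = 2008
    horizon_year: int = 2020

    def __post_init__(self) -> None:
        if self.horizon_year <= self.base_year:
            raise ValueError("horizon_year must be after base_year")
        for c, g in self.cagr.items():
            if g <= -1:
                raise ValueError(f"CAGR for {c!r} must be > -1, got {g}")

    @property
    def years(self) -> int:
        return self.horizon_year - self.base_year

    def copy(self) -> "GrowthAssumptions":
        return GrowthAssumptions(dict(self.cagr), self.base_year, self.horizon_year)


def project_marginal(p0: float, g: float, years: int) -> float:
    """Prevalence after ``years`` of compound growth, capped at 1."""
    if not 0.0 <= p0 <= 1.0:
        raise ValueError(f"prevalence must be in [0,1], got {p0}")
    if years < 0:
        raise ValueError("years must be >= 0")
    if g <= -1:
        raise ValueError(f"CAGR must be > -1, got {g}")
    return min(1.0, p0 * (1.0 + g) ** years)


def discount(amount: float, rate: float, years: int) -> float:
    """Present value of ``amount`` received ``years`` ahead at a compound rate."""
    if rate <= -1:
        raise ValueError(f"discount rate must be > -1, got {rate}")
    if years < 0:
        raise ValueError("years must be >= 0")
    return amount / (1.0 + rate) ** years


def project_burden(
    pack: "ParameterPack",
    reference: "ConditionalMatrix",
    discount_rate: float | None = None,
) -> "YearResult":
    """Recompute the full burden at the pack's horizon year.

    Component and hypertension prevalences are projected by their CAGRs, the
    conditional matrix is re-calibrated to the projected marginals, and the
    decomposition, consequences and costs are recomputed on horizon-year
    demography at base-year prices.  When ``discount_rate`` is given, the
    result additionally carries cost breakdowns discounted back to the base
    year.
    """
    from .pipeline import run_year  # deferred: pipeline composes this module

    return run_year(pack, reference, year="horizon", discount_rate=discount_rate)
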