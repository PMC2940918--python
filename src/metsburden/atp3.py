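"""Modified ATP III component classification and risk-category assignment.

Metabolic syndrome (MetS) is defined here by the Adult Treatment Panel III
criteria of the US National Cholesterol Education Program, with the blood
pressure cut-off raised from 135/85 to 140/90 mm Hg (the treatment threshold
used by current European and US hypertension guidelines, and the definition
used by the epidemiological sources the model draws on).  A subject has MetS
when at least three of the five components are present; because the model
covers the hypertensive population only, this is equivalent to hypertension
plus at least two of the four other components.

Inequality directions follow the printed criteria exactly: waist strictly
greater-than, HDL strictly less-than, triglycerides / fasting glucose / blood
pressure inclusive greater-or-equal.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Mapping

__all__ = [
    "Atp3Thresholds",
    "ComponentFlags",
    "RiskCategory",
    "MODIFIED_ATP3",
    "UNMODIFIED_ATP3",
    "ClassificationError",
    "OutOfModelError",
    "classify_components",
    "assign_risk_category",
]

#: Canonical component order used throughout the package.  The four non-BP
#: components keep this order when encoding component subsets as bit strings.
COMPONENTS = ("obesity", "hypertension", "low_hdl", "high_tg", "impaired_glucose")
NON_BP_COMPONENTS = ("obesity", "low_hdl", "high_tg", "impaired_glucose")

#: Measurement fields classify_components requires, in order.
MEASUREMENT_FIELDS = (
    "waist_cm",
    "sbp_mmhg",
    "dbp_mmhg",
    "hdl_mgdl",
    "tg_mgdl",
    "fpg_mgdl",
)


class ClassificationError(ValueError):
    """A subject could not be classified (missing/invalid measurement)."""


class OutOfModelError(ValueError):
    """The subject falls outside the modelled (hypertensive) population."""


@dataclass(frozen=True)
class Atp3Thresholds:
    """Diagnostic cut-offs for the five MetS components.

    Units: waist in cm, blood pressure in mm Hg, HDL / triglycerides /
    fasting plasma glucose in mg/dL.
    """

    waist_cm_male: float = 102.0
    waist_cm_female: float = 88.0
    sbp_mmhg: float = 140.0
    dbp_mmhg: float = 90.0
    hdl_mgdl_male: float = 40.0
    hdl_mgdl_female: float = 50.0
    tg_mgdl: float = 150.0
    fpg_mgdl: float = 110.0

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not v > 0:
                raise ValueError(f"threshold {f.name} must be strictly positive, got {v!r}")


#: Default profile: ATP III with the blood-pressure criterion modified to 140/90.
MODIFIED_ATP3 = Atp3Thresholds()
#: The unmodified ATP III profile (blood pressure 135/85), for comparison runs.
UNMODIFIED_ATP3 = Atp3Thresholds(sbp_mmhg=135.0, dbp_mmhg=85.0)


@dataclass(frozen=True)
class ComponentFlags:
    """Presence/absence of the five ATP III components for one subject."""

    obesity: bool
    hypertension: bool
    low_hdl: bool
    high_tg: bool
    impaired_glucose: bool

    @property
    def n_components(self) -> int:
        """Number of components present (0..5)."""
        return sum(
            (self.obesity, self.hypertension, self.low_hdl, self.high_tg, self.impaired_glucose)
        )

    @property
    def k_other(self) -> int:
        """Number of non-blood-pressure components present (0..4)."""
        return self.n_components - int(self.hypertension)


@dataclass(frozen=True)
class RiskCategory:
    """Risk group of a hypertensive subject.

    ``k_other`` is the count of non-BP components present; ``mets`` is true
    iff ``k_other >= 2`` (i.e. three of five components overall).  Together
    with the binary MetS split these are the model's seven risk categories.
    """

    k_other: int
    mets: bool

    def __post_init__(self) -> None:
        if not 0 <= self.k_other <= 4:
            raise ValueError(f"k_other must be in 0..4, got {self.k_other}")
        if self.mets != (self.k_other >= 2):
            raise ValueError("mets must equal (k_other >= 2)")


def classify_components(
    measurements: Mapping[str, object],
    sex: str,
    thresholds: Atp3Thresholds = MODIFIED_ATP3,
) -> ComponentFlags:
    """Classify one subject's raw clinical values against the ATP III cut-offs.

    Parameters
    ----------
    measurements
        Mapping with keys ``waist_cm``, ``sbp_mmhg``, ``dbp_mmhg``,
        ``hdl_mgdl``, ``tg_mgdl``, ``fpg_mgdl`` (non-negative numbers) and
        ``known_diabetes`` (bool).  An optional truthy
        ``treated_hypertension`` marks a subject on antihypertensive
        medication, who counts as hypertensive regardless of measured BP.
    sex
        ``"male"`` or ``"female"`` — selects the waist and HDL cut-offs.
    thresholds
        Cut-off profile; defaults to the modified (140/90) ATP III profile.

    Raises
    ------
    ClassificationError
        If a required measurement is missing or negative, naming the field.
    ValueError
        For an unknown sex code.
    """
    if sex not in ("male", "female"):
        raise ValueError(f"unknown sex code {sex!r}; expected 'male' or 'female'")
    vals = {}
    for field in MEASUREMENT_FIELDS:
        if field not in measurements or measurements[field] is None:
            raise ClassificationError(f"missing measurement {field!r}")
        v = float(measurements[field])  # type: ignore[arg-type]
        if v < 0:
            raise ClassificationError(f"measurement {field!r} must be non-negative, got {v}")
        vals[field] = v
    if "known_diabetes" not in measurements:
        raise ClassificationError("missing measurement 'known_diabetes'")
    known_diabetes = bool(measurements["known_diabetes"])
    treated = bool(measurements.get("treated_hypertension", False))

    waist_cut = thresholds.waist_cm_male if sex == "male" else thresholds.waist_cm_female
    hdl_cut = thresholds.hdl_mgdl_male if sex == "male" else thresholds.hdl_mgdl_female

    return ComponentFlags(
        obesity=vals["waist_cm"] > waist_cut,
        hypertension=(
            vals["sbp_mmhg"] >= thresholds.sbp_mmhg
            or vals["dbp_mmhg"] >= thresholds.dbp_mmhg
            or treated
        ),
        low_hdl=vals["hdl_mgdl"] < hdl_cut,
        high_tg=vals["tg_mgdl"] >= thresholds.tg_mgdl,
        impaired_glucose=vals["fpg_mgdl"] >= thresholds.fpg_mgdl or known_diabetes,
    )


def assign_risk_category(flags: ComponentFlags) -> RiskCategory:
    """Assign a hypertensive subject to one of the model's risk categories.

    Refuses non-hypertensive subjects: the model covers the hypertensive
    population only, and silent dropping would hide upstream filtering bugs.
    """
    if not flags.hypertension:
        raise OutOfModelError(
            "subject is not hypertensive; the model covers the hypertensive population only"
        )
    k = flags.k_other
    return RiskCategory(k_other=k, mets=k >= 2)
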