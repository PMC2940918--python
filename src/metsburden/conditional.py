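"""Conditional structure of the non-BP MetS components among hypertensives.

The model needs, per age/sex stratum, the joint distribution of the four
non-blood-pressure components (abdominal obesity, low HDL, high
triglycerides, impaired fasting glucose) conditional on hypertension: a
probability vector over the 16 component subsets.  That structure is
estimated once from survey microdata and then transferred to each country by
re-fitting it to the country's component marginal prevalences with iterative
proportional fitting (IPF), which moves the four single-component margins to
their targets while preserving the survey's interaction (odds-ratio)
structure.  Finally the country's hypertensive head-counts are decomposed
into the five risk groups k = 0..4 additional components (MetS <=> k >= 2).

Subset labels are 4-bit strings in the canonical component order
obesity -> low_hdl -> high_tg -> impaired_glucose, obesity being the most
significant bit (``"0000"`` = hypertension only, ``"1111"`` = all four).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .atp3 import NON_BP_COMPONENTS
from .microdata import _pattern_codes

__all__ = [
    "SUBSET_LABELS",
    "SUBSET_SIZE",
    "ConditionalMatrix",
    "ConvergenceError",
    "estimate_conditional_matrix",
    "calibrate_to_marginals",
    "decompose_population",
    "mets_split",
]

logger = logging.getLogger(__name__)

SUBSET_LABELS = tuple(format(i, "04b") for i in range(16))
#: Number of components present in each subset, aligned with SUBSET_LABELS.
SUBSET_SIZE = np.array([label.count("1") for label in SUBSET_LABELS])
#: membership[j, i] is 1 when component j is present in subset i.
_MEMBERSHIP = np.array(
    [[int(label[j]) for label in SUBSET_LABELS] for j in range(4)], dtype=float
)

RISK_GROUPS = ("k0", "k1", "k2", "k3", "k4")


class ConvergenceError(RuntimeError):
    """IPF failed to reach the marginal targets within max_iter sweeps."""


@dataclass
class ConditionalMatrix:
    """Per-stratum probability vectors over the 16 non-BP component subsets.

    ``table`` is indexed by (age_band, sex) with the 16 subset columns in
    :data:`SUBSET_LABELS` order; every row is a probability vector.
    """

    table: pd.DataFrame
    #: per-stratum IPF iteration counts from the last calibration, if any
    ipf_iterations: dict[tuple[str, str], int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if list(self.table.columns) != list(SUBSET_LABELS):
            raise ValueError("ConditionalMatrix needs exactly the 16 canonical subset columns")
        v = self.table.to_numpy(dtype=float)
        if (v < 0).any():
            raise ValueError("subset probabilities must be non-negative")
        bad = np.abs(v.sum(axis=1) - 1.0) > 1e-12
        if bad.any():
            raise ValueError(
                f"stratum rows must sum to 1 within 1e-12; offending strata: "
                f"{list(self.table.index[bad])}"
            )

    @property
    def strata(self) -> list[tuple[str, str]]:
        return list(self.table.index)

    def marginals(self) -> pd.DataFrame:
        """Implied P(component | hypertension) per stratum and component."""
        probs = self.table.to_numpy(dtype=float)
        return pd.DataFrame(
            probs @ _MEMBERSHIP.T, index=self.table.index, columns=NON_BP_COMPONENTS
        )

    def group_shares(self) -> pd.DataFrame:
        """Probability of k = 0..4 additional components per stratum."""
        probs = self.table.to_numpy(dtype=float)
        out = np.zeros((len(self.table), 5))
        for k in range(5):
            out[:, k] = probs[:, SUBSET_SIZE == k].sum(axis=1)
        return pd.DataFrame(out, index=self.table.index, columns=RISK_GROUPS)

    # -- serialisation ----------------------------------------------------
    def to_csv(self, path) -> None:
        out = self.table.copy()
        out.insert(0, "sex", [s for _, s in out.index])
        out.insert(0, "age_band", [b for b, _ in out.index])
        out.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ConditionalMatrix":
        df = pd.read_csv(path, dtype={"age_band": str, "sex": str})
        df = df.set_index(["age_band", "sex"])
        df.columns = [str(c).zfill(4) for c in df.columns]
        df.index = pd.MultiIndex.from_tuples([tuple(t) for t in df.index])
        return cls(df[list(SUBSET_LABELS)].astype(float))


def estimate_conditional_matrix(records: pd.DataFrame) -> ConditionalMatrix:
    """Weighted subset frequencies among hypertensive records, per stratum.

    Every (age_band, sex) stratum present in ``records`` must contain at
    least one hypertensive subject; offending strata are all listed in the
    error rather than silently pooled.
    """
    strata = sorted(set(zip(records["age_band"], records["sex"])))
    empty = [
        s
        for s in strata
        if records[
            (records["age_band"] == s[0])
            & (records["sex"] == s[1])
            & (records["hypertension"] == 1)
        ].empty
    ]
    if empty:
        raise ValueError(f"strata with no hypertensive records: {empty}")
    rows = {}
    htn = records[records["hypertension"] == 1]
    for (band, sex), sub in htn.groupby(["age_band", "sex"], sort=True):
        codes = _pattern_codes(sub, NON_BP_COMPONENTS)
        mass = np.bincount(codes, weights=sub["weight"].to_numpy(dtype=float), minlength=16)
        rows[(band, sex)] = mass / mass.sum()
    table = pd.DataFrame.from_dict(rows, orient="index", columns=list(SUBSET_LABELS))
    table.index = pd.MultiIndex.from_tuples(table.index)
    return ConditionalMatrix(table)


def _ipf_stratum(
    p: np.ndarray, targets: np.ndarray, tol: float, max_iter: int
) -> tuple[np.ndarray, int, list[float]]:
    """One stratum's IPF on the 16-cell vector.

    Returns (fitted vector, sweeps used, per-sweep max marginal discrepancy).
    """
    p = p.copy()
    history: list[float] = []
    for it in range(1, max_iter + 1):
        for j in range(4):
            sel = _MEMBERSHIP[j].astype(bool)
            m = p[sel].sum()
            t = targets[j]
            p[sel] *= t / m
            p[~sel] *= (1.0 - t) / (1.0 - m)
        p /= p.sum()
        marg = _MEMBERSHIP @ p
        err = float(np.abs(marg - targets).max())
        history.append(err)
        if err < tol:
            return p, it, history
    raise ConvergenceError(
        f"IPF did not converge after {max_iter} sweeps; "
        f"worst marginal discrepancy {history[-1]:.3e}"
    )


def calibrate_to_marginals(
    reference: ConditionalMatrix,
    targets: pd.DataFrame,
    tol: float = 1e-8,
    max_iter: int = 10_000,
    zero_cell_eps: float = 1e-9,
) -> ConditionalMatrix:
    """Re-fit the reference structure to new single-component marginals.

    ``targets`` is indexed by (age_band, sex) with one column per non-BP
    component, each value strictly inside (0, 1) (values are epsilon-clipped
    to [1e-9, 1 - 1e-9]).  Cells with zero reference mass are lifted to
    ``zero_cell_eps`` before fitting so every marginal target is reachable.
    The returned matrix matches each target within ``tol`` while keeping the
    reference's odds-ratio structure (the IPF fixed point minimises
    Kullback-Leibler divergence to the reference subject to the margins).
    """
    missing = [s for s in reference.strata if s not in targets.index]
    if missing:
        raise ValueError(f"targets missing for strata: {missing}")
    eps = 1e-9
    rows = {}
    iters = {}
    for stratum in reference.strata:
        p = reference.table.loc[stratum].to_numpy(dtype=float)
        p = np.maximum(p, zero_cell_eps)
        p /= p.sum()
        t = targets.loc[stratum, list(NON_BP_COMPONENTS)].to_numpy(dtype=float)
        t = np.clip(t, eps, 1.0 - eps)
        fitted, n_iter, history = _ipf_stratum(p, t, tol, max_iter)
        logger.info(
            "IPF stratum %s: %d sweeps, final marginal discrepancy %.3e",
            stratum, n_iter, history[-1],
        )
        rows[stratum] = fitted
        iters[stratum] = n_iter
    table = pd.DataFrame.from_dict(rows, orient="index", columns=list(SUBSET_LABELS))
    table.index = pd.MultiIndex.from_tuples(table.index)
    return ConditionalMatrix(table, ipf_iterations=iters)


def decompose_population(htn_counts: pd.Series, matrix: ConditionalMatrix) -> pd.DataFrame:
    """Split per-stratum hypertensive head-counts into risk groups k = 0..4.

    Returns a DataFrame indexed like ``htn_counts`` with columns
    ``k0..k4``; each row sums to the stratum's hypertensive count exactly
    (persons are conserved).  MetS counts are the k >= 2 columns.
    """
    if (np.asarray(htn_counts, dtype=float) < 0).any():
        raise ValueError("hypertensive counts must be non-negative")
    missing = [s for s in htn_counts.index if s not in matrix.table.index]
    if missing:
        raise ValueError(f"strata missing from conditional matrix: {missing}")
    shares = matrix.group_shares().loc[htn_counts.index]
    out = shares.mul(np.asarray(htn_counts, dtype=float), axis=0)
    out.index = htn_counts.index
    return out


def mets_split(groups: pd.DataFrame | pd.Series) -> tuple[float, float]:
    """(MetS, non-MetS) person totals from a k0..k4 risk-group table."""
    if isinstance(groups, pd.DataFrame):
        totals = groups.sum(axis=0)
    else:
        totals = groups
    mets = float(totals[["k2", "k3", "k4"]].sum())
    non = float(totals[["k0", "k1"]].sum())
    return mets, non
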