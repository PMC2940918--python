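"""Synthetic survey-style microdata with controllable clustering.

The conditional-structure stage of the model was originally estimated from a
public-use health examination survey (age, sex, survey weight and the five
ATP III component indicators per respondent).  This module generates
microdata with the same shape from a fully specified stochastic model, so the
estimation stage can be exercised and validated without any external data.

Dependence between the five binary components is induced by a Gaussian
copula: a latent multivariate normal vector with unit variances and a
user-supplied correlation matrix is thresholded at the Gaussian quantiles of
the per-stratum marginal prevalences.  One matrix therefore spans
independence (identity) through strong risk-factor clustering, which is the
salient feature of real metabolic-syndrome data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .atp3 import COMPONENTS

__all__ = [
    "AGE_BANDS",
    "SEXES",
    "GeneratorSpec",
    "default_generator_spec",
    "generate_microdata",
    "empirical_joint",
]

AGE_BANDS = ("20-29", "30-39", "40-49", "50-59", "60-69", "70-79", "80+")
SEXES = ("male", "female")

#: Default seed for reproducible runs; any CLI run logs the seed it used.
DEFAULT_SEED = 20080101

# Age sampled uniformly within a band; the open-ended band is capped at 89.
_BAND_RANGES = {b: (int(b[:2]), int(b[3:5])) for b in AGE_BANDS[:-1]} | {"80+": (80, 89)}


@dataclass
class GeneratorSpec:
    """Full specification of the synthetic microdata model.

    Parameters
    ----------
    n_subjects
        Total number of records to draw.
    seed
        Seed for the pseudo-random stream; a fixed seed gives a bit-identical
        record stream.
    strata
        ``(age_band, sex, population_share)`` triples; shares must sum to 1.
    marginals
        Per-stratum mapping ``component -> prevalence`` for the five
        components, each strictly inside (0, 1).
    association
        5x5 latent correlation matrix (unit diagonal, positive semi-definite)
        over the components in :data:`metsburden.atp3.COMPONENTS` order.
    weight_model
        ``"equal"`` for unit survey weights, or ``("lognormal", sigma)`` for
        log-normal weights normalised to mean 1.
    """

    n_subjects: int
    seed: int = DEFAULT_SEED
    strata: Sequence[tuple[str, str, float]] = ()
    marginals: Mapping[tuple[str, str], Mapping[str, float]] = field(default_factory=dict)
    association: np.ndarray = field(default_factory=lambda: np.eye(5))
    weight_model: Literal["equal"] | tuple[str, float] = "equal"

    def validate(self) -> None:
        if self.n_subjects <= 0:
            raise ValueError("n_subjects must be positive")
        if not self.strata:
            raise ValueError("at least one stratum is required")
        shares = np.array([s[2] for s in self.strata], dtype=float)
        if np.any(shares < 0) or abs(shares.sum() - 1.0) > 1e-9:
            raise ValueError("stratum population shares must be non-negative and sum to 1")
        for band, sex, _ in self.strata:
            if band not in _BAND_RANGES:
                raise ValueError(f"unknown age band {band!r}")
            if sex not in SEXES:
                raise ValueError(f"unknown sex {sex!r}")
            m = self.marginals.get((band, sex))
            if m is None:
                raise ValueError(f"no marginals for stratum {(band, sex)}")
            for c in COMPONENTS:
                p = m.get(c)
                if p is None or not 0.0 < p < 1.0:
                    raise ValueError(
                        f"marginal for {c!r} in stratum {(band, sex)} must lie in (0,1), got {p!r}"
                    )
        a = np.asarray(self.association, dtype=float)
        if a.shape != (5, 5):
            raise ValueError("association must be a 5x5 matrix")
        if not np.allclose(a, a.T, atol=1e-12):
            raise ValueError("association matrix must be symmetric")
        if not np.allclose(np.diag(a), 1.0, atol=1e-12):
            raise ValueError("association matrix must have unit diagonal")
        # PSD check up to numerical jitter
        w = np.linalg.eigvalsh(a)
        if w.min() < -1e-10:
            raise ValueError(
                f"association matrix is not positive semi-definite (min eigenvalue {w.min():.3g})"
            )
        if self.weight_model != "equal":
            kind, sigma = self.weight_model
            if kind != "lognormal" or sigma < 0:
                raise ValueError(f"unknown weight model {self.weight_model!r}")


def default_generator_spec(n_subjects: int = 50_000, seed: int = DEFAULT_SEED) -> GeneratorSpec:
    """A survey-like default: age-graded prevalences and moderate clustering.

    Hypertension prevalence rises steeply with age; the metabolic components
    rise more gently.  Latent correlations of 0.25-0.40 among the metabolic
    components and 0.15-0.25 with hypertension emulate the well-documented
    clustering of cardiometabolic risk factors.
    """
    # prevalence by age-band index (0 = 20-29 ... 6 = 80+), per sex
    htn = {
        "male": (0.12, 0.20, 0.32, 0.47, 0.62, 0.72, 0.78),
        "female": (0.06, 0.12, 0.25, 0.42, 0.60, 0.72, 0.80),
    }
    obesity = {
        "male": (0.18, 0.28, 0.36, 0.42, 0.47, 0.48, 0.44),
        "female": (0.22, 0.30, 0.38, 0.45, 0.52, 0.55, 0.50),
    }
    low_hdl = {
        "male": (0.22, 0.26, 0.28, 0.30, 0.30, 0.28, 0.26),
        "female": (0.26, 0.28, 0.32, 0.34, 0.36, 0.34, 0.32),
    }
    high_tg = {
        "male": (0.22, 0.32, 0.38, 0.42, 0.42, 0.38, 0.32),
        "female": (0.14, 0.20, 0.28, 0.36, 0.40, 0.40, 0.36),
    }
    ifg = {
        "male": (0.06, 0.12, 0.20, 0.30, 0.38, 0.42, 0.42),
        "female": (0.04, 0.08, 0.15, 0.25, 0.34, 0.40, 0.42),
    }
    # adult age pyramid, equal sexes
    band_shares = (0.16, 0.17, 0.19, 0.17, 0.14, 0.11, 0.06)
    strata = [
        (band, sex, band_shares[i] / 2.0)
        for i, band in enumerate(AGE_BANDS)
        for sex in SEXES
    ]
    marginals = {
        (band, sex): {
            "obesity": obesity[sex][i],
            "hypertension": htn[sex][i],
            "low_hdl": low_hdl[sex][i],
            "high_tg": high_tg[sex][i],
            "impaired_glucose": ifg[sex][i],
        }
        for i, band in enumerate(AGE_BANDS)
        for sex in SEXES
    }
    # component order: obesity, hypertension, low_hdl, high_tg, impaired_glucose
    association = np.array(
        [
            [1.00, 0.25, 0.30, 0.35, 0.30],
            [0.25, 1.00, 0.10, 0.15, 0.20],
            [0.30, 0.10, 1.00, 0.40, 0.20],
            [0.35, 0.15, 0.40, 1.00, 0.25],
            [0.30, 0.20, 0.20, 0.25, 1.00],
        ]
    )
    return GeneratorSpec(
        n_subjects=n_subjects,
        seed=seed,
        strata=strata,
        marginals=marginals,
        association=association,
        weight_model=("lognormal", 0.5),
    )


def _allocate(n: int, shares: np.ndarray) -> np.ndarray:
    """Largest-remainder allocation of n subjects to strata (sums to n)."""
    raw = n * shares
    base = np.floor(raw).astype(int)
    rem = n - base.sum()
    order = np.argsort(-(raw - base))
    base[order[:rem]] += 1
    return base


def generate_microdata(spec: GeneratorSpec) -> pd.DataFrame:
    """Draw a weighted microdata table from the generator specification.

    Returns a DataFrame with columns ``subject_id, age_band, age, sex,
    weight`` and the five 0/1 component columns, one row per subject.
    Reproducible: a fixed spec (including seed) yields a bit-identical table.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    shares = np.array([s[2] for s in spec.strata], dtype=float)
    counts = _allocate(spec.n_subjects, shares)
    chol = np.linalg.cholesky(
        np.asarray(spec.association, dtype=float) + 1e-12 * np.eye(5)
    )

    frames = []
    next_id = 0
    for (band, sex, _), n_s in zip(spec.strata, counts):
        if n_s == 0:
            continue
        m = spec.marginals[(band, sex)]
        p = np.array([m[c] for c in COMPONENTS])
        z = rng.standard_normal((n_s, 5)) @ chol.T
        flags = (z > stats.norm.ppf(1.0 - p)).astype(np.int8)
        lo, hi = _BAND_RANGES[band]
        ages = rng.integers(lo, hi + 1, size=n_s)
        if spec.weight_model == "equal":
            w = np.ones(n_s)
        else:
            sigma = float(spec.weight_model[1])
            w = np.exp(sigma * rng.standard_normal(n_s) - 0.5 * sigma**2)
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": np.arange(next_id, next_id + n_s),
                    "age_band": band,
                    "age": ages,
                    "sex": sex,
                    "weight": w,
                }
                | {c: flags[:, j] for j, c in enumerate(COMPONENTS)}
            )
        )
        next_id += n_s
    return pd.concat(frames, ignore_index=True)


def _pattern_codes(records: pd.DataFrame, components: Sequence[str]) -> np.ndarray:
    code = np.zeros(len(records), dtype=int)
    for c in components:  # first component = most significant bit
        code = 2 * code + records[c].to_numpy().astype(int)
    return code


def empirical_joint(records: pd.DataFrame, stratum: tuple[str, str]) -> pd.Series:
    """Weighted joint distribution over the 32 component combinations.

    The cells are indexed by 5-bit strings in ``COMPONENTS`` order (obesity
    is the most significant bit) and sum to 1.  Survey weights are used, so
    the result is invariant to a global rescaling of the weights.

    Raises ``ValueError`` naming the stratum if it contains no records.
    """
    band, sex = stratum
    sub = records[(records["age_band"] == band) & (records["sex"] == sex)]
    if sub.empty:
        raise ValueError(f"no records in stratum {stratum!r}")
    codes = _pattern_codes(sub, COMPONENTS)
    w = sub["weight"].to_numpy(dtype=float)
    mass = np.bincount(codes, weights=w, minlength=32)
    labels = [format(i, "05b") for i in range(32)]
    return pd.Series(mass / mass.sum(), index=labels, name=f"{band}/{sex}")
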