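"""Conditional-structure estimation, IPF calibration and decomposition."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq

from metsburden.atp3 import NON_BP_COMPONENTS
from metsburden.conditional import (
    SUBSET_LABELS,
    SUBSET_SIZE,
    ConditionalMatrix,
    ConvergenceError,
    _ipf_stratum,
    calibrate_to_marginals,
    decompose_population,
    estimate_conditional_matrix,
    mets_split,
)
from metsburden.microdata import empirical_joint

STRATUM = ("50-59", "male")


def one_stratum_matrix(probs):
    table = pd.DataFrame(
        [np.asarray(probs, dtype=float)],
        index=pd.MultiIndex.from_tuples([STRATUM]),
        columns=list(SUBSET_LABELS),
    )
    return ConditionalMatrix(table)


def targets_frame(obesity, low_hdl, high_tg, impaired_glucose):
    return pd.DataFrame(
        {
            "obesity": [obesity],
            "low_hdl": [low_hdl],
            "high_tg": [high_tg],
            "impaired_glucose": [impaired_glucose],
        },
        index=pd.MultiIndex.from_tuples([STRATUM]),
    )


def product_probs(p):
    """Independent joint over the 16 subsets from four marginals."""
    out = np.empty(16)
    for i, label in enumerate(SUBSET_LABELS):
        out[i] = np.prod([p[j] if label[j] == "1" else 1 - p[j] for j in range(4)])
    return out


# ---------------------------------------------------------------------------
# estimation
# ---------------------------------------------------------------------------

class TestEstimate:
    def test_hand_fixture_matches_weighted_tally(self, hand_records):
        """Hypertensive weights: '0000' 3, '1010' 3, '1111' 2 of total 8."""
        m = estimate_conditional_matrix(hand_records)
        row = m.table.loc[STRATUM]
        assert row["0000"] == pytest.approx(3 / 8)
        assert row["1010"] == pytest.approx(3 / 8)
        assert row["1111"] == pytest.approx(2 / 8)
        assert row.sum() == pytest.approx(1.0, abs=1e-12)

    def test_degenerate_all_hypertension_only(self):
        df = pd.DataFrame(
            {
                "subject_id": range(3),
                "age_band": "40-49",
                "sex": "female",
                "weight": [1.0, 2.0, 0.5],
                "obesity": 0,
                "hypertension": 1,
                "low_hdl": 0,
                "high_tg": 0,
                "impaired_glucose": 0,
            }
        )
        m = estimate_conditional_matrix(df)
        assert m.table.loc[("40-49", "female"), "0000"] == 1.0

    def test_equals_renormalized_hypertensive_slice_of_joint(self, small_records):
        """The estimate is exactly empirical_joint restricted to
        hypertension-true cells and renormalised."""
        m = estimate_conditional_matrix(small_records)
        stratum = ("60-69", "female")
        joint = empirical_joint(small_records, stratum)
        htn_cells = joint[[lbl for lbl in joint.index if lbl[1] == "1"]]
        renorm = htn_cells / htn_cells.sum()
        for lbl5, p in renorm.items():
            lbl4 = lbl5[0] + lbl5[2:]  # drop the hypertension bit
            assert m.table.loc[stratum, lbl4] == pytest.approx(p, abs=1e-12)

    def test_error_lists_strata_without_hypertensives(self, hand_records):
        extra = hand_records.copy()
        extra["age_band"] = "20-29"
        extra["hypertension"] = 0
        with pytest.raises(ValueError, match=r"20-29.*male"):
            estimate_conditional_matrix(pd.concat([hand_records, extra]))


# ---------------------------------------------------------------------------
# IPF calibration
# ---------------------------------------------------------------------------

class TestCalibrate:
    def test_own_marginals_are_a_fixed_point(self, reference):
        fitted = calibrate_to_marginals(reference, reference.marginals())
        assert np.abs(fitted.table.to_numpy() - reference.table.to_numpy()).max() < 1e-8

    def test_independent_reference_yields_product_distribution(self):
        ref = one_stratum_matrix(product_probs([0.3, 0.4, 0.2, 0.5]))
        new = [0.6, 0.25, 0.45, 0.1]
        fitted = calibrate_to_marginals(ref, targets_frame(*new))
        assert np.abs(fitted.table.loc[STRATUM].to_numpy() - product_probs(new)).max() < 1e-8

    def test_two_by_two_odds_ratio_preserving_closed_form(self):
        """Calibrating a pair with odds ratio 4 to margins 0.5/0.5 must land
        on the closed-form 2x2 solution (cells 1/3, 1/6, 1/6, 1/3), since IPF
        preserves odds ratios."""
        theta, r0, c0, m = 4.0, 0.3, 0.4, 0.2
        a0 = brentq(
            lambda a: a * (1 - r0 - c0 + a) - theta * (r0 - a) * (c0 - a), 1e-9, min(r0, c0) - 1e-9
        )
        pair = {  # (obesity, low_hdl) joint with OR 4 and margins 0.3/0.4
            (1, 1): a0, (1, 0): r0 - a0, (0, 1): c0 - a0, (0, 0): 1 - r0 - c0 + a0,
        }
        probs = [
            pair[(int(lbl[0]), int(lbl[1]))]
            * (m if lbl[2] == "1" else 1 - m)
            * (m if lbl[3] == "1" else 1 - m)
            for lbl in SUBSET_LABELS
        ]
        fitted = calibrate_to_marginals(one_stratum_matrix(probs), targets_frame(0.5, 0.5, m, m))
        # closed-form 2x2 with margins 0.5/0.5 and OR 4
        a = brentq(lambda a: a * a - theta * (0.5 - a) ** 2, 1e-9, 0.5 - 1e-9)
        assert a == pytest.approx(1.0 / 3.0, abs=1e-9)
        row = fitted.table.loc[STRATUM]
        implied = {
            (i, j): sum(
                row[lbl] for lbl in SUBSET_LABELS if (int(lbl[0]), int(lbl[1])) == (i, j)
            )
            for i in (0, 1)
            for j in (0, 1)
        }
        for cell, expected in [((1, 1), a), ((1, 0), 0.5 - a), ((0, 1), 0.5 - a),
                               ((0, 0), a)]:
            assert abs(implied[cell] - expected) < 1e-6

    def test_marginals_hit_within_tol(self, reference):
        t = targets_frame(0.62, 0.34, 0.45, 0.42)
        targets = pd.concat([t] * len(reference.strata))
        targets.index = pd.MultiIndex.from_tuples(reference.strata)
        fitted = calibrate_to_marginals(reference, targets, tol=1e-10)
        err = (fitted.marginals() - targets[list(NON_BP_COMPONENTS)]).abs().to_numpy().max()
        assert err < 1e-10

    def test_discrepancy_decreases_monotonically(self):
        rng = np.random.default_rng(3)
        p = rng.dirichlet(np.ones(16))
        _, _, history = _ipf_stratum(p, np.array([0.6, 0.2, 0.45, 0.35]), 1e-12, 10_000)
        assert all(b <= a + 1e-15 for a, b in zip(history, history[1:]))

    def test_non_convergence_reports_discrepancy(self):
        probs = np.zeros(16)
        probs[0] = 0.5
        probs[-1] = 0.5  # maximal dependence: slow IPF convergence
        ref = one_stratum_matrix(probs)
        with pytest.raises(ConvergenceError, match="discrepancy"):
            calibrate_to_marginals(ref, targets_frame(0.9, 0.2, 0.7, 0.4), tol=1e-12, max_iter=2)

    def test_zero_cells_lifted_so_targets_stay_reachable(self):
        probs = np.zeros(16)
        probs[0] = 0.5
        probs[-1] = 0.5  # only the empty and the full subset have mass
        fitted = calibrate_to_marginals(
            one_stratum_matrix(probs), targets_frame(0.3, 0.4, 0.5, 0.6)
        )
        marg = fitted.marginals().loc[STRATUM]
        assert np.abs(marg.to_numpy() - [0.3, 0.4, 0.5, 0.6]).max() < 1e-8

    def test_raising_a_target_raises_mets_share(self, reference):
        """With the positively dependent copula-generated reference, a higher
        obesity target strictly increases the k >= 2 population share."""
        base = reference.marginals()
        lifted = base.copy()
        lifted["obesity"] = np.minimum(base["obesity"] + 0.10, 0.95)
        share = lambda m: m.group_shares()[["k2", "k3", "k4"]].sum(axis=1)
        s0 = share(calibrate_to_marginals(reference, base))
        s1 = share(calibrate_to_marginals(reference, lifted))
        assert (s1 > s0).all()


# ---------------------------------------------------------------------------
# decomposition
# ---------------------------------------------------------------------------

class TestDecompose:
    def test_uniform_matrix_gives_binomial_subset_counts(self):
        m = one_stratum_matrix(np.full(16, 1 / 16))
        counts = pd.Series([1600.0], index=m.table.index)
        groups = decompose_population(counts, m)
        assert groups.loc[STRATUM].tolist() == pytest.approx([100, 400, 600, 400, 100])
        mets, non = mets_split(groups)
        assert (mets, non) == pytest.approx((1100.0, 500.0))

    def test_all_mass_on_empty_subset(self):
        probs = np.zeros(16)
        probs[0] = 1.0
        m = one_stratum_matrix(probs)
        groups = decompose_population(pd.Series([1000.0], index=m.table.index), m)
        assert groups.loc[STRATUM, "k0"] == 1000.0
        assert mets_split(groups)[0] == 0.0

    @settings(derandomize=True, max_examples=100)
    @given(
        st.lists(st.floats(0.01, 1.0), min_size=16, max_size=16),
        st.floats(0.0, 1e7),
    )
    def test_persons_are_conserved(self, raw, count):
        probs = np.array(raw) / np.sum(raw)
        m = one_stratum_matrix(probs)
        groups = decompose_population(pd.Series([count], index=m.table.index), m)
        assert groups.loc[STRATUM].sum() == pytest.approx(count, abs=1e-9 * max(count, 1.0))

    def test_missing_stratum_error(self):
        m = one_stratum_matrix(np.full(16, 1 / 16))
        counts = pd.Series([10.0], index=pd.MultiIndex.from_tuples([("20-29", "female")]))
        with pytest.raises(ValueError, match="missing"):
            decompose_population(counts, m)

    def test_negative_counts_rejected(self):
        m = one_stratum_matrix(np.full(16, 1 / 16))
        with pytest.raises(ValueError, match="non-negative"):
            decompose_population(pd.Series([-5.0], index=m.table.index), m)


def test_group_shares_align_with_subset_sizes():
    probs = np.zeros(16)
    probs[SUBSET_SIZE == 2] = 1 / 6  # six two-component subsets
    shares = one_stratum_matrix(probs).group_shares()
    assert shares.loc[STRATUM].tolist() == pytest.approx([0, 0, 1, 0, 0])
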