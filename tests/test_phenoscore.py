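"""D-score system: ROC/Youden correctness against brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from stresspheno.config import PAPER_CUTOFFS, SCORED_MARKERS
from stresspheno.phenoscore import (
    DScoreModel,
    MarkerDirection,
    PhysioRecord,
    assign_dscore,
    classify_mouse,
    cohort_retention,
    marker_predictiveness,
    roc_curve,
    youden_cutoff,
)
from stresspheno.synthetic import MarkerParams, PhysioGenSpec, gen_physio_cohort

HIGHER = MarkerDirection("m", "stress_higher")
LOWER = MarkerDirection("m", "stress_lower")


def rank_auc(control, stress, direction):
    """Mann-Whitney oracle: pairwise comparisons with ties counted 1/2."""
    u = 0.0
    for s in stress:
        for c in control:
            if s == c:
                u += 0.5
            elif (s > c) == (direction.direction == "stress_higher"):
                u += 1.0
    return u / (len(control) * len(stress))


def brute_force_youden(values, labels, direction):
    """Exhaustive scan of every candidate threshold, spec tie-breaks."""
    distinct = np.unique(values)
    pad = 0.5 * np.min(np.diff(distinct)) if distinct.size > 1 else 1.0
    candidates = np.concatenate(([distinct[0] - pad], 0.5 * (distinct[:-1] + distinct[1:]), [distinct[-1] + pad]))
    pos = np.asarray(labels) == "stress"
    best = None
    for t in candidates:
        if direction.direction == "stress_higher":
            hit = values > t
        else:
            hit = values < t
        tpr = hit[pos].mean()
        fpr = hit[~pos].mean()
        j = tpr - fpr
        # maximize J, then TPR, then minimize threshold
        key = (round(j, 12), round(tpr, 12), -t)
        if best is None or key > best[0]:
            best = (key, t)
    return best[1]


def random_instance(rng, max_n=25):
    n0 = rng.integers(2, max_n)
    n1 = rng.integers(2, max_n)
    # mix continuous values and heavy ties
    pool = rng.choice([0.0, 1.0], p=[0.6, 0.4])
    if pool:
        vals = rng.integers(0, 6, size=n0 + n1).astype(float)
    else:
        vals = rng.normal(0, 1, size=n0 + n1)
    labels = np.array(["control"] * n0 + ["stress"] * n1)
    return vals, labels


class TestRocCurve:
    def test_perfect_separation_gives_auc_one(self):
        vals = np.array([1.0, 2.0, 3.0, 10.0, 11.0, 12.0])
        labels = np.array(["control"] * 3 + ["stress"] * 3)
        roc = roc_curve(vals, labels, HIGHER)
        assert roc.auc == pytest.approx(1.0)
        assert roc.max_j == pytest.approx(1.0)
        # cutoff at the midpoint between the closest cross-group values
        assert roc.youden_cutoff == pytest.approx(6.5)

    def test_constant_marker_gives_chance_auc(self):
        vals = np.full(10, 3.0)
        labels = np.array(["control"] * 5 + ["stress"] * 5)
        roc = roc_curve(vals, labels, HIGHER)
        assert roc.auc == pytest.approx(0.5)

    def test_six_vs_six_matches_rank_oracle(self):
        control = np.array([1.0, 2.0, 2.0, 3.5, 4.0, 6.0])
        stress = np.array([2.0, 3.5, 5.0, 5.5, 6.0, 8.0])
        vals = np.concatenate([control, stress])
        labels = np.array(["control"] * 6 + ["stress"] * 6)
        roc = roc_curve(vals, labels, HIGHER)
        assert roc.auc == pytest.approx(rank_auc(control, stress, HIGHER))

    def test_auc_matches_rank_oracle_randomized(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            vals, labels = random_instance(rng)
            direction = HIGHER if rng.random() < 0.5 else LOWER
            roc = roc_curve(vals, labels, direction)
            oracle = rank_auc(vals[labels == "control"], vals[labels == "stress"], direction)
            assert roc.auc == pytest.approx(oracle, abs=1e-12)

    def test_curve_endpoints_and_monotonicity(self):
        rng = np.random.default_rng(0)
        vals, labels = random_instance(rng)
        roc = roc_curve(vals, labels, HIGHER)
        assert roc.fpr[0] == 0 and roc.tpr[0] == 0
        assert roc.fpr[-1] == 1 and roc.tpr[-1] == 1
        assert np.all(np.diff(roc.fpr) >= 0) and np.all(np.diff(roc.tpr) >= 0)

    def test_direction_antisymmetry(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            vals, labels = random_instance(rng)
            a = roc_curve(vals, labels, HIGHER).auc
            b = roc_curve(vals, labels, LOWER).auc
            assert a + b == pytest.approx(1.0)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError, match="each group"):
            roc_curve([1.0, 2.0], ["control", "control"], HIGHER)

    def test_missing_values_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            roc_curve([1.0, np.nan], ["control", "stress"], HIGHER)

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(st.data())
    def test_auc_rank_equivalence_property(self, data):
        """Trapezoid AUC equals the tie-corrected rank statistic (n <= 50)."""
        n0 = data.draw(st.integers(1, 25))
        n1 = data.draw(st.integers(1, 25))
        vals = np.array(
            data.draw(
                st.lists(
                    st.floats(-5, 5, allow_nan=False).map(lambda x: round(x, 1)),
                    min_size=n0 + n1,
                    max_size=n0 + n1,
                )
            )
        )
        labels = np.array(["control"] * n0 + ["stress"] * n1)
        roc = roc_curve(vals, labels, HIGHER)
        oracle = rank_auc(vals[:n0], vals[n0:], HIGHER)
        assert roc.auc == pytest.approx(oracle, abs=1e-9)


class TestYoudenCutoff:
    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(123)
        for _ in range(200):
            vals, labels = random_instance(rng)
            direction = HIGHER if rng.random() < 0.5 else LOWER
            roc = roc_curve(vals, labels, direction)
            assert youden_cutoff(roc) == pytest.approx(
                brute_force_youden(vals, labels, direction), abs=1e-12
            )

    def test_overlapping_ten_sample_example(self):
        vals = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 3.5, 4.5, 5.5, 6.5, 7.5])
        labels = np.array(["control"] * 5 + ["stress"] * 5)
        roc = roc_curve(vals, labels, HIGHER)
        assert youden_cutoff(roc) == pytest.approx(brute_force_youden(vals, labels, HIGHER))

    def test_monotone_recovery_with_widening_separation(self):
        rng = np.random.default_rng(9)
        control = rng.normal(0, 1, 60)
        stress_base = rng.normal(0, 1, 60)
        labels = np.array(["control"] * 60 + ["stress"] * 60)
        js = []
        for delta in [0.0, 0.5, 1.0, 2.0, 4.0, 8.0]:
            vals = np.concatenate([control, stress_base + delta])
            js.append(roc_curve(vals, labels, HIGHER).max_j)
        assert np.all(np.diff(js) >= -1e-12)
        assert js[-1] == pytest.approx(1.0)

    def test_cutoff_recovers_bayes_midpoint_on_equal_variance_cohort(self):
        """With equal group sds the Youden cutoff estimator centers on the
        mean midpoint (the analytic Bayes boundary). A single draw of the
        empirical argmax carries cube-root-rate noise, so the estimator mean
        over replicate cohorts at n = 1e4 per group is checked."""
        cutoffs = []
        for seed in range(10):
            spec = PhysioGenSpec(
                n_control=10_000,
                n_stress=10_000,
                bw_gain_g=MarkerParams(5.0, 1.0, 3.0, 1.0),
                seed=seed,
            )
            df = gen_physio_cohort(spec)
            roc = roc_curve(
                df["bw_gain_g"].to_numpy(),
                df["group"].to_numpy(),
                MarkerDirection("bw_gain_g", "stress_lower"),
            )
            cutoffs.append(roc.youden_cutoff)
        gap = 5.0 - 3.0
        assert abs(np.mean(cutoffs) - 4.0) < 0.02 * gap


class TestDScore:
    CUTS = dict(PAPER_CUTOFFS)

    def rec(self, bw, adr, thy):
        return PhysioRecord("m1", "stress", bw, adr, thy)

    def test_all_three_markers_altered_scores_three(self):
        # adrenal above cutoff, body-weight gain below, thymus below
        r = assign_dscore(self.rec(3.0, 1.4e-4, 1.2e-3), self.CUTS, SCORED_MARKERS)
        assert r.dscore == 3
        assert all(r.flags.values())
        assert r.classification == "stressed"

    def test_no_marker_altered_scores_zero(self):
        r = assign_dscore(self.rec(5.0, 1.0e-4, 2.0e-3), self.CUTS, SCORED_MARKERS)
        assert r.dscore == 0
        assert r.classification == "non-stressed"

    def test_value_exactly_at_cutoff_not_altered(self):
        r = assign_dscore(
            self.rec(self.CUTS["bw_gain_g"], 1.0e-4, 2.0e-3), self.CUTS, SCORED_MARKERS
        )
        assert not r.flags["bw_gain_g"]

    def test_missing_marker_error_names_marker(self):
        with pytest.raises(ValueError, match="thymus_norm"):
            assign_dscore(
                {"mouse_id": "x", "bw_gain_g": 3.0, "adrenal_norm": 1.4e-4},
                self.CUTS,
                SCORED_MARKERS,
            )

    @pytest.mark.parametrize(
        "score,expected",
        [(0, "non-stressed"), (1, "non-stressed"), (2, "stressed"), (3, "stressed")],
    )
    def test_classification_boundaries(self, score, expected):
        assert classify_mouse(score) == expected

    def test_out_of_range_score_rejected(self):
        with pytest.raises(ValueError):
            classify_mouse(4)


class TestCohortSummaries:
    def test_all_control_d0_gives_full_retention(self):
        scores = pd.DataFrame({"group": ["control"] * 4, "dscore": [0, 0, 0, 0]})
        ret = cohort_retention(scores)
        assert ret["retention_percent"]["control"] == pytest.approx(100.0)

    def test_toy_cohort_matches_hand_tally(self):
        scores = pd.DataFrame(
            {
                "group": ["control", "control", "stress", "stress"],
                "dscore": [0, 2, 1, 3],
            }
        )
        ret = cohort_retention(scores)
        assert ret["dscore_percent"]["control"] == {0: 50.0, 1: 0.0, 2: 50.0, 3: 0.0}
        assert ret["retention_percent"]["control"] == pytest.approx(50.0)
        assert ret["retention_percent"]["stress"] == pytest.approx(50.0)
        for pct in ret["dscore_percent"].values():
            assert sum(pct.values()) == pytest.approx(100.0)

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            cohort_retention(pd.DataFrame({"group": [], "dscore": []}))

    def test_classification_invariant_to_record_order(self, default_cohort):
        res = DScoreModel(default_cohort).fit()
        shuffled = default_cohort.sample(frac=1.0, random_state=3)
        res2 = DScoreModel(shuffled).fit()
        a = res.scores.set_index("mouse_id").sort_index()
        b = res2.scores.set_index("mouse_id").sort_index()
        pd.testing.assert_frame_equal(a, b)
        assert res.cutoffs == res2.cutoffs


class TestMarkerPredictiveness:
    def test_random_marker_flagged_uninformative(self):
        rng = np.random.default_rng(17)
        df = pd.DataFrame(
            {
                "group": ["control"] * 1000 + ["stress"] * 1000,
                "noise": rng.normal(0, 1, 2000),
            }
        )
        rep = marker_predictiveness(df, [MarkerDirection("noise", "stress_higher")])
        assert abs(rep.loc[0, "auc"] - 0.5) < 0.05
        assert bool(rep.loc[0, "uninformative"])

    def test_perfect_marker_not_flagged(self):
        df = pd.DataFrame(
            {"group": ["control"] * 3 + ["stress"] * 3, "m": [1.0, 2.0, 3.0, 7.0, 8.0, 9.0]}
        )
        rep = marker_predictiveness(df, [MarkerDirection("m", "stress_higher")])
        assert not bool(rep.loc[0, "uninformative"])

    def test_scored_marker_auc_consistent_with_roc(self, default_cohort):
        res = DScoreModel(default_cohort).fit()
        rep = res.predictiveness()
        for _, row in rep.iterrows():
            assert row["auc"] == pytest.approx(res.roc[row["marker"]].auc)

    def test_default_cort_is_uninformative(self, default_cohort):
        rep = marker_predictiveness(
            default_cohort, [MarkerDirection("cort", "stress_higher")], margin=0.1
        )
        assert bool(rep.loc[0, "uninformative"])


class TestDScoreModel:
    def test_frozen_cutoffs_used_verbatim(self, default_cohort):
        res = DScoreModel(default_cohort).fit(cutoffs=PAPER_CUTOFFS)
        assert res.cutoff_source == "frozen"
        assert res.cutoffs == PAPER_CUTOFFS
        assert res.roc == {}

    def test_frozen_cutoffs_must_be_complete(self, default_cohort):
        with pytest.raises(ValueError, match="missing markers"):
            DScoreModel(default_cohort).fit(cutoffs={"bw_gain_g": 3.5})

    def test_summary_mentions_retention(self, default_cohort):
        text = DScoreModel(default_cohort).fit().summary()
        assert "retention" in text and "cutoffs" in text
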