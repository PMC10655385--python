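"""Paired differential selection, Spearman projection, elbow k-means, survival."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from mbscreen._errors import InsufficientDesignError
from mbscreen.stratify import (
    ExpressionMatrix,
    correlate_to_references,
    elbow_kmeans,
    paired_differential,
    survival_compare,
)


def _expr(values, samples, models, genes=None):
    values = np.asarray(values, float)
    genes = genes or [f"G{i}" for i in range(values.shape[0])]
    return ExpressionMatrix(
        pd.DataFrame(values, index=genes, columns=samples),
        sample_info=pd.DataFrame({"model": models}, index=samples),
    )


class TestPairedDifferential:
    def test_identical_matrices_select_nothing(self, rng):
        x = rng.normal(8, 1, (40, 3))
        S = _expr(x, ["s1", "s2", "s3"], ["m1", "m2", "m3"])
        R = _expr(x, ["r1", "r2", "r3"], ["m1", "m2", "m3"])
        res = paired_differential(S, R)
        assert not res["selected"].any()
        assert (res["p_paired"] == 1.0).all()

    def test_planted_shift_is_selected(self, rng):
        base = rng.normal(8, 1, (200, 3))
        shifted = base.copy()
        shifted[:50] += 2.0  # first 50 features up in R
        noise = rng.normal(0, 0.1, (200, 3))
        S = _expr(base, ["s1", "s2", "s3"], ["m1", "m2", "m3"])
        R = _expr(shifted + noise, ["r1", "r2", "r3"], ["m1", "m2", "m3"])
        res = paired_differential(S, R)
        assert res["selected"].iloc[:50].all()
        assert res["selected"].iloc[50:].mean() < 0.10
        assert (res["z_of_median"].iloc[:50] > res["z_of_median"].iloc[50:].mean()).all()

    def test_features_missing_in_one_side_are_excluded(self, rng):
        S = _expr(rng.normal(8, 1, (30, 2)), ["s1", "s2"], ["m1", "m2"])
        R = _expr(
            rng.normal(8, 1, (20, 2)), ["r1", "r2"], ["m1", "m2"],
            genes=[f"G{i}" for i in range(10, 30)],
        )
        res = paired_differential(S, R)
        assert list(res.index) == [f"G{i}" for i in range(10, 30)]

    def test_single_pair_is_undefined(self, rng):
        S = _expr(rng.normal(8, 1, (10, 1)), ["s1"], ["m1"])
        R = _expr(rng.normal(8, 1, (10, 1)), ["r1"], ["m1"])
        with pytest.raises(InsufficientDesignError):
            paired_differential(S, R)


class TestSpearman:
    def test_identity_and_reversal(self, rng):
        x = rng.normal(0, 1, 30)
        cohort = pd.DataFrame(
            {"same": x, "reversed": -x}, index=[f"G{i}" for i in range(30)]
        )
        refs = pd.DataFrame({"ref": x}, index=cohort.index)
        corr = correlate_to_references(cohort, refs)
        assert corr.loc["same", "ref"] == pytest.approx(1.0)
        assert corr.loc["reversed", "ref"] == pytest.approx(-1.0)

    def test_closed_form_rank_formula_on_tie_free_vectors(self, rng):
        x = rng.permutation(10).astype(float)
        y = rng.permutation(10).astype(float)
        cohort = pd.DataFrame({"p": x}, index=[f"G{i}" for i in range(10)])
        refs = pd.DataFrame({"r": y}, index=cohort.index)
        d = stats.rankdata(x) - stats.rankdata(y)
        expected = 1 - 6 * np.sum(d**2) / (10 * (10**2 - 1))
        assert correlate_to_references(cohort, refs).iloc[0, 0] == pytest.approx(expected)

    def test_matches_scipy_with_ties(self, rng):
        x = rng.integers(0, 5, (50, 4)).astype(float)  # heavy ties
        y = rng.integers(0, 5, (50, 3)).astype(float)
        cohort = pd.DataFrame(x, index=[f"G{i}" for i in range(50)])
        refs = pd.DataFrame(y, index=cohort.index, columns=["a", "b", "c"])
        corr = correlate_to_references(cohort, refs)
        for i in range(4):
            for j, c in enumerate(["a", "b", "c"]):
                assert corr.iloc[i][c] == pytest.approx(
                    stats.spearmanr(x[:, i], y[:, j]).statistic
                )

    def test_monotone_transform_invariance(self, rng):
        x = rng.normal(0, 1, (40, 2))
        refs = pd.DataFrame(rng.normal(0, 1, (40, 2)), index=[f"G{i}" for i in range(40)])
        cohort = pd.DataFrame(x, index=refs.index)
        warped = pd.DataFrame(np.exp(3 * x), index=refs.index)
        pd.testing.assert_frame_equal(
            correlate_to_references(cohort, refs),
            correlate_to_references(warped, refs),
        )

    def test_insufficient_overlap(self, rng):
        cohort = pd.DataFrame(rng.normal(size=(2, 2)), index=["G1", "G2"])
        refs = pd.DataFrame(rng.normal(size=(2, 2)), index=["G1", "G2"])
        with pytest.raises(InsufficientDesignError):
            correlate_to_references(cohort, refs)


class TestElbowKmeans:
    def test_three_separated_blobs(self, rng):
        centers = np.eye(3)  # mutually 1.41 apart in 3-d
        labels_true = rng.integers(0, 3, 300)
        X = centers[labels_true] + rng.normal(0, 0.05, (300, 3))
        res = elbow_kmeans(X, seed=0)
        assert res.k == 3
        assert adjusted_rand_score(labels_true, res.labels) >= 0.95

    def test_single_blob_gives_one_cluster(self, rng):
        X = rng.normal(0, 1, (200, 6))
        assert elbow_kmeans(X, seed=0).k == 1

    def test_identical_rows_warn_and_give_one_cluster(self):
        X = np.ones((50, 4))
        with pytest.warns(UserWarning, match="identical"):
            res = elbow_kmeans(X, seed=0)
        assert res.k == 1

    def test_wss_curve_monotone_nonincreasing(self, rng):
        X = rng.normal(0, 1, (100, 4))
        res = elbow_kmeans(X, seed=1)
        assert (np.diff(res.wss_curve.to_numpy()) <= 1e-9).all()


def _numpy_logrank_chi2(time, event, group):
    """Independent multivariate log-rank statistic (numpy, for permutations)."""
    groups = np.unique(group)
    times = np.unique(time[event == 1])
    O = np.zeros(len(groups))
    E = np.zeros(len(groups))
    V = np.zeros(len(groups))
    for t in times:
        at_risk = time >= t
        d = float(((time == t) & (event == 1)).sum())
        n = float(at_risk.sum())
        for gi, g in enumerate(groups):
            n_g = float((at_risk & (group == g)).sum())
            d_g = float(((time == t) & (event == 1) & (group == g)).sum())
            O[gi] += d_g
            E[gi] += d * n_g / n
            if n > 1:
                V[gi] += d * (n_g / n) * (1 - n_g / n) * (n - d) / (n - 1)
    # chi-square over k-1 groups using the diagonal approximation is not
    # exact for k > 2; keep the oracle two-group where it is exact
    return (O[0] - E[0]) ** 2 / V[0]


class TestSurvival:
    def test_no_events_gives_flat_curves_and_na(self):
        surv = pd.DataFrame(
            {"time": [1.0, 2.0, 3.0, 4.0], "event": 0, "cluster": [0, 0, 1, 1]}
        )
        res = survival_compare(surv)
        assert np.isnan(res.p_value)
        for curve in res.km_curves.values():
            assert (curve["S"] == 1.0).all()

    def test_single_event_step_closed_form(self):
        n = 5
        surv = pd.DataFrame(
            {
                "time": [2.0] + [10.0] * (n - 1) + [5.0] * n,
                "event": [1] + [0] * (n - 1) + [0] * n,
                "cluster": [0] * n + [1] * n,
            }
        )
        res = survival_compare(surv)
        s = res.km_curves[0]["S"]
        assert s.loc[2.0] == pytest.approx((n - 1) / n)

    def test_km_equals_empirical_survival_without_censoring(self, rng):
        t = rng.exponential(5.0, 60)
        surv = pd.DataFrame({"time": np.r_[t, t * 0.5], "event": 1,
                             "cluster": [0] * 60 + [1] * 60})
        res = survival_compare(surv)
        curve = res.km_curves[0]
        for tt in np.quantile(t, [0.25, 0.5, 0.75]):
            idx = curve.index[curve.index <= tt]
            emp = (t > tt).mean()
            assert curve.loc[idx[-1], "S"] == pytest.approx(emp, abs=1e-9)

    def test_logrank_agrees_with_permutation_oracle(self, rng):
        n = 60
        time = np.r_[rng.exponential(1 / 0.1, n), rng.exponential(1 / 0.25, n)]
        cens = rng.exponential(15.0, 2 * n)
        event = (time <= cens).astype(int)
        tobs = np.minimum(time, cens)
        group = np.r_[np.zeros(n, int), np.ones(n, int)]
        surv = pd.DataFrame({"time": tobs, "event": event, "cluster": group})
        res = survival_compare(surv)
        # the numpy statistic replicates lifelines' on the observed data
        chi2 = _numpy_logrank_chi2(tobs, event, group)
        assert chi2 == pytest.approx(res.statistic, rel=1e-6)
        perm = np.array(
            [
                _numpy_logrank_chi2(tobs, event, rng.permutation(group))
                for _ in range(2000)
            ]
        )
        p_perm = (np.sum(perm >= chi2) + 1) / (len(perm) + 1)
        se = np.sqrt(p_perm * (1 - p_perm) / len(perm))
        assert abs(res.p_value - p_perm) < max(4 * se, 0.02)
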