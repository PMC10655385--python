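"""4PL fitting, GI50 censoring, selectivity ratios and VECC units."""

import itertools
import math

import numpy as np
import pytest

from mbscreen._errors import InsufficientDesignError, PairingError, ParameterError
from mbscreen.doseresponse import (
    FIVEFOLD6,
    CensoredRatio,
    DoseResponseFit,
    VeccUnit,
    classify_selectivity,
    fit_4pl,
    four_pl,
    resistance_ratio,
    summarize_selectivity,
    vecc_cocktail,
)

DOSES = np.array(FIVEFOLD6)


def _fit(params, doses=DOSES):
    return fit_4pl(doses, four_pl(doses, *params))


class TestFit4PL:
    def test_noise_free_recovery(self):
        fit = _fit((0.0, 100.0, 1.0, 1.0))
        assert fit.gi50 == pytest.approx(1.0, rel=1e-3)
        assert fit.midpoint == pytest.approx(1.0, rel=1e-3)
        assert not fit.censored

    def test_grid_oracle_agreement_on_noise_free_data(self):
        """A coarse brute-force grid search lands on the same optimum."""
        params = (10.0, 100.0, 0.3, 1.8)
        v = four_pl(DOSES, *params)
        grid = itertools.product(
            np.linspace(0, 30, 16),
            np.linspace(90, 110, 11),
            np.logspace(-2, 0.5, 40),
            np.linspace(0.5, 3.0, 26),
        )
        best = min(grid, key=lambda p: np.sum((four_pl(DOSES, *p) - v) ** 2))
        fit = _fit(params)
        assert fit.midpoint == pytest.approx(best[2], rel=0.15)  # coarse grid
        assert fit.midpoint == pytest.approx(params[2], rel=1e-3)
        assert fit.hill == pytest.approx(params[3], rel=1e-3)
        assert fit.bottom == pytest.approx(params[0], abs=0.1)
        assert fit.top == pytest.approx(params[1], abs=0.1)

    def test_plateau_data_censored(self):
        # viability never drops below 60%: no 50% crossing in range
        fit = _fit((60.0, 100.0, 0.5, 1.0))
        assert fit.censored
        assert fit.gi50 == DOSES.max()
        assert "greater" not in fit.gi50_label and fit.gi50_label.startswith(">")

    def test_censoring_matches_fitted_minimum_rule(self):
        for params in [(0.0, 100.0, 0.2, 1.5), (45.0, 100.0, 0.5, 2.0), (55.0, 100.0, 0.1, 1.0)]:
            fit = _fit(params)
            v_min = float(fit.predict(np.array([fit.top_dose]))[0])
            assert fit.censored == (v_min > 50.0)

    def test_dose_unit_equivariance(self):
        params = (5.0, 100.0, 0.4, 1.6)
        f1 = _fit(params)
        c = 1000.0  # e.g. nM instead of µM
        f2 = fit_4pl(DOSES * c, four_pl(DOSES, *params))
        assert f2.midpoint == pytest.approx(c * f1.midpoint, rel=1e-3)
        assert f2.gi50 == pytest.approx(c * f1.gi50, rel=1e-3)
        assert f2.hill == pytest.approx(f1.hill, rel=1e-3)
        assert f2.top == pytest.approx(f1.top, rel=1e-3)
        assert f2.bottom == pytest.approx(f1.bottom, abs=1e-2)

    def test_gi50_midpoint_relation(self):
        # bottom = 0, top = 100: the 50% crossing IS the midpoint
        f = _fit((0.0, 100.0, 0.5, 2.0))
        assert f.gi50 == pytest.approx(f.midpoint, rel=1e-6)
        # bottom > 0 pulls the absolute crossing right of the midpoint
        f2 = _fit((30.0, 100.0, 0.5, 2.0))
        assert f2.gi50 > f2.midpoint

    def test_insufficient_distinct_doses(self):
        with pytest.raises(InsufficientDesignError):
            fit_4pl([1.0, 1.0, 2.0, 3.0], [90, 88, 60, 30])

    def test_nonpositive_dose_rejected(self):
        with pytest.raises(ParameterError):
            fit_4pl([0.0, 1.0, 2.0, 4.0], [100, 80, 50, 20])


def _mkfit(gi50, censored=False, top_dose=5.0):
    return DoseResponseFit(
        bottom=0.0, top=100.0, hill=1.0, midpoint=gi50, gi50=gi50,
        censored=censored, rss=0.0, n_points=6, top_dose=top_dose,
    )


class TestRatiosAndSelectivity:
    def test_resistance_ratio_basic(self):
        assert resistance_ratio(_mkfit(4.0), _mkfit(1.0)) == pytest.approx(4.0)
        assert resistance_ratio(_mkfit(2.0), _mkfit(2.0)) == pytest.approx(1.0)

    def test_censored_ratio_is_a_bound(self):
        r = resistance_ratio(_mkfit(5.0, censored=True, top_dose=5.0), _mkfit(1.0))
        assert isinstance(r, CensoredRatio)
        assert r.direction == ">" and r.bound == pytest.approx(5.0)
        assert str(r) == "> 5"

    def test_classify_clear_cases(self):
        recs = classify_selectivity(
            [
                ("potent_on_R", _mkfit(10.0), _mkfit(1.0)),
                ("equal", _mkfit(1.0), _mkfit(1.0)),
                ("potent_on_S", _mkfit(0.3), _mkfit(3.0)),
            ]
        )
        by = {r.compound_id: r for r in recs}
        assert by["potent_on_R"].selective_R and not by["potent_on_R"].selective_S
        assert not by["equal"].selective_R and not by["equal"].selective_S
        assert by["potent_on_S"].selective_S

    def test_censored_sensitive_arm_gives_bounded_call(self):
        # inactive on S up to 5 µM but GI50 1 µM on R: fold bound 5 > 2
        recs = classify_selectivity(
            [("c", _mkfit(5.0, censored=True, top_dose=5.0), _mkfit(1.0))]
        )
        assert recs[0].selective_R

    def test_doubly_censored_is_inactive(self):
        recs = classify_selectivity(
            [("dead", _mkfit(5.0, censored=True), _mkfit(5.0, censored=True))]
        )
        assert recs[0].inactive
        assert not recs[0].selective_R and not recs[0].selective_S

    def test_calls_mutually_exclusive_across_models(self):
        recs = classify_selectivity(
            [
                ("c", _mkfit(10.0), _mkfit(1.0)),  # 10x for R on model 1
                ("c", _mkfit(1.0), _mkfit(3.0)),  # 3x for S on model 2
            ]
        )
        assert recs[0].selective_R and not recs[0].selective_S

    def test_unmatched_pair_raises(self):
        with pytest.raises(PairingError):
            classify_selectivity([("c", None, _mkfit(1.0))])


class TestSummary:
    def test_screen_summary_percentages(self):
        recs = (
            [_rec(f"r{i}", sel_R=True) for i in range(56)]
            + [_rec(f"s{i}", sel_S=True) for i in range(23)]
            + [_rec(f"n{i}") for i in range(303 - 56 - 23)]
        )
        summary = summarize_selectivity(recs)
        assert summary["pct_selective_R"] == 18.48
        assert summary["pct_selective_S"] == 7.59

    def test_antimetabolite_fraction(self):
        recs = [_rec(f"r{i}", sel_R=True) for i in range(16)] + [
            _rec(f"n{i}") for i in range(41 - 16)
        ]
        assert summarize_selectivity(recs)["pct_selective_R"] == 39.02

    def test_empty_class_and_consistency(self):
        assert summarize_selectivity([_rec("a")], n_total=100)["pct_selective_R"] == 0.0
        with pytest.raises(ParameterError):
            summarize_selectivity([_rec("a", sel_R=True)] * 3, n_total=2)


def _rec(cid, sel_R=False, sel_S=False):
    from mbscreen.doseresponse import SelectivityRecord

    return SelectivityRecord(cid, 3.0 if sel_R else 1.0, 3.0 if sel_S else 1.0,
                             sel_R, sel_S, False)


class TestVecc:
    UNIT = VeccUnit(0.004, 0.8, 1.5, 90.0)

    def test_one_unit_is_each_drug_at_its_gi50(self):
        assert vecc_cocktail(self.UNIT, 1.0) == self.UNIT.as_dict()

    def test_zero_units_is_vehicle(self):
        assert all(v == 0.0 for v in vecc_cocktail(self.UNIT, 0.0).values())

    def test_linearity(self):
        lo, hi = vecc_cocktail(self.UNIT, 0.1), vecc_cocktail(self.UNIT, 0.2)
        for drug in lo:
            assert hi[drug] == pytest.approx(2.0 * lo[drug])

    def test_negative_multiplier_rejected(self):
        with pytest.raises(ParameterError):
            vecc_cocktail(self.UNIT, -0.1)

    def test_nonfinite_gi50_rejected(self):
        with pytest.raises(ParameterError):
            VeccUnit(math.inf, 1.0, 1.0, 1.0)
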