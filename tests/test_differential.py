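import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from spectranote import (
    DEConfig,
    NSAFMatrix,
    anova_scan,
    de_call,
    nsaf,
    presence_filter,
    signed_fold,
    updown_summary,
)

from conftest import make_counts

positive = st.floats(min_value=1e-6, max_value=1e6, allow_nan=False)


class TestSignedFold:
    def test_caleosin_row(self):
        # treatment-mean NSAF 1.2 (control) vs 0.1 (heat stress): 12-fold drop
        assert signed_fold(1.2, 0.1) == pytest.approx(-12.0)

    def test_equal_means_is_plus_one(self):
        assert signed_fold(0.7, 0.7) == 1.0

    @given(a=positive, b=positive)
    @settings(max_examples=500, derandomize=True)
    def test_antisymmetry(self, a, b):
        if a != b:
            assert signed_fold(a, b) == pytest.approx(-signed_fold(b, a))
        assert abs(signed_fold(a, b)) >= 1.0

    def test_absence_sentinels(self):
        assert signed_fold(0.0, 0.5) == np.inf
        assert signed_fold(0.5, 0.0) == -np.inf

    def test_both_zero_errors(self):
        with pytest.raises(ValueError):
            signed_fold(0.0, 0.0)


def _nsaf_from_values(values: pd.DataFrame, design: pd.DataFrame) -> NSAFMatrix:
    return NSAFMatrix(values=values, scale_factor=1.0, design=design)


def _two_treatment_design():
    return pd.DataFrame(
        {
            "sample_id": ["A_r1", "A_r2", "A_r3", "B_r1", "B_r2", "B_r3"],
            "treatment": ["A"] * 3 + ["B"] * 3,
            "replicate": [1, 2, 3, 1, 2, 3],
        }
    )


class TestDECall:
    def test_identical_groups_not_called(self):
        vals = pd.DataFrame([[2.0] * 6], index=["P1"],
                            columns=_two_treatment_design()["sample_id"])
        res = de_call(_nsaf_from_values(vals, _two_treatment_design()), "A", "B", ["P1"])
        row = res.iloc[0]
        assert not row["call"] and row["reason"] == "not_de"
        assert row["fold"] == 1.0 and row["p_value"] == 1.0

    def test_absence_branch(self):
        vals = pd.DataFrame([[1.0, 1.2, 0.8, 0.0, 0.0, 0.0]], index=["P1"],
                            columns=_two_treatment_design()["sample_id"])
        res = de_call(_nsaf_from_values(vals, _two_treatment_design()), "A", "B", ["P1"])
        row = res.iloc[0]
        assert row["call"] and row["reason"] == "absence"
        assert row["fold"] == -np.inf

    def test_absence_never_fires_with_detections_both_sides(self):
        cm = make_counts(100, seed=31, max_count=4)
        m = nsaf(cm)
        res = de_call(m, "P-C", "P-HS", presence_filter(cm).retained)
        det_a = (m.values[m.samples_of("P-C")] > 0).any(axis=1)
        det_b = (m.values[m.samples_of("P-HS")] > 0).any(axis=1)
        both = set(det_a.index[det_a & det_b])
        fired = set(res.loc[res["reason"] == "absence", "accession"])
        assert not (fired & both)

    def test_swap_flips_folds_preserves_p_and_call(self):
        cm = make_counts(150, seed=41, max_count=6)
        m = nsaf(cm)
        retained = presence_filter(cm).retained
        ab = de_call(m, "P-C", "P-HS", retained).set_index("accession")
        ba = de_call(m, "P-HS", "P-C", retained).set_index("accession")
        ab, ba = ab.align(ba, join="inner", axis=0)
        finite = np.isfinite(ab["fold"]) & (ab["fold"].abs() > 1)
        np.testing.assert_allclose(
            ab.loc[finite, "fold"], -ba.loc[finite, "fold"], rtol=1e-12
        )
        inf = np.isinf(ab["fold"])
        assert (ab.loc[inf, "fold"] == -ba.loc[inf, "fold"]).all()
        np.testing.assert_allclose(ab["p_value"], ba["p_value"], rtol=1e-12)
        assert (ab["call"] == ba["call"]).all()

    def test_min_fold_one_passes_condition3_for_finite_folds(self):
        cm = make_counts(80, seed=51, max_count=6)
        m = nsaf(cm)
        res = de_call(m, "P-C", "P-HS", presence_filter(cm).retained,
                      DEConfig(min_fold=1.0))
        defined = ~res["fold"].isna()
        assert res.loc[defined, "cond3"].all()

    def test_welch_variant_changes_p_not_fold(self):
        cm = make_counts(60, seed=61)
        m = nsaf(cm)
        retained = presence_filter(cm).retained
        s = de_call(m, "P-C", "P-HS", retained, DEConfig(test_variant="student"))
        w = de_call(m, "P-C", "P-HS", retained, DEConfig(test_variant="welch"))
        pd.testing.assert_series_equal(s["fold"], w["fold"])
        assert not np.allclose(s["p_value"], w["p_value"])

    def test_sorted_by_absolute_fold(self):
        cm = make_counts(70, seed=71, max_count=5)
        m = nsaf(cm)
        res = de_call(m, "P-C", "P-HS", presence_filter(cm).retained)
        absfold = res["fold"].abs().fillna(-1).to_numpy()
        assert (np.diff(absfold) <= 1e-12).all()


class TestUpdownSummary:
    @pytest.mark.parametrize(
        "n_total,n_up,pct_up,pct_down",
        [(130, 38, 29, 71), (95, 53, 56, 44), (118, 37, 31, 69), (5, 5, 100, 0)],
    )
    def test_printed_percentages(self, n_total, n_up, pct_up, pct_down):
        res = pd.DataFrame(
            {
                "call": [True] * n_total,
                "fold": [2.0] * n_up + [-2.0] * (n_total - n_up),
            }
        )
        s = updown_summary(res)
        assert (s["pct_up"], s["pct_down"]) == (pct_up, pct_down)

    def test_zero_calls(self):
        s = updown_summary(pd.DataFrame({"call": [False], "fold": [1.0]}))
        assert s["n_total"] == 0 and s["pct_up"] is None


class TestAnova:
    def _matrix(self, values):
        design = pd.DataFrame(
            {
                "sample_id": [f"{t}_r{r}" for t in "ABCD" for r in (1, 2, 3)],
                "treatment": [t for t in "ABCD" for _ in range(3)],
                "replicate": [1, 2, 3] * 4,
            }
        )
        vals = pd.DataFrame(values, columns=design["sample_id"])
        vals.index = [f"P{i}" for i in range(len(vals))]
        return _nsaf_from_values(vals, design)

    def test_identical_values_f_zero(self):
        res = anova_scan(self._matrix([[3.0] * 12]))
        assert res["F"].iloc[0] == 0.0 and res["degenerate"].iloc[0]

    def test_two_groups_f_equals_t_squared(self):
        rng = np.random.default_rng(5)
        vals = rng.random((10, 6))
        design = _two_treatment_design()
        m = _nsaf_from_values(
            pd.DataFrame(vals, index=[f"P{i}" for i in range(10)],
                         columns=design["sample_id"]),
            design,
        )
        res = anova_scan(m)
        t = stats.ttest_ind(vals[:, :3], vals[:, 3:], axis=1)
        np.testing.assert_allclose(res["F"], t.statistic**2, rtol=1e-9)
        np.testing.assert_allclose(res["p_value"], t.pvalue, rtol=1e-9)

    def test_matches_scipy_f_oneway(self):
        rng = np.random.default_rng(12)
        vals = rng.random((40, 12))
        m = self._matrix(vals)
        res = anova_scan(m)
        groups = [vals[:, i * 3 : (i + 1) * 3] for i in range(4)]
        ref = stats.f_oneway(*groups, axis=1)
        np.testing.assert_allclose(res["F"], ref.statistic, rtol=1e-9)
        np.testing.assert_allclose(res["p_value"], ref.pvalue, rtol=1e-9)
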