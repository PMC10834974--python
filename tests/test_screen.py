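"""Univariate screening: test routing, rank AUC vs a brute-force pairwise
oracle, Youden scan vs exhaustive enumeration, ratios, fold changes,
normalization, the significance filter, and the PCA overview."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import silhouette_score

from metabodx.screen import (
    DECREASED,
    DEFAULT_RATIOS,
    INCREASED,
    MANN_WHITNEY,
    T_TEST,
    UNCHANGED,
    compare_groups,
    derive_ratios,
    log2fc,
    minmax_normalize,
    normality_route,
    pca_overview,
    rank_auc,
    screen,
    results_frame,
    youden,
)
from metabodx.simulate import CASE, CONTROL, CohortConfig, generate_cohort

from conftest import flat_panel


def brute_force_auc(ctrl, case):
    """Oracle: concordant-pair count over all n1*n2 pairs, ties counted 1/2."""
    ctrl, case = np.asarray(ctrl, float), np.asarray(case, float)
    wins = sum((k > c) + 0.5 * (k == c) for c in ctrl for k in case)
    a = wins / (len(ctrl) * len(case))
    return max(a, 1 - a)


def brute_force_youden(ctrl, case):
    """Oracle: try every rule of the form x>c / x<c over all observed values."""
    ctrl, case = np.asarray(ctrl, float), np.asarray(case, float)
    best = 0.0
    for c in np.concatenate([ctrl, case]):
        for sens, spec in [
            ((case > c).mean(), (ctrl <= c).mean()),
            ((case >= c).mean(), (ctrl < c).mean()),
            ((case < c).mean(), (ctrl >= c).mean()),
            ((case <= c).mean(), (ctrl > c).mean()),
        ]:
            best = max(best, sens + spec - 1)
    return best


group = st.lists(st.floats(-50, 50, allow_nan=False), min_size=1, max_size=40)


class TestNormalityRoute:
    def test_two_normal_samples_route_parametric(self):
        rng = np.random.default_rng(2)
        assert normality_route(rng.normal(0, 1, 80), rng.normal(1, 1, 80)) == T_TEST

    def test_lognormal_sample_routes_nonparametric(self):
        rng = np.random.default_rng(2)
        assert normality_route(rng.normal(0, 1, 80),
                               rng.lognormal(0, 1.5, 80)) == MANN_WHITNEY

    def test_degenerate_groups_route_nonparametric(self):
        assert normality_route(np.ones(3), np.array([1.0, 2.0, 3.0])) == MANN_WHITNEY
        assert normality_route(np.array([1.0, 2.0]), np.ones(5)) == MANN_WHITNEY


class TestCompareGroups:
    def test_identical_groups(self):
        p, d = compare_groups(np.ones(5), np.ones(5), MANN_WHITNEY)
        assert p == 1.0 and d == UNCHANGED

    def test_complete_separation_mann_whitney(self):
        p, d = compare_groups(np.array([1, 2, 3, 4, 5.0]),
                              np.array([10, 11, 12, 13, 14.0]), MANN_WHITNEY)
        # U = 0: exact two-sided p = 2 * 1/C(10,5) = 2/252
        assert p == pytest.approx(2 / 252, rel=1e-6)
        assert d == INCREASED

    def test_swap_symmetry(self):
        a = np.array([1, 2, 3, 9.0])
        b = np.array([4, 5, 6, 7.0])
        p1, d1 = compare_groups(a, b, MANN_WHITNEY)
        p2, d2 = compare_groups(b, a, MANN_WHITNEY)
        assert p1 == pytest.approx(p2)
        assert {d1, d2} == {INCREASED, DECREASED}


class TestRankAuc:
    @pytest.mark.parametrize(
        "ctrl, case, expected",
        [
            ([1, 2], [3, 4], 1.0),                  # perfect separation
            ([1, 1, 1], [1, 1, 1], 0.5),            # all ties
            ([1, 3, 5], [2, 4, 6], 6 / 9),          # interleaved, oracle-counted
        ],
    )
    def test_known_values(self, ctrl, case, expected):
        assert rank_auc(np.array(ctrl, float), np.array(case, float)) == \
            pytest.approx(expected)

    @settings(derandomize=True, max_examples=200, deadline=None)
    @given(group, group)
    def test_matches_brute_force_oracle(self, ctrl, case):
        assert rank_auc(np.array(ctrl), np.array(case)) == \
            pytest.approx(brute_force_auc(ctrl, case), abs=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            rank_auc(np.array([]), np.array([1.0]))


class TestYouden:
    def test_perfect_separation(self):
        j, sps, cutoff = youden(np.array([1, 2.0]), np.array([5, 6.0]))
        assert j == 1.0 and sps == 2.0 and 2.0 < cutoff < 5.0

    def test_identical_distributions(self):
        j, sps, _ = youden(np.ones(4), np.ones(4))
        assert j == 0.0 and sps == 1.0

    @settings(derandomize=True, max_examples=150, deadline=None)
    @given(group, group)
    def test_matches_exhaustive_scan(self, ctrl, case):
        j, sps, _ = youden(np.array(ctrl), np.array(case))
        assert j == pytest.approx(brute_force_youden(ctrl, case), abs=1e-12)
        assert sps == pytest.approx(j + 1.0)
        assert 0.0 <= j <= 1.0


class TestRatios:
    def _table(self, **cols):
        n = len(next(iter(cols.values())))
        base = {"subject_id": [f"s{i}" for i in range(n)],
                "group": [CONTROL] * n, "age": [40.0] * n, "sex": [""] * n}
        return pd.DataFrame({**base, **cols})

    def test_fisher_and_gsg_values(self):
        t = self._table(Valine=[1.0], Isoleucine=[1.0], Leucine=[1.0],
                        Phenylalanine=[1.0], Tyrosine=[1.0],
                        Glutamate=[2.0], Serine=[1.0], Glycine=[1.0])
        out = derive_ratios(t, DEFAULT_RATIOS)
        assert out["Fisher ratio"].iloc[0] == pytest.approx(1.5)
        assert out["GSG ratio"].iloc[0] == pytest.approx(1.0)

    def test_nonpositive_denominator_gives_nan(self):
        t = self._table(Valine=[1.0], Isoleucine=[1.0], Leucine=[1.0],
                        Phenylalanine=[0.0], Tyrosine=[0.0],
                        Glutamate=[1.0], Serine=[1.0], Glycine=[1.0])
        out = derive_ratios(t, DEFAULT_RATIOS)
        assert np.isnan(out["Fisher ratio"].iloc[0])

    def test_missing_precursor_rejected(self):
        t = self._table(Valine=[1.0])
        with pytest.raises(KeyError):
            derive_ratios(t, DEFAULT_RATIOS)


class TestLog2FC:
    def test_known_values_and_antisymmetry(self):
        one, four = np.array([1.0, 1, 1]), np.array([4.0, 4, 4])
        assert log2fc(one, one) == 0.0
        assert log2fc(one, four) == pytest.approx(2.0)
        assert log2fc(four, one) == pytest.approx(-2.0)

    def test_nonpositive_median_undefined(self):
        assert np.isnan(log2fc(np.array([0.0, 0.0, 0.0]), np.array([1.0])))


class TestMinMax:
    def test_scales_to_unit_interval(self):
        assert np.allclose(minmax_normalize(np.array([2.0, 4.0, 6.0])),
                           [0.0, 0.5, 1.0])
        full = np.array([0.0, 0.25, 1.0])
        assert np.allclose(minmax_normalize(full), full)

    def test_constant_column_warns_and_zeroes(self):
        with pytest.warns(UserWarning):
            out = minmax_normalize(np.full(4, 3.0))
        assert np.allclose(out, 0.0)


class TestScreen:
    def _cohort(self, effect, seed=13, n_met=20, n_affected=5):
        panel = flat_panel(n_met, baseline=100.0, slope=0.0, cv=0.2)
        affected = frozenset(f"M{i:03d}" for i in range(n_affected)) if effect else frozenset()
        for i in range(n_affected):
            panel[i] = panel[i].__class__(**{**panel[i].__dict__,
                                             "group_log2_effect": effect})
        cfg = CohortConfig(n_control=40, n_case=40,
                           control_age_dist=(40.0, 35.0, 45.0),
                           case_age_dist=(40.0, 35.0, 45.0),
                           seed=seed, affected_metabolites=affected)
        return generate_cohort(cfg, panel)[0]

    def test_recovers_affected_metabolites(self):
        table = self._cohort(effect=1.5)
        res = screen(table)
        passed = {r.metabolite for r in res if r.passes_filter}
        affected = {f"M{i:03d}" for i in range(5)}
        assert len(passed & affected) >= 5 * 0.9
        # false passes stay near the nominal level
        assert len(passed - affected) <= 3

    def test_vacuous_thresholds_pass_everything(self):
        table = self._cohort(effect=0.0)
        res = screen(table, p_thresh=1.01, auc_thresh=0.0)
        assert all(r.passes_filter for r in res)

    def test_null_cohort_passes_nothing_strong(self):
        table = self._cohort(effect=0.0)
        res = screen(table)
        assert sum(r.passes_filter for r in res) <= 2

    def test_results_frame_sorted_and_complete(self, small_cohort):
        table, _ = small_cohort
        res = screen(table)
        df = results_frame(res)
        assert len(df) == 87
        assert (df["auc"] >= 0.5).all()
        assert np.allclose(df["sens_plus_spec"], df["youden_j"] + 1.0)

    def test_no_metabolites_rejected(self):
        t = pd.DataFrame({"subject_id": ["a"], "group": [CASE],
                          "age": [50.0], "sex": [""]})
        with pytest.raises(ValueError):
            screen(t)


class TestPcaOverview:
    def test_separated_groups_have_positive_silhouette(self):
        table = TestScreen()._cohort(effect=2.0)
        scores, flags = pca_overview(table)
        pcs = scores[["pc1", "pc2"]].to_numpy()
        assert silhouette_score(pcs, table["group"]) > 0

    def test_duplicated_subjects_get_identical_scores(self):
        table = TestScreen()._cohort(effect=0.0).head(6)
        dup = pd.concat([table, table.assign(subject_id=table.subject_id + "_b")],
                        ignore_index=True)
        scores, _ = pca_overview(dup)
        top = scores[["pc1", "pc2"]].to_numpy()
        assert np.allclose(top[:6], top[6:])

    def test_constant_matrix_warns(self):
        t = pd.DataFrame({"subject_id": list("abc"), "group": [CONTROL] * 3,
                          "age": [40.0] * 3, "sex": [""] * 3,
                          "m1": [1.0] * 3, "m2": [2.0] * 3})
        with pytest.warns(UserWarning):
            scores, flags = pca_overview(t)
        assert not flags.any()
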