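"""Fingerprint-activity modeling: GCA, Pearson screening, marker report."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from specfx import datasets
from specfx import fingerprint_activity as fa
from specfx import synthetic_data as sd
from specfx.exceptions import ConfigurationError, DegenerateInputError


class TestGreyNormalize:
    def test_mean_scheme(self):
        assert list(fa.grey_normalize([1, 2, 3], "mean")) == [0.5, 1.0, 1.5]

    def test_constant_sequence_mean_scheme(self):
        assert list(fa.grey_normalize([4, 4, 4], "mean")) == [1.0, 1.0, 1.0]

    def test_minmax_scheme(self):
        assert list(fa.grey_normalize([1, 2, 3], "minmax")) == [0.0, 0.5, 1.0]

    def test_initial_value_scheme(self):
        assert list(fa.grey_normalize([2, 4, 6], "initial-value")) == [1.0, 2.0, 3.0]

    def test_degenerate_sequences_rejected(self):
        with pytest.raises(DegenerateInputError):
            fa.grey_normalize([1, -1], "mean")
        with pytest.raises(DegenerateInputError):
            fa.grey_normalize([2, 2], "minmax")
        with pytest.raises(DegenerateInputError):
            fa.grey_normalize([0, 1], "initial-value")


class TestGreyRelationalGrade:
    def test_identity_comparison_grade_one(self):
        ref = [1.0, 2.0, 3.0]
        for rho in [0.1, 0.5, 1.0]:
            res = fa.grey_relational_grade(ref, pd.DataFrame({"c": ref}), fa.GreyParams(rho=rho))
            assert res.grades["c"] == pytest.approx(1.0)

    def test_hand_computed_example(self):
        # ref [1, .5, 0] vs cmp [.5, .5, .5]: Delta=[.5,0,.5], xi=[1/3,1,1/3]
        res = fa.grey_relational_grade(
            [1.0, 0.5, 0.0], pd.DataFrame({"c": [0.5, 0.5, 0.5]}), normalize=False
        )
        assert np.allclose(res.xi["c"], [1 / 3, 1.0, 1 / 3], atol=1e-12)
        assert res.grades["c"] == pytest.approx(5 / 9, abs=1e-12)

    def test_pointwise_closer_sequence_grades_higher(self):
        ref = np.array([1.0, 0.5, 0.0, 0.8])
        cmp1 = ref + 0.05  # uniformly closer
        cmp2 = ref + 0.30
        res = fa.grey_relational_grade(ref, pd.DataFrame({"c1": cmp1, "c2": cmp2}), normalize=False)
        assert res.grades["c1"] > res.grades["c2"]
        assert res.ranks["c1"] == 1

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        data=st.lists(
            st.tuples(st.floats(0.1, 100), st.floats(0.1, 100), st.floats(0.1, 100)),
            min_size=2, max_size=10,
        ),
        rho=st.floats(0.05, 1.0),
    )
    def test_xi_always_in_unit_interval(self, data, rho):
        arr = np.array(data)
        ref, c1, c2 = arr[:, 0], arr[:, 1], arr[:, 2]
        res = fa.grey_relational_grade(
            ref, pd.DataFrame({"a": c1, "b": c2}), fa.GreyParams(rho=rho)
        )
        assert ((res.xi > 0) & (res.xi <= 1)).all().all()
        assert ((res.grades > 0) & (res.grades <= 1)).all()

    def test_all_identical_comparisons_grade_one(self):
        ref = [1.0, 2.0]
        res = fa.grey_relational_grade(ref, pd.DataFrame({"a": ref, "b": ref}))
        assert (res.grades == 1.0).all()

    def test_invalid_rho_rejected(self):
        with pytest.raises(ConfigurationError):
            fa.GreyParams(rho=0.0)
        with pytest.raises(ConfigurationError):
            fa.GreyParams(rho=1.5)


class TestPearsonMatrix:
    @staticmethod
    def _aligned(x_cols, y_cols):
        idx = pd.RangeIndex(len(next(iter(x_cols.values()))))
        return (pd.DataFrame(x_cols, index=idx), pd.DataFrame(y_cols, index=idx))

    def test_proportional_is_one(self):
        areas, ind = self._aligned({"P1": [1.0, 2.0, 3.0]}, {"ALT": [2.0, 4.0, 6.0]})
        res = fa.pearson_matrix(areas, ind)
        assert res.r.at["P1", "ALT"] == pytest.approx(1.0)

    def test_hand_example(self):
        areas, ind = self._aligned({"P1": [1.0, 2.0, 3.0, 4.0]}, {"ALT": [1.0, 3.0, 2.0, 4.0]})
        res = fa.pearson_matrix(areas, ind)
        assert res.r.at["P1", "ALT"] == pytest.approx(0.8)

    def test_matches_product_moment_oracle(self):
        rng = np.random.default_rng(3)
        areas = pd.DataFrame(rng.uniform(1, 100, (12, 5)), columns=[f"P{i+1}" for i in range(5)])
        ind = pd.DataFrame(rng.uniform(1, 100, (12, 3)), columns=["ALT", "AST", "MDA"])
        res = fa.pearson_matrix(areas, ind)
        for p in areas.columns:
            for c in ind.columns:
                x, y = areas[p].to_numpy(), ind[c].to_numpy()
                xc, yc = x - x.mean(), y - y.mean()
                oracle = (xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum())
                assert res.r.at[p, c] == pytest.approx(oracle, abs=1e-12)

    def test_critical_r_at_n12_near_alpha(self):
        # r = 0.576 with n = 12 sits at the alpha = 0.05 boundary
        r = 0.576
        t = r * np.sqrt(10 / (1 - r**2))
        from scipy import stats

        p = 2 * stats.t.sf(t, 10)
        assert p == pytest.approx(0.05, abs=0.005)

    def test_zero_variance_rejected(self):
        areas, ind = self._aligned({"P1": [1.0, 1.0, 1.0]}, {"ALT": [1.0, 2.0, 3.0]})
        with pytest.raises(DegenerateInputError):
            fa.pearson_matrix(areas, ind)


class TestPairing:
    def test_high_dose_policy_length_12(self, fingerprint_matrix, efficacy_table):
        areas, ind = fa.pair_fingerprints_with_efficacy(fingerprint_matrix, efficacy_table, "high")
        assert len(areas) == len(ind) == 12
        assert list(ind.columns) == ["ALT", "AST", "MDA", "SOD", "CAT", "POD"]
        # replicates of one treatment share their group means
        t0 = areas.index[fingerprint_matrix.sample_meta["treatment_mM"] == 0]
        assert ind.loc[t0].nunique().max() == 1

    def test_treatment_mean_policy_length_4(self, fingerprint_matrix, efficacy_table):
        areas, ind = fa.pair_fingerprints_with_efficacy(
            fingerprint_matrix, efficacy_table, "treatment-mean"
        )
        assert len(areas) == len(ind) == 4

    def test_missing_group_rejected(self, fingerprint_matrix, efficacy_table):
        trimmed = efficacy_table.data[efficacy_table.data["group"] != "H300"]
        from specfx.pharmacology import EfficacyTable

        with pytest.raises(ConfigurationError):
            fa.pair_fingerprints_with_efficacy(
                fingerprint_matrix, EfficacyTable(trimmed), "high"
            )


class TestScreenGca:
    def test_reported_alt_positive_top5(self):
        sel, prov = fa.screen_gca(datasets.gca_grade_series(), top_k=5)
        alt_pos = prov[(prov["indicator"] == "ALT") & (prov["mode"] == "positive")]
        assert set(alt_pos["peak_id"]) == {"P1", "P12", "P8", "P9", "P5"}

    def test_reported_pod_negative_top5(self):
        _, prov = fa.screen_gca(datasets.gca_grade_series(), top_k=5)
        pod_neg = prov[(prov["indicator"] == "POD") & (prov["mode"] == "negative")]
        assert set(pod_neg["peak_id"]) == {"N10", "N1", "N8", "N11", "N6"}

    def test_rank_one_set(self):
        sel, _ = fa.screen_gca(datasets.gca_grade_series(), top_k=1)
        assert sel == {"P1", "P4", "P5", "P2", "N12", "N1", "N9", "N10"}

    def test_ties_at_kth_grade_all_included(self):
        grades = pd.Series(
            {"P1": 0.9, "P2": 0.8, "P3": 0.8, "P4": 0.7},
        )
        sel, _ = fa.screen_gca({"ALT": grades}, top_k=2)
        assert sel == {"P1", "P2", "P3"}

    def test_fewer_peaks_than_k_returns_all(self):
        grades = pd.Series({"P1": 0.9, "P2": 0.8})
        sel, _ = fa.screen_gca({"ALT": grades}, top_k=5)
        assert sel == {"P1", "P2"}


@pytest.fixture()
def reported():
    r = datasets.pearson_r_matrix()
    n = 12
    t = r.abs() * np.sqrt((n - 2) / (1 - r.abs() ** 2))
    from scipy import stats

    p = 2 * stats.t.sf(t, n - 2)
    return fa.CorrelationResult(r, pd.DataFrame(p, index=r.index, columns=r.columns), n)


class TestScreenBca:
    @pytest.mark.parametrize(
        "indicator,expected",
        [
            ("ALT", {"P10", "P12", "N6"}),
            ("AST", {"N11", "N14"}),
            ("POD", {"N8", "N11"}),
            ("CAT", {"N5", "N9", "N14"}),
        ],
    )
    def test_reported_columns_above_half(self, reported, indicator, expected):
        _, prov = fa.screen_bca(reported, rule="abs_r", threshold=0.5)
        assert set(prov[prov["indicator"] == indicator]["peak_id"]) == expected

    def test_p_rule_matches_reported_stars(self, reported):
        sel, prov = fa.screen_bca(reported, rule="p", alpha=0.05)
        starred = datasets.load_pearson_r()["starred"].dropna()
        assert sel == set(starred.index)

    def test_unknown_rule_rejected(self, reported):
        with pytest.raises(ConfigurationError):
            fa.screen_bca(reported, rule="bogus")


class TestUnionAndReport:
    def test_reported_selections_union_to_19(self):
        sel = datasets.load_marker_selection()
        union = fa.union_markers(sel["gca"], sel["bca"])
        assert len(union) == 19

    def test_union_identities(self):
        assert fa.union_markers({"P1"}, set()) == {"P1"}
        assert fa.union_markers({"P10"}, {"P10", "N6"}) == {"P10", "N6"}

    def test_marker_report_15_markers_2_unknown(self, library):
        sel = datasets.load_marker_selection()
        union = fa.union_markers(sel["gca"], sel["bca"])
        rep = fa.build_marker_report(union, library, sel["gca"], sel["bca"])
        assert rep.n_markers == 15
        assert rep.n_unknown == 2
        unknown_members = {p for m in rep.markers if m["is_unknown"] for p in m["member_peaks"]}
        assert unknown_members == {"P3", "N4"}

    def test_marker_classes_cover_reported_families(self, library):
        sel = datasets.load_marker_selection()
        union = fa.union_markers(sel["gca"], sel["bca"])
        rep = fa.build_marker_report(union, library)
        classes = {m["compound_class"] for m in rep.markers}
        assert {"organic acid", "flavonoid", "terpenoid", "phenylpropanoid", "quinone", "unknown"} <= classes

    def test_empty_union_empty_report(self, library):
        rep = fa.build_marker_report(set(), library)
        assert rep.n_markers == 0


class TestPipeline:
    def test_deterministic_rerun(self, fingerprint_matrix, efficacy_table, library):
        rep1 = fa.run_pipeline(fingerprint_matrix, efficacy_table, library)
        rep2 = fa.run_pipeline(fingerprint_matrix, efficacy_table, library)
        assert rep1.union == rep2.union
        assert rep1.markers == rep2.markers
        pd.testing.assert_frame_equal(rep1.evidence, rep2.evidence)

    def test_planted_peak_survives_both_screens(self, efficacy_table, library):
        cfg = sd.GeneratorConfig(seed=13)
        matrix = sd.generate_fingerprints(cfg)
        _, ind = fa.pair_fingerprints_with_efficacy(matrix, efficacy_table, "high")
        planted = sd.plant_correlated_peak(matrix, ind["ALT"], 1.0, seed=13)
        areas, ind2 = fa.pair_fingerprints_with_efficacy(planted, efficacy_table, "high")
        gca = fa.gca_all_indicators(areas, ind2)
        assert gca["ALT"].ranks["P_planted"] == 1
        bca_sel, _ = fa.screen_bca(fa.pearson_matrix(areas, ind2))
        assert "P_planted" in bca_sel
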