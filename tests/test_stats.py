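"""Group summaries, mixed ANOVA, Dunnett, correlations and 2-SD bands."""

import numpy as np
import pandas as pd
import pytest

from orbitq.stats import (
    age_anova,
    dunnett_critical_value,
    dunnett_posthoc,
    group_summary,
    healthy_reference,
    normalize_to_healthy,
    pearson_with_p,
    rm_anova_laterality,
    sd_band_counts,
    sex_chi2,
    table2_summary,
)
from orbitq.synthetic import default_group_specs, make_cohort


def _toy_table(rng=None, k=3, n=8, shift=None, lr_slope=0.5):
    rng = rng or np.random.default_rng(0)
    shift = shift or [0.0] * k
    rows = []
    for gi in range(k):
        for i in range(n):
            left = rng.normal(shift[gi], 1.0)
            right = lr_slope * left + rng.normal(0.0, 1.0)
            pid = f"g{gi}p{i}"
            for eye, val in (("L", left), ("R", right)):
                rows.append({
                    "group": f"g{gi}", "patient_id": pid, "eye": eye,
                    "muscle": "LR", "volume_mm3": val,
                })
    return pd.DataFrame(rows)


class TestGroupSummary:
    def test_pooled_eyes_mean_sd(self):
        df = pd.DataFrame({
            "group": ["a"] * 4, "patient_id": ["p1", "p1", "p2", "p2"],
            "eye": ["L", "R", "L", "R"], "muscle": ["LR"] * 4,
            "volume_mm3": [1.0, 2.0, 3.0, 4.0],
        })
        s = group_summary(df, "volume_mm3")
        assert s.loc[0, "mean"] == pytest.approx(2.5)
        assert s.loc[0, "n"] == 4

    def test_eye_average_switch(self):
        df = pd.DataFrame({
            "group": ["a"] * 4, "patient_id": ["p1", "p1", "p2", "p2"],
            "eye": ["L", "R", "L", "R"], "muscle": ["LR"] * 4,
            "volume_mm3": [1.0, 3.0, 2.0, 4.0],
        })
        s = group_summary(df, "volume_mm3", pool_eyes=False)
        assert s.loc[0, "mean"] == pytest.approx(2.5)
        assert s.loc[0, "n"] == 2

    def test_single_row_sd_undefined(self):
        df = pd.DataFrame({
            "group": ["a"], "patient_id": ["p1"], "eye": ["L"],
            "muscle": ["LR"], "volume_mm3": [1.0],
        })
        s = group_summary(df, "volume_mm3")
        assert np.isnan(s.loc[0, "sd"])

    def test_constant_metric_zero_sd(self):
        df = pd.DataFrame({
            "group": ["a"] * 3, "patient_id": list("pqr"), "eye": ["L"] * 3,
            "muscle": ["LR"] * 3, "volume_mm3": [2.0, 2.0, 2.0],
        })
        assert group_summary(df, "volume_mm3").loc[0, "sd"] == 0.0


class TestMixedAnova:
    def test_matches_pingouin_on_balanced_data(self):
        """Reference implementation agreement to 1e-8 (balanced design)."""
        pg = pytest.importorskip("pingouin")
        df = _toy_table(shift=[0.0, 0.5, 1.0])
        mine = rm_anova_laterality(df, "volume_mm3", "LR")
        ref = pg.mixed_anova(
            data=df.rename(columns={"volume_mm3": "y"}), dv="y",
            within="eye", subject="patient_id", between="group",
        )
        f_mine = dict(zip(mine["source"], mine["F"]))
        ss_mine = dict(zip(mine["source"], mine["ss"]))
        f_ref = dict(zip(ref["Source"], ref["F"]))
        ss_ref = dict(zip(ref["Source"], ref["SS"]))
        assert f_mine["group"] == pytest.approx(f_ref["group"], abs=1e-8)
        assert f_mine["laterality"] == pytest.approx(f_ref["eye"], abs=1e-8)
        assert f_mine["group:laterality"] == pytest.approx(
            f_ref["Interaction"], abs=1e-8
        )
        assert ss_mine["group"] == pytest.approx(ss_ref["group"], abs=1e-8)

    def test_identical_eyes_zero_laterality_f(self):
        df = _toy_table(lr_slope=1.0)
        df["volume_mm3"] = df.groupby(["patient_id"])["volume_mm3"].transform(
            "first"
        )
        res = rm_anova_laterality(df, "volume_mm3", "LR")
        lat = res.set_index("source")
        assert lat.loc["laterality", "F"] == 0.0
        assert lat.loc["laterality", "p"] == 1.0

    def test_sums_of_squares_partition(self):
        """SS_total decomposes exactly into the five components."""
        df = _toy_table(shift=[0.0, 1.0, 2.0])
        res = rm_anova_laterality(df, "volume_mm3", "LR")
        y = df["volume_mm3"].to_numpy()
        ss_total = float(np.sum((y - y.mean()) ** 2))
        assert res["ss"].sum() == pytest.approx(ss_total, rel=1e-10)

    def test_small_group_excluded_with_warning(self):
        df = _toy_table(k=2, n=6)
        solo = pd.DataFrame({
            "group": ["tiny"] * 2, "patient_id": ["t1"] * 2,
            "eye": ["L", "R"], "muscle": ["LR"] * 2, "volume_mm3": [1.0, 1.1],
        })
        with pytest.warns(UserWarning, match="tiny"):
            res = rm_anova_laterality(pd.concat([df, solo]), "volume_mm3", "LR")
        assert res.set_index("source").loc["group", "df"] == 1

    def test_null_type_i_error_calibrated(self):
        """1000 null datasets: rejection rate inside the 95% binomial CI."""
        rng = np.random.default_rng(42)
        from orbitq.stats import _mixed_anova_arrays

        groups = np.repeat(["a", "b", "c"], 10)
        hits = 0
        n_rep = 1000
        for _ in range(n_rep):
            left = rng.standard_normal(30)
            right = rng.standard_normal(30)
            res = _mixed_anova_arrays(left, right, groups)
            p = res.set_index("source").loc["group", "p"]
            hits += p < 0.05
        rate = hits / n_rep
        ci = 1.96 * np.sqrt(0.05 * 0.95 / n_rep)
        assert abs(rate - 0.05) < ci


class TestDunnett:
    def test_critical_values_match_published_tables(self):
        """Two-sided alpha=0.05, k=3 many-to-one table values."""
        assert dunnett_critical_value(3, 10) == pytest.approx(2.76, abs=0.01)
        assert dunnett_critical_value(3, 20) == pytest.approx(2.54, abs=0.01)
        assert dunnett_critical_value(3, 30) == pytest.approx(2.47, abs=0.01)
        assert dunnett_critical_value(3, 60) == pytest.approx(2.41, abs=0.01)

    def test_single_comparison_reduces_to_t(self):
        from scipy import stats as sps

        assert dunnett_critical_value(1, 25) == pytest.approx(
            sps.t.ppf(0.975, 25), abs=1e-3
        )

    def test_identical_groups_adjusted_p_near_one(self):
        """Groups with literally identical data: adjusted p of 1."""
        df = _toy_table(k=1, n=10)
        copies = []
        for g in ("g1", "g2", "g3"):
            c = df.copy()
            c["group"] = g
            c["patient_id"] = g + c["patient_id"]
            copies.append(c)
        full = pd.concat([df] + copies, ignore_index=True)
        res = dunnett_posthoc(full, "volume_mm3", "LR",
                              reference_group="g0", seed=0)
        assert (res["p_adjusted"] > 0.999).all()
        assert np.allclose(res["statistic"], 0.0)

    def test_adjusted_at_least_unadjusted(self):
        from scipy import stats as sps

        df = _toy_table(k=4, n=10, shift=[0, 0.3, 0.8, 1.5])
        res = dunnett_posthoc(df, "volume_mm3", "LR", reference_group="g0",
                              seed=0)
        control = df[df.group == "g0"]["volume_mm3"]
        for _, row in res.iterrows():
            other = df[df.group == row["group"]]["volume_mm3"]
            t_p = sps.ttest_ind(other, control).pvalue
            assert row["p_adjusted"] >= t_p - 0.02

    def test_large_shift_detected(self):
        df = _toy_table(k=3, n=12, shift=[0.0, 0.0, 5.0])
        res = dunnett_posthoc(df, "volume_mm3", "LR", reference_group="g0",
                              seed=0)
        p = res.set_index("group").loc["g2", "p_adjusted"]
        assert p < 1e-4

    def test_empty_reference_rejected(self):
        df = _toy_table(k=2)
        with pytest.raises(ValueError, match="reference"):
            dunnett_posthoc(df, "volume_mm3", "LR", reference_group="nope")


class TestPearson:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        r, p = pearson_with_p(x, 2 * x)
        assert r == pytest.approx(1.0)
        assert p < 1e-10

    def test_independent_near_zero(self):
        rng = np.random.default_rng(8)
        r, _ = pearson_with_p(rng.standard_normal(10_000),
                              rng.standard_normal(10_000))
        assert abs(r) < 0.05

    def test_generator_roundtrip_negative_correlation(self):
        """CPEO-like cohorts: volume correlates negatively with the
        severity sum-score through the duction-volume coupling."""
        specs = [s for s in default_group_specs(n_scale=5.0)
                 if s.name == "CPEO"]
        t = make_cohort(specs, seed=21)
        lr = t[t.muscle == "LR"]
        limitation = 40.0 - lr["duction_abduction_deg"]
        r, p = pearson_with_p(lr["volume_mm3"].to_numpy(),
                              limitation.to_numpy())
        assert r < -0.3
        assert p < 0.01

    def test_zero_variance_flagged(self):
        r, p = pearson_with_p(np.ones(5), np.arange(5.0))
        assert np.isnan(r) and np.isnan(p)

    def test_validation(self):
        with pytest.raises(ValueError):
            pearson_with_p([1.0, 2.0], [1.0, 2.0])
        with pytest.raises(ValueError):
            pearson_with_p([1.0, np.nan, 2.0], [1.0, 2.0, 3.0])


class TestNormalisation:
    def test_healthy_rows_normalise_to_one(self):
        t = make_cohort(seed=2)
        ref = healthy_reference(t)
        normed = normalize_to_healthy(t, ref)
        healthy = t["group"] == "healthy"
        per_muscle = normed[healthy].groupby(t.loc[healthy, "muscle"]).mean()
        np.testing.assert_allclose(per_muscle, 1.0, atol=1e-12)

    def test_arithmetic(self):
        t = make_cohort(seed=2)
        ref = healthy_reference(t)
        idx = t.index[0]
        muscle = t.loc[idx, "muscle"]
        expected = t.loc[idx, "volume_mm3"] / ref.mean.loc[muscle, "volume_mm3"]
        assert normalize_to_healthy(t, ref).loc[idx] == pytest.approx(expected)

    def test_order_preserved_and_scale_equivariant(self):
        t = make_cohort(seed=2)
        ref = healthy_reference(t)
        n1 = normalize_to_healthy(t, ref)
        t2 = t.copy()
        t2["volume_mm3"] *= 3.0
        n2 = normalize_to_healthy(t2, healthy_reference(t2))
        assert list(n1.index) == list(t.index)
        np.testing.assert_allclose(n1, n2, rtol=1e-12)

    def test_missing_reference_muscle_rejected(self):
        t = make_cohort(seed=2)
        ref = healthy_reference(t[t.muscle != "IR"])
        with pytest.raises(ValueError, match="IR"):
            normalize_to_healthy(t, ref)


class TestSdBandCounts:
    def test_values_at_mean_give_category_zero(self):
        t = make_cohort(seed=3)
        ref = healthy_reference(t)
        flat = t.copy()
        flat["volume_mm3"] = flat["muscle"].map(ref.mean["volume_mm3"])
        res = sd_band_counts(flat, ref)
        assert (res["category"] == "0").all()

    def test_one_outlier_muscle_is_category_one(self):
        t = make_cohort(seed=3)
        ref = healthy_reference(t)
        flat = t.copy()
        flat["volume_mm3"] = flat["muscle"].map(ref.mean["volume_mm3"])
        pid = flat["patient_id"].iloc[0]
        sel = (
            (flat.patient_id == pid) & (flat.eye == "L") & (flat.muscle == "LR")
        )
        flat.loc[sel, "volume_mm3"] += 3.0 * ref.sd.loc["LR", "volume_mm3"]
        res = sd_band_counts(flat, ref)
        assert (
            res.set_index("patient_id").loc[pid, "category"] == "1"
        )

    def test_gaussian_out_of_band_fraction(self):
        """Per-observation tail mass outside +/-2 SD is about 4.6%."""
        rng = np.random.default_rng(6)
        n = 40_000
        rows = {
            "group": ["healthy"] * n,
            "patient_id": [f"p{i}" for i in range(n)],
            "eye": ["L"] * n,
            "muscle": ["LR"] * n,
            "volume_mm3": rng.normal(700.0, 100.0, n),
        }
        t = pd.DataFrame(rows)
        ref = healthy_reference(t)
        with pytest.warns(UserWarning, match="missing muscle rows"):
            res = sd_band_counts(t, ref)
        frac = (res["n_out"] > 0).mean()
        expected = 0.0455
        assert abs(frac - expected) < 0.005

    def test_affine_invariance(self):
        t = make_cohort(seed=4)
        ref = healthy_reference(t)
        r1 = sd_band_counts(t, ref)
        t2 = t.copy()
        t2["volume_mm3"] = 2.0 * t2["volume_mm3"] + 100.0
        r2 = sd_band_counts(t2, healthy_reference(t2))
        assert (r1["n_out"].to_numpy() == r2["n_out"].to_numpy()).all()


class TestConvenience:
    def test_baseline_tests_run(self):
        t = make_cohort(seed=5)
        f, p = age_anova(t)
        chi2, p2 = sex_chi2(t)
        assert np.isfinite(f) and 0 <= p <= 1
        assert np.isfinite(chi2) and 0 <= p2 <= 1

    def test_table2_summary_shape(self):
        t = make_cohort(seed=5)
        s = table2_summary(t)
        assert set(s["metric"]) == {"volume_mm3", "fat_fraction", "t2water_ms"}
        assert len(s) == 3 * 7 * 4
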