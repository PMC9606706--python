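"""Design orchestration and the statistical pipeline."""

import itertools

import numpy as np
import pandas as pd
import pytest

from pacsim import experiment
from pacsim.experiment import (
    InsufficientDataError,
    art_anova_fallback,
    assumption_checks,
    boxcox,
    paired_individualization_test,
    rm_anova_2x2,
    run_configuration,
    run_design,
    run_statistics,
    zscore_within_subject,
)
from pacsim.simulate import CohortSpec, simulate_cohort

LEVELS = ("template", "individual")


def make_table(rng, n_subjects=10, anatomy_effect=0.0, electrode_effect=0.0,
               interaction=0.0, noise=1.0, lognormal=False):
    rows = []
    for s in range(n_subjects):
        subj_offset = rng.normal(0, 1)
        for a, e in itertools.product(LEVELS, LEVELS):
            val = (
                subj_offset
                + anatomy_effect * (a == "individual")
                + electrode_effect * (e == "individual")
                + interaction * (a == "individual") * (e == "individual")
                + noise * rng.normal()
            )
            if lognormal:
                val = np.exp(val)
            rows.append(dict(subject=s, anatomy=a, electrodes=e, value=val))
    return pd.DataFrame(rows)


def hand_ss_anova(df):
    """Independent sums-of-squares decomposition for the 2x2 within design."""
    wide = df.pivot_table(index="subject", columns=["anatomy", "electrodes"],
                          values="value")
    y = wide.to_numpy()  # subjects x 4 cells, column order alphabetical
    cols = list(wide.columns)
    n = y.shape[0]
    a_lvl = np.array([c[0] for c in cols])
    e_lvl = np.array([c[1] for c in cols])
    grand = y.mean()
    out = {}
    for name, lvl in (("anatomy", a_lvl), ("electrodes", e_lvl)):
        m1 = y[:, lvl == lvl[0]].mean(axis=1)
        m2 = y[:, lvl != lvl[0]].mean(axis=1)
        effect_means = np.array([m1.mean(), m2.mean()])
        ss_effect = 2 * n * np.sum((effect_means - grand) ** 2)
        # effect x subject interaction = error term
        per_subj = np.column_stack([m1, m2])
        ss_err = 2 * np.sum((per_subj - per_subj.mean(axis=0)
                             - per_subj.mean(axis=1, keepdims=True) + grand) ** 2)
        out[name] = (ss_effect / 1) / (ss_err / (n - 1))
    # interaction: contrast per subject
    sign_a = np.where(a_lvl == a_lvl[0], 1, -1)
    sign_e = np.where(e_lvl == e_lvl[0], 1, -1)
    c = (y * (sign_a * sign_e)).sum(axis=1) / 2
    ss_int = n * c.mean() ** 2
    ss_err = np.sum((c - c.mean()) ** 2)
    out["interaction"] = ss_int / (ss_err / (n - 1))
    return out


class TestZscore:
    def test_unit_moments_per_subject(self, rng):
        df = make_table(rng)
        df["metric"], df["hemisphere"], df["method"] = "m", "L", "dSPM"
        z = zscore_within_subject(df)
        g = z.groupby("subject")["value"]
        np.testing.assert_allclose(g.mean(), 0.0, atol=1e-12)
        np.testing.assert_allclose(g.std(ddof=1), 1.0, rtol=1e-12)

    def test_location_invariance(self, rng):
        df = make_table(rng)
        shifted = df.copy()
        shifted["value"] = df["value"] + df["subject"].map(lambda s: 100.0 * s)
        np.testing.assert_allclose(
            zscore_within_subject(df)["value"].to_numpy(),
            zscore_within_subject(shifted)["value"].to_numpy(),
            atol=1e-9,
        )

    def test_matches_per_subject_loop(self, rng):
        df = make_table(rng, n_subjects=6)
        z = zscore_within_subject(df)
        for s, g in df.groupby("subject"):
            v = g["value"].to_numpy()
            expected = (v - v.mean()) / v.std(ddof=1)
            got = z[z["subject"] == s]["value"].to_numpy()
            np.testing.assert_allclose(got, expected, rtol=1e-12)

    def test_degenerate_subject_flagged_as_zeros(self):
        df = pd.DataFrame(
            dict(subject=[0, 0, 0, 0], anatomy=["t", "t", "i", "i"],
                 electrodes=["t", "i", "t", "i"], value=[2.0, 2.0, 2.0, 2.0])
        )
        z = zscore_within_subject(df)
        assert z["degenerate"].all()
        np.testing.assert_array_equal(z["value"], 0.0)


class TestBoxcox:
    def test_lambda_one_is_affine_shift(self):
        x = np.linspace(1.0, 5.0, 50)
        xs = x  # already positive: no shift
        y = (xs**1.0 - 1.0) / 1.0
        np.testing.assert_allclose(y, x - 1.0)

    def test_recovers_log_for_lognormal(self, rng):
        x = rng.lognormal(0.0, 1.0, size=1000)
        _, lam, shift = boxcox(x)
        assert shift == 0.0
        assert -0.2 <= lam <= 0.2

    def test_mle_beats_log_on_normal_data(self, rng):
        from scipy.stats import boxcox_llf

        x = rng.normal(10.0, 1.0, size=500)
        _, lam, shift = boxcox(x)
        assert boxcox_llf(lam, x + shift) >= boxcox_llf(0.0, x + shift)

    def test_constant_input_skipped(self):
        y, lam, shift = boxcox(np.full(10, 3.0))
        assert lam is None
        np.testing.assert_array_equal(y, 3.0)

    def test_nonpositive_input_shifted_to_min_one(self, rng):
        x = rng.normal(0.0, 1.0, 200)
        y, lam, shift = boxcox(x)
        assert shift == pytest.approx(1.0 - x.min())
        assert np.all(np.isfinite(y))


class TestRmAnova:
    def test_null_data_f_near_zero(self):
        # identical condition means: all effect F exactly 0
        rows = []
        for s in range(6):
            for a, e in itertools.product(LEVELS, LEVELS):
                rows.append(dict(subject=s, anatomy=a, electrodes=e, value=float(s)))
        res = rm_anova_2x2(pd.DataFrame(rows))
        for eff in res.values():
            assert eff["F"] == pytest.approx(0.0, abs=1e-10)

    def test_matches_hand_ss_decomposition(self, rng):
        df = make_table(rng, n_subjects=5, anatomy_effect=1.0)
        res = rm_anova_2x2(df)
        oracle = hand_ss_anova(df)
        for eff in ("anatomy", "electrodes", "interaction"):
            assert res[eff]["F"] == pytest.approx(oracle[eff], rel=1e-6)
        assert res["anatomy"]["F"] > 4 * res["interaction"]["F"]

    def test_subject_label_permutation_invariant(self, rng):
        df = make_table(rng, n_subjects=8, anatomy_effect=0.7)
        perm = dict(zip(range(8), np.random.default_rng(0).permutation(8)))
        shuffled = df.copy()
        shuffled["subject"] = shuffled["subject"].map(perm)
        a = rm_anova_2x2(df)
        b = rm_anova_2x2(shuffled)
        for eff in a:
            assert a[eff]["F"] == pytest.approx(b[eff]["F"], rel=1e-9)

    def test_too_few_subjects_rejected(self, rng):
        df = make_table(rng, n_subjects=2)
        with pytest.raises(InsufficientDataError):
            rm_anova_2x2(df)


class TestAssumptionChecks:
    def test_levene_calibrated_under_null(self, rng):
        ok = 0
        for _ in range(200):
            df = make_table(rng, n_subjects=50)
            if assumption_checks(df)["levene_p"] > 0.05:
                ok += 1
        assert ok >= 180

    def test_levene_detects_heteroscedasticity(self, rng):
        hits = 0
        for _ in range(100):
            df = make_table(rng, n_subjects=50)
            blow = (df["anatomy"] == "template") & (df["electrodes"] == "template")
            df.loc[blow, "value"] *= 10
            if assumption_checks(df)["levene_p"] < 0.05:
                hits += 1
        assert hits >= 90

    def test_normal_residuals_not_rejected(self, rng):
        df = make_table(rng, n_subjects=40)
        checks = assumption_checks(df)
        assert checks["normality_p"] > 0.01


class TestArtFallback:
    def test_true_effect_survives_monotone_transform(self, rng):
        # alignment uses means, so invariance is approximate: the genuine
        # effect must stay dominant and significant after a monotone warp
        df = make_table(rng, n_subjects=12, anatomy_effect=1.5)
        res1 = art_anova_fallback(df)
        warped = df.copy()
        warped["value"] = np.exp(df["value"] / 2.0)  # monotone map
        res2 = art_anova_fallback(warped)
        for res in (res1, res2):
            assert res["anatomy"]["F"] > res["electrodes"]["F"]
            assert res["anatomy"]["F"] > res["interaction"]["F"]
            assert res["anatomy"]["p"] < 0.05

    def test_null_type_one_error_calibrated(self, rng):
        # rejection rate at alpha = 0.05 over 500 null simulations
        rejections = {"anatomy": 0, "electrodes": 0, "interaction": 0}
        n_sim = 500
        for _ in range(n_sim):
            df = make_table(rng, n_subjects=8)
            res = art_anova_fallback(df)
            for eff in rejections:
                rejections[eff] += res[eff]["p"] < 0.05
        for eff, count in rejections.items():
            assert 0.02 <= count / n_sim <= 0.08, (eff, count / n_sim)

    def test_wilcoxon_on_identical_pairs_is_one(self):
        rows = []
        for s in range(6):
            for a, e in itertools.product(LEVELS, LEVELS):
                rows.append(dict(subject=s, anatomy=a, electrodes=e, value=float(s)))
        res = art_anova_fallback(pd.DataFrame(rows))
        assert all(p == 1.0 for p in res["wilcoxon_posthoc"].values())


@pytest.fixture(scope="module")
def small_cohort():
    return simulate_cohort(
        CohortSpec(n_subjects=4, n_trials=30, n_vertices=400, master_seed=11)
    )


@pytest.fixture(scope="module")
def table(small_cohort):
    return run_design(small_cohort, methods=("dSPM",))


class TestPipeline:
    def test_record_bookkeeping(self, table):
        # 4 subjects x 4 conditions x 1 method x 2 hemispheres x 7 metrics
        assert len(table) == 4 * 4 * 2 * 7
        assert set(table["metric"]) == set(experiment.METRIC_NAMES)
        assert set(table["anatomy"]) == set(LEVELS)

    def test_rerun_configuration_deterministic(self, small_cohort, table):
        rec = run_configuration(small_cohort.subjects[0], "template", "individual", "dSPM")
        sub = table[
            (table.subject == 0) & (table.anatomy == "template")
            & (table.electrodes == "individual") & (table.method == "dSPM")
        ]
        merged = sub.merge(
            pd.DataFrame(rec), on=["subject", "hemisphere", "metric"], suffixes=("", "_b")
        )
        valid = ~merged["missing"]
        np.testing.assert_allclose(
            merged.loc[valid, "value"].astype(float),
            merged.loc[valid, "value_b"].astype(float),
            rtol=1e-10,
        )

    def test_statistics_pipeline_runs_and_logs_exclusions(self, table):
        effects, exclusions = run_statistics(table)
        assert {"metric", "effect", "branch", "F", "p"} <= set(effects.columns)
        for exc in exclusions:
            assert {"metric", "subject", "reason"} <= set(exc)
        # every analyzed slice reports all three effects
        counts = effects.groupby(["metric", "hemisphere", "method"]).size()
        assert (counts == 3).all()

    def test_effect_sizes_only_on_parametric_branch(self, table):
        effects, _ = run_statistics(table)
        art = effects[effects["branch"] == "aligned-rank"]
        assert art["np2"].isna().all()

    def test_paired_test_shapes(self, table):
        res = paired_individualization_test(table, "loc_error", "dSPM", better="lower")
        assert 0 <= res["p"] <= 1
        assert res["n"] <= 4


def test_zero_perturbation_configurations_identical():
    """With no anatomy or montage perturbation, all four configurations are the
    same forward model, so paired contrasts are exactly null."""
    from pacsim.geometry import PerturbationProfile

    spec = CohortSpec(
        n_subjects=3, n_trials=20, n_vertices=300, master_seed=21,
        perturbation=PerturbationProfile(mean_displacement=0.0, between_subject_sd=0.0),
        anatomy_scale_sd=0.0, anatomy_center_offset=0.0,
    )
    cohort = simulate_cohort(spec)
    table = run_design(cohort, methods=("dSPM",))
    res = paired_individualization_test(table, "loc_error", "dSPM", better="lower")
    assert res["mean_difference"] == pytest.approx(0.0, abs=1e-12)
    assert res["p"] == 1.0
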