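"""Mixed-model fitting, Kenward-Roger tests and Tukey comparisons.

The ``kr_fixture`` expectations were computed with an independent
mixed-model stack (lme4 1.1-37 REML fits, type-III Kenward-Roger F-tests,
and Tukey-adjusted estimated-marginal-mean contrasts with Kenward-Roger
degrees of freedom) on the identical table and frozen here.
"""

import numpy as np
import pandas as pd
import pytest

from whiskkin import mixed_stats as ms
from whiskkin import synthetic_data as sd
from whiskkin.mixed_stats import LmmSpec, SingularDesignError, fit_lmm, tukey_pairwise


@pytest.fixture(scope="module")
def toy_two_group() -> pd.DataFrame:
    """Two groups of three animals, one clip each: an OLS-equivalent design."""
    return pd.DataFrame(
        {
            "y": [1.0, 2.0, 3.0, 3.0, 4.0, 5.0],
            "treatment": ["MIA"] * 3 + ["control"] * 3,
            "animal_id": [f"a{i}" for i in range(6)],
        }
    )


def test_one_clip_per_animal_reduces_to_classical_anova(toy_two_group):
    """Group means 2 vs 4, MSW = 1: one-way ANOVA gives F = 6 on (1, 4) df."""
    fit = fit_lmm(toy_two_group, LmmSpec("y", ("treatment",)))
    assert fit.ols_equivalent
    tt = fit.tests["treatment"]
    assert tt.f_stat == pytest.approx(6.0, abs=1e-6)
    assert tt.df1 == 1
    assert tt.df2 == pytest.approx(4.0, abs=1e-6)
    assert tt.p_value == pytest.approx(0.0705, abs=2e-4)


def test_constant_response_gives_zero_f(toy_two_group):
    flat = toy_two_group.assign(y=2.5)
    fit = fit_lmm(flat, LmmSpec("y", ("treatment",)))
    assert fit.tests["treatment"].f_stat == pytest.approx(0.0, abs=1e-10)


def test_balanced_one_clip_design_matches_ols_oracle():
    """With one clip per animal the KR machinery must equal plain ANOVA."""
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    rng = np.random.default_rng(1)
    df = pd.DataFrame(
        {
            "y": rng.normal(size=24),
            "treatment": np.repeat(["MIA", "control"], 12),
            "object_texture": np.tile(np.repeat(["smooth", "textured"], 6), 2),
            "animal_id": [f"a{i}" for i in range(24)],
        }
    )
    fit = fit_lmm(df, LmmSpec("y", ("treatment", "object_texture")))
    ref = sm.stats.anova_lm(
        ols("y ~ C(treatment, Sum) * C(object_texture, Sum)", df).fit(), typ=3
    )
    for term, ref_row in (
        ("treatment", "C(treatment, Sum)"),
        ("object_texture", "C(object_texture, Sum)"),
        ("treatment:object_texture", "C(treatment, Sum):C(object_texture, Sum)"),
    ):
        tt = fit.tests[term]
        assert tt.f_stat == pytest.approx(ref.loc[ref_row, "F"], rel=1e-8)
        assert tt.df2 == pytest.approx(20.0)
        assert tt.p_value == pytest.approx(ref.loc[ref_row, "PR(>F)"], rel=1e-8)


def test_singular_design_raises_naming_problem(toy_two_group):
    df = toy_two_group.assign(object_texture="smooth")  # one-level factor
    with pytest.raises(Exception, match="(?i)levels|rank|aliased"):
        fit_lmm(df, LmmSpec("y", ("treatment", "object_texture")))


# --- Kenward-Roger against the independent reference ----------------------

KR_REFERENCE = {
    "sigma2_animal": 0.59327,
    "sigma2_resid": 1.23623,
    "tests": {
        "treatment": (1.11256, 7.74725, 0.32331),
        "object_texture": (0.87203, 16.95766, 0.36350),
        "treatment:object_texture": (0.02773, 16.95766, 0.86970),
    },
    # (|estimate|, SE, KR df, Tukey p) keyed by unordered cell pair
    "tukey": {
        ("MIA:smooth", "MIA:textured"): (0.33469, 0.58028, 16.485, 0.93765),
        ("MIA:smooth", "control:smooth"): (0.77779, 0.75094, 12.448, 0.73242),
        ("MIA:smooth", "control:textured"): (0.29781, 0.82905, 15.332, 0.98352),
        ("MIA:textured", "control:smooth"): (1.11248, 0.76620, 13.281, 0.49116),
        ("MIA:textured", "control:textured"): (0.63250, 0.84290, 16.040, 0.87518),
        ("control:smooth", "control:textured"): (0.47997, 0.65142, 17.340, 0.88095),
    },
}


@pytest.fixture(scope="module")
def kr_fit(kr_fixture):
    return fit_lmm(kr_fixture, LmmSpec("y", ("treatment", "object_texture")))


def test_reml_variance_components_match_reference(kr_fit):
    assert kr_fit.sigma2_animal == pytest.approx(KR_REFERENCE["sigma2_animal"], rel=1e-4)
    assert kr_fit.sigma2_resid == pytest.approx(KR_REFERENCE["sigma2_resid"], rel=1e-4)
    assert not kr_fit.boundary and not kr_fit.ols_equivalent


def test_kr_f_tests_match_reference(kr_fit):
    for term, (f_ref, df2_ref, p_ref) in KR_REFERENCE["tests"].items():
        tt = kr_fit.tests[term]
        assert tt.method == "KR"
        assert tt.f_stat == pytest.approx(f_ref, abs=2e-5)
        assert tt.df2 == pytest.approx(df2_ref, abs=2e-4)
        assert tt.p_value == pytest.approx(p_ref, abs=2e-5)


def test_reml_fit_matches_statsmodels_mixedlm(kr_fixture):
    """Independent REML cross-check of variance components and coefficients."""
    import statsmodels.formula.api as smf

    ref = smf.mixedlm(
        "y ~ C(treatment, Sum) * C(object_texture, Sum)",
        kr_fixture,
        groups=kr_fixture["animal_id"],
    ).fit(reml=True)
    fit = fit_lmm(kr_fixture, LmmSpec("y", ("treatment", "object_texture")))
    assert fit.sigma2_resid == pytest.approx(ref.scale, rel=1e-5)
    assert fit.sigma2_animal == pytest.approx(
        float(ref.cov_re.iloc[0, 0]), rel=1e-4
    )
    np.testing.assert_allclose(fit.beta, ref.fe_params.to_numpy(), rtol=1e-6)


def test_tukey_contrasts_match_reference(kr_fit):
    comps = tukey_pairwise(kr_fit)
    assert len(comps) == 6  # 4 cells -> k(k-1)/2 contrasts
    assert all(c.family_size == 4 for c in comps)

    def key(label_half):
        parts = dict(p.split("=") for p in label_half.split(","))
        return f"{parts['treatment']}:{parts['object_texture']}"

    for c in comps:
        a, b = (key(h) for h in c.contrast.split(" - "))
        ref = KR_REFERENCE["tukey"].get((a, b)) or KR_REFERENCE["tukey"][(b, a)]
        est_ref, se_ref, df_ref, p_ref = ref
        assert abs(c.estimate) == pytest.approx(est_ref, abs=1e-4)
        assert c.se == pytest.approx(se_ref, abs=1e-4)
        assert c.df == pytest.approx(df_ref, abs=2e-3)
        assert c.p_tukey == pytest.approx(p_ref, abs=1e-4)


def test_tukey_adjustment_never_decreases_p(kr_fit):
    for c in tukey_pairwise(kr_fit):
        assert c.p_raw - 1e-12 <= c.p_tukey <= 1.0


def test_tukey_family_of_two_equals_raw_p(toy_two_group):
    fit = fit_lmm(toy_two_group, LmmSpec("y", ("treatment",)))
    comps = tukey_pairwise(fit)
    assert len(comps) == 1
    assert comps[0].p_tukey == pytest.approx(comps[0].p_raw, rel=1e-9)


def test_kr_df_between_animal_and_clip_bounds(small_cohort):
    """KR denominator df must fall between animals - rank and clips - rank."""
    from whiskkin import kinematics

    metrics = kinematics.metrics_table(small_cohort.traces, small_cohort.metadata)
    fem = metrics[metrics["sex"] == "female"]
    fit = fit_lmm(fem, LmmSpec("delta_mean_angle", ("treatment", "object_texture")))
    lo = fit.n_groups - fit.rank
    hi = fit.n_obs - fit.rank
    for tt in fit.tests.values():
        assert lo - 1e-6 <= tt.df2 <= hi + 1e-6


# --- analysis suite --------------------------------------------------------


@pytest.fixture(scope="module")
def null_metrics():
    cfg = sd.SyntheticConfig(
        animals_per_cell={
            ("MIA", "female"): 6,
            ("MIA", "male"): 6,
            ("control", "female"): 6,
            ("control", "male"): 6,
        },
        clips_per_animal=(2, 3),
        pc_frames=(100, 140),
        dc_frames=(100, 160),
    )
    return sd.simulate_metrics_table(cfg, seed=21)


def test_analysis_suite_structure_on_null_cohort(null_metrics):
    report = ms.analysis_suite(null_metrics)
    combined = report.models[report.models["stage"] == "combined"]
    stratified = report.models[report.models["stage"] == "stratified"]
    assert combined[["response"]].drop_duplicates().shape[0] == 12
    assert stratified[["stratum", "response"]].drop_duplicates().shape[0] == 24
    assert set(combined["term"]) == {"treatment", "sex", "treatment:sex"}
    # post-hoc sections exist exactly where a stage-2 interaction clears alpha
    inter = stratified[stratified["term"] == "treatment:object_texture"]
    expected = set(
        map(tuple, inter.loc[inter["p"] < report.alpha, ["stratum", "response"]].values)
    )
    got = (
        set(map(tuple, report.posthoc[["stratum", "response"]].drop_duplicates().values))
        if len(report.posthoc)
        else set()
    )
    assert got == expected


def test_analysis_suite_alpha_one_emits_all_posthocs(null_metrics):
    report = ms.analysis_suite(null_metrics, alpha=1.0)
    sections = report.posthoc[["stratum", "response"]].drop_duplicates()
    assert len(sections) == 24
    assert len(report.posthoc) == 24 * 6


def test_analysis_suite_survives_single_model_failure(null_metrics):
    broken = null_metrics.copy()
    broken["delta_spread"] = np.nan  # one response entirely missing
    report = ms.analysis_suite(broken)
    assert len(report.errors) >= 1
    assert (report.errors["response"] == "delta_spread").all()
    remaining = report.models[["stage", "stratum", "response"]].drop_duplicates()
    assert len(remaining) == 12 + 24 - 3
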