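"""Statistical battery: rank tests against enumeration/permutation oracles,
cluster-robust regression identities, coefficient comparison calibration."""

import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.stats as sps

from actipair.stats import (
    MEASURE_PAIRS,
    TIERS,
    activity_correlations,
    battery_to_frame,
    compare_coefficients,
    fit_bmi_model,
    fit_model_battery,
    paired_comparison_suite,
    run_sensitivity,
    spearman,
    trend_test,
    wilcoxon_signed_rank,
)


# --- Spearman ---------------------------------------------------------------

def test_spearman_perfect_monotone():
    x = [1, 2, 5, 9, 11]
    assert spearman(x, x)[0] == pytest.approx(1.0)
    assert spearman(x, [-v for v in x])[0] == pytest.approx(-1.0)


def test_spearman_ties_match_rank_then_pearson(rng):
    x = rng.integers(0, 5, 8).astype(float)
    y = rng.integers(0, 5, 8).astype(float)
    y[0] += 0.5  # avoid fully constant
    r, _ = spearman(x, y)
    oracle = np.corrcoef(sps.rankdata(x), sps.rankdata(y))[0, 1]
    assert r == pytest.approx(oracle)


def test_spearman_invariant_under_monotone_transform(rng):
    x = rng.normal(0, 1, 50)
    y = rng.normal(0, 1, 50)
    r1, _ = spearman(x, y)
    r2, _ = spearman(np.exp(x), y**3)
    assert r1 == pytest.approx(r2)


def test_spearman_constant_input_errors():
    with pytest.raises(ValueError, match="constant"):
        spearman([1, 1, 1, 1], [1, 2, 3, 4])
    with pytest.raises(ValueError, match="3 complete pairs"):
        spearman([1, 2], [3, 4])


# --- Wilcoxon ---------------------------------------------------------------

def enumerate_wilcoxon_p(d):
    """Exact two-sided p by full 2^n enumeration of sign assignments."""
    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    ranks = sps.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = np.array(
        [
            sum(r for r, s in zip(ranks, signs) if s)
            for signs in itertools.product([0, 1], repeat=d.size)
        ]
    )
    return min(1.0, 2 * min((ws <= w_obs + 1e-9).mean(), (ws >= w_obs - 1e-9).mean()))


def test_wilcoxon_three_identical_differences():
    # all differences +1: most extreme of the 2^3 assignments, p = 2/8
    _, p = wilcoxon_signed_rank([1, 2, 3], [2, 3, 4])
    assert p == pytest.approx(0.25)


def test_wilcoxon_symmetric_differences_at_null_center():
    w, p = wilcoxon_signed_rank([1, -1, 2, -2], [0, 0, 0, 0])
    n = 4
    assert w == pytest.approx(n * (n + 1) / 4)
    assert p == pytest.approx(1.0)


def test_wilcoxon_exact_matches_enumeration(rng):
    for _ in range(25):
        n = int(rng.integers(3, 11))
        x = rng.integers(0, 6, n).astype(float)
        y = rng.integers(0, 6, n).astype(float)
        if np.all(x == y):
            continue
        _, p = wilcoxon_signed_rank(x, y)
        assert p == pytest.approx(enumerate_wilcoxon_p(x - y))


def test_wilcoxon_large_sample_matches_scipy_normal_approx(rng):
    x = rng.normal(0.3, 1, 80)
    y = rng.normal(0.0, 1, 80)
    _, p = wilcoxon_signed_rank(x, y)
    p_scipy = sps.wilcoxon(x, y, correction=False, method="approx").pvalue
    assert p == pytest.approx(p_scipy, rel=1e-6)


def test_wilcoxon_all_zero_differences_errors():
    with pytest.raises(ValueError, match="zero"):
        wilcoxon_signed_rank([1, 2], [1, 2])


# --- trend test -------------------------------------------------------------

def test_trend_two_groups_equals_rank_sum(rng):
    x = rng.normal(0, 1, 40)
    g = np.array([0] * 18 + [1] * 22)
    res = trend_test(x, g)
    z_rs = sps.ranksums(x[g == 1], x[g == 0]).statistic
    assert res.z**2 == pytest.approx(z_rs**2, rel=1e-9)


def test_trend_matches_permutation_p(rng):
    vals = np.concatenate(
        [rng.normal(0, 1, 15), rng.normal(0.4, 1, 15), rng.normal(0.8, 1, 15)]
    )
    grp = np.repeat([1, 2, 3], 15)
    res = trend_test(vals, grp)
    ranks = sps.rankdata(vals)
    li = grp.astype(float)
    t_obs = float(li @ ranks)
    perm = np.array([rng.permutation(li) @ ranks for _ in range(10_000)])
    p_perm = 2 * sps.norm.sf(abs((t_obs - perm.mean()) / perm.std()))
    assert res.p_value == pytest.approx(p_perm, abs=0.01)


def test_trend_null_is_calm(rng):
    vals = rng.normal(0, 1, 90)
    grp = np.repeat([1, 2, 3], 30)
    res = trend_test(vals, grp)
    assert abs(res.z) < 3


def test_trend_detects_monotone_signal(rng):
    vals = np.concatenate([np.full(30, 25.0), np.full(30, 27.0), np.full(30, 29.0)])
    vals += rng.normal(0, 0.1, 90)
    res = trend_test(vals, np.repeat([1, 2, 3], 30))
    assert res.p_value < 1e-10
    assert res.group_n == [30, 30, 30]
    assert sum(res.group_n) == 90


def test_trend_single_group_errors():
    with pytest.raises(ValueError):
        trend_test([1.0, 2.0, 3.0], [1, 1, 1])


# --- regressions ------------------------------------------------------------

def toy_frame(rng, n=120, clusters=None, noise=2.0, beta=-0.5):
    t = rng.lognormal(1, 0.5, n)
    pid = np.arange(n) if clusters is None else clusters
    return pd.DataFrame(
        {
            "participant_id": pid,
            "bmi": 25 + beta * t + rng.normal(0, noise, n),
            "x": t,
            "wear_time": rng.normal(16, 1, n),
            "device_location": "wrist",
            "season": "fall",
        }
    )


def test_zero_noise_fit_is_exact(rng):
    df = toy_frame(rng, noise=0.0)
    m = fit_bmi_model(df, "x", tier="base")
    assert m.coefficient("x") == pytest.approx(-0.5, abs=1e-10)
    assert float(m.bse["x"]) == pytest.approx(0.0, abs=1e-8)


def test_singleton_clusters_equal_hc1(rng):
    import statsmodels.api as sm

    df = toy_frame(rng)
    m = fit_bmi_model(df, "x", tier="base")
    X = sm.add_constant(np.column_stack([df.x, df.wear_time]))
    ref = sm.OLS(df.bmi, X).fit(cov_type="HC1")
    assert m.coefficient("x") == pytest.approx(ref.params.iloc[1])
    assert float(m.bse["x"]) == pytest.approx(ref.bse.iloc[1], rel=1e-10)


def test_cluster_correction_factor_matches_formula(rng):
    """The sandwich applies G/(G-1) * (N-1)/(N-K) to the uncorrected meat."""
    df = toy_frame(rng, n=90, clusters=np.repeat(np.arange(30), 3))
    m = fit_bmi_model(df, "x", tier="base")
    X = np.column_stack(
        [np.ones(len(df)), df.x, df.wear_time]
    )
    y = df.bmi.to_numpy()
    xtx_inv = np.linalg.inv(X.T @ X)
    resid = y - X @ xtx_inv @ X.T @ y
    meat = np.zeros((3, 3))
    for g in range(30):
        xg = (X[g * 3 : g * 3 + 3] * resid[g * 3 : g * 3 + 3, None]).sum(axis=0)
        meat += np.outer(xg, xg)
    G, N, K = 30, 90, 3
    cov = (G / (G - 1)) * ((N - 1) / (N - K)) * xtx_inv @ meat @ xtx_inv
    # column order in the fitted model: const, x, wear_time
    assert float(m.bse["x"]) == pytest.approx(np.sqrt(cov[1, 1]), rel=1e-9)


def test_standardized_and_natural_units_share_t_statistics(rng):
    df = toy_frame(rng)
    mn = fit_bmi_model(df, "x", tier="base", unit_mode="natural")
    ms = fit_bmi_model(df, "x", tier="base", unit_mode="standardized")
    t_n = mn.coefficient("x") / float(mn.bse["x"])
    t_s = ms.coefficient("x") / float(ms.bse["x"])
    assert t_n == pytest.approx(t_s, rel=1e-9)
    assert ms.coefficient("x") == pytest.approx(
        mn.coefficient("x") * ms.predictor_sds["x"], rel=1e-9
    )
    assert mn.pvalues["x"] == pytest.approx(ms.pvalues["x"], rel=1e-9)


def test_confidence_interval_uses_normal_critical_value(rng):
    df = toy_frame(rng)
    m = fit_bmi_model(df, "x", tier="base")
    lo, hi = m.conf_int.loc["x"]
    assert hi - lo == pytest.approx(2 * 1.959963984540054 * float(m.bse["x"]), rel=1e-9)


def test_rank_deficiency_names_columns(rng):
    df = toy_frame(rng)
    df["x_copy"] = df["x"]
    with pytest.raises(ValueError, match="x_copy|x"):
        fit_bmi_model(df, ["x", "x_copy"], tier="base")


def test_unknown_tier_rejected(rng):
    with pytest.raises(ValueError, match="tier"):
        fit_bmi_model(toy_frame(rng), "x", tier="everything")


# --- coefficient comparison -------------------------------------------------

def test_model_compared_with_itself_is_null(rng):
    df = toy_frame(rng)
    m1 = fit_bmi_model(df, "x", tier="base")
    m2 = fit_bmi_model(df, "x", tier="base")
    cc = compare_coefficients(m1, m2, "x", "x")
    assert cc.difference == pytest.approx(0.0, abs=1e-9)
    assert cc.p_value == pytest.approx(1.0, abs=1e-4)


def test_stacked_point_estimates_equal_separate_fits(rng):
    df = toy_frame(rng, clusters=np.repeat(np.arange(40), 3))
    df["x2"] = df["x"] + rng.normal(0, 1, len(df))
    ma = fit_bmi_model(df, "x", tier="base")
    mb = fit_bmi_model(df, "x2", tier="base")
    cc = compare_coefficients(ma, mb, "x", "x2")
    assert cc.fitbit_beta == pytest.approx(ma.coefficient("x"), rel=1e-10)
    assert cc.ipaq_beta == pytest.approx(mb.coefficient("x2"), rel=1e-10)


def test_stacked_se_matches_cluster_bootstrap(rng):
    """The stacked-system SE of the coefficient difference agrees with a
    cluster bootstrap on a small clustered cohort."""
    pids = np.repeat(np.arange(60), rng.integers(1, 3, 60))
    n = pids.size
    u = rng.normal(0, 1.5, 60)[pids]
    t = rng.lognormal(2, 0.5, n)
    df = pd.DataFrame(
        {
            "participant_id": pids,
            "bmi": 25 - 0.3 * t + u + rng.normal(0, 2, n),
            "x1": t + rng.normal(0, 1, n),
            "x2": t + rng.normal(0, 3, n),
            "wear_time": rng.normal(16, 1, n),
            "device_location": "wrist",
            "season": "fall",
        }
    )
    ma = fit_bmi_model(df, "x1", tier="base")
    mb = fit_bmi_model(df, "x2", tier="base")
    cc = compare_coefficients(ma, mb, "x1", "x2")
    se_stacked = abs(cc.difference) / np.sqrt(cc.wald_statistic)
    clusters = df.participant_id.unique()
    diffs = []
    for _ in range(300):
        pick = rng.choice(clusters, size=clusters.size, replace=True)
        parts = [
            df[df.participant_id == c].assign(participant_id=f"b{j}")
            for j, c in enumerate(pick)
        ]
        dfb = pd.concat(parts)
        a = fit_bmi_model(dfb, "x1", tier="base")
        b = fit_bmi_model(dfb, "x2", tier="base")
        diffs.append(a.coefficient("x1") - b.coefficient("x2"))
    se_boot = np.std(diffs)
    assert 0.7 < se_stacked / se_boot < 1.4


def test_comparison_type_one_error_calibrated(rng):
    """Equal true effects and equal predictor noise: the stacked Wald test
    rejects at about the nominal 5% rate (1000 replicates)."""
    rej = 0
    reps = 1000
    for _ in range(reps):
        n = 150
        t = rng.lognormal(1, 0.6, n)
        df = pd.DataFrame(
            {
                "participant_id": np.arange(n),
                "bmi": 25 - 0.4 * t + rng.normal(0, 2, n),
                "x1": t + rng.normal(0, 1, n),
                "x2": t + rng.normal(0, 1, n),
                "wear_time": rng.normal(16, 1, n),
                "device_location": "wrist",
                "season": "fall",
            }
        )
        ma = fit_bmi_model(df, "x1", tier="base")
        mb = fit_bmi_model(df, "x2", tier="base")
        if compare_coefficients(ma, mb, "x1", "x2").p_value < 0.05:
            rej += 1
    assert 0.03 <= rej / reps <= 0.07


def test_comparison_requires_same_observations(rng):
    df = toy_frame(rng)
    ma = fit_bmi_model(df, "x", tier="base")
    mb = fit_bmi_model(df.iloc[:-5], "x", tier="base")
    with pytest.raises(ValueError, match="same observations"):
        compare_coefficients(ma, mb, "x", "x")


# --- battery and sensitivity ------------------------------------------------

@pytest.fixture(scope="module")
def cohort_frame():
    from actipair.simulate import GeneratorConfig, generate_weekly_cohort

    return generate_weekly_cohort(GeneratorConfig(n_participants=250), seed=77)


def test_battery_cardinality(cohort_frame):
    fams = fit_model_battery(cohort_frame)
    assert len(fams) == len(MEASURE_PAIRS) * len(TIERS)  # 6 x 3
    per_tier = {}
    for f in fams:
        per_tier.setdefault(f.tier, []).append(f)
    for tier, fs in per_tier.items():
        assert len(fs) == 6
        # 12 separate + 6 combined models per tier
        assert sum(1 for f in fs for _ in (f.fitbit_model, f.ipaq_model)) == 12
        assert sum(1 for f in fs) == 6
    frame = battery_to_frame(fams)
    # 6 families x 3 tiers x (1 + 1 + 2 predictor rows)
    assert frame.shape[0] == 6 * 3 * 4


def test_combined_duplicate_predictor_is_rank_deficient(cohort_frame):
    df = cohort_frame.copy()
    df["ipaq_active_h"] = df["fitbit_active_h"]
    with pytest.raises(ValueError, match="rank deficient"):
        fit_bmi_model(df, ["fitbit_active_h", "ipaq_active_h"], tier="base")


def test_correlation_and_paired_suites_cover_all_pairs(cohort_frame):
    first = cohort_frame[cohort_frame.observation_rank == 1]
    corr = activity_correlations(first)
    assert list(corr["variable"]) == [v for v, _, _ in MEASURE_PAIRS]
    assert corr["spearman_r"].between(-1, 1).all()
    paired = paired_comparison_suite(first)
    assert len(paired) == 5  # overall pair excluded (different scales)
    # the generator's recall biases push self-report below device for walking
    walk = paired.set_index("variable").loc["walking"]
    assert walk["ipaq_median"] < walk["fitbit_median"]


def test_sensitivity_excludes_expected_counts(cohort_frame):
    res = run_sensitivity(cohort_frame, "torso", tiers=("base",))
    n_torso = int((cohort_frame.device_location == "torso").sum())
    assert res.n_excluded == n_torso
    assert res.fraction_excluded == pytest.approx(n_torso / len(cohort_frame))
    assert len(res.battery) == 6

    none_flagged = cohort_frame[cohort_frame.data_source != "mobiletrack"]
    res2 = run_sensitivity(none_flagged, "mobiletrack", tiers=("base",))
    assert res2.n_excluded == 0
    # identical to the main analysis when nothing is excluded
    main = activity_correlations(none_flagged)
    pd.testing.assert_frame_equal(res2.correlations, main)


def test_sensitivity_all_rows_flagged_errors(cohort_frame):
    df = cohort_frame.copy()
    df["data_source"] = "mobiletrack"
    with pytest.raises(ValueError, match="every observation"):
        run_sensitivity(df, "mobiletrack")
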