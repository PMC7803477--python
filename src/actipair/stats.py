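"""Comparative statistics for paired device / self-report activity and BMI.

Implements the analysis battery: Spearman rank correlations and Wilcoxon
matched-pairs signed-rank tests for agreement between the two measurement
modes, a Cuzick-type nonparametric trend test across ordered activity
categories, least-squares BMI regressions with cluster-robust (sandwich)
standard errors grouped by participant, Wald comparisons of device versus
self-report coefficients (within combined models, or across separate models
via a stacked-system fit sharing the participant-level cluster covariance),
and exclusion-based sensitivity reruns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as sps
import statsmodels.api as sm

BASE_COVARIATES = ["wear_time", "device_location", "season"]
DEMOGRAPHICS = ["age", "gender", "education", "income", "race", "ethnicity"]
BEHAVIORS = ["smoking", "alcohol_drinks_wk"]
CLINICAL = ["coronary_artery_disease", "diabetes", "hyperlipidemia", "hypertension"]

#: cumulative adjustment tiers
TIERS = {
    "base": [],
    "demographics": DEMOGRAPHICS,
    "full": DEMOGRAPHICS + BEHAVIORS + CLINICAL,
}

#: the six analogous device / self-report predictor pairs
MEASURE_PAIRS = [
    ("sedentary", "fitbit_sedentary_h", "ipaq_sedentary_h"),
    ("walking", "fitbit_walking_h", "ipaq_walking_h"),
    ("moderate", "fitbit_moderate_h", "ipaq_moderate_h"),
    ("vigorous", "fitbit_vigorous_h", "ipaq_vigorous_h"),
    ("active", "fitbit_active_h", "ipaq_active_h"),
    ("overall", "fitbit_steps_per_day", "ipaq_met_h"),
]

Z95 = 1.959963984540054  # normal 97.5th percentile


# ---------------------------------------------------------------------------
# Nonparametric agreement and bivariate tests
# ---------------------------------------------------------------------------

def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with average ranks for ties; p-value from
    the large-sample t approximation.  Requires >= 3 complete pairs and
    non-constant inputs."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValueError(f"need at least 3 complete pairs, got {x.size}")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("correlation undefined for constant input")
    r, p = sps.spearmanr(x, y)
    return float(r), float(p)


def wilcoxon_signed_rank(x, y) -> tuple[float, float]:
    """Wilcoxon matched-pairs signed-rank test.

    Zero differences are dropped and tied absolute differences midranked.
    For n <= 25 retained pairs the two-sided p-value is exact, computed from
    the full null distribution of the positive-rank sum (every sign
    assignment equally likely); beyond that a normal approximation with tie
    correction is used.  Returns ``(W_plus, p)``.
    """
    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    d = d[np.isfinite(d)]
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise ValueError("all differences are zero; test degenerate")
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())

    if n <= 25:
        # exact distribution of W+ via subset-sum DP on doubled (integer) ranks
        r2 = np.rint(2 * ranks).astype(int)
        total = int(r2.sum())
        dist = np.zeros(total + 1)
        dist[0] = 1.0
        for r in r2:
            dist[r:] += dist[: total + 1 - r]
        dist /= dist.sum()
        w2 = int(round(2 * w_plus))
        cdf = dist[: w2 + 1].sum()
        sf = dist[w2:].sum()
        p = min(1.0, 2.0 * min(cdf, sf))
        return w_plus, float(p)

    mean = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    _, counts = np.unique(ranks, return_counts=True)
    var -= (counts**3 - counts).sum() / 48.0
    z = (w_plus - mean) / np.sqrt(var)
    return w_plus, float(2 * sps.norm.sf(abs(z)))


@dataclass
class TrendTestResult:
    """Cuzick-type trend test across ordered groups."""

    group_labels: list
    group_n: list[int]
    group_mean: list[float]
    group_sd: list[float]
    z: float
    p_value: float


def trend_test(values, groups) -> TrendTestResult:
    """Nonparametric test for trend across ordered categories (Cuzick's
    rank test with equally spaced group scores and a tie correction).

    ``groups`` may be any orderable labels, or a pandas ``Categorical``
    whose declared order is respected.  With two groups the statistic
    reduces to the Wilcoxon rank-sum z.
    """
    values = np.asarray(values, dtype=float)
    if isinstance(groups, pd.Categorical):
        order = [g for g in groups.categories if (groups == g).any()]
        glab = np.asarray(groups)
    else:
        glab = np.asarray(groups)
        order = sorted(set(glab.tolist()))
    keep = np.isfinite(values)
    values, glab = values[keep], glab[keep]
    order = [g for g in order if (glab == g).any()]
    if len(order) < 2:
        raise ValueError("trend test needs at least 2 nonempty ordered groups")

    n_total = values.size
    ranks = sps.rankdata(values)
    scores = {g: i + 1 for i, g in enumerate(order)}
    li = np.array([scores[g] for g in glab], dtype=float)
    t_stat = float((li * ranks).sum())

    n_g = np.array([(glab == g).sum() for g in order], dtype=float)
    l_g = np.arange(1, len(order) + 1, dtype=float)
    sum_nl = float((n_g * l_g).sum())
    sum_nl2 = float((n_g * l_g**2).sum())
    e_t = (n_total + 1) / 2.0 * sum_nl
    var_t = (n_total + 1) / 12.0 * (n_total * sum_nl2 - sum_nl**2)
    _, counts = np.unique(values, return_counts=True)
    tie_factor = 1.0 - (counts**3 - counts).sum() / (n_total**3 - n_total)
    var_t *= tie_factor
    z = (t_stat - e_t) / np.sqrt(var_t)
    p = float(2 * sps.norm.sf(abs(z)))
    return TrendTestResult(
        group_labels=list(order),
        group_n=[int((glab == g).sum()) for g in order],
        group_mean=[float(values[glab == g].mean()) for g in order],
        group_sd=[float(values[glab == g].std(ddof=1)) if (glab == g).sum() > 1 else float("nan") for g in order],
        z=float(z),
        p_value=p,
    )


# ---------------------------------------------------------------------------
# Cluster-robust BMI regressions
# ---------------------------------------------------------------------------

_CATEGORICAL = {
    "device_location",
    "season",
    "gender",
    "education",
    "income",
    "race",
    "ethnicity",
    "smoking",
}


def _design_matrix(df: pd.DataFrame, columns: list[str]) -> pd.DataFrame:
    """Build a numeric design matrix: categorical columns become dummy
    indicators (first level dropped), booleans become 0/1, numerics pass
    through.  Column order follows ``columns``."""
    parts = [pd.Series(1.0, index=df.index, name="const")]
    for col in columns:
        s = df[col]
        if col in _CATEGORICAL or s.dtype == object or isinstance(
            s.dtype, pd.CategoricalDtype
        ):
            dummies = pd.get_dummies(s.astype(str), prefix=col, drop_first=True)
            parts.append(dummies.astype(float))
        else:
            parts.append(s.astype(float))
    return pd.concat(parts, axis=1)


def _check_full_rank(X: pd.DataFrame) -> None:
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # identify columns whose removal restores full rank
        guilty = []
        for col in X.columns:
            if col == "const":
                continue
            sub = X.drop(columns=[col])
            if np.linalg.matrix_rank(sub.to_numpy()) == rank:
                guilty.append(col)
        raise ValueError(f"design matrix is rank deficient; collinear columns: {guilty}")


@dataclass
class RegressionResult:
    """Cluster-robust linear regression output.

    Confidence intervals use the normal critical value, ``beta +/- 1.96 SE``
    (a t-with-G-1-df option is available via ``critical_value``); the
    covariance is the clustered sandwich with the small-sample factor
    ``G/(G-1) * (N-1)/(N-K)``.
    """

    outcome: str
    predictors: list[str]
    params: pd.Series
    cov: pd.DataFrame
    bse: pd.Series
    conf_int: pd.DataFrame
    pvalues: pd.Series
    n_obs: int
    n_clusters: int
    tier: str
    unit_mode: str
    predictor_sds: dict[str, float]
    # internals retained for stacked-system coefficient comparison
    _X: pd.DataFrame = field(repr=False, default=None)
    _y: pd.Series = field(repr=False, default=None)
    _groups: pd.Series = field(repr=False, default=None)

    def coefficient(self, name: str) -> float:
        return float(self.params[name])


def fit_bmi_model(
    data: pd.DataFrame,
    activity_predictors: list[str] | str,
    tier: str = "full",
    unit_mode: str = "natural",
    cluster_col: str = "participant_id",
    outcome: str = "bmi",
    critical_value: float | None = None,
    base_covariates: list[str] | None = None,
) -> RegressionResult:
    """Least-squares regression of untransformed BMI on activity predictors
    with cluster-robust standard errors grouped by participant.

    Every model adjusts for device wear time, wear location and season;
    ``tier`` adds demographic and then behavioral + clinical blocks
    cumulatively.  ``unit_mode="standardized"`` divides each activity
    predictor by its sample SD over the analysis set, so coefficients are
    per-SD.  Complete cases only; requires >= 2 clusters unless every
    cluster is a singleton (then the estimate equals ordinary least squares
    with heteroskedasticity-robust errors).
    """
    if isinstance(activity_predictors, str):
        activity_predictors = [activity_predictors]
    if tier not in TIERS:
        raise ValueError(f"unknown tier {tier!r}; choose from {list(TIERS)}")
    if unit_mode not in ("natural", "standardized"):
        raise ValueError("unit_mode must be 'natural' or 'standardized'")
    if base_covariates is None:
        base_covariates = BASE_COVARIATES

    columns = activity_predictors + base_covariates + TIERS[tier]
    use = data[[outcome, cluster_col] + columns].dropna()
    if use.empty:
        raise ValueError("no complete cases for the requested model")

    work = use.copy()
    sds: dict[str, float] = {}
    if unit_mode == "standardized":
        for col in activity_predictors:
            sd = float(work[col].std(ddof=1))
            if sd == 0:
                raise ValueError(f"cannot standardize constant predictor {col}")
            work[col] = work[col] / sd
            sds[col] = sd

    # drop categorical columns that are constant in the analysis set
    kept = [
        c
        for c in columns
        if c in activity_predictors or work[c].nunique(dropna=True) > 1
    ]
    X = _design_matrix(work, kept)
    _check_full_rank(X)
    y = work[outcome].astype(float)
    groups = work[cluster_col]
    n_clusters = groups.nunique()
    if n_clusters < 2:
        raise ValueError("cluster-robust inference needs >= 2 clusters")

    fit = sm.OLS(y.to_numpy(), X.to_numpy()).fit(
        cov_type="cluster",
        cov_kwds={"groups": pd.factorize(groups)[0], "use_correction": True},
        use_t=False,
    )
    params = pd.Series(fit.params, index=X.columns)
    bse = pd.Series(fit.bse, index=X.columns)
    crit = Z95 if critical_value is None else critical_value
    ci = pd.DataFrame(
        {"lower": params - crit * bse, "upper": params + crit * bse}, index=X.columns
    )
    pvals = pd.Series(fit.pvalues, index=X.columns)
    return RegressionResult(
        outcome=outcome,
        predictors=list(activity_predictors),
        params=params,
        cov=pd.DataFrame(fit.cov_params(), index=X.columns, columns=X.columns),
        bse=bse,
        conf_int=ci,
        pvalues=pvals,
        n_obs=int(fit.nobs),
        n_clusters=int(n_clusters),
        tier=tier,
        unit_mode=unit_mode,
        predictor_sds=sds,
        _X=X,
        _y=y,
        _groups=groups,
    )


@dataclass
class CoefficientComparison:
    """Wald comparison of the device coefficient against the self-report
    coefficient for an analogous activity measure."""

    fitbit_beta: float
    ipaq_beta: float
    difference: float
    wald_statistic: float
    p_value: float
    model_mode: str  # "separate" | "combined"


def _cluster_wald(
    X: np.ndarray, y: np.ndarray, groups: np.ndarray, contrast: np.ndarray
) -> tuple[np.ndarray, float, float]:
    """OLS fit with clustered sandwich covariance (Stata-style small-sample
    correction) and a single-df Wald test of ``contrast @ beta = 0``."""
    n, k = X.shape
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ (X.T @ y)
    resid = y - X @ beta
    codes, uniq = pd.factorize(groups)
    g = len(uniq)
    meat = np.zeros((k, k))
    xu = X * resid[:, None]
    sums = np.zeros((g, k))
    np.add.at(sums, codes, xu)
    meat = sums.T @ sums
    correction = (g / (g - 1)) * ((n - 1) / (n - k))
    cov = correction * xtx_inv @ meat @ xtx_inv
    diff = float(contrast @ beta)
    var = float(contrast @ cov @ contrast)
    wald = diff**2 / var if var > 0 else np.inf
    p = float(sps.chi2.sf(wald, df=1)) if np.isfinite(wald) else 0.0
    return beta, wald, p


def compare_coefficients(
    model_a: RegressionResult,
    model_b: RegressionResult | None = None,
    predictor_a: str | None = None,
    predictor_b: str | None = None,
) -> CoefficientComparison:
    """Wald test of ``beta_fitbit - beta_ipaq = 0``.

    With two separate models (fit on the same observations and clusters),
    the two equations are re-estimated jointly as a stacked system — the
    design matrices placed block-diagonally, observations duplicated — so
    the participant-level clustering links the equations and yields a valid
    covariance for the cross-model contrast; point estimates are unchanged.
    With a single combined model (``model_b=None``), the contrast is tested
    within that model's covariance.
    """
    if model_b is None:
        pa = predictor_a or model_a.predictors[0]
        pb = predictor_b or model_a.predictors[1]
        beta_a = model_a.coefficient(pa)
        beta_b = model_a.coefficient(pb)
        c = pd.Series(0.0, index=model_a.params.index)
        c[pa], c[pb] = 1.0, -1.0
        var = float(c @ model_a.cov @ c)
        diff = beta_a - beta_b
        wald = diff**2 / var if var > 0 else np.inf
        p = float(sps.chi2.sf(wald, df=1)) if np.isfinite(wald) else 0.0
        return CoefficientComparison(beta_a, beta_b, diff, wald, p, "combined")

    pa = predictor_a or model_a.predictors[0]
    pb = predictor_b or model_b.predictors[0]
    if not model_a._y.index.equals(model_b._y.index):
        raise ValueError("models must be estimated on the same observations")
    if not model_a._groups.equals(model_b._groups):
        raise ValueError("models must share the same clusters")

    Xa, Xb = model_a._X.to_numpy(), model_b._X.to_numpy()
    n = Xa.shape[0]
    ka, kb = Xa.shape[1], Xb.shape[1]
    X = np.zeros((2 * n, ka + kb))
    X[:n, :ka] = Xa
    X[n:, ka:] = Xb
    y = np.concatenate([model_a._y.to_numpy(), model_b._y.to_numpy()])
    groups = np.concatenate([model_a._groups.to_numpy(), model_b._groups.to_numpy()])
    contrast = np.zeros(ka + kb)
    contrast[model_a._X.columns.get_loc(pa)] = 1.0
    contrast[ka + model_b._X.columns.get_loc(pb)] = -1.0
    beta, wald, p = _cluster_wald(X, y, groups, contrast)
    beta_a = float(beta[model_a._X.columns.get_loc(pa)])
    beta_b = float(beta[ka + model_b._X.columns.get_loc(pb)])
    return CoefficientComparison(beta_a, beta_b, beta_a - beta_b, wald, p, "separate")


# ---------------------------------------------------------------------------
# The model battery and sensitivity reruns
# ---------------------------------------------------------------------------

@dataclass
class ModelFamily:
    """One analogous measure pair at one adjustment tier: the two separate
    predictor models, the combined head-to-head model, and the Wald
    comparisons."""

    variable: str
    tier: str
    unit_mode: str
    fitbit_model: RegressionResult
    ipaq_model: RegressionResult
    combined_model: RegressionResult
    separate_comparison: CoefficientComparison
    combined_comparison: CoefficientComparison


def fit_model_battery(
    data: pd.DataFrame,
    tiers: tuple[str, ...] = ("base", "demographics", "full"),
    unit_mode: str = "natural",
    cluster_col: str = "participant_id",
) -> list[ModelFamily]:
    """Fit the full battery: for each of the 6 analogous activity measure
    pairs and each adjustment tier, 2 separate predictor models (12 per
    tier) and 1 combined head-to-head model (6 per tier), each with the
    device-versus-self-report Wald comparison."""
    families: list[ModelFamily] = []
    complete = data.dropna(
        subset=["bmi"]
        + [c for _, f, i in MEASURE_PAIRS for c in (f, i)]
        + BASE_COVARIATES
        + TIERS[max(tiers, key=lambda t: len(TIERS[t]))]
    )
    for variable, fit_col, ipaq_col in MEASURE_PAIRS:
        for tier in tiers:
            m_fit = fit_bmi_model(
                complete, fit_col, tier=tier, unit_mode=unit_mode, cluster_col=cluster_col
            )
            m_ipaq = fit_bmi_model(
                complete, ipaq_col, tier=tier, unit_mode=unit_mode, cluster_col=cluster_col
            )
            m_comb = fit_bmi_model(
                complete,
                [fit_col, ipaq_col],
                tier=tier,
                unit_mode=unit_mode,
                cluster_col=cluster_col,
            )
            families.append(
                ModelFamily(
                    variable=variable,
                    tier=tier,
                    unit_mode=unit_mode,
                    fitbit_model=m_fit,
                    ipaq_model=m_ipaq,
                    combined_model=m_comb,
                    separate_comparison=compare_coefficients(
                        m_fit, m_ipaq, fit_col, ipaq_col
                    ),
                    combined_comparison=compare_coefficients(
                        m_comb, predictor_a=fit_col, predictor_b=ipaq_col
                    ),
                )
            )
    return families


def battery_to_frame(families: list[ModelFamily]) -> pd.DataFrame:
    """One row per model x predictor, mirroring the layout of the published
    coefficient tables."""
    rows = []
    for fam in families:
        for mode, model in (
            ("separate_fitbit", fam.fitbit_model),
            ("separate_ipaq", fam.ipaq_model),
            ("combined", fam.combined_model),
        ):
            for pred in model.predictors:
                source = "fitbit" if pred.startswith("fitbit") else "ipaq"
                cmp = (
                    fam.combined_comparison
                    if mode == "combined"
                    else fam.separate_comparison
                )
                rows.append(
                    {
                        "variable": fam.variable,
                        "tier": fam.tier,
                        "unit_mode": fam.unit_mode,
                        "model": mode,
                        "source": source,
                        "beta": model.coefficient(pred),
                        "se": float(model.bse[pred]),
                        "ci_lower": float(model.conf_int.loc[pred, "lower"]),
                        "ci_upper": float(model.conf_int.loc[pred, "upper"]),
                        "p_value": float(model.pvalues[pred]),
                        "wald_p_fitbit_vs_ipaq": cmp.p_value,
                        "n_obs": model.n_obs,
                        "n_clusters": model.n_clusters,
                    }
                )
    return pd.DataFrame(rows)


def activity_correlations(data: pd.DataFrame) -> pd.DataFrame:
    """Spearman correlations between the paired device and self-report
    measures (the numeric content of the agreement scatter panels)."""
    rows = []
    for variable, fit_col, ipaq_col in MEASURE_PAIRS:
        sub = data[[fit_col, ipaq_col]].dropna()
        r, p = spearman(sub[fit_col], sub[ipaq_col])
        rows.append(
            {"variable": variable, "spearman_r": r, "p_value": p, "n": len(sub)}
        )
    return pd.DataFrame(rows)


def paired_comparison_suite(data: pd.DataFrame) -> pd.DataFrame:
    """Wilcoxon matched-pairs tests and medians for each analogous measure
    pair (device vs self-report on the same week)."""
    rows = []
    for variable, fit_col, ipaq_col in MEASURE_PAIRS:
        if variable == "overall":
            continue  # measured on different scales
        sub = data[[fit_col, ipaq_col]].dropna()
        w, p = wilcoxon_signed_rank(sub[fit_col], sub[ipaq_col])
        rows.append(
            {
                "variable": variable,
                "fitbit_median": float(sub[fit_col].median()),
                "ipaq_median": float(sub[ipaq_col].median()),
                "w_plus": w,
                "p_value": p,
                "n": len(sub),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class SensitivityResult:
    exclusion: str
    n_excluded: int
    fraction_excluded: float
    correlations: pd.DataFrame
    battery: list[ModelFamily]


def run_sensitivity(
    data: pd.DataFrame,
    exclusion: str,
    tiers: tuple[str, ...] = ("base", "demographics", "full"),
    unit_mode: str = "natural",
) -> SensitivityResult:
    """Repeat the correlations and model battery after excluding either the
    smartphone-sourced rows (``"mobiletrack"``) or torso-worn devices
    (``"torso"``)."""
    if exclusion == "mobiletrack":
        mask = data["data_source"] == "mobiletrack"
    elif exclusion == "torso":
        mask = data["device_location"] == "torso"
    else:
        raise ValueError("exclusion must be 'mobiletrack' or 'torso'")
    kept = data[~mask]
    if kept.empty:
        raise ValueError(f"exclusion {exclusion!r} removes every observation")
    return SensitivityResult(
        exclusion=exclusion,
        n_excluded=int(mask.sum()),
        fraction_excluded=float(mask.mean()),
        correlations=activity_correlations(kept),
        battery=fit_model_battery(kept, tiers=tiers, unit_mode=unit_mode),
    )
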