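"""Between-subject statistics: hierarchical regression, moderation,
bootstrapped mediation, group comparisons, JZS Bayes factors, and leisure
utilities.

All regression machinery is ordinary least squares via statsmodels; the
moderation model enters variables raw (not mean-centered) with conditional
effects of the predictor probed at moderator mean +/- 1 SD. Mediation uses
a percentile bootstrap over subjects. The JZS Bayes factor integrates the
noncentral-t likelihood over a Cauchy prior on effect size.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import integrate, stats


@dataclass
class RegressionStep:
    """One block of a hierarchical regression."""

    label: str
    r2: float
    adj_r2: float
    r2_change: float
    f_change: float
    p_change: float
    terms: pd.DataFrame  # per-term: beta_std, t, p, ci_low, ci_high


@dataclass
class ModerationResult:
    coefficients: pd.DataFrame  # index: const, predictor, moderator, interaction, covariates
    conditional_effects: pd.DataFrame  # effect of predictor at moderator mean-SD/mean/mean+SD
    r2: float
    mse: float


@dataclass
class MediationResult:
    indirect: float
    boot_se: float
    ci_low: float
    ci_high: float
    n_boot: int
    seed: Optional[int]
    a_path: float
    b_path: float
    n_redrawn: int = 0


def _standardized_terms(y: np.ndarray, X: pd.DataFrame) -> pd.DataFrame:
    """Per-term standardized beta, t, p and raw-coefficient 95% CI."""
    Xc = sm.add_constant(X)
    fit = sm.OLS(y, Xc).fit()
    zX = (X - X.mean()) / X.std(ddof=1)
    zy = (y - y.mean()) / y.std(ddof=1)
    zfit = sm.OLS(zy, sm.add_constant(zX)).fit()
    ci = fit.conf_int()
    rows = []
    for name in X.columns:
        rows.append(
            {
                "term": name,
                "beta_std": zfit.params[name],
                "coef": fit.params[name],
                "t": fit.tvalues[name],
                "p": fit.pvalues[name],
                "ci_low": ci.loc[name, 0],
                "ci_high": ci.loc[name, 1],
            }
        )
    return pd.DataFrame(rows).set_index("term")


def hierarchical_regression(
    table: pd.DataFrame,
    outcome: str,
    ordered_blocks: Sequence[tuple[str, Sequence[str]]],
) -> list[RegressionStep]:
    """OLS per cumulative block with R²-change F tests between nested models.

    ``ordered_blocks`` is a sequence of (label, [predictor columns]); each
    step refits with all predictors up to and including that block. Raises
    on rank deficiency, naming the collinear terms.
    """
    y = table[outcome].to_numpy(float)
    n = y.size
    used: list[str] = []
    steps: list[RegressionStep] = []
    prev_ssr = float(np.sum((y - y.mean()) ** 2))
    prev_k = 0
    for label, cols in ordered_blocks:
        # a predictor repeated across blocks adds nothing (R2/F change 0);
        # genuine collinearity among distinct terms is an error
        new_cols = [c for c in cols if c not in used]
        used_cols = used + new_cols
        X = table[used_cols].astype(float)
        Xc = sm.add_constant(X)
        rank = np.linalg.matrix_rank(Xc.to_numpy())
        if rank < Xc.shape[1]:
            raise ValueError(
                f"rank-deficient design in block {label!r}: check {used_cols}"
            )
        fit = sm.OLS(y, Xc).fit()
        ssr = float(fit.ssr)
        k = fit.df_model
        df_num = k - prev_k
        df_den = n - k - 1
        if df_num > 0 and ssr > 0 and prev_ssr > ssr * (1 + 1e-12):
            f_change = ((prev_ssr - ssr) / df_num) / (ssr / df_den)
            p_change = float(stats.f.sf(f_change, df_num, df_den))
        elif df_num > 0:
            f_change = max((prev_ssr - ssr), 0.0) / df_num / max(ssr / df_den, 1e-300)
            p_change = float(stats.f.sf(f_change, df_num, df_den)) if f_change > 0 else 1.0
        else:
            f_change, p_change = 0.0, 1.0
        steps.append(
            RegressionStep(
                label=label,
                r2=float(fit.rsquared),
                adj_r2=float(fit.rsquared_adj),
                r2_change=float(fit.rsquared - (steps[-1].r2 if steps else 0.0)),
                f_change=float(f_change),
                p_change=p_change,
                terms=_standardized_terms(y, X),
            )
        )
        used = used_cols
        prev_ssr, prev_k = ssr, k
    return steps


def moderation(
    table: pd.DataFrame,
    outcome: str = "mean_rt",
    predictor: str = "cri_leisure",
    moderator: str = "cpp_slope",
    covariates: Sequence[str] = (),
    center: bool = False,
) -> ModerationResult:
    """OLS moderation: outcome ~ predictor * moderator (+ covariates).

    Variables enter raw by default (set ``center=True`` to mean-center the
    predictor and moderator first). Conditional effects of the predictor are
    reported at moderator mean - SD, mean, and mean + SD, with standard
    errors from the coefficient covariance of the linear combination
    b_pred + m * b_inter.
    """
    d = table.copy()
    if center:
        d[predictor] = d[predictor] - d[predictor].mean()
        d[moderator] = d[moderator] - d[moderator].mean()
    d["_inter"] = d[predictor] * d[moderator]
    cols = [moderator, predictor, "_inter", *covariates]
    X = sm.add_constant(d[cols].astype(float))
    y = d[outcome].to_numpy(float)
    fit = sm.OLS(y, X).fit()
    ci = fit.conf_int()
    coefs = pd.DataFrame(
        {
            "coef": fit.params,
            "se": fit.bse,
            "t": fit.tvalues,
            "p": fit.pvalues,
            "ci_low": ci[0],
            "ci_high": ci[1],
        }
    )

    m_mean = float(d[moderator].mean())
    m_sd = float(d[moderator].std(ddof=1))
    probes = {"mean-sd": m_mean - m_sd, "mean": m_mean, "mean+sd": m_mean + m_sd}
    cov = fit.cov_params()
    b_p, b_i = fit.params[predictor], fit.params["_inter"]
    var_p = cov.loc[predictor, predictor]
    var_i = cov.loc["_inter", "_inter"]
    cov_pi = cov.loc[predictor, "_inter"]
    rows = []
    df_resid = fit.df_resid
    for name, m in probes.items():
        eff = b_p + m * b_i
        se = float(np.sqrt(var_p + 2 * m * cov_pi + m * m * var_i))
        t = eff / se
        p = 2 * stats.t.sf(abs(t), df_resid)
        tc = stats.t.ppf(0.975, df_resid)
        rows.append(
            {
                "probe": name,
                "moderator_value": m,
                "effect": eff,
                "se": se,
                "t": t,
                "p": p,
                "ci_low": eff - tc * se,
                "ci_high": eff + tc * se,
            }
        )
    rename = {"_inter": f"{predictor}:{moderator}"}
    return ModerationResult(
        coefficients=coefs.rename(index=rename),
        conditional_effects=pd.DataFrame(rows).set_index("probe"),
        r2=float(fit.rsquared),
        mse=float(fit.mse_resid),
    )


def _two_predictor_slopes(x: np.ndarray, m: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """(a, b): slope of m~x, and coefficient of m in y ~ x + m."""
    vx = x - x.mean()
    vm = m - m.mean()
    vy = y - y.mean()
    sxx = vx @ vx
    a = (vx @ vm) / sxx
    # partial out x from m and y (Frisch-Waugh)
    rm = vm - (vx @ vm) / sxx * vx
    rss = rm @ rm
    if rss <= 1e-12 * (vm @ vm):
        # mediator perfectly collinear with x (fully deterministic chain):
        # attribute the whole effect to the mediator path
        b = (vm @ vy) / (vm @ vm)
    else:
        b = (rm @ vy) / rss
    return float(a), float(b)


def mediation_bootstrap(
    table: pd.DataFrame,
    x: str,
    mediator: str,
    y: str,
    n_boot: int = 5000,
    seed: Optional[int] = None,
) -> MediationResult:
    """Percentile-bootstrap indirect effect (a path x b path).

    ``a`` is the slope of mediator on x; ``b`` the mediator coefficient in
    the outcome model controlling for x. Bootstrap resamples subjects with
    replacement; degenerate resamples (constant x or mediator) are redrawn
    and counted.
    """
    d = table[[x, mediator, y]].dropna()
    if len(d) < 10:
        raise ValueError("mediation requires at least 10 complete cases")
    xv = d[x].to_numpy(float)
    mv = d[mediator].to_numpy(float)
    yv = d[y].to_numpy(float)
    a, b = _two_predictor_slopes(xv, mv, yv)
    point = a * b

    rng = np.random.default_rng(seed)
    n = xv.size
    est = np.empty(n_boot)
    n_redrawn = 0
    i = 0
    while i < n_boot:
        idx = rng.integers(0, n, size=n)
        xb = xv[idx]
        mb = mv[idx]
        if np.ptp(xb) == 0 or np.ptp(mb) == 0:
            n_redrawn += 1
            continue
        ab, bb = _two_predictor_slopes(xb, mb, yv[idx])
        est[i] = ab * bb
        i += 1
    lo, hi = np.percentile(est, [2.5, 97.5])
    return MediationResult(
        indirect=point,
        boot_se=float(est.std(ddof=1)),
        ci_low=float(lo),
        ci_high=float(hi),
        n_boot=n_boot,
        seed=seed,
        a_path=a,
        b_path=b,
        n_redrawn=n_redrawn,
    )


def group_compare(values: np.ndarray, groups: np.ndarray) -> dict[str, float]:
    """One-way ANOVA with partial eta², plus Student and Welch t variants."""
    values = np.asarray(values, float)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    samples = [values[groups == g] for g in labels]
    f, p = stats.f_oneway(*samples)
    grand = values.mean()
    ss_effect = sum(len(s) * (s.mean() - grand) ** 2 for s in samples)
    ss_error = sum(((s - s.mean()) ** 2).sum() for s in samples)
    out = {
        "F": float(f),
        "p": float(p),
        "df_between": float(len(labels) - 1),
        "df_within": float(values.size - len(labels)),
        "partial_eta_sq": float(ss_effect / (ss_effect + ss_error)),
    }
    if len(labels) == 2:
        t_s, p_s = stats.ttest_ind(samples[0], samples[1])
        t_w, p_w = stats.ttest_ind(samples[0], samples[1], equal_var=False)
        out.update(
            t_student=float(t_s), p_student=float(p_s), t_welch=float(t_w), p_welch=float(p_w)
        )
    return out


def jzs_bf_ttest(
    values: Sequence[float] | np.ndarray,
    values2: Optional[Sequence[float]] = None,
    mode: str = "one-sample",
    null: float = 0.0,
    cauchy_scale: float = 0.707,
    direction: str = "two-sided",
) -> float:
    """JZS Bayes factor (BF10) for a t test with a Cauchy prior on effect size.

    BF10 = [integral of the noncentral-t likelihood over the Cauchy prior]
    divided by the central-t likelihood at the observed statistic.
    ``direction`` one of 'two-sided', 'greater', 'less' (half-Cauchy priors
    for the directional cases).
    """
    v1 = np.asarray(values, float)
    if mode == "one-sample":
        if v1.size < 3:
            raise ValueError("need at least 3 observations")
        n_eff = float(v1.size)
        df = v1.size - 1
        t_obs = (v1.mean() - null) / (v1.std(ddof=1) / np.sqrt(v1.size))
    elif mode == "independent":
        v2 = np.asarray(values2, float)
        if v1.size < 3 or v2.size < 3:
            raise ValueError("need at least 3 observations per group")
        n_eff = v1.size * v2.size / (v1.size + v2.size)
        df = v1.size + v2.size - 2
        t_obs = stats.ttest_ind(v1, v2).statistic
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return bf10_from_t(float(t_obs), n_eff, int(df), cauchy_scale, direction)


def _nct_pdf(x: float, df: float, ncp: float) -> float:
    """Noncentral-t density via the chi-mixture integral.

    Stable for large df (scipy's boost implementation overflows past
    df ~ 340): f(x) = int f_U(u) * u * phi(x*u - ncp) du with
    U = sqrt(chi2_df / df), everything in log space under the integral.
    """
    from scipy.special import gammaln

    log_norm_const = (
        np.log(2.0) + 0.5 * df * np.log(df / 2.0) - gammaln(df / 2.0)
    ) - 0.5 * np.log(2.0 * np.pi)

    def f(u: float) -> float:
        if u <= 0:
            return 0.0
        logv = (
            log_norm_const
            + df * np.log(u)
            - df * u * u / 2.0
            - 0.5 * (x * u - ncp) ** 2
        )
        return np.exp(logv)

    mode = np.sqrt(max(df - 1.0, 0.5) / df)
    sd = 1.0 / np.sqrt(2.0 * df)
    hi = mode + 12.0 * sd
    val, _ = integrate.quad(f, 0.0, hi, points=[mode], limit=200)
    return val


def bf10_from_t(
    t_obs: float,
    n_eff: float,
    df: int,
    cauchy_scale: float = 0.707,
    direction: str = "two-sided",
) -> float:
    """BF10 from a t statistic, effective N and degrees of freedom."""
    sqrt_n = np.sqrt(n_eff)

    def integrand(delta: float) -> float:
        return _nct_pdf(t_obs, df, delta * sqrt_n) * stats.cauchy.pdf(
            delta, scale=cauchy_scale
        )

    # the likelihood peaks near delta = t/sqrt(N) with width ~ 1/sqrt(N);
    # split the integral there so quad cannot step over the peak
    center = t_obs / sqrt_n
    width = 8.0 / sqrt_n

    def _quad(lo: float, hi: float) -> float:
        pts = sorted(
            {p for p in (center - width, center, center + width) if lo < p < hi}
        )
        total = 0.0
        edges = [lo, *pts, hi]
        for a_, b_ in zip(edges[:-1], edges[1:]):
            val, _ = integrate.quad(integrand, a_, b_, limit=200)
            total += val
        return total

    if direction == "two-sided":
        alt = _quad(-np.inf, np.inf)
    elif direction == "greater":
        alt = 2.0 * _quad(0.0, np.inf)
    elif direction == "less":
        alt = 2.0 * _quad(-np.inf, 0.0)
    else:
        raise ValueError(f"unknown direction {direction!r}")
    null_like = stats.t.pdf(t_obs, df)
    return float(alt / null_like)


def life_percentage(years_activity: float, age: float) -> float:
    """Percent of adult life spent on an activity: years / (age - 18) * 100.

    Values above 100 are permitted (rounding conventions of the source
    questionnaire can push totals past a full adult lifetime).
    """
    if age <= 18:
        raise ValueError("age must exceed 18")
    return years_activity / (age - 18.0) * 100.0
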