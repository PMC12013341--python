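"""Inferential layer: repeated-measures ANOVA with Greenhouse-Geisser
correction, Tukey post hoc, Friedman, paired/unpaired rank and t tests,
Levene's test, simple regression of HRV change on survey change, and the
paired-design power computation.

The RM-ANOVA is the classical univariate within-subject decomposition; the
Greenhouse-Geisser epsilon is computed from the double-centered
within-subject covariance (equivalently, from orthonormal effect
contrasts), and corrected p-values use epsilon-scaled degrees of freedom.
No multiple-testing correction is applied across metrics or scales beyond
Tukey within an ANOVA family, matching the analysis this package mirrors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "StatResult",
    "rm_anova_gg",
    "tukey_posthoc",
    "friedman",
    "paired_tests",
    "unpaired_tests",
    "simple_regression",
    "delta_vs_delta",
    "design_power",
    "enrollment_from_flow",
    "demographic_percent",
]


@dataclass
class StatResult:
    """One test outcome: statistic, (possibly corrected) df, p, extras."""

    test: str
    statistic: float
    p: float
    df: float | None = None
    df2: float | None = None
    correction: str | None = None
    extra: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Repeated-measures ANOVA with Greenhouse-Geisser correction
# ---------------------------------------------------------------------------

def _orthonormal_contrasts(k: int) -> np.ndarray:
    """(k-1) x k matrix with orthonormal rows spanning the mean-free subspace."""
    center = np.eye(k) - np.ones((k, k)) / k
    _, s, vt = np.linalg.svd(center)
    return vt[s > 1e-10]


def _gg_epsilon(sigma: np.ndarray, contrasts: np.ndarray) -> float:
    """epsilon-hat = (tr M)^2 / (df * tr(M M)) with M the contrast-projected
    covariance; clipped to its [1/df, 1] range."""
    M = contrasts @ sigma @ contrasts.T
    df = contrasts.shape[0]
    tr = np.trace(M)
    tr2 = np.trace(M @ M)
    if tr2 <= 0:
        return 1.0
    eps = (tr * tr) / (df * tr2)
    return float(np.clip(eps, 1.0 / df, 1.0))


def _anova_row(effect: str, ss_eff: float, df1: int, ss_err: float, df2: int,
               eps: float) -> dict:
    ms_eff = ss_eff / df1
    ms_err = ss_err / df2
    F = ms_eff / ms_err if ms_err > 0 else np.inf
    p_unc = float(sps.f.sf(F, df1, df2))
    p_gg = float(sps.f.sf(F, eps * df1, eps * df2))
    return {
        "effect": effect, "F": F, "df1": df1, "df2": df2,
        "eps": eps, "df1_gg": eps * df1, "df2_gg": eps * df2,
        "p_unc": p_unc, "p_gg": p_gg,
        "ss_effect": ss_eff, "ss_error": ss_err,
    }


def _rm_anova_oneway(Y: np.ndarray) -> pd.DataFrame:
    n, k = Y.shape
    if k < 2:
        raise ValueError("factor needs >= 2 levels")
    if n < 2:
        raise ValueError("need >= 2 subjects")
    grand = Y.mean()
    m_j = Y.mean(axis=0)
    m_s = Y.mean(axis=1)
    ss_treat = n * np.sum((m_j - grand) ** 2)
    resid = Y - m_s[:, None] - m_j[None, :] + grand
    ss_err = np.sum(resid**2)
    # With 2 levels there is a single contrast variable: sphericity holds
    # trivially and epsilon is exactly 1.
    eps = 1.0 if k == 2 else _gg_epsilon(np.cov(Y, rowvar=False), _orthonormal_contrasts(k))
    row = _anova_row("within", ss_treat, k - 1, ss_err, (k - 1) * (n - 1), eps)
    return pd.DataFrame([row])


def _rm_anova_twoway(Y: np.ndarray) -> pd.DataFrame:
    """Y is subjects x levels(A) x levels(B), one observation per cell."""
    n, a, b = Y.shape
    if a < 2 or b < 2:
        raise ValueError("each factor needs >= 2 levels")
    if n < 2:
        raise ValueError("need >= 2 subjects")
    grand = Y.mean()
    m_i = Y.mean(axis=(0, 2))  # A level means
    m_j = Y.mean(axis=(0, 1))  # B level means
    m_s = Y.mean(axis=(1, 2))  # subject means
    m_ij = Y.mean(axis=0)
    m_si = Y.mean(axis=2)
    m_sj = Y.mean(axis=1)

    ss_a = n * b * np.sum((m_i - grand) ** 2)
    ss_b = n * a * np.sum((m_j - grand) ** 2)
    ss_ab = n * np.sum((m_ij - m_i[:, None] - m_j[None, :] + grand) ** 2)
    ss_as = b * np.sum((m_si - m_s[:, None] - m_i[None, :] + grand) ** 2)
    ss_bs = a * np.sum((m_sj - m_s[:, None] - m_j[None, :] + grand) ** 2)
    resid = (
        Y
        - m_si[:, :, None] - m_sj[:, None, :] - m_ij[None, :, :]
        + m_s[:, None, None] + m_i[None, :, None] + m_j[None, None, :]
        - grand
    )
    ss_abs = np.sum(resid**2)

    sigma = np.cov(Y.reshape(n, a * b), rowvar=False)
    c_a = _orthonormal_contrasts(a)
    c_b = _orthonormal_contrasts(b)
    one_a = np.ones((1, a)) / np.sqrt(a)
    one_b = np.ones((1, b)) / np.sqrt(b)
    eps_a = 1.0 if a == 2 else _gg_epsilon(sigma, np.kron(c_a, one_b))
    eps_b = 1.0 if b == 2 else _gg_epsilon(sigma, np.kron(one_a, c_b))
    eps_ab = _gg_epsilon(sigma, np.kron(c_a, c_b))

    rows = [
        _anova_row("A", ss_a, a - 1, ss_as, (a - 1) * (n - 1), eps_a),
        _anova_row("B", ss_b, b - 1, ss_bs, (b - 1) * (n - 1), eps_b),
        _anova_row("A*B", ss_ab, (a - 1) * (b - 1), ss_abs, (a - 1) * (b - 1) * (n - 1), eps_ab),
    ]
    return pd.DataFrame(rows)


def rm_anova_gg(
    data,
    dv: str | None = None,
    within: str | list[str] | None = None,
    subject: str | None = None,
) -> pd.DataFrame:
    """Within-subject ANOVA with Greenhouse-Geisser-corrected p-values.

    ``data`` is either a wide array — subjects x levels for one factor,
    subjects x levelsA x levelsB for two — or a long DataFrame with ``dv``,
    ``within`` (one or two column names) and ``subject`` given. Participants
    with incomplete cells are dropped (and counted in no row; callers log
    them). Returns one row per effect with uncorrected and corrected p.
    """
    if isinstance(data, pd.DataFrame):
        if dv is None or within is None or subject is None:
            raise ValueError("long-format input needs dv, within and subject")
        factors = [within] if isinstance(within, str) else list(within)
        wide = data.pivot_table(index=subject, columns=factors, values=dv, aggfunc="mean")
        wide = wide.dropna(axis=0)  # complete cases only
        if len(factors) == 1:
            return _rm_anova_oneway(wide.to_numpy())
        a = wide.columns.get_level_values(0).unique().size
        b = wide.columns.get_level_values(1).unique().size
        if wide.shape[1] != a * b:
            raise ValueError("incomplete factor crossing: every session x time cell is required")
        wide = wide.sort_index(axis=1)
        return _rm_anova_twoway(wide.to_numpy().reshape(len(wide), a, b))
    Y = np.asarray(data, dtype=float)
    if Y.ndim == 2:
        return _rm_anova_oneway(Y)
    if Y.ndim == 3:
        return _rm_anova_twoway(Y)
    raise ValueError("array input must be 2-D (one-way) or 3-D (two-way)")


def tukey_posthoc(Y, labels: list[str] | None = None) -> pd.DataFrame:
    """Tukey multiple comparisons over the levels of a within-subject factor.

    ``Y`` is subjects x levels. The studentized-range statistic per pair is
    q = |mean_i - mean_j| / sqrt(MS_error / n) with MS_error and df from the
    one-way RM decomposition; for two levels q = t * sqrt(2) of the paired t.
    """
    Y = np.asarray(Y, dtype=float)
    n, k = Y.shape
    labels = labels or [f"level{i}" for i in range(k)]
    table = _rm_anova_oneway(Y).iloc[0]
    ms_err = table["ss_error"] / table["df2"]
    df_err = table["df2"]
    means = Y.mean(axis=0)
    se = np.sqrt(ms_err / n)
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            q = abs(means[i] - means[j]) / se if se > 0 else 0.0
            p = float(sps.studentized_range.sf(q, k, df_err)) if se > 0 else 1.0
            rows.append(
                {
                    "level_a": labels[i], "level_b": labels[j],
                    "mean_diff": means[j] - means[i],
                    "q": q, "p_adj": min(p, 1.0),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Nonparametric tests
# ---------------------------------------------------------------------------

def friedman(blocks) -> StatResult:
    """Friedman chi-square over complete blocks (rows) x conditions (columns).

    Ties are mid-ranked with the standard correction; fully tied data (every
    block constant) has no rank information and returns chi2 = 0, p = 1.
    """
    X = np.asarray(blocks, dtype=float)
    if X.ndim != 2 or X.shape[1] < 3:
        raise ValueError("need a complete blocks x k table with k >= 3")
    if np.isnan(X).any():
        raise ValueError("incomplete block design")
    if np.all(X == X[:, [0]]):
        return StatResult("friedman", 0.0, 1.0, df=X.shape[1] - 1)
    chi2, p = sps.friedmanchisquare(*X.T)
    return StatResult("friedman", float(chi2), float(p), df=X.shape[1] - 1)


def _signed_w(diff: np.ndarray) -> float:
    """Sum of positive ranks minus sum of negative ranks of |differences|."""
    ranks = sps.rankdata(np.abs(diff))
    return float(ranks[diff > 0].sum() - ranks[diff < 0].sum())


def paired_tests(pre, post, kind: str = "wilcoxon_signed_rank") -> StatResult:
    """Paired comparison of post against pre.

    Wilcoxon reports the signed statistic W = sum(positive ranks) -
    sum(negative ranks) of the post-pre differences (zero differences
    dropped), exact p for n <= 25 without ties, normal approximation with
    continuity correction otherwise. ``kind='paired_t'`` is the standard
    paired t test on post-pre.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape:
        raise ValueError("pre and post must be matched pairs")
    diff = post - pre
    if kind == "paired_t":
        if np.all(diff == diff[0]) and diff[0] == 0:
            return StatResult("paired_t", 0.0, 1.0, df=diff.size - 1)
        t, p = sps.ttest_rel(post, pre)
        return StatResult("paired_t", float(t), float(p), df=diff.size - 1)
    if kind != "wilcoxon_signed_rank":
        raise ValueError(f"unknown paired test {kind!r}")
    d = diff[diff != 0]
    if d.size == 0:
        return StatResult("wilcoxon_signed_rank", float("nan"), float("nan"),
                          extra={"note": "all differences zero"})
    ties = np.unique(np.abs(d)).size < d.size
    method = "exact" if (d.size <= 25 and not ties) else "approx"
    res = sps.wilcoxon(d, method=method, correction=(method == "approx"))
    return StatResult(
        "wilcoxon_signed_rank", _signed_w(d), float(res.pvalue),
        extra={"n_nonzero": int(d.size), "method": method},
    )


def unpaired_tests(a, b, kind: str = "mann_whitney") -> StatResult:
    """Two-sample comparison: 'mann_whitney', 't', or 'levene'.

    Levene uses absolute deviations from the group medians (the
    Brown-Forsythe variant, robust to non-normality).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need >= 2 observations per sample")
    if kind == "mann_whitney":
        u, p = sps.mannwhitneyu(a, b, alternative="two-sided")
        return StatResult("mann_whitney", float(u), float(p))
    if kind == "t":
        t, p = sps.ttest_ind(a, b)
        return StatResult("unpaired_t", float(t), float(p), df=a.size + b.size - 2)
    if kind == "levene":
        w, p = sps.levene(a, b, center="median")
        return StatResult("levene", float(w), float(p), df=1, df2=a.size + b.size - 2,
                          extra={"variant": "brown_forsythe"})
    raise ValueError(f"unknown unpaired test {kind!r}")


# ---------------------------------------------------------------------------
# Regression of HRV change on survey change
# ---------------------------------------------------------------------------

def simple_regression(x, y) -> StatResult:
    """Ordinary least squares y on x: slope, R^2, and the slope t-test p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 matched (x, y) points")
    if np.std(x) == 0:
        return StatResult("simple_regression", float("nan"), float("nan"),
                          extra={"note": "zero x variance"})
    res = sps.linregress(x, y)
    return StatResult(
        "simple_regression", float(res.slope), float(res.pvalue), df=x.size - 2,
        extra={
            "intercept": float(res.intercept),
            "r_squared": float(res.rvalue**2),
            "stderr": float(res.stderr),
        },
    )


def delta_vs_delta(
    hrv_metrics: pd.DataFrame,
    survey_diffs: pd.DataFrame,
    metric: str = "sdnn",
    scale: str = "suds",
    window: str = "music/10-15",
    baseline_label: str = "baseline",
) -> pd.DataFrame:
    """Join per-participant HRV change with survey change.

    x = metric in ``window`` minus metric in the baseline window;
    y = post-minus-pre total for ``scale``. Participants missing from either
    table are dropped (the joined table simply omits them).
    """
    hm = hrv_metrics[hrv_metrics["metric"] == metric]
    late = hm[hm["window"] == window].set_index("participant")["value"]
    base = hm[hm["window"] == baseline_label].set_index("participant")["value"]
    x = (late - base).dropna().rename("x")
    y = (
        survey_diffs[survey_diffs["scale"] == scale]
        .set_index("participant")["diff"]
        .rename("y")
    )
    joined = pd.concat([x, y], axis=1, join="inner").dropna().reset_index()
    return joined


# ---------------------------------------------------------------------------
# Design arithmetic
# ---------------------------------------------------------------------------

def design_power(n: int, alpha: float = 0.05, effect_d: float = 0.8) -> float:
    """Power of the two-sided one-sample/paired t test at effect size d.

    Noncentrality delta = d * sqrt(n), df = n - 1;
    power = P(|T'| > t_crit) under the noncentral t.
    """
    if n < 2 or not (0 < alpha < 1) or effect_d <= 0:
        raise ValueError("require n >= 2, 0 < alpha < 1, effect_d > 0")
    df = n - 1
    t_crit = sps.t.ppf(1 - alpha / 2, df)
    nc = effect_d * np.sqrt(n)
    return float(sps.nct.sf(t_crit, df, nc) + sps.nct.cdf(-t_crit, df, nc))


def enrollment_from_flow(recruited: int, not_screened: int, ineligible: int) -> int:
    """Enrolled count from recruitment-flow numbers."""
    enrolled = recruited - not_screened - ineligible
    if enrolled < 0:
        raise ValueError("flow counts imply negative enrollment")
    return enrolled


def demographic_percent(count: int, total: int) -> int:
    """Integer percentage as printed in demographic tables."""
    if total <= 0 or count < 0 or count > total:
        raise ValueError("invalid counts")
    return int(round(100.0 * count / total))
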