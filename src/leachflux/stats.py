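"""Assumption-driven bioassay statistics, dose-response fitting and PCA.

The test-selection tree mirrors common ecotoxicology practice for small
replicated dilution series compared against a control:

1. per-group Shapiro–Wilk normality at level alpha;
2. homoscedasticity by Levene's test (normal data) or the Fligner–Killeen
   test (non-normal data);
3. branch:
   * normal + homoscedastic   -> one-way ANOVA + Dunnett's many-to-one test;
   * normal + heteroscedastic -> Welch's ANOVA + Tamhane–Dunnett-type
     Welch-t comparisons against the control (Šidák family adjustment);
   * non-normal               -> Kruskal–Wallis + Dunn's rank test against
     the control (Holm adjustment).

Groups are the dilution levels; the control is dilution 0.

Dose–response uses the two-parameter log-logistic (LL.2) model

    f(x) = 1 / (1 + exp(b * (ln x - ln e)))

with asymptotes fixed at 0 and 1, fitted by multi-start least squares to a
min–max-normalized response, plus the classic lack-of-fit F test against the
saturated group-means model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

__all__ = [
    "StatsError",
    "InsufficientReplicatesError",
    "DegenerateDataError",
    "ConfigurationError",
    "AssumptionReport",
    "PosthocComparison",
    "TestReport",
    "DoseResponseFit",
    "PCASummary",
    "assumption_checks",
    "select_and_run",
    "welch_anova",
    "ll2",
    "fit_ll2",
    "lack_of_fit",
    "pca_summary",
]

TREATMENT_COLUMNS = ["treatment", "dilution_pct", "replicate", "response"]


class StatsError(ValueError):
    """Base class for statistical-input errors."""


class InsufficientReplicatesError(StatsError):
    pass


class DegenerateDataError(StatsError):
    pass


class ConfigurationError(StatsError):
    pass


# ---------------------------------------------------------------------------
# Assumption checks and the decision tree
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AssumptionReport:
    normal: bool
    homoscedastic: bool
    normality_p: dict[float, float]
    variance_test: str
    variance_p: float


@dataclass(frozen=True)
class PosthocComparison:
    group: float
    statistic: float
    p_adjusted: float
    significant: bool


@dataclass(frozen=True)
class TestReport:
    branch: str
    normality_p: dict[float, float]
    variance_test: str
    variance_p: float
    omnibus_test: str
    omnibus_stat: float
    omnibus_df: tuple[float, ...]
    omnibus_p: float
    posthoc_test: str
    posthoc: list[PosthocComparison]
    alpha: float


def _groups(table: pd.DataFrame) -> dict[float, np.ndarray]:
    """Split a treatment table into dilution groups, sorted by dose."""
    missing = [c for c in TREATMENT_COLUMNS if c not in table.columns]
    if missing:
        raise ConfigurationError(f"treatment table missing column(s) {missing}")
    out: dict[float, np.ndarray] = {}
    for dose, g in table.groupby("dilution_pct", sort=True):
        out[float(dose)] = g["response"].to_numpy(dtype=float)
    if len(out) < 2:
        raise ConfigurationError("need at least 2 dilution groups")
    return out


def assumption_checks(table: pd.DataFrame, alpha: float = 0.05) -> AssumptionReport:
    """Per-group Shapiro–Wilk plus the branch-appropriate variance test.

    ``normal`` requires every group to pass Shapiro–Wilk at ``alpha``;
    homoscedasticity uses Levene's test when normal, Fligner–Killeen
    otherwise.  Groups need >= 3 observations and non-zero spread.
    """
    groups = _groups(table)
    normality_p: dict[float, float] = {}
    for dose, values in groups.items():
        if len(values) < 3:
            raise InsufficientReplicatesError(
                f"group dilution={dose}: {len(values)} observations; "
                "Shapiro–Wilk needs at least 3"
            )
        if np.ptp(values) == 0:
            raise DegenerateDataError(
                f"group dilution={dose}: zero within-group variance; "
                "normality is undefined"
            )
        normality_p[dose] = float(stats.shapiro(values).pvalue)
    normal = all(p >= alpha for p in normality_p.values())
    samples = list(groups.values())
    if normal:
        variance_test = "levene"
        variance_p = float(stats.levene(*samples).pvalue)
    else:
        variance_test = "fligner"
        variance_p = float(stats.fligner(*samples).pvalue)
    return AssumptionReport(
        normal=normal,
        homoscedastic=variance_p >= alpha,
        normality_p=normality_p,
        variance_test=variance_test,
        variance_p=variance_p,
    )


def welch_anova(*samples: np.ndarray) -> tuple[float, float, float, float]:
    """Welch's heteroscedasticity-robust one-way ANOVA.

    Returns ``(F, df1, df2, p)``.  Standard Welch (1951) statistic with
    inverse-variance weights and the Welch–Satterthwaite denominator df.
    """
    k = len(samples)
    if k < 2:
        raise ConfigurationError("Welch ANOVA needs >= 2 groups")
    n = np.array([len(s) for s in samples], dtype=float)
    m = np.array([np.mean(s) for s in samples])
    v = np.array([np.var(s, ddof=1) for s in samples])
    if np.any(v == 0):
        raise DegenerateDataError("zero within-group variance in Welch ANOVA")
    w = n / v
    grand = np.sum(w * m) / np.sum(w)
    num = np.sum(w * (m - grand) ** 2) / (k - 1)
    lam = np.sum((1 - w / np.sum(w)) ** 2 / (n - 1))
    den = 1 + 2 * (k - 2) / (k**2 - 1) * lam
    f_stat = num / den
    df1 = k - 1.0
    df2 = (k**2 - 1) / (3 * lam)
    p = float(stats.f.sf(f_stat, df1, df2))
    return float(f_stat), df1, df2, p


def _dunn_vs_control(
    groups: dict[float, np.ndarray], control: float
) -> list[tuple[float, float, float]]:
    """Dunn's rank test of every group against the control.

    Tie-corrected z statistics on joint ranks; raw two-sided p values.
    Returns ``(group, z, p_raw)`` tuples.
    """
    doses = list(groups)
    pooled = np.concatenate([groups[d] for d in doses])
    ranks = stats.rankdata(pooled)
    n_total = len(pooled)
    # tie correction to the rank variance
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(counts**3 - counts) / (12.0 * (n_total - 1))
    rank_means: dict[float, float] = {}
    offset = 0
    for d in doses:
        size = len(groups[d])
        rank_means[d] = float(np.mean(ranks[offset : offset + size]))
        offset += size
    out = []
    n_c = len(groups[control])
    for d in doses:
        if d == control:
            continue
        n_d = len(groups[d])
        se = math.sqrt(
            (n_total * (n_total + 1) / 12.0 - tie_term) * (1.0 / n_c + 1.0 / n_d)
        )
        z = (rank_means[d] - rank_means[control]) / se
        p = 2.0 * float(stats.norm.sf(abs(z)))
        out.append((d, float(z), p))
    return out


def _tamhane_dunnett(
    groups: dict[float, np.ndarray], control: float
) -> list[tuple[float, float, float]]:
    """Welch-t comparisons against the control with Šidák family adjustment.

    The heteroscedastic many-to-one analogue of Dunnett's test: each
    comparison uses its own Welch–Satterthwaite df; the single-step Šidák
    step controls the family-wise error over the m comparisons.
    """
    doses = [d for d in groups if d != control]
    m = len(doses)
    x_c = groups[control]
    out = []
    for d in doses:
        x_t = groups[d]
        t_stat, p_raw = stats.ttest_ind(x_t, x_c, equal_var=False)
        p_adj = min(1.0, 1.0 - (1.0 - float(p_raw)) ** m)
        out.append((d, float(t_stat), p_adj))
    return out


def select_and_run(table: pd.DataFrame, alpha: float = 0.05) -> TestReport:
    """Run the assumption-driven decision tree on a treatment table.

    The control group is dilution 0 and must be present; post hoc
    comparisons are many-to-one against it only.
    """
    groups = _groups(table)
    if 0.0 not in groups:
        raise ConfigurationError("no control group (dilution_pct == 0) present")
    checks = assumption_checks(table, alpha)
    samples = [groups[d] for d in groups]
    control = 0.0
    treated = [d for d in groups if d != control]

    if checks.normal and checks.homoscedastic:
        branch = "anova_dunnett"
        omnibus_test = "one-way ANOVA"
        f_stat, p = stats.f_oneway(*samples)
        n_total = sum(len(s) for s in samples)
        df = (len(samples) - 1.0, float(n_total - len(samples)))
        # fixed rng: Dunnett's p relies on Monte Carlo multivariate-t
        # integration and must be reproducible across runs
        res = stats.dunnett(
            *[groups[d] for d in treated], control=groups[control],
            rng=np.random.default_rng(0),
        )
        posthoc_test = "dunnett"
        posthoc = [
            PosthocComparison(d, float(s), float(pv), bool(pv < alpha))
            for d, s, pv in zip(treated, res.statistic, res.pvalue)
        ]
        omnibus_stat, omnibus_p = float(f_stat), float(p)
    elif checks.normal:
        branch = "welch_tamhane_dunnett"
        omnibus_test = "Welch ANOVA"
        f_stat, df1, df2, p = welch_anova(*samples)
        df = (df1, df2)
        posthoc_test = "tamhane_dunnett"
        posthoc = [
            PosthocComparison(d, s, pv, bool(pv < alpha))
            for d, s, pv in _tamhane_dunnett(groups, control)
        ]
        omnibus_stat, omnibus_p = f_stat, float(p)
    else:
        branch = "kruskal_dunn"
        omnibus_test = "Kruskal–Wallis"
        h_stat, p = stats.kruskal(*samples)
        df = (len(samples) - 1.0,)
        raw = _dunn_vs_control(groups, control)
        rejected, p_adj, _, _ = multipletests(
            [r[2] for r in raw], alpha=alpha, method="holm"
        )
        posthoc_test = "dunn_holm"
        posthoc = [
            PosthocComparison(d, z, float(pa), bool(rej))
            for (d, z, _), pa, rej in zip(raw, p_adj, rejected)
        ]
        omnibus_stat, omnibus_p = float(h_stat), float(p)

    return TestReport(
        branch=branch,
        normality_p=checks.normality_p,
        variance_test=checks.variance_test,
        variance_p=checks.variance_p,
        omnibus_test=omnibus_test,
        omnibus_stat=omnibus_stat,
        omnibus_df=df,
        omnibus_p=omnibus_p,
        posthoc_test=posthoc_test,
        posthoc=posthoc,
        alpha=alpha,
    )


# ---------------------------------------------------------------------------
# Two-parameter log-logistic dose-response
# ---------------------------------------------------------------------------


def ll2(x: np.ndarray, b: float, e: float) -> np.ndarray:
    """LL.2 response ``1/(1 + exp(b·(ln x − ln e)))`` with f(0) = its limit.

    For ``b < 0`` the response rises from 0 at dose 0 to 1 at infinite dose;
    ``b > 0`` mirrors that.  ``e`` is the midpoint (dose of half response).
    """
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    positive = x > 0
    with np.errstate(over="ignore"):
        out[positive] = 1.0 / (
            1.0 + np.exp(b * (np.log(x[positive]) - math.log(e)))
        )
    out[~positive] = 0.0 if b < 0 else 1.0
    return out


@dataclass(frozen=True)
class DoseResponseFit:
    slope_b: float
    midpoint_e: float
    residual_ss: float
    converged: bool
    normalized: bool
    norm_min: float
    norm_max: float
    doses: np.ndarray = field(repr=False)
    response: np.ndarray = field(repr=False)

    def predict(self, dose: np.ndarray) -> np.ndarray:
        """Predicted response on the original scale."""
        f = ll2(np.asarray(dose, dtype=float), self.slope_b, self.midpoint_e)
        return self.norm_min + (self.norm_max - self.norm_min) * f


def fit_ll2(
    dose: np.ndarray, response: np.ndarray, normalize: bool = True
) -> DoseResponseFit:
    """Fit the LL.2 model by multi-start least squares.

    The control (dose 0) is represented by the model's asymptotic limit and
    excluded from the log-dose residuals.  When ``normalize`` is true the
    response is min–max scaled to [0, 1] first (the LL.2 asymptotes are
    fixed), and predictions are mapped back.  Starts span e over the
    quartiles of the positive doses and b over {±0.5, ±2}; the best residual
    sum of squares wins, ties broken by the smallest |b|.  Optimizer failure
    is reported via ``converged=False`` rather than raised.
    """
    dose = np.asarray(dose, dtype=float)
    response = np.asarray(response, dtype=float)
    if dose.shape != response.shape:
        raise ConfigurationError("dose and response must have the same length")
    pos = dose > 0
    distinct = np.unique(dose[pos])
    if len(distinct) < 3:
        raise ConfigurationError(
            f"need >= 3 distinct positive doses, got {len(distinct)}"
        )

    if normalize:
        lo, hi = float(np.min(response)), float(np.max(response))
        if hi <= lo:
            raise DegenerateDataError("response has zero range; cannot normalize")
        y = (response - lo) / (hi - lo)
    else:
        lo, hi = 0.0, 1.0
        y = response
    x_fit, y_fit = dose[pos], y[pos]

    def residuals(theta: np.ndarray) -> np.ndarray:
        return ll2(x_fit, theta[0], math.exp(theta[1])) - y_fit

    starts = [
        (b0, math.log(e0))
        for e0 in np.percentile(distinct, [25, 50, 75])
        for b0 in (-2.0, -0.5, 0.5, 2.0)
    ]
    best = None
    converged = False
    for theta0 in starts:
        try:
            sol = optimize.least_squares(residuals, theta0, method="lm")
        except Exception:
            continue
        if not np.all(np.isfinite(sol.x)):
            continue
        converged = converged or sol.success
        ss = float(2.0 * sol.cost)
        cand = (ss, abs(sol.x[0]), sol.x)
        if (
            best is None
            or ss < best[0] - 1e-12
            or (abs(ss - best[0]) <= 1e-12 and cand[1] < best[1])
        ):
            best = cand
    if best is None:
        return DoseResponseFit(
            slope_b=float("nan"),
            midpoint_e=float("nan"),
            residual_ss=float("nan"),
            converged=False,
            normalized=normalize,
            norm_min=lo,
            norm_max=hi,
            doses=dose,
            response=response,
        )
    ss, _, theta = best
    return DoseResponseFit(
        slope_b=float(theta[0]),
        midpoint_e=float(math.exp(theta[1])),
        residual_ss=ss,
        converged=converged,
        normalized=normalize,
        norm_min=lo,
        norm_max=hi,
        doses=dose,
        response=response,
    )


def lack_of_fit(fit: DoseResponseFit, table: pd.DataFrame | None = None) -> tuple[float, float]:
    """Lack-of-fit F test of the LL.2 model against the group-means model.

    Partitions the model residual SS (computed on the same normalized scale
    the model was fitted on, over all doses including the control at its
    asymptotic limit) into pure error (within replicated doses) and lack of
    fit; ``F = (SS_lof/(k−2)) / (SS_pe/(N−k))`` with k distinct doses.
    Requires replication at at least one dose.
    """
    if table is not None:
        dose = table["dilution_pct"].to_numpy(dtype=float)
        resp = table["response"].to_numpy(dtype=float)
    else:
        dose, resp = fit.doses, fit.response
    span = fit.norm_max - fit.norm_min
    y = (resp - fit.norm_min) / span if fit.normalized else resp
    pred = ll2(dose, fit.slope_b, fit.midpoint_e)

    distinct = np.unique(dose)
    n_total = len(dose)
    k = len(distinct)
    if n_total <= k:
        raise DegenerateDataError(
            "no replicated doses: pure-error SS is undefined"
        )
    ss_pe = 0.0
    ss_lof = 0.0
    for d in distinct:
        mask = dose == d
        group = y[mask]
        ss_pe += float(np.sum((group - np.mean(group)) ** 2))
        ss_lof += float(len(group) * (np.mean(group) - pred[mask][0]) ** 2)
    df_lof = max(k - 2, 1)
    df_pe = n_total - k
    tiny = 1e-12 * (1.0 + float(np.sum(y**2)))
    if ss_pe <= tiny:
        return (0.0, 1.0) if ss_lof <= tiny else (float("inf"), 0.0)
    f_stat = (ss_lof / df_lof) / (ss_pe / df_pe)
    p = float(stats.f.sf(f_stat, df_lof, df_pe))
    return float(f_stat), p


# ---------------------------------------------------------------------------
# PCA summary
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PCASummary:
    scores: np.ndarray
    loadings: np.ndarray
    explained_variance: np.ndarray
    scaled: bool
    mean: np.ndarray
    std: np.ndarray | None


def pca_summary(matrix: np.ndarray, scale: bool = True) -> PCASummary:
    """Column-centred (optionally unit-variance) PCA of samples × variables.

    Keeps every component, so the explained-variance fractions sum to 1.
    Sign convention: within each component the largest-magnitude loading is
    made positive.  ``scores @ loadings.T`` reconstructs the centred
    (scaled) data.
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ConfigurationError("need a 2-D matrix with >= 2 samples and >= 2 variables")
    if np.any(~np.isfinite(x)):
        raise ConfigurationError("matrix contains missing or non-finite values")
    mean = x.mean(axis=0)
    std = None
    xc = x - mean
    if scale:
        std = x.std(axis=0, ddof=1)
        zero = np.flatnonzero(std == 0)
        if zero.size:
            raise DegenerateDataError(
                f"constant column(s) {zero.tolist()} cannot be unit-variance scaled"
            )
        xc = xc / std
    pca = PCA(n_components=min(x.shape[0], x.shape[1]), svd_solver="full")
    scores = pca.fit_transform(xc)
    loadings = pca.components_.T  # variables × components
    # sign convention: dominant loading positive per component
    for j in range(loadings.shape[1]):
        idx = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[idx, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    total = pca.explained_variance_.sum()
    explained = pca.explained_variance_ / total
    return PCASummary(
        scores=scores,
        loadings=loadings,
        explained_variance=explained,
        scaled=scale,
        mean=mean,
        std=std,
    )
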