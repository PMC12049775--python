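"""Association and survival statistics for score/class/outcome analyses.

Group comparisons dispatch Mann-Whitney U (two groups) or Kruskal-Wallis
(three or more), two-sided; p-values are corrected with Benjamini-Hochberg.
Correlations are Pearson product-moment. Survival is analysed with
Kaplan-Meier curves and log-rank tests (univariate) and a Cox proportional
hazards model maximised by Newton iteration on the Breslow partial
likelihood (multivariable). A single-covariate binomial logistic fit is
provided for 2x2 enrichment questions, where the coefficient equals the
log odds ratio of the table.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats as sps
from statsmodels.api import GLM, add_constant
from statsmodels.genmod.families import Binomial
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)


@dataclass
class TestResult:
    statistic: float
    pvalue: float
    method: str
    n_per_group: Dict[str, int]
    p_adjusted: Optional[float] = None


def group_compare(values: Sequence[float], groups: Sequence) -> TestResult:
    """Two-sided Mann-Whitney U for two groups, Kruskal-Wallis for >= 3.

    The Mann-Whitney p-value uses scipy's exact distribution for small
    untied samples and the tie-corrected normal approximation otherwise.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if len(values) != len(groups):
        raise ValueError("values and groups must have equal length")
    labels = pd.unique(groups)
    split = [values[groups == g] for g in labels]
    sizes = {str(g): len(v) for g, v in zip(labels, split)}
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(v) == 0 for v in split):
        raise ValueError("every group must be non-empty")
    if len(labels) == 2:
        res = sps.mannwhitneyu(split[0], split[1], alternative="two-sided", method="auto")
        return TestResult(float(res.statistic), float(res.pvalue), "mann-whitney-u", sizes)
    res = sps.kruskal(*split)
    return TestResult(float(res.statistic), float(res.pvalue), "kruskal-wallis", sizes)


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving,
    monotonicity enforced)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def pearson_r(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Pearson product-moment correlation with t-distribution p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("Pearson correlation requires n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    r, p = sps.pearsonr(x, y)
    return TestResult(float(r), float(p), "pearson", {"n": len(x)})


@dataclass
class ConcordanceResult:
    fraction: float
    table: pd.DataFrame  # 2x2 contingency of binarised RNA class vs mIF status


def concordance(
    class_rna: pd.Series,
    status_mif: pd.Series,
    positive_classes: Sequence[str] = ("TLS3",),
) -> ConcordanceResult:
    """Fraction of samples on which the binarised RNA TLS class agrees with
    the mIF TLS status. The default mapping calls TLS3 positive and
    TLS1/TLS2 negative; pass ``("TLS2", "TLS3")`` for the alternative."""
    if set(class_rna.index) != set(status_mif.index):
        raise ValueError("RNA classes and mIF statuses cover different samples")
    status_mif = status_mif.loc[class_rna.index]
    rna_pos = class_rna.isin(positive_classes)
    mif_pos = status_mif == "positive"
    frac = float((rna_pos == mif_pos).mean())
    table = pd.crosstab(
        rna_pos.rename("rna_positive"), mif_pos.rename("mif_positive"), dropna=False
    )
    return ConcordanceResult(frac, table)


# ---------------------------------------------------------------------------
# Survival
# ---------------------------------------------------------------------------

@dataclass
class KMResult:
    fitters: Dict[str, KaplanMeierFitter]
    statistic: float
    pvalue: float
    medians: Dict[str, float]


def km_logrank(df: pd.DataFrame, group_col: str, time_col: str = "time_months",
               event_col: str = "event") -> KMResult:
    """Kaplan-Meier product-limit curves per group plus the log-rank test
    (chi-square on observed-minus-expected events over the shared risk
    sets; 1 df for two groups)."""
    if df[event_col].sum() < 1:
        raise ValueError("no events observed; survival comparison impossible")
    if (df[time_col] <= 0).any():
        raise ValueError("survival times must be positive")
    fitters: Dict[str, KaplanMeierFitter] = {}
    medians: Dict[str, float] = {}
    for g, grp in df.groupby(group_col, sort=True):
        kmf = KaplanMeierFitter(label=str(g))
        kmf.fit(grp[time_col], grp[event_col])
        fitters[str(g)] = kmf
        medians[str(g)] = float(kmf.median_survival_time_)
    res = multivariate_logrank_test(df[time_col], df[group_col], df[event_col])
    return KMResult(fitters, float(res.test_statistic), float(res.p_value), medians)


@dataclass
class CoxResult:
    summary: pd.DataFrame  # index covariate: coef, hr, se, ci_lower, ci_upper, z, p
    log_likelihood: float
    n: int
    n_events: int
    iterations: int
    separation_flag: bool = False

    def forest_table(self) -> str:
        """Plain-text forest table (one row per covariate)."""
        lines = [f"{'covariate':<24}{'HR':>8}{'95% CI':>20}{'p':>12}"]
        for cov, row in self.summary.iterrows():
            ci = f"[{row.ci_lower:.3f}, {row.ci_upper:.3f}]"
            lines.append(f"{cov:<24}{row.hr:>8.3f}{ci:>20}{row.p:>12.2e}")
        return "\n".join(lines)


def cox_log_partial_likelihood(
    beta: np.ndarray, X: np.ndarray, time: np.ndarray, event: np.ndarray
) -> float:
    """Breslow partial log-likelihood at beta (tied event times share the
    full risk-set denominator)."""
    ll, _, _ = _breslow_ll_grad_hess(np.asarray(beta, float), X, time, event)
    return float(ll)


def _breslow_ll_grad_hess(beta, X, time, event):
    order = np.argsort(-time, kind="stable")
    X = X[order]
    time = time[order]
    event = event[order].astype(bool)
    n, p = X.shape
    eta = X @ beta
    eta_shift = eta - eta.max()  # overflow guard; cancels in ratios, offset in ll
    w = np.exp(eta_shift)
    cum_w = np.cumsum(w)
    cum_wx = np.cumsum(w[:, None] * X, axis=0)
    cum_wxx = np.cumsum(w[:, None, None] * (X[:, :, None] * X[:, None, :]), axis=0)
    # risk set of an event at t = all subjects with time >= t: in descending
    # order that is every index up to the end of the tie group containing it
    new_grp = np.r_[True, time[1:] != time[:-1]]
    grp_id = np.cumsum(new_grp) - 1
    starts = np.flatnonzero(new_grp)
    ends = np.r_[starts[1:], n] - 1  # last index of each tie group
    idx = ends[grp_id][event]
    denom = cum_w[idx]
    ll = float(np.sum(eta_shift[event] - np.log(denom)))
    xbar = cum_wx[idx] / denom[:, None]
    grad = X[event].sum(axis=0) - xbar.sum(axis=0)
    exx = cum_wxx[idx] / denom[:, None, None]
    hess = -(exx - xbar[:, :, None] * xbar[:, None, :]).sum(axis=0)
    return ll, grad, hess


def cox_fit(
    df: pd.DataFrame,
    covariates: Sequence[str],
    time_col: str = "time_months",
    event_col: str = "event",
    tol: float = 1e-8,
    max_iter: int = 100,
) -> CoxResult:
    """Multivariable Cox proportional hazards fit.

    The Breslow partial likelihood is maximised by Newton iteration with
    step-halving until the gradient norm drops below ``tol``. Categorical
    covariates must be pre-encoded (treatment-contrast dummies; see
    :func:`encode_covariates`). Reports per-covariate beta, hazard ratio,
    Wald 95% CI and p-value.
    """
    covariates = list(covariates)
    X = df[covariates].to_numpy(dtype=float)
    time = df[time_col].to_numpy(dtype=float)
    event = df[event_col].to_numpy(dtype=float)
    n_events = int(event.sum())
    if n_events < len(covariates):
        raise ValueError(f"{n_events} events for {len(covariates)} covariates; underdetermined")
    const = X.std(axis=0) == 0
    if const.any():
        bad = [c for c, f in zip(covariates, const) if f]
        raise ValueError(f"constant covariate(s): {bad}")
    # standardise internally for conditioning; back-transform afterwards
    mu, sd = X.mean(axis=0), X.std(axis=0)
    Xs = (X - mu) / sd
    beta = np.zeros(X.shape[1])
    ll, grad, hess = _breslow_ll_grad_hess(beta, Xs, time, event)
    separation = False
    it = 0
    for it in range(1, max_iter + 1):
        if np.linalg.norm(grad) < tol:
            break
        step = np.linalg.solve(-hess, grad)
        new_beta = beta + step
        new_ll, new_grad, new_hess = _breslow_ll_grad_hess(new_beta, Xs, time, event)
        halvings = 0
        while new_ll < ll and halvings < 30:
            step /= 2.0
            new_beta = beta + step
            new_ll, new_grad, new_hess = _breslow_ll_grad_hess(new_beta, Xs, time, event)
            halvings += 1
        beta, ll, grad, hess = new_beta, new_ll, new_grad, new_hess
        if np.abs(beta).max() > 20:
            separation = True
            warnings.warn("possible complete separation: |beta| diverging", stacklevel=2)
            break
    else:
        raise RuntimeError(f"Cox Newton iteration did not converge in {max_iter} steps")
    cov_s = np.linalg.inv(-hess)
    beta_raw = beta / sd
    se_raw = np.sqrt(np.diag(cov_s)) / sd
    z = beta_raw / se_raw
    pvals = 2.0 * sps.norm.sf(np.abs(z))
    zc = sps.norm.ppf(0.975)
    summary = pd.DataFrame(
        {
            "coef": beta_raw,
            "hr": np.exp(beta_raw),
            "se": se_raw,
            "ci_lower": np.exp(beta_raw - zc * se_raw),
            "ci_upper": np.exp(beta_raw + zc * se_raw),
            "z": z,
            "p": pvals,
        },
        index=pd.Index(covariates, name="covariate"),
    )
    return CoxResult(summary, ll, len(df), n_events, it, separation)


def encode_covariates(df: pd.DataFrame, covariates: Sequence[str]) -> pd.DataFrame:
    """Treatment-contrast dummy encoding of non-numeric covariates; numeric
    columns pass through unchanged."""
    cols = df[list(covariates)]
    return pd.get_dummies(cols, drop_first=True, dtype=float)


@dataclass
class EnrichmentResult:
    coef: float  # log odds ratio
    se: float
    pvalue: float
    table: pd.DataFrame
    haldane: bool = False


def binomial_enrichment(outcome: Sequence, predictor: Sequence) -> EnrichmentResult:
    """Single-covariate binomial logistic regression.

    The fitted coefficient equals the log odds ratio of the 2x2 table. A
    table with an empty cell has an infinite MLE; it is reported with the
    Haldane-Anscombe +0.5 correction and a warning.
    """
    y = pd.Series(outcome).astype(bool)
    x = pd.Series(predictor).astype(bool)
    if y.nunique() < 2 or x.nunique() < 2:
        raise ValueError("both variables must have both levels present")
    table = pd.crosstab(y, x)
    a = float(table.loc[True, True])
    b = float(table.loc[True, False])
    c = float(table.loc[False, True])
    d = float(table.loc[False, False])
    if min(a, b, c, d) == 0:
        warnings.warn(
            "empty 2x2 cell: odds ratio infinite; using Haldane-Anscombe correction",
            stacklevel=2,
        )
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        coef = np.log(a * d / (b * c))
        se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
        p = 2.0 * sps.norm.sf(abs(coef / se))
        return EnrichmentResult(float(coef), float(se), float(p), table, haldane=True)
    model = GLM(y.to_numpy(dtype=float), add_constant(x.to_numpy(dtype=float)),
                family=Binomial())
    fit = model.fit()
    return EnrichmentResult(
        float(fit.params[1]), float(fit.bse[1]), float(fit.pvalues[1]), table
    )
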