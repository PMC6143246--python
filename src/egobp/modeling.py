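"""Linear-model building for blood pressure: base, genetic, network and
optimal models with AIC / adjusted-R-squared sequential selection.

Four model families are fitted per response (SBP or DBP, mmHg):

* **base** — age, BMI, sex (male = 1, female = 2);
* **genetic** — base plus the ACE haplotype coding entered as one block;
* **network** — base plus the square-root-transformed network measures that
  survive the keep rule;
* **optimal** — base plus haplotype block plus surviving network measures.

The keep rule is conjunctive and strict: a candidate stays only if adding it
*decreases* AIC and *increases* adjusted R-squared.  The haplotype columns
enter and leave together; individual haplotype p-values are reported but
never drive selection.

AIC uses the full Gaussian profile likelihood with the residual variance
counted as a parameter, ``AIC = n (ln(2 pi RSS / n) + 1) + 2 (k + 1)`` for
``k`` regression coefficients including the intercept — the convention of
mainstream statistical software, so absolute values are comparable across
implementations.  Model comparisons (nested F, selection) depend only on
AIC differences, where the constants cancel.

Pairwise haplotype-group contrasts use Tukey's HSD with the Kramer
correction for unequal group sizes; adjusted p-values come from the
studentized-range distribution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm

logger = logging.getLogger(__name__)

BASE_COVARIATES = ("age", "bmi", "sex")
HAPLOTYPE_BLOCK = ("dosage_hap2", "dosage_hap3", "dosage_hap4")
NETWORK_TERMS = ("sqrt_mean_betweenness", "sqrt_mean_distance",
                 "sqrt_pct_family", "sqrt_pct_central_family")


class ModelingError(ValueError):
    pass


@dataclass(frozen=True)
class DesignSpec:
    """What to fit: response column, fixed covariates, candidate blocks.

    Candidate blocks are tried in order: the haplotype coding block first,
    then each network measure singly.
    """
    response: str
    covariates: tuple = BASE_COVARIATES
    haplotype_block: tuple = HAPLOTYPE_BLOCK
    network_terms: tuple = NETWORK_TERMS


@dataclass(frozen=True)
class FitResult:
    response: str
    terms: tuple                  # design columns, intercept excluded
    params: pd.Series             # indexed by 'Intercept' + terms
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    n: int
    k: int                        # coefficients including intercept
    rss: float
    r_squared: float
    adj_r_squared: float
    aic: float

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"coefficient": self.params, "std_error": self.bse,
                             "t": self.tvalues, "p_value": self.pvalues})


def gaussian_aic(n: int, rss: float, k: int) -> float:
    """Full-likelihood Gaussian AIC with sigma counted as a parameter."""
    return float(n * (np.log(2.0 * np.pi * rss / n) + 1.0) + 2.0 * (k + 1))


def ols_fit(table: pd.DataFrame, response: str, terms: Sequence[str]) -> FitResult:
    """OLS of ``response`` on ``terms`` plus an intercept.

    Coefficients come from a pseudoinverse least-squares solve; standard
    errors from ``sigma^2 (X'X)^-1`` with ``sigma^2 = RSS / (n - k)``; t and
    two-sided p from the t(n - k) reference.  Rank-deficient designs raise,
    naming the aliased columns.
    """
    terms = tuple(terms)
    missing = [c for c in (response, *terms) if c not in table.columns]
    if missing:
        raise ModelingError(f"columns not in table: {missing}")
    y = table[response].to_numpy(dtype=float)
    X = sm.add_constant(table[list(terms)].astype(float), has_constant="add")
    X.columns = ["Intercept", *terms]
    n, k = X.shape
    if n <= k:
        raise ModelingError(f"n = {n} <= k = {k}: cannot fit")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < k:
        aliased = _aliased_columns(X.to_numpy(), list(X.columns))
        raise ModelingError(f"rank-deficient design; aliased columns: {aliased}")
    res = sm.OLS(y, X).fit()
    rss = float(res.ssr)
    return FitResult(response=response, terms=terms,
                     params=res.params, bse=res.bse,
                     tvalues=res.tvalues, pvalues=res.pvalues,
                     n=n, k=k, rss=rss,
                     r_squared=float(res.rsquared),
                     adj_r_squared=float(res.rsquared_adj),
                     aic=gaussian_aic(n, rss, k))


def _aliased_columns(x: np.ndarray, names: list) -> list:
    """Columns linearly dependent on their predecessors (QR pivot check)."""
    aliased = []
    kept = np.empty((x.shape[0], 0))
    for j, name in enumerate(names):
        cand = np.column_stack([kept, x[:, j]])
        if np.linalg.matrix_rank(cand) == kept.shape[1]:
            aliased.append(name)
        else:
            kept = cand
    return aliased


def nested_f_test(fit_reduced: FitResult, fit_full: FitResult):
    """Extra-sum-of-squares F test of nested linear models.

    Returns ``(F, df1, df2, p)``.
    """
    if not set(fit_reduced.terms) <= set(fit_full.terms):
        raise ModelingError("models are not nested")
    if fit_reduced.n != fit_full.n:
        raise ModelingError("models fitted on different row counts")
    df1 = fit_full.k - fit_reduced.k
    df2 = fit_full.n - fit_full.k
    if df1 == 0:
        return 0.0, 0, df2, 1.0
    if fit_full.rss <= 0:
        return float("inf"), df1, df2, 0.0
    f = ((fit_reduced.rss - fit_full.rss) / df1) / (fit_full.rss / df2)
    p = float(st.f.sf(f, df1, df2))
    return float(f), df1, df2, p


def bonferroni_threshold(alpha: float = 0.05, m: int = 5) -> float:
    """Per-test significance threshold alpha / m.

    Default m = 5: one haplotype block plus four network measures.
    """
    if not (0 < alpha < 1):
        raise ModelingError(f"alpha {alpha} outside (0, 1)")
    if m < 1:
        raise ModelingError(f"m must be >= 1, got {m}")
    return alpha / m


@dataclass(frozen=True)
class SelectionStep:
    candidate: tuple
    aic_before: float
    aic_after: float
    adj_r2_before: float
    adj_r2_after: float
    kept: bool


def _keep(aic_before, aic_after, adj_before, adj_after) -> bool:
    """Strict conjunctive keep rule: AIC down AND adjusted R-squared up."""
    return bool(aic_after < aic_before) and bool(adj_after > adj_before)


def _select(table, response, fixed_terms, candidates):
    """Sequentially try candidate blocks on top of ``fixed_terms``."""
    current = list(fixed_terms)
    fit = ols_fit(table, response, current)
    trace = []
    for block in candidates:
        block = tuple(block)
        trial = ols_fit(table, response, current + list(block))
        step = SelectionStep(candidate=block, aic_before=fit.aic, aic_after=trial.aic,
                             adj_r2_before=fit.adj_r_squared,
                             adj_r2_after=trial.adj_r_squared,
                             kept=_keep(fit.aic, trial.aic,
                                        fit.adj_r_squared, trial.adj_r_squared))
        trace.append(step)
        if step.kept:
            current = current + list(block)
            fit = trial
    return fit, current, trace


def sequential_selection(design: DesignSpec, table: pd.DataFrame):
    """Fit the base / genetic / network / optimal models with a full audit.

    Returns ``(fits, trace)`` where ``fits`` maps model name to
    :class:`FitResult` and ``trace`` maps ``"network"`` / ``"optimal"`` to the
    list of :class:`SelectionStep` taken.  The genetic model always carries
    the whole haplotype block; selection for the optimal model starts from
    the base covariates and tries the haplotype block first, then each
    network measure in declared order.
    """
    base_terms = list(design.covariates)
    extra = [c for c in ("medicated",) if c in table.columns]
    base_terms += extra

    # constant candidate columns (e.g. a haplotype absent from the cohort)
    # carry no information and would alias the intercept: drop them
    def _informative(cols):
        kept = tuple(c for c in cols if table[c].nunique() > 1)
        dropped = set(cols) - set(kept)
        if dropped:
            logger.warning("%s: dropping constant design columns %s",
                           design.response, sorted(dropped))
        return kept

    hap_block = _informative(design.haplotype_block)
    network_terms = _informative(design.network_terms)

    fits = {}
    fits["base"] = ols_fit(table, design.response, base_terms)
    fits["genetic"] = ols_fit(table, design.response,
                              base_terms + list(hap_block))
    net_fit, _, net_trace = _select(table, design.response, base_terms,
                                    [(t,) for t in network_terms])
    fits["network"] = net_fit
    candidates = [hap_block] if hap_block else []
    candidates += [(t,) for t in network_terms]
    opt_fit, opt_terms, opt_trace = _select(table, design.response, base_terms,
                                            candidates)
    fits["optimal"] = opt_fit
    trace = {"network": net_trace, "optimal": opt_trace}
    logger.info("%s optimal terms: %s", design.response, opt_terms)
    return fits, trace


@dataclass(frozen=True)
class TukeyResult:
    anova_f: float
    anova_p: float
    df_between: int
    df_within: int
    pairs: pd.DataFrame   # group_a, group_b, mean_diff, se, q, p_adjusted


def tukey_kramer(groups: Sequence, values: Sequence) -> TukeyResult:
    """One-way ANOVA plus Tukey–Kramer all-pairs comparisons.

    ``q_ij = |mean_i - mean_j| / sqrt(MSW (1/n_i + 1/n_j) / 2)`` with adjusted
    p from the studentized-range distribution on (k groups, N - k df).
    Singleton groups are allowed (Kramer correction) as long as the pooled
    within-group degrees of freedom are positive.
    """
    groups = pd.Series(list(groups))
    values = np.asarray(list(values), dtype=float)
    labels = groups.unique()
    k = len(labels)
    if k < 2:
        raise ModelingError("need at least 2 groups")
    n_i = np.array([(groups == g).sum() for g in labels])
    means = np.array([values[groups == g].mean() for g in labels])
    n_total = len(values)
    df_within = n_total - k
    if df_within < 1:
        raise ModelingError("no within-group degrees of freedom")
    ssw = sum(((values[groups == g] - m) ** 2).sum() for g, m in zip(labels, means))
    grand = values.mean()
    ssb = float((n_i * (means - grand) ** 2).sum())
    msw = ssw / df_within
    msb = ssb / (k - 1)
    f = msb / msw if msw > 0 else float("inf")
    p_anova = float(st.f.sf(f, k - 1, df_within))

    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            diff = means[i] - means[j]
            se = np.sqrt(msw * (1.0 / n_i[i] + 1.0 / n_i[j]) / 2.0)
            q = abs(diff) / se if se > 0 else float("inf")
            p_adj = float(st.studentized_range.sf(q, k, df_within))
            rows.append({"group_a": labels[i], "group_b": labels[j],
                         "mean_diff": float(diff), "se": float(se),
                         "q": float(q), "p_adjusted": p_adj})
    return TukeyResult(anova_f=float(f), anova_p=p_anova, df_between=k - 1,
                       df_within=df_within, pairs=pd.DataFrame(rows))


def screen_interactions(table: pd.DataFrame, focal: str, response: str,
                        optimal_terms: Sequence[str], alpha: float = 0.01):
    """Interaction and change-point screen for one focal term.

    For every other term of the optimal model, adds ``focal x term`` to the
    model and reports the nested F test.  Also scans a single change point on
    the focal term (indicator ``focal > c`` over a grid of observed values,
    best split by RSS) and reports the likelihood-ratio statistic with a
    chi-squared(1) reference (anti-conservative under the scan; meant as a
    flag, not a calibrated test).
    """
    if focal not in table.columns:
        raise ModelingError(f"focal term {focal!r} not in table")
    optimal_terms = list(optimal_terms)
    base_fit = ols_fit(table, response, optimal_terms)
    rows = []
    for term in optimal_terms:
        if term == focal:
            continue
        col = f"{focal}:{term}"
        aug = table.copy()
        aug[col] = aug[focal] * aug[term]
        full = ols_fit(aug, response, optimal_terms + [col])
        f, df1, df2, p = nested_f_test(base_fit, full)
        rows.append({"test": "interaction", "term": term, "stat": f,
                     "p_value": p, "flagged": p < alpha})
    interactions = pd.DataFrame(rows)

    vals = np.unique(table[focal].to_numpy(dtype=float))
    cuts = vals[:-1] if len(vals) > 1 else np.array([])
    if len(cuts) > 32:
        # thin the scan to an even quantile grid of observed values
        cuts = np.unique(np.quantile(cuts, np.linspace(0, 1, 32),
                                     method="nearest"))
    best = None
    n = len(table)
    for c in cuts:
        aug = table.copy()
        aug["_above"] = (aug[focal] > c).astype(float)
        try:
            fit = ols_fit(aug, response, optimal_terms + ["_above"])
        except ModelingError:
            continue
        if best is None or fit.rss < best[1]:
            best = (float(c), fit.rss)
    if best is None:
        threshold = {"cut": float("nan"), "lr": 0.0, "p_value": 1.0, "flagged": False}
    else:
        lr = n * np.log(base_fit.rss / best[1])
        p = float(st.chi2.sf(lr, 1))
        threshold = {"cut": best[0], "lr": float(lr), "p_value": p,
                     "flagged": p < alpha}
    return {"interactions": interactions, "threshold": threshold}
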