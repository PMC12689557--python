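"""Cohort-level gene screen: differential expression, Cox selection, KM strata.

The screen runs the classical pipeline upstream of the network: a per-gene
Welch t-test between tumor and normal samples with Benjamini–Hochberg
adjustment, Cox proportional-hazards fitting of candidate genes by
Newton–Raphson on the Breslow partial likelihood, greedy stepwise selection
by AIC, and Kaplan–Meier stratification of samples by the median of the
fitted risk score with a log-rank test between the strata.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "differential_expression",
    "CoxModel",
    "cox_fit",
    "cox_null_log_likelihood",
    "stepwise_aic_select",
    "RiskStratification",
    "risk_stratify",
]


# ---------------------------------------------------------------------------
# differential expression
# ---------------------------------------------------------------------------

def differential_expression(
    expression: pd.DataFrame,
    group_labels: pd.Series,
    fc_threshold: float = 1.0,
    p_threshold: float = 0.05,
    use_adjusted: bool = True,
) -> pd.DataFrame:
    """Per-gene Welch t-test of tumor vs normal on log2 intensities.

    Returns a table with ``log2FC`` (tumor minus normal mean log2),
    ``p_value``, ``adjusted_p`` (Benjamini–Hochberg) and ``direction`` in
    {up, down, ns}; a gene passes when |log2FC| > ``fc_threshold`` and the
    (adjusted, by default) p-value is below ``p_threshold``.  Genes with zero
    variance in both groups get p = 1 and are flagged.
    """
    tumor = group_labels.index[group_labels == "tumor"]
    normal = group_labels.index[group_labels == "normal"]
    if len(tumor) < 2 or len(normal) < 2:
        raise ValueError("need >=2 samples per group")
    lt = np.log2(np.maximum(expression[tumor].values, 1e-300))
    ln = np.log2(np.maximum(expression[normal].values, 1e-300))
    log2fc = lt.mean(axis=1) - ln.mean(axis=1)
    with np.errstate(all="ignore"):
        res = stats.ttest_ind(lt, ln, axis=1, equal_var=False)
        pvals = np.asarray(res.pvalue, dtype=float)
    zero_var = (lt.std(axis=1) == 0) & (ln.std(axis=1) == 0)
    pvals[~np.isfinite(pvals)] = 1.0
    pvals[zero_var] = 1.0
    from statsmodels.stats.multitest import multipletests
    adj = multipletests(pvals, method="fdr_bh")[1]
    crit = adj if use_adjusted else pvals
    passed = (np.abs(log2fc) > fc_threshold) & (crit < p_threshold)
    direction = np.where(passed, np.where(log2fc > 0, "up", "down"), "ns")
    return pd.DataFrame(
        {
            "log2FC": log2fc,
            "p_value": pvals,
            "adjusted_p": adj,
            "direction": direction,
            "zero_variance": zero_var,
        },
        index=expression.index,
    )


# ---------------------------------------------------------------------------
# Cox proportional hazards (Breslow partial likelihood, Newton–Raphson)
# ---------------------------------------------------------------------------

@dataclass
class CoxModel:
    """A fitted proportional-hazards model for a gene set."""

    covariates: list
    beta: pd.Series
    se: pd.Series
    hr: pd.Series
    ci_lower: pd.Series
    ci_upper: pd.Series
    log_likelihood: float
    aic: float
    n: int
    n_events: int
    converged: bool = True
    n_iter: int = 0
    warnings: list = field(default_factory=list)

    def risk_scores(self, X: pd.DataFrame) -> pd.Series:
        """Linear predictor Σ β_g x_g for each sample (0 for the null model)."""
        if not self.covariates:
            return pd.Series(0.0, index=X.index)
        return X[self.covariates] @ self.beta


def _breslow_stats(beta, X, time, event, need_hess=True):
    """Log partial likelihood, score and observed information (Breslow ties)."""
    order = np.argsort(-time, kind="stable")
    Xs, ts, es = X[order], time[order], event[order]
    n, k = Xs.shape
    lp = Xs @ beta
    lp_c = lp - lp.max()
    w = np.exp(lp_c)
    S0 = np.cumsum(w)
    S1 = np.cumsum(w[:, None] * Xs, axis=0)
    # risk set of i = all samples with t >= t_i: last index of i's tie group
    last = np.searchsorted(-ts, -ts, side="right") - 1
    ev = es == 1
    r = last[ev]
    ll = float(np.sum(lp_c[ev] - np.log(S0[r])))
    xbar = S1[r] / S0[r, None]
    grad = (Xs[ev] - xbar).sum(axis=0)
    hess = None
    if need_hess:
        S2 = np.cumsum(w[:, None, None] * (Xs[:, :, None] * Xs[:, None, :]), axis=0)
        V = S2[r] / S0[r, None, None] - xbar[:, :, None] * xbar[:, None, :]
        hess = -V.sum(axis=0)
    return ll, grad, hess


def cox_null_log_likelihood(time, event) -> float:
    """Breslow log partial likelihood of the model with no covariates."""
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    ll, _, _ = _breslow_stats(np.zeros(1), np.zeros((len(time), 1)), time, event,
                              need_hess=False)
    return ll


def cox_fit(
    survival: pd.DataFrame,
    covariates: pd.DataFrame | None,
    max_iter: int = 100,
    tol: float = 1e-8,
    beta_cap: float = 15.0,
) -> CoxModel:
    """Fit a Cox model by Newton–Raphson with step-halving.

    ``survival`` needs columns ``time`` and ``event``; ``covariates`` is a
    samples × genes frame aligned to it (``None`` or empty fits the null
    model).  Constant covariates are dropped with a warning.  Convergence is
    max |score| < ``tol`` or ``max_iter`` iterations; monotone likelihood
    (a coefficient running away) is flagged and the coefficient capped.
    Standard errors come from the observed information; Wald 95% intervals.
    """
    time = survival["time"].values.astype(float)
    event = survival["event"].values.astype(int)
    n, n_events = len(time), int(event.sum())
    if n_events < 1:
        raise ValueError("cox_fit requires at least one event")

    notes: list = []
    names: list = []
    if covariates is not None and covariates.shape[1] > 0:
        covariates = covariates.loc[survival.index]
        for c in covariates.columns:
            vals = covariates[c].values.astype(float)
            if not np.all(np.isfinite(vals)):
                raise ValueError(f"non-finite covariate {c!r}")
            if np.ptp(vals) == 0:
                notes.append(f"dropped constant covariate {c!r}")
                warnings.warn(notes[-1])
            else:
                names.append(c)
    empty = pd.Series(dtype=float)
    if not names:
        ll = cox_null_log_likelihood(time, event)
        return CoxModel([], empty, empty, empty, empty, empty,
                        ll, -2 * ll, n, n_events, warnings=notes)

    X = covariates[names].values.astype(float)
    k = len(names)
    beta = np.zeros(k)
    ll, grad, hess = _breslow_stats(beta, X, time, event)
    converged, it = False, 0
    for it in range(1, max_iter + 1):
        if np.max(np.abs(grad)) < tol:
            converged = True
            break
        try:
            step = np.linalg.solve(hess, -grad)
        except np.linalg.LinAlgError:
            step = np.linalg.pinv(hess) @ (-grad)
        # step-halving: never accept a step that lowers the partial likelihood
        factor = 1.0
        for _ in range(30):
            cand = beta + factor * step
            ll_new, grad_new, hess_new = _breslow_stats(cand, X, time, event)
            if ll_new >= ll - 1e-12:
                break
            factor /= 2.0
        beta, ll, grad, hess = cand, ll_new, grad_new, hess_new
        if np.max(np.abs(beta)) > beta_cap:
            beta = np.clip(beta, -beta_cap, beta_cap)
            ll, grad, hess = _breslow_stats(beta, X, time, event)
            notes.append("monotone likelihood suspected: coefficient capped")
            warnings.warn(notes[-1])
            break
    else:
        it = max_iter
    if np.max(np.abs(grad)) < tol:
        converged = True

    info = -hess
    try:
        cov = np.linalg.inv(info)
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        se = np.full(k, np.nan)
        notes.append("singular information matrix")
    z = stats.norm.ppf(0.975)
    beta_s = pd.Series(beta, index=names)
    se_s = pd.Series(se, index=names)
    return CoxModel(
        covariates=names,
        beta=beta_s,
        se=se_s,
        hr=np.exp(beta_s),
        ci_lower=np.exp(beta_s - z * se_s),
        ci_upper=np.exp(beta_s + z * se_s),
        log_likelihood=ll,
        aic=2 * k - 2 * ll,
        n=n,
        n_events=n_events,
        converged=converged,
        n_iter=it,
        warnings=notes,
    )


def stepwise_aic_select(
    survival: pd.DataFrame,
    covariates: pd.DataFrame,
    candidate_genes=None,
    direction: str = "backward",
) -> CoxModel:
    """Greedy stepwise Cox-model selection minimizing AIC.

    Backward (default) starts from the full candidate set and removes the
    gene whose removal lowers AIC most; forward starts from the null model
    and adds greedily.  Equal-AIC ties resolve toward the smaller model, and
    candidates are processed in sorted-id order so the search is
    deterministic.
    """
    if candidate_genes is None:
        candidate_genes = list(covariates.columns)
    candidates = sorted(candidate_genes)
    if not candidates:
        raise ValueError("candidate set is empty")
    n_events = int(survival["event"].sum())
    if n_events <= len(candidates):
        warnings.warn(
            f"{n_events} events for {len(candidates)} candidates: selection may be unstable"
        )

    def fit(genes):
        sub = covariates[list(genes)] if genes else None
        return cox_fit(survival, sub)

    if direction not in {"backward", "forward"}:
        raise ValueError("direction must be 'backward' or 'forward'")

    if direction == "backward":
        current = list(candidates)
        model = fit(current)
        improved = True
        while improved and current:
            improved = False
            best_aic, best_genes, best_model = model.aic, None, None
            for g in current:  # sorted order
                trial = [x for x in current if x != g]
                m = fit(trial)
                if m.aic <= best_aic:   # tie -> smaller model wins
                    best_aic, best_genes, best_model = m.aic, trial, m
            if best_genes is not None:
                current, model, improved = best_genes, best_model, True
        return model
    # forward
    current: list = []
    model = fit(current)
    remaining = list(candidates)
    improved = True
    while improved and remaining:
        improved = False
        best_aic, best_gene, best_model = model.aic, None, None
        for g in remaining:
            m = fit(sorted(current + [g]))
            if m.aic < best_aic:        # tie -> do not grow the model
                best_aic, best_gene, best_model = m.aic, g, m
        if best_gene is not None:
            current.append(best_gene)
            remaining.remove(best_gene)
            model, improved = best_model, True
    return model


# ---------------------------------------------------------------------------
# risk stratification
# ---------------------------------------------------------------------------

@dataclass
class RiskStratification:
    """Median-split risk groups with KM curves and a log-rank comparison."""

    scores: pd.Series
    groups: pd.Series                 # sample -> {"high", "low"}
    km_curves: dict                   # group -> DataFrame(time, survival)
    logrank_chi2: float
    p_value: float


def risk_stratify(model: CoxModel, covariates: pd.DataFrame,
                  survival: pd.DataFrame) -> RiskStratification:
    """Split samples at the median risk score and compare strata by log-rank.

    The split is rank-based so the two groups differ in size by at most one;
    identical scores for all samples make stratification meaningless and
    raise an error.  Kaplan–Meier curves use the product-limit estimator.
    """
    from lifelines import KaplanMeierFitter
    from lifelines.statistics import logrank_test

    scores = model.risk_scores(covariates.loc[survival.index])
    if np.ptp(scores.values) == 0:
        raise ValueError("all risk scores identical: cannot stratify")
    ranks = stats.rankdata(scores.values, method="ordinal")
    high = ranks > len(scores) / 2
    groups = pd.Series(np.where(high, "high", "low"), index=scores.index)

    km_curves = {}
    for g in ("low", "high"):
        mask = groups == g
        kmf = KaplanMeierFitter()
        kmf.fit(survival.loc[mask.values, "time"], survival.loc[mask.values, "event"])
        sf = kmf.survival_function_
        km_curves[g] = pd.DataFrame(
            {"time": sf.index.values, "survival": sf.iloc[:, 0].values}
        )
    res = logrank_test(
        survival.loc[(groups == "high").values, "time"],
        survival.loc[(groups == "low").values, "time"],
        event_observed_A=survival.loc[(groups == "high").values, "event"],
        event_observed_B=survival.loc[(groups == "low").values, "event"],
    )
    return RiskStratification(
        scores=scores,
        groups=groups,
        km_curves=km_curves,
        logrank_chi2=float(res.test_statistic),
        p_value=float(res.p_value),
    )
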