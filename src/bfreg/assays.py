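"""Closed-form validation statistics: limiting dilution, TGI, tumor volume, ΔΔCT.

- Limiting-dilution analysis fits the single-hit Poisson model
  P(negative well) = exp(−f·dose) by binomial regression with a
  complementary log-log link and log-dose offset, giving the sphere-forming
  (stem-like) cell frequency f with a Wald 95% interval on log f.
- Tumor growth inhibition: TGI(%) = (1 − mean treated weight / mean control
  weight) × 100.
- Tumor volume: (length × width²)/2 in mm³.
- Relative expression by qPCR: 2^−ΔΔCt with a reference gene and a control
  group.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["LDAFit", "elda_fit", "lda_log_likelihood", "tgi", "tumor_volume", "ddct"]


@dataclass
class LDAFit:
    """Estimated stem-cell frequency with 95% confidence bounds."""

    f_hat: float
    ci_lower: float
    ci_upper: float
    display: str
    flagged: bool = False
    note: str = ""


def lda_log_likelihood(f: float, data: pd.DataFrame) -> float:
    """Binomial log likelihood of well counts under P(positive)=1−exp(−f·dose)."""
    d = data["dose"].values.astype(float)
    n = data["wells"].values.astype(int)
    k = data["positive"].values.astype(int)
    p = 1.0 - np.exp(-f * d)
    p = np.clip(p, 1e-300, 1 - 1e-16)
    return float(np.sum(k * np.log(p) + (n - k) * np.log1p(-p)))


def elda_fit(data: pd.DataFrame, ci_method: str = "wald") -> LDAFit:
    """Limiting-dilution estimate of the active-cell frequency.

    ``data`` needs columns ``dose`` (cells per well), ``wells`` and
    ``positive``.  The fit is a complementary log-log binomial regression
    with log(dose) offset, whose intercept is log f.  95% CI by Wald interval
    on log f (default) or by profile likelihood (``ci_method="lr"``).

    All wells positive at every dose leaves f unbounded (error); all wells
    negative gives f̂ = 0 with an upper bound only (flagged).
    """
    import statsmodels.api as sm

    required = {"dose", "wells", "positive"}
    if not required <= set(data.columns):
        raise ValueError(f"data must have columns {sorted(required)}")
    if len(data["dose"].unique()) < 2:
        raise ValueError("need >=2 distinct doses")
    if (data["positive"] > data["wells"]).any():
        raise ValueError("positive wells exceed total wells")
    n_pos = int(data["positive"].sum())
    n_tot = int(data["wells"].sum())
    if n_pos == n_tot:
        raise ValueError("all wells positive at every dose: frequency unbounded")
    if n_pos == 0:
        # likelihood exp(−f Σ dose·wells): 95% upper bound where it drops to 5%
        exposure = float((data["dose"] * data["wells"]).sum())
        upper = -np.log(0.05) / exposure
        return LDAFit(0.0, 0.0, upper, "0 (upper bound only)", flagged=True,
                      note="no positive wells: upper bound only")

    endog = np.column_stack([data["positive"], data["wells"] - data["positive"]])
    exog = np.ones((len(data), 1))
    offset = np.log(data["dose"].values.astype(float))
    glm = sm.GLM(endog, exog,
                 family=sm.families.Binomial(link=sm.families.links.CLogLog()),
                 offset=offset)
    res = glm.fit()
    logf = float(res.params[0])
    f_hat = float(np.exp(logf))

    if ci_method == "wald":
        se = float(res.bse[0])
        lo, hi = np.exp(logf - 1.96 * se), np.exp(logf + 1.96 * se)
    elif ci_method == "lr":
        from scipy.optimize import brentq
        ll_hat = lda_log_likelihood(f_hat, data)
        target = ll_hat - 3.841459 / 2.0

        def dev(f):
            return lda_log_likelihood(f, data) - target

        lo = brentq(dev, 1e-12, f_hat) if dev(1e-12) < 0 else 1e-12
        hi = brentq(dev, f_hat, 1.0 - 1e-12)
        lo, hi = float(lo), float(hi)
    else:
        raise ValueError("ci_method must be 'wald' or 'lr'")
    return LDAFit(
        f_hat=f_hat,
        ci_lower=float(lo),
        ci_upper=float(hi),
        display=f"1/{1.0 / f_hat:.1f}",
    )


def tgi(control_weights, treated_weights) -> float:
    """Tumor growth inhibition (%) = (1 − mean treated / mean control) × 100."""
    control = np.asarray(control_weights, dtype=float)
    treated = np.asarray(treated_weights, dtype=float)
    if control.size == 0 or treated.size == 0:
        raise ValueError("empty group")
    if control.mean() <= 0:
        raise ValueError("control mean weight must be positive")
    return float((1.0 - treated.mean() / control.mean()) * 100.0)


def tumor_volume(length: float, width: float) -> float:
    """Tumor volume (mm³) from caliper length and width: L·W²/2."""
    if length <= 0 or width <= 0:
        raise ValueError("dimensions must be positive")
    if width > length:
        warnings.warn("width exceeds length: check measurement orientation")
    return float(length * width ** 2 / 2.0)


def ddct(records: pd.DataFrame) -> dict:
    """Relative expression 2^−ΔΔCt from a qPCR cycle-threshold table.

    ``records`` needs columns ``Ct_target``, ``Ct_reference`` and ``group``
    (values "control"/"treated").  ΔCt = Ct_target − Ct_reference per sample,
    ΔΔCt = mean ΔCt(treated) − mean ΔCt(control).  Returns the group-level
    fold change plus per-sample fold changes of the treated group relative to
    the control-group mean ΔCt.
    """
    for col in ("Ct_target", "Ct_reference", "group"):
        if col not in records.columns:
            raise ValueError(f"missing column {col!r}")
    ct = records[["Ct_target", "Ct_reference"]].astype(float)
    if not np.all(np.isfinite(ct.values)) or (ct.values <= 0).any():
        raise ValueError("Ct values must be finite and positive")
    dct = ct["Ct_target"] - ct["Ct_reference"]
    is_ctrl = records["group"] == "control"
    is_trt = records["group"] == "treated"
    if is_ctrl.sum() < 1 or is_trt.sum() < 1:
        raise ValueError("need >=1 control and >=1 treated sample")
    ddct_val = dct[is_trt].mean() - dct[is_ctrl].mean()
    return {
        "ddct": float(ddct_val),
        "fold_change": float(2.0 ** (-ddct_val)),
        "per_sample_fold_change": (2.0 ** (-(dct[is_trt] - dct[is_ctrl].mean()))).tolist(),
    }
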