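"""Chou–Talalay median-effect analysis and the combination index.

The median-effect equation fa/fu = (D/Dm)^m linearizes to

    log10(fa/(1−fa)) = m·log10(D) − m·log10(Dm),

so (m, Dm) come from ordinary least squares on the transformed points.  The
combination index at an observed combination effect fa is the two-term
(mutually exclusive) form CI = d1/DxA(fa) + d2/DxB(fa), where Dx is the
single-drug dose producing fa; CI < 1 is synergy, ≈ 1 additivity, > 1
antagonism.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MedianEffectFit",
    "CIResult",
    "fit_median_effect",
    "median_effect_fa",
    "dose_for_effect",
    "combination_index",
    "fa_ci_curve",
    "fa_from_viability",
]

ADDITIVE_TOL = 1e-9


@dataclass
class MedianEffectFit:
    """(m, Dm, r): slope, median-effect dose and linear-fit correlation."""

    m: float
    Dm: float
    r: float
    n_points: int = 0

    def __post_init__(self):
        if self.Dm <= 0:
            raise ValueError("Dm must be positive")


@dataclass
class CIResult:
    d1: float
    d2: float
    fa: float
    ci: float
    classification: str


def fa_from_viability(viability_percent) -> np.ndarray:
    """Fraction affected from percent viability: fa = 1 − v/100."""
    return 1.0 - np.asarray(viability_percent, dtype=float) / 100.0


def fit_median_effect(points) -> MedianEffectFit:
    """Least-squares fit of the linearized median-effect equation.

    ``points`` is an iterable of (dose, fa) or a DataFrame with columns
    ``dose`` and ``fa``.  Points with fa outside (0, 1) are excluded with a
    warning (the transform is undefined there); at least two usable points
    with distinct doses are required.
    """
    if isinstance(points, pd.DataFrame):
        points = list(zip(points["dose"], points["fa"]))
    pts = [(float(d), float(f)) for d, f in points]
    usable = [(d, f) for d, f in pts if 0.0 < f < 1.0]
    if len(usable) < len(pts):
        warnings.warn(f"excluded {len(pts) - len(usable)} points with fa outside (0,1)")
    if len(usable) < 2 or len({d for d, _ in usable}) < 2:
        raise ValueError("need >=2 usable points with distinct positive doses")
    d = np.array([p[0] for p in usable])
    f = np.array([p[1] for p in usable])
    if (d <= 0).any():
        raise ValueError("doses must be positive")
    x = np.log10(d)
    y = np.log10(f / (1.0 - f))
    res = stats.linregress(x, y)
    m = float(res.slope)
    if m <= 0:
        raise ValueError(f"non-positive median-effect slope m={m:.4g}")
    Dm = 10.0 ** (-res.intercept / m)
    return MedianEffectFit(m=m, Dm=float(Dm), r=float(res.rvalue), n_points=len(usable))


def median_effect_fa(fit: MedianEffectFit, dose) -> np.ndarray:
    """Predicted fraction affected at a dose under the fitted model."""
    r = (np.asarray(dose, dtype=float) / fit.Dm) ** fit.m
    return r / (1.0 + r)


def dose_for_effect(fit: MedianEffectFit, fa: float) -> float:
    """Dx = Dm · (fa/(1−fa))^(1/m), the dose producing effect level fa."""
    if not 0.0 < fa < 1.0:
        raise ValueError("fa must be in (0, 1)")
    return float(fit.Dm * (fa / (1.0 - fa)) ** (1.0 / fit.m))


def _classify(ci: float) -> str:
    if abs(ci - 1.0) <= ADDITIVE_TOL:
        return "additive"
    return "synergy" if ci < 1.0 else "antagonism"


def combination_index(fit_a: MedianEffectFit, fit_b: MedianEffectFit,
                      combo) -> CIResult:
    """Two-term combination index of a (d1, d2, fa) observation.

    CI = d1/DxA(fa) + d2/DxB(fa) with Dx from each drug's median-effect fit.
    """
    d1, d2, fa = (float(v) for v in combo)
    if fit_a.m <= 0 or fit_b.m <= 0:
        raise ValueError("degenerate median-effect fit (m <= 0)")
    ci = d1 / dose_for_effect(fit_a, fa) + d2 / dose_for_effect(fit_b, fa)
    return CIResult(d1=d1, d2=d2, fa=fa, ci=float(ci), classification=_classify(ci))


def fa_ci_curve(fit_a: MedianEffectFit, fit_b: MedianEffectFit, combos) -> pd.DataFrame:
    """CI per combination point, sorted by fa (the Fa–CI plot table)."""
    if isinstance(combos, pd.DataFrame):
        combos = list(zip(combos["d1"], combos["d2"], combos["fa"]))
    combos = list(combos)
    if not combos:
        raise ValueError("need >=1 combination point")
    rows = [combination_index(fit_a, fit_b, c) for c in combos]
    out = pd.DataFrame(
        {
            "fa": [r.fa for r in rows],
            "d1": [r.d1 for r in rows],
            "d2": [r.d2 for r in rows],
            "CI": [r.ci for r in rows],
            "classification": [r.classification for r in rows],
        }
    )
    return out.sort_values("fa", kind="stable").reset_index(drop=True)
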