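"""Drug-pair scoring and the top-30% combination screen.

A drug acts by multiplicative inhibition of its target genes' expression; a
pair acts on the union of the two target sets (overlapping targets are
inhibited once).  The trained survival network scores a pair by the mean
predicted risk reduction over evaluation samples — treated versus untreated —
and pairs are ranked by that synergy score, the top 30% being retained.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .network import FittedSurvivalModel

__all__ = ["DrugTargetMap", "ComboScore", "apply_drug", "score_pair", "rank_and_screen"]


class DrugTargetMap:
    """drug id → set of target gene ids."""

    def __init__(self, table: pd.DataFrame, gene_universe=None):
        self.targets: dict = {
            d: set(sub["gene"]) for d, sub in table.groupby("drug")
        }
        if gene_universe is not None:
            universe = set(gene_universe)
            for d, genes in self.targets.items():
                stray = genes - universe
                if stray:
                    raise ValueError(
                        f"drug {d!r} targets genes outside the hierarchy: {sorted(stray)[:5]}"
                    )

    def __getitem__(self, drug: str) -> set:
        try:
            return self.targets[drug]
        except KeyError:
            raise KeyError(f"unknown drug id {drug!r}") from None

    def union(self, drugs) -> set:
        out: set = set()
        for d in drugs:
            out |= self[d]
        return out

    @property
    def drugs(self) -> list:
        return sorted(self.targets)


@dataclass
class ComboScore:
    pair: tuple
    synergy_score: float
    rank: int = 0
    retained: bool = False


def apply_drug(expression: pd.DataFrame, drugs, target_map: DrugTargetMap,
               inhibition: float = 1.0) -> pd.DataFrame:
    """Multiply targeted genes' expression by (1 − inhibition).

    ``drugs`` may be a single id or an iterable; a pair inhibits the union of
    target sets, so shared targets are scaled once.
    """
    if not 0 <= inhibition <= 1:
        raise ValueError("inhibition must be in [0, 1]")
    if isinstance(drugs, str):
        drugs = [drugs]
    targets = target_map.union(drugs)
    out = expression.copy()
    hit = [g for g in out.index if g in targets]
    out.loc[hit] = out.loc[hit] * (1.0 - inhibition)
    return out


def score_pair(model: FittedSurvivalModel, expression: pd.DataFrame, pair,
               target_map: DrugTargetMap, inhibition: float = 1.0,
               samples=None) -> float:
    """Mean predicted risk reduction of the pair over evaluation samples.

    synergy_score = mean_i [risk_i(untreated) − risk_i(pair-treated)];
    higher means better predicted recurrence-free survival under the pair.
    """
    a, b = pair
    if a == b:
        warnings.warn(f"pair of identical drugs {a!r}: scored as single drug")
    expr = expression if samples is None else expression[list(samples)]
    base = model.risk_scores(expr)
    treated = model.risk_scores(apply_drug(expr, pair, target_map, inhibition))
    return float(np.mean(base - treated))


def rank_and_screen(scores, retain_fraction: float = 0.30) -> pd.DataFrame:
    """Rank pairs by synergy score and retain the top fraction (default 30%).

    Descending sort by score with ties broken by lexicographic pair id, so
    the retained set is invariant to input order.  The retained count is
    ceil(retain_fraction · n).
    """
    if not 0 <= retain_fraction <= 1:
        raise ValueError("retain_fraction must be in [0, 1]")
    rows = []
    for item in scores:
        if isinstance(item, ComboScore):
            rows.append((item.pair, item.synergy_score))
        else:
            pair, s = item
            rows.append((tuple(pair), float(s)))
    if not rows:
        return pd.DataFrame(columns=["drugA", "drugB", "synergy_score", "rank", "retained"])
    if not all(math.isfinite(s) for _, s in rows):
        raise ValueError("synergy scores must be finite")
    rows.sort(key=lambda r: (-r[1], r[0]))
    n_keep = math.ceil(retain_fraction * len(rows))
    return pd.DataFrame(
        {
            "drugA": [p[0] for p, _ in rows],
            "drugB": [p[1] for p, _ in rows],
            "synergy_score": [s for _, s in rows],
            "rank": np.arange(1, len(rows) + 1),
            "retained": [i < n_keep for i in range(len(rows))],
        }
    )
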