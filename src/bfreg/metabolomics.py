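"""Metabolomics pathway analysis: differential filter, enrichment, intersections.

Per treatment comparison, metabolites are filtered by a Welch t-test on log2
intensities at the conventional thresholds (raw p < 0.05 and |log2FC| > 1),
then tested for pathway over-representation with the one-sided
hypergeometric test against a measured background.  The top 25 pathways per
comparison are intersected within a context (in vitro, in vivo), and the two
context-level common sets are intersected again to give the core pathways.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic import MetabolitePanel

__all__ = [
    "differential_metabolites",
    "pathway_enrichment",
    "topk_select",
    "common_pathways",
    "core_pathways",
    "IN_VITRO_COMMON_PATHWAYS",
    "IN_VIVO_COMMON_PATHWAYS",
]

# Context-level common-pathway sets reported for the motivating
# ovarian-cancer combination experiment (in vitro: common to all three
# treatment comparisons in cells; in vivo: common in tumors). Used as a
# worked-example fixture for the intersection logic.
IN_VITRO_COMMON_PATHWAYS = frozenset({
    "purine metabolism",
    "tryptophan metabolism",
    "vitamin b6 metabolism",
    "nicotinate and nicotinamide metabolism",
    "histidine metabolism",
    "glutathione metabolism",
    "arginine and proline metabolism",
    "tyrosine metabolism",
})
IN_VIVO_COMMON_PATHWAYS = frozenset({
    "butanoate metabolism",
    "citrate cycle (tca cycle)",
    "propanoate metabolism",
    "glutathione metabolism",
    "vitamin b6 metabolism",
    "steroid hormone biosynthesis",
})


def _norm(name: str) -> str:
    return name.strip().lower()


def differential_metabolites(
    panel: MetabolitePanel,
    comparison: tuple,
    p_threshold: float = 0.05,
    fc_threshold: float = 1.0,
    use_adjusted: bool = False,
) -> pd.DataFrame:
    """Welch t-test per metabolite between two treatment groups.

    ``comparison`` is (groupA, groupB); log2FC is mean log2 intensity of
    groupA minus groupB.  A metabolite is significant when p < ``p_threshold``
    (raw p by default) and |log2FC| > ``fc_threshold`` — both conditions
    required.  Zero-variance metabolites get p = 1 and are flagged.
    """
    ga, gb = comparison
    sa = panel.sample_groups.index[panel.sample_groups == ga]
    sb = panel.sample_groups.index[panel.sample_groups == gb]
    if len(sa) < 2 or len(sb) < 2:
        raise ValueError(f"need >=2 samples per group in comparison {comparison}")
    la = np.log2(panel.intensities[sa].values)
    lb = np.log2(panel.intensities[sb].values)
    log2fc = la.mean(axis=1) - lb.mean(axis=1)
    with np.errstate(all="ignore"):
        pvals = np.asarray(stats.ttest_ind(la, lb, axis=1, equal_var=False).pvalue,
                           dtype=float)
    zero_var = (la.std(axis=1) == 0) & (lb.std(axis=1) == 0)
    pvals[~np.isfinite(pvals)] = 1.0
    pvals[zero_var] = 1.0
    crit = pvals
    adj = None
    if use_adjusted:
        from statsmodels.stats.multitest import multipletests
        adj = multipletests(pvals, method="fdr_bh")[1]
        crit = adj
    out = pd.DataFrame(
        {
            "log2FC": log2fc,
            "p": pvals,
            "significant": (crit < p_threshold) & (np.abs(log2fc) > fc_threshold),
            "zero_variance": zero_var,
        },
        index=panel.intensities.index,
    )
    if adj is not None:
        out["adjusted_p"] = adj
    return out


def pathway_enrichment(hits, library: dict, background) -> pd.DataFrame:
    """One-sided hypergeometric over-representation of each pathway.

    For a pathway with K members in the background of size N and a hit list
    of size n overlapping it in k metabolites, p = P(X ≥ k) with
    X ~ Hypergeom(N, K, n).  Pathways are ranked by ascending p with
    alphabetical tie-break.  Empty hit lists give p = 1 everywhere.
    """
    hits = set(hits)
    background = set(background)
    if not hits <= background:
        raise ValueError("hits must be a subset of the background")
    if not library:
        raise ValueError("empty pathway library")
    N, n = len(background), len(hits)
    rows = []
    for name in sorted(library, key=_norm):
        members = set(library[name]) & background
        K = len(members)
        k = len(members & hits)
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if k > 0 else 1.0
        rows.append((name, k, K, n, N, min(p, 1.0)))
    table = pd.DataFrame(rows, columns=["pathway", "k", "K", "n", "N", "p"])
    table = table.sort_values(
        by=["p", "pathway"], key=lambda c: c.map(_norm) if c.name == "pathway" else c,
        kind="stable",
    ).reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    return table


def topk_select(table: pd.DataFrame, k: int = 25) -> set:
    """The first min(k, n) pathways of a ranked enrichment table."""
    if "rank" not in table.columns:
        raise ValueError("table must be ranked (run pathway_enrichment first)")
    kept = table.sort_values("rank").head(k)
    return set(kept["pathway"])


def common_pathways(*sets) -> set:
    """Exact intersection of two or more pathway sets.

    Names are matched case-insensitively after trimming whitespace.  A single
    argument is taken as an iterable of sets.
    """
    if len(sets) == 1:
        sets = tuple(sets[0])
    if not sets:
        return set()
    normed = [{_norm(x) for x in s} for s in sets]
    out = normed[0]
    for s in normed[1:]:
        out = out & s
    return out


def core_pathways(in_vitro_common, in_vivo_common) -> set:
    """Cross-context core set: intersection of the two common sets."""
    return common_pathways(in_vitro_common, in_vivo_common)
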