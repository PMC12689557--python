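"""Synthetic-data generators with planted ground truth.

Every input the pipeline consumes can be generated here with a known answer
key: a tumor/normal expression cohort with planted differential genes and a
planted proportional-hazards survival signal, a gene→protein→pathway
hierarchy with planted functional modules, drug→target tables with planted
synergistic pairs, median-effect dose–response panels with known (Dm, m) and
known combination index, limiting-dilution plates with known sphere-forming
frequency, and metabolite intensity tables with planted pathway signal.

All generators are pure functions of their arguments including ``seed``;
randomness comes from one ``numpy.random.default_rng(seed)`` per call, never
from global state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SyntheticCohort",
    "TrueHierarchy",
    "DoseResponsePanel",
    "DilutionExperiment",
    "MetabolitePanel",
    "gen_cohort",
    "gen_hierarchy",
    "gen_drug_panel",
    "gen_dose_response",
    "gen_dilution",
    "gen_metabolites",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class SyntheticCohort:
    """Expression + survival with planted differential and prognostic genes.

    ``expression`` is genes × samples on a TPM-like (positive) scale.
    ``true_log2fc`` holds the planted tumor-vs-normal shift per gene (0 for
    non-differential genes); ``true_beta`` the planted Cox coefficient per
    gene on standardized log2 expression (0 for non-prognostic genes).
    """

    expression: pd.DataFrame
    group_labels: pd.Series          # sample -> {"tumor", "normal"}
    survival: pd.DataFrame           # index: tumor samples; columns time, event
    true_log2fc: pd.Series
    true_beta: pd.Series

    @property
    def true_deg(self) -> set:
        return set(self.true_log2fc.index[self.true_log2fc != 0])

    @property
    def tumor_samples(self) -> list:
        return list(self.group_labels.index[self.group_labels == "tumor"])

    def validate(self) -> None:
        assert (self.expression.values >= 0).all(), "expression must be non-negative"
        assert set(self.group_labels.unique()) <= {"tumor", "normal"}
        assert set(self.survival.index) == set(self.tumor_samples)
        assert (self.survival["time"].values > 0).all()
        assert set(self.survival["event"].unique()) <= {0, 1}


@dataclass
class TrueHierarchy:
    """Layered regulatory network used as ground truth for the model topology."""

    genes: list
    proteins: list
    pathways: list
    gene_edges: list                 # list of (gene, gene)
    protein_edges: list
    pathway_edges: list
    gene_to_protein: list            # list of (gene, protein)
    protein_to_pathway: list         # list of (protein, pathway)
    planted_modules: list = field(default_factory=list)  # list of gene-id lists

    def validate(self) -> None:
        gs, ps, ws = set(self.genes), set(self.proteins), set(self.pathways)
        for a, b in self.gene_edges:
            assert a in gs and b in gs
        for a, b in self.protein_edges:
            assert a in ps and b in ps
        for a, b in self.pathway_edges:
            assert a in ws and b in ws
        for g, p in self.gene_to_protein:
            assert g in gs and p in ps
        for p, w in self.protein_to_pathway:
            assert p in ps and w in ws
        mapped = {g for g, _ in self.gene_to_protein}
        assert mapped == gs, "every gene must map to >=1 protein"


@dataclass
class DoseResponsePanel:
    """Median-effect dose–response data with known (Dm, m) and known CI."""

    single: pd.DataFrame             # columns: drug, dose, fa
    combo: pd.DataFrame              # columns: d1, d2, fa, true_ci
    true_params: dict                # drug -> {"Dm": float, "m": float}
    clip_eps: float = 1e-6


@dataclass
class DilutionExperiment:
    """Limiting-dilution plate counts under the single-hit Poisson model."""

    data: pd.DataFrame               # columns: dose, wells, positive
    true_f: float


@dataclass
class MetabolitePanel:
    """Per-group metabolite intensities with planted pathway signal."""

    intensities: pd.DataFrame        # metabolite × samples
    sample_groups: pd.Series         # sample -> group
    planted_diff: dict               # (groupA, groupB) -> set of metabolite ids
    library: dict                    # pathway -> set of metabolite ids
    planted_pathways: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

def gen_cohort(
    n_tumor: int,
    n_normal: int,
    n_genes: int,
    n_deg: int = 0,
    n_prognostic: int = 0,
    effect_sizes: dict | None = None,
    seed: int = 0,
    deg_genes: list | None = None,
    prognostic_genes: list | None = None,
) -> SyntheticCohort:
    """Generate a two-group expression cohort with planted survival signal.

    Expression is log-normal: log2 intensities are Gaussian around a
    gene-specific baseline, with the planted log2 fold change added to
    differential genes in the tumor group.  Recurrence-free survival times for
    tumor samples follow an exponential proportional-hazards model whose
    linear predictor is ``sum_g beta_g * z_g`` over standardized log2
    expression, with independent uniform censoring at a stated rate.

    Parameters in ``effect_sizes`` (defaults in parentheses): ``deg_log2fc``
    (2.0), ``beta`` (2.5, applied to each planted prognostic gene),
    ``noise_sd`` (1.0, log2-scale within-group SD), ``censor_rate`` (0.2),
    ``baseline_hazard`` (0.02 events/month).
    """
    if min(n_tumor, n_normal, n_genes) <= 0:
        raise ValueError("counts must be positive")
    if n_deg > n_genes or n_prognostic > n_genes:
        raise ValueError("planted gene counts exceed n_genes")
    cfg = {
        "deg_log2fc": 2.0,
        "beta": 2.5,
        "noise_sd": 1.0,
        "censor_rate": 0.2,
        "baseline_hazard": 0.02,
    }
    cfg.update(effect_sizes or {})
    if not (0 <= cfg["censor_rate"] < 1):
        raise ValueError("censoring rate must be in [0, 1)")
    finite = np.all(np.isfinite(np.atleast_1d(cfg["beta"]))) and np.all(
        np.isfinite([cfg["deg_log2fc"], cfg["noise_sd"]])
    )
    if not finite:
        raise ValueError("effect sizes must be finite")

    rng = np.random.default_rng(seed)
    genes = [f"G{i:04d}" for i in range(n_genes)]
    tumor = [f"T{i:03d}" for i in range(n_tumor)]
    normal = [f"N{i:03d}" for i in range(n_normal)]

    if deg_genes is None:
        deg_genes = genes[:n_deg]
    if prognostic_genes is None:
        prognostic_genes = genes[:n_prognostic]
    unknown = (set(deg_genes) | set(prognostic_genes)) - set(genes)
    if unknown:
        raise ValueError(f"planted genes not in cohort: {sorted(unknown)}")

    log2fc = pd.Series(0.0, index=genes)
    log2fc[list(deg_genes)] = cfg["deg_log2fc"]
    beta = pd.Series(0.0, index=genes)
    b = cfg["beta"]   # scalar, or one value per planted prognostic gene
    beta[list(prognostic_genes)] = (
        list(b) if np.ndim(b) else [float(b)] * len(prognostic_genes)
    )

    baseline = rng.normal(5.0, 1.0, size=n_genes)
    log2x = baseline[:, None] + rng.normal(
        0.0, cfg["noise_sd"], size=(n_genes, n_tumor + n_normal)
    )
    log2x[:, :n_tumor] += log2fc.values[:, None]
    expr = pd.DataFrame(2.0 ** log2x, index=genes, columns=tumor + normal)

    # linear predictor on standardized log2 expression of tumor samples
    tum_log2 = log2x[:, :n_tumor]
    mu = tum_log2.mean(axis=1, keepdims=True)
    sd = tum_log2.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = (tum_log2 - mu) / sd
    lp = beta.values @ z
    hazard = cfg["baseline_hazard"] * np.exp(lp)
    event_time = rng.exponential(1.0 / hazard)
    # independent censoring: C ~ Uniform(0, W), with the window W calibrated
    # on the sampled event times so that P(C < T) matches censor_rate
    if cfg["censor_rate"] > 0:
        from scipy.optimize import brentq

        def censored_frac(w):
            return np.mean(np.minimum(event_time, w) / w)

        lo, hi = event_time.min() * 1e-3, event_time.max() * 1e3
        window = brentq(lambda w: censored_frac(w) - cfg["censor_rate"], lo, hi)
        cens_time = rng.uniform(0, window, size=n_tumor)
        time = np.minimum(event_time, cens_time)
        event = (event_time <= cens_time).astype(int)
    else:
        time = event_time
        event = np.ones(n_tumor, dtype=int)
    time = np.maximum(time, 1e-6)
    surv = pd.DataFrame({"time": time, "event": event}, index=tumor)

    labels = pd.Series(
        ["tumor"] * n_tumor + ["normal"] * n_normal, index=tumor + normal
    )
    cohort = SyntheticCohort(expr, labels, surv, log2fc, beta)
    cohort.validate()
    return cohort


def standardized_log_expression(cohort: SyntheticCohort, samples=None) -> pd.DataFrame:
    """Per-gene z-scores of log2 expression over the given samples (tumor by default)."""
    samples = cohort.tumor_samples if samples is None else list(samples)
    x = np.log2(cohort.expression[samples].values + 1e-12)
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return pd.DataFrame((x - mu) / sd, index=cohort.expression.index, columns=samples)


# ---------------------------------------------------------------------------
# hierarchy
# ---------------------------------------------------------------------------

def gen_hierarchy(
    n_genes: int,
    n_proteins: int,
    n_pathways: int,
    edge_density: float = 0.08,
    n_modules: int = 1,
    module_size: int = 10,
    seed: int = 0,
) -> TrueHierarchy:
    """Random layered hierarchy with planted connected gene modules.

    Each planted module is a connected gene set (ring plus random chords)
    whose genes map to a dedicated block of proteins that all share one
    dedicated pathway — so the module has a clean route to the outcome node.
    Every remaining gene maps to >=1 random protein and every protein to >=1
    random pathway.
    """
    if min(n_genes, n_proteins, n_pathways) <= 0:
        raise ValueError("node counts must be positive")
    if not 0 <= edge_density <= 1:
        raise ValueError("edge_density must be in [0, 1]")
    if n_modules * module_size > n_genes:
        raise ValueError("modules exceed available genes")
    if n_modules > n_pathways or n_modules * 2 > n_proteins:
        raise ValueError("not enough proteins/pathways for the planted modules")

    rng = np.random.default_rng(seed)
    genes = [f"G{i:04d}" for i in range(n_genes)]
    proteins = [f"P{i:04d}" for i in range(n_proteins)]
    pathways = [f"W{i:03d}" for i in range(n_pathways)]

    def random_edges(nodes):
        edges = []
        for i in range(len(nodes)):
            for j in range(i + 1, len(nodes)):
                if rng.uniform() < edge_density:
                    edges.append((nodes[i], nodes[j]))
        return edges

    gene_edges = random_edges(genes)
    protein_edges = random_edges(proteins)
    pathway_edges = random_edges(pathways)

    modules = [genes[k * module_size:(k + 1) * module_size] for k in range(n_modules)]
    # wire each module into a ring so it is connected regardless of density
    for mod in modules:
        for a, b in zip(mod, mod[1:] + mod[:1]):
            if (a, b) not in gene_edges and (b, a) not in gene_edges and a != b:
                gene_edges.append((a, b))

    # inter-level maps: module genes -> dedicated protein block -> dedicated pathway
    proteins_per_module = max(2, n_proteins // max(2 * n_modules, 1)) if n_modules else 0
    gene_to_protein, protein_to_pathway = [], []
    used_proteins = 0
    for k, mod in enumerate(modules):
        block = proteins[used_proteins:used_proteins + proteins_per_module]
        used_proteins += proteins_per_module
        for g in mod:
            gene_to_protein.append((g, block[rng.integers(len(block))]))
        for p in block:
            protein_to_pathway.append((p, pathways[k]))
    free_proteins = proteins[used_proteins:] or proteins
    free_pathways = pathways[n_modules:] or pathways
    module_genes = {g for mod in modules for g in mod}
    for g in genes:
        if g not in module_genes:
            gene_to_protein.append((g, free_proteins[rng.integers(len(free_proteins))]))
    mapped_p = {p for p, _ in protein_to_pathway}
    for p in proteins:
        if p not in mapped_p:
            protein_to_pathway.append((p, free_pathways[rng.integers(len(free_pathways))]))

    hier = TrueHierarchy(
        genes, proteins, pathways,
        gene_edges, protein_edges, pathway_edges,
        gene_to_protein, protein_to_pathway,
        planted_modules=modules,
    )
    hier.validate()
    return hier


# ---------------------------------------------------------------------------
# drugs
# ---------------------------------------------------------------------------

def gen_drug_panel(
    n_drugs: int,
    targets_per_drug: int,
    hierarchy: TrueHierarchy,
    n_synergistic_pairs: int = 1,
    seed: int = 0,
    pair_filter=None,
):
    """Drug→target table with planted synergistic pairs.

    Each planted pair's two drugs split one planted module between them, so
    the pair jointly covers the module; all other drugs draw their targets
    outside planted modules.  Returns ``(targets, pairs, synergistic)`` where
    ``targets`` is a DataFrame (drug, gene), ``pairs`` the candidate pair list
    (after the optional ``pair_filter`` hook), and ``synergistic`` the planted
    pair set.
    """
    if targets_per_drug > len(hierarchy.genes):
        raise ValueError("targets_per_drug exceeds number of genes")
    if n_synergistic_pairs > len(hierarchy.planted_modules):
        raise ValueError("not enough planted modules to cover the requested pairs")
    if 2 * n_synergistic_pairs > n_drugs:
        raise ValueError("not enough drugs for the requested synergistic pairs")

    rng = np.random.default_rng(seed)
    drugs = [f"D{i:03d}" for i in range(n_drugs)]
    module_genes = {g for mod in hierarchy.planted_modules for g in mod}
    outside = [g for g in hierarchy.genes if g not in module_genes] or hierarchy.genes

    rows, synergistic = [], set()
    for k in range(n_synergistic_pairs):
        mod = hierarchy.planted_modules[k]
        half = len(mod) // 2
        a, b = drugs[2 * k], drugs[2 * k + 1]
        for g in mod[:half]:
            rows.append((a, g))
        for g in mod[half:]:
            rows.append((b, g))
        for d in (a, b):
            n_fill = max(0, targets_per_drug - sum(1 for r in rows if r[0] == d))
            for g in rng.choice(outside, size=min(n_fill, len(outside)), replace=False):
                rows.append((d, g))
        synergistic.add(tuple(sorted((a, b))))
    for d in drugs[2 * n_synergistic_pairs:]:
        for g in rng.choice(outside, size=min(targets_per_drug, len(outside)), replace=False):
            rows.append((d, g))

    targets = pd.DataFrame(rows, columns=["drug", "gene"]).drop_duplicates()
    pairs = [tuple(sorted((a, b))) for i, a in enumerate(drugs) for b in drugs[i + 1:]]
    if pair_filter is not None:
        pairs = [p for p in pairs if pair_filter(p)]
    return targets, pairs, synergistic


# ---------------------------------------------------------------------------
# dose–response
# ---------------------------------------------------------------------------

def _median_effect_fa(dose, Dm, m):
    r = (np.asarray(dose, dtype=float) / Dm) ** m
    return r / (1.0 + r)


def gen_dose_response(
    Dm1: float,
    m1: float,
    Dm2: float,
    m2: float,
    doses=(8.0, 4.0, 2.0, 1.0, 0.5, 0.25),
    combo_design: dict | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> DoseResponsePanel:
    """Median-effect panel for two drugs plus combination points with known CI.

    Single-drug fraction affected follows fa = (D/Dm)^m / (1 + (D/Dm)^m),
    optionally with Gaussian noise on the logit(fa) scale.  Combination points
    are built on the Loewe-additive isobole at chosen effect levels and then
    both doses are scaled by the planted interaction factor κ, which makes the
    true combination index exactly κ at every point.

    ``combo_design`` keys: ``ratio`` (d1:d2 ratio, default (1, 1)),
    ``fa_levels`` (default (0.2, 0.35, 0.5, 0.65, 0.8)), ``interaction``
    (κ, default 1.0 = additive).
    """
    if min(Dm1, m1, Dm2, m2) <= 0:
        raise ValueError("Dm and m must be positive")
    doses = np.asarray(doses, dtype=float)
    if (doses <= 0).any() or len(set(doses)) != len(doses):
        raise ValueError("doses must be positive and distinct")
    design = {"ratio": (1.0, 1.0), "fa_levels": (0.2, 0.35, 0.5, 0.65, 0.8),
              "interaction": 1.0}
    design.update(combo_design or {})
    kappa = float(design["interaction"])
    r1, r2 = design["ratio"]

    rng = np.random.default_rng(seed)
    eps = 1e-6

    def noisy(fa):
        if noise_sd == 0:
            return fa
        logit = np.log(fa / (1 - fa)) + rng.normal(0, noise_sd, size=np.shape(fa))
        return np.clip(1 / (1 + np.exp(-logit)), eps, 1 - eps)

    single = []
    for drug, Dm, m in (("A", Dm1, m1), ("B", Dm2, m2)):
        fa = noisy(_median_effect_fa(doses, Dm, m))
        for d, f in zip(doses, fa):
            single.append((drug, d, f))

    combo = []
    for fa in design["fa_levels"]:
        dx1 = Dm1 * (fa / (1 - fa)) ** (1 / m1)
        dx2 = Dm2 * (fa / (1 - fa)) ** (1 / m2)
        t = 1.0 / (r1 / dx1 + r2 / dx2)      # additive isobole along the ratio
        d1, d2 = kappa * t * r1, kappa * t * r2
        combo.append((d1, d2, float(noisy(np.asarray(fa))), kappa))

    return DoseResponsePanel(
        single=pd.DataFrame(single, columns=["drug", "dose", "fa"]),
        combo=pd.DataFrame(combo, columns=["d1", "d2", "fa", "true_ci"]),
        true_params={"A": {"Dm": Dm1, "m": m1}, "B": {"Dm": Dm2, "m": m2}},
        clip_eps=eps,
    )


# ---------------------------------------------------------------------------
# limiting dilution
# ---------------------------------------------------------------------------

def gen_dilution(
    true_f: float,
    doses=(200, 100, 50, 25),
    wells: int = 10,
    seed: int = 0,
) -> DilutionExperiment:
    """Binomial well counts under the single-hit Poisson model.

    P(well positive at dose d) = 1 − exp(−f·d); the default plate design is
    four cell doses with 10 replicate wells each.
    """
    if not 0 < true_f < 1:
        raise ValueError("true_f must be in (0, 1)")
    doses = [int(d) for d in doses]
    if len(set(doses)) != len(doses):
        raise ValueError("doses must be distinct")
    rng = np.random.default_rng(seed)
    rows = []
    for d in doses:
        p = 1.0 - np.exp(-true_f * d)
        rows.append((d, wells, int(rng.binomial(wells, p))))
    return DilutionExperiment(
        pd.DataFrame(rows, columns=["dose", "wells", "positive"]), true_f
    )


# ---------------------------------------------------------------------------
# metabolomics
# ---------------------------------------------------------------------------

def gen_metabolites(
    groups=("combo", "model", "drugA", "drugB"),
    n_metabolites: int = 200,
    planted: dict | None = None,
    library_spec: dict | None = None,
    seed: int = 0,
) -> MetabolitePanel:
    """Log-normal metabolite intensities with planted pathway signal.

    ``planted`` keys: ``pathways`` (names to plant, default ["PATH_01"]),
    ``per_pathway`` (planted metabolites per pathway, default 10), ``log2fc``
    (shift applied in the first group of every comparison, default 2.0),
    ``comparisons`` (default: first group vs each other group).
    ``library_spec`` keys: ``n_pathways`` (default 12), ``pathway_size``
    (default 15).
    """
    groups = list(groups)
    if len(groups) < 2:
        raise ValueError("need >=2 groups")
    p = {"pathways": ["PATH_01"], "per_pathway": 10, "log2fc": 2.0,
         "comparisons": [(groups[0], g) for g in groups[1:]], "n_per_group": 6}
    p.update(planted or {})
    lib = {"n_pathways": 12, "pathway_size": 15}
    lib.update(library_spec or {})
    if p["per_pathway"] > lib["pathway_size"]:
        raise ValueError("per_pathway exceeds pathway_size")

    rng = np.random.default_rng(seed)
    mets = [f"M{i:04d}" for i in range(n_metabolites)]

    # library: planted pathways get dedicated leading blocks so their members
    # are exactly the shifted metabolites plus unshifted same-pathway fillers
    library: dict = {}
    cursor = 0
    names = list(p["pathways"]) + [
        f"PATH_{i + 1 + len(p['pathways']):02d}" for i in range(lib["n_pathways"] - len(p["pathways"]))
    ]
    planted_members: dict = {}
    for name in p["pathways"]:
        members = mets[cursor:cursor + lib["pathway_size"]]
        cursor += lib["pathway_size"]
        library[name] = set(members)
        planted_members[name] = set(members[:p["per_pathway"]])
    for name in names[len(p["pathways"]):]:
        if cursor + lib["pathway_size"] > n_metabolites:
            members = list(rng.choice(mets, size=lib["pathway_size"], replace=False))
        else:
            members = mets[cursor:cursor + lib["pathway_size"]]
            cursor += lib["pathway_size"]
        library[name] = set(members)

    shifted = set().union(*planted_members.values()) if planted_members else set()
    shifted_groups = {c[0] for c in p["comparisons"]}

    base = rng.normal(10.0, 1.5, size=n_metabolites)
    cols, data, sample_groups = [], [], []
    for g in groups:
        for i in range(p["n_per_group"]):
            sid = f"{g}_{i}"
            log2v = base + rng.normal(0, 0.5, size=n_metabolites)
            if g in shifted_groups:
                idx = [mets.index(m) for m in shifted]
                log2v[idx] += p["log2fc"]
            cols.append(sid)
            data.append(2.0 ** log2v)
            sample_groups.append(g)
    intensities = pd.DataFrame(np.array(data).T, index=mets, columns=cols)

    planted_diff = {tuple(c): set(shifted) for c in p["comparisons"]}
    return MetabolitePanel(
        intensities=intensities,
        sample_groups=pd.Series(sample_groups, index=cols),
        planted_diff=planted_diff,
        library=library,
        planted_pathways=list(p["pathways"]),
    )
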