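"""Simulate every input the pipeline consumes, with planted ground truth.

Writes a tumor/normal expression cohort with planted differential and
prognostic genes, a gene→protein→pathway hierarchy with one planted
functional module, a drug→target panel with one planted synergistic pair,
median-effect dose–response panels with known (Dm, m) and known CI,
limiting-dilution plates with known sphere-forming frequency, and metabolite
tables with planted pathway signal.
"""

import json
import sys
from pathlib import Path

from bfreg import io
from bfreg.synthetic import (
    gen_cohort,
    gen_dilution,
    gen_dose_response,
    gen_drug_panel,
    gen_hierarchy,
    gen_metabolites,
)

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 42
OUT = Path(__file__).resolve().parent.parent / "results" / "simulated"
OUT.mkdir(parents=True, exist_ok=True)

hier = gen_hierarchy(n_genes=50, n_proteins=30, n_pathways=8, seed=SEED)
cohort = gen_cohort(n_tumor=500, n_normal=100, n_genes=50, n_deg=10,
                    n_prognostic=10, seed=SEED,
                    prognostic_genes=hier.planted_modules[0])
targets, pairs, synergistic = gen_drug_panel(
    n_drugs=12, targets_per_drug=5, hierarchy=hier, n_synergistic_pairs=1,
    seed=SEED)
doses = gen_dose_response(Dm1=45.47, m1=1.3, Dm2=2.0, m2=1.0,
                          combo_design={"interaction": 0.57}, noise_sd=0.05,
                          seed=SEED)
plate = gen_dilution(true_f=1 / 170, seed=SEED)
metab = gen_metabolites(seed=SEED)

io.write_expression(cohort.expression, OUT / "expression.tsv")
io.write_survival(cohort.survival, OUT / "survival.tsv")
io.write_edges(hier.gene_edges, OUT / "gene_edges.tsv")
io.write_edges(hier.protein_edges, OUT / "protein_edges.tsv")
io.write_edges(hier.gene_to_protein, OUT / "gene_to_protein.tsv",
               header=("child", "parent"))
io.write_edges(hier.protein_to_pathway, OUT / "protein_to_pathway.tsv",
               header=("child", "parent"))
io.write_drug_targets(targets, OUT / "drug_targets.tsv")
io.write_dose_response(doses.single, OUT / "dose_response.csv")
io.write_dose_response(doses.combo, OUT / "combo_points.csv")
plate.data.to_csv(OUT / "dilution.csv", index=False)
metab.intensities.to_csv(OUT / "metabolites.csv")
io.write_gmt(metab.library, OUT / "pathways.gmt")
(OUT / "ground_truth.json").write_text(json.dumps({
    "seed": SEED,
    "planted_module": hier.planted_modules[0],
    "planted_synergistic_pairs": sorted(map(list, synergistic)),
    "true_dilution_frequency": plate.true_f,
    "true_combo_ci": 0.57,
    "planted_pathways": metab.planted_pathways,
}, indent=2))

print(f"simulated inputs written to {OUT}")
print(f"  cohort: {cohort.expression.shape[1]} samples x {cohort.expression.shape[0]} genes, "
      f"event rate {cohort.survival['event'].mean():.2f}")
print(f"  planted prognostic module: {hier.planted_modules[0]}")
print(f"  planted synergistic pair(s): {sorted(synergistic)} of {len(pairs)} candidate pairs")
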