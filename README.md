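# bfreg

An in-silico drug-combination discovery pipeline for tumor cohorts, built
around a biologically structured survival network, together with the
quantitative pharmacology and metabolomics analyses used to validate a
candidate combination.  Everything runs on synthetic data with planted
ground truth, so every stage is testable without external downloads.

The package is aimed at computational biologists who want a fully
reproducible, desk-scale version of this kind of discovery pipeline:
prognostic-gene screening on a tumor/normal expression cohort, a
hierarchical neural network trained to predict recurrence-free survival,
drug-pair ranking by predicted risk reduction, Chou–Talalay combination
indices, limiting-dilution stem-cell frequencies, tumor-growth statistics,
and metabolic-pathway intersection logic.

## The model

The core is a **hierarchical survival network** whose structure mirrors the
biology.  Nodes are organised in levels L = (gene, protein, pathway,
survival).  Each node i starts from a linear embedding of its scalar input
x_i (standardized log2 expression),

    H_i^0 = x_i · e_i ,

messages pass within a level along its adjacency A^l,

    Ĥ_i = σ( w_self · H_i + w_msg · Σ_{j ∈ A_i} a_ij H_j ) ,

and propagation to the next level is masked elementwise by the inter-level
map M^l (gene→protein, protein→pathway, pathway→survival):

    Ĥ^{l+1} = σ( (M^l ⊙ W^l) Ĥ^l + b^l ) ,

so absent biological relations contribute exactly zero.  A learnable
adjacency (default: gene level) replaces the binary a_ij with β_ij from a
two-layer perceptron on the pair of embeddings, where known edges keep the
full weight β_ij and unknown edges are down-weighted to α·β_ij with
α = 0.005 — biological knowledge is respected while latent regulation can
still be discovered.  The single survival node is read out linearly to a
risk score H_i per patient, trained with the Cox partial-likelihood loss

    L_Cox = − Σ_i ( H_i − log Σ_{j ∈ R_i} e^{H_j} ) ,

(sum over events, R_i the risk set) using Adam at learning rate 1e-4,
batch size 32, up to 200 epochs, an 80/20 train/validation split, and early
stopping on validation loss.  Performance is the concordance index on the
held-out split; drug pairs are then scored by the mean predicted risk
reduction when the pair's target genes are inhibited, and the top 30% of
pairs survive the screen.

Gradients come from a small in-package reverse-mode autodiff engine on
numpy arrays (`bfreg.autodiff`); no GPU or deep-learning framework is
needed.

## Worked example

The numbered scripts under `analysis/` run the whole study on simulated
data (seed 42 by default) and write their tables under `results/`:

```
python analysis/01_simulate.py          # all inputs, with planted truth
python analysis/02_gene_screen.py       # DEG screen -> Cox/AIC -> KM strata
python analysis/03_train_network.py     # network training + attribution
python analysis/04_rank_combinations.py # pair scoring + top-30% screen
python analysis/05_combination_index.py # median-effect fits + Fa-CI curve
python analysis/06_downstream_assays.py # dilution, TGI, volumes, ddCt
python analysis/07_metabolomics.py      # pathway intersections
```

Representative output (seed 42):

```
differential screen: 10 genes called (10 up, 0 down); 10/10 planted recovered
stepwise AIC kept 10 genes (AIC 2870.5): ['G0000', ..., 'G0009']
median-split log-rank: chi2 = 586.56, p = 1.40e-129

trained 400+100 samples, best epoch 49, held-out c-index 0.937
top-10 attributed genes overlap planted module: 8/10 (Jaccard 0.67)

66 pairs scored, top 30% retained = 20
planted synergistic pair ('D000', 'D001'): rank 1/66, retained=True

drug A: m = 1.322, Dm = 43.567 uM, r = 0.9995
planted CI 0.57; mean fitted CI 0.565 (5/5 points synergistic)

limiting dilution: true f = 1/170, fitted 1/167.7 (95% CI 1/100.2 .. 1/280.6)
TGI: control mean 0.953 g, treated mean 0.340 g -> 64.29%
worked literature example: ['glutathione metabolism', 'vitamin b6 metabolism'] (n=2)
```

Reading this: the Welch/BH screen recovers all ten planted differential
genes; backward stepwise AIC keeps exactly the planted prognostic module,
whose median-split risk strata separate sharply by log-rank.  The trained
network ranks held-out patients with c-index 0.937 (values above 0.9
indicate strong agreement between predicted and observed survival), and
integrated gradients point back at the planted module.  The drug pair that
jointly covers the module ranks first of 66 and survives the 30% screen.
The median-effect fit recovers the planted IC50 within sampling noise and
the combination index reproduces the planted CI = 0.57 (synergy); the
single-hit Poisson fit recovers the planted sphere-forming frequency
1/170; and intersecting the two reported context-level common-pathway sets
leaves exactly glutathione and vitamin B6 metabolism.

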