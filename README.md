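# synprof

Interpretable drug-pair synergy prediction from target-protein inhibition
profiles, with a synthetic benchmark that makes every stage of the
pipeline verifiable by planted-motif recovery.

## The problem

Deep models that predict the synergy of a drug combination on a cancer
cell line usually consume thousands of structural fingerprint bits and
are accurate but opaque. An alternative is a **two-stage framework** whose
features mean something biologically:

1. **Stage 1 — target models.** For each protein in a 13-member panel of
   frequent cancer targets (ABL1, CSF1R, EGFR, FLT1, FLT4, KDR, KIT,
   MCL1, NR1I2, PDGFRB, RET, TOP2A, TUBB1), a binary classifier maps a
   compound's structure to an inhibition score in [0, 1]. Activity labels
   follow the screening convention IC50 ≤ 10 μM = inhibitory, an explicit
   inactive flag = non-inhibitory; performance is reported as ROC-AUC
   under stratified tenfold CV.
2. **Stage 2 — synergy regressor.** A feed-forward network with three
   hidden layers (nodes ∈ {128, 256, 512}, activations ∈ {tanh, ReLU},
   dropout 0.5 after each layer, linear output) maps the 33-dimensional
   input *x* = [profile(drug A) | profile(drug B) | mutation codes] to the
   pair's ZIP synergy score *s* (normalized to mean 0, variance 1 on the
   training split). Pairs are unordered, so training tables are doubled by
   swapping the two profile blocks and inference averages f(A,B) and
   f(B,A). Hyperparameters are chosen by a 3×3 nested cross-validation
   stratified by cell line: inner folds pick the grid cell with the best
   mean validation Pearson r, outer folds estimate generalization.

Because every input node is a named protein (or mutation), the trained
ensemble can be **interpreted in input space**: enumerate all binary
26-bit inhibition profiles with N = 2…4 active entries, score each probe
with the ensemble, summarize per target as none / one drug / both drugs
(states 0/1/2), keep the top-20 patterns, and cluster them with Euclidean
distance into pattern groups — candidate multi-target mechanisms of
synergy.

## The synthetic benchmark

Public synergy and bioactivity databases are replaced by a generator that
emulates them: compounds with Bernoulli fingerprints whose bits determine
latent inhibition probabilities through a sparse logistic map (calibrated
so a set fraction of the library inhibits each target, with near-saturated
scores like real classifier outputs); imbalanced per-target screens with
IC50/inactive records; cell lines with 0/1/2 mutation codes; and a
DrugComb-shaped pair table whose ZIP-like scores come from **planted
synergy motifs**: a motif is a set of targets with one-drug/both-drug
requirements that adds `effect_size × line_weight` when a pair covers it,
plus Gaussian noise. Ground truth is known, so recovery — does the
interpretation stage place the planted motifs in its top-20 patterns? —
is a measurable quantity rather than a narrative.

## Worked example

```python
from synprof import synthetic as syn
from synprof.model import HyperParams, TrainingSchedule
from synprof.validation import nested_cv
from synprof.interpretation import discover_patterns, motif_recovery_score

lib = syn.simulate_compound_library(80, 256, 13, 0.2, seed=1)
panel = syn.simulate_cell_lines(5, 7, seed=2)
motifs = syn.default_motifs(5)                     # 2 planted motifs
pairs = syn.simulate_synergy_table(lib, panel, motifs, 800, noise_sd=0.5, seed=3)

hp = HyperParams(nodes=(128, 128, 128), activations=("tanh", "relu", "relu"),
                 learning_rate=1e-3)
results = nested_cv(pairs, lib.latent_profile_frame(), panel, [hp], seed=1,
                    schedule=TrainingSchedule(max_epochs=200, patience=40))
print([round(r.report.overall_r, 3) for r in results])
# [0.824, 0.831, 0.853]   <- outer-fold test Pearson r of the 3 models

ensemble = [r.model for r in results]
top, dendro = discover_patterns(ensemble, panel.codes_for("LINE-0"),
                                cell_line="LINE-0", n_active_range=range(2, 5))
print(top[0].states, round(top[0].predicted_score, 2))
# (0, 0, 0, 1, 2, 0, 0, 0, 0, 1, 0, 0, 0) 2.14
print(motif_recovery_score(top, motifs).match_scores)
# [1.0, 1.0]
```

The three outer-fold correlations (~0.82–0.85) say the regressor recovers
most of the learnable signal (the planted noise caps r below 1). The
highest-scoring pattern on LINE-0 reads: *one drug inhibits target 3,
both drugs inhibit target 4* (plus a spurious extra target) — a superset
of the second planted motif — and the exact pattern of the first motif
(one drug on target 0, one on target 1, both on target 2) also sits in
the top-20, so both motifs reach a recovery match of 1.0.

The same chain is available from the shell:

```bash
synprof run-all --seed 1 --out run1     # desk-scale end-to-end run
```

which writes `pairs.csv`, `profiles.csv`, `predictions.csv`,
`report.json`, `top_patterns_<line>.csv`, dendrograms (TSV + Newick) and
`recovery_report.json` into `run1/`.

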