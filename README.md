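# fcserology

Systems-serology analysis of antibody **Fc effector function** in early
HIV infection, built around one question: can the functional profile of
a subject's HIV-specific IgG at ~6 months post-infection predict whether
they will develop **broadly neutralizing antibodies (bNAbs)** years
later?

The package implements the full computational chain for a two-group
cohort (bNAb developers vs non-developers, plus HIV-negative controls):

1. **Assay scoring** — composite scores for the four Fc effector
   functions: phagocytosis (ADCP, geometric bead MFI × % uptake),
   complement deposition (ADCD, MFI × % C3b⁺ cells), cytotoxicity
   (ADCC, % granzyme-B activity net of no-IgG background) and
   trogocytosis (ADCT, % double-positive monocytes); HIV-negative
   thresholding (mean + 3 SD subtracted, floored at 0) and HIVIG-based
   plate normalization.
2. **Composite scores** — the Fc polyfunctionality Z-score
   `Z_i = Σ_f (x_if − x̄_f)/s_f` summed over the four functions; the IgG
   subclass diversity score `(IgG2 + IgG4)/IgG1`; relative subclass
   abundances; the activating/inhibitory binding ratio FcγRIIa/FcγRIIb.
3. **Inferential statistics** — Mann-Whitney U (exact for small
   tie-free samples), Kruskal-Wallis with Dunn-type post-hocs, Spearman
   correlations and correlation matrices, and Benjamini-Hochberg
   feature selection: every candidate feature is rank-correlated with
   the 0/1 group label and kept when its BH-adjusted p falls below a
   5% false-discovery rate.
4. **Multivariate classification** — PCA; a 500-tree random forest with
   out-of-bag (OOB) cross-validation, Gini importance ranking, and a
   label-permutation test that reports the proportion of random
   relabelings whose OOB accuracy beats the observed model.
5. **Sequence metrics** — viral divergence from antigen reference
   sequences and longitudinal intra-host diversity as uncorrected
   p-distances (pairwise deletion of gap/N columns) on pre-aligned
   FASTA.
6. **Synthetic cohort generator** — 13-vs-10 cohorts with the group
   structure the analysis expects (elevated ADCD/ADCT, FcγR/C1q
   binding, IgG2/IgG4, CXCL13 and breadth in the bNAb group; lower CD4;
   viral load matched), so every stage runs and is testable with no
   external data.

Intended users are immunologists and biostatisticians analysing Fc
effector panels (flow-based functional assays plus Luminex binding
arrays) against a binary clinical outcome.

## Worked example

```python
from fcserology import PipelineConfig, run_pipeline

summary = run_pipeline(PipelineConfig(n_shuffles=5000, seed=1))
print(summary["confusion_matrix"])
print(summary["metrics_pct"])
print(summary["permutation"]["n_exceeding"])
```

prints (seed 1):

```
{'tp': 13, 'fn': 0, 'tn': 9, 'fp': 1}
{'sensitivity': 100.0, 'specificity': 90.0, 'accuracy': 95.6522}
0
```

Read: on a simulated 13-vs-10 cohort with the default effect profile,
the FDR screen keeps 19 of 29 candidate features, and the forest's
out-of-bag vote misclassifies a single no-bNAb subject (95.7%
accuracy). None of 5000 label shuffles produced a forest that beat the
observed accuracy — the classification is driven by the Fc feature
profile, not chance. The `examples/` directory has one short script per
capability (simulation, scoring, polyfunctionality, feature selection,
classification, sequence distances).

A thin CLI mirrors the pipeline stages:

```bash
fcserology run-all --seed 1 --out results/run1
fcserology simulate --seed 1 --out cohort.csv
fcserology seqdist --fasta aligned.fasta --out diversity.tsv
```

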