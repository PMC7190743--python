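# variomics

Multi-assay functional profiling of protein variants, built around the
analysis pipeline of a multi-model *PTEN* variant functionalization
study.  Missense variants of PTEN — a phosphatase antagonizing PI3K-AKT
signaling, recurrently mutated in autism spectrum disorder, PTEN
hamartoma tumor syndrome and cancer — are assayed in several model
systems (yeast genetic interactions, fly developmental timing, worm
chemotaxis, HEK293 pAKT/AKT and stability flow cytometry, rat neuronal
growth), and this package turns the raw replicate measurements into
comparable functional scores, phenotype calls and a pathogenicity
classification.  It is aimed at groups running multiplexed or
multi-model variant-effect assays who need the statistical layer, not
the wet lab.

## What it computes

1. **Raw assay metrics** exactly as each assay defines them: flow
   gating and background-subtracted median ratios, the chemotaxis index
   (A − B)/(A + B), western densitometry double normalization, colony
   ratios, rolling medians.
2. **Mixed-model normalization.** Per assay, y = Xβ + Zu + ε with
   genotype fixed effects and batch random intercepts, fitted by REML
   (profiled over the variance ratio); contrasts against WT and null
   controls use Satterthwaite degrees of freedom (validated against
   `lmerTest`).  Random-effect-adjusted values ŷ = Xβ̂ + ε̂ are rescaled
   so null = 0 and WT = 1 (nF), with SEs rescaled by the same factor.
3. **Phenotype calls** per variant × assay: WT-like / GoF / partial LoF
   / complete LoF / dominant-negative (function significantly below
   both controls), plus the parental-vs-PTEN-knockout rescue test that
   separates true dominant negativity from substrate switching.
4. **Classification**: binary LoF at <50% of WT effect, stability
   assays included only for unstable proteins, score s = n_LoF/n_assays,
   labels Pathogenic / Likely Pathogenic / Likely Benign / VUS.
5. **Mechanism**: nF − nS per variant (nS = yeast abundance for yeast
   assays, HEK stability otherwise), stability-independent domains
   AA 1–55, 92–93, 123–131, split cross-assay Pearson matrices, and
   COSMIC-frequency stratification (0 / 1–7 / ≥8 reports) with two-way
   ANOVA.
6. **Synthetic data** with known ground truth for every stage — the
   package is fully testable offline.

## Worked example

Run the whole pipeline on the bundled synthetic study (30 real PTEN
variant ids spanning WT-like to dominant-negative classes):

```sh
variomics run --out demo --seed 7
```

prints the final classification tallies over the 30 variants

```
{"PATHOGENIC": 18, "LIKELY_PATHOGENIC": 0, "LIKELY_BENIGN": 10, "VUS": 2}
```

and writes `scores.tsv`, `calls.tsv`, `classification.tsv`,
`mechanism.tsv`, correlation matrices and a `manifest.json` (run
parameters + per-file hashes) into `demo/`.  A slice of `scores.tsv`
for the HEK293 pAKT/AKT assay:

```
variant_id    assay       n_f      sem   n       p_vs_wt    p_vs_null
     C124S hek_pakt -0.500259 0.030475  16 5.361701e-105 1.025720e-19
     D326N hek_pakt -0.079113 0.039613  16  2.119099e-67 1.336933e-01
     P354Q hek_pakt  0.978994 0.035030  16  6.901615e-01 2.024269e-58
     T167N hek_pakt  0.488351 0.036783  16  1.765714e-20 6.275109e-19
```

Read: C124S sits *below* the null level (dominant negative, p ≪ 0.05
against both controls), D326N is indistinguishable from the null
(complete LoF), P354Q is indistinguishable from WT, and T167N is a
partial LoF at ~49% of WT function.  The classification stage then
yields, for the same variants:

```
variant_id  n_assays  n_lof  score         label
     C124S         6      6    1.0    PATHOGENIC
     D326N         8      8    1.0    PATHOGENIC
     P354Q         6      0    0.0 LIKELY_BENIGN
     T167N         8      4    0.5           VUS
```

(C124S counts 6 assays because its WT-like stability is excluded by the
stability-inclusion rule; D326N's unstable protein adds both stability
assays as LoF.)

The same stages are available as library calls
(`variomics.normalize.score_study`, `variomics.classify.classify_study`,
…) and as individual subcommands (`simulate`, `metrics`, `fit`,
`normalize`, `call`, `classify`, `mechanism`).

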