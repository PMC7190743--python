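# Methods

## The problem

PTEN is a 403-residue lipid/protein phosphatase that antagonizes PI3K-AKT
signaling; missense variants of it recur in autism spectrum disorder,
PTEN hamartoma tumor syndrome and somatic cancers, mostly as variants of
uncertain significance. `variomics` implements the analysis layer of a
multi-model functionalization study of such variants: several independent
assays (yeast genetic-interaction colony growth, fly eclosion timing, worm
NaCl chemotaxis, HEK293 pAKT/AKT flow cytometry, rat neuronal growth
readouts, plus two protein stability/abundance measures) each report a
raw quantitative phenotype per variant, and the pipeline turns these into
control-anchored functional scores, five-way phenotype calls, a four-tier
pathogenicity classification and a stability-dependence mechanism
analysis.

## Statistical model

Each assay's replicate measurements follow a linear mixed model

    y = X beta + Z u + eps,    u ~ N(0, sigma_u^2 I_q),  eps ~ N(0, sigma_e^2 I_N)

with genotype as a fixed effect (cell-means coding, so `beta_g` is the
genotype mean) and experimental batch/day as a random intercept.  Fitting
is REML.  Because the random structure is a single intercept, the
likelihood is profiled over the variance ratio `lambda = sigma_u^2 /
sigma_e^2`: for fixed lambda the GLS fixed effects and the residual
variance are closed-form, computed from per-batch sufficient statistics
via the Woodbury identity (no N x N matrix is formed).  The
one-dimensional profiled criterion is minimized by a log-spaced grid scan
(lambda in [0, 1e8]) followed by bounded refinement (`xatol = 1e-12`),
with the `lambda = 0` boundary always compared explicitly.

Contrasts of each genotype against the WT and null controls are t tests
with Satterthwaite degrees of freedom: `df = 2 f^2 / (g' A g)` where
`f(theta)` is the contrast variance as a function of
`theta = (sigma_u^2, sigma_e^2)`, `g` its finite-difference gradient, and
`A` the asymptotic covariance of the REML estimates obtained from the
finite-difference Hessian of the REML deviance.  The implementation
reproduces `lmerTest` (R) estimates and p-values on shared fixtures to
~6 significant digits.

Numerical edge cases:

- **Boundary fits.** When the variance-ratio estimate is zero, inference
  falls back exactly to OLS on genotype means with `df = N - p` (noted in
  the log); the test suite asserts bit-level agreement with the classical
  pooled t test.
- **Zero residual variance.** A perfectly noise-free fit has
  `sigma_e = 0`; p-values then follow the degenerate convention p = 1 for
  an exactly zero contrast and p = 0 otherwise.  This keeps the noise-free
  limit of the whole pipeline exact, which is used as an end-to-end test.
- **Confounded genotypes.** A genotype observed only in a private batch is
  flagged with a warning; its mean and batch effect are not separable.

## Normalization

Per-row adjusted values `y_hat = X beta_hat + eps_hat` remove the
estimated batch contribution.  Genotype means of adjusted values are then
mapped affinely so the null-control mean is exactly 0 and the WT mean
exactly 1; SEMs are divided by |m_WT - m_null|, the unique linear error
propagation consistent with that map.  The map self-orients assays whose
raw measure decreases with function (pAKT, colony ratio, synapse
density); the per-assay `orientation` flag is metadata validated against
the estimated control separation, not a second transformation.  The
normalization is idempotent and invariant to affine transforms of the raw
data; both are property-tested.

## Phenotype calls and classification

Per variant x assay, the five-way rule (evaluated in order, alpha = 0.05
two-sided on nominal p-values, no multiplicity correction): WT-like if
not significant vs WT; GoF if significant vs WT with mean > 1; dominant
negative if significant vs null with mean < 0 ("below LoF" in assays
without an endogenous-protein readout: yeast, fly — headline complete-LoF
counts fold these in, HEK-style assays keep them separate); partial LoF
if significant vs null with 0 < mean < 1; complete LoF if significant vs
WT but not vs null; otherwise indeterminate (a case the rule set does not
cover; it is excluded from tallies rather than silently called WT-like).
Dominant-negative effects are confirmed by a parental-vs-knockout
pooled-variance t test: ABROGATED when significant and the knockout mean
is no longer below null, RETAINED otherwise; a >10% parental-vs-KO
stability change is flagged separately.

Classification reduces each tested assay to binary LoF (normalized
function < 0.5; exactly 0.5 is WT-like).  Stability assays join a
variant's tally only when the protein is unstable (stability < 0.5),
because WT-like stability does not predict WT-like function while
instability predicts dysfunction.  With score s = n_LoF / n_assays over
non-missing assays, first match wins: Pathogenic (s >= 0.75, >= 3 LoF),
Likely Pathogenic (s > 0.5, >= 2 LoF), Likely Benign (s < 0.25, >= 2
WT-like), else VUS (including the no-data case, which carries a note).
Pathogenic-first precedence resolves the overlap between the s >= 0.75
and s > 0.5 rules.  An exhaustive truth-table test covers all
(n_assays <= 10, n_lof) pairs and checks monotonicity: more LoF assays
never move a label toward benign.

## Mechanism analysis

delta = nF - nS per variant and functional assay, with nS taken from
yeast abundance for yeast assays and HEK293 stability otherwise.
Variants parse from HGVS-protein-style ids (special tokens such as `4A`
and `C124S-4A` have no single position and stay unassigned).
Stability-independent domains are AA 1-55, 92-93 and 123-131 — exactly 66
of 403 positions.  Group comparison of deltas uses a pooled-variance two-
sample t test; pooling across assays uses the per-variant mean delta
(one stated interpretation among several possible).  Cross-assay
concordance is a Pearson matrix over pairwise-complete variants (cells
with < 3 shared variants are missing), optionally restricted to one
domain group.  COSMIC report counts stratify variants into 0 / 1-7 / >= 8
report groups, compared by a two-way fixed-effects ANOVA (stratum +
assay main effects, type-II sums of squares via statsmodels; on balanced
designs this equals the classical decomposition, which the tests verify
by hand on a 2x2 table).

## Synthetic data

The generator emulates the study's replicate structure with known ground
truth; it is the test bed for every downstream stage.

- **Replicate tables**: value = raw(truth) + span * (u_batch + eps), with
  per-assay affine raw maps (anchors chosen as realistic magnitudes per
  readout: colony ratio 1.0 -> 0.35, eclosion 96 h -> 122 h, chemotaxis
  index -0.35 -> 0.72, pAKT effect 0 -> -0.8, etc.).  Noise SDs are
  fractions of each assay's WT-null span; the defaults
  (sigma_batch = 0.05, sigma_resid = 0.15, 4 batches x 4 replicates)
  separate WT from the null control at p < 0.05 at the study's replicate
  counts (n = 16 for the yeast sentinel) — they are not fits to the real
  per-assay variances, which are unpublished.
- **Flow wells**: transfected cells have log-normal expression (rfp);
  gfp = stability x rfp x gain; the pAKT proxy ratio falls with expression
  for functional variants and rises above the untransfected baseline for
  dominant negatives.  Dominant negativity is multiplied by an
  endogenous-protein indicator (1 parental, 0 knockout), the single-
  parameter mechanism that reproduces the rescue behavior.  Channel
  values are truncated at zero; gates mirror the real analysis (sfGFP
  300-20,000 a.u. for pAKT; rfp-positive, gfp < 20,000 for stability).
- **Chemotaxis**: worms reach either scoring zone with probability 0.8
  (middle-zone animals are uncounted), and scored worms split binomially
  with a preference mapped affinely from ground-truth function.
- **Default roster**: 30 real PTEN variant ids spanning all five classes
  plus WT/EV controls, positioned so catalytic-pocket variants are stable
  but dead (stability-independent) while C-terminal LoF tracks stability;
  sized for sub-minute test runs.

What the generator does *not* emulate: real per-assay error magnitudes
and heavy-tailed noise, unbalanced designs, plate/edge effects,
transfection-efficiency drift, genuine biological pleiotropy across
assays (simulated assays share one true function value, so cross-assay
correlations are near 1 rather than the 0.55-0.82 observed in real
data).  Green tests therefore demonstrate correctness of the statistical
machinery and decision rules under the stated model, not robustness to
real-data pathologies.

## Reproduction scope

The per-variant summary statistics of the original study (deposited at
doi:10.5683/SP2/DQOKPB and in the journal's Source Data) are not
redistributed here.  `variomics.source` re-runs the downstream stages on
such a table when provided (`data/pten_source_summary.tsv`), and the
corresponding acceptance test states the published values it checks
(cross-assay correlations, per-assay tallies, final classification
counts); without the deposit that test reports failure rather than
silently passing.

## Problem sizes

Defaults are chosen for fast, deterministic runs: 30-variant roster,
8 assays, 4 batches x 4 replicates (480 rows per assay), 2,000 cells per
flow well, 500-1,000 simulations for calibration checks.  All randomness
flows from explicit integer seeds; identical seeds give byte-identical
outputs.
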