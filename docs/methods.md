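# Methods

## Overview

`bh3rank` couples two pre-treatment tumor readouts — qPCR expression of
multidrug-resistance (MDR) linked genes and BH3-profiling apoptotic
priming — to rank candidate chemotherapy drugs per tumor and to classify
tumors by expected response. The pipeline is deterministic end to end:
identical inputs, configuration and seed produce byte-identical outputs.

## Relative expression (comparative Ct)

For sample *s* and target gene *g*,

- ΔCt(s, g) = Ct(s, g) − mean over reference genes of Ct(s, ref)
- ΔΔCt(s, g) = ΔCt(s, g) − mean over normal control samples of ΔCt(·, g)
- RQ(s, g) = 2^−ΔΔCt(s, g)

Assumptions: ~100 % amplification efficiency for every assay (no Pfaffl
correction, no standard curves, no inter-plate calibration) and reference
genes unaffected by tumor state. Reference gene(s) and control samples are
mandatory, explicit configuration — leaving them implicit invites silent
misuse. The arithmetic mean Ct over reference genes defines the
normalizer. Missing Ct values propagate as missing; nothing is imputed.
Normal samples are normalized against the same control mean, so a
single-control design yields control RQ ≡ 1.

Quartile Ct binning: for one gene, tumors are split at the observed
min / 25th / 50th / 75th percentile / max of tumor Ct (or at explicit
boundaries). Quartile 1 (lowest Ct = highest expression) predicts
resistance, quartile 2 moderate response, quartiles 3–4 sensitivity. A Ct
equal to an interior boundary joins the lower-Ct quartile so that
contiguous printed ranges like 19–23 / 23–26 are honored with the shared
endpoint in the lower range.

Overexpression calls use RQ ≥ fold_threshold (default 2.0, the
conventional two-fold rule; the threshold is a parameter because no
universal cutoff exists). Venn-region counts report, for each realized
gene subset, how many samples overexpress exactly that subset.

## Percent apoptotic priming

Each sample carries solvent-only (DMSO) and uncoupler (FCCP) control
wells. With F̄ the replicate-mean fluorescence,

    priming(i, j) = 100 · (F̄_DMSO(i) − F̄_j(i)) / (F̄_DMSO(i) − F̄_FCCP(i))

This is the unique monotone linear map sending the DMSO mean to 0 % and
the FCCP mean to 100 %. It is invariant to positive affine rescaling of a
sample's RFU values, so plate-reader gain and additive background cancel
per sample. Design choices:

- Single-wavelength JC-1 signal model (no red/green ratio).
- Replicates are averaged *before* normalization (mean, not median); the
  replicate coefficient of variation (sample SD / mean of raw drug-well
  RFU) is reported so callers can reject noisy wells (QC flag default
  CV > 0.20).
- Values outside [0, 100] are clamped, not rejected: overshoot is an
  expected consequence of replicate noise at the scale anchors. Clamping
  events are counted and surfaced in QC.
- F̄_DMSO ≤ F̄_FCCP is a polarity violation and raises an error for that
  sample rather than silently flipping the scale.

## Drug ranking (BPD / RD)

BPD_i = argmax_j priming(i, j); RD(i, j) = priming(i, BPD_i) −
priming(i, j). RD is nonnegative, zero at the best drug, and invariant to
adding a constant to a tumor's whole priming row. Ties in the argmax are
kept as sets and attributed fractionally (1/|BPD_i| each) to the BPD
frequency, so frequencies always sum to 1 regardless of ties — a
deterministic, drug-order-independent convention. Two cohort averages are
exposed because either may be wanted: the cohort-wide mean RD per drug
(tumors where the drug is best contribute 0) and the BPD-conditional mean
RD (restricted to tumors whose best drug is a given reference drug;
undefined, not zero, when no tumor has that reference as its best).
Missing priming entries are excluded pairwise and the effective n per drug
is reported.

## Correlation and significance

Pearson r between RQ(·, gene) and priming(·, drug) across tumors, plus a
pseudo-column against the per-tumor mean priming over all drugs.
Significance is the exact transform t = r·sqrt((n−2)/(1−r²)) on n−2
degrees of freedom, two-tailed — the standard test of r = 0. A permutation
alternative (`pearson_r_permutation`) exists for very small n. Constant
inputs make r undefined (flagged NaN, never 0). Optional stratification by
a metadata column (e.g. gender) computes one matrix per stratum. No
multiple-testing correction is applied by default; a Benjamini–Hochberg
helper is provided for callers who want it.

## Tumor classification

Two independent routes:

**Composite score + thresholds.** score(i) = z(mean priming over drugs) −
z(mean log2 RQ over resistance genes) + z(mean log2 RQ over protective
genes), with cohort z-scoring (population SD; a constant term z-scores to
0). Higher = more sensitive. Default protective set {TP53} (its loss, not
its expression, confers resistance), resistance set = all other genes.
Cuts default to the cohort score terciles; degenerate (coincident)
terciles label everything moderate. The published analysis this emulates
does not state its per-tumor ordering rule, so the score is exposed as an
explicit, documented construction rather than a claimed reproduction.

**PAM (k-medoids).** Classical Kaufman–Rousseeuw BUILD + SWAP on the
tumor × feature matrix of column-z-scored Ct values concatenated with
per-drug priming (z-scoring reconciles cycles with percentage points).
BUILD greedily picks the k medoids minimizing total Euclidean
dissimilarity; SWAP exchanges (medoid, non-medoid) pairs in lexicographic
first-improvement order while any exchange strictly (by > 1e-12) lowers
total cost, guaranteeing termination. There is no random initialization:
fitting is deterministic, and ties break toward the lowest point index.
Clusters are mapped to labels by mean priming (highest → sensitive,
lowest → resistant). k defaults to 3 but is a free parameter; no automatic
k selection is attempted.

Known limitation: BUILD+SWAP is a single-swap descent. It always ends at a
swap-local optimum but this is provably not always the exhaustive optimum
even for n ≤ 8 — a small fraction of random Gaussian instances terminate
strictly above the global minimum, and R's reference `cluster::pam`
converges to the same suboptimal cost on such instances. The test suite
therefore asserts local optimality always, and global optimality only as
the majority behaviour.

## Statistical primitives

- Variance F-test: F = s_a²/s_b², (n_a−1, n_b−1) df, two-tailed
  p = 2·min(P[F ≤ f], P[F ≥ f]); optional larger-variance-on-top
  presentation leaves p unchanged. Zero denominator variance is flagged
  undefined.
- One-way ANOVA: explicit between/within sums of squares with an
  upper-tail F p-value; all-identical data is flagged undefined rather
  than reported as F = 0/0.
- Simple linear regression: least squares via `scipy.stats.linregress`,
  reporting slope, intercept, R² and the two-tailed slope p-value. R²
  equals the squared Pearson r on the same data by construction (checked
  as a cross-module invariant).

Tail probabilities come from `scipy.stats` distributions; sums of squares
and correlation sums are computed in-package so scipy's own test functions
can serve as independent oracles in the test suite.

## Synthetic cohorts

The generator emulates the study design the analysis assumes: 31 tumors
plus a few normal controls, 11 MDR-linked target genes plus a GAPDH-like
reference, and 5 drugs, with a *single latent resistance score* per tumor
as the only coupling between expression and priming:

- s_i ~ Normal(class mean, 1) + gender_effect·[male], with three planted
  classes (sensitive / moderate / resistant) of increasing class means.
- Ct(i, g) = baseline_g − resistance_effect_ct · s_i · loading_g + ε,
  ε ~ Normal(0, ct_noise_sd). Loadings: +1 for resistance genes, −1 for
  the protective gene(s) (higher expression in sensitive tumors), 0 for
  the reference gene. Normals sit at baseline.
- priming(i, j) = clamp(drug_mean_j − resistance_effect_priming · s_i + ε,
  0, 100), ε ~ Normal(0, priming_noise_sd). Priming is a percentage of a
  bounded depolarization scale, hence the clamp.
- Plate wells invert the normalization contract: drug-well target RFU =
  F_DMSO − priming/100 · (F_DMSO − F_FCCP) around fixed control levels
  (1000 / 200 RFU), with multiplicative well noise of CV `rfu_noise_cv`.
  With all noise at zero, `percent_priming` recovers the generated priming
  exactly.

Default study conditions: drug mean primings 42.5 % for the taxane analog,
37.5 % for the vinca/anthracycline pair next in line, 32.5 % for the
remaining two (matching the 40–45 / 35–40 / 30–35 % bands the design
targets); resistance effects 1 cycle and 10 percentage points per latent
SD; noise 0.5 cycles, 5 pp, 2 % well CV; class proportions 13/16/2 out of
31; class means (−3, 0, 3); gender shift +0.5 latent SD for male tumors
(higher MDR expression, lower priming). All draws flow from one
`numpy.random.default_rng(seed)` stream, so cohorts are bitwise
reproducible.

What the generator deliberately does *not* emulate: multi-gene latent
structure (one factor drives everything), amplification-efficiency
artifacts, plate position/batch effects, heavy-tailed or censored Ct
values, dose–response or kinetic behaviour, and correlated replicate
noise. Passing parameter-recovery tests therefore demonstrates that the
pipeline's inference machinery is correct under its own model assumptions,
not that those assumptions hold for any real cohort.

A structural consequence of the planted design worth knowing: with a
resistant-class proportion of 2/31, many simulated cohorts contain zero or
one resistant tumor, and a forced k = 3 clustering of such a cohort cannot
reproduce a three-class labeling; and with unit within-class latent SD,
class means a few SD apart still produce overlapping latent draws, which
bounds any classifier's agreement with the planted labels. Cluster
recovery is therefore assessed in the tests both at the study conditions
and under genuinely forced separation (balanced classes, 8-SD gaps).

## Pipeline and reproducibility

`run_pipeline` composes the stages (input or synthesis → expression →
priming → ranking → correlation → quartiles → classification → report)
from one YAML/JSON config holding every knob and a single seed. Outputs
are CSV/JSON with sorted keys and floats rounded to 10 decimal places in
JSON reports, plus the SHA-256 config hash, so reruns are byte-identical.
A failing stage removes partial outputs and raises an error naming the
stage; a log line per stage records record counts. Problem sizes used in
the shipped tests (31-tumor cohorts, 100-replicate recovery studies,
1000 random ranking matrices, 200 small clustering instances) were chosen
so the whole suite runs in well under a minute on one CPU while keeping
binomial sampling error on recovery rates a few percent.
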