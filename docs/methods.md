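# Methods

## Diagnostic model

A cyst fluid specimen is classified mucinous (mPCN) or non-mucinous (nmPCL)
by two independent procedures.

**Step-wise clinical algorithm.** Six features are evaluated in a fixed,
configurable order; the first firing rule decides mPCN, and a case in which
no rule fires is nmPCL. The default order is

1. cytology ∈ {atypical/suspicious, positive},
2. cyst fluid CEA ≥ 192 ng/ml,
3. viscous fluid,
4. mural nodule present,
5. mucinous EUS impression **and** cyst size ≥ 30 mm.

A missing feature skips its step rather than voting; a case with all six
features missing is unclassifiable (an error, not a default label). The
published description of this algorithm names the six inputs but not their
exact flow, so the order here is a documented reconstruction: cytology leads
because an atypical/suspicious or positive category is essentially 100%
specific for neoplasia in cohort data, CEA follows as the best single fluid
biomarker, then the physical features. The order is part of
`AlgorithmConfig` and is logged per case in the rationale trail; no clinical
validity is claimed for the reconstruction beyond its measured concordance.

Threshold conventions: the CEA cut-off is inclusive (≥ 192 ng/ml), the usual
reading of a biomarker "cut-off". 192 ng/ml is the consensus value; 124
ng/ml is carried as a documented alternate. The 30 mm size threshold is an
extrapolation from guideline "worrisome feature" practice (no size cut-off
is printed in the source description) and is configurable.

**Molecular rule.** mPCN iff at least one retained somatic variant falls in
the mucinous panel {BRAF, KRAS, GNAS, PIK3CA, CDKN2A, PTEN, SMAD4, TP53}.
Germline SNPs never count. A VHL-only profile is annotated SCA-suggestive
but remains nmPCL. With `use_maf_gate`, KRAS variants count only when their
MAF is ≥ 1.8% (the ROC-derived threshold separating neoplastic cysts from
incidental low-fraction KRAS, e.g. PanIN shed into fluid) or when the MAF is
unmeasured; the gate is inclusive at 1.8% ("at least 1.8%") and can only
move cases from mPCN to nmPCL. Genes outside the panel (ATM, APC, FGFR3, …)
never count toward mPCN.

**Grade flag.** For molecularly mucinous cases only:
`elevated_grade_suspicion` iff any somatic variant lies outside KRAS/GNAS,
or KRAS or GNAS carries ≥ 2 distinct protein changes; else
`low_grade_consistent`. This encodes the observed grade structure: low-grade
lesions carry only single KRAS and/or GNAS mutations, while additional genes
and double mutations appear from intermediate grade upward.

## PNA-clamp quantification

ΔCt = Ct(with clamp) − Ct(without clamp). The mutant/wild-type call compares
the sample ΔCt with the 1% control: wild-type iff sample ΔCt ≥ control + 2
cycles, the boundary inclusive as stated by the assay rule. The 2-cycle
margin is a single configurable constant for all four targets (nothing
suggests it is target-specific). Quantification interpolates log10(percent
mutant) piecewise-linearly against ΔCt through the 100/10/1% controls —
chosen because qPCR Ct is log-linear in template abundance; the assay
description prescribes comparison against the ladder without a formula.
Values below the 100% control ΔCt clamp to 100%; beyond the 1% control the
last segment's slope extrapolates downward, floored at the 0.01% detection
limit, which is also returned at or beyond the 0% control ΔCt. The function
is exact at the calibration points, monotone non-increasing in ΔCt and
bounded in [0.01, 100].

## NGS retention rules

An NGS call is retained iff read depth ≥ 10 (inclusive), MAF strictly
greater than 1%, and the annotation confirms a known somatic hotspot; known
germline SNPs are dropped regardless of assay. The annotation is an
injectable `(gene, protein_change) → status` lookup; the packaged default is
a micro-table of the panel's recurrent pancreatic-cyst hotspots (activating
codons for KRAS/GNAS/BRAF/PIK3CA, gene-level somatic status for the
tumor-suppressor genes whose damaging changes are dispersed). The assay's
0.2% analytic limit of sensitivity is carried as policy metadata and plays
no role in retention. Dual-pipeline concordance matches on (gene, protein
change) and merges concordant calls at the mean of the two MAFs.

## Statistics

- 2×2 metrics: sensitivity, specificity, PPV, NPV, accuracy in percent to
  one decimal, rounded half away from zero; any metric with a zero
  denominator is reported as missing, never as 0 or 100. The same
  fraction can print as 41.6% or 41.7% depending on rounding convention, so
  tests compare counts or use ±0.1 tolerance.
- Two-tailed Fisher exact test: two-sided p sums the hypergeometric
  probabilities, over tables with the observed margins, that do not exceed
  the observed table's probability. Two-sided Fisher definitions vary across
  software; this "probability method" is the mainstream convention and is
  verified in the tests against an exact integer-arithmetic enumeration
  oracle for every 2×2 table with total n ≤ 40.
- Mann-Whitney: exact null enumeration for tie-free samples with combined
  n ≤ 25, otherwise the normal approximation with tie correction; the method
  used is always returned with the p-value.
- ROC: candidate thresholds are midpoints between consecutive distinct
  scores plus ∓∞ sentinels, prediction positive at score ≥ threshold; the
  optimal threshold maximizes the Youden index with ties broken toward the
  lower threshold (favoring sensitivity — the screening context). AUC is
  trapezoidal, and on tie-free data equals the Mann-Whitney U statistic
  divided by n₁·n₂ (asserted in the tests).

## Synthetic cohort generator

The generator emulates the cohort structure the classifiers were evaluated
on; it is the test bed for every stage and for parameter recovery. What it
models, with defaults:

- **Cyst type prevalence** from the 46-case surgical series: IPMN 19/46,
  MCN 9/46, PDAC 8/46, SCA 2/46, PNET 3/46, pseudocyst 5/46; grade mix
  within IPMN (12/5/2 LG/MG/HG) and MCN (5/4 LG/MG). Truth label =
  type ∈ {IPMN, MCN, PDAC}, mirroring the surgical gold standard — the
  classifiers are scored against this label, never against each other's
  output (scoring the algorithm against itself would artificially inflate
  the specificity of its own inputs).
- **Mutation spectra** per (type, grade): KRAS 0.82 and GNAS 0.41 for
  mucinous lesions; intermediate grade adds one of {TP53, CDKN2A, APC} with
  probability 0.33; high grade and PDAC add an additional gene with
  probability 0.90; SCA carries VHL with probability 1; pseudocysts carry
  incidental KRAS with probability 0.2. Mucinous KRAS/GNAS carriers acquire
  a second distinct protein change with probability 0.104/0.063.
- **MAF**: log-normal, median 25% (mucinous) and 5% (incidental,
  non-mucinous carriers), σ(ln) 0.9/0.8 — medians from cohort summaries,
  dispersions chosen once so the simulated ranges (~1–90%) match the
  reported ranges; clipped to [0.05, 95]. The Youden-optimal MAF threshold
  implied by these defaults is the density crossing ≈ 11.2% (geometric mean
  of the medians at equal σ); `bayes_maf_boundary` computes it in closed
  form and the ROC recovery test targets it.
- **CEA**: log-normal, medians 2126.7 (mucinous) and 188.9 ng/ml
  (non-mucinous), σ(ln) 1.5 (chosen to span the reported 0.1–11000 range);
  measured in 224/318 of cases.
- **Cytology conditionals**: P(category | mucinous) = 11/147 POS, 53/147
  ATY/SUS, 38/147 NEG, 45/147 ND; P(category | non-mucinous) = 118/162 NEG,
  44/162 ND; missing with probability 9/318.
- **Viscosity**: P(viscous | mucinous) = 91/126, P(viscous | non-mucinous)
  = 36/149, known in 275/318.
- **Partial testing**: KRAS assayed in all cases; the multi-gene panel
  (including GNAS and VHL) in 182/303 — VHL-bearing SCA cases are therefore
  only detectable as SCA when multi-gene tested, as in practice.
- **Assumed, not sourced** (no per-case or conditional data exist):
  mural nodule P(yes)=0.15/0.02 by class, EUS impression 0.70/0.15 mucinous
  by class with 10% unknown, cyst size and amylase drawn from triangular
  distributions anchored at the reported minima/maxima with modes at the
  class medians (an approximate fit to summary statistics by construction).

What passing tests on synthetic data do **not** show: the generator draws
features conditionally independent given the class, has no inter-feature
correlation (e.g. CEA–viscosity), no longitudinal progression, no imaging
detail and no laboratory failure modes beyond missingness; recovery results
demonstrate the pipeline's correctness and calibration, not clinical
performance on real cohorts.

## Problem sizes and determinism

The test suite and the acceptance script use cohorts of 1000–10000 synthetic
cases (recovery checks at n = 1000–2000, marginal checks at n = 10000, ROC
recovery at n = 4000) — sizes at which binomial Monte-Carlo error (3
standard errors ≈ 2.7% for a 93.3% rate at n ≈ 780 mucinous cases) is small
relative to the tolerances asserted. All randomness flows from
`numpy.random.default_rng` seeded per run; replicate seeds are derived
arithmetically from the base seed. Exhaustive checks (Fisher vs enumeration
for all tables n ≤ 40; the 46-case molecular-column reproduction) are
deterministic.

## Known limitations

- The full 318-specimen cohort exists only as printed summary constants; its
  per-case results are emulated, not reproduced. Headline full-cohort rates
  (93.3%/43.5% sensitivity) are covered by parameter-recovery tests on
  cohorts configured to those rates, not by re-analysis of the real data.
- The surgical fixture stores the algorithm label as transcribed because the
  per-case clinical inputs (CEA, viscosity, size) for those 46 cases are not
  published; the clinical classifier is therefore exercised on synthetic and
  user data, and validated against the stored labels only at cohort level
  (89% concordance).
- Two same-type reference cases carry discordant transcribed algorithm
  labels (cases 37 and 38, both SCA, labelled mPCN and nmPCL respectively);
  the fixture preserves the transcription rather than correcting it, and the
  concordance figure reflects it.
- The molecular rule assumes variant calls already passed retention
  filtering; it validates gene-vs-panel membership but cannot re-derive
  depth/MAF filters for calls lacking those fields (as in the MAF-free
  reference fixture).
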