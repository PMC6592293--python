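# pancyst

Classification of pancreatic cyst fluid specimens from EUS-FNA: a step-wise
clinical algorithm, a somatic-mutation decision rule, PNA-clamp qPCR
quantification, NGS variant filtering, and the diagnostic-accuracy statistics
that evaluate them against surgical pathology.

## The problem

Pancreatic cystic lesions (PCL) are common incidental imaging findings. The
mucinous neoplasms among them — intraductal papillary mucinous neoplasm
(IPMN), mucinous cystic neoplasm (MCN) and lesions already harboring ductal
adenocarcinoma (PDAC) — are precursors of pancreatic cancer and need
surveillance or surgery, while serous cystadenomas (SCA), neuroendocrine
tumors (PNET) and pseudocysts do not. Cytology of the aspirated fluid is
specific but insensitive: many specimens are paucicellular (non-diagnostic)
or negative even when the lesion is mucinous. Cyst fluid, however, carries
tumor DNA: *KRAS* and *GNAS* hotspot mutations mark mucinous neoplasia, *VHL*
marks SCA, and additional mutations (*TP53*, *SMAD4*, *CDKN2A*, ...) track
dysplasia grade.

`pancyst` implements, as tested reusable code, both diagnostic routes and the
statistics for comparing them:

- **Clinical algorithm** — six features evaluated step-wise (cytology
  category, cyst fluid CEA ≥ 192 ng/ml, fluid viscosity, mural nodule,
  EUS impression with cyst size); the first firing rule labels the specimen
  mucinous (mPCN), otherwise non-mucinous (nmPCL). Missing features skip
  their step.
- **Molecular rule** — mPCN iff ≥ 1 retained somatic variant in the
  eight-gene panel {*BRAF, KRAS, GNAS, PIK3CA, CDKN2A, PTEN, SMAD4, TP53*},
  with an optional ROC-derived 1.8% *KRAS* MAF gate and a dysplasia-grade
  flag (any non-*KRAS/GNAS* mutation, or a double *KRAS*/*GNAS* mutation,
  raises grade suspicion).
- **PNA-clamp qPCR** — ΔCt = Ct(clamped) − Ct(unclamped); wild-type iff the
  sample ΔCt is ≥ 2 cycles above the 1% control; mutant fraction quantified
  by log-linear interpolation through the 100/10/1% control ladder.
- **NGS filtering** — retain calls with ≥ 10 reads, MAF > 1% and a confirmed
  somatic hotspot annotation; germline SNPs always drop; dual-pipeline
  concordance with mean-MAF merging.
- **Statistics** — 2×2 sensitivity/specificity/PPV/NPV, two-tailed Fisher
  exact test, exact Mann-Whitney test, ROC with Youden-optimal threshold
  (J = sens + spec − 1).
- **Synthetic cohorts** — a generator emulating the cohort structure
  (cyst-type prevalence, grade-conditional mutation spectra, log-normal MAF
  and CEA, cytology conditionals, partial *GNAS* testing) for
  parameter-recovery testing without any external data.

A 46-case surgically verified reference cohort ships with the package
(checksum-guarded TSVs) and is the in-repo evaluation dataset.

## Worked example

```python
from pancyst import load_table1, evaluate_surgical_cohort, classify_molecular

cases = load_table1()                 # 46 resected cases with variant calls
ev = evaluate_surgical_cohort(cases)  # scored against surgical pathology
print(ev.molecular_sensitivity)       # 88.9   (32 of 36 mucinous lesions)
print(ev.cytology_sensitivity)        # 41.7   (15 of 36)
print(ev.algorithm_concordance)       # 89.1   (41 of 46 cases)
print(ev.molecular_vs_cytology_p)     # 4.672072653486718e-05

d = classify_molecular(cases[0])      # IPMN with KRAS p.G12V
print(d.label.value, d.grade_flag.value)  # mPCN low_grade_consistent
```

The numbers read: molecular analysis of preoperative cyst fluid detected 32
of the 36 surgically confirmed mucinous neoplasms (88.9%) versus 15 of 36 for
cytology alone (41.7%), a difference significant by Fisher's exact test; the
clinical algorithm agreed with the resection diagnosis in 41 of 46 cases.

A command-line surface mirrors the library:

```sh
pancyst fixtures table1 --out cases.tsv --variants-out variants.tsv
pancyst classify --cases cases.tsv --variants variants.tsv --mode molecular --out report.json
pancyst evaluate                       # metrics on the packaged cohort
pancyst simulate --n-cases 1000 --seed 7 --out cohort.tsv
```

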