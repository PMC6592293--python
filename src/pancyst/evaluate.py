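"""End-to-end evaluation of the classifiers against pathology ground truth.

`evaluate_surgical_cohort` recomputes every headline diagnostic-accuracy
number for a surgically verified case series: molecular and cytology
sensitivity among mucinous lesions, KRAS/GNAS mutation prevalence (overall
and among cytology-missed cases), clinical-algorithm concordance with
pathology, the Fisher comparison of molecular vs cytology detection, and the
grade-structure counts (additional-gene mutations by dysplasia grade).
"""

from __future__ import annotations

from dataclasses import dataclass

from .classify import classify_molecular
from .fixture import surgical_truth
from .stats import ConfusionTable, confusion, fisher_exact_2x2, round_percent
from .types import AlgorithmConfig, Cytology, CystCase, DxLabel, DysplasiaGrade, PathologyDx

#: Cytology categories that count as a correct mucinous detection.
_DETECTING = (Cytology.ATY_SUS, Cytology.POS)


def cytology_detects(case: CystCase) -> bool:
    """Whether the cytology category alone identifies a neoplasm."""
    return case.cytology in _DETECTING


def has_kras_or_gnas(case: CystCase) -> bool:
    return any(v.gene in ("KRAS", "GNAS") for v in case.somatic_variants())


def has_additional_gene(case: CystCase) -> bool:
    """Any somatic variant outside KRAS/GNAS (grade-associated genes)."""
    return any(v.gene not in ("KRAS", "GNAS") for v in case.somatic_variants())


@dataclass(frozen=True)
class SurgicalEvaluation:
    """All derived quantities for a surgically verified cohort."""

    n_cases: int
    n_mucinous: int
    molecular_confusion: ConfusionTable
    cytology_confusion: ConfusionTable
    algorithm_confusion: ConfusionTable
    cytology_detected_mucinous: int
    kras_gnas_mucinous: int
    cytology_missed: int
    cytology_missed_with_kras_gnas: int
    molecular_vs_cytology_p: float
    low_grade_mucinous: int
    mg_cases: int
    mg_with_additional_gene: int
    hg_or_pdac_cases: int
    hg_or_pdac_with_additional_gene: int
    mcn_cases: int
    mcn_molecular_negative: int

    @property
    def molecular_sensitivity(self) -> float | None:
        return self.molecular_confusion.sensitivity

    @property
    def cytology_sensitivity(self) -> float | None:
        return self.cytology_confusion.sensitivity

    @property
    def algorithm_concordance(self) -> float | None:
        return self.algorithm_confusion.accuracy

    @property
    def kras_gnas_pct(self) -> float | None:
        return round_percent(self.kras_gnas_mucinous, self.n_mucinous)

    @property
    def cytology_missed_kras_gnas_pct(self) -> float | None:
        return round_percent(self.cytology_missed_with_kras_gnas, self.cytology_missed)


def evaluate_surgical_cohort(cases: list[CystCase],
                             cfg: AlgorithmConfig | None = None,
                             recompute_molecular: bool = True) -> SurgicalEvaluation:
    """Score molecular, cytology and algorithm classifications against pathology.

    ``recompute_molecular`` runs :func:`~pancyst.classify.classify_molecular`
    on each case's variants; when False the stored molecular label is used.
    The algorithm label is always taken as stored (its per-case clinical
    inputs are not part of a surgical case table).
    """
    cfg = cfg or AlgorithmConfig()
    truth = [surgical_truth(c) for c in cases]
    if recompute_molecular:
        mol = ["mucinous" if classify_molecular(c, cfg).label == DxLabel.MPCN
               else "non_mucinous" for c in cases]
    else:
        mol = ["mucinous" if c.molecular_label == DxLabel.MPCN else "non_mucinous"
               for c in cases]
    cyt = ["mucinous" if cytology_detects(c) else "non_mucinous" for c in cases]
    alg = ["mucinous" if c.algorithm_label == DxLabel.MPCN else "non_mucinous"
           for c in cases]

    mol_tab = confusion(mol, truth, positive="mucinous")
    cyt_tab = confusion(cyt, truth, positive="mucinous")
    alg_tab = confusion(alg, truth, positive="mucinous")

    mucinous = [c for c, t in zip(cases, truth) if t == "mucinous"]
    n_muc = len(mucinous)
    detected = sum(cytology_detects(c) for c in mucinous)
    missed = [c for c in mucinous if not cytology_detects(c)]
    missed_kg = sum(has_kras_or_gnas(c) for c in missed)
    mol_detected = sum(m == "mucinous" for m, t in zip(mol, truth) if t == "mucinous")

    # paired 2x2: detection by molecular analysis vs by cytology among mucinous
    p = fisher_exact_2x2([[mol_detected, n_muc - mol_detected],
                          [detected, n_muc - detected]])

    mol_by_id = dict(zip((c.case_id for c in cases), mol))
    lg = [c for c in mucinous if c.dysplasia_grade == DysplasiaGrade.LG]
    mg = [c for c in mucinous if c.dysplasia_grade == DysplasiaGrade.MG]
    hg_pdac = [c for c in mucinous
               if c.dysplasia_grade == DysplasiaGrade.HG
               or c.pathology_dx == PathologyDx.PDAC]
    mcn = [c for c in cases if c.pathology_dx == PathologyDx.MCN]

    return SurgicalEvaluation(
        n_cases=len(cases),
        n_mucinous=n_muc,
        molecular_confusion=mol_tab,
        cytology_confusion=cyt_tab,
        algorithm_confusion=alg_tab,
        cytology_detected_mucinous=detected,
        kras_gnas_mucinous=sum(has_kras_or_gnas(c) for c in mucinous),
        cytology_missed=len(missed),
        cytology_missed_with_kras_gnas=missed_kg,
        molecular_vs_cytology_p=p,
        low_grade_mucinous=len(lg),
        mg_cases=len(mg),
        mg_with_additional_gene=sum(has_additional_gene(c) for c in mg),
        hg_or_pdac_cases=len(hg_pdac),
        hg_or_pdac_with_additional_gene=sum(has_additional_gene(c) for c in hg_pdac),
        mcn_cases=len(mcn),
        mcn_molecular_negative=sum(mol_by_id[c.case_id] == "non_mucinous" for c in mcn),
    )
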