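"""The two diagnostic procedures: step-wise clinical algorithm and molecular rule.

Clinical algorithm
    Six cyst fluid / imaging features are evaluated in a fixed, configurable
    order; the first firing rule labels the specimen mucinous (mPCN), and if
    no rule fires it is labelled non-mucinous (nmPCL). Missing features skip
    their step rather than voting. The default order places cytology first
    (an atypical/suspicious or positive cytology is essentially specific for
    neoplasia), then cyst fluid CEA at the 192 ng/ml consensus cut-off, then
    the physical features (viscosity, mural nodule, EUS impression with size).

Molecular rule
    A specimen is mucinous iff at least one retained somatic variant falls in
    the eight-gene mucinous panel (BRAF, KRAS, GNAS, PIK3CA, CDKN2A, PTEN,
    SMAD4, TP53). A VHL-only profile is annotated as suggestive of serous
    cystadenoma. Optionally, a KRAS MAF gate (default 1.8%, ROC-derived)
    discounts low-frequency KRAS calls that may reflect incidental PanIN.

Grade flag
    Low-grade mucinous lesions carry only single KRAS and/or GNAS mutations;
    a variant in any other gene, or two distinct protein changes in KRAS or
    in GNAS, raises suspicion of intermediate/high-grade dysplasia.
"""

from __future__ import annotations

from .types import (
    AlgorithmConfig,
    Cytology,
    CystCase,
    Diagnosis,
    DxLabel,
    EusImpression,
    GradeFlag,
    RuleRecord,
    Tristate,
    VariantCall,
    Viscosity,
)


class UnclassifiableCaseError(ValueError):
    """No clinical feature available, or molecular preconditions unmet."""


def _clinical_steps(case: CystCase, cfg: AlgorithmConfig):
    """Yield (name, available, fired, evidence) for each configured step."""
    def cytology():
        if case.cytology == Cytology.MISSING:
            return False, False, "cytology not available"
        fired = case.cytology in (Cytology.ATY_SUS, Cytology.POS)
        return True, fired, f"cytology {case.cytology.value}"

    def cea():
        if case.cea_ng_ml is None:
            return False, False, "CEA not measured"
        fired = case.cea_ng_ml >= cfg.cea_threshold_ng_ml
        return True, fired, (f"CEA {case.cea_ng_ml:g} ng/ml vs "
                             f"threshold {cfg.cea_threshold_ng_ml:g}")

    def viscosity():
        if case.viscosity == Viscosity.UNKNOWN:
            return False, False, "viscosity not recorded"
        return True, case.viscosity == Viscosity.VISCOUS, f"fluid {case.viscosity.value}"

    def mural_nodule():
        if case.mural_nodule == Tristate.UNKNOWN:
            return False, False, "mural nodule status unknown"
        return True, case.mural_nodule == Tristate.YES, f"mural nodule {case.mural_nodule.value}"

    def eus_size():
        if case.eus_impression == EusImpression.UNKNOWN or case.cyst_size_mm is None:
            return False, False, "EUS impression or cyst size missing"
        fired = (case.eus_impression == EusImpression.MUCINOUS
                 and case.cyst_size_mm >= cfg.size_threshold_mm)
        return True, fired, (f"EUS {case.eus_impression.value}, "
                             f"size {case.cyst_size_mm:g} mm vs {cfg.size_threshold_mm:g}")

    table = {"cytology": cytology, "cea": cea, "viscosity": viscosity,
             "mural_nodule": mural_nodule, "eus_size": eus_size}
    for name in cfg.clinical_step_order:
        yield (name, *table[name]())


def classify_clinical(case: CystCase, cfg: AlgorithmConfig | None = None) -> Diagnosis:
    """Step-wise clinical classification of one specimen.

    Raises :class:`UnclassifiableCaseError` when all six clinical features
    are missing.
    """
    cfg = cfg or AlgorithmConfig()
    any_available = False
    rationale: list[RuleRecord] = []
    label: DxLabel | None = None
    for name, available, fired, evidence in _clinical_steps(case, cfg):
        if not available:
            rationale.append(RuleRecord(name, False, f"skipped: {evidence}"))
            continue
        any_available = True
        rationale.append(RuleRecord(name, fired, evidence))
        if fired and label is None:
            label = DxLabel.MPCN
    if not any_available:
        raise UnclassifiableCaseError(
            f"case {case.case_id}: all clinical features missing")
    return Diagnosis(case.case_id, label or DxLabel.NMPCL,
                     GradeFlag.NOT_APPLICABLE, rationale)


def _counted_variants(case: CystCase, cfg: AlgorithmConfig) -> list[VariantCall]:
    """Panel variants that count toward mPCN, after the optional MAF gate."""
    counted = []
    for v in case.somatic_variants():
        if v.gene not in cfg.mucinous_gene_panel:
            continue
        if (cfg.use_maf_gate and v.gene == "KRAS" and v.maf_percent is not None
                and v.maf_percent < cfg.kras_maf_threshold_pct):
            continue
        counted.append(v)
    return counted


def classify_molecular(case: CystCase, cfg: AlgorithmConfig | None = None) -> Diagnosis:
    """Molecular classification from retained somatic variants.

    Variants are assumed to have passed :func:`pancyst.variants.filter_variants`
    (germline SNPs are additionally ignored here). A variant in a gene absent
    from ``genes_tested`` is an input error.
    """
    cfg = cfg or AlgorithmConfig()
    if not case.genes_tested:
        raise UnclassifiableCaseError(f"case {case.case_id}: no genes tested")
    for v in case.variants:
        if v.gene not in case.genes_tested:
            raise ValueError(
                f"case {case.case_id}: variant in untested gene {v.gene}")
    somatic = case.somatic_variants()
    counted = _counted_variants(case, cfg)
    gated_out = [v for v in somatic
                 if v.gene in cfg.mucinous_gene_panel and v not in counted]
    rationale = [RuleRecord(
        "mucinous_panel",
        bool(counted),
        ("panel variants: " + ", ".join(f"{v.gene} {v.protein_change}" for v in counted))
        if counted else "no retained variant in the mucinous gene panel",
    )]
    if cfg.use_maf_gate:
        rationale.append(RuleRecord(
            "kras_maf_gate", bool(gated_out),
            (f"KRAS calls below {cfg.kras_maf_threshold_pct:g}% MAF discounted: "
             + ", ".join(f"{v.protein_change} @ {v.maf_percent:g}%" for v in gated_out))
            if gated_out else f"no KRAS call below {cfg.kras_maf_threshold_pct:g}% MAF"))
    label = DxLabel.MPCN if counted else DxLabel.NMPCL
    marker_genes = {v.gene for v in somatic}
    if marker_genes and marker_genes <= cfg.nonmucinous_marker_genes:
        rationale.append(RuleRecord(
            "nonmucinous_marker", True,
            f"{'/'.join(sorted(marker_genes))}-only profile: SCA-suggestive"))
    flag = _grade_flag_from_variants(counted, somatic) if label == DxLabel.MPCN \
        else GradeFlag.NOT_APPLICABLE
    return Diagnosis(case.case_id, label, flag, rationale)


def _grade_flag_from_variants(counted: list[VariantCall],
                              somatic: list[VariantCall]) -> GradeFlag:
    non_kras_gnas = [v for v in somatic if v.gene not in ("KRAS", "GNAS")]
    kras_changes = {v.protein_change for v in somatic if v.gene == "KRAS"}
    gnas_changes = {v.protein_change for v in somatic if v.gene == "GNAS"}
    if non_kras_gnas or len(kras_changes) >= 2 or len(gnas_changes) >= 2:
        return GradeFlag.ELEVATED_GRADE_SUSPICION
    return GradeFlag.LOW_GRADE_CONSISTENT


def grade_flag(case: CystCase, cfg: AlgorithmConfig | None = None) -> GradeFlag:
    """Dysplasia-grade suspicion for a molecularly mucinous specimen.

    ``not_applicable`` unless the molecular rule labels the case mPCN;
    otherwise ``elevated_grade_suspicion`` iff any retained variant lies
    outside KRAS/GNAS or either gene carries two or more distinct protein
    changes, else ``low_grade_consistent``.
    """
    cfg = cfg or AlgorithmConfig()
    return classify_molecular(case, cfg).grade_flag
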