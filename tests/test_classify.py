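"""Clinical step-wise algorithm, molecular rule and grade flag."""

import dataclasses

import pytest

from pancyst.classify import (
    UnclassifiableCaseError,
    classify_clinical,
    classify_molecular,
    grade_flag,
)
from pancyst.types import (
    AlgorithmConfig,
    Assay,
    Cytology,
    CystCase,
    DxLabel,
    EusImpression,
    GradeFlag,
    SomaticStatus,
    Tristate,
    VariantCall,
    Viscosity,
)

PANEL = frozenset({"BRAF", "KRAS", "GNAS", "PIK3CA", "CDKN2A", "PTEN", "SMAD4",
                   "TP53", "VHL", "ATM", "APC", "RB1"})


def case(**kw):
    kw.setdefault("case_id", "X")
    kw.setdefault("genes_tested", PANEL)
    return CystCase(**kw)


def vc(gene, change="p.?", maf=None):
    return VariantCall(gene, change, maf, 500, Assay.NGS,
                       SomaticStatus.COSMIC_CONFIRMED)


class TestClinical:
    def test_positive_cytology_alone_is_mucinous_via_first_step(self):
        d = classify_clinical(case(cytology=Cytology.POS))
        assert d.label == DxLabel.MPCN
        assert d.rationale[0].rule == "cytology" and d.rationale[0].fired

    def test_cea_threshold_is_inclusive(self):
        d = classify_clinical(case(cytology=Cytology.NEG, cea_ng_ml=192.0,
                                   viscosity=Viscosity.NON_VISCOUS))
        assert d.label == DxLabel.MPCN
        assert [r.rule for r in d.rationale if r.fired] == ["cea"]
        assert classify_clinical(case(cytology=Cytology.NEG, cea_ng_ml=191.9)
                                 ).label == DxLabel.NMPCL

    def test_all_features_non_mucinous_yields_nmpcl(self):
        d = classify_clinical(case(
            cytology=Cytology.NEG, cea_ng_ml=10.0, cyst_size_mm=12.0,
            mural_nodule=Tristate.NO, viscosity=Viscosity.NON_VISCOUS,
            eus_impression=EusImpression.NON_MUCINOUS))
        assert d.label == DxLabel.NMPCL
        assert not any(r.fired for r in d.rationale)
        assert [r.rule for r in d.rationale] == list(
            AlgorithmConfig().clinical_step_order)

    def test_eus_step_needs_both_impression_and_size(self):
        assert classify_clinical(case(
            cytology=Cytology.NEG, eus_impression=EusImpression.MUCINOUS,
            cyst_size_mm=35.0)).label == DxLabel.MPCN
        assert classify_clinical(case(
            cytology=Cytology.NEG, eus_impression=EusImpression.MUCINOUS,
            cyst_size_mm=20.0)).label == DxLabel.NMPCL

    def test_missing_steps_are_recorded_as_skipped(self):
        d = classify_clinical(case(viscosity=Viscosity.VISCOUS))
        assert d.label == DxLabel.MPCN
        skipped = [r.rule for r in d.rationale if r.evidence.startswith("skipped")]
        assert set(skipped) == {"cytology", "cea", "mural_nodule", "eus_size"}

    def test_fully_missing_case_is_unclassifiable(self):
        with pytest.raises(UnclassifiableCaseError):
            classify_clinical(case())

    def test_determinism_includes_rationale(self):
        c = case(cytology=Cytology.ATY_SUS, cea_ng_ml=500.0)
        assert classify_clinical(c) == classify_clinical(c)


class TestMolecular:
    def test_single_kras_variant_is_mucinous(self):
        d = classify_molecular(case(variants=[vc("KRAS", "p.G12V")]))
        assert d.label == DxLabel.MPCN

    def test_vhl_only_profile_is_non_mucinous_and_sca_suggestive(self):
        d = classify_molecular(case(variants=[vc("VHL")]))
        assert d.label == DxLabel.NMPCL
        assert any("SCA-suggestive" in r.evidence for r in d.rationale)

    def test_no_variants_is_non_mucinous(self):
        assert classify_molecular(case()).label == DxLabel.NMPCL

    def test_off_panel_gene_does_not_count(self):
        assert classify_molecular(case(variants=[vc("ATM")])).label == DxLabel.NMPCL

    def test_germline_snp_never_counts(self):
        snp = VariantCall("TP53", "p.P72R", 49.0, 800, Assay.NGS,
                          SomaticStatus.GERMLINE_SNP)
        assert classify_molecular(case(variants=[snp])).label == DxLabel.NMPCL

    def test_maf_gate_discounts_low_frequency_kras(self):
        cfg = AlgorithmConfig(use_maf_gate=True)
        assert classify_molecular(case(variants=[vc("KRAS", "p.G12D", 1.5)]),
                                  cfg).label == DxLabel.NMPCL
        assert classify_molecular(case(variants=[vc("KRAS", "p.G12D", 1.8)]),
                                  cfg).label == DxLabel.MPCN
        # missing MAF is not gated
        assert classify_molecular(case(variants=[vc("KRAS", "p.G12D")]),
                                  cfg).label == DxLabel.MPCN

    def test_maf_gate_only_moves_cases_toward_non_mucinous(self, table1):
        gated = AlgorithmConfig(use_maf_gate=True)
        for c in table1:
            plain = classify_molecular(c).label
            with_gate = classify_molecular(c, gated).label
            assert not (plain == DxLabel.NMPCL and with_gate == DxLabel.MPCN)

    def test_no_genes_tested_is_an_error(self):
        with pytest.raises(UnclassifiableCaseError):
            classify_molecular(CystCase(case_id="X"))

    def test_reproduces_stored_molecular_labels_on_all_46_cases(self, table1):
        for c in table1:
            assert classify_molecular(c).label == c.molecular_label, c.case_id

    def test_enlarging_the_panel_never_flips_mucinous_to_non_mucinous(self, table1):
        small = AlgorithmConfig(mucinous_gene_panel=frozenset({"KRAS", "GNAS"}))
        full = AlgorithmConfig()
        for c in table1:
            if classify_molecular(c, small).label == DxLabel.MPCN:
                assert classify_molecular(c, full).label == DxLabel.MPCN

    def test_panel_growth_trades_specificity_for_sensitivity(self, table1):
        from pancyst.evaluate import evaluate_surgical_cohort

        small = evaluate_surgical_cohort(
            table1, AlgorithmConfig(mucinous_gene_panel=frozenset({"KRAS", "GNAS"})))
        full = evaluate_surgical_cohort(table1)
        assert full.molecular_sensitivity >= small.molecular_sensitivity
        assert full.molecular_confusion.specificity <= small.molecular_confusion.specificity


class TestGradeFlag:
    def test_single_kras_plus_gnas_is_low_grade_consistent(self):
        c = case(variants=[vc("KRAS", "p.G12V"), vc("GNAS", "p.R201C")])
        assert grade_flag(c) == GradeFlag.LOW_GRADE_CONSISTENT

    def test_additional_gene_raises_suspicion(self):
        c = case(variants=[vc("KRAS", "p.G12V"), vc("TP53"), vc("PIK3CA")])
        assert grade_flag(c) == GradeFlag.ELEVATED_GRADE_SUSPICION

    def test_double_same_gene_mutation_raises_suspicion(self):
        c = case(variants=[vc("KRAS", "p.G12A"), vc("KRAS", "p.G12T"),
                           vc("GNAS", "p.R201C"), vc("GNAS", "p.R201H")])
        assert grade_flag(c) == GradeFlag.ELEVATED_GRADE_SUSPICION

    def test_molecularly_negative_case_is_not_applicable(self):
        assert grade_flag(case()) == GradeFlag.NOT_APPLICABLE

    def test_flags_on_reference_cases(self, table1):
        by_id = {c.case_id: c for c in table1}
        assert grade_flag(by_id["2"]) == GradeFlag.LOW_GRADE_CONSISTENT
        assert grade_flag(by_id["16"]) == GradeFlag.ELEVATED_GRADE_SUSPICION
        assert grade_flag(by_id["18"]) == GradeFlag.ELEVATED_GRADE_SUSPICION
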