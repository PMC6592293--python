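"""Domain data model for pancreatic cyst fluid classification.

A pancreatic cystic lesion (PCL) sampled by EUS-FNA yields cyst fluid that can
be examined cytologically, assayed chemically (CEA, amylase) and genotyped
(PNA-clamp qPCR and amplicon NGS).  The pipeline classifies each specimen as a
mucinous pancreatic cystic neoplasm (``mPCN`` -- IPMN, MCN or PDAC-associated)
or a non-mucinous lesion (``nmPCL`` -- serous cystadenoma, neuroendocrine
tumor, pseudocyst), two routes that differ in management: mucinous neoplasms
are precursor lesions of pancreatic adenocarcinoma and warrant surveillance or
surgery.

The types here are shared by every downstream stage (variant filtering, the
clinical and molecular classifiers, the statistics, the simulator).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field


class PathologyDx(str, enum.Enum):
    """Surgical pathology diagnosis of the resected cyst."""

    IPMN = "IPMN"
    MCN = "MCN"
    PDAC = "PDAC"
    SCA = "SCA"
    PNET = "PNET"
    PSEUDOCYST = "PSEUDOCYST"
    UNKNOWN = "UNKNOWN"


#: Pathology diagnoses that count as mucinous neoplasia (ground truth).
MUCINOUS_PATHOLOGY = frozenset({PathologyDx.IPMN, PathologyDx.MCN, PathologyDx.PDAC})


class DysplasiaGrade(str, enum.Enum):
    """Histologic grade of the precursor lesion (IPMN/MCN only)."""

    LG = "LG"   # low grade
    MG = "MG"   # intermediate grade
    HG = "HG"   # high grade
    NA = "NA"


class Cytology(str, enum.Enum):
    """Four-tier cytology reporting categories for cyst fluid."""

    ND = "ND"            # non-diagnostic (paucicellular or acellular)
    NEG = "NEG"          # negative for malignancy
    ATY_SUS = "ATY_SUS"  # atypical / suspicious for malignancy
    POS = "POS"          # positive for malignancy
    MISSING = "MISSING"  # specimen not submitted for cytology


class Tristate(str, enum.Enum):
    YES = "yes"
    NO = "no"
    UNKNOWN = "unknown"


class Viscosity(str, enum.Enum):
    VISCOUS = "viscous"
    NON_VISCOUS = "non_viscous"
    UNKNOWN = "unknown"


class EusImpression(str, enum.Enum):
    MUCINOUS = "mucinous"
    NON_MUCINOUS = "non_mucinous"
    UNKNOWN = "unknown"


class DxLabel(str, enum.Enum):
    """Binary diagnostic label produced by either classifier."""

    MPCN = "mPCN"
    NMPCL = "nmPCL"


class GradeFlag(str, enum.Enum):
    LOW_GRADE_CONSISTENT = "low_grade_consistent"
    ELEVATED_GRADE_SUSPICION = "elevated_grade_suspicion"
    NOT_APPLICABLE = "not_applicable"


class Assay(str, enum.Enum):
    PNA_CLAMP = "PNA_CLAMP"
    NGS = "NGS"


class SomaticStatus(str, enum.Enum):
    COSMIC_CONFIRMED = "cosmic_confirmed"
    GERMLINE_SNP = "germline_snp"
    UNREVIEWED = "unreviewed"


@dataclass
class VariantCall:
    """One somatic variant call in cyst fluid DNA.

    ``maf_percent`` is the mutant allele frequency: the relative fraction of
    mutant amplicon in the total DNA amplicon at the locus, in percent.
    """

    gene: str
    protein_change: str = "p.?"
    maf_percent: float | None = None
    read_depth: int | None = None
    assay: Assay = Assay.NGS
    somatic_status: SomaticStatus = SomaticStatus.COSMIC_CONFIRMED

    def __post_init__(self) -> None:
        self.gene = self.gene.upper()
        if self.maf_percent is not None and not (0.0 < self.maf_percent <= 100.0):
            raise ValueError(
                f"MAF must be in (0, 100], got {self.maf_percent} for {self.gene}"
            )
        if self.read_depth is not None and self.read_depth < 0:
            raise ValueError(f"read_depth must be non-negative, got {self.read_depth}")

    @property
    def key(self) -> tuple[str, str]:
        """Identity used for cross-pipeline concordance matching."""
        return (self.gene, self.protein_change)


@dataclass
class CystCase:
    """One cyst fluid specimen with clinical features and variant calls."""

    case_id: str
    pathology_dx: PathologyDx = PathologyDx.UNKNOWN
    dysplasia_grade: DysplasiaGrade = DysplasiaGrade.NA
    cytology: Cytology = Cytology.MISSING
    cea_ng_ml: float | None = None
    amylase_u_l: float | None = None
    cyst_size_mm: float | None = None
    mural_nodule: Tristate = Tristate.UNKNOWN
    viscosity: Viscosity = Viscosity.UNKNOWN
    eus_impression: EusImpression = EusImpression.UNKNOWN
    genes_tested: frozenset[str] = frozenset()
    variants: list[VariantCall] = field(default_factory=list)
    algorithm_label: DxLabel | None = None
    molecular_label: DxLabel | None = None
    metadata: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.genes_tested = frozenset(g.upper() for g in self.genes_tested)
        for v in self.variants:
            if v.gene not in self.genes_tested:
                raise ValueError(
                    f"case {self.case_id}: variant in {v.gene} but gene not in genes_tested"
                )
        if self.dysplasia_grade != DysplasiaGrade.NA and self.pathology_dx not in (
            PathologyDx.IPMN,
            PathologyDx.MCN,
        ):
            raise ValueError(
                f"case {self.case_id}: dysplasia grade only applies to IPMN/MCN"
            )
        for val, name in ((self.cea_ng_ml, "cea_ng_ml"),
                          (self.amylase_u_l, "amylase_u_l"),
                          (self.cyst_size_mm, "cyst_size_mm")):
            if val is not None and val < 0:
                raise ValueError(f"case {self.case_id}: {name} must be non-negative")

    def somatic_variants(self) -> list[VariantCall]:
        """Variants usable by classifiers (germline SNPs are never used)."""
        return [v for v in self.variants if v.somatic_status != SomaticStatus.GERMLINE_SNP]


@dataclass
class AlgorithmConfig:
    """Thresholds and gene panels shared by the two classifiers.

    Defaults: 192 ng/ml cyst fluid CEA (consensus mucinous cut-off; 124 ng/ml
    is a data-driven alternate), 1.8% KRAS MAF (ROC-derived, used only when
    ``use_maf_gate``), a 30 mm size threshold for the EUS-impression step, and
    the eight-gene mucinous panel used by the molecular rule.
    """

    cea_threshold_ng_ml: float = 192.0
    kras_maf_threshold_pct: float = 1.8
    size_threshold_mm: float = 30.0
    mucinous_gene_panel: frozenset[str] = frozenset(
        {"BRAF", "KRAS", "GNAS", "PIK3CA", "CDKN2A", "PTEN", "SMAD4", "TP53"}
    )
    nonmucinous_marker_genes: frozenset[str] = frozenset({"VHL"})
    use_maf_gate: bool = False
    # evaluation order of the step-wise clinical algorithm (see classify module)
    clinical_step_order: tuple[str, ...] = (
        "cytology", "cea", "viscosity", "mural_nodule", "eus_size",
    )

    def __post_init__(self) -> None:
        for thr, name in ((self.cea_threshold_ng_ml, "cea_threshold_ng_ml"),
                          (self.kras_maf_threshold_pct, "kras_maf_threshold_pct"),
                          (self.size_threshold_mm, "size_threshold_mm")):
            if thr <= 0:
                raise ValueError(f"{name} must be strictly positive")
        self.mucinous_gene_panel = frozenset(g.upper() for g in self.mucinous_gene_panel)
        self.nonmucinous_marker_genes = frozenset(
            g.upper() for g in self.nonmucinous_marker_genes
        )
        if self.mucinous_gene_panel & self.nonmucinous_marker_genes:
            raise ValueError("mucinous and non-mucinous gene panels must be disjoint")


@dataclass
class RuleRecord:
    """One evaluated rule in a rationale trail."""

    rule: str
    fired: bool
    evidence: str


@dataclass
class Diagnosis:
    """Classifier output: label, grade flag and rule-by-rule rationale."""

    case_id: str
    label: DxLabel
    grade_flag: GradeFlag = GradeFlag.NOT_APPLICABLE
    rationale: list[RuleRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.rationale:
            raise ValueError("rationale trail must be non-empty")
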