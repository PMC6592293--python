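"""Packaged 46-case surgical reference cohort and full-cohort summary counts.

The package ships an exact transcription of a 46-specimen surgical resection
series of pancreatic cystic lesions: for every case, the surgical pathology
diagnosis (the diagnostic gold standard), dysplasia grade where applicable,
the preoperative cyst fluid cytology category, the somatic variants detected
in the fluid, and the labels assigned by the step-wise clinical algorithm and
by the molecular rule. Per-case MAF values were not reported for this series
and are stored as missing, as are the per-case clinical measurements
(CEA, size, viscosity); the transcribed algorithm label is therefore stored
as given rather than recomputed.

Summary constants for the full 318-specimen EUS-FNA cohort (cytology category
counts, mucinous split per category, numbers molecularly tested) are exposed
as :data:`COHORT_SUMMARY`; per-case data for that cohort are unpublished and
are only emulated by :mod:`pancyst.simulate`.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from .io import attach_variants, read_case_table, read_variant_table
from .types import Cytology, CystCase, MUCINOUS_PATHOLOGY, PathologyDx

_CASES_SHA256 = "33c49d58c77db2d629943c0ef686ee8d1ace99104fa89fa341e449dc1e190ce2"
_VARIANTS_SHA256 = "bedfbb4af645e6392d0d2d6469cb947cf10d4bcf7e0f8d80083b27e741885582"


class FixtureIntegrityError(RuntimeError):
    """Packaged fixture does not match its recorded checksum."""


def _fixture_path(name: str) -> Path:
    return Path(resources.files("pancyst").joinpath("data", name))  # type: ignore[arg-type]


def _verify(path: Path, expected: str) -> None:
    digest = hashlib.sha256(path.read_bytes()).hexdigest()
    if digest != expected:
        raise FixtureIntegrityError(
            f"{path.name}: checksum {digest} != expected {expected}; "
            "the packaged fixture has been modified")


def load_table1(verify_checksum: bool = True) -> list[CystCase]:
    """Load the 46 surgical cases with their variant calls attached.

    The packaged TSVs are checksum-guarded: silent edits raise
    :class:`FixtureIntegrityError`.
    """
    cases_path = _fixture_path("table1_cases.tsv")
    variants_path = _fixture_path("table1_variants.tsv")
    if verify_checksum:
        _verify(cases_path, _CASES_SHA256)
        _verify(variants_path, _VARIANTS_SHA256)
    cases = read_case_table(cases_path, dialect="tsv")
    variants = read_variant_table(variants_path, dialect="tsv")
    return attach_variants(cases, variants)


def surgical_truth(case: CystCase) -> str:
    """Ground-truth class from surgical pathology.

    A lesion is mucinous iff the resection diagnosis is IPMN, MCN or PDAC.
    """
    if case.pathology_dx == PathologyDx.UNKNOWN:
        raise ValueError(f"case {case.case_id}: pathology diagnosis unknown")
    return "mucinous" if case.pathology_dx in MUCINOUS_PATHOLOGY else "non_mucinous"


@dataclass(frozen=True)
class CohortSummary:
    """Printed summary counts for the full 318-specimen EUS-FNA cohort."""

    n_total: int = 318
    n_with_cytology: int = 309
    cytology_counts: dict[Cytology, int] = field(default_factory=lambda: {
        Cytology.ND: 89, Cytology.NEG: 156, Cytology.ATY_SUS: 53, Cytology.POS: 11,
    })
    mucinous_by_cytology: dict[Cytology, int] = field(default_factory=lambda: {
        Cytology.ND: 45, Cytology.NEG: 38, Cytology.ATY_SUS: 53, Cytology.POS: 11,
    })
    n_kras_tested: int = 303
    n_dual_tested: int = 182

    def __post_init__(self) -> None:
        if sum(self.cytology_counts.values()) != self.n_with_cytology:
            raise ValueError("cytology counts must sum to n_with_cytology")
        for k, m in self.mucinous_by_cytology.items():
            if m > self.cytology_counts[k]:
                raise ValueError(f"mucinous count exceeds total for {k}")


COHORT_SUMMARY = CohortSummary()
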