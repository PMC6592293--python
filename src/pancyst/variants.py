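"""NGS variant retention rules and dual-pipeline concordance.

Amplicon-panel calls are retained for classification only when they have at
least 10 supporting reads, a mutant allele frequency strictly above 1%, and a
known somatic (hotspot) annotation; known germline SNPs are always discarded.
Annotation is an injectable lookup so that curated hotspot/SNP tables can be
swapped in without any network access; a micro-subset covering the panel's
recurrent pancreatic-cyst hotspots is packaged as the default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

from .types import Assay, SomaticStatus, VariantCall

#: Recurrent hotspot changes per gene for the cyst panel. Genes whose exact
#: protein change varies across tumors (TP53, SMAD4, ...) are annotated
#: somatic at the gene level here; "p.?" matches any change in such genes.
HOTSPOT_SOMATIC: dict[str, frozenset[str] | None] = {
    "KRAS": frozenset({"p.G12D", "p.G12V", "p.G12R", "p.G12A", "p.G12C", "p.G12S",
                       "p.G12T", "p.G13D", "p.Q61H", "p.Q61R", "p.Q61L", "p.Q61C"}),
    "GNAS": frozenset({"p.R201C", "p.R201H", "p.R201S"}),
    "BRAF": frozenset({"p.V600E", "p.T599I", "p.?"}),
    "PIK3CA": frozenset({"p.E542K", "p.E545K", "p.H1047R", "p.?"}),
    # tumor-suppressor genes: inactivating changes are spread across the gene
    "TP53": None, "CDKN2A": None, "PTEN": None, "SMAD4": None,
    "VHL": None, "APC": None, "ATM": None, "RB1": None,
}

#: Common germline polymorphisms that recur in panel output.
KNOWN_GERMLINE_SNPS: frozenset[tuple[str, str]] = frozenset({
    ("TP53", "p.P72R"),
    ("KIT", "p.M541L"),
    ("PDGFRA", "p.V824V"),
    ("FGFR3", "p.T651T"),
})


def default_annotation(gene: str, protein_change: str) -> SomaticStatus:
    """Packaged hotspot/SNP lookup: gene + protein change -> somatic status."""
    gene = gene.upper()
    if (gene, protein_change) in KNOWN_GERMLINE_SNPS:
        return SomaticStatus.GERMLINE_SNP
    if gene in HOTSPOT_SOMATIC:
        allowed = HOTSPOT_SOMATIC[gene]
        if allowed is None or protein_change in allowed:
            return SomaticStatus.COSMIC_CONFIRMED
    return SomaticStatus.UNREVIEWED


@dataclass
class FilterPolicy:
    """Retention thresholds for NGS calls.

    ``limit_of_sensitivity_pct`` is the assay's analytic floor; it is metadata
    only and plays no part in the retention rule.
    """

    min_reads: int = 10
    min_maf_percent: float = 1.0
    require_both_pipelines: bool = True
    annotation: Callable[[str, str], SomaticStatus] = field(default=default_annotation)
    limit_of_sensitivity_pct: float = 0.2

    def __post_init__(self) -> None:
        if self.min_reads < 1:
            raise ValueError("min_reads must be >= 1")
        if self.min_maf_percent < 0:
            raise ValueError("min_maf_percent must be >= 0")


def annotate(call: VariantCall, policy: FilterPolicy) -> VariantCall:
    """Resolve an unreviewed call's somatic status via the policy's lookup."""
    if call.somatic_status == SomaticStatus.UNREVIEWED:
        call.somatic_status = policy.annotation(call.gene, call.protein_change)
    return call


def filter_variants(calls: list[VariantCall],
                    policy: FilterPolicy | None = None) -> list[VariantCall]:
    """Apply the retention rules; order-preserving, output is a sublist.

    NGS calls are kept iff read_depth >= min_reads, MAF strictly greater than
    min_maf_percent, and the annotation confirms a somatic hotspot. Known
    germline SNPs are dropped regardless of assay. Clamp-assay calls
    otherwise pass through untouched (their quantification and confirmation
    happen upstream, in :mod:`pancyst.clamp`).
    """
    policy = policy or FilterPolicy()
    kept: list[VariantCall] = []
    for call in calls:
        call = annotate(call, policy)
        if call.somatic_status == SomaticStatus.GERMLINE_SNP:
            continue
        if call.assay == Assay.PNA_CLAMP:
            kept.append(call)
            continue
        if call.read_depth is None or call.maf_percent is None:
            raise ValueError(
                f"NGS call {call.gene} {call.protein_change}: read depth and MAF required")
        if (call.read_depth >= policy.min_reads
                and call.maf_percent > policy.min_maf_percent
                and call.somatic_status == SomaticStatus.COSMIC_CONFIRMED):
            kept.append(call)
    return kept


def concordant_calls(
    pipeline_a: list[VariantCall], pipeline_b: list[VariantCall]
) -> tuple[list[VariantCall], list[VariantCall], list[VariantCall]]:
    """Compare calls from two variant-calling pipelines.

    Calls match on (gene, protein change); a concordant call takes the mean
    MAF of its two sources. Returns ``(concordant, only_a, only_b)`` — an
    exhaustive, disjoint partition of the two call sets.
    """
    by_key_b = {c.key: c for c in pipeline_b}
    keys_a = {c.key for c in pipeline_a}
    concordant: list[VariantCall] = []
    only_a: list[VariantCall] = []
    for a in pipeline_a:
        b = by_key_b.get(a.key)
        if b is None:
            only_a.append(a)
            continue
        mafs = [m for m in (a.maf_percent, b.maf_percent) if m is not None]
        concordant.append(VariantCall(
            gene=a.gene,
            protein_change=a.protein_change,
            maf_percent=sum(mafs) / len(mafs) if mafs else None,
            read_depth=a.read_depth if a.read_depth is not None else b.read_depth,
            assay=a.assay,
            somatic_status=a.somatic_status,
        ))
    only_b = [b for b in pipeline_b if b.key not in keys_a]
    return concordant, only_a, only_b
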