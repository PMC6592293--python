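"""PNA-clamp real-time PCR interpretation.

A peptide nucleic acid (PNA) clamp blocks amplification of the wild-type
allele, so mutant template amplifies preferentially in the clamped reaction.
Each target is run with and without the clamp; the cycle-threshold difference
DeltaCt = Ct(with clamp) - Ct(without clamp) shrinks as the mutant fraction
grows. Each run carries a four-point dilution calibration (100%, 10%, 1% and
0% mutant); the sample DeltaCt is scored against the 1% control for the
mutant / wild-type call and against the full ladder for quantification.

Because qPCR Ct is log-linear in template abundance, quantification
interpolates log10(mutant percent) piecewise-linearly against DeltaCt through
the 100/10/1% control points, clamped to 100% below the 100%-control DeltaCt
and floored at the assay detection limit (0.01%) at or beyond the 0% control.
"""

from __future__ import annotations

import csv
import enum
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

#: Margin (cycles) above the 1% control at which a sample is reported
#: wild-type; at exactly the margin the call is wild-type.
WILD_TYPE_MARGIN_CYCLES = 2.0

#: Smallest mutant fraction (percent) the diluted-control series resolves.
DETECTION_LIMIT_PCT = 0.01

CONTROL_LEVELS = (100.0, 10.0, 1.0, 0.0)


class ClampTarget(str, enum.Enum):
    KRAS_12_13 = "KRAS_12_13"
    KRAS_61 = "KRAS_61"
    GNAS_201 = "GNAS_201"
    BRAF_598_602 = "BRAF_598_602"


class ClampCall(str, enum.Enum):
    MUTANT = "mutant"
    WILD_TYPE = "wild_type"


@dataclass
class ClampAssay:
    """Paired Ct values plus the control calibration for one target."""

    target: ClampTarget
    ct_with_clamp: float
    ct_without_clamp: float
    controls: dict[float, float]  # % mutant -> DeltaCt (cycles)

    def __post_init__(self) -> None:
        missing = [lvl for lvl in CONTROL_LEVELS if lvl not in self.controls]
        if missing:
            raise ValueError(f"missing control levels: {missing}")
        # DeltaCt must grow strictly as mutant fraction falls
        dcts = [self.controls[lvl] for lvl in CONTROL_LEVELS]
        if not all(a < b for a, b in zip(dcts, dcts[1:])):
            raise ValueError(
                "control DeltaCt must strictly increase as % mutant decreases")


def delta_ct(assay: ClampAssay) -> float:
    """DeltaCt = Ct(with clamp) - Ct(without clamp), in cycles."""
    if not (math.isfinite(assay.ct_with_clamp) and math.isfinite(assay.ct_without_clamp)):
        raise ValueError("Ct values must be finite")
    return assay.ct_with_clamp - assay.ct_without_clamp


def call_clamp(sample_dct: float, assay: ClampAssay,
               margin: float = WILD_TYPE_MARGIN_CYCLES) -> ClampCall:
    """Mutant/wild-type call against the 1% control.

    Wild-type iff the sample DeltaCt is at least ``margin`` cycles above the
    1% control DeltaCt (the boundary itself is wild-type); otherwise mutant.
    A mutant call is an assay-level result; reporting additionally requires
    sequence confirmation (``somatic_status != unreviewed`` on the resulting
    :class:`~pancyst.types.VariantCall`).
    """
    if 1.0 not in assay.controls:
        raise ValueError("1% control required for the clamp call")
    if sample_dct >= assay.controls[1.0] + margin:
        return ClampCall.WILD_TYPE
    return ClampCall.MUTANT


def quantify_maf(sample_dct: float, assay: ClampAssay) -> float:
    """Mutant fraction (percent) from the control calibration curve.

    Exact at the calibration points (100/10/1%), log-linear between them,
    clamped to 100% below the 100%-control DeltaCt. Beyond the 1% control the
    last segment's slope extrapolates downward, floored at the 0.01% detection
    limit, which is also returned for any DeltaCt at or above the 0% control.
    """
    c100, c10, c1, c0 = (assay.controls[lvl] for lvl in CONTROL_LEVELS)
    if sample_dct >= c0:
        return DETECTION_LIMIT_PCT
    if sample_dct <= c100:
        return 100.0
    # log10(percent): 2 at the 100% control, 1 at 10%, 0 at 1%
    log10p = float(np.interp(sample_dct, [c100, c10, c1], [2.0, 1.0, 0.0]))
    if sample_dct > c1:  # np.interp clips right; extrapolate with last slope
        slope = -1.0 / (c1 - c10)  # decades per cycle, negative
        log10p = 0.0 + slope * (sample_dct - c1)
    return max(10.0 ** log10p, DETECTION_LIMIT_PCT)


@dataclass
class PlateWell:
    well: str
    target: ClampTarget
    ct_with_clamp: float
    ct_without_clamp: float
    role: str                       # "sample" or "control"
    control_percent: float | None   # set for control wells


def read_plate(path: str | Path) -> list[PlateWell]:
    """Read a qPCR plate export TSV (well, target, Ct pair, role, control %)."""
    wells: list[PlateWell] = []
    with Path(path).open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"well", "target", "ct_with_clamp", "ct_without_clamp", "role"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise ValueError(f"{path}: plate export must contain {sorted(required)}")
        for row in reader:
            pct = row.get("control_percent")
            wells.append(PlateWell(
                well=row["well"],
                target=ClampTarget(row["target"]),
                ct_with_clamp=float(row["ct_with_clamp"]),
                ct_without_clamp=float(row["ct_without_clamp"]),
                role=row["role"],
                control_percent=float(pct) if pct not in (None, "") else None,
            ))
    return wells


def quantify_plate(wells: list[PlateWell]) -> list[dict]:
    """Interpret every sample well on a plate against its target's controls.

    Returns one record per sample well with DeltaCt, the mutant/wild-type
    call, and the quantified mutant percent for mutant calls.
    """
    by_target: dict[ClampTarget, dict[float, float]] = {}
    for w in wells:
        if w.role == "control":
            if w.control_percent is None:
                raise ValueError(f"control well {w.well} lacks control_percent")
            by_target.setdefault(w.target, {})[w.control_percent] = (
                w.ct_with_clamp - w.ct_without_clamp)
    results = []
    for w in wells:
        if w.role != "sample":
            continue
        if w.target not in by_target:
            raise ValueError(f"no controls on plate for target {w.target.value}")
        assay = ClampAssay(w.target, w.ct_with_clamp, w.ct_without_clamp,
                           by_target[w.target])
        dct = delta_ct(assay)
        call = call_clamp(dct, assay)
        results.append({
            "well": w.well,
            "target": w.target.value,
            "delta_ct": dct,
            "call": call.value,
            "maf_percent": quantify_maf(dct, assay) if call == ClampCall.MUTANT else None,
        })
    return results
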