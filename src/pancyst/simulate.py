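"""Synthetic EUS-FNA cyst fluid cohorts with realistic mutation structure.

The generator emulates the statistical structure of a tertiary-care cyst
fluid cohort: cyst-type prevalence matching a surgical resection series,
per-type/grade mutation spectra (low-grade mucinous lesions carry only KRAS
and/or GNAS; intermediate and high grades add tumor-suppressor mutations;
serous cystadenomas carry VHL; a minority of pseudocysts carry incidental
low-frequency KRAS), right-skewed log-normal MAF and CEA distributions,
cytology categories drawn conditionally on the true class, fluid viscosity
conditionals, and partial multi-gene testing (GNAS and the wider panel are
assayed only in a subset, as in practice).

Every case carries a ground-truth label (mucinous iff the simulated type is
IPMN, MCN or PDAC), so both classifiers can be scored against truth rather
than against each other -- scoring the clinical algorithm against its own
output would artificially inflate the specificity of its inputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from fractions import Fraction

import numpy as np
import pandas as pd

from .classify import UnclassifiableCaseError, classify_clinical, classify_molecular
from .fixture import surgical_truth
from .stats import confusion
from .types import (
    Assay,
    Cytology,
    CystCase,
    DxLabel,
    DysplasiaGrade,
    EusImpression,
    PathologyDx,
    SomaticStatus,
    Tristate,
    VariantCall,
    Viscosity,
)

_KRAS_CHANGES = ("p.G12D", "p.G12V", "p.G12R", "p.G12A", "p.G12T", "p.Q61H", "p.Q61C")
_GNAS_CHANGES = ("p.R201C", "p.R201H")


@dataclass(frozen=True)
class LogNormalModel:
    """Log-normal with its natural clinical parameterization (median, sigma)."""

    median: float
    sigma: float

    def draw(self, rng: np.random.Generator, n: int = 1) -> np.ndarray:
        return np.exp(rng.normal(math.log(self.median), self.sigma, size=n))


@dataclass(frozen=True)
class StratumMutations:
    """Per-gene mutation probabilities for one (type, grade) stratum."""

    gene_probs: dict[str, float] = field(default_factory=dict)
    additional_prob: float = 0.0          # chance of one extra gene from the pool
    additional_pool: tuple[str, ...] = ()


def _default_mutation_model() -> dict[tuple[PathologyDx, DysplasiaGrade], StratumMutations]:
    kras_gnas = {"KRAS": 0.82, "GNAS": 0.41}
    model: dict[tuple[PathologyDx, DysplasiaGrade], StratumMutations] = {}
    for t in (PathologyDx.IPMN, PathologyDx.MCN):
        model[(t, DysplasiaGrade.LG)] = StratumMutations(dict(kras_gnas))
        model[(t, DysplasiaGrade.MG)] = StratumMutations(
            dict(kras_gnas), additional_prob=0.33,
            additional_pool=("TP53", "CDKN2A", "APC"))
        model[(t, DysplasiaGrade.HG)] = StratumMutations(
            dict(kras_gnas), additional_prob=0.90,
            additional_pool=("TP53", "SMAD4", "CDKN2A", "PTEN", "RB1", "PIK3CA", "BRAF"))
    model[(PathologyDx.PDAC, DysplasiaGrade.NA)] = StratumMutations(
        dict(kras_gnas), additional_prob=0.90,
        additional_pool=("TP53", "SMAD4", "CDKN2A", "PTEN", "RB1", "PIK3CA"))
    model[(PathologyDx.SCA, DysplasiaGrade.NA)] = StratumMutations({"VHL": 1.0})
    model[(PathologyDx.PNET, DysplasiaGrade.NA)] = StratumMutations({})
    model[(PathologyDx.PSEUDOCYST, DysplasiaGrade.NA)] = StratumMutations({"KRAS": 0.2})
    return model


def _frac(a: int, b: int) -> float:
    return float(Fraction(a, b))


@dataclass
class SimConfig:
    """Cohort-level generative parameters.

    Defaults reproduce the study conditions: type prevalence from the
    46-case surgical series, cytology conditionals and CEA medians from the
    318-case cohort summary, dual-gene testing in 182/303 of cases, and the
    grade-structured mutation spectra described above.
    """

    n_cases: int = 318
    seed: int = 0
    type_prevalence: dict[PathologyDx, float] = field(default_factory=lambda: {
        PathologyDx.IPMN: _frac(19, 46), PathologyDx.MCN: _frac(9, 46),
        PathologyDx.PDAC: _frac(8, 46), PathologyDx.SCA: _frac(2, 46),
        PathologyDx.PNET: _frac(3, 46), PathologyDx.PSEUDOCYST: _frac(5, 46),
    })
    grade_mix: dict[PathologyDx, dict[DysplasiaGrade, float]] = field(
        default_factory=lambda: {
            PathologyDx.IPMN: {DysplasiaGrade.LG: _frac(12, 19),
                               DysplasiaGrade.MG: _frac(5, 19),
                               DysplasiaGrade.HG: _frac(2, 19)},
            PathologyDx.MCN: {DysplasiaGrade.LG: _frac(5, 9),
                              DysplasiaGrade.MG: _frac(4, 9)},
        })
    mutation_model: dict[tuple[PathologyDx, DysplasiaGrade], StratumMutations] = field(
        default_factory=_default_mutation_model)
    # second distinct protein change in the same gene (mucinous carriers)
    kras_double_prob: float = 0.104
    gnas_double_prob: float = 0.063
    maf_model: dict[str, LogNormalModel] = field(default_factory=lambda: {
        "mucinous": LogNormalModel(median=25.0, sigma=0.9),
        "incidental": LogNormalModel(median=5.0, sigma=0.8),
    })
    cea_model: dict[str, LogNormalModel] = field(default_factory=lambda: {
        "mucinous": LogNormalModel(median=2126.7, sigma=1.5),
        "non_mucinous": LogNormalModel(median=188.9, sigma=1.5),
    })
    cea_measured_prob: float = _frac(224, 318)
    cytology_conditionals: dict[str, dict[Cytology, float]] = field(
        default_factory=lambda: {
            "mucinous": {Cytology.POS: _frac(11, 147), Cytology.ATY_SUS: _frac(53, 147),
                         Cytology.NEG: _frac(38, 147), Cytology.ND: _frac(45, 147)},
            "non_mucinous": {Cytology.NEG: _frac(118, 162), Cytology.ND: _frac(44, 162)},
        })
    cytology_missing_prob: float = _frac(9, 318)
    viscosity_conditionals: dict[str, float] = field(default_factory=lambda: {
        "mucinous": _frac(91, 126), "non_mucinous": _frac(36, 149)})
    viscosity_known_prob: float = _frac(275, 318)
    mural_nodule_prob: dict[str, float] = field(default_factory=lambda: {
        "mucinous": 0.15, "non_mucinous": 0.02})
    eus_conditionals: dict[str, dict[EusImpression, float]] = field(
        default_factory=lambda: {
            "mucinous": {EusImpression.MUCINOUS: 0.70,
                         EusImpression.NON_MUCINOUS: 0.20,
                         EusImpression.UNKNOWN: 0.10},
            "non_mucinous": {EusImpression.MUCINOUS: 0.15,
                             EusImpression.NON_MUCINOUS: 0.75,
                             EusImpression.UNKNOWN: 0.10},
        })
    # triangular (lo, mode, hi): medians/ranges are only summarized in the
    # source cohort, so these fits are approximate by construction
    size_triangular: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: {"mucinous": (5.0, 30.2, 114.0),
                                 "non_mucinous": (5.0, 36.6, 114.0)})
    amylase_triangular: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: {"mucinous": (2.4, 5061.8, 24990.0),
                                 "non_mucinous": (2.4, 7764.6, 24990.0)})
    gnas_tested_prob: float = _frac(182, 303)
    multigene_panel: tuple[str, ...] = (
        "GNAS", "BRAF", "PIK3CA", "CDKN2A", "PTEN", "SMAD4", "TP53",
        "VHL", "ATM", "APC", "RB1")

    def __post_init__(self) -> None:
        if self.n_cases < 0:
            raise ValueError("n_cases must be non-negative")
        for name, pmap in (("type_prevalence", self.type_prevalence),
                           *((f"cytology_conditionals[{k}]", v)
                             for k, v in self.cytology_conditionals.items()),
                           *((f"eus_conditionals[{k}]", v)
                             for k, v in self.eus_conditionals.items()),
                           *((f"grade_mix[{k}]", v) for k, v in self.grade_mix.items())):
            total = sum(pmap.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1, got {total}")
            if any(not 0.0 <= p <= 1.0 for p in pmap.values()):
                raise ValueError(f"{name} has a rate outside [0, 1]")
        for strat in self.mutation_model.values():
            if any(not 0.0 <= p <= 1.0 for p in strat.gene_probs.values()):
                raise ValueError("mutation probabilities must lie in [0, 1]")
            if not 0.0 <= strat.additional_prob <= 1.0:
                raise ValueError("additional_prob must lie in [0, 1]")

    @classmethod
    def with_detection_probability(cls, p: float, n_cases: int = 1000,
                                   seed: int = 0) -> "SimConfig":
        """Config whose per-case chance of any panel mutation, given a
        mucinous lesion, is exactly ``p`` (and zero otherwise).

        Used for parameter-recovery checks: the molecular classifier's
        sensitivity on such a cohort estimates ``p`` binomially.
        """
        model: dict[tuple[PathologyDx, DysplasiaGrade], StratumMutations] = {}
        for t in (PathologyDx.IPMN, PathologyDx.MCN):
            for g in (DysplasiaGrade.LG, DysplasiaGrade.MG, DysplasiaGrade.HG):
                model[(t, g)] = StratumMutations({"KRAS": p})
        model[(PathologyDx.PDAC, DysplasiaGrade.NA)] = StratumMutations({"KRAS": p})
        for t in (PathologyDx.SCA, PathologyDx.PNET, PathologyDx.PSEUDOCYST):
            model[(t, DysplasiaGrade.NA)] = StratumMutations({})
        return cls(n_cases=n_cases, seed=seed, mutation_model=model,
                   kras_double_prob=0.0, gnas_double_prob=0.0,
                   gnas_tested_prob=1.0)


def _draw(rng: np.random.Generator, pmap: dict) -> object:
    keys = list(pmap)
    probs = np.array([pmap[k] for k in keys], dtype=float)
    return keys[rng.choice(len(keys), p=probs / probs.sum())]


def _truth_class(dx: PathologyDx) -> str:
    return "mucinous" if dx in (PathologyDx.IPMN, PathologyDx.MCN, PathologyDx.PDAC) \
        else "non_mucinous"


def generate(config: SimConfig) -> list[CystCase]:
    """Draw a fully populated synthetic cohort, reproducible from the seed."""
    rng = np.random.default_rng(config.seed)
    cases: list[CystCase] = []
    for i in range(config.n_cases):
        dx = _draw(rng, config.type_prevalence)
        grade = _draw(rng, config.grade_mix[dx]) if dx in config.grade_mix \
            else DysplasiaGrade.NA
        cls = _truth_class(dx)
        mucinous = cls == "mucinous"

        genes_tested = {"KRAS"}
        if rng.random() < config.gnas_tested_prob:
            genes_tested.update(config.multigene_panel)

        stratum = config.mutation_model[(dx, grade)]
        mutated: list[str] = [g for g, p in stratum.gene_probs.items()
                              if rng.random() < p]
        if stratum.additional_prob and rng.random() < stratum.additional_prob:
            extra = stratum.additional_pool[rng.integers(len(stratum.additional_pool))]
            if extra not in mutated:
                mutated.append(extra)

        maf_model = config.maf_model["mucinous" if mucinous else "incidental"]
        variants: list[VariantCall] = []
        for gene in mutated:
            if gene not in genes_tested:
                continue
            n_alleles = 1
            if mucinous and gene == "KRAS" and rng.random() < config.kras_double_prob:
                n_alleles = 2
            if mucinous and gene == "GNAS" and rng.random() < config.gnas_double_prob:
                n_alleles = 2
            pool = {"KRAS": _KRAS_CHANGES, "GNAS": _GNAS_CHANGES}.get(gene)
            changes = (list(rng.choice(pool, size=n_alleles, replace=False))
                       if pool else ["p.?"] * n_alleles)
            for change in changes:
                maf = float(np.clip(maf_model.draw(rng)[0], 0.05, 95.0))
                variants.append(VariantCall(
                    gene=gene, protein_change=change, maf_percent=maf,
                    read_depth=int(rng.integers(100, 2500)), assay=Assay.NGS,
                    somatic_status=SomaticStatus.COSMIC_CONFIRMED))

        if rng.random() < config.cytology_missing_prob:
            cytology = Cytology.MISSING
        else:
            cytology = _draw(rng, config.cytology_conditionals[cls])
        cea = float(config.cea_model[cls].draw(rng)[0]) \
            if rng.random() < config.cea_measured_prob else None
        if rng.random() < config.viscosity_known_prob:
            viscosity = Viscosity.VISCOUS \
                if rng.random() < config.viscosity_conditionals[cls] \
                else Viscosity.NON_VISCOUS
        else:
            viscosity = Viscosity.UNKNOWN
        nodule = Tristate.YES if rng.random() < config.mural_nodule_prob[cls] \
            else Tristate.NO
        eus = _draw(rng, config.eus_conditionals[cls])
        lo, mode, hi = config.size_triangular[cls]
        size = float(rng.triangular(lo, mode, hi))
        lo, mode, hi = config.amylase_triangular[cls]
        amylase = float(rng.triangular(lo, mode, hi))

        cases.append(CystCase(
            case_id=f"SIM{i:05d}", pathology_dx=dx,
            dysplasia_grade=grade if dx in config.grade_mix else DysplasiaGrade.NA,
            cytology=cytology, cea_ng_ml=cea, amylase_u_l=amylase,
            cyst_size_mm=size, mural_nodule=nodule, viscosity=viscosity,
            eus_impression=eus, genes_tested=frozenset(genes_tested),
            variants=variants))
    return cases


def score_cohort(cases: list[CystCase]) -> dict[str, dict[str, float | None]]:
    """Run both classifiers on a cohort and score them against truth."""
    truth = [surgical_truth(c) for c in cases]
    mol_pred = ["mucinous" if classify_molecular(c).label == DxLabel.MPCN
                else "non_mucinous" for c in cases]
    mol = confusion(mol_pred, truth, positive="mucinous")
    clin_pred, clin_truth = [], []
    for c, t in zip(cases, truth):
        try:
            d = classify_clinical(c)
        except UnclassifiableCaseError:
            continue
        clin_pred.append("mucinous" if d.label == DxLabel.MPCN else "non_mucinous")
        clin_truth.append(t)
    clin = confusion(clin_pred, clin_truth, positive="mucinous")
    return {
        "molecular": {"sensitivity": mol.sensitivity, "specificity": mol.specificity,
                      "n": mol.n},
        "clinical": {"sensitivity": clin.sensitivity, "specificity": clin.specificity,
                     "n": clin.n},
    }


def recover_operating_characteristics(config: SimConfig, n_reps: int) -> pd.DataFrame:
    """Replicate cohorts and summarize recovered classifier accuracy.

    Returns a table with mean and standard deviation of sensitivity and
    specificity (percent) per classifier over ``n_reps`` independent
    replicates (seeds derived from ``config.seed``).
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rows = []
    for rep in range(n_reps):
        cohort = generate(replace(config, seed=(config.seed + 1000003 * rep) % (2**31)))
        for clf, metrics in score_cohort(cohort).items():
            rows.append({"rep": rep, "classifier": clf, **metrics})
    df = pd.DataFrame(rows)
    return (df.groupby("classifier")[["sensitivity", "specificity"]]
              .agg(["mean", "std"]))


def bayes_maf_boundary(config: SimConfig) -> float:
    """MAF (percent) where the two configured log-normal densities intersect.

    This is the Youden-optimal score threshold for the generator's MAF
    models: the Youden index sens(t) + spec(t) - 1 is stationary where the
    two class densities are equal, independently of class prevalence. For
    equal sigmas it is the geometric mean of the two medians.
    """
    m = config.maf_model["mucinous"]
    i = config.maf_model["incidental"]
    mu1, s1 = math.log(m.median), m.sigma
    mu0, s0 = math.log(i.median), i.sigma
    if abs(s1 - s0) < 1e-12:
        return math.exp((mu0 + mu1) / 2.0)
    # unequal sigmas: locate the density crossing between the two log-medians
    from scipy.optimize import brentq
    from scipy.stats import norm

    def diff(x: float) -> float:
        return norm.logpdf(x, mu1, s1) - norm.logpdf(x, mu0, s0)

    return math.exp(brentq(diff, min(mu0, mu1), max(mu0, mu1)))
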