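"""The rare-variant filter cascade and cohort summary.

Four stages, each a pure predicate on one variant's annotations:

1. functional class — missense, small in-frame indels, and loss of
   function (stop gain, frameshift, splice site);
2. brain expression — positive in at least 3 of 4 expression databases
   (GTEx, BioGPS, CGAP, HBT); missing entries are non-positive votes;
3. rarity — MAF below 1% in every population panel reporting the variant
   (SHGPdb, 1000 Genomes, ExAC, Kaviar); absent panels do not veto;
4. deleteriousness consensus — "deleterious" votes from at least 2 of 3
   predictors (CADD phred, PredictSNP2, FATHMM-MKL), with an optional
   exemption for LoF classes whose impact the missense-trained predictors
   systematically understate.

The final pass is the conjunction of the four stages, so stage order is
immaterial.  Gene-level constraint (pLI, missense Z) is carried as
annotation only and never filters.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import pandas as pd

from .inheritance import (
    InheritanceCall,
    Mode,
    SegregationProfile,
    annotate_segregation,
    classify_trio_tolerant,
)
from .io import (
    BRAIN_DBS,
    LOF_CONSEQUENCES,
    BrainExpressionProfile,
    Consequence,
    FamilyPedigree,
    FrequencyProfile,
    GenotypeCall,
    GenotypeTable,
    PredictionProfile,
    VariantRecord,
)

__all__ = [
    "PrioritizeConfig",
    "FilterTrace",
    "CohortSummary",
    "PrioritizedVariant",
    "filter_functional",
    "filter_brain_expression",
    "filter_frequency",
    "consensus_deleterious",
    "prioritize_cohort",
]


@dataclass
class PrioritizeConfig:
    """Tunable thresholds of the cascade (defaults match the published list)."""

    maf_threshold: float = 0.01
    cadd_cutoff: float = 20.0
    fathmm_cutoff: float = 0.5
    min_deleterious_votes: int = 2
    min_brain_votes: int = 3
    lof_exempt: bool = True
    strict_missing_maf: bool = False  # strict mode: all-missing frequency fails
    include_suspected: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.maf_threshold <= 1.0):
            raise ValueError(f"maf_threshold outside (0,1]: {self.maf_threshold}")


@dataclass
class FilterTrace:
    functional_pass: bool
    brain_pass: bool
    rare_pass: bool
    deleterious_pass: bool
    deleterious_votes: int

    @property
    def final_pass(self) -> bool:
        return (
            self.functional_pass
            and self.brain_pass
            and self.rare_pass
            and self.deleterious_pass
        )


@dataclass
class CohortSummary:
    n_unique_variants: int = 0
    n_unique_genes: int = 0
    n_de_novo: int = 0
    n_inherited: int = 0
    n_families_with_hits: int = 0
    n_families_analyzed: int = 0

    def as_dict(self) -> dict[str, int]:
        return asdict(self)


@dataclass
class PrioritizedVariant:
    variant: VariantRecord
    family_id: str
    inheritance: InheritanceCall
    trace: FilterTrace
    segregation: Optional[SegregationProfile] = None


# ---------------------------------------------------------------------------
# stage predicates


def filter_functional(v: VariantRecord) -> bool:
    """True iff the consequence class is functional (missense/indel/LoF)."""
    return v.is_functional


def filter_brain_expression(b: BrainExpressionProfile, min_votes: int = 3) -> bool:
    """True iff the gene is expression-positive in ≥ ``min_votes`` of the
    four brain-expression databases; missing entries never vote positive."""
    return b.n_positive() >= min_votes


def filter_frequency(f: FrequencyProfile, threshold: float = 0.01, strict_missing: bool = False) -> bool:
    """True iff every non-missing panel MAF is below ``threshold``.

    Panels that never observed the variant (missing) do not veto; with
    ``strict_missing`` an all-missing profile fails instead of passing.
    """
    if not (0.0 < threshold <= 1.0):
        raise ValueError(f"frequency threshold outside (0,1]: {threshold}")
    observed = [v for v in f.maf_by_panel.values() if v is not None]
    if not observed:
        return not strict_missing
    return all(v < threshold for v in observed)


def consensus_deleterious(
    p: PredictionProfile,
    consequence: Consequence,
    cadd_cutoff: float = 20.0,
    fathmm_cutoff: float = 0.5,
    min_votes: int = 2,
    lof_exempt: bool = True,
) -> tuple[bool, int]:
    """Count deleterious votes from CADD, PredictSNP2 and FATHMM-MKL.

    A missing predictor never votes.  LoF classes (stop gain, frameshift,
    splice site) pass regardless of the vote count when ``lof_exempt`` is
    on: the three predictors are calibrated on missense-like substitutions
    and can assign low scores to unambiguous truncating alleles.
    """
    votes = 0
    if p.cadd_phred is not None and p.cadd_phred >= cadd_cutoff:
        votes += 1
    if p.predictsnp2_label == "deleterious":
        votes += 1
    if p.fathmm_mkl_score is not None and p.fathmm_mkl_score >= fathmm_cutoff:
        votes += 1
    passes = votes >= min_votes or (lof_exempt and consequence in LOF_CONSEQUENCES)
    return passes, votes


def apply_filters(
    variant: VariantRecord,
    freq: FrequencyProfile,
    pred: PredictionProfile,
    brain: BrainExpressionProfile,
    config: Optional[PrioritizeConfig] = None,
) -> FilterTrace:
    """Run all four cascade stages on one annotated variant."""
    cfg = config or PrioritizeConfig()
    deleterious_pass, votes = consensus_deleterious(
        pred,
        variant.consequence,
        cadd_cutoff=cfg.cadd_cutoff,
        fathmm_cutoff=cfg.fathmm_cutoff,
        min_votes=cfg.min_deleterious_votes,
        lof_exempt=cfg.lof_exempt,
    )
    return FilterTrace(
        functional_pass=filter_functional(variant),
        brain_pass=filter_brain_expression(brain, cfg.min_brain_votes),
        rare_pass=filter_frequency(freq, cfg.maf_threshold, cfg.strict_missing_maf),
        deleterious_pass=deleterious_pass,
        deleterious_votes=votes,
    )


# ---------------------------------------------------------------------------
# cohort-level driver


@dataclass
class AnnotatedSite:
    """One annotated site joined to the genotype matrix."""

    variant: VariantRecord
    frequency: FrequencyProfile
    prediction: PredictionProfile
    brain: BrainExpressionProfile


def prioritize_cohort(
    table: GenotypeTable,
    annotations: dict[tuple[str, int, str, str], AnnotatedSite],
    pedigrees: list[FamilyPedigree],
    config: Optional[PrioritizeConfig] = None,
) -> tuple[list[PrioritizedVariant], CohortSummary, list[VariantRecord]]:
    """Classify, filter and summarize a cohort.

    Returns (per-family listing of passing variants, cohort summary,
    rejected-unjoinable variants).  Summary counts are over unique
    variants — a variant seen in two families counts once — while the
    listing keeps one row per (variant, family).
    """
    cfg = config or PrioritizeConfig()
    samples_with_data = set(table.samples)
    analyzed = [p for p in pedigrees if p.passed_qc]

    results: list[PrioritizedVariant] = []
    rejects: list[VariantRecord] = []
    for i, vrec in enumerate(table.variants):
        ann = annotations.get(vrec.key)
        if ann is None:
            rejects.append(vrec)
            continue
        trace = apply_filters(ann.variant, ann.frequency, ann.prediction, ann.brain, cfg)
        if not trace.final_pass:
            continue
        row = table.row(i)
        for ped in analyzed:
            proband = ped.proband
            if proband is None:
                continue
            mo, fa = ped.parents_of(proband.sample_id)
            trio_calls = {
                s: row.get(s, GenotypeCall.MISSING)
                for s in (proband.sample_id, mo, fa)
                if s is not None
            }
            pg = trio_calls.get(proband.sample_id, GenotypeCall.MISSING)
            if not pg.carries_alt:
                continue
            call = classify_trio_tolerant(
                pg,
                trio_calls.get(mo, GenotypeCall.MISSING),
                trio_calls.get(fa, GenotypeCall.MISSING),
                chrom=ann.variant.chrom,
                proband_sex=proband.sex,
                pos=ann.variant.pos,
            )
            fam_genotypes = {
                m.sample_id: row[m.sample_id]
                for m in ped.members
                if m.sample_id in row and row[m.sample_id] != GenotypeCall.MISSING
            }
            seg = None
            if proband.sample_id in fam_genotypes:
                seg = annotate_segregation(
                    fam_genotypes, ped, include_suspected=cfg.include_suspected
                )
            results.append(
                PrioritizedVariant(ann.variant, ped.family_id, call, trace, seg)
            )

    summary = summarize(results, n_families_analyzed=len(analyzed))
    return results, summary, rejects


def summarize(results: list[PrioritizedVariant], n_families_analyzed: int) -> CohortSummary:
    """Cohort summary over unique variants; de novo at the variant level
    (a variant is de novo if its trio call in any carrying family is)."""
    uniq: dict[tuple[str, int, str, str], PrioritizedVariant] = {}
    for r in results:
        key = r.variant.key
        if key not in uniq or r.inheritance.mode == Mode.DE_NOVO:
            uniq[key] = r
    n_unique = len(uniq)
    n_de_novo = sum(1 for r in uniq.values() if r.inheritance.mode == Mode.DE_NOVO)
    genes = {r.variant.gene for r in uniq.values() if r.variant.gene}
    fams = {r.family_id for r in results}
    return CohortSummary(
        n_unique_variants=n_unique,
        n_unique_genes=len(genes),
        n_de_novo=n_de_novo,
        n_inherited=n_unique - n_de_novo,
        n_families_with_hits=len(fams),
        n_families_analyzed=n_families_analyzed,
    )


def results_frame(results: list[PrioritizedVariant]) -> pd.DataFrame:
    """Long-format table of prioritized variants (one row per variant/family)."""
    rows = []
    for r in results:
        seg = r.segregation
        rows.append(
            {
                "family": r.family_id,
                "gene": r.variant.gene,
                "chrom": r.variant.chrom,
                "pos": r.variant.pos,
                "ref": r.variant.ref,
                "alt": r.variant.alt,
                "consequence": r.variant.consequence.value,
                "mode": r.inheritance.mode.value,
                "deleterious_votes": r.trace.deleterious_votes,
                "fully_segregates": None if seg is None else seg.fully_segregates,
                "n_affected_carriers": None if seg is None else seg.n_affected_carriers,
                "n_unaffected_carriers": None if seg is None else seg.n_unaffected_carriers,
            }
        )
    return pd.DataFrame(rows)
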