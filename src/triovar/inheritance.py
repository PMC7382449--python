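"""Trio inheritance-mode classification, compound-het scan, segregation.

The classifier assigns exactly one transmission mode per (variant, family):

* ``DE_NOVO`` — proband carries at least one alternate allele while both
  parents are homozygous reference.
* ``AUTOSOMAL_RECESSIVE`` — proband homozygous alternate, both parents
  carriers.
* ``AUTOSOMAL_DOMINANT`` — heterozygous proband with at least one carrier
  parent.
* ``X_LINKED`` — variant on X non-PAR transmitted through the X; a male
  proband is evaluated hemizygously.  A de novo event on the X in a
  carrier-free trio is still labelled DE_NOVO.
* ``UNRESOLVED`` — proband does not carry the allele, or the configuration
  is impossible under Mendelian transmission (genotyping error, mosaicism
  and uniparental disomy are not modelled; such sites are surfaced, not
  dropped).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional

from .io import (
    AffectedStatus,
    FamilyPedigree,
    GenotypeCall,
    Sex,
    VariantRecord,
    is_x_nonpar,
    normalize_chrom,
)

__all__ = [
    "Mode",
    "InheritanceCall",
    "SegregationProfile",
    "CompoundHetCandidate",
    "classify_trio",
    "classify_trio_tolerant",
    "scan_compound_het",
    "annotate_segregation",
]


class Mode(str, enum.Enum):
    DE_NOVO = "DE_NOVO"
    AUTOSOMAL_RECESSIVE = "AUTOSOMAL_RECESSIVE"
    AUTOSOMAL_DOMINANT = "AUTOSOMAL_DOMINANT"
    X_LINKED = "X_LINKED"
    UNRESOLVED = "UNRESOLVED"


@dataclass(frozen=True)
class InheritanceCall:
    mode: Mode
    carrier_state_proband: GenotypeCall
    detail: str = ""  # e.g. "maternal", "de_novo_hemizygous", "not_carried"


def _carries(call: GenotypeCall) -> bool:
    return call.carries_alt


def classify_trio(
    proband: GenotypeCall,
    mother: GenotypeCall,
    father: GenotypeCall,
    chrom: str = "1",
    proband_sex: Sex = Sex.UNKNOWN,
    pos: Optional[int] = None,
) -> InheritanceCall:
    """Classify the transmission mode of one variant from trio genotypes.

    All three calls must be non-MISSING; use :func:`classify_trio_tolerant`
    for calls with missingness.
    """
    for name, call in (("proband", proband), ("mother", mother), ("father", father)):
        if call == GenotypeCall.MISSING:
            raise ValueError(
                f"{name} genotype is MISSING; use classify_trio_tolerant for "
                "missing-tolerant classification"
            )
    chrom = normalize_chrom(chrom)
    x_nonpar = is_x_nonpar(chrom, pos)

    if not _carries(proband):
        return InheritanceCall(Mode.UNRESOLVED, proband, "not_carried")

    # De novo: both parents homozygous reference, proband carries.
    if mother == GenotypeCall.HOM_REF and father == GenotypeCall.HOM_REF:
        if x_nonpar:
            detail = "de_novo_hemizygous" if proband == GenotypeCall.HEMI_ALT else "de_novo"
            return InheritanceCall(Mode.DE_NOVO, proband, detail)
        return InheritanceCall(Mode.DE_NOVO, proband, "")

    if x_nonpar:
        return _classify_x(proband, mother, father, proband_sex)

    # Autosomal transmitted configurations.
    if proband == GenotypeCall.HET:
        mother_can_ref = mother in (GenotypeCall.HOM_REF, GenotypeCall.HET)
        father_can_ref = father in (GenotypeCall.HOM_REF, GenotypeCall.HET)
        mother_can_alt = _carries(mother)
        father_can_alt = _carries(father)
        possible = (mother_can_alt and father_can_ref) or (father_can_alt and mother_can_ref)
        if not possible:
            return InheritanceCall(Mode.UNRESOLVED, proband, "mendelian_inconsistent")
        return InheritanceCall(Mode.AUTOSOMAL_DOMINANT, proband, "")

    # proband HOM_ALT (HEMI_ALT on autosomes would be a data error; treat as alt-carrying hom)
    if _carries(mother) and _carries(father):
        return InheritanceCall(Mode.AUTOSOMAL_RECESSIVE, proband, "")
    return InheritanceCall(Mode.UNRESOLVED, proband, "mendelian_inconsistent")


def _classify_x(
    proband: GenotypeCall, mother: GenotypeCall, father: GenotypeCall, proband_sex: Sex
) -> InheritanceCall:
    """X non-PAR transmitted configurations (de novo handled by caller).

    Mothers are diploid; fathers hemizygous (their WT/HOM labels mean
    HEMI_REF/HEMI_ALT).
    """
    father_alt = _carries(father)
    mother_alt = _carries(mother)
    if proband == GenotypeCall.HEMI_ALT:  # male proband
        if mother_alt:
            return InheritanceCall(Mode.X_LINKED, proband, "maternal")
        # mother HOM_REF with carrier father cannot transmit to a son's X
        return InheritanceCall(Mode.UNRESOLVED, proband, "mendelian_inconsistent")
    if proband == GenotypeCall.HET:  # female proband, one transmitted X
        if mother_alt or father_alt:
            return InheritanceCall(Mode.X_LINKED, proband, "")
        return InheritanceCall(Mode.UNRESOLVED, proband, "mendelian_inconsistent")
    # female proband HOM_ALT: needs alt from both parents
    if mother_alt and father_alt:
        return InheritanceCall(Mode.X_LINKED, proband, "")
    return InheritanceCall(Mode.UNRESOLVED, proband, "mendelian_inconsistent")


def classify_trio_tolerant(
    proband: GenotypeCall,
    mother: GenotypeCall,
    father: GenotypeCall,
    chrom: str = "1",
    proband_sex: Sex = Sex.UNKNOWN,
    pos: Optional[int] = None,
) -> InheritanceCall:
    """Missing-tolerant wrapper: UNRESOLVED when any trio call is MISSING."""
    if GenotypeCall.MISSING in (proband, mother, father):
        return InheritanceCall(Mode.UNRESOLVED, proband, "missing_genotype")
    return classify_trio(proband, mother, father, chrom, proband_sex, pos)


# ---------------------------------------------------------------------------
# compound heterozygosity


@dataclass(frozen=True)
class CompoundHetCandidate:
    gene: str
    variant_pair: tuple[VariantRecord, VariantRecord]
    phase_support: str  # "trans_by_parents" | "unphased"


def _parental_origin(mother: GenotypeCall, father: GenotypeCall) -> str:
    """Infer the transmitting parent of a heterozygous proband allele.

    Returns "maternal" / "paternal" when only one parent carries the
    allele, else "ambiguous" (both carry, or neither: apparent de novo).
    """
    m, f = _carries(mother), _carries(father)
    if m and not f:
        return "maternal"
    if f and not m:
        return "paternal"
    return "ambiguous"


def scan_compound_het(
    variants_in_gene: list[tuple[VariantRecord, GenotypeCall, GenotypeCall, GenotypeCall]],
) -> list[CompoundHetCandidate]:
    """Scan one gene's variants for compound-heterozygous candidates.

    Input items are (variant, proband, mother, father) with the proband
    heterozygous at every variant.  A pair is ``trans_by_parents`` when the
    two alleles demonstrably came one from each parent; pairs containing an
    ambiguous-origin variant are returned as ``unphased``.  Pairs proven to
    sit on the same parental haplotype (both maternal or both paternal) are
    not candidates.
    """
    if not variants_in_gene:
        return []
    genes = {v.gene for v, *_ in variants_in_gene}
    if len(genes) > 1:
        raise ValueError(f"variants span multiple genes: {sorted(genes)}")
    gene = genes.pop()
    for v, p, _, _ in variants_in_gene:
        if p != GenotypeCall.HET:
            raise ValueError(f"proband not heterozygous at {v.key}")

    origins = [(_v, _parental_origin(mo, fa)) for _v, _p, mo, fa in variants_in_gene]
    out: list[CompoundHetCandidate] = []
    for (v1, o1), (v2, o2) in combinations(origins, 2):
        if {o1, o2} == {"maternal", "paternal"}:
            out.append(CompoundHetCandidate(gene, (v1, v2), "trans_by_parents"))
        elif "ambiguous" in (o1, o2) and not (o1 == o2 != "ambiguous"):
            out.append(CompoundHetCandidate(gene, (v1, v2), "unphased"))
        # same known origin -> cis, excluded
    return out


# ---------------------------------------------------------------------------
# segregation


@dataclass
class SegregationProfile:
    genotype_by_member: dict[str, GenotypeCall] = field(default_factory=dict)
    n_affected_carriers: int = 0
    n_unaffected_carriers: int = 0
    n_affected_matching_proband: int = 0
    n_unaffected_matching_proband: int = 0
    fully_segregates: Optional[bool] = None  # None when no non-proband screened


def annotate_segregation(
    genotypes: dict[str, GenotypeCall],
    pedigree: FamilyPedigree,
    include_suspected: bool = False,
) -> SegregationProfile:
    """Summarize how a variant tracks with affected status across a family.

    ``fully_segregates`` is True iff every screened affected member shares
    the proband's exact genotype and no screened unaffected member does.
    It is None (undefined) when the proband is the only screened member.
    Suspected-status members are excluded from both counts unless
    ``include_suspected`` promotes them to affected.
    """
    proband = pedigree.proband
    if proband is None or proband.sample_id not in genotypes:
        raise ValueError("proband genotype required for segregation annotation")
    pg = genotypes[proband.sample_id]

    affected_ids = {
        m.sample_id
        for m in pedigree.affected_members(include_suspected=include_suspected)
        if m.sample_id in genotypes and genotypes[m.sample_id] != GenotypeCall.MISSING
    }
    unaffected_ids = {
        m.sample_id
        for m in pedigree.unaffected_members()
        if m.sample_id in genotypes and genotypes[m.sample_id] != GenotypeCall.MISSING
    }

    prof = SegregationProfile(genotype_by_member=dict(genotypes))
    prof.n_affected_carriers = sum(1 for s in affected_ids if genotypes[s].carries_alt)
    prof.n_unaffected_carriers = sum(1 for s in unaffected_ids if genotypes[s].carries_alt)
    prof.n_affected_matching_proband = sum(1 for s in affected_ids if genotypes[s] == pg)
    prof.n_unaffected_matching_proband = sum(1 for s in unaffected_ids if genotypes[s] == pg)

    screened_others = (affected_ids | unaffected_ids) - {proband.sample_id}
    if screened_others:
        all_affected_match = all(genotypes[s] == pg for s in affected_ids)
        no_unaffected_match = all(genotypes[s] != pg for s in unaffected_ids)
        prof.fully_segregates = all_affected_match and no_unaffected_match
    return prof
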