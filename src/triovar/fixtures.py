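"""Packaged cohort fixtures: the study's printed tables as typed objects.

Three tables from the source cohort (16 families, ADHD trio WES) ship
with the package as plain TSV under ``triovar/data``:

* demographic roster of affected individuals (sex, age, role);
* array CNV segments per family member with printed coordinates;
* the 32 validated rare variants with gene, consequence, panel MAFs,
  prediction scores, constraint metrics, and per-member Sanger genotypes.

Genomic positions for the variant table are synthetic placeholders
(ordinal megabase positions) because the printed table reports variants
by HGVS coding coordinates only; chromosome assignments are real.  The
per-database brain-expression votes are likewise a synthetic
reconstruction consistent with the published statements (all genes
brain-positive; one gene negative in HBT) and live in
``brain_expression_synthetic.tsv``.

The F9 trio failed sequencing QC in the source study; its pedigree is
loaded with ``passed_qc=False`` so the analyzed-family denominator is 15
of 16 enrolled.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

from .cnv import CnvSegment, ProbeState
from .enrichment import GeneSetCollection
from .io import (
    AffectedStatus,
    BrainExpressionProfile,
    Consequence,
    ConstraintMetrics,
    FamilyPedigree,
    FrequencyProfile,
    GenotypeCall,
    GenotypeTable,
    PredictionProfile,
    Role,
    SampleInfo,
    Sex,
    VariantRecord,
    normalize_table_genotype,
    read_gene_intervals,
    read_pedigree,
)
from .prioritize import AnnotatedSite

__all__ = [
    "Table3Row",
    "load_pedigrees",
    "load_table1",
    "load_table2",
    "load_table3",
    "load_brain_expression",
    "load_gene_intervals",
    "load_toy_gene_sets",
    "table3_genotype_table",
]

QC_FAILED_FAMILIES = frozenset({"F9"})


def _data_path(name: str) -> Path:
    return Path(str(resources.files("triovar").joinpath("data", name)))


def load_pedigrees() -> list[FamilyPedigree]:
    """All 16 enrolled families; the QC-failed trio is flagged."""
    peds = read_pedigree(_data_path("cohort.ped"))
    for ped in peds:
        if ped.family_id in QC_FAILED_FAMILIES:
            ped.passed_qc = False
    return peds


def load_table1() -> list[SampleInfo]:
    """Affected-individual roster (sex, age, role) for all 16 families."""
    df = pd.read_csv(_data_path("table1_cases.tsv"), sep="\t")
    counters: dict[str, int] = {}
    out: list[SampleInfo] = []
    for _, row in df.iterrows():
        fam = row["family"]
        role = row["role"]
        if role == "proband":
            sid = f"{fam}_P"
            role_enum = Role.PROBAND
        elif role == "affected_father":
            sid = f"{fam}_AF"
            role_enum = Role.FATHER
        else:
            counters[fam] = counters.get(fam, 0) + 1
            sid = f"{fam}_AS{counters[fam]}"
            role_enum = Role.SIBLING
        age = None if str(row["age_years"]) == "NA" or pd.isna(row["age_years"]) else float(row["age_years"])
        suspected = bool(int(row["suspected"]))
        out.append(
            SampleInfo(
                sample_id=sid,
                family_id=fam,
                sex=Sex(row["sex"]),
                affected=AffectedStatus.SUSPECTED if suspected else AffectedStatus.AFFECTED,
                role=role_enum,
                age_years=age,
            )
        )
    return out


def load_table2() -> pd.DataFrame:
    """CNV segments printed per family member, with typed segment objects
    in a ``segment`` column."""
    df = pd.read_csv(_data_path("table2_cnv.tsv"), sep="\t", dtype={"chrom": str})
    df["segment"] = [
        CnvSegment(
            chrom=str(r.chrom),
            start=int(r.start),
            end=int(r.end),
            state=ProbeState(r.state),
            zygosity=None if pd.isna(r.zygosity) else str(r.zygosity),
        )
        for r in df.itertuples()
    ]
    return df


@dataclass
class Table3Row:
    family_id: str
    variant: VariantRecord
    frequency: FrequencyProfile
    prediction: PredictionProfile
    constraint: ConstraintMetrics
    genotypes: dict[str, GenotypeCall]  # normalized calls per screened member
    raw_genotypes: dict[str, str]  # table-dialect labels as printed


def _opt(v) -> float | None:
    return None if pd.isna(v) else float(v)


def load_table3(pedigrees: list[FamilyPedigree] | None = None) -> list[Table3Row]:
    """The 32 validated rare variants with annotations and per-member
    genotypes, normalized against member sex (male X non-PAR labels become
    hemizygous)."""
    peds = pedigrees if pedigrees is not None else load_pedigrees()
    sex_by_sample = {m.sample_id: m.sex for p in peds for m in p.members}
    df = pd.read_csv(_data_path("table3_variants.tsv"), sep="\t", dtype={"chrom": str})
    rows: list[Table3Row] = []
    for r in df.itertuples():
        variant = VariantRecord(
            chrom=str(r.chrom),
            pos=int(r.pos),
            ref=str(r.ref),
            alt=str(r.alt),
            gene=str(r.gene),
            consequence=Consequence(r.consequence),
            hgvs_c=None if pd.isna(r.hgvs_c) else str(r.hgvs_c),
            hgvs_p=None if pd.isna(r.hgvs_p) else str(r.hgvs_p),
        )
        freq = FrequencyProfile(
            maf_by_panel={
                "SHGPdb": _opt(r.maf_shgpdb),
                "KG1000": _opt(r.maf_1000g),
                "ExAC": _opt(r.maf_exac),
                "Kaviar": _opt(r.maf_kaviar),
            }
        )
        pred = PredictionProfile(
            cadd_phred=_opt(r.cadd_phred),
            predictsnp2_label=str(r.predictsnp2_label).lower(),
            predictsnp2_accuracy_pct=_opt(r.predictsnp2_accuracy),
            fathmm_mkl_score=_opt(r.fathmm_mkl),
        )
        constraint = ConstraintMetrics(pli=_opt(r.pli), mis_z=_opt(r.mis_z))
        raw: dict[str, str] = {}
        calls: dict[str, GenotypeCall] = {}
        for item in str(r.genotypes).split(";"):
            sid, label = item.split("=")
            raw[sid] = label
            calls[sid] = normalize_table_genotype(
                label,
                chrom=variant.chrom,
                pos=variant.pos,
                sex=sex_by_sample.get(sid, Sex.UNKNOWN),
            )
        rows.append(Table3Row(str(r.family), variant, freq, pred, constraint, calls, raw))
    return rows


def load_brain_expression() -> dict[str, BrainExpressionProfile]:
    """Synthetic per-database brain-expression votes for the 31 fixture
    genes (see module docstring for provenance)."""
    df = pd.read_csv(_data_path("brain_expression_synthetic.tsv"), sep="\t")
    out: dict[str, BrainExpressionProfile] = {}
    for r in df.itertuples():
        out[str(r.gene)] = BrainExpressionProfile(
            positive_by_db={
                "GTEx": bool(r.gtex),
                "BioGPS": bool(r.biogps),
                "CGAP": bool(r.cgap),
                "HBT": bool(r.hbt),
            }
        )
    return out


def load_gene_intervals() -> pd.DataFrame:
    """hg19 intervals for the three CNV genes of interest."""
    return read_gene_intervals(_data_path("genes_hg19.bed"))


def load_toy_gene_sets() -> GeneSetCollection:
    """Small synthetic gene-set collection covering the fixture genes."""
    return GeneSetCollection.from_gmt(_data_path("gene_sets_toy.gmt"))


def table3_genotype_table() -> tuple[GenotypeTable, dict, list[FamilyPedigree]]:
    """Assemble the variant fixture into pipeline inputs: a genotype table
    over all screened members (MISSING outside the carrying family), the
    joined annotation map, and the QC-flagged pedigrees."""
    peds = load_pedigrees()
    rows = load_table3(peds)
    brain = load_brain_expression()
    samples = [m.sample_id for p in peds for m in p.members]
    call_rows = []
    variants = []
    annotations: dict[tuple, AnnotatedSite] = {}
    for row in rows:
        variants.append(row.variant)
        call_rows.append(
            [row.genotypes.get(s, GenotypeCall.MISSING) for s in samples]
        )
        annotations[row.variant.key] = AnnotatedSite(
            variant=row.variant,
            frequency=row.frequency,
            prediction=row.prediction,
            brain=brain.get(row.variant.gene, BrainExpressionProfile()),
        )
    calls = pd.DataFrame(call_rows, columns=samples, dtype=object)
    return GenotypeTable(variants, calls), annotations, peds
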