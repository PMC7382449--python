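"""Readers/writers for the standard formats the pipeline touches.

Covers 6-column PED pedigrees (with optional role/age/status columns),
multi-sample VCF 4.2 (GRCh37 contig names, with or without a ``chr``
prefix), per-variant annotation TSVs, GMT gene-set collections, and
BED gene intervals.

Genotypes are normalized into a small enum (:class:`GenotypeCall`).
Two dialects are accepted: VCF ``GT`` strings and the WT/HET/HOM labels
used by Sanger screening tables.  On male X non-PAR both ``HET`` and
``HOM`` collapse to :attr:`GenotypeCall.HEMI_ALT` — array and screening
reports use diploid labels there, but the biology is hemizygous.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "Sex",
    "AffectedStatus",
    "Role",
    "GenotypeCall",
    "Consequence",
    "FUNCTIONAL_CONSEQUENCES",
    "SampleInfo",
    "FamilyPedigree",
    "VariantRecord",
    "FrequencyProfile",
    "PredictionProfile",
    "ConstraintMetrics",
    "BrainExpressionProfile",
    "GenotypeTable",
    "PedigreeError",
    "read_pedigree",
    "write_pedigree",
    "read_cohort_vcf",
    "write_cohort_vcf",
    "read_annotations",
    "read_gmt",
    "read_gene_intervals",
    "normalize_chrom",
    "is_x_nonpar",
    "normalize_table_genotype",
]


class Sex(str, enum.Enum):
    MALE = "male"
    FEMALE = "female"
    UNKNOWN = "unknown"


class AffectedStatus(str, enum.Enum):
    AFFECTED = "affected"
    UNAFFECTED = "unaffected"
    SUSPECTED = "suspected"
    UNKNOWN = "unknown"


class Role(str, enum.Enum):
    PROBAND = "proband"
    MOTHER = "mother"
    FATHER = "father"
    SIBLING = "sibling"
    OTHER = "other"


class GenotypeCall(str, enum.Enum):
    HOM_REF = "HOM_REF"
    HET = "HET"
    HOM_ALT = "HOM_ALT"
    HEMI_ALT = "HEMI_ALT"
    MISSING = "MISSING"

    @property
    def carries_alt(self) -> bool:
        return self in (GenotypeCall.HET, GenotypeCall.HOM_ALT, GenotypeCall.HEMI_ALT)

    @property
    def dosage(self) -> float:
        """Alternate-allele dosage; hemizygous alt counts 1, missing is NaN."""
        return {
            GenotypeCall.HOM_REF: 0.0,
            GenotypeCall.HET: 1.0,
            GenotypeCall.HOM_ALT: 2.0,
            GenotypeCall.HEMI_ALT: 1.0,
            GenotypeCall.MISSING: float("nan"),
        }[self]


class Consequence(str, enum.Enum):
    MISSENSE = "missense"
    INFRAME_INDEL = "inframe_indel"
    STOP_GAIN = "stop_gain"
    FRAMESHIFT = "frameshift"
    SPLICE_SITE = "splice_site"
    SYNONYMOUS = "synonymous"
    OTHER = "other"


#: Consequence classes counted as "functional": missense, small indels and
#: loss of function (stop gain, frameshift, canonical splice site).
FUNCTIONAL_CONSEQUENCES = frozenset(
    {
        Consequence.MISSENSE,
        Consequence.INFRAME_INDEL,
        Consequence.STOP_GAIN,
        Consequence.FRAMESHIFT,
        Consequence.SPLICE_SITE,
    }
)

#: Loss-of-function subset of the functional classes.
LOF_CONSEQUENCES = frozenset(
    {Consequence.STOP_GAIN, Consequence.FRAMESHIFT, Consequence.SPLICE_SITE}
)


class PedigreeError(ValueError):
    """Structural problem in a pedigree file (cycles, duplicates, orphans)."""


@dataclass
class SampleInfo:
    sample_id: str
    family_id: str
    sex: Sex = Sex.UNKNOWN
    affected: AffectedStatus = AffectedStatus.UNKNOWN
    role: Role = Role.OTHER
    age_years: Optional[float] = None
    suspected: bool = False

    def __post_init__(self) -> None:
        if self.age_years is not None and self.age_years < 0:
            raise ValueError(f"negative age for {self.sample_id}")
        if self.affected == AffectedStatus.SUSPECTED:
            self.suspected = True


@dataclass
class FamilyPedigree:
    """One family: members plus child → (mother, father) links.

    ``passed_qc`` marks whether the family's trio sequencing data passed
    quality control; families failing QC stay in the cohort description
    but are excluded from the analyzed-family denominator.
    """

    family_id: str
    members: list[SampleInfo] = field(default_factory=list)
    parent_links: dict[str, tuple[Optional[str], Optional[str]]] = field(default_factory=dict)
    passed_qc: bool = True

    def __post_init__(self) -> None:
        ids = [m.sample_id for m in self.members]
        dup = {i for i in ids if ids.count(i) > 1}
        if dup:
            raise PedigreeError(f"duplicate sample ids in {self.family_id}: {sorted(dup)}")
        probands = [m for m in self.members if m.role == Role.PROBAND]
        if len(probands) > 1:
            raise PedigreeError(f"multiple probands in {self.family_id}")
        for role in (Role.MOTHER, Role.FATHER):
            if len([m for m in self.members if m.role == role]) > 1:
                raise PedigreeError(f"multiple {role.value}s in {self.family_id}")
        known = set(ids)
        for child, (mo, fa) in self.parent_links.items():
            for p in (mo, fa):
                if p is not None and p not in known:
                    raise PedigreeError(
                        f"{self.family_id}: parent {p} of {child} not a member"
                    )
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        # DFS over child->parent edges; a back edge is a parentage cycle.
        state: dict[str, int] = {}

        def visit(node: str, path: list[str]) -> None:
            state[node] = 1
            for parent in self.parent_links.get(node, (None, None)):
                if parent is None:
                    continue
                if state.get(parent) == 1:
                    cycle = path + [node, parent]
                    raise PedigreeError(
                        f"cyclic parentage in {self.family_id}: {' -> '.join(cycle)}"
                    )
                if state.get(parent) != 2:
                    visit(parent, path + [node])
            state[node] = 2

        for m in self.members:
            if state.get(m.sample_id) != 2:
                visit(m.sample_id, [])

    # -- convenience accessors -------------------------------------------
    def get(self, sample_id: str) -> SampleInfo:
        for m in self.members:
            if m.sample_id == sample_id:
                return m
        raise KeyError(sample_id)

    @property
    def proband(self) -> Optional[SampleInfo]:
        for m in self.members:
            if m.role == Role.PROBAND:
                return m
        return None

    def parents_of(self, sample_id: str) -> tuple[Optional[str], Optional[str]]:
        """Return (mother_id, father_id) of a member; absent links are None."""
        return self.parent_links.get(sample_id, (None, None))

    def trio_complete(self, samples_with_data: Optional[set[str]] = None) -> bool:
        """True iff proband, mother and father exist (and have genotype data
        when ``samples_with_data`` is given)."""
        p = self.proband
        if p is None:
            return False
        mo, fa = self.parents_of(p.sample_id)
        if mo is None or fa is None:
            return False
        if samples_with_data is not None:
            return {p.sample_id, mo, fa} <= samples_with_data
        return True

    def affected_members(self, include_suspected: bool = False) -> list[SampleInfo]:
        ok = {AffectedStatus.AFFECTED}
        if include_suspected:
            ok.add(AffectedStatus.SUSPECTED)
        return [m for m in self.members if m.affected in ok]

    def unaffected_members(self) -> list[SampleInfo]:
        return [m for m in self.members if m.affected == AffectedStatus.UNAFFECTED]


@dataclass(frozen=True)
class VariantRecord:
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    gene: str = ""
    transcript: str = ""
    consequence: Consequence = Consequence.OTHER
    hgvs_c: Optional[str] = None
    hgvs_p: Optional[str] = None

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def is_functional(self) -> bool:
        return self.consequence in FUNCTIONAL_CONSEQUENCES


PANELS = ("SHGPdb", "KG1000", "ExAC", "Kaviar")
BRAIN_DBS = ("GTEx", "BioGPS", "CGAP", "HBT")


@dataclass
class FrequencyProfile:
    """Per-panel minor allele frequencies; a panel may be missing (None).

    A printed frequency of 0 means observed-absent and is stored as 0.0 —
    distinct from a missing panel.
    """

    maf_by_panel: dict[str, Optional[float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for panel, v in self.maf_by_panel.items():
            if v is not None and not (0.0 <= v <= 1.0):
                raise ValueError(f"MAF out of [0,1] for {panel}: {v}")


@dataclass
class PredictionProfile:
    cadd_phred: Optional[float] = None
    predictsnp2_label: str = "missing"  # deleterious | neutral | missing
    predictsnp2_accuracy_pct: Optional[float] = None
    fathmm_mkl_score: Optional[float] = None

    def __post_init__(self) -> None:
        if self.predictsnp2_label not in ("deleterious", "neutral", "missing"):
            raise ValueError(f"bad PredictSNP2 label: {self.predictsnp2_label}")
        if self.cadd_phred is not None and self.cadd_phred < 0:
            raise ValueError("CADD phred must be non-negative")
        if self.fathmm_mkl_score is not None and not (0 <= self.fathmm_mkl_score <= 1):
            raise ValueError("FATHMM-MKL score must be in [0,1]")


@dataclass
class ConstraintMetrics:
    """Gene-level intolerance metrics (pLI, missense Z); annotation only,
    never used as a filter."""

    pli: Optional[float] = None
    mis_z: Optional[float] = None


@dataclass
class BrainExpressionProfile:
    positive_by_db: dict[str, Optional[bool]] = field(default_factory=dict)

    def n_positive(self) -> int:
        # missing entries count as non-positive votes
        return sum(1 for db in BRAIN_DBS if self.positive_by_db.get(db))


# ---------------------------------------------------------------------------
# chromosome / genotype normalization

# hg19 X pseudo-autosomal regions (1-based inclusive)
_PAR1 = (60001, 2_699_520)
_PAR2 = (154_931_044, 155_260_560)


def normalize_chrom(chrom: str) -> str:
    c = str(chrom)
    if c.lower().startswith("chr"):
        c = c[3:]
    if c.upper() in ("X", "Y", "MT", "M"):
        return c.upper()
    return c


def is_x_nonpar(chrom: str, pos: Optional[int] = None) -> bool:
    if normalize_chrom(chrom) != "X":
        return False
    if pos is None:
        return True
    return not (_PAR1[0] <= pos <= _PAR1[1] or _PAR2[0] <= pos <= _PAR2[1])


_TABLE_DIALECT = {"WT": GenotypeCall.HOM_REF, "HET": GenotypeCall.HET, "HOM": GenotypeCall.HOM_ALT}


def normalize_table_genotype(
    label: str,
    chrom: str = "1",
    pos: Optional[int] = None,
    sex: Sex = Sex.UNKNOWN,
) -> GenotypeCall:
    """Map a screening-table genotype label (WT/HET/HOM) to a GenotypeCall.

    Male X non-PAR labels HET and HOM both normalize to HEMI_ALT: the
    table dialect reports diploid-style labels regardless of ploidy.
    """
    lab = label.strip().upper()
    if lab in ("", ".", "NA", "ND"):
        return GenotypeCall.MISSING
    try:
        call = _TABLE_DIALECT[lab]
    except KeyError:
        raise ValueError(f"unknown genotype label {label!r}") from None
    if sex == Sex.MALE and is_x_nonpar(chrom, pos) and call.carries_alt:
        return GenotypeCall.HEMI_ALT
    return call


def denormalize_table_genotype(call: GenotypeCall) -> str:
    """Print a GenotypeCall back in the screening-table dialect."""
    return {
        GenotypeCall.HOM_REF: "WT",
        GenotypeCall.HET: "HET",
        GenotypeCall.HOM_ALT: "HOM",
        GenotypeCall.HEMI_ALT: "HOM",
        GenotypeCall.MISSING: "NA",
    }[call]


def _normalize_vcf_alleles(
    alleles: list[int], chrom: str, pos: int, sex: Sex
) -> GenotypeCall:
    """Map a list of allele indices (0/1, -1 missing) to a GenotypeCall."""
    if not alleles or any(a < 0 for a in alleles):
        return GenotypeCall.MISSING
    n_alt = sum(1 for a in alleles if a > 0)
    if len(alleles) == 1:
        return GenotypeCall.HEMI_ALT if n_alt else GenotypeCall.HOM_REF
    if n_alt == 0:
        call = GenotypeCall.HOM_REF
    elif n_alt == len(alleles):
        call = GenotypeCall.HOM_ALT
    else:
        call = GenotypeCall.HET
    if sex == Sex.MALE and is_x_nonpar(chrom, pos) and call.carries_alt:
        return GenotypeCall.HEMI_ALT
    return call


# ---------------------------------------------------------------------------
# genotype matrix container


class GenotypeTable:
    """Genotype calls keyed by (variant, sample).

    Thin wrapper over a pandas DataFrame of :class:`GenotypeCall` values
    (rows = variants in input order, columns = samples) plus the list of
    :class:`VariantRecord` for the rows.
    """

    def __init__(self, variants: list[VariantRecord], calls: pd.DataFrame):
        if len(variants) != len(calls):
            raise ValueError("variants and call matrix row count differ")
        keys = [v.key for v in variants]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (chrom,pos,ref,alt) in call set")
        self.variants = list(variants)
        self.calls = calls.reset_index(drop=True)

    @property
    def samples(self) -> list[str]:
        return list(self.calls.columns)

    def __len__(self) -> int:
        return len(self.variants)

    def genotype(self, variant_index: int, sample_id: str) -> GenotypeCall:
        return self.calls.at[variant_index, sample_id]

    def row(self, variant_index: int) -> dict[str, GenotypeCall]:
        return self.calls.iloc[variant_index].to_dict()

    def dosage_matrix(self) -> pd.DataFrame:
        """Samples × sites alternate-allele dosage matrix (NaN = missing)."""
        dos = self.calls.map(lambda c: c.dosage)
        dos.index = pd.Index([f"{v.chrom}:{v.pos}:{v.ref}:{v.alt}" for v in self.variants])
        return dos.T


# ---------------------------------------------------------------------------
# PED


_PED_COLUMNS = ["family", "sample", "father", "mother", "sex", "phenotype"]
_SEX_CODES = {"1": Sex.MALE, "2": Sex.FEMALE, "0": Sex.UNKNOWN, "-9": Sex.UNKNOWN}
_PHENO_CODES = {
    "2": AffectedStatus.AFFECTED,
    "1": AffectedStatus.UNAFFECTED,
    "0": AffectedStatus.UNKNOWN,
    "-9": AffectedStatus.UNKNOWN,
}


def read_pedigree(path: str | Path) -> list[FamilyPedigree]:
    """Read a 6-column PED file (optional extra columns: role, age, status).

    Returns one :class:`FamilyPedigree` per family, in file order.
    Unknown parents (``0``) become absent links.
    """
    path = Path(path)
    rows: list[list[str]] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 6:
                raise PedigreeError(f"{path}: PED line has <6 columns: {line!r}")
            rows.append(parts)

    seen: set[str] = set()
    by_family: dict[str, FamilyPedigree] = {}
    order: list[str] = []
    for parts in rows:
        fam, sid, father, mother, sex_code, pheno = parts[:6]
        role_s = parts[6] if len(parts) > 6 else ""
        age_s = parts[7] if len(parts) > 7 else ""
        status_s = parts[8] if len(parts) > 8 else ""
        if sid in seen:
            raise PedigreeError(f"duplicate sample_id {sid!r}")
        seen.add(sid)
        affected = _PHENO_CODES.get(pheno, AffectedStatus.UNKNOWN)
        if status_s:
            affected = AffectedStatus(status_s)
        role = Role(role_s) if role_s else Role.OTHER
        age = None if age_s in ("", "NA", ".", "-9") else float(age_s)
        info = SampleInfo(
            sample_id=sid,
            family_id=fam,
            sex=_SEX_CODES.get(sex_code, Sex.UNKNOWN),
            affected=affected,
            role=role,
            age_years=age,
        )
        if fam not in by_family:
            by_family[fam] = FamilyPedigree(family_id=fam)
            order.append(fam)
        ped = by_family[fam]
        ped.members.append(info)
        mo = None if mother in ("0", "") else mother
        fa = None if father in ("0", "") else father
        if mo is not None or fa is not None:
            ped.parent_links[sid] = (mo, fa)

    # re-validate after assembly (constructor ran on empty pedigrees)
    out = []
    for fam in order:
        ped = by_family[fam]
        out.append(
            FamilyPedigree(
                family_id=ped.family_id,
                members=ped.members,
                parent_links=ped.parent_links,
                passed_qc=ped.passed_qc,
            )
        )
    return out


def write_pedigree(pedigrees: list[FamilyPedigree], path: str | Path) -> None:
    sex_out = {Sex.MALE: "1", Sex.FEMALE: "2", Sex.UNKNOWN: "0"}
    pheno_out = {
        AffectedStatus.AFFECTED: "2",
        AffectedStatus.UNAFFECTED: "1",
        AffectedStatus.SUSPECTED: "0",
        AffectedStatus.UNKNOWN: "0",
    }
    with open(path, "w") as fh:
        fh.write("#family\tsample\tfather\tmother\tsex\tphenotype\trole\tage\tstatus\n")
        for ped in pedigrees:
            for m in ped.members:
                mo, fa = ped.parent_links.get(m.sample_id, (None, None))
                age = "NA" if m.age_years is None else (
                    str(int(m.age_years)) if float(m.age_years).is_integer() else str(m.age_years)
                )
                fh.write(
                    "\t".join(
                        [
                            ped.family_id,
                            m.sample_id,
                            fa or "0",
                            mo or "0",
                            sex_out[m.sex],
                            pheno_out[m.affected],
                            m.role.value,
                            age,
                            m.affected.value,
                        ]
                    )
                    + "\n"
                )


# ---------------------------------------------------------------------------
# VCF


def read_cohort_vcf(
    path: str | Path,
    pedigrees: Optional[list[FamilyPedigree]] = None,
    drop_filtered: bool = False,
) -> GenotypeTable:
    """Read a multi-sample VCF into a :class:`GenotypeTable`.

    Sample sexes (for male X hemizygosity) are taken from the pedigrees
    when provided.  Pedigree members absent from the VCF are added as
    all-MISSING columns with a warning.  Sites failing FILTER are dropped
    only when ``drop_filtered`` is set; by default every site is kept —
    filtering is the pipeline's job, not the reader's.
    """
    from cyvcf2 import VCF

    sex_by_sample: dict[str, Sex] = {}
    ped_samples: list[str] = []
    for ped in pedigrees or []:
        for m in ped.members:
            sex_by_sample[m.sample_id] = m.sex
            ped_samples.append(m.sample_id)

    try:
        vcf = VCF(str(path))
    except Exception as exc:  # pragma: no cover - cyvcf2 raises on open
        raise ValueError(f"malformed VCF {path}: {exc}") from exc
    samples = list(vcf.samples)
    variants: list[VariantRecord] = []
    rows: list[list[GenotypeCall]] = []
    for var in vcf:
        if drop_filtered and var.FILTER is not None:
            continue
        chrom = normalize_chrom(var.CHROM)
        alts = var.ALT or ["."]
        gene = var.INFO.get("GENE", "") or ""
        csq = var.INFO.get("CSQ", "") or ""
        try:
            consequence = Consequence(csq) if csq else Consequence.OTHER
        except ValueError:
            consequence = Consequence.OTHER
        rec = VariantRecord(
            chrom=chrom,
            pos=var.POS,
            ref=var.REF,
            alt=alts[0],
            gene=str(gene),
            consequence=consequence,
        )
        calls = []
        for sample, gt in zip(samples, var.genotypes):
            alleles = [a for a in gt[:-1]]  # last entry is the phased flag
            sex = sex_by_sample.get(sample, Sex.UNKNOWN)
            calls.append(_normalize_vcf_alleles(alleles, chrom, var.POS, sex))
        variants.append(rec)
        rows.append(calls)

    frame = pd.DataFrame(rows, columns=samples, dtype=object)
    missing = [s for s in dict.fromkeys(ped_samples) if s not in samples]
    if missing:
        warnings.warn(
            f"pedigree samples absent from VCF, filled with MISSING: {missing}",
            stacklevel=2,
        )
        for s in missing:
            frame[s] = GenotypeCall.MISSING
    return GenotypeTable(variants, frame)


_VCF_GT = {
    GenotypeCall.HOM_REF: "0/0",
    GenotypeCall.HET: "0/1",
    GenotypeCall.HOM_ALT: "1/1",
    GenotypeCall.HEMI_ALT: "1",
    GenotypeCall.MISSING: "./.",
}


def write_cohort_vcf(table: GenotypeTable, path: str | Path) -> None:
    """Write a GenotypeTable as a minimal VCF 4.2 with GENE/CSQ INFO tags."""
    samples = table.samples
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">\n')
        fh.write('##INFO=<ID=CSQ,Number=1,Type=String,Description="Consequence class">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        contigs = list(dict.fromkeys(v.chrom for v in table.variants))
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        order = sorted(
            range(len(table.variants)),
            key=lambda i: (contigs.index(table.variants[i].chrom), table.variants[i].pos),
        )
        for i in order:
            v = table.variants[i]
            info_parts = []
            if v.gene:
                info_parts.append(f"GENE={v.gene}")
            if v.consequence != Consequence.OTHER:
                info_parts.append(f"CSQ={v.consequence.value}")
            info = ";".join(info_parts) or "."
            gts = [_VCF_GT[table.calls.at[i, s]] for s in samples]
            fh.write(
                f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\t.\t{info}\tGT\t" + "\t".join(gts) + "\n"
            )


# ---------------------------------------------------------------------------
# annotation tables, GMT, gene intervals


def read_annotations(path: str | Path) -> pd.DataFrame:
    """Read a per-variant annotation TSV keyed by (chrom,pos,ref,alt).

    Expected columns mirror the packaged fixture dialect: gene, consequence,
    panel MAFs (``maf_shgpdb``, ``maf_1000g``, ``maf_exac``, ``maf_kaviar``),
    prediction scores and optional constraint metrics.  Empty cells mean
    missing — not zero.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    df["chrom"] = df["chrom"].map(normalize_chrom)
    return df


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT file: name <tab> description <tab> genes..."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            sets[parts[0]] = {g for g in parts[2:] if g}
    return sets


def read_gene_intervals(path: str | Path) -> pd.DataFrame:
    """Read gene intervals from BED (0-based half-open) into 1-based inclusive
    columns (chrom, start, end, gene)."""
    df = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start0", "end", "gene"],
        usecols=[0, 1, 2, 3],
    )
    df["chrom"] = df["chrom"].map(normalize_chrom)
    df["start"] = df["start0"].astype(int) + 1
    df["end"] = df["end"].astype(int)
    return df[["chrom", "start", "end", "gene"]]
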