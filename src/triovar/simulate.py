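"""Synthetic family cohorts with planted, fully known ground truth.

The generator emulates the structure of the study cohort — nuclear
families of two parents, one proband and optional affected/unaffected
siblings, from a population with optional founder consanguinity — and
plants events whose expected pipeline outcome is recorded in a truth
manifest:

* rare variants under each transmission mode (de novo, autosomal
  recessive, autosomal dominant, X-linked, compound heterozygous), each
  designed either to survive the full filter cascade or to fail at
  exactly one named stage;
* background common SNPs in Hardy–Weinberg proportions (for relatedness
  statistics), transmitted by gamete dropping so Mendelian consistency
  holds everywhere except where a de novo is planted;
* probe-level log2-ratio tracks with planted gain/loss segments under
  Gaussian noise.

Everything is drawn from a single seeded generator: the same seed gives
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .cnv import ProbeTrack
from .io import (
    AffectedStatus,
    BrainExpressionProfile,
    Consequence,
    FamilyPedigree,
    FrequencyProfile,
    GenotypeCall,
    GenotypeTable,
    PredictionProfile,
    Role,
    SampleInfo,
    Sex,
    VariantRecord,
    write_cohort_vcf,
    write_pedigree,
)
from .prioritize import AnnotatedSite

__all__ = [
    "PlantedVariant",
    "PlantedCnv",
    "SimulationConfig",
    "SimulatedCohort",
    "simulate_cohort",
]

MODES = ("de_novo", "autosomal_recessive", "autosomal_dominant", "x_linked", "compound_het")
FAIL_STAGES = ("functional", "brain", "frequency", "deleterious")


@dataclass(frozen=True)
class PlantedVariant:
    """One designed rare variant: transmission mode, carrying family, and
    the filter stage it is designed to fail (None = designed to pass)."""

    mode: str
    gene: str
    family_index: int
    fail_stage: Optional[str] = None

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.fail_stage is not None and self.fail_stage not in FAIL_STAGES:
            raise ValueError(f"unknown fail stage {self.fail_stage!r}")

    @property
    def designed_pass(self) -> bool:
        return self.fail_stage is None


@dataclass(frozen=True)
class PlantedCnv:
    chrom: str
    start: int
    end: int
    state: str  # "gain" | "loss"
    family_index: int
    carrier_roles: tuple[str, ...] = ("proband",)  # proband/mother/father/sibling ids


def _default_plants(n_families: int = 15) -> list[PlantedVariant]:
    """Study-shaped default: with the default 15 families, 13 carry two
    passing rare variants each under a mix of transmission modes, plus
    designed failures exercising every cascade stage.  Scales down with
    smaller cohorts (all but two families carry plants)."""
    n_hit = max(1, min(13, n_families if n_families <= 2 else n_families - 2))
    plants: list[PlantedVariant] = []
    modes = ["autosomal_dominant", "autosomal_recessive", "de_novo", "autosomal_dominant"]
    g = 0
    for fam in range(n_hit):
        for j in range(2):
            plants.append(PlantedVariant(modes[(fam + j) % 4], f"GENE{g:03d}", fam))
            g += 1
    for i, stage in enumerate(FAIL_STAGES):
        plants.append(
            PlantedVariant("autosomal_dominant", f"GENE{g:03d}", i % n_hit, fail_stage=stage)
        )
        g += 1
    return plants


@dataclass
class SimulationConfig:
    n_families: int = 15
    n_affected_sibs: int = 1
    n_unaffected_sibs: int = 1
    n_sites: int = 1000  # background common SNPs
    allele_freq_range: tuple[float, float] = (0.05, 0.5)
    rare_maf: float = 5e-4  # panel MAF given to passing planted variants
    common_maf: float = 0.02  # the frequency-stage failure value
    planted_variants: Optional[list[PlantedVariant]] = None  # None -> study-shaped default
    cnv_plants: list[PlantedCnv] = field(default_factory=list)
    probe_spacing_bp: int = 5000
    noise_sd: float = 0.2
    loss_log2: float = -1.5
    gain_log2: float = 1.0
    founder_inbreeding: float = 0.0
    genotype_error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.planted_variants is None:
            self.planted_variants = _default_plants(self.n_families)
        for pv in self.planted_variants:
            if pv.family_index >= self.n_families:
                raise ValueError(
                    f"planted variant family_index {pv.family_index} out of range"
                )


@dataclass
class SimulatedCohort:
    pedigrees: list[FamilyPedigree]
    table: GenotypeTable
    annotations: dict[tuple, AnnotatedSite]
    probe_tracks: dict[str, list[ProbeTrack]]  # sample -> tracks
    truth: pd.DataFrame  # one row per planted item with expected outcome

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write VCF + PED + annotation TSV + probe TSV + truth manifest."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "vcf": outdir / "cohort.vcf",
            "ped": outdir / "cohort.ped",
            "annotations": outdir / "annotations.tsv",
            "probes": outdir / "probes.tsv",
            "truth": outdir / "truth.tsv",
        }
        write_cohort_vcf(self.table, paths["vcf"])
        write_pedigree(self.pedigrees, paths["ped"])
        ann_rows = []
        for site in self.annotations.values():
            v = site.variant
            ann_rows.append(
                {
                    "chrom": v.chrom,
                    "pos": v.pos,
                    "ref": v.ref,
                    "alt": v.alt,
                    "gene": v.gene,
                    "consequence": v.consequence.value,
                    "maf_shgpdb": site.frequency.maf_by_panel.get("SHGPdb"),
                    "maf_1000g": site.frequency.maf_by_panel.get("KG1000"),
                    "maf_exac": site.frequency.maf_by_panel.get("ExAC"),
                    "maf_kaviar": site.frequency.maf_by_panel.get("Kaviar"),
                    "cadd_phred": site.prediction.cadd_phred,
                    "predictsnp2_label": site.prediction.predictsnp2_label,
                    "fathmm_mkl": site.prediction.fathmm_mkl_score,
                    "brain_votes": site.brain.n_positive(),
                }
            )
        pd.DataFrame(ann_rows).to_csv(paths["annotations"], sep="\t", index=False)
        probe_rows = []
        for sample, tracks in self.probe_tracks.items():
            for t in tracks:
                for pos, lr in zip(t.positions, t.log2_ratio):
                    probe_rows.append((sample, t.chrom, int(pos), float(lr)))
        pd.DataFrame(probe_rows, columns=["sample", "chrom", "pos", "log2"]).to_csv(
            paths["probes"], sep="\t", index=False
        )
        self.truth.to_csv(paths["truth"], sep="\t", index=False)
        return paths


# ---------------------------------------------------------------------------


def _make_pedigree(cfg: SimulationConfig, fam_idx: int) -> FamilyPedigree:
    fam = f"SF{fam_idx + 1}"
    # proband sex follows the 3:1 male:female ratio of the emulated cohort
    proband_sex = Sex.FEMALE if fam_idx % 4 == 3 else Sex.MALE
    members = [
        SampleInfo(f"{fam}_F", fam, Sex.MALE, AffectedStatus.UNAFFECTED, Role.FATHER),
        SampleInfo(f"{fam}_M", fam, Sex.FEMALE, AffectedStatus.UNAFFECTED, Role.MOTHER),
        SampleInfo(f"{fam}_P", fam, proband_sex, AffectedStatus.AFFECTED, Role.PROBAND),
    ]
    links = {f"{fam}_P": (f"{fam}_M", f"{fam}_F")}
    for i in range(cfg.n_affected_sibs):
        sid = f"{fam}_AS{i + 1}"
        members.append(SampleInfo(sid, fam, Sex.MALE, AffectedStatus.AFFECTED, Role.SIBLING))
        links[sid] = (f"{fam}_M", f"{fam}_F")
    for i in range(cfg.n_unaffected_sibs):
        sid = f"{fam}_US{i + 1}"
        members.append(SampleInfo(sid, fam, Sex.FEMALE, AffectedStatus.UNAFFECTED, Role.SIBLING))
        links[sid] = (f"{fam}_M", f"{fam}_F")
    return FamilyPedigree(family_id=fam, members=members, parent_links=links)


def _founder_dosages(
    rng: np.random.Generator, freqs: np.ndarray, inbreeding: float
) -> np.ndarray:
    """Draw one founder's dosage vector; with probability ``inbreeding`` a
    site is autozygous (one allele drawn and doubled)."""
    a1 = (rng.random(len(freqs)) < freqs).astype(np.int8)
    a2 = (rng.random(len(freqs)) < freqs).astype(np.int8)
    if inbreeding > 0:
        auto = rng.random(len(freqs)) < inbreeding
        return np.where(auto, 2 * a1, a1 + a2).astype(np.int8)
    return (a1 + a2).astype(np.int8)


def _drop_gametes(rng: np.random.Generator, dosage: np.ndarray) -> np.ndarray:
    """Vectorized meiosis: transmitted allele count per site from one parent."""
    coin = rng.integers(0, 2, size=len(dosage)).astype(np.int8)
    out = np.where(dosage == 2, 1, np.where(dosage == 1, coin, 0))
    return out.astype(np.int8)


def _dosage_to_call(dosage: int) -> GenotypeCall:
    return (GenotypeCall.HOM_REF, GenotypeCall.HET, GenotypeCall.HOM_ALT)[dosage]


def _passing_annotation(v: VariantRecord, cfg: SimulationConfig, fail_stage: Optional[str]) -> AnnotatedSite:
    maf = cfg.rare_maf
    freq = {"SHGPdb": maf, "KG1000": maf, "ExAC": maf, "Kaviar": maf}
    pred = PredictionProfile(cadd_phred=28.0, predictsnp2_label="deleterious", fathmm_mkl_score=0.9)
    brain = {db: True for db in ("GTEx", "BioGPS", "CGAP", "HBT")}
    if fail_stage == "frequency":
        freq["ExAC"] = cfg.common_maf
    elif fail_stage == "deleterious":
        pred = PredictionProfile(cadd_phred=5.0, predictsnp2_label="neutral", fathmm_mkl_score=0.1)
    elif fail_stage == "brain":
        brain = {"GTEx": True, "BioGPS": False, "CGAP": False, "HBT": False}
    return AnnotatedSite(
        variant=v,
        frequency=FrequencyProfile(maf_by_panel=freq),
        prediction=pred,
        brain=BrainExpressionProfile(positive_by_db=brain),
    )


def simulate_cohort(cfg: SimulationConfig) -> SimulatedCohort:
    """Generate a cohort per the configuration; see the module docstring.

    Raises a config error for infeasible plants (an X-linked hemizygous
    plant in a family with a female proband).
    """
    rng = np.random.default_rng(cfg.seed)
    pedigrees = [_make_pedigree(cfg, i) for i in range(cfg.n_families)]
    samples = [m.sample_id for p in pedigrees for m in p.members]
    sample_sex = {m.sample_id: m.sex for p in pedigrees for m in p.members}

    variants: list[VariantRecord] = []
    call_rows: list[list[GenotypeCall]] = []
    annotations: dict[tuple, AnnotatedSite] = {}
    truth_rows: list[dict] = []

    # ---- background common SNPs: founders HWE, children by gamete drop
    lo, hi = cfg.allele_freq_range
    freqs = rng.uniform(lo, hi, size=cfg.n_sites)
    dosages = np.zeros((cfg.n_sites, len(samples)), dtype=np.int8)
    col = {s: i for i, s in enumerate(samples)}
    for ped in pedigrees:
        fam = ped.family_id
        fa, mo = f"{fam}_F", f"{fam}_M"
        dosages[:, col[fa]] = _founder_dosages(rng, freqs, cfg.founder_inbreeding)
        dosages[:, col[mo]] = _founder_dosages(rng, freqs, cfg.founder_inbreeding)
        for m in ped.members:
            if m.role in (Role.FATHER, Role.MOTHER):
                continue
            dosages[:, col[m.sample_id]] = _drop_gametes(
                rng, dosages[:, col[mo]]
            ) + _drop_gametes(rng, dosages[:, col[fa]])
    for i in range(cfg.n_sites):
        v = VariantRecord(chrom="1", pos=10_000 + i * 100, ref="A", alt="G", gene="", consequence=Consequence.OTHER)
        variants.append(v)
        call_rows.append([_dosage_to_call(int(d)) for d in dosages[i]])
        annotations[v.key] = AnnotatedSite(
            variant=v,
            frequency=FrequencyProfile(maf_by_panel={"ExAC": min(freqs[i], 1 - freqs[i])}),
            prediction=PredictionProfile(),
            brain=BrainExpressionProfile(),
        )

    # ---- planted rare variants
    next_pos = {"2": 1_000_000, "X": 10_000_000}
    for idx, pv in enumerate(cfg.planted_variants):
        ped = pedigrees[pv.family_index]
        fam = ped.family_id
        chrom = "X" if pv.mode == "x_linked" else "2"
        proband = ped.proband
        if pv.mode == "x_linked" and proband.sex != Sex.MALE:
            raise ValueError(
                f"infeasible plant: x_linked hemizygous variant in family {fam} "
                "with a female proband"
            )
        n_sites_for_plant = 2 if pv.mode == "compound_het" else 1
        site_records = []
        for k in range(n_sites_for_plant):
            pos = next_pos[chrom]
            next_pos[chrom] += 100_000
            consequence = (
                Consequence.SYNONYMOUS if pv.fail_stage == "functional" else Consequence.MISSENSE
            )
            v = VariantRecord(chrom=chrom, pos=pos, ref="C", alt="T", gene=pv.gene, consequence=consequence)
            site_records.append(v)

        for k, v in enumerate(site_records):
            calls = {s: GenotypeCall.HOM_REF for s in samples}
            mo_id, fa_id = ped.parents_of(proband.sample_id)
            if pv.mode == "de_novo":
                calls[proband.sample_id] = GenotypeCall.HET
            elif pv.mode == "autosomal_recessive":
                calls[mo_id] = GenotypeCall.HET
                calls[fa_id] = GenotypeCall.HET
                calls[proband.sample_id] = GenotypeCall.HOM_ALT
                for m in ped.members:
                    if m.role == Role.SIBLING:
                        calls[m.sample_id] = (
                            GenotypeCall.HOM_ALT
                            if m.affected == AffectedStatus.AFFECTED
                            else GenotypeCall.HET
                        )
            elif pv.mode == "autosomal_dominant":
                # fully penetrant: transmitted from the one carrier parent
                carrier = mo_id if idx % 2 == 0 else fa_id
                calls[carrier] = GenotypeCall.HET
                calls[proband.sample_id] = GenotypeCall.HET
                for m in ped.members:
                    if m.role == Role.SIBLING and m.affected == AffectedStatus.AFFECTED:
                        calls[m.sample_id] = GenotypeCall.HET
            elif pv.mode == "x_linked":
                calls[mo_id] = GenotypeCall.HET
                calls[proband.sample_id] = GenotypeCall.HEMI_ALT
                for m in ped.members:
                    if m.role == Role.SIBLING and m.affected == AffectedStatus.AFFECTED:
                        calls[m.sample_id] = (
                            GenotypeCall.HEMI_ALT if m.sex == Sex.MALE else GenotypeCall.HET
                        )
            else:  # compound_het: site 0 maternal, site 1 paternal
                origin = mo_id if k == 0 else fa_id
                calls[origin] = GenotypeCall.HET
                calls[proband.sample_id] = GenotypeCall.HET

            variants.append(v)
            call_rows.append([calls[s] for s in samples])
            annotations[v.key] = _passing_annotation(v, cfg, pv.fail_stage)
            truth_rows.append(
                {
                    "kind": "variant",
                    "family": fam,
                    "gene": pv.gene,
                    "chrom": v.chrom,
                    "pos": v.pos,
                    "mode": pv.mode,
                    "fail_stage": pv.fail_stage or "",
                    "expected_pass": pv.designed_pass,
                }
            )

    # ---- optional genotyping errors (exercise the UNRESOLVED path)
    if cfg.genotype_error_rate > 0:
        flat = [(i, j) for i in range(len(call_rows)) for j in range(len(samples))]
        for i, j in flat:
            if rng.random() < cfg.genotype_error_rate:
                current = call_rows[i][j]
                others = [
                    c
                    for c in (GenotypeCall.HOM_REF, GenotypeCall.HET, GenotypeCall.HOM_ALT)
                    if c != current
                ]
                call_rows[i][j] = others[int(rng.integers(len(others)))]

    # ---- probe tracks with planted CNV segments
    probe_tracks: dict[str, list[ProbeTrack]] = {s: [] for s in samples}
    by_chrom: dict[str, list[PlantedCnv]] = {}
    for plant in cfg.cnv_plants:
        by_chrom.setdefault(plant.chrom, []).append(plant)
    for chrom, plants in by_chrom.items():
        lo_pos = min(p.start for p in plants) - 50 * cfg.probe_spacing_bp
        hi_pos = max(p.end for p in plants) + 50 * cfg.probe_spacing_bp
        positions = np.arange(max(1, lo_pos), hi_pos, cfg.probe_spacing_bp, dtype=np.int64)
        for ped in pedigrees:
            for m in ped.members:
                baseline = rng.normal(0.0, cfg.noise_sd, size=len(positions))
                for plant in plants:
                    if pedigrees[plant.family_index] is not ped:
                        continue
                    role_ids = _carrier_ids(ped, plant.carrier_roles)
                    if m.sample_id not in role_ids:
                        continue
                    inside = (positions >= plant.start) & (positions <= plant.end)
                    level = cfg.loss_log2 if plant.state == "loss" else cfg.gain_log2
                    baseline[inside] += level
                probe_tracks[m.sample_id].append(
                    ProbeTrack(chrom=chrom, positions=positions, log2_ratio=baseline)
                )
    for plant in cfg.cnv_plants:
        truth_rows.append(
            {
                "kind": "cnv",
                "family": pedigrees[plant.family_index].family_id,
                "gene": "",
                "chrom": plant.chrom,
                "pos": plant.start,
                "mode": plant.state,
                "fail_stage": "",
                "expected_pass": True,
            }
        )

    calls_df = pd.DataFrame(call_rows, columns=samples, dtype=object)
    table = GenotypeTable(variants, calls_df)
    truth = pd.DataFrame(
        truth_rows,
        columns=["kind", "family", "gene", "chrom", "pos", "mode", "fail_stage", "expected_pass"],
    )
    return SimulatedCohort(pedigrees, table, annotations, probe_tracks, truth)


def _carrier_ids(ped: FamilyPedigree, roles: tuple[str, ...]) -> set[str]:
    out: set[str] = set()
    for r in roles:
        if r in ("proband", "mother", "father"):
            for m in ped.members:
                if m.role.value == r:
                    out.add(m.sample_id)
        else:
            out.add(r)  # explicit sample id
    return out
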