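"""Trio classification, compound-het scan, and segregation annotation.

The classifier is checked against an independent gamete-enumeration
oracle over every autosomal trio configuration, and against the
packaged cohort's screened genotypes.
"""

import itertools

import pytest

from triovar.inheritance import (
    Mode,
    annotate_segregation,
    classify_trio,
    classify_trio_tolerant,
    scan_compound_het,
)
from triovar.io import (
    AffectedStatus,
    Consequence,
    FamilyPedigree,
    GenotypeCall,
    Role,
    SampleInfo,
    Sex,
    VariantRecord,
)

G = GenotypeCall
DIPLOID = [G.HOM_REF, G.HET, G.HOM_ALT]


def _gametes(call: GenotypeCall) -> set[int]:
    """Alleles a diploid parent can transmit."""
    return {G.HOM_REF: {0}, G.HET: {0, 1}, G.HOM_ALT: {1}}[call]


def mendel_oracle(proband: G, mother: G, father: G) -> Mode:
    """Independent truth table for autosomal trios, built by enumerating
    parental gametes rather than by genotype pattern-matching."""
    if proband == G.HOM_REF:
        return Mode.UNRESOLVED  # allele not carried: nothing to classify
    if mother == G.HOM_REF and father == G.HOM_REF:
        return Mode.DE_NOVO  # carrier child of two reference-homozygous parents
    child_dosage = {G.HET: (0, 1), G.HOM_ALT: (1, 1)}[proband]
    possible = any(
        sorted((gm, gf)) == sorted(child_dosage)
        for gm in _gametes(mother)
        for gf in _gametes(father)
    )
    if not possible:
        return Mode.UNRESOLVED
    return Mode.AUTOSOMAL_RECESSIVE if proband == G.HOM_ALT else Mode.AUTOSOMAL_DOMINANT


class TestClassifyTrio:
    def test_agrees_with_enumeration_oracle_on_all_27_autosomal_configs(self):
        for p, m, f in itertools.product(DIPLOID, repeat=3):
            got = classify_trio(p, m, f, chrom="7").mode
            assert got == mendel_oracle(p, m, f), (p, m, f)

    @pytest.mark.parametrize(
        "p,m,f,expected",
        [
            (G.HET, G.HOM_REF, G.HOM_REF, Mode.DE_NOVO),
            (G.HOM_ALT, G.HET, G.HET, Mode.AUTOSOMAL_RECESSIVE),
            (G.HOM_REF, G.HET, G.HET, Mode.UNRESOLVED),
            (G.HET, G.HET, G.HOM_REF, Mode.AUTOSOMAL_DOMINANT),
            (G.HOM_ALT, G.HOM_REF, G.HET, Mode.UNRESOLVED),
        ],
    )
    def test_autosomal_examples(self, p, m, f, expected):
        assert classify_trio(p, m, f, chrom="17").mode == expected

    def test_male_x_maternal_transmission(self):
        call = classify_trio(
            G.HEMI_ALT, G.HET, G.HOM_REF, chrom="X", proband_sex=Sex.MALE, pos=11_000_000
        )
        assert call.mode == Mode.X_LINKED
        assert call.detail == "maternal"

    def test_male_x_de_novo_flagged(self):
        call = classify_trio(
            G.HEMI_ALT, G.HOM_REF, G.HOM_REF, chrom="X", proband_sex=Sex.MALE, pos=11_000_000
        )
        assert call.mode == Mode.DE_NOVO
        assert "hemizygous" in call.detail

    def test_female_x_het_with_carrier_parent_is_x_linked(self):
        call = classify_trio(
            G.HET, G.HET, G.HOM_REF, chrom="X", proband_sex=Sex.FEMALE, pos=11_000_000
        )
        assert call.mode == Mode.X_LINKED

    def test_missing_genotype_raises_and_tolerant_wrapper_unresolves(self):
        with pytest.raises(ValueError, match="missing-tolerant"):
            classify_trio(G.HET, G.MISSING, G.HOM_REF)
        call = classify_trio_tolerant(G.HET, G.MISSING, G.HOM_REF)
        assert call.mode == Mode.UNRESOLVED
        assert call.detail == "missing_genotype"

    def test_fixture_cohort_yields_exactly_two_de_novo(self, table3_rows, pedigrees):
        peds = {p.family_id: p for p in pedigrees}
        de_novo_genes = []
        for row in table3_rows:
            ped = peds[row.family_id]
            proband = ped.proband
            mo, fa = ped.parents_of(proband.sample_id)
            call = classify_trio_tolerant(
                row.genotypes[proband.sample_id],
                row.genotypes.get(mo, G.MISSING),
                row.genotypes.get(fa, G.MISSING),
                chrom=row.variant.chrom,
                proband_sex=proband.sex,
                pos=row.variant.pos,
            )
            if call.mode == Mode.DE_NOVO:
                de_novo_genes.append((row.family_id, row.variant.gene))
        assert sorted(de_novo_genes) == [("F12", "PDHA1"), ("F19", "TLK2")]

    def test_fixture_lrrk1_is_recessive(self, table3_rows):
        row = next(r for r in table3_rows if r.variant.gene == "LRRK1")
        call = classify_trio(
            row.genotypes["F1_P"], row.genotypes["F1_UM"], row.genotypes["F1_UF"], chrom="15"
        )
        assert call.mode == Mode.AUTOSOMAL_RECESSIVE


def _var(gene: str, pos: int) -> VariantRecord:
    return VariantRecord("2", pos, "C", "T", gene=gene, consequence=Consequence.MISSENSE)


class TestCompoundHet:
    def test_opposite_parental_origin_gives_trans_candidate(self):
        items = [
            (_var("LRRK1", 100), G.HET, G.HET, G.HOM_REF),  # maternal
            (_var("LRRK1", 200), G.HET, G.HOM_REF, G.HET),  # paternal
        ]
        (cand,) = scan_compound_het(items)
        assert cand.phase_support == "trans_by_parents"
        assert cand.gene == "LRRK1"

    def test_same_parental_origin_gives_no_candidate(self):
        items = [
            (_var("LRRK1", 100), G.HET, G.HET, G.HOM_REF),
            (_var("LRRK1", 200), G.HET, G.HET, G.HOM_REF),
        ]
        assert scan_compound_het(items) == []

    def test_ambiguous_origin_flagged_unphased(self):
        items = [
            (_var("LRRK1", 100), G.HET, G.HET, G.HET),  # both parents carry
            (_var("LRRK1", 200), G.HET, G.HOM_REF, G.HET),
        ]
        (cand,) = scan_compound_het(items)
        assert cand.phase_support == "unphased"

    def test_empty_input_gives_empty_list(self):
        assert scan_compound_het([]) == []

    def test_mixed_genes_rejected(self):
        items = [
            (_var("A", 100), G.HET, G.HET, G.HOM_REF),
            (_var("B", 200), G.HET, G.HOM_REF, G.HET),
        ]
        with pytest.raises(ValueError, match="multiple genes"):
            scan_compound_het(items)

    def test_six_variant_gene_matches_all_pairs_brute_force(self):
        # deterministic mix of origins over six heterozygous proband variants
        origins = ["maternal", "paternal", "ambiguous", "maternal", "paternal", "ambiguous"]
        parent_calls = {
            "maternal": (G.HET, G.HOM_REF),
            "paternal": (G.HOM_REF, G.HET),
            "ambiguous": (G.HET, G.HET),
        }
        items = [
            (_var("GENE", 100 * (i + 1)), G.HET, *parent_calls[o])
            for i, o in enumerate(origins)
        ]
        got = {
            (c.variant_pair[0].pos, c.variant_pair[1].pos): c.phase_support
            for c in scan_compound_het(items)
        }
        # brute force over all C(6,2) pairs straight from the origin labels
        expected = {}
        for (i, oi), (j, oj) in itertools.combinations(enumerate(origins), 2):
            pair = (100 * (i + 1), 100 * (j + 1))
            if {oi, oj} == {"maternal", "paternal"}:
                expected[pair] = "trans_by_parents"
            elif "ambiguous" in (oi, oj):
                expected[pair] = "unphased"
        assert got == expected


def _family(statuses: dict[str, AffectedStatus]) -> FamilyPedigree:
    members = [SampleInfo("P", "FAM", Sex.MALE, AffectedStatus.AFFECTED, Role.PROBAND)]
    for sid, status in statuses.items():
        members.append(SampleInfo(sid, "FAM", Sex.MALE, status, Role.SIBLING))
    return FamilyPedigree("FAM", members, {"P": (None, None)})


class TestSegregation:
    def test_lrrk1_family_counts(self, table3_rows, pedigrees):
        row = next(r for r in table3_rows if r.variant.gene == "LRRK1")
        ped = next(p for p in pedigrees if p.family_id == "F1")
        prof = annotate_segregation(row.genotypes, ped)
        assert prof.fully_segregates is False
        assert prof.n_affected_matching_proband == 3  # proband + two homozygous brothers
        assert prof.n_affected_carriers == 4
        assert prof.n_unaffected_carriers == 4  # parents and both unaffected sibs are HET

    def test_proband_only_family_is_undefined(self):
        ped = _family({})
        prof = annotate_segregation({"P": G.HET}, ped)
        assert prof.fully_segregates is None

    def test_fully_penetrant_dominant_family_segregates(self):
        ped = _family({"AS1": AffectedStatus.AFFECTED, "US1": AffectedStatus.UNAFFECTED})
        prof = annotate_segregation({"P": G.HET, "AS1": G.HET, "US1": G.HOM_REF}, ped)
        assert prof.fully_segregates is True

    def test_invariant_under_sample_relabeling(self):
        ped1 = _family({"AS1": AffectedStatus.AFFECTED, "US1": AffectedStatus.UNAFFECTED})
        genos1 = {"P": G.HET, "AS1": G.HET, "US1": G.HET}
        ped2 = _family({"X9": AffectedStatus.AFFECTED, "Y7": AffectedStatus.UNAFFECTED})
        genos2 = {"P": G.HET, "X9": G.HET, "Y7": G.HET}
        p1 = annotate_segregation(genos1, ped1)
        p2 = annotate_segregation(genos2, ped2)
        assert (p1.fully_segregates, p1.n_affected_carriers, p1.n_unaffected_carriers) == (
            p2.fully_segregates, p2.n_affected_carriers, p2.n_unaffected_carriers
        )

    def test_suspected_member_excluded_by_default(self, table3_rows, pedigrees):
        row = next(r for r in table3_rows if r.variant.gene == "PSRC1")
        ped = next(p for p in pedigrees if p.family_id == "F25")
        default = annotate_segregation(row.genotypes, ped)
        included = annotate_segregation(row.genotypes, ped, include_suspected=True)
        # the suspected sister carries the variant; she counts only on request
        assert included.n_affected_carriers == default.n_affected_carriers + 1

    def test_missing_proband_genotype_rejected(self):
        ped = _family({})
        with pytest.raises(ValueError, match="proband"):
            annotate_segregation({}, ped)
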