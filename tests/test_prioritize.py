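"""The four-stage filter cascade and the cohort-level driver."""

import itertools

import pytest

from triovar.io import (
    BrainExpressionProfile,
    Consequence,
    FrequencyProfile,
    PredictionProfile,
    VariantRecord,
)
from triovar.prioritize import (
    PrioritizeConfig,
    apply_filters,
    consensus_deleterious,
    filter_brain_expression,
    filter_frequency,
    filter_functional,
    prioritize_cohort,
    summarize,
)
from triovar.simulate import SimulationConfig, simulate_cohort


def _variant(csq: Consequence) -> VariantRecord:
    return VariantRecord("1", 100, "C", "T", gene="GENE", consequence=csq)


class TestFunctionalStage:
    @pytest.mark.parametrize(
        "csq,expected",
        [
            (Consequence.MISSENSE, True),
            (Consequence.INFRAME_INDEL, True),
            (Consequence.STOP_GAIN, True),
            (Consequence.FRAMESHIFT, True),
            (Consequence.SPLICE_SITE, True),
            (Consequence.SYNONYMOUS, False),
            (Consequence.OTHER, False),
        ],
    )
    def test_functional_classes(self, csq, expected):
        assert filter_functional(_variant(csq)) is expected


class TestBrainStage:
    def test_three_of_four_passes(self):
        b = BrainExpressionProfile({"GTEx": True, "BioGPS": True, "CGAP": True, "HBT": False})
        assert filter_brain_expression(b)

    def test_two_of_four_fails(self):
        b = BrainExpressionProfile({"GTEx": True, "BioGPS": True, "CGAP": False, "HBT": False})
        assert not filter_brain_expression(b)

    def test_all_missing_fails(self):
        assert not filter_brain_expression(BrainExpressionProfile({}))


class TestFrequencyStage:
    def test_rare_in_all_panels_passes(self):
        f = FrequencyProfile({"SHGPdb": 1.86e-4, "KG1000": 7.99e-4, "ExAC": 5e-4, "Kaviar": 3.95e-4})
        assert filter_frequency(f)

    def test_one_common_panel_vetoes(self):
        f = FrequencyProfile({"SHGPdb": 1e-4, "ExAC": 0.02})
        assert not filter_frequency(f)

    def test_all_missing_passes_by_default_but_fails_strict(self):
        f = FrequencyProfile({})
        assert filter_frequency(f)
        assert not filter_frequency(f, strict_missing=True)

    def test_threshold_is_strict_less_than(self):
        f = FrequencyProfile({"ExAC": 0.01})
        assert not filter_frequency(f, threshold=0.01)

    @pytest.mark.parametrize("bad", [0.0, -0.1, 1.5])
    def test_bad_threshold_rejected(self, bad):
        with pytest.raises(ValueError):
            filter_frequency(FrequencyProfile({}), threshold=bad)


class TestDeleteriousConsensus:
    def test_two_votes_pass_missense(self):
        # high CADD + high FATHMM outvote a neutral PredictSNP2 label
        p = PredictionProfile(cadd_phred=23.5, predictsnp2_label="neutral", fathmm_mkl_score=0.85074)
        ok, votes = consensus_deleterious(p, Consequence.MISSENSE)
        assert (ok, votes) == (True, 2)

    def test_zero_votes_fail_missense(self):
        p = PredictionProfile(cadd_phred=5.0, predictsnp2_label="neutral", fathmm_mkl_score=0.1)
        ok, votes = consensus_deleterious(p, Consequence.MISSENSE)
        assert (ok, votes) == (False, 0)

    def test_stop_gain_passes_via_lof_exemption_with_one_vote(self):
        # truncating allele scored deleterious by CADD only
        p = PredictionProfile(cadd_phred=36.0, predictsnp2_label="neutral", fathmm_mkl_score=0.08066)
        ok, votes = consensus_deleterious(p, Consequence.STOP_GAIN)
        assert (ok, votes) == (True, 1)
        ok_off, _ = consensus_deleterious(p, Consequence.STOP_GAIN, lof_exempt=False)
        assert not ok_off

    def test_missing_predictors_never_vote(self):
        p = PredictionProfile()
        ok, votes = consensus_deleterious(p, Consequence.MISSENSE)
        assert (ok, votes) == (False, 0)

    def test_votes_bounded_by_available_predictors(self):
        p = PredictionProfile(cadd_phred=30.0)
        _, votes = consensus_deleterious(p, Consequence.MISSENSE)
        assert votes == 1


class TestCascadeOnFixture:
    def test_every_fixture_variant_passes_every_stage_under_defaults(
        self, fixture_pipeline_inputs
    ):
        table, annotations, _ = fixture_pipeline_inputs
        for site in annotations.values():
            trace = apply_filters(site.variant, site.frequency, site.prediction, site.brain)
            assert trace.functional_pass, site.variant.gene
            assert trace.brain_pass, site.variant.gene
            assert trace.rare_pass, site.variant.gene
            assert trace.deleterious_pass, site.variant.gene
            assert trace.final_pass

    def test_final_pass_is_stage_order_free(self, fixture_pipeline_inputs):
        # conjunction of independent predicates: permuting evaluation order
        # of the stage flags cannot change the outcome
        table, annotations, _ = fixture_pipeline_inputs
        site = next(iter(annotations.values()))
        trace = apply_filters(site.variant, site.frequency, site.prediction, site.brain)
        flags = [trace.functional_pass, trace.brain_pass, trace.rare_pass, trace.deleterious_pass]
        for perm in itertools.permutations(flags):
            assert all(perm) == trace.final_pass


class TestCohortDriver:
    def test_fixture_cohort_summary_counts(self, fixture_pipeline_inputs):
        table, annotations, pedigrees = fixture_pipeline_inputs
        results, summary, rejects = prioritize_cohort(table, annotations, pedigrees)
        assert summary.as_dict() == {
            "n_unique_variants": 32,
            "n_unique_genes": 31,
            "n_de_novo": 2,
            "n_inherited": 30,
            "n_families_with_hits": 13,
            "n_families_analyzed": 15,
        }
        assert rejects == []

    def test_empty_cohort_gives_zero_summary(self, fixture_pipeline_inputs):
        _, _, pedigrees = fixture_pipeline_inputs
        summary = summarize([], n_families_analyzed=len([p for p in pedigrees if p.passed_qc]))
        assert summary.n_unique_variants == 0
        assert summary.n_de_novo == 0
        assert summary.n_families_with_hits == 0

    def test_unjoinable_variants_are_reported_not_silently_dropped(
        self, fixture_pipeline_inputs
    ):
        table, annotations, pedigrees = fixture_pipeline_inputs
        partial = dict(list(annotations.items())[:-1])
        _, summary, rejects = prioritize_cohort(table, partial, pedigrees)
        assert len(rejects) == 1
        assert summary.n_unique_variants == 31

    def test_planted_cohort_recovers_exactly_the_designed_passes(self):
        cohort = simulate_cohort(SimulationConfig(seed=5, n_sites=100))
        results, summary, _ = prioritize_cohort(
            cohort.table, cohort.annotations, cohort.pedigrees
        )
        truth = cohort.truth[cohort.truth.kind == "variant"]
        want = {
            (r.family, r.chrom, r.pos) for r in truth.itertuples() if r.expected_pass
        }
        got = {(r.family_id, r.variant.chrom, r.variant.pos) for r in results}
        assert got == want

    def test_de_novo_count_matches_trio_labels(self, fixture_pipeline_inputs):
        from triovar.inheritance import Mode

        table, annotations, pedigrees = fixture_pipeline_inputs
        results, summary, _ = prioritize_cohort(table, annotations, pedigrees)
        n_dn = sum(1 for r in results if r.inheritance.mode == Mode.DE_NOVO)
        assert n_dn == summary.n_de_novo


class TestConfig:
    def test_bad_maf_threshold_rejected(self):
        with pytest.raises(ValueError):
            PrioritizeConfig(maf_threshold=0.0)
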