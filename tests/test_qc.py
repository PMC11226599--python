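"""Site hard filters, genotype masking, re-qualification, and the
vectorised cohort pipeline's agreement with the scalar operations."""

import numpy as np
import pytest

from varlens.qc import (
    GenotypeCall,
    SiteQCAnnotations,
    apply_site_hard_filters,
    drop_multiallelic_subject_sites,
    filter_low_coverage_samples,
    mask_genotype_call,
    requalify_site,
    run_qc,
)
from varlens.synthetic import SimulationConfig, simulate_ecosystem


def _site(**kw):
    base = dict(qd=20.0, qual=100.0, fs=1.0, mq=59.0, mq_rank_sum=0.0, read_pos_rank_sum=0.0)
    base.update(kw)
    return SiteQCAnnotations(**base)


def _call(gt="het", ad_ref=10, ad_alt=10, dp=20, gq=60, sample="s1"):
    return GenotypeCall(sample_id=sample, gt=gt, ad_ref=ad_ref, ad_alt=ad_alt, dp=dp, gq=gq)


class TestHardFilters:
    def test_low_qd_fails_alone(self):
        ok, failed = apply_site_hard_filters(_site(qd=4.0))
        assert not ok and failed == ["QD"]

    def test_boundaries_pass_with_strict_operators(self):
        site = _site(qd=5.0, qual=30.0, fs=15.0, mq=50.0, mq_rank_sum=-12.5, read_pos_rank_sum=-8.0)
        ok, failed = apply_site_hard_filters(site)
        assert ok and failed == []

    def test_multiple_rules_all_listed(self):
        ok, failed = apply_site_hard_filters(_site(fs=20.0, mq=40.0))
        assert not ok and set(failed) == {"FS", "MQ"}

    def test_missing_core_annotation_fails_conservatively(self):
        ok, failed = apply_site_hard_filters(_site(qd=float("nan")))
        assert not ok and "missing-annotation" in failed

    def test_missing_rank_sums_are_tolerated(self):
        ok, _ = apply_site_hard_filters(_site(mq_rank_sum=None, read_pos_rank_sum=float("nan")))
        assert ok


class TestGenotypeMasking:
    def test_high_ab_het_masked(self):
        out = mask_genotype_call(_call(ad_ref=1, ad_alt=9, dp=10, gq=30))
        assert out.masked and out.mask_reason == "allelic-imbalance"

    def test_all_boundaries_kept(self):
        out = mask_genotype_call(_call(ad_ref=2, ad_alt=8, dp=10, gq=20))
        assert not out.masked  # AB=0.8, DP=10, GQ=20 all at strict boundaries

    def test_low_dp_masks_hom_calls_too(self):
        out = mask_genotype_call(_call(gt="hom-alt", ad_ref=0, ad_alt=9, dp=9, gq=99))
        assert out.masked and out.mask_reason == "low-dp"

    def test_zero_ad_het_is_extreme_imbalance(self):
        out = mask_genotype_call(_call(ad_ref=0, ad_alt=0, dp=30, gq=60))
        assert out.masked and out.mask_reason == "allelic-imbalance"

    def test_reason_priority_order(self):
        # a no-call beats everything; low-dp beats low-gq beats imbalance
        out = mask_genotype_call(_call(gt="missing", dp=1, gq=1))
        assert out.mask_reason == "no-call"
        out = mask_genotype_call(_call(ad_ref=0, ad_alt=9, dp=9, gq=1))
        assert out.mask_reason == "low-dp"
        out = mask_genotype_call(_call(ad_ref=0, ad_alt=20, dp=20, gq=10))
        assert out.mask_reason == "low-gq"

    def test_hom_calls_never_masked_for_imbalance(self):
        out = mask_genotype_call(_call(gt="hom-ref", ad_ref=1, ad_alt=19, dp=20, gq=60))
        assert not out.masked


class TestRequalification:
    def test_dimorphic_kept(self):
        calls = [_call(gt="hom-ref"), _call(gt="hom-ref"), _call(gt="het")]
        assert requalify_site(calls) == (True, None)

    def test_alt_fixed_dropped(self):
        calls = [_call(gt="hom-alt"), _call(gt="hom-alt")]
        keep, reason = requalify_site(calls)
        assert not keep and reason == "monomorphic"

    def test_all_masked_dropped_as_no_data(self):
        masked = [mask_genotype_call(_call(gt="missing")) for _ in range(3)]
        keep, reason = requalify_site(masked)
        assert not keep and reason == "no-data"


class TestMultiallelicSubject:
    def test_single_subject_three_alleles_drops_site(self):
        drop, offenders = drop_multiallelic_subject_sites({"s1": ["A", "G", "T"], "s2": ["A", "A"]})
        assert drop and offenders == ["s1"]

    def test_all_biallelic_kept(self):
        drop, _ = drop_multiallelic_subject_sites({"s1": ["A", "G"], "s2": ["G", "G"]})
        assert not drop

    def test_rule_is_per_subject_not_site_wide(self):
        drop, _ = drop_multiallelic_subject_sites({"s1": ["A", "G"], "s2": ["A", "T"]})
        assert not drop


class TestSampleCoverage:
    def test_boundary_and_below(self):
        retained = filter_low_coverage_samples({"a": 9.9, "b": 10.0, "c": 70.0})
        assert retained == ["b", "c"]

    def test_identity_when_all_covered(self):
        depths = {"a": 30.0, "b": 12.0}
        assert filter_low_coverage_samples(depths) == list(depths)


class TestCohortPipeline:
    def test_idempotence(self, small_ecosystem):
        first = run_qc(small_ecosystem.cohort)
        second = run_qc(first.cohort)
        assert second.report.sites_in == second.report.sites_out
        assert np.array_equal(first.cohort.gt, second.cohort.gt)
        assert first.cohort.sites[["chrom", "pos"]].equals(second.cohort.sites[["chrom", "pos"]])

    def test_report_sum_consistency(self, small_ecosystem):
        res = run_qc(small_ecosystem.cohort)
        res.report.validate()
        assert res.report.sites_in == small_ecosystem.cohort.n_sites

    def test_artifact_monotonicity(self, small_ecosystem):
        """Corrupting one extra call never decreases the masked count."""
        base = run_qc(small_ecosystem.clean_cohort)
        n_masked_before = sum(base.report.genotypes_masked_by_reason.values())
        worse = small_ecosystem.clean_cohort.copy()
        worse.gq[0, 0] = 5
        res = run_qc(worse)
        assert sum(res.report.genotypes_masked_by_reason.values()) >= n_masked_before + 1

    def test_vectorised_masking_matches_scalar_op(self, small_ecosystem):
        cohort = small_ecosystem.cohort
        res = run_qc(cohort)
        masked_lookup = {(c, p, s): r for c, p, s, r in res.masked_calls}
        gt_names = {-1: "missing", 0: "hom-ref", 1: "het", 2: "hom-alt"}
        rng = np.random.default_rng(0)
        rows = rng.integers(0, cohort.n_sites, 300)
        cols = rng.integers(0, cohort.n_samples, 300)
        site_ok = {}
        for row, col in zip(rows, cols):
            site = cohort.sites.iloc[row]
            key = (str(site["chrom"]), int(site["pos"]))
            if key not in site_ok:
                ok, _ = apply_site_hard_filters(
                    SiteQCAnnotations(
                        qd=site["qd"], qual=site["qual"], fs=site["fs"], mq=site["mq"],
                        mq_rank_sum=site["mq_rank_sum"], read_pos_rank_sum=site["read_pos_rank_sum"],
                    )
                )
                site_ok[key] = ok and row not in cohort.extra_alleles
            if not site_ok[key]:
                continue  # site dropped before masking in the pipeline
            call = mask_genotype_call(
                GenotypeCall(
                    sample_id=cohort.samples[col],
                    gt=gt_names[int(cohort.gt[row, col])],
                    ad_ref=int(cohort.ad_ref[row, col]),
                    ad_alt=int(cohort.ad_alt[row, col]),
                    dp=int(cohort.dp[row, col]),
                    gq=float(cohort.gq[row, col]),
                )
            )
            pipeline_reason = masked_lookup.get((key[0], key[1], cohort.samples[col]))
            if call.masked and call.gt != "missing":
                assert pipeline_reason == call.mask_reason
            else:
                assert pipeline_reason is None

    def test_artifact_free_cohort_loses_no_sites(self):
        config = SimulationConfig(
            n_individuals=40, n_colonies=4, n_genes=4, mean_cds_length_codons=100,
            artifact_low_gq_fraction=0.0, artifact_low_dp_fraction=0.0,
            artifact_ab_fraction=0.0, artifact_site_rule_fraction=0.0,
            artifact_third_allele_fraction=0.0, seed=9,
        )
        eco = simulate_ecosystem(config)
        res = run_qc(eco.cohort)
        assert res.report.sites_out == res.report.sites_in
        assert sum(res.report.genotypes_masked_by_reason.values()) == 0
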