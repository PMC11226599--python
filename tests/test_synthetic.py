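"""Generator contracts: determinism, spectrum recovery, artifact
bookkeeping, label/feature construction and configuration validation."""

import filecmp

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

from varlens.selection import pairwise_dnds
from varlens.synthetic import (
    ConfigurationError,
    SimulationConfig,
    generate_gene_panel,
    inject_qc_artifacts,
    simulate_cohort_genotypes,
    simulate_curated_db,
    simulate_ecosystem,
    simulate_training_matrix,
)


def _cfg(**kw):
    base = dict(n_individuals=60, n_colonies=4, n_genes=6, mean_cds_length_codons=100, seed=1)
    base.update(kw)
    return SimulationConfig(**base)


class TestConfigValidation:
    def test_zero_genes_rejected(self):
        with pytest.raises(ConfigurationError, match="zero genes"):
            _cfg(n_genes=0)

    def test_bad_af_law_rejected(self):
        with pytest.raises(ConfigurationError):
            _cfg(benign_af_law=("fixed", {"af": 1.5}))
        with pytest.raises(ConfigurationError):
            _cfg(benign_af_law=("lognormal", {}))

    def test_artifact_fractions_must_not_exceed_one(self):
        with pytest.raises(ConfigurationError):
            _cfg(artifact_low_gq_fraction=0.5, artifact_low_dp_fraction=0.4, artifact_ab_fraction=0.2)

    def test_multiplier_below_one_rejected(self):
        with pytest.raises(ConfigurationError):
            _cfg(cpg_mutation_multiplier=0.5)


class TestDeterminism:
    def test_byte_identical_outputs(self, tmp_path):
        cfg = _cfg(seed=5)
        simulate_ecosystem(cfg, outdir=tmp_path / "a")
        simulate_ecosystem(cfg, outdir=tmp_path / "b")
        for name in [
            "panel.fa",
            "orthology.tsv",
            "annotations.tsv",
            "curated.tsv",
            "features.tsv",
            "human_af.tsv",
            "cohort.vcf",
            "cohort.clean.vcf",
            "artifacts.json",
            "truth.json",
        ]:
            assert filecmp.cmp(tmp_path / "a" / name, tmp_path / "b" / name, shallow=False), name


class TestGenePanel:
    def test_zero_divergence_yields_identical_sequences(self):
        cfg = _cfg(n_genes=1, mean_cds_length_codons=2, divergence_per_site=0.0)
        panel = generate_gene_panel(cfg)
        gene = panel.genes[0]
        assert gene.seq_a == gene.seq_b
        frame = panel.orthology_frame()
        offsets = frame["dst_pos"] - frame["src_pos"] if not gene.strand_flip else None
        if offsets is not None:
            assert offsets.nunique() == 1  # constant-offset identity map

    def test_relaxed_regime_diverges_more_nonsynonymously(self):
        cfg = SimulationConfig(
            n_individuals=8, n_colonies=4, n_genes=80, nd_gene_fraction=0.5,
            mean_cds_length_codons=200, seed=3,
        )
        panel = generate_gene_panel(cfg)
        by_regime = {"strong-purifying": [], "relaxed": []}
        for gene in panel.genes:
            stats = pairwise_dnds(gene.alignment())
            if stats.dnds is not None:
                by_regime[gene.regime].append(stats.dnds)
        assert np.mean(by_regime["relaxed"]) > np.mean(by_regime["strong-purifying"])

    def test_sequences_are_in_frame_and_stop_free(self, small_ecosystem):
        for gene in small_ecosystem.panel.genes:
            aln = gene.alignment()  # validates frame/stop invariants
            assert len(aln.seq_a) % 3 == 0


class TestCohortGenotypes:
    def test_deleterious_af_never_exceeds_ceiling(self, small_ecosystem):
        eco = small_ecosystem
        afs = eco.macaque_afs()
        for key, cls in eco.truth.variant_class.items():
            if cls == "deleterious":
                assert afs[key] <= eco.config.deleterious_af_ceiling + 1e-12

    def test_singleton_fraction_recovered(self):
        cfg = SimulationConfig(
            n_individuals=150, n_colonies=8, n_genes=40, mean_cds_length_codons=300, seed=8
        )
        panel = generate_gene_panel(cfg)
        sim = simulate_cohort_genotypes(cfg, panel)
        gt = sim.cohort.gt
        assert gt.shape[0] >= 2000
        ac = np.where(gt > 0, gt, 0).sum(axis=1)
        singleton = float(np.mean(ac == 1))
        assert abs(singleton - cfg.singleton_target_fraction) <= 0.05

    def test_cpg_enrichment_matches_configured_multiplier(self):
        cfg = SimulationConfig(
            n_individuals=60, n_colonies=4, n_genes=40, mean_cds_length_codons=300, seed=8
        )
        panel = generate_gene_panel(cfg)
        sim = simulate_cohort_genotypes(cfg, panel)
        coding = sim.annotations[sim.annotations["region"] == "coding"]
        f = panel.cpg_base_fraction()
        lam = cfg.cpg_mutation_multiplier
        expected_fold = lam / (1 + f * (lam - 1))
        realized_fold = coding["cpg"].mean() / f
        assert abs(realized_fold - expected_fold) <= 0.5

    def test_forced_fixation_single_individual(self):
        cfg = SimulationConfig(
            n_individuals=1, n_colonies=1, n_genes=1, mean_cds_length_codons=30,
            benign_af_law=("fixed", {"af": 1.0}), missense_deleterious_fraction=0.0,
            artifact_low_gq_fraction=0.0, artifact_low_dp_fraction=0.0,
            artifact_ab_fraction=0.0, artifact_site_rule_fraction=0.0,
            artifact_third_allele_fraction=0.0, seed=2,
        )
        panel = generate_gene_panel(cfg)
        sim = simulate_cohort_genotypes(cfg, panel)
        assert sim.cohort.n_sites >= 1
        # every variant not subject to the deleterious AF ceiling fixes as 1/1
        keys = sim.cohort.variant_keys()
        uncapped = np.array(
            [sim.truth.variant_class[k] != "deleterious" for k in keys]
        )
        assert uncapped.any()
        assert (sim.cohort.gt[uncapped] == 2).all()

    def test_truth_covers_every_variant_exactly_once(self, small_ecosystem):
        eco = small_ecosystem
        keys = eco.cohort.variant_keys()
        assert len(keys) == len(set(keys))
        assert set(keys) == set(eco.truth.variant_class)
        assert set(eco.truth.variant_class.values()) <= {
            "benign", "deleterious", "neutral-noncoding"
        }

    def test_hardy_weinberg_het_excess_absent(self):
        """With exact allele placement, realised het counts sit near the
        conditional Hardy-Weinberg expectation 2*ac*(an-ac)/(an*(an-1))/2."""
        cfg = SimulationConfig(
            n_individuals=200, n_colonies=1, n_genes=20, mean_cds_length_codons=200,
            between_colony_fst=0.0, seed=4,
        )
        sim = simulate_cohort_genotypes(cfg, generate_gene_panel(cfg))
        gt = sim.cohort.gt
        an = 2 * gt.shape[1]
        ac = np.where(gt > 0, gt, 0).sum(axis=1)
        het = (gt == 1).sum(axis=1)
        common = ac >= 20
        expected = ac[common] * (an - ac[common]) / (an - 1)
        assert np.mean(het[common]) == pytest.approx(np.mean(expected), rel=0.05)


class TestArtifacts:
    def test_zero_fraction_is_identity(self):
        cfg = _cfg(
            artifact_low_gq_fraction=0.0, artifact_low_dp_fraction=0.0,
            artifact_ab_fraction=0.0, artifact_site_rule_fraction=0.0,
            artifact_third_allele_fraction=0.0,
        )
        sim = simulate_cohort_genotypes(cfg, generate_gene_panel(cfg))
        corrupted, ledger = inject_qc_artifacts(sim.cohort, cfg)
        assert ledger.n_total == 0
        assert np.array_equal(corrupted.gt, sim.cohort.gt)
        assert np.array_equal(corrupted.dp, sim.cohort.dp)
        assert np.array_equal(corrupted.gq, sim.cohort.gq)
        assert corrupted.sites.equals(sim.cohort.sites)

    def test_ab_artifacts_are_strictly_imbalanced(self, small_ecosystem):
        eco = small_ecosystem
        keyed = {
            (a["chrom"], a["pos"], a["sample"]): a["kind"] for a in eco.ledger.call_artifacts
        }
        idx = {s: i for i, s in enumerate(eco.cohort.samples)}
        rows = {
            (str(c), int(p)): r
            for r, (c, p) in enumerate(zip(eco.cohort.sites["chrom"], eco.cohort.sites["pos"]))
        }
        checked = 0
        for (chrom, pos, sample), kind in keyed.items():
            if kind != "allelic-imbalance":
                continue
            r, c = rows[(chrom, pos)], idx[sample]
            ab = eco.cohort.ad_alt[r, c] / (eco.cohort.ad_ref[r, c] + eco.cohort.ad_alt[r, c])
            assert ab > 0.8 or ab < 0.2
            checked += 1
        assert checked > 0

    def test_ledger_count_equals_call_diff(self, small_ecosystem):
        eco = small_ecosystem
        clean, bad = eco.clean_cohort, eco.cohort
        changed_calls = int(
            np.sum(
                (clean.dp != bad.dp) | (clean.gq != bad.gq)
                | (clean.ad_ref != bad.ad_ref) | (clean.ad_alt != bad.ad_alt)
            )
        )
        site_cols = ["qd", "qual", "fs", "mq"]
        changed_sites = int(
            (clean.sites[site_cols].to_numpy() != bad.sites[site_cols].to_numpy()).any(axis=1).sum()
        )
        assert changed_calls == len(eco.ledger.call_artifacts)
        assert changed_sites == len(eco.ledger.site_artifacts)
        assert len(bad.extra_alleles) == len(eco.ledger.multiallelic_sites)


class TestCuratedDB:
    def test_zero_mislabel_rate_labels_faithfully(self, small_ecosystem):
        """Without mislabelling, every labelled true-deleterious variant
        carries a deleterious string, and a harmonised-deleterious
        verdict can only arise from a true-deleterious variant (benign
        conflicts win under the harmonisation rules, so the converse
        does not hold for conflicted rows)."""
        eco = small_ecosystem
        assert eco.config.mislabel_rate == 0.0
        from varlens.classify import (
            CLINVAR_PATHOGENIC,
            HGMD_DELETERIOUS,
            SWISSVAR_DELETERIOUS,
            harmonize_frame,
        )

        def has_deleterious_string(row):
            return (
                row.hgmd in HGMD_DELETERIOUS
                or row.clinvar in CLINVAR_PATHOGENIC
                or row.swissvar in SWISSVAR_DELETERIOUS
            )

        verdicts = harmonize_frame(eco.curated)
        n_checked = 0
        for row, verdict in zip(eco.curated.itertuples(index=False), verdicts):
            truth = eco.truth.variant_class[row.variant_key]
            if truth == "deleterious" and (row.hgmd or row.clinvar or row.swissvar):
                if row.clinvar not in ("Uncertain_significance",
                                       "Conflicting_interpretations_of_pathogenicity"):
                    assert has_deleterious_string(row), row
                    n_checked += 1
            if verdict == "deleterious":
                assert truth == "deleterious"
        assert n_checked > 0

    def test_conflict_rate_binomial(self):
        cfg = SimulationConfig(
            n_individuals=100, n_colonies=4, n_genes=30, mean_cds_length_codons=200,
            label_fraction=1.0, conflict_rate=0.1, vus_label_fraction=0.0, seed=6,
        )
        sim = simulate_cohort_genotypes(cfg, generate_gene_panel(cfg))
        curated = simulate_curated_db(sim.truth, cfg, sim.annotations)
        labelled = curated[(curated[["hgmd", "clinvar", "swissvar"]] != "").any(axis=1)]
        n_sources = (labelled[["hgmd", "clinvar", "swissvar"]] != "").sum(axis=1)
        n_conflicts = int((n_sources >= 2).sum())
        n = len(labelled)
        expected = 0.1 * n
        assert abs(n_conflicts - expected) <= 4 * np.sqrt(expected)

    def test_unlabelled_variants_have_empty_fields(self, small_ecosystem):
        curated = small_ecosystem.curated
        unlabelled = curated[(curated[["hgmd", "clinvar", "swissvar"]] == "").all(axis=1)]
        assert len(unlabelled) > 0


class TestFeatureScores:
    def test_zero_effect_feature_has_null_auc(self):
        cfg = _cfg(feature_effect_sizes=tuple([0.0] + [1.0] * 10), feature_missing_rate=0.0)
        frame = simulate_training_matrix(cfg, n_pathogenic=1500, n_benign=1500, seed=2)
        y = (frame["label"] == "pathogenic").astype(int)
        auc = roc_auc_score(y, frame["cadd_phred"])
        assert abs(auc - 0.5) <= 0.03

    def test_zero_missing_rate_leaves_no_gaps(self):
        cfg = _cfg(feature_missing_rate=0.0)
        eco = simulate_ecosystem(cfg)
        score_cols = [c for c in eco.features.columns if c not in ("variant_key", "human_af")]
        assert not eco.features[score_cols].isna().any().any()

    def test_feature_rows_are_dual_matched_missense(self, small_ecosystem):
        eco = small_ecosystem
        ann = eco.annotations.set_index("variant_key")
        for key in eco.features["variant_key"]:
            assert ann.at[key, "csq_macaque"] == "missense"
            assert bool(ann.at[key, "dual_aa_match"])
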