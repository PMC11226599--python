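"""End-to-end study experiments at desk scale.

Each function runs one slice of the pipeline on freshly generated
synthetic inputs (or on printed worked-example inputs) and returns the
measured quantities.  Problem sizes are scaled-down study conditions;
see docs/methods.md for the rationale behind each size.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import classify as _classify
from . import hmscore as _hm
from . import popgen as _popgen
from . import qc as _qc
from . import selection as _selection
from .synthetic import (
    SimulationConfig,
    generate_gene_panel,
    simulate_cohort_genotypes,
    simulate_ecosystem,
    simulate_training_matrix,
    stage_rng,
)


def _derived_seed(seed: int, stage: str) -> int:
    return int(stage_rng(seed, stage).integers(0, 2**31 - 1))


# ---------------------------------------------------------------------------
# worked-example arithmetic from printed inputs
# ---------------------------------------------------------------------------


def worked_examples() -> dict[str, float]:
    """Recompute the printed worked examples from their printed inputs.

    * CpG enrichment: 33.1% of 46,444 autosomal SNVs at CpG-context
      bases versus an 8.9% CpG base share of the target.
    * Homozygote frequencies: 66/1179, 280/1843 and 256/1837 carriers.
    * NMD-candidate loss-of-function count: 19 early stop-gains plus 24
      non-final-intron splice variants out of 29 + 26 LoF variants.
    """
    n_total = 46_444
    k = round(0.331 * n_total)
    enrich = _popgen.cpg_enrichment_test(k, n_total, 0.089)

    hf = {
        "hf_intronic_modifier": _popgen.round_half_up(
            _popgen.homozygote_frequency(66, 1179), 2
        ),
        "hf_missense_common": _popgen.round_half_up(
            _popgen.homozygote_frequency(280, 1843), 2
        ),
        "hf_missense_rare_human": _popgen.round_half_up(
            _popgen.homozygote_frequency(256, 1837), 2
        ),
    }

    tx = _classify.TranscriptModel(gene="L1", exon_cds_lengths=(300, 300, 300, 120))
    flags = []
    # 29 stop-gains: 19 well upstream of the last junction, 10 escaping
    for i in range(19):
        flags.append(_classify.flag_lof_nmd("stop_gain", tx, stop_cds_pos=30 + 30 * i))
    for i in range(10):
        flags.append(_classify.flag_lof_nmd("stop_gain", tx, stop_cds_pos=860 + 6 * i))
    # 26 splice-site variants: 24 at internal introns, 2 at the final one
    for i in range(24):
        flags.append(_classify.flag_lof_nmd("splice", tx, splice_junction_index=i % 2))
    for _ in range(2):
        flags.append(_classify.flag_lof_nmd("splice", tx, splice_junction_index=tx.n_exons - 2))
    n_nmd = sum(f == "nmd-likely" for f in flags)

    return {
        "cpg_fold_enrichment": enrich.fold_display,
        "cpg_log10_pvalue": enrich.log10_pvalue,
        **hf,
        "lof_nmd_candidates": float(n_nmd),
    }


# ---------------------------------------------------------------------------
# cohort spectrum recovery
# ---------------------------------------------------------------------------


def cohort_spectrum_experiment(seed: int, n_individuals: int = 500, n_genes: int = 25,
                               codons: int = 300) -> dict[str, float]:
    """Generate a scaled cohort, run QC, and summarise the AF spectrum."""
    config = SimulationConfig(
        n_individuals=n_individuals,
        n_colonies=8,
        n_genes=n_genes,
        mean_cds_length_codons=codons,
        seed=_derived_seed(seed, "spectrum"),
    )
    eco = simulate_ecosystem(config)
    result = _qc.run_qc(eco.cohort)
    cohort = result.cohort
    records = [
        _popgen.compute_site_frequencies(cohort.gt[i]) for i in range(cohort.n_sites)
    ]
    pairs = list(zip(cohort.sites["ref"], cohort.sites["alt"]))
    summary = _popgen.spectrum_summary(records, pairs)
    coding = eco.annotations[eco.annotations["region"] == "coding"]
    f_cpg = eco.panel.cpg_base_fraction()
    enrich = _popgen.cpg_enrichment_test(
        int(coding["cpg"].sum()), int(len(coding)), f_cpg
    )
    return {
        "n_snvs_post_qc": float(summary.n_snvs),
        "singleton_fraction": summary.singleton_fraction,
        "fraction_af_le_half_percent": summary.fraction_af_le_half_percent,
        "tstv_ratio": summary.tstv if summary.tstv is not None else float("nan"),
        "realized_cpg_fold": enrich.fold,
        "realized_cpg_log10_p": enrich.log10_pvalue,
    }


# ---------------------------------------------------------------------------
# selection calibration
# ---------------------------------------------------------------------------


def neutral_calibration(seed: int, n_genes: int = 200, codons: int = 300) -> dict[str, float]:
    """Neutral panel: omega = 1, uniform mutation, no deleterious class.

    Median NG86 dN/dS should sit near 1, as should the median
    McDonald-Kreitman Neutrality Index.
    """
    config = SimulationConfig(
        n_individuals=60,
        n_colonies=4,
        n_genes=n_genes,
        mean_cds_length_codons=codons,
        omega_strong=1.0,
        omega_relaxed=1.0,
        divergence_per_site=0.08,
        cpg_mutation_multiplier=1.0,
        ts_prob_cpg=1 / 3,
        ts_prob_noncpg=1 / 3,
        missense_deleterious_fraction=0.0,
        snv_rate_per_base=0.10,
        seed=_derived_seed(seed, "neutral"),
    )
    panel = generate_gene_panel(config)
    sim = simulate_cohort_genotypes(config, panel)
    ann = sim.annotations
    dnds, nis = [], []
    for gene in panel.genes:
        stats = _selection.pairwise_dnds(gene.alignment())
        stats = _selection.attach_polymorphism(
            stats, ann.loc[ann["gene"] == gene.gene_id, "csq_macaque"]
        )
        if stats.dnds is not None:
            dnds.append(stats.dnds)
        if stats.ni is not None:
            nis.append(stats.ni)
    return {
        "neutral_median_dnds": float(np.median(dnds)),
        "neutral_median_ni": float(np.median(nis)),
        "n_neutral_genes": float(len(dnds)),
    }


def regime_separation(seed: int, genes_per_set: int = 30, codons: int = 300) -> dict[str, float]:
    """Strong-purifying vs relaxed gene sets, one-sided rank-sum test."""
    config = SimulationConfig(
        n_individuals=16,
        n_colonies=4,
        n_genes=2 * genes_per_set,
        nd_gene_fraction=0.5,
        mean_cds_length_codons=codons,
        seed=_derived_seed(seed, "regimes"),
    )
    panel = generate_gene_panel(config)
    values: dict[str, list[float]] = {"strong-purifying": [], "relaxed": []}
    for gene in panel.genes:
        stats = _selection.pairwise_dnds(gene.alignment())
        if stats.dnds is not None:
            values[gene.regime].append(stats.dnds)
    cmp = _selection.compare_gene_sets(
        values["strong-purifying"], values["relaxed"], alternative="less"
    )
    return {
        "dnds_median_strong_purifying": float(np.median(values["strong-purifying"])),
        "dnds_median_relaxed": float(np.median(values["relaxed"])),
        "regime_ranksum_p": cmp.pvalue,
    }


# ---------------------------------------------------------------------------
# QC ledger recovery
# ---------------------------------------------------------------------------


def qc_ledger_recovery(seed: int, n_individuals: int = 150, n_genes: int = 20,
                       codons: int = 200) -> dict[str, float]:
    """Inject artifacts strictly beyond the boundaries and measure the
    precision/recall of QC against the injection ledger."""
    config = SimulationConfig(
        n_individuals=n_individuals,
        n_colonies=8,
        n_genes=n_genes,
        mean_cds_length_codons=codons,
        seed=_derived_seed(seed, "qc-ledger"),
    )
    eco = simulate_ecosystem(config)
    result = _qc.run_qc(eco.cohort)

    ledger_calls = {
        (a["chrom"], a["pos"], a["sample"], a["kind"]) for a in eco.ledger.call_artifacts
    }
    qc_calls = set(result.masked_calls)
    ledger_sites = {(a["chrom"], a["pos"], a["rule"]) for a in eco.ledger.site_artifacts}
    qc_sites = {
        (chrom, pos, rule) for chrom, pos, rules in result.failed_sites for rule in rules
    }
    ledger_multi = {(a["chrom"], a["pos"]) for a in eco.ledger.multiallelic_sites}
    qc_multi = set(result.multiallelic_sites)

    flagged = qc_calls | qc_sites | qc_multi
    ledgered = ledger_calls | ledger_sites | ledger_multi
    tp = len(flagged & ledgered)
    precision = tp / len(flagged) if flagged else 1.0
    recall = tp / len(ledgered) if ledgered else 1.0
    return {
        "qc_artifact_precision": precision,
        "qc_artifact_recall": recall,
        "n_injected_artifacts": float(len(ledgered)),
    }


# ---------------------------------------------------------------------------
# benign-filter parameter recovery
# ---------------------------------------------------------------------------


def benign_filter_recovery(seed: int, n_individuals: int = 500, n_genes: int = 25,
                           codons: int = 300) -> dict[str, float]:
    """Derive the dual-species AF cutoffs from curated deleterious
    variants and verify no true-deleterious variant is flagged benign.

    With 500 diploid individuals the allele-count ceiling 0.038 is
    exactly representable (38/1000), so the derived macaque cutoff
    recovers the configured ceiling exactly.
    """
    config = SimulationConfig(
        n_individuals=n_individuals,
        n_colonies=8,
        n_genes=n_genes,
        mean_cds_length_codons=codons,
        seed=_derived_seed(seed, "benign-filter"),
    )
    eco = simulate_ecosystem(config)
    afs = eco.macaque_afs()
    shared_keys = [k for k, s in eco.truth.shared_with_human.items() if s]
    human_afs = dict(zip(shared_keys, eco.human_db["af"].tolist()))

    verdicts = _classify.harmonize_frame(eco.curated)
    deleterious_keys = [
        k for k, v in zip(eco.curated["variant_key"], verdicts) if v == "deleterious"
    ]
    cutoffs = _classify.derive_af_cutoffs(
        [afs[k] for k in deleterious_keys],
        [human_afs.get(k, 0.0) for k in deleterious_keys],
    )
    n_true_del_flagged = 0
    n_true_benign_flagged = 0
    for key, cls in eco.truth.variant_class.items():
        flagged = _classify.filter_putative_benign(
            afs.get(key), human_afs.get(key, 0.0), cutoffs
        )
        if flagged and cls == "deleterious":
            n_true_del_flagged += 1
        if flagged and cls == "benign":
            n_true_benign_flagged += 1
    return {
        "derived_macaque_af_cutoff": cutoffs.macaque_cutoff,
        "derived_human_af_cutoff": cutoffs.human_cutoff,
        "n_curated_deleterious": float(cutoffs.n_deleterious_used),
        "true_deleterious_flagged_benign": float(n_true_del_flagged),
        "true_benign_flagged_benign": float(n_true_benign_flagged),
    }


# ---------------------------------------------------------------------------
# integrative-score experiments
# ---------------------------------------------------------------------------


def _matrix_from_frame(frame: pd.DataFrame) -> _hm.FeatureMatrix:
    return _hm.FeatureMatrix(
        X=frame[_hm.FEATURE_COLUMNS].reset_index(drop=True),
        y=(frame["label"] == "pathogenic").astype(int).to_numpy(),
        keys=frame["variant_key"].tolist(),
    )


def _oriented_single_feature_aucs(matrix: _hm.FeatureMatrix) -> dict[str, float]:
    out = {}
    for col in _hm.FEATURE_COLUMNS:
        x = matrix.X[col].to_numpy(dtype=float)
        med = np.nanmedian(x)
        x = np.where(np.isnan(x), med, x)
        auc = _hm.auc_score(matrix.y, x)
        out[col] = max(auc, 1.0 - auc)  # orientation-free
    return out


def dominance_experiment(seed: int, n_train: int = 5000, n_test: int = 2000,
                         k: int = 5) -> dict[str, float]:
    """Train the leaderboard and compare the best combined model's
    held-out AUC with every single-feature AUC on an independent set."""
    config = SimulationConfig(n_individuals=16, seed=seed)
    n_path = int(round(n_train * 5079 / (5079 + 5757)))
    train = simulate_training_matrix(
        config, n_path, n_train - n_path, seed=_derived_seed(seed, "dom-train")
    )
    test = simulate_training_matrix(
        config, n_test // 2, n_test - n_test // 2, seed=_derived_seed(seed, "dom-test")
    )
    m_train, m_test = _matrix_from_frame(train), _matrix_from_frame(test)
    results = _hm.train_hm_model(m_train, k=k, seed=seed % (2**31))
    holdout = _hm.auc_score(m_test.y, results.score(m_test.X))
    singles = _oriented_single_feature_aucs(m_test)
    best_single = max(singles.values())
    return {
        "best_family_cv_auc": results.cv_auc,
        "holdout_auc": holdout,
        "max_single_feature_auc": best_single,
        "min_single_feature_auc": min(singles.values()),
        "dominates": float(holdout > best_single),
    }


def shuffled_label_auc(seed: int, n: int = 2000, k: int = 5) -> float:
    """Mean CV AUC after label shuffling (leakage guard; expect ~0.5)."""
    config = SimulationConfig(n_individuals=16, seed=seed)
    frame = simulate_training_matrix(config, n // 2, n - n // 2,
                                     seed=_derived_seed(seed, "shuffle"))
    matrix = _matrix_from_frame(frame)
    rng = np.random.default_rng(_derived_seed(seed, "shuffle-perm"))
    y = rng.permutation(matrix.y)
    _, mean = _hm.crossval_auc(matrix.X, y, "random_forest", k=k, seed=seed % (2**31))
    return float(mean)


def top_percentile_experiment(seed: int, n_train: int = 4000, n_cohort: int = 3000
                              ) -> dict[str, float]:
    """Score an unlabelled cohort-like matrix and take the top-1% cut."""
    config = SimulationConfig(n_individuals=16, seed=seed)
    train = simulate_training_matrix(
        config, n_train // 2, n_train - n_train // 2, seed=_derived_seed(seed, "thr-train")
    )
    # cohort-like mix: mostly benign-class feature profiles with a small
    # deleterious admixture, emulating post-filter cohort missense SNVs
    n_del = max(1, n_cohort // 50)
    cohort = simulate_training_matrix(
        config, n_del, n_cohort - n_del, seed=_derived_seed(seed, "thr-cohort")
    )
    results = _hm.train_hm_model(
        _matrix_from_frame(train),
        families=["random_forest", "naive_bayes", "logistic_regression"],
        k=5,
        seed=seed % (2**31),
    )
    scores = results.score(cohort[_hm.FEATURE_COLUMNS])
    threshold, flags = _hm.top_percentile_threshold(scores, 0.01)
    return {
        "hm_top1pct_threshold": float(threshold),
        "n_flagged_top1pct": float(flags.sum()),
        "n_scored": float(len(scores)),
    }
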