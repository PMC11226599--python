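"""Synthetic multi-colony cohort generator.

Produces a fully synthetic ecosystem for the downstream pipeline: a
two-species gene panel (codon-level divergence under per-gene selection
regimes), a multi-sample SNV cohort with a rare-variant-dominated
allele-frequency spectrum, CpG-biased mutation placement and
Hardy-Weinberg genotypes within colonies, injected genotype- and
site-level QC artifacts with a complete ledger, a curated-label table
drawn from the HGMD/ClinVar/SwissVar vocabularies, and class-conditional
in-silico feature scores for missense variants.

Determinism: one global integer seed; each stage derives its own
generator from a stable hash of (seed, stage name), so identical
configurations yield byte-identical outputs.

What the generator emulates, and what it does not, is documented in
docs/methods.md.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .classify import TranscriptModel
from .hmscore import FEATURE_COLUMNS
from .ortho import COMPLEMENT
from .selection import CODON_TO_AA, SENSE_CODONS, STOP_CODONS, CodonAlignment
from .vcfio import Cohort, variant_key, write_vcf

BASES = "ACGT"
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}

REGIMES = ("strong-purifying", "relaxed")
TRUE_CLASSES = ("benign", "deleterious", "neutral-noncoding")

_INTRON_LEN = 120


class ConfigurationError(ValueError):
    pass


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Deterministic per-stage generator derived from the global seed."""
    digest = hashlib.blake2b(f"{seed}:{stage}".encode(), digest_size=4).digest()
    return np.random.default_rng(int.from_bytes(digest, "big") % (2**31))


def _default_effect_sizes() -> tuple[float, ...]:
    # per-score separations chosen so single-feature AUCs span the
    # 0.71-0.95 range typical of established missense predictors
    from scipy.special import ndtri

    aucs = np.linspace(0.71, 0.95, 11)
    return tuple(float(math.sqrt(2.0) * ndtri(a)) for a in aucs)


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic ecosystem.

    Defaults describe a cohort of 1,845 diploid individuals from eight
    colonies sequenced over a 374-gene panel (a 286/88 split between
    retinal-disease and neurodevelopmental genes) at ~70x depth, with a
    singleton-heavy AF spectrum, five-fold elevated mutability at CpG
    dinucleotides, and curated-deleterious allele frequencies capped at
    0.038.
    """

    n_individuals: int = 1845
    n_colonies: int = 8
    n_genes: int = 374
    nd_gene_fraction: float = 88 / 374
    mean_cds_length_codons: int = 500
    # mutation / spectrum
    snv_rate_per_base: float = 0.085
    cpg_mutation_multiplier: float = 5.0
    ts_prob_cpg: float = 0.90
    ts_prob_noncpg: float = 0.67
    singleton_target_fraction: float = 0.26
    deleterious_af_ceiling: float = 0.038
    deleterious_human_af_ceiling: float = 5.1e-3
    # probability a shared deleterious variant's human AF sits exactly
    # at the ceiling (AFs are discrete AC/AN ratios, so the maximum is
    # an atom, as for the macaque allele-count cap)
    human_af_ceiling_atom: float = 0.35
    missense_deleterious_fraction: float = 0.15
    benign_af_law: tuple[str, dict] = field(
        default_factory=lambda: ("beta", {"a": 0.2, "b": 5.0})
    )
    # divergence / selection
    divergence_per_site: float = 0.06
    omega_strong: float = 0.10
    omega_relaxed: float = 0.40
    # population / cross-species structure
    between_colony_fst: float = 0.02
    unmapped_fraction: float = 0.005
    strand_flip_fraction: float = 0.2
    shared_polymorphism_fraction: float = 0.31
    mean_depth: float = 70.2
    # curated labels
    label_fraction: float = 0.30
    mislabel_rate: float = 0.0
    conflict_rate: float = 0.02
    vus_label_fraction: float = 0.30
    # feature scores
    feature_effect_sizes: tuple[float, ...] | None = None
    feature_missing_rate: float = 0.05
    feature_correlation: float = 0.6
    # QC artifact injection
    artifact_low_gq_fraction: float = 0.01
    artifact_low_dp_fraction: float = 0.01
    artifact_ab_fraction: float = 0.01
    artifact_site_rule_fraction: float = 0.004
    artifact_third_allele_fraction: float = 0.002
    seed: int = 0

    def __post_init__(self) -> None:
        if self.feature_effect_sizes is None:
            self.feature_effect_sizes = _default_effect_sizes()
        if len(self.feature_effect_sizes) != 11:
            raise ConfigurationError("feature_effect_sizes must carry 11 entries")
        if self.n_individuals < 1:
            raise ConfigurationError("need at least one individual")
        if self.n_genes < 1:
            raise ConfigurationError("degenerate configuration: zero genes")
        if self.mean_cds_length_codons < 2:
            raise ConfigurationError("mean CDS length must be >= 2 codons")
        if self.n_colonies < 1 or self.n_colonies > self.n_individuals:
            raise ConfigurationError("colony count must be in [1, n_individuals]")
        if self.cpg_mutation_multiplier < 1:
            raise ConfigurationError("cpg_mutation_multiplier must be >= 1")
        proportions = {
            "nd_gene_fraction": self.nd_gene_fraction,
            "singleton_target_fraction": self.singleton_target_fraction,
            "deleterious_af_ceiling": self.deleterious_af_ceiling,
            "deleterious_human_af_ceiling": self.deleterious_human_af_ceiling,
            "human_af_ceiling_atom": self.human_af_ceiling_atom,
            "missense_deleterious_fraction": self.missense_deleterious_fraction,
            "between_colony_fst": self.between_colony_fst,
            "unmapped_fraction": self.unmapped_fraction,
            "strand_flip_fraction": self.strand_flip_fraction,
            "shared_polymorphism_fraction": self.shared_polymorphism_fraction,
            "label_fraction": self.label_fraction,
            "mislabel_rate": self.mislabel_rate,
            "conflict_rate": self.conflict_rate,
            "vus_label_fraction": self.vus_label_fraction,
            "feature_missing_rate": self.feature_missing_rate,
            "feature_correlation": self.feature_correlation,
            "ts_prob_cpg": self.ts_prob_cpg,
            "ts_prob_noncpg": self.ts_prob_noncpg,
        }
        for name, value in proportions.items():
            if not 0.0 <= value <= 1.0:
                raise ConfigurationError(f"{name} must be a proportion, got {value}")
        call_total = (
            self.artifact_low_gq_fraction
            + self.artifact_low_dp_fraction
            + self.artifact_ab_fraction
        )
        if call_total > 1:
            raise ConfigurationError("call-artifact fractions sum above 1")
        site_total = 4 * self.artifact_site_rule_fraction + self.artifact_third_allele_fraction
        if site_total > 1:
            raise ConfigurationError("site-artifact fractions sum above 1")
        law, params = self.benign_af_law
        if law == "beta":
            if params.get("a", 0) <= 0 or params.get("b", 0) <= 0:
                raise ConfigurationError("beta AF law needs positive shape parameters")
        elif law == "fixed":
            af = params.get("af", 0)
            if not 0 < af <= 1:
                raise ConfigurationError("fixed AF law must lie in (0, 1]")
        else:
            raise ConfigurationError(f"unknown AF law {law!r}")


# ---------------------------------------------------------------------------
# gene panel
# ---------------------------------------------------------------------------


@dataclass
class Gene:
    gene_id: str
    panel_set: str  # IRD | ND
    regime: str
    omega: float
    chrom: str
    src_start: int
    dst_chrom: str
    dst_start: int
    strand_flip: bool
    exon_cds_lengths: tuple[int, ...]
    seq_a: str
    seq_b: str
    pos_of_cds: np.ndarray  # genomic position per CDS base (1-based)
    splice_positions: tuple[tuple[int, int, str], ...]  # (pos, junction, intron base)

    @property
    def n_codons(self) -> int:
        return len(self.seq_a) // 3

    def transcript_model(self) -> TranscriptModel:
        return TranscriptModel(gene=self.gene_id, exon_cds_lengths=self.exon_cds_lengths)

    def alignment(self) -> CodonAlignment:
        return CodonAlignment(gene_id=self.gene_id, seq_a=self.seq_a, seq_b=self.seq_b)

    def dst_pos_of_cds(self, cds_index: int) -> int:
        offset = int(self.pos_of_cds[cds_index]) - self.src_start
        if self.strand_flip:
            span = int(self.pos_of_cds[-1]) - self.src_start
            return self.dst_start + (span - offset)
        return self.dst_start + offset

    def cpg_context(self) -> np.ndarray:
        """CpG-context flags on the species-A coding sequence."""
        seq = self.seq_a
        n = len(seq)
        flags = np.zeros(n, dtype=bool)
        for i in range(n):
            if seq[i] == "C" and i + 1 < n and seq[i + 1] == "G":
                flags[i] = True
            elif seq[i] == "G" and i > 0 and seq[i - 1] == "C":
                flags[i] = True
        return flags


@dataclass
class GenePanel:
    genes: list[Gene]
    unmapped_positions: frozenset[tuple[str, int]]

    def gene_by_id(self) -> dict[str, Gene]:
        return {g.gene_id: g for g in self.genes}

    def cpg_base_fraction(self) -> float:
        total = cpg = 0
        for g in self.genes:
            flags = g.cpg_context()
            total += flags.size
            cpg += int(flags.sum())
        return cpg / total if total else 0.0

    def orthology_frame(self) -> pd.DataFrame:
        rows = []
        for g in self.genes:
            for i in range(len(g.seq_a)):
                src_pos = int(g.pos_of_cds[i])
                if (g.chrom, src_pos) in self.unmapped_positions:
                    continue
                base_b = g.seq_b[i]
                dst_ref = COMPLEMENT[base_b] if g.strand_flip else base_b
                rows.append(
                    {
                        "src_chrom": g.chrom,
                        "src_pos": src_pos,
                        "dst_chrom": g.dst_chrom,
                        "dst_pos": g.dst_pos_of_cds(i),
                        "dst_ref": dst_ref,
                        "strand": "-" if g.strand_flip else "+",
                    }
                )
        return pd.DataFrame(rows)

    def to_fasta(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            for g in self.genes:
                fh.write(f">{g.gene_id}|A\n{g.seq_a}\n>{g.gene_id}|B\n{g.seq_b}\n")
        return path

    def transcript_models(self) -> dict[str, TranscriptModel]:
        return {g.gene_id: g.transcript_model() for g in self.genes}


#: multiplicative penalty per CpG dinucleotide when sampling codons;
#: tuned so the panel's CpG base content sits near the ~9% typical of
#: CpG-depleted mammalian coding sequence
_CPG_DEPLETION = 0.60


def _codon_sampler() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Cumulative codon distributions given whether the previous codon
    ends in C (CpG-depleted Markov sampling at codon granularity)."""
    internal_cg = np.array([c.count("CG") for c in SENSE_CODONS], dtype=float)
    base_w = _CPG_DEPLETION**internal_cg
    after_c_w = base_w * np.where(
        np.array([c[0] == "G" for c in SENSE_CODONS]), _CPG_DEPLETION, 1.0
    )
    cum_base = np.cumsum(base_w / base_w.sum())
    cum_after_c = np.cumsum(after_c_w / after_c_w.sum())
    return cum_base, cum_after_c, internal_cg


_CUM_BASE, _CUM_AFTER_C, _ = _codon_sampler()


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    codons = ["ATG"]
    for _ in range(n_codons - 1):
        cum = _CUM_AFTER_C if codons[-1][-1] == "C" else _CUM_BASE
        codons.append(SENSE_CODONS[int(np.searchsorted(cum, rng.random()))])
    return "".join(codons)


def _evolve_codon(codon: str, div: float, omega: float, rng: np.random.Generator) -> str:
    """One divergence step per codon position.

    A proposal that would create a stop codon is redirected to another
    base (stop mutations are lethal and never fix), keeping the
    realised per-site substitution rate aligned with the NG86 site
    expectation; nonsynonymous proposals fix with probability omega.
    """
    cur = codon
    for i in range(3):
        if rng.random() >= div:
            continue
        choices = [b for b in BASES if b != cur[i]]
        rng.shuffle(choices)
        for base in choices:
            cand = cur[:i] + base + cur[i + 1 :]
            if cand in STOP_CODONS:
                continue
            if CODON_TO_AA[cand] == CODON_TO_AA[cur] or rng.random() < omega:
                cur = cand
            break
    return cur


def _split_exons(rng: np.random.Generator, cds_len: int) -> tuple[int, ...]:
    max_exons = max(1, min(8, cds_len // 9))
    n_exons = int(rng.integers(1, max_exons + 1)) if max_exons > 1 else 1
    if n_exons == 1:
        return (cds_len,)
    cuts = np.sort(rng.choice(np.arange(3, cds_len - 2), size=n_exons - 1, replace=False))
    lengths = np.diff(np.concatenate([[0], cuts, [cds_len]]))
    if (lengths < 3).any():  # merge tiny exons into their neighbour
        return (cds_len,)
    return tuple(int(x) for x in lengths)


def generate_gene_panel(config: SimulationConfig) -> GenePanel:
    """Two-species codon-level gene panel under per-gene selection regimes.

    Neurodevelopmental (ND) genes evolve under strong purifying
    selection (low omega) and retinal-disease (IRD) genes under a more
    relaxed regime; setting both omegas to 1 yields a neutral panel.
    """
    rng = stage_rng(config.seed, "gene-panel")
    n_nd = int(round(config.nd_gene_fraction * config.n_genes))
    genes: list[Gene] = []
    src_cursor: dict[str, int] = {}
    dst_cursor: dict[str, int] = {}
    for g_idx in range(config.n_genes):
        is_nd = g_idx < n_nd
        panel_set = "ND" if is_nd else "IRD"
        regime = "strong-purifying" if is_nd else "relaxed"
        omega = config.omega_strong if is_nd else config.omega_relaxed
        gene_id = f"{panel_set}{g_idx:04d}"
        n_codons = max(2, int(rng.poisson(config.mean_cds_length_codons)))
        seq_a = _random_cds(rng, n_codons)
        seq_b = "".join(
            _evolve_codon(seq_a[i : i + 3], config.divergence_per_site, omega, rng)
            for i in range(0, len(seq_a), 3)
        )
        exon_lengths = _split_exons(rng, len(seq_a))
        chrom = f"chr{(g_idx % 20) + 1}"
        dst_chrom = f"hchr{(g_idx % 20) + 1}"
        src_start = src_cursor.get(chrom, 1_000_000)
        dst_start = dst_cursor.get(dst_chrom, 2_000_000)
        strand_flip = bool(rng.random() < config.strand_flip_fraction)

        pos_of_cds = np.empty(len(seq_a), dtype=np.int64)
        splice: list[tuple[int, int, str]] = []
        cursor = src_start
        cds_i = 0
        for e_idx, e_len in enumerate(exon_lengths):
            if e_idx > 0:
                # acceptor side of the intron preceding this exon
                splice.append((cursor - 2, e_idx - 1, BASES[rng.integers(0, 4)]))
                splice.append((cursor - 1, e_idx - 1, BASES[rng.integers(0, 4)]))
            for _ in range(e_len):
                pos_of_cds[cds_i] = cursor
                cursor += 1
                cds_i += 1
            if e_idx < len(exon_lengths) - 1:
                splice.append((cursor, e_idx, BASES[rng.integers(0, 4)]))
                splice.append((cursor + 1, e_idx, BASES[rng.integers(0, 4)]))
                cursor += _INTRON_LEN
        span = cursor - src_start
        src_cursor[chrom] = src_start + span + 50_000
        dst_cursor[dst_chrom] = dst_start + span + 80_000
        genes.append(
            Gene(
                gene_id=gene_id,
                panel_set=panel_set,
                regime=regime,
                omega=omega,
                chrom=chrom,
                src_start=src_start,
                dst_chrom=dst_chrom,
                dst_start=dst_start,
                strand_flip=strand_flip,
                exon_cds_lengths=exon_lengths,
                seq_a=seq_a,
                seq_b=seq_b,
                pos_of_cds=pos_of_cds,
                splice_positions=tuple(splice),
            )
        )
    # a small fraction of coding bases has no orthologous position
    all_coding = [(g.chrom, int(p)) for g in genes for p in g.pos_of_cds]
    n_unmapped = int(round(config.unmapped_fraction * len(all_coding)))
    unmapped = frozenset(
        all_coding[i] for i in stage_rng(config.seed, "unmapped").choice(
            len(all_coding), size=n_unmapped, replace=False
        )
    ) if n_unmapped else frozenset()
    return GenePanel(genes=genes, unmapped_positions=unmapped)


# ---------------------------------------------------------------------------
# cohort genotypes
# ---------------------------------------------------------------------------


@dataclass
class SyntheticTruth:
    """Ground truth kept out of every emitted VCF/TSV column."""

    variant_class: dict[str, str]
    shared_with_human: dict[str, bool]
    regime_by_gene: dict[str, str]

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(
            json.dumps(
                {
                    "variant_class": self.variant_class,
                    "shared_with_human": self.shared_with_human,
                    "regime_by_gene": self.regime_by_gene,
                },
                indent=0,
            )
        )
        return path


@dataclass
class CohortSimulation:
    cohort: Cohort
    truth: SyntheticTruth
    annotations: pd.DataFrame
    human_db: pd.DataFrame


def _draw_allele_count(
    rng: np.random.Generator, an: int, config: SimulationConfig, deleterious: bool
) -> int:
    law, params = config.benign_af_law
    if law == "fixed":
        ac = max(1, int(round(params["af"] * an)))
    elif rng.random() < config.singleton_target_fraction:
        ac = 1
    else:
        q = rng.beta(params["a"], params["b"])
        ac = min(max(int(round(q * an)), 2), an)
    if deleterious:
        cap = max(1, int(math.floor(config.deleterious_af_ceiling * an)))
        ac = min(ac, cap)
    return ac


def _place_genotypes(
    rng: np.random.Generator,
    ac: int,
    colony_members: list[np.ndarray],
    fst: float,
) -> np.ndarray:
    """Distribute exactly ``ac`` alternate alleles over chromosomes.

    Colony weights follow a Dirichlet with concentration set by an
    Fst-like parameter; within a colony the copies land on distinct
    chromosomes chosen uniformly, which is Hardy-Weinberg sampling
    conditional on the colony allele count.
    """
    n_total = sum(len(m) for m in colony_members)
    genotypes = np.zeros(n_total, dtype=np.int8)
    caps = np.array([2 * len(m) for m in colony_members])
    shares = caps / caps.sum()
    if fst > 0 and len(colony_members) > 1:
        alpha = shares * (1.0 - fst) / fst
        weights = rng.dirichlet(alpha)
    else:
        weights = shares
    counts = rng.multinomial(ac, weights)
    # respect per-colony chromosome capacity
    excess = int(np.maximum(counts - caps, 0).sum())
    counts = np.minimum(counts, caps)
    while excess > 0:
        spare = caps - counts
        i = int(np.argmax(spare))
        take = min(excess, int(spare[i]))
        counts[i] += take
        excess -= take
    for members, k in zip(colony_members, counts):
        if k == 0:
            continue
        chrom_idx = rng.choice(2 * len(members), size=int(k), replace=False)
        np.add.at(genotypes, members[chrom_idx // 2], 1)
    return genotypes


def _codon_consequence(codon: str, pos_in_codon: int, alt: str) -> tuple[str, str, str]:
    """(kind, ref_aa, alt_aa) of substituting ``alt`` into a sense codon."""
    alt_codon = codon[:pos_in_codon] + alt + codon[pos_in_codon + 1 :]
    ref_aa = CODON_TO_AA[codon]
    alt_aa = "*" if alt_codon in STOP_CODONS else CODON_TO_AA[alt_codon]
    if alt_aa == "*":
        kind = "stop_gain"
    elif alt_aa == ref_aa:
        kind = "synonymous"
    else:
        kind = "missense"
    return kind, ref_aa, alt_aa


def _draw_alt(rng: np.random.Generator, ref: str, ts_prob: float) -> str:
    if rng.random() < ts_prob:
        return _TRANSITION[ref]
    transversions = [b for b in BASES if b != ref and b != _TRANSITION[ref]]
    return transversions[rng.integers(0, 2)]


def simulate_cohort_genotypes(
    config: SimulationConfig, panel: GenePanel
) -> CohortSimulation:
    """Simulate biallelic SNV genotypes over the panel.

    Variant sites arise with probability ``snv_rate_per_base``
    (multiplied at CpG-context positions), allele counts follow the
    configured AF law with true-deleterious variants capped at the
    deleterious AF ceiling, and genotypes are drawn under
    Hardy-Weinberg within colonies with exact cohort allele counts.
    """
    rng = stage_rng(config.seed, "cohort")
    n = config.n_individuals
    an = 2 * n
    samples = [f"S{i + 1:05d}" for i in range(n)]
    colony_names = [f"C{(i % config.n_colonies) + 1}" for i in range(n)]
    colonies = dict(zip(samples, colony_names))
    colony_members = [
        np.array([i for i in range(n) if i % config.n_colonies == c])
        for c in range(config.n_colonies)
    ]

    site_rows: list[dict] = []
    ann_rows: list[dict] = []
    human_rows: list[dict] = []
    gt_rows: list[np.ndarray] = []
    variant_class: dict[str, str] = {}
    shared_with: dict[str, bool] = {}

    for gene in panel.genes:
        cpg = gene.cpg_context()
        rate = np.where(
            cpg,
            min(config.snv_rate_per_base * config.cpg_mutation_multiplier, 0.98),
            config.snv_rate_per_base,
        )
        is_variant = rng.random(len(gene.seq_a)) < rate
        # coding variants
        for cds_i in np.flatnonzero(is_variant):
            cds_i = int(cds_i)
            ref = gene.seq_a[cds_i]
            ts_prob = config.ts_prob_cpg if cpg[cds_i] else config.ts_prob_noncpg
            alt = _draw_alt(rng, ref, ts_prob)
            codon_idx, pos_in = divmod(cds_i, 3)
            codon_a = gene.seq_a[3 * codon_idx : 3 * codon_idx + 3]
            kind_a, ref_aa_a, alt_aa_a = _codon_consequence(codon_a, pos_in, alt)
            pos = int(gene.pos_of_cds[cds_i])
            mapped = (gene.chrom, pos) not in panel.unmapped_positions
            base_b = gene.seq_b[cds_i]
            kind_b = ref_aa_b = alt_aa_b = None
            if mapped and alt != base_b:
                codon_b = gene.seq_b[3 * codon_idx : 3 * codon_idx + 3]
                if base_b == codon_b[pos_in]:
                    kind_b, ref_aa_b, alt_aa_b = _codon_consequence(codon_b, pos_in, alt)
            if kind_a == "stop_gain":
                true_class = "deleterious"
            elif kind_a == "missense":
                true_class = (
                    "deleterious"
                    if rng.random() < config.missense_deleterious_fraction
                    else "benign"
                )
            else:
                true_class = "benign"
            deleterious = true_class == "deleterious"
            ac = _draw_allele_count(rng, an, config, deleterious)
            gt = _place_genotypes(rng, ac, colony_members, config.between_colony_fst)
            key = variant_key(gene.chrom, pos, ref, alt)
            shared = bool(
                mapped
                and alt != base_b
                and rng.random() < config.shared_polymorphism_fraction
            )
            dual = (
                kind_a == kind_b
                and ref_aa_a == ref_aa_b
                and alt_aa_a == alt_aa_b
                and kind_b is not None
            )
            ann_rows.append(
                {
                    "variant_key": key,
                    "chrom": gene.chrom,
                    "pos": pos,
                    "ref": ref,
                    "alt": alt,
                    "gene": gene.gene_id,
                    "panel_set": gene.panel_set,
                    "region": "coding",
                    "cds_index": cds_i,
                    "protein_pos": codon_idx + 1,
                    "cpg": bool(cpg[cds_i]),
                    "csq_macaque": kind_a,
                    "aa_ref_macaque": ref_aa_a,
                    "aa_alt_macaque": alt_aa_a,
                    "csq_human": kind_b,
                    "aa_ref_human": ref_aa_b,
                    "aa_alt_human": alt_aa_b,
                    "dual_aa_match": dual,
                    "splice_junction": -1,
                }
            )
            variant_class[key] = true_class
            shared_with[key] = shared
            if shared:
                dst_pos = gene.dst_pos_of_cds(cds_i)
                dst_ref = COMPLEMENT[base_b] if gene.strand_flip else base_b
                dst_alt = COMPLEMENT[alt] if gene.strand_flip else alt
                if deleterious:
                    ceiling = config.deleterious_human_af_ceiling
                    if rng.random() < config.human_af_ceiling_atom:
                        af_h = float(ceiling)
                    else:
                        af_h = float(
                            10 ** rng.uniform(-6, math.log10(ceiling))
                        )
                        af_h = min(af_h, ceiling)
                else:
                    af_h = float(np.clip(rng.beta(0.3, 3.0), 1e-6, 0.999))
                human_rows.append(
                    {
                        "chrom": gene.dst_chrom,
                        "pos": dst_pos,
                        "ref": dst_ref,
                        "alt": dst_alt,
                        "af": af_h,
                    }
                )
            site_rows.append({"chrom": gene.chrom, "pos": pos, "ref": ref, "alt": alt})
            gt_rows.append(gt)
        # canonical splice-site variants (neutral-noncoding truth class)
        for pos, junction, intron_base in gene.splice_positions:
            if rng.random() >= config.snv_rate_per_base:
                continue
            alt = _draw_alt(rng, intron_base, config.ts_prob_noncpg)
            key = variant_key(gene.chrom, pos, intron_base, alt)
            ac = _draw_allele_count(rng, an, config, deleterious=False)
            gt = _place_genotypes(rng, ac, colony_members, config.between_colony_fst)
            ann_rows.append(
                {
                    "variant_key": key,
                    "chrom": gene.chrom,
                    "pos": pos,
                    "ref": intron_base,
                    "alt": alt,
                    "gene": gene.gene_id,
                    "panel_set": gene.panel_set,
                    "region": "splice",
                    "cds_index": -1,
                    "protein_pos": -1,
                    "cpg": False,
                    "csq_macaque": "splice",
                    "aa_ref_macaque": None,
                    "aa_alt_macaque": None,
                    "csq_human": None,
                    "aa_ref_human": None,
                    "aa_alt_human": None,
                    "dual_aa_match": False,
                    "splice_junction": junction,
                }
            )
            variant_class[key] = "neutral-noncoding"
            shared_with[key] = False
            site_rows.append({"chrom": gene.chrom, "pos": pos, "ref": intron_base, "alt": alt})
            gt_rows.append(gt)

    n_sites = len(site_rows)
    gt = np.vstack(gt_rows) if n_sites else np.zeros((0, n), dtype=np.int8)

    # clean per-call depths, allele depths and genotype qualities
    dp = np.maximum(rng.poisson(config.mean_depth, size=(n_sites, n)), 12).astype(np.int32)
    ad_alt = np.zeros_like(dp)
    het = gt == 1
    if het.any():
        raw = rng.binomial(dp[het], 0.5)
        lo = np.ceil(0.25 * dp[het]).astype(np.int64)
        hi = np.floor(0.75 * dp[het]).astype(np.int64)
        ad_alt[het] = np.clip(raw, lo, hi)
    ad_alt[gt == 2] = dp[gt == 2]
    ad_ref = dp - ad_alt
    ad_ref[gt == 2] = 0
    gq = rng.integers(30, 100, size=(n_sites, n)).astype(np.int32)

    sites = pd.DataFrame(site_rows)
    sites["qual"] = rng.uniform(60, 2000, n_sites)
    sites["qd"] = rng.uniform(10, 35, n_sites)
    sites["fs"] = rng.uniform(0, 6, n_sites)
    sites["mq"] = rng.uniform(55, 60, n_sites)
    ranksum_missing = rng.random(n_sites) < 0.2
    sites["mq_rank_sum"] = np.where(
        ranksum_missing, np.nan, np.clip(rng.normal(0, 1, n_sites), -6, 6)
    )
    sites["read_pos_rank_sum"] = np.where(
        ranksum_missing, np.nan, np.clip(rng.normal(0, 1, n_sites), -6, 6)
    )

    cohort = Cohort(
        samples=samples,
        sites=sites,
        gt=gt.astype(np.int8),
        ad_ref=ad_ref.astype(np.int32),
        ad_alt=ad_alt.astype(np.int32),
        dp=dp,
        gq=gq,
        colonies=colonies,
    )
    truth = SyntheticTruth(
        variant_class=variant_class,
        shared_with_human=shared_with,
        regime_by_gene={g.gene_id: g.regime for g in panel.genes},
    )
    return CohortSimulation(
        cohort=cohort,
        truth=truth,
        annotations=pd.DataFrame(ann_rows),
        human_db=pd.DataFrame(human_rows, columns=["chrom", "pos", "ref", "alt", "af"]),
    )


# ---------------------------------------------------------------------------
# QC artifact injection
# ---------------------------------------------------------------------------


@dataclass
class ArtifactLedger:
    """Complete record of every injected corruption."""

    call_artifacts: list[dict] = field(default_factory=list)
    site_artifacts: list[dict] = field(default_factory=list)
    multiallelic_sites: list[dict] = field(default_factory=list)

    @property
    def n_total(self) -> int:
        return len(self.call_artifacts) + len(self.site_artifacts) + len(self.multiallelic_sites)

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(asdict(self), indent=1))
        return path


_SITE_RULES = ("QD", "QUAL", "FS", "MQ")


def inject_qc_artifacts(
    cohort: Cohort, config: SimulationConfig
) -> tuple[Cohort, ArtifactLedger]:
    """Corrupt a clean cohort with call- and site-level QC artifacts.

    Every injected value lies strictly beyond its filtering boundary
    (GQ <= 19, DP <= 9, AB outside [0.2, 0.8], QD < 5, QUAL < 30,
    FS > 15, MQ < 50), and targets are chosen disjointly so each
    artifact maps to exactly one masking/dropping reason downstream.
    """
    rng = stage_rng(config.seed, "artifacts")
    out = cohort.copy()
    ledger = ArtifactLedger()
    n_sites, n_samples = out.n_sites, out.n_samples
    if n_sites == 0:
        return out, ledger
    chroms = out.sites["chrom"].to_numpy()
    poss = out.sites["pos"].to_numpy()

    site_pool = rng.permutation(n_sites)
    cursor = 0

    n_third = int(round(config.artifact_third_allele_fraction * n_sites))
    third_rows = site_pool[cursor : cursor + n_third]
    cursor += n_third
    rule_rows: dict[str, np.ndarray] = {}
    n_rule = int(round(config.artifact_site_rule_fraction * n_sites))
    for rule in _SITE_RULES:
        rule_rows[rule] = site_pool[cursor : cursor + n_rule]
        cursor += n_rule

    for row in third_rows:
        row = int(row)
        candidates = np.flatnonzero(out.gt[row] != -1)
        if candidates.size == 0:
            continue
        s_idx = int(rng.choice(candidates))
        ref, alt = out.sites.at[row, "ref"], out.sites.at[row, "alt"]
        alt2 = next(b for b in BASES if b not in (ref, alt))
        out.extra_alleles[row] = (s_idx, alt2)
        ledger.multiallelic_sites.append(
            {"chrom": str(chroms[row]), "pos": int(poss[row]), "sample": out.samples[s_idx]}
        )

    injectors = {
        "QD": ("qd", lambda: rng.uniform(0.2, 4.9)),
        "QUAL": ("qual", lambda: rng.uniform(1.0, 29.5)),
        "FS": ("fs", lambda: rng.uniform(15.5, 60.0)),
        "MQ": ("mq", lambda: rng.uniform(20.0, 49.5)),
    }
    for rule, rows in rule_rows.items():
        col, draw = injectors[rule]
        for row in rows:
            row = int(row)
            out.sites.at[row, col] = draw()
            ledger.site_artifacts.append(
                {"chrom": str(chroms[row]), "pos": int(poss[row]), "rule": rule}
            )

    # call artifacts only on sites untouched above, so the reason codes
    # recovered by QC match the ledger one-to-one
    touched = set(int(r) for r in third_rows) | {
        int(r) for rows in rule_rows.values() for r in rows
    }
    clean_rows = np.array([r for r in range(n_sites) if r not in touched], dtype=int)
    if clean_rows.size:
        sub_gt = out.gt[clean_rows]
        called = sub_gt != -1
        flat_called = np.flatnonzero(called.ravel())
        flat_het = np.flatnonzero((sub_gt == 1).ravel())
        n_calls = flat_called.size

        # AB corruption is a het-call phenomenon: the fraction applies
        # to heterozygous calls so the AF spectrum is not distorted
        n_ab = min(int(round(config.artifact_ab_fraction * flat_het.size)), flat_het.size)
        ab_targets = rng.choice(flat_het, size=n_ab, replace=False) if n_ab else np.array([], dtype=int)
        remaining = np.setdiff1d(flat_called, ab_targets, assume_unique=False)
        n_dp = int(round(config.artifact_low_dp_fraction * n_calls))
        n_gq = int(round(config.artifact_low_gq_fraction * n_calls))
        picked = (
            rng.choice(remaining, size=min(n_dp + n_gq, remaining.size), replace=False)
            if n_dp + n_gq
            else np.array([], dtype=int)
        )
        dp_targets, gq_targets = picked[:n_dp], picked[n_dp:]

        def _rc(flat_idx: int) -> tuple[int, int]:
            r, c = divmod(int(flat_idx), n_samples)
            return int(clean_rows[r]), c

        for idx in ab_targets:
            row, col = _rc(idx)
            total = int(out.dp[row, col])
            if rng.random() < 0.5:
                out.ad_alt[row, col] = total - 1  # AB > 0.9
                out.ad_ref[row, col] = 1
            else:
                out.ad_alt[row, col] = 1  # AB < 0.1 at DP >= 12
                out.ad_ref[row, col] = total - 1
            ledger.call_artifacts.append(
                {
                    "chrom": str(chroms[row]),
                    "pos": int(poss[row]),
                    "sample": out.samples[col],
                    "kind": "allelic-imbalance",
                }
            )
        for idx in dp_targets:
            row, col = _rc(idx)
            new_dp = int(rng.integers(2, 10))
            out.dp[row, col] = new_dp
            if out.gt[row, col] == 1:
                out.ad_alt[row, col] = new_dp // 2
                out.ad_ref[row, col] = new_dp - new_dp // 2
            elif out.gt[row, col] == 2:
                out.ad_alt[row, col] = new_dp
                out.ad_ref[row, col] = 0
            else:
                out.ad_ref[row, col] = new_dp
                out.ad_alt[row, col] = 0
            ledger.call_artifacts.append(
                {
                    "chrom": str(chroms[row]),
                    "pos": int(poss[row]),
                    "sample": out.samples[col],
                    "kind": "low-dp",
                }
            )
        for idx in gq_targets:
            row, col = _rc(idx)
            out.gq[row, col] = int(rng.integers(0, 20))
            ledger.call_artifacts.append(
                {
                    "chrom": str(chroms[row]),
                    "pos": int(poss[row]),
                    "sample": out.samples[col],
                    "kind": "low-gq",
                }
            )
    return out, ledger


# ---------------------------------------------------------------------------
# curated labels and feature scores
# ---------------------------------------------------------------------------

_DELETERIOUS_SOURCES = (
    ("hgmd", "Disease_causing_mutation"),
    ("clinvar", "Pathogenic"),
    ("clinvar", "Likely_pathogenic"),
    ("clinvar", "Pathogenic/Likely_pathogenic"),
    ("swissvar", "LP/P"),
)
_BENIGN_SOURCES = (
    ("clinvar", "Benign"),
    ("clinvar", "Likely_benign"),
    ("clinvar", "Benign/Likely_benign"),
    ("swissvar", "LB/B"),
)
_VUS_STRINGS = ("Uncertain_significance", "Conflicting_interpretations_of_pathogenicity")


def simulate_curated_db(
    truth: SyntheticTruth, config: SimulationConfig, annotations: pd.DataFrame
) -> pd.DataFrame:
    """Curated-label table over a labelled subset of the variants.

    True-deleterious variants receive deleterious vocabulary (with a
    configurable mislabel rate), true-benign variants benign
    vocabulary, and noncoding variants occasionally a VUS string.  At
    ``conflict_rate`` a labelled row gains a conflicting second-source
    annotation.  Unlabelled variants keep empty label fields.
    """
    rng = stage_rng(config.seed, "curated")
    rows = []
    for key in annotations["variant_key"]:
        labels = {"hgmd": "", "clinvar": "", "swissvar": ""}
        if rng.random() < config.label_fraction:
            true_class = truth.variant_class[key]
            if true_class in ("deleterious", "benign"):
                flip = rng.random() < config.mislabel_rate
                as_deleterious = (true_class == "deleterious") != flip
                pool = _DELETERIOUS_SOURCES if as_deleterious else _BENIGN_SOURCES
                source, value = pool[rng.integers(0, len(pool))]
                labels[source] = value
                if rng.random() < config.conflict_rate:
                    other_pool = _BENIGN_SOURCES if as_deleterious else _DELETERIOUS_SOURCES
                    candidates = [(s, v) for s, v in other_pool if s != source]
                    s2, v2 = candidates[rng.integers(0, len(candidates))]
                    labels[s2] = v2
            elif rng.random() < config.vus_label_fraction:
                labels["clinvar"] = _VUS_STRINGS[rng.integers(0, len(_VUS_STRINGS))]
        rows.append({"variant_key": key, **labels})
    return pd.DataFrame(rows, columns=["variant_key", "hgmd", "clinvar", "swissvar"])


# per-feature location/scale/clipping used to place scores on familiar
# scales; the class separation itself comes from feature_effect_sizes
_SCORE_SHAPES: list[tuple[str, float, float, float, float]] = [
    ("cadd_phred", 8.0, 6.0, 0.0, 50.0),
    ("revel", 0.25, 0.18, 0.0, 1.0),
    ("polyphen2_hvar", 0.30, 0.25, 0.0, 1.0),
    ("mutation_assessor", 1.20, 0.90, -3.0, 6.0),
    ("metasvm", -0.40, 0.50, -2.0, 2.0),
    ("metalr", 0.30, 0.20, 0.0, 1.0),
    ("phylop100", 1.50, 2.00, -20.0, 10.0),
    ("phastcons100", 0.50, 0.25, 0.0, 1.0),
    ("vest3", 0.35, 0.20, 0.0, 1.0),
    ("dann", 0.60, 0.18, 0.0, 1.0),
    ("gerp", 2.00, 2.00, -12.0, 6.0),
]


def _class_conditional_scores(
    rng: np.random.Generator,
    is_deleterious: np.ndarray,
    effects: Sequence[float],
    correlation: float = 0.6,
) -> dict[str, np.ndarray]:
    """Equicorrelated class-conditional normals per in-silico score.

    A shared latent factor with weight ``correlation`` models the strong
    mutual correlation of published predictors, which caps how much a
    combined model can gain over the best single feature.
    """
    n = is_deleterious.size
    shared = rng.normal(0.0, 1.0, n)
    out = {}
    for (name, base, scale, lo, hi), effect in zip(_SCORE_SHAPES, effects):
        noise = rng.normal(0.0, 1.0, n)
        z = math.sqrt(correlation) * shared + math.sqrt(1.0 - correlation) * noise
        out[name] = np.clip(base + scale * (z + effect * is_deleterious), lo, hi)
    return out


def simulate_feature_scores(
    truth: SyntheticTruth,
    config: SimulationConfig,
    annotations: pd.DataFrame,
    macaque_af: Mapping[str, float],
    human_af: Mapping[str, float],
) -> pd.DataFrame:
    """In-silico feature table for dual-genome-matched missense variants.

    Scores are class-conditional normals with the configured per-feature
    effect sizes; allele frequencies come from the realised cohort and
    the simulated human table (absence recorded as 0).  Missing cells
    appear at ``feature_missing_rate`` in the 11 score columns.
    """
    mask = (annotations["csq_macaque"] == "missense") & annotations["dual_aa_match"]
    keys = annotations.loc[mask, "variant_key"].tolist()
    rng = stage_rng(config.seed, "features")
    is_del = np.array(
        [truth.variant_class[k] == "deleterious" for k in keys], dtype=float
    )
    scores = _class_conditional_scores(
        rng, is_del, config.feature_effect_sizes, config.feature_correlation
    )
    frame = pd.DataFrame({"variant_key": keys})
    frame["macaque_af"] = [float(macaque_af.get(k, np.nan)) for k in keys]
    frame["human_af"] = [float(human_af.get(k, 0.0)) for k in keys]
    for name, _, _, _, _ in _SCORE_SHAPES:
        col = scores[name]
        if config.feature_missing_rate > 0:
            col = np.where(rng.random(len(keys)) < config.feature_missing_rate, np.nan, col)
        frame[name] = col
    return frame[["variant_key", *FEATURE_COLUMNS]]


def simulate_training_matrix(
    config: SimulationConfig,
    n_pathogenic: int = 5079,
    n_benign: int = 5757,
    seed: int | None = None,
) -> pd.DataFrame:
    """Stand-alone labelled 13-feature matrix emulating a curated
    missense training set (default class sizes 5079 / 5757).

    Pathogenic variants carry near-zero human AFs and macaque AFs below
    the deleterious ceiling; benign AFs are heavy-tailed in both
    species.  Returns FEATURE_COLUMNS plus a ``label`` column.
    """
    rng = stage_rng(seed if seed is not None else config.seed, "training-matrix")
    n = n_pathogenic + n_benign
    is_del = np.concatenate([np.ones(n_pathogenic), np.zeros(n_benign)])
    perm = rng.permutation(n)
    is_del = is_del[perm]

    mac = np.where(
        is_del == 1,
        10 ** rng.uniform(math.log10(2.5e-4), math.log10(config.deleterious_af_ceiling), n),
        np.clip(rng.beta(0.2, 5.0, n), 2.5e-4, 1.0),
    )
    hum = np.where(
        is_del == 1,
        10 ** rng.uniform(-6, -4, n),
        np.where(rng.random(n) < 0.3, 0.0, np.clip(rng.beta(0.3, 3.0, n), 0, 0.999)),
    )
    frame = pd.DataFrame({"macaque_af": mac, "human_af": hum})
    for name, col in _class_conditional_scores(
        rng, is_del, config.feature_effect_sizes, config.feature_correlation
    ).items():
        if config.feature_missing_rate > 0:
            col = np.where(rng.random(n) < config.feature_missing_rate, np.nan, col)
        frame[name] = col
    frame = frame[FEATURE_COLUMNS].copy()
    frame["label"] = np.where(is_del == 1, "pathogenic", "benign")
    frame["variant_key"] = [f"T{i:06d}" for i in range(n)]
    return frame


# ---------------------------------------------------------------------------
# full ecosystem
# ---------------------------------------------------------------------------


@dataclass
class Ecosystem:
    config: SimulationConfig
    panel: GenePanel
    clean_cohort: Cohort
    cohort: Cohort  # with injected artifacts
    ledger: ArtifactLedger
    truth: SyntheticTruth
    annotations: pd.DataFrame
    curated: pd.DataFrame
    features: pd.DataFrame
    human_db: pd.DataFrame

    def macaque_afs(self) -> dict[str, float]:
        """Realised cohort AF per variant key (clean genotypes)."""
        keys = self.clean_cohort.variant_keys()
        gt = self.clean_cohort.gt
        called = gt >= 0
        an = 2 * called.sum(axis=1)
        ac = np.where(called, gt, 0).sum(axis=1)
        with np.errstate(invalid="ignore"):
            af = np.where(an > 0, ac / np.maximum(an, 1), np.nan)
        return dict(zip(keys, af.astype(float)))


def _write_tsv(frame: pd.DataFrame, path: Path) -> None:
    frame.replace("", ".").to_csv(path, sep="\t", index=False, na_rep=".")


def simulate_ecosystem(
    config: SimulationConfig, outdir: str | Path | None = None
) -> Ecosystem:
    """Generate every artifact of the synthetic study; optionally write
    the file ecosystem (FASTA, VCFs, TSVs, JSON ledgers) to ``outdir``."""
    panel = generate_gene_panel(config)
    sim = simulate_cohort_genotypes(config, panel)
    corrupted, ledger = inject_qc_artifacts(sim.cohort, config)
    curated = simulate_curated_db(sim.truth, config, sim.annotations)
    eco = Ecosystem(
        config=config,
        panel=panel,
        clean_cohort=sim.cohort,
        cohort=corrupted,
        ledger=ledger,
        truth=sim.truth,
        annotations=sim.annotations,
        curated=curated,
        features=pd.DataFrame(),
        human_db=sim.human_db,
    )
    # human AF keyed back to macaque variant keys via the truth sharing table
    shared_keys = [k for k, s in sim.truth.shared_with_human.items() if s]
    afs = dict(zip(shared_keys, sim.human_db["af"].tolist()))
    eco.features = simulate_feature_scores(
        sim.truth, config, sim.annotations, eco.macaque_afs(), afs
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        panel.to_fasta(outdir / "panel.fa")
        _write_tsv(panel.orthology_frame(), outdir / "orthology.tsv")
        _write_tsv(sim.annotations, outdir / "annotations.tsv")
        _write_tsv(curated, outdir / "curated.tsv")
        _write_tsv(eco.features, outdir / "features.tsv")
        _write_tsv(sim.human_db, outdir / "human_af.tsv")
        write_vcf(sim.cohort, outdir / "cohort.clean.vcf")
        write_vcf(corrupted, outdir / "cohort.vcf")
        ledger.to_json(outdir / "artifacts.json")
        sim.truth.to_json(outdir / "truth.json")
        _write_tsv(
            pd.DataFrame(
                {"sample": sim.cohort.samples, "colony": [sim.cohort.colonies[s] for s in sim.cohort.samples]}
            ),
            outdir / "colonies.tsv",
        )
    return eco
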