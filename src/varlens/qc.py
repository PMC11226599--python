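"""Genotype and site quality control for multi-sample SNV cohorts.

Implements the hard-filter / masking scheme used for deep targeted
sequencing panels:

* site hard filters on QD, QUAL, FS, MQ, MQRankSum and ReadPosRankSum
  with strict comparisons (boundary values pass);
* per-call masking of no-calls, low-depth (DP < 10), low-quality
  (GQ < 20) and allelically imbalanced heterozygotes (AB > 0.8 or
  AB < 0.2, AB = alt reads / (ref + alt reads));
* re-qualification: sites must remain dimorphic over unmasked calls;
* exclusion of sites where a single subject shows more than two
  distinct alleles (evaluated on raw, pre-masking observations);
* exclusion of samples with mean target coverage below 10x.

Scalar operations mirror the vectorised cohort pipeline one-to-one so
single calls can be reasoned about (and property-tested) directly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .vcfio import Cohort

MASK_REASONS = ("no-call", "low-dp", "low-gq", "allelic-imbalance")
_REASON_CODE = {r: i + 1 for i, r in enumerate(MASK_REASONS)}


@dataclass(frozen=True)
class HardFilterThresholds:
    """Site-level hard-filter thresholds (GATK-style defaults)."""

    qd: float = 5.0
    qual: float = 30.0
    fs: float = 15.0
    mq: float = 50.0
    mq_rank_sum: float = -12.5
    read_pos_rank_sum: float = -8.0


DEFAULT_THRESHOLDS = HardFilterThresholds()


@dataclass
class SiteQCAnnotations:
    qd: float | None
    qual: float | None
    fs: float | None
    mq: float | None
    mq_rank_sum: float | None = None
    read_pos_rank_sum: float | None = None


@dataclass
class GenotypeCall:
    """One sample x site call. ``gt`` is one of hom-ref/het/hom-alt/missing."""

    sample_id: str
    gt: str
    ad_ref: int
    ad_alt: int
    dp: int
    gq: float
    masked: bool = False
    mask_reason: str | None = None


def _missing(x) -> bool:
    return x is None or (isinstance(x, float) and np.isnan(x))


def apply_site_hard_filters(
    site: SiteQCAnnotations, thresholds: HardFilterThresholds = DEFAULT_THRESHOLDS
) -> tuple[bool, list[str]]:
    """Return (passes, failed_rules) for one site.

    All comparisons are strict, exactly as the rules are stated, so
    boundary values pass.  Missing QD/QUAL/FS/MQ fail conservatively
    with reason ``missing-annotation``; the rank-sum annotations may be
    legitimately absent and are then skipped.
    """
    failed: list[str] = []
    for name in ("qd", "qual", "fs", "mq"):
        if _missing(getattr(site, name)):
            failed.append("missing-annotation")
            break
    if site.qd is not None and not _missing(site.qd) and site.qd < thresholds.qd:
        failed.append("QD")
    if site.qual is not None and not _missing(site.qual) and site.qual < thresholds.qual:
        failed.append("QUAL")
    if site.fs is not None and not _missing(site.fs) and site.fs > thresholds.fs:
        failed.append("FS")
    if site.mq is not None and not _missing(site.mq) and site.mq < thresholds.mq:
        failed.append("MQ")
    if not _missing(site.mq_rank_sum) and site.mq_rank_sum < thresholds.mq_rank_sum:
        failed.append("MQRankSum")
    if not _missing(site.read_pos_rank_sum) and site.read_pos_rank_sum < thresholds.read_pos_rank_sum:
        failed.append("ReadPosRankSum")
    return (not failed), failed


def mask_genotype_call(call: GenotypeCall) -> GenotypeCall:
    """Mask a call with the first matching reason in fixed order.

    Order: no-call, low-dp, low-gq, allelic-imbalance.  AB is computed
    from AD (not DP); an AB with zero denominator on a het call is
    treated as extreme imbalance.  Non-het calls are never masked for
    imbalance.  Boundary values (DP=10, GQ=20, AB=0.2/0.8) are kept.
    """
    reason: str | None = None
    if call.gt == "missing":
        reason = "no-call"
    elif call.dp < 10:
        reason = "low-dp"
    elif call.gq < 20:
        reason = "low-gq"
    elif call.gt == "het":
        denom = call.ad_ref + call.ad_alt
        if denom == 0:
            reason = "allelic-imbalance"
        else:
            ab = call.ad_alt / denom
            if ab > 0.8 or ab < 0.2:
                reason = "allelic-imbalance"
    if reason is None:
        return call
    return GenotypeCall(
        sample_id=call.sample_id,
        gt=call.gt,
        ad_ref=call.ad_ref,
        ad_alt=call.ad_alt,
        dp=call.dp,
        gq=call.gq,
        masked=True,
        mask_reason=reason,
    )


def requalify_site(calls: Sequence[GenotypeCall]) -> tuple[bool, str | None]:
    """Keep a site iff >= 2 distinct alleles remain over unmasked calls."""
    unmasked = [c for c in calls if not c.masked and c.gt != "missing"]
    if not unmasked:
        return False, "no-data"
    has_ref = any(c.gt in ("hom-ref", "het") for c in unmasked)
    has_alt = any(c.gt in ("het", "hom-alt") for c in unmasked)
    if has_ref and has_alt:
        return True, None
    return False, "monomorphic"


def drop_multiallelic_subject_sites(
    subject_alleles: Mapping[str, Iterable[str]]
) -> tuple[bool, list[str]]:
    """Drop a site iff any single subject shows > 2 distinct alleles.

    The rule is per-subject: two subjects jointly covering three
    alleles do not trigger it.
    """
    offenders = [s for s, alleles in subject_alleles.items() if len(set(alleles)) > 2]
    return (len(offenders) > 0), offenders


def filter_low_coverage_samples(
    mean_depths: Mapping[str, float], min_depth: float = 10.0
) -> list[str]:
    """Samples retained for analysis (mean target depth >= 10x)."""
    return [s for s, d in mean_depths.items() if d >= min_depth]


@dataclass
class QCReport:
    sites_in: int = 0
    sites_failed_hard_filter: int = 0
    sites_monomorphic_after_masking: int = 0
    sites_multiallelic_subject: int = 0
    sites_out: int = 0
    samples_in: int = 0
    samples_dropped_low_coverage: list[str] = field(default_factory=list)
    genotypes_masked_by_reason: dict[str, int] = field(default_factory=dict)

    def validate(self) -> None:
        total = (
            self.sites_out
            + self.sites_failed_hard_filter
            + self.sites_monomorphic_after_masking
            + self.sites_multiallelic_subject
        )
        if total != self.sites_in:
            raise AssertionError("QC report site counts are not sum-consistent")

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(asdict(self), indent=2))
        return path


@dataclass
class QCResult:
    cohort: Cohort
    report: QCReport
    #: (chrom, pos, sample, reason) for every masked genotype on retained sites
    masked_calls: list[tuple[str, int, str, str]]
    #: (chrom, pos, failed_rules) for hard-filter failures
    failed_sites: list[tuple[str, int, tuple[str, ...]]]
    #: (chrom, pos) dropped for a multiallelic single subject
    multiallelic_sites: list[tuple[str, int]]
    #: (chrom, pos) dropped as monomorphic after masking
    monomorphic_sites: list[tuple[str, int]]


def run_qc(
    cohort: Cohort, thresholds: HardFilterThresholds = DEFAULT_THRESHOLDS
) -> QCResult:
    """Full QC pipeline over a cohort; vectorised but semantically
    identical to the scalar operations above.

    Stage order: low-coverage sample exclusion -> multiallelic-subject
    site exclusion (pre-masking) -> site hard filters -> genotype
    masking -> dimorphism re-qualification.  Each dropped site is
    attributed to the first stage that claims it.
    """
    report = QCReport(sites_in=cohort.n_sites, samples_in=cohort.n_samples)

    retained_samples = filter_low_coverage_samples(cohort.mean_sample_depth())
    report.samples_dropped_low_coverage = [
        s for s in cohort.samples if s not in set(retained_samples)
    ]
    sample_mask = np.array([s in set(retained_samples) for s in cohort.samples])
    work = cohort.subset(sample_mask=sample_mask)

    # multiallelic single subject (raw, pre-masking observations)
    multi_rows = sorted(work.extra_alleles)
    multiallelic_sites = [
        (str(work.sites.at[r, "chrom"]), int(work.sites.at[r, "pos"])) for r in multi_rows
    ]
    report.sites_multiallelic_subject = len(multi_rows)
    keep = np.ones(work.n_sites, dtype=bool)
    keep[multi_rows] = False

    # site hard filters
    failed_sites: list[tuple[str, int, tuple[str, ...]]] = []
    for row in np.flatnonzero(keep):
        site = work.sites.iloc[row]
        ok, rules = apply_site_hard_filters(
            SiteQCAnnotations(
                qd=site["qd"],
                qual=site["qual"],
                fs=site["fs"],
                mq=site["mq"],
                mq_rank_sum=site["mq_rank_sum"],
                read_pos_rank_sum=site["read_pos_rank_sum"],
            ),
            thresholds,
        )
        if not ok:
            failed_sites.append((str(site["chrom"]), int(site["pos"]), tuple(rules)))
            keep[row] = False
    report.sites_failed_hard_filter = len(failed_sites)

    work = work.subset(site_mask=keep)

    # genotype masking (vectorised; same priority order as the scalar op)
    gt, dp, gq = work.gt, work.dp, work.gq
    denom = work.ad_ref + work.ad_alt
    with np.errstate(divide="ignore", invalid="ignore"):
        ab = np.where(denom > 0, work.ad_alt / np.maximum(denom, 1), np.nan)
    het = gt == 1
    imbalance = het & ((denom == 0) | (ab > 0.8) | (ab < 0.2))
    reason_code = np.select(
        [gt == -1, dp < 10, gq < 20, imbalance],
        [1, 2, 3, 4],
        default=0,
    ).astype(np.int8)

    masked = reason_code > 0
    masked_calls: list[tuple[str, int, str, str]] = []
    by_reason = {r: 0 for r in MASK_REASONS}
    chroms = work.sites["chrom"].to_numpy()
    poss = work.sites["pos"].to_numpy()
    for row, col in zip(*np.nonzero(masked & (gt != -1))):
        reason = MASK_REASONS[reason_code[row, col] - 1]
        masked_calls.append((str(chroms[row]), int(poss[row]), work.samples[col], reason))
    for code, reason in enumerate(MASK_REASONS, start=1):
        by_reason[reason] = int(np.sum(reason_code == code))
    report.genotypes_masked_by_reason = by_reason

    new_gt = np.where(masked, np.int8(-1), gt).astype(np.int8)

    # re-qualification: site must stay dimorphic over unmasked calls
    has_ref = np.any((new_gt == 0) | (new_gt == 1), axis=1)
    has_alt = np.any((new_gt == 1) | (new_gt == 2), axis=1)
    dimorphic = has_ref & has_alt
    monomorphic_sites = [
        (str(chroms[r]), int(poss[r])) for r in np.flatnonzero(~dimorphic)
    ]
    report.sites_monomorphic_after_masking = len(monomorphic_sites)

    work.gt = new_gt
    out = work.subset(site_mask=dimorphic)
    report.sites_out = out.n_sites
    report.validate()
    return QCResult(
        cohort=out,
        report=report,
        masked_calls=masked_calls,
        failed_sites=failed_sites,
        multiallelic_sites=multiallelic_sites,
        monomorphic_sites=monomorphic_sites,
    )
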