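"""Multi-sample VCF container and pysam-backed reader/writer.

A :class:`Cohort` holds one biallelic SNV per row with per-call
GT/AD/DP/GQ arrays and the site-level annotations used by the hard
filters (QD, QUAL, FS, MQ, MQRankSum, ReadPosRankSum).  Sites carrying
a third allele observed in a single subject (the multiallelic-subject
QC case) are represented with a second ALT allele and that subject's
genotype spanning both alternates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

SITE_COLUMNS = [
    "chrom",
    "pos",
    "ref",
    "alt",
    "qual",
    "qd",
    "fs",
    "mq",
    "mq_rank_sum",
    "read_pos_rank_sum",
]

_INFO_KEYS = {
    "qd": "QD",
    "fs": "FS",
    "mq": "MQ",
    "mq_rank_sum": "MQRankSum",
    "read_pos_rank_sum": "ReadPosRankSum",
}


def variant_key(chrom: str, pos: int, ref: str, alt: str) -> str:
    return f"{chrom}:{pos}:{ref}:{alt}"


@dataclass
class Cohort:
    """In-memory multi-sample SNV cohort.

    ``gt`` codes per individual: -1 no-call, 0 hom-ref, 1 het,
    2 hom-alt.  ``extra_alleles`` maps a site row to ``(sample_index,
    second_alt_base)`` for sites where one subject shows a third allele.
    """

    samples: list[str]
    sites: pd.DataFrame
    gt: np.ndarray
    ad_ref: np.ndarray
    ad_alt: np.ndarray
    dp: np.ndarray
    gq: np.ndarray
    colonies: dict[str, str] | None = None
    extra_alleles: dict[int, tuple[int, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n_sites, n_samples = self.gt.shape
        if len(self.sites) != n_sites or len(self.samples) != n_samples:
            raise ValueError("inconsistent cohort dimensions")
        for arr in (self.ad_ref, self.ad_alt, self.dp, self.gq):
            if arr.shape != self.gt.shape:
                raise ValueError("per-call arrays must share the genotype shape")
        missing = [c for c in SITE_COLUMNS if c not in self.sites.columns]
        if missing:
            raise ValueError(f"site table lacks columns: {missing}")

    @property
    def n_sites(self) -> int:
        return self.gt.shape[0]

    @property
    def n_samples(self) -> int:
        return self.gt.shape[1]

    def variant_keys(self) -> list[str]:
        return [
            variant_key(c, int(p), r, a)
            for c, p, r, a in zip(
                self.sites["chrom"], self.sites["pos"], self.sites["ref"], self.sites["alt"]
            )
        ]

    def copy(self) -> "Cohort":
        return Cohort(
            samples=list(self.samples),
            sites=self.sites.copy().reset_index(drop=True),
            gt=self.gt.copy(),
            ad_ref=self.ad_ref.copy(),
            ad_alt=self.ad_alt.copy(),
            dp=self.dp.copy(),
            gq=self.gq.copy(),
            colonies=dict(self.colonies) if self.colonies else None,
            extra_alleles=dict(self.extra_alleles),
        )

    def subset(self, site_mask: np.ndarray | None = None, sample_mask: np.ndarray | None = None) -> "Cohort":
        """Row/column subset; remaps ``extra_alleles`` bookkeeping."""
        site_idx = np.flatnonzero(site_mask) if site_mask is not None else np.arange(self.n_sites)
        samp_idx = np.flatnonzero(sample_mask) if sample_mask is not None else np.arange(self.n_samples)
        old_to_new_site = {int(o): n for n, o in enumerate(site_idx)}
        old_to_new_samp = {int(o): n for n, o in enumerate(samp_idx)}
        extra = {}
        for row, (s_idx, base) in self.extra_alleles.items():
            if row in old_to_new_site and s_idx in old_to_new_samp:
                extra[old_to_new_site[row]] = (old_to_new_samp[s_idx], base)
        samples = [self.samples[i] for i in samp_idx]
        return Cohort(
            samples=samples,
            sites=self.sites.iloc[site_idx].reset_index(drop=True),
            gt=self.gt[np.ix_(site_idx, samp_idx)],
            ad_ref=self.ad_ref[np.ix_(site_idx, samp_idx)],
            ad_alt=self.ad_alt[np.ix_(site_idx, samp_idx)],
            dp=self.dp[np.ix_(site_idx, samp_idx)],
            gq=self.gq[np.ix_(site_idx, samp_idx)],
            colonies={s: self.colonies[s] for s in samples} if self.colonies else None,
            extra_alleles=extra,
        )

    def mean_sample_depth(self) -> dict[str, float]:
        means = self.dp.mean(axis=0) if self.n_sites else np.zeros(self.n_samples)
        return {s: float(m) for s, m in zip(self.samples, means)}


def _build_header(cohort: Cohort) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for chrom in dict.fromkeys(cohort.sites["chrom"]):
        header.contigs.add(str(chrom), length=500_000_000)
    header.add_line('##INFO=<ID=QD,Number=1,Type=Float,Description="Variant quality by depth">')
    header.add_line('##INFO=<ID=FS,Number=1,Type=Float,Description="Fisher strand bias (phred)">')
    header.add_line('##INFO=<ID=MQ,Number=1,Type=Float,Description="RMS mapping quality">')
    header.add_line('##INFO=<ID=MQRankSum,Number=1,Type=Float,Description="Mapping quality rank sum">')
    header.add_line('##INFO=<ID=ReadPosRankSum,Number=1,Type=Float,Description="Read position rank sum">')
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.add_line('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">')
    header.add_line('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">')
    header.add_line('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">')
    for sample in cohort.samples:
        header.add_sample(sample)
    return header

_GT_TUPLES = {-1: (None, None), 0: (0, 0), 1: (0, 1), 2: (1, 1)}


def write_vcf(cohort: Cohort, path: str | Path) -> Path:
    """Write the cohort as an uncompressed VCFv4.2 file."""
    path = Path(path)
    header = _build_header(cohort)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for row in range(cohort.n_sites):
            site = cohort.sites.iloc[row]
            extra = cohort.extra_alleles.get(row)
            alleles = [site["ref"], site["alt"]]
            if extra is not None:
                alleles.append(extra[1])
            rec = out.new_record(
                contig=str(site["chrom"]),
                start=int(site["pos"]) - 1,
                stop=int(site["pos"]),
                alleles=tuple(alleles),
            )
            rec.qual = None if _is_missing(site["qual"]) else float(site["qual"])
            for col, key in _INFO_KEYS.items():
                if not _is_missing(site[col]):
                    rec.info[key] = float(site[col])
            for s_idx, sample in enumerate(cohort.samples):
                call = rec.samples[sample]
                adr = int(cohort.ad_ref[row, s_idx])
                ada = int(cohort.ad_alt[row, s_idx])
                if extra is not None and s_idx == extra[0]:
                    call["GT"] = (1, 2)
                    third = max(1, (adr + ada) // 3)
                    call["AD"] = (adr, max(ada - third, 1), third)
                else:
                    call["GT"] = _GT_TUPLES[int(cohort.gt[row, s_idx])]
                    call["AD"] = (adr, ada) + ((0,) if extra is not None else ())
                call["DP"] = int(cohort.dp[row, s_idx])
                call["GQ"] = int(cohort.gq[row, s_idx])
            out.write(rec)
    return path


def _is_missing(x) -> bool:
    try:
        return x is None or (isinstance(x, float) and math.isnan(x)) or pd.isna(x)
    except (TypeError, ValueError):
        return False


def read_vcf(path: str | Path) -> Cohort:
    """Read a (biallelic-plus-artifact) SNV VCF back into a Cohort."""
    rows, gts, adrs, adas, dps, gqs = [], [], [], [], [], []
    extra_alleles: dict[int, tuple[int, str]] = {}
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        for rec in vcf:
            alts = rec.alts or ()
            if not alts:
                continue
            info = rec.info
            rows.append(
                {
                    "chrom": rec.contig,
                    "pos": rec.pos,
                    "ref": rec.ref,
                    "alt": alts[0],
                    "qual": rec.qual if rec.qual is not None else np.nan,
                    **{
                        col: (float(info[key]) if key in info else np.nan)
                        for col, key in _INFO_KEYS.items()
                    },
                }
            )
            row_gt = np.full(len(samples), -1, dtype=np.int8)
            row_adr = np.zeros(len(samples), dtype=np.int32)
            row_ada = np.zeros(len(samples), dtype=np.int32)
            row_dp = np.zeros(len(samples), dtype=np.int32)
            row_gq = np.zeros(len(samples), dtype=np.int32)
            for s_idx, sample in enumerate(samples):
                call = rec.samples[sample]
                alleles = call.get("GT")
                if alleles is None or all(a is None for a in alleles):
                    code = -1
                else:
                    observed = {a for a in alleles if a is not None}
                    if len(observed) > 1 and max(observed) >= 2:
                        extra_alleles[len(rows) - 1] = (s_idx, alts[1])
                        code = 1  # treated as het on the primary alt downstream
                    else:
                        code = sum(1 for a in alleles if a == 1)
                row_gt[s_idx] = code
                ad = call.get("AD")
                if ad is not None:
                    row_adr[s_idx] = ad[0] or 0
                    row_ada[s_idx] = (ad[1] or 0) if len(ad) > 1 else 0
                    if len(ad) > 2 and (ad[2] or 0) > 0 and s_idx not in [
                        v[0] for k, v in extra_alleles.items() if k == len(rows) - 1
                    ]:
                        extra_alleles[len(rows) - 1] = (s_idx, alts[1])
                row_dp[s_idx] = call.get("DP") or 0
                gq = call.get("GQ")
                row_gq[s_idx] = gq if gq is not None else 0
            gts.append(row_gt)
            adrs.append(row_adr)
            adas.append(row_ada)
            dps.append(row_dp)
            gqs.append(row_gq)
    sites = pd.DataFrame(rows, columns=SITE_COLUMNS)
    return Cohort(
        samples=samples,
        sites=sites,
        gt=np.vstack(gts) if gts else np.zeros((0, len(samples)), dtype=np.int8),
        ad_ref=np.vstack(adrs) if adrs else np.zeros((0, len(samples)), dtype=np.int32),
        ad_alt=np.vstack(adas) if adas else np.zeros((0, len(samples)), dtype=np.int32),
        dp=np.vstack(dps) if dps else np.zeros((0, len(samples)), dtype=np.int32),
        gq=np.vstack(gqs) if gqs else np.zeros((0, len(samples)), dtype=np.int32),
        extra_alleles=extra_alleles,
    )
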