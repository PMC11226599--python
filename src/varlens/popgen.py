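"""Per-site and cohort-level population statistics.

Allele and homozygote frequencies with per-base denominators, allele
frequency spectrum summaries (singleton fraction, rare fraction,
het/hom split), transition/transversion ratio, and an exact two-sided
binomial test for CpG mutational enrichment computed in log space so
that astronomically small tail probabilities remain representable via
their log10.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

import numpy as np
from scipy.special import logsumexp
from scipy.stats import binom

TRANSITIONS = frozenset({("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")})

#: relative tolerance when collecting outcomes no more likely than the
#: observed one (the minimum-likelihood two-sided convention)
_MINLIKE_RELTOL = 1e-7


def round_half_up(x: float, ndigits: int) -> float:
    """Decimal round-half-up used for report display (0.065 -> 0.07)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class FrequencyRecord:
    """Allele-count summary of one biallelic site in one population."""

    an: int
    ac: int
    af: float
    n_hom_alt: int
    n_het: int
    n_genotyped: int
    hf: float
    chrom: str | None = None
    pos: int | None = None
    ref: str | None = None
    alt: str | None = None
    population: str | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.ac <= self.an) or self.an % 2:
            raise ValueError("require 0 <= ac <= an with an even")
        if 2 * self.n_hom_alt + self.n_het != self.ac:
            raise ValueError("2*n_hom_alt + n_het must equal ac")


def compute_site_frequencies(
    genotypes: Sequence[int] | np.ndarray, **site_fields
) -> FrequencyRecord:
    """Frequency record from per-individual alt-allele counts.

    ``genotypes`` holds one entry per individual: 0/1/2 alt-allele
    copies, or -1 for a missing/masked call (excluded from AN, so the
    denominator is per-base).  Raises on a site with no data.
    """
    g = np.asarray(genotypes, dtype=int)
    called = g[g >= 0]
    if called.size == 0:
        raise ValueError("no-data site: all genotypes missing or masked")
    if called.max(initial=0) > 2:
        raise ValueError("genotype codes must be in {-1, 0, 1, 2}")
    n_genotyped = int(called.size)
    an = 2 * n_genotyped
    ac = int(called.sum())
    n_hom = int(np.sum(called == 2))
    n_het = int(np.sum(called == 1))
    return FrequencyRecord(
        an=an,
        ac=ac,
        af=ac / an,
        n_hom_alt=n_hom,
        n_het=n_het,
        n_genotyped=n_genotyped,
        hf=n_hom / n_genotyped,
        **site_fields,
    )


def homozygote_frequency(n_hom_alt: int, n_genotyped: int) -> float:
    """Exact homozygote frequency n_hom_alt / n_genotyped.

    Display rounding (half-up to two decimals) is left to
    :func:`round_half_up`; e.g. (66, 1179) reports as 0.06.
    """
    if n_genotyped <= 0:
        raise ValueError("n_genotyped must be positive")
    if not 0 <= n_hom_alt <= n_genotyped:
        raise ValueError("need 0 <= n_hom_alt <= n_genotyped")
    return n_hom_alt / n_genotyped


def is_transition(ref: str, alt: str) -> bool:
    return (ref.upper(), alt.upper()) in TRANSITIONS


def tstv_ratio(ref_alt_pairs: Iterable[tuple[str, str]]) -> float | None:
    """Transition/transversion ratio over SNVs; None when no transversions."""
    ts = tv = 0
    for ref, alt in ref_alt_pairs:
        if is_transition(ref, alt):
            ts += 1
        else:
            tv += 1
    if tv == 0:
        return None
    return ts / tv


@dataclass
class SpectrumSummary:
    n_snvs: int
    singleton_fraction: float
    fraction_af_le_half_percent: float
    het_fraction: float
    hom_fraction: float
    tstv: float | None


def spectrum_summary(
    records: Sequence[FrequencyRecord],
    ref_alt_pairs: Sequence[tuple[str, str]] | None = None,
) -> SpectrumSummary:
    """Cohort AF-spectrum summary over (typically autosomal) sites.

    A singleton is a site with cohort-wide alt allele count 1; the
    het/hom split is over non-reference genotype calls.  ``ref_alt_pairs``
    (parallel to ``records`` or any SNV collection) feeds the Ts/Tv
    ratio and may be omitted.
    """
    if not records:
        raise ValueError("no frequency records")
    n = len(records)
    singletons = sum(1 for r in records if r.ac == 1)
    rare = sum(1 for r in records if r.af <= 0.005)
    n_het = sum(r.n_het for r in records)
    n_hom = sum(r.n_hom_alt for r in records)
    nonref = n_het + n_hom
    tstv = tstv_ratio(ref_alt_pairs) if ref_alt_pairs is not None else None
    return SpectrumSummary(
        n_snvs=n,
        singleton_fraction=singletons / n,
        fraction_af_le_half_percent=rare / n,
        het_fraction=n_het / nonref if nonref else float("nan"),
        hom_fraction=n_hom / nonref if nonref else float("nan"),
        tstv=tstv,
    )


@dataclass
class CpGEnrichment:
    n_cpg: int
    n_total: int
    cpg_base_fraction: float
    observed_fraction: float
    fold: float
    pvalue: float
    log10_pvalue: float

    @property
    def fold_display(self) -> float:
        return round_half_up(self.fold, 1)


def cpg_enrichment_test(
    n_snvs_at_cpg: int, n_snvs_total: int, cpg_base_fraction: float
) -> CpGEnrichment:
    """Fold enrichment of SNVs at CpG-context bases + exact binomial p.

    Two-sided p by the minimum-likelihood convention: the sum of
    probabilities of all outcomes k with P(k) <= P(observed), evaluated
    from log-pmf values with logsumexp so extreme tails keep a finite
    log10 even when the linear p underflows.
    """
    if not 0 < cpg_base_fraction < 1:
        raise ValueError("cpg_base_fraction must be in (0, 1)")
    if n_snvs_total <= 0 or not 0 <= n_snvs_at_cpg <= n_snvs_total:
        raise ValueError("need 0 <= n_snvs_at_cpg <= n_snvs_total, n_snvs_total > 0")
    k = np.arange(n_snvs_total + 1)
    logpmf = binom.logpmf(k, n_snvs_total, cpg_base_fraction)
    log_obs = logpmf[n_snvs_at_cpg]
    mask = logpmf <= log_obs + _MINLIKE_RELTOL
    log_p = float(logsumexp(logpmf[mask]))
    log_p = min(log_p, 0.0)
    if log_p > -575.0:
        # away from underflow, an ascending linear sum of pmf values is
        # more accurate than exponentiating the logsumexp result
        pmf = binom.pmf(k, n_snvs_total, cpg_base_fraction)
        p_linear = float(np.sum(np.sort(pmf[mask])))
        p_value = min(p_linear, 1.0)
    else:
        p_value = math.exp(log_p)
    observed = n_snvs_at_cpg / n_snvs_total
    return CpGEnrichment(
        n_cpg=n_snvs_at_cpg,
        n_total=n_snvs_total,
        cpg_base_fraction=cpg_base_fraction,
        observed_fraction=observed,
        fold=observed / cpg_base_fraction,
        pvalue=p_value,
        log10_pvalue=log_p / math.log(10.0),
    )
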