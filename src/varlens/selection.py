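"""Per-gene molecular-evolution statistics.

Implements Nei-Gojobori (1986) style counting of synonymous and
nonsynonymous sites and differences on codon-aligned coding sequence
pairs, within-species pN/pS from annotated polymorphisms, the
McDonald-Kreitman Neutrality Index, and rank-sum comparison of
per-gene statistics between gene sets.

Conventions
-----------
* Site counts: for each codon position the synonymous-site fraction is
  the number of the three alternative bases that preserve the amino
  acid, divided by three.  Changes to stop codons are counted as
  nonsynonymous, so every codon contributes exactly three sites.
* Differences: codons differing at more than one position are scored by
  averaging over all minimal single-step mutational paths; paths that
  pass through a stop codon are excluded and the average renormalised
  over the remaining paths.  If every path is blocked (rare), all paths
  are used and steps into or out of a stop codon count as
  nonsynonymous.
* Distances default to uncorrected proportions (dn = nd / n_sites);
  a Jukes-Cantor multiple-hit correction is optional.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from itertools import permutations
from typing import Iterable, Sequence

from Bio.Data import CodonTable
from scipy import stats as _sps

_TABLE = CodonTable.unambiguous_dna_by_id[1]
CODON_TO_AA: dict[str, str] = dict(_TABLE.forward_table)
STOP_CODONS: frozenset[str] = frozenset(_TABLE.stop_codons)
SENSE_CODONS: tuple[str, ...] = tuple(sorted(CODON_TO_AA))
BASES = "ACGT"
GAP = "-"

#: consequence vocabulary entering pN (nonsynonymous polymorphism)
NONSYNONYMOUS_CONSEQUENCES = frozenset({"missense", "stop_gain"})
#: consequence vocabulary entering pS
SYNONYMOUS_CONSEQUENCES = frozenset({"synonymous"})

_CSQ_ALIASES = {
    "missense_variant": "missense",
    "stop_gained": "stop_gain",
    "stopgain": "stop_gain",
    "nonsense": "stop_gain",
    "synonymous_variant": "synonymous",
}


class CodonError(ValueError):
    """Raised for gapped, ambiguous or stop codons where disallowed."""


def _check_codon(codon: str) -> str:
    codon = codon.upper()
    if len(codon) != 3 or any(b not in BASES for b in codon):
        raise CodonError(f"not an unambiguous codon: {codon!r}")
    if codon in STOP_CODONS:
        raise CodonError(f"stop codon not countable: {codon!r}")
    return codon


@lru_cache(maxsize=None)
def ng86_site_counts(codon: str) -> tuple[float, float]:
    """Expected (synonymous, nonsynonymous) site counts of one codon.

    Each position contributes s_i = (# synonymous single-base
    neighbours)/3 synonymous sites; neighbours that are stop codons are
    nonsynonymous.  The two counts always sum to 3.
    """
    codon = _check_codon(codon)
    aa = CODON_TO_AA[codon]
    syn = 0.0
    for i in range(3):
        for b in BASES:
            if b == codon[i]:
                continue
            neighbour = codon[:i] + b + codon[i + 1 :]
            if neighbour not in STOP_CODONS and CODON_TO_AA[neighbour] == aa:
                syn += 1.0 / 3.0
    return syn, 3.0 - syn


def _step_is_synonymous(c1: str, c2: str) -> bool:
    aa1 = "*" if c1 in STOP_CODONS else CODON_TO_AA[c1]
    aa2 = "*" if c2 in STOP_CODONS else CODON_TO_AA[c2]
    return aa1 == aa2 and aa1 != "*"


@lru_cache(maxsize=None)
def codon_path_differences(c1: str, c2: str) -> tuple[float, float]:
    """Path-averaged (nonsynonymous, synonymous) differences of a codon pair.

    Averages over all orderings of the differing positions, excluding
    paths through stop codons (renormalised).  Returns fractional
    counts; they sum to the number of differing positions.
    """
    c1, c2 = _check_codon(c1), _check_codon(c2)
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0

    def walk(order: Sequence[int], allow_stops: bool) -> tuple[float, float] | None:
        nd = sd = 0.0
        cur = c1
        for i in order:
            nxt = cur[:i] + c2[i] + cur[i + 1 :]
            if nxt in STOP_CODONS and not allow_stops:
                return None
            if _step_is_synonymous(cur, nxt):
                sd += 1.0
            else:
                nd += 1.0
            cur = nxt
        return nd, sd

    results = [r for order in permutations(diff) if (r := walk(order, False))]
    if not results:  # every path blocked by a stop codon
        results = [walk(order, True) for order in permutations(diff)]
    nd = sum(r[0] for r in results) / len(results)
    sd = sum(r[1] for r in results) / len(results)
    return nd, sd


@dataclass
class CodonAlignment:
    """A pairwise, in-frame codon alignment of one gene's CDS.

    Gaps ('-') are allowed only as whole codons.  Terminal stop codons
    are tolerated (and skipped); internal stops raise.
    """

    gene_id: str
    seq_a: str
    seq_b: str

    def __post_init__(self) -> None:
        self.seq_a = self.seq_a.upper()
        self.seq_b = self.seq_b.upper()
        if len(self.seq_a) != len(self.seq_b):
            raise ValueError(f"{self.gene_id}: unequal sequence lengths")
        if len(self.seq_a) % 3:
            raise ValueError(f"{self.gene_id}: length not divisible by 3")
        for seq in (self.seq_a, self.seq_b):
            for cod in self._codons(seq):
                if GAP in cod and set(cod) != {GAP}:
                    raise ValueError(
                        f"{self.gene_id}: gap not aligned to codon boundary: {cod}"
                    )
        n = len(self.seq_a) // 3
        for idx in range(n):
            for seq in (self.seq_a, self.seq_b):
                cod = seq[3 * idx : 3 * idx + 3]
                if cod in STOP_CODONS and idx < n - 1:
                    raise ValueError(f"{self.gene_id}: internal stop codon at codon {idx}")

    @staticmethod
    def _codons(seq: str) -> list[str]:
        return [seq[i : i + 3] for i in range(0, len(seq), 3)]

    def comparable_codon_pairs(self) -> list[tuple[str, str]]:
        """Ungapped, non-stop codon pairs entering the NG86 counts."""
        pairs = []
        for ca, cb in zip(self._codons(self.seq_a), self._codons(self.seq_b)):
            if GAP in ca or GAP in cb:
                continue
            if ca in STOP_CODONS or cb in STOP_CODONS:
                continue  # terminal stops (internal ones already rejected)
            pairs.append((ca, cb))
        return pairs


@dataclass
class SelectionStats:
    """Per-gene divergence and polymorphism summary."""

    gene_id: str
    n_sites: float = 0.0
    s_sites: float = 0.0
    nd: float = 0.0
    sd: float = 0.0
    dn: float | None = None
    ds: float | None = None
    dnds: float | None = None
    pn: int | None = None
    ps: int | None = None
    pnps: float | None = None
    ni: float | None = None
    n_codons: int = 0


def _jc_correct(p: float) -> float | None:
    if p >= 0.75:
        return None
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def pairwise_dnds(aln: CodonAlignment, jukes_cantor: bool = False) -> SelectionStats:
    """NG86 divergence statistics for a pairwise codon alignment.

    Site totals are the average of the two sequences' totals; dn and ds
    are proportions of differences per site (optionally Jukes-Cantor
    corrected).  ``dnds`` is None when ds is zero or undefined.
    """
    pairs = aln.comparable_codon_pairs()
    if not pairs:
        raise ValueError(f"{aln.gene_id}: no comparable codons")
    n_a = s_a = n_b = s_b = 0.0
    nd = sd = 0.0
    for ca, cb in pairs:
        sa, na = ng86_site_counts(ca)
        sb, nb = ng86_site_counts(cb)
        s_a += sa
        n_a += na
        s_b += sb
        n_b += nb
        d_n, d_s = codon_path_differences(ca, cb)
        nd += d_n
        sd += d_s
    n_sites = (n_a + n_b) / 2.0
    s_sites = (s_a + s_b) / 2.0
    dn: float | None = nd / n_sites if n_sites > 0 else None
    ds: float | None = sd / s_sites if s_sites > 0 else None
    if jukes_cantor:
        dn = _jc_correct(dn) if dn is not None else None
        ds = _jc_correct(ds) if ds is not None else None
    dnds = None
    if dn is not None and ds is not None and ds > 0:
        dnds = dn / ds
    return SelectionStats(
        gene_id=aln.gene_id,
        n_sites=n_sites,
        s_sites=s_sites,
        nd=nd,
        sd=sd,
        dn=dn,
        ds=ds,
        dnds=dnds,
        n_codons=len(pairs),
    )


def normalize_consequence(csq: str) -> str:
    csq = csq.strip().lower()
    return _CSQ_ALIASES.get(csq, csq)


def polymorphism_pnps(consequences: Iterable[str]) -> tuple[int, int, float | None]:
    """Count nonsynonymous (missense + stop-gain) vs synonymous polymorphisms.

    Consequences outside the two whitelists (intronic, UTR, splice, ...)
    are ignored.  pN/pS is None when no synonymous polymorphism exists.
    """
    pn = ps = 0
    for csq in consequences:
        c = normalize_consequence(csq)
        if c in NONSYNONYMOUS_CONSEQUENCES:
            pn += 1
        elif c in SYNONYMOUS_CONSEQUENCES:
            ps += 1
    pnps = pn / ps if ps > 0 else None
    return pn, ps, pnps


def neutrality_index(
    pn: float, ps: float, dn: float, ds: float
) -> float | None:
    """NI = (pN/pS) / (dN/dS); None when ps, dn or ds is zero.

    The ratio is scale-invariant, so the divergence pair may be given
    either as per-site rates or as raw difference counts, as long as the
    polymorphism pair uses the matching convention.
    """
    if min(pn, ps, dn, ds) < 0:
        raise ValueError("all NI inputs must be non-negative")
    if ps == 0 or dn == 0 or ds == 0:
        return None
    return (pn / ps) / (dn / ds)


def attach_polymorphism(
    stats: SelectionStats, consequences: Iterable[str]
) -> SelectionStats:
    """Fill pn/ps/pnps/ni on a divergence result from per-gene variants.

    The NI uses the McDonald-Kreitman count form (pn/ps)/(nd/sd): both
    ratios are raw counts, so the per-site normalisation factors cancel
    and neutral evolution gives NI = 1.
    """
    pn, ps, pnps = polymorphism_pnps(consequences)
    stats.pn, stats.ps, stats.pnps = pn, ps, pnps
    stats.ni = neutrality_index(pn, ps, stats.nd, stats.sd)
    return stats


@dataclass
class GeneSetComparison:
    statistic: float
    pvalue: float
    n_a: int
    n_b: int
    n_excluded: int
    alternative: str


def compare_gene_sets(
    values_a: Sequence[float | None],
    values_b: Sequence[float | None],
    alternative: str = "less",
) -> GeneSetComparison:
    """Wilcoxon rank-sum (Mann-Whitney U) comparison of per-gene metrics.

    ``alternative='less'`` tests whether values in set A tend to be
    smaller than those in set B.  Genes with an undefined metric (None
    or NaN) are excluded and counted in ``n_excluded``.
    """
    def clean(vals: Sequence[float | None]) -> list[float]:
        return [v for v in vals if v is not None and not (isinstance(v, float) and math.isnan(v))]

    a, b = clean(values_a), clean(values_b)
    n_excluded = (len(values_a) - len(a)) + (len(values_b) - len(b))
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least two genes with a defined metric per set")
    res = _sps.mannwhitneyu(a, b, alternative=alternative)
    return GeneSetComparison(
        statistic=float(res.statistic),
        pvalue=float(res.pvalue),
        n_a=len(a),
        n_b=len(b),
        n_excluded=n_excluded,
        alternative=alternative,
    )
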