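"""NG86 counting, pN/pS, Neutrality Index and gene-set comparison.

The enumeration oracle below is independent of the implementation: it
hard-codes the standard genetic code and walks mutational paths with
itertools directly.
"""

from fractions import Fraction
from itertools import permutations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from varlens.selection import (
    CodonAlignment,
    CodonError,
    GeneSetComparison,
    attach_polymorphism,
    codon_path_differences,
    compare_gene_sets,
    neutrality_index,
    ng86_site_counts,
    pairwise_dnds,
    polymorphism_pnps,
)

# independent statement of the standard genetic code (TCAG order)
_B = "TCAG"
_AA = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
ORACLE_CODE = {
    a + b + c: _AA[16 * i + 4 * j + k]
    for i, a in enumerate(_B)
    for j, b in enumerate(_B)
    for k, c in enumerate(_B)
}
SENSE = sorted(c for c, aa in ORACLE_CODE.items() if aa != "*")


def oracle_site_counts(codon):
    syn = Fraction(0)
    for i in range(3):
        for b in "ACGT":
            if b == codon[i]:
                continue
            neighbour = codon[:i] + b + codon[i + 1 :]
            if ORACLE_CODE[neighbour] != "*" and ORACLE_CODE[neighbour] == ORACLE_CODE[codon]:
                syn += Fraction(1, 3)
    return float(syn), float(3 - syn)


def oracle_path_differences(c1, c2):
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    paths = []
    for order in permutations(diff):
        cur, nd, sd, ok = c1, 0, 0, True
        for i in order:
            nxt = cur[:i] + c2[i] + cur[i + 1 :]
            if ORACLE_CODE[nxt] == "*":
                ok = False
                break
            if ORACLE_CODE[nxt] == ORACLE_CODE[cur]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        if ok:
            paths.append((nd, sd))
    if not paths:
        return None
    return (
        sum(p[0] for p in paths) / len(paths),
        sum(p[1] for p in paths) / len(paths),
    )


class TestSiteCounts:
    @pytest.mark.parametrize(
        "codon,syn,nonsyn",
        [("TTT", 1 / 3, 8 / 3), ("TGG", 0.0, 3.0), ("CTC", 1.0, 2.0)],
    )
    def test_known_codons(self, codon, syn, nonsyn):
        s, n = ng86_site_counts(codon)
        assert s == pytest.approx(syn)
        assert n == pytest.approx(nonsyn)

    def test_rejects_stop_gap_and_ambiguity(self):
        for bad in ("TAA", "TGA", "TAG", "T-G", "NNT", "AT"):
            with pytest.raises((CodonError, ValueError)):
                ng86_site_counts(bad)


class TestPathDifferences:
    def test_single_synonymous_step(self):
        assert codon_path_differences("TTT", "TTC") == (0.0, 1.0)

    def test_identical(self):
        assert codon_path_differences("ATG", "ATG") == (0.0, 0.0)

    def test_stop_blocked_path_excluded(self):
        # TAT -> TAG (stop) -> TGG is forbidden; only TAT -> TGT -> TGG
        # survives, and both its steps are nonsynonymous
        assert codon_path_differences("TAT", "TGG") == (2.0, 0.0)

    def test_oracle_agreement_on_all_pairs_is_checked_in_acceptance(self):
        # spot-check a handful of multi-hit pairs here
        for c1, c2 in [("TTT", "GGG"), ("ATG", "TCA"), ("AAA", "CCC")]:
            expected = oracle_path_differences(c1, c2)
            got = codon_path_differences(c1, c2)
            assert got == pytest.approx(expected)


class TestPairwiseDnds:
    def test_identical_sequences(self):
        stats = pairwise_dnds(CodonAlignment("g", "ATGTTT", "ATGTTT"))
        assert stats.nd == 0 and stats.sd == 0
        assert stats.dnds is None

    def test_single_synonymous_codon(self):
        stats = pairwise_dnds(CodonAlignment("g", "TTT", "TTC"))
        assert stats.sd == 1.0 and stats.nd == 0.0
        assert stats.s_sites == pytest.approx(1 / 3)
        assert stats.ds == pytest.approx(3.0)
        assert stats.dnds == 0.0

    def test_all_codons_gapped_is_an_error(self):
        with pytest.raises(ValueError, match="no comparable codons"):
            pairwise_dnds(CodonAlignment("g", "---", "---"))

    def test_internal_stop_rejected(self):
        with pytest.raises(ValueError, match="internal stop"):
            CodonAlignment("g", "TAAATG", "TAAATG")

    def test_gap_must_align_to_codon(self):
        with pytest.raises(ValueError, match="gap"):
            CodonAlignment("g", "A-GTTT", "ATGTTT")

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        codons_a = [SENSE[i] for i in rng.integers(0, len(SENSE), 10)]
        codons_b = [SENSE[i] for i in rng.integers(0, len(SENSE), 10)]
        a, b = "".join(codons_a), "".join(codons_b)
        sa = pairwise_dnds(CodonAlignment("x", a, b))
        sb = pairwise_dnds(CodonAlignment("x", b, a))
        assert sa.nd == pytest.approx(sb.nd)
        assert sa.sd == pytest.approx(sb.sd)
        assert sa.n_sites == pytest.approx(sb.n_sites)
        assert sa.s_sites == pytest.approx(sb.s_sites)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_site_conservation_per_gene(self, seed):
        rng = np.random.default_rng(seed)
        seq = "".join(SENSE[i] for i in rng.integers(0, len(SENSE), 15))
        stats = pairwise_dnds(CodonAlignment("x", seq, seq))
        assert stats.n_sites + stats.s_sites == pytest.approx(3 * stats.n_codons)


class TestPolymorphism:
    def test_direct_counts(self):
        pn, ps, pnps = polymorphism_pnps(["missense", "missense", "stop_gain", "synonymous"])
        assert (pn, ps, pnps) == (3, 1, 3.0)

    def test_undefined_without_synonymous(self):
        assert polymorphism_pnps(["missense"]) == (1, 0, None)

    def test_noncoding_excluded(self):
        pn, ps, _ = polymorphism_pnps(
            ["missense", "intron", "splice", "5_prime_utr", "synonymous_variant"]
        )
        assert (pn, ps) == (1, 1)


class TestNeutralityIndex:
    def test_formula(self):
        assert neutrality_index(10, 5, 2, 4) == pytest.approx(4.0)
        assert neutrality_index(1, 1, 1, 1) == pytest.approx(1.0)

    def test_undefined_cases(self):
        assert neutrality_index(1, 0, 1, 1) is None
        assert neutrality_index(1, 1, 0, 1) is None
        assert neutrality_index(1, 1, 1, 0) is None

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            neutrality_index(-1, 1, 1, 1)

    def test_attach_polymorphism_fills_mk_ni(self):
        stats = pairwise_dnds(CodonAlignment("g", "TTTAAA", "TTCAAG"))
        stats = attach_polymorphism(stats, ["missense", "synonymous"])
        # pn/ps = 1; nd/sd = 0/2 -> NI undefined (no nonsyn divergence)
        assert stats.pn == 1 and stats.ps == 1
        assert stats.ni is None


class TestGeneSetComparison:
    def test_exact_rank_sum_p_for_complete_separation(self):
        nd = [0.1, 0.12, 0.15, 0.2, 0.25]
        ird = [0.3, 0.4, 0.5, 0.6, 0.7]
        cmp = compare_gene_sets(nd, ird, alternative="less")
        assert cmp.pvalue == pytest.approx(1 / 252, rel=1e-9)

    def test_identical_distributions_give_uniform_p(self):
        rng = np.random.default_rng(0)
        ps = []
        for _ in range(200):
            a, b = rng.normal(size=8), rng.normal(size=8)
            ps.append(compare_gene_sets(a, b, alternative="less").pvalue)
        assert 0.4 < float(np.mean(ps)) < 0.6

    def test_undefined_metrics_excluded_and_counted(self):
        cmp = compare_gene_sets([1.0, None, 2.0], [3.0, float("nan"), 4.0], "less")
        assert cmp.n_a == 2 and cmp.n_b == 2 and cmp.n_excluded == 2

    def test_empty_set_after_exclusion_errors(self):
        with pytest.raises(ValueError):
            compare_gene_sets([None, None], [1.0, 2.0], "less")
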