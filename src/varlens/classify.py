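"""Curated-database label harmonisation and allele-frequency filtering.

Harmonises HGMD / ClinVar / SwissVar classification strings into a
deleterious / benign / neither verdict, derives dual-species allele
frequency cutoffs as the maximum AF observed among curated deleterious
variants, flags putative benign variants whose AF in either species
exceeds its cutoff, selects reported putative pathogenic variants
(CADD >= 25, configurable gene exclusions), and applies the 50-nt
rule to call nonsense-mediated-decay (NMD) fate for loss-of-function
variants.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

HGMD_DELETERIOUS = frozenset({"Disease_causing_mutation"})
HGMD_VOCAB = HGMD_DELETERIOUS | frozenset({"Likely_disease_causing", "Polymorphism"})

CLINVAR_PATHOGENIC = frozenset({"Pathogenic", "Likely_pathogenic", "Pathogenic/Likely_pathogenic"})
CLINVAR_BENIGN = frozenset({"Benign", "Likely_benign", "Benign/Likely_benign"})
CLINVAR_VOCAB = (
    CLINVAR_PATHOGENIC
    | CLINVAR_BENIGN
    | frozenset({"Uncertain_significance", "Conflicting_interpretations_of_pathogenicity"})
)

SWISSVAR_DELETERIOUS = frozenset({"LP/P"})
SWISSVAR_BENIGN = frozenset({"LB/B"})
SWISSVAR_VOCAB = SWISSVAR_DELETERIOUS | SWISSVAR_BENIGN | frozenset({"US"})

NMD_FLAGS = ("nmd-likely", "nmd-escape", "not-lof")

#: minimum distance (nt) of a premature stop upstream of the last
#: exon-exon junction for NMD to be predicted (the 50-nt rule)
NMD_JUNCTION_RULE_NT = 50


class VocabularyError(ValueError):
    """Raised for a classification string outside the controlled lists."""


@dataclass
class CuratedLabel:
    """Per-variant classification strings from the three curated sources."""

    hgmd: str = ""
    clinvar: str = ""
    swissvar: str = ""
    harmonized: str | None = None


def _check_vocab(value: str, vocab: frozenset[str], source: str) -> None:
    if value and value not in vocab:
        raise VocabularyError(f"unknown {source} classification string: {value!r}")


def harmonize_labels(label: CuratedLabel) -> str:
    """Collapse three curated sources into deleterious / benign / neither.

    Deleterious requires a pathogenic-family string whose named benign
    exclusions do not apply; any benign-family string in the excluding
    source blocks deleterious assignment, while uncertain/conflicting
    strings do not.  Benign is any ClinVar benign-family or SwissVar
    LB/B string.  Benign wins over an otherwise-deleterious pattern
    because the deleterious rules all carry a not-benign exclusion.
    """
    _check_vocab(label.hgmd, HGMD_VOCAB, "HGMD")
    _check_vocab(label.clinvar, CLINVAR_VOCAB, "ClinVar")
    _check_vocab(label.swissvar, SWISSVAR_VOCAB, "SwissVar")

    clinvar_benign = label.clinvar in CLINVAR_BENIGN
    swissvar_benign = label.swissvar in SWISSVAR_BENIGN

    deleterious = (
        (label.hgmd in HGMD_DELETERIOUS and not clinvar_benign and not swissvar_benign)
        or (label.clinvar in CLINVAR_PATHOGENIC and not swissvar_benign)
        or (label.swissvar in SWISSVAR_DELETERIOUS and not clinvar_benign)
    )
    benign = clinvar_benign or swissvar_benign
    if benign:
        verdict = "benign"
    elif deleterious:
        verdict = "deleterious"
    else:
        verdict = "neither"
    label.harmonized = verdict
    return verdict


def harmonize_frame(curated: pd.DataFrame) -> pd.Series:
    """Vector version over a TSV-shaped frame with hgmd/clinvar/swissvar columns."""
    def _clean(x) -> str:
        if x is None or (isinstance(x, float) and math.isnan(x)) or pd.isna(x):
            return ""
        x = str(x)
        return "" if x == "." else x

    return pd.Series(
        [
            harmonize_labels(
                CuratedLabel(hgmd=_clean(r.hgmd), clinvar=_clean(r.clinvar), swissvar=_clean(r.swissvar))
            )
            for r in curated.itertuples(index=False)
        ],
        index=curated.index,
        name="harmonized",
    )


@dataclass
class AFCutoffs:
    """Per-species benign-filter cutoffs derived from deleterious variants."""

    macaque_cutoff: float
    human_cutoff: float
    n_deleterious_used: int

    def __post_init__(self) -> None:
        for c in (self.macaque_cutoff, self.human_cutoff):
            if not 0 <= c <= 1:
                raise ValueError("cutoffs must be proportions")


def derive_af_cutoffs(
    macaque_afs: Sequence[float | None], human_afs: Sequence[float | None]
) -> AFCutoffs:
    """Cutoff per species = maximum AF among curated deleterious variants.

    The two sequences run parallel over the deleterious set; missing
    AFs (None/NaN) are skipped per species.  An empty deleterious set,
    or one with no defined AF in a species, is an error.
    """
    if len(macaque_afs) != len(human_afs):
        raise ValueError("AF sequences must be parallel")
    if len(macaque_afs) == 0:
        raise ValueError("cannot derive cutoff from an empty deleterious set")

    def _max(vals: Sequence[float | None], species: str) -> float:
        clean = [v for v in vals if v is not None and not (isinstance(v, float) and math.isnan(v))]
        if not clean:
            raise ValueError(f"no defined {species} AF among deleterious variants")
        return float(max(clean))

    return AFCutoffs(
        macaque_cutoff=_max(macaque_afs, "macaque"),
        human_cutoff=_max(human_afs, "human"),
        n_deleterious_used=len(macaque_afs),
    )


def filter_putative_benign(
    macaque_af: float | None, human_af: float | None, cutoffs: AFCutoffs
) -> bool:
    """Benign-by-AF iff AF strictly exceeds either species cutoff.

    Comparison is strict ("higher than"); a missing AF in a species
    never triggers that species' clause.
    """
    def _defined(v: float | None) -> bool:
        return v is not None and not (isinstance(v, float) and math.isnan(v))

    if _defined(macaque_af) and macaque_af > cutoffs.macaque_cutoff:
        return True
    if _defined(human_af) and human_af > cutoffs.human_cutoff:
        return True
    return False


DEFAULT_GENE_EXCLUSIONS = frozenset({"RPGR"})


def select_reported_pathogenic(
    variants: pd.DataFrame,
    cadd_min: float = 25.0,
    gene_exclusions: Iterable[str] = DEFAULT_GENE_EXCLUSIONS,
) -> pd.Series:
    """Boolean mask of reported putative pathogenic variants.

    Pool: ClinVar pathogenic-family, or HGMD disease-causing not
    annotated benign in ClinVar.  Variants with CADD < ``cadd_min`` or
    in an excluded gene (copy-number-unstable regions) are rejected.
    Requires columns: clinvar, hgmd, cadd, gene.
    """
    excl = set(gene_exclusions)

    def _clean(x) -> str:
        return "" if pd.isna(x) or str(x) == "." else str(x)

    pool = []
    for r in variants.itertuples(index=False):
        clinvar, hgmd = _clean(r.clinvar), _clean(r.hgmd)
        in_pool = clinvar in CLINVAR_PATHOGENIC or (
            hgmd in HGMD_DELETERIOUS and clinvar not in CLINVAR_BENIGN
        )
        cadd_ok = (not pd.isna(r.cadd)) and r.cadd >= cadd_min
        pool.append(in_pool and cadd_ok and str(r.gene) not in excl)
    return pd.Series(pool, index=variants.index, name="reported_pathogenic")


@dataclass(frozen=True)
class TranscriptModel:
    """Exon structure of a coding transcript in CDS coordinates."""

    gene: str
    exon_cds_lengths: tuple[int, ...]

    def __post_init__(self) -> None:
        if not self.exon_cds_lengths or any(l <= 0 for l in self.exon_cds_lengths):
            raise ValueError("exon lengths must be positive")

    @property
    def n_exons(self) -> int:
        return len(self.exon_cds_lengths)

    @property
    def last_junction_cds(self) -> int:
        """CDS coordinate (0-based, nt) of the last exon-exon junction."""
        return sum(self.exon_cds_lengths[:-1])


def flag_lof_nmd(
    consequence: str,
    transcript: TranscriptModel,
    stop_cds_pos: int | None = None,
    splice_junction_index: int | None = None,
) -> str:
    """NMD fate of a loss-of-function variant.

    Stop-gains are nmd-likely iff the premature stop starts more than
    50 nt upstream of the last exon-exon junction; stops in the last
    exon (or within 50 nt of the final junction, or in single-exon
    transcripts) escape.  Canonical splice-site variants are nmd-likely
    by default, except those at the final intron, whose retention
    leaves the last junction unused.  Anything else is not-lof.
    """
    csq = consequence.strip().lower().replace("_variant", "")
    if csq in ("stop_gain", "stop_gained", "stopgain", "nonsense"):
        if stop_cds_pos is None:
            raise ValueError("stop-gain NMD call requires the stop's CDS position")
        if transcript.n_exons == 1:
            return "nmd-escape"
        distance = transcript.last_junction_cds - stop_cds_pos
        return "nmd-likely" if distance > NMD_JUNCTION_RULE_NT else "nmd-escape"
    if csq in ("splice", "splice_acceptor", "splice_donor", "splicing"):
        if splice_junction_index is not None and splice_junction_index == transcript.n_exons - 2:
            return "nmd-escape"
        return "nmd-likely"
    return "not-lof"
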