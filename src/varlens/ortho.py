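"""Cross-species coordinate mapping and consequence harmonisation.

Maps macaque SNVs to human coordinates through a flat per-base
orthology map (src_chrom, src_pos, dst_chrom, dst_pos, dst_ref,
strand), detects reference-allele swaps (a macaque alternate allele
that is the human reference base), classifies cross-species sharing
against a human allele-frequency table, and matches amino-acid level
consequences between the two gene annotations.

Coordinates are 1-based inclusive throughout (VCF convention).  Strand
flips complement both alleles on the destination genome.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import pandas as pd

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

STATUSES = ("unmapped", "shared-polymorphism", "alt-is-human-ref", "macaque-specific")

ORTHOLOGY_COLUMNS = ["src_chrom", "src_pos", "dst_chrom", "dst_pos", "dst_ref", "strand"]


@dataclass(frozen=True)
class OrthologyEntry:
    src_chrom: str
    src_pos: int
    dst_chrom: str
    dst_pos: int
    dst_ref: str
    strand_flip: bool


class OrthologyMap:
    """Per-base src->dst coordinate map with O(1) lookup."""

    def __init__(self, entries: Mapping[tuple[str, int], OrthologyEntry]):
        self._entries = dict(entries)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "OrthologyMap":
        missing = [c for c in ORTHOLOGY_COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"orthology map lacks columns: {missing}")
        entries: dict[tuple[str, int], OrthologyEntry] = {}
        for row in frame.itertuples(index=False):
            key = (str(row.src_chrom), int(row.src_pos))
            if key in entries:
                raise ValueError(f"duplicate source position {key}")
            dst_ref = str(row.dst_ref).upper()
            if dst_ref not in COMPLEMENT:
                raise ValueError(f"invalid destination reference base {dst_ref!r}")
            entries[key] = OrthologyEntry(
                src_chrom=key[0],
                src_pos=key[1],
                dst_chrom=str(row.dst_chrom),
                dst_pos=int(row.dst_pos),
                dst_ref=dst_ref,
                strand_flip=str(row.strand) in ("-", "flip", "True", "true"),
            )
        return cls(entries)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "OrthologyMap":
        return cls.from_frame(pd.read_csv(path, sep="\t", dtype={"src_chrom": str, "dst_chrom": str}))

    def lookup(self, chrom: str, pos: int) -> OrthologyEntry | None:
        return self._entries.get((str(chrom), int(pos)))

    def __len__(self) -> int:
        return len(self._entries)

    def inverse(self) -> "OrthologyMap":
        """dst->src map; useful for round-trip checking."""
        inv: dict[tuple[str, int], OrthologyEntry] = {}
        for e in self._entries.values():
            # the inverse lacks a source reference base, so reuse dst_ref
            inv[(e.dst_chrom, e.dst_pos)] = OrthologyEntry(
                src_chrom=e.dst_chrom,
                src_pos=e.dst_pos,
                dst_chrom=e.src_chrom,
                dst_pos=e.src_pos,
                dst_ref=e.dst_ref,
                strand_flip=e.strand_flip,
            )
        return OrthologyMap(inv)


@dataclass
class LiftedVariant:
    src_chrom: str
    src_pos: int
    src_ref: str
    src_alt: str
    dst_chrom: str | None
    dst_pos: int | None
    dst_ref: str | None = None
    ref: str | None = None  # source ref expressed on the destination strand
    alt: str | None = None
    strand_flip: bool = False
    ref_mismatch: bool = False

    @property
    def mapped(self) -> bool:
        return self.dst_pos is not None


def lift_variant(
    chrom: str, pos: int, ref: str, alt: str, ortho_map: OrthologyMap
) -> LiftedVariant:
    """Map one biallelic SNV to the destination genome.

    Returns strand-adjusted alleles and flags a reference mismatch when
    the (strand-adjusted) source reference differs from the destination
    reference base.  Positions absent from the map come back unmapped.
    """
    ref, alt = ref.upper(), alt.upper()
    if ref not in COMPLEMENT or alt not in COMPLEMENT or ref == alt:
        raise ValueError(f"not a biallelic SNV: {ref}>{alt}")
    entry = ortho_map.lookup(chrom, pos)
    if entry is None:
        return LiftedVariant(chrom, pos, ref, alt, None, None)
    if entry.strand_flip:
        lifted_ref, lifted_alt = COMPLEMENT[ref], COMPLEMENT[alt]
    else:
        lifted_ref, lifted_alt = ref, alt
    return LiftedVariant(
        src_chrom=chrom,
        src_pos=pos,
        src_ref=ref,
        src_alt=alt,
        dst_chrom=entry.dst_chrom,
        dst_pos=entry.dst_pos,
        dst_ref=entry.dst_ref,
        ref=lifted_ref,
        alt=lifted_alt,
        strand_flip=entry.strand_flip,
        ref_mismatch=lifted_ref != entry.dst_ref,
    )


class HumanFrequencyDB:
    """Human population allele frequencies keyed by (chrom,pos,ref,alt)."""

    def __init__(self, afs: Mapping[tuple[str, int, str, str], float]):
        self._afs = dict(afs)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "HumanFrequencyDB":
        required = ["chrom", "pos", "ref", "alt", "af"]
        missing = [c for c in required if c not in frame.columns]
        if missing:
            raise ValueError(f"frequency table lacks columns: {missing}")
        return cls(
            {
                (str(r.chrom), int(r.pos), str(r.ref).upper(), str(r.alt).upper()): float(r.af)
                for r in frame.itertuples(index=False)
            }
        )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "HumanFrequencyDB":
        return cls.from_frame(pd.read_csv(path, sep="\t", dtype={"chrom": str}))

    def lookup(self, chrom: str, pos: int, ref: str, alt: str) -> float | None:
        return self._afs.get((str(chrom), int(pos), ref.upper(), alt.upper()))

    def __len__(self) -> int:
        return len(self._afs)


@dataclass
class CrossSpeciesStatus:
    status: str
    human_af: float | None = None
    consequence_match: bool | None = None

    def __post_init__(self) -> None:
        if self.status not in STATUSES:
            raise ValueError(f"unknown status {self.status!r}")
        if self.human_af is not None and self.status == "unmapped":
            raise ValueError("unmapped variants cannot carry a human AF")


def classify_cross_species_status(
    lifted: LiftedVariant, human_db: HumanFrequencyDB
) -> CrossSpeciesStatus:
    """Partition a lifted variant into one of four exclusive statuses.

    shared-polymorphism: the same alternate allele segregates in the
    human table at the mapped site; alt-is-human-ref: the macaque
    alternate equals the human reference base; otherwise
    macaque-specific.
    """
    if not lifted.mapped:
        return CrossSpeciesStatus("unmapped")
    af = human_db.lookup(lifted.dst_chrom, lifted.dst_pos, lifted.dst_ref, lifted.alt)
    if af is not None:
        return CrossSpeciesStatus("shared-polymorphism", human_af=af)
    if lifted.alt == lifted.dst_ref:
        return CrossSpeciesStatus("alt-is-human-ref")
    return CrossSpeciesStatus("macaque-specific")


@dataclass(frozen=True)
class ProteinConsequence:
    """Protein-level effect of a coding SNV in one gene annotation."""

    gene: str
    kind: str  # missense | synonymous | stop_gain | ...
    ref_aa: str | None = None
    protein_pos: int | None = None
    alt_aa: str | None = None


def match_amino_acid_consequence(
    a: ProteinConsequence | None, b: ProteinConsequence | None
) -> tuple[bool, str | None]:
    """True iff gene, kind, ref AA, protein position and alt AA all agree.

    Exact protein-level agreement is required; a missing annotation on
    either side is a non-match with the reason recorded.
    """
    if a is None or b is None:
        return False, "missing-annotation"
    if a.gene != b.gene:
        return False, "gene-mismatch"
    if a.kind != b.kind:
        return False, "kind-mismatch"
    if (a.ref_aa, a.protein_pos, a.alt_aa) != (b.ref_aa, b.protein_pos, b.alt_aa):
        return False, "amino-acid-mismatch"
    return True, None
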