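"""Genome-build-independent set encoding via flanking sequences.

Coordinate-based encoding breaks when two parties call variants against
different reference builds.  This encoding removes the coordinate
dependence: segments are anchored at known common SNPs (dbSNP-style
landmarks present in every build), and each variant inside a segment is
represented not by its position but by its 500 bp flanking sequence on
each side (1000 bp total, variant base excluded).  The per-segment
concatenation of flank signatures, hashed with the protocol's salted hash,
yields set elements that are identical across builds whenever the local
sequence context is identical — empirically almost always, so two
individuals on different builds can still compare sketches.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Sequence, Tuple

import numpy as np

from .genome_encoding import ReferenceGenome
from .secure_sketch import ProtocolParams, salted_hash

__all__ = [
    "Anchor",
    "AnchorList",
    "FlankSignature",
    "SegmentWindow",
    "anchor_segments",
    "flank_signature",
    "build_independent_element",
    "build_independent_set",
    "build_stability",
    "read_anchor_tsv",
]

DEFAULT_FLANK = 500


@dataclass(frozen=True)
class Anchor:
    chrom: str
    position: int
    snp_id: str


@dataclass(frozen=True)
class AnchorList:
    """Known common SNPs usable as segment anchors, sorted within chromosome."""

    anchors: Tuple[Anchor, ...]

    def __post_init__(self) -> None:
        ids = [a.snp_id for a in self.anchors]
        if len(set(ids)) != len(ids):
            raise ValueError("anchor SNP ids must be unique")
        by_chrom: dict = {}
        for a in self.anchors:
            if by_chrom.get(a.chrom, -1) > a.position:
                raise ValueError("anchors must be sorted by position within chromosome")
            by_chrom[a.chrom] = a.position

    def for_chrom(self, chrom: str) -> List[Anchor]:
        return [a for a in self.anchors if a.chrom == chrom]


@dataclass(frozen=True)
class SegmentWindow:
    """Half-open anchor-started window [start, start + L) on one chromosome."""

    chrom: str
    start: int
    end: int
    anchor_id: str


@dataclass(frozen=True)
class FlankSignature:
    """1000 bp of context around a variant: 500 bp each side, variant base
    excluded, N-padded at contig edges."""

    position: int
    flank: str
    build_id: str

    def __post_init__(self) -> None:
        if len(self.flank) % 2 != 0:
            raise ValueError("flank string must have even length (two half-flanks)")


def anchor_segments(anchors: AnchorList, L: int) -> List[SegmentWindow]:
    """Greedy left-to-right anchor-started windows, never overlapping.

    The first anchor on a chromosome opens [a, a+L); the next window opens
    at the first anchor at or beyond the previous window's end.
    """
    if not anchors.anchors:
        raise ValueError("anchor list is empty")
    if L <= 0:
        raise ValueError("segment length must be positive")
    windows: List[SegmentWindow] = []
    chroms = []
    for a in anchors.anchors:
        if a.chrom not in chroms:
            chroms.append(a.chrom)
    for chrom in chroms:
        nxt = None
        for a in anchors.for_chrom(chrom):
            if nxt is None or a.position >= nxt:
                windows.append(SegmentWindow(chrom, a.position, a.position + L, a.snp_id))
                nxt = a.position + L
    return windows


def flank_signature(
    position: int,
    reference: ReferenceGenome,
    chrom: str,
    flank: int = DEFAULT_FLANK,
) -> FlankSignature:
    """Concatenated upstream+downstream flanks of a variant position.

    Upper-cased; the variant base itself is excluded; positions within
    ``flank`` of a contig edge are padded with ``N``.
    """
    if reference.sequences is None or chrom not in reference.sequences:
        raise ValueError("reference carries no sequence for flank extraction")
    seq = reference.sequences[chrom]
    if not 0 <= position < len(seq):
        raise ValueError(f"position {position} outside chromosome {chrom!r}")
    left = seq[max(0, position - flank) : position].upper()
    left = "N" * (flank - len(left)) + left
    right = seq[position + 1 : position + 1 + flank].upper()
    right = right + "N" * (flank - len(right))
    return FlankSignature(position, left + right, reference.build_id)


def build_independent_element(
    window: SegmentWindow,
    variant_positions: Sequence[int],
    reference: ReferenceGenome,
    params: ProtocolParams,
    flank: int = DEFAULT_FLANK,
) -> int:
    """Hash of the position-ordered concatenation of flank signatures of all
    variants inside a window (one haplotype).  Windows with no variants emit
    a reserved element derived from the anchor id, so that window counts
    stay comparable across individuals."""
    inside = sorted(p for p in variant_positions if window.start <= p < window.end)
    if not inside:
        payload = b"empty-window:" + window.anchor_id.encode()
    else:
        sigs = [flank_signature(p, reference, window.chrom, flank).flank for p in inside]
        payload = "".join(sigs).encode()
    # map the byte payload onto the salted-hash integer domain so downstream
    # sketching is identical to the coordinate-based path
    as_int = int.from_bytes(payload, "big")
    return salted_hash(as_int, params)


def build_independent_set(
    windows: Sequence[SegmentWindow],
    haplotype_positions: Tuple[Sequence[int], Sequence[int]],
    reference: ReferenceGenome,
    params: ProtocolParams,
    flank: int = DEFAULT_FLANK,
) -> List[int]:
    """Per-individual element list: one element per (window, haplotype)."""
    out: List[int] = []
    for w in windows:
        for hap_pos in haplotype_positions:
            out.append(build_independent_element(w, hap_pos, reference, params, flank))
    return out


def build_stability(
    signatures_a: Sequence[FlankSignature],
    signatures_b: Sequence[FlankSignature],
) -> float:
    """Fraction of SNP-id-aligned flank pairs whose hashes differ between two
    builds (the build-portability failure rate)."""
    if len(signatures_a) != len(signatures_b):
        raise ValueError("signature lists must be aligned (equal length)")
    if not signatures_a:
        raise ValueError("no signatures to compare")
    import hashlib

    mismatched = sum(
        1
        for a, b in zip(signatures_a, signatures_b)
        if hashlib.sha256(a.flank.encode()).digest()
        != hashlib.sha256(b.flank.encode()).digest()
    )
    return mismatched / len(signatures_a)


def read_anchor_tsv(path: str) -> AnchorList:
    """Anchor list from a TSV with columns chrom, pos, id (no header)."""
    anchors = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            chrom, pos, snp_id = line.split("\t")[:3]
            anchors.append(Anchor(chrom, int(pos), snp_id))
    return AnchorList(tuple(anchors))
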