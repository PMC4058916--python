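"""File formats: phased VCF input, FASTA references, pedigree export.

Input genomes are phased VCFs (GT with ``|`` separators); an unphased
genotype is an error, not something to fix silently — phasing belongs to
dedicated tools.  Only single-base substitutions participate in the
encoding; indels, multi-allelic and other records are skipped and counted.
References come from FASTA (via pyfaidx) or from a ``.fai`` index alone
when only chromosome lengths are needed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .genome_encoding import PhasedIndividual, ReferenceGenome
from .pedigree_sim import Pedigree, SimIndividual, label_pairs

logger = logging.getLogger("cryptokin")

__all__ = [
    "UnphasedGenotypeError",
    "read_phased_vcf",
    "reference_from_fasta",
    "reference_from_fai",
    "write_pedigree_vcf",
    "write_pedigree_tsv",
    "write_labeled_pairs_tsv",
]


class UnphasedGenotypeError(ValueError):
    """A ``/``-separated genotype was found where phased data is required."""


def read_phased_vcf(path: str) -> List[PhasedIndividual]:
    """Parse a phased VCF into per-haplotype variant position sets.

    Positions are 0-based.  Non-SNV and multi-allelic records are skipped
    (logged with a count); an unphased genotype raises
    ``UnphasedGenotypeError`` naming the record.
    """
    import pysam

    skipped = 0
    with pysam.VariantFile(path) as vcf:
        samples = list(vcf.header.samples)
        variants: Dict[str, Dict[str, Tuple[List[int], List[int]]]] = {
            s: {} for s in samples
        }
        for rec in vcf:
            alts = rec.alts or ()
            if len(alts) != 1 or len(rec.ref) != 1 or len(alts[0]) != 1:
                skipped += 1
                continue
            for s in samples:
                sample = rec.samples[s]
                gt = sample.get("GT")
                if gt is None or all(a is None for a in gt):
                    continue
                if len(gt) == 2 and not sample.phased:
                    raise UnphasedGenotypeError(
                        f"unphased genotype for sample {s} at "
                        f"{rec.chrom}:{rec.pos}; phase the input first"
                    )
                per_chrom = variants[s].setdefault(rec.chrom, ([], []))
                for hap_idx, allele in enumerate(gt[:2]):
                    if allele:
                        per_chrom[hap_idx].append(rec.start)
    if skipped:
        logger.info("skipped %d non-SNV/multi-allelic records", skipped)
    out = []
    for s in samples:
        per_chrom = {
            chrom: (
                np.array(sorted(h1), dtype=np.int64),
                np.array(sorted(h2), dtype=np.int64),
            )
            for chrom, (h1, h2) in variants[s].items()
        }
        out.append(PhasedIndividual(s, per_chrom))
    return out


def reference_from_fasta(path: str, build_id: Optional[str] = None) -> ReferenceGenome:
    """Reference with sequences, via pyfaidx."""
    from pyfaidx import Fasta

    fa = Fasta(path)
    chroms = tuple((name, len(fa[name])) for name in fa.keys())
    seqs = {name: str(fa[name][:]) for name in fa.keys()}
    return ReferenceGenome(build_id or path, chroms, seqs)


def reference_from_fai(path: str, build_id: Optional[str] = None) -> ReferenceGenome:
    """Lengths-only reference from a .fai index (no sequence available)."""
    chroms = []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 2:
                chroms.append((parts[0], int(parts[1])))
    return ReferenceGenome(build_id or path, tuple(chroms))


# ---------------------------------------------------------------------------
# Pedigree export
# ---------------------------------------------------------------------------


def write_pedigree_vcf(ped: Pedigree, path: str, generation: Optional[int] = None) -> None:
    """Phased VCF of simulated individuals (one generation or everyone).

    The variant allele is written as A->T at every site; the encoding only
    ever looks at presence/absence of a single-base difference.
    """
    inds = (
        ped.generation_members(generation)
        if generation is not None
        else sorted(ped.individuals.values(), key=lambda i: i.individual_id)
    )
    inds = sorted(inds, key=lambda i: i.individual_id)
    pos = ped.catalog.positions
    carriers: List[Tuple[np.ndarray, np.ndarray]] = []
    n = ped.catalog.n_sites
    for ind in inds:
        c1 = np.zeros(n, dtype=bool)
        c2 = np.zeros(n, dtype=bool)
        c1[ind.hap1] = True
        c2[ind.hap2] = True
        carriers.append((c1, c2))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID=1,length={ped.config.genome_length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(i.individual_id for i in inds)
            + "\n"
        )
        for j in range(n):
            gts = "\t".join(
                f"{int(c1[j])}|{int(c2[j])}" for c1, c2 in carriers
            )
            fh.write(f"1\t{int(pos[j]) + 1}\t.\tA\tT\t.\tPASS\t.\tGT\t{gts}\n")


def write_pedigree_tsv(ped: Pedigree, path: str) -> None:
    """Pedigree table: id, sire, dam, generation, subpopulation."""
    with open(path, "w") as fh:
        fh.write("id\tsire\tdam\tgeneration\tpop\n")
        for ind in sorted(ped.individuals.values(), key=lambda i: i.individual_id):
            sire, dam = ind.parents if ind.parents else (".", ".")
            fh.write(f"{ind.individual_id}\t{sire}\t{dam}\t{ind.generation}\t{ind.pop}\n")


def write_labeled_pairs_tsv(
    ped: Pedigree, path: str, ids: Optional[Sequence[str]] = None
) -> None:
    with open(path, "w") as fh:
        fh.write("id_a\tid_b\trelationship\n")
        for lab in label_pairs(ped, ids):
            fh.write(f"{lab.id_a}\t{lab.id_b}\t{lab.relationship}\n")
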