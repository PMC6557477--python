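"""Strain-difference SNP loading and allele-window reconstruction.

A biallelic SNP between two inbred strains acts as a pair of natural
alleles: the reference strain carries the genome base, the alternative
strain the substituted base.  For motif scoring, each SNP is expanded into
a pair of sequence windows of length 2L (L = motif length) with the SNP at
0-based offset L-1, so that every L-window overlapping the SNP is contained
in the pair.  The two windows differ at exactly one position.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import pysam

log = logging.getLogger(__name__)

_SNV_BASES = frozenset("ACGT")


class ReferenceMismatchError(ValueError):
    """Genome base at the SNP position does not match the recorded ref allele."""


@dataclass(frozen=True)
class SnpRecord:
    """One biallelic single-nucleotide strain difference.

    ``ref_allele`` is the base of the reference strain (the genome
    assembly, C57BL/6J role); ``alt_allele`` the alternative strain
    (FVB/NJ role).  ``pos`` is 1-based, as in VCF.
    """

    id: str
    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    pass_quality: bool = True

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"{self.id}: position must be >= 1")
        if self.ref_allele not in _SNV_BASES or self.alt_allele not in _SNV_BASES:
            raise ValueError(f"{self.id}: alleles must be single bases in ACGT")
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"{self.id}: ref and alt alleles are identical")


@dataclass(frozen=True)
class AlleleWindowPair:
    """Paired reference/alternative sequence windows around one SNP.

    Coordinates are 0-based half-open on the genome.  ``ref_seq`` and
    ``alt_seq`` have equal length and differ at exactly ``snp_offset``.
    """

    snp: SnpRecord
    window_start: int
    window_end: int
    ref_seq: str
    alt_seq: str
    snp_offset: int

    def __post_init__(self) -> None:
        if len(self.ref_seq) != len(self.alt_seq):
            raise ValueError("ref and alt windows must have equal length")
        diffs = [i for i, (a, b) in enumerate(zip(self.ref_seq, self.alt_seq)) if a != b]
        if diffs != [self.snp_offset]:
            raise ValueError(
                f"{self.snp.id}: windows must differ exactly at snp_offset "
                f"{self.snp_offset}, differ at {diffs}"
            )


def load_snps(vcf_path: str | Path, require_pass: bool = True) -> Iterator[SnpRecord]:
    """Stream biallelic SNVs from a VCF, dropping everything else.

    Indels, MNPs and multi-allelic sites are dropped (counted and logged).
    With ``require_pass`` (default), only FILTER == PASS records are kept.
    Unsorted input triggers a warning but records are passed through.
    """
    try:
        vcf = pysam.VariantFile(str(vcf_path))
    except (OSError, ValueError) as exc:
        raise ValueError(f"{vcf_path}: cannot parse VCF header: {exc}") from exc

    dropped_shape = dropped_filter = kept = 0
    last: dict[str, int] = {}
    warned_unsorted = False
    counter = 0
    with vcf:
        for rec in vcf:
            counter += 1
            if not warned_unsorted and rec.chrom in last and rec.pos < last[rec.chrom]:
                log.warning("%s: records are not position-sorted", vcf_path)
                warned_unsorted = True
            last[rec.chrom] = rec.pos

            alts = rec.alts or ()
            if (
                len(alts) != 1
                or len(rec.ref) != 1
                or len(alts[0]) != 1
                or rec.ref not in _SNV_BASES
                or alts[0] not in _SNV_BASES
            ):
                dropped_shape += 1
                continue
            filters = list(rec.filter.keys())
            is_pass = filters == ["PASS"] or filters == []
            if require_pass and not is_pass:
                dropped_filter += 1
                continue
            kept += 1
            yield SnpRecord(
                id=rec.id or f"{rec.chrom}:{rec.pos}",
                chrom=rec.chrom,
                pos=rec.pos,
                ref_allele=rec.ref,
                alt_allele=alts[0],
                pass_quality=is_pass,
            )
    log.info(
        "%s: kept %d biallelic SNVs (%d non-SNV/multi-allelic dropped, %d failed FILTER)",
        vcf_path, kept, dropped_shape, dropped_filter,
    )


def build_allele_windows(snp: SnpRecord, genome, motif_length: int) -> AlleleWindowPair:
    """Reconstruct the 2L reference/alternative windows around one SNP.

    ``genome`` is an indexed FASTA (a ``pyfaidx.Fasta``).  The window spans
    2L bases with the SNP at offset L-1, truncated at chromosome ends with
    the offset adjusted.  Raises :class:`ReferenceMismatchError` when the
    genome base disagrees with the recorded reference allele, and
    ``KeyError`` when the chromosome is absent from the FASTA.
    """
    if snp.chrom not in genome:
        raise KeyError(f"chromosome {snp.chrom!r} absent from genome FASTA")
    chrom_len = len(genome[snp.chrom])
    if not 1 <= snp.pos <= chrom_len:
        raise ValueError(f"{snp.id}: position {snp.pos} outside {snp.chrom} (len {chrom_len})")

    L = motif_length
    pos0 = snp.pos - 1
    start = max(0, pos0 - (L - 1))
    end = min(chrom_len, pos0 - (L - 1) + 2 * L)
    ref_seq = str(genome[snp.chrom][start:end]).upper()
    offset = pos0 - start

    if ref_seq[offset] != snp.ref_allele:
        raise ReferenceMismatchError(
            f"{snp.id}: genome base {ref_seq[offset]} at {snp.chrom}:{snp.pos} "
            f"!= recorded ref allele {snp.ref_allele}"
        )
    alt_seq = ref_seq[:offset] + snp.alt_allele + ref_seq[offset + 1 :]
    return AlleleWindowPair(
        snp=snp,
        window_start=start,
        window_end=end,
        ref_seq=ref_seq,
        alt_seq=alt_seq,
        snp_offset=offset,
    )


def iter_allele_windows(
    snps: Iterable[SnpRecord], genome, motif_length: int
) -> Iterator[AlleleWindowPair]:
    """Yield allele-window pairs, skipping (and logging) reference mismatches."""
    mismatches = 0
    for snp in snps:
        try:
            yield build_allele_windows(snp, genome, motif_length)
        except ReferenceMismatchError as exc:
            mismatches += 1
            log.warning("skipping %s: %s", snp.id, exc)
    if mismatches:
        log.info("skipped %d SNPs with genome/VCF reference mismatches", mismatches)
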