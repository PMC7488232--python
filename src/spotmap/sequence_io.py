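"""Genome, variant and gene-model containers plus FASTA/VCF/GFF3 I/O.

The pipeline models two fixed haplotypes: a reference genome (the "BW"
allele) and an alternate species haplotype (the "PO" allele) obtained by
applying a validated set of SNPs and short indels to the reference.  All
coordinates visible in files or reports are 1-based inclusive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

_VALID_BASES = frozenset("ACGTN")
_ALLELE_BASES = frozenset("ACGT")


class SpotmapError(ValueError):
    """Base error for invalid inputs anywhere in the pipeline."""


@dataclass(frozen=True)
class Interval:
    """1-based inclusive genomic interval."""

    contig: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise SpotmapError(
                f"invalid interval {self.contig}:{self.start}-{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def contains(self, contig: str, pos: int) -> bool:
        return contig == self.contig and self.start <= pos <= self.end


@dataclass
class Genome:
    """Ordered collection of named contigs of uppercase A/C/G/T/N sequence."""

    contigs: dict[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.contigs.items():
            if not name:
                raise SpotmapError("empty contig name")
            bad = set(seq) - _VALID_BASES
            if bad:
                raise SpotmapError(f"contig {name!r} has invalid characters {bad}")

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.contigs.values())

    def fetch(self, contig: str, start: int, end: int) -> str:
        """Return the sequence of a 1-based inclusive window."""
        seq = self.contigs[contig]
        if not (1 <= start <= end <= len(seq)):
            raise SpotmapError(f"window {contig}:{start}-{end} out of bounds")
        return seq[start - 1 : end]


@dataclass(frozen=True)
class Variant:
    """Anchored biallelic variant between the two haplotypes.

    ``pos`` is the 1-based position of the first reference base.  Indels use
    the VCF anchored-base convention: ref and alt share their first base.
    """

    contig: str
    pos: int
    ref_allele: str
    alt_allele: str

    def __post_init__(self) -> None:
        for allele in (self.ref_allele, self.alt_allele):
            if not allele or set(allele) - _ALLELE_BASES:
                raise SpotmapError(
                    f"bad allele {allele!r} at {self.contig}:{self.pos}"
                )
        if self.ref_allele == self.alt_allele:
            raise SpotmapError(f"ref == alt at {self.contig}:{self.pos}")
        self.kind  # reject equal-length multi-base substitutions up front

    @property
    def kind(self) -> str:
        """One of ``SNP``, ``insertion``, ``deletion``."""
        nr, na = len(self.ref_allele), len(self.alt_allele)
        if nr == 1 and na == 1:
            return "SNP"
        if na > nr:
            return "insertion"
        if na < nr:
            return "deletion"
        raise SpotmapError(
            f"unsupported multi-base substitution at {self.contig}:{self.pos}"
        )

    @property
    def end(self) -> int:
        """1-based inclusive end of the reference span."""
        return self.pos + len(self.ref_allele) - 1

    def length_change(self) -> int:
        return len(self.alt_allele) - len(self.ref_allele)


@dataclass
class GeneModel:
    """A single transcript's exon/CDS structure on the genome."""

    gene_id: str
    transcript_id: str
    contig: str
    strand: str
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int]] = field(default_factory=list)
    gene_symbol: str = ""

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise SpotmapError(f"bad strand {self.strand!r} for {self.transcript_id}")
        self.exons = sorted(tuple(e) for e in self.exons)
        self.cds = sorted(tuple(c) for c in self.cds)
        prev_end = 0
        for s, e in self.exons:
            if s <= prev_end:
                raise SpotmapError(f"overlapping/unsorted exons in {self.transcript_id}")
            if e < s:
                raise SpotmapError(f"inverted exon in {self.transcript_id}")
            prev_end = e
        for cs, ce in self.cds:
            if not any(s <= cs and ce <= e for s, e in self.exons):
                raise SpotmapError(f"CDS outside exon in {self.transcript_id}")

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds)


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> Genome:
    """Load a multi-record FASTA into a Genome.

    Sequences are uppercased; any character outside A/C/G/T/N is replaced by
    N (a warning with the replacement count is logged).  Duplicate contig
    names and empty files are hard errors.
    """
    contigs: dict[str, str] = {}
    n_replaced = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in contigs:
            raise SpotmapError(f"duplicate contig name {rec.id!r} in {path}")
        seq = str(rec.seq).upper()
        cleaned = []
        for ch in seq:
            if ch in _VALID_BASES:
                cleaned.append(ch)
            else:
                cleaned.append("N")
                n_replaced += 1
        contigs[rec.id] = "".join(cleaned)
    if not contigs:
        raise SpotmapError(f"no FASTA records in {path}")
    if n_replaced:
        logger.warning("read_fasta: replaced %d non-ACGTN characters with N", n_replaced)
    return Genome(contigs)


def write_fasta(genome: Genome, path: str | Path, width: int = 70) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in genome.contigs.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# VCF


def read_vcf(path: str | Path, genome: Genome) -> tuple[list[Variant], list[str]]:
    """Read a biallelic-SNP/indel VCF and validate each record against the genome.

    Returns ``(variants, errors)``: records whose REF disagrees with the
    genome, that are multiallelic, or that carry symbolic/invalid alleles are
    skipped and described in ``errors``.
    """
    from cyvcf2 import VCF

    variants: list[Variant] = []
    errors: list[str] = []
    for rec in VCF(str(path)):
        where = f"{rec.CHROM}:{rec.POS}"
        if len(rec.ALT) != 1:
            errors.append(f"{where}: multiallelic record")
            continue
        if rec.CHROM not in genome.contigs:
            errors.append(f"{where}: unknown contig")
            continue
        ref, alt = rec.REF.upper(), rec.ALT[0].upper()
        end = rec.POS + len(ref) - 1
        if end > len(genome.contigs[rec.CHROM]):
            errors.append(f"{where}: REF runs past contig end")
            continue
        observed = genome.fetch(rec.CHROM, rec.POS, end)
        if observed != ref:
            errors.append(f"{where}: REF {ref} != genome {observed}")
            continue
        try:
            variants.append(Variant(rec.CHROM, rec.POS, ref, alt))
        except SpotmapError as exc:
            errors.append(f"{where}: {exc}")
    return variants, errors


def write_vcf(variants: Iterable[Variant], genome: Genome, path: str | Path) -> None:
    """Write a minimal VCF v4.2 (CHROM/POS/ID/REF/ALT columns)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for name, seq in genome.contigs.items():
            fh.write(f"##contig=<ID={name},length={len(seq)}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in sorted(variants, key=lambda v: (v.contig, v.pos)):
            fh.write(f"{v.contig}\t{v.pos}\t.\t{v.ref_allele}\t{v.alt_allele}\t.\t.\t.\n")


# ---------------------------------------------------------------------------
# GFF3


def read_gff(path: str | Path) -> tuple[list[GeneModel], list[str]]:
    """Parse a GFF3 (gene/mRNA/exon/CDS subset) into one GeneModel per transcript.

    Transcripts violating the structural invariants (overlapping exons, CDS
    outside an exon) are dropped and reported in the returned error list.
    """
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    models: list[GeneModel] = []
    errors: list[str] = []
    for mrna in db.features_of_type("mRNA"):
        exons = [(f.start, f.end) for f in db.children(mrna, featuretype="exon")]
        cds = [(f.start, f.end) for f in db.children(mrna, featuretype="CDS")]
        gene_id = mrna.attributes.get("Parent", [mrna.id])[0]
        symbol = ""
        try:
            gene = db[gene_id]
            symbol = gene.attributes.get("Name", [""])[0]
        except gffutils.FeatureNotFoundError:
            pass
        try:
            models.append(
                GeneModel(
                    gene_id=gene_id,
                    transcript_id=mrna.id,
                    contig=mrna.seqid,
                    strand=mrna.strand,
                    exons=exons,
                    cds=cds,
                    gene_symbol=symbol,
                )
            )
        except SpotmapError as exc:
            errors.append(f"{mrna.id}: {exc}")
    return models, errors


def write_gff(models: Iterable[GeneModel], path: str | Path) -> None:
    """Write gene/mRNA/exon/CDS features for the given transcripts."""
    by_gene: dict[str, list[GeneModel]] = {}
    for m in models:
        by_gene.setdefault(m.gene_id, []).append(m)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gene_id, txs in by_gene.items():
            start = min(t.span[0] for t in txs)
            end = max(t.span[1] for t in txs)
            t0 = txs[0]
            attrs = f"ID={gene_id}"
            if t0.gene_symbol:
                attrs += f";Name={t0.gene_symbol}"
            fh.write(
                f"{t0.contig}\tspotmap\tgene\t{start}\t{end}\t.\t{t0.strand}\t.\t{attrs}\n"
            )
            for t in txs:
                s, e = t.span
                fh.write(
                    f"{t.contig}\tspotmap\tmRNA\t{s}\t{e}\t.\t{t.strand}\t.\t"
                    f"ID={t.transcript_id};Parent={gene_id}\n"
                )
                for i, (xs, xe) in enumerate(t.exons, 1):
                    fh.write(
                        f"{t.contig}\tspotmap\texon\t{xs}\t{xe}\t.\t{t.strand}\t.\t"
                        f"ID={t.transcript_id}.exon{i};Parent={t.transcript_id}\n"
                    )
                for i, (cs, ce) in enumerate(t.cds, 1):
                    fh.write(
                        f"{t.contig}\tspotmap\tCDS\t{cs}\t{ce}\t.\t{t.strand}\t0\t"
                        f"ID={t.transcript_id}.cds{i};Parent={t.transcript_id}\n"
                    )


# ---------------------------------------------------------------------------
# Haplotype construction


def apply_variants(
    genome: Genome,
    variants: Iterable[Variant],
    contig: str,
    window: Interval,
) -> tuple[str, dict[int, tuple[int, bool]]]:
    """Apply non-overlapping variants to a reference window.

    Returns the alternate-haplotype sequence of the window together with a
    coordinate map from reference position (1-based, genome frame) to
    ``(alt_position, deleted)`` where ``alt_position`` is 1-based within the
    returned sequence.  Reference bases removed by a deletion map to the last
    retained alternate base with ``deleted=True``.

    Variants must be fully contained in the window and pairwise
    non-overlapping; overlap is a hard error naming the offending pair.
    """
    if window.contig != contig:
        raise SpotmapError("window contig mismatch")
    relevant = sorted(
        (v for v in variants if v.contig == contig and not (v.end < window.start or v.pos > window.end)),
        key=lambda v: v.pos,
    )
    for v in relevant:
        if v.pos < window.start or v.end > window.end:
            raise SpotmapError(
                f"variant {v.contig}:{v.pos} not fully contained in window"
            )
    for a, b in zip(relevant, relevant[1:]):
        if b.pos <= a.end:
            raise SpotmapError(
                f"overlapping variants at {contig}:{a.pos} and {contig}:{b.pos}"
            )
    ref_seq = genome.fetch(contig, window.start, window.end)
    alt_parts: list[str] = []
    coord: dict[int, tuple[int, bool]] = {}
    cursor = window.start
    alt_len = 0
    for v in relevant:
        for p in range(cursor, v.pos):
            alt_len += 1
            coord[p] = (alt_len, False)
            alt_parts.append(ref_seq[p - window.start])
        observed = genome.fetch(contig, v.pos, v.end)
        if observed != v.ref_allele:
            raise SpotmapError(
                f"variant REF mismatch at {contig}:{v.pos}: {v.ref_allele} != {observed}"
            )
        alt_start = alt_len
        alt_parts.append(v.alt_allele)
        alt_len += len(v.alt_allele)
        for j in range(len(v.ref_allele)):
            if j < len(v.alt_allele):
                coord[v.pos + j] = (alt_start + j + 1, False)
            else:
                coord[v.pos + j] = (alt_start + len(v.alt_allele), True)
        cursor = v.end + 1
    for p in range(cursor, window.end + 1):
        alt_len += 1
        coord[p] = (alt_len, False)
        alt_parts.append(ref_seq[p - window.start])
    return "".join(alt_parts), coord
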