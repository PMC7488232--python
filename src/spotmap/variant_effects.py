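"""Simplified variant-consequence annotation.

Two layers: genomic-region classification (exon/intron/UTR/splice/flank/
intergenic, reported per overlapping transcript with multiplicity) and
coding-effect classification (silent/missense/nonsense/indel effects) by
splicing the CDS, applying the variant and translating both haplotypes with
the standard genetic code.

Splice-site extents follow the common annotation-tool convention: the
acceptor/donor dinucleotides are the two intronic bases abutting an exon
boundary; the splice region covers intronic bases 3–8 and exonic bases 1–3
from a boundary.  Both are configurable.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Sequence

from Bio.Seq import Seq

from .sequence_io import GeneModel, Genome, SpotmapError, Variant

REGION_CATEGORIES = (
    "exon",
    "intron",
    "utr5",
    "utr3",
    "splice_acceptor",
    "splice_donor",
    "splice_region",
    "upstream5kb",
    "downstream5kb",
    "intergenic",
)

CODING_EFFECTS = (
    "silent",
    "missense",
    "nonsense",
    "inframe_deletion",
    "inframe_insertion",
    "frameshift",
    "stop_lost",
    "start_lost",
)

NONSYNONYMOUS = frozenset(CODING_EFFECTS) - {"silent"}


@dataclass(frozen=True)
class RegionAnnotation:
    variant: Variant
    category: str
    gene_id: str | None = None
    transcript_id: str | None = None

    def __post_init__(self) -> None:
        if self.category not in REGION_CATEGORIES:
            raise SpotmapError(f"unknown region category {self.category!r}")


@dataclass(frozen=True)
class CodingEffect:
    variant: Variant
    transcript_id: str
    effect: str
    ref_aa: str = ""
    alt_aa: str = ""
    aa_position: int | None = None

    def __post_init__(self) -> None:
        if self.effect not in CODING_EFFECTS:
            raise SpotmapError(f"unknown coding effect {self.effect!r}")


def _span_overlaps(a_lo: int, a_hi: int, b_lo: int, b_hi: int) -> bool:
    return a_lo <= b_hi and b_lo <= a_hi


def classify_region(
    variant: Variant,
    gene_models: Sequence[GeneModel],
    flank: int = 5000,
    splice_site: int = 2,
    splice_region_intron: tuple[int, int] = (3, 8),
    splice_region_exon: int = 3,
) -> list[RegionAnnotation]:
    """Region annotations for one variant across all overlapping transcripts.

    A variant may collect several annotations (one per category per
    transcript); ``intergenic`` is the fallback when nothing overlaps within
    ``flank`` of any transcript.
    """
    lo, hi = variant.pos, variant.end
    out: list[RegionAnnotation] = []
    for m in gene_models:
        if m.contig != variant.contig:
            continue
        span_lo, span_hi = m.span
        if not _span_overlaps(lo, hi, span_lo - flank, span_hi + flank):
            continue
        cats: set[str] = set()
        if _span_overlaps(lo, hi, span_lo, span_hi):
            cats |= _transcript_categories(
                variant, m, splice_site, splice_region_intron, splice_region_exon
            )
        # strand-aware flanks measured from the transcript span
        before = _span_overlaps(lo, hi, span_lo - flank, span_lo - 1)
        after = _span_overlaps(lo, hi, span_hi + 1, span_hi + flank)
        if m.strand == "+":
            if before:
                cats.add("upstream5kb")
            if after:
                cats.add("downstream5kb")
        else:
            if before:
                cats.add("downstream5kb")
            if after:
                cats.add("upstream5kb")
        out.extend(
            RegionAnnotation(variant, c, m.gene_id, m.transcript_id) for c in sorted(cats)
        )
    if not out:
        out.append(RegionAnnotation(variant, "intergenic"))
    return out


def _transcript_categories(
    variant: Variant,
    m: GeneModel,
    splice_site: int,
    sr_intron: tuple[int, int],
    sr_exon: int,
) -> set[str]:
    lo, hi = variant.pos, variant.end
    cats: set[str] = set()
    for xs, xe in m.exons:
        if _span_overlaps(lo, hi, xs, xe):
            cats.add("exon")
    if m.cds:
        cds_lo = m.cds[0][0]
        cds_hi = m.cds[-1][1]
        for xs, xe in m.exons:
            left = (xs, min(xe, cds_lo - 1)) if xs < cds_lo else None
            right = (max(xs, cds_hi + 1), xe) if xe > cds_hi else None
            for seg, side in ((left, "left"), (right, "right")):
                if seg is None or seg[0] > seg[1]:
                    continue
                if _span_overlaps(lo, hi, *seg):
                    if (side == "left") == (m.strand == "+"):
                        cats.add("utr5")
                    else:
                        cats.add("utr3")
    introns = [
        (a_end + 1, b_start - 1)
        for (_, a_end), (b_start, _) in zip(m.exons, m.exons[1:])
        if b_start - a_end > 1
    ]
    for is_, ie in introns:
        if _span_overlaps(lo, hi, is_, ie):
            cats.add("intron")
        # 5' side of the intron in genome order abuts the preceding exon
        left_site = (is_, min(ie, is_ + splice_site - 1))
        right_site = (max(is_, ie - splice_site + 1), ie)
        if m.strand == "+":
            donor, acceptor = left_site, right_site
        else:
            donor, acceptor = right_site, left_site
        if _span_overlaps(lo, hi, *donor):
            cats.add("splice_donor")
        if _span_overlaps(lo, hi, *acceptor):
            cats.add("splice_acceptor")
        sr_lo, sr_hi = sr_intron
        for seg in (
            (is_ + sr_lo - 1, min(ie, is_ + sr_hi - 1)),
            (max(is_, ie - sr_hi + 1), ie - sr_lo + 1),
        ):
            if seg[0] <= seg[1] and _span_overlaps(lo, hi, *seg):
                cats.add("splice_region")
    # exonic part of the splice region: first/last bases of internal exon edges
    for i, (xs, xe) in enumerate(m.exons):
        if i > 0 and _span_overlaps(lo, hi, xs, min(xe, xs + sr_exon - 1)):
            cats.add("splice_region")
        if i < len(m.exons) - 1 and _span_overlaps(lo, hi, max(xs, xe - sr_exon + 1), xe):
            cats.add("splice_region")
    return cats


# ---------------------------------------------------------------------------
# Coding effects


def _spliced_cds(genome: Genome, m: GeneModel) -> str:
    parts = [genome.fetch(m.contig, s, e) for s, e in m.cds]
    seq = "".join(parts)
    if m.strand == "-":
        seq = str(Seq(seq).reverse_complement())
    return seq


def _cds_index(m: GeneModel, pos: int) -> int | None:
    """0-based index of a genome position in the spliced CDS (transcript
    orientation), or None when the position is not coding."""
    offset = 0
    for s, e in m.cds:
        if s <= pos <= e:
            idx = offset + (pos - s)
            if m.strand == "-":
                return m.cds_length - 1 - idx
            return idx
        offset += e - s + 1
    return None


def coding_effect(
    variant: Variant, transcript: GeneModel, genome: Genome
) -> CodingEffect | None:
    """Coding consequence of a variant on one transcript, or None when the
    variant is not cleanly contained in the CDS or the CDS is incomplete.

    SNPs are classified by codon comparison after splicing and (for minus
    strand) reverse complementing; indels by length change modulo 3.
    """
    if not transcript.cds or transcript.cds_length % 3 != 0:
        return None
    positions = range(variant.pos, variant.end + 1)
    idxs = [_cds_index(transcript, p) for p in positions]
    if variant.kind == "SNP":
        idx = idxs[0]
        if idx is None:
            return None
        cds = _spliced_cds(genome, transcript)
        base = variant.alt_allele
        if transcript.strand == "-":
            base = str(Seq(base).reverse_complement())
        alt_cds = cds[:idx] + base + cds[idx + 1 :]
        codon_i = idx // 3
        ref_aa = str(Seq(cds[codon_i * 3 : codon_i * 3 + 3]).translate())
        alt_aa = str(Seq(alt_cds[codon_i * 3 : codon_i * 3 + 3]).translate())
        if ref_aa == alt_aa:
            effect = "silent"
        elif codon_i == 0 and ref_aa == "M":
            effect = "start_lost"
        elif alt_aa == "*":
            effect = "nonsense"
        elif ref_aa == "*":
            effect = "stop_lost"
        else:
            effect = "missense"
        return CodingEffect(
            variant, transcript.transcript_id, effect, ref_aa, alt_aa, codon_i + 1
        )
    # indel: the changed bases are those after the shared anchor base
    changed = idxs if variant.kind == "insertion" else idxs[1:]
    if variant.kind == "insertion":
        if idxs[0] is None:
            return None
    elif any(i is None for i in changed) or idxs[0] is None:
        return None
    delta = variant.length_change()
    if delta % 3 == 0:
        effect = "inframe_insertion" if delta > 0 else "inframe_deletion"
    else:
        effect = "frameshift"
    aa_pos = min(i for i in idxs if i is not None) // 3 + 1
    return CodingEffect(variant, transcript.transcript_id, effect, aa_position=aa_pos)


# ---------------------------------------------------------------------------
# Summary


@dataclass
class EffectSummary:
    region_counts: Counter
    coding_counts: Counter
    n_variants: int
    n_genes_with_cds_snp: int
    n_genes_nonsynonymous: int
    variant_rate_bp: int | None

    def coding_fractions(self) -> dict[str, float]:
        """Fraction of classified coding SNP effects (silent/missense/nonsense)."""
        snp_effects = {
            k: self.coding_counts[k] for k in ("silent", "missense", "nonsense")
        }
        total = sum(snp_effects.values())
        if total == 0:
            return {k: 0.0 for k in snp_effects}
        return {k: v / total for k, v in snp_effects.items()}


def summarize(
    variants: Sequence[Variant],
    gene_models: Sequence[GeneModel],
    genome: Genome,
    covered_length: int,
    flank: int = 5000,
) -> EffectSummary:
    """Per-category annotation counts (with multiplicity), per-gene rollups
    and the overall variant rate (covered bases per variant)."""
    if covered_length <= 0:
        raise SpotmapError("covered_length must be positive")
    region_counts: Counter = Counter()
    coding_counts: Counter = Counter()
    genes_cds_snp: set[str] = set()
    genes_nonsyn: set[str] = set()
    by_contig: dict[str, list[GeneModel]] = {}
    for m in gene_models:
        by_contig.setdefault(m.contig, []).append(m)
    models_by_tid = {m.transcript_id: m for m in gene_models}
    for v in variants:
        annotations = classify_region(v, by_contig.get(v.contig, []), flank=flank)
        for ann in annotations:
            region_counts[ann.category] += 1
            if ann.category == "exon" and ann.transcript_id:
                m = models_by_tid[ann.transcript_id]
                eff = coding_effect(v, m, genome)
                if eff is None:
                    continue
                coding_counts[eff.effect] += 1
                if v.kind == "SNP":
                    genes_cds_snp.add(m.gene_id)
                if eff.effect in NONSYNONYMOUS:
                    genes_nonsyn.add(m.gene_id)
    rate = _rate(covered_length, len(variants))
    return EffectSummary(
        region_counts=region_counts,
        coding_counts=coding_counts,
        n_variants=len(variants),
        n_genes_with_cds_snp=len(genes_cds_snp),
        n_genes_nonsynonymous=len(genes_nonsyn),
        variant_rate_bp=rate,
    )


def _rate(covered_length: int, n_variants: int) -> int | None:
    if n_variants == 0:
        return None
    return round(covered_length / n_variants)
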