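"""Region classification and coding-effect annotation against independent
brute-force and translate-and-compare oracles."""

import pytest
from Bio.Seq import Seq

from spotmap import (
    GeneModel,
    Genome,
    SpotmapError,
    Variant,
    classify_region,
    coding_effect,
    summarize,
)
from spotmap.variant_effects import NONSYNONYMOUS


def region_oracle(variant, model, flank=5000):
    """Brute-force per-base category assignment for one transcript."""
    cats = set()
    span_lo, span_hi = model.span
    positions = range(variant.pos, variant.end + 1)
    exon_edges_internal_left = {xs for i, (xs, xe) in enumerate(model.exons) if i > 0}
    exon_edges_internal_right = {
        xe for i, (xs, xe) in enumerate(model.exons) if i < len(model.exons) - 1
    }
    introns = [
        (a[1] + 1, b[0] - 1) for a, b in zip(model.exons, model.exons[1:])
    ]
    cds_lo = model.cds[0][0] if model.cds else None
    cds_hi = model.cds[-1][1] if model.cds else None
    for p in positions:
        if p < span_lo - flank or p > span_hi + flank:
            continue
        if p < span_lo:
            cats.add("upstream5kb" if model.strand == "+" else "downstream5kb")
        if p > span_hi:
            cats.add("downstream5kb" if model.strand == "+" else "upstream5kb")
        for xs, xe in model.exons:
            if xs <= p <= xe:
                cats.add("exon")
                if model.cds:
                    if p < cds_lo:
                        cats.add("utr5" if model.strand == "+" else "utr3")
                    if p > cds_hi:
                        cats.add("utr3" if model.strand == "+" else "utr5")
                for edge in exon_edges_internal_left:
                    if xs == edge and p - xs < 3:
                        cats.add("splice_region")
                for edge in exon_edges_internal_right:
                    if xe == edge and xe - p < 3:
                        cats.add("splice_region")
        for is_, ie in introns:
            if is_ <= p <= ie:
                cats.add("intron")
                d_left = p - is_ + 1  # 1-based distance into intron from left
                d_right = ie - p + 1
                donor_d, acceptor_d = (
                    (d_left, d_right) if model.strand == "+" else (d_right, d_left)
                )
                if donor_d <= 2:
                    cats.add("splice_donor")
                if acceptor_d <= 2:
                    cats.add("splice_acceptor")
                if 3 <= d_left <= 8 or 3 <= d_right <= 8:
                    cats.add("splice_region")
    return cats


def _model(strand="+"):
    # exons 101-200, 301-400, 501-600; CDS 151-200, 301-400, 501-554 (204 nt)
    return GeneModel(
        "g1",
        "t1",
        "c",
        strand,
        exons=[(101, 200), (301, 400), (501, 600)],
        cds=[(151, 200), (301, 400), (501, 554)],
    )


class TestClassifyRegion:
    def test_cds_exon_variant(self):
        anns = classify_region(Variant("c", 180, "A", "G"), [_model()])
        assert {a.category for a in anns} == {"exon"}

    def test_donor_boundary_plus_strand(self):
        # 2 bases into the intron after the first exon of a + strand gene
        anns = classify_region(Variant("c", 202, "A", "G"), [_model("+")])
        assert {a.category for a in anns} == {"intron", "splice_donor"}
        # intronic base 3 enters the splice region instead
        anns = classify_region(Variant("c", 203, "A", "G"), [_model("+")])
        assert {a.category for a in anns} == {"intron", "splice_region"}

    def test_acceptor_on_minus_strand_mirrors_donor(self):
        # same physical bases, donor/acceptor swap with strand
        anns_plus = classify_region(Variant("c", 299, "A", "G"), [_model("+")])
        anns_minus = classify_region(Variant("c", 299, "A", "G"), [_model("-")])
        assert {a.category for a in anns_plus} == {"intron", "splice_acceptor"}
        assert {a.category for a in anns_minus} == {"intron", "splice_donor"}

    def test_utrs_are_strand_aware(self):
        anns = classify_region(Variant("c", 120, "A", "G"), [_model("+")])
        assert {a.category for a in anns} == {"exon", "utr5"}
        anns = classify_region(Variant("c", 120, "A", "G"), [_model("-")])
        assert {a.category for a in anns} == {"exon", "utr3"}

    def test_flanks_and_intergenic(self):
        anns = classify_region(Variant("c", 50, "A", "G"), [_model("+")])
        assert {a.category for a in anns} == {"upstream5kb"}
        anns = classify_region(Variant("c", 50, "A", "G"), [_model("-")])
        assert {a.category for a in anns} == {"downstream5kb"}
        anns = classify_region(Variant("c", 99_999, "A", "G"), [_model("+")])
        assert [a.category for a in anns] == ["intergenic"]

    @pytest.mark.parametrize("strand", "+-")
    def test_matches_brute_force_oracle_across_gene(self, strand):
        model = _model(strand)
        for pos in range(1, 700, 1):
            v = Variant("c", pos, "A", "G")
            got = {a.category for a in classify_region(v, [model])}
            expected = region_oracle(v, model) or {"intergenic"}
            assert got == expected, f"pos {pos} strand {strand}"

    def test_every_variant_gets_an_annotation(self, genome_pair):
        truth = genome_pair
        for v in truth.variants[:500]:
            assert classify_region(v, truth.gene_models)


def translate_compare_oracle(variant, model, genome):
    """Independent whole-protein comparison oracle for SNP effects."""
    from spotmap.variant_effects import _cds_index, _spliced_cds

    idx = _cds_index(model, variant.pos)
    if idx is None:
        return None
    cds = _spliced_cds(genome, model)
    base = variant.alt_allele
    if model.strand == "-":
        base = str(Seq(base).reverse_complement())
    alt = cds[:idx] + base + cds[idx + 1 :]
    p_ref = str(Seq(cds).translate())
    p_alt = str(Seq(alt).translate())
    if p_ref == p_alt:
        return "silent"
    i = next(i for i, (a, b) in enumerate(zip(p_ref, p_alt)) if a != b)
    if i == 0 and p_ref[0] == "M":
        return "start_lost"
    if p_alt[i] == "*":
        return "nonsense"
    if p_ref[i] == "*":
        return "stop_lost"
    return "missense"


class TestCodingEffect:
    def _genome(self):
        # CDS reads ATG TCT CGA CTT ... TAA on the + strand
        seq = ["A"] * 700
        coding = "ATG" + "TCTCGACTT" * 22 + "TAA"  # 204 bases = CDS length
        model = _model("+")
        cds_positions = [
            p for s, e in model.cds for p in range(s, e + 1)
        ]
        assert len(cds_positions) == len(coding)
        for p, b in zip(cds_positions, coding):
            seq[p - 1] = b
        return Genome({"c": "".join(seq)}), model

    @pytest.mark.parametrize(
        "pos, ref, alt, effect, aa",
        [
            (154, "T", "G", "missense", ("S", "A")),  # TCT -> GCT
            (157, "C", "T", "nonsense", ("R", "*")),  # CGA -> TGA
            (162, "T", "C", "silent", ("L", "L")),  # CTT -> CTC
            (152, "T", "C", "start_lost", ("M", "T")),  # ATG -> ACG
        ],
    )
    def test_point_effects(self, pos, ref, alt, effect, aa):
        genome, model = self._genome()
        assert genome.fetch("c", pos, pos) == ref
        eff = coding_effect(Variant("c", pos, ref, alt), model, genome)
        assert eff.effect == effect
        assert (eff.ref_aa, eff.alt_aa) == aa

    def test_indel_effects(self):
        genome, model = self._genome()
        ref3 = genome.fetch("c", 154, 157)
        eff = coding_effect(Variant("c", 154, ref3, ref3[0]), model, genome)
        assert eff.effect == "inframe_deletion"
        ref1 = genome.fetch("c", 154, 155)
        eff = coding_effect(Variant("c", 154, ref1, ref1[0]), model, genome)
        assert eff.effect == "frameshift"
        eff = coding_effect(Variant("c", 154, "T", "TGGG"), model, genome)
        assert eff.effect == "inframe_insertion"

    def test_incomplete_cds_skipped(self):
        genome, _ = self._genome()
        broken = GeneModel(
            "g1", "t1", "c", "+", exons=[(101, 200)], cds=[(151, 200)]
        )  # 50 bases, not divisible by 3
        assert coding_effect(Variant("c", 160, "A", "G"), broken, genome) is None

    def test_snp_effects_match_translation_oracle(self):
        """Every CDS position, every alternative base, both strands."""
        genome, model = self._genome()
        minus = _model("-")
        for m in (model, minus):
            cds_positions = [p for s, e in m.cds for p in range(s, e + 1)]
            for pos in cds_positions:
                ref = genome.fetch("c", pos, pos)
                for alt in "ACGT":
                    if alt == ref:
                        continue
                    v = Variant("c", pos, ref, alt)
                    eff = coding_effect(v, m, genome)
                    assert eff is not None
                    assert eff.effect == translate_compare_oracle(v, m, genome)

    def test_reverse_complement_symmetry(self):
        """Mirroring genome and gene leaves every classification unchanged."""
        genome, model = self._genome()
        n = len(genome.contigs["c"])
        rc = str(Seq(genome.contigs["c"]).reverse_complement())
        mirror_genome = Genome({"c": rc})
        mirror = GeneModel(
            "g1",
            "t1",
            "c",
            "-",
            exons=[(n - e + 1, n - s + 1) for s, e in model.exons],
            cds=[(n - e + 1, n - s + 1) for s, e in model.cds],
        )
        for pos in range(151, 180):
            ref = genome.fetch("c", pos, pos)
            for alt in "ACGT":
                if alt == ref:
                    continue
                eff = coding_effect(Variant("c", pos, ref, alt), model, genome)
                m_pos = n - pos + 1
                m_ref = str(Seq(ref).reverse_complement())
                m_alt = str(Seq(alt).reverse_complement())
                m_eff = coding_effect(
                    Variant("c", m_pos, m_ref, m_alt), mirror, mirror_genome
                )
                assert (eff.effect, eff.ref_aa, eff.alt_aa, eff.aa_position) == (
                    m_eff.effect,
                    m_eff.ref_aa,
                    m_eff.alt_aa,
                    m_eff.aa_position,
                )


class TestSummarize:
    def test_variant_rate_identity(self, genome_pair):
        truth = genome_pair
        n = len(truth.variants)
        summary = summarize(
            truth.variants, truth.gene_models, truth.genome, covered_length=n * 68
        )
        assert summary.variant_rate_bp == 68
        assert summary.n_variants == n
        # multiplicity: total annotations at least one per variant
        assert sum(summary.region_counts.values()) >= n
        assert summary.n_genes_nonsynonymous <= len(
            {m.gene_id for m in truth.gene_models}
        )
        fr = summary.coding_fractions()
        assert abs(sum(fr.values()) - 1.0) < 1e-9 or sum(fr.values()) == 0.0

    def test_empty_and_invalid_inputs(self, genome_pair):
        truth = genome_pair
        summary = summarize([], truth.gene_models, truth.genome, covered_length=100)
        assert summary.variant_rate_bp is None
        assert sum(summary.region_counts.values()) == 0
        with pytest.raises(SpotmapError):
            summarize(truth.variants, truth.gene_models, truth.genome, 0)

    def test_gene_rollups_monotone(self, genome_pair):
        truth = genome_pair
        summary = summarize(
            truth.variants, truth.gene_models, truth.genome, covered_length=10_000
        )
        nonsyn_count = sum(summary.coding_counts[e] for e in NONSYNONYMOUS)
        if summary.n_genes_nonsynonymous:
            assert nonsyn_count >= summary.n_genes_nonsynonymous
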