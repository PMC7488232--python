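#!/usr/bin/env python
"""Simulate the two-species genome pair.

Generates a reference genome with interspecific variants at one per 68 bp
(~89% SNPs, ~11% short indels), planted enzyme-site-disrupting variants and
gene models.  Sequence files (FASTA/VCF/GFF3) go to scratch/sim/; a small
summary table goes to results/.
"""

from pathlib import Path

from spotmap import (
    GenomeSimConfig,
    make_genome_pair,
    write_fasta,
    write_gff,
    write_vcf,
)

ROOT = Path(__file__).resolve().parents[1]
SIM_DIR = ROOT / "scratch" / "sim"
RESULTS = ROOT / "results"

CONFIG = GenomeSimConfig(
    n_contigs=4,
    contig_length=150_000,
    n_planted_rflp=12,
    n_genes=24,
    seed=2020,
)


def main() -> None:
    SIM_DIR.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(exist_ok=True)
    truth = make_genome_pair(CONFIG)
    write_fasta(truth.genome, SIM_DIR / "reference.fa")
    write_vcf(truth.variants, truth.genome, SIM_DIR / "variants.vcf")
    write_gff(truth.gene_models, SIM_DIR / "genes.gff3")
    with open(SIM_DIR / "planted_rflp.tsv", "w") as fh:
        fh.write("contig\tpos\tref\talt\tenzyme\tsite_position\n")
        for p in truth.planted_rflp:
            v = p.variant
            fh.write(
                f"{v.contig}\t{v.pos}\t{v.ref_allele}\t{v.alt_allele}\t"
                f"{p.enzyme_name}\t{p.site_position}\n"
            )

    kinds = [v.kind for v in truth.variants]
    n = len(kinds)
    rate = truth.genome.total_length / n
    with open(RESULTS / "01_genome_pair_summary.tsv", "w") as fh:
        fh.write("quantity\tvalue\n")
        fh.write(f"genome_length_bp\t{truth.genome.total_length}\n")
        fh.write(f"n_variants\t{n}\n")
        fh.write(f"bases_per_variant\t{rate:.1f}\n")
        fh.write(f"snp_fraction\t{kinds.count('SNP') / n:.4f}\n")
        fh.write(f"insertion_fraction\t{kinds.count('insertion') / n:.4f}\n")
        fh.write(f"deletion_fraction\t{kinds.count('deletion') / n:.4f}\n")
        fh.write(f"n_planted_rflp\t{len(truth.planted_rflp)}\n")
        fh.write(f"n_gene_models\t{len(truth.gene_models)}\n")
    print(
        f"Simulated {truth.genome.total_length:,} bp over {CONFIG.n_contigs} "
        f"contigs: {n:,} variants (one per {rate:.0f} bp), "
        f"{len(truth.planted_rflp)} planted RFLP variants, "
        f"{len(truth.gene_models)} gene models."
    )
    print(f"Sequence files in {SIM_DIR}, summary in results/01_genome_pair_summary.tsv")


if __name__ == "__main__":
    main()
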