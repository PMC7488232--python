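"""Synthetic stand-ins for the two-species genome pair and the spotting
backcross, with recorded ground truth for every planted feature.

The genome generator emulates a pair of closely related rodent genomes
differing at roughly one variant per 68 bp (~89% SNPs, ~11% short indels),
with a configurable number of planted enzyme-site-disrupting variants and
non-overlapping gene models.  The cross generator emulates a dominant
white-spotting locus carried through an interspecific backcross: carriers
segregate 1:1, spot size depends on unlinked modifier loci, and carriers can
be phenotypically rescued (no spot) or lost to lethality, the two mechanisms
the deficit of affected animals cannot distinguish.

All generators are pure functions of (config, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .restriction import IUPAC, BUILTIN_ENZYMES
from .rflp import SITE_LOST_IN_ALT, variant_site_effects
from .sequence_io import GeneModel, Genome, SpotmapError, Variant

_BASES = np.array(list("ACGT"))


# ===========================================================================
# Genome pair


@dataclass(frozen=True)
class GenomeSimConfig:
    n_contigs: int = 2
    contig_length: int = 100_000
    variant_rate_bp: float = 68.0
    snp_fraction: float = 0.893
    ins_fraction: float = 0.0535
    del_fraction: float = 0.0535
    max_indel_len: int = 8
    n_planted_rflp: int = 0
    enzyme_panel: tuple[str, ...] = ("EcoRI", "StuI", "BamHI", "KpnI", "DraI")
    n_genes: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        total = self.snp_fraction + self.ins_fraction + self.del_fraction
        if abs(total - 1.0) > 1e-9:
            raise SpotmapError("variant-type fractions must sum to 1")
        if self.variant_rate_bp <= 0:
            raise SpotmapError("variant_rate_bp must be positive")


@dataclass(frozen=True)
class PlantedRflp:
    variant: Variant
    enzyme_name: str
    site_position: int


@dataclass
class GenomePairTruth:
    """Everything the generator planted, sufficient to score every
    downstream stage without re-deriving anything."""

    genome: Genome
    variants: list[Variant]
    gene_models: list[GeneModel]
    planted_rflp: list[PlantedRflp]
    config: GenomeSimConfig


def _concrete_motif(motif: str, rng: np.random.Generator) -> str:
    return "".join(c if c in "ACGT" else rng.choice(list(IUPAC[c])) for c in motif)




def make_genome_pair(config: GenomeSimConfig) -> GenomePairTruth:
    """Simulate a reference genome plus the variant set distinguishing the
    alternate species, with planted RFLP-informative variants and gene
    models recorded as ground truth.

    Neutral variants are rejection-sampled so that none of them disturbs a
    recognition site of the configured enzyme panel; only the planted
    variants are site-disrupting.
    """
    rng = np.random.default_rng(config.seed)
    panel = [BUILTIN_ENZYMES[n] for n in config.enzyme_panel]
    contig_names = [f"ctg{i + 1}" for i in range(config.n_contigs)]
    seqs = {
        name: rng.choice(_BASES, size=config.contig_length)
        for name in contig_names
    }

    total_len = config.n_contigs * config.contig_length
    n_variants = int(rng.binomial(total_len, 1.0 / config.variant_rate_bp))
    margin = config.max_indel_len + 2
    min_gap = 2 * margin  # keeps variant ref spans disjoint with slack
    n_slots = total_len // min_gap
    if config.n_planted_rflp + n_variants > n_slots:
        raise SpotmapError(
            f"infeasible density: {config.n_planted_rflp + n_variants} variants "
            f"for {n_slots} available slots"
        )
    slot_ids = rng.permutation(n_slots)

    def slot_to_locus(slot: int) -> tuple[str, int]:
        contig_i = slot * min_gap // config.contig_length
        pos0 = slot * min_gap - contig_i * config.contig_length
        pos0 = min(pos0, config.contig_length - margin - 1)
        return contig_names[contig_i], pos0 + 1  # 1-based

    planted: list[PlantedRflp] = []
    variants: list[Variant] = []
    used = 0

    # --- planted site-disrupting SNPs
    for _ in range(config.n_planted_rflp):
        enzyme = panel[int(rng.integers(len(panel)))]
        motif = _concrete_motif(enzyme.recognition, rng)
        placed = False
        while used < n_slots and not placed:
            contig, pos = slot_to_locus(int(slot_ids[used]))
            used += 1
            arr = seqs[contig]
            arr[pos - 1 : pos - 1 + len(motif)] = list(motif)
            genome_view = Genome({contig: "".join(arr)})
            offset = int(rng.integers(len(motif)))
            ref_base = motif[offset]
            others = [e for e in panel if e.name != enzyme.name]
            for alt_base in rng.permutation([b for b in "ACGT" if b != ref_base]):
                v = Variant(contig, pos + offset, ref_base, str(alt_base))
                effects = variant_site_effects(genome_view, v, enzyme)
                clean = len(effects) == 1 and effects[0][0] == SITE_LOST_IN_ALT
                if clean and all(
                    not variant_site_effects(genome_view, v, e) for e in others
                ):
                    planted.append(PlantedRflp(v, enzyme.name, effects[0][1]))
                    variants.append(v)
                    placed = True
                    break
        if not placed:
            raise SpotmapError("could not place all planted RFLP variants")

    genome = Genome({name: "".join(seqs[name]) for name in contig_names})

    # --- neutral variants, rejection-sampled to be panel-silent
    kinds = rng.choice(
        ["SNP", "insertion", "deletion"],
        size=n_variants,
        p=[config.snp_fraction, config.ins_fraction, config.del_fraction],
    )
    for kind in kinds:
        while used < n_slots:
            contig, pos = slot_to_locus(int(slot_ids[used]))
            used += 1
            v = _draw_variant(genome, contig, pos, str(kind), config.max_indel_len, rng)
            if v is None:
                continue
            if all(not variant_site_effects(genome, v, e) for e in panel):
                variants.append(v)
                break
        else:
            raise SpotmapError("ran out of placement slots for neutral variants")

    gene_models = _place_genes(genome, config.n_genes, rng)
    variants.sort(key=lambda v: (v.contig, v.pos))
    return GenomePairTruth(genome, variants, gene_models, planted, config)


def _draw_variant(
    genome: Genome,
    contig: str,
    pos: int,
    kind: str,
    max_indel: int,
    rng: np.random.Generator,
) -> Variant | None:
    seq = genome.contigs[contig]
    anchor = seq[pos - 1]
    if anchor == "N":
        return None
    if kind == "SNP":
        alt = str(rng.choice([b for b in "ACGT" if b != anchor]))
        return Variant(contig, pos, anchor, alt)
    length = int(rng.integers(1, max_indel + 1))
    if kind == "insertion":
        ins = "".join(rng.choice(_BASES, size=length))
        return Variant(contig, pos, anchor, anchor + ins)
    ref = seq[pos - 1 : pos + length]
    if len(ref) < length + 1 or "N" in ref:
        return None
    return Variant(contig, pos, ref, anchor)


def _place_genes(
    genome: Genome, n_genes: int, rng: np.random.Generator
) -> list[GeneModel]:
    """Non-overlapping multi-exon gene models with in-frame CDS."""
    models: list[GeneModel] = []
    if n_genes == 0:
        return models
    names = list(genome.contigs)
    per_contig = {name: [] for name in names}
    for g in range(n_genes):
        contig = names[g % len(names)]
        contig_len = len(genome.contigs[contig])
        for _ in range(200):
            n_exons = int(rng.integers(2, 5))
            exon_lens = rng.integers(90, 300, size=n_exons)
            intron_lens = rng.integers(60, 400, size=n_exons - 1)
            gene_len = int(exon_lens.sum() + intron_lens.sum())
            start = int(rng.integers(1, max(2, contig_len - gene_len)))
            end = start + gene_len - 1
            if any(
                not (end < s2 - 10_000 or start > e2 + 10_000)
                for (s2, e2) in per_contig[contig]
            ):
                continue
            exons = []
            cursor = start
            for i in range(n_exons):
                exons.append((cursor, cursor + int(exon_lens[i]) - 1))
                if i < n_exons - 1:
                    cursor += int(exon_lens[i]) + int(intron_lens[i])
            # CDS: trim UTRs off first/last exon, pad to a multiple of 3
            utr5 = int(rng.integers(10, 60))
            utr3 = int(rng.integers(10, 60))
            cds = [list(e) for e in exons]
            cds[0][0] += utr5
            cds[-1][1] -= utr3
            total = sum(e - s + 1 for s, e in cds)
            cds[-1][1] -= total % 3
            if any(e <= s for s, e in cds):
                continue
            strand = "+" if rng.random() < 0.5 else "-"
            per_contig[contig].append((start, end))
            models.append(
                GeneModel(
                    gene_id=f"gene{g + 1}",
                    transcript_id=f"tx{g + 1}",
                    contig=contig,
                    strand=strand,
                    exons=exons,
                    cds=[tuple(c) for c in cds],
                    gene_symbol=f"Gene{g + 1}",
                )
            )
            break
        else:
            raise SpotmapError("could not place all genes without overlap")
    return models


# ===========================================================================
# Backcross


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of the lognormal with the given arithmetic mean and sd."""
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return mu, math.sqrt(sigma2)


@dataclass(frozen=True)
class CrossSimConfig:
    """Backcross of interspecific F1 spotting carriers to the PO stock.

    The causal dominant locus sits at ``causal_marker_index`` on a single
    mapped chromosome; ``k_modifiers`` unlinked biallelic loci shift spot
    size (each PO allele shrinks the spot multiplicatively) and, in the
    rescue regime, suppress the spot entirely in carriers homozygous PO at
    every modifier.
    """

    n_f1: int = 6
    n_n2: int = 125
    marker_positions_cm: tuple[float, ...] = (0.0, 10.0, 20.0, 30.0, 40.0)
    causal_marker_index: int = 2
    k_modifiers: int = 2
    rescue_prob: float = 0.0  # P(no spot | carrier, all modifiers PO/PO)
    sn2_lethal_prob: float = 0.0  # P(lost | carrier), the alternative mechanism
    bw_spot_mean: float = 77.6
    bw_spot_sd: float = 36.6
    f1_spot_mean: float = 3.75
    f1_spot_sd: float = 1.56
    s_homozygote_lethal: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.rescue_prob, self.sn2_lethal_prob):
            if not 0.0 <= p <= 1.0:
                raise SpotmapError("probabilities must be in [0, 1]")
        if self.k_modifiers < 0:
            raise SpotmapError("k_modifiers must be >= 0")
        if min(self.bw_spot_sd, self.f1_spot_sd) <= 0:
            raise SpotmapError("spot-size sds must be positive")
        if not 0 <= self.causal_marker_index < len(self.marker_positions_cm):
            raise SpotmapError("causal_marker_index out of range")


@dataclass
class Animal:
    animal_id: str
    generation: str  # P, F1 or N2
    marker_genotypes: dict[str, str]
    modifier_genotypes: tuple[str, ...]
    carrier: bool
    spotted: bool
    spot_size_mm2: float | None
    resembles_f1: bool | None


@dataclass
class Pedigree:
    animals: list[Animal]
    marker_names: tuple[str, ...]
    config: CrossSimConfig

    def n2_animals(self) -> list[Animal]:
        return [a for a in self.animals if a.generation == "N2"]

    def affected_n2(self) -> list[Animal]:
        return [a for a in self.n2_animals() if a.spotted]

    def affected_calls(self, marker: str) -> list[str]:
        return [a.marker_genotypes[marker] for a in self.affected_n2()]


def _haldane_recomb_probs(positions_cm: Sequence[float]) -> np.ndarray:
    d = np.diff(np.asarray(positions_cm, dtype=float)) / 100.0
    return 0.5 * (1.0 - np.exp(-2.0 * d))


def simulate_backcross(config: CrossSimConfig) -> Pedigree:
    """Simulate F1 carriers and their N2 backcross offspring.

    F1 animals are heterozygous everywhere and carry the causal allele on
    the BW haplotype.  N2 gametes from the F1 parent recombine along the
    marker map under the Haldane model (no interference); the PO parent
    always contributes PO, so N2 genotypes are BW/PO or PO/PO.  Carrier
    status cosegregates exactly with the BW allele at the causal marker.
    Spot sizes are lognormal, shifted down multiplicatively per PO modifier
    allele beyond the all-BW background and calibrated against the BW and F1
    summary statistics.
    """
    rng = np.random.default_rng(config.seed)
    markers = tuple(f"M{i + 1}" for i in range(len(config.marker_positions_cm)))
    k = config.k_modifiers

    mu_bw, sigma_bw = _lognormal_params(config.bw_spot_mean, config.bw_spot_sd)
    mu_f1, sigma_f1 = _lognormal_params(config.f1_spot_mean, config.f1_spot_sd)
    # F1 carries one PO allele at each of the k modifiers
    beta = (mu_bw - mu_f1) / k if k else 0.0
    sigma_slope = (sigma_f1 - sigma_bw) / k if k else 0.0
    f1_band = (
        math.exp(mu_f1 - 1.96 * sigma_f1),
        math.exp(mu_f1 + 1.96 * sigma_f1),
    )

    def spot_size(n_po_alleles: int) -> float:
        mu = mu_bw - beta * n_po_alleles
        sigma = max(0.05, sigma_bw + sigma_slope * n_po_alleles)
        return float(math.exp(rng.normal(mu, sigma)))

    animals: list[Animal] = []
    for i in range(config.n_f1):
        size = spot_size(k)
        animals.append(
            Animal(
                animal_id=f"F1_{i + 1}",
                generation="F1",
                marker_genotypes={m: "BW/PO" for m in markers},
                modifier_genotypes=tuple("BW/PO" for _ in range(k)),
                carrier=True,
                spotted=True,
                spot_size_mm2=size,
                resembles_f1=f1_band[0] <= size <= f1_band[1],
            )
        )

    recomb = _haldane_recomb_probs(config.marker_positions_cm)
    n = config.n_n2
    # F1 gamete haplotypes along the chromosome: True = BW allele
    gam = np.empty((n, len(markers)), dtype=bool)
    gam[:, 0] = rng.random(n) < 0.5
    for j, r in enumerate(recomb):
        switch = rng.random(n) < r
        gam[:, j + 1] = np.where(switch, ~gam[:, j], gam[:, j])
    carrier = gam[:, config.causal_marker_index]
    mod_bw = rng.random((n, k)) < 0.5 if k else np.zeros((n, 0), dtype=bool)

    lethal = carrier & (rng.random(n) < config.sn2_lethal_prob)
    all_po_mod = ~mod_bw.any(axis=1) if k else np.zeros(n, dtype=bool)
    rescued = carrier & all_po_mod & (rng.random(n) < config.rescue_prob)
    spotted = carrier & ~rescued & ~lethal

    for i in range(n):
        if lethal[i]:
            continue  # lost before phenotyping
        genotypes = {
            m: ("BW/PO" if gam[i, j] else "PO/PO") for j, m in enumerate(markers)
        }
        modifiers = tuple(
            "BW/PO" if mod_bw[i, j] else "PO/PO" for j in range(k)
        )
        size = None
        resembles = None
        if spotted[i]:
            n_po = sum(1 if mod_bw[i, j] else 2 for j in range(k))
            size = spot_size(n_po)
            resembles = f1_band[0] <= size <= f1_band[1]
        animals.append(
            Animal(
                animal_id=f"N2_{i + 1}",
                generation="N2",
                marker_genotypes=genotypes,
                modifier_genotypes=modifiers,
                carrier=bool(carrier[i]),
                spotted=bool(spotted[i]),
                spot_size_mm2=size,
                resembles_f1=resembles,
            )
        )
    return Pedigree(animals, markers, config)


# ===========================================================================
# Intercross (carrier x carrier)


@dataclass(frozen=True)
class EmbryoOutcome:
    embryo_id: str
    genotype: str  # S/S, S/+ or +/+
    lethal: bool


def simulate_intercross(
    n_embryos: int,
    s_homozygote_lethal: bool = True,
    seed: int = 0,
) -> list[EmbryoOutcome]:
    """Embryo genotypes from a carrier-by-carrier intercross (1:2:1), with
    S/S homozygotes flagged lethal when the lethality switch is on."""
    rng = np.random.default_rng(seed)
    draws = rng.choice(["S/S", "S/+", "+/+"], size=n_embryos, p=[0.25, 0.5, 0.25])
    return [
        EmbryoOutcome(
            f"E{i + 1}", str(g), bool(s_homozygote_lethal and g == "S/S")
        )
        for i, g in enumerate(draws)
    ]


# ===========================================================================
# Tabular export


def write_pedigree(pedigree: Pedigree, path: str | Path) -> None:
    mk = pedigree.marker_names
    with open(path, "w") as fh:
        header = ["animal_id", "generation", "carrier", "spotted", "spot_size_mm2",
                  "resembles_f1", *mk]
        header += [f"mod{i + 1}" for i in range(pedigree.config.k_modifiers)]
        fh.write("\t".join(header) + "\n")
        for a in pedigree.animals:
            size = f"{a.spot_size_mm2:.2f}" if a.spot_size_mm2 is not None else "NA"
            res = {True: "yes", False: "no", None: "NA"}[a.resembles_f1]
            row = [a.animal_id, a.generation, str(int(a.carrier)),
                   str(int(a.spotted)), size, res]
            row += [a.marker_genotypes[m] for m in mk]
            row += list(a.modifier_genotypes)
            fh.write("\t".join(row) + "\n")
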