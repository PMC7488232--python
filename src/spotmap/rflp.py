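"""Species-diagnostic RFLP/CAPS marker discovery, design and genotype calling.

A variant that creates or destroys a restriction-enzyme recognition site
between the two haplotypes makes a PCR amplicon spanning the site
genotype-diagnostic: the two homozygote digests differ, and the heterozygote
shows the union of both banding patterns.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .restriction import Enzyme, digest_fragments, scan_sites
from .sequence_io import Genome, Interval, SpotmapError, Variant, apply_variants

GENOTYPES = ("BW/BW", "BW/PO", "PO/PO")

SITE_LOST_IN_ALT = "site_lost_in_alt"
SITE_GAINED_IN_ALT = "site_gained_in_alt"


class MarkerDesignError(SpotmapError):
    """No amplicon satisfying the design constraints exists; the message
    carries the reason."""


@dataclass(frozen=True)
class RflpCandidate:
    """A variant that changes an enzyme's site presence between haplotypes."""

    variant: Variant
    enzyme: Enzyme
    effect: str
    site_position: int  # 1-based genome start of the affected site

    def __post_init__(self) -> None:
        if self.effect not in (SITE_LOST_IN_ALT, SITE_GAINED_IN_ALT):
            raise SpotmapError(f"bad effect {self.effect!r}")


@dataclass
class RflpMarker:
    """A designed diagnostic amplicon with expected per-genotype digests."""

    name: str
    candidate: RflpCandidate
    amplicon: Interval
    pattern_by_genotype: dict[str, tuple[int, ...]]
    primer_fwd: str = ""
    primer_rev: str = ""


@dataclass(frozen=True)
class GenotypeCall:
    animal_id: str
    marker_name: str
    call: str  # BW/BW, BW/PO, PO/PO or no_call


def site_diff(ref_window: str, alt_window: str, enzyme: Enzyme) -> str | None:
    """Compare site presence between a reference window and its
    variant-applied counterpart.

    Returns ``site_lost_in_alt`` when the alternate haplotype has fewer
    sites, ``site_gained_in_alt`` when it has more, and ``None`` when the
    site sets correspond.
    """
    n_ref = len(scan_sites(ref_window, enzyme))
    n_alt = len(scan_sites(alt_window, enzyme))
    if n_alt < n_ref:
        return SITE_LOST_IN_ALT
    if n_alt > n_ref:
        return SITE_GAINED_IN_ALT
    return None


def _local_windows(
    genome: Genome, variant: Variant, radius: int
) -> tuple[str, str, Interval, dict[int, tuple[int, bool]]]:
    contig_len = len(genome.contigs[variant.contig])
    start = max(1, variant.pos - radius)
    end = min(contig_len, variant.end + radius)
    window = Interval(variant.contig, start, end)
    ref_seq = genome.fetch(variant.contig, start, end)
    alt_seq, coord = apply_variants(genome, [variant], variant.contig, window)
    return ref_seq, alt_seq, window, coord


def variant_site_effects(
    genome: Genome, variant: Variant, enzyme: Enzyme
) -> list[tuple[str, int]]:
    """Site-presence changes one variant causes for one enzyme.

    Windows of ±(motif length − 1) around the variant's reference span are
    compared — the minimal radius at which every affected site overlaps the
    window.  Reference sites are mapped into alternate coordinates; a site
    whose mapped start no longer matches is lost, an unmatched alternate
    site is gained.  Returns ``(effect, site_position)`` pairs with the site
    anchored in reference coordinates.
    """
    radius = len(enzyme.recognition) - 1
    ref_seq, alt_seq, window, coord = _local_windows(genome, variant, radius)
    ref_sites = {window.start + p - 1 for p in scan_sites(ref_seq, enzyme)}
    alt_site_local = set(scan_sites(alt_seq, enzyme))
    mapped = {}
    for g in ref_sites:
        alt_pos, deleted = coord[g]
        mapped[g] = None if deleted else alt_pos
    effects: list[tuple[str, int]] = []
    for g in sorted(g for g, ap in mapped.items() if ap not in alt_site_local):
        effects.append((SITE_LOST_IN_ALT, g))
    matched_alt = {ap for ap in mapped.values() if ap in alt_site_local}
    back = {v[0]: k for k, v in coord.items() if not v[1]}
    for ap in sorted(alt_site_local - matched_alt):
        effects.append((SITE_GAINED_IN_ALT, back.get(ap, variant.pos)))
    return effects


def find_rflp_variants(
    genome: Genome, variants: Sequence[Variant], enzymes: Sequence[Enzyme]
) -> list[RflpCandidate]:
    """All (variant, enzyme) pairs where the variant creates or destroys a
    recognition site; one variant may yield candidates for several enzymes."""
    candidates: list[RflpCandidate] = []
    for variant in variants:
        for enzyme in enzymes:
            for effect, site in variant_site_effects(genome, variant, enzyme):
                candidates.append(RflpCandidate(variant, enzyme, effect, site))
    return candidates


@dataclass(frozen=True)
class MarkerDesignParams:
    min_len: int = 200
    max_len: int = 600
    gel_resolution: int = 20  # bases: minimum resolvable band-size difference

    def __post_init__(self) -> None:
        if not (0 < self.min_len < self.max_len):
            raise SpotmapError("require 0 < min_len < max_len")
        if self.gel_resolution <= 0:
            raise SpotmapError("gel_resolution must be positive")


def _patterns_distinct(
    a: tuple[int, ...], b: tuple[int, ...], resolution: int
) -> bool:
    """Two band patterns are distinguishable when one contains a fragment
    with no counterpart within the gel resolution in the other."""
    return any(all(abs(x - y) >= resolution for y in b) for x in a) or any(
        all(abs(x - y) >= resolution for y in a) for x in b
    )


def _genotype_patterns(
    genome: Genome, candidate: RflpCandidate, amplicon: Interval
) -> dict[str, tuple[int, ...]]:
    enzyme = candidate.enzyme
    bw_seq = genome.fetch(amplicon.contig, amplicon.start, amplicon.end)
    po_seq, _ = apply_variants(genome, [candidate.variant], amplicon.contig, amplicon)
    bw = digest_fragments(bw_seq, [enzyme]).sorted_lengths()
    po = digest_fragments(po_seq, [enzyme]).sorted_lengths()
    het = tuple(sorted(bw + po))
    return {"BW/BW": bw, "BW/PO": het, "PO/PO": po}


def design_marker(
    genome: Genome,
    candidate: RflpCandidate,
    params: MarkerDesignParams | None = None,
    name: str | None = None,
) -> RflpMarker:
    """Choose a diagnostic amplicon for an RFLP candidate.

    The amplicon must contain the affected site, stay within the configured
    length bounds, carry exactly one site for the enzyme on the cut-bearing
    allele (and none on the other), and yield three per-genotype band
    patterns that are pairwise distinguishable at the gel resolution with no
    fragment shorter than the resolution.  Raises :class:`MarkerDesignError`
    with the reason when no placement works.
    """
    params = params or MarkerDesignParams()
    variant = candidate.variant
    contig_len = len(genome.contigs[variant.contig])
    motif_len = len(candidate.enzyme.recognition)
    site_lo = candidate.site_position
    site_hi = candidate.site_position + motif_len - 1
    reasons: set[str] = set()

    lengths = list(range(params.min_len, params.max_len + 1, 25))
    fracs = (0.5, 0.35, 0.65, 0.25, 0.75, 0.15, 0.85)
    for length in lengths:
        for frac in fracs:
            start = site_lo - int(frac * (length - motif_len))
            start = max(1, min(start, contig_len - length + 1))
            end = start + length - 1
            if end > contig_len or start > site_lo or end < site_hi:
                reasons.add("site does not fit in contig at this length")
                continue
            if not (start <= variant.pos and variant.end <= end):
                reasons.add("variant span outside amplicon")
                continue
            amplicon = Interval(variant.contig, start, end)
            patterns = _genotype_patterns(genome, candidate, amplicon)
            cut_allele = (
                "BW/BW" if candidate.effect == SITE_LOST_IN_ALT else "PO/PO"
            )
            uncut_allele = "PO/PO" if cut_allele == "BW/BW" else "BW/BW"
            if len(patterns[cut_allele]) != 2:
                reasons.add("cut-bearing allele is not single-cut in amplicon")
                continue
            if len(patterns[uncut_allele]) != 1:
                reasons.add("uncut allele has a constitutive site in amplicon")
                continue
            if min(patterns["BW/PO"]) < params.gel_resolution:
                reasons.add("fragment below gel resolution")
                continue
            pats = list(patterns.values())
            if not all(
                _patterns_distinct(pats[i], pats[j], params.gel_resolution)
                for i in range(3)
                for j in range(i + 1, 3)
            ):
                reasons.add("genotype patterns not distinguishable on gel")
                continue
            marker_name = name or (
                f"{variant.contig}_{variant.pos}_{candidate.enzyme.name}"
            )
            return RflpMarker(marker_name, candidate, amplicon, patterns)
    raise MarkerDesignError(
        "no admissible amplicon: " + "; ".join(sorted(reasons or {"no window tried"}))
    )


def _multiset_match(
    observed: Sequence[int], expected: Sequence[int], tolerance: int
) -> bool:
    if len(observed) != len(expected):
        return False
    return all(
        abs(o - e) <= tolerance for o, e in zip(sorted(observed), sorted(expected))
    )


def call_genotype(
    marker: RflpMarker,
    observed_fragments: Sequence[int],
    tolerance: int = 10,
    animal_id: str = "",
) -> GenotypeCall:
    """Call a genotype from observed gel fragment lengths.

    The call is the unique genotype whose expected pattern matches the
    observed multiset within ±tolerance per fragment; zero or multiple
    matches give ``no_call``.
    """
    if not observed_fragments:
        raise SpotmapError("observed_fragments is empty")
    matches = [
        g
        for g, pat in marker.pattern_by_genotype.items()
        if _multiset_match(observed_fragments, pat, tolerance)
    ]
    call = matches[0] if len(matches) == 1 else "no_call"
    return GenotypeCall(animal_id, marker.name, call)


def write_marker_table(markers: Iterable[RflpMarker], path: str | Path) -> None:
    """TSV export mirroring the candidate-gene marker table layout."""
    with open(path, "w") as fh:
        fh.write(
            "marker\tcontig\tamplicon_start\tamplicon_end\tpolymorphism_pos\t"
            "enzyme\teffect\tbw_pattern\thet_pattern\tpo_pattern\n"
        )
        for m in markers:
            c = m.candidate
            pat = m.pattern_by_genotype
            fh.write(
                f"{m.name}\t{m.amplicon.contig}\t{m.amplicon.start}\t{m.amplicon.end}\t"
                f"{c.variant.pos}\t{c.enzyme.name}\t{c.effect}\t"
                f"{','.join(map(str, pat['BW/BW']))}\t"
                f"{','.join(map(str, pat['BW/PO']))}\t"
                f"{','.join(map(str, pat['PO/PO']))}\n"
            )
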