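"""IUPAC-aware restriction-site scanning, in-silico digestion and genome-wide
site statistics for RADseq enzyme selection.

A recognition site at position ``p`` (1-based) means the window starting at
``p`` matches the enzyme's motif on the forward strand, or the motif's
reverse complement matches there (a site is cuttable regardless of which
strand the motif is written for).  Each genomic start position is counted
once.  ``N`` in the sequence never matches any motif character, so assembly
gaps cannot inflate counts.
"""

from __future__ import annotations

import csv
import math
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .sequence_io import Genome, Interval, SpotmapError

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

_COMPLEMENT = {
    "A": "T", "T": "A", "C": "G", "G": "C",
    "R": "Y", "Y": "R", "S": "S", "W": "W",
    "K": "M", "M": "K", "B": "V", "V": "B",
    "D": "H", "H": "D", "N": "N",
}


def iupac_revcomp(motif: str) -> str:
    return "".join(_COMPLEMENT[c] for c in reversed(motif))


def _round_half_up(x: float) -> int:
    return math.floor(x + 0.5)


@dataclass(frozen=True)
class Enzyme:
    """A restriction enzyme: name, IUPAC recognition motif, top-strand cut offset.

    ``cut_offset`` is the number of bases of the site left of the cut; when
    unspecified the cut is placed mid-site.  Downstream genotype logic uses
    only fragment-size differences, so the exact offset is not critical.
    """

    name: str
    recognition: str
    cut_offset: int | None = None
    cpg: bool = False

    def __post_init__(self) -> None:
        if len(self.recognition) < 4:
            raise SpotmapError(f"{self.name}: recognition motif shorter than 4")
        bad = set(self.recognition) - set(IUPAC)
        if bad:
            raise SpotmapError(f"{self.name}: non-IUPAC characters {bad}")

    @property
    def is_palindromic(self) -> bool:
        return self.recognition == iupac_revcomp(self.recognition)

    @property
    def effective_cut_offset(self) -> int:
        if self.cut_offset is not None:
            return self.cut_offset
        return len(self.recognition) // 2


@dataclass(frozen=True)
class SiteStats:
    """Genome-wide recognition-site statistics for one enzyme.

    ``rad_markers`` is twice the site count (each site yields two flanking
    sequenced RAD markers); ``avg_fragment`` is total genome length divided
    by site count, rounded to the nearest integer, undefined when the enzyme
    never cuts.
    """

    enzyme_name: str
    site_count: int
    genome_length: int

    @property
    def rad_markers(self) -> int:
        return 2 * self.site_count

    @property
    def avg_fragment(self) -> int | None:
        if self.site_count == 0:
            return None
        return _round_half_up(self.genome_length / self.site_count)


@dataclass(frozen=True)
class FragmentPattern:
    """Multiset of digest fragment lengths from one source sequence."""

    fragment_lengths: tuple[int, ...]
    source_length: int

    def __post_init__(self) -> None:
        if sum(self.fragment_lengths) != self.source_length:
            raise SpotmapError("fragments do not partition the source sequence")

    def sorted_lengths(self) -> tuple[int, ...]:
        return tuple(sorted(self.fragment_lengths))


def _motif_regex(motif: str) -> re.Pattern[str]:
    # N in the subject never matches, so classes contain only ACGT.
    return re.compile("".join(f"[{IUPAC[c]}]" for c in motif))


def scan_sites(sequence: str, enzyme: Enzyme) -> list[int]:
    """All 1-based start positions of the enzyme's site in ``sequence``.

    Overlapping occurrences are all reported; forward-strand and
    reverse-complement matches are pooled and each start position reported
    once.
    """
    positions: set[int] = set()
    motifs = {enzyme.recognition}
    if not enzyme.is_palindromic:
        motifs.add(iupac_revcomp(enzyme.recognition))
    for motif in motifs:
        pat = _motif_regex(motif)
        pos = 0
        while True:
            m = pat.search(sequence, pos)
            if m is None:
                break
            positions.add(m.start() + 1)
            pos = m.start() + 1
    return sorted(positions)


def digest_fragments(
    sequence: str, enzymes: Sequence[Enzyme], source: Interval | None = None
) -> FragmentPattern:
    """Fragment-length pattern from digesting ``sequence`` with all ``enzymes``.

    Cut coordinates are site start + cut offset; an uncut sequence yields a
    single full-length fragment.
    """
    if not enzymes:
        raise SpotmapError("digest_fragments needs at least one enzyme")
    n = len(sequence)
    cuts: set[int] = set()
    for enz in enzymes:
        off = enz.effective_cut_offset
        for p in scan_sites(sequence, enz):
            c = p - 1 + off  # fragment boundary after this many bases
            if 0 < c < n:
                cuts.add(c)
    bounds = [0, *sorted(cuts), n]
    lengths = tuple(b - a for a, b in zip(bounds, bounds[1:]))
    return FragmentPattern(lengths, n)


def genome_site_stats(genome: Genome, enzyme: Enzyme) -> SiteStats:
    """Total recognition-site count and derived RADseq statistics."""
    if genome.total_length == 0:
        raise SpotmapError("empty genome")
    count = sum(len(scan_sites(seq, enzyme)) for seq in genome.contigs.values())
    return SiteStats(enzyme.name, count, genome.total_length)


def rank_enzymes(
    genome: Genome, enzymes: Sequence[Enzyme], target_marker_spacing: int
) -> list[SiteStats]:
    """Order enzymes by how close their average fragment size comes to the
    target marker spacing (ties alphabetical; non-cutting enzymes last)."""
    if not enzymes:
        raise SpotmapError("empty enzyme list")
    if target_marker_spacing <= 0:
        raise SpotmapError("target spacing must be positive")
    stats = [genome_site_stats(genome, e) for e in enzymes]

    def key(s: SiteStats) -> tuple[float, str]:
        if s.avg_fragment is None:
            return (math.inf, s.enzyme_name)
        return (abs(s.avg_fragment - target_marker_spacing), s.enzyme_name)

    return sorted(stats, key=key)


# ---------------------------------------------------------------------------
# Built-in catalog: the 30-enzyme RADseq panel plus the marker-design set.

_BUILTIN = [
    # name, motif, CpG-flag
    ("AciI", "CCGC", True),
    ("ApaI", "GGGCCC", True),
    ("AscI", "GGCGCGCC", True),
    ("AvrII", "CCTAGG", False),
    ("BamHI", "GGATCC", False),
    ("BspQI", "GCTCTTC", False),
    ("BssHII", "GCGCGC", True),
    ("DraI", "TTTAAA", False),
    ("EagI", "CGGCCG", True),
    ("EcoRI", "GAATTC", False),
    ("FseI", "GGCCGGCC", True),
    ("HindIII", "AAGCTT", False),
    ("KpnI", "GGTACC", False),
    ("MspI", "CCGG", True),
    ("NaeI", "GCCGGC", True),
    ("NarI", "GGCGCC", True),
    ("NheI", "GCTAGC", False),
    ("NotI", "GCGGCCGC", True),
    ("PacI", "TTAATTAA", False),
    ("PmeI", "GTTTAAAC", False),
    ("RsrII", "CGGWCCG", True),
    ("SacI", "GAGCTC", False),
    ("SacII", "CCGCGG", True),
    ("SalI", "GTCGAC", True),
    ("SbfI", "CCTGCAGG", False),
    ("SgrAI", "CRCCGGYG", True),
    ("SmaI", "CCCGGG", True),
    ("SpeI", "ACTAGT", False),
    ("SphI", "GCATGC", False),
    ("SspI", "AATATT", False),
    ("StuI", "AGGCCT", False),
    ("SwaI", "ATTTAAAT", False),
    ("XbaI", "TCTAGA", False),
    ("XhoI", "CTCGAG", True),
]

BUILTIN_ENZYMES: dict[str, Enzyme] = {
    name: Enzyme(name, motif, cpg=cpg) for name, motif, cpg in _BUILTIN
}

#: The 30-enzyme panel used for genome-wide RADseq site statistics.
RADSEQ_PANEL: tuple[str, ...] = tuple(
    n for n in sorted(BUILTIN_ENZYMES) if n not in {"AciI", "KpnI", "MspI", "StuI"}
)


def get_enzyme(name: str) -> Enzyme:
    try:
        return BUILTIN_ENZYMES[name]
    except KeyError:
        raise SpotmapError(f"unknown enzyme {name!r}") from None


def read_enzyme_table(path: str | Path) -> list[Enzyme]:
    """Load a user enzyme catalog (TSV: name, recognition, cut_offset, cpg)."""
    enzymes: list[Enzyme] = []
    with open(path) as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            off = row.get("cut_offset", "")
            cut = int(off) if off not in ("", None, ".") else None
            cpg = str(row.get("cpg", "")).strip().lower() in {"yes", "true", "1"}
            enzymes.append(Enzyme(row["name"], row["recognition"].upper(), cut, cpg))
    return enzymes


def write_site_stats_table(stats: Iterable[SiteStats], path: str | Path) -> None:
    """TSV report: enzyme, site count, RAD markers, average fragment size."""
    with open(path, "w") as fh:
        fh.write("enzyme\tsite_count\trad_markers\tavg_fragment\n")
        for s in stats:
            avg = s.avg_fragment if s.avg_fragment is not None else "NA"
            fh.write(f"{s.enzyme_name}\t{s.site_count}\t{s.rad_markers}\t{avg}\n")
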