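#!/usr/bin/env python
"""Discover species-diagnostic RFLP variants and design CAPS markers.

Scans every variant/enzyme pair for created or destroyed recognition sites,
designs diagnostic amplicons (200–600 bp, three distinguishable genotype
patterns at 20 bp gel resolution), and verifies each designed marker by
calling genotypes from its own expected patterns.
"""

import importlib
from pathlib import Path

from spotmap import (
    MarkerDesignError,
    call_genotype,
    design_marker,
    find_rflp_variants,
    get_enzyme,
    make_genome_pair,
)
from spotmap.rflp import write_marker_table

sim = importlib.import_module("01_simulate_genome_pair")

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    truth = make_genome_pair(sim.CONFIG)
    panel = [get_enzyme(n) for n in truth.config.enzyme_panel]
    candidates = find_rflp_variants(truth.genome, truth.variants, panel)
    planted = {
        (p.variant.contig, p.variant.pos, p.enzyme_name)
        for p in truth.planted_rflp
    }
    found = {(c.variant.contig, c.variant.pos, c.enzyme.name) for c in candidates}
    print(
        f"{len(candidates)} RFLP candidates from {len(truth.variants):,} variants; "
        f"planted recovery: {len(found & planted)}/{len(planted)}"
    )

    markers, failures = [], 0
    for cand in candidates:
        try:
            markers.append(design_marker(truth.genome, cand))
        except MarkerDesignError:
            failures += 1
    write_marker_table(markers, RESULTS / "03_rflp_markers.tsv")

    verified = sum(
        all(
            call_genotype(m, pattern, tolerance=10).call == genotype
            for genotype, pattern in m.pattern_by_genotype.items()
        )
        for m in markers
    )
    print(
        f"Designed {len(markers)} markers ({failures} candidates without an "
        f"admissible amplicon); {verified}/{len(markers)} give correct "
        f"genotype calls on their expected patterns."
    )
    print("Marker table in results/03_rflp_markers.tsv")


if __name__ == "__main__":
    main()
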