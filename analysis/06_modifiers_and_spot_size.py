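#!/usr/bin/env python
"""Modifier-locus inference and spot-size comparison.

Runs the modifier-count analysis on the study's tabulated counts (17 of 46
affected backcross offspring resembling the F1 parent), the stock-colony
segregation check (165 spotted of 310), and Welch's comparison of spot size
between BW carriers (25 animals, 77.6 ± 36.6 mm²) and N2 carriers
(46 animals, 14.5 ± 13 mm²).
"""

from pathlib import Path

from spotmap import (
    expected_resemblance_fraction,
    modifier_inference,
    segregation_test,
    welch_from_summary,
)

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    lines = []

    mi = modifier_inference(17, 46, [1, 2, 3], alpha=0.05)
    lines.append("Modifier-locus models for 17/46 offspring resembling the F1 parent:")
    for k, g in mi.per_k.items():
        frac = expected_resemblance_fraction(k)
        verdict = "retained" if k in mi.retained_k else "rejected"
        lines.append(
            f"  k={k} (expected {frac:.1%} resemblance): {g.summary()} -> {verdict}"
        )
    lines.append(
        f"Modifier counts consistent with the data: "
        f"{', '.join(map(str, mi.retained_k))}"
    )

    stock = segregation_test(165, 310)
    lines.append(f"Stock-colony segregation (165 spotted / 310): {stock.summary()}")

    w = welch_from_summary(77.6, 36.6, 25, 14.5, 13.0, 46)
    lines.append(
        f"Spot size, BW carriers vs N2 carriers: {w.summary()} "
        f"(Satterthwaite df {w.df_raw:.2f})"
    )

    report = "\n".join(lines)
    (RESULTS / "06_modifier_statistics.txt").write_text(report + "\n")
    print(report)
    print("Report in results/06_modifier_statistics.txt")


if __name__ == "__main__":
    main()
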