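"""Backcross genetics statistics: exclusion/linkage tests, interval
refinement, segregation distortion, modifier-locus count inference and
Welch's two-sample comparison.

Goodness-of-fit tests follow the reporting conventions common in mouse
genetics papers: expected counts are rounded half-up to integers (the last
class taken by complement so expectations always sum to N), no continuity
correction is applied, and df = number of classes − 1.  Unrounded
expectations are also carried for comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

from scipy import stats as sps

from .sequence_io import SpotmapError


def _round_half_up(x: float) -> int:
    return math.floor(x + 0.5)


@dataclass(frozen=True)
class GofResult:
    """Chi-square goodness-of-fit result (upper-tail p)."""

    observed: tuple[int, ...]
    expected: tuple[float, ...]
    chi2: float
    df: int
    p: float
    chi2_unrounded: float | None = None

    def summary(self) -> str:
        n = sum(self.observed)
        return f"chi2({self.df}, N = {n}) = {self.chi2:.2f}, p = {self.p:.3g}"


def chi_square_gof(
    observed: Sequence[int],
    expected_fractions: Sequence[float],
    round_expected: bool = True,
) -> GofResult:
    """Chi-square goodness of fit of observed counts to expected fractions.

    With ``round_expected`` (the default) each expected count except the last
    is rounded half-up and the last is obtained by subtraction, so the
    expectations are integers summing exactly to N.  No continuity
    correction.
    """
    observed = tuple(int(o) for o in observed)
    if len(observed) != len(expected_fractions) or len(observed) < 2:
        raise SpotmapError("observed and expected_fractions must align (≥2 classes)")
    if any(o < 0 for o in observed):
        raise SpotmapError("negative observed count")
    if abs(sum(expected_fractions) - 1.0) > 1e-9:
        raise SpotmapError("expected fractions must sum to 1")
    n = sum(observed)
    if n == 0:
        raise SpotmapError("N = 0")
    raw = [n * f for f in expected_fractions]
    if round_expected:
        expected = [float(_round_half_up(e)) for e in raw[:-1]]
        expected.append(float(n - sum(expected)))
    else:
        expected = raw
    if any(e <= 0 for e in expected):
        raise SpotmapError("an expected count is zero; test undefined")
    chi2 = sum((o - e) ** 2 / e for o, e in zip(observed, expected))
    chi2_raw = sum((o - e) ** 2 / e for o, e in zip(observed, raw))
    df = len(observed) - 1
    p = float(sps.chi2.sf(chi2, df))
    return GofResult(
        observed=observed,
        expected=tuple(expected),
        chi2=chi2,
        df=df,
        p=p,
        chi2_unrounded=chi2_raw if round_expected else None,
    )


# ---------------------------------------------------------------------------
# Linkage / exclusion


@dataclass(frozen=True)
class LinkageResult:
    marker_name: str
    n_affected: int
    n_het: int
    n_hom_po: int
    n_dropped: int
    verdict: str  # linked | excluded
    gof: GofResult


def exclusion_test(
    calls: Sequence[str],
    marker_name: str = "",
    exclusion_threshold: int = 2,
) -> LinkageResult:
    """Candidate-locus exclusion test on affected backcross animals.

    The causal allele arose on the BW stock, so every affected N2 animal
    must be BW/PO at a linked marker; affected animals homozygous PO carry a
    recombination separating marker and trait.  The marker is declared
    ``excluded`` when at least ``exclusion_threshold`` affected animals are
    PO/PO (default 2, i.e. multiple recombinants), else ``linked``.
    ``no_call`` entries are dropped and counted.
    """
    kept = [c for c in calls if c != "no_call"]
    n_dropped = len(calls) - len(kept)
    if not kept:
        raise SpotmapError("no usable genotype calls")
    bad = set(kept) - {"BW/PO", "PO/PO"}
    if bad:
        raise SpotmapError(f"unexpected calls for a PO backcross: {bad}")
    n_het = sum(c == "BW/PO" for c in kept)
    n_hom = len(kept) - n_het
    verdict = "excluded" if n_hom >= exclusion_threshold else "linked"
    try:
        gof = chi_square_gof([n_het, n_hom], [0.5, 0.5])
    except SpotmapError:
        # N = 1: integer rounding would zero one expectation
        gof = chi_square_gof([n_het, n_hom], [0.5, 0.5], round_expected=False)
    return LinkageResult(marker_name, len(kept), n_het, n_hom, n_dropped, verdict, gof)


@dataclass(frozen=True)
class LinkedInterval:
    """Marker-bounded interval containing the causal locus."""

    left_marker: str | None  # None = open-ended on that side
    right_marker: str | None
    core_markers: tuple[str, ...]  # markers heterozygous in every affected animal


def linked_interval(
    ordered_markers: Sequence[str],
    affected_genotypes: Mapping[str, Sequence[str]],
) -> LinkedInterval:
    """Refine the linked region from a panel of ordered markers.

    The causal locus lies in the maximal run of markers heterozygous in all
    affected animals; the bounding markers are the nearest flanking markers
    showing at least one PO/PO affected animal (recombinant), open-ended
    where no recombinant marker exists on that side.
    """
    if not ordered_markers:
        raise SpotmapError("no markers")
    has_recomb = {}
    for name in ordered_markers:
        calls = [c for c in affected_genotypes[name] if c != "no_call"]
        has_recomb[name] = any(c == "PO/PO" for c in calls)
    core = [name for name in ordered_markers if not has_recomb[name]]
    if not core:
        raise SpotmapError("no linked block: every marker has a recombinant")
    # use the longest contiguous non-recombinant run
    runs: list[list[str]] = [[]]
    for name in ordered_markers:
        if has_recomb[name]:
            runs.append([])
        else:
            runs[-1].append(name)
    best = max(runs, key=len)
    i0 = ordered_markers.index(best[0])
    i1 = ordered_markers.index(best[-1])
    left = ordered_markers[i0 - 1] if i0 > 0 else None
    right = ordered_markers[i1 + 1] if i1 < len(ordered_markers) - 1 else None
    return LinkedInterval(left, right, tuple(best))


def segregation_test(n_affected: int, n_total: int) -> GofResult:
    """Test the affected count in a backcross against the Mendelian 1:1
    expectation for a dominant trait."""
    if n_total <= 0:
        raise SpotmapError("n_total must be positive")
    if not (0 <= n_affected <= n_total):
        raise SpotmapError("need 0 <= n_affected <= n_total")
    return chi_square_gof([n_affected, n_total - n_affected], [0.5, 0.5])


# ---------------------------------------------------------------------------
# Modifier-locus inference


def expected_resemblance_fraction(k: int) -> float:
    """Expected fraction of affected backcross offspring resembling the F1
    parent when k unlinked biallelic modifier loci set the phenotype: the
    offspring must be heterozygous at every modifier, probability 2^-k."""
    if not isinstance(k, int) or k < 1:
        raise SpotmapError("k must be an integer >= 1")
    return 2.0 ** (-k)


@dataclass(frozen=True)
class ModifierInference:
    n_resemble: int
    n_total: int
    alpha: float
    per_k: Mapping[int, GofResult]
    retained_k: tuple[int, ...]


def modifier_inference(
    n_resemble: int,
    n_total: int,
    k_range: Sequence[int] = (1, 2, 3),
    alpha: float = 0.05,
) -> ModifierInference:
    """Which modifier-locus counts are consistent with the observed number of
    affected offspring resembling the F1 parent.

    For each k the observed [resemble, not] split is tested against
    [2^-k, 1 - 2^-k]; k is retained when the goodness-of-fit p ≥ alpha.
    """
    if not (0 <= n_resemble <= n_total):
        raise SpotmapError("need 0 <= n_resemble <= n_total")
    if not k_range:
        raise SpotmapError("empty k_range")
    per_k: dict[int, GofResult] = {}
    for k in sorted(k_range):
        f = expected_resemblance_fraction(k)
        per_k[k] = chi_square_gof([n_resemble, n_total - n_resemble], [f, 1 - f])
    retained = tuple(k for k, g in per_k.items() if g.p >= alpha)
    return ModifierInference(n_resemble, n_total, alpha, per_k, retained)


# ---------------------------------------------------------------------------
# Welch's t


@dataclass(frozen=True)
class WelchResult:
    m1: float
    s1: float
    n1: int
    m2: float
    s2: float
    n2: int
    t: float
    df_raw: float
    df_report: int
    p: float

    def summary(self) -> str:
        return f"Welch's t({self.df_report}) = {self.t:.2f}, p = {self.p:.3g}"


def welch_from_summary(
    m1: float, s1: float, n1: int, m2: float, s2: float, n2: int
) -> WelchResult:
    """Welch's two-sample t-test from group summary statistics.

    t = (m1 - m2) / sqrt(s1²/n1 + s2²/n2); degrees of freedom by
    Welch–Satterthwaite, reported floored to an integer while the two-sided
    p is computed at the unfloored value.
    """
    if n1 < 2 or n2 < 2:
        raise SpotmapError("each group needs n >= 2")
    if s1 <= 0 or s2 <= 0:
        raise SpotmapError("standard deviations must be positive")
    v1, v2 = s1**2 / n1, s2**2 / n2
    se = math.sqrt(v1 + v2)
    t = (m1 - m2) / se
    df_raw = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    p = float(2 * sps.t.sf(abs(t), df_raw))
    return WelchResult(m1, s1, n1, m2, s2, n2, t, df_raw, math.floor(df_raw), p)
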