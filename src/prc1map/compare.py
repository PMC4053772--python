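"""Two-sample comparisons: target-set overlap between fibroblast strains and
binding-profile concordance between conditions (e.g. proliferating vs
senescent cells).

Target-set comparison is exact set arithmetic on gene identifiers, mirroring
a Venn diagram of candidate target lists. Profile concordance is
coordinate-level: the fraction of sites reciprocally recovered in the other
condition plus the median score ratio of matched sites, which captures the
senescence phenotype of preserved peak locations with globally reduced read
density.
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import median
from typing import Sequence

from .peaks import CooccupancySite
from .targets import TargetCall

__all__ = ["OverlapResult", "ConcordanceResult", "compare_targets", "profile_concordance"]


@dataclass(frozen=True, slots=True)
class OverlapResult:
    """Venn decomposition of two target-gene sets."""

    shared: frozenset[str]
    unique_a: frozenset[str]
    unique_b: frozenset[str]

    def __post_init__(self) -> None:
        if self.shared & (self.unique_a | self.unique_b) or self.unique_a & self.unique_b:
            raise ValueError("shared/unique sets must be disjoint")

    @property
    def counts(self) -> tuple[int, int, int, int, int]:
        """(|A|, |B|, |shared|, |unique_a|, |unique_b|)."""
        return (
            len(self.shared) + len(self.unique_a),
            len(self.shared) + len(self.unique_b),
            len(self.shared),
            len(self.unique_a),
            len(self.unique_b),
        )

    def to_dict(self) -> dict:
        n_a, n_b, n_shared, n_ua, n_ub = self.counts
        return {
            "n_a": n_a,
            "n_b": n_b,
            "n_shared": n_shared,
            "n_unique_a": n_ua,
            "n_unique_b": n_ub,
        }


@dataclass(frozen=True, slots=True)
class ConcordanceResult:
    """Coordinate-level agreement of two site lists.

    location_overlap: (fraction of A sites overlapped by B, fraction of B
    sites overlapped by A). density_ratio: median over reciprocally matched
    site pairs of (max member score in B) / (max member score in A); None
    when no sites match.
    """

    location_overlap: tuple[float, float]
    density_ratio: float | None
    n_matched: int

    def __post_init__(self) -> None:
        for f in self.location_overlap:
            if not (0.0 <= f <= 1.0):
                raise ValueError("location_overlap fractions must be in [0, 1]")
        if self.density_ratio is not None and self.density_ratio <= 0:
            raise ValueError("density_ratio must be > 0 when defined")

    def to_dict(self) -> dict:
        return {
            "location_overlap_a_in_b": self.location_overlap[0],
            "location_overlap_b_in_a": self.location_overlap[1],
            "density_ratio": self.density_ratio,
            "n_matched": self.n_matched,
        }


def compare_targets(
    calls_a: Sequence[TargetCall] | Sequence[str],
    calls_b: Sequence[TargetCall] | Sequence[str],
) -> OverlapResult:
    """Venn of two target-gene lists (accepts calls or bare gene ids)."""
    set_a = {c.gene_id if isinstance(c, TargetCall) else c for c in calls_a}
    set_b = {c.gene_id if isinstance(c, TargetCall) else c for c in calls_b}
    return OverlapResult(
        shared=frozenset(set_a & set_b),
        unique_a=frozenset(set_a - set_b),
        unique_b=frozenset(set_b - set_a),
    )


def profile_concordance(
    sites_a: Sequence[CooccupancySite],
    sites_b: Sequence[CooccupancySite],
) -> ConcordanceResult:
    """Quantify how well two site landscapes coincide.

    Sites are matched when they reciprocally overlap (>=1 shared base); a
    site of A overlapping several B sites is matched to the one with the
    largest shared span.
    """
    if not sites_a or not sites_b:
        raise ValueError("profile_concordance requires non-empty site lists on both sides")

    def _overlapped(xs, ys) -> int:
        by_chrom: dict[str, list[CooccupancySite]] = {}
        for y in ys:
            by_chrom.setdefault(y.interval.chrom, []).append(y)
        return sum(
            1
            for x in xs
            if any(x.interval.overlaps(y.interval) for y in by_chrom.get(x.interval.chrom, []))
        )

    frac_a = _overlapped(sites_a, sites_b) / len(sites_a)
    frac_b = _overlapped(sites_b, sites_a) / len(sites_b)

    by_chrom_b: dict[str, list[CooccupancySite]] = {}
    for y in sites_b:
        by_chrom_b.setdefault(y.interval.chrom, []).append(y)
    ratios: list[float] = []
    for x in sites_a:
        best = None
        best_len = 0
        for y in by_chrom_b.get(x.interval.chrom, []):
            ol = x.interval.overlap_length(y.interval)
            if ol > best_len:
                best, best_len = y, ol
        if best is None:
            continue
        a_score, b_score = x.max_score, best.max_score
        if a_score > 0 and b_score > 0:
            ratios.append(b_score / a_score)
    return ConcordanceResult(
        location_overlap=(frac_a, frac_b),
        density_ratio=median(ratios) if ratios else None,
        n_matched=len(ratios),
    )
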