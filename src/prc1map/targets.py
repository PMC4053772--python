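"""Assignment of co-occupancy sites to candidate target genes and
classification of each locus's peak architecture.

Each site is assigned to the gene with the nearest TSS, except that a site
overlapping both a coding and a noncoding gene body goes to the coding gene,
and a cluster spanning the bodies of closely linked genes is declared
AMBIGUOUS rather than forced onto one locus. Per-gene architecture is then
classified from the positions of the assigned sites relative to the TSS and
TES: TSS-associated, TES-associated, or peaks at both ends of the
transcription unit — the last subdivided into discrete flanking peaks,
purely internal peaks, and peaks distributed across the unit.
"""

from __future__ import annotations

import logging
from bisect import bisect_left
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .core import GeneModel, GenomicInterval, Peak, nearest_feature
from .peaks import CooccupancySite

__all__ = [
    "ArchitectureConfig",
    "TargetCall",
    "AssignmentResult",
    "assign_targets",
    "classify_architecture",
    "category_proportions",
    "spacing_regularity",
    "target_table",
    "write_assigned_sites_bed",
    "CATEGORIES",
    "SUBCATEGORIES",
]

logger = logging.getLogger(__name__)

CATEGORIES = ("TSS_ASSOCIATED", "TES_ASSOCIATED", "BOTH_ENDS", "AMBIGUOUS")
SUBCATEGORIES = ("FLANKING_DISCRETE", "INTERNAL", "DISTRIBUTED")


@dataclass(frozen=True, slots=True)
class ArchitectureConfig:
    """Tunable geometry of the architecture classification.

    end_window
        Distance (bp) from TSS/TES within which a site counts as "at" that
        end. Default 10 kb — the conventional promoter-proximal range, though
        observed assignment distances run far beyond it.
    body_overlap_fraction
        Minimum fraction of a site lying inside the gene body for the site
        to count as internal.
    max_assignment_distance
        Optional cap (bp) on site-to-TSS assignment distance; unbounded by
        default because genuine targets occur hundreds of kb from the TSS.
    """

    end_window: int = 10_000
    body_overlap_fraction: float = 0.5
    max_assignment_distance: int | None = None

    def __post_init__(self) -> None:
        if self.end_window <= 0:
            raise ValueError("end_window must be > 0")
        if not (0.0 < self.body_overlap_fraction <= 1.0):
            raise ValueError("body_overlap_fraction must be in (0, 1]")


@dataclass(frozen=True, slots=True)
class TargetCall:
    """One candidate target locus: a gene plus its assigned sites.

    ``n_prc1_factors`` counts distinct CBX/RING factors over all assigned
    sites (>= 2 by the co-occupancy criterion). Distances are signed genomic
    offsets (site midpoint minus TSS/TES) of the closest assigned site.
    ``shares_sites_with`` lists co-members of an ambiguous cluster whose
    calls reference the same sites.
    """

    gene: GeneModel
    category: str
    sites: tuple[CooccupancySite, ...]
    subcategory: str | None = None
    distance_to_tss: int | None = None
    distance_to_tes: int | None = None
    shares_sites_with: tuple[str, ...] = ()
    owns_sites: bool = True

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if (self.subcategory is not None) != (self.category == "BOTH_ENDS"):
            raise ValueError("subcategory present iff category is BOTH_ENDS")
        if self.subcategory is not None and self.subcategory not in SUBCATEGORIES:
            raise ValueError(f"unknown subcategory {self.subcategory!r}")
        if self.n_prc1_factors < 2:
            raise ValueError("a target needs >=2 PRC1 factors (>=1 CBX, >=1 RING)")

    @property
    def gene_id(self) -> str:
        return self.gene.gene_id

    @property
    def n_prc1_factors(self) -> int:
        seen: set[str] = set()
        for s in self.sites:
            seen |= s.prc1_factors
        return len(seen)


@dataclass(slots=True)
class AssignmentResult:
    calls: list[TargetCall]
    unassigned: list[CooccupancySite] = field(default_factory=list)

    def by_gene(self) -> dict[str, TargetCall]:
        return {c.gene_id: c for c in self.calls}


class _TssIndex:
    """Sorted per-chromosome TSS index with the nearest_feature tie rule.

    Equivalent to an exhaustive scan (coding-before-noncoding, then
    lexicographic gene_id on |distance| ties) but O(log n) per query.
    """

    def __init__(self, genes: Sequence[GeneModel]):
        self._by_chrom: dict[str, tuple[list[int], list[GeneModel]]] = {}
        for chrom in {g.chrom for g in genes}:
            ordered = sorted(
                (g for g in genes if g.chrom == chrom),
                key=lambda g: (g.tss, 0 if g.biotype == "coding" else 1, g.gene_id),
            )
            self._by_chrom[chrom] = ([g.tss for g in ordered], ordered)

    def nearest(self, chrom: str, pos: int) -> tuple[GeneModel, int] | None:
        entry = self._by_chrom.get(chrom)
        if entry is None:
            return None
        positions, ordered = entry
        i = bisect_left(positions, pos)
        best_abs = None
        for j in (i - 1, i):
            if 0 <= j < len(positions):
                d = abs(positions[j] - pos)
                best_abs = d if best_abs is None else min(best_abs, d)
        # expand to every gene at |distance| == best_abs, then apply tie rule
        lo = bisect_left(positions, pos - best_abs)
        hi = bisect_left(positions, pos + best_abs + 1)
        candidates = [g for g in ordered[lo:hi] if abs(g.tss - pos) == best_abs]
        winner = min(
            candidates,
            key=lambda g: (0 if g.biotype == "coding" else 1, g.gene_id),
        )
        return winner, winner.tss - pos


def assign_targets(
    sites: Sequence[CooccupancySite],
    genes: Sequence[GeneModel],
    config: ArchitectureConfig | None = None,
    distance_reference: str = "midpoint",
) -> AssignmentResult:
    """Assign co-occupancy sites to genes and classify each locus.

    Assignment uses the nearest TSS to the site midpoint (or summit of the
    strongest member peak when ``distance_reference='summit'``), with coding
    genes preferred over noncoding ones whose bodies the site also overlaps.
    Sites with no gene on their chromosome (or beyond
    ``max_assignment_distance``) land in the ``unassigned`` sink.
    """
    if not genes:
        raise ValueError("assign_targets requires a non-empty gene annotation")
    config = config or ArchitectureConfig()
    if distance_reference not in ("midpoint", "summit"):
        raise ValueError("distance_reference must be midpoint|summit")

    genes_by_id = {g.gene_id: g for g in genes}
    tss_index = _TssIndex(genes)
    genes_by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        genes_by_chrom.setdefault(g.chrom, []).append(g)
    for lst in genes_by_chrom.values():
        lst.sort(key=lambda g: g.interval.start)
    starts_by_chrom = {c: [g.interval.start for g in lst] for c, lst in genes_by_chrom.items()}
    lookback = {c: max(g.interval.length for g in lst) for c, lst in genes_by_chrom.items()}

    def _overlapping_genes(site: CooccupancySite) -> list[GeneModel]:
        chrom = site.interval.chrom
        lst = genes_by_chrom.get(chrom)
        if not lst:
            return []
        starts = starts_by_chrom[chrom]
        hi = bisect_left(starts, site.interval.end)
        out = []
        j = hi - 1
        floor = site.interval.start - lookback[chrom]
        while j >= 0 and starts[j] > floor:
            if lst[j].interval.end > site.interval.start:
                out.append(lst[j])
            j -= 1
        out.reverse()
        return out

    assigned: dict[str, list[CooccupancySite]] = {}
    ambiguous_groups: list[tuple[frozenset[str], CooccupancySite]] = []
    unassigned: list[CooccupancySite] = []

    for site in sorted(sites, key=lambda s: (s.interval.chrom, s.interval.start)):
        ref = _site_reference(site, distance_reference)
        overlapping = _overlapping_genes(site)
        # coding preference: when the span touches coding and noncoding
        # bodies, only the coding loci compete
        candidates = [g for g in overlapping if g.biotype == "coding"] or overlapping

        linked = _closely_linked(candidates, config.end_window)
        if len(linked) >= 2:
            ambiguous_groups.append((frozenset(g.gene_id for g in linked), site))
            continue

        if candidates:
            hit = nearest_feature(
                (site.interval.chrom, ref), [((g.chrom, g.tss), g) for g in candidates]
            )
        else:
            hit = tss_index.nearest(site.interval.chrom, ref)
        if hit is None:
            unassigned.append(site)
            continue
        gene, dist = hit
        if (
            config.max_assignment_distance is not None
            and abs(dist) > config.max_assignment_distance
            and not candidates
        ):
            unassigned.append(site)
            continue
        assigned.setdefault(gene.gene_id, []).append(site)

    calls: list[TargetCall] = []
    for gene_id, gene_sites in assigned.items():
        call = TargetCall(
            gene=genes_by_id[gene_id],
            category="TSS_ASSOCIATED",  # placeholder; classified next
            sites=tuple(gene_sites),
        )
        calls.append(
            classify_architecture(call, genes_by_id[gene_id], config,
                                  distance_reference=distance_reference)
        )

    # ambiguous clusters: every implicated gene gets an AMBIGUOUS call; the
    # nearest-TSS gene owns the sites, co-members reference them
    amb_sites: dict[str, list[CooccupancySite]] = {}
    amb_partners: dict[str, set[str]] = {}
    owners: dict[int, str] = {}
    for group, site in ambiguous_groups:
        ref = _site_reference(site, distance_reference)
        pool = [((genes_by_id[g].chrom, genes_by_id[g].tss), genes_by_id[g]) for g in group]
        owner, _ = nearest_feature((site.interval.chrom, ref), pool)
        owners[id(site)] = owner.gene_id
        for gid in group:
            amb_sites.setdefault(gid, []).append(site)
            amb_partners.setdefault(gid, set()).update(group - {gid})
    for gid, gsites in amb_sites.items():
        calls.append(
            TargetCall(
                gene=genes_by_id[gid],
                category="AMBIGUOUS",
                sites=tuple(gsites),
                shares_sites_with=tuple(sorted(amb_partners[gid])),
                owns_sites=all(owners[id(s)] == gid for s in gsites),
            )
        )

    calls.sort(key=lambda c: c.gene_id)
    return AssignmentResult(calls=calls, unassigned=unassigned)


def _site_reference(site: CooccupancySite, mode: str) -> int:
    if mode == "summit" and site.member_peaks:
        strongest = max(site.member_peaks, key=lambda p: p.score)
        return strongest.summit
    return site.interval.midpoint


def _closely_linked(genes: list[GeneModel], end_window: int) -> list[GeneModel]:
    """Genes whose bodies all lie within 2*end_window of another member."""
    if len(genes) < 2:
        return genes
    linked: set[str] = set()
    for i, a in enumerate(genes):
        for b in genes[i + 1:]:
            gap = max(a.interval.start, b.interval.start) - min(a.interval.end, b.interval.end)
            if gap <= 2 * end_window:
                linked.add(a.gene_id)
                linked.add(b.gene_id)
    return [g for g in genes if g.gene_id in linked] if linked else [genes[0]]


def classify_architecture(
    call: TargetCall,
    gene: GeneModel,
    config: ArchitectureConfig | None = None,
    distance_reference: str = "midpoint",
) -> TargetCall:
    """Set the architecture category/subcategory of a target call.

    Sites within ``end_window`` of the TSS (resp. TES) form the end
    clusters. Both clusters populated => BOTH_ENDS; only a TES cluster, or
    no clusters with the TES strictly nearer => TES_ASSOCIATED; sites lying
    wholly within the gene body away from both ends => BOTH_ENDS/INTERNAL
    (internal peaks belong to the both-ends group of profiles); otherwise
    TSS_ASSOCIATED. BOTH_ENDS splits into FLANKING_DISCRETE (no site
    overlaps the body), INTERNAL, or DISTRIBUTED.

    Genes shorter than twice ``end_window`` are classified with the window
    shrunk to half the gene length; such calls are logged because the
    TSS/TES distinction is debatable for short genes.
    """
    if not call.sites:
        raise ValueError("classify_architecture requires >= 1 assigned site")
    config = config or ArchitectureConfig()
    w = config.end_window
    if gene.interval.length < 2 * w:
        w = max(1, gene.interval.length // 2)
        logger.info(
            "gene %s shorter than 2x end_window; shrunk window to %d bp",
            gene.gene_id, w,
        )

    refs = [_site_reference(s, distance_reference) for s in call.sites]
    d_tss = [r - gene.tss for r in refs]
    d_tes = [r - gene.tes for r in refs]
    near_tss = [abs(d) <= w for d in d_tss]
    near_tes = [abs(d) <= w for d in d_tes]
    inside = [
        s.interval.overlap_length(gene.interval) / s.interval.length
        >= config.body_overlap_fraction
        for s in call.sites
    ]

    min_tss = min(abs(d) for d in d_tss)
    min_tes = min(abs(d) for d in d_tes)

    subcategory: str | None = None
    if any(near_tss) and any(near_tes):
        category = "BOTH_ENDS"
    elif not any(near_tss) and not any(near_tes) and all(inside):
        category = "BOTH_ENDS"
        subcategory = "INTERNAL"
    elif any(near_tes) and not any(near_tss):
        category = "TES_ASSOCIATED"
    elif not any(near_tss) and not any(near_tes) and min_tes < min_tss:
        category = "TES_ASSOCIATED"
    else:
        category = "TSS_ASSOCIATED"

    if category == "BOTH_ENDS" and subcategory is None:
        if not any(inside):
            subcategory = "FLANKING_DISCRETE"
        elif all(inside) and not any(near_tss) and not any(near_tes):
            subcategory = "INTERNAL"
        else:
            subcategory = "DISTRIBUTED"

    sign_tss = min(d_tss, key=abs)
    sign_tes = min(d_tes, key=abs)
    return replace(
        call,
        category=category,
        subcategory=subcategory,
        distance_to_tss=sign_tss,
        distance_to_tes=sign_tes,
    )


def category_proportions(calls: Sequence[TargetCall]) -> tuple[dict[str, float], float]:
    """Fractions of target loci per architecture category.

    Returns ``(proportions, ambiguous_fraction)``: proportions are over
    non-AMBIGUOUS calls and sum to 1; the AMBIGUOUS share of all calls is
    reported separately.
    """
    if not calls:
        return {}, 0.0
    resolved = [c for c in calls if c.category != "AMBIGUOUS"]
    n_amb = len(calls) - len(resolved)
    props: dict[str, float] = {}
    if resolved:
        for cat in CATEGORIES[:3]:
            k = sum(1 for c in resolved if c.category == cat)
            if k:
                props[cat] = k / len(resolved)
    return props, n_amb / len(calls)


def spacing_regularity(
    peaks: Sequence[Peak], min_peaks: int = 4
) -> tuple[float, float] | None:
    """Summit-spacing summary for evenly spaced peak arrays.

    Returns ``(mean_gap, regularity)`` where regularity = max(0, 1 - CV) of
    successive summit gaps (CV = population SD / mean); a perfectly even
    array scores 1. Returns ``None`` with fewer than ``min_peaks`` peaks.
    """
    if len(peaks) < min_peaks:
        return None
    summits = np.sort([p.summit for p in peaks])
    gaps = np.diff(summits).astype(float)
    mean_gap = float(gaps.mean())
    if mean_gap == 0:
        return 0.0, 0.0
    cv = float(gaps.std() / mean_gap)
    return mean_gap, max(0.0, 1.0 - cv)


# ---------------------------------------------------------------------------
# Tabular output (per-locus table of PRC1 protein counts + architecture)
# ---------------------------------------------------------------------------

def target_table(
    calls_by_sample: dict[str, Sequence[TargetCall]],
    activity_by_sample: dict[str, dict[str, bool]] | None = None,
):
    """Combined per-locus table across samples.

    One row per gene called in any sample: per-sample PRC1 factor counts
    (0 when not a target there), architecture category/subcategory and
    distances from the first sample calling the gene, plus per-sample
    TRUE/FALSE transcriptional-activity flags when provided. Returns a
    pandas DataFrame sorted alphabetically by gene name.
    """
    import pandas as pd

    samples = list(calls_by_sample)
    index: dict[str, dict] = {}
    for sample in samples:
        for call in calls_by_sample[sample]:
            row = index.setdefault(
                call.gene_id,
                {
                    "gene_id": call.gene_id,
                    "name": call.gene.name,
                    "category": call.category,
                    "subcategory": call.subcategory or "",
                    "distance_to_tss": call.distance_to_tss,
                    "distance_to_tes": call.distance_to_tes,
                },
            )
            row[f"n_prc1_factors_{sample}"] = call.n_prc1_factors
    for sample in samples:
        col = f"n_prc1_factors_{sample}"
        for row in index.values():
            row.setdefault(col, 0)
        if activity_by_sample and sample in activity_by_sample:
            flags = activity_by_sample[sample]
            for gid, row in index.items():
                row[f"active_{sample}"] = bool(flags.get(gid, False))
    cols = ["gene_id", "name"] + [f"n_prc1_factors_{s}" for s in samples] + [
        "category", "subcategory", "distance_to_tss", "distance_to_tes",
    ]
    if activity_by_sample:
        cols += [f"active_{s}" for s in samples if s in activity_by_sample]
    df = pd.DataFrame(sorted(index.values(), key=lambda r: r["name"]))
    if df.empty:
        return pd.DataFrame(columns=cols)
    return df[cols]


def write_assigned_sites_bed(result: AssignmentResult, path: str | Path) -> None:
    """BED of every assigned site tagged with its gene; sink sites tagged UNASSIGNED."""
    rows = []
    for call in result.calls:
        for s in call.sites:
            if not call.owns_sites:
                continue
            tag = call.gene_id if call.category != "AMBIGUOUS" else (
                "|".join(sorted({call.gene_id, *call.shares_sites_with}))
            )
            rows.append((s.interval, tag, s.max_score))
    for s in result.unassigned:
        rows.append((s.interval, "UNASSIGNED", s.max_score))
    rows.sort(key=lambda r: (r[0].chrom, r[0].start))
    with open(path, "w") as fh:
        for iv, tag, score in rows:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{tag}\t{score:g}\t.\n")
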