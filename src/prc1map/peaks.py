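"""From per-replicate peak calls to per-factor binding regions and
multi-factor co-occupancy sites.

A candidate PRC1 target locus is a genomic span at which ChIP-seq detects at
least one CBX (Pc ortholog), at least one RING (Sce ortholog) and the
H3K27me3 mark. The RING union approximates all catalytically active PRC1,
so the criterion demands both a reader and a ligase subunit plus the PRC2
mark before a span is considered PRC1-occupied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .core import (
    ConfigError,
    FactorRegistry,
    GenomicInterval,
    Peak,
    merge_intervals,
    read_peaks,
)

__all__ = [
    "BindingRegion",
    "CooccupancySite",
    "merge_replicates",
    "call_cooccupancy",
    "filter_foothills",
    "Manifest",
    "ManifestEntry",
    "load_manifest",
    "regions_from_manifest",
    "write_cooccupancy_bed",
]


@dataclass(frozen=True, slots=True)
class BindingRegion:
    """A merged per-factor binding region with replicate support."""

    interval: GenomicInterval
    factor: str
    support: int
    max_score: float
    member_peaks: tuple[Peak, ...] = ()

    def __post_init__(self) -> None:
        if self.support < 1:
            raise ValueError("support must be >= 1")


@dataclass(frozen=True, slots=True)
class CooccupancySite:
    """A span where >=1 CBX, >=1 RING and H3K27me3 all bind.

    ``rejected`` marks sites that stopped satisfying the criterion after
    foothill filtering; they are retained for auditing, never dropped
    silently.
    """

    interval: GenomicInterval
    factors_present: frozenset[str]
    cbx_members: frozenset[str]
    ring_members: frozenset[str]
    has_h3k27me3: bool
    member_peaks: tuple[Peak, ...] = ()
    rejected: bool = False

    def __post_init__(self) -> None:
        if not self.rejected:
            if not self.cbx_members or not self.ring_members or not self.has_h3k27me3:
                raise ValueError(
                    "co-occupancy criterion violated: need >=1 CBX, >=1 RING "
                    "and H3K27me3"
                )
        if not self.factors_present >= (self.cbx_members | self.ring_members):
            raise ValueError("factors_present must contain all CBX/RING members")

    @property
    def max_score(self) -> float:
        if not self.member_peaks:
            return 0.0
        return max(p.score for p in self.member_peaks)

    @property
    def prc1_factors(self) -> frozenset[str]:
        return self.cbx_members | self.ring_members


def merge_replicates(
    peaks: list[Peak],
    mode: str = "union",
    gap: int = 0,
) -> list[BindingRegion]:
    """Merge one factor/sample's replicate peak calls into binding regions.

    ``union``: per-base union over all replicates, joining gaps <= ``gap``;
    ``support`` counts the distinct replicates contributing to each region.
    ``intersection``: keeps only regions where >=2 replicates overlap,
    trimmed to the merged span of the overlapping peaks.
    """
    if mode not in ("union", "intersection"):
        raise ConfigError(f"unknown replicate mode {mode!r} (union|intersection)")
    if not peaks:
        return []
    factors = {p.factor for p in peaks}
    samples = {p.sample for p in peaks}
    if len(factors) > 1 or len(samples) > 1:
        raise ValueError(
            f"merge_replicates expects one factor/sample, got factors={sorted(factors)} "
            f"samples={sorted(samples)}"
        )
    factor = peaks[0].factor

    merged = merge_intervals([p.interval for p in peaks], gap=gap)
    # every peak lies wholly inside exactly one union span, so a two-pointer
    # sweep over the co-sorted lists partitions peaks among spans in O(n)
    ordered = sorted(peaks, key=lambda p: (p.interval.chrom, p.interval.start))
    regions: list[BindingRegion] = []
    i = 0
    for span in merged:
        members: list[Peak] = []
        while (
            i < len(ordered)
            and ordered[i].interval.chrom == span.chrom
            and ordered[i].interval.start <= span.end
        ):
            members.append(ordered[i])
            i += 1
        members_t = tuple(members)
        reps = {p.replicate for p in members_t}
        if mode == "intersection":
            trimmed = _intersection_span(members_t)
            if trimmed is None:
                continue
            span = trimmed
            members_t = tuple(p for p in members_t if p.interval.overlaps(span))
            reps = {p.replicate for p in members_t}
        regions.append(
            BindingRegion(
                interval=span,
                factor=factor,
                support=len(reps),
                max_score=max(p.score for p in members_t),
                member_peaks=members_t,
            )
        )
    return sorted(regions, key=lambda r: (r.interval.chrom, r.interval.start))


def _intersection_span(members: tuple[Peak, ...]) -> GenomicInterval | None:
    """Merged span of peaks that overlap a peak from another replicate."""
    keep: set[int] = set()
    for i, p in enumerate(members):
        for j, q in enumerate(members):
            if (
                i != j
                and p.replicate != q.replicate
                and p.interval.overlaps(q.interval)
            ):
                keep.add(i)
                keep.add(j)
    if not keep:
        return None
    ivs = [members[i].interval for i in sorted(keep)]
    merged = merge_intervals(ivs, gap=0)
    # a single binding event: contributing overlapping peaks form one span
    return GenomicInterval(
        merged[0].chrom, min(iv.start for iv in merged), max(iv.end for iv in merged)
    )


def call_cooccupancy(
    regions_by_factor: dict[str, list[BindingRegion]],
    registry: FactorRegistry,
    required_mark: str = "H3K27me3",
    link_gap: int = 1000,
) -> list[CooccupancySite]:
    """Compile co-occupancy sites from per-factor binding regions.

    All factors' regions are pooled and merged with ``link_gap`` into
    candidate spans; a span becomes a site when the overlapping factors
    include >=1 CBX-class, >=1 RING-class and ``required_mark``.
    """
    if not regions_by_factor:
        return []
    for factor in regions_by_factor:
        registry.class_of(factor)  # raises ConfigError on unknown factor
    if required_mark not in regions_by_factor:
        raise ConfigError(f"required mark {required_mark!r} missing from input tracks")

    pooled = sorted(
        (
            (r.interval.chrom, r.interval.start, factor, r)
            for factor, regions in regions_by_factor.items()
            for r in regions
        ),
        key=lambda t: (t[0], t[1]),
    )
    spans = merge_intervals([t[3].interval for t in pooled], gap=link_gap)

    # each pooled region lies wholly inside exactly one linked span
    sites: list[CooccupancySite] = []
    i = 0
    for span in spans:
        present: set[str] = set()
        members: list[Peak] = []
        while i < len(pooled) and pooled[i][0] == span.chrom and pooled[i][1] <= span.end:
            _, _, factor, region = pooled[i]
            present.add(factor)
            members.extend(region.member_peaks)
            i += 1
        cbx = frozenset(f for f in present if registry.class_of(f) == "CBX")
        ring = frozenset(f for f in present if registry.class_of(f) == "RING")
        if cbx and ring and required_mark in present:
            sites.append(
                CooccupancySite(
                    interval=span,
                    factors_present=frozenset(present),
                    cbx_members=cbx,
                    ring_members=ring,
                    has_h3k27me3=True,
                    member_peaks=tuple(
                        sorted(members, key=lambda p: (p.interval.start, p.factor, p.replicate))
                    ),
                )
            )
    return sorted(sites, key=lambda s: (s.interval.chrom, s.interval.start))


def filter_foothills(
    site: CooccupancySite,
    registry: FactorRegistry,
    min_fraction: float = 0.0,
) -> CooccupancySite:
    """Drop weak flanking ('foothill') member peaks from a site.

    Removes member peaks scoring below ``min_fraction`` of the site's maximum
    member-peak score and recomputes the factor sets. A site that no longer
    satisfies the co-occupancy criterion is returned flagged ``rejected``.
    """
    if not (0.0 <= min_fraction <= 1.0):
        raise ConfigError(f"min_fraction must be in [0, 1], got {min_fraction}")
    if min_fraction == 0.0 or not site.member_peaks:
        return site
    threshold = min_fraction * max(p.score for p in site.member_peaks)
    kept = tuple(p for p in site.member_peaks if p.score >= threshold)
    present = frozenset(p.factor for p in kept)
    cbx = frozenset(f for f in present if registry.class_of(f) == "CBX")
    ring = frozenset(f for f in present if registry.class_of(f) == "RING")
    has_mark = "H3K27me3" in present
    rejected = not (cbx and ring and has_mark)
    return CooccupancySite(
        interval=site.interval,
        factors_present=present,
        cbx_members=cbx,
        ring_members=ring,
        has_h3k27me3=has_mark,
        member_peaks=kept,
        rejected=rejected,
    )


# ---------------------------------------------------------------------------
# Track manifests
# ---------------------------------------------------------------------------

@dataclass(frozen=True, slots=True)
class ManifestEntry:
    path: str
    factor: str
    factor_class: str
    sample: str
    replicate: str
    format: str = "narrowPeak"


@dataclass(slots=True)
class Manifest:
    """Declares every peak file with its factor, class, sample and replicate."""

    entries: list[ManifestEntry]
    base_dir: Path = field(default_factory=Path)

    @property
    def registry(self) -> FactorRegistry:
        return FactorRegistry(
            {e.factor: e.factor_class for e in self.entries}
        )

    def samples(self) -> list[str]:
        return sorted({e.sample for e in self.entries})

    def validate(self) -> None:
        missing = [
            str(self.base_dir / e.path)
            for e in self.entries
            if not (self.base_dir / e.path).is_file()
        ]
        if missing:
            raise ConfigError(f"manifest references missing files: {missing}")
        by_factor = {}
        for e in self.entries:
            by_factor.setdefault(e.factor, set()).add(e.factor_class)
        conflicting = {f: sorted(c) for f, c in by_factor.items() if len(c) > 1}
        if conflicting:
            raise ConfigError(f"factors declared with conflicting classes: {conflicting}")


def load_manifest(path: str | Path) -> Manifest:
    """Load a YAML manifest (``tracks:`` list of path/factor/class/sample/replicate)."""
    path = Path(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "tracks" not in doc:
        raise ConfigError(f"manifest {path} must be a mapping with a 'tracks' list")
    entries = []
    for i, rec in enumerate(doc["tracks"]):
        try:
            entries.append(
                ManifestEntry(
                    path=rec["path"],
                    factor=rec["factor"],
                    factor_class=rec["class"],
                    sample=str(rec["sample"]),
                    replicate=str(rec["replicate"]),
                    format=rec.get("format", "narrowPeak"),
                )
            )
        except KeyError as exc:
            raise ConfigError(f"manifest track #{i + 1} missing key {exc}") from None
    return Manifest(entries=entries, base_dir=path.parent)


def regions_from_manifest(
    manifest: Manifest,
    sample: str,
    mode: str = "union",
    gap: int = 0,
) -> dict[str, list[BindingRegion]]:
    """Read one sample's tracks and merge replicates per factor."""
    peaks_by_factor: dict[str, list[Peak]] = {}
    for e in manifest.entries:
        if e.sample != sample:
            continue
        peaks = read_peaks(
            manifest.base_dir / e.path,
            format=e.format,
            factor=e.factor,
            sample=e.sample,
            replicate=e.replicate,
        )
        peaks_by_factor.setdefault(e.factor, []).extend(peaks)
    return {
        factor: merge_replicates(peaks, mode=mode, gap=gap)
        for factor, peaks in peaks_by_factor.items()
    }


def write_cooccupancy_bed(sites: list[CooccupancySite], path: str | Path) -> None:
    """BED6+ of sites; column 7 lists factors_present comma-joined."""
    with open(path, "w") as fh:
        for i, s in enumerate(sites):
            iv = s.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\tsite_{i + 1}\t"
                f"{s.max_score:g}\t.\t{','.join(sorted(s.factors_present))}\n"
            )
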