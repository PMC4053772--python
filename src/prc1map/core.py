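"""Genomic domain types, interval arithmetic, and peak/gene file I/O.

Coordinates are 0-based half-open throughout (BED convention). GTF input,
which is 1-based inclusive, is converted on read and back on write. Strand
``+``/``-``/``.`` follows BED; gene models must be stranded because TSS and
TES are strand-derived.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Sequence

__all__ = [
    "ParseError",
    "ConfigError",
    "GenomicInterval",
    "Peak",
    "GeneModel",
    "FactorRegistry",
    "DEFAULT_REGISTRY",
    "read_peaks",
    "write_peaks",
    "read_genes",
    "write_genes_gtf",
    "merge_intervals",
    "nearest_feature",
]


class ParseError(ValueError):
    """Malformed record in an input file; message names the line number."""


class ConfigError(ValueError):
    """Invalid configuration (unknown format, out-of-range parameter...)."""


@dataclass(frozen=True, slots=True)
class GenomicInterval:
    """A located genomic span, 0-based half-open.

    Invariants: ``0 <= start < end``, non-empty ``chrom``, strand in
    ``{+, -, .}``.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval", min_overlap: int = 1) -> bool:
        """True when the two spans share at least ``min_overlap`` bases."""
        if self.chrom != other.chrom:
            return False
        return min(self.end, other.end) - max(self.start, other.start) >= min_overlap

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True, slots=True)
class Peak:
    """One peak call: an interval plus enrichment score and provenance.

    ``summit_offset`` is relative to ``interval.start`` (narrowPeak column 10);
    ``None`` means no summit was called.
    """

    interval: GenomicInterval
    score: float
    factor: str
    sample: str = ""
    replicate: str = ""
    summit_offset: int | None = None

    def __post_init__(self) -> None:
        if self.score < 0:
            raise ValueError(f"peak score must be >= 0, got {self.score}")
        if self.summit_offset is not None and not (
            0 <= self.summit_offset < self.interval.length
        ):
            raise ValueError(
                f"summit_offset {self.summit_offset} outside interval of length "
                f"{self.interval.length}"
            )

    @property
    def summit(self) -> int:
        """Absolute summit position; falls back to the interval midpoint."""
        if self.summit_offset is None:
            return self.interval.midpoint
        return self.interval.start + self.summit_offset


@dataclass(frozen=True, slots=True)
class GeneModel:
    """A gene with strand-derived TSS/TES and a coding/noncoding biotype.

    Multi-isoform genes are represented by their outermost span, so the TSS
    is the 5'-most base and the TES the 3'-most base of any isoform.
    """

    gene_id: str
    name: str
    interval: GenomicInterval
    biotype: str = "coding"

    def __post_init__(self) -> None:
        if self.interval.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id} must be stranded (+/-)")
        if self.biotype not in ("coding", "noncoding"):
            raise ValueError(f"gene {self.gene_id}: biotype must be coding|noncoding")

    @property
    def tss(self) -> int:
        iv = self.interval
        return iv.start if iv.strand == "+" else iv.end - 1

    @property
    def tes(self) -> int:
        iv = self.interval
        return iv.end - 1 if iv.strand == "+" else iv.start

    @property
    def chrom(self) -> str:
        return self.interval.chrom


# ---------------------------------------------------------------------------
# Factor registry
# ---------------------------------------------------------------------------

_FACTOR_CLASSES = ("CBX", "RING", "HISTONE_MARK", "OTHER")


class FactorRegistry:
    """Maps factor names to classes {CBX, RING, HISTONE_MARK, OTHER}.

    The co-occupancy criterion is expressed in classes, not names, so new
    tracks (HPH, BMI1, MEL18...) can be added by configuration alone.
    """

    def __init__(self, classes: dict[str, str]):
        for name, cls in classes.items():
            if cls not in _FACTOR_CLASSES:
                raise ConfigError(
                    f"factor {name!r}: class {cls!r} not in {_FACTOR_CLASSES}"
                )
        self._classes = dict(classes)

    def __contains__(self, factor: str) -> bool:
        return factor in self._classes

    def class_of(self, factor: str) -> str:
        try:
            return self._classes[factor]
        except KeyError:
            raise ConfigError(f"factor {factor!r} not in registry") from None

    def factors(self, cls: str | None = None) -> list[str]:
        if cls is None:
            return sorted(self._classes)
        return sorted(f for f, c in self._classes.items() if c == cls)

    def is_prc1(self, factor: str) -> bool:
        return self.class_of(factor) in ("CBX", "RING")

    @classmethod
    def from_mapping(cls, mapping: dict[str, str]) -> "FactorRegistry":
        return cls(mapping)

    def to_mapping(self) -> dict[str, str]:
        return dict(self._classes)


#: The study's five PRC1 tracks plus the two reference histone marks.
DEFAULT_REGISTRY = FactorRegistry(
    {
        "CBX6": "CBX",
        "CBX7": "CBX",
        "CBX8": "CBX",
        "RING1": "RING",
        "RING2": "RING",
        "H3K27me3": "HISTONE_MARK",
        "H3K4me3": "HISTONE_MARK",
    }
)


# ---------------------------------------------------------------------------
# Peak file I/O (BED6 / ENCODE narrowPeak)
# ---------------------------------------------------------------------------

def _parse_int(text: str, what: str, lineno: int) -> int:
    try:
        return int(text)
    except ValueError:
        raise ParseError(f"line {lineno}: non-integer {what}: {text!r}") from None


def read_peaks(
    path: str | Path,
    format: str = "narrowPeak",
    factor: str = "",
    sample: str = "",
    replicate: str = "",
) -> list[Peak]:
    """Read a BED6 or ENCODE narrowPeak file into :class:`Peak` records.

    narrowPeak column 7 (signalValue) becomes the score and column 10 the
    summit offset (``-1`` meaning absent). BED6 uses column 5 as the score.
    Coordinates are taken verbatim (both formats are 0-based half-open).
    """
    if format == "narrowPeak":
        min_cols = 10
    elif format == "bed6":
        min_cols = 6
    else:
        raise ConfigError(f"unknown peak format {format!r} (narrowPeak|bed6)")

    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < min_cols:
                raise ParseError(
                    f"line {lineno}: expected >= {min_cols} columns for "
                    f"{format}, got {len(cols)}"
                )
            start = _parse_int(cols[1], "start", lineno)
            end = _parse_int(cols[2], "end", lineno)
            if start >= end:
                raise ParseError(f"line {lineno}: start >= end ({start} >= {end})")
            strand = cols[5] if cols[5] in ("+", "-", ".") else "."
            if format == "narrowPeak":
                score = float(cols[6])
                off = _parse_int(cols[9], "summit offset", lineno)
                summit = None if off < 0 else off
            else:
                score = float(cols[4])
                summit = None
            try:
                peaks.append(
                    Peak(
                        interval=GenomicInterval(cols[0], start, end, strand),
                        score=score,
                        factor=factor,
                        sample=sample,
                        replicate=replicate,
                        summit_offset=summit,
                    )
                )
            except ValueError as exc:
                raise ParseError(f"line {lineno}: {exc}") from None
    return peaks


def write_peaks(peaks: Iterable[Peak], path: str | Path, format: str = "narrowPeak") -> None:
    """Write peaks as narrowPeak (default) or BED6; inverse of :func:`read_peaks`."""
    if format not in ("narrowPeak", "bed6"):
        raise ConfigError(f"unknown peak format {format!r}")
    with open(path, "w") as fh:
        for i, p in enumerate(peaks):
            iv = p.interval
            name = f"{p.factor or 'peak'}_{i + 1}"
            if format == "narrowPeak":
                off = -1 if p.summit_offset is None else p.summit_offset
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t"
                    f"{min(1000, int(round(p.score)))}\t{iv.strand}\t"
                    f"{p.score:g}\t-1\t-1\t{off}\n"
                )
            else:
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{p.score:g}\t{iv.strand}\n"
                )


# ---------------------------------------------------------------------------
# Gene annotation I/O (GTF / BED12)
# ---------------------------------------------------------------------------

def _parse_gtf_attributes(text: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for part in text.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        if " " in part:
            key, _, value = part.partition(" ")
            attrs[key] = value.strip().strip('"')
    return attrs


_NONCODING_BIOTYPES = {
    "lincRNA", "lncRNA", "miRNA", "snoRNA", "snRNA", "rRNA", "tRNA",
    "antisense", "processed_transcript", "pseudogene", "noncoding",
    "misc_RNA", "scaRNA",
}


def _biotype_from_attr(value: str | None) -> str:
    if value is None:
        return "coding"
    if value in ("coding", "protein_coding"):
        return "coding"
    if value in _NONCODING_BIOTYPES:
        return "noncoding"
    # Unrecognized biotypes with "coding" in the name stay coding; everything
    # else is treated as noncoding for the assignment preference rule.
    return "coding" if "coding" in value and "non" not in value else "noncoding"


def read_genes(path: str | Path, format: str = "gtf") -> list[GeneModel]:
    """Read gene models from GTF or BED12.

    GTF: ``gene`` feature lines are used when present; otherwise the outermost
    span per ``gene_id`` over all features is taken (multi-isoform genes
    collapse to their extremal coordinates). 1-based inclusive coordinates are
    converted to 0-based half-open. Biotype comes from ``gene_biotype`` /
    ``gene_type`` and defaults to coding.
    """
    if format == "gtf":
        return _read_genes_gtf(path)
    if format == "bed12":
        return _read_genes_bed12(path)
    raise ConfigError(f"unknown gene format {format!r} (gtf|bed12)")


def _read_genes_gtf(path: str | Path) -> list[GeneModel]:
    gene_lines: list[GeneModel] = []
    # per-gene aggregation across features, used only when no gene lines exist
    agg: dict[str, dict] = {}
    seen_gene_ids: set[str] = set()
    duplicates: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 9:
                raise ParseError(f"line {lineno}: GTF needs 9 columns, got {len(cols)}")
            chrom, _source, feature, start_s, end_s, _score, strand, _frame, attr_s = cols[:9]
            start1 = _parse_int(start_s, "start", lineno)
            end1 = _parse_int(end_s, "end", lineno)
            if strand not in ("+", "-"):
                raise ParseError(f"line {lineno}: gene feature without strand")
            attrs = _parse_gtf_attributes(attr_s)
            gene_id = attrs.get("gene_id")
            if gene_id is None:
                raise ParseError(f"line {lineno}: missing gene_id attribute")
            start0, end0 = start1 - 1, end1  # 1-based inclusive -> half-open
            if start0 >= end0 or start0 < 0:
                raise ParseError(f"line {lineno}: invalid span {start1}-{end1}")
            biotype = _biotype_from_attr(attrs.get("gene_biotype") or attrs.get("gene_type"))
            name = attrs.get("gene_name", gene_id)
            if feature == "gene":
                if gene_id in seen_gene_ids:
                    duplicates.add(gene_id)
                seen_gene_ids.add(gene_id)
                gene_lines.append(
                    GeneModel(gene_id, name, GenomicInterval(chrom, start0, end0, strand), biotype)
                )
            else:
                rec = agg.setdefault(
                    gene_id,
                    {"chrom": chrom, "start": start0, "end": end0, "strand": strand,
                     "biotype": biotype, "name": name},
                )
                if rec["chrom"] == chrom and rec["strand"] == strand:
                    rec["start"] = min(rec["start"], start0)
                    rec["end"] = max(rec["end"], end0)
    if duplicates:
        raise ParseError(f"duplicate gene_id records: {sorted(duplicates)}")
    if gene_lines:
        return gene_lines
    return [
        GeneModel(gid, r["name"],
                  GenomicInterval(r["chrom"], r["start"], r["end"], r["strand"]),
                  r["biotype"])
        for gid, r in agg.items()
    ]


def _read_genes_bed12(path: str | Path) -> list[GeneModel]:
    genes: list[GeneModel] = []
    seen: set[str] = set()
    duplicates: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 12:
                raise ParseError(f"line {lineno}: BED12 needs 12 columns, got {len(cols)}")
            start = _parse_int(cols[1], "start", lineno)
            end = _parse_int(cols[2], "end", lineno)
            if start >= end:
                raise ParseError(f"line {lineno}: start >= end")
            strand = cols[5]
            if strand not in ("+", "-"):
                raise ParseError(f"line {lineno}: gene without strand")
            gene_id = cols[3]
            if gene_id in seen:
                duplicates.add(gene_id)
            seen.add(gene_id)
            genes.append(
                GeneModel(gene_id, gene_id, GenomicInterval(cols[0], start, end, strand))
            )
    if duplicates:
        raise ParseError(f"duplicate gene_id records: {sorted(duplicates)}")
    return genes


def write_genes_gtf(genes: Iterable[GeneModel], path: str | Path) -> None:
    """Write gene models as GTF ``gene`` lines (converting back to 1-based)."""
    with open(path, "w") as fh:
        for g in genes:
            iv = g.interval
            biotype = "protein_coding" if g.biotype == "coding" else "lncRNA"
            attrs = (
                f'gene_id "{g.gene_id}"; gene_name "{g.name}"; '
                f'gene_biotype "{biotype}";'
            )
            fh.write(
                f"{iv.chrom}\tprc1map\tgene\t{iv.start + 1}\t{iv.end}\t.\t"
                f"{iv.strand}\t.\t{attrs}\n"
            )


# ---------------------------------------------------------------------------
# Interval arithmetic
# ---------------------------------------------------------------------------

def merge_intervals(
    intervals: Sequence[GenomicInterval], gap: int = 0
) -> list[GenomicInterval]:
    """Union of intervals, joining spans separated by <= ``gap`` bases.

    Returns maximal disjoint intervals sorted by (chrom, start); strand is
    dropped (merged spans are unstranded).
    """
    if gap < 0:
        raise ConfigError(f"gap must be >= 0, got {gap}")
    if not intervals:
        return []
    ordered = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
    merged: list[GenomicInterval] = []
    cur = ordered[0]
    cur_chrom, cur_start, cur_end = cur.chrom, cur.start, cur.end
    for iv in ordered[1:]:
        if iv.chrom == cur_chrom and iv.start - cur_end <= gap:
            cur_end = max(cur_end, iv.end)
        else:
            merged.append(GenomicInterval(cur_chrom, cur_start, cur_end))
            cur_chrom, cur_start, cur_end = iv.chrom, iv.start, iv.end
    merged.append(GenomicInterval(cur_chrom, cur_start, cur_end))
    return merged


def nearest_feature(
    position: tuple[str, int],
    features: Sequence[tuple[tuple[str, int], object]],
    tie_key: Callable[[object], object] | None = None,
) -> tuple[object, int] | None:
    """Find the feature closest to ``position`` on the same chromosome.

    Returns ``(payload, signed_distance)`` with distance = feature - query,
    or ``None`` when no feature shares the chromosome ("unassigned").
    Ties on |distance| are broken by ``tie_key`` applied to the payload
    (default: coding genes before noncoding, then lexicographic gene_id;
    falls back to ``str(payload)`` for arbitrary payloads).
    """
    chrom, base = position
    if tie_key is None:
        tie_key = _default_tie_key
    best: tuple[int, object, object, int] | None = None  # (|d|, key, payload, d)
    for (f_chrom, f_pos), payload in features:
        if f_chrom != chrom:
            continue
        d = f_pos - base
        cand = (abs(d), tie_key(payload), payload, d)
        if best is None or cand[:2] < best[:2]:
            best = cand
    if best is None:
        return None
    return best[2], best[3]


def _default_tie_key(payload: object):
    if isinstance(payload, GeneModel):
        return (0 if payload.biotype == "coding" else 1, payload.gene_id)
    return (0, str(payload))
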