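"""Transcriptional activity calls from duplicate RNA read counts and their
integration with the target-gene table.

A gene is deemed transcriptionally active when it reaches a read-count
threshold (default ten) in duplicate RNA-seq samples; everything else is
considered silent. Counts are raw per-gene mapped read counts, not
length-normalised values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .peaks import BindingRegion
from .targets import TargetCall

__all__ = [
    "ExpressionRecord",
    "read_counts_table",
    "call_active",
    "active_fraction",
    "background_ratio",
    "flag_h3k4me3_tss",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True, slots=True)
class ExpressionRecord:
    """Per-gene read counts over >=2 replicates of one sample."""

    gene_id: str
    counts: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.counts) < 2:
            raise ValueError(
                f"{self.gene_id}: activity is defined on duplicate samples "
                f"(got {len(self.counts)} replicate counts)"
            )
        if any(c < 0 for c in self.counts):
            raise ValueError(f"{self.gene_id}: negative read count")


def read_counts_table(path: str | Path) -> dict[str, list[ExpressionRecord]]:
    """Read a TSV count matrix into per-sample expression records.

    Expected columns: ``gene_id`` then ``<sample>:<replicate>`` count
    columns (e.g. ``BF:rep1``). Returns ``{sample: [ExpressionRecord...]}``
    with replicate counts ordered by replicate label.
    """
    df = pd.read_csv(path, sep="\t")
    if "gene_id" not in df.columns:
        raise ValueError(f"{path}: count table needs a gene_id column")
    sample_cols: dict[str, list[str]] = {}
    for col in df.columns:
        if col == "gene_id":
            continue
        sample, _, rep = col.partition(":")
        if not rep:
            raise ValueError(f"{path}: count column {col!r} is not '<sample>:<replicate>'")
        sample_cols.setdefault(sample, []).append(col)
    out: dict[str, list[ExpressionRecord]] = {}
    gene_ids = df["gene_id"].tolist()
    for sample, cols in sample_cols.items():
        cols = sorted(cols)
        mat = df[cols].to_numpy()
        out[sample] = [
            ExpressionRecord(gene_id=gid, counts=tuple(int(c) for c in row))
            for gid, row in zip(gene_ids, mat)
        ]
    return out


def call_active(
    record: ExpressionRecord, threshold: int = 10, mode: str = "each"
) -> bool:
    """True when the gene is transcriptionally active.

    ``each`` (default): count >= threshold in every replicate.
    ``sum``: replicate counts summed before thresholding (alternative
    reading of a per-duplicate threshold).
    """
    if mode == "each":
        return all(c >= threshold for c in record.counts)
    if mode == "sum":
        return sum(record.counts) >= threshold
    raise ValueError(f"unknown activity mode {mode!r} (each|sum)")


def active_fraction(
    calls: Sequence[TargetCall],
    expression: Sequence[ExpressionRecord],
    threshold: int = 10,
    mode: str = "each",
) -> tuple[float, float]:
    """(fraction_active, fraction_silent) over target loci.

    A target without an expression record is counted silent (and logged):
    absence of measurable reads is treated as absence of transcription.
    """
    if not calls:
        raise ValueError("active_fraction requires >= 1 target call")
    by_gene = {r.gene_id: r for r in expression}
    n_active = 0
    missing = []
    for call in calls:
        rec = by_gene.get(call.gene_id)
        if rec is None:
            missing.append(call.gene_id)
            continue
        if call_active(rec, threshold=threshold, mode=mode):
            n_active += 1
    if missing:
        logger.warning(
            "%d target genes without expression records counted silent (e.g. %s)",
            len(missing), missing[:5],
        )
    fa = n_active / len(calls)
    return fa, 1.0 - fa


def background_ratio(
    all_genes: Sequence[ExpressionRecord], threshold: int = 10, mode: str = "each"
) -> tuple[float, float]:
    """(fraction_active, fraction_silent) over the whole annotation.

    The genome-wide comparator for the target-cohort activity fraction.
    """
    if not all_genes:
        raise ValueError("background_ratio requires >= 1 expression record")
    n_active = sum(1 for r in all_genes if call_active(r, threshold=threshold, mode=mode))
    fa = n_active / len(all_genes)
    return fa, 1.0 - fa


def flag_h3k4me3_tss(
    calls: Sequence[TargetCall],
    h3k4me3: Sequence[BindingRegion],
    window: int = 2000,
) -> tuple[dict[str, bool], float]:
    """Flag targets with an H3K4me3 region at the TSS.

    A call is flagged when any H3K4me3 region overlaps
    ``[tss - window, tss + window)``. Returns per-gene flags and the flagged
    fraction of the cohort.
    """
    if window <= 0:
        raise ValueError("window must be > 0")
    by_chrom: dict[str, list[BindingRegion]] = {}
    for r in h3k4me3:
        by_chrom.setdefault(r.interval.chrom, []).append(r)
    flags: dict[str, bool] = {}
    for call in calls:
        g = call.gene
        lo, hi = g.tss - window, g.tss + window
        flags[call.gene_id] = any(
            r.interval.start < hi and r.interval.end > lo
            for r in by_chrom.get(g.chrom, [])
        )
    frac = sum(flags.values()) / len(flags) if flags else 0.0
    return flags, frac
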