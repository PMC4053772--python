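"""End-to-end orchestration: manifest + annotation + counts in, report
bundle out.

Stage order follows the analysis narrative: per-factor profiling, target
compilation, strain comparison, expression integration, and (optionally)
the proliferating-vs-senescent concordance check. Every applied default is
echoed into the run log so convention-driven parameters (link gap, end
window, promoter window) are always visible in the output.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from .compare import compare_targets, profile_concordance
from .core import ConfigError, read_genes
from .expression import (
    active_fraction,
    background_ratio,
    call_active,
    flag_h3k4me3_tss,
    read_counts_table,
)
from .peaks import (
    call_cooccupancy,
    filter_foothills,
    load_manifest,
    regions_from_manifest,
    write_cooccupancy_bed,
)
from .targets import (
    ArchitectureConfig,
    assign_targets,
    category_proportions,
    target_table,
    write_assigned_sites_bed,
)

__all__ = ["RunConfig", "RunReport", "run"]

logger = logging.getLogger(__name__)


@dataclass(slots=True)
class RunConfig:
    """Everything a full run needs; unset options keep documented defaults."""

    manifest: str
    genes: str
    counts: str | None = None
    outdir: str = "prc1map_out"
    genes_format: str = "gtf"
    replicate_mode: str = "union"
    replicate_gap: int = 0
    link_gap: int = 1000
    foothill_min_fraction: float = 0.0
    end_window: int = 10_000
    body_overlap_fraction: float = 0.5
    max_assignment_distance: int | None = None
    activity_threshold: int = 10
    activity_mode: str = "each"
    h3k4me3_window: int = 2000
    required_mark: str = "H3K27me3"
    samples: tuple[str, ...] | None = None
    concordance_pair: tuple[str, str] | None = None

    def architecture(self) -> ArchitectureConfig:
        return ArchitectureConfig(
            end_window=self.end_window,
            body_overlap_fraction=self.body_overlap_fraction,
            max_assignment_distance=self.max_assignment_distance,
        )


@dataclass(slots=True)
class RunReport:
    """In-memory results mirroring the files written to outdir."""

    samples: list[str]
    sites: dict = field(default_factory=dict)          # sample -> [CooccupancySite]
    assignments: dict = field(default_factory=dict)    # sample -> AssignmentResult
    proportions: dict = field(default_factory=dict)    # sample -> (props, amb_frac)
    activity: dict = field(default_factory=dict)       # sample -> dict of fractions
    h3k4me3: dict = field(default_factory=dict)        # sample -> (flags, fraction)
    overlap: object | None = None                      # OverlapResult
    concordance: object | None = None                  # ConcordanceResult
    table: pd.DataFrame | None = None


def run(config: RunConfig) -> RunReport:
    """Execute the full pipeline and write the report bundle to outdir."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_lines = [f"parameters: {json.dumps(asdict(config), default=str, sort_keys=True)}"]

    manifest = load_manifest(config.manifest)
    manifest.validate()
    registry = manifest.registry
    genes = read_genes(config.genes, format=config.genes_format)
    if not genes:
        raise ConfigError(f"no genes read from {config.genes}")

    samples = list(config.samples) if config.samples else manifest.samples()
    arch = config.architecture()
    report = RunReport(samples=samples)

    expr_by_sample = read_counts_table(config.counts) if config.counts else {}

    for sample in samples:
        stage = f"cooccupancy[{sample}]"
        try:
            regions = regions_from_manifest(
                manifest, sample, mode=config.replicate_mode, gap=config.replicate_gap
            )
            site_tracks = {
                f: r
                for f, r in regions.items()
                if registry.is_prc1(f) or f == config.required_mark
            }
            sites = call_cooccupancy(
                site_tracks, registry,
                required_mark=config.required_mark, link_gap=config.link_gap,
            )
            if config.foothill_min_fraction > 0:
                filtered = [
                    filter_foothills(s, registry, config.foothill_min_fraction)
                    for s in sites
                ]
                n_rej = sum(1 for s in filtered if s.rejected)
                log_lines.append(f"{stage}: foothill filter rejected {n_rej} sites")
                sites = [s for s in filtered if not s.rejected]
            report.sites[sample] = sites
            write_cooccupancy_bed(sites, outdir / f"cooccupancy_{sample}.bed")
            log_lines.append(f"{stage}: {len(sites)} co-occupancy sites")

            stage = f"targets[{sample}]"
            result = assign_targets(sites, genes, arch)
            report.assignments[sample] = result
            write_assigned_sites_bed(result, outdir / f"assigned_sites_{sample}.bed")
            props, amb = category_proportions(result.calls)
            report.proportions[sample] = (props, amb)
            log_lines.append(
                f"{stage}: {len(result.calls)} target loci, "
                f"{len(result.unassigned)} unassigned sites, "
                f"ambiguous fraction {amb:.3f}"
            )

            if "H3K4me3" in regions:
                flat = [r for r in regions["H3K4me3"]]
                report.h3k4me3[sample] = flag_h3k4me3_tss(
                    result.calls, flat, window=config.h3k4me3_window
                )

            if sample in expr_by_sample:
                stage = f"expression[{sample}]"
                expr = expr_by_sample[sample]
                fa, fs = active_fraction(
                    result.calls, expr,
                    threshold=config.activity_threshold, mode=config.activity_mode,
                )
                bg_a, bg_s = background_ratio(
                    expr, threshold=config.activity_threshold, mode=config.activity_mode
                )
                report.activity[sample] = {
                    "target_active": fa, "target_silent": fs,
                    "background_active": bg_a, "background_silent": bg_s,
                }
        except Exception as exc:
            (outdir / "INCOMPLETE").write_text(f"failed at stage {stage}: {exc}\n")
            raise RuntimeError(f"stage {stage} failed: {exc}") from exc

    # category proportion table (per sample)
    rows = []
    for sample in samples:
        if sample in report.proportions:
            props, amb = report.proportions[sample]
            for cat, frac in sorted(props.items()):
                rows.append({"sample": sample, "category": cat, "fraction": frac})
            rows.append({"sample": sample, "category": "AMBIGUOUS", "fraction": amb})
    pd.DataFrame(rows).to_csv(outdir / "category_proportions.tsv", sep="\t", index=False)

    # combined per-locus table with activity flags
    activity_flags: dict[str, dict[str, bool]] = {}
    for sample in samples:
        if sample in expr_by_sample:
            activity_flags[sample] = {
                r.gene_id: call_active(
                    r, threshold=config.activity_threshold, mode=config.activity_mode
                )
                for r in expr_by_sample[sample]
            }
    calls_by_sample = {
        s: report.assignments[s].calls for s in samples if s in report.assignments
    }
    report.table = target_table(calls_by_sample, activity_flags or None)
    report.table.to_csv(outdir / "target_table.tsv", sep="\t", index=False)

    # activity fractions
    if report.activity:
        pd.DataFrame(
            [{"sample": s, **vals} for s, vals in report.activity.items()]
        ).to_csv(outdir / "activity_fractions.tsv", sep="\t", index=False)

    # two-sample target overlap (first two samples with assignments)
    assigned_samples = [s for s in samples if s in report.assignments]
    if len(assigned_samples) >= 2:
        a, b = assigned_samples[:2]
        report.overlap = compare_targets(
            report.assignments[a].calls, report.assignments[b].calls
        )
        with open(outdir / "target_overlap.json", "w") as fh:
            json.dump(
                {"sample_a": a, "sample_b": b, **report.overlap.to_dict()}, fh, indent=1
            )

    if config.concordance_pair:
        a, b = config.concordance_pair
        if a in report.sites and b in report.sites:
            report.concordance = profile_concordance(report.sites[a], report.sites[b])
            with open(outdir / "concordance.json", "w") as fh:
                json.dump(
                    {"condition_a": a, "condition_b": b, **report.concordance.to_dict()},
                    fh, indent=1,
                )

    (outdir / "run_log.txt").write_text("\n".join(log_lines) + "\n")
    return report
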