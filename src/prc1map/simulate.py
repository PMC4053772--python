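"""Synthetic PRC1 ChIP-seq landscape generator with planted ground truth.

Emulates the structure of the study data this pipeline is built for: five
PRC1 factor tracks (CBX6/7/8, RING1/2) x two replicates x two fibroblast
strains, H3K27me3/H3K4me3 reference tracks, duplicate RNA count tables per
strain, and a "senescent" condition whose peaks keep their locations but
lose read density. Every planted property — which genes are targets in
which strain, their peak architecture category, transcriptional activity,
promoter H3K4me3 — is recorded in a truth object so the whole analysis can
be benchmarked by label recovery.

Planted geometry deliberately avoids classification boundaries (site
centres stay >= 20% clear of the end-window edge), so at default noise the
pipeline should recover the planted labels nearly perfectly; the jitter and
score-noise knobs exist to degrade that on purpose.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import (
    DEFAULT_REGISTRY,
    GeneModel,
    GenomicInterval,
    Peak,
    write_genes_gtf,
    write_peaks,
)

__all__ = ["GeneratorConfig", "SyntheticTruth", "SyntheticDataset", "generate", "truth_table"]

PRC1_FACTORS = ("CBX6", "CBX7", "CBX8", "RING1", "RING2")
CBX_FACTORS = ("CBX6", "CBX7", "CBX8")
RING_FACTORS = ("RING1", "RING2")
REPLICATES = ("rep1", "rep2")


@dataclass(frozen=True, slots=True)
class GeneratorConfig:
    """Study-shaped defaults for the synthetic landscape.

    The category mix (0.66 TSS / 0.155 TES / 0.18 both-ends, remainder to
    ambiguous constructs), strain sharing (685:301:414), 28% active targets
    against a 47% active background, 38% promoter H3K4me3, and the 0.6
    senescence density scale all echo the fibroblast study this pipeline
    reproduces.
    """

    n_genes: int = 2500
    n_targets: int = 1000
    category_mix: tuple[float, float, float] = (0.66, 0.155, 0.18)
    both_ends_submix: tuple[float, float, float] = (0.3, 0.2, 0.5)
    shared_fraction: float = 685 / 1400
    unique_a_fraction: float = 301 / 1400
    unique_b_fraction: float = 414 / 1400
    active_target_fraction: float = 0.28
    background_active_fraction: float = 0.47
    h3k4me3_target_fraction: float = 0.38
    foothill_rate: float = 0.2
    periodic_array_rate: float = 0.3
    decoy_rate: float = 0.1
    noncoding_fraction: float = 0.15
    jitter_sd: float = 50.0
    score_noise: float = 0.2
    senescence_scale: float = 0.6
    activity_threshold: int = 10
    nb_dispersion: float = 0.1
    silent_mean: float = 1.0
    active_mean: float = 100.0
    samples: tuple[str, str] = ("BF", "Hs68")
    senescent_sample: str = "Hs68_senescent"
    n_chromosomes: int = 3

    def validate(self) -> None:
        if self.n_targets > self.n_genes:
            raise ValueError("infeasible config: n_targets > n_genes")
        fracs = [
            *self.category_mix, *self.both_ends_submix,
            self.shared_fraction, self.unique_a_fraction, self.unique_b_fraction,
            self.active_target_fraction, self.background_active_fraction,
            self.h3k4me3_target_fraction, self.foothill_rate,
            self.periodic_array_rate, self.decoy_rate, self.noncoding_fraction,
        ]
        if any(not (0.0 <= f <= 1.0) for f in fracs):
            raise ValueError("all fractions must lie in [0, 1]")
        if sum(self.category_mix) > 1.0 + 1e-9:
            raise ValueError("category_mix must sum to <= 1")
        if abs(
            self.shared_fraction + self.unique_a_fraction + self.unique_b_fraction - 1.0
        ) > 1e-9:
            raise ValueError("sharing fractions must sum to 1")
        if self.senescence_scale <= 0:
            raise ValueError("senescence_scale must be > 0")
        if self.h3k4me3_target_fraction < self.active_target_fraction:
            raise ValueError(
                "h3k4me3_target_fraction must be >= active_target_fraction "
                "(active promoters carry the mark)"
            )


@dataclass(slots=True)
class GeneLabel:
    """Planted truth for one gene."""

    gene_id: str
    name: str
    is_target: dict  # sample -> bool
    category: str | None = None
    subcategory: str | None = None
    n_factors: dict = field(default_factory=dict)  # sample -> int
    is_active: dict = field(default_factory=dict)  # sample -> bool
    h3k4me3_at_tss: dict = field(default_factory=dict)  # sample -> bool
    periodic: bool = False
    has_foothills: bool = False
    ambiguous_partner: str | None = None


@dataclass(slots=True)
class SyntheticTruth:
    seed: int
    config: GeneratorConfig
    labels: dict[str, GeneLabel]

    def targets(self, sample: str) -> set[str]:
        return {g for g, lab in self.labels.items() if lab.is_target.get(sample, False)}

    def to_json(self) -> str:
        doc = {
            "seed": self.seed,
            "config": asdict(self.config),
            "labels": {
                g: {
                    "name": lab.name,
                    "is_target": lab.is_target,
                    "category": lab.category,
                    "subcategory": lab.subcategory,
                    "n_factors": lab.n_factors,
                    "is_active": lab.is_active,
                    "h3k4me3_at_tss": lab.h3k4me3_at_tss,
                    "periodic": lab.periodic,
                    "has_foothills": lab.has_foothills,
                    "ambiguous_partner": lab.ambiguous_partner,
                }
                for g, lab in sorted(self.labels.items())
            },
        }
        return json.dumps(doc, indent=1, sort_keys=True)


@dataclass(slots=True)
class SyntheticDataset:
    """In-memory dataset plus writers for the on-disk fixture layout."""

    truth: SyntheticTruth
    genes: list[GeneModel]
    peaks: dict[tuple[str, str, str], list[Peak]]  # (sample, factor, replicate)
    counts: pd.DataFrame

    def write(self, outdir: str | Path) -> Path:
        """Write genes.gtf, counts.tsv, peaks/, manifest.yaml, truth files."""
        outdir = Path(outdir)
        (outdir / "peaks").mkdir(parents=True, exist_ok=True)
        write_genes_gtf(self.genes, outdir / "genes.gtf")
        self.counts.to_csv(outdir / "counts.tsv", sep="\t", index=False)
        tracks = []
        for (sample, factor, rep) in sorted(self.peaks):
            rel = f"peaks/{sample}_{factor}_{rep}.narrowPeak"
            write_peaks(self.peaks[(sample, factor, rep)], outdir / rel)
            tracks.append(
                {
                    "path": rel,
                    "factor": factor,
                    "class": DEFAULT_REGISTRY.class_of(factor),
                    "sample": sample,
                    "replicate": rep,
                }
            )
        with open(outdir / "manifest.yaml", "w") as fh:
            yaml.safe_dump({"tracks": tracks}, fh, sort_keys=False)
        (outdir / "truth.json").write_text(self.truth.to_json())
        truth_table(self.truth).to_csv(outdir / "truth_table.tsv", sep="\t", index=False)
        return outdir


def _round_counts(n: int, fractions: list[float]) -> list[int]:
    """Largest-remainder apportionment of n among fractions (sums to n
    when fractions sum to 1)."""
    raw = [f * n for f in fractions]
    base = [int(x) for x in raw]
    rem = n - sum(base) if abs(sum(fractions) - 1.0) < 1e-9 else 0
    order = sorted(range(len(raw)), key=lambda i: raw[i] - base[i], reverse=True)
    for i in order[:max(0, rem)]:
        base[i] += 1
    return base


def generate(config: GeneratorConfig | None = None, seed: int = 0) -> SyntheticDataset:
    """Generate the full labelled dataset; deterministic given (config, seed)."""
    config = config or GeneratorConfig()
    config.validate()
    rng = np.random.default_rng(seed)
    sample_a, sample_b = config.samples

    # --- plant per-gene labels -------------------------------------------
    n = config.n_targets
    n_shared, n_ua, n_ub = _round_counts(
        n, [config.shared_fraction, config.unique_a_fraction, config.unique_b_fraction]
    )
    cat_fracs = list(config.category_mix) + [1.0 - sum(config.category_mix)]
    n_tss, n_tes, n_both, n_amb = _round_counts(n, cat_fracs)
    if n_amb % 2 == 1:  # ambiguous constructs come in linked pairs
        n_amb -= 1
        n_tss += 1
    n_flank, n_internal, n_dist = _round_counts(n_both, list(config.both_ends_submix))

    categories = (
        ["TSS_ASSOCIATED"] * n_tss
        + ["TES_ASSOCIATED"] * n_tes
        + [("BOTH_ENDS", "FLANKING_DISCRETE")] * n_flank
        + [("BOTH_ENDS", "INTERNAL")] * n_internal
        + [("BOTH_ENDS", "DISTRIBUTED")] * n_dist
    )
    rng.shuffle(categories)

    # ambiguous pairs are planted as shared-in-both loci, so the remaining
    # shared quota for regular targets shrinks by n_amb to keep the planted
    # Venn counts exact
    if n_shared < n_amb:
        raise ValueError("infeasible config: ambiguous constructs exceed shared quota")
    membership = ["shared"] * (n_shared - n_amb) + ["a"] * n_ua + ["b"] * n_ub
    rng.shuffle(membership)

    # --- gene layout ------------------------------------------------------
    # Each gene owns a territory wide enough that its planted sites are
    # always nearest to its own TSS; ambiguous pairs violate this on purpose.
    genes: list[GeneModel] = []
    labels: dict[str, GeneLabel] = {}
    plans: list[dict] = []  # per-locus peak plans

    n_regular = n - n_amb
    n_background = config.n_genes - n
    per_chrom = int(np.ceil(config.n_genes / config.n_chromosomes))

    # interleave targets and background deterministically
    roles = ["target"] * n_regular + ["amb_pair"] * (n_amb // 2) + ["background"] * n_background
    rng.shuffle(roles)

    target_pad = 55_000
    background_pad = 8_000
    gene_counter = 0
    target_counter = 0
    amb_counter = 0
    cursor = 0
    chrom_idx = 0
    genes_on_chrom = 0

    def _new_gene(length: int, pad: int, biotype: str) -> GeneModel:
        nonlocal cursor, gene_counter
        gene_counter += 1
        start = cursor + pad
        strand = "+" if rng.random() < 0.5 else "-"
        gid = f"G{gene_counter:05d}"
        g = GeneModel(
            gene_id=gid,
            name=f"SYN{gene_counter:05d}",
            interval=GenomicInterval(f"chrS{chrom_idx + 1}", start, start + length, strand),
            biotype=biotype,
        )
        cursor = start + length + pad
        genes.append(g)
        return g

    for role in roles:
        if genes_on_chrom >= per_chrom:
            chrom_idx += 1
            cursor = 0
            genes_on_chrom = 0
        if role == "background":
            length = int(rng.integers(2_000, 40_000))
            biotype = "noncoding" if rng.random() < config.noncoding_fraction else "coding"
            g = _new_gene(length, background_pad, biotype)
            labels[g.gene_id] = GeneLabel(
                g.gene_id, g.name, {sample_a: False, sample_b: False}
            )
            plans.append({"kind": "background", "gene": g})
            genes_on_chrom += 1
        elif role == "target":
            cat = categories[target_counter]
            member = membership[target_counter]
            target_counter += 1
            periodic = False
            if isinstance(cat, tuple):
                category, subcategory = cat
                if subcategory in ("INTERNAL", "DISTRIBUTED"):
                    periodic = rng.random() < config.periodic_array_rate
                length = int(rng.integers(38_000, 46_000))
            else:
                category, subcategory = cat, None
                length = int(rng.integers(30_000, 40_000))
            g = _new_gene(length, target_pad, "coding")
            in_a = member in ("shared", "a")
            in_b = member in ("shared", "b")
            labels[g.gene_id] = GeneLabel(
                g.gene_id, g.name, {sample_a: in_a, sample_b: in_b},
                category=category, subcategory=subcategory, periodic=periodic,
            )
            plans.append({"kind": "target", "gene": g})
            genes_on_chrom += 1
        else:  # amb_pair: two closely linked coding genes, one spanning cluster
            amb_counter += 1
            len1 = int(rng.integers(22_000, 28_000))
            len2 = int(rng.integers(22_000, 28_000))
            g1 = _new_gene(len1, target_pad, "coding")
            # second gene 5 kb downstream, inside the pair territory
            start2 = g1.interval.end + 5_000
            gene_counter += 1
            g2 = GeneModel(
                gene_id=f"G{gene_counter:05d}",
                name=f"SYN{gene_counter:05d}",
                interval=GenomicInterval(
                    g1.chrom, start2, start2 + len2, "+" if rng.random() < 0.5 else "-"
                ),
                biotype="coding",
            )
            genes.append(g2)
            cursor = g2.interval.end + target_pad
            for ga, gb in ((g1, g2), (g2, g1)):
                labels[ga.gene_id] = GeneLabel(
                    ga.gene_id, ga.name, {sample_a: True, sample_b: True},
                    category="AMBIGUOUS", ambiguous_partner=gb.gene_id,
                )
            plans.append({"kind": "amb_pair", "genes": (g1, g2)})
            genes_on_chrom += 2

    # --- activity and promoter-mark labels -------------------------------
    for sample in (sample_a, sample_b):
        t_ids = sorted(g for g, lab in labels.items() if lab.is_target[sample])
        nt_ids = sorted(g for g in labels if g not in set(t_ids))
        n_active_t = round(config.active_target_fraction * len(t_ids))
        active_t = set(rng.choice(t_ids, size=n_active_t, replace=False)) if t_ids else set()
        n_active_total = round(config.background_active_fraction * config.n_genes)
        n_active_nt = min(max(n_active_total - n_active_t, 0), len(nt_ids))
        active_nt = set(rng.choice(nt_ids, size=n_active_nt, replace=False))
        n_k4 = round(config.h3k4me3_target_fraction * len(t_ids))
        silent_t = [g for g in t_ids if g not in active_t]
        extra = max(0, n_k4 - len(active_t))
        k4_t = set(active_t) | (
            set(rng.choice(silent_t, size=min(extra, len(silent_t)), replace=False))
            if extra else set()
        )
        for gid, lab in labels.items():
            lab.is_active[sample] = gid in active_t or gid in active_nt
            lab.h3k4me3_at_tss[sample] = (gid in k4_t) or (gid in active_nt)

    # --- peak planting ----------------------------------------------------
    peaks: dict[tuple[str, str, str], list[Peak]] = {
        (s, f, r): []
        for s in (sample_a, sample_b)
        for f in (*PRC1_FACTORS, "H3K27me3", "H3K4me3")
        for r in REPLICATES
    }

    def _draw_factors() -> tuple[str, ...]:
        if rng.random() < 0.6:
            return PRC1_FACTORS
        n_c = int(rng.integers(1, 4))
        n_r = int(rng.integers(1, 3))
        cbx = rng.choice(CBX_FACTORS, size=n_c, replace=False)
        ring = rng.choice(RING_FACTORS, size=n_r, replace=False)
        return tuple(sorted(cbx) + sorted(ring))

    def _plant_site(sample: str, factors, centers: list[int], scores_mean: float,
                    chrom: str, foothills: bool) -> None:
        """One co-occupancy site: every factor peaks at each centre, plus an
        H3K27me3 block covering the span, per replicate."""
        half = 1_000
        for rep in REPLICATES:
            lo = hi = None
            for c in centers:
                for factor in factors:
                    cj = c + int(round(rng.normal(0, config.jitter_sd)))
                    score = scores_mean * float(rng.lognormal(0, config.score_noise))
                    iv = GenomicInterval(chrom, max(0, cj - half), cj + half)
                    peaks[(sample, factor, rep)].append(
                        Peak(iv, round(score, 3), factor, sample, rep,
                             summit_offset=iv.length // 2)
                    )
                    lo = iv.start if lo is None else min(lo, iv.start)
                    hi = iv.end if hi is None else max(hi, iv.end)
            m_iv = GenomicInterval(chrom, max(0, lo - 500), hi + 500)
            peaks[(sample, "H3K27me3", rep)].append(
                Peak(m_iv, round(scores_mean * 0.8, 3), "H3K27me3", sample, rep,
                     summit_offset=m_iv.length // 2)
            )
        if foothills:
            side = 1 if rng.random() < 0.5 else -1
            c = centers[0] + side * int(rng.integers(1_800, 2_200))
            for factor in list(factors)[: int(rng.integers(1, 3))]:
                iv = GenomicInterval(chrom, max(0, c - 500), c + 500)
                peaks[(sample, factor, "rep1")].append(
                    Peak(iv, round(scores_mean * 0.15, 3), factor, sample, "rep1",
                         summit_offset=iv.length // 2)
                )

    def _site_centers(g: GeneModel, category: str, subcategory: str | None,
                      periodic: bool) -> list[list[int]]:
        """Per-site centre lists; a multi-centre site is a periodic array."""
        iv = g.interval
        up = -1 if iv.strand == "+" else 1  # genomic direction of "upstream"
        off = int(rng.integers(0, 6_000))
        if category == "TSS_ASSOCIATED":
            return [[g.tss + up * off]]
        if category == "TES_ASSOCIATED":
            return [[g.tes - up * off]]
        if subcategory == "FLANKING_DISCRETE":
            d1 = int(rng.integers(3_000, 6_000))
            d2 = int(rng.integers(3_000, 6_000))
            return [[g.tss + up * d1], [g.tes - up * d2]]
        body_mid = iv.midpoint
        if periodic:
            spacing = int(rng.integers(1_700, 2_000))
            n_arr = int(rng.integers(4, 7))
            first = body_mid - spacing * (n_arr - 1) // 2
            array = [first + k * spacing for k in range(n_arr)]
        else:
            array = [body_mid]
        if subcategory == "INTERNAL":
            return [array]
        d1 = int(rng.integers(0, 6_000))
        d2 = int(rng.integers(0, 6_000))
        return [[g.tss + up * d1], array, [g.tes - up * d2]]

    for plan in plans:
        if plan["kind"] == "background":
            g = plan["gene"]
            if rng.random() < config.decoy_rate:
                # sub-criterion decoys: a lone factor, or marks without PRC1
                choice = rng.random()
                c = g.tss + int(rng.integers(-2_000, 2_000))
                iv = GenomicInterval(g.chrom, max(0, c - 1_000), c + 1_000)
                for sample in (sample_a, sample_b):
                    if choice < 0.5:
                        f = str(rng.choice(PRC1_FACTORS))
                        for rep in REPLICATES:
                            peaks[(sample, f, rep)].append(
                                Peak(iv, 20.0, f, sample, rep, summit_offset=1_000)
                            )
                    else:
                        for rep in REPLICATES:
                            peaks[(sample, "H3K27me3", rep)].append(
                                Peak(iv, 15.0, "H3K27me3", sample, rep, summit_offset=1_000)
                            )
        elif plan["kind"] == "target":
            g = plan["gene"]
            lab = labels[g.gene_id]
            centers_per_site = _site_centers(g, lab.category, lab.subcategory, lab.periodic)
            foothill_here = rng.random() < config.foothill_rate
            lab.has_foothills = foothill_here
            for sample in (sample_a, sample_b):
                if not lab.is_target[sample]:
                    continue
                factors = _draw_factors()
                lab.n_factors[sample] = len(factors)
                scores_mean = float(rng.gamma(4.0, 10.0)) + 10.0
                for k, centers in enumerate(centers_per_site):
                    _plant_site(sample, factors, centers, scores_mean, g.chrom,
                                foothills=foothill_here and k == 0)
        else:  # amb_pair
            g1, g2 = plan["genes"]
            span_lo = g1.interval.midpoint
            span_hi = g2.interval.midpoint
            centers = list(range(span_lo, span_hi + 1, 3_000))
            for sample in (sample_a, sample_b):
                factors = _draw_factors()
                for gg in (g1, g2):
                    labels[gg.gene_id].n_factors[sample] = len(factors)
                scores_mean = float(rng.gamma(4.0, 10.0)) + 10.0
                _plant_site(sample, factors, centers, scores_mean, g1.chrom,
                            foothills=False)

    # H3K4me3 at flagged promoters
    for sample in (sample_a, sample_b):
        for g in genes:
            if labels[g.gene_id].h3k4me3_at_tss[sample]:
                iv = GenomicInterval(g.chrom, max(0, g.tss - 800), g.tss + 800)
                for rep in REPLICATES:
                    peaks[(sample, "H3K4me3", rep)].append(
                        Peak(iv, 30.0, "H3K4me3", sample, rep, summit_offset=800)
                    )

    # --- senescent condition: same locations, scaled density --------------
    for factor in (*PRC1_FACTORS, "H3K27me3", "H3K4me3"):
        for rep in REPLICATES:
            scaled = []
            for p in peaks[(sample_b, factor, rep)]:
                noise = float(rng.lognormal(0, 0.05))
                scaled.append(
                    Peak(p.interval, round(p.score * config.senescence_scale * noise, 3),
                         factor, config.senescent_sample, rep,
                         summit_offset=p.summit_offset)
                )
            peaks[(config.senescent_sample, factor, rep)] = scaled

    # sort every track for deterministic, position-ordered files
    for key in peaks:
        peaks[key].sort(key=lambda p: (p.interval.chrom, p.interval.start))

    # --- duplicate count tables ------------------------------------------
    r = 1.0 / config.nb_dispersion
    rows = []
    for g in genes:
        lab = labels[g.gene_id]
        row: dict = {"gene_id": g.gene_id}
        for sample in (sample_a, sample_b):
            mean = config.active_mean if lab.is_active[sample] else config.silent_mean
            p_nb = r / (r + mean)
            c = rng.negative_binomial(r, p_nb, size=2).astype(int)
            t = config.activity_threshold
            if lab.is_active[sample]:
                c = np.maximum(c, t)  # planted active genes must clear the threshold
            elif (c >= t).all():
                c[0] = int(rng.integers(0, t))  # silent genes fail in >=1 replicate
            row[f"{sample}:rep1"], row[f"{sample}:rep2"] = int(c[0]), int(c[1])
        rows.append(row)
    counts = pd.DataFrame(rows)

    truth = SyntheticTruth(seed=seed, config=config, labels=labels)
    return SyntheticDataset(truth=truth, genes=genes, peaks=peaks, counts=counts)


def truth_table(truth: SyntheticTruth) -> pd.DataFrame:
    """Planted targets in the per-locus report schema (factor counts per
    sample + TRUE/FALSE activity), for direct diffing against the pipeline's
    output table."""
    sample_a, sample_b = truth.config.samples
    rows = []
    for gid, lab in sorted(truth.labels.items(), key=lambda kv: kv[1].name):
        if not (lab.is_target[sample_a] or lab.is_target[sample_b]):
            continue
        rows.append(
            {
                "gene_id": gid,
                "name": lab.name,
                f"n_prc1_factors_{sample_a}": lab.n_factors.get(sample_a, 0),
                f"n_prc1_factors_{sample_b}": lab.n_factors.get(sample_b, 0),
                "category": lab.category,
                "subcategory": lab.subcategory or "",
                f"active_{sample_a}": bool(lab.is_active.get(sample_a, False)),
                f"active_{sample_b}": bool(lab.is_active.get(sample_b, False)),
            }
        )
    cols = [
        "gene_id", "name",
        f"n_prc1_factors_{sample_a}", f"n_prc1_factors_{sample_b}",
        "category", "subcategory", f"active_{sample_a}", f"active_{sample_b}",
    ]
    return pd.DataFrame(rows, columns=cols)
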