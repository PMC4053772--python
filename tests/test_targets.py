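"""Site-to-gene assignment, architecture classification and spacing."""

import numpy as np
import pytest

from prc1map.core import GeneModel, GenomicInterval, Peak
from prc1map.peaks import CooccupancySite
from prc1map.targets import (
    ArchitectureConfig,
    TargetCall,
    assign_targets,
    category_proportions,
    classify_architecture,
    spacing_regularity,
)


def _site(chrom, start, end, factors=("CBX7", "RING1", "H3K27me3"), scores=None):
    peaks = tuple(
        Peak(GenomicInterval(chrom, start, end), (scores or {}).get(f, 10.0), f)
        for f in factors
    )
    return CooccupancySite(
        interval=GenomicInterval(chrom, start, end),
        factors_present=frozenset(factors),
        cbx_members=frozenset(f for f in factors if f.startswith("CBX")),
        ring_members=frozenset(f for f in factors if f.startswith("RING")),
        has_h3k27me3=True,
        member_peaks=peaks,
    )


def _gene(gid, chrom, start, end, strand="+", biotype="coding"):
    return GeneModel(gid, gid, GenomicInterval(chrom, start, end, strand), biotype)


class TestAssignTargets:
    def test_distal_downstream_site_assigned_to_lone_gene(self):
        # a simple peak ~150 kb beyond the gene's TES with no other locus
        # within 500 kb still belongs to that gene
        gene = _gene("MEIS1like", "c", 1_000_000, 1_060_000, "+")
        site = _site("c", 1_209_000, 1_211_000)
        result = assign_targets([site], [gene])
        (call,) = result.calls
        assert call.gene_id == "MEIS1like"
        assert call.category == "TES_ASSOCIATED"  # far closer to the 3' end
        assert result.unassigned == []

    def test_coding_preference_beats_nearer_noncoding_tss(self):
        coding = _gene("gCod", "c", 100_000, 160_000, "+")
        noncod = _gene("gNc", "c", 171_000, 174_000, "+", biotype="noncoding")
        # site overlaps both bodies; the noncoding TSS is nearer its midpoint
        site = _site("c", 155_000, 185_000)
        result = assign_targets([site], [coding, noncod])
        assert [c.gene_id for c in result.calls] == ["gCod"]

    def test_no_gene_on_chromosome_goes_to_unassigned_sink(self):
        result = assign_targets([_site("chrZ", 0, 100)], [_gene("g", "c", 0, 1000)])
        assert result.calls == []
        assert len(result.unassigned) == 1

    def test_closely_linked_spanning_cluster_is_ambiguous_for_both(self):
        g1 = _gene("gA", "c", 100_000, 125_000)
        g2 = _gene("gB", "c", 130_000, 155_000)  # bodies 5 kb apart
        site = _site("c", 110_000, 145_000)  # overlaps both bodies
        result = assign_targets([site], [g1, g2])
        cats = {c.gene_id: c.category for c in result.calls}
        assert cats == {"gA": "AMBIGUOUS", "gB": "AMBIGUOUS"}
        shared = {c.gene_id: c.shares_sites_with for c in result.calls}
        assert shared["gA"] == ("gB",) and shared["gB"] == ("gA",)

    def test_sites_conserved_between_calls_and_sink(self):
        rng = np.random.default_rng(6)
        genes = [
            _gene(f"g{i}", "c", 200_000 * i, 200_000 * i + 30_000,
                  "+" if i % 2 else "-")
            for i in range(10)
        ]
        sites = []
        for _ in range(40):
            s = int(rng.integers(0, 2_000_000))
            sites.append(_site("c", s, s + int(rng.integers(500, 5_000))))
        result = assign_targets(sites, genes)
        owned = [id(s) for c in result.calls if c.owns_sites for s in c.sites]
        owned += [id(s) for s in result.unassigned]
        assert sorted(owned) == sorted(id(s) for s in sites)

    def test_matches_exhaustive_nearest_tss_scan(self):
        rng = np.random.default_rng(7)
        genes = []
        for i in range(50):
            start = 150_000 * i + int(rng.integers(0, 50_000))
            length = int(rng.integers(5_000, 60_000))
            genes.append(
                _gene(
                    f"g{i:02d}", "c", start, start + length,
                    "+" if rng.random() < 0.5 else "-",
                    "noncoding" if rng.random() < 0.2 else "coding",
                )
            )
        sites = []
        for _ in range(200):
            s = int(rng.integers(0, 150_000 * 50))
            sites.append(_site("c", s, s + int(rng.integers(500, 8_000))))
        result = assign_targets(sites, genes)

        # independent linear-scan oracle
        def oracle(site):
            ov = [g for g in genes if site.interval.overlaps(g.interval)]
            cand = [g for g in ov if g.biotype == "coding"] or ov
            linked = set()
            for i, a in enumerate(cand):
                for b in cand[i + 1:]:
                    gap = max(a.interval.start, b.interval.start) - min(
                        a.interval.end, b.interval.end
                    )
                    if gap <= 20_000:
                        linked |= {a.gene_id, b.gene_id}
            if len(linked) >= 2:
                return ("AMBIGUOUS", frozenset(linked))
            pool = cand or genes
            mid = site.interval.midpoint
            best = min(
                pool,
                key=lambda g: (abs(g.tss - mid), 0 if g.biotype == "coding" else 1, g.gene_id),
            )
            return ("ASSIGNED", best.gene_id)

        got = {}
        for call in result.calls:
            for s in call.sites:
                if call.category == "AMBIGUOUS":
                    got.setdefault(id(s), ("AMBIGUOUS", set()))
                    got[id(s)][1].add(call.gene_id)
                else:
                    got[id(s)] = ("ASSIGNED", call.gene_id)
        for site in sites:
            kind, val = oracle(site)
            if kind == "AMBIGUOUS":
                assert got[id(site)][0] == "AMBIGUOUS"
                assert frozenset(got[id(site)][1]) == val
            else:
                assert got[id(site)] == (kind, val)


class TestClassifyArchitecture:
    CFG = ArchitectureConfig(end_window=5_000)

    def _call(self, gene, sites):
        return TargetCall(gene=gene, category="TSS_ASSOCIATED", sites=tuple(sites))

    def test_single_upstream_site_is_tss_associated(self):
        gene = _gene("g", "c", 100_000, 140_000, "+")
        call = classify_architecture(
            self._call(gene, [_site("c", 99_000, 100_000)]), gene, self.CFG
        )
        assert call.category == "TSS_ASSOCIATED"
        assert call.subcategory is None
        assert call.distance_to_tss == -500

    def test_discrete_flanking_peaks_both_ends(self):
        gene = _gene("g", "c", 100_000, 140_000, "+")
        sites = [_site("c", 96_000, 98_000), _site("c", 141_500, 143_500)]
        call = classify_architecture(self._call(gene, sites), gene, self.CFG)
        assert (call.category, call.subcategory) == ("BOTH_ENDS", "FLANKING_DISCRETE")

    def test_upstream_internal_downstream_is_distributed(self):
        gene = _gene("g", "c", 100_000, 140_000, "+")
        sites = [
            _site("c", 97_000, 99_000),
            _site("c", 118_000, 122_000),
            _site("c", 141_000, 143_000),
        ]
        call = classify_architecture(self._call(gene, sites), gene, self.CFG)
        assert (call.category, call.subcategory) == ("BOTH_ENDS", "DISTRIBUTED")

    def test_body_only_sites_are_both_ends_internal(self):
        gene = _gene("g", "c", 100_000, 140_000, "+")
        call = classify_architecture(
            self._call(gene, [_site("c", 118_000, 122_000)]), gene, self.CFG
        )
        assert (call.category, call.subcategory) == ("BOTH_ENDS", "INTERNAL")

    def test_tes_cluster_only(self):
        gene = _gene("g", "c", 100_000, 140_000, "+")
        call = classify_architecture(
            self._call(gene, [_site("c", 138_000, 141_000)]), gene, self.CFG
        )
        assert call.category == "TES_ASSOCIATED"

    def test_short_gene_shrinks_window(self):
        gene = _gene("g", "c", 100_000, 104_000, "+")  # shorter than 2x window
        call = classify_architecture(
            self._call(gene, [_site("c", 99_600, 100_400)]), gene, self.CFG
        )
        # shrunk window (2 kb) still separates the two ends
        assert call.category == "TSS_ASSOCIATED"

    def test_mirror_symmetry_under_strand_flip(self):
        # reflecting every coordinate and flipping strand swaps no labels
        L = 1_000_000
        rng = np.random.default_rng(8)
        for _ in range(25):
            start = int(rng.integers(200_000, 400_000))
            length = int(rng.integers(25_000, 60_000))
            gene = _gene("g", "c", start, start + length, "+")
            sites = []
            for _ in range(int(rng.integers(1, 4))):
                s = start + int(rng.integers(-15_000, length + 15_000))
                sites.append(_site("c", s, s + int(rng.integers(500, 6_000))))
            fwd = classify_architecture(self._call(gene, sites), gene, self.CFG)

            gene_m = _gene("g", "c", L - (start + length), L - start, "-")
            sites_m = [
                _site("c", L - s.interval.end, L - s.interval.start) for s in sites
            ]
            rev = classify_architecture(self._call(gene_m, sites_m), gene_m, self.CFG)
            assert (fwd.category, fwd.subcategory) == (rev.category, rev.subcategory)


class TestCategoryProportions:
    def _call(self, cat, sub=None):
        gene = _gene("g", "c", 0, 30_000)
        return TargetCall(
            gene=gene, category=cat, subcategory=sub, sites=(_site("c", 0, 100),)
        )

    def test_all_one_category(self):
        props, amb = category_proportions([self._call("TSS_ASSOCIATED")] * 10)
        assert props == {"TSS_ASSOCIATED": 1.0}
        assert amb == 0.0

    def test_mixed_with_fractions(self):
        calls = (
            [self._call("TSS_ASSOCIATED")] * 2
            + [self._call("TES_ASSOCIATED")]
            + [self._call("BOTH_ENDS", "DISTRIBUTED")]
        )
        props, _ = category_proportions(calls)
        assert props == {
            "TSS_ASSOCIATED": 0.5,
            "TES_ASSOCIATED": 0.25,
            "BOTH_ENDS": 0.25,
        }
        assert abs(sum(props.values()) - 1.0) < 1e-9

    def test_ambiguous_reported_separately(self):
        calls = [self._call("TSS_ASSOCIATED")] * 3 + [self._call("AMBIGUOUS")]
        props, amb = category_proportions(calls)
        assert props == {"TSS_ASSOCIATED": 1.0}
        assert amb == 0.25

    def test_empty_input(self):
        assert category_proportions([]) == ({}, 0.0)


class TestSpacingRegularity:
    def _peaks(self, summits):
        return [
            Peak(GenomicInterval("c", s, s + 100), 1.0, "CBX7", summit_offset=0)
            for s in summits
        ]

    def test_perfectly_even_array(self):
        mean_gap, reg = spacing_regularity(self._peaks([0, 1000, 2000, 3000]))
        assert (mean_gap, reg) == (1000.0, 1.0)

    def test_uneven_array_hand_computed(self):
        # gaps {800, 1200, 1200}: mean 1066.67, population SD 188.56,
        # CV 0.176777, regularity 1 - CV = 0.823223
        mean_gap, reg = spacing_regularity(self._peaks([0, 800, 2000, 3200]))
        assert mean_gap == pytest.approx(3200 / 3)
        assert reg == pytest.approx(0.8232233, abs=1e-6)

    def test_below_min_peaks_is_absent(self):
        assert spacing_regularity(self._peaks([0, 1000, 2000]), min_peaks=4) is None
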