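"""Replicate merging, co-occupancy compilation and foothill filtering."""

import numpy as np
import pytest

from prc1map.core import ConfigError, DEFAULT_REGISTRY, GenomicInterval, Peak
from prc1map.peaks import (
    CooccupancySite,
    call_cooccupancy,
    filter_foothills,
    load_manifest,
    merge_replicates,
)


def _peak(start, end, factor="CBX7", rep="rep1", score=10.0, sample="BF"):
    return Peak(GenomicInterval("c", start, end), score, factor, sample, rep)


class TestMergeReplicates:
    def test_union_overlapping_replicates(self):
        regions = merge_replicates(
            [_peak(100, 200, rep="rep1"), _peak(150, 300, rep="rep2")], mode="union"
        )
        (r,) = regions
        assert (r.interval.start, r.interval.end) == (100, 300)
        assert r.support == 2

    def test_intersection_of_disjoint_replicates_is_empty(self):
        regions = merge_replicates(
            [_peak(100, 200, rep="rep1"), _peak(400, 500, rep="rep2")],
            mode="intersection",
        )
        assert regions == []

    def test_mixed_factor_or_sample_rejected(self):
        with pytest.raises(ValueError, match="one factor"):
            merge_replicates([_peak(0, 10, factor="CBX7"), _peak(0, 10, factor="CBX8")])
        with pytest.raises(ConfigError):
            merge_replicates([_peak(0, 10)], mode="median")

    def test_union_and_intersection_against_per_base_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(30):
            chrom_len = 50_000
            cover = {r: np.zeros(chrom_len, dtype=bool) for r in ("rep1", "rep2")}
            peaks = []
            for rep in ("rep1", "rep2"):
                for _ in range(50):
                    s = int(rng.integers(0, chrom_len - 1_000))
                    e = s + int(rng.integers(50, 1_000))
                    peaks.append(_peak(s, e, rep=rep))
                    cover[rep][s:e] = True
            union = merge_replicates(peaks, mode="union")
            got = np.zeros(chrom_len, dtype=bool)
            for r in union:
                got[r.interval.start:r.interval.end] = True
            assert (got == (cover["rep1"] | cover["rep2"])).all()

            # intersection regions: every base with >=2 replicate coverage is
            # inside a region, and every region holds at least one such base
            inter = merge_replicates(peaks, mode="intersection")
            both = cover["rep1"] & cover["rep2"]
            got = np.zeros(chrom_len, dtype=bool)
            for r in inter:
                got[r.interval.start:r.interval.end] = True
                assert both[r.interval.start:r.interval.end].any()
            assert (both & ~got).sum() == 0

    def test_support_counts_distinct_replicates(self):
        regions = merge_replicates(
            [_peak(0, 100, rep="rep1"), _peak(50, 120, rep="rep1"), _peak(60, 90, rep="rep2")]
        )
        assert regions[0].support == 2


def _region_map(tracks):
    """tracks: {factor: [(start, end), ...]} -> regions_by_factor."""
    out = {}
    for factor, spans in tracks.items():
        peaks = [_peak(s, e, factor=factor) for s, e in spans]
        out[factor] = merge_replicates(peaks)
    return out


class TestCallCooccupancy:
    def test_criterion_met(self):
        regions = _region_map(
            {"CBX7": [(100, 200)], "RING1": [(150, 250)], "H3K27me3": [(120, 260)]}
        )
        (site,) = call_cooccupancy(regions, DEFAULT_REGISTRY)
        assert (site.interval.start, site.interval.end) == (100, 260)
        assert site.factors_present == {"CBX7", "RING1", "H3K27me3"}

    def test_missing_mark_gives_no_sites(self):
        regions = _region_map(
            {"CBX7": [(100, 200)], "RING1": [(150, 250)], "H3K27me3": [(5000, 5100)]}
        )
        # the mark exists elsewhere but not at the CBX/RING span
        assert call_cooccupancy(regions, DEFAULT_REGISTRY) == []

    def test_required_mark_absent_from_mapping_is_config_error(self):
        regions = _region_map({"CBX7": [(0, 100)], "RING1": [(0, 100)]})
        with pytest.raises(ConfigError):
            call_cooccupancy(regions, DEFAULT_REGISTRY)

    def test_unregistered_factor_is_error(self):
        regions = _region_map({"MYSTERY": [(0, 100)], "H3K27me3": [(0, 100)]})
        with pytest.raises(ConfigError):
            call_cooccupancy(regions, DEFAULT_REGISTRY)

    def test_empty_mapping_is_empty(self):
        assert call_cooccupancy({}, DEFAULT_REGISTRY) == []

    def test_link_gap_joins_nearby_regions(self):
        regions = _region_map(
            {"CBX7": [(0, 100)], "RING1": [(500, 600)], "H3K27me3": [(0, 600)]}
        )
        assert len(call_cooccupancy(regions, DEFAULT_REGISTRY, link_gap=1000)) == 1

    def test_permutation_invariance(self):
        tracks = {
            "CBX6": [(0, 120), (4000, 4100)],
            "RING2": [(80, 300)],
            "H3K27me3": [(0, 350), (3900, 4200)],
            "RING1": [(3950, 4150)],
            "CBX8": [(3900, 4000)],
        }
        regions = _region_map(tracks)
        base = call_cooccupancy(regions, DEFAULT_REGISTRY)
        for order in (reversed(list(tracks)), sorted(tracks)):
            shuffled = {f: regions[f] for f in order}
            assert call_cooccupancy(shuffled, DEFAULT_REGISTRY) == base

    def test_matches_per_base_brute_force(self):
        rng = np.random.default_rng(4)
        factors = ["CBX6", "CBX7", "CBX8", "RING1", "RING2", "H3K27me3"]
        for _ in range(40):
            chrom_len = 100_000
            cover = {f: np.zeros(chrom_len, dtype=bool) for f in factors}
            regions = {}
            for f in factors:
                peaks = []
                for _ in range(int(rng.integers(1, 8))):
                    s = int(rng.integers(0, chrom_len - 3_000))
                    e = s + int(rng.integers(200, 3_000))
                    peaks.append(_peak(s, e, factor=f))
                    cover[f][s:e] = True
                regions[f] = merge_replicates(peaks)
            got = call_cooccupancy(regions, DEFAULT_REGISTRY, link_gap=0)

            # brute force: connected components of any-factor coverage,
            # kept when >=1 CBX, >=1 RING and the mark are present
            any_cov = np.zeros(chrom_len, dtype=bool)
            for f in factors:
                any_cov |= cover[f]
            expected = []
            edges = np.flatnonzero(np.diff(np.r_[0, any_cov.view(np.int8), 0]))
            for s, e in zip(edges[::2], edges[1::2]):
                present = {f for f in factors if cover[f][s:e].any()}
                cbx = present & {"CBX6", "CBX7", "CBX8"}
                ring = present & {"RING1", "RING2"}
                if cbx and ring and "H3K27me3" in present:
                    expected.append((int(s), int(e), frozenset(present)))
            assert [
                (st.interval.start, st.interval.end, st.factors_present) for st in got
            ] == expected

    def test_monotonicity_adding_a_peak_never_removes_sites(self):
        rng = np.random.default_rng(5)
        tracks = {
            "CBX7": [(0, 1000), (30_000, 31_000)],
            "RING1": [(500, 1500), (30_200, 30_800)],
            "H3K27me3": [(0, 1600), (29_900, 31_100)],
        }
        regions = _region_map(tracks)
        before = {
            (s.interval.chrom, s.interval.start, s.interval.end)
            for s in call_cooccupancy(regions, DEFAULT_REGISTRY)
        }
        for _ in range(20):
            f = str(rng.choice(["CBX6", "CBX7", "RING2", "H3K27me3"]))
            s = int(rng.integers(0, 40_000))
            extra = dict(tracks)
            extra[f] = extra.get(f, []) + [(s, s + int(rng.integers(100, 2_000)))]
            after_sites = call_cooccupancy(_region_map(extra), DEFAULT_REGISTRY)
            covered = set()
            for site in after_sites:
                covered.add((site.interval.chrom, site.interval.start, site.interval.end))
            # every old site survives, possibly widened by the new peak
            for chrom, st, en in before:
                assert any(
                    c == chrom and s2 <= st and e2 >= en for c, s2, e2 in covered
                )

    def test_every_site_satisfies_criterion_by_construction(self):
        with pytest.raises(ValueError):
            CooccupancySite(
                interval=GenomicInterval("c", 0, 10),
                factors_present=frozenset({"CBX7"}),
                cbx_members=frozenset({"CBX7"}),
                ring_members=frozenset(),
                has_h3k27me3=True,
            )


class TestFilterFoothills:
    def _site(self, scores):
        peaks = tuple(
            _peak(i * 100, i * 100 + 50, factor=f, score=s)
            for i, (f, s) in enumerate(scores)
        )
        return CooccupancySite(
            interval=GenomicInterval("c", 0, 1000),
            factors_present=frozenset(f for f, _ in scores),
            cbx_members=frozenset(f for f, _ in scores if f.startswith("CBX")),
            ring_members=frozenset(f for f, _ in scores if f.startswith("RING")),
            has_h3k27me3=True,
            member_peaks=peaks,
        )

    def test_zero_fraction_is_identity(self):
        site = self._site([("CBX7", 10.0), ("RING1", 9.0), ("H3K27me3", 2.0)])
        assert filter_foothills(site, DEFAULT_REGISTRY, 0.0) is site

    def test_half_fraction_removes_weak_peak(self):
        site = self._site([("CBX7", 10.0), ("RING1", 9.0), ("CBX6", 2.0), ("H3K27me3", 8.0)])
        out = filter_foothills(site, DEFAULT_REGISTRY, 0.5)
        assert {p.factor for p in out.member_peaks} == {"CBX7", "RING1", "H3K27me3"}
        assert not out.rejected

    def test_fraction_one_keeps_only_maximal_peaks(self):
        site = self._site([("CBX7", 10.0), ("RING1", 9.0), ("H3K27me3", 2.0)])
        out = filter_foothills(site, DEFAULT_REGISTRY, 1.0)
        assert {p.factor for p in out.member_peaks} == {"CBX7"}
        assert out.rejected  # criterion no longer satisfied -> flagged, kept

    def test_fraction_out_of_range(self):
        site = self._site([("CBX7", 10.0), ("RING1", 9.0), ("H3K27me3", 2.0)])
        with pytest.raises(ConfigError):
            filter_foothills(site, DEFAULT_REGISTRY, 1.5)


class TestManifest:
    def test_missing_file_fails_validation(self, tmp_path):
        m = tmp_path / "manifest.yaml"
        m.write_text(
            "tracks:\n"
            "- {path: nope.narrowPeak, factor: CBX7, class: CBX, sample: BF, replicate: rep1}\n"
        )
        manifest = load_manifest(m)
        with pytest.raises(ConfigError, match="missing"):
            manifest.validate()

    def test_registry_built_from_entries(self, tmp_path):
        f = tmp_path / "a.narrowPeak"
        f.write_text("")
        m = tmp_path / "manifest.yaml"
        m.write_text(
            "tracks:\n"
            "- {path: a.narrowPeak, factor: HPH1, class: OTHER, sample: BF, replicate: rep1}\n"
        )
        manifest = load_manifest(m)
        manifest.validate()
        assert manifest.registry.class_of("HPH1") == "OTHER"
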