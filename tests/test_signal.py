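import dataclasses

import numpy as np
import pandas as pd
import pytest

from chromstate.core import GeneRecord, GenomicInterval, PeakSet, fragments_from_arrays
from chromstate.signal import (
    CoverageTrack,
    bin_coverage,
    call_peaks_simple,
    cpm_normalize,
    metaprofile,
    nucleosome_occupancy,
    reproducible_peaks,
    rpkm,
    window_count,
    window_counts,
)
from chromstate.simulate import SimulationConfig, simulate_annotation, \
    simulate_atac_fragments


def make_frags(chroms, starts, ends, chrom_sizes=None, assay="atac"):
    return fragments_from_arrays(
        chroms, np.asarray(starts), np.asarray(ends),
        sample_id="t", genotype="control", assay=assay, chrom_sizes=chrom_sizes,
    )


def random_frags(rng, n, chrom_len=100_000, chroms=("chr1", "chr2")):
    names = rng.choice(chroms, n)
    starts = rng.integers(0, chrom_len - 600, n)
    ends = starts + rng.integers(1, 600, n)
    return make_frags(names, starts, ends,
                      chrom_sizes={c: chrom_len for c in chroms})


class TestBinCoverage:
    def test_single_fragment_single_bin(self):
        frags = make_frags(["chr1"], [0], [10], {"chr1": 100})
        track = bin_coverage(frags, 10)["chr1"]
        assert track.values[0] == 1 and track.values[1:].sum() == 0

    def test_spanning_fragment_counts_in_both_bins(self):
        frags = make_frags(["chr1"], [5], [15], {"chr1": 100})
        track = bin_coverage(frags, 10)["chr1"]
        assert list(track.values[:3]) == [1, 1, 0]

    def test_fragment_beyond_chromosome_end(self):
        frags = make_frags(["chr1"], [90], [120], {"chr1": 100})
        with pytest.raises(ValueError, match="beyond"):
            bin_coverage(frags, 10)

    def test_matches_bruteforce_loop(self, rng):
        """Seeded 10^4-fragment set equals a naive per-fragment loop."""
        frags = random_frags(rng, 10_000)
        bin_size = 25
        tracks = bin_coverage(frags, bin_size)
        expected = {
            c: np.zeros(int(np.ceil(100_000 / bin_size)))
            for c in ("chr1", "chr2")
        }
        for row in frags.fragments.itertuples():
            for b in range(row.start // bin_size, (row.end - 1) // bin_size + 1):
                expected[row.chrom][b] += 1
        for c in expected:
            np.testing.assert_array_equal(tracks[c].values, expected[c])

    def test_conservation_midpoint_partition(self, rng):
        """Window counts over a midpoint-tiling partition sum to n fragments."""
        n = 2000
        starts = rng.integers(0, 99_000, n)
        frags = make_frags(["chr1"] * n, starts, starts + 50,
                           {"chr1": 100_000})
        mids = starts + 25
        tiles = [GenomicInterval("chr1", s, s + 10_000)
                 for s in range(0, 100_000, 10_000)]
        total = sum(
            int(((mids >= t.start) & (mids < t.end)).sum()) for t in tiles
        )
        assert total == n


class TestWindowCount:
    def test_empty(self):
        frags = make_frags([], [], [])
        assert window_count(frags, GenomicInterval("chr1", 0, 100)) == 0

    def test_abutting_fragment_not_counted(self):
        frags = make_frags(["chr1"], [100], [200])
        assert window_count(frags, GenomicInterval("chr1", 0, 100)) == 0
        assert window_count(frags, GenomicInterval("chr1", 0, 101)) == 1

    def test_matches_linear_scan(self, rng):
        frags = random_frags(rng, 3000)
        table = frags.fragments
        for _ in range(100):
            chrom = rng.choice(["chr1", "chr2"])
            s = int(rng.integers(0, 95_000))
            w = GenomicInterval(str(chrom), s, s + int(rng.integers(1, 5000)))
            naive = int(
                ((table["chrom"] == w.chrom)
                 & (table["start"] < w.end)
                 & (table["end"] > w.start)).sum()
            )
            assert window_count(frags, w) == naive


class TestNormalization:
    def test_cpm(self):
        assert cpm_normalize(0, 1000) == 0
        assert cpm_normalize(1000, 1000) == 1e6
        np.testing.assert_allclose(
            cpm_normalize([3, 7], 2_000_000), [1.5, 3.5]
        )

    def test_rpkm(self):
        assert rpkm(0, 1000, 10**6) == 0
        assert rpkm(1000, 1000, 10**6) == 1000
        counts = np.array([5, 50, 500])
        lengths = np.array([200, 2000, 777])
        lib = 3_456_789
        np.testing.assert_allclose(
            rpkm(counts, lengths, lib), counts * 1e9 / (lengths * lib)
        )

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            cpm_normalize(1, 0)
        with pytest.raises(ValueError):
            rpkm(1, 0, 100)


class TestMetaProfile:
    def test_uniform_coverage_background_one(self):
        """Uniform fragment cover -> every normalized bin ~ 1."""
        starts = np.arange(0, 20_000, 10)
        frags = make_frags(["chr1"] * len(starts), starts, starts + 50)
        anchors = [GeneRecord("g", "chr1", 10_000, "+", 100)]
        prof = metaprofile(frags, anchors, flank=2000, bin_size=10)
        assert prof.edge_mean == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(prof.values, 1.0, rtol=0.05)

    def test_edge_normalization_exact(self, rng):
        frags = random_frags(rng, 5000)
        anchors = [GeneRecord(f"g{i}", "chr1", int(p), "+", 100)
                   for i, p in enumerate(rng.integers(5000, 95_000, 20))]
        prof = metaprofile(frags, anchors, flank=1000, bin_size=10)
        assert abs(prof.edge_mean - 1.0) < 1e-12

    def test_center_enrichment_hand_computed(self):
        """20 fragments at the anchor: center bins >> 1, edges define scale."""
        center_starts = [9_990] * 20
        edge_starts = list(range(7_000, 13_000, 100))  # sparse background
        starts = np.array(center_starts + edge_starts)
        frags = make_frags(["chr1"] * len(starts), starts, starts + 20)
        prof = metaprofile(
            frags, [GeneRecord("g", "chr1", 10_000, "+", 100)],
            flank=2000, bin_size=10,
        )
        assert prof.values[len(prof.values) // 2 - 1] > 5
        assert prof.edge_mean == pytest.approx(1.0, abs=1e-12)

    def test_strand_mirror_symmetry(self):
        """Mirror-image placements produce identical oriented profiles."""
        plus_starts = np.array([10_500, 10_700, 10_900])
        minus_starts = 40_000 - plus_starts - 100
        frags = make_frags(
            ["chr1"] * 6,
            np.r_[plus_starts, minus_starts],
            np.r_[plus_starts, minus_starts] + 100,
        )
        bg = np.arange(5_000, 45_000, 40)
        allf = make_frags(
            ["chr1"] * (6 + len(bg)),
            np.r_[plus_starts, minus_starts, bg],
            np.r_[plus_starts + 100, minus_starts + 100, bg + 40],
        )
        p_plus = metaprofile(
            allf, [GeneRecord("gp", "chr1", 10_000, "+", 1)], 2000, 10
        )
        p_minus = metaprofile(
            allf, [GeneRecord("gm", "chr1", 30_000, "-", 1)], 2000, 10
        )
        np.testing.assert_allclose(p_plus.values, p_minus.values, atol=0.35)

    def test_errors(self):
        frags = make_frags(["chr1"], [0], [10])
        with pytest.raises(ValueError, match="anchor"):
            metaprofile(frags, [], 1000, 10)
        with pytest.raises(ValueError, match="edge"):
            metaprofile(frags, [GeneRecord("g", "chr1", 100, "+", 1)], 50, 10)
        empty = make_frags([], [], [])
        with pytest.raises(ValueError, match="zero signal"):
            metaprofile(empty, [GeneRecord("g", "chr1", 5000, "+", 1)], 1000, 10)


class TestCallPeaksSimple:
    def _tracks(self, t_vals, c_vals):
        return (
            CoverageTrack("chr1", 100, np.array(t_vals, float)),
            CoverageTrack("chr1", 100, np.array(c_vals, float)),
        )

    def test_identical_tracks_no_peaks(self):
        t, c = self._tracks([5] * 50, [5] * 50)
        assert len(call_peaks_simple(t, c, 4.0, 100)) == 0

    def test_single_enriched_region(self):
        vals = np.ones(100)
        vals[40:45] = 10.0  # 500 bp at 10x background
        t, c = self._tracks(vals, np.ones(100))
        peaks = call_peaks_simple(t, c, 4.0, 100,
                                  treatment_library=1000, control_library=1000)
        assert len(peaks) == 1
        peak = peaks.intervals[0]
        assert peak.start <= 4000 and peak.end >= 4500

    def test_threshold_monotonicity(self, rng):
        vals = rng.poisson(3, 200).astype(float)
        vals[50:60] += 20
        vals[120:140] += 8
        t, c = self._tracks(vals, np.ones(200) * 3)
        prev = None
        for thr in (2.0, 4.0, 8.0, 16.0):
            peaks = call_peaks_simple(t, c, thr, 100,
                                      treatment_library=1, control_library=1)
            if prev is not None:
                assert len(peaks) <= prev
            prev = len(peaks)

    def test_min_width_never_shrinks_output(self):
        vals = np.ones(100)
        vals[10:12] = 20
        vals[50:60] = 20
        t, c = self._tracks(vals, np.ones(100))
        wide = call_peaks_simple(t, c, 4.0, 500,
                                 treatment_library=1, control_library=1)
        narrow = call_peaks_simple(t, c, 4.0, 100,
                                   treatment_library=1, control_library=1)
        assert len(narrow) >= len(wide)


def random_peakset(rng, n, name, chrom_len=200_000):
    starts = np.sort(rng.integers(0, chrom_len, n))
    return PeakSet(
        name=name,
        intervals=[
            GenomicInterval("chr1", int(s), int(s) + int(w))
            for s, w in zip(starts, rng.integers(50, 800, n))
        ],
    )


class TestReproduciblePeaks:
    def test_two_of_three_kept(self):
        r1 = PeakSet("r1", [GenomicInterval("chr1", 100, 200)])
        r2 = PeakSet("r2", [GenomicInterval("chr1", 150, 260)])
        r3 = PeakSet("r3", [GenomicInterval("chr1", 5000, 5100)])
        kept = reproducible_peaks([r1, r2, r3], min_support=2)
        assert [(iv.start, iv.end) for iv in kept] == [(100, 260)]

    def test_single_replicate_peak_dropped(self):
        r1 = PeakSet("r1", [GenomicInterval("chr1", 100, 200)])
        r2 = PeakSet("r2", [])
        r3 = PeakSet("r3", [GenomicInterval("chr1", 5000, 5100)])
        assert len(reproducible_peaks([r1, r2, r3], min_support=2)) == 0

    def test_min_support_exceeds_replicates(self):
        with pytest.raises(ValueError, match="min_support"):
            reproducible_peaks([PeakSet("r1", [])], min_support=2)

    @pytest.mark.parametrize("case", range(25))
    def test_matches_bruteforce_support_counting(self, case):
        """Merged-locus support equals O(n^2) enumeration on random sets."""
        rng = np.random.default_rng(900 + case)
        reps = [random_peakset(rng, int(rng.integers(5, 60)), f"r{i}")
                for i in range(3)]
        got = reproducible_peaks(reps, min_support=2)

        # oracle: merge all intervals naively, then count supporting reps
        ivs = sorted(
            [iv for ps in reps for iv in ps.intervals],
            key=lambda x: (x.start, x.end),
        )
        merged = []
        for iv in ivs:
            if merged and iv.start <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], iv.end)
            else:
                merged.append([iv.start, iv.end])
        expected = []
        for s, e in merged:
            support = sum(
                any(p.start < e and s < p.end for p in ps.intervals)
                for ps in reps
            )
            if support >= 2:
                expected.append((s, e))
        assert [(iv.start, iv.end) for iv in got] == expected


class TestNucleosomeOccupancy:
    def test_all_subnucleosomal_gives_zero(self):
        starts = np.arange(1000, 2000, 50)
        frags = make_frags(["chr1"] * len(starts), starts, starts + 60)
        prof = nucleosome_occupancy(
            frags, GenomicInterval("chr1", 1000, 2000), 100
        )
        covered = ~np.isnan(prof.occupancy)
        assert covered.any()
        assert (prof.occupancy[covered] == 0).all()

    def test_all_mononucleosomal_gives_one(self):
        starts = np.arange(1000, 2000, 50)
        frags = make_frags(["chr1"] * len(starts), starts, starts + 200)
        prof = nucleosome_occupancy(
            frags, GenomicInterval("chr1", 1000, 2000), 100
        )
        covered = ~np.isnan(prof.occupancy)
        assert (prof.occupancy[covered] == 1).all()

    def test_empty_bins_missing_not_zero(self):
        frags = make_frags(["chr1"], [1000], [1200])
        prof = nucleosome_occupancy(
            frags, GenomicInterval("chr1", 0, 2000), 100
        )
        assert np.isnan(prof.occupancy[0])

    def test_dyads_recovered_from_simulation(self):
        """Occupancy maxima co-locate with >= 90% of truth dyads."""
        cfg = SimulationConfig(
            n_genes=40, n_pre_like=4, n_chroms=1, chrom_length=2_000_000,
            depth=400_000, seed=11,
        )
        _, truth = simulate_annotation(cfg)
        atac = simulate_atac_fragments(truth, "control")
        accessible = truth.table.index[truth.table["atac_control"] >= 1.0]
        hits = total = 0
        for gid in accessible:
            row = truth.table.loc[gid]
            region = GenomicInterval(
                row["chrom"], int(row["tss"]) - 600, int(row["tss"]) + 600
            )
            prof = nucleosome_occupancy(atac, region, 50)
            gene_dyads = truth.dyads.loc[
                (truth.dyads["gene_id"] == gid)
                & (truth.dyads["pos"] - row["tss"]).abs().le(500), "pos"
            ]
            for pos in gene_dyads:
                b = (int(pos) - region.start) // 50
                window = prof.occupancy[max(0, b - 1): b + 2]
                window = window[~np.isnan(window)]
                total += 1
                if len(window) and window.max() > 0.7:
                    hits += 1
        assert total >= 80
        assert hits / total >= 0.9
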