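"""Copy-number pipeline: binning, normalization, segmentation, purity."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from cnsmeth import cnv, synthetic
from cnsmeth.genome import toy_genome


def profile_from_values(values, stage="corrected", chrom_sizes=None, bin_size=1_000_000):
    """Build a BinProfile directly from a per-bin value array."""
    values = np.asarray(values, dtype=float)
    genome = toy_genome(1, len(values) * bin_size) if chrom_sizes is None else chrom_sizes
    bins = genome.bins(bin_size)
    return cnv.BinProfile(bins=bins.iloc[: len(values)].copy(), values=values, stage=stage)


class TestBinning:
    def test_reads_land_in_their_midpoint_bin(self):
        g = toy_genome(1, 5_000_000)
        reads = pd.DataFrame(
            {"chrom": ["chr1"] * 10, "start": [1_200_000] * 10,
             "end": [1_200_500] * 10, "count": [1] * 10}
        )
        profile = cnv.bin_counts(reads, g)
        assert profile.values.tolist() == [0, 10, 0, 0, 0]

    def test_total_count_conserved(self):
        g = toy_genome(2, 10_000_000)
        rng = np.random.default_rng(0)
        starts = rng.integers(0, 9_999_000, size=500)
        reads = pd.DataFrame(
            {"chrom": rng.choice(["chr1", "chr2"], size=500), "start": starts,
             "end": starts + 500, "count": rng.integers(1, 5, size=500)}
        )
        profile = cnv.bin_counts(reads, g)
        assert profile.values.sum() == reads["count"].sum()

    def test_matches_naive_per_read_assignment(self):
        g = toy_genome(2, 20_000_000)
        bin_size = 1_000_000
        rng = np.random.default_rng(42)
        chroms = rng.choice(["chr1", "chr2"], size=1000)
        starts = rng.integers(0, 19_990_000, size=1000)
        reads = pd.DataFrame(
            {"chrom": chroms, "start": starts, "end": starts + 400,
             "count": np.ones(1000, dtype=int)}
        )
        profile = cnv.bin_counts(reads, g, bin_size=bin_size)
        naive: dict[tuple[str, int], int] = {}
        for chrom, start, end in zip(chroms, starts, starts + 400):
            b = ((start + end) // 2) // bin_size
            naive[(chrom, b)] = naive.get((chrom, b), 0) + 1
        for i, row in profile.bins.iterrows():
            assert profile.values[i] == naive.get((row["chrom"], row["start"] // bin_size), 0)

    def test_unknown_chromosome_rejected(self):
        reads = pd.DataFrame(
            {"chrom": ["chrZ"], "start": [0], "end": [100], "count": [1]}
        )
        with pytest.raises(ValueError, match="unknown chromosome"):
            cnv.bin_counts(reads, toy_genome())

    def test_count_floor_masks_shallow_bins(self):
        g = toy_genome(1, 3_000_000)
        reads = pd.DataFrame(
            {"chrom": ["chr1", "chr1"], "start": [100, 1_000_100],
             "end": [200, 1_000_200], "count": [3, 50]}
        )
        profile = cnv.bin_counts(reads, g, min_count=10)
        assert profile.mask.tolist() == [True, False, True]


class TestNormalization:
    def test_flat_counts_normalize_to_zero(self):
        raw = profile_from_values([100] * 20, stage="raw")
        assert np.allclose(cnv.normalize(raw).values, 0.0)

    def test_scale_invariance(self):
        rng = np.random.default_rng(1)
        counts = rng.integers(50, 150, size=30).astype(float)
        a = cnv.normalize(profile_from_values(counts, stage="raw"))
        b = cnv.normalize(profile_from_values(2 * counts, stage="raw"))
        assert np.allclose(a.values, b.values)

    def test_cn4_at_full_purity_sits_at_log2_of_two(self):
        """A CN=4 segment in a pure tumor doubles the diploid depth:
        normalized ratio ~ 1.0 at high coverage."""
        g = toy_genome(4, 25_000_000)
        raw = synthetic.simulate_bin_counts(
            [("chr1", 0, 25_000_000, 4)], 1.0, mean_count=10_000.0,
            dispersion=0.0, genome=g, seed=0,
        )
        norm = cnv.normalize(raw)
        in_seg = (norm.bins["chrom"] == "chr1").to_numpy()
        # 3 sigma for 25 Poisson(2e4) bins plus autosomal-median noise
        assert abs(norm.values[in_seg].mean() - 1.0) < 0.015

    def test_zero_counts_become_masked(self):
        raw = profile_from_values([100, 0, 100, 100], stage="raw")
        norm = cnv.normalize(raw)
        assert norm.mask.tolist() == [False, True, False, False]
        assert np.isnan(norm.values[1])


class TestReferenceSubtraction:
    def test_self_subtraction_yields_zeros(self):
        rng = np.random.default_rng(2)
        norm = cnv.normalize(
            profile_from_values(rng.integers(80, 120, 50).astype(float), stage="raw")
        )
        out = cnv.subtract_reference(norm, norm)
        assert out.stage == "corrected"
        assert np.allclose(out.values[~out.mask], 0.0)

    def test_zero_reference_is_identity(self):
        rng = np.random.default_rng(3)
        norm = cnv.normalize(
            profile_from_values(rng.integers(80, 120, 50).astype(float), stage="raw")
        )
        ref = cnv.BinProfile(
            bins=norm.bins, values=np.zeros(len(norm)), stage="normalized"
        )
        out = cnv.subtract_reference(norm, ref)
        assert np.allclose(out.values, norm.values)

    def test_shared_artifact_cancels(self):
        base = np.zeros(40)
        tumor, ref = base.copy(), base.copy()
        tumor[7] += 0.5  # platform artifact present in both
        ref[7] += 0.5
        t = cnv.BinProfile(bins=profile_from_values(base).bins, values=tumor, stage="normalized")
        r = cnv.BinProfile(bins=profile_from_values(base).bins, values=ref, stage="normalized")
        out = cnv.subtract_reference(t, r)
        assert out.values[7] == 0.0

    def test_grid_mismatch_rejected(self):
        a = cnv.BinProfile(
            bins=toy_genome(1, 5_000_000).bins(1_000_000),
            values=np.zeros(5), stage="normalized",
        )
        b = cnv.BinProfile(
            bins=toy_genome(1, 6_000_000).bins(1_000_000),
            values=np.zeros(6), stage="normalized",
        )
        with pytest.raises(ValueError, match="grids differ"):
            cnv.subtract_reference(a, b)


class TestSegmentation:
    def test_flat_noiseless_profile_is_one_segment_per_chromosome(self):
        g = toy_genome(2, 30_000_000)
        profile = cnv.BinProfile(
            bins=g.bins(1_000_000), values=np.zeros(60), stage="corrected"
        )
        segs = cnv.segment(profile, seed=0)
        assert len(segs) == 2
        assert segs.df["n_bins"].tolist() == [30, 30]
        assert np.allclose(segs.df["mean_log2"], 0.0)

    def test_planted_breakpoint_recovered_within_two_bins(self):
        """A +1.0 step at bin 100 of 200 with noise SD 0.1."""
        rng = np.random.default_rng(0)
        values = rng.normal(0.0, 0.1, 200)
        values[100:] += 1.0
        profile = profile_from_values(values, chrom_sizes=toy_genome(1, 200_000_000))
        segs = cnv.segment(profile, seed=1)
        assert len(segs) == 2
        breakpoint_bin = segs.df["end"].iloc[0] // 1_000_000
        assert abs(breakpoint_bin - 100) <= 2

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_best_split_matches_exhaustive_least_squares(self, seed):
        """The maximal-t breakpoint equals the two-segment least-squares
        optimum on profiles of <= 100 bins."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(20, 100))
        x = rng.normal(0, 0.2, n)
        x[n // 3:] += rng.uniform(0.3, 1.0)
        min_bins = 5
        k_t, _ = cnv._best_split(x, min_bins)
        sse = {
            k: ((x[:k] - x[:k].mean()) ** 2).sum() + ((x[k:] - x[k:].mean()) ** 2).sum()
            for k in range(min_bins, n - min_bins + 1)
        }
        best_sse = min(sse.values())
        assert sse[k_t] == pytest.approx(best_sse)

    def test_min_bins_respected(self):
        rng = np.random.default_rng(5)
        values = rng.normal(0, 0.05, 40)
        values[20:] += 1.0
        profile = profile_from_values(values, chrom_sizes=toy_genome(1, 40_000_000))
        segs = cnv.segment(profile, min_bins=8, seed=0)
        assert (segs.df["n_bins"] >= 8).all()


class TestFocalEvents:
    def test_flat_profile_has_no_events(self):
        segs = cnv.SegmentSet(
            df=pd.DataFrame(
                [("chr1", 0, 50_000_000, 0.0, 50)],
                columns=["chrom", "start", "end", "mean_log2", "n_bins"],
            ),
            residual_sd=0.05,
        )
        assert cnv.detect_focal_events(segs) == []

    def test_planted_focal_gain_is_annotated(self):
        segs = cnv.SegmentSet(
            df=pd.DataFrame(
                [
                    ("chr1", 0, 20_000_000, 0.0, 20),
                    ("chr1", 20_000_000, 22_000_000, 0.3, 2),
                    ("chr1", 22_000_000, 50_000_000, 0.0, 28),
                ],
                columns=["chrom", "start", "end", "mean_log2", "n_bins"],
            ),
            residual_sd=0.05,
        )
        annotations = pd.DataFrame(
            [("chr1", 20_500_000, 21_000_000, "BRAF")],
            columns=["chrom", "start", "end", "name"],
        )
        events = cnv.detect_focal_events(segs, annotations=annotations)
        assert len(events) == 1
        event = events[0]
        assert event.direction == "gain"
        assert event.annotation == "BRAF"
        assert event.width == 2_000_000

    def test_whole_chromosome_gain_is_not_focal(self):
        segs = cnv.SegmentSet(
            df=pd.DataFrame(
                [
                    ("chr1", 0, 50_000_000, 0.58, 50),
                    ("chr2", 0, 50_000_000, 0.0, 50),
                ],
                columns=["chrom", "start", "end", "mean_log2", "n_bins"],
            ),
            residual_sd=0.05,
        )
        assert cnv.detect_focal_events(segs, max_width=10_000_000) == []


def segments_for_purity(means_widths):
    rows = []
    pos = 0
    for mean, width in means_widths:
        rows.append(("chr1", pos, pos + width, mean, max(width // 1_000_000, 1)))
        pos += width
    return cnv.SegmentSet(
        df=pd.DataFrame(rows, columns=["chrom", "start", "end", "mean_log2", "n_bins"]),
        residual_sd=0.02,
    )


class TestPurity:
    def test_flat_diploid_profile_is_unidentifiable(self):
        segs = segments_for_purity([(0.0, 100_000_000)])
        fit = cnv.estimate_purity(segs)
        assert not fit.identifiable
        assert fit.cellularity is None
        assert "chromosomal alterations" in fit.reason

    def test_pure_tumor_with_simple_karyotype_fits_exactly(self):
        means = [
            (np.log2(1 / 2), 20_000_000),   # CN 1
            (0.0, 60_000_000),              # CN 2
            (np.log2(3 / 2), 20_000_000),   # CN 3
        ]
        fit = cnv.estimate_purity(segments_for_purity(means))
        assert fit.identifiable
        assert fit.cellularity == pytest.approx(1.0)
        assert fit.copy_assignments.tolist() == [1, 2, 3]
        assert fit.fit_error == pytest.approx(0.0, abs=1e-12)

    def test_recovery_with_noise_on_segment_means(self):
        """alpha=0.4, 30% of the genome CN=1, segment-mean noise from
        bin noise SD 0.05: recovered within +-0.05."""
        rng = np.random.default_rng(0)
        for seed in range(10):
            rng = np.random.default_rng(seed)
            e_cn1 = cnv.expected_log2(1, 0.4, 2.0)
            means = [
                (e_cn1 + rng.normal(0, 0.05 / np.sqrt(300)), 300_000_000),
                (rng.normal(0, 0.05 / np.sqrt(700)), 700_000_000),
            ]
            fit = cnv.estimate_purity(segments_for_purity(means))
            assert fit.identifiable
            assert abs(fit.cellularity - 0.4) <= 0.05

    def test_half_cellularity_degeneracy_resolves_high(self):
        """A fit at cellularity a is exactly mirrored at a/2 with copy
        states doubled; the parsimonious high branch is returned."""
        means = [
            (cnv.expected_log2(1, 0.5, 2.0), 300_000_000),
            (0.0, 700_000_000),
            (cnv.expected_log2(3, 0.5, 2.0), 200_000_000),
        ]
        fit = cnv.estimate_purity(segments_for_purity(means))
        assert fit.cellularity == pytest.approx(0.5)

    def test_identifiability_ladder_fails_safe(self):
        """Shrinking the aneuploid fraction drives the fit to
        unidentifiable before it returns a wrong cellularity."""
        for frac in (0.30, 0.20, 0.10, 0.04, 0.01):
            aneu = int(frac * 1_000_000_000)
            means = [
                (cnv.expected_log2(1, 0.4, 2.0), aneu),
                (0.0, 1_000_000_000 - aneu),
            ]
            fit = cnv.estimate_purity(segments_for_purity(means))
            if fit.identifiable:
                assert abs(fit.cellularity - 0.4) <= 0.05
            else:
                assert fit.cellularity is None
        # the most diluted rungs must be unidentifiable
        tiny = segments_for_purity(
            [(cnv.expected_log2(1, 0.4, 2.0), 10_000_000), (0.0, 990_000_000)]
        )
        assert not cnv.estimate_purity(tiny).identifiable

    def test_empty_segment_set_rejected(self):
        empty = cnv.SegmentSet(
            df=pd.DataFrame(columns=["chrom", "start", "end", "mean_log2", "n_bins"]),
            residual_sd=0.0,
        )
        with pytest.raises(ValueError, match="empty"):
            cnv.estimate_purity(empty)
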