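import numpy as np
import pandas as pd
import pytest

from nucscore import PipelineConfig
from nucscore.config import GeneModel, GenomeAssembly
from nucscore.annotate import (
    classify_h2az,
    element_track_means,
    gene_promoter_score,
    nfr_interval,
    overlap_fraction_by_bin,
    overlaps_any,
    promoter_interval,
    rank_sum_test,
    score_per_bp,
    target_fraction_by_bin,
    tss_element_profile,
    tss_metaprofile,
)


def gene(tss, strand, chrom="chrI", gid="G", cls="mRNA"):
    return GeneModel(gid, chrom, tss, strand, cls)


class TestIntervals:
    def test_nfr_plus_strand(self, config):
        assert nfr_interval(gene(1000, "+"), config) == (750, 950)

    def test_nfr_minus_strand(self, config):
        assert nfr_interval(gene(1000, "-"), config) == (1050, 1250)

    def test_nfr_clipped_at_origin(self, config):
        assert nfr_interval(gene(100, "+"), config) == (0, 50)

    def test_nfr_clipped_at_chrom_end(self, config):
        assert nfr_interval(gene(1000, "-"), config, chrom_length=1100) == (1050, 1100)

    def test_promoter_orientation(self, config):
        assert promoter_interval(gene(1000, "+"), config) == (750, 1000)
        assert promoter_interval(gene(1000, "-"), config) == (1000, 1250)


class TestOverlap:
    def elements(self, intervals):
        return pd.DataFrame(
            [("chrI", s, e) for s, e in intervals], columns=["chrom", "start", "end"]
        )

    def test_whole_genome_feature_hits_everything(self):
        el = self.elements([(0, 10), (50, 60)])
        feats = self.elements([(0, 1000)])
        assert overlaps_any(el, feats).all()

    def test_no_features_hits_nothing(self):
        el = self.elements([(0, 10)])
        feats = self.elements([]).astype({"start": int, "end": int})
        assert not overlaps_any(el, feats).any()

    def test_single_bp_overlap_counts(self):
        el = self.elements([(0, 192)])
        feats = self.elements([(191, 300)])
        assert overlaps_any(el, feats).all()

    def test_bookended_does_not_overlap(self):
        el = self.elements([(0, 192)])
        feats = self.elements([(192, 300)])
        assert not overlaps_any(el, feats).any()

    def test_fraction_by_bin(self):
        el = self.elements([(0, 10), (20, 30), (100, 110), (200, 210)])
        bins = pd.Series(["low", "low", "high", "high"])
        feats = self.elements([(0, 50)])
        frac = overlap_fraction_by_bin(el, bins, feats)
        assert frac.to_dict() == {"low": 1.0, "high": 0.0}


class TestScorePerBp:
    def test_single_window_covers_seven_bins(self, config):
        scored = pd.DataFrame(
            {"chrom": ["chrI"], "start": [0], "end": [167], "IS": [2.0]}
        )
        track = score_per_bp(scored, "IS", config)
        assert track["start"].tolist() == [0, 25, 50, 75, 100, 125, 150]
        assert (track["value"] == 2.0).all()

    def test_overlapping_windows_average(self, config):
        scored = pd.DataFrame(
            {"chrom": "chrI", "start": [0, 25], "end": [167, 192], "IS": [1.0, 3.0]}
        )
        track = score_per_bp(scored, "IS", config)
        by_start = track.set_index("start")["value"]
        assert by_start[0] == 1.0  # only first window covers bin 0
        assert by_start[25] == 2.0  # both windows cover bin 25

    def test_no_kept_windows_gives_empty_track(self, config):
        scored = pd.DataFrame(
            {"chrom": ["chrI"], "start": [0], "end": [167], "IS": [np.nan]}
        )
        assert len(score_per_bp(scored, "IS", config)) == 0


class TestMetaprofile:
    def flat_genome(self, length=10_000):
        return GenomeAssembly({"chrI": "A" * length})

    def constant_track(self, value, length=10_000, step=25):
        starts = np.arange(0, length, step)
        return pd.DataFrame(
            {"chrom": "chrI", "start": starts, "end": starts + step, "value": value}
        )

    def test_constant_track_flat_profile(self, config):
        genome = self.flat_genome()
        track = self.constant_track(3.0)
        prof = tss_metaprofile(track, [gene(5000, "+")], genome, config)
        assert np.allclose(prof.mean_value, 3.0)
        centered = tss_metaprofile(track, [gene(5000, "+")], genome, config, center=True)
        assert np.allclose(centered.mean_value, 0.0, atol=1e-12)

    def test_mirror_symmetry(self, config):
        """Reflecting the genome and flipping strands leaves the profile
        unchanged."""
        rng = np.random.default_rng(0)
        length = 10_000
        values = rng.normal(size=length // 25)
        starts = np.arange(0, length, 25)
        track = pd.DataFrame(
            {"chrom": "chrI", "start": starts, "end": starts + 25, "value": values}
        )
        mirrored = pd.DataFrame(
            {
                "chrom": "chrI",
                "start": length - starts - 25,
                "end": length - starts,
                "value": values,
            }
        )
        genome = self.flat_genome(length)
        fwd = tss_metaprofile(track, [gene(4000, "+")], genome, config)
        rev = tss_metaprofile(mirrored, [gene(length - 1 - 4000, "-")], genome, config)
        np.testing.assert_allclose(fwd.mean_value, rev.mean_value)

    def test_conservation_of_contributions(self, config):
        """sum(n * mean) over offsets equals the sum of contributed values."""
        rng = np.random.default_rng(1)
        genome = self.flat_genome()
        starts = np.arange(0, 10_000, 25)
        track = pd.DataFrame(
            {"chrom": "chrI", "start": starts, "end": starts + 25,
             "value": rng.normal(size=len(starts))}
        )
        genes = [gene(3000, "+"), gene(7000, "-")]
        prof = tss_metaprofile(track, genes, genome, config)
        total = np.nansum(prof.mean_value * prof.n)
        grid = track.set_index("start")["value"]
        expected = 0.0
        for g in genes:
            for o in prof.offsets:
                center = g.tss + o + 12.5 if g.strand == "+" else g.tss - o - 12.5
                expected += grid[int(center // 25) * 25]
        assert total == pytest.approx(expected)

    def test_element_density_profile_localizes_midpoint(self, config):
        elements = pd.DataFrame(
            {"chrom": ["chrI"], "start": [4875], "end": [4925]}
        )  # midpoint 4900 = tss - 100
        prof = tss_element_profile(elements, [gene(5000, "+")], config)
        hot = prof.offsets[prof.mean_value > 0]
        assert hot.tolist() == [-100]

    def test_no_genes_rejected(self, config):
        with pytest.raises(ValueError):
            tss_metaprofile(self.constant_track(1.0), [], self.flat_genome(), config)


class TestH2AZClassification:
    def elements(self, n, width=25):
        return pd.DataFrame(
            {"chrom": "chrI", "start": np.arange(n) * width,
             "end": np.arange(n) * width + width}
        )

    def track_with_values(self, values, width=25):
        return pd.DataFrame(
            {"chrom": "chrI", "start": np.arange(len(values)) * width,
             "end": np.arange(len(values)) * width + width, "value": values}
        )

    def test_top_and_bottom_three_of_ten(self, config):
        labels = classify_h2az(
            self.track_with_values(np.arange(1.0, 11.0)), self.elements(10), config
        )
        assert (labels[7:] == "H2AZ+").all()
        assert (labels[:3] == "H2AZ-").all()
        assert (labels[3:7] == "neither").all()

    def test_constant_track_classifies_nothing(self, config):
        labels = classify_h2az(
            self.track_with_values(np.full(10, 2.0)), self.elements(10), config
        )
        assert (labels == "neither").all()

    def test_uncovered_elements_are_neither(self, config):
        track = self.track_with_values(np.arange(1.0, 6.0))
        elements = self.elements(6)  # last element beyond track
        labels = classify_h2az(track, elements, config)
        assert labels.iloc[5] == "neither"

    def test_element_track_means_weighted_by_coverage(self):
        track = pd.DataFrame(
            {"chrom": ["chrI", "chrI"], "start": [0, 10], "end": [10, 20],
             "value": [1.0, 3.0]}
        )
        elements = pd.DataFrame({"chrom": ["chrI"], "start": [5], "end": [15]})
        assert element_track_means(elements, track)[0] == pytest.approx(2.0)


class TestRankSum:
    def test_identical_groups_two_sided_p_one(self):
        res = rank_sum_test([1, 2, 3], [1, 2, 3], "two-sided")
        assert res.p_value == 1.0

    def test_exact_one_sided_enumeration(self):
        res = rank_sum_test([1, 2, 3], [4, 5, 6], "one-sided-less")
        assert res.p_value == pytest.approx(1 / 20)

    def test_exact_two_sided_doubles(self):
        res = rank_sum_test([1, 2, 3], [4, 5, 6], "two-sided")
        assert res.p_value == pytest.approx(0.1)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            rank_sum_test([], [1.0], "two-sided")

    def test_large_sample_normal_approximation(self):
        rng = np.random.default_rng(0)
        a = rng.normal(1.0, 1, 300)
        b = rng.normal(0.0, 1, 300)
        res = rank_sum_test(a, b, "one-sided-greater")
        assert res.p_value < 1e-10


class TestGeneScores:
    def scored(self):
        starts = np.arange(0, 2000, 25)
        return pd.DataFrame(
            {"chrom": "chrI", "start": starts, "end": starts + 167,
             "RS": np.linspace(0, 1, len(starts))}
        )

    def test_max_window_within_halfwidth_of_tss(self, config):
        s = self.scored()
        score = gene_promoter_score(s, "RS", [gene(500, "+")], config)
        mids = (s["start"] + s["end"]) // 2
        in_range = s.loc[(mids >= 250) & (mids < 750), "RS"]
        assert score["G"] == pytest.approx(in_range.max())

    def test_gene_without_windows_gets_nan(self, config):
        score = gene_promoter_score(self.scored(), "RS", [gene(100_000, "+")], config)
        assert np.isnan(score["G"])

    def test_target_fraction_concentrates_in_top_bins(self, config):
        cfg = PipelineConfig(percentile_edges=(0, 50, 90, 100))
        scores = pd.Series(np.arange(100, dtype=float), index=[f"G{i}" for i in range(100)])
        targets = {f"G{i}" for i in range(90, 100)}  # exactly the top decile
        frac, test = target_fraction_by_bin(scores, targets, cfg)
        assert frac["90-100"] == 1.0
        assert frac["0-50"] == 0.0
        assert test.p_value < 0.01

    def test_disjoint_target_set_rejected(self, config):
        scores = pd.Series([1.0, 2.0], index=["A", "B"])
        with pytest.raises(ValueError):
            target_fraction_by_bin(scores, {"Z"}, config)
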