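"""Coverage normalization, peak calling, correlation, PAM-by-rank summaries."""

import math

import numpy as np
import pytest
from scipy.stats import spearmanr

from cascadescope import chip_quant as cq
from cascadescope import offtarget_scan as scan
from cascadescope import synthetic_data as synth
from cascadescope.duplex_model import TargetSite

from conftest import random_spacer


def track(values, total_reads=None, contig="chr"):
    return cq.CoverageTrack(contig=contig, values=np.asarray(values, float), total_reads=total_reads)


class TestNormalize:
    def test_formula(self):
        t = cq.normalize_coverage(track([300.0], total_reads=1_500_000))
        assert t.values[0] == pytest.approx(20.0)  # 300 / (1.5e6 / 1e5)

    def test_invariant_under_joint_scaling(self):
        raw = np.array([10.0, 40.0, 5.0])
        a = cq.normalize_coverage(track(raw, total_reads=200_000))
        b = cq.normalize_coverage(track(raw * 10, total_reads=2_000_000))
        np.testing.assert_allclose(a.values, b.values)

    def test_unit_denominator_is_identity(self):
        raw = np.array([1.0, 7.0, 3.0])
        t = cq.normalize_coverage(track(raw, total_reads=100_000))
        np.testing.assert_array_equal(t.values, raw)

    def test_missing_or_zero_depth_rejected(self):
        with pytest.raises(ValueError):
            cq.normalize_coverage(track([1.0]))
        with pytest.raises(ValueError):
            cq.normalize_coverage(track([1.0], total_reads=0))


class TestCallPeaks:
    def test_flat_track_below_threshold_gives_no_peaks(self):
        assert cq.call_peaks(track(np.ones(1000)), threshold=2.0) == []

    def test_two_separated_pileups_give_two_peaks(self):
        v = np.zeros(2000)
        v[200:250] = 5.0
        v[1200:1280] = 7.0
        peaks = cq.call_peaks(track(v), threshold=1.0, merge_gap=100)
        assert len(peaks) == 2
        assert peaks[0].center == 200  # leftmost argmax on the plateau
        assert peaks[1].center_coverage == 7.0

    def test_gap_merging_and_min_width(self):
        v = np.zeros(1000)
        v[100:110] = 3.0
        v[150:160] = 3.0
        assert len(cq.call_peaks(track(v), 1.0, merge_gap=50)) == 1
        assert len(cq.call_peaks(track(v), 1.0, merge_gap=10)) == 2
        assert cq.call_peaks(track(v), 1.0, merge_gap=10, min_width=20) == []

    def test_simulated_pileup_center_near_site_midpoint(self, spacer):
        genome = {"chr": synth.make_genome(20_000, 0.5, 1)}
        spec = synth.PlantSpec("sp8", "AAG", frozenset(range(1, 33)), "chr", 10_000, "+")
        _, truth = synth.plant_sites(genome, spacer, [spec])
        truth.weights = [20_000.0]
        t = synth.simulate_chip_coverage(20_000, truth, background=1.0, fragment_sd=60, seed=2)
        peaks = cq.call_peaks(cq.normalize_coverage(t), threshold=1.0, merge_gap=200)
        assert len(peaks) == 1
        assert abs(peaks[0].center - 10_017) <= 60

    def test_boundary_runs(self):
        v = np.full(100, 9.0)
        peaks = cq.call_peaks(track(v), threshold=1.0)
        assert len(peaks) == 1 and peaks[0].start == 0 and peaks[0].end == 100


class TestWindowMax:
    def test_constant_track(self):
        m = cq.window_max_track(track(np.full(2500, 4.0)), window=1000)
        assert m.tolist() == [4.0, 4.0, 4.0]  # ceil(2500/1000) tiles

    def test_single_spike_elevates_one_tile(self):
        v = np.ones(5000)
        v[3210] = 50.0
        m = cq.window_max_track(track(v), window=1000)
        assert (m == 50.0).sum() == 1 and m[3] == 50.0


class TestDatasetR2:
    def fake_peaks(self, centers):
        return [cq.Peak("chr", c - 5, c + 5, c, 1.0) for c in centers]

    def test_linear_relation_gives_r2_of_one(self):
        rng = np.random.default_rng(0)
        a = track(rng.uniform(1, 10, 1000))
        b = track(a.values * 2.0)
        peaks = self.fake_peaks(range(10, 910, 100))
        assert cq.dataset_r2(peaks, a, b) == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_independent_tracks_give_low_r2(self, seed):
        rng = np.random.default_rng(seed)
        a = track(rng.uniform(1, 10, 2000))
        b = track(rng.uniform(1, 10, 2000))
        peaks = self.fake_peaks(range(0, 2000, 20))  # n = 100
        assert cq.dataset_r2(peaks, a, b) < 0.2

    def test_bounds_and_errors(self):
        rng = np.random.default_rng(4)
        a = track(rng.uniform(1, 10, 500))
        b = track(rng.uniform(1, 10, 500))
        peaks = self.fake_peaks(range(0, 500, 10))
        r2 = cq.dataset_r2(peaks, a, b)
        assert 0.0 <= r2 <= 1.0
        with pytest.raises(ValueError):
            cq.dataset_r2(peaks[:2], a, b)
        assert cq.dataset_r2(peaks, track(np.ones(500)), b) is None


def simulate_cohort(spacer, seed, n_sites=50, length=220_000):
    specs, _ = synth.sample_offtarget_specs(
        spacer, genome_length=length, n_sites=n_sites, seed=seed,
        include_on_target=False, min_spacing=4000,
    )
    genome = {"chr": synth.make_genome(length, 0.5, seed)}
    genome, truth = synth.plant_sites(genome, spacer, specs)
    rng = np.random.default_rng(seed + 1)
    truth.weights = list(np.exp(rng.uniform(np.log(2e3), np.log(2e5), len(specs))))
    return genome, truth


class TestAffinityRecovery:
    @pytest.mark.parametrize("seed", [31, 32, 33])
    def test_rank_correlation_between_weights_and_center_coverage(self, spacer, seed):
        """Planted affinities are recovered in normalized peak-center coverage."""
        genome, truth = simulate_cohort(spacer, seed)
        t = synth.simulate_chip_coverage(
            len(genome["chr"]), truth, background=1.0, fragment_sd=60, seed=seed + 2
        )
        norm = cq.normalize_coverage(t)
        # threshold: 8 raw fragments (background is ~1/base), in normalized units
        thr = 8 * cq.READS_PER_UNIT / t.total_reads
        peaks = cq.call_peaks(norm, threshold=thr, merge_gap=300, min_width=50)
        # match each planted site to the peak containing its midpoint
        matched = []
        for planted, w in zip(truth.sites, truth.weights):
            mid = (planted.site.start + planted.site.end) // 2
            for p in peaks:
                if p.start - 200 <= mid < p.end + 200:
                    matched.append((w, p.center_coverage))
                    break
        assert len(matched) >= 45  # nearly all 50 sites recovered as peaks
        rho = spearmanr([m[0] for m in matched], [m[1] for m in matched]).statistic
        assert rho >= 0.9

    def test_peaks_fall_on_planted_sites(self, spacer):
        genome, truth = simulate_cohort(spacer, 34)
        t = synth.simulate_chip_coverage(
            len(genome["chr"]), truth, background=1.0, fragment_sd=60, seed=35
        )
        norm = cq.normalize_coverage(t)
        thr = 8 * cq.READS_PER_UNIT / t.total_reads
        peaks = cq.call_peaks(norm, threshold=thr, merge_gap=300, min_width=50)
        mids = [(p.site.start + p.site.end) // 2 for p in truth.sites]
        orphans = [
            p for p in peaks if min(abs(p.center - m) for m in mids) > 500
        ]
        # false positives below 1 per Mb on a 0.22-Mb genome: none expected
        assert len(orphans) == 0


class TestPamFractionByRank:
    def annotate(self, spacer, pams, enrichments):
        """Annotated peaks with controlled PAM and enrichment."""
        out = []
        for i, (pam, e) in enumerate(zip(pams, enrichments)):
            peak = cq.Peak("chr", i * 100, i * 100 + 10, i * 100, float(e))
            site = TargetSite(
                contig="chr", start=i * 100, end=i * 100 + 35, strand="+",
                pam=pam, protospacer=spacer.sequence,
            )
            hit = scan._make_hit(spacer, site, scan.ScanConfig())
            out.append(cq.AnnotatedPeak(peak=peak, hit=hit))
        return out

    def test_all_aag(self, spacer):
        annotated = self.annotate(spacer, ["AAG"] * 10, range(10))
        assert cq.pam_fraction_by_rank(annotated) == (1.0, 1.0)

    def test_constructed_top_split(self, spacer):
        pams = ["AAG", "AAG"] + ["GAG"] * 8
        enrich = [100, 90] + list(range(8))
        annotated = self.annotate(spacer, pams, enrich)
        assert cq.pam_fraction_by_rank(annotated, top_fraction=0.2) == (1.0, 0.0)

    def test_matches_independent_recount(self, spacer):
        rng = np.random.default_rng(6)
        pams = [str(p) for p in rng.choice(["AAG", "GAG", "TAG"], size=20)]
        enrich = rng.uniform(1, 100, size=20)
        annotated = self.annotate(spacer, pams, enrich)
        frac_top, frac_rest = cq.pam_fraction_by_rank(annotated, top_fraction=0.2)
        order = np.argsort(-enrich, kind="stable")
        top, rest = order[:4], order[4:]
        assert frac_top == pytest.approx(np.mean([pams[i] == "AAG" for i in top]))
        assert frac_rest == pytest.approx(np.mean([pams[i] == "AAG" for i in rest]))

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            cq.pam_fraction_by_rank([])


class TestAssociatePeaks:
    def test_best_hit_selection(self, spacer):
        genome = {"chr": synth.make_genome(4000, 0.5, 40)}
        specs = [
            synth.PlantSpec("sp8", "AAG", frozenset(range(1, 33)), "chr", 2000, "+"),
            synth.PlantSpec("sp8", "AAG", frozenset(range(1, 6)), "chr", 2100, "+"),
        ]
        genome, _ = synth.plant_sites(genome, spacer, specs)
        hits = scan.scan_genome(genome, spacer)
        peak = cq.Peak("chr", 2050, 2090, 2080, 5.0)
        annotated = cq.associate_peaks([peak], hits, max_dist=250)
        # the full-match site wins despite being farther from the center
        assert annotated[0].hit.site.start == 2000

    def test_no_hit_in_range_gives_none(self, spacer):
        genome = {"chr": synth.make_genome(4000, 0.5, 41)}
        spec = synth.PlantSpec("sp8", "AAG", frozenset(range(1, 33)), "chr", 3000, "+")
        genome, _ = synth.plant_sites(genome, spacer, [spec])
        hits = scan.scan_genome(genome, spacer)
        peak = cq.Peak("chr", 100, 140, 120, 5.0)
        assert cq.associate_peaks([peak], hits, max_dist=250)[0].hit is None
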