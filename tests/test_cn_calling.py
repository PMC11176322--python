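"""The progenitor-referenced copy-number caller, step by step and end to
end against planted truth."""

import numpy as np
import pandas as pd
import pytest

from scnakit import cn_calling as cc
from scnakit.containers import BinCounts, make_bin_grid
from scnakit.synthetic import PlantedEvent, SimConfig, generate_clone_pair


def constant_track(values, n_chrom=1):
    grid = make_bin_grid(len(values), n_chrom)
    values = np.asarray(values, dtype=float)
    return cc.DepthRatioTrack(bins=grid, ratio=values,
                              masked=~np.isfinite(values))


class TestDepthRatio:
    def test_identical_samples_give_unit_ratios(self):
        grid = make_bin_grid(100, 2)
        counts = np.random.default_rng(0).poisson(100, 100)
        a = BinCounts("p", grid, counts)
        b = BinCounts("d", grid, counts.copy())
        track = cc.compute_depth_ratio(a, b)
        assert np.allclose(track.ratio[~track.masked], 1.0)

    def test_zero_coverage_bins_masked(self):
        grid = make_bin_grid(10, 1)
        p = BinCounts("p", grid, [100] * 9 + [0])
        d = BinCounts("d", grid, [0] + [100] * 9)
        track = cc.compute_depth_ratio(p, d)
        assert track.masked[0] and track.masked[9]
        assert not track.masked[1:9].any()

    def test_planted_doubling_recovered(self):
        rng = np.random.default_rng(1)
        grid = make_bin_grid(1000, 4)
        base = rng.poisson(200, 1000)
        doubled = base.copy()
        doubled[:100] = rng.poisson(400, 100)
        p = BinCounts("p", grid, base)
        d = BinCounts("d", grid, doubled)
        track = cc.compute_depth_ratio(p, d)
        scale = p.total_reads / d.total_reads
        assert track.ratio[:100].mean() == pytest.approx(2.0 * scale, rel=0.05)

    def test_normalization_invariance(self):
        grid = make_bin_grid(50, 1)
        rng = np.random.default_rng(2)
        p = BinCounts("p", grid, rng.poisson(100, 50))
        d_counts = rng.poisson(100, 50)
        t1 = cc.compute_depth_ratio(p, BinCounts("d", grid, d_counts))
        t2 = cc.compute_depth_ratio(p, BinCounts("d", grid, d_counts * 7))
        assert np.allclose(t1.ratio, t2.ratio, equal_nan=True)

    def test_mismatched_grids_report_discrepancy(self):
        a = BinCounts("p", make_bin_grid(10, 1), [1] * 10)
        b = BinCounts("d", make_bin_grid(10, 2), [1] * 10)
        with pytest.raises(ValueError, match="row"):
            cc.compute_depth_ratio(a, b)


class TestSNPBalance:
    def test_exact_center_is_balanced(self):
        df = pd.DataFrame({"chrom": ["chr1"], "pos": [5], "ref_count": [50],
                           "alt_count": [50]})
        out = cc.test_snp_balance(df)
        assert out["balance_p"].iloc[0] == 1.0
        assert bool(out["balanced"].iloc[0])

    def test_strong_imbalance_rejected(self):
        df = pd.DataFrame({"chrom": ["chr1"], "pos": [5], "ref_count": [20],
                           "alt_count": [80]})
        out = cc.test_snp_balance(df)
        assert out["balance_p"].iloc[0] < 1e-8
        assert not bool(out["balanced"].iloc[0])

    def test_depth_and_alt_filters(self):
        df = pd.DataFrame({
            "chrom": ["chr1"] * 2, "pos": [1, 2],
            "ref_count": [15, 80], "alt_count": [15, 5],
        })
        out = cc.test_snp_balance(df)
        assert not out["retained"].any()
        assert out["drop_reason"].iloc[0] == "depth<40"
        assert out["drop_reason"].iloc[1] == "alt<10"

    def test_matches_scipy_exact_binomial(self):
        from scipy.stats import binomtest
        for n, k in [(40, 12), (55, 30), (100, 60)]:
            df = pd.DataFrame({"chrom": ["c"], "pos": [0],
                               "ref_count": [n - k], "alt_count": [k]})
            p = cc.test_snp_balance(df)["balance_p"].iloc[0]
            assert p == pytest.approx(binomtest(k, n, 0.5).pvalue, rel=1e-9)


class TestBalancedBins:
    def _snps(self, bin_idx, balanced_flags):
        n = len(bin_idx)
        df = pd.DataFrame({
            "chrom": ["chr1"] * n,
            "pos": np.asarray(bin_idx) * 1_000_000 + 17,
            "ref_count": [50] * n,
            "alt_count": [50 if b else 90 for b in balanced_flags],
        })
        return cc.test_snp_balance(df)

    def test_half_balanced_flags_bin(self):
        snps = self._snps([0] * 10, [True] * 5 + [False] * 5)
        flags = cc.identify_balanced_bins(snps, make_bin_grid(3, 1))
        assert flags[0] and not flags[1:].any()

    def test_ten_percent_balanced_does_not_flag(self):
        snps = self._snps([0] * 10, [True] + [False] * 9)
        flags = cc.identify_balanced_bins(snps, make_bin_grid(3, 1))
        assert not flags[0]

    def test_bin_without_snps_unflagged(self):
        snps = self._snps([0] * 10, [True] * 10)
        flags = cc.identify_balanced_bins(snps, make_bin_grid(3, 1))
        assert not flags[1] and not flags[2]

    def test_min_snps_gate(self):
        snps = self._snps([0] * 4, [True] * 4)
        flags = cc.identify_balanced_bins(snps, make_bin_grid(3, 1), min_snps=5)
        assert not flags[0]


class TestSegmentation:
    def test_constant_track_single_segment_per_chromosome(self):
        track = constant_track(np.ones(200), n_chrom=4)
        segs = cc.segment_ratios(track)
        assert len(segs) == 4

    def test_step_detected_near_true_breakpoint(self):
        rng = np.random.default_rng(3)
        x = np.concatenate([
            rng.normal(1.0, 0.05, 100), rng.normal(1.8, 0.05, 100)
        ])
        segs = cc.segment_ratios(constant_track(x))
        assert len(segs) == 2
        assert abs(segs[1].start_bin - 100) <= 2

    def test_pure_noise_rarely_split(self):
        n_single = 0
        for seed in range(100):
            x = np.random.default_rng(seed).normal(1.0, 0.05, 150)
            n_single += len(cc.segment_ratios(constant_track(x))) == 1
        assert n_single >= 95

    def test_masked_bins_excluded_from_segments(self):
        x = np.ones(50)
        x[10] = np.nan
        segs = cc.segment_ratios(constant_track(x))
        covered = set()
        for s in segs:
            covered.update(range(s.start_bin, s.end_bin + 1))
        assert 10 in covered  # inside segment span but not its statistics
        assert len(segs) == 1


class TestReferenceModel:
    def test_single_state_recovery(self):
        rng = np.random.default_rng(4)
        track = constant_track(rng.normal(1.0, 0.05, 500))
        model = cc.fit_reference_model(track, np.ones(500, bool))
        assert np.exp(model.reference_mu) == pytest.approx(1.0, abs=0.01)

    def test_two_state_reference_is_majority_component(self):
        rng = np.random.default_rng(5)
        vals = np.concatenate([
            rng.normal(1.0, 0.04, 300), rng.normal(1.5, 0.04, 200)
        ])
        track = constant_track(vals)
        model = cc.fit_reference_model(track, np.ones(500, bool))
        assert np.exp(model.reference_mu) == pytest.approx(1.0, abs=0.02)
        assert model.weights[model.reference_index] == pytest.approx(0.6, abs=0.05)

    def test_constant_input_hits_sigma_floor(self):
        track = constant_track(np.ones(200))
        model = cc.fit_reference_model(track, np.ones(200, bool))
        assert model.reference_sigma >= 1e-4

    def test_too_few_balanced_bins_raises(self):
        track = constant_track(np.ones(30))
        with pytest.raises(ValueError, match="balanced bins"):
            cc.fit_reference_model(track, np.ones(30, bool))


class TestCalls:
    def _model(self, sigma=0.05):
        return cc.ReferenceModel(
            means=np.array([0.0]), sigmas=np.array([sigma]),
            weights=np.array([1.0]), reference_index=0,
        )

    def test_segment_at_reference_is_neutral(self):
        track = constant_track(np.ones(10))
        seg = cc.Segment("chr1", 0, 9, 1.0, 10)
        calls = cc.call_gains_losses([seg], self._model(), track)
        assert (calls.call == "neutral").all()

    def test_elevated_segment_is_gain_and_mirrored_loss(self):
        up = constant_track(np.full(10, 1.5))
        down = constant_track(np.full(10, 1 / 1.5))
        seg = cc.Segment("chr1", 0, 9, 1.5, 10)
        gain = cc.call_gains_losses([seg], self._model(), up)
        seg2 = cc.Segment("chr1", 0, 9, 1 / 1.5, 10)
        loss = cc.call_gains_losses([seg2], self._model(), down)
        assert (gain.call == "gain").all()
        assert (loss.call == "loss").all()
        # log-scale symmetry: mirrored fold changes give mirrored z
        assert gain.z[0] == pytest.approx(-loss.z[0], rel=1e-6)

    def test_bin_level_sigma_is_more_conservative(self):
        track = constant_track(np.full(10, 1.1))
        seg = cc.Segment("chr1", 0, 9, 1.1, 10)
        z_seg = cc.call_gains_losses([seg], self._model(), track).z[0]
        z_bin = cc.call_gains_losses(
            [seg], self._model(), track, use_segment_se=False
        ).z[0]
        assert abs(z_bin) < abs(z_seg)


class TestAnnotateGenes:
    def _calls(self):
        grid = make_bin_grid(10, 1)
        call = np.array(["neutral"] * 10, dtype=object)
        call[2:4] = "gain"
        call[7] = "loss"
        return cc.CNCallTrack(bins=grid, call=call, z=np.zeros(10),
                              p=np.ones(10))

    def test_any_overlap_rule(self):
        genes = pd.DataFrame({
            "gene": ["inside_gain", "spans_gain_and_neutral", "in_loss"],
            "chrom": ["chr1"] * 3,
            "start": [2_200_000, 3_500_000, 7_100_000],
            "end": [2_800_000, 5_500_000, 7_300_000],
        })
        lists = cc.annotate_genes(self._calls(), genes)
        assert lists["gained"] == ["inside_gain", "spans_gain_and_neutral"]
        assert lists["lost"] == ["in_loss"]

    def test_gene_outside_grid_warns(self):
        genes = pd.DataFrame({
            "gene": ["off_grid"], "chrom": ["chrX"], "start": [0], "end": [10],
        })
        with pytest.warns(UserWarning, match="off_grid"):
            lists = cc.annotate_genes(self._calls(), genes)
        assert lists == {"gained": [], "lost": []}

    def test_empty_table(self):
        genes = pd.DataFrame(columns=["gene", "chrom", "start", "end"])
        assert cc.annotate_genes(self._calls(), genes) == {
            "gained": [], "lost": [],
        }


class TestEndToEnd:
    def test_planted_events_recovered(self, small_clone_pair):
        cfg, prog, daughter, snps, truth = small_clone_pair
        calls = cc.call_clone_pair(prog, daughter, snps)
        truth_mask = truth.event_bin_mask(cfg.n_bins)
        pred = np.where(calls.call == "gain", 1,
                        np.where(calls.call == "loss", -1, 0))
        valid = calls.call != "masked"
        tp = int(((pred != 0) & (pred == truth_mask) & valid).sum())
        fp = int(((pred != 0) & (truth_mask == 0) & valid).sum())
        fn = int(((truth_mask != 0) & (pred == 0) & valid).sum())
        assert tp / (tp + fp) >= 0.9
        assert tp / (tp + fn) >= 0.9

    def test_gain_loss_symmetry(self):
        cfg = SimConfig(seed=77, n_bins=1200, n_chromosomes=8)
        gains = [PlantedEvent(100, 130, 1), PlantedEvent(400, 440, 2)]
        losses = [PlantedEvent(e.start_bin, e.end_bin, -e.delta) for e in gains]
        for events, expected in [(gains, "gain"), (losses, "loss")]:
            prog, dau, snps, _ = generate_clone_pair(
                cfg, ploidy=3, events=events, mean_depth=250
            )
            calls = cc.call_clone_pair(prog, dau, snps)
            for ev in events:
                inside = calls.call[ev.start_bin:ev.end_bin]
                assert (inside == expected).mean() > 0.8

    def test_daughter_scaling_leaves_calls_unchanged(self, small_clone_pair):
        cfg, prog, daughter, snps, _ = small_clone_pair
        scaled = BinCounts("d2", daughter.bins, daughter.counts * 3)
        c1 = cc.call_clone_pair(prog, daughter, snps)
        c2 = cc.call_clone_pair(prog, scaled, snps)
        assert (c1.call == c2.call).all()
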