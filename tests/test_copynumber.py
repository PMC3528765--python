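"""Threshold calling, cumulative frequencies, common-region extraction and
BAF imbalance flagging, checked against simulator ground truth."""
import dataclasses

import numpy as np
import pandas as pd
import pytest

from brcadel.copynumber import (
    baf_imbalance, call_probes, common_region_overlap, cumulative_frequency,
)
from brcadel.simulate import make_truth, simulate_baf, simulate_cgh


def _profile(ratios, chrom="13", probe_prefix="p"):
    n = len(ratios)
    return pd.DataFrame({
        "chromosome": chrom,
        "start": np.arange(n) * 10,
        "end": (np.arange(n) + 1) * 10,
        "probe_id": [f"{probe_prefix}{i:03d}" for i in range(n)],
        "log2ratio": ratios,
    })


class TestCallProbes:
    def test_all_zero_ratios_neutral(self):
        out = call_probes(_profile([0.0] * 5))
        assert (out["call"] == "neutral").all()

    def test_threshold_boundaries(self):
        out = call_probes(_profile([-1.0, -0.25, -0.1, 0.25, 1.0]))
        assert out["call"].tolist() == ["loss", "loss", "neutral", "gain", "gain"]

    def test_relaxing_loss_threshold_is_monotone(self):
        rng = np.random.default_rng(0)
        prof = _profile(rng.normal(0, 0.5, 60))
        strict = set(call_probes(prof, loss_thr=-0.5)["probe_id"][
            call_probes(prof, loss_thr=-0.5)["call"] == "loss"])
        relaxed = set(call_probes(prof, loss_thr=-0.2)["probe_id"][
            call_probes(prof, loss_thr=-0.2)["call"] == "loss"])
        assert strict <= relaxed

    def test_noise_free_simulation_calls_match_truth(self, small_config):
        cfg = dataclasses.replace(small_config, cgh_noise_sd=0.0,
                                  tumor_fraction_range=(0.8, 0.8))
        truth = make_truth(cfg)
        cgh = simulate_cgh(cfg, truth)
        deleted = truth.deletion_mask("probes")
        for sid, grp in cgh.groupby("sample_id"):
            called = call_probes(grp).set_index("probe_id")
            expected = deleted[sid].loc[called.index]
            assert ((called["call"] == "loss") == expected).all()


class TestCumulativeFrequency:
    def test_uniform_loss_reaches_one(self):
        profs = [call_probes(_profile([-1.0] * 4)) for _ in range(4)]
        track = cumulative_frequency(profs)
        assert (track["frac_loss"] == 1.0).all()
        assert (track["frac_gain"] == 0.0).all()

    def test_empty_group_is_error(self):
        with pytest.raises(ValueError):
            cumulative_frequency([])

    def test_matches_per_column_mean_oracle(self):
        rng = np.random.default_rng(1)
        profs = [call_probes(_profile(rng.normal(0, 0.4, 30))) for _ in range(7)]
        track = cumulative_frequency(profs)
        calls = np.vstack([p["call"].to_numpy() for p in profs])
        np.testing.assert_allclose(track["frac_loss"], (calls == "loss").mean(axis=0))
        np.testing.assert_allclose(track["frac_gain"], (calls == "gain").mean(axis=0))
        assert (track["frac_gain"] + track["frac_loss"] <= 1.0 + 1e-12).all()


class TestCommonRegionOverlap:
    def test_single_sample_runs_verbatim(self):
        ratios = [0, -1, -1, 0, -1, 0]
        regions = common_region_overlap([call_probes(_profile(ratios))])
        assert regions[["start", "end"]].to_numpy().tolist() == [[10, 30], [40, 50]]

    def test_two_sample_interval_intersection(self):
        # loss runs [10,50) and [30,80) on a 10-probe grid -> [30,50)
        a = [0, -1, -1, -1, -1, 0, 0, 0, 0, 0]
        b = [0, 0, 0, -1, -1, -1, -1, -1, 0, 0]
        regions = common_region_overlap([call_probes(_profile(a)),
                                         call_probes(_profile(b))])
        assert regions[["start", "end"]].to_numpy().tolist() == [[30, 50]]

    def test_no_shared_loss_gives_empty_set(self):
        a, b = [-1, 0], [0, -1]
        regions = common_region_overlap([call_probes(_profile(a)),
                                         call_probes(_profile(b))])
        assert len(regions) == 0

    def test_adding_a_sample_never_grows_the_region(self):
        rng = np.random.default_rng(2)
        profs = [call_probes(_profile(rng.normal(-0.3, 0.3, 40))) for _ in range(4)]

        def as_set(regions):
            return {(r.chromosome, s) for r in regions.itertuples()
                    for s in range(r.start, r.end, 10)}

        base = as_set(common_region_overlap(profs[:3]))
        extended = as_set(common_region_overlap(profs))
        assert extended <= base

    def test_neutral_probe_breaks_run_unless_gap_tolerated(self):
        ratios = [-1, -1, 0, -1, -1]
        prof = call_probes(_profile(ratios))
        strict = common_region_overlap([prof])
        assert len(strict) == 2
        tolerant = common_region_overlap([prof], gap_tolerance=1)
        assert tolerant[["start", "end"]].to_numpy().tolist() == [[0, 50]]

    def test_recovers_true_boundaries_on_simulated_cohort(self, small_config):
        cfg = dataclasses.replace(small_config, cgh_noise_sd=0.15,
                                  tumor_fraction_range=(0.7, 0.95))
        truth = make_truth(cfg)
        cgh = simulate_cgh(cfg, truth)
        case_ids = truth.samples.index[truth.samples["group"] == "BRCA2"]
        profs = [call_probes(grp) for sid, grp in cgh.groupby("sample_id")
                 if sid in set(case_ids)]
        found = common_region_overlap(profs)
        spacing = 10_000_000 // 6  # probe spacing in the test genome
        for _, region in truth.regions.iterrows():
            overlapping = found[(found["chromosome"] == region["chromosome"])
                                & (found["end"] > region["start"])
                                & (found["start"] < region["end"])]
            assert len(overlapping) >= 1
            assert abs(overlapping["start"].min() - region["start"]) <= spacing
            assert abs(overlapping["end"].max() - region["end"]) <= spacing


class TestBafImbalance:
    def _track(self, baf, chrom="13"):
        n = len(baf)
        return pd.DataFrame({"chromosome": chrom, "pos": np.arange(n) * 1000,
                             "baf": baf, "is_het": True})

    def test_balanced_hets_unflagged(self):
        assert len(baf_imbalance(self._track([0.5] * 100))) == 0

    def test_window_larger_than_track_single_decision(self):
        flagged = baf_imbalance(self._track([0.9] * 10), window=50)
        assert len(flagged) == 1
        assert len(baf_imbalance(self._track([0.5] * 10), window=50)) == 0

    def test_simulated_deletion_flagged_inside_truth(self, small_config):
        # denser SNP track so windows sit well inside the deleted regions
        genome = tuple((c, b, g, p, 60) for c, b, g, p, _ in small_config.genome)
        cfg = dataclasses.replace(small_config, genome=genome, baf_noise_sd=0.03,
                                  tumor_fraction_range=(0.8, 0.8))
        truth = make_truth(cfg)
        baf = simulate_baf(cfg, truth)
        case = truth.samples.index[truth.samples["group"] == "BRCA2"][0]
        track = baf[baf["sample_id"] == case]
        flagged = baf_imbalance(track, window=10, dev_thr=0.15)
        assert len(flagged) >= len(truth.regions)
        for _, region in truth.regions.iterrows():
            cover = flagged[(flagged["chromosome"] == region["chromosome"])
                            & (flagged["end"] > region["start"])
                            & (flagged["start"] < region["end"])]
            assert len(cover) >= 1
            covered = sum(min(r.end, region["end"]) - max(r.start, region["start"])
                          for r in cover.itertuples())
            assert covered >= 0.6 * (region["end"] - region["start"])
        # no flagged region falls entirely outside the truth
        for r in flagged.itertuples():
            hits = truth.regions[(truth.regions["chromosome"] == r.chromosome)
                                 & (truth.regions["end"] > r.start)
                                 & (truth.regions["start"] < r.end)]
            assert len(hits) >= 1
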