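"""Per-run feature extraction: threshold boundaries, trace construction,
deconvolution, isotope grouping, and ground-truth recovery."""

import numpy as np
import pytest

from conftest import make_peak_run
from residomics.features import (Feature, FeatureParams, Tolerance,
                                 build_chromatograms, crop, deconvolve,
                                 detect_masses, duration_filter,
                                 extract_features, group_isotopes,
                                 representatives)
from residomics.io import CentroidRun, CentroidScan, RunMetadata
from residomics.simulate import SimConfig, make_signatures, simulate_run


def scan(index, rt, pairs):
    pairs = sorted(pairs)
    return CentroidScan(index=index, rt=rt,
                        mz=np.array([p[0] for p in pairs]),
                        intensity=np.array([p[1] for p in pairs]))


def run_of(scans, run_id="r"):
    return CentroidRun(metadata=RunMetadata(run_id=run_id), scans=scans)


class TestCrop:
    def test_identity_inside_ranges(self):
        r = run_of([scan(1, 0.5, [(200.0, 1e4)]), scan(2, 0.6, [(300.0, 2e4)])])
        out = crop(r)
        assert len(out.scans) == 2
        assert out.scans[0].n_centroids == 1

    def test_out_of_range_scans_removed(self):
        scans = [scan(i, 0.01 + 0.01 * i, [(500.0, 1e4)]) for i in range(1, 11)]
        # five violations: two scan-index, two RT, one m/z
        scans.append(scan(2000, 5.0, [(500.0, 1e4)]))
        scans.append(scan(2001, 5.1, [(500.0, 1e4)]))
        scans.insert(0, scan(0, 0.001, [(500.0, 1e4)]))
        bad_rt = scan(50, 12.9, [(500.0, 1e4)])
        bad_mz = scan(60, 6.0, [(50.0, 1e4), (1500.0, 1e4)])
        r = CentroidRun(metadata=RunMetadata(run_id="x"),
                        scans=sorted(scans + [bad_rt, bad_mz], key=lambda s: s.rt))
        out = crop(r)
        kept = [s for s in out.scans]
        assert all(1 <= s.index <= 1130 and 0.01 <= s.rt <= 12.51 for s in kept)
        assert sum(s.n_centroids for s in kept) == 10  # bad_mz emptied

    def test_inverted_range_rejected(self):
        r = run_of([scan(1, 0.5, [(200.0, 1e4)])])
        with pytest.raises(ValueError, match="inverted"):
            crop(r, rt_range=(10.0, 1.0))

    def test_idempotent(self):
        r = run_of([scan(1, 0.5, [(200.0, 1e4)]), scan(2000, 13.0, [(300.0, 1e4)])])
        once = crop(r)
        twice = crop(once)
        assert [s.index for s in once.scans] == [s.index for s in twice.scans]


class TestDetectMasses:
    def test_zero_level_identity(self):
        s = scan(1, 0.5, [(200.0, 10.0), (300.0, 1e5)])
        assert detect_masses(s, 0.0).n_centroids == 2

    def test_boundary_inclusive(self):
        s = scan(1, 0.5, [(200.0, 599.0), (300.0, 601.0), (400.0, 600.0)])
        out = detect_masses(s, 600.0)
        assert out.mz.tolist() == [300.0, 400.0]

    def test_empty_scan(self):
        s = CentroidScan(1, 0.5, np.empty(0), np.empty(0))
        assert detect_masses(s, 600.0).n_centroids == 0

    def test_idempotent(self):
        s = scan(1, 0.5, [(200.0, 599.0), (300.0, 601.0)])
        once = detect_masses(s, 600.0)
        twice = detect_masses(once, 600.0)
        assert once.mz.tolist() == twice.mz.tolist()


class TestBuildChromatograms:
    def test_single_planted_peak_single_trace(self):
        r = make_peak_run([(400.0, 5.0, 2e4)])
        traces = build_chromatograms(r)
        assert len(traces) == 1
        assert traces[0].representative_mz == pytest.approx(400.0, abs=1e-6)

    def test_close_compounds_not_merged(self):
        # 0.1 Th apart is 10x the 0.01 Th tolerance: two traces
        r = make_peak_run([(400.0, 5.0, 2e4), (400.1, 5.0, 2e4)])
        traces = build_chromatograms(r)
        assert len(traces) == 2

    def test_single_scan_spike_dropped(self):
        scans = [scan(1, 1.0, [(400.0, 2e4)]), scan(2, 1.011, []),
                 scan(3, 1.022, [])]
        traces = build_chromatograms(run_of(scans))
        assert traces == []

    def test_min_height_filter(self):
        r = make_peak_run([(400.0, 5.0, 4.9e3)])
        assert build_chromatograms(r, min_height=5e3) == []
        assert len(build_chromatograms(r, min_height=4e3)) == 1


class TestDeconvolve:
    def trace_from(self, rts, intens, mz=400.0):
        from residomics.features import Trace
        rts = np.asarray(rts, dtype=float)
        intens = np.asarray(intens, dtype=float)
        return Trace(scan_index=np.arange(1, len(rts) + 1), rt=rts,
                     mz=np.full(len(rts), mz), intensity=intens)

    def test_bimodal_yields_two_features(self):
        rts = np.arange(0, 0.5, 0.011)
        a = 2e4 * np.exp(-0.5 * ((rts - 0.1) / 0.03) ** 2)
        b = 2e4 * np.exp(-0.5 * ((rts - 0.35) / 0.03) ** 2)
        tr = self.trace_from(rts, a + b)
        feats = deconvolve(tr)
        assert len(feats) == 2
        assert feats[0].rt == pytest.approx(0.1, abs=0.02)
        assert feats[1].rt == pytest.approx(0.35, abs=0.02)

    def test_flat_below_baseline_no_features(self):
        tr = self.trace_from(np.arange(0, 0.3, 0.011), np.full(28, 8e3))
        assert deconvolve(tr) == []

    def test_above_baseline_below_min_height(self):
        rts = np.arange(0, 0.3, 0.011)
        tr = self.trace_from(rts, 9.5e3 * np.exp(-0.5 * ((rts - 0.15) / 0.05) ** 2))
        assert deconvolve(tr) == []

    def test_threshold_sharp_at_min_height(self):
        rts = np.arange(0, 0.3, 0.011)
        shape = np.exp(-0.5 * ((rts - rts[13]) / 0.05) ** 2)
        kept = deconvolve(self.trace_from(rts, 1.0e4 * shape))
        dropped = deconvolve(self.trace_from(rts, 0.99e4 * shape))
        assert len(kept) == 1 and dropped == []

    def test_area_is_trapezoid_integral(self):
        rts = np.arange(0, 0.3, 0.011)
        inten = 2e4 * np.exp(-0.5 * ((rts - 0.15) / 0.05) ** 2)
        feats = deconvolve(self.trace_from(rts, inten))
        mask = inten > 9e3
        expected = np.trapezoid(inten[mask], rts[mask])
        assert feats[0].area == pytest.approx(expected, rel=1e-9)

    def test_duration_range_enforced(self):
        rts = np.arange(0, 3.0, 0.011)
        tr = self.trace_from(rts, np.full(len(rts), 2e4))  # 3-min plateau
        assert deconvolve(tr, duration_range=(0.0, 2.0)) == []


class TestDurationFilter:
    def test_inside_identity(self):
        feats = [Feature(400.0, rt, 2e4, 1.0) for rt in (0.5, 6.0, 11.9)]
        assert duration_filter(feats) == feats

    def test_outside_removed(self):
        feats = [Feature(400.0, 12.3, 2e4, 1.0), Feature(400.0, 6.0, 2e4, 1.0)]
        out = duration_filter(feats, (0.01, 12.01))
        assert [f.rt for f in out] == [6.0]

    def test_empty(self):
        assert duration_filter([]) == []

    def test_idempotent(self):
        feats = [Feature(400.0, 12.3, 2e4, 1.0), Feature(400.0, 6.0, 2e4, 1.0)]
        once = duration_filter(feats)
        assert duration_filter(once) == once


class TestGroupIsotopes:
    def test_a0_a1_pair_grouped(self):
        a0 = Feature(400.0, 5.0, 1e5, 1.0)
        a1 = Feature(401.0034, 5.01, 1.1e4, 1.0)
        out = group_isotopes([a0, a1])
        groups = {f.group for f in out}
        assert len(groups) == 1
        rep = [f for f in out if f.representative]
        assert len(rep) == 1 and rep[0].mz == 400.0
        assert rep[0].charge == 1

    def test_unrelated_features_singletons(self):
        f1 = Feature(400.0, 5.0, 1e5, 1.0)
        f2 = Feature(405.0, 5.0, 1e5, 1.0)
        out = group_isotopes([f1, f2])
        assert len({f.group for f in out}) == 2
        assert all(f.representative for f in out)

    def test_monotonic_shape_blocks_rising_ladder(self):
        a0 = Feature(400.0, 5.0, 1.1e4, 1.0)
        a1 = Feature(401.0034, 5.01, 1e5, 1.0)  # taller than A+0
        out = group_isotopes([a0, a1], monotonic=True)
        assert len({f.group for f in out}) == 2

    def test_conservation(self):
        rng = np.random.default_rng(0)
        feats = [Feature(float(mz), float(rt), float(h), 1.0)
                 for mz, rt, h in zip(rng.uniform(100, 1200, 40),
                                      rng.uniform(1, 12, 40),
                                      rng.uniform(1e4, 1e6, 40))]
        out = group_isotopes(feats)
        assert len(out) == len(feats)
        assert sorted(f.mz for f in out) == sorted(f.mz for f in feats)
        # exactly one representative per group
        import collections
        per_group = collections.Counter(f.group for f in out if f.representative)
        assert set(per_group.values()) == {1}

    def test_rt_tolerance_blocks_distant_pair(self):
        a0 = Feature(400.0, 5.0, 1e5, 1.0)
        a1 = Feature(401.0034, 5.2, 1.1e4, 1.0)  # 0.2 min apart
        out = group_isotopes([a0, a1], rt_tol=0.05)
        assert len({f.group for f in out}) == 2


class TestRecovery:
    def test_planted_peaks_recovered_one_to_one(self):
        # moderate noise (2 ppm, 0.01 min) well inside half the tolerances
        cfg = SimConfig(species=("NQU", "RGL"), compounds_per_species=25,
                        replicates=1, mz_error_ppm=2.0, rt_jitter_sd=0.01,
                        abundance_log10_mean=5.5, abundance_log10_sd=0.15,
                        mixtures={}, seed=21)
        sig = make_signatures(cfg)
        run, truth = simulate_run("QC_NQU_TA", {"NQU": 1.0}, "TA", sig, cfg)
        reps = representatives(extract_features(run, FeatureParams()))
        truth = truth[truth["height"] >= 1.2e4]  # clear of the 1e4 threshold
        matched = 0
        used = set()
        for t in truth.itertuples():
            cands = [i for i, f in enumerate(reps)
                     if i not in used
                     and abs(f.mz - t.mz) <= 10e-6 * t.mz
                     and abs(f.rt - t.rt) <= 0.05]
            if cands:
                used.add(cands[0])
                matched += 1
        assert matched == len(truth)

    def test_extract_features_representatives_subset(self):
        r = make_peak_run([(400.0, 5.0, 2e4), (500.0, 6.0, 5e4)])
        feats = extract_features(r, FeatureParams())
        reps = representatives(feats)
        assert len(reps) == 2
        assert all(f in feats for f in reps)
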