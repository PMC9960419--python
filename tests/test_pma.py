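import numpy as np
import pandas as pd
import pytest

from oriscan import mutcontext as mc
from oriscan import pma
from oriscan.genome import GenomeIndex
from oriscan.pma import PmaConfig, PmaTrack


def make_track(n_bins=300, bin_size=1000):
    z = lambda: np.zeros(n_bins, dtype=np.int64)
    return PmaTrack("chr1", bin_size, z(), z(), z())


def brute_force_pma(track, n, d):
    """Direct double-loop evaluation of the windowed score at bin n."""
    lo, hi = max(n - d, 0), min(n + d + 1, track.n_bins)
    ul = sum(track.lead[i] for i in range(lo, n))
    ug = sum(track.lag[i] for i in range(lo, n))
    dl = sum(track.lead[i] for i in range(n, hi))
    dg = sum(track.lag[i] for i in range(n, hi))
    w = sum(track.total[i] for i in range(lo, hi))
    if w == 0:
        return np.nan
    return 4.0 / w**2 * (ul * dg - ug * dl)


class TestPmaScore:
    def test_ideal_on_target_is_one(self):
        t = make_track()
        c, d = 150, 100
        t.lead[c - 50:c] = 1
        t.lag[c:c + 50] = 1
        t.total = t.lead + t.lag
        assert pma.pma_profile(t, d)[c] == pytest.approx(1.0)

    def test_ideal_reversed_is_minus_one(self):
        t = make_track()
        c, d = 150, 100
        t.lag[c - 50:c] = 1
        t.lead[c:c + 50] = 1
        t.total = t.lead + t.lag
        assert pma.pma_profile(t, d)[c] == pytest.approx(-1.0)

    def test_hand_worked_example(self):
        # upstream lead=3 lag=1, downstream lead=1 lag=3, W=8 -> 0.5
        t = make_track()
        c, d = 150, 100
        t.lead[c - 10] = 3
        t.lag[c - 20] = 1
        t.lead[c + 10] = 1
        t.lag[c + 20] = 3
        t.total = t.lead + t.lag
        assert pma.pma_profile(t, d)[c] == pytest.approx(
            4 / 64 * (3 * 3 - 1 * 1))

    def test_empty_window_masked_not_zero(self):
        t = make_track()
        assert np.isnan(pma.pma_profile(t, 100)[150])

    def test_prefix_sums_equal_brute_force(self, rng):
        t = make_track(n_bins=120)
        t.lead = rng.integers(0, 4, 120)
        t.lag = rng.integers(0, 4, 120)
        t.total = t.lead + t.lag + rng.integers(0, 3, 120)
        d = 25
        prof = pma.pma_profile(t, d, min_coverage=0.0)
        for n in range(120):
            expect = brute_force_pma(t, n, d)
            if np.isnan(expect):
                assert np.isnan(prof[n])
            else:
                assert prof[n] == pytest.approx(expect)

    def test_bounded_in_unit_interval(self, rng):
        for _ in range(20):
            t = make_track(n_bins=80)
            t.lead = rng.integers(0, 5, 80)
            t.lag = rng.integers(0, 5, 80)
            t.total = t.lead + t.lag + rng.integers(0, 5, 80)
            prof = pma.pma_profile(t, 20, min_coverage=0.0)
            ok = ~np.isnan(prof)
            assert np.all(prof[ok] >= -1.0) and np.all(prof[ok] <= 1.0)

    def test_lead_lag_swap_negates(self, rng):
        t = make_track(n_bins=100)
        t.lead = rng.integers(0, 5, 100)
        t.lag = rng.integers(0, 5, 100)
        t.total = t.lead + t.lag
        swapped = PmaTrack("chr1", 1000, t.lag.copy(), t.lead.copy(),
                           t.total.copy())
        a = pma.pma_profile(t, 30, min_coverage=0.0)
        b = pma.pma_profile(swapped, 30, min_coverage=0.0)
        np.testing.assert_allclose(a, -b)


class TestSmooth:
    def test_constant_unchanged(self):
        v = np.full(50, 0.7)
        np.testing.assert_allclose(pma.smooth(v, 5), v)

    def test_centered_average(self):
        v = np.array([0.0, 0, 10, 0, 0])
        assert pma.smooth(v, 5)[2] == pytest.approx(2.0)

    def test_all_masked_stays_masked(self):
        v = np.full(20, np.nan)
        assert np.all(np.isnan(pma.smooth(v, 5)))

    def test_masked_bins_excluded_from_average(self):
        v = np.array([1.0, np.nan, 3.0])
        assert pma.smooth(v, 3)[1] == pytest.approx(2.0)


class TestPickPeaks:
    def test_single_bump(self):
        v = np.zeros(1000)
        v[450:551] = 0.4 - np.abs(np.arange(-50, 51)) * 0.004
        assert list(pma.pick_peaks(v, 100, 0.1)) == [500]

    def test_close_bumps_merge_to_higher(self):
        v = np.zeros(1000)
        v[480] = 0.3
        v[530] = 0.5  # 50 bins apart < neighlim
        assert list(pma.pick_peaks(v, 100, 0.1)) == [530]

    def test_below_threshold_dropped(self):
        v = np.zeros(1000)
        v[500] = 0.05
        assert len(pma.pick_peaks(v, 100, 0.1)) == 0

    def test_output_spacing_invariant(self, rng):
        for _ in range(10):
            v = rng.random(2000)
            peaks = pma.pick_peaks(v, 50, 0.0)
            if len(peaks) > 1:
                assert np.min(np.diff(peaks)) >= 50


class TestFisherFilter:
    def test_exact_p_for_5_0_0_5(self):
        from scipy.stats import fisher_exact
        p = fisher_exact([[5, 0], [0, 5]], alternative="two-sided")[1]
        assert p == pytest.approx(2 / 252)

    def test_balanced_table_filtered_out(self):
        t = make_track()
        t.lead[140] = 1
        t.lag[145] = 1
        t.lead[155] = 1
        t.lag[160] = 1
        t.total = t.lead + t.lag
        t.pma_raw = pma.pma_profile(t, 100, min_coverage=0.0)
        calls = pma.fisher_filter([("chr1", 150)], {"chr1": t}, 100, alpha=0.01)
        assert calls == []

    def test_bh_retains_uniformly_small_p(self):
        from statsmodels.stats.multitest import multipletests
        q = multipletests(np.full(100, 0.001), method="fdr_bh")[1]
        assert np.all(q < 0.01)

    def test_strong_asymmetry_survives(self):
        t = make_track()
        c = 150
        t.lead[c - 50:c - 30] = 1
        t.lag[c + 30:c + 50] = 1
        t.total = t.lead + t.lag
        t.pma_raw = pma.pma_profile(t, 100, min_coverage=0.0)
        calls = pma.fisher_filter([("chr1", c)], {"chr1": t}, 100, alpha=0.01)
        assert len(calls) == 1
        assert calls[0].position == c * 1000 + 500
        assert calls[0].n_support == 40


class TestClassProfileAndClustering:
    def test_single_class_ideal_asymmetry(self, make_rec):
        ori = [("chr1", 200_000)]
        recs = [make_rec(pos=200_000 - 50_000 + i * 100, obs="TCT>TAT")
                for i in range(50)]
        recs += [make_rec(pos=200_000 + i * 100, obs="AGA>ATA")
                 for i in range(50)]
        prof = pma.class_pma_profile(recs, ori, top_k=10)
        assert prof.values.loc["S1", "TCT>TAT"] == pytest.approx(1.0)
        others = prof.values.drop(columns=["TCT>TAT"])
        assert others.isna().all().all()

    def test_symmetric_class_near_zero(self, rng, make_rec):
        ori = [("chr1", 200_000)]
        recs = []
        for i in range(2000):
            pos = int(200_000 + rng.integers(-90_000, 90_000))
            obs = "ACA>AGA" if rng.random() < 0.5 else mc.revcomp_class("ACA>AGA")
            recs.append(make_rec(pos=pos, obs=obs))
        prof = pma.class_pma_profile(recs, ori, top_k=10)
        assert abs(prof.values.loc["S1", "ACA>AGA"]) < 0.1

    def test_cluster_sign_flip_swaps_labels(self):
        cols = [mc.ca_representative(c) for c in mc.canonical_classes()[:6]]
        base = np.array([[0.8, 0.7, -0.8, -0.7, 0.0, 0.05]] * 4)
        df = pd.DataFrame(base, index=list("wxyz"), columns=cols)
        up = pma.cluster_classes(pma.ClassPmaProfile(df), k=3)
        down = pma.cluster_classes(pma.ClassPmaProfile(-df), k=3)
        assert set(up["A"]) == set(down["B"])
        assert set(up["B"]) == set(down["A"])
        assert set(up["other"]) == set(down["other"])

    def test_single_column_profile_rejected(self):
        df = pd.DataFrame({"TCT>TAT": [0.5, 0.6]}, index=["a", "b"])
        with pytest.raises(ValueError):
            pma.cluster_classes(pma.ClassPmaProfile(df))


class TestDetectMori:
    def test_single_ideal_origin_single_call(self, make_rec):
        index = GenomeIndex({"chr1": 1_000_000})
        ori = 500_000
        recs = []
        for i in range(200):
            recs.append(make_rec(pos=ori - (i + 1) * 400, obs="TCT>TAT"))
            recs.append(make_rec(pos=ori + i * 400, obs="AGA>ATA"))
        calls, _ = pma.detect_from_scheme(recs, mc.stage1_scheme(), index,
                                          PmaConfig())
        assert len(calls) == 1
        assert abs(calls[0].position - ori) <= 2000

    def test_no_records_rejected(self, small_index):
        with pytest.raises(ValueError):
            pma.detect_mori([], small_index)

    def test_no_selected_samples_rejected(self, small_index, make_rec):
        recs = [make_rec(pos=i * 100, obs="ACA>AGA") for i in range(100)]
        with pytest.raises(ValueError, match="fraction"):
            pma.detect_mori(recs, small_index)
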