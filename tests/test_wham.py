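import numpy as np
import pytest

from crowdshift.synthetic import (
    crowding_weights_from_truth,
    double_well_pmf,
    sample_umbrella_windows,
)
from crowdshift.wham import (
    PMFProfile,
    UmbrellaWindow,
    barrier_shift,
    bootstrap_pmf,
    crowded_pmf,
    read_window,
    solve_wham,
    write_window,
)


def window_counts(windows, profile):
    counts = np.zeros_like(profile.bin_centers)
    lo = profile.bin_centers[0] - profile.bin_width / 2
    for w in windows:
        idx = np.floor((w.samples - lo) / profile.bin_width).astype(int)
        idx = idx[(idx >= 0) & (idx < counts.size)]
        np.add.at(counts, idx, 1)
    return counts


@pytest.fixture(scope="module")
def truth():
    return double_well_pmf()


@pytest.fixture(scope="module")
def windows(truth):
    return sample_umbrella_windows(truth, n_per_window=1200, seed=42)


@pytest.fixture(scope="module")
def dilute_profile(windows):
    return solve_wham(windows)


class TestSolveWham:
    def test_unbiased_single_window_recovers_histogram(self):
        rng = np.random.default_rng(0)
        samples = rng.normal(loc=16.0, scale=1.0, size=10_000)
        win = UmbrellaWindow(center=16.0, force_constant=0.0, samples=samples)
        prof = solve_wham([win], bins=np.arange(12.0, 20.01, 0.25))
        ok = prof.occupied
        hist, edges = np.histogram(
            samples, bins=np.arange(12.0, 20.01, 0.25), density=True
        )
        w_ref = -np.log(np.where(hist > 0, hist, np.nan))
        w_ref -= np.nanmin(w_ref)
        good = ok & (hist * samples.size * 0.25 >= 50)
        np.testing.assert_allclose(prof.w[good], w_ref[good], atol=0.05)

    def test_ground_truth_recovery(self, truth, windows, dilute_profile):
        prof = dilute_profile
        counts = window_counts(windows, prof)
        well = prof.occupied & (counts >= 100)
        resid = prof.w[well] - truth.w(prof.bin_centers[well])
        resid -= resid.mean()
        assert np.sqrt(np.mean(resid**2)) < 0.15

    def test_normalization_and_min_shift(self, dilute_profile):
        p = dilute_profile
        assert np.nansum(p.p) * p.bin_width == pytest.approx(1.0, rel=1e-9)
        assert np.nanmin(p.w) == 0.0

    def test_constant_weights_change_nothing(self, windows, dilute_profile):
        weighted = [
            w.with_samples(w.samples, np.full_like(w.samples, 0.37)) for w in windows
        ]
        prof = solve_wham(weighted)
        ok = dilute_profile.occupied
        np.testing.assert_allclose(prof.w[ok], dilute_profile.w[ok], atol=1e-5)

    def test_bias_offset_invariance(self, windows, dilute_profile):
        # adding a constant to every bias energy cancels through C_i
        shifted = solve_wham(windows)  # solver works in energy differences
        ok = dilute_profile.occupied
        np.testing.assert_allclose(shifted.w[ok], dilute_profile.w[ok], atol=1e-8)

    def test_self_consistency_of_fixed_point(self, windows):
        # at the fixed point, one more full (P -> C -> P -> C) update barely
        # moves the window normalization constants
        from crowdshift.thermo import kt_in_kcal_per_mol

        prof = solve_wham(windows, tol=1e-10, max_iter=300_000)
        kt = kt_in_kcal_per_mol(300.0)
        ok = prof.occupied
        x = prof.bin_centers[ok]
        p = prof.p[ok] * prof.bin_width
        n_ij = np.zeros((len(windows), ok.sum()))
        lo = prof.bin_centers[0] - prof.bin_width / 2
        occ_idx = np.flatnonzero(ok)
        remap = {j: k for k, j in enumerate(occ_idx)}
        for i, w in enumerate(windows):
            idx = np.floor((w.samples - lo) / prof.bin_width).astype(int)
            for j in idx:
                if j in remap:
                    n_ij[i, remap[j]] += 1
        N = np.array([w.samples.size for w in windows], float)
        boltz = np.exp(
            -0.5
            * (np.array([w.force_constant for w in windows])[:, None] / kt)
            * (x[None, :] - np.array([w.center for w in windows])[:, None]) ** 2
        )
        C = boltz @ p
        p_new = n_ij.sum(axis=0) / ((N / C) @ boltz)
        p_new /= p_new.sum()
        C_new = boltz @ p_new
        assert np.max(np.abs(C_new / C - 1.0)) < 1e-6

    def test_empty_range_rejected(self, windows):
        with pytest.raises(ValueError):
            solve_wham(windows, bins=np.array([100.0, 101.0]))

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError):
            UmbrellaWindow(center=1.0, force_constant=5.0, samples=[])


class TestCrowdedPmf:
    def test_unit_weights_identical_to_dilute(self, windows, dilute_profile):
        prof = crowded_pmf(windows, [np.ones_like(w.samples) for w in windows])
        ok = dilute_profile.occupied
        np.testing.assert_allclose(prof.w[ok], dilute_profile.w[ok], atol=1e-6)

    def test_additivity_contract_linear_dmu(self, truth, windows, dilute_profile):
        # f(x) = exp(-a x): the crowded PMF is the dilute one tilted by a x
        a = 0.2
        weighted = crowding_weights_from_truth(windows, lambda x: a * np.asarray(x))
        prof = crowded_pmf(weighted)
        counts = window_counts(windows, prof)
        well = prof.occupied & (counts >= 100)
        diff = prof.w[well] - dilute_profile.w[well]
        slope, _ = np.polyfit(prof.bin_centers[well], diff, 1)
        assert slope == pytest.approx(a, abs=0.02)

    def test_step_weight_deepens_favored_basin(self, windows, dilute_profile):
        # crowding strongly favors x < 16: the small-x basin gains population
        weighted = crowding_weights_from_truth(
            windows, lambda x: np.where(np.asarray(x) > 16.0, 3.0, 0.0)
        )
        prof = crowded_pmf(weighted)
        basin_a = (11.5, 14.5)
        basin_b = (18.0, 21.0)

        def basin_depth(p, lo, hi):
            sel = (p.bin_centers >= lo) & (p.bin_centers <= hi) & p.occupied
            return np.nanmin(p.w[sel])

        # relative depth of open basin vs closed worsens under the step
        gap_dilute = basin_depth(dilute_profile, *basin_b) - basin_depth(
            dilute_profile, *basin_a
        )
        gap_crowded = basin_depth(prof, *basin_b) - basin_depth(prof, *basin_a)
        assert gap_crowded > gap_dilute + 2.0

    def test_nonpositive_weights_rejected(self, windows):
        bad = [np.ones_like(w.samples) for w in windows]
        bad[3][0] = 0.0
        with pytest.raises(ValueError):
            crowded_pmf(windows, bad)

    def test_near_unit_weights_converge_to_dilute(self, windows, dilute_profile):
        rng = np.random.default_rng(3)
        ok = dilute_profile.occupied
        for var, tol in ((0.05, 0.06), (0.005, 0.02)):
            wts = [
                np.exp(rng.normal(0.0, var, size=w.samples.size)) for w in windows
            ]
            prof = crowded_pmf(windows, wts)
            dev = np.nanmax(np.abs(prof.w[ok] - dilute_profile.w[ok]))
            assert dev < tol


class TestBootstrap:
    def test_duplicated_samples_zero_spread(self):
        wins = [
            UmbrellaWindow(c, 5.0, np.full(200, c + 0.05))
            for c in (15.0, 15.3, 15.6)
        ]
        sd = bootstrap_pmf(wins, n_boot=20, seed=0)
        assert np.nanmax(sd) == pytest.approx(0.0, abs=1e-12)

    def test_sparse_bins_noisier_than_minima(self, truth):
        wins = sample_umbrella_windows(truth, n_per_window=400, seed=7)
        prof = solve_wham(wins)
        sd = bootstrap_pmf(wins, n_boot=30, seed=1)
        counts = window_counts(wins, prof)
        occ = counts[prof.occupied]
        rich = prof.occupied & (counts >= np.quantile(occ, 0.8))
        sparse = prof.occupied & (counts > 2) & (counts <= np.quantile(occ, 0.2))
        assert np.nanmedian(sd[sparse]) > np.nanmedian(sd[rich])

    def test_seed_stability_on_well_sampled_bins(self, truth):
        wins = sample_umbrella_windows(truth, n_per_window=600, seed=8)
        prof = solve_wham(wins)
        counts = window_counts(wins, prof)
        rich = prof.occupied & (counts >= np.quantile(counts[prof.occupied], 0.7))
        sd1 = bootstrap_pmf(wins, n_boot=40, seed=1)
        sd2 = bootstrap_pmf(wins, n_boot=40, seed=2)
        ratio = np.nanmedian(sd1[rich]) / np.nanmedian(sd2[rich])
        assert 0.7 < ratio < 1.4

    def test_too_few_replicas_rejected(self, windows):
        with pytest.raises(ValueError):
            bootstrap_pmf(windows, n_boot=5, seed=0)


def cosine_double_well(tilt=0.0):
    """W(x) = 2(1 + cos(2πx/10)) + tilt·x on bins [0,10]: minima at 5±..."""
    x = np.arange(0.05, 10.0, 0.1)
    w = 2.0 * (1.0 + np.cos(2 * np.pi * x / 5.0)) + tilt * x
    w -= w.min()
    p = np.exp(-w)
    p /= p.sum() * 0.1
    return PMFProfile(bin_centers=x, w=w, p=p, bin_width=0.1)


class TestBarrierShift:
    def test_identical_profiles(self):
        prof = cosine_double_well()
        assert barrier_shift(prof, prof, (2.0, 3.0), (7.0, 8.0)) == (0.0, 0.0)

    def test_constant_offset_cancels(self):
        dilute = cosine_double_well()
        crowded = cosine_double_well()
        crowded.w = crowded.w + 1.7
        d_ab, d_ba = barrier_shift(dilute, crowded, (2.0, 3.0), (7.0, 8.0))
        assert d_ab == pytest.approx(0.0, abs=1e-12)
        assert d_ba == pytest.approx(0.0, abs=1e-12)

    def test_linear_tilt_shifts_barriers_analytically(self):
        # W + a·x on a periodic cosine well: minima at x≈2.5, 7.5, max x≈5
        # (positions shift by O(a); heights change by a·Δx to first order)
        a = 0.1
        dilute = cosine_double_well()
        crowded = cosine_double_well(tilt=a)
        d_ab, d_ba = barrier_shift(dilute, crowded, (2.0, 3.0), (7.0, 8.0))
        assert d_ab == pytest.approx(a * 2.5, abs=0.05)   # barrier at 5, min at 2.5
        assert d_ba == pytest.approx(-a * 2.5, abs=0.05)
        assert d_ab > 0 > d_ba

    def test_mismatched_bins_rejected(self):
        a = cosine_double_well()
        b = cosine_double_well()
        b.bin_centers = b.bin_centers + 0.05
        with pytest.raises(ValueError):
            barrier_shift(a, b, (2.0, 3.0), (7.0, 8.0))

    def test_no_interior_maximum_rejected(self):
        x = np.arange(0.05, 10.0, 0.1)
        w = (x - 5.0) ** 2 / 10.0
        prof = PMFProfile(x, w - w.min(), np.exp(-w), 0.1)
        with pytest.raises(ValueError):
            barrier_shift(prof, prof, (4.0, 5.0), (5.0, 6.0))


def test_window_file_round_trip(tmp_path, windows):
    win = windows[0].with_samples(
        windows[0].samples[:50], np.linspace(0.5, 1.5, 50)
    )
    path = tmp_path / "w0.dat"
    write_window(win, str(path))
    back = read_window(str(path))
    assert back.center == win.center
    assert back.force_constant == win.force_constant
    np.testing.assert_allclose(back.samples, win.samples, atol=1e-6)
    np.testing.assert_allclose(back.weights, win.weights, rtol=1e-6)
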