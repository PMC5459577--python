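"""Exponential fitting: recovery, oracles, selection and aggregation."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from switchsim import (
    FitError,
    FitResult,
    TimeTrace,
    aggregate_motif_rates,
    estimate_noise,
    fit_biexp,
    fit_monoexp,
    select_model,
)
from switchsim.synth import TraceSpec, generate_nmr_trace


class TestEstimateNoise:
    def test_noiseless_exponential_gives_near_zero(self):
        # dense sampling so the curvature term is below the threshold
        t = np.linspace(0, 600, 1_000_000)
        trace = TimeTrace(times=t, intensities=np.exp(-0.01 * t))
        assert estimate_noise(trace) < 1e-10 * 1.0

    def test_known_gaussian_noise_recovered(self, rng):
        y = 1.0 + rng.normal(0, 0.05, size=200)
        trace = TimeTrace(times=np.arange(200.0), intensities=y)
        assert 0.04 < estimate_noise(trace) < 0.06

    def test_explicit_sigma_passes_through(self):
        trace = TimeTrace(times=np.arange(8.0), intensities=np.ones(8), sigma=0.123)
        assert estimate_noise(trace) == 0.123

    def test_too_few_points_rejected(self):
        with pytest.raises(FitError):
            estimate_noise(TimeTrace(times=np.arange(3.0), intensities=np.ones(3)))


class TestMonoexp:
    def test_noiseless_recovery_to_1e6(self):
        spec = TraceSpec(order=1, amplitudes=(1.0,), rates=(0.01,), t_max=600, n_points=60, noise_sd=0.0)
        fit = fit_monoexp(generate_nmr_trace(spec))
        assert fit.rates[0] == pytest.approx(0.01, abs=1e-6)
        assert fit.amplitudes[0] == pytest.approx(1.0, rel=1e-6)

    def test_matches_exhaustive_grid_search(self, rng):
        """Brute-force (A, k) grid oracle agrees to grid resolution."""
        k_true, a_true = 0.05, 1.3
        t = np.linspace(0, 100, 60)
        y = a_true * np.exp(-k_true * t) + rng.normal(0, 0.05, t.size)
        a_grid = np.linspace(0.5, 2.0, 400)
        k_grid = np.linspace(0.005, 0.5, 400)
        e = np.exp(-np.outer(k_grid, t))  # (nk, nt)
        # rss(a, k) minimised over the grid
        best = (np.inf, None, None)
        for i, k in enumerate(k_grid):
            r = y[None, :] - a_grid[:, None] * e[i][None, :]
            rss = np.sum(r * r, axis=1)
            j = int(np.argmin(rss))
            if rss[j] < best[0]:
                best = (rss[j], a_grid[j], k)
        fit = fit_monoexp(TimeTrace(times=t, intensities=y), fit_plateau=False)
        assert abs(fit.rates[0] - best[2]) <= (k_grid[1] - k_grid[0])
        assert abs(fit.amplitudes[0] - best[1]) <= (a_grid[1] - a_grid[0])

    def test_rise_traces_fit_with_negative_amplitude(self):
        spec = TraceSpec(order=1, plateau=1.0, amplitudes=(-1.0,), rates=(0.1,), t_max=60, n_points=40, noise_sd=0.0)
        fit = fit_monoexp(generate_nmr_trace(spec))
        assert fit.rates[0] == pytest.approx(0.1, rel=1e-6)
        assert fit.amplitudes[0] == pytest.approx(-1.0, rel=1e-6)

    def test_too_few_points_rejected(self):
        with pytest.raises(FitError):
            fit_monoexp(TimeTrace(times=np.arange(5.0), intensities=np.exp(-np.arange(5.0))))

    @given(scale=st.floats(1e-6, 1e6))
    def test_scale_equivariance(self, scale):
        """Multiplying intensities scales amplitudes and leaves rates fixed."""
        spec = TraceSpec(order=1, amplitudes=(1.0,), rates=(0.02,), t_max=250, n_points=40, noise_sd=0.02, seed=5)
        base = generate_nmr_trace(spec)
        fit0 = fit_monoexp(base)
        fit1 = fit_monoexp(
            TimeTrace(times=base.times, intensities=base.intensities * scale)
        )
        assert fit1.rates[0] == pytest.approx(fit0.rates[0], rel=1e-10)
        # amplitudes are equivariant up to normalisation round-off
        assert fit1.amplitudes[0] == pytest.approx(fit0.amplitudes[0] * scale, rel=1e-8)


class TestBiexp:
    def test_noiseless_recovery_of_combined_pathway_rates(self):
        """The fast-refolding + rate-limiting-dissociation pair is recovered exactly."""
        spec = TraceSpec(
            order=2, amplitudes=(0.5, 0.5), rates=(2e-2, 1.2e-3),
            t_max=5 / 1.2e-3, n_points=80, noise_sd=0.0,
        )
        fit = fit_biexp(generate_nmr_trace(spec))
        assert fit.rates[0] == pytest.approx(2e-2, rel=1e-4)
        assert fit.rates[1] == pytest.approx(1.2e-3, rel=1e-4)

    def test_zero_second_amplitude_degenerates_to_mono(self):
        spec = TraceSpec(order=1, amplitudes=(1.0,), rates=(0.05,), t_max=100, n_points=60, noise_sd=0.0)
        trace = generate_nmr_trace(spec)
        mono = fit_monoexp(trace)
        bi = fit_biexp(trace)
        dominant = int(np.argmax(np.abs(bi.amplitudes)))
        assert bi.rates[dominant] == pytest.approx(mono.rates[0], abs=1e-6 * mono.rates[0] + 1e-9)

    def test_slow_pair_recovered_within_printed_bands(self):
        """Noisy AT-dissociation traces recover (5e-4, 1.1e-4) on average."""
        k1s, k2s = [], []
        for i in range(60):
            spec = TraceSpec(
                order=2, amplitudes=(0.5, 0.5), rates=(5e-4, 1.1e-4),
                t_max=3 / 1.1e-4, n_points=80, noise_sd=0.02, seed=900 + i,
            )
            fit = fit_biexp(generate_nmr_trace(spec))
            k1s.append(fit.rates[0])
            k2s.append(fit.rates[1])
        assert abs(np.mean(k1s) - 5e-4) < 2e-4
        assert abs(np.mean(k2s) - 1.1e-4) < 0.4e-4

    def test_rates_ordered_fast_first(self):
        spec = TraceSpec(order=2, amplitudes=(0.3, 0.7), rates=(1e-1, 1e-2), t_max=500, n_points=60, noise_sd=0.0)
        fit = fit_biexp(generate_nmr_trace(spec))
        assert fit.rates[0] > fit.rates[1]


class TestSelectModel:
    def test_pure_monoexp_selects_order_one(self):
        spec = TraceSpec(order=1, amplitudes=(1.0,), rates=(0.05,), t_max=100, n_points=60, noise_sd=0.0)
        assert select_model(generate_nmr_trace(spec)).order == 1

    def test_well_separated_biexp_selected(self):
        hits = 0
        for i in range(20):
            spec = TraceSpec(
                order=2, amplitudes=(0.5, 0.5), rates=(1.7e-2, 1e-3),
                t_max=5000, n_points=60, noise_sd=0.05, seed=300 + i,
            )
            hits += select_model(generate_nmr_trace(spec)).order == 2
        assert hits >= 18

    def test_near_degenerate_rates_fall_back_to_mono(self):
        hits = 0
        for i in range(20):
            spec = TraceSpec(
                order=2, amplitudes=(0.5, 0.5), rates=(1.2e-2, 1e-2),
                t_max=500, n_points=60, noise_sd=0.1, seed=600 + i,
            )
            hits += select_model(generate_nmr_trace(spec)).order == 1
        assert hits >= 18

    def test_decision_thresholds_recorded(self):
        spec = TraceSpec(order=1, amplitudes=(1.0,), rates=(0.05,), t_max=100, n_points=60, noise_sd=0.02, seed=1)
        sel = select_model(generate_nmr_trace(spec))
        assert sel.selection["alpha"] == 0.05
        assert sel.selection["min_rate_ratio"] == 3.0
        assert sel.selection["order_chosen"] == sel.order


def _fake_fit(k, motif, signal_id="s"):
    return FitResult(
        order=1,
        plateau=0.0,
        amplitudes=np.array([1.0]),
        rates=np.array([k]),
        stderr_plateau=None,
        stderr_amplitudes=np.array([np.nan]),
        stderr_rates=np.array([np.nan]),
        rss=0.0,
        n_points=20,
        n_varied=3,
        signal_id=signal_id,
        motif=motif,
    )


class TestAggregate:
    def test_mean_and_sd_are_plain_statistics(self):
        fits = [_fake_fit(k, "ligand_binding", f"s{k}") for k in (0.2, 0.24, 0.28)]
        summary = aggregate_motif_rates(fits)["ligand_binding"]
        assert summary.mean_rates[0] == pytest.approx(0.24)
        assert summary.sd_rates[0] == pytest.approx(np.std([0.2, 0.24, 0.28], ddof=1))
        assert summary.n_signals == 3

    def test_single_signal_flagged_with_zero_sd(self):
        summary = aggregate_motif_rates([_fake_fit(0.1, "TH")])["TH"]
        assert summary.mean_rates[0] == pytest.approx(0.1)
        assert summary.sd_rates[0] == 0.0
        assert "single_signal" in summary.flags

    def test_fifty_nine_signal_set_recovers_motif_means(self):
        """A synthetic 59-signal campaign grouped into 4 motifs recovers the truth."""
        motif_truth = {"ligand_binding": 0.24, "PA": 2e-2, "AT": 9e-3, "TH": 0.14}
        counts = {"ligand_binding": 15, "PA": 15, "AT": 15, "TH": 14}  # 59 total
        fits = []
        i = 0
        for motif, k in motif_truth.items():
            for _ in range(counts[motif]):
                spec = TraceSpec(
                    order=1, amplitudes=(1.0,), rates=(k,), t_max=5 / k,
                    n_points=40, noise_sd=0.05, seed=7000 + i, motif=motif,
                    signal_id=f"sig{i}",
                )
                fits.append(fit_monoexp(generate_nmr_trace(spec)))
                i += 1
        assert i == 59
        summaries = aggregate_motif_rates(fits)
        for motif, k in motif_truth.items():
            s = summaries[motif]
            sem = s.sd_rates[0] / np.sqrt(s.n_signals)
            assert abs(s.mean_rates[0] - k) < 2 * sem + 0.02 * k
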