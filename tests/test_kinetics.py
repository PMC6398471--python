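"""Event detection and dwell-time kinetics: construction oracles, truncated
exponential MLE consistency, rate conversions."""

import math

import numpy as np
import pandas as pd
import pytest

import kymoxl as kx
from kymoxl.kinetics import EstimationError
from kymoxl.synth import SimulationConfig, GroundTruthEvents, render_kymograph, simulate_binding_events

DT = 0.13


def kymo_with_blocks(blocks, n_frames=60, n_pixels=40, background=10.0, amp=10.0, dt=DT):
    """Blank kymograph with rectangular events: (first_frame, n_frames, pixel)."""
    data = np.full((n_frames, n_pixels), background)
    for f0, nf, px in blocks:
        data[f0 : f0 + nf, px] += amp
    return kx.Kymograph(data, dt, 0.16)


class TestDetectEvents:
    def test_injected_durations_recovered_exactly(self):
        kymo = kymo_with_blocks([(5, 4, 3), (20, 6, 10), (30, 10, 30)])
        table = kx.detect_events(kymo, noise_sd=1.0, min_frames=3)
        assert sorted(table.events["n_frames"]) == [4, 6, 10]
        assert sorted(table.events["duration_s"]) == pytest.approx(
            [4 * DT, 6 * DT, 10 * DT]
        )

    def test_short_events_excluded_by_three_frame_rule(self):
        kymo = kymo_with_blocks([(5, 2, 3), (20, 5, 10)])
        table = kx.detect_events(kymo, noise_sd=1.0, min_frames=3)
        assert table.events["n_frames"].tolist() == [5]

    def test_blank_noisy_kymograph_empty(self):
        rng = np.random.default_rng(0)
        kymo = kx.Kymograph(rng.normal(10, 1, (200, 50)), DT, 0.16)
        table = kx.detect_events(kymo, intensity_threshold=5.0, min_frames=3)
        assert len(table) == 0

    def test_censoring_flags_at_movie_edges(self):
        kymo = kymo_with_blocks([(0, 5, 3), (55, 5, 10), (20, 5, 20)], n_frames=60)
        ev = kx.detect_events(kymo, noise_sd=1.0).events.sort_values("first_frame")
        assert ev["censored_start"].tolist() == [True, False, False]
        assert ev["censored_end"].tolist() == [False, False, True]

    def test_gap_linking_bridges_single_dark_frame(self):
        data = np.full((30, 20), 10.0)
        data[5:10, 4] += 10.0
        data[11:16, 4] += 10.0  # one dark frame at 10
        kymo = kx.Kymograph(data, DT, 0.16)
        ev = kx.detect_events(kymo, noise_sd=1.0, max_gap=1).events
        assert len(ev) == 1
        assert ev["n_frames"].iloc[0] == 11

    def test_parameter_errors(self):
        kymo = kymo_with_blocks([])
        with pytest.raises(ValueError):
            kx.detect_events(kymo, intensity_threshold=0.0)
        with pytest.raises(ValueError):
            kx.detect_events(kymo_with_blocks([], n_frames=2), min_frames=3)

    def test_noiseless_pipeline_matches_truth_sidecar(self):
        """With a threshold that counts any touched frame, detected frame spans
        equal the truth's frame quantization exactly (no noise)."""
        cfg = SimulationConfig(mt_lengths=(40.0,), duration=20.0, noise_sd=0.0, seed=0)
        # well-separated positions so PSF tails cannot bridge events
        events = pd.DataFrame(
            {
                "mt_id": [0] * 6,
                "position_um": [3.0, 9.0, 15.0, 21.0, 27.0, 33.0],
                "t_on": [0.50, 1.07, 4.00, 7.77, 10.03, 14.99],
                "dwell_s": [0.70, 1.30, 0.52, 2.00, 0.40, 1.11],
            }
        )
        kymo = render_kymograph(GroundTruthEvents(events, cfg), cfg)
        # threshold barely above background: any positive-overlap frame counts
        detected = kx.detect_events(
            kymo, intensity_threshold=1.0, noise_sd=1e-9, min_frames=1
        ).events
        expected = sorted(
            int((ev.t_on + ev.dwell_s) // DT) - int(ev.t_on // DT) + 1
            for ev in events.itertuples()
        )
        assert sorted(detected["n_frames"]) == expected


class TestDwellFit:
    def test_constant_durations_continuous_mle(self):
        durations = np.full(20, 0.39 + 0.5)
        fit = kx.fit_dwell_distribution(durations, t_min=0.39, n_boot=10)
        assert fit.tau == pytest.approx(0.5)

    def test_truncated_mle_consistency_vs_grid_search(self):
        rng = np.random.default_rng(1)
        tau_true = 0.625
        t = rng.exponential(tau_true, 100_000)
        t = t[t >= 0.39][:50_000] if (t >= 0.39).sum() >= 50_000 else t[t >= 0.39]
        fit = kx.fit_dwell_distribution(t, t_min=0.39, n_boot=10)
        assert fit.tau == pytest.approx(tau_true, rel=0.02)
        # independent oracle: grid-search the truncated log-likelihood
        grid = np.linspace(0.3, 1.2, 2001)
        loglik = [-t.size * math.log(g) - np.sum(t - 0.39) / g for g in grid]
        assert fit.tau == pytest.approx(grid[int(np.argmax(loglik))], abs=2 * (grid[1] - grid[0]))

    def test_discrete_mle_unbiased_on_frame_quantized_dwells(self):
        rng = np.random.default_rng(2)
        for koff, dt in [(1.6, 0.13), (25.8, 0.015)]:
            d = rng.exponential(1 / koff, 100_000)
            k = np.floor(d / dt + rng.uniform(0, 1, d.size)).astype(int)
            durs = k[k >= 3] * dt
            fit = kx.fit_dwell_distribution(durs, t_min=3 * dt, frame_interval=dt, n_boot=10)
            assert 1 / fit.tau == pytest.approx(koff, rel=0.02)

    def test_mle_and_survival_lsq_agree(self):
        rng = np.random.default_rng(3)
        t = 0.2 + rng.exponential(0.7, 10_000)
        mle = kx.fit_dwell_distribution(t, t_min=0.2, method="mle", n_boot=10)
        lsq = kx.fit_dwell_distribution(t, t_min=0.2, method="survival_lsq", n_boot=10)
        assert lsq.tau == pytest.approx(mle.tau, rel=0.05)

    @pytest.mark.parametrize("c", [0.5, 3.7])
    def test_unit_rescaling_equivariance(self, c):
        rng = np.random.default_rng(4)
        t = 0.3 + rng.exponential(0.9, 500)
        base = kx.fit_dwell_distribution(t, t_min=0.3, n_boot=10)
        scaled = kx.fit_dwell_distribution(c * t, t_min=c * 0.3, n_boot=10)
        assert scaled.tau == pytest.approx(c * base.tau, rel=1e-9)
        assert kx.off_rate(scaled.tau) == pytest.approx(kx.off_rate(base.tau) / c, rel=1e-9)

    def test_bootstrap_ci_contains_point_estimate(self):
        rng = np.random.default_rng(5)
        t = 0.39 + rng.exponential(0.6, 300)
        fit = kx.fit_dwell_distribution(t, t_min=0.39, n_boot=200, seed=7)
        assert fit.tau_ci[0] <= fit.tau <= fit.tau_ci[1]

    def test_insufficient_or_invalid_data(self):
        with pytest.raises(EstimationError):
            kx.fit_dwell_distribution(np.ones(5), t_min=0.0)
        with pytest.raises(ValueError):
            kx.fit_dwell_distribution(np.full(20, 0.1), t_min=0.2)


class TestRates:
    def test_off_rate_reciprocal(self):
        assert kx.off_rate(0.5) == pytest.approx(2.0)
        assert kx.off_rate(0.625) == pytest.approx(1.6)
        with pytest.raises(ValueError):
            kx.off_rate(0.0)

    def test_on_rate_normalization(self):
        assert kx.on_rate(50, 100.0, 50.0, 10.0) == pytest.approx(1.0e-3)
        assert kx.on_rate(0, 100.0, 50.0, 10.0) == 0.0
        with pytest.raises(ValueError):
            kx.on_rate(5, 0.0, 50.0, 10.0)

    def test_on_rate_recovers_simulated_landing_density(self):
        kon = 1e-3
        ests = []
        for s in range(100):
            cfg = SimulationConfig(
                kon_density=kon, concentration=50.0, mt_lengths=(50.0,),
                duration=40.0, seed=s,
            )
            truth = simulate_binding_events(cfg)
            ests.append(kx.on_rate(len(truth), cfg.duration, cfg.total_length, cfg.concentration))
        mean_n = kon * 50 * 50 * 40
        se = kon / math.sqrt(mean_n * 100)  # Poisson SE on the pooled estimate
        assert abs(np.mean(ests) - kon) < 3 * se

    def test_kinetic_rates_invariants(self):
        rng = np.random.default_rng(6)
        t = 0.39 + rng.exponential(0.6, 200)
        fit = kx.fit_dwell_distribution(t, t_min=0.39, n_boot=50)
        rates = kx.KineticRates.from_fit(fit)
        assert rates.koff * rates.tau == pytest.approx(1.0)
        assert rates.koff_ci[0] <= rates.koff <= rates.koff_ci[1]
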