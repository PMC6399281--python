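"""Simulator: signal model, Poisson arrivals, determinism, truth I/O."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import stats

from difc import (
    SimArtifact,
    SimConfig,
    SimEvent,
    SimTruth,
    read_truth,
    simulate_scan,
    write_truth,
)
from difc.simulate import TruthParseError


def quiet_cfg(**kw):
    base = dict(
        duration=10.0,
        concentration=0.0,
        noise_sigma=0.0,
        baseline_drift_amplitude=0.0,
        seed=7,
    )
    base.update(kw)
    return SimConfig(**base)


class TestSignalModel:
    def test_no_signal_case_is_flat_baseline(self):
        t1, t2, truth = simulate_scan(quiet_cfg())
        assert not truth.events and not truth.artifacts
        assert np.all(t1.samples == 10_000.0)
        assert np.all(t2.samples == 10_000.0)
        assert t1.n_samples == 10_000

    def test_forward_event_delay_and_width(self):
        """One arterial cell: ch2 apex lags by d/v, pulse FWHM = FOV/v."""
        cfg = quiet_cfg(
            duration=4.0,
            concentration=25.0,  # lambda*T ~ 0.47; scan seeds until one event
            arterial_fraction=1.0,
            arterial_speed_sd=0.0,
            arterial_speed_mean=112.3,
            amplitude_log_sd=0.0,
            channel_jitter_log_sd=0.0,
        )
        t1 = t2 = truth = None
        for seed in range(30):
            cfg_s = quiet_cfg(**{**cfg.__dict__, "seed": seed})
            t1, t2, truth = simulate_scan(cfg_s)
            if len(truth.events) == 1 and 0.5 < truth.events[0].arrival_time < 3.5:
                break
        assert truth is not None and len(truth.events) == 1
        apex1 = np.argmax(t1.samples)
        apex2 = np.argmax(t2.samples)
        lag_s = (apex2 - apex1) / cfg.sample_rate
        assert lag_s == pytest.approx(3.0 / 112.3, abs=1.5e-3)
        # FWHM on channel 1 from half-max crossings of the rendered pulse
        y = t1.samples - 10_000.0
        above = np.flatnonzero(y >= y[apex1] / 2.0)
        fwhm_s = (above[-1] - above[0]) / cfg.sample_rate
        assert fwhm_s == pytest.approx(1.1 / 112.3, abs=2e-3)

    def test_delay_sign_by_direction_noiseless(self):
        """Forward events peak on ch1 first; reverse events on ch2 first."""
        cfg = quiet_cfg(
            duration=400.0,
            concentration=20.0,
            arterial_fraction=0.5,
            seed=3,
        )
        t1, t2, truth = simulate_scan(cfg)
        assert len(truth.events) > 10
        rate = cfg.sample_rate
        for e in truth.events:
            i = int(round(e.arrival_time * rate))
            w = int(0.1 * rate)
            lo, hi = max(i - w, 0), min(i + w, t1.n_samples)
            a1 = lo + np.argmax(t1.samples[lo:hi])
            a2 = lo + np.argmax(t2.samples[lo:hi])
            if e.direction == "forward":
                assert a2 > a1
            else:
                assert a2 < a1

    def test_baseline_conservation_with_noise(self):
        cfg = SimConfig(
            duration=30.0,
            concentration=0.0,
            noise_sigma=40.0,
            baseline_drift_amplitude=0.0,
            seed=11,
        )
        t1, _, _ = simulate_scan(cfg)
        se = 40.0 / np.sqrt(t1.n_samples)
        assert abs(t1.samples.mean() - 10_000.0) < 3 * se

    def test_artifact_kinds_land_on_expected_channels(self):
        cfg = quiet_cfg(
            duration=120.0,
            artifact_rate_single=5.0,
            artifact_rate_coincident=5.0,
            seed=5,
        )
        t1, t2, truth = simulate_scan(cfg)
        kinds = {a.kind for a in truth.artifacts}
        assert kinds <= {"single_ch1", "single_ch2", "coincident"}
        for a in truth.artifacts:
            i = int(round(a.time * cfg.sample_rate))
            lo, hi = max(i - 10, 0), min(i + 10, t1.n_samples)
            on1 = t1.samples[lo:hi].max() > 10_000.0 + a.amplitude / 2
            on2 = t2.samples[lo:hi].max() > 10_000.0 + a.amplitude / 2
            if a.kind == "coincident":
                assert on1 and on2
                # identical apex sample on both channels
                assert np.argmax(t1.samples[lo:hi]) == np.argmax(t2.samples[lo:hi])
            elif a.kind == "single_ch1":
                assert on1 and not on2
            else:
                assert on2 and not on1


class TestArrivals:
    def test_poisson_event_count_mean(self):
        """Mean event count over seeds matches concentration x sampled volume."""
        lam_t = 100 * 0.284 * 1.0  # 60 s at 100 cells/mL and 0.284 mL/min
        counts = []
        for seed in range(200):
            _, _, truth = simulate_scan(
                quiet_cfg(duration=60.0, concentration=100.0, seed=seed)
            )
            counts.append(len(truth.events))
        counts = np.asarray(counts)
        se = np.sqrt(lam_t / counts.size)
        assert abs(counts.mean() - lam_t) < 3 * se

    def test_poisson_count_distribution_gof(self):
        """Chi-square goodness of fit of event counts to Poisson(lambda*T)."""
        lam_t = 35.0 * 0.284 / 60.0 * 30.0  # ~4.97
        counts = np.array(
            [
                len(
                    simulate_scan(
                        quiet_cfg(duration=30.0, concentration=35.0, seed=s)
                    )[2].events
                )
                for s in range(400)
            ]
        )
        kmax = int(counts.max()) + 1
        observed = np.bincount(counts, minlength=kmax).astype(float)
        expected = stats.poisson.pmf(np.arange(kmax), lam_t) * counts.size
        # pool sparse tails so each bin expects >= 5
        obs_p, exp_p = [], []
        o_acc = e_acc = 0.0
        for o, e in zip(observed, expected):
            o_acc += o
            e_acc += e
            if e_acc >= 5:
                obs_p.append(o_acc)
                exp_p.append(e_acc)
                o_acc = e_acc = 0.0
        obs_p[-1] += o_acc
        exp_p[-1] += e_acc
        exp_p = np.array(exp_p) * (counts.size / np.sum(exp_p))
        _, p = stats.chisquare(obs_p, exp_p)
        assert p > 0.01

    def test_time_varying_concentration_decays(self):
        tau = 60.0
        cfg = quiet_cfg(
            duration=240.0,
            concentration=lambda t: 500.0 * np.exp(-np.asarray(t) / tau),
            seed=21,
        )
        _, _, truth = simulate_scan(cfg)
        times = np.array([e.arrival_time for e in truth.events])
        early = np.sum(times < 60.0)
        late = np.sum(times >= 180.0)
        assert early > 3 * late


class TestDeterminismAndValidation:
    def test_identical_seed_bitwise_identical(self):
        cfg = SimConfig(
            duration=5.0,
            concentration=200.0,
            artifact_rate_single=2.0,
            artifact_rate_coincident=1.0,
            seed=42,
        )
        a1, a2, ta = simulate_scan(cfg)
        b1, b2, tb = simulate_scan(cfg)
        assert np.array_equal(a1.samples, b1.samples)
        assert np.array_equal(a2.samples, b2.samples)
        assert ta == tb

    @pytest.mark.parametrize(
        "kw",
        [
            {"duration": 0.0},
            {"duration": -1.0},
            {"sample_rate": 0.0},
            {"arterial_fraction": 1.5},
            {"noise_sigma": -1.0},
            {"concentration": -5.0},
        ],
    )
    def test_invalid_config_rejected(self, kw):
        with pytest.raises(ValueError):
            SimConfig(**kw)


class TestTruthIO:
    def test_empty_truth_roundtrip(self, tmp_path):
        p = tmp_path / "truth.csv"
        write_truth(SimTruth(), p)
        back = read_truth(p)
        assert back.events == [] and back.artifacts == []

    def test_roundtrip_identity(self, tmp_path):
        truth = SimTruth(
            events=[
                SimEvent(1.25, "forward", 112.3, 530.0, 510.0),
                SimEvent(2.5, "reverse", 76.6, 400.0, 420.0),
                SimEvent(7.125, "forward", 99.9, 251.0, 249.0),
            ],
            artifacts=[
                SimArtifact(0.5, "single_ch1", 900.0),
                SimArtifact(3.0, "coincident", 1500.0),
            ],
        )
        p = tmp_path / "truth.csv"
        write_truth(truth, p)
        assert read_truth(p) == truth

    def test_non_numeric_speed_names_line(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text(
            "time_s,kind,direction,speed_mm_s,amp1_nA,amp2_nA\n"
            "1.0,cell,forward,fast,500,500\n"
        )
        with pytest.raises(TruthParseError, match="line 2"):
            read_truth(p)

    def test_bad_header_rejected(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("a,b,c\n")
        with pytest.raises(TruthParseError, match="line 1"):
            read_truth(p)
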