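"""Simulator contracts: determinism, latent-label structure, anomalies."""

import numpy as np
import pytest

from speckscore import (
    Drift,
    RateSpike,
    Saturation,
    SimConfig,
    VariantTruth,
    four_pl,
    inject_anomalies,
    simulate_experiment,
    simulate_sample,
)


def test_seeded_determinism_is_bit_identical(sim_cfg, wt_truth):
    t1, _ = simulate_sample(sim_cfg, wt_truth, seed=3)
    t2, _ = simulate_sample(sim_cfg, wt_truth, seed=3)
    assert t1.data.equals(t2.data)
    t3, _ = simulate_sample(sim_cfg, wt_truth, seed=4)
    assert not t1.data.equals(t3.data)


def test_manifest_label_conservation(wt_sample):
    events, rec = wt_sample
    counts = rec.label_counts()
    assert counts["n_debris"] + counts["n_doublet"] + counts["n_singlet"] == events.n_events
    # nesting: specks only among cells, transfection only meaningful there
    assert counts["n_speck"] <= counts["n_events"]


def test_no_transfection_means_no_expression():
    cfg = SimConfig(n_events=10_000, transfected_fraction=0.0, seed=2)
    events, rec = simulate_sample(cfg, VariantTruth("WT", 1.0), seed=2)
    assert rec.is_transfected.sum() == 0
    # no event above 5 sigma of the log-normal background
    hi = 10 ** (cfg.background_mu + 5 * cfg.background_sigma)
    assert (events.data["GFP-A"] > hi).sum() == 0


def test_speck_rate_matches_logistic_in_narrow_window(wt_sample, sim_cfg):
    """Fraction of speck labels near the midpoint converges to pi(phi)~0.5."""
    events, rec = wt_sample
    singlet = ~(rec.is_debris | rec.is_doublet)
    sel = singlet & rec.is_transfected
    x = np.log10(np.clip(events.data["GFP-A"].to_numpy()[sel], 1, None))
    speck = rec.is_speck[sel]
    for center in (2.6, 3.2, 3.8):
        window = np.abs(x - center) < 0.1
        n = window.sum()
        assert n > 50
        expected = four_pl(center, sim_cfg.pi_floor,
                           sim_cfg.pi_max - sim_cfg.pi_floor,
                           sim_cfg.eta_true, sim_cfg.phi_wt)
        observed = speck[window].mean()
        # 4 binomial sigmas plus window-averaging slack
        tol = 4 * np.sqrt(expected * (1 - expected) / n) + 0.03
        assert abs(observed - expected) < tol


def test_invalid_configs_are_rejected():
    with pytest.raises(ValueError, match="ec50_ratio"):
        VariantTruth("bad", -0.5)
    with pytest.raises(ValueError, match="pi_floor"):
        SimConfig(pi_floor=0.9, pi_max=0.5).validate()
    with pytest.raises(ValueError, match="phi_wt"):
        SimConfig(phi_wt=-1.0).validate()
    with pytest.raises(ValueError, match="finite"):
        SimConfig(expr_mu=float("nan")).validate()


class TestAnomalies:
    def test_rate_spike_multiplies_window_count(self, wt_sample):
        events, _ = wt_sample
        spiked, mask = inject_anomalies(events, RateSpike(50.0, 5.0, 10.0), seed=1)
        t = spiked.data["time_s"].to_numpy()
        in_win = ((t >= 50) & (t < 55)).sum()
        before = ((t >= 40) & (t < 45)).sum()
        after = ((t >= 60) & (t < 65)).sum()
        neighbor = (before + after) / 2
        assert 7 * neighbor < in_win < 13 * neighbor
        assert mask.sum() > 0 and len(mask) == spiked.n_events

    def test_rate_spike_outside_span_raises(self, wt_sample):
        events, _ = wt_sample
        t_end = events.data["time_s"].iloc[-1]
        with pytest.raises(ValueError, match="span"):
            inject_anomalies(events, RateSpike(t_end + 10, 5.0, 10.0))

    def test_saturation_pins_exact_count(self, wt_sample):
        events, _ = wt_sample
        sat, mask = inject_anomalies(events, Saturation("GFP-A", 0.02), seed=1)
        expected = int(np.ceil(0.02 * events.n_events))
        assert mask.sum() == expected
        ch_max = events.channel_ranges["GFP-A"]
        assert (sat.data["GFP-A"].to_numpy()[mask] == ch_max).all()

    def test_drift_makes_bin_medians_increase(self, wt_sample):
        events, _ = wt_sample
        drifted, _ = inject_anomalies(events, Drift("GFP-A", 0.02), seed=1)
        t = drifted.data["time_s"].to_numpy()
        v = drifted.data["GFP-A"].to_numpy()
        edges = np.linspace(t[0], t[-1], 9)
        medians = [np.median(v[(t >= a) & (t < b)])
                   for a, b in zip(edges[:-1], edges[1:])]
        assert all(m2 > m1 for m1, m2 in zip(medians, medians[1:]))

    def test_unknown_anomaly_kind_raises(self, wt_sample):
        events, _ = wt_sample
        with pytest.raises(ValueError, match="unknown anomaly"):
            inject_anomalies(events, "rate_spike?")


class TestExperiment:
    def test_batch_layout_and_truth(self):
        panel = [
            VariantTruth("WT", 1.0),
            VariantTruth("A", 0.8),
            VariantTruth("B", 1.0, {"nigericin": 0.8}),
        ]
        cfg = SimConfig(n_events=500, seed=9)
        tables, manifest = simulate_experiment(
            panel, cfg, ["untreated", "nigericin"], replicates=3, seed=9)
        assert len(tables) == 3 * 2 * 3
        frame = manifest.to_frame()
        assert len(frame) == 18
        wt = frame[frame["variant_label"] == "WT"]
        assert (wt["true_asc50"] == 0.0).all()
        b_untr = frame.query("variant_label == 'B' and condition == 'untreated'")
        b_nig = frame.query("variant_label == 'B' and condition == 'nigericin'")
        assert np.allclose(b_untr["true_asc50"], 0.0)
        assert np.allclose(b_nig["true_asc50"], 1 - 1.0 * 0.8)

    def test_missing_wt_entry_raises(self):
        panel = [VariantTruth("A", 0.8)]
        with pytest.raises(ValueError, match="WT"):
            simulate_experiment(panel, SimConfig(n_events=100), ["untreated"], 1)

    def test_file_emission_round_trip(self, tmp_path):
        panel = [VariantTruth("WT", 1.0), VariantTruth("A", 0.7)]
        cfg = SimConfig(n_events=300, seed=4)
        tables, manifest = simulate_experiment(
            panel, cfg, ["untreated"], 2, out_dir=tmp_path, seed=4)
        assert (tmp_path / "sample_sheet.csv").exists()
        assert (tmp_path / "manifest.json").exists()
        written = sorted(p.name for p in tmp_path.glob("*.csv")
                         if p.name != "sample_sheet.csv")
        assert len(written) == 4
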