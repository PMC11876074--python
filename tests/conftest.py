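"""Shared fixtures: seeded synthetic samples with ground-truth manifests."""

import numpy as np
import pandas as pd
import pytest

from speckscore import (
    EventTable,
    SimConfig,
    VariantTruth,
    derive_gates,
    run_qc,
    simulate_sample,
)


@pytest.fixture(scope="session")
def sim_cfg():
    return SimConfig(seed=11)


@pytest.fixture(scope="session")
def wt_truth():
    return VariantTruth("WT", 1.0)


@pytest.fixture(scope="session")
def wt_sample(sim_cfg, wt_truth):
    """(events, truth record) for a default WT acquisition."""
    return simulate_sample(sim_cfg, wt_truth, seed=11)


@pytest.fixture(scope="session")
def wt_clean(wt_sample):
    """QC-passed WT events plus the QC report (labels still aligned via mask)."""
    events, record = wt_sample
    clean, report = run_qc(events)
    return clean, report, record


@pytest.fixture(scope="session")
def wt_gates(wt_clean):
    clean, _, _ = wt_clean
    return derive_gates(clean)


def make_control_table(n=4000, metric_means=(0.3, 0.8), metric_sd=0.05,
                       pos_weight=0.5, seed=5):
    """Hand-built control: singlet scatter cloud + bimodal speck metric.

    Independent of the simulator; used to probe gate derivation against a
    construction whose true density valley is known analytically.
    """
    rng = np.random.default_rng(seed)
    fsc_a = 10 ** rng.normal(4.7, 0.12, n)
    fsc_h = 0.8 * fsc_a * (1 + rng.normal(0, 0.03, n))
    ssc_a = 10 ** rng.normal(4.3, 0.18, n)
    transfected = rng.random(n) < 0.5
    gfp = np.where(transfected,
                   10 ** rng.normal(3.2, 0.8, n),
                   10 ** rng.normal(0.7, 0.2, n))
    is_pos = transfected & (rng.random(n) < pos_weight * 2)  # ~pos_weight overall
    metric = np.where(is_pos, metric_means[1], metric_means[0])
    metric = metric + rng.normal(0, metric_sd, n)
    df = pd.DataFrame({
        "time_s": np.cumsum(rng.exponential(0.01, n)),
        "FSC-A": fsc_a,
        "FSC-H": fsc_h,
        "SSC-A": ssc_a,
        "GFP-A": gfp,
        "BFP-A": 10 ** rng.normal(2.8, 0.25, n),
        "speck_metric": metric,
    })
    return EventTable(data=df, sample_id="handmade_control")
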