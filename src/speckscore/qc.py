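"""Acquisition quality control.

Removes artifact events before gating, applying three criteria in the order
flow rate, signal acquisition (drift), dynamic range:

1. *Flow rate* — events are binned by time; bins whose event count deviates
   from the median by more than ``rate_mad_z`` robust z-units are dropped.
2. *Signal acquisition* — per-bin medians of each fluorescence channel are
   compared with the grand median; outlier bins are dropped.
3. *Dynamic range* — events with any fluorescence value at or above
   ``(1 - range_margin) * channel_max``, or at/below zero, are dropped.

Each criterion is an explicit robust-statistics rule (MAD scaled by 1.4826
for normal consistency; IQR fallback when the MAD degenerates to zero; no
bins flagged when both are zero).  The rules are transparent and directly
testable against injected anomalies; no changepoint segmentation is
attempted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import FLUORESCENCE_CHANNELS, EventTable

_MAD_SCALE = 1.4826


class TooFewEventsError(ValueError):
    """Sample has too few events for QC; it is flagged, not scored."""


@dataclass
class QCConfig:
    time_bin_s: float = 1.0
    rate_mad_z: float = 5.0
    drift_mad_z: float = 5.0
    drift_min_run: int = 2     # outlier bins must persist this many bins
    range_margin: float = 0.0
    min_events: int = 200
    fluorescence_channels: tuple = FLUORESCENCE_CHANNELS

    def validate(self) -> None:
        if not self.time_bin_s > 0:
            raise ValueError("time_bin_s must be > 0")
        if not (self.rate_mad_z > 0 and self.drift_mad_z > 0):
            raise ValueError("MAD thresholds must be > 0")
        if not 0 <= self.range_margin < 0.5:
            raise ValueError("range_margin must be in [0, 0.5)")
        if self.min_events < 1:
            raise ValueError("min_events must be >= 1")


@dataclass
class QCReport:
    sample_id: str
    n_input: int
    n_removed_rate: int
    n_removed_drift: int
    n_removed_range: int
    n_output: int
    flagged_bins: list = field(default_factory=list)  # (start_s, end_s, reason)
    saturation_counts: dict = field(default_factory=dict)
    #: boolean mask over input events (True = removed); not serialized
    removed_mask: np.ndarray | None = None

    @property
    def n_removed_total(self) -> int:
        return self.n_input - self.n_output

    def to_dict(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "n_input": self.n_input,
            "n_removed_rate": self.n_removed_rate,
            "n_removed_drift": self.n_removed_drift,
            "n_removed_range": self.n_removed_range,
            "n_removed_total": self.n_removed_total,
            "n_output": self.n_output,
            "flagged_bins": [
                {"start_s": s, "end_s": e, "reason": r}
                for s, e, r in self.flagged_bins
            ],
            "saturation_counts": self.saturation_counts,
        }

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    def flagged_intervals_csv(self, path) -> None:
        pd.DataFrame(
            [(s, e) for s, e, _ in self.flagged_bins],
            columns=["start_s", "end_s"],
        ).to_csv(path, index=False)


def _robust_outliers(values: np.ndarray, z: float) -> np.ndarray:
    """Boolean mask of robust-z outliers; MAD -> IQR -> no-flag fallbacks."""
    med = np.median(values)
    dev = np.abs(values - med)
    mad = np.median(dev) * _MAD_SCALE
    if mad == 0:
        q75, q25 = np.percentile(values, [75, 25])
        mad = (q75 - q25) / 1.349  # normal-consistent IQR scale
    if mad == 0:
        return np.zeros(len(values), dtype=bool)
    return dev > z * mad


def run_qc(events: EventTable, cfg: QCConfig | None = None) -> tuple[EventTable, QCReport]:
    """Apply the three QC criteria; return cleaned events and a report.

    Events removed by more than one criterion are counted once in the
    reconciliation (``n_output = n_input - |union|``); the per-criterion
    counts report each rule's own flag set.
    """
    cfg = cfg or QCConfig()
    cfg.validate()
    events.require("time_s")
    df = events.data
    n = len(df)
    if n < cfg.min_events:
        raise TooFewEventsError(
            f"sample {events.sample_id!r}: {n} events < min_events={cfg.min_events}"
        )
    t = df["time_s"].to_numpy()
    t0 = t[0]
    bin_idx = np.floor((t - t0) / cfg.time_bin_s).astype(np.int64)
    n_bins = int(bin_idx.max()) + 1

    flagged_bins: list = []

    # 1. flow rate
    counts = np.bincount(bin_idx, minlength=n_bins)
    rate_bad = _robust_outliers(counts.astype(float), cfg.rate_mad_z)
    rate_mask = rate_bad[bin_idx]
    for b in np.flatnonzero(rate_bad):
        flagged_bins.append((t0 + b * cfg.time_bin_s,
                             t0 + (b + 1) * cfg.time_bin_s, "rate"))

    # 2. signal acquisition (per-bin median drift)
    drift_bad = np.zeros(n_bins, dtype=bool)
    channels = [c for c in cfg.fluorescence_channels if c in df.columns]
    for ch in channels:
        values = df[ch].to_numpy()
        med_per_bin = np.full(n_bins, np.nan)
        order = np.argsort(bin_idx, kind="stable")
        sorted_bins = bin_idx[order]
        sorted_vals = values[order]
        boundaries = np.searchsorted(sorted_bins, np.arange(n_bins + 1))
        for b in range(n_bins):
            seg = sorted_vals[boundaries[b]:boundaries[b + 1]]
            if len(seg):
                med_per_bin[b] = np.median(seg)
        valid = ~np.isnan(med_per_bin)
        if valid.sum() >= 3:
            bad = np.zeros(n_bins, dtype=bool)
            bad[valid] = _robust_outliers(med_per_bin[valid], cfg.drift_mad_z)
            drift_bad |= bad
    if cfg.drift_min_run > 1 and drift_bad.any():
        # acquisition problems are serially correlated; an isolated one-bin
        # median excursion is sampling noise (bin medians of a bimodal
        # channel are heavy-tailed), not drift
        keep = np.zeros(n_bins, dtype=bool)
        run_start = None
        for b in range(n_bins + 1):
            if b < n_bins and drift_bad[b]:
                if run_start is None:
                    run_start = b
            elif run_start is not None:
                if b - run_start >= cfg.drift_min_run:
                    keep[run_start:b] = True
                run_start = None
        drift_bad = keep
    drift_mask = drift_bad[bin_idx]
    for b in np.flatnonzero(drift_bad):
        flagged_bins.append((t0 + b * cfg.time_bin_s,
                             t0 + (b + 1) * cfg.time_bin_s, "drift"))

    # 3. dynamic range
    range_mask = np.zeros(n, dtype=bool)
    saturation_counts: dict = {}
    for ch in channels:
        ch_max = events.channel_ranges.get(ch)
        if ch_max is None:
            continue
        values = df[ch].to_numpy()
        sat = values >= (1.0 - cfg.range_margin) * ch_max
        low = values <= 0.0
        saturation_counts[ch] = int(sat.sum())
        range_mask |= sat | low

    removed = rate_mask | drift_mask | range_mask
    cleaned = events.copy()
    cleaned.data = df.loc[~removed].reset_index(drop=True)
    report = QCReport(
        sample_id=events.sample_id,
        n_input=n,
        n_removed_rate=int(rate_mask.sum()),
        n_removed_drift=int(drift_mask.sum()),
        n_removed_range=int(range_mask.sum()),
        n_output=int((~removed).sum()),
        flagged_bins=flagged_bins,
        saturation_counts=saturation_counts,
        removed_mask=removed,
    )
    return cleaned, report


def qc_kept_mask(events: EventTable, cfg: QCConfig | None = None) -> np.ndarray:
    """Boolean mask over the *input* events marking those QC keeps.

    Convenience for aligning QC output with per-event ground-truth labels.
    """
    _, report = run_qc(events, cfg)
    return ~report.removed_mask
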