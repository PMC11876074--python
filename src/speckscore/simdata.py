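"""Seeded simulator of the ASC-BFP HEK293T speck assay.

Emulates a transfected HEK293T-like population measured on a conventional
cytometer: log-normal GFP-NLRP3 expression on top of an untransfected
background, debris and doublets, a bimodal speck-metric channel, and a
logistic speck-probability-versus-expression relationship whose midpoint is
shifted per variant.  Every sample carries latent per-event labels in a
ground-truth manifest so downstream stages (QC, gating, dose-response,
scoring) can be tested against a known answer.

Model
-----
Each transfected cell expresses GFP-NLRP3 at a linear intensity
``10**N(expr_mu, expr_sigma)``.  With ``x = log10(GFP-A)``, the probability
that the cell holds an ASC speck is the four-parameter logistic

    pi(x) = pi_floor + (pi_max - pi_floor) / (1 + exp(-eta_true * (x - phi)))

where ``phi = ec50_ratio * phi_wt * modifier(condition)`` is the variant's
true midpoint.  The scalar ``speck_metric`` channel is drawn from a
two-component Gaussian conditional on speck status, mimicking the pulse-shape
redistribution signature of an ASC speck.  The ground-truth speck score is

    ASC50_true = 1 - ec50_ratio * modifier(condition)

i.e. the relative EC50 difference between the variant and wild type.

Event arrival is homogeneous Poisson at ``event_rate``; acquisition
anomalies (flow-rate spikes, signal drift, channel saturation) never emerge
from the model and are only added by explicit injection.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    DEFAULT_CHANNEL_RANGES,
    EventTable,
    write_events,
)

UNTREATED = "untreated"


def four_pl(x, alpha: float, delta: float, eta: float, phi: float):
    """4PL logistic ``alpha + delta / (1 + exp(-eta * (x - phi)))``."""
    x = np.asarray(x, dtype=float)
    return alpha + delta / (1.0 + np.exp(-eta * (x - phi)))


@dataclass
class SimConfig:
    """Study conditions for one simulated sample.

    Intensities are linear arbitrary units >= 0; expression parameters are on
    the log10 scale.  Defaults place the WT speck midpoint (``phi_wt = 3.2``)
    near the centre of the transfected expression distribution so wild type
    reaches ~50% specks inside the observed range, and keep the untransfected
    background well below the transfected population.
    """

    n_events: int = 20_000
    transfected_fraction: float = 0.35
    debris_fraction: float = 0.08
    doublet_fraction: float = 0.03
    expr_mu: float = 3.2            # log10 a.u., transfected GFP-NLRP3
    expr_sigma: float = 0.9
    background_mu: float = 0.7      # log10 a.u., untransfected background
    background_sigma: float = 0.2
    phi_wt: float = 3.2             # WT speck midpoint on the log10 axis
    eta_true: float = 3.0           # logistic steepness
    pi_floor: float = 0.02
    pi_max: float = 0.98
    speck_metric_means: tuple = (0.3, 0.8)   # (speck-negative, speck-positive)
    speck_metric_sd: float = 0.05
    event_rate: float = 100.0       # events per second
    seed: int = 0

    def validate(self) -> None:
        probs = {
            "transfected_fraction": self.transfected_fraction,
            "debris_fraction": self.debris_fraction,
            "doublet_fraction": self.doublet_fraction,
            "pi_floor": self.pi_floor,
            "pi_max": self.pi_max,
        }
        for name, value in probs.items():
            if not (np.isfinite(value) and 0.0 <= value <= 1.0):
                raise ValueError(f"{name} must be a probability in [0, 1], got {value}")
        if self.debris_fraction + self.doublet_fraction >= 1.0:
            raise ValueError("debris_fraction + doublet_fraction must be < 1")
        if not self.pi_floor < self.pi_max:
            raise ValueError("pi_floor must be < pi_max")
        if not (np.isfinite(self.phi_wt) and self.phi_wt > 0):
            raise ValueError("phi_wt must be finite and > 0")
        for name in ("expr_sigma", "background_sigma"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("expr_mu", "background_mu", "eta_true", "event_rate",
                     "speck_metric_sd"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if self.event_rate <= 0:
            raise ValueError("event_rate must be > 0")
        if self.n_events < 1:
            raise ValueError("n_events must be >= 1")


@dataclass
class VariantTruth:
    """Ground-truth description of one variant's activity.

    ``ec50_ratio`` is r > 0 with true midpoint ``phi = r * phi_wt``;
    ``condition_modifiers`` multiply the midpoint further under named
    treatments (e.g. a nigericin-sensitive variant has a modifier < 1).
    """

    variant_label: str
    ec50_ratio: float = 1.0
    condition_modifiers: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (np.isfinite(self.ec50_ratio) and self.ec50_ratio > 0):
            raise ValueError(f"ec50_ratio must be > 0, got {self.ec50_ratio}")
        for cond, m in self.condition_modifiers.items():
            if not (np.isfinite(m) and m > 0):
                raise ValueError(f"modifier for {cond!r} must be > 0, got {m}")

    def modifier(self, condition: str) -> float:
        if condition == UNTREATED:
            return 1.0
        return float(self.condition_modifiers.get(condition, 1.0))

    def true_phi(self, cfg: SimConfig, condition: str) -> float:
        return self.ec50_ratio * cfg.phi_wt * self.modifier(condition)

    def true_asc50(self, condition: str) -> float:
        return 1.0 - self.ec50_ratio * self.modifier(condition)


@dataclass
class SampleRecord:
    """One manifest row: sample identity, truth, and latent event labels."""

    sample_id: str
    variant_label: str
    condition: str
    replicate: str
    batch: str = "batch1"
    role: str = "variant"
    true_phi: float = float("nan")
    true_asc50: float = float("nan")
    is_debris: np.ndarray | None = None
    is_doublet: np.ndarray | None = None
    is_transfected: np.ndarray | None = None
    is_speck: np.ndarray | None = None
    anomalous: np.ndarray | None = None

    def label_counts(self) -> dict:
        n = len(self.is_debris)
        return {
            "n_events": n,
            "n_debris": int(self.is_debris.sum()),
            "n_doublet": int(self.is_doublet.sum()),
            "n_singlet": int(n - self.is_debris.sum() - self.is_doublet.sum()),
            "n_transfected": int(self.is_transfected.sum()),
            "n_speck": int(self.is_speck.sum()),
            "n_anomalous": int(self.anomalous.sum()) if self.anomalous is not None else 0,
        }


@dataclass
class GroundTruthManifest:
    """Per-sample truth records for a simulated experiment."""

    samples: list = field(default_factory=list)

    def add(self, record: SampleRecord) -> None:
        self.samples.append(record)

    def get(self, sample_id: str) -> SampleRecord:
        for rec in self.samples:
            if rec.sample_id == sample_id:
                return rec
        raise KeyError(sample_id)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for rec in self.samples:
            row = {
                "sample_id": rec.sample_id,
                "variant_label": rec.variant_label,
                "condition": rec.condition,
                "replicate": rec.replicate,
                "batch": rec.batch,
                "role": rec.role,
                "true_phi": rec.true_phi,
                "true_asc50": rec.true_asc50,
            }
            row.update(rec.label_counts())
            rows.append(row)
        return pd.DataFrame(rows)

    def to_json(self, path, include_labels: bool = False) -> None:
        payload = []
        for rec in self.samples:
            entry = {
                "sample_id": rec.sample_id,
                "variant_label": rec.variant_label,
                "condition": rec.condition,
                "replicate": rec.replicate,
                "batch": rec.batch,
                "role": rec.role,
                "true_phi": rec.true_phi,
                "true_asc50": rec.true_asc50,
                "label_counts": rec.label_counts(),
            }
            if include_labels:
                entry["labels"] = {
                    "is_debris": rec.is_debris.astype(int).tolist(),
                    "is_doublet": rec.is_doublet.astype(int).tolist(),
                    "is_transfected": rec.is_transfected.astype(int).tolist(),
                    "is_speck": rec.is_speck.astype(int).tolist(),
                }
                if rec.anomalous is not None:
                    entry["labels"]["anomalous"] = rec.anomalous.astype(int).tolist()
            payload.append(entry)
        Path(path).write_text(json.dumps(payload, indent=1))


# ---------------------------------------------------------------------------
# Sample simulation
# ---------------------------------------------------------------------------

def _singlet_scatter(rng: np.random.Generator, n: int):
    """FSC/SSC for intact single cells (log-normal cloud, tight H/A ratio)."""
    fsc_a = 10 ** rng.normal(4.7, 0.12, n)
    fsc_h = 0.8 * fsc_a * (1.0 + rng.normal(0.0, 0.03, n))
    ssc_a = 10 ** rng.normal(4.3, 0.18, n)
    return fsc_a, fsc_h, ssc_a


def _debris_scatter(rng: np.random.Generator, n: int):
    fsc_a = 10 ** rng.normal(3.4, 0.25, n)
    fsc_h = 0.8 * fsc_a * (1.0 + rng.normal(0.0, 0.10, n))
    ssc_a = 10 ** rng.normal(3.2, 0.3, n)
    return fsc_a, fsc_h, ssc_a


def simulate_sample(cfg: SimConfig, truth: VariantTruth, condition: str = UNTREATED,
                    seed: int | None = None,
                    sample_id: str | None = None) -> tuple[EventTable, SampleRecord]:
    """Simulate one acquisition and return the events plus its truth record.

    Events appear in time order; debris, doublets and singlets are
    interleaved at random.  Doublets are the channel-wise sum of two latent
    singlets with FSC-H = 1.3x the singlet FSC-H (pulse-shape convention),
    so the singlet gate has signal to find.  All intensities saturate at the
    per-channel detector range.
    """
    cfg.validate()
    if condition != UNTREATED and condition not in truth.condition_modifiers:
        # an unknown condition is allowed but acts as untreated; keep it
        # explicit for sample bookkeeping
        pass
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    n = cfg.n_events
    phi = truth.true_phi(cfg, condition)

    # event categories
    u = rng.random(n)
    is_debris = u < cfg.debris_fraction
    is_doublet = (~is_debris) & (u < cfg.debris_fraction + cfg.doublet_fraction)
    is_singlet = ~(is_debris | is_doublet)

    fsc_a = np.empty(n)
    fsc_h = np.empty(n)
    ssc_a = np.empty(n)
    gfp = np.empty(n)
    bfp = np.empty(n)
    metric = np.empty(n)
    is_transfected = np.zeros(n, dtype=bool)
    is_speck = np.zeros(n, dtype=bool)

    def _draw_cells(m: int):
        """Latent single-cell draws: channels + transfection/speck labels."""
        a, h, s = _singlet_scatter(rng, m)
        transfected = rng.random(m) < cfg.transfected_fraction
        log_gfp = np.where(
            transfected,
            rng.normal(cfg.expr_mu, cfg.expr_sigma, m),
            rng.normal(cfg.background_mu, cfg.background_sigma, m),
        )
        g = 10 ** log_gfp
        b = 10 ** rng.normal(2.8, 0.25, m)
        pi = four_pl(log_gfp, cfg.pi_floor, cfg.pi_max - cfg.pi_floor,
                     cfg.eta_true, phi)
        speck = rng.random(m) < pi
        mu = np.where(speck, cfg.speck_metric_means[1], cfg.speck_metric_means[0])
        sm = rng.normal(mu, cfg.speck_metric_sd)
        return a, h, s, g, b, sm, transfected, speck

    # singlets
    m = int(is_singlet.sum())
    a, h, s, g, b, sm, tr, sp = _draw_cells(m)
    fsc_a[is_singlet], fsc_h[is_singlet], ssc_a[is_singlet] = a, h, s
    gfp[is_singlet], bfp[is_singlet], metric[is_singlet] = g, b, sm
    is_transfected[is_singlet] = tr
    is_speck[is_singlet] = sp

    # doublets: sum of two latent cells, FSC-H only 1.3x one cell's height
    m = int(is_doublet.sum())
    if m:
        a1, h1, s1, g1, b1, sm1, tr1, sp1 = _draw_cells(m)
        a2, _h2, s2, g2, b2, sm2, tr2, sp2 = _draw_cells(m)
        fsc_a[is_doublet] = a1 + a2
        fsc_h[is_doublet] = 1.3 * h1
        ssc_a[is_doublet] = s1 + s2
        gfp[is_doublet] = g1 + g2
        bfp[is_doublet] = b1 + b2
        metric[is_doublet] = np.maximum(sm1, sm2)
        # doublets are excluded by gating; latent labels kept for bookkeeping
        is_transfected[is_doublet] = tr1 | tr2
        is_speck[is_doublet] = sp1 | sp2

    # debris
    m = int(is_debris.sum())
    if m:
        a, h, s = _debris_scatter(rng, m)
        fsc_a[is_debris], fsc_h[is_debris], ssc_a[is_debris] = a, h, s
        gfp[is_debris] = 10 ** rng.normal(cfg.background_mu, cfg.background_sigma, m)
        bfp[is_debris] = 10 ** rng.normal(1.5, 0.4, m)
        metric[is_debris] = rng.normal(cfg.speck_metric_means[0], cfg.speck_metric_sd, m)

    # homogeneous Poisson arrival
    time_s = np.cumsum(rng.exponential(1.0 / cfg.event_rate, n))

    df = pd.DataFrame({
        "time_s": time_s,
        "FSC-A": fsc_a,
        "FSC-H": fsc_h,
        "SSC-A": ssc_a,
        "GFP-A": gfp,
        "BFP-A": bfp,
        "speck_metric": metric,
    })
    ranges = dict(DEFAULT_CHANNEL_RANGES)
    for ch in ("FSC-A", "FSC-H", "SSC-A", "GFP-A", "BFP-A", "speck_metric"):
        df[ch] = np.clip(df[ch], 0.0, ranges[ch])

    sid = sample_id or f"{truth.variant_label}_{condition}_r1"
    table = EventTable(data=df, sample_id=sid, channel_ranges=ranges)
    record = SampleRecord(
        sample_id=sid,
        variant_label=truth.variant_label,
        condition=condition,
        replicate="1",
        role="wt_control" if math.isclose(truth.ec50_ratio, 1.0) and not truth.condition_modifiers else "variant",
        true_phi=phi,
        true_asc50=truth.true_asc50(condition),
        is_debris=is_debris,
        is_doublet=is_doublet,
        is_transfected=is_transfected,
        is_speck=is_speck,
        anomalous=np.zeros(n, dtype=bool),
    )
    return table, record


# ---------------------------------------------------------------------------
# Anomaly injection
# ---------------------------------------------------------------------------

@dataclass
class RateSpike:
    """Burst of extra events so the flow rate in a window is ~factor x."""
    start_s: float
    duration_s: float
    factor: float = 10.0


@dataclass
class Drift:
    """Multiplicative linear drift of one channel over acquisition time."""
    channel: str
    slope: float  # fractional change per second


@dataclass
class Saturation:
    """Pins ceil(fraction * n) random events of one channel at its max."""
    channel: str
    fraction: float


def inject_anomalies(events: EventTable, spec, seed: int = 0,
                     record: SampleRecord | None = None) -> tuple[EventTable, np.ndarray]:
    """Return a modified copy of ``events`` plus a boolean anomaly mask.

    The mask marks *injected or altered* events in the returned table.  When
    a manifest ``record`` is given, its latent label arrays are kept aligned
    (injected rate-spike events inherit the labels of the events they were
    resampled from) and ``record.anomalous`` is updated in place.
    """
    rng = np.random.default_rng(seed)
    table = events.copy()
    df = table.data
    n = len(df)
    t = df["time_s"].to_numpy()

    if isinstance(spec, RateSpike):
        t0, t1 = spec.start_s, spec.start_s + spec.duration_s
        if t0 < t[0] - 1e-9 or t1 > t[-1] + 1e-9:
            raise ValueError("rate-spike window outside acquisition span")
        if spec.factor <= 1:
            raise ValueError("rate-spike factor must be > 1")
        span = t[-1] - t[0]
        in_win = (t >= t0) & (t < t1)
        base_rate = (n - in_win.sum()) / max(span - spec.duration_s, 1e-9)
        n_new = int(round((spec.factor - 1.0) * base_rate * spec.duration_s))
        src = rng.integers(0, n, n_new)
        new_rows = df.iloc[src].copy()
        new_rows["time_s"] = rng.uniform(t0, t1, n_new)
        mask = np.concatenate([np.zeros(n, dtype=bool), np.ones(n_new, dtype=bool)])
        out = pd.concat([df, new_rows], ignore_index=True)
        order = np.argsort(out["time_s"].to_numpy(), kind="stable")
        out = out.iloc[order].reset_index(drop=True)
        mask = mask[order]
        table.data = out
        if record is not None:
            for name in ("is_debris", "is_doublet", "is_transfected", "is_speck"):
                lab = getattr(record, name)
                setattr(record, name, np.concatenate([lab, lab[src]])[order])
            prev = record.anomalous if record.anomalous is not None else np.zeros(n, bool)
            record.anomalous = np.concatenate([prev, np.ones(n_new, bool)])[order]
        return table, mask

    if isinstance(spec, Drift):
        if spec.channel not in df.columns:
            raise ValueError(f"unknown channel {spec.channel!r}")
        rel = t - t[0]
        df[spec.channel] = np.clip(
            df[spec.channel] * (1.0 + spec.slope * rel),
            0.0, table.channel_ranges[spec.channel],
        )
        mask = np.ones(n, dtype=bool)
        if record is not None:
            prev = record.anomalous if record.anomalous is not None else np.zeros(n, bool)
            record.anomalous = prev | mask
        return table, mask

    if isinstance(spec, Saturation):
        if spec.channel not in df.columns:
            raise ValueError(f"unknown channel {spec.channel!r}")
        if not 0 < spec.fraction <= 1:
            raise ValueError("saturation fraction must be in (0, 1]")
        k = int(np.ceil(spec.fraction * n))
        idx = rng.choice(n, size=k, replace=False)
        df.loc[df.index[idx], spec.channel] = table.channel_ranges[spec.channel]
        mask = np.zeros(n, dtype=bool)
        mask[idx] = True
        if record is not None:
            prev = record.anomalous if record.anomalous is not None else np.zeros(n, bool)
            record.anomalous = prev | mask
        return table, mask

    raise ValueError(f"unknown anomaly kind: {spec!r}")


# ---------------------------------------------------------------------------
# Experiment simulation
# ---------------------------------------------------------------------------

def simulate_experiment(panel: list, cfg: SimConfig,
                        conditions: list | None = None,
                        replicates: int = 3,
                        out_dir=None, file_format: str = "csv",
                        batch: str = "batch1",
                        seed: int | None = None,
                        wt_label: str | None = None):
    """Simulate a variant x condition x replicate batch.

    The panel must contain exactly one wild-type entry (``ec50_ratio == 1``
    with no condition modifiers); it serves as the batch's WT control under
    every condition.  Returns ``(tables, manifest)`` where ``tables`` maps
    sample_id -> EventTable; when ``out_dir`` is given each sample is also
    written to disk (``file_format``: csv or fcs) along with a manifest JSON.
    """
    conditions = list(conditions or [UNTREATED])
    if wt_label is None:
        wt = [v for v in panel
              if math.isclose(v.ec50_ratio, 1.0) and not v.condition_modifiers]
        if len(wt) != 1:
            raise ValueError(
                "panel must contain exactly one WT entry "
                "(ec50_ratio == 1, no condition modifiers); found "
                f"{len(wt)}; pass wt_label to disambiguate"
            )
        wt_label = wt[0].variant_label
    else:
        wt = [v for v in panel if v.variant_label == wt_label]
        if len(wt) != 1 or not math.isclose(wt[0].ec50_ratio, 1.0):
            raise ValueError(
                f"wt_label {wt_label!r} must name exactly one panel entry "
                "with ec50_ratio == 1"
            )
    base_seed = cfg.seed if seed is None else seed

    manifest = GroundTruthManifest()
    tables: dict[str, EventTable] = {}
    for vi, truth in enumerate(panel):
        for ci, condition in enumerate(conditions):
            for rep in range(1, replicates + 1):
                sid = f"{batch}_{truth.variant_label}_{condition}_r{rep}"
                sample_seed = (base_seed * 1_000_003
                               + vi * 10_007 + ci * 101 + rep) % (2**31)
                table, record = simulate_sample(
                    cfg, truth, condition, seed=sample_seed, sample_id=sid
                )
                record.replicate = str(rep)
                record.batch = batch
                record.role = "wt_control" if truth.variant_label == wt_label else "variant"
                tables[sid] = table
                manifest.add(record)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        sheet_rows = []
        for rec in manifest.samples:
            fname = f"{rec.sample_id}.{file_format}"
            write_events(tables[rec.sample_id], out_dir / fname, file_format)
            sheet_rows.append({
                "file": fname,
                "variant_label": rec.variant_label,
                "condition": rec.condition,
                "replicate": rec.replicate,
                "batch": rec.batch,
                "role": rec.role,
            })
        pd.DataFrame(sheet_rows).to_csv(out_dir / "sample_sheet.csv", index=False)
        manifest.to_json(out_dir / "manifest.json")
    return tables, manifest


def default_panel() -> list:
    """Small screening panel with known truths, used by the CLI demo."""
    return [
        VariantTruth("WT", 1.0),
        VariantTruth("R262W", 0.6),
        VariantTruth("D305N", 0.7, {"cold_32C": 0.85}),
        VariantTruth("Y861H", 0.95, {"nigericin": 0.7}),
        VariantTruth("T438P", 0.55, {"mcc950_4h": 1.0, "mcc950_12h": 1.0}),
        VariantTruth("L355P", 0.65, {"cold_32C": 0.8, "mcc950_4h": 1.0,
                                     "mcc950_12h": 1.4}),
    ]
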