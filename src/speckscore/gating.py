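"""Automated gating: non-debris -> singlets -> transfected -> speck status.

Gates are derived once from a wild-type control sample and then applied
uniformly across the batch, mirroring standard control-anchored cytometry
practice:

* debris cutoff — deepest valley of a kernel-density estimate (Silverman
  bandwidth, log10 axis) below the main scatter mode, per scatter channel;
  falls back to a fixed quantile when no valley exists;
* singlet band — robust (Siegel) line fit of FSC-H on FSC-A over non-debris
  events, accepting events within ``k`` residual-MADs of the line;
* speck threshold — minimum-density valley of the speck-metric KDE between
  its two largest modes (Otsu fallback on the histogram, flagged in
  provenance);
* GFP-positive cutoff — 99.5th percentile of GFP-A in the speck-negative
  low-GFP (untransfected background) population.

Boundary convention: an event exactly at a threshold is assigned to the
non-positive side (half-open intervals throughout).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
from scipy import stats

from .io import EventTable


class GateDerivationError(ValueError):
    """The control sample cannot support gate derivation."""


@dataclass
class GatingConfig:
    scatter_channels: tuple = ("FSC-A", "SSC-A")
    singlet_band_mads: float = 4.0        # half-width in residual MAD units
    debris_fallback_quantile: float = 0.05
    min_cell_scatter: float = 1.0e4       # main FSC-A mode must exceed this
    gfp_background_quantile: float = 0.995
    kde_grid_points: int = 512
    max_kde_sample: int = 10_000          # subsample cap for KDE fits
    max_line_fit_sample: int = 4_000      # cap for the robust singlet line fit
    min_mode_height: float = 0.05         # modes below this fraction of max ignored


@dataclass
class GateSet:
    """Gate parameters derived from a WT control, applied batch-wide."""

    debris_thresholds: dict                # channel -> lower cutoff (a.u.)
    singlet_slope: float
    singlet_intercept: float
    singlet_half_width: float
    speck_threshold: float
    gfp_positive_cutoff: float
    provenance: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps({
            "debris_thresholds": self.debris_thresholds,
            "singlet_slope": self.singlet_slope,
            "singlet_intercept": self.singlet_intercept,
            "singlet_half_width": self.singlet_half_width,
            "speck_threshold": self.speck_threshold,
            "gfp_positive_cutoff": self.gfp_positive_cutoff,
            "provenance": self.provenance,
        }, indent=1))

    @classmethod
    def from_json(cls, path) -> "GateSet":
        return cls(**json.loads(Path(path).read_text()))


@dataclass
class GatedEvents:
    """Event table plus nested per-event population labels."""

    events: EventTable
    is_debris: np.ndarray
    is_singlet: np.ndarray
    is_transfected: np.ndarray        # defined on singlets only
    is_speck_positive: np.ndarray     # defined on transfected singlets only

    @property
    def n_events(self) -> int:
        return self.events.n_events

    def counts(self) -> dict:
        return {
            "n_events": self.n_events,
            "n_debris": int(self.is_debris.sum()),
            "n_singlet": int(self.is_singlet.sum()),
            "n_transfected": int(self.is_transfected.sum()),
            "n_speck_positive": int(self.is_speck_positive.sum()),
        }

    def expression(self, channel: str = "GFP-A"):
        """Linear expression of (speck-positive, speck-negative) transfected singlets."""
        values = self.events.data[channel].to_numpy()
        pos = values[self.is_speck_positive]
        neg = values[self.is_transfected & ~self.is_speck_positive]
        return pos, neg


def _kde(values: np.ndarray, cfg: GatingConfig, rng_seed: int = 0):
    """Silverman-bandwidth Gaussian KDE evaluated on a regular grid."""
    if len(values) > cfg.max_kde_sample:
        rng = np.random.default_rng(rng_seed)
        values = rng.choice(values, cfg.max_kde_sample, replace=False)
    kde = stats.gaussian_kde(values, bw_method="silverman")
    lo, hi = values.min(), values.max()
    pad = 0.05 * (hi - lo + 1e-12)
    grid = np.linspace(lo - pad, hi + pad, cfg.kde_grid_points)
    return grid, kde(grid)


def _modes(grid: np.ndarray, density: np.ndarray, min_height: float):
    """Local maxima of the density above ``min_height * max``."""
    interior = (density[1:-1] > density[:-2]) & (density[1:-1] >= density[2:])
    idx = np.flatnonzero(interior) + 1
    idx = idx[density[idx] >= min_height * density.max()]
    return idx[np.argsort(density[idx])[::-1]]  # tallest first


def _valley_between(grid, density, i: int, j: int) -> float:
    lo, hi = sorted((i, j))
    seg = density[lo:hi + 1]
    # ties broken toward the lower value on the grid
    return float(grid[lo + int(np.argmin(seg))])


def derive_gates(wt_control: EventTable, cfg: GatingConfig | None = None) -> GateSet:
    """Derive the batch gate set from a QC-passed WT control sample."""
    cfg = cfg or GatingConfig()
    wt_control.require("FSC-A", "FSC-H", "GFP-A", "speck_metric",
                       *cfg.scatter_channels)
    df = wt_control.data
    provenance = {
        "control_sample_id": wt_control.sample_id,
        "derived_at": datetime.now(timezone.utc).isoformat(timespec="seconds"),
        "fallbacks": [],
    }

    # --- debris cutoffs (per scatter channel, on log10 axis) -------------
    debris_thresholds: dict = {}
    for ch in cfg.scatter_channels:
        values = np.log10(np.clip(df[ch].to_numpy(), 1.0, None))
        grid, density = _kde(values, cfg)
        modes = _modes(grid, density, cfg.min_mode_height)
        if len(modes) == 0:
            raise GateDerivationError(
                f"{wt_control.sample_id}: no density mode on {ch}"
            )
        main = modes[0]
        if ch == "FSC-A" and 10 ** grid[main] < cfg.min_cell_scatter:
            raise GateDerivationError(
                f"{wt_control.sample_id}: main FSC-A mode at "
                f"{10 ** grid[main]:.3g} a.u. is below min_cell_scatter="
                f"{cfg.min_cell_scatter:.3g}; control lacks a cell population"
            )
        below = [m for m in modes[1:] if m < main]
        if below:
            cut = _valley_between(grid, density, below[0], main)
        else:
            cut = float(np.quantile(values, cfg.debris_fallback_quantile))
            provenance["fallbacks"].append(f"debris_quantile:{ch}")
        debris_thresholds[ch] = float(10 ** cut)

    non_debris = np.ones(len(df), dtype=bool)
    for ch, cut in debris_thresholds.items():
        non_debris &= df[ch].to_numpy() > cut

    # --- singlet band: robust FSC-H ~ FSC-A line -------------------------
    fa = df["FSC-A"].to_numpy()[non_debris]
    fh = df["FSC-H"].to_numpy()[non_debris]
    if len(fa) < 10:
        raise GateDerivationError("too few non-debris events for singlet fit")
    if len(fa) > cfg.max_line_fit_sample:
        # Siegel's repeated-median fit is quadratic in n; a seeded subsample
        # is ample for a 2-parameter line
        rng = np.random.default_rng(0)
        keep = rng.choice(len(fa), cfg.max_line_fit_sample, replace=False)
        slope, intercept = stats.siegelslopes(fh[keep], fa[keep])
    else:
        slope, intercept = stats.siegelslopes(fh, fa)
    resid = fh - (slope * fa + intercept)
    mad = np.median(np.abs(resid - np.median(resid))) * 1.4826
    if mad == 0:
        mad = np.std(resid) or 1.0
    half_width = cfg.singlet_band_mads * mad

    singlet = np.zeros(len(df), dtype=bool)
    resid_all = df["FSC-H"].to_numpy() - (slope * df["FSC-A"].to_numpy() + intercept)
    singlet[non_debris] = np.abs(resid_all[non_debris]) < half_width

    # --- speck threshold: valley between the two largest metric modes ----
    metric = df["speck_metric"].to_numpy()[singlet]
    grid, density = _kde(metric, cfg)
    modes = _modes(grid, density, cfg.min_mode_height)
    if len(modes) >= 2:
        speck_threshold = _valley_between(grid, density, modes[0], modes[1])
    else:
        # Otsu fallback on the histogram, flagged in provenance.  Accepted
        # only if the threshold sits in a genuine density dip; a unimodal
        # control has its maximum density near the Otsu split and is
        # rejected instead of yielding a meaningless gate.
        if np.ptp(metric) == 0:
            raise GateDerivationError(
                f"{wt_control.sample_id}: speck_metric is unimodal; control "
                "lacks a speck-positive population"
            )
        hist, edges = np.histogram(metric, bins=128)
        centers = (edges[:-1] + edges[1:]) / 2
        p = hist / hist.sum()
        omega = np.cumsum(p)
        mu = np.cumsum(p * centers)
        mu_t = mu[-1]
        with np.errstate(divide="ignore", invalid="ignore"):
            between = (mu_t * omega - mu) ** 2 / (omega * (1.0 - omega))
        between[~np.isfinite(between)] = -np.inf
        speck_threshold = float(centers[int(np.argmax(between))])
        dens_at = np.interp(speck_threshold, grid, density)
        lo_med = np.median(metric[metric <= speck_threshold])
        hi_med = np.median(metric[metric > speck_threshold])
        dens_cls = min(np.interp(lo_med, grid, density),
                       np.interp(hi_med, grid, density))
        if not dens_at < 0.9 * dens_cls:
            raise GateDerivationError(
                f"{wt_control.sample_id}: speck_metric is unimodal; control "
                "lacks a speck-positive population"
            )
        provenance["fallbacks"].append("speck_threshold:otsu")

    # --- GFP-positive cutoff from the untransfected background ----------
    speck_neg = singlet & (df["speck_metric"].to_numpy() <= speck_threshold)
    log_gfp = np.log10(np.clip(df["GFP-A"].to_numpy()[speck_neg], 1.0, None))
    grid, density = _kde(log_gfp, cfg)
    modes = _modes(grid, density, cfg.min_mode_height)
    if len(modes) >= 2:
        lo_mode, hi_mode = sorted(modes[:2])
        split = _valley_between(grid, density, lo_mode, hi_mode)
        background = log_gfp[log_gfp < split]
    else:
        background = log_gfp
        provenance["fallbacks"].append("gfp_cutoff:unsplit_background")
    if len(background) < 10:
        background = log_gfp
    gfp_positive_cutoff = float(
        10 ** np.quantile(background, cfg.gfp_background_quantile)
    )

    return GateSet(
        debris_thresholds=debris_thresholds,
        singlet_slope=float(slope),
        singlet_intercept=float(intercept),
        singlet_half_width=float(half_width),
        speck_threshold=float(speck_threshold),
        gfp_positive_cutoff=gfp_positive_cutoff,
        provenance=provenance,
    )


def apply_gates(events: EventTable, gates: GateSet) -> GatedEvents:
    """Label events with the batch gate set (pure, deterministic).

    Population labels nest: speck status is only defined on transfected
    singlets, transfection only on singlets.  Events exactly at a threshold
    fall on the non-positive side.
    """
    needed = list(gates.debris_thresholds) + ["FSC-A", "FSC-H", "GFP-A",
                                              "speck_metric"]
    events.require(*dict.fromkeys(needed))
    df = events.data

    non_debris = np.ones(len(df), dtype=bool)
    for ch, cut in gates.debris_thresholds.items():
        non_debris &= df[ch].to_numpy() > cut

    resid = df["FSC-H"].to_numpy() - (
        gates.singlet_slope * df["FSC-A"].to_numpy() + gates.singlet_intercept
    )
    is_singlet = non_debris & (np.abs(resid) < gates.singlet_half_width)

    is_transfected = is_singlet & (df["GFP-A"].to_numpy() > gates.gfp_positive_cutoff)
    is_speck = is_transfected & (df["speck_metric"].to_numpy() > gates.speck_threshold)

    return GatedEvents(
        events=events,
        is_debris=~non_debris,
        is_singlet=is_singlet,
        is_transfected=is_transfected,
        is_speck_positive=is_speck,
    )
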