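"""Expression-conditioned speck dose-response, 4PL fitting, and ASC50.

The speck-positive proportion is computed as a function of per-cell
GFP-NLRP3 expression by *step-binning*: a window of fixed width — one
quarter of the pooled expression range — is stepped through the transformed
expression axis in 0.1-unit increments, and within each window the numbers
of speck-positive and -negative cells are compared.  The resulting curve is
fitted with the four-parameter logistic

    f(x) = alpha + delta / (1 + exp(-eta * (x - phi)))

under the box constraints alpha in (0, 1), delta in (-inf, 1], eta free,
phi in (0, inf); phi is the midpoint (EC50).  A sample's score is

    ASC50 = (EC50_WT - EC50_sample) / EC50_WT

so a positive ASC50 means the variant reaches half-maximal speck formation
at lower expression than wild type (hyperactivity).

Window convention: windows are half-open [a, b) except the last, whose right
edge is clamped to the pooled maximum and closed, so the convention is
unambiguous and the whole curve is reproducible by brute-force enumeration.
The "MFI" axis is the transformed (default log10) per-event GFP intensity:
a 0.1 step is only meaningful on a compressed scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .simdata import four_pl

__all__ = [
    "TransformSpec", "StepBinConfig", "DoseResponseCurve", "FourPLFit",
    "FitConfig", "ASCScore", "transform_expression", "step_binned_curve",
    "octile_curve", "fit_4pl", "compute_asc50", "score_replicates",
    "CurveTooSparseError",
]


class CurveTooSparseError(ValueError):
    """Too few curve points to fit; the replicate is excluded from scoring."""


@dataclass
class TransformSpec:
    """Monotone compression of linear intensities before binning.

    ``log10`` clips at ``clip_floor`` (>= 1 a.u. so transformed values stay
    > 0, honoring the phi > 0 fit bound); ``asinh`` uses ``cofactor``.
    """

    method: str = "log10"
    cofactor: float = 150.0
    clip_floor: float = 1.0

    def validate(self) -> None:
        if self.method not in ("log10", "asinh"):
            raise ValueError(f"unknown transform {self.method!r}")
        if self.cofactor <= 0:
            raise ValueError("cofactor must be > 0")
        if self.method == "log10" and self.clip_floor < 1.0:
            raise ValueError("clip_floor must be >= 1 for log10")


def transform_expression(values, spec: TransformSpec | None = None) -> np.ndarray:
    spec = spec or TransformSpec()
    spec.validate()
    values = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("expression values must be finite")
    if np.any(values < 0):
        raise ValueError("expression values must be >= 0")
    if spec.method == "log10":
        return np.log10(np.clip(values, spec.clip_floor, None))
    return np.arcsinh(values / spec.cofactor)


@dataclass
class StepBinConfig:
    width_fraction: float = 0.25   # window width as fraction of range
    step: float = 0.1              # window advance on the transformed axis
    min_events_per_window: int = 20

    def validate(self) -> None:
        if not 0 < self.width_fraction <= 1:
            raise ValueError("width_fraction must be in (0, 1]")
        if not self.step > 0:
            raise ValueError("step must be > 0")
        if self.min_events_per_window < 1:
            raise ValueError("min_events_per_window must be >= 1")


@dataclass
class DoseResponseCurve:
    """Step-binned (x_center, n_pos, n_total, proportion) points."""

    points: pd.DataFrame               # columns x_center, n_pos, n_total, proportion
    range: tuple                       # (lo, hi) of the pooled transformed axis
    config: StepBinConfig | None = None

    @property
    def n_points(self) -> int:
        return len(self.points)

    @property
    def x(self) -> np.ndarray:
        return self.points["x_center"].to_numpy()

    @property
    def proportion(self) -> np.ndarray:
        return self.points["proportion"].to_numpy()

    def to_csv(self, path) -> None:
        self.points.to_csv(path, index=False)


def enumerate_windows(lo: float, hi: float, width: float, step: float):
    """Window list ``[(left, right, closed_right)]`` for the step-binning.

    Windows start at ``lo + k*step``; the first window whose right edge
    reaches ``hi`` is clamped to ``hi`` and closed, and iteration stops.
    """
    windows = []
    k = 0
    while True:
        left = lo + k * step
        right = left + width
        if right >= hi - 1e-12:
            windows.append((left, hi, True))
            break
        windows.append((left, right, False))
        k += 1
    return windows


def step_binned_curve(pos_x, neg_x, cfg: StepBinConfig | None = None) -> DoseResponseCurve:
    """Step-binned speck-positive proportion along the expression axis.

    ``pos_x``/``neg_x`` are the transformed expression values of
    speck-positive and speck-negative cells.  Windows with fewer than
    ``min_events_per_window`` events are omitted.
    """
    cfg = cfg or StepBinConfig()
    cfg.validate()
    pos_x = np.asarray(pos_x, dtype=float)
    neg_x = np.asarray(neg_x, dtype=float)
    pooled = np.concatenate([pos_x, neg_x])
    if len(pooled) == 0:
        raise ValueError("no events to bin")
    lo, hi = float(pooled.min()), float(pooled.max())
    if hi - lo <= 0:
        raise ValueError("zero expression range; all events identical")
    width = cfg.width_fraction * (hi - lo)

    pos_sorted = np.sort(pos_x)
    neg_sorted = np.sort(neg_x)
    rows = []
    for left, right, closed in enumerate_windows(lo, hi, width, cfg.step):
        side = "right" if closed else "left"
        n_pos = int(np.searchsorted(pos_sorted, right, side=side)
                    - np.searchsorted(pos_sorted, left, side="left"))
        n_neg = int(np.searchsorted(neg_sorted, right, side=side)
                    - np.searchsorted(neg_sorted, left, side="left"))
        n_total = n_pos + n_neg
        if n_total < cfg.min_events_per_window:
            continue
        rows.append({
            "x_center": (left + right) / 2.0,
            "n_pos": n_pos,
            "n_total": n_total,
            "proportion": n_pos / n_total,
        })
    points = pd.DataFrame(rows, columns=["x_center", "n_pos", "n_total", "proportion"])
    return DoseResponseCurve(points=points, range=(lo, hi), config=cfg)


def octile_curve(pos_x, neg_x, mode: str = "equal_count") -> DoseResponseCurve:
    """Eight-subgroup curve (the manual FlowJo-style analysis path).

    ``equal_count`` splits the pooled events at their octiles;
    ``equal_width`` uses eight equal-width bins across the pooled range.
    """
    if mode not in ("equal_count", "equal_width"):
        raise ValueError(f"unknown octile mode {mode!r}")
    pos_x = np.asarray(pos_x, dtype=float)
    neg_x = np.asarray(neg_x, dtype=float)
    pooled = np.concatenate([pos_x, neg_x])
    if len(pooled) < 8:
        raise ValueError("octile curve needs at least 8 events")
    lo, hi = float(pooled.min()), float(pooled.max())
    if mode == "equal_count":
        order = np.argsort(pooled, kind="stable")
        is_pos = np.concatenate([np.ones(len(pos_x), bool),
                                 np.zeros(len(neg_x), bool)])[order]
        x_sorted = pooled[order]
        splits = np.array_split(np.arange(len(pooled)), 8)
        rows = []
        for idx in splits:
            n_total = len(idx)
            n_pos = int(is_pos[idx].sum())
            rows.append({
                "x_center": float(np.mean(x_sorted[idx])),
                "n_pos": n_pos,
                "n_total": n_total,
                "proportion": n_pos / n_total,
            })
    else:
        edges = np.linspace(lo, hi, 9)
        rows = []
        for i in range(8):
            left, right = edges[i], edges[i + 1]
            if i == 7:
                in_pos = (pos_x >= left) & (pos_x <= right)
                in_neg = (neg_x >= left) & (neg_x <= right)
            else:
                in_pos = (pos_x >= left) & (pos_x < right)
                in_neg = (neg_x >= left) & (neg_x < right)
            n_pos, n_neg = int(in_pos.sum()), int(in_neg.sum())
            n_total = n_pos + n_neg
            rows.append({
                "x_center": (left + right) / 2.0,
                "n_pos": n_pos,
                "n_total": n_total,
                "proportion": n_pos / n_total if n_total else np.nan,
            })
        rows = [r for r in rows if r["n_total"] > 0]
    points = pd.DataFrame(rows, columns=["x_center", "n_pos", "n_total", "proportion"])
    return DoseResponseCurve(points=points, range=(lo, hi), config=None)


# ---------------------------------------------------------------------------
# 4PL fit
# ---------------------------------------------------------------------------

_EPS = 1e-9


@dataclass
class FitConfig:
    weighted: bool = False        # binomial weights (off: unweighted, default)
    xtol: float = 1e-12
    ftol: float = 1e-12
    gtol: float = 1e-12
    phi_boundary_factor: float = 10.0  # phi < factor*xtol marks non-convergence


@dataclass
class FourPLFit:
    alpha: float
    delta: float
    eta: float
    phi: float
    converged: bool
    rss: float
    n_points: int

    def predict(self, x):
        return four_pl(x, self.alpha, self.delta, self.eta, self.phi)

    @property
    def ec50(self) -> float:
        return self.phi

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha, "delta": self.delta, "eta": self.eta,
            "phi": self.phi, "converged": self.converged,
            "rss": self.rss, "n_points": self.n_points,
        }


def fit_4pl(curve: DoseResponseCurve, cfg: FitConfig | None = None) -> FourPLFit:
    """Box-constrained least squares fit of the 4PL to a curve.

    Initialisation: alpha0 = min proportion clipped into (0, 1); delta0 =
    max - min proportion; phi0 = x at the proportion nearest midrange;
    eta0 sign from the rank correlation of (x, proportion).  Two steepness
    starts are tried and the lower-RSS solution kept.
    """
    cfg = cfg or FitConfig()
    if curve.n_points < 4:
        raise CurveTooSparseError(
            f"curve has {curve.n_points} points; at least 4 are required"
        )
    x = curve.x
    p = curve.proportion
    n = curve.points["n_total"].to_numpy()

    alpha0 = float(np.clip(p.min(), _EPS, 1 - _EPS))
    delta0 = float(np.clip(p.max() - p.min(), _EPS, 1.0))
    mid = (p.max() + p.min()) / 2.0
    phi0 = float(np.clip(x[np.argmin(np.abs(p - mid))], _EPS, None))
    rho = stats.spearmanr(x, p).statistic
    sign = -1.0 if (rho is not None and not math.isnan(rho) and rho < 0) else 1.0

    if cfg.weighted:
        w = np.sqrt(n)
    else:
        w = np.ones_like(p)

    def residuals(theta):
        return w * (four_pl(x, *theta) - p)

    lower = [_EPS, -np.inf, -np.inf, _EPS]
    upper = [1 - _EPS, 1.0, np.inf, np.inf]
    best = None
    for eta0 in (sign * 1.0, sign * 4.0):
        theta0 = [alpha0, delta0, eta0, phi0]
        try:
            res = optimize.least_squares(
                residuals, theta0, bounds=(lower, upper), method="trf",
                xtol=cfg.xtol, ftol=cfg.ftol, gtol=cfg.gtol, max_nfev=2000,
            )
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        return FourPLFit(alpha0, delta0, sign, phi0, False, float("inf"),
                         curve.n_points)

    alpha, delta, eta, phi = (float(v) for v in best.x)
    rss = float(2 * best.cost)
    converged = bool(best.success)
    # phi pinned at its lower bound is a degenerate EC50, not an estimate
    if phi < cfg.phi_boundary_factor * max(cfg.xtol, _EPS):
        converged = False
    return FourPLFit(alpha, delta, eta, phi, converged, rss, curve.n_points)


# ---------------------------------------------------------------------------
# ASC50
# ---------------------------------------------------------------------------

def compute_asc50(fit_sample: FourPLFit, fit_wt: FourPLFit) -> float:
    """Relative EC50 difference ``(phi_WT - phi_sample) / phi_WT``.

    Positive values mean the sample reaches half-maximal speck formation at
    lower expression than wild type.
    """
    if not (fit_sample.converged and fit_wt.converged):
        raise ValueError("ASC50 requires converged fits for sample and WT control")
    if not fit_wt.phi > 0:
        raise ValueError("WT EC50 must be > 0")
    return (fit_wt.phi - fit_sample.phi) / fit_wt.phi


@dataclass
class ASCScore:
    """Replicate-aggregated ASC50 for one variant under one condition."""

    variant_label: str
    condition: str
    values: list = field(default_factory=list)
    single_replicate: bool = False

    @property
    def n_replicates(self) -> int:
        return len(self.values)

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    @property
    def sem(self) -> float:
        if len(self.values) < 2:
            return 0.0
        return float(np.std(self.values, ddof=1) / math.sqrt(len(self.values)))

    def to_dict(self) -> dict:
        return {
            "variant_label": self.variant_label,
            "condition": self.condition,
            "mean_asc50": self.mean,
            "sem": self.sem,
            "n_replicates": self.n_replicates,
            "single_replicate": self.single_replicate,
            "values": list(self.values),
        }


def score_replicates(asc50_values, variant_label: str = "",
                     condition: str = "untreated") -> ASCScore:
    """Aggregate per-replicate ASC50 values into mean +/- SEM."""
    values = [float(v) for v in asc50_values]
    if not values:
        raise ValueError("no replicate ASC50 values to aggregate")
    return ASCScore(
        variant_label=variant_label,
        condition=condition,
        values=values,
        single_replicate=(len(values) == 1),
    )
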