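"""End-to-end orchestration: sample sheet -> QC -> gates -> curves -> scores.

Per batch the pipeline (i) runs QC on every sample, (ii) derives the gate
set from the batch's WT control, (iii) applies it across the sample set,
(iv) builds the step-binned dose-response per sample and fits the
constrained 4PL, (v) converts each sample's EC50 to ASC50 against the
matched WT control, (vi) aggregates replicates and computes condition
contrasts, response flags and classification recommendations.

The WT reference for ASC50 is, by default, the WT control measured under
the *same condition* (and same replicate when available); ``reference =
"untreated_wt"`` scores every sample against the untreated WT instead.
Samples that fail QC or whose curve is too sparse are excluded and logged
with the reason; a batch without a converged WT fit is skipped and
reported.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .dose_response import (
    ASCScore,
    CurveTooSparseError,
    FitConfig,
    StepBinConfig,
    TransformSpec,
    compute_asc50,
    fit_4pl,
    score_replicates,
    step_binned_curve,
    transform_expression,
)
from .gating import GateDerivationError, GatingConfig, apply_gates, derive_gates
from .io import EventTable, SampleSheet, read_events
from .qc import QCConfig, TooFewEventsError, run_qc
from .variant_scoring import (
    ClassifierConfig,
    UNTREATED,
    classify_variant,
    contrast_conditions,
    flag_response,
)

logger = logging.getLogger("speckscore")


@dataclass
class RunConfig:
    """Serializable configuration for a full pipeline run."""

    qc: QCConfig = field(default_factory=QCConfig)
    gating: GatingConfig = field(default_factory=GatingConfig)
    transform: TransformSpec = field(default_factory=TransformSpec)
    binning: StepBinConfig = field(default_factory=StepBinConfig)
    fit: FitConfig = field(default_factory=FitConfig)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    reference: str = "same_condition"   # or "untreated_wt"
    contrast_method: str = "student"
    out_dir: str | None = None
    seed: int = 0
    verbosity: str = "INFO"

    def validate(self) -> None:
        if self.reference not in ("same_condition", "untreated_wt"):
            raise ValueError("reference must be 'same_condition' or 'untreated_wt'")
        self.qc.validate()
        self.transform.validate()
        self.binning.validate()
        self.classifier.validate()

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1))

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        raw = json.loads(Path(path).read_text())
        def build(klass, key):
            kwargs = raw.get(key, {})
            if "speck_metric_means" in kwargs:
                kwargs["speck_metric_means"] = tuple(kwargs["speck_metric_means"])
            if "scatter_channels" in kwargs:
                kwargs["scatter_channels"] = tuple(kwargs["scatter_channels"])
            if "fluorescence_channels" in kwargs:
                kwargs["fluorescence_channels"] = tuple(kwargs["fluorescence_channels"])
            return klass(**kwargs)
        return cls(
            qc=build(QCConfig, "qc"),
            gating=build(GatingConfig, "gating"),
            transform=build(TransformSpec, "transform"),
            binning=build(StepBinConfig, "binning"),
            fit=build(FitConfig, "fit"),
            classifier=build(ClassifierConfig, "classifier"),
            reference=raw.get("reference", "same_condition"),
            contrast_method=raw.get("contrast_method", "student"),
            out_dir=raw.get("out_dir"),
            seed=raw.get("seed", 0),
            verbosity=raw.get("verbosity", "INFO"),
        )


@dataclass
class ReportBundle:
    """All per-run outputs: scores, contrasts, recommendations, funnels."""

    scores: pd.DataFrame
    contrasts: pd.DataFrame
    recommendations: pd.DataFrame
    sample_log: pd.DataFrame
    qc_reports: dict = field(default_factory=dict)
    gate_sets: dict = field(default_factory=dict)
    curves: dict = field(default_factory=dict)
    fits: dict = field(default_factory=dict)
    score_objects: dict = field(default_factory=dict)   # (variant, condition) -> ASCScore
    skipped_batches: list = field(default_factory=list)

    def write(self, out_dir) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        self.scores.to_csv(out_dir / "scores.csv", index=False)
        self.contrasts.to_csv(out_dir / "contrasts.csv", index=False)
        self.recommendations.to_csv(out_dir / "recommendations.csv", index=False)
        self.sample_log.to_csv(out_dir / "sample_log.csv", index=False)
        (out_dir / "scores.json").write_text(
            self.scores.to_json(orient="records", indent=1))
        for batch, gates in self.gate_sets.items():
            gates.to_json(out_dir / f"gates_{batch}.json")
        qc_payload = {sid: rep.to_dict() for sid, rep in self.qc_reports.items()}
        (out_dir / "qc_reports.json").write_text(json.dumps(qc_payload, indent=1))
        curve_dir = out_dir / "curves"
        curve_dir.mkdir(exist_ok=True)
        for sid, curve in self.curves.items():
            curve.to_csv(curve_dir / f"{sid}.csv")


def _score_sample(gated, cfg: RunConfig):
    """Transformed dose-response curve and 4PL fit for one gated sample."""
    pos_lin, neg_lin = gated.expression("GFP-A")
    pos_x = transform_expression(pos_lin, cfg.transform)
    neg_x = transform_expression(neg_lin, cfg.transform)
    curve = step_binned_curve(pos_x, neg_x, cfg.binning)
    fit = fit_4pl(curve, cfg.fit)
    return curve, fit


def run_pipeline(sheet: SampleSheet, cfg: RunConfig | None = None,
                 tables: dict | None = None,
                 base_dir=None,
                 priors: dict | None = None) -> ReportBundle:
    """Run the full analysis for every batch in the sample sheet.

    ``tables`` may supply in-memory :class:`EventTable` objects keyed by the
    sheet's ``file`` column (simulation workflows); otherwise files are read
    from ``base_dir``.  ``priors`` maps variant labels to prior
    classifications for the recommendation step.
    """
    cfg = cfg or RunConfig()
    cfg.validate()
    priors = priors or {}
    logging.basicConfig(level=getattr(logging, cfg.verbosity.upper(), logging.INFO))

    qc_reports: dict = {}
    gate_sets: dict = {}
    curves: dict = {}
    fits: dict = {}
    log_rows: list = []
    skipped_batches: list = []
    sample_scores: list = []   # per-sample rows with asc50

    rows = sheet.rows
    for batch, batch_rows in rows.groupby("batch", sort=False):
        # ---- load + QC ---------------------------------------------------
        cleaned: dict = {}
        for _, row in batch_rows.iterrows():
            key = row["file"]
            if tables is not None and key in tables:
                table = tables[key]
            else:
                path = Path(base_dir or ".") / key
                table = read_events(path)
            entry = {
                "sample_id": table.sample_id or key,
                "batch": batch,
                "variant_label": row["variant_label"],
                "condition": row["condition"],
                "replicate": str(row["replicate"]),
                "role": row["role"],
                "n_events": table.n_events,
            }
            try:
                clean, report = run_qc(table, cfg.qc)
            except TooFewEventsError as exc:
                entry.update(status="excluded", reason=str(exc))
                log_rows.append(entry)
                continue
            qc_reports[entry["sample_id"]] = report
            entry["n_after_qc"] = clean.n_events
            cleaned[entry["sample_id"]] = (clean, entry)

        # ---- gates from the batch WT control -----------------------------
        # prefer the untreated WT, lowest replicate id, that survived QC
        wt_candidates = sorted(
            (sid for sid, (_t, ent) in cleaned.items()
             if ent["role"] == "wt_control"),
            key=lambda sid: (cleaned[sid][1]["condition"] != UNTREATED,
                             cleaned[sid][1]["replicate"]),
        )
        control_id = wt_candidates[0] if wt_candidates else None
        if control_id is None:
            skipped_batches.append((batch, "no WT control survived QC"))
            for _, entry in cleaned.values():
                entry.update(status="excluded", reason="batch skipped: no WT control")
                log_rows.append(entry)
            continue
        try:
            gates = derive_gates(cleaned[control_id][0], cfg.gating)
        except GateDerivationError as exc:
            skipped_batches.append((batch, f"gate derivation failed: {exc}"))
            for _, entry in cleaned.values():
                entry.update(status="excluded", reason=f"batch skipped: {exc}")
                log_rows.append(entry)
            continue
        gate_sets[batch] = gates

        # ---- gating + curves + fits --------------------------------------
        batch_fits: dict = {}
        for sid, (table, entry) in cleaned.items():
            gated = apply_gates(table, gates)
            counts = gated.counts()
            entry.update(
                n_singlet=counts["n_singlet"],
                n_transfected=counts["n_transfected"],
                n_speck_positive=counts["n_speck_positive"],
            )
            try:
                curve, fit = _score_sample(gated, cfg)
            except (CurveTooSparseError, ValueError) as exc:
                entry.update(status="excluded", reason=str(exc))
                log_rows.append(entry)
                continue
            curves[sid] = curve
            fits[sid] = fit
            entry["n_windows"] = curve.n_points
            entry["fit_converged"] = fit.converged
            entry["phi"] = fit.phi
            batch_fits[sid] = (fit, entry)
            logger.info(
                "%s: %d events -> %d after QC -> %d singlets -> %d transfected "
                "-> %d windows -> fit %s",
                sid, entry["n_events"], entry["n_after_qc"], counts["n_singlet"],
                counts["n_transfected"], curve.n_points,
                "ok" if fit.converged else "FAILED",
            )

        # ---- WT references ------------------------------------------------
        wt_fits: dict = {}   # (condition, replicate) -> fit
        for sid, (fit, entry) in batch_fits.items():
            if entry["role"] == "wt_control" and fit.converged:
                wt_fits[(entry["condition"], entry["replicate"])] = fit
        if not wt_fits:
            skipped_batches.append((batch, "no converged WT fit"))
            for sid, (fit, entry) in batch_fits.items():
                entry.update(status="excluded", reason="batch skipped: no converged WT fit")
                log_rows.append(entry)
            continue

        def wt_reference(condition: str, replicate: str):
            cond = UNTREATED if cfg.reference == "untreated_wt" else condition
            for key in ((cond, replicate),):
                if key in wt_fits:
                    return wt_fits[key]
            same_cond = [f for (c, _), f in wt_fits.items() if c == cond]
            if same_cond:
                return same_cond[0]
            if cond != UNTREATED:
                # fall back to untreated WT when a treated control is absent
                untr = [f for (c, _), f in wt_fits.items() if c == UNTREATED]
                if untr:
                    return untr[0]
            return None

        # ---- ASC50 per sample ---------------------------------------------
        for sid, (fit, entry) in batch_fits.items():
            if not fit.converged:
                entry.update(status="excluded", reason="4PL fit did not converge")
                log_rows.append(entry)
                continue
            ref = wt_reference(entry["condition"], entry["replicate"])
            if ref is None:
                entry.update(status="excluded", reason="no WT reference for condition")
                log_rows.append(entry)
                continue
            asc50 = compute_asc50(fit, ref)
            entry.update(status="scored", reason="", asc50=asc50)
            log_rows.append(entry)
            sample_scores.append({
                "batch": batch,
                "variant_label": entry["variant_label"],
                "condition": entry["condition"],
                "replicate": entry["replicate"],
                "role": entry["role"],
                "asc50": asc50,
            })

    # ---- replicate aggregation -------------------------------------------
    per_sample = pd.DataFrame(sample_scores)
    score_objects: dict = {}
    score_rows: list = []
    if len(per_sample):
        for (variant, condition), grp in per_sample.groupby(
                ["variant_label", "condition"], sort=False):
            score = score_replicates(grp["asc50"].tolist(), variant, condition)
            score_objects[(variant, condition)] = score
            score_rows.append({
                "variant_label": variant,
                "condition": condition,
                "mean_asc50": score.mean,
                "sem": score.sem,
                "n_replicates": score.n_replicates,
            })
    scores_df = pd.DataFrame(
        score_rows, columns=["variant_label", "condition", "mean_asc50",
                             "sem", "n_replicates"])

    # ---- contrasts, flags, classification --------------------------------
    contrast_rows: list = []
    reco_rows: list = []
    variants = scores_df["variant_label"].unique() if len(scores_df) else []
    for variant in variants:
        my_scores = {c: s for (v, c), s in score_objects.items() if v == variant}
        contrasts: dict = {}
        for condition, score in my_scores.items():
            if condition == UNTREATED:
                continue
            base = my_scores.get(UNTREATED)
            if base is None or base.n_replicates < 2 or score.n_replicates < 2:
                continue
            result = contrast_conditions(base, score, cfg.contrast_method,
                                         cfg.classifier.alpha)
            contrasts[condition] = result
            contrast_rows.append(result.to_dict())
        flags = flag_response(contrasts, my_scores, cfg.classifier)
        basal = my_scores.get(UNTREATED) or next(iter(my_scores.values()))
        reco = classify_variant(basal, priors.get(variant, "unknown"),
                                cfg.classifier)
        row = reco.to_dict()
        row.update(
            mean_asc50=basal.mean, sem=basal.sem,
            n_replicates=basal.n_replicates, condition=basal.condition,
        )
        row.update(flags)
        reco_rows.append(row)

    contrasts_df = pd.DataFrame(contrast_rows, columns=[
        "variant_label", "condition_a", "condition_b", "mean_a", "mean_b",
        "sem_a", "sem_b", "n_a", "n_b", "delta_mean", "t_statistic",
        "p_value", "significant", "degenerate"])
    reco_df = pd.DataFrame(reco_rows)
    log_df = pd.DataFrame(log_rows)

    bundle = ReportBundle(
        scores=scores_df,
        contrasts=contrasts_df,
        recommendations=reco_df,
        sample_log=log_df,
        qc_reports=qc_reports,
        gate_sets=gate_sets,
        curves=curves,
        fits=fits,
        score_objects=score_objects,
        skipped_batches=skipped_batches,
    )
    if cfg.out_dir:
        bundle.write(cfg.out_dir)
    return bundle


def plot_curve(curve, fit=None, path=None, title: str = ""):
    """Dose-response points (optionally with the 4PL fit) as PNG/SVG."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.scatter(curve.x, curve.proportion, s=18, color="#1f6fb4",
               label="step-binned proportion")
    if fit is not None:
        xs = np.linspace(curve.range[0], curve.range[1], 200)
        ax.plot(xs, fit.predict(xs), color="#c23b22",
                label=f"4PL fit (EC50={fit.phi:.2f})")
    ax.set_xlabel("transformed GFP-NLRP3 expression")
    ax.set_ylabel("speck-positive proportion")
    ax.set_ylim(-0.02, 1.02)
    if title:
        ax.set_title(title)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
        return None
    return fig
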