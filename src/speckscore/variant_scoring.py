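"""Variant-level interpretation of ASC50 scores.

Covers the symptomatic-variant cutoff (default 0.281, the lower bound of the
95% confidence interval of ASC50 over symptomatic variants), classification
recommendations, paired-condition contrasts (two-tailed t-tests between
untreated and treated replicate scores), treatment-response flags
(nigericin hypersensitivity, cold sensitivity, MCC950 resistance), and
protein-level variant/domain annotation for NLRP3.

The tool reports *functional evidence only*: a recommendation states what
the assay supports, never a clinical classification, which additionally
requires literature review and clinical context.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .dose_response import ASCScore

# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

PRIOR_CLASSES = ("pathogenic", "likely_pathogenic", "VUS", "likely_benign",
                 "benign", "unknown")

FUNCTIONAL_CALLS = ("supports_pathogenic", "supports_benign_review",
                    "borderline", "below_cutoff", "not_scorable")


@dataclass
class ClassifierConfig:
    pathogenicity_threshold: float = 0.281
    borderline_rule: bool = True
    ci_level: float = 0.95
    ci_method: str = "t"          # or "normal"
    alpha: float = 0.05           # significance level for contrasts/flags
    multiple_testing: str | None = None   # None or "bh"

    def validate(self) -> None:
        if not np.isfinite(self.pathogenicity_threshold):
            raise ValueError("pathogenicity_threshold must be finite")
        if not 0 < self.ci_level < 1:
            raise ValueError("ci_level must be in (0, 1)")
        if self.ci_method not in ("t", "normal"):
            raise ValueError("ci_method must be 't' or 'normal'")


# ---------------------------------------------------------------------------
# Symptomatic cutoff
# ---------------------------------------------------------------------------

def symptomatic_threshold(asc50_means, cfg: ClassifierConfig | None = None) -> float:
    """Lower bound of the CI of mean ASC50 over symptomatic variants.

    Returns ``mean - q * sem`` where q is the two-sided ``ci_level``
    quantile (Student-t with n-1 df, or normal).
    """
    cfg = cfg or ClassifierConfig()
    cfg.validate()
    values = np.asarray(list(asc50_means), dtype=float)
    n = len(values)
    if n < 2:
        raise ValueError("need at least 2 symptomatic variants for a CI")
    mean = values.mean()
    sem = values.std(ddof=1) / np.sqrt(n)
    tail = (1 + cfg.ci_level) / 2
    if cfg.ci_method == "t":
        q = stats.t.ppf(tail, df=n - 1)
    else:
        q = stats.norm.ppf(tail)
    return float(mean - q * sem)


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

@dataclass
class Recommendation:
    variant_label: str
    prior_classification: str
    functional_call: str
    rationale: str

    def to_dict(self) -> dict:
        return {
            "variant_label": self.variant_label,
            "prior_classification": self.prior_classification,
            "functional_call": self.functional_call,
            "rationale": self.rationale,
        }


def classify_variant(score: ASCScore, prior: str = "unknown",
                     cfg: ClassifierConfig | None = None) -> Recommendation:
    """Recommendation from one replicate-aggregated ASC50 score.

    Rules (threshold T = ``pathogenicity_threshold``):

    * no finite replicates -> ``not_scorable``;
    * |mean - T| <= SEM (borderline rule on) -> ``borderline``;
    * mean > T -> ``supports_pathogenic``;
    * mean < T with a pathogenic/likely-pathogenic prior ->
      ``supports_benign_review``;
    * mean < T otherwise -> ``below_cutoff`` (no functional support for
      pathogenicity; prior stands).
    """
    cfg = cfg or ClassifierConfig()
    cfg.validate()
    if prior not in PRIOR_CLASSES:
        prior = "unknown"
    thr = cfg.pathogenicity_threshold

    if score.n_replicates == 0 or not np.isfinite(score.mean):
        call, why = "not_scorable", "no converged replicate fits"
    elif cfg.borderline_rule and abs(score.mean - thr) <= score.sem:
        call = "borderline"
        why = (f"mean ASC50 {score.mean:.3f} within one SEM "
               f"({score.sem:.3f}) of the cutoff {thr}")
    elif score.mean > thr:
        call = "supports_pathogenic"
        why = f"mean ASC50 {score.mean:.3f} > cutoff {thr}"
    elif prior in ("pathogenic", "likely_pathogenic"):
        call = "supports_benign_review"
        why = (f"mean ASC50 {score.mean:.3f} < cutoff {thr} despite "
               f"{prior} prior; review recommended")
    else:
        call = "below_cutoff"
        why = f"mean ASC50 {score.mean:.3f} < cutoff {thr}; prior stands"
    return Recommendation(
        variant_label=score.variant_label,
        prior_classification=prior,
        functional_call=call,
        rationale=why + " (functional evidence only)",
    )


# ---------------------------------------------------------------------------
# Condition contrasts
# ---------------------------------------------------------------------------

@dataclass
class ContrastResult:
    variant_label: str
    condition_a: str
    condition_b: str
    mean_a: float
    mean_b: float
    sem_a: float
    sem_b: float
    n_a: int
    n_b: int
    delta_mean: float
    t_statistic: float
    p_value: float
    significant: bool
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "variant_label", "condition_a", "condition_b", "mean_a", "mean_b",
            "sem_a", "sem_b", "n_a", "n_b", "delta_mean", "t_statistic",
            "p_value", "significant", "degenerate")}


def contrast_conditions(scores_a: ASCScore, scores_b: ASCScore,
                        method: str = "student",
                        alpha: float = 0.05) -> ContrastResult:
    """Two-tailed t-test between two replicate ASC50 sets.

    ``student`` pools variances (the conventional default of the original
    analysis software); ``welch`` drops the equal-variance assumption.
    Degenerate zero-variance groups: identical groups give t = 0, p = 1;
    unequal constant groups are flagged and reported at the machine floor.
    """
    if method not in ("student", "welch"):
        raise ValueError("method must be 'student' or 'welch'")
    a = np.asarray(scores_a.values, dtype=float)
    b = np.asarray(scores_b.values, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 replicates")

    degenerate = False
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        degenerate = True
        if a.mean() == b.mean():
            t_stat, p = 0.0, 1.0
        else:
            t_stat = np.inf if b.mean() < a.mean() else -np.inf
            p = float(np.finfo(float).tiny)  # below any meaningful alpha
    else:
        t_stat, p = stats.ttest_ind(a, b, equal_var=(method == "student"))
        t_stat, p = float(t_stat), float(p)

    return ContrastResult(
        variant_label=scores_a.variant_label,
        condition_a=scores_a.condition,
        condition_b=scores_b.condition,
        mean_a=float(a.mean()), mean_b=float(b.mean()),
        sem_a=scores_a.sem, sem_b=scores_b.sem,
        n_a=len(a), n_b=len(b),
        delta_mean=float(b.mean() - a.mean()),
        t_statistic=t_stat,
        p_value=p,
        significant=bool(p < alpha),
        degenerate=degenerate,
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (optional, off by default)."""
    p = np.asarray(list(p_values), dtype=float)
    m = len(p)
    order = np.argsort(p)
    ranked = p[order] * m / (np.arange(m) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.clip(ranked, 0, 1)
    return out


# ---------------------------------------------------------------------------
# Treatment-response flags
# ---------------------------------------------------------------------------

#: condition names with built-in flag semantics
NIGERICIN = "nigericin"
COLD = "cold_32C"
MCC950_CONDITIONS = ("mcc950_4h", "mcc950_12h")
UNTREATED = "untreated"


def flag_response(contrasts: dict, scores: dict,
                  cfg: ClassifierConfig | None = None) -> dict:
    """Treatment-response flags for one variant.

    Parameters
    ----------
    contrasts
        Map ``condition -> ContrastResult`` of (untreated, condition) tests.
    scores
        Map ``condition -> ASCScore`` (must include the treated conditions).

    Rules
    -----
    * ``nigericin_hypersensitive`` — significant *increase* under nigericin.
    * ``cold_sensitive`` — significant increase at 32 C versus 37 C.
    * ``mcc950_resistant`` — under MCC950 (longest tested exposure): no
      significant decrease AND the treated mean remains above the
      pathogenicity cutoff.  (Operational rule: "remains resistant" means
      the inhibitor neither lowered the score nor pushed it below the
      level that flags hyperactivity.)

    Missing condition pairs yield ``None`` (undetermined).
    """
    cfg = cfg or ClassifierConfig()
    flags: dict = {}

    c = contrasts.get(NIGERICIN)
    flags["nigericin_hypersensitive"] = (
        None if c is None else bool(c.significant and c.delta_mean > 0)
    )

    c = contrasts.get(COLD)
    flags["cold_sensitive"] = (
        None if c is None else bool(c.significant and c.delta_mean > 0)
    )

    mcc = [cond for cond in MCC950_CONDITIONS if cond in contrasts]
    if not mcc:
        flags["mcc950_resistant"] = None
    else:
        cond = mcc[-1]  # longest exposure present
        c = contrasts[cond]
        decreased = c.significant and c.delta_mean < 0
        treated = scores.get(cond)
        still_active = (treated is not None
                        and treated.mean > cfg.pathogenicity_threshold)
        flags["mcc950_resistant"] = bool((not decreased) and still_active)
    return flags


# ---------------------------------------------------------------------------
# Variant annotation
# ---------------------------------------------------------------------------

_AA = set("ACDEFGHIKLMNPQRSTVWY")
_VARIANT_RE = re.compile(r"^([A-Z])(\d+)(?:([A-Z*])|(fs)|(del))$")


@dataclass
class VariantAnnotation:
    variant_label: str
    position: int
    ref: str
    alt: str | None
    kind: str              # missense | nonsense | frameshift | deletion
    domain: str | None = None
    domain_group: str | None = None


def parse_variant_name(label: str) -> VariantAnnotation:
    """Parse a protein-level variant label like R262W, R556*, F257fs, T440del."""
    m = _VARIANT_RE.match(label.strip())
    if not m:
        raise ValueError(f"unparseable variant label {label!r}")
    ref, pos, alt, fs, dele = m.groups()
    if ref not in _AA:
        raise ValueError(f"{label!r}: unknown reference residue {ref!r}")
    position = int(pos)
    if position < 1:
        raise ValueError(f"{label!r}: position must be >= 1")
    if fs:
        kind, alt_out = "frameshift", None
    elif dele:
        kind, alt_out = "deletion", None
    elif alt == "*":
        kind, alt_out = "nonsense", "*"
    else:
        if alt not in _AA:
            raise ValueError(f"{label!r}: unknown alternate residue {alt!r}")
        kind, alt_out = "missense", alt
    return VariantAnnotation(label, position, ref, alt_out, kind)


#: default NLRP3 domain boundary table (1-based inclusive; literature-derived,
#: user-replaceable).  Subdomain -> parent group.
DEFAULT_DOMAIN_TABLE = [
    # (subdomain, group, start, end)
    ("PYD", "PYD", 1, 95),
    ("linker", "linker", 96, 130),
    ("FISNA", "NACHT", 131, 216),
    ("NBD", "NACHT", 217, 372),
    ("HD1", "NACHT", 373, 434),
    ("WHD", "NACHT", 435, 541),
    ("HD2", "NACHT", 542, 651),
    ("trLRR", "LRR", 652, 686),
    ("cnLRR", "LRR", 687, 1036),
]


def load_domain_table(path) -> list:
    """Read a domain table TSV (domain, group, start, end; 1-based inclusive)."""
    rows = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0].lower() in ("domain", "subdomain"):
                continue
            name, group, start, end = parts[:4]
            rows.append((name, group, int(start), int(end)))
    return rows


def save_domain_table(table, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("domain\tgroup\tstart\tend\n")
        for name, group, start, end in table:
            fh.write(f"{name}\t{group}\t{start}\t{end}\n")


def annotate_domain(position: int, table=None) -> tuple:
    """(subdomain, group) of the first table interval containing ``position``."""
    table = table if table is not None else DEFAULT_DOMAIN_TABLE
    if position < 1:
        raise ValueError("position must be >= 1")
    for name, group, start, end in table:
        if start <= position <= end:
            return name, group
    span = max(end for *_, end in table)
    raise ValueError(f"position {position} is beyond the table span (1-{span})")


def annotate_variant(label: str, table=None) -> VariantAnnotation:
    ann = parse_variant_name(label)
    ann.domain, ann.domain_group = annotate_domain(ann.position, table)
    return ann


def domain_density(labels, table=None, flagged=None) -> dict:
    """Variants per residue for each domain (hotspot-density summary).

    ``labels`` are variant labels; ``flagged`` optionally restricts the count
    to a subset (e.g. strongly active variants).  Unparseable labels are
    skipped.  Returns ``domain -> {count, length, per_residue}``.
    """
    table = table if table is not None else DEFAULT_DOMAIN_TABLE
    keep = set(flagged) if flagged is not None else None
    counts = {name: 0 for name, *_ in table}
    for label in labels:
        if keep is not None and label not in keep:
            continue
        try:
            ann = annotate_variant(label, table)
        except ValueError:
            continue
        counts[ann.domain] += 1
    out = {}
    for name, group, start, end in table:
        length = end - start + 1
        out[name] = {
            "group": group,
            "count": counts[name],
            "length": length,
            "per_residue": counts[name] / length,
        }
    return out
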