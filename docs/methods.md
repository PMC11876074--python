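# Methods

## The assay model

The pipeline analyses a per-cell functional readout of NLRP3 activity:
HEK293T cells stably expressing BFP-tagged ASC are transfected with a
GFP-tagged NLRP3 variant; on inflammasome assembly the diffuse ASC signal
condenses into a single speck. On a conventional cytometer the speck state
is summarised by a scalar channel (`speck_metric` — in practice a
pulse-shape statistic such as a height/area ratio or width of the BFP
signal; the algorithm is agnostic to which proxy a lab maps onto it).

The probability that a cell carries a speck rises with its NLRP3
expression. With x the log10 GFP-NLRP3 intensity, the expected
speck-positive proportion follows a four-parameter logistic

    f(x) = alpha + delta / (1 + exp(-eta * (x - phi)))

whose midpoint phi is the expression level producing half-maximal speck
formation (EC50). Variant activity is a *left shift* of this curve:
a hyperactive variant needs less NLRP3 to assemble inflammasomes. The
score

    ASC50 = (EC50_WT - EC50_sample) / EC50_WT

is the relative EC50 difference against the wild-type control of the same
batch; positive values indicate hyperactivity, values near zero wild-type
behaviour, negative values loss of function. Because the reference is
measured in the same batch (and, by default, under the same condition),
instrument scale and batch effects largely cancel; ASC50 is nevertheless
not invariant to affine rescaling of the expression axis, which is why a
matched WT control is mandatory in every batch.

## Pipeline stages and parameters

### Quality control (`qc`)

Events are binned by acquisition time (`time_bin_s`, default 1 s) and three
rules applied:

1. **Flow rate** — bins whose event count deviates from the median by more
   than `rate_mad_z` (default 5) normal-consistent MADs are removed (IQR
   fallback when the MAD is zero; no flags when both are zero).
2. **Signal acquisition** — per-bin medians of each fluorescence channel
   are compared with the grand median at `drift_mad_z` (default 5) MADs.
   Outlier bins must persist for at least `drift_min_run` (default 2)
   consecutive bins: genuine acquisition drift is serially correlated in
   time, whereas isolated one-bin median excursions arise from sampling
   noise — the per-bin median of a bimodal channel (background +
   transfected mixture) is heavy-tailed even under clean acquisition.
3. **Dynamic range** — events at or above `(1 - range_margin)` times the
   detector range (default margin 0, i.e. saturated values only) or at/below
   zero are removed.

Rules are evaluated on the input independently and the union removed, so
the report reconciles exactly (`n_output = n_input - |union|`). Samples
with fewer than `min_events` (default 200) are flagged as unscorable
rather than processed. These explicit rules replace changepoint-based QC:
they are transparent, individually testable against injected anomalies,
and reproduce the three stated criteria (rate, acquisition, range).

### Gating (`gating`)

All gates come from one wild-type control per batch and are applied
unchanged to every sample, which is what makes EC50s comparable within a
batch.

* **Debris** — per scatter channel, a Gaussian KDE (Silverman bandwidth) on
  the log10 axis; the cutoff is the deepest density valley below the main
  mode, falling back to a fixed quantile (default 5%) when no sub-mode
  exists. A control whose main FSC-A mode sits below `min_cell_scatter`
  (default 1e4 a.u.) is rejected as lacking a cell population.
* **Singlets** — robust Siegel line fit of FSC-H on FSC-A over non-debris
  events (subsampled to 4000 points; the repeated-median estimator is
  quadratic in n), accepting events within `singlet_band_mads` (default 4)
  residual MADs. Doublets sum area channels but not height, so they fall
  below the band.
* **Speck threshold** — minimum-density valley of the speck-metric KDE
  between its two largest modes, ties toward the lower value. When the KDE
  shows a single mode an Otsu threshold is tried and accepted only if it
  sits in a genuine density dip (flagged in the gate provenance); otherwise
  the control is rejected as lacking a speck-positive population.
* **GFP-positive cutoff** — 99.5th percentile of GFP-A over the
  speck-negative low-GFP (untransfected background) population. By
  construction ~0.5% of background events exceed it; a pure-background
  sample therefore shows a small, bounded false-positive transfection rate
  rather than exactly zero.

Events exactly at any threshold fall on the negative side (half-open
intervals); gate application is a pure function of (events, gate set).

### Dose–response and fitting (`dose_response`)

Expression is transformed before binning (default log10 with values clipped
at 1 a.u., keeping transformed values > 0 and hence compatible with the
phi > 0 bound; an asinh option with configurable cofactor exists). The
0.1-unit step is only meaningful on such a compressed axis.

**Step-binning.** Over the pooled speck-positive and -negative transformed
expressions with range [lo, hi], a window of width `width_fraction`
(default 1/4) times the range advances from lo in `step` (default 0.1)
increments. Windows are half-open [a, b); the first window whose right edge
reaches hi is clamped to hi and closed, so every event including the
maximum is countable and the whole construction can be reproduced by naive
enumeration. Windows with fewer than `min_events_per_window` (default 20)
events are omitted — sparse tail windows otherwise contribute
high-variance proportions that dominate the fit. Each reported point is
(window centre, n_pos, n_total, proportion).

**Octile curve.** The manual-analysis analogue: the pooled events are split
into eight subgroups (equal-count at the octiles, or equal-width), with the
speck percentage per subgroup. It serves as a cross-check; on simulated
samples its fitted EC50 agrees with the step-binned fit within a few
percent.

**4PL fit.** Box-constrained trust-region least squares on the
(centre, proportion) points, unweighted by default (binomial weighting is
available but off, matching common dose-response fitting defaults). Bounds:
alpha in (0, 1), delta ≤ 1, eta unbounded (so decreasing curves fit with
eta < 0), phi > 0. Initialisation: alpha from the minimum proportion, delta
from the proportion span, phi from the point nearest mid-range, eta sign
from the rank correlation; two steepness magnitudes are started and the
lower-RSS solution kept. A fit is marked non-converged when the optimizer
fails or phi lands within 10x the solver tolerance of its lower bound
(a boundary EC50 is a degenerate estimate, not a measurement). Curves with
fewer than four points raise and the replicate is excluded and logged.

**Scoring.** ASC50 per sample against the batch WT control of the same
condition and replicate (falling back to any same-condition WT, then the
untreated WT; `reference="untreated_wt"` switches the convention — which
normalisation treated samples should use is genuinely open, and the
same-condition control is the default because it cancels treatment effects
on the wild type itself). The WT control scored against itself gives
exactly 0. Replicates aggregate to mean ± s.e.m. (sample sd / sqrt(n);
zero with a flag when n = 1).

### Variant interpretation (`variant_scoring`)

* **Cutoff** — default 0.281, the lower bound of the 95% confidence
  interval of ASC50 over symptomatic variants; `symptomatic_threshold`
  recomputes it from any symptomatic set with either a Student-t or normal
  quantile (which quantile family produced the published value is not
  documented, so both are provided and the cutoff is directly settable).
* **Recommendations** — mean above the cutoff supports pathogenicity; a
  mean below it with a pathogenic/likely-pathogenic prior supports review
  toward benign; within one s.e.m. of the cutoff is borderline (rule can
  be disabled); a below-cutoff mean with any other prior is reported as
  `below_cutoff` (the spec rule table leaves this cell open; an explicit
  value is clearer than overloading the review call). Outputs are labelled
  functional evidence only — clinical classification additionally needs
  literature and clinical context, which the tool never infers.
* **Contrasts** — two-tailed t-tests between untreated and treated
  replicate ASC50 sets; Student (pooled variance) by default, Welch
  optional. Zero-variance identical groups give t = 0, p = 1; zero-variance
  unequal groups are flagged degenerate with p at the machine floor. No
  multiple-testing correction by default (per-variant tests are reported
  individually); Benjamini–Hochberg is available.
* **Flags** — nigericin hypersensitivity and cold sensitivity are
  significant score increases under the treatment; MCC950 resistance is
  operationalised as *no significant decrease under MCC950 (longest tested
  exposure) and a treated mean still above the pathogenicity cutoff* —
  "remained resistant" is not formally defined upstream, and this two-part
  rule requires both that the inhibitor failed to act and that the variant
  remains in the hyperactive range. Missing condition pairs yield
  undetermined (None), never False.
* **Annotation** — protein-level labels (R262W, R556*, F257fs, T440del
  grammar) are parsed and mapped onto an NLRP3 domain table (PYD, FISNA,
  NBD, HD1, WHD, HD2, trLRR, cnLRR with NACHT/LRR groupings). Boundaries
  are configuration data (TSV-replaceable), not code constants, because
  published domain schematics differ in detail; the defaults are
  literature-derived. `domain_density` recomputes flagged-variant counts
  per residue of domain length.

## The simulator and what it does not emulate

`simdata` generates the study conditions every test runs under. Defaults
(all overridable): 20,000 events/sample at 100 events/s (Poisson arrival);
35% transfection; 8% debris, 3% doublets; transfected log10 expression
N(3.2, 0.9) over an untransfected background N(0.7, 0.2); logistic speck
probability with floor 0.02, ceiling 0.98, steepness 3 and WT midpoint
phi_wt = 3.2 — placed mid-distribution so the wild type reaches ~50% specks
well inside the observed expression range; speck metric N(0.3, 0.05) /
N(0.8, 0.05) conditional on speck state (10 sd separation); detector
saturation at 262,144 a.u. (18-bit convention). A variant is a multiplier r
on the WT midpoint, optionally modified per condition, so its ground-truth
score is ASC50 = 1 − r·modifier, recorded per sample in a manifest along
with latent per-event labels (debris/doublet/transfected/speck). Doublets
are channel-wise sums of two latent cells with FSC-H only 1.3x a single
height. Anomalies (rate spikes, drift, saturation) are explicit injections
recorded in the manifest, never emergent.

Not emulated: spectral spillover/compensation, autofluorescence structure,
day-to-day instrument drift, transfection-batch effects, imaging-level
speck morphology, or biological covariance between expression and speck
propensity beyond the logistic model. Passing tests therefore demonstrate
that the algorithms recover known truth under a faithful but idealised
event model — they do not validate performance on any particular
instrument's artefact profile, and real transfection efficiencies and
event counts are not published for the assay, so those defaults are
plausible rather than measured.

## Numerical choices and degenerate inputs

* MAD scaled by 1.4826; IQR/1.349 fallback; no flags when both vanish.
* KDEs: Silverman bandwidth, 512-point grid, 10,000-event subsample cap,
  modes below 5% of the peak ignored, valley ties broken toward the lower
  value.
* Identical expression values (zero range), empty inputs, sub-minimum
  samples, unimodal controls, non-converged fits and missing condition
  pairs all raise or flag explicitly; nothing silently scores.
* Determinism: one seed drives each simulated sample
  (bit-identical reruns); the analysis path contains no randomness beyond
  seeded subsampling inside gate derivation, so full runs are reproducible
  byte-for-byte given (inputs, config).

## Problem sizes used in verification

The test-suite and acceptance-script experiments use 20,000 events per
sample, 3 replicates and 5 simulated experiments per setting (the ratio
ladder r = 0.6–1.0), which puts the replicate s.e.m. of recovered ASC50
near 0.01–0.03 — comfortably inside the ±0.05 recovery band while keeping
a full verification run in tens of seconds on one core.

## Known limitations

* ASC50 depends on the transform of the expression axis; comparisons are
  only meaningful under a fixed transform and within-batch WT referencing.
* The unweighted 4PL fit treats all windows equally although tail windows
  carry fewer cells; enabling binomial weighting changes EC50s slightly.
* The speck metric is a one-dimensional proxy; real BFP pulse-shape
  distributions may need an adapter mapping before the bimodal-valley gate
  applies.
* Classification output is evidence, not diagnosis: the assay measures one
  axis (spontaneous/conditional speck formation at varying expression) and
  is known not to predict clinical severity for individual patients.
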