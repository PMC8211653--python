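# Methods

This note documents the models and procedures the package implements, the
parameters that matter, what the synthetic generators do and do not emulate,
and the numerical choices behind the fits.  Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Screen scoring

**Model.** A chemosensitization screen reads one viability (luminescence)
value per siRNA per arm (drug / vehicle) per replicate.  Signals are log2
transformed and normalized per plate by subtracting the plate median
(multiplicative plate effects become additive offsets in log space, so the
median removes them exactly).  The Drug Effect score is
`DE = norm(drug) − norm(vehicle)` in log2 units; negative DE =
chemosensitization.  DE scores are standardized as
`Z = (DE − median) / MAD` with the *raw* MAD (no 1.4826 factor), so `Z = −2`
literally reads "two MADs below the median effect"; hits are `Z < −2`,
strict.  A `scaled_mad` flag restores the normal-consistency factor for users
who want σ-calibrated Z scores.

**Plate aggregate.** The plate median is computed over library wells only.
Controls occupy fixed positions and have biased values (the positive control
kills most cells), so letting them into the aggregate would shift every
score on control-heavy plates; they are still *normalized with* the
library-derived median.  `include_controls=True` restores the pooled
behaviour for sensitivity analysis.  Empty wells never enter any aggregate,
and zero signals are tolerated in control wells (dead-cell controls, log2 =
−inf) but are an error in library wells, whose log2 must stay finite for DE.

**Replicates.** Triplicate screens are combined at the normalized-well level
by median (mean available); the median of an even-count set is the mean of
the two central values, which matters because hit calls depend on it.
Perturbations observed in only one arm are excluded with a logged warning.
Z aggregates are computed per screen (one drug/vehicle pair), never pooled
across compounds.

**Degenerate screens.** MAD = 0 (constant synthetic inputs) falls back to
the sample standard deviation with a warning; an all-constant screen returns
all-zero Z rather than crashing.

**Calibration.** With the strict `Z < −2` unscaled-MAD rule, a null screen
flags ≈ 8.9% of siRNAs.  Because triplicates are combined by median, the
null DE is a difference of medians-of-3 Gaussians, not a Gaussian; the test
suite checks the pipeline against a frozen ≥ 1e5-draw Monte-Carlo value for
that exact statistic (0.0889), which happens to sit within half a point of
the plain normal-theory value Φ(−2·0.6745) ≈ 8.87%.

**QC.** Per-plate control separation = median(log2 positive) −
median(log2 negative); plates whose cell-killing positive controls do not
fall below the negatives are flagged, and a robust standardized separation
(separation over pooled scaled MAD of the control groups) is reported.

## Dose–response (4PL)

**Model.** `y = bottom + (top − bottom) / (1 + (x/xc50)^hill)`, fitted by
least squares in `(bottom, top, log10 xc50, hill)`.  The 4PL has the exact
symmetry `(bottom, top, hill) → (top, bottom, −hill)`; fits are
canonicalized to `top ≥ bottom`, so descending (inhibition) data get
`hill > 0` and mirrored (activation) data the same xc50 with `hill < 0`.

**Initialization.** Single-start 4PL fits fall into local minima when the
midpoint guess is off by orders of magnitude, so the optimizer is
multi-started: log10-midpoint at every distinct measured concentration ×
hill ∈ {+1, −1}, best RSS wins.  Parameters are unconstrained by default
(`bottom` may go negative — real plates have background drift); bounds are
accepted.  Tolerances 1e-12 so noiseless data recover generating parameters
to ~1e-8.

**Flags.** `extrapolated`: fitted midpoint outside the measured span.
`indeterminate`: dynamic range `|top − bottom| ≤ 3·RMSE` (or zero response
range) — monotone-flat data whose midpoint should not be interpreted.
A 0-dose vehicle point is a normalization reference, never a fittable x.

**Uncertainty.** Optional seeded pairs bootstrap (default 200 resamples),
95% percentile interval on xc50.  Note a 95% interval misses the truth on
~5% of plates; the test suite checks interval sanity, not single-draw
coverage.

**Derived metrics.** Percent inhibition =
`100 (neg − signal) / (neg − pos)` with neg = uninhibited (DMSO) and pos =
fully inhibited controls; affine-invariant to common rescaling.  Surviving
fraction = value / untreated reference (reference ≡ 1.0).  Survival AUC =
trapezoid of SF over log10(dose), divided by the log10 span, so an
insensitive line at SF = 1 scores exactly 1.0 and smaller = more sensitive.

## Enzymology

**Initial rates.** Progress curves are quenched at 0/5/15/30/45/60 min.
Replicates are averaged per timepoint, the t = 0 baseline subtracted, and
the rate is the least-squares slope over the largest prefix of timepoints
whose linear fit has R² ≥ 0.98 (minimum 3 points).  The prefix rule is this
package's own convention and is configurable: 0.98 tolerates mild curvature
(a 50%-conversion depletion trace still fits the full window at R² ≈ 0.99),
so analyses that need strict initial-slope behaviour should raise `r2_min`
(the depletion test uses 0.9995).  Flat traces return v = 0 flagged `flat`;
significantly negative slopes flag `nonmonotone`.  Endpoint-only analysis is
available implicitly (fit the 60-min signals) and the depletion demo shows
why the time-course route is less biased.

**Rate laws.** With shared Vmax, Km (substrate units), Ki (inhibitor units)
and α:

| modality       | v(S, I) |
|----------------|---------|
| competitive    | Vmax·S / (Km(1 + I/Ki) + S) |
| uncompetitive  | Vmax·S / (Km + S(1 + I/Ki)) |
| noncompetitive | Vmax·S / ((Km + S)(1 + I/Ki)) |
| mixed          | Vmax·S / (Km(1 + I/Ki) + S(1 + I/(αKi))) |

All reduce to Michaelis–Menten at I = 0 (the grids therefore must include
the DMSO row).  Apparent IC50 as a function of S —
`(Km + S)/(Km/Ki + S/(αKi))` in general — rises with S for competitive,
falls for uncompetitive and is constant (= Ki) for noncompetitive
inhibition; it is exposed as a closed-form secondary diagnostic.

**Fitting and model selection.** Each law is fitted globally to the full
(S, I) rate table by least squares in log-parameters (positivity by
construction), multi-started over Ki (min/geometric-mean/max of the tested
inhibitor range) and α ∈ {0.3, 1, 3} for mixed.  Selection is by AICc
(small-sample corrected; the grids have ~56 points).  Two policies handle
the fact that the mixed law *nests* all three pure laws (α → ∞, 0, 1):

1. RSS is floored at numerical precision (`n·(1e-6·RMS(v))²`) so that
   noiseless data, where nested models tie at ~1e-26 RSS, are separated by
   the parameter-count penalty instead of floating-point noise.
2. Mixed is the umbrella model, not a rival hypothesis: it wins only when it
   beats the best pure law by ≥ 2 AICc (the conventional "within 2 AICc =
   equivalent, prefer simpler" rule).  Otherwise the best pure law is
   reported, with `collapsed_from_mixed=True` when mixed was numerically
   lower.  `delta_aicc` is always the winner's margin to the best *rival
   pure law*.  An earlier rule gated the collapse on |α − 1| < 0.2; at 5% CV
   noise α drifts past that bound while mixed's AICc edge stays ≤ ~3, which
   misclassified ~15% of noncompetitive grids — the margin rule fixes this
   and was adopted instead.

Measured behaviour (test suite): noiseless self-generated grids are
classified correctly with ΔAICc > 10 and parameters recovered to ≤ 1e-4
relative; at 5% CV, ≥ 95/100 seeds classify correctly on both grids, and
competitive/uncompetitive confusion is ≤ 5%.

**DSF.** Fluorescence is smoothed by a Savitzky–Golay local polynomial
(default 5-point window, order 2), differentiated against temperature, and
Tm taken as the largest interior positive derivative peak (rising edge —
environment-sensitive dyes gain signal on unfolding), refined by parabolic
interpolation; accuracy is within one temperature-grid step on sigmoid
fixtures.  The extraction is invariant to offset and positive gain.  Traces
whose derivative never rises meaningfully above the baseline slope (span
≤ 1e-9 of its magnitude) are flagged transition-free; additional peaks at
≥ 25% of the main amplitude are reported as secondary transitions (e.g.
free DNA melting apart from the protein).  ΔTm(c) = Tm(compound at c) −
Tm(matched DMSO reference), computed separately with and without DNA, Tm per
condition averaged over replicate curves.

## Cell assays

**Reporter.** Activity = (NanoLuc/Firefly) / median(NanoLuc/Firefly over
DMSO wells).  Firefly (cell density × transfection efficiency) must be > 0;
the DMSO aggregate is a median (robust to edge wells), so the DMSO set has
median activity exactly 1.

**Resection.** `ΔCt = Ct(digested) − Ct(mock)`;
`ssDNA% = 100 / (2^(ΔCt − 1) + 0.5)`.  The formula is implemented exactly as
stated (the −1 and 0.5 come from the heterozygous-digestion derivation in
the source method and are not re-derived).  It is a strictly decreasing
bijection on ΔCt ∈ ℝ; ΔCt < 0 is nonphysical and flagged, never clamped.

**Recruitment.** ratio = ROI / same-nucleus background (cancels expression
differences and common photobleaching); optionally rescaled to the
pre-damage frame.  The plateau (mean of the last 10 frames) and half-rise
time are descriptive extensions beyond the raw trace and are off by default
(`summary=False`).

**Apoptosis.** 100 × green (caspase) area / confluence area, elementwise;
zero-confluence timepoints are NaN, negative areas an error.

## Synthetic data

All generators are deterministic functions of (parameters, seed); the single
config seed fans out into a named substream per assay (SeedSequence keyed on
a CRC of the stream name), so adding one generator call never shifts
another's draws.  Ground truth is always returned alongside the
measurements, and every output validates against its CSV schema.

Defaults encode the emulated designs: 384-well screen plates with 368
library + 12 negative-control + 4 positive-control wells (positive controls
at 10% of baseline — a strong kill control), a 1418-siRNA library in
triplicate, plate baselines ~U(0.7, 1.3) so normalization is genuinely
exercised; 10-point half-log dilutions from 120 or 12 µM and 10-point
3-fold dilutions from 12 µM; substrate grids DNA 200 → 1.563 nM and dNTP
10 → 0.078125 µM (two-fold) × inhibitor 50 → 1.563 nM plus DMSO, quenched
at 0/5/15/30/45/60 min; 20 → 99 °C melt ramps at 0.5 °C steps.

Noise: plate-reader signals get mean-one multiplicative log-normal noise
with CV 5% by default (`additive_gaussian` alternative); qPCR Ct values get
additive SD 0.15 cycles.  Where a log2-scale SD is specified (screen
spike-in studies), `log2_sd_to_cv` converts exactly.  Melt curves are an
exception: their error is dominated by well-to-well gain, so each replicate
curve gets one log-normal gain factor plus small additive per-point read
noise (1% of transition amplitude) — per-point 5% multiplicative noise is
not how melt ramps misbehave and would swamp the derivative.  True assay
noise magnitudes were not available; these are conventions, exposed in
`GeneratorConfig`.

The dose–response generator places 16 uninhibited (DMSO) and 16 fully
inhibited control wells per replicate, as on a real 384-well potency plate;
percent-inhibition calculations aggregate controls by median, so the control
estimate is much less noisy than any single well.  The reporter generator
gives each well its own log-normal Firefly level (CV 15%) so the Firefly
normalization is load-bearing, with four technical replicates per dose.

**What a green test does and does not establish.**  The generators emulate
the *statistical readout layer* only: no spatial plate gradients (off by
default, matching an analysis with no spatial correction), no cell-population
or DNA-damage mechanism, no reagent drift or edge effects, and melt curves
are clean two-state sigmoids without post-transition aggregation decay.
Recovery of a generating parameter therefore validates the analysis
pipeline's correctness and calibration, not instrument- or biology-level
robustness.

## Workflow

`run_demo(workdir, seed)` chains every generator and analysis, writes
per-assay measurement/result CSVs, a JSON+markdown report of recovered vs
generating quantities, and a manifest (command, seed, package version,
parameter hash, timestamps, outputs).  Result CSVs are byte-identical across
reruns with the same seed; the manifest carries the timestamps.  As a
library there are no process exit codes: failures raise, and a failed stage
still writes the manifest with `status="failed"` and the partial outputs
listed.

## Known limitations

* Progress-curve rates assume quasi-linear early kinetics; heavy substrate
  depletion biases the default R² ≥ 0.98 window (raise `r2_min` or model the
  curvature upstream).
* The modality family is steady-state only — no slow-binding, tight-binding
  or time-dependent inhibition.
* DSF Tm is a derivative inflection, not a thermodynamic ΔG fit; strongly
  sloped post-transition baselines or overlapping transitions within ~2 °C
  will merge.
* The screen model treats wells as exchangeable within a plate; row/column
  (spatial) artifacts are out of scope by design.
* Bootstrap CIs are percentile intervals over wells; with ≤ 3 replicates per
  dose they are indicative, not calibrated.
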