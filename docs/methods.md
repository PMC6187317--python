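# Methods

## The measurement being modeled

A cell stained with FITC-labelled anti-β-actin antibody is aspirated through
a microfluidic constriction channel whose 8 µm × 8 µm cross-section is
smaller than the cell, so the cell deforms into a plug that fills the lumen.
An opaque chrome mask leaves a 2.5 µm optical window; a photomultiplier
sampled at 100 kHz records the fluorescence passing that window. As the plug
translates at velocity *v*, the recorded pulse is a trapezoid:

- rising domain, duration *T*<sub>r</sub>, while the plug front crosses the
  window;
- stable domain, duration *T*<sub>s</sub> at plateau level *I*<sub>f</sub>,
  while the plug spans the window;
- declining domain, duration *T*<sub>d</sub>, while the tail leaves it.

## Plug-flow model

The package's forward/inverse model treats the plug as a cylinder of length
*L* = *V*/*A* moving at constant *v* (plug flow), with *V* = (π/6)
*D*<sub>c</sub>³ the volume of the undeformed spherical cell and *A* = 64 µm²
the channel cross-section:

- forward: *T*<sub>r</sub> = *T*<sub>d</sub> = *w*/*v*,
  *T*<sub>s</sub> = (*L* − *w*)/*v*, with *w* = 2.5 µm the window width;
- inverse: *v* = 2*w*/(*T*<sub>r</sub> + *T*<sub>d</sub>),
  *L* = *v T*<sub>s</sub> + *w*, *V* = *A L*,
  *D*<sub>c</sub> = (6*V*/π)<sup>1/3</sup>.

Using the mean of *T*<sub>r</sub> and *T*<sub>d</sub> for the velocity makes
the inverse robust to mild rise/decline asymmetry; a `velocity_mode="rise"`
switch uses *T*<sub>r</sub> alone. The model assumes constant velocity inside
the window, no compression of cell volume, and a window much shorter than the
plug (cells whose plug would be shorter than the window are outside the
model's domain and raise an error; the simulator truncates its diameter draws
at a plug length of 1.1 windows).

The plateau converts to concentration through a calibration line
*I* = *k C* + *b* fitted by ordinary least squares to plateau readings of
free labelled-antibody solutions of known concentration run through the same
channel. Because the calibration solution and the cell plug fill the same
optical volume, the window volume cancels and the gain is per concentration
(mV/µM). Calibration readings in this package are baseline-subtracted
plateau means, so an ideal system has *b* = 0; a fitted non-zero intercept
absorbs residual background. The per-cell quantities are then

- *C*<sub>p</sub> = (*I*<sub>f</sub> − *b*)/*k* (µM),
- *n*<sub>p</sub> = *C*<sub>p</sub> · *V* · 602.214 copies, where
  602.214 molecules µm⁻³ µM⁻¹ is Avogadro's number in package units
  (µm, ms, mV, µM, µm³).

Copy numbers are bound-antibody equivalents: the model assumes saturating
1:1 staining and does not correct for the fluorophore-per-antibody degree of
labeling — the same convention as the instrument's headline numbers.

Applied to the published mean (*C*<sub>p</sub>, *D*<sub>c</sub>) of each
line, the identity *n*<sub>p</sub> = *C*<sub>p</sub>(π/6)*D*<sub>c</sub>³·*N*<sub>A</sub>
reproduces the published mean copy numbers within 1.4–6.9% (a mean of
products is not a product of means, so exact equality is not expected).
Note the published mean durations are *not* jointly consistent with any
single-velocity trapezoid at the published mean diameters, and the
instrument's own translation formulas are not public; this package's
simulator and inference therefore share the plug-flow model above, and
correctness is certified by round-trip recovery against ground truth rather
than by matching the published raw duration means.

## Synthetic data

The generator stands in for the device. Per population it draws:

- diameter: truncated normal (lower bound at the plug-flow validity limit),
  defaults per line 14.3 ± 1.9, 13.1 ± 2.2, 12.8 ± 1.6 µm;
- copy number: lognormal by default — positive and right-skewed, matching
  the observed ~50% CVs — with (µ, σ) solved so the *arithmetic* mean and SD
  of draws hit the targets (9.9 ± 4.6, 6.8 ± 4.0, 11.4 ± 5.5 ×10⁵ per cell);
  a truncated-normal alternative is available for sensitivity checks;
- velocity: lognormal, 1.25 ± 0.25 µm/ms (CV 20%). Velocity is sampled, not
  derived from the driving pressure — hydrodynamics is out of scope;
- arrivals: Poisson process (default 6 cells/s) with no enforced separation,
  so coincident cells (doublets) occur naturally and exercise QC;
- an "image diameter" side channel with 8% relative noise, emulating the
  microscopy cross-check of pulse-derived diameters.

Traces are rendered at 100 kHz: each cell contributes a trapezoid with
durations from the forward model and plateau height *k* · *C*<sub>p</sub>
above baseline; overlapping pulses sum; Gaussian noise is added and values
clip at saturation when set. Everything is deterministic per seed.

The instrument's baseline level, noise magnitude and PMT gain are not
public; the defaults (baseline 10 mV, noise 1.7 mV ≈ 2% of a typical
plateau, gain 85 mV/µM so that a 1 µM cell sits at 85 mV — the level the
published A549 row pairs with 1.0 µM) are simulator conventions chosen to
put plateaus in the observed tens-to-hundreds of mV range.

What the generator does **not** emulate: staining kinetics, photobleaching,
flow instability or velocity drift within a pulse, optical point-spread
blurring of the pulse edges, cell deformation dynamics, and any correlation
between cell size and expression beyond independence of the diameter and
copy-number draws. Passing round-trip tests therefore certify the
signal-processing and inversion chain under the stated model, not the
instrument's physics.

## Pulse processing

1. **Baseline**: the trace is chunked into windows (1% of the trace, ≥16
   samples); the quietest quarter (lowest variance, ties broken toward the
   lower level) is pooled; baseline = median, noise SD = 1.4826 × MAD.
   Assumes the baseline occupies a substantial fraction of the trace.
2. **Detection**: hysteresis thresholding — open at baseline + 5σ, close at
   baseline + 2σ, drop segments shorter than 0.5 ms, pad 3 samples. The 5σ/2σ
   constants and the minimum duration are processing choices (config-exposed);
   the instrument's publication specifies none.
3. **Trapezoid fit**: least-squares piecewise-linear model
   (baseline | rise | plateau | decline | baseline). For fixed breakpoints
   the optimal plateau height is closed-form, so only the four breakpoints
   are searched: initialization at the 10%/90% threshold crossings, then
   Nelder–Mead on the profiled sum of squares with the breakpoints
   parametrized as (start, log-gaps) to preserve ordering. Rise and decline
   durations floor at one sample period (0.01 ms), so a sampled rectangle
   reports one-sample edges. Fits whose plateau holds fewer than two samples
   or is shorter than one sample period are flagged `no_plateau`.
4. **QC**: rejects saturated pulses; fits whose RMS residual exceeds both
   10% of the plateau and 3× the trace noise SD (the noise floor prevents
   culling dim but well-fit pulses, which would bias population dispersion);
   plateaus shorter than 0.05 ms; events wider than 60 ms; and doublets.
   Doublets are identified by multiple distinct rising edges (smoothed,
   lag-differenced signal; runs merge unless the trace is genuinely flat
   between them) or excursions beyond the fitted plateau by more than 25%
   plus 5× the noise SD. Doublets are rejected, not deconvolved.

## Statistics and classification

Per population: sample mean, *n*−1 SD, CV = SD/mean, type-7 (linearly
interpolated) quartiles — the quartile convention is not stated by the
instrument's publication; type-7 is the common default and is config-exposed
— and the quartile coefficient of dispersion
QCD = (*Q*₃ − *Q*₁)/(*Q*₃ + *Q*₁). Reported percentages round to one
decimal. One-way ANOVA is computed from explicit between/within sums of
squares with the upper-tail F p-value and the p < 0.01 significance
convention; the degenerate all-constant case defines F = 0.

Pairwise classification uses a two-layer feed-forward network (10 logistic
hidden units; for two classes the logistic output is equivalent to a 2-unit
softmax), trained by L-BFGS on a stratified 70/30 split with features
standardized on the training fold, deterministic per seed. Hidden size,
split, epoch cap and optimizer are package choices (the original analysis
used a GUI application whose settings are unpublished); all are
config-exposed. A logistic-regression baseline guards against training
pathologies: the network must match it on linearly separable problems.
The published pairwise rates themselves (73.8 / 63.9 / 73.1%) derive from
the real instrument's empirical distributions and are not reproducible from
summary moments; the package checks the qualitative structure instead —
chance level on identical populations, near-Bayes accuracy on known
Gaussians, and the published ordering (A549 vs HeLa weakest) on populations
drawn from the published per-line laws.

## Problem sizes and numerical choices

- Round-trip validation runs 1,000 cells per line at 2% plateau noise with
  a 3 cells/s arrival rate — low coincidence, so the experiment measures
  inversion fidelity; doublet behavior is tested separately. Traces are
  synthesized in 250-cell batches to bound memory.
- The analysis drivers default to 300 cells per line; the acceptance script
  uses 600 per line. These desk-scale runs reproduce the qualitative
  structure of the full-scale (14,754–36,949 cells/line) published study.
- Seeds: every stochastic stage takes an explicit seed; child seeds derive
  from `numpy.random.SeedSequence` and stay below 2³¹.
- Tolerances: the internal identities (copies = C·V·N_A, diameter–volume)
  are enforced at 1e−9 relative on every emitted record; serialization
  round-trips are exact for JSON/CSV and 10⁻⁴ mV / exact-grid time for the
  two-column trace text format.

## Known limitations

- The trapezoid model ignores edge rounding from the finite optical window;
  on real data the rise/decline would be smoothed and *T*<sub>r</sub>
  estimates biased long.
- Baseline estimation assumes a baseline-majority trace; very high event
  rates violate it.
- Doublet rejection (rather than deconvolution) biases throughput, and at
  high arrival rates slightly prunes long-pulse (large, slow) cells.
- Lognormal copy-number laws are an assumption consistent with the reported
  CVs and skewness, not a measured single-cell distribution.
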