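# Methods

This note records the models, defaults, and numerical choices behind
`storemetrics`, and what the synthetic-data tests do and do not establish
about real instrument data.

## SICM stiffness mapping

**Physical picture.** In pressurized hopping-mode SICM the nanopipette is
back-pressurized (P0 = 2 kPa by default) so the escaping nanofluidic jet
indents the sample as the tip approaches. On rigid glass the percent
ion-current drop rises steeply with depth; on a compliant cell the surface
yields and the drop rises more slowly. The per-pixel window slope *s*
(regressed over the 1–2 % drop window) relative to the substrate slope *s∞*
carries the stiffness information through

    E = A · P0 / (s∞/s − 1),

with A = 0.1617, a dimensionless geometry factor for the tip used (taken as
given; its finite-element derivation is out of scope). E is strictly
increasing in *s* on (0, s∞) and linear in P0. Pixels with *s* ≥ *s∞* are
at least as stiff as glass and carry a `+inf` ("rigid") sentinel; pixels
with fewer than 3 in-window samples carry NaN — noise can legitimately empty
the narrow window, so this is a flag, not an exception.

**Forward model (synthetic scans).** The analysis uses only two features of
an approach curve: the window slope and the stop-threshold crossing. The
generator therefore uses the minimal model exercising both: the drop is zero
above a sensing onset and linear in depth below it, with slope
s = s∞/(1 + A·P0/E) on cell pixels. The full nonlinear SICM transfer
function is deliberately not modelled; recovery tests on these curves
validate the inverse algebra and the pipeline plumbing, not the
electrochemistry of a real nanopipette.

The onset sits a fixed sensing distance `stop_threshold/s∞` above the local
surface. Consequence: on glass the 2.1 % crossing recovers the surface
exactly, while on a compliant pixel it lands `stop·(1/s − 1/s∞)` *below*
the true contact — a compliance bias that real pressurized SICM shares
qualitatively (the jet pushes the soft surface away). Topography-accuracy
tests therefore use stiff phantoms; for soft phantoms the bias (~0.5 µm at
50 Pa with the defaults) only erodes the mask rim.

**Defaults.** Stop threshold 2.1 %, window 1–2 %, hop height 5 µm, 200
reference hops, s∞ = 25 %/µm, z sampling step 5 nm. The substrate slope and
z step are instrument-scale choices: together they put ~10 samples in the
window on glass and ~20 on a 300 Pa cell, enough for a stable regression
while keeping a 64×64 scan around 10⁷ samples.

**Leveling.** Topography is reported relative to a least-squares plane fit
to the substrate, found iteratively (fit all pixels, drop those more than
`min_height_um` above the plane, refit). This assumes glass is the majority
phase, which holds for the sparse cell fields mapped here.

**Segmentation.** Foreground = pixels ≥ 0.2 µm (`min_height_um`) above the
plane; the threshold is this package's rule — the original exclusion of
"glass pixels" had no stated criterion. Markers for the watershed come from
the Gaussian-smoothed (σ = 1 px) topography with maxima shallower than
`marker_h_um = 0.1 µm` suppressed by morphological reconstruction: a
biconcave cell's rim ridge (whose undulations are a few hundredths of a µm)
merges into a single marker, while two cells fused by a neck deeper than
0.1 µm keep separate markers and split at the saddle. Plain point-maxima
markers were rejected because they fragment the rim ridge into several
markers and oversegment single cells.

**Region statistics.** For one labeled cell, pixels are ranked by
normalized Euclidean distance from the region boundary; "center" is the
innermost 25 % of pixels and "edge" the outermost 25 %, summarized by 5 %
trimmed means over finite-modulus pixels. Quantiles of the pixel
*distribution* (rather than fixed distance thresholds) keep the two bands
at equal pixel counts regardless of cell shape. Regions under 8 pixels are
rejected.

**Phantom fixtures.** `as1_center`: 10 µm radius biconcave cell (2.5 µm rim,
0.4× center dimple), 300 Pa plateau out to r = 0.55 ramping to an 80 Pa
band beyond r = 0.85 — the center-at-300 Pa / edge-below-100 Pa structure
reported for cells imaged in their storage medium. `as1n_pss`: the same
geometry with a uniformly soft 80 → 50 Pa profile, emulating
normoglycemically stored cells in a plasma-like buffer, all below 100 Pa.
`stiff`: 1 MPa throughout, for topography accuracy checks. The height
profile h(r) = h_rim·(0.4 + 0.6·sin πr) is one convenient dimpled shape;
only the center-vs-edge modulus structure matters to the tests.

## Glucose maintenance

**Consumption model.** Stored cells consume glucose fastest early in
storage; the bag simulator uses a single-exponential rate
r(t) = r0·e^(−t/τ), integrated in closed form between events. No numeric
rates were available, so the defaults (r0 = 1.3 µmol/h, τ = 450 h for a
50 mL bag) are calibrated — an inference, not a measurement — to the stated
dosing behaviour: ~0.87 µL of 300 mM stock per 12-minute tick early in
storage (the reported 800–1000 nL every 10–15 min) decaying to one
bolus-equivalent per ~4 h at day 56.

**Controller.** Two layers. Feed-forward: at each 12-minute tick, the mass
the model predicts will be consumed is converted to stock volume and
delivered. Feedback: at each glucometer reading below target, the exact
mixing volume v = V·(target − measured)/(stock − target) that restores the
target is delivered; this is an identity of the mixing equation, so with a
perfect meter the bolus lands exactly on target. Control is one-sided —
high readings are flagged, never "corrected", since the hardware cannot
withdraw glucose. The exact original dosing flowchart was not available;
this reconstruction reproduces all its stated behaviour (bolus sizes and
cadence, ~75 % time-in-range at ±1 mM).

**Quantization.** All volumes are floored to whole pump steps (160 nL per
0.225° step) with the sub-step remainder carried to the next bolus, so the
cumulative shortfall never exceeds one step. A 1 ns-scale epsilon
(`+1e-9` step fractions) absorbs float dust when carried remainders sum to
an exact step; the remainder is clamped at zero.

**Meter noise.** Multiplicative mean-one lognormal at CV 5 % (no meter
precision was stated; 5 % is typical of handheld glucometers). Time-in-range
is computed on the *measured* values, as in practice. Measurement cadence
defaults to 3.5 days → 16 readings per bag, 64 over four bags in 56 days.

**What the closed-loop tests show.** With the exact consumption model and a
noiseless meter, 100 % of readings are in band — the residual drift is the
slow dilution from feeding volume (mass replacement keeps M constant while
V grows ~4 % over 56 days), which the feedback layer absorbs. With 5 % CV
the simulated time-in-range is ~85–100 % depending on seed, comfortably
above the 75 % observed with real bags; real donor variability,
model-mismatch in consumption, and manual sampling are not in the
simulator, so the margin is expected.

## Bulk assays

**Lysis.** The percentage formula is implemented exactly as printed:
100·[Hb_sup]·(1 − HCT)/([Hb_sup] + [Hb_pellet]). Unit note: the
denominator adds a supernatant-phase concentration to a pellet-phase
concentration, so it is not a strict whole-bag mass balance; it is kept
as-is rather than "corrected". HCT enters as a fraction in (0, 1), which
bounds the result by 100·(1 − HCT) < 100. Dilution corrections (×10
supernatant, ×1000 pellet) are applied upstream when raw absorbances are
given. The synthetic absorbance generator inverts exactly this chain, so
the noise-free round trip is exact by construction — it validates the
plumbing and the formula's self-consistency, not plate-reader physics.

**Savitzky–Golay smoothing.** Window = 0.5 % of the trace length, forced
odd and at least `poly_order + 2` samples; polynomial order 2 (the original
analysis stated only the window). Degree-≤2 signals pass through unchanged
(interior points), and peaks much wider than the window change height by
< 1 %.

**Peak heights.** Height = maximum within 45 s after the injection minus
the median of the 5 s before it (local baseline; the original baseline
handling was unstated). The generator's Gaussian peaks have an apex 15 s
after injection; neighbouring-peak tail bleed bounds noise-free round-trip
error at ~10⁻⁶ relative.

**Standard addition.** OLS of height vs added concentration; endogenous
concentration = intercept/slope (the magnitude of the negative
x-intercept), exact on any noiseless affine response regardless of response
factor. Whether reported ATP values sit on the injected 7 %-hematocrit
basis or the ~60 % storage basis was ambiguous, so the result object
carries both the injected-basis value and the value scaled by a
caller-supplied `dilution_factor`.

## Solutions

Ideal-dissociation osmolarity = Σ concentration × particle count, with
integer counts calibrated once against the CPD row (trisodium citrate 4,
citric acid 1, monosodium phosphate 2, NaCl 2, dextrose/adenine/mannitol 1)
and frozen; rounding is half-away-from-zero to whole mOsm/L, matching the
printed tables. CPD (533), CPD-N (410), and AS-1N (357) agree with their
declared values; AS-1 computes to 462 against a declared 465 — the 3 mOsm/L
gap is reported by `compare_to_declared`, never reconciled, since the
convention behind the declared figure is unknown. Activity coefficients and
buffer speciation are out of scope.

## Problem sizes and determinism

Every generator draws from one `numpy` Generator seeded per call; identical
seeds give bit-identical outputs, and scenario summaries are byte-stable.
Packaged scenarios and the acceptance script use 64×64 scans (≈4,100
curves plus 200 reference hops, a few seconds end to end) and 4 bags × 56
days at 12-minute control ticks; unit tests use 16–32 px grids. These sizes
were chosen as the smallest at which the recovery statistics are stable.

## Known limitations

* The scan forward model is linear-in-window by design; it cannot probe
  robustness to curvature of real approach curves near contact.
* Consumption kinetics are a single exponential with donor-independent
  defaults; real bags differ donor-to-donor and the controller's
  feed-forward layer would inherit that model error.
* The compliance bias on topography is documented but not corrected; soft
  thin structures (< ~0.7 µm apparent height at 50 Pa) can fall below the
  mask threshold.
* Donor-level inferential statistics (between-condition significance tests)
  are out of scope; the package computes per-cell and per-bag quantities.
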