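# Methods

## Scope and model overview

`scintidose` models the computational chain of a photon-counting personal
dosimeter built from a LYSO scintillator on a SiPM: photon transport is
reduced to a single interaction probability per photon, the analog chain to
an affine gain with Gaussian noise, and the digitizer to a triggered peak
sampler with a fixed per-pulse busy time.  Everything downstream of those
abstractions — histogramming, deadtime arithmetic, Am-241 auto-calibration,
and the spectrum-to-effective-dose conversion — is implemented exactly as a
device firmware would run it, which is the part of the system this package
exists to make testable.

## Physics tables

Two packaged CSV tables drive the dose algorithm (units: keV, 1/mm,
pSv·cm²):

* `lyso_attenuation.csv` — linear attenuation coefficient of LYSO
  (Lu₁.₈Y₀.₂SiO₅, ρ = 7.1 g/cm³), built by composition-weighting elemental
  total mass-attenuation values transcribed from standard photon
  cross-section compilations.  The grid spans 10–150 keV and contains
  points at 63.2 and 63.4 keV so that no interpolated segment bridges the
  Lu K-edge discontinuity.  Absolute accuracy is at the ~10% level of the
  transcribed anchors; all quantities the tests assert are self-consistent
  against this same table.
* `icrp116_ap_dose_coefficients.csv` — effective dose per photon fluence,
  anteroposterior geometry, transcribed from ICRP Publication 116
  Table A.1 (10–150 keV rows).

Interpolation is linear in log-log space: both quantities are near
power-law in energy, and this is the standard choice for photon cross
sections.  Energies outside a table's grid raise an error rather than
extrapolate — the calibration defines the only energy range the device can
attribute, and silently extrapolated dose coefficients would be
untrustworthy.  `pb_attenuation.csv` / `al_attenuation.csv` provide filter
attenuation for the tube source model on the same terms.

## Pulse simulator

Arrivals are homogeneous Poisson at the configured intensity (photons per
second on the crystal face).  Each photon interacts with probability η(E)
(Bernoulli thinning), deposits its full energy (no escape or partial
deposition), and produces amplitude `gain_a·E + gain_b` in ADC-bin units
plus Gaussian noise with σ(amp) = `resolution_sigma`·√amp — scintillator
photo-statistics scaling.  The defaults (gain 8 bins/keV, offset 10 bins,
`resolution_sigma` 1.8 bins/√bin) give ≈17% FWHM energy resolution at
59.5 keV, typical for a small LYSO + SiPM channel, and a 1024-bin ADC
covering ≈127 keV.  The comparator threshold (60 bins ≈ 6 keV) discards
sub-threshold amplitudes without triggering.

Deadtime is non-paralyzable: an accepted trigger opens a τ = 13 μs busy
window and photons interacting inside it are dropped, or — with
`pileup_enabled` — their amplitudes are summed into the pending pulse
(amplitude summation within the coincidence window; off by default since
the device's high-rate nonlinearity is attributed to pile-up but not
modeled quantitatively).  Digitized amplitudes clamp to the last bin,
reproducing pulse-height saturation.

Source models:

* `monoenergetic` and `lines` — delta lines with weights.
* `am241` — 59.54 keV γ plus the Np L X-ray lines (13.9, 17.8, 20.8 keV)
  and the weak 26.3 keV γ, with default weights {0.07, 0.20, 0.17, 0.03,
  0.53}.  These weights are a documented package default chosen once so
  that the resolution-smeared low-energy envelope peaks at ≈19 keV — the
  empirical anchor the two-point calibration assumes — rather than
  evaluated nuclear-data intensities, which would put the smeared envelope
  peak near 16.6 keV.  Physically this stands in for the energy-dependent
  attenuation between source and crystal (source encapsulation, reflector
  tape) that shapes the envelope a real device sees.
* `tube` — Kramers photon-fluence bremsstrahlung, `N(E) ∝ kV/E − 1`,
  attenuated by a Pb or Al filter, discretized on a 0.25 keV grid.  The
  sampler and every analytic expectation integrate over the *same* grid,
  so simulated estimates can be compared against exact ground truth.

A model limitation worth stating: with heavy Pb filtration the Kramers
spectrum concentrates just below the Pb K-edge (88 keV), giving mean
energies of ≈80–86 keV for 2–8 mm Pb at 90–120 kV.  Real clinical setups
filtered this way report somewhat softer average energies (tube inherent
filtration, anode characteristic lines, room scatter, and the survey
meter's own energy estimator all contribute); none of that realism is
modeled, and the tube source should be read as "a hard filtered spectrum
in the 50–120 keV band", not a spectral twin of any particular tube.

## Deadtime arithmetic

For Poisson triggers at rate n the non-paralyzable observed rate is
`n/(1 + nτ)` (renewal argument: one cycle is a busy time τ plus an
exponential wait), saturating at 1/τ ≈ 76,923 cps for τ = 13 μs.  The
device-side estimate of the deadtime fraction is `observed·τ`, and the
correction multiplies every bin by `1/(1 − observed·τ)` — the exact
algebraic inverse of the observed-rate map.  The correction is applied
uniformly per bin (deadtime is energy-independent in the single-τ model)
and produces real-valued counts: re-rounding would bias dose sums.
Beyond a guard cap of deadtime fraction 0.9 the correction (>10×) is
refused and the histogram is flagged unreliable; the cap value is a design
choice — the device's output is unreliable somewhere beyond the linear
region, and 0.9 bounds the amplification of counting noise.

## Am-241 auto-calibration

Acquisition accumulates events until the tallest bin reaches a stop count
(default 50, so the returned maximum equals the stop count exactly) or a
60 s timeout.  On timeout with fewer than 10 counts in the tallest bin the
procedure reports insufficient statistics instead of fitting noise.  The
raw histogram is smoothed with a centered 7-bin moving average (window
shrinks at the edges); the two most prominent local maxima at least
10 bins apart with prominence ≥10% of the global maximum are taken as the
envelope and γ peaks.  Peak position defaults to the count-weighted
centroid of the bins above half maximum, which suppresses quantization
error relative to the raw argmax (`peak_mode="argmax"` is available).  The
two-point fit maps the low peak to 19 keV and the high peak to 59.5 keV
exactly; the 19 keV anchor is applied as given — its empirical uncertainty
propagates into the dose estimate and is not compensated.  The valid
energy range spans bin 0 to the last bin, clipped to the 10–150 keV table
coverage, and the calibration persists as JSON (the software analog of
device flash memory, surviving power cycling; a dose reset does not clear
it).

Under the default detector model the recovered slope is within ~2% of the
true inverse gain: the residual comes from the smeared envelope peaking at
≈18.6 keV rather than exactly 19 — the same bias a physical device
accepts when it adopts the 19 keV anchor.

## Dose engine

Per window: deadtime-correct the counts, map bin centers to energies
through the calibration, drop (and tally) bins outside the valid range or
table coverage, divide by η(E) to recover incident photons, multiply by
e(E)/A, and sum.  Bins with η < 0.01 are excluded rather than divided —
dividing would amplify a single noise count a hundredfold; the floor is
configurable and the excluded counts are reported per window so users see
what fraction of the spectrum was ignored.  Deadtime correction precedes
the efficiency correction; both are multiplicative per bin so the order
only fixes reproducibility.  Energies are evaluated at bin centers.  Dose
rate is `increment/Δt·3600` (Sv/h, Δt = 1 s default) and the accumulated
dose is the running sum, non-decreasing until an explicit reset.

## Device runtime

The four-screen state machine (dose-rate display, accumulated-dose
display, options, calibrating) follows the single-button grammar: short
press toggles the two displays; long press opens options; in options a
short press resets the dose values (returning to the dose-rate display —
the post-reset screen is not specified by the interface description, and
returning to the primary display is the conventional choice) and a long
press starts calibration, which completes on the next 1 Hz tick.  All
events are legal everywhere; undefined combinations are no-ops.  The dose
log is a ring buffer of (timestamp, dose rate, accumulated dose) samples
at 1 Hz — both quantities are logged since the device description does not
single one out — holding 10 h × 3600 = 36,000 entries, oldest evicted
first, exported as CSV that round-trips bit-exactly.

## Characterization sweeps and problem sizes

`characterize count-rate` simulates a monoenergetic beam per grid point
(5 s per rate by default) and reports output rate and deadtime percent;
it matches `n/(1+nτ)` within counting error.  `characterize linearity`
sets the source intensity for each target dose-rate level analytically
from the spectrum-averaged per-photon dose `⟨e(E)⟩/A` — ground truth is
computed, never tuned — calibrates once from a synthetic Am-241 run, and
runs the full pipeline for 60 s per level.  The default sweep
(0.1–1000 μSv/h, five levels) simulates ≈10⁷ photons at the top level and
completes in seconds; worst-case relative error is a few percent,
dominated by counting statistics at 0.1 μSv/h (≈15 incident photons per
second on a 25 mm² face).  The acceptance script and the test suite use
these same sizes.

## What the simulator does and does not establish

Passing tests show that the algorithms are internally consistent and exact
where the model is exact: the deadtime correction inverts the
non-paralyzable loss, the calibration inverts the simulator's gain up to
quantization and the envelope-anchor bias, and the dose pipeline recovers
the analytic fluence-to-dose product for any source the simulator can
express.  They do not validate the physics abstractions against hardware:
partial energy deposition and escape, SiPM saturation and temperature
drift, optical light transport, analog shaping, Lu-176 intrinsic
background, angular response, and real tube spectra are all outside the
model, so accuracy figures produced here characterize the algorithms, not
a physical instrument.
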