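# scintidose

Software model of a scintillator-based personal X-ray dosimeter: the full
computational chain of a LYSO + SiPM photon-counting device — Am-241
spectral auto-calibration, pulse-height-spectrum-to-effective-dose
conversion, and non-paralyzable deadtime handling — with a Monte-Carlo
pulse simulator standing in for the physical hardware, so every algorithm
can be exercised and tested without a detector on the bench.

It is aimed at medical-physics and health-physics developers who want to
prototype, validate, or teach the dose-calculation firmware of low-cost
active dosimeters used for occupational exposure monitoring in diagnostic
and interventional radiology (photon energies roughly 10–150 keV).

## The model

A photon of energy *E* incident on a slab crystal of thickness *t* interacts
with probability

    η(E) = 1 − exp(−μ(E)·t)

where μ is the crystal's linear attenuation coefficient (packaged table for
LYSO, 1 mm default, with grid points bracketing the Lu K-edge at 63.3 keV).
Accepted pulses have amplitude *a′E + b′* plus Gaussian photo-statistics
noise; the digitizer is busy for τ = 13 μs per accepted pulse, so a true
trigger rate *n* yields the observed rate

    n_out = n / (1 + n·τ),   saturating at 1/τ ≈ 77,000 cps,

with deadtime fraction estimated on-device as *n_out·τ* and inverted by
scaling counts with 1/(1 − n_out·τ) inside a guarded reliable region.

Calibration uses any Am-241 source (e.g. from an ionization smoke
detector): the histogram's two major peaks — the 59.5 keV γ line and the
10–23 keV Np L X-ray envelope, taken empirically to peak at 19 keV — anchor
a two-point linear fit *E = a·bin + b*.

Effective dose per window is then

    ΔD = Σ_bins  counts_corr(bin) / η(E_bin) · e(E_bin) / A,

with *e(E)* the ICRP 116 effective-dose-per-fluence coefficients (AP
geometry, pSv·cm², packaged table) and *A* the crystal face area (25 mm²).
Dose rate and accumulated dose update at 1 Hz into a 10-hour ring-buffer
log, mirroring the device loop and its single-button state machine.

## Worked example

Simulate a 60 s Am-241 acquisition, auto-calibrate, and sweep dose-rate
accuracy over four decades:

```sh
cat > am.yaml <<EOF
source:
  kind: am241
  intensity: 3000
EOF
scintidose simulate --config am.yaml --seed 1 --duration 60 --out am_stream.csv
scintidose calibrate --in am_stream.csv --out calibration.json
scintidose characterize linearity --seed 1 --levels 0.1,10,1000 --out linearity.csv
```

prints

```
wrote 151494 pulses to am_stream.csv
calibration a=0.12274 keV/bin, b=-0.5887 keV -> calibration.json
 true_uSv_h  estimated_uSv_h  rel_err_pct  deadtime_fraction  reliable
        0.1         0.104777     4.776891           0.000198      True
       10.0        10.005253     0.052535           0.018653      True
     1000.0      1002.062325     0.206233           0.655668      True
```

The fitted slope 0.12274 keV/bin is the inverse of the simulator's true
gain (8 bins/keV → 0.125 keV/bin) to within the half-bin quantization and
envelope-anchor uncertainty of the two-point fit.  Each sweep row compares
the full pipeline (simulate → histogram → deadtime correction → efficiency
correction → ICRP coefficients) against the analytically known dose rate of
the filtered-tube source; the relative error stays at the few-percent
level even at 1000 μSv/h, where more than half the pulses are lost to
deadtime before correction.

Other subcommands: `scintidose dose` (stream + calibration → 1 Hz dose
log), `scintidose run` (live simulated session), `scintidose characterize
count-rate`, `scintidose export`.

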