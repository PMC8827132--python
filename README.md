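# gatedphasor

Phasor analysis of time-gated single-photon FLIM data from binary
(1-bit) SPAD-array cameras.

Wide-field fluorescence lifetime imaging (FLIM) with large-format SPAD
arrays records, at each of `G` gate positions scanned across the laser
period `T`, an accumulation of `b` one-bit binary frames: during a frame
exposure the pixel memory latches on the first detected photon and ignores
the rest. The gates are long (typically 10.8–22.8 ns, a quarter to half of
the 50 ns period) and overlap heavily, which rules out the usual
fitting-based lifetime extraction. This package implements the
fitting-free phasor analysis chain for such data, aimed at microscopists
and detector developers who want to analyse or simulate gated SPAD
acquisitions:

- **Forward simulator** of the acquisition: periodic exponential decays
  seen through rectangular (optionally trapezoidal) gates, Bernoulli
  1-bit frames accumulated into 8-bit (`b = 255`) or 10-bit (`b = 1020`)
  gate images, dark counts, hot pixels, and optional deterministic
  per-pixel gate skew. Pile-up emerges naturally from the 1-bit scheme.
- **Corrections**: pile-up linearization
  `I_corr = −I_max · ln(1 − I_rec / I_max)`, tail-window background
  estimation and subtraction, top-percentile hot-pixel masking with
  4-neighbor interpolation.
- **Phasor analysis**: per-pixel/per-ROI phasors
  `z = Σ_k I_k e^{i2πf t_k} / Σ_k I_k`, calibration against a reference
  dye of known lifetime (one complex division removes IRF and gate
  effects), phase lifetimes `τ = tan(φ)/(2πf)`, two-species mixture
  unmixing via the phasor ratio, phasor-ratio lifetime maps and 2-D
  phasor histograms.
- **Photon economy**: the F-value `F = √N σ_τ / τ`, the analytic
  gate-width bound `F_W = √(1 + (W/τ)²/12)` from uniform timestamp
  blurring (Bates statistics of the mean), and a Monte Carlo estimator
  that propagates the calibration sample's shot noise through the exact
  phasor + calibration code path.
- **I/O and CLI**: multi-page 16-bit TIFF stacks with schema-validated
  JSON sidecars, a converter for the 4×8-bit sub-frame file layout, and
  a `gatedphasor` command with `simulate`, `correct`, `phasor`, `run`,
  `fvalue-mc`, `framerate` and `convert-ss2` subcommands.

## Worked example

Simulate two dye samples (a 4.08 ns sample and a 2.8 ns calibration
reference) with 140 gates of width 13.1 ns scanned across a 50 ns
period, correct pile-up, and recover the sample lifetime by calibrated
phasor analysis:

```python
import numpy as np
import gatedphasor as gp
from gatedphasor.corrections import correct_stack
from gatedphasor.phasor import calibrate_image, compute_phasor_image
from gatedphasor.statistics import monte_carlo_f

laser = gp.LaserConfig(period_ns=50.0)               # 20 MHz pulsed laser
gates = gp.GateConfig(width_ns=13.1, step_ns=50/140, num_gates=140)

def acquire(tau_ns, seed):
    params = gp.SimulationParams(
        laser=laser, gates=gates, decay=gp.DecayModel.single(tau_ns),
        shape=(32, 32), brightness=0.8, frames_per_gate=255, seed=seed)
    return gp.simulate_gate_stack(params)

sample, reference = acquire(4.08, seed=1), acquire(2.8, seed=2)

img = compute_phasor_image(correct_stack(sample).values, sample.timestamps_ns, 20e6)
cal = compute_phasor_image(correct_stack(reference).values, reference.timestamps_ns, 20e6)
taus = calibrate_image(img, cal, tau_cal_ns=2.8,
                       granularity="per_pixel").phase_lifetimes_ns()
print(f"phase lifetime: {np.nanmean(taus):.3f} +/- {np.nanstd(taus):.3f} ns")

rep = monte_carlo_f(4.08, 2.8, 13.1, 140, 50.0, 2000, 2000, 20e6,
                    replicates=400, seed=1)
print(f"Monte Carlo F = {rep.F:.2f} +/- {rep.F_se:.2f}"
      f"  (analytic bound F_W = {rep.analytic_F_W:.2f})")
```

This prints:

```
phase lifetime: 4.081 +/- 0.119 ns
Monte Carlo F = 2.24 +/- 0.08  (analytic bound F_W = 1.36)
```

The per-pixel mean recovers the 4.08 ns ground truth; the pixel scatter
(0.119 ns here) is shot-noise limited and shrinks as `G^{-1/2}` when more
gates (hence more photons) are used. The Monte Carlo F-value says that,
with 2000 detected photons each for the sample and the calibration
reference, this gated phasor measurement needs `F² ≈ 5` times more
photons than an ideal TCSPC instrument for the same lifetime precision;
the analytic `F_W` from pure timestamp blurring is a lower bound.

The same pipeline is available from the shell:

```sh
gatedphasor simulate --config sim.json --seed 17 --out stack.tif
gatedphasor correct stack.tif corrected.tif --pileup --background tail:40,49
gatedphasor phasor corrected.tif phasors.csv --roi 4
gatedphasor fvalue-mc --tau 4.08 --tau-cal 2.8 -W 13.1 -G 140 --n 100000 --ncal 100000
gatedphasor framerate --tread 10.2e-6 --texp 10e-6 --b 255 --gates 16
```

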