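# Methods

## Acquisition model

A pulsed laser with period `T` (default 50 ns, i.e. 20 MHz) excites the
sample once per period. Under steady-state periodic excitation a
single-exponential emitter with lifetime `τ` produces the per-period
arrival-phase density

    p(t) = exp(−t/τ) / (τ (1 − exp(−T/τ))),   t ∈ [0, T).

The detector is sensitive only inside a rectangular gate of width `W`
whose start is stepped across the period in increments `δt` (`G`
positions, timestamps `t_k = offset + (k−1)·δt`). The expected capture
fraction of a gate is the closed-form integral of `p` over the
period-wrapped window; multi-exponential decays are amplitude-weighted
sums of single-lifetime fractions. Gates are ideal rectangles by
default; an opt-in trapezoid mode with user-set linear rise/fall edge
durations (area-preserving, integrated by 32-node Gauss–Legendre
quadrature against `p`) approximates real gate edges, for which no
canonical functional form exists.

Each gate image accumulates `b` one-bit frames (`b = 255` for 8-bit,
`1020` for 10-bit images). During one frame the pixel memory latches on
the first detected photon, so with in-gate Poisson mean `λ` the
detection probability is `1 − e^{−λ}` and recorded counts are
`Binomial(b, 1 − e^{−λ})`. Pile-up — saturation of counts below `bλ` —
is therefore an emergent property of the simulator, not an injected
distortion. Dark counts are uniform in time and contribute only while
the gate is open: `DCR · (T_exp/T) · W` per frame, with the binary-frame
exposure `T_exp` a simulation parameter (default 10 μs ≈ 200 periods).
Hot pixels are a user-set fraction of pixels whose DCR is replaced by a
user-set rate (default 10 kcps; no canonical distribution exists, so a
scalar is exposed rather than assumed). Per-pixel gate skew is modelled,
optionally, as a static additive offset of the gate start, reflecting
the deterministic character of gate-edge non-uniformity in large arrays.

All internal times are nanoseconds; frequencies convert at the type
boundary. Randomness derives from one master seed through
`SeedSequence(seed, spawn_key=(row, col))`, so any sub-region of a
simulated frame can be regenerated independently and bit-identically.

## Corrections

Order is fixed: pile-up inversion → background subtraction → optional
ROI binning → phasor. The pile-up inverse
`I_corr = −I_max ln(1 − I_rec/I_max)` is nonlinear, hence valid only on
raw per-pixel counts. Fully saturated bins (`I_rec = I_max`, where the
logarithm diverges) are clamped to `I_max − ½` and flagged; the choice
is pragmatic, there being no principled finite value. The inversion
applied to binomial counts carries a small convexity (Jensen) bias,
about 1% of the signal at `λ = 2` per frame and shrinking quadratically
for smaller `λ`; the test suite pins it against an exact
binomial-expectation oracle.

Background is estimated per pixel as the mean of gates whose timestamps
fall in a user-chosen tail window where fluorescence is negligible. The
estimator assumes `τ ≪ T − W`; for longer lifetimes the decay never
reaches background within the period and the estimate is biased high —
no quantitative threshold is enforced, the choice of window is the
user's. Subtraction results are deliberately not clamped at zero, since
clamping would bias phasor sums of low-count pixels. Hot pixels can be
masked by total-intensity percentile and repaired by iterative
4-neighbor mean interpolation (edge pixels use available neighbors).

## Phasor analysis

The phasor of a gate profile is
`z = Σ_k I_k e^{i2πf t_k} / Σ_k I_k` with `f` the phasor frequency
(default: the repetition rate; harmonics supported but unused by
default). Single-exponential decays lie on the universal semicircle
`(g−½)² + s² = ¼`, with `g = 1/(1+u²)`, `s = u/(1+u²)`, `u = 2πfτ`; the
modulus exponent is −½, the only convention consistent with the
semicircle and the τ → 0 and τ → ∞ limits. The phase lifetime is
`τ_φ = tan(φ)/(2πf)`, computed with `atan2` and flagged NaN for `g ≤ 0`
rather than returned negative.

Scanning a gate across the period circularly correlates the decay with
the gate window, which multiplies the phasor by a common complex factor
(plus aliasing terms that vanish rapidly with growing `G`; in practice
`G > 10` suffices). Measuring a calibration sample of known lifetime
determines that factor, and `z_cor = z_exp · z_cal,theo / z_cal,exp`
removes IRF and gate effects in one complex division. Calibration can be
global (intensity-weighted), per pixel, or per n×n ROI (default 4×4,
8×8 recommended for mixtures). Zero-intensity pixels carry a validity
flag instead of propagating NaN.

Two-species mixtures: the mixture phasor lies on the segment joining the
pure-species phasors. Each phasor is orthogonally projected onto that
segment, the projection clamped to the segment, and the phasor ratio is
`r₁ = d₂/(d₁+d₂)`. The volume fraction follows from
`r₁⁻¹ = 1 + (μχ)⁻¹(v₁⁻¹ − 1)`, with `μ` the stock-concentration ratio
and `χ` the brightness ratio; `μχ` is fitted from (v₁, r₁) series by
nonlinear least squares (scipy `curve_fit`), reporting the estimate and
its standard error. Lifetime maps color-code the per-pixel ratio through
a spectrum scale (ratio 0 → red, 1 → blue) at constant luminance
(`flat`) or luminance scaled by normalised intensity (`scaled`).

## Photon economy

`F = √N σ_τ/τ` normalises lifetime precision to the ideal TCSPC limit
`F = 1`. A gate of width `W` blurs each timestamp by a uniform offset of
std `W/√12`; the mean of `N` such offsets (Bates-distributed) adds
`W²/(12N)` to the timestamp-mean variance, giving the first-order bound
`F_W = √(1 + (W/τ)²/12)`. The approximation degrades for `W ≳ τ` but
remains a lower bound.

The Monte Carlo estimator reproduces the measurement: per replicate it
draws `N_i` detected sample photons and `N_c` detected calibration
photons through `G` independent gate exposures, computes both phasors
and the calibrated phase lifetime with the same code used for real
stacks, and reports the replicate std `σ̃` (sample and calibration shot
noise combined, equivalent to summing their variances) and
`F̃ = √N_i σ̃/τ_i`, with standard errors from bootstrap resampling of
the replicate set. Because each gate position is an independent
exposure, per-gate detected counts conditioned on the total are exactly
multinomial with weights proportional to the gate capture fractions, and
the sampler uses that closed form directly. The package also provides a
multiply-counting discretizer (`gate_bin_timestamps`) in which one
photon stream is re-detected at every gate position; it is useful as a
deterministic binning utility but deliberately **not** used in the Monte
Carlo, since fully correlated gate counts make the gate transfer factor
noiseless and understate the width dependence of `F`. The default
replicate count is 1000 (SE of `σ̃` ≈ `σ̃/√(2R)`); tests and the
acceptance suite run 300–500 replicates at `N = 500–8000` photons, which
resolves the scaling laws in seconds.

Acquisition timing: the frame rate is
`f_read = ((T_read + T_exp)·b·G)⁻¹`, with the binary-frame exposure set
by a firmware counter `T_exp = n·400 ns − 50 ns`. The ~1.5 s FPGA
restart dead time for sequences beyond 250 ten-bit images is not
modelled. Note the counter cannot produce exactly 10 μs (no integer `n`
gives 10,000 ns), so `T_exp` is accepted as a free parameter and the
counter arithmetic is a separate helper. Gate decimation (keeping every
k-th gate with its timestamp) emulates faster acquisitions; photon
counts drop as `1/k` and the phase-lifetime std grows as `√k`. The
microlens concentration factor is the ratio of dark-subtracted mean
counts with/without the microlens array, and the effective fill factor
is that ratio times the native fill factor.

## Synthetic data versus real data

The simulator emulates: periodic single/multi-exponential decays,
rectangular or trapezoidal scanned gates, 1-bit pile-up, uniform dark
counts, hot pixels, deterministic gate skew, and 8/10-bit accumulation.
It does not emulate afterpulsing, crosstalk, photon-detection-efficiency
non-uniformity, laser-pulse width (calibration absorbs the IRF by
construction, so simulated calibrations are *exact* in a way real ones
are only approximately), readout non-idealities, or the non-Poisson
variance inflation of pile-up-corrected signals. Passing tests therefore
demonstrate the correctness and internal consistency of the analysis
chain under the stated noise model, not detector-specific artefact
handling on real hardware.

Default study conditions used by the test and acceptance suites:
`T = 50 ns`, `f = 20 MHz`, `W = 13.1 ns` (3 ns for the semicircle
geometry check, where narrow gates minimise aliasing), `G = 140` (560
before decimation in the scaling check), `b = 255`, lifetimes 2.8 / 3.6
/ 4.08 ns, mean brightness 0.4–0.8 photons per binary frame, images
24×24–48×48 pixels. These sizes resolve every statistical assertion at
3-SE confidence in a few seconds each.

## Numerical choices and edge cases

- Capture fractions use `expm1`-based closed forms; windows wrapping the
  period split at `T`; conservation over partitions holds to 1e−10.
- `W ≥ T` short-circuits to capture fraction 1.
- Saturated counts clamp to `I_max − ½` and set a per-pixel flag.
- Hot-pixel percentile masking flags ties at the threshold; `p = 0`
  flags nothing.
- Mixture ratios clamp off-segment projections to the nearest endpoint;
  `r₁ ∈ {0, 1}` inverts exactly to `v₁ ∈ {0, 1}`.
- The ROI binner drops trailing partial tiles (a 472×256 frame bins to
  118×64 at 4×4).
- Gate decimation by `target_gates` requires an exact divisor of the
  available gate count; `keep_every` always works.
- Sidecar times are stored in nanoseconds with a seconds mirror field,
  avoiding μs/ns confusion between acquisition timing and gate steps.

## Known limitations

- The tail-average background estimator has no automatic validity
  check against `τ / (T − W)`; the 3-point method suited to long
  lifetimes is not implemented.
- The analytic `F_W` bound is loose for `W ≳ τ`; use the Monte Carlo
  for quantitative expectations.
- Pipeline per-ROI calibration requires the sample and calibration
  stacks to share the sensor grid.
- The simulator's per-pixel generator streams favour reproducibility
  over raw throughput; frames much larger than ~10⁵ pixels simulate in
  tens of seconds rather than milliseconds.
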