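"""Photon-economy analytics and acquisition-timing arithmetic.

The figure of merit for lifetime precision is the F-value

    F = sqrt(N) * sigma_tau / tau,

which equals 1 for an ideal TCSPC measurement of a single-exponential decay
(lifetime estimated as the mean photon arrival time).  A rectangular gate of
width W blurs each photon timestamp by a uniform offset with standard
deviation W/sqrt(12); the mean of N such offsets follows a Bates
distribution, so gating adds W^2/(12 N) to the timestamp-mean variance and

    F_W = sqrt(1 + (W/tau)^2 / 12)

is a first-order lower bound on the achievable F.  A Monte Carlo estimator
reproduces the full pipeline — timestamp simulation, gate binning, phasor
computation and calibration against an independently noisy calibration
sample — to quantify the precision actually delivered by calibrated
phase-lifetime analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .gate_model import GateConfig
from .phasor import calibrate, compute_phasor, phase_lifetime
from .simulator import (
    GateStack,
    gate_bin_timestamps,
    simulate_detected_gate_counts,
    simulate_photon_timestamps,
)

__all__ = [
    "FValueReport",
    "TimingConfig",
    "f_value",
    "sigma_gate",
    "sigma_gate_mean",
    "analytic_sigma_tau",
    "analytic_F",
    "combined_sigma",
    "combined_F",
    "monte_carlo_f",
    "decimate_gates",
    "frame_rate",
    "exposure_time",
    "concentration_factor",
    "effective_fill_factor",
]

THETA0_NS = 50.0   # firmware exposure-counter offset
THETA1_NS = 400.0  # firmware exposure-counter increment


def f_value(n_photons: float, sigma_tau: float, tau: float) -> float:
    """Normalized relative lifetime error F = sqrt(N) * sigma_tau / tau."""
    if tau <= 0:
        raise ValueError("lifetime must be positive")
    if n_photons < 1:
        raise ValueError("need at least one photon")
    if sigma_tau < 0:
        raise ValueError("sigma cannot be negative")
    return math.sqrt(n_photons) * sigma_tau / tau


def sigma_gate(width_ns: float) -> float:
    """Std of a timestamp uniformly blurred over a gate of width W: W/sqrt(12)."""
    return width_ns / math.sqrt(12.0)


def sigma_gate_mean(width_ns: float, n_photons: float) -> float:
    """Std of the mean of N gate-blurred timestamps (Bates): W/sqrt(12 N)."""
    return width_ns / math.sqrt(12.0 * n_photons)


def analytic_sigma_tau(width_ns: float, n_photons: float, tau_ns: float) -> float:
    """Shot-noise + gate-blur lifetime std for timestamp-mean estimation:

    sigma_tau = (tau/sqrt(N)) * sqrt(1 + (W/tau)^2 / 12).
    """
    if width_ns <= 0 or tau_ns <= 0:
        raise ValueError("gate width and lifetime must be positive")
    if n_photons < 1:
        raise ValueError("need at least one photon")
    return tau_ns / math.sqrt(n_photons) * math.sqrt(1.0 + (width_ns / tau_ns) ** 2 / 12.0)


def analytic_F(width_ns: float, tau_ns: float) -> float:
    """Lower-bound F-value of a width-W gated measurement:
    F_W = sqrt(1 + (W/tau)^2 / 12).

    The uniform-blur approximation degrades as W grows past tau, but remains
    a lower bound for the measured phase-lifetime std.
    """
    if width_ns <= 0 or tau_ns <= 0:
        raise ValueError("gate width and lifetime must be positive")
    return math.sqrt(1.0 + (width_ns / tau_ns) ** 2 / 12.0)


def combined_sigma(sigma_sample: float, sigma_cal: float) -> float:
    """Independent sample + calibration noise: sqrt(sigma_i^2 + sigma_c^2)."""
    if sigma_sample < 0 or sigma_cal < 0:
        raise ValueError("sigmas cannot be negative")
    return math.hypot(sigma_sample, sigma_cal)


def combined_F(n_sample: float, sigma_combined_ns: float, tau_sample_ns: float) -> float:
    """F-value including calibration noise: sqrt(N_i) * sigma~ / tau_i."""
    return f_value(n_sample, sigma_combined_ns, tau_sample_ns)


@dataclass(frozen=True)
class FValueReport:
    """Result of a Monte Carlo photon-economy run."""

    n_photons: float
    tau_ns: float
    sigma_tau_ns: float
    sigma_se_ns: float
    F: float
    F_se: float
    analytic_F_W: float
    replicates: int


def monte_carlo_f(
    tau_sample_ns: float,
    tau_cal_ns: float,
    width_ns: float,
    num_gates: int,
    period_ns: float,
    n_sample: int,
    n_cal: int,
    freq_hz: float,
    replicates: int = 1000,
    seed: int = 0,
    bootstrap: int = 200,
) -> FValueReport:
    """Monte Carlo F-value of calibrated phase-lifetime estimation.

    Each replicate simulates N_i detected sample photons (lifetime tau_i)
    and N_c detected calibration photons (tau_c) through G independent gate
    exposures of width W scanned uniformly over the period, computes both
    phasors and the calibrated sample phase lifetime — the same phasor and
    calibration code path used on real stacks.  sigma~ is the std over
    replicates (sample and calibration shot noise combined);
    F~ = sqrt(N_i) * sigma~ / tau_i.  The standard error of sigma~ (and F~)
    comes from bootstrap resampling of the replicate set.
    """
    if replicates < 2:
        raise ValueError("need at least two replicates")
    gates = GateConfig(
        width_ns=width_ns, step_ns=period_ns / num_gates, num_gates=num_gates
    )
    root = np.random.SeedSequence(seed)
    taus = np.empty(replicates)
    for i, child in enumerate(root.spawn(replicates)):
        rng = np.random.default_rng(child)
        I_i = simulate_detected_gate_counts(tau_sample_ns, gates, period_ns, n_sample, rng)
        I_c = simulate_detected_gate_counts(tau_cal_ns, gates, period_ns, n_cal, rng)
        t_k = gates.first_offset_ns + gates.step_ns * np.arange(num_gates)
        z_i = compute_phasor(I_i, t_k, freq_hz)
        z_c = compute_phasor(I_c, t_k, freq_hz)
        z = calibrate(z_i, z_c, tau_cal_ns, freq_hz)
        taus[i] = phase_lifetime(z, freq_hz)

    sigma = float(np.std(taus, ddof=1))
    boot_rng = np.random.default_rng(root.spawn(1)[0])
    idx = boot_rng.integers(0, replicates, size=(bootstrap, replicates))
    sigma_boot = np.std(taus[idx], axis=1, ddof=1)
    sigma_se = float(np.std(sigma_boot, ddof=1))

    F = f_value(n_sample, sigma, tau_sample_ns)
    F_se = math.sqrt(n_sample) * sigma_se / tau_sample_ns
    return FValueReport(
        n_photons=n_sample,
        tau_ns=tau_sample_ns,
        sigma_tau_ns=sigma,
        sigma_se_ns=sigma_se,
        F=F,
        F_se=F_se,
        analytic_F_W=analytic_F(width_ns, tau_sample_ns),
        replicates=replicates,
    )


def decimate_gates(stack: GateStack, keep_every: int | None = None,
                   target_gates: int | None = None) -> GateStack:
    """Retain every k-th gate (with its timestamp) of a stack.

    Emulates a faster acquisition with fewer, more widely spaced gates
    ('virtual' frame-rate experiments).  Give either ``keep_every`` or
    ``target_gates`` (which must divide the available count).
    """
    G = stack.num_gates
    if (keep_every is None) == (target_gates is None):
        raise ValueError("give exactly one of keep_every / target_gates")
    if target_gates is not None:
        if target_gates > G:
            raise ValueError(f"cannot keep {target_gates} of {G} gates")
        if G % target_gates:
            raise ValueError(f"{target_gates} does not evenly subsample {G} gates")
        keep_every = G // target_gates
    if keep_every < 1 or keep_every > G:
        raise ValueError("keep_every out of range")
    sel = slice(0, None, keep_every)
    new_gates = GateConfig(
        width_ns=stack.gates.width_ns,
        step_ns=stack.gates.step_ns * keep_every,
        num_gates=len(range(*sel.indices(G))),
        first_offset_ns=stack.gates.first_offset_ns,
        edge_ns=stack.gates.edge_ns,
    )
    return GateStack(
        counts=stack.counts[sel].copy(),
        timestamps_ns=stack.timestamps_ns[sel].copy(),
        i_max=stack.i_max,
        bit_depth=stack.bit_depth,
        laser=stack.laser,
        gates=new_gates,
    )


@dataclass(frozen=True)
class TimingConfig:
    """Binary-frame acquisition timing (global shutter: expose then read).

    All times in nanoseconds; ``frames_per_gate`` is b (255 for 8-bit
    gate images, 1020 for 10-bit) and ``num_gates`` is G.
    """

    t_read_ns: float
    t_exp_ns: float
    frames_per_gate: int
    num_gates: int

    def __post_init__(self) -> None:
        if min(self.t_read_ns, self.t_exp_ns) <= 0:
            raise ValueError("times must be positive")
        if self.frames_per_gate < 1 or self.num_gates < 1:
            raise ValueError("counts must be >= 1")

    @classmethod
    def from_exposure_counter(cls, n: int, t_read_ns: float,
                              frames_per_gate: int, num_gates: int) -> "TimingConfig":
        return cls(t_read_ns, exposure_time(n), frames_per_gate, num_gates)


def exposure_time(n: int) -> float:
    """Binary-frame exposure from the firmware counter: T_exp = n*400ns - 50ns."""
    if n < 1:
        raise ValueError("counter must be >= 1")
    return n * THETA1_NS - THETA0_NS


def frame_rate(cfg: TimingConfig) -> float:
    """Acquisition frame rate f_read = 1 / ((T_read + T_exp) * b * G), in Hz.

    This is the inverse of the total expose+readout time of one full gate
    sequence; FPGA-restart dead time for very long sequences is not modeled.
    """
    total_ns = (cfg.t_read_ns + cfg.t_exp_ns) * cfg.frames_per_gate * cfg.num_gates
    return 1e9 / total_ns


def acquisition_time_s(cfg: TimingConfig) -> float:
    """Wall time of one full sequence (the reciprocal of the frame rate)."""
    return 1.0 / frame_rate(cfg)


def concentration_factor(mean_with: float, mean_without: float,
                         dark_with: float = 0.0, dark_without: float = 0.0) -> float:
    """Microlens concentration factor: ratio of dark-subtracted mean counts
    with and without the microlens array."""
    num = mean_with - dark_with
    den = mean_without - dark_without
    if den <= 0:
        raise ValueError("dark-subtracted reference mean must be positive")
    return num / den


def effective_fill_factor(cf: float, native_fill_factor_pct: float) -> float:
    """Effective fill factor (%) = concentration factor x native fill factor."""
    if cf <= 0 or native_fill_factor_pct <= 0:
        raise ValueError("inputs must be positive")
    return cf * native_fill_factor_pct
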