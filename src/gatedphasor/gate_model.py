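"""Domain types and the noiseless forward model of time-gated decay detection.

A pulsed laser with period ``T`` excites a fluorescent sample; emission decays
exponentially with lifetime ``tau``.  The detector is sensitive only during a
rectangular gate of width ``W`` whose start is scanned across the period in
steps of ``dt`` (``G`` positions).  Under steady-state periodic excitation the
per-period photon-arrival density for a single-exponential decay is

    p(t) = exp(-t/tau) / (tau * (1 - exp(-T/tau))),   t in [0, T),

and the expected fraction of photons captured by a gate is its integral over
the (period-wrapped) gate window, available in closed form.

All times are in nanoseconds throughout the package; frequencies are
converted to ns^-1 at the type boundary.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "LaserConfig",
    "GateConfig",
    "DecayModel",
    "gate_timestamps",
    "expected_gate_fraction",
    "expected_gate_profile",
]

NS_PER_S = 1e9


@dataclass(frozen=True)
class LaserConfig:
    """Pulsed-laser timing: period ``T`` (ns) and phasor frequency ``f`` (Hz).

    The phasor frequency defaults to the repetition rate 1/T (the fundamental
    harmonic); higher harmonics may be requested explicitly.
    """

    period_ns: float
    phasor_freq_hz: float | None = None

    def __post_init__(self) -> None:
        if not self.period_ns > 0:
            raise ValueError(f"laser period must be positive, got {self.period_ns}")
        if self.phasor_freq_hz is None:
            object.__setattr__(self, "phasor_freq_hz", self.rep_rate_hz)
        if not self.phasor_freq_hz > 0:
            raise ValueError("phasor frequency must be positive")

    @property
    def rep_rate_hz(self) -> float:
        return NS_PER_S / self.period_ns

    @property
    def phasor_freq_per_ns(self) -> float:
        """Phasor frequency in ns^-1 (the unit used by all internal math)."""
        return self.phasor_freq_hz / NS_PER_S


@dataclass(frozen=True)
class GateConfig:
    """Rectangular-gate scan: width W, step dt, count G, first offset (ns).

    ``edge_ns`` optionally models linear rise/fall edges (trapezoidal gate);
    the default 0 is the ideal rectangle.
    """

    width_ns: float
    step_ns: float
    num_gates: int
    first_offset_ns: float = 0.0
    edge_ns: float = 0.0

    def __post_init__(self) -> None:
        if not self.width_ns > 0:
            raise ValueError("gate width must be positive")
        if not self.step_ns > 0:
            raise ValueError("gate step must be positive")
        if self.num_gates < 1:
            raise ValueError("need at least one gate")
        if self.edge_ns < 0:
            raise ValueError("edge duration cannot be negative")


@dataclass(frozen=True)
class DecayModel:
    """Fluorescence decay: one or more lifetimes (ns) with amplitudes.

    Amplitudes are relative photon-number weights (normalised internally).
    ``background_rate_per_ns`` is an uncorrelated (time-uniform) count rate.
    """

    lifetimes_ns: tuple[float, ...]
    amplitudes: tuple[float, ...] = ()
    background_rate_per_ns: float = 0.0

    def __post_init__(self) -> None:
        lifetimes = tuple(float(t) for t in np.atleast_1d(self.lifetimes_ns))
        object.__setattr__(self, "lifetimes_ns", lifetimes)
        amps = self.amplitudes
        if len(amps) == 0:
            amps = (1.0,) * len(lifetimes)
        amps = tuple(float(a) for a in amps)
        object.__setattr__(self, "amplitudes", amps)
        if len(amps) != len(lifetimes):
            raise ValueError("amplitudes and lifetimes must have equal length")
        if any(t <= 0 for t in lifetimes):
            raise ValueError("all lifetimes must be positive")
        if any(a < 0 for a in amps):
            raise ValueError("amplitudes must be nonnegative")
        if sum(amps) <= 0:
            raise ValueError("amplitudes must not all vanish")
        if self.background_rate_per_ns < 0:
            raise ValueError("background rate cannot be negative")

    @classmethod
    def single(cls, tau_ns: float, background_rate_per_ns: float = 0.0) -> "DecayModel":
        return cls((float(tau_ns),), (1.0,), background_rate_per_ns)

    @property
    def weights(self) -> np.ndarray:
        a = np.asarray(self.amplitudes, dtype=float)
        return a / a.sum()


def gate_timestamps(cfg: GateConfig) -> np.ndarray:
    """Gate timestamps t_k = first_offset + (k-1)*step for k = 1..G (ns)."""
    return cfg.first_offset_ns + cfg.step_ns * np.arange(cfg.num_gates, dtype=float)


def _exp_window_integral(u: np.ndarray, v: np.ndarray, tau: float, T: float) -> np.ndarray:
    """Integral of the periodic steady-state decay density over [u, v] ⊂ [0, T]."""
    norm = -np.expm1(-T / tau)
    return (np.exp(-u / tau) - np.exp(-v / tau)) / norm


def _single_fraction(gate_start: np.ndarray, W: float, tau: float, T: float) -> np.ndarray:
    a = np.mod(gate_start, T)
    end = a + W
    # split at the period boundary when the window wraps
    main = _exp_window_integral(a, np.minimum(end, T), tau, T)
    wrap = np.where(end > T, _exp_window_integral(0.0, np.maximum(end - T, 0.0), tau, T), 0.0)
    return main + wrap


def expected_gate_fraction(
    decay: DecayModel,
    gate_start: float | np.ndarray,
    width_ns: float,
    period_ns: float,
    edge_ns: float = 0.0,
) -> float | np.ndarray:
    """Fraction of fluorescence photons falling in a gate window.

    The gate opens at ``gate_start`` (taken modulo the period) for
    ``width_ns``; windows wider than the period capture everything.  With
    ``edge_ns > 0`` the gate is a symmetric trapezoid whose rise/fall each
    last ``edge_ns`` and whose flat top still spans ``width_ns - edge_ns``
    (area preserved); the edge integrals are evaluated by fixed-order
    Gauss-Legendre quadrature of the linear ramps against the decay density.

    Multi-exponential decays give the amplitude-weighted sum of the
    single-lifetime fractions.  The uncorrelated background term is *not*
    included here (see :func:`expected_gate_profile`).
    """
    W, T = float(width_ns), float(period_ns)
    if W <= 0 or T <= 0:
        raise ValueError("gate width and period must be positive")
    starts = np.asarray(gate_start, dtype=float)
    scalar = starts.ndim == 0

    if W >= T and edge_ns == 0.0:
        out = np.ones_like(starts, dtype=float)
        return float(out) if scalar else out

    if edge_ns > 0.0:
        out = _trapezoid_fraction(decay, starts, W, T, float(edge_ns))
        return float(out) if scalar else out

    out = np.zeros_like(starts, dtype=float)
    for tau, w in zip(decay.lifetimes_ns, decay.weights):
        out += w * _single_fraction(starts, W, tau, T)
    return float(out) if scalar else out


def _trapezoid_fraction(
    decay: DecayModel, starts: np.ndarray, W: float, T: float, edge: float
) -> np.ndarray:
    """Trapezoidal-gate capture fraction via quadrature of the ramp edges.

    Transmission ramps 0→1 over [start-edge/2, start+edge/2], is 1 on the
    flat top, and ramps down symmetrically around start+W; total area equals
    the W of the ideal rectangle.
    """
    if edge > W:
        raise ValueError("edge duration cannot exceed the gate width")
    # 32-node Gauss-Legendre on each ramp is exact to machine precision for
    # the smooth integrand at any realistic edge/tau ratio.
    nodes, wts = np.polynomial.legendre.leggauss(32)

    def density(t: np.ndarray) -> np.ndarray:
        t = np.mod(t, T)
        p = np.zeros_like(t)
        for tau, w in zip(decay.lifetimes_ns, decay.weights):
            p += w * np.exp(-t / tau) / (tau * -np.expm1(-T / tau))
        return p

    flat = expected_gate_fraction(
        DecayModel(decay.lifetimes_ns, decay.amplitudes), starts + edge / 2.0, W - edge, T
    )
    out = np.asarray(flat, dtype=float).copy()
    for s0, rising in ((starts - edge / 2.0, True), (starts + W - edge / 2.0, False)):
        t = s0[..., None] + (nodes + 1.0) * (edge / 2.0)
        ramp = (nodes + 1.0) / 2.0
        if not rising:
            ramp = 1.0 - ramp
        out += (edge / 2.0) * np.sum(wts * ramp * density(t), axis=-1)
    return out


def expected_gate_profile(
    decay: DecayModel,
    gates: GateConfig,
    laser: LaserConfig,
    photons_per_frame: float,
    pulses_per_frame: float = 1.0,
) -> np.ndarray:
    """Expected detected photons per binary frame at each gate position.

    lambda_k = photons_per_frame * capture_fraction(t_k)
             + background_rate * W * pulses_per_frame

    ``photons_per_frame`` is the expected number of fluorescence photons per
    binary frame reaching the pixel (summed over all laser pulses in the
    frame exposure); the uniform background contributes only while the gate
    is open, i.e. for W per pulse.  The profile is periodic in the gate
    timestamp with period T.
    """
    if photons_per_frame < 0:
        raise ValueError("photons_per_frame cannot be negative")
    t = gate_timestamps(gates)
    frac = expected_gate_fraction(
        decay, t, gates.width_ns, laser.period_ns, edge_ns=gates.edge_ns
    )
    dark = decay.background_rate_per_ns * gates.width_ns * pulses_per_frame
    return photons_per_frame * np.asarray(frac, dtype=float) + dark


# --- JSON sidecar (de)serialization -----------------------------------------

_SIDE_KEYS = ("period_ns", "gate_width_ns", "gate_step_ns", "num_gates",
              "first_offset_ns", "phasor_freq_hz")


def configs_to_dict(laser: LaserConfig, gates: GateConfig) -> dict:
    return {
        "period_ns": laser.period_ns,
        "gate_width_ns": gates.width_ns,
        "gate_step_ns": gates.step_ns,
        "num_gates": gates.num_gates,
        "first_offset_ns": gates.first_offset_ns,
        "phasor_freq_hz": laser.phasor_freq_hz,
    }


def configs_from_dict(d: dict) -> tuple[LaserConfig, GateConfig]:
    missing = [k for k in _SIDE_KEYS if k not in d]
    if missing:
        raise KeyError(f"sidecar missing keys: {missing}")
    laser = LaserConfig(period_ns=d["period_ns"], phasor_freq_hz=d["phasor_freq_hz"])
    gates = GateConfig(
        width_ns=d["gate_width_ns"],
        step_ns=d["gate_step_ns"],
        num_gates=int(d["num_gates"]),
        first_offset_ns=d["first_offset_ns"],
    )
    return laser, gates


def save_configs(laser: LaserConfig, gates: GateConfig, path: str | Path) -> None:
    Path(path).write_text(json.dumps(configs_to_dict(laser, gates), indent=2))


def load_configs(path: str | Path) -> tuple[LaserConfig, GateConfig]:
    return configs_from_dict(json.loads(Path(path).read_text()))
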