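"""Forward simulator of binary-frame time-gated acquisitions.

The camera records 1-bit frames: during one frame exposure any number of
photons may arrive while the gate is open, but the pixel memory stores only
whether at least one was detected.  ``b`` binary frames are accumulated into
one gate image, so the recorded count at a gate position is

    counts ~ Binomial(b, 1 - exp(-lambda)),

with ``lambda`` the expected in-gate photons per binary frame.  Pile-up (the
saturation of counts below ``b * lambda``) therefore emerges naturally rather
than being injected.

A second, lighter-weight path simulates individual photon timestamps and bins
them through the (overlapping) gate windows; this is the engine of the
Monte Carlo F-value machinery in :mod:`gatedphasor.statistics`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .gate_model import (
    DecayModel,
    GateConfig,
    LaserConfig,
    expected_gate_fraction,
    gate_timestamps,
)

__all__ = [
    "SimulationParams",
    "GateStack",
    "binary_detection_probability",
    "simulate_gate_stack",
    "simulate_photon_timestamps",
    "gate_bin_timestamps",
    "simulate_detected_gate_counts",
]


@dataclass
class GateStack:
    """A stack of G gate images with acquisition metadata.

    ``counts`` has shape (G, H, W); every entry lies in [0, i_max] where
    ``i_max`` equals the number of accumulated binary frames (255 for 8-bit,
    1020 for 10-bit acquisitions).
    """

    counts: np.ndarray
    timestamps_ns: np.ndarray
    i_max: int
    bit_depth: int
    laser: LaserConfig
    gates: GateConfig

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.timestamps_ns = np.asarray(self.timestamps_ns, dtype=float)
        if self.counts.ndim != 3:
            raise ValueError("counts must be a (G, H, W) array")
        if len(self.timestamps_ns) != self.counts.shape[0]:
            raise ValueError("one timestamp per gate required")
        if self.bit_depth not in (8, 10):
            raise ValueError("bit depth must be 8 or 10")
        if self.counts.min(initial=0) < 0 or self.counts.max(initial=0) > self.i_max:
            raise ValueError("counts must lie in [0, i_max]")

    @property
    def num_gates(self) -> int:
        return self.counts.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.counts.shape[1:]

    def total_intensity(self) -> np.ndarray:
        """Per-pixel intensity summed over gates."""
        return self.counts.sum(axis=0)


@dataclass
class SimulationParams:
    """Everything needed to synthesise a gate stack.

    brightness: expected fluorescence photons per binary frame, scalar or
        per-pixel (H, W) map.
    dark_count_rate_cps: detector dark counts per second, scalar or map;
        dark photons are uniform in time and detected only while the gate is
        open.
    hot_pixel_fraction: fraction of pixels whose DCR is replaced by
        ``hot_pixel_dcr_cps`` (the field mimics fabrication defects).
    skew_ns: optional per-pixel additive offset of the gate start
        (deterministic gate-edge non-uniformity).
    frame_exposure_ns: exposure of one binary frame; together with the laser
        period it sets the number of pulses (and the gate-open time) per
        frame.
    """

    laser: LaserConfig
    gates: GateConfig
    decay: DecayModel
    shape: tuple[int, int]
    brightness: float | np.ndarray
    frames_per_gate: int = 255
    dark_count_rate_cps: float | np.ndarray = 0.0
    hot_pixel_fraction: float = 0.0
    hot_pixel_dcr_cps: float = 10_000.0
    skew_ns: np.ndarray | None = None
    frame_exposure_ns: float = 10_000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frames_per_gate < 1:
            raise ValueError("frames_per_gate must be >= 1")
        if not (0.0 <= self.hot_pixel_fraction < 1.0):
            raise ValueError("hot_pixel_fraction must be in [0, 1)")
        if np.any(np.asarray(self.brightness) < 0):
            raise ValueError("brightness must be nonnegative")
        if np.any(np.asarray(self.dark_count_rate_cps) < 0):
            raise ValueError("dark count rate must be nonnegative")
        for name in ("brightness", "dark_count_rate_cps", "skew_ns"):
            arr = getattr(self, name)
            if arr is not None and np.ndim(arr) not in (0, 2):
                raise ValueError(f"{name} must be scalar or a (H, W) map")
            if np.ndim(arr) == 2 and np.shape(arr) != tuple(self.shape):
                raise ValueError(f"{name} map shape {np.shape(arr)} != {self.shape}")

    @property
    def pulses_per_frame(self) -> float:
        return self.frame_exposure_ns / self.laser.period_ns


def binary_detection_probability(lam: float | np.ndarray) -> float | np.ndarray:
    """Probability that a 1-bit pixel memory is set during one frame.

    Photon arrivals are Poisson with in-gate mean ``lam``; the memory latches
    on the first detection, so P(set) = 1 - exp(-lam).
    """
    lam = np.asarray(lam, dtype=float)
    if np.any(lam < 0):
        raise ValueError("expected photon number cannot be negative")
    out = -np.expm1(-lam)
    return float(out) if out.ndim == 0 else out


def _pixel_rng(seed: int, row: int, col: int) -> np.random.Generator:
    # independent, order-free stream per pixel: sub-regions regenerate alone
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(row, col)))


def _as_map(value, shape) -> np.ndarray:
    return np.broadcast_to(np.asarray(value, dtype=float), shape).copy()


def simulate_gate_stack(params: SimulationParams) -> GateStack:
    """Draw a synthetic gate stack; identical params + seed give identical data.

    Per pixel and gate position, counts ~ Binomial(b, 1 - exp(-lambda_k))
    where lambda_k combines the fluorescence capture fraction of the
    (possibly skewed) gate and the dark-count contribution
    DCR * gate-open-time-per-frame.
    """
    H, W = params.shape
    G = params.gates.num_gates
    t = gate_timestamps(params.gates)
    T = params.laser.period_ns

    brightness = _as_map(params.brightness, (H, W))
    dcr = _as_map(params.dark_count_rate_cps, (H, W))
    skew = (
        np.zeros((H, W)) if params.skew_ns is None else _as_map(params.skew_ns, (H, W))
    )

    # hot pixels chosen from a dedicated stream so the set is seed-stable
    if params.hot_pixel_fraction > 0:
        n_hot = int(round(params.hot_pixel_fraction * H * W))
        hot_rng = np.random.default_rng(
            np.random.SeedSequence(params.seed, spawn_key=(0x407,))
        )
        flat = hot_rng.choice(H * W, size=n_hot, replace=False)
        dcr.flat[flat] = params.hot_pixel_dcr_cps

    gate_open_ns = params.gates.width_ns * params.pulses_per_frame
    dark_lambda = dcr * 1e-9 * gate_open_ns  # cps -> counts/ns

    counts = np.empty((G, H, W), dtype=np.uint16)
    unique_skews = np.unique(skew)
    # capture fractions depend on the pixel only through its skew; cache per value
    frac_by_skew = {
        s: np.asarray(
            expected_gate_fraction(
                params.decay, t + s, params.gates.width_ns, T,
                edge_ns=params.gates.edge_ns,
            )
        )
        for s in unique_skews
    }
    for r in range(H):
        for c in range(W):
            lam = brightness[r, c] * frac_by_skew[skew[r, c]] + dark_lambda[r, c]
            p = -np.expm1(-lam)
            rng = _pixel_rng(params.seed, r, c)
            counts[:, r, c] = rng.binomial(params.frames_per_gate, p)

    bit_depth = 8 if params.frames_per_gate <= 255 else 10
    return GateStack(
        counts=counts,
        timestamps_ns=t,
        i_max=params.frames_per_gate,
        bit_depth=bit_depth,
        laser=params.laser,
        gates=params.gates,
    )


def simulate_photon_timestamps(
    tau_ns: float, period_ns: float, n: int, rng: np.random.Generator | int
) -> np.ndarray:
    """Draw ``n`` photon arrival times in [0, T) under periodic excitation.

    Steady state with one excitation pulse per period is equivalent to
    drawing exponential(tau) delays and folding them modulo T.
    """
    if tau_ns <= 0 or period_ns <= 0:
        raise ValueError("lifetime and period must be positive")
    if n < 1:
        raise ValueError("need at least one photon")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    return np.mod(rng.exponential(tau_ns, size=n), period_ns)


def gate_bin_timestamps(
    timestamps_ns: np.ndarray, gates: GateConfig, period_ns: float
) -> np.ndarray:
    """Count photons falling inside each (wrapped) gate window.

    Overlapping gates multiply-count photons, exactly as a scanned-gate
    acquisition re-detects the same part of the decay at every position.
    """
    ts = np.asarray(timestamps_ns, dtype=float)
    if np.any((ts < 0) | (ts >= period_ns)):
        raise ValueError("timestamps must lie in [0, T)")
    starts = np.mod(gate_timestamps(gates), period_ns)
    if gates.width_ns >= period_ns:
        return np.full(gates.num_gates, ts.size, dtype=np.int64)
    # photon at x is in gate k iff (x - start_k) mod T < W; count via sorted
    # order statistics, splitting windows that wrap past the period end
    srt = np.sort(ts)
    end = starts + gates.width_ns
    main = np.searchsorted(srt, np.minimum(end, period_ns), side="left") - \
        np.searchsorted(srt, starts, side="left")
    wrapped = np.searchsorted(srt, np.maximum(end - period_ns, 0.0), side="left")
    return main + np.where(end > period_ns, wrapped, 0)


def simulate_detected_gate_counts(
    tau_ns: float,
    gates: GateConfig,
    period_ns: float,
    n_detected: int,
    rng: np.random.Generator | int,
) -> np.ndarray:
    """Simulate per-gate photon counts of a sequential scanned-gate acquisition.

    Unlike :func:`gate_bin_timestamps` (which re-detects one photon stream at
    every gate position, so overlapping gates share photons), this models the
    physical process in which each gate position is an independent exposure:
    an emitted photon arrives during exactly one gate exposure, drawn
    uniformly over the sequence, and is detected only if its arrival phase
    falls inside that gate's window.  Sampling continues until ``n_detected``
    photons are recorded, so the counts are multinomial over gates with
    probabilities proportional to the gate capture fractions — the model
    behind the shot-noise Monte Carlo.
    """
    if n_detected < 1:
        raise ValueError("need at least one detected photon")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    # conditioning the sequential detection process on the total detected
    # count makes the per-gate counts exactly multinomial with weights
    # proportional to the gate capture fractions
    t = gate_timestamps(gates)
    frac = np.asarray(
        expected_gate_fraction(
            DecayModel.single(tau_ns), t, gates.width_ns, period_ns,
            edge_ns=gates.edge_ns,
        )
    )
    return rng.multinomial(n_detected, frac / frac.sum())
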