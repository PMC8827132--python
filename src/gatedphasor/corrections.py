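"""Pre-processing of recorded gate stacks.

Order of operations is fixed: pile-up linearization (per pixel, per gate, on
raw recorded counts) -> background subtraction -> optional ROI binning ->
phasor analysis.  The pile-up inverse is nonlinear, so it is only valid on
per-pixel recorded counts, never on binned or background-subtracted data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .simulator import GateStack

__all__ = [
    "CorrectedStack",
    "pileup_correct",
    "saturate",
    "estimate_background_tail",
    "subtract_background",
    "hot_pixel_mask",
    "interpolate_masked",
    "correct_stack",
]


@dataclass
class CorrectedStack:
    """Gate stack after corrections: real-valued, possibly negative entries.

    Provenance flags record, per pixel, whether any gate saturated, whether
    the pixel was masked as hot, and whether its values were interpolated
    from neighbors.  ``background`` is the per-pixel per-gate offset that was
    subtracted (zeros if none).
    """

    values: np.ndarray
    timestamps_ns: np.ndarray
    saturated: np.ndarray
    hot: np.ndarray
    interpolated: np.ndarray
    background: np.ndarray
    laser: object = None
    gates: object = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        shape = self.values.shape[1:]
        for name in ("saturated", "hot", "interpolated", "background"):
            arr = np.asarray(getattr(self, name))
            if arr.shape != shape:
                raise ValueError(f"{name} shape {arr.shape} != image shape {shape}")
            setattr(self, name, arr)

    def total_intensity(self) -> np.ndarray:
        return self.values.sum(axis=0)


def pileup_correct(i_rec: np.ndarray, i_max: int) -> np.ndarray:
    """Invert 1-bit pile-up saturation: I_corr = -I_max * ln(1 - I_rec/I_max).

    Monotone increasing, >= I_rec, and asymptotically linear for small
    counts.  Fully saturated bins (I_rec == I_max) are clamped to
    I_max - 0.5 before the logarithm (which otherwise diverges); use
    :func:`saturation_mask` / the stack-level pipeline to track them.
    """
    if i_max <= 0:
        raise ValueError("i_max must be positive")
    rec = np.asarray(i_rec, dtype=float)
    if np.any(rec < 0) or np.any(rec > i_max):
        raise ValueError("recorded counts must lie in [0, i_max]")
    rec = np.where(rec >= i_max, i_max - 0.5, rec)
    out = -i_max * np.log1p(-rec / i_max)
    return out if out.ndim else float(out)


def saturate(i_true: np.ndarray, i_max: int) -> np.ndarray:
    """Forward pile-up model (expected counts): I_max * (1 - exp(-I/I_max))."""
    return i_max * -np.expm1(-np.asarray(i_true, dtype=float) / i_max)


def saturation_mask(i_rec: np.ndarray, i_max: int) -> np.ndarray:
    return np.asarray(i_rec) >= i_max


def estimate_background_tail(
    values: np.ndarray, timestamps_ns: np.ndarray, tail_window_ns: tuple[float, float]
) -> np.ndarray:
    """Per-pixel background per gate from the decay tail.

    Averages, per pixel, the gate values whose timestamps fall inside
    ``tail_window_ns`` = (t0, t1].  Valid when the lifetime is much shorter
    than T - W so the window sees only uncorrelated background; for longer
    lifetimes the decay never reaches the background level within the period
    and this estimator is biased high.
    """
    t0, t1 = tail_window_ns
    ts = np.asarray(timestamps_ns, dtype=float)
    sel = (ts >= t0) & (ts <= t1)
    if not sel.any():
        raise ValueError(f"no gate timestamps inside window ({t0}, {t1}) ns")
    return np.asarray(values, dtype=float)[sel].mean(axis=0)


def subtract_background(values: np.ndarray, background: np.ndarray) -> np.ndarray:
    """Subtract a per-pixel (or scalar) per-gate background offset.

    Results are deliberately not clamped at zero: clamping would bias the
    phasor sums of low-count pixels.
    """
    values = np.asarray(values, dtype=float)
    background = np.asarray(background, dtype=float)
    if background.ndim and background.shape != values.shape[1:]:
        raise ValueError("background map must match the image shape")
    return values - background


def hot_pixel_mask(intensity: np.ndarray, percentile: float) -> np.ndarray:
    """Flag pixels whose total intensity is in the top ``percentile``.

    ``percentile`` = p flags values >= the (100 - p)th percentile; p = 0
    flags nothing.  Ties at the threshold are all flagged.
    """
    if not (0 <= percentile < 100):
        raise ValueError("percentile must be in [0, 100)")
    intensity = np.asarray(intensity, dtype=float)
    if percentile == 0:
        return np.zeros(intensity.shape, dtype=bool)
    thresh = np.percentile(intensity, 100.0 - percentile)
    return intensity >= thresh


def interpolate_masked(image: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Replace masked pixels by the mean of their unmasked 4-neighbors.

    Edge pixels use whichever neighbors exist.  Pixels all of whose
    neighbors are masked are resolved iteratively, propagating values
    inwards from the unmasked boundary.
    """
    image = np.asarray(image, dtype=float).copy()
    mask = np.asarray(mask, dtype=bool).copy()
    if mask.all():
        raise ValueError("cannot interpolate: every pixel is masked")
    while mask.any():
        filled_any = False
        out = image.copy()
        new_mask = mask.copy()
        rows, cols = np.nonzero(mask)
        for r, c in zip(rows, cols):
            acc, n = 0.0, 0
            for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
                rr, cc = r + dr, c + dc
                if 0 <= rr < image.shape[0] and 0 <= cc < image.shape[1] and not mask[rr, cc]:
                    acc += image[rr, cc]
                    n += 1
            if n:
                out[r, c] = acc / n
                new_mask[r, c] = False
                filled_any = True
        image, mask = out, new_mask
        if not filled_any:  # pragma: no cover - unreachable when not all masked
            raise RuntimeError("interpolation failed to progress")
    return image


def correct_stack(
    stack: GateStack,
    pileup: bool = True,
    tail_window_ns: tuple[float, float] | None = None,
    background: float | np.ndarray | None = None,
    hot_percentile: float = 0.0,
    interpolate_hot: bool = True,
) -> CorrectedStack:
    """Full pre-processing pipeline on a recorded stack.

    Applies, in order: pile-up linearization, tail-window (or user-supplied
    constant) background subtraction, hot-pixel masking on total intensity
    and 4-neighbor interpolation of the masked pixels in every gate plane.
    """
    values = stack.counts.astype(float)
    saturated = saturation_mask(stack.counts, stack.i_max).any(axis=0)
    if pileup:
        values = pileup_correct(stack.counts, stack.i_max)

    shape = stack.frame_shape
    bg = np.zeros(shape)
    if tail_window_ns is not None and background is not None:
        raise ValueError("give either a tail window or a constant background, not both")
    if tail_window_ns is not None:
        bg = estimate_background_tail(values, stack.timestamps_ns, tail_window_ns)
    elif background is not None:
        bg = np.broadcast_to(np.asarray(background, dtype=float), shape).copy()
    values = subtract_background(values, bg)

    hot = np.zeros(shape, dtype=bool)
    interpolated = np.zeros(shape, dtype=bool)
    if hot_percentile > 0:
        hot = hot_pixel_mask(values.sum(axis=0), hot_percentile)
        if interpolate_hot and hot.any() and not hot.all():
            values = np.stack([interpolate_masked(plane, hot) for plane in values])
            interpolated = hot.copy()

    return CorrectedStack(
        values=values,
        timestamps_ns=stack.timestamps_ns,
        saturated=saturated,
        hot=hot,
        interpolated=interpolated,
        background=bg,
        laser=stack.laser,
        gates=stack.gates,
    )
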