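"""Phasor analysis: computation, calibration, lifetimes, mixtures, maps.

The phasor of a decay sampled by gates k = 1..G with intensities I_k and
timestamps t_k is the normalised first Fourier coefficient at the phasor
frequency f (by default the laser repetition rate):

    z = g + i s = sum_k I_k exp(i 2 pi f t_k) / sum_k I_k.

Single-exponential decays lie on the universal semicircle
(g - 1/2)^2 + s^2 = 1/4, and the phase angle gives the fitting-free phase
lifetime tau = tan(phi) / (2 pi f).  Instrument response and the gate
integration rescale/rotate every phasor by a common complex factor, which a
measurement of a known-lifetime calibration sample removes by complex
division.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "Phasor",
    "PhasorImage",
    "MixtureResult",
    "compute_phasor",
    "compute_phasor_image",
    "phase_lifetime",
    "single_exp_phasor",
    "calibrate",
    "calibrate_image",
    "bin_rois",
    "phasor_ratio",
    "volume_fraction",
    "phasor_ratio_from_volume_fraction",
    "fit_mu_chi",
    "lifetime_map",
    "phasor_histogram2d",
]

TWO_PI = 2.0 * np.pi


@dataclass(frozen=True)
class Phasor:
    """A point z = g + i*s in the phasor plane."""

    g: float
    s: float

    @property
    def z(self) -> complex:
        return complex(self.g, self.s)

    @property
    def modulus(self) -> float:
        return float(np.hypot(self.g, self.s))

    @property
    def phase(self) -> float:
        return float(np.arctan2(self.s, self.g))

    @classmethod
    def from_complex(cls, z: complex) -> "Phasor":
        return cls(float(np.real(z)), float(np.imag(z)))

    def semicircle_residual(self) -> float:
        """Signed distance^2 offset from the universal semicircle:
        (g - 1/2)^2 + s^2 - 1/4 (zero for any single-exponential decay)."""
        return (self.g - 0.5) ** 2 + self.s**2 - 0.25


@dataclass
class PhasorImage:
    """Per-pixel (or per-ROI) phasor maps with intensity and validity."""

    g: np.ndarray
    s: np.ndarray
    intensity: np.ndarray
    valid: np.ndarray
    freq_hz: float

    def __post_init__(self) -> None:
        shapes = {np.shape(a) for a in (self.g, self.s, self.intensity, self.valid)}
        if len(shapes) != 1:
            raise ValueError(f"phasor-image component shapes differ: {shapes}")

    @property
    def z(self) -> np.ndarray:
        return self.g + 1j * self.s

    def phase_lifetimes_ns(self) -> np.ndarray:
        """Per-pixel phase lifetime (ns); NaN where invalid or g <= 0."""
        f_ns = self.freq_hz * 1e-9
        ok = self.valid & (self.g > 0)
        out = np.full(np.shape(self.g), np.nan)
        out[ok] = self.s[ok] / self.g[ok] / (TWO_PI * f_ns)
        return out


def compute_phasor(
    intensities: np.ndarray, timestamps_ns: np.ndarray, freq_hz: float
) -> Phasor:
    """Phasor of a single decay profile (scalar call: zero intensity raises)."""
    I = np.asarray(intensities, dtype=float)
    t = np.asarray(timestamps_ns, dtype=float)
    if I.shape != t.shape:
        raise ValueError("intensities and timestamps must have equal length")
    total = I.sum()
    if total == 0:
        raise ValueError("zero total intensity: phasor undefined")
    f_ns = freq_hz * 1e-9
    z = np.sum(I * np.exp(1j * TWO_PI * f_ns * t)) / total
    return Phasor.from_complex(z)


def compute_phasor_image(
    values: np.ndarray, timestamps_ns: np.ndarray, freq_hz: float
) -> PhasorImage:
    """Per-pixel phasors of a (G, H, W) stack; zero-intensity pixels are
    flagged invalid (not NaN-propagated)."""
    values = np.asarray(values, dtype=float)
    t = np.asarray(timestamps_ns, dtype=float)
    f_ns = freq_hz * 1e-9
    total = values.sum(axis=0)
    valid = total != 0
    phases = np.exp(1j * TWO_PI * f_ns * t)
    num = np.tensordot(phases, values, axes=(0, 0))
    z = np.zeros(total.shape, dtype=complex)
    np.divide(num, total, out=z, where=valid)
    return PhasorImage(
        g=z.real, s=z.imag, intensity=total, valid=valid, freq_hz=freq_hz
    )


def phase_lifetime(p: Phasor, freq_hz: float) -> float:
    """Phase lifetime tau = tan(phi) / (2 pi f) = s / (g * 2 pi f), in ns.

    Only first-quadrant phasors (g > 0) map to a physical lifetime; g <= 0
    returns NaN rather than a negative lifetime.
    """
    if p.g <= 0:
        return float("nan")
    f_ns = freq_hz * 1e-9
    return p.s / p.g / (TWO_PI * f_ns)


def single_exp_phasor(tau_ns: float, freq_hz: float) -> Phasor:
    """Theoretical phasor of a single-exponential decay.

    With u = 2 pi f tau: g = 1/(1+u^2), s = u/(1+u^2) — i.e. modulus
    (1+u^2)^(-1/2) and phase atan(u); always on the universal semicircle,
    approaching (1, 0) as tau -> 0 and (0, 0) as tau -> infinity.
    """
    if tau_ns < 0:
        raise ValueError("lifetime cannot be negative")
    u = TWO_PI * freq_hz * 1e-9 * tau_ns
    d = 1.0 + u * u
    return Phasor(1.0 / d, u / d)


def calibrate(z_exp: Phasor, z_cal_exp: Phasor, tau_cal_ns: float, freq_hz: float) -> Phasor:
    """Correct a measured phasor for IRF and gate effects.

    The instrument multiplies every theoretical phasor by a common complex
    factor; measuring a calibration sample of known lifetime determines it:

        z_corrected = z_exp * z_cal_theo / z_cal_exp.
    """
    if z_cal_exp.g == 0 and z_cal_exp.s == 0:
        raise ValueError("calibration phasor is zero")
    z_theo = single_exp_phasor(tau_cal_ns, freq_hz).z
    return Phasor.from_complex(z_exp.z * z_theo / z_cal_exp.z)


def calibrate_image(
    img: PhasorImage,
    cal: "PhasorImage | Phasor",
    tau_cal_ns: float,
    granularity: str = "per_pixel",
) -> PhasorImage:
    """Calibrate a phasor image with a calibration image or single phasor.

    ``granularity`` selects how the calibration factor is resolved when
    ``cal`` is an image: "global" (one intensity-weighted factor),
    "per_pixel", or "roi:n" (n x n binned calibration map, the paper-style
    per-ROI calibration; img must already be binned to the same grid).
    """
    z_theo = single_exp_phasor(tau_cal_ns, img.freq_hz).z
    if isinstance(cal, Phasor):
        factor = z_theo / cal.z
        z = img.z * factor
        valid = img.valid.copy()
    else:
        if cal.freq_hz != img.freq_hz:
            raise ValueError("calibration frequency differs from image frequency")
        if granularity == "global":
            w = np.where(cal.valid, cal.intensity, 0.0)
            z_cal = (cal.z * w).sum() / w.sum()
            z = img.z * (z_theo / z_cal)
            valid = img.valid.copy()
        elif granularity == "per_pixel" or granularity.startswith("roi"):
            if cal.g.shape != img.g.shape:
                raise ValueError(
                    "calibration map shape differs from image shape; bin both "
                    "to the same ROI grid first"
                )
            valid = img.valid & cal.valid
            z = np.zeros_like(img.z)
            np.divide(img.z * z_theo, cal.z, out=z, where=valid)
        else:
            raise ValueError(f"unknown granularity {granularity!r}")
    return PhasorImage(
        g=z.real, s=z.imag, intensity=img.intensity, valid=valid, freq_hz=img.freq_hz
    )


def bin_rois(values: np.ndarray, n: int) -> np.ndarray:
    """Sum an image (..., H, W) over contiguous n x n tiles.

    Trailing rows/columns that do not fill a tile are dropped.  Leading axes
    (e.g. the gate axis of a stack) are preserved.
    """
    if n < 1:
        raise ValueError("ROI side must be >= 1")
    values = np.asarray(values)
    H, W = values.shape[-2:]
    if n > H or n > W:
        raise ValueError(f"ROI side {n} exceeds image shape {(H, W)}")
    h, w = H // n, W // n
    v = values[..., : h * n, : w * n]
    v = v.reshape(*values.shape[:-2], h, n, w, n)
    return v.sum(axis=(-3, -1))


def phasor_ratio(z: Phasor, z1: Phasor, z2: Phasor) -> tuple[float, Phasor]:
    """Fraction of species 1 from the position along the segment z1--z2.

    The phasor is orthogonally projected onto the line through the two pure
    species' phasors, the projection clamped to the segment, and
    r1 = d2 / (d1 + d2) with d1, d2 the distances from the projection to z1
    and z2.  r1 = 1 at z1, 0 at z2.  Returns (r1, projection point).
    """
    seg = z2.z - z1.z
    L2 = abs(seg) ** 2
    if L2 == 0:
        raise ValueError("reference phasors coincide")
    t = ((z.z - z1.z) * np.conj(seg)).real / L2
    t = min(max(t, 0.0), 1.0)
    proj = z1.z + t * seg
    return 1.0 - t, Phasor.from_complex(proj)


def phasor_ratio_from_volume_fraction(v1: float | np.ndarray, mu_chi: float):
    """Forward mixture relation: r1^-1 = 1 + (mu*chi)^-1 (v1^-1 - 1).

    mu is the stock-concentration ratio and chi the brightness (extinction
    coefficient x quantum yield) ratio of the two dyes; the relation is
    linear only when mu*chi = 1.
    """
    v1 = np.asarray(v1, dtype=float)
    out = np.where(
        v1 <= 0.0, 0.0,
        np.where(v1 >= 1.0, 1.0, 1.0 / (1.0 + (1.0 / mu_chi) * (1.0 / np.maximum(v1, 1e-300) - 1.0))),
    )
    return float(out) if out.ndim == 0 else out


def volume_fraction(r1: float | np.ndarray, mu_chi: float):
    """Invert the phasor ratio to the volume fraction of species 1."""
    if mu_chi <= 0:
        raise ValueError("mu*chi must be positive")
    r1 = np.asarray(r1, dtype=float)
    out = np.where(
        r1 <= 0.0, 0.0,
        np.where(r1 >= 1.0, 1.0, 1.0 / (1.0 + mu_chi * (1.0 / np.maximum(r1, 1e-300) - 1.0))),
    )
    return float(out) if out.ndim == 0 else out


def fit_mu_chi(v1: np.ndarray, r1: np.ndarray) -> tuple[float, float]:
    """Least-squares fit of mu*chi from (volume fraction, phasor ratio) pairs.

    Returns (estimate, standard error).  Raises on degenerate input (< 2
    pairs or all ratios at the 0/1 extremes).
    """
    v1 = np.asarray(v1, dtype=float)
    r1 = np.asarray(r1, dtype=float)
    if v1.size < 2:
        raise ValueError("need at least two (v1, r1) pairs")
    interior = (r1 > 0) & (r1 < 1) & (v1 > 0) & (v1 < 1)
    if interior.sum() < 1:
        raise ValueError("degenerate fit: no interior data points")

    def model(v, mc):
        return phasor_ratio_from_volume_fraction(v, mc)

    popt, pcov = curve_fit(model, v1, r1, p0=[1.0], maxfev=10000)
    return float(popt[0]), float(np.sqrt(pcov[0, 0]))


@dataclass(frozen=True)
class MixtureResult:
    """Phasor-ratio analysis of one mixture against two pure references."""

    r1: float
    d1: float
    d2: float
    projection: Phasor
    v1: float | None = None
    mu_chi: float | None = None


def analyze_mixture(
    z: Phasor, z1: Phasor, z2: Phasor, mu_chi: float | None = None
) -> MixtureResult:
    r1, proj = phasor_ratio(z, z1, z2)
    d1 = abs(proj.z - z1.z)
    d2 = abs(proj.z - z2.z)
    v1 = volume_fraction(r1, mu_chi) if mu_chi is not None else None
    return MixtureResult(r1=r1, d1=d1, d2=d2, projection=proj, v1=v1, mu_chi=mu_chi)


def lifetime_map(
    img: PhasorImage,
    ref_red: Phasor,
    ref_blue: Phasor,
    mode: str = "flat",
    null_color: tuple[float, float, float] = (0.0, 0.0, 0.0),
    cmap: str = "jet_r",
) -> np.ndarray:
    """Color-coded phasor-ratio map as an (H, W, 3) RGB float image.

    Each valid pixel's phasor ratio against the two reference phasors is
    mapped through a spectrum color scale: ratio 0 (at ``ref_red``, the
    short-lifetime reference) renders red, ratio 1 (at ``ref_blue``, the
    long-lifetime reference) renders blue.  ``mode="flat"`` keeps luminance
    constant; ``mode="scaled"`` multiplies by the normalised intensity so
    dark pixels stay dark.  Invalid pixels get ``null_color``.
    """
    from matplotlib import colormaps

    if mode not in ("flat", "scaled"):
        raise ValueError("mode must be 'flat' or 'scaled'")
    seg = ref_blue.z - ref_red.z
    L2 = abs(seg) ** 2
    if L2 == 0:
        raise ValueError("reference phasors coincide")
    t = ((img.z - ref_red.z) * np.conj(seg)).real / L2
    t = np.clip(t, 0.0, 1.0)

    rgb = np.asarray(colormaps[cmap](t))[..., :3]
    if mode == "scaled":
        peak = img.intensity[img.valid].max() if img.valid.any() else 1.0
        lum = np.clip(img.intensity / peak if peak > 0 else img.intensity, 0.0, 1.0)
        rgb = rgb * lum[..., None]
    rgb[~img.valid] = null_color
    return rgb


def phasor_histogram2d(
    img: PhasorImage,
    bins: int = 100,
    range_gs: tuple[tuple[float, float], tuple[float, float]] = ((0.0, 1.0), (0.0, 0.6)),
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """2-D histogram of valid per-pixel phasors over the (g, s) plane.

    Returns (counts, g_edges, s_edges); the total count equals the number of
    valid phasors falling inside ``range_gs``.
    """
    if bins < 1:
        raise ValueError("bins must be >= 1")
    g = img.g[img.valid]
    s = img.s[img.valid]
    counts, g_edges, s_edges = np.histogram2d(g, s, bins=bins, range=range_gs)
    return counts, g_edges, s_edges
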