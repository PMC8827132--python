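"""Stack file I/O, sidecar schema, and the end-to-end analysis pipeline.

A stack on disk is a multi-page 16-bit grayscale TIFF (one page per gate, in
ascending timestamp order) next to a JSON sidecar holding the acquisition
metadata and an append-only processing provenance list.  The sidecar is
validated with a pydantic schema before any pixel data is touched.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import tifffile
from pydantic import BaseModel, Field, field_validator

from .corrections import correct_stack
from .gate_model import GateConfig, LaserConfig, gate_timestamps
from .phasor import (
    Phasor,
    bin_rois,
    calibrate_image,
    compute_phasor_image,
    lifetime_map,
    single_exp_phasor,
)
from .simulator import GateStack

__all__ = ["Sidecar", "read_stack", "write_stack", "convert_ss2",
           "PipelineConfig", "run_pipeline", "phasor_image_to_frame"]

log = logging.getLogger("gatedphasor")


class Sidecar(BaseModel):
    """JSON sidecar schema for a gate-stack TIFF."""

    period_ns: float = Field(gt=0)
    gate_width_ns: float = Field(gt=0)
    gate_step_ns: float = Field(gt=0)
    num_gates: int = Field(ge=1)
    first_offset_ns: float = 0.0
    phasor_freq_hz: float = Field(gt=0)
    bit_depth: Literal[8, 10]
    i_max: int = Field(ge=1)
    # seconds-denominated mirrors for interoperability; ns fields are primary
    period_s: float | None = None
    provenance: list[str] = Field(default_factory=list)

    @field_validator("i_max")
    @classmethod
    def _i_max_matches_depth(cls, v, info):
        depth = info.data.get("bit_depth")
        if depth == 8 and v > 255:
            raise ValueError("8-bit stack cannot exceed i_max 255")
        if depth == 10 and v > 1020:
            raise ValueError("10-bit stack cannot exceed i_max 1020")
        return v

    def to_configs(self) -> tuple[LaserConfig, GateConfig]:
        laser = LaserConfig(period_ns=self.period_ns, phasor_freq_hz=self.phasor_freq_hz)
        gates = GateConfig(
            width_ns=self.gate_width_ns,
            step_ns=self.gate_step_ns,
            num_gates=self.num_gates,
            first_offset_ns=self.first_offset_ns,
        )
        return laser, gates


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_stack(stack: GateStack, path: str | Path,
                provenance: Sequence[str] = ()) -> None:
    """Write a stack as multi-page uint16 TIFF + JSON sidecar (lossless)."""
    path = Path(path)
    tifffile.imwrite(path, stack.counts.astype(np.uint16))
    side = Sidecar(
        period_ns=stack.laser.period_ns,
        gate_width_ns=stack.gates.width_ns,
        gate_step_ns=stack.gates.step_ns,
        num_gates=stack.gates.num_gates,
        first_offset_ns=stack.gates.first_offset_ns,
        phasor_freq_hz=stack.laser.phasor_freq_hz,
        bit_depth=stack.bit_depth,
        i_max=stack.i_max,
        period_s=stack.laser.period_ns * 1e-9,
        provenance=list(provenance),
    )
    _sidecar_path(path).write_text(side.model_dump_json(indent=2))


def read_stack(path: str | Path) -> GateStack:
    """Read a TIFF + sidecar pair, validating schema and invariants."""
    path = Path(path)
    side_path = _sidecar_path(path)
    if not side_path.exists():
        raise FileNotFoundError(f"missing sidecar {side_path}")
    side = Sidecar.model_validate_json(side_path.read_text())
    counts = tifffile.imread(path)
    if counts.ndim == 2:  # single-page stack read back as a plain image
        counts = counts[None]
    if counts.ndim != 3:
        raise ValueError("stack TIFF must be a multi-page 2-D image series")
    if counts.shape[0] != side.num_gates:
        raise ValueError(
            f"TIFF has {counts.shape[0]} pages but sidecar says {side.num_gates} gates"
        )
    if counts.max(initial=0) > side.i_max:
        raise ValueError(f"counts exceed i_max={side.i_max}")
    laser, gates = side.to_configs()
    return GateStack(
        counts=counts,
        timestamps_ns=gate_timestamps(gates),
        i_max=side.i_max,
        bit_depth=side.bit_depth,
        laser=laser,
        gates=gates,
    )


def convert_ss2(subframe_paths: Sequence[str | Path], out_path: str | Path) -> GateStack:
    """Merge four consecutive 8-bit sub-frame stacks into one 10-bit stack.

    The raw-file layout stores each 10-bit gate image as 4 consecutive 8-bit
    gate images; their counts add (255 * 4 = 1020 maximum).
    """
    if len(subframe_paths) != 4:
        raise ValueError("exactly four 8-bit sub-frame stacks expected")
    stacks = [read_stack(p) for p in subframe_paths]
    first = stacks[0]
    for s in stacks[1:]:
        if s.counts.shape != first.counts.shape:
            raise ValueError("sub-frame stacks have inconsistent shapes")
        if s.bit_depth != 8:
            raise ValueError("sub-frame stacks must be 8-bit")
    total = np.sum([s.counts.astype(np.uint16) for s in stacks], axis=0)
    merged = GateStack(
        counts=total,
        timestamps_ns=first.timestamps_ns,
        i_max=first.i_max * 4,
        bit_depth=10,
        laser=first.laser,
        gates=first.gates,
    )
    write_stack(merged, out_path, provenance=["convert-ss2: merged 4 x 8-bit sub-frames"])
    return merged


def phasor_image_to_frame(img, tau_img=None) -> pd.DataFrame:
    """Flatten a PhasorImage into the standard CSV table layout."""
    H, W = img.g.shape
    yy, xx = np.mgrid[0:H, 0:W]
    tau = img.phase_lifetimes_ns()
    return pd.DataFrame(
        {
            "x": xx.ravel(),
            "y": yy.ravel(),
            "g": img.g.ravel(),
            "s": img.s.ravel(),
            "intensity": img.intensity.ravel(),
            "tau_phase_ns": tau.ravel(),
            "valid": img.valid.ravel(),
        }
    )


class PipelineConfig(BaseModel):
    """Declarative configuration of the correct -> bin -> phasor -> calibrate
    -> export pipeline."""

    input_stack: str
    output_dir: str
    pileup: bool = True
    tail_window_ns: tuple[float, float] | None = None
    background: float | None = None
    hot_percentile: float = 0.0
    roi_bin: int = 1
    calibration_stack: str | None = None
    tau_cal_ns: float | None = None
    calibration_granularity: str = "roi:4"
    map_mode: Literal["flat", "scaled", "none"] = "none"
    map_ref_red_tau_ns: float | None = None
    map_ref_blue_tau_ns: float | None = None
    seed: int = 0


def _config_hash(cfg: PipelineConfig) -> str:
    return hashlib.sha256(cfg.model_dump_json().encode()).hexdigest()[:12]


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run the full analysis pipeline; returns a summary dict.

    Stages: read -> corrections -> ROI binning -> phasor -> calibration ->
    exports (phasor CSV, optional lifetime-map PNG).  Every output records
    the config hash and seed in the provenance JSON; identical config and
    inputs reproduce outputs bit-identically.
    """
    out_dir = Path(cfg.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    chash = _config_hash(cfg)

    def stage(name, fn, *args, **kwargs):
        log.info("pipeline[%s] stage %s", chash, name)
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    stack = stage("read", read_stack, cfg.input_stack)
    corrected = stage(
        "correct",
        correct_stack,
        stack,
        pileup=cfg.pileup,
        tail_window_ns=cfg.tail_window_ns,
        background=cfg.background,
        hot_percentile=cfg.hot_percentile,
    )
    values = corrected.values
    if cfg.roi_bin > 1:
        values = stage("bin", bin_rois, values, cfg.roi_bin)
    freq = stack.laser.phasor_freq_hz
    img = stage("phasor", compute_phasor_image, values, stack.timestamps_ns, freq)

    if cfg.calibration_stack is not None:
        if cfg.tau_cal_ns is None:
            raise RuntimeError("pipeline stage 'calibrate' failed: tau_cal_ns required")
        cal_stack = stage("read-cal", read_stack, cfg.calibration_stack)
        cal_corr = stage("correct-cal", correct_stack, cal_stack, pileup=cfg.pileup)
        cal_values = cal_corr.values
        gran = cfg.calibration_granularity
        if gran.startswith("roi:"):
            n = int(gran.split(":", 1)[1])
            if cfg.roi_bin != n:
                cal_values = bin_rois(cal_values, n)
                # analysis image must live on the same grid
                if cfg.roi_bin == 1:
                    values = bin_rois(corrected.values, n)
                    img = compute_phasor_image(values, stack.timestamps_ns, freq)
            else:
                cal_values = bin_rois(cal_values, n)
            gran_mode = "per_pixel"
        elif gran in ("global", "per_pixel"):
            gran_mode = gran
        else:
            raise RuntimeError(f"pipeline stage 'calibrate' failed: bad granularity {gran!r}")
        cal_img = compute_phasor_image(cal_values, cal_stack.timestamps_ns, freq)
        img = stage("calibrate", calibrate_image, img, cal_img, cfg.tau_cal_ns, gran_mode)

    table = phasor_image_to_frame(img)
    csv_path = out_dir / "phasors.csv"
    table.to_csv(csv_path, index=False)

    outputs = {"phasors_csv": str(csv_path)}
    if cfg.map_mode != "none":
        if cfg.map_ref_red_tau_ns is None or cfg.map_ref_blue_tau_ns is None:
            raise RuntimeError("pipeline stage 'map' failed: reference lifetimes required")
        ref_r = single_exp_phasor(cfg.map_ref_red_tau_ns, freq)
        ref_b = single_exp_phasor(cfg.map_ref_blue_tau_ns, freq)
        rgb = stage("map", lifetime_map, img, ref_r, ref_b, cfg.map_mode)
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        png_path = out_dir / "lifetime_map.png"
        plt.imsave(png_path, rgb)
        outputs["lifetime_map_png"] = str(png_path)

    valid_tau = table.loc[table["valid"], "tau_phase_ns"].dropna()
    summary = {
        "config_hash": chash,
        "seed": cfg.seed,
        "n_valid": int(table["valid"].sum()),
        "mean_tau_phase_ns": float(valid_tau.mean()) if len(valid_tau) else float("nan"),
        "outputs": outputs,
    }
    (out_dir / "provenance.json").write_text(
        json.dumps({"config": cfg.model_dump(), **summary}, indent=2)
    )
    return summary
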