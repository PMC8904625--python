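"""File handling: frame-sequence CSV + JSON sidecar, manifests, run config.

A frame sequence is stored as a plain CSV with columns
``time_s, pupil_mm, blink, z3 … z14`` (OSA-indexed coefficients in µm; blink
rows leave the wavefront columns empty) plus a JSON sidecar carrying
``device_frame_rate`` and ``wavelength``.  Floats are written with full
precision so that write→read round-trips are lossless.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .metrics import METRIC_NAMES, MetricSpec
from .optics import ChromaticModel, PowerVector, ZernikeWavefront
from .psf import SamplingConfig
from .refraction import Frame, FrameSequence
from .synthetic import SyntheticAcquisition

__all__ = [
    "write_sequence_csv",
    "read_sequence_csv",
    "write_manifest",
    "read_manifest",
    "RunConfig",
    "load_config",
]

logger = logging.getLogger(__name__)

_Z_COLS = [f"z{j}" for j in range(3, 15)]
_COLUMNS = ["time_s", "pupil_mm", "blink"] + _Z_COLS


def _sidecar_path(csv_path: Path) -> Path:
    return csv_path.with_suffix(".json")


def write_sequence_csv(seq: FrameSequence, path: str | Path, wavelength: float | None = None) -> Path:
    """Write a frame sequence as CSV + JSON sidecar; returns the CSV path."""
    path = Path(path)
    rows = []
    wl = wavelength
    for f in seq.frames:
        if f.blink:
            rows.append([f.time, np.nan, 1] + [np.nan] * 12)
        else:
            w = f.wavefront
            wl = w.wavelength if wl is None else wl
            rows.append([f.time, w.pupil_diameter, 0] + list(w.coefficients[3:]))
    df = pd.DataFrame(rows, columns=_COLUMNS)
    df.to_csv(path, index=False, float_format="%.17g")
    sidecar = {
        "device_frame_rate": seq.frame_rate,
        "wavelength": wl if wl is not None else 555.0,
        "n_frames": len(seq),
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))
    return path


def read_sequence_csv(path: str | Path) -> FrameSequence:
    """Read a frame sequence written by :func:`write_sequence_csv`.

    Validates the column layout and strictly increasing times.
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    if list(df.columns) != _COLUMNS:
        raise ValueError(
            f"{path}: unexpected columns {list(df.columns)}; expected {_COLUMNS}"
        )
    wavelength = 555.0
    frame_rate = None
    sc = _sidecar_path(path)
    if sc.exists():
        meta = json.loads(sc.read_text())
        wavelength = meta.get("wavelength", wavelength)
        frame_rate = meta.get("device_frame_rate")
    frames = []
    for row in df.itertuples(index=False):
        if int(row.blink):
            frames.append(Frame(time=float(row.time_s), wavefront=None, blink=True))
        else:
            coeffs = np.zeros(15)
            coeffs[3:] = [getattr(row, c) for c in _Z_COLS]
            frames.append(
                Frame(
                    time=float(row.time_s),
                    wavefront=ZernikeWavefront(coeffs, float(row.pupil_mm), wavelength),
                )
            )
    return FrameSequence(frames=tuple(frames), frame_rate=frame_rate)


def write_manifest(
    acquisitions: Sequence[SyntheticAcquisition],
    out_dir: str | Path,
    prefix: str = "eye",
) -> Path:
    """Write a cohort to ``out_dir``: one CSV per eye plus ``manifest.csv``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, acq in enumerate(acquisitions):
        eye_id = f"{prefix}{i:03d}"
        fname = f"{eye_id}.csv"
        write_sequence_csv(acq.sequence, out_dir / fname, wavelength=acq.config.wavelength)
        rows.append(
            {
                "eye_id": eye_id,
                "file": fname,
                "truth_M": acq.truth.M,
                "truth_J0": acq.truth.J0,
                "truth_J45": acq.truth.J45,
                "subjective_M": acq.subjective.M,
                "subjective_J0": acq.subjective.J0,
                "subjective_J45": acq.subjective.J45,
            }
        )
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False, float_format="%.17g")
    return manifest


def read_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"eye_id", "file", "subjective_M", "subjective_J0", "subjective_J45"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest {path} is missing columns: {sorted(missing)}")
    return df


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RunConfig:
    """Validated pipeline configuration (YAML-loadable).

    Defaults follow the published procedure: best 5 % selection for the
    static search, top 20 % for the dynamic approach, 0.25 D / 5°
    prescription steps.
    """

    sampling: SamplingConfig = SamplingConfig()
    metrics: tuple[str, ...] = METRIC_NAMES
    chromatic_mode: str = "identity"           # 'identity' or 'reduced_eye'
    measurement_wavelength: float = 555.0
    reference_wavelength: float = 555.0
    mode: str = "dynamic"                      # 'static' or 'dynamic'
    top_fraction_static: float = 0.05
    top_fraction_dynamic: float = 0.20
    sphere_step: float = 0.25
    cylinder_step: float = 0.25
    axis_step: float = 5.0
    include_sa_correction: bool = False
    n_eyes: int = 10
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        for name in self.metrics:
            if name not in METRIC_NAMES:
                raise ValueError(f"unknown metric {name!r} in config")
        if self.chromatic_mode not in ("identity", "reduced_eye"):
            raise ValueError("chromatic_mode must be 'identity' or 'reduced_eye'")
        if self.mode not in ("static", "dynamic"):
            raise ValueError("mode must be 'static' or 'dynamic'")
        for frac in (self.top_fraction_static, self.top_fraction_dynamic):
            if not (0.0 < frac <= 1.0):
                raise ValueError("top fractions must lie in (0, 1]")
        if self.n_eyes < 1:
            raise ValueError("n_eyes must be ≥ 1")

    @property
    def chromatic(self) -> ChromaticModel:
        if self.chromatic_mode == "identity":
            return ChromaticModel.identity()
        return ChromaticModel.reduced_eye(
            self.measurement_wavelength, self.reference_wavelength
        )

    @property
    def metric_specs(self) -> tuple[MetricSpec, ...]:
        return tuple(MetricSpec(n) for n in self.metrics)

    @property
    def top_fraction(self) -> float:
        return self.top_fraction_static if self.mode == "static" else self.top_fraction_dynamic

    def config_hash(self) -> str:
        payload = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def to_dict(self) -> dict:
        return {
            "sampling": {
                "grid_size": self.sampling.grid_size,
                "pupil_fill_fraction": self.sampling.pupil_fill_fraction,
                "psf_window_arcmin": self.sampling.psf_window_arcmin,
            },
            "metrics": list(self.metrics),
            "chromatic_mode": self.chromatic_mode,
            "measurement_wavelength": self.measurement_wavelength,
            "reference_wavelength": self.reference_wavelength,
            "mode": self.mode,
            "top_fraction_static": self.top_fraction_static,
            "top_fraction_dynamic": self.top_fraction_dynamic,
            "sphere_step": self.sphere_step,
            "cylinder_step": self.cylinder_step,
            "axis_step": self.axis_step,
            "include_sa_correction": self.include_sa_correction,
            "n_eyes": self.n_eyes,
            "seed": self.seed,
            "log_level": self.log_level,
        }


def load_config(path: str | Path | None) -> RunConfig:
    """Load a :class:`RunConfig` from YAML (``None`` → defaults)."""
    if path is None:
        return RunConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config {path} must be a YAML mapping")
    sampling_raw = raw.pop("sampling", {})
    known = set(RunConfig.__dataclass_fields__) - {"sampling"}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "metrics" in raw:
        raw["metrics"] = tuple(raw["metrics"])
    return RunConfig(sampling=SamplingConfig(**sampling_raw), **raw)
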