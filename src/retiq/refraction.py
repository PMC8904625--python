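"""Objective-refraction prediction from wavefront aberrometry.

Two prediction strategies are provided, both scored by retinal image-quality
metrics on the PSF of the *residual* wavefront (eye minus trial correction):

* :class:`StaticRefraction` — brute-force sphero-cylindrical search around a
  base prescription (±1.5 D sphere and ±1 D cylinder in 0.25 D steps, ±20°
  axis in 5° steps, ≤ 1215 candidates).  The predicted refraction for each
  metric is the unweighted mean of the power vectors within the best 5 % of
  candidates.

* :class:`DynamicRefraction` — for a timestamped acquisition (~8 Hz, ~10 s),
  each non-blink frame contributes its own measured refraction, quantized to
  clinical steps, as the candidate correction; frames are ranked by the
  metric of their residual PSF and the prediction is the mean power vector of
  the top 20 % of frames.  This acts as a temporal filter that discards
  accommodation excursions and tear-film-degraded frames.

Both follow the statsmodels idiom: construct the model from data, call
``fit()``, inspect the returned :class:`RefractionResults` (``summary()``,
``refraction(metric)``, per-candidate/per-frame score table).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .metrics import MetricSpec, compute_metrics, default_metrics
from .optics import (
    ChromaticModel,
    PowerVector,
    SpheroCylinder,
    ZernikeWavefront,
    chromatic_correct,
    from_power_vector,
    rescale_pupil,
    sc_to_zernike,
    to_power_vector,
    zernike_to_sc,
)
from .psf import SamplingConfig, compute_psf, diffraction_limited_psf

__all__ = [
    "SearchGrid",
    "Frame",
    "FrameSequence",
    "OptimizationResult",
    "RefractionResults",
    "StaticRefraction",
    "DynamicRefraction",
    "build_search_grid",
    "residual_wavefront",
    "filter_blinks",
    "quantize_prescription",
    "static_optimize",
    "dynamic_optimize",
    "iqm_timeseries",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Search grid
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SearchGrid:
    """Candidate corrections for the static brute-force search."""

    base: SpheroCylinder
    sphere_offsets: tuple[float, ...]
    cylinder_offsets: tuple[float, ...]
    axis_offsets: tuple[float, ...]
    candidates: tuple[SpheroCylinder, ...]
    n_raw: int

    def __len__(self) -> int:
        return len(self.candidates)


def _offsets(extent: float, step: float) -> tuple[float, ...]:
    n = int(round(extent / step))
    return tuple(step * k for k in range(-n, n + 1))


def build_search_grid(
    base: SpheroCylinder,
    sphere_extent: float = 1.5,
    sphere_step: float = 0.25,
    cylinder_extent: float = 1.0,
    cylinder_step: float = 0.25,
    axis_extent: float = 20.0,
    axis_step: float = 5.0,
) -> SearchGrid:
    """Cartesian sphero-cylindrical search grid around ``base``.

    Trial cylinders are clamped to the negative-cylinder domain (≤ 0) and the
    axis is wrapped into [0, 180); duplicates arising from clamping or from a
    zero cylinder (axis-degenerate) are removed, preserving enumeration order
    (sphere, then cylinder, then axis ascending).
    """
    s_off = _offsets(sphere_extent, sphere_step)
    c_off = _offsets(cylinder_extent, cylinder_step)
    a_off = _offsets(axis_extent, axis_step)
    seen: set[tuple[float, float, float]] = set()
    cands: list[SpheroCylinder] = []
    for ds in s_off:
        for dc in c_off:
            for da in a_off:
                cand = SpheroCylinder(
                    base.sphere + ds,
                    min(base.cylinder + dc, 0.0),
                    base.axis + da,
                )
                key = (round(cand.sphere, 6), round(cand.cylinder, 6), round(cand.axis, 6))
                if key not in seen:
                    seen.add(key)
                    cands.append(cand)
    return SearchGrid(
        base=base,
        sphere_offsets=s_off,
        cylinder_offsets=c_off,
        axis_offsets=a_off,
        candidates=tuple(cands),
        n_raw=len(s_off) * len(c_off) * len(a_off),
    )


# ---------------------------------------------------------------------------
# Residual wavefront and frame handling
# ---------------------------------------------------------------------------

def residual_wavefront(
    w: ZernikeWavefront,
    correction: SpheroCylinder | PowerVector,
    chroma: ChromaticModel = ChromaticModel.identity(),
) -> ZernikeWavefront:
    """Wavefront left after applying a trial sphero-cylindrical correction.

    The (chromatically corrected) correction is converted to second-order
    Zernike coefficients on the wavefront's own pupil and subtracted; orders
    3–4 pass through unchanged, so the residual carries the eye's high-order
    aberrations.
    """
    pv = correction if isinstance(correction, PowerVector) else to_power_vector(correction)
    pv = chromatic_correct(pv, chroma)
    low = sc_to_zernike(pv, w.pupil_diameter)
    c = w.coefficients.copy()
    c[3:6] -= low
    return ZernikeWavefront(c, w.pupil_diameter, w.wavelength)


@dataclass(frozen=True, eq=False)
class Frame:
    """One aberrometry frame: acquisition time, wavefront, blink flag."""

    time: float
    wavefront: ZernikeWavefront | None
    blink: bool = False

    def __post_init__(self) -> None:
        if not self.blink and self.wavefront is None:
            raise ValueError("non-blink frames must carry a wavefront")

    @property
    def pupil(self) -> float | None:
        return None if self.wavefront is None else self.wavefront.pupil_diameter


@dataclass(frozen=True, eq=False)
class FrameSequence:
    """A dynamic aberrometry acquisition (ordered, timestamped frames)."""

    frames: tuple[Frame, ...]
    frame_rate: float | None = None

    def __post_init__(self) -> None:
        times = [f.time for f in self.frames]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("frame times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)

    @property
    def duration(self) -> float:
        if not self.frames:
            return 0.0
        return self.frames[-1].time - self.frames[0].time

    @property
    def n_valid(self) -> int:
        return sum(1 for f in self.frames if not f.blink)


def filter_blinks(seq: FrameSequence) -> FrameSequence:
    """Drop blink-flagged frames, preserving order; error if none remain."""
    kept = tuple(f for f in seq.frames if not f.blink)
    if not kept:
        raise ValueError("all frames are blink-flagged; empty acquisition")
    n_dropped = len(seq) - len(kept)
    if n_dropped:
        logger.info("blink filter: dropped %d of %d frames", n_dropped, len(seq))
    return FrameSequence(frames=kept, frame_rate=seq.frame_rate)


def quantize_prescription(
    pv: PowerVector,
    sphere_step: float = 0.25,
    cylinder_step: float = 0.25,
    axis_step: float = 5.0,
) -> SpheroCylinder:
    """Round a refraction to the closest clinically available prescription."""
    sc = from_power_vector(pv)
    sphere = sphere_step * round(sc.sphere / sphere_step)
    cylinder = min(cylinder_step * round(sc.cylinder / cylinder_step), 0.0)
    axis = (axis_step * round(sc.axis / axis_step)) % 180.0
    return SpheroCylinder(sphere, cylinder, axis)


# ---------------------------------------------------------------------------
# Results containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True, eq=False)
class OptimizationResult:
    """Outcome of one optimizer run for a single metric."""

    refraction: PowerVector
    metric_name: str
    n_candidates_evaluated: int
    n_selected: int
    selected_fraction: float
    scores: pd.DataFrame | None = None
    selected_indices: np.ndarray | None = None

    @property
    def prescription(self) -> SpheroCylinder:
        return from_power_vector(self.refraction)


def _select_top(values: np.ndarray, minimize: bool, k: int) -> np.ndarray:
    """Indices of the k best scores; ties broken by enumeration order.

    NaN scores (failed metric evaluations) always rank last.
    """
    vals = np.array(values, dtype=float) if minimize else -np.array(values, dtype=float)
    vals[np.isnan(values)] = np.inf
    order = np.argsort(vals, kind="stable")
    return order[:k]


def _n_selected(top_fraction: float, n: int) -> int:
    if not (0.0 < top_fraction <= 1.0):
        raise ValueError("top_fraction must lie in (0, 1]")
    return max(1, math.ceil(top_fraction * n))


class RefractionResults:
    """Fitted refraction predictions for one eye, one result per metric.

    Attributes
    ----------
    method : 'static' or 'dynamic'
    scores : pandas.DataFrame
        One row per candidate (static) or per frame (dynamic) with the
        candidate power vector and one column per metric.
    """

    def __init__(
        self,
        method: str,
        scores: pd.DataFrame,
        specs: Sequence[MetricSpec],
        top_fraction: float,
    ) -> None:
        self.method = method
        self.scores = scores
        self.specs = tuple(specs)
        self.top_fraction = top_fraction
        self.n_candidates = len(scores)
        self.n_selected = _n_selected(top_fraction, self.n_candidates)
        self._selected: dict[str, np.ndarray] = {}
        self._refractions: dict[str, PowerVector] = {}
        m = scores[["M", "J0", "J45"]].to_numpy()
        for spec in self.specs:
            idx = _select_top(
                scores[spec.name].to_numpy(), spec.minimize, self.n_selected
            )
            sel = m[idx]
            self._selected[spec.name] = idx
            self._refractions[spec.name] = PowerVector(*sel.mean(axis=0))

    @property
    def metric_names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.specs)

    @property
    def refractions(self) -> dict[str, PowerVector]:
        return dict(self._refractions)

    def refraction(self, metric: str) -> PowerVector:
        return self._refractions[metric]

    def prescription(self, metric: str) -> SpheroCylinder:
        return from_power_vector(self._refractions[metric])

    def selected(self, metric: str) -> np.ndarray:
        """Row indices (into ``scores``) of the selected top candidates."""
        return self._selected[metric].copy()

    def result(self, metric: str) -> OptimizationResult:
        return OptimizationResult(
            refraction=self._refractions[metric],
            metric_name=metric,
            n_candidates_evaluated=self.n_candidates,
            n_selected=self.n_selected,
            selected_fraction=self.top_fraction,
            scores=self.scores,
            selected_indices=self.selected(metric),
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, pv in self._refractions.items():
            sc = from_power_vector(pv)
            rows.append(
                {
                    "metric": name,
                    "M": pv.M,
                    "J0": pv.J0,
                    "J45": pv.J45,
                    "sphere": sc.sphere,
                    "cylinder": sc.cylinder,
                    "axis": sc.axis,
                    "n_candidates": self.n_candidates,
                    "n_selected": self.n_selected,
                }
            )
        return pd.DataFrame(rows)

    def timeseries(self, metric: str) -> pd.DataFrame:
        """Per-frame signal (dynamic fits): time, refraction, normalized metric.

        ``metric_norm`` is min-max scaled to [0, 1]; ``selected`` marks the
        top-quantile frames used for the prediction.
        """
        if self.method != "dynamic":
            raise ValueError("timeseries is only defined for dynamic fits")
        df = self.scores[["time", "M", "J0", "J45", metric]].copy()
        df = df.rename(columns={metric: "metric_value"})
        v = df["metric_value"].to_numpy()
        span = v.max() - v.min()
        df["metric_norm"] = (v - v.min()) / span if span > 0 else np.zeros_like(v)
        sel = np.zeros(len(df), dtype=bool)
        sel[self._selected[metric]] = True
        df["selected"] = sel
        return df

    def summary(self) -> str:
        lines = [
            f"Refraction prediction ({self.method} approach)",
            f"  candidates evaluated: {self.n_candidates}"
            f"   selected per metric: {self.n_selected}"
            f" (top {100 * self.top_fraction:g}%)",
            "",
            f"  {'metric':8s} {'M (D)':>8s} {'J0 (D)':>8s} {'J45 (D)':>8s}   prescription",
        ]
        for name, pv in self._refractions.items():
            sc = from_power_vector(pv)
            lines.append(
                f"  {name:8s} {pv.M:8.3f} {pv.J0:8.3f} {pv.J45:8.3f}   {sc}"
            )
        return "\n".join(lines)

    def __repr__(self) -> str:
        return f"<RefractionResults method={self.method} metrics={self.metric_names}>"


# ---------------------------------------------------------------------------
# Models
# ---------------------------------------------------------------------------

class StaticRefraction:
    """Brute-force IQM refraction search on a single static wavefront.

    Parameters
    ----------
    wavefront : ZernikeWavefront
        The measured aberration state of the eye.
    base : SpheroCylinder
        Center of the search grid (typically the instrument's own refraction).
    metrics : iterable of MetricSpec, optional
        Metrics to optimize (default: all eight).
    sampling, chromatic, grid : configuration overrides.
    """

    def __init__(
        self,
        wavefront: ZernikeWavefront,
        base: SpheroCylinder,
        metrics: Iterable[MetricSpec] | None = None,
        sampling: SamplingConfig = SamplingConfig(),
        chromatic: ChromaticModel = ChromaticModel.identity(),
        grid: SearchGrid | None = None,
        analysis_pupil: float | None = None,
    ) -> None:
        if analysis_pupil is not None:
            wavefront = rescale_pupil(wavefront, analysis_pupil)
        self.wavefront = wavefront
        self.base = base
        self.specs = tuple(metrics) if metrics is not None else default_metrics()
        self.sampling = sampling
        self.chromatic = chromatic
        self.grid = grid if grid is not None else build_search_grid(base)

    def score_candidates(self) -> pd.DataFrame:
        """Evaluate every metric for every grid candidate (one PSF each)."""
        w = self.wavefront
        psf_dl = diffraction_limited_psf(w.pupil_diameter, w.wavelength, self.sampling)
        rows = []
        for cand in self.grid.candidates:
            pv = to_power_vector(cand)
            # candidates live in reference-wavelength space; map back to the
            # measurement wavelength of the wavefront before subtracting
            res = residual_wavefront(w, cand, self.chromatic.inverse())
            psf = compute_psf(res, self.sampling)
            vals = compute_metrics(psf, psf_dl, self.specs, on_error="nan")
            rows.append(
                {
                    "sphere": cand.sphere,
                    "cylinder": cand.cylinder,
                    "axis": cand.axis,
                    "M": pv.M,
                    "J0": pv.J0,
                    "J45": pv.J45,
                    **vals,
                }
            )
        return pd.DataFrame(rows)

    def fit(self, top_fraction: float = 0.05) -> RefractionResults:
        """Run the search; the prediction per metric is the mean power vector
        of the best ``top_fraction`` of candidates."""
        scores = self.score_candidates()
        for spec in self.specs:
            if np.isnan(scores[spec.name].to_numpy()).all():
                raise ValueError(f"metric {spec.name!r} failed on every candidate")
        return RefractionResults("static", scores, self.specs, top_fraction)


class DynamicRefraction:
    """Top-quantile IQM selection over a dynamic aberrometry sequence.

    Each non-blink frame's own measured refraction, rounded to clinical steps
    (``sphere_step``/``cylinder_step`` D, ``axis_step``°), is the candidate
    correction for that frame; frames are ranked by the image quality of
    their residual PSF.

    Parameters
    ----------
    sequence : FrameSequence
    metrics : iterable of MetricSpec, optional (default: all eight)
    include_sa_correction : bool
        Add the paraxial spherical-aberration term when reading each frame's
        refraction (off by default).
    pupil_bounds : (low, high) mm
        Frames with pupils outside this range are rejected as artifacts.
    analysis_pupil : float, mm, optional
        Fixed analysis diameter: each frame's wavefront is rescaled to this
        pupil (standard Zernike subaperture refit); frames whose measured
        pupil is smaller are rejected.  Default: use each frame's own pupil.
    """

    MIN_FRAMES = 5

    def __init__(
        self,
        sequence: FrameSequence,
        metrics: Iterable[MetricSpec] | None = None,
        sampling: SamplingConfig = SamplingConfig(),
        chromatic: ChromaticModel = ChromaticModel.identity(),
        sphere_step: float = 0.25,
        cylinder_step: float = 0.25,
        axis_step: float = 5.0,
        include_sa_correction: bool = False,
        pupil_bounds: tuple[float, float] = (1.5, 9.0),
        analysis_pupil: float | None = None,
    ) -> None:
        self.sequence = sequence
        self.specs = tuple(metrics) if metrics is not None else default_metrics()
        self.sampling = sampling
        self.chromatic = chromatic
        self.sphere_step = sphere_step
        self.cylinder_step = cylinder_step
        self.axis_step = axis_step
        self.include_sa_correction = include_sa_correction
        self.pupil_bounds = pupil_bounds
        self.analysis_pupil = analysis_pupil

    def _usable_frames(self) -> list[Frame]:
        seq = filter_blinks(self.sequence)
        lo, hi = self.pupil_bounds
        if self.analysis_pupil is not None:
            lo = max(lo, self.analysis_pupil)
        kept = [f for f in seq if lo <= f.wavefront.pupil_diameter < hi]
        n_rej = len(seq.frames) - len(kept)
        if n_rej:
            logger.warning("pupil guard: rejected %d frames outside (%g, %g) mm", n_rej, lo, hi)
        if len(kept) < self.MIN_FRAMES:
            raise ValueError(
                f"need at least {self.MIN_FRAMES} usable frames, got {len(kept)}"
            )
        return kept

    def score_frames(self) -> pd.DataFrame:
        """Per-frame candidate refraction and metric values."""
        rows = []
        for f in self._usable_frames():
            w = f.wavefront
            if self.analysis_pupil is not None:
                w = rescale_pupil(w, self.analysis_pupil)
            pv_frame = zernike_to_sc(w, self.include_sa_correction)
            pv_frame = chromatic_correct(pv_frame, self.chromatic)
            cand = quantize_prescription(
                pv_frame, self.sphere_step, self.cylinder_step, self.axis_step
            )
            pv_cand = to_power_vector(cand)
            res = residual_wavefront(w, cand, self.chromatic.inverse())
            psf = compute_psf(res, self.sampling)
            psf_dl = diffraction_limited_psf(w.pupil_diameter, w.wavelength, self.sampling)
            vals = compute_metrics(psf, psf_dl, self.specs, on_error="nan")
            rows.append(
                {
                    "time": f.time,
                    "pupil": w.pupil_diameter,
                    "sphere": cand.sphere,
                    "cylinder": cand.cylinder,
                    "axis": cand.axis,
                    "M": pv_cand.M,
                    "J0": pv_cand.J0,
                    "J45": pv_cand.J45,
                    **vals,
                }
            )
        return pd.DataFrame(rows)

    def fit(self, top_fraction: float = 0.20) -> RefractionResults:
        """Rank frames per metric and average the top-quantile refractions."""
        scores = self.score_frames()
        if _n_selected(top_fraction, len(scores)) > len(scores):
            raise ValueError("fewer frames than needed for one selected frame")
        for spec in self.specs:
            if np.isnan(scores[spec.name].to_numpy()).all():
                raise ValueError(f"metric {spec.name!r} failed on every frame")
        return RefractionResults("dynamic", scores, self.specs, top_fraction)


# ---------------------------------------------------------------------------
# Functional wrappers (single-metric convenience API)
# ---------------------------------------------------------------------------

def static_optimize(
    w: ZernikeWavefront,
    base: SpheroCylinder,
    spec: MetricSpec,
    top_fraction: float = 0.05,
    **kwargs,
) -> OptimizationResult:
    """Single-metric static brute-force search (see :class:`StaticRefraction`)."""
    model = StaticRefraction(w, base, metrics=[spec], **kwargs)
    return model.fit(top_fraction=top_fraction).result(spec.name)


def dynamic_optimize(
    seq: FrameSequence,
    spec: MetricSpec,
    top_fraction: float = 0.20,
    **kwargs,
) -> OptimizationResult:
    """Single-metric dynamic top-quantile selection (see :class:`DynamicRefraction`)."""
    model = DynamicRefraction(seq, metrics=[spec], **kwargs)
    return model.fit(top_fraction=top_fraction).result(spec.name)


def iqm_timeseries(
    seq: FrameSequence,
    spec: MetricSpec,
    top_fraction: float = 0.20,
    **kwargs,
) -> pd.DataFrame:
    """Per-frame dynamic signal: time, M/J0/J45, normalized metric, selection mask."""
    model = DynamicRefraction(seq, metrics=[spec], **kwargs)
    return model.fit(top_fraction=top_fraction).timeseries(spec.name)
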