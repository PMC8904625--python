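"""Seedable simulator of dynamic ocular wavefront acquisitions.

Real patient aberrometry videos are not publicly available, so this module
generates physiologically styled stand-ins for end-to-end testing: each eye
has a stable "true" refraction plateau perturbed by

* accommodation **microfluctuations** — a low-frequency (< 0.6 Hz) and a
  high-frequency (1–2.3 Hz) sinusoidal defocus component with random phase,
* transient **myopic accommodation excursions** (instrument myopia): raised-
  cosine episodes of extra negative defocus accompanied by increased coma and
  spherical aberration, so that image quality objectively degrades during an
  excursion,
* **tear-film drift** — high-order aberrations growing linearly between
  blinks and resetting at each blink,
* blink gaps (flagged frames with no wavefront) and per-coefficient Gaussian
  measurement noise.

A paired "subjective" refraction is drawn as truth plus perceptual noise.
Everything is reproducible from ``(config, seed)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .optics import PowerVector, SpheroCylinder, ZernikeWavefront, sc_to_zernike, to_power_vector
from .refraction import Frame, FrameSequence

__all__ = ["EyeModelConfig", "SyntheticAcquisition", "simulate_sequence", "simulate_cohort"]


def _default_hoa() -> dict[int, float]:
    # µm on a ~4 mm pupil: trefoil, vertical/horizontal coma, spherical aberration
    return {6: 0.02, 7: 0.03, 8: 0.05, 12: 0.04}


@dataclass(frozen=True)
class EyeModelConfig:
    """Study conditions for one simulated eye.

    Amplitudes are diopters (defocus terms) or µm (Zernike coefficients);
    rates are per second.  Defaults emulate an adult eye observed by an 8 Hz
    open-view aberrometer for 10 s, with excursion parameters sized so that
    the unfiltered frame mean carries an instrument-myopia bias of roughly
    −0.15 D.
    """

    true_refraction: PowerVector = PowerVector(-1.0, 0.0, 0.0)
    pupil_mm: float = 4.0
    baseline_hoa: Mapping[int, float] = field(default_factory=_default_hoa)
    # microfluctuations (two-band structure of accommodation fluctuation)
    lf_amplitude: float = 0.10      # D, < 0.6 Hz drift band
    lf_band: tuple[float, float] = (0.1, 0.6)
    hf_amplitude: float = 0.05      # D, 1-2.3 Hz band
    hf_band: tuple[float, float] = (1.0, 2.3)
    # myopic accommodation excursions
    excursion_rate: float = 0.25    # episodes per second (Poisson)
    excursion_magnitude: float = 0.75  # D, applied as negative (myopic) defocus
    excursion_duration: float = 1.5    # s
    excursion_hoa: float = 0.15        # µm extra coma+SA at episode peak
    # tear film
    tearfilm_drift: float = 0.01    # µm/s HOA growth between blinks
    # blinks
    blink_interval: float = 4.0     # s
    blink_duration: float = 0.25    # s
    # measurement noise
    noise_sd: float = 0.01          # µm per coefficient
    # perceptual (subjective-refraction) noise
    subjective_noise_m: float = 0.25   # D
    subjective_noise_j: float = 0.10   # D
    # acquisition geometry
    frame_rate: float = 8.0         # Hz
    duration: float = 10.0          # s
    wavelength: float = 555.0       # nm (coefficients already chromatically referred)

    def __post_init__(self) -> None:
        for name in (
            "lf_amplitude", "hf_amplitude", "excursion_rate", "excursion_magnitude",
            "excursion_duration", "excursion_hoa", "tearfilm_drift", "blink_duration",
            "noise_sd", "subjective_noise_m", "subjective_noise_j",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.frame_rate * self.duration < 10:
            raise ValueError("frame_rate × duration must be at least 10 frames")
        if self.blink_interval < 0:
            raise ValueError("blink_interval must be non-negative (0 disables blinks)")

    def quiet(self) -> "EyeModelConfig":
        """Copy with all dynamics, blinks and noise switched off."""
        return replace(
            self,
            lf_amplitude=0.0, hf_amplitude=0.0,
            excursion_rate=0.0, excursion_hoa=0.0,
            tearfilm_drift=0.0, blink_interval=0.0,
            noise_sd=0.0, subjective_noise_m=0.0, subjective_noise_j=0.0,
        )


@dataclass(frozen=True, eq=False)
class SyntheticAcquisition:
    """A simulated acquisition with its generating truth and provenance."""

    sequence: FrameSequence
    truth: PowerVector
    subjective: PowerVector
    config: EyeModelConfig
    seed: int | None = None


def simulate_sequence(
    cfg: EyeModelConfig, seed: int | np.random.Generator | None = None
) -> SyntheticAcquisition:
    """Simulate one dynamic acquisition under the conditions in ``cfg``."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    seed_val = seed if isinstance(seed, (int, np.integer)) else None

    n = int(round(cfg.frame_rate * cfg.duration))
    t = np.arange(n) / cfg.frame_rate
    truth = cfg.true_refraction

    # defocus fluctuation: two sinusoidal bands with random frequency/phase
    dm = np.zeros(n)
    for amp, band in ((cfg.lf_amplitude, cfg.lf_band), (cfg.hf_amplitude, cfg.hf_band)):
        if amp > 0:
            f = rng.uniform(*band)
            phi = rng.uniform(0, 2 * np.pi)
            dm += amp * np.sin(2 * np.pi * f * t + phi)

    # myopic accommodation excursions with raised-cosine envelopes
    env = np.zeros(n)
    if cfg.excursion_rate > 0 and cfg.excursion_magnitude >= 0:
        n_exc = rng.poisson(cfg.excursion_rate * cfg.duration)
        starts = np.sort(rng.uniform(0.0, cfg.duration, size=n_exc))
        for s in starts:
            inside = (t >= s) & (t < s + cfg.excursion_duration)
            env[inside] += np.sin(np.pi * (t[inside] - s) / cfg.excursion_duration) ** 2
        env = np.clip(env, 0.0, 1.0)
    dm -= cfg.excursion_magnitude * env

    # blink schedule
    blink = np.zeros(n, dtype=bool)
    blink_starts: list[float] = []
    if cfg.blink_interval > 0:
        s = cfg.blink_interval
        while s < cfg.duration:
            start = s + rng.uniform(-0.2, 0.2)
            blink_starts.append(start)
            blink |= (t >= start) & (t < start + cfg.blink_duration)
            s += cfg.blink_interval

    # tear-film sawtooth: time since last blink end
    since_blink = t - 0.0
    for start in blink_starts:
        end = start + cfg.blink_duration
        after = t >= end
        since_blink[after] = t[after] - end

    frames = []
    hoa_j = np.array(sorted(cfg.baseline_hoa))
    hoa_base = np.array([cfg.baseline_hoa[j] for j in hoa_j])
    for i in range(n):
        if blink[i]:
            frames.append(Frame(time=float(t[i]), wavefront=None, blink=True))
            continue
        pv = PowerVector(truth.M + dm[i], truth.J0, truth.J45)
        coeffs = np.zeros(15)
        coeffs[3:6] = sc_to_zernike(pv, cfg.pupil_mm)
        coeffs[hoa_j] += hoa_base
        # excursion-linked HOA rise: split between horizontal coma and SA
        coeffs[8] += 0.6 * cfg.excursion_hoa * env[i]
        coeffs[12] += 0.4 * cfg.excursion_hoa * env[i]
        # inter-blink tear-film drift on trefoil and SA
        drift = cfg.tearfilm_drift * since_blink[i]
        coeffs[6] += 0.5 * drift
        coeffs[12] += 0.5 * drift
        if cfg.noise_sd > 0:
            coeffs[3:] += rng.normal(0.0, cfg.noise_sd, size=12)
        frames.append(
            Frame(
                time=float(t[i]),
                wavefront=ZernikeWavefront(coeffs, cfg.pupil_mm, cfg.wavelength),
            )
        )

    subjective = PowerVector(
        truth.M + (rng.normal(0.0, cfg.subjective_noise_m) if cfg.subjective_noise_m > 0 else 0.0),
        truth.J0 + (rng.normal(0.0, cfg.subjective_noise_j) if cfg.subjective_noise_j > 0 else 0.0),
        truth.J45 + (rng.normal(0.0, cfg.subjective_noise_j) if cfg.subjective_noise_j > 0 else 0.0),
    )
    return SyntheticAcquisition(
        sequence=FrameSequence(frames=tuple(frames), frame_rate=cfg.frame_rate),
        truth=truth,
        subjective=subjective,
        config=cfg,
        seed=seed_val,
    )


def simulate_cohort(
    n_eyes: int,
    seed: int | None = None,
    base_config: EyeModelConfig | None = None,
    sphere_range: tuple[float, float] = (-6.25, 3.0),
    cylinder_range: tuple[float, float] = (-3.0, 0.0),
    pupil_range: tuple[float, float] = (3.5, 5.0),
) -> list[SyntheticAcquisition]:
    """Simulate a cohort of eyes with a clinically styled refraction spread.

    Spheres are drawn from a mildly myopic-centered normal distribution and
    clipped into ``sphere_range``; cylinders are half-normal (always ≤ 0)
    clipped into ``cylinder_range``; axes are uniform.  Each eye gets an
    independent child seed, so any single eye can be re-simulated alone.
    """
    if n_eyes < 1:
        raise ValueError("n_eyes must be ≥ 1")
    base = base_config if base_config is not None else EyeModelConfig()
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_eyes + 1)
    rng = np.random.default_rng(children[0])
    out = []
    for i in range(n_eyes):
        sphere = float(np.clip(rng.normal(-0.5, 2.0), *sphere_range))
        cylinder = float(np.clip(-abs(rng.normal(0.0, 0.75)), *cylinder_range))
        axis = float(rng.uniform(0.0, 180.0))
        pupil = float(np.round(rng.uniform(*pupil_range), 1))
        hoa_scale = float(rng.uniform(0.5, 1.5))
        cfg = replace(
            base,
            true_refraction=to_power_vector(SpheroCylinder(sphere, cylinder, axis)),
            pupil_mm=pupil,
            baseline_hoa={j: v * hoa_scale for j, v in base.baseline_hoa.items()},
        )
        out.append(simulate_sequence(cfg, seed=np.random.default_rng(children[i + 1])))
    return out
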