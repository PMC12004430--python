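"""Synthetic data generators for the engineered-ventricle pipeline.

Every downstream stage (beat analytics, displacement reconstruction, drug
response, ΔΔCt) is validated against traces from this module, whose ground
truth is known by construction:

* pulsatile flow traces built from a half-sine ejection lobe whose analytic
  integral equals the prescribed stroke volume, followed by a slower
  half-sine refill lobe of equal and opposite volume, so every beat conserves
  volume exactly;
* rectified motion-magnitude traces whose per-beat sum equals twice the
  displacement amplitude (a return-to-origin path of amplitude A has
  rectified path length 2A);
* speckle-textured beating videos (radial pulsation or rigid translation)
  for exercising dense optical-flow estimation;
* two-group qPCR Ct tables whose mean ΔΔCt encodes a prescribed fold change.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import ParameterError
from .traces import FlowTrace, MotionTrace

__all__ = [
    "VentricleSimParams",
    "ejection_peak_flow",
    "generate_flow_trace",
    "generate_drug_pair",
    "generate_motion_trace",
    "generate_beating_video",
    "generate_ct_table",
]


@dataclass(frozen=True)
class VentricleSimParams:
    """Parameters of the pulsatile-flow simulator.

    The waveform per beat is a positive half-sine ejection lobe occupying
    ``systole_fraction`` of the beat period, a negative half-sine refill lobe
    occupying ``refill_fraction``, and quiescence for the remainder. Ejection
    and refill volumes are equal (``stroke_volume``), so net displaced volume
    per beat is zero, matching a closed medium-filled chamber.

    Units: beat_rate bpm, stroke_volume nL, noise_sd µL/min (additive white
    Gaussian), drift_rate µL/min per minute (linear sensor drift),
    sample_rate Hz, duration s. ``rate_jitter_cv`` is the coefficient of
    variation of lognormally distributed beat periods.
    """

    beat_rate: float = 60.0
    stroke_volume: float = 10.0
    systole_fraction: float = 0.3
    refill_fraction: float = 0.5
    noise_sd: float = 0.0
    drift_rate: float = 0.0
    rate_jitter_cv: float = 0.0
    sample_rate: float = 50.0
    duration: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.beat_rate <= 0:
            raise ParameterError("beat_rate must be > 0 bpm")
        if self.stroke_volume < 0:
            raise ParameterError("stroke_volume must be >= 0 nL")
        if not 0 < self.systole_fraction < 1:
            raise ParameterError("systole_fraction must lie in (0, 1)")
        if self.refill_fraction <= 0:
            raise ParameterError("refill_fraction must be > 0")
        if self.systole_fraction + self.refill_fraction > 1:
            raise ParameterError(
                "systole_fraction + refill_fraction must be <= 1"
            )
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")
        if self.rate_jitter_cv < 0:
            raise ParameterError("rate_jitter_cv must be >= 0")
        if self.sample_rate < 20.0 * self.beat_rate / 60.0:
            raise ParameterError(
                "sample_rate must be >= 20 x (beat_rate/60) Hz so each "
                "ejection lobe holds enough samples"
            )
        if self.duration < 3.0 * 60.0 / self.beat_rate:
            raise ParameterError("duration must cover at least 3 beat periods")

    @property
    def period(self) -> float:
        """Nominal beat period in seconds."""
        return 60.0 / self.beat_rate


def ejection_peak_flow(params: VentricleSimParams) -> float:
    """Peak of the noise-free ejection lobe in µL/min.

    A half-sine of duration d_e [s] and peak Q integrates to Q·2·d_e/π
    µL·s/min = Q·2·d_e/π·(1000/60) nL; solving for the prescribed stroke
    volume SV [nL] gives Q = SV·π·60 / (2·d_e·1000).
    """
    d_e = params.systole_fraction * params.period
    return params.stroke_volume * math.pi * 60.0 / (2.0 * d_e * 1000.0)


def _beat_onsets_and_periods(
    params: VentricleSimParams, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Beat onset times and periods covering the full duration."""
    mean_t = params.period
    n_max = int(math.ceil(params.duration / mean_t)) + 8
    if params.rate_jitter_cv > 0:
        sigma2 = math.log1p(params.rate_jitter_cv**2)
        mu = math.log(mean_t) - sigma2 / 2.0  # lognormal with exact mean T
        periods = rng.lognormal(mean=mu, sigma=math.sqrt(sigma2), size=n_max)
    else:
        periods = np.full(n_max, mean_t)
    onsets = np.concatenate(([0.0], np.cumsum(periods)[:-1]))
    keep = onsets < params.duration
    return onsets[keep], periods[keep]


def generate_flow_trace(params: VentricleSimParams) -> FlowTrace:
    """Simulate a flow-sensor recording of a beating engineered ventricle.

    Each beat contributes a positive half-sine ejection lobe with analytic
    integral ``stroke_volume`` and a negative half-sine refill lobe with
    integral ``-stroke_volume``; Gaussian noise and linear drift are added
    afterwards. Ground-truth beat onsets are stored in ``metadata``.
    """
    rng = np.random.default_rng(params.seed)
    n = int(round(params.duration * params.sample_rate))
    t = np.arange(n) / params.sample_rate
    q = np.zeros(n)

    onsets, periods = _beat_onsets_and_periods(params, rng)
    if params.stroke_volume > 0:
        # discrete trapezoid integral target per lobe, in µL·s/min
        target = params.stroke_volume * 60.0 / 1000.0
        h = 1.0 / params.sample_rate
        for onset, period in zip(onsets, periods):
            d_e = params.systole_fraction * period
            d_r = params.refill_fraction * period
            q_e = params.stroke_volume * math.pi * 60.0 / (2.0 * d_e * 1000.0)
            q_r = params.stroke_volume * math.pi * 60.0 / (2.0 * d_r * 1000.0)
            i0 = np.searchsorted(t, onset, side="left")
            i1 = np.searchsorted(t, onset + d_e, side="left")
            i2 = np.searchsorted(t, onset + d_e + d_r, side="left")
            lobe_e = q_e * np.sin(np.pi * (t[i0:i1] - onset) / d_e)
            lobe_r = -q_r * np.sin(np.pi * (t[i1:i2] - onset - d_e) / d_r)
            # Calibrate fully sampled lobes so the sampled trace's trapezoid
            # integral per lobe is exactly ±stroke_volume: every interior
            # sample carries weight h in the composite trapezoid rule, so
            # scaling by target/(h·Σ) makes beats conserve volume to float
            # round-off at any sample rate. Truncated trailing lobes are
            # left at the analytic amplitude.
            if i2 < n:
                se, sr = lobe_e.sum() * h, lobe_r.sum() * h
                if se > 0:
                    lobe_e *= target / se
                if sr < 0:
                    lobe_r *= -target / sr
            q[i0:i1] += lobe_e
            q[i1:i2] += lobe_r

    if params.noise_sd > 0:
        q = q + params.noise_sd * rng.standard_normal(n)
    if params.drift_rate != 0.0:
        q = q + params.drift_rate * t / 60.0

    return FlowTrace(
        t=t,
        q=q,
        sample_rate=params.sample_rate,
        metadata={
            "generator": "generate_flow_trace",
            "params": asdict(params),
            "true_onsets": onsets,
            "true_periods": periods,
        },
    )


def generate_drug_pair(
    params: VentricleSimParams, rate_effect: float, sv_effect: float
) -> tuple[FlowTrace, FlowTrace]:
    """Paired pre/post-drug recordings differing only in the injected effects.

    The post-incubation trace is generated with ``beat_rate * rate_effect``
    and ``stroke_volume * sv_effect`` under the same seed, mirroring the
    paired control-then-treatment flow-measurement protocol.
    """
    if rate_effect <= 0:
        raise ParameterError("rate_effect must be > 0")
    if sv_effect <= 0:
        raise ParameterError("sv_effect must be > 0")
    post_params = replace(
        params,
        beat_rate=params.beat_rate * rate_effect,
        stroke_volume=params.stroke_volume * sv_effect,
    )
    return generate_flow_trace(params), generate_flow_trace(post_params)


def generate_motion_trace(
    beat_rate: float,
    amplitude: float,
    fps: float,
    duration: float,
    noise_sd: float = 0.0,
    seed: int = 0,
    active_fraction: float = 0.5,
) -> MotionTrace:
    """Rectified motion-magnitude trace of a contracting tissue.

    The underlying displacement rises smoothly 0 → amplitude → 0 within each
    beat (a sin² pulse occupying ``active_fraction`` of the period, then
    quiescence); the emitted magnitude is |Δdisplacement| per frame plus
    truncated-at-zero Gaussian noise. Noise-free, the per-beat sum of
    magnitudes equals 2·amplitude (the rectified path length of a
    return-to-origin excursion).
    """
    if beat_rate <= 0:
        raise ParameterError("beat_rate must be > 0 bpm")
    if amplitude < 0:
        raise ParameterError("amplitude must be >= 0 px")
    if fps < 20.0 * beat_rate / 60.0:
        raise ParameterError("fps must be >= 20 x (beat_rate/60)")
    if not 0 < active_fraction <= 1:
        raise ParameterError("active_fraction must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    n = int(round(duration * fps))
    t = np.arange(n) / fps
    period = 60.0 / beat_rate
    phase = np.mod(t, period) / (active_fraction * period)
    disp = np.where(phase < 1.0, amplitude * np.sin(np.pi * phase) ** 2, 0.0)
    mag = np.zeros(n)
    mag[:-1] = np.abs(np.diff(disp))
    if noise_sd > 0:
        mag = np.maximum(0.0, mag + noise_sd * rng.standard_normal(n))
    return MotionTrace(
        frame_index=np.arange(n),
        magnitude=mag,
        fps=fps,
        frame_offset=1,
        metadata={
            "generator": "generate_motion_trace",
            "beat_rate": beat_rate,
            "amplitude": amplitude,
            "active_fraction": active_fraction,
            "true_displacement": disp,
        },
    )


def _speckle_texture(shape: tuple[int, int], rng: np.random.Generator) -> np.ndarray:
    """Smooth periodic speckle in [0, 1] with dense gradients everywhere."""
    tex = rng.random(shape)
    tex = ndimage.gaussian_filter(tex, sigma=2.0, mode="wrap")
    tex -= tex.min()
    tex /= tex.max()
    return tex


def generate_beating_video(
    mode: str,
    n_frames: int,
    frame_size: int,
    motion_amplitude: float,
    beat_rate: float = 60.0,
    fps: float = 30.0,
    seed: int = 0,
) -> np.ndarray:
    """Render an 8-bit grayscale frame stack with known motion.

    ``pulsate`` draws a speckle-textured disk whose radius oscillates by
    ``motion_amplitude`` px with a sin² waveform at ``beat_rate``; ``translate``
    shifts a periodic speckle texture by ``motion_amplitude`` px per frame
    (sub-pixel shifts via Fourier interpolation), giving an exact ground-truth
    displacement for optical-flow validation.
    """
    if mode not in ("pulsate", "translate"):
        raise ParameterError(f"unknown video mode: {mode!r}")
    if frame_size < 32:
        raise ParameterError("frame_size must be >= 32 px")
    if motion_amplitude < 0:
        raise ParameterError("motion_amplitude must be >= 0 px")
    if motion_amplitude > frame_size / 8:
        raise ParameterError("motion_amplitude must be <= frame_size/8")
    rng = np.random.default_rng(seed)
    tex = _speckle_texture((frame_size, frame_size), rng)
    frames = np.empty((n_frames, frame_size, frame_size), dtype=np.uint8)

    if mode == "translate":
        f_tex = np.fft.fft2(tex)
        for k in range(n_frames):
            shifted = np.fft.ifft2(
                ndimage.fourier_shift(f_tex, (0.0, k * motion_amplitude))
            ).real
            frames[k] = np.clip(shifted * 255.0, 0, 255).astype(np.uint8)
        return frames

    yy, xx = np.mgrid[0:frame_size, 0:frame_size]
    center = (frame_size - 1) / 2.0
    dist = np.hypot(yy - center, xx - center)
    r0 = 0.30 * frame_size
    period = 60.0 / beat_rate
    for k in range(n_frames):
        phase = math.fmod(k / fps, period) / period
        radius = r0 + motion_amplitude * math.sin(math.pi * phase) ** 2
        mask = np.clip(radius - dist, 0.0, 1.0)  # 1-px soft edge
        frames[k] = np.clip(tex * mask * 255.0, 0, 255).astype(np.uint8)
    return frames


def generate_ct_table(
    fold_spec: Mapping[str, float],
    reference_ct: float | Mapping[str, float] = 30.0,
    replicate_sd: float = 0.0,
    n_replicates: int = 3,
    seed: int = 0,
    reference_group: str = "day0",
    test_group: str = "ventricle",
    housekeeping_gene: str = "GAPDH",
    housekeeping_ct: float = 18.0,
) -> pd.DataFrame:
    """Two-group qPCR Ct table encoding prescribed fold changes.

    The housekeeping gene has the same mean Ct in both groups; each target
    gene's test-group Ct is offset by −log2(fold) from its reference-group
    Ct, so the mean ΔΔCt equals −log2(fold) and the ΔΔCt method recovers the
    prescribed fold exactly when ``replicate_sd`` is zero. Replicate noise is
    N(0, replicate_sd²) cycles. Returns a tidy DataFrame with columns
    ``group, gene, replicate, ct``; the housekeeping gene label is stored in
    ``df.attrs['housekeeping_gene']``.
    """
    if n_replicates < 1:
        raise ParameterError("n_replicates must be >= 1")
    if replicate_sd < 0:
        raise ParameterError("replicate_sd must be >= 0")
    for gene, fold in fold_spec.items():
        if fold <= 0:
            raise ParameterError(f"fold change for {gene} must be > 0")
    rng = np.random.default_rng(seed)

    def base_ct(gene: str) -> float:
        if isinstance(reference_ct, Mapping):
            return float(reference_ct[gene])
        return float(reference_ct)

    rows = []
    for group in (reference_group, test_group):
        for rep in range(1, n_replicates + 1):
            rows.append(
                (group, housekeeping_gene, rep,
                 housekeeping_ct + replicate_sd * rng.standard_normal())
            )
        for gene, fold in fold_spec.items():
            mean_ct = base_ct(gene)
            if group == test_group:
                mean_ct -= math.log2(fold)
            for rep in range(1, n_replicates + 1):
                rows.append(
                    (group, gene, rep,
                     mean_ct + replicate_sd * rng.standard_normal())
                )
    df = pd.DataFrame(rows, columns=["group", "gene", "replicate", "ct"])
    df.attrs["housekeeping_gene"] = housekeeping_gene
    return df
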