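"""Synthetic EEG-fMRI sessions with exact ground truth.

Generates multichannel sessions that combine task-locked neural activity
with the three MR artifact families seen in simultaneous EEG-fMRI:

* **imaging (gradient) artifact** -- a deterministic, TR-periodic comb of
  cosines at ``k*f_slice +/- m*f_volume``, i.e. harmonics of the slice
  repetition frequency convolved with harmonics of the volume repetition
  frequency, with amplitudes far above the physiology (default 20 mV);
* **ballistocardiogram (BCG) artifact** -- a smooth heartbeat-locked
  template (>50 uV, spectral mass below 25 Hz) placed at each R-peak with
  per-beat amplitude and latency jitter;
* **helium-pump vibration artifact** -- stationary harmonics of the pump
  fundamental (>= 30 Hz) with slow amplitude modulation;
* **motion bursts** -- band-limited (1-25 Hz) transients coupled into scalp
  and loop channels during finger-tapping blocks only.

Six carbon-wire-loop (CWL) reference channels carry lag-shifted mixtures of
the artifact *sources* plus sensor noise and no neural signal, and an ECG
channel carries an R-wave train.  The assembled recording decomposes
*exactly* into ``neural + imaging + bcg + pump + motion + noise`` -- the
:class:`GroundTruth` container keeps every term so correction error can be
measured against the clean signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.stats import truncnorm

from .core_io import CWL, ECG, SCALP, Marker, MarkerList, Recording, SessionConfig, log

MIN_RR_S = 0.3  # physiological floor on the inter-beat interval


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------

@dataclass
class ArtifactParams:
    """Amplitudes and spectral structure of the simulated MR artifacts.

    All amplitudes in microvolts.  Defaults reflect a 3 T acquisition with
    TR = 1.1 s and effective slice frequency ``n_slices_per_tr / tr_s``:
    imaging artifact in the tens-of-millivolt range, BCG well above 50 uV
    with power below 25 Hz, pump harmonics at or above 30 Hz.
    """

    slice_freq_hz: float = 16 / 1.1
    volume_freq_hz: float = 1 / 1.1
    n_slice_harmonics: int = 8
    n_volume_harmonics: int = 8
    imaging_amp_uv: float = 20000.0

    bcg_amp_uv: float = 250.0
    bcg_lowpass_hz: float = 25.0
    bcg_amp_cv: float = 0.05  # per-beat amplitude coefficient of variation
    bcg_latency_sd_ms: float = 2.0  # per-beat latency jitter
    bcg_delay_s: float = 0.21  # pulse-arrival delay from R-peak to artifact onset

    pump_freq_hz: float = 42.0
    pump_harmonics: int = 2
    pump_amp_uv: float = 30.0

    motion_rate_hz: float = 1.0  # burst rate during tapping blocks
    motion_amp_uv: float = 40.0

    cwl_noise_uv: float = 1.0
    cwl_max_lag_ms: float = 10.0  # spread of loop lags relative to scalp sources

    def __post_init__(self) -> None:
        if self.pump_freq_hz < 30.0:
            raise ValueError("pump fundamental must be >= 30 Hz")
        if self.bcg_amp_uv < 0 or self.imaging_amp_uv < 0:
            raise ValueError("artifact amplitudes must be non-negative")


@dataclass
class NeuralParams:
    """Amplitudes (uV RMS) and timing of the simulated neural components."""

    alpha_eo_uv: float = 1.0
    alpha_ec_uv: float = 3.0
    block_s: float = 40.0
    n_blocks: int = 22  # alternating EO/EC

    mu_alpha_uv: float = 2.0  # central alpha during rest (tapping task)
    mu_beta_uv: float = 1.5
    gamma_uv: float = 0.3
    erd_alpha_depth: float = 0.7  # fractional *amplitude* reduction during tapping
    erd_beta_depth: float = 0.5
    gamma_ers_gain: float = 2.0  # amplitude gain of the 0-1 s gamma burst
    tap_block_s: float = 3.0
    rest_choices_s: tuple = (3.0, 5.0, 7.0)
    n_taps: int = 60

    vep_p1_uv: float = 5.0
    vep_p1_ms: float = 120.0
    vep_n1_uv: float = -6.0
    vep_n1_ms: float = 175.0
    stim_duration_s: float = 0.7
    iti_choices_s: tuple = (1.7, 3.7, 5.7)
    n_trials_per_condition: int = 42

    pink_uv: float = 3.0  # 1/f background, per channel
    ipsi_fraction: float = 0.0  # VEP gain on the ipsilateral hemisphere

    def __post_init__(self) -> None:
        if not (self.alpha_ec_uv > self.alpha_eo_uv >= 0):
            raise ValueError("EC alpha power must exceed EO alpha power")
        for d in (self.erd_alpha_depth, self.erd_beta_depth):
            if not (0 < d <= 1):
                raise ValueError("ERD depths must lie in (0, 1]")


# ---------------------------------------------------------------------------
# Scalp layout
# ---------------------------------------------------------------------------

@dataclass
class ScalpLayout:
    """Parametric 2-D scalp grid: x in [-1, 1] left->right, y in [-1, 1]
    occipital->frontal.  Topographies are Gaussian blobs over this layout.
    """

    n_channels: int = 32
    labels: list[str] = field(default_factory=list)
    xy: np.ndarray = field(default_factory=lambda: np.zeros((0, 2)))

    def __post_init__(self) -> None:
        if not self.labels:
            n_rows = max(2, int(round(np.sqrt(self.n_channels / 2))))
            n_cols = int(np.ceil(self.n_channels / n_rows))
            xs = np.linspace(-1, 1, n_cols)
            ys = np.linspace(1, -1, n_rows)
            pts = [(x, y) for y in ys for x in xs][: self.n_channels]
            self.xy = np.array(pts)
            self.labels = [f"S{i:02d}" for i in range(self.n_channels)]

    def topography(self, center: tuple[float, float], sigma: float = 0.35) -> np.ndarray:
        """Gaussian blob weights, normalized to a maximum of 1."""
        d2 = np.sum((self.xy - np.asarray(center)) ** 2, axis=1)
        w = np.exp(-d2 / (2 * sigma**2))
        return w / w.max()

    def group(self, name: str) -> list[str]:
        x, y = self.xy[:, 0], self.xy[:, 1]
        masks = {
            "occipital": y < -0.5,
            "left_central": (x < 0) & (np.abs(y) < 0.5),
            "posterior_left": (y < -0.3) & (x < 0),
            "posterior_right": (y < -0.3) & (x > 0),
        }
        if name not in masks:
            raise KeyError(f"unknown channel group {name!r}")
        return [l for l, m in zip(self.labels, masks[name]) if m]

    def hemisphere_map(self) -> dict[str, list[str]]:
        return {"left": self.group("posterior_left"), "right": self.group("posterior_right")}


# ---------------------------------------------------------------------------
# Component simulators
# ---------------------------------------------------------------------------

def simulate_rpeaks(duration_s: float, hr_mean_bpm: float = 65.0, hr_sd_bpm: float = 3.0,
                    seed: int | np.random.Generator = 0, fs: float = 5000.0) -> np.ndarray:
    """R-peak sample indices with i.i.d. truncated-normal inter-beat intervals.

    The interval distribution is Normal(60/hr_mean, 60*hr_sd/hr_mean^2)
    truncated below at 300 ms; the first peak falls within the first 2 s.
    """
    if hr_mean_bpm <= 0:
        raise ValueError("hr_mean_bpm must be positive")
    if hr_sd_bpm < 0:
        raise ValueError("hr_sd_bpm must be non-negative")
    if duration_s < MIN_RR_S:
        raise ValueError(f"duration {duration_s} s too short for a single beat")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mean_rr = 60.0 / hr_mean_bpm
    sd_rr = 60.0 * hr_sd_bpm / hr_mean_bpm**2
    t = float(rng.uniform(0.1, min(2.0, duration_s)))
    peaks = []
    while t < duration_s:
        peaks.append(t)
        if sd_rr == 0:
            rr = mean_rr
        else:
            a = (MIN_RR_S - mean_rr) / sd_rr
            rr = float(truncnorm.rvs(a, np.inf, loc=mean_rr, scale=sd_rr, random_state=rng))
        t += rr
    return np.round(np.array(peaks) * fs).astype(int)


def simulate_imaging_artifact(params: ArtifactParams, fs: float, duration_s: float,
                              channel_gains: np.ndarray,
                              return_source: bool = False):
    """Gradient-artifact matrix: cosines at ``k*f_slice +/- m*f_volume``.

    All generated frequencies are integer multiples of the volume frequency,
    so the waveform is exactly periodic with the TR (sample-for-sample when
    ``fs * tr`` is an integer).  Peak amplitude is scaled to
    ``imaging_amp_uv`` on a unit-gain channel.
    """
    f_s, f_v = params.slice_freq_hz, params.volume_freq_hz
    f_max = params.n_slice_harmonics * f_s + params.n_volume_harmonics * f_v
    if fs <= 2 * f_max:
        raise ValueError(
            f"sampling rate {fs} Hz cannot represent harmonics up to {f_max:.1f} Hz")
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    source = np.zeros(n)
    for k in range(1, params.n_slice_harmonics + 1):
        wk = 1.0 / k
        source += wk * np.cos(2 * np.pi * k * f_s * t)
        for m in range(1, params.n_volume_harmonics + 1):
            wm = wk / (1.0 + m)
            source += wm * np.cos(2 * np.pi * (k * f_s + m * f_v) * t)
            f_lo = k * f_s - m * f_v
            if f_lo > 0:
                source += wm * np.cos(2 * np.pi * f_lo * t)
    peak = np.max(np.abs(source))
    if peak > 0:
        source *= params.imaging_amp_uv / peak
    gains = np.atleast_1d(np.asarray(channel_gains, dtype=float))
    mat = gains[:, None] * source[None, :]
    return (mat, source) if return_source else mat


def _bcg_waveforms(fs: float, params: ArtifactParams) -> list[np.ndarray]:
    """Two smooth beat-template shapes (Gaussian-windowed oscillations).

    Support is [0, 0.65) s relative to R-peak; spectral content is a few Hz
    so that >= 90% of signal power stays below 25 Hz.
    """
    t = np.arange(int(round(0.65 * fs))) / fs
    # oscillation frequencies span the 3-10 Hz range: the beat-locked
    # artifact overlaps the alpha band, which is what makes it harmful to
    # resting-state analyses even after imaging-artifact reduction
    comps = [
        ((0.20, 0.060, 4.0, 1.0), (0.32, 0.060, 9.0, 1.0), (0.45, 0.070, 6.0, 0.5)),
        ((0.28, 0.080, 3.0, 0.8), (0.40, 0.065, 10.0, 0.9), (0.52, 0.050, 7.0, 0.6)),
    ]
    waves = []
    for spec in comps:
        w = np.zeros_like(t)
        for c, s, f, a in spec:
            w += a * np.exp(-0.5 * ((t - c) / s) ** 2) * np.cos(2 * np.pi * f * (t - c))
        waves.append(w / np.max(np.abs(w)))
    return waves


def simulate_bcg(rpeaks: np.ndarray, params: ArtifactParams, fs: float, n_samples: int,
                 topography: np.ndarray, seed: int | np.random.Generator = 0,
                 return_sources: bool = False):
    """Heartbeat-locked BCG artifact.

    Two template waveforms, each with its own scalp topography, are placed
    ``bcg_delay_s`` after every R-peak with per-beat amplitude jitter
    (lognormal, CV ``bcg_amp_cv``) and latency jitter (normal, SD
    ``bcg_latency_sd_ms``).  ``topography`` is ``(2, n_channels)`` or
    ``(n_channels,)`` (then shared).  Peak amplitude on a unit-weight
    channel is scaled to ``bcg_amp_uv``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    topo = np.atleast_2d(np.asarray(topography, dtype=float))
    if topo.shape[0] == 1:
        topo = np.vstack([topo, 0.6 * topo])
    waves = _bcg_waveforms(fs, params)
    delay = int(round(params.bcg_delay_s * fs))
    sources = np.zeros((2, n_samples))
    rpeaks = np.sort(np.asarray(rpeaks, dtype=int))
    sigma_log = np.sqrt(np.log1p(params.bcg_amp_cv**2))
    for r in rpeaks:
        amp = float(np.exp(rng.normal(-0.5 * sigma_log**2, sigma_log))) if params.bcg_amp_cv > 0 else 1.0
        lat = int(round(rng.normal(0.0, params.bcg_latency_sd_ms / 1000.0 * fs))) \
            if params.bcg_latency_sd_ms > 0 else 0
        start = r + delay + lat
        for s, w in enumerate(waves):
            a, b = max(start, 0), min(start + w.size, n_samples)
            if a < b:
                sources[s, a:b] += amp * w[a - start:b - start]
    sources *= params.bcg_amp_uv
    mat = topo.T @ sources if topo.shape[0] == 2 else topo[:, None] * sources[0]
    return (mat, sources) if return_sources else mat


def simulate_pump(params: ArtifactParams, fs: float, duration_s: float,
                  channel_gains: np.ndarray, seed: int | np.random.Generator = 0,
                  return_source: bool = False):
    """Helium-pump vibration artifact: narrowband harmonics of the pump
    fundamental with slow random amplitude modulation.

    Mechanical vibration is not phase-coherent over a session, so each
    harmonic is narrowband noise (~0.5 Hz bandwidth) rather than a pure
    tone; the spectrum still shows sharp peaks at the harmonics only.
    """
    if params.pump_freq_hz < 30.0:
        raise ValueError("pump fundamental must be >= 30 Hz")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    freqs = np.fft.rfftfreq(n, 1 / fs)
    spec = np.zeros(freqs.size, dtype=complex)
    white = np.fft.rfft(rng.standard_normal(n))
    for h in range(1, params.pump_harmonics + 1):
        f = h * params.pump_freq_hz
        if f >= fs / 2:
            break
        spec += (1.0 / h) * np.exp(-0.5 * ((freqs - f) / 0.25) ** 2) * white
    source = np.fft.irfft(spec, n=n)
    peak = np.max(np.abs(source))
    if peak > 0:
        source *= params.pump_amp_uv / peak
    gains = np.atleast_1d(np.asarray(channel_gains, dtype=float))
    mat = gains[:, None] * source[None, :]
    return (mat, source) if return_source else mat


def simulate_motion(params: ArtifactParams, fs: float, n_samples: int,
                    burst_spans: Iterable[tuple[int, int]], channel_gains: np.ndarray,
                    seed: int | np.random.Generator = 0, return_source: bool = False):
    """Band-limited (1-25 Hz) random bursts within the given sample spans,
    emulating tapping-induced cable/head motion."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    source = np.zeros(n_samples)
    spans = list(burst_spans)
    if spans:
        sos = sps.butter(4, [1.0, 25.0], btype="bandpass", fs=fs, output="sos")
        for a, b in spans:
            a, b = max(a, 0), min(b, n_samples)
            if b - a < int(0.1 * fs):
                continue
            n_bursts = rng.poisson(params.motion_rate_hz * (b - a) / fs)
            for _ in range(n_bursts):
                width = int(rng.uniform(0.2, 0.6) * fs)
                c = int(rng.uniform(a, b))
                lo, hi = max(c - width, 0), min(c + width, n_samples)
                burst = sps.sosfiltfilt(sos, rng.standard_normal(hi - lo))
                burst *= np.hanning(hi - lo)
                source[lo:hi] += burst
        peak = np.max(np.abs(source))
        if peak > 0:
            source *= params.motion_amp_uv / peak
    gains = np.atleast_1d(np.asarray(channel_gains, dtype=float))
    mat = gains[:, None] * source[None, :]
    return (mat, source) if return_source else mat


# ---------------------------------------------------------------------------
# Neural signal
# ---------------------------------------------------------------------------

def _pink_noise(n_channels: int, n_samples: int, rms_uv: float,
                rng: np.random.Generator, fs: float) -> np.ndarray:
    """1/f background noise, independent per channel, normalized to rms_uv."""
    white = rng.standard_normal((n_channels, n_samples))
    if rms_uv == 0:
        return np.zeros_like(white)
    spec = np.fft.rfft(white, axis=1)
    f = np.fft.rfftfreq(n_samples, 1 / fs)
    scale = 1.0 / np.sqrt(np.maximum(f, 1.0))
    spec *= scale
    out = np.fft.irfft(spec, n=n_samples, axis=1)
    out *= rms_uv / np.sqrt(np.mean(out**2, axis=1, keepdims=True))
    return out


def _band_noise(band: tuple[float, float], n_samples: int, fs: float,
                rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS band-limited noise (4th-order Butterworth, zero phase)."""
    sos = sps.butter(4, band, btype="bandpass", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, rng.standard_normal(n_samples))
    rms = np.sqrt(np.mean(x**2))
    return x / rms if rms > 0 else x


def vep_kernel(fs: float, params: NeuralParams, tmax_s: float = 0.5) -> np.ndarray:
    """Biphasic visual-evoked-potential kernel: positive P1 peak (~120 ms)
    and negative N1 peak (~175 ms), Gaussian-shaped."""
    t = np.arange(int(round(tmax_s * fs))) / fs * 1000.0  # ms
    k = (params.vep_p1_uv * np.exp(-0.5 * ((t - params.vep_p1_ms) / 15.0) ** 2)
         + params.vep_n1_uv * np.exp(-0.5 * ((t - params.vep_n1_ms) / 22.0) ** 2))
    return k


def simulate_neural(task: str, params: NeuralParams, fs: float, duration_s: float,
                    seed: int | np.random.Generator = 0,
                    layout: ScalpLayout | None = None) -> tuple[np.ndarray, pd.DataFrame]:
    """Task-locked neural scalp signal plus event table.

    * ``resting``: occipital alpha (8-12 Hz) whose RMS alternates between the
      EO and EC levels across blocks.
    * ``tapping``: left-central mu-alpha and beta suppressed by the ERD depths
      during 0-3 s tap blocks; gamma (70-80 Hz) burst in the first second.
    * ``checkerboard``: VEP kernel at each stimulus onset with a topography
      contralateral to the stimulated hemifield.

    Everything rides on independent 1/f background noise per channel.
    Returns ``(n_channels x n_samples matrix, events)`` where ``events`` has
    columns ``condition`` and ``sample``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    layout = layout or ScalpLayout()
    n_ch = layout.n_channels
    n = int(round(duration_s * fs))
    sig = _pink_noise(n_ch, n, params.pink_uv, rng, fs)
    events: list[tuple[str, int]] = []

    if task == "resting":
        topo = layout.topography((0.0, -0.9))
        alpha = _band_noise((8.0, 12.0), n, fs, rng)
        env = np.zeros(n)
        block = int(round(params.block_s * fs))
        cond = ["EO", "EC"]
        for b in range(params.n_blocks):
            a = b * block
            if a >= n:
                break
            amp = params.alpha_eo_uv if b % 2 == 0 else params.alpha_ec_uv
            env[a:a + block] = amp
            events.append((cond[b % 2], a))
        sig += topo[:, None] * (alpha * env)[None, :]

    elif task == "tapping":
        topo = layout.topography((-0.5, 0.0))
        mu = _band_noise((8.0, 12.0), n, fs, rng)
        beta = _band_noise((15.0, 25.0), n, fs, rng)
        gamma = _band_noise((70.0, 80.0), n, fs, rng) if fs > 170 else np.zeros(n)
        env_a = np.full(n, params.mu_alpha_uv)
        env_b = np.full(n, params.mu_beta_uv)
        env_g = np.full(n, params.gamma_uv)
        t0 = int(round(2.0 * fs))
        tap = int(round(params.tap_block_s * fs))
        for _ in range(params.n_taps):
            if t0 + tap > n:
                break
            events.append(("tap", t0))
            env_a[t0:t0 + tap] *= (1.0 - params.erd_alpha_depth)
            env_b[t0:t0 + tap] *= (1.0 - params.erd_beta_depth)
            env_g[t0:t0 + int(round(1.0 * fs))] *= params.gamma_ers_gain
            rest = float(rng.choice(params.rest_choices_s))
            t0 += tap + int(round(rest * fs))
        sig += topo[:, None] * (mu * env_a + beta * env_b + gamma * env_g)[None, :]

    elif task == "checkerboard":
        kern = vep_kernel(fs, params)
        topo_l = layout.topography((-0.5, -0.9))
        topo_r = layout.topography((0.5, -0.9))
        conditions = ["LU", "LL", "RU", "RL"]
        onsets: list[tuple[str, int]] = []
        t0 = int(round(2.0 * fs))
        order = rng.permutation(np.repeat(conditions, params.n_trials_per_condition))
        for cond in order:
            if t0 + kern.size > n:
                break
            onsets.append((str(cond), t0))
            iti = float(rng.choice(params.iti_choices_s))
            t0 += int(round((params.stim_duration_s + iti) * fs))
        for cond, a in onsets:
            # contralateral projection: left-field stimuli drive the right hemisphere
            topo = topo_r if cond.startswith("L") else topo_l
            ipsi = topo_l if cond.startswith("L") else topo_r
            proj = topo + params.ipsi_fraction * ipsi
            sig[:, a:a + kern.size] += proj[:, None] * kern[None, :]
            events.append((cond, a))
    else:
        raise ValueError(f"unknown task {task!r}")

    ev = pd.DataFrame(events, columns=["condition", "sample"])
    return sig, ev.sort_values("sample", ignore_index=True)


# ---------------------------------------------------------------------------
# CWL reference channels
# ---------------------------------------------------------------------------

def simulate_cwl_reference(sources: dict[str, np.ndarray], lags_ms: np.ndarray,
                           weights: np.ndarray, sensor_noise_uv: float,
                           fs: float, seed: int | np.random.Generator = 0,
                           return_clean: bool = False):
    """Six carbon-wire-loop channels: lag-shifted weighted mixtures of the
    artifact source signals plus white sensor noise -- no neural component.

    ``sources`` maps component name to a 1-D source series or a
    ``(n_sources, n_samples)`` stack; ``weights`` is ``(6, total_sources)``
    and ``lags_ms`` gives one lag per loop (positive = loop lags the scalp).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    stack = []
    for name in sorted(sources):
        s = np.atleast_2d(np.asarray(sources[name], dtype=float))
        stack.append(s)
    S = np.vstack(stack) if stack else np.zeros((0, 0))
    lags_ms = np.asarray(lags_ms, dtype=float)
    weights = np.atleast_2d(np.asarray(weights, dtype=float))
    if lags_ms.shape[0] != 6 or weights.shape[0] != 6:
        raise ValueError("six lag/weight sets are required")
    if np.any(np.abs(lags_ms) > 50.0):
        raise ValueError("loop lags must be within +/-50 ms")
    if S.size and weights.shape[1] != S.shape[0]:
        raise ValueError(f"weights have {weights.shape[1]} columns for {S.shape[0]} sources")
    n = S.shape[1] if S.size else 0
    loops = np.zeros((6, n))
    for i in range(6):
        shift = int(round(lags_ms[i] / 1000.0 * fs))
        shifted = shift_samples(S, shift)
        loops[i] = weights[i] @ shifted
    clean = loops.copy()
    if sensor_noise_uv > 0 and n:
        loops = loops + sensor_noise_uv * rng.standard_normal(loops.shape)
    return (loops, clean) if return_clean else loops


def shift_samples(x: np.ndarray, shift: int) -> np.ndarray:
    """Shift along the last axis with zero fill (positive = delay)."""
    out = np.zeros_like(x)
    if shift == 0:
        return x.copy()
    if shift > 0:
        out[..., shift:] = x[..., :-shift]
    else:
        out[..., :shift] = x[..., -shift:]
    return out


def simulate_ecg(rpeaks: np.ndarray, fs: float, n_samples: int,
                 r_amp_uv: float = 600.0) -> np.ndarray:
    """Synthetic ECG trace: sharp biphasic QRS at each R-peak plus a small
    T-wave 250 ms later."""
    t_qrs = np.arange(int(round(0.04 * fs))) / fs
    qrs = -np.gradient(np.exp(-0.5 * ((t_qrs - 0.02) / 0.006) ** 2))
    qrs /= np.max(np.abs(qrs))
    t_t = np.arange(int(round(0.16 * fs))) / fs
    twave = np.exp(-0.5 * ((t_t - 0.08) / 0.03) ** 2)
    ecg = np.zeros(n_samples)
    for r in np.asarray(rpeaks, dtype=int):
        a = r - t_qrs.size // 2
        lo, hi = max(a, 0), min(a + qrs.size, n_samples)
        if lo < hi:
            ecg[lo:hi] += r_amp_uv * qrs[lo - a:hi - a]
        a = r + int(0.18 * fs)
        lo, hi = max(a, 0), min(a + twave.size, n_samples)
        if lo < hi:
            ecg[lo:hi] += 0.15 * r_amp_uv * twave[lo - a:hi - a]
    return ecg


# ---------------------------------------------------------------------------
# Session assembly
# ---------------------------------------------------------------------------

@dataclass
class GroundTruth:
    """Exact decomposition of a simulated session.

    ``recording.data == neural + sum(components.values()) + noise`` holds
    sample for sample.  ``neural`` rows for CWL channels are identically
    zero (the loops are isolated from the scalp); the ECG row of ``neural``
    carries the cardiac trace, which is physiological rather than
    MR-induced.
    """

    neural: np.ndarray  # (n_channels, n_samples)
    components: dict[str, np.ndarray]  # imaging, bcg, pump, motion
    noise: np.ndarray
    rpeak_samples: np.ndarray
    events: pd.DataFrame
    layout: ScalpLayout
    fs: float

    def total(self) -> np.ndarray:
        """Reassemble ``neural + noise + components`` in the canonical order
        used by :func:`assemble_session` (bitwise identical to the
        recording)."""
        data = self.neural + self.noise
        for name in ("imaging", "bcg", "pump", "motion"):
            data = data + self.components[name]
        return data

    def reference_recording(self, labels: list[str]) -> Recording:
        """Clean comparison data: neural + sensor noise on scalp channels only
        (the role played by a recording made outside the scanner)."""
        n_scalp = self.layout.n_channels
        data = self.neural[:n_scalp] + self.noise[:n_scalp]
        return Recording(data.copy(), self.fs, labels[:n_scalp],
                         [SCALP] * n_scalp, "none")


def assemble_session(config: SessionConfig,
                     artifact: ArtifactParams | None = None,
                     neural: NeuralParams | None = None,
                     sensor_noise_uv: float = 1.5,
                     ) -> tuple[Recording, MarkerList, GroundTruth]:
    """Build a full synthetic EEG-fMRI session.

    Channel order: ``n_scalp`` scalp channels, six CWL loops, one ECG.
    Volume markers are placed every TR starting at sample 0; task events are
    emitted as stimulus/block markers labelled with their condition.
    """
    ap = artifact or ArtifactParams(slice_freq_hz=config.slice_freq_hz,
                                    volume_freq_hz=config.volume_freq_hz,
                                    **config.artifact)
    np_ = neural or NeuralParams(**config.neural)
    fs, dur = config.fs_hz, config.duration_s
    n = int(round(fs * dur))
    rng = np.random.default_rng(config.seed)
    r_sim, r_art, r_noise, r_cwl = [np.random.default_rng(s.entropy)
                                    for s in rng.bit_generator.seed_seq.spawn(4)]

    layout = ScalpLayout(config.n_scalp)
    n_scalp = layout.n_channels
    n_ch = n_scalp + 7
    labels = layout.labels + [f"CWL{i+1}" for i in range(6)] + ["ECG"]
    roles = [SCALP] * n_scalp + [CWL] * 6 + [ECG]

    # neural ------------------------------------------------------------
    scalp_neural, events = simulate_neural(config.task, np_, fs, dur, r_sim, layout)
    rpeaks = simulate_rpeaks(dur, seed=r_sim, fs=fs)
    neural_full = np.zeros((n_ch, n))
    neural_full[:n_scalp] = scalp_neural
    neural_full[-1] = simulate_ecg(rpeaks, fs, n)

    # artifact sources and scalp projections ----------------------------
    img_gain = 0.8 + 0.4 * r_art.random(n_scalp)
    img_scalp, img_src = simulate_imaging_artifact(ap, fs, dur, img_gain, return_source=True)
    # smooth blob topographies modulated channel-by-channel: BCG gain varies
    # strongly between electrodes (local vessel/electrode geometry), so the
    # artifact does not cancel under average re-referencing
    bcg_topo = np.vstack([layout.topography((0.0, -0.6), 0.6),
                          layout.topography((-0.3, 0.4), 0.6)])
    bcg_topo = bcg_topo * np.exp(0.2 * r_art.standard_normal(bcg_topo.shape))
    bcg_scalp, bcg_src = simulate_bcg(rpeaks, ap, fs, n, bcg_topo, r_art, return_sources=True)
    pump_gain = 0.7 + 0.6 * r_art.random(n_scalp)
    pump_scalp, pump_src = simulate_pump(ap, fs, dur, pump_gain, r_art, return_source=True)
    tap_spans = [(int(s), int(s + np_.tap_block_s * fs))
                 for s in events.loc[events.condition == "tap", "sample"]] \
        if config.task == "tapping" else []
    mot_gain = 0.5 + 0.5 * r_art.random(n_scalp)
    mot_scalp, mot_src = simulate_motion(ap, fs, n, tap_spans, mot_gain, r_art,
                                         return_source=True)

    sources = {"bcg": bcg_src, "imaging": img_src, "motion": mot_src, "pump": pump_src}
    n_src = 2 + 3  # bcg (2) + imaging + motion + pump, in sorted-name order
    lags_ms = r_cwl.uniform(-ap.cwl_max_lag_ms, ap.cwl_max_lag_ms, size=6)
    weights = 0.5 + r_cwl.random((6, n_src))
    loops, loops_clean = simulate_cwl_reference(sources, lags_ms, weights,
                                                0.0, fs, r_cwl, return_clean=True)

    # split the clean loop signal back into per-component contributions so
    # that the ground-truth decomposition stays exact
    def loop_part(names: list[str]) -> np.ndarray:
        sub = {k: sources[k] for k in names}
        idx = []
        pos = 0
        for name in sorted(sources):
            k = np.atleast_2d(sources[name]).shape[0]
            if name in names:
                idx.extend(range(pos, pos + k))
            pos += k
        return simulate_cwl_reference(sub, lags_ms, weights[:, idx], 0.0, fs, r_cwl)

    components = {}
    for name, scalp_mat in (("imaging", img_scalp), ("bcg", bcg_scalp),
                            ("pump", pump_scalp), ("motion", mot_scalp)):
        full = np.zeros((n_ch, n))
        full[:n_scalp] = scalp_mat
        full[n_scalp:n_scalp + 6] = loop_part([name])
        components[name] = full
    # imaging artifact couples weakly into the ECG lead as well
    components["imaging"][-1] = 0.05 * img_src

    noise = sensor_noise_uv * r_noise.standard_normal((n_ch, n))
    noise[n_scalp:n_scalp + 6] = ap.cwl_noise_uv * r_noise.standard_normal((6, n))

    data = neural_full + noise
    for name in ("imaging", "bcg", "pump", "motion"):
        data = data + components[name]

    rec = Recording(data, fs, labels, roles, "none")
    markers = MarkerList()
    tr_samples = config.tr_s * fs
    for v, s in enumerate(np.arange(0, n, tr_samples)):
        markers.add("volume", "R128", int(round(s)))
    kind = "block" if config.task in ("resting", "tapping") else "stimulus"
    for _, row in events.iterrows():
        markers.add(kind, str(row.condition), int(row["sample"]))
    markers.sort()

    gt = GroundTruth(neural_full, components, noise, rpeaks, events, layout, fs)
    return rec, markers, gt
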