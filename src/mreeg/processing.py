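"""Resampling, FIR filtering, re-referencing, epoching and Welch PSD.

All operations take and return the package's :class:`~mreeg.core_io.Recording`
container (or plain arrays for the spectral estimators).  Filtering is
zero-phase: odd-length linear-phase Hamming-windowed-sinc kernels applied by
centered convolution, with the kernel length set by Fred Harris'
rule-of-thumb ``N = atten_db / (22 * transition / fs)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import signal as sps

from .core_io import MarkerList, Recording, SCALP, log

PSD_FLOOR_DB = -300.0


@dataclass
class PSDResult:
    """Per-channel power spectral density in dB (10*log10 of uV^2/Hz)."""

    freqs: np.ndarray  # (n_freqs,)
    power_db: np.ndarray  # (n_channels, n_freqs)
    channel_labels: list[str]
    fs: float
    nperseg: int
    overlap: float
    taper: str
    pad_applied: int = 0  # zero-padding added to reach one full segment

    @property
    def df(self) -> float:
        return float(self.freqs[1] - self.freqs[0])


@dataclass
class EpochSet:
    """Fixed-length epochs cut around events: (epochs, channels, samples)."""

    data: np.ndarray
    tmin: float
    tmax: float
    fs: float
    events: pd.DataFrame  # rows retained per epoch, in epoch order
    channel_labels: list[str]

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def times(self) -> np.ndarray:
        n = self.data.shape[2]
        return self.tmin + np.arange(n) / self.fs


def resample(rec: Recording, new_fs: float, markers: MarkerList | None = None):
    """Polyphase anti-aliased downsampling; marker samples are rescaled by the
    rate ratio and rounded to nearest.

    The anti-aliasing filter cuts at 0.9x the new Nyquist frequency.
    Upsampling is refused.
    """
    if new_fs > rec.fs:
        raise ValueError(f"upsampling from {rec.fs} to {new_fs} Hz is not supported")
    if new_fs == rec.fs:
        out = rec.copy()
        return (out, markers.rescaled(1.0)) if markers is not None else out
    frac = Fraction(new_fs / rec.fs).limit_denominator(10000)
    up, down = frac.numerator, frac.denominator
    # windowed-sinc anti-aliasing kernel at the upsampled rate; long enough
    # that the transition band stays above 0.8 x the new Nyquist
    n_taps = 2 * 32 * max(up, down) + 1
    cutoff = 0.9 / down  # in units of the upsampled Nyquist
    h = sps.firwin(n_taps, cutoff, window=("kaiser", 5.0))
    data = sps.resample_poly(rec.data, up, down, axis=1, window=h * up)
    out = Recording(data, new_fs, list(rec.channel_labels), list(rec.channel_roles),
                    rec.reference)
    if markers is not None:
        return out, markers.rescaled(new_fs / rec.fs)
    return out


def harris_length(stopband_atten_db: float, transition_hz: float, fs: float) -> int:
    """Fred Harris' rule for the windowed-sinc length, rounded up to odd."""
    if transition_hz <= 0:
        raise ValueError("transition bandwidth must be positive")
    n = int(np.ceil(stopband_atten_db / (22.0 * transition_hz / fs)))
    return n + 1 if n % 2 == 0 else n


def design_lowpass_fir(cutoff_hz: float, fs: float, stopband_atten_db: float = 30.0,
                       transition_hz: float = 1.0) -> np.ndarray:
    """Odd-length linear-phase Hamming-windowed-sinc low-pass filter with
    unit DC gain, sized by the Harris rule."""
    if not (0 < cutoff_hz < fs / 2):
        raise ValueError(f"cutoff {cutoff_hz} Hz outside (0, {fs / 2}) Hz")
    n = harris_length(stopband_atten_db, transition_hz, fs)
    return sps.firwin(n, cutoff_hz, window="hamming", fs=fs)


def apply_fir_zerophase(data: np.ndarray, h: np.ndarray) -> np.ndarray:
    """Apply an odd-length linear-phase FIR with centered (zero-phase)
    convolution; edges are handled by reflection padding."""
    if h.size % 2 == 0:
        raise ValueError("zero-phase application requires an odd-length filter")
    data = np.atleast_2d(data)
    if h.size > data.shape[1]:
        raise ValueError(f"filter length {h.size} exceeds signal length {data.shape[1]}")
    half = h.size // 2
    padded = np.pad(data, [(0, 0), (half, half)], mode="reflect")
    out = sps.fftconvolve(padded, h[None, :], mode="valid", axes=1)
    return out


def filter_lowpass(rec: Recording, cutoff_hz: float, stopband_atten_db: float = 30.0,
                   transition_hz: float = 1.0) -> Recording:
    h = design_lowpass_fir(cutoff_hz, rec.fs, stopband_atten_db, transition_hz)
    out = rec.copy()
    out.data = apply_fir_zerophase(out.data, h)
    return out


def rereference_average(rec: Recording) -> Recording:
    """Subtract the instantaneous mean of the scalp channels from every scalp
    channel; CWL and ECG channels are untouched."""
    idx = rec.indices(SCALP)
    if idx.size < 2:
        raise ValueError("average re-referencing requires at least 2 scalp channels")
    out = rec.copy()
    out.data[idx] -= out.data[idx].mean(axis=0, keepdims=True)
    out.reference = "average"
    return out


def epoch_data(rec: Recording | np.ndarray, events: pd.DataFrame, tmin_s: float,
               tmax_s: float, fs: float | None = None,
               channel_labels: list[str] | None = None) -> EpochSet:
    """Cut half-open windows ``[event + round(tmin*fs), event + round(tmax*fs))``
    around each event.  Events whose window leaves the recording are dropped
    (logged); epochs may overlap."""
    if isinstance(rec, Recording):
        data, fs = rec.data, rec.fs
        channel_labels = list(rec.channel_labels)
    else:
        data = np.atleast_2d(rec)
        if fs is None:
            raise ValueError("fs is required for array input")
        channel_labels = channel_labels or [f"ch{i}" for i in range(data.shape[0])]
    lo = int(round(tmin_s * fs))
    hi = int(round(tmax_s * fs))
    if hi <= lo:
        raise ValueError("tmax must exceed tmin")
    n = data.shape[1]
    keep_rows = []
    chunks = []
    for _, row in events.iterrows():
        a, b = int(row["sample"]) + lo, int(row["sample"]) + hi
        if a < 0 or b > n:
            log.info("dropping boundary epoch at sample %d", row["sample"])
            continue
        keep_rows.append(row)
        chunks.append(data[:, a:b])
    if not chunks:
        raise ValueError("no epochs survive the recording boundaries")
    return EpochSet(np.stack(chunks), tmin_s, tmax_s, fs,
                    pd.DataFrame(keep_rows).reset_index(drop=True), channel_labels)


def welch_psd(x: np.ndarray, fs: float, nperseg: int = 4096, overlap: float = 0.5,
              taper: str = "hamming", pad_to: int | None = None,
              channel_labels: list[str] | None = None) -> PSDResult:
    """Welch PSD in dB with density scaling.

    Input shorter than one segment is zero-padded to ``nperseg`` (a single
    tapered segment), mirroring the treatment of short trials.  Multi-channel
    input yields one PSD per channel; summaries over channels must average
    the per-channel PSDs, not the time-domain signals (see
    :func:`mreeg.features.summary_channel_psd`).
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[1] < 1:
        raise ValueError("empty input")
    pad_applied = 0
    target = pad_to if pad_to is not None else nperseg
    if x.shape[1] < target:
        pad_applied = target - x.shape[1]
        x = np.pad(x, [(0, 0), (0, pad_applied)])
    freqs, pxx = sps.welch(x, fs=fs, window=taper, nperseg=nperseg,
                           noverlap=int(round(overlap * nperseg)),
                           scaling="density", detrend=False, axis=1)
    if np.any(pxx <= 0):
        log.info("zero-power bins floored at %g dB", PSD_FLOOR_DB)
    power_db = 10.0 * np.log10(np.maximum(pxx, 10 ** (PSD_FLOOR_DB / 10.0)))
    labels = channel_labels or [f"ch{i}" for i in range(x.shape[0])]
    return PSDResult(freqs, power_db, labels, fs, nperseg, overlap, taper, pad_applied)


def welch_psd_epochs(epochs: EpochSet, nperseg: int = 4096, overlap: float = 0.5,
                     taper: str = "hamming") -> list[PSDResult]:
    """One PSD per epoch (channels x freqs each)."""
    return [welch_psd(epochs.data[i], epochs.fs, nperseg, overlap, taper,
                      channel_labels=epochs.channel_labels)
            for i in range(epochs.n_epochs)]
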