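"""Evaluation features: band power contrasts, summary channels, VEP
difference waves, RMS-ratio SNR, and RMSD.

Band power is summarized as the mean of the dB-scale PSD over the band's
frequency bins (inclusive at both edges); multi-channel summaries average
per-channel PSDs in the dB domain.  The evoked-response SNR is the maximum
of a sliding RMS inside the peak window divided by the mean sliding RMS of
the pre-stimulus baseline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import log
from .processing import EpochSet, PSDResult


@dataclass(frozen=True)
class BandDefinition:
    name: str
    lo_hz: float
    hi_hz: float

    def __post_init__(self) -> None:
        if not (0 < self.lo_hz < self.hi_hz):
            raise ValueError("band edges must satisfy 0 < lo < hi")


ALPHA = BandDefinition("alpha", 8.0, 12.0)
BETA = BandDefinition("beta", 15.0, 25.0)
GAMMA = BandDefinition("gamma", 70.0, 80.0)

#: evoked-response windows (ms): difference-wave peaks, VEP peaks, baseline
VEP_WINDOWS = {
    "D1": (70.0, 100.0),
    "D2": (130.0, 170.0),
    "P1": (100.0, 140.0),
    "N1": (150.0, 200.0),
    "baseline": (-200.0, 0.0),
}


def band_mean_power(psd: PSDResult, band: BandDefinition) -> np.ndarray:
    """Mean dB power over the band's frequency bins, per channel (band edges
    inclusive at grid resolution)."""
    if band.hi_hz > psd.freqs[-1]:
        raise ValueError(f"band {band.name} [{band.lo_hz}, {band.hi_hz}] Hz "
                         f"exceeds the frequency grid (max {psd.freqs[-1]:.1f} Hz)")
    mask = (psd.freqs >= band.lo_hz) & (psd.freqs <= band.hi_hz)
    if not mask.any():
        raise ValueError(f"no frequency bins inside band {band.name}")
    return psd.power_db[:, mask].mean(axis=1)


def select_summary_channels(values: np.ndarray, labels: list[str],
                            z_threshold: float = 1.0, sign: int = 1) -> list[str]:
    """Channels whose standardized topography value exceeds the threshold.

    ``z = (v - mean) / SD`` over channels (sample SD); the returned set is
    ``{channels with sign * z > z_threshold}``, ordered by ``|z|``
    descending with ties broken by label order.  Zero variance across
    channels yields an empty set with a warning.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 3:
        raise ValueError("channel selection requires at least 3 channels")
    sd = values.std(ddof=1)
    if sd == 0:
        log.warning("zero variance across channels; no summary channels selected")
        return []
    z = (values - values.mean()) / sd
    picked = [(abs(z[i]), labels[i]) for i in range(values.size) if sign * z[i] > z_threshold]
    order = sorted(range(len(picked)), key=lambda k: (-picked[k][0], labels.index(picked[k][1])))
    return [picked[k][1] for k in order]


def summary_channel_psd(psd: PSDResult, selected: list[str]) -> PSDResult:
    """Bin-wise dB-domain mean PSD over the selected channels."""
    if not selected:
        raise ValueError("no channels selected")
    idx = []
    for lab in selected:
        if lab not in psd.channel_labels:
            raise KeyError(f"unknown channel label {lab!r}")
        idx.append(psd.channel_labels.index(lab))
    mean_db = psd.power_db[idx].mean(axis=0, keepdims=True)
    return PSDResult(psd.freqs, mean_db, ["summary"], psd.fs, psd.nperseg,
                     psd.overlap, psd.taper, psd.pad_applied)


def contra_ipsi_waves(epochs: EpochSet, hemisphere_map: dict[str, list[str]]
                      ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Contralateral / ipsilateral mean responses and their difference.

    The contralateral wave averages left-hemisphere channels over
    right-field trials (RU, RL) together with right-hemisphere channels
    over left-field trials (LU, LL); the ipsilateral wave is the converse.
    """
    for side in ("left", "right"):
        if side not in hemisphere_map or not hemisphere_map[side]:
            raise KeyError(f"hemisphere map entry {side!r} missing or empty")
    conds = set(epochs.events["condition"])
    missing = {"LU", "LL", "RU", "RL"} - conds
    if missing:
        raise ValueError(f"missing stimulus conditions: {sorted(missing)}")
    idx = {side: [epochs.channel_labels.index(l) for l in hemisphere_map[side]]
           for side in ("left", "right")}
    is_left_field = epochs.events["condition"].str.startswith("L").to_numpy()

    def mean_over(field_left: bool, side: str) -> np.ndarray:
        trials = np.where(is_left_field == field_left)[0]
        return epochs.data[np.ix_(trials, idx[side])].mean(axis=(0, 1))

    contra = 0.5 * (mean_over(False, "left") + mean_over(True, "right"))
    ipsi = 0.5 * (mean_over(False, "right") + mean_over(True, "left"))
    return contra, ipsi, contra - ipsi


def window_mean_amplitude(series: np.ndarray, window_ms: tuple[float, float],
                          fs: float, t0_s: float = 0.0) -> float:
    """Mean amplitude over a closed time window (ms relative to the event;
    ``t0_s`` is the epoch start time)."""
    series = np.asarray(series, dtype=float)
    t_ms = (t0_s + np.arange(series.size) / fs) * 1000.0
    mask = (t_ms >= window_ms[0]) & (t_ms <= window_ms[1])
    if not mask.any() or window_ms[0] < t_ms[0] - 0.5 or window_ms[1] > t_ms[-1] + 0.5:
        raise ValueError(f"window {window_ms} ms outside epoch [{t_ms[0]:.0f}, {t_ms[-1]:.0f}] ms")
    return float(series[mask].mean())


def sliding_rms(series: np.ndarray, span: int) -> np.ndarray:
    """RMS over a centered sliding sub-window of ``span`` samples."""
    span = max(int(span), 1)
    sq = np.asarray(series, dtype=float) ** 2
    kernel = np.ones(span) / span
    ms = np.convolve(sq, kernel, mode="same")
    return np.sqrt(np.maximum(ms, 0.0))


def snr_rms(series: np.ndarray, peak_window_ms: tuple[float, float],
            baseline_window_ms: tuple[float, float], fs: float, t0_s: float,
            rms_span_ms: float = 20.0) -> float:
    """Evoked-response SNR: max sliding RMS in the peak window over the mean
    sliding RMS of the baseline window."""
    series = np.asarray(series, dtype=float)
    t_ms = (t0_s + np.arange(series.size) / fs) * 1000.0
    span = max(int(round(rms_span_ms / 1000.0 * fs)), 1)
    rms = sliding_rms(series, span)
    masks = []
    for window in (peak_window_ms, baseline_window_ms):
        m = (t_ms >= window[0]) & (t_ms <= window[1])
        if not m.any():
            raise ValueError(f"window {window} ms outside epoch")
        masks.append(m)
    baseline = float(rms[masks[1]].mean())
    if baseline <= 0:
        raise ValueError("zero baseline RMS; degenerate input")
    return float(rms[masks[0]].max() / baseline)


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Root-mean-square deviation between two equal-length series (uV)."""
    a, b = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    return float(np.sqrt(np.mean((a - b) ** 2)))


def band_power_table(rows: list[dict]) -> pd.DataFrame:
    """Assemble feature records into the delimited-text table consumed by the
    inference layer."""
    return pd.DataFrame(rows)
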