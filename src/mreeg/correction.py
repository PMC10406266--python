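"""MR artifact reduction: AAS, OBS, CWL regression, R-peak detection.

The three correctors implemented here are the standard toolchain for EEG
recorded during fMRI:

* :func:`aas_correct` -- average artifact subtraction: a channel-wise
  sliding-mean template over the nearest epochs, subtracted at each anchor
  (volume markers for imaging-artifact reduction, R-peaks for BCG);
* :func:`obs_correct` -- optimal basis set: per channel, the mean plus the
  leading principal components of the stacked heartbeat epochs are fitted
  by least squares to every epoch and subtracted;
* :func:`cwl_regress` -- carbon-wire-loop regression: per Hann-tapered time
  window, the six loop signals and their time-shifted copies are regressed
  out of each EEG channel, and the residual windows are overlap-added.

:func:`run_variant` composes them into the evaluated pipeline variants
NC / IAR / AAS / OBS / CWL, where every BCG-stage method runs on
imaging-artifact-reduced data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .core_io import MarkerList, Recording, SCALP, log

VARIANTS = ("NC", "IAR", "AAS", "OBS", "CWL")


@dataclass
class ArtifactTemplate:
    """Per-channel template waveforms, one per anchor: (n_anchors, n_channels,
    pre + post)."""

    waveforms: np.ndarray
    span: tuple[int, int]  # (pre, post) samples relative to anchor
    n_windows: int


@dataclass
class OBSBasis:
    """Per-channel mean waveform plus K orthonormal principal-component
    waveforms."""

    means: np.ndarray  # (n_channels, epoch_len)
    components: np.ndarray  # (n_channels, K, epoch_len), rows orthonormal
    n_pcs: int


@dataclass
class CWLDesign:
    """Windowing and lag grid for carbon-wire-loop regression."""

    window_s: float = 4.0
    taper: str = "hann"
    max_lag_s: float = 0.021
    lag_step: int = 1
    include_intercept: bool = True

    def __post_init__(self) -> None:
        if self.window_s <= 2 * self.max_lag_s:
            raise ValueError("window length must exceed twice the maximum lag")
        if self.lag_step < 1:
            raise ValueError("lag step must be >= 1 sample")


# ---------------------------------------------------------------------------
# R-peak detection
# ---------------------------------------------------------------------------

def detect_rpeaks(ecg: np.ndarray, fs: float, refractory_s: float = 0.3) -> np.ndarray:
    """Detect R-peaks with a derivative-energy detector.

    Band-pass 5-15 Hz, squared derivative, 150 ms moving-window integration,
    adaptive-threshold peak picking with a 300 ms refractory period.  The
    squaring step makes detection polarity-invariant.  A flat trace yields
    an empty list (with a warning) rather than an error.
    """
    ecg = np.asarray(ecg, dtype=float)
    if fs < 100:
        raise ValueError("R-peak detection requires fs >= 100 Hz")
    if not np.all(np.isfinite(ecg)):
        raise ValueError("ECG contains non-finite values")
    if ecg.size < int(fs) or np.ptp(ecg) == 0:
        log.warning("flat or too-short ECG; no R-peaks detected")
        return np.zeros(0, dtype=int)
    sos = sps.butter(2, [5.0, 15.0], btype="bandpass", fs=fs, output="sos")
    bp = sps.sosfiltfilt(sos, ecg)
    energy = np.gradient(bp) ** 2
    win = max(int(round(0.15 * fs)), 1)
    env = np.convolve(energy, np.ones(win) / win, mode="same")
    dist = max(int(round(refractory_s * fs)), 1)
    cand, _ = sps.find_peaks(env, distance=dist)
    if cand.size == 0:
        log.warning("no candidate R-peaks found")
        return np.zeros(0, dtype=int)
    heights = env[cand]
    thr = 0.2 * np.percentile(heights, 95)
    kept = cand[heights > thr]
    # refine each detection to the center of QRS energy (robust to the
    # biphasic shape and to polarity)
    half = int(round(0.06 * fs))
    qwin = max(int(round(0.02 * fs)), 1)
    qk = np.ones(qwin) / qwin
    qrs_energy = np.convolve(energy, qk, mode="same")
    refined = []
    for c in kept:
        lo, hi = max(c - half, 0), min(c + half + 1, ecg.size)
        refined.append(lo + int(np.argmax(qrs_energy[lo:hi])))
    refined = np.unique(refined)
    # enforce the refractory period after refinement
    out: list[int] = []
    for r in refined:
        if out and r - out[-1] < dist:
            if qrs_energy[r] > qrs_energy[out[-1]]:
                out[-1] = int(r)
        else:
            out.append(int(r))
    return np.array(out, dtype=int)


# ---------------------------------------------------------------------------
# shared epoch machinery
# ---------------------------------------------------------------------------

def _valid_anchors(anchors: np.ndarray, pre: int, post: int, n: int) -> np.ndarray:
    a = np.sort(np.asarray(anchors, dtype=int))
    return a[(a - pre >= 0) & (a + post <= n)]


def _ownership_bounds(anchors: np.ndarray, pre: int, post: int,
                      n: int) -> list[tuple[int, int, int]]:
    """For each anchor, the sample range it owns for subtraction.

    Overlap between consecutive epochs is split at the midpoint between the
    anchors (nearest-anchor ownership); ranges are clipped to the recording.
    Returns (anchor, own_start, own_stop) triples.
    """
    anchors = np.sort(np.asarray(anchors, dtype=int))
    bounds = []
    for i, a in enumerate(anchors):
        start, stop = a - pre, a + post
        if i > 0:
            mid = (anchors[i - 1] + a + 1) // 2
            start = max(start, min(mid, anchors[i - 1] + post))
        if i + 1 < anchors.size:
            mid = (a + anchors[i + 1] + 1) // 2
            stop = min(stop, max(mid, anchors[i + 1] - pre))
        start, stop = max(start, 0), min(stop, n)
        if start < stop:
            bounds.append((int(a), start, stop))
    return bounds


def _stack_epochs(data: np.ndarray, anchors: np.ndarray, pre: int, post: int) -> np.ndarray:
    """(n_channels, n_anchors, pre + post) epoch stack via fancy indexing."""
    idx = anchors[:, None] + np.arange(-pre, post)[None, :]
    return data[:, idx]


# ---------------------------------------------------------------------------
# AAS
# ---------------------------------------------------------------------------

def aas_correct(rec: Recording, anchors: np.ndarray, n_windows: int = 25,
                epoch_span: tuple[int, int] | None = None,
                channel_idx: np.ndarray | None = None,
                ) -> tuple[Recording, ArtifactTemplate]:
    """Average artifact subtraction.

    For each anchor, the template is the channel-wise mean over the
    ``n_windows`` nearest epochs (centered sliding window, truncated at the
    recording edges) and is subtracted over the samples that anchor owns.
    ``epoch_span = (pre, post)`` in samples; default ``(0, median anchor
    spacing)`` which tiles volume epochs exactly.  Samples outside all
    epochs are untouched.
    """
    anchors = np.sort(np.asarray(anchors, dtype=int))
    if anchors.size < n_windows:
        raise ValueError(
            f"{anchors.size} anchors < n_windows={n_windows}; use a smaller n_windows")
    if epoch_span is None:
        spacing = int(np.median(np.diff(anchors))) if anchors.size > 1 else rec.n_samples
        epoch_span = (0, spacing)
    pre, post = int(epoch_span[0]), int(epoch_span[1])
    n = rec.n_samples
    ch = np.arange(rec.n_channels) if channel_idx is None else np.asarray(channel_idx)

    valid = _valid_anchors(anchors, pre, post, n)
    if valid.size < n_windows:
        raise ValueError(
            f"only {valid.size} full epochs fit the recording; use a smaller n_windows")
    epochs = _stack_epochs(rec.data[ch], valid, pre, post)  # (nch, nv, L)
    csum = np.concatenate([np.zeros((ch.size, 1, pre + post)),
                           np.cumsum(epochs, axis=1)], axis=1)

    def template_for(anchor: int) -> np.ndarray:
        # nearest n_windows valid epochs, centered on the anchor
        pos = int(np.searchsorted(valid, anchor))
        lo = int(np.clip(pos - n_windows // 2, 0, valid.size - n_windows))
        return (csum[:, lo + n_windows] - csum[:, lo]) / n_windows

    out = rec.copy()
    waveforms = np.zeros((anchors.size, ch.size, pre + post))
    templ_by_anchor = {}
    for k, a in enumerate(anchors):
        waveforms[k] = templ_by_anchor[a] = template_for(a)
    for a, start, stop in _ownership_bounds(anchors, pre, post, n):
        off = start - (a - pre)
        out.data[np.ix_(ch, np.arange(start, stop))] -= \
            templ_by_anchor[a][:, off:off + (stop - start)]
    return out, ArtifactTemplate(waveforms, (pre, post), n_windows)


# ---------------------------------------------------------------------------
# OBS
# ---------------------------------------------------------------------------

def obs_correct(rec: Recording, anchors: np.ndarray, n_pcs: int = 3,
                epoch_span: tuple[int, int] = None, channel_idx: np.ndarray | None = None,
                ) -> tuple[Recording, OBSBasis]:
    """Optimal-basis-set BCG correction.

    Per channel: stack the anchor-aligned epochs, compute their mean and the
    first ``n_pcs`` principal components, least-squares fit the basis
    ``[mean, PC_1..PC_K]`` to every epoch, and subtract the fit.  Epoch
    overlap is resolved by nearest-anchor ownership.  If the epoch matrix
    has rank < n_pcs + 1 the component count is reduced with a warning.
    With ``n_pcs = 0`` the fit reduces to a scaled mean template.
    """
    anchors = np.sort(np.asarray(anchors, dtype=int))
    if epoch_span is None:
        raise ValueError("epoch_span (pre, post) in samples is required")
    pre, post = int(epoch_span[0]), int(epoch_span[1])
    L = pre + post
    n = rec.n_samples
    ch = np.arange(rec.n_channels) if channel_idx is None else np.asarray(channel_idx)
    valid = _valid_anchors(anchors, pre, post, n)
    if valid.size < n_pcs + 2:
        raise ValueError(f"need at least n_pcs + 2 = {n_pcs + 2} full epochs, got {valid.size}")

    epochs = _stack_epochs(rec.data[ch], valid, pre, post)  # (nch, nv, L)
    means = epochs.mean(axis=1)  # (nch, L)
    demeaned = epochs - means[:, None, :]
    k_eff = n_pcs
    comps = np.zeros((ch.size, n_pcs, L))
    if n_pcs > 0:
        for c in range(ch.size):
            _, sv, vt = np.linalg.svd(demeaned[c], full_matrices=False)
            rank = int(np.sum(sv > sv[0] * 1e-10)) if sv.size else 0
            k_c = min(n_pcs, rank)
            if k_c < k_eff:
                k_eff = k_c
                log.warning("epoch matrix rank %d < n_pcs + 1; reducing to %d PCs", rank, k_c)
            comps[c, :k_c] = vt[:k_c]
        comps = comps[:, :k_eff]

    out = rec.copy()
    # least-squares fit of [mean, PCs] to each epoch, channel-wise
    fitted_by_anchor: dict[int, np.ndarray] = {}
    for a in anchors:
        start = a - pre
        lo, hi = max(start, 0), min(start + L, n)
        seg = np.zeros((ch.size, L))
        seg[:, lo - start:hi - start] = out.data[np.ix_(ch, np.arange(lo, hi))]
        fit = np.zeros((ch.size, L))
        for c in range(ch.size):
            basis = np.vstack([means[c][None, :], comps[c]]) if k_eff else means[c][None, :]
            coef, *_ = np.linalg.lstsq(basis.T, seg[c], rcond=None)
            fit[c] = basis.T @ coef
        fitted_by_anchor[a] = fit
    for a, start, stop in _ownership_bounds(anchors, pre, post, n):
        off = start - (a - pre)
        out.data[np.ix_(ch, np.arange(start, stop))] -= \
            fitted_by_anchor[a][:, off:off + (stop - start)]
    return out, OBSBasis(means, comps, k_eff)


# ---------------------------------------------------------------------------
# CWL regression
# ---------------------------------------------------------------------------

def cwl_regress(rec: Recording, cwl: np.ndarray | None = None,
                design: CWLDesign | None = None,
                channel_idx: np.ndarray | None = None) -> Recording:
    """Regress the six loop signals and their lagged copies out of each EEG
    channel, window by window.

    The recording is split into Hann-tapered windows of ``design.window_s``
    at 50% hop.  Within each window, the tapered EEG segment is regressed on
    the tapered lagged loop copies (plus an intercept) by ordinary least
    squares; the residual is tapered once and the windows are overlap-added
    with explicit weight normalization, so zero regressors reproduce the
    input exactly.  Rank deficiency falls back to the minimum-norm solution
    (logged).
    """
    design = design or CWLDesign()
    if cwl is None:
        cwl = rec.cwl()
        if cwl.size == 0:
            raise ValueError("recording has no CWL channels and none were supplied")
    cwl = np.atleast_2d(cwl)
    if cwl.shape[1] != rec.n_samples:
        raise ValueError("CWL signals must be sample-aligned with the recording")
    ch = rec.indices(SCALP) if channel_idx is None else np.asarray(channel_idx)
    n = rec.n_samples
    fs = rec.fs
    W = int(round(design.window_s * fs))
    W = min(W if W % 2 == 0 else W + 1, n if n % 2 == 0 else n - 1)
    W = max(W, 2)
    hop = W // 2
    taper = sps.get_window(design.taper, W, fftbins=True)
    L = int(round(design.max_lag_s * fs))
    lags = np.arange(-L, L + 1, design.lag_step)

    n_loops = cwl.shape[0]
    padded = np.pad(cwl, [(0, 0), (L, L)])
    y = rec.data[ch]  # (nch, n)
    acc = np.zeros_like(y)
    norm = np.zeros(n)
    # untapered residuals cover the zero-weight samples at the recording edges
    untap = np.zeros_like(y)
    filled = np.zeros(n, dtype=bool)

    starts = list(range(0, max(n - W, 0) + 1, hop))
    if starts and starts[-1] + W < n:
        starts.append(n - W)
    if not starts:
        starts = [0]
    for a in starts:
        b = min(a + W, n)
        m = b - a
        w = taper[:m].copy()
        # boundary windows get flat edges so that the first/last samples are
        # fully weighted in their only covering fit
        if a == starts[0]:
            w[:min(hop, m)] = 1.0
        if a == starts[-1]:
            w[max(m - hop, 0):] = 1.0
        cols = [padded[:, a + L + lag: a + L + lag + m] for lag in lags]
        X = np.concatenate(cols, axis=0).T  # (m, n_loops * n_lags)
        if design.include_intercept:
            X = np.concatenate([X, np.ones((m, 1))], axis=1)
        seg = y[:, a:b].T  # (m, nch)
        if X.shape[1] and np.any(X):
            Xw = X * w[:, None]
            G = Xw.T @ Xw
            # tiny ridge keeps near-collinear lag copies from producing
            # unbounded coefficients (and covers exact rank deficiency)
            lam = 1e-8 * np.trace(G) / G.shape[0]
            if lam <= 0:
                lam = 1e-12
            G[np.diag_indices_from(G)] += lam
            beta = np.linalg.solve(G, Xw.T @ (seg * w[:, None]))
            resid = seg - X @ beta
        else:
            resid = seg
        acc[:, a:b] += (resid * w[:, None]).T
        norm[a:b] += w
        new = ~filled[a:b]
        untap[:, a:b][:, new] = resid.T[:, new]
        filled[a:b] |= True
    nz = norm > 1e-12
    out = rec.copy()
    merged = np.where(nz[None, :], acc / np.maximum(norm, 1e-300), untap)
    out.data[ch] = merged
    return out


# ---------------------------------------------------------------------------
# variant composition
# ---------------------------------------------------------------------------

def run_variant(rec: Recording, markers: MarkerList, variant: str, *,
                n_windows_iar: int = 25, n_windows_bcg: int = 21, n_pcs: int = 3,
                bcg_delay_s: float = 0.21, bcg_span_s: tuple[float, float] = (0.25, 0.65),
                cwl_design: CWLDesign | None = None,
                rpeaks: np.ndarray | None = None) -> Recording:
    """Apply one of the evaluated pipeline variants.

    NC is the identity; IAR is AAS on the volume markers; AAS/OBS apply the
    respective BCG correction after IAR; CWL applies loop regression after
    IAR (the loops themselves are imaging-artifact-reduced first).
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; expected one of {VARIANTS}")
    if variant == "NC":
        return rec.copy()

    volumes = markers.samples_of("volume")
    if volumes.size == 0:
        raise ValueError(f"variant {variant} requires volume markers")
    iar, _ = aas_correct(rec, volumes, n_windows=min(n_windows_iar, volumes.size))
    if variant == "IAR":
        return iar

    if variant == "CWL":
        cwl_idx = rec.indices("cwl")
        if cwl_idx.size == 0:
            raise ValueError("variant CWL requires six carbon-wire-loop channels")
        return cwl_regress(iar, iar.data[cwl_idx], cwl_design)

    # BCG stage (AAS / OBS) needs R-peaks
    if rpeaks is None:
        marked = markers.samples_of("rpeak")
        if marked.size:
            rpeaks = marked
        else:
            ecg_idx = rec.indices("ecg")
            if ecg_idx.size == 0:
                raise ValueError(
                    f"variant {variant} requires an ECG channel or rpeak markers")
            rpeaks = detect_rpeaks(iar.data[ecg_idx[0]], rec.fs)
    if rpeaks is None or len(rpeaks) == 0:
        raise ValueError(f"variant {variant}: no R-peaks available")
    anchors = np.asarray(rpeaks, dtype=int) + int(round(bcg_delay_s * rec.fs))
    span = (int(round(bcg_span_s[0] * rec.fs)), int(round(bcg_span_s[1] * rec.fs)))
    scalp = rec.indices(SCALP)
    if variant == "AAS":
        nw = min(n_windows_bcg, len(anchors))
        out, _ = aas_correct(iar, anchors, n_windows=nw, epoch_span=span, channel_idx=scalp)
        return out
    out, _ = obs_correct(iar, anchors, n_pcs=n_pcs, epoch_span=span, channel_idx=scalp)
    return out
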