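"""Study orchestration: simulate -> correct -> extract -> fit -> report.

:func:`run_study` reproduces the evaluation structure of the comparison:
a cohort of simulated participants, the six data variants (REF plus
NC / IAR / AAS / OBS / CWL), task-matched feature extraction, hierarchical
model fits, and an :class:`EvaluationReport` with posterior summaries,
pairwise ordering probabilities, diagnostics and ground-truth error
metrics.

Simulated participants differ by seed-controlled draws of heart rate,
artifact amplitudes, and neural effect sizes, which populates the
between-participant level of the hierarchical models.  Default study sizes
(participants, block and trial counts, processing rate) are scaled to
desk-size runs; every knob is in :class:`StudyConfig`.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import features as ft
from .bayes import (ModelSpec, fit_effect_size_model, fit_single_level_model,
                    fit_two_level_model, posterior_probability, robust_correlation,
                    summarize_posterior)
from .core_io import MarkerList, Recording, SCALP, SessionConfig, log
from .correction import run_variant
from .processing import epoch_data, filter_lowpass, rereference_average, welch_psd
from .synthetic import ArtifactParams, GroundTruth, NeuralParams, assemble_session

SPECTRAL_ORDER = ["NC", "IAR", "OBS", "AAS", "CWL", "REF"]
TIME_DOMAIN_ORDER = ["IAR", "OBS", "AAS", "CWL", "REF"]  # NC excluded in time domain
MR_VARIANTS = ["NC", "IAR", "AAS", "OBS", "CWL"]


@dataclass
class StudyConfig:
    """Study-level settings (cohort size, task scales, sampler budget)."""

    seed: int = 0
    n_participants: int = 8
    tasks: tuple = ("resting",)
    fs_hz: float = 250.0
    tr_s: float = 1.1
    n_slices_per_tr: int = 16
    n_scalp: int = 32

    # resting
    block_s: float = 8.0
    n_block_pairs: int = 3
    # tapping
    n_taps: int = 8
    # checkerboard
    n_trials_per_condition: int = 6

    nperseg: int = 1024
    chains: int = 2
    warmup: int = 500
    draws: int = 500

    artifact_overrides: dict = field(default_factory=dict)
    neural_overrides: dict = field(default_factory=dict)


@dataclass
class EvaluationReport:
    """Nested result tables of one study run (JSON-serializable)."""

    data: dict

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.data, indent=1, sort_keys=True, default=_jsonify)
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text


def _jsonify(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON-serializable: {type(x)}")


# ---------------------------------------------------------------------------
# participant-level simulation
# ---------------------------------------------------------------------------

def _participant_params(cfg: StudyConfig, rng: np.random.Generator,
                        task: str) -> tuple[SessionConfig, ArtifactParams, NeuralParams]:
    """Draw one participant's session parameters around the study defaults."""
    jitter = lambda sd=0.1: float(np.exp(rng.normal(0.0, sd)))
    art = dict(
        slice_freq_hz=cfg.n_slices_per_tr / cfg.tr_s,
        volume_freq_hz=1.0 / cfg.tr_s,
        imaging_amp_uv=20000.0 * jitter(),
        # BCG amplitude varies strongly across people (anatomy, electrode
        # placement); this drives the between-participant level
        bcg_amp_uv=250.0 * jitter(0.25),
        pump_amp_uv=30.0 * jitter(),
        motion_amp_uv=40.0 * jitter(),
    )
    art.update(cfg.artifact_overrides)
    neu = dict(
        alpha_eo_uv=1.0 * jitter(),
        alpha_ec_uv=3.0 * jitter(),
        block_s=cfg.block_s,
        n_blocks=2 * cfg.n_block_pairs,
        n_taps=cfg.n_taps,
        n_trials_per_condition=cfg.n_trials_per_condition,
        vep_p1_uv=5.0 * jitter(),
        vep_n1_uv=-6.0 * jitter(),
    )
    neu.update(cfg.neural_overrides)
    if task == "resting":
        duration = cfg.block_s * 2 * cfg.n_block_pairs + 2.0
    elif task == "tapping":
        duration = 2.0 + cfg.n_taps * (3.0 + 7.0) + 2.0
    else:
        duration = 2.0 + cfg.n_trials_per_condition * 4 * (0.7 + 5.7) + 2.0
    session = SessionConfig(fs_hz=cfg.fs_hz, tr_s=cfg.tr_s,
                            n_slices_per_tr=cfg.n_slices_per_tr,
                            duration_s=float(duration), task=task,
                            seed=int(rng.integers(2**31 - 1)), n_scalp=cfg.n_scalp)
    return session, ArtifactParams(**art), NeuralParams(**neu)


def simulate_participant(cfg: StudyConfig, participant: int, task: str):
    """One participant's session plus all six data variants."""
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, participant]))
    session, art, neu = _participant_params(cfg, rng, task)
    rec, markers, gt = assemble_session(session, art, neu)
    variants: dict[str, Recording] = {}
    for v in MR_VARIANTS:
        variants[v] = run_variant(rec, markers, v, rpeaks=gt.rpeak_samples)
    variants["REF"] = gt.reference_recording(rec.channel_labels)
    return rec, markers, gt, variants


def _scalp_only(rec: Recording) -> Recording:
    idx = rec.indices(SCALP)
    return Recording(rec.data[idx].copy(), rec.fs,
                     [rec.channel_labels[i] for i in idx],
                     [SCALP] * idx.size, rec.reference)


def rms_error_vs_clean(variants: dict[str, Recording], gt: GroundTruth,
                       trim_s: float = 5.0) -> dict[str, float]:
    """RMS error of each variant against the clean neural signal (uV),
    averaged over scalp channels, edges trimmed."""
    n_scalp = gt.layout.n_channels
    clean = gt.neural[:n_scalp]
    a = int(trim_s * gt.fs)
    out = {}
    for name, rec in variants.items():
        d = rec.data[:n_scalp, a:clean.shape[1] - a] - clean[:, a:clean.shape[1] - a]
        out[name] = float(np.sqrt(np.mean(d**2)))
    return out


# ---------------------------------------------------------------------------
# resting-state analysis
# ---------------------------------------------------------------------------

def resting_features(variants: dict[str, Recording], gt: GroundTruth,
                     participant: int, nperseg: int) -> pd.DataFrame:
    """Per-block-pair alpha-band DeltaPSD (EC - EO, dB) on the summary channel.

    Summary channels are selected once per participant from the REF
    DeltaPSD topography (channels beyond one standard deviation).
    """
    events = gt.events
    rows = []
    per_channel: dict[str, list] = {}
    block_psd: dict[str, dict] = {}
    for name, rec in variants.items():
        sc = rereference_average(_scalp_only(rec))
        epochs = epoch_data(sc, events, 0.0, float(np.diff(sorted(
            events["sample"].iloc[:2]))[0] / rec.fs) if len(events) > 1 else 8.0)
        psds = [welch_psd(epochs.data[i], epochs.fs, nperseg,
                          channel_labels=epochs.channel_labels)
                for i in range(epochs.n_epochs)]
        block_psd[name] = {"psds": psds, "events": epochs.events, "labels": epochs.channel_labels}

    # summary-channel selection on REF
    ref = block_psd["REF"]
    alpha_by_block = np.array([ft.band_mean_power(p, ft.ALPHA) for p in ref["psds"]])
    is_ec = (ref["events"]["condition"] == "EC").to_numpy()
    topo = alpha_by_block[is_ec].mean(axis=0) - alpha_by_block[~is_ec].mean(axis=0)
    selected = ft.select_summary_channels(topo, ref["labels"], z_threshold=1.0)
    if not selected:
        z_order = np.argsort(-topo)
        selected = [ref["labels"][i] for i in z_order[:3]]
        log.warning("flat DeltaPSD topography; falling back to top-3 channels")

    for name, blk in block_psd.items():
        vals = np.array([ft.band_mean_power(ft.summary_channel_psd(p, selected), ft.ALPHA)[0]
                         for p in blk["psds"]])
        cond = blk["events"]["condition"].to_numpy()
        eo = vals[cond == "EO"]
        ec = vals[cond == "EC"]
        for k in range(min(eo.size, ec.size)):
            rows.append(dict(participant=participant, pair=k, variant=name,
                             dpsd=float(ec[k] - eo[k])))
    return pd.DataFrame(rows)


def _variant_design(table: pd.DataFrame, order: list[str], value_col: str):
    """One-hot variant design for the two-level model."""
    table = table[table["variant"].isin(order)]
    midx = table["variant"].map({v: i for i, v in enumerate(order)}).to_numpy()
    X = np.zeros((len(table), len(order)))
    X[np.arange(len(table)), midx] = 1.0
    pids = np.unique(table["participant"])
    pidx = table["participant"].map({p: i for i, p in enumerate(pids)}).to_numpy()
    y = table[value_col].to_numpy(dtype=float)
    return ModelSpec(y, X, pidx, midx), order


def fit_variant_model(table: pd.DataFrame, order: list[str], value_col: str,
                      cfg: StudyConfig, seed: int, direction: str = ">",
                      max_treedepth: int = 8) -> dict:
    """Fit the two-level model and summarize per-variant posteriors plus
    adjacent pairwise ordering probabilities."""
    spec, order = _variant_design(table, order, value_col)
    samples, diag = fit_two_level_model(spec, chains=cfg.chains, warmup=cfg.warmup,
                                        draws=cfg.draws, seed=seed,
                                        max_treedepth=max_treedepth)
    beta = samples.flat("beta")
    out = {"variants": {}, "pairwise": {}, "diagnostics": {
        "max_rhat": diag.max_rhat, "min_ess_bulk": diag.min_ess_bulk,
        "min_ess_tail": diag.min_ess_tail, "divergence_rate": diag.divergence_rate,
        "converged": bool(diag.converged)}}
    for i, v in enumerate(order):
        s = summarize_posterior(samples, "beta", index=i)
        s["p_gt_zero"] = float(np.mean(beta[:, i] > 0))
        s["p_lt_zero"] = float(np.mean(beta[:, i] < 0))
        out["variants"][v] = s
    for a, b in zip(order[:-1], order[1:]):
        ia, ib = order.index(a), order.index(b)
        out["pairwise"][f"{b}>{a}"] = float(np.mean(beta[:, ib] > beta[:, ia]))
    return out


# ---------------------------------------------------------------------------
# finger-tapping analysis
# ---------------------------------------------------------------------------

_TAP_BANDS = {
    "alpha": (ft.ALPHA, (-3.0, 0.0), (0.0, 3.0), -1),
    "beta": (ft.BETA, (-3.0, 0.0), (0.0, 3.0), -1),
    "gamma": (ft.GAMMA, (-1.0, 0.0), (0.0, 1.0), +1),
}


def tapping_features(variants: dict[str, Recording], gt: GroundTruth,
                     participant: int, nperseg: int) -> pd.DataFrame:
    """Per-trial DeltaPSD (tap minus baseline, dB) per band on band-specific
    summary channels selected from the REF topography (|z| > 2)."""
    events = gt.events[gt.events["condition"] == "tap"]
    rows = []
    epochs_by_variant = {}
    for name, rec in variants.items():
        sc = rereference_average(_scalp_only(rec))
        epochs_by_variant[name] = epoch_data(sc, events, -3.0, 3.0)

    for band_name, (band, base_win, resp_win, sign) in _TAP_BANDS.items():
        per_variant_dpsd = {}
        for name, epochs in epochs_by_variant.items():
            fs = epochs.fs
            t = epochs.times
            base = epochs.data[:, :, (t >= base_win[0]) & (t < base_win[1])]
            resp = epochs.data[:, :, (t >= resp_win[0]) & (t < resp_win[1])]
            nseg = min(nperseg, base.shape[2])
            d = []
            for i in range(epochs.n_epochs):
                p_b = welch_psd(base[i], fs, nseg, channel_labels=epochs.channel_labels)
                p_r = welch_psd(resp[i], fs, nseg, channel_labels=epochs.channel_labels)
                d.append(ft.band_mean_power(p_r, band) - ft.band_mean_power(p_b, band))
            per_variant_dpsd[name] = (np.array(d), epochs.channel_labels)
        dpsd_ref, labels = per_variant_dpsd["REF"]
        topo = dpsd_ref.mean(axis=0)
        selected = ft.select_summary_channels(topo, labels, z_threshold=2.0, sign=sign)
        if not selected:
            z_order = np.argsort(-sign * topo)
            selected = [labels[i] for i in z_order[:3]]
        sel_idx = [labels.index(l) for l in selected]
        for name, (dpsd, _) in per_variant_dpsd.items():
            for k, v in enumerate(dpsd[:, sel_idx].mean(axis=1)):
                rows.append(dict(participant=participant, trial=k, band=band_name,
                                 variant=name, dpsd=float(v)))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# VEP analysis
# ---------------------------------------------------------------------------

def vep_features(variants: dict[str, Recording], gt: GroundTruth,
                 participant: int) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Trial-level VEP features for the time-domain analyses.

    Returns (amplitude rows, SNR rows, participant-average waves).
    Amplitude rows carry the D1/D2 window means of the hemisphere summary
    channels, one contralateral and one ipsilateral row per trial.
    """
    events = gt.events
    hemi = gt.layout.hemisphere_map()
    amp_rows, snr_rows = [], []
    waves: dict[str, dict] = {}
    for name, rec in variants.items():
        if name == "NC":
            continue  # meaningless in the time domain
        sc = rereference_average(_scalp_only(rec))
        sc = filter_lowpass(sc, 30.0)
        epochs = epoch_data(sc, events, -0.2, 0.5)
        t0 = epochs.tmin
        fs = epochs.fs
        # baseline correction per epoch
        base_mask = epochs.times < 0
        data = epochs.data - epochs.data[:, :, base_mask].mean(axis=2, keepdims=True)
        idx = {side: [epochs.channel_labels.index(l) for l in hemi[side]]
               for side in ("left", "right")}
        conds = epochs.events["condition"].to_numpy()
        left_field = np.char.startswith(conds.astype(str), "L")
        for i in range(epochs.n_epochs):
            contra_side = "right" if left_field[i] else "left"
            ipsi_side = "left" if left_field[i] else "right"
            for side_label, side, is_contra in ((contra_side, "contra", 1),
                                                (ipsi_side, "ipsi", 0)):
                seg = data[i, idx[side_label]].mean(axis=0)
                for win in ("D1", "D2"):
                    amp_rows.append(dict(
                        participant=participant, trial=i, variant=name, window=win,
                        side=side, contra=is_contra,
                        amplitude=ft.window_mean_amplitude(
                            seg, ft.VEP_WINDOWS[win], fs, t0)))
            # SNR on the pooled posterior summary channel
            seg_all = data[i, idx["left"] + idx["right"]].mean(axis=0)
            for peak in ("P1", "N1"):
                snr_rows.append(dict(
                    participant=participant, trial=i, variant=name, peak=peak,
                    level="trial",
                    snr=ft.snr_rms(seg_all, ft.VEP_WINDOWS[peak],
                                   ft.VEP_WINDOWS["baseline"], fs, t0)))
        # participant-average waves per condition, and average-level SNR
        waves[name] = {}
        for cond in ("LU", "LL", "RU", "RL"):
            sel = conds == cond
            if not sel.any():
                continue
            pool = idx["right"] if cond.startswith("L") else idx["left"]
            avg = data[sel][:, pool].mean(axis=(0, 1))
            waves[name][cond] = avg[epochs.times >= 0.0]
        erp = data[:, idx["left"] + idx["right"]].mean(axis=(0, 1))
        for peak in ("P1", "N1"):
            snr_rows.append(dict(
                participant=participant, trial=-1, variant=name, peak=peak,
                level="average",
                snr=ft.snr_rms(erp, ft.VEP_WINDOWS[peak],
                               ft.VEP_WINDOWS["baseline"], fs, t0)))
    return pd.DataFrame(amp_rows), pd.DataFrame(snr_rows), waves


def fit_vep_effect_sizes(amp_table: pd.DataFrame, window: str, cfg: StudyConfig,
                         seed: int) -> dict:
    """Within-participant effect sizes of the contra-ipsi difference."""
    table = amp_table[amp_table["window"] == window]
    order = [v for v in TIME_DOMAIN_ORDER if v in set(table["variant"])]
    M = len(order)
    midx = table["variant"].map({v: i for i, v in enumerate(order)}).to_numpy()
    contra = table["contra"].to_numpy(dtype=float)
    X = np.zeros((len(table), 2 * M))
    X[np.arange(len(table)), midx] = 1.0
    X[np.arange(len(table)), M + midx] = contra
    pids = np.unique(table["participant"])
    pidx = table["participant"].map({p: i for i, p in enumerate(pids)}).to_numpy()
    spec = ModelSpec(table["amplitude"].to_numpy(dtype=float), X, pidx, midx,
                     "per_method_per_participant_pooled")
    samples, diag = fit_effect_size_model(
        spec, effect_cols=np.arange(M, 2 * M), chains=cfg.chains,
        warmup=cfg.warmup, draws=cfg.draws, seed=seed, max_treedepth=7)
    es = samples.flat("effect_size")
    out = {"variants": {}, "pairwise": {}, "diagnostics": {
        "max_rhat": diag.max_rhat, "converged": bool(diag.converged)}}
    for i, v in enumerate(order):
        s = summarize_posterior(samples, "effect_size", index=i)
        out["variants"][v] = s
    for a, b in zip(order[:-1], order[1:]):
        ia, ib = order.index(a), order.index(b)
        out["pairwise"][f"{b}>{a}"] = float(np.mean(es[:, ib] > es[:, ia]))
    return out


def fit_snr_models(snr_table: pd.DataFrame, cfg: StudyConfig, seed: int) -> dict:
    """Trial-level SNR via the two-level model (log scale), average-level SNR
    via single-level regression; medians back-transformed to ratio units."""
    out = {}
    for peak in ("P1", "N1"):
        sub = snr_table[(snr_table["peak"] == peak) & (snr_table["level"] == "trial")].copy()
        sub["log_snr"] = np.log(sub["snr"])
        res = fit_variant_model(sub, [v for v in TIME_DOMAIN_ORDER
                                      if v in set(sub["variant"])], "log_snr",
                                cfg, seed, max_treedepth=7)
        for v, s in res["variants"].items():
            s["median_snr"] = float(np.exp(s["median"]))
        out[f"trial_{peak}"] = res

        avg = snr_table[(snr_table["peak"] == peak) & (snr_table["level"] == "average")]
        order = [v for v in TIME_DOMAIN_ORDER if v in set(avg["variant"])]
        midx = avg["variant"].map({v: i for i, v in enumerate(order)}).to_numpy()
        X = np.zeros((len(avg), len(order)))
        X[np.arange(len(avg)), midx] = 1.0
        y = np.log(avg["snr"].to_numpy(dtype=float))
        if len(avg) > len(order):
            samples, diag = fit_single_level_model(y, X, chains=cfg.chains,
                                                   warmup=cfg.warmup, draws=cfg.draws,
                                                   seed=seed + 7)
            entry = {"variants": {}, "diagnostics": {"max_rhat": diag.max_rhat,
                                                     "converged": bool(diag.converged)}}
            for i, v in enumerate(order):
                s = summarize_posterior(samples, "beta", index=i)
                s["median_snr"] = float(np.exp(s["median"]))
                entry["variants"][v] = s
            out[f"average_{peak}"] = entry
    return out


def vep_similarity(waves_by_participant: list[dict], cfg: StudyConfig, seed: int) -> dict:
    """Robust correlation and RMSD of each variant's grand-average VEP
    against REF, per stimulus condition."""
    out = {}
    # grand averages across participants
    grand: dict[str, dict[str, np.ndarray]] = {}
    for waves in waves_by_participant:
        for variant, conds in waves.items():
            for cond, w in conds.items():
                grand.setdefault(variant, {}).setdefault(cond, []).append(w)
    for variant in grand:
        for cond in grand[variant]:
            n = min(len(w) for w in grand[variant][cond])
            grand[variant][cond] = np.mean([w[:n] for w in grand[variant][cond]], axis=0)
    ref = grand.get("REF", {})
    for variant, conds in grand.items():
        if variant == "REF":
            continue
        out[variant] = {}
        for cond, w in conds.items():
            if cond not in ref:
                continue
            n = min(w.size, ref[cond].size)
            # the low-passed waves are heavily oversampled; thin them so the
            # iid bivariate-t likelihood is not artificially overconfident
            step = max(1, n // 40)
            a_w, b_w = ref[cond][:n:step], w[:n:step]
            samples, diag = robust_correlation(a_w, b_w, chains=2,
                                               warmup=min(300, cfg.warmup),
                                               draws=min(300, cfg.draws), seed=seed,
                                               max_treedepth=7)
            out[variant][cond] = {
                "correlation_median": float(np.median(samples.flat("rho"))),
                "rmsd": ft.rmsd(ref[cond][:n], w[:n]),
                "diagnostics": {"max_rhat": diag.max_rhat,
                                "converged": bool(diag.converged)},
            }
    return out


# ---------------------------------------------------------------------------
# study driver
# ---------------------------------------------------------------------------

def run_study(cfg: StudyConfig) -> EvaluationReport:
    """Run the full simulated evaluation for the tasks in ``cfg.tasks``."""
    report: dict = {"config": asdict(cfg), "ground_truth_rms": {}}
    for task in cfg.tasks:
        log.info("task %s: simulating %d participants", task, cfg.n_participants)
        rms_acc: dict[str, list] = {}
        rest_rows, tap_rows = [], []
        amp_rows, snr_rows, waves_all = [], [], []
        for participant in range(cfg.n_participants):
            _, _, gt, variants = simulate_participant(cfg, participant, task)
            for name, err in rms_error_vs_clean(variants, gt, trim_s=3.0).items():
                rms_acc.setdefault(name, []).append(err)
            if task == "resting":
                rest_rows.append(resting_features(variants, gt, participant, cfg.nperseg))
            elif task == "tapping":
                tap_rows.append(tapping_features(variants, gt, participant, cfg.nperseg))
            else:
                a, s, w = vep_features(variants, gt, participant)
                amp_rows.append(a)
                snr_rows.append(s)
                waves_all.append(w)
        report["ground_truth_rms"][task] = {k: float(np.mean(v))
                                            for k, v in rms_acc.items()}
        if task == "resting":
            table = pd.concat(rest_rows, ignore_index=True)
            report["resting_alpha"] = fit_variant_model(
                table, SPECTRAL_ORDER, "dpsd", cfg, cfg.seed + 11)
            report["resting_alpha"]["features_n"] = len(table)
        elif task == "tapping":
            table = pd.concat(tap_rows, ignore_index=True)
            report["tapping"] = {}
            for band in _TAP_BANDS:
                sub = table[table["band"] == band]
                report["tapping"][band] = fit_variant_model(
                    sub, SPECTRAL_ORDER, "dpsd", cfg, cfg.seed + 23)
        else:
            amp = pd.concat(amp_rows, ignore_index=True)
            snr = pd.concat(snr_rows, ignore_index=True)
            report["vep_effect_size"] = {
                win: fit_vep_effect_sizes(amp, win, cfg, cfg.seed + 31)
                for win in ("D1", "D2")}
            report["vep_snr"] = fit_snr_models(snr, cfg, cfg.seed + 41)
            report["vep_similarity"] = vep_similarity(waves_all, cfg, cfg.seed + 51)
    return EvaluationReport(report)
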