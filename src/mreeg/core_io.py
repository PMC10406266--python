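"""Data model and BrainVision-format I/O.

The in-memory containers used throughout the package are :class:`Recording`
(a channels x samples matrix in microvolts with per-channel roles) and
:class:`MarkerList` (a typed, sample-resolved event stream).  Recordings are
persisted as BrainVision triplets -- an INI-style ``.vhdr`` header, a
``.vmrk`` marker file and a multiplexed IEEE float32 little-endian ``.eeg``
binary -- plus a small JSON sidecar carrying metadata the BrainVision header
has no field for (channel roles, marker kinds, reference state).

Conventions: sample indexing is 0-based and time windows are half-open
``[start, stop)`` everywhere inside the package; BrainVision ``.vmrk``
positions are 1-based and are converted on read/write.  Amplitudes are
microvolts everywhere.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml

log = logging.getLogger("mreeg")

SCALP = "scalp"
CWL = "cwl"
ECG = "ecg"
ROLES = (SCALP, CWL, ECG)

MARKER_KINDS = ("volume", "slice", "rpeak", "stimulus", "block")

#: default scanner-trigger description for volume (TR) markers
DEFAULT_VOLUME_LABEL = "R128"

# BrainVision marker *type* field used when writing each kind
_KIND_TO_BV_TYPE = {
    "volume": "Response",
    "slice": "Response",
    "rpeak": "Response",
    "stimulus": "Stimulus",
    "block": "Comment",
}


def configure_logging(level: int | str = logging.INFO) -> None:
    """Attach a line-oriented stream handler to the package logger."""
    handler = logging.StreamHandler()
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s"))
    log.handlers[:] = [handler]
    log.setLevel(level)


@dataclass
class Marker:
    kind: str  # one of MARKER_KINDS
    label: str
    sample: int  # 0-based


@dataclass
class MarkerList:
    """Ordered event stream at sample resolution."""

    entries: list[Marker] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def add(self, kind: str, label: str, sample: int) -> None:
        if kind not in MARKER_KINDS:
            raise ValueError(f"unknown marker kind {kind!r}")
        self.entries.append(Marker(kind, label, int(sample)))

    def sort(self) -> "MarkerList":
        self.entries.sort(key=lambda m: m.sample)
        return self

    def of_kind(self, kind: str) -> list[Marker]:
        return [m for m in self.entries if m.kind == kind]

    def samples_of(self, kind: str) -> np.ndarray:
        return np.array([m.sample for m in self.entries if m.kind == kind], dtype=int)

    def rescaled(self, ratio: float) -> "MarkerList":
        """Markers with sample indices scaled by ``ratio`` (rounded to nearest)."""
        return MarkerList([Marker(m.kind, m.label, int(round(m.sample * ratio))) for m in self.entries])


@dataclass
class Recording:
    """Multichannel EEG recording in microvolts.

    ``data`` has one row per channel; ``channel_roles`` assigns each row one
    of ``{"scalp", "cwl", "ecg"}``.  ``reference`` names the reference
    channel, or is ``"average"`` after average re-referencing.
    """

    data: np.ndarray  # (n_channels, n_samples) float, microvolts
    fs: float
    channel_labels: list[str]
    channel_roles: list[str]
    reference: str = "none"

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def indices(self, role: str) -> np.ndarray:
        return np.array([i for i, r in enumerate(self.channel_roles) if r == role], dtype=int)

    def scalp(self) -> np.ndarray:
        return self.data[self.indices(SCALP)]

    def cwl(self) -> np.ndarray:
        return self.data[self.indices(CWL)]

    def ecg(self) -> np.ndarray:
        idx = self.indices(ECG)
        return self.data[idx[0]] if idx.size else np.zeros(0)

    def copy(self) -> "Recording":
        return Recording(self.data.copy(), self.fs, list(self.channel_labels),
                         list(self.channel_roles), self.reference)

    def pick(self, labels: Sequence[str]) -> "Recording":
        idx = [self.channel_labels.index(l) for l in labels]
        return Recording(self.data[idx].copy(), self.fs, [self.channel_labels[i] for i in idx],
                         [self.channel_roles[i] for i in idx], self.reference)


def validate_recording(rec: Recording) -> list[str]:
    """Return a list of invariant violations (empty iff the recording is valid).

    Reports, never raises.
    """
    violations: list[str] = []
    if rec.fs <= 0:
        violations.append(f"sampling rate must be positive, got {rec.fs}")
    if rec.data.ndim != 2:
        violations.append(f"data must be 2-D (channels x samples), got ndim={rec.data.ndim}")
        return violations
    if rec.data.shape[0] != len(rec.channel_labels):
        violations.append(
            f"data has {rec.data.shape[0]} rows but {len(rec.channel_labels)} channel labels")
    if len(rec.channel_labels) != len(rec.channel_roles):
        violations.append("channel_labels and channel_roles lengths differ")
    seen: set[str] = set()
    for lab in rec.channel_labels:
        if lab in seen:
            violations.append(f"duplicate channel label {lab!r}")
        seen.add(lab)
    for role in set(rec.channel_roles):
        if role not in ROLES:
            violations.append(f"unknown channel role {role!r}")
    n_cwl = sum(r == CWL for r in rec.channel_roles)
    if n_cwl not in (0, 6):
        violations.append(f"cwl channel count must be 0 or 6, got {n_cwl}")
    n_ecg = sum(r == ECG for r in rec.channel_roles)
    if n_ecg not in (0, 1):
        violations.append(f"ecg channel count must be 0 or 1, got {n_ecg}")
    if not np.all(np.isfinite(rec.data)):
        violations.append("data contains non-finite values")
    return violations


def validate_markers(markers: MarkerList, n_samples: int) -> list[str]:
    violations = []
    prev = -1
    prev_vol = -1
    for m in markers:
        if m.sample < prev:
            violations.append("markers not sorted by sample")
            break
        prev = m.sample
    for m in markers:
        if not (0 <= m.sample < n_samples):
            violations.append(f"marker at sample {m.sample} outside recording of {n_samples} samples")
        if m.kind == "volume":
            if m.sample <= prev_vol:
                violations.append("volume markers not strictly increasing")
            prev_vol = m.sample
    return violations


# ---------------------------------------------------------------------------
# BrainVision writing
# ---------------------------------------------------------------------------

def write_brainvision(rec: Recording, markers: MarkerList, path: str | Path,
                      basename: str = "recording",
                      volume_label: str = DEFAULT_VOLUME_LABEL) -> Path:
    """Write a BrainVision triplet (+ JSON sidecar) and return the header path.

    Data are stored as multiplexed IEEE float32 little-endian with unit
    resolution, so values round-trip exactly up to float32 quantization.
    Marker sample indices round-trip exactly (converted to the 1-based
    convention of ``.vmrk`` on write and back on read).
    """
    violations = validate_recording(rec)
    if violations:
        raise ValueError("invalid recording: " + "; ".join(violations))
    path = Path(path)
    try:
        path.mkdir(parents=True, exist_ok=True)
    except OSError as e:  # unwritable target
        raise IOError(f"cannot create output directory {path}: {e}") from e

    markers = MarkerList(sorted(markers.entries, key=lambda m: m.sample))
    vhdr = path / f"{basename}.vhdr"
    vmrk = path / f"{basename}.vmrk"
    eeg = path / f"{basename}.eeg"
    sidecar = path / f"{basename}.roles.json"

    # header -----------------------------------------------------------------
    lines = [
        "Brain Vision Data Exchange Header File Version 1.0",
        "; Written by mreeg",
        "",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={eeg.name}",
        f"MarkerFile={vmrk.name}",
        "DataFormat=BINARY",
        "DataOrientation=MULTIPLEXED",
        f"NumberOfChannels={rec.n_channels}",
        f"DataPoints={rec.n_samples}",
        # sampling interval in microseconds
        f"SamplingInterval={1e6 / rec.fs:.10g}",
        "",
        "[Binary Infos]",
        "BinaryFormat=IEEE_FLOAT_32",
        "",
        "[Channel Infos]",
        "; Each entry: Ch<n>=<Name>,<RefName>,<Resolution in \"Unit\">,<Unit>",
    ]
    for i, lab in enumerate(rec.channel_labels, start=1):
        lines.append(f"Ch{i}={lab},,1,µV")
    vhdr.write_text("\n".join(lines) + "\n", encoding="utf-8")

    # markers ----------------------------------------------------------------
    mlines = [
        "Brain Vision Data Exchange Marker File, Version 1.0",
        "",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={eeg.name}",
        "",
        "[Marker Infos]",
        "; Each entry: Mk<n>=<Type>,<Description>,<Position>,<Size>,<ChNr>",
        "Mk1=New Segment,,1,1,0",
    ]
    for i, m in enumerate(markers, start=2):
        bv_type = _KIND_TO_BV_TYPE.get(m.kind, "Comment")
        # .vmrk positions are 1-based
        mlines.append(f"Mk{i}={bv_type},{m.label},{m.sample + 1},1,0")
    vmrk.write_text("\n".join(mlines) + "\n", encoding="utf-8")

    # binary -----------------------------------------------------------------
    arr = np.asarray(rec.data, dtype="<f4").T  # (samples, channels) multiplexed
    arr.tofile(eeg)

    sidecar.write_text(json.dumps({
        "channel_roles": rec.channel_roles,
        "reference": rec.reference,
        "marker_kinds": [m.kind for m in markers],
        "volume_label": volume_label,
    }, indent=1), encoding="utf-8")
    return vhdr


# ---------------------------------------------------------------------------
# BrainVision reading
# ---------------------------------------------------------------------------

def _parse_ini(text: str) -> dict[str, dict[str, str]]:
    """Parse the INI-like BrainVision header into {section: {key: value}}."""
    sections: dict[str, dict[str, str]] = {}
    current: dict[str, str] | None = None
    for raw in text.splitlines():
        line = raw.strip()
        if not line or line.startswith(";"):
            continue
        if line.startswith("[") and line.endswith("]"):
            current = sections.setdefault(line[1:-1], {})
        elif "=" in line and current is not None:
            key, _, value = line.partition("=")
            current[key.strip()] = value.strip()
    return sections


def read_brainvision(header_path: str | Path,
                     volume_label: str | None = None) -> tuple[Recording, MarkerList]:
    """Read a BrainVision triplet; returns data scaled to microvolts and
    markers at 0-based sample indices.

    If the JSON sidecar written by :func:`write_brainvision` is present,
    channel roles and marker kinds are recovered from it; otherwise roles
    default to ``scalp`` and marker kinds are inferred from the BrainVision
    type field (``Response`` markers whose description equals the volume
    label become volume markers).
    """
    header_path = Path(header_path)
    if not header_path.exists():
        raise IOError(f"missing header file {header_path}")
    sections = _parse_ini(header_path.read_text(encoding="utf-8"))
    common = sections.get("Common Infos", {})
    binary = sections.get("Binary Infos", {})

    fmt = binary.get("BinaryFormat", "IEEE_FLOAT_32")
    if fmt != "IEEE_FLOAT_32":
        raise ValueError(f"unsupported binary format {fmt!r} (only IEEE_FLOAT_32)")
    if common.get("DataFormat", "BINARY") != "BINARY":
        raise ValueError("unsupported DataFormat (only BINARY)")
    if common.get("DataOrientation", "MULTIPLEXED") != "MULTIPLEXED":
        raise ValueError("unsupported DataOrientation (only MULTIPLEXED)")

    n_channels = int(common["NumberOfChannels"])
    fs = 1e6 / float(common["SamplingInterval"])

    chans = sections.get("Channel Infos", {})
    labels: list[str] = []
    resolutions = np.ones(n_channels)
    for i in range(1, n_channels + 1):
        entry = chans.get(f"Ch{i}")
        if entry is None:
            raise ValueError(f"header declares {n_channels} channels but Ch{i} is missing")
        parts = entry.split(",")
        labels.append(parts[0])
        if len(parts) > 2 and parts[2]:
            resolutions[i - 1] = float(parts[2])

    eeg_path = header_path.parent / common["DataFile"]
    vmrk_path = header_path.parent / common["MarkerFile"]
    if not eeg_path.exists():
        raise IOError(f"missing data file {eeg_path}")
    if not vmrk_path.exists():
        raise IOError(f"missing marker file {vmrk_path}")

    raw = np.fromfile(eeg_path, dtype="<f4")
    if raw.size % n_channels != 0:
        raise ValueError(
            f"binary stream of {raw.size} values is not a multiple of {n_channels} channels")
    data = raw.reshape(-1, n_channels).T.astype(np.float64)
    data *= resolutions[:, None]  # scale to microvolts

    # sidecar metadata -------------------------------------------------------
    sidecar = header_path.with_suffix(".roles.json")
    roles = [SCALP] * n_channels
    reference = "none"
    sidecar_kinds: list[str] | None = None
    if sidecar.exists():
        meta = json.loads(sidecar.read_text(encoding="utf-8"))
        roles = meta.get("channel_roles", roles)
        reference = meta.get("reference", reference)
        sidecar_kinds = meta.get("marker_kinds")
        if volume_label is None:
            volume_label = meta.get("volume_label", DEFAULT_VOLUME_LABEL)
    if volume_label is None:
        volume_label = DEFAULT_VOLUME_LABEL

    # markers ----------------------------------------------------------------
    msections = _parse_ini(vmrk_path.read_text(encoding="utf-8"))
    markers = MarkerList()
    infos = msections.get("Marker Infos", {})
    idx = 0
    for key in sorted(infos, key=lambda k: int(k[2:])):
        parts = infos[key].split(",")
        bv_type, desc = parts[0], parts[1] if len(parts) > 1 else ""
        if bv_type == "New Segment":
            continue
        sample = int(parts[2]) - 1  # to 0-based
        if sidecar_kinds is not None and idx < len(sidecar_kinds):
            kind = sidecar_kinds[idx]
        elif bv_type == "Response" and desc == volume_label:
            kind = "volume"
        elif bv_type == "Stimulus":
            kind = "stimulus"
        elif bv_type == "Comment":
            kind = "block"
        else:
            kind = "stimulus"
        markers.add(kind, desc, sample)
        idx += 1

    rec = Recording(data, fs, labels, roles, reference)
    return rec, markers


# ---------------------------------------------------------------------------
# Session configuration
# ---------------------------------------------------------------------------

@dataclass
class SessionConfig:
    """Parameters of one simulated EEG-fMRI session.

    The artifact and neural parameter blocks live in
    :mod:`mreeg.synthetic`; this container only fixes the acquisition frame
    (sampling rate, TR, duration, task) and the seed that pins all
    downstream randomness.
    """

    fs_hz: float = 5000.0
    tr_s: float = 1.1
    n_slices_per_tr: int = 16  # effective slice events per TR (64 slices / MB 4)
    duration_s: float = 60.0
    task: str = "resting"
    seed: int = 0
    n_scalp: int = 32
    artifact: dict = field(default_factory=dict)  # overrides for ArtifactParams
    neural: dict = field(default_factory=dict)  # overrides for NeuralParams

    def __post_init__(self) -> None:
        if self.tr_s <= 0:
            raise ValueError("tr_s must be positive")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.task not in ("resting", "tapping", "checkerboard"):
            raise ValueError(f"unknown task {self.task!r}")

    @property
    def slice_freq_hz(self) -> float:
        return self.n_slices_per_tr / self.tr_s

    @property
    def volume_freq_hz(self) -> float:
        return 1.0 / self.tr_s

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.__dict__, sort_keys=False), encoding="utf-8")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SessionConfig":
        return cls(**yaml.safe_load(Path(path).read_text(encoding="utf-8")))
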