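"""Containers, file formats and pipeline configuration.

The native on-disk recording format is a raw little-endian float32 array
(channel-major) next to a JSON sidecar carrying the sampling rate, channel
labels and event markers.  EDF files are read through :mod:`mne`.
Connectivity tensors (trials x pairs x latencies) go to HDF5 via h5py.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

logger = logging.getLogger("plvdecode")

NATIVE_ARRAY_SUFFIX = ".f32"
NATIVE_SIDECAR_SUFFIX = ".json"


class ConfigurationError(ValueError):
    """Raised when a configuration or schedule entry is invalid."""


@dataclass(frozen=True)
class Event:
    """An event marker: onset in seconds plus a class label."""

    onset: float
    label: str


@dataclass
class Recording:
    """A continuous multichannel recording.

    data : float array, shape (n_channels, n_samples)
    fs : sampling frequency in Hz
    labels : channel names (10-10 montage names for the study design)
    events : cue onsets with class labels ("left" / "right")
    """

    data: np.ndarray
    fs: float
    labels: list[str]
    events: list[Event] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if len(self.labels) != self.data.shape[0]:
            raise ValueError("one label per channel required")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs


# ---------------------------------------------------------------------------
# native format


def _native_paths(path: str | Path) -> tuple[Path, Path]:
    base = Path(path)
    if base.suffix in (NATIVE_ARRAY_SUFFIX, NATIVE_SIDECAR_SUFFIX):
        base = base.with_suffix("")
    return (
        base.with_suffix(NATIVE_ARRAY_SUFFIX),
        base.with_suffix(NATIVE_SIDECAR_SUFFIX),
    )


def write_native(recording: Recording, path: str | Path) -> Path:
    """Write a recording as raw little-endian float32 plus a JSON sidecar.

    Returns the path of the array file; the sidecar sits next to it.
    """
    arr_path, sidecar_path = _native_paths(path)
    data = np.ascontiguousarray(recording.data, dtype="<f4")
    arr_path.parent.mkdir(parents=True, exist_ok=True)
    data.tofile(arr_path)
    sidecar = {
        "format": "plvdecode-native",
        "version": 1,
        "fs": recording.fs,
        "labels": list(recording.labels),
        "shape": list(data.shape),
        "dtype": "<f4",
        "events": [{"onset": e.onset, "label": e.label} for e in recording.events],
        "meta": recording.meta,
    }
    sidecar_path.write_text(json.dumps(sidecar, indent=1))
    return arr_path


def read_native(path: str | Path) -> Recording:
    arr_path, sidecar_path = _native_paths(path)
    if not sidecar_path.exists():
        raise FileNotFoundError(f"missing events/metadata sidecar: {sidecar_path}")
    if not arr_path.exists():
        raise FileNotFoundError(f"missing array file: {arr_path}")
    try:
        sidecar = json.loads(sidecar_path.read_text())
        shape = tuple(sidecar["shape"])
        fs = float(sidecar["fs"])
        labels = list(sidecar["labels"])
        events = [Event(float(e["onset"]), str(e["label"])) for e in sidecar["events"]]
    except (KeyError, TypeError, json.JSONDecodeError) as exc:
        raise ValueError(f"malformed native sidecar {sidecar_path}: {exc}") from exc
    data = np.fromfile(arr_path, dtype=sidecar.get("dtype", "<f4")).reshape(shape)
    if len(labels) != shape[0]:
        raise ValueError(
            f"malformed native sidecar {sidecar_path}: "
            f"{len(labels)} labels for {shape[0]} channels"
        )
    return Recording(data=data, fs=fs, labels=labels, events=events,
                     meta=sidecar.get("meta", {}))


def _read_edf(path: str | Path) -> Recording:
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data()
    events = []
    for onset, _dur, desc in zip(raw.annotations.onset, raw.annotations.duration,
                                 raw.annotations.description):
        events.append(Event(float(onset), str(desc)))
    return Recording(data=data, fs=float(raw.info["sfreq"]),
                     labels=list(raw.ch_names), events=events)


def read_recording(path: str | Path, fmt: str = "auto") -> Recording:
    """Load a recording from EDF or the native array+sidecar format."""
    path = Path(path)
    if fmt == "auto":
        fmt = "edf" if path.suffix.lower() == ".edf" else "native"
    if fmt == "edf":
        return _read_edf(path)
    if fmt == "native":
        return read_native(path)
    raise ValueError(f"unknown format {fmt!r} (expected 'edf' or 'native')")


# ---------------------------------------------------------------------------
# connectivity tensors


def save_sequences(path: str | Path, vecs: np.ndarray, **attrs) -> None:
    """Store a (trials x pairs x latencies) tensor with its metadata."""
    import h5py

    with h5py.File(path, "w") as h5:
        ds = h5.create_dataset("sequences", data=np.asarray(vecs))
        for key, value in attrs.items():
            ds.attrs[key] = value


def load_sequences(path: str | Path) -> tuple[np.ndarray, dict]:
    import h5py

    with h5py.File(path, "r") as h5:
        ds = h5["sequences"]
        return np.asarray(ds), dict(ds.attrs)


# ---------------------------------------------------------------------------
# pipeline configuration


@dataclass
class PipelineConfig:
    """Printed parameters of the decoding pipeline, with study defaults.

    step_cued / step_stream : stepping-window advance in s for cued decoding
        (350 ms) and for streaming/self-paced operation (20 ms).
    cycles : cycle criterion; the window spans this many cycles of the band's
        lowest frequency.
    k_static : number of couplings kept by static feature screening.
    n_rand / n_boot : label permutations for the score threshold / bootstrap
        resamples for the consistency profile.
    segment_width / switch_threshold : readout-segment width in s and the
        detection confidence threshold of the switch.
    n_splits : Monte-Carlo cross-validation splits for self-paced evaluation.
    """

    band: str = "alpha1"
    step_cued: float = 0.35
    step_stream: float = 0.02
    cycles: int = 3
    k_static: int = 10
    n_rand: int = 100
    n_boot: int = 30
    segment_width: float = 0.5
    switch_threshold: float = 0.5
    n_splits: int = 100
    seed: int = 0

    def validate(self, fs: float | None = None) -> None:
        from .preprocess import BANDS

        if self.band not in BANDS:
            raise ConfigurationError(f"unknown band {self.band!r}")
        for name in ("step_cued", "step_stream", "cycles", "k_static", "n_rand",
                     "n_boot", "segment_width", "n_splits"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if not 0.0 < self.switch_threshold < 1.0:
            raise ConfigurationError("switch_threshold must lie in (0, 1)")
        if fs is not None:
            low, high = BANDS[self.band]
            if high >= fs / 2:
                raise ConfigurationError(
                    f"band edge {high} Hz is at or above the Nyquist "
                    f"frequency {fs / 2} Hz"
                )

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        return cls(**json.loads(text))

    def config_hash(self) -> str:
        """Short stable digest identifying this parameterization."""
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:12]


def write_report(path: str | Path, payload: dict, config: PipelineConfig) -> None:
    """Write a JSON artifact stamped with the config hash and seed."""
    out = dict(payload)
    out["config_hash"] = config.config_hash()
    out["seed"] = config.seed
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(out, indent=1, sort_keys=True))
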