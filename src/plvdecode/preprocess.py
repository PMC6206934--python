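"""Band-limited filtering, epoching and average re-referencing.

The seven canonical EEG rhythms are isolated with third-order Butterworth
band-pass filters applied forward-backward (zero-phase) on the *continuous*
recording, before epoching, so filter transients never touch trial edges.
Bad channels are supplied by the caller (their identification is a manual,
inspection-based procedure); a variance-based convenience flagger is provided
but is not authoritative.
"""
from __future__ import annotations

import numpy as np
from dataclasses import dataclass, field
from scipy import signal as sps

from .io import ConfigurationError, Event, Recording

#: The seven canonical EEG frequency bands, edges in Hz.
BANDS: dict[str, tuple[float, float]] = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha1": (8.0, 10.0),
    "alpha2": (10.0, 13.0),
    "beta1": (13.0, 20.0),
    "beta2": (20.0, 30.0),
    "gamma": (30.0, 45.0),
}

#: Wideband pre-filter applied before re-referencing and band splitting.
WIDEBAND: tuple[float, float] = (0.5, 45.0)


def resolve_band(band: str | tuple[float, float]) -> tuple[float, float]:
    if isinstance(band, str):
        try:
            return BANDS[band]
        except KeyError:
            raise ConfigurationError(f"unknown band {band!r}") from None
    low, high = band
    if not 0 < low < high:
        raise ConfigurationError(f"degenerate band edges ({low}, {high})")
    return float(low), float(high)


@dataclass
class TrialSet:
    """Epoched trials: (n_trials, n_channels, n_samples) plus class labels."""

    trials: np.ndarray
    labels: list[str]
    fs: float
    channels: list[str]
    band: str | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.trials = np.asarray(self.trials)
        if self.trials.ndim != 3:
            raise ValueError("trials must be 3-D (trials x channels x samples)")
        if len(self.labels) != self.trials.shape[0]:
            raise ValueError("one class label per trial required")
        if len(self.channels) != self.trials.shape[1]:
            raise ValueError("one channel name per channel required")

    @property
    def n_trials(self) -> int:
        return self.trials.shape[0]

    @property
    def n_channels(self) -> int:
        return self.trials.shape[1]


def bandpass_filter(data: np.ndarray, fs: float,
                    band: str | tuple[float, float], order: int = 3) -> np.ndarray:
    """Zero-phase Butterworth band-pass along the last axis.

    Forward-backward application (``sosfiltfilt``) doubles the effective
    order and cancels phase distortion; edges are handled by scipy's
    odd-reflection padding of three filter lengths.
    """
    low, high = resolve_band(band)
    if high >= fs / 2:
        raise ConfigurationError(
            f"band edge {high} Hz is at or above the Nyquist frequency {fs / 2} Hz")
    sos = sps.butter(order, (low, high), btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, np.asarray(data, dtype=float), axis=-1)


def average_rereference(data: np.ndarray) -> np.ndarray:
    """Subtract the instantaneous mean over channels from every sample."""
    data = np.asarray(data, dtype=float)
    return data - data.mean(axis=0, keepdims=True)


def drop_bad_channels(recording: Recording,
                      bad_channels: list[str] | tuple = ()) -> Recording:
    bad = set(bad_channels)
    unknown = bad - set(recording.labels)
    if unknown:
        raise ConfigurationError(f"bad-channel labels not in recording: {sorted(unknown)}")
    keep = [i for i, name in enumerate(recording.labels) if name not in bad]
    if not keep:
        raise ValueError("all channels marked bad")
    return Recording(data=recording.data[keep], fs=recording.fs,
                     labels=[recording.labels[i] for i in keep],
                     events=list(recording.events), meta=dict(recording.meta))


def flag_bad_channels(recording: Recording, z_thresh: float = 4.0) -> list[str]:
    """Convenience flagger: channels whose variance is a z-score outlier.

    Not authoritative — the study identifies bad sensors by visual/spectral
    inspection; this helper only automates an obvious screen.
    """
    variances = np.log(recording.data.var(axis=1) + np.finfo(float).tiny)
    z = (variances - variances.mean()) / (variances.std() + np.finfo(float).tiny)
    return [name for name, zi in zip(recording.labels, z) if abs(zi) > z_thresh]


def segment(recording: Recording, events: list[Event] | None = None,
            window: tuple[float, float] = (0.0, 5.0)) -> TrialSet:
    """Cut epochs around event onsets; window in seconds relative to onset."""
    if events is None:
        events = recording.events
    t0, t1 = window
    if t1 <= t0:
        raise ValueError(f"empty epoch window ({t0}, {t1})")
    n_len = int(round((t1 - t0) * recording.fs))
    epochs, labels = [], []
    for ev in events:
        start = int(round((ev.onset + t0) * recording.fs))
        stop = start + n_len
        if start < 0 or stop > recording.n_samples:
            raise IndexError(
                f"epoch window [{ev.onset + t0:.3f}, {ev.onset + t1:.3f}] s "
                f"exceeds the {recording.duration:.3f} s recording")
        epochs.append(recording.data[:, start:stop])
        labels.append(ev.label)
    return TrialSet(trials=np.stack(epochs), labels=labels, fs=recording.fs,
                    channels=list(recording.labels))


def segment_and_rereference(recording: Recording,
                            events: list[Event] | None = None,
                            window: tuple[float, float] = (0.0, 5.0),
                            bad_channels: list[str] | tuple = ()) -> TrialSet:
    """Drop bad channels, average-re-reference the good ones, then epoch."""
    good = drop_bad_channels(recording, bad_channels)
    good.data = average_rereference(good.data)
    return segment(good, events=events, window=window)


def segment_rest(recording: Recording, trial_length: float = 8.0,
                 n_trials: int = 20) -> TrialSet:
    """Cut a rest recording into consecutive non-overlapping baseline trials."""
    n_len = int(round(trial_length * recording.fs))
    if n_trials * n_len > recording.n_samples:
        raise ValueError(
            f"rest recording of {recording.duration:.1f} s is too short for "
            f"{n_trials} non-overlapping {trial_length} s trials")
    trials = np.stack([recording.data[:, i * n_len:(i + 1) * n_len]
                       for i in range(n_trials)])
    return TrialSet(trials=trials, labels=["rest"] * n_trials, fs=recording.fs,
                    channels=list(recording.labels))


def prepare_continuous(recording: Recording, band: str | tuple[float, float],
                       bad_channels: list[str] | tuple = ()) -> Recording:
    """Wideband-filter, average-re-reference, then band-split a recording.

    Re-referencing is done once on the wideband (0.5-45 Hz) signal; the
    rhythm-specific band-pass follows.  All filtering happens on the
    continuous data, before any epoching.
    """
    good = drop_bad_channels(recording, bad_channels)
    wide = bandpass_filter(good.data, good.fs, WIDEBAND)
    reref = average_rereference(wide)
    banded = bandpass_filter(reref, good.fs, band)
    return Recording(data=banded, fs=good.fs, labels=good.labels,
                     events=good.events, meta=dict(good.meta))
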