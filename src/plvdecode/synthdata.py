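"""Seeded multichannel recordings with planted, class-conditioned phase coupling.

The generator emulates the study design: ~61 channels at 256 Hz, 40 cued
motor-imagery trials (20 per class, 3 s fixation then ~5 s imagery) and a
3-min rest recording.  Each channel is a sum of seven narrowband oscillators
— one per canonical EEG rhythm, realized as cos(phi(t)) with phi a
random-walk-perturbed linear phase at the band's center frequency — on top of
1/f-shaped Gaussian background noise.  Channel phases are independent except
where a :class:`CouplingSchedule` entry plants a shared latent phase for a
channel pair, in one band, for one class, inside an event-locked latency
window: there the channel's band component becomes the power-normalized
mixture

    (1 - kappa) * cos(phi_own) + kappa * cos(phi_latent + jitter_ch)

with mixing weight kappa in [0, 1] and per-channel Gaussian phase jitter.
kappa ramps on/off with a short raised cosine at the window edges so the
waveform stays continuous.  All randomness flows from one seed through
spawned sub-streams, so the output is bit-reproducible.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .io import ConfigurationError, Event, Recording
from .preprocess import (BANDS, TrialSet, resolve_band, segment,
                         segment_rest)

#: 61 scalp sites of the extended 10-10 montage used by the study scanner.
STANDARD_61: tuple[str, ...] = (
    "Fp1", "Fpz", "Fp2", "AF7", "AF3", "AFz", "AF4", "AF8",
    "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
    "FT7", "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6", "FT8",
    "T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8",
    "TP7", "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6", "TP8",
    "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8",
    "PO7", "PO3", "POz", "PO4", "PO8", "O1", "Oz", "O2",
)

#: raised-cosine on/off ramp for planted couplings, in seconds
_RAMP = 0.1


def montage_labels(n_channels: int) -> list[str]:
    if n_channels <= len(STANDARD_61):
        return list(STANDARD_61[:n_channels])
    extra = [f"EX{i}" for i in range(n_channels - len(STANDARD_61))]
    return list(STANDARD_61) + extra


@dataclass(frozen=True)
class CouplingEntry:
    """One planted coupling: a channel pair locks phases in one band,
    for one class, inside an event-locked latency window (s, re onset)."""

    pair: tuple[str | int, str | int]
    band: str
    label: str
    window: tuple[float, float]
    kappa: float


@dataclass
class CouplingSchedule:
    """Planted couplings plus the background-noise shape.

    jitter_sd : per-sample Gaussian phase jitter (radians) added to each
        coupled channel's copy of the latent phase.
    noise_exponent : spectral exponent of the 1/f^a background noise.
    snr_db : total oscillation power over total noise power, in dB.

    Entries are applied in order: if two same-band entries share a channel in
    overlapping windows, the later mix dilutes the earlier lock; schedules
    normally use channel-disjoint pairs per band.
    """

    entries: list[CouplingEntry] = field(default_factory=list)
    jitter_sd: float = 0.2
    noise_exponent: float = 1.0
    snr_db: float = 10.0


@dataclass
class SimulationConfig:
    """Study-design parameters: 61 channels at 256 Hz, 20 trials per class,
    3 s fixation + 5 s imagery, a 180 s rest recording cut into 20 x 8 s."""

    n_channels: int = 61
    fs: float = 256.0
    n_trials_per_class: int = 20
    trial_length: float = 5.0
    fixation: float = 3.0
    inter_trial: float = 2.0
    rest_length: float = 180.0
    rest_trial_length: float = 8.0
    n_rest_trials: int = 20
    schedule: CouplingSchedule | None = None
    seed: int = 0


def default_schedule(labels: list[str] | None = None) -> CouplingSchedule:
    """Class-dependent sensorimotor couplings: imagining one hand locks
    contralateral central sites in the lower-alpha and lower-beta rhythms.

    On montages lacking the named central sites (reduced channel counts),
    the same layout is planted on channel-disjoint index pairs at the two
    ends of the montage instead.
    """
    window = (0.5, 4.0)
    kappa = 0.8
    # channel-disjoint pairs per class: a channel appearing in two same-band
    # entries would have its coupled component re-mixed by the later entry
    left_pairs = [("C4", "FC4"), ("CP4", "C6"), ("C2", "FC2"), ("CP2", "P4")]
    right_pairs = [("C3", "FC3"), ("CP3", "C5"), ("C1", "FC1"), ("CP1", "P3")]
    needed = {ch for pr in left_pairs + right_pairs for ch in pr}
    if labels is not None and not needed <= set(labels):
        n = len(labels)
        if n < 8:
            raise ConfigurationError(
                "default schedule needs >= 8 channels on a generic montage")
        per_class = min(4, n // 4)
        left_pairs = [(n - 1 - 2 * j, n - 2 - 2 * j) for j in range(per_class)]
        right_pairs = [(2 * j, 2 * j + 1) for j in range(per_class)]
    entries = []
    for band in ("alpha1", "beta1"):
        for pairs, label in ((left_pairs, "left"), (right_pairs, "right")):
            for pair in pairs:
                entries.append(CouplingEntry(tuple(pair), band, label, window, kappa))
    return CouplingSchedule(entries=entries, jitter_sd=0.1)


def _resolve_channel(ch: str | int, labels: list[str]) -> int:
    if isinstance(ch, (int, np.integer)):
        if not 0 <= ch < len(labels):
            raise ConfigurationError(f"channel index {ch} out of range")
        return int(ch)
    try:
        return labels.index(ch)
    except ValueError:
        raise ConfigurationError(f"channel {ch!r} not in montage") from None


def _validate_schedule(schedule: CouplingSchedule, labels: list[str],
                       trial_length: float) -> None:
    for entry in schedule.entries:
        a = _resolve_channel(entry.pair[0], labels)
        b = _resolve_channel(entry.pair[1], labels)
        if a == b:
            raise ConfigurationError(f"self-coupling on channel {entry.pair[0]!r}")
        if entry.band not in BANDS:
            raise ConfigurationError(f"unknown band {entry.band!r} in schedule")
        w0, w1 = entry.window
        if not 0.0 <= w0 < w1 <= trial_length:
            raise ConfigurationError(
                f"coupling window {entry.window} outside the "
                f"[0, {trial_length}] s trial")
        if not 0.0 <= entry.kappa <= 1.0:
            raise ConfigurationError(f"kappa {entry.kappa} outside [0, 1]")


def _band_amplitudes() -> dict[str, float]:
    # 1/sqrt(f_c) amplitude law gives the familiar low-frequency-dominated
    # EEG spectrum; absolute scale is arbitrary (SNR is set separately).
    return {name: (0.5 * (lo + hi)) ** -0.5 for name, (lo, hi) in BANDS.items()}


def _phase_sigma(band: str, fs: float) -> float:
    # Random-walk increments sized so the Lorentzian linewidth of the
    # oscillator is about half the band width (keeps power inside the band).
    lo, hi = BANDS[band]
    return float(np.sqrt(2 * np.pi * 0.5 * (hi - lo) / fs))


def _random_walk_phase(n: int, f_center: float, fs: float, sigma: float,
                       rng: np.random.Generator) -> np.ndarray:
    theta0 = rng.uniform(0.0, 2 * np.pi)
    increments = rng.normal(0.0, sigma, size=n)
    t = np.arange(n) / fs
    return 2 * np.pi * f_center * t + theta0 + np.cumsum(increments)


def _kappa_envelope(n: int, fs: float, kappa: float) -> np.ndarray:
    env = np.full(n, kappa)
    ramp = min(int(round(_RAMP * fs)), n // 2)
    if ramp > 0:
        shape = 0.5 * (1 - np.cos(np.pi * np.arange(ramp) / ramp))
        env[:ramp] = kappa * shape
        env[n - ramp:] = kappa * shape[::-1]
    return env


def _band_confine(comp: np.ndarray, fs: float, lo: float, hi: float) -> np.ndarray:
    """Zero all spectral content of a component outside [lo, hi] Hz."""
    spec = np.fft.rfft(comp, axis=1)
    freqs = np.fft.rfftfreq(comp.shape[1], d=1.0 / fs)
    spec[:, (freqs < lo) | (freqs > hi)] = 0.0
    return np.fft.irfft(spec, n=comp.shape[1], axis=1)


def _shaped_noise(shape: tuple[int, int], fs: float, exponent: float,
                  rng: np.random.Generator) -> np.ndarray:
    """Gaussian noise with a 1/f^exponent amplitude spectrum, unit power."""
    white = rng.standard_normal(shape)
    freqs = np.fft.rfftfreq(shape[1], d=1.0 / fs)
    gain = np.empty_like(freqs)
    gain[1:] = freqs[1:] ** (-exponent / 2.0)
    gain[0] = gain[1]
    shaped = np.fft.irfft(np.fft.rfft(white, axis=1) * gain, n=shape[1], axis=1)
    return shaped / shaped.std(axis=1, keepdims=True)


def _synthesize(n_channels: int, n_samples: int, fs: float,
                schedule: CouplingSchedule, labels: list[str],
                coupling_jobs: list[tuple[CouplingEntry, int]],
                seed_seq: np.random.SeedSequence) -> np.ndarray:
    """Render background oscillators + noise, applying scheduled couplings.

    coupling_jobs: (entry, onset_sample) pairs already filtered by class.
    """
    ss_bg, ss_cpl, ss_noise = seed_seq.spawn(3)
    rng_bg = np.random.default_rng(ss_bg)
    rng_cpl = np.random.default_rng(ss_cpl)
    rng_noise = np.random.default_rng(ss_noise)

    amplitudes = _band_amplitudes()
    out = np.zeros((n_channels, n_samples))
    for band, (lo, hi) in BANDS.items():
        f_c = 0.5 * (lo + hi)
        sigma = _phase_sigma(band, fs)
        phases = np.stack([
            _random_walk_phase(n_samples, f_c, fs, sigma, rng_bg)
            for _ in range(n_channels)
        ])
        comp = np.cos(phases)
        for entry, onset in coupling_jobs:
            if entry.band != band:
                continue
            a = _resolve_channel(entry.pair[0], labels)
            b = _resolve_channel(entry.pair[1], labels)
            i0 = onset + int(round(entry.window[0] * fs))
            i1 = onset + int(round(entry.window[1] * fs))
            i0, i1 = max(i0, 0), min(i1, n_samples)
            if i1 <= i0:
                continue
            seg = i1 - i0
            latent = _random_walk_phase(seg, f_c, fs, sigma, rng_cpl)
            env = _kappa_envelope(seg, fs, entry.kappa)
            norm = np.sqrt((1.0 - env) ** 2 + env ** 2)  # keep band power
            for ch in (a, b):
                jitter = (rng_cpl.normal(0.0, schedule.jitter_sd, size=seg)
                          if schedule.jitter_sd > 0 else 0.0)
                comp[ch, i0:i1] = ((1.0 - env) * comp[ch, i0:i1]
                                   + env * np.cos(latent + jitter)) / norm
        # confine each oscillator to its band: the random-walk phase has
        # Lorentzian tails that would otherwise leak across rhythms
        out += _band_confine(amplitudes[band] * comp, fs, lo, hi)

    signal_power = sum(a ** 2 for a in amplitudes.values()) / 2.0
    noise_power = signal_power / 10 ** (schedule.snr_db / 10.0)
    out += np.sqrt(noise_power) * _shaped_noise(
        (n_channels, n_samples), fs, schedule.noise_exponent, rng_noise)
    return out


def simulate_recording(config: SimulationConfig) -> tuple[Recording, list[Event]]:
    """Simulate the cued motor-imagery session as one continuous recording.

    Trials alternate in a seeded balanced-random order; each spans
    fixation + imagery + inter-trial gap, and the event marks imagery onset.
    Deterministic given ``config.seed``.
    """
    labels = montage_labels(config.n_channels)
    schedule = (config.schedule if config.schedule is not None
                else default_schedule(labels))
    _validate_schedule(schedule, labels, config.trial_length)
    if config.fs <= 2 * max(hi for _, hi in BANDS.values()):
        raise ConfigurationError(
            f"fs={config.fs} Hz under-samples the {max(h for _, h in BANDS.values())}"
            " Hz band edge")

    ss = np.random.SeedSequence(config.seed)
    ss_order, ss_signal, _ss_rest = ss.spawn(3)
    rng_order = np.random.default_rng(ss_order)

    n_trials = 2 * config.n_trials_per_class
    classes = ["left"] * config.n_trials_per_class + ["right"] * config.n_trials_per_class
    order = rng_order.permutation(n_trials)
    classes = [classes[i] for i in order]

    span = config.fixation + config.trial_length + config.inter_trial
    lead = config.inter_trial
    n_samples = int(round((lead + n_trials * span) * config.fs))

    events, jobs = [], []
    for i, label in enumerate(classes):
        onset_s = lead + i * span + config.fixation
        onset = int(round(onset_s * config.fs))
        events.append(Event(onset_s, label))
        for entry in schedule.entries:
            if entry.label == label:
                jobs.append((entry, onset))

    data = _synthesize(config.n_channels, n_samples, config.fs, schedule,
                       labels, jobs, ss_signal)
    rec = Recording(data=data, fs=config.fs, labels=labels, events=events,
                    meta={"seed": config.seed, "kind": "mi"})
    return rec, events


def simulate_rest(config: SimulationConfig) -> Recording:
    """Simulate the resting-state recording: background only, no couplings."""
    labels = montage_labels(config.n_channels)
    schedule = (config.schedule if config.schedule is not None
                else default_schedule(labels))
    ss = np.random.SeedSequence(config.seed)
    _ss_order, _ss_signal, ss_rest = ss.spawn(3)
    n_samples = int(round(config.rest_length * config.fs))
    data = _synthesize(config.n_channels, n_samples, config.fs, schedule,
                       labels, [], ss_rest)
    return Recording(data=data, fs=config.fs, labels=labels, events=[],
                     meta={"seed": config.seed, "kind": "rest"})


@dataclass
class StudyDataset:
    """A complete synthetic subject: continuous recordings, raw epochs and
    the ground-truth schedule for recovery tests."""

    mi_recording: Recording
    rest_recording: Recording
    left: TrialSet
    right: TrialSet
    rest: TrialSet
    schedule: CouplingSchedule
    config: SimulationConfig


def make_study_dataset(config: SimulationConfig | None = None) -> StudyDataset:
    """Simulate one subject and epoch the raw (unfiltered) trials.

    MI epochs run onset -> onset + trial_length; the rest recording is cut
    into consecutive non-overlapping baseline trials.
    """
    if config is None:
        config = SimulationConfig()
    if config.rest_length < config.n_rest_trials * config.rest_trial_length:
        raise ValueError(
            f"rest recording of {config.rest_length} s cannot hold "
            f"{config.n_rest_trials} non-overlapping "
            f"{config.rest_trial_length} s trials")
    schedule = (config.schedule if config.schedule is not None
                else default_schedule(montage_labels(config.n_channels)))
    config = replace(config, schedule=schedule)

    mi_rec, events = simulate_recording(config)
    rest_rec = simulate_rest(config)

    window = (0.0, config.trial_length)
    all_trials = segment(mi_rec, events, window=window)
    left_idx = [i for i, lab in enumerate(all_trials.labels) if lab == "left"]
    right_idx = [i for i, lab in enumerate(all_trials.labels) if lab == "right"]

    def _subset(idx: list[int], label: str) -> TrialSet:
        return TrialSet(trials=all_trials.trials[idx], labels=[label] * len(idx),
                        fs=config.fs, channels=list(mi_rec.labels))

    rest = segment_rest(rest_rec, trial_length=config.rest_trial_length,
                        n_trials=config.n_rest_trials)
    return StudyDataset(mi_recording=mi_rec, rest_recording=rest_rec,
                        left=_subset(left_idx, "left"),
                        right=_subset(right_idx, "right"),
                        rest=rest, schedule=schedule, config=config)


def schedule_to_json(schedule: CouplingSchedule) -> dict:
    """Ground-truth schedule in a JSON-serializable form."""
    return {
        "jitter_sd": schedule.jitter_sd,
        "noise_exponent": schedule.noise_exponent,
        "snr_db": schedule.snr_db,
        "entries": [
            {"pair": list(e.pair), "band": e.band, "label": e.label,
             "window": list(e.window), "kappa": e.kappa}
            for e in schedule.entries
        ],
    }
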