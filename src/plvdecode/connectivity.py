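"""Hilbert-phase extraction and PLV connectivity, static and sliding-window.

The phase locking value between two band-limited channels is the modulus of
the time-averaged unit phasor of their instantaneous phase difference,

    PLV(x_k, x_r) = (1/n) | sum_t exp(i (phi_k(t) - phi_r(t))) |,

1 for perfect locking, ~0 for independence.  All sensor pairs are computed
in one pass as the Gram matrix of unit phasors, so a full [N x N] pattern
costs one complex matrix product per integration window.

Sliding-window sequences use the cycle criterion: the window spans three
cycles of the band's lowest frequency, and advances by a configurable step
(350 ms for cued decoding, 20 ms for streaming).  Phases are extracted once
per trial on the full epoch; windows then slice the phase series, avoiding
per-window Hilbert edge effects.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import hilbert

from .preprocess import TrialSet, resolve_band

#: PLV == 1 would give zero graph distance; cap just below.
PLV_CAP = 1.0 - 1e-6


def pair_indices(n_channels: int) -> list[tuple[int, int]]:
    """The fixed vec(W) ordering: pairs (r, k) with r < k, scanned k-major.

    vec position i holds W[k, r] for the i-th entry of this list, i.e. the
    lower-triangular scan k = 1..N-1, r = 0..k-1 (equivalently the upper
    triangle W_kr with r < k of the symmetric matrix).
    """
    rows, cols = np.tril_indices(n_channels, -1)
    return [(int(r), int(k)) for k, r in zip(rows, cols)]


def vec_index(n_channels: int) -> dict[tuple[int, int], int]:
    """Map an (r, k) channel pair (either order) to its vec(W) position."""
    table = {}
    for i, (r, k) in enumerate(pair_indices(n_channels)):
        table[(r, k)] = i
        table[(k, r)] = i
    return table


def n_pairs(n_channels: int) -> int:
    return n_channels * (n_channels - 1) // 2


def vectorize(W: np.ndarray) -> np.ndarray:
    """Upper-triangular vector of a symmetric pattern, in the fixed ordering."""
    return W[np.tril_indices(W.shape[0], -1)]


def unvectorize(vec: np.ndarray, n_channels: int, diagonal: float = 1.0) -> np.ndarray:
    W = np.full((n_channels, n_channels), diagonal)
    rows, cols = np.tril_indices(n_channels, -1)
    W[rows, cols] = vec
    W[cols, rows] = vec
    return W


def instantaneous_phase(trial: np.ndarray) -> np.ndarray:
    """Per-channel analytic-signal phase in (-pi, pi], shape (channels, samples).

    Input must already be band-limited; a constant (zero) channel has no
    defined phase and is flagged with a warning.
    """
    trial = np.asarray(trial, dtype=float)
    flat = np.ptp(trial, axis=-1) == 0
    if np.any(flat):
        warnings.warn(
            f"constant channel(s) {np.flatnonzero(flat).tolist()}: phase undefined",
            RuntimeWarning, stacklevel=2)
    return np.angle(hilbert(trial, axis=-1))


@dataclass
class ConnectivityPattern:
    """A symmetric PLV matrix with unit diagonal, plus its vec(W) form."""

    W: np.ndarray
    band: str | None = None
    window: tuple[float, float] | None = None

    @property
    def vec(self) -> np.ndarray:
        return vectorize(self.W)

    @property
    def n_channels(self) -> int:
        return self.W.shape[0]

    @property
    def n_pairs(self) -> int:
        return n_pairs(self.W.shape[0])


@dataclass
class ConnectivitySequence:
    """vec(W[tau]) for tau = 1..N_tau: shape (n_pairs, n_tau).

    ``starts`` gives each window's onset in seconds within the trial; the
    sequence index tau runs at the (coarser) stepping-window resolution,
    distinct from the sample clock.
    """

    vecs: np.ndarray
    step: float
    t_window: float
    band: str | None = None
    n_channels: int | None = None
    starts: np.ndarray | None = None

    @property
    def n_tau(self) -> int:
        return self.vecs.shape[1]


def plv_from_phases(phases: np.ndarray, t1: int = 0,
                    t2: int | None = None) -> np.ndarray:
    """All-pairs PLV over samples [t1, t2) of a (channels, samples) phase array.

    One-pass vectorized form: the Gram matrix of time-averaged unit phasors.
    """
    phases = np.asarray(phases)
    n_samp = phases.shape[1]
    if t2 is None:
        t2 = n_samp
    if not (0 <= t1 < t2 <= n_samp):
        raise IndexError(f"window [{t1}, {t2}) outside trial of {n_samp} samples")
    if t2 - t1 < 2:
        raise ValueError("PLV window needs at least 2 samples")
    U = np.exp(1j * phases[:, t1:t2])
    G = (U @ U.conj().T) / (t2 - t1)
    W = np.abs(G)
    np.fill_diagonal(W, 1.0)
    return np.clip(W, 0.0, 1.0)


def plv_matrix(trial: np.ndarray, t1: int = 0, t2: int | None = None,
               band: str | None = None) -> ConnectivityPattern:
    """PLV pattern of one band-limited trial over sample window [t1, t2)."""
    phases = instantaneous_phase(trial)
    W = plv_from_phases(phases, t1, t2)
    return ConnectivityPattern(W=W, band=band)


def cycle_window(band: str | tuple[float, float], cycles: int = 3) -> float:
    """Cycle-criterion window width in seconds: cycles / lowest band frequency."""
    low, _high = resolve_band(band)
    return cycles / low


def sliding_connectivity(trial: np.ndarray, fs: float,
                         band: str | tuple[float, float],
                         step: float, cycles: int = 3) -> ConnectivitySequence:
    """Sliding-window PLV sequence of one band-limited trial.

    Windows of the cycle-criterion width advance by ``step`` seconds and are
    truncated at the trial end (no partial windows), so
    N_tau = floor((L - T_window) / step) + 1.
    """
    trial = np.asarray(trial, dtype=float)
    if step <= 0:
        raise ValueError("step must be positive")
    t_window = cycle_window(band, cycles)
    w = int(round(t_window * fs))
    hop = int(round(step * fs))
    n_samp = trial.shape[1]
    if w > n_samp:
        raise ValueError(
            f"cycle-criterion window {t_window:.3f} s exceeds the "
            f"{n_samp / fs:.3f} s trial")
    phases = instantaneous_phase(trial)
    starts = np.arange(0, n_samp - w + 1, hop)
    vecs = np.empty((n_pairs(trial.shape[0]), starts.size))
    for j, s in enumerate(starts):
        vecs[:, j] = vectorize(plv_from_phases(phases, int(s), int(s) + w))
    band_name = band if isinstance(band, str) else None
    return ConnectivitySequence(vecs=vecs, step=step, t_window=t_window,
                                band=band_name, n_channels=trial.shape[0],
                                starts=starts / fs)


def static_patterns(trials: TrialSet) -> np.ndarray:
    """Full-window vec(W) per trial: shape (n_trials, n_pairs)."""
    return np.stack([plv_matrix(tr, band=trials.band).vec for tr in trials.trials])


def sequence_stack(trials: TrialSet, band: str | tuple[float, float],
                   step: float, cycles: int = 3) -> tuple[np.ndarray, ConnectivitySequence]:
    """vec(W[tau]) for every trial: (n_trials, n_pairs, n_tau) + a template."""
    seqs = [sliding_connectivity(tr, trials.fs, band, step, cycles)
            for tr in trials.trials]
    return np.stack([s.vecs for s in seqs]), seqs[0]
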