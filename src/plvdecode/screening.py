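"""Discriminative-coupling selection.

Static screening ranks couplings by the absolute standardized two-sample
Wilcoxon rank-sum statistic |z| and keeps the top k (default 10).  Dynamic
screening scores every coupling at every stepping-window latency, derives a
global 99.9th-percentile threshold from label-permuted data (so a coupling
crossing it is discriminative at p < 0.001), removes short-lived
supra-threshold excursions with a row-wise running median (temporal
consistency: only couplings that stay discriminative for > ~100 ms survive),
and aggregates the resulting persistence profiles over bootstrap resamples
of the trials.  The final selection — pairs whose average profile clears the
selection floor — is the fixed feature set shared by all time-indexed
decoders.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import median_filter
from scipy.stats import rankdata

#: minimum persistence of a discriminative coupling, in seconds
PERSISTENCE = 0.1


def wilcoxon_scores(group_a: np.ndarray, group_b: np.ndarray) -> np.ndarray:
    """Per-feature |z| of the two-sample Wilcoxon rank-sum statistic.

    Inputs are (n_samples, n_features); higher score = more discriminative.
    The tie-corrected normal standardization is used; an all-tied feature
    scores 0.  Being rank-based, the score is invariant under any monotone
    transform of a feature.
    """
    a = np.atleast_2d(np.asarray(group_a, dtype=float))
    b = np.atleast_2d(np.asarray(group_b, dtype=float))
    if a.shape[1] != b.shape[1]:
        raise ValueError("feature dimensions differ between groups")
    na, nb = a.shape[0], b.shape[0]
    if na < 2 or nb < 2:
        raise ValueError("need at least 2 samples per group")
    n = na + nb
    x = np.vstack([a, b])
    ranks = rankdata(x, axis=0)
    r_a = ranks[:na].sum(axis=0)
    mu = na * (n + 1) / 2.0
    # tie correction: sum(t^3 - t) over tie groups, per feature
    xs = np.sort(x, axis=0)
    tie_term = np.zeros(x.shape[1])
    has_ties = (np.diff(xs, axis=0) == 0).any(axis=0)
    for j in np.flatnonzero(has_ties):
        _, counts = np.unique(xs[:, j], return_counts=True)
        tie_term[j] = np.sum(counts.astype(float) ** 3 - counts)
    var = na * nb / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(var > 0, (r_a - mu) / np.sqrt(var), 0.0)
    return np.abs(z)


def select_static_features(left: np.ndarray, right: np.ndarray,
                           k: int = 10) -> np.ndarray:
    """Indices of the k most discriminative couplings (stable tie-break)."""
    scores = wilcoxon_scores(left, right)
    if k > scores.size:
        raise ValueError(f"k={k} exceeds the {scores.size} available features")
    # descending score, ascending index on ties
    order = np.lexsort((np.arange(scores.size), -scores))
    return np.sort(order[:k])


def timeindexed_scores(left_seqs: np.ndarray, right_seqs: np.ndarray) -> np.ndarray:
    """Score(r, tau): the rank-sum score applied at every latency.

    Inputs are (n_trials, n_pairs, n_tau); output is (n_pairs, n_tau).
    """
    left_seqs = np.asarray(left_seqs)
    right_seqs = np.asarray(right_seqs)
    if left_seqs.shape[1:] != right_seqs.shape[1:]:
        raise ValueError("sequences must share n_pairs and n_tau across groups")
    n_pairs, n_tau = left_seqs.shape[1:]
    flat = wilcoxon_scores(left_seqs.reshape(left_seqs.shape[0], -1),
                           right_seqs.reshape(right_seqs.shape[0], -1))
    return flat.reshape(n_pairs, n_tau)


def permutation_threshold(left_seqs: np.ndarray, right_seqs: np.ndarray,
                          n_rand: int = 100, percentile: float = 99.9,
                          rng: np.random.Generator | None = None) -> float:
    """Global score threshold from label-permuted data.

    Trials are pooled and randomly re-partitioned ``n_rand`` times into two
    groups of the original sizes; the requested percentile of the pooled
    (features x latencies x permutations) null scores is returned, marking
    couplings discriminative at p < (100 - percentile)/100.
    """
    if n_rand < 20:
        raise ValueError("n_rand must be at least 20 for a usable tail estimate")
    rng = np.random.default_rng(rng)
    pooled = np.concatenate([left_seqs, right_seqs], axis=0)
    n_left = left_seqs.shape[0]
    n_total = pooled.shape[0]
    if n_total < 4:
        raise ValueError("too few trials to permute")
    flat = pooled.reshape(n_total, -1)
    null_scores = np.empty((n_rand, flat.shape[1]))
    for i in range(n_rand):
        perm = rng.permutation(n_total)
        null_scores[i] = wilcoxon_scores(flat[perm[:n_left]], flat[perm[n_left:]])
    return float(np.percentile(null_scores, percentile))


def persistence_window(step: float, persistence: float = PERSISTENCE) -> int:
    """Running-median length: smallest odd w with (w-1)/2 * step >= persistence."""
    return 2 * int(np.ceil(persistence / step)) + 1


def consistency_profile(scores: np.ndarray, thr: float,
                        median_window: int) -> tuple[np.ndarray, np.ndarray]:
    """Threshold Score(r, tau), sieve short excursions, count persistence.

    I(r, tau) = H(Score - thr) is median-filtered row-wise (odd window,
    zero-padded ends), eliminating supra-threshold runs shorter than the
    persistence floor; Profile(r) is the row sum of the sieved mask and the
    selected pairs are the non-zero rows.
    """
    if median_window % 2 != 1:
        raise ValueError("median_window must be odd")
    mask = (np.asarray(scores) > thr).astype(float)
    sieved = median_filter(mask, size=(1, median_window),
                           mode="constant", cval=0.0) > 0.5
    profile = sieved.sum(axis=1)
    return profile, np.flatnonzero(profile > 0)


@dataclass
class ScreeningResult:
    """Outcome of dynamic feature screening."""

    scores: np.ndarray
    threshold: float
    profile: np.ndarray
    selected: np.ndarray
    n_rand: int
    n_boot: int = 0
    fallback: bool = False
    boot_profiles: np.ndarray | None = field(default=None, repr=False)


def screen_timeindexed(left_seqs: np.ndarray, right_seqs: np.ndarray,
                       step: float, n_rand: int = 100, percentile: float = 99.9,
                       median_window: int | None = None,
                       rng: np.random.Generator | None = None) -> ScreeningResult:
    """Single-pass dynamic screening (no bootstrap aggregation)."""
    rng = np.random.default_rng(rng)
    if median_window is None:
        median_window = persistence_window(step)
    scores = timeindexed_scores(left_seqs, right_seqs)
    thr = permutation_threshold(left_seqs, right_seqs, n_rand=n_rand,
                                percentile=percentile, rng=rng)
    profile, selected = consistency_profile(scores, thr, median_window)
    return ScreeningResult(scores=scores, threshold=thr, profile=profile,
                           selected=selected, n_rand=n_rand)


def bootstrap_select(left_seqs: np.ndarray, right_seqs: np.ndarray,
                     step: float, n_boot: int = 30, n_rand: int = 100,
                     percentile: float = 99.9, median_window: int | None = None,
                     selection_floor: float | None = None, k_fallback: int = 10,
                     rng: np.random.Generator | None = None) -> ScreeningResult:
    """Bootstrap-aggregated dynamic selection: the fixed feature set.

    The trials are resampled with replacement (within class, preserving the
    group sizes) ``n_boot`` times; the consistency profile of each resample
    is computed against a single permutation threshold derived from the
    observed data, the profiles are averaged, and pairs whose average
    profile exceeds ``selection_floor`` are selected.  The default floor
    scales with the latency grid: a pair must persist, on average across
    resamples, for at least the 100-ms persistence floor
    (max(0.5, persistence/step) supra-threshold latencies).  An empty
    selection triggers a warning and falls back to the top-k static ranking
    of the time-averaged patterns.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be at least 2")
    rng = np.random.default_rng(rng)
    if median_window is None:
        median_window = persistence_window(step)
    if selection_floor is None:
        selection_floor = max(0.5, PERSISTENCE / step)
    left_seqs = np.asarray(left_seqs)
    right_seqs = np.asarray(right_seqs)

    scores = timeindexed_scores(left_seqs, right_seqs)
    thr = permutation_threshold(left_seqs, right_seqs, n_rand=n_rand,
                                percentile=percentile, rng=rng)
    profiles = np.empty((n_boot, left_seqs.shape[1]))
    for b in range(n_boot):
        il = rng.integers(0, left_seqs.shape[0], size=left_seqs.shape[0])
        ir = rng.integers(0, right_seqs.shape[0], size=right_seqs.shape[0])
        boot_scores = timeindexed_scores(left_seqs[il], right_seqs[ir])
        profiles[b], _ = consistency_profile(boot_scores, thr, median_window)
    avg_profile = profiles.mean(axis=0)
    selected = np.flatnonzero(avg_profile > selection_floor)
    fallback = False
    if selected.size == 0:
        warnings.warn("bootstrap selection is empty; falling back to the "
                      "top-k static ranking", RuntimeWarning, stacklevel=2)
        fallback = True
        k = min(k_fallback, left_seqs.shape[1])
        selected = select_static_features(left_seqs.mean(axis=2),
                                          right_seqs.mean(axis=2), k=k)
    return ScreeningResult(scores=scores, threshold=thr, profile=avg_profile,
                           selected=selected, n_rand=n_rand, n_boot=n_boot,
                           fallback=fallback, boot_profiles=profiles)


def selection_to_json(selected: np.ndarray, channels: list[str],
                      pairs: list[tuple[int, int]]) -> dict:
    """Selected couplings as pair indices plus channel-label pairs."""
    return {
        "selected": [int(i) for i in selected],
        "couplings": [[channels[pairs[i][0]], channels[pairs[i][1]]]
                      for i in selected],
    }
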