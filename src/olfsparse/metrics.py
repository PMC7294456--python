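"""Summary statistics of the simulated odor responses.

Covers population firing rates, the Treves-Rolls sparseness measure in its
population and temporal flavors, activation-pattern correlations between
odors (single-trial and trial-averaged), activated-KC fractions, spikes
per active cell, and mean pairwise cross-correlations of PN spike trains.

Conventions
-----------
* The "evoked spike count" window for activation patterns and population
  sparseness is the full 1000 ms stimulus window.
* Temporal sparseness uses the KC population rate in 20 bins of 50 ms over
  the same window.
* Patterns with zero variance (e.g. no KC spike under strong inhibition)
  yield a missing value (NaN) rather than zero, and downstream averages
  report how many pairs were excluded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .stimulus import ReceptorProfileParams, StimulusSpec, driven_glomeruli

__all__ = [
    "population_rate",
    "treves_rolls",
    "temporal_sparseness",
    "population_sparseness",
    "pattern_correlation_single_trial",
    "pattern_correlation_trial_averaged",
    "fraction_activated",
    "mean_spikes_per_active",
    "pairwise_crosscorrelation",
    "classify_driven",
    "CorrelationSummary",
]

STIM_WINDOW = (1000.0, 2000.0)   # default stimulus epoch, ms
SPONT_WINDOW = (0.0, 1000.0)     # pre-stimulus epoch, ms


def population_rate(recordings, population: str, bin_ms: float = 10.0,
                    t0: float = 0.0, t1: float | None = None) -> np.ndarray:
    """Trial- and population-averaged firing rate time series in Hz.

    ``recordings`` is a single :class:`TrialRecording` or an iterable of
    them (averaged as repeated trials of the same protocol).
    """
    recs = [recordings] if hasattr(recordings, "binned_counts") else list(recordings)
    if not recs:
        raise ValueError("no recordings given")
    acc = None
    for rec in recs:
        counts = rec.binned_counts(population, bin_ms, t0, t1)
        r = counts.mean(axis=0) / (bin_ms * 1e-3)
        acc = r if acc is None else acc + r
    return acc / len(recs)


def treves_rolls(a: np.ndarray) -> float:
    """Modified Treves-Rolls sparseness ``1 - <a>^2 / <a^2>`` in [0, 1).

    High values indicate sparse activity.  ``a`` must be non-negative;
    an all-zero vector is undefined and returns NaN with a warning.
    """
    a = np.asarray(a, dtype=float)
    if a.ndim != 1 or a.size == 0:
        raise ValueError("expected a non-empty 1-d array")
    if np.any(a < 0):
        raise ValueError("activity values must be non-negative")
    peak = a.max()
    if peak == 0.0:
        warnings.warn("all-zero activity vector: sparseness undefined")
        return float("nan")
    a = a / peak  # scale-invariant; guards against under/overflow in a^2
    return float(1.0 - np.mean(a) ** 2 / np.mean(a * a))


def population_sparseness(recording, population: str = "kc",
                          window: tuple[float, float] = STIM_WINDOW) -> float:
    """Treves-Rolls sparseness over per-neuron stimulus-window spike counts."""
    return treves_rolls(recording.spike_counts(population, *window))


def temporal_sparseness(recording, population: str = "kc",
                        bin_ms: float = 50.0,
                        window: tuple[float, float] = STIM_WINDOW) -> float:
    """Treves-Rolls sparseness of the binned population rate across time.

    Defaults to 20 bins of 50 ms over the 1 s stimulus window.
    """
    counts = recording.binned_counts(population, bin_ms, *window)
    return treves_rolls(counts.sum(axis=0).astype(float))


def _pearson(n: np.ndarray, m: np.ndarray) -> float:
    n = np.asarray(n, dtype=float)
    m = np.asarray(m, dtype=float)
    if n.shape != m.shape or n.ndim != 1:
        raise ValueError("patterns must be 1-d arrays of equal length")
    if n.std() == 0.0 or m.std() == 0.0:
        return float("nan")
    return float(np.corrcoef(n, m)[0, 1])


def pattern_correlation_single_trial(pattern_a: np.ndarray,
                                     pattern_b: np.ndarray) -> float:
    """Pearson correlation between two single-trial activation patterns.

    Returns NaN for zero-variance patterns (the caller averages over
    trials/realizations with NaNs excluded and counted).
    """
    return _pearson(pattern_a, pattern_b)


def pattern_correlation_trial_averaged(patterns_a: np.ndarray,
                                       patterns_b: np.ndarray) -> float:
    """Pearson correlation between trial-averaged activation patterns.

    ``patterns_a``/``patterns_b`` are (n_trials, n_neurons) count matrices
    (a single pattern vector is treated as one trial).  Averaging the
    patterns before correlating suppresses trial-to-trial variability, so
    this measure is in expectation at least as high as the mean
    single-trial correlation.
    """
    pa = np.atleast_2d(np.asarray(patterns_a, dtype=float))
    pb = np.atleast_2d(np.asarray(patterns_b, dtype=float))
    return _pearson(pa.mean(axis=0), pb.mean(axis=0))


@dataclass
class CorrelationSummary:
    mean: float
    sd: float
    n_used: int
    n_excluded: int


def summarize_pattern_correlations(values) -> CorrelationSummary:
    """Average single-trial correlations, excluding (and counting) NaNs."""
    v = np.asarray(list(values), dtype=float)
    ok = ~np.isnan(v)
    if not ok.any():
        return CorrelationSummary(float("nan"), float("nan"), 0, int(v.size))
    return CorrelationSummary(float(v[ok].mean()), float(v[ok].std()),
                              int(ok.sum()), int((~ok).sum()))


_EPOCHS = {
    "stimulus": STIM_WINDOW,
    "spontaneous": SPONT_WINDOW,
    "transient": (STIM_WINDOW[0], STIM_WINDOW[0] + 50.0),
}


def fraction_activated(recordings, population: str = "kc",
                       epoch: str | tuple[float, float] = "stimulus"
                       ) -> tuple[float, float]:
    """Mean and SD over trials of the fraction of neurons with >= 1 spike.

    ``epoch`` is one of ``"stimulus"`` (the 1 s odor window),
    ``"spontaneous"`` (1 s before odor onset), ``"transient"`` (first
    50 ms after onset), or an explicit (t0, t1) window in ms.
    """
    window = _EPOCHS[epoch] if isinstance(epoch, str) else epoch
    recs = [recordings] if hasattr(recordings, "spike_counts") else list(recordings)
    fracs = [(r.spike_counts(population, *window) > 0).mean() for r in recs]
    return float(np.mean(fracs)), float(np.std(fracs))


def mean_spikes_per_active(recording, population: str = "kc",
                           epoch: str | tuple[float, float] = "stimulus"
                           ) -> float:
    """Mean spike count among neurons active in the epoch (NaN if none)."""
    window = _EPOCHS[epoch] if isinstance(epoch, str) else epoch
    counts = recording.spike_counts(population, *window)
    active = counts > 0
    if not active.any():
        return float("nan")
    return float(counts[active].mean())


def pairwise_crosscorrelation(recordings, population: str = "pn",
                              bin_ms: float = 50.0,
                              t0: float = 0.0, t1: float | None = None
                              ) -> float:
    """Mean pairwise Pearson correlation of binned spike trains.

    For each neuron the spike train is binned into ``bin_ms`` windows; the
    Pearson correlation is computed for every neuron pair and averaged
    over pairs and trials.  Pairs involving a silent (zero-variance)
    neuron are excluded.
    """
    recs = [recordings] if hasattr(recordings, "binned_counts") else list(recordings)
    per_trial = []
    for rec in recs:
        x = rec.binned_counts(population, bin_ms, t0, t1).astype(float)
        if x.shape[0] < 2:
            raise ValueError("need at least two neurons")
        sd = x.std(axis=1)
        keep = sd > 0
        if keep.sum() < 2:
            continue
        c = np.corrcoef(x[keep])
        iu = np.triu_indices_from(c, k=1)
        per_trial.append(float(c[iu].mean()))
    return float(np.mean(per_trial)) if per_trial else float("nan")


def classify_driven(stimulus: StimulusSpec | int,
                    params: ReceptorProfileParams = ReceptorProfileParams()
                    ) -> np.ndarray:
    """Boolean mask of glomeruli driven by the odor (positive activation)."""
    k_S = stimulus.k_S if isinstance(stimulus, StimulusSpec) else stimulus
    if k_S is None:
        return np.zeros(params.n_receptor_types, dtype=bool)
    return driven_glomeruli(k_S, params)
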