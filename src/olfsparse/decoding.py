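"""Time-resolved odor-identity decoding.

Odor identity is read out independently in every 50 ms bin of the trial
(60 bins over 3000 ms) from one of three feature sources: PN spike
counts, KC spike counts, or the amplitudes of the KC adaptation currents.
A Gaussian naive Bayes classifier with stratified threefold
cross-validation gives per-bin accuracy (mean and SD over folds);
maximum-a-posteriori prediction.  With seven odor classes the chance
level is 1/7 ~ 0.14.

KC count features are mostly zero, so exact zero-variance features would
break the Gaussian likelihood; the classifier therefore applies a variance
floor proportional to the largest feature variance (scikit-learn's
``var_smoothing``), never excluding features.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB

__all__ = [
    "FeatureTensor",
    "extract_features",
    "decode_timecourse",
    "summarize_decoding",
    "DEFAULT_ODORS",
]

#: Default decoding odor set: seven odors spaced two receptor types apart.
DEFAULT_ODORS = (0, 2, 4, 6, 8, 10, 12)

SOURCES = ("pn_counts", "kc_counts", "kc_adaptation")


@dataclass
class FeatureTensor:
    """Per-trial, per-neuron, per-bin decoding features with odor labels."""

    X: np.ndarray          # (n_trials, n_neurons, n_bins)
    labels: np.ndarray     # (n_trials,) odor indices
    source: str
    bin_ms: float = 50.0

    @property
    def n_bins(self) -> int:
        return self.X.shape[2]

    @property
    def n_classes(self) -> int:
        return np.unique(self.labels).size


def features_from_trial(recording, source: str, bin_ms: float = 50.0
                        ) -> np.ndarray:
    """(n_neurons, n_bins) feature matrix for one trial.

    ``kc_adaptation`` features are the mean of the 1 ms-sampled adaptation
    current within each bin; :func:`extract_features` can request a
    bin-end sample instead.
    """
    return _features_from_trial(recording, source, bin_ms, "mean")


def _features_from_trial(recording, source, bin_ms, ia_summary):
    if source == "pn_counts":
        return recording.binned_counts("pn", bin_ms).astype(np.float64)
    if source == "kc_counts":
        return recording.binned_counts("kc", bin_ms).astype(np.float64)
    if source == "kc_adaptation":
        trace = recording.kc_adaptation
        if trace is None:
            raise ValueError(
                "recording has no KC adaptation trace; rerun the simulation "
                "with record_adaptation=True")
        per_bin = int(round(bin_ms / recording.ia_sample_ms))
        n_bins = trace.shape[0] // per_bin
        t = trace[: n_bins * per_bin].reshape(n_bins, per_bin, -1)
        if ia_summary == "last":
            out = t[:, -1, :]
        else:
            out = t.mean(axis=1)
        return np.ascontiguousarray(out.T, dtype=np.float64)
    raise ValueError(f"unknown feature source {source!r}; pick from {SOURCES}")


def extract_features(recordings, source: str, bin_ms: float = 50.0,
                     ia_summary: str = "mean") -> FeatureTensor:
    """Build the decoding feature tensor from labelled trial recordings.

    Parameters
    ----------
    recordings
        Iterable of :class:`TrialRecording` with odor labels.
    source
        ``"pn_counts"``, ``"kc_counts"`` or ``"kc_adaptation"``.
    ia_summary
        ``"mean"`` (default) averages the adaptation trace within each
        bin; ``"last"`` takes the bin-end sample.
    """
    mats, labels = [], []
    for rec in recordings:
        if rec.odor is None:
            raise ValueError("cannot decode a stimulus-free recording")
        mats.append(_features_from_trial(rec, source, bin_ms, ia_summary))
        labels.append(rec.odor)
    if not mats:
        raise ValueError("no recordings given")
    return FeatureTensor(np.stack(mats), np.asarray(labels), source, bin_ms)


def decode_timecourse(features: FeatureTensor, folds: int = 3,
                      seed: int | None = 0, var_smoothing: float = 1e-9
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Per-bin decoding accuracy (mean, SD over cross-validation folds).

    The same stratified fold assignment is reused for every time bin so
    the accuracy time course is comparable across bins.
    """
    X, y = features.X, features.labels
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("need at least two odor classes")
    if folds > counts.min():
        raise ValueError("more folds than trials in the smallest class")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(skf.split(np.zeros_like(y), y))
    acc = np.empty((features.n_bins, folds))
    for b in range(features.n_bins):
        Xb = X[:, :, b]
        for f, (tr, te) in enumerate(splits):
            if Xb[tr].var(axis=0).max() == 0.0:
                # featureless bin (e.g. no KC spike anywhere): the Gaussian
                # likelihood is uninformative, prediction falls back to the
                # class prior (chance for balanced classes)
                prior_class = classes[np.argmax(
                    np.bincount(np.searchsorted(classes, y[tr])))]
                acc[b, f] = float(np.mean(y[te] == prior_class))
            else:
                clf = GaussianNB(var_smoothing=var_smoothing)
                clf.fit(Xb[tr], y[tr])
                acc[b, f] = clf.score(Xb[te], y[te])
    return acc.mean(axis=1), acc.std(axis=1)


@dataclass
class DecodingSummary:
    chance: float
    pre_mean: float          # bins fully before stimulus onset
    onset_peak: float        # max accuracy in the first 200 ms after onset
    onset_peak_bin: int
    plateau_mean: float      # mid-stimulus (onset+200 ms .. offset)
    offset_peak: float       # max accuracy within 200 ms after offset
    post_mean: float         # from offset+200 ms to trial end
    n_above_chance_onset: int   # consecutive above-chance bins from onset


def summarize_decoding(accuracy: np.ndarray, sd: np.ndarray | None = None,
                       bin_ms: float = 50.0,
                       stim_window: tuple[float, float] = (1000.0, 2000.0),
                       n_classes: int = 7,
                       chance_margin: float = 0.05) -> DecodingSummary:
    """Epoch summary of an accuracy time course.

    "Above chance" means exceeding 1/n_classes by ``chance_margin``.
    ``n_above_chance_onset`` counts consecutive above-chance bins starting
    at stimulus onset, the signature distinguishing the transient KC spike
    count code from the sustained PN and adaptation codes.
    """
    acc = np.asarray(accuracy, dtype=float)
    chance = 1.0 / n_classes
    on = int(round(stim_window[0] / bin_ms))
    off = int(round(stim_window[1] / bin_ms))
    k200 = max(1, int(round(200.0 / bin_ms)))
    pre = acc[:on]
    onset = acc[on: min(on + k200, acc.size)]
    plateau = acc[min(on + k200, acc.size): off]
    offset = acc[off: min(off + k200, acc.size)]
    post = acc[min(off + k200, acc.size):]
    above = acc[on:] > chance + chance_margin
    n_above = 0
    for flag in above:
        if not flag:
            break
        n_above += 1
    return DecodingSummary(
        chance=chance,
        pre_mean=float(pre.mean()) if pre.size else float("nan"),
        onset_peak=float(onset.max()) if onset.size else float("nan"),
        onset_peak_bin=int(on + np.argmax(onset)) if onset.size else -1,
        plateau_mean=float(plateau.mean()) if plateau.size else float("nan"),
        offset_peak=float(offset.max()) if offset.size else float("nan"),
        post_mean=float(post.mean()) if post.size else float("nan"),
        n_above_chance_onset=n_above,
    )
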