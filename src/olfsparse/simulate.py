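"""Trial and experiment runners around the integration kernel.

A trial consists of a 2000 ms unrecorded pre-run (spontaneous drive, to
reach the stochastic steady state from the cold start v = E_L, I_A = 0)
followed by a recorded window (default 3000 ms) containing a 1 s odor step
at t = 1000 ms.  All spike times in a :class:`TrialRecording` are relative
to the start of the recorded window.

Randomness is organised around numpy ``SeedSequence``: every (realization,
odor, trial) combination owns an independent substream derived from the
master seed, so trial sets are reproducible and order-independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np

from . import _kernel
from .network import NetworkRealization
from .params import ConditionSpec
from .stimulus import (GlomerularDrive, ReceptorProfileParams, StimulusSpec,
                       sample_glomerular_drive)

__all__ = ["TrialRecording", "run_trial", "run_experiment"]

POPULATIONS = ("pn", "ln", "kc")


@dataclass
class TrialRecording:
    """Spikes (and optionally KC adaptation-current traces) of one trial."""

    spike_ids: dict[str, np.ndarray]
    spike_times: dict[str, np.ndarray]       # ms, relative to recording start
    n_neurons: dict[str, int]
    duration: float                          # recorded duration, ms
    stimulus: StimulusSpec
    condition_label: str = ""
    trial: int = 0
    realization: int = 0
    seed: int | None = None
    kc_adaptation: np.ndarray | None = None  # (n_samples, n_kc), pA
    ia_sample_ms: float = 1.0
    probe: np.ndarray | None = None          # per-step state of neuron 0s
    labels: dict = field(default_factory=dict)

    @property
    def odor(self) -> int | None:
        return self.stimulus.k_S

    def spikes(self, population: str) -> tuple[np.ndarray, np.ndarray]:
        return self.spike_ids[population], self.spike_times[population]

    def mean_rate(self, population: str,
                  t0: float = 0.0, t1: float | None = None) -> float:
        """Population-mean firing rate (Hz) in the window [t0, t1)."""
        if t1 is None:
            t1 = self.duration
        t = self.spike_times[population]
        n = np.count_nonzero((t > t0) & (t <= t1))
        return n / self.n_neurons[population] / ((t1 - t0) * 1e-3)

    def spike_counts(self, population: str,
                     t0: float = 0.0, t1: float | None = None) -> np.ndarray:
        """Per-neuron spike counts in the window (t0, t1]."""
        if t1 is None:
            t1 = self.duration
        ids, t = self.spikes(population)
        sel = (t > t0) & (t <= t1)
        return np.bincount(ids[sel], minlength=self.n_neurons[population])

    def binned_counts(self, population: str, bin_ms: float,
                      t0: float = 0.0, t1: float | None = None) -> np.ndarray:
        """(n_neurons, n_bins) spike-count matrix on a regular grid."""
        if t1 is None:
            t1 = self.duration
        n_bins = int(round((t1 - t0) / bin_ms))
        if abs(n_bins * bin_ms - (t1 - t0)) > 1e-9:
            raise ValueError("bin width must tile the window exactly")
        ids, t = self.spikes(population)
        sel = (t > t0) & (t <= t1)
        ids, t = ids[sel], t[sel]
        b = np.minimum(((t - t0 - 1e-9) / bin_ms).astype(np.int64), n_bins - 1)
        out = np.zeros((self.n_neurons[population], n_bins), dtype=np.int64)
        np.add.at(out, (ids, b), 1)
        return out


def _child_seeds(seed) -> tuple[np.random.Generator, int]:
    ss = seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed)
    drive_ss, noise_ss = ss.spawn(2)
    noise_seed = int(noise_ss.generate_state(1, dtype=np.uint32)[0])
    return np.random.default_rng(drive_ss), noise_seed


def run_trial(
    realization: NetworkRealization,
    condition: ConditionSpec,
    stimulus: StimulusSpec,
    duration: float = 3000.0,
    prerun: float = 2000.0,
    dt: float = 0.1,
    seed: int | np.random.SeedSequence | None = None,
    record_adaptation: bool = False,
    ia_sample_ms: float = 1.0,
    noise_sample_ms: float = 1.0,
    drive: GlomerularDrive | None = None,
    profile: ReceptorProfileParams | None = None,
    probe: bool = False,
) -> TrialRecording:
    """Simulate one trial and return its labelled recording.

    All neurons start at the leak potential with zero adaptation current
    and empty conductances; the network then runs unrecorded for ``prerun``
    ms under spontaneous drive before the recorded window begins.

    Parameters
    ----------
    drive
        Pre-sampled glomerular drive covering ``prerun + duration`` ms
        (stimulus times shifted by ``prerun``); sampled internally when
        omitted.  Supplying a fixed drive makes the trial deterministic
        up to the adaptation channel noise.
    """
    if dt <= 0 or dt > 0.1 + 1e-12:
        raise ValueError("dt must be positive and at most 0.1 ms")
    rng, noise_seed = _child_seeds(seed)
    total = prerun + duration
    if drive is None:
        drive = sample_glomerular_drive(
            stimulus.shifted(prerun), total, dt,
            params=profile or ReceptorProfileParams(), rng=rng)
    if drive.n_steps != int(round(total / dt)):
        raise ValueError("drive length does not match prerun + duration")

    n = condition.neuron
    s = condition.synapse
    a = condition.adaptation
    ref_steps = int(round(n.tau_ref / dt))
    record_from = int(round(prerun / dt))
    ia_every = int(round(ia_sample_ms / dt)) if record_adaptation else 0
    noise_every = max(1, int(round(noise_sample_ms / dt)))

    (pn_id, pn_t, ln_id, ln_t, kc_id, kc_t, ia_trace, probe_trace, status
     ) = _kernel.integrate(
        drive.counts, realization.W, dt, record_from,
        condition.w_OP, condition.w_OL, condition.w_LP, condition.w_PK,
        s.E_E, s.E_I, s.tau_E, s.tau_I,
        n.c_m, n.g_L, n.E_L, n.V_R, n.V_T, ref_steps,
        a.delta_I_A, a.tau_A, a.sigma2_I,
        condition.sfa_pn, condition.sfa_ln, condition.sfa_kc,
        condition.i0, condition.i0,
        noise_seed, ia_every, noise_every, probe,
    )
    if status != 0:
        raise FloatingPointError(
            "non-finite membrane state during integration; check parameter "
            "magnitudes and dt")
    shift = prerun
    return TrialRecording(
        spike_ids={"pn": pn_id, "ln": ln_id, "kc": kc_id},
        spike_times={"pn": pn_t - shift, "ln": ln_t - shift, "kc": kc_t - shift},
        n_neurons={"pn": realization.n_glomeruli,
                   "ln": realization.n_glomeruli,
                   "kc": realization.n_kc},
        duration=duration,
        stimulus=stimulus,
        condition_label=condition.label,
        seed=None if isinstance(seed, np.random.SeedSequence) else seed,
        kc_adaptation=ia_trace if record_adaptation else None,
        ia_sample_ms=ia_sample_ms,
        probe=probe_trace if probe else None,
    )


def trial_seed(master_seed: int, realization: int, odor: int, trial: int,
               condition_index: int = 0) -> np.random.SeedSequence:
    """Deterministic, order-independent substream for one trial."""
    return np.random.SeedSequence(
        master_seed, spawn_key=(condition_index, realization, odor + 1, trial))


def run_experiment(
    conditions: Iterable[ConditionSpec],
    odors: Iterable[int | None],
    realizations: Iterable[NetworkRealization],
    n_trials: int = 50,
    master_seed: int = 0,
    duration: float = 3000.0,
    prerun: float = 2000.0,
    dt: float = 0.1,
    record_adaptation: bool = False,
    stimulus_template: StimulusSpec | None = None,
) -> Iterator[TrialRecording]:
    """Yield labelled recordings over the (condition x realization x odor x
    trial) grid.

    Every trial draws its randomness from an independent substream keyed by
    (condition index, realization index, odor, trial) under the master
    seed, so identical master seeds give bit-identical spike outputs
    regardless of iteration order or grid subsetting.
    """
    template = stimulus_template or StimulusSpec()
    for ci, cond in enumerate(conditions):
        for ri, realization in enumerate(realizations):
            for odor in odors:
                stim = (StimulusSpec.spontaneous() if odor is None else
                        StimulusSpec(odor, template.t_start, template.t_stop,
                                     template.amplitude))
                for trial in range(n_trials):
                    ss = trial_seed(master_seed, ri,
                                    -1 if odor is None else odor, trial, ci)
                    rec = run_trial(
                        realization, cond, stim,
                        duration=duration, prerun=prerun, dt=dt, seed=ss,
                        record_adaptation=record_adaptation,
                    )
                    rec.condition_label = cond.label
                    rec.trial = trial
                    rec.realization = ri
                    yield rec
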