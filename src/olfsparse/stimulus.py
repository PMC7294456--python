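"""Receptor input: odor definitions and pooled Poisson ORN drive.

Odors are indexed by a stimulus index ``k_S`` in ``0..34``.  Each of the 35
receptor types responds with a half-sine activation profile over receptor
space, so that exactly 11 types are driven by any one odor and odors with
nearby indices activate overlapping receptor sets (similar odors), while
odors more than 12 indices apart activate disjoint sets (dissimilar odors).

All 284 ORNs of one receptor type converge on a single glomerulus.  Rather
than simulating 35 x 284 individual Poisson generators, the drive to each
glomerulus is sampled directly as Poisson spike *counts* per integration
step with mean 284 * r(t) * dt — exact by the superposition property of
Poisson processes.  The same realized counts feed both the PN and the LN
of the glomerulus.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "StimulusSpec",
    "ReceptorProfileParams",
    "GlomerularDrive",
    "receptor_activation",
    "orn_rate",
    "rate_profile",
    "sample_glomerular_drive",
]


@dataclass(frozen=True)
class ReceptorProfileParams:
    """Geometry of the receptor response profile."""

    n_receptor_types: int = 35   # number of receptor types = glomeruli
    n_activated: int = 11        # receptor types driven by one odor
    r_spontaneous: float = 20.0  # spontaneous ORN rate, Hz
    n_orn_per_type: int = 284    # ORNs converging on each glomerulus

    def __post_init__(self) -> None:
        if min(self.n_receptor_types, self.n_activated, self.n_orn_per_type) <= 0:
            raise ValueError("all counts must be positive")
        if self.n_activated >= self.n_receptor_types:
            raise ValueError("n_activated must be smaller than n_receptor_types")
        if self.r_spontaneous < 0:
            raise ValueError("spontaneous rate must be non-negative")


@dataclass(frozen=True)
class StimulusSpec:
    """A 1 s odor step: which odor, when, and how strongly.

    Times are in ms relative to the start of the recorded trial window.
    ``k_S`` may be None for a stimulus-free (spontaneous-activity) trial.
    """

    k_S: int | None = 0
    t_start: float = 1000.0
    t_stop: float = 2000.0
    amplitude: float = 40.0      # peak ORN activation, Hz

    def __post_init__(self) -> None:
        if self.t_start >= self.t_stop:
            raise ValueError("t_start must precede t_stop")
        if self.k_S is not None and not 0 <= self.k_S <= 34:
            raise ValueError("odor index k_S must lie in 0..34")

    def shifted(self, offset_ms: float) -> "StimulusSpec":
        """The same stimulus on a time axis shifted by ``offset_ms``."""
        return StimulusSpec(self.k_S, self.t_start + offset_ms,
                            self.t_stop + offset_ms, self.amplitude)

    @classmethod
    def spontaneous(cls) -> "StimulusSpec":
        return cls(k_S=None)


@dataclass(frozen=True)
class GlomerularDrive:
    """Pooled ORN spike counts per glomerulus per integration step."""

    counts: np.ndarray        # (n_glomeruli, n_steps) integer counts
    dt: float                 # step width, ms
    seed: int | None = None

    @property
    def n_glomeruli(self) -> int:
        return self.counts.shape[0]

    @property
    def n_steps(self) -> int:
        return self.counts.shape[1]


def receptor_activation(
    k_RT: int,
    k_S: int,
    params: ReceptorProfileParams = ReceptorProfileParams(),
    amplitude: float = 40.0,
) -> float:
    """Evoked rate increment (Hz) of receptor type ``k_RT`` for odor ``k_S``.

    The activation follows half a sine period across receptor space:
    ``amplitude * sin(pi * x)`` for ``0 < x < 1`` with
    ``x = ((k_RT - k_S) mod N_RT) / (N_a + 1)``, zero otherwise.  Exactly
    ``n_activated`` receptor types receive a positive increment per odor.
    """
    n = params.n_receptor_types
    if not 0 <= k_RT < n:
        raise ValueError(f"receptor type index {k_RT} outside 0..{n - 1}")
    if not 0 <= k_S < n:
        raise ValueError(f"odor index {k_S} outside 0..{n - 1}")
    x = ((k_RT - k_S) % n) / (params.n_activated + 1)
    if 0.0 < x < 1.0:
        return amplitude * float(np.sin(np.pi * x))
    return 0.0


def orn_rate(
    k_RT: int,
    stimulus: StimulusSpec,
    t: float,
    params: ReceptorProfileParams = ReceptorProfileParams(),
) -> float:
    """Single-ORN firing rate (Hz) of type ``k_RT`` at time ``t`` (ms).

    Spontaneous rate plus the receptor activation inside the half-open
    stimulus window [t_start, t_stop).
    """
    if t < 0:
        raise ValueError("time must be non-negative")
    rate = params.r_spontaneous
    if stimulus.k_S is not None and stimulus.t_start <= t < stimulus.t_stop:
        rate += receptor_activation(k_RT, stimulus.k_S, params, stimulus.amplitude)
    return rate


def rate_profile(
    k_S: int,
    params: ReceptorProfileParams = ReceptorProfileParams(),
    amplitude: float = 40.0,
    evoked_only: bool = False,
) -> np.ndarray:
    """Vector of per-type ORN rates (Hz) during the stimulus for odor ``k_S``.

    With ``evoked_only`` the spontaneous baseline is omitted.  This is the
    input-level activation pattern used for input pattern correlations.
    """
    base = 0.0 if evoked_only else params.r_spontaneous
    return np.array([
        base + receptor_activation(k, k_S, params, amplitude)
        for k in range(params.n_receptor_types)
    ])


def driven_glomeruli(
    k_S: int, params: ReceptorProfileParams = ReceptorProfileParams()
) -> np.ndarray:
    """Boolean mask of glomeruli receiving positive activation for ``k_S``."""
    return rate_profile(k_S, params, evoked_only=True) > 0


def sample_glomerular_drive(
    stimulus: StimulusSpec,
    duration: float,
    dt: float,
    params: ReceptorProfileParams = ReceptorProfileParams(),
    rng: np.random.Generator | int | None = None,
) -> GlomerularDrive:
    """Sample pooled ORN spike counts for every glomerulus on the time grid.

    For glomerulus g and step k the count is Poisson with mean
    ``n_orn_per_type * r_g(t_k) * dt`` (rates in Hz, dt in ms).  The rate is
    piecewise constant, so the counts are sampled segment-by-segment.

    Parameters
    ----------
    duration
        Total drive duration in ms; must be a multiple of ``dt``.
    rng
        numpy Generator or integer seed; fixed seed gives a reproducible
        realization.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    n_steps = int(round(duration / dt))
    if abs(n_steps * dt - duration) > 1e-9 * max(1.0, duration):
        raise ValueError("duration must be an integer multiple of dt")
    seed = rng if isinstance(rng, (int, np.integer)) else None
    gen = np.random.default_rng(rng)
    n_glu = params.n_receptor_types
    counts = np.zeros((n_glu, n_steps), dtype=np.int64)
    if n_steps == 0:
        return GlomerularDrive(counts, dt, seed)

    # segment boundaries in steps: [0, start, stop, n_steps]
    spont_mean = params.n_orn_per_type * params.r_spontaneous * dt * 1e-3
    if stimulus.k_S is None:
        counts[:] = gen.poisson(spont_mean, size=(n_glu, n_steps))
        return GlomerularDrive(counts, dt, seed)

    k0 = int(np.clip(np.ceil(stimulus.t_start / dt), 0, n_steps))
    k1 = int(np.clip(np.ceil(stimulus.t_stop / dt), 0, n_steps))
    rates = rate_profile(stimulus.k_S, params, stimulus.amplitude)
    for (a, b), evoked in (((0, k0), False), ((k0, k1), True), ((k1, n_steps), False)):
        if b <= a:
            continue
        if evoked:
            mean = params.n_orn_per_type * rates * dt * 1e-3
            counts[:, a:b] = gen.poisson(mean[:, None], size=(n_glu, b - a))
        else:
            counts[:, a:b] = gen.poisson(spont_mean, size=(n_glu, b - a))
    return GlomerularDrive(counts, dt, seed)
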