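"""Network construction: glomerular layout and random PN->KC connectivity.

The antennal lobe holds 35 glomeruli, each with exactly one projection
neuron (PN) and one local interneuron (LN); both receive the pooled ORN
drive of their glomerulus.  Every LN inhibits every PN (including the PN of
its own glomerulus), implementing unspecific global lateral inhibition.
The mushroom body holds 1000 Kenyon cells (KCs); each PN->KC connection is
drawn independently with probability k_mean / n_glomeruli, so KCs receive
on average ``k_mean`` (default 12) PN inputs with binomial in-degree
variability — KCs with many inputs respond preferentially, which is part
of the mechanism, so the in-degree is deliberately not fixed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .params import DEFAULT_B, ConditionSpec, condition_weights

__all__ = ["NetworkRealization", "build_connectivity", "calibrate_b"]


@dataclass(frozen=True)
class NetworkRealization:
    """One random draw of the PN->KC wiring (the AL side is deterministic)."""

    W: np.ndarray          # (n_kc, n_glomeruli) binary connectivity matrix
    k_mean: float          # target mean in-degree
    seed: int | None       # connectivity seed

    @property
    def n_kc(self) -> int:
        return self.W.shape[0]

    @property
    def n_glomeruli(self) -> int:
        return self.W.shape[1]

    @property
    def in_degrees(self) -> np.ndarray:
        return self.W.sum(axis=1)


def build_connectivity(
    n_kc: int = 1000,
    n_glu: int = 35,
    k_mean: float = 12.0,
    seed: int | None = None,
) -> NetworkRealization:
    """Draw the random PN->KC connectivity matrix.

    Each of the ``n_kc * n_glu`` possible connections is present
    independently with probability ``k_mean / n_glu``.
    """
    if not 0 < k_mean <= n_glu:
        raise ValueError("k_mean must lie in (0, n_glomeruli]")
    rng = np.random.default_rng(seed)
    W = (rng.random((n_kc, n_glu)) < k_mean / n_glu).astype(np.float64)
    return NetworkRealization(W=W, k_mean=k_mean, seed=seed)


def calibrate_b(
    target_pn_rate: float = 8.0,
    alpha_grid: tuple[float, ...] = (0.0, 3.0, 6.0, 9.0),
    b_grid: tuple[float, ...] = (0.0, 0.02, 0.04, 0.06, 0.08),
    record_ms: float = 5000.0,
    seed: int | None = 0,
    tolerance_hz: float = 1.5,
) -> float:
    """Re-derive the feedforward compensation slope ``b`` from simulations.

    For every candidate ``b`` the full network is run without stimulus at
    each lateral-inhibition strength in ``alpha_grid`` (SFA on) and the mean
    spontaneous PN rate is measured over ``record_ms`` of recorded time; the
    ``b`` minimizing the summed squared deviation from ``target_pn_rate``
    is returned.  The shipped default ``b = 0.04`` makes this optional.

    Raises a warning (with the achieved rate profile) if no candidate keeps
    every grid point within ``tolerance_hz`` of the target.
    """
    from .simulate import run_trial  # deferred: avoid import cycle
    from .stimulus import StimulusSpec

    if record_ms <= 0:
        raise ValueError("simulation budget must be positive")
    if any(a < 0 or a > 9 for a in alpha_grid):
        raise ValueError("alpha_grid must lie within [0, 9]")
    if tuple(alpha_grid) == (0.0,):
        return DEFAULT_B  # w_OP does not depend on b at alpha = 0

    realization = build_connectivity(seed=seed)
    stim = StimulusSpec.spontaneous()
    losses = []
    profiles = []
    for b in b_grid:
        errs = []
        rates = []
        for j, alpha in enumerate(alpha_grid):
            cond = condition_weights(alpha=alpha, sfa=True, b=b)
            rec = run_trial(
                realization, cond, stim,
                duration=record_ms, prerun=2000.0,
                seed=(0 if seed is None else seed) * 1009 + j,
            )
            r = rec.mean_rate("pn")
            rates.append(r)
            errs.append((r - target_pn_rate) ** 2)
        losses.append(sum(errs))
        profiles.append(rates)
    best = int(np.argmin(losses))
    achieved = profiles[best]
    if max(abs(r - target_pn_rate) for r in achieved) > tolerance_hz:
        warnings.warn(
            "calibrate_b did not reach the target rate at every alpha; "
            f"best b={b_grid[best]:g} gives PN rates {achieved} Hz "
            f"for alpha={list(alpha_grid)}"
        )
    return float(b_grid[best])


def condition(label: str | None = None, **kwargs) -> ConditionSpec:
    """Convenience re-export of :func:`olfsparse.params.condition_weights`."""
    return condition_weights(label, **kwargs)
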