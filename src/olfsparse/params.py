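"""Model constants: cell, synapse, and adaptation parameters, and the four
canonical simulation conditions.

Units are mV, ms, nS, pF and pA throughout.  These combine consistently in
the membrane equation: conductance times driving force (nS * mV) and the
adaptation current are both in pA, and pF * mV / ms = pA.

All three neuron populations (projection neurons, local interneurons,
Kenyon cells) share a single :class:`NeuronParams` record; the model is
deliberately generic, so none of its effects can be attributed to
cell-type-specific membrane parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

__all__ = [
    "NeuronParams",
    "SynapticParams",
    "AdaptationParams",
    "ConditionSpec",
    "condition_weights",
    "CANONICAL_CONDITIONS",
    "DEFAULT_B",
]

#: Compensation slope b in w_OP = w_0 * (1 + alpha * b); chosen so that the
#: spontaneous PN rate stays near 8 Hz across lateral-inhibition strengths.
#: ``calibrate_b`` in :mod:`olfsparse.network` re-derives it from simulations.
DEFAULT_B = 0.04

#: Static compensation current (pA) replacing the dynamic adaptation current
#: in PNs and LNs when spike-frequency adaptation is disabled.
I0_COMPENSATION_PA = 380.0


@dataclass(frozen=True)
class NeuronParams:
    """Leaky integrate-and-fire cell parameters, shared by PN, LN and KC."""

    c_m: float = 289.5      # membrane capacitance, pF
    g_L: float = 28.95      # leak conductance, nS
    E_L: float = -70.0      # leak (resting) potential, mV
    V_R: float = -70.0      # reset potential, mV
    V_T: float = -57.0      # spike threshold, mV
    tau_ref: float = 5.0    # absolute refractory time, ms

    def __post_init__(self) -> None:
        if self.c_m <= 0 or self.g_L <= 0:
            raise ValueError("capacitance and leak conductance must be positive")
        if self.V_R > self.V_T:
            raise ValueError("reset potential must not exceed threshold")

    @property
    def tau_m(self) -> float:
        """Membrane time constant c_m / g_L in ms (10 ms with defaults)."""
        return self.c_m / self.g_L


@dataclass(frozen=True)
class SynapticParams:
    """Conductance-based synapse parameters."""

    E_E: float = 0.0        # excitatory reversal potential, mV
    tau_E: float = 2.0      # excitatory decay time constant, ms
    E_I: float = -75.0      # inhibitory reversal potential, mV
    tau_I: float = 10.0     # inhibitory decay time constant, ms
    w_0: float = 1.0        # base synaptic weight, nS
    w_PK: float = 5.0       # PN->KC synaptic weight, nS

    def __post_init__(self) -> None:
        if self.tau_E <= 0 or self.tau_I <= 0:
            raise ValueError("synaptic time constants must be positive")


@dataclass(frozen=True)
class AdaptationParams:
    """Spike-triggered adaptation current with diffusive channel noise.

    Each own spike increments the adaptation current I_A by ``delta_I_A``;
    I_A decays back with time constant ``tau_A`` and receives an
    Ornstein-Uhlenbeck noise term whose stationary variance is ``sigma2_I``
    (the diffusion approximation of adaptation-channel noise).
    """

    delta_I_A: float = 132.0   # spike-triggered increment, pA (0.132 nA)
    tau_A: float = 389.0       # adaptation time constant, ms
    sigma2_I: float = 87.1     # stationary variance of I_A, pA^2

    def __post_init__(self) -> None:
        if self.tau_A <= 0:
            raise ValueError("adaptation time constant must be positive")
        if self.sigma2_I < 0:
            raise ValueError("adaptation current variance must be non-negative")


@dataclass(frozen=True)
class ConditionSpec:
    """One simulation scenario: lateral-inhibition strength and SFA flags.

    The four canonical conditions are
    ``i``   no lateral inhibition, no adaptation (control),
    ``ii``  lateral inhibition only,
    ``iii`` adaptation only,
    ``iv``  lateral inhibition and adaptation (the full model).

    Lateral inhibition strength is the dimensionless factor ``alpha`` with
    w_LP = alpha * w_0, and the feedforward ORN->PN weight is compensated as
    w_OP = w_0 * (1 + alpha * b) so the spontaneous PN rate stays near 8 Hz.
    Where SFA is disabled, PNs and LNs instead receive the static current
    ``i0`` and KCs receive no adaptation current at all.
    """

    label: str
    alpha: float
    sfa_pn: bool
    sfa_ln: bool
    sfa_kc: bool
    w_OL: float = 1.0          # ORN->LN weight, nS
    w_OP: float = 1.0          # ORN->PN weight, nS
    w_LP: float = 0.0          # LN->PN weight, nS
    w_PK: float = 5.0          # PN->KC weight, nS
    i0: float = I0_COMPENSATION_PA   # static compensation current, pA
    b: float = DEFAULT_B
    neuron: NeuronParams = field(default_factory=NeuronParams)
    synapse: SynapticParams = field(default_factory=SynapticParams)
    adaptation: AdaptationParams = field(default_factory=AdaptationParams)

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError("lateral-inhibition strength alpha must be >= 0")

    @property
    def sfa_any(self) -> bool:
        return self.sfa_pn or self.sfa_ln or self.sfa_kc

    def with_overrides(self, **kwargs) -> "ConditionSpec":
        return replace(self, **kwargs)


def _make_condition(label: str, alpha: float, sfa: bool | tuple[bool, bool, bool],
                    b: float = DEFAULT_B, **kwargs) -> ConditionSpec:
    if isinstance(sfa, bool):
        sfa = (sfa, sfa, sfa)
    syn = kwargs.pop("synapse", SynapticParams())
    return ConditionSpec(
        label=label,
        alpha=alpha,
        sfa_pn=sfa[0], sfa_ln=sfa[1], sfa_kc=sfa[2],
        w_OL=syn.w_0,
        w_OP=syn.w_0 * (1.0 + alpha * b),
        w_LP=alpha * syn.w_0,
        w_PK=syn.w_PK,
        b=b,
        synapse=syn,
        **kwargs,
    )


CANONICAL_CONDITIONS = {
    "i": dict(alpha=0.0, sfa=False),
    "ii": dict(alpha=3.0, sfa=False),
    "iii": dict(alpha=0.0, sfa=True),
    "iv": dict(alpha=3.0, sfa=True),
}


def condition_weights(
    label: str | None = None,
    alpha: float | None = None,
    sfa: bool | tuple[bool, bool, bool] | None = None,
    b: float = DEFAULT_B,
    **kwargs,
) -> ConditionSpec:
    """Build a :class:`ConditionSpec` for a canonical label or a custom alpha.

    Parameters
    ----------
    label
        One of ``"i"``, ``"ii"``, ``"iii"``, ``"iv"``; reproduces the
        canonical weight table exactly.  Omit for a custom condition.
    alpha
        Lateral-inhibition strength for a custom condition (overrides the
        label's alpha if both are given).
    sfa
        Either one boolean for all populations or a (PN, LN, KC) triple.
    b
        Compensation slope for w_OP = w_0 * (1 + alpha * b).

    Examples
    --------
    >>> c = condition_weights("iv")
    >>> (c.w_OL, c.w_OP, c.w_LP, c.w_PK)
    (1.0, 1.12, 3.0, 5.0)
    """
    if label is not None and label in CANONICAL_CONDITIONS:
        base = CANONICAL_CONDITIONS[label]
        a = base["alpha"] if alpha is None else float(alpha)
        s = base["sfa"] if sfa is None else sfa
        return _make_condition(label, a, s, b=b, **kwargs)
    if alpha is None:
        raise ValueError(f"unknown condition label {label!r} and no alpha given")
    if alpha < 0:
        raise ValueError("alpha must be non-negative")
    if sfa is None:
        sfa = True
    return _make_condition(label or f"alpha={alpha:g}", float(alpha), sfa, b=b, **kwargs)
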