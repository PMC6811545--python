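"""Conductance waveforms, NMDA magnesium block, and synaptic currents.

A synaptic event at time ``t_spike`` produces, after a conduction delay, a
difference-of-exponentials conductance normalized so that its peak equals 1
at ``t_peak``.  Currents follow the driving-force convention

    I_syn = A * g_max * s(t) * (v - E_rev)        [pA, positive = outward]

so the *injected* current entering the membrane equation is ``-I_syn``:
excitatory input (E_rev above v) then depolarizes.  NMDA currents carry an
additional voltage-dependent factor G(v) in (0, 1] describing the
sigmoidal relief of the Mg2+ block with depolarization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from barrel4.params import SynapseSpec


@dataclass(frozen=True)
class MgBlockParams:
    """Voltage-dependent magnesium block of NMDA receptors."""

    a: float = 0.062  # voltage sensitivity, 1/mV
    b: float = 3.57  # Mg sensitivity constant, mM
    mg_out: float = 1.3  # extracellular Mg2+, mM

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b <= 0 or self.mg_out < 0:
            raise ValueError(f"require a > 0, b > 0, mg_out >= 0; got {self}")


def t_peak(spec: SynapseSpec) -> float:
    """Time of the conductance maximum after onset (excluding delay), ms."""
    tr, td = spec.tau_rise, spec.tau_decay
    return tr * td / (td - tr) * np.log(td / tr)


def peak_norm_factor(spec: SynapseSpec) -> float:
    """Amplitude normalization making the waveform peak exactly 1."""
    tp = t_peak(spec)
    return 1.0 / (np.exp(-tp / spec.tau_decay) - np.exp(-tp / spec.tau_rise))


def alpha_conductance(t, spec: SynapseSpec, t_spike: float = 0.0) -> np.ndarray:
    """Normalized conductance s(t) in [0, 1] for a single event.

    Zero before ``t_spike + t_conduct`` (causality); peaks at exactly 1.
    """
    t = np.asarray(t, dtype=float)
    dt = t - t_spike - spec.t_conduct
    f = peak_norm_factor(spec)
    with np.errstate(over="ignore", invalid="ignore"):
        s = f * (np.exp(-dt / spec.tau_decay) - np.exp(-dt / spec.tau_rise))
    return np.where(dt >= 0.0, s, 0.0)


def conductance_train(
    t_grid: np.ndarray,
    event_times: np.ndarray,
    amplitudes: np.ndarray,
    spec: SynapseSpec,
) -> np.ndarray:
    """Linear superposition of per-event waveforms on a time grid.

    Each event's contribution is scaled by its (short-term depression)
    amplitude factor, frozen at the event time.
    """
    event_times = np.atleast_1d(np.asarray(event_times, dtype=float))
    amplitudes = np.atleast_1d(np.asarray(amplitudes, dtype=float))
    if event_times.shape != amplitudes.shape:
        raise ValueError("event_times and amplitudes must have matching shapes")
    g = np.zeros_like(t_grid, dtype=float)
    for te, a in zip(event_times, amplitudes):
        g += a * alpha_conductance(t_grid, spec, te)
    return g


def mg_block(v, p: MgBlockParams = MgBlockParams()) -> np.ndarray:
    """Fraction of NMDA conductance unblocked at membrane potential v (mV)."""
    v = np.asarray(v, dtype=float)
    return 1.0 / (1.0 + np.exp(-p.a * v) * p.mg_out / p.b)


def syn_current(v, spec: SynapseSpec, s, a_stp=1.0, g_block=1.0) -> np.ndarray:
    """Synaptic current in pA (positive = outward).

    ``s`` is the normalized conductance, ``a_stp`` the depression amplitude
    factor in (0, 1], ``g_block`` the optional Mg-block factor for NMDA.
    """
    v = np.asarray(v, dtype=float)
    s = np.asarray(s, dtype=float)
    if np.any(s < 0):
        raise ValueError("normalized conductance must be >= 0")
    return np.asarray(a_stp) * g_block * spec.g_max * s * (v - spec.e_rev)


class ExpSynAccumulator:
    """Two-state-variable implementation of summed synaptic waveforms.

    Maintains, per target, the rise and decay exponentials of the
    difference-of-exponentials synapse.  ``add(w)`` registers weighted
    presynaptic events (already delayed and scaled by depression);
    ``advance(dt)`` decays both states; ``conductance()`` returns the summed
    normalized waveform times the registered weights.  Mathematically
    identical to the explicit per-event sum in :func:`conductance_train`.
    """

    def __init__(self, spec: SynapseSpec, n: int):
        self.spec = spec
        self._f = peak_norm_factor(spec)
        self.x_decay = np.zeros(n)
        self.x_rise = np.zeros(n)

    def add(self, w: np.ndarray) -> None:
        self.x_decay += w
        self.x_rise += w

    def advance(self, dt: float) -> None:
        self.x_decay *= np.exp(-dt / self.spec.tau_decay)
        self.x_rise *= np.exp(-dt / self.spec.tau_rise)

    def conductance(self) -> np.ndarray:
        return self._f * (self.x_decay - self.x_rise)
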