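"""Two-factor short-term synaptic depression: simulation and fitting.

The normalized amplitude of the k-th response in a train is
``A_k = D1(t_k) * D2(t_k)`` where the depression variables start at 1, are
multiplied by per-spike factors ``d1``, ``d2`` immediately *after* each
stimulus is read out, and recover exponentially towards 1 between stimuli
(first-order kinetics with time constants ``tau_d1``, ``tau_d2``).  Recovery
uses the exact exponential solution rather than Euler steps: the recovery
ODE is linear, so exactness is free.

Fitting minimises equally weighted squared residuals across depression
curves recorded at several stimulation frequencies simultaneously, using a
Levenberg-Marquardt search.  Bounds (d's in (0, 1], taus positive) are
enforced by a smooth reparameterization, with a small multi-start to guard
against local minima.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize

from barrel4.params import DepressionFixture, STPParams


@dataclass(frozen=True)
class STPState:
    """Instantaneous depression state of one synapse."""

    d1: float = 1.0
    d2: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 < self.d1 <= 1.0 and 0.0 < self.d2 <= 1.0):
            raise ValueError(f"depression variables must be in (0, 1], got {self}")

    @property
    def amplitude(self) -> float:
        return self.d1 * self.d2


def stp_on_spike(state: STPState, p: STPParams) -> STPState:
    """Apply the per-spike depression step D -> D*d."""
    return STPState(state.d1 * p.d1, state.d2 * p.d2)


def stp_recover(state: STPState, dt: float, p: STPParams) -> STPState:
    """Relax both depression variables towards 1 over ``dt`` ms (exact)."""
    if dt < 0:
        raise ValueError(f"dt must be >= 0, got {dt}")
    d1 = 1.0 - (1.0 - state.d1) * np.exp(-dt / p.tau_d1)
    d2 = 1.0 - (1.0 - state.d2) * np.exp(-dt / p.tau_d2)
    return STPState(d1, d2)


def amplitudes_at(p: STPParams, times: np.ndarray) -> np.ndarray:
    """Normalized amplitudes at arbitrary (sorted) stimulus times, ms.

    The k-th amplitude is read out *before* that stimulus's depression step.
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size == 0:
        raise ValueError("times must be a non-empty 1-D array")
    if np.any(np.diff(times) <= 0):
        raise ValueError("stimulus times must be strictly increasing")
    d1 = d2 = 1.0
    amps = np.empty(times.size)
    for k in range(times.size):
        if k > 0:
            dt = times[k] - times[k - 1]
            d1 = 1.0 - (1.0 - d1) * np.exp(-dt / p.tau_d1)
            d2 = 1.0 - (1.0 - d2) * np.exp(-dt / p.tau_d2)
        amps[k] = d1 * d2
        d1 *= p.d1
        d2 *= p.d2
    return amps


def simulate_amplitude_train(p: STPParams, frequency: float, n_stim: int) -> np.ndarray:
    """Normalized amplitudes of a regular ``n_stim``-stimulus train (Hz)."""
    if frequency <= 0:
        raise ValueError(f"frequency must be > 0, got {frequency}")
    if n_stim < 1:
        raise ValueError(f"n_stim must be >= 1, got {n_stim}")
    isi = 1000.0 / frequency
    return amplitudes_at(p, isi * np.arange(n_stim))


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class STPFit:
    params: STPParams
    residual_norm: float
    converged: bool
    n_starts: int


def _unpack(theta: np.ndarray) -> STPParams:
    # logistic for the per-spike factors, exp for the time constants
    d1 = 1.0 / (1.0 + np.exp(-theta[0]))
    d2 = 1.0 / (1.0 + np.exp(-theta[1]))
    return STPParams(min(d1, 1.0), min(d2, 1.0), np.exp(theta[2]), np.exp(theta[3]))


def _pack(p: STPParams) -> np.ndarray:
    def logit(x):
        x = np.clip(x, 1e-9, 1 - 1e-9)
        return np.log(x / (1 - x))

    return np.array([logit(p.d1), logit(p.d2), np.log(p.tau_d1), np.log(p.tau_d2)])


def fit_stp(
    curves: Mapping[float, np.ndarray] | DepressionFixture,
    n_starts: int = 3,
    seed: int = 0,
) -> STPFit:
    """Fit depression parameters jointly to curves at multiple frequencies.

    ``curves`` maps stimulation frequency (Hz) to the normalized amplitude
    train measured at that frequency.  All points are weighted equally.
    The two depression factors are exchangeable in the model, so fitted
    parameters are reported with the slow-recovering factor first
    (tau_d1 >= tau_d2).  Non-convergence is flagged, never silent.
    """
    if isinstance(curves, DepressionFixture):
        curves = curves.amplitudes
    freqs = sorted(curves)
    if len(freqs) < 2:
        raise ValueError("need curves at >= 2 frequencies")
    if any(len(curves[f]) < 3 for f in freqs):
        raise ValueError("need >= 3 stimuli per curve")

    ydata = np.concatenate([np.asarray(curves[f], dtype=float) for f in freqs])

    def residuals(theta: np.ndarray) -> np.ndarray:
        p = _unpack(theta)
        model = np.concatenate(
            [simulate_amplitude_train(p, f, len(curves[f])) for f in freqs]
        )
        return model - ydata

    rng = np.random.default_rng(seed)
    starts = [_pack(STPParams(0.7, 0.9, 50.0, 500.0))]
    for _ in range(n_starts - 1):
        starts.append(
            _pack(
                STPParams(
                    rng.uniform(0.3, 0.95),
                    rng.uniform(0.5, 0.99),
                    float(np.exp(rng.uniform(np.log(10), np.log(300)))),
                    float(np.exp(rng.uniform(np.log(100), np.log(3000)))),
                )
            )
        )

    best = None
    for x0 in starts:
        try:
            res = optimize.least_squares(residuals, x0, method="lm", xtol=1e-14, ftol=1e-14)
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise RuntimeError("all Levenberg-Marquardt starts failed")
    p = _unpack(best.x)
    # the two factors are exchangeable; report the slow-recovering one first
    if p.tau_d1 < p.tau_d2:
        p = STPParams(p.d2, p.d1, p.tau_d2, p.tau_d1)
    return STPFit(
        params=p,
        residual_norm=float(np.sqrt(2 * best.cost)),
        converged=bool(best.success),
        n_starts=len(starts),
    )


@dataclass(frozen=True)
class BiexpFit:
    """Bi-exponential decay fit y = a1*exp(-x/tau1) + a2*exp(-x/tau2) + c."""

    a1: float
    tau1: float
    a2: float
    tau2: float
    c: float
    residual_norm: float
    converged: bool

    def __call__(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return self.a1 * np.exp(-x / self.tau1) + self.a2 * np.exp(-x / self.tau2) + self.c


def fit_biexponential(x: Sequence[float], y: Sequence[float], seed: int = 0) -> BiexpFit:
    """Least-squares bi-exponential decay fit; tau1 <= tau2 by convention.

    The abscissa is whatever the caller provides (stimulus index for
    per-stimulus depression curves).  Degenerate data (effectively constant
    or single-exponential) converges with one amplitude near zero or nearly
    equal time constants; rank-deficiency is reported via ``converged``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 5:
        raise ValueError("need >= 5 points for a bi-exponential fit")
    span = max(x.max() - x.min(), 1e-9)

    def model(theta):
        a1, lt1, a2, lt2, c = theta
        return a1 * np.exp(-x / np.exp(lt1)) + a2 * np.exp(-x / np.exp(lt2)) + c

    def residuals(theta):
        return model(theta) - y

    amp = y.max() - y.min()
    rng = np.random.default_rng(seed)
    starts = [
        np.array([amp * 0.6, np.log(span / 5), amp * 0.4, np.log(span), y.min()]),
        np.array([amp * 0.5, np.log(span / 10), amp * 0.5, np.log(span * 2), y.min()]),
    ]
    for _ in range(2):
        starts.append(
            np.array(
                [
                    amp * rng.uniform(0.2, 0.8),
                    np.log(span * rng.uniform(0.05, 0.5)),
                    amp * rng.uniform(0.2, 0.8),
                    np.log(span * rng.uniform(0.5, 3.0)),
                    y.min() + amp * rng.uniform(-0.2, 0.2),
                ]
            )
        )

    best = None
    for x0 in starts:
        try:
            res = optimize.least_squares(residuals, x0, method="lm", xtol=1e-13, ftol=1e-13)
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise RuntimeError("bi-exponential fit failed from all starts")

    a1, lt1, a2, lt2, c = best.x
    t1, t2 = np.exp(lt1), np.exp(lt2)
    if t1 > t2:  # enforce tau1 <= tau2
        a1, a2, t1, t2 = a2, a1, t2, t1
    return BiexpFit(
        a1=float(a1),
        tau1=float(t1),
        a2=float(a2),
        tau2=float(t2),
        c=float(c),
        residual_norm=float(np.sqrt(2 * best.cost)),
        converged=bool(best.success),
    )
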