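"""Spike-train statistics.

Spike density functions (SDFs) smooth 1 ms-discretized spike times with a
Gaussian kernel (SD 5 ms, truncated at 3 SD, each spike's in-window mass
renormalized to exactly 1).  The van Rossum distance maps each train to a
sum of causal exponentials (decay constant tau, default 50 ms) and measures
the L2 distance between the filtered trains under the normalization

    D^2 = (1/tau) * integral (f_A - f_B)^2 dt

which makes the distance between a lone spike and an empty train equal
sqrt(1/2).  The production implementation uses the closed-form pairwise
exponential sum; a brute-force fine-grid integral is kept for testing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class VanRossumSpec:
    """Exponential-filter spike-train metric parameters."""

    tau: float = 50.0  # ms
    #: identifier of the normalization convention: 'rate' = (1/tau)*integral,
    #: lone spike vs empty train -> sqrt(1/2).
    normalization: str = "rate"

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError(f"tau must be > 0, got {self.tau}")


@dataclass
class SDF:
    """Per-trial and trial-averaged spike density on a 1 ms grid."""

    t: np.ndarray  # bin left edges, ms
    per_trial: np.ndarray  # (n_trials, n_bins), spikes per bin
    sigma: float
    truncation: float

    @property
    def mean(self) -> np.ndarray:
        return self.per_trial.mean(axis=0)


def _as_trains(raster) -> list[np.ndarray]:
    """Accept a list of spike-time arrays or a tidy raster frame."""
    if isinstance(raster, pd.DataFrame):
        return [
            np.sort(g["t_ms"].to_numpy())
            for _, g in raster.groupby("trial", sort=True)
        ]
    return [np.asarray(tr, dtype=float) for tr in raster]


def spike_density(
    raster,
    duration: float,
    sigma: float = 5.0,
    truncation: float = 3.0,
    bin_ms: float = 1.0,
) -> SDF:
    """Gaussian-kernel spike density per trial and trial-averaged.

    ``raster`` is a list of per-trial spike-time arrays (ms) or a tidy frame
    with ``trial``/``t_ms`` columns.  Each spike contributes total mass 1
    within +/- ``truncation`` * ``sigma`` of its (1 ms-discretized) time;
    kernels clipped by the raster boundaries are renormalized over the
    in-bounds window so mass is conserved.
    """
    trains = _as_trains(raster)
    n_bins = int(np.ceil(duration / bin_ms))
    t = np.arange(n_bins) * bin_ms
    half = int(np.ceil(truncation * sigma / bin_ms))
    offs = np.arange(-half, half + 1) * bin_ms
    kernel = np.exp(-0.5 * (offs / sigma) ** 2)
    out = np.zeros((max(len(trains), 1), n_bins))
    for tr_i, spikes in enumerate(trains):
        for s in spikes:
            c = int(np.floor(s / bin_ms))
            lo = max(c - half, 0)
            hi = min(c + half + 1, n_bins)
            k = kernel[lo - (c - half) : kernel.size - ((c + half + 1) - hi)]
            out[tr_i, lo:hi] += k / k.sum()
    return SDF(t=t, per_trial=out, sigma=sigma, truncation=truncation)


@dataclass(frozen=True)
class FirstSpikeStats:
    mean_latency: float  # ms, NaN if no trial spiked
    sd_latency: float  # inter-trial SD, ms
    per_trial: tuple[float, ...]  # latency per responding trial
    n_silent: int  # trials with no spike in the window


def first_spike_stats(raster, window: tuple[float, float]) -> FirstSpikeStats:
    """First-spike latency per trial relative to the window start."""
    t0, t1 = window
    trains = _as_trains(raster)
    lat = []
    n_silent = 0
    for spikes in trains:
        inwin = spikes[(spikes >= t0) & (spikes <= t1)]
        if inwin.size:
            lat.append(float(inwin[0] - t0))
        else:
            n_silent += 1
    if not lat:
        return FirstSpikeStats(np.nan, np.nan, (), n_silent)
    arr = np.asarray(lat)
    sd = float(arr.std(ddof=0)) if arr.size > 1 else 0.0
    return FirstSpikeStats(float(arr.mean()), sd, tuple(lat), n_silent)


# ---------------------------------------------------------------------------
# van Rossum distance
# ---------------------------------------------------------------------------


def _cross_sum(a: np.ndarray, b: np.ndarray, tau: float) -> float:
    if a.size == 0 or b.size == 0:
        return 0.0
    d = np.abs(a[:, None] - b[None, :])
    return float(np.exp(-d / tau).sum())


def van_rossum(
    train_a: Sequence[float],
    train_b: Sequence[float],
    spec: VanRossumSpec = VanRossumSpec(),
) -> float:
    """Closed-form van Rossum distance between two spike trains (ms times)."""
    a = np.asarray(train_a, dtype=float)
    b = np.asarray(train_b, dtype=float)
    tau = spec.tau
    d2 = 0.5 * (_cross_sum(a, a, tau) + _cross_sum(b, b, tau) - 2.0 * _cross_sum(a, b, tau))
    return float(np.sqrt(max(d2, 0.0)))


def van_rossum_grid(
    train_a: Sequence[float],
    train_b: Sequence[float],
    spec: VanRossumSpec = VanRossumSpec(),
    dt: float = 0.01,
    pad_tau: float = 20.0,
) -> float:
    """Brute-force fine-grid evaluation of the same distance (test oracle)."""
    a = np.asarray(train_a, dtype=float)
    b = np.asarray(train_b, dtype=float)
    if a.size == 0 and b.size == 0:
        return 0.0
    hi = max(a.max() if a.size else 0.0, b.max() if b.size else 0.0) + pad_tau * spec.tau
    t = np.arange(0.0, hi, dt)

    def filt(tr):
        f = np.zeros_like(t)
        for s in tr:
            m = t >= s
            f[m] += np.exp(-(t[m] - s) / spec.tau)
        return f

    diff = filt(a) - filt(b)
    return float(np.sqrt(np.trapezoid(diff**2, t) / spec.tau))


@dataclass(frozen=True)
class RateStats:
    counts: tuple[int, ...]  # spikes per trial
    mean_count: float
    count_cv: float  # trial-to-trial CV of the count (population SD / mean)
    mean_inst_freq: float  # Hz, mean of per-trial mean 1/ISI; NaN if no ISIs


def rate_stats(raster) -> RateStats:
    """Per-trial spike counts, instantaneous frequency and rate variability."""
    trains = _as_trains(raster)
    counts = tuple(int(tr.size) for tr in trains)
    arr = np.asarray(counts, dtype=float)
    mean_count = float(arr.mean()) if arr.size else 0.0
    cv = float(arr.std(ddof=0) / mean_count) if mean_count > 0 else np.nan
    inst = []
    for tr in trains:
        if tr.size >= 2:
            isi = np.diff(np.sort(tr))
            inst.append(float(np.mean(1000.0 / isi)))
    mean_inst = float(np.mean(inst)) if inst else np.nan
    return RateStats(counts, mean_count, cv, mean_inst)


@dataclass
class PopulationSummary:
    t: np.ndarray  # bin edges, ms
    synchrony: dict[str, np.ndarray]  # per population, fraction coactive per bin
    rates: dict[str, np.ndarray]  # per population, spikes per neuron per bin


def population_summary(
    raster: pd.DataFrame,
    duration: float,
    pop_sizes: dict[str, int],
    bin_ms: float = 1.0,
) -> PopulationSummary:
    """Fraction of coactive neurons per bin and Ex/In rate trajectories.

    The paired (Ex rate, In rate) series is the phase-plane trajectory of
    the population interaction.
    """
    n_bins = int(np.ceil(duration / bin_ms))
    t = np.arange(n_bins) * bin_ms
    synchrony = {}
    rates = {}
    for pop, size in pop_sizes.items():
        sub = raster[raster["population"] == pop]
        counts = np.zeros(n_bins)
        active = np.zeros(n_bins)
        if len(sub):
            bins = np.clip((sub["t_ms"].to_numpy() / bin_ms).astype(int), 0, n_bins - 1)
            np.add.at(counts, bins, 1.0)
            uniq = sub.assign(b=bins).groupby("b")["neuron"].nunique()
            active[uniq.index.to_numpy()] = uniq.to_numpy()
        n_trials = max(raster["trial"].nunique(), 1) if len(raster) else 1
        synchrony[pop] = active / (size * n_trials)
        rates[pop] = counts / (size * n_trials)
    return PopulationSummary(t=t, synchrony=synchrony, rates=rates)
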