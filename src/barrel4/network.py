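"""Recurrent spiking network of one layer-4 barrel.

800 excitatory (Ex, stellate-cell-like) and 150 inhibitory (In,
fast-spiking-like) leaky integrate-and-fire neurons are randomly connected
(no autapses) with class-specific probabilities.  Ex axons carry AMPA and
NMDA conductances (shared short-term-depression state), In axons carry
GABA_A.  External thalamocortical (TC) drive reaches 80% of each population
as AMPA + NMDA synapses activated at the stimulus-train times; the TC peak
conductances are jittered multiplicatively between trials and the
thalamorecipient subset is reshuffled per trial.

Integration is forward Euler at 0.5 ms as in the original model; spike
times are discretized to 1 ms by flooring the crossing time.  There is no
spontaneous background drive: with external weights silenced the network is
quiescent.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from barrel4.params import GenotypeParams, STPParams, SynapseSpec, sample_neuron_population
from barrel4.stp import amplitudes_at
from barrel4.synapses import MgBlockParams, peak_norm_factor, mg_block
from barrel4.units import MOHM_NS

#: Multiplier applied to the unitary TC conductance for network neurons,
#: representing the convergence of several thalamic afferents per cell
#: (placeholder; the unitary peak is the measured 1 nS).
DEFAULT_TC_GAIN = 3.0


@dataclass(frozen=True)
class StimulusTrain:
    """Thalamocortical stimulus times, optionally with an inserted oddball."""

    times: tuple[float, ...]  # ms, strictly increasing
    frequency: float  # Hz of the regular scaffold
    n_base: int
    oddball_index: int | None = None  # position of the inserted event in times

    def __post_init__(self) -> None:
        t = np.asarray(self.times)
        if t.size and np.any(np.diff(t) <= 0):
            raise ValueError("stimulus times must be strictly increasing")

    @property
    def oddball_time(self) -> float | None:
        return None if self.oddball_index is None else self.times[self.oddball_index]


def make_train(frequency: float, n_stim: int = 5, t0: float = 100.0) -> StimulusTrain:
    """Regular train of ``n_stim`` stimuli at ``frequency`` Hz starting at t0."""
    if frequency <= 0:
        raise ValueError("frequency must be > 0")
    times = t0 + np.arange(n_stim) * 1000.0 / frequency
    return StimulusTrain(tuple(times), frequency, n_stim)


def insert_oddball(train: StimulusTrain, k: int) -> StimulusTrain:
    """Insert an extra stimulus at the midpoint of inter-stimulus interval ``k``.

    ``k`` is 1-based: interval ``k`` separates regular stimuli ``k`` and
    ``k+1``, so a 5-stimulus train admits positions 1-4.  All original
    stimulus times are preserved.
    """
    if not 1 <= k < train.n_base:
        raise ValueError(f"oddball position k must satisfy 1 <= k < {train.n_base}, got {k}")
    if train.oddball_index is not None:
        raise ValueError("train already contains an oddball")
    t = list(train.times)
    t_odd = 0.5 * (t[k - 1] + t[k])
    new_times = sorted(t + [t_odd])
    return StimulusTrain(tuple(new_times), train.frequency, train.n_base, new_times.index(t_odd))


@dataclass(frozen=True)
class NetworkConfig:
    """Sizes, resolution and variability settings of the barrel network."""

    n_ex: int = 800
    n_in: int = 150
    tc_fraction: float = 0.8
    dt: float = 0.5  # ms, forward Euler step
    duration: float = 1000.0  # ms
    spike_dt: float = 1.0  # ms, spike-time discretization
    mg: MgBlockParams = field(default_factory=MgBlockParams)
    tc_gain: float = DEFAULT_TC_GAIN
    nmda_ratio: float = 0.35  # NMDA peak conductance relative to AMPA
    nmda_tau_rise: float = 2.0  # ms
    nmda_tau_decay: float = 60.0  # ms
    ext_jitter_cv: float = 0.2  # per-trial multiplicative SD of TC g_max
    sigma_log: float = 1.0  # log-SD of the Ex-Ex weight distribution
    rho_rc: float = 0.5  # shared-variance correlation of (R_in, C_m)

    def __post_init__(self) -> None:
        if self.n_ex <= 0 or self.n_in <= 0:
            raise ValueError("population sizes must be positive")
        if not 0.0 <= self.tc_fraction <= 1.0:
            raise ValueError("tc_fraction must be in [0, 1]")
        if self.dt <= 0 or self.spike_dt < self.dt:
            raise ValueError("require dt > 0 and spike_dt >= dt")


#: Recurrent connection classes as (name, pre-population, post-population).
_REC_CLASSES = (
    ("ex_ex", "ex", "ex"),
    ("ex_in", "ex", "in"),
    ("in_ex", "in", "ex"),
    ("in_in", "in", "in"),
)


@dataclass
class Network:
    """A realized network: per-neuron parameters plus weighted adjacency.

    Weight matrices are (n_post, n_pre), zero where unconnected; the
    diagonal of within-population classes is empty (no autapses).
    """

    cfg: NetworkConfig
    gen: GenotypeParams
    seed: int
    # per-neuron parameter arrays, Ex block first then In block
    r_in: np.ndarray
    c_m: np.ndarray
    v_rest: np.ndarray
    v_thresh: np.ndarray
    v_reset: np.ndarray
    t_ref: np.ndarray
    weights: dict[str, np.ndarray]
    tc_base: dict[str, np.ndarray]  # per-neuron TC weight, per population

    @property
    def n_total(self) -> int:
        return self.cfg.n_ex + self.cfg.n_in

    def population(self, i: int) -> str:
        return "ex" if i < self.cfg.n_ex else "in"


def _draw_weights(rng, n_post, n_pre, p, g_max, lognormal, sigma_log, autapse_free):
    conn = rng.random((n_post, n_pre)) < p
    if autapse_free:
        np.fill_diagonal(conn, False)
    if lognormal:
        # heavy-tailed weights with median g_max*exp(-sigma^2): the bulk sits
        # below g_max and the 99.9th percentile near g_max*exp(2*sigma)
        w = g_max * np.exp(rng.normal(-sigma_log**2, sigma_log, size=(n_post, n_pre)))
    else:
        # uniform fractional weights on (0, 1] * g_max
        w = g_max * (1.0 - rng.random((n_post, n_pre)))
    return np.where(conn, w, 0.0)


def build_network(cfg: NetworkConfig, gen: GenotypeParams, seed: int) -> Network:
    """Realize a random network from a genotype parameter set.

    Each ordered pair is connected independently with its class probability.
    Ex-Ex weights are log-normal (heavy-tailed, as observed for recurrent
    excitation); all other classes draw uniform fractional weights up to the
    class peak conductance.
    """
    rng = np.random.default_rng(seed)
    ex = sample_neuron_population(gen, "ex", cfg.n_ex, int(rng.integers(2**31)), cfg.rho_rc)
    inh = sample_neuron_population(gen, "in", cfg.n_in, int(rng.integers(2**31)), cfg.rho_rc)
    cells = list(ex) + list(inh)

    def arr(name):
        return np.array([getattr(c, name) for c in cells])

    r_in = arr("r_in")
    c_m = arr("c_m")
    # forward Euler needs the effective time constant (tau_m shortened by
    # the synaptic conductance load) to stay above dt: the rare cell
    # sampled with an extreme time constant gets its capacitance raised to
    # the stability bound (affects ~1% of draws)
    tau_floor = 20.0 * cfg.dt
    c_m = np.maximum(c_m, 1000.0 * tau_floor / r_in)

    sizes = {"ex": cfg.n_ex, "in": cfg.n_in}
    weights = {}
    for name, pre, post in _REC_CLASSES:
        spec = gen.synapses[name]
        p = gen.conn_prob.get(name, 0.0)
        weights[name] = _draw_weights(
            rng,
            sizes[post],
            sizes[pre],
            p,
            spec.g_max,
            lognormal=(name == "ex_ex"),
            sigma_log=cfg.sigma_log,
            autapse_free=(pre == post),
        )

    tc_base = {
        "ex": cfg.tc_gain * gen.synapses["tc_ex"].g_max * (1.0 - rng.random(cfg.n_ex)),
        "in": cfg.tc_gain * gen.synapses["tc_in"].g_max * (1.0 - rng.random(cfg.n_in)),
    }

    return Network(
        cfg=cfg,
        gen=gen,
        seed=seed,
        r_in=r_in,
        c_m=c_m,
        v_rest=arr("v_rest"),
        v_thresh=arr("v_thresh"),
        v_reset=arr("v_reset"),
        t_ref=arr("t_ref"),
        weights=weights,
        tc_base=tc_base,
    )


@dataclass
class SpikeRaster:
    """Tidy spike records of one trial (or a stack of trials)."""

    df: pd.DataFrame  # columns: trial, neuron, population, t_ms
    duration: float
    spike_dt: float
    train: StimulusTrain | None = None
    meta: dict = field(default_factory=dict)

    def spikes_of(self, neuron: int, trial: int | None = None) -> np.ndarray:
        m = self.df["neuron"] == neuron
        if trial is not None:
            m &= self.df["trial"] == trial
        return np.sort(self.df.loc[m, "t_ms"].to_numpy())


class _DelayedClass:
    """Synaptic bookkeeping for one connection class with a fixed delay."""

    def __init__(self, spec: SynapseSpec, n_post: int, dt: float, tau_override=None):
        tau_r = spec.tau_rise if tau_override is None else tau_override[0]
        tau_d = spec.tau_decay if tau_override is None else tau_override[1]
        self.e_rev = spec.e_rev
        self.decay_r = np.exp(-dt / tau_r)
        self.decay_d = np.exp(-dt / tau_d)
        eff = replace(spec, tau_rise=tau_r, tau_decay=tau_d)
        self.norm = peak_norm_factor(eff)
        self.delay_steps = max(int(round(spec.t_conduct / dt)), 0)
        self.x_r = np.zeros(n_post)
        self.x_d = np.zeros(n_post)
        self.buffer: dict[int, np.ndarray] = {}
        self.n_post = n_post

    def schedule(self, step: int, increment: np.ndarray) -> None:
        tgt = step + self.delay_steps
        if tgt in self.buffer:
            self.buffer[tgt] += increment
        else:
            self.buffer[tgt] = increment.copy()

    def advance(self, step: int) -> np.ndarray:
        """Decay state, deliver due events, return conductance vector (nS)."""
        self.x_r *= self.decay_r
        self.x_d *= self.decay_d
        due = self.buffer.pop(step, None)
        if due is not None:
            self.x_r += due
            self.x_d += due
        return self.norm * (self.x_d - self.x_r)


class _StpBank:
    """Per-presynaptic-neuron depression state for one connection class."""

    def __init__(self, p: STPParams | None, n_pre: int):
        self.p = p
        self.d1 = np.ones(n_pre)
        self.d2 = np.ones(n_pre)
        self.t_last = np.zeros(n_pre)

    def amplitude_and_depress(self, idx: np.ndarray, t: float) -> np.ndarray:
        if self.p is None:
            return np.ones(idx.size)
        dt = t - self.t_last[idx]
        d1 = 1.0 - (1.0 - self.d1[idx]) * np.exp(-dt / self.p.tau_d1)
        d2 = 1.0 - (1.0 - self.d2[idx]) * np.exp(-dt / self.p.tau_d2)
        amp = d1 * d2
        self.d1[idx] = d1 * self.p.d1
        self.d2[idx] = d2 * self.p.d2
        self.t_last[idx] = t
        return amp


def simulate_network(
    net: Network,
    train: StimulusTrain,
    seed: int,
    trial: int = 0,
    record_voltages: Sequence[int] | None = None,
    i_inject_pa: float | np.ndarray = 0.0,
) -> SpikeRaster:
    """Simulate one trial; returns the spike raster (+ optional voltages).

    The trial ``seed`` controls the per-trial TC conductance jitter and the
    reshuffling of the thalamorecipient subsets; identical (net, train,
    seed) gives identical rasters.
    """
    cfg = net.cfg
    dt = cfg.dt
    n_steps = int(round(cfg.duration / dt))
    n_ex, n_in = cfg.n_ex, cfg.n_in
    n = n_ex + n_in
    rng = np.random.default_rng(seed)

    # per-trial external input realisation: per-synapse multiplicative jitter
    # of the TC peak conductances
    jitter = {
        pop: np.clip(rng.normal(1.0, cfg.ext_jitter_cv, size=size), 0.0, None)
        for pop, size in (("ex", n_ex), ("in", n_in))
    }
    tc_mask = {}
    for pop, size in (("ex", n_ex), ("in", n_in)):
        k = int(round(cfg.tc_fraction * size))
        chosen = rng.choice(size, size=k, replace=False)
        m = np.zeros(size)
        m[chosen] = 1.0
        tc_mask[pop] = m
    w_ext = {pop: net.tc_base[pop] * jitter[pop] * tc_mask[pop] for pop in ("ex", "in")}

    syn = net.gen.synapses
    nmda_tau = (cfg.nmda_tau_rise, cfg.nmda_tau_decay)
    # recurrent classes: AMPA + NMDA for Ex axons, GABA for In axons
    classes = {
        "ex_ex": _DelayedClass(syn["ex_ex"], n_ex, dt),
        "ex_in": _DelayedClass(syn["ex_in"], n_in, dt),
        "in_ex": _DelayedClass(syn["in_ex"], n_ex, dt),
        "in_in": _DelayedClass(syn["in_in"], n_in, dt),
        "ex_ex_nmda": _DelayedClass(syn["ex_ex"], n_ex, dt, tau_override=nmda_tau),
        "ex_in_nmda": _DelayedClass(syn["ex_in"], n_in, dt, tau_override=nmda_tau),
        "tc_ex": _DelayedClass(syn["tc_ex"], n_ex, dt),
        "tc_in": _DelayedClass(syn["tc_in"], n_in, dt),
        "tc_ex_nmda": _DelayedClass(syn["tc_ex"], n_ex, dt, tau_override=nmda_tau),
        "tc_in_nmda": _DelayedClass(syn["tc_in"], n_in, dt, tau_override=nmda_tau),
    }
    stp = {
        "ex_ex": _StpBank(syn["ex_ex"].stp, n_ex),
        "ex_in": _StpBank(syn["ex_in"].stp, n_ex),
        "in_ex": _StpBank(syn["in_ex"].stp, n_in),
        "in_in": _StpBank(syn["in_in"].stp, n_in),
    }

    # external events: same afferent volley for all targets, so the
    # depression amplitude train is computed once per class
    stim = np.asarray(train.times, dtype=float)
    ext_amp = {
        "tc_ex": amplitudes_at(syn["tc_ex"].stp, stim) if syn["tc_ex"].stp else np.ones_like(stim),
        "tc_in": amplitudes_at(syn["tc_in"].stp, stim) if syn["tc_in"].stp else np.ones_like(stim),
    }
    for cls, pop in (("tc_ex", "ex"), ("tc_in", "in")):
        for t_s, a in zip(stim, ext_amp[cls]):
            step = int(round(t_s / dt))
            inc = a * w_ext[pop]
            classes[cls].schedule(step, inc)
            classes[cls + "_nmda"].schedule(step, cfg.nmda_ratio * inc)

    v = net.v_rest.copy()
    tau_m = net.r_in * net.c_m / 1000.0
    ref_until = np.full(n, -np.inf)
    rec_idx = np.asarray(record_voltages) if record_voltages is not None else None
    v_rec = np.empty((rec_idx.size, n_steps)) if rec_idx is not None else None

    spike_rows: list[tuple[int, str, float]] = []
    for step in range(n_steps):
        t = step * dt
        g_ex = np.zeros(n_ex)
        g_in = np.zeros(n_in)
        i_syn_ex = np.zeros(n_ex)
        i_syn_in = np.zeros(n_in)
        v_ex, v_in = v[:n_ex], v[n_ex:]
        gmb_ex = mg_block(v_ex, cfg.mg)
        gmb_in = mg_block(v_in, cfg.mg)
        for name, c in classes.items():
            g = np.clip(c.advance(step), 0.0, None)
            tgt_ex = c.n_post == n_ex
            vv = v_ex if tgt_ex else v_in
            cur = g * (vv - c.e_rev)
            if name.endswith("nmda"):
                cur = cur * (gmb_ex if tgt_ex else gmb_in)
            if tgt_ex:
                i_syn_ex += cur
            else:
                i_syn_in += cur
        i_syn = np.concatenate([i_syn_ex, i_syn_in])  # pA, positive = outward
        i_syn = i_syn - i_inject_pa  # injected current is inward-positive

        # forward Euler on tau_m dv/dt = -(v - v_rest) - R * I_syn
        dv = (-(v - net.v_rest) - net.r_in * MOHM_NS * i_syn) * (dt / tau_m)
        v = v + dv
        refractory = t < ref_until
        v[refractory] = net.v_reset[refractory]

        if np.max(np.abs(v)) > 200.0:
            raise FloatingPointError(
                f"numerical blow-up at t={t:.1f} ms (|v| > 200 mV); reduce dt or weights"
            )

        crossed = (v >= net.v_thresh) & ~refractory
        if np.any(crossed):
            idx = np.nonzero(crossed)[0]
            t_spike = np.floor(t / cfg.spike_dt) * cfg.spike_dt
            for i in idx:
                spike_rows.append((int(i), net.population(int(i)), t_spike, t))
            v[crossed] = net.v_reset[crossed]
            ref_until[crossed] = t + net.t_ref[crossed]

            ex_sp = idx[idx < n_ex]
            in_sp = idx[idx >= n_ex] - n_ex
            if ex_sp.size:
                a = stp["ex_ex"].amplitude_and_depress(ex_sp, t)
                inc = net.weights["ex_ex"][:, ex_sp] @ a
                classes["ex_ex"].schedule(step, inc)
                classes["ex_ex_nmda"].schedule(step, cfg.nmda_ratio * inc)
                a2 = stp["ex_in"].amplitude_and_depress(ex_sp, t)
                inc2 = net.weights["ex_in"][:, ex_sp] @ a2
                classes["ex_in"].schedule(step, inc2)
                classes["ex_in_nmda"].schedule(step, cfg.nmda_ratio * inc2)
            if in_sp.size:
                a = stp["in_ex"].amplitude_and_depress(in_sp, t)
                classes["in_ex"].schedule(step, net.weights["in_ex"][:, in_sp] @ a)
                a2 = stp["in_in"].amplitude_and_depress(in_sp, t)
                classes["in_in"].schedule(step, net.weights["in_in"][:, in_sp] @ a2)

        if rec_idx is not None:
            v_rec[:, step] = v[rec_idx]

    df = pd.DataFrame(spike_rows, columns=["neuron", "population", "t_ms", "t_exact"])
    df.insert(0, "trial", trial)
    meta = {"seed": seed, "network_seed": net.seed, "genotype": net.gen.label}
    if rec_idx is not None:
        meta["voltages"] = v_rec
        meta["voltage_neurons"] = rec_idx
    return SpikeRaster(df=df, duration=cfg.duration, spike_dt=cfg.spike_dt, train=train, meta=meta)


def run_experiment(
    genotypes: Mapping[str, GenotypeParams],
    trains: Sequence[StimulusTrain],
    cfg: NetworkConfig | None = None,
    n_seeds: int = 5,
    n_trials: int = 10,
    base_seed: int = 0,
) -> pd.DataFrame:
    """Run the full (genotype x network seed x trial x train) grid.

    Returns a tidy frame of spikes with provenance columns (genotype,
    net_seed, trial, frequency_hz, oddball_k).  Deterministic given
    ``base_seed``; every random draw is attributable to a derived seed.
    """
    cfg = cfg or NetworkConfig()
    frames = []
    ss = np.random.SeedSequence(base_seed)
    net_seeds = ss.generate_state(n_seeds * len(genotypes)) % (2**31)
    k = 0
    for label, gen in genotypes.items():
        for s in range(n_seeds):
            net = build_network(cfg, gen, int(net_seeds[k]))
            k += 1
            for train in trains:
                for trial in range(n_trials):
                    trial_seed = int(
                        np.random.SeedSequence([base_seed, net.seed, trial, int(train.frequency)])
                        .generate_state(1)[0] % (2**31)
                    )
                    ras = simulate_network(net, train, seed=trial_seed, trial=trial)
                    df = ras.df.copy()
                    df["genotype"] = label
                    df["net_seed"] = net.seed
                    df["frequency_hz"] = train.frequency
                    df["oddball_k"] = -1 if train.oddball_index is None else train.oddball_index
                    frames.append(df)
    frames = [f for f in frames if len(f)]  # silent trials contribute no rows
    if not frames:
        return pd.DataFrame(
            columns=["trial", "neuron", "population", "t_ms", "t_exact",
                     "genotype", "net_seed", "frequency_hz", "oddball_k"]
        )
    return pd.concat(frames, ignore_index=True)
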