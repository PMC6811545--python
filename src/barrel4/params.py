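"""Genotype parameter sets, population sampling and synthetic fixtures.

Parameter provenance
--------------------
Defaults fall into two classes, distinguished by the ``source`` tag attached
to each entry in :data:`PARAM_SOURCES`:

``"measured"``
    printed in the study this package models: passive membrane properties of
    excitatory stellate cells (input resistance, capacitance, time constant,
    resting potential), the synaptic reversal potentials (0 mV glutamatergic,
    -71 mV GABAergic), the 1 nS thalamocortical peak conductance, the
    Mg2+-block constants and the 1.5 ms refractory period.

``"placeholder"``
    constrained only qualitatively (the quantitative table was published as
    supplementary material and is not reproduced here): fast-spiking
    interneuron passive properties, synaptic kinetics, short-term-plasticity
    coefficients, the excitation-inhibition onset lag and connection
    probabilities.  Placeholder values were fixed once so that the knockout
    set is slower, more depressing and later-inhibited than wild type, and so
    that the single-cell model reproduces the study's reported model-level
    contrasts.  Every placeholder is logged at WARNING level when a default
    genotype set is constructed.

All quantities use the package unit system (mV, ms, nS, pA, pF, MOhm), see
:mod:`barrel4.units`.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from barrel4.units import tau_m_ms

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1

#: Connection classes of the layer-4 circuit. ``tc_*`` are external
#: thalamocortical inputs; the rest are recurrent.  ``ffi`` is the compound
#: disynaptic feed-forward inhibitory input used by the single-cell model
#: (its depression parameters describe the feed-forward IPSC, not the
#: unitary In->Ex synapse).
CONNECTION_CLASSES = ("tc_ex", "tc_in", "ex_ex", "ex_in", "in_ex", "in_in", "ffi")

GENOTYPES = ("WT", "KO")


@dataclass(frozen=True)
class NeuronParams:
    """Passive and threshold parameters of one leaky integrate-and-fire cell."""

    r_in: float  # input resistance, MOhm
    c_m: float  # membrane capacitance, pF
    v_rest: float  # resting potential, mV
    v_thresh: float  # spike threshold, mV
    v_reset: float  # post-spike reset, mV
    t_ref: float = 1.5  # absolute refractory period, ms

    def __post_init__(self) -> None:
        if not (self.r_in > 0 and np.isfinite(self.r_in)):
            raise ValueError(f"r_in must be positive and finite, got {self.r_in}")
        if not (self.c_m > 0 and np.isfinite(self.c_m)):
            raise ValueError(f"c_m must be positive and finite, got {self.c_m}")
        if not self.v_reset < self.v_thresh:
            raise ValueError(
                f"v_reset ({self.v_reset}) must be below v_thresh ({self.v_thresh})"
            )
        if self.t_ref < 0:
            raise ValueError(f"t_ref must be >= 0, got {self.t_ref}")

    @property
    def tau_m(self) -> float:
        """Membrane time constant R_in * C_m, ms."""
        return tau_m_ms(self.r_in, self.c_m)


@dataclass(frozen=True)
class STPParams:
    """Two-factor short-term depression parameters.

    Each presynaptic spike multiplies the depression variables D1, D2 by the
    per-spike factors ``d1``, ``d2`` (in (0, 1]); between spikes each D
    recovers exponentially towards 1 with its own time constant.
    """

    d1: float
    d2: float
    tau_d1: float  # ms
    tau_d2: float  # ms

    def __post_init__(self) -> None:
        for name in ("d1", "d2"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        for name in ("tau_d1", "tau_d2"):
            v = getattr(self, name)
            if not v > 0:
                raise ValueError(f"{name} must be > 0, got {v}")


@dataclass(frozen=True)
class SynapseSpec:
    """Kinetics, strength and plasticity of one connection class."""

    tau_rise: float  # ms
    tau_decay: float  # ms
    t_conduct: float  # conduction delay, ms
    g_max: float  # peak conductance, nS
    e_rev: float  # reversal potential, mV
    stp: STPParams | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.tau_rise < self.tau_decay:
            raise ValueError(
                "requires 0 < tau_rise < tau_decay, got "
                f"tau_rise={self.tau_rise}, tau_decay={self.tau_decay}"
                + (
                    "; equal rise and decay make the waveform singular, use "
                    "epsilon-separated constants"
                    if self.tau_rise == self.tau_decay
                    else ""
                )
            )
        if self.t_conduct < 0:
            raise ValueError(f"t_conduct must be >= 0, got {self.t_conduct}")
        if self.g_max < 0:
            raise ValueError(f"g_max must be >= 0, got {self.g_max}")


@dataclass(frozen=True)
class GenotypeParams:
    """Complete parameter set for one genotype.

    ``*_sd`` mappings give the population dispersion (SD) of the jittered
    fields; fields absent from a mapping are treated as non-jittered.
    ``conn_prob`` holds per-class connection probabilities for the recurrent
    network.  ``ei_lag`` is the onset delay of feed-forward inhibition
    relative to the thalamocortical excitation it follows.
    """

    label: str
    ex_cell: NeuronParams
    in_cell: NeuronParams
    ex_cell_sd: Mapping[str, float] = field(default_factory=dict)
    in_cell_sd: Mapping[str, float] = field(default_factory=dict)
    synapses: Mapping[str, SynapseSpec] = field(default_factory=dict)
    conn_prob: Mapping[str, float] = field(default_factory=dict)
    ei_lag: float = 2.0  # ms
    ex_rheobase: float = 72.0  # pA, minimum step current firing the Ex cell

    def __post_init__(self) -> None:
        if self.label not in GENOTYPES:
            raise ValueError(f"unknown genotype label {self.label!r}; valid: {GENOTYPES}")
        for k, p in self.conn_prob.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"connection probability {k}={p} outside [0, 1]")
        for m in (self.ex_cell_sd, self.in_cell_sd):
            for k, v in m.items():
                if v < 0:
                    raise ValueError(f"dispersion {k}={v} must be >= 0")
        if self.ei_lag < 0:
            raise ValueError(f"ei_lag must be >= 0, got {self.ei_lag}")


@dataclass(frozen=True)
class DepressionFixture:
    """Synthetic normalized depression curves with known ground truth."""

    frequencies: tuple[float, ...]  # Hz
    amplitudes: Mapping[float, np.ndarray]  # per frequency, first = 1 if noiseless
    truth: STPParams
    noise_sd: float
    seed: int


# ---------------------------------------------------------------------------
# Default genotype tables
# ---------------------------------------------------------------------------

# Spike threshold / reset of the network LIF cells (placeholders: not printed
# in the main text; resting potential -64 mV is measured).
_V_REST = -64.0
_V_THRESH = -40.0
_V_RESET = -60.0
_T_REF = 1.5

# Population SDs for excitatory cells, derived as SEM * sqrt(N) from the
# printed mean +/- SEM and cell counts (WT N=33, KO N=37).
_EX_SD = {
    "WT": {"r_in": 33.0 * np.sqrt(33), "c_m": 6.7 * np.sqrt(33), "v_rest": 1.7 * np.sqrt(33)},
    "KO": {"r_in": 43.0 * np.sqrt(37), "c_m": 4.9 * np.sqrt(37), "v_rest": 1.3 * np.sqrt(37)},
}
_IN_SD = {
    "WT": {"r_in": 60.0, "c_m": 10.0},
    "KO": {"r_in": 80.0, "c_m": 10.0},
}

# Placeholder short-term-depression coefficients per connection class.
# Knockout values depress more, and the feed-forward IPSC more than the
# EPSC, per the qualitative voltage-clamp findings.  Calibrated once against
# the study's reported single-cell model contrasts (see module docstring).
_STP = {
    "WT": {
        "tc_ex": STPParams(0.85, 0.93, 30.0, 700.0),
        "tc_in": STPParams(0.80, 0.92, 30.0, 700.0),
        "ex_ex": STPParams(0.65, 0.95, 80.0, 800.0),
        "ex_in": STPParams(0.80, 0.93, 50.0, 800.0),
        "in_ex": STPParams(0.75, 0.95, 40.0, 800.0),
        "in_in": STPParams(0.85, 0.95, 50.0, 800.0),
        "ffi": STPParams(0.59, 0.95, 30.0, 700.0),
    },
    "KO": {
        "tc_ex": STPParams(0.72, 0.80, 30.0, 700.0),
        "tc_in": STPParams(0.65, 0.88, 30.0, 700.0),
        "ex_ex": STPParams(0.65, 0.95, 80.0, 800.0),
        "ex_in": STPParams(0.65, 0.90, 50.0, 800.0),
        "in_ex": STPParams(0.55, 0.90, 60.0, 800.0),
        "in_in": STPParams(0.85, 0.95, 50.0, 800.0),
        "ffi": STPParams(0.44, 0.92, 125.0, 700.0),
    },
}

# Placeholder kinetics (ms).  Glutamatergic kinetics match between genotypes
# (no genotype difference was detected for EPSCs); knockout feed-forward
# inhibition is slower (rise, decay) and the compound disynaptic lag longer.
_KINETICS = {
    # class: (tau_rise, tau_decay, t_conduct) per genotype
    "tc_ex": {"WT": (0.5, 9.0, 1.0), "KO": (0.5, 11.2, 1.0)},
    "tc_in": {"WT": (0.4, 2.5, 1.0), "KO": (0.4, 2.5, 1.0)},
    "ex_ex": {"WT": (0.6, 3.0, 1.2), "KO": (0.6, 3.0, 1.2)},
    "ex_in": {"WT": (0.3, 1.5, 0.8), "KO": (0.3, 1.5, 0.8)},
    "in_ex": {"WT": (0.8, 7.0, 0.8), "KO": (1.0, 12.0, 0.8)},
    "in_in": {"WT": (0.8, 7.0, 0.8), "KO": (1.0, 12.0, 0.8)},
    "ffi": {"WT": (0.8, 7.0, 0.0), "KO": (1.0, 12.0, 0.0)},
}

# Peak conductances (nS).  tc_ex = 1 nS is measured (printed); the rest are
# placeholders with genotype-independent unitary strengths (connection
# strengths did not differ between genotypes).
_GMAX = {
    "tc_ex": 1.0,
    "tc_in": 1.0,
    "ex_ex": 0.55,
    "ex_in": 1.0,
    "in_ex": 1.5,
    "in_in": 1.0,
    "ffi": 1.0,  # scaled by the G/A ratio in the single-cell model
}

_E_REV = {
    "tc_ex": 0.0,
    "tc_in": 0.0,
    "ex_ex": 0.0,
    "ex_in": 0.0,
    "in_ex": -71.0,
    "in_in": -71.0,
    "ffi": -71.0,
}

# Placeholder connection probabilities (shown graphically in the source
# study): fast-spiking <-> stellate connectivity is reduced in the knockout,
# stellate-stellate connectivity is unchanged at this age.
_CONN_PROB = {
    "WT": {"ex_ex": 0.20, "ex_in": 0.45, "in_ex": 0.55, "in_in": 0.0},
    "KO": {"ex_ex": 0.20, "ex_in": 0.25, "in_ex": 0.35, "in_in": 0.0},
}

# Feed-forward inhibition onset lag after thalamocortical excitation (ms);
# longer in the knockout (placeholder magnitudes).
_EI_LAG = {"WT": 1.2, "KO": 4.3}

#: Provenance of every default entry, keyed by dotted path.
PARAM_SOURCES = {
    "ex_cell.r_in": "measured",
    "ex_cell.c_m": "measured",
    "ex_cell.v_rest": "measured",
    "ex_cell.v_thresh": "placeholder",
    "ex_cell.v_reset": "placeholder",
    "ex_cell.t_ref": "measured",
    "ex_rheobase": "measured",
    "in_cell": "placeholder",
    "synapses.tc_ex.g_max": "measured",
    "synapses.*.e_rev": "measured",
    "synapses.*.kinetics": "placeholder",
    "synapses.*.stp": "placeholder",
    "conn_prob": "placeholder",
    "ei_lag": "placeholder",
}


def default_genotype_params(label: str) -> GenotypeParams:
    """Return the full default parameter set for ``label`` ("WT" or "KO").

    Measured fields carry the printed genotype means; placeholder fields are
    documented in :data:`PARAM_SOURCES` and logged on construction.
    """
    if label not in GENOTYPES:
        raise ValueError(f"unknown genotype label {label!r}; valid labels: {list(GENOTYPES)}")

    placeholders = sorted(k for k, v in PARAM_SOURCES.items() if v == "placeholder")
    logger.warning(
        "genotype %s uses placeholder defaults for: %s", label, ", ".join(placeholders)
    )

    if label == "WT":
        ex = NeuronParams(412.0, 94.0, _V_REST, _V_THRESH, _V_RESET, _T_REF)
        inh = NeuronParams(250.0, 55.0, _V_REST, _V_THRESH, _V_RESET, _T_REF)
    else:
        ex = NeuronParams(609.0, 89.0, _V_REST, _V_THRESH, _V_RESET, _T_REF)
        inh = NeuronParams(340.0, 55.0, _V_REST, _V_THRESH, _V_RESET, _T_REF)

    synapses = {}
    for cls in CONNECTION_CLASSES:
        tr, td, tc = _KINETICS[cls][label]
        synapses[cls] = SynapseSpec(
            tau_rise=tr,
            tau_decay=td,
            t_conduct=tc,
            g_max=_GMAX[cls],
            e_rev=_E_REV[cls],
            stp=_STP[label][cls],
        )

    return GenotypeParams(
        label=label,
        ex_cell=ex,
        in_cell=inh,
        ex_cell_sd=dict(_EX_SD[label]),
        in_cell_sd=dict(_IN_SD[label]),
        synapses=synapses,
        conn_prob=dict(_CONN_PROB[label]),
        ei_lag=_EI_LAG[label],
        ex_rheobase=72.0 if label == "WT" else 44.0,
    )


# ---------------------------------------------------------------------------
# Population sampling
# ---------------------------------------------------------------------------

_MIN_POSITIVE = 1e-6


def sample_neuron_population(
    gen: GenotypeParams,
    which: str,
    n: int,
    seed: int,
    rho_rc: float = 0.5,
) -> list[NeuronParams]:
    """Draw ``n`` neuron parameter sets for population ``which`` ("ex"|"in").

    Input resistance and capacitance are sampled jointly from a bivariate
    Gaussian with correlation ``rho_rc`` (they share variance across cells);
    every other jittered field is independent Gaussian.  Scale parameters are
    clipped to stay positive, and reset/threshold ordering is preserved.
    Identical arguments (including ``seed``) give identical output.
    """
    if n < 0:
        raise ValueError(f"n must be >= 0, got {n}")
    if which not in ("ex", "in"):
        raise ValueError(f"which must be 'ex' or 'in', got {which!r}")
    if not 0.0 <= rho_rc <= 1.0:
        raise ValueError(f"rho_rc must be in [0, 1], got {rho_rc}")

    mean = gen.ex_cell if which == "ex" else gen.in_cell
    sd = dict(gen.ex_cell_sd if which == "ex" else gen.in_cell_sd)

    rng = np.random.default_rng(seed)
    s_r, s_c = sd.get("r_in", 0.0), sd.get("c_m", 0.0)
    cov = np.array(
        [[s_r**2, rho_rc * s_r * s_c], [rho_rc * s_r * s_c, s_c**2]]
    )
    # bivariate Gaussian truncated at zero by rejection resampling; a
    # degenerate (zero-dispersion) axis is held at its mean
    if s_r == 0.0 and s_c == 0.0:
        rc = np.tile([mean.r_in, mean.c_m], (n, 1)).astype(float)
    else:

        def draw(k):
            if s_r == 0.0 or s_c == 0.0:
                z = rng.normal(size=(k, 2))
                return np.column_stack(
                    [mean.r_in + s_r * z[:, 0], mean.c_m + s_c * z[:, 1]]
                )
            return rng.multivariate_normal(
                [mean.r_in, mean.c_m], cov, size=k, method="cholesky"
            )

        rc = draw(n)
        for _ in range(100):
            bad = (rc[:, 0] <= 0.0) | (rc[:, 1] <= 0.0)
            if not bad.any():
                break
            rc[bad] = draw(int(bad.sum()))
    r_in = np.clip(rc[:, 0], _MIN_POSITIVE, None)
    c_m = np.clip(rc[:, 1], _MIN_POSITIVE, None)

    out = []
    for i in range(n):
        fields = {"r_in": r_in[i], "c_m": c_m[i]}
        for name in ("v_rest", "v_thresh", "v_reset", "t_ref"):
            s = sd.get(name, 0.0)
            v = getattr(mean, name) + (rng.normal(0.0, s) if s > 0 else 0.0)
            fields[name] = v
        fields["t_ref"] = max(fields["t_ref"], 0.0)
        # keep the reset strictly below threshold under jitter
        if fields["v_reset"] >= fields["v_thresh"]:
            fields["v_reset"] = fields["v_thresh"] - 1.0
        out.append(NeuronParams(**fields))
    return out


# ---------------------------------------------------------------------------
# Synthetic depression fixtures
# ---------------------------------------------------------------------------


def generate_depression_fixture(
    stp: STPParams,
    frequencies: Sequence[float],
    n_stim: int,
    noise_sd: float,
    seed: int,
) -> DepressionFixture:
    """Generate normalized amplitude trains at several frequencies.

    Noiseless curves follow the two-factor depression recursion exactly
    (first amplitude 1); ``noise_sd`` adds i.i.d. Gaussian noise on top,
    emulating trial-averaged voltage-clamp measurement error.
    """
    from barrel4.stp import simulate_amplitude_train

    if n_stim < 2:
        raise ValueError(f"n_stim must be >= 2, got {n_stim}")
    if noise_sd < 0:
        raise ValueError(f"noise_sd must be >= 0, got {noise_sd}")
    freqs = tuple(float(f) for f in frequencies)
    if any(f <= 0 for f in freqs):
        raise ValueError("frequencies must be positive")

    rng = np.random.default_rng(seed)
    amps = {}
    for f in freqs:
        a = simulate_amplitude_train(stp, f, n_stim)
        if noise_sd > 0:
            a = a + rng.normal(0.0, noise_sd, size=a.shape)
            a = np.clip(a, _MIN_POSITIVE, None)
        amps[f] = a
    return DepressionFixture(freqs, amps, stp, noise_sd, seed)


# ---------------------------------------------------------------------------
# JSON serialization
# ---------------------------------------------------------------------------


def genotype_to_dict(gen: GenotypeParams) -> dict:
    d = dataclasses.asdict(gen)
    d["ex_cell_sd"] = dict(gen.ex_cell_sd)
    d["in_cell_sd"] = dict(gen.in_cell_sd)
    d["conn_prob"] = dict(gen.conn_prob)
    d["synapses"] = {k: dataclasses.asdict(v) for k, v in gen.synapses.items()}
    return {"schema_version": SCHEMA_VERSION, "genotype": d}


def genotype_from_dict(payload: Mapping) -> GenotypeParams:
    if "schema_version" not in payload:
        raise ValueError("missing mandatory 'schema_version' field")
    if payload["schema_version"] != SCHEMA_VERSION:
        raise ValueError(
            f"unsupported schema_version {payload['schema_version']} (expected {SCHEMA_VERSION})"
        )
    d = dict(payload["genotype"])
    d["ex_cell"] = NeuronParams(**d["ex_cell"])
    d["in_cell"] = NeuronParams(**d["in_cell"])
    syns = {}
    for k, s in d["synapses"].items():
        s = dict(s)
        if s.get("stp") is not None:
            s["stp"] = STPParams(**s["stp"])
        syns[k] = SynapseSpec(**s)
    d["synapses"] = syns
    return GenotypeParams(**d)


def save_genotype(gen: GenotypeParams, path) -> None:
    with open(path, "w") as fh:
        json.dump(genotype_to_dict(gen), fh, indent=2)


def load_genotype(path) -> GenotypeParams:
    with open(path) as fh:
        return genotype_from_dict(json.load(fh))
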