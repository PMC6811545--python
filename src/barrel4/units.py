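"""Unit conventions and conversions.

The package works in a single consistent unit system throughout:

==============  ======
quantity        unit
==============  ======
voltage         mV
time            ms
conductance     nS
current         pA
capacitance     pF
resistance      MOhm
frequency       Hz
==============  ======

These combine conveniently: nS * mV = pA, and pA / pF = mV/ms.  The two
conversions that need an explicit power of ten live here so they are written
(and tested) exactly once.
"""

#: MOhm * pF = microseconds; divide by this to obtain ms.
_US_PER_MS = 1000.0

#: MOhm * nS is dimensionless after scaling by 1e-3 (1e6 Ohm * 1e-9 S).
MOHM_NS = 1e-3


def tau_m_ms(r_in_mohm: float, c_m_pf: float) -> float:
    """Membrane time constant R*C in ms from MOhm and pF."""
    return r_in_mohm * c_m_pf / _US_PER_MS


def mohm_pa_to_mv(r_mohm: float, i_pa: float) -> float:
    """Voltage drop R*I in mV from MOhm and pA (1 MOhm * 1 pA = 1 uV)."""
    return r_mohm * i_pa * 1e-3
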