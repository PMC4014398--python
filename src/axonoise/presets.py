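"""Named axon parameter sets.

Four axon models are available: the squid giant axon with the classic
Hodgkin–Huxley kinetics (``squid_hh``) or with delayed-opening Na⁺ kinetics
(``squid_patlak``), a rat hippocampal interneuron axon (``rat_interneuron``)
and a rodent C-fibre (``c_fibre``).  Passive properties, channel densities,
single-channel conductances, reversals and temperatures follow the published
parameter table for these models; the Patlak and C-fibre (Nav1.8) kinetic
schemes are not bundled and must be supplied by the caller.
"""

from __future__ import annotations

from .cable import AxonSpec
from .kinetics import (KineticScheme, equilibrium_distribution,
                       hh_squid_schemes, wang_buzsaki_schemes)

__all__ = ["preset", "PRESET_NAMES", "SPIKE_TRAIN_PASSIVE"]

PRESET_NAMES = ("squid_hh", "squid_patlak", "rat_interneuron", "c_fibre")

#: Passive overrides used for the spike-train protocol (cortical-like
#: membrane): R_a = 70 Ω·cm, R_m = 20000 Ω·cm² (leak 0.05 mS/cm²).
SPIKE_TRAIN_PASSIVE = {"axial_resistivity": 70.0, "leak_conductance": 0.05}

_TABLE = {
    #               cm     Ra    gL     E_L     gNa dNa   gK  dK   E_Na  E_K   T
    "squid_hh":     (1.0,  35.4, 0.3,  -54.4,   20, 60.0, 20, 18.0, 50.0, -77.0, 6.3),
    "squid_patlak": (1.0,  35.4, 0.3,  -54.4,   20, 60.0, 20, 18.0, 50.0, -77.0, 6.3),
    "rat_interneuron": (1.0, 70.0, 0.1, -65.0,  15, 23.0, 14, 6.0,  55.0, -90.0, 35.0),
    "c_fibre":      (0.81, 70.0, 0.14, -61.14,  20, 62.5, 17, 10.0, 79.6, -85.0, 24.0),
}


def preset(name: str, diameter: float = 0.2, axon_length: float = 2000.0,
           compartment_length: float = 10.0,
           na_scheme: KineticScheme | None = None,
           k_scheme: KineticScheme | None = None, **overrides) -> AxonSpec:
    """Build an :class:`AxonSpec` from a named parameter set.

    ``squid_patlak`` and ``c_fibre`` have no bundled kinetic schemes (their
    rate functions live in the cited channel literature) and require
    ``na_scheme``/``k_scheme``.

    By default the leak reversal is solved so that the nominal resting
    potential (−65 mV) is a true fixed point of the full membrane (pass
    ``leak_reversal=<mV>`` to override); for the squid set this reproduces
    the tabulated −54.4 mV.
    """
    overrides.setdefault("leak_reversal", "balance")
    if name not in _TABLE:
        raise KeyError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")
    cm, ra, gl, el, g_na, d_na, g_k, d_k, e_na, e_k, temp = _TABLE[name]
    if name == "squid_hh":
        default_na, default_k = hh_squid_schemes()
    elif name == "rat_interneuron":
        default_na, default_k = wang_buzsaki_schemes()
    else:
        default_na = default_k = None
    na = na_scheme or default_na
    k = k_scheme or default_k
    if na is None or k is None:
        raise ValueError(
            f"preset {name!r} has no bundled kinetic schemes: supply na_scheme "
            "and k_scheme (the framework accepts any configured Markov scheme)"
        )
    # preset conductances/reversals take precedence over scheme defaults
    na = KineticScheme(na.name, na.states, na.transitions, na.conducting,
                       single_channel_conductance=g_na, reversal_potential=e_na)
    k = KineticScheme(k.name, k.states, k.transitions, k.conducting,
                      single_channel_conductance=g_k, reversal_potential=e_k)
    kw = dict(
        diameter=diameter,
        axon_length=axon_length,
        compartment_length=compartment_length,
        membrane_capacitance=cm,
        axial_resistivity=ra,
        leak_conductance=gl,
        leak_reversal=el,
        resting_potential=-65.0,
        channel_populations=((na, d_na), (k, d_k)),
        temperature=temp,
        name=name,
    )
    kw.update(overrides)
    if kw["leak_reversal"] == "balance":
        kw["leak_reversal"] = balance_leak_reversal(
            kw["channel_populations"], kw["leak_conductance"],
            kw["resting_potential"])
    return AxonSpec(**kw)


def balance_leak_reversal(channel_populations, leak_conductance: float,
                          v_rest: float) -> float:
    """Leak reversal that makes ``v_rest`` a true fixed point.

    All model axons rest at −65 mV; the leak battery absorbs the small
    steady window currents of the voltage-gated channels at that potential
    (for the squid parameter set this recovers the classic −54.4 mV).
    Returns E_L = v_rest + (ΣI_ion(v_rest)) / g_L with currents per area.
    """
    i_ion = 0.0  # µA/cm²
    for sch, density in channel_populations:
        pi = equilibrium_distribution(sch, v_rest)
        open_frac = float(pi[sch.conducting_indices].sum())
        g = density * sch.single_channel_conductance * 0.1 * open_frac  # mS/cm²
        i_ion += g * (v_rest - sch.reversal_potential)
    return v_rest + i_ion / leak_conductance
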