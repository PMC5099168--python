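"""Default model parameters and configuration loading.

The defaults reproduce the published parameter table of the circuit model:
ten cell groups (the mitral cell contributes two electrically coupled
compartments), thirteen projections, and the set of cholinergically
modulated parameters with their without|with endpoint values.

A configuration is a plain nested dict; :func:`default_config` builds it and
:func:`load_config` reads the same structure from YAML or JSON, merged over
the defaults so partial override files are enough.
"""

from __future__ import annotations

import copy
import json
from pathlib import Path
from typing import Any

import yaml

# Groups whose presynaptic output is a continuous rate rather than spikes.
GRADED_GROUPS = ("OSN", "PG")

#: Cell groups: label -> parameter row.  "Mi_apical" is the passive apical
#: compartment of the mitral cell (integration only, output taken at the
#: soma).  Negative theta_min values produce spontaneous activity at rest.
DEFAULT_POPULATIONS: dict[str, dict[str, Any]] = {
    "OSN": dict(spiking=False, tau=5.0, beta=1.0, theta_min=0.0, theta_max=15.0),
    "PG": dict(spiking=False, tau=2.0, beta=1.0, theta_min=0.0, theta_max=10.0),
    "Mi_apical": dict(spiking=False, tau=5.0, beta=1.0, theta_min=0.0, theta_max=15.0),
    "Mi_soma": dict(spiking=True, tau=5.0, beta=2.0, theta_min=-1.0, theta_max=7.0),
    "Gr": dict(spiking=True, tau=5.0, beta=2.0, theta_min=-0.3, theta_max=9.5),
    "Ff": dict(spiking=True, tau=5.0, beta=1.0, theta_min=-0.3, theta_max=15.0),
    "Pyr": dict(
        spiking=True, tau=10.0, beta=2.0, theta_min=0.0, theta_max=15.0,
        ahc_amplitude=10.0, ahc_tau=100.0, ahc_E=-15.0,
    ),
    "Fb": dict(spiking=True, tau=5.0, beta=2.0, theta_min=-0.03, theta_max=15.0),
    "Gb": dict(spiking=True, tau=5.0, beta=3.0, theta_min=0.0, theta_max=15.0),
    "Ac": dict(spiking=True, tau=10.0, beta=1.0, theta_min=-0.5, theta_max=15.0),
}

#: Projections: label -> row.  "identity" masks wire unit i to unit i (the
#: glomerular channels); "density" masks draw a fixed number of inputs per
#: target; Pyr->Pyr is all-to-all (no self-connections), plastic, and its
#: drive is averaged over the presynaptic population.
DEFAULT_SYNAPSES: dict[str, dict[str, Any]] = {
    "OSN->PG": dict(source="OSN", target="PG", g_max=0.166, E_N=70.0,
                    tau_rise=1.0, tau_decay=2.0, mask="identity"),
    "OSN->Mi_apical": dict(source="OSN", target="Mi_apical", g_max=0.35, E_N=70.0,
                           tau_rise=1.0, tau_decay=2.0, mask="identity"),
    "PG->Mi_apical": dict(source="PG", target="Mi_apical", g_max=0.38, E_N=-10.0,
                          tau_rise=4.0, tau_decay=8.0, mask="identity"),
    "Mi_soma->Gr": dict(source="Mi_soma", target="Gr", g_max=0.09, E_N=70.0,
                        tau_rise=1.0, tau_decay=2.0, mask="density", density=0.2),
    "Gr->Mi_soma": dict(source="Gr", target="Mi_soma", g_max=0.18, E_N=-10.0,
                        tau_rise=4.0, tau_decay=8.0, mask="density", density=0.2),
    "Mi_soma->Ff": dict(source="Mi_soma", target="Ff", g_max=0.2, E_N=70.0,
                        tau_rise=1.0, tau_decay=2.0, mask="density", density=0.2),
    "Mi_soma->Pyr": dict(source="Mi_soma", target="Pyr", g_max=0.76, E_N=70.0,
                         tau_rise=1.0, tau_decay=2.0, mask="density", density=0.2),
    "Ff->Pyr": dict(source="Ff", target="Pyr", g_max=0.055, E_N=-10.0,
                    tau_rise=4.0, tau_decay=8.0, mask="density", density=1.0),
    "Pyr->Fb": dict(source="Pyr", target="Fb", g_max=0.25, E_N=70.0,
                    tau_rise=1.0, tau_decay=2.0, mask="density", density=0.2),
    "Fb->Pyr": dict(source="Fb", target="Pyr", g_max=0.55, E_N=-10.0,
                    tau_rise=4.0, tau_decay=8.0, mask="density", density=1.0),
    "Pyr->Pyr": dict(source="Pyr", target="Pyr", g_max=650.0, E_N=70.0,
                     tau_rise=1.0, tau_decay=2.0, mask="full_no_self",
                     plastic=True, normalize=True),
    "Pyr->Gb": dict(source="Pyr", target="Gb", g_max=0.085, E_N=70.0,
                    tau_rise=1.0, tau_decay=2.0, mask="density", density=0.4),
    "Gb->Ac": dict(source="Gb", target="Ac", g_max=0.12, E_N=-10.0,
                   tau_rise=4.0, tau_decay=8.0, mask="density", density=1.0),
}

#: Cholinergically modulated parameters: (target label, parameter) ->
#: (value without modulation, value with full modulation).  Effective value
#: at modulation level M is the linear interpolation without + M*(with-without).
DEFAULT_MODULATED: list[tuple[str, str, float, float]] = [
    ("Mi_soma", "theta_max", 7.0, 3.0),
    ("PG", "theta_max", 10.0, 5.0),
    ("Gr", "theta_max", 9.5, 7.0),
    ("Fb", "theta_min", -0.03, -0.13),
    ("Fb->Pyr", "g_max", 0.55, 0.28),
    ("Pyr->Pyr", "g_max", 650.0, 300.0),
    ("Pyr", "ahc_amplitude", 10.0, 0.0),
]

#: Cholinergic loop constants.  Y_half, beta_ach, tau_ach and gain are not
#: published; the defaults come from the documented calibration procedure
#: (see neuromodulation.calibrate and docs/methods.md).  a_init is the
#: spontaneous equilibrium of the filtered cholinergic activation, so every
#: run starts at maximal modulation.
DEFAULT_NEUROMODULATION: dict[str, float] = {
    "Y_half": 0.217,
    "beta_ach": 5.25,
    "tau_ach": 100.0,
    "gain": 88.7,
    "a_init": 0.6,
}

#: Recurrent-plasticity constants.  tau_pp is calibrated (not published) so
#: that nine 1 s training sessions drive within-pattern weights close to
#: saturation; the NMDA trace constants and the axonal delay are likewise
#: calibrated defaults.
DEFAULT_PLASTICITY: dict[str, Any] = {
    "w_max": 0.4,
    "w_init_max": 0.04,
    "tau_pp": 18000.0,
    "t_delay": 1.0,
    "tau_nmda_rise": 10.0,
    "tau_nmda_fall": 100.0,
    "trace_mode": "product",  # literal product of two decays; or "difference"
    # depolarisation (mV above threshold) below which the Hebbian rule does
    # not engage -- the NMDA-receptor voltage dependence; keeps potentiation
    # specific to the strongly driven (odor-pattern) cells
    "learning_threshold": 2.5,
    # Summation convention for the association fibers: the recurrent drive is
    # g_max * sum_j(w_ij * z_j) / recurrent_divisor.  The published table
    # gives only g_max; with raw per-synapse summation at the stated weight
    # scale the recurrent input is of order 10^2-10^3 mV and the cortex
    # saturates instantly, so the drive is normalised by this calibrated
    # divisor (~ population size x kernel-integral scale).
    "recurrent_divisor": 350.0,
}

DEFAULT_SIMULATION: dict[str, float] = {
    "dt": 0.5,            # ms, Euler step
    "n_units": 100,       # units per group
    "osn_gain": 15.0,     # affinity -> OSN input voltage (theta_max of OSN)
}


def default_config() -> dict[str, Any]:
    """Full default configuration as a nested dict (deep copy, safe to edit)."""
    return copy.deepcopy(
        {
            "simulation": DEFAULT_SIMULATION,
            "populations": DEFAULT_POPULATIONS,
            "synapses": DEFAULT_SYNAPSES,
            "modulated": [list(e) for e in DEFAULT_MODULATED],
            "neuromodulation": DEFAULT_NEUROMODULATION,
            "plasticity": DEFAULT_PLASTICITY,
        }
    )


def _deep_merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for key, value in override.items():
        if key in out and isinstance(out[key], dict) and isinstance(value, dict):
            out[key] = _deep_merge(out[key], value)
        else:
            out[key] = copy.deepcopy(value)
    return out


def load_config(path: str | Path | None = None) -> dict[str, Any]:
    """Load a YAML/JSON config file merged over the defaults.

    ``None`` returns the defaults unchanged.
    """
    cfg = default_config()
    if path is None:
        return cfg
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".json",):
        override = json.loads(text)
    else:
        override = yaml.safe_load(text)
    if override is None:
        return cfg
    if not isinstance(override, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    return _deep_merge(cfg, override)


def save_config(cfg: dict[str, Any], path: str | Path) -> None:
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(cfg, indent=2))
    else:
        path.write_text(yaml.safe_dump(cfg, sort_keys=False))
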