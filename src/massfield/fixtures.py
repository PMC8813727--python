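"""Named experiment configurations for the studied regimes.

Each fixture is a complete run config (see :mod:`massfield.config`) for a
documented parameter regime: the mean-field validation run, the beta-
rebound protocol, the single-population and E-I oscillations, the 1D
bulk/standing/travelling-wave simulations, the instability-curve tracing,
and the 2D rotating-wave and localised-spot regimes.  Use
``massfield fixtures list`` / ``massfield fixtures run <name>`` or
:func:`get_fixture` programmatically.
"""

from __future__ import annotations

from .config import RunConfig, resolve_config

__all__ = ["FIXTURES", "get_fixture", "list_fixtures"]

_FIELD_1D_COMMON = {
    "eta0": 1.0, "kappa_s": 10.0, "tau": 15.0, "alpha": 0.5, "gamma": 0.5,
    "L": 125.66370614359172, "n": 256,
}
_FIELD_2D_COMMON = {
    "eta0": 2.0, "kappa_s": 12.0, "tau": 20.0, "alpha": 0.5, "gamma": 0.5,
}

FIXTURES: dict[str, dict] = {
    "mass_vs_network": {
        "model": "network",
        "params": {"N": 1000, "eta0": 2.0, "gamma": 0.5, "tau": 16.0,
                   "kappa_v": 1.0, "kappa_s": 1.0, "alpha": 0.5, "T": 2000.0},
        "experiment": {"compare_mass": True, "window": 5.0},
    },
    "mass_limit_cycle": {
        "model": "mass",
        "params": {"eta0": 1.0, "kappa_v": 1.2, "kappa_s": 1.0, "tau": 15.0,
                   "alpha": 0.5, "gamma": 0.5},
        "numerics": {"T": 3000.0, "dt": 1.0},
    },
    "mass_hopf_locus": {
        "model": "mass",
        "params": {"eta0": 1.0, "kappa_s": 1.0, "tau": 15.0, "alpha": 0.5,
                   "gamma": 0.5},
        "experiment": {"kind": "hopf-locus", "gammas": [0.25, 0.5, 1.0],
                       "eta0_range": [0.25, 4.0, 16]},
    },
    "beta_rebound_weak": {
        "model": "mass",
        "params": {"eta0": 1.0, "kappa_v": 0.5, "kappa_s": 1.0, "tau": 15.0,
                   "alpha": 0.1, "gamma": 0.5},
        "experiment": {"kind": "beta-rebound", "pulse_duration": 400.0,
                       "pulse_magnitude": 3.0, "tau_f": 50.0},
    },
    "beta_rebound_intermediate": {
        "model": "mass",
        "params": {"eta0": 1.0, "kappa_v": 1.0, "kappa_s": 1.0, "tau": 15.0,
                   "alpha": 0.1, "gamma": 0.5},
        "experiment": {"kind": "beta-rebound", "pulse_duration": 400.0,
                       "pulse_magnitude": 3.0, "tau_f": 50.0},
    },
    "beta_rebound_strong": {
        "model": "mass",
        "params": {"eta0": 1.0, "kappa_v": 1.5, "kappa_s": 1.0, "tau": 15.0,
                   "alpha": 0.1, "gamma": 0.5},
        "experiment": {"kind": "beta-rebound", "pulse_duration": 400.0,
                       "pulse_magnitude": 3.0, "tau_f": 50.0},
    },
    "ei_bursting": {
        "model": "ei",
        "params": {"eta0_E": 5.0, "eta0_I": -3.0, "kappa_v_E": 0.5,
                   "kappa_v_I": 0.5},
        "numerics": {"T": 600.0, "dt": 0.05},
    },
    "ei_coexistence_sweep": {
        "model": "ei",
        "params": {"eta0_E": 5.0, "kappa_v_E": 0.0, "kappa_v_I": 0.5},
        "experiment": {"kind": "sweep", "free": "eta0_I",
                       "from": -15.0, "to": 8.0, "step": 0.25},
    },
    "fig8_turing_curves": {
        "model": "field1d",
        "params": {**_FIELD_1D_COMMON, "c": 1.0, "kappa_v": 0.85},
        "experiment": {"kind": "instability-curves",
                       "c_values": [0.05, 0.08, 0.1, 0.12, 0.15, 0.2, 0.3,
                                    0.5, 0.8, 1.0, 1.5, 2.0]},
    },
    "field1d_bulk": {
        "model": "field1d",
        "params": {**_FIELD_1D_COMMON, "c": 0.1, "kappa_v": 0.85},
        "experiment": {"ic": "uniform+noise", "amplitude": 5e-3, "seed": 1},
        "numerics": {"T": 12000.0, "save_every": 4.0},
    },
    "field1d_standing": {
        "model": "field1d",
        "params": {**_FIELD_1D_COMMON, "c": 0.11, "kappa_v": 0.855},
        "experiment": {"ic": "uniform+noise", "amplitude": 5e-3, "seed": 1},
        "numerics": {"T": 12000.0, "save_every": 4.0},
    },
    "field1d_travelling": {
        "model": "field1d",
        "params": {**_FIELD_1D_COMMON, "c": 1.0, "kappa_v": 0.88},
        "experiment": {"ic": "uniform+noise", "amplitude": 5e-3, "seed": 1},
        "numerics": {"T": 12000.0, "save_every": 4.0},
    },
    "field2d_rotating_waves": {
        "model": "field2d",
        "params": {**_FIELD_2D_COMMON, "c": 1.0, "kappa_v": 0.695,
                   "L": 30.0, "n": 64},
        "experiment": {"ic": "periodic-lattice", "amplitude": 5e-3,
                       "n_cells": 4, "noise": 1e-3, "seed": 0},
        "numerics": {"T": 4600.0, "save_every": 2.0, "save_start": 3200.0},
    },
    "field2d_spirals": {
        "model": "field2d",
        "params": {**_FIELD_2D_COMMON, "c": 1.0, "kappa_v": 0.8,
                   "L": 30.0, "n": 64},
        "experiment": {"ic": "periodic-lattice", "amplitude": 5e-3,
                       "n_cells": 4, "noise": 1e-3, "seed": 0},
        "numerics": {"T": 4600.0, "save_every": 2.0, "save_start": 3200.0},
    },
    "field2d_oscillating_spots": {
        "model": "field2d",
        "params": {"eta0": 0.1, "kappa_s": -25.0, "tau": 1.0, "alpha": 5.0,
                   "gamma": 0.5, "c": 10.0, "kappa_v": 1.0, "L": 30.0, "n": 64},
        "experiment": {"ic": "uniform+noise", "amplitude": 0.05, "seed": 0},
        "numerics": {"T": 400.0, "save_every": 1.0},
    },
}


def list_fixtures() -> list[str]:
    return sorted(FIXTURES)


def get_fixture(name: str) -> RunConfig:
    if name not in FIXTURES:
        raise KeyError(f"unknown fixture {name!r}; available: {list_fixtures()}")
    return resolve_config({k: (dict(v) if isinstance(v, dict) else v)
                           for k, v in FIXTURES[name].items()})
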