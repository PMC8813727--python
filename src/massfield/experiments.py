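"""End-to-end experiment drivers for the headline analyses.

These functions tie the modules together into the studied protocols: the
two-parameter instability diagram of the 1D field with its codimension-2
crossing, the E-I bistability window located by attractor sweeps, and the
2D rotating-wave synchrony measurements.  They are used by the acceptance
script and the heavier tests, and are runnable from the fixtures.
"""

from __future__ import annotations

import numpy as np

from .bifurcation import _ei_run, refine_branch_edge
from .field import make_initial_condition, simulate_field
from .mass import ei_fixed_point
from .params import EIParams, FieldParams, MassParams
from .stability import instability_curves

__all__ = [
    "WAVE_REGIME_1D",
    "ROTATING_WAVE_REGIME_2D",
    "EI_INHIBITORY_GAP_REGIME",
    "turing_hopf_crossing",
    "ei_coexistence_edges",
    "rotating_wave_synchrony",
]

#: 1D field regime of the two-parameter (c, kappa_v) instability diagram
WAVE_REGIME_1D = MassParams(eta0=1.0, kappa_s=10.0, tau=15.0, alpha=0.5, gamma=0.5)

#: 2D field regime supporting rotating waves and spirals
ROTATING_WAVE_REGIME_2D = MassParams(eta0=2.0, kappa_s=12.0, tau=20.0, alpha=0.5,
                                     gamma=0.5)

#: E-I regime with gap junctions in the inhibitory population only
EI_INHIBITORY_GAP_REGIME = EIParams(kappa_v_E=0.0, kappa_v_I=0.5)


def turing_hopf_crossing(
    mass: MassParams = WAVE_REGIME_1D,
    c_values: np.ndarray | None = None,
    kv_bracket: tuple[float, float] = (0.05, 3.0),
    nk: int = 161,
    tol: float = 1e-6,
) -> dict:
    """Hopf / Turing-Hopf thresholds over c, their crossing, and the floor.

    Returns a dict with the two :class:`InstabilityCurve` objects, the
    codimension-2 crossing speed ``c_star`` (where the two thresholds
    exchange order) and the stability floor ``kv_min`` = min over c of the
    first-instability gap-junction strength.
    """
    if c_values is None:
        c_values = np.array([0.05, 0.08, 0.1, 0.12, 0.15, 0.2, 0.25, 0.3,
                             0.5, 0.8, 1.0, 1.5, 2.0])
    p = FieldParams(mass=mass, c=1.0, dim=1)
    return instability_curves(p, np.asarray(c_values, dtype=float),
                              kv_bracket=kv_bracket, nk=nk, tol=tol)


def ei_coexistence_edges(
    p: EIParams = EI_INHIBITORY_GAP_REGIME,
    refine_T: float = 1500.0,
    edge_tol: float = 0.05,
    rtol: float = 1e-6,
) -> dict:
    """Edges of the window where two stable oscillations coexist (Fig-7b-type
    regime): continuation sweeps place one state on each branch, then each
    branch is continued into its bracket by bisection until it is lost.

    The high-amplitude branch (R_I peaks of several) is born at the lower
    edge; the moderate-amplitude branch (R_I peaks of order one) dies at the
    upper edge.  Identity is decided by the R_I maximum.
    """

    def run(eta, s0, T=400.0):
        return _ei_run(p.replace(eta0_I=float(eta)), s0, T, T / 2, 0.05, rtol)

    # place a state on the high-amplitude branch by backward continuation
    s = ei_fixed_point(p.replace(eta0_I=4.0)) + np.array([2, 1, 2, 1] + [0] * 8)
    for eta in (2.0, 0.0, -2.0, -4.0, -6.0):
        summ = run(eta, s)
        s = summ.end_state
    if summ.extrema["R_I"][1] <= 3.0:
        raise RuntimeError("failed to land on the high-amplitude branch")
    lower = refine_branch_edge(p, "eta0_I", -6.0, -9.5, s,
                               on_branch=lambda s: s.extrema["R_I"][1] > 3.0,
                               T=refine_T, tol=edge_tol, rtol=rtol)

    # place a state on the moderate branch by forward continuation
    s = ei_fixed_point(p.replace(eta0_I=-12.0)) + 1e-2
    for eta in (-12.0, -10.0, -8.0, -6.0, -5.0):
        summ = run(eta, s)
        s = summ.end_state
    if not summ.extrema["R_I"][1] < 3.0:
        raise RuntimeError("failed to land on the moderate-amplitude branch")
    upper = refine_branch_edge(p, "eta0_I", -5.0, -2.0, s,
                               on_branch=lambda s: s.extrema["R_I"][1] < 3.0,
                               T=refine_T, tol=edge_tol, rtol=rtol)
    return {"lower": lower, "upper": upper}


def rotating_wave_synchrony(
    kappa_v: float,
    seed: int = 0,
    mass: MassParams = ROTATING_WAVE_REGIME_2D,
    c: float = 1.0,
    L: float = 30.0,
    n: int = 64,
    n_cells: int = 4,
    amplitude: float = 5e-3,
    noise: float = 1e-3,
    T_transient: float = 3200.0,
    T_measure: float = 1400.0,
) -> dict:
    """Post-transient |Z| range at a probe near a rotating-wave core.

    The uniform state is perturbed with a spatially periodic lattice (cell
    count matched to the critical wavenumber) plus seeded symmetry-breaking
    noise; after the transient the probe is the grid point with the largest
    temporal standard deviation of |Z|, which sits next to a core where the
    synchrony swings most.  Returns the probe extrema and the global |Z|
    range.
    """
    p = FieldParams(mass=mass.replace(kappa_v=kappa_v), c=c, dim=2, L=L, n=n)
    ic = make_initial_condition(p, "periodic-lattice", amplitude=amplitude,
                                n_cells=n_cells, noise=noise, seed=seed)
    settle = simulate_field(p, ic, T=T_transient, save_every=50.0)
    meas = simulate_field(p, settle.final_state, T=T_measure, save_every=2.0)
    absZ = np.abs(meas.Z)
    std = absZ.std(axis=0)
    i, j = np.unravel_index(int(np.argmax(std)), std.shape)
    probe = absZ[:, i, j]
    return {
        "probe": (int(i), int(j)),
        "probe_min": float(probe.min()),
        "probe_max": float(probe.max()),
        "global_min": float(absZ.min()),
        "global_max": float(absZ.max()),
    }
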