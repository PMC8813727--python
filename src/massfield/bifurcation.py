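"""One-parameter attractor sweeps and Hopf detection for the mass models.

Stable attractors are found by direct simulation: forward and backward
sweeps that continue each attractor's end state to the next parameter value
(attractor continuation), plus perturbed-fixed-point and large-kick initial
conditions at every grid point.  Trajectories are classified as fixed point
or limit cycle from their post-transient extrema; coexistence windows are
maximal parameter intervals on which at least two distinct stable
oscillations are observed, with edges sharpened by bisection that continues
the dying branch from its nearest surviving state.

Unstable orbits are not continued; everything reported is an attractor of
the flow.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mass import ei_fixed_point, mass_fixed_points, simulate_ei
from .observables import OSCILLATION_AMPLITUDE_TOL, oscillation_extrema
from .params import EIParams, MassParams

__all__ = [
    "AttractorSummary",
    "hopf_point_1param",
    "classify_trajectory",
    "sweep_attractors",
    "coexistence_windows",
    "refine_branch_edge",
]


class FoldError(RuntimeError):
    """Raised when the tracked fixed point disappears inside the bracket."""


def hopf_point_1param(
    p: MassParams,
    free: str = "kappa_v",
    bracket: tuple[float, float] = (0.0, 1.2),
    tol: float = 1e-8,
) -> float:
    """Hopf bifurcation of the single-population fixed point by bisection.

    Bisects ``max Re(eig J)`` of the principal fixed point over ``free``;
    requires a complex pair at the crossing and raises :class:`FoldError`
    if the fixed point vanishes inside the bracket.
    """

    def max_re(v: float) -> tuple[float, float]:
        fps = mass_fixed_points(p.replace(**{free: v}))
        if not fps:
            raise FoldError(f"fixed point disappeared at {free} = {v}")
        ev = fps[-1].eigenvalues
        i = int(np.argmax(ev.real))
        return float(ev.real[i]), abs(float(ev.imag[i]))

    lo, hi = bracket
    g_lo, _ = max_re(lo)
    g_hi, _ = max_re(hi)
    if g_lo * g_hi > 0:
        raise ValueError(f"no eigenvalue sign change over {free} in {bracket}")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        g_mid, _ = max_re(mid)
        if g_mid * g_lo <= 0:
            hi = mid
        else:
            lo, g_lo = mid, g_mid
    value = 0.5 * (lo + hi)
    _, om = max_re(value)
    if om <= 1e-8:
        raise ValueError("eigenvalue crossing is real (not a Hopf point)")
    return value


@dataclass
class AttractorSummary:
    """Post-transient classification of one trajectory."""

    param: float
    ic_id: str
    kind: str  # fixed-point | limit-cycle | undetermined
    extrema: dict
    period: float
    end_state: np.ndarray


def classify_trajectory(t, series: dict, amplitude_tol: float = OSCILLATION_AMPLITUDE_TOL,
                        min_periods: int = 5) -> tuple[str, dict, float]:
    """(kind, extrema, period) of post-transient series keyed by variable."""
    extrema = {}
    period = np.nan
    primary = next(iter(series))
    for name, x in series.items():
        lo, hi, per = oscillation_extrema(x, t, transient_fraction=0.0)
        extrema[name] = (lo, hi)
        if name == primary:
            period = per
    amp = extrema[primary][1] - extrema[primary][0]
    if amp <= amplitude_tol:
        return "fixed-point", extrema, np.nan
    # guard against decaying transients: amplitude must not collapse over
    # the second half of the window
    x = np.asarray(series[primary], dtype=float)
    half = len(x) // 2
    amp1, amp2 = np.ptp(x[:half]), np.ptp(x[half:])
    if amp2 <= amplitude_tol:
        return "fixed-point", extrema, np.nan
    if amp2 < 0.5 * amp1:
        return "undetermined", extrema, period
    if not np.isfinite(period) or (t[-1] - t[0]) / period < min_periods:
        return "undetermined", extrema, period
    return "limit-cycle", extrema, period


def _ei_run(p: EIParams, s0, T, transient, dt, rtol) -> AttractorSummary:
    tr = simulate_ei(p, s0=s0, T=T, dt=dt, rtol=rtol, atol=1e-9)
    sel = tr.t >= transient
    kind, extrema, period = classify_trajectory(
        tr.t[sel], {"R_I": tr.y[2][sel], "R_E": tr.y[0][sel]})
    return AttractorSummary(param=np.nan, ic_id="", kind=kind, extrema=extrema,
                            period=period, end_state=tr.y[:, -1].copy())


def _default_ei_ics(p: EIParams, rng: np.random.Generator) -> dict[str, np.ndarray]:
    ics: dict[str, np.ndarray] = {}
    try:
        fp = ei_fixed_point(p)
        ics["fp+eps"] = fp + 1e-2
        ics["kick"] = fp + np.array([2.0, 1.0, 2.0, 1.0] + [0.0] * 8)
    except RuntimeError:
        ics["kick"] = np.array([2.0, 0.0, 2.0, 0.0] + [1.0, 0.0] * 4)
    return ics


def sweep_attractors(
    p: EIParams,
    free: str = "eta0_I",
    grid: np.ndarray | None = None,
    T: float = 400.0,
    transient: float = 200.0,
    dt: float = 0.05,
    rtol: float = 1e-6,
    seed: int = 0,
) -> pd.DataFrame:
    """Forward/backward continuation sweep of the E-I model attractors.

    For each value of ``free`` the runs are: continuation of the previous
    forward attractor, continuation of the previous backward attractor, a
    perturbed fixed point and a large-amplitude kick.  Returns one row per
    (value, initial condition) with kind, R_E/R_I extrema and period.
    """
    if grid is None:
        grid = np.arange(-15.0, 10.01, 0.25)
    grid = np.asarray(grid, dtype=float)
    rng = np.random.default_rng(seed)

    rows = []
    carry = {"fwd": None, "bwd": None}
    for direction, values in (("fwd", grid), ("bwd", grid[::-1])):
        state = None
        for v in values:
            pv = p.replace(**{free: float(v)})
            ics = _default_ei_ics(pv, rng)
            if state is not None:
                ics = {direction: state, **ics}
            else:
                ics = {direction: next(iter(ics.values())), **ics}
            for ic_id, s0 in ics.items():
                if direction == "bwd" and ic_id in ("fp+eps", "kick"):
                    continue  # static ICs already run in the forward pass
                try:
                    summ = _ei_run(pv, s0, T, transient, dt, rtol)
                except RuntimeError:
                    summ = AttractorSummary(param=float(v), ic_id=ic_id,
                                            kind="undetermined", extrema={},
                                            period=np.nan, end_state=None)
                summ.param = float(v)
                summ.ic_id = ic_id
                rows.append(summ)
                if ic_id == direction and summ.end_state is not None:
                    state = summ.end_state

    recs = []
    for s in rows:
        rec = {"param": s.param, "ic_id": s.ic_id, "kind": s.kind, "period": s.period}
        for var in ("R_I", "R_E"):
            lo, hi = s.extrema.get(var, (np.nan, np.nan))
            rec[f"{var}_min"], rec[f"{var}_max"] = lo, hi
        recs.append(rec)
    return pd.DataFrame(recs)


def _distinct(a: tuple[float, float], b: tuple[float, float],
              noise_floor: float = 0.02) -> bool:
    """Two oscillations are distinct if their extrema differ clearly."""
    tol = 5.0 * noise_floor + 0.1 * max(abs(a[0]), abs(a[1]), abs(b[0]), abs(b[1]))
    return abs(a[0] - b[0]) > tol or abs(a[1] - b[1]) > tol


def coexistence_windows(df: pd.DataFrame, var: str = "R_I",
                        noise_floor: float = 0.02) -> list[tuple[float, float]]:
    """Maximal parameter intervals with >= 2 distinct stable oscillations."""
    flags = {}
    for v, grp in df[df.kind == "limit-cycle"].groupby("param"):
        ext = list(zip(grp[f"{var}_min"], grp[f"{var}_max"]))
        found = []
        for e in ext:
            if not any(not _distinct(e, f, noise_floor) for f in found):
                found.append(e)
        flags[v] = len(found) >= 2
    vals = sorted(flags)
    windows = []
    start = None
    for v in vals:
        if flags[v] and start is None:
            start = v
        if not flags[v] and start is not None:
            windows.append((start, prev))
            start = None
        prev = v
    if start is not None:
        windows.append((start, vals[-1]))
    return windows


def refine_branch_edge(
    p: EIParams,
    free: str,
    survive_at: float,
    die_at: float,
    branch_state: np.ndarray,
    on_branch,
    T: float = 1500.0,
    transient: float = 500.0,
    dt: float = 0.05,
    rtol: float = 1e-6,
    tol: float = 0.05,
) -> float:
    """Bisect the parameter at which a stable branch is lost.

    Continues the branch from its nearest surviving state toward the edge;
    ``on_branch(summary)`` decides branch identity from the post-transient
    extrema.  Returns the midpoint of the final bracket.
    """
    state = np.array(branch_state, dtype=float)
    lo, hi = survive_at, die_at
    while abs(hi - lo) > tol:
        mid = 0.5 * (lo + hi)
        summ = _ei_run(p.replace(**{free: float(mid)}), state, T, transient, dt, rtol)
        if summ.kind == "limit-cycle" and on_branch(summ):
            lo = mid
            state = summ.end_state
        else:
            hi = mid
    return 0.5 * (lo + hi)
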