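"""Exact mean-field (neural mass) models of coupled QIF populations.

The single-population model evolves the instantaneous firing rate ``R``, the
average membrane potential ``V`` and the synaptic activity ``U``::

    tau dR/dt = -kappa_v R + 2 R V + gamma / (pi tau)
    tau dV/dt = eta0 + A(t) + V^2 - pi^2 tau^2 R^2 + kappa_s U
    Q U       = R,      Q = (1 + alpha^-1 d/dt)^2

with the second-order synaptic operator ``Q`` written in state-space form
``d2U/dt2 = alpha^2 (R - U) - 2 alpha dU/dt``.  An external drive ``A(t)``
(e.g. a stimulation current) enters as ``eta0 -> eta0 + A(t)``.

The complex Kuramoto order parameter is obtained from ``(R, V)`` through the
conformal (Moebius) map ``Z = (1 - W*) / (1 + W*)`` with ``W = pi tau R + iV``;
``|Z| = 1`` is full within-population synchrony and ``|Z| = 0`` full
asynchrony.

The two-population extension couples an excitatory and an inhibitory
population through four synaptic variables ``U_ab`` (target ``a``, source
``b``), each with its own rise rate ``alpha_ab``; gap junctions act only
within a population.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import fsolve

from .params import CONNECTIONS, EIParams, MassParams

__all__ = [
    "to_kuramoto",
    "from_kuramoto",
    "mass_rhs",
    "mass_jacobian",
    "mass_fixed_points",
    "FixedPoint",
    "simulate_mass",
    "filtered_pulse",
    "make_pulse",
    "ei_rhs",
    "make_ei_rhs",
    "ei_fixed_point",
    "simulate_ei",
    "MassTrajectory",
    "EITrajectory",
    "EI_STATE_LABELS",
]


# ---------------------------------------------------------------------------
# conformal map between (R, V) and the Kuramoto order parameter


def to_kuramoto(R, V, tau):
    """Map firing rate and mean voltage to the Kuramoto order parameter.

    ``Z = (1 - W*)/(1 + W*)`` with ``W = pi tau R + i V``.  For ``R >= 0``
    the map sends the right half-plane onto the unit disc, so ``|Z| <= 1``.
    Accepts scalars or arrays (broadcast).
    """
    W_conj = np.pi * tau * np.asarray(R, dtype=float) - 1j * np.asarray(V, dtype=float)
    denom = 1.0 + W_conj
    if np.any(denom == 0):
        raise ZeroDivisionError("conformal map undefined at W = -1 (requires R < 0)")
    return (1.0 - W_conj) / denom


def from_kuramoto(Z, tau):
    """Inverse conformal map: recover ``(R, V)`` from ``Z``."""
    Z_conj = np.conj(np.asarray(Z))
    W = (1.0 - Z_conj) / (1.0 + Z_conj)
    return W.real / (np.pi * tau), W.imag


# ---------------------------------------------------------------------------
# single population

#: state vector layout of the single-population model
STATE_LABELS = ("R", "V", "U", "Udot")


def mass_rhs(y, p: MassParams, A: float = 0.0):
    """Time derivative of the state ``y = (R, V, U, Udot)``.

    ``A`` is the instantaneous external drive added to ``eta0``.
    """
    R, V, U, Ud = y
    dR = (-p.kappa_v * R + 2.0 * R * V + p.gamma / (np.pi * p.tau)) / p.tau
    dV = (p.eta0 + A + V * V - (np.pi * p.tau * R) ** 2 + p.kappa_s * U) / p.tau
    dU = Ud
    dUd = p.alpha**2 * (R - U) - 2.0 * p.alpha * Ud
    return np.array([dR, dV, dU, dUd])


def mass_jacobian(y, p: MassParams):
    """Analytic 4x4 Jacobian of :func:`mass_rhs` at state ``y``."""
    R, V, _, _ = y
    t = p.tau
    return np.array(
        [
            [(-p.kappa_v + 2.0 * V) / t, 2.0 * R / t, 0.0, 0.0],
            [-2.0 * np.pi**2 * t * R, 2.0 * V / t, p.kappa_s / t, 0.0],
            [0.0, 0.0, 0.0, 1.0],
            [p.alpha**2, 0.0, -p.alpha**2, -2.0 * p.alpha],
        ]
    )


@dataclass(frozen=True)
class FixedPoint:
    """A steady state of a mass model together with its linearisation."""

    state: np.ndarray
    eigenvalues: np.ndarray

    @property
    def stable(self) -> bool:
        return bool(np.max(self.eigenvalues.real) < 0)

    @property
    def R(self) -> float:
        return float(self.state[0])

    @property
    def V(self) -> float:
        return float(self.state[1])


def mass_fixed_points(p: MassParams) -> list[FixedPoint]:
    """All steady states with ``R0 > 0`` of the single-population model.

    At steady state ``U0 = R0`` and ``V0 = kappa_v/2 - gamma/(2 pi tau R0)``;
    substituting into the voltage balance gives a quartic in ``R0``::

        -4 pi^4 tau^4 R^4 + 4 pi^2 tau^2 kappa_s R^3
        + pi^2 tau^2 (4 eta0 + kappa_v^2) R^2 - 2 pi tau kappa_v gamma R
        + gamma^2 = 0

    Real positive roots are polished by Newton iteration on the residual and
    returned with the eigenvalues of the 4x4 Jacobian, sorted by ``R0``.
    """
    pt = np.pi * p.tau
    coeffs = [
        -4.0 * pt**4,
        4.0 * pt**2 * p.kappa_s,
        pt**2 * (4.0 * p.eta0 + p.kappa_v**2),
        -2.0 * pt * p.kappa_v * p.gamma,
        p.gamma**2,
    ]
    roots = np.roots(coeffs)
    out: list[FixedPoint] = []
    seen: list[float] = []
    for r in roots:
        if abs(r.imag) > 1e-9 * max(1.0, abs(r.real)) or r.real <= 0:
            continue
        R0 = float(r.real)
        # polish: Newton on f(R) = eta0 + V0(R)^2 - (pi tau R)^2 + kappa_s R
        for _ in range(50):
            V0 = p.kappa_v / 2.0 - p.gamma / (2.0 * pt * R0)
            f = p.eta0 + V0 * V0 - (pt * R0) ** 2 + p.kappa_s * R0
            df = 2.0 * V0 * p.gamma / (2.0 * pt * R0 * R0) - 2.0 * pt**2 * R0 + p.kappa_s
            step = f / df
            R0 -= step
            if abs(step) < 1e-14 * max(1.0, abs(R0)):
                break
        if R0 <= 0 or any(abs(R0 - s) < 1e-9 * max(1.0, s) for s in seen):
            continue
        seen.append(R0)
        V0 = p.kappa_v / 2.0 - p.gamma / (2.0 * pt * R0)
        state = np.array([R0, V0, R0, 0.0])
        out.append(FixedPoint(state=state, eigenvalues=np.linalg.eigvals(mass_jacobian(state, p))))
    out.sort(key=lambda fp: fp.R)
    return out


# ---------------------------------------------------------------------------
# external drive


def filtered_pulse(t, t_on: float, duration: float, magnitude: float, tau_f: float = 50.0):
    """Temporally filtered square pulse (first-order low-pass response).

    A square pulse of the given onset, duration and magnitude convolved with
    the unit-mass kernel ``exp(-t/tau_f)/tau_f``; ``tau_f -> 0`` recovers the
    raw square pulse.  Vectorised over ``t``.
    """
    if duration <= 0:
        raise ValueError("pulse duration must be positive")
    t = np.asarray(t, dtype=float)
    t_off = t_on + duration
    if tau_f <= 0:
        return np.where((t >= t_on) & (t < t_off), magnitude, 0.0)
    rise = magnitude * (1.0 - np.exp(-np.clip(t - t_on, 0.0, None) / tau_f))
    decay_gate = np.where(t >= t_off, np.exp(-(np.clip(t - t_off, 0.0, None)) / tau_f), 1.0)
    peak = magnitude * (1.0 - np.exp(-duration / tau_f))
    return np.where(t < t_on, 0.0, np.where(t < t_off, rise, peak * decay_gate))


def make_pulse(t_on: float, duration: float, magnitude: float, tau_f: float = 50.0) -> Callable:
    """Bind :func:`filtered_pulse` parameters into a drive function ``A(t)``."""

    def A(t):
        return filtered_pulse(t, t_on, duration, magnitude, tau_f)

    return A


# ---------------------------------------------------------------------------
# trajectories


@dataclass
class MassTrajectory:
    """Sampled trajectory of the single-population mass model."""

    t: np.ndarray
    y: np.ndarray  # shape (4, nt): rows R, V, U, Udot
    params: MassParams

    @property
    def R(self) -> np.ndarray:
        return self.y[0]

    @property
    def V(self) -> np.ndarray:
        return self.y[1]

    @property
    def U(self) -> np.ndarray:
        return self.y[2]

    @property
    def Z(self) -> np.ndarray:
        return to_kuramoto(self.R, self.V, self.params.tau)

    def to_dataframe(self):
        import pandas as pd

        Z = self.Z
        return pd.DataFrame(
            {"t": self.t, "R": self.R, "V": self.V, "U": self.U,
             "ReZ": Z.real, "ImZ": Z.imag}
        )


@dataclass
class EITrajectory:
    """Sampled trajectory of the two-population E-I mass network."""

    t: np.ndarray
    y: np.ndarray  # shape (12, nt), layout EI_STATE_LABELS
    params: EIParams

    def __getattr__(self, name):
        if name in EI_STATE_LABELS:
            return self.y[EI_STATE_LABELS.index(name)]
        raise AttributeError(name)

    @property
    def Z_E(self) -> np.ndarray:
        return to_kuramoto(self.y[0], self.y[1], self.params.tau_E)

    @property
    def Z_I(self) -> np.ndarray:
        return to_kuramoto(self.y[2], self.y[3], self.params.tau_I)

    def to_dataframe(self):
        import pandas as pd

        d = {"t": self.t}
        d.update({lab: self.y[i] for i, lab in enumerate(EI_STATE_LABELS[:4])})
        d["absZ_E"], d["absZ_I"] = np.abs(self.Z_E), np.abs(self.Z_I)
        return pd.DataFrame(d)


class IntegrationError(RuntimeError):
    """Raised when a trajectory blows up or the solver fails."""


_BLOWUP = 1e6


def _integrate(rhs, y0, T, dt, rtol, atol, t0=0.0):
    def blowup(t, y):
        return float(np.max(np.abs(y)) - _BLOWUP)

    blowup.terminal = True
    t_eval = t0 + np.arange(int(np.floor(T / dt + 1e-9)) + 1) * dt
    sol = solve_ivp(rhs, (t0, t0 + T), np.asarray(y0, dtype=float), method="RK45",
                    t_eval=t_eval, rtol=rtol, atol=atol, events=blowup, dense_output=False)
    if sol.status == 1:
        raise IntegrationError(f"trajectory blew up (|y| > {_BLOWUP:g}) at t = {sol.t_events[0][0]:.3f}")
    if not sol.success:
        raise IntegrationError(sol.message)
    return sol


def simulate_mass(
    p: MassParams,
    s0: Sequence[float] | None = None,
    T: float = 2000.0,
    dt: float = 1.0,
    drive: Callable | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    t0: float = 0.0,
) -> MassTrajectory:
    """Integrate the single-population model and sample it every ``dt`` ms.

    Parameters
    ----------
    s0 : sequence of 4 floats, optional
        Initial ``(R, V, U, Udot)``.  Defaults to a small perturbation of the
        first fixed point (or a generic seed state if no fixed point exists).
    drive : callable, optional
        External drive ``A(t)`` added to ``eta0`` (see :func:`make_pulse`).
    dt : float
        Output sampling interval; the integrator itself is adaptive (RK45).
    """
    if dt >= p.tau / 10:
        raise ValueError("output step dt must be below tau/10")
    if s0 is None:
        fps = mass_fixed_points(p)
        if fps:
            s0 = fps[0].state + np.array([1e-3, 1e-3, 0.0, 0.0])
        else:
            s0 = np.array([0.1, 0.0, 0.1, 0.0])

    if drive is None:
        rhs = lambda t, y: mass_rhs(y, p)  # noqa: E731
    else:
        rhs = lambda t, y: mass_rhs(y, p, A=float(drive(t)))  # noqa: E731
    sol = _integrate(rhs, s0, T, dt, rtol, atol, t0=t0)
    return MassTrajectory(t=sol.t, y=sol.y, params=p)


# ---------------------------------------------------------------------------
# two-population E-I network

EI_STATE_LABELS = (
    "R_E", "V_E", "R_I", "V_I",
    "U_EE", "Ud_EE", "U_EI", "Ud_EI", "U_IE", "Ud_IE", "U_II", "Ud_II",
)

def make_ei_rhs(p: EIParams) -> Callable:
    """Bind :class:`EIParams` into a fast ``rhs(t, y)`` closure.

    The parameter lookups are hoisted out of the per-step call, which matters
    for attractor sweeps with hundreds of integrations.
    """
    tE, tI = p.tau_E, p.tau_I
    kvE, kvI = p.kappa_v_E, p.kappa_v_I
    gE, gI = p.gamma_E / (np.pi * tE), p.gamma_I / (np.pi * tI)
    e0E, e0I = p.eta0_E, p.eta0_I
    kEE, kEI, kIE, kII = p.kappa_s_EE, p.kappa_s_EI, p.kappa_s_IE, p.kappa_s_II
    aEE, aEI, aIE, aII = p.alpha_EE, p.alpha_EI, p.alpha_IE, p.alpha_II
    piE2, piI2 = (np.pi * tE) ** 2, (np.pi * tI) ** 2

    def rhs(t, y):
        R_E, V_E, R_I, V_I = y[0], y[1], y[2], y[3]
        U_EE, Ud_EE, U_EI, Ud_EI = y[4], y[5], y[6], y[7]
        U_IE, Ud_IE, U_II, Ud_II = y[8], y[9], y[10], y[11]
        return np.array([
            (-kvE * R_E + 2.0 * R_E * V_E + gE) / tE,
            (e0E + V_E * V_E - piE2 * R_E * R_E + kEE * U_EE + kEI * U_EI) / tE,
            (-kvI * R_I + 2.0 * R_I * V_I + gI) / tI,
            (e0I + V_I * V_I - piI2 * R_I * R_I + kIE * U_IE + kII * U_II) / tI,
            Ud_EE, aEE * aEE * (R_E - U_EE) - 2.0 * aEE * Ud_EE,
            Ud_EI, aEI * aEI * (R_I - U_EI) - 2.0 * aEI * Ud_EI,
            Ud_IE, aIE * aIE * (R_E - U_IE) - 2.0 * aIE * Ud_IE,
            Ud_II, aII * aII * (R_I - U_II) - 2.0 * aII * Ud_II,
        ])

    return rhs


def ei_rhs(y, p: EIParams):
    """Time derivative of the 12-dimensional E-I state.

    Layout: ``(R_E, V_E, R_I, V_I)`` then ``(U_ab, Udot_ab)`` for
    ``ab`` in EE, EI, IE, II.  ``U_ab`` is driven by the source-population
    rate ``R_b`` and enters the voltage equation of target ``a`` with weight
    ``kappa_s_ab`` (target-source convention).
    """
    return make_ei_rhs(p)(0.0, np.asarray(y, dtype=float))


def ei_fixed_point(p: EIParams, guess: Sequence[float] | None = None) -> np.ndarray:
    """A steady state of the E-I system, found by root-finding.

    At steady state ``U_ab = R_b`` and ``Udot_ab = 0``, so the problem reduces
    to 4 equations in ``(R_E, V_E, R_I, V_I)``.  Raises if no root converges.
    """

    def reduced(x):
        y = np.empty(12)
        y[:4] = x
        rates = {"E": x[0], "I": x[2]}
        for i, ab in enumerate(CONNECTIONS):
            y[4 + 2 * i] = rates[ab[1]]
            y[5 + 2 * i] = 0.0
        return ei_rhs(y, p)[:4]

    guesses = [guess[:4]] if guess is not None else []
    for R in (0.05, 0.3, 1.0, 3.0):
        guesses.append([R, -0.5, R, -0.5])
    for g in guesses:
        x, info, ier, _ = fsolve(reduced, g, full_output=True)
        if ier == 1 and x[0] > 0 and x[2] > 0 and np.max(np.abs(info["fvec"])) < 1e-10:
            y = np.empty(12)
            y[:4] = x
            rates = {"E": x[0], "I": x[2]}
            for i, ab in enumerate(CONNECTIONS):
                y[4 + 2 * i] = rates[ab[1]]
                y[5 + 2 * i] = 0.0
            return y
    raise RuntimeError("no E-I fixed point converged from the default starts")


def simulate_ei(
    p: EIParams,
    s0: Sequence[float] | None = None,
    T: float = 500.0,
    dt: float = 0.05,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> EITrajectory:
    """Integrate the E-I mass network and sample every ``dt`` ms."""
    if dt >= min(p.tau_E, p.tau_I) / 10 + 1e-12:
        raise ValueError("output step dt must be below min(tau_E, tau_I)/10")
    if s0 is None:
        s0 = ei_fixed_point(p) + 1e-3
    sol = _integrate(make_ei_rhs(p), s0, T, dt, rtol, atol)
    return EITrajectory(t=sol.t, y=sol.y, params=p)
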