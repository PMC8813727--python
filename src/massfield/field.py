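"""Delayed integro-differential neural field on periodic 1D/2D domains.

The local dynamics at every grid point are those of the mass model; the
synaptic variable is driven by the space- and delay-dependent drive::

    Q U = Psi,   Psi(r, t) = integral w(|r - r'|) R(r', t - |r - r'|/c) dr'

with the balanced wizard-hat kernel ``w`` and axonal speed ``c``.  The
domain is a periodic interval (1D) or square (2D); distances are
minimum-image and the kernel is truncated where ``|w| < 1e-8``.

The delayed convolution is discretised by assigning each spatial offset a
delay ``d/c`` split linearly between the two neighbouring solver steps
(exact linear interpolation in time).  Two evaluation paths implement the
identical quadrature: a direct per-offset summation (the reference) and a
spectral path that accumulates, per delay slice, a circular convolution via
FFTs of the stored rate history.  Time stepping is explicit Heun
(trapezoidal predictor-corrector).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mass import to_kuramoto
from .kernels import kernel_value, truncation_radius
from .params import FieldParams
from .stability import uniform_steady_state

__all__ = [
    "FieldState",
    "FieldTrajectory",
    "DelayedConvolution",
    "delayed_drive",
    "make_initial_condition",
    "simulate_field",
    "simulate_field_1d",
    "simulate_field_2d",
]

KERNEL_TRUNC_TOL = 1e-8


class CFLError(ValueError):
    """Raised when the requested dt violates the explicit-step limits."""


def _grid_shape(p: FieldParams) -> tuple[int, ...]:
    return (p.n,) * p.dim


def minimum_image_distance(p: FieldParams) -> np.ndarray:
    """Min-image distance from the origin cell to every grid cell."""
    ax = np.arange(p.n) * p.dx
    ax = np.minimum(ax, p.L - ax)
    if p.dim == 1:
        return ax
    return np.sqrt(ax[:, None] ** 2 + ax[None, :] ** 2)


class DelayedConvolution:
    """Discretised delayed spatial convolution for a fixed grid and dt.

    Each spatial offset with distance ``d`` contributes its quadrature
    weight ``w(d) dx^dim`` at delay ``d/c``, split between solver steps
    ``floor(d/(c dt))`` and the next (linear interpolation).  With
    ``balance=True`` the self-weight is corrected so the discrete weights
    sum exactly to zero, making the uniform steady state an equilibrium of
    the discrete system as it is of the continuum one.
    """

    def __init__(self, p: FieldParams, dt: float, balance: bool = True):
        self.p = p
        self.dt = float(dt)
        D = minimum_image_distance(p)
        w = kernel_value(D, p.dim) * p.dx**p.dim
        w[np.abs(kernel_value(D, p.dim)) < KERNEL_TRUNC_TOL] = 0.0
        r_tr = truncation_radius(KERNEL_TRUNC_TOL, p.dim)
        w[D > r_tr] = 0.0
        if balance:
            w.flat[0] -= w.sum()
        delay_steps = D / (p.c * self.dt)
        j0 = np.floor(delay_steps).astype(int)
        frac = delay_steps - j0
        self.max_steps = int(j0.max()) + 1
        shape = _grid_shape(p)
        # per-delay-slice kernels in real space; scatter each spatial offset
        # into its two neighbouring delay slices
        slices = np.zeros((self.max_steps + 1,) + shape)
        if p.dim == 1:
            ix = (np.arange(p.n),)
        else:
            ii, jj = np.meshgrid(np.arange(p.n), np.arange(p.n), indexing="ij")
            ix = (ii, jj)
        np.add.at(slices, (j0, *ix), w * (1.0 - frac))
        np.add.at(slices, (j0 + 1, *ix), w * frac)
        nz = [j for j in range(self.max_steps + 1) if np.any(slices[j])]
        self.delay_bins = np.array(nz, dtype=int)
        self._w_slices = slices[nz]
        # spectral path: kernels are even, so their DFT is real
        axes = tuple(range(-p.dim, 0))
        self._w_hat = np.real(np.fft.rfftn(self._w_slices, axes=axes))
        self._axes = axes

    # -- spectral path -----------------------------------------------------
    def rhat(self, R: np.ndarray) -> np.ndarray:
        return np.fft.rfftn(R, axes=self._axes)

    def apply_hat(self, rhat_history) -> np.ndarray:
        """Psi from rate-history FFTs; ``rhat_history(j)`` = FFT of R(t - j dt)."""
        psi_hat = np.zeros_like(self._w_hat[0], dtype=complex)
        for wj, j in zip(self._w_hat, self.delay_bins):
            psi_hat += wj * rhat_history(int(j))
        return np.fft.irfftn(psi_hat, s=_grid_shape(self.p), axes=self._axes)

    # -- direct path (reference) ------------------------------------------
    def apply_direct(self, R_history: np.ndarray) -> np.ndarray:
        """Psi from raw history, shape (n_hist, *grid); last slice = now.

        Direct periodic correlation per delay slice; O(n^2) per slice, used
        as the reference implementation on small grids.
        """
        n_hist = R_history.shape[0]
        if n_hist < self.max_steps + 1:
            raise ValueError(
                f"history too short: need {self.max_steps + 1} slices, got {n_hist}")
        p = self.p
        psi = np.zeros(_grid_shape(p))
        idx = np.arange(p.n)
        for wj, j in zip(self._w_slices, self.delay_bins):
            Rj = R_history[-1 - int(j)]
            if p.dim == 1:
                # psi[i] = sum_m w[m] R[i - m] (periodic correlation; w even)
                psi += np.array([np.sum(wj * Rj[(i - idx) % p.n]) for i in idx])
            else:
                ii = (idx[:, None] - idx[None, :]) % p.n
                for a in idx:
                    for b in idx:
                        psi[a, b] += np.sum(wj * Rj[(a - idx[:, None]) % p.n,
                                                    (b - idx[None, :]) % p.n])
        return psi


def delayed_drive(R_history: np.ndarray, p: FieldParams, dt: float,
                  method: str = "fft", balance: bool = True) -> np.ndarray:
    """Evaluate ``Psi`` now from a rate history (oldest first, now last)."""
    conv = DelayedConvolution(p, dt, balance=balance)
    if R_history.shape[0] < conv.max_steps + 1:
        raise ValueError(
            f"history too short: need {conv.max_steps + 1} slices of R "
            f"(max delay {conv.max_steps * dt:.3f} ms), got {R_history.shape[0]}")
    if method == "direct":
        return conv.apply_direct(R_history)
    if method == "fft":
        hats = {int(j): conv.rhat(R_history[-1 - int(j)]) for j in conv.delay_bins}
        return conv.apply_hat(lambda j: hats[j])
    raise ValueError(f"unknown method {method!r}")


@dataclass
class FieldState:
    """Instantaneous field state plus the rate history the delays require.

    ``history`` holds R over the most recent solver steps (oldest first,
    spacing ``dt``); its last slice equals ``R``.
    """

    R: np.ndarray
    V: np.ndarray
    U: np.ndarray
    Ud: np.ndarray
    history: np.ndarray
    dt: float

    def copy(self) -> "FieldState":
        return FieldState(self.R.copy(), self.V.copy(), self.U.copy(),
                          self.Ud.copy(), self.history.copy(), self.dt)


@dataclass
class FieldTrajectory:
    """Space-time output of a field run (samples every ``save_every`` ms)."""

    t: np.ndarray
    x: np.ndarray
    R: np.ndarray  # (nt, n) or (nt, n, n), float32
    V: np.ndarray
    U: np.ndarray
    params: FieldParams
    final_state: FieldState | None = None

    @property
    def Z(self) -> np.ndarray:
        return to_kuramoto(self.R.astype(float), self.V.astype(float), self.params.mass.tau)

    @property
    def absZ(self) -> np.ndarray:
        return np.abs(self.Z)

    @property
    def theta(self) -> np.ndarray:
        return np.angle(self.Z)


def make_initial_condition(
    p: FieldParams,
    kind: str = "uniform+noise",
    amplitude: float = 1e-2,
    seed: int = 0,
    width: float = 2.0,
    n_bars: int = 4,
    n_cells: int = 4,
    mode_k: int = 0,
    noise: float = 0.0,
    dt: float | None = None,
) -> FieldState:
    """Uniform steady state plus a named perturbation of the rate field.

    Kinds: ``uniform+noise`` (seeded white noise), ``gaussian-bump``
    (centred bump of the given width), ``horizontal-bars`` (2D, ``n_bars``
    bands of high activity), ``periodic-lattice`` (product-cosine lattice
    with ``n_cells`` cells per side, discrete translation symmetry L/n_cells),
    ``mode`` (single Fourier mode ``mode_k`` in x, for linear-regime checks).
    ``amplitude = 0`` returns the exact uniform steady state.  The rate
    history is filled with the perturbed field (a frozen pre-0 past).
    """
    fp = uniform_steady_state(p)[-1]
    R0, V0 = fp.R, fp.V
    shape = _grid_shape(p)
    x = np.arange(p.n) * p.dx
    xc = x - p.L / 2

    pert = np.zeros(shape)
    if amplitude != 0:
        if kind == "uniform+noise":
            rng = np.random.default_rng(seed)
            pert = amplitude * rng.standard_normal(shape)
        elif kind == "gaussian-bump":
            if p.dim == 1:
                pert = amplitude * np.exp(-(xc**2) / (2 * width**2))
            else:
                r2 = xc[:, None] ** 2 + xc[None, :] ** 2
                pert = amplitude * np.exp(-r2 / (2 * width**2))
        elif kind == "horizontal-bars":
            if p.dim != 2:
                raise ValueError("horizontal-bars is a 2D initial condition")
            pert = amplitude * np.cos(2 * np.pi * n_bars * x / p.L)[:, None] * np.ones((1, p.n))
        elif kind == "periodic-lattice":
            cx = np.cos(2 * np.pi * n_cells * x / p.L)
            pert = amplitude * (cx[:, None] * cx[None, :] if p.dim == 2 else cx)
        elif kind == "mode":
            cx = np.cos(2 * np.pi * mode_k * x / p.L)
            pert = amplitude * (np.tile(cx, (p.n, 1)) if p.dim == 2 else cx)
        elif kind == "travelling-mode":
            # full linear eigenmode of the seeded wavenumber: one member of
            # the +-omega pair, so a single propagation direction (1D only)
            if p.dim != 1:
                raise ValueError("travelling-mode is a 1D initial condition")
            from .kernels import transfer_function
            from .stability import leading_eigenvalue

            m = p.mass
            k = 2 * np.pi * mode_k / p.L
            lam = leading_eigenvalue(k, p)
            v_hat = (m.tau * lam + m.kappa_v - 2.0 * V0) / (2.0 * R0)
            u_hat = transfer_function(k, lam, p.c, 1) / (1.0 + lam / m.alpha) ** 2
            step_ = dt if dt is not None else p.step
            conv_ = DelayedConvolution(p, step_)
            n_hist = conv_.max_steps + 2
            t_past = -(np.arange(n_hist)[::-1]) * step_
            carrier = np.exp(1j * k * x[None, :] + lam * t_past[:, None])
            history = np.clip(R0 + amplitude * carrier.real, 1e-12, None)
            now = carrier[-1]
            return FieldState(
                R=history[-1].copy(),
                V=V0 + amplitude * (v_hat * now).real,
                U=amplitude * (u_hat * now).real,
                Ud=amplitude * (lam * u_hat * now).real,
                history=history, dt=step_)
        else:
            raise ValueError(f"unknown initial-condition kind {kind!r}")

    if noise:
        # symmetry-breaking jitter on top of a structured perturbation
        rng = np.random.default_rng(seed)
        pert = pert + noise * rng.standard_normal(shape)

    R = np.clip(R0 + pert, 1e-12, None)
    step = dt if dt is not None else p.step
    conv = DelayedConvolution(p, step)
    history = np.broadcast_to(R, (conv.max_steps + 2,) + shape).copy()
    return FieldState(R=R, V=np.full(shape, V0), U=np.zeros(shape),
                      Ud=np.zeros(shape), history=history, dt=step)


def _check_cfl(p: FieldParams, dt: float) -> None:
    if dt > 0.01 * p.mass.tau * (1 + 1e-9):
        raise CFLError(
            f"dt = {dt:g} exceeds tau/100 = {0.01 * p.mass.tau:g}; decrease dt")
    # delay-resolution limit; moot when the whole kernel delay fits in one step
    if truncation_radius(KERNEL_TRUNC_TOL, p.dim) / p.c <= dt:
        return
    lim = 0.25 * p.dx / p.c
    if dt > lim * (1 + 1e-9):
        raise CFLError(
            f"dt = {dt:g} exceeds the delay-resolution limit 0.25 dx/c = {lim:g}; "
            f"decrease dt or refine the grid")


def simulate_field(
    p: FieldParams,
    ic: FieldState | None = None,
    T: float = 500.0,
    save_every: float = 1.0,
    save_start: float = 0.0,
    method: str = "fft",
    balance: bool = True,
    keep_final_state: bool = True,
) -> FieldTrajectory:
    """Integrate the delayed neural field with explicit Heun stepping.

    ``save_every``/``save_start`` control the output sampling (fields are
    stored as float32).  Pass the previous run's ``final_state`` as ``ic``
    to continue a simulation (e.g. discard a transient, then sample
    densely).
    """
    dt = p.step
    _check_cfl(p, dt)
    if ic is None:
        ic = make_initial_condition(p, dt=dt)
    if abs(ic.dt - dt) > 1e-12:
        raise ValueError(f"initial state was built for dt={ic.dt}, solver uses dt={dt}")
    conv = DelayedConvolution(p, dt, balance=balance)
    m = p.mass
    shape = _grid_shape(p)
    n_hist = conv.max_steps + 2
    if ic.history.shape[0] < n_hist:
        raise ValueError(
            f"initial history too short: need {n_hist} slices, got {ic.history.shape[0]}")

    use_fft = method == "fft"
    if not use_fft and method != "direct":
        raise ValueError(f"unknown method {method!r}")

    # ring buffer of rate history (spectral path stores FFTs)
    ring_len = n_hist + 1
    if use_fft:
        ring = np.zeros((ring_len,) + conv._w_hat.shape[1:], dtype=complex)
        for j in range(n_hist):
            ring[j] = conv.rhat(ic.history[ic.history.shape[0] - n_hist + j])
    else:
        ring = np.zeros((ring_len,) + shape)
        ring[:n_hist] = ic.history[-n_hist:]
    head = n_hist - 1  # ring index of "now"

    def psi_from(head_idx):
        if use_fft:
            return conv.apply_hat(lambda j: ring[(head_idx - j) % ring_len])
        hist = np.stack([ring[(head_idx - j) % ring_len]
                         for j in range(conv.max_steps, -1, -1)])
        return conv.apply_direct(hist)

    R, V, U, Ud = (a.astype(float).copy() for a in (ic.R, ic.V, ic.U, ic.Ud))

    def rhs(R, V, U, Ud, psi):
        dR = (-m.kappa_v * R + 2.0 * R * V + m.gamma / (np.pi * m.tau)) / m.tau
        dV = (m.eta0 + V * V - (np.pi * m.tau * R) ** 2 + m.kappa_s * U) / m.tau
        dUd = m.alpha**2 * (psi - U) - 2.0 * m.alpha * Ud
        return dR, dV, Ud, dUd

    n_steps = int(round(T / dt))
    stride = max(1, int(round(save_every / dt)))
    ts, Rs, Vs, Us = [], [], [], []

    def maybe_save(step_i):
        t_now = step_i * dt
        if t_now + 1e-9 >= save_start and step_i % stride == 0:
            ts.append(t_now)
            Rs.append(R.astype(np.float32))
            Vs.append(V.astype(np.float32))
            Us.append(U.astype(np.float32))

    maybe_save(0)
    for i in range(1, n_steps + 1):
        psi0 = psi_from(head)
        k1 = rhs(R, V, U, Ud, psi0)
        Rp = np.clip(R + dt * k1[0], 0.0, None)
        Vp = V + dt * k1[1]
        Up = U + dt * k1[2]
        Udp = Ud + dt * k1[3]
        # predictor R enters the history to evaluate Psi at t + dt
        head = (head + 1) % ring_len
        ring[head] = conv.rhat(Rp) if use_fft else Rp
        psi1 = psi_from(head)
        k2 = rhs(Rp, Vp, Up, Udp, psi1)
        R = np.clip(R + 0.5 * dt * (k1[0] + k2[0]), 0.0, None)
        V = V + 0.5 * dt * (k1[1] + k2[1])
        U = U + 0.5 * dt * (k1[2] + k2[2])
        Ud = Ud + 0.5 * dt * (k1[3] + k2[3])
        ring[head] = conv.rhat(R) if use_fft else R
        if not np.all(np.isfinite(V)):
            raise RuntimeError(f"field blew up at t = {i * dt:.2f} ms")
        maybe_save(i)

    final = None
    if keep_final_state:
        if use_fft:
            hist = np.stack([np.fft.irfftn(ring[(head - j) % ring_len],
                                           s=shape, axes=conv._axes)
                             for j in range(n_hist - 1, -1, -1)])
        else:
            hist = np.stack([ring[(head - j) % ring_len]
                             for j in range(n_hist - 1, -1, -1)])
        final = FieldState(R=R, V=V, U=U, Ud=Ud, history=hist, dt=dt)

    x = np.arange(p.n) * p.dx
    return FieldTrajectory(t=np.array(ts), x=x, R=np.array(Rs), V=np.array(Vs),
                           U=np.array(Us), params=p, final_state=final)


def simulate_field_1d(p: FieldParams, ic: FieldState | None = None, T: float = 500.0,
                      **kw) -> FieldTrajectory:
    if p.dim != 1:
        raise ValueError("simulate_field_1d requires dim=1 parameters")
    return simulate_field(p, ic, T, **kw)


def simulate_field_2d(p: FieldParams, ic: FieldState | None = None, T: float = 500.0,
                      **kw) -> FieldTrajectory:
    if p.dim != 2:
        raise ValueError("simulate_field_2d requires dim=2 parameters")
    return simulate_field(p, ic, T, **kw)
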