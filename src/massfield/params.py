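"""Parameter containers for the microscopic network, mass and field models.

All time constants are in milliseconds, rates in 1/ms, and the spatial unit of
the field model is the exponential decay scale of the connectivity kernel.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

__all__ = [
    "MassParams",
    "EIParams",
    "NetworkParams",
    "FieldParams",
    "POPULATIONS",
    "CONNECTIONS",
]

POPULATIONS = ("E", "I")
#: connection labels, first index = target population, second = source
CONNECTIONS = ("EE", "EI", "IE", "II")


class ParameterError(ValueError):
    """Raised when a model parameter violates its admissibility constraints."""


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ParameterError(msg)


@dataclass(frozen=True)
class MassParams:
    """Parameters of the single-population mean-field (neural mass) model.

    Attributes
    ----------
    eta0 : float
        Median background drive (level of excitability).
    gamma : float
        Half-width of the Lorentzian distribution of background drives
        (degree of heterogeneity); must be positive.
    tau : float
        Membrane time constant in ms.
    kappa_v : float
        Gap-junction (electrical) coupling strength; non-negative.
    kappa_s : float
        Synaptic coupling strength; signed (negative = inhibitory feedback).
    alpha : float
        Inverse synaptic time-to-peak in 1/ms; the synaptic filter is
        ``s(t) = alpha^2 t exp(-alpha t) H(t)``.
    """

    eta0: float = 1.0
    gamma: float = 0.5
    tau: float = 15.0
    kappa_v: float = 1.0
    kappa_s: float = 1.0
    alpha: float = 0.5

    def __post_init__(self) -> None:
        _require(self.gamma > 0, f"gamma must be positive, got {self.gamma}")
        _require(self.tau > 0, f"tau must be positive, got {self.tau}")
        _require(self.alpha > 0, f"alpha must be positive, got {self.alpha}")
        _require(self.kappa_v >= 0, f"kappa_v must be non-negative, got {self.kappa_v}")

    def replace(self, **kw) -> "MassParams":
        return replace(self, **kw)


@dataclass(frozen=True)
class EIParams:
    """Parameters of the two-population excitatory-inhibitory mass network.

    Gap junctions only couple neurons within the same population; synaptic
    coupling exists within and between populations.  Connection subscripts
    follow the target-source convention: ``kappa_s_IE`` is the strength of the
    excitatory drive onto the inhibitory population.  Inhibitory strengths
    carry their sign in ``kappa_s_*``.
    """

    eta0_E: float = 5.0
    eta0_I: float = -3.0
    gamma_E: float = 0.5
    gamma_I: float = 0.5
    tau_E: float = 1.0
    tau_I: float = 1.0
    kappa_v_E: float = 0.5
    kappa_v_I: float = 0.5
    kappa_s_EE: float = 15.0
    kappa_s_EI: float = -15.0
    kappa_s_IE: float = 25.0
    kappa_s_II: float = -15.0
    alpha_EE: float = 0.2
    alpha_EI: float = 0.07
    alpha_IE: float = 0.1
    alpha_II: float = 0.06

    def __post_init__(self) -> None:
        for a in POPULATIONS:
            _require(getattr(self, f"gamma_{a}") > 0, f"gamma_{a} must be positive")
            _require(getattr(self, f"tau_{a}") > 0, f"tau_{a} must be positive")
            _require(getattr(self, f"kappa_v_{a}") >= 0, f"kappa_v_{a} must be non-negative")
        for ab in CONNECTIONS:
            _require(getattr(self, f"alpha_{ab}") > 0, f"alpha_{ab} must be positive")

    def population(self, a: str) -> MassParams:
        """Single-population parameters of population ``a`` with synapses off."""
        return MassParams(
            eta0=getattr(self, f"eta0_{a}"),
            gamma=getattr(self, f"gamma_{a}"),
            tau=getattr(self, f"tau_{a}"),
            kappa_v=getattr(self, f"kappa_v_{a}"),
            kappa_s=0.0,
            alpha=1.0,
        )

    def replace(self, **kw) -> "EIParams":
        return replace(self, **kw)


@dataclass(frozen=True)
class NetworkParams:
    """Parameters of the microscopic QIF network simulation.

    The network is all-to-all coupled; background drives ``eta_i`` are drawn
    from a Lorentzian with median ``eta0`` and half-width ``gamma``, either as
    i.i.d. samples (``eta_mode="random"``) or as equally spaced quantiles
    (``eta_mode="deterministic-quantile"``, the reproducible default).
    """

    N: int = 1000
    eta0: float = 2.0
    gamma: float = 0.5
    tau: float = 16.0
    kappa_v: float = 1.0
    kappa_s: float = 1.0
    alpha: float = 0.5
    v_th: float = 1000.0
    v_r: float = -1000.0
    dt: float | None = None
    T: float = 1000.0
    seed: int = 0
    eta_mode: Literal["random", "deterministic-quantile"] = "deterministic-quantile"

    def __post_init__(self) -> None:
        _require(self.N >= 1, f"N must be at least 1, got {self.N}")
        _require(self.gamma > 0, f"gamma must be positive, got {self.gamma}")
        _require(self.tau > 0, f"tau must be positive, got {self.tau}")
        _require(self.alpha > 0, f"alpha must be positive, got {self.alpha}")
        _require(self.kappa_v >= 0, f"kappa_v must be non-negative, got {self.kappa_v}")
        _require(self.v_r < self.v_th, "v_r must be below v_th")
        _require(self.eta_mode in ("random", "deterministic-quantile"),
                 f"unknown eta_mode {self.eta_mode!r}")
        if self.dt is not None:
            _require(0 < self.dt < self.tau, "dt must satisfy 0 < dt < tau")

    @property
    def step(self) -> float:
        """Integration step: explicit ``dt`` or the default 0.01*tau."""
        return self.dt if self.dt is not None else 0.01 * self.tau

    def mass(self) -> MassParams:
        """The corresponding mean-field parameters (infinite-threshold limit)."""
        return MassParams(eta0=self.eta0, gamma=self.gamma, tau=self.tau,
                          kappa_v=self.kappa_v, kappa_s=self.kappa_s, alpha=self.alpha)

    def replace(self, **kw) -> "NetworkParams":
        return replace(self, **kw)


@dataclass(frozen=True)
class FieldParams:
    """Parameters of the spatially extended (neural field) model.

    The local dynamics are those of :class:`MassParams`; the synaptic drive is
    the distance-dependent, axonally delayed convolution of the firing rate
    with a balanced "wizard hat" kernel.  ``kappa_s > 0`` with the inverted
    wizard hat gives long-range excitation / short-range inhibition; the
    regular wizard hat regime is obtained with ``kappa_s < 0``.
    """

    mass: MassParams = field(default_factory=MassParams)
    c: float = 1.0
    dim: Literal[1, 2] = 1
    L: float = 40.0
    n: int = 256
    dt: float | None = None

    def __post_init__(self) -> None:
        _require(self.c > 0, f"axonal speed c must be positive, got {self.c}")
        _require(self.dim in (1, 2), f"dim must be 1 or 2, got {self.dim}")
        _require(self.n >= 4 and self.n % 2 == 0, "n must be an even integer >= 4")
        _require(self.L > 0, "L must be positive")
        if self.dt is not None:
            _require(self.dt > 0, "dt must be positive")

    @property
    def dx(self) -> float:
        return self.L / self.n

    @property
    def step(self) -> float:
        """Explicit ``dt`` or the default min(0.25*dx/c, 0.01*tau).

        When the axonal speed is so large that the whole (truncated) kernel
        is reached within one membrane-limited step, the delay-resolution
        limit is moot and only the tau/100 limit applies.
        """
        if self.dt is not None:
            return self.dt
        tau_lim = 0.01 * self.mass.tau
        if 25.0 / self.c <= tau_lim:  # 25 bounds the kernel truncation radius
            return tau_lim
        return min(0.25 * self.dx / self.c, tau_lim)

    def replace(self, **kw) -> "FieldParams":
        return replace(self, **kw)
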