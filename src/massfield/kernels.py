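"""Spatial connectivity kernels and their delayed transfer functions.

The field model uses the balanced "wizard hat" family::

    w(x) = (|x| - 1) e^{-|x|}            (1D)
    w(r) = (r/2 - 1) e^{-r} / (2 pi)     (2D, r = radial distance)

Both integrate to zero over the whole domain (balance), so a spatially
uniform firing rate produces no net synaptic drive.  With ``kappa_s > 0``
this shape is an *inverted* wizard hat (long-range excitation, short-range
inhibition); the regular wizard hat regime (short-range excitation,
long-range inhibition) is obtained by flipping the sign of ``kappa_s``.

For a perturbation ``exp(lambda t + i k . r)`` the axonally delayed
convolution acts as multiplication by the transfer function

    G(k, lambda) = FT_space[ w(|r|) exp(-lambda |r| / c) ](k)

which has the closed forms implemented here (``beta = 1 + lambda/c``).
"""

from __future__ import annotations

import numpy as np

__all__ = ["kernel_value", "transfer_function", "truncation_radius", "BranchError"]


class BranchError(ValueError):
    """Raised when Re(1 + lambda/c) <= 0, outside the causal branch."""


def kernel_value(d, dim: int = 1):
    """Wizard-hat kernel at distance ``d >= 0`` (vectorised).

    The same shape serves both coupling regimes: the sign of the synaptic
    interaction lives in ``kappa_s``, not in ``w``.
    """
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("distance must be non-negative")
    if dim == 1:
        return (d - 1.0) * np.exp(-d)
    if dim == 2:
        return (d / 2.0 - 1.0) * np.exp(-d) / (2.0 * np.pi)
    raise ValueError(f"dim must be 1 or 2, got {dim}")


def truncation_radius(tol: float = 1e-8, dim: int = 1) -> float:
    """Distance beyond which ``|w|`` stays below ``tol``."""
    d = np.linspace(0.0, 80.0, 80001)
    w = np.abs(kernel_value(d, dim))
    above = np.nonzero(w >= tol)[0]
    return float(d[above[-1]]) if above.size else 0.0


def transfer_function(k, lam, c: float, dim: int = 1):
    """Closed-form delayed-kernel transfer function ``G(k, lambda)``.

    1D: ``G = 2[(beta^2 - k^2)/(beta^2 + k^2)^2 - beta/(beta^2 + k^2)]``
    2D: ``G = [(2 beta^2 - k^2)/2 - beta (beta^2 + k^2)] / (beta^2 + k^2)^{5/2}``

    with ``beta = 1 + lambda/c`` and the principal branch of the half-integer
    power (positive real part).  Requires ``Re(beta) > 0``.
    """
    k = np.asarray(k, dtype=float)
    lam = np.asarray(lam, dtype=complex)
    beta = 1.0 + lam / c
    if np.any(beta.real <= 0):
        raise BranchError("transfer function requires Re(1 + lambda/c) > 0")
    q = beta * beta + k * k
    if dim == 1:
        return 2.0 * ((beta * beta - k * k) / (q * q) - beta / q)
    if dim == 2:
        s = np.sqrt(q)  # principal branch, Re(s) >= 0
        return ((2.0 * beta * beta - k * k) / 2.0 - beta * q) / (s * q * q)
    raise ValueError(f"dim must be 1 or 2, got {dim}")
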