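"""Linear stability of the spatially uniform state of the neural field.

Perturbing the uniform steady state ``(R0, V0, U0=0)`` with a mode
``exp(lambda t + i k x)`` and eliminating the synaptic variable yields the
scalar characteristic function

    E(k, lambda) = (tau lambda + kappa_v - 2 V0)(tau lambda - 2 V0)(1 + lambda/alpha)^2
                   + 4 pi^2 tau^2 R0^2 (1 + lambda/alpha)^2
                   - 2 R0 kappa_s G(k, lambda)

where ``G`` is the delayed-kernel transfer function.  Instabilities are
classified by the critical wavenumber ``k_c`` and frequency ``omega_c`` of
the first root crossing ``Re(lambda) = 0``: a Hopf bifurcation (``k_c = 0``,
``omega_c > 0``) gives bulk oscillations, a Turing bifurcation
(``k_c > 0``, ``omega_c = 0``) static patterns, and a Turing-Hopf
bifurcation (both nonzero) travelling/standing waves.

In 1D the rational structure of ``G`` can be cleared exactly, turning
``E = 0`` into a degree-8 polynomial whose roots are filtered by the causal
branch condition ``Re(1 + lambda/c) > 0``.  In 2D (half-integer powers) the
leading root is tracked by damped Newton iteration with multi-start and
continuation in ``k``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.polynomial import Polynomial

from .kernels import BranchError, transfer_function
from .mass import FixedPoint, mass_fixed_points
from .params import FieldParams, MassParams

__all__ = [
    "uniform_steady_state",
    "characteristic_residual",
    "leading_eigenvalue",
    "dispersion_relation",
    "DispersionResult",
    "critical_threshold",
    "instability_curves",
    "InstabilityCurve",
    "hopf_locus_mass",
]

#: classification tolerances: a critical wavenumber below EPS_K counts as
#: k = 0 (Hopf); a frequency below EPS_OMEGA counts as static (Turing)
EPS_K = 1e-3
EPS_OMEGA = 1e-3


def uniform_steady_state(p: FieldParams) -> list[FixedPoint]:
    """Spatially uniform steady states of the field model.

    The balanced kernel annihilates constants, so ``U0 = 0`` and the steady
    state solves the single-population equations with the synaptic coupling
    absent; it is therefore independent of ``kappa_s``.  All positive-rate
    roots are returned sorted by ``R0``; the last (largest ``R0``) is the
    principal one.
    """
    return mass_fixed_points(p.mass.replace(kappa_s=0.0))


def _steady_rv(p: FieldParams) -> tuple[float, float]:
    fps = uniform_steady_state(p)
    if not fps:
        raise RuntimeError("no uniform steady state with R0 > 0 found")
    fp = fps[-1]
    return fp.R, fp.V


def characteristic_residual(k: float, lam: complex, p: FieldParams) -> complex:
    """The characteristic function ``E(k, lambda)``; roots are eigenvalues."""
    m = p.mass
    R0, V0 = _steady_rv(p)
    G = transfer_function(k, lam, p.c, p.dim)
    syn = (1.0 + lam / m.alpha) ** 2
    return (
        (m.tau * lam + m.kappa_v - 2.0 * V0) * (m.tau * lam - 2.0 * V0) * syn
        + 4.0 * np.pi**2 * m.tau**2 * R0**2 * syn
        - 2.0 * R0 * m.kappa_s * G
    )


# ---------------------------------------------------------------------------
# root finding


def _char_polynomial_1d(k: float, p: FieldParams) -> Polynomial:
    """``E(k, .) * (beta^2 + k^2)^2`` as a polynomial in lambda (1D only)."""
    m = p.mass
    R0, V0 = _steady_rv(p)
    lam = Polynomial([0.0, 1.0])
    beta = 1.0 + lam / p.c
    B = beta * beta + k * k
    syn = (1.0 + lam / m.alpha) ** 2
    G_cleared = 2.0 * ((beta * beta - k * k) - beta * B)  # G * B^2
    return (
        (m.tau * lam + m.kappa_v - 2.0 * V0) * (m.tau * lam - 2.0 * V0) * syn * B * B
        + 4.0 * np.pi**2 * m.tau**2 * R0**2 * syn * B * B
        - 2.0 * R0 * m.kappa_s * G_cleared
    )


def _roots_1d(k: float, p: FieldParams) -> np.ndarray:
    """Causal roots of ``E(k, .) = 0`` in 1D via polynomial clearing."""
    poly = _char_polynomial_1d(k, p)
    roots = poly.roots()
    keep = []
    for lam in roots:
        beta = 1.0 + lam / p.c
        if beta.real <= 1e-12:
            continue  # acausal branch
        if abs(beta * beta + k * k) < 1e-10:
            continue  # spurious root of the cleared denominator
        keep.append(lam)
    if not keep:
        raise RuntimeError(f"no causal eigenvalue found at k={k}")
    return np.array(sorted(keep, key=lambda z: -z.real))


def _newton_root(k: float, lam0: complex, p: FieldParams,
                 tol: float = 1e-11, maxit: int = 60) -> complex | None:
    """Damped Newton iteration on ``E(k, .)`` from the start ``lam0``."""
    lam = complex(lam0)
    for _ in range(maxit):
        try:
            f = characteristic_residual(k, lam, p)
        except BranchError:
            return None
        h = 1e-7 * max(1.0, abs(lam))
        try:
            df = (characteristic_residual(k, lam + h, p)
                  - characteristic_residual(k, lam - h, p)) / (2.0 * h)
        except BranchError:
            return None
        if df == 0:
            return None
        step = f / df
        # damping: keep the iterate on the causal branch
        scale = 1.0
        while scale > 1e-4 and (1.0 + (lam - scale * step) / p.c).real <= 0:
            scale *= 0.5
        lam = lam - scale * step
        if abs(step) * scale < tol * max(1.0, abs(lam)):
            return lam
    return None


def _mass_like_starts(p: FieldParams, k: float) -> list[complex]:
    """Heuristic Newton starts: kappa_s = 0 factors plus 1D-cleared roots."""
    m = p.mass
    R0, V0 = _steady_rv(p)
    # roots of (tau L + kv - 2V0)(tau L - 2V0) + 4 pi^2 tau^2 R0^2 = 0
    b = m.kappa_v - 4.0 * V0
    c0 = (m.kappa_v - 2.0 * V0) * (-2.0 * V0) + 4.0 * np.pi**2 * m.tau**2 * R0**2
    disc = np.sqrt(complex(b * b - 4.0 * c0))
    starts = [(-b + disc) / (2.0 * m.tau), (-b - disc) / (2.0 * m.tau),
              complex(-m.alpha, 1e-3)]
    try:
        starts.extend(_roots_1d(k, p.replace(dim=1))[:4])
    except RuntimeError:
        pass
    return starts


def leading_eigenvalue(k: float, p: FieldParams, lam_guess: complex | None = None) -> complex:
    """Root of ``E(k, .) = 0`` with the largest real part (causal branch)."""
    k = abs(float(k))
    if p.dim == 1:
        return complex(_roots_1d(k, p)[0])
    starts: list[complex] = []
    if lam_guess is not None:
        starts.append(complex(lam_guess))
    starts.extend(_mass_like_starts(p, k))
    found: list[complex] = []
    for s in starts:
        lam = _newton_root(k, s, p)
        if lam is None:
            continue
        if abs(characteristic_residual(k, lam, p)) > 1e-6:
            continue
        if not any(abs(lam - f) < 1e-8 * max(1.0, abs(f)) for f in found):
            found.append(lam)
    if not found:
        raise RuntimeError(f"no converged eigenvalue at k={k} (dim=2)")
    return max(found, key=lambda z: z.real)


@dataclass
class DispersionResult:
    """Leading eigenvalue along a wavenumber grid, with classification."""

    k: np.ndarray
    lam: np.ndarray
    k_star: float
    classification: str  # stable | Hopf | Turing | Turing-Hopf

    @property
    def max_growth(self) -> float:
        return float(self.lam.real.max())


def _classify(k_star: float, omega: float, unstable: bool) -> str:
    if not unstable:
        return "stable"
    if k_star < EPS_K:
        return "Hopf" if omega > EPS_OMEGA else "stable"  # k=0, omega=0 cannot destabilise
    return "Turing-Hopf" if omega > EPS_OMEGA else "Turing"


def dispersion_relation(p: FieldParams, k_max: float = 4.0, nk: int = 161) -> DispersionResult:
    """Leading eigenvalue on a uniform k-grid, tracked by continuation."""
    ks = np.linspace(0.0, k_max, nk)
    lams = np.empty(nk, dtype=complex)
    guess: complex | None = None
    for i, k in enumerate(ks):
        lams[i] = leading_eigenvalue(k, p, lam_guess=guess)
        guess = lams[i]
    i_star = int(np.argmax(lams.real))
    k_star = float(ks[i_star])
    omega = abs(lams[i_star].imag)
    return DispersionResult(k=ks, lam=lams, k_star=k_star,
                            classification=_classify(k_star, omega, lams[i_star].real > 0))


# ---------------------------------------------------------------------------
# thresholds and two-parameter curves


def _branch_growth(p: FieldParams, branch: str, k_max: float, nk: int) -> tuple[float, float, float]:
    """(max Re lambda, k at max, |Im lambda| at max) restricted to a branch.

    ``branch='hopf'`` looks only at k = 0.  ``branch='turing-hopf'`` looks at
    the local maxima of Re lambda(k) beyond the first local minimum, so the
    k = 0 lobe is excluded.  ``branch='any'`` is the global maximum.
    """
    if branch == "hopf":
        lam = leading_eigenvalue(0.0, p)
        return lam.real, 0.0, abs(lam.imag)
    disp = dispersion_relation(p, k_max=k_max, nk=nk)
    re = disp.lam.real
    if branch == "any":
        i = int(np.argmax(re))
        return re[i], float(disp.k[i]), abs(disp.lam[i].imag)
    if branch == "turing-hopf":
        i_g = int(np.argmax(re))
        if i_g == len(re) - 1:  # maximum at the grid edge: k_max too small
            raise RuntimeError("Turing-Hopf lobe extends beyond k_max; increase k_max")
        if disp.k[i_g] > disp.k[1]:  # global maximum away from k = 0
            return re[i_g], float(disp.k[i_g]), abs(disp.lam[i_g].imag)
        # k = 0 lobe dominates: look beyond the first interior local minimum
        mins = np.nonzero((re[1:-1] <= re[:-2]) & (re[1:-1] <= re[2:]))[0] + 1
        if mins.size == 0:
            return -np.inf, np.nan, np.nan
        j0 = mins[0]
        i = j0 + int(np.argmax(re[j0:]))
        if i == len(re) - 1:
            raise RuntimeError("Turing-Hopf lobe extends beyond k_max; increase k_max")
        return re[i], float(disp.k[i]), abs(disp.lam[i].imag)
    raise ValueError(f"unknown branch {branch!r}")


def _refine_kstar(p: FieldParams, k0: float, half_width: float = 0.08) -> tuple[float, float, float]:
    """Polish the critical wavenumber by a fine local scan around ``k0``."""
    ks = np.linspace(max(0.0, k0 - half_width), k0 + half_width, 33)
    lams = np.array([leading_eigenvalue(k, p) for k in ks])
    i = int(np.argmax(lams.real))
    return float(lams[i].real), float(ks[i]), abs(float(lams[i].imag))


def critical_threshold(
    p: FieldParams,
    free: str = "kappa_v",
    bracket: tuple[float, float] = (0.0, 2.0),
    branch: str = "any",
    k_max: float = 4.0,
    nk: int = 161,
    tol: float = 1e-6,
) -> tuple[float, float, float, str]:
    """Bisection for the parameter value where the branch growth rate crosses 0.

    Returns ``(value, k_c, omega_c, classification)``.  ``free`` names a
    :class:`MassParams` field or ``"c"``.
    """

    def with_value(v: float) -> FieldParams:
        if free == "c":
            return p.replace(c=v)
        return p.replace(mass=p.mass.replace(**{free: v}))

    def growth(v: float) -> float:
        return _branch_growth(with_value(v), branch, k_max, nk)[0]

    lo, hi = bracket
    g_lo, g_hi = growth(lo), growth(hi)
    # g = -inf (branch lobe absent) is a legitimate "stable" sign
    if np.isnan(g_lo) or np.isnan(g_hi) or np.sign(g_lo) * np.sign(g_hi) > 0:
        raise ValueError(
            f"no sign change of the {branch} growth rate over {free} in {bracket}: "
            f"g({lo})={g_lo:.3g}, g({hi})={g_hi:.3g}")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if np.sign(growth(mid)) * np.sign(g_lo) <= 0:
            hi = mid
        else:
            lo = mid
    value = 0.5 * (lo + hi)
    g, k_c, omega_c = _branch_growth(with_value(value), branch, k_max, nk)
    if k_c > EPS_K:
        g, k_c, omega_c = _refine_kstar(with_value(value), k_c)
    return value, k_c, omega_c, _classify(k_c, omega_c, True)


@dataclass
class InstabilityCurve:
    """Locus of marginal stability in a two-parameter plane."""

    plane: tuple[str, str]
    branch: str  # Hopf | Turing | Turing-Hopf
    points: np.ndarray  # shape (npts, 2): columns follow `plane`
    k_c: np.ndarray
    omega_c: np.ndarray


def instability_curves(
    p: FieldParams,
    c_values: np.ndarray,
    kv_bracket: tuple[float, float] = (0.05, 3.0),
    k_max: float = 4.0,
    nk: int = 161,
    tol: float = 1e-6,
) -> dict:
    """Hopf and Turing-Hopf thresholds in the (c, kappa_v) plane.

    For each axonal speed ``c`` the gap-junction strength at which each
    branch first destabilises the uniform state is located by bisection.
    Returns the two curves, the codimension-2 crossing ``c_star`` where the
    branches exchange order (None if they do not cross in range), and the
    stability floor ``kv_min`` = min over c of the first-instability
    threshold.
    """
    curves = {"Hopf": [], "Turing-Hopf": []}
    gaps = {"Hopf": [], "Turing-Hopf": []}

    def threshold(c: float, branch: str) -> tuple[float, float, float] | None:
        try:
            v, k_c, om, _ = critical_threshold(
                p.replace(c=c), "kappa_v", kv_bracket, branch.lower(), k_max, nk, tol)
            return v, k_c, om
        except (ValueError, RuntimeError):
            return None

    for c in c_values:
        for branch in curves:
            res = threshold(float(c), branch)
            if res is None:
                gaps[branch].append(float(c))
            else:
                curves[branch].append((float(c), *res))

    out_curves = {}
    for branch, pts in curves.items():
        arr = np.array(pts) if pts else np.empty((0, 4))
        out_curves[branch] = InstabilityCurve(
            plane=("c", "kappa_v"), branch=branch,
            points=arr[:, :2], k_c=arr[:, 2] if arr.size else np.empty(0),
            omega_c=arr[:, 3] if arr.size else np.empty(0))

    # codim-2 crossing: bisect on the threshold difference where it changes sign
    c_star = None
    hopf_by_c = {c: v for c, v, *_ in curves["Hopf"]}
    th_by_c = {c: v for c, v, *_ in curves["Turing-Hopf"]}
    both = sorted((c, hopf_by_c[c], th_by_c[c]) for c in hopf_by_c if c in th_by_c)
    diffs = [(c, h - t) for c, h, t in both]
    for (c1, d1), (c2, d2) in zip(diffs[:-1], diffs[1:]):
        if d1 == 0:
            c_star = c1
            break
        if d1 * d2 < 0:
            lo, hi, d_lo = c1, c2, d1
            while hi - lo > tol:
                mid = 0.5 * (lo + hi)
                rh = threshold(mid, "Hopf")
                rt = threshold(mid, "Turing-Hopf")
                if rh is None or rt is None:
                    break
                d_mid = rh[0] - rt[0]
                if d_mid * d_lo <= 0:
                    hi = mid
                else:
                    lo, d_lo = mid, d_mid
            c_star = 0.5 * (lo + hi)
            break

    first = [min(h, t) for _, h, t in both]
    kv_min = float(np.min(first)) if first else None
    return {"curves": out_curves, "c_star": c_star, "kv_min": kv_min}


def hopf_locus_mass(
    p: MassParams,
    eta0_values: np.ndarray,
    gamma_list: tuple[float, ...] = (0.5,),
    kv_bracket: tuple[float, float] = (0.0, 5.0),
    tol: float = 1e-8,
) -> dict[float, InstabilityCurve]:
    """Mass-model Hopf locus in the (kappa_v, eta0) plane, per gamma.

    For each ``eta0`` the gap-junction strength at which the fixed point's
    leading eigenvalue pair crosses the imaginary axis is located by
    bisection on ``max Re(eig J)``; oscillations emerge to the right of each
    curve.  Points where no crossing exists in the bracket are skipped.
    """

    def max_re(kv: float, eta0: float, gamma: float) -> tuple[float, float]:
        q = p.replace(kappa_v=kv, eta0=eta0, gamma=gamma)
        fps = mass_fixed_points(q)
        if not fps:
            return np.nan, np.nan
        ev = fps[-1].eigenvalues
        i = int(np.argmax(ev.real))
        return float(ev.real[i]), abs(float(ev.imag[i]))

    out: dict[float, InstabilityCurve] = {}
    for gamma in gamma_list:
        pts, oms = [], []
        for eta0 in eta0_values:
            lo, hi = kv_bracket
            g_lo, _ = max_re(lo, float(eta0), gamma)
            g_hi, _ = max_re(hi, float(eta0), gamma)
            if not np.isfinite(g_lo) or not np.isfinite(g_hi) or g_lo * g_hi > 0:
                continue
            while hi - lo > tol:
                mid = 0.5 * (lo + hi)
                g_mid, _ = max_re(mid, float(eta0), gamma)
                if g_mid * g_lo <= 0:
                    hi = mid
                else:
                    lo, g_lo = mid, g_mid
            kv = 0.5 * (lo + hi)
            _, om = max_re(kv, float(eta0), gamma)
            pts.append((kv, float(eta0)))
            oms.append(om)
        arr = np.array(pts) if pts else np.empty((0, 2))
        out[gamma] = InstabilityCurve(plane=("kappa_v", "eta0"), branch="Hopf",
                                      points=arr, k_c=np.zeros(len(pts)),
                                      omega_c=np.array(oms))
    return out
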