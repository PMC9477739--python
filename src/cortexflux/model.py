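"""Growth-law dynamical system for WSP-1/F-actin cortical condensates.

The model tracks two integrated fluorescence amounts per condensate, the
WSP-1 amount ``W`` and the F-actin amount ``A`` (both in intensity units,
IU).  Condensate volume is tied linearly to molecular content,

    V = v_A * A + v_W * W,

and the amounts evolve under mass-action growth laws

    dW/dt = k_r * W  -  k_l * A * W / V
    dA/dt = k_b * A * W / V  -  k_d * A,

where ``k_r`` is WSP-1 self-recruitment, ``k_l`` the branching-dependent
WSP-1 loss coefficient, ``k_b`` the branching coefficient and ``k_d`` the
F-actin loss rate.  The vector field is degree-1 homogeneous: composition
variables (stoichiometry ``s = A/(A+W)``, effective F-actin volume fraction
``phi = v_A*A/V``, concentrations) evolve independently of condensate size.

Both nullclines of this system are rays of constant stoichiometry through
the origin.  When the WSP-1 nullcline lies below the F-actin nullcline the
origin supports a homoclinic loop — condensates grow, turn over and
dissolve (dynamic instability).  When the rays switch order, growth is
unbounded.  The switch happens at the critical coefficient combination

    v_A*k_r/k_l + v_W*k_d/k_b = 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .errors import DegenerateGeometryError, DomainError, NoDominantCompositionError

__all__ = [
    "KineticParams",
    "VolumeCoefficients",
    "DerivedObservables",
    "Trajectory",
    "DEFAULT_PARAMS",
    "DEFAULT_VOLUME",
    "volume",
    "growth_rates",
    "nullcline_stoichiometries",
    "critical_kd",
    "classify_regime",
    "regime_criterion",
    "integrate_orbit",
    "stoichiometry_to_phi",
    "phi_to_stoichiometry",
    "phi_dynamics",
    "fixed_point_phi",
    "observables",
    "predict_flux_field",
]

#: Tolerance on the regime criterion used to label a parameter set "critical".
CRITICAL_TOL = 1e-9


@dataclass(frozen=True)
class KineticParams:
    """The four growth-law coefficients.

    Parameters
    ----------
    k_r : float
        WSP-1 self-recruitment rate (1/s).
    k_l : float
        Branching-dependent WSP-1 loss coefficient (um^3 / IU / s).
    k_b : float
        Branching coefficient for WSP-1-dependent F-actin growth
        (um^3 / IU / s).
    k_d : float
        F-actin loss rate (1/s).
    """

    k_r: float
    k_l: float
    k_b: float
    k_d: float

    def __post_init__(self) -> None:
        for name in ("k_r", "k_l", "k_b", "k_d"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise DomainError(f"{name} must be finite and > 0, got {v!r}")

    def replace(self, **changes: float) -> "KineticParams":
        d = {"k_r": self.k_r, "k_l": self.k_l, "k_b": self.k_b, "k_d": self.k_d}
        d.update(changes)
        return KineticParams(**d)


@dataclass(frozen=True)
class VolumeCoefficients:
    """Linear volume-per-intensity coefficients (um^3 / IU)."""

    v_A: float
    v_W: float

    def __post_init__(self) -> None:
        for name in ("v_A", "v_W"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise DomainError(f"{name} must be finite and > 0, got {v!r}")


# Canonical coefficients used as generator defaults throughout the package.
# The volume coefficients are the measured values; the kinetic coefficients
# are the minimal round choice that places the WSP-1 and F-actin nullclines
# at stoichiometries 0.85 and 0.90 with a bounded (homoclinic) regime.
DEFAULT_VOLUME = VolumeCoefficients(v_A=1.54e-7, v_W=2.34e-7)
DEFAULT_PARAMS = KineticParams(k_r=0.1, k_l=1.9529e-8, k_b=2.43e-7, k_d=0.15)


@dataclass(frozen=True)
class DerivedObservables:
    """Per-state derived quantities (all computed from the volume relation)."""

    V: np.ndarray | float
    s: np.ndarray | float
    phi: np.ndarray | float
    c_A: np.ndarray | float
    c_W: np.ndarray | float


@dataclass
class Trajectory:
    """Integrated orbit of the growth laws, sampled at fixed intervals."""

    t: np.ndarray
    A: np.ndarray
    W: np.ndarray
    vol: VolumeCoefficients = field(default=DEFAULT_VOLUME)

    @property
    def stoichiometry(self) -> np.ndarray:
        tot = self.A + self.W
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(tot > 0, self.A / tot, np.nan)

    @property
    def phi(self) -> np.ndarray:
        V = volume(self.A, self.W, self.vol)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(V > 0, self.vol.v_A * self.A / V, np.nan)

    @property
    def volume(self) -> np.ndarray:
        return volume(self.A, self.W, self.vol)


def volume(A, W, vol: VolumeCoefficients = DEFAULT_VOLUME):
    """Condensate volume from molecular content, V = v_A*A + v_W*W (um^3)."""
    return vol.v_A * np.asarray(A, dtype=float) + vol.v_W * np.asarray(W, dtype=float)


def growth_rates(
    A,
    W,
    params: KineticParams = DEFAULT_PARAMS,
    vol: VolumeCoefficients = DEFAULT_VOLUME,
):
    """Evaluate (dW/dt, dA/dt) of the growth laws, vectorised over states.

    The bilinear terms are evaluated as ``(A/V)*W`` so that they remain
    finite along rays approaching the origin; exactly at (0, 0) both rates
    are zero (the fixed point).

    Returns
    -------
    (dW, dA) : tuple of ndarray or float
        Rates in IU/s, shaped like the broadcast of ``A`` and ``W``.
    """
    A = np.asarray(A, dtype=float)
    W = np.asarray(W, dtype=float)
    if np.any(A < 0) or np.any(W < 0):
        raise DomainError("amounts must be nonnegative")
    V = volume(A, W, vol)
    with np.errstate(invalid="ignore", divide="ignore"):
        bilinear = np.where(V > 0, A * W / V, 0.0)
    dW = params.k_r * W - params.k_l * bilinear
    dA = params.k_b * bilinear - params.k_d * A
    # the origin is a fixed point
    dW = np.where(V > 0, dW, 0.0)
    dA = np.where(V > 0, dA, 0.0)
    if dW.ndim == 0:
        return float(dW), float(dA)
    return dW, dA


def nullcline_stoichiometries(
    params: KineticParams = DEFAULT_PARAMS,
    vol: VolumeCoefficients = DEFAULT_VOLUME,
) -> tuple[float, float]:
    """Stoichiometries of the two nullcline rays, (s_W, s_A).

    Both nullclines are rays through the origin.  Setting dW/dt = 0 with
    W > 0 gives ``k_r = k_l * A / V``, a condition on composition only;
    likewise for dA/dt = 0.  In stoichiometry terms:

        s_W = k_r*v_W / (k_r*v_W + k_l - k_r*v_A)
        s_A = (k_b - k_d*v_W) / (k_b - k_d*v_W + k_d*v_A)

    Degenerate cases: if ``k_l <= k_r*v_A`` the WSP-1 nullcline collapses
    onto the A axis (returned as s_W = 1); if ``k_b <= k_d*v_W`` the F-actin
    nullcline collapses onto the W axis (s_A = 0).
    """
    num_W = params.k_r * vol.v_W
    den_W = num_W + params.k_l - params.k_r * vol.v_A
    s_W = 1.0 if params.k_l <= params.k_r * vol.v_A else num_W / den_W

    num_A = params.k_b - params.k_d * vol.v_W
    s_A = 0.0 if num_A <= 0 else num_A / (num_A + params.k_d * vol.v_A)
    return float(s_W), float(s_A)


def regime_criterion(
    params: KineticParams, vol: VolumeCoefficients = DEFAULT_VOLUME
) -> float:
    """The bifurcation criterion value v_A*k_r/k_l + v_W*k_d/k_b.

    Below 1 the WSP-1 nullcline lies below the F-actin nullcline and orbits
    are bounded homoclinic loops; above 1 the rays switch and growth is
    unbounded.
    """
    return vol.v_A * params.k_r / params.k_l + vol.v_W * params.k_d / params.k_b


def critical_kd(
    params: KineticParams = DEFAULT_PARAMS,
    vol: VolumeCoefficients = DEFAULT_VOLUME,
) -> float:
    """F-actin loss rate at which the two nullclines coincide.

    Solves v_A*k_r/k_l + v_W*k_d/k_b = 1 for k_d:

        k_d* = (k_b / v_W) * (1 - v_A*k_r/k_l)

    Raises
    ------
    DegenerateGeometryError
        If ``k_l <= k_r*v_A``: the WSP-1 nullcline is degenerate and no
        bounded regime exists for any k_d.
    """
    x = vol.v_A * params.k_r / params.k_l
    if x >= 1.0:
        if x == 1.0:
            return 0.0
        raise DegenerateGeometryError(
            "k_l <= k_r*v_A: WSP-1 nullcline degenerate, no bounded regime"
        )
    return params.k_b / vol.v_W * (1.0 - x)


def classify_regime(
    params: KineticParams = DEFAULT_PARAMS,
    vol: VolumeCoefficients = DEFAULT_VOLUME,
    tol: float = CRITICAL_TOL,
) -> str:
    """Classify the parameter set as 'bounded', 'unbounded' or 'critical'."""
    c = regime_criterion(params, vol)
    if abs(c - 1.0) <= tol:
        return "critical"
    return "bounded" if c < 1.0 else "unbounded"


def integrate_orbit(
    params: KineticParams,
    vol: VolumeCoefficients,
    initial: Sequence[float],
    duration: float,
    step: float = 0.1,
    rtol: float = 1e-8,
    atol: float = 1e-12,
    origin_floor: float = 1e-9,
) -> Trajectory:
    """Integrate the growth laws from ``initial = (A0, W0)``.

    Uses adaptive Runge-Kutta (RK45) with relative error control; orbits
    span decades in amplitude so relative tolerance is what matters.
    Integration terminates early once the total amount falls below
    ``origin_floor`` times its starting value: the homoclinic orbit has
    returned to the fixed point and the remaining tail is held at the
    terminal state (continuing to integrate an exponentially vanishing
    state is numerically meaningless).

    Parameters
    ----------
    initial : (A0, W0)
        Starting amounts in IU; must not both be zero.
    duration : float
        Integration horizon (s).
    step : float
        Output sampling interval (s); internal steps are adaptive.
    """
    if duration <= 0:
        raise DomainError("duration must be > 0")
    if step <= 0:
        raise DomainError("step must be > 0")
    A0, W0 = float(initial[0]), float(initial[1])
    if A0 < 0 or W0 < 0:
        raise DomainError("initial amounts must be nonnegative")
    if A0 == 0 and W0 == 0:
        raise DomainError("initial state is the fixed point (0, 0)")

    def rhs(_t, y):
        A, W = max(y[0], 0.0), max(y[1], 0.0)
        dW, dA = growth_rates(A, W, params, vol)
        return [dA, dW]

    floor = origin_floor * (A0 + W0)

    def at_origin(_t, y):
        return y[0] + y[1] - floor

    at_origin.terminal = True
    at_origin.direction = -1

    t_eval = np.arange(0.0, duration + step / 2, step)
    sol = solve_ivp(
        rhs, (0.0, duration), [A0, W0], t_eval=t_eval, rtol=rtol, atol=atol,
        method="RK45", events=at_origin,
    )
    if sol.status < 0 or not np.all(np.isfinite(sol.y)):
        raise DomainError(f"integration failed: {sol.message}")
    A = np.clip(sol.y[0], 0.0, None)
    W = np.clip(sol.y[1], 0.0, None)
    t = sol.t
    if sol.status == 1 and t.size < t_eval.size:
        # hold the terminal (origin) state over the remaining sample times
        pad = t_eval[t.size:]
        A = np.concatenate([A, np.full(pad.size, A[-1])])
        W = np.concatenate([W, np.full(pad.size, W[-1])])
        t = np.concatenate([t, pad])
    return Trajectory(t=t, A=A, W=W, vol=vol)


def stoichiometry_to_phi(s, vol: VolumeCoefficients = DEFAULT_VOLUME):
    """Convert stoichiometry s = A/(A+W) to effective F-actin volume fraction."""
    s = np.asarray(s, dtype=float)
    if np.any(s < 0) or np.any(s > 1):
        raise DomainError("stoichiometry must lie in [0, 1]")
    out = vol.v_A * s / (vol.v_A * s + vol.v_W * (1.0 - s))
    return float(out) if out.ndim == 0 else out


def phi_to_stoichiometry(phi, vol: VolumeCoefficients = DEFAULT_VOLUME):
    """Inverse of :func:`stoichiometry_to_phi`."""
    phi = np.asarray(phi, dtype=float)
    if np.any(phi < 0) or np.any(phi > 1):
        raise DomainError("phi must lie in [0, 1]")
    out = vol.v_W * phi / (vol.v_W * phi + vol.v_A * (1.0 - phi))
    return float(out) if out.ndim == 0 else out


def phi_dynamics(
    phi,
    params: KineticParams = DEFAULT_PARAMS,
    vol: VolumeCoefficients = DEFAULT_VOLUME,
):
    """Autonomous dynamics of the effective F-actin volume fraction.

    Because the amount dynamics are degree-1 homogeneous, phi evolves
    independently of condensate volume (intensive dynamics):

        dphi/dt = phi*(1-phi) * [ k_b*(1-phi)/v_W - k_d - k_r + (k_l/v_A)*phi ]

    Vanishes at phi = 0 and phi = 1 (the invariant axes).
    """
    phi = np.asarray(phi, dtype=float)
    if np.any(phi < 0) or np.any(phi > 1):
        raise DomainError("phi must lie in [0, 1]")
    bracket = (
        params.k_b * (1.0 - phi) / vol.v_W
        - params.k_d
        - params.k_r
        + (params.k_l / vol.v_A) * phi
    )
    out = phi * (1.0 - phi) * bracket
    return float(out) if out.ndim == 0 else out


def fixed_point_phi(
    params: KineticParams = DEFAULT_PARAMS,
    vol: VolumeCoefficients = DEFAULT_VOLUME,
) -> tuple[float, float]:
    """Dominant composition: interior stable root of the phi dynamics.

    The bracket in :func:`phi_dynamics` is linear in phi, with root

        phi* = (k_b/v_W - k_d - k_r) / (k_b/v_W - k_l/v_A).

    Stability (dphi/dt > 0 below, < 0 above) requires k_b/v_W > k_l/v_A and
    phi* in (0, 1).  Returns ``(phi*, s*)`` where s* is the corresponding
    stoichiometry; condensate composition dynamics are slowest at s*, so s*
    is the dominant stoichiometry of the ensemble.

    Raises
    ------
    NoDominantCompositionError
        If no stable interior root exists (unbounded-regime geometry).
    """
    slope = params.k_b / vol.v_W - params.k_l / vol.v_A
    if slope <= 0:
        raise NoDominantCompositionError(
            "phi dynamics have no stable interior root (bracket slope >= 0)"
        )
    phi_star = (params.k_b / vol.v_W - params.k_d - params.k_r) / slope
    if not (0.0 < phi_star < 1.0):
        raise NoDominantCompositionError(
            f"interior root phi*={phi_star:.4g} outside (0, 1)"
        )
    return float(phi_star), float(phi_to_stoichiometry(phi_star, vol))


def observables(A, W, vol: VolumeCoefficients = DEFAULT_VOLUME) -> DerivedObservables:
    """Derived per-state quantities V, s, phi, c_A, c_W.

    Concentrations use the relation-derived volume, so the identity
    ``v_A*c_A + v_W*c_W = 1`` holds exactly.
    """
    A = np.asarray(A, dtype=float)
    W = np.asarray(W, dtype=float)
    if np.any(A < 0) or np.any(W < 0):
        raise DomainError("amounts must be nonnegative")
    V = volume(A, W, vol)
    if np.any(V <= 0):
        raise DomainError("observables undefined at the (0, 0) state")
    s = A / (A + W)
    phi = vol.v_A * A / V
    c_A = A / V
    c_W = W / V
    if V.ndim == 0:
        return DerivedObservables(float(V), float(s), float(phi), float(c_A), float(c_W))
    return DerivedObservables(V, s, phi, c_A, c_W)


def predict_flux_field(
    params: KineticParams,
    vol: VolumeCoefficients,
    A_nodes,
    W_nodes,
):
    """Exact growth-law rates on a grid of (A, W) nodes.

    Returns a :class:`~cortexflux.fields.FluxField` whose per-bin means are
    the analytic rates evaluated at the node coordinates (no averaging, no
    masking).  Used to overlay theory arrows on empirical portraits and as
    the residual baseline for kinetic fits.
    """
    from .fields import FluxField, edges_from_centres

    A_nodes = np.asarray(A_nodes, dtype=float)
    W_nodes = np.asarray(W_nodes, dtype=float)
    AA, WW = np.meshgrid(A_nodes, W_nodes, indexing="ij")
    dW, dA = growth_rates(AA, WW, params, vol)
    zeros = np.zeros_like(dW)
    return FluxField(
        A_edges=edges_from_centres(A_nodes),
        W_edges=edges_from_centres(W_nodes),
        A_centres=A_nodes,
        W_centres=W_nodes,
        mean_dW=dW,
        mean_dA=dA,
        count=np.ones(dW.shape, dtype=int),
        sem_dW=zeros,
        sem_dA=zeros,
        min_count=0,
    )
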