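"""Kinetic-coefficient estimation from relative growth rates.

The growth laws imply that both relative rates are linear in the effective
F-actin volume fraction phi:

    (dW/dt)/W = k_r - (k_l/v_A) * phi
    (dA/dt)/A = (k_b/v_W) * (1 - phi) - k_d

so two weighted linear regressions of per-point relative rates on phi,
restricted to the validity window of the volume relation, recover all four
coefficients:

    k_r = intercept_W            k_l = -slope_W * v_A
    k_b = -slope_A * v_W         k_d = -slope_A - intercept_A

Uncertainties come from a bootstrap over condensates.  The same module
compares fitted conditions (RNAi fold changes), predicts perturbed phase
portraits, and extrapolates a lower bound on the F-actin loss rate for
conditions with no measurable condensates.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field as dc_field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import DomainError
from .fields import FluxField
from .model import (
    KineticParams,
    VolumeCoefficients,
    classify_regime,
    critical_kd,
    nullcline_stoichiometries,
    predict_flux_field,
    stoichiometry_to_phi,
)
from .volume import DEFAULT_WINDOW, VolumeModel

__all__ = [
    "KineticFit",
    "ConditionComparison",
    "PerturbedPortrait",
    "fit_kinetics",
    "compare_conditions",
    "predict_perturbed_portrait",
    "estimate_kd_lower_bound",
]

log = logging.getLogger(__name__)

COEFFS = ("k_r", "k_l", "k_b", "k_d")


@dataclass
class KineticFit:
    """Fitted growth-law coefficients with diagnostics."""

    params: KineticParams
    vol: VolumeCoefficients
    standard_errors: dict
    window_phi: tuple[float, float]
    n_points: int
    r_squared: dict
    residual_trend: dict
    flags: list = dc_field(default_factory=list)

    @property
    def regime(self) -> str:
        return classify_regime(self.params, self.vol)

    def to_dict(self) -> dict:
        return {
            "k_r": self.params.k_r,
            "k_l": self.params.k_l,
            "k_b": self.params.k_b,
            "k_d": self.params.k_d,
            "v_A": self.vol.v_A,
            "v_W": self.vol.v_W,
            "se": dict(self.standard_errors),
            "window_phi": list(self.window_phi),
            "n_points": self.n_points,
            "r_squared": dict(self.r_squared),
            "residual_trend": dict(self.residual_trend),
            "flags": list(self.flags),
            "regime": self.regime,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "KineticFit":
        return cls(
            params=KineticParams(d["k_r"], d["k_l"], d["k_b"], d["k_d"]),
            vol=VolumeCoefficients(d["v_A"], d["v_W"]),
            standard_errors=dict(d.get("se", {})),
            window_phi=tuple(d.get("window_phi", (0.0, 1.0))),
            n_points=int(d.get("n_points", 0)),
            r_squared=dict(d.get("r_squared", {})),
            residual_trend=dict(d.get("residual_trend", {})),
            flags=list(d.get("flags", [])),
        )


def _weighted_linefit(x, y, w):
    """Weighted least squares of y on [1, x]; returns (intercept, slope)."""
    sw = np.sqrt(w)
    X = np.column_stack([sw, sw * x])
    beta, *_ = np.linalg.lstsq(X, sw * y, rcond=None)
    return beta[0], beta[1]


def fit_kinetics(
    points: pd.DataFrame,
    model: VolumeModel,
    window: tuple[float, float] = DEFAULT_WINDOW,
    min_amount: float = 0.5,
    n_boot: int = 200,
    rng_seed: int = 0,
    min_points: int = 100,
) -> KineticFit:
    """Estimate the four kinetic coefficients from per-point rates.

    Parameters
    ----------
    points : DataFrame
        Output of :func:`cortexflux.portrait.derivatives_table` (columns
        ``a_iu, w_iu, da, dw`` plus ``condensate_id`` for the bootstrap).
    model : VolumeModel
        Supplies (v_A, v_W) and the stoichiometry validity window; the
        fitting window in phi is the image of the stoichiometry window.
    min_amount : float
        Points with either amount below this floor are excluded (relative
        rates diverge as amounts approach zero).

    Notes
    -----
    Weights are proportional to the respective amount, stabilising the
    variance of relative rates under multiplicative noise.  A nonnegative
    slope in either regression would violate positivity of k_l or k_b; the
    fit is then flagged rather than silently clipped.
    """
    co = model.coefficients
    A = points["a_iu"].to_numpy(float)
    W = points["w_iu"].to_numpy(float)
    dA = points["da"].to_numpy(float)
    dW = points["dw"].to_numpy(float)
    V = co.v_A * A + co.v_W * W
    ok = (A > min_amount) & (W > min_amount)
    phi_lo = stoichiometry_to_phi(window[0], co)
    phi_hi = stoichiometry_to_phi(window[1], co)
    with np.errstate(invalid="ignore", divide="ignore"):
        phi = np.where(V > 0, co.v_A * A / V, np.nan)
    ok &= (phi >= phi_lo) & (phi <= phi_hi)
    n_in = int(ok.sum())
    if n_in < min_points:
        raise DomainError(f"only {n_in} usable points in the phi window, need {min_points}")
    A, W, dA, dW, phi = A[ok], W[ok], dA[ok], dW[ok], phi[ok]
    rel_W = dW / W
    rel_A = dA / A

    flags: list[str] = []
    res_W = sm.WLS(rel_W, sm.add_constant(phi), weights=W).fit()
    res_A = sm.WLS(rel_A, sm.add_constant(phi), weights=A).fit()
    b_W, m_W = res_W.params
    b_A, m_A = res_A.params
    if m_W >= 0:
        flags.append("nonnegative_W_slope")
        warnings.warn("nonnegative slope in the WSP-1 regression (k_l <= 0)", stacklevel=2)
    if m_A >= 0:
        flags.append("nonnegative_A_slope")
        warnings.warn("nonnegative slope in the F-actin regression (k_b <= 0)", stacklevel=2)

    k_r = float(b_W)
    k_l = float(-m_W * co.v_A)
    k_b = float(-m_A * co.v_W)
    k_d = float(-m_A - b_A)

    # residual trend vs phi (quadratic term of an OLS on residuals)
    trend = {}
    for name, res, x in (("W", res_W, phi), ("A", res_A, phi)):
        r = res.resid
        c = np.polyfit(x, r, 1)
        trend[name] = float(c[0])

    se: dict[str, float] = {c: 0.0 for c in COEFFS}
    if n_boot > 0 and "condensate_id" in points.columns:
        ids = points["condensate_id"].to_numpy()[ok]
        uniq = np.unique(ids)
        groups = {u: np.flatnonzero(ids == u) for u in uniq}
        rng = np.random.default_rng(rng_seed)
        draws = np.empty((n_boot, 4))
        for b in range(n_boot):
            pick = rng.choice(uniq, size=uniq.size, replace=True)
            idx = np.concatenate([groups[u] for u in pick])
            bw, mw = _weighted_linefit(phi[idx], rel_W[idx], W[idx])
            ba, ma = _weighted_linefit(phi[idx], rel_A[idx], A[idx])
            draws[b] = (bw, -mw * co.v_A, -ma * co.v_W, -ma - ba)
        sds = draws.std(axis=0, ddof=1)
        se = dict(zip(COEFFS, map(float, sds)))

    if min(k_r, k_l, k_b, k_d) <= 0:
        flags.append("nonpositive_coefficient")
        params = KineticParams(
            k_r=max(k_r, np.finfo(float).tiny),
            k_l=max(k_l, np.finfo(float).tiny),
            k_b=max(k_b, np.finfo(float).tiny),
            k_d=max(k_d, np.finfo(float).tiny),
        )
    else:
        params = KineticParams(k_r=k_r, k_l=k_l, k_b=k_b, k_d=k_d)
    return KineticFit(
        params=params,
        vol=co,
        standard_errors=se,
        window_phi=(float(phi_lo), float(phi_hi)),
        n_points=n_in,
        r_squared={"W": float(res_W.rsquared), "A": float(res_A.rsquared)},
        residual_trend=trend,
        flags=flags,
    )


@dataclass
class ConditionComparison:
    """Coefficient changes between a control and a perturbed condition."""

    fold_changes: dict
    percent_changes: dict
    fold_se: dict
    control_regime: str
    perturbed_regime: str
    control_critical_kd: float
    perturbed_kd_exceeds_critical: bool

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coefficient": list(COEFFS),
                "fold": [self.fold_changes[c] for c in COEFFS],
                "percent": [self.percent_changes[c] for c in COEFFS],
                "fold_se": [self.fold_se[c] for c in COEFFS],
            }
        )


def compare_conditions(control: KineticFit, perturbed: KineticFit) -> ConditionComparison:
    """Per-coefficient fold and percent changes with propagated errors.

    Fold-change errors use first-order propagation of the two bootstrap
    standard errors.  Also reports the control critical F-actin loss rate
    and whether the perturbed k_d exceeds it (nullcline switch predicted).
    """
    folds, pcts, ses = {}, {}, {}
    for c in COEFFS:
        x0 = getattr(control.params, c)
        x1 = getattr(perturbed.params, c)
        f = x1 / x0
        folds[c] = float(f)
        pcts[c] = float(100.0 * (f - 1.0))
        s0 = control.standard_errors.get(c, 0.0)
        s1 = perturbed.standard_errors.get(c, 0.0)
        ses[c] = float(abs(f) * np.sqrt((s0 / x0) ** 2 + (s1 / x1) ** 2))
    kd_star = critical_kd(control.params, control.vol)
    return ConditionComparison(
        fold_changes=folds,
        percent_changes=pcts,
        fold_se=ses,
        control_regime=control.regime,
        perturbed_regime=perturbed.regime,
        control_critical_kd=float(kd_star),
        perturbed_kd_exceeds_critical=bool(perturbed.params.k_d > kd_star),
    )


@dataclass
class PerturbedPortrait:
    """Theory portrait predicted for an overridden F-actin loss rate."""

    params: KineticParams
    field: FluxField
    s_W: float
    s_A: float
    nullclines_switched: bool
    regime: str


def predict_perturbed_portrait(
    control: KineticFit,
    kd_override: float,
    A_nodes: Optional[np.ndarray] = None,
    W_nodes: Optional[np.ndarray] = None,
) -> PerturbedPortrait:
    """Substitute k_d into a fitted model and predict the phase portrait.

    Used for conditions where no dynamic condensates exist to measure:
    the control fit supplies k_r, k_l, k_b and an extrapolated k_d is
    imposed.  Reports whether the nullclines are switched relative to the
    bounded ordering: the F-actin nullcline moves above the WSP-1
    nullcline in the amount plane, i.e. s_A < s_W in stoichiometry.
    """
    if kd_override <= 0:
        raise DomainError("kd_override must be > 0")
    params = control.params.replace(k_d=kd_override)
    if A_nodes is None:
        A_nodes = np.geomspace(1.0, 1e3, 25)
    if W_nodes is None:
        W_nodes = np.geomspace(1.0, 1e3, 25)
    fld = predict_flux_field(params, control.vol, A_nodes, W_nodes)
    s_W, s_A = nullcline_stoichiometries(params, control.vol)
    return PerturbedPortrait(
        params=params,
        field=fld,
        s_W=s_W,
        s_A=s_A,
        nullclines_switched=bool(s_A < s_W),
        regime=classify_regime(params, control.vol),
    )


def estimate_kd_lower_bound(
    kd_values: Sequence[float],
    counts: Sequence[float],
) -> float:
    """Lower-bound k_d for a condition with no measurable condensates.

    Conditions are ordered by severity (decreasing condensate count); the
    fitted k_d values are extrapolated linearly in severity rank to the
    position of the zero-count condition.  Returned as a lower bound (the
    true value may exceed it).

    Parameters
    ----------
    kd_values : sequence of float
        Fitted F-actin loss rates for conditions with dynamic condensates,
        ordered by increasing severity.
    counts : sequence of float
        Condensate counts for the same conditions (used to check ordering;
        severity = rank, not count magnitude).
    """
    kd_values = np.asarray(kd_values, float)
    counts = np.asarray(counts, float)
    if kd_values.size < 2:
        raise DomainError("need at least two fitted conditions to extrapolate")
    if kd_values.size != counts.size:
        raise DomainError("kd_values and counts must have equal length")
    if np.any(np.diff(counts) > 0):
        warnings.warn("condensate counts are not decreasing with severity", stacklevel=2)
    if np.any(np.diff(kd_values) < 0):
        warnings.warn("fitted k_d not monotone across severity; extrapolating anyway",
                      stacklevel=2)
    rank = np.arange(kd_values.size, dtype=float)
    slope, intercept = np.polyfit(rank, kd_values, 1)
    return float(intercept + slope * kd_values.size)
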