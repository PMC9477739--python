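"""The linear volume relation V = v_A*A + v_W*W.

Condensate volumes measured from cross-sectional areas (spherical
assumption) are well described, within a stoichiometry window, by summing
per-intensity volume contributions of the two channels.  This module fits
the two coefficients by zero-intercept least squares, converts areas to
volumes, computes concentrations and exposes the line of constant total
density ``v_A*c_A + v_W*c_W = 1`` that the relation implies in
concentration space.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import DomainError, RankDeficientDesignError
from .model import VolumeCoefficients

__all__ = [
    "VolumeModel",
    "DensityLine",
    "sphere_volume_from_area",
    "fit_volume_coefficients",
    "concentrations",
    "density_line",
]

log = logging.getLogger(__name__)

#: Stoichiometry window within which the linear volume relation holds.
DEFAULT_WINDOW = (0.65, 0.93)


@dataclass(frozen=True)
class VolumeModel:
    """Fitted volume relation with its validity window and uncertainties."""

    coefficients: VolumeCoefficients
    window: tuple[float, float] = DEFAULT_WINDOW
    se_v_A: float = 0.0
    se_v_W: float = 0.0
    n_points: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.window
        if not (0.0 <= lo < hi <= 1.0):
            raise DomainError(f"invalid stoichiometry window {self.window}")
        if self.se_v_A < 0 or self.se_v_W < 0:
            raise DomainError("uncertainties must be nonnegative")


@dataclass(frozen=True)
class DensityLine:
    """The locus v_A*c_A + v_W*c_W = 1 in concentration space."""

    coefficients: VolumeCoefficients

    @property
    def c_A_intercept(self) -> float:
        return 1.0 / self.coefficients.v_A

    @property
    def c_W_intercept(self) -> float:
        return 1.0 / self.coefficients.v_W

    def residual(self, c_A, c_W):
        """Signed deviation of concentration pairs from the line."""
        return (
            self.coefficients.v_A * np.asarray(c_A, float)
            + self.coefficients.v_W * np.asarray(c_W, float)
            - 1.0
        )

    def c_W_of_c_A(self, c_A):
        """The line solved for c_W."""
        return (1.0 - self.coefficients.v_A * np.asarray(c_A, float)) / self.coefficients.v_W


def sphere_volume_from_area(area):
    """Volume of a sphere whose cross-section has the given area (um^2 -> um^3)."""
    area = np.asarray(area, dtype=float)
    if np.any(area < 0):
        raise DomainError("area must be nonnegative")
    r = np.sqrt(area / np.pi)
    out = 4.0 / 3.0 * np.pi * r**3
    return float(out) if out.ndim == 0 else out


def fit_volume_coefficients(
    table: pd.DataFrame,
    window: tuple[float, float] = DEFAULT_WINDOW,
    n_boot: int = 200,
    rng_seed: int = 0,
    min_points: int = 10,
) -> VolumeModel:
    """Fit (v_A, v_W) by zero-intercept least squares of measured volume on
    the two amounts, restricted to the stoichiometry window.

    The relation has no offset by construction, so no constant term is
    included.  Uncertainties come from a bootstrap that resamples whole
    condensates (points within a track are autocorrelated).

    Parameters
    ----------
    table : DataFrame
        Track table with columns ``a_iu``, ``w_iu``, ``area_um2`` and
        ``condensate_id``.

    Raises
    ------
    DomainError
        Fewer than ``min_points`` usable points in the window.
    RankDeficientDesignError
        All in-window points share one stoichiometry (collinear design).
    """
    t = table.dropna(subset=["area_um2"])
    A = t["a_iu"].to_numpy(float)
    W = t["w_iu"].to_numpy(float)
    tot = A + W
    with np.errstate(invalid="ignore", divide="ignore"):
        s = np.where(tot > 0, A / tot, np.nan)
    inside = (s >= window[0]) & (s <= window[1]) & np.isfinite(s)
    if inside.sum() < min_points:
        raise DomainError(
            f"only {int(inside.sum())} points in stoichiometry window, need {min_points}"
        )
    A, W = A[inside], W[inside]
    V = sphere_volume_from_area(t["area_um2"].to_numpy(float)[inside])
    ids = t["condensate_id"].to_numpy()[inside]

    X = np.column_stack([A, W])
    if np.linalg.matrix_rank(X) < 2:
        raise RankDeficientDesignError(
            "all points share one stoichiometry; v_A and v_W are not identifiable"
        )
    res = sm.OLS(V, X).fit()
    v_A, v_W = res.params

    se_A = se_W = 0.0
    if n_boot > 0:
        rng = np.random.default_rng(rng_seed)
        uniq = np.unique(ids)
        groups = {u: np.flatnonzero(ids == u) for u in uniq}
        boots = np.empty((n_boot, 2))
        for b in range(n_boot):
            pick = rng.choice(uniq, size=uniq.size, replace=True)
            idx = np.concatenate([groups[u] for u in pick])
            Xb, Vb = X[idx], V[idx]
            if np.linalg.matrix_rank(Xb) < 2:
                boots[b] = (v_A, v_W)
                continue
            boots[b], *_ = np.linalg.lstsq(Xb, Vb, rcond=None)
        se_A, se_W = boots.std(axis=0, ddof=1)

    return VolumeModel(
        coefficients=VolumeCoefficients(v_A=float(v_A), v_W=float(v_W)),
        window=window,
        se_v_A=float(se_A),
        se_v_W=float(se_W),
        n_points=int(inside.sum()),
    )


def concentrations(
    table: pd.DataFrame,
    model: VolumeModel,
    volume_source: str = "relation",
) -> pd.DataFrame:
    """Per-point concentrations (c_A, c_W) in IU/um^3.

    With ``volume_source='relation'`` the volume is v_A*A + v_W*W, so all
    returned pairs satisfy the density-line identity exactly.  With
    ``'measured'`` the spherical conversion of the measured area is used;
    points with nonpositive or missing volume are dropped (count logged).
    """
    A = table["a_iu"].to_numpy(float)
    W = table["w_iu"].to_numpy(float)
    co = model.coefficients
    if volume_source == "relation":
        V = co.v_A * A + co.v_W * W
    elif volume_source == "measured":
        area = table["area_um2"].to_numpy(float)
        V = sphere_volume_from_area(np.nan_to_num(area, nan=0.0))
        V = np.where(np.isfinite(area), V, np.nan)
    else:
        raise DomainError(f"unknown volume_source {volume_source!r}")
    ok = np.isfinite(V) & (V > 0)
    n_dropped = int((~ok).sum())
    if n_dropped:
        log.info("concentrations: dropped %d points with nonpositive volume", n_dropped)
    out = table.loc[ok, ["condition", "oocyte_id", "condensate_id", "t"]].copy()
    out["c_a"] = A[ok] / V[ok]
    out["c_w"] = W[ok] / V[ok]
    return out.reset_index(drop=True)


def density_line(model: VolumeModel) -> DensityLine:
    """Line of constant total density implied by the volume relation."""
    return DensityLine(coefficients=model.coefficients)
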