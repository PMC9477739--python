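"""Mass-balance-imaging reconstruction of condensate phase portraits.

Given tracked per-condensate intensity time series, this module estimates
per-point time derivatives (net molecular fluxes), bins them into vector
fields over the (A, W) amount plane and the (phi, V) composition-volume
plane, extracts empirical nullclines as constant-stoichiometry rays,
summarises growth rates against stoichiometry, and locates the preferred
concentration pair via 2-D kernel density estimation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter, map_coordinates, maximum_filter
from scipy.signal import savgol_filter
from scipy.stats import binned_statistic_2d
from skimage import measure

from .errors import (
    DomainError,
    EmptyFieldError,
    EmptySliceError,
    NoNullclineError,
)
from .fields import FluxField, PhiVField, geometric_edges
from .model import VolumeCoefficients
from .volume import VolumeModel

__all__ = [
    "estimate_derivatives",
    "derivatives_table",
    "bin_vector_field",
    "EmpiricalNullcline",
    "extract_nullcline",
    "growth_vs_stoichiometry",
    "zero_crossing_stoichiometry",
    "Contour",
    "occupancy_contours",
    "PreferredPair",
    "preferred_concentration_pair",
    "phi_V_field",
    "volume_nullcline_phi",
    "intensivity_slopes",
    "conditional_rate_slices",
]


# ---------------------------------------------------------------------------
# derivatives


def estimate_derivatives(track: pd.DataFrame, smooth: bool = False) -> pd.DataFrame:
    """Central-difference time derivatives of both channels for one track.

    Endpoints are dropped (no one-sided estimates); central differences are
    exact for quadratics, so the leading bias is O(dt^2).  With ``smooth``
    a local-quadratic (Savitzky-Golay, 5-frame window) derivative replaces
    the plain difference — off by default because smoothing biases rates
    near the loop's turning points.

    Raises
    ------
    DomainError
        Track shorter than 3 frames or irregular spacing beyond 1%.
    """
    if len(track) < 3:
        raise DomainError("need at least 3 frames for central differences")
    t = track["t"].to_numpy(float)
    dts = np.diff(t)
    dt = np.median(dts)
    if dt <= 0 or np.any(np.abs(dts - dt) > 0.01 * dt):
        raise DomainError("irregular time spacing beyond 1% tolerance")
    w = track["w_iu"].to_numpy(float)
    a = track["a_iu"].to_numpy(float)
    if smooth and len(track) >= 5:
        dw = savgol_filter(w, 5, 2, deriv=1, delta=dt)[1:-1]
        da = savgol_filter(a, 5, 2, deriv=1, delta=dt)[1:-1]
    else:
        dw = (w[2:] - w[:-2]) / (2.0 * dt)
        da = (a[2:] - a[:-2]) / (2.0 * dt)
    out = track.iloc[1:-1].copy()
    out["dw"] = dw
    out["da"] = da
    return out


def derivatives_table(table: pd.DataFrame, smooth: bool = False) -> pd.DataFrame:
    """Apply :func:`estimate_derivatives` per condensate; concatenated result."""
    parts = [
        estimate_derivatives(g, smooth=smooth)
        for _, g in table.groupby(["oocyte_id", "condensate_id"], sort=False)
        if len(g) >= 3
    ]
    if not parts:
        raise DomainError("no track long enough for derivative estimation")
    return pd.concat(parts, ignore_index=True)


# ---------------------------------------------------------------------------
# binned vector fields


def bin_vector_field(
    points: pd.DataFrame,
    n_bins: int = 24,
    min_count: int = 20,
) -> FluxField:
    """Bin per-point rates into a mean vector field over the amount plane.

    Bins are geometric (log-spaced) on each axis because amounts span
    roughly two orders of magnitude.  Means and SEMs are permutation
    invariant by construction.
    """
    if len(points) < 1:
        raise EmptyFieldError("no points to bin")
    A = points["a_iu"].to_numpy(float)
    W = points["w_iu"].to_numpy(float)
    pos = (A > 0) & (W > 0)
    A, W = A[pos], W[pos]
    dW = points["dw"].to_numpy(float)[pos]
    dA = points["da"].to_numpy(float)[pos]
    if A.size == 0:
        raise EmptyFieldError("no strictly positive points to bin")
    A_edges = geometric_edges(A, n_bins)
    W_edges = geometric_edges(W, n_bins)

    def stats(values):
        mean = binned_statistic_2d(A, W, values, "mean", bins=[A_edges, W_edges]).statistic
        std = binned_statistic_2d(A, W, values, "std", bins=[A_edges, W_edges]).statistic
        return mean, std

    count = binned_statistic_2d(A, W, None, "count", bins=[A_edges, W_edges]).statistic
    count = count.astype(int)
    mean_dW, std_dW = stats(dW)
    mean_dA, std_dA = stats(dA)
    with np.errstate(invalid="ignore", divide="ignore"):
        sem_dW = np.where(count > 1, std_dW / np.sqrt(np.maximum(count, 1)), np.nan)
        sem_dA = np.where(count > 1, std_dA / np.sqrt(np.maximum(count, 1)), np.nan)
    field = FluxField(
        A_edges=A_edges,
        W_edges=W_edges,
        A_centres=np.sqrt(A_edges[:-1] * A_edges[1:]),
        W_centres=np.sqrt(W_edges[:-1] * W_edges[1:]),
        mean_dW=mean_dW,
        mean_dA=mean_dA,
        count=count,
        sem_dW=sem_dW,
        sem_dA=sem_dA,
        min_count=min_count,
    )
    if np.all(field.masked):
        raise EmptyFieldError(f"no bin reached min_count={min_count}")
    return field


# ---------------------------------------------------------------------------
# nullclines


@dataclass
class EmpiricalNullcline:
    """A nullcline summarised as a constant-stoichiometry ray through the origin."""

    component: str  # "W" or "A"
    zero_points: np.ndarray  # (n, 2) array of (A, W) crossing coordinates
    fitted_stoichiometry: float
    stoichiometry_se: float


def _ray_stoichiometry(pts: np.ndarray) -> float:
    """Total-least-squares ray through the origin for (A, W) points.

    Points are normalised to unit length first so that large-amount bins do
    not dominate; the ray direction is the top eigenvector of the outer
    product sum, which minimises summed perpendicular distances.
    """
    norms = np.linalg.norm(pts, axis=1)
    u = pts[norms > 0] / norms[norms > 0, None]
    M = u.T @ u
    evals, evecs = np.linalg.eigh(M)
    d = evecs[:, np.argmax(evals)]
    if d.sum() < 0:
        d = -d
    return float(d[0] / (d[0] + d[1]))


def extract_nullcline(
    field: FluxField,
    component: str = "W",
    n_boot: int = 200,
    rng_seed: int = 0,
    z_min: float = 2.0,
    min_crossings: int = 3,
) -> EmpiricalNullcline:
    """Locate the empirical nullcline of one rate component.

    For each A column the binned mean rate is scanned along W.  A crossing
    is registered between two bins whose means are both significantly
    nonzero (``z_min`` standard errors) with opposite signs, with only
    insignificant bins between them; the zero is placed by linear
    interpolation between the two significant bin centres.  Requiring
    significance on both flanks stops sampling noise at the edge of the
    occupied region from fabricating crossings, while allowing gaps of
    small-mean bins right at the nullcline where the rate genuinely
    approaches zero.  The crossings are summarised by a
    total-least-squares ray through the origin (constant stoichiometry);
    the uncertainty is a bootstrap over crossing points.

    Raises
    ------
    NoNullclineError
        Fewer than ``min_crossings`` significant sign changes — expected
        for unbounded-regime data, where one rate does not change sign
        over the occupied region.
    """
    if component not in ("W", "A"):
        raise DomainError("component must be 'W' or 'A'")
    rates = field.mean_dW if component == "W" else field.mean_dA
    sems = field.sem_dW if component == "W" else field.sem_dA
    ok = ~field.masked & np.isfinite(rates)
    crossings = []
    nA, nW = rates.shape
    for i in range(nA):
        cols = np.flatnonzero(ok[i])
        sig = []
        for j in cols:
            s = sems[i, j]
            if (not np.isfinite(s)) or s == 0:
                if rates[i, j] != 0.0:
                    sig.append(j)  # exact (theory) fields
            elif abs(rates[i, j]) > z_min * s:
                sig.append(j)
        for j0, j1 in zip(sig[:-1], sig[1:]):
            r0, r1 = rates[i, j0], rates[i, j1]
            if r0 * r1 < 0:
                f = r0 / (r0 - r1)
                w0, w1 = field.W_centres[j0], field.W_centres[j1]
                crossings.append((field.A_centres[i], w0 + f * (w1 - w0)))
    if len(crossings) < min_crossings:
        raise NoNullclineError(
            f"only {len(crossings)} significant sign change(s) for the {component} "
            f"rate (need {min_crossings} for a credible nullcline)"
        )
    pts = np.asarray(crossings, dtype=float)
    s_hat = _ray_stoichiometry(pts)
    se = 0.0
    if n_boot > 0 and len(pts) > 1:
        rng = np.random.default_rng(rng_seed)
        boots = np.empty(n_boot)
        for b in range(n_boot):
            idx = rng.integers(0, len(pts), size=len(pts))
            boots[b] = _ray_stoichiometry(pts[idx])
        se = float(boots.std(ddof=1))
    return EmpiricalNullcline(
        component=component,
        zero_points=pts,
        fitted_stoichiometry=s_hat,
        stoichiometry_se=se,
    )


# ---------------------------------------------------------------------------
# growth-rate-vs-stoichiometry curves


def growth_vs_stoichiometry(
    points: pd.DataFrame,
    n_bins: int = 20,
    min_count: int = 20,
) -> pd.DataFrame:
    """Binned mean growth rates of both channels against stoichiometry.

    Returns a tidy frame with columns ``s_centre, mean_dw, sem_dw,
    mean_da, sem_da, count`` restricted to bins meeting ``min_count``.
    In the bounded regime the dW curve crosses zero at a lower
    stoichiometry than the dA curve.
    """
    A = points["a_iu"].to_numpy(float)
    W = points["w_iu"].to_numpy(float)
    tot = A + W
    ok = tot > 0
    s = A[ok] / tot[ok]
    dW = points["dw"].to_numpy(float)[ok]
    dA = points["da"].to_numpy(float)[ok]
    edges = np.linspace(s.min(), np.nextafter(s.max(), 2), n_bins + 1)
    idx = np.clip(np.digitize(s, edges) - 1, 0, n_bins - 1)
    rows = []
    for b in range(n_bins):
        m = idx == b
        n = int(m.sum())
        if n < min_count:
            continue
        rows.append(
            {
                "s_centre": 0.5 * (edges[b] + edges[b + 1]),
                "mean_dw": dW[m].mean(),
                "sem_dw": dW[m].std(ddof=1) / np.sqrt(n),
                "mean_da": dA[m].mean(),
                "sem_da": dA[m].std(ddof=1) / np.sqrt(n),
                "count": n,
            }
        )
    if not rows:
        raise EmptyFieldError(f"no stoichiometry bin reached min_count={min_count}")
    return pd.DataFrame(rows)


def zero_crossing_stoichiometry(curve: pd.DataFrame, column: str) -> float:
    """Interpolated stoichiometry at which a binned mean rate crosses zero
    from positive to negative (raises if there is no such crossing)."""
    s = curve["s_centre"].to_numpy()
    y = curve[column].to_numpy()
    for i in range(len(y) - 1):
        if y[i] > 0 >= y[i + 1]:
            f = y[i] / (y[i] - y[i + 1])
            return float(s[i] + f * (s[i + 1] - s[i]))
    raise NoNullclineError(f"no positive-to-negative crossing in {column}")


# ---------------------------------------------------------------------------
# kernel-density utilities (binned KDE: 2-D histogram + Gaussian smoothing)


def _kde_grid(x, y, n_grid: int = 128, bandwidth_scale: float = 1.0):
    """Binned Gaussian KDE on a regular grid with Silverman bandwidths.

    Returns (x_grid, y_grid, density, point_density) where point_density
    evaluates the KDE at the input points by bilinear interpolation.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size
    hx = np.std(x, ddof=1) * n ** (-1.0 / 6.0) * bandwidth_scale
    hy = np.std(y, ddof=1) * n ** (-1.0 / 6.0) * bandwidth_scale
    if hx <= 0 or hy <= 0:
        raise DomainError("degenerate point cloud (zero variance)")
    x_edges = np.linspace(x.min() - 3 * hx, x.max() + 3 * hx, n_grid + 1)
    y_edges = np.linspace(y.min() - 3 * hy, y.max() + 3 * hy, n_grid + 1)
    H, _, _ = np.histogram2d(x, y, bins=[x_edges, y_edges])
    dx = x_edges[1] - x_edges[0]
    dy = y_edges[1] - y_edges[0]
    dens = gaussian_filter(H, sigma=(hx / dx, hy / dy), mode="constant")
    dens /= dens.sum() * dx * dy
    xc = 0.5 * (x_edges[:-1] + x_edges[1:])
    yc = 0.5 * (y_edges[:-1] + y_edges[1:])
    ci = (x - xc[0]) / dx
    cj = (y - yc[0]) / dy
    pt_dens = map_coordinates(dens, np.vstack([ci, cj]), order=1, mode="nearest")
    return xc, yc, dens, pt_dens


@dataclass
class Contour:
    """A highest-density region at one probability level."""

    level: float
    threshold: float
    polygons: list  # list of (n, 2) arrays in data coordinates
    enclosed_fraction: float
    centroid: tuple[float, float]


def occupancy_contours(
    points: pd.DataFrame,
    x: str = "c_a",
    y: str = "c_w",
    levels: tuple[float, ...] = (0.68, 0.25),
    n_grid: int = 128,
) -> list[Contour]:
    """Highest-density-region contours containing the stated point mass.

    The density threshold for each level is the (1 - level) quantile of the
    KDE density evaluated at the points themselves, so the enclosed point
    fraction is calibrated by construction (within histogram discreteness).
    """
    if len(points) < 100:
        raise DomainError("need at least 100 points for occupancy contours")
    xs = points[x].to_numpy(float)
    ys = points[y].to_numpy(float)
    xc, yc, dens, pt_dens = _kde_grid(xs, ys, n_grid=n_grid)
    out = []
    for level in levels:
        thr = float(np.quantile(pt_dens, 1.0 - level))
        inside = pt_dens >= thr
        polys = []
        for contour in measure.find_contours(dens, thr):
            px = np.interp(contour[:, 0], np.arange(xc.size), xc)
            py = np.interp(contour[:, 1], np.arange(yc.size), yc)
            polys.append(np.column_stack([px, py]))
        out.append(
            Contour(
                level=level,
                threshold=thr,
                polygons=polys,
                enclosed_fraction=float(inside.mean()),
                centroid=(float(xs[inside].mean()), float(ys[inside].mean())),
            )
        )
    return out


@dataclass
class PreferredPair:
    """Mode of the 2-D concentration density with bootstrap spread."""

    c_A: float
    c_W: float
    c_A_se: float
    c_W_se: float
    ambiguous: bool = False


def preferred_concentration_pair(
    points: pd.DataFrame,
    n_grid: int = 128,
    n_boot: int = 50,
    rng_seed: int = 0,
) -> PreferredPair:
    """Preferred (most commonly maintained) concentration pair.

    Located as the mode of the binned KDE of instantaneous (c_A, c_W)
    pairs.  If a second local maximum comes within 1% of the peak height an
    ambiguity flag is set and the highest peak is returned.  The spread is
    a bootstrap over condensates when an id column is present, else over
    points.
    """
    if len(points) < 100:
        raise DomainError("need at least 100 points")
    xs = points["c_a"].to_numpy(float)
    ys = points["c_w"].to_numpy(float)
    if np.ptp(xs) == 0 and np.ptp(ys) == 0:
        # degenerate point mass: the mode is the point itself
        return PreferredPair(float(xs[0]), float(ys[0]), 0.0, 0.0)

    def mode_of(xv, yv):
        xc, yc, dens, _ = _kde_grid(xv, yv, n_grid=n_grid)
        i, j = np.unravel_index(np.argmax(dens), dens.shape)
        return float(xc[i]), float(yc[j]), dens

    cA, cW, dens = mode_of(xs, ys)
    local_max = (dens == maximum_filter(dens, size=5)) & (dens > 0)
    peaks = np.sort(dens[local_max])[::-1]
    ambiguous = len(peaks) > 1 and peaks[1] >= 0.99 * peaks[0]

    se_A = se_W = 0.0
    if n_boot > 0:
        rng = np.random.default_rng(rng_seed)
        if "condensate_id" in points.columns:
            ids = points["condensate_id"].to_numpy()
            uniq = np.unique(ids)
            groups = {u: np.flatnonzero(ids == u) for u in uniq}
            draws = np.empty((n_boot, 2))
            for b in range(n_boot):
                pick = rng.choice(uniq, size=uniq.size, replace=True)
                idx = np.concatenate([groups[u] for u in pick])
                draws[b, 0], draws[b, 1], _ = mode_of(xs[idx], ys[idx])
        else:
            draws = np.empty((n_boot, 2))
            for b in range(n_boot):
                idx = rng.integers(0, xs.size, size=xs.size)
                draws[b, 0], draws[b, 1], _ = mode_of(xs[idx], ys[idx])
        se_A, se_W = draws.std(axis=0, ddof=1)
    return PreferredPair(cA, cW, float(se_A), float(se_W), ambiguous)


# ---------------------------------------------------------------------------
# (phi, V) plane


def phi_V_field(
    points: pd.DataFrame,
    model: VolumeModel,
    n_bins: int = 24,
    min_count: int = 20,
) -> PhiVField:
    """Vector field of composition-volume dynamics, (dphi/dt, dV/dt).

    Per-point rates follow by the chain rule from the amount rates using
    the relation volume:  dV = v_A*dA + v_W*dW  and
    dphi = (v_A*dA - phi*dV) / V.  phi bins are linear, V bins geometric.
    """
    co: VolumeCoefficients = model.coefficients
    A = points["a_iu"].to_numpy(float)
    W = points["w_iu"].to_numpy(float)
    dA = points["da"].to_numpy(float)
    dW = points["dw"].to_numpy(float)
    V = co.v_A * A + co.v_W * W
    ok = V > 0
    A, W, dA, dW, V = A[ok], W[ok], dA[ok], dW[ok], V[ok]
    if V.size == 0:
        raise EmptyFieldError("no points with positive volume")
    phi = co.v_A * A / V
    dV = co.v_A * dA + co.v_W * dW
    dphi = (co.v_A * dA - phi * dV) / V

    phi_edges = np.linspace(phi.min(), np.nextafter(phi.max(), 2), n_bins + 1)
    V_edges = geometric_edges(V, n_bins)

    def stats(values):
        mean = binned_statistic_2d(phi, V, values, "mean", bins=[phi_edges, V_edges]).statistic
        std = binned_statistic_2d(phi, V, values, "std", bins=[phi_edges, V_edges]).statistic
        return mean, std

    count = binned_statistic_2d(phi, V, None, "count", bins=[phi_edges, V_edges]).statistic
    count = count.astype(int)
    mean_dphi, std_dphi = stats(dphi)
    mean_dV, std_dV = stats(dV)
    with np.errstate(invalid="ignore", divide="ignore"):
        sem_dphi = np.where(count > 1, std_dphi / np.sqrt(np.maximum(count, 1)), np.nan)
        sem_dV = np.where(count > 1, std_dV / np.sqrt(np.maximum(count, 1)), np.nan)
    field = PhiVField(
        phi_edges=phi_edges,
        V_edges=V_edges,
        phi_centres=0.5 * (phi_edges[:-1] + phi_edges[1:]),
        V_centres=np.sqrt(V_edges[:-1] * V_edges[1:]),
        mean_dphi=mean_dphi,
        mean_dV=mean_dV,
        count=count,
        sem_dphi=sem_dphi,
        sem_dV=sem_dV,
        min_count=min_count,
    )
    if np.all(field.masked):
        raise EmptyFieldError(f"no (phi, V) bin reached min_count={min_count}")
    return field


def volume_nullcline_phi(field: PhiVField) -> float:
    """phi at which the mean volume rate crosses zero (count-weighted over
    V rows), i.e. the growth-to-shrinkage transition volume fraction."""
    ok = ~field.masked & np.isfinite(field.mean_dV)
    crossings = []
    weights = []
    n_phi, n_V = field.mean_dV.shape
    for j in range(n_V):
        for i in range(n_phi - 1):
            if not (ok[i, j] and ok[i + 1, j]):
                continue
            r0, r1 = field.mean_dV[i, j], field.mean_dV[i + 1, j]
            if r0 > 0 >= r1:
                f = r0 / (r0 - r1)
                crossings.append(
                    field.phi_centres[i] + f * (field.phi_centres[i + 1] - field.phi_centres[i])
                )
                weights.append(field.count[i, j] + field.count[i + 1, j])
    if not crossings:
        raise NoNullclineError("no volume-rate sign change in the (phi, V) field")
    return float(np.average(crossings, weights=weights))


def intensivity_slopes(field: PhiVField, min_bins: int = 3) -> pd.DataFrame:
    """Per-phi-column slope of mean dphi/dt against log V.

    Intensive dynamics predict slope 0: the composition rate should not
    depend on condensate volume.  Returns columns ``phi_centre, slope,
    slope_se, n_bins``.
    """
    rows = []
    ok = ~field.masked & np.isfinite(field.mean_dphi)
    for i in range(field.mean_dphi.shape[0]):
        cols = np.flatnonzero(ok[i])
        if cols.size < min_bins:
            continue
        x = np.log(field.V_centres[cols])
        y = field.mean_dphi[i, cols]
        wts = field.count[i, cols].astype(float)
        xm = np.average(x, weights=wts)
        ym = np.average(y, weights=wts)
        sxx = np.sum(wts * (x - xm) ** 2)
        slope = np.sum(wts * (x - xm) * (y - ym)) / sxx
        resid = y - ym - slope * (x - xm)
        dof = max(cols.size - 2, 1)
        slope_se = np.sqrt(np.sum(wts * resid**2) / (dof * sxx))
        rows.append(
            {"phi_centre": field.phi_centres[i], "slope": slope, "slope_se": slope_se,
             "n_bins": cols.size}
        )
    if not rows:
        raise EmptyFieldError("no phi column with enough occupied V bins")
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# slices


def conditional_rate_slices(field: FluxField, axis: str, value: float) -> pd.DataFrame:
    """1-D mean-rate profile at constant A (axis='A') or constant W.

    Returns the unmasked bins of the row/column containing ``value`` with
    columns ``centre, mean_dw, sem_dw, mean_da, sem_da, count``.
    """
    if axis not in ("A", "W"):
        raise DomainError("axis must be 'A' or 'W'")
    edges = field.A_edges if axis == "A" else field.W_edges
    if not (edges[0] <= value < edges[-1]):
        raise EmptySliceError(f"{axis}={value} outside the occupied range")
    k = int(np.searchsorted(edges, value, side="right") - 1)
    if axis == "A":
        sel = ~field.masked[k]
        df = pd.DataFrame(
            {
                "centre": field.W_centres[sel],
                "mean_dw": field.mean_dW[k, sel],
                "sem_dw": field.sem_dW[k, sel],
                "mean_da": field.mean_dA[k, sel],
                "sem_da": field.sem_dA[k, sel],
                "count": field.count[k, sel],
            }
        )
    else:
        sel = ~field.masked[:, k]
        df = pd.DataFrame(
            {
                "centre": field.A_centres[sel],
                "mean_dw": field.mean_dW[sel, k],
                "sem_dw": field.sem_dW[sel, k],
                "mean_da": field.mean_dA[sel, k],
                "sem_da": field.sem_dA[sel, k],
                "count": field.count[sel, k],
            }
        )
    if df.empty:
        raise EmptySliceError(f"slice at {axis}={value} intersects no populated bin")
    return df
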