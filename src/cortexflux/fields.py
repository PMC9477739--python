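"""Binned vector-field containers shared by the model and portrait layers."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


def edges_from_centres(centres: np.ndarray) -> np.ndarray:
    """Bin edges bracketing a monotone centre sequence (geometric midpoints
    for positive centres, arithmetic otherwise)."""
    c = np.asarray(centres, dtype=float)
    if c.size == 1:
        return np.array([c[0] * 0.5, c[0] * 1.5]) if c[0] > 0 else np.array([c[0] - 0.5, c[0] + 0.5])
    if np.all(c > 0):
        mids = np.sqrt(c[:-1] * c[1:])
        first = c[0] ** 2 / mids[0]
        last = c[-1] ** 2 / mids[-1]
    else:
        mids = 0.5 * (c[:-1] + c[1:])
        first = 2 * c[0] - mids[0]
        last = 2 * c[-1] - mids[-1]
    return np.concatenate([[first], mids, [last]])


def geometric_edges(values: np.ndarray, n_bins: int, pad: float = 1e-9) -> np.ndarray:
    """Log-spaced bin edges spanning the strictly positive range of ``values``."""
    v = np.asarray(values, dtype=float)
    v = v[v > 0]
    if v.size == 0:
        raise ValueError("no positive values to bin")
    lo, hi = v.min(), v.max()
    if lo == hi:
        lo, hi = lo * (1 - 1e-6) - pad, hi * (1 + 1e-6) + pad
    return np.geomspace(lo, hi * (1 + 1e-12), n_bins + 1)


@dataclass
class FluxField:
    """Binned mean mass-flux vector field over the (A, W) amount plane.

    Arrays are indexed ``[i_A, j_W]``.  Bins with ``count < min_count`` are
    excluded from nullcline extraction and slicing (see :attr:`masked`).
    """

    A_edges: np.ndarray
    W_edges: np.ndarray
    A_centres: np.ndarray
    W_centres: np.ndarray
    mean_dW: np.ndarray
    mean_dA: np.ndarray
    count: np.ndarray
    sem_dW: np.ndarray
    sem_dA: np.ndarray
    min_count: int = 20

    @property
    def masked(self) -> np.ndarray:
        """Boolean array, True where a bin is below the occupancy threshold."""
        return self.count < self.min_count

    @property
    def n_points(self) -> int:
        return int(self.count.sum())

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format table (one row per occupied bin)."""
        ii, jj = np.nonzero(self.count > 0)
        return pd.DataFrame(
            {
                "a_centre": self.A_centres[ii],
                "w_centre": self.W_centres[jj],
                "mean_dw": self.mean_dW[ii, jj],
                "mean_da": self.mean_dA[ii, jj],
                "sem_dw": self.sem_dW[ii, jj],
                "sem_da": self.sem_dA[ii, jj],
                "count": self.count[ii, jj],
            }
        )


@dataclass
class PhiVField:
    """Binned vector field in the (phi, V) composition-volume plane.

    phi bins are linear on [0, 1]; V bins are geometric.  Arrays indexed
    ``[i_phi, j_V]``.
    """

    phi_edges: np.ndarray
    V_edges: np.ndarray
    phi_centres: np.ndarray
    V_centres: np.ndarray
    mean_dphi: np.ndarray
    mean_dV: np.ndarray
    count: np.ndarray
    sem_dphi: np.ndarray
    sem_dV: np.ndarray
    min_count: int = 20

    @property
    def masked(self) -> np.ndarray:
        return self.count < self.min_count

    def to_frame(self) -> pd.DataFrame:
        ii, jj = np.nonzero(self.count > 0)
        return pd.DataFrame(
            {
                "phi_centre": self.phi_centres[ii],
                "v_centre": self.V_centres[jj],
                "mean_dphi": self.mean_dphi[ii, jj],
                "mean_dv": self.mean_dV[ii, jj],
                "sem_dphi": self.sem_dphi[ii, jj],
                "sem_dv": self.sem_dV[ii, jj],
                "count": self.count[ii, jj],
            }
        )
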