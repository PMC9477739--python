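"""Track-table I/O and ensemble summary statistics.

The on-disk track format is a UTF-8 tab-separated file with the exact
header ``condition  oocyte_id  condensate_id  t  w_iu  a_iu  area_um2``,
"." as decimal separator, times in seconds and intensities in IU.  The
``area_um2`` column may be empty.  Within a condensate, rows must be
sorted by time with constant spacing (1% tolerance) and the key
(condition, oocyte_id, condensate_id, t) must be unique.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .errors import DomainError, TrackFormatError
from .synthetic import TRACK_COLUMNS

__all__ = [
    "read_tracks",
    "write_tracks",
    "LifetimeSummary",
    "lifetime_distribution",
    "classify_rnai_strength",
    "wsp1_molecules",
    "MOLECULES_PER_IU",
]

log = logging.getLogger(__name__)

#: WSP-1 calibration: 8 IU correspond to ~100 molecules, i.e. 12.5 per IU.
MOLECULES_PER_IU = 12.5

_KEY = ["condition", "oocyte_id", "condensate_id", "t"]


def _line_of(idx: int) -> int:
    # +2: 1-based lines plus the header row
    return idx + 2


def read_tracks(path) -> pd.DataFrame:
    """Read and validate a track TSV.

    Raises
    ------
    TrackFormatError
        Missing columns, negative or nonfinite intensities, duplicate
        keys, or unsorted / irregular times — each reported with the
        offending file line numbers.
    """
    path = Path(path)
    table = pd.read_csv(path, sep="\t", dtype={"condition": str, "oocyte_id": str,
                                               "condensate_id": str})
    missing = [c for c in TRACK_COLUMNS if c not in table.columns]
    if missing:
        raise TrackFormatError(f"{path}: missing columns {missing}")
    table = table[TRACK_COLUMNS]
    if table.empty:
        log.warning("%s: empty track table", path)
        return table

    for col in ("t", "w_iu", "a_iu"):
        vals = pd.to_numeric(table[col], errors="coerce")
        bad = ~np.isfinite(vals) | (vals < 0)
        if bad.any():
            lines = [_line_of(i) for i in np.flatnonzero(bad.to_numpy())[:5]]
            raise TrackFormatError(
                f"{path}: negative or non-numeric {col} at line(s) {lines}"
            )
        table[col] = vals.astype(float)
    table["area_um2"] = pd.to_numeric(table["area_um2"], errors="coerce")

    dup = table.duplicated(subset=_KEY)
    if dup.any():
        lines = [_line_of(i) for i in np.flatnonzero(dup.to_numpy())[:5]]
        raise TrackFormatError(f"{path}: duplicate (condition, oocyte, condensate, t) "
                               f"keys at line(s) {lines}")

    for (_, _, _cid), g in table.groupby(["condition", "oocyte_id", "condensate_id"],
                                         sort=False):
        t = g["t"].to_numpy()
        if len(t) > 1:
            dts = np.diff(t)
            if np.any(dts <= 0):
                i = g.index[int(np.argmax(dts <= 0)) + 1]
                raise TrackFormatError(
                    f"{path}: unsorted times in condensate {_cid!r} at line {_line_of(i)}"
                )
            dt = np.median(dts)
            if np.any(np.abs(dts - dt) > 0.01 * dt):
                i = g.index[int(np.argmax(np.abs(dts - dt) > 0.01 * dt)) + 1]
                raise TrackFormatError(
                    f"{path}: irregular frame spacing in condensate {_cid!r} "
                    f"at line {_line_of(i)}"
                )
    return table


def write_tracks(table: pd.DataFrame, path) -> None:
    """Write a track table as TSV, preserving 15 significant digits."""
    missing = [c for c in TRACK_COLUMNS if c not in table.columns]
    if missing:
        raise TrackFormatError(f"cannot write table missing columns {missing}")
    table[TRACK_COLUMNS].to_csv(path, sep="\t", index=False, float_format="%.15g")


@dataclass
class LifetimeSummary:
    """Per-condensate lifetime distribution of an ensemble."""

    lifetimes: pd.Series  # indexed by condensate_id, seconds
    mean: float
    median: float
    hist_edges: np.ndarray
    hist_counts: np.ndarray
    n_censored: int = 0
    censored_ids: Optional[list] = None


def lifetime_distribution(
    table: pd.DataFrame,
    bin_width: float = 1.0,
    horizon: Optional[float] = None,
) -> LifetimeSummary:
    """Lifetimes (last minus first frame time) per condensate.

    Parameters
    ----------
    horizon : float, optional
        Observation horizon in seconds; tracks whose lifetime reaches the
        horizon (within one frame) are flagged as censored and reported
        separately, not mixed into the histogram.
    """
    if table.empty:
        raise DomainError("empty track table")
    grouped = table.groupby(["oocyte_id", "condensate_id"], sort=False)["t"]
    life = grouped.max() - grouped.min()
    dt = table.groupby(["oocyte_id", "condensate_id"], sort=False)["t"].apply(
        lambda s: np.median(np.diff(s)) if len(s) > 1 else np.nan
    )
    censored_mask = (
        life >= (horizon - dt) if horizon is not None else pd.Series(False, index=life.index)
    )
    censored_ids = list(life.index[censored_mask])
    obs = life[~censored_mask]
    edges = np.arange(0.0, (obs.max() if len(obs) else bin_width) + bin_width, bin_width)
    counts, edges = np.histogram(obs, bins=edges)
    return LifetimeSummary(
        lifetimes=life,
        mean=float(obs.mean()) if len(obs) else float("nan"),
        median=float(obs.median()) if len(obs) else float("nan"),
        hist_edges=edges,
        hist_counts=counts,
        n_censored=int(censored_mask.sum()),
        censored_ids=censored_ids,
    )


def classify_rnai_strength(
    count: int,
    mild_range: tuple[int, int] = (30, 70),
    moderate_range: tuple[int, int] = (70, 120),
) -> str:
    """Classify ARP2/3 knockdown strength from condensates per oocyte.

    0 condensates -> 'strong'; 30-70 -> 'mild'; 70-120 -> 'moderate'
    (the shared boundary 70 is assigned to moderate); anything else ->
    'control-like'.  Note the counting windows put mild below moderate —
    this ordering is deliberate and matches the reported classification.
    """
    if count < 0 or int(count) != count:
        raise DomainError("count must be a nonnegative integer")
    count = int(count)
    if count == 0:
        return "strong"
    if moderate_range[0] <= count <= moderate_range[1]:
        return "moderate"
    if mild_range[0] <= count < mild_range[1]:
        return "mild"
    return "control-like"


def wsp1_molecules(intensity, molecules_per_iu: float = MOLECULES_PER_IU):
    """Convert WSP-1 intensity (IU) to an approximate molecule count."""
    intensity = np.asarray(intensity, dtype=float)
    if np.any(intensity < 0):
        raise DomainError("intensity must be nonnegative")
    out = intensity * molecules_per_iu
    return float(out) if out.ndim == 0 else out
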