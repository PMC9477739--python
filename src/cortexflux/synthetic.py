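"""Synthetic condensate-track ensembles.

Emulates the observation process behind cortical-condensate track data:
condensates nucleate stochastically in time, start as small WSP-1-rich
seeds, follow the growth laws of :mod:`cortexflux.model` perturbed by
intrinsic rate noise, and are observed at a finite frame interval with
multiplicative measurement noise until their total intensity falls below a
detection threshold.

The generator is the package's stand-in for deposited microscopy-derived
track tables: it produces the same TSV schema plus a ground-truth sidecar
(true coefficients, seeds) so that every downstream stage — volume fit,
flux portrait, kinetic fit — can be tested for recovery.

Noise model
-----------
Each of the four rate terms r_i receives an independent Gaussian kick per
integration substep (chemical-Langevin-like):

    dX = sum_i (+/-) r_i dt  +  sigma_int * sum_i (+/-) r_i sqrt(dt) xi_i

Multiplicative noise preserves positivity (states are clipped at zero) and
approximately preserves the degree-1 homogeneity of the dynamics.  The
deterministic drift is advanced with a classical RK4 substep so the
noise-free limit reproduces the integrated orbit accurately.

Observation noise multiplies each latent amount (and the derived area) by
an independent log-normal factor of log-sd ``obs_noise_sd`` per frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .errors import DomainError, EmptyEnsembleError
from .model import (
    DEFAULT_PARAMS,
    DEFAULT_VOLUME,
    KineticParams,
    VolumeCoefficients,
    critical_kd,
    volume,
)

__all__ = [
    "GeneratorConfig",
    "GroundTruth",
    "simulate_track",
    "generate_ensemble",
    "rnai_preset",
    "count_rescue_events",
    "TRACK_COLUMNS",
]

TRACK_COLUMNS = ["condition", "oocyte_id", "condensate_id", "t", "w_iu", "a_iu", "area_um2"]


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for track generation.

    Defaults encode the reference observation scenario: ~10 s condensate
    lifetimes resolved at 0.5 s frame interval, WSP-1-rich log-normal
    nucleation seeds sitting above the WSP-1 nullcline, 10% intrinsic rate
    noise, 5% measurement noise and a 1 IU detection threshold.
    """

    params: KineticParams = DEFAULT_PARAMS
    vol: VolumeCoefficients = DEFAULT_VOLUME
    nucleation_rate: float = 20.0  # events / s per field of view
    seed_w_median: float = 3.0  # IU, log-normal median of nucleation WSP-1
    seed_w_logsd: float = 0.5
    seed_a: float = 0.2  # IU, nucleation F-actin amount
    frame_interval: float = 0.5  # s
    duration: float = 120.0  # s, per-track observation horizon
    intrinsic_noise_sd: float = 0.1  # per sqrt(s), multiplicative on rate terms
    obs_noise_sd: float = 0.05  # log-sd of per-frame measurement factors
    detection_threshold: float = 1.0  # IU total intensity
    substeps: int = 10  # integration substeps per frame
    rng_seed: int = 0
    condition: str = "control"
    oocyte_id: str = "oo1"

    def __post_init__(self) -> None:
        if self.frame_interval <= 0 or self.duration < self.frame_interval:
            raise DomainError("need frame_interval > 0 and duration >= frame_interval")
        if self.intrinsic_noise_sd < 0 or self.obs_noise_sd < 0:
            raise DomainError("noise scales must be nonnegative")
        if self.detection_threshold < 0:
            raise DomainError("detection_threshold must be nonnegative")
        if self.nucleation_rate <= 0:
            raise DomainError("nucleation_rate must be > 0")
        if self.substeps < 1:
            raise DomainError("substeps must be >= 1")

    def replace(self, **changes) -> "GeneratorConfig":
        return replace(self, **changes)


@dataclass
class GroundTruth:
    """Sidecar record of what generated an ensemble (for recovery tests)."""

    config: GeneratorConfig
    n_nucleated: int
    n_tracks: int
    n_censored: int
    nucleation_times: np.ndarray
    latent: Optional[pd.DataFrame] = field(default=None, repr=False)

    def to_keyvalues(self) -> dict:
        c, p, v = self.config, self.config.params, self.config.vol
        return {
            "k_r": p.k_r, "k_l": p.k_l, "k_b": p.k_b, "k_d": p.k_d,
            "v_A": v.v_A, "v_W": v.v_W,
            "nucleation_rate": c.nucleation_rate,
            "frame_interval": c.frame_interval,
            "duration": c.duration,
            "intrinsic_noise_sd": c.intrinsic_noise_sd,
            "obs_noise_sd": c.obs_noise_sd,
            "detection_threshold": c.detection_threshold,
            "rng_seed": c.rng_seed,
            "condition": c.condition,
            "n_nucleated": self.n_nucleated,
            "n_tracks": self.n_tracks,
            "n_censored": self.n_censored,
        }


def rnai_preset(name: str, base: KineticParams = DEFAULT_PARAMS) -> KineticParams:
    """Kinetic coefficients for the ARP2/3 knockdown conditions.

    The mild and moderate presets rescale the control coefficients by the
    measured fold changes (dominant effect: 1.7x and 2.7x increase of the
    F-actin loss rate k_d, with small decreases of k_r and, for moderate, a
    20% increase of k_l).  The strong preset cannot be measured from
    dynamic condensates; it pins k_d at 1.2x the critical value, just past
    the nullcline switch, yielding unbounded growth by construction.
    """
    name = name.lower()
    if name == "control":
        return base
    if name == "mild":
        return KineticParams(
            k_r=base.k_r * 0.83, k_l=base.k_l * 1.01, k_b=base.k_b, k_d=base.k_d * 1.7
        )
    if name == "moderate":
        return KineticParams(
            k_r=base.k_r * 0.85, k_l=base.k_l * 1.20, k_b=base.k_b, k_d=base.k_d * 2.7
        )
    if name == "strong":
        return base.replace(k_d=1.2 * critical_kd(base, DEFAULT_VOLUME))
    raise DomainError(f"unknown RNAi preset {name!r}")


def _rate_terms(A, W, p: KineticParams, v: VolumeCoefficients):
    """The four nonnegative rate terms (r, l, b, d) evaluated elementwise."""
    V = volume(A, W, v)
    with np.errstate(invalid="ignore", divide="ignore"):
        bil = np.where(V > 0, A * W / V, 0.0)
    return p.k_r * W, p.k_l * bil, p.k_b * bil, p.k_d * A


def _drift(A, W, p, v):
    r, l, b, d = _rate_terms(A, W, p, v)
    return b - d, r - l  # (dA, dW)


def _simulate_latent(cfg: GeneratorConfig, n: int, rng: np.random.Generator):
    """Advance ``n`` tracks in parallel; returns per-frame latent arrays.

    Returns (A_frames, W_frames) of shape (n_frames, n) where frame 0 is the
    nucleation state.  Dead tracks (total below threshold) keep their last
    state frozen; liveness is resolved afterwards from the threshold rule.
    """
    p, v = cfg.params, cfg.vol
    dt = cfg.frame_interval / cfg.substeps
    n_frames = int(round(cfg.duration / cfg.frame_interval)) + 1
    sig = cfg.intrinsic_noise_sd
    sqdt = np.sqrt(dt)

    W = rng.lognormal(mean=np.log(cfg.seed_w_median), sigma=cfg.seed_w_logsd, size=n)
    A = np.full(n, cfg.seed_a, dtype=float)
    A_frames = np.empty((n_frames, n))
    W_frames = np.empty((n_frames, n))
    A_frames[0], W_frames[0] = A, W

    alive = (A + W) >= cfg.detection_threshold
    for f in range(1, n_frames):
        for _ in range(cfg.substeps):
            # RK4 drift step (noise-free limit matches the integrated orbit)
            dA1, dW1 = _drift(A, W, p, v)
            dA2, dW2 = _drift(
                np.clip(A + 0.5 * dt * dA1, 0, None), np.clip(W + 0.5 * dt * dW1, 0, None), p, v
            )
            dA3, dW3 = _drift(
                np.clip(A + 0.5 * dt * dA2, 0, None), np.clip(W + 0.5 * dt * dW2, 0, None), p, v
            )
            dA4, dW4 = _drift(
                np.clip(A + dt * dA3, 0, None), np.clip(W + dt * dW3, 0, None), p, v
            )
            incA = dt / 6.0 * (dA1 + 2 * dA2 + 2 * dA3 + dA4)
            incW = dt / 6.0 * (dW1 + 2 * dW2 + 2 * dW3 + dW4)
            if sig > 0:
                r, l, b, d = _rate_terms(A, W, p, v)
                xi = rng.standard_normal((4, n))
                incW = incW + sig * sqdt * (r * xi[0] - l * xi[1])
                incA = incA + sig * sqdt * (b * xi[2] - d * xi[3])
            A = np.where(alive, np.clip(A + incA, 0.0, None), A)
            W = np.where(alive, np.clip(W + incW, 0.0, None), W)
            if not np.all(np.isfinite(A)) or not np.all(np.isfinite(W)):
                raise DomainError("nonfinite latent state during simulation")
        A_frames[f], W_frames[f] = A, W
        alive = alive & ((A + W) >= cfg.detection_threshold)
        if not alive.any():
            A_frames = A_frames[: f + 1]
            W_frames = W_frames[: f + 1]
            break
    return A_frames, W_frames


def _track_lengths(A_frames, W_frames, threshold):
    """Observed length per track: frames up to (excluding) the first frame
    whose latent total intensity drops below the detection threshold."""
    total = A_frames + W_frames
    below = total < threshold
    n_frames, n = below.shape
    lengths = np.where(below.any(axis=0), below.argmax(axis=0), n_frames)
    return lengths


def generate_ensemble(
    config: GeneratorConfig,
    n_condensates: Optional[int] = None,
    return_latent: bool = False,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate a track table plus its ground-truth sidecar.

    Parameters
    ----------
    n_condensates : int, optional
        Number of nucleation events.  If None, drawn from a Poisson law
        with mean ``nucleation_rate * duration``.
    return_latent : bool
        Attach the noise-free latent amounts (columns ``a_true, w_true``)
        to the ground truth for oracle comparisons.

    Returns
    -------
    (table, truth)
        ``table`` follows the track TSV schema (see :data:`TRACK_COLUMNS`);
        tracks shorter than 3 observed frames are discarded.

    Raises
    ------
    EmptyEnsembleError
        If no track survives the detection rules.
    """
    rng = np.random.default_rng(config.rng_seed)
    if n_condensates is None:
        n = int(rng.poisson(config.nucleation_rate * config.duration))
    else:
        n = int(n_condensates)
    if n <= 0:
        raise EmptyEnsembleError("no condensates nucleated")

    # Poisson-process nucleation times, snapped to the acquisition grid.
    t_nuc = np.sort(rng.uniform(0.0, config.duration, size=n))
    t_nuc = np.round(t_nuc / config.frame_interval) * config.frame_interval

    A_frames, W_frames = _simulate_latent(config, n, rng)
    lengths = _track_lengths(A_frames, W_frames, config.detection_threshold)
    max_frames = A_frames.shape[0]

    rows_tab = []
    rows_lat = []
    n_censored = 0
    kept = 0
    for i in range(n):
        li = int(lengths[i])
        if li < 3:
            continue
        if li == max_frames:
            n_censored += 1
        cid = f"c{i:06d}"
        t = t_nuc[i] + np.arange(li) * config.frame_interval
        a_lat = A_frames[:li, i]
        w_lat = W_frames[:li, i]
        if config.obs_noise_sd > 0:
            fw = rng.lognormal(0.0, config.obs_noise_sd, size=li)
            fa = rng.lognormal(0.0, config.obs_noise_sd, size=li)
            fs = rng.lognormal(0.0, config.obs_noise_sd, size=li)
        else:
            fw = fa = fs = np.ones(li)
        V_lat = volume(a_lat, w_lat, config.vol)
        radius = np.cbrt(3.0 * V_lat / (4.0 * np.pi))
        area = np.pi * radius**2 * fs
        rows_tab.append(
            pd.DataFrame(
                {
                    "condition": config.condition,
                    "oocyte_id": config.oocyte_id,
                    "condensate_id": cid,
                    "t": t,
                    "w_iu": w_lat * fw,
                    "a_iu": a_lat * fa,
                    "area_um2": area,
                }
            )
        )
        if return_latent:
            rows_lat.append(
                pd.DataFrame({"condensate_id": cid, "t": t, "w_true": w_lat, "a_true": a_lat})
            )
        kept += 1

    if kept == 0:
        raise EmptyEnsembleError(
            "all generated tracks fell below the detection threshold or length 3"
        )
    table = pd.concat(rows_tab, ignore_index=True)
    latent = pd.concat(rows_lat, ignore_index=True) if return_latent else None
    truth = GroundTruth(
        config=config,
        n_nucleated=n,
        n_tracks=kept,
        n_censored=n_censored,
        nucleation_times=t_nuc,
        latent=latent,
    )
    return table, truth


def simulate_track(
    config: GeneratorConfig, nucleation_time: float = 0.0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a single track; returns (observed track, latent states).

    Deterministic for a fixed config (all randomness flows from
    ``config.rng_seed``).  The observed track may be empty if the seed
    state never clears the detection threshold for 3 frames.
    """
    rng = np.random.default_rng(config.rng_seed)
    A_frames, W_frames = _simulate_latent(config, 1, rng)
    li = int(_track_lengths(A_frames, W_frames, config.detection_threshold)[0])
    t = nucleation_time + np.arange(li) * config.frame_interval
    a_lat, w_lat = A_frames[:li, 0], W_frames[:li, 0]
    if config.obs_noise_sd > 0:
        fw = rng.lognormal(0.0, config.obs_noise_sd, size=li)
        fa = rng.lognormal(0.0, config.obs_noise_sd, size=li)
        fs = rng.lognormal(0.0, config.obs_noise_sd, size=li)
    else:
        fw = fa = fs = np.ones(li)
    V_lat = volume(a_lat, w_lat, config.vol)
    area = np.pi * np.cbrt(3.0 * V_lat / (4.0 * np.pi)) ** 2 * fs
    track = pd.DataFrame(
        {
            "condition": config.condition,
            "oocyte_id": config.oocyte_id,
            "condensate_id": "c000000",
            "t": t,
            "w_iu": w_lat * fw,
            "a_iu": a_lat * fa,
            "area_um2": area,
        }
    )
    latent = pd.DataFrame({"condensate_id": "c000000", "t": t, "w_true": w_lat, "a_true": a_lat})
    return track, latent


def count_rescue_events(latent: pd.DataFrame, s_threshold: float) -> int:
    """Number of tracks whose stoichiometry crosses ``s_threshold`` upward
    and later falls back below it (stochastic rescue).

    In the amount plane an upward stoichiometry crossing is a downward
    crossing of the WSP-1 nullcline ray; falling back below is a re-crossing
    into the growth regime.
    """
    n_rescues = 0
    for _, g in latent.groupby("condensate_id", sort=False):
        tot = g["a_true"].to_numpy() + g["w_true"].to_numpy()
        with np.errstate(invalid="ignore", divide="ignore"):
            s = np.where(tot > 0, g["a_true"].to_numpy() / tot, np.nan)
        above = s > s_threshold
        if above.any():
            i_up = int(np.argmax(above))
            if np.any(~above[i_up:]):
                n_rescues += 1
    return n_rescues
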