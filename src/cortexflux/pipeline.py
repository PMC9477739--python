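"""End-to-end analysis pipeline: generate/read tracks -> volume fit ->
flux portrait -> kinetic fit -> summary report.

Configuration is a single YAML file with flat sections ``generator``,
``model``, ``fitting`` and ``io``.  All randomness flows from one seed
(config key ``seed``, overridable per call); with a fixed seed the numeric
outputs are bit-identical between runs.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from . import io as cio
from . import portrait as cpt
from .errors import CortexFluxError, NoNullclineError
from .kinetics import fit_kinetics
from .model import (
    DEFAULT_PARAMS,
    DEFAULT_VOLUME,
    KineticParams,
    VolumeCoefficients,
    classify_regime,
    critical_kd,
    fixed_point_phi,
    nullcline_stoichiometries,
)
from .synthetic import GeneratorConfig, generate_ensemble, rnai_preset
from .volume import DEFAULT_WINDOW, concentrations, density_line, fit_volume_coefficients

__all__ = ["load_config", "run_pipeline"]

log = logging.getLogger(__name__)

_GEN_KEYS = {
    "nucleation_rate", "seed_w_median", "seed_w_logsd", "seed_a", "frame_interval",
    "duration", "intrinsic_noise_sd", "obs_noise_sd", "detection_threshold",
    "substeps", "condition", "oocyte_id",
}


def load_config(path) -> dict:
    """Load a pipeline YAML config into a plain dict."""
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise CortexFluxError(f"{path}: config must be a mapping")
    return cfg


def _params_from_config(cfg: dict) -> tuple[KineticParams, VolumeCoefficients]:
    m = cfg.get("model", {}) or {}
    gen = cfg.get("generator", {}) or {}
    vol = VolumeCoefficients(
        v_A=float(m.get("v_A", DEFAULT_VOLUME.v_A)),
        v_W=float(m.get("v_W", DEFAULT_VOLUME.v_W)),
    )
    if "preset" in gen and gen["preset"]:
        params = rnai_preset(str(gen["preset"]))
    else:
        params = KineticParams(
            k_r=float(m.get("k_r", DEFAULT_PARAMS.k_r)),
            k_l=float(m.get("k_l", DEFAULT_PARAMS.k_l)),
            k_b=float(m.get("k_b", DEFAULT_PARAMS.k_b)),
            k_d=float(m.get("k_d", DEFAULT_PARAMS.k_d)),
        )
    return params, vol


def run_pipeline(config, out_dir, seed: Optional[int] = None) -> dict:
    """Run the full pipeline; returns the machine-readable summary dict.

    Parameters
    ----------
    config : dict or path
        Pipeline configuration (see package README for the schema).
    out_dir : path
        Output directory (created if needed) receiving ``tracks.tsv``,
        field and curve TSVs, fit reports and ``summary.json``.
    seed : int, optional
        Overrides the config seed.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0) if seed is None else seed)
    gen_cfg_raw = config.get("generator", {}) or {}
    fit_cfg = config.get("fitting", {}) or {}
    io_cfg = config.get("io", {}) or {}
    params, vol = _params_from_config(config)
    summary: dict = {"seed": seed, "stages": {}}

    # --- stage: tracks (simulate or read) -----------------------------------
    tracks_path = io_cfg.get("tracks")
    if tracks_path:
        log.info("reading tracks from %s", tracks_path)
        table = cio.read_tracks(tracks_path)
        summary["stages"]["tracks"] = {"source": str(tracks_path), "rows": len(table)}
    else:
        gen_kwargs = {k: v for k, v in gen_cfg_raw.items() if k in _GEN_KEYS}
        gcfg = GeneratorConfig(params=params, vol=vol, rng_seed=seed, **gen_kwargs)
        n = gen_cfg_raw.get("n_condensates")
        table, truth = generate_ensemble(gcfg, n_condensates=n)
        log.info("simulated %d tracks (%d rows), seed=%d", truth.n_tracks, len(table), seed)
        cio.write_tracks(table, out / "tracks.tsv")
        with open(out / "ground_truth.txt", "w", encoding="utf-8") as fh:
            for k, v in truth.to_keyvalues().items():
                fh.write(f"{k}\t{v}\n")
        summary["stages"]["tracks"] = {
            "source": "synthetic",
            "rows": len(table),
            "n_tracks": truth.n_tracks,
            "n_censored": truth.n_censored,
        }

    n_tracks = table.groupby(["oocyte_id", "condensate_id"]).ngroups

    # --- stage: volume fit ---------------------------------------------------
    window = tuple(fit_cfg.get("window", DEFAULT_WINDOW))
    vmodel = fit_volume_coefficients(
        table, window=window, n_boot=int(fit_cfg.get("n_boot", 200)), rng_seed=seed + 1
    )
    with open(out / "volume_model.txt", "w", encoding="utf-8") as fh:
        fh.write(f"v_A\t{vmodel.coefficients.v_A:.6e}\n")
        fh.write(f"v_W\t{vmodel.coefficients.v_W:.6e}\n")
        fh.write(f"se_v_A\t{vmodel.se_v_A:.6e}\nse_v_W\t{vmodel.se_v_W:.6e}\n")
        fh.write(f"window\t{window[0]}\t{window[1]}\nn_points\t{vmodel.n_points}\n")
    summary["stages"]["volume"] = {
        "v_A": vmodel.coefficients.v_A,
        "v_W": vmodel.coefficients.v_W,
        "se_v_A": vmodel.se_v_A,
        "se_v_W": vmodel.se_v_W,
        "n_points": vmodel.n_points,
    }

    # --- stage: flux portrait ------------------------------------------------
    points = cpt.derivatives_table(table)
    n_bins = int(fit_cfg.get("n_bins", 24))
    min_count = int(fit_cfg.get("min_count", 20))
    field = cpt.bin_vector_field(points, n_bins=n_bins, min_count=min_count)
    field.to_frame().to_csv(out / "flux_field.tsv", sep="\t", index=False)
    curve = cpt.growth_vs_stoichiometry(points, min_count=min_count)
    curve.to_csv(out / "growth_vs_stoichiometry.tsv", sep="\t", index=False)
    portrait_summary: dict = {"n_points": int(field.n_points)}
    for comp in ("W", "A"):
        try:
            nc = cpt.extract_nullcline(field, comp, rng_seed=seed + 2)
            portrait_summary[f"nullcline_{comp}"] = {
                "stoichiometry": nc.fitted_stoichiometry,
                "se": nc.stoichiometry_se,
                "n_crossings": len(nc.zero_points),
            }
        except NoNullclineError:
            portrait_summary[f"nullcline_{comp}"] = None
            log.warning("no empirical %s nullcline (no sign change)", comp)
    summary["stages"]["portrait"] = portrait_summary

    # --- stage: kinetic fit --------------------------------------------------
    kfit = fit_kinetics(
        points, vmodel, window=window,
        min_amount=float(fit_cfg.get("min_amount", 0.5)),
        n_boot=int(fit_cfg.get("n_boot", 200)), rng_seed=seed + 3,
    )
    with open(out / "kinetics.json", "w", encoding="utf-8") as fh:
        json.dump(kfit.to_dict(), fh, indent=2)
    s_W, s_A = nullcline_stoichiometries(kfit.params, kfit.vol)
    kin_summary = kfit.to_dict()
    kin_summary["s_W"] = s_W
    kin_summary["s_A"] = s_A
    kin_summary["critical_kd"] = (
        critical_kd(kfit.params, kfit.vol)
        if kfit.params.k_l > kfit.params.k_r * kfit.vol.v_A
        else None
    )
    try:
        phi_star, s_star = fixed_point_phi(kfit.params, kfit.vol)
        kin_summary["phi_star"] = phi_star
        kin_summary["s_star"] = s_star
    except CortexFluxError:
        kin_summary["phi_star"] = kin_summary["s_star"] = None
    summary["stages"]["kinetics"] = kin_summary
    summary["regime"] = classify_regime(kfit.params, kfit.vol)

    # --- stage: ensemble summary --------------------------------------------
    horizon = gen_cfg_raw.get("duration")
    lt = cio.lifetime_distribution(table, horizon=horizon)
    conc = concentrations(table, vmodel, volume_source="relation")
    pair = cpt.preferred_concentration_pair(
        conc, n_boot=int(fit_cfg.get("pair_boot", 20)), rng_seed=seed + 4
    )
    dline = density_line(vmodel)
    summary["stages"]["ensemble"] = {
        "n_tracks": int(n_tracks),
        "mean_lifetime_s": lt.mean,
        "median_lifetime_s": lt.median,
        "n_censored": lt.n_censored,
        "preferred_c_A": pair.c_A,
        "preferred_c_W": pair.c_W,
        "preferred_pair_on_density_line_residual": float(
            dline.residual(pair.c_A, pair.c_W)
        ),
    }

    with open(out / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    log.info("pipeline complete; regime=%s", summary["regime"])
    return summary
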