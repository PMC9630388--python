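"""End-to-end seeded workflows: simulate -> correlate -> fit, and
simulate -> track analysis -> report.

A workflow is driven by a plain mapping (usually loaded from YAML).  Every
numeric output is deterministic given (config, seed): a single master seed
is forked per stage through a stable hash of the stage name, so adding a
stage does not perturb the draws of earlier stages.  Outputs are written
under a run directory with a manifest recording the config hash and every
file produced.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import fcs, io, spt
from .comovement import detect_comoving, distance_density, frame_matched_distances
from .correlate import average_curves, multitau_correlate
from .simulate import (
    SimulationConfig,
    molecules_for_occupancy,
    simulate_brownian_tracks,
    simulate_cotracked_pairs,
    simulate_photon_traces,
)

__all__ = ["stage_seed", "run_fcs_workflow", "run_spt_workflow"]

log = logging.getLogger("difftrans")

_FCS_KEYS = {"seed", "focal_waist", "kappa", "mean_occupancy", "bin_width",
             "duration", "n_repeats", "box_size", "brightness", "background",
             "conditions"}
_SPT_KEYS = {"seed", "frame_interval", "n_frames", "localization_sigma",
             "box_size", "conditions", "comovement"}


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31, independent of stage order."""
    h = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def _check_keys(config: dict, allowed: set, where: str) -> None:
    unknown = set(config) - allowed
    if unknown:
        raise ValueError(f"unknown {where} config keys: {sorted(unknown)}")


def run_fcs_workflow(config: dict, outdir) -> dict:
    """Simulate photon traces per condition, correlate, fit, derive D and C.

    ``config['conditions']`` maps a condition name to a species list
    ``[(D, fraction), ...]``; per condition ``n_repeats`` traces are
    simulated, multi-tau correlated, averaged, and fit with one- and
    two-component models.  The report includes the model comparison, the
    fitted diffusion times converted to coefficients, and the apparent
    concentration from the amplitude.
    """
    _check_keys(config, _FCS_KEYS, "FCS workflow")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    w = float(config.get("focal_waist", 0.26))
    kappa = float(config.get("kappa", 5.0))
    volume = fcs.FocalVolume(w, kappa)
    bin_width = float(config.get("bin_width", 1e-5))
    duration = float(config.get("duration", 10.0))
    n_repeats = int(config.get("n_repeats", 5))
    occupancy = float(config.get("mean_occupancy", 2.0))
    box = tuple(config.get("box_size", (1.6, 1.6, 4.0)))
    chash = io.config_hash(config)
    manifest = {"config_hash": chash, "seed": seed, "files": [], "stages": {}}

    rows = []
    for name, species in config["conditions"].items():
        cfg = SimulationConfig(
            n_particles=1,
            box_size=box,
            diffusion_coefficients=[tuple(s) for s in species],
            bin_width=bin_width,
            n_frames=int(round(duration / bin_width)),
            focal_waist=w,
            axial_ratio=kappa,
            brightness=float(config.get("brightness", 5e4)),
            background=float(config.get("background", 1e3)),
            seed=stage_seed(seed, f"simulate:{name}"),
        )
        cfg.n_particles = molecules_for_occupancy(occupancy, cfg)
        log.info("condition %s: %d molecules, %d bins", name, cfg.n_particles, cfg.n_frames)
        rng = np.random.default_rng(cfg.seed)
        curves = []
        for rep in range(n_repeats):
            trace = simulate_photon_traces(cfg, rng=rng)
            curves.append(multitau_correlate(trace))
        avg = average_curves(curves)
        io.write_curve(avg, outdir / f"curve_{name}.csv")
        manifest["files"].append(f"curve_{name}.csv")
        report = fcs.compare_models(avg, kappa=kappa, fix={"T": 0.0})
        best = report["two"] if report["two_component_preferred"] else report["one"]
        row = {
            "condition": name,
            "two_component_preferred": report["two_component_preferred"],
            "residual_excess": report["residual_excess"],
            "G0": best.G0,
            "tau1_s": best.params["tau1"],
            "D1_um2_s": fcs.diffusion_time_to_coefficient(best.params["tau1"], volume),
            "concentration_nM": fcs.estimate_concentration(best.G0, best.params["T"], volume) * 1e9,
        }
        if report["two_component_preferred"]:
            row["tau2_s"] = best.params["tau2"]
            row["D2_um2_s"] = fcs.diffusion_time_to_coefficient(best.params["tau2"], volume)
            row["A_fast"] = best.params["A"]
        rows.append(row)
    table = pd.DataFrame(rows)
    table.to_csv(outdir / "fcs_fits.csv", index=False)
    manifest["files"].append("fcs_fits.csv")
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return {"table": table, "manifest": manifest}


def run_spt_workflow(config: dict, outdir) -> dict:
    """Simulate trajectory fields per condition and run the SPT analyses.

    Per condition: a two-population Brownian field, one-lag displacement
    extraction and a CDF fit; with >= 2 conditions a global shared-D fit is
    added.  An optional ``comovement`` block simulates a two-color tethered
    field and runs the dwell-based co-movement calling plus the
    annulus-normalized distance density.
    """
    _check_keys(config, _SPT_KEYS, "SPT workflow")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    chash = io.config_hash(config)
    manifest = {"config_hash": chash, "seed": seed, "files": []}

    conditions = config.get("conditions", {})
    displacement_sets = []
    names = []
    rows = []
    for name, block in conditions.items():
        cfg = SimulationConfig(
            n_particles=int(block.get("n_particles", 1000)),
            box_size=tuple(config.get("box_size", (10.0, 10.0))),
            diffusion_coefficients=[tuple(s) for s in block["species"]],
            frame_interval=float(config.get("frame_interval", 0.005)),
            n_frames=int(config.get("n_frames", 20)),
            localization_sigma=float(config.get("localization_sigma", 0.0)),
            seed=stage_seed(seed, f"tracks:{name}"),
        )
        tracks = simulate_brownian_tracks(cfg)
        tracks.to_csv(outdir / f"tracks_{name}.csv")
        manifest["files"].append(f"tracks_{name}.csv")
        disp = spt.extract_displacements(tracks, lag=1)
        displacement_sets.append(disp)
        names.append(name)
        fit = spt.fit_cdf_two_component(disp)
        rows.append(
            {
                "condition": name,
                "fit": "single",
                "a_slow": fit.a_slow,
                "d_slow_um2_s": fit.d_slow,
                "d_fast_um2_s": fit.d_fast,
            }
        )
    if len(displacement_sets) >= 2:
        for name, fit in zip(names, spt.fit_cdf_global(displacement_sets)):
            rows.append(
                {
                    "condition": name,
                    "fit": "global",
                    "a_slow": fit.a_slow,
                    "d_slow_um2_s": fit.d_slow,
                    "d_fast_um2_s": fit.d_fast,
                }
            )
    table = pd.DataFrame(rows)
    if len(table):
        table.to_csv(outdir / "cdf_fits.csv", index=False)
        manifest["files"].append("cdf_fits.csv")

    result = {"table": table, "manifest": manifest}
    co = config.get("comovement")
    if co:
        cfg = SimulationConfig(
            n_particles=int(co.get("n_particles", 100)),
            box_size=tuple(config.get("box_size", (10.0, 10.0))),
            diffusion_coefficients=[tuple(s) for s in co.get("species", [(0.5, 1.0)])],
            frame_interval=float(config.get("frame_interval", 0.01)),
            n_frames=int(config.get("n_frames", 50)),
            localization_sigma=float(config.get("localization_sigma", 0.0)),
            bound_fraction_two_color=float(co.get("bound_fraction", 0.3)),
            tether_sigma=float(co.get("tether_sigma", 0.05)),
            seed=stage_seed(seed, "comovement"),
        )
        a, b = simulate_cotracked_pairs(cfg)
        res = detect_comoving(
            a,
            b,
            max_distance=float(co.get("max_distance", 0.32)),
            min_dwell=float(co.get("min_dwell", 0.010)),
        )
        res.pairs.to_csv(outdir / "comoving_pairs.csv", index=False)
        manifest["files"].append("comoving_pairs.csv")
        dens = distance_density(
            frame_matched_distances(a, b),
            bin_width=0.05,
            r_max=2.0,
            baseline_beyond=2 * res.max_distance,
        )
        pd.DataFrame(
            {
                "r_um": dens.bin_centers,
                "count": dens.counts,
                "density": dens.density,
            }
        ).to_csv(outdir / "distance_density.csv", index=False)
        manifest["files"].append("distance_density.csv")
        result["comovement"] = res
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return result
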