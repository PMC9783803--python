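"""Structured run configuration and the reproducible analysis pipeline.

One YAML file describes a full figure-style analysis: where the trajectory
comes from (a file or a synthetic simulation), which D-H...A bridges to
follow, and which analysis blocks to run.  ``run_pipeline`` executes the
requested stages in dependency order, writes CSV/JSON outputs and a
manifest (config hash, seed, package version, output checksums) so that a
deterministic run is reproducible bit-for-bit from its config.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .descriptors import (
    audit_sapt,
    classify_interaction,
    espinosa_energy,
    read_descriptor_tables,
)
from .errors import ConfigurationError, HBridgeError
from .hbond import (
    BridgeDefinition,
    detect_transfers,
    distance_series,
    locate_minima_barrier,
    pmf_from_series,
    pooled_bead_series,
    proton_histogram2d,
)
from .model_systems import (
    ModelPotential,
    PathSettings,
    SimulationSettings,
    simulate_md,
    simulate_pimd,
)
from .spectra import band_maximum, compute_vacf, power_spectrum
from .trajectory_io import (
    CellParameters,
    centroid,
    read_cpmd_trajectory,
    read_xyz,
    trim_equilibration,
    write_bead_trajectory,
    write_xyz,
)

logger = logging.getLogger(__name__)

__all__ = ["load_config", "validate_config", "run_pipeline"]

_ANALYSES = ("spectra", "vacf", "histogram", "pmf", "transfers", "qtaim", "sapt")


def load_config(path) -> dict:
    """Load and validate a YAML run configuration."""
    path = Path(path)
    with open(path) as fh:
        config = yaml.safe_load(fh)
    if not isinstance(config, dict):
        raise ConfigurationError(f"{path.name}: config must be a mapping")
    config.setdefault("_config_dir", str(path.parent))
    validate_config(config)
    return config


def _resolve(config: dict, p) -> Path:
    p = Path(p)
    if not p.is_absolute() and "_config_dir" in config:
        p = Path(config["_config_dir"]) / p
    return p


def _bridge_map(config: dict) -> dict[str, BridgeDefinition]:
    bridges = {}
    for spec in config.get("bridges", []):
        b = BridgeDefinition(
            donor_index=int(spec["donor"]),
            hydrogen_index=int(spec["hydrogen"]),
            acceptor_index=int(spec["acceptor"]),
            label=str(spec.get("label", f"bridge{len(bridges)}")),
        )
        bridges[b.label] = b
    return bridges


def validate_config(config: dict) -> None:
    """Validate every block before any computation starts."""
    has_input = "input" in config
    has_sim = "simulate" in config
    analyses = config.get("analyses", {})
    if not isinstance(analyses, dict) or not analyses:
        raise ConfigurationError("config requires a non-empty 'analyses' block")
    unknown = set(analyses) - set(_ANALYSES)
    if unknown:
        raise ConfigurationError(
            f"unknown analysis block(s) {sorted(unknown)}; "
            f"expected among {_ANALYSES}")

    needs_traj = [a for a in analyses
                  if a in ("spectra", "vacf", "histogram", "pmf", "transfers")]
    if needs_traj and not (has_input or has_sim):
        raise ConfigurationError(
            f"analyses {needs_traj} need an 'input' or 'simulate' block")
    if has_input and has_sim:
        raise ConfigurationError("give either 'input' or 'simulate', not both")

    if has_input:
        blk = config["input"]
        if "path" not in blk:
            raise ConfigurationError("input block needs a 'path'")
        p = _resolve(config, blk["path"])
        if not p.exists():
            raise ConfigurationError(f"input trajectory {p} does not exist")
        if blk.get("format", "xyz") not in ("xyz", "cpmd"):
            raise ConfigurationError("input format must be 'xyz' or 'cpmd'")
    if has_sim:
        blk = config["simulate"]
        ModelPotential(**blk.get("model", {}))
        SimulationSettings(**blk.get("settings", {}))
        if "pimd" in blk:
            PathSettings(**blk["pimd"])

    bridges = _bridge_map(config)
    for name in ("histogram", "pmf", "transfers"):
        if name in analyses:
            blk = analyses[name] or {}
            label = blk.get("bridge")
            if label is None and len(bridges) == 1:
                continue
            if label is None or label not in bridges:
                raise ConfigurationError(
                    f"analysis '{name}' needs a 'bridge' label from "
                    f"{sorted(bridges) or '(none defined)'}")
    if "pmf" in analyses:
        blk = analyses["pmf"] or {}
        if blk.get("coordinate", "r_HA") not in ("r_HA", "r_DH", "r_DA", "delta"):
            raise ConfigurationError("pmf coordinate must be a bridge coordinate")
    for name in ("qtaim", "sapt"):
        if name in analyses:
            blk = analyses[name] or {}
            if "path" not in blk:
                raise ConfigurationError(f"analysis '{name}' needs a table 'path'")
            p = _resolve(config, blk["path"])
            if not p.exists():
                raise ConfigurationError(f"{name} table {p} does not exist")
    if "cell" in config:
        CellParameters(**config["cell"])


def _config_hash(config: dict) -> str:
    public = {k: v for k, v in config.items() if not k.startswith("_")}
    blob = json.dumps(public, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_csv(df: pd.DataFrame, path: Path) -> Path:
    df.to_csv(path, index=False, float_format="%.10g")
    return path


def run_pipeline(config: dict, outdir=None, seed: Optional[int] = None) -> dict:
    """Execute the configured stages; returns a result bundle.

    The bundle maps stage names to their in-memory results and lists the
    files written; ``manifest.json`` in the output directory records the
    config hash, seed, package version and per-file checksums.  On a stage
    failure the partial outputs are kept next to a ``FAILED`` marker and
    the error names the failing stage.
    """
    validate_config(config)
    outdir = Path(outdir if outdir is not None else config.get("outdir", "."))
    outdir.mkdir(parents=True, exist_ok=True)
    if seed is not None:
        config = dict(config)
        config["seed"] = seed
    run_seed = int(config.get("seed", 0))
    analyses = config.get("analyses", {})
    bridges = _bridge_map(config)
    cell = CellParameters(**config["cell"]) if "cell" in config else None
    results: dict = {}
    outputs: list[Path] = []
    stage = "setup"
    t0 = time.perf_counter()

    def _stage_done(name):
        logger.info("stage %-10s done at %.2f s", name, time.perf_counter() - t0)

    try:
        traj = None
        btraj = None
        geom_source = None  # series provider for geometry analyses
        if "simulate" in config:
            stage = "simulate"
            blk = config["simulate"]
            model = ModelPotential(**blk.get("model", {}))
            settings_kw = dict(blk.get("settings", {}))
            settings_kw.setdefault("seed", run_seed)
            settings = SimulationSettings(**settings_kw)
            if "pimd" in blk:
                btraj = simulate_pimd(model, settings, PathSettings(**blk["pimd"]))
                traj = centroid(btraj)
                outputs += write_bead_trajectory(btraj, outdir / "beads")
            else:
                traj = simulate_md(model, settings)
                write_xyz(traj, outdir / "trajectory.xyz")
                outputs.append(outdir / "trajectory.xyz")
            if not bridges:
                bridges = {"bridge": BridgeDefinition(0, 1, 2, "bridge")}
            _stage_done(stage)
        elif "input" in config:
            stage = "read"
            blk = config["input"]
            path = _resolve(config, blk["path"])
            if blk.get("format", "xyz") == "cpmd":
                traj = read_cpmd_trajectory(
                    path, dt_au=float(blk.get("dt_au", 3.0)),
                    stride=int(blk.get("stride", 1)),
                    atom_labels=blk.get("labels"))
            else:
                traj = read_xyz(path)
            _stage_done(stage)

        if traj is not None and config.get("trim", 0):
            stage = "trim"
            traj = trim_equilibration(traj, int(config["trim"]))
            _stage_done(stage)

        def bridge_for(blk):
            label = (blk or {}).get("bridge")
            if label is None:
                return next(iter(bridges.values()))
            return bridges[label]

        def series_for(blk):
            b = bridge_for(blk)
            if btraj is not None:
                return pooled_bead_series(btraj, b, cell)
            return distance_series(traj, b, cell)

        if "vacf" in analyses:
            stage = "vacf"
            blk = analyses["vacf"] or {}
            vacf = compute_vacf(traj, blk.get("selection"),
                                max_lag=blk.get("max_lag"))
            results["vacf"] = vacf
            outputs.append(_write_csv(
                pd.DataFrame({"lag_fs": vacf.lags, "vacf": vacf.values}),
                outdir / "vacf.csv"))
            _stage_done(stage)

        if "spectra" in analyses:
            stage = "spectra"
            blk = analyses["spectra"] or {}
            spec = power_spectrum(
                traj, blk.get("selection"),
                window=blk.get("window", "hann"),
                n_segments=int(blk.get("n_segments", 1)))
            results["spectrum"] = spec
            if "band" in blk:
                lo, hi = blk["band"]
                results["band_maximum"] = band_maximum(spec, lo, hi)
            outputs.append(_write_csv(
                pd.DataFrame({"wavenumber_cm1": spec.wavenumbers,
                              "intensity": spec.intensity}),
                outdir / "spectrum.csv"))
            _stage_done(stage)

        if "histogram" in analyses or "pmf" in analyses or "transfers" in analyses:
            stage = "hbgeom"
            geom_source = series_for(
                analyses.get("histogram") or analyses.get("pmf")
                or analyses.get("transfers"))
            results["geometry"] = geom_source
            outputs.append(_write_csv(
                pd.DataFrame({"time_fs": geom_source.times,
                              "r_DH": geom_source.r_DH,
                              "r_HA": geom_source.r_HA,
                              "r_DA": geom_source.r_DA}),
                outdir / "hbgeom.csv"))
            _stage_done(stage)

        if "histogram" in analyses:
            stage = "histogram"
            blk = analyses["histogram"] or {}
            hist = proton_histogram2d(series_for(blk),
                                      bin_width=float(blk.get("bin_width", 0.02)))
            results["histogram"] = hist
            xc = 0.5 * (hist.x_edges[:-1] + hist.x_edges[1:])
            yc = 0.5 * (hist.y_edges[:-1] + hist.y_edges[1:])
            xx, yy = np.meshgrid(xc, yc, indexing="ij")
            outputs.append(_write_csv(
                pd.DataFrame({"r_DH": xx.ravel(), "r_HA": yy.ravel(),
                              "density": hist.density.ravel()}),
                outdir / "histogram2d.csv"))
            _stage_done(stage)

        if "pmf" in analyses:
            stage = "pmf"
            blk = analyses["pmf"] or {}
            pmf = pmf_from_series(
                series_for(blk),
                coordinate=blk.get("coordinate", "r_HA"),
                n_bins=int(blk.get("n_bins", 60)),
                temperature=float(blk.get("temperature", 297.0)),
                jacobian_r2=bool(blk.get("jacobian_r2", False)))
            minima, barrier = locate_minima_barrier(
                pmf, smooth_window=int(blk.get("smooth_window", 0)))
            results["pmf"] = pmf
            results["pmf_minima"] = minima
            results["pmf_barrier"] = barrier
            outputs.append(_write_csv(
                pd.DataFrame({"bin_center": pmf.bin_centers,
                              "free_energy_kcal": pmf.free_energy,
                              "occupied": pmf.mask}),
                outdir / "pmf.csv"))
            _stage_done(stage)

        if "transfers" in analyses:
            stage = "transfers"
            blk = analyses["transfers"] or {}
            ev = detect_transfers(series_for(blk),
                                  hysteresis=float(blk.get("hysteresis", 0.1)))
            results["transfers"] = ev
            path = outdir / "transfers.json"
            path.write_text(json.dumps({
                "n_events": ev.n_events,
                "event_times_fs": ev.event_times.tolist(),
                "residence_donor": ev.residence_donor,
                "residence_acceptor": ev.residence_acceptor,
                "hysteresis": ev.hysteresis,
            }, indent=2))
            outputs.append(path)
            _stage_done(stage)

        if "qtaim" in analyses:
            stage = "qtaim"
            blk = analyses["qtaim"]
            cps = read_descriptor_tables(_resolve(config, blk["path"]))
            rows = []
            for cp in cps:
                energy = espinosa_energy(cp)
                rows.append({
                    "system": cp.system, "label": cp.label,
                    "rho": cp.rho, "laplacian": cp.laplacian,
                    "V_BCP": cp.V_BCP, "H_BCP": cp.H_BCP,
                    "espinosa_kcal": energy,
                    "class": classify_interaction(cp),
                })
            results["qtaim"] = rows
            outputs.append(_write_csv(pd.DataFrame(rows), outdir / "qtaim.csv"))
            _stage_done(stage)

        if "sapt" in analyses:
            stage = "sapt"
            blk = analyses["sapt"]
            comps = read_descriptor_tables(_resolve(config, blk["path"]))
            reports = [audit_sapt(c, tol=float(blk.get("tol", 0.01)))
                       for c in comps]
            results["sapt"] = reports
            path = outdir / "sapt_audit.json"
            path.write_text(json.dumps(reports, indent=2))
            outputs.append(path)
            _stage_done(stage)

    except Exception as exc:
        (outdir / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n")
        raise HBridgeError(f"stage '{stage}' failed: {exc}") from exc

    manifest = {
        "package_version": __version__,
        "config_hash": _config_hash(config),
        "seed": run_seed,
        "outputs": {str(p.name): _sha256(p) for p in outputs},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    results["manifest"] = manifest
    results["outputs"] = [str(p) for p in outputs]
    return results
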