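"""Pipeline orchestration: configs, manifests, and the end-to-end recipe.

A run is described by a single YAML config naming the stages to execute
(``synth``/``simulate`` -> ``stress`` -> ``structure`` -> ``percolate`` ->
``collapse`` -> ``report``) with one mapping of options per stage.  Every
output lands under one run directory together with a manifest recording the
config hash, the per-stage seeds and the produced files, which is what makes
deterministic stages bitwise reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .dynamics import run_simulation
from .fields import ScalarField2D
from .fss import fss_collapse, spanning_probability_crossing
from .params import ModelParams
from .percolation import percolation_curves
from .stress import isotropic_stress
from .structure import classify_state, pair_correlation
from .synthetic import (dipole_chain_field, gaussian_correlated_field,
                        iid_uniform_field)

__all__ = ["RunManifest", "run_pipeline", "validate_config", "load_config"]

STAGES = ("synth", "simulate", "stress", "structure", "percolate", "collapse",
          "report")


@dataclass
class RunManifest:
    config_hash: str
    seeds: dict = field(default_factory=dict)
    stages: list = field(default_factory=list)
    outputs: dict = field(default_factory=dict)
    version: str = __version__
    started: str = ""
    finished: str = ""

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)


def load_config(config) -> dict:
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            return yaml.safe_load(fh) or {}
    return dict(config)


def _config_hash(cfg: dict) -> str:
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def validate_config(config) -> list[str]:
    """Check a pipeline config; returns a list of violations (empty = ok).

    Never mutates any file.  Checks model-parameter invariants when a
    simulate stage is configured, subsystem sizes against field extents, and
    p-grid bounds.
    """
    try:
        cfg = load_config(config)
    except OSError as exc:
        return [f"unreadable config: {exc}"]
    v: list[str] = []
    stages = cfg.get("stages", [])
    unknown = [s for s in stages if s not in STAGES]
    if unknown:
        v.append(f"unknown stages: {unknown}")
    if "simulate" in stages or "simulate" in cfg:
        try:
            p = ModelParams.from_dict(cfg.get("simulate", {}).get("params", {}))
            v.extend(p.validate())
        except (ValueError, TypeError) as exc:
            v.append(f"simulate.params: {exc}")
    perc = cfg.get("percolate", {})
    p_min = perc.get("p_min", 0.0)
    p_max = perc.get("p_max", 1.0)
    if not (0.0 <= p_min < p_max <= 1.0):
        v.append(f"percolate p-grid bounds invalid: [{p_min}, {p_max}]")
    ells = perc.get("ells")
    shape = cfg.get("synth", {}).get("shape")
    if ells and shape:
        bad = [e for e in ells if e + 1 > min(shape)]
        if bad:
            v.append(
                f"subsystem lengths {bad} exceed the field extent {min(shape)} "
                f"(need ell + 1 <= field side)")
    return v


def _stage_synth(cfg, out, rng):
    opts = cfg.get("synth", {})
    kind = opts.get("kind", "iid")
    shape = tuple(opts.get("shape", (65, 65)))
    n = int(opts.get("n_fields", 1))
    fields = []
    for _ in range(n):
        if kind == "iid":
            f = iid_uniform_field(shape, rng=rng)
        elif kind == "correlated":
            f = gaussian_correlated_field(shape, opts.get("spectral_exponent", 1.0),
                                          rng=rng)
        elif kind == "dipole":
            f = dipole_chain_field(shape, opts.get("n_chains", 8),
                                   opts.get("amplitude", 1.0), rng=rng)
        else:
            raise ValueError(f"unknown synth kind {kind!r}")
        fields.append(f)
    d = out / "fields"
    d.mkdir(exist_ok=True)
    for k, f in enumerate(fields):
        f.save(d / f"field_{k:04d}.npz")
    return fields


def run_pipeline(config, out_dir: str | Path, seed: int | None = None) -> RunManifest:
    """Execute the configured stages in order under ``out_dir``.

    Returns the manifest; a report (JSON + text) is written when the report
    stage is requested.  Raises with an actionable message naming the
    producing stage when an input is missing.
    """
    cfg = load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if seed is None:
        seed = int(cfg.get("seed", 0))
    manifest = RunManifest(config_hash=_config_hash(cfg),
                           started=time.strftime("%Y-%m-%dT%H:%M:%S"))
    manifest.seeds["root"] = seed
    root = np.random.default_rng(seed)

    stages = cfg.get("stages", [])
    fields: list[ScalarField2D] = []
    traj = None
    curves = None
    fits = {}
    report: dict = {"seed": seed, "config_hash": manifest.config_hash}

    for stage in stages:
        stage_seed = int(root.integers(2**31))
        manifest.seeds[stage] = stage_seed
        rng = np.random.default_rng(stage_seed)

        if stage == "synth":
            fields = _stage_synth(cfg, out, rng)
            manifest.outputs["synth"] = str(out / "fields")

        elif stage == "simulate":
            p = ModelParams.from_dict(cfg.get("simulate", {}).get("params", {}))
            p.seed = stage_seed if cfg.get("simulate", {}).get("reseed", True) else p.seed
            traj = run_simulation(p, stress_every=cfg.get("simulate", {}).get("stress_every", 20))
            np.savez_compressed(out / "trajectory.npz",
                                centroids=traj.centroids, thetas=traj.thetas,
                                tractions=traj.tractions, volumes=traj.volumes)
            manifest.outputs["simulate"] = str(out / "trajectory.npz")

        elif stage == "stress":
            if traj is None or traj.stress_mean is None:
                raise RuntimeError(
                    "stress stage needs a simulated trajectory with recorded "
                    "stress frames; run the simulate stage first")
            opts = cfg.get("stress", {})
            iso = isotropic_stress(traj.stress_mean, normalize=True,
                                   convention=opts.get("normalize", "compression"))
            iso.save(out / "iso_stress.npz")
            iso.to_csv(out / "iso_stress.csv")
            fields = [iso]
            manifest.outputs["stress"] = str(out / "iso_stress.npz")

        elif stage == "structure":
            if traj is None:
                raise RuntimeError("structure stage needs a trajectory; "
                                   "run the simulate stage first")
            pos = traj.time_averaged_positions()
            gr = pair_correlation(pos, traj.box, traj.params.R0)
            rep = classify_state(gr)
            import pandas as pd
            pd.DataFrame({"r_over_R0": gr.r_centers, "g": gr.g,
                          "n_pairs": gr.n_pairs}).to_csv(out / "gr.csv", index=False)
            report["structure"] = {"label": rep.label, "dominant": rep.dominant,
                                   "peaks": rep.peaks[:5]}
            manifest.outputs["structure"] = str(out / "gr.csv")

        elif stage == "percolate":
            if not fields:
                raise RuntimeError("percolate stage needs fields; run the "
                                   "synth or stress stage first")
            opts = cfg.get("percolate", {})
            p_grid = np.arange(opts.get("p_min", 0.30),
                               opts.get("p_max", 0.90) + 1e-12,
                               opts.get("p_step", 0.005))
            curves = percolation_curves(fields, p_grid, ells=opts.get("ells"),
                                        connectivity=opts.get("connectivity", "face4"))
            curves.save_csv(out / "curves.csv")
            manifest.outputs["percolate"] = str(out / "curves.csv")

        elif stage == "collapse":
            if curves is None:
                raise RuntimeError("collapse stage needs percolation curves; "
                                   "run the percolate stage first")
            opts = cfg.get("collapse", {})
            try:
                pc0, _ = spanning_probability_crossing(curves)
            except Exception:
                pc0 = None
            for obs in opts.get("observables", ["P", "S"]):
                fits[obs] = fss_collapse(curves, observable=obs, pc0=pc0,
                                         n_bootstrap=int(opts.get("n_bootstrap", 50)),
                                         seed=stage_seed)
            with open(out / "fits.json", "w") as fh:
                json.dump({k: f.summary() for k, f in fits.items()}, fh, indent=2)
            manifest.outputs["collapse"] = str(out / "fits.json")

        elif stage == "report":
            table = {}
            if "P" in fits:
                table["pc"] = [fits["P"].pc, fits["P"].pc_err]
                table["nu"] = [fits["P"].nu, fits["P"].nu_err]
                table["beta"] = [fits["P"].exponent, fits["P"].exponent_err]
            if "S" in fits:
                table["gamma"] = [fits["S"].exponent, fits["S"].exponent_err]
            report["exponents"] = table
            with open(out / "report.json", "w") as fh:
                json.dump(report, fh, indent=2, default=str)
            lines = ["stress-percolation pipeline report", "=" * 36]
            for k, (val, err) in table.items():
                lines.append(f"{k:>6s} = {val:.4f} +- {err:.4f}")
            if "structure" in report:
                lines.append(f"g(r) classification: {report['structure']['label']}")
            (out / "report.txt").write_text("\n".join(lines) + "\n")
            manifest.outputs["report"] = str(out / "report.json")

        manifest.stages.append(stage)

    manifest.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
    manifest.save(out / "manifest.json")
    return manifest
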