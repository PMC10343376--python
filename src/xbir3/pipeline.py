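"""End-to-end workflows behind one config: ensemble → MM-PBSA → benchmark,
and complex/ensemble → pharmacophore → screen → metrics.

A single YAML config drives everything; every artifact written embeds the
seed and a hash of the config so reruns are reproducible and
self-describing.  The ``simulate`` step materializes a fully synthetic
input bundle (structures, parameter tables, multi-model-PDB ensembles,
screening library) under the output directory so the downstream stages
exercise exactly the same file interfaces they would with real inputs.
"""
from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as xio
from .bench import AffinityRecord, correlate
from .entropy import interaction_entropy
from .mmpbsa import estimate_binding, frame_energy_series, per_residue_decomposition
from .pb import PBGridSpec
from .pharmacophore import (read_model, roc_auc, screen_library,
                            screening_metrics, write_model)
from .synthetic import (EnsembleRecipe, LibraryRecipe, make_ensemble,
                        make_reference_pharmacophore, make_screening_library,
                        make_toy_complex, read_library, write_library)

log = logging.getLogger(__name__)


def _with_defaults(cfg: dict) -> dict:
    cfg.setdefault("seed", 0)
    cfg.setdefault("temperature", 303.15)
    cfg.setdefault("output_dir", "xbir3_run")
    return cfg


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    return _with_defaults(cfg)


def config_hash(cfg: dict) -> str:
    """Hash of the scientific configuration (output location excluded)."""
    hashed = {k: v for k, v in cfg.items() if k != "output_dir"}
    return hashlib.sha256(yaml.safe_dump(hashed, sort_keys=True).encode()).hexdigest()[:12]


def _write_csv(df: pd.DataFrame, path: Path, meta: dict) -> None:
    with open(path, "w") as fh:
        for k, v in meta.items():
            fh.write(f"# {k}={v}\n")
        df.to_csv(fh, lineterminator="\n")


def simulate_bundle(cfg: dict) -> dict:
    """Write a synthetic input bundle and return the stage configs for it."""
    sim = cfg.get("simulate", {})
    seed = int(cfg["seed"])
    out = Path(cfg["output_dir"]) / "inputs"
    out.mkdir(parents=True, exist_ok=True)
    n_complexes = int(sim.get("n_complexes", 2))
    complexes = []
    rng = np.random.default_rng(seed)
    for k in range(n_complexes):
        cid = f"SYN{k + 1}"
        sub_seed = int(rng.integers(2 ** 31 - 1))
        top = make_toy_complex(int(sim.get("n_residues", 4)), seed=sub_seed)
        recipe = EnsembleRecipe(top, sigma=float(sim.get("sigma", 0.15)),
                                n_frames=int(sim.get("n_frames", 4)), seed=sub_seed,
                                temperature=float(cfg["temperature"]))
        traj = make_ensemble(recipe)
        xio.write_structure(top, out / f"{cid}.pdb")
        xio.write_parameters(top, out / f"{cid}.params.csv")
        xio.write_trajectory(traj, out / f"{cid}.traj.pdb", out / f"{cid}.traj.yaml")
        complexes.append({"id": cid, "structure": str(out / f"{cid}.pdb"),
                          "parameters": str(out / f"{cid}.params.csv"),
                          "trajectory": str(out / f"{cid}.traj.pdb"),
                          "trajectory_config": str(out / f"{cid}.traj.yaml"),
                          "ic50_nM": float(10 ** rng.uniform(1, 4))})
    lib_cfg = sim.get("library", {})
    model = make_reference_pharmacophore(seed)
    write_model(model, out / "reference_model.txt")
    entries = make_screening_library(LibraryRecipe(
        n_active=int(lib_cfg.get("n_active", 25)),
        n_inactive=int(lib_cfg.get("n_inactive", 100)),
        reference=model,
        corrupt_active_fraction=float(lib_cfg.get("corrupt_active_fraction", 0.2)),
        seed=seed))
    write_library(entries, out / "library")
    return {"complexes": complexes, "model": str(out / "reference_model.txt"),
            "library": str(out / "library")}


def run_mmpbsa_workflow(cfg: dict) -> dict:
    """Per-complex MM-PBSA estimates (± entropy options) plus benchmarking."""
    mcfg = cfg.get("mmpbsa", {})
    complexes = mcfg.get("complexes", [])
    if not complexes:
        raise ValueError("mmpbsa workflow: no complexes configured")
    out = Path(cfg["output_dir"]) / "mmpbsa"
    out.mkdir(parents=True, exist_ok=True)
    meta = {"seed": cfg["seed"], "config_hash": config_hash(cfg),
            "sd_convention": "population"}
    pb_spec = PBGridSpec(spacing=float(mcfg.get("pb_spacing", 0.8)),
                         padding=float(mcfg.get("pb_padding", 8.0)),
                         temperature=float(cfg["temperature"]))
    stride = int(mcfg.get("stride", 1))
    entropy_opts = [str(e).lower() for e in mcfg.get("entropy", ["none"])]
    estimates: dict[str, dict[str, object]] = {}
    records, predictions = [], {}
    for entry in complexes:
        cid = entry["id"]
        log.info("mmpbsa: complex %s", cid)
        top = xio.read_structure(entry["structure"])
        xio.read_parameters(entry["parameters"], top)
        traj = xio.read_trajectory(entry["trajectory"], top,
                                   config_path=entry.get("trajectory_config"))
        series = frame_energy_series(traj, stride=stride, pb_spec=pb_spec,
                                     n_sphere_points=int(mcfg.get("sphere_points", 240)))
        per_frame = pd.DataFrame(
            [{"frame": f.frame_index + 1, "elec": f.e_inte.elec, "vdw": f.e_inte.vdw,
              "g_polar": f.g_polar, "g_nonpolar": f.g_nonpolar, "total": f.total}
             for f in series]).set_index("frame")
        _write_csv(per_frame, out / f"{cid}_frames.csv", {**meta, "complex": cid})
        estimates[cid] = {}
        for opt in entropy_opts:
            ent = None
            if opt == "ie":
                e_series = [f.e_inte.e_inte for f in series]
                if len(e_series) >= 2:
                    ent = interaction_entropy(e_series, float(cfg["temperature"]))
            est = estimate_binding(series, ent)
            estimates[cid][opt] = est
        decomp = per_residue_decomposition(traj, stride=stride, pb_spec=pb_spec,
                                           n_sphere_points=int(mcfg.get("sphere_points", 240)))
        _write_csv(decomp.table, out / f"{cid}_decomposition.csv",
                   {**meta, "complex": cid, **decomp.metadata})
        if entry.get("ic50_nM"):
            records.append(AffinityRecord.from_value(cid, float(entry["ic50_nM"]), "nM",
                                                     float(cfg["temperature"])))
            predictions[cid] = estimates[cid][entropy_opts[0]].mean_dg
    summary = pd.DataFrame(
        [{"complex": cid, "entropy": opt, "dG": est.mean_dg, "sd": est.sd,
          "elec": est.mean_elec, "vdw": est.mean_vdw, "polar": est.mean_polar,
          "nonpolar": est.mean_nonpolar, "entropy_term": est.entropy_term,
          "n_frames": est.n_frames}
         for cid, opts in estimates.items() for opt, est in opts.items()]
    ).set_index(["complex", "entropy"])
    _write_csv(summary, out / "summary.csv", meta)
    report = {"estimates": estimates, "summary": summary, "correlation": None}
    if len(records) >= 3:
        corr = correlate(records, predictions)
        report["correlation"] = corr
        pd.DataFrame(corr.pairs, columns=["complex", "dg_exp", "dg_pred"]).to_csv(
            out / "correlation.csv", index=False)
    return report


def run_pharm_workflow(cfg: dict) -> dict:
    """Screen the configured library with the configured model(s)."""
    pcfg = cfg.get("pharm", {})
    if "model" not in pcfg or "library" not in pcfg:
        raise ValueError("pharm workflow needs 'model' and 'library' paths")
    out = Path(cfg["output_dir"]) / "pharm"
    out.mkdir(parents=True, exist_ok=True)
    meta = {"seed": cfg["seed"], "config_hash": config_hash(cfg),
            "omission_mode": "exhaustive single-feature enumeration",
            "early_auc_convention": "normalized partial AUC on the ranked top fraction"}
    model = read_model(pcfg["model"])
    library = read_library(pcfg["library"])
    rows = []
    outcomes = {}
    for omit in [int(o) for o in pcfg.get("omissions", [0, 1])]:
        outcome = screen_library(model, library, max_omitted=omit)
        outcomes[omit] = outcome
        m = screening_metrics(outcome)
        ids = sorted(outcome.scores)
        scores = [outcome.scores[i] for i in ids]
        labels = [outcome.labels[i] for i in ids]
        rows.append({"model": model.name, "omissions": omit,
                     "sensitivity_pct": 100 * m["sensitivity"],
                     "specificity_pct": 100 * m["specificity"],
                     "EF": m["EF"],
                     "AUC_1.5pct": roc_auc(scores, labels, fraction=0.015),
                     "AUC_100pct": roc_auc(scores, labels, fraction=1.0),
                     "TP": m["TP"], "TN": m["TN"]})
    table = pd.DataFrame(rows).set_index(["model", "omissions"])
    _write_csv(table, out / "screening_metrics.csv", meta)
    return {"model": model, "outcomes": outcomes, "metrics": table}


def run_all(cfg: dict) -> dict:
    """Simulate (if configured), then both workflows; returns all reports."""
    cfg = _with_defaults(cfg)
    out = Path(cfg["output_dir"])
    out.mkdir(parents=True, exist_ok=True)
    if "simulate" in cfg:
        bundle = simulate_bundle(cfg)
        cfg.setdefault("mmpbsa", {}).setdefault("complexes", bundle["complexes"])
        cfg.setdefault("pharm", {})
        cfg["pharm"].setdefault("model", bundle["model"])
        cfg["pharm"].setdefault("library", bundle["library"])
    with open(out / "run_metadata.json", "w") as fh:
        json.dump({"seed": cfg["seed"], "config_hash": config_hash(cfg)}, fh, indent=2)
    reports = {}
    if cfg.get("mmpbsa", {}).get("complexes"):
        reports["mmpbsa"] = run_mmpbsa_workflow(cfg)
    if cfg.get("pharm", {}).get("model"):
        reports["pharm"] = run_pharm_workflow(cfg)
    return reports
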