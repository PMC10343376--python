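"""Structure, ensemble and parameter-table I/O.

Structures travel as PDB (ATOM/HETATM records); conformational ensembles as
multi-model PDB (MODEL/ENDMDL blocks) with a small YAML sidecar declaring
frame spacing, temperature and optional per-residue segment overrides.
Per-atom force-field/PB parameters come from a flat comma- or tab-separated
table (one row per atom) — parameter *generation* (CGENFF et al.) is out of
scope here, the table is consumed as given.
"""
from __future__ import annotations

import logging
import math
from pathlib import Path

import numpy as np
import yaml

from .topology import (STANDARD_AMINO_ACIDS, AtomRecord, ComplexTopology,
                       Trajectory)

log = logging.getLogger(__name__)

PARAM_COLUMNS = ("atom_index", "charge", "lj_epsilon", "lj_rmin_half", "pb_radius", "mass")


class PDBParseError(ValueError):
    pass


def _parse_atom_line(line: str, lineno: int, segment_overrides: dict[int, str]) -> AtomRecord:
    if len(line.rstrip("\n")) < 54:
        raise PDBParseError(f"line {lineno}: truncated ATOM/HETATM record "
                            f"(needs at least 54 columns): {line.rstrip()!r}")
    try:
        serial = int(line[6:11])
        name = line[12:16].strip()
        resname = line[17:20].strip()
        resid = int(line[22:26])
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except ValueError as exc:
        raise PDBParseError(f"line {lineno}: malformed ATOM/HETATM record: {exc}") from exc
    element = line[76:78].strip() if len(line) >= 78 else ""
    is_h = (element == "H") if element else name.startswith("H") or (
        len(name) > 1 and name[0].isdigit() and name[1] == "H")
    if resid in segment_overrides:
        segment = segment_overrides[resid]
    else:
        segment = "receptor" if resname in STANDARD_AMINO_ACIDS else "ligand"
    return AtomRecord(atom_index=serial, atom_name=name, residue_name=resname,
                      residue_id=resid, segment=segment, coords=np.array([x, y, z]),
                      is_hydrogen=is_h)


def read_structure(path, segment_overrides: dict[int, str] | None = None,
                   strip_heterogens: bool = True) -> ComplexTopology:
    """Read ATOM/HETATM records from a PDB file (first model only).

    Residue ids are taken verbatim from the columns.  Standard amino-acid
    residue names are assigned to the receptor segment, everything else to
    the ligand, unless ``segment_overrides`` maps a residue id elsewhere.
    Crystallographic waters and ions (HOH/WAT/TIP3 and bare ion names) are
    stripped by default and the count logged.
    """
    path = Path(path)
    overrides = segment_overrides or {}
    solvent_names = {"HOH", "WAT", "TIP3", "TIP", "SOL", "CLA", "SOD", "POT", "K", "NA", "CL"}
    atoms: list[AtomRecord] = []
    n_stripped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec == "ENDMDL":
                break
            if rec not in ("ATOM", "HETATM"):
                continue
            resname = line[17:20].strip()
            if strip_heterogens and resname in solvent_names:
                n_stripped += 1
                continue
            atoms.append(_parse_atom_line(line, lineno, overrides))
    if not atoms:
        raise PDBParseError(f"{path}: no ATOM/HETATM records found")
    if n_stripped:
        log.info("%s: stripped %d solvent/ion records", path, n_stripped)
    return ComplexTopology(atoms, provenance=path.stem)


def write_structure(top: ComplexTopology, path, frame: np.ndarray | None = None) -> None:
    """Write a topology (optionally with replacement coordinates) as PDB."""
    coords = top.coords() if frame is None else np.asarray(frame, dtype=float)
    with open(path, "w") as fh:
        _write_model(fh, top, coords)
        fh.write("END\n")


def _write_model(fh, top: ComplexTopology, coords: np.ndarray) -> None:
    for a, xyz in zip(top.atoms, coords):
        record = "ATOM  " if a.segment == "receptor" else "HETATM"
        name = a.atom_name if len(a.atom_name) == 4 else f" {a.atom_name:<3s}"
        fh.write(f"{record}{a.atom_index:5d} {name:<4s}{a.residue_name:>4s} "
                 f"{a.residue_id:4d}    {xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
                 f"  1.00  0.00\n")


def write_trajectory(traj: Trajectory, path, config_path=None) -> None:
    """Write an ensemble as multi-model PDB plus an optional YAML sidecar."""
    with open(path, "w") as fh:
        for k, frame in enumerate(traj.frames, start=1):
            fh.write(f"MODEL     {k:4d}\n")
            _write_model(fh, traj.topology, frame)
            fh.write("ENDMDL\n")
        fh.write("END\n")
    if config_path is not None:
        with open(config_path, "w") as fh:
            yaml.safe_dump({"frame_interval": traj.frame_interval,
                            "temperature": traj.temperature}, fh)


def read_trajectory(path, top: ComplexTopology, frame_interval: float = 20.0,
                    temperature: float = 303.15, config_path=None) -> Trajectory:
    """Read a multi-model PDB as a Trajectory over an existing topology.

    Every MODEL block must carry exactly the topology's atom count; frames
    are ordered by MODEL number.  Frame spacing and temperature come from
    the YAML sidecar when given, else from the keyword defaults.
    """
    if config_path is not None:
        with open(config_path) as fh:
            cfg = yaml.safe_load(fh) or {}
        frame_interval = float(cfg.get("frame_interval", frame_interval))
        temperature = float(cfg.get("temperature", temperature))
    models: list[tuple[int, np.ndarray]] = []
    current: list[list[float]] | None = None
    current_no = 0
    saw_model = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec == "MODEL":
                saw_model = True
                current = []
                current_no = int(line.split()[1])
            elif rec in ("ATOM", "HETATM"):
                if current is None:
                    current = []          # single-model file without MODEL card
                    current_no = 1
                if len(line.rstrip("\n")) < 54:
                    raise PDBParseError(f"line {lineno}: truncated record in model {current_no}")
                current.append([float(line[30:38]), float(line[38:46]), float(line[46:54])])
            elif rec == "ENDMDL":
                _close_model(models, current, current_no, top)
                current = None
    if current:                            # file without trailing ENDMDL
        _close_model(models, current, current_no if saw_model else 1, top)
    if not models:
        raise PDBParseError(f"{path}: no coordinate models found")
    models.sort(key=lambda kv: kv[0])
    return Trajectory(top, [m for _, m in models],
                      frame_interval=frame_interval, temperature=temperature)


def _close_model(models, current, model_no, top) -> None:
    if current is None:
        return
    arr = np.asarray(current, dtype=float)
    if arr.shape[0] != top.n_atoms:
        raise PDBParseError(f"model {model_no}: {arr.shape[0]} atoms, "
                            f"topology has {top.n_atoms}")
    models.append((model_no, arr))


def write_parameters(top: ComplexTopology, path, sep: str = ",") -> None:
    """Write the per-atom parameter table (header + one row per atom)."""
    with open(path, "w") as fh:
        fh.write(sep.join(PARAM_COLUMNS) + "\n")
        for a in top.atoms:
            fh.write(sep.join([str(a.atom_index)] + [
                f"{v:.6g}" for v in (a.charge, a.lj_epsilon, a.lj_rmin_half,
                                     a.pb_radius, a.mass)]) + "\n")


def read_parameters(path, top: ComplexTopology) -> ComplexTopology:
    """Assign charges/LJ/PB radii/masses from a flat table, in place.

    The table is comma- or tab-separated with a header naming at least the
    columns ``atom_index, charge, lj_epsilon, lj_rmin_half, pb_radius,
    mass``.  Every atom of the topology must appear; net segment charges
    are logged after assignment.
    """
    path = Path(path)
    with open(path) as fh:
        header_line = fh.readline()
        sep = "\t" if "\t" in header_line else ","
        header = [h.strip() for h in header_line.rstrip("\n").split(sep)]
        missing_cols = [c for c in PARAM_COLUMNS if c not in header]
        if missing_cols:
            raise ValueError(f"{path}: parameter table missing columns {missing_cols}")
        col = {name: header.index(name) for name in PARAM_COLUMNS}
        rows: dict[int, dict[str, float]] = {}
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = [p.strip() for p in line.rstrip("\n").split(sep)]
            try:
                idx = int(parts[col["atom_index"]])
                vals = {name: float(parts[col[name]]) for name in PARAM_COLUMNS[1:]}
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path} line {lineno}: malformed row: {exc}") from exc
            for name, v in vals.items():
                if not math.isfinite(v):
                    raise ValueError(f"{path} line {lineno}: non-finite {name}")
            rows[idx] = vals
    missing = [a.atom_index for a in top.atoms if a.atom_index not in rows]
    if missing:
        raise ValueError(f"parameter table missing atom indices: {missing}")
    for a in top.atoms:
        vals = rows[a.atom_index]
        a.charge = vals["charge"]
        a.lj_epsilon = vals["lj_epsilon"]
        a.lj_rmin_half = vals["lj_rmin_half"]
        a.pb_radius = vals["pb_radius"]
        a.mass = vals["mass"]
    log.info("net receptor charge %+.3f e, net ligand charge %+.3f e",
             top.net_charge("receptor") if top.segment_positions("receptor") else 0.0,
             top.net_charge("ligand") if top.segment_positions("ligand") else 0.0)
    return top
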