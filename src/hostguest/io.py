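"""Readers and writers: CSV tables, multi-model PDB, XYZ + JSON topology, reports.

Conventions: coordinates in angstrom throughout; frame indices 0-based in
memory and 1-based in reports; glucose units 1-based.  The PDB dialect honors
only MODEL/ENDMDL/ATOM/HETATM/CRYST1 records — anything else is skipped.
Malformed input raises a typed error carrying the offending line or frame;
readers never silently coerce.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import InvalidInputError, ParseError, SchemaError, TopologyError
from .geometry import Topology, Trajectory
from .phase_thermo import SolubilityDiagram, StabilityConstant

# Residue names recognized when inferring atom roles from a PDB file.
HOST_RESNAMES = {"CDX", "CD", "DMB", "BCD"}
GUEST_RESNAMES = {"LIG", "GST", "AUR"}
SOLVENT_RESNAMES = {"HOH", "WAT", "SOL"}


# ---------------------------------------------------------------------------
# tabular input

def _read_csv_checked(path, required: Sequence[str], numeric: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path}: empty file") from None
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {', '.join(missing)}")
    if len(df) == 0:
        raise SchemaError(f"{path}: no data rows")
    for col in numeric:
        try:
            df[col] = pd.to_numeric(df[col], errors="raise")
        except (ValueError, TypeError):
            raise SchemaError(f"{path}: non-numeric cell in column {col!r}") from None
    return df


def read_solubility_csv(path) -> list[SolubilityDiagram]:
    """Read phase-solubility diagrams, one per (label, temperature) group.

    Columns: ``host_conc``, ``guest_conc``, ``temperature`` (K), optional
    ``unit`` (``M`` or ``mM``, default M) and ``label``.
    """
    df = _read_csv_checked(
        path,
        required=["host_conc", "guest_conc", "temperature"],
        numeric=["host_conc", "guest_conc", "temperature"],
    )
    if "label" not in df.columns:
        df["label"] = ""
    if "unit" in df.columns:
        factors = {"M": 1.0, "mM": 1e-3}
        bad = set(df["unit"]) - set(factors)
        if bad:
            raise SchemaError(f"{path}: unknown concentration unit(s) {sorted(bad)}")
        scale = df["unit"].map(factors)
        df["host_conc"] = df["host_conc"] * scale
        df["guest_conc"] = df["guest_conc"] * scale
    diagrams = []
    for (label, temp), grp in df.groupby(["label", "temperature"], sort=True):
        grp = grp.sort_values("host_conc")
        diagrams.append(
            SolubilityDiagram(
                host_conc=grp["host_conc"].to_numpy(),
                guest_conc=grp["guest_conc"].to_numpy(),
                temperature=float(temp),
                label=str(label),
            )
        )
    return diagrams


def read_kc_csv(path) -> dict[str, list[StabilityConstant]]:
    """Read stability constants grouped by label.

    Columns: ``temperature_K``, ``kc_per_M``, ``label``.
    """
    df = _read_csv_checked(
        path,
        required=["temperature_K", "kc_per_M", "label"],
        numeric=["temperature_K", "kc_per_M"],
    )
    out: dict[str, list[StabilityConstant]] = {}
    for label, grp in df.groupby("label", sort=True):
        grp = grp.sort_values("temperature_K")
        out[str(label)] = [
            StabilityConstant(kc=float(r.kc_per_M), temperature=float(r.temperature_K),
                              label=str(label))
            for r in grp.itertuples()
        ]
    return out


def read_energy_csv(path) -> list[pd.DataFrame]:
    """Read per-snapshot MM/PBSA components, split by replicate.

    Columns: ``replicate``, ``frame``, ``e_vdw``, ``e_ele``, ``g_solv_polar``,
    ``g_solv_nonpolar``.
    """
    cols = ["e_vdw", "e_ele", "g_solv_polar", "g_solv_nonpolar"]
    df = _read_csv_checked(path, required=["replicate"] + cols, numeric=cols)
    return [grp.reset_index(drop=True) for _, grp in df.groupby("replicate", sort=True)]


def read_entropy_csv(path) -> list[float]:
    """Read per-replicate T*dS values; columns ``replicate``, ``t_delta_s``."""
    df = _read_csv_checked(path, required=["replicate", "t_delta_s"], numeric=["t_delta_s"])
    return [float(v) for v in df.sort_values("replicate")["t_delta_s"]]


# ---------------------------------------------------------------------------
# topology helpers

def build_topology(
    names: Sequence[str],
    elements: Sequence[str],
    roles: Sequence[str],
    unit_index: Sequence[int],
    n_units: int | None = None,
) -> Topology:
    """Assemble a Topology, deriving the O2/O3/O4 site map from atom names.

    Host atoms named O2/O3/O4 with a 1-based unit index populate the site map;
    each unit must contribute exactly one of each site.
    """
    unit_index = np.asarray(unit_index, dtype=int)
    host_units = unit_index[np.array(roles) == "host"]
    if n_units is None:
        n_units = int(host_units.max()) if host_units.size else 0
    site_map: dict[str, list[int]] = {}
    if n_units > 0:
        for site in ("O2", "O3", "O4"):
            idx = [None] * n_units
            for i, (nm, role, u) in enumerate(zip(names, roles, unit_index)):
                if role == "host" and nm.upper() == site and 1 <= u <= n_units:
                    if idx[u - 1] is not None:
                        raise TopologyError(f"unit {u} has more than one {site} site")
                    idx[u - 1] = i
            missing = [u + 1 for u, v in enumerate(idx) if v is None]
            if missing:
                raise TopologyError(f"missing {site} site for unit(s) {missing}")
            site_map[site] = np.array(idx, dtype=int)
    return Topology(
        names=tuple(names),
        elements=tuple(elements),
        roles=tuple(roles),
        unit_index=unit_index,
        n_units=n_units,
        site_map=site_map,
    )


def _role_from_resname(resname: str, line_no: int) -> str:
    rn = resname.upper()
    if rn in HOST_RESNAMES:
        return "host"
    if rn in GUEST_RESNAMES:
        return "guest"
    if rn in SOLVENT_RESNAMES:
        return "solvent"
    raise ParseError(f"cannot infer atom role from residue name {resname!r}", line=line_no)


# ---------------------------------------------------------------------------
# multi-model PDB

def read_pdb_trajectory(path) -> tuple[Trajectory, Topology]:
    """Read a multi-model PDB into a trajectory plus role/site topology.

    Honors MODEL/ENDMDL/ATOM/HETATM/CRYST1; atom roles come from residue
    names (host: CDX..., guest: LIG..., solvent: HOH/WAT/SOL) and glucose
    units from the host residue sequence numbers.
    """
    path = Path(path)
    frames: list[list[tuple[float, float, float]]] = []
    meta: list[tuple[str, str, str, int]] = []  # name, element, role, unit
    box = None
    current: list[tuple[float, float, float]] | None = None
    current_meta: list | None = None
    model_no = 0
    saw_model = False
    line_no = 0

    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec == "CRYST1":
                try:
                    box = np.array([float(line[6:15]), float(line[15:24]), float(line[24:33])])
                except ValueError:
                    raise ParseError("unreadable CRYST1 record", line=line_no) from None
            elif rec == "MODEL":
                if current is not None:
                    raise ParseError("MODEL opened before previous ENDMDL", line=line_no)
                current = []
                current_meta = []
                model_no += 1
                saw_model = True
            elif rec == "ENDMDL":
                if current is None:
                    raise ParseError("ENDMDL without matching MODEL", line=line_no)
                if frames and len(current) != len(frames[0]):
                    raise ParseError(
                        f"atom count {len(current)} differs from first frame "
                        f"({len(frames[0])})",
                        frame=model_no,
                    )
                if not frames:
                    meta = current_meta
                frames.append(current)
                current = None
                current_meta = None
            elif rec in ("ATOM", "HETATM"):
                if current is None:  # single-model file without MODEL records
                    current = []
                    current_meta = []
                    model_no = 1
                try:
                    xyz = (float(line[30:38]), float(line[38:46]), float(line[46:54]))
                except ValueError:
                    raise ParseError("unreadable coordinates", line=line_no) from None
                name = line[12:16].strip()
                resname = line[17:20].strip()
                try:
                    resid = int(line[22:26])
                except ValueError:
                    raise ParseError("unreadable residue number", line=line_no) from None
                element = line[76:78].strip() or name[:1]
                role = _role_from_resname(resname, line_no)
                current.append(xyz)
                current_meta.append((name, element, role, resid if role == "host" else 0))

    if current is not None:
        if saw_model or not current:
            raise ParseError("file truncated inside a MODEL block", line=line_no)
        meta = current_meta
        frames.append(current)
    if not frames:
        raise ParseError("no coordinate frames found", line=0)

    names, elements, roles, units = (list(t) for t in zip(*meta))
    topo = build_topology(names, elements, roles, units)
    traj = Trajectory(coordinates=np.array(frames, dtype=float), box=box)
    return traj, topo


def write_pdb_trajectory(traj: Trajectory, topo: Topology, path) -> None:
    """Write a trajectory as multi-model PDB (fixed-width, 3-decimal coordinates)."""
    resname = {"host": "CDX", "guest": "LIG", "solvent": "HOH"}
    with open(path, "w") as fh:
        if traj.box is not None:
            fh.write(
                f"CRYST1{traj.box[0]:9.3f}{traj.box[1]:9.3f}{traj.box[2]:9.3f}"
                f"{90.0:7.2f}{90.0:7.2f}{90.0:7.2f} P 1           1\n"
            )
        for f in range(traj.n_frames):
            fh.write(f"MODEL     {f + 1:4d}\n")
            serial = 0
            resid_counter = topo.n_units
            nonhost_resid = {}
            for i in range(topo.n_atoms):
                serial += 1
                role = topo.roles[i]
                if role == "host":
                    resid = int(topo.unit_index[i])
                else:
                    key = (role, i)
                    resid_counter += 1
                    resid = nonhost_resid.setdefault(key, resid_counter)
                x, y, z = traj.coordinates[f, i]
                fh.write(
                    f"ATOM  {serial % 100000:5d} {topo.names[i][:4]:<4s}"
                    f"{resname[role]:>4s} A{resid % 10000:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
                    f"{topo.elements[i][:2]:>2s}\n"
                )
            fh.write("ENDMDL\n")
        fh.write("END\n")


# ---------------------------------------------------------------------------
# XYZ + JSON topology sidecar

def read_xyz_trajectory(path, topology_path) -> tuple[Trajectory, Topology]:
    """Read a multi-frame XYZ file with a JSON topology sidecar.

    The sidecar carries ``names``, ``elements``, ``roles``, ``unit_index``
    (1-based, 0 outside the ring), optional ``n_units`` and ``box``.
    """
    with open(topology_path) as fh:
        try:
            side = json.load(fh)
        except json.JSONDecodeError as exc:
            raise SchemaError(f"{topology_path}: invalid JSON ({exc})") from None
    for key in ("names", "elements", "roles", "unit_index"):
        if key not in side:
            raise SchemaError(f"{topology_path}: missing key {key!r}")
    topo = build_topology(
        side["names"], side["elements"], side["roles"], side["unit_index"],
        n_units=side.get("n_units"),
    )
    box = np.asarray(side["box"], dtype=float) if side.get("box") else None

    frames = []
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    frame_no = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        frame_no += 1
        try:
            n_atoms = int(lines[i].strip())
        except ValueError:
            raise ParseError("expected atom count", line=i + 1) from None
        if i + 2 + n_atoms > len(lines):
            raise ParseError("file truncated inside a frame", line=len(lines), frame=frame_no)
        coords = np.empty((n_atoms, 3))
        for j in range(n_atoms):
            parts = lines[i + 2 + j].split()
            if len(parts) < 4:
                raise ParseError("malformed atom line", line=i + 3 + j, frame=frame_no)
            try:
                coords[j] = [float(parts[1]), float(parts[2]), float(parts[3])]
            except ValueError:
                raise ParseError("non-numeric coordinate", line=i + 3 + j,
                                 frame=frame_no) from None
        if n_atoms != topo.n_atoms:
            raise ParseError(
                f"frame has {n_atoms} atoms but topology has {topo.n_atoms}",
                frame=frame_no,
            )
        frames.append(coords)
        i += 2 + n_atoms
    if not frames:
        raise ParseError("no frames in XYZ file", line=0)
    return Trajectory(coordinates=np.array(frames), box=box), topo


def write_xyz_trajectory(traj: Trajectory, topo: Topology, path, topology_path=None) -> None:
    """Write a multi-frame XYZ file and (optionally) its JSON topology sidecar."""
    with open(path, "w") as fh:
        for f in range(traj.n_frames):
            fh.write(f"{topo.n_atoms}\n")
            fh.write(f"frame {f + 1}\n")
            for i in range(topo.n_atoms):
                x, y, z = traj.coordinates[f, i]
                fh.write(f"{topo.elements[i]:<2s} {x:14.6f} {y:14.6f} {z:14.6f}\n")
    if topology_path is not None:
        side = {
            "names": list(topo.names),
            "elements": list(topo.elements),
            "roles": list(topo.roles),
            "unit_index": [int(u) for u in topo.unit_index],
            "n_units": topo.n_units,
            "box": list(map(float, traj.box)) if traj.box is not None else None,
        }
        with open(topology_path, "w") as fh:
            json.dump(side, fh, indent=1)


def read_trajectory(path, topology_path=None, fmt: str | None = None):
    """Dispatch on format: multi-model PDB, or XYZ plus JSON topology sidecar."""
    path = Path(path)
    if fmt is None:
        fmt = "xyz" if path.suffix.lower() == ".xyz" else "pdb"
    if fmt == "pdb":
        return read_pdb_trajectory(path)
    if fmt == "xyz":
        if topology_path is None:
            raise InvalidInputError("XYZ trajectories need a JSON topology sidecar")
        return read_xyz_trajectory(path, topology_path)
    raise InvalidInputError(f"unknown trajectory format {fmt!r}")


# ---------------------------------------------------------------------------
# reports and config

def _jsonify(value):
    if isinstance(value, np.ma.MaskedArray):
        return [
            [None if m else float(v) for v, m in zip(row, mrow)]
            for row, mrow in zip(value.data, np.ma.getmaskarray(value))
        ]
    if isinstance(value, np.ndarray):
        return [_jsonify(v) for v in value.tolist()]
    if isinstance(value, (np.floating, float)):
        v = float(value)
        return None if math.isnan(v) else v
    if isinstance(value, (np.integer,)):
        return int(value)
    if isinstance(value, Mapping):
        return {k: _jsonify(v) for k, v in value.items()}
    if isinstance(value, (list, tuple)):
        return [_jsonify(v) for v in value]
    if isinstance(value, pd.DataFrame):
        return _jsonify(value.to_dict(orient="records"))
    return value


def write_report(results, path, fmt: str = "tsv", float_fmt: str = "%.6g") -> None:
    """Write results as TSV (DataFrame) or JSON (any mapping; NaN/masked -> null).

    Column order is preserved; float formatting applies to display only.
    """
    path = Path(path)
    if fmt == "tsv":
        df = results if isinstance(results, pd.DataFrame) else pd.DataFrame(results)
        df.to_csv(path, sep="\t", index=False, float_format=float_fmt, na_rep="-")
    elif fmt == "json":
        with open(path, "w") as fh:
            json.dump(_jsonify(results), fh, indent=1, sort_keys=False)
            fh.write("\n")
    else:
        raise InvalidInputError(f"unknown report format {fmt!r}")


def load_config(path, allowed_keys: Sequence[str] | None = None) -> dict:
    """Load a JSON or YAML run configuration; unknown keys are rejected."""
    path = Path(path)
    with open(path) as fh:
        cfg = yaml.safe_load(fh) if path.suffix.lower() in (".yml", ".yaml") else json.load(fh)
    if not isinstance(cfg, dict):
        raise SchemaError(f"{path}: configuration must be a mapping")
    if allowed_keys is not None:
        unknown = set(cfg) - set(allowed_keys)
        if unknown:
            raise SchemaError(f"{path}: unknown configuration key(s) {sorted(unknown)}")
    return cfg
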