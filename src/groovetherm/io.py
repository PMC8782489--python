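"""File I/O: trajectories through MDAnalysis, tabular data through pandas.

Trajectory topologies are PDB; coordinate series XTC or DCD.  Melting
curves are CSV with explicit temperature units; work tables are two-column
CSV (direction, work).  All CSV is comma-separated with a header row and
'.' decimals.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .crooks import WorkSet
from .helix import DensityMap
from .melting import MeltingCurve, ThermoParams
from .trajectory import Trajectory


# ---------------------------------------------------------------------------
# trajectories (MDAnalysis bridge)
# ---------------------------------------------------------------------------

def read_trajectory(top_path: str, traj_path: str | None = None,
                    selection: str | None = None) -> Trajectory:
    """Load PDB (+ optional XTC/DCD) into the in-memory container.

    ``selection`` is an MDAnalysis selection string; matching zero atoms is
    an error.  Frames are 0-based; coordinates in Å.
    """
    import MDAnalysis as mda

    for p in (top_path, traj_path):
        if p is not None and not os.path.exists(p):
            raise FileNotFoundError(p)
    u = mda.Universe(top_path) if traj_path is None \
        else mda.Universe(top_path, traj_path)
    ag = u.atoms if selection is None else u.select_atoms(selection)
    if len(ag) == 0:
        raise ValueError(f"selection {selection!r} matches zero atoms")
    coords = np.stack([ag.positions.copy() for _ in u.trajectory])
    resids = ag.resindices - ag.resindices.min()
    try:
        box = u.dimensions[:3].copy() if u.dimensions is not None else None
    except AttributeError:
        box = None
    return Trajectory(coords.astype(float), [a.name for a in ag],
                      np.asarray(resids, dtype=int),
                      [a.resname for a in ag],
                      [a.segid for a in ag], box)


def write_trajectory(traj: Trajectory, top_path: str,
                     traj_path: str | None = None) -> None:
    """Write the topology as PDB and, optionally, all frames as XTC/DCD
    (format chosen by the extension)."""
    import warnings

    import MDAnalysis as mda
    from MDAnalysis.coordinates.memory import MemoryReader

    n_res = traj.n_residues
    segidx = np.zeros(n_res, dtype=int)
    seg_labels = []
    res_seg = {}
    for i in range(traj.n_atoms):
        res_seg[int(traj.resids[i])] = traj.segids[i]
    for r in range(n_res):
        s = res_seg.get(r, "X")
        if s not in seg_labels:
            seg_labels.append(s)
        segidx[r] = seg_labels.index(s)

    u = mda.Universe.empty(traj.n_atoms, n_residues=n_res,
                           n_segments=len(seg_labels),
                           atom_resindex=traj.resids,
                           residue_segindex=segidx, trajectory=True)
    u.add_TopologyAttr("name", traj.names)
    res_names = [""] * n_res
    for i in range(traj.n_atoms):
        res_names[int(traj.resids[i])] = traj.resnames[i]
    u.add_TopologyAttr("resname", res_names)
    u.add_TopologyAttr("resid", np.arange(1, n_res + 1))
    u.add_TopologyAttr("segid", seg_labels)
    u.add_TopologyAttr("element", ["C"] * traj.n_atoms)
    u.load_new(traj.coords.astype(np.float32), format=MemoryReader)
    if traj.box is not None:
        dims = np.array([*traj.box, 90.0, 90.0, 90.0], dtype=np.float32)
        for ts in u.trajectory:
            ts.dimensions = dims
        u.trajectory.rewind()

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.atoms.write(top_path)
        if traj_path is not None:
            kwargs = {}
            if traj_path.lower().endswith(".xtc"):
                kwargs["precision"] = 5  # decimal places (nm): 1e-4 Å grid
            with mda.Writer(traj_path, traj.n_atoms, **kwargs) as w:
                for _ in u.trajectory:
                    w.write(u.atoms)


# ---------------------------------------------------------------------------
# melting curves
# ---------------------------------------------------------------------------

def read_melting_curve(path: str, Ct: float, condition: str = "",
                       sequence_id: str = "",
                       temperature_unit: str | None = None) -> MeltingCurve:
    """Read a CSV melting curve.

    Accepts columns ``temperature_K`` or ``temperature_C`` (unit taken from
    the header), or a plain ``temperature`` column with an explicit
    ``temperature_unit`` of "K" or "C".
    """
    df = pd.read_csv(path)
    if "temperature_K" in df.columns:
        T = df["temperature_K"].to_numpy(float)
    elif "temperature_C" in df.columns:
        T = df["temperature_C"].to_numpy(float) + 273.15
    elif "temperature" in df.columns:
        if temperature_unit not in ("K", "C"):
            raise ValueError("plain 'temperature' column requires "
                             "temperature_unit='K' or 'C'")
        T = df["temperature"].to_numpy(float)
        if temperature_unit == "C":
            T = T + 273.15
    else:
        raise ValueError("no temperature column found")
    return MeltingCurve(T, df["absorbance"].to_numpy(float), Ct,
                        condition, sequence_id)


def write_melting_curve(curve: MeltingCurve, path: str) -> None:
    pd.DataFrame({"temperature_K": curve.T, "absorbance": curve.A}) \
        .to_csv(path, index=False)


def write_thermo_table(params: dict[str, ThermoParams], path: str) -> None:
    """Per-condition thermodynamic table (kcal/mol units)."""
    rows = []
    for cond, p in params.items():
        rows.append({"condition": cond, "dH_kcal_mol": p.dH,
                     "dS_kcal_mol_K": p.dS, "dG300_kcal_mol": p.dG300,
                     "r2": p.r2, "direction": p.direction})
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# work tables
# ---------------------------------------------------------------------------

def load_work_values(path: str, T: float = 300.0, label: str = "",
                     unit: str = "kJ/mol") -> WorkSet:
    """Two-column work table: direction in {F, R}, work in kJ/mol.

    ``unit="kBT"`` converts inputs from k_BT at ``T``.  Malformed rows and
    unknown direction tokens are errors.
    """
    from .constants import kBT_kJ

    df = pd.read_csv(path)
    if df.shape[0] == 0:
        raise ValueError(f"{path}: empty work table")
    cols = {c.lower(): c for c in df.columns}
    if "direction" not in cols or "work" not in cols:
        raise ValueError(f"{path}: need 'direction' and 'work' columns")
    dirs = df[cols["direction"]].astype(str).str.strip().str.upper()
    unknown = set(dirs) - {"F", "R"}
    if unknown:
        raise ValueError(f"{path}: unknown direction token(s) {sorted(unknown)}")
    work = pd.to_numeric(df[cols["work"]], errors="coerce")
    if work.isna().any():
        bad = int(work.isna().idxmax())
        raise ValueError(f"{path}: malformed work value on row {bad}")
    w = work.to_numpy(float)
    if unit == "kBT":
        w = w * kBT_kJ(T)
    elif unit != "kJ/mol":
        raise ValueError("unit must be 'kJ/mol' or 'kBT'")
    return WorkSet(w[dirs == "F"], w[dirs == "R"], T, label)


def write_work_values(ws: WorkSet, path: str) -> None:
    pd.DataFrame({
        "direction": ["F"] * ws.n_F + ["R"] * ws.n_R,
        "work": np.concatenate([ws.W_F, ws.W_R]),
    }).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# density maps
# ---------------------------------------------------------------------------

def write_density_map(dmap: DensityMap, path: str) -> None:
    """Long-form CSV: one row per (R, A) cell with molarity and bulk ratio."""
    rows = []
    rm = 0.5 * (dmap.r_edges[:-1] + dmap.r_edges[1:])
    am = 0.5 * (dmap.a_edges[:-1] + dmap.a_edges[1:])
    bulk = dmap.bulk_molarity
    for i, r in enumerate(rm):
        for j, a in enumerate(am):
            m = dmap.molarity[i, j]
            rows.append({"R_mid_A": r, "A_mid_deg": a,
                         "mean_count": dmap.counts[i, j], "molarity_M": m,
                         "bulk_ratio": m / bulk if bulk and np.isfinite(bulk)
                         and bulk > 0 else np.nan})
    pd.DataFrame(rows).to_csv(path, index=False)
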