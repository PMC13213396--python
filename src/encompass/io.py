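"""Readers and writers for the formats the pipeline touches.

Structural ensembles travel as multi-model PDB (via biotite) or as a columnar
XYZ table; discrete trajectories as plain text or CSV; TPMs, reports and
tables as CSV; models and manifests as JSON. PDB does not carry residue
class, site labels or radii, so writers emit an optional metadata sidecar
that readers can re-apply.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import biotite.structure as struc
import biotite.structure.io.pdb as pdb

from .ensemble import ATOM_COLUMNS, DEFAULT_RADII, FALLBACK_RADIUS, StructureEnsemble
from .msm import TPM, DiscreteTrajectorySet

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Structure ensembles
# ---------------------------------------------------------------------------

def write_ensemble_pdb(
    ensemble: StructureEnsemble, path: str | Path, write_meta: bool = True
) -> None:
    """Write one MODEL per frame; ligand atoms become HETATM records.

    A ``<path>.meta.csv`` sidecar preserves metadata PDB cannot carry.
    """
    path = Path(path)
    n_frames, n_atoms = ensemble.n_frames, ensemble.n_atoms
    atoms = ensemble.atoms
    array = struc.AtomArray(n_atoms)
    array.chain_id = atoms["chain"].to_numpy(dtype="U4")
    array.res_id = atoms["residue_index"].to_numpy(dtype=int) + 1  # 1-based on disk
    array.res_name = np.where(atoms["is_ligand"], "LIG", "RES")
    array.atom_name = atoms["atom_name"].to_numpy(dtype="U6")
    array.element = atoms["element"].to_numpy(dtype="U2")
    array.hetero = atoms["is_ligand"].to_numpy(dtype=bool)
    stack = struc.stack([array] * n_frames)
    stack.coord = ensemble.coords.astype(np.float32)
    pdb_file = pdb.PDBFile()
    pdb.set_structure(pdb_file, stack)
    pdb_file.write(str(path))
    if write_meta:
        meta = atoms[["residue_class", "radius", "is_ca", "site_label"]].copy()
        meta.to_csv(path.with_suffix(path.suffix + ".meta.csv"), index=False)


def write_ensemble_xyz(
    ensemble: StructureEnsemble, path: str | Path, write_meta: bool = True
) -> None:
    """Columnar table: frame, chain, residue, atom, x, y, z (Angstrom)."""
    path = Path(path)
    atoms = ensemble.atoms
    n_frames, n_atoms = ensemble.n_frames, ensemble.n_atoms
    frame_col = np.repeat(np.arange(n_frames), n_atoms)
    table = pd.DataFrame(
        {
            "frame": frame_col,
            "chain": np.tile(atoms["chain"].to_numpy(), n_frames),
            "residue": np.tile(atoms["residue_index"].to_numpy(), n_frames),
            "atom": np.tile(atoms["atom_name"].to_numpy(), n_frames),
            "x": ensemble.coords[:, :, 0].ravel(),
            "y": ensemble.coords[:, :, 1].ravel(),
            "z": ensemble.coords[:, :, 2].ravel(),
        }
    )
    table.to_csv(path, index=False, float_format="%.6f")
    if write_meta:
        meta = atoms[["residue_class", "radius", "is_ca", "site_label", "is_ligand",
                      "element"]].copy()
        meta.to_csv(Path(str(path) + ".meta.csv"), index=False)


def _apply_meta(atoms: pd.DataFrame, meta_path: Path) -> pd.DataFrame:
    if meta_path.exists():
        meta = pd.read_csv(meta_path, keep_default_na=False)
        if len(meta) != len(atoms):
            raise ValueError("metadata sidecar does not match atom roster")
        for col in meta.columns:
            atoms[col] = meta[col].to_numpy()
        atoms["radius"] = atoms["radius"].astype(float)
        atoms["is_ca"] = atoms["is_ca"].astype(bool)
        if "is_ligand" in meta.columns:
            atoms["is_ligand"] = atoms["is_ligand"].astype(bool)
    return atoms


def read_structure_ensemble(path: str | Path, format: str | None = None) -> StructureEnsemble:
    """Read a multi-model PDB or columnar XYZ table into an ensemble.

    The format is inferred from the extension unless given. A constant atom
    roster across models is enforced; unknown elements fall back to a default
    radius with a warning. Residue numbering is converted to 0-based.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "pdb" if path.suffix.lower() == ".pdb" else "xyz"
    if format == "pdb":
        return _read_pdb(path)
    if format == "xyz":
        return _read_xyz(path)
    raise ValueError(f"unknown format {format!r}")


def _radius_for(element: str) -> float:
    element = str(element).strip().upper()
    if element not in DEFAULT_RADII:
        logger.warning("unknown element %r; using default radius %.2f A",
                       element, FALLBACK_RADIUS)
        return FALLBACK_RADIUS
    return DEFAULT_RADII[element]


def _read_pdb(path: Path) -> StructureEnsemble:
    pdb_file = pdb.PDBFile.read(str(path))
    try:
        stack = pdb_file.get_structure()
    except Exception as exc:  # biotite raises on roster mismatch between models
        raise ValueError(f"inconsistent atom roster across models in {path}: {exc}") from exc
    if isinstance(stack, struc.AtomArray):
        stack = struc.stack([stack])
    first = stack[0]
    atoms = pd.DataFrame(
        {
            "chain": first.chain_id,
            "residue_index": first.res_id.astype(int) - 1,
            "residue_class": "hydrophobic",
            "atom_name": first.atom_name,
            "element": first.element,
            "radius": [_radius_for(e) for e in first.element],
            "is_ca": first.atom_name == "CA",
            "is_ligand": first.hetero,
            "site_label": "",
        }
    )
    atoms = _apply_meta(atoms, path.with_suffix(path.suffix + ".meta.csv"))
    return StructureEnsemble(coords=np.asarray(stack.coord, dtype=float), atoms=atoms)


def _read_xyz(path: Path) -> StructureEnsemble:
    table = pd.read_csv(path)
    required = {"frame", "chain", "residue", "atom", "x", "y", "z"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"XYZ table missing columns: {sorted(missing)}")
    frames = np.sort(table["frame"].unique())
    rosters = table.groupby("frame", sort=True).size()
    if rosters.nunique() != 1:
        bad = rosters[rosters != rosters.iloc[0]].index[0]
        raise ValueError(f"atom roster mismatch at frame {bad}")
    first = table[table["frame"] == frames[0]]
    atoms = pd.DataFrame(
        {
            "chain": first["chain"].to_numpy(),
            "residue_index": first["residue"].to_numpy(dtype=int),
            "residue_class": "hydrophobic",
            "atom_name": first["atom"].to_numpy(),
            "element": "C",
            "radius": FALLBACK_RADIUS,
            "is_ca": first["atom"].to_numpy() == "CA",
            "is_ligand": False,
            "site_label": "",
        }
    )
    atoms = _apply_meta(atoms, Path(str(path) + ".meta.csv"))
    n_atoms = len(first)
    coords = (
        table.sort_values(["frame"], kind="stable")[["x", "y", "z"]]
        .to_numpy(dtype=float)
        .reshape(len(frames), n_atoms, 3)
    )
    return StructureEnsemble(coords=coords, atoms=atoms)


# ---------------------------------------------------------------------------
# Discrete trajectories, TPMs
# ---------------------------------------------------------------------------

def write_dtrajs_csv(dtrajs: DiscreteTrajectorySet, path: str | Path) -> None:
    rows = []
    for t, traj in enumerate(dtrajs.trajectories):
        rows.append(pd.DataFrame({"trajectory": t, "state": traj}))
    table = pd.concat(rows, ignore_index=True)
    table.to_csv(path, index=False)


def read_dtrajs_csv(path: str | Path, frame_interval: float = 1.0) -> DiscreteTrajectorySet:
    table = pd.read_csv(path)
    trajs = [g["state"].to_numpy(dtype=int) for _, g in table.groupby("trajectory", sort=True)]
    n_states = int(max(t.max() for t in trajs)) + 1
    return DiscreteTrajectorySet(trajs, n_states=n_states, frame_interval=frame_interval)


def write_dtraj_txt(traj: np.ndarray, path: str | Path) -> None:
    np.savetxt(path, np.asarray(traj, dtype=int), fmt="%d")


def read_dtraj_txt(path: str | Path) -> np.ndarray:
    return np.loadtxt(path, dtype=int)


def write_tpm_csv(tpm: TPM, path: str | Path) -> None:
    """TPM as CSV with the active set in the header row/column."""
    frame = pd.DataFrame(tpm.matrix, index=tpm.active_set, columns=tpm.active_set)
    frame.index.name = f"lag={tpm.lag}"
    frame.to_csv(path)


def write_json(obj, path: str | Path) -> None:
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, (np.bool_,)):
            return bool(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=default, sort_keys=True))


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())
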