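"""Structural ensemble container shared across featurization and interface analysis.

A :class:`StructureEnsemble` is a fixed atom roster observed over many frames.
Coordinates are always in Angstrom; time is abstract (frames times an optional
``frame_interval``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Default van der Waals radii (Angstrom) used when no per-atom radius is given.
DEFAULT_RADII = {"C": 1.7, "N": 1.55, "O": 1.52, "S": 1.8}
FALLBACK_RADIUS = 1.7

ATOM_COLUMNS = [
    "chain",
    "residue_index",
    "residue_class",
    "atom_name",
    "element",
    "radius",
    "is_ca",
    "is_ligand",
    "site_label",
]


@dataclass
class StructureEnsemble:
    """Frames of a two-chain complex with per-atom metadata.

    Parameters
    ----------
    coords
        Array of shape ``(n_frames, n_atoms, 3)`` in Angstrom.
    atoms
        DataFrame with one row per atom and the columns in :data:`ATOM_COLUMNS`.
        ``chain`` is ``"A"`` or ``"B"``; ``residue_class`` is one of
        ``{"charged", "polar", "hydrophobic"}`` (free-form tolerated);
        ``site_label`` is ``""`` for unlabeled atoms.
    frame_state
        Optional integer macro-state label per frame.
    frame_interval
        Duration of one frame in abstract time units.
    """

    coords: np.ndarray
    atoms: pd.DataFrame
    frame_state: np.ndarray | None = None
    frame_interval: float = 1.0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if len(self.atoms) != self.coords.shape[1]:
            raise ValueError(
                f"atom roster ({len(self.atoms)}) does not match coordinate "
                f"array ({self.coords.shape[1]} atoms)"
            )
        missing = [c for c in ATOM_COLUMNS if c not in self.atoms.columns]
        if missing:
            raise ValueError(f"atom table missing columns: {missing}")
        if len(self.atoms) == 0:
            raise ValueError("ensemble has no atoms")
        radii = np.asarray(self.atoms["radius"], dtype=float)
        if np.any(radii <= 0):
            raise ValueError("all atom radii must be positive")
        chains = set(self.atoms["chain"])
        if not chains <= {"A", "B"}:
            raise ValueError(f"unknown chain ids: {sorted(chains - {'A', 'B'})}")
        if self.frame_state is not None:
            self.frame_state = np.asarray(self.frame_state, dtype=int)
            if self.frame_state.shape[0] != self.n_frames:
                raise ValueError("frame_state length must equal n_frames")
        self.atoms = self.atoms.reset_index(drop=True)

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def chain_mask(self, chain: str) -> np.ndarray:
        return (self.atoms["chain"] == chain).to_numpy()

    def radii(self) -> np.ndarray:
        return self.atoms["radius"].to_numpy(dtype=float)

    def subset_frames(self, indices) -> "StructureEnsemble":
        idx = np.asarray(indices, dtype=int)
        fs = None if self.frame_state is None else self.frame_state[idx]
        return StructureEnsemble(
            coords=self.coords[idx],
            atoms=self.atoms.copy(),
            frame_state=fs,
            frame_interval=self.frame_interval,
        )

    def with_frame_state(self, labels) -> "StructureEnsemble":
        return StructureEnsemble(
            coords=self.coords,
            atoms=self.atoms.copy(),
            frame_state=np.asarray(labels, dtype=int),
            frame_interval=self.frame_interval,
        )


def make_atom_table(records: list[dict]) -> pd.DataFrame:
    """Build a validated atom table from partial per-atom dicts.

    Unspecified fields receive defaults: element ``C``, radius from
    :data:`DEFAULT_RADII`, flags ``False``, ``site_label`` empty.
    """
    rows = []
    for rec in records:
        element = rec.get("element", "C")
        row = {
            "chain": rec["chain"],
            "residue_index": int(rec["residue_index"]),
            "residue_class": rec.get("residue_class", "hydrophobic"),
            "atom_name": rec.get("atom_name", "CA"),
            "element": element,
            "radius": float(rec.get("radius", DEFAULT_RADII.get(element, FALLBACK_RADIUS))),
            "is_ca": bool(rec.get("is_ca", False)),
            "is_ligand": bool(rec.get("is_ligand", False)),
            "site_label": rec.get("site_label", ""),
        }
        rows.append(row)
    return pd.DataFrame(rows, columns=ATOM_COLUMNS)
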