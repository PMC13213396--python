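"""Structural characterization of metastable states.

Representative frame selection, interface RMSD against microstate-center
references, Shrake-Rupley solvent-accessible surface area, buried surface
area, residue contact frequencies with residue-class breakdown, and the
shortlist rule that picks design-ready states.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .ensemble import StructureEnsemble

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Geometry helpers
# ---------------------------------------------------------------------------

def kabsch(mobile: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Optimal rotation R and translation t mapping mobile onto target.

    Apply as ``x @ R.T + t``.
    """
    cm = mobile.mean(axis=0)
    ct = target.mean(axis=0)
    h = (mobile - cm).T @ (target - ct)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    t = ct - cm @ r.T
    return r, t


def golden_spiral_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden spiral)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * i
    return np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )


# ---------------------------------------------------------------------------
# SASA / BSA
# ---------------------------------------------------------------------------

def sasa(
    coords: np.ndarray,
    radii: np.ndarray,
    probe_radius: float = 1.4,
    n_sphere_points: int = 960,
) -> np.ndarray:
    """Per-atom Shrake-Rupley solvent-accessible surface area (Angstrom^2).

    Test points are placed on each atom's expanded sphere (radius + probe);
    the exposed fraction scales the analytic sphere area. Deterministic: no
    RNG is involved in point placement.
    """
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    if n_sphere_points < 32:
        raise ValueError("n_sphere_points must be >= 32")
    if coords.shape[0] != radii.shape[0]:
        raise ValueError("one radius per atom required")
    expanded = radii + probe_radius
    unit = golden_spiral_points(n_sphere_points)
    tree = cKDTree(coords)
    max_reach = 2.0 * expanded.max()
    areas = np.empty(len(coords))
    for i in range(len(coords)):
        points = coords[i] + expanded[i] * unit
        neighbors = tree.query_ball_point(coords[i], expanded[i] + expanded.max())
        neighbors = [j for j in neighbors if j != i]
        exposed = np.ones(n_sphere_points, dtype=bool)
        for j in neighbors:
            d2 = np.sum((points - coords[j]) ** 2, axis=1)
            exposed &= d2 >= expanded[j] ** 2
            if not exposed.any():
                break
        areas[i] = exposed.mean() * 4.0 * np.pi * expanded[i] ** 2
    return areas


def bsa(
    frame_coords: np.ndarray,
    radii: np.ndarray,
    chain_mask_a: np.ndarray,
    probe_radius: float = 1.4,
    n_sphere_points: int = 960,
) -> float:
    """Buried surface area: SASA(A) + SASA(B) - SASA(complex), clipped at 0."""
    chain_mask_a = np.asarray(chain_mask_a, dtype=bool)
    mask_b = ~chain_mask_a
    if not chain_mask_a.any() or not mask_b.any():
        raise ValueError("both chains must contain atoms")
    sasa_complex = sasa(frame_coords, radii, probe_radius, n_sphere_points).sum()
    sasa_a = sasa(frame_coords[chain_mask_a], radii[chain_mask_a],
                  probe_radius, n_sphere_points).sum()
    sasa_b = sasa(frame_coords[mask_b], radii[mask_b],
                  probe_radius, n_sphere_points).sum()
    value = sasa_a + sasa_b - sasa_complex
    if value < -0.1:
        logger.warning("BSA clipped from %.3f to 0", value)
    return float(max(value, 0.0))


# ---------------------------------------------------------------------------
# Representative frames and interface RMSD
# ---------------------------------------------------------------------------

def representative_structure(
    projection: np.ndarray,
    frame_microstates: np.ndarray,
    state_frames: np.ndarray,
    microstate_populations: dict[int, float] | np.ndarray,
) -> int:
    """Frame closest to the center of the state's most populated microstate.

    Ties in population break toward the lower microstate index; ties in
    distance toward the lower frame index.
    """
    state_frames = np.asarray(state_frames, dtype=int)
    if len(state_frames) == 0:
        raise ValueError("state has no frames")
    projection = np.atleast_2d(np.asarray(projection, dtype=float))
    if projection.shape[0] == 1 and projection.shape[1] == len(frame_microstates):
        projection = projection.T
    micros = np.asarray(frame_microstates, dtype=int)[state_frames]
    present = np.unique(micros)
    if isinstance(microstate_populations, dict):
        pops = np.array([microstate_populations.get(int(m), 0.0) for m in present])
    else:
        pops = np.asarray(microstate_populations, dtype=float)[present]
    best_micro = present[int(np.argmax(pops))]  # argmax -> lowest index on ties
    member_frames = state_frames[micros == best_micro]
    pts = projection[member_frames]
    center = pts.mean(axis=0)
    dist = np.linalg.norm(pts - center, axis=1)
    return int(member_frames[int(np.argmin(dist))])


def _interface_selections(
    ensemble: StructureEnsemble, reference: np.ndarray, cutoff: float
) -> tuple[np.ndarray, np.ndarray]:
    """Return (chain-A interface atom idx, interface Ca atom idx) on a reference."""
    atoms = ensemble.atoms
    mask_a = ensemble.chain_mask("A")
    mask_b = ~mask_a
    tree_b = cKDTree(reference[mask_b])
    tree_a = cKDTree(reference[mask_a])
    idx_a = np.flatnonzero(mask_a)
    idx_b = np.flatnonzero(mask_b)
    da, _ = tree_b.query(reference[mask_a])
    db, _ = tree_a.query(reference[mask_b])
    contact_res = set()
    for i, close in zip(idx_a[da < cutoff], atoms.loc[idx_a[da < cutoff], "residue_index"]):
        contact_res.add(("A", int(close)))
    for i, close in zip(idx_b[db < cutoff], atoms.loc[idx_b[db < cutoff], "residue_index"]):
        contact_res.add(("B", int(close)))
    keys = list(zip(atoms["chain"], atoms["residue_index"].astype(int)))
    in_interface = np.array([k in contact_res for k in keys])
    fit_atoms = np.flatnonzero(in_interface & mask_a)
    rmsd_atoms = np.flatnonzero(in_interface & atoms["is_ca"].to_numpy())
    return fit_atoms, rmsd_atoms


def interface_rmsd(
    ensemble: StructureEnsemble,
    reference_frames: list[int],
    interface_cutoff: float = 10.0,
    frame_subset: np.ndarray | None = None,
    aggregate: str = "min",
) -> dict:
    """Interface RMSD of each frame against microstate-center references.

    Interface residues are defined on each reference (any heavy atom within
    ``interface_cutoff`` of the other chain). Frames are superposed on the
    reference using chain-A interface atoms only, so the RMSD over both
    chains' interface Ca atoms measures relative pose change. Per frame the
    ``aggregate`` ("min" or "mean") over references is taken; the summary is
    mean +/- sd over frames.
    """
    if not reference_frames:
        raise ValueError("need at least one reference frame")
    if interface_cutoff <= 0:
        raise ValueError("interface_cutoff must be positive")
    frames = (
        np.arange(ensemble.n_frames) if frame_subset is None
        else np.asarray(frame_subset, dtype=int)
    )
    per_ref = np.full((len(frames), len(reference_frames)), np.nan)
    for r, ref_idx in enumerate(reference_frames):
        ref = ensemble.coords[ref_idx]
        fit_atoms, rmsd_atoms = _interface_selections(ensemble, ref, interface_cutoff)
        if len(fit_atoms) < 3 or len(rmsd_atoms) == 0:
            raise ValueError(
                f"reference {ref_idx}: empty interface at cutoff {interface_cutoff}; "
                "try a larger cutoff"
            )
        ref_fit = ref[fit_atoms]
        ref_rmsd = ref[rmsd_atoms]
        for f, frame_idx in enumerate(frames):
            mob = ensemble.coords[frame_idx]
            rot, trans = kabsch(mob[fit_atoms], ref_fit)
            moved = mob[rmsd_atoms] @ rot.T + trans
            per_ref[f, r] = np.sqrt(np.mean(np.sum((moved - ref_rmsd) ** 2, axis=1)))
    if aggregate == "min":
        per_frame = per_ref.min(axis=1)
    elif aggregate == "mean":
        per_frame = per_ref.mean(axis=1)
    else:
        raise ValueError("aggregate must be 'min' or 'mean'")
    return {
        "per_frame": per_frame,
        "mean": float(per_frame.mean()),
        "sd": float(per_frame.std()),
    }


# ---------------------------------------------------------------------------
# Contacts
# ---------------------------------------------------------------------------

def contact_frequency(
    ensemble: StructureEnsemble,
    heavy_atom_cutoff: float = 4.5,
    frame_subset: np.ndarray | None = None,
) -> dict:
    """Interchain residue-pair contact frequencies plus residue-class shares.

    A pair (a in A, b in B) is in contact in a frame iff any interchain
    heavy-atom distance is below the cutoff. Frequencies are fractions of the
    analyzed frames; the class breakdown tallies contact events by the residue
    classes on both sides and normalizes to 1.
    """
    if heavy_atom_cutoff <= 0:
        raise ValueError("cutoff must be positive")
    atoms = ensemble.atoms
    mask_a = ensemble.chain_mask("A")
    idx_a = np.flatnonzero(mask_a)
    idx_b = np.flatnonzero(~mask_a)
    res_a = sorted(atoms.loc[idx_a, "residue_index"].astype(int).unique())
    res_b = sorted(atoms.loc[idx_b, "residue_index"].astype(int).unique())
    pos_a = {r: i for i, r in enumerate(res_a)}
    pos_b = {r: i for i, r in enumerate(res_b)}
    atom_res_a = atoms.loc[idx_a, "residue_index"].astype(int).to_numpy()
    atom_res_b = atoms.loc[idx_b, "residue_index"].astype(int).to_numpy()
    def _modal_class(series: pd.Series) -> str:
        counts = series.value_counts()
        top = counts[counts == counts.max()]
        return sorted(top.index)[0]  # deterministic on ties

    class_a = {r: _modal_class(atoms.loc[idx_a[atom_res_a == r], "residue_class"]) for r in res_a}
    class_b = {r: _modal_class(atoms.loc[idx_b[atom_res_b == r], "residue_class"]) for r in res_b}
    frames = (
        np.arange(ensemble.n_frames) if frame_subset is None
        else np.asarray(frame_subset, dtype=int)
    )
    counts = np.zeros((len(res_a), len(res_b)))
    class_counts: dict[str, float] = {}
    for frame_idx in frames:
        xa = ensemble.coords[frame_idx, idx_a]
        xb = ensemble.coords[frame_idx, idx_b]
        pairs = cKDTree(xa).query_ball_tree(cKDTree(xb), heavy_atom_cutoff)
        seen = set()
        for ia, blist in enumerate(pairs):
            for ib in blist:
                key = (atom_res_a[ia], atom_res_b[ib])
                if key not in seen:
                    seen.add(key)
                    counts[pos_a[key[0]], pos_b[key[1]]] += 1
                    for cls in (class_a[key[0]], class_b[key[1]]):
                        class_counts[cls] = class_counts.get(cls, 0.0) + 1.0
    freq = counts / len(frames)
    total = sum(class_counts.values())
    fractions = (
        {k: v / total for k, v in sorted(class_counts.items())} if total > 0 else {}
    )
    matrix = pd.DataFrame(freq, index=res_a, columns=res_b)
    return {"matrix": matrix, "class_fractions": fractions}


# ---------------------------------------------------------------------------
# Reports and shortlisting
# ---------------------------------------------------------------------------

@dataclass
class StateInterfaceReport:
    state_id: int
    representative_frame: int
    irmsd_mean: float
    irmsd_sd: float
    bsa_mean: float
    bsa_sd: float
    contact_matrix: pd.DataFrame | None = None
    residue_class_fractions: dict = field(default_factory=dict)
    population: float = float("nan")


def state_report(
    ensemble: StructureEnsemble,
    state_id: int,
    state_frames: np.ndarray,
    reference_frames: list[int],
    representative_frame: int,
    population: float = float("nan"),
    interface_cutoff: float = 10.0,
    contact_cutoff: float = 4.5,
    probe_radius: float = 1.4,
    n_sphere_points: int = 960,
    max_bsa_frames: int = 20,
    irmsd_aggregate: str = "min",
) -> StateInterfaceReport:
    """Full structural report for one metastable state.

    BSA is averaged over an evenly strided subset of at most ``max_bsa_frames``
    frames (SASA is the expensive step).
    """
    state_frames = np.asarray(state_frames, dtype=int)
    irmsd = interface_rmsd(
        ensemble, reference_frames, interface_cutoff,
        frame_subset=state_frames, aggregate=irmsd_aggregate,
    )
    stride = max(1, len(state_frames) // max_bsa_frames)
    bsa_frames = state_frames[::stride][:max_bsa_frames]
    radii = ensemble.radii()
    mask_a = ensemble.chain_mask("A")
    bsa_vals = np.array(
        [bsa(ensemble.coords[f], radii, mask_a, probe_radius, n_sphere_points)
         for f in bsa_frames]
    )
    contacts = contact_frequency(ensemble, contact_cutoff, frame_subset=state_frames)
    return StateInterfaceReport(
        state_id=state_id,
        representative_frame=int(representative_frame),
        irmsd_mean=irmsd["mean"],
        irmsd_sd=irmsd["sd"],
        bsa_mean=float(bsa_vals.mean()),
        bsa_sd=float(bsa_vals.std()),
        contact_matrix=contacts["matrix"],
        residue_class_fractions=contacts["class_fractions"],
        population=float(population),
    )


def shortlist_states(
    reports: list[StateInterfaceReport],
    populations: dict[int, float] | None = None,
    pop_min: float = 0.05,
    irmsd_max: float = 10.0,
    bsa_min: float | None = None,
) -> dict[int, dict]:
    """Design-readiness verdict per state.

    A state passes iff population >= ``pop_min``, mean interface RMSD <=
    ``irmsd_max`` and mean BSA >= ``bsa_min`` (default: 60% of the median
    mean BSA across states). Failing criteria are listed as reasons.
    """
    if bsa_min is None:
        bsa_values = [r.bsa_mean for r in reports if np.isfinite(r.bsa_mean)]
        bsa_min = 0.6 * float(np.median(bsa_values)) if bsa_values else 0.0
    verdicts: dict[int, dict] = {}
    for report in reports:
        pop = (
            populations.get(report.state_id, report.population)
            if populations is not None
            else report.population
        )
        metrics = {"population": pop, "irmsd_mean": report.irmsd_mean,
                   "bsa_mean": report.bsa_mean}
        if any(not np.isfinite(v) for v in metrics.values()):
            verdicts[report.state_id] = {
                "pass": False, "reasons": ["insufficient data"], "metrics": metrics,
            }
            continue
        reasons = []
        if pop < pop_min:
            reasons.append("population")
        if report.irmsd_mean > irmsd_max:
            reasons.append("interface heterogeneity")
        if report.bsa_mean < bsa_min:
            reasons.append("low burial")
        verdicts[report.state_id] = {
            "pass": not reasons, "reasons": reasons, "metrics": metrics,
            "thresholds": {"pop_min": pop_min, "irmsd_max": irmsd_max,
                           "bsa_min": bsa_min},
        }
    return verdicts
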