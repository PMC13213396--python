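"""Post-docking candidate prioritization.

Receptor-ensemble snapshot selection from core-region microstates, pose
selection by unsuperposed ligand RMSD, bootstrap aggregation of
per-trajectory binding free energies, and joint threshold/tier
classification.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

POSE_COLUMNS = ["compound", "state", "pose", "ligand_rmsd"]
ENERGY_COLUMNS = ["compound", "state", "trajectory", "dG_kcal_mol"]


def core_region(
    microstate_populations: dict[int, float] | np.ndarray,
    population_min: float = 0.01,
) -> list[int]:
    """Microstates with stationary population above the core threshold."""
    if isinstance(microstate_populations, dict):
        items = sorted(microstate_populations.items())
    else:
        items = list(enumerate(np.asarray(microstate_populations, dtype=float)))
    core = [int(m) for m, p in items if p > population_min]
    if not core:
        raise ValueError("no microstate exceeds the core population threshold")
    return core


def prepare_receptor_ensemble(
    microstate_populations: dict[int, float] | np.ndarray,
    frames_by_microstate: dict[int, np.ndarray],
    n_snapshots: int = 200,
    seed: int = 0,
    population_min: float = 0.01,
) -> dict:
    """Random receptor snapshots from the core region of one metastable state.

    Sampling is uniform without replacement; if the frame pool is smaller than
    ``n_snapshots`` sampling falls back to with-replacement (logged). The
    result records that ligands must be stripped before docking.
    """
    core = core_region(microstate_populations, population_min)
    pool = np.concatenate(
        [np.asarray(frames_by_microstate[m], dtype=int) for m in core
         if m in frames_by_microstate and len(frames_by_microstate[m])]
    ) if any(m in frames_by_microstate for m in core) else np.array([], dtype=int)
    if pool.size == 0:
        raise ValueError("core region contains no frames")
    rng = np.random.default_rng(seed)
    replace = pool.size < n_snapshots
    if replace:
        logger.warning(
            "frame pool (%d) smaller than n_snapshots (%d); sampling with replacement",
            pool.size, n_snapshots,
        )
    chosen = rng.choice(pool, size=n_snapshots, replace=replace)
    return {
        "frames": chosen,
        "core_microstates": core,
        "sampled_with_replacement": replace,
        "remove_ligands": True,
    }


def select_poses(poses: pd.DataFrame, n_keep: int = 5) -> pd.DataFrame:
    """Keep the ``n_keep`` lowest-RMSD poses per (compound, state) group.

    Ties break by pose id. Groups smaller than ``n_keep`` are kept whole with
    a warning; empty groups are skipped.
    """
    if n_keep < 1:
        raise ValueError("n_keep must be >= 1")
    missing = [c for c in POSE_COLUMNS if c not in poses.columns]
    if missing:
        raise ValueError(f"pose table missing columns: {missing}")
    if poses.duplicated(subset=["compound", "state", "pose"]).any():
        raise ValueError("duplicate (compound, state, pose) rows")
    if (poses["ligand_rmsd"] < 0).any():
        raise ValueError("ligand_rmsd must be >= 0")
    kept = []
    for (compound, state), group in poses.groupby(["compound", "state"], sort=True):
        if group.empty:
            logger.warning("empty pose group (%s, %s) skipped", compound, state)
            continue
        if len(group) < n_keep:
            logger.warning(
                "group (%s, %s) has only %d poses (< %d); keeping all",
                compound, state, len(group), n_keep,
            )
        kept.append(group.sort_values(["ligand_rmsd", "pose"], kind="stable").head(n_keep))
    return pd.concat(kept, ignore_index=True) if kept else poses.iloc[0:0].copy()


def bootstrap_energy(
    energies: pd.DataFrame, n_boot: int = 10, seed: int = 0
) -> pd.DataFrame:
    """Bootstrap mean +/- sd of binding free energy per (compound, state).

    Each bootstrap iteration resamples the trajectory list with replacement
    and records the mean; the reported value and error are the mean and sd
    across iterations. Deterministic under the seed.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    missing = [c for c in ENERGY_COLUMNS if c not in energies.columns]
    if missing:
        raise ValueError(f"energy table missing columns: {missing}")
    rng = np.random.default_rng(seed)
    rows = []
    for (compound, state), group in energies.groupby(["compound", "state"], sort=True):
        values = group["dG_kcal_mol"].to_numpy(dtype=float)
        if len(values) == 1:
            logger.warning(
                "single trajectory for (%s, %s); bootstrap sd is 0", compound, state
            )
        if np.ptp(values) == 0.0:
            # degenerate input: every resample is identical, exactly
            rows.append({"compound": compound, "state": state,
                         "dG_mean": float(values[0]), "dG_sd": 0.0,
                         "n_traj": len(values)})
            continue
        draws = rng.integers(0, len(values), size=(n_boot, len(values)))
        boot_means = values[draws].mean(axis=1)
        rows.append(
            {
                "compound": compound,
                "state": state,
                "dG_mean": float(boot_means.mean()),
                "dG_sd": float(boot_means.std()),
                "n_traj": len(values),
            }
        )
    return pd.DataFrame(rows)


def classify_compounds(
    summaries: pd.DataFrame,
    threshold: float = -77.0,
    tier_fraction: float = 0.5,
) -> pd.DataFrame:
    """Rank compounds and split into top/bottom classes.

    Per compound the best state is the argmin of mean binding free energy.
    Compounds are ranked ascending by that value (ties by compound id). The
    ``top`` class requires membership in the top ``tier_fraction`` AND a mean
    at or below ``threshold``; both single-rule memberships are reported so
    either can be audited. Compounds with non-finite energies are excluded
    with a reason.
    """
    required = {"compound", "state", "dG_mean"}
    missing = required - set(summaries.columns)
    if missing:
        raise ValueError(f"summary table missing columns: {sorted(missing)}")
    summaries = summaries.sort_values(["compound", "state"], kind="stable")
    rows, excluded = [], []
    for compound, group in summaries.groupby("compound", sort=True):
        finite = group[np.isfinite(group["dG_mean"])]
        if finite.empty:
            excluded.append({"compound": compound, "reason": "non-finite energies"})
            continue
        best = finite.loc[finite["dG_mean"].idxmin()]
        rows.append(
            {
                "compound": compound,
                "best_state": best["state"],
                "dG_mean": float(best["dG_mean"]),
                "dG_sd": float(best.get("dG_sd", np.nan)),
            }
        )
    if not rows:
        raise ValueError("no compound with finite energies")
    report = pd.DataFrame(rows).sort_values(
        ["dG_mean", "compound"], kind="stable"
    ).reset_index(drop=True)
    report["rank"] = np.arange(1, len(report) + 1)
    n_tier = int(np.ceil(tier_fraction * len(report)))
    report["in_top_tier"] = report["rank"] <= n_tier
    report["below_threshold"] = report["dG_mean"] <= threshold
    report["class"] = np.where(
        report["in_top_tier"] & report["below_threshold"], "top", "bottom"
    )
    if excluded:
        logger.warning("excluded compounds: %s", excluded)
    report.attrs["excluded"] = excluded
    return report
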