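"""Staged pipeline: simulate -> featurize -> msm -> igme -> interfaces -> sites -> rank.

Each stage writes its artifacts plus a manifest (hash of the stage-relevant
configuration, seeds, and the upstream manifest hash). A rerun with an
unchanged manifest hash skips the stage, so editing only a downstream
threshold reruns only downstream stages.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import load_config
from .ensemble import StructureEnsemble
from .featurize import interchain_ca_distances, oasis_select, tica_fit, tica_transform
from .igme import igme_scan, lump_dtrajs, macro_tpm_series, pcca_lump
from .interfaces import representative_structure, shortlist_states, state_report
from .io import (
    read_json,
    read_structure_ensemble,
    write_dtrajs_csv,
    write_ensemble_pdb,
    write_ensemble_xyz,
    write_json,
    write_tpm_csv,
)
from .msm import DiscreteTrajectorySet, estimate_tpm, implied_timescales, kmeans_cluster
from .ranking import bootstrap_energy, classify_compounds, select_poses
from .sites import sites_from_labels, viability_matrix
from .synthetic import EnergyTableSpec, gen_energy_table, gen_interface_ensemble, planted_screen_spec

logger = logging.getLogger(__name__)

STAGES = ["simulate", "featurize", "msm", "igme", "interfaces", "sites", "rank"]

# configuration sections each stage's manifest hash depends on
_STAGE_SECTIONS = {
    "simulate": ["simulate"],
    "featurize": ["featurize"],
    "msm": ["msm"],
    "igme": ["igme"],
    "interfaces": ["interfaces"],
    "sites": ["sites"],
    "rank": ["rank"],
}
_STAGE_SEEDS = {
    "simulate": ["simulate"],
    "featurize": ["oasis"],
    "msm": ["cluster"],
    "igme": [],
    "interfaces": [],
    "sites": [],
    "rank": ["rank"],
}


def _stage_hash(config: dict, stage: str, upstream_hash: str) -> str:
    payload = {
        "stage": stage,
        "version": __version__,
        "config": {s: config[s] for s in _STAGE_SECTIONS[stage]},
        "seeds": {s: config["seeds"][s] for s in _STAGE_SEEDS[stage]},
        "upstream": upstream_hash,
    }
    return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()


def _stage_dir(outdir: Path, stage: str) -> Path:
    d = outdir / stage
    d.mkdir(parents=True, exist_ok=True)
    return d


def _manifest_ok(stage_dir: Path, expected_hash: str) -> bool:
    manifest = stage_dir / "manifest.json"
    if not manifest.exists():
        return False
    try:
        return read_json(manifest)["hash"] == expected_hash
    except (KeyError, json.JSONDecodeError):
        return False


def _write_manifest(stage_dir: Path, stage: str, stage_hash: str, config: dict) -> None:
    write_json(
        {
            "stage": stage,
            "hash": stage_hash,
            "version": __version__,
            "seeds": {s: config["seeds"][s] for s in _STAGE_SEEDS[stage]},
        },
        stage_dir / "manifest.json",
    )


DEFAULT_ENERGY_COMPOUNDS = ["cpd1", "cpd2", "cpd3", "cpd4"]
DEFAULT_ENERGY_STATES = ["state0", "state1"]
DEFAULT_ENERGY_MEANS = [
    [-82.0, -79.0],
    [-78.5, -80.0],
    [-74.0, -76.0],
    [-70.0, -68.0],
]
DEFAULT_ENERGY_SDS = [[1.0, 1.0]] * 4


def run_pipeline(
    config: dict | str | Path | None = None,
    stages: list[str] | None = None,
    force: bool = False,
) -> dict:
    """Execute the requested stages (all by default) with resume support.

    ``config`` may be a loaded dict, a YAML path, or None for defaults.
    Returns a dict of stage result paths.
    """
    if config is None or isinstance(config, (str, Path)):
        config = load_config(config)
    stages = stages or STAGES
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    outdir = Path(config["paths"]["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    results: dict[str, Path] = {}
    upstream_hash = ""
    for stage in STAGES:
        stage_hash = _stage_hash(config, stage, upstream_hash)
        sdir = _stage_dir(outdir, stage)
        if stage in stages:
            if not force and _manifest_ok(sdir, stage_hash):
                logger.info("stage %s up to date; skipping", stage)
            else:
                logger.info("running stage %s", stage)
                _RUNNERS[stage](config, outdir)
                _write_manifest(sdir, stage, stage_hash, config)
            results[stage] = sdir
        upstream_hash = stage_hash
    return results


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"missing upstream artifact {path}; rerun stage {stage!r}"
        )
    return path


# ---------------------------------------------------------------------------
# Stage runners
# ---------------------------------------------------------------------------

def _run_simulate(config: dict, outdir: Path) -> None:
    cfg = config["simulate"]
    seed = config["seeds"]["simulate"]
    sdir = outdir / "simulate"
    spec, truth = planted_screen_spec(
        jitter_good=cfg["jitter_good"],
        jitter_hetero=cfg["jitter_hetero"],
        stay_prob=cfg["stay_prob"],
    )
    ensemble, labels = gen_interface_ensemble(spec, cfg["n_frames"], seed=seed)
    write_ensemble_pdb(ensemble, sdir / "ensemble.pdb")
    write_ensemble_xyz(ensemble, sdir / "ensemble.xyz.csv")
    pd.DataFrame({"frame": np.arange(len(labels)), "geometry": labels}).to_csv(
        sdir / "geometry_labels.csv", index=False
    )
    write_json(truth, sdir / "ground_truth.json")
    spec_energy = EnergyTableSpec(
        compounds=cfg["energy_compounds"] or DEFAULT_ENERGY_COMPOUNDS,
        states=cfg["energy_states"] or DEFAULT_ENERGY_STATES,
        means=np.asarray(cfg["energy_means"] or DEFAULT_ENERGY_MEANS, float),
        sds=np.asarray(cfg["energy_sds"] or DEFAULT_ENERGY_SDS, float),
        n_traj=cfg["energy_n_traj"],
    )
    gen_energy_table(spec_energy, seed=seed + 1).to_csv(
        sdir / "energy_table.csv", index=False
    )


def _load_ensemble(config: dict, outdir: Path) -> StructureEnsemble:
    path = config["paths"]["ensemble"]
    if path is None:
        path = _require(outdir / "simulate" / "ensemble.pdb", "simulate")
    return read_structure_ensemble(path)


def _run_featurize(config: dict, outdir: Path) -> None:
    cfg = config["featurize"]
    sdir = outdir / "featurize"
    ensemble = _load_ensemble(config, outdir)
    features = interchain_ca_distances(ensemble, stride_chainB=cfg["stride_chainB"])
    n_select = min(cfg["n_select"], features.n_features)
    selected, error = oasis_select(features, n_select, seed=config["seeds"]["oasis"])
    reduced = features.select_columns(selected)
    model = tica_fit(reduced, lag=cfg["tica_lag"], n_components=cfg["n_cvs"])
    projection = tica_transform(model, reduced)
    np.save(sdir / "projection.npy", projection)
    write_json(
        {
            "n_features": features.n_features,
            "selected_columns": selected,
            "nystrom_error": error,
            "tica_lag": model.lag,
            "tica_eigenvalues": model.eigenvalues,
        },
        sdir / "featurize.json",
    )


def _run_msm(config: dict, outdir: Path) -> None:
    cfg = config["msm"]
    sdir = outdir / "msm"
    projection = np.load(_require(outdir / "featurize" / "projection.npy", "featurize"))
    dtrajs, centers = kmeans_cluster(
        projection, cfg["n_microstates"], seed=config["seeds"]["cluster"]
    )
    write_dtrajs_csv(dtrajs, sdir / "dtrajs.csv")
    np.save(sdir / "centers.npy", centers)
    tpm = estimate_tpm(dtrajs, cfg["lag"])
    write_tpm_csv(tpm, sdir / "tpm.csv")
    valid_lags = [l for l in cfg["its_lags"] if l < dtrajs.min_length]
    its = implied_timescales(dtrajs, valid_lags, n_timescales=min(8, tpm.n_states - 1))
    rows = [
        {"lag": lag, "timescale_index": i + 1, "timescale": float(t)}
        for lag, ts in its.items()
        for i, t in enumerate(ts)
    ]
    pd.DataFrame(rows).to_csv(sdir / "implied_timescales.csv", index=False)


def _run_igme(config: dict, outdir: Path) -> None:
    cfg = config["igme"]
    sdir = outdir / "igme"
    from .io import read_dtrajs_csv

    dtrajs = read_dtrajs_csv(_require(outdir / "msm" / "dtrajs.csv", "msm"))
    lag = config["msm"]["lag"]
    tpm_rev = estimate_tpm(dtrajs, lag, reversible=True)
    n_macro = min(cfg["n_macrostates"], tpm_rev.n_states)
    lumping = pcca_lump(tpm_rev, n_macro)
    macro = lump_dtrajs(dtrajs, lumping, active_set=tpm_rev.active_set)
    max_k = min(cfg["K"], (macro.min_length - 1) // cfg["tau"])
    series = macro_tpm_series(macro, tau=cfg["tau"], K=max_k)
    grid = [
        (n0, L)
        for n0 in cfg["n0_values"]
        for L in cfg["L_values"]
        if n0 + L - 1 <= series.K
    ]
    ensemble_fit = igme_scan(series, grid, top_fraction=cfg["top_fraction"])
    best = ensemble_fit.retained[0]
    write_dtrajs_csv(macro, sdir / "macro_dtrajs.csv")
    np.save(sdir / "micro_to_macro.npy", lumping.assignment)
    np.save(sdir / "active_set.npy", tpm_rev.active_set)
    write_json(
        {
            "A": best.A,
            "T_hat": best.T_hat,
            "fit_window": list(best.fit_window),
            "rmse": best.rmse,
            "tau": best.tau,
            "stationary": best.stationary,
            "timescales": best.timescales,
            "summary": {k: np.asarray(v) for k, v in ensemble_fit.summary.items()},
            "n_models": len(ensemble_fit.models),
            "n_retained": len(ensemble_fit.retained),
        },
        sdir / "igme_model.json",
    )


def _macro_frame_labels(outdir: Path) -> tuple[np.ndarray, np.ndarray]:
    from .io import read_dtrajs_csv

    macro = read_dtrajs_csv(_require(outdir / "igme" / "macro_dtrajs.csv", "igme"))
    micro = read_dtrajs_csv(_require(outdir / "msm" / "dtrajs.csv", "msm"))
    return np.concatenate(macro.trajectories), np.concatenate(micro.trajectories)


def _run_interfaces(config: dict, outdir: Path) -> None:
    cfg = config["interfaces"]
    sdir = outdir / "interfaces"
    ensemble = _load_ensemble(config, outdir)
    projection = np.load(_require(outdir / "featurize" / "projection.npy", "featurize"))
    macro_labels, micro_labels = _macro_frame_labels(outdir)
    model = read_json(outdir / "igme" / "igme_model.json")
    populations = np.asarray(model["stationary"], dtype=float)
    micro_counts = np.bincount(micro_labels)
    micro_pops = micro_counts / micro_counts.sum()
    reports, state_frame_map = [], {}
    for state in range(len(populations)):
        frames = np.flatnonzero(macro_labels == state)
        if len(frames) == 0:
            continue
        state_frame_map[state] = frames
        rep = representative_structure(projection, micro_labels, frames, micro_pops)
        # references: nearest frame to each constituent microstate center
        refs = []
        for m in np.unique(micro_labels[frames]):
            mf = frames[micro_labels[frames] == m]
            pts = projection[mf]
            refs.append((len(mf), int(mf[np.argmin(
                np.linalg.norm(pts - pts.mean(axis=0), axis=1))])))
        refs.sort(reverse=True)
        ref_frames = [r for _, r in refs[: cfg["max_references"]]]
        try:
            report = state_report(
                ensemble, state, frames, ref_frames, rep,
                population=populations[state],
                interface_cutoff=cfg["interface_cutoff"],
                contact_cutoff=cfg["contact_cutoff"],
                probe_radius=cfg["probe_radius"],
                n_sphere_points=cfg["n_sphere_points"],
                max_bsa_frames=cfg["max_bsa_frames"],
                irmsd_aggregate=cfg["irmsd_aggregate"],
            )
        except ValueError as exc:
            logger.warning("state %d interface analysis degraded: %s", state, exc)
            from .interfaces import StateInterfaceReport

            report = StateInterfaceReport(
                state_id=state, representative_frame=rep,
                irmsd_mean=float("nan"), irmsd_sd=float("nan"),
                bsa_mean=float("nan"), bsa_sd=float("nan"),
                population=populations[state],
            )
        reports.append(report)
    verdicts = shortlist_states(
        reports,
        pop_min=cfg["pop_min"],
        irmsd_max=cfg["irmsd_max"],
        bsa_min=cfg["bsa_min"],
    )
    table = pd.DataFrame(
        [
            {
                "state": r.state_id,
                "population": r.population,
                "representative_frame": r.representative_frame,
                "irmsd_mean": r.irmsd_mean,
                "irmsd_sd": r.irmsd_sd,
                "bsa_mean": r.bsa_mean,
                "bsa_sd": r.bsa_sd,
                "shortlisted": verdicts[r.state_id]["pass"],
                "reasons": ";".join(verdicts[r.state_id]["reasons"]),
            }
            for r in reports
        ]
    )
    table.to_csv(sdir / "state_reports.csv", index=False)
    write_json(
        {str(k): {"pass": v["pass"], "reasons": v["reasons"]} for k, v in verdicts.items()},
        sdir / "shortlist.json",
    )
    np.save(sdir / "macro_labels.npy", macro_labels)


def _run_sites(config: dict, outdir: Path) -> None:
    cfg = config["sites"]
    sdir = outdir / "sites"
    ensemble = _load_ensemble(config, outdir)
    shortlist = read_json(_require(outdir / "interfaces" / "shortlist.json", "interfaces"))
    macro_labels = np.load(_require(outdir / "interfaces" / "macro_labels.npy", "interfaces"))
    candidates, anchor = sites_from_labels(ensemble)
    state_frames = {
        int(state): np.flatnonzero(macro_labels == int(state))
        for state, verdict in shortlist.items()
        if verdict["pass"]
    }
    matrix = viability_matrix(
        ensemble, state_frames, candidates, anchor,
        dist_max=cfg["dist_max"],
        sasa_min=cfg["sasa_min"],
        caveat_band=cfg["caveat_band"],
        probe_radius=config["interfaces"]["probe_radius"],
        n_sphere_points=config["interfaces"]["n_sphere_points"],
        max_sasa_frames=cfg["max_sasa_frames"],
    )
    matrix.to_csv(sdir / "viability_matrix.csv", index=False)


def _run_rank(config: dict, outdir: Path) -> None:
    cfg = config["rank"]
    sdir = outdir / "rank"
    energy_path = config["paths"]["energy_table"]
    if energy_path is None:
        energy_path = _require(outdir / "simulate" / "energy_table.csv", "simulate")
    energies = pd.read_csv(energy_path)
    summaries = bootstrap_energy(energies, n_boot=cfg["n_boot"], seed=config["seeds"]["rank"])
    summaries.to_csv(sdir / "energy_summaries.csv", index=False)
    report = classify_compounds(
        summaries, threshold=cfg["threshold"], tier_fraction=cfg["tier_fraction"]
    )
    report.to_csv(sdir / "ranking.csv", index=False)
    pose_path = config["paths"]["pose_table"]
    if pose_path is not None:
        poses = pd.read_csv(pose_path)
        select_poses(poses, n_keep=cfg["n_keep_poses"]).to_csv(
            sdir / "selected_poses.csv", index=False
        )


_RUNNERS = {
    "simulate": _run_simulate,
    "featurize": _run_featurize,
    "msm": _run_msm,
    "igme": _run_igme,
    "interfaces": _run_interfaces,
    "sites": _run_sites,
    "rank": _run_rank,
}
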