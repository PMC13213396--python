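"""Pipeline configuration: structured defaults, YAML loading, strict key checking."""

from __future__ import annotations

import copy
from pathlib import Path

import yaml

#: Stage defaults. Printed-threshold defaults follow the published workflow:
#: 2000 selected features, 4 CVs, 100 microstates, 6 macrostates, top 5% of
#: IGME models, 1%/5% population cuts, 10 A^2 exposure, 15 A linker reach,
#: -77 kcal/mol tier threshold, 200 snapshots, 5 poses, 10 bootstrap
#: iterations. Toy-scale knobs (frames, cluster counts) are sized for the
#: bundled synthetic fixture.
DEFAULT_CONFIG: dict = {
    "paths": {
        "outdir": "pipeline_out",
        "ensemble": None,       # set by the simulate stage or by the user
        "energy_table": None,
        "pose_table": None,
    },
    "seeds": {
        "simulate": 1,
        "oasis": 1,
        "cluster": 1,
        "rank": 1,
    },
    "simulate": {
        "n_frames": 6000,
        "jitter_good": 0.4,
        "jitter_hetero": 6.0,
        "stay_prob": 0.96,
        "energy_means": None,   # compounds x states nested list; default built-in
        "energy_sds": None,
        "energy_compounds": None,
        "energy_states": None,
        "energy_n_traj": 5,
    },
    "featurize": {
        "stride_chainB": 1,
        "n_select": 40,
        "tica_lag": 10,
        "n_cvs": 5,
    },
    "msm": {
        "n_microstates": 30,
        "lag": 5,
        "its_lags": [1, 2, 5, 10, 20],
    },
    "igme": {
        "n_macrostates": 6,
        "tau": 2,
        "K": 30,
        "n0_values": [1, 2, 3, 4, 5, 6, 7, 8],
        "L_values": [3, 4, 5, 6, 7],
        "top_fraction": 0.05,
    },
    "interfaces": {
        "interface_cutoff": 10.0,
        "contact_cutoff": 4.5,
        "probe_radius": 1.4,
        "n_sphere_points": 960,
        "pop_min": 0.05,
        "irmsd_max": 10.0,
        "bsa_min": None,        # default: 60% of median BSA across states
        "irmsd_aggregate": "min",
        "max_bsa_frames": 12,
        "max_references": 3,
    },
    "sites": {
        "dist_max": 15.0,
        "sasa_min": 10.0,
        "caveat_band": 0.10,
        "max_sasa_frames": 16,
    },
    "rank": {
        "n_snapshots": 200,
        "core_population_min": 0.01,
        "n_keep_poses": 5,
        "n_boot": 10,
        "threshold": -77.0,
        "tier_fraction": 0.5,
    },
}


def _merge(base: dict, override: dict, path: str = "") -> dict:
    out = copy.deepcopy(base)
    for key, value in override.items():
        here = f"{path}.{key}" if path else key
        if key not in base:
            raise KeyError(f"unknown configuration key: {here}")
        if isinstance(base[key], dict) and isinstance(value, dict):
            out[key] = _merge(base[key], value, here)
        else:
            out[key] = copy.deepcopy(value)
    return out


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    """Defaults, optionally merged with a YAML file and explicit overrides.

    Unknown keys raise; threshold sanity is enforced.
    """
    config = copy.deepcopy(DEFAULT_CONFIG)
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(loaded, dict):
            raise ValueError("configuration file must hold a mapping")
        config = _merge(config, loaded)
    if overrides:
        config = _merge(config, overrides)
    _validate(config)
    return config


def _validate(config: dict) -> None:
    positive = [
        ("featurize", "n_select"), ("featurize", "tica_lag"), ("featurize", "n_cvs"),
        ("msm", "n_microstates"), ("msm", "lag"),
        ("igme", "n_macrostates"), ("igme", "tau"), ("igme", "K"),
        ("interfaces", "interface_cutoff"), ("interfaces", "contact_cutoff"),
        ("interfaces", "probe_radius"), ("interfaces", "n_sphere_points"),
        ("sites", "dist_max"), ("sites", "sasa_min"),
        ("rank", "n_snapshots"), ("rank", "n_keep_poses"), ("rank", "n_boot"),
    ]
    for section, key in positive:
        value = config[section][key]
        if value is not None and value <= 0:
            raise ValueError(f"{section}.{key} must be positive, got {value}")
    for key, value in config["seeds"].items():
        if not isinstance(value, int):
            raise ValueError(f"seeds.{key} must be an integer")
    if not 0 < config["igme"]["top_fraction"] <= 1:
        raise ValueError("igme.top_fraction must be in (0, 1]")
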