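import logging

import numpy as np
import pandas as pd
import pytest

from encompass.ensemble import StructureEnsemble, make_atom_table
from encompass.synthetic import memory_chain_spec

logging.getLogger("encompass").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def memory_spec():
    """9->3 lumped chain with planted non-Markovian memory."""
    return memory_chain_spec()


@pytest.fixture
def two_bead_ensemble():
    """Minimal two-chain ensemble: one Ca bead per chain, 3 frames."""
    atoms = make_atom_table(
        [
            {"chain": "A", "residue_index": 0, "is_ca": True},
            {"chain": "B", "residue_index": 0, "is_ca": True},
        ]
    )
    coords = np.array(
        [
            [[0.0, 0.0, 0.0], [3.0, 4.0, 0.0]],
            [[0.0, 0.0, 0.0], [5.0, 0.0, 0.0]],
            [[1.0, 1.0, 1.0], [4.0, 5.0, 1.0]],
        ]
    )
    return StructureEnsemble(coords=coords, atoms=atoms)


def helix_ensemble(n_res_a=10, n_res_b=7, n_frames=1, spacing=8.0):
    """Two straight Ca chains, deterministic coordinates."""
    records, coords = [], []
    for i in range(n_res_a):
        records.append({"chain": "A", "residue_index": i, "is_ca": True})
        coords.append([0.0, 1.5 * i, 0.0])
    for i in range(n_res_b):
        records.append({"chain": "B", "residue_index": i, "is_ca": True})
        coords.append([spacing, 1.5 * i, 0.0])
    atoms = make_atom_table(records)
    xyz = np.tile(np.asarray(coords), (n_frames, 1, 1))
    return StructureEnsemble(coords=xyz, atoms=atoms)


@pytest.fixture
def straight_chains():
    return helix_ensemble()


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory):
    """One full pipeline run on the bundled synthetic fixture, shared per session."""
    from encompass.config import load_config
    from encompass.pipeline import run_pipeline

    outdir = tmp_path_factory.mktemp("pipeline")
    config = load_config(overrides={"paths": {"outdir": str(outdir)}})
    run_pipeline(config)
    return outdir, config
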