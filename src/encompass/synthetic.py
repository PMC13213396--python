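"""Synthetic inputs with known ground truth.

Three generators cover the pipeline's input surface:

* discrete trajectories from a hidden fine-grained Markov chain whose
  state-lumping plants controllable non-Markovian memory in the observed
  dynamics, plus the exact lag-indexed projected propagators as oracles;
* two-chain bead ensembles hopping between planted rigid interface
  geometries with Gaussian jitter;
* per-compound/per-state binding-energy tables with known cell means.

All generators are bit-reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ensemble import StructureEnsemble, make_atom_table
from .msm import DiscreteTrajectorySet, stationary_distribution


def _check_row_stochastic(matrix: np.ndarray, name: str, tol: float = 1e-12) -> np.ndarray:
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ValueError(f"{name} must be square")
    if np.any(matrix < 0):
        raise ValueError(f"{name} has negative entries")
    if not np.allclose(matrix.sum(axis=1), 1.0, atol=tol):
        raise ValueError(f"{name} rows must sum to 1 within {tol}")
    return matrix


@dataclass
class FineChainSpec:
    """Hidden fine Markov chain plus a surjective projection onto observed states."""

    n_fine: int
    M: np.ndarray
    projection: np.ndarray
    tau_frame: float = 1.0

    def __post_init__(self) -> None:
        self.M = _check_row_stochastic(self.M, "M")
        if self.M.shape[0] != self.n_fine:
            raise ValueError("M dimension must equal n_fine")
        self.projection = np.asarray(self.projection, dtype=int)
        if self.projection.shape != (self.n_fine,):
            raise ValueError("projection must map each fine state")
        if self.projection.min() < 0:
            raise ValueError("projection indices must be non-negative")
        n_obs = self.projection.max() + 1
        covered = np.unique(self.projection)
        if len(covered) != n_obs:
            missing = sorted(set(range(n_obs)) - set(covered))
            raise ValueError(f"projection does not cover observed indices {missing}")

    @property
    def n_obs(self) -> int:
        return int(self.projection.max() + 1)

    def stationary(self) -> np.ndarray:
        return stationary_distribution(self.M)

    def projected_stationary(self) -> np.ndarray:
        pi = self.stationary()
        out = np.zeros(self.n_obs)
        np.add.at(out, self.projection, pi)
        return out


@dataclass
class TPMSeries:
    """Lag-indexed transition matrices T(k*tau) for k = 1..K."""

    tau: int
    matrices: list[np.ndarray]
    frame_interval: float = 1.0
    counts: list[np.ndarray] | None = None

    def __post_init__(self) -> None:
        self.matrices = [np.asarray(m, dtype=float) for m in self.matrices]
        if not self.matrices:
            raise ValueError("series must contain at least one matrix")
        n = self.matrices[0].shape[0]
        for k, m in enumerate(self.matrices, start=1):
            if m.shape != (n, n):
                raise ValueError("inconsistent matrix dimensions in series")
            if not np.allclose(m.sum(axis=1), 1.0, atol=1e-10):
                raise ValueError(f"T({k}*tau) is not row-stochastic within 1e-10")

    @property
    def K(self) -> int:
        return len(self.matrices)

    @property
    def n_states(self) -> int:
        return self.matrices[0].shape[0]

    def matrix(self, k: int) -> np.ndarray:
        """T(k*tau), 1-based in k."""
        return self.matrices[k - 1]


def gen_fine_chain(
    spec: FineChainSpec, n_traj: int, n_frames: int, seed: int
) -> tuple[DiscreteTrajectorySet, DiscreteTrajectorySet]:
    """Sample hidden-chain trajectories and their projections.

    Hidden chains start from the exact stationary distribution of ``M``.
    Returns ``(observed, hidden)`` trajectory sets.
    """
    if n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    if n_traj < 1:
        raise ValueError("n_traj must be >= 1")
    rng = np.random.default_rng(seed)
    pi = spec.stationary()
    cum_m = np.cumsum(spec.M, axis=1)
    states = rng.choice(spec.n_fine, size=n_traj, p=pi)
    hidden = np.empty((n_traj, n_frames), dtype=int)
    hidden[:, 0] = states
    for t in range(1, n_frames):
        u = rng.random(n_traj)
        states = (cum_m[states] < u[:, None]).sum(axis=1)
        hidden[:, t] = states
    observed = spec.projection[hidden]
    hidden_set = DiscreteTrajectorySet(
        list(hidden), n_states=spec.n_fine, frame_interval=spec.tau_frame
    )
    observed_set = DiscreteTrajectorySet(
        list(observed), n_states=spec.n_obs, frame_interval=spec.tau_frame
    )
    return observed_set, hidden_set


def exact_projected_tpms(spec: FineChainSpec, max_lag_steps: int) -> TPMSeries:
    """Exact observed-state propagators of the lumped hidden chain.

    T_obs(k)[a, b] = sum_{i in a, j in b} pi_i (M^k)_{ij} / sum_{i in a} pi_i.
    """
    if max_lag_steps < 1:
        raise ValueError("max_lag_steps must be >= 1")
    pi = spec.stationary()
    proj = np.zeros((spec.n_fine, spec.n_obs))
    proj[np.arange(spec.n_fine), spec.projection] = 1.0
    pi_obs = proj.T @ pi
    matrices = []
    mk = np.eye(spec.n_fine)
    for _ in range(max_lag_steps):
        mk = mk @ spec.M
        t_obs = proj.T @ (pi[:, None] * mk) @ proj / pi_obs[:, None]
        t_obs = t_obs / t_obs.sum(axis=1, keepdims=True)  # tidy 1e-16 drift
        matrices.append(t_obs)
    return TPMSeries(tau=1, matrices=matrices, frame_interval=spec.tau_frame)


def memory_chain_spec() -> FineChainSpec:
    """Canonical 9->3 planted-memory fixture.

    Three observed blocks, each with a fast state, a slow state and a gateway
    state; blocks exchange cyclically through the gateways only. Lumping the
    blocks plants strong short-lived memory (max |T(2) - T(1)^2| ~ 0.086)
    while the full chain mixes fast (slowest implied timescale ~ 2.4 frames),
    and the projected stationary distribution is exactly uniform by symmetry.
    """
    fs, sf, fg, gf, sg, gs, ex = 0.13, 0.38, 0.60, 0.15, 0.11, 0.07, 0.55
    m = np.zeros((9, 9))
    for b in range(3):
        f, s, g = 3 * b, 3 * b + 1, 3 * b + 2
        f_next = 3 * ((b + 1) % 3)
        m[f, s], m[s, f] = fs, sf
        m[f, g], m[g, f] = fg, gf
        m[s, g], m[g, s] = sg, gs
        m[g, f_next] = ex
    np.fill_diagonal(m, 1.0 - m.sum(axis=1))
    return FineChainSpec(n_fine=9, M=m, projection=np.repeat(np.arange(3), 3))


@dataclass
class InterfaceEnsembleSpec:
    """Planted interface geometries for a toy two-chain complex.

    ``pose_transforms`` is a list of ``(R, t)`` pairs applied to chain B
    (rotation then translation); chain A stays fixed. ``jitter_sigma`` is a
    scalar or one value per geometry.
    """

    n_geometries: int
    pose_transforms: list[tuple[np.ndarray, np.ndarray]]
    jitter_sigma: float | np.ndarray
    hop_matrix: np.ndarray
    chain_templates: pd.DataFrame
    template_coords: np.ndarray = None

    def __post_init__(self) -> None:
        if len(self.pose_transforms) != self.n_geometries:
            raise ValueError("need one pose transform per geometry")
        checked = []
        for g, (rot, trans) in enumerate(self.pose_transforms):
            rot = np.asarray(rot, dtype=float)
            trans = np.asarray(trans, dtype=float)
            if rot.shape != (3, 3) or trans.shape != (3,):
                raise ValueError(f"transform {g} must be a 3x3 rotation and 3-vector")
            if not np.allclose(rot @ rot.T, np.eye(3), atol=1e-8):
                raise ValueError(f"rotation {g} is not orthonormal")
            if not np.isclose(np.linalg.det(rot), 1.0, atol=1e-8):
                raise ValueError(f"rotation {g} is not proper (det != +1)")
            checked.append((rot, trans))
        self.pose_transforms = checked
        sigma = np.asarray(self.jitter_sigma, dtype=float)
        if sigma.ndim == 0:
            sigma = np.full(self.n_geometries, float(sigma))
        if sigma.shape != (self.n_geometries,):
            raise ValueError("jitter_sigma must be scalar or one value per geometry")
        if np.any(sigma < 0):
            raise ValueError("jitter_sigma must be >= 0")
        self.jitter_sigma = sigma
        self.hop_matrix = _check_row_stochastic(self.hop_matrix, "hop_matrix")
        if self.hop_matrix.shape[0] != self.n_geometries:
            raise ValueError("hop_matrix dimension must equal n_geometries")
        if len(self.chain_templates) == 0:
            raise ValueError("chain template has no atoms")
        self.template_coords = np.asarray(self.template_coords, dtype=float)
        if self.template_coords.shape != (len(self.chain_templates), 3):
            raise ValueError("template_coords must be (n_atoms, 3)")
        lig_a = self.chain_templates.query("chain == 'A' and is_ligand")
        lig_b = self.chain_templates.query("chain == 'B' and is_ligand")
        if len(lig_a) and len(lig_b):
            anchors = self.chain_templates[
                self.chain_templates["site_label"] == "anchor"
            ]
            if len(anchors) != 1:
                raise ValueError("exactly one atom must carry the 'anchor' site label")
            sites = self.chain_templates[
                self.chain_templates["site_label"].str.startswith("Site").fillna(False)
            ]
            if len(sites) < 1:
                raise ValueError("at least one candidate 'Site*' label required")


def gen_interface_ensemble(
    spec: InterfaceEnsembleSpec, n_frames: int, seed: int
) -> tuple[StructureEnsemble, np.ndarray]:
    """Sample a jittered two-chain ensemble hopping between planted geometries.

    Returns the ensemble and the per-frame ground-truth geometry labels.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    rng = np.random.default_rng(seed)
    pi_geo = stationary_distribution(spec.hop_matrix)
    cum = np.cumsum(spec.hop_matrix, axis=1)
    labels = np.empty(n_frames, dtype=int)
    g = int(rng.choice(spec.n_geometries, p=pi_geo))
    labels[0] = g
    for t in range(1, n_frames):
        g = int(np.searchsorted(cum[g], rng.random()))
        labels[t] = g
    mask_b = (spec.chain_templates["chain"] == "B").to_numpy()
    base = spec.template_coords
    coords = np.empty((n_frames, len(base), 3))
    for t in range(n_frames):
        rot, trans = spec.pose_transforms[labels[t]]
        frame = base.copy()
        frame[mask_b] = frame[mask_b] @ rot.T + trans
        sigma = spec.jitter_sigma[labels[t]]
        if sigma > 0:
            frame = frame + rng.normal(0.0, sigma, size=frame.shape)
        coords[t] = frame
    ensemble = StructureEnsemble(coords=coords, atoms=spec.chain_templates.copy())
    return ensemble, labels


def geometry_coordinates(spec: InterfaceEnsembleSpec, geometry: int) -> np.ndarray:
    """Noise-free coordinates of one planted geometry (ground-truth oracle)."""
    rot, trans = spec.pose_transforms[geometry]
    mask_b = (spec.chain_templates["chain"] == "B").to_numpy()
    frame = spec.template_coords.copy()
    frame[mask_b] = frame[mask_b] @ rot.T + trans
    return frame


@dataclass
class EnergyTableSpec:
    """Known per-compound/state binding free-energy distribution parameters."""

    compounds: list[str]
    states: list[str]
    means: np.ndarray
    sds: np.ndarray
    n_traj: int = 5

    def __post_init__(self) -> None:
        shape = (len(self.compounds), len(self.states))
        self.means = np.asarray(self.means, dtype=float).reshape(shape)
        self.sds = np.asarray(self.sds, dtype=float).reshape(shape)
        if self.means.shape != shape or self.sds.shape != shape:
            raise ValueError(f"means/sds must have shape {shape}")
        if np.any(self.sds < 0):
            raise ValueError("standard deviations must be >= 0")
        if self.n_traj < 1:
            raise ValueError("n_traj must be >= 1")


def gen_energy_table(spec: EnergyTableSpec, seed: int) -> pd.DataFrame:
    """Gaussian per-trajectory binding-energy draws for every compound/state cell.

    Columns: ``compound, state, trajectory, dG_kcal_mol``.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for i, compound in enumerate(spec.compounds):
        for j, state in enumerate(spec.states):
            draws = rng.normal(spec.means[i, j], spec.sds[i, j], size=spec.n_traj)
            for t, dg in enumerate(draws):
                rows.append((compound, state, t, float(dg)))
    return pd.DataFrame(rows, columns=["compound", "state", "trajectory", "dG_kcal_mol"])


def planted_screen_spec(
    jitter_good: float = 0.4,
    jitter_hetero: float = 6.0,
    stay_prob: float = 0.96,
) -> tuple[InterfaceEnsembleSpec, dict]:
    """End-to-end fixture: 6 planted geometries with known design verdicts.

    Chain A is a coarse helix along y at the origin with a three-site ligand;
    chain B is a parallel helix carrying the anchor atom. Geometries rotate
    chain B about chain A's long axis:

    * geometries 0-3 (0/90/180/270 degrees): bound, low jitter -> design-ready
    * geometry 4 (45 degrees, large jitter): kinetically one state but
      structurally heterogeneous -> fails the interface-RMSD criterion
    * geometry 5 (135 degrees, pushed radially outward): no burial decoy

    Planted site truth, identical across the four good states by design:
    Site1 exposed and within linker reach (viable); Site2 displaced along the
    helix axis beyond reach (too_far); Site3 caged by unlabeled ligand beads
    (occluded). Returns the spec and a ground-truth dict.
    """
    classes = ["charged", "polar", "hydrophobic"]
    rec_a, xyz_a = _helix_chain("A", 12, np.zeros(3), np.array([0.0, 1.0, 0.0]), classes)
    rec_b, xyz_b = _helix_chain(
        "B", 12, np.array([9.0, 0.0, 0.0]), np.array([0.0, 1.0, 0.0]), classes
    )
    lig_a = [
        {"chain": "A", "residue_index": 900, "atom_name": "L1", "element": "C",
         "is_ligand": True, "site_label": "Site1", "residue_class": "hydrophobic"},
        {"chain": "A", "residue_index": 900, "atom_name": "L2", "element": "N",
         "is_ligand": True, "site_label": "Site2", "residue_class": "polar"},
        {"chain": "A", "residue_index": 900, "atom_name": "L3", "element": "O",
         "is_ligand": True, "site_label": "Site3", "residue_class": "polar"},
    ]
    lig_a_xyz = np.array([
        [4.0, 8.0, 5.0],    # Site1: sticks out above the seam -> exposed
        [4.0, -9.0, 0.0],   # Site2: far end of the helix axis -> too far
        [-5.0, 14.0, 0.0],  # Site3: back side, caged -> occluded
    ])
    # occluding cage around Site3 (unlabeled ligand beads)
    cage_center = lig_a_xyz[2]
    cage_dirs = []
    for dx in (-1, 1):
        for dy in (-1, 1):
            for dz in (-1, 1):
                cage_dirs.append([dx, dy, dz])
    cage_dirs += [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]]
    cage_dirs = np.asarray(cage_dirs, float)
    cage_dirs /= np.linalg.norm(cage_dirs, axis=1, keepdims=True)
    cage_xyz = cage_center + 2.6 * cage_dirs
    cage = [
        {"chain": "A", "residue_index": 900, "atom_name": f"X{i}", "element": "C",
         "is_ligand": True, "residue_class": "hydrophobic"}
        for i in range(len(cage_xyz))
    ]
    lig_b = [
        {"chain": "B", "residue_index": 901, "atom_name": "LC", "element": "C",
         "is_ligand": True, "site_label": "anchor", "residue_class": "hydrophobic"},
    ]
    lig_b_xyz = np.array([[6.0, 8.0, 0.0]])
    atoms = make_atom_table(rec_a + rec_b + lig_a + cage + lig_b)
    template = np.vstack([xyz_a, xyz_b, lig_a_xyz, cage_xyz, lig_b_xyz])
    axis_y = np.array([0.0, 1.0, 0.0])
    angles = np.deg2rad([0.0, 90.0, 180.0, 270.0, 45.0, 135.0])
    transforms = []
    for g, theta in enumerate(angles):
        rot = rotation_about_axis(axis_y, theta)
        trans = np.zeros(3)
        if g == 5:  # decoy: push chain B radially outward, away from chain A
            outward = rot @ np.array([1.0, 0.0, 0.0])
            trans = 9.0 * outward
        transforms.append((rot, trans))
    jitter = np.array([jitter_good] * 4 + [jitter_hetero, jitter_good])
    n_geo = 6
    hop = np.full((n_geo, n_geo), (1 - stay_prob) / (n_geo - 1))
    np.fill_diagonal(hop, stay_prob)
    spec = InterfaceEnsembleSpec(
        n_geometries=n_geo,
        pose_transforms=transforms,
        jitter_sigma=jitter,
        hop_matrix=hop,
        chain_templates=atoms,
        template_coords=template,
    )
    truth = {
        "good_geometries": [0, 1, 2, 3],
        "heterogeneous_geometry": 4,
        "decoy_geometry": 5,
        "site_verdicts": {"Site1": "viable", "Site2": "too_far", "Site3": "occluded"},
    }
    return spec, truth


def rotation_about_axis(axis: np.ndarray, angle: float) -> np.ndarray:
    """Proper rotation matrix about an arbitrary axis (Rodrigues)."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    k = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + np.sin(angle) * k + (1 - np.cos(angle)) * (k @ k)


def _helix_chain(
    chain: str,
    n_residues: int,
    start: np.ndarray,
    direction: np.ndarray,
    classes: list[str],
) -> tuple[list[dict], np.ndarray]:
    direction = np.asarray(direction, float)
    direction = direction / np.linalg.norm(direction)
    # orthonormal frame for a coarse helix
    ref = np.array([0.0, 0.0, 1.0])
    if abs(direction @ ref) > 0.9:
        ref = np.array([1.0, 0.0, 0.0])
    u = np.cross(direction, ref)
    u /= np.linalg.norm(u)
    v = np.cross(direction, u)
    records, coords = [], []
    for i in range(n_residues):
        angle = 2 * np.pi * i / 3.6
        pos = start + 1.5 * i * direction + 2.3 * (np.cos(angle) * u + np.sin(angle) * v)
        records.append(
            {
                "chain": chain,
                "residue_index": i,
                "residue_class": classes[i % len(classes)],
                "atom_name": "CA",
                "element": "C",
                "is_ca": True,
            }
        )
        coords.append(pos)
    return records, np.asarray(coords)


def default_two_chain_spec(
    n_geometries: int = 2,
    jitter_sigma: float | np.ndarray = 0.3,
    hop_matrix: np.ndarray | None = None,
    n_res_a: int = 12,
    n_res_b: int = 12,
    separations: np.ndarray | None = None,
    with_ligands: bool = True,
) -> InterfaceEnsembleSpec:
    """A ready-made toy spec: two coarse helical chains plus optional ligands.

    Geometry ``g`` places chain B at a distinct rotation/translation; by
    default geometries are spaced along x so their centroids are well
    separated. Chain A's ligand carries labeled candidate sites Site1..Site3;
    chain B's ligand carries the anchor atom.
    """
    classes = ["charged", "polar", "hydrophobic"]
    rec_a, xyz_a = _helix_chain("A", n_res_a, np.zeros(3), np.array([0.0, 1.0, 0.0]), classes)
    rec_b, xyz_b = _helix_chain(
        "B", n_res_b, np.array([9.0, 0.0, 0.0]), np.array([0.0, 1.0, 0.0]), classes
    )
    records = rec_a + rec_b
    coords = [xyz_a, xyz_b]
    if with_ligands:
        lig_a_origin = xyz_a.mean(axis=0) + np.array([3.5, 0.0, 0.0])
        lig_a = [
            {"chain": "A", "residue_index": 900, "atom_name": "L1", "element": "C",
             "is_ligand": True, "site_label": "Site1", "residue_class": "hydrophobic"},
            {"chain": "A", "residue_index": 900, "atom_name": "L2", "element": "N",
             "is_ligand": True, "site_label": "Site2", "residue_class": "polar"},
            {"chain": "A", "residue_index": 900, "atom_name": "L3", "element": "O",
             "is_ligand": True, "site_label": "Site3", "residue_class": "polar"},
        ]
        lig_a_xyz = lig_a_origin + np.array(
            [[0.0, 0.0, 0.0], [0.0, 2.5, 0.0], [0.0, -2.5, 0.0]]
        )
        lig_b_origin = xyz_b.mean(axis=0) - np.array([3.5, 0.0, 0.0])
        lig_b = [
            {"chain": "B", "residue_index": 901, "atom_name": "LC", "element": "C",
             "is_ligand": True, "site_label": "anchor", "residue_class": "hydrophobic"},
        ]
        lig_b_xyz = lig_b_origin[None, :]
        records += lig_a + lig_b
        coords += [lig_a_xyz, lig_b_xyz]
    atoms = make_atom_table(records)
    template = np.vstack(coords)
    if separations is None:
        separations = 30.0 * np.arange(n_geometries)
    transforms = []
    for g in range(n_geometries):
        rot = rotation_about_axis(np.array([0.0, 0.0, 1.0]), 0.15 * g)
        trans = np.array([float(separations[g]), 0.0, 0.0])
        transforms.append((rot, trans))
    if hop_matrix is None:
        stay = 0.98
        hop_matrix = np.full((n_geometries, n_geometries),
                             (1 - stay) / max(n_geometries - 1, 1))
        np.fill_diagonal(hop_matrix, stay if n_geometries > 1 else 1.0)
    return InterfaceEnsembleSpec(
        n_geometries=n_geometries,
        pose_transforms=transforms,
        jitter_sigma=jitter_sigma,
        hop_matrix=np.asarray(hop_matrix, float),
        chain_templates=atoms,
        template_coords=template,
    )
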