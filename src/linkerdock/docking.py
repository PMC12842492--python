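"""Stochastic flexible-ligand, rigid-receptor pose search.

Blind whole-surface docking by default: the search box is the receptor
bounding box plus a margin, the ligand is free to translate, rotate and
rotate its torsions.  The search is iterated Monte Carlo — random
rigid-body + torsion perturbations with Metropolis acceptance — followed by
derivative-free local optimisation of the best accepted state, repeated over
independent restarts (the analog of a docking tool's "exhaustiveness").

Determinism contract: restart r uses seed = config.seed + r, so serial and
parallel execution agree and identical configs give bitwise-identical poses.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from .scoring import ReceptorGrid, ScoreBreakdown, ScoringWeights, score_pose
from .structures import Atom, Ligand, ProteinModel

#: ligand atoms may protrude at most this far beyond the box faces
_PROTRUSION = 2.0


@dataclass(frozen=True)
class SearchBox:
    center: np.ndarray
    dims: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float))
        object.__setattr__(self, "dims", np.asarray(self.dims, dtype=float))
        if np.any(self.dims <= 0):
            raise ValueError("box dims must be positive")

    @property
    def lo(self) -> np.ndarray:
        return self.center - self.dims / 2

    @property
    def hi(self) -> np.ndarray:
        return self.center + self.dims / 2


@dataclass(frozen=True)
class DockingConfig:
    n_runs: int = 8
    n_steps: int = 250
    temperature_like: float = 1.2  # kcal/mol acceptance scale
    seed: int = 0
    max_poses: int = 8
    clash_floor: float = 2.0  # Å, minimum receptor–ligand heavy-atom distance
    opt_budget: int = 400  # local-optimisation evaluations per restart

    def __post_init__(self):
        if min(self.n_runs, self.n_steps, self.max_poses, self.opt_budget) < 1:
            raise ValueError("n_runs, n_steps, max_poses, opt_budget must be positive")
        if self.temperature_like <= 0 or self.clash_floor <= 0:
            raise ValueError("temperature_like and clash_floor must be positive")


@dataclass
class Pose:
    """A placed ligand: rigid placement + torsion angles + its score.

    ``translation`` is the centroid of the placed ligand; ``orientation``
    is a unit quaternion (x, y, z, w); ``torsion_angles`` are degrees of
    rotation about each rotatable bond relative to the reference
    conformation.
    """

    ligand_ref: Ligand
    translation: np.ndarray
    orientation: np.ndarray
    torsion_angles: np.ndarray
    delta_g: float = 0.0
    breakdown: ScoreBreakdown | None = None

    def __post_init__(self):
        self.translation = np.asarray(self.translation, dtype=float)
        q = np.asarray(self.orientation, dtype=float)
        norm = np.linalg.norm(q)
        if norm == 0:
            raise ValueError("zero quaternion")
        self.orientation = q / norm
        self.torsion_angles = np.asarray(self.torsion_angles, dtype=float)

    def coords(self) -> np.ndarray:
        return _place_coords(self.ligand_ref, self.translation, self.orientation,
                             self.torsion_angles)

    def placed_ligand(self, ligand_id: str | None = None) -> Ligand:
        lig = self.ligand_ref.copy(ligand_id=ligand_id)
        lig.set_coords(self.coords())
        return lig


def _torsion_partitions(lig: Ligand) -> list[np.ndarray]:
    """For each rotatable torsion (a,b,c,d): indices of atoms that move when
    rotating about the b–c bond (the component containing c)."""
    g = lig.bond_graph()
    parts = []
    for (_, b, c, _) in lig.rotatable_torsions:
        h = g.copy()
        h.remove_edge(b, c)
        moving = nx.node_connected_component(h, c) - {c}
        parts.append(np.array(sorted(moving), dtype=int))
    return parts


def _apply_torsions(lig: Ligand, angles_deg: np.ndarray,
                    partitions: list[np.ndarray] | None = None) -> np.ndarray:
    coords = lig.coords()
    if len(angles_deg) != lig.n_rot:
        raise ValueError("torsion angle count mismatch")
    if partitions is None:
        partitions = _torsion_partitions(lig)
    for (_, b, c, _), angle, moving in zip(lig.rotatable_torsions, angles_deg, partitions):
        if len(moving) == 0 or angle == 0.0:
            continue
        axis = coords[c] - coords[b]
        axis = axis / np.linalg.norm(axis)
        rot = Rotation.from_rotvec(np.radians(angle) * axis)
        coords[moving] = rot.apply(coords[moving] - coords[c]) + coords[c]
    return coords


def _place_coords(lig: Ligand, translation: np.ndarray, quat: np.ndarray,
                  torsions: np.ndarray, partitions: list[np.ndarray] | None = None) -> np.ndarray:
    coords = _apply_torsions(lig, torsions, partitions)
    centroid = coords.mean(axis=0)
    rot = Rotation.from_quat(quat)
    return rot.apply(coords - centroid) + np.asarray(translation, dtype=float)


def default_box(model: ProteinModel, margin: float = 6.0) -> SearchBox:
    """Axis-aligned bounding box of all atoms, expanded by ``margin`` per side."""
    coords = model.coords()
    if len(coords) == 0:
        raise ValueError("empty model")
    lo = coords.min(axis=0) - margin
    hi = coords.max(axis=0) + margin
    return SearchBox(center=(lo + hi) / 2, dims=hi - lo)


def _containment_violation(coords: np.ndarray, box: SearchBox) -> float:
    """0 when the centroid is in the box and no atom protrudes more than the
    allowance; otherwise the total violation depth in Å."""
    centroid = coords.mean(axis=0)
    v = np.maximum(box.lo - centroid, 0).sum() + np.maximum(centroid - box.hi, 0).sum()
    v += np.maximum(box.lo - _PROTRUSION - coords, 0).sum()
    v += np.maximum(coords - (box.hi + _PROTRUSION), 0).sum()
    return float(v)


class _Objective:
    """Penalised scoring objective over the pose parameter vector
    [translation(3), rotation-vector delta(3), torsions(k)]."""

    def __init__(self, grid: ReceptorGrid, lig: Ligand, box: SearchBox,
                 clash_floor: float, partitions: list[np.ndarray]):
        self.grid = grid
        self.lig = lig
        self.box = box
        self.clash_floor = clash_floor
        self.partitions = partitions
        (self.radii, self.hyd, self.don, self.acc) = grid.ligand_arrays(lig)
        self.n_rot = lig.n_rot

    def coords_for(self, translation, quat, torsions) -> np.ndarray:
        return _place_coords(self.lig, translation, quat, torsions, self.partitions)

    def penalised(self, coords: np.ndarray) -> float:
        penalty = 0.0
        v = _containment_violation(coords, self.box)
        if v > 0:
            penalty += 10.0 + 1000.0 * v
        mind = self.grid.min_distance(coords)
        if mind < self.clash_floor:
            penalty += 10.0 + 1000.0 * (self.clash_floor - mind)
        dg = self.grid.breakdown(coords, self.radii, self.hyd, self.don, self.acc,
                                 self.n_rot).delta_g
        return dg + penalty

    def vector(self, x: np.ndarray, base_quat: np.ndarray) -> float:
        t = x[:3]
        quat = (Rotation.from_rotvec(x[3:6]) * Rotation.from_quat(base_quat)).as_quat()
        torsions = x[6:]
        return self.penalised(self.coords_for(t, quat, torsions))


def _random_quat(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    return q / np.linalg.norm(q)


def _mc_run(obj: _Objective, box: SearchBox, config: DockingConfig,
            rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    t = rng.uniform(box.lo, box.hi)
    q = _random_quat(rng)
    tor = rng.uniform(-180.0, 180.0, obj.n_rot)
    e = obj.penalised(obj.coords_for(t, q, tor))
    best = (t.copy(), q.copy(), tor.copy(), e)
    for _ in range(config.n_steps):
        t_new = t + rng.normal(0.0, 0.75, 3)
        dq = Rotation.from_rotvec(rng.normal(0.0, 0.25, 3))
        q_new = (dq * Rotation.from_quat(q)).as_quat()
        tor_new = tor + rng.normal(0.0, 30.0, obj.n_rot) if obj.n_rot else tor
        e_new = obj.penalised(obj.coords_for(t_new, q_new, tor_new))
        if e_new <= e or rng.random() < np.exp(-(e_new - e) / config.temperature_like):
            t, q, tor, e = t_new, q_new, tor_new, e_new
            if e < best[3]:
                best = (t.copy(), q.copy(), tor.copy(), e)
    return best


def local_optimize(pose: Pose, receptor_atoms: list[Atom],
                   weights: ScoringWeights | None = None,
                   budget: int = 400,
                   box: SearchBox | None = None,
                   clash_floor: float = 2.0) -> Pose:
    """Derivative-free local refinement; never returns a worse pose and
    terminates within ``budget`` objective evaluations."""
    weights = weights or ScoringWeights()
    grid = ReceptorGrid(receptor_atoms, weights)
    lig = pose.ligand_ref
    partitions = _torsion_partitions(lig)
    if box is None:
        # an effectively unbounded box centred on the pose
        box = SearchBox(center=pose.translation, dims=np.full(3, 1e6))
    obj = _Objective(grid, lig, box, clash_floor, partitions)

    x0 = np.concatenate([pose.translation, np.zeros(3), pose.torsion_angles])
    base_quat = pose.orientation
    e0 = obj.vector(x0, base_quat)
    res = minimize(lambda x: obj.vector(x, base_quat), x0, method="Nelder-Mead",
                   options={"maxfev": budget, "xatol": 1e-5, "fatol": 1e-10})
    if res.fun < e0:
        t = res.x[:3]
        quat = (Rotation.from_rotvec(res.x[3:6]) * Rotation.from_quat(base_quat)).as_quat()
        tor = res.x[6:]
    else:
        t, quat, tor = pose.translation, base_quat, pose.torsion_angles
    out = Pose(ligand_ref=lig, translation=np.array(t), orientation=np.array(quat),
               torsion_angles=np.array(tor))
    _finalise(out, receptor_atoms, weights)
    return out


def _finalise(pose: Pose, receptor_atoms: list[Atom], weights: ScoringWeights) -> None:
    """Recompute the pose score from scratch so delta_g can never be stale."""
    placed = pose.placed_ligand()
    bd = score_pose(receptor_atoms, placed, weights)
    pose.breakdown = bd
    pose.delta_g = bd.delta_g


def dock(receptor_atoms: list[Atom], ligand: Ligand, box: SearchBox,
         weights: ScoringWeights | None = None,
         config: DockingConfig | None = None) -> list[Pose]:
    """Search for favourable poses; returns up to ``max_poses`` poses sorted
    best-first, each clash-free, contained in the box and locally optimised."""
    weights = weights or ScoringWeights()
    config = config or DockingConfig()
    lig_radius = 0.0
    if len(ligand.atoms) > 1:
        c = ligand.coords()
        lig_radius = float(np.linalg.norm(c - c.mean(axis=0), axis=1).max())
    if lig_radius > min(box.dims) / 2 + _PROTRUSION:
        raise ValueError("box too small to contain the ligand")

    grid = ReceptorGrid(receptor_atoms, weights)
    partitions = _torsion_partitions(ligand)
    obj = _Objective(grid, ligand, box, config.clash_floor, partitions)

    poses: list[Pose] = []
    for r in range(config.n_runs):
        rng = np.random.default_rng(config.seed + r)
        t, q, tor, _ = _mc_run(obj, box, config, rng)
        pose = Pose(ligand_ref=ligand, translation=t, orientation=q, torsion_angles=tor)
        pose = local_optimize(pose, receptor_atoms, weights, budget=config.opt_budget,
                              box=box, clash_floor=config.clash_floor)
        coords = pose.coords()
        if grid.min_distance(coords) < config.clash_floor or _containment_violation(coords, box) > 0:
            continue  # restart ended in a penalised state; drop it
        poses.append(pose)
    poses.sort(key=lambda p: (round(p.delta_g, 6), p.translation[0], p.translation[1],
                              p.translation[2]))
    return poses[: config.max_poses]
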