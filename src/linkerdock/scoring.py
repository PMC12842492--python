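"""Empirical pairwise scoring of protein–ligand poses.

The score maps a pose to a predicted binding free energy ΔG (kcal/mol)
using the Vina-style functional form: per-pair steric terms on the
surface distance s = d − r_i − r_j,

    gauss1     = exp(−(s / 0.5)²)
    gauss2     = exp(−((s − 3) / 2)²)
    repulsion  = s²            for s < 0, else 0

plus class-gated linear ramps for hydrophobic contacts (both atoms
hydrophobic: 1 for s < 0.5, 0 for s > 1.5) and polar hydrogen bonds
(donor/acceptor pairing: 1 for s < −0.7, 0 for s > 0).  The weighted
intermolecular sum is then attenuated by the rotatable-bond count:

    ΔG = c_inter / (1 + w_rot · n_rot)

so a more negative ΔG means stronger binding, on the ≈ −4 to −7 kcal/mol
scale familiar from empirical docking scores of sugar-sized ligands.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import yaml

from .structures import (
    ACCEPTOR_CLASSES,
    DONOR_CLASSES,
    HYDROPHOBIC,
    Atom,
    Ligand,
)

#: fixed van der Waals radius table, Å (versioned with the package)
VDW_RADII: dict[str, float] = {
    "C": 1.9, "N": 1.8, "O": 1.7, "S": 2.0, "P": 2.1,
    "H": 1.0, "F": 1.5, "CL": 1.8, "BR": 2.0, "I": 2.2,
    "ZN": 1.2, "MG": 1.2, "MN": 1.2, "FE": 1.2, "CU": 1.2, "NI": 1.2,
    "CO": 1.2, "NA": 1.2, "K": 1.2,
}
_DEFAULT_RADIUS = 1.8


@dataclass(frozen=True)
class ScoringWeights:
    """Term weights; defaults are the published values of the empirical
    scorer whose ΔG scale the pipeline reports."""

    w_gauss1: float = -0.035579
    w_gauss2: float = -0.005156
    w_repulsion: float = 0.840245
    w_hydrophobic: float = -0.035069
    w_hbond: float = -0.587439
    w_rot: float = 0.05846
    cutoff: float = 8.0

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh)

    @classmethod
    def from_yaml(cls, path) -> "ScoringWeights":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


@dataclass
class ScoreBreakdown:
    """Per-term unweighted sums plus the weighted total and final ΔG."""

    gauss1: float
    gauss2: float
    repulsion: float
    hydrophobic: float
    hbond: float
    c_inter: float
    delta_g: float

    def to_dict(self) -> dict[str, float]:
        return asdict(self)


def surface_distance(d: float, r_i: float, r_j: float) -> float:
    """Distance between atomic surfaces: d − r_i − r_j (may be negative)."""
    return d - r_i - r_j


def vdw_radius(element: str) -> float:
    return VDW_RADII.get(element.upper(), _DEFAULT_RADIUS)


def _ramp(s: np.ndarray, good: float, bad: float) -> np.ndarray:
    """Linear ramp: 1 where s <= good, 0 where s >= bad."""
    return np.clip((bad - s) / (bad - good), 0.0, 1.0)


def _check_assigned(atoms, label: str) -> None:
    for a in atoms:
        if a.interaction_class is None:
            raise ValueError(f"{label}: atom {a.serial} ({a.name}) has no interaction class; "
                             "run assign_interaction_classes first")


class ReceptorGrid:
    """Receptor-side arrays precomputed once so pose search can re-score a
    moving ligand cheaply."""

    def __init__(self, receptor_atoms: list[Atom], weights: ScoringWeights):
        _check_assigned(receptor_atoms, "receptor")
        self.weights = weights
        self.n = len(receptor_atoms)
        self.coords = np.array([a.coords for a in receptor_atoms], dtype=float).reshape(self.n, 3)
        self.radii = np.array([vdw_radius(a.element) for a in receptor_atoms])
        classes = [a.interaction_class for a in receptor_atoms]
        self.is_hydrophobic = np.array([c == HYDROPHOBIC for c in classes])
        self.is_donor = np.array([c in DONOR_CLASSES for c in classes])
        self.is_acceptor = np.array([c in ACCEPTOR_CLASSES for c in classes])

    def ligand_arrays(self, ligand: Ligand):
        _check_assigned(ligand.atoms, ligand.ligand_id)
        radii = np.array([vdw_radius(a.element) for a in ligand.atoms])
        classes = [a.interaction_class for a in ligand.atoms]
        return (
            radii,
            np.array([c == HYDROPHOBIC for c in classes]),
            np.array([c in DONOR_CLASSES for c in classes]),
            np.array([c in ACCEPTOR_CLASSES for c in classes]),
        )

    def breakdown(self, lig_coords: np.ndarray, lig_radii: np.ndarray,
                  lig_hyd: np.ndarray, lig_don: np.ndarray, lig_acc: np.ndarray,
                  n_rot: int) -> ScoreBreakdown:
        w = self.weights
        if self.n == 0 or len(lig_coords) == 0:
            return ScoreBreakdown(0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0)
        diff = self.coords[:, None, :] - lig_coords[None, :, :]
        d = np.sqrt((diff * diff).sum(axis=-1))
        s = d - self.radii[:, None] - lig_radii[None, :]
        within = s <= w.cutoff
        s = np.where(within, s, np.inf)

        gauss1 = np.where(within, np.exp(-((s / 0.5) ** 2)), 0.0).sum()
        gauss2 = np.where(within, np.exp(-(((s - 3.0) / 2.0) ** 2)), 0.0).sum()
        rep = np.where(within & (s < 0), s * s, 0.0).sum()

        hyd_pair = self.is_hydrophobic[:, None] & lig_hyd[None, :] & within
        hydro = np.where(hyd_pair, _ramp(s, 0.5, 1.5), 0.0).sum()

        hb_pair = ((self.is_donor[:, None] & lig_acc[None, :])
                   | (self.is_acceptor[:, None] & lig_don[None, :])) & within
        hbond = np.where(hb_pair, _ramp(s, -0.7, 0.0), 0.0).sum()

        c_inter = (w.w_gauss1 * gauss1 + w.w_gauss2 * gauss2 + w.w_repulsion * rep
                   + w.w_hydrophobic * hydro + w.w_hbond * hbond)
        delta_g = c_inter / (1.0 + w.w_rot * n_rot)
        return ScoreBreakdown(float(gauss1), float(gauss2), float(rep),
                              float(hydro), float(hbond), float(c_inter), float(delta_g))

    def min_distance(self, lig_coords: np.ndarray) -> float:
        if self.n == 0 or len(lig_coords) == 0:
            return np.inf
        diff = self.coords[:, None, :] - lig_coords[None, :, :]
        return float(np.sqrt((diff * diff).sum(axis=-1)).min())


def score_pose(receptor_atoms: list[Atom], ligand: Ligand,
               weights: ScoringWeights | None = None) -> ScoreBreakdown:
    """Score a placed ligand against a rigid receptor.

    Sums the pair terms over every receptor–ligand heavy-atom pair within
    the surface-distance cutoff, then applies the rotatable-bond
    attenuation of the ligand (receptor atoms — including previously placed
    ligand copies — contribute no torsion penalty).
    """
    weights = weights or ScoringWeights()
    grid = ReceptorGrid(receptor_atoms, weights)
    radii, hyd, don, acc = grid.ligand_arrays(ligand)
    return grid.breakdown(ligand.coords(), radii, hyd, don, acc, ligand.n_rot)


def score_pair_profile(class_i: str, class_j: str, s: float,
                       weights: ScoringWeights | None = None) -> float:
    """Weighted kcal/mol contribution of a single atom pair at surface
    distance s; consistent with :func:`score_pose` on a 2-atom system
    (with n_rot = 0)."""
    w = weights or ScoringWeights()
    if s > w.cutoff:
        return 0.0
    total = w.w_gauss1 * np.exp(-((s / 0.5) ** 2))
    total += w.w_gauss2 * np.exp(-(((s - 3.0) / 2.0) ** 2))
    if s < 0:
        total += w.w_repulsion * s * s
    if class_i == HYDROPHOBIC and class_j == HYDROPHOBIC:
        total += w.w_hydrophobic * float(_ramp(np.array(s), 0.5, 1.5))
    donor_acceptor = ((class_i in DONOR_CLASSES and class_j in ACCEPTOR_CLASSES)
                      or (class_j in DONOR_CLASSES and class_i in ACCEPTOR_CLASSES))
    if donor_acceptor:
        total += w.w_hbond * float(_ramp(np.array(s), -0.7, 0.0))
    return float(total)
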