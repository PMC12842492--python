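"""Sequential multi-ligand docking protocol.

Round k docks a fresh ligand copy against the protein plus the ligands
placed in rounds < k; the best-scoring (most negative ΔG) pose is frozen
into the receptor for the next round.  Ten rounds by default, emulating a
gradually rising ligand concentration.  Previously placed copies are scored
exactly like receptor atoms and contribute no rotatable-bond penalty.

Also implements the retained-subset control: strip chosen rounds from a
finished complex, keep the rest, and rerun a full fresh protocol against
that partially occupied receptor.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .docking import DockingConfig, Pose, default_box, dock
from .scoring import ScoringWeights
from .structures import Complex, Ligand, ProteinModel, assign_interaction_classes


@dataclass(frozen=True)
class ProtocolConfig:
    n_rounds: int = 10
    docking: DockingConfig = field(default_factory=DockingConfig)
    weights: ScoringWeights = field(default_factory=ScoringWeights)

    def __post_init__(self):
        if self.n_rounds < 1:
            raise ValueError("n_rounds must be >= 1")


@dataclass
class RoundRecord:
    round_index: int  # 1-based
    ligand_species: str
    pose: Pose
    delta_g: float
    region_label: object | None = None  # filled later by sitestats


@dataclass
class SequentialRun:
    model_id: str
    time_label_ns: float
    ligand_species: str
    rounds: list[RoundRecord]
    final_complex: Complex
    retained_rounds: tuple[int, ...] = ()


def _round_seed(base_seed: int, round_index: int) -> int:
    return base_seed + 1000 * round_index


def run_sequential(model: ProteinModel, ligand: Ligand,
                   config: ProtocolConfig | None = None,
                   _preplaced: list[Ligand] | None = None,
                   _retained_rounds: tuple[int, ...] = ()) -> SequentialRun:
    """Run the full sequential protocol for one (conformer, ligand species)
    pair.  The docking box is derived once from the bare protein and reused
    in every round."""
    config = config or ProtocolConfig()
    assign_interaction_classes(model)
    assign_interaction_classes(ligand)
    protein_atoms = model.atom_list()
    box = default_box(model)

    placed: list[Ligand] = [lig.copy() for lig in (_preplaced or [])]
    for lig in placed:
        assign_interaction_classes(lig)
    receptor_atoms = protein_atoms + [a for lig in placed for a in lig.atoms]
    n_preplaced = len(placed)

    rounds: list[RoundRecord] = []
    for k in range(1, config.n_rounds + 1):
        dock_cfg = replace(config.docking, seed=_round_seed(config.docking.seed, k))
        poses = dock(receptor_atoms, ligand, box, config.weights, dock_cfg)
        if not poses:
            raise RuntimeError(f"docking failed in round {k}: no clash-free pose found")
        best = poses[0]
        copy_id = f"{ligand.species}_{k}"
        placed_copy = best.placed_ligand(ligand_id=copy_id)
        for prev in placed:
            sep = float(np.linalg.norm(prev.centroid() - placed_copy.centroid()))
            if sep <= 1.5:
                raise RuntimeError(f"round {k}: ligand copy overlaps {prev.ligand_id} "
                                   f"(centroid separation {sep:.2f} Å)")
        placed.append(placed_copy)
        receptor_atoms = receptor_atoms + list(placed_copy.atoms)
        rounds.append(RoundRecord(round_index=k, ligand_species=ligand.species,
                                  pose=best, delta_g=best.delta_g))

    final = Complex(protein=model, ligands=placed)
    assert len(final.ligands) == config.n_rounds + n_preplaced
    return SequentialRun(model_id=model.model_id, time_label_ns=model.time_label_ns,
                         ligand_species=ligand.species, rounds=rounds,
                         final_complex=final, retained_rounds=_retained_rounds)


def rerun_with_retained_subset(run: SequentialRun, keep_round_indices: set[int],
                               config: ProtocolConfig | None = None,
                               ligand: Ligand | None = None) -> SequentialRun:
    """Keep only the chosen rounds' ligand copies on the protein and run a
    fresh full protocol against that receptor.

    With an empty keep-set and the same seed this is bitwise identical to
    :func:`run_sequential` from scratch.
    """
    if not run.rounds:
        raise ValueError("cannot rerun an empty SequentialRun")
    valid = {rec.round_index for rec in run.rounds}
    bad = set(keep_round_indices) - valid
    if bad:
        raise ValueError(f"keep indices not present in run: {sorted(bad)}")
    kept = [rec.pose.placed_ligand(ligand_id=f"retained_{rec.ligand_species}_{rec.round_index}")
            for rec in run.rounds if rec.round_index in keep_round_indices]
    lig = ligand if ligand is not None else run.rounds[0].pose.ligand_ref
    return run_sequential(run.final_complex.protein, lig, config,
                          _preplaced=kept,
                          _retained_rounds=tuple(sorted(keep_round_indices)))
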