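"""Geometric interaction profiling of docked complexes.

Detects protein–ligand and ligand–ligand hydrogen bonds from heavy-atom
geometry (donor/acceptor classes within a distance cap — poses carry no
hydrogens, so the default cap of 3.6 Å is deliberately stricter than
hydrogen-aware criteria), and groups placed ligand copies into clusters
connected by H-bonds or close heavy-atom contacts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .structures import (
    ACCEPTOR_CLASSES,
    DONOR_CLASSES,
    Atom,
    Complex,
    Ligand,
)

PROTEIN_LIGAND = "protein-ligand"
LIGAND_LIGAND = "ligand-ligand"


@dataclass(frozen=True)
class HBondParams:
    d_max: float = 3.6          # Å, heavy-atom donor–acceptor cap
    angle_min: float = 120.0    # degrees, only applied when hydrogens exist
    contact_max: float = 4.0    # Å, ligand–ligand contact edge for clustering
    min_cluster_size: int = 3


@dataclass
class HBond:
    donor_ref: tuple      # ("protein", (chain, seq, ins), atom_name) or ("ligand", ligand_id, atom_index)
    acceptor_ref: tuple
    distance: float
    partner_kind: str
    angle: float | None = None

    def to_dict(self) -> dict:
        return {
            "donor": list(self.donor_ref),
            "acceptor": list(self.acceptor_ref),
            "distance": round(self.distance, 3),
            "partner_kind": self.partner_kind,
        }


@dataclass
class LigandCluster:
    member_ligand_ids: frozenset[str]
    size: int
    edge_list: list[tuple[str, str]] = field(default_factory=list)


def _polar_atoms(complex_: Complex):
    """Yield (ref, atom, owner) for every donor/acceptor-capable heavy atom.

    ``owner`` is None for protein atoms, else the ligand id; ``ref`` is a
    stable address used in reports.
    """
    entries = []
    for res in complex_.protein.residues():
        for atom in res.atoms:
            cls = atom.interaction_class
            if cls in DONOR_CLASSES or cls in ACCEPTOR_CLASSES:
                entries.append((("protein", res.key, atom.name), atom, None))
    for lig in complex_.ligands:
        for i, atom in enumerate(lig.atoms):
            cls = atom.interaction_class
            if cls in DONOR_CLASSES or cls in ACCEPTOR_CLASSES:
                entries.append((("ligand", lig.ligand_id, i), atom, lig.ligand_id))
    return entries


def _check_classes(complex_: Complex) -> None:
    for atom in complex_.protein.atoms():
        if atom.interaction_class is None:
            raise ValueError("protein atoms lack interaction classes")
    for lig in complex_.ligands:
        for atom in lig.atoms:
            if atom.interaction_class is None:
                raise ValueError(f"ligand {lig.ligand_id} lacks interaction classes")


def _orient_pair(ref_i, atom_i, ref_j, atom_j):
    """Decide donor/acceptor orientation for a polar pair, or None if the
    classes cannot form a bond.  Two ambivalent (donor_acceptor) partners
    are reported once, lower address as donor — a documented arbitrary
    convention."""
    ci, cj = atom_i.interaction_class, atom_j.interaction_class
    i_don, i_acc = ci in DONOR_CLASSES, ci in ACCEPTOR_CLASSES
    j_don, j_acc = cj in DONOR_CLASSES, cj in ACCEPTOR_CLASSES
    if i_don and j_acc and not (i_acc and j_don):
        return (ref_i, ref_j)
    if j_don and i_acc and not (j_acc and i_don):
        return (ref_j, ref_i)
    if i_don and j_acc and i_acc and j_don:
        return (ref_i, ref_j) if ref_i <= ref_j else (ref_j, ref_i)
    return None


def detect_hbonds(complex_: Complex, params: HBondParams | None = None) -> list[HBond]:
    """All protein–ligand and ligand–ligand hydrogen bonds in the complex.

    Heavy-atom mode: every donor–acceptor-capable pair within ``d_max``
    counts, excluding pairs within one molecule (covalent and 1-3 related
    pairs are intramolecular by construction and never considered).
    """
    params = params or HBondParams()
    _check_classes(complex_)
    entries = _polar_atoms(complex_)
    if not entries:
        return []
    coords = np.array([a.coords for _, a, _ in entries])
    bonds: list[HBond] = []
    n = len(entries)
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    for i in range(n):
        ref_i, atom_i, owner_i = entries[i]
        for j in range(i + 1, n):
            ref_j, atom_j, owner_j = entries[j]
            if owner_i == owner_j:
                continue  # same molecule (both protein, or same ligand copy)
            if owner_i is None and owner_j is None:
                continue
            if d[i, j] > params.d_max:
                continue
            oriented = _orient_pair(ref_i, atom_i, ref_j, atom_j)
            if oriented is None:
                continue
            kind = LIGAND_LIGAND if (owner_i and owner_j) else PROTEIN_LIGAND
            bonds.append(HBond(donor_ref=oriented[0], acceptor_ref=oriented[1],
                               distance=float(d[i, j]), partner_kind=kind))
    bonds.sort(key=lambda b: (b.donor_ref, b.acceptor_ref))
    return bonds


def ligand_ligand_bonds(complex_: Complex, params: HBondParams | None = None) -> list[HBond]:
    """H-bonds between atoms of distinct ligand copies only."""
    return [b for b in detect_hbonds(complex_, params) if b.partner_kind == LIGAND_LIGAND]


def find_clusters(complex_: Complex, params: HBondParams | None = None) -> list[LigandCluster]:
    """Group ligand copies into contact clusters.

    Edge rule: two copies are connected when a ligand–ligand H-bond exists
    between them or any heavy-atom pair is within ``contact_max``.  Clusters
    are connected components of size >= ``min_cluster_size``, sorted largest
    first.
    """
    params = params or HBondParams()
    g = nx.Graph()
    ligands = complex_.ligands
    g.add_nodes_from(lig.ligand_id for lig in ligands)
    coords = [lig.coords() for lig in ligands]
    for i in range(len(ligands)):
        for j in range(i + 1, len(ligands)):
            diff = coords[i][:, None, :] - coords[j][None, :, :]
            if np.sqrt((diff * diff).sum(axis=-1)).min() <= params.contact_max:
                g.add_edge(ligands[i].ligand_id, ligands[j].ligand_id)
    for b in ligand_ligand_bonds(complex_, params):
        g.add_edge(b.donor_ref[1], b.acceptor_ref[1])
    clusters = []
    for comp in nx.connected_components(g):
        if len(comp) >= params.min_cluster_size:
            clusters.append(LigandCluster(
                member_ligand_ids=frozenset(comp),
                size=len(comp),
                edge_list=sorted((min(u, v), max(u, v)) for u, v in g.subgraph(comp).edges),
            ))
    clusters.sort(key=lambda c: (-c.size, sorted(c.member_ligand_ids)))
    return clusters


def profile_report(complex_: Complex, params: HBondParams | None = None) -> dict:
    """JSON-serialisable interaction report for one complex."""
    bonds = detect_hbonds(complex_, params)
    clusters = find_clusters(complex_, params)
    return {
        "n_ligands": len(complex_.ligands),
        "hbonds": [b.to_dict() for b in bonds],
        "clusters": [
            {"members": sorted(c.member_ligand_ids), "size": c.size, "edges": c.edge_list}
            for c in clusters
        ],
    }


def write_profile_report(complex_: Complex, path, params: HBondParams | None = None) -> None:
    with open(path, "w") as fh:
        json.dump(profile_report(complex_, params), fh, indent=2, sort_keys=True)
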