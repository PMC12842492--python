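"""Domain types and I/O for protein conformers, ligands and region annotations.

Coordinates are in Ångström throughout.  Residue identity is the triple
``(chain_id, author seq_number, insertion_code)`` with 1-based author
numbering preserved, because binding-site residues are always reported in
author numbering (e.g. the UxuR linker Gly61–Gly94).

All downstream geometry works in heavy-atom-only mode: docking poses
typically carry no hydrogens, so interaction classes are assigned from
residue/atom-name tables (proteins) or from bond topology (ligands) rather
than from explicit protons.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import networkx as nx
import numpy as np
import yaml

log = logging.getLogger(__name__)

# interaction classes -------------------------------------------------------

HYDROPHOBIC = "hydrophobic"
DONOR = "donor"
ACCEPTOR = "acceptor"
DONOR_ACCEPTOR = "donor_acceptor"
POLAR_OTHER = "polar_other"
METAL = "metal"
NONE = "none"

INTERACTION_CLASSES = frozenset(
    {HYDROPHOBIC, DONOR, ACCEPTOR, DONOR_ACCEPTOR, POLAR_OTHER, METAL, NONE}
)

#: classes that can act as an H-bond donor (metals are treated like donors
#: for the purpose of the polar pair term; see docs/methods.md)
DONOR_CLASSES = frozenset({DONOR, DONOR_ACCEPTOR, METAL})
#: classes that can act as an H-bond acceptor
ACCEPTOR_CLASSES = frozenset({ACCEPTOR, DONOR_ACCEPTOR})


@dataclass
class Atom:
    """One atom: name, element, coordinates and an interaction class.

    ``interaction_class`` is ``None`` until :func:`assign_interaction_classes`
    has run; scoring and profiling refuse to work with unassigned atoms.
    """

    serial: int
    name: str
    element: str
    coords: np.ndarray
    residue_ref: tuple | None = None
    interaction_class: str | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.serial}: coords must be a finite 3-vector")
        if not self.element:
            raise ValueError(f"atom {self.serial}: empty element symbol")
        if self.interaction_class is not None and self.interaction_class not in INTERACTION_CLASSES:
            raise ValueError(f"unknown interaction class {self.interaction_class!r}")


@dataclass
class Residue:
    chain_id: str
    seq_number: int
    name: str
    atoms: list[Atom] = field(default_factory=list)
    ins_code: str = ""

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.seq_number, self.ins_code)

    def atom(self, name: str) -> Atom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(f"residue {self.key}: no atom {name!r}")


@dataclass
class ProteinModel:
    """One protein conformer; ``time_label_ns`` stands in for an MD snapshot time."""

    model_id: str
    time_label_ns: float = 0.0
    chains: dict[str, list[Residue]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.time_label_ns < 0:
            raise ValueError("time_label_ns must be non-negative")

    def residues(self) -> Iterator[Residue]:
        for chain in self.chains.values():
            yield from chain

    def atoms(self) -> Iterator[Atom]:
        for res in self.residues():
            yield from res.atoms

    def atom_list(self) -> list[Atom]:
        return list(self.atoms())

    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms()], dtype=float)

    def residue_index(self) -> dict[tuple[str, int, str], Residue]:
        return {r.key: r for r in self.residues()}

    def n_atoms(self) -> int:
        return sum(1 for _ in self.atoms())


@dataclass
class Ligand:
    """Small molecule with typed atoms, bond list and rotatable torsions.

    ``bonds`` holds ``(i, j, order)`` with 0-based atom indices.
    ``rotatable_torsions`` holds 4-tuples of atom indices (a, b, c, d) for
    the rotation about the b–c bond.
    """

    ligand_id: str
    species: str
    atoms: list[Atom] = field(default_factory=list)
    bonds: list[tuple[int, int, int]] = field(default_factory=list)
    rotatable_torsions: list[tuple[int, int, int, int]] = field(default_factory=list)

    @property
    def n_rot(self) -> int:
        return len(self.rotatable_torsions)

    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=float)

    def set_coords(self, coords: np.ndarray) -> None:
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ValueError("coordinate shape mismatch")
        for atom, xyz in zip(self.atoms, coords):
            atom.coords = np.array(xyz, dtype=float)

    def copy(self, ligand_id: str | None = None) -> "Ligand":
        atoms = [replace(a, coords=a.coords.copy()) for a in self.atoms]
        return Ligand(
            ligand_id=ligand_id or self.ligand_id,
            species=self.species,
            atoms=atoms,
            bonds=list(self.bonds),
            rotatable_torsions=list(self.rotatable_torsions),
        )

    def bond_graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(len(self.atoms)))
        g.add_edges_from((i, j) for i, j, _ in self.bonds)
        return g

    def centroid(self) -> np.ndarray:
        return self.coords().mean(axis=0)


@dataclass(frozen=True)
class RegionAnnotation:
    """Named residue set, e.g. region ``linker`` = the inter-domain linker."""

    region_name: str
    members: frozenset[tuple[str, int]]

    def contains(self, chain_id: str, seq_number: int) -> bool:
        return (chain_id, seq_number) in self.members


@dataclass
class Complex:
    """A protein conformer plus the ligand copies placed on it so far."""

    protein: ProteinModel
    ligands: list[Ligand] = field(default_factory=list)


# ---------------------------------------------------------------------------
# PDB I/O (via biotite)
# ---------------------------------------------------------------------------

_WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}
_METAL_ELEMENTS = {"ZN", "MG", "MN", "FE", "CU", "NI", "CO", "NA", "K", "CA_ION"}


def read_pdb(path: str | Path, model_id: str | None = None, time_label_ns: float = 0.0) -> ProteinModel:
    """Read one conformer from a PDB file into a :class:`ProteinModel`.

    Waters are dropped; other HETATM records (metals, pre-placed ligands)
    are kept as residues of their own.  Insertion codes are preserved as
    part of the residue identity.
    """
    import biotite.structure.io.pdb as pdb

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        pdb_file = pdb.PDBFile.read(str(path))
        arr = pdb_file.get_structure(model=1, altloc="first")
    except Exception as exc:  # malformed records
        raise ValueError(f"cannot parse PDB file {path}: {exc}") from exc
    if arr.array_length() == 0:
        raise ValueError(f"{path}: empty model (no ATOM/HETATM records)")

    model = ProteinModel(model_id=model_id or path.stem, time_label_ns=time_label_ns)
    serial = 0
    current: Residue | None = None
    for i in range(arr.array_length()):
        res_name = str(arr.res_name[i])
        if res_name in _WATER_NAMES:
            continue
        chain_id = str(arr.chain_id[i])
        seq_number = int(arr.res_id[i])
        ins = str(arr.ins_code[i]) if hasattr(arr, "ins_code") else ""
        key = (chain_id, seq_number, ins)
        if current is None or current.key != key or current.name != res_name:
            current = Residue(chain_id=chain_id, seq_number=seq_number, name=res_name, ins_code=ins)
            model.chains.setdefault(chain_id, []).append(current)
        serial += 1
        element = str(arr.element[i]).upper() or str(arr.atom_name[i])[0]
        current.atoms.append(
            Atom(
                serial=serial,
                name=str(arr.atom_name[i]),
                element=element,
                coords=arr.coord[i],
                residue_ref=key,
            )
        )
    if not model.chains:
        raise ValueError(f"{path}: no residues after filtering waters")
    return model


#: default HETATM residue names used when writing ligand copies
LIGAND_RESNAMES = {
    "D-glucose": "GLC",
    "D-fructuronate": "FRU",
    "D-galacturonate": "GAL",
    "D-glucuronate": "GCU",
}

_LIGAND_CHAIN_IDS = "XYZWVUTSRQPONMLKJIHGFEDCBA"


def write_pdb(obj: ProteinModel | Complex, path: str | Path, resname_map: dict[str, str] | None = None) -> None:
    """Write a model or complex as PDB; ligand copies become HETATM residues
    with unique chain ids."""
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdb

    if isinstance(obj, ProteinModel):
        obj = Complex(protein=obj)
    resname_map = {**LIGAND_RESNAMES, **(resname_map or {})}

    records: list[tuple[str, int, str, str, str, np.ndarray, bool]] = []
    for res in obj.protein.residues():
        for a in res.atoms:
            records.append((res.chain_id, res.seq_number, res.ins_code, res.name, a.name, a.coords, False))
    used_chains = set(obj.protein.chains)
    free_chains = [c for c in _LIGAND_CHAIN_IDS if c not in used_chains]
    for k, lig in enumerate(obj.ligands):
        chain = free_chains[k % len(free_chains)]
        resname = resname_map.get(lig.species, lig.species[:3].upper() or "LIG")
        for a in lig.atoms:
            records.append((chain, k + 1, "", resname, a.name, a.coords, True))

    arr = struc.AtomArray(len(records))
    for i, (chain, seq, ins, resname, name, xyz, het) in enumerate(records):
        arr.chain_id[i] = chain
        arr.res_id[i] = seq
        arr.ins_code[i] = ins
        arr.res_name[i] = resname
        arr.atom_name[i] = name
        arr.element[i] = _element_from_name(name)
        arr.hetero[i] = het
        arr.coord[i] = xyz
    pdb_file = pdb.PDBFile()
    pdb_file.set_structure(arr)
    pdb_file.write(str(path))


def _element_from_name(name: str) -> str:
    stripped = "".join(c for c in name if c.isalpha())
    if len(stripped) >= 2 and stripped[:2].upper() in {"ZN", "MG", "FE", "CL", "BR", "MN", "CU", "NA"}:
        return stripped[:2].capitalize()
    return stripped[:1].upper()


# ---------------------------------------------------------------------------
# Ligand I/O (via RDKit) and rotatable-bond detection
# ---------------------------------------------------------------------------


def read_ligand(path: str | Path, fmt: str | None = None, ligand_id: str | None = None,
                species: str | None = None) -> Ligand:
    """Read an SDF (V2000) or MOL2 ligand.

    Rotatable torsions are detected as acyclic single bonds between heavy
    atoms, each end bearing at least one further heavy-atom neighbour (so
    terminal methyls and hydroxyls never rotate, and ring bonds never
    rotate).
    """
    from rdkit import Chem

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt is None:
        fmt = path.suffix.lstrip(".").lower()
        fmt = {"sd": "sdf", "mol": "sdf"}.get(fmt, fmt)
    if fmt == "sdf":
        mol = Chem.MolFromMolFile(str(path), sanitize=True, removeHs=False)
    elif fmt == "mol2":
        mol = Chem.MolFromMol2File(str(path), sanitize=True, removeHs=False)
    else:
        raise ValueError(f"unsupported ligand format {fmt!r}")
    if mol is None:
        raise ValueError(f"cannot parse {fmt} file {path}")
    return ligand_from_rdkit(mol, ligand_id=ligand_id or path.stem, species=species or path.stem)


_KNOWN_ELEMENTS = {
    "H", "C", "N", "O", "S", "P", "F", "CL", "BR", "I", "B", "SI",
    "ZN", "MG", "MN", "FE", "CU", "NI", "CO", "NA", "K", "CA",
}


def ligand_from_rdkit(mol, ligand_id: str, species: str) -> Ligand:
    conf = mol.GetConformer()
    atoms: list[Atom] = []
    for i, rd_atom in enumerate(mol.GetAtoms()):
        element = rd_atom.GetSymbol().upper()
        if element not in _KNOWN_ELEMENTS:
            raise ValueError(f"{ligand_id}: unknown element {rd_atom.GetSymbol()!r}")
        pos = conf.GetAtomPosition(i)
        atoms.append(Atom(serial=i + 1, name=f"{rd_atom.GetSymbol()}{i + 1}",
                          element=element, coords=(pos.x, pos.y, pos.z)))
    bonds = []
    for b in mol.GetBonds():
        order = int(round(b.GetBondTypeAsDouble())) or 1
        bonds.append((b.GetBeginAtomIdx(), b.GetEndAtomIdx(), order))
    lig = Ligand(ligand_id=ligand_id, species=species, atoms=atoms, bonds=bonds)
    heavy = [i for i, a in enumerate(lig.atoms) if a.element != "H"]
    if heavy:
        sub = lig.bond_graph().subgraph(heavy)
        if not nx.is_connected(sub):
            raise ValueError(f"{ligand_id}: disconnected heavy-atom bond graph")
    lig.rotatable_torsions = detect_rotatable_torsions(lig)
    return lig


def detect_rotatable_torsions(lig: Ligand) -> list[tuple[int, int, int, int]]:
    """Apply the rotatable-bond rule to every bond of the ligand.

    A bond (b, c) is rotatable iff it is a single bond, not in a ring, both
    atoms are heavy, and each of b and c has at least one further heavy
    neighbour.  The torsion quadruple uses the lowest-index further heavy
    neighbour on each side.
    """
    g = lig.bond_graph()
    is_heavy = [a.element != "H" for a in lig.atoms]
    ring_edges: set[frozenset[int]] = set()
    for cycle in nx.cycle_basis(g):
        for i in range(len(cycle)):
            ring_edges.add(frozenset((cycle[i], cycle[(i + 1) % len(cycle)])))
    torsions = []
    for b, c, order in lig.bonds:
        if order != 1 or frozenset((b, c)) in ring_edges:
            continue
        if not (is_heavy[b] and is_heavy[c]):
            continue
        b_nb = sorted(n for n in g.neighbors(b) if n != c and is_heavy[n])
        c_nb = sorted(n for n in g.neighbors(c) if n != b and is_heavy[n])
        if b_nb and c_nb:
            torsions.append((b_nb[0], b, c, c_nb[0]))
    return torsions


# ---------------------------------------------------------------------------
# Interaction-class assignment
# ---------------------------------------------------------------------------

# Side-chain polar atoms of the standard amino acids.  Hydroxyls are
# donor/acceptor; amides split into a donor N and an acceptor O;
# carboxylates are acceptors; His ring nitrogens can do either.
_SIDECHAIN_CLASSES: dict[tuple[str, str], str] = {
    ("SER", "OG"): DONOR_ACCEPTOR,
    ("THR", "OG1"): DONOR_ACCEPTOR,
    ("TYR", "OH"): DONOR_ACCEPTOR,
    ("ASP", "OD1"): ACCEPTOR,
    ("ASP", "OD2"): ACCEPTOR,
    ("GLU", "OE1"): ACCEPTOR,
    ("GLU", "OE2"): ACCEPTOR,
    ("ASN", "OD1"): ACCEPTOR,
    ("ASN", "ND2"): DONOR,
    ("GLN", "OE1"): ACCEPTOR,
    ("GLN", "NE2"): DONOR,
    ("ARG", "NE"): DONOR,
    ("ARG", "NH1"): DONOR,
    ("ARG", "NH2"): DONOR,
    ("LYS", "NZ"): DONOR,
    ("TRP", "NE1"): DONOR,
    ("HIS", "ND1"): DONOR_ACCEPTOR,
    ("HIS", "NE2"): DONOR_ACCEPTOR,
    ("CYS", "SG"): POLAR_OTHER,
    ("MET", "SD"): POLAR_OTHER,
}

# Carbons bonded to N/O are excluded from the hydrophobic class
# (Vina-style carbon typing).
_POLARIZED_CARBONS: dict[str, set[str]] = {
    "SER": {"CB"}, "THR": {"CB"}, "CYS": {"CB"}, "MET": {"CG", "CE"},
    "ASP": {"CG"}, "ASN": {"CG"}, "GLU": {"CD"}, "GLN": {"CD"},
    "ARG": {"CD", "CZ"}, "LYS": {"CE"}, "TYR": {"CZ"},
    "HIS": {"CG", "CD2", "CE1"}, "TRP": {"CD1", "CE2"}, "PRO": {"CD"},
}

_STANDARD_AA = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}


def _classify_protein_atom(res_name: str, atom: Atom) -> str:
    name, element = atom.name, atom.element
    if element == "H":
        return NONE
    if element in _METAL_ELEMENTS and res_name not in _STANDARD_AA:
        return METAL
    if name == "N":
        return DONOR if res_name != "PRO" else POLAR_OTHER
    if name in ("O", "OXT"):
        return ACCEPTOR
    if name in ("C", "CA"):
        return POLAR_OTHER  # carbonyl C / Cα bonded to backbone N
    key = (res_name, name)
    if key in _SIDECHAIN_CLASSES:
        return _SIDECHAIN_CLASSES[key]
    if element == "C":
        if name in _POLARIZED_CARBONS.get(res_name, set()):
            return POLAR_OTHER
        return HYDROPHOBIC
    if element in ("O",):
        return ACCEPTOR
    if element in ("N",):
        return DONOR
    if element in ("S", "P"):
        return POLAR_OTHER
    log.debug("unclassified protein atom %s/%s -> none", res_name, name)
    return NONE


def _classify_ligand_atoms(lig: Ligand) -> None:
    g = lig.bond_graph()
    heavy_deg = [sum(1 for n in g.neighbors(i) if lig.atoms[n].element != "H")
                 for i in range(len(lig.atoms))]
    for i, atom in enumerate(lig.atoms):
        el = atom.element
        if el == "H":
            atom.interaction_class = NONE
        elif el in _METAL_ELEMENTS and el not in ("CA",):
            atom.interaction_class = METAL
        elif el == "O":
            if heavy_deg[i] >= 2:
                # ether / ring oxygen (e.g. pyranose ring O)
                atom.interaction_class = ACCEPTOR
            else:
                parent = next((n for n in g.neighbors(i) if lig.atoms[n].element != "H"), None)
                sibling_os = 0
                if parent is not None:
                    sibling_os = sum(
                        1 for n in g.neighbors(parent)
                        if n != i and lig.atoms[n].element == "O" and heavy_deg[n] == 1
                    )
                dbl = any(order >= 2 and i in (a, b) for a, b, order in lig.bonds)
                if dbl or sibling_os >= 1:
                    # carbonyl / carboxylate oxygen
                    atom.interaction_class = ACCEPTOR
                else:
                    # hydroxyl oxygen
                    atom.interaction_class = DONOR_ACCEPTOR
        elif el == "N":
            atom.interaction_class = DONOR if heavy_deg[i] <= 2 else POLAR_OTHER
        elif el == "C":
            polar_nb = any(lig.atoms[n].element in ("O", "N") for n in g.neighbors(i))
            atom.interaction_class = POLAR_OTHER if polar_nb else HYDROPHOBIC
        elif el in ("S", "P"):
            atom.interaction_class = POLAR_OTHER
        elif el in ("F", "CL", "BR", "I"):
            atom.interaction_class = HYDROPHOBIC
        else:
            log.debug("unclassified ligand atom %s -> none", atom.name)
            atom.interaction_class = NONE


def assign_interaction_classes(obj):
    """Fill ``interaction_class`` on every atom of a model, ligand or complex.

    Returns the same object.  Atoms that match no rule fall to class
    ``none`` (logged at debug level), never an error.
    """
    if isinstance(obj, Complex):
        assign_interaction_classes(obj.protein)
        for lig in obj.ligands:
            assign_interaction_classes(lig)
        return obj
    if isinstance(obj, ProteinModel):
        for res in obj.residues():
            for atom in res.atoms:
                if atom.interaction_class is None:
                    atom.interaction_class = _classify_protein_atom(res.name, atom)
        return obj
    if isinstance(obj, Ligand):
        if any(a.interaction_class is None for a in obj.atoms):
            _classify_ligand_atoms(obj)
        return obj
    raise TypeError(f"cannot assign interaction classes to {type(obj)!r}")


# ---------------------------------------------------------------------------
# Superposition / RMSD
# ---------------------------------------------------------------------------


def kabsch_rmsd(P: np.ndarray, Q: np.ndarray) -> float:
    """RMSD between two equal-size coordinate sets after optimal rigid
    superposition (proper rotation only, no reflection)."""
    P = np.asarray(P, dtype=float).reshape(-1, 3)
    Q = np.asarray(Q, dtype=float).reshape(-1, 3)
    if P.shape != Q.shape:
        raise ValueError(f"size mismatch: {P.shape} vs {Q.shape}")
    if len(P) == 0:
        raise ValueError("empty coordinate sets")
    Pc = P - P.mean(axis=0)
    Qc = Q - Q.mean(axis=0)
    H = Pc.T @ Qc
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    diff = Pc @ R.T - Qc
    return float(np.sqrt((diff * diff).sum() / len(P)))


def rmsd_profile(ensemble: Sequence[ProteinModel], reference_index: int = 0,
                 atom_name: str = "CA") -> list[tuple[float, float]]:
    """Per-snapshot RMSD against one reference conformer.

    Atoms are matched by ``(chain, seq_number, ins_code, atom_name)``;
    a snapshot missing any reference residue is an error naming it.
    """
    if not ensemble:
        raise ValueError("empty ensemble")
    ref = ensemble[reference_index]
    selection = [(res.key, atom_name) for res in ref.residues()
                 if any(a.name == atom_name for a in res.atoms)]
    if not selection:
        raise ValueError(f"reference has no {atom_name} atoms")

    def coords_for(model: ProteinModel) -> np.ndarray:
        index = model.residue_index()
        missing = [key for key, _ in selection if key not in index]
        if missing:
            raise ValueError(f"model {model.model_id}: missing residues {missing}")
        return np.array([index[key].atom(name).coords for key, name in selection])

    ref_coords = coords_for(ref)
    return [(m.time_label_ns, kabsch_rmsd(coords_for(m), ref_coords)) for m in ensemble]


# ---------------------------------------------------------------------------
# Region annotations
# ---------------------------------------------------------------------------


def parse_region_spans(config: dict[str, list[str]]) -> list[RegionAnnotation]:
    """Build annotations from a mapping ``region_name -> ["A:61-94", ...]``."""
    annotations = []
    seen = set()
    for region_name, spans in config.items():
        if region_name in seen:
            raise ValueError(f"duplicate region name {region_name!r}")
        seen.add(region_name)
        members = set()
        for span in spans:
            try:
                chain, rng = span.split(":")
                if "-" in rng:
                    lo, hi = (int(x) for x in rng.split("-"))
                else:
                    lo = hi = int(rng)
            except ValueError as exc:
                raise ValueError(f"bad span {span!r} (expected 'chain:start-end')") from exc
            members.update((chain, seq) for seq in range(lo, hi + 1))
        annotations.append(RegionAnnotation(region_name=region_name, members=frozenset(members)))
    return annotations


def read_region_annotations(path: str | Path) -> list[RegionAnnotation]:
    """Read a YAML/JSON region config mapping names to 'chain:start-end' spans."""
    with open(path) as fh:
        config = yaml.safe_load(fh)
    if not isinstance(config, dict):
        raise ValueError(f"{path}: expected a mapping of region names to span lists")
    return parse_region_spans(config)


def write_region_annotations(annotations: Iterable[RegionAnnotation], path: str | Path) -> None:
    config: dict[str, list[str]] = {}
    for ann in annotations:
        spans = []
        by_chain: dict[str, list[int]] = {}
        for chain, seq in sorted(ann.members):
            by_chain.setdefault(chain, []).append(seq)
        for chain, seqs in sorted(by_chain.items()):
            seqs.sort()
            start = prev = seqs[0]
            for s in seqs[1:]:
                if s != prev + 1:
                    spans.append(f"{chain}:{start}-{prev}")
                    start = s
                prev = s
            spans.append(f"{chain}:{start}-{prev}")
        config[ann.region_name] = spans
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh)
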