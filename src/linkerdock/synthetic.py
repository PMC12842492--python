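"""Synthetic inputs for the whole pipeline.

Everything the stages consume can be generated here at desk scale: toy MD-like
conformer ensembles of a two-domain protein joined by a flexible linker,
sugar-like ligands with rotatable hydroxymethyl arms, ground-truth H-bond
fixtures, and ΔG tables with a Gaussian nonspecific background plus planted
significant binders.

The protein backbone is built from ideal internal coordinates (N–CA 1.458 Å,
CA–C 1.525 Å, C–N 1.329 Å and standard angles).  Domains are ideal α-helices
(φ = −57°, ψ = −47°); the linker is an extended coil whose backbone dihedrals
are resampled per snapshot from a normal law around extended-coil values.
Side chains are reduced to CB, except linker residues which carry a
serine-like OG hydroxyl so that the linker offers H-bond anchors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .structures import (
    ACCEPTOR,
    DONOR_ACCEPTOR,
    HYDROPHOBIC,
    Atom,
    Ligand,
    ProteinModel,
    RegionAnnotation,
    Residue,
    assign_interaction_classes,
)

# ideal backbone internal coordinates
_B_N_CA = 1.458
_B_CA_C = 1.525
_B_C_N = 1.329
_B_C_O = 1.231
_B_CA_CB = 1.530
_A_N_CA_C = 111.0
_A_CA_C_N = 116.2
_A_C_N_CA = 121.7
_A_CA_C_O = 120.5

_HELIX_PHI, _HELIX_PSI = -57.0, -47.0
_COIL_PHI, _COIL_PSI = -120.0, 130.0


@dataclass
class ToyProteinSpec:
    """Shape of the synthetic two-domain protein and its snapshot ensemble."""

    n_domain1: int = 14
    n_linker: int = 10
    n_domain2: int = 14
    n_snapshots: int = 3
    linker_dihedral_sd: float = 15.0  # degrees
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_domain1, self.n_linker, self.n_domain2) < 1:
            raise ValueError("residue counts must be >= 1")
        if self.n_snapshots < 1:
            raise ValueError("n_snapshots must be >= 1")


@dataclass
class DgTableSpec:
    """Synthetic pooled ΔG table: Gaussian background plus planted binders."""

    background_mean: float = -4.5
    background_sd: float = 0.25
    n_background: int = 100
    planted: list[tuple[str, float, int, str]] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.background_sd <= 0:
            raise ValueError("background_sd must be positive")


def _place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
                length: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """NeRF placement: position d with |cd| = length, angle(b,c,d) and
    dihedral(a,b,c,d) as given."""
    theta = np.radians(angle_deg)
    chi = np.radians(dihedral_deg)
    bc = c - b
    bc_hat = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc_hat)
    n_hat = n / np.linalg.norm(n)
    m_hat = np.cross(n_hat, bc_hat)
    d_local = np.array([
        -length * np.cos(theta),
        length * np.sin(theta) * np.cos(chi),
        length * np.sin(theta) * np.sin(chi),
    ])
    return c + d_local[0] * bc_hat + d_local[1] * m_hat + d_local[2] * n_hat


def _build_backbone(phi: np.ndarray, psi: np.ndarray) -> list[dict[str, np.ndarray]]:
    """Build N/CA/C/O/CB positions for a chain with given per-residue φ/ψ."""
    n_res = len(phi)
    residues: list[dict[str, np.ndarray]] = []
    # first residue in a canonical frame
    N = np.array([0.0, 0.0, 0.0])
    CA = np.array([_B_N_CA, 0.0, 0.0])
    ang = np.radians(_A_N_CA_C)
    C = CA + _B_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])
    residues.append({"N": N, "CA": CA, "C": C})
    for i in range(1, n_res):
        prev = residues[-1]
        N = _place_atom(prev["N"], prev["CA"], prev["C"], _B_C_N, _A_CA_C_N, psi[i - 1])
        CA = _place_atom(prev["CA"], prev["C"], N, _B_N_CA, _A_C_N_CA, 180.0)  # trans omega
        C = _place_atom(prev["C"], N, CA, _B_CA_C, _A_N_CA_C, phi[i])
        residues.append({"N": N, "CA": CA, "C": C})
    # carbonyl O and CB from local frames
    for i, res in enumerate(residues):
        psi_i = psi[i] if i < n_res else psi[-1]
        res["O"] = _place_atom(res["N"], res["CA"], res["C"], _B_C_O, _A_CA_C_O, psi_i + 180.0)
        res["CB"] = _place_atom(res["C"], res["N"], res["CA"], _B_CA_CB, 110.5, 122.5)
    return residues


def _has_ca_clash(residues: list[dict[str, np.ndarray]], cutoff: float = 3.0) -> bool:
    ca = np.array([r["CA"] for r in residues])
    d = np.linalg.norm(ca[:, None, :] - ca[None, :, :], axis=-1)
    n = len(ca)
    idx = np.abs(np.arange(n)[:, None] - np.arange(n)[None, :])
    return bool(np.any(d[idx >= 2] < cutoff))


def make_toy_protein(spec: ToyProteinSpec) -> tuple[list[ProteinModel], list[RegionAnnotation]]:
    """Generate an MD-like snapshot ensemble of a helix–linker–helix protein.

    Domains keep fixed ideal-helix dihedrals across snapshots; only the
    linker dihedrals are resampled per snapshot, so per-domain superposition
    gives near-zero RMSD while whole-chain and linker RMSD fluctuate — the
    behaviour the pipeline expects from MD conformers of a flexibly linked
    two-domain protein.  Snapshots are clash-checked (no non-bonded CA–CA
    pair below 3 Å) and resampled on failure.
    """
    rng = np.random.default_rng(spec.seed)
    n_total = spec.n_domain1 + spec.n_linker + spec.n_domain2
    linker_lo = spec.n_domain1  # 0-based indices of linker residues
    linker_hi = spec.n_domain1 + spec.n_linker

    base_phi = np.full(n_total, _HELIX_PHI)
    base_psi = np.full(n_total, _HELIX_PSI)
    base_phi[linker_lo:linker_hi] = _COIL_PHI
    base_psi[linker_lo:linker_hi] = _COIL_PSI

    models: list[ProteinModel] = []
    for snap in range(spec.n_snapshots):
        for attempt in range(1000):
            phi = base_phi.copy()
            psi = base_psi.copy()
            if spec.linker_dihedral_sd > 0:
                phi[linker_lo:linker_hi] += rng.normal(0.0, spec.linker_dihedral_sd, spec.n_linker)
                psi[linker_lo:linker_hi] += rng.normal(0.0, spec.linker_dihedral_sd, spec.n_linker)
            backbone = _build_backbone(phi, psi)
            if not _has_ca_clash(backbone):
                break
        else:
            raise RuntimeError(
                "could not build a clash-free linker conformation in 1000 attempts; "
                "try a smaller linker_dihedral_sd"
            )
        time_ns = 10.0 * (snap + 1)
        model = ProteinModel(model_id=f"toy_{int(time_ns)}ns", time_label_ns=time_ns)
        chain: list[Residue] = []
        serial = 0
        for i, pos in enumerate(backbone):
            in_linker = linker_lo <= i < linker_hi
            res_name = "SER" if in_linker else "ALA"
            res = Residue(chain_id="A", seq_number=i + 1, name=res_name)
            atom_names = ["N", "CA", "C", "O", "CB"]
            coords = dict(pos)
            if in_linker:
                # serine-like hydroxyl anchor off CB
                cb = pos["CB"]
                ca = pos["CA"]
                direction = cb - ca
                direction = direction / np.linalg.norm(direction)
                coords["OG"] = cb + 1.42 * direction
                atom_names.append("OG")
            for name in atom_names:
                serial += 1
                res.atoms.append(Atom(serial=serial, name=name,
                                      element=name[:1], coords=coords[name],
                                      residue_ref=res.key))
            chain.append(res)
        model.chains["A"] = chain
        assign_interaction_classes(model)
        models.append(model)

    linker_members = frozenset(("A", i + 1) for i in range(linker_lo, linker_hi))
    # a pocket-like patch in the middle of domain 2 stands in for the CTD cavity
    mid = linker_hi + spec.n_domain2 // 2
    pocket_members = frozenset(("A", s) for s in range(max(linker_hi + 1, mid - 2), min(n_total, mid + 3)))
    annotations = [
        RegionAnnotation(region_name="linker", members=linker_members),
        RegionAnnotation(region_name="pocket", members=pocket_members),
    ]
    return models, annotations


# ---------------------------------------------------------------------------
# Toy ligands
# ---------------------------------------------------------------------------


def make_toy_ligand(kind: str, seed: int = 0) -> Ligand:
    """Build a toy ligand: ``probe_single_atom``, ``rigid_diatomic`` or
    ``pyranose_like`` (a 6-ring of 5 C + 1 O carrying four hydroxyls and an
    exocyclic CH2OH arm, so n_rot >= 1 like a real hexose)."""
    if kind == "probe_single_atom":
        lig = Ligand(ligand_id="probe", species="probe_single_atom",
                     atoms=[Atom(serial=1, name="C1", element="C", coords=(0.0, 0.0, 0.0),
                                 interaction_class=HYDROPHOBIC)])
        return lig
    if kind == "rigid_diatomic":
        atoms = [
            Atom(serial=1, name="C1", element="C", coords=(0.0, 0.0, 0.0), interaction_class=HYDROPHOBIC),
            Atom(serial=2, name="C2", element="C", coords=(1.53, 0.0, 0.0), interaction_class=HYDROPHOBIC),
        ]
        return Ligand(ligand_id="diatomic", species="rigid_diatomic", atoms=atoms, bonds=[(0, 1, 1)])
    if kind != "pyranose_like":
        raise ValueError(f"unknown toy ligand kind {kind!r}")

    ring_r = 1.50  # hexagon edge = circumradius
    names, elements, coords = [], [], []
    # ring atoms C1..C5 at 0..240 deg, ring O at 300 deg
    for i in range(5):
        a = np.radians(60.0 * i)
        names.append(f"C{i + 1}")
        elements.append("C")
        coords.append((ring_r * np.cos(a), ring_r * np.sin(a), 0.0))
    a = np.radians(300.0)
    names.append("O5")
    elements.append("O")
    coords.append((ring_r * np.cos(a), ring_r * np.sin(a), 0.0))
    # hydroxyl oxygens O1..O4 radially off C1..C4
    for i in range(4):
        a = np.radians(60.0 * i)
        r = ring_r + 1.43
        names.append(f"O{i + 1}")
        elements.append("O")
        coords.append((r * np.cos(a), r * np.sin(a), 0.0))
    # exocyclic CH2OH arm off C5 (tilted out of plane, tetrahedral-ish)
    c5 = np.array(coords[4])
    radial = c5 / np.linalg.norm(c5)
    up = np.array([0.0, 0.0, 1.0])
    arm_dir = (radial + up) / np.linalg.norm(radial + up)
    c6 = c5 + 1.52 * arm_dir
    names.append("C6")
    elements.append("C")
    coords.append(tuple(c6))
    o6 = c6 + 1.43 * up
    names.append("O6")
    elements.append("O")
    coords.append(tuple(o6))

    atoms = [Atom(serial=i + 1, name=n, element=e, coords=c)
             for i, (n, e, c) in enumerate(zip(names, elements, coords))]
    # indices: C1-C5 = 0..4, O5 = 5, O1-O4 = 6..9, C6 = 10, O6 = 11
    bonds = [(0, 1, 1), (1, 2, 1), (2, 3, 1), (3, 4, 1), (4, 5, 1), (5, 0, 1)]
    bonds += [(i, 6 + i, 1) for i in range(4)]
    bonds += [(4, 10, 1), (10, 11, 1)]
    lig = Ligand(ligand_id=f"pyr{seed}", species="pyranose_like", atoms=atoms, bonds=bonds)
    from .structures import detect_rotatable_torsions

    lig.rotatable_torsions = detect_rotatable_torsions(lig)
    assign_interaction_classes(lig)
    if seed:
        # deterministically rotate the reference frame so distinct seeds
        # give distinct (but congruent) reference coordinates
        from scipy.spatial.transform import Rotation

        R = Rotation.random(random_state=np.random.RandomState(seed)).as_matrix()
        lig.set_coords(lig.coords() @ R.T)
    return lig


# ---------------------------------------------------------------------------
# ΔG tables
# ---------------------------------------------------------------------------


def make_dg_table(spec: DgTableSpec) -> pd.DataFrame:
    """Synthetic pooled ΔG table with columns
    ``model_id, round, delta_g, region``.

    Background records are drawn from Normal(background_mean, background_sd)
    and labeled region ``other`` (i.e. nonspecific surface attachment);
    planted records are inserted verbatim.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    draws = rng.normal(spec.background_mean, spec.background_sd, spec.n_background)
    for i, dg in enumerate(draws):
        rows.append({"model_id": f"bg{i}", "round": i % 10 + 1,
                     "delta_g": float(dg), "region": "other"})
    for region_name, delta_g, round_index, model_id in spec.planted:
        rows.append({"model_id": model_id, "round": int(round_index),
                     "delta_g": float(delta_g), "region": region_name})
    return pd.DataFrame(rows, columns=["model_id", "round", "delta_g", "region"])


# ---------------------------------------------------------------------------
# H-bond ground-truth fixture
# ---------------------------------------------------------------------------


@dataclass
class HBondFixture:
    """Constructed complex whose H-bond list is known by construction.

    ``expected`` pairs are ``((chain, seq, ins, atom_name), (ligand_id, atom_index))``
    with the protein hydroxyl as donor and the ligand oxygen as acceptor.
    """

    protein: ProteinModel
    ligands: list[Ligand]
    expected: list[tuple[tuple[str, int, str, str], tuple[str, int]]]


def make_hbond_fixture(n_bonds: int, seed: int = 0) -> HBondFixture:
    """Place ``n_bonds`` serine hydroxyl donors 2.9 Å from single-oxygen
    probe ligands with every other polar pair >= 5 Å apart, giving an exact
    ground truth for the H-bond detector."""
    if n_bonds < 0:
        raise ValueError("n_bonds must be >= 0")
    rng = np.random.default_rng(seed)
    n_res = max(n_bonds, 1) + 2
    spacing = 8.0
    jitter = rng.uniform(-0.1, 0.1, n_res)

    model = ProteinModel(model_id=f"hbfix_{n_bonds}_{seed}", time_label_ns=0.0)
    chain: list[Residue] = []
    serial = 0
    for i in range(n_res):
        x = spacing * i + jitter[i]
        res = Residue(chain_id="A", seq_number=i + 1, name="SER")
        positions = {
            "N": (x, 0.0, 0.0),
            "CA": (x + 1.46, 0.0, 0.0),
            "C": (x + 1.46 + 0.76, 1.32, 0.0),
            "CB": (x + 1.46, 0.0, 1.53),
            "OG": (x + 1.46, 0.0, 1.53 + 1.43),
        }
        for name, xyz in positions.items():
            serial += 1
            res.atoms.append(Atom(serial=serial, name=name, element=name[:1],
                                  coords=xyz, residue_ref=res.key))
        chain.append(res)
    model.chains["A"] = chain
    assign_interaction_classes(model)

    ligands: list[Ligand] = []
    expected = []
    for k in range(n_bonds):
        og = chain[k].atom("OG")
        pos = og.coords + np.array([0.0, 0.0, 2.9])
        lig = Ligand(ligand_id=f"probeO{k + 1}", species="probe_oxygen",
                     atoms=[Atom(serial=1, name="O1", element="O", coords=pos,
                                 interaction_class=ACCEPTOR)])
        ligands.append(lig)
        expected.append(((chain[k].chain_id, chain[k].seq_number, chain[k].ins_code, "OG"),
                         (lig.ligand_id, 0)))
    return HBondFixture(protein=model, ligands=ligands, expected=expected)
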