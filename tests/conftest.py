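"""Shared fixtures: tiny molecule files and toy ensembles, all generated
programmatically."""

from __future__ import annotations

import numpy as np
import pytest

import linkerdock as ld

ETHANE_SDF = """ethane
  toy

  2  1  0  0  0  0  0  0  0  0999 V2000
    0.0000    0.0000    0.0000 C   0  0
    1.5300    0.0000    0.0000 C   0  0
  1  2  1  0
M  END
"""

BUTANE_SDF = """butane
  toy

  4  3  0  0  0  0  0  0  0  0999 V2000
    0.0000    0.0000    0.0000 C   0  0
    1.5300    0.0000    0.0000 C   0  0
    2.0400    1.4400    0.0000 C   0  0
    3.5700    1.4400    0.0000 C   0  0
  1  2  1  0
  2  3  1  0
  3  4  1  0
M  END
"""


def _cyclohexane_sdf() -> str:
    lines = ["cyclohexane", "  toy", "", "  6  6  0  0  0  0  0  0  0  0999 V2000"]
    r = 1.54
    for i in range(6):
        a = np.radians(60 * i)
        lines.append(f"{r * np.cos(a):10.4f}{r * np.sin(a):10.4f}{0.0:10.4f} C   0  0")
    for i in range(6):
        lines.append(f"{i + 1:3d}{(i + 1) % 6 + 1:3d}  1  0")
    lines.append("M  END")
    return "\n".join(lines) + "\n"


CYCLOHEXANE_SDF = _cyclohexane_sdf()


@pytest.fixture(scope="session")
def sdf_dir(tmp_path_factory):
    d = tmp_path_factory.mktemp("sdf")
    (d / "ethane.sdf").write_text(ETHANE_SDF)
    (d / "butane.sdf").write_text(BUTANE_SDF)
    (d / "cyclohexane.sdf").write_text(CYCLOHEXANE_SDF)
    return d


@pytest.fixture(scope="session")
def toy_ensemble():
    """Three snapshots of the helix–linker–helix toy protein."""
    return ld.make_toy_protein(ld.ToyProteinSpec(n_snapshots=3, linker_dihedral_sd=20.0, seed=11))


@pytest.fixture(scope="session")
def pyranose():
    return ld.make_toy_ligand("pyranose_like")


@pytest.fixture(scope="session")
def probe():
    return ld.make_toy_ligand("probe_single_atom")


@pytest.fixture(scope="session")
def single_receptor_atom():
    """One hydrophobic carbon at the origin: the analytic 2-atom system."""
    return ld.make_toy_ligand("probe_single_atom").atoms


@pytest.fixture(scope="session")
def pair_potential_optimum(single_receptor_atom):
    """Oracle argmin distance of the hydrophobic C–C pair potential from a
    fine 1-D grid scan."""
    s = np.linspace(-1.0, 8.0, 90001)
    vals = np.array([ld.score_pair_profile("hydrophobic", "hydrophobic", x) for x in s])
    radii_sum = 1.9 + 1.9
    return float(s[vals.argmin()] + radii_sum)


@pytest.fixture(scope="session")
def small_sequential_config():
    """Reduced search effort for protocol-contract tests (the contracts are
    independent of search quality)."""
    return ld.ProtocolConfig(
        docking=ld.DockingConfig(n_runs=2, n_steps=60, opt_budget=120, seed=5)
    )
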