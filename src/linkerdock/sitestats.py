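"""Region assignment, background statistics and significance calls.

A pose is assigned to a binding-site category from the annotated regions it
touches: ``pocket`` (effector-binding pocket only), ``linker`` (disordered
linker only), ``bridging`` (linker plus another region — the ligand connects
the linker to the structured domain), or ``nonspecific`` (no annotated
region).  Nonspecific ΔG values pooled across conformers of one
protein–ligand pair form the background; a complex is called significant
when its ΔG is stronger than the background mean by at least k standard
deviations (k = 3 by default, boundary inclusive, on the affinity-strength
axis where more negative is stronger).

Group comparisons use the Mann–Whitney U test (exact enumeration for small
groups, normal approximation with tie and continuity corrections otherwise)
after checking normality with Shapiro–Wilk — the conventional pairing when
pooled affinity sets are non-Gaussian.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .sequential import SequentialRun
from .structures import Complex, Ligand, RegionAnnotation

POCKET = "pocket"
LINKER = "linker"
BRIDGING = "bridging"
NONSPECIFIC = "nonspecific"

#: categories excluded from the nonspecific background pool
SPECIFIC_CATEGORIES = frozenset({POCKET, LINKER, BRIDGING})


@dataclass(frozen=True)
class RegionParams:
    contact_max: float = 4.0  # Å; an H-bond (<= 3.6 Å) always implies contact


@dataclass(frozen=True)
class RegionLabel:
    category: str
    regions_touched: frozenset[str]


@dataclass(frozen=True)
class BackgroundStats:
    mean: float
    sd: float
    n: int
    ligand_species: str = ""


@dataclass(frozen=True)
class OccupancySummary:
    region_name: str
    mean_count: float
    sd_count: float
    n_models: int


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str
    n1: int
    n2: int

    def __post_init__(self):
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p_value outside [0, 1]")


# ---------------------------------------------------------------------------
# Region assignment
# ---------------------------------------------------------------------------


def assign_region(ligand: Ligand, complex_: Complex,
                  annotations: Sequence[RegionAnnotation],
                  params: RegionParams | None = None) -> RegionLabel:
    """Label one placed ligand copy by the annotated regions it touches.

    A region is touched when any ligand heavy atom lies within
    ``contact_max`` of any atom of a region residue; because the H-bond
    distance cap is below ``contact_max``, an H-bond to a region residue
    always implies touching.
    """
    params = params or RegionParams()
    index = complex_.protein.residue_index()
    known = {(key[0], key[1]) for key in index}
    lig_coords = np.array([a.coords for a in ligand.atoms if a.element != "H"])
    touched: set[str] = set()
    for ann in annotations:
        missing = ann.members - known
        if missing:
            raise ValueError(f"region {ann.region_name!r} references residues absent "
                             f"from the model: {sorted(missing)[:5]}")
        region_coords = []
        for key, res in index.items():
            if (key[0], key[1]) in ann.members:
                region_coords.extend(a.coords for a in res.atoms)
        region_coords = np.asarray(region_coords)
        if len(region_coords) == 0:
            continue
        diff = lig_coords[:, None, :] - region_coords[None, :, :]
        if np.sqrt((diff * diff).sum(axis=-1)).min() <= params.contact_max:
            touched.add(ann.region_name)

    if not touched:
        category = NONSPECIFIC
    elif LINKER in touched:
        category = BRIDGING if len(touched) > 1 else LINKER
    else:
        # any non-linker annotated region counts as the structured-domain pocket side
        category = POCKET
    return RegionLabel(category=category, regions_touched=frozenset(touched))


def label_run(run: SequentialRun, annotations: Sequence[RegionAnnotation],
              params: RegionParams | None = None) -> list[RegionLabel]:
    """Assign a region label to every round of a sequential run (in place on
    the round records, and returned)."""
    labels = []
    new_ids = {f"{run.ligand_species}_{rec.round_index}" for rec in run.rounds}
    by_id = {lig.ligand_id: lig for lig in run.final_complex.ligands if lig.ligand_id in new_ids}
    for rec in run.rounds:
        lig = by_id[f"{run.ligand_species}_{rec.round_index}"]
        label = assign_region(lig, run.final_complex, annotations, params)
        rec.region_label = label
        labels.append(label)
    return labels


def records_from_runs(runs: Iterable[SequentialRun]) -> pd.DataFrame:
    """Flatten labeled runs into one record per (model, round)."""
    rows = []
    for run in runs:
        for rec in run.rounds:
            if rec.region_label is None:
                raise ValueError(f"run {run.model_id}: rounds are unlabeled; call label_run first")
            rows.append({
                "model_id": run.model_id,
                "time_label_ns": run.time_label_ns,
                "ligand_species": run.ligand_species,
                "round": rec.round_index,
                "delta_g": rec.delta_g,
                "category": rec.region_label.category,
            })
    return pd.DataFrame(rows, columns=["model_id", "time_label_ns", "ligand_species",
                                       "round", "delta_g", "category"])


# ---------------------------------------------------------------------------
# Background statistics and the k-SD significance criterion
# ---------------------------------------------------------------------------


def compute_background(records: pd.DataFrame, ligand_species: str = "",
                       label_column: str | None = None) -> BackgroundStats:
    """Pooled nonspecific background: mean and sample SD (n−1 denominator)
    of ΔG over all records whose label is outside the specific categories
    (pocket / linker / bridging)."""
    if label_column is None:
        label_column = "category" if "category" in records.columns else "region"
    mask = ~records[label_column].isin(SPECIFIC_CATEGORIES)
    values = records.loc[mask, "delta_g"].to_numpy(dtype=float)
    if len(values) < 2:
        raise ValueError(f"need >= 2 nonspecific records for a background, got {len(values)}")
    return BackgroundStats(mean=float(values.mean()),
                           sd=float(values.std(ddof=1)),
                           n=len(values),
                           ligand_species=ligand_species)


def flag_significant(delta_g: float, bg: BackgroundStats, k: float = 3.0) -> bool:
    """True iff the affinity is stronger (more negative) than the background
    mean by at least k standard deviations; the boundary itself is flagged.
    With a degenerate sd of 0 only strictly stronger ΔG is flagged."""
    if bg.sd == 0.0:
        return delta_g < bg.mean
    return delta_g <= bg.mean - k * bg.sd


def occupancy_summary(runs: Iterable[SequentialRun], region_name: str) -> OccupancySummary:
    """Ligands-per-model occupancy of one category over labeled runs.

    Bridging poses touch the linker by definition, so they count toward
    linker occupancy.
    """
    counts = []
    for run in runs:
        c = 0
        for rec in run.rounds:
            if rec.region_label is None:
                raise ValueError("rounds are unlabeled; call label_run first")
            cat = rec.region_label.category
            if cat == region_name or (region_name == LINKER and cat == BRIDGING):
                c += 1
        counts.append(c)
    if not counts:
        raise ValueError("no runs")
    arr = np.array(counts, dtype=float)
    sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
    return OccupancySummary(region_name=region_name, mean_count=float(arr.mean()),
                            sd_count=sd, n_models=len(arr))


# ---------------------------------------------------------------------------
# Group-comparison tests
# ---------------------------------------------------------------------------


def _u_statistic(pooled_ranks: np.ndarray, idx_a: Sequence[int], n1: int) -> float:
    return float(pooled_ranks[list(idx_a)].sum() - n1 * (n1 + 1) / 2)


def mann_whitney(group_a: Sequence[float], group_b: Sequence[float],
                 mode: str = "exact") -> TestResult:
    """Two-sided Mann–Whitney U test with midrank ties.

    ``exact`` enumerates all C(n1+n2, n1) group labelings (limited to
    n1+n2 <= 12); ``normal_approx`` uses the normal approximation with tie
    and continuity corrections.  The reported statistic is
    min(U_A, U_B), the conventional small-U.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    n1, n2 = len(a), len(b)
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)  # midranks
    u_a = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2)
    u_b = n1 * n2 - u_a
    mu = n1 * n2 / 2.0

    if mode == "exact":
        if n1 + n2 > 12:
            raise ValueError("exact mode limited to n1+n2 <= 12")
        n = n1 + n2
        obs_dev = abs(u_a - mu)
        count = 0
        total = comb(n, n1)
        for idx in combinations(range(n), n1):
            u = _u_statistic(ranks, idx, n1)
            if abs(u - mu) >= obs_dev - 1e-12:
                count += 1
        p = count / total
        method = "mann-whitney-exact"
    elif mode == "normal_approx":
        n = n1 + n2
        _, tie_counts = np.unique(pooled, return_counts=True)
        tie_term = float(((tie_counts ** 3) - tie_counts).sum())
        var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
        if var <= 0:
            p = 1.0  # all values tied: no evidence of a shift
        else:
            z = max(abs(u_a - mu) - 0.5, 0.0) / np.sqrt(var)
            p = min(1.0, 2.0 * sps.norm.sf(z))
        method = "mann-whitney-normal"
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return TestResult(statistic=min(u_a, u_b), p_value=float(p), method=method, n1=n1, n2=n2)


def normality_test(values: Sequence[float]) -> TestResult:
    """Shapiro–Wilk normality test (3 <= n <= 5000).

    A constant sample has no defined W and raises, matching the degenerate
    contract documented in the methods note.
    """
    x = np.asarray(values, dtype=float)
    if len(x) < 3:
        raise ValueError("Shapiro–Wilk needs n >= 3")
    if len(x) > 5000:
        raise ValueError("Shapiro–Wilk limited to n <= 5000")
    if np.ptp(x) == 0.0:
        raise ValueError("constant sample: normality test undefined")
    w, p = sps.shapiro(x)
    return TestResult(statistic=float(w), p_value=float(min(max(p, 0.0), 1.0)),
                      method="shapiro-wilk", n1=len(x), n2=0)


# ---------------------------------------------------------------------------
# Heat-map export
# ---------------------------------------------------------------------------


def heatmap_table(runs: Sequence[SequentialRun], bg: BackgroundStats,
                  k: float = 3.0) -> pd.DataFrame:
    """Heat-map analog: rows = docking rounds, columns = snapshot time
    labels, cells = ``ΔG|category|flag`` where flag ``*`` marks affinities
    beyond the k-SD significance cutoff (the bold values of a printed map).
    """
    if not runs:
        raise ValueError("no runs")
    n_rounds = max(rec.round_index for run in runs for rec in run.rounds)
    columns = {}
    for run in sorted(runs, key=lambda r: r.time_label_ns):
        col = []
        by_round = {rec.round_index: rec for rec in run.rounds}
        for r in range(1, n_rounds + 1):
            rec = by_round.get(r)
            if rec is None:
                col.append("")
                continue
            if rec.region_label is None:
                raise ValueError("rounds are unlabeled; call label_run first")
            flag = "*" if flag_significant(rec.delta_g, bg, k) else ""
            col.append(f"{rec.delta_g:.2f}|{rec.region_label.category}|{flag}")
        columns[f"{run.time_label_ns:g}ns"] = col
    df = pd.DataFrame(columns, index=pd.RangeIndex(1, n_rounds + 1, name="round"))
    return df


def write_heatmap(runs: Sequence[SequentialRun], bg: BackgroundStats, path,
                  k: float = 3.0) -> None:
    heatmap_table(runs, bg, k).to_csv(path, sep="\t")
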