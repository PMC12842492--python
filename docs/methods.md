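# Methods

This note documents the models, numerical choices and limitations of the
`linkerdock` pipeline in the package's own terms.  Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Scope and assumptions

The pipeline treats the receptor as rigid within one docking round; protein
flexibility enters only through the conformer ensemble (one pose search per
snapshot).  Ligand flexibility is full rigid-body freedom plus rotation
about every rotatable bond.  All geometry is heavy-atom only: docked poses
carry no hydrogens, so hydrogen-bond donors/acceptors are typed from
residue/atom-name tables (proteins) and bond topology (ligands) rather than
from explicit protons, and the H-bond criterion is purely distance-based by
default.  Waters are dropped on input; metals are kept and typed `metal`
(treated as donors in the polar pair term).

## Scoring

The score is the classical empirical pair potential over surface distance
s = d − rᵢ − rⱼ with fixed van der Waals radii (C 1.9, N 1.8, O 1.7, S 2.0,
P 2.1 Å; 1.8 Å otherwise).  Default weights: gauss1 −0.035579,
gauss2 −0.005156, repulsion 0.840245, hydrophobic −0.035069,
hbond −0.587439, rotatable-bond coefficient 0.05846, cutoff 8 Å on s.
Hydrophobic ramp: 1 for s < 0.5 Å, 0 for s > 1.5 Å, linear between.  H-bond
ramp: 1 for s < −0.7 Å, 0 for s > 0, linear between.  These published
defaults keep outputs on the familiar kcal/mol docking scale; all weights
are configurable and serialisable to YAML.

Two deliberate simplifications, both documented limitations:

- **No ligand intramolecular term.**  Poses are kept clash-free by the
  search constraints instead (no receptor–ligand heavy-atom pair below
  2.0 Å; ligand generators guarantee internally clash-free geometry).
- **No numeric parity** with any binary of the original docking tools is
  claimed; the functional form and weights are the same, grids and
  conformer handling are not.

Previously placed ligand copies are scored exactly like receptor atoms and
contribute no rotatable-bond penalty — only the mobile ligand's N_rot
enters the denominator.

## Pose search

Blind docking over the receptor bounding box expanded by 6 Å per side.
Containment rule: the ligand centroid must stay inside the box; atoms may
protrude at most 2 Å (avoids edge artifacts).  The search runs
`n_runs` = 8 independent restarts (the exhaustiveness analog) of
`n_steps` = 250 Metropolis steps at an acceptance scale of 1.2 kcal/mol,
with per-step Gaussian perturbations (0.75 Å translation, 0.25 rad
rotation, 30° per torsion), followed by Nelder–Mead refinement of each
restart's best state (≤ 400 evaluations; clash and containment violations
enter the objective as steep linear penalties).  Restart r uses seed
`config.seed + r`, so parallel and serial execution agree and equal
configurations are bitwise reproducible.  Equal-ΔG poses (to 1e-6) are
ranked by lexicographic translation order.

These search sizes are the package's desk-scale defaults, chosen so that a
full ten-round sequential run on the synthetic two-domain protein completes
in well under a minute on one CPU while recovering the analytic optimum of
the two-atom reference system in ≥ 95% of seeded attempts (measured by the
acceptance script at 100 attempts).

## Sequential protocol

Ten rounds by default.  Round k docks a fresh copy against protein +
copies from rounds < k; the most negative-ΔG pose is frozen (frozen copies
never move; the protein is never modified).  The docking box is derived
once from the bare protein and reused for all rounds — re-deriving it per
round would let the box drift as ligands accumulate.  Round k uses seed
`base + 1000·k` for independence across rounds and full determinism.  The
retained-subset control strips chosen rounds from a finished complex and
reruns a complete fresh protocol against the partially occupied receptor;
with nothing retained it reduces exactly to a from-scratch run.

## Interaction profiling

Heavy-atom H-bond criterion: donor-capable vs acceptor-capable classes
within 3.6 Å, intermolecular pairs only (protein–ligand and distinct ligand
copies).  The 3.6 Å cap is deliberately stricter than hydrogen-aware
donor–acceptor limits (≈ 4.1 Å) because without protons the angle test is
unavailable; this trades recall for false-positive control and is
configurable.  When both partners are ambivalent (hydroxyl–hydroxyl), the
bond is reported once with the lower atom address as donor — an arbitrary
but deterministic convention.  Ligand clusters are connected components of
the graph with an edge when two copies share an H-bond or any heavy-atom
pair within 4.0 Å; components below 3 members are not reported as clusters
by default.

## Region labels and statistics

A pose touches a region when any heavy atom is within 4.0 Å of a region
residue; since the H-bond cap is below that, H-bonded regions are always
touched.  Category resolution: linker only → `linker`; linker + any other
region → `bridging`; any non-linker annotated region (all treated as the
structured-domain/pocket side) → `pocket`; nothing → `nonspecific`.
Bridging counts toward linker occupancy summaries.

The background pools one ΔG record per (conformer, round) whose label is
outside {pocket, linker, bridging}, across all conformers of one
protein–ligand pair; mean and sample SD (n−1).  Significance:
ΔG ≤ μ − k·σ with k = 3, boundary inclusive, interpreted on the
affinity-strength axis (more negative = stronger).  With σ = 0 only
strictly stronger values are flagged.  No multiple-testing correction is
applied by default (a Bonferroni-style adjustment can be layered on by the
caller); the pipeline reports raw flags.

Mann–Whitney U uses midranks; exact mode enumerates all C(n₁+n₂, n₁)
labelings (limited to n₁+n₂ ≤ 12) and reports the two-sided permutation
p-value on |U − n₁n₂/2|; the normal approximation applies tie and
continuity corrections.  Normality testing is Shapiro–Wilk via the standard
SciPy routine (3 ≤ n ≤ 5000); a constant sample raises instead of returning
an undefined W.

## Sequence alignment

Global Needleman–Wunsch with affine gaps (Gotoh three-state recursion);
a gap of length L costs `gap_open + L·gap_extend`.  Defaults BLOSUM62,
gap_open 10, gap_extend 0.5 — the EMBOSS needle convention.  Traceback ties
resolve diagonal > up > left.  Printed homology scores for specific
transcription-factor domain pairs depend on domain boundary choices that
are not part of this package's contract; the implementation is instead
validated against exhaustive alignment-space enumeration for short
sequences.

## Synthetic data

The toy protein is two ideal α-helical domains (φ = −57°, ψ = −47°; 14
residues each by default) joined by a 10-residue coil linker
(φ = −120°, ψ = 130°), built from ideal internal coordinates (N–CA
1.458 Å, CA–C 1.525 Å, C–N 1.329 Å, trans ω).  Side chains are reduced to
CB, except linker residues which carry a serine-like OG hydroxyl so the
linker offers H-bond anchors.  Per snapshot, only the linker dihedrals are
resampled from a normal law (default SD 15°) around the coil values; a
snapshot is rejected and resampled (up to 1000 attempts) if any non-bonded
CA–CA pair falls below 3.0 Å.  Snapshots are labeled 10, 20, 30 … ns to
mirror an MD sampling grid.  The annotation marks the linker residues as
region `linker` and a small patch in the middle of the second domain as
region `pocket`, standing in for the effector-binding cavity.

The pyranose-like toy sugar is a planar 6-ring (5 C + ring O) with four
hydroxyls and an exocyclic CH₂OH arm — one rotatable bond, six H-bond-
capable oxygens, all bond lengths within 1.2–1.8 Å and no non-bonded pair
below 2.4 Å.  ΔG tables draw a Gaussian nonspecific background and insert
planted records verbatim.  The H-bond fixture places serine hydroxyls
2.9 Å from single-oxygen probes with every other polar pair ≥ 5 Å away,
giving an exact detector ground truth.

What the generators do **not** emulate: real side-chain chemistry and
packing, solvent, a deep effector pocket, charged sugars, and MD force-field
correlations between snapshots.  Passing tests therefore demonstrate the
correctness of the machinery (scoring, search contracts, statistics,
detection) on controlled geometry — not that the pipeline's biological
conclusions transfer to any particular protein.  ΔG magnitudes on the toy
receptor (≈ −2 to −4.5 kcal/mol) are accordingly shallower than on real
proteins.

## Degenerate inputs and tie-breaks

- Empty receptor: every pose scores exactly 0; ranking falls back to the
  deterministic translation order.
- 1–2 point RMSD: the rotation is underdetermined but the superposed RMSD
  is still well defined and returned.
- Zero-noise ensembles collapse to identical snapshots (RMSD profile all
  zeros) by construction.
- Pose ΔG is always recomputed from the placed coordinates before being
  stored, so reported scores can never go stale.

## Known limitations

Rigid receptor within a round; no protonation-state prediction; no solvent
model; no hydrophobic-contact/π-stacking/salt-bridge profiling (only
H-bonds and distance clusters, which is what the downstream statistics
consume); exact Mann–Whitney limited to 12 observations; single-chain
synthetic proteins only (multi-chain input files are fully supported).
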