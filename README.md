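# linkerdock

Sequential carbohydrate docking onto intrinsically disordered protein
linkers, with region-aware statistics that separate genuine binding
preferences from nonspecific surface attachment.

## The problem

GntR-family bacterial transcription factors carry a DNA-binding domain and
an effector-binding domain joined by a flexible, intrinsically disordered
linker.  Whether such linkers can act as sensors for metabolic sugars
(D-glucose, hexuronates, …) is hard to judge from a single docking run:
individual sugar–linker contacts are weak and sit close to the level of
random surface attachment.  The approach implemented here combines three
ingredients:

1. **Conformer ensembles.**  Docking is repeated across snapshots of the
   protein (MD-like conformers differing mainly in linker geometry), since
   a disordered linker exposes different surfaces at different times.
2. **Sequential multi-ligand docking.**  In each round the best-scoring
   ligand copy is frozen into the receptor and a fresh copy is docked
   against the growing complex (ten rounds by default).  This emulates a
   rising ligand concentration and reveals multi-molecular clustering that
   single-ligand docking cannot show.
3. **Background statistics.**  Poses are classified by the annotated
   regions they touch — effector **pocket**, **linker**, **bridging**
   (linker plus structured domain), or **nonspecific**.  The nonspecific
   ΔG values pooled over conformers give a background mean μ and standard
   deviation σ; a pose is called significant when ΔG ≤ μ − 3σ
   (more negative = stronger binding).

## The score

Poses are scored with the empirical Vina-style pair potential over the
surface distance s = d − rᵢ − rⱼ of receptor–ligand heavy-atom pairs:

    c_inter = Σ [ w₁·exp(−(s/0.5)²) + w₂·exp(−((s−3)/2)²) + w_rep·s²·𝟙(s<0)
                + w_hyd·ramp(s; 0.5, 1.5) + w_hb·ramp(s; −0.7, 0) ]
    ΔG = c_inter / (1 + w_rot·N_rot)                        [kcal/mol]

with the published default weights of that scorer, hydrophobic and H-bond
terms gated by per-atom interaction classes, and a rotatable-bond penalty
on the mobile ligand only.  The pose search is iterated Monte Carlo with
Metropolis acceptance plus derivative-free local refinement, over a box
covering the whole protein surface (blind docking).

Everything downstream is geometric and statistical: heavy-atom H-bond
detection, ligand-cluster identification (connected components of the
contact graph), occupancy summaries, Mann–Whitney U comparisons (exact
enumeration for small groups), Shapiro–Wilk normality checks, and global
Needleman–Wunsch alignment with affine gaps for domain-homology
comparisons.

A synthetic-data module generates every input at desk scale: helix–linker–
helix conformer ensembles with resampled linker dihedrals, pyranose-like
toy sugars, H-bond fixtures with known ground truth, and ΔG tables with
planted significant binders.

## Worked example

```python
import linkerdock as ld
from linkerdock.sitestats import (compute_background, label_run,
                                  records_from_runs, flag_significant,
                                  occupancy_summary)

models, regions = ld.make_toy_protein(ld.ToyProteinSpec(n_snapshots=3, seed=61))
sugar = ld.make_toy_ligand("pyranose_like")

runs = []
for i, model in enumerate(models):
    cfg = ld.ProtocolConfig(docking=ld.DockingConfig(seed=29 + 10_000 * i))
    run = ld.run_sequential(model, sugar, cfg)   # ten rounds
    label_run(run, regions)
    runs.append(run)

bg = compute_background(records_from_runs(runs))
occ = occupancy_summary(runs, "linker")
print(f"background: {bg.mean:.2f} +/- {bg.sd:.2f} kcal/mol (n={bg.n})")
print(f"linker occupancy: {occ.mean_count:.1f} +/- {occ.sd_count:.1f} ligands per conformer")
for rec in runs[0].rounds[:3]:
    star = "*" if flag_significant(rec.delta_g, bg) else ""
    print(f"round {rec.round_index}: {rec.delta_g:.2f} kcal/mol "
          f"[{rec.region_label.category}]{star}")
print("largest cluster:", ld.find_clusters(runs[0].final_complex)[0].size, "ligands")
```

prints

```
background: -2.77 +/- 0.33 kcal/mol (n=7)
linker occupancy: 6.0 +/- 1.0 ligands per conformer
round 1: -2.15 kcal/mol [linker]
round 2: -3.24 kcal/mol [linker]
round 3: -3.32 kcal/mol [linker]
largest cluster: 10 ligands
```

The toy linker attracts most sugar copies (6 of 10 rounds per conformer on
average) and the copies aggregate into one contact cluster, while the
per-pose affinities stay near the nonspecific background — the signature
the statistics are designed to resolve.  A `*` after a ΔG marks values
beyond the 3σ significance cutoff.  The ΔG magnitudes of the toy system
are smaller than for a real protein because the synthetic receptor offers
only a shallow, mostly backbone surface.

The same pipeline is available from the shell:

```
linkerdock simulate --out demo --snapshots 3
linkerdock sequential --model demo/toy_10ns.pdb --ligand pyranose_like \
    --annotations demo/regions.yaml --seed 29 --out run.json
linkerdock pipeline manifest.yaml
```

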