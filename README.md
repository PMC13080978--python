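# rnapose

Post-docking analysis for RNA-targeted ensemble docking.

When a small-molecule library is docked against an *ensemble* of RNA
conformations (crystal structure plus frames sampled from enhanced-sampling
MD), the raw output is tens of thousands of poses per compound and no
obvious connection to the experimental affinity series. `rnapose`
implements the analysis layer that turns that pile of poses into an
interpretable structure–affinity story:

1. **Conformational-ensemble curation.** RNA conformations are compared
   with the eRMSD metric, computed from nucleotide g-vectors: each base
   gets a local frame from its C2/C4/C6 ring atoms, the position **r** of
   every other base in that frame is anisotropically rescaled,
   r̃ = (r_x/a, r_y/a, r_z/b) with a = 5 Å, b = 3 Å, and mapped to the
   smooth 4-vector
   **G**(r̃) = ( sin(γρ̃)·r̃/ρ̃ , 1 + cos(γρ̃) ), γ = π/2.4, which vanishes
   for ρ̃ = |r̃| ≥ 2.4. Then
   eRMSD(A,B) = √( (1/N) Σ_{j≠k} |**G**_A(j,k) − **G**_B(j,k)|² ).
   Unlike plain RMSD, this responds specifically to base-pairing
   rearrangements. Frames are grouped by Quality-Threshold (QT) clustering
   on the eRMSD matrix (cutoff 0.7), and cluster medoids are retained only
   if they are mutually farther than 0.7 apart, yielding a small, maximally
   diverse docking ensemble.
2. **Symmetry-corrected pose clustering.** Docked poses of a congeneric
   series are compared on their common scaffold, *in the receptor frame and
   without superposition*, minimising the RMSD over all element- and
   bond-preserving scaffold automorphisms (a two-fold symmetric diamidine
   core has two). QT clustering at 5 Å on this matrix resolves the major
   binding modes; the most populated clusters covering ≥ 50% of poses are
   retained.
3. **Interaction fingerprints.** Seven geometric interaction categories
   (hydrogen bond, halogen bond, lipophilic, cation–anion, π-stacking,
   π-cation, π-anion) are detected between each pose and the RNA and
   histogrammed by contact distance, 2–8 Å in 80 bins, giving one
   7 × 80 bin-count fingerprint per pose.
4. **Affinity trends.** PCA on the fingerprint bins of the retained poses,
   the per-ligand mean PC1 score per cluster, and an OLS regression of
   log10(CD50) on mean PC1 rank the binding modes by how well they
   rationalise the affinity series (R²); the PC1 loadings, reshaped onto
   the category × distance grid, show which contacts at which distances
   drive the trend.

A fully controlled synthetic generator (idealised RNA helix, perturbed
ensembles, a symmetric-scaffold congeneric series, pose sets with a planted
interaction–affinity signal at a calibrated target R²) makes every stage
testable without any external data.

## Worked example

```python
from rnapose import (PlantedScenario, make_idealized_helix,
                     make_congeneric_series, plant_pose_set,
                     run_pipeline_objects, loading_profile)

scenario = PlantedScenario(seed=1)          # 15 ligands x 200 poses,
rna = make_idealized_helix(44, seed=1)      # 3 binding modes, one carrying
series, _ = make_congeneric_series(15, 1)   # an R^2 = 0.85 affinity signal
poses, affinities, truth = plant_pose_set(rna[0], series, scenario)

report, outputs = run_pipeline_objects(
    rna, poses, affinities, None, site_residues={"S1": list(range(15, 31))})
```

prints (via the summary fields of `report` and the PC1 loading profile):

```
pose clusters (sizes): [1200, 1050, 750]
retained clusters:     [0, 1] (75% of poses)
top cluster:           0 (planted signal cluster: 0)
affinity trend:        R^2 = 0.85 over 13 ligands
PC1 loading span:      hydrogen_bond  2.60-3.80 A  sign +1
PC1 loading span:      lipophilic     4.70-6.72 A  sign -1
PC1 loading span:      cation_anion   3.50-3.88 A  sign +1
```

The three planted spatial modes are recovered exactly by QT clustering at
5 Å; the coverage rule keeps the two largest (75% of poses); the cluster
carrying the planted signal ranks first with R² = 0.85 over the 13 ligands
that have numeric CD50 values (two are ">500 μM" and excluded); and the
PC1 loadings say *why*: hydrogen bonds and cation–anion contacts load
positively (more of them → stronger binding), lipophilic contacts load
negatively — the planted chemistry.

The same pipeline runs from files via the CLI:

```bash
rnapose synth --seed 1 --out fixtures/        # write PDB/SDF/CSV/YAML inputs
rnapose run   --config pipeline.yaml          # full staged run
# or stage by stage:
rnapose ingest | rnametrics | curate | cluster-poses | fingerprints | trends
```

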