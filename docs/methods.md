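# Methods

This note documents the models and procedures implemented in `rnapose`,
the parameter choices that matter, what the synthetic benchmark does and
does not emulate, and the numerical conventions a user relying on the
outputs should know.

## eRMSD and g-vectors

Each nucleotide receives a local orthonormal frame built from its C2/C4/C6
ring atoms: origin at their centroid, x toward C2, y the component of the
origin→C4 vector orthogonal to x, z = x × y. The same three-atom rule is
used for purines and pyrimidines; the pipeline needs internal consistency
across conformations of the *same* molecule, not bit-compatibility with
any external tool, and C2/C4/C6 is the minimal atom set shared by all four
bases.

For an ordered residue pair (j, k), the origin of k expressed in frame j
is rescaled anisotropically, r̃ = (r_x/a, r_y/a, r_z/b), reflecting that
base-base interactions reach farther in the base plane than normal to it.
Defaults a = 5 Å, b = 3 Å and cutoff ρ̃ < r_cut = 2.4 are the established
constants of the metric; they are exposed in `ErmsdParameters` for
sensitivity analysis. Inside the cutoff the pair contributes

G(r̃) = ( sin(γρ̃)·r̃_x/ρ̃, sin(γρ̃)·r̃_y/ρ̃, sin(γρ̃)·r̃_z/ρ̃, 1 + cos(γρ̃) ),
γ = π/r_cut,

and zero outside; all four components go smoothly to zero at the cutoff,
so the metric is continuous as contacts form and break. **Normalisation
convention:** the components are used exactly as written above, with no
additional 1/γ factor, and eRMSD(A,B) = √((1/N)·Σ_{j≠k}|ΔG|²) with N the
*residue* count. The pipeline's working thresholds (QT cutoff 0.7,
centroid-retention cutoff 0.7) are calibrated to this convention; values
in the 0.7–0.8 range and above indicate changed base-base arrangements on
this scale. Published eRMSD values computed under a 1/γ-scaled convention
differ by a constant factor γ ≈ 1.31 and should not be compared digit for
digit.

Site-restricted conformational features concatenate the G vectors of all
ordered pairs within a binding-site residue list in fixed lexicographic
order (4·m·(m−1) features for m residues), which feeds the same PCA
machinery used for fingerprints.

Heavy-atom RMSD uses Kabsch superposition (centroid removal + optimal
least-squares rotation) over all non-hydrogen atoms of the selection; an
independent quaternion (Horn) implementation serves as the test oracle.

## Quality-Threshold clustering

QT clustering on a precomputed distance matrix is used twice: on the
eRMSD matrix of ensemble frames (threshold 0.7) and on the pose distance
matrix (threshold 5 Å). The algorithm is deterministic: grow one candidate
cluster from every remaining item, commit the largest (ties: lowest seed
index), remove its members, repeat. Within a committed cluster the
*diameter* — the maximum pairwise distance — never exceeds the threshold.

A subset of diameter ≤ t is exactly a clique of the graph that connects
items closer than t. Greedy diameter growth (repeatedly adding the item
that minimally increases the diameter) is the traditional heuristic, but
it is not always optimal even at n ≈ 10. Candidate growth here is
therefore *exact* — a deterministic branch-and-bound maximum clique over
the seed's neighbourhood — whenever that neighbourhood has ≤ 30 items, and
falls back to greedy growth for larger neighbourhoods, where exhaustive
search is infeasible and where, in the intended regime (well-separated
binding modes whose members are mutually within threshold), greedy growth
is exact anyway. The suite verifies exactness against full subset
enumeration on random matrices at n ≤ 12.

Cluster "centroids" on a distance matrix are medoids (minimum summed
distance to the rest of the cluster; ties to the lowest index).
Diverse-centroid retention scans centroids in descending parent-cluster
size and keeps one only if it is farther than the retention cutoff from
every centroid already kept — the largest cluster's medoid is always
retained. The scan order is a design choice (larger clusters are more
representative); a simultaneous all-pairs formulation would be
order-free but can discard the dominant cluster, which contradicts the
purpose of the rule. Coverage selection returns the shortest prefix of
size-ordered clusters whose cumulative population reaches the requested
fraction (default 0.5).

## Symmetry-corrected pose distances

Pose–pose distances are computed on the scaffold atoms common to the
congeneric series, **in the receptor coordinate frame, without
superposition**: docked poses share the receptor frame, and superposing
pose pairs would erase exactly the placement information that
distinguishes binding modes. A superposed variant exists behind
`superpose=True` for sensitivity analysis only.

Scaffold symmetry is handled by enumerating all element-preserving
automorphisms of the scaffold bond graph (VF2 on the coloured graph,
deterministic ordering, hard cap 10,000) and taking the minimum RMSD over
permutations. For the two-fold symmetric diamidine-like core this is
identity + arm swap; for para-substituted symmetric arms the correction is
essential — the arm-swapped copy of a pose is the *same* physical pose and
must be at distance zero. Because in-frame RMSD is a scaled Euclidean
distance of flattened coordinates, the full matrix is computed with one
`cdist` per permutation and an elementwise minimum, and the result is
symmetric because an automorphism group is closed under inversion.

## Interaction typing and fingerprints

Seven categories are detected with distance and (where geometry permits)
angular criteria. The rule table is a documented package choice,
overridable via `RuleTable`:

| category | partners | cutoff | angular criterion |
|---|---|---|---|
| hydrogen bond | N/O donor → N/O acceptor (both directions) | D···A ≤ 3.9 Å | D–H···A ≥ 100° when an explicit H is present |
| halogen bond | C–X (X = Cl/Br/I) → acceptor | X···A ≤ 4.0 Å | C–X···A ≥ 140° |
| lipophilic | apolar ligand C → RNA base C | recorded to 8 Å; ≤ 4.5 Å flagged as core | — |
| cation–anion | charged-group centroids | ≤ 5.5 Å | — |
| π-stacking | ring centroids | ≤ 5.5 Å | interplanar ≤ 30° or 60–90°, lateral offset ≤ 2.5 Å |
| π-cation | cation ↔ ring centroid | ≤ 6.0 Å | charge–centroid vs normal ≤ 40° |
| π-anion | anion ↔ ring centroid | ≤ 5.5 Å | same as π-cation |

RNA centers come from a built-in dictionary: Watson–Crick/Hoogsteen edge
donors and acceptors per base (e.g. G: donors N1/N2, acceptors O6/N3/N7),
the 2'-hydroxyl as donor and acceptor, and the two non-bridging phosphate
oxygens as anion centers *and* acceptors. Ligand typing needs only
elements, bonds and formal charges; a positively charged atom is merged
with an adjacent C(N,N) resonance group (amidinium/guanidinium) into one
cation center at the group centroid. When a molecule carries no explicit
hydrogens (the usual case for both RNA inputs and docked poses),
hydrogen-bond detection is distance-only; this is logged, not silently
assumed. Lipophilic contacts are recorded over the full histogram range
rather than truncated at the classic 4.5 Å, because the *distance
structure* of apolar packing (peaks near 5 Å) is itself informative in the
fingerprint; the core flag preserves the conventional definition.

Each detected interaction carries one characteristic distance (D···A,
X···A, C···C, charge–charge, centroid–centroid, charge–centroid); the
per-pose fingerprint histograms these per category from d_min = 2 Å to
d_max = 8 Å in 80 bins (width 0.075 Å), category order frozen as listed
above, flattened to 560 features. Instance counting is used: one increment
per detected center pair, not per pose–residue pair. Row sums therefore
equal in-range interaction counts exactly — the conservation property the
suite asserts.

## Trend analysis

PCA is mean-centred, unscaled (bin counts share units), with a
deterministic sign convention: each component's largest-magnitude loading
is positive. The sign of PC1 is therefore an artefact of that convention;
slopes are reported alongside R² and may flip between datasets without
meaning. After pose clustering, PCA is *refit* on the retained-cluster
subset — restricting to coherent binding modes concentrates variance in
the leading components.

Per (cluster, ligand) cells with fewer than `min_poses = 3` poses are
treated as missing (too few poses to define a mode-specific score). The
regression is OLS of affinity on mean PC1, with R² the squared Pearson
correlation. Affinity enters as log10(CD50) by default — the series spans
orders of magnitude, and log-scale residuals are the natural error model —
with raw CD50 available. Out-of-range (">500 μM") ligands are excluded by
default; capping them at the assay bound is available as a sensitivity
option, and neither choice is presented as canonical. Degenerate inputs
are defined, not crashed: constant response → R² = 0 with a warning;
constant predictor or < 3 usable ligands → error. Clusters are ranked by
descending R²; the top cluster is the one whose binding mode best
rationalises the series.

Loading profiles reshape a component onto the 7 × 80 grid and report, per
category, the contiguous bin run around the category's peak where
|loading| ≥ 30% of the global maximum, as a distance span in left bin
edges. The 30% threshold is a reporting choice: low enough that a
secondary category with genuine signal (cation–anion alongside dominant
hydrogen bonding) is reported, high enough to suppress noise bins.

## Synthetic benchmark: what it emulates, and what it does not

The generators produce *controlled abstractions*, not imitation data:

- `make_idealized_helix` — stacked planar six-rings on a regular helix
  (rise 2.8 Å, twist 32.7°, base centres 4 Å and phosphates 7 Å off-axis),
  alternating A/U with two G–C pairs mid-sequence, plus per-base
  donor/acceptor decorations and OP1/OP2. Deterministic.
- `perturb_ensemble` — per-base random rotations (sd in degrees) and
  translations about each base's frame origin, a stand-in for MD frame
  variability. Mean eRMSD to the reference grows monotonically with the
  perturbation magnitude, which the suite checks.
- `make_congeneric_series` — a rigid two-arm scaffold (two pyridine-like
  rings, N–C–N linker) whose bond graph has exactly two automorphisms;
  every ligand carries the full substituent decoration (12 neutral polar
  N, 8 charged N, 10 apolar C) at fixed topological positions so that any
  planted interaction count is realisable for any ligand without
  saturation bias. Ligands are abstract topologies with valid elements,
  charges and bonds — bond lengths are not physical and no real chemistry
  is imitated.
- `plant_pose_set` — poses in `n_clusters` spatial modes around the helix
  (120° azimuthal spacing keeps inter-mode scaffold RMSD far above the
  5 Å threshold; per-pose jitter of 0.5 Å / 5° keeps intra-mode diameters
  well below it). Per pose, a number of substituents is *engaged* —
  placed at interaction range from an RNA partner (polar N at 2.8–3.4 Å
  from base/sugar acceptors; charged groups at 3.2–3.8 Å from the OP1/OP2
  midpoint, a bidentate salt bridge; apolar C at 3.4–4.4 Å from base
  carbons) — and the rest parked > 8 Å from all RNA atoms. Engaged counts
  are binomial with means linear in a per-ligand driver: in the signal
  cluster the driver is the calibrated affinity signal (hydrogen-bond and
  cation–anion rates increase with affinity, lipophilic rates decrease);
  in the other clusters it is an affinity-independent per-ligand random
  level, so those modes carry realistic variance but no signal.

**Calibration.** The target R² is enforced at generation time: the driver
is √r²·ŝ + √(1−r²)·δ̂, where ŝ is the standardised −log10(CD50) and δ̂ a
noise vector empirically orthogonalised and standardised against ŝ over
the ligands with numeric affinities (out-of-range ligands do not enter the
default regression, so calibration matches the evaluated subset). The
squared correlation between driver and log-affinity is therefore exactly
r² at the rate level; the pipeline adds only pose-sampling and
PCA-estimation noise on top, so the recovered R² fluctuates narrowly
around the target.

What passing the planted benchmark does **not** show: that the rule-table
cutoffs are optimal for real RNA–ligand complexes, that PC1 of real
fingerprints is affinity-aligned (here it is by construction dominant),
or that real docking poses form well-separated modes. The benchmark
validates the *machinery* — metric correctness, clustering exactness,
bookkeeping, conservation, and the end-to-end statistical plumbing —
under known ground truth.

Default problem sizes (15 ligands × 200 poses × 3 modes, 44-residue
helix, 10-model ensembles) were chosen so a full planted pass takes
seconds on one core while keeping ≥ 50 poses per (ligand, cluster) cell,
enough that binomial noise averages out against the planted signal.

## Numerical conventions and degenerate inputs

- Distance matrices must be symmetric within 1e-9 with an exactly zero
  diagonal; the pose matrix is symmetrised by an elementwise min with its
  transpose before validation (pure floating-point guard).
- Histogram binning is half-open, floor((d − d_min)/width), with d =
  d_max excluded; a contact at exactly d_max − ε stays in the last bin.
- PCA uses the full SVD solver; zero-variance input returns zero scores
  and loadings with a warning rather than an error, so an all-identical
  pose set propagates as "no structure" instead of crashing a batch run.
- All generators take explicit seeds; the pipeline itself contains no
  randomness, so identical config + inputs reproduce identical outputs.

## Known limitations

- Interaction geometry for RNA donors is distance-only (RNA inputs
  normally lack hydrogens); a donor-orientation criterion would need
  hydrogen placement, which is out of scope.
- The automorphism cap (10,000) rejects pathological scaffolds; supply an
  explicit permutation list for such cases.
- mmCIF and binary trajectory formats are not read; multi-MODEL PDB is
  the ensemble interchange format.
- QT growth is exact only for neighbourhoods ≤ 30 items; above that the
  greedy heuristic can in principle under-grow a candidate on adversarial
  matrices with large, strongly overlapping near-cliques.
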