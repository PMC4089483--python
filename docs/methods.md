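# Methods

This note records the model behind `blobid`, the defaults that matter,
what the synthetic data do and do not emulate, and the choices made where
the design was genuinely open. Units are Angstrom (Å) throughout unless
stated.

## Density model and the synthetic simulator

Maps are regular 3D scalar fields on orthogonal P1 grids, canonically
ordered X-fastest, read and written as MRC2014/CCP4 volumes through
`gemmi` (arbitrary on-disk axis orders are permuted on read; non-orthogonal
cells are rejected as a documented limitation). Map values are never
rescaled; every threshold in the pipeline is relative to `sigma_level`,
the standard deviation of the map over the whole grid. How experimental
difference maps are absolutely scaled varies between programs, so
absolute-scale behaviour is untested.

The simulator renders each heavy atom as an isotropic Gaussian of peak
height Z (the atomic number) and width

    s = 0.25 × nominal resolution,

sampled at 0.3 Å spacing on a grid padded 4 Å beyond the atoms, with the
origin snapped to the spacing lattice so whole-voxel scene shifts move
the field exactly. Seeded Gaussian noise with SD = `noise_frac` × peak is
added afterwards and `sigma_level` is recomputed from the noisy field.
Two equal Gaussians merge into a single maximum exactly when their
separation is ≤ 2s, so with this width bonded atoms (1.4–1.5 Å apart)
are cleanly resolved at 1.0 Å resolution while short bonds (≈1.2 Å) blur
together by 2.5 Å; typical C–C separations remain marginally resolved at
2.5 Å, which is optimistic relative to experimental maps (see
*Limitations*). The refinement module reuses the identical kernel for
model density, so a correctly posed ligand in a noise-free synthetic map
reaches RSCC ≈ 1 by construction.

What the simulator does **not** emulate: Fourier series truncation
ripples, solvent flattening artifacts, anisotropy, model-phase bias,
crystallographic symmetry and packing neighbours, and experimental
scale/B-factor effects. Passing tests therefore demonstrate the internal
consistency and resolution dependence of the method, not its performance
on deposited PDB data.

## Sparse-grid construction

Free atoms are placed greedily: candidate voxels are those with density
≥ 1.0 × `sigma_level` (the contour level at which difference blobs are
conventionally displayed; configurable), the first atom is the densest
candidate within 5 Å of the user's approximate blob location, and each
subsequent atom is the densest remaining candidate lying 1.2–1.7 Å from
an already-placed atom and ≥ 1.2 Å from all of them, up to a cap of 250.
Greedy densest-first placement is deterministic, which the original
"biased towards higher density" wording leaves open. The 2.0 Å cluster
selection, the σ-profile thinning (sample SD with n−1 denominator over
the three successive differences; peaks = strict maxima in a ±3-index
window exceeding mean + 1 SD of the σ sequence, at most five), and the
2.3 Å re-clustering follow the four-step procedure directly. Grids with
fewer than 3 points are discarded. When no σ-peak qualifies, the single
grid retaining every clustered atom is returned.

Grid quality is scored by a *symmetric* nearest-neighbour RMSD,

    NNRMSD(A, B) = sqrt[(Σ_{a∈A} min_b |a−b|² + Σ_{b∈B} min_a |b−a|²) / (|A|+|B|)],

penalizing both missing and spurious points; the one-sided form would
reward degenerate grids.

A known failure mode: at high resolution with a hard density floor the
blob can fragment into per-atom islands more than 1.7 Å apart, and the
placement chain cannot jump the gap (the neighbour invariant forbids it).
Roughly a third of noise-free scenes of large, extended ligands at
≤1.3 Å show this; modest map noise and the 5 Å seed snap usually rescue
real cohorts, and the per-case table flags such cases via their
atom/grid-point ratio.

## The 22 descriptors

Order: 11 moment invariants, chirality, 2 distance features, 4
connectivity features, 3 centroid-distance moments, atom count. All are
invariant to translation and rotation; only connectivity and atom count
are conformation-invariant. Moment tensors are averaged per point, so the
descriptors depend on shape, not on how many atoms express it; no spatial
rescaling is applied (size in the spatial sense is a legitimate signal —
the atom-count feature and normalization handle the count sense).

The moment-invariant basis (full contractions of the per-point second-
and third-order central moment tensors S and T, with V_i = T_ijj,
W_k = S_ij T_ijk, M_il = T_ijk T_ljk):

    tr S, tr S², det S, T:T, V·V, V·S·V, W·V, W·W, tr(M S), W·S·W, V·S²·V

Each is reported as its signed d-th root (d = its degree in length) so
all eleven are in Å and numerically commensurable. The chirality index is
the signed 15th root of det[V W U] with U_k = (S²)_ij T_ijk; under an
improper rotation each of the three vectors gains one sign flip, so the
determinant is a pseudoscalar, and for planar sets all three vectors lie
in the plane, so it vanishes. Collinear sets are degenerate: the three
second-order invariants are computed, the third-order ones report 0.

Connectivity features are the two smallest and two largest eigenvalues of
the Burden matrix: atomic number on the diagonal (the carbon-equivalent
constant 6 for pseudo-atoms — free atoms carry no element identity at
these resolutions), 0.1 × bond order off-diagonal for bonded pairs and
0.001 otherwise. Pseudo-bonds connect grid points within 1.8 Å — wide
enough to span the 1.2–1.7 Å attachment window, narrow enough not to
bridge the 2.3 Å cluster linkage. For point sets smaller than four, the
four slots are filled by duplicating the extreme eigenvalues.

Centroid-distance moments use bias-uncorrected sample formulas
(population variance, skewness m₃/m₂^1.5, excess kurtosis m₄/m₂²−3); a
degenerate distribution (all points on a sphere about the centroid)
reports (0, 0, 0). Feature vectors are defined down to three points via
the degenerate rules, so even heavily thinned grids of 5-atom ligands
can be ranked.

## Matching and weight training

Database entries (up to 200 conformers per ligand; 50 in the screening
configuration) are z-scored with statistics fitted over all entries, which
turns the feature covariance matrix into a correlation matrix. Initial
weights take each feature's share of the variance explained by the five
leading principal components, raw_i = Σ_{j≤5} λ_j u_{j,i}², normalized to
sum 1; exactly degenerate eigenvalues that straddle the five-component
boundary share their group's allocation fractionally, making the result
basis-independent. The published form of this initialization survives
only in prose, so the formula above is a declared reconstruction.

The per-feature "score" is |Δz| and the combination is the weighted L1
distance — L1 is robust to a single wildly mismatched feature, e.g. the
atom count when a grid over- or under-samples the ligand. A ligand's
composite is the **minimum** over its conformers × all grids ("min" vs
"mean" is a config switch; min performed better and matches the goal of
finding the correct ligand in the correct conformation on the
best-thinned grid). Ties break by ligand code.

Cross-entropy training samples weight vectors around a running mean
(population 60, elite 10, 40 iterations, initial SD 0.3, clipped to the
simplex), maximizing the mean reciprocal rank of the true ligand —
reciprocal rank was chosen over alternatives because top-1 placement is
what the final refinement stage consumes. Each training case contributes
its single best grid (lowest NNRMSD to the known true coordinates);
ground truth is available during training by construction. The best-ever
vector is returned, so training can never underperform its
initialization on the training cases.

## Flexible alignment (GA) and real-space refinement

The ligand's principal axes (eigenvectors of the centered second-moment
tensor, descending eigenvalues, right-handed) are aligned with the
grid's in the four proper sign combinations, each searched independently
with its own seeded stream. Individuals are torsion states on the 60°
grid; evaluation applies the torsions, superposes onto current
nearest-neighbour grid points (3 iterative-closest-point rounds of
least-squares Kabsch superposition), and scores

    score = (1/k) Σ_i exp(−d_i² / (2·0.5²)),   k = ligand atom count,

a saturating per-pair reward whose published functional form is lost;
this reconstruction is fixed by the documented requirement that one
clean atom pair outscores two half-matched neighbours (enforced by
test). Pairing runs ligand→grid because grids over- or under-sample the
ligand (observed atom/point ratios 0.25–1.7). Crossover mixes elite
torsion vectors uniformly, a ±10° shake refines them, clashing offspring
are rejected, and elitism makes the best score non-decreasing across
generations. Defaults 30/30/6 (population/generations/elite); the
screening profile uses 8/6/3.

Real-space refinement maximizes RSCC over rigid motion (3 translations,
3 rotations about the centroid) plus the rotatable torsions by
coordinate-wise ascent with shrinking steps (initial 0.3 Å, 5°, 10°;
halved when a sweep finds no improvement; stop after 50 sweeps, a sweep
gain < 1e-4, or steps shrunk 16-fold). Only improving moves are
accepted, so the correlation is monotone by construction. The
correlation mask — voxels within 2.5 Å of any atom — is fixed from the
starting pose for the whole ascent so trial poses are compared over one
region; masks beyond 8000 voxels (4000 in the screening profile) are
strided down deterministically. Bond lengths and angles are never
touched, so stereochemistry is preserved exactly.

## Ligand library, conformers, redundancy groups

The embedded library holds 46 compounds (5–44 heavy atoms) spanning
cryoprotectants, buffers, carboxylic acids, PEG oligomers and
nucleotide-like scaffolds, authored as SMILES and embedded once per
process with seeded ETKDG + MMFF. Hydrogens are dropped everywhere.
Torsion driving enumerates the full 60° grid when it has ≤ 6⁵ states and
otherwise draws a seeded random pool (4× the requested count), rejecting
states with non-bonded contacts < 2.0 Å, then keeps a maximum-
dissimilarity (farthest-point, plain-RMSD) subset including the
reference. Ring puckers are not enumerated; alternative puckers would
enter as separate library entries. Disulfide-containing compounds are
excluded because S–S bonds exceed the 2.0 Å bond-length invariant.

Redundancy groups come from seeded k-means on the four BCUT descriptors
with k = 0.6 × library size, mirroring the ~140→82 reduction obtained
when common crystallographic ligands are grouped by heavy-atom
substructure. The winner's group members are offered as alternates, and
group membership counts as a correct identification in the evaluation
harness (a sulfate blob explained as phosphate is not an error at these
resolutions).

For users curating real-map case sets, the conventional inclusion filter
is a ≥ 0.75 correlation between deposited-ligand density and the
difference map (`blobid.config.TRAINING_CC_FILTER`); it plays no role on
synthetic data.

## Study-scale evaluation conditions

The standardized synthetic conditions used by the acceptance script and
suite: 50 scenes (ligands uniform over the library, resolutions uniform
in 1.0–2.5 Å, 5 % noise, master seed 1 in the test suite), 30
high-resolution scenes (1.0–1.6 Å), a 46-ligand × ≤50-conformer
database, weights trained on an independent 60-scene cohort, screening
GA/refinement profile, top-20 hand-off. Scene conformers are drawn from
the same torsion-grid conformer sets the database holds, and the
user-supplied blob location is jittered ≤ 1.5 Å from the true centroid.
One full pipeline run takes ~3–4 s per scene on one CPU.

## Known limitations

- Real difference density is harsher than the simulator in every way
  listed above; measured recall here bounds the method's internal
  consistency, not PDB performance.
- Feature-only recall degrades with resolution (100 % top-10 at
  1.0–1.6 Å falling to ~70 % at 2.0–2.5 Å on the standard cohort):
  blurred small blobs of 5–10-atom compounds are genuinely
  shape-degenerate, and the free-atom parameterization needs visible
  inter-atomic gaps to thin clusters accurately. CC re-ranking recovers
  most of these because a wrong ligand cannot reproduce the observed
  density in detail.
- Symmetry-related density, covalent ligands, protonation states, and
  protein–ligand contacts are out of scope.
- The GA and CE optimizers are stochastic searches; results are exactly
  reproducible only under the same seeds and configuration.
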