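# Methods

## The PCS model

A nucleus at ion→nucleus vector **r** (length r, meters) near a
paramagnetic center with susceptibility-anisotropy tensor Δχ (3×3
symmetric traceless, m³) experiences a pseudocontact shift

δ = (1 / 12π r⁵) · Σᵢⱼ Δχᵢⱼ (3 rᵢrⱼ − r² δᵢⱼ)  [dimensionless; ×10⁶ → ppm].

Expanding in five independent components gives one linear "geometry row"
per measured nucleus,

g(r) = (10⁶ / 12π r⁵) · [½(2z² − x² − y²), ½(x² − y²), 2xy, 2xz, 2yz],

so that stacking rows yields M·v = P with P the observed PCSs in ppm.
With at least 5 measurements and a rank-5 geometry matrix, v is the
least-squares solution (`numpy.linalg.lstsq`); the solve is exact at n = 5.
The condition number of M is logged and a warning issued above 10⁶.

**Tensor reconstruction conventions.** In the row basis above, the solved
vector relates to the traceless tensor by v = 3·(Tzz, Txx−Tyy, Txy, Txz,
Tyz); this "physical" mapping — under which g·v reproduces the standard
Cartesian PCS expansion exactly — is the default. Because published
principal values do not always state the reconstruction, a "literal"
convention (v components identified directly with the tensor elements,
differing by a factor 3 in the reported tensor) is selectable per fit.
Fitting and back-calculation round trips are convention-invariant; only
the reported principal values differ.

**Units.** All coordinates are Å at every interface; the Å→m conversion
and the 10⁶ ppm factor live only inside the geometry row, so the linear
system is consistently (ppm, m³). Principal values are reported sorted by
absolute value ascending (Δχxx, Δχyy, Δχzz), the order in which |Δχzz| is
the largest.

**Carbon-only geometry.** The structural model tabulates methyl carbons
(Ala Cβ, Val Cγ1/Cγ2). When both ¹³C and ¹H PCSs exist for one methyl they
contribute two rows built from the same carbon coordinates — an
approximation justified by the ~1 Å C–H offset against 13–40 Å ion
distances, and by the empirical equality of the two PCSs (the 1:1 relation
used for peak pairing).

## Q-factor

Q = Σ(obs − calc)² / Σ(obs)², with no square root. Q = 0 is perfect
agreement; an all-zero back-calculation scores exactly 1. Q is undefined
(error) for all-zero observations and invariant under common rescaling.

## Orientation grid search

The tagged domain (Ig2 by default) and the ion are held static; the mobile
domain (Ig1) is rotated rigidly about the Cα of a configured linker pivot
residue: x → p + R(α,β,γ)·(x − p). Euler angles are ZXZ, interpreted as
active intrinsic R = Rz(α)·Rx(β)·Rz(γ) on column vectors — the convention
is not uniquely determined by "ZXZ" alone, so it is fixed here, used
consistently for planting and recovery, and verified against
`scipy.spatial.transform.Rotation` in the tests.

The grid is the Cartesian product of evenly spaced values per angle with
endpoints inclusive (spacing = range/(n−1); 50 values per angle over
α, γ ∈ [−90°, 90°], β ∈ [0°, 180°] gives 125,000 orientations, spacing
≈ 3.67°). Ordering is deterministic (α outer, β middle, γ inner) and ties
in Q resolve to the first grid index. β = 0 nodes are gimbal-degenerate
(only α+γ matters); they are scored as legitimate orientations and flagged
in the top-model manifest. Scoring is fully vectorized: all rotation
matrices are built in one batch and applied by einsum, so a full
125,000-orientation search over ~12 methyls takes a few seconds.

The tensor is fitted once from the tagged domain — by default pooling
ligand-bound and unbound measurements, since ligand binding at the mobile
domain is not expected to change the tag geometry — and held fixed across
the search. Per-condition tensors are available for sensitivity analysis.
No continuous refinement follows the grid; the reported optimum is a grid
node.

**Degenerate valleys.** With ~12 methyl sites in the mobile domain the Q
landscape typically has one sharp basin plus a shallow valley along which
α and γ partially compensate (and, more rarely, distant near-degenerate
minima arising from the evenness of the PCS quadratic form). Noiseless
on-grid planted rotations are recovered exactly; off-grid or noisy data
can move the discrete argmin along the valley by more than one Euler
spacing even when the recovered rotation is close in rotation space. This
mirrors the weak-constraint direction observed in real data and is a
property of the data, not the optimizer.

**Clashing conformers.** A candidate rotation may sweep a site arbitrarily
close to the ion. Ion–nucleus distances below 0.1 Å are floored during
grid scoring, producing enormous calculated PCSs and hence enormous Q, so
sterically impossible orientations eliminate themselves without aborting
the scan. Outside the grid search the same distance is a hard error, since
there it signals a malformed model.

## Peak pairing

For one methyl the ¹H and ¹³C PCSs are equal in ppm, so a true
diamagnetic/paramagnetic pair satisfies Δδ_C ≈ Δδ_H. Pairing minimizes
Σ|Δδ_C − Δδ_H| over one-to-one matchings subject to a per-pair tolerance
(default 0.05 ppm), solved exactly with the Hungarian algorithm on an
augmented matrix in which every peak may instead remain unmatched at a
fixed penalty larger than any admissible mismatch — making the matching
cardinality-maximal first, cost-minimal second. Unmatched paramagnetic
peaks (decoys, new peaks) and unmatched diamagnetic peaks (bleached by
paramagnetic relaxation) are reported, not guessed.

## Resonance assignment

Each spin system is scored against each candidate residue by
Σ_t w_t·((obs_t − pred_t)/s_t)² over the shared shift types, plus a
penalty (default 1.0) per predicted type missing from the observation, and
optionally a PCS term ((measured − calculated)/0.02 ppm)² when a tensor
and structure are supplied. Per-type scales default to typical
shift-prediction accuracies — 1.0 ppm for ¹³C, 0.25 ppm for ¹H — and are
configurable, as no canonical weighting exists. Mutagenesis knowledge
enters as force/forbid constraints on (peak, residue) pairs.

The optimal one-to-one assignment is found exactly with the Hungarian
algorithm — at these problem sizes (tens of methyls) exact optimization is
trivial, deterministic and testable, so no stochastic search is needed;
the tests verify equality with brute-force enumeration up to n = 8. The
gap to the second-best complete assignment (re-solving with each optimal
pair forbidden in turn) is reported as a confidence indicator.

## Synthetic data generator

The generator emulates the study conditions of a tagged two-domain methyl
system; all outputs are pure functions of (spec, seed) and carry
ground-truth JSON sidecars.

* **Geometry.** Two clusters of 12 methyl sites each (Ala Cβ singletons
  and Val Cγ1/Cγ2 geminal pairs 2.5 Å apart), uniformly placed in 12 Å
  spheres with centroids 40 Å apart; the pivot Cα sits at the midpoint.
  The ion is offset (−15, 0, 20) Å from the tagged centroid — on the
  mobile-domain-facing side, ~25 Å from the tagged centroid and ~32 Å from
  the mobile centroid — reflecting the design requirement that labeled
  sites in *both* domains lie within the ~30 Å sphere of PCS influence.
  Site clusters are random points, not Ig-fold mimics: the physics needs
  distance and orientation scales, not fold realism.
* **Planted tensor.** Principal values (−4.3, −34, 38.3)×10⁻³² m³ (the
  magnitude scale of a Dy³⁺ tag) in a seed-random orientation.
* **Measurability window.** Every site's noiseless |PCS| must fall in
  0.01–3 ppm (below: unmeasurable against linewidth; above: unphysically
  close). Clusters are redrawn up to 50 times if a site violates the
  window or comes within 5 Å of the ion — resampling escapes the tensor's
  magic-angle null surface; generation then fails loudly.
* **Noise.** I.i.d. Gaussian, default σ = 0.01 ppm, added independently
  per nucleus row; 0.005–0.02 ppm brackets realistic PCS read precision
  from 2D spectra at high field. The ligand-bound state is a pure rigid
  rotation of the mobile domain (no tensor change).
* **Peak lists.** Paramagnetic peaks sit at diamagnetic positions plus the
  site PCS in both dimensions; optional decoys and a bleach fraction
  emulate new/vanished peaks.

What passing tests therefore show: the solver, scoring and search recover
planted ground truth under Gaussian noise at realistic geometry scales.
What they do not show: performance under conformational averaging (the
analysis fits a single rigid structure by design), correlated or
non-Gaussian shift errors, peak overlap in crowded spectra, or imperfect
rigid-domain geometry.

## Numerical and interface choices

* PDB I/O via gemmi; ion detection accepts any single lanthanide HETATM
  (ambiguity is an error, never a guess) or explicit coordinates.
* Domain ranges default to Ig1 = 61–165, Ig2 = 166–266 (split at the
  linker residue); the pivot residue defaults to 165 and is configurable —
  the source literature is internally inconsistent about the pivot
  residue's identity, so it is exposed rather than resolved.
* Domain superposition is Kabsch (SVD with proper-rotation correction) on
  sites matched by (residue number, methyl label); the fitted transform is
  applied to all coordinates including ion and pivot.
* Problem sizes in the test and acceptance runs — 24 methyl sites, grids
  of 13³–50³, 100 noisy replicates — were chosen so the full suite
  completes in well under a minute while exercising the same code paths
  as a full 125,000-orientation analysis.

## Known limitations

* Single-conformer analysis: no ensemble averaging over interdomain
  motion, no flexible-linker sampling, no translation search.
* The lanthanide position is taken from the model, not fitted.
* No residual dipolar coupling or paramagnetic relaxation enhancement
  models; no temperature dependence of Δχ.
* Stereospecific Val Me1/Me2 discrimination relies entirely on the cost
  model; no NOE-based disambiguation.
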