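# Methods

This note documents the models, numerical choices and limitations of
`maskfit`. All distances are millimetres; meshes are triangulated
surfaces in a right-handed frame with the face looking along +z.

## Rigid registration

Alignment is point-to-point ICP on mesh vertices: correspondences are
source-vertex → nearest target-vertex (KD-tree accelerated; results
identical to exhaustive search, ties to the lowest index), solved each
round with the closed-form Kabsch/SVD fit constrained to proper
rotations. Iteration stops when the RMS correspondence distance changes
by less than `rms_tolerance` (default 1e-4 mm) or after
`max_iterations` (default 100). An optional trim fraction drops the
worst correspondences each round; when trimming is active, the reported
and optimized RMS is the trimmed one, which keeps the objective robust
to regions that genuinely differ between the surfaces.

Point-to-point ICP is local, and from a plain centroid initialization
it stalls well short of the optimum under rotations of tens of degrees
(nearest-vertex assignments lock at the sampling scale). The search is
therefore started from a small deterministic candidate set — identity,
centroid shift, and the four sign-consistent principal-axis alignments
of the two clouds — each rolled out for 20 iterations; the best rollout
(by final RMS, with earlier candidates winning ties so symmetric
geometries resolve deterministically) is refined to convergence. On
identical geometry this recovers rotations of at least 30° and
translations of 20 mm to machine precision.

Two registrations compare surfaces that genuinely differ where tissue
moved: loaded-to-unloaded face alignment, and registration of the
deformed respirator onto the loaded face. Both default to a 20% trim so
the alignment anchors on unchanged regions rather than chasing the very
deformations being measured.

Known limitation: when the source is a strict subset of a larger target
(the respirator's whole geometry against a head-with-respirator scan),
vertex-correspondence ICP locks at roughly the mesh sampling scale
(~1 mm, ~2° here) rather than converging exactly; this does not affect
downstream results because the internal surface is subsequently
re-registered to the face, but it is why the synthetic scenes model the
respirator scans (acquired in a single tomography session) as
near-aligned to begin with.

## The three-step alignment cascade

Both facial scans are ICP-aligned to a reference head; the respirator's
whole geometry is aligned to the reference head with the respirator in
situ; and the internal surface — which has no stable overlap of its own
to register — is carried along by that second transform. All later
stages operate in this common frame.

## Deformation ladder (non-rigid ICP)

A semi-rigid facepiece deforms when strapped on. The package emulates
this with a displacement-field non-rigid ICP indexed by eight levels
δ₁…δ₈ whose stiffness follows a geometric schedule s(k) = 0.05·4^(k−1).
After a rigid pre-alignment, each iteration pulls every vertex toward
its nearest target vertex, regularizes the pull field by Laplacian
smoothing over the mesh graph (per pass each vertex's displacement
becomes (1−b)·own + b·neighbour-mean), and applies a fraction of the
regularized field. Stiffness maps to the three controls as

* step size 1/(1+s) — the fraction of the regularized pull applied,
* smoothing passes 1 + round(√s) capped at 31,
* blend b = s/(1+s), clipped to [0.05, 0.999],

so δ₁ chases the target almost freely while δ₈ applies a tiny fraction
of a heavily diffused field (whose smooth component the rigid
pre-alignment has already absorbed). Iteration stops when the largest
per-vertex motion falls below 0.01 mm or after 50 iterations; there is
no randomness anywhere in registration. One stiffness governs all
vertices of a level — per-region stiffness maps are out of scope.

No particular elastic energy is claimed; the ladder is specified by its
testable contract: at δ₁ the deformed surface sits within 0.2 mm mean
|signed distance| of a smooth target, at δ₈ it deviates from the rigid
result by under 0.5 mm mean vertex displacement, conformity is monotone
non-increasing down the ladder (1 percentage point slack), and the RIGID
level is bit-identical to rigid ICP. The RIGID "level" means no
deformation at all. Because the analysis downstream consumes only the
resulting distance distributions, any formulation meeting this contract
is interchangeable.

## Signed distances and summaries

For each query vertex the signed distance to the reference surface is
the distance to the nearest reference *vertex*, signed by the outward
normal at that vertex (negative = inside the reference envelope =
indentation; positive = gap). A point-to-surface mode (exact closest
point on the triangulation, found via KD-tree candidate faces and the
barycentric clamp) is available as an option; the vertex mode is the
default and is what the sweep uses. Per-vertex weights are one third of
incident-triangle area, so weighted vertex statistics equal surface
integrals for piecewise-linear fields; count weighting is available for
sensitivity checks.

The distribution summary reports the weighted 2.5th and 97.5th
percentiles (linear interpolation of the weighted empirical CDF at
positions (cᵢ − wᵢ/2)/W) and their difference — the width of the
central interval containing 95% of the area-weighted distances — plus a
density-normalized histogram (default 100 bins over the data range).
The "central-95% width" is the scalar used to rank deformation levels.

## Goodness of fit and the optimum rule

Band conventions follow the strict gap/indentation inequalities and the
closed seal range: gap d > 0, indentation d < −3, seal −3 ≤ d ≤ 0
(d = 0 and d = −3 both count as seal); the three partition the area
exactly. Conformity |d| ≤ 1 (closed) overlaps them and is reported
alongside. The −3 mm indentation bound is the conventional threshold
beyond which facial soft tissue is considered at risk under sustained
load.

The δ-optimum is the level with maximum conformity; conformities tied
within 0.05 percentage points fall through to the smaller central-95%
width, and any remaining tie goes to the stiffer level (shape
preservation costs nothing when conformity is equal). Fed the published
per-participant conformity columns, this rule reproduces each published
per-participant optimum.

## Soft-tissue displacement

The loaded face is rigidly registered onto the unloaded face (20% trim,
see above) and signed distances of loaded vertices against the unloaded
surface are summarized; the 2.5th/97.5th percentiles are reported as the
negative (indentation) and positive (bulge) soft-tissue displacements
caused by donning the respirator.

## Anthropometrics

Four landmark-pair distances: bio-ocular width (exocanthion–
exocanthion), alar width (alare–alare), dorsal nasal length
(nasion–pronasale; "sellion" accepted as an alias), and lower-third
facial height (subnasale–menton) — the lower third because facial scans
routinely cut off the hairline. Landmarks come from a JSON/CSV file of
named coordinates; automatic landmarking is out of scope. Associations
with fit percentages use Shapiro–Wilk normality checks on both
variables (the smaller p is reported) and two-sided Pearson correlation
at α = 0.05.

## Synthetic scenes

Faces are height fields z = f(x, y): an elliptic-paraboloid dome
(35 mm) plus a Gaussian nose ridge (12 mm high) and two cheek mounds
(6 mm), sampled on an n×n grid (default 80, full pipeline in well under
a minute on one CPU; several tests use 40–60 for speed). Height fields
have no undercuts, keeping distance signs unambiguous. The respirator's
internal surface is the nose-and-mouth region offset along the face
normals by a standoff field (default: 0.5 mm base, a 2.5 mm
nose-bridge gap, and a slightly pre-indented −0.5 mm sealing rim); the
whole geometry adds an outer shell 4 mm further out. The loaded face
applies flat-topped (eighth-order super-Gaussian, σ = 30 mm) normal
displacement patches — a 5 mm cheek-rim indentation and a 4 mm lateral
bulge by default, the magnitude range reported for real respirator
donning — placed mostly outside the sealing region, as strap tension
loads the rim and bulges the tissue laterally. Flat tops guarantee that
well over 2.5% of face area experiences the full peak, so the
prescribed 2.5th/97.5th area-weighted percentiles sit within 0.1 mm of
the peak magnitudes; these ground-truth percentiles are computed from
the prescribed field only, never from registration output.

Subject meshes carry recorded rigid misalignments (defaults: 10° and a
few mm for the facial scans, sub-millimetre for the respirator scans,
see the rigid-registration limitation above); the reference head plays
the standardized-head-form role and stays canonical, with the covered
face region occluded in its with-respirator counterpart, as a real scan
would be. Optional Gaussian vertex noise on the loaded face is seeded;
scenes are bit-reproducible given a seed.

What the scenes do *not* model: real anthropometric variation between
faces, undercut geometry (nostrils, chin), scan holes and topological
noise, strap mechanics, and material behaviour of the facepiece.
Passing tests therefore demonstrate the correctness of the geometric
machinery and the recoverability of prescribed deformations — not
clinical accuracy of fit prediction on real faces.

## Numerical conventions

* STL welding tolerance 1e-6 mm (grid rounding; first occurrence keeps
  its index). Units are taken as mm — STL carries no unit metadata.
* Mesh cleaning removes duplicate and zero-area faces and connected
  components below 1% of the largest component's area, then drops
  unreferenced vertices; the operation is idempotent.
* Nearest-neighbour ties resolve to the lowest index everywhere.
* Rotation matrices are validated orthonormal with determinant +1 to
  1e-8; reflections are rejected in construction and in the Kabsch fit.
* Degenerate Kabsch configurations (fewer than 3 pairs, collinear
  points) raise rather than return an arbitrary rotation.
* Histograms of constant data are given a token ±0.5 mm range so the
  density still normalizes.

## CLI

`maskfit synth | sweep | fit | displacement | anthro`, configured by
flags or a JSON config file (flags win). Outputs are CSV/JSON plus PLY
meshes colour-mapped blue (indentation) → white (contact) → red (gap).
Exit codes: 0 success, 2 validation error, 3 numerical failure (only
with `--strict` when a registration reports non-convergence). Runs are
byte-reproducible given identical inputs and seed; logs record input
checksums and per-stage iteration counts and RMS.
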