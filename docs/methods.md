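# Methods

## Refinement model

`nrrs` treats refinement as a sequence of local two-point tracing problems.
The working assumption, inherited from curated reconstruction pipelines, is
that the soma (root) and all terminal tips of a reconstruction are correct,
while interior geometry may deviate from the imaged neurite. Refinement
therefore only ever moves internal nodes; root and tip coordinates are
bit-identical before and after, and the branching topology is invariant.

A reconstruction is decomposed into branches between critical nodes (root,
bifurcations, tips) and each branch into pieces of arc length strictly below
`max_segment_len` (default 50 µm, measured in µm through the voxel size).
Short pieces keep image quality consistent within each tracing problem and
bound the voxel-graph size. Pieces are cut into the minimal number of
equal-arc parts, with each cut snapped to the nearest existing node; should
snapping leave a piece at or above the cap (possible with very coarse node
spacing), the exact interpolated cut point is inserted instead, so the
strict bound always holds.

### The GD tracer

The graph step builds a 26-connected voxel graph over a crop around the
segment (bounding box dilated by `crop_margin`, default 16 voxels) with edge
weights `‖v0−v1‖·(g_I(v0)+g_I(v1))/2`, `g_I = exp(λ_I(1−I/I_max)²)`, and
runs Dijkstra (scipy's sparse-graph implementation) between the rounded
endpoints. `g_I ≥ 1` with equality at `I_max`, so all weights are positive
and the optimum is a simple path hugging bright voxels. With the default
`λ_I = 10` the cost of a fully dark voxel is `e^10 ≈ 2.2·10⁴` times that of
a bright one — darkness is effectively impassable whenever a bright detour
exists, which is what lets the tracer recover deep bends from a straight
chord initialization. `I_max` is the crop's maximum; blocks above a voxel
budget (default 512×512×256) are refused with a request to crop.

The deform step minimizes `E = α E_image + β E_length + γ E_smoothness`
over the path's interior control points (endpoints fixed). `E_length` is the
sum of squared consecutive gaps — interpreted over all K−1 consecutive pairs
— and `E_smoothness` the squared offsets of interior points from their
neighbors' midpoints. `E_image` adds, per control point, an intensity
shortfall term `λ_I(1−I(C_k)/max_Θ I)²` against the maximum over the
neighborhood `Θ(C_k, r)` (voxels within `r = 4` of `C_k`, trilinear
interpolation at `C_k`) and a centroid term
`λ_C · Σ_Θ ‖C_k−q‖² I(q) / Σ_Θ I(q)` (`λ_C = 1`), which is minimal when the
point sits at the intensity centroid of its neighborhood. A fully dark
neighborhood contributes the fallback value `λ_I` and is logged.

The optimizer is a damped cyclic coordinate scheme: each interior point
takes a step (factor 0.5) toward the blend of the local intensity centroid
(weight α) and its neighbors' midpoint (weight β+γ), and the move is kept
only if the exact local energy decreases, making the total energy
non-increasing by construction. Iteration stops when a full sweep changes
the energy by less than `1e-4` or after 100 sweeps. The scheme is
derivative-free and, on straight noise-free tubes, reaches the centerline to
well under half a voxel RMS. K is kept fixed during deformation; curves are
not resampled inside the optimizer.

Pass 1 uses α=1, β=γ=0.2 (image fidelity dominates while anchors may be
off-signal); pass 2 uses α=β=γ=0.5 (anchors are on-signal, so length and
smoothness matter as much as image fit).

### Midpoints, junctions and stitching

Each first-pass curve is cut at its half-arc-length midpoint (robust to
non-uniform spacing, unlike a middle-index rule). Adjacent midpoints are
traced pairwise in pass 2; a pair whose span crosses a bifurcation is traced
once per child branch, so two (or more) pass-2 curves run through the
junction. After resampling both at 0.5-voxel arc steps from the shared
parent midpoint, the refined junction is the last point of their maximal
common prefix (pointwise spread ≤ 1 voxel); the averaged prefix becomes the
parent-side polyline and the remainders the child sides. If the curves share
no prefix at all, the original bifurcation is snapped to the nearest point
on either curve and the case is flagged in the report. The outermost half of
the first and last pass-1 curve of each root-to-tip run has no adjacent
midpoint beyond its fixed anchor and is spliced in unchanged — the region
adjacent to soma and terminals is refined only by pass 1.

Stitching concatenates, per branch: junction-side polyline (or pass-1 outer
half at root/tips), the within-branch pass-2 curves, and the end-side
polyline, then rebuilds the tree with consecutive ids, radii interpolated by
relative arc length from the input branch, and type codes carried over.
A topology check (bifurcation/tip counts, root position) runs after stitch
and aborts with a diff on violation. Per-segment energies, node counts and
fallbacks are collected in a `RefineReport`.

Degenerate inputs: a single-edge tree between two fixed endpoints is
returned unchanged; a segment in an all-dark crop falls back to its input
polyline (flagged); coincident trace endpoints yield the trivial two-point
curve with a warning.

## Synthetic benchmark

The generator emulates local image blocks around a single neurite with one
side branch. Skeletons are cubic Béziers sampled at 1-voxel arc steps,
spanning the block's z extent, with interior control points laterally offset
by 22–42 voxels in opposite directions, which produces the pronounced bends
(turning ≥ 35° over 10-sample chords) that make the missed-bend case
meaningful; a second Bézier leaves a mid-arc node at 30–90°. All points keep
two tube radii from the block border. Images are Gaussian-profile tubes:
`I(v) = bg + (peak−bg)·exp(−d(v)²/2σ²)` with `d` the distance to the
skeleton (computed against a 0.25-voxel dense resampling), plus Gaussian
noise, clipped and quantized to 8 bits. The profile σ is tied to the stored
SWC radius by `σ = radius/√(2 ln 2)`, so the tube reaches half its amplitude
exactly at the nominal radius. Defaults: 128×128×64 blocks, radius drawn
U[2.0, 2.75] voxels per sample, peak 200, background 12, noise σ 6 —
a bright, moderately noisy block typical of usable fMOST data.

Three perturbation cases, all preserving topology, root and tip positions:

- **missed bend** — the most-bent window of the longest branch (starting at
  ~20 nodes, grown up to ~45 until the whole-skeleton mean deviation exceeds
  1 voxel) is replaced by its straight chord;
- **displaced bifurcation** — the junction moves by a magnitude drawn
  U[8, 12] voxels in a random direction, blended linearly into the ~10
  nearest nodes of each incident branch;
- **neurite shift** — every interior node moves by one direction vector of
  magnitude U[3, 8] voxels, tapering to zero over the 5 nodes nearest the
  root and each tip (the endpoint-correctness assumption forces the taper).

Magnitudes for the first two cases are the package's own choices: the
missed-bend window is sized and the bifurcation magnitude drawn so every
sample leaves a clearly measurable deviation (mean > 1 voxel) for refinement
to fix; sample draws violating any generator invariant are redrawn from the
next derived seed. Every quantity is a pure function of the master seed.

What the phantom does *not* model: PSF anisotropy, shot noise, intensity
falloff with depth, crossing or parallel neurites, boutons and spines, and
gaps in labeling. Passing benchmarks here shows the geometry pipeline works
under clean single-neurite conditions; performance on cluttered or
low-SNR real blocks must be judged on real data.

## Metrics and baselines

All comparisons resample skeletons to a common 2 µm arc interval. Skeleton
deviation is the mean distance from resampled test points to the nearest
point on the ground-truth polyline (point-to-segment). Bifurcation deviation
matches junctions by topology (deterministic pre-order), never by proximity,
and errors out on a topology mismatch. The information extraction rate
voxelizes both skeletons as unions of spheres carrying their local radii and
reports `|S_test ∩ S_gt| / |S_gt|`; information loss is its complement.
Radius estimation grows a ball on a 0.5-voxel grid until fewer than 95% of
its voxels exceed the background threshold; intensity extraction averages
trilinear intensities at the nodes. Storage is the node count and canonical
SWC byte size.

The Mean-Shift baseline iterates each interior node to the intensity-weighted
centroid of its search ball (radius 5 voxels, convergence 0.1 voxel); the
searching distance also caps the total displacement — the parameter exists
to constrain the solution space, and without the cap the iteration can walk
arbitrarily far along an intensity tail. The simplified auto-parameter
variant resamples branches to 1-voxel steps first and sets each node's
radius to twice its locally estimated tube radius (minimum 2), trading
storage for coverage. Benchmark aggregates report post/pre deviation ratios
as ratios of the global means (per-block mean ratios are also emitted, since
either convention is defensible).

## Numerical choices

- Dijkstra ties: scipy's predecessor choice is deterministic run-to-run;
  all geometrically consequential cases in the test suite have strictly
  unique optima.
- Trilinear interpolation everywhere a continuous position is read;
  neighborhoods use voxel centers.
- Deviation metrics use exact point-to-segment distances, vectorized; the
  volume overlap assigns each voxel to its nearest sphere center (exact for
  per-branch-constant radii, an approximation for strongly varying radii).
- Problem sizes in the shipped benchmark (60 blocks of 128×128×64, three
  tracer calls plus two junction traces per sample) keep a full benchmark
  run in the minutes range on one CPU; the generator accepts larger blocks.

## Known limitations

- The common-prefix junction rule assumes the pass-2 curves through a
  bifurcation genuinely overlap along the parent; on very obtuse junctions
  with thick tubes the recovered point can sit 1–2 voxels past the geometric
  junction (where the child tubes' ridges separate).
- Tracts adjacent to soma and terminals are refined by pass 1 only; a wrong
  terminal annotation is not corrected (by design).
- One energy-coefficient set per pass; blocks whose SNR differs wildly from
  the defaults may need `λ_I` adjusted via the config file.
- The deform step does not insert nodes, so extremely sparse input sampling
  limits attainable smoothness (mitigated by tracing at voxel resolution).
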