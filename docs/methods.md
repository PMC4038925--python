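# Methods

## Model

`multipeak` implements deterministic streamline propagation over a
multi-peak direction field. The field assigns each voxel up to *n* fiber-ODF
maxima (axial vectors; their norm is a magnitude such as the AFD at the
maximum). Tracking happens entirely in world millimetres through the NIfTI
affine, so the step size is independent of voxel anisotropy, and peak
vectors are interpreted as world-frame (RAS) directions.

One propagation step:

1. Sample the scalar map *f* at the current position by nearest-neighbour
   lookup (the same rounding rule the peak lookup uses, so mask and peaks
   agree on voxel membership). Out-of-grid positions stop first, then
   *f* < threshold, then an empty peak set.
2. Select **V**ₙ as the peak orientation minimizing the angle to the
   incoming direction **V**ₙ₋₁; both orientations ±p of each peak are
   candidates because fODF maxima carry no intrinsic sign. Ties break to
   the lowest storage index. Peak magnitude plays no role here — only in
   the initial-direction draw.
3. Evolve: **V**ₙ₊₁ = normalize(*f* **V**ₙ + (1−*f*)((1−*g*) **V**ₙ₋₁ + *g* **V**ₙ)),
   with *f* clamped to [0, 1] before use (the map itself is read as-is; a
   binary mask acts as a 0/1 map). An exactly cancelling blend (antiparallel
   terms with equal coefficients) is a stop condition.
4. Stop if the realized turn angle(V_{n-1}, V_{n+1}) exceeds θ_max, or if the
   path length would exceed the maximum; otherwise advance by
   step_size · **V**ₙ₊₁.

The angle test applies to the *evolved* direction rather than the raw
selected peak: the constraint governs the geometry of the path actually
taken, and the evolved direction is what the streamline follows. Peak
selection and evolution run at every step, not only on voxel change; at the
default step of one voxel the two policies coincide, and per-step
application avoids carrying voxel identity in the state.

Each seed spawns two halves along ±v₀, where v₀ is drawn among the seed
voxel's peaks with probability proportional to peak norm (one seeded
generator per run; seed order defines consumption order, which makes runs
bit-reproducible). The first step of each half uses v₀ itself as
**V**ₙ₋₁. Halves are merged with the seed appearing once; the min/max
length filter applies to the merged streamline, with length defined as
(n_points − 1) · step_size. A hard cap of ceil(max_length/step) + 1 points
per half guards non-termination.

## Parameters

| parameter | meaning | default | notes |
|---|---|---|---|
| `f_threshold` | minimum scalar-map value to continue | 0.1 | standard FA stopping value |
| `theta_max` | max angle between consecutive steps (deg) | 35 | or derived from a curvature radius R via θ = min(2 asin(s/2R), 90°) |
| `step_size` | step in mm | 1 voxel | per-bundle presets use 0.5–2 mm |
| `g` | in/out weight | 0.20 | g→1 eases sharp turns (curved bundles), g→0 smooths (straight bundles) |
| `min_length`, `max_length` | merged length bounds (mm) | 0 / 300 | |
| `rng_seed` | run seed | 0 | initial-direction draws and mask seeding |

Shipped presets (`multipeak/presets/*.yaml`): `default`, plus per-bundle
sets for the fornix, corticospinal tract, inferior fronto-occipital
fasciculus and corpus callosum, reflecting that optimal parameters vary by
bundle shape (tight angle and small steps for the highly curved fornix;
larger steps and g = 0 for the long straight CST).

## Sampling and upsampling

Tracking reads the field nearest-neighbour; the intended workflow upsamples
the data once beforehand (e.g. 2 mm → 1 mm) so that nearest-neighbour reads
in the fine grid approximate native-resolution interpolation.
`upsample_trilinear` resamples a 3D/4D volume on a node-centred finer grid:
output index j samples input index j/f, so input voxel centres are
reproduced exactly for any integer factor and the affine is scaled by 1/f
with no offset (output dims f·(n−1)+1). Node-centring was chosen over
cell-centring because exact reproduction of input samples is the property
the tracker relies on; cell-centred grids cannot satisfy it for even
factors. Upsampling an already-extracted peak field per component is an
approximation to upsampling the diffusion data before peak extraction —
adequate inside coherent bundles, less meaningful where neighbouring voxels
hold different peak counts or orderings.

## Phantoms

The generator rasterizes tubular bundles (polyline or arc centerlines,
fixed radius) onto a voxel grid: in-tube voxels hold a peak along the local
centerline tangent (central differences on a densely resampled centerline,
so tangent error stays below the angle one voxel subtends along the
centerline); overlapping tubes contribute one peak each. Tubes have flat
end caps at the centerline termini so that the tracking domain ends exactly
where the endpoint ROIs sit. The scalar map is two-level (0.8 inside any
tube, 0 outside), making the tube exactly the tracking domain at the
default threshold of 0.1. Endpoint ROIs are 2-voxel-radius balls at the
termini; each bundle contributes one expected ROI pair.

The `fibercup7` preset arranges seven bundles — three straights, two short
obliques, one long vertical producing two orthogonal crossings, and one
C-shaped arc — on a 64×64×3 grid of 3 mm isotropic voxels. It is a
*topological* emulation of the classic seven-bundle validation phantom
(same bundle count, crossing and curved motifs, same grid dimensions), not
a geometric replica; accordingly the package's validation on it is
structure-level (bundle recovery counts), never decimal connectivity
fractions. Peak magnitudes are 1 everywhere so initial-direction draws are
uniform across bundles inside crossings.

What the phantoms do **not** emulate: diffusion signal formation, noise,
peak-extraction errors, partial-volume fanning, or anatomically realistic
geometry. Passing phantom tests therefore demonstrates correctness of the
propagation, seeding and scoring machinery under ideal peak fields — not
tracking accuracy on acquired data.

## Scoring

Rasterization marks every voxel whose cube a streamline traverses
(segments resampled at half-voxel intervals), then dilates by a Euclidean
world-distance tolerance (default 1.5 mm) so parallel bundles one voxel
apart compare as overlapping. In two-map comparison both maps are dilated,
a symmetric choice that preserves the symmetry of the Dice coefficient; the
`compare` command offers one-sided dilation as an option.

Connectivity classification is endpoint-based: a streamline is *valid* if
its two endpoints lie in the two distinct ROIs of an expected pair,
*invalid* if they lie in two distinct ROIs not forming an expected pair,
and *no-connection* otherwise (including both endpoints in the same ROI).
VC/IC/NC are fractions of all streamlines and sum to 1 exactly. VB counts
expected pairs with at least one valid streamline; IB counts distinct
unexpected pairs produced. ABC is the mean over expected pairs of the
fraction of that pair's reference-bundle voxels crossed by its valid
streamlines (tolerance-0 rasterization); ARC applies the same coverage to
the seed regions. Endpoint-only membership is the simplest reading of
"connecting two ROIs" and is the documented contract; note that with ROI
balls comparable in size to the tube radius, a minority of full-length
streamlines can terminate in an unlabeled voxel just outside the ball
(lateral offset plus one step past the tube cap), which depresses VC
slightly without affecting VB.

## Numerical choices and degenerate inputs

- Directions are renormalized after every blend; spacing between
  consecutive points is exactly the step size.
- Zero-norm peaks are ignored everywhere; a voxel holding only zero peaks
  stops propagation.
- Angle comparison uses a 1e-12 slack on the cosine to keep exact-boundary
  turns (e.g. θ_max = 90° with an orthogonal blend) stable.
- Dice of two empty maps and overlap of an empty reference are undefined
  and raise, rather than returning a silent 0.
- Stop precedence: out-of-grid → below threshold → no peaks → degenerate
  blend → angle → max length.

## Problem sizes

The shipped validation runs use the 64×64×3 phantom grid; the seven-bundle
recovery experiment tracks ≈4000 seeds (9 per ROI voxel) of ≤100 steps
each, and metric oracles use 16³ random maps — sizes chosen so the full
suite and the acceptance script each complete in well under a minute on a
single core while exercising every code path.

## Known limitations

- Deterministic only; no probabilistic propagation.
- Nearest-neighbour field sampling assumes pre-upsampled data; tracking
  directly on coarse fields quantizes paths noticeably.
- Per-component upsampling of peak fields does not re-extract maxima and
  can blend unrelated peaks across slot boundaries.
- The phantom tangent discretization limits curvature fidelity to roughly
  one voxel of arc; very tight arcs (radius ≲ 2 voxels) are not
  representable.
- TRK input is accepted via nibabel's reader, but TCK is the canonical
  output format.
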