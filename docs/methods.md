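# Methods

This note documents the models, conventions and numerical choices behind
`stereogold` — what each stage assumes, which knobs matter, and what the
synthetic fixtures do and do not establish.

## Coordinate conventions

Voxel grids are stored `(z, y, x)` (one XY image per milling step); voxel
sizes are `(x, y, z)` in nm because FIB-SEM data are strongly anisotropic
(Z steps of 10–20 nm against XY pixels of ~2–3 nm).  Voxel `(i, j, k)` maps
to the physical centre `((i+½)Δx, (j+½)Δy, (k+½)Δz)`, which keeps centroid
arithmetic independent of the grid origin.  All point coordinates handed
between stages are `(x, y, z)` micrometres.

## File formats

AmiraMesh support is deliberately narrow: the uniform-`Lattice`, byte-label
dialect that a segmentation label field exports as ("Amira RLE"), with raw
or `HxByteRLE` data sections.  Anything else is rejected loudly rather than
half-read; multipage TIFF is the supported alternative for both label
fields and EM stacks.  The byte-RLE codec (high-bit control byte = literal
run, else repeat run, runs ≤ 127) round-trips bit-exactly and is validated
against an independent decoder in the tests.  Link/usage tables are
headerless 4×N CSV; their invariants (four rows, unique nonzero IDs, no
usage flag on a placeholder) always raise on violation, never
warn-and-continue.  Output tables are CSV with `%.9g` formatting so that
repeated runs are byte-identical; the row-average summary is CSV rather
than a binary spreadsheet.

## Stack preparation

Mutual information for slice alignment is computed on a 64-bin joint
intensity histogram of the overlap region, with an exhaustive integer-pixel
search inside the translation bound (default 0.5% of the frame size, i.e.
±3 px on a 600-px frame).  No subpixel interpolation and no rotation:
translation-only registration chained frame-to-frame is the modeled
procedure, and cumulative drift of the chain is accepted.  Constant
(zero-entropy) frames make the histogram degenerate and raise.

Resizing (default factor 1/4, XY only) uses nearest-neighbour sampling for
label volumes — resampling must never invent a label — and local-average
interpolation for intensity stacks; the voxel size is rescaled so physical
extent is preserved to within one output voxel per axis.

## Orientation

Per-tower axes come from PCA of the *sampled* border points (default a
random 1/10 of border voxels, seeded): the long axis of a tower is robust
to subsampling, and the sample also feeds association and visualization.
PCA signs are ambiguous, so each axis is flipped with probability ½
(seeded), giving two balanced antipodal clusters on the sphere; mean shift
with a Gaussian angular kernel (bandwidth 0.3 rad — not prescribed
anywhere, chosen well below the ~90° cluster separation and above the
few-degree cluster spread; configurable) finds the two mode centres, merging
modes within half a bandwidth.

"Upward" is the candidate `u` minimizing `std_t(min_p⟨p, u⟩)` across
towers: bases rest on a common plate, so minimum projections coincide under
the true up but spread under its negation.  The mirrored reading (spread of
per-tower *maxima*) is available as `extremity="max"`.  Ties (identical
spreads within 1e−9, e.g. two congruent towers) go to the candidate with
the larger mean per-tower maximum projection — towers extend upward — then
lexicographic order.

The selected candidate is then *refined* as the spherical mean of all
principal axes sign-corrected into its hemisphere.  The raw mean-shift mode
is a kernel mean over whichever axes the random flips placed in its
cluster and therefore carries flip-subset noise of a degree or two; after
the up/down decision every tower's axis is evidence, and averaging all of
them shrinks the error by ~1/√n and makes the estimate independent of the
flip seed.

## Rigid normalization and azimuths

A single Rodrigues rotation about the pooled border-point centre of mass
maps upward onto +z (antiparallel case: half-turn about the x-axis, a
documented arbitrary choice), followed by a translation putting the minimum
z over *used* towers at exactly 0.  Rotation and translation are applied
identically to towers and beads, so all pairwise distances are preserved.

The link table's columns define the MET axis: a total-least-squares XY line
through each column's tower centroids, oriented from the short-row end
toward the kinocilium-row end, is the column's mechanosensitive direction;
north is its negation and is shared by every member of the column (one
arrow per column, not per-pair tip-link vectors).  Columns with fewer than
two locatable towers have no azimuth and their towers drop out of pooling.
The azimuth transform spins each tower about the vertical axis through its
own XY centroid so north maps to (0, 1, 0); z coordinates are untouched.

## Measurement and template registration

Height is the z extent of the border points; radius is the *mean* XY
distance from the vertical axis through the XY centroid — mean rather than
max, to be robust to segmentation roughness.  Template registration is the
only non-rigid step: z scales by `avg_height/height` and XY radially by
`avg_radius/radius` about the tower's base axis point, applied equally to
the tower's beads.  Kinocilia (row 1) pass through every stage and are
reported in their own tables, but the headline quantification concerns the
three stereocilia rows.

## Bead association

"Nearest neighbours" is interpreted as a k-NN plurality vote over the
pooled border samples (k = 10 by default; k = 1 reduces to pure
nearest-surface-sample); ties break toward the smaller mean distance.  The
distance-transform route computes one anisotropy-aware Euclidean distance
transform with nearest-label propagation and reads it at the bead's voxel.
Both honour the exclusion threshold (default 100 µm — at bundle scale a
deliberate no-op, kept for pathological inputs).  On bundles whose
inter-tower gaps dwarf the bead-to-surface offsets the two routes agree on
≥95% of beads; disagreements concentrate near equidistant surfaces.

## Histograms and densities

Sector 1 is *centred* on north (boundaries at odd multiples of
`180°/n_sectors`), indexed counterclockwise viewed from the top; the
edge-aligned alternative is available via `sector_origin="edge"`.  Beads
exactly on the axis go to sector 1 deterministically.  Height bins split
`[0, H]` evenly with a final above-tip bin for z > H; beads with z < 0
(possible after registration of slightly tilted towers) are clamped into
segment 1 and counted.  Folding adds the above-tip counts sector-wise into
the top shaft segment and conserves totals exactly.

The ~200-nm segment rule is `max(1, round(H/0.2 µm))` with round half away
from zero; with the stated row heights (2.4 / 2.0 / 1.2 µm) it yields
12 / 10 / 6 shaft segments.  Density is
`count / (π · diameter · H/n_segments / n_sectors) / n_cilia`, and the
inversion `density × area × n_cilia = counts` holds to 1e−12 relative.
Aggregation pools bead coordinates, hull points and per-tower dimensions
across cells in sorted directory order (hence order-invariant) and divides
by the pooled cilia count.

## Synthetic fixtures: what a green test establishes

The generator renders capped cylinders on a common base plane with a small
seeded axis tilt (default ≤3°, avoiding artificial PCA degeneracy), a
single kinocilium column, and the validation bead pattern: one bead per
stereocilium — tall row at the tip on the side away from the middle row,
middle row mid-shaft away from the tall row, short row near the base away
from the middle row, none on the kinocilium.  Bead placements use
mid-segment height fractions so the expected (segment, sector) cell is
unambiguous under voxelization error.  Default dimensions correspond to a
P4 outer-hair-cell bundle: rows 2.4 / 2.0 / 1.2 µm tall and 0.2 µm in
diameter, a 3 µm kinocilium, 0.45–0.5 µm spacing.

Fixture voxels are 10 × 10 × 15 nm — the working resolution real data
reach after the pipeline's default 4× lateral downsampling — so analyses of
fixtures run with `resize_factor = 1`; this is a pure performance scaling,
and resizing itself is tested separately.  Synthetic beads are ~40-nm
spheres (slightly larger than real 10-nm gold, keeping centroids stable at
the coarser fixture voxel size).

What the fixtures do *not* emulate: EM texture and noise, membrane coats,
segmentation roughness, partial (truncated) stereocilia, curved or
non-cylindrical shafts, and realistic bead counts per cell.  A green
validation test therefore establishes correctness of the geometry,
association and binning chain on clean label data — not robustness to
segmentation quality, which on real data is controlled by the usage table
and by inspection of the step figures.

## Known limitations

* The absolute sense of the MET direction (toward vs away from the
  kinocilium) is fixed by convention (short row → kinocilium row); only
  relative sector patterns are validated.
* Byte labels cap a volume at 255 towers (matching the deposited format);
  the TIFF path accepts 16-bit labels.
* Translation-only alignment cannot remove rotational drift.
* Template registration assumes towers are near-cylindrical; strongly
  tapered or bent structures would be distorted by the radial scaling.
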