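# Methods

## Landmark model and registration

A specimen is an ordered list of 2-D landmarks (µm) with per-landmark
structure tags (organ outline, cavity, jacket-cell wall, apex outer wall)
and two designated bottom anchors.  Correspondence across frames and
specimens is strictly by index with equal landmark counts — the package
never resamples or re-matches outlines, because tracked-point data carry
their correspondence and any inferred matching would be a second model.

Registration is rigid only: tilt θ = arctan(slope of the anchor line),
center = anchor midpoint, clockwise rotation of every landmark about that
center.  Three choices deserve note:

* **Per-series, not per-frame.**  The transform is estimated from the
  first frame of a series and applied unchanged to every frame.  This
  makes registration a pure change of coordinates: inter-frame
  deformation (the thing under study) is preserved exactly, which a
  per-frame re-estimate would partially absorb.
* **arctan, not atan2.**  The tilt lives in (−π/2, π/2); anchors are
  re-ordered by x-coordinate first, and the synthetic generator caps
  orientation jitter at ±60°, well inside the domain.  Vertical anchor
  lines are an error naming the specimen and frame, not a silent fix.
* **Apex-up rule.**  If apex-tagged landmarks end with negative mean y
  after rotation, the anchors were evidently swapped and the geometry is
  rotated by π; with no apex tags no flip is attempted.  Geometries whose
  apex lands exactly on the anchor axis are rejected as ambiguous.

Mean shapes are per-index arithmetic means of registered specimens
(identical inputs short-circuit to the input, keeping the
mean-of-identical-copies identity exact in floating point).  The burst
deformation field is the per-index difference of the post- and pre-burst
mean shapes; displacement statistics are grouped by wall class in a fixed
order (inner, outer, lateral_a, lateral_b).

## Morphometrics

* **Cell width / length.**  Width is the distance between the arc-length
  weighted centroids of the outer and inner walls (the radial chord);
  length between the two lateral-wall centroids (the axial chord).
  Arc-length weighting makes both independent of how densely a wall was
  digitized.  The measurement chords are not specified by any tracing
  protocol we know of; this definition is the package's own, chosen so
  that inner walls bowing toward the cavity increase width.
* **Organ width.**  The x-extent of the *normalized* organ outline.  It
  is the one metric defined in the canonical frame rather than rigidly
  invariant on raw input; the registration step supplies the frame.
* **Areas.**  Absolute shoelace area; input orientation is irrelevant;
  self-intersecting outlines are rejected (shapely validity check).
* **Curvature.**  Magnitude is 1/R from a total-least-squares circle fit
  (Taubin algebraic seed, geometric Gauss–Newton refinement) — more
  robust to landmark noise than discrete three-point curvature, and exact
  on noise-free arcs.  The sign compares the wall's net bulge side
  against a cavity reference point: positive toward the cavity.  Walls
  collinear to 1e-9 of their span return 0; a reference on the chord is
  an error rather than an arbitrary sign.
* **Angles.**  Between end-to-end chords of two walls sharing a junction
  endpoint (1e-6 µm), both chords pointing away from the junction;
  reported in degrees.
* **Percent changes** are (after − before)/before × 100 with a zero
  baseline rejected.  Ratio summaries average per-cell ratios (mean of
  ratios), matching how per-cell distributions are plotted; this is why
  the width, length and ratio population means are three independent
  targets rather than two.

## Kinematics

The sperm mass is a tracked circle.  The center-displacement formula
yields a coordinate pair per step; its Euclidean norm is used as the
scalar Center_speed so that End_speed = Center_speed + Radius_speed is
well-typed — speeds are reported as scalars throughout.  Radius_speed is
signed (a shrinking mass is meaningful and propagates into End_speed).
The three-point mean filter is applied only where all three samples
exist: the smoothed series drops one boundary step at each end rather
than padding, because padding would invent data.  Tracks must have a
uniform time step (tolerance 1e-6 s); a mismatch against a stated frame
rate is an error, never a silent resample.  Individual sperm release
speed is the first-step displacement rate from the tracked initial point.

## Synthetic data generator

The generator exists so every stage has a recovery test against recorded
ground truth.  It emulates the *measured geometry* of burst, not its
mechanics — there is no pressure, elasticity or contact model.

* **Template.**  An upright egg-shaped organ outline (72 points, 5°
  sampling, height 45 µm, basal width 30 µm), a cavity ellipse inside, an
  apex outer-wall polyline, and a ring of 2×10 jacket cells plus two
  apical cells.  Each cell is built in a local (tangential, radial) frame
  as a quadrilateral with a circular-arc inner wall bowed toward the
  cavity (sagitta 0.25 × half-chord) and a straight outer wall 5 µm out.
  Wall junctions are shared bit-for-bit between adjacent wall polylines.
  Cell counts and dimensions are of the order seen in longitudinal
  sections of mature antheridia; they are scenario parameters, not
  constants.
* **Factor calibration.**  Per-cell (width, length) factors come from an
  equal-weight two-point mixture (W ± δw, L ± δl).  Requiring
  E[w] = 1.169, E[l] = 0.951 and E[w/l] = 1.211 simultaneously is only
  possible with Cov(w, l) > 0, because the ratio of means (≈1.229)
  exceeds the target mean of ratios.  The ratio constraint is linear in
  δw at fixed δl, giving δw(δl) = (WL − R(L² − δl²))/δl, minimized at
  δl* = √(L(W − RL)/R); the solution is closed-form, exact, and
  degenerates to constant pairs when R = W/L.  Infeasible user triples
  (a non-positive component) raise a calibration error.  The implied
  per-cell spread (δw ≈ 0.28) is a consequence of the three constraints,
  and it is what makes the recovered means statistical rather than
  deterministic quantities.
* **Burst deformation.**  Each cell is rebuilt analytically in its local
  frame: the inner-wall arc radius shrinks by the curvature gain
  (default 1.3, so curvature strictly increases for every cell), the
  chord shrinks exactly by the drawn length factor, and the outer wall is
  positioned so the centroid-to-centroid width equals exactly the drawn
  width factor times the pre-burst width.  Cells are anchored at their
  stiff outer wall, so inner walls do the moving — the observed
  asymmetry.  Rebuilding (rather than scaling the before-polygon) is what
  lets noise-free recovery be exact to 1e-9 while curvature still rises
  for cells whose width factor is below 1.  Organ outline and apex wall
  are scaled anisotropically (x by the width factor, y by area/width) and
  the cavity isotropically, hitting the organ-level factors exactly;
  cell, organ and cavity channels are deliberately independent because
  they are measured independently and no coupling model is reported.
* **Imaging imperfections.**  Rigid jitter (uniform tilt ≤ ±60°,
  translation ±25 µm; one pose per specimen, shared by both frames) and
  i.i.d. Gaussian landmark noise (default σ = 0.05 µm, sub-landmark, the
  package's own choice).  Coincident junction duplicates receive one
  shared draw — a digitizer clicks a junction once — which also keeps
  cell polygons chained under noise.
* **Apex series.**  Arc length grows linearly from L₀ to L₀(1 + 0.073)
  over 2.6 s at 15 frames/s (40 frames) and the series ends at the
  maximum; only the endpoint change and duration are constrained by
  measurement, so linear is the least-committal profile.
* **Tracks.**  Sperm-mass tracks integrate per-step center/radius speed
  profiles along +x; individual sperm swim at constant speed with a
  heading random walk on a 20× finer internal grid, so recorded chords
  slightly under-measure the path — the bias a real camera would show.

What the generator does **not** emulate: specimen-to-specimen template
variation (all specimens share one template shape), curved-axis or
asymmetric organs, tracking dropouts, correlated digitization error, and
any mechanical feedback between cells.  Passing recovery tests therefore
demonstrate that the *pipeline* is faithful, not that real micrographs
would yield these numbers.

## Numerical choices

Geometric test equality is 1e-9 µm; user-facing junction/closure
tolerances are 1e-6 µm.  Cell polygons must chain and be simple; the
smoother needs ≥ 3 steps; curvature needs ≥ 3 points.  CSV floats carry 9
significant digits, and reading preserves file row order so write→read is
an identity and read→write is byte-stable.  All randomness flows through
numpy Generators seeded per call; datasets derive per-specimen seeds from
one SeedSequence, so every artifact is a pure function of
(scenario, seed).

Problem sizes: recovery runs use 50 specimens × 22 cells (≈750 landmarks
per frame) and finish in seconds; the statistical round-trip check spans
20 seeds × 50 specimens.  At these sizes the mean width change carries a
standard error near 0.9 percentage points — any single seed's recovered
mean scatters accordingly, while noise-free runs are exact.

## Known limitations

* The width/length chord definitions and the organ-width chord are
  reasoned substitutes for an unpublished tracing protocol.
* Registration assumes the anchor line tilts less than 90° (generator
  caps at 60°); upside-down specimens are recovered only when apex
  landmarks are present.
* The factor mixture reproduces three population means, not the full
  per-cell distribution, which is unknown.
* Speeds are 2-D projections; out-of-plane motion is invisible to the
  model.
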