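# Methods

## Measurement model

A bleb is represented by its base outline: a simple closed polygon in
retinal-plane coordinates, arbitrary units, with the canonical frame
+x = nasal→temporal and +y = superior.  Raw annotations traced from
intraoperative footage may use an image frame (y growing downward);
`canonicalize` normalizes them given the `superior_direction` declared in
the study manifest.  All downstream code assumes the canonical frame.

*Proximal* always means "toward the visual-streak centerline" and is
determined geometrically from the sign of `vs_reference_y − retinotomy.y`,
never from the injection-site label; a label that contradicts the
geometry produces a validation warning and the geometric definition wins.

### Vertical extents and A_V

`p_prox` (`p_dist`) is the largest vertical distance from the retinotomy
to any outline vertex on the proximal (distal) side, clamped at zero when
the outline lies entirely on one side.  The extreme-margin definition (as
opposed to measuring along the retinotomy's own vertical line) reflects
how the distances are drawn in the source annotations: arrows from the
retinotomy to the farthest proximal/distal margins.  The temporal–nasal
component is disregarded entirely, so the metrics are exactly invariant
under horizontal scaling.

`A_V = p_prox / p_dist` is undefined (reported as null, excluded from
group statistics with a logged count) when `p_dist = 0`; capping or
mapping to infinity would put an arbitrary mass point into a ratio
distribution.  Classification: *away* `A_V < 0.9`, *balanced*
`0.9 ≤ A_V ≤ 1.1` (closed interval, making the three classes a partition),
*toward* `A_V > 1.1`.

### Area split

The polygon is clipped by the horizontal line through the retinotomy
(shapely line split); `area_prox` is the piece on the VS side.  The split
conserves total area to 1e-9 relative tolerance (enforced, not assumed).
`area_anisotropy = area_prox / area_dist` cross-validates `A_V` using the
whole region rather than a single extreme point.

### Ellipse fit and tilt

The base is approximated by a *moment ellipse*: center = region centroid;
axis directions and ratio from the eigen-decomposition of the region's
second central moment tensor, computed exactly for the polygon via
Green's-theorem integrals; the axes are then scaled jointly so the
ellipse area equals the polygon area.  For a solid ellipse the covariance
eigenvalues are a²/4 and b²/4, so a polygon densely sampling a true
ellipse recovers it (within vertex-sampling error; ≤ 1 % at ≥ 256
vertices, the tolerance used in the recovery tests).  Moment fitting was
chosen over algebraic conic fitting to the vertices because it is
deterministic, has no data-dependent failure modes, and is insensitive to
uneven vertex spacing in hand-traced outlines.

Tilt is the unsigned acute angle of the long axis from horizontal,
folded into [0, 90]°; the temporal/nasal lean direction is not
distinguished.  Tilt is only recorded for sufficiently eccentric blebs,
strictly `a/b > 1.1`; for near-circular fits the long-axis direction is
numerically meaningless.

## Statistical procedures

All tests are two-sided and implemented from their defining formulas (only
tail probabilities come from scipy's t and χ² distributions); scipy's
reference implementations serve as independent oracles in the test suite.

- **Welch t-test** (unequal variances, Welch–Satterthwaite df), both on
  raw values and from printed (n, mean, SEM) summaries.  The summary form
  exists because published group comparisons must be reconstructible when
  raw data are unavailable: with s²ᵢ/nᵢ = SEMᵢ² the two forms agree to
  machine precision.  Welch rather than pooled Student is the default
  because only Welch on the published A_V summaries (14, 0.67, 0.11 vs
  27, 1.27, 0.18) reproduces the published p = 0.0070 (pooled gives
  ≈ 0.028); the pooled variant remains available
  (`student_t_from_summary`).  Zero variance in both groups: p = 1 when
  means are equal, p = 0 (with a note) otherwise.
- **Pearson χ²** on the 2×2 away vs. not-away table, df = 1, *no*
  continuity correction: the uncorrected statistic on the published
  counts [[11, 3], [11, 16]] yields p = 0.0212 exactly as printed, which
  identifies the variant.  *Away* is tested against the pooled complement
  (balanced + toward).
- **D'Agostino–Pearson K²**: z-transformed skewness (D'Agostino 1970) and
  kurtosis (Anscombe–Glynn 1983), K² = z₁² + z₂² against χ²₂.  Requires
  n ≥ 8 and non-zero variance; smaller samples raise an explicit
  unsupported-size error.
- **Lognormal fitting**: ML on logs (divisor n).  Moment matching
  (σ² = ln(1 + s²/m²), μ = ln m − σ²/2) converts a published mean ± SD
  into exact lognormal parameters.
- Percentiles/IQR use linear interpolation (numpy default, type-7);
  tilt group means are plain arithmetic means of unsigned angles in
  [0, 90]° — the reported angle summaries carry no sign or circular
  structure that would justify circular statistics.

Eyes are treated as independent observations even though the cohort
design pairs two eyes within most animals; the report flags this
("multiple eyes per animal…") rather than modelling a random effect.

## Synthetic-study generator

The generator's purpose is *construct-to-measure*: each bleb is built so
that its ground-truth measurements are known exactly, making parameter
recovery a strict test of the geometry code.

Per bleb: draw `A_V` from the group's lognormal, tilt from a normal
folded into [0, 90]°, axis ratio uniform on [1.15, 2.2]; build the
ellipse with that tilt and ratio whose vertical span equals `size_scale`
(default 10 arbitrary units); place the retinotomy on the ellipse's
vertical chord such that the proximal/distal split realizes the drawn
`A_V` exactly (the chord midpoint at that height keeps the point
interior); set the VS reference on the correct side for the group label;
sample 256 boundary points and apply multiplicative radial jitter.

Calibration: group `A_V` distributions are lognormals moment-matched to
the published summaries with SD = SEM·√n — inferior (0.67, 0.11·√14),
superior (1.27, 0.18·√27); group sizes default to the cohort's 14 and 27.
The lognormal family follows the published distributional description of
the group data.  Tilt: inferior mean 0° with sd 3° (reported as
"exclusively horizontal"), superior mean 56° with sd 25° — no dispersion
is published for either group, so the sds are this package's choice:
small enough to keep the inferior group essentially horizontal, large
enough to make the superior group visibly dispersed across [0, 90]°.

Outline noise is *bounded uniform* multiplicative radial jitter
(±`outline_noise`, default 0.02).  Bounded jitter inflates both extreme
margins by a nearly deterministic factor ≈ (1 + noise) that cancels in
the `A_V` ratio, mimicking tracing imprecision without biasing the ratio
statistic; unbounded (Gaussian) jitter would make the boundary extrema
heavy-tailed in a way hand-traced outlines are not.  At the defaults,
metric recovery stays within the 1 % test tolerance; at noise 0.05 the
metrics stay within 10 % of truth for ≥ 95 % of draws.

Determinism: a study is a pure function of (specs, seed).  Each record
uses an RNG substream seeded by `[seed, record_counter]`, so records are
independent of generation order; the study carries a SHA-256 digest of
its full generating configuration.

The optional `barrier_growth_outline` generator grows a star-convex front
whose per-step advance is inversely proportional to a local adhesion
field — a caricature of detachment barriers (a horizontal high-adhesion
band for the VS, a vertical band for the superior vascular trunk).  It
produces non-elliptical outlines for stress-testing the ellipse
approximation only; it is not the calibration path and fits no physics.

### What passing tests do and do not show

The generator reproduces the *marginal* group distributions of `A_V` and
tilt and the measurement geometry, not the data-generating physics: real
blebs are not ellipses, their annotation error is not radial, eyes within
an animal are correlated, and `A_V` and tilt are drawn independently
although mechanically they share a cause (the same barriers).  Passing
recovery and calibration tests therefore validates the measurement and
inference code, not any biological claim.

## Numerical conventions

- Area conservation of the split: 1e-9 relative; ellipse recovery: 1 %
  (vertex-sampling limited at 256 vertices).
- Orientation reported in (−90, 90]; tilt folded to [0, 90].
- Outline CSV I/O writes 12 significant digits and round-trips exactly at
  that precision; report JSON is key-sorted with floats at 12 significant
  digits, so repeated runs are byte-identical.
- A retinotomy outside the outline is a warning, not an error: near-edge
  annotation jitter is expected, and exclusion decisions belong to the
  analyst, not the library.
- Degenerate inputs: collinear polygons raise a fit error; `p_dist = 0`
  makes `A_V` undefined (null), never an exception; per-eye failures in a
  batch are quarantined to a failures table and the run continues.

## Problem sizes used in the validation suite

Simulation-based checks run at sizes chosen to make Monte-Carlo error
comfortably smaller than the tested tolerances: 1 000 zero-noise records
for parameter recovery; 1e5 draws for lognormal calibration; 1e4
replicates for the Welch type-I error at the cohort's group sizes
(14 vs 27); 400 replicates (n = 100) for normality-test power; 40
datasets × 4 000 permutations for the permutation cross-check of the
Welch p-value.

## Known limitations

- No image segmentation: outlines are taken as given annotations.
- No 3-D volume or dome-height modelling, and no physical-unit
  calibration — all lengths stay in arbitrary units.
- The area-anisotropy group comparison is computed but its published
  counterpart cannot be numerically reconstructed from the printed
  summaries (the dispersion convention behind the printed ± values is
  ambiguous), so it carries no reference value.
- No multiple-testing correction and no mixed-effects modelling of the
  two-eyes-per-animal structure (a per-animal random effect is a natural
  extension hook in the generator, deliberately left unimplemented).
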