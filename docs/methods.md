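# Methods

This note records the model choices, parameter defaults and numerical
conventions behind `octseg`, and what the synthetic evaluation does and
does not demonstrate.

## Coordinates and units

A B-scan is a 2-D array with row 0 on the vitreous side (depth increases
downward, matching OCT display convention) and one A-scan per column. A
`LayerBoundary` stores one fractional row index per column, masked invalid
where undefined; positions stay in pixels and are converted to micrometres
only at reporting time using the per-volume axial spacing — no device
constant is baked in. Intensities are floats internally regardless of the
stored bit depth, because the filters need signed arithmetic. DICOM OPT
support is read-oriented and covers the minimal attribute set (rows,
columns, frame count, pixel data, pixel spacing from the shared functional
groups or top level); only uncompressed little-endian transfer syntaxes are
accepted, and the writer — intended for fixtures and interchange — requires
16-bit-representable intensities.

## Edge extraction

Speckle suppression is a single 3×3 boxcar with replicated borders; no
further denoising. Boundaries are modelled as loci of maximal axial
gradient, detected as zero crossings of a Laplacian-of-Gaussian response.
Numerical conventions that matter:

* The LoG is applied separably with explicitly **zero-summed**
  second-derivative kernels (truncated at 4σ). A truncated kernel whose
  taps do not sum to zero leaks the local intensity level into the
  response, fabricating sign changes in flat regions; zero-summing makes
  the response of any constant exactly zero, which also gives exact
  invariance to intensity offsets.
* Of the two pixels flanking a sign change, the one with the smaller
  absolute response is marked; ties (within a 1e-9 relative tolerance, so
  symmetric crossings are stable under float noise) go to the upper/left
  pixel.
* Responses below `ZC_EPS = 1e-4` of the frame peak count as zero: far
  filter tails carry no edge evidence and would otherwise contribute
  meaningless crossings.
* Default σ = 2 px, per layer overridable. The scale must resolve the
  ISe/RPE/BM transitions, which sit ~12–18 px apart at a Spectralis-like
  3.87 µm axial sampling.

Crossing weights are the rectified signed vertical gradient
(central differences of the smoothed image): dark→bright layers keep
positive-gradient crossings, bright→dark the opposite, and wrong-polarity
crossings get weight zero. This is the simplest scheme consistent with
"weight by local intensity/gradient character" and polarity suppression; a
richer, context-aware weighting (e.g. using band intensities above/below)
is a known extension point. Hysteresis linking uses thresholds relative to
the per-frame maximum weight (low 0.05, high 0.2), making the pipeline
invariant to global intensity scaling; survivors are labelled into
8-connected candidate segments (4-connectivity would fragment the
near-horizontal but locally diagonal boundary curves).

## Endpoint anchoring

The tracer needs a source (left) and destination (right) pixel. Within each
end band (3 columns — a region rather than a single column, to tolerate
border artifacts) the mean intensity profile is smoothed axially (9-px
moving average) and normalized by its 2nd/98th percentiles, which keeps the
normalization insensitive to speckle spikes. Two reference structures are
detected as threshold runs containing the global maximum: the whole
retinal bright complex (≥0.40 normalized; entered from the vitreous side)
and the hyperreflective outer band (≥0.75). Each layer anchors to one edge
of one structure: ILM = complex top, ISe = hyper-band top, RPE = hyper-band
bottom, BM = complex bottom. The strongest candidate within ±12 rows of the
anchor wins (falling back to the nearest candidate), so a true boundary
edge beats a speckle candidate sitting closer to the anchor. These
assignments are configuration (`LayerProfile.band` / `anchor_edge`), not
algorithm, and are overridable per run.

## Path graph and routing

Nodes are the candidate pixels; arcs connect column `c` to `c+1` with
`|Δrow| ≤ max_jump`. Costs reward strong edges and penalize axial
excursion: `α·(1 − w/W) + β·|Δrow|` with α = 1, β = 0.3, max_jump = 15.
β controls the trade-off between following weak evidence and leaping to a
stronger neighbouring boundary; 0.3 makes a 150-px round-trip detour onto a
parallel surface cost more than any plausible per-column advantage on a
512-column scan, while still allowing the path to cross a lesion. Two
kinds of zero-weight filler nodes keep the graph useful on pathological
input: candidate-free columns get a node at every row (bridging patchy or
locally discontinuous layer signal), and every column additionally gets
nodes on a coarse row grid (stride `max_jump // 2`), which guarantees
connectivity when a noisy column's candidates all sit far from the local
track.

Routing is Dijkstra with lexicographic priority (cost, cumulative |Δrow|,
column, row): the secondary key makes the minimum-jump optimum the unique
deterministic answer among cost ties. Must-pass picks are enforced exactly
by decomposing the route into sequential legs between waypoints — matching
the semantics of a grader pinning a point and the path re-routing around
it — rather than by arc-cost manipulation. Endpoints are concrete candidate
pixels (virtual terminals would add nothing under the waypoint
decomposition). Integer path rows are refined to sub-pixel positions by
linearly interpolating the LoG zero location between the path pixel and its
vertical neighbour (correction bounded to one pixel); grader picks are
pinned and never moved by refinement. Re-running a cached session with an
augmented `ConstraintSet` recomputes only graph construction and routing
and counts the re-route iterations.

## Manual baseline

The manual method interpolates grader seed points with a **natural cubic
spline**, evaluated at every integer column between the first and last
seed; with two seeds it degenerates to the straight line. No extrapolation
beyond the seeded span — those columns stay masked, since the grader gave
no information there. The spline passes through every seed to machine
precision (integer-column knots are written back exactly).

## Statistics

"Per pixel" means per image column (a boundary has one axial value per
A-scan); frames aggregate into the volume. All comparisons use only columns
valid in every boundary involved, and reports carry the coverage fraction.

* ΔBL: per-column |difference| × axial spacing (µm); symmetric.
* Inter-grader reproducibility: per volume and layer, the mean ΔBL over all
  common-valid columns, frames and grader pairs; summarized as mean and
  population (1/n) sd across volumes — population so a single-volume study
  reports 0, not undefined, for identical graders.
* Concordance correlation: Lin's form `2·cov/(var_x + var_y + (μx − μy)²)`
  with population moments, computed on per-volume, per-pair grader-mean
  layer locations pooled over pairs (one coefficient per layer/method; the
  pooling choice is recorded in the report metadata). Undefined (zero
  variance, equal means) is reported as NaN rather than 1.
* Agreement: per column |mean-over-graders(manual) −
  mean-over-graders(edge-select)|, averaged per volume; the paired Wilcoxon
  test uses the *signed* per-volume mean differences. All-zero differences
  are flagged degenerate with p = 1.
* Wilcoxon signed rank: zeros dropped, midranks for ties; for n ≤ 25 the
  exact two-sided p comes from a dynamic program over doubled ranks
  (equivalent to enumerating all 2ⁿ sign patterns, ties handled exactly);
  beyond that, a normal approximation with midrank tie correction and no
  continuity correction. Two-sided doubles the smaller tail, capped at 1.

## Synthetic phantoms and the in-silico study

A phantom renders five reflectivity zones (vitreous 15, inner retina 115,
outer hyperreflective band 210, sub-RPE 127, choroid 44, arbitrary units)
between four smooth truth curves, 4× axially supersampled so fractional
boundary positions produce partial-volume pixels. The inner-retina and
sub-RPE levels are chosen so neighbouring same-polarity transitions have
comparable gradient magnitude — as in real scans, no boundary dominates its
neighbours, which is exactly what makes RPE/BM disambiguation genuinely
hard rather than trivial. Speckle is multiplicative unit-mean gamma noise;
the default variance 1/9 reflects the averaging of several frames per
B-scan position typical of acquisition protocols. Cysts are superellipses
of hyporeflective fluid clipped to the retina, optionally with a thin
reflective roof; `surface_cyst_phantom` builds the canonical hard case (a
120-px dome over a large cyst) used in the re-routing evaluation. Default
geometry is 496×512 px at 3.87/11.72 µm spacing, clearly synthetic.

Simulated graders are deliberately minimal: the manual model samples truth
every 32 columns with Gaussian seed jitter (sd 2 px) and fits the spline;
the edge-select model runs the unguided trace, finds spans erring by more
than 2 px against truth, and adds one jittered (sd 1 px), candidate-snapped
must-pass pick per span before re-routing. They exercise the statistics
pipeline; they are not models of human behaviour. The in-silico study runs
12 single-frame 224×288 phantoms (geometry scaled from the full default)
with 3 graders per arm — a size chosen so the full study re-runs routinely;
its statistics are structurally identical to a full-size volume study.

What passing shows — and does not. The phantom establishes that the
pipeline localizes ideal, piecewise-constant boundaries to sub-pixel
accuracy, that constraint re-routing works exactly, and that determinism
collapses inter-grader variability when picks coincide. It does not
establish performance on real OCT: real speckle is spatially correlated,
layers have texture and shadowing, and real graders' picks differ far more
richly than Gaussian jitter. Pixel-level reproducibility numbers from the
in-silico study characterize the simulation's jitter settings, not human
graders.

## Known limitations

* The RPE and BM transitions have equal-polarity, near-equal-strength
  gradients ~12 px apart; under heavy speckle the unguided path can settle
  on the neighbouring surface for stretches, and the single-pass simulated
  grader does not always correct it fully (visible as a larger RPE
  agreement offset in the study). Inter-grader reproducibility is
  unaffected — the failure is deterministic — but accuracy on the outer
  complex benefits from more picks or a context-aware weighting.
* Layers are traced per B-scan; no cross-frame smoothness coupling and no
  simultaneous multi-surface optimization.
* The weighting scheme is a rectified gradient only; intensity context
  (band brightness above/below a crossing) is not used.
* No eye-motion or decentration handling, and no reading of proprietary
  device formats — DICOM OPT is the interchange container.
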