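# Methods

## Track statistics

A track is a strictly time-ordered sequence of ≥ 2 localisations
(frame, t, x, y, z) in physical micrometres. All geometry is computed in
3D; 2D inputs are accepted with z = 0 and degrade gracefully. For a track
with positions **x**₀…**x**ₙ:

* **path length** L = Σ ‖**x**ᵢ₊₁ − **x**ᵢ‖;
* **displacement** d = ‖**x**ₙ − **x**₀‖;
* **mean velocity** v̄ = L / duration, with duration = tₙ − t₀ in minutes.
  This is the path-length definition, not the mean of per-step speeds; the
  two coincide under uniform frame intervals, and the path-length form is
  robust to frame gaps. Tracking software varies in which definition it
  uses, so ingested summary exports should be compared with that in mind.
* **confinement ratio** r = d / L. When L = 0 (a cell that never moved) the
  ratio is formally 0/0 and is set to 0 by convention; such a cell has
  v̄ = 0 and is classified static under any positive velocity threshold, so
  the convention cannot change any downstream result.

Missing frames are preserved at the I/O layer and bridged by the single
straight segment between flanking points when computing L. This fabricates
no positions and slightly underestimates the true path.

Default inclusion filters are min 5 points and min 5 minutes of
observation, both configurable down to 0. They exist to stop 2-point noise
tracks from dominating cohort statistics; every exclusion is logged with
its reason.

## Quadrant classification

Thresholds default to v̄\* = 2 µm/min (a cell moving more than roughly one
cell width from its origin during a 30-min recording) and r\* = 0.2.
Boundary rule: the threshold value itself counts as "high" on both axes.
Velocity inclusivity (≥ 2 µm/min = motile) is the established convention;
the confinement rule is chosen symmetrically and documented here because
only one of the two is fixed by convention.

Q2 ("intermittent migration") pairs sub-threshold velocity with a *high*
confinement ratio. Since the confinement ratio measures straightness, this
pairing can seem counter-intuitive; it reflects how these quadrants are
conventionally drawn for dermal T cell data, and the implementation applies
the definition as stated rather than reinterpreting it.

Aggregation is strictly hierarchical: quadrant percentages are computed
within each field of view (fov), fov values are averaged with equal weight
per mouse, and mouse values are averaged per group with
SEM = sample SD / √(n mice). Pooled-over-cells motile fractions and
velocity histograms are also exposed (the default for frequency
distributions), because per-cell dot plots and fov-averaged bar summaries
answer different questions. Velocity histograms use half-open bins
[k·w, (k+1)·w) with default width w = 0.5 µm/min; published frequency
curves rarely state their binning, so the width is configurable.

Cell density is mean(count/volume) over 2–3 counting regions, converted
with 1 mm³ = 10⁹ µm³.

## SHG quantification

Stacks are (z, y, x), 0-based, pixel centres at integer coordinates, voxel
sizes supplied by configuration (TIFF metadata is not trusted). The
analysis crops to a 150 × 150 µm region chosen to exclude hair follicles,
extracts either the xy plane at surface_z + round(depth / z-step) — 60 µm
below the surface by default — or a zx cross-section at a given y, and
computes the percentage of pixels **at or above** a threshold.

The thresholding rule must be explicit for reproducibility: the default is
Otsu's between-class-variance maximiser on a 256-bin per-image histogram
(delegated to scikit-image), with a fixed user threshold as the
alternative; the threshold actually used is recorded in every result row.
Two caveats are documented rather than hidden: (i) on a truly bimodal image
the between-class variance is constant across an empty inter-mode
histogram region, and the argmax convention returns the lowest maximising
bin — any threshold in the gap yields the same segmentation; (ii) per-image
Otsu adapts to each image's histogram, so comparisons across conditions
with very different signal abundance can be sensitive to this choice — use
a fixed threshold when comparing absolute area fractions across groups.
A constant image has no Otsu threshold; the midpoint of its degenerate
range is used with a warning (marking all pixels positive). The surface
reference defaults to z = 0 (first acquired plane) unless configured,
since automated surface detection is out of scope.

## Synthetic experiments

The generator exists because raw intravital recordings are not
redistributable; it emulates the acquisition protocol (frames every 60 s
for 30 min ⇒ 31 frames; 512 × 512 fields; 2 µm z steps to 100 µm) and the
behavioural repertoire, giving every analysis stage a known ground truth.

**Track model.** Discrete-time persistent random walk with a two-state
pause/run Markov chain, initialised at its stationary distribution. While
running, the step direction is the previous direction blended with a fresh
isotropic unit vector (weight = persistence, renormalised) and the step
length is max(0, N(speed_mean, speed_sd)) × Δt. Phenotypes with a
confinement radius experience a per-frame harmonic pull
−k·(pos − anchor) toward their follicle anchor (k = `anchor_stiffness`),
making excursions mean-reverting; the radius parameter documents the
intended containment scale. Per-coordinate Gaussian localisation jitter
(`noise_sd`) is added to each recorded position, and positions reflect at
the volume boundaries. Cells are seeded within a 50 µm cluster radius of
follicle anchors, mirroring perifollicular Treg organisation.

**Phenotype defaults** (speeds µm/min, lengths µm):

| phenotype | speed (mean ± sd) | persistence | pause / resume | anchor radius, k | designed quadrant |
|---|---|---|---|---|---|
| static | 0 | 0 | 1.0 / 0.0 | 2, 0.5 | Q1 |
| intermittent | 4 ± 1 | 0.7 | 0.5 / 0.3 | — | Q2 (below 2 µm/min) |
| continuous | 4 ± 1 | 0.9 | 0 / 1 | — | Q3 |
| fast_confined | 5 ± 1 | 0.2 | 0 / 1 | 25, 0.2 | Q4 |

All phenotypes use 0.2 µm localisation jitter. Two defaults deserve
justification. The static anchor (2 µm, stiff): a free jitter walk of
n = 30 steps has expected confinement ≈ n^(−1/2) ≈ 0.18, which straddles
the 0.2 classification line; tethering the walk to a tight anchor keeps
displacement — and hence confinement — small, matching the biology of
sessile perifollicular cells. The intermittent chain (pause 0.5, resume
0.3) has stationary run fraction 0.3/0.8 = 0.375, putting the expected
average velocity at ≈ 1.5 µm/min — below the motility line but with mass
straddling it, as intermittent cells genuinely do; property tests therefore
assert only that a majority falls below 2 µm/min. The fast_confined
25 µm anchor sits within the observed ~50 µm perifollicular migration
range and forces low confinement at high speed.

**Seeding.** A single root seed spawns one independent stream per track
via `numpy` `SeedSequence` spawn keys (mouse, fov, track), so outputs are
bit-reproducible and enlarging a cohort never perturbs earlier tracks.

**SHG stacks.** Random straight capsules (default length 60 µm, thickness
3 µm, mostly in-plane with z tilt ∼ N(0, 0.3)) are stamped into a boolean
voxel mask one at a time until the volumetric fill is within ±2 points of
the requested fraction; unreachable targets raise with a parameter
suggestion. The intensity volume is uniform background noise strictly
below a known ceiling (default 40) with fibre voxels lifted to 120–215, so
thresholding at the ceiling recovers the ground-truth mask exactly. The
default rendering volume is 150 × 150 × 20 µm at 2 µm voxels — small
enough that simulation-heavy tests run in seconds while leaving ≈ 5 600
pixels per analysed plane (binomial sampling error ≈ 0.5 points at 85 %
fill).

**What the generator does not emulate:** optical point-spread blurring,
photon (Poisson) noise, cell entry/exit mid-recording, division, follicle
geometry beyond point anchors, or any real correlation between collagen
density and cell speed. Passing tests therefore demonstrate correctness of
the measurement pipeline on idealised motion, not biological fidelity of
any particular parameter value.

## Statistics

* **Mann-Whitney U**, two-sided. Exact mode enumerates all C(n₁+n₂, n₁)
  rank assignments and reports P(min(U₁,U₂) ≤ observed); auto mode uses it
  when min(n) ≤ 8 and the pooled data are tie-free (at most 12 870 splits),
  otherwise the normal approximation with tie-corrected variance and a 0.5
  continuity correction (flagged in the method string). Degenerate
  all-tied input returns p = 1.
* **Kruskal-Wallis H** with the standard tie correction; p from χ²(k − 1).
* **Dunn's post hoc**: pairwise z on pooled mean ranks with tie-corrected
  variance, over all pairs or versus a control; raw p adjusted by
  Holm-Šídák by default (Bonferroni by flag). The Holm-Šídák default keeps
  one documented family-wise rule across the package.
* **Holm-Šídák**: step-down adjusted pᵢ = max over j ≤ i of
  1 − (1 − p₍ⱼ₎)^(m − j + 1), clipped to 1; monotone by construction.
* **Quadrant panels** are compared with Welch (unequal-variance) t tests on
  per-mouse percentages, Holm-Šídák-corrected across the four quadrants —
  the parametric battery conventionally applied to such panels. Welch is
  chosen over pooled-variance t because mice-per-group counts are small
  and variances are not credibly equal.

Note the calibration consequence of discreteness: for n = 10 per group the
exact attainable size of a nominal α = 0.05 Mann-Whitney test is ≈ 0.043,
so Monte-Carlo type-I estimates hover slightly below 0.05 by design, not by
error.

## Pipeline and reproducibility

A run is described by one YAML config (validated with pydantic; all
violations reported at once). Stage order: ingest/simulate → metrics →
behaviour → statistics → SHG. SHG task failures are collected, not fatal;
the report is then flagged partial (CLI exit code 4). All tables are
written with a fixed 9-significant-digit float format, so synthetic-mode
runs are byte-identical given the same config and seed; `report.json`
carries provenance (config hash, seed, package version, timestamp — the
timestamp is deliberately kept out of the numeric tables).

Problem sizes used by the test suite and acceptance script (100-track
oracle sweeps, 200 tracks per phenotype, 200 replicate mixture-recovery
cohorts, 2 000-replicate null calibrations) were chosen to make sampling
error a small fraction of each tested tolerance while keeping the whole
suite desk-scale.

## Known limitations

* "Mean velocity" from commercial trackers may be the mean of
  instantaneous speeds; ingested pre-computed summaries are taken at face
  value.
* No µm-per-pixel default exists for converting pixel-space exports; the
  caller must calibrate before ingest (coordinates are physical µm).
* Per-image Otsu thresholds complicate cross-condition comparisons of
  absolute SHG area (see above).
* The quadrant classification is a qualitative description; no attempt is
  made to model the velocity–confinement joint distribution.
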