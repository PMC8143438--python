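# dermtrack

Quantitative analysis of regulatory T cell (Treg) interstitial migration in
skin, as measured by multiphoton intravital microscopy (MP-IVM).

Tregs in resting dermis are mostly sessile and cluster around hair
follicles; inflammation recruits them and switches a large fraction into a
migratory state. Quantifying that switch from time-lapse 3D recordings
requires a small but exacting battery of computations: per-cell track
statistics, a behavioural classification on the velocity–confinement
plane, collagen-density readouts from the second-harmonic-generation (SHG)
channel, and nonparametric statistics over a mouse/field-of-view hierarchy.
`dermtrack` implements that battery as a tested, reusable pipeline, together
with a synthetic-experiment generator so every stage can be validated
against known ground truth.

## What it computes

For each cell track (positions **x**₀…**x**ₙ at times t₀…tₙ, in µm/s):

* total track length `L = Σᵢ ‖xᵢ₊₁ − xᵢ‖` (µm)
* displacement `d = ‖xₙ − x₀‖` (µm)
* mean velocity `v̄ = L / (tₙ − t₀)` (µm/min)
* confinement ratio `r = d / L ∈ [0, 1]` (1 = perfectly straight)

Cells are classified on the (v̄, r) plane with thresholds v̄\* = 2 µm/min and
r\* = 0.2 into four quadrants: **Q1** static (low/low), **Q2** intermittent
migration (low velocity, high confinement ratio), **Q3** continuous
migration (high/high), **Q4** fast but confined (high velocity, low
confinement). A cell is *motile* when v̄ ≥ 2 µm/min, so the motile fraction
equals %Q3 + %Q4. Quadrant percentages aggregate strictly up the
experimental hierarchy — per field of view, averaged per mouse, then
mean ± SEM across mice per group.

The SHG module crops each stack to a 150 × 150 µm region (excluding hair
follicles), extracts an xy plane at a chosen depth below the skin surface
(or a zx cross-section), and reports the percentage of area at or above an
Otsu or fixed intensity threshold, plus the mean intensity. Cell abundance
is reported as cells/mm³ averaged over counting regions.

Group comparisons use Mann-Whitney U (exact by enumeration for small
tie-free samples), Kruskal-Wallis with Dunn's post hoc for ≥ 3 groups, and
Holm-Šídák-corrected families of Welch t tests for quadrant panels.

## Worked example

Simulate a two-group experiment — an "untreated" static-dominant cohort and
an "inflamed" cohort dominated by continuous migrators — and analyse it
end-to-end. Write `run.yaml`:

```yaml
synthetic_groups:
  - group: inflamed
    mixture_weights: {static: 0.15, intermittent: 0.2, continuous: 0.45, fast_confined: 0.2}
    n_tracks_per_fov: 20
    n_fov_per_mouse: 3
    n_mice: 4
  - group: untreated
    mixture_weights: {static: 0.7, intermittent: 0.2, continuous: 0.05, fast_confined: 0.05}
    n_tracks_per_fov: 20
    n_fov_per_mouse: 3
    n_mice: 4
shg_tasks:
  - {name: collagen, synthetic_fill: 0.85, method: fixed, threshold: 40.0, depth_um: 10.0}
seed: 1
```

then:

```text
$ dermtrack analyze run.yaml --output-dir out
analysis complete: outputs in out
$ dermtrack report out
inflamed: n=240 tracks, motile 70.4%, median velocity 3.53 µm/min
untreated: n=240 tracks, motile 15.4%, median velocity 0.51 µm/min
rejected tracks: 0
```

The inflamed group is strongly motile (70 % of cells at ≥ 2 µm/min versus
15 % in the resting group), and `out/stats.csv` records the two-group
Mann-Whitney on per-cell velocities (p ≈ 6 × 10⁻³²) plus Holm-Šídák-corrected
Welch t tests on the per-mouse quadrant percentages:

```text
comparison,statistic,p_value,method,n_per_group,adjusted
velocity: inflamed vs untreated,10924,5.9638857e-32,mann_whitney_normal_approx_cc,240/240,False
Q1%: inflamed vs untreated,-11.4683907,0.000170342192,welch_t_holm_sidak,4/4,True
```

`out/shg.csv` shows the synthetic collagen stack (85 % true fibre fill)
quantified at 86.2 % area above threshold in the analysed plane:

```text
task,plane,depth_um,percent_area,threshold_used,...
collagen,xy,10,86.1688889,40,...
```

The run also writes `per_track.csv` (metrics + quadrant per cell),
`per_fov.csv` / `per_mouse.csv` / `per_group.csv` (hierarchical quadrant
summaries with SEM), per-group velocity histograms, and `report.json` with
provenance (config hash, seed, version). The same analyses are available as
library calls (`dermtrack.motility`, `dermtrack.behaviour`, `dermtrack.shg`,
`dermtrack.stats`, `dermtrack.pipeline.run`), and real data enter as
long-format CSV track tables (`track_id, frame, t_s, x_um, y_um, z_um,
mouse, fov, group`) plus grayscale TIFF stacks.

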