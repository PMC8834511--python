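# cardioquant

Quantitative analyses for imaging and transcriptomic studies of the aging
zebrafish heart, built as an open, tested pipeline with ground-truthed
synthetic data for every stage.

The package targets three recurring measurement problems in this field:

1. **AFOG histology quantification.** Trichrome-style (acid fuchsin-orange G)
   sections show muscle in brown-orange, fibrin/cell debris in red and
   collagen in blue. A trainable pixel classifier (random forest over
   color/texture features, scribble-supervised) segments each section into
   {background, muscle, fibrin, collagen}; per-heart wound metrics are

   - wound % = 100 · (A_fibrin + A_collagen) / A_muscle
   - collagen-in-wound % = 100 · A_collagen / (A_fibrin + A_collagen)

   with areas in µm² summed over a heart's serial sections before forming
   the ratio, valve regions excluded by mask, and leukocyte counts
   normalized per 1000 µm² of muscle.

2. **4D immune-cell tracking.** Light-sheet movies (t, z, y, x; frames every
   2 min, 90 cycles) of fluorescent mpeg⁺ cells are band-pass denoised
   (difference of Gaussians), segmented per frame by anisotropy-aware
   watershed, filtered by volume to remove debris, drift-corrected
   (median displacement of mutually-nearest-neighbor centroids), and linked
   into tracks by gated optimal assignment; tracks shorter than five
   timepoints are excluded. Per track the pipeline reports Wadell sphericity

   ψ = π^(1/3) (6V)^(2/3) / A,

   mean speed (µm/min) and the time-averaged mean squared displacement
   MSD(τ) = ⟨|r(t+τ) − r(t)|²⟩, whose slope versus lag time is 6D for 3D
   Brownian motion. Group comparisons (Welch t, Wilcoxon rank-sum) use
   hearts, not cells, as replicates.

3. **DEG set comparisons.** Differential-expression tables
   (gene_id, log2fc, padj) are compared at adjusted p < 0.05 (strict):
   overlap between studies, direction concordance of shared genes,
   marker-panel reports (e.g. complement components) and unique-marker
   intersections with lineage rollups.

Every stage has a synthetic generator with exact ground truth
(`cardioquant.synthetic`): AFOG-like annular sections whose class areas match
the configured wound fractions to the pixel; movies of prolate-ellipsoid
cells whose analytic sphericity equals a sampled target and whose centroids
follow reflected Brownian motion with optional stage drift; and paired DEG
tables with exact overlap and concordance counts.

## Worked example

Simulate a small movie (5 cells, 10 debris objects, 8 frames at 2 min),
run the full tracking chain and summarize the heart:

```python
from cardioquant.synthetic import MovieSimConfig, generate_movie
from cardioquant.pipeline4d import track_movie
from cardioquant.tracking import summarize_heart

cfg = MovieSimConfig(n_cells=5, n_debris=10, frames=8,
                     diffusion_um2_per_min=0.5,
                     target_sphericity_mean=0.85, target_sphericity_sd=0.05,
                     noise_model={"gaussian_sd": 0.0, "poisson_scaling": 0.0},
                     seed=5)
movie, truth, debris = generate_movie(cfg)
res = track_movie(movie, cell_radius_um=5.0, min_volume_um3=cfg.volume_filter_um3)
s = summarize_heart(res.tracks, "demo-heart", "young",
                    cfg.frame_interval_min, ref_lag=3)
print(f"tracks: {s.n_tracks}  cells at t0: {s.n_cells_t0}")
print(f"mean speed: {s.mean_track_speed_um_per_min:.3f} um/min")
print(f"mean MSD(lag 3 = 6 min): {s.mean_msd_at_ref_lag_um2:.2f} um^2")
print(f"mean sphericity: {s.mean_sphericity:.3f}")
```

prints

```
tracks: 5  cells at t0: 5
mean speed: 0.986 um/min
mean MSD(lag 3 = 6 min): 21.48 um^2
mean sphericity: 0.828
```

All five simulated cells are recovered as full-length tracks, the ten
sub-threshold debris objects are removed by the volume filter, the mean
speed is consistent with the configured diffusivity (for 3D Brownian motion
the expected frame-to-frame speed is 2√(2·2DΔt/π)/Δt ≈ 1.1 µm/min at
D = 0.5 µm²/min; with only five cells the drift correction absorbs a small
part of the shared motion, lowering the estimate slightly), and the
measured sphericity sits close to the generator's analytic target (0.862)
up to voxelization.

A YAML-configured end-to-end run (synthetic histology + tracking + DEG
overlap, with per-stage seeds derived from one global seed and every output
stamped with the config hash) is available as `cardioquant run config.yaml`;
see `cardioquant --help` for the other subcommands (`histo-train`,
`histo-quant`, `track`, `deg-compare`, `deg-panel`).

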