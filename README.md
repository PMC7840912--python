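# granuletrack

Single-granule tracking and dynamics analysis for time-lapse
fluorescence movies of cells bearing mutant-keratin aggregates.

Cells expressing disease-causing keratin mutants (such as the
K14 R125C mutant found in *epidermolysis bullosa simplex*) form
spherical cytoplasmic keratin granules that are surprisingly dynamic:
they nucleate near the cell edge, grow for tens of minutes while being
transported toward the cell centre, frequently fuse with each other,
and finally dissolve at a sharp transition zone roughly 10 µm from the
cell boundary.  Quantifying this life cycle — and how drugs change
it — requires following every granule individually through a movie.
`granuletrack` provides that pipeline for cell biologists and image
analysts:

- **Spot detection** per frame with a Laplacian-of-Gaussian filter
  matched to ~1 µm blobs, sub-pixel localization and background-
  corrected fluorescence measurement.
- **Tracking** by exact linear-assignment linking (1 µm gate), gap
  closing (1 µm, up to 2 missed frames) and merging (1 µm); splitting
  is disabled, and tracks shorter than 10 spots are dropped.
- **Track taxonomy**: solo tracks (granules that never fuse) versus
  merging families consisting of one *main* track (the longest-lived
  granule) and *sub* tracks that end by fusing into it.
- **Kinematics**: gliding 8-frame local track speed (path length per
  minute) and advance speed (net displacement per minute), their
  ratio, persistence, lifetimes, and peak-aligned fluorescence
  growth/shrink profiles.
- **MSD analysis** with the power-law model ⟨r²⟩ = Γ tᵅ fitted on
  log–log axes (fits with R² < 0.8 discarded): α ≈ 1 free diffusion,
  α > 1 directed transport, α < 1 constrained motion; per-axis α
  after rotating each track onto its transport axis; sliding local α;
  pair-count-weighted ensemble MSD with D from MSD = 4Dt.
- **Cohort statistics** for before/after drug experiments: per-cell
  solo-track summaries compared with the exact Wilcoxon matched-pairs
  signed-rank test and labelled `*`, `**`, `***` at p ≤ 0.05 / 0.01 /
  0.001.
- **A synthetic movie simulator** that encodes the granule life-cycle
  model (peripheral Poisson nucleation, logistic growth to a plateau,
  size-dependent inward drift, diffusion, fusion, linear dissolution)
  and renders ground-truthed 16-bit TIFF stacks — so every stage of
  the pipeline is testable without microscope data.

## Worked example

`examples/04_msd_alpha.py` simulates the three reference motion
regimes and runs the MSD-exponent analysis on each:

```
free diffusion   : mean alpha = 0.96  (200 accepted fits)
inward drift     : mean alpha = 1.96  (200 accepted fits)
0.5 um box       : mean alpha = 0.57  (155 accepted fits)
ensemble diffusion coefficient: 1.62e-04 um^2/s (simulated 1.67e-04; ...)
```

Free 2-D diffusion is recovered at α ≈ 1, constant inward drift is
classified as directed transport (α → 2), and diffusion confined to a
0.5 µm reflecting box as constrained motion (α < 1); the ensemble fit
recovers the simulated diffusion coefficient within a few percent.
The other example scripts cover the remaining capabilities —
simulation (`01`), detection + tracking + classification (`02`),
kinematics (`03`) and the paired drug comparison (`05`); for instance
`02` reports

```
detected 1602 spots across 60 frames
built 49 tracks in 41 groups (34 solo, 7 merging families, 8 fusion events)
```

on a 60-frame simulated movie, i.e. the per-frame detections, the
linked tracks and the solo/merging breakdown with fusion counts.

## Command line

The same stages are available as a thin CLI:

```sh
granuletrack simulate --seed 7 --out run/sim
granuletrack detect   --movie run/sim/movie.tif --out run/spots.csv
granuletrack track    --spots run/spots.csv --out run/tracks
granuletrack analyze  --tracks run/tracks/tracks.csv --out run/analysis
granuletrack msd      --tracks run/tracks/tracks.csv --out run/msd
granuletrack compare  --tracks cell1.csv cell2.csv ... --out run/compare
granuletrack render   --movie run/sim/movie.tif --tracks run/tracks/tracks.csv --out run/overlay
```

Every run writes its resolved YAML configuration and a manifest
(config hash, seed, versions), and is bit-reproducible given the same
config and seed.

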