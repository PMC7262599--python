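# centrodyn

Quantification of centrosome dynamics in multi-channel time-lapse
fluorescence microscopy of adherent (U2OS-like) cells: spot detection,
nuclear/cell segmentation, track linking, and the derived separation,
congression and positioning statistics — together with a synthetic movie
generator with full ground truth, so every stage of the pipeline is
verifiable without microscopy data.

## The problem

Before nuclear envelope breakdown (NEBD), the two centrosomes of a cell
separate and move to opposite sides of the flat, disk-shaped nucleus;
after inhibition of the kinesin Eg5 they move back together
("congression").  Quantifying this requires, per cell and per 5-min frame:
the positions of two diffraction-limited spots, the nuclear and cellular
centroids, and tracks linking the spots through time.  From these the
pipeline computes:

- inter-centrosome distance d(t), separation onset and time of first
  contact (d < 1.5 μm sustained for 2 frames), and the cohort-level
  cumulative percentage of congressed cells;
- per-centrosome speeds (path length / elapsed time over the active
  phase) and time-averaged mean squared displacement
  MSD(τ) = ⟨|r(t+τ) − r(t)|²⟩, with per-cell high/low displacement
  grouping;
- the angle subtended at the nuclear centroid by the two centrosomes, the
  midpoint-to-centroid alignment distance, and distances of each
  centrosome to the nuclear and cellular centroids;
- nuclear-envelope contact phases (outside / pause / after-pause speeds),
  rule-based position classes, and the acute rotation angle between the
  centrosome axes at two time points;
- EB3 comet statistics (speed, MSD, track lengths) and
  nuclear-envelope line profiles with percent-of-max normalization plus a
  perinuclear ring-prominence score.

Detection follows the difference-of-Gaussians recipe for spots of size
~3 px (sigmas 1.5/4.5 px), Otsu background, maxima-seeded region growing
with a 15-px minimum spot size, and a circularity filter 4πA/P² ≥ 0.7.
Nuclei are segmented by threshold → morphology → distance transform →
watershed; cells by Gabor texture energy.  Linking offers
nearest-neighbour, drift-prediction and constant-velocity Kalman models
(EB3 default search radius 3 px).

## Worked example

```python
from centrodyn.config import PipelineConfig
from centrodyn.pipeline import run_pipeline
from centrodyn.synth import (SceneConfig, TrajectoryProgram, make_scene,
                             render_movie, simulate_pair)

scene = make_scene(SceneConfig(n_frames=30))          # 51×51 μm, 0.2 μm/px
prog = TrajectoryProgram(mode="separation", speeds_um_min=(0.3, 0.3),
                         target_distance_um=10.0, target_angle_deg=180.0)
truth = simulate_pair(prog, scene, seed=5)
stack = render_movie(scene, truth, seed=5)            # T,C,Y,X float stack
res = run_pipeline(PipelineConfig(), stack)
print(res["pair_metrics"][["final_distance_um", "angle_deg",
                           "speed_c1_um_min"]].round(3))
```

prints

```
   final_distance_um  angle_deg  speed_c1_um_min
0             10.002    179.915            0.306
```

i.e. the pipeline recovers, from rendered images alone, the programmed
10-μm endpoint distance, the diametric (180°) arrangement about the
nuclear centroid, and the 0.30 μm/min separation speed.

The same stages are available from the shell:

```
centrodyn simulate --mode separation --seed 3 --out sim/
centrodyn detect --stack sim/movie.ome.tif --out spots.csv
centrodyn track --spots spots.csv --radius 10 --out tracks.csv
centrodyn run --stack sim/movie.ome.tif --out results/
```

## Acceptance script

`scripts/acceptance.py` regenerates a small synthetic cohort (separation
and congression programs at the stated imaging regime), pushes every
movie through the full image pipeline, and prints the recovered endpoint
distance, angle, speed and contact-frame error next to the programmed
values:

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```
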