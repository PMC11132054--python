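# antheridyn

Quantitative 2-D morphodynamics of antheridium burst in the moss
*Physcomitrium patens*.

When a mature moss antheridium is hydrated, the inner walls of its two
apical cells rupture, the apex swells, and the capsule — a single layer of
sterile jacket cells around the sperm chamber — snaps: the jacket-cell
inner walls, bowed toward the cavity under turgor, extend inward and expel
the sperm mass within seconds.  `antheridyn` is a library and CLI for
quantifying that process from tracked 2-D landmarks (µm) digitized off
time-lapse micrographs: no image processing, landmarks in, numbers out.
It is written for plant biomechanics groups measuring dehiscence-like
events on small numbers of specimens.

## What it computes

**Landmark normalization and mean shapes.**  A specimen *k* at time *t* is
an ordered landmark list *geometry*ᵏ(*t*) = ((x₁,y₁),…,(xₙ,yₙ)).  Two
bottom anchor landmarks (x_l, y_l), (x_r, y_r) taken at the first frame
define a tilt

θᵏ = arctan((y_r − y_l)/(x_r − x_l)) ∈ (−π/2, π/2),  cᵏ = anchor midpoint,

and every landmark is replaced by R(θᵏ)(p − cᵏ) with the clockwise
rotation R, putting the anchors symmetrically on the x-axis and the apex
on top (a π flip is applied if needed).  The per-index average over
specimens is the geometry model, and the burst deformation field is

dynamics = geometry_model(t = 1) − geometry_model(t = 0),

with t = 0, 1 the frames right before and after burst.

**Morphometrics.**  Per jacket cell: width (outer-to-inner wall centroid
distance), length (lateral-to-lateral centroid distance), width/length
ratio, polygon area, and signed inner-wall curvature (total-least-squares
circle fit; positive toward the cavity).  Per organ: outline and cavity
areas, longitudinal width, apex outer-wall arc-length series, and angles
between adjacent outer walls.  All changes are reported as percent change
(after − before)/before × 100.

**Kinematics.**  The ejected sperm mass is a tracked circle (center,
radius).  Per step: Center_speed = ‖Δcenter‖/Δt, Radius_speed = Δr/Δt,
End_speed = Center_speed + Radius_speed, each raw and smoothed with a
three-point mean filter.  Individual sperm release speed is the
displacement rate out of the tracked initial point.

**Synthetic data.**  A calibrated generator builds antheridium templates
and burst deformations whose *population* effect sizes are the measured
ones (+16.9% cell width, −4.9% length, +21.1% ratio, −9.4% organ area,
−5.0% organ width, −21.9% cavity area, +7.3% apex wall in 2.6 s at
15 frames/s), with recorded per-specimen ground truth for recovery tests.
Hitting the width, length *and* mean-of-ratios targets simultaneously
forces positively correlated per-cell (width, length) factors; the
generator solves an equal-weight two-point mixture for this in closed
form.

## Worked example

```python
import antheridyn as ad

scenario = ad.BurstScenario()                      # the wild-type conditions
series, truths = ad.simulate_burst_dataset(scenario, n_specimens=50, seed=1)
metrics = ad.dataset_metrics(series)               # normalize + measure
print(ad.summarize_metrics(metrics).to_string(index=False))
```

```
                metric units    n       mean        sd
    cavity_area_change     %   50 -21.917360  0.158237
   cell_area_extension     % 1100  13.053223 40.550989
    cell_length_change     % 1100  -5.346127 11.716892
     cell_ratio_change     % 1100  20.614300 14.898727
     cell_width_change     % 1100  15.872827 28.205604
 inner_curvature_after  1/µm 1100   0.375409  0.082663
inner_curvature_before  1/µm 1100   0.290227  0.065582
     organ_area_change     %   50  -9.398560  0.076888
    organ_width_change     %   50  -4.973666  0.231801
```

Fifty noisy, randomly oriented specimens recover the embedded population
effect sizes: mean jacket-cell width up ~15.9% (truth 16.9%, standard
error ≈ 0.9), length down ~5.3%, ratio up ~20.6% (truth 21.1%), while the
organ-level changes — applied deterministically per specimen — come back
to within a tenth of a percent (−9.4% area, −5.0% width, −21.9% cavity).
The per-cell standard deviations reflect the calibrated factor mixture,
not measurement error.  Inner-wall curvature increases for every cell
(0.29 → 0.38 µm⁻¹), the direction that drives sperm expulsion.

The same stages are available from a shell:

```sh
antheridyn simulate --seed 1 --n-specimens 5 --output run
antheridyn normalize --input run_landmarks.csv --output norm.csv
antheridyn metrics   --input run_landmarks.csv --output met.csv
antheridyn kinematics --input run_tracks.csv --output speeds.csv --fps 15
antheridyn report    --metrics met.csv
```

## Layout

- `src/antheridyn/geometry.py` — landmark types, normalization, mean
  shapes, deformation fields
- `src/antheridyn/morphometrics.py` — areas, widths, curvature, angles,
  apex extension
- `src/antheridyn/kinematics.py` — sperm-mass and sperm speeds, smoothing
- `src/antheridyn/synthetic.py` — calibrated generator with ground truth
- `src/antheridyn/io.py`, `cli.py`, `pipeline.py` — formats, commands,
  end-to-end helpers
- `docs/methods.md` — models, assumptions, numerical choices

Not in scope: 3-D volume reconstruction, AFM/TEM quantification,
fluorescence intensity, landmark detection from pixels, and non-rigid
(Procrustes-style) registration.
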