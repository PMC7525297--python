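# otomsi — multispectral otoscopy analysis toolkit

Accurate delineation of the tympanic membrane (TM, the eardrum) in
otoendoscopic images supports the diagnosis of otitis media and the planning
of middle-ear surgery, but under standard white-light illumination the TM,
the handle of the malleus and the surrounding ear-canal wall have low mutual
contrast and the image is criss-crossed by blood vessels. Multispectral
imaging changes the picture: hemoglobin absorbs very little red light
(~630 nm), so under red illumination the vessels disappear, the canal wall
becomes homogeneous, and the collagen-rich membrane stands out sharply from
its surroundings — making the TM boundary far easier to find than in the
white, green (~530 nm) or blue (~450 nm) channels.

`otomsi` packages that analysis as tested, reproducible code:

* **`otomsi.phantom`** — a seeded generator of synthetic multispectral
  eardrum image sets (four co-registered channels plus ground-truth masks)
  that reproduce the contrast structure above, since real patient images of
  this kind generally cannot be shared;
* **`otomsi.msio`** — image I/O, grayscale and jet-colormap conversion, and
  the region-histogram / line-profile tools used to quantify per-channel
  contrast;
* **`otomsi.snake`** — a localized region-based active contour on a level
  set: the contour is the zero level of a signed distance function φ, region
  membership is expressed through a smoothed Heaviside

  ℋ(φ) = 1 for φ ≤ −ε, 0 for φ ≥ ε, ½(1 − φ/ε − sin(πφ/ε)/π) otherwise,

  updates are confined to the band selected by its derivative magnitude, the
  smoothed Dirac δ(φ) = (1 + cos(πφ/ε))/2ε for |φ| < ε, and each band pixel
  moves under the competition of its local interior and exterior mean
  intensities within a window of half-width *r*, plus curvature
  regularization;
* **`otomsi.metrics`** — Dice similarity coefficient
  DSC = 2|A∩B| / (|A|+|B|) and maximum Hausdorff distance
  HD(A,B) = max{h(A,B), h(B,A)}, h(A,B) = max_{a∈A} min_{b∈B} ‖a−b‖,
  computed on boundary pixel sets in pixel units;
* **`otomsi.pipeline`** — the cohort experiment: generate phantoms, place
  one covering-ellipse initialization per set, segment all four channels
  from that same mask, aggregate per-channel Dice / max-HD means and rank
  the channels.

## Worked example

```python
from otomsi import phantom, pipeline, snake, metrics

spec = phantom.default_phantom_spec()            # 976 x 494 px
ms = phantom.generate_phantom(spec, seed=7)      # four channels + ground truth

init, init_mask = pipeline.make_init_mask(ms, jitter_seed=1)
params = snake.default_contour_params((spec.height, spec.width))
res = snake.evolve_contour(ms.channels["red"], init_mask, params)

rec = metrics.evaluate(res.mask, ms.gt_tm_mask, "red", "demo")
print(f"converged={res.converged} after {res.iterations_run} iterations")
print(f"dice={rec.dice:.4f}  max_hd={rec.max_hd:.2f} px")
```

prints

```
converged=True after 97 iterations
dice=0.9997  max_hd=7.00 px
```

i.e. the contour, started from an ellipse 5% larger than the true membrane
with seeded placement jitter, locks onto the red-channel TM boundary with
99.97% overlap against ground truth and a worst-case boundary error of 7
pixels (at the malleus attachment, where the membrane rim has no local
contrast under red light). Running all four channels of a 12-phantom cohort
(`pipeline.run_experiment(spec, 12, master_seed=42)`) ranks red first both
by mean Dice and by mean max HD, with white and green degraded by their
overlapping inside/outside intensity histograms and vessel crossings, and
blue by low illumination and noise.

The same operations are available from the shell:

```bash
otomsi phantom generate --n 12 --seed 42 --out phantoms/
otomsi snake segment --image red.png --init mask.png --out out.png
otomsi metrics evaluate --pred out.png --truth gt.png
otomsi experiment run --n 12 --seed 42 --out results/
```

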