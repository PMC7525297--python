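# Methods

## The segmentation model

The tympanic membrane (TM) is segmented with a localized region-based active
contour represented implicitly: the contour C is the zero level set of a
signed distance function φ over the image domain, with φ < 0 inside. Region
membership enters through a smoothed Heaviside of φ,

    ℋ(φ) = 1                       φ ≤ −ε
         = 0                       φ ≥ ε
         = ½(1 − φ/ε − sin(πφ/ε)/π)   otherwise,

whose derivative magnitude is the smoothed Dirac

    δ(φ) = (1 + cos(πφ/ε)) / 2ε    for |φ| < ε, else 0.

ℋ is continuous and C¹ across the band edges and δ integrates to one over
[−ε, ε]; both properties are pinned by tests. The sign convention (ℋ = 1 on
the interior, where φ < 0) makes ℋ the interior indicator and 1 − ℋ the
exterior indicator.

At every pixel in the band where δ > 0, the image is modelled as locally
two-phase: μ_in and μ_out are the ℋ-weighted means of the intensity over the
interior and exterior parts of a square window of half-width *r*
(`local_radius`) centred on the pixel. The evolution law is

    φ_t = δ(φ) · [ F + ν · κ̂ ],

with the per-pixel normalized region-competition force

    F = ((I − μ_in)² − (I − μ_out)²) / ((I − μ_in)² + (I − μ_out)² + tiny) ∈ [−1, 1]

and κ̂ = clip(κ / κ_sat, −1, 1) the saturated mean curvature
(κ = div(∇φ/|∇φ|), κ_sat = 0.15 px⁻¹). Each iteration applies a CFL-capped
step (largest |Δφ| equal to `step_size`), followed by one upwind step of the
Sussman reinitialization PDE φ_t = sign(φ)(1 − |∇φ|), which restores
|∇φ| ≈ 1 near the band while preserving the sub-pixel interface; an exact
Euclidean-distance-transform rebuild runs every `reinit_every` iterations.
Evolution stops when the fraction of pixels changing inside/outside label,
averaged over a 10-iteration window, falls below `convergence_tol` (checked
after a 30-iteration warm-up so the start-up transient — φ accumulating
sub-pixel motion before any label flips — is not mistaken for convergence),
or at `max_iters`. The procedure is fully deterministic.

### Why these numerical choices

* **Per-pixel force normalization.** Normalizing the raw mean-separation
  force by its band maximum lets a handful of strong-edge pixels set the CFL
  scale, and the rest of the front crawls at ~2% of the cap; scaling by a
  band quantile loses a race described below. The per-pixel ratio gives
  every off-boundary pixel a comparable speed and — crucially — saturates at
  ±1 on genuine edges, making them stiff against the regularizer.
* **Saturated curvature with ν > 1.** Where the membrane rim has no local
  contrast (the malleus handle meets the rim at the same intensity as the
  canal wall under red light; see the phantom description), the local
  two-phase energy has no stable minimum: left to run, the contour slowly
  carves a finger down the malleus strip, which is energetically favourable
  at every step. With curvature saturated at κ_sat and weighted by ν = 1.2,
  bending sharper than κ_sat (feature radius below ~7 px) outweighs even a
  fully saturated data force, so the contour cannot push a finger through a
  low-contrast gap narrower than ~2/κ_sat ≈ 13 px, while the smooth rim
  (κ ≈ 0.005 px⁻¹) is essentially unregularized. Residual sag of the contour
  across the malleus attachment is ~3–8 px and sets the worst-case boundary
  error of red-channel segmentations.
* **Early stopping as part of the method.** Even with the saturation
  argument above, the no-contrast junction admits slow residual motion; the
  windowed label-change criterion halts the evolution once the contrast-
  bearing parts of the boundary are pinned. This mirrors how such contours
  are used in practice — a fixed mask and a fixed number of loops — and the
  result at the junction is therefore initialization- and
  stopping-dependent; the tests quantify exactly this regime.
* **Localization window.** The window is a square (a Chebyshev-norm ball) of
  half-width `local_radius`, computed with separable box filters whose cost
  is independent of the radius. The pointwise `local_means` diagnostic uses
  the identical window. The radius must exceed the largest expected
  initialization offset: beyond it both half-windows see the same tissue and
  the data force vanishes. With the default initialization (covering factor
  1.05, 3% jitter) offsets reach ~35 px at the ellipse major-axis tips, so
  the full-resolution default is r = 40 px, scaled proportionally for
  smaller rasters.
* **Narrow band by construction.** The update is multiplied by δ(φ), whose
  support *is* the narrow band; the dense vectorized computation and a
  band-masked one are bit-identical, so no separate full-domain switch
  exists.
* **Sussman maintenance vs. distance-transform rebuild.** A mask-based EDT
  rebuild quantizes the zero level to pixel boundaries; applied frequently
  it erases sub-unit φ progress and freezes the front, applied rarely it
  lets the stale band strand the contour (updates are confined to |φ| < ε).
  One Sussman step per iteration keeps φ a near-SDF without either failure
  mode; the periodic exact rebuild (default every 25 iterations) bounds
  drift. The rebuild preserves inside/outside labels exactly, so it does not
  disturb the convergence statistic.

### Defaults

| parameter | default | units | note |
|---|---|---|---|
| ε (band half-width) | 1.5 | px | band ≈ one pixel layer each side after reinit |
| local_radius | 40 (full res) | px | scaled by image size; must exceed init offset |
| curvature_weight ν | 1.2 | — | relative to the saturated data force |
| κ_sat | 0.15 | px⁻¹ | curvature saturation scale |
| step_size | 0.45 | px | CFL cap on max |Δφ| per iteration |
| max_iters | 600 | — | cohort runs converge in 50–150 |
| reinit_every | 25 | — | exact EDT rebuild cadence |
| convergence_tol | 1e-4 | — | label-change fraction, 10-iteration window |

## Evaluation metrics

Dice = 2|A∩B|/(|A|+|B|) on full masks. The maximum Hausdorff distance is
computed between **boundary pixel sets** (mask pixels with an exterior
4-neighbour), with Euclidean distances on pixel-centre coordinates, and is
reported in **pixels** — the only length unit the rasters carry — so values
are resolution-dependent and comparable only at equal resolution. Dice and
HD are deliberately complementary: a contour that is right almost everywhere
but locally protrudes keeps a high Dice while HD exposes the defect. The
fast implementations (set operations; KD-tree nearest neighbours) are tested
for exact agreement with all-pairs brute-force oracles.

## The synthetic cohort

Real multispectral TM images are generally private; the phantom generator
replaces them with rasters that reproduce the features that matter to the
analysis, at the native camera resolution of 976 × 494 px:

* an elliptical TM (default centre (488, 250), semi-axes 300 × 185 px,
  rotation 0.15 rad) on a homogeneous canal-wall background;
* a malleus-handle strip (16 px wide) from the upper rim to the umbo
  (ellipse centre);
* a cone-of-light wedge (0.45 rad opening) in the anterior-inferior
  quadrant, brightened in every channel;
* random smooth vessels (8 curves, 3 px wide, cubic-spline paths radiating
  inward across the canal wall and over the TM), darkened per channel;
* per-channel photometry (means on [0, 1], i.i.d. Gaussian noise, clipped),
  fixed in `src/otomsi/data/default_phantom.yaml`:

| channel | TM | outside | malleus | vessel contrast | noise sd |
|---|---|---|---|---|---|
| white | 0.62 | 0.52 | 0.70 | 0.25 | 0.040 |
| red | 0.75 | 0.35 | 0.35 | 0.00 | 0.020 |
| green | 0.55 | 0.47 | 0.62 | 0.30 | 0.035 |
| blue | 0.22 | 0.18 | 0.26 | 0.10 | 0.100 |

These values operationalize the observed contrast structure of
multispectral otoscopy: vessels invisible and the malleus indistinguishable
from the canal wall under red light; a large red inside/outside separation
against small, histogram-overlapping separations in white and green; a
narrow homogeneous red canal-wall peak; and a dim, noisy blue channel. They
were fixed once from those qualitative observations, and the
contrast-structure test suite verifies the implied histogram ordering on
every seed it draws.

Cohorts jitter the ellipse geometry by ±5% per member with seeds derived
from a master seed (all derived seeds < 2³¹). Ground truth is the generating
geometry (ellipse ∪ malleus strip — the segmentation target includes the
malleus) and is invariant to all photometric parameters; the random stream
is consumed identically regardless of photometry, so a render and its
vessel-free twin differ only where vessels darken pixels.

**What the phantoms do not emulate:** specular glare, radial illumination
falloff, lens distortion, demosaicing artefacts, channel misregistration,
anatomical texture within the membrane, and pathology (effusion, retraction,
perforation). Passing the cohort benchmarks therefore shows that the
pipeline recovers boundaries under the stated contrast/noise structure — not
clinical performance on patient images.

## The cohort experiment

Each of the 12 phantoms is initialized with a single ellipse mask derived
from its ground-truth geometry, scaled by a covering factor (default 1.05)
with ±3% seeded jitter standing in for hand placement; the *same* mask and
the *same* parameters drive all four channels. Results are scored against
ground truth, aggregated per channel (mean and sd of Dice and max HD), and
ranked (ties break on channel name). A vanished contour yields a flagged
record — Dice 0, HD measured against the initialization boundary — rather
than aborting the cohort; no such failure occurs at the defaults. The entire
experiment is reproducible byte-for-byte from the master seed.

At the defaults the red channel converges to mean Dice ≈ 0.998–0.999 and
mean max HD ≈ 6–7 px over the cohort and ranks first on both metrics; white
and green lose accuracy to their overlapping intensity distributions and to
vessels crossing the rim, and blue to noise. The acceptance script
(`scripts/acceptance.py`) recomputes the red-channel means from scratch for
any seed.

## Degenerate inputs and edge cases

* Masks that are all-true or all-false are rejected wherever a two-phase
  field is required (SDF construction, evolution init).
* An empty side of a local-means window is flagged, never returned as NaN.
* Empty predictions produce flagged metric records (Dice 0, HD NaN).
* A line profile that misses the reference ellipse returns zero boundary
  marks with a warning flag instead of raising.
* Histogram overlap requires identical bin edges; region histograms require
  a non-empty region.

## Known limitations

* The boundary position at zero-contrast sections (malleus attachment in
  red) is set by initialization, curvature and stopping time, not by data;
  its ~3–8 px error dominates red-channel HD.
* HD is reported in pixels; no physical calibration is attempted.
* The contour is single-component in practice but topology is not enforced.
* Channels are assumed perfectly co-registered (true for phantoms; real
  endoscope sequences may need registration first).
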