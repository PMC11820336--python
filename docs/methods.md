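# Methods

`speclive` implements a snapshot spectral-imaging liveness-detection pipeline
end to end on a simulated sensor. This note records the models, the defaults
and why they hold, the numerical choices, and what the synthetic world does
and does not establish.

## Forward sensing model

A 16-channel multi-spectral filter array (MSFA) tiles the sensor in periodic
4×4 units; pixel (r, c) sees the scene through channel `layout[r mod 4, c mod
4]`. The DN value of channel i is

    I_i = Σ_λ f(λ) q(λ) t_i(λ) = Σ_λ f(λ) m_i(λ),   I = M f,

with f the incident spectrum on the working grid (400–750 nm, 2 nm, 176
points), q the quantum efficiency and t_i the filter transmission. The
synthetic filters are Gaussian lobes (centers spread over 410–740 nm, FWHM
≈ 40 nm, ±3 nm / ±10 % seeded jitter) on a broadband pedestal equal to the
`crosstalk` fraction (default 0.08) of the unit peak; micro-filter crosstalk
is precisely what makes the naive weighted-sum reconstruction blurry and the
regularized inversion necessary. Real micro-filter curves are sensor-specific and not tabulated here, so
these shapes are stand-ins with the same qualitative structure. DN noise is per-pixel independent multiplicative
Gaussian with CV 0.04 (the ~4 % end-to-end DN error of the real system);
quantization is 12-bit and can be disabled to isolate algebraic error.

## Tikhonov reconstruction

Recovering 176 spectral samples from 16 DN values is underdetermined, so the
pipeline solves

    min_f ||M f − I||² + α ||f||²,   f̂ = V diag(s/(s²+α)) Uᵀ I

through the thin SVD M = U S Vᵀ, computed once per sensor. Reconstruction of
n spectra is then a single (n×16)·(16×L) product — this is what makes
whole-face reconstruction (10⁵ pixels) cheap. α is fixed rather than tuned
per capture (GCV/L-curve buy little fidelity here): the default is
α = 10⁻² · s_max², calibrated once so that mean fidelity over 50 smooth
random spectra with 4 % DN noise exceeds 0.99 while noiseless round-trip
fidelity stays above 0.999. Negative excursions in f̂ are clipped only at
export/metric time; the solver output stays linear in I so superposition
remains testable.

Fidelity between spectra is the squared Bhattacharyya coefficient of their
sum-normalized (probability-form) values, F = (Σ√(p q))²: 1 iff the shapes
coincide, invariant to exposure, symmetric. RMSE is reported on spectra
normalized the same way on both sides.

## Demosaicing

Each channel is native on a stride-4 lattice. The intensity-guided scheme
(pseudo-panchromatic difference interpolation) does: (1) estimate a smooth
per-pixel intensity from the exact 4×4-period means, placed at period centers
and bilinearly interpolated — period means are residue-correct, i.e. every
estimate averages all 16 channels exactly once, which a plain box filter with
reflect padding gets wrong at image borders where DN varies by an order of
magnitude between channels; (2) per channel, bilinearly interpolate the
sparse (channel − intensity) differences from native sites (linear
extrapolation at borders) and add the intensity back. Native sites keep the
raw DN exactly. The reference baseline, period replication, broadcasts each
period's 16 raw values across the period; the ablation harness shows the
intensity-guided scheme strictly improves plane RMSE and downstream spectral
fidelity on spatially varying scenes, and coincides with the baseline on
uniform scenes. The scheme is deliberately simple and fully specified; it is
replaceable behind the `demosaic_msfa` contract.

## Region selection

The face box comes from a pluggable detector (the repo ships a ground-truth
detector for synthetic scenes; a production adapter can wrap any external
face detector). The top fifth of the box (the forehead strip,
`strip_fraction = 0.2`) provides the mean 16-channel reference vector; a
pixel is selected when the Euclidean distance of its 16-channel DN vector
from the reference is below `k·||ref||`. The relative form keeps the
threshold exposure-independent. k defaults to 0.25, calibrated once to sit
between the class distance scales: flat-skin pixels land at ≲0.1·||ref||
(4 % noise across 16 channels plus demosaic mixing), while eyebrow/mouth/
shadow pixels sit at ≳0.45·||ref||; tighter thresholds (e.g. 0.15) clip the
1–2-pixel demosaic-mixing ring around excluded regions and cost ~10 % of
flat-skin recall. By default vectors are *not*
L2-normalized before the distance, so shadows — pure intensity scalings —
are excluded along with eyebrows and mouth, matching how forehead-referenced
selection behaves on real faces (shadowed skin is excluded); `normalize=True` switches to
shape-only distance, which makes shadows selectable. Mask growth is monotone
in the threshold by construction.

## Dataset construction

Order of operations per sample: clip negatives → row-normalize (default
`max1`, preserving peak shape; normalization runs on the full band so the
crop cannot change the scaling) → crop to 450–700 nm (126 points, the band
holding the oxyhemoglobin features) → compress to exactly 2000 rows. The
compression randomly permutes the rows (seeded) and mean-filters contiguous
groups that are as equal as possible (the first n mod 2000 groups get one
extra row); 2000 rows per sample gives every sample equal weight during
training. Inputs with fewer than 2000 spectra are rejected rather than
up-sampled — real selected regions hold 5×10⁴–3×10⁵ pixels, so fewer than
2000 indicates a broken capture.

The split is two-level, reconciling the sample-level and spectrum-level
descriptions of the protocol: per group, half of the samples (floor, at least
one, never all) build the model; within each building sample the 2000 rows
split 2/3 train (floor: 1333) / 1/3 validation; the remaining samples are
held out entirely for system-level testing. All stages are seeded and
deterministic end to end.

## Classifier and training

Labels are fixed: 0 = "2D", 1 = "Real", 2 = "3D". The classifier is a small
1D CNN — Conv1d(1→16, k=7) + ReLU + maxpool2 → Conv1d(16→32, k=5) + ReLU +
maxpool2 → flatten → Linear(→64) + ReLU → Linear(64→3) — softmax at
prediction time, logits + cross-entropy during training. The reference
architecture fixes the module types but not the sizes, so the defaults are a
stand-in and `ClassifierSpec` makes every size configurable. The network is
implemented in numpy (no NN framework is available in the runtime); backprop
is verified against finite differences in the test suite.

Training follows the reference protocol: batch 2048 (clamped with a warning
when the dataset is smaller), 200 epochs by default, Adadelta, and a
learning-rate profile starting at 4×10⁻⁴ that halves every 25 epochs. A
checkpoint is saved at every new validation-loss minimum; once neither the
training-loss nor the validation-loss minimum has improved for 10 consecutive
epochs (and the epoch index exceeds 10), checkpointing freezes as a guard
against overfitting while training still runs to completion for the full
loss curves. The best checkpoint is restored at the end.

One scale choice needs flagging: Adadelta's accumulator-ratio update has a
natural unit step size (its original formulation has no global rate), and a
literal multiplier of 4×10⁻⁴ freezes the network — the cumulative parameter
motion over a desk-scale run is ~10⁻³ of a weight's initial magnitude, so no
protocol of this length could converge. The nominal rate is therefore kept
as the schedule's bookkeeping value and the optimizer consumes the *relative*
profile lr(epoch)/lr(0) ∈ {1, ½, ¼, …} by default (`lr_absolute=True`
restores the literal reading). The desk-scale benchmark trains at 60 epochs
(reduced from 200) to stay within CPU budgets; the network runs in float32,
which halves single-core time without affecting the verified gradients.

Per-sample prediction tallies the per-row argmax over the 2000 compressed
spectra; the sample label is the majority class (ties break to the lowest
class index) and the tally proportions are the reported class probabilities.

## Synthetic world

The scene generator stands in for captured faces. Live skin reflectance is a
monotone melanin-like baseline with two Gaussian oxyhemoglobin dips at 542 nm
(σ ≈ 10 nm) and 577 nm (σ ≈ 9 nm), with dip depth a fraction of the local
baseline (defaults 0.20 / 0.16, per-sample draws 0.15–0.28 / 0.12–0.24);
2D print/photo spoofs have a dye-like sigmoidal edge (random position
560–620 nm) and no dips; 3D silicone/resin spoofs are smooth and nearly
featureless. Every material carries a seeded smooth random perturbation
(correlation ≈ 60 nm, amplitude 2–5 %). A face scene contains a flat
forehead strip and cheeks of the face material, eyebrow/mouth stripes of a
dark non-skin material, a shadow strip (illumination × 0.55, spectral shape
preserved), and a distinct background; region labels are exact by
construction. Benchmark scenes are 320×320 (the real sensor is 1920×1080):
this scale puts ~5×10⁴ selected pixels in each face region — the real
system's lower bound — so the 2000-row compression mean-filters ~24 spectra
per row, inside the 20–200× ratio the full-size system operates at. The
ratio matters: compression is the pipeline's noise-reduction step, and at
toy scales (a few thousand selected pixels, groups of ~2) residual row noise
overlaps the closest skin/spoof pairs and caps per-spectrum accuracy near
97 % for any classifier; at the system's own ratio the classes separate
cleanly.

What a green benchmark establishes: the pipeline's stages compose correctly,
the reconstruction preserves the class-discriminating band, and the
classifier separates the three stated material families at the stated noise
level. What it does not establish: performance on real skin (no
radiative-transfer skin model, no pose/illumination geometry, no detector
errors — the ground-truth face box replaces a real detector), nor any
real-hardware accuracy figure, which depends on the actual camera and
volunteer population.

## Numerical and degenerate-input choices

- Grids must divide exactly; no implicit resampling anywhere. Off-grid crop
  bounds are rejected rather than resampled.
- `make_operator` rejects α = 0 for rank-deficient M, naming the offending
  singular value.
- All-zero spectra cannot be normalized (rejected); fidelity clips negative
  reconstruction values to zero before forming probabilities.
- Mosaic dims must be multiples of 4 (full periods). Saturation above 1 % of
  pixels warns with the fraction.
- Compression requires n ≥ target; `n == target` degenerates to a
  permutation.
- Prediction-map cells straddling the edge use their partial extent; an
  empty mask yields an all-unselected map with a `None` majority.

## Known limitations

- The filter responses, CNN layer sizes, and demosaicing operator are
  documented stand-ins for hardware-specific details that vary between
  sensors and are not modelled numerically here.
- The 2D/3D spoof families are low-dimensional parametric models; real spoof
  materials are more varied, and the benchmark's held-out accuracy reflects
  coverage of these parametric families only.
- Single-threaded numpy training is the throughput bottleneck; sub-second detection
  timing is a property of hardware/compiled pipelines and is out of scope.
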