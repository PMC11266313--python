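# Methods

This note documents the models, conventions, parameter choices and known
limitations behind `semgshift`, in the spirit of a methods appendix.

## Grid conventions

Channels are indexed 0-based in row-major order against the physical grid
(row 0 at the top). Acquisition hardware does not necessarily number
channels this way; the mapping between device channel order and the grid is
a **package convention**, configurable through `ElectrodeGrid.channel_order`
so adapters for real recordings can remap. The able-bodied grid is taken to
be 8 rows × 24 columns (192 electrodes at 10 mm pitch): that is the unique
rectangle consistent with 192 electrodes and the half-grid shapes 8 × 12
and 4 × 24 that the parity splits must produce. The amputee grid is 6 × 24.

Shift splits assign even parity on the split axis to the training side for
`inwards`/`upwards` and odd parity for their complements. Which physical
parity class is "black dots" versus "white dots" on a real montage is a
convention; flipping it exchanges the roles of the paired directions and
nothing else.

## Synthetic HD-sEMG model

The generator produces the *statistical structure the pipeline consumes* —
a gesture-specific, spatially smooth, reproducible RMS topography with
trial-to-trial variability — and nothing more. Per channel `c` and trial:

```
x_c(t) = A * [ sqrt(snr/(1+snr)) * g_c * e_c(t)  +  sqrt(1/(1+snr)) * b_c(t) ]
```

- `g_c`: gesture activation gain, a mixture of 2–3 Gaussian bumps (width
  `spatial_scale_mm`, default 25 mm = 2.5 pitches) at gesture-specific
  locations, peak-normalized to 1. Per repetition the bump centers shift by
  a uniform sub-pitch offset and the whole field scales by a lognormal
  jitter (σ = 0.15), so cross-validation folds are not trivially identical.
- `e_c(t)`: unit-RMS band-limited (20–500 Hz) Gaussian carrier, independent
  per channel — the standard amplitude-modulation surrogate for
  interference-pattern EMG.
- `b_c(t)`: unit-RMS background noise, band-limited and then smoothed
  across the grid so neighboring electrodes see correlated interference.
  Each channel is re-normalized to unit long-run RMS, so the background
  carries **no stable spatial pattern**: at `snr = 0` the recordings are
  label-independent by construction and any classifier must score 1/9.
- `A = active_rms_mv` (default 0.3 mV) sets the overall scale; samples are
  hard-clipped to ±2.5 mV, the assumed acquisition dynamic range. The
  0.3 mV level is a free choice — no amplitude statistics of real
  recordings are modeled — picked as a typical forearm surface-EMG RMS
  comfortably inside the dynamic range.
- `snr` (default 16) is the gesture-field-to-background power ratio. The
  default makes classes cleanly separable, which is the regime the
  recovery tests require; lowering it degrades accuracy smoothly to chance.

Trials are 5,400 samples (the 4,500-sample task window plus a 10% margin on
each side); the tracked center is placed mid-recording with a small seeded
jitter. Every artifact is a pure function of `(profile, seed)`: per-trial
substreams are derived from `(seed, gesture, repetition)` via
`np.random.SeedSequence`, so generation order never matters.

**What the generator does not emulate:** motor-unit physiology, force
dynamics, electrode-skin impedance drift, inter-subject anatomy, or any
amplitude statistics of real recordings. Passing tests therefore show that
the *pipeline* behaves correctly on data with the assumed spatial-smoothness
structure — they do not certify accuracy numbers on clinical data.

## Featurization choices

- RMS frames are contiguous and non-overlapping ("evenly divided"); windows
  that do not divide evenly are rejected rather than padded.
- The mV→gray map clamps out-of-range values to the (0, 255) endpoints
  rather than erroring: ±2.5 mV is treated as the full scale of the
  acquisition.
- Max-min normalization uses the **per-image** minimum and maximum (the
  formula carries no dataset index, and per-image normalization is what
  reduces within-sample variance shift). A constant frame maps to the
  all-zero image, so division by zero is impossible on near-silent frames.
- All feature math runs in float64; images are handed to the network as
  floating point in [0, 1]. Whether an 8-bit quantization round-trip should
  be inserted is an open question for real-data fidelity; the grayscale
  step is treated here as a normalization device, not a storage format.

## Damage model

Damaged channels have their raw signal replaced — before any featurization
— by 50 Hz narrowband Gaussian noise: white Gaussian noise through a
resonant peak filter at 50 Hz (Q = 10), applied forward-backward. This is
the standard powerline-interference model: a 50 Hz carrier with
Rayleigh-distributed envelope and slowly wandering phase, spectrum peaked
exactly on the carrier. (A sinusoid with *real-valued* Gaussian amplitude
modulation was considered and rejected: its envelope statistics are
folded-normal with heavy estimator tails and its modulation flattens the
spectral peak.) A flat-top band-passed variant is available via
`DamageConfig(mode="bandpass")`.

The noise RMS defaults to the median per-channel RMS of the recording being
damaged — loud enough that damage is never invisible, bounded so it never
saturates the dynamic range. Whether real damaged electrodes should be
amplitude-matched this way is unknown; the level is configurable. The same
channel list (in full-grid coordinates) applies to both sides of a shift
split and to every trial of a condition.

## Network and training

Architecture: conv 3×3 (1→32) + ReLU, conv 3×3 (32→64) + ReLU, conv 3×3
(64→128), plus a 1×1 projection (32→128) of the first activation added
residually, then ReLU; SE attention (bottleneck 128→32→128, sigmoid gate);
flatten; dense 512 → 256 → 64 with ReLU and dropout 0.3 after the first two
dense activations; linear to 9 classes; LogSoftmax. Design points that were
genuinely open and the choices made:

- The residual connection bridges the two expansion convs (layers 2–3)
  through a 1×1 projection (widths differ, so an identity skip is
  impossible). Whether it should span one or two conv blocks is not
  determined by the architecture description; bridging the expansion is the
  reading that makes the skip nontrivial.
- SE reduction ratio r = 4 (128 → 32), standard SE practice scaled to a
  small channel count. Dropout 0.3, the closest in-family precedent.
  Dropout is applied after the ReLU activation.
- No pooling: the spatial maps are at most 8 × 24, so same-padding convs
  preserve shape and the flatten feeds the 512-unit layer directly.
- Weight init: He-normal (fan-in) for ReLU layers, variance-1/fan-in for
  the SE gate output and the classification head, drawn in a fixed order
  from a seeded generator — two builds from the same config are
  bit-identical. The gate-free variant (`se_enabled=False`) draws the SE
  weights anyway, so it shares every other parameter bit-for-bit with the
  gated build; forcing the gate to 1 reproduces it exactly.
- Loss is NLL against the LogSoftmax outputs (the pairing the head forces);
  optimizer Adam at lr 0.001, batch 128, no early stopping.
- The implementation is pure NumPy (im2col convolutions, fused in-place
  Adam), float32 by default with a float64 switch used by the
  finite-difference gradient tests.

## Evaluation protocol

K = 4 stratified cross-validation over FSIs. The default split is at the
**frame level** — 4,320 FSIs into 3,240/1,080, reproducing the protocol's
arithmetic — which lets frames of one trial land on both sides of a fold
and therefore inflates absolute accuracy on both real and synthetic data.
`TrainConfig(group_by_trial=True)` provides the leakage-free variant that
keeps whole trials together; it is the right choice for scientific claims,
while the default preserves protocol fidelity.

Per-condition accuracy is reported as mean ± sample standard deviation
(n−1 denominator) over folds × subjects; confusion matrices are pooled over
folds and normalized per true class.

The Wilcoxon signed-rank test is two-sided, drops zero differences, and
uses midranks for ties. The p-value is exact for up to 25 nonzero pairs,
computed by subset-sum counting over doubled midranks — identical to brute
force enumeration of all 2^n sign assignments — and a normal approximation
with continuity and tie corrections beyond that. (The approximation's
continuity-correction convention differs from SciPy's by < 0.01 in p; the
exact regime matches SciPy exactly on tie-free data.)

## Problem sizes used in the automated checks

The test-suite and acceptance-script experiments run at the following
scales, chosen so each check exercises the property it targets:

- Bookkeeping checks (FSI counts, fold sizes, split geometry) run at the
  protocol's native scale: 9 gestures × 16 repetitions, 8 × 24 grid.
- The baseline-recovery check trains fold 0 of the default subject for 30
  epochs (batch 128, lr 0.001) and requires accuracy > 0.90.
- The zero-SNR control trains for 3 epochs: on label-independent inputs
  accuracy sits at chance regardless of epoch count, so more epochs add
  information about nothing.
- The degradation ordering (baseline ≥ shift ≥ shift+damage, averaged over
  5 seeds) runs at 3 repetitions × 8 epochs per condition, fold 0; the
  paired-sample bookkeeping (112 = 7 × 4 × 4) runs with 2 repetitions and
  untrained folds, since it checks record-keeping, not learning.

## Known limitations

- The synthetic generator's separability is tunable and its default is
  optimistic; absolute accuracies on synthetic data say nothing about
  clinical recordings (see the leakage note above as well).
- Only rectangular grids and one-pitch shifts are modeled; no sub-pitch
  interpolation, rotation, or intermittent (time-varying) faults.
- The comparison models from the surrounding literature (LSDA, plain CNN,
  TCN, LSTM, attention-BiLSTM, Transformer, Swin-Transformer) are out of
  scope; the harness interface (`train_fold` on image stacks) is what an
  adapter for them would implement.
- Training is single-threaded CPU NumPy; it is fast enough for the tiny
  FSI inputs but not a general-purpose deep-learning stack.
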