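# Methods

## Problem and pipeline

`uwbfall` classifies human activity — five daily actions and five fall
variants — from impulse ultra-wideband (UWB) radar recordings.  A
recording is a pulse matrix: fast-time samples (range) × slow-time
pulses.  The pipeline is

1. **MTI clutter suppression.**  The three-pulse canceller
   `y(n) = x(n+1) − 2x(n) + x(n−1)` is applied along slow time per
   range bin.  It is the discrete second difference, so any return that
   is constant or drifts linearly across pulses is annihilated exactly;
   its magnitude response is `4 sin²(πf/prf)`.
2. **Three maps.**  (a) *Range–time*: the analytic-signal envelope
   (Hilbert transform along slow time, per range bin).  (b)
   *Time–Doppler*: the analytic signal is summed coherently across
   range bins and a magnitude STFT (window 128, overlap 110, Hann) is
   taken along slow time.  (c) *Range–Doppler*: magnitude FFT along
   slow time per range bin.
3. **Imaging.**  Each map is log-compressed (dB relative to its
   maximum, floored at −60 dB), min–max normalized to [0, 1] and
   resampled to 80 × 80.
4. **Classification.**  One SE-RCNet per map kind.
5. **Fusion.**  The three per-sample decisions are combined by majority
   vote with a confidence fallback (*decision fusion*) or by
   accuracy-weighted confidences (*adaptive weighted fusion*).

## Radar model and synthetic data

Default radar parameters: PRF 240 Hz, carrier 4.3 GHz, bandwidth
1.7 GHz (range resolution c/2B ≈ 8.8 cm), 5 s recordings (1200 pulses),
256 range bins over 5 m.  The unambiguous Doppler span is ±120 Hz,
i.e. radial speeds up to ≈ 4.2 m/s.

The simulator renders a **single point scatterer** on a radial
trajectory R(t): each pulse carries a Gaussian range envelope of width
c/2B centered at R(t), modulated by the carrier phase
`cos(4π·fc·R(t)/c)`, plus a time-constant clutter column (default
amplitude 2.0, i.e. clutter ~6 dB above the unit-amplitude target) and
i.i.d. Gaussian noise (default σ = 0.15).  After Hilbert conversion and
slow-time spectral analysis the scatterer produces a Doppler line at
`2|v|fc/c` — for v = 1 m/s, ≈ 28.7 Hz.  Because a single real receive
channel is modeled, the *sign* of the velocity is not present in the
Doppler maps; approach/recede is distinguished by the range–time
trajectory instead.

Trajectories are class-conditional seeded families built from
raised-cosine velocity bumps (posture transitions, falls) or sustained
constant-velocity segments (walking).  Falls are short bursts with peak
radial speed in 1.5–3 m/s followed by stillness and a reflectivity drop
(body prone); posture transitions stay below 0.8 m/s; walking runs at
0.75–0.95 m/s across the 1–4.5 m gate.  Each of the five fall variants
occupies a distinct peak-speed sub-band and direction, standing in for
the distinct micro-Doppler signatures of real fall directions: a
radial-only point-scatterer model cannot otherwise distinguish, e.g., a
left- from a right-oblique fall.  Consequences for interpretation:
passing recovery tests show the pipeline separates classes whose maps
differ in Doppler extent, timing and range excursion; they do not show
robustness to multi-limb micro-Doppler texture, multipath, or
sensor-specific artifacts of real recordings.

Numerical details: trajectories integrate a velocity law by trapezoid
rule on a 4096-point grid and interpolate; the event onset is drawn
uniformly in the middle of the recording (scaled with duration so short
test clips remain valid); all randomness flows through
`numpy.random.SeedSequence`, so every artifact is bit-reproducible from
one integer seed.

## Preprocessing choices

* **Hilbert axis.**  Applied along slow time, per range bin: Doppler
  lives on the slow-time axis and this makes the single-sided Doppler
  line recoverable by the downstream FFT/STFT.
* **STFT input.**  The analytic signal is summed across range bins
  before the STFT (standard micro-Doppler practice), yielding one
  time–frequency map per recording.  Framing is "valid": frame count
  `⌊(N − 128)/18⌋ + 1`.
* **Resampling.**  Bilinear with Gaussian anti-aliasing when
  downsampling.  The raw maps have up to ~1200 columns; narrow Doppler
  ridges and envelope tracks would alias away under point
  interpolation, and the anti-aliasing filter instead averages them
  into the 80 × 80 grid.
* **dB floor −60 dB.**  Keeps the image dynamic range stable across
  noise levels; images are invariant to any positive rescaling of the
  map.
* The MTI stage shortens slow time by two pulses; all map time axes
  refer to the filtered grid.

## SE-RCNet

Input 80 × 80 × 1.  Initial 3×3 conv + ReLU, then six blocks, flatten,
dense softmax head.  Each block: conv→BN→ReLU twice, element-wise sum
of the two stage outputs (residual learning), squeeze-and-excite
recalibration of the sum (global average pool → C/r bottleneck → ReLU →
sigmoid gates, r = 4), merge with the block input, 2×2 max-pool.  The
merge is **channel concatenation** by default ("dense" connection;
additive merge is a config switch and requires equal channel counts).
Spatial sizes follow floor-halving: 80→40→20→10→5→2→1.

Reference configuration: channels (16, 32, 48, 64, 80, 96), Adam
lr = 1e-3, batch 32, 100 epochs.  The implementation is pure NumPy
(im2col convolutions over BLAS, manual backprop) and single-threaded
deterministic: initialization and shuffling derive from one seed, and
training twice with the same seed reproduces the history bit-for-bit.
Training keeps the weights of the best validation-accuracy epoch.  With
learning rate 0 the model is left untouched (no parameter or
batch-norm-statistic updates), so a zero step size is exactly a no-op.

CPU-scale experiments (tests, acceptance script) use a reduced width
(6, 8, 10, 12, 14, 16) and 16 epochs on 500 samples (per_class = 50,
6:2:2 split) — sizes chosen so a full three-map experiment runs in a
few minutes on one core while the time–Doppler classifier still reaches
well above 5× chance.

## Fusion

For each test sample each map yields logits z, softmax probabilities s
(computed shift-invariantly), confidence smax = max(s) and prediction
imax = argmax(s).

* **Decision fusion:** majority over {imax₁, imax₂, imax₃}; if all
  differ, the highest-smax map wins.
* **Adaptive weighted fusion:** m = (smax₁, smax₂, smax₃)/Σ smax
  (per-sample sum normalization — the reading that makes m a
  probability vector over the three maps), w = n ∘ m with n the per-map
  *overall* validation accuracies (scalar per map; a per-class variant
  would make w a 3×K matrix and is not the default), per-class score
  w′(c) = Σ{wᵢ : imaxᵢ = c}, fused class = argmax w′.

All ties (argmax of s, of smax, of w′) break to the lowest index.  When
all three maps agree, both rules provably return that class for any
valid n.

## Evaluation protocol

Stratified 6:2:2 train/validation/test split and stratified 5-fold CV
(scikit-learn under the hood).  Metrics: accuracy = trace/total and
one-vs-rest precision/recall/F1 per class, macro-averaged for headline
numbers (micro by flag); never-predicted classes get precision 0.
Improvement of fused over the best single map is reported **both** as
absolute percentage points and as relative percent, since the two
conventions differ and reported fusion gains in the literature are
sometimes one, sometimes the other.

The experiment driver's degraded-map option adds seeded Gaussian pixel
noise (default σ = 0.35, clipped to [0, 1]) to one map kind before
training and testing, creating the asymmetric-quality regime where
adaptive weighting should beat uniform-weight decision fusion.  The
fusion comparison aggregates macro F1 over 10 replicate evaluation sets
(fresh simulation seeds, same degradation, frozen classifiers) — the
replicates vary the data, not the training, which keeps the comparison
affordable on one CPU.

## Known limitations

* Single scatterer: no limbs, no multipath, no multiple people.
* Real-valued single channel: Doppler sign is unobservable; left/right
  fall obliqueness is emulated by speed sub-bands, not geometry.
* The NumPy trainer is small-scale by design; it is not a general deep
  learning framework (no GPU, no data augmentation, fixed 3×3/2×2
  geometry).
* Max-pool gradient routes ties to the first maximum; batch-norm uses
  running statistics at evaluation with momentum 0.1.
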