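# Methods

## Signal model and synthetic generator

A record is 20 minutes of fetal heart rate at 2 Hz: 2400 integer bpm
values, with 0 coding Doppler signal loss. The generator builds the clean
portion as

    v(t) = baseline + variability(t) + Σ events(t)

* **baseline** — class 0 uses the configured value (default 140 bpm);
  class 1 redraws it per record outside the normal 110–160 band,
  tachycardic U(162, 178) or bradycardic U(92, 108) with equal
  probability. This generative definition of "abnormal" (baseline out of
  band, variability < 5 bpm, elevated decelerations) follows standard CTG
  interpretation; it is a modeling choice of this package.
* **variability(t)** — Gaussian noise smoothed at two scales (σ = 4
  samples for short-term variation, σ = 120 for slow wander), scaled so
  the short-term band is roughly the configured peak-to-peak value
  (default 12 bpm for class 0; class 1 caps it below 5 bpm). The slow
  component doubles as per-record baseline wander, which is why class-0
  records differ without explicit baseline jitter.
* **events** — Poisson-count accelerations/decelerations (defaults 2.0 and
  0.4 per record for class 0; class 1 elevates decelerations to ≥ 3 and
  halves accelerations), each a raised-cosine-plateau (Tukey) bump of
  ~45 s × U(0.8, 1.5) and amplitude 22 bpm × U(0.85, 1.25).

Spike artifacts displace isolated samples by > 25 bpm (magnitude
U(26, 60), direction random, result kept inside (0, 300)); the 25 bpm
floor guarantees the stabilization stage's jump rule sees them. Dropouts
draw a category from the mixture {none: 0.33, ~100: 0.511, 200–500: 0.147,
~1000: 0.012}; the total zeroed count comes from the category's range
([50,150], [200,500], [800,1200] points) and is split over 1–3
non-overlapping uniformly placed runs. Everything is a pure function of
(seed, record index) via `SeedSequence([seed, index])`.

What the generator does **not** emulate: true cardiovascular dynamics
(no ODEs), uterine contractions, sinusoidal patterns, gradual sensor
drift, or label noise — real labels come from expert consensus and are far
noisier than this generative rule. Passing tests therefore demonstrate
pipeline correctness and learnability of the encoded class structure, not
clinical performance.

## Feature table

Each clean trace is summarized into nine numeric fields plus a class code
(stored as {1, 2} on disk, mapped to labels {0, 1} in memory). Baseline is
the 10%-trimmed mean; accelerations are excursions ≥ +15 bpm above
baseline sustained ≥ 15 s, decelerations the mirror image (the
conventional 15 bpm / 15 s criteria). Two columns have no standard
definition, so this package fixes its own: **Frequency** is the total
accel + decel event count, and **Period** the mean onset-to-onset spacing
in minutes (0 with fewer than two events). Event durations are reported in
seconds, amplitudes as peak excursion above/below baseline in bpm.

## Preprocessing

Stages run in a fixed order; each preserves length and none introduces
zeros downstream of repair.

1. **QC accounting** — zeros and the longest zero run are counted and
   converted to seconds. A record is rejected when total missing exceeds
   10 s, or (checked second) when one gap exceeds 30 s. Comparisons are
   strict, so exactly 10 s / 30 s is retained. Note that under these
   thresholds every nonzero dropout category of the default mixture is
   rejected; only complete records (~33%) survive, and end-to-end runs
   train on that surviving subset.
2. **Linear interpolation** — interior zero runs become the line between
   the nearest nonzero neighbors; leading/trailing runs are filled by
   constant extension (two-sided interpolation is impossible there).
3. **Spike stabilization** — scanning left to right, a successive
   difference > 25 bpm opens an unstable segment; it closes at the first
   index whose next five successive differences are each < 10 bpm ("the
   stable point"), and the interior is replaced by a straight line. With
   no stable point before the end, the last stable value is extended.
   Passes repeat until one makes no change. A jump that lands directly on
   a stable point has no interior to re-interpolate and is kept as a
   genuine level shift — the only reading that terminates on all inputs —
   so the "no residual jump > 25 bpm" property holds for isolated spike
   artifacts, not for irreducible steps.
4. **Savitzky–Golay smoothing** — window 15 samples (7.5 s), order 3,
   boundary handled by polynomial fit on the truncated window. The window
   was chosen to remove single-sample jitter while leaving ≥ 15 s
   accelerations intact (a cubic fit over 7.5 s reproduces them almost
   exactly); both parameters are configurable. Smoothing runs last and is
   asserted never to create jumps beyond what stabilization left.

## Rasterization

Clipping maps bpm below 80 to 80 and above 200 to 200. The raster has 120
rows × 2400 columns; row r = round-half-up((200 − v) · 119/120), so
200 bpm → row 0 and 80 bpm → row 119 (conventional chart orientation,
higher rate at the top). 120 rows span 121 integer bpm values, hence the
119/120 scale rather than dropping a value. Consecutive samples are
connected by filling, in column t+1, the rows from r(t+1) toward r(t)
*excluding* r(t): each column's pixel interval then ends at its own
sample's row, which makes the trace recoverable from the image to within
half a row (±0.504 bpm) by taking, per column, the interval endpoint
farther from the previous column's recovered row. Images are binary; the
PNG writer emits 8-bit grayscale (0 background, 255 curve).

Augmentation is horizontal translation only, by an integer offset drawn
uniformly in ±20% of the width, with vacated columns replicating the
nearest surviving column (keeps every column covered). Vertical shifts and
flips are excluded because they change the clinical meaning of the curve.

## Architectures and training

MKNet convolution blocks stack four 3×3 stride-1 same-padded ReLU
convolutions — jointly a 9×9 receptive field, the cheap substitute for a
single 9×9 kernel — plus one 2×2 max pool; blocks carry 8, 16, 32 filters.
MKNet-A is block1 + fc1 + softmax; B and C append further blocks before
the dense head. Counting conv, pool, dense and softmax layers (dropout and
flatten excluded) gives 7 / 12 / 17. Optional extras, off by default:
one 1×1 convolution per block, fc2/fc3, and per-block dropout
(rate 0.25). Dense widths (64/32/16) are this package's defaults. Default
conv stride is (1,1) — stride (4,4) remains available per layer but would
break the receptive-field substitution. A `warm_start` option copies
matching-shape parameters from a shallower trained model (stage-wise
initialization); no fidelity claim is attached to it.

MKRNN is a single LSTM (default 64 units, dropout and recurrent dropout
0.25) over the cleaned trace shaped (time steps, 1), followed by a small
dense layer and softmax. Sequence inputs are clipped and scaled to [0, 1]
by (v − 80)/120.

Training minimizes softmax cross-entropy with RMSprop (default,
lr 1e-3) or Adagrad in the package's numpy engine (im2col convolutions,
argmax-routed pooling gradients, full-sequence BPTT); epochs default to
70 and batch size to 32 at full scale. All initialization and shuffling
derive from the config seed, so runs are bit-reproducible on a fixed
backend.

## Evaluation protocol

60/20/20 train/test/validation splits use per-class largest-remainder
rounding, so n = 1000 gives exactly (600, 200, 200). Neural models are
evaluated on the holdout test split (the validation split drives the
learning curves); feature baselines use stratified 5-fold CV on the full
corpus. "Avg/total" rows are support-weighted averages; a class with zero
support gets NaN per-class metrics and zero weight. ROC curves come from
the standard threshold sweep with tied scores grouped; the mean ROC
vertically averages member curves on a fixed 101-point FPR grid with
endpoints pinned at (0,0)/(1,1), and the mean AUC is the arithmetic mean
of member AUCs. The SVM baseline re-runs the hyperparameter grid search
on each training fold and fits the winner; the printed default
{rbf, C=1000, γ=1e-4} is what `fit_svm` uses when called directly.

## Scaled experiment sizes

The end-to-end reference run uses 400 generated records (≈134 surviving
QC), full 120×2400 rasters block-max-pooled to 30×300 for training,
MKNet-A with filters (4,) and fc1 = 32, 8 epochs, batch 32 — sizes chosen
so the whole experiment runs in well under a minute per stage on a single
CPU while leaving the class structure fully learnable. The LSTM path
decimates sequences 30-fold (80 time steps) for the same reason. Full-scale
geometry is the same code path with the default numbers.

## Known limitations

* The QC thresholds and the dropout mixture are mutually harsh: defaults
  discard about two-thirds of generated records (see Preprocessing).
* The numpy engine targets small experiments; it has no GPU path and its
  LSTM is O(T) Python-stepped.
* Spike stabilization's level-shift exception means pathological
  square-wave inputs can retain > 25 bpm steps (documented above).
* Feature-table baselines inherit the nine-field summary's information
  loss; their accuracy ceiling on synthetic data (~mid-90s%) reflects
  that compression, not an implementation limit.
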