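# Methods

`semgdec` decodes finger kinematics from multichannel surface
electromyography (sEMG). One recording session pairs a 16-channel sEMG
stream from a 4x4 dry-electrode grid on the extensor digitorum (4000
samples/s, microvolts) with a 16-joint hand-kinematics track from an
optical motion sensor (up to 120 frames/s, degrees) and an annotation of
timed gesture events. The decoding model is a factorized spatio-temporal
transformer that regresses short signal windows onto the 16 joint angles;
a downstream extra-trees classifier turns those angle vectors into
discrete gesture decisions. Because no public dataset accompanies this
acquisition setup, the package includes a synthetic-session simulator
that reproduces the protocol and the statistical structure the decoder
relies on, so the entire stack is testable offline.

## The acquisition protocol and its simulation

A session consists of 14 gestures x 7 repetitions = 98 events in
randomized order, each a 5 s hold followed by a 3 s pause (an 8 s ideal
cycle), performed under one of four hand-position settings (three static
arm postures and one dynamic free-movement condition). The simulator
(`semgdec.synthetic`) generates:

- **Protocol** (`make_protocol`): the randomized 98-event schedule with a
  leading pause. Optional Gaussian cue jitter (clipped to 45% of the
  pause) models subjects anticipating the auditory cue; with zero jitter
  the inter-onset intervals are exactly the ideal cycle.
- **Kinematics** (`synth_kinematics`): piecewise-linear joint
  trajectories — rest pose during pauses, 0.5 s transition ramps, a
  plateau at the gesture's template angles during holds — plus i.i.d.
  Gaussian motion-estimator noise (default SD 2 deg, the scale of optical
  hand-tracking jitter). The rest pose is every joint at the midpoint of
  its nominal range of motion.
- **sEMG** (`synth_semg`): per channel, an activation envelope multiplies
  a band-limited carrier. The carrier is Gaussian white noise band-passed
  to 20-450 Hz and normalized to unit RMS — the standard surrogate for
  interference-pattern sEMG. The envelope follows the active gesture's
  per-electrode gain, scaled per repetition by a lognormal force factor
  (unit mean, CV 0.2; subjects are not instructed to hold a constant
  force, so amplitude varies between repetitions of the same gesture) and
  lagging the kinematic onset by 100 ms (electromechanical-style delay;
  sEMG onset follows the motion-sensor trace). Added on top: power-line
  sinusoids at 50 and 100 Hz (10 and 5 uV, common phase across channels),
  white instrumentation noise (3 uV), nearest-neighbour grid crosstalk
  (10%), and rare brief spikes appearing simultaneously on all electrodes
  (0.5/min, 200 uV, 5 ms) standing in for mechanical artifacts.

**Gesture templates.** Each of the 14 default gestures has a 16-joint
plateau pose derived from its digit flexion pattern (flexed digits at 90%
of the joint range, extended at 10%) and a 16-electrode activation
pattern. Activation patterns are binary recruitment codes taken from the
rows of a 16x16 Hadamard matrix (strongly recruited electrodes at 50 uV,
weakly recruited at 10 uV): any two gestures differ on exactly 8 of 16
electrodes. This realizes the *well-separated templates* regime that the
recovery experiments assume; `default_templates(separation=s)` pulls all
templates toward their common mean for `s < 1`, making the discrimination
problem arbitrarily harder. The defaults are simulator parameters, not
claims about real muscle anatomy.

**What the simulator does not emulate**: motor-unit physiology, volume
conduction, electrode-skin impedance drift, realistic crosstalk anatomy,
posture-dependent signal changes between the four settings, and
between-subject variability in electrode placement. Passing the recovery
tests therefore shows that the pipeline is correct and the estimator
consistent under its own assumptions — not that comparable accuracy would
be reached on real recordings.

## Preprocessing

- **sEMG** (`filter_semg`): IIR notches at the power-line frequencies (50
  and 100 Hz, Q = 30), then a 4th-order Butterworth high-pass at 20 Hz,
  then per-channel z-scoring over the full recording. Filters run
  forward-backward (zero-phase) by default — offline analysis can afford
  the non-causality, and it leaves envelope timing undistorted; the
  magnitude response is squared as a result, which all design checks
  account for. By default only the listed base frequencies are notched so
  that genuine sEMG content between harmonics (e.g. 150 Hz) passes
  untouched; `comb_n_harmonics` extends each base to a full comb when a
  recording needs it. A constant channel z-scores to zeros with a warning
  rather than dividing by zero.
- **Kinematics** (`smooth_kinematics`): an order-1 Savitzky-Golay filter
  — i.e. a weighted moving average — with a 502-sample window. The window
  counts samples on a reference clock (default the 4000 Hz sEMG clock,
  making it a 125.5 ms average) and is duration-converted for tracks at
  other rates: interpreted literally at the 120 Hz motion-sensor rate,
  502 samples would be a 4.2 s average that flattens entire 5 s holds.
  Tracks are then linearly interpolated onto the sEMG clock
  (`resample_kinematics`), endpoints held.
- **Outlier rejection** (`reject_outlier_samples`): within each annotated
  gesture-hold interval, the per-joint median is computed and a sample is
  kept iff no joint deviates from its median by 15 deg or more. This
  removes execution mistakes and corrections — and, as a side effect, the
  transition ramps at the edges of each hold, which is precisely the
  "exclude transient actions" behaviour wanted for training. The rule's
  keep-mask later removes every analysis window that overlaps a rejected
  sample.

## Windowing

A rolling window of 512 ms with a 2 ms stride cuts the recording into
`L = floor((N - S)/t) + 1` windows of `S` samples (window `k` starts at
sample `k*t`; trailing partial windows are discarded). Each window's 16
channels are placed on the 4x4 grid according to the session's layout
map, producing the video-shaped tensor `[L x S x 4 x 4]`. Windows are
extremely redundant at the 2 ms stride, so `WindowTensor` stores one
reference to the channel-reordered signal plus start indices and
materializes batches on demand.

Per-window regression targets are the joint angles at the window's end
(causal: predict the current pose from the immediately preceding signal);
window-centre and window-mean reductions are available for ablation. The
window's label is the annotated gesture covering the target time, else
`rest`; rest/transition windows default to being kept (they teach the
rest pose) and are routed to the training split only.

**Augmentation** (training only): independently per channel, with
probability 0.5, one span of duration ~ Uniform[6, 400] ms is zeroed at a
uniformly random feasible onset (drawn so the span fits inside the
window; spans longer than the window are truncated with a warning), then
Gaussian noise of SD 0.1 is added to the z-scored signal. An optional
amplitude-scale jitter (`scale_jitter_sd`, off by default) multiplies
each window by a unit-mean lognormal factor — the standard EMG
augmentation against force-level dependence, mirroring the simulator's
per-repetition force variability.

## The decoder

Each `(S, 4, 4)` window is split into non-overlapping temporal patches;
every (patch, grid-cell) pair is one token. Tokens are embedded by a
linear patch projection with learned temporal and spatial position
embeddings, passed through a stack of transformer encoder blocks
attending across the 16 grid cells within each temporal slot (spatial
attention), then a stack attending across temporal slots within each
cell (temporal attention) — the factorized self-attention arrangement.
Token features are mean-pooled and a final fully connected layer emits
the 16 joint angles in degrees. Blocks are pre-norm with GELU MLPs;
training is Adam on mean-squared error with validation-based early
stopping that restores the best checkpoint exactly.

Two defaults depart from the video-transformer template, both motivated
by what the tokens contain here:

- **Embed activation** (`embed_activation=True`): a GELU follows the
  patch projection. A purely linear embedding of a zero-mean
  interference-pattern patch is itself zero-mean *whatever the
  amplitude*, yet amplitude is what codes muscle activation; the
  asymmetric nonlinearity turns carrier scale into token mean
  (E[GELU(sigma*u)] grows with sigma), making activation level visible to
  attention and pooling.
- **Untied patch projections** (`tied_patch_embed=False`): each grid cell
  has its own projection weights. The 4x4 array is 16 distinct physical
  sensors — there is no translation structure to justify shared weights,
  and with shared weights every cell's expected token is the same
  direction scaled by channel amplitude, so mean pooling collapses the
  spatial activation pattern to a scalar.

Both are switchable back to the conventional tied/linear form.

The network and its gradients are implemented in NumPy on a small
reverse-mode autodiff engine (`semgdec.nn`) — tensors record backward
closures, graphs are walked in reverse topological order, and every
primitive's gradient is checked against central finite differences in the
test suite. Computation is single precision; parameter counts follow a
closed form verified against the instantiated model.

Defaults (all configurable): 32-sample temporal patches, embedding width
64, two spatial + two temporal blocks, 4 heads, MLP expansion 2, MSE
loss, Adam at 1e-3, batch 64, early-stopping patience 5. Optional
per-joint target standardization (`normalize_targets`) trains in z-space
and maps predictions back to degrees; it conditions the optimization
dramatically better when joint ranges differ by an order of magnitude.

## Downstream classification and evaluation

The decoder's 16-dimensional angle outputs for training windows fit an
extremely randomized trees classifier (100 trees, seeded); at test time
each window's predicted angles are classified and window votes are
aggregated to one label per gesture event by majority (ties break
lexicographically). Both window-level and event-level confusion matrices
are reported.

Metrics (`semgdec.evaluation`):

- per-joint error normalized by anatomical range of motion (shipped
  range defaults are round goniometry figures; analyses should inject
  explicit ranges), plus plain MAE in degrees;
- confusion matrix, accuracy (= trace/total), one-vs-rest F1 per gesture;
- Pearson correlation between settings' per-subject accuracy vectors
  (requires >= 3 subjects; exact duplicate columns correlate exactly 1);
- two-sided paired t-tests on per-subject accuracies, with zero-variance
  differences flagged as degenerate instead of returning unguarded
  infinities;
- inter-onset-interval (IOI) analysis against the 8 s ideal cycle
  (empirical CDF and mean absolute deviation);
- classical sEMG features: zero crossings and slope sign changes (strict
  sign changes with a 0.01 dead band on z-scored signals, suppressing
  numerical chatter) and the spectral centroid of a Hann-tapered
  periodogram over 20-450 Hz, whose variance across windows indexes
  spectral nonstationarity.

## Train/validation/test partition

Events are partitioned by repetition index: repetition 1 is dropped
entirely (subjects adjust to the task during the first attempt),
repetition 5 is the test set, repetition 4 validation, and repetitions
{2, 3, 6, 7} train. Windows inherit the repetition of their covering
event, so the three window sets are disjoint by construction; rest
windows go to training only.

## The reference scaled-down study

`semgdec.pipeline.reference_study` is the package's canonical end-to-end
experiment, sized for a single CPU: one simulated subject under the full
98-event protocol; preprocessing as above; windowing with the 512 ms
window but a 32 ms stride (the 2 ms stride would give ~390k windows —
adjacent windows overlap 94% even at 32 ms, so the information loss is
minor); a deliberately small decoder (16 ms patches, width 16, two
heads, one spatial + one temporal block, ~22k parameters — at this data
scale extra capacity goes into memorizing carrier realizations and
*raises* held-out error); training with L1 loss and amplitude-scale
jitter on up to 6000 subsampled windows for at most 18 epochs with early
stopping; evaluation on the held-out fifth repetition. A chance-level
control refits the classifier on shuffled labels and must land inside
the 95% binomial band around 1/14. The problem sizes here are the
package's reference conditions for its own regression tests;
`PipelineConfig` exposes every knob for larger studies.

Observed behaviour worth stating plainly: held-out gesture
classification from the decoder's angle outputs is essentially solved at
this scale (window-level accuracy near 1), while the per-window angle
estimates wobble around the true plateau pose by a few degrees. That
wobble is dominated by sensitivity to the particular 512 ms carrier
realization — errors of neighbouring, 94%-overlapping windows correlate
above 0.9 — so it is not removable by output smoothing, and it shrinks
only slowly with more training. Closing the remaining gap to the
motion-estimator noise floor is a matter of optimization budget, not of
information: the features that separate the gestures perfectly are
demonstrably present in the windows.

## Numerical choices and degenerate inputs

- Zero-phase filtering squares magnitude responses; design checks
  (e.g. the -3 dB point doubling to -6 dB) account for it.
- Savitzky-Golay windows are adjusted to the nearest odd length
  (502 -> 501), as the symmetric formulation requires.
- `iirnotch` sections are cascaded as SOS arrays for numerical stability.
- Ties in majority voting break toward the lexicographically smallest
  label; tie-breaks are therefore deterministic.
- An empty gesture interval, a kinematic track shorter than the smoothing
  window, a recording shorter than one analysis window, non-bijective
  grid layouts, and out-of-vocabulary labels all raise informative
  errors rather than propagating garbage.
- All randomness flows from explicit seeds (simulator, augmentation,
  weight init, batch shuffling, subsampling); identical seeds reproduce
  sessions bit-for-bit and training histories exactly.

## Known limitations

- The simulator's envelope model is piecewise-linear and stationary
  within a hold; real sEMG shows richer nonstationarity (fatigue,
  tremor, posture drift).
- Decoder capacity and training length are sized for CPU regression
  tests, not for state-of-the-art accuracy; the architecture scales, but
  no claim is made about optimal hyperparameters.
- The four settings are simulated as independent sessions; the simulator
  does not model the systematic signal differences between arm postures,
  so cross-setting analyses on synthetic cohorts exercise the statistics,
  not the physiology.
- Real-time (causal, streaming) operation is out of scope; the filters
  default to non-causal zero-phase mode.
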