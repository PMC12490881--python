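# semgdec

Decoding finger joint angles and hand gestures from multichannel surface
electromyography (sEMG).

A wireless 4x4 grid of dry electrodes on the extensor digitorum records
16 channels of sEMG at 4000 samples/s while an optical motion sensor
tracks 16 finger joint angles (thumb/index/middle/ring/pinky
carpometacarpal, metacarpophalangeal and proximal interphalangeal
flexion/abduction) as ground truth. Subjects hold each of 14 gestures
for 5 s with 3 s pauses, 7 repetitions in random order — 98 events per
session — under static and dynamic arm postures. `semgdec` implements
the full offline decoding stack for such sessions:

- **`semgdec.synthetic`** — a session simulator that reproduces the
  acquisition protocol and the signal structure the decoder relies on
  (activation envelopes x band-limited carrier, power-line interference,
  grid crosstalk, force variability, motion-estimator noise), so the
  whole pipeline is testable without hardware;
- **`semgdec.session_io`** — the on-disk session format (arrays + JSON
  sidecar), schema validation, and the repetition-based
  train/validation/test split (drop repetition 1, test on 5, validate
  on 4);
- **`semgdec.preprocess`** — 50/100 Hz notch filtering, 4th-order 20 Hz
  Butterworth high-pass, per-channel z-scoring; Savitzky-Golay smoothing
  and resampling of the kinematics; the 15-degree median-deviation
  outlier rule applied per gesture hold;
- **`semgdec.windowing`** — rolling 512 ms windows (2 ms stride),
  grid-shaped `[L x S x 4 x 4]` tensors, per-window angle targets and
  labels, channel-silencing/noise augmentation;
- **`semgdec.decoder`** — a factorized spatio-temporal transformer
  (spatial self-attention over the electrode grid, temporal
  self-attention over patch time, linear head to the 16 joint angles),
  implemented in NumPy on a small reverse-mode autodiff engine
  (`semgdec.nn`), trained with Adam, MSE loss and validation-based early
  stopping;
- **`semgdec.evaluation`** — extra-trees gesture classification on the
  decoder's angle outputs, confusion matrices / accuracy / per-gesture
  F1, range-normalized joint errors, per-subject setting correlations,
  paired t-tests, inter-onset-interval statistics, and classical sEMG
  features (zero crossings, slope sign changes, spectral centroid);
- **`semgdec.pipeline` / the `semgdec` CLI** — one-config orchestration
  of simulate -> preprocess -> window -> train -> predict -> evaluate
  with seeded, bit-reproducible runs.

The model in one line: windows `x in R^{S x 4 x 4}` are tokenized into
(temporal-patch, grid-cell) pairs, encoded by factorized self-attention,
and regressed onto the joint-angle vector `theta in R^16` (degrees); a
downstream extremely-randomized-trees classifier maps `theta` to one of
the 14 gestures, with window votes aggregated per event by majority.

See `docs/methods.md` for the model, the simulator's assumptions, and
every default parameter.

## Worked example

Simulate a session, decode it, and evaluate on the held-out repetition:

```bash
semgdec simulate --seed 1 --out runs/demo/session
semgdec evaluate runs/demo/session --seed 1 --out runs/demo/report.json
```

or in Python:

```python
from semgdec.pipeline import reference_study

study = reference_study(seed=1)
print(f"event accuracy   {study['event_accuracy']:.3f}")
print(f"window accuracy  {study['window_accuracy']:.3f}")
print(f"plateau MAE      {study['plateau_mae_deg']:.2f} deg")
print(f"chance control   {study['chance_event_accuracy']:.3f}")
```

which prints (seed 1):

```
event accuracy   1.000
window accuracy  1.000
plateau MAE      4.38 deg
chance control   0.071
```

One synthetic subject performs the full 98-event protocol; after
preprocessing, windowing (512 ms windows, 32 ms stride at this desk
scale) and training on repetitions {2, 3, 6, 7}, the decoder's angle
predictions on the never-seen fifth repetition classify every test
window and all 14 test events correctly, and the chance control
(classifier refit on shuffled labels) lands at 1/14, confirming the
accuracy is not an artifact of the evaluation plumbing. The predicted
joint angles wobble around the true plateau poses by 4.4 degrees on
average — gesture identity is decoded essentially perfectly at this
training scale, while the per-window angle estimates retain a few
degrees of carrier-realization noise that shrinks slowly with further
training (see `docs/methods.md`).

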