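# lateralgait

Lateral-walking gait-phase recognition and continuous hip-angle prediction
from surface EMG.

Lateral (sideways) walking is a staple of hip-abductor rehabilitation and a
target movement for resistance-training exoskeletons, yet nearly all
EMG-driven gait analysis targets forward walking. This package implements a
dual-task pipeline for the lateral gait: a **phase classifier** that
recognizes the four phases of a lateral step — narrow double support (NDS),
guided foot swing (GFS, leading leg airborne), wide double support (WDS),
and follow leg swing (FLS, trailing leg airborne) — from six channels of
hip-muscle EMG (gluteus medius, tensor fascia lata, gluteus maximus of each
leg), and a cascaded **regressor** that predicts the continuous hip-abduction
angle of each leg from the same features plus the classifier's phase
decision.

Because no public lateral-walking EMG corpus exists, the package ships a
first-class synthetic-session generator that emulates the recording setup
(6-channel EMG at 1000 Hz; hip angles and four plantar-pressure channels at
200 Hz; ~1.46 s per step) with phase-locked EMG bursts, smooth hip-angle
trajectories, and contact-driven pressure traces, so every stage of the
pipeline is testable end to end.

## The model

The pipeline is:

1. **Preprocess** — Butterworth band-pass 20–400 Hz + 50 Hz notch on EMG;
   pressure and angles linearly upsampled onto the 1000 Hz EMG clock.
2. **Label** — per-foot contact states from thresholded plantar pressure
   (touch "O" / off "F"), mapped to phases by the state table
   (L,R) = (O,F) → GFS, (F,O) → FLS, (O,O) → NDS or WDS by cycle order.
3. **Featurize** — sliding windows (250 ms length, 3 ms increment) over
   each EMG channel yield 8 time-domain features (max, variance, mean
   absolute value, mean, min, RMS, zero crossings, SD), assembled into the
   51-column sample x = [f₁ … f₄₈, P, θ_left, θ_right].
4. **Classify** — the *Elder Brother* network: input 48×1×1 → conv 3×3/32
   (ReLU) → conv 3×3/64 (ReLU) gated by squeeze-excitation channel
   attention → 2×1 max-pool → 22-step sequence → LSTM(48) → dense 64 → 16 →
   4 softmax, trained with Adam (lr 0.01, ×0.1 per 700 epochs) and
   cross-entropy L = −(1/G) Σᵢ Σⱼ h_ij log H_ij.
5. **Regress** — the *Younger Brother* network: the 48 features
   concatenated with the phase decision (49 inputs) → dense 20 → 12 → 6 → 1,
   MSE loss; one head per target (θ_left, θ_right, or within-phase
   percentage).

Evaluation covers the confusion matrix, per-phase recall / FPR / F1 /
one-vs-rest AUC, angle RMSE and R², paired t-tests between models,
advance (future-window) prediction, and contiguous-fraction test sets.
Six comparison classifiers (SVM, KNN, NN, CNN, LSTM, CNN-LSTM) run on the
identical feature matrix.

## Worked example

```python
import lateralgait as lg

cfg = lg.SimulationConfig(n_steps=10, seed=3)      # ~14.6 s session
rec = lg.simulate_session(cfg)                     # EMG + angles + pressure
synced = lg.synchronize(rec)                       # filter, upsample to 1 kHz
labels = lg.label_recording(synced.pressure, fs=synced.fs)
df = lg.assemble_samples(synced, labels)           # 4,780 x 52 feature table

train, test = df.iloc[:-1434], df.iloc[-1434:]     # chronological 70/30
model = lg.TwinBrotherModel.from_dataframe(
    train,
    elder_config=lg.ElderConfig(epochs=100, seed=3),
    younger_config=lg.YoungerConfig(epochs=100, seed=3))
res = model.fit()
print(res.summary())
```

```
Twin Brother dual-task model
==============================================
samples:            3346
elder epochs:       100   final CE loss: 0.0125
training accuracy:  0.9985
theta_left_deg: RMSE 0.2501   R2 0.9995   final MSE loss 0.0005
theta_right_deg: RMSE 0.5389   R2 0.9976   final MSE loss 0.0024
==============================================
```

On the held-out 30% of windows this fit reaches phase accuracy 0.950 and
angle RMSE 1.09° / 1.27° (R² 0.990 / 0.987): the classifier recovers the
four phases from the burst structure of the EMG envelopes, and the
regressor tracks the half-cosine abduction trajectory, with the residual
set by the noise floor of 250 ms amplitude estimates and the phase
boundaries. The same objects expose
`res.predict(features)` for new windows and `res.evaluate(...)` for the
full metric report.

A command-line interface mirrors the stages
(`lateralgait simulate | preprocess | label | featurize | train | predict |
baseline | evaluate | run`), driven by a single YAML config with a global
seed; `lateralgait run` executes the whole pipeline and writes every
artifact plus a hashed manifest.

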