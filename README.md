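# mdrgait

Micro-Doppler radar (MDR) gait analysis and faller classification.

The package implements a complete, reproducible pipeline for assessing
fall risk from 24 GHz continuous-wave radar recordings of a person walking
toward the sensor:

1. **Synthetic cohorts** (`mdrgait.simulate`) — a parametric walking model
   (torso + two toes + two shanks as scattering centres) synthesizes
   complex-baseband I/Q records for labeled faller / non-faller cohorts.
   The generator is calibrated so that cohorts pushed through the full
   pipeline reproduce the published group statistics of the four gait
   parameters.
2. **Signal processing** (`mdrgait.processing`) — 20 Hz zero-phase
   Butterworth high-pass (static-clutter removal), STFT spectrogram with a
   128-sample Hamming window and 127-sample overlap at 600 Hz, and the
   Doppler-to-velocity conversion `v = c·f_d / (2·f_0)`.
3. **Envelope extraction** (`mdrgait.envelopes`) — per-frame upper, lower,
   and power-weighted-mean velocity envelopes using a frame-relative
   −20 dB significance threshold and a 0.125 m/s velocity floor.
4. **Gait features** (`mdrgait.features`) — the four fall-risk parameters
   (`v_m_mean`, `v_u_mean`, `v_u_std`, `v_l_std`) over the steady-state
   window, plus Welch's t-test for group comparison.
5. **Classification** (`mdrgait.classify`) — soft-margin Gaussian-kernel
   SVM with grid-searched hyperparameters tuned for accuracy or
   sensitivity on a stratified 70/30 train/validation split; fallers are
   the positive class; confusion-matrix metrics (accuracy, sensitivity,
   specificity, precision).
6. **Experiment runner** (`mdrgait.experiment`, `mdrgait.cli`) — one-command
   simulate → features → train → test experiments, fully determined by a
   YAML config and a master seed.

## CLI

```bash
mdrgait simulate --n-fallers 14 --n-nonfallers 19 --seed 1 --out signals/
mdrgait spectrogram signals/subj0000.csv --out spec.csv
mdrgait envelopes signals/subj0000.csv --out env.csv
mdrgait features signals/ --out features.csv
mdrgait train features.csv --objective accuracy --out model.json
mdrgait evaluate model.json features.csv
mdrgait run-experiment --seed 1 --out results/
mdrgait verify-tables          # checks embedded printed-table fixtures
```

Signals are stored as plain `t,i,q` CSV files with a JSON metadata sidecar;
all other artifacts are CSV/JSON/YAML.  Identical config + seed produce
byte-identical outputs.

## Notes on conventions

* The spectrogram maps FFT bins onto the frequency interval [0, f_s),
  i.e. velocities 0–3.75 m/s at 600 Hz / 24 GHz.  Since the subject walks
  toward the radar all physical Doppler content is positive, so the full
  complex sampling bandwidth is unambiguous; `frequency_convention`
  switches to a conventional two-sided axis if desired.
* The simulator caps scatterer speeds at 3.5 m/s, keeping Doppler content
  clear of both the velocity-ambiguity edge and the high-pass filter's
  image band near the sampling frequency.
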