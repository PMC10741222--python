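# tbrloop

A tested re-implementation of a closed-loop theta/beta-ratio (TBR)
neurofeedback system for a virtual-classroom attention-training protocol,
plus its offline analysis pipeline. Everything runs at desk scale against a
synthetic-EEG module with known ground truth, so every stage is verifiable
without any real recording.

## What's inside

| Module | Purpose |
|---|---|
| `tbrloop.io` | BrainVision (`.vhdr/.vmrk/.eeg`, float32 µV) and EDF (16-bit, lossy) recordings; BIDS-style events TSV |
| `tbrloop.synth` | Latent-attention traces, multichannel EEG/ECG synthesis, muscle bursts, MR gradient + ballistocardiogram contamination, simulated task behavior — all seeded and emitting ground truth |
| `tbrloop.engine` | Streaming TBR: 3 s Hanning window / 1 s hop, average reference, Fz theta (4–7.5 Hz) / beta (13–19 Hz) power, T7 jaw-muscle gate (3×), relax/focus calibration (min / mean-of-top-quarter), normalization to [0, 1] |
| `tbrloop.feedback` | Helicopter altitude dynamics `h' = clip(h + nfb·10·dt − 0.5·10·dt)`, attention-proportional distraction scheduler (1 per 3 s at full focus, ≥ 1 per 30 s block), closed-loop session orchestrator |
| `tbrloop.tasks` | Go/nogo blocks (20 trials, exactly 25 % 'X'), omission/commission scoring, ±3 SD RT cleaning, adaptive calculation task (70 % rule), Rest/Regulation transfer paradigm (6 + 6 × 30 s) |
| `tbrloop.mr` | Hybrid mean/median moving-template subtraction (gradient L=30 K=6, pulse L=40 K=5), 70 Hz FIR low-pass + downsample to 500 Hz, QRS detection |
| `tbrloop.microstates` | GFP peaks, polarity-invariant modified k-means (100 restarts, best GEV), two-level recording→group clustering, smoothed back-fitting (50 ms window, factor 10) |
| `tbrloop.analysis` | VR preprocessing (1–40 Hz FIR, 50 Hz notch, spherical-spline interpolation, average reference), session TBR relative to the calculation-task baseline, training-period summaries, transfer-task 10 s epoch statistics |

## CLI

All functionality is exposed under a single `tbrloop` entry point:

```sh
tbrloop simulate eeg --duration 60 --seed 1 --out rec.vhdr
tbrloop calibrate --in rec.vhdr --out bounds.json
tbrloop stream-tbr --in rec.vhdr --bounds bounds.json --out tbr.csv
tbrloop run-session --config session.yaml --seed 1 --out sessionlog/
tbrloop gen-task gonogo --seed 1 --out trials.tsv
tbrloop score-gonogo --trials trials.tsv --responses resp.tsv --out score.json
tbrloop simulate mr --duration 60 --seed 1 --out raw5k.vhdr
tbrloop clean-mr --in raw5k.vhdr --events raw5k_events.tsv --out clean.vhdr --qc qc.json
tbrloop microstates fit --in r1.vhdr --in r2.vhdr --k 5 --reps 100 --seed 1 --out maps.json
tbrloop microstates backfit --maps maps.json --in r1.vhdr --out seg.tsv
tbrloop analyze session --tbr tbr.csv --events events.tsv --out session.json
tbrloop analyze transfer --in clean.vhdr --blocks blocks.tsv --out transfer.json
```

## Notes

- All generators are pure functions of `(params, seed)`; ground truth
  (band envelopes, R-peaks, TR onsets, the clean signal) always travels
  with the synthetic data.
- EDF output is documented lossy (16-bit) and does not carry annotations;
  use BrainVision for exact round-trips.
- Template subtraction inherently leaks a trimmed-mean average of the EEG
  into the artifact template (≈ 1/(L−2K) of the signal variance per
  stage); the injection–recovery tests quantify this floor.
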