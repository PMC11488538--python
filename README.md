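# soundstates

Tools for comparing sound representations in the same neural population
across brain states (wakefulness vs. anesthesia), together with a synthetic
two-state recording simulator so every analysis stage can be exercised and
validated without raw recordings.

The package covers:

- **Stimulus protocol** (`soundstates.protocol`) — the 307-sound battery
  (8 categories: 28 pure tones, 26 intensity ramps, 48 chords, 20 chirps,
  30 noises, 48 AM sounds, 60 complex sounds, 47 decompositions) and the
  block-structured session schedule (12 repetitions per sound, blocks of 30
  trials at 1-s onset spacing → 123 blocks, 20 interleaved 30-s natural
  segments, 142 inter-segment gaps of ≥ 3 s).
- **Two-state simulator** (`soundstates.simulate`) — ground-truth populations
  with state-dependent remodeling (response decreases/increases, sign flips,
  complete silencing), Gaussian-in-log2-frequency tuning with a soft level
  threshold, inhomogeneous Poisson spiking, per-state spike templates, and
  synthetic voltage snippets.
- **Signal metrics** (`soundstates.signal_metrics`) — raw MAD noise estimate,
  spike SNR (peak template amplitude / MAD), wake/anesthesia fluctuation ratio.
- **Response metrics** (`soundstates.responses`) — trial-resolved
  baseline-subtracted response tensors (10-ms bins, −0.3 to 1.0 s windows),
  spontaneous rate from inter-block gaps, evoked modulation, trial-pair
  reliability, tuning curves, best frequency, half-width in octaves,
  ramp intensity threshold (2-SD rule), and Mann-Whitney classification of
  best-frequency response changes across states.
- **Unit matching** (`soundstates.matching`) — template-correlation matching
  across states with an empirical chance null (95th percentile of maximal
  cross-recording correlations) and a 0.2 ambiguity margin.
- **Population decoding** (`soundstates.decoding`) — pseudo-population
  nearest-correlation sound classification over 50 random trial half-splits,
  same-state and cross-state designs, time-course or time-averaged codes,
  confusion matrices, per-category accuracies, and a 100-resample neuron
  bootstrap for category accuracy differences.
- **State space** (`soundstates.statespace`) — per-(sound, state) population
  vectors, joint 3-PC projection, 10-fold linear SVM state classification
  (folds stratified 1:1 by state), and rotation of the 2-PC plane to the
  decision boundary with per-axis wake/anesthesia Pearson regressions.
- **Pipeline + CLI** (`soundstates.pipeline`, `soundstates.cli`) — a seeded
  end-to-end run with a JSON report.

## CLI

```bash
soundstates protocol build --seed 0 --out runs/proto
soundstates simulate --units 40 --seed 0 --protocol runs/proto --out runs/sim
soundstates metrics   --sim runs/sim --protocol runs/proto --out runs/metrics
soundstates match     --sim runs/sim --out runs/match
soundstates decode    --sim runs/sim --protocol runs/proto --design cross --out runs/decode
soundstates statespace --sim runs/sim --protocol runs/proto --out runs/statespace
soundstates run --seed 0 --units 40 --out runs/full   # everything + report.json
```

Exit codes: 0 ok, 1 internal error, 2 usage error.

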