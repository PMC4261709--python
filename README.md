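# dyadscope

Quantify parent–infant dyadic interaction from a pair of depth-sensor
recordings — without any hardware. The package covers the full chain for a
tabletop play session observed by two sensors placed at 90° around the
table, one facing each participant:

- **recording_io** — a fully specified on-disk "recording bundle" layout
  (skeleton / source-angle / calibration / image-timestamp XML streams,
  WAV audio, YAML manifest) plus gap-aware nearest-neighbor resampling
  onto a common 30 Hz clock. Gaps are first-class: nothing is ever
  interpolated across missing data.
- **calibration** — spatial registration of the two sensors from
  chessboard corner correspondences (SVD orthogonal-Procrustes with
  determinant correction; reflections are rejected) and temporal
  alignment of the two free-running sensor clocks from a shared clap
  detected in both audio tracks. The world frame puts the table center at
  the origin, +y up, +z along the chessboard column direction.
- **skeleton** — per-slot parent/child labeling by seat proximity,
  suppression of inconsistent frames (teleports, implausible shoulder
  widths, far-from-seat tracks), fusion of the two sensor streams into
  one `DyadSeries` (the facing sensor wins when both agree, disagreement
  becomes a gap), gap-aware moving-average smoothing, and protocol phase
  segmentation (free play 4 min, directed game 2 min, parent occupied
  2 min).
- **features** — shoulder-center and closest-hand distances to the table
  center, cross-pair hand distances, head distance, shoulder orientation
  versus the z axis and relative shoulder orientation (acute angles in
  [0°, 90°]; facing the table reads 45°, facing the partner 90°, face to
  face 0° relative), speeds, per-partner movement-contribution shares,
  approach/avoid labeling, debounced hand-contact events, and per-phase
  summaries.
- **audio** — a transparent short-time-energy VAD (percentile noise
  floor, logistic probability, 100 ms sustain), attribution of detected
  sound to a participant by matching the sensor's source azimuth against
  each head's azimuth, utterance extraction with bridging, and
  speech-turn counting (a turn = a speaker change).
- **cib** — validation of 43-item interactive-behavior records (1–5
  Likert codes) and the eight composite subscores as arithmetic means of
  their item sets, plus a comparison bar chart.
- **synthetic** — a seeded generator that emits complete two-sensor
  bundles *with ground truth*: unknown rigid transform and clock offset,
  shared clap, seated torsos with mean-reverting jitter and
  attention-driven rotations, scripted hand contacts and speech bursts,
  frame drops and a scripted child off-camera window. Two built-in
  behavioral profiles ("control" and "pathological") realize contrasting
  proximity / movement-leadership / turn-taking patterns.
- **pipeline / cli** — orchestration of
  calibrate → preprocess → extract → audio → report, producing CSV tables,
  an event list, per-phase summaries and an HTML report with PNG panels.

## CLI

```bash
# synthesize a 4-minute recording bundle with ground truth
dyadscope simulate --profile control --duration 240 --seed 42 --out bundle/

# individual stages
dyadscope calibrate bundle/ --out calibration_result.yaml
dyadscope preprocess bundle/ --out results/
dyadscope extract bundle/ --out results/
dyadscope audio bundle/ --out results/

# everything, including the HTML report
dyadscope run bundle/ --out results/

# composite scoring of a long-format item-code CSV (dyad_id, item, code)
dyadscope cib score cib.csv --out cib_composites.csv --plot cib.png
```

Every threshold (clock rate, fusion max gap, smoothing window, contact
threshold/hysteresis/debounce, VAD framing, ...) lives in a YAML config
passed via `--config`; defaults are in `dyadscope.pipeline.PipelineConfig`.

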