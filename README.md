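# stringpull

Whole-body and fine-kinematic analysis of rodent **string-pulling** videos.

String pulling — hand-over-hand reeling-in of an overhanging string — is a
naturalistic skilled-reaching behavior used to assay motor function in mice
and rats. This package turns a video epoch of the behavior into quantitative
read-outs at two levels, with no neural-network training required:

* **Whole-body characterization** (no tracking needed). Dense optical flow
  by the combined local-global (CLG) variational method converts frame
  pairs into calibrated speed frames, `speed = |(u, v)| · fps / (10 · px/mm)`
  in cm/s. Each pixel's intensity or speed time series is then summarized
  into measurement frames — mean, median, mode, σ (N−1), skewness,
  kurtosis, Fano factor σ²/μ, temporal entropy −Σp·log₂p, and the Higuchi
  fractal dimension (slope of log L(k) vs log 1/k, kmax = 10). Single
  frames are summarized by spatial entropy, sharpness Σ|∇I|/(H·W), and the
  box-counting (Hausdorff) fractal dimension −d log N(ε)/d log ε. PCA and
  fastICA of the pixels × frames matrix expose dominant postures and
  high-spatiotemporal-contrast events (hand/string appearances).
* **Heuristic part tracking and kinematics.** Fur, ears, nose, hands and
  string are segmented by per-object color models (range search at
  Euclidean RGB radius 1.5 in 8-bit units, k-nearest-neighbor, or a
  grid-filtered variant). Rules that exploit the animal's geometry and the
  previous frame's state identify the body ellipse, the two ears, the nose
  and the two hands; from these come body length/tilt, head yaw
  (ln d(nose, earR)/d(nose, earL)), roll, pitch, hand trajectories and
  speeds, reach-cycle rise/fall times, dominant frequencies, and two-group
  comparisons (Student's t, Cohen's d).

A **synthetic mouse generator** renders colored elliptical body parts with
sinusoidal hand oscillators (12-frame cycle, hands 180° out of phase) and
exact ground-truth masks, so every stage of the pipeline is testable end to
end.

## Worked example

Generate a 120-frame synthetic mouse, segment it, track all parts, and
score against ground truth:

```python
import numpy as np
from stringpull.synthetic import SyntheticSpec, modeled_mouse
from stringpull.segmentation import ColorModel, mask_range
from stringpull.tracking import run_tracking, benchmark_accuracy
from stringpull.kinematics import hand_series, segment_reach_cycles, dominant_frequency

spec = SyntheticSpec(n_frames=120, seed=0)
stack, truth = modeled_mouse(spec)
models = {p: ColorModel(p, [spec.colors[p]]) for p in ("fur", "ears", "nose", "hands")}
provider = lambda t: {p: mask_range(stack.frame(t), m, radius=1.5) for p, m in models.items()}
init = {"hand_R": truth.part_xy("hand_R", 0), "hand_L": truth.part_xy("hand_L", 0)}
track = run_tracking(provider, stack.n_frames, stack.px_per_mm, init)
print("accuracy:", benchmark_accuracy(track, truth))
hs = hand_series(track, stack.fps, stack.px_per_mm, stack.shape[0])
cycles = segment_reach_cycles(hs["hand_R_y"], stack.fps)
print(f"reach cycles: {len(cycles)}, median duration "
      f"{np.median([c.end - c.start for c in cycles]):.0f} frames")
print(f"dominant hand frequency: {dominant_frequency(hs['hand_R_y'], stack.fps):.1f} Hz")
```

Output:

```
accuracy: {'body': 100.0, 'ears': 100.0, 'nose': 100.0, 'hands': 100.0}
reach cycles: 9, median duration 12 frames
dominant hand frequency: 5.0 Hz
```

Every part is found in every frame (the synthetic video has separable
colors and no occlusion), the hand completes one reach cycle every 12
frames, and at 60 fps that is the expected 60/12 = 5 Hz rhythm.

## Command line

`stringpull` exposes the pipeline as subcommands — `synth`,
`define-colors`, `make-masks`, `benchmark`, `compare`, and `run` (the whole
framework from one YAML config, writing CSV/TIFF artifacts, a bit-packed
mask archive and a manifest with seeds and per-stage status). Frame numbers
printed on the console are 1-based, matching on-video frame counters.

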