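# mwcolon

In-silico model of a microwave-based accessory for colonoscopy. A ring of
8 transmitting + 8 receiving antennas, worn on the colonoscope tip and
operating at 7.5 GHz, measures scattered microwave fields while the
endoscope is withdrawn through the colon. Because neoplastic tissue differs
from healthy mucosa in its dielectric properties (relative permittivity
ε_r and conductivity σ), each cross-sectional "frame" can be turned into an
image of dielectric contrast: healthy colon reconstructs dark and
homogeneous, a polyp appears as a bright blob, and an alert can be raised
the moment the ring passes a lesion.

This package simulates the whole chain and detects polyps from it:

1. **Scenes** — synthetic pull-back timelines with polyps (wide, many-frame
   inclusions), stool remnants (short inclusions), wall-contact events that
   corrupt channels, and ground-truth annotations.
2. **Forward model** — Born-approximation scattering in a homogeneous
   mucosa background with the 2-D Green's function G(r) = (−j/4)·H₀⁽²⁾(kr),
   producing the 24 complex channels per frame defined by the switching
   schedule (each transmitter read by its adjacent and two diagonal
   receivers).
3. **Imaging** — per-frame unit-norm matched-filter backprojection
   I(p) = |a_p^H (d − b)| / ‖a_p‖ of the baseline-subtracted residual on a
   polar grid, reduced to an angular profile and a per-frame scalar
   aggregate; stacked over frames this is the longitudinal B-scan.
4. **Quality** — frames whose channels deviate from baseline on ≥ m_min
   channels by more than τ_chan (relative) are flagged invalid (antenna
   mismatch from wall/stool contact).
5. **Detection** — threshold μ + 5σ calibrated on a leading healthy window;
   above-threshold runs bridged over small gaps; runs ≥ L_min = 10 frames
   are polyp alerts, shorter runs stool.
6. **Evaluation** — segment-level scoring against ground truth, plus two
   canned experiments: a 600-frame sequence with 3 isolated polyp and 4
   healthy segments, and recovery of a 14% contact-corruption rate on a
   7087-frame stream.

See `docs/methods.md` for the model's assumptions and parameter rationale.

## Worked example

Simulate the 600-frame replica sequence, detect, and score:

```sh
mwcolon simulate --replica-fig3 --seed 1 --out-dir demo
mwcolon detect --stream demo/stream.h5 --seed 1 --out-dir demo
```

prints `3 event(s)` and writes `demo/events.tsv`:

```text
# mwcolon intervals: 0-based, half-open [frame_start, frame_end)
frame_start  frame_end  label  theta_peak  peak_contrast
73           99         polyp  5.9395      0.000742
162          189        polyp  2.6998      0.000726
528          561        polyp  2.6016      0.000794
```

Three bright runs, each at least 26 frames wide (≥ L_min, hence labelled
polyp), with the angular position of the peak in radians and the peak
contrast in arbitrary units. The one-shot experiment command

```sh
mwcolon replica-fig3 --seed 1 --out-dir demo2
```

runs the same pipeline and scores it against ground truth, printing
`polyp segments detected: 3/3; healthy false positives: 0` and writing
`demo2/report.json`:

```json
{
  "polyp_segments": 3,
  "polyp_detected": 3,
  "healthy_segments": 4,
  "healthy_with_false_polyp": 0,
  "stool_segments": 0,
  "stool_misclassified_as_polyp": 0,
  "n_frames": 600,
  "seed": 1
}
```

i.e. every polyp-containing segment received an overlapping polyp alert and
no healthy-mucosa segment did. `mwcolon trial2-recovery --seed 1 --out-dir t2`
runs the discard-rate experiment: on a 7087-frame stream with 14% of frames
contact-corrupted it prints the fraction the validity classifier recovers
(`invalid fraction: 0.1400 (generator: 0.1400)`).

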