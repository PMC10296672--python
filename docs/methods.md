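# Methods

`mwcolon` is an in-silico model of a microwave accessory for colonoscopy: a
ring of antennas worn on the colonoscope tip that senses the dielectric
contrast between colorectal polyps and healthy mucosa while the endoscope is
withdrawn, and raises an alert when a polyp passes the ring. This note
records the model, its assumptions, the tunable parameters, and the design
choices made where the design was genuinely open.

## Physical model

**Dielectrics.** Tissue is described by relative permittivity `eps_r` and
conductivity `sigma` (S/m), combined at the single operating frequency
f = 7.5 GHz into a complex relative permittivity
`eps* = eps_r − j·sigma/(2·pi·f·eps0)` under the `e^{+j·omega·t}` time
convention (losses negative). The imaged quantity is the relative contrast
`chi = (eps*_inc − eps*_bg)/eps*_bg`. Default tissue values (mucosa 50/6,
polyp 60/8, stool 40/4) are plausible high-water-content soft-tissue values
chosen to give a clear polyp contrast (|chi| ≈ 0.21); they are configurable
placeholders, not measured data.

**Array and schedule.** Eight transmit and eight receive antennas sit on a
10 mm-radius ring at uniform 45° spacing. The receive ring keeps the
transmit indexing but is rotated by half the element spacing (22.5°), so
rx_i lies between tx_i and tx_{i+1}; a literally co-located tx/rx pair would
make the direct-coupling term singular, and the half-spacing offset
preserves the 45° rotational symmetry that several properties (and tests)
rely on. Each transmitter is read by its adjacent receiver and the two
diagonal neighbours, giving 24 complex channels per frame.

**Forward model.** Each frame is an independent 2-D cross-section in a
homogeneous mucosa background with complex wavenumber
`k = (2·pi·f/c)·sqrt(eps*_bg)`, branch `Im(k) ≤ 0`. Propagation uses the 2-D
scalar outgoing-wave Green's function `G(r) = (−j/4)·H0^(2)(k·r)`.
Scattering is Born (single scattering): channel = deterministic tx→rx
baseline + Σ_s `amplitude_s·chi_s·G(tx,s)·G(s,rx)` + circular complex
Gaussian noise whose std is `noise_sigma` (default 1e-3) times the median
baseline magnitude. Inclusions are point scatterers: an extended lesion is
absorbed into `amplitude`, which keeps every forward value analytic and
every property (linearity, rotation equivariance, monotonicity in |chi|)
testable to tight tolerance. Wall-contact events multiply a subset of
channels by a severity factor (default 10) with a random phase, emulating
antenna mismatch.

## Reconstruction

The per-frame image is the unit-norm matched filter over a polar grid
(default 20 radial bins to 25 mm, 64 angular bins):

    I(p) = |a_p^H (d − b)| / ||a_p||,   a_p[pair] = G(tx,p)·G(p,rx)

with `b` a per-channel baseline estimated as the component-wise median over
the first `calib_frames` (default 50) frames, which the operator asserts are
healthy. The norm in the denominator matters: in a lossy background
`||a_p||` decays steeply with distance from the ring, and the unnormalized
adjoint systematically drags the radial argmax toward the antennas; the
normalized statistic peaks at the true scatterer cell (angular bin exact,
radial bin within ±1 in our placement sweeps). Pixels within 2 mm of any
antenna are excluded (set to zero): the point-source model is meaningless in
an element's reactive near field, and such pixels otherwise host
matched-filter sidelobes. No regularized inversion is attempted — the output
is a qualitative contrast magnitude, which is all the detector consumes.

Each frame is summarized by its angular profile (radial max per angular bin)
and a scalar aggregate (profile max). Max, not mean, because a polyp is a
peak criterion: a small bright feature must not be washed out by averaging.
Stacking profiles over frames gives the longitudinal B-scan map.

## Frame validity

Contact-corrupted frames are flagged by a per-channel relative-deviation
count: channel c is deviant when `|d_c − b_c|/|b_c| > tau_chan` (default
0.5), and a frame is invalid when at least `m_min` (default 2) channels are
deviant. A count rather than a norm, because contact mismatches specific
antennas; one strong polyp echo on one channel must not invalidate a frame.
With the default tissue contrasts the largest polyp-induced per-channel
deviation is ~0.03, a factor ≈ 16 below `tau_chan`, while a severity-10
contact produces deviations of 9 on the affected channels, so the two
regimes are cleanly separated.

## Detection

The detection threshold is `mu + k_sigma·sd` (default `k_sigma` = 5) of the
aggregate over the first `calib_frames` valid frames. Candidate runs are
maximal intervals of valid frames with aggregate above threshold, bridging
interior gaps up to `gap_bridge` = 3 frames. A run spanning at least
`L_min` = 10 frames is labelled polyp, anything shorter stool: run width is
the single discriminant, and `L_min` sits between the generator's stool
extents (2–5 frames) and polyp extents (15–39 frames) with margin on both
sides. Alerts are frame-stamped events (start, end, angular peak, peak
contrast, label) — the machine-readable form of the device's acoustic
signal; no audio is rendered.

## Synthetic scenes and what they do not capture

The scene generator emulates the *stream structure* of an animal pull-back:
isolated polyps (wide bright runs), stool remnants (short bright runs),
contact-corrupted frames at a configurable fraction (placed disjointly and
trimmed so the realized coverage matches the requested fraction exactly),
and optional clustered (overlapping) polyps whose overlap region is
annotated `cluster` and excluded from scoring. Ground-truth labels are
assigned per frame with priority contact > cluster > polyp > stool >
healthy. The canned `replica_fig3_timeline` produces a 600-frame sequence
with exactly 3 isolated polyp segments and 4 healthy segments; the leading
healthy stretch is at least 60 frames so calibration always sees a clean
start, and by default it contains no stool so the 3 + 4 segment composition
is invariant across seeds (an `include_stool` flag exists for exercising the
stool path).

The generator does **not** model haustral folds, peristalsis, extended
lesion shape, mucosal heterogeneity, antenna element patterns, mutual
coupling beyond the baseline term, or multiple scattering. Passing tests
therefore show that the *pipeline logic* — calibration, imaging,
validity classification, run-width discrimination, segment scoring — behaves
correctly under the declared physics, not that the device performs at any
particular level on real tissue.

## Numerical choices

- Frame intervals are 0-based, half-open everywhere.
- All randomness flows from a single integer seed through
  `numpy.random.default_rng`; identical seeds give byte-identical archives
  (HDF5 written without modification-time tracking).
- Linearity checks compare einsum paths that sum in different orders;
  tolerances of 1e-10 (channels) / 1e-8 (images) absorb the resulting
  last-digit differences after near-cancellation.
- Median (not mean) baseline estimation tolerates a minority of corrupted
  frames inside the calibration window.
- Degenerate inputs: empty annotation files read as empty tracks; zero
  baseline channels are excluded from mismatch scores with a warning; a
  scatterer placed exactly on an antenna raises.

## Problem sizes

The replica experiment runs the full simulate–reconstruct–detect–score
pipeline on 600 frames in well under a second; the repeatability sweep uses
20 seeds. The discard-rate experiment uses a 7087-frame stream. These sizes
match the study design being emulated and keep every experiment desk-scale.

## Known limitations

- Born + point scatterers means reconstruction amplitude is qualitative;
  no permittivity values are recovered.
- Radial resolution of a single-frequency, 24-channel ring is inherently
  coarse (±1 radial bin ≈ ±1.25 mm under the default grid).
- The contact model is multiplicative mismatch on whole channels; real
  antenna detuning is frequency- and geometry-dependent.
- Cluster exclusion is annotation-driven; no declustering algorithm is
  claimed or implemented.
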