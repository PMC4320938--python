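# Methods

This note records the model, the numerical choices, and the places where
the design was genuinely open, so results can be interpreted and reproduced
without reading the source.

## Pipeline model and assumptions

The detector assumes (i) leads are time-aligned views of the same electrical
activity, so fiducials found on one lead are valid on all; (ii) within a
record, normal beats recur with near-identical morphology, so they form a
motif and any beat excluded from it is suspect; (iii) the TP segment is
isoelectric, so morphology comparison can be confined to the P-wave, PR and
QT portions of each cycle; (iv) anomalies of interest are whole-beat
morphology changes (PVC-like), not rhythm-only or ST-level changes.

### Preprocessing

Two cascaded 2nd-order Butterworth biquads — low-pass 20 Hz, then high-pass
2 Hz — each applied forward–backward (`scipy.signal.sosfiltfilt`, default
odd-reflection padding).  Forward–backward filtering squares each magnitude
response; measured attenuation at 50 Hz and 0.3 Hz relative to the 10 Hz
passband exceeds 30 dB, and passband group delay is zero, which is what
keeps R/P/T peaks of symmetric deflections in place.  Two biquads rather
than one band-pass design keep the two clinical roles (mains suppression,
wander suppression) independently tunable (`preprocess.low_cut_hz`,
`high_cut_hz`, `order`).

### Motif discovery and the bitsave score

Window lengths run from the starting length `round((1/3)(100/60) fs)` to
twice that value, step `max(1, round(fs/50))` (configurable).  The starting
length is one systole at the 100 bpm top of the normal resting range; the
2x ceiling covers bradycardic cycles.  In practice the winning length sits
at the *minimum RR interval* of the record: windows keep saving bits as they
grow until they can no longer tile one window per cycle, at which point a
member drops out and bitsave collapses.  (A window equal to the P-to-T span
never wins — the extra low-cost TP samples still save bits — so tests
assert the period property, not the span.)

Windows are z-normalized with the population SD; constant windows map to
the zero vector.  Two windows may pair or co-exist in a group only if their
intervals do not overlap — without this trivial-match rule the closest pair
is always a one-sample shift of itself.  The candidate pair search uses the
correlation identity `d^2 = 2m(1 - rho)` on running window sums (O(n^2) per
length instead of O(n^2 m)); an object-level search on explicit subsequence
lists uses the direct quadratic scan, and a test pins the two paths to each
other.  Ties break lexicographically on start indices everywhere, making
the whole module deterministic.

Bitsave is `sum_members [DL(member) - DL(member | center)] - DL(center)`
with the center fixed at the average of the founding pair (re-averaging as
members join is available as `motif.recenter` but off by default — the
founding pair is the cleanest estimate of the template, and a drifting
center makes acceptance order-dependent).  Vectors are quantized to 8-bit
levels over [-4, 4] sigma; `DL(raw) = 8m` bits; residuals against the
center are Rice-coded (k = 2, sign folded): `cost(r) = 3 + floor(|r|/2)`
bits per sample.  A neighbour is accepted exactly when coding it against
the center is cheaper than coding it raw, i.e. when its mean residual cost
is below 8 bits/sample (about 0.3 sigma mean absolute residual).  Rice
k = 2 is the matched code for the near-zero geometric residuals a correct
template produces; it admits noisy copies of the template (noise at the
default sensor-noise level costs ~4 bits/sample) and rejects windows of
independent or PVC-like content (>= 9 bits/sample).  A simpler logarithmic
residual code was rejected because its cost tops out near 10 bits/sample,
barely above the 8-bit baseline, which would let pure-noise windows into
every group.

Growth visits unused non-overlapping windows in ascending Euclidean
distance to the center and stops at the first rejection.  The cleanest lead
is the argmax of per-lead bitsave (ties to the lowest index).  Anomaly
candidates are the maximal uncovered spans of the cleanest lead, minus
fragments shorter than half the motif length (boundary slack that cannot
hold a beat).

### Segmentation

Leads are polarity-oriented before delineation: when the dominant
deflection of the band-passed lead is negative (|min| > |max| — routine in
clinical leads such as aVR, or any lead with inverted electrode polarity),
the working signal is flipped so the R wave, P and T maxima point up;
returned indices refer to the original lead.

QRS: first difference `d_t = x_{t+1} - x_t`; an R candidate is a voltage
maximum enclosed by `d >= thr` followed within 0.10 s (the QRS upper bound)
by `d <= -thr`; candidates within the 0.20 s refractory period resolve to
the taller peak.  The adaptive threshold is half the median of the three
largest local extrema of `|d|` per 2-s window: a window holds 2–3 beats, so
those extrema are R up/downstrokes, putting the threshold ~3x above T-wave
slopes with no fixed voltage assumption.  Q and S are the local minima
flanking R within 0.05 s (argmin fallback on monotone data).  P peak is the
maximum within 0.20 s before Q (the PR upper bound), T peak the maximum
within 0.38 s after S (QT upper bound minus QRS lower bound); wave onsets
and ends are the flanking minima within 0.06 s (half the P-wave upper
bound), clipped so the fiducial chain stays ordered.  All windows are
specified in seconds and converted with `round(sec * fs)`.

Beats whose P or T search windows would cross the record edge are dropped
(`segmentation.drop_edge_beats`); a partial morphology cannot feed the
partial-DTW distance.  Delineation runs on the filtered signal — the
pipeline order implies it, and the slope operator needs the wander removed.
Argmax/argmin ties resolve to the earliest index.  TP segments are
`[t_end(k), p_onset(k+1))`; an empty segment (overlapping beats) is kept
and flagged so downstream shifting retains its anchors.

### Detection

DTW uses squared pointwise cost, steps {(1,1),(1,0),(0,1)}, both ends
anchored, no band constraint (the compared segments are short, tens to a
hundred samples, so the full O(nm) table is cheap; numba-compiled with a
pure-Python fallback).  The beat distance is the sum of three DTW terms
(P-wave, PR, QT), each segment z-normalized first so the terms are
comparable across amplitude differences (`detection.normalize_segments`);
a collapsed zero-length portion is stood in by a single baseline sample so
the other beat's portion is still scored.

The flagging threshold is the mean plus sample SD (ddof = 1) of the
pairwise beat-distance pool of the lead, and a beat alerts when its
*nearest-neighbour* distance strictly exceeds it.  Pooling all pairwise
distances rather than the nearest-neighbour minima is deliberate: the
standardized maximum of ~10 nearest-neighbour values exceeds mean + SD with
high probability for any non-degenerate sample, which would flag at least
one normal beat on clean records; a minimum exceeding the mean + SD of
*all* distances, by contrast, means "far from every other beat", which is
the quantity of clinical interest.  The narrower pool remains available as
`detection.threshold_source = "nearest"`.  This pooling is also what makes
artifact leads quiet: a persistent artifact inflates every pairwise
distance in its lead, raising the threshold in proportion.

Motif-stage candidates are shifted onto cardiac-cycle boundaries (start to
the nearest P onset, end to the nearest T end; equidistant ties to the
earlier anchor; a collapsed result snaps to the most-overlapping beat's
span) and kept only when they land on a beat that is *not* motif-covered
(>= 50 % of its span under motif members).  This realizes "candidates are
the beats excluded from the motif" and discards beatless complement
fragments (record tails).  The record-level set is the union
(configurable: union / majority / cleanest-only) of per-lead flags plus
these candidate beats, reported as whole beat spans — a detection can never
cover half a cycle by construction.

## Synthetic data: what it emulates, what it does not

Each beat is five Gaussian bumps (P, Q, R, S, T) with defaults chosen so
the clinical normal ranges hold by construction: PR 0.17 s (0.12–0.20),
P-wave 0.11 s (<= 0.12), QRS 0.09 s (0.06–0.10), QT 0.38 s (0.36–0.44).
Rhythm defaults: 70 bpm, RR jitter SD 20 ms (clipped at 3 SD), amplitude
jitter CV 5 %, sensor noise 0.01 mV SD, first beat at 0.45 s and the last
at least 0.5 s before the record end so every beat's search windows fit.
Leads differ by gain/polarity only; TP segments are isoelectric.  A PVC
replaces a beat in place: no P bump, QRS widths and amplitudes x1.6,
inverted T; its ground-truth morphology box is the ectopic R core
(+-2.2 widened sigmas) — the clinically defining feature, and the part any
correct detection must cover.

Artifacts are additive and local: wandering baseline (0.3 Hz sinusoid,
0.5 mV), AC interference (50 Hz, 0.3 mV), muscle tremor (Laplacian noise
high-passed at 30 Hz, 0.35 mV rms), motion (2–4 random steps smoothed with
a 0.4 s Gaussian, 1.5 mV), each faded in and out with a wide (alpha 0.5)
Tukey taper — clinical artifact sources wax and wane; a sharp onset would
manufacture broadband transients that no physical wander process contains.
The standard contamination pattern applies each class over the whole
record, matching how mains coupling, tremor and electrode trouble afflict
real excerpts, and matching the threshold-adaptation assumption above.
Magnitudes are set so contamination is clearly visible to the motif stage
while detection remains reliable; multiplying them by >= 5 reproduces an
"extremely noisy" regime where detection is expected to degrade.  The
morphology mimic is a time-compressed (to 80 % of the TP gap), 0.8-scaled
copy of the normal beat template inside one TP segment of one lead — an
artifact by definition, so truth labels do not change.

What the generator does *not* emulate: realistic 12-lead projection
geometry (gains are scalars, not dipole projections), respiratory
modulation, rhythm disorders (only morphology anomalies), U waves,
multi-morphology PVC populations (injected PVCs share one shape), and
non-additive artifacts (electrode saturation, clipping).  Passing tests
therefore show robustness of the *mechanism* — lead ranking, segmentation,
portion-wise comparison, adaptive thresholding — on morphology like real
ECG, not clinical performance on any patient population.

## Problem sizes and determinism

The shipped experiments use 10-s records at 257 Hz (10–21 beats), 1–12
leads, 20 seeds per property and 10 per acceptance-script experiment; the
motif kernel is O((n - 2m)^2) per grid length, giving ~0.5 s per lead at
these sizes.  Every random draw flows from an explicit integer seed
(`numpy.random.default_rng`); the detector itself contains no randomness,
so `detect(record, config)` is a pure function.

## Known limitations

* Several identical anomalous beats can in principle seed the motif pair
  themselves (their taller QRS lowers relative noise after z-normalization);
  with RR jitter this did not occur in testing, but a record dominated by
  one ectopic morphology (e.g. sustained bigeminy with machine-identical
  complexes) would defeat the "normal beats are the majority motif" premise,
  as it would for the original method.
* The cardiologist criterion is only as good as the segmentation of the
  cleanest lead; if no lead segments (flat record, pervasive noise in all
  leads), detection raises rather than guessing.
* Beat-level FP attribution counts one FP per normal beat intersected by an
  unmatched detection and one FP for a detection touching no beat at all;
  in the latter case tp+fp+fn+tn exceeds the beat count — unavoidable if
  free-floating detections are to be penalized at all.
* Metrics with empty denominators (sensitivity with no anomalous beats,
  AoD likewise) are reported as None/"n/a", never 0 or 100.
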