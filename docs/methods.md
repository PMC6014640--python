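# Methods

This note documents the model and the numerical choices behind
`fhrcluster`, in the order the pipeline runs.

## Signal model and conventions

A single-channel abdominal ECG is treated as a sampled voltage series
(typically 1 kHz, arbitrary units). All sample indexing is 0-based;
plain-text annotation files carry 0-based indices (the 50 ms matching
tolerance makes a one-sample convention difference immaterial, but one
convention is fixed to avoid off-by-one matching drift). Beat matching is
one-to-one and greedy in reference order; with fetal RR ≥ 270 ms and a
50 ms tolerance this coincides with optimal assignment except in
pathological inputs.

## Wavelet preprocessing

One orthogonal DWT (default `db6`) decomposes the signal to depth L = 7.
The depth-L approximations — DC offset and baseline wander at 1 kHz — are
zeroed. The M = 3 finest detail levels are shrunk with the universal
threshold `σ·√(2 ln N)`; σ is the MAD-based noise estimate
`median(|d₁|)/0.6745` from the level-1 details only and is reused at all
thresholded levels ("single rescaling", the `wden`-style `'sln'`
semantics of the MATLAB wavelet toolbox, whose vocabulary these parameter
names follow). `N` is the full signal length, not the per-level
coefficient count — same toolbox semantics. Details at levels 4–7 pass
unchanged; at 1 kHz they carry the QRS energy, which is why noise-free
QRS amplitudes survive denoising essentially intact (tested ≥ 80%,
observed ≈ 90%).

Numerical choices: symmetric (half-point) boundary extension; a zero
threshold (noise-free input) is a no-op rather than a 0/0 shrink; signals
too short for depth 7 are processed at the largest feasible depth with a
warning instead of being rejected, so short fixtures still run.

## Max-min points

An RS-peak candidate is a strict local maximum followed by the next local
minimum. Plateaus (runs of equal samples, common in 16-bit data) count as
one extremum at the run's first sample. A maximum whose next extremum is
not a minimum is discarded — only the immediate R→S geometry matters. No
gating happens here: separating noise from fetal/maternal peaks is the
clustering stage's job, which is the point of the method (no amplitude
thresholds to tune).

## Feature selection

Per analysis window the amplitude histogram uses 50 equal bins over
`[0, MA]` (MA = window maximum amplitude; top edge inclusive), normalized
by the point count, then smoothed. The smoothing filter is a centered
moving average of width 5 bins with shrinking edge windows: parameter-free
beyond the width, which at 50 bins suppresses single-bin jitter without
merging the fetal and maternal modes; the width is an argument. Local
extrema on the smoothed series use strict comparison with the same
plateau-first-bin rule; boundary bins may be extrema one-sidedly. Scanning
from bin 0, the first local minimum marks the noise boundary; maxima above
it with smoothed mass ≥ 0.5% (a prominence floor against noise wiggles,
also an argument) are the candidate fetal/maternal modes. The case table:

| post-noise maxima | condition               | feature            |
|-------------------|--------------------------|--------------------|
| 2                 | `dmax-max ≥ 0.35·MA`     | amplitude          |
| 2                 | `dmax-max < 0.35·MA`     | amplitude × span   |
| 1                 | —                        | amplitude × span   |
| 0 or > 2          | —                        | amplitude (fallback)|

`dmax-max` is measured between bin centers; a tie at exactly `0.35·MA`
selects amplitude. Every comparison is relative to MA, so the decision is
scale-invariant.

## Clustering

k-medoids with k = 3 (noise / fetal / maternal), squared-Euclidean
dissimilarity on the 1-D feature, ++ seeding (first medoid uniform, each
next sampled ∝ squared distance to the nearest chosen medoid), 20
restarts, best total cost kept. The update step is Voronoi-style
alternation; with a squared-Euclidean cost the optimal medoid of a
cluster is its member closest to the cluster mean, which is computed
exactly rather than by an O(m²) scan. An iteration cap of 100 guards the
label-stability stopping rule. One seeded generator drives all restarts,
so a seed fully determines the output. Tests verify the best-of-20 cost
against exhaustive search over all medoid triples at small n.

Roles come from cluster medians: smallest → noise, largest → maternal,
middle → fetal. An even-sized cluster's median is the mean of its two
central values; tied medians are resolved toward the larger medoid with a
warning.

## Refinement and RR correction

Refinement re-checks fetal-labelled points against window-derived limits:
amplitude at least the first-local-minimum bin center (noise boundary),
at most the midpoint of the two post-noise mode centers when both exist
(else MA), and RS span at most 60 ms. The limits can be overridden with
absolute values.

The FP/FN correction works on RR plausibility. The published description
of this stage is conceptual ("RR time distances … heart rate limits"), so
the concrete rules here are this package's reconstruction, fully
config-exposed and to be treated as tunable defaults rather than
authorial values: a centered running median over 9 RR intervals (shrunk
at the ends, robust to genuine FHR drift); an interval below 0.5× the
running median, or implying > 220 bpm, drops the pair member with the
smaller RS amplitude; an interval above 1.5× the running median, or
implying < 100 bpm, is scanned at the expected beat position ± 30 ms for
the largest unused max-min point, walking multi-beat gaps one expected
position at a time. The FP pass runs before the FN pass, each as one
forward sweep; every removal/insertion is recorded in an audit list, and
gaps with no insertion candidate are logged and left alone.

## Windowing

Detection runs on consecutive 50,000-sample windows (feature selection,
clustering and refinement are per-window; detection quality is flat over
roughly 10,000–60,000-sample windows, so a final partial window of at
least 10,000 samples stands alone and a shorter one merges into its
predecessor). Denoising is applied once to the whole record — windowing
from feature extraction onward avoids window-edge wavelet artifacts; a
flag enables per-window denoising instead. Duplicate detections within
the matching tolerance across a window seam keep the larger amplitude.
RR correction runs once over the concatenated record-level train.

## Synthetic data

The generator emulates exactly what the detector consumes: a strong
maternal beat train (default 80 bpm, amplitude 1.0, 45 ms RS width) plus
a weaker faster fetal train (140 bpm), sinusoidal baseline wander
(0.3 a.u. at 0.25 Hz) and white Gaussian noise. Each beat is a biphasic
difference of two Gaussian lobes — richer P-QRS-T morphology would add
nothing the pipeline measures. RR jitter is multiplicative Gaussian
(sd 2%), clipped at ±3σ so intervals stay positive and bounded. The two
presets fix the regimes: `scenario1` (fetal amplitude 0.3× maternal,
25 ms width) and `scenario2` (0.9× amplitude, 20 ms vs 45 ms width);
preset noise is 5% of the fetal amplitude. The fetal train is placed
independently of the maternal train, so beats overlap naturally near rate
crossings; overlapped truth beats stay in the truth and count as misses
if the (masked) fetal peak is not recovered — these overlaps are what
keeps synthetic sensitivity below 100% in scenario 1.

What the generator does *not* model: electrode geometry and volume
conduction, electromyographic/uterine-contraction noise, artifacts,
saturation, fetal QRS polarity inversion, or morphology variation.
Passing the synthetic benchmark therefore demonstrates the algorithmic
correctness of the chain under controlled amplitude/width regimes, not
clinical performance on real abdominal recordings.

## Known limitations

* Inverted fetal complexes (S before R) are not detected; negating the
  signal is the user-level workaround.
* The amplitude-distribution logic assumes the window's modes are
  histogram-resolvable; heavily artifacted windows fall back to the
  amplitude feature and may cluster poorly (such windows are skipped with
  a warning if degenerate).
* WFDB support covers format-16 signal files (header gain/baseline
  applied); other storage formats and annotation files are out of scope —
  convert annotations to the plain-text dialect first.
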