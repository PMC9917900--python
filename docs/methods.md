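# Methods

## ΔF/F0 normalization

Single-wavelength calcium dyes report activity as a transient intensity
rise over a resting level that varies per pixel (dye loading, cell
thickness, illumination). We estimate the resting level F0 as the 10th
temporal percentile of each pixel's time series: transients occupy a
minority of frames at physiological rates, so a low quantile is robust to
them, while still tracking slow offsets better than a global minimum.
F0 is floored at 10⁻⁶ of the global intensity maximum to keep dim pixels
finite, and pixels that are exactly zero at every frame map to 0 rather
than to a division artifact. The output (F − F0)/F0 is dimensionless,
invariant under global intensity rescaling, and may legitimately be
negative below baseline; it is carried in the same stack container as raw
video, whose nonnegativity requirement applies to loaded raw data only.

The quantile baseline partly absorbs slow photobleaching (the baseline
follows the pixel's own distribution), but no explicit detrending is
performed; strong bleaching shortens the effective dynamic range of late
transients.

## Locality: spatial bins

"Local" frequency and phase are computed on a rectangular grid of bins,
default 16×16 px — roughly one cell diameter at 10× magnification —
with per-pixel analysis available as bin = 1. Bins are contiguous
rectangles in row-major order; edge bins may be smaller. The bin trace
is the unweighted mean ΔF/F0 of its pixels, which suppresses independent
pixel noise by ≈ the square root of the bin area while preserving timing
(means commute with time).

## Peak detection

The detector follows the classical `findpeaks` semantics:

1. **Candidates** are strict local maxima; a plateau (flat run strictly
   above both flanks) yields one candidate at its first index; trace
   endpoints are never peaks.
2. **Height filter**: candidates below `min_height` (default 0.2 ΔF/F0)
   are dropped.
3. **Prominence filter** (off by default): prominence is the peak height
   minus the higher of the two minima separating it from its nearest
   strictly higher neighbors (or the trace ends).
4. **Separation pruning**: candidates are accepted greedily in order of
   descending height (ties toward the earlier index); a candidate is
   accepted only if it lies ≥ `min_distance` (default 0.1 s, supporting
   rates up to 600 bpm) from every already-accepted peak.

Filter order — height, then prominence, then separation — matches common
`findpeaks` implementations; prominences are always computed on the full
trace, not on the filtered candidate set. The greedy tallest-first rule
is equivalent to choosing, among all separation-feasible candidate
subsets, the one that is lexicographically greatest in priority order;
the test suite verifies this equivalence exhaustively against a
brute-force subset search over every 4-level sequence up to length 12.
The kernels are numba-compiled, which is also what makes that exhaustive
verification (≈ 2 × 10⁷ sequences) affordable.

Separation comparisons use a 10⁻⁹-frame tolerance so that a spacing
exactly equal to `min_distance` is accepted regardless of floating-point
representation of seconds/frames.

## Frequency and phase maps

Frequency uses (n − 1)/(t_last − t_first) over a region's peaks rather
than n/duration: it is exact for any observation window that starts or
ends mid-cycle and is unaffected by silent lead-in frames. Regions with
fewer than two peaks are *inactive* and carry NaN — a silent region is
not a 0 Hz oscillator.

Phase needs a reference; we use the peaks of the whole-field mean trace,
a population-level reference that makes "earlier/later" well defined
without privileging any region. Each regional peak is matched to the
nearest reference beat within ± half the mean reference inter-beat
interval (the largest window for which the nearest match is unique);
unmatched peaks are ignored. The region value is the mean of
(t_reference − t_region), so **positive phase = earlier beating**.
Phase is reported in seconds; a period-fraction view is derivable by
multiplying with the modal frequency. By construction |phase| is bounded
by half the reference period; swapping region and reference negates the
value up to discretization.

## Synchrony classification

The per-well call operationalizes what is usually a visual judgment, so
the thresholds are explicit, conservative and configurable rather than
inferred: modal frequency from a 0.1 Hz histogram (ties resolve to the
lower bin; the reported modal value is the mean of in-bin frequencies),
region synchronous iff |f − f_modal| ≤ 0.10·f_modal and
|φ| ≤ 0.10/f_modal, well synchronous iff ≥ 25% of regions are active and
≥ 80% of active regions are synchronous. With four wells per condition
the per-day percentage of synchronous wells takes values
{0, 25, 50, 75, 100}.

## Motion-based beating rate

The motion signal is the mean absolute frame difference, normalized to
its own 95th percentile (frame 0 is 0). Because tissue moves during both
contraction and relaxation, the signal peaks twice per mechanical cycle;
the rate estimator therefore halves the peak-train frequency in its
default two-peaks-per-cycle mode (calcium traces, which peak once per
beat, use one-peak-per-cycle). Peak detection on motion signals defaults
to a prominence criterion (≥ 0.25 of the normalized scale) instead of an
absolute height floor: the frame-difference signal of a noisy video rides
on a pedestal (the mean |ΔI| of sensor noise), and prominence measures
height above that pedestal.

## Quantification formulas

Troponin-T score: positivity by Otsu's threshold on the marker channel
(deterministic, standard for bimodal fluorescence; an explicit threshold
can be passed, and is required for degenerate single-level images), raw
percentage of positive pixels, normalized by the seeded fraction of
differentiation-competent cells (default 0.30 for a 30:70
myoblast:fibroblast co-culture). Normalized scores above 100% — possible
when the competent population outgrows its seeding fraction — are
reported as computed and flagged, never clipped, because the
normalization assumes equal basal growth of both populations and a
silent clip would hide violations of that assumption.

DMA moduli: E′ = (σ₀/ε₀)·cos δ and E″ = (σ₀/ε₀)·sin δ with σ₀ the stress
amplitude (kPa), ε₀ the strain amplitude and δ ∈ [0, π/2] the
stress–strain phase angle. The quotient σ₀/ε₀ (not the product) is the
reading consistent with modulus units and with the Young's-modulus
identity E = √(E′² + E″²) = σ₀/ε₀, which holds exactly and independently
of δ.

## Synthetic monolayer generator

Cells tile the frame as `cell_size` squares (default 16 px); square
tiling rather than Voronoi keeps the truth bookkeeping exact. Each
synchronized cell fires at k·P − φ(cell) with P the common period, so a
positive φ means earlier firing, matching the analysis sign convention.
The transient waveform is amplitude·(1 − e^(−t/τ_rise))·e^(−t/τ_decay),
rescaled to peak at `amplitude`; defaults τ_rise 30 ms, τ_decay 250 ms,
amplitude 1.0 ΔF/F0 are a plausible fast-dye transient scale. Its
time-to-peak is τ_rise·ln(1 + τ_decay/τ_rise). A `desync_fraction` of
cells ignores the common rhythm and fires at independent rates drawn
uniformly from 0.5–3 Hz (the spread of intrinsic pacemaker frequencies
in primary cultures) with random phase. Pixel intensity is
baseline·(1 + activity), optionally multiplied by e^(−t/bleach_tau),
blurred with a Gaussian PSF (default σ = 1 px) and corrupted with
additive Gaussian noise of SD = noise_sd × dynamic range (default 0.05),
clipped at zero. One RNG stream (a mandatory seed) drives all draws;
identical parameters give bit-identical output.

The default video is 256×256 px, 20 fps, 30 s: ≥ 38 beats at the slowest
emulated condition (77 bpm) while a single simulation plus analysis
stays in the seconds range on one CPU.

The motion video renders each cell as an anti-aliased disc at the cell
centroid whose radius follows a *harmonic* contraction cycle, maximally
contracted at the cell's beat times. Two deliberate idealizations: the
soft 1 px disc edge converts sub-pixel radius changes into smooth
intensity changes (a hard-thresholded disc produces spurious
frame-difference spikes at discrete pixel-ring crossings), and the
harmonic waveform — rather than a twitch with diastolic rest — keeps the
two frame-difference bursts per cycle resolvable at ordinary frame
rates, since a twitch's contraction and relaxation strokes merge at
20 fps. Real cardiomyocyte motion has asymmetric twitch kinetics and a
diastolic interval; rate estimates on real brightfield data should be
sanity-checked in one-peak-per-cycle mode as well.

What the generator does *not* emulate: electrophysiological coupling
(phase structure is imposed, not emergent), wave propagation or re-entry,
cell shape heterogeneity, focus drift, and shot-noise statistics
(noise is additive Gaussian, not Poisson). Passing recovery tests
therefore demonstrates correctness of the measurement chain on videos
with known timing structure, not robustness to every optical artifact of
real microscopy.

## Problem sizes in the test and acceptance runs

Rate-recovery runs use the full default video (256², 600 frames) with 10
seeds per rate and report the median modal rate; synchrony
discrimination and phase-gradient recovery use 96² px / 300 frames (36
regions), which keeps the whole suite within a few minutes while leaving
≥ 19 beats per trace at the slowest rates tested. The exhaustive
peak-detector verification covers all 4-level sequences of lengths 3–12
for representative filter settings, plus the full filter grid on shorter
sequences against a pure-Python oracle.

## Known limitations

- Frequency estimation assumes approximately stationary rates within a
  recording; rate drift biases (n − 1)/span toward the mean rate.
- The phase reference collapses for wells with two equally sized
  antiphase populations (reference beats may interleave); phase values
  remain bounded but their interpretation degrades — the synchrony call
  still correctly rejects such wells.
- AVI input is routed through imageio and requires an ffmpeg/pyav
  backend at runtime; multi-page TIFF is the primary, always-available
  path.
- No motion correction or registration: drifting fields blur bins and
  bias phase; recordings are assumed mechanically stable at the bin
  scale.
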