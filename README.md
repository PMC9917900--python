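# cardiosync

Quantitative beating analysis for cardiomyocyte cultures from
calcium-imaging and motion videos.

When primary cardiomyocytes are cultured on or inside a hydrogel, the
questions a tissue-engineering lab asks are functional: how fast does the
culture beat, do all regions of a well beat at the same rate and in phase,
and how do these properties evolve over days in culture on different
matrices? `cardiosync` answers them from time-lapse recordings of a
calcium-sensitive dye (e.g. Fluo-4) and from plain brightfield motion
videos, and adds the two scalar assays that routinely accompany such
studies: an immunofluorescence differentiation score and dynamic
mechanical analysis moduli.

## What it computes

**Calcium pipeline.** A raw stack *F(t, x, y)* is normalized per pixel to
ΔF/F₀ with F₀ the 10th temporal percentile of that pixel. The field is
partitioned into bins (default 16×16 px ≈ one cell at 10×), and each
bin's mean trace is scanned for transient peaks — strict local maxima
filtered by minimum height, minimum separation and (optionally) minimum
topographic prominence, with tallest-first greedy separation pruning.
Per region:

- **beating frequency**  f = (n − 1)/(t_last − t_first)  for n ≥ 2 peaks
  (Hz, with a bpm view = 60f);
- **phase lag**  φ = mean(t_ref − t_region) over peaks matched to the
  nearest whole-field reference beat within ± half the mean reference
  inter-beat interval. **Positive φ = the region beats earlier** than the
  population, negative = retarded.

**Synchrony.** A well is synchronous when ≥ 80% of its active regions lie
within 10% of the well's modal frequency *and* within 10% of the modal
period in |phase| (thresholds configurable). Per condition and day the
percentage of synchronous wells is tabulated.

**Motion rate.** Frame-difference energy (mean |F(t) − F(t−1)|) peaks on
both the contraction and the relaxation stroke; the beating rate is
60·(n − 1)/span of its peaks, halved in two-peaks-per-cycle mode.

**Quantification formulas.**
Troponin-T differentiation score: raw % = marker-positive area / total
area (Otsu threshold by default), normalized by the seeded fraction of
differentiation-competent cells (default 0.30).
DMA moduli: E′ = (σ₀/ε₀)·cos δ, E″ = (σ₀/ε₀)·sin δ,
E = √(E′² + E″²) = σ₀/ε₀.

**Synthetic data.** `cardiosync.synthetic_data` simulates a beating
monolayer (square cells, configurable rate, phase field, desynchronized
subpopulations, photobleaching, PSF blur, sensor noise) together with its
exact ground truth, so the whole pipeline is testable without any
recording.

## Worked example

```bash
cardiosync simulate --rate-bpm 206 --size 256 --fps 20 --duration 30 \
    --seed 42 --out sim.tif --truth truth.json
cardiosync maps sim.tif --fps 20 --out maps/
```

prints

```
wrote calcium video sim.tif
wrote ground truth truth.json
well synchronous: True (sync fraction 1.00, modal 206.1 bpm)
wrote maps to maps
```

The simulated culture beats at 206 bpm (the fastest of the three
conditions the package's acceptance run emulates); the pipeline's modal
rate of 206.1 bpm recovers it to 0.05%, every one of the 256 regions
agrees with the modal frequency and phase, so the well is classified
synchronous. `maps/maps.csv` holds per-region frequency (Hz and bpm),
signed phase (s) and peak counts; `frequency.png` / `phase.png` are
rendered maps (diverging colormap centered at 0 for phase).

The same in Python:

```python
from cardiosync import SimParams, simulate_monolayer, analyze_calcium_video

calcium, motion, truth = simulate_monolayer(SimParams(rate_bpm=206, seed=42))
res = analyze_calcium_video(calcium)
print(res.report.well_synchronous, res.frequency.values_bpm[:3])
# True [206.06060606 206.06060606 206.06060606]
```

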