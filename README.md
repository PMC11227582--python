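# striakit

Analysis toolkit for studies of striatal cholinergic interneurons (ChIs) —
neurons that co-release acetylcholine (ACh) and glutamate because their
synaptic vesicles carry both the vesicular ACh transporter (VAChT) and the
atypical vesicular glutamate transporter VGLUT3. Experiments probing this
system typically combine four bespoke computations, and `striakit`
implements each as a tested, reusable pipeline with a seeded synthetic-data
generator for ground-truth validation:

1. **Fiber photometry** (`striakit.photometry`) — processing of two-channel
   recordings from a fluorescent ACh sensor (465 nm signal, 405 nm
   isosbestic control) into z-scored ΔF/F, and detection of spontaneous ACh
   transients with a robust median-absolute-deviation (MAD) threshold rule.
2. **Spot co-localization** (`striakit.colocalization`) — nearest-neighbor
   distances (NND) between two-color STED spots and classification of
   vesicles as co-expressing both transporters at a 95 nm NND threshold.
3. **Vesicular uptake synergy** (`striakit.uptake`) — group summaries and
   percent-change arithmetic for radiolabeled uptake assays, including the
   glutamate-driven enhancement of vesicular ACh accumulation ("vesicular
   synergy") and a transporter's share of total uptake.
4. **Addiction-like criteria** (`striakit.cohort`) — the 75th-percentile
   2-of-3 classification of operant behavioral scores (persistence,
   motivation, compulsivity), plus carrier/allele-frequency arithmetic and
   Fisher's exact test for human cohort counts.

## Methods at a glance

**Photometry.** Each channel is mean-bin downsampled (default 120 Hz),
autofluorescence-corrected, detrended by a least-squares exponential fit
`a·e^(−t/τ) + c` (restoring the channel mean as offset), and converted to
ΔF/F = (F − F₀)/F₀ with F₀ the fitted asymptote plus the restored offset.
The control ΔF/F is subtracted from the signal ΔF/F and the result z-scored.
Events: with residual `r = z − rollmed₁₀ₛ(z)` and unscaled
`MAD₁ = median|r − median(r)|`, samples with `r > 2·MAD₁` are set aside,
and strict local maxima of `z` exceeding `median(z_filtered) + 3·MAD₂` are
events (0.5 s minimum separation, larger peak wins). Summaries: mean
amplitude (z), frequency (events/min), inter-event intervals compared by
two-sample Kolmogorov–Smirnov test.

**Co-localization.** For each channel-A spot, the Euclidean NND to channel
B (directional, A→B, via a k-d tree); spots with NND ≤ 95 nm count as
co-expressing. Group fractions are compared by Pearson χ² on the 2×2 table,
full NND distributions by KS. Under complete spatial randomness the chance
fraction is `1 − exp(−ρ·π·r²)` for B-spot density ρ.

**Uptake.** Per (genotype × condition) cell: mean, SEM = sd/√n, n. Synergy
= `100·(stimulated − basal)/basal`; transporter contribution =
`(total − residual, 100·(total − residual)/total)` from wild-type and
knockout means. Rounding (nearest / floor / none) is always an explicit
parameter.

**Behavior.** Criterion thresholds are the empirical (linear-interpolation)
75th percentiles of the wild-type control scores; an animal strictly above
threshold on ≥ 2 of 3 criteria is "addicted". A Gaussian-quantile mode
(mean + 0.6745·sd) is available behind a flag.

## Worked example

Simulate a two-color spot field (200 channel-A spots, 40% with a true
channel-B partner displaced by Rayleigh(σ = 40 nm), 20 unpaired B spots in a
10 × 10 µm field) and classify co-expression at 95 nm:

```bash
$ striakit sim --kind spots --seed 7 --out-dir demo/sim
wrote spots data to demo/sim
$ striakit coloc --spots demo/sim/spots.tsv --out-dir demo/coloc
79/200 spots co-expressing (39.5%)
```

79 of 200 spots have a channel-B neighbor within 95 nm — the classifier
recovers the simulated 40% co-expression fraction (paired spots occasionally
land beyond 95 nm, chance encounters add a compensating ~2%). The same
library calls are available in Python:

```python
from striakit import colocalization, simulate

field = simulate.simulate_spot_field(simulate.SpotFieldSimConfig(seed=7))
profile = colocalization.nearest_neighbor_distances(field)
result = colocalization.classify_coexpression(profile, threshold_nm=95.0)
print(result.n_below, result.fraction_below)   # 79 0.395
```

Uptake synergy on simulated replicate tables (defaults reproduce a
wild-type vs mutant ACh-uptake experiment, basal vs 1 mM glutamate):

```bash
$ striakit sim --kind uptake --seed 7 --out-dir demo/sim
$ striakit uptake --table demo/sim/uptake.csv --out-dir demo/upt --rounding nearest
summarized 4 cells (2 synergy estimates)
```

The summary JSON reports, for this seed, +99% synergy in wild type
(12.1 → 24.2 pmol·mg⁻¹·10 min⁻¹) versus +41% in the mutant (11.2 → 15.7):
glutamate roughly doubles vesicular ACh uptake when the transporter is
intact, and the blunted mutant synergy is visible in a single simulated
experiment.

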