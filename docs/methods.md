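# Methods

This note records the models behind `nmjkit`'s generators and estimators,
the defaults that matter, and the limits of what the synthetic-data tests
can show about real recordings and micrographs.

## 1. Electrophysiology generator (`ephys_sim`)

A recording is a membrane-potential time series at 20 kHz (default;
anything ≥ 10 kHz resolves the ≤ 1.5 ms rise-time criterion) composed of:

- **Resting membrane potential (RMP).** A per-minute Gaussian random walk
  (default mean −72 mV, step SD 1 mV/min), linearly interpolated, and, for
  healthy presets, bounded below −55 mV. A `depolarized_fiber` preset
  starts at −52 mV with a 6 mV/min unbounded walk to exercise the
  rejection rule (recordings more positive than −50 mV at any time are
  rejected).
- **Spontaneous mEPPs.** A homogeneous Poisson process at the group rate.
  Amplitudes at the −70 mV reference are log-normal with the group mean
  and CV 0.30 (right-skewed positive support, the usual shape of quantal
  amplitude data; only means ± SEM are published, so the CV is a design
  assumption). The amplitude actually inserted into the trace is scaled
  by |RMP(t)|/70, so the standard correction `A·70/|RMP|` recovers the
  reference value exactly.
- **Evoked EPPs.** Placed at the protocol's stimulus times (3 stimuli at
  0.1 Hz, or 2400 at 20 Hz). Per-NMJ level: log-normal, CV 0.12 between
  NMJs plus 0.05 stimulus-to-stimulus — deliberately tighter than the
  published between-NMJ scatter (≈28%), so that 50-NMJ recovery runs
  resolve the group means; consequences for realism are noted in §6.
- **Waveform.** Difference of exponentials, peak-normalized; the fast
  time constant is solved numerically so the 0–100% (onset-to-peak) rise
  time is exact. Defaults: rise 0.8 ms, decay 3 ms (assumptions; the
  source protocol publishes only the ≤ 1.5 ms criterion).
- **Noise.** White Gaussian, SD 0.1 mV (typical sharp-electrode baseline).

Each component (RMP, mEPPs, EPPs, noise) draws from its own seeded
substream. This keeps recordings with a shared seed *paired* across
scenarios: changing one group's mEPP rate does not shift the other
components' draws. The paired design is what the 16-week relative-effect
recovery uses (§5).

**Group presets.** `presets/ephys_scenarios.json` holds one entry per age
× genotype. Published group means carry `printed: true`; the remaining
values are interpolations along the published age trajectories and are
flagged `printed: false`. The 16-week SOD1 entry stores the published
*relative* effects instead of absolute means: the builder derives its
evoked amplitude by inverting the Martin formula so that the generator's
quantal-content ratio against same-age wildtype is exactly 1 − 0.277, and
its mEPP rate as wildtype × (1 − 0.437).

**Train model.** Per pulse, `Q_i = round(p·N_i)` quanta are released and
the pool recovers a fraction `r` of its deficit before the next pulse:
`N_{i+1} = (1−p)N_i + r(N_0 − (1−p)N_i)`. The steady state is
`N* = rN_0/(p + r − pr)`. `p = 0.12`; `N_0` is sized so `p·N_0` matches
the group's single-shock quantal content; `r` is set so the late plateau
is ≈ 0.70 of the first EPP in healthy groups and ≈ 0.35 in SOD1 groups
from 12 weeks (the published impairment is a roughly halved ability to
maintain amplitude). The pool parameters are model scaffolding, not
published quantities. With small pools (young NMJs, `Q₁` ≈ 9) the
`round()` quantization makes the realized plateau deviate from `N*/N_0`
by up to ~10%; the closed form is exact in the large-pool limit.

## 2. Event detection and measurement (`ephys_analysis`)

1. Subtract a 0.5 s boxcar baseline (separates ms-scale synaptic events
   from minute-scale drift).
2. Matched-filter the residual with the unit-norm synaptic template;
   candidate onsets are peaks above 3× the robust (MAD-based) SD of the
   filter output, minimum separation 3 ms (overlapping events merge into
   the larger candidate).
3. Re-estimate each candidate by least squares — amplitude and a local
   baseline offset, template shift scanned ±0.4 ms — then subtract the
   fitted events from the trace, recompute the boxcar baseline, and fit
   once more. The second pass removes the ~0.5% negative bias caused by
   event area leaking into the baseline; the residual amplitude bias of
   the full chain is below 0.3%.
4. Discard fitted candidates below 0.2 mV. This physical floor is what
   keeps white-noise excursions above the 3σ detection threshold (which
   would otherwise inflate mEPP frequency by tens of percent) out of the
   event table; genuine quantal events in this preparation are ≥ ~0.5 mV.
5. Apply the inclusion rules: local RMP above −50 mV ⇒ excluded
   (`rmp_above_-50mV`); evoked rise time > 1.5 ms ⇒ excluded. Events with
   a neighbour within 5 ms are flagged non-isolated: they count toward
   frequency but not amplitude summaries (summed overlaps bias the mean
   upward; with Poisson timing the exclusion is unbiased).

Evoked EPPs are measured stimulus-locked: baseline = mean of the 5 ms
pre-stimulus window, peak within 12 ms, onset = last 5%-of-amplitude
crossing. Quantal content uses the −70 mV-corrected means with `V_m = 70`
(keeping QC independent of the fiber's RMP); `use_corrected_for_qc=False`
switches to raw means with the measured RMP. QC is computed per NMJ and
averaged, matching the per-NMJ bookkeeping of group tables; because the
Martin correction is convex in `E`, group-mean QC carries a small (< 1%)
Jensen inflation relative to plugging group means into the formula.

## 3. Micrograph generator (`image_sim`)

512 × 512 px at 0.16 µm/px (a 6.45 µm-pixel camera behind a 40×
objective). The pretzel is a correlated random walk (0.5 µm steps, weak
pull toward an annulus, ~5 branches) dilated to a 2.5 µm ribbon; typical
AChR areas come out at 150–350 µm². Intensities, on the 8-bit scale
(arbitrary units — there is no absolute fluorescence calibration):

- background 15 ± 4 (well below the 40-gray histogram cutoff);
- bright ribbon: spatially smooth Gaussian band 185 ± 15 — a single tall
  histogram peak;
- **dim (reduced-expression) regions**: contiguous sub-regions grown to
  exactly `round(dim_fraction · AChR area)` pixels, painted with a
  spatially smooth field whose marginal is uniform over gray 32–150. The
  dim label therefore fills the broad shallow region between the
  background cutoff and the bright peak rather than forming a second
  mode — the shape the intensity-bimodality procedure (§4) presumes. The
  band deliberately straddles the cutoff: a gap above 40 would create an
  empty histogram stretch in which the valley search bottoms out at the
  cutoff and reads a zero dim fraction. The cost is that ~2–4% of dim
  pixels fall below the cutoff after noise and are excluded from both
  numerator and denominator.
- **floccular (granular) regions**: discrete round holes (radius
  0.25–0.45 µm) punched to background level at ~40% coverage of the
  granular region. Discrete disks below the continuum-percolation
  threshold stay compact, which is what the hole-based detector keys on.
- **extrajunctional satellites**: 1–3 disks of radius 0.3–0.7 µm placed
  2–10 µm beyond the endplate at 40–60% of the bright intensity.

Per-image floccular category (none / small / large → fractions 0 / 0.25
/ 0.70) and satellite presence are sampled from per-group incidence
probabilities following the published trajectories: wildtype never
receives the large category, symptomatic SOD1 draws it at 0.22; satellite
incidence is 0.10 everywhere. Fixing `floccular_fraction` or
`n_extrajunctional` on the scenario overrides the sampling. Ground-truth
masks (AChR, endplate, dim, floccular, satellites) are returned with
every image; the dim-mask bookkeeping is exact up to rounding.

## 4. Morphometry (`morphometry`)

**Segmentation.** 8-bit conversion (pass-through for 8-bit input; linear
min–max rescale for deeper images), 3 × 3 mean smoothing, Huang–Wang
fuzzy-entropy threshold. The threshold is computed on the minimal
rectangle enclosing the label, not the full field: with ~98% background
the fuzzy-entropy objective is dominated by the background term and the
argmin wanders (sometimes splitting inside the label or the background);
restricting to the NMJ neighbourhood mirrors the manual region selection
of the semi-automated workflow and is stable. Specks below 0.5 µm² are
removed; the *endplate* is the hole-filled closing (disk radius = 1/10 of
the footprint's Feret diameter) of the largest receptor structure;
receptor components inside it are the AChR clusters (8-connectivity),
components outside are candidate satellites.

**Variables.** Areas are pixel counts × (pixel size)²; perimeters use the
Freeman-weighted boundary length; the endplate diameter is the maximum
Feret diameter measured across pixel corners (a w × w square reads
w·√2). Compactness is emitted as printed, `(a/d)·100` (≥ 100 by
construction, endplate over AChR); `compactness_achr_over_endplate`
carries the conventional inverse. Derived identities `g = d/f`,
`h = a − d`, `j = 1 − 1/f` are computed exactly from `(a, d, f)`.

**Fractal dimension.** Boxes of 1, 2, 4, 8, 16, 32, 64 px tiled from the
image origin; a box scores if it contains a perimeter pixel; the
dimension is the least-squares slope of log(hits) vs log(1/s). Scales
with fewer than 10 occupied boxes are dropped: the tiling remainder
(E[N] ≈ L/s + O(1)) dominates there and flattens the slope (a 400-px
straight line would otherwise measure ≈ 0.95 instead of ≈ 0.99). A
multi-offset average is available behind `FractalConfig.multi_offset`.
Pixelated smooth outlines measure slightly *below* 1 (the 1→2 px step
counts staircase pixels); synthetic endplate outlines come out at
0.91–0.99, and tests treat the theoretical lower bound of 1 with a 0.1
fitting tolerance. The upper bound of 2 is structural (quadrupling boxes
per halving).

**Intensity bimodality.** Within the ROI (auto: bounding box of the
label): 8-bit conversion, 3 × 3 *median* smoothing (removes isolated
extremes without manufacturing intermediate gray levels at ribbon edges —
a mean filter inflates the dim count by ~8 points), 256-bin histogram,
5-bin moving-average smoothing, bins < 40 excluded as background. The
AChR peak is the global maximum at ≥ 40; the valley is the lowest
smoothed count between 40 and the peak (ties → lowest gray level). Both
readings of "ratio of the minimum to the peak maximum" are emitted —
count ratio (`valley_peak_ratio`) and gray-level ratio — and the dim-area
fraction is the pixel share of [40, valley] among pixels ≥ 40. The
estimator presumes the bright mode dominates the histogram; on this
generator that holds for dim fractions up to ~0.7, and the
valley/peak-ratio monotonicity test covers 0.2–0.6. Heavily granular
images read a few points low (punched holes remove label pixels).

**Disruption.** Floccular score: dark pixels (< 25, unsmoothed image)
inside the filled ribbon, grouped 8-connected; components are holes if
they are compact (contain a fully dark cross-shaped core — thin enclosed
background slivers along ribbon junctions are not) and no larger than
20 µm² (larger enclosed regions are genuine pretzel openings). The
granular area is the 4-px neighbourhood of the holes within the ribbon;
its fraction maps to none (< 0.15 — the category requires an *obvious*
granular area), lt50 (< 0.5), gt50. On labelled generator output the
three-way accuracy is ≈ 95%. Satellites: receptor components outside the
endplate, smaller than 30% of the main AChR area and dimmer than the
ribbon median. En-face status is a metadata flag supplied by the
generator or user, never judged from the image.

## 5. Statistics and study orchestration

The experimental unit is the NMJ; muscles are carried as nesting counts
but not modeled (fixed-effects ANOVA, as is common for endplate data).
Electrophysiological measures: two-way ANOVA (age × genotype, statsmodels
OLS, type-II) with per-age t post-tests, Bonferroni family = number of
ages within a measure. Morphometric measures: Ansari–Bradley dispersion
test then Mann–Whitney U per age (medians ± IQR), plus a two-sided
variance-ratio F test. Groups below n = 3 are flagged underpowered and
get no p-value. A 2,000-replicate null suite checks each test's type-I
error against binomial tolerance at α = 0.05.

`run_study` derives every stage seed as a SHA-256 hash of (master seed,
stage, group, replicate) — reproducible end to end and uncorrelated
across stages. The 16-week relative-effect recovery (QC and frequency
reductions) simulates the two genotypes as a *paired* design, reusing the
same derived seed per NMJ index: shared sampling noise cancels from the
genotype ratio, shrinking its SD from ≈ 3 pp to ≈ 1 pp at 50 NMJs/group.

Recovery runs in the test suite use 150 NMJs per scenario for precision
and assert against the 2-standard-error tolerance of the 50-NMJ design
(SE = per-NMJ SD/√50); report-level runs use the 50-NMJ design itself.

## 6. What the synthetic tests do and do not show

The generators reproduce the *published group structure* — means, relative
effects, incidences, and their age trajectories — with plausible but
assumed shape parameters. Passing recovery tests therefore shows the
estimators are unbiased and correctly calibrated *under this model*:
Poisson event timing, log-normal amplitudes, stationary noise, clean
stimulus artifacts, flat-field micrographs with crisp ribbon borders and
well-separated intensity bands. They do not exercise electrode drift
transients, stimulus artifacts overlapping EPP rise, non-stationary
noise, out-of-focus or curved (non-en-face) NMJs, uneven illumination, or
labeling-efficiency variation between preparations — all of which real
data contain. The deliberately tightened between-NMJ EPP scatter (CV 0.12
vs ≈ 0.28 published) means real-data group comparisons need the published
sample sizes, not the smaller ones that suffice here. Perimeter
complexity does not yet increase with disease in the generator, so the
fractal pipeline is validated only for calibration (smooth references,
upper bound), not for genotype discrimination.
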