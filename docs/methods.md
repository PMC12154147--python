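# Methods

This note records the models behind each analysis arm, the parameters that
matter, what the synthetic generators do and do not emulate, and the
numerical choices made where the procedure left room for interpretation.

## Cavitation dose decomposition

**Model.** Microbubbles driven at *f*<sub>c</sub> = 1.5 MHz emit tones at
integer harmonics during stable (volumetric) oscillation, odd
half-integer ultraharmonics near the stability threshold, and broadband
noise during inertial collapse. Each received pulse is transformed with a
plain (rectangular-window) real FFT; the magnitude spectrum is restricted
to the 3–9 MHz analysis band by a frequency-domain mask — the band limit
is applied to the spectrum, not the waveform, so no filter transient or
phase distortion enters. Windows of total width 20 kHz (±10 kHz) centered
on each tonal frequency define the harmonic and ultraharmonic regions;
every in-band bin outside all windows is the inertial (residual) region.
Per-pulse doses are RMS spectral amplitudes over each region, and the
pulse is the time point of the dose series (pulses arrive at 10 Hz).

**Key decisions.**

* The fundamental (1.5 MHz) and the lowest ultraharmonic (2.25 MHz) fall
  below the 3 MHz band edge; they are excluded from every dose bin, and
  the exclusion is logged, because the band limit is applied first.
* Regions are made disjoint by construction: windows are merged where they
  overlap, with harmonic windows taking precedence over ultraharmonic
  ones. This guarantees the exact energy partition
  E<sub>h</sub> + E<sub>u</sub> + E<sub>resid</sub> = E<sub>band</sub>
  that the test suite asserts to 1e-9 relative.
* Cumulative doses sum the per-pulse RMS amplitudes (primary scale,
  matching an amplitude integral over the sonication); the per-region
  squared-amplitude sums are also accumulated and reported as a secondary
  energy scale, since which of the two the original off-line analysis
  integrated is not documented.
* Normalization divides the cumulative dose by (baseline per-pulse mean ×
  pulse count), i.e. the mean per-pulse dose in units of baseline, which
  makes a bubble-free sonication read ≈ 1. A zero baseline component is
  flagged undefined (NaN), never silently infinite.
* No window function is applied before the FFT by default; a Hann flag
  exists to probe sensitivity. With the synthetic generator's timing every
  tonal frequency falls exactly on a DFT bin, so leakage is nil either
  way.

**Synthetic emissions.** Treatment pulses are sums of fixed-amplitude
sinusoids with per-pulse random phase plus white Gaussian noise
(`broadband_level` = per-sample SD); baseline pulses are noise only.
Pulses are generated independently (inter-pulse dead time carries no
information for a per-pulse analysis) and lazily, so full-length
sonications never sit in memory. Real emissions have amplitude drift,
frequency-dependent transducer sensitivity, and non-white broadband
spectra; none of that is modeled, so passing tests show the decomposition
arithmetic is right, not that the simulator reproduces bubble physics.
Emission amplitudes are free parameters (no absolute scale is available);
defaults fall off with harmonic order. Tests and the acceptance script
shorten pulses to 1 ms (50 000 samples at 50 MHz) — doses scale
predictably with pulse length, and the 1 kHz bin spacing still resolves
the 20 kHz windows — and run the full 1200-pulse schedule (10 Hz × 120 s).

## MRI opening volumetry

**Model.** Gadolinium enhancement marks opened barrier. The threshold is
mean + 2·SD of a contralateral-hemisphere ROI (population SD by default;
a flag switches to n−1 — the difference is negligible at the ROI sizes
used). The mask is strict (`voxel > threshold`), restricted to the brain
mask and the analyzed slice range; per-slice areas (voxel count ×
in-plane 0.1 × 0.1 mm area) are summed, and the sum is reported raw (mm²)
and times the 0.4 mm slice spacing (mm³). Whether the original convention
folded slice thickness into its "volume" is ambiguous, so both numbers
are emitted. No connectivity filtering is applied by default; a
minimum-component-size option exists. Brain masks are required inputs
(skull stripping is out of scope).

**Phantom.** Gaussian background (mean 100, SD 5) inside an ellipsoidal
brain mask (radii 2.1 × 2.1 × 1.8 mm) on a 64 × 64 × 12 grid of
0.1 × 0.1 × 0.4 mm voxels; an ellipsoidal lesion (radii 1.7 × 1.7 ×
1.55 mm, offset 0.3 mm to one side) of additive contrast 50 — a
contrast-to-noise ratio of 10; a box contralateral ROI (~440 voxels) on
the opposite side. The true volume is exact: voxel centers inside the
ellipsoid × voxel volume.

The geometry was chosen once so the procedure's statistical behavior is
visible rather than swamped: a mean+2·SD threshold passes ~2.3% of
background voxels by construction, so recovery accuracy depends on the
ratio of non-lesion brain volume to lesion volume — with this geometry
the systematic surplus is ~2–4%, within the ±5% recovery band — and the
contralateral ROI is large enough (hundreds of voxels) that
threshold-estimation noise does not inflate the false-positive rate.
Note the discretization limit: counting voxel centers on 0.4 mm slices
differs from the analytic ellipsoid volume by a few voxel volumes (≈ 3%
for a 0.5 × 0.5 × 0.8 mm lesion), which is inherent to the acquisition
geometry, not an implementation error. Real data adds coil-profile bias
fields, motion, and partial-volume edges that the phantom does not model.

## Confocal morphometry

**Vessels.** Foreground by threshold (an explicit value, mean+2·SD of a
background ROI, or Otsu, in that order of preference), connected
components, skeletonization, Euclidean distance transform sampled along
the skeleton; diameter = 2 × median radius × pixel size. The raw EDT
radius is used without sub-pixel correction: for tubes thresholded near
half maximum the distance to the nearest background pixel tracks the
half-max contour within half a pixel (measured MAE 0.57 px over 4–20 µm
tubes at 0.2 µm/px). Skeleton ordering uses the principal axis of the
component, adequate for the near-straight segments targeted here;
strongly tortuous vessels would need a graph traversal. Calibers split at
10 µm with the boundary assigned to "large" (the printed classes "<10"
and ">10" leave 10 µm unassigned; one closed side had to be chosen).

**Leakage.** The tracer threshold is deliberately a required input — it
is an acquisition-dependent constant with no universal value, and the
synthetic fixtures document theirs (half the halo amplitude). A vessel is
leaky when its 1-px-dilated mask overlaps the tracer mask in ≥ 5 pixels
(guarding against single-pixel noise; the qualitative definition is bare
"colocalization"). Per-vessel leakage area and summed tracer intensity
are measured in a square ROI of configurable half-width (default 15 µm —
the original ROI size is unspecified) centered on the vessel centroid,
clipped and flagged at image borders. Corrected intensity is
ΣROI − |ROI| · mean(background); normalized optical density divides
ipsilateral by contralateral corrected intensities of matched ROIs.

**Tight junctions.** Junction reporters run along endothelial contacts,
which in a 2-D projection appear as strands along the two long edges of
each vessel; strand paths are therefore the centerline offset outward by
the median radius on each side, and all accounting operates on the max
projection. Intensity is sampled along each path (maximum over a ±1 px
perpendicular probe); sub-threshold runs bounded by signal on both sides
are gaps, with boundaries placed halfway between the bracketing samples.
Runs shorter than 0.4 µm are below the detection floor and discarded; the
gap bins are the closed interval [0.4, 2.5] µm and the open (2.5, ∞) µm,
mirroring the printed ranges, with a strand counting once per bin it has
any gap in. A vessel with no junction signal on either edge is emitted as
a single "absent" record — capillaries genuinely lacking strands are a
real observation class — and absent strands are excluded from bin
denominators. Vessel-subtype labels (arteriole/capillary/venule) are
input annotations, not computed: in the source workflow they come from
expert inspection and smooth-muscle staining.

**Scene generator.** Straight tubes with an error-function cross profile
whose 1 px edge makes FWHM equal the nominal diameter exactly; tracer
halos only around leaky vessels; strands with Gaussian cross profiles and
crisp longitudinal gap edges, so programmed gap lengths transfer to the
image at pixel accuracy. Gaps under 2 px trigger a resolvability warning
in the render metadata. Real images add depth-dependent blur, vessel
curvature and crossings, and autofluorescence, none of which is modeled —
the noiseless fixture demonstrates the measurement chain, not robustness
to histology. Default scene: five vessels (4–16 µm, three leaky), eight
strands with gaps straddling the 2.5 µm cutoff, one vessel with no
strands at all, at 0.2 µm/px on a 512² grid.

## Expression scoring and enrichment

QC keeps a cell iff genes > 200, 1000 < molecules < 50 000 and
mito% < 20, all strict as printed, and every rejection lists all violated
rules. The gene score is −log₁₀(p)·sign(log₂FC) with sign(0) = 0 and
zero p-values clamped to 1e-300 (configurable) with a logged warning.
Ranking sorts descending with lexicographic tie-breaking for determinism.

The enrichment score is the classic weighted Kolmogorov–Smirnov running
sum at weight exponent 1 (the preranked default): hits add
|s|/Σ<sub>hits</sub>|s|, misses subtract 1/(N − N<sub>hits</sub>), ES is
the signed extremum. For any proper subset the walk ends at zero (hit
increments total +1, miss decrements −1); empty or whole-universe
intersections are undefined-flagged. ES is invariant under positive
rescaling of the scores.

Significance uses a gene-label permutation null (random same-size sets
from the ranked universe): nominal p is the same-sign tail fraction, NES
divides ES by the same-sign null mean magnitude, and FDR q uses the
standard NES-ratio estimator (pooled null tail over observed tail,
clipped to [0, 1], monotone within each sign) — the exact estimator
variant in historical GSEA builds is not recoverable, so the standard one
is implemented and named. Defaults: 1000 permutations, set sizes 5–1500
(minimum unstated upstream; 5 chosen and configurable), significance at
q ≤ 0.3. Excluded sets are retained in the output with a reason.

The DE simulator plants true genes with log-uniform p in 1e-12–1e-6 and
Normal(2, 0.5) fold-change magnitudes against Uniform(0,1) null p-values,
so planted sets are unambiguous positive controls; it does not model
count noise, correlation between genes, or p-value/fold-change dependence.

## Problem sizes and runtime

The default verification sizes are: 50 random spectra for the energy
partition; one 1200-pulse harmonic-only sonication (1 ms pulses) plus 20
paired 2 s sonications for broadband monotonicity; 20 phantom seeds each
for MRI recovery and false-positive control; the five-vessel fixture plus
20 random tubes for morphometry; 100 random set/list pairs for the ES
oracle, 1000 permutations for planted-set FDR and 80 null sets × 200
permutations for p-value calibration. The full suite runs in well under a
minute on one CPU apart from the sonication simulations (~15 s).

## Known limitations

* The cavitation arm assumes tonal components sit on DFT bins of the
  pulse; real drifts would leak energy into the residual region and bias
  ICD upward slightly.
* The MRI arm has a built-in positive volume bias equal to the threshold
  tail rate times the non-lesion analyzed volume; reporting both area and
  volume conventions does not remove it.
* Vessel morphometry targets isolated, near-straight vessels; touching or
  crossing vessels merge into one component.
* Gap measurement reads intensity along an expected geometric path; a
  strand that wanders off the vessel edge (e.g. at branch points) would
  register spurious gaps.
* The permutation null permutes gene labels, not phenotypes; correlated
  gene sets on real data make this null anti-conservative, which is one
  reason the downstream significance cut is as lenient as q ≤ 0.3.
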