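# Methods

This note documents the measurement models behind `retquant`, the defaults
and why they were chosen, what the synthetic generators do and do not
emulate, and the numerical choices a maintainer should know about.

## Coordinate and unit conventions

Images are `(row, col)` arrays with row 0 on the scleral (inner-segment)
side; rows increase toward the vitreal side, so the band order top-to-bottom
is IS → ONL → OPL. All reported lengths are micrometres, areas µm²;
`pixel_size_um` converts pixel counts. Masks are boolean pixel sets
(half-open index intervals for band masks).

## Retinal-section phantom (`synthgen.retina`)

The phantom is a 5-channel float stack (nuclei, bipolar marker, OPL synaptic
marker, IS marker, TUNEL) rendered as foreground/background levels (default
200/20), blurred by a Gaussian PSF and corrupted with additive Gaussian
noise. Defaults describe a realistic 40× confocal field of mouse central
retina: 480 × 360 px at 0.5 µm/px (240 × 180 µm), an IS band of 30 µm, ONL
of 100 µm, OPL of 30 µm; nuclei are 5 µm disks at 2 per 100 µm² of ONL;
PSF σ = 0.2 µm; noise σ = 8 on the 0–255 scale. No study-specific noise
statistics exist for these defaults — they are free parameters chosen once
to be representative, and the layer-mask and sprouting recovery criteria are
evaluated at exactly these settings.

Sprouts are polylines in µm coordinates that must start inside the OPL; they
are rasterized without anti-aliasing at a width of 1.5 µm (3 px at the
default calibration), a realistic rod-bipolar dendrite caliber. A thinner
2-px line was rejected because after generator PSF plus the pipeline's own
blur its peak intensity approaches the Otsu cut and the traced skeleton
fragments. Ground truth records the exact Euclidean polyline lengths, the
rasterized sprout ∩ ONL area fraction, the band masks, and the planted
TUNEL count. Every generator is a pure function of its spec (seed included);
identical specs give bit-identical stacks.

## Layer segmentation (`imgquant.layers`)

Band detection operates on column-averaged row profiles (smoothed, σ = 1 px)
thresholded at half-range; the dominant contiguous run is the band. The OPL
comes from the pixelwise union of the synaptic-marker channels, the IS from
its marker channel when present, and the ONL is the full gap between the IS
and OPL bands (validated against the nuclei-dense band). Deriving the ONL
edges from the neighbouring marker bands rather than from the nuclei profile
avoids the half-coverage bias at a nuclear band's edge, where disk-shaped
nuclei thin out over one nucleus radius. Without an IS marker, the ONL's
scleral edge falls back to the nuclei band edge and the IS becomes a
declared default-thickness band (30 µm). Masks are full-width row bands and
disjoint by construction.

## Sprouting quantification (`imgquant.sprouting`)

Pipeline: Gaussian blur (σ = 1 px) → threshold (Otsu by default, fixed value
overridable) → binary mask → per-component skeletonization → path tracing.
Candidates are 8-connected components of the mask inside the ONL. Because
the bright OPL band bleeds a few pixels past the boundary and would bridge
all sprouts into one component, rows within 3 px of the OPL/ONL boundary are
excluded when forming components; a component is "rooted" when it reaches
the first kept row. Each retained skeleton's length is the calibrated
8-connected path length (1 per orthogonal step, √2 per diagonal; diagonal
adjacencies short-circuited by an orthogonal neighbour are not double
counted) plus the excluded 3-px margin the sprout necessarily crossed.

The "beyond one ONL nucleus" rule is operationalized as a minimum
penetration depth, measured from the boundary row to the component's deepest
extent, of one nucleus diameter (default 5 µm). Components smaller than
6 px or with skeletons shorter than 3 px are treated as noise. Density is
retained component area / ONL area × 100; the small area the margin removes
(~2 µm² per sprout) is not added back, a bias far below the 2-percentage-
point recovery band. Measurements are made on maximum-intensity projections.

Known limitations: crossing sprouts merge into one traced component (count
drops, total length is mostly preserved); strongly oblique sprouts incur the
usual ≤ 8% digital-length bias of 8-connected metrics.

## TUNEL and thickness

TUNEL-positive nuclei are components of the thresholded channel inside the
region whose area lies in [0.25, 4] × the nominal nucleus area; merged
overlapping nuclei count once. ONL thickness emulates a grid-overlay
randomization: 12 evenly spaced columns, a seeded generator draws 3 without
replacement, thickness is the column-wise ONL extent × pixel size; absent
columns are resampled with a warning and error out after bounded retries.

## TEM morphometry (`tem`, `synthgen.tem`)

The measurement contract consumes externally produced masks (in the source
studies these are manual tracings): a terminal label image and a binary
mitochondria mask. Areas are pixel counts × pixel size²; mitochondria are
8-connected components within each terminal (8-connectivity matches visual
tracing of closed organelles); occupancy is Σ mitochondrial area / terminal
area, clamped to [0, 1]. Stray mitochondria pixels outside all terminals are
assigned to the nearest terminal within 0.5 µm (warning), otherwise rejected.
Occupancy is computed per section-image, not averaged across sections.

The phantom rasterizes polygonal terminals (truth area by the shoelace
formula) and elliptical mitochondria (truth area πab) at 0.01 µm/px — the
nm-scale pixel pitch of a 4000× micrograph — which keeps rasterization error
well under the 2% recovery band. Rod terminals carry exactly one large
mitochondrion by default, cones several smaller ones, matching wild-type
ultrastructure. Ellipse containment is validated geometrically before
rasterization.

## ERG (`erg`, `synthgen.erg`)

Feature definitions: baseline = mean over [flash − 50 ms, flash); a-wave
amplitude = baseline − minimum over (flash, flash + 80 ms], implicit time =
trough latency from flash; b-wave amplitude = trough-to-peak with the peak
searched from the trough to the record end. The baseline and search windows
are free parameters (the measurement definitions do not fix them) and are
configurable. For degenerate traces without a b-wave peak, a reference
implicit time (e.g. the wild-type b-wave latency at the same intensity)
substitutes for peak search: b = V(flash + reference) − V(trough), floored
at 0. The trough-referenced choice follows the b-wave definition itself
(trough → peak); when a true peak sits exactly at the reference time the two
modes agree identically. Flash intensities are validated against the
0.622–6.955 log photons/µm² stimulus range.

The generator builds waveforms from monotone pieces — half-cosine descent to
the a-trough, half-cosine rise to the b-peak, exponential relaxation
(τ = 80 ms) that never exceeds the peak — so stated amplitudes and latencies
are realized exactly at zero noise; the lobe shapes themselves are a
modelling convenience, not a claim about retinal dynamics. Intensity-response
tables report per-(intensity, group) mean and SEM (sd/√n) and, where two
groups have n ≥ 2, a two-sided unpaired Welch t-test; smaller groups are
flagged untested. Oscillatory-potential filtering is not applied.

## Spectral-count differential expression (`prot`)

**Identification filter.** Peptides: length strictly > 5 aa, no 1+ charge
state, peptide probability strictly > 80%. Proteins: ≥ 2 surviving distinct
peptides, protein probability strictly > 99%, FDR strictly < 1%. Counts per
protein are per-sample sums over surviving peptides. Protein-inference
probabilities and FDR are consumed as table columns, never computed.

**Normalization.** Each sample column is scaled so its total equals the mean
(configurable: median) of the input column totals — a declared stand-in for
Scaffold's undocumented N-SC procedure. Normalization is idempotent, and all
downstream statistics (W, p, FC, pass flags) are invariant to rescaling any
single input sample.

**The triple filter.** Per protein, with group replicate vectors x₁, x₂:

- W = (μ₁ − μ₂)/(δ₁ + δ₂), the signal-to-noise weight; pass if |W| > 0.8.
  The difference-form denominator (δ₁ − δ₂) is also implemented
  (`denominator_mode="as_printed"`) but is ill-defined when the spreads are
  equal and can flip sign; the |0.8| cutoff is only interpretable on the sum
  scale, so `sum` is the default and the mode is logged with every run.
- One-tail Welch t-test with Welch–Satterthwaite df, tail toward the
  observed difference; pass if p < 0.05. Identical groups give p = 0.5;
  zero variance in both groups gives p = 1 (flagged).
- Fold change = mean ratio (group 1 / group 2); pass if FC ≥ T or ≤ 1/T,
  default T = 1.5. A 0.5 pseudocount is added to both means only when either
  falls below 0.5, guaranteeing finiteness with negligible bias at realistic
  counts.

`is_dep` is the conjunction of the three flags. No across-protein multiple-
testing correction is applied to the call (the conjunction is the filter);
a Benjamini–Hochberg column is emitted for transparency.

**Fold-change calibration.** From any user-declared control split (which
samples constitute "controls" is a study decision), per-protein ratios of
split means are restricted to the inner-quartile abundance range; the
threshold is exp of the 99th percentile of |ln ratio| (upper-interpolation
quantile, so the stated coverage holds on the calibrating data by
construction), clamped to [1.5, 2.0]. The ln–ln Pearson R between splits is
reported; on the default synthetic control splits R ≈ 0.87–0.95, since R
reflects the dynamic range of abundances relative to replicate noise, which
is generator-dependent. An R gate is configurable but not enforced. Fewer
than 20 inner-quartile proteins aborts calibration as unstable.

**Set comparison and enrichment.** DEP tables are ranked by ascending
one-tail p (stable, id tie-break) and truncated at top 40; Venn counts are
set cardinalities. Over-representation per GMT gene set is the upper-tail
hypergeometric probability of the observed DEP overlap within the declared
universe, ranked and truncated at top 20; a companion export lists per-set
member fold changes under two conditions for dumbbell-style plots.

## Count generator and simulation conditions

Counts are negative-binomial with mean m and dispersion α (variance
m + αm²); α = 0 is the exact deterministic limit (counts = round(m)) used to
pin expectations in tests. Defaults describe the study design the pipeline
targets: two groups of n = 4, 2000 proteins, baseline mean 50, α = 0.05,
per-protein log-normal abundance spread (σ_ln = 1) so calibration sees a
realistic dynamic range, unit library factors. Planted effects multiply the
first group's mean. Null and power properties are evaluated at exactly these
conditions: across 20 seeds the null DEP fraction stays below the one-tail
level (the conjunction can only shrink the t-pass set), and with FC = 2.5
planted in 5% of proteins sensitivity exceeds 0.8.

## What the phantoms do not emulate

Optics beyond a Gaussian PSF, depth-dependent attenuation and scatter,
autofluorescence, nucleus clustering and chromatin texture, membrane
ultrastructure in TEM, oscillatory potentials and drift in ERG, and
MS-specific artefacts (shared peptides, missing values not at random).
Passing recovery tests on phantoms therefore demonstrates correctness of
the measurement definitions and their implementation — not robustness to
every failure mode of real acquisitions.

## Determinism

Every stochastic component draws from `numpy.random.default_rng` seeded
from the spec or CLI `--seed`; CSV/JSON/TIFF writers avoid timestamps and
use fixed float formatting, so identical configs and seeds reproduce
byte-identical outputs.
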