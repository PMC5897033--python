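# Methods

This note documents the models, estimators and numerical choices behind
`tetraco`, in the order data flows through the package.

## Meiosis simulator (`tetraco.simulate`)

### Model

Crossovers are placed on the four-chromatid bivalent along a genetic axis
spanning the two marker intervals, with the axis measured in Morgans.
Event positions follow a stationary gamma renewal process: inter-event
distances are Gamma(shape = `nu`, mean = 1/rate) with the rate fixed at
**2 events per Morgan per bivalent**, so an interval of genetic size d cM
receives on average 2·d/100 crossovers and each chromatid is recombinant
with probability ≈ d/100 for small d — the definition of map distance.
`nu = 1` reduces to a Poisson process (independent placement, no
interference); larger `nu` regularises inter-crossover spacing, the
standard counting-family description of crossover interference. This is
the minimal model in which the interference-ratio statistic has a known
limit (IR → 1 as `nu` → 1), which is what makes the estimators testable.

Each crossover involves one chromatid of each homolog, chosen uniformly
and independently (**no chromatid interference**). Mechanically, the four
spore products are paths along the four chromatid tracks: a crossover
between tracks i and j reconnects the two paths currently travelling on
those tracks, which then swap tracks for all more distal positions.
Processing events in position order and reading track occupancy at the
marker positions (0, d1, d1 + d2) yields the spore genotypes. Uniform
chromatid choice makes two-crossover intervals resolve into
2-strand : 3-strand : 4-strand events as 1 : 2 : 1, i.e. PD : T : NPD
among double-crossover tetrads — an analytic consequence the test suite
checks by simulation.

Parental phase is all-cis: one homolog carries all three fluorophores.
No obligate-crossover constraint is imposed — the modelled intervals are
short sub-chromosomal windows, not whole chromosomes.

### Stationarity and sampling

A renewal process observed from a fixed origin is stationary only if the
first event is drawn from the equilibrium (forward-recurrence)
distribution. Rather than sampling that distribution (awkward for
non-integer `nu`), the process is started 10 mean inter-event distances
(5 Morgans) before the origin and burnt in; at `nu ≥ 1` the process
relaxes well within that window. Draws are vectorised: each meiosis gets
a fixed-width block of gamma gaps sized to exceed the span with ~10 sigma
to spare, with a rare-path extension loop as a guarantee.

Determinism: one root `numpy` Generator seeded from `SimParams.seed`
drives the whole batch, so identical parameters give bit-identical
output. (Per-meiosis sub-streams would preclude the vectorised draw; the
determinism contract is at the parameter-set level.)

### Tetrad classification oracle

`enumerate_tetrad_patterns` exhaustively generates all 6³ = 216 spore ×
marker matrices with 2:2 segregation and groups them into orbits under
the 24 spore permutations: exactly 12 orbits result. Its type logic is
written against the ditype/tetratype definitions as multiset equalities,
deliberately independent of the recombinant-spore counting used by
`classify_tetrad`, so each validates the other. The A–L letter scheme
(A = (PD,PD), B = (T,PD), C = (PD,T), D–G = the four (T,T) strand
configurations, H–L = the NPD-containing pairs) is a documented
convention centralised in one table; every downstream statistic depends
only on the per-interval types, so relabelling to any published scheme is
a one-table change.

## Genetic statistics (`tetraco.stats`)

**Perkins distance.** D = 100·(t + 6f)/2 cM with t, f the tetratype and
NPD frequencies. Standard error by the delta method under multinomial
(PD, T, NPD) sampling:

    Var(D) = 50² · [ t(1−t) + 36·f(1−f) − 12·t·f ] / n.

Validated two ways: against direct hand evaluation, and by simulation
(200 replicates of n = 2000 at d = 10 cM: mean estimate within 0.5 cM,
empirical spread within 25% of the mean reported SE).

**Z-test.** z = (D_a − D_b)/√(SE_a² + SE_b²), two-sided normal p. Zero
combined SE with equal distances returns (0, 1); with unequal distances
it is an error.

**Interference ratio.** "Crossover present in the conditioning interval"
means type T or NPD there (an NPD implies at least two crossovers).
The chi-square for H0: D1 = D2 is a 2×3 contingency test on the
(PD, T, NPD) counts of the target interval in the two subpopulations,
df = 2, without continuity correction. Distribution equality is a
sufficient (not necessary) condition for D1 = D2; the test is therefore
of the stronger hypothesis, which is the conservative reading. Columns
empty in both subpopulations are dropped (df adjusts); if any expected
cell count falls below 1 the p-value is reported as unavailable rather
than trusted. `ir_avg` is the arithmetic mean of the IRs computed in the
two reciprocal conditioning directions.

Null calibration is checked with 500 simulated no-interference datasets
of **n = 5000** tetrads each: rejection at α = 0.05 lands in 5% ± 2%.
The per-replicate size is 5000 rather than 2000 because at d = 10 cM the
expected NPD cell in the smaller (with-crossover) subpopulation drops
below 1 in roughly an eighth of n = 2000 replicates, so the
expected-count rule would censor the calibration; at n = 5000 every
replicate is testable. No multiple-testing correction is applied
anywhere: results are reported per interval and genotype pair, as is
conventional for these designs.

## Image pipeline (`tetraco.foci`)

Segmentation: triangle-threshold binarisation of the axis channel
(256-bin histogram over the observed range), binary closing with a disk
of radius 2 px, removal of connected components under 50 px (hot-pixel
rejection). Enhancement: white top-hat (image minus its opening) with a
disk of radius 3 px. Counting: local maxima of the enhanced image with
value ≥ threshold and pairwise separation ≥ 3 px, intersected with the
ROI. The default threshold is mean + 5 SD of the enhanced image outside
the ROI. All radii and the threshold are overridable; the defaults are
declared package choices — acquisition protocols fix exposure, not
analysis thresholds. Coordinates are (row, col), 0-based, origin
top-left.

Group comparisons use Fisher's (protected) LSD: pairwise t statistics on
the pooled one-way-ANOVA MSE with N − k df and unadjusted two-sided
p-values — LSD performs no multiplicity correction by construction. The
implementation is the closed-form formula, cross-checked in the tests
against an independently coded oracle and by null calibration (1000
replicates: pairwise type-I error within 3–7% at α = 0.05).

## Synthetic meiocyte images (`tetraco.imagesim`)

The generator emulates a chromosome spread in two 16-bit channels:

* **Axis channel**: 2–4 chromosome-like curves (thick random walks,
  7 px wide) at high contrast over dark background plus iid read noise.
* **Focus channel**: Gaussian spots of width `focus_sigma` (default
  1.5 px, diffraction-limited at typical sampling) at known coordinates;
  planted in-ROI spots are sampled from the slightly eroded true mask
  with ≥ 8 px pairwise spacing, distractors ≥ 10 px outside the mask.
  `snr` is the peak spot amplitude divided by the total noise SD.

The noise budget mirrors a real micrograph rather than a textbook iid
field, in three parts: (i) a smooth autofluorescence background
(Gaussian field, 4 px correlation length, 0.87 of the noise SD) — the
slowly varying structure the top-hat transform exists to remove; (ii)
iid pixel shot/read noise (0.5 of the SD); (iii) dim granular debris
outside the cell region (Poisson-scattered particles at 1–4 noise SD,
density 1/400 px) such as real slides carry in the cytoplasmic
surround. The debris matters: it keeps the background-derived
significance threshold as conservative as it is on real images. On a
perfectly clean synthetic background the mean + 5 SD rule sits directly
on the Gaussian tail of the pixel noise, and single-pixel noise
excursions become borderline detections at batch scale — an artefact of
over-idealised data, not of the pipeline. With the realistic budget,
planted-focus recovery is exact (recall = precision = 1.0 over 100
images at snr 8–12, zero false peaks on 30 pure-noise images) while the
detector still misses ~5% of spots at snr 4, i.e. the recovery property
is discriminating.

What the generator does **not** emulate: overlapping nuclei, focus
blur/z-structure, chromatin-texture variation inside the ROI,
stage-dependent focus densities, bleed-through between channels.
Passing recovery tests therefore demonstrate the pipeline's correctness
on well-spread, in-focus cells, not robustness to every acquisition
pathology.

## Ortholog assignment (`tetraco.orthologs`)

"At least 10% higher" is implemented inclusively (margin ≥ 0.10), and
the runner-up is the best hit from a **different** family, not the
literal second hit overall — the rule exists to disambiguate families
(DMC1 vs RAD51), and a second-best hit from the same family carries no
disambiguating information. Both readings are centralised should the
alternative ever be needed. Margins are scale-free; exact cross-family
ties give margin 0 and leave the query unassigned. The module consumes
pre-computed score tables (plain CSV or 12-column tabular BLAST output,
best HSP per pair); running the search tools is out of scope.

## Problem sizes and runtime

The simulation-based checks use 50,000 tetrads for the interference-
ratio null (SE of the averaged ratio ≈ 0.02), 100,000 for the Poisson
and double-crossover distributional checks, 200 × 2,000 for estimator
recovery, 500 × 5,000 for chi-square calibration, and 50 images of
256 × 256 px per snr level for focus recovery. The full test suite runs
in about half a minute on one CPU; the acceptance script in a few
seconds.

## Known limitations

* Gene conversion is not modelled; non-2:2 tetrads are excluded and
  reported, never interpreted.
* The simulator covers exactly three markers / two adjacent intervals,
  matching the experimental design it emulates.
* The interference chi-square tests distribution equality, which is
  stronger than D1 = D2; a targeted test of the distance contrast would
  require a variance model for conditioned Perkins estimates.
* Stage assignment of meiocytes is accepted as metadata; inferring it
  from synaptonemal-complex signal extent is out of scope.
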