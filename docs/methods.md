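# Methods

This note documents the models and conventions implemented in
`exoscreen`, the defaults and why they were chosen, what the synthetic
generators emulate, and the numerical details that affect results.

## Coordinates and windows

Annotation inputs (TSV/GFF3) use 1-based inclusive coordinates; the
internal representation is 0-based half-open, and bedGraph is consumed
as 0-based half-open per its standard. For a GFF3 `gene` feature the
TSS is the strand-aware 5′ end (start on `+`, end on `−`).

The binding window spans `upstream_bp` to `downstream_bp` around the
TSS (defaults 1,000/1,000), **inclusive of both endpoints and the TSS**
— 2,001 positions at the defaults. Windows are read 5′→3′ in the
gene's orientation: relative position −250 always means 250 bp upstream
regardless of strand, and for `−` strand genes the genomic slice is
reversed. Window extraction is strand-flip equivariant (mirroring a
chromosome and flipping the strand yields an identical profile), which
the tests verify.

Positions falling off a chromosome end are **clipped and excluded from
the mean**, not zero-padded: zero-padding would systematically deflate
the statistic for telomeric genes. The metagene profile applies the
same rule position-wise, so a clipped gene contributes only to the
positions it covers.

Replicate tracks for one TF × condition are averaged base-wise before
windowing. The per-gene statistic averages per-base signal (not
per-read assignments); with integer count tracks the two coincide up to
the chosen normalisation of the input.

## Target calling

A gene is a target when its window mean strictly exceeds
`threshold_factor` (default 2.5) times the background, where the
background is the unweighted mean of the window means over **all**
annotated genes — targets included, with no iterative re-estimation.
The gene universe is whatever the annotation file provides; nothing is
hard-coded. Consequences that are tested as invariants: the target set
is antitone in the threshold factor, invariant under rescaling all
means by a positive constant, and empty when all genes carry the same
positive mean; the mean signal over targets always exceeds
`threshold_factor ×` background when targets exist.

Degenerate input: an all-zero track makes the background 0, and any
positive mean would pass `> 0`. The rule is applied literally but a
`RuntimeWarning` flags the situation.

## Set comparison

Condition comparisons partition two target sets into shared and
exclusive regions; the counts satisfy inclusion–exclusion exactly by
construction. Fold increases are reported rounded half away from zero
at one decimal (the raw ratio is retained). The cross-TF summary
defines: shared-in-stress = intersection of the two stress sets;
shared-in-control likewise; shared-in-both-media = intersection of
those two; stress-exclusive-shared = shared-in-stress minus every gene
either TF targeted in control. These definitions are applied as stated
and are not forced to reconcile with any particular external tally.
Known-target annotation intersects a called set with a user-supplied
table (e.g. a regulation-database export); no live database is queried.

## Motif scanning

Slash consensus notation (each position a base optionally followed by
`/alternative`) is parsed into IUPAC classes; the YRE
5′-T(T/G)A(C/G)T(C/A)A-3′ becomes `TKASTMA`. Matching is positional
set membership; `N` in a sequence never matches a specific pattern
class, while a pattern `N` matches anything. Both-strand scanning
tests each window and its reverse complement, reporting hits in
gene-relative forward coordinates; note the YRE's classes are
reverse-complement symmetric, so each of its forward hits has a mirror
reverse-strand hit at the same offset. Promoters are taken as
−1,000 … −1 relative to the TSS, aligning the scan region with the
upstream arm of the binding window. Gene-level statistics count a gene
once regardless of hit multiplicity.

The PDRE (Pdr1/Pdr3 response element) has no single printed consensus
in the screen this package models; `PDRE_DEFAULT` ships the common
literature core `TCCGCGGA` purely as a configurable placeholder and
should be overridden deliberately.

## GO enrichment

One-sided over-representation only: raw p is the hypergeometric upper
tail P(X ≥ k) (scipy's implementation, computed in log space). Terms
with k = 0 are excluded from the report **and from the correction
family**, matching common term-finder behaviour; this choice changes m
and therefore the adjusted p-values, so it is stated here. The default
correction is Bonferroni — closest to classic term-finder websites —
with BH available; a term is enriched when corrected p < alpha
(default 0.1). Targets outside the universe are dropped with a
warning. The bundled published GO rows are a fixture of printed gene
lists; their term sizes in any map built from them are the list
lengths, not the full genome-wide term sizes printed alongside.

## Growth screens

Calibration is monotone piecewise-linear interpolation through the
supplier's (green value, OD600) table. Values below the curve domain
are clamped to the smallest OD with a warning (plate background);
values above refuse to extrapolate, since the curve's shape outside its
domain is unknown.

Per well, with positive OD and at least 8 time points, a cubic
smoothing spline is fitted to ln OD versus time. The smoothing budget
defaults to m·σ̂² where σ̂ is a robust noise estimate from second
differences of ln OD (1.4826 · median|Δ²y| / √6); this targets the same
residual level a cross-validated smoother aims for, collapses to exact
interpolation on noiseless data, and can be overridden. The derivative
is evaluated on a grid 10× denser than the sampling; μ_max is its
maximum, the minimum generation time is ln 2 / μ_max, and the lag is
the tangent construction standard in growth-curve work: the time where
the tangent at the μ_max point crosses ln od₀, clamped to
[0, last time point], with od₀ the mean of the first three OD
readings. Noiseless-limit properties verified by tests: exact μ on a
clean exponential, time-shift equivariance (lag shifts, generation
time fixed) and OD-scale invariance. Because od₀ averages the first
three readings, a curve growing from t = 0 reports a small positive
lag (≈ half the span of those readings); with a genuine lag phase the
first readings are flat and the construction is unbiased. A fit with
μ_max ≤ 0 (e.g. constant OD) is returned with `fit_ok = False` rather
than raising, and pipeline reports carry such wells explicitly.

Strain comparisons use Welch (unequal-variance) two-sample t-tests on
generation time and lag, requiring ≥ 2 successful replicate fits per
group. The BH family is all strain × metric tests of one screen (one
plate condition), matching per-figure star reporting; stars follow
ns > 0.05 ≥ \* > 0.01 ≥ \*\* > 0.001 ≥ \*\*\* > 0.0001 ≥ \*\*\*\*.

## Synthetic data

The generators produce exactly the formats the analysis consumes, plus
truth tables, and are byte-deterministic under a fixed seed.

**ChIP-exo tracks.** One chromosome, genes every 3,000 bp with
alternating strands. Background counts are i.i.d. Poisson per base
(default mean 5.0, placing non-target window means in the 4–6 range
typical of unstressed control tracks; a gamma–Poisson overdispersion
option exists). Planted targets add a rectangular peak of total mass
`peak_fold ×` the window's expected background mass (default fold 8),
width 100 bp, centred 250 bp upstream of the TSS on the gene's strand
— so the calling threshold has a direct dial and the metagene maximum
falls in the 200–300 bp upstream band. Control tracks are background
only.

**Promoters.** Uniform random sequence is made motif-free by
rescanning and resampling any window matching the pattern on either
strand (bounded attempts; an over-permissive pattern such as all-`N`
raises). One concrete motif instance is then planted per chosen gene
at a known TSS-relative offset.

**GO maps.** Non-enriched terms draw members uniformly from the
universe. Enriched terms draw their target-gene count from a binomial
with success probability `factor × |targets| / |universe|` — i.e. the
term's target fraction is over-represented by the configured factor —
then fill both strata uniformly.

**Growth curves.** OD follows a generalized Baranyi–Roberts model: a
smooth lag adjustment (sharpness ν = 10, so the ramp is short relative
to the exponential phase but still differentiable) followed by
logistic growth from od₀ = 0.1 toward a carrying capacity of 5.0
(typical final OD600 of yeast on ~2% glucose minimal medium). The
log-OD asymptote during exponential phase is exactly
ln od₀ + μ(t − lag), so the tangent lag construction targets the
planted lag by design. A hard od = od₀ switch at the lag was rejected:
the kink is non-differentiable and corrupts any derivative-based
estimator, and real cultures ramp smoothly. The diauxic option runs a
first phase to 40% of capacity, a ~4 h plateau, then a second phase at
0.6 μ — producing the two derivative maxima characteristic of diauxic
curves. Noise is multiplicative lognormal (σ = 0.02 on the log scale);
sampling is every 0.5 h for 96 h, mirroring half-hourly plate reads.
Curves can be emitted as green values through the inverse of a bundled
**test-only** calibration table (`TEST_CALIBRATION`); real screens must
use the instrument supplier's curve.

What the simulators do **not** emulate: read-level sequencing artifacts
(exonuclease footprints, mappability, GC bias), correlated or
heavy-tailed ChIP noise, realistic promoter base composition or motif
clustering, GO term overlap/DAG structure, evaporation or well-edge
effects in plates. Passing recovery tests therefore demonstrates
correctness of the statistics under the stated models, not robustness
to every artifact of real data.

Recovery performance under the default conditions (recomputed by
`scripts/acceptance.py`): target recall 1.0 with zero false positives
at fold 8; median relative error ≈ 2–4% for μ and ≈ 2% for lag across
50 curves with μ ∈ [0.1, 0.5] and lag ∈ [0, 10] h. The residual μ bias
is the od₀/capacity ceiling of the realized log-slope plus a small
smoothing loss.

## Problem sizes

Simulated studies default to 200 genes on a 603 kb chromosome, 20
planted targets, 20-term GO maps over a 200-gene universe, and
four-strain triplicate growth screens — large enough for stable
statistics while keeping the full test suite and the acceptance script
fast on a single CPU.

## Known limitations

- The calling rule uses means only; no variance model or per-gene
  significance is attached to a call.
- Background includes the targets themselves, so heavy planting (or a
  genuinely large regulon) inflates the threshold; the simulators plant
  ~10% of genes to stay in the regime where the rule separates cleanly.
- The GO machinery assumes the input map is already ancestor-closed;
  no DAG propagation is performed.
- Diauxic curves are quantified only through μ_max and lag; the second
  phase is not parametrically fitted.
- The spline smoothing default is a plug-in noise estimate, not full
  cross-validation; pathological sampling (very sparse or bursty) may
  need an explicit `smoothing` override.
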