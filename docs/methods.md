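# Methods

## Scope and model

The package analyses two-colour MeDIP/Input promoter tiling arrays for a
two-group (exposed vs control) replicated design, and integrates the
resulting differential methylation calls with miRNA/gene expression,
predicted miRNA→target interactions, genomic-interval catalogs and qPCR
assays.  Coordinates are 0-based half-open throughout; BED is the on-disk
interval convention and TSV-with-header the internal table dialect.

## Normalization

`quantile_normalize` maps every sample column onto the per-rank mean of the
column order statistics and then centres each column on its median.  Ties
are handled limma-style: a tie group receives the mean of the rank-mean
values over the ranks it occupies.  On continuous log ratios (the designed
input) the operation is exactly idempotent and all columns share one value
multiset; with heavily tied inputs those two properties hold only
approximately, because preserving within-column ties and forcing a common
multiset are incompatible in general.

`linear_smooth` is a fixed-width running mean over probe midpoints
(default 300 bp, configurable), never crossing chromosome boundaries.  The
original vendor tooling chains several smoothing implementations whose
kernels are not published; a windowed mean is the simplest member of that
family and its width is an explicit, documented parameter rather than a
claim of equivalence.

## Peak calling

Each probe receives a one-sided p-value for the hypothesis that the probes
within the centred window (default 750 bp) are shifted upward relative to
the track-wide score distribution.  The test is a Wilcoxon rank-sum of the
window members against the remaining probes: with one global midrank vector
the statistic reduces to a cumulative rank sum per window, so the whole
scan is O(n log n).  The p-value uses the tie-corrected,
continuity-corrected normal approximation (identical to the asymptotic
two-sample Mann–Whitney test); tracks of ≤ 20 probes fall back to the exact
null enumeration.  P-values are clamped into (0, 1] and an empty comparison
set yields p = 1 (no evidence).  Windows advance per probe, not per base.

`find_peaks` emits maximal runs of probes with −log10 p at or above the
cutoff (default 2), split where consecutive qualifying probes are more than
`max_gap_bp` (default 500) apart, discarding runs below `min_probes`
(default 2).  `PeakScore = −log10(mean member p)`, so a PeakScore of 2
corresponds exactly to a mean member p-value of 0.01.

## Differential enrichment (DEP) analysis

`M'` is the difference of per-group replicate means of the normalized log2
ratios, per probe.  Gains are scanned on M' and losses on −M' in separate
passes so hyper- and hypo-methylation keep their identity; swapping the
group labels maps the two sets onto each other exactly (a tested
invariant).

**Boundary refinement.**  Because the window test assigns significance to a
probe whenever its window is shifted, raw qualifying runs overhang the
truly enriched interval by up to half a window per side (plus smoothing
smear).  Left in place, that overhang dilutes the within-peak medians used
by the quality filters and systematically rejects genuine differential
regions.  Each run is therefore trimmed inward from both ends at half
maximum — member probes whose own sign-adjusted M' falls below half the
peak's maximum are dropped from the ends (never from the interior) — and
the `min_probes` requirement is re-checked.  Half-maximum boundaries are
the standard width convention for peak-shaped signals and restore planted
interval recovery from roughly 88% to 98–99% under the default simulation
conditions without affecting the zero-effect calibration.

**Filters.**  A peak is accepted as a DEP when

* (i) at least one group's median log2(MeDIP/Input) over member probes is
  ≥ 0.3 *and* the median M' is positive in the peak's direction; and
* (ii) at least half of the member probes have a coefficient of
  variability ≤ 0.8 in both groups, where CV = replicate sd (ddof 1)
  divided by |replicate mean|.

Probes with |mean| < 1e−8 receive CV = +∞ (the ratio is undefined and such
probes cannot demonstrate replicate consistency); a single-replicate group
has CV defined as 0.  Rejected peaks carry reason codes
(`median_ratio`, `cv`), and criterion (i)'s "at least one group" is taken
literally.  The top-fraction selection (peaks in both the top 20% by
PeakScore and by |PeakDMValue|, ties broken by genomic position) is applied
after (i)/(ii) and selects the regions used for heat-map clustering; it is
a display/prioritisation step, so sensitivity figures are quoted for the
criteria-filtered DEP set.  `PeakDMValue` is defined here as the median
member M' (configurable to the maximum); vendor documentation never
defines it.

The per-sample PeakScore matrix re-runs the probe scan on each sample's own
log2 ratios and scores each selected region per sample; clustering is UPGMA
(Euclidean distance, average linkage, SciPy's deterministic
nearest-neighbour-chain agglomeration).  `cluster_purity` cuts the sample
dendrogram into two clusters and reports the best two-way label agreement.

## Expression and qPCR

Differential expression is a per-feature one-way ANOVA across the two
groups (algebraically the equal-variance t-test for two groups) with a
signed linear fold change: 2^Δ for Δ ≥ 0, −2^−Δ below 1, matching the
negative-reciprocal reporting convention.  The default stringency filter is
|FC| ≥ 1.2 at p ≤ 0.05 with no multiple-testing correction, mirroring
common array practice at this scale; a Benjamini–Hochberg option
(`adjust="bh"`) is available and off by default.  Groups with fewer than
two samples make features untestable rather than raising.

ΔΔCt quantitation averages technical replicates per sample first, forms
ΔCt = target Ct − endogenous-control Ct per sample, ΔΔCt as the difference
of group means, fold change 2^−ΔΔCt, and an unpaired two-sided t-test on
the per-sample ΔCt values.  The fold change is invariant to any per-sample
Ct offset applied to both the target and the control reaction.

## Integration

The inverse-pair filter keeps predicted miRNA→gene interactions whose
confidence label is at least `moderate` (rank order
predicted < low < moderate < high), whose tissue label matches (default
`brain`), whose two members both pass their expression filters, and whose
fold changes have opposite signs; pairs naming unknown features are logged
and skipped.  Promoter concordance counts DE features whose annotated
promoter interval overlaps ≥ 1 accepted DEP by ≥ 1 bp (features without a
promoter annotation are excluded from the denominator and reported).
`map_to_regions` labels features with every catalog region they overlap;
`region_enrichment` draws same-size feature sets from a declared universe
without replacement and reports
p = (1 + #{draws with mapped count ≥ observed}) / (n_perm + 1), which is
super-uniform under the null by construction.  miRNA genomic coordinates
come from an annotation table generated alongside the catalogs (or supplied
by the user), not from a live database query, and CTCF analysis is interval
overlap against a user-supplied BED, not motif scanning.

## Synthetic data generator

The generator emulates the study design rather than any real genome.  Each
promoter occupies its own synthetic chromosome tiled with 50 bp probes
every 100 bp across a window spanning 8.2 kb upstream to 3 kb downstream of
the TSS (11.2 kb, 112 probes).  Defaults: 40 promoters, 3 biological
replicates per group, a planted DMR in 25% of promoters (width 750 bp,
|effect| 1.0 log2, random sign), and iid Gaussian noise (sd 0.3 log2) per
probe and replicate.

Planted DMRs carry a +0.5 log2 enrichment plateau in *both* groups, with
the signed differential effect added on top for the exposed group.  The
plateau reflects that a methylated locus is enriched over input in both
conditions; it is also what makes the CV criterion meaningful — with a
zero-mean baseline in the unmethylated group, CV = sd/|mean| would diverge
and criterion (ii) would reject every true region.

Expression truth is tied to the methylation truth: the gene behind each DMR
promoter is planted as differentially expressed with sign opposite to the
methylation change (|log2 FC| drawn from 0.3–0.65, i.e. 1.23–1.57-fold,
the subtle range typical of these studies), and each such gene is targeted
by 1–3 planted miRNAs with inverse fold changes that appear in the target
table at high confidence, brain tissue.  Decoy pairs — same-direction,
low-confidence, wrong-tissue and null-feature — exercise the filter.  A
quarter of the planted DE miRNAs are placed inside three imprinted-region
stand-ins on distinct chromosomes (named after the murine Sfmbt2,
Snrpn-Ube3a and Dlk1-Dio3 clusters); the catalogs, CTCF point sites and
miRNA loci all derive from the same seeded design, so tiling, expression
and annotation outputs are mutually consistent.  The qPCR simulator plants
a configurable fold change (default 1.45) for one target against an
endogenous control across 6 biological × 3 technical replicates.

What the generator does **not** model: probe sequence/affinity effects and
GC structure, dye bias, spatially correlated noise, pooling of animals
within biological replicates, linked methylation across promoters, and
realistic genome geometry.  Passing tests therefore demonstrate the
correctness and calibration of the algorithms under the stated noise
model — not performance on real arrays, where normalization artefacts and
probe effects dominate.

## Numerical choices and determinism

All randomness flows from one integer seed through
`numpy.random.SeedSequence.spawn`, so every output table is bit-reproducible
for a given configuration; the pipeline report embeds a SHA-256 hash of the
configuration.  Rank-sum p-values are floored at the smallest positive
double; peak qualification uses a 1e−9 tolerance on −log10 p so that
p = 10^−cutoff qualifies despite floating-point log rounding.  Top-fraction
selection takes ⌈f·n⌉ per ranking with genomic-order tie-breaking.
Permutation tests require an explicit seed.

## Problem sizes

Default analyses run on 4,480 probes (40 promoters × 112 probes) — a
deliberate desk-scale stand-in for the ~2.1 M probes of the original array
class; the scan is O(n log n) and scales linearly in memory with probe
count.  The calibration suites use 20 simulation replicates for recovery
and null rates, 2,500 features for ANOVA calibration, and 200 runs × 99
permutations for the enrichment null.

## Known limitations

* The vendor peak caller's exact probe-level test is unpublished; the
  rank-sum design here matches its published parameters and interface but
  is not a bit-level reproduction.
* PeakDMValue and the smoothing kernel are under-specified upstream; both
  are explicit, documented choices here.
* Criterion (ii)'s CV is undefined at zero mean; the +∞ convention makes
  near-zero-mean probes count against replicate consistency.
* The ANOVA assumes equal variances and independence across features; no
  correction for the correlation structure of tiled probes is attempted
  beyond the window-level test itself.
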