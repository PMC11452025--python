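# Methods

`triplocall` calls SNP-array genotypes for triploid (and, by parameter,
diploid or higher-ploidy) individuals from two-channel luminescence
intensities, without prior per-marker cluster positions. This note documents
the model, the algorithmic choices, the defaults, and what the synthetic-data
generator does and does not emulate.

## Signal model and coordinates

Each marker × sample pair has two raw probe intensities, `SA` and `SB`
(arbitrary positive luminescence units). All computation happens in the
transformed plane

```
x = contrast   = log2(SA / SB)
y = sigstren   = (log2(SA) + log2(SB)) / 2
```

Genotype clusters separate along `x`; `y` exposes aberrant clusters (an
unexpectedly weak heterozygote signal). Both coordinates are rounded to three
decimal places once, at transform time, and every downstream statistic uses
the rounded values; this bounds memory and makes runs bit-reproducible across
platforms. Non-positive intensities are rejected at load rather than floored:
a floored zero would fabricate an extreme contrast.

## Per-marker clustering

A marker with ploidy p admits at most p+1 genotypes (allele dosages 0..p).
Asking a mixture model for exactly p+1 components tends to miss low-frequency
genotypes, so each marker is deliberately *over-clustered*: the EM is asked
for `n_clus_init = 2·(p+1)` components (8 for triploids), and clusters that
are too close in contrast to be distinct genotypes are merged afterwards.

**Mixture family.** Components are bivariate Gaussians with free mixing
proportions and a single covariance matrix shared by all components
(a homoscedastic mixture). The shared covariance is a deliberate choice:
with free per-component covariances, the maximum-likelihood solution under
over-clustering often inflates one component to absorb the few members of a
low-frequency genotype plus assorted stragglers; the resulting cluster has a
poisoned contrast spread, is blanked wholesale by QC, and the marker fails
the call-rate filter. With a common covariance such degenerate components are
impossible and the likelihood instead rewards placing a component on the
minor genotype itself. Genotype clouds have similar spread on these axes, so
the assumption is mild; the growth of spread with |contrast| is handled
downstream by the merge rule and the QC spread cap, both of which scale their
allowance with |mean contrast|.

**Initialization and restarts.** Each of `n_init` restarts (default 5) seeds
the component means from k individuals sampled without replacement, the first
uniformly and each subsequent one with probability proportional to its
squared distance from the nearest centre already chosen. Distance weighting
is what lets a restart land a centre on the two-to-five individuals of a rare
genotype, which a uniform draw would almost never hit. The initial covariance
is the diagonal data covariance split k ways; weights start uniform. The
restart with the highest log-likelihood that passes the failure test wins.

**Failure and retries.** A fit fails when EM does not converge within 500
iterations (relative log-likelihood change < 1e-6), when any component ends
with fewer than two assigned individuals, or when the covariance is
near-singular (condition number > 1e8). The covariance is floored at the
variance of the three-decimal rounding noise (0.001²/12 per axis), so a
component holding two nearly coincident individuals is not spuriously
singular. When all restarts fail, the marker is retried with one fewer
component and two fewer restarts (floor 1) — a marker that cannot support the
full component count rarely displays all genotypes, so a cheaper search
suffices — down to a single component; if even that fails, the marker gets
the degenerate one-cluster model with sample moments. Clustering is therefore
total: it never raises on data.

**Merging.** Two clusters with mean contrasts `c1, c2` are "the same
genotype" when

```
|c1 − c2| < dmin · (1 + |(c1 + c2) / 2|),        dmin = 0.28
```

the allowance growing away from zero because within-genotype spread does.
While more than p+1 clusters remain, the globally closest pair (smallest
contrast distance) is merged; within bounds, the closest pair among those
satisfying the criterion is merged until none does. Ties on distance break
toward the pair with smaller absolute mean contrast, then lower index.
A merge sums the two membership-probability columns (row sums of the
probability matrix are invariant) and recomputes mean, spread and weight from
the pooled member points — pooled statistics, not moment combinations,
because the spread feeds QC directly.

**Calibrating dmin.** `calibrate_dmin` re-derives the coefficient for a new
platform: markers are force-fitted with 8 components and every cluster pair
contributes the ratio D/(1+M) (distance over one-plus-mean-contrast). With
known truth (simulator output) the boundary is the midpoint between the
largest same-genotype ratio and the smallest different-genotype ratio; on the
default simulation this lands at 0.28–0.31, recovering the canonical 0.28.
Without labels, a reproducible two-class split of the log ratios approximates
the boundary (log scale, because ratios of same-genotype and increasingly
distant genotype pairs differ multiplicatively); it is biased low by the
heavy tail of within-genotype splits and is documented as approximate — on
data with truth available, prefer the labelled variant.

## Genotype calling

Dosage labels render as strings of `A`s then `B`s (`dosage 2` at ploidy 3 →
`AAB`).

**Single population (default).** Under Hardy–Weinberg, samples from one
population cannot show both homozygotes without the heterozygotes between
them. The cluster with the largest |mean contrast| anchors the homozygote of
its sign (all-A if positive); remaining clusters take consecutively adjacent
dosages toward the other homozygote, ordered by proximity. One cluster is
always a homozygote; two clusters are a homozygote plus its nearest
heterozygote. An exactly symmetric tie between extremes anchors the positive
side (deterministic, measure-zero).

**Shifted-signal correction.** A marker whose whole signal is displaced
sideways can present a heterozygote as the extreme cluster. For exactly three
clusters at ploidy 3, if the extreme cluster (currently labelled homozygous)
holds fewer than half the members of the opposing extreme cluster, every
cluster steps one dosage toward the opposing side. The rationale is again
Hardy–Weinberg: an extreme-cluster count below half the opposing cluster
corresponds to an A-allele frequency below 0.55, at which the missing
B-homozygote would have expected frequency ≥ 0.1 — its absence is then far
more plausibly a shift than a sampling accident. The correction only fires
while the extreme cluster is labelled homozygous, making it idempotent.

**Multiple populations.** With genetically distant samples, two clusters
*can* be the two homozygotes (alternative alleles fixed in different
populations). Reference contrasts per genotype are averaged over markers that
attained all p+1 clusters; every remaining marker's clusters take the
genotype of the nearest reference. When two clusters point at the same
reference, the more extreme keeps it and the other takes the adjacent
genotype toward the centre, cascading outward; a cluster that would have to
move more than one genotype away from its nearest reference marks the marker
as an unresolvable collision, which QC rejects.

## Quality control

Three no-call rules (applied cluster-level first, in the order 3, 1, 2):

1. samples with post-merge membership probability < 0.85 become NA;
2. samples farther than 2.8 cluster-SDs from their cluster's mean contrast
   become NA (under normality ±2.8 SD covers ~99.5% of a clean cluster, so
   this blanks ~0.5%);
3. a cluster whose contrast SD exceeds `0.28·(1 + 0.5·|mean|)` is blanked
   wholesale — the signature of a cluster secretly covering several
   genotypes.

Four marker filters, checked in a fixed order so labels are deterministic:

| filter | threshold | failure label |
|---|---|---|
| call rate | ≥ 0.97 | CallRateBelowThreshold |
| HetSO | > −0.3 | OffTargetVariant |
| FLD | > 3.4 | Others |
| HomRO | ≥ {0.6, 0.3, 0.3, −0.9} for 1–4 genotypes | Others |

FLD is the contrast distance of the two nearest genotypes in units of their
two-sample pooled standard deviation. HetSO is the minimum, over heterozygous
genotypes, of the offset of the heterozygote's mean signal strength from the
line joining the two homozygote centroids evaluated at the heterozygote's
mean contrast (single-homozygote markers use that homozygote's strength as
baseline). HomRO is the minimum over homozygote clusters of mean contrast
signed toward the expected side. The HetSO/HomRO formulas are this package's
definitions (the platform's own are proprietary); the thresholds are the
established defaults. The HomRO table extends beyond four genotype counts by
reusing the maximal-count entry at p+1 genotypes and 0.3 for intermediates —
an extrapolation, flagged as such.

Markers passing all filters are accepted and categorized by the number of
genotypes retaining at least one called sample: 1 → MonoHighResolution,
p+1 → PolyHighResolution, in between → NoMinorHomozygote. The multi-pop
collision flag and an all-NA marker map to Others. Categorization is a
partition: every marker gets exactly one label, and loosening a threshold
never moves a marker from accepted to rejected.

## Synthetic data

The generator works directly in the (contrast, sigstren) plane and inverts
the transform to emit intensities (`SA = 2^(y + x/2)`, `SB = 2^(y − x/2)`),
so loading and transforming its output round-trips exactly up to rounding.
Per marker: a minor-allele frequency uniform on [0.1, 0.5] (A minor with
probability ½), per-sample dosages from Hardy–Weinberg binomial proportions,
contrast centres {−1.5, −0.5, +0.5, +1.5} for dosages 0..3, Gaussian noise
with SD 0.12 in contrast and 0.1 in signal strength around a baseline of 1.0.
Stress options: a per-marker Gaussian contrast shift (`shift_sd`) emulating
displaced markers, and a fraction of off-target markers whose heterozygote
strength is depressed 0.6 below baseline (beyond the −0.3 HetSO bound). The
defaults (no shift, no off-target) are the clean study conditions used by the
acceptance checks.

What the generator does **not** emulate: cross-hybridization, batch and
plate effects, intensity-dependent variance, contrast spread growing with
|contrast| (the clean-data spread is constant by construction), genotyping
chemistry failures, or linkage between markers. Passing tests therefore
demonstrate the algorithm's behaviour under its own model assumptions plus
the modelled stressors, not performance on any real cohort.

## Numerical and engineering choices

- **Determinism.** Every marker's EM is seeded from (run seed, marker index)
  via a seed sequence, so results are bit-identical regardless of the number
  of worker processes or execution order.
- **Phase separation.** Clustering serializes per-marker models (cluster
  statistics, per-sample coordinates, assignments, membership probabilities)
  as JSON lines; genotyping and QC consume only that file, so thresholds can
  be re-tuned without re-running EM.
- **Degenerate inputs.** Markers with ≤ 2 samples fall through the retry
  ladder to the one-cluster fallback; a singleton cluster gets SD 0 (its
  members are never blanked by the distance rule); a pooled SD of exactly 0
  makes FLD infinite (perfectly separated).
- **Problem sizes.** The heavier checks run 1,000 markers × 200 samples for
  end-to-end recovery and 300 markers × 400 samples for the
  initialization-effect comparison; the acceptance script uses 300 × 200.
  These sizes give stable rates (binomial SE on the accepted fraction
  ≈ 0.7 pp at n = 1000) while keeping a laptop-scale runtime.

## Known limitations

- The EM convergence tolerance and the shared-covariance family make results
  approximate relative to other mixture engines; equivalence with any
  particular implementation is structural, not bitwise.
- The shifted-signal correction is implemented for ploidy 3 only; other
  ploidies use the uncorrected ordinal rule.
- The unlabelled dmin calibration is a heuristic split and tends to sit below
  the labelled boundary; treat its output as a starting point.
- HomRO thresholds beyond four genotype clusters are an extrapolation.
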