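# triplocall

Genotype calling for **triploid** (and general polyploid or diploid) SNP
arrays from two-channel luminescence signals.

Triploids are widely used in aquaculture and horticulture because induced
sterility improves growth and product quality and protects wild populations
from escapees. Using their genetic information, however, requires calling
allele *dosage* at each SNP — a triploid marker has four possible genotypes
(BBB, ABB, AAB, AAA), one more than the diploid callers shipped with array
platforms can handle. `triplocall` fills that gap for anyone working with
raw A/B probe intensities: breeders recovering pedigrees of triploid
offspring, and researchers genotyping any autopolyploid cohort.

## Method

Raw intensities `SA`, `SB` are transformed to the plane where genotype
clusters live:

```
x = contrast   = log2(SA / SB)
y = sigstren   = (log2 SA + log2 SB) / 2
```

For each marker, a Gaussian-mixture EM is asked for **more clusters than
genotypes exist** (8 for ploidy 3) so that low-frequency genotypes get their
own cluster, then clusters too close in contrast to be distinct genotypes
are merged: clusters with mean contrasts c₁, c₂ merge when

```
|c₁ − c₂| < Dmin · (1 + |(c₁ + c₂)/2|),      Dmin = 0.28
```

Dosages are assigned from cluster positions alone — no per-marker reference
positions needed — with a Hardy–Weinberg argument resolving the ambiguous
cases (a lone cluster is a homozygote; two clusters in one population are a
homozygote plus its nearest heterozygote; a suspiciously small extreme
cluster on a shifted marker is relabelled heterozygote). Markers are then
filtered and categorized by call rate (≥ 0.97), cluster separation
(FLD > 3.4), heterozygote strength offset (HetSO > −0.3) and homozygote
position (HomRO), into PolyHighResolution / NoMinorHomozygote /
MonoHighResolution (accepted) or CallRateBelowThreshold / OffTargetVariant /
Others (rejected).

A simulator with known dosage truth (Hardy–Weinberg genotype draws, Gaussian
clusters, optional contrast shifts and off-target artefacts) makes the whole
pipeline testable offline. See `docs/methods.md` for the full model.

## Worked example

Simulate 50 markers × 200 samples, transform, cluster, genotype:

```
triplocall simulate sim --n-markers 50 --n-samples 200 --seed 7
triplocall format sim.signals.tsv transformed.tsv
triplocall cluster transformed.tsv models.jsonl --workers 1 --seed 7
triplocall genotype models.jsonl genotyped
triplocall report genotyped
```

prints

```
{
  "n_markers": 50,
  "categories": {
    "PolyHighResolution": 36,
    "NoMinorHomozygote": 14,
    "MonoHighResolution": 0,
    "CallRateBelowThreshold": 0,
    "OffTargetVariant": 0,
    "Others": 0
  },
  "accepted": 50,
  "accepted_fraction": 1.0
}
```

All 50 markers pass QC: 36 show all four genotypes (PolyHighResolution) and
14 lack one homozygote (NoMinorHomozygote) — expected under Hardy–Weinberg
when the minor-allele frequency makes the rare homozygote's expected count
near zero. `genotyped/` then contains the genotype matrix, the integer
dosage matrix (−1 = no-call), and the per-marker QC report:

```
marker_id  call_rate  fld     hetso    homro   n_genotypes  category
M00001     1.0        9.5043  -0.0103  1.4902  4            PolyHighResolution
M00002     1.0        8.2403  -0.009   1.5218  4            PolyHighResolution
```

```
marker_id  S0001  S0002  S0003  S0004  S0005
M00001     ABB    AAA    AAB    AAB    AAB
M00002     ABB    ABB    AAB    ABB    BBB
```

M00001 separates its nearest genotype pair by 9.5 pooled standard deviations
(FLD), its heterozygotes sit on the homozygote baseline (HetSO ≈ 0), and its
homozygotes are where they should be (HomRO ≈ 1.5) — a clean marker whose
calls can feed downstream analyses such as parentage assignment. The same
steps run from Python via `triplocall.simulate_dataset`, `transform`,
`run_clustering` and `run_genotyping`; `calibrate-dmin` re-derives the merge
coefficient for a new platform, and `report --apply-edits` applies a manual
edits table.

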