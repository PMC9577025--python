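# zerolink

Zero-aware correlation and association-network inference for microbial
abundance profiles.

Microbial community tables (OTUs × samples) are dominated by zeros: a few
dozen abundant taxa carry most of the reads while a long tail of rare taxa
is absent — or merely undetected — in most samples. How those zeros are
treated before computing pairwise correlations changes the coefficients,
and therefore the co-occurrence and co-exclusion networks built from them,
as much as the choice of correlation method does. `zerolink` makes the
zero-handling step explicit, comparable and reproducible.

## What it does

* **Six zero-treatment policies**, applied either to the whole profile or
  pair-by-pair:

  | code | name | rule |
  |------|------|------|
  | 1 | `ZERO_AS_IS` | keep zeros as 0 |
  | 2 | `KNN_IMPUTE` | replace zeros by k-nearest-neighbour expectations across taxa |
  | 3 | `FILL_PSEUDO` | replace every zero by a pseudo-value (default 0.01) |
  | 4 | `DROP_PAIRED_FILL` | per pair, drop samples where both taxa are 0; fill unpaired zeros with the pseudo-value |
  | 5 | `DROP_PAIRED_KEEP` | per pair, drop samples where both taxa are 0; keep unpaired zeros |
  | 6 | `COMPLETE_CASE` | per pair, drop any sample where either taxon is 0 |

* **Sequential pairwise correlation** (Pearson, Spearman, Kendall τ_b) with
  a minimum-overlap rule: a pair enters the analysis only if it retains more
  than 30 paired valid observations after filtering.
* **SparCC** (sparse compositional correlation), implemented from scratch:
  basis correlations ρ_ij solved from the log-ratio variance matrix
  t_ij = Var log(x_i/x_j) = ω_i + ω_j − 2ρ_ij√(ω_iω_j) under a sparsity
  assumption, with Dirichlet resampling (pseudo-count 1) and iterative
  exclusion of strongly correlated pairs.
* **Signed association networks**: co-occurrence (r > 0.6) and co-exclusive
  (r < −0.6) graphs at p < 0.001, Cytoscape-convention topology metrics,
  hub subnetworks (first neighbours of the ten most connected nodes),
  consensus networks by edge intersection, and overlap counts.
* **A synthetic generator** producing zero-inflated profiles with known
  latent (Gaussian-copula) correlations on a long-tailed rank-abundance
  backbone, with per-sample sequencing depth and structural zeros — so every
  claim the toolkit makes can be scored against a planted truth.
* Profile utilities: TSV I/O, removal of aggregate rows, rarefaction to a
  common depth (multivariate hypergeometric, without replacement),
  occurrence-frequency filtering, and the centered log-ratio transform.

## Worked example

```python
from zerolink import (tara_like_spec, generate_profile, frequency_filter,
                      FrequencyBand, benchmark_policies, zero_fraction)

spec = tara_like_spec(seed=0)           # 1500 taxa, 139 samples, 39,410 reads each
profile, truth = generate_profile(spec)
print(f"profile: {profile.n_taxa} taxa x {profile.n_samples} samples, "
      f"zero fraction {zero_fraction(profile):.3f}")

abundant = frequency_filter(profile, FrequencyBand(min_samples=60))
print(f"taxa present in >=60 samples: {abundant.n_taxa}")

report = benchmark_policies(abundant, method="spearman", policies=(1, 2, 3, 5))
for policy, s in sorted(report.items()):
    print(f"policy {policy}: mean |rho| = {s.mean_abs_r:.3f}, "
          f"MAD vs paired standard = {s.mad_vs_standard:.3f}")
```

prints

```
profile: 1500 taxa x 139 samples, zero fraction 0.873
taxa present in >=60 samples: 141
policy 1: mean |rho| = 0.158, MAD vs paired standard = 0.176
policy 2: mean |rho| = 0.152, MAD vs paired standard = 0.206
policy 3: mean |rho| = 0.158, MAD vs paired standard = 0.176
policy 5: mean |rho| = 0.101, MAD vs paired standard = 0.000
```

Reading: on a survey-like profile that is 87% zeros, keeping or
pseudo-filling zeros (policies 1/3 — identical under Spearman, since the
fill preserves ranks) inflates coefficient magnitudes relative to the
paired-exclusion standard (policy 5), and kNN imputation (policy 2) strays
furthest from it — the mean absolute deviation (MAD) column. Those
distortions propagate directly into which edges clear the |r| > 0.6 network
cutoff.

The same workflow is available from the shell:

```sh
zerolink synth --seed 0 --outdir runs/synth
zerolink benchmark --input runs/synth/synthetic_profile.tsv --outdir runs/bench
zerolink correlate --input runs/synth/synthetic_profile.tsv \
    --policies 1,3,5 --methods spearman --outdir runs/edges
zerolink network --edges runs/edges/edges_spearman_policy5.tsv --outdir runs/nets
```

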