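# chondrorisk

A tested pipeline for global chondrichthyan (shark, ray, chimaera)
extinction-risk analysis: trait-based threat modelling with nested
taxonomic random effects, imputation of Data Deficient species' status,
Red List category apportioning, family-level threat tests, spatial
hotspot/irreplaceability scoring, and fisheries-landings trend statistics.
Everything runs end-to-end on synthetic data with known ground truth; no
external downloads are required.

## Modules

| module | what it does |
| --- | --- |
| `chondrorisk.species` | validated species trait/status tables (CSV I/O), derived features, z-scores, VIFs |
| `chondrorisk.tabulation` | Red List category summaries, exact one-tailed binomial family tests, regional-category averaging |
| `chondrorisk.risk_models` | logistic GLM (Newton) and binomial GLMM with nested random intercepts (Laplace approximation), AICc / Akaike weights / variable importance, effect sizes, marginal & conditional R² |
| `chondrorisk.dd_imputation` | nested predictive GLMs on log10 traits, ROC/AUC (Mann–Whitney), threshold choice, Data Deficient status prediction, NT/LC apportioning |
| `chondrorisk.spatial` | per-cell richness/threat/DD counts on an equal-area incidence grid, residual-threat regression, irreplaceability (sum-inverse and mean-log10 variants) |
| `chondrorisk.fisheries` | landings panel cleaning (`"<0.5"`, `"."` conventions), missing fractions, decade shares, ray:shark log ratios, EEZ-span overrepresentation, B/B_MSY decline arithmetic |
| `chondrorisk.synthetic` | seeded generators for species tables, incidence matrices, and landings panels with retained ground truth |

## CLI

```bash
chondrorisk simulate --seed 42 --out-dir fixtures/   # write synthetic fixtures
chondrorisk validate fixtures/species.csv
chondrorisk tabulate fixtures/species.csv --by habitat
chondrorisk familytest fixtures/species.csv --null-rate auto
chondrorisk fit fixtures/species.csv --random order,family,genus --out fit.json
chondrorisk impute fixtures/species.csv --threshold 0.5 --mode share
chondrorisk hotspots fixtures/incidence.csv fixtures/cells.csv fixtures/species.csv --metric residual
chondrorisk landings fixtures/landings.csv --meta fixtures/landings_meta.csv --report missing
```

## Notes

- The GLMM is fitted by maximising a Laplace approximation to the
  marginal likelihood (damped Newton inner loop over coefficients and
  random effects; derivative-free outer search over log-scale variance
  components). It agrees with `lme4::glmer` to ~1e-2 on coefficients and
  standard errors and reduces to the plain GLM when variance components
  are pinned at zero.
- Apportioning supports two readings of the NT:LC ratio — as the NT
  *share* of the remainder (default; reproduces the published counts) and
  as literal *odds* — selected via `mode=`.
- Irreplaceability offers both the sum-of-reciprocal-ranges and the
  mean-log10 cell statistics; the variant is recorded in the output.
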