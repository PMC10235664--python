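# protnet

Weighted correlation-network analysis of serum proteomic panels, built for
dissecting the heterogeneity of major depressive disorder (MDD): which
clusters of circulating proteins travel together, whether a cluster's
summary level differs between currently depressed patients and controls,
and which *individual* depressive symptoms drive that difference.

The package is aimed at psychiatric-epidemiology and proteomics groups
working with multiplexed immunoassay panels (a few hundred analytes,
~10²–10³ subjects) and questionnaire-level phenotypes such as the
IDS-SR30.  Cohort data of this kind are rarely redistributable, so the
package ships a synthetic cohort generator with the full statistical
structure the analysis assumes, and every stage is tested end to end on
generated data.

## The method

1. **Preprocess.** Analytes with > 30 % missing data are excluded; censored
   values are imputed at their detection limit, remaining gaps at the
   analyte median; each analyte is rank-based inverse-normal transformed,
   value ← Φ⁻¹((rank − 3/8)/(n + 1/4)).
2. **Network.** Unsigned weighted network a_ij = |r_ij|^β with β = 4;
   topological overlap
   TOM_ij = (Σ_u a_iu a_uj + a_ij)/(min(k_i,k_j) + 1 − a_ij);
   average-linkage clustering of 1 − TOM; modules from a dynamic branch
   decomposition with a minimum module size of 5 and statistical branch
   validation.  Each module m is summarised by its **eigenprotein** E_m,
   the first principal component of the module submatrix (mean 0, SD 1),
   and each analyte by its **module membership** kME_jm = cor(x_j, E_m).
3. **Association.** OLS with treatment coding,
   E_m ~ status + covariates, status ∈ {control (ref), remitted, current};
   and per symptom, E_m ~ factor + covariates with the four-level factor
   {control (ref), remitted, current-low, current-high} splitting current
   cases at item score ≥ 2.  Covariate tiers: base (batch, site, sex, age,
   education) ⊂ lifestyle ⊂ bmi.  Bonferroni: p × n_modules for the status
   scan, p × n_symptoms × n_modules for symptom scans, clipped at 1.
4. **Stability.** The cohort is repeatedly split into random halves
   (1621 → 811 + 810); the network analysis is re-run per half; the module
   overlapping the reference module most is recorded, yielding per-analyte
   inclusion frequencies across 2 × iterations clusterings.

See `docs/methods.md` for assumptions, parameter defaults and the design
rationale of every numerical choice.

## Worked example

```python
from protnet import ProteomicNetworkModel, simulate

cfg = simulate.SimulationConfig(seed=1)          # study-scale synthetic cohort
proteins, phenotypes, truth = simulate.generate_cohort(cfg)
proteins = simulate.inject_missingness(proteins, cfg)

results = ProteomicNetworkModel(proteins, phenotypes).fit()
print(results.summary())
```

```
Proteomic correlation network
================================================================
analytes: 171 (excluded by missingness: 0)   subjects: 1621
network: unsigned, beta=4, dissimilarity=tom, min module size 5
scale-free fit: R^2=0.672 slope=-0.96
----------------------------------------------------------------
  module   size  var.expl.   mean |r|
       1     24      0.254      0.222
       2     21      0.319      0.285
       3     13      0.289      0.230
       4     10      0.300      0.222
       5      7      0.329      0.217
       6      6      0.360      0.232
unassigned: 90
================================================================
```

Six modules are detected; 90 of the 171 analytes belong to none (they are
not connected strongly enough to any group of at least five analytes).
Module 2 — 21 analytes with mean within-module |r| = 0.285 — is the
cohort's immuno-metabolic cluster: the generator plants an effect of its
latent factor on the five energy-related symptoms in a small dysregulated
subgroup.  The status scan compares each eigenprotein between current MDD
and controls (Bonferroni × 6):

```python
for r in results.status_scan(tier="base"):
    flag = " <- selected" if r.min_p_flag else ""
    print(f"{r.module}: estimate {r.estimate:+.3f}  p {r.p:.3g}  adj. p {r.p_bonferroni:.3g}{flag}")
```

```
M1: estimate +0.012  p 0.845   adj. p 1
M2: estimate +0.110  p 0.0771  adj. p 0.463 <- selected
M3: estimate -0.033  p 0.591   adj. p 1
...
```

The current-MDD elevation of module 2 is modest (≈ 0.1 SD here; its size
varies seed to seed), which is exactly why the symptom-level scan matters.
Contrasting current cases with *high endorsement* of each of 28 symptoms
against controls (Bonferroni × 28):

```python
for r in results.symptom_scan(modules=["M2"], contrast="high")[:5]:
    print(f"{r.factor_name:22s} estimate {r.estimate:+.3f}  adj. p {r.p_bonferroni:.3g}")
```

```
appetite_increased     estimate +2.534  adj. p 1.81e-61
leaden_paralysis       estimate +2.572  adj. p 6.69e-61
energy_level           estimate +2.558  adj. p 6.82e-60
sleeping_too_much      estimate +2.518  adj. p 4.92e-58
weight_increase        estimate +2.550  adj. p 1.06e-55
```

The five planted energy-related symptoms lead the scan: subjects highly
endorsing them carry a strongly elevated module-2 eigenprotein, while the
same contrast on *low* endorsers (`contrast="low"`) returns nothing —
the association is driven by the symptom profile, not by depression per
se.  Finally, split-half stability of the selected module:

```python
report = results.stability(reference_module=2, iterations=200, seed=1)
print(report.summary())   # mean_size 21.0, mean_overlap 21.0, sd_overlap 0.0
```

At the default noise level the 21-analyte module is recovered perfectly in
every half-sample; per-analyte inclusion frequencies are in
`report.frequencies`.

The same pipeline is available from the shell:

```bash
protnet simulate --seed 1 --out cohort/
protnet preprocess --proteins cohort/proteins.tsv --lod cohort/lod.tsv --out prep/
protnet network --proteins prep/proteins.transformed.tsv --out net/
protnet associate --eigenproteins net/eigenproteins.tsv \
    --phenotypes cohort/phenotypes.tsv --contrast symptom-high --out assoc.tsv
protnet run-all --seed 1 --out run/          # everything, plus report.json/md
```

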