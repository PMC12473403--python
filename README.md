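# commstab

Community-stability analysis for species-abundance tables sampled along
an ordered disturbance gradient — the situation of vegetation relevés
(quadrat counts) grouped into disturbance levels, such as alpine-meadow
plots spanning a gradient of subterranean-rodent (zokor) mound
disturbance from none (ND) through light (LD), moderate (MD) and heavy
(HD) to extreme (ED).

The package implements four complementary views of stability and its
drivers over a samples × species count matrix with per-sample level,
plot and point metadata:

1. **Compositional stability (AVD).** The variation degree of species
   *i* in sample *j* of a level is the standardized absolute deviation
   *a*ᵢⱼ = |xᵢⱼ − x̄ᵢ| / δᵢ, with the mean and standard deviation taken
   within the level. The average variation degree AVD = Σ *a* / (K·n)
   over the level's K samples and n species, and stability is reported
   as 1 − AVD (lower AVD = steadier composition).
2. **Co-occurrence cohesion.** Each species gets the mean of its
   statistically significant positive (negative) Pearson correlations
   with all other species, r̄ᵢ⁺ (r̄ᵢ⁻), computed on the pooled dataset.
   Per-sample cohesion weights these by relative abundance:
   C⁺ⱼ = Σᵢ pᵢⱼ·r̄ᵢ⁺ ∈ [0, 1] and C⁻ⱼ = Σᵢ pᵢⱼ·r̄ᵢ⁻ ∈ [−1, 0], with
   total cohesion |C⁺| + |C⁻| and the network-stability ratio |C⁻|/C⁺.
3. **Indicator species (SPEC–OCCU).** Specificity is the share of a
   species' across-level mean abundance concentrated at one level
   (summing to 1 over levels); occupancy is the fraction of the level's
   quadrats occupied. A species indicates a level when both reach the
   dual threshold (≥ 0.4, inclusive).
4. **Group comparison and driver attribution.** One-way ANOVA with
   Tukey-HSD compact letter displays across levels; Pearson screens of
   any stability metric against soil/vegetation covariates (pooled, per
   level, or per adjacent-level pair); boosted-regression-tree models
   whose Friedman relative influence (% of total squared-error
   reduction per covariate) ranks drivers, including the
   "transition" models fitted on pooled adjacent-level samples.

A seeded synthetic-community generator reproduces the study design
(5 levels × 3 plots × 5 points = 75 quadrats, 40-species lognormal
rank-abundance pool) with retrievable ground truth — a planted
stability gradient, indicator species, correlated species pairs, and
covariates causally linked to the stability axis — so every stage of
the analysis is testable without field data.

## Worked example

```python
import commstab as cs

table, meta, env, truth = cs.simulate(cs.default_scenario(seed=42))

v = cs.variation_degree(table, meta)
print(v.per_level_stability.round(3).to_string())

comp = cs.anova_tukey(cs.sample_stability(v), meta, metric="stability")
print(comp.summary.round(3).to_string(index=False))
print(f"F = {comp.f_statistic:.1f}, p = {comp.p_value:.2e}")
```

```
ND    0.165
LD    0.200
MD    0.234
HD    0.284
ED    0.386
level  n  mean    sd letter
   ND 15 0.165 0.088      c
   LD 15 0.200 0.052     bc
   MD 15 0.234 0.113     bc
   HD 15 0.284 0.132      b
   ED 15 0.386 0.071      a
F = 12.1, p = 1.59e-07
```

Per-level stability (1 − AVD) rises monotonically from the undisturbed
to the extremely disturbed level — the gradient the generator planted —
and the letter display shows ED significantly more stable than every
other level at α = 0.05. The indicator table recovers the planted
indicator species at their levels:

```python
st = cs.spec_occu_table(table, meta)
print(st.flagged()[["species", "level", "specificity", "occupancy"]]
      .round(2).head(4).to_string(index=False))
```

```
species level  specificity  occupancy
   sp21    ND         0.85       0.93
   sp22    ND         0.84       1.00
   sp23    LD         0.87       1.00
   sp24    LD         0.84       0.80
```

The same pipeline runs from the shell over delimited-text tables:

```sh
commstab simulate --seed 42 --out data/
commstab avd data/abundance.csv data/sample_meta.csv
commstab run-all --seed 42 --out results/
```

`run-all` writes every stage table (stability, cohesion, SPEC–OCCU,
ANOVA letters, driver screens, BRT influences) into one directory;
re-running with the same manifest reproduces each file byte-for-byte.

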