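# metstab

Genotype-by-environment stability analysis for balanced
multi-environment trials (MET): combined ANOVA, the AMMI model, GGE
biplot geometry, broad-sense heritability, rank correlations and Ward
clustering — with a packaged lentil grain Fe/Zn/phytic-acid dataset and
a synthetic trial generator for parameter-recovery testing.

The package is aimed at plant breeders and biometricians who need to
(i) quantify how much of the variation in a quality trait is genotype,
environment, or their interaction, (ii) pick genotypes that are both
high-performing and stable across locations, and (iii) group test
locations into mega-environments.

## The models

For cell means Ȳ_ij of genotype i at environment j (r replicates):

* **AMMI** — Ȳ_ij = μ + g_i + e_j + Σ_n λ_n γ_in δ_jn + ε_ij. Additive
  main effects by ANOVA; the doubly-centered interaction residual is
  decomposed by SVD into interaction principal component axes with
  SS(PCn) = r·λ_n², tested on Gollob degrees of freedom
  df_n = g+e−1−2n against the pooled plot error.
* **GGE** — SVD of the environment-centered matrix Ȳ_ij − Ē_j, so
  genotype main effect and interaction are displayed jointly. From the
  two leading axes the package derives mean-vs-stability projections on
  the average environment axis (AEA), ideal-genotype distances,
  environment discriminativeness/representativeness, which-won-where
  sector partitions, and bootstrap confidence limits for all scores.
* **Heritability** — per location, entry-mean broad-sense
  H² = σ²_g / (σ²_g + σ²_e/r) from the randomized-block ANOVA.

See `docs/methods.md` for conventions, assumptions and known
limitations.

## Worked example

```python
import metstab as ms

ds = ms.lentil_fixture()           # 16 genotypes x 6 locations, Fe/Zn/PA cell means, r=3
table, res = ms.anova_from_dataset(ds, "Fe")
print(table[["source", "df", "SS", "MS", "pct_TSS"]].round(2).to_string(index=False))
```

```
 source  df       SS      MS  pct_TSS
    ENV   5 13588.74 2717.75    29.30
    GEN  15 13776.81  918.45    29.71
GEN×ENV  75 19010.95  253.48    40.99
    PC1  19  7581.95  399.05    39.88
    PC2  17  4951.61  291.27    26.05
    PC3  15  4081.08  272.07    21.47
    PC4  13  1536.85  118.22     8.08
    PC5  11   859.45   78.13     4.52
    PC6   9     0.00    0.00     0.00
```

Environment, genotype and interaction each explain roughly a third of
the grain-iron variation (29.3/29.7/41.0% of the three-way total), and
the first interaction axis carries 39.9% of the interaction sum of
squares — a strong, structured genotype-by-environment signal. The F
column is empty here because the fixture is mean-level; replicate-level
input fills it from the pooled plot error automatically.

```python
gge = ms.gge_decompose(ms.cell_means(ds, "Fe"))
print(ms.mean_stability(gge).sort_values("stability_rank").round(2).head(3))
print(ms.which_won_where(gge).mega_environments)
```

```
        aea_projection  aec_distance  mean_rank  stability_rank
PL 406          -13.65          3.20       14.0             1.0
PL 639          -12.26          3.73       13.0             2.0
L 4717           -1.54          3.86        7.0             3.0
{'L 4596': ['Delhi', 'Sabour'], 'L 4147': ['Kanpur', 'Sagar', 'Sehore', 'Samastipore']}
```

`aea_projection` is the mean-performance proxy (signed, larger = more
iron), `aec_distance` the instability proxy (smaller = more stable):
PL 406 is the most stable line but a below-average performer, while the
which-won-where partition splits the six locations into two
mega-environments — L 4596 wins at Delhi and Sabour, L 4147 everywhere
else. Among the above-average performers, L 4076 has the smallest AEC
distance, which is what makes it the "ideal" stable high-iron line.

The same analyses run from the shell:

```
metstab report --traits Fe,Zn,PA --out results/full_run
metstab simulate --seed 7 --out sim.csv
metstab gge --input sim.csv --level replicate --trait synthetic \
        --view www --out-prefix sim_gge
```

`metstab report` writes, per trait, the descriptive table, the
ANOVA/AMMI table, GGE scores and all derived rankings, Spearman
correlation matrices, Ward dendrograms (newick), and the four biplot
views as SVG; with replicate-level input it adds per-location
heritability and bootstrap confidence limits.

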