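# plastiqtl

QTL mapping of drought-plasticity traits in biparental recombinant
inbred line (RIL) populations, using linear-regression residuals as
plasticity scores.

## The problem

Field trials of wheat under contrasting irrigation regimes (well-watered
WW vs. water-limited WL) measure complex traits — yield components,
biomass, morphology, physiology and phenology — whose response to stress
is confounded by flowering time: early-heading lines partially escape
terminal drought, so an apparent "drought QTL" may really be a heading
QTL in disguise. `plastiqtl` implements a residual-regression approach
that separates these signals and maps them on a genetic map built from
the same population. It is aimed at quantitative geneticists working
with biparental inbred populations (here a durum × wild emmer wheat
cross is the motivating design: two homozygous parental alleles, 14
chromosomes, ~150 F6 lines).

## The method

For each observed trait `V` (line means per environment) three
derivative trait sets are defined by ordinary least squares:

* **adjusted-phenology traits** (`df`), per environment, with `DH` the
  days-to-heading score:
  `V_DH = β + α·DH`, residual `E_DH = V − V_DH`;
* **drought plasticity I** (`d`):
  `prV_WL = β + α·V_WW`, residual `E_WL = V_WL − prV_WL` — the stress
  response normalized for the trait's non-stress level;
* **drought plasticity II** (`ddf`):
  `V_WL^DH = β + α₁·V_WW − α₂·DH_WL`, residual `E_WL^DH = V_WL − V_WL^DH`
  — plasticity I with the heading-mediated (drought-escape) component
  removed.

Broad-sense heritability across the two regimes comes from the ANOVA
mean squares: `σ_g² = (MS_gen − MS_g×e)/e`, `σ_g×e² = MS_g×e`,
`h² = σ_g² / (σ_g² + σ_g×e²/e)`.

All trait sets are scanned by Haley–Knott regression interval mapping on
a skeleton map built from the genotype matrix (marker QC, co-segregation
binning, RF ≤ 0.2 single-linkage grouping with end-to-end merging to the
chromosome number, greedy + 2-opt ordering, Kosambi cM from
selfed-RIL-corrected recombination `R = 2r/(1+2r)`). Evidence is
`LOD = (n/2)·log₁₀(SSE₀/SSE₁)` with genome-wide thresholds from
permutations, 1.5-LOD support intervals, line-resampling bootstrap
uncertainties, two-linked-QTL and joint two-environment models, and a
multiple-interval-mapping style background adjustment.

Co-localized effects are grouped into loci and classified:
**phenology** (associated / plastic / non-plastic with respect to
heading), **drought** (plastic / non-plastic), and **drought-resistance
strategy** — *escape* (plasticity-I effect without the matching
plasticity-II effect), *avoidance* (carbon-isotope ratio, leaf rolling),
*tolerance* (osmotic potential, chlorophyll). Support intervals are
anchored to physical coordinates for candidate-gene listing from a GFF3
annotation.

A synthetic-data generator with a known QTL architecture (including
heading-mediated and environment-specific effects, segregation
distortion and missing genotypes) makes every stage testable end to end
and provides truth registries for parameter-recovery checks.

## Worked example

Run the full simulated study (150 lines, 14 chromosomes, 17 traits, two
regimes, three replicates) and scan a subset of traits:

```python
from plastiqtl.pipeline import RunConfig, run_all

report = run_all(RunConfig(out_dir="demo", seed=7, n_perm=300,
                           scan_traits=["DP-H", "GY", "TKW", "OP", "d13C"]))
print(report["stages"])
```

Output (abridged):

```
"simulate": {"n_lines": 150, "n_markers": 1368, "n_qtls": 26}
"buildmap": {"n_groups": 14, "total_length_cM": 1826.5}
"scan":     {"n_effects": 28}
"classify": {"n_loci": 6, "labels": {"2B.1": "non-plastic", ...,
             "5A.1": "associated", "7B.1": "associated"}}
```

The rebuilt map recovers all 14 linkage groups at 1826.5 cM with an
8.8% non-recombinant-chromosome rate over the 150 × 14 = 2100
line-chromosome units. Locus `7B.1` — the simulated major heading QTL
that acts more strongly under water limitation — is labelled
*associated* with heading, *plastic* to drought, strategy *escape*: its
grain-yield plasticity-I effect has no plasticity-II counterpart, i.e.
the stress response is mediated by earlier heading. The WL-specific
carbon-isotope locus `4A.1` is classified *avoidance* and the osmotic
potential locus `4B.1` *tolerance*, matching their simulated truth.

The same stages are available from the shell:

```bash
plastiqtl simulate --seed 7 --out demo
plastiqtl buildmap --genotypes demo/genotypes.tsv --target-groups 14 --out demo
plastiqtl scan --genotypes demo/genotypes.tsv --map demo/map_built.tsv \
               --phenotypes demo/phenotypes.tsv --n-perm 300 --out demo
```

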