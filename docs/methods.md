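# Methods

This note documents the models, numerical choices and limitations of
`plastiqtl`, in the order the pipeline runs them.

## Synthetic study design

The generator emulates a biparental RIL study: `n_lines = 150` F6 lines
from a durum × wild emmer cross, 14 linkage groups totalling 1835.7 cM
(A genome 953.1, B genome 882.6; the shortest group 84.6 cM, the longest
165.3 cM), a mean skeleton-marker spacing of 1.355 cM (~1369 loci), two
irrigation regimes and three replicates per regime. Genotypes are fully
homozygous two-state calls coded as dosage −1 for the domesticated
parent (P1) and +1 for the wild parent (P2); residual F6 heterozygosity
is ignored.

Chromosomes are simulated as a Markov crossover process over adjacent
marker intervals: interval length in cM is converted to a meiotic
recombination fraction by the Kosambi map function
(`r = ½·tanh(d/50)`), and the observed recombination between inbred-line
genotypes uses the selfed-RIL correction `R = 2r/(1+2r)`. No
interference is modelled beyond what Kosambi implies for two-point
distances. The map function is an assumption — the classical
ultra-dense mapping tools this mirrors do not publish theirs — but the
simulator and the map builder share it, so round-trip tests are exact in
expectation.

Phenotypes follow a causal chain: days-to-heading (DP-H) is generated
first from its own QTLs; every other trait is
`intercept + Σ(QTL effects at the line's dosages, per environment)
+ coupling × (line's genetic heading deviation) + N(0, σ_env)` replicate
noise. The coupling slope is what creates heading-mediated QTL effects:
a heading QTL with environment-dependent effects induces, at the same
position, an apparent effect on every coupled trait whose
environment-specific part is pure drought escape. Per-QTL truth records
direct and mediated components separately, and a truth registry derives
the locus labels an ideal analysis would assign — using the *same* rule
functions as the classifier, so registry and classifier cannot drift
apart.

Segregation distortion is simulated as selection-like replacement: on a
chromosome with shift `s`, each line's chromosome is replaced by the
favored parental allele with probability `2|s|`, moving the expected
allele frequency to `0.5 + |s|` while preserving linkage among
unaffected lines. Missing genotypes are uniform at the configured rate.
Epistasis, genotyping error and block effects are not simulated.

### What the idealized fixtures do and do not show

Two expected signatures of the residual approach hold exactly only when
the conditioning variables are measured without error:

* equal QTL effects in both regimes cancel in plasticity I only if the
  WL-on-WW regression slope is 1; replicate-mean noise in the WW
  predictor attenuates the slope (errors-in-variables) and lets a
  fraction of a "non-plastic" effect leak into the residual;
* full suppression of a heading-mediated effect by the `df`/`ddf`
  adjustments is exact only for noiseless heading scores.

The archetype fixtures therefore use high-heritability noise settings
(replicate SD 0.2–0.6 against unit QTL effects), where the leak is far
below any genome-wide threshold. On real data — and in the default
generator, whose noise gives line-mean heritabilities around 0.6–0.8 —
partial leak-through of strong non-plastic effects into plasticity scans
is expected behavior of the method, not a bug.

## Derivative traits and statistics

All regressions are ordinary least squares with an intercept on line
means, with per-fit listwise deletion (a line is dropped only from fits
whose inputs it lacks). Degenerate designs raise typed errors: constant
predictors, and plasticity II predictors correlated beyond `1 − 1e−8`.
Residual sets are validated against an independent normal-equations
oracle to 1e-10 relative error.

Heritability uses the ANOVA mean-square identities
`σ_g² = (MS_gen − MS_g×e)/e`, `σ_g×e² = MS_g×e`,
`h² = σ_g²/(σ_g² + σ_g×e²/e)`. Mean squares are computed from
replicate-level data by balanced two-way sums of squares; block terms
are omitted (the generator has none, and a split-plot layout is not
recoverable from the line/env/replicate schema). Negative genotypic
variance estimates are truncated to zero and logged. Normality checks
on trait distributions are advisory only — they are logged, never
blocking, since mildly non-normal traits (e.g. ordinal leaf-rolling
scores) are still analyzed.

Correlation analysis offers Pearson and Kendall rank correlations on
pairwise-complete observations, with an edge-list export thresholded at
|r| ≥ 0.16 by default for network displays.

## Map construction

* **QC**: markers with more than 10% missing calls or a 1:1 chi-square
  above 35 are removed (both configurable).
* **Binning**: markers with RF = 0 over shared informative lines are
  merged; the skeleton representative is the least-missing member, ties
  broken by the smallest identifier.
* **Grouping**: single-linkage at RF ≤ 0.2. If more groups emerge than
  the chromosome number, the two groups with the smallest inter-group
  RF are merged repeatedly (end-to-end association). Fewer natural
  groups than the target is only a warning — groups are never split.
* **Ordering**: greedy nearest-neighbour seeded at the most distal
  marker (largest total RF to the rest), then 2-opt segment reversals
  until no adjacent-RF-sum improvement; deterministic and adequate at
  skeleton density (order recovery on simulated data is exact at
  n = 1000). The stability tests of guided evolutionary ordering are
  replaced by 2-opt convergence plus truth-recovery tests.
* **cM assignment**: adjacent observed RF → meiotic `r = R/(2−2R)`
  (clamped at 0.49) → Kosambi cM, accumulated from zero. Orientation
  is fixed by the anchor table when present (ascending with bp),
  otherwise by placing the lexicographically smallest end marker first.
* **Diagnostics**: per-marker 1:1 chi-square (df = 1, homozygous classes
  only) with distorted counts split by favored parent; non-recombinant
  line × group units (all non-missing calls identical, at least two
  calls — a single call carries no recombination information; units
  with fewer calls are excluded from the denominator and logged); and
  per-group |Spearman| concordance between genetic and physical order
  (absolute value because group orientation is arbitrary; groups with
  fewer than three anchors are skipped).

## QTL scans

Haley–Knott regression on expected dosages replaces mixture-model EM:
for near-homozygous RILs the two are nearly equivalent, and the
regression form reduces each scan position to one centered dot product,
which is what makes permutation loops cheap. Conditional dosages use
the two nearest non-missing flanking markers under the Markov model
(single-flank conditioning at chromosome ends; dosage 0 for lines with
no calls on a chromosome). The evaluation grid is a 1 cM lattice plus
every marker position.

`LOD = −(n/2)·log₁₀(1−R²)` with a ceiling of 50 for numerically perfect
fits; ties at the ceiling are broken by the larger R². The additive
effect is the dosage slope (half the homozygote difference, positive
toward the wild parent; the increasing allele is P2 iff a > 0), PEV is
the model R² at the peak, and the support interval is the widest
contiguous grid region around the peak within 1.5 LOD of it.

Genome-wide thresholds are per-trait empirical `(1−α)` quantiles of the
max-LOD over permutations of trait values across lines (genotypes
fixed); no cross-trait multiplicity correction is applied, matching
per-trait permutation testing practice. Default 1000 permutations and
500 bootstraps keep a full run at desk scale with Monte-Carlo error on
the 0.05 threshold of about ±0.007; both are configurable up to 5000.
The bootstrap resamples lines with replacement and rescans the
chromosome; degenerate replicates are skipped and counted.

The two-linked-QTL search fits all ordered position pairs separated by
at least 10 cM and keeps the pair only when its LOD exceeds the best
single-QTL LOD by 2.0 — both margins are configurable; no principled
selection rule exists for this model family, so the defaults are
deliberately conservative. The joint two-environment scan fits
environment-specific intercepts and slopes; because the two regimes are
independent samples, the joint LOD is the sum of the per-environment
profiles, and the specificity tag reports which per-environment slope
is individually significant (pointwise F test at 0.05) at the joint
peak. MIM-style refinement residualizes the trait on peak dosages of
QTLs detected on *other* chromosomes (constant or collinear covariates
dropped), rescans, and iterates at most 3 rounds or until peaks move
less than 1 cM.

## Classification

Loci are single-linkage groups of effects with overlapping support
intervals on one chromosome; ids are `<chrom>.<k>` in cM order.

* **Phenology**: *associated* if the locus affects the heading trait
  itself or some observed effect has no `df` counterpart for the same
  trait and environment (full suppression); *plastic* if a `df` effect
  lacks an observed counterpart or an observed/`df` pair is not
  similar; else *non-plastic*. "Similar" is operationalized as the
  same increasing-allele parent and a standardized-effect ratio within
  [0.5, 2], computed as `sqrt(PEV_df/PEV_obs)` (√PEV is proportional to
  the standardized additive effect in a balanced biparental design).
  Precedence when member traits conflict: associated > plastic >
  non-plastic, mirroring the convention that heading-affecting loci are
  marked associated regardless of other members. Loci with only
  plasticity members get *not-applicable*.
* **Drought**: *plastic* iff any member is a `d` or `ddf` effect.
* **Strategies** (a set, since pleiotropic loci can span several):
  *tolerance* for osmotic potential or chlorophyll members, *avoidance*
  for carbon-isotope ratio or leaf rolling, *escape* when some trait
  has a `d` effect without a `ddf` effect. Loci affecting none of
  these (e.g. pure yield loci) get the explicit label *none*. For
  osmotic potential the resistance-conferring direction is the
  value-decreasing allele, so the resistance allele is the opposite of
  the increasing-value parent.
* **ITV accounting**: per-trait, per-parent counts and summed PEV over
  plasticity effects; when `d` and `ddf` co-locate for one trait within
  a locus, only the higher-PEV effect contributes.

## Candidate genes

Physical anchors (marker, chromosome, 1-based bp) project the 1.5-LOD
support interval of the locus's highest-LOD effect to bp by taking the
nearest anchored marker at or outside each cM endpoint — conservative
outward widening that guarantees coverage of the support region;
endpoints beyond the terminal anchors clip to them with a flag. Gene
listing uses inclusive-coordinate overlap against GFF3 `gene` features;
intervals with more than 200 genes are flagged as excluded from
candidate-gene analysis. Gene cM positions are linear interpolations of
the gene midpoint bp between flanking anchors (exact at anchors,
monotone between monotone anchors; local inversions interpolate with a
warning; extrapolation clamps to the terminal cM).

## Validation problem sizes

The validation experiments run at: map recovery n = 1000 lines at 2 cM
spacing over all 14 chromosomes; threshold calibration with 1000
permutations and 200 independent null scans at n = 150; power with 50
replicates of a PEV = 0.20 QTL at n = 150 with 200 permutations per
replicate; archetype classification at n = 200 with 200 permutations
per trait set. These sizes give binomial/Monte-Carlo error comfortably
inside the stated tolerances while keeping the whole suite at
desk scale.

## Known limitations

* Real-data mode expects clean rectangular TSV inputs; no genotype
  imputation or error correction beyond the QC filters.
* No epistasis scan, no dominance (meaningless for inbred lines), no
  composite interval mapping with cofactor selection, no REML
  mixed-model heritability.
* The joint-environment model assumes independent samples per regime
  (true for different field plots, not for repeated measures).
* Plasticity residuals inherit the errors-in-variables attenuation
  discussed above; with noisy predictors the classifier's
  full-suppression and escape calls are conservative in the direction
  of over-calling plasticity.
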