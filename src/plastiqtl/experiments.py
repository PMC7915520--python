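"""Self-contained validation experiments for the pipeline.

Each function simulates data under known conditions, runs the relevant
pipeline stages from scratch and returns the measured quantities:
map-recovery accuracy, residual-oracle agreement, genome-wide
family-wise error calibration, QTL detection power, plasticity-scan
specificity and archetype classification.  They back both the
acceptance checks and the reproducibility script, and are ordinary
library functions a user can run at other problem sizes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import classify as classify_mod
from . import mapping, qtl, traits
from .simulate import (ARCHETYPE_CHROMS, ARCHETYPE_LENGTHS, SimConfig,
                       archetype_architecture, dosage_matrix,
                       simulate_map_and_genotypes, simulate_phenotypes)


# ---------------------------------------------------------------------------
# map construction

def map_recovery(n_lines: int = 1000, spacing_cM: float = 2.0,
                 seed: int = 0) -> dict:
    """Rebuild the 14-chromosome map from simulated genotypes.

    Returns group count, worst per-group |Spearman| order correlation
    against the simulated order, and the estimated/true total lengths.
    """
    cfg = SimConfig(n_lines=n_lines, marker_spacing_cM=spacing_cM, seed=seed)
    mp, geno = simulate_map_and_genotypes(cfg)
    built = mapping.build_map(geno, target_groups=cfg.n_chromosomes)
    truth_rank = {m: i for i, m in enumerate(mp["marker"])}
    truth_chrom = dict(zip(mp["marker"], mp["chrom"]))
    rhos = []
    pure = True
    for group in built.groups:
        tab = built.group_table(group)
        if len({truth_chrom[m] for m in tab["marker"]}) > 1:
            pure = False
        rho = stats.spearmanr([truth_rank[m] for m in tab["marker"]],
                              tab["order"]).statistic
        rhos.append(abs(float(rho)))
    true_length = float(mp.groupby("chrom")["cM"].max().sum())
    return {
        "n_groups": len(built.groups),
        "groups_pure": pure,
        "min_abs_order_correlation": min(rhos),
        "total_length_cM": built.total_length,
        "true_length_cM": true_length,
        "length_rel_error": abs(built.total_length - true_length)
                            / true_length,
    }


def diagnostics_denominator(n_lines: int = 150, seed: int = 0) -> dict:
    """Non-recombinant screen on a rebuilt 14-group map of ``n_lines``."""
    cfg = SimConfig(n_lines=n_lines, marker_spacing_cM=10.0, seed=seed)
    _, geno = simulate_map_and_genotypes(cfg)
    built = mapping.build_map(geno, target_groups=cfg.n_chromosomes)
    diag = mapping.map_diagnostics(geno, built)
    return {"n_groups": len(built.groups), "n_units": diag.n_units,
            "n_units_evaluated": diag.n_units_evaluated,
            "nonrecombinant_proportion": diag.nonrecombinant_proportion}


# ---------------------------------------------------------------------------
# derivative traits

def residual_oracle_error(n_fixtures: int = 100, seed: int = 0) -> float:
    """Worst relative deviation of the three derivative-trait fits from
    an independent normal-equations oracle over random fixtures."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_fixtures):
        n = int(rng.integers(20, 80))
        idx = pd.Index([f"L{i:03d}" for i in range(n)])
        ww = pd.Series(rng.normal(10, 3, n), index=idx)
        dh = pd.Series(rng.normal(55, 5, n), index=idx)
        wl = pd.Series(0.6 * ww.to_numpy() - 0.3 * dh.to_numpy()
                       + rng.normal(0, 1, n), index=idx)

        def oracle(y, X):
            Z = np.column_stack([np.ones(n), X])
            return y - Z @ np.linalg.solve(Z.T @ Z, Z.T @ y)

        cases = [
            (traits.adjust_for_phenology(wl, dh)[0],
             oracle(wl.to_numpy(), dh.to_numpy()[:, None])),
            (traits.plasticity_I(ww, wl)[0],
             oracle(wl.to_numpy(), ww.to_numpy()[:, None])),
            (traits.plasticity_II(ww, wl, dh)[0],
             oracle(wl.to_numpy(),
                    np.column_stack([ww.to_numpy(), dh.to_numpy()]))),
        ]
        for got, exp in cases:
            scale = float(np.max(np.abs(exp))) + 1.0
            worst = max(worst,
                        float(np.max(np.abs(got.to_numpy() - exp))) / scale)
    return worst


# ---------------------------------------------------------------------------
# scan calibration and power

@dataclass
class _Genome:
    cfg: SimConfig
    map_df: pd.DataFrame
    geno: pd.DataFrame
    probs: qtl.GenotypeProbabilities


def _study_genome(n_lines: int = 150, seed: int = 0) -> _Genome:
    cfg = SimConfig(n_lines=n_lines, seed=seed)
    mp, geno = simulate_map_and_genotypes(cfg)
    probs = qtl.genotype_probabilities(mp, geno, step_cM=1.0)
    return _Genome(cfg, mp, geno, probs)


def null_calibration(n_lines: int = 150, n_perm: int = 1000,
                     n_null: int = 200, alpha: float = 0.05,
                     seed: int = 0) -> dict:
    """Family-wise error of the permutation threshold under a global null.

    One permutation threshold is calibrated on a null trait; the realized
    FWE is the fraction of independent null scans whose genome-wide max
    LOD exceeds it.  The binomial 95% interval around ``alpha`` is
    returned alongside.
    """
    g = _study_genome(n_lines, seed)
    rng = np.random.default_rng(seed + 1)
    y = pd.Series(rng.normal(0, 1, n_lines), index=g.geno.index)
    thr = qtl.permutation_threshold(g.probs, y, n_perm=n_perm, alpha=alpha,
                                    seed=seed + 2)
    hits = 0
    for _ in range(n_null):
        y_null = pd.Series(rng.normal(0, 1, n_lines), index=g.geno.index)
        hits += qtl.scan_single(g.probs, y_null).max_lod > thr.lod_threshold
    half = 1.96 * np.sqrt(alpha * (1 - alpha) / n_null)
    return {"n_null": n_null, "alpha": alpha,
            "lod_threshold": thr.lod_threshold,
            "fwe": hits / n_null,
            "binomial_95_interval": (max(0.0, alpha - half), alpha + half)}


def power_study(n_reps: int = 50, pev: float = 0.20, n_lines: int = 150,
                n_perm: int = 200, alpha: float = 0.05,
                seed: int = 0) -> dict:
    """Detection power and position accuracy for a single additive QTL.

    The QTL sits at a marker near 70 cM on chromosome 2A of the
    14-chromosome study genome; the noise SD realizes the requested
    proportion of explained variance given the unit dosage variance.
    A replicate counts as detected when the genome-wide maximum LOD
    clears its own permutation threshold on the correct chromosome.
    """
    g = _study_genome(n_lines, seed)
    sub = g.map_df[g.map_df["chrom"] == "2A"]
    row = sub.iloc[(sub["cM"] - 70.0).abs().argmin()]
    d = dosage_matrix(g.geno)[row.marker]
    a = 1.0
    noise_sd = a * np.sqrt((1 - pev) / pev)   # var(dosage) ~ 1 in a RIL
    rng = np.random.default_rng(seed + 10)
    detected = 0
    errors = []
    for rep in range(n_reps):
        y = pd.Series(a * d + rng.normal(0, noise_sd, n_lines),
                      index=g.geno.index)
        thr = qtl.permutation_threshold(g.probs, y, n_perm=n_perm,
                                        alpha=alpha, seed=seed + 100 + rep)
        prof = qtl.scan_single(g.probs, y)
        peak = prof.table.loc[prof.table["lod"].idxmax()]
        if peak["lod"] > thr.lod_threshold and peak["chrom"] == "2A":
            detected += 1
            errors.append(abs(float(peak["cM"]) - float(row.cM)))
    return {"n_reps": n_reps, "power": detected / n_reps,
            "median_position_error_cM":
                float(np.median(errors)) if errors else float("nan"),
            "true_position_cM": float(row.cM)}


def wl_specific_detection(n_lines: int = 150, n_perm: int = 200,
                          alpha: float = 0.05, seed: int = 0) -> dict:
    """A WL-only QTL must surface on the plasticity-I scan, not on the
    observed-WW scan, at matched per-trait thresholds."""
    g = _study_genome(n_lines, seed)
    sub = g.map_df[g.map_df["chrom"] == "3B"]
    row = sub.iloc[(sub["cM"] - 50.0).abs().argmin()]
    d = dosage_matrix(g.geno)[row.marker]
    rng = np.random.default_rng(seed + 20)
    ww = pd.Series(rng.normal(20, 1, n_lines), index=g.geno.index)
    wl = pd.Series(20 + 1.2 * d + rng.normal(0, 1, n_lines),
                   index=g.geno.index)
    d_trait, _ = traits.plasticity_I(ww, wl)

    def max_lod_and_thr(y, tag):
        thr = qtl.permutation_threshold(g.probs, y, n_perm=n_perm,
                                        alpha=alpha, seed=seed + 30)
        prof = qtl.scan_single(g.probs, y)
        return prof.max_lod, thr.lod_threshold

    d_lod, d_thr = max_lod_and_thr(d_trait, "d")
    ww_lod, ww_thr = max_lod_and_thr(ww, "obs-WW")
    return {"d_scan_max_lod": d_lod, "d_scan_threshold": d_thr,
            "d_detected": d_lod > d_thr,
            "ww_scan_max_lod": ww_lod, "ww_scan_threshold": ww_thr,
            "ww_detected": ww_lod > ww_thr}


# ---------------------------------------------------------------------------
# classification archetypes

def archetype_classification(name: str, n_lines: int = 200,
                             n_perm: int = 200, alpha: float = 0.05,
                             seed: int = 0) -> dict:
    """Simulate one archetype, run scan + classification, compare labels.

    Returns the truth-registry labels of the locus carrying the
    architecture's QTL(s), the labels assigned to the corresponding
    detected locus, and whether they match exactly.
    """
    cfg = SimConfig(n_lines=n_lines, n_chromosomes=2,
                    chrom_lengths_cM=list(ARCHETYPE_LENGTHS),
                    chrom_names=list(ARCHETYPE_CHROMS),
                    marker_spacing_cM=5.0, seed=seed)
    arch = archetype_architecture(name)
    mp, geno = simulate_map_and_genotypes(cfg)
    table, truth = simulate_phenotypes(mp, geno, arch, cfg)
    means = traits.aggregate_means(table)
    derived = traits.derive_all(means)
    probs = qtl.genotype_probabilities(mp, geno, step_cM=1.0)

    effects = []
    rng = np.random.default_rng(seed + 40)
    trait_names = sorted({t.name for t in arch.traits})
    for trait in trait_names:
        jobs = [("obs", "WW"), ("obs", "WL"), ("d", None)]
        if trait != traits.PHENOLOGY_TRAIT:
            jobs += [("df", "WW"), ("df", "WL"), ("ddf", None)]
        for set_tag, env in jobs:
            if set_tag == "obs":
                y = means[env][trait]
            elif set_tag == "df":
                y = derived.values[f"df{trait}_{env}"]
            elif set_tag == "d":
                y = derived.values[f"d{trait}"]
            else:
                y = derived.values[f"ddf{trait}"]
            thr = qtl.permutation_threshold(
                probs, y, n_perm=n_perm, alpha=alpha,
                seed=int(rng.integers(0, 2**31 - 1)))
            prof = qtl.scan_single(probs, y, trait=trait, set_tag=set_tag,
                                   env=env)
            effects.extend(qtl.effect_summary(prof, thr))

    loci = classify_mod.classify_loci(
        classify_mod.group_colocalized_effects(effects))
    qtl_chrom = arch.qtls[0].chrom
    truth_locus = next(l for l in truth.loci if l.chrom == qtl_chrom)
    detected = [l for l in loci if l.chrom == qtl_chrom]
    if not detected:
        return {"archetype": name, "match": False,
                "truth": _labels(truth_locus), "detected": None}
    best = max(detected, key=lambda l: l.peak_member.lod)
    return {"archetype": name,
            "truth": _labels(truth_locus),
            "detected": _labels(best),
            "n_spurious_loci": len(loci) - 1,
            "match": _labels(truth_locus) == _labels(best)}


def _labels(locus) -> dict:
    return {"phenology": locus.phenology_label,
            "drought": locus.drought_label,
            "strategies": sorted(locus.strategies)}
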