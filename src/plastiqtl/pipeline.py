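"""End-to-end orchestration: simulate -> derive -> buildmap -> scan ->
classify -> genes, driven by one configuration object.

Every stage writes plain-text outputs into the run directory and the
final report JSON records parameters, seeds and a checksum per output
file, so re-running an identical configuration reproduces identical
checksums.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import classify as classify_mod
from . import genes as genes_mod
from . import io, mapping, qtl, simulate, traits

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    In synthetic mode (default) the generator produces all inputs; in
    real-data mode the genotype/phenotype/anchor/GFF paths must exist.
    """

    out_dir: str = "plastiqtl_run"
    seed: int = 0
    # simulation (synthetic mode)
    simulate: bool = True
    sim: dict = field(default_factory=dict)       # SimConfig overrides
    # real-data inputs (used when simulate=False)
    genotypes: Optional[str] = None
    phenotypes: Optional[str] = None
    anchors: Optional[str] = None
    gff: Optional[str] = None
    # stage toggles
    stages: tuple[str, ...] = ("simulate", "derive", "buildmap", "scan",
                               "classify", "genes")
    # map parameters
    max_missing: float = 0.10
    max_distortion_chi2: float = 35.0
    rf_threshold: float = 0.2
    target_groups: int = 14
    # scan parameters
    scan_traits: Optional[list[str]] = None       # None = all traits
    scan_sets: tuple[str, ...] = ("obs", "df", "d", "ddf")
    step_cM: float = 1.0
    n_perm: int = 1000
    n_boot: int = 500
    alpha: float = 0.05
    run_bootstrap: bool = False
    # classification / genes
    similarity_band: tuple[float, float] = (0.5, 2.0)
    max_genes: int = genes_mod.DEFAULT_MAX_GENES

    def validate(self) -> None:
        if not self.simulate:
            for name in ("genotypes", "phenotypes"):
                path = getattr(self, name)
                if "derive" in self.stages or "buildmap" in self.stages:
                    if path is None or not Path(path).exists():
                        raise ValueError(
                            f"real-data mode requires an existing {name} file")
            if "genes" in self.stages:
                for name in ("anchors", "gff"):
                    path = getattr(self, name)
                    if path is None or not Path(path).exists():
                        raise ValueError(
                            f"the genes stage requires an existing {name} file")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        for key in ("stages", "scan_sets", "similarity_band"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)


def _synthetic_anchors(map_df: pd.DataFrame, bp_per_cM: float = 6e5,
                       ) -> pd.DataFrame:
    """Monotone physical anchors for a simulated map (1-based bp)."""
    out = map_df.copy()
    out["bp"] = (out["cM"] * bp_per_cM).round().astype(int) + 1
    return out[["marker", "chrom", "bp"]]


def _synthetic_gff(map_df: pd.DataFrame, path, bp_per_cM: float = 6e5,
                   gene_spacing_bp: int = 250_000,
                   gene_length_bp: int = 3_000) -> None:
    """A gene-grid GFF3 matching the synthetic anchor coordinates."""
    lines = ["##gff-version 3"]
    for chrom, sub in map_df.groupby("chrom", sort=False):
        length = int(sub["cM"].max() * bp_per_cM) + 1
        start = gene_spacing_bp // 2
        k = 0
        for pos in range(start, length, gene_spacing_bp):
            k += 1
            gid = f"gene_{chrom}_{k:05d}"
            lines.append("\t".join([
                str(chrom), "synthetic", "gene", str(pos),
                str(pos + gene_length_bp - 1), ".", "+", ".", f"ID={gid}"]))
    Path(path).write_text("\n".join(lines) + "\n")


def _derivative_series(derived: traits.DerivativeTraitSet, means,
                       trait: str, set_tag: str, env: Optional[str]):
    if set_tag == "obs":
        return means[env][trait]
    if set_tag == "df":
        return derived.values.get(f"df{trait}_{env}")
    if set_tag == "d":
        return derived.values.get(f"d{trait}")
    if set_tag == "ddf":
        return derived.values.get(f"ddf{trait}")
    raise ValueError(f"unknown set tag {set_tag!r}")


def run_all(config: RunConfig) -> dict:
    """Execute all configured stages and write the run report."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": {k: (list(v) if isinstance(v, tuple) else v)
                               for k, v in asdict(config).items()},
                    "stages": {}, "files": {}, "warnings": []}
    t0 = time.time()

    def record(path: Path) -> None:
        report["files"][path.name] = io.file_checksum(path)

    # ---- simulate -------------------------------------------------------
    geno = map_df = table = truth = None
    if "simulate" in config.stages and config.simulate:
        sim_cfg = simulate.SimConfig(seed=config.seed, **config.sim)
        arch = simulate.adapt_architecture(simulate.default_architecture(),
                                           sim_cfg.lengths)
        map_df, clean = simulate.simulate_map_and_genotypes(sim_cfg)
        geno = simulate.corrupt_genotypes(clean, sim_cfg, map_df)
        table, truth = simulate.simulate_phenotypes(map_df, clean, arch,
                                                    sim_cfg)
        io.write_genotypes(geno, out / "genotypes.tsv")
        io.write_map(map_df, out / "map_truth.tsv")
        io.write_phenotypes(table, out / "phenotypes.tsv")
        (out / "truth.json").write_text(truth.to_json())
        anchors = _synthetic_anchors(map_df)
        anchors.to_csv(out / "anchors.tsv", sep="\t", index=False)
        _synthetic_gff(map_df, out / "genes.gff3")
        for name in ("genotypes.tsv", "map_truth.tsv", "phenotypes.tsv",
                     "truth.json", "anchors.tsv", "genes.gff3"):
            record(out / name)
        report["stages"]["simulate"] = {
            "n_lines": sim_cfg.n_lines, "n_markers": geno.shape[1],
            "n_qtls": len(truth.qtls)}
    elif not config.simulate:
        geno = io.read_genotypes(config.genotypes)
        table = io.read_phenotypes(config.phenotypes)

    anchors_path = out / "anchors.tsv" if config.simulate else config.anchors
    gff_path = out / "genes.gff3" if config.simulate else config.gff

    # ---- derive ---------------------------------------------------------
    derived = means = None
    if "derive" in config.stages:
        means = traits.aggregate_means(table)
        derived = traits.derive_all(means)
        derived.values.to_csv(out / "derived_traits.tsv", sep="\t",
                              index_label="line", na_rep="NA")
        fits = {k: f.to_dict() for k, f in derived.fits.items()}
        (out / "fits.json").write_text(json.dumps(fits, indent=1,
                                                  sort_keys=True))
        h2 = {}
        for trait in sorted(table["trait"].unique()):
            try:
                h2[trait] = traits.variance_components_heritability(
                    table, trait).to_dict()
            except ValueError as exc:
                report["warnings"].append(f"heritability {trait}: {exc}")
        (out / "heritability.json").write_text(
            json.dumps(h2, indent=1, sort_keys=True))
        for env in ("WW", "WL"):
            corr, _ = traits.correlation_analysis(means[env])
            corr.to_csv(out / f"correlations_{env}.tsv", sep="\t")
        for name in ("derived_traits.tsv", "fits.json", "heritability.json",
                     "correlations_WW.tsv", "correlations_WL.tsv"):
            record(out / name)
        report["stages"]["derive"] = {"n_derivatives": derived.values.shape[1]}

    # ---- buildmap -------------------------------------------------------
    built = None
    if "buildmap" in config.stages:
        anchor_df = genes_mod.read_anchor_table(anchors_path) \
            if anchors_path and Path(anchors_path).exists() else None
        built = mapping.build_map(
            geno, max_missing=config.max_missing,
            max_distortion_chi2=config.max_distortion_chi2,
            rf_threshold=config.rf_threshold,
            target_groups=config.target_groups, anchors=anchor_df)
        io.write_map(built.table, out / "map_built.tsv")
        diag = mapping.map_diagnostics(geno, built, anchors=anchor_df)
        (out / "map_diagnostics.json").write_text(json.dumps({
            "n_markers": int(len(built.table)),
            "n_groups": len(built.groups),
            "total_length_cM": built.total_length,
            "n_distorted": diag.n_distorted,
            "distorted_by_parent": diag.distorted_by_parent,
            "n_units": diag.n_units,
            "n_units_evaluated": diag.n_units_evaluated,
            "nonrecombinant_proportion": diag.nonrecombinant_proportion,
            "physical_concordance": diag.concordance,
        }, indent=1, sort_keys=True))
        record(out / "map_built.tsv")
        record(out / "map_diagnostics.json")
        report["stages"]["buildmap"] = {
            "n_groups": len(built.groups),
            "total_length_cM": built.total_length}

    # ---- scan -----------------------------------------------------------
    effects = []
    if "scan" in config.stages:
        if built is None or derived is None:
            raise ValueError("scan stage needs buildmap and derive outputs")
        probs = qtl.genotype_probabilities(built, geno, config.step_cM)
        trait_names = config.scan_traits or sorted(table["trait"].unique())
        profiles = []
        rng = np.random.default_rng(config.seed)
        for trait in trait_names:
            jobs = []
            if "obs" in config.scan_sets:
                jobs += [("obs", "WW"), ("obs", "WL")]
            if "df" in config.scan_sets and trait != traits.PHENOLOGY_TRAIT:
                jobs += [("df", "WW"), ("df", "WL")]
            if "d" in config.scan_sets:
                jobs += [("d", None)]
            if "ddf" in config.scan_sets and trait != traits.PHENOLOGY_TRAIT:
                jobs += [("ddf", None)]
            for set_tag, env in jobs:
                y = _derivative_series(derived, means, trait, set_tag, env)
                if y is None or y.notna().sum() < 10:
                    continue
                prof = qtl.scan_single(probs, y, trait=trait,
                                       set_tag=set_tag, env=env)
                thr = qtl.permutation_threshold(
                    probs, y, n_perm=config.n_perm, alpha=config.alpha,
                    seed=int(rng.integers(0, 2**31 - 1)), trait=trait,
                    set_tag=set_tag)
                found = qtl.effect_summary(prof, thr)
                if found:
                    found = qtl.mim_refine(found, probs, y)
                    if config.run_bootstrap:
                        for eff in found:
                            bs = qtl.bootstrap_ci(
                                probs, y, eff.chrom, n_boot=config.n_boot,
                                seed=int(rng.integers(0, 2**31 - 1)))
                            eff.pos_sd = bs.pos_sd
                            eff.additive_sd = bs.additive_sd
                effects.extend(found)
                prof_out = prof.table[["chrom", "cM", "lod"]].copy()
                prof_out.insert(0, "set", set_tag if env is None
                                else f"{set_tag}-{env}")
                prof_out.insert(0, "trait", trait)
                prof_out["threshold"] = thr.lod_threshold
                profiles.append(prof_out)
        if profiles:
            pd.concat(profiles, ignore_index=True).to_csv(
                out / "scan_profiles.tsv", sep="\t", index=False,
                float_format="%.4f")
            record(out / "scan_profiles.tsv")
        io.write_effects(effects, out / "effects.json")
        record(out / "effects.json")
        report["stages"]["scan"] = {"n_effects": len(effects)}

    # ---- classify -------------------------------------------------------
    loci = None
    if "classify" in config.stages and effects:
        loci = classify_mod.group_colocalized_effects(effects)
        classify_mod.classify_loci(loci, config.similarity_band)
        io.write_loci(loci, out / "loci.json")
        classify_mod.summarize_architecture(loci).to_csv(
            out / "architecture_summary.tsv", sep="\t", index=False)
        classify_mod.itv_accounting(loci).to_csv(
            out / "itv_accounting.tsv", sep="\t", index=False)
        for name in ("loci.json", "architecture_summary.tsv",
                     "itv_accounting.tsv"):
            record(out / name)
        report["stages"]["classify"] = {
            "n_loci": len(loci),
            "labels": {l.locus_id: l.phenology_label for l in loci}}

    # ---- genes ----------------------------------------------------------
    if "genes" in config.stages and loci:
        anchor_df = genes_mod.read_anchor_table(anchors_path)
        gene_df = genes_mod.read_gff3_genes(gff_path)
        rows = []
        for locus in loci:
            try:
                interval = genes_mod.qtl_physical_interval(
                    locus, built, anchor_df)
            except ValueError as exc:
                report["warnings"].append(f"genes {locus.locus_id}: {exc}")
                continue
            genes_mod.genes_in_interval(interval, gene_df, config.max_genes)
            rows.append(vars(interval))
        pd.DataFrame(rows).to_csv(out / "qtl_intervals.tsv", sep="\t",
                                  index=False)
        record(out / "qtl_intervals.tsv")
        report["stages"]["genes"] = {"n_intervals": len(rows)}

    report["runtime_s"] = round(time.time() - t0, 2)
    (out / "report.json").write_text(json.dumps(report, indent=1,
                                                sort_keys=True))
    return report
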