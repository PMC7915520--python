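"""Synthetic RIL population generator with a known QTL architecture.

The generator emulates the statistical structure of a biparental durum ×
wild emmer recombinant-inbred-line study: 150 F6 lines genotyped on a
14-chromosome skeleton map of ~1369 loci, phenotyped for 17 traits in
three replicates under two irrigation regimes (well-watered WW and
water-limited WL).  The phenology trait (days to heading, DP-H) is
simulated first from its own QTLs and then feeds into every downstream
trait through a per-trait coupling slope, so heading-mediated,
environment-specific and plasticity QTL effects all have known ground
truth for parameter-recovery tests.

Genotypes are two-state homozygous calls: ``A`` for the domesticated
parent (P1, dosage -1) and ``B`` for the wild parent (P2, dosage +1).
Chromosomes are simulated as a Markov crossover process on the meiotic
scale (Kosambi map function, no extra interference) with the selfed-RIL
correction R = 2r/(1+2r) applied to adjacent-marker recombination.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import classify as _rules
from .linkage import ril_r_from_cm
from .model import P1, P2, QTLEffect, QTLLocus

PHENOLOGY_TRAIT = _rules.PHENOLOGY_TRAIT
ENVIRONMENTS = ("WW", "WL")

#: tetraploid wheat chromosome names (A and B genomes)
DEFAULT_CHROMOSOMES = tuple(f"{i}{g}" for g in "AB" for i in range(1, 8))

#: per-chromosome map lengths (cM); totals 1835.7 cM with the shortest
#: group at 84.6 and the longest at 165.3, matching a dense skeleton map
#: of a durum x wild emmer RIL population
DEFAULT_CHROM_LENGTHS = (
    138.3, 143.0, 141.4, 123.5, 152.8, 118.0, 136.1,   # A genome: 953.1
    129.2, 140.5, 139.9, 84.6, 165.3, 95.0, 128.1,     # B genome: 882.6
)


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class SimConfig:
    """Population design of the simulated RIL study."""

    n_lines: int = 150
    n_chromosomes: int = 14
    chrom_lengths_cM: Sequence[float] = DEFAULT_CHROM_LENGTHS
    chrom_names: Sequence[str] = DEFAULT_CHROMOSOMES
    marker_spacing_cM: float = 1.355
    missing_rate: float = 0.0
    #: chromosome name -> allele-frequency shift in [0, 0.5); positive
    #: values favor the wild parent (P2), negative the domesticated one
    distortion: Optional[dict[str, float]] = None
    seed: int = 0
    replicates_per_env: int = 3

    def __post_init__(self) -> None:
        if self.n_lines < 2:
            raise ConfigError("n_lines must be >= 2")
        self.chrom_lengths_cM = tuple(self.chrom_lengths_cM)[: self.n_chromosomes]
        self.chrom_names = tuple(self.chrom_names)[: self.n_chromosomes]
        if len(self.chrom_lengths_cM) != self.n_chromosomes:
            raise ConfigError("need one map length per chromosome")
        if len(self.chrom_names) != self.n_chromosomes:
            raise ConfigError("need one name per chromosome")
        if any(l <= 0 for l in self.chrom_lengths_cM):
            raise ConfigError("chromosome map lengths must be positive")
        if not 0 <= self.missing_rate < 1:
            raise ConfigError("missing_rate must lie in [0, 1)")
        if self.marker_spacing_cM <= 0:
            raise ConfigError("marker_spacing_cM must be positive")
        for chrom, shift in (self.distortion or {}).items():
            if chrom not in self.chrom_names:
                raise ConfigError(f"distortion names unknown chromosome {chrom!r}")
            if not abs(shift) < 0.5:
                raise ConfigError("distortion shift must satisfy |shift| < 0.5")

    @property
    def lengths(self) -> dict[str, float]:
        return dict(zip(self.chrom_names, self.chrom_lengths_cM))


@dataclass
class QTLSpec:
    """A true additive QTL acting on one trait."""

    trait: str
    chrom: str
    pos_cM: float
    effect_ww: float   # additive effect (half homozygote difference), + toward P2
    effect_wl: float


@dataclass
class TraitSpec:
    """One trait of the architecture.

    ``phenology_coupling`` is the slope of the trait's dependence on the
    line's genetic heading-date deviation, applied within each
    environment; it is what makes heading-mediated QTL effects possible.
    """

    name: str
    group: str = "yield"       # yield / biomass / morphology / DAT / phenology
    intercept: float = 0.0
    phenology_coupling: float = 0.0
    noise_sd: dict[str, float] = field(default_factory=lambda: {"WW": 1.0, "WL": 1.0})


@dataclass
class TraitArchitecture:
    traits: list[TraitSpec]
    qtls: list[QTLSpec]

    def __post_init__(self) -> None:
        names = [t.name for t in self.traits]
        if len(set(names)) != len(names):
            raise ConfigError("duplicate trait names")
        known = set(names)
        for q in self.qtls:
            if q.trait not in known:
                raise ConfigError(f"QTL targets unknown trait {q.trait!r}")
        if any(t.phenology_coupling != 0 for t in self.traits):
            if PHENOLOGY_TRAIT not in known:
                raise ConfigError(
                    f"phenology coupling requires a {PHENOLOGY_TRAIT} trait")

    def validate_positions(self, lengths: dict[str, float]) -> None:
        for q in self.qtls:
            if q.chrom not in lengths:
                raise ConfigError(f"QTL on unknown chromosome {q.chrom!r}")
            if not 0 <= q.pos_cM <= lengths[q.chrom]:
                raise ConfigError(
                    f"QTL at {q.pos_cM} cM outside chromosome {q.chrom} "
                    f"(length {lengths[q.chrom]} cM)")


@dataclass
class TrueQTL:
    """Ground truth for one simulated QTL, including mediation bookkeeping."""

    trait: str
    chrom: str
    pos_cM: float
    marker: str                # marker the effect was applied at
    direct_ww: float
    direct_wl: float
    mediated_ww: float         # coupling x (heading QTL effect at this position)
    mediated_wl: float

    @property
    def total_ww(self) -> float:
        return self.direct_ww + self.mediated_ww

    @property
    def total_wl(self) -> float:
        return self.direct_wl + self.mediated_wl


@dataclass
class TruthRegistry:
    """The simulator's ground-truth architecture plus expected labels.

    Expected classification labels are derived from the architecture with
    the *same* rule functions the classifier applies to detected effects,
    so the registry is self-consistent with the classification module by
    construction.
    """

    qtls: list[TrueQTL]
    loci: list[QTLLocus]       # expected loci built from the architecture

    def to_json(self) -> str:
        return json.dumps({
            "qtls": [vars(q) for q in self.qtls],
            "loci": [l.to_dict() for l in self.loci],
        }, indent=1)

    @property
    def expected_labels(self) -> dict[str, dict]:
        return {l.locus_id: {"phenology": l.phenology_label,
                             "drought": l.drought_label,
                             "strategies": sorted(l.strategies)}
                for l in self.loci}


# ---------------------------------------------------------------------------
# genotypes and map

def _marker_positions(length: float, spacing: float) -> np.ndarray:
    n = max(2, int(round(length / spacing)) + 1)
    return np.linspace(0.0, length, n)


def simulate_map_and_genotypes(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the skeleton map and fully homozygous RIL genotypes.

    Returns ``(map_df, geno)`` where ``map_df`` has columns
    ``marker, chrom, cM`` and ``geno`` is a lines x markers DataFrame of
    ``A``/``B`` calls (no missing data; apply :func:`corrupt_genotypes`
    for missingness and segregation distortion).
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    width = max(3, len(str(config.n_lines)))
    lines = [f"RIL{i + 1:0{width}d}" for i in range(config.n_lines)]

    map_rows = []
    geno_blocks = []
    for chrom, length in zip(config.chrom_names, config.chrom_lengths_cM):
        pos = _marker_positions(length, config.marker_spacing_cM)
        markers = [f"{chrom}_M{j + 1:04d}" for j in range(len(pos))]
        map_rows.append(pd.DataFrame({"marker": markers, "chrom": chrom, "cM": pos}))

        R = ril_r_from_cm(np.diff(pos))                       # adjacent RIL recomb.
        start = rng.integers(0, 2, size=config.n_lines) * 2 - 1
        flips = rng.random((config.n_lines, len(pos) - 1)) < R[None, :]
        sign = np.cumprod(np.where(flips, -1, 1), axis=1)
        dosage = np.column_stack([start, start[:, None] * sign])
        geno_blocks.append(pd.DataFrame(
            np.where(dosage > 0, "B", "A"), index=lines, columns=markers))

    map_df = pd.concat(map_rows, ignore_index=True)
    geno = pd.concat(geno_blocks, axis=1)
    return map_df, geno


def corrupt_genotypes(geno: pd.DataFrame, config: SimConfig,
                      map_df: Optional[pd.DataFrame] = None) -> pd.DataFrame:
    """Apply missingness and segregation distortion to clean genotypes.

    Missing calls are introduced uniformly at random at
    ``config.missing_rate``.  On chromosomes with a distortion shift *s*,
    each line's whole chromosome is replaced by the favored parental
    allele with probability ``2|s|``, which moves the expected allele
    frequency from 0.5 to 0.5 + |s| (a selection-like mechanism that
    preserves linkage among the remaining lines).  ``map_df`` is required
    when distortion is configured, to resolve marker -> chromosome.
    """
    out = geno.copy()
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(2)[1])

    if config.distortion:
        if map_df is None:
            raise ConfigError("distortion requires the marker map")
        chrom_of = dict(zip(map_df["marker"], map_df["chrom"]))
        for chrom, shift in config.distortion.items():
            cols = [m for m in out.columns if chrom_of.get(m) == chrom]
            if not cols:
                continue
            favored = "B" if shift > 0 else "A"
            take = rng.random(len(out)) < 2 * abs(shift)
            out.loc[take, cols] = favored

    if config.missing_rate > 0:
        mask = rng.random(out.shape) < config.missing_rate
        vals = out.to_numpy(dtype=object)
        vals[mask] = np.nan
        out = pd.DataFrame(vals, index=out.index, columns=out.columns)
    return out


def dosage_matrix(geno: pd.DataFrame) -> pd.DataFrame:
    """Numeric dosage view: A -> -1, B -> +1, missing -> NaN."""
    arr = geno.to_numpy(dtype=object)
    out = np.full(arr.shape, np.nan)
    out[arr == "A"] = -1.0
    out[arr == "B"] = 1.0
    return pd.DataFrame(out, index=geno.index, columns=geno.columns)


# ---------------------------------------------------------------------------
# phenotypes

def _nearest_marker(map_df: pd.DataFrame, chrom: str, pos: float) -> str:
    sub = map_df[map_df["chrom"] == chrom]
    if sub.empty:
        raise ConfigError(f"no markers on chromosome {chrom!r}")
    idx = (sub["cM"] - pos).abs().idxmin()
    return str(sub.loc[idx, "marker"])


def simulate_phenotypes(map_df: pd.DataFrame, geno: pd.DataFrame,
                        arch: TraitArchitecture, config: SimConfig,
                        ) -> tuple[pd.DataFrame, TruthRegistry]:
    """Simulate replicate-level phenotypes under both irrigation regimes.

    The heading trait is generated first: its per-line genetic value is
    the sum of its QTL effects at the line's dosages.  Every other trait
    is ``intercept + sum(QTL effects) + coupling * heading_deviation +
    replicate noise``, per environment.  Effects are applied at the
    nearest skeleton marker to the requested position (recorded in the
    truth registry).
    """
    arch.validate_positions(map_df.groupby("chrom")["cM"].max().to_dict())
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(3)[2])
    dos = dosage_matrix(geno).fillna(0.0)
    lines = geno.index

    # genetic value of heading per environment (deviation from intercept)
    dph_qtls = [q for q in arch.qtls if q.trait == PHENOLOGY_TRAIT]
    snap = {id(q): _nearest_marker(map_df, q.chrom, q.pos_cM) for q in arch.qtls}
    dph_dev = {env: pd.Series(0.0, index=lines) for env in ENVIRONMENTS}
    for q in dph_qtls:
        d = dos[snap[id(q)]]
        dph_dev["WW"] += q.effect_ww * d
        dph_dev["WL"] += q.effect_wl * d

    # heading effect available for mediation at each (chrom, marker)
    dph_at = {}
    for q in dph_qtls:
        key = (q.chrom, snap[id(q)])
        ww, wl = dph_at.get(key, (0.0, 0.0))
        dph_at[key] = (ww + q.effect_ww, wl + q.effect_wl)

    records = []
    truths: list[TrueQTL] = []
    by_trait = {t.name: [] for t in arch.traits}
    for q in arch.qtls:
        by_trait[q.trait].append(q)

    marker_pos = dict(zip(map_df["marker"], map_df["cM"]))
    for tspec in arch.traits:
        coupling = tspec.phenology_coupling if tspec.name != PHENOLOGY_TRAIT else 0.0
        for env in ENVIRONMENTS:
            g = pd.Series(tspec.intercept, index=lines, dtype=float)
            for q in by_trait[tspec.name]:
                eff = q.effect_ww if env == "WW" else q.effect_wl
                g = g + eff * dos[snap[id(q)]]
            g = g + coupling * dph_dev[env]
            sd = tspec.noise_sd[env] if isinstance(tspec.noise_sd, dict) else float(tspec.noise_sd)
            for rep in range(1, config.replicates_per_env + 1):
                noise = rng.normal(0.0, sd, size=len(lines))
                for line, val in zip(lines, g.to_numpy() + noise):
                    records.append((line, env, rep, tspec.name, val))

        # truth covers every position where the trait has an effect: its
        # direct QTLs plus, for coupled traits, every heading QTL locus
        # (a heading-mediated effect with no direct component)
        direct_at: dict[tuple[str, str], tuple[float, float]] = {}
        for q in by_trait[tspec.name]:
            key = (q.chrom, snap[id(q)])
            ww, wl = direct_at.get(key, (0.0, 0.0))
            direct_at[key] = (ww + q.effect_ww, wl + q.effect_wl)
        loci_keys = set(direct_at)
        if coupling != 0.0:
            loci_keys |= set(dph_at)
        for chrom, mk in sorted(loci_keys):
            dir_ww, dir_wl = direct_at.get((chrom, mk), (0.0, 0.0))
            if tspec.name == PHENOLOGY_TRAIT:
                med_ww = med_wl = 0.0
            else:
                dww, dwl = dph_at.get((chrom, mk), (0.0, 0.0))
                med_ww = coupling * dww
                med_wl = coupling * dwl
            truths.append(TrueQTL(
                trait=tspec.name, chrom=chrom, pos_cM=float(marker_pos[mk]),
                marker=mk, direct_ww=dir_ww, direct_wl=dir_wl,
                mediated_ww=med_ww, mediated_wl=med_wl))

    table = pd.DataFrame(records,
                         columns=["line", "env", "replicate", "trait", "value"])
    registry = TruthRegistry(qtls=truths, loci=expected_loci(truths))
    return table, registry


# ---------------------------------------------------------------------------
# expected effects and labels

_EFFECT_TOL = 1e-9
_TRUTH_SUPPORT_HALF_WIDTH = 5.0   # nominal support half-width for truth loci


def expected_effects(truths: Sequence[TrueQTL]) -> list[QTLEffect]:
    """Translate true QTLs into the effects an ideal scan would report.

    Per derivative set, a true QTL produces an effect when:

    * ``obs`` (per env): the total (direct + heading-mediated) effect in
      that environment is nonzero;
    * ``df`` (per env): the direct effect survives the heading adjustment;
    * ``d`` (plasticity I): the total WL effect differs from the total WW
      effect (equal effects cancel in the WL-on-WW residual, assuming the
      population regression slope is ~1, which holds for the symmetric
      architectures simulated here);
    * ``ddf`` (plasticity II): the *direct* WL and WW effects differ, i.e.
      environment-specificity that is not mediated by heading.

    Nominal LOD/PEV proxies are filled from squared standardized effects so
    that the similarity-ratio rule behaves as it would on detected effects.
    """
    out: list[QTLEffect] = []

    def add(trait, set_tag, env, tq: TrueQTL, a: float) -> None:
        lo = max(0.0, tq.pos_cM - _TRUTH_SUPPORT_HALF_WIDTH)
        hi = tq.pos_cM + _TRUTH_SUPPORT_HALF_WIDTH
        out.append(QTLEffect(
            trait=trait, set_tag=set_tag, env=env, chrom=tq.chrom,
            pos_cM=tq.pos_cM, lod=abs(a), additive=a, pev=min(1.0, a * a),
            support=(lo, hi), model="truth"))

    for tq in truths:
        if abs(tq.total_ww) > _EFFECT_TOL:
            add(tq.trait, "obs", "WW", tq, tq.total_ww)
        if abs(tq.total_wl) > _EFFECT_TOL:
            add(tq.trait, "obs", "WL", tq, tq.total_wl)
        if tq.trait != PHENOLOGY_TRAIT:
            if abs(tq.direct_ww) > _EFFECT_TOL:
                add(tq.trait, "df", "WW", tq, tq.direct_ww)
            if abs(tq.direct_wl) > _EFFECT_TOL:
                add(tq.trait, "df", "WL", tq, tq.direct_wl)
        if abs(tq.total_wl - tq.total_ww) > _EFFECT_TOL:
            add(tq.trait, "d", None, tq, tq.total_wl - tq.total_ww)
        if tq.trait != PHENOLOGY_TRAIT and \
                abs(tq.direct_wl - tq.direct_ww) > _EFFECT_TOL:
            add(tq.trait, "ddf", None, tq, tq.direct_wl - tq.direct_ww)
    return out


def expected_loci(truths: Sequence[TrueQTL]) -> list[QTLLocus]:
    """Group expected effects into loci and label them with the classifier."""
    loci = _rules.group_colocalized_effects(expected_effects(truths))
    return _rules.classify_loci(loci)


#: archetype fixtures covering the four canonical locus classes
ARCHETYPES = ("escape", "avoidance", "tolerance", "suppressed")

#: genome used by the archetype fixtures: two 60 cM chromosomes
ARCHETYPE_CHROMS = ("7B", "2A")
ARCHETYPE_LENGTHS = (60.0, 60.0)


def archetype_architecture(name: str) -> TraitArchitecture:
    """A minimal architecture realizing one locus archetype.

    * ``escape`` — a heading QTL that acts more strongly under water
      limitation drives grain yield through negative coupling: the yield
      locus shows a plasticity-I effect but no plasticity-II effect.
    * ``avoidance`` — a WL-specific carbon-isotope-ratio QTL.
    * ``tolerance`` — a WL-specific osmotic-potential QTL whose wild
      allele lowers OP (the resistance direction).
    * ``suppressed`` — a heading QTL with equal effects in both regimes
      whose downstream kernel-weight effect is entirely
      heading-mediated, hence fully suppressed after adjustment.

    The fixtures use high-heritability noise settings: measurement error
    in the line means attenuates the residual regressions
    (errors-in-variables) and would otherwise leak a sliver of a
    structurally absent effect into the plasticity scans.
    """
    dph = TraitSpec("DP-H", "phenology", 55.0, 0.0,
                    {"WW": 0.2, "WL": 0.2})
    if name == "escape":
        return TraitArchitecture(
            traits=[dph,
                    TraitSpec("GY", "yield", 20.0, -0.6,
                              {"WW": 0.6, "WL": 0.6})],
            qtls=[QTLSpec("DP-H", "7B", 30.0, -1.0, -2.0)])
    if name == "avoidance":
        return TraitArchitecture(
            traits=[dph, TraitSpec("d13C", "DAT", -28.0, 0.0,
                                   {"WW": 0.6, "WL": 0.6})],
            qtls=[QTLSpec("d13C", "2A", 30.0, 0.0, 1.2)])
    if name == "tolerance":
        return TraitArchitecture(
            traits=[dph, TraitSpec("OP", "DAT", -1.5, 0.0,
                                   {"WW": 0.5, "WL": 0.5})],
            qtls=[QTLSpec("OP", "2A", 30.0, 0.0, -1.2)])
    if name == "suppressed":
        return TraitArchitecture(
            traits=[dph, TraitSpec("TKW", "yield", 35.0, -0.6,
                                   {"WW": 0.2, "WL": 0.2})],
            qtls=[QTLSpec("DP-H", "7B", 30.0, -1.5, -1.5)])
    raise ConfigError(f"unknown archetype {name!r}; "
                      f"choose one of {ARCHETYPES}")


def adapt_architecture(arch: TraitArchitecture,
                       lengths: dict[str, float]) -> TraitArchitecture:
    """Fit an architecture onto a (possibly smaller) simulated genome.

    QTLs on absent chromosomes are reassigned round-robin over the
    available ones and positions are clamped into the chromosome length,
    so the default architecture stays usable on reduced test genomes.
    """
    chroms = list(lengths)
    qtls = []
    k = 0
    for q in arch.qtls:
        chrom = q.chrom
        if chrom not in lengths:
            chrom = chroms[k % len(chroms)]
            k += 1
        pos = min(q.pos_cM, lengths[chrom])
        qtls.append(QTLSpec(q.trait, chrom, pos, q.effect_ww, q.effect_wl))
    return TraitArchitecture(traits=arch.traits, qtls=qtls)


# ---------------------------------------------------------------------------
# default study-like architecture

def default_architecture() -> TraitArchitecture:
    """A 17-trait architecture emulating the study's causal structure.

    Trait groups: yield (GY, TKW, KNSP, HI), biomass (SpDM, VegDM,
    TotDM), morphology (CL, SpL, FLL, FLW), drought-adaptive (d13C, OP,
    Chl, LR) and phenology (DP-H, DH-M).  A major heading QTL on 7B
    drives downstream traits through negative coupling (earlier heading
    under stress increases yield: drought escape); further QTLs provide
    non-plastic, WL-specific (avoidance/tolerance) and
    phenology-suppressed archetypes.  Noise SDs give line-mean
    heritabilities in the 0.6-0.8 range typical of field trials.
    """
    sd1 = {"WW": 1.0, "WL": 1.0}
    traits = [
        TraitSpec("DP-H", "phenology", 55.0, 0.0, {"WW": 1.0, "WL": 1.0}),
        TraitSpec("DH-M", "phenology", 40.0, -0.8, sd1.copy()),
        TraitSpec("GY", "yield", 20.0, -0.6, sd1.copy()),
        TraitSpec("TKW", "yield", 35.0, -0.4, sd1.copy()),
        TraitSpec("KNSP", "yield", 30.0, -0.3, sd1.copy()),
        TraitSpec("HI", "yield", 0.4, -0.2, {"WW": 0.5, "WL": 0.5}),
        TraitSpec("SpDM", "biomass", 10.0, -0.3, sd1.copy()),
        TraitSpec("VegDM", "biomass", 15.0, 0.2, sd1.copy()),
        TraitSpec("TotDM", "biomass", 25.0, 0.2, sd1.copy()),
        TraitSpec("CL", "morphology", 80.0, 0.3, sd1.copy()),
        TraitSpec("SpL", "morphology", 7.0, 0.0, {"WW": 0.6, "WL": 0.6}),
        TraitSpec("FLL", "morphology", 20.0, 0.0, sd1.copy()),
        TraitSpec("FLW", "morphology", 12.0, 0.0, sd1.copy()),
        TraitSpec("d13C", "DAT", -28.0, 0.0, {"WW": 0.6, "WL": 0.6}),
        TraitSpec("OP", "DAT", -1.5, 0.0, {"WW": 0.5, "WL": 0.5}),
        TraitSpec("Chl", "DAT", 45.0, 0.0, sd1.copy()),
        TraitSpec("LR", "DAT", 2.0, 0.0, {"WW": 0.7, "WL": 0.7}),
    ]
    qtls = [
        # major heading QTL on 7B, stronger under water limitation: the
        # wild allele heads earlier (negative effect) in both regimes
        QTLSpec("DP-H", "7B", 30.0, -1.2, -1.8),
        # second heading QTL
        QTLSpec("DP-H", "5A", 80.0, 0.8, 0.8),
        # non-plastic yield QTL: equal direct effects in both regimes
        QTLSpec("TKW", "6A", 50.0, 1.0, 1.0),
        # WL-specific avoidance QTL on carbon-isotope ratio
        QTLSpec("d13C", "4A", 60.0, 0.0, 0.9),
        # tolerance QTL: wild allele lowers osmotic potential under stress
        QTLSpec("OP", "4B", 40.0, 0.0, -0.8),
        # WL-specific direct yield QTL (plasticity I and II)
        QTLSpec("GY", "2B", 70.0, 0.0, 1.0),
        # morphology QTL, domesticated allele increases leaf width
        QTLSpec("FLW", "1B", 55.0, -0.9, -0.9),
        # leaf-rolling plasticity, domesticated allele
        QTLSpec("LR", "7A", 90.0, 0.0, -0.8),
    ]
    return TraitArchitecture(traits=traits, qtls=qtls)
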