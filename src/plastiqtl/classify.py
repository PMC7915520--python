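"""Rule-based classification of co-localized QTL effects.

Trait-level effects detected by the scans are grouped into loci when their
1.5-LOD support intervals overlap on the same chromosome.  Each locus is
then labelled along two axes and mapped onto drought-resistance strategies:

* **phenology** — how the locus relates to heading-date variation:
  ``associated`` (acts on heading itself, or its trait effects vanish once
  traits are adjusted for heading), ``plastic`` (effects appear only on the
  heading-adjusted traits, or observed/adjusted effects differ materially),
  or ``non-plastic`` (observed and adjusted effects co-occur and are
  similar);
* **drought** — ``plastic`` when the locus affects any drought-plasticity
  residual trait (plasticity I or II), else ``non-plastic``;
* **strategy** — ``escape`` (plasticity-I effect with no matching
  plasticity-II effect, i.e. the stress response is mediated by earlier
  heading), ``avoidance`` (carbon-isotope ratio or leaf rolling),
  ``tolerance`` (osmotic potential or chlorophyll content).

All labels are pure functions of the member effects, so re-running the
classifier on serialized loci reproduces them exactly.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .model import P1, P2, QTLEffect, QTLLocus

#: the phenology trait driving the adjustment regressions
PHENOLOGY_TRAIT = "DP-H"

#: drought-adaptive traits mapped to resistance strategies
TOLERANCE_TRAITS = frozenset({"OP", "Chl"})
AVOIDANCE_TRAITS = frozenset({"d13C", "LR"})

#: observed/adjusted effects count as "similar" when the ITV parent matches
#: and the standardized-effect ratio lies within this band
DEFAULT_SIMILARITY_BAND = (0.5, 2.0)

PHENOLOGY_LABELS = ("non-plastic", "plastic", "associated", "not-applicable")
DROUGHT_LABELS = ("non-plastic", "plastic")
STRATEGIES = ("escape", "avoidance", "tolerance", "none")


def group_colocalized_effects(effects: Iterable[QTLEffect]) -> list[QTLLocus]:
    """Single-linkage grouping of effects by support-interval overlap.

    Effects on the same chromosome whose closed support intervals overlap
    (directly or through a chain of overlaps) form one locus.  Locus ids
    are ``<chrom>.<k>`` with ``k`` assigned in cM order along the
    chromosome; the result is invariant to the input order of effects.
    """
    by_chrom: dict[str, list[QTLEffect]] = defaultdict(list)
    for eff in effects:
        by_chrom[eff.chrom].append(eff)

    loci: list[QTLLocus] = []
    for chrom in sorted(by_chrom):
        members = sorted(by_chrom[chrom],
                         key=lambda e: (e.support[0], e.support[1], e.label))
        clusters: list[list[QTLEffect]] = []
        cur: list[QTLEffect] = []
        cur_hi = -np.inf
        for eff in members:
            lo, hi = eff.support
            if cur and lo <= cur_hi:
                cur.append(eff)
                cur_hi = max(cur_hi, hi)
            else:
                if cur:
                    clusters.append(cur)
                cur = [eff]
                cur_hi = hi
        if cur:
            clusters.append(cur)
        for k, cluster in enumerate(clusters, start=1):
            lo = min(e.support[0] for e in cluster)
            hi = max(e.support[1] for e in cluster)
            loci.append(QTLLocus(locus_id=f"{chrom}.{k}", chrom=chrom,
                                 members=cluster, support=(lo, hi)))
    return loci


def _standardized_effect(eff: QTLEffect) -> float:
    # sqrt(PEV) is proportional to |a|/sd(trait) for a balanced biparental
    # design, which makes effects comparable across the obs and df scales
    return float(np.sqrt(max(eff.pev, 0.0)))


def _similar(obs: QTLEffect, df: QTLEffect,
             band: tuple[float, float]) -> bool:
    if obs.itv != df.itv:
        return False
    so, sd = _standardized_effect(obs), _standardized_effect(df)
    if so == 0 or sd == 0:
        return False
    ratio = sd / so
    return band[0] <= ratio <= band[1]


def classify_phenology(locus: QTLLocus,
                       similarity_band: tuple[float, float] = DEFAULT_SIMILARITY_BAND,
                       ) -> str:
    """Label a locus relative to heading-date variation.

    Precedence when member traits trigger different rules:
    associated > plastic > non-plastic.
    """
    obs = [m for m in locus.members if m.set_tag == "obs"]
    df = [m for m in locus.members if m.set_tag == "df"]
    if not obs and not df:
        return "not-applicable"

    def df_match(trait: str, env) -> QTLEffect | None:
        for m in df:
            if m.trait == trait and (m.env is None or env is None or m.env == env):
                return m
        return None

    def obs_match(trait: str, env) -> QTLEffect | None:
        for m in obs:
            if m.trait == trait and (m.env is None or env is None or m.env == env):
                return m
        return None

    # associated: acts on heading itself, or full suppression of some
    # observed effect after the heading adjustment
    if any(m.trait == PHENOLOGY_TRAIT for m in locus.members):
        return "associated"
    for m in obs:
        if m.trait == PHENOLOGY_TRAIT:
            continue
        if df_match(m.trait, m.env) is None:
            return "associated"

    # plastic: an adjusted-trait effect with no observed counterpart, or an
    # observed/adjusted pair whose effects are not similar
    for m in df:
        if obs_match(m.trait, m.env) is None:
            return "plastic"
    for m in obs:
        partner = df_match(m.trait, m.env)
        if partner is not None and not _similar(m, partner, similarity_band):
            return "plastic"

    return "non-plastic"


def classify_drought_plasticity(locus: QTLLocus) -> str:
    """``plastic`` when any member is a plasticity-I/II residual effect."""
    if any(m.set_tag in ("d", "ddf") for m in locus.members):
        return "plastic"
    return "non-plastic"


def assign_strategy(locus: QTLLocus) -> set[str]:
    """Map a locus onto drought-resistance strategies (possibly several)."""
    strategies: set[str] = set()
    traits = locus.traits
    if traits & TOLERANCE_TRAITS:
        strategies.add("tolerance")
    if traits & AVOIDANCE_TRAITS:
        strategies.add("avoidance")
    d_traits = {m.trait for m in locus.members if m.set_tag == "d"}
    ddf_traits = {m.trait for m in locus.members if m.set_tag == "ddf"}
    if d_traits - ddf_traits:
        strategies.add("escape")
    return strategies or {"none"}


def resistance_allele(effect: QTLEffect) -> str:
    """Parent allele conferring drought resistance for this effect.

    For osmotic potential lower values indicate better osmotic adjustment,
    so the resistance allele is the value-decreasing one (the opposite of
    the increasing-trait-value parent); for all other traits the ITV
    allele is returned unchanged.
    """
    if effect.trait == "OP":
        return P1 if effect.itv == P2 else P2
    return effect.itv


def classify_loci(loci: Sequence[QTLLocus],
                  similarity_band: tuple[float, float] = DEFAULT_SIMILARITY_BAND,
                  ) -> list[QTLLocus]:
    """Apply all three label rules to every locus, in place."""
    for locus in loci:
        locus.phenology_label = classify_phenology(locus, similarity_band)
        locus.drought_label = classify_drought_plasticity(locus)
        locus.strategies = assign_strategy(locus)
    return list(loci)


def itv_accounting(loci: Sequence[QTLLocus]) -> pd.DataFrame:
    """Per-trait, per-parent counts and summed PEV of plasticity effects.

    When plasticity-I and plasticity-II effects for the same trait
    co-locate within one locus, only the higher-PEV one contributes.
    """
    rows: dict[tuple[str, str], dict[str, float]] = defaultdict(
        lambda: {"n_effects": 0, "total_pev": 0.0})
    for locus in loci:
        plastic = [m for m in locus.members if m.set_tag in ("d", "ddf")]
        by_trait: dict[str, list[QTLEffect]] = defaultdict(list)
        for m in plastic:
            by_trait[m.trait].append(m)
        for trait, effs in by_trait.items():
            best = max(effs, key=lambda e: e.pev)
            rec = rows[(trait, best.itv)]
            rec["n_effects"] += 1
            rec["total_pev"] += best.pev
    out = pd.DataFrame(
        [{"trait": t, "itv_parent": p, **v} for (t, p), v in sorted(rows.items())],
        columns=["trait", "itv_parent", "n_effects", "total_pev"],
    )
    return out


def summarize_architecture(loci: Sequence[QTLLocus]) -> pd.DataFrame:
    """Per-trait locus counts in a summary-table layout.

    One row per trait: total / multi-trait / single-trait locus counts,
    LOD range over the trait's effects, ITV-parent counts (by the
    highest-LOD member effect per locus), environment specificity of the
    observed effects, and phenology/drought category counts.
    """
    per_trait: dict[str, dict] = {}
    for locus in loci:
        for trait in locus.traits:
            rec = per_trait.setdefault(trait, {
                "trait": trait, "n_loci": 0, "n_multi_trait": 0,
                "n_single_trait": 0, "lod_min": np.inf, "lod_max": -np.inf,
                "itv_P1": 0, "itv_P2": 0, "env_WL": 0, "env_WW": 0,
                "phen_associated": 0, "phen_plastic": 0, "phen_non_plastic": 0,
                "drought_plastic": 0, "drought_non_plastic": 0,
            })
            effs = [m for m in locus.members if m.trait == trait]
            rec["n_loci"] += 1
            rec["n_multi_trait" if locus.multi_trait else "n_single_trait"] += 1
            rec["lod_min"] = min(rec["lod_min"], min(m.lod for m in effs))
            rec["lod_max"] = max(rec["lod_max"], max(m.lod for m in effs))
            best = max(effs, key=lambda m: m.lod)
            rec["itv_P1" if best.itv == P1 else "itv_P2"] += 1
            envs = {m.env for m in effs if m.set_tag in ("obs", "df") and m.env}
            if envs == {"WL"}:
                rec["env_WL"] += 1
            elif envs == {"WW"}:
                rec["env_WW"] += 1
            if locus.phenology_label == "associated":
                rec["phen_associated"] += 1
            elif locus.phenology_label == "plastic":
                rec["phen_plastic"] += 1
            elif locus.phenology_label == "non-plastic":
                rec["phen_non_plastic"] += 1
            if locus.drought_label == "plastic":
                rec["drought_plastic"] += 1
            elif locus.drought_label == "non-plastic":
                rec["drought_non_plastic"] += 1
    df = pd.DataFrame(sorted(per_trait.values(), key=lambda r: r["trait"]))
    if df.empty:
        df = pd.DataFrame(columns=[
            "trait", "n_loci", "n_multi_trait", "n_single_trait", "lod_min",
            "lod_max", "itv_P1", "itv_P2", "env_WL", "env_WW",
            "phen_associated", "phen_plastic", "phen_non_plastic",
            "drought_plastic", "drought_non_plastic"])
    return df
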