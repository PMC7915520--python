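"""Skeleton genetic-map construction and diagnostics for RIL genotypes.

The workflow mirrors the classical ultra-dense mapping recipe for
biparental inbred populations:

1. marker QC — drop markers with excessive missingness or extreme
   segregation distortion (chi-square against the 1:1 Mendelian ratio);
2. pairwise recombination-fraction (RF) estimation over informative
   lines, truncated at 0.5;
3. binning of fully co-segregating markers, keeping one skeleton marker
   per bin (least missing, ties broken by identifier);
4. single-linkage clustering into linkage groups at an RF threshold,
   with end-to-end merging down to the expected chromosome number;
5. per-group marker ordering (greedy nearest-neighbour seeded at the
   most distal marker, improved by 2-opt passes) and cM assignment from
   RIL-corrected adjacent RFs through the Kosambi map function;
6. diagnostics — per-marker distortion tests, the proportion of
   non-recombinant line x group units, and rank-correlation concordance
   with physical marker order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import sparse, stats
from scipy.sparse.csgraph import connected_components

from .linkage import cm_from_ril_r

logger = logging.getLogger(__name__)

_CALLS = {"A", "B"}


def _validate_genotypes(geno: pd.DataFrame) -> None:
    if geno.shape[0] < 2 or geno.shape[1] < 2:
        raise ValueError("genotype matrix needs >= 2 lines and >= 2 markers")
    vals = set(pd.unique(geno.to_numpy().ravel()))
    bad = {v for v in vals if isinstance(v, str) and v not in _CALLS}
    if bad:
        raise ValueError(f"unexpected genotype codes: {sorted(bad)}")


def _dosage(geno: pd.DataFrame) -> np.ndarray:
    """A -> -1, B -> +1, missing -> 0 (uninformative)."""
    arr = geno.to_numpy(dtype=object)
    out = np.zeros(arr.shape, dtype=float)
    out[arr == "A"] = -1.0
    out[arr == "B"] = 1.0
    return out


class EmptyMapError(ValueError):
    """All markers were removed by quality control."""


# ---------------------------------------------------------------------------
# QC

def distortion_chi2(geno: pd.DataFrame) -> pd.DataFrame:
    """Per-marker 1:1 segregation chi-square (df=1) over non-missing calls."""
    d = _dosage(geno)
    n_b = (d > 0).sum(axis=0).astype(float)
    n_a = (d < 0).sum(axis=0).astype(float)
    n = n_a + n_b
    with np.errstate(invalid="ignore", divide="ignore"):
        chi2 = np.where(n > 0, (n_a - n_b) ** 2 / n, np.nan)
    p = stats.chi2.sf(chi2, df=1)
    return pd.DataFrame({
        "n_P1": n_a.astype(int), "n_P2": n_b.astype(int),
        "chi2": chi2, "p": p,
        "favored": np.where(n_a >= n_b, "P1", "P2"),
    }, index=geno.columns)


def qc_filter_markers(geno: pd.DataFrame, max_missing: float = 0.10,
                      max_distortion_chi2: float = 35.0,
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove markers with > ``max_missing`` missing calls or chi2 > threshold.

    Returns the filtered matrix and a per-marker removal report
    (missing fraction, chi2, kept flag).
    """
    if max_missing <= 0 or max_distortion_chi2 <= 0:
        raise ValueError("QC thresholds must be positive")
    _validate_genotypes(geno)
    miss = geno.isna().mean(axis=0)
    chi = distortion_chi2(geno)
    too_missing = miss > max_missing
    too_distorted = chi["chi2"] > max_distortion_chi2
    keep = ~(too_missing | too_distorted)
    report = pd.DataFrame({
        "missing_frac": miss, "chi2": chi["chi2"],
        "removed_missing": too_missing, "removed_distortion": too_distorted,
        "kept": keep})
    if not keep.any():
        raise EmptyMapError("quality control removed every marker")
    n_rm = int((~keep).sum())
    if n_rm:
        logger.info("QC removed %d/%d markers (%d missingness, %d distortion)",
                    n_rm, len(keep), int(too_missing.sum()),
                    int(too_distorted.sum()))
    return geno.loc[:, keep], report


# ---------------------------------------------------------------------------
# recombination fractions

@dataclass
class RFMatrix:
    """Pairwise observed recombination fractions between markers.

    ``rf`` is truncated at 0.5 and NaN where no informative line pairs
    exist; ``raw`` keeps the untruncated recombinant fraction and
    ``counts`` the number of informative lines per pair.
    """

    rf: pd.DataFrame
    counts: pd.DataFrame
    raw: pd.DataFrame

    def loc(self, a: str, b: str) -> float:
        return float(self.rf.loc[a, b])


def estimate_rf_matrix(geno: pd.DataFrame) -> RFMatrix:
    """Estimate RF for every marker pair from shared non-missing lines."""
    _validate_genotypes(geno)
    d = _dosage(geno)
    inf = (d != 0).astype(float)
    counts = inf.T @ inf                    # informative lines per pair
    match_minus_mismatch = d.T @ d
    with np.errstate(invalid="ignore", divide="ignore"):
        recomb = (counts - match_minus_mismatch) / 2.0
        raw = np.where(counts > 0, recomb / counts, np.nan)
    rf = np.minimum(raw, 0.5)
    np.fill_diagonal(rf, 0.0)
    np.fill_diagonal(raw, 0.0)
    mk = geno.columns
    return RFMatrix(
        rf=pd.DataFrame(rf, index=mk, columns=mk),
        counts=pd.DataFrame(counts.astype(int), index=mk, columns=mk),
        raw=pd.DataFrame(raw, index=mk, columns=mk))


# ---------------------------------------------------------------------------
# binning

def bin_skeleton_markers(geno: pd.DataFrame, rf: RFMatrix,
                         ) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Merge fully co-segregating markers (RF = 0 on shared lines) into bins.

    The bin representative (skeleton marker) is the member with the least
    missing data, ties broken by the lexicographically smallest
    identifier.  Returns the skeleton genotype matrix and a mapping
    skeleton -> satellite markers.
    """
    markers = list(geno.columns)
    idx = {m: i for i, m in enumerate(markers)}
    rf_arr = rf.rf.loc[markers, markers].to_numpy()
    cnt = rf.counts.loc[markers, markers].to_numpy()
    adj = sparse.csr_matrix((rf_arr == 0) & (cnt > 0))
    n_comp, labels = connected_components(adj, directed=False)

    miss = geno.isna().mean(axis=0)
    bins: dict[str, list[str]] = {}
    for comp in range(n_comp):
        members = sorted((m for m in markers if labels[idx[m]] == comp),
                         key=lambda m: (miss[m], m))
        skeleton = members[0]
        bins[skeleton] = members[1:]
    skeletons = [m for m in markers if m in bins]   # preserve input order
    return geno.loc[:, skeletons], bins


# ---------------------------------------------------------------------------
# linkage groups

def cluster_linkage_groups(skeleton: pd.DataFrame, rf: RFMatrix,
                           rf_threshold: float = 0.2,
                           target_groups: Optional[int] = None,
                           ) -> list[list[str]]:
    """Single-linkage clustering of skeleton markers at ``RF <= threshold``.

    If more groups emerge than ``target_groups``, the pair of groups with
    the smallest end-to-end RF (minimum RF between members of the two
    groups) is merged repeatedly until the target is reached.  Fewer
    natural groups than the target only triggers a warning.
    """
    if not 0 < rf_threshold < 0.5:
        raise ValueError("rf_threshold must lie in (0, 0.5)")
    markers = list(skeleton.columns)
    rf_arr = rf.rf.loc[markers, markers].to_numpy()
    cnt = rf.counts.loc[markers, markers].to_numpy()
    linked = (rf_arr <= rf_threshold) & (cnt > 0)
    np.fill_diagonal(linked, False)
    n_comp, labels = connected_components(sparse.csr_matrix(linked),
                                          directed=False)
    groups = [[m for m, l in zip(markers, labels) if l == c]
              for c in range(n_comp)]

    if target_groups is not None:
        if len(groups) < target_groups:
            logger.warning("only %d natural linkage groups found "
                           "(target %d); no groups were split",
                           len(groups), target_groups)
        while len(groups) > target_groups:
            best = None
            for i in range(len(groups)):
                ii = [markers.index(m) for m in groups[i]]
                for j in range(i + 1, len(groups)):
                    jj = [markers.index(m) for m in groups[j]]
                    sub = rf_arr[np.ix_(ii, jj)]
                    if np.all(np.isnan(sub)):
                        continue
                    d = np.nanmin(sub)
                    if best is None or d < best[0]:
                        best = (d, i, j)
            if best is None:
                logger.warning("no informative RF between remaining groups; "
                               "stopping merges at %d groups", len(groups))
                break
            _, i, j = best
            groups[i] = groups[i] + groups[j]
            del groups[j]
    groups.sort(key=len, reverse=True)
    return groups


# ---------------------------------------------------------------------------
# ordering

def _path_length(order: np.ndarray, rf_arr: np.ndarray) -> float:
    return float(rf_arr[order[:-1], order[1:]].sum())


def _two_opt(order: np.ndarray, rf_arr: np.ndarray) -> np.ndarray:
    """2-opt segment-reversal passes until no adjacent-RF-sum improvement."""
    m = len(order)
    improved = True
    while improved:
        improved = False
        for i in range(m - 1):
            for j in range(i + 1, m):
                # reversing order[i..j] changes at most two boundary edges
                delta = 0.0
                if i > 0:
                    delta += rf_arr[order[i - 1], order[j]] - \
                        rf_arr[order[i - 1], order[i]]
                if j < m - 1:
                    delta += rf_arr[order[i], order[j + 1]] - \
                        rf_arr[order[j], order[j + 1]]
                if delta < -1e-12:
                    order[i:j + 1] = order[i:j + 1][::-1]
                    improved = True
    return order


def order_and_space_markers(markers: Sequence[str], rf: RFMatrix,
                            ) -> pd.DataFrame:
    """Order one linkage group and assign cumulative cM positions.

    The order minimizes the sum of adjacent RFs (greedy nearest-neighbour
    from the most distal marker, refined by 2-opt).  Adjacent distances
    are RIL-corrected and passed through the Kosambi map function; the
    orientation is fixed by placing the lexicographically smallest end
    marker at the lower end.  Returns columns ``marker, order, cM``.
    """
    markers = list(markers)
    if len(markers) == 1:
        return pd.DataFrame({"marker": markers, "order": [0], "cM": [0.0]})
    rf_arr = rf.rf.loc[markers, markers].to_numpy().copy()
    rf_arr = np.where(np.isnan(rf_arr), 0.5, rf_arr)

    # seed at the most distal marker: largest total RF to the others
    start = int(np.argmax(rf_arr.sum(axis=1)))
    unvisited = set(range(len(markers))) - {start}
    order = [start]
    while unvisited:
        last = order[-1]
        nxt = min(unvisited, key=lambda k: (rf_arr[last, k], markers[k]))
        order.append(nxt)
        unvisited.discard(nxt)
    order = _two_opt(np.asarray(order), rf_arr)

    if markers[order[-1]] < markers[order[0]]:
        order = order[::-1]
    adj_rf = rf_arr[order[:-1], order[1:]]
    cm = np.concatenate([[0.0], np.cumsum(cm_from_ril_r(adj_rf))])
    return pd.DataFrame({"marker": [markers[k] for k in order],
                         "order": np.arange(len(markers)), "cM": cm})


# ---------------------------------------------------------------------------
# assembled map

@dataclass
class GeneticMap:
    """Ordered skeleton map: per-marker group, order index and cM position."""

    table: pd.DataFrame                       # marker, group, order, cM
    bins: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        need = {"marker", "group", "order", "cM"}
        if not need <= set(self.table.columns):
            raise ValueError(f"map table needs columns {sorted(need)}")

    @property
    def groups(self) -> list[str]:
        return list(dict.fromkeys(self.table["group"]))

    def group_table(self, group: str) -> pd.DataFrame:
        sub = self.table[self.table["group"] == group]
        return sub.sort_values("order").reset_index(drop=True)

    def lengths(self) -> pd.Series:
        return self.table.groupby("group", observed=True)["cM"].max()

    @property
    def total_length(self) -> float:
        return float(self.lengths().sum())


def build_map(geno: pd.DataFrame, max_missing: float = 0.10,
              max_distortion_chi2: float = 35.0, rf_threshold: float = 0.2,
              target_groups: Optional[int] = 14,
              anchors: Optional[pd.DataFrame] = None) -> GeneticMap:
    """Full pipeline: QC -> RF -> binning -> clustering -> ordering.

    Groups are named ``LG01, LG02, ...`` in decreasing size order, or by
    the majority chromosome of their anchored markers when an anchor
    table (columns ``marker, chrom, bp``) is supplied; anchors also fix
    each group's orientation (genetic order ascending with bp).
    """
    geno_qc, _ = qc_filter_markers(geno, max_missing, max_distortion_chi2)
    rf = estimate_rf_matrix(geno_qc)
    skeleton, bins = bin_skeleton_markers(geno_qc, rf)
    groups = cluster_linkage_groups(skeleton, rf, rf_threshold, target_groups)

    anchor_chrom = anchor_bp = {}
    if anchors is not None:
        anchor_chrom = dict(zip(anchors["marker"], anchors["chrom"]))
        anchor_bp = dict(zip(anchors["marker"], anchors["bp"]))

    tables = []
    used_names: set[str] = set()
    for gi, members in enumerate(groups):
        ordered = order_and_space_markers(members, rf)
        name = f"LG{gi + 1:02d}"
        if anchor_chrom:
            chroms = [anchor_chrom[m] for m in members if m in anchor_chrom]
            if chroms:
                majority = pd.Series(chroms).mode().iloc[0]
                if majority not in used_names:
                    name = str(majority)
            bps = ordered["marker"].map(anchor_bp)
            if bps.notna().sum() >= 2:
                rho = stats.spearmanr(ordered.loc[bps.notna(), "order"],
                                      bps.dropna()).statistic
                if rho < 0:   # orient ascending with physical position
                    ordered = ordered.iloc[::-1].reset_index(drop=True)
                    ordered["order"] = np.arange(len(ordered))
                    ordered["cM"] = float(ordered["cM"].max()) - ordered["cM"]
        used_names.add(name)
        ordered.insert(1, "group", name)
        tables.append(ordered)
    return GeneticMap(table=pd.concat(tables, ignore_index=True), bins=bins)


# ---------------------------------------------------------------------------
# diagnostics

@dataclass
class MapDiagnostics:
    distortion: pd.DataFrame          # per-marker chi2 / p / favored parent
    n_distorted: int
    distorted_by_parent: dict[str, int]
    nonrecombinant: pd.DataFrame      # line x group boolean (NaN = excluded)
    n_units: int                      # lines x groups
    n_units_evaluated: int
    nonrecombinant_proportion: float
    concordance: dict[str, float] = field(default_factory=dict)


def map_diagnostics(geno: pd.DataFrame, gmap: GeneticMap,
                    alpha: float = 0.05,
                    anchors: Optional[pd.DataFrame] = None) -> MapDiagnostics:
    """Segregation-distortion and non-recombination screens for a built map.

    A line x group unit is *non-recombinant* when all of its non-missing
    calls across the group's markers are identical; units with fewer than
    two non-missing calls carry no recombination information and are
    excluded from the denominator (and logged).
    """
    missing = set(gmap.table["marker"]) - set(geno.columns)
    if missing:
        raise ValueError(f"map covers markers absent from genotypes: "
                         f"{sorted(missing)[:5]}")
    dist = distortion_chi2(geno.loc[:, gmap.table["marker"]])
    sig = dist[dist["p"] <= alpha]
    by_parent = sig["favored"].value_counts().to_dict()

    groups = gmap.groups
    flags = pd.DataFrame(index=geno.index, columns=groups, dtype=object)
    for group in groups:
        cols = gmap.group_table(group)["marker"].tolist()
        d = _dosage(geno[cols])
        n_calls = (d != 0).sum(axis=1)
        same = np.abs(d.sum(axis=1)) == n_calls   # all non-missing identical
        flag = np.where(n_calls >= 2, same, np.nan)
        flags[group] = flag
    n_units = len(geno.index) * len(groups)
    evaluated = flags.notna().to_numpy().sum()
    if evaluated < n_units:
        logger.info("%d line x group units excluded (fewer than 2 calls)",
                    n_units - evaluated)
    n_nonrec = int(np.nansum(flags.to_numpy(dtype=float)))
    prop = n_nonrec / evaluated if evaluated else float("nan")

    concordance = {}
    if anchors is not None:
        concordance = physical_concordance(gmap, anchors)
    return MapDiagnostics(
        distortion=dist, n_distorted=len(sig),
        distorted_by_parent={p: int(by_parent.get(p, 0)) for p in ("P1", "P2")},
        nonrecombinant=flags, n_units=n_units,
        n_units_evaluated=int(evaluated),
        nonrecombinant_proportion=prop, concordance=concordance)


def physical_concordance(gmap: GeneticMap, anchors: pd.DataFrame,
                         ) -> dict[str, float]:
    """Absolute Spearman correlation of genetic vs physical marker order.

    Computed per linkage group over its anchored markers; the absolute
    value is reported because group orientation is arbitrary.  Groups
    with fewer than three anchors are skipped with a warning.
    """
    bp = dict(zip(anchors["marker"], anchors["bp"]))
    out = {}
    for group in gmap.groups:
        sub = gmap.group_table(group)
        anchored = sub[sub["marker"].isin(bp)]
        if len(anchored) < 3:
            logger.warning("group %s: fewer than 3 anchored markers; skipped",
                           group)
            continue
        rho = stats.spearmanr(anchored["order"],
                              anchored["marker"].map(bp)).statistic
        out[group] = float(abs(rho))
    return out
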