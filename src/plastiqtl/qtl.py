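"""Regression-based QTL interval mapping on a RIL genetic map.

The scan machinery follows Haley-Knott regression: at every grid
position the trait is regressed on the *expected* genotype dosage
conditional on the nearest non-missing flanking markers, and evidence is
summarized as ``LOD = (n/2) * log10(SSE_0 / SSE_1)``, equivalently
``-(n/2) * log10(1 - R^2)``.  For near-fully homozygous RILs this is
near-equivalent to the mixture-model EM scan at a fraction of the cost,
which matters inside permutation and bootstrap loops.

Provided scans: single-QTL per chromosome, two-linked-QTL grid search,
joint two-environment analysis (environment-specific intercepts and
dosage effects), and a multiple-interval-mapping style refinement that
residualizes the trait on detected QTLs from other chromosomes.
Genome-wide significance is calibrated by permutation of trait values
across lines; support intervals are 1.5-LOD drops and position/effect
uncertainty comes from a line-resampling bootstrap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .linkage import ril_r_from_cm
from .model import QTLEffect

logger = logging.getLogger(__name__)

DEFAULT_LOD_CEILING = 50.0
TWO_QTL_MIN_SEPARATION_CM = 10.0
TWO_QTL_LOD_MARGIN = 2.0


def as_map_frame(map_like) -> pd.DataFrame:
    """Normalize a map input to columns ``marker, chrom, cM``."""
    if hasattr(map_like, "table"):    # GeneticMap
        df = map_like.table.rename(columns={"group": "chrom"})
    else:
        df = map_like.copy()
    need = {"marker", "chrom", "cM"}
    if not need <= set(df.columns):
        raise ValueError(f"map needs columns {sorted(need)}")
    return df[["marker", "chrom", "cM"]]


# ---------------------------------------------------------------------------
# conditional dosages

@dataclass
class GenotypeProbabilities:
    """Expected dosage per line at every evaluation position.

    ``dosage`` is lines x positions; ``positions`` has columns
    ``chrom, cM`` (the cM grid plus every marker position).  Dosage at a
    non-missing marker equals the observed call (+/-1); elsewhere it is
    the conditional expectation under the Markov crossover model with
    RIL-corrected recombination, bounded by [-1, +1].
    """

    lines: pd.Index
    positions: pd.DataFrame
    dosage: np.ndarray
    step_cM: float

    def chrom_mask(self, chrom: str) -> np.ndarray:
        return (self.positions["chrom"] == chrom).to_numpy()

    @property
    def chroms(self) -> list[str]:
        return list(dict.fromkeys(self.positions["chrom"]))


def _line_dosage(grid: np.ndarray, t_obs: np.ndarray, g_obs: np.ndarray,
                 ) -> np.ndarray:
    """Conditional expected dosage along one chromosome for one line."""
    out = np.zeros(len(grid))
    if len(t_obs) == 0:
        return out
    ri = np.searchsorted(t_obs, grid, side="left")
    li = ri - 1
    at = np.zeros(len(grid), dtype=bool)
    in_range = ri < len(t_obs)
    at[in_range] = np.isclose(t_obs[ri[in_range]], grid[in_range])
    left_only = (ri == len(t_obs)) & ~at
    right_only = (ri == 0) & ~at
    both = ~(at | left_only | right_only)

    out[at] = g_obs[ri[at]]
    if left_only.any():
        d = grid[left_only] - t_obs[li[left_only]]
        out[left_only] = g_obs[li[left_only]] * (1 - 2 * ril_r_from_cm(d))
    if right_only.any():
        d = t_obs[ri[right_only]] - grid[right_only]
        out[right_only] = g_obs[ri[right_only]] * (1 - 2 * ril_r_from_cm(d))
    if both.any():
        gl = g_obs[li[both]]
        gr = g_obs[ri[both]]
        rl = ril_r_from_cm(grid[both] - t_obs[li[both]])
        rr = ril_r_from_cm(t_obs[ri[both]] - grid[both])
        w_b = np.where(gl > 0, 1 - rl, rl) * np.where(gr > 0, 1 - rr, rr)
        w_a = np.where(gl < 0, 1 - rl, rl) * np.where(gr < 0, 1 - rr, rr)
        out[both] = (w_b - w_a) / (w_b + w_a)
    return out


def genotype_probabilities(map_like, geno: pd.DataFrame,
                           step_cM: float = 1.0) -> GenotypeProbabilities:
    """Expected dosage at every grid point and marker position.

    Lines with no non-missing marker on a chromosome get dosage 0
    (uninformative) along that chromosome.
    """
    map_df = as_map_frame(map_like)
    arr = geno.to_numpy(dtype=object)
    vals = np.zeros(arr.shape)
    vals[arr == "A"] = -1.0
    vals[arr == "B"] = 1.0
    dos_obs = pd.DataFrame(vals, index=geno.index, columns=geno.columns)
    pos_frames = []
    blocks = []
    for chrom in dict.fromkeys(map_df["chrom"]):
        sub = map_df[map_df["chrom"] == chrom].sort_values("cM")
        markers = [m for m in sub["marker"] if m in geno.columns]
        t_mark = sub.set_index("marker").loc[markers, "cM"].to_numpy(float)
        length = float(sub["cM"].max())
        grid = np.unique(np.round(np.concatenate(
            [np.arange(0.0, length + step_cM / 2, step_cM), t_mark]), 6))
        grid = grid[grid <= length + 1e-9]
        pos_frames.append(pd.DataFrame({"chrom": chrom, "cM": grid}))
        block = np.zeros((len(geno.index), len(grid)))
        D = dos_obs[markers].to_numpy()
        for i in range(len(geno.index)):
            obs = np.flatnonzero(D[i] != 0)
            if len(obs) == 0:
                logger.debug("line %s has no calls on %s", geno.index[i], chrom)
            block[i] = _line_dosage(grid, t_mark[obs], D[i, obs])
        blocks.append(block)
    return GenotypeProbabilities(
        lines=geno.index, positions=pd.concat(pos_frames, ignore_index=True),
        dosage=np.hstack(blocks), step_cM=step_cM)


# ---------------------------------------------------------------------------
# single-QTL scan

@dataclass
class ScanProfile:
    """Genome-wide LOD profile of one trait under one model."""

    trait: str
    set_tag: str
    env: Optional[str]
    model: str
    table: pd.DataFrame         # chrom, cM, lod, r2, additive
    n: int

    def chrom_table(self, chrom: str) -> pd.DataFrame:
        return self.table[self.table["chrom"] == chrom]

    @property
    def max_lod(self) -> float:
        return float(self.table["lod"].max())


def _align(probs: GenotypeProbabilities, y: pd.Series,
           ) -> tuple[np.ndarray, np.ndarray]:
    y = y.dropna()
    common = probs.lines.intersection(y.index)
    rows = probs.lines.get_indexer(common)
    return probs.dosage[rows], y.loc[common].to_numpy(float)


def _profile_stats(D: np.ndarray, y: np.ndarray,
                   lod_ceiling: float = DEFAULT_LOD_CEILING,
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-column regression of y on dosage: (lod, r2, slope)."""
    n = len(y)
    yc = y - y.mean()
    ss_y = float(yc @ yc)
    Dc = D - D.mean(axis=0)
    ss_d = np.einsum("ij,ij->j", Dc, Dc)
    cov = Dc.T @ yc
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where((ss_d > 0) & (ss_y > 0), cov ** 2 / (ss_d * ss_y), 0.0)
        slope = np.where(ss_d > 0, cov / ss_d, 0.0)
    r2 = np.clip(r2, 0.0, 1.0)
    with np.errstate(divide="ignore"):
        lod = -(n / 2.0) * np.log10(np.maximum(1.0 - r2, 0.0))
    lod = np.minimum(np.nan_to_num(lod, posinf=lod_ceiling), lod_ceiling)
    return lod, r2, slope


def scan_single(probs: GenotypeProbabilities, y: pd.Series,
                trait: str = "", set_tag: str = "obs",
                env: Optional[str] = None,
                lod_ceiling: float = DEFAULT_LOD_CEILING,
                min_lines: int = 10) -> ScanProfile:
    """Single-QTL Haley-Knott scan over the whole evaluation grid."""
    D, yv = _align(probs, y)
    if len(yv) < min_lines:
        raise ValueError(f"need >= {min_lines} informative lines, "
                         f"got {len(yv)}")
    lod, r2, slope = _profile_stats(D, yv, lod_ceiling)
    table = probs.positions.copy()
    table["lod"] = lod
    table["r2"] = r2
    table["additive"] = slope
    return ScanProfile(trait=trait, set_tag=set_tag, env=env,
                       model="single", table=table, n=len(yv))


# ---------------------------------------------------------------------------
# thresholds

@dataclass
class Threshold:
    """Genome-wide permutation threshold for one trait."""

    trait: str
    set_tag: str
    n_perm: int
    alpha: float
    lod_threshold: float
    sample: np.ndarray = field(repr=False, default=None)

    def __float__(self) -> float:
        return self.lod_threshold


def permutation_threshold(probs: GenotypeProbabilities, y: pd.Series,
                          n_perm: int = 1000, alpha: float = 0.05,
                          seed: int = 0, trait: str = "",
                          set_tag: str = "obs") -> Threshold:
    """Genome-wide max-LOD null distribution by permuting trait values.

    Genotypes stay fixed; the threshold is the ``(1 - alpha)`` empirical
    quantile of the permuted genome-wide maximum LOD.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    D, yv = _align(probs, y)
    rng = np.random.default_rng(seed)
    n = len(yv)
    yc = yv - yv.mean()
    ss_y = float(yc @ yc)
    Dc = D - D.mean(axis=0)
    ss_d = np.einsum("ij,ij->j", Dc, Dc)
    ok = ss_d > 0
    denom = np.sqrt(ss_d[ok] * ss_y)
    sample = np.empty(n_perm)
    for b in range(n_perm):
        yp = yc[rng.permutation(n)]
        r = (Dc[:, ok].T @ yp) / denom
        r2max = float(np.max(r ** 2))
        sample[b] = -(n / 2.0) * np.log10(max(1.0 - r2max, 1e-300))
    thr = float(np.quantile(sample, 1.0 - alpha))
    return Threshold(trait=trait, set_tag=set_tag, n_perm=n_perm,
                     alpha=alpha, lod_threshold=thr, sample=sample)


# ---------------------------------------------------------------------------
# effect summaries

def support_interval(chrom_table: pd.DataFrame, peak_idx: int,
                     drop: float = 1.5) -> tuple[float, float]:
    """Widest contiguous region around the peak with LOD >= peak - drop."""
    lod = chrom_table["lod"].to_numpy()
    cm = chrom_table["cM"].to_numpy()
    floor = lod[peak_idx] - drop
    lo = peak_idx
    while lo > 0 and lod[lo - 1] >= floor:
        lo -= 1
    hi = peak_idx
    while hi < len(lod) - 1 and lod[hi + 1] >= floor:
        hi += 1
    return float(cm[lo]), float(cm[hi])


def effect_summary(profile: ScanProfile,
                   threshold: Union[Threshold, float],
                   drop: float = 1.5) -> list[QTLEffect]:
    """One QTL effect per chromosome whose peak LOD clears the threshold."""
    thr = float(threshold)
    effects = []
    for chrom in dict.fromkeys(profile.table["chrom"]):
        sub = profile.chrom_table(chrom).reset_index(drop=True)
        # ties can arise when the LOD ceiling caps several positions;
        # break them by the larger model R^2
        top = sub["lod"] == sub["lod"].max()
        peak = int(sub.loc[top, "r2"].idxmax())
        if sub.loc[peak, "lod"] < thr:
            continue
        a = float(sub.loc[peak, "additive"])
        if a == 0.0:
            continue
        effects.append(QTLEffect(
            trait=profile.trait, set_tag=profile.set_tag, env=profile.env,
            chrom=chrom, pos_cM=float(sub.loc[peak, "cM"]),
            lod=float(sub.loc[peak, "lod"]), additive=a,
            pev=float(sub.loc[peak, "r2"]),
            support=support_interval(sub, peak, drop),
            model=profile.model))
    return effects


# ---------------------------------------------------------------------------
# two-linked-QTL model

@dataclass
class TwoQTLResult:
    retained: bool
    chrom: str
    lod_two: float
    lod_single: float
    positions: tuple[float, float]
    additive: tuple[float, float]
    r2: float


def scan_two_linked(probs: GenotypeProbabilities, y: pd.Series, chrom: str,
                    min_separation_cM: float = TWO_QTL_MIN_SEPARATION_CM,
                    lod_margin: float = TWO_QTL_LOD_MARGIN,
                    ) -> TwoQTLResult:
    """Exhaustive two-position joint fit on one chromosome.

    The two-QTL model is retained only when its LOD exceeds the best
    single-QTL LOD on the chromosome by ``lod_margin``.  Falls back to
    the single-QTL result (retained=False) when the chromosome is too
    short or too sparse for two separated positions.
    """
    mask = probs.chrom_mask(chrom)
    cm = probs.positions.loc[mask, "cM"].to_numpy()
    D_all, yv = _align(probs, y)
    D = D_all[:, mask]
    n = len(yv)
    lod1, r2_1, slope1 = _profile_stats(D, yv)
    best1 = int(np.argmax(lod1))
    single = TwoQTLResult(False, chrom, float(lod1[best1]), float(lod1[best1]),
                          (float(cm[best1]),) * 2,
                          (float(slope1[best1]),) * 2, float(r2_1[best1]))
    n_markers = mask.sum()
    if cm.max() - cm.min() < 2 * min_separation_cM or n_markers < 4:
        logger.warning("chromosome %s too small for a two-QTL search", chrom)
        return single

    yc = yv - yv.mean()
    ss0 = float(yc @ yc)
    Dc = D - D.mean(axis=0)
    best = None
    for i in range(len(cm)):
        js = np.flatnonzero(cm >= cm[i] + min_separation_cM)
        for j in js:
            X = Dc[:, [i, j]]
            beta, res, rank, _ = np.linalg.lstsq(X, yc, rcond=None)
            if rank < 2:
                continue
            sse = float(res[0]) if res.size else float(
                ((yc - X @ beta) ** 2).sum())
            lod2 = (n / 2.0) * np.log10(max(ss0 / max(sse, 1e-300), 1.0))
            if best is None or lod2 > best[0]:
                best = (lod2, i, j, beta, sse)
    if best is None:
        return single
    lod2, i, j, beta, sse = best
    retained = lod2 >= single.lod_single + lod_margin
    return TwoQTLResult(
        retained=retained, chrom=chrom, lod_two=float(lod2),
        lod_single=single.lod_single,
        positions=(float(cm[i]), float(cm[j])),
        additive=(float(beta[0]), float(beta[1])),
        r2=1.0 - sse / ss0)


# ---------------------------------------------------------------------------
# joint two-environment scan

@dataclass
class JointScanResult:
    profile: ScanProfile                      # joint LOD (sum over envs)
    per_env: dict[str, ScanProfile]
    specificity: Optional[str]                # both / WL-specific / WW-specific


def scan_joint_environments(probs: GenotypeProbabilities,
                            y_ww: Optional[pd.Series],
                            y_wl: Optional[pd.Series],
                            trait: str = "", set_tag: str = "obs",
                            env_alpha: float = 0.05) -> JointScanResult:
    """Multi-environment scan with environment-specific dosage effects.

    Both environments contribute independent samples, so the joint LOD
    against the no-QTL-in-either-environment null is the sum of the two
    per-environment LOD profiles.  The specificity tag records which
    per-environment slope is individually significant at ``env_alpha``
    (pointwise F test) at the joint peak.
    """
    series = {"WW": y_ww, "WL": y_wl}
    present = {e: s for e, s in series.items()
               if s is not None and s.notna().sum() >= 10}
    if not present:
        raise ValueError("no environment has enough data")
    per_env = {e: scan_single(probs, s, trait=trait, set_tag=set_tag, env=e)
               for e, s in present.items()}
    if len(present) == 1:
        env = next(iter(present))
        prof = per_env[env]
        prof = ScanProfile(trait=trait, set_tag=set_tag, env=env,
                           model="joint-env-degraded", table=prof.table,
                           n=prof.n)
        logger.warning("only environment %s available; joint scan degraded "
                       "to a single-environment scan", env)
        return JointScanResult(profile=prof, per_env=per_env,
                               specificity=f"{env}-only-data")

    table = probs.positions.copy()
    table["lod"] = sum(p.table["lod"].to_numpy() for p in per_env.values())
    table["r2"] = np.mean([p.table["r2"].to_numpy()
                           for p in per_env.values()], axis=0)
    table["additive"] = np.mean([p.table["additive"].to_numpy()
                                 for p in per_env.values()], axis=0)
    profile = ScanProfile(trait=trait, set_tag=set_tag, env=None,
                          model="joint-env", table=table,
                          n=sum(p.n for p in per_env.values()))

    peak = int(table["lod"].idxmax())
    sig = []
    for e, p in per_env.items():
        r2 = float(p.table.loc[peak, "r2"])
        n = p.n
        if r2 >= 1.0:
            sig.append(e)
            continue
        f = (n - 2) * r2 / (1.0 - r2)
        if stats.f.sf(f, 1, n - 2) <= env_alpha:
            sig.append(e)
    if len(sig) == 2:
        specificity = "both"
    elif sig:
        specificity = f"{sig[0]}-specific"
    else:
        specificity = None
    return JointScanResult(profile=profile, per_env=per_env,
                           specificity=specificity)


# ---------------------------------------------------------------------------
# MIM-style refinement

def _peak_dosage(probs: GenotypeProbabilities, effect: QTLEffect,
                 ) -> np.ndarray:
    mask = probs.chrom_mask(effect.chrom)
    cm = probs.positions.loc[mask, "cM"].to_numpy()
    col = np.flatnonzero(mask)[int(np.argmin(np.abs(cm - effect.pos_cM)))]
    return probs.dosage[:, col]


def mim_refine(effects: Sequence[QTLEffect], probs: GenotypeProbabilities,
               y: pd.Series, max_rounds: int = 3,
               tol_cM: float = 1.0) -> list[QTLEffect]:
    """Rescan each chromosome after removing other-chromosome QTL signal.

    The trait is residualized on the peak dosages of detected QTLs that
    reside on *other* chromosomes, then the chromosome is rescanned;
    rounds repeat until peaks move less than ``tol_cM`` (at most
    ``max_rounds``).  Collinear background covariates are dropped.
    """
    if not effects:
        raise ValueError("no detected effects to refine")
    current = list(effects)
    yd = y.dropna()
    common = probs.lines.intersection(yd.index)
    rows = probs.lines.get_indexer(common)
    yv = yd.loc[common].to_numpy(float)

    for _ in range(max_rounds):
        updated = []
        moved = 0.0
        for eff in current:
            others = [e for e in current if e.chrom != eff.chrom]
            if others:
                X = np.column_stack([np.ones(len(rows))] +
                                    [_peak_dosage(probs, e)[rows]
                                     for e in others])
                keep = [0]
                for k in range(1, X.shape[1]):
                    col = X[:, k]
                    if col.std() == 0:
                        logger.info("dropping constant background covariate")
                        continue
                    sub = X[:, keep]
                    beta, *_ = np.linalg.lstsq(sub, col, rcond=None)
                    resid = col - sub @ beta
                    if float(resid @ resid) < 1e-10 * float(col @ col):
                        logger.info("dropping collinear background covariate")
                        continue
                    keep.append(k)
                Xk = X[:, keep]
                beta, *_ = np.linalg.lstsq(Xk, yv, rcond=None)
                resid = yv - Xk @ beta
            else:
                resid = yv
            mask = probs.chrom_mask(eff.chrom)
            D = probs.dosage[np.ix_(rows, mask)]
            cm = probs.positions.loc[mask, "cM"].to_numpy()
            lod, r2, slope = _profile_stats(D, resid)
            peak = int(np.argmax(lod))
            sub_table = pd.DataFrame({"cM": cm, "lod": lod})
            new = QTLEffect(
                trait=eff.trait, set_tag=eff.set_tag, env=eff.env,
                chrom=eff.chrom, pos_cM=float(cm[peak]),
                lod=float(lod[peak]), additive=float(slope[peak]),
                pev=float(r2[peak]),
                support=support_interval(sub_table, peak),
                model="MIM-adjusted")
            moved = max(moved, abs(new.pos_cM - eff.pos_cM))
            updated.append(new)
        current = updated
        if moved < tol_cM:
            break
    return current


# ---------------------------------------------------------------------------
# bootstrap

@dataclass
class BootstrapResult:
    n_boot: int
    n_used: int
    pos_sd: float
    additive_sd: float
    pos_ci: tuple[float, float]
    additive_ci: tuple[float, float]


def bootstrap_ci(probs: GenotypeProbabilities, y: pd.Series, chrom: str,
                 n_boot: int = 500, seed: int = 0) -> BootstrapResult:
    """Line-resampling bootstrap of the peak position and additive effect."""
    mask = probs.chrom_mask(chrom)
    D_all, yv = _align(probs, y)
    D = D_all[:, mask]
    cm = probs.positions.loc[mask, "cM"].to_numpy()
    rng = np.random.default_rng(seed)
    n = len(yv)
    pos, add = [], []
    skipped = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, n)
        yb = yv[idx]
        if yb.std() == 0:
            skipped += 1
            continue
        lod, r2, slope = _profile_stats(D[idx], yb)
        if np.all(lod == 0):
            skipped += 1
            continue
        peak = int(np.argmax(lod))
        pos.append(cm[peak])
        add.append(slope[peak])
    if skipped:
        logger.info("%d degenerate bootstrap replicates skipped", skipped)
    pos = np.asarray(pos)
    add = np.asarray(add)
    return BootstrapResult(
        n_boot=n_boot, n_used=len(pos),
        pos_sd=float(pos.std(ddof=1)), additive_sd=float(add.std(ddof=1)),
        pos_ci=(float(np.percentile(pos, 2.5)), float(np.percentile(pos, 97.5))),
        additive_ci=(float(np.percentile(add, 2.5)),
                     float(np.percentile(add, 97.5))))
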