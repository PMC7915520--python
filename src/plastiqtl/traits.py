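"""Derivative plasticity traits, heritability and correlation analyses.

Three derivative trait sets are defined by ordinary-least-squares
residuals on line means:

* **adjusted-phenology traits** (prefix ``df``), per environment: the
  residual of the trait on days-to-heading, removing the heading-date
  component of trait variation;
* **drought plasticity I** (prefix ``d``): the residual of the
  water-limited value on the well-watered value, a stress-response score
  normalized for the trait's non-stress level;
* **drought plasticity II** (prefix ``ddf``): the residual of the
  water-limited value on both the well-watered value and water-limited
  heading date, removing the drought-escape (earliness-mediated)
  component from plasticity I.

Broad-sense heritability across the two irrigation regimes is estimated
from the genotype and genotype-by-environment ANOVA mean squares:
``sigma_g^2 = (MS_gen - MS_gxe) / e``, ``sigma_gxe^2 = MS_gxe`` and
``h^2 = sigma_g^2 / (sigma_g^2 + sigma_gxe^2 / e)`` with *e* the number
of environments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

ENVIRONMENTS = ("WW", "WL")
PHENOLOGY_TRAIT = "DP-H"


class DegenerateFitError(ValueError):
    """A regression predictor is constant or (near-)collinear."""


@dataclass
class RegressionFit:
    """An OLS fit underlying one derivative-trait set."""

    intercept: float
    coefs: np.ndarray            # slope(s) on the predictor(s)
    fitted: pd.Series
    residuals: pd.Series
    n: int
    r2: float

    def to_dict(self) -> dict:
        return {"intercept": self.intercept, "coefs": list(self.coefs),
                "n": self.n, "r2": self.r2}


def _ols(y: pd.Series, X: pd.DataFrame) -> RegressionFit:
    """Plain normal-equations OLS with an intercept on complete cases."""
    data = pd.concat([y.rename("__y"), X], axis=1).dropna()
    yv = data["__y"].to_numpy(dtype=float)
    Xv = np.column_stack([np.ones(len(data)),
                          data[X.columns].to_numpy(dtype=float)])
    beta, *_ = np.linalg.lstsq(Xv, yv, rcond=None)
    fitted = Xv @ beta
    resid = yv - fitted
    tss = float(np.sum((yv - yv.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid ** 2)) / tss if tss > 0 else 0.0
    return RegressionFit(
        intercept=float(beta[0]), coefs=beta[1:],
        fitted=pd.Series(fitted, index=data.index),
        residuals=pd.Series(resid, index=data.index),
        n=len(data), r2=r2)


# ---------------------------------------------------------------------------
# aggregation

def aggregate_means(table: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Line means over non-missing replicates, per environment.

    ``table`` is the long replicate table (line, env, replicate, trait,
    value).  Returns ``{"WW": means, "WL": means}`` with lines as rows and
    traits as columns; cells with zero non-missing replicates are NaN.
    Distribution summaries (skewness, normality-test p) are logged per
    trait and environment as an advisory check.
    """
    envs = set(table["env"].unique())
    if not envs <= set(ENVIRONMENTS):
        raise ValueError(f"unknown environments {envs - set(ENVIRONMENTS)}")
    all_lines = pd.Index(sorted(table["line"].unique()), name="line")
    out = {}
    for env in ENVIRONMENTS:
        sub = table[table["env"] == env]
        means = sub.pivot_table(index="line", columns="trait", values="value",
                                aggfunc="mean", dropna=False)
        means = means.reindex(all_lines)   # keep lines with no usable reps
        means.columns.name = None
        out[env] = means
        for trait in means.columns:
            vals = means[trait].dropna()
            if len(vals) >= 8:
                skew = stats.skew(vals)
                p = stats.normaltest(vals).pvalue
                logger.debug("trait %s (%s): skew=%.2f normality p=%.3g",
                             trait, env, skew, p)
    return out


# ---------------------------------------------------------------------------
# derivative traits

def adjust_for_phenology(trait_means: pd.Series, dh: pd.Series,
                         ) -> tuple[pd.Series, RegressionFit]:
    """Residual of a trait on heading date within one environment (``df``)."""
    common = trait_means.dropna().index.intersection(dh.dropna().index)
    if len(common) < 3:
        raise ValueError("need >= 3 lines with both trait and heading values")
    if np.isclose(float(dh[common].std(ddof=0)), 0.0):
        raise DegenerateFitError("heading date has zero variance")
    fit = _ols(trait_means, pd.DataFrame({"DH": dh}))
    return fit.residuals, fit


def plasticity_I(v_ww: pd.Series, v_wl: pd.Series,
                 ) -> tuple[pd.Series, RegressionFit]:
    """Residual of the WL value on the WW value (``d``, plasticity I)."""
    common = v_ww.dropna().index.intersection(v_wl.dropna().index)
    if len(common) < 3:
        raise ValueError("need >= 3 lines with both environments")
    if np.isclose(float(v_ww[common].std(ddof=0)), 0.0):
        raise DegenerateFitError("well-watered values have zero variance")
    fit = _ols(v_wl, pd.DataFrame({"V_WW": v_ww}))
    return fit.residuals, fit


def plasticity_II(v_ww: pd.Series, v_wl: pd.Series, dh_wl: pd.Series,
                  ) -> tuple[pd.Series, RegressionFit]:
    """Residual of WL on (WW, WL heading date) (``ddf``, plasticity II)."""
    X = pd.DataFrame({"V_WW": v_ww, "DH_WL": dh_wl})
    common = X.dropna().index.intersection(v_wl.dropna().index)
    if len(common) < 4:
        raise ValueError("need >= 4 lines with all three inputs")
    sub = X.loc[common]
    for col in X.columns:
        if np.isclose(float(sub[col].std(ddof=0)), 0.0):
            raise DegenerateFitError(f"predictor {col} is constant")
    corr = float(sub["V_WW"].corr(sub["DH_WL"]))
    if abs(corr) > 1 - 1e-8:
        raise DegenerateFitError(
            f"predictors V_WW and DH_WL are collinear (r={corr:.10f})")
    fit = _ols(v_wl, X)
    return fit.residuals, fit


@dataclass
class DerivativeTraitSet:
    """All derivative traits of a population, wide by line.

    Columns are named ``df<trait>_WW``, ``df<trait>_WL``, ``d<trait>``
    and ``ddf<trait>``; heading itself has no df/ddf versions (it cannot
    be adjusted for itself).
    """

    values: pd.DataFrame
    fits: dict[str, RegressionFit] = field(default_factory=dict)


def derive_all(means: dict[str, pd.DataFrame],
               phenology_trait: str = PHENOLOGY_TRAIT) -> DerivativeTraitSet:
    """Compute the df / d / ddf trait sets from per-environment line means."""
    ww, wl = means["WW"], means["WL"]
    traits = [t for t in ww.columns if t in wl.columns]
    if phenology_trait not in traits:
        raise ValueError(f"phenology trait {phenology_trait!r} not present")
    dh = {"WW": ww[phenology_trait], "WL": wl[phenology_trait]}

    cols: dict[str, pd.Series] = {}
    fits: dict[str, RegressionFit] = {}
    for trait in traits:
        if trait != phenology_trait:
            for env, m in (("WW", ww), ("WL", wl)):
                name = f"df{trait}_{env}"
                cols[name], fits[name] = adjust_for_phenology(m[trait], dh[env])
        name = f"d{trait}"
        cols[name], fits[name] = plasticity_I(ww[trait], wl[trait])
        if trait != phenology_trait:
            name = f"ddf{trait}"
            cols[name], fits[name] = plasticity_II(ww[trait], wl[trait], dh["WL"])
    return DerivativeTraitSet(values=pd.DataFrame(cols), fits=fits)


# ---------------------------------------------------------------------------
# heritability

@dataclass
class VarianceComponents:
    ms_gen: float
    ms_gxe: float
    n_env: int
    sigma_g2: float
    sigma_gxe2: float
    h2: float
    truncated: bool = False

    def to_dict(self) -> dict:
        return vars(self).copy()


def heritability_from_ms(ms_gen: float, ms_gxe: float, n_env: int,
                         ) -> VarianceComponents:
    """Variance components and broad-sense h2 from ANOVA mean squares."""
    if n_env < 2:
        raise ValueError("need at least two environments")
    sigma_g2 = (ms_gen - ms_gxe) / n_env
    truncated = sigma_g2 < 0
    sigma_g2 = max(sigma_g2, 0.0)
    if truncated:
        logger.info("negative genotypic variance truncated to 0")
    sigma_gxe2 = ms_gxe
    denom = sigma_g2 + sigma_gxe2 / n_env
    h2 = sigma_g2 / denom if denom > 0 else 0.0
    return VarianceComponents(ms_gen=ms_gen, ms_gxe=ms_gxe, n_env=n_env,
                              sigma_g2=sigma_g2, sigma_gxe2=sigma_gxe2,
                              h2=h2, truncated=truncated)


def variance_components_heritability(table: pd.DataFrame, trait: str,
                                     ) -> VarianceComponents:
    """Two-way genotype x environment ANOVA on replicate data for one trait.

    Mean squares are computed from the replicate-level values (genotype
    and genotype-by-environment terms); empty genotype x environment
    cells are an error because the interaction is then inestimable.
    """
    sub = table[(table["trait"] == trait)].dropna(subset=["value"])
    if sub.empty:
        raise ValueError(f"no data for trait {trait!r}")
    cells = sub.groupby(["line", "env"], observed=True).size().unstack()
    if cells.isna().any().any() or (cells == 0).any().any():
        empty = [(l, e) for (l, e) in
                 cells.stack(future_stack=True)[lambda s: s.isna() | (s == 0)].index]
        raise ValueError(f"empty genotype x environment cells: {empty[:10]}")
    n_env = cells.shape[1]
    if n_env < 2 or cells.shape[0] < 2:
        raise ValueError("need >= 2 lines and >= 2 environments")

    y = sub["value"].to_numpy(dtype=float)
    grand = y.mean()
    cell_means = sub.groupby(["line", "env"], observed=True)["value"].mean().unstack()
    line_means = sub.groupby("line", observed=True)["value"].mean()
    env_means = sub.groupby("env", observed=True)["value"].mean()
    # balanced-design sums of squares on replicate data
    r = float(cells.to_numpy().mean())
    g = cells.shape[0]
    ss_gen = n_env * r * float(((line_means - grand) ** 2).sum())
    inter = (cell_means
             .sub(line_means, axis=0)
             .sub(env_means, axis=1) + grand)
    ss_gxe = r * float((inter.to_numpy() ** 2).sum())
    ms_gen = ss_gen / (g - 1)
    ms_gxe = ss_gxe / ((g - 1) * (n_env - 1))
    return heritability_from_ms(ms_gen, ms_gxe, n_env)


# ---------------------------------------------------------------------------
# correlations

def correlation_analysis(values: pd.DataFrame, method: str = "pearson",
                         min_pairs: int = 3,
                         ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise-complete correlation matrix with per-pair sample sizes.

    ``method`` is ``pearson`` or ``kendall`` (rank correlation).  Entries
    with fewer than ``min_pairs`` complete pairs, or involving a constant
    column, are NaN.  Returns ``(corr, n_pairs)``.
    """
    if method not in ("pearson", "kendall"):
        raise ValueError(f"unsupported method {method!r}")
    corr = values.corr(method=method, min_periods=min_pairs)
    notna = values.notna().astype(int)
    n_pairs = notna.T @ notna
    for col in values.columns:
        v = values[col].dropna()
        if len(v) and np.isclose(float(v.std(ddof=0)), 0.0):
            logger.info("constant column %s: correlations undefined", col)
    for col in corr.columns:
        corr.loc[col, col] = 1.0
    return corr, n_pairs


def correlation_edges(corr: pd.DataFrame, min_abs_r: float = 0.16,
                      ) -> pd.DataFrame:
    """Edge list of trait pairs with |r| at or above a display threshold."""
    rows = []
    cols = list(corr.columns)
    for i, a in enumerate(cols):
        for b in cols[i + 1:]:
            r = corr.loc[a, b]
            if pd.notna(r) and abs(r) >= min_abs_r:
                rows.append({"trait_a": a, "trait_b": b, "r": float(r)})
    return pd.DataFrame(rows, columns=["trait_a", "trait_b", "r"])
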