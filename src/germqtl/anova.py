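"""Balanced ANOVA, variance components and broad-sense heritability.

The experimental design is a randomized complete block: every genotype is
scored in every replicate (and, for the full model, every treatment), one
dish per cell.  Two models are supported:

* two-way, genotype + replicate random, with the genotype x replicate
  interaction serving as error (one observation per cell):
  ``y_ij = mu + g_i + r_j + gr_ij``;
* three-way with a fixed treatment factor:
  ``y_ijk = mu + g_i + r_j + t_k + tg_ik + tgr_ijk`` where the treatment
  mean square is tested against the genotype x treatment interaction and
  everything else against the residual.

From the two-way table, method-of-moments variance components are
``sigma2_GR = MS_E`` and ``sigma2_G = (MS_G - MS_E) / r`` (clamped at 0),
and broad-sense heritability comes in two flavours:

* ``entry_mean`` (default): sigma2_G / (sigma2_G + sigma2_GR / r), the
  heritability of a genotype (entry) mean, algebraically 1 - 1/F_G for the
  balanced design;
* ``printed``: sigma2_G / (sigma2_G + sigma2_GR), the plot-basis ratio.

The entry-mean flavour is the default because it is the one consistent
with heritabilities customarily reported next to genotype F ratios from
replicated trials (h2 = 1 - 1/F).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataWarning, InvalidDesignError, InvalidInputError, undefined
from .germination import TraitTable

#: Significance coding used in the report tables.
SIG_LEVELS = ((0.001, "***"), (0.01, "**"), (0.05, "*"), (0.1, "+"))


def sig_code(p: float) -> str:
    """ns / + / * / ** / *** for p-value thresholds 0.1/0.05/0.01/0.001."""
    if not np.isfinite(p):
        return "ns"
    for level, code in SIG_LEVELS:
        if p < level:
            return code
    return "ns"


@dataclass
class AnovaResult:
    """ANOVA source table plus variance components and heritability."""

    table: pd.DataFrame  # index: source; columns: df, ss, ms, f, p, sig
    var_g: float
    var_gr: float
    n_reps: int
    h2_entry_mean: float
    h2_printed: float
    f_g_infinite: bool = field(default=False)

    @property
    def f_genotype(self) -> float:
        return float(self.table.loc["genotype", "f"])


def _ss_oneway(values: np.ndarray, axis: int) -> float:
    """Sum of squares of a main effect (deviation of level means, weighted)."""
    level_means = values.mean(axis=axis)
    n_per_level = values.size / level_means.size
    return float(n_per_level * ((level_means - values.mean()) ** 2).sum())


def anova_two_way(values: np.ndarray, strict: bool = False) -> AnovaResult:
    """Balanced genotype x replicate ANOVA with GR interaction as error.

    ``values`` is a genotypes x replicates matrix with no missing cells.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 2:
        raise InvalidDesignError("expected a 2-D genotype x replicate matrix")
    g, r = values.shape
    if g < 2 or r < 2:
        raise InvalidDesignError("need at least 2 genotypes and 2 replicates")
    if np.isnan(values).any():
        raise InvalidDesignError(
            "missing cells: only balanced designs are supported; impute or drop")

    grand = values.mean()
    ss_total = float(((values - grand) ** 2).sum())
    ss_g = _ss_oneway(values, axis=1)
    ss_r = _ss_oneway(values, axis=0)
    ss_e = max(ss_total - ss_g - ss_r, 0.0)

    df_g, df_r = g - 1, r - 1
    df_e = df_g * df_r
    ms_g, ms_r, ms_e = ss_g / df_g, ss_r / df_r, ss_e / df_e

    f_inf = False
    if ms_e == 0.0:
        if ms_g == 0.0:  # constant data
            f_g = f_r = p_g = p_r = float("nan")
            undefined("constant response: F ratios undefined", strict)
        else:
            f_inf = True
            f_g = f_r = float("inf")
            p_g = p_r = 0.0
    else:
        f_g = ms_g / ms_e
        f_r = ms_r / ms_e
        p_g = float(stats.f.sf(f_g, df_g, df_e))
        p_r = float(stats.f.sf(f_r, df_r, df_e))

    table = pd.DataFrame(
        {
            "df": [df_g, df_r, df_e],
            "ss": [ss_g, ss_r, ss_e],
            "ms": [ms_g, ms_r, ms_e],
            "f": [f_g, f_r, np.nan],
            "p": [p_g, p_r, np.nan],
        },
        index=pd.Index(["genotype", "replicate", "error"], name="source"),
    )
    table["sig"] = [sig_code(p_g), sig_code(p_r), ""]

    var_gr = ms_e
    var_g = max((ms_g - ms_e) / r, 0.0)
    if var_g == 0.0 and var_gr == 0.0:
        h2e = h2p = undefined("all variance components zero; H2 undefined", strict)
    else:
        h2e = broad_sense_heritability(var_g, var_gr, r, mode="entry_mean")
        h2p = broad_sense_heritability(var_g, var_gr, r, mode="printed")
    return AnovaResult(table, var_g, var_gr, r, h2e, h2p, f_inf)


def anova_with_treatment(values: np.ndarray, strict: bool = False) -> AnovaResult:
    """Balanced genotype x treatment x replicate ANOVA, treatment fixed.

    ``values[i, k, j]`` is genotype i under treatment k in replicate j.
    Sums of squares are fitted for genotype, replicate, treatment and the
    genotype x treatment interaction; the remainder is the residual
    (tgr) error.  F for the fixed treatment uses MS_GT as denominator;
    genotype and G x T are tested against the residual.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 3:
        raise InvalidDesignError("expected genotype x treatment x replicate array")
    g, t, r = values.shape
    if min(g, t, r) < 2:
        raise InvalidDesignError("need >= 2 levels of every factor")
    if np.isnan(values).any():
        raise InvalidDesignError("missing cells: only balanced designs supported")

    grand = values.mean()
    ss_total = float(((values - grand) ** 2).sum())
    g_means = values.mean(axis=(1, 2))
    t_means = values.mean(axis=(0, 2))
    r_means = values.mean(axis=(0, 1))
    ss_g = float(t * r * ((g_means - grand) ** 2).sum())
    ss_t = float(g * r * ((t_means - grand) ** 2).sum())
    ss_r = float(g * t * ((r_means - grand) ** 2).sum())
    gt_means = values.mean(axis=2)
    ss_gt = float(
        r * ((gt_means - g_means[:, None] - t_means[None, :] + grand) ** 2).sum())
    ss_e = max(ss_total - ss_g - ss_t - ss_r - ss_gt, 0.0)

    df_g, df_t, df_r, df_gt = g - 1, t - 1, r - 1, (g - 1) * (t - 1)
    df_e = g * t * r - 1 - df_g - df_t - df_r - df_gt
    ms = {
        "genotype": ss_g / df_g,
        "replicate": ss_r / df_r,
        "treatment": ss_t / df_t,
        "genotype:treatment": ss_gt / df_gt,
        "error": ss_e / df_e,
    }
    ms_e, ms_gt = ms["error"], ms["genotype:treatment"]

    def _f(num: float, den: float, dfn: int, dfd: int) -> tuple[float, float]:
        if den == 0.0:
            return (float("inf"), 0.0) if num > 0 else (float("nan"), float("nan"))
        f = num / den
        return f, float(stats.f.sf(f, dfn, dfd))

    f_g, p_g = _f(ms["genotype"], ms_e, df_g, df_e)
    f_r, p_r = _f(ms["replicate"], ms_e, df_r, df_e)
    f_t, p_t = _f(ms["treatment"], ms_gt, df_t, df_gt)
    f_gt, p_gt = _f(ms_gt, ms_e, df_gt, df_e)

    table = pd.DataFrame(
        {
            "df": [df_g, df_r, df_t, df_gt, df_e],
            "ss": [ss_g, ss_r, ss_t, ss_gt, ss_e],
            "ms": list(ms.values()),
            "f": [f_g, f_r, f_t, f_gt, np.nan],
            "p": [p_g, p_r, p_t, p_gt, np.nan],
        },
        index=pd.Index(
            ["genotype", "replicate", "treatment", "genotype:treatment", "error"],
            name="source"),
    )
    table["sig"] = [sig_code(p) for p in table["p"][:-1]] + [""]

    # variance components on the within-treatment basis (per-dish error)
    var_gr = ms_e
    var_g = max((ms["genotype"] - ms_e) / (t * r), 0.0)
    if var_g == 0.0 and var_gr == 0.0:
        h2e = h2p = undefined("all variance components zero; H2 undefined", strict)
    else:
        h2e = var_g / (var_g + var_gr / (t * r))
        h2p = var_g / (var_g + var_gr)
    return AnovaResult(table, var_g, var_gr, r, h2e, h2p, not np.isfinite(f_g))


def broad_sense_heritability(
    var_g: float, var_gr: float, n_reps: int, mode: str = "entry_mean"
) -> float:
    """H2 from variance components; ``entry_mean`` divides sigma2_GR by r."""
    if var_g < 0 or var_gr < 0:
        raise InvalidInputError("variance components must be >= 0")
    if n_reps < 1:
        raise InvalidInputError("n_reps must be >= 1")
    if var_g == 0 and var_gr == 0:
        raise InvalidInputError("both variance components zero; H2 undefined")
    if mode == "entry_mean":
        return var_g / (var_g + var_gr / n_reps)
    if mode == "printed":
        return var_g / (var_g + var_gr)
    raise InvalidInputError(f"unknown heritability mode {mode!r}")


def entry_mean_h2_from_f(f_genotype: float) -> float:
    """Entry-mean H2 = 1 - 1/F_G, the balanced-design identity (F >= 1)."""
    if f_genotype <= 0 or not np.isfinite(f_genotype):
        raise InvalidInputError("F ratio must be positive and finite")
    return max(1.0 - 1.0 / f_genotype, 0.0)


def correlation_matrix(
    traits: TraitTable | pd.DataFrame, min_pairs: int = 3
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Pairwise-complete Pearson correlations with t-test significance codes.

    Returns (r, p, sig) DataFrames.  Pairs with fewer than ``min_pairs``
    complete observations or a zero-variance member are reported as NaN.
    """
    df = traits.data if isinstance(traits, TraitTable) else traits
    cols = list(df.columns)
    k = len(cols)
    r_m = np.full((k, k), np.nan)
    p_m = np.full((k, k), np.nan)
    x = df.to_numpy(dtype=float)
    for i in range(k):
        for j in range(i, k):
            both = ~np.isnan(x[:, i]) & ~np.isnan(x[:, j])
            n = int(both.sum())
            if n < min_pairs:
                continue
            xi, xj = x[both, i], x[both, j]
            if np.ptp(xi) == 0 or np.ptp(xj) == 0:
                continue
            if i == j:
                r_m[i, i], p_m[i, i] = 1.0, 0.0
                continue
            res = stats.pearsonr(xi, xj)
            r_m[i, j] = r_m[j, i] = res.statistic
            p_m[i, j] = p_m[j, i] = res.pvalue
    r_df = pd.DataFrame(r_m, index=cols, columns=cols)
    p_df = pd.DataFrame(p_m, index=cols, columns=cols)
    sig = p_df.map(sig_code)
    return r_df, p_df, sig


def pca_summary(
    traits: TraitTable | pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """PCA on centered-and-scaled traits (eigen decomposition of the
    correlation matrix).

    Returns (loadings, scores, pct_variance).  Constant columns are dropped
    with a warning; component signs are fixed so the largest-|loading|
    entry of each component is positive.
    """
    df = traits.data if isinstance(traits, TraitTable) else traits
    df = df.dropna(axis=0, how="any")
    keep = [c for c in df.columns if df[c].nunique() > 1]
    dropped = set(df.columns) - set(keep)
    if dropped:
        warnings.warn(f"constant columns dropped from PCA: {sorted(dropped)}",
                      DataWarning)
    df = df[keep]
    x = df.to_numpy(dtype=float)
    z = (x - x.mean(axis=0)) / x.std(axis=0, ddof=1)
    corr = np.atleast_2d(np.corrcoef(z, rowvar=False))
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = np.maximum(eigval[order], 0.0), eigvec[:, order]
    for j in range(eigvec.shape[1]):  # sign convention
        if eigvec[np.argmax(np.abs(eigvec[:, j])), j] < 0:
            eigvec[:, j] *= -1
    pcs = [f"PC{i + 1}" for i in range(len(eigval))]
    loadings = pd.DataFrame(eigvec, index=df.columns, columns=pcs)
    scores = pd.DataFrame(z @ eigvec, index=df.index, columns=pcs)
    pct = 100.0 * eigval / eigval.sum()
    return loadings, scores, pct
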