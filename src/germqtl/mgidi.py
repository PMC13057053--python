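"""Multi-trait Genotype-Ideotype Distance Index (MGIDI) selection.

The index works in four stages:

1. every trait is rescaled to the 0-100 range so that 100 is always the
   desirable end (``increase`` traits keep their orientation, ``decrease``
   traits are flipped); the ideotype is the all-100 row;
2. an exploratory factor analysis of the rescaled traits retains the
   factors with eigenvalue >= 1 (Kaiser rule), varimax-rotates the
   loadings, and derives genotype factor scores by the regression method
   (scores = Z R^-1 Lambda on the column-standardized rescaled matrix);
3. MGIDI_i is the Euclidean distance between genotype i's factor scores
   and the ideotype's scores -- lower means closer to the ideal genotype;
4. a selection pressure (default 15 %) keeps the ceil(p * n) lowest-MGIDI
   genotypes; per-factor shares omega_ij = |gamma_ij - gamma_j| /
   sum_j |gamma_ij - gamma_j| read out each genotype's strengths (small
   share) and weaknesses (large share).

Selection gains are plain relative mean differences,
SG% = 100 * (mean_selected - mean_all) / mean_all, flagged as desirable
when their sign matches the trait's direction.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataWarning, InvalidInputError
from .germination import TraitTable, default_directions


def rescale_trait(values: np.ndarray, direction: str) -> np.ndarray:
    """Linear 0-100 rescale; ``decrease`` traits are flipped so 100 = ideal."""
    values = np.asarray(values, dtype=float)
    finite = values[~np.isnan(values)]
    if finite.size < 2 or np.ptp(finite) == 0:
        raise InvalidInputError("cannot rescale a constant trait")
    lo, hi = finite.min(), finite.max()
    if direction == "increase":
        return 100.0 * (values - lo) / (hi - lo)
    if direction == "decrease":
        return 100.0 * (hi - values) / (hi - lo)
    raise InvalidInputError(f"unknown direction {direction!r}")


def varimax(loadings: np.ndarray, tol: float = 1e-8, max_iter: int = 1000,
            kaiser_normalize: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """Varimax rotation (SVD form).  Returns (rotated loadings, rotation T)."""
    a = np.array(loadings, dtype=float)
    p, k = a.shape
    if k < 2:
        return a, np.eye(k)
    h = np.sqrt((a ** 2).sum(axis=1)) if kaiser_normalize else np.ones(p)
    h[h == 0] = 1.0
    a_n = a / h[:, None]
    t = np.eye(k)
    for _ in range(max_iter):
        b = a_n @ t
        grad = a_n.T @ (b ** 3 - b @ np.diag((b ** 2).sum(axis=0)) / p)
        u, _, vt = np.linalg.svd(grad)
        t_new = u @ vt
        delta = np.abs(t_new - t).max()
        t = t_new
        if delta < tol:
            break
    rotated = (a_n @ t) * h[:, None]
    return rotated, t


@dataclass
class FactorModel:
    """Rotated factor solution of the rescaled trait matrix."""

    rescaled: pd.DataFrame          # genotype x trait, in [0, 100]
    trait_means: pd.Series          # of the rescaled matrix
    trait_sds: pd.Series            # ddof=1
    correlation: pd.DataFrame
    eigenvalues: np.ndarray         # descending, all traits
    n_factors: int
    loadings_rotated: pd.DataFrame  # trait x factor
    scores: pd.DataFrame            # genotype x factor
    ideotype_scores: pd.Series      # per factor

    @property
    def factor_names(self) -> list[str]:
        return list(self.loadings_rotated.columns)


def factor_analysis(rescaled: pd.DataFrame, ridge: float = 1e-8) -> FactorModel:
    """Eigen factor analysis with Kaiser retention and varimax rotation.

    ``rescaled`` must already be on the 0-100 ideotype scale (see
    :func:`rescale_trait`); the all-100 ideotype is projected with the same
    regression weights as the genotypes.
    """
    x = rescaled.to_numpy(dtype=float)
    if np.isnan(x).any():
        raise InvalidInputError("rescaled matrix must be complete (impute or drop)")
    n, p = x.shape
    mu = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    if (sd == 0).any():
        bad = list(rescaled.columns[sd == 0])
        raise InvalidInputError(f"constant columns cannot be factor-analysed: {bad}")
    z = (x - mu) / sd

    corr = np.corrcoef(z, rowvar=False)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    n_factors = max(int((eigval >= 1.0).sum()), 1)
    if n_factors >= n:
        raise InvalidInputError("need more genotypes than retained factors")

    lam = eigvec[:, :n_factors] * np.sqrt(np.maximum(eigval[:n_factors], 0.0))
    lam_rot, _ = varimax(lam)
    # canonical form: order factors by explained variance, largest |loading| > 0
    ssq = (lam_rot ** 2).sum(axis=0)
    lam_rot = lam_rot[:, np.argsort(ssq)[::-1]]
    for j in range(n_factors):
        if lam_rot[np.argmax(np.abs(lam_rot[:, j])), j] < 0:
            lam_rot[:, j] *= -1

    eig_min = float(eigval[-1])
    if eig_min < 1e-10:
        warnings.warn("singular correlation matrix; ridge-stabilized inverse used",
                      DataWarning)
        r_inv = np.linalg.inv(corr + ridge * np.eye(p))
    else:
        r_inv = np.linalg.inv(corr)
    weights = r_inv @ lam_rot
    scores = z @ weights
    z_ideal = (100.0 - mu) / sd
    ideo = z_ideal @ weights

    factors = [f"FA{i + 1}" for i in range(n_factors)]
    return FactorModel(
        rescaled=rescaled,
        trait_means=pd.Series(mu, index=rescaled.columns),
        trait_sds=pd.Series(sd, index=rescaled.columns),
        correlation=pd.DataFrame(corr, index=rescaled.columns, columns=rescaled.columns),
        eigenvalues=eigval,
        n_factors=n_factors,
        loadings_rotated=pd.DataFrame(lam_rot, index=rescaled.columns, columns=factors),
        scores=pd.DataFrame(scores, index=rescaled.index, columns=factors),
        ideotype_scores=pd.Series(ideo, index=factors),
    )


@dataclass
class MgidiResult:
    """Per-genotype distance to the ideotype plus selection bookkeeping."""

    mgidi: pd.Series                # ascending = better
    rank: pd.Series                 # 1 = closest to ideotype
    omega: pd.DataFrame             # genotype x factor shares, rows sum to 1
    factor_model: FactorModel
    selected: list[str] | None = None
    cutpoint: float | None = None
    selection_gain: pd.DataFrame | None = None


def mgidi_index(fm: FactorModel) -> MgidiResult:
    """MGIDI distances, ranks and per-factor omega shares."""
    delta = fm.scores.to_numpy() - fm.ideotype_scores.to_numpy()[None, :]
    dist = np.sqrt((delta ** 2).sum(axis=1))
    absd = np.abs(delta)
    row_sums = absd.sum(axis=1)
    omega = np.empty_like(absd)
    zero = row_sums == 0
    if zero.any():
        warnings.warn("genotype at the ideotype in every factor; uniform omega used",
                      DataWarning)
        omega[zero] = 1.0 / fm.n_factors
    omega[~zero] = absd[~zero] / row_sums[~zero, None]
    mgidi = pd.Series(dist, index=fm.scores.index, name="MGIDI")
    rank = mgidi.rank(method="first").astype(int)
    return MgidiResult(
        mgidi=mgidi,
        rank=rank,
        omega=pd.DataFrame(omega, index=fm.scores.index, columns=fm.factor_names),
        factor_model=fm,
    )


def select_genotypes(result: MgidiResult, pressure: float = 0.15
                     ) -> tuple[list[str], float]:
    """Keep the ceil(pressure * n) closest genotypes; ties keep input order."""
    if not 0 < pressure < 1:
        raise InvalidInputError("selection pressure must be in (0, 1)")
    n = len(result.mgidi)
    k = math.ceil(pressure * n)
    order = np.argsort(result.mgidi.to_numpy(), kind="stable")
    values = result.mgidi.to_numpy()[order]
    if k < n and values[k - 1] == values[k]:
        warnings.warn("MGIDI tie at the selection cutpoint; input order decides",
                      DataWarning)
    selected = [result.mgidi.index[i] for i in order[:k]]
    cutpoint = float(values[k - 1])
    result.selected, result.cutpoint = selected, cutpoint
    return selected, cutpoint


def selection_gain(traits: TraitTable, selected: list[str]) -> pd.DataFrame:
    """SG% = 100 * (mean_selected - mean_all)/mean_all, with desirability flag."""
    if not selected:
        raise InvalidInputError("selected set is empty")
    df = traits.data
    mean_all = df.mean(axis=0)
    mean_sel = df.loc[selected].mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        sg = 100.0 * (mean_sel - mean_all) / mean_all
    sg[mean_all == 0] = np.nan
    out = pd.DataFrame({"mean_all": mean_all, "mean_selected": mean_sel, "sg_pct": sg})
    out["direction"] = [traits.directions[c] for c in df.columns]
    out["desirable"] = [
        (s > 0) if d == "increase" else (s < 0) if s == s else False
        for s, d in zip(out["sg_pct"], out["direction"])
    ]
    return out


def run_mgidi(
    traits: TraitTable,
    pressure: float = 0.15,
    directions: dict[str, str] | None = None,
) -> MgidiResult:
    """Full chain: rescale -> factor analysis -> MGIDI -> selection -> gains.

    Constant or incomplete traits are dropped with a warning before the
    factor analysis (they carry no ranking information / cannot be scored).
    """
    directions = {**default_directions(traits.data.columns),
                  **traits.directions, **(directions or {})}
    df = traits.data.dropna(axis=1, how="any")
    dropped = set(traits.data.columns) - set(df.columns)
    rescaled = {}
    for col in df.columns:
        try:
            rescaled[col] = rescale_trait(df[col].to_numpy(), directions[col])
        except InvalidInputError:
            dropped.add(col)
    rescaled_df = pd.DataFrame(rescaled, index=df.index)
    # exactly collinear pairs (e.g. a pace trait and its reciprocal-rate
    # twin rescale to the same column) make the correlation matrix singular
    # and the regression scores meaningless: keep the first of each pair
    corr = np.corrcoef(rescaled_df.to_numpy(), rowvar=False)
    keep_mask = np.ones(len(rescaled_df.columns), dtype=bool)
    for j in range(1, len(rescaled_df.columns)):
        if np.any(np.abs(corr[j, :j][keep_mask[:j]]) >= 1.0 - 1e-10):
            keep_mask[j] = False
            dropped.add(rescaled_df.columns[j])
    rescaled_df = rescaled_df.loc[:, keep_mask]
    if dropped:
        warnings.warn(f"traits dropped before MGIDI: {sorted(dropped)}", DataWarning)
    fm = factor_analysis(rescaled_df)
    result = mgidi_index(fm)
    selected, _ = select_genotypes(result, pressure)
    kept = TraitTable(traits.data[list(rescaled_df.columns)],
                      {c: directions[c] for c in rescaled_df.columns})
    result.selection_gain = selection_gain(kept, selected)
    return result
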