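"""Multi-trait stability index (MTSI) selection.

The genotype x trait table of WAASBY values is standardized and reduced
by exploratory factor analysis: principal factors of its correlation
matrix, Kaiser retention (eigenvalue > 1), varimax rotation, and factor
scores by the regression (Thomson) method F = Z R^-1 L.  An ideotype
scoring the maximum WAASBY of 100 on every trait is standardized with
the observed column means and SDs and scored identically; each
genotype's MTSI is then its Euclidean distance from the ideotype in
factor-score space,

    MTSI_i = [ sum_f (F_if - F_f)^2 ]^(1/2),

so lower is better and the ideotype itself scores 0.  Selection keeps
the floor(intensity * G) lowest-MTSI genotypes; the per-trait selection
differential SD% = 100 (Xs - Xo) / Xo and the expected gain
SG% = SD% x h2_mean use the heritability of genotype means.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .stability import StabilityScores

__all__ = [
    "FactorModel",
    "MTSIResult",
    "build_waasby_table",
    "fit_factor_model",
    "varimax",
    "mtsi_scores",
    "select_genotypes",
    "selection_response",
    "factor_contributions",
]


@dataclass(frozen=True)
class FactorModel:
    traits: tuple[str, ...]
    correlation: pd.DataFrame
    eigenvalues: np.ndarray  # descending, sums to len(traits)
    n_factors: int
    loadings: pd.DataFrame  # traits x factors, varimax-rotated
    rotation: np.ndarray  # orthogonal rotation matrix
    communalities: pd.Series
    scores: pd.DataFrame  # genotypes x factors
    ideotype_scores: pd.Series  # per factor

    def explained_variance(self) -> pd.DataFrame:
        """Eigenvalue table (share and cumulative share, percent)."""
        share = 100.0 * self.eigenvalues / self.eigenvalues.sum()
        return pd.DataFrame(
            {
                "eigenvalue": self.eigenvalues,
                "variance_pct": share,
                "cumulative_pct": np.cumsum(share),
            },
            index=[f"PC{k+1}" for k in range(len(self.eigenvalues))],
        )


@dataclass(frozen=True)
class MTSIResult:
    mtsi: pd.Series  # per genotype, >= 0
    ranks: pd.Series  # 1 = closest to ideotype


def build_waasby_table(per_trait: Mapping[str, StabilityScores]) -> pd.DataFrame:
    """Assemble the genotype x trait WAASBY matrix, trait order as given.

    Every trait must cover the same genotype set; a mismatch names the
    offending genotypes.
    """
    cols = {}
    index = None
    for trait, scores in per_trait.items():
        s = scores.waasby
        if index is None:
            index = s.index
        else:
            diff = set(index).symmetric_difference(s.index)
            if diff:
                raise ValueError(
                    f"genotype set mismatch for trait {trait!r}: {sorted(diff)}"
                )
        cols[trait] = s.reindex(index)
    return pd.DataFrame(cols, index=index)


def varimax(
    loadings: np.ndarray,
    normalize: bool = True,
    tol: float = 1e-10,
    max_iter: int = 1000,
) -> tuple[np.ndarray, np.ndarray]:
    """Orthogonal varimax rotation (Kaiser row-normalized by default).

    Returns (rotated loadings, rotation matrix R) with R orthogonal;
    communalities are preserved exactly up to floating point.
    """
    L = np.asarray(loadings, dtype=float).copy()
    p, k = L.shape
    if k < 2:
        return L, np.eye(k)
    if normalize:
        h = np.sqrt((L**2).sum(axis=1))
        h[h == 0] = 1.0
        L = L / h[:, None]
    R = np.eye(k)
    obj = 0.0
    for _ in range(max_iter):
        Lr = L @ R
        B = L.T @ (Lr**3 - Lr @ np.diag((Lr**2).sum(axis=0)) / p)
        u, s, vt = np.linalg.svd(B)
        R = u @ vt
        new = s.sum()
        if new <= obj * (1.0 + tol):
            break
        obj = new
    L = L @ R
    if normalize:
        L = L * h[:, None]
    return L, R


def fit_factor_model(
    table: pd.DataFrame, n_factors: int | None = None
) -> FactorModel:
    """Exploratory factor analysis of the WAASBY table.

    Columns are standardized with sample (n-1) SDs; the factor count
    defaults to the Kaiser rule (eigenvalues of the correlation matrix
    greater than 1).  Factor scores use the regression method on the
    rotated solution, and the all-100 ideotype is scored with the same
    standardization and weights.
    """
    if table.shape[1] < 3:
        raise ValueError("factor analysis needs at least 3 traits")
    traits = tuple(table.columns)
    X = table.to_numpy(dtype=float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        dead = [t for t, s in zip(traits, sd) if s == 0]
        raise ValueError(f"constant trait column(s): {dead}")
    Z = (X - mu) / sd
    Rcorr = np.corrcoef(Z, rowvar=False)
    cond = np.linalg.cond(Rcorr)
    if not np.isfinite(cond) or cond > 1e10:
        raise np.linalg.LinAlgError(
            f"correlation matrix is ill-conditioned (cond={cond:.2e})"
        )
    eigval, eigvec = np.linalg.eigh(Rcorr)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]

    if n_factors is None:
        n_factors = int((eigval > 1.0).sum())
        if n_factors == 0:
            raise ValueError(
                "no eigenvalue exceeds 1; pass n_factors explicitly"
            )
    if not 1 <= n_factors <= len(traits):
        raise ValueError("n_factors out of range")
    if table.shape[0] < n_factors + 1:
        raise ValueError("need more genotypes than retained factors")

    A = eigvec[:, :n_factors] * np.sqrt(eigval[:n_factors])
    L, rot = varimax(A)
    communal = (L**2).sum(axis=1)
    Rinv = np.linalg.inv(Rcorr)
    W = Rinv @ L  # regression score weights
    F = Z @ W
    z_ideo = (np.full(len(traits), 100.0) - mu) / sd
    F_ideo = z_ideo @ W

    cols = [f"FA{k+1}" for k in range(n_factors)]
    return FactorModel(
        traits=traits,
        correlation=pd.DataFrame(Rcorr, index=traits, columns=traits),
        eigenvalues=eigval,
        n_factors=n_factors,
        loadings=pd.DataFrame(L, index=traits, columns=cols),
        rotation=rot,
        communalities=pd.Series(communal, index=traits, name="communality"),
        scores=pd.DataFrame(F, index=table.index, columns=cols),
        ideotype_scores=pd.Series(F_ideo, index=cols, name="ideotype"),
    )


def mtsi_scores(model: FactorModel) -> MTSIResult:
    """Genotype-ideotype Euclidean distance in factor-score space."""
    diff = model.scores - model.ideotype_scores
    mtsi = np.sqrt((diff**2).sum(axis=1))
    mtsi.name = "mtsi"
    ranks = mtsi.rank(method="first").astype(int)
    ranks.name = "rank"
    return MTSIResult(mtsi=mtsi, ranks=ranks)


def select_genotypes(result: MTSIResult, intensity: float = 0.15) -> list[str]:
    """The floor(intensity * G) lowest-MTSI genotypes (ties by label)."""
    if not 0 < intensity <= 1:
        raise ValueError("intensity must be in (0, 1]")
    n = math.floor(intensity * len(result.mtsi))
    if n == 0:
        raise ValueError(
            f"selection of floor({intensity} * {len(result.mtsi)}) = 0 genotypes"
        )
    order = result.mtsi.sort_values(kind="stable").index
    return list(order[:n])


def selection_response(
    means: pd.DataFrame,
    selected: Sequence[str],
    h2_mean: Mapping[str, float],
) -> pd.DataFrame:
    """Per-trait selection differential and expected gain.

    Xo is the mean of all genotypes, Xs the mean of the selected set;
    SD% = 100 (Xs - Xo) / Xo and SG% = SD% * h2_mean (heritability of
    genotype means, so SG%/SD% recovers h2_mean exactly).
    """
    if len(selected) == 0:
        raise ValueError("selected set is empty")
    missing = [t for t in means.columns if t not in h2_mean]
    if missing:
        raise KeyError(f"h2_mean missing for trait(s): {missing}")
    xo = means.mean(axis=0)
    xs = means.loc[list(selected)].mean(axis=0)
    sd_pct = 100.0 * (xs - xo) / xo
    h2 = pd.Series({t: h2_mean[t] for t in means.columns})
    return pd.DataFrame(
        {
            "Xo": xo,
            "Xs": xs,
            "SD_pct": sd_pct,
            "SG_pct": sd_pct * h2,
            "h2_mean": h2,
        }
    )


def factor_contributions(
    model: FactorModel, result: MTSIResult, selected: Sequence[str] | None = None
) -> pd.DataFrame:
    """Each factor's share of a genotype's squared ideotype distance.

    Shares sum to 1 per genotype; a genotype exactly at the ideotype
    (MTSI = 0) gets uniform shares with ``undefined`` flagged.
    """
    idx = list(selected) if selected is not None else list(model.scores.index)
    diff2 = (model.scores.loc[idx] - model.ideotype_scores) ** 2
    total = diff2.sum(axis=1)
    out = diff2.div(total.where(total > 0), axis=0)
    undefined = total == 0
    out.loc[undefined, :] = 1.0 / model.n_factors
    out["undefined"] = undefined
    return out
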