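"""WAASB, WAASBY and Mean-vs-WAASB quadrant classification.

WAASB (weighted average of absolute scores from BLUP) measures a
genotype's contribution to genotype-by-environment interaction from the
singular value decomposition of the interaction BLUP matrix:

    WAASB_i = sum_k |IPCA_ik| EP_k / sum_k EP_k,

with EP_k the share of interaction variance on axis k; lower is more
stable.  WAASBY blends 0-100 rescaled performance (rY) and rescaled
stability (rW, small WAASB -> 100) with weights theta_y : theta_s
(default 65:35, favouring performance).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "StabilityScores",
    "waasb_scores",
    "rescale_linear",
    "waasby_index",
    "classify_quadrants",
    "stability_table",
]


@dataclass(frozen=True)
class StabilityScores:
    trait: str
    mean: pd.Series
    waasb: pd.Series
    rescaled_yield: pd.Series  # rY in [0, 100]
    rescaled_stability: pd.Series  # rW in [0, 100]
    waasby: pd.Series
    quadrant: pd.Series

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "mean": self.mean,
                "waasb": self.waasb,
                "rY": self.rescaled_yield,
                "rW": self.rescaled_stability,
                "waasby": self.waasby,
                "quadrant": self.quadrant,
            }
        )


def waasb_scores(ge_blups: pd.DataFrame, n_axes: int | None = None) -> pd.Series:
    """Per-genotype WAASB from the interaction BLUP matrix (G x E).

    All K = min(G, E) - 1 axes enter by default; ``n_axes`` truncates.
    Scores use the symmetric scaling u_ik sqrt(lambda_k); since WAASB
    takes absolute values it is invariant to axis sign flips.  A zero
    matrix yields WAASB = 0 everywhere.
    """
    if ge_blups.size == 0:
        raise ValueError("empty interaction BLUP matrix")
    X = ge_blups.to_numpy(dtype=float)
    G, E = X.shape
    K = min(G, E) - 1
    if n_axes is not None:
        K = min(K, int(n_axes))
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    lam = s[:K]
    total = float((lam**2).sum())
    if total == 0.0:
        return pd.Series(np.zeros(G), index=ge_blups.index, name="waasb")
    ep = lam**2 / total
    scores = np.abs(U[:, :K] * np.sqrt(lam))
    waasb = (scores * ep).sum(axis=1) / ep.sum()
    return pd.Series(waasb, index=ge_blups.index, name="waasb")


def rescale_linear(values: pd.Series, smaller_is_better: bool = False) -> pd.Series:
    """Affine map onto [0, 100]; with ``smaller_is_better`` the minimum
    maps to 100.  A constant vector has no usable range and raises."""
    x = values.astype(float)
    lo, hi = float(x.min()), float(x.max())
    if hi == lo:
        raise ValueError("cannot rescale a constant vector")
    r = (100.0 * (x - lo) / (hi - lo)).clip(0.0, 100.0)
    return (100.0 - r) if smaller_is_better else r


def waasby_index(
    rY: pd.Series, rW: pd.Series, theta_y: float = 65.0, theta_s: float = 35.0
) -> pd.Series:
    """Weighted blend (rY*theta_y + rW*theta_s) / (theta_y + theta_s)."""
    if len(rY) != len(rW):
        raise ValueError("rY and rW must have equal length")
    if theta_y < 0 or theta_s < 0 or theta_y + theta_s == 0:
        raise ValueError("weights must be >= 0 and not both zero")
    return (rY * theta_y + rW * theta_s) / (theta_y + theta_s)


def classify_quadrants(means: pd.Series, waasb: pd.Series) -> pd.Series:
    """Mean-vs-WAASB quadrants.

    The x-split sits at the grand mean of the trait, the y-split at the
    mean WAASB.  I = below-mean performance, high WAASB (unstable, poor);
    II = above-mean, high WAASB (good only where conditions favour it);
    III = below-mean, low WAASB (stable but poor); IV = above-mean, low
    WAASB (stable and superior).  A genotype exactly on a split is
    assigned to the high-mean / low-WAASB side.
    """
    if len(means) != len(waasb):
        raise ValueError("means and waasb must have equal length")
    x_split = float(means.mean())
    y_split = float(waasb.mean())
    high_mean = means >= x_split
    low_waasb = waasb <= y_split
    labels = np.where(
        high_mean, np.where(low_waasb, "IV", "II"), np.where(low_waasb, "III", "I")
    )
    return pd.Series(labels, index=means.index, name="quadrant")


def stability_table(
    trait: str,
    genotype_means: pd.Series,
    ge_blups: pd.DataFrame,
    theta_y: float = 65.0,
    theta_s: float = 35.0,
    larger_is_better: bool = True,
    n_axes: int | None = None,
) -> StabilityScores:
    """Full per-trait stability summary: WAASB, rescales, WAASBY and
    quadrant labels, aligned on the genotype index."""
    w = waasb_scores(ge_blups, n_axes=n_axes).reindex(genotype_means.index)
    rY = rescale_linear(genotype_means, smaller_is_better=not larger_is_better)
    rW = rescale_linear(w, smaller_is_better=True)  # small WAASB -> 100
    y = waasby_index(rY, rW, theta_y, theta_s)
    q = classify_quadrants(genotype_means, w)
    return StabilityScores(
        trait=trait,
        mean=genotype_means,
        waasb=w,
        rescaled_yield=rY,
        rescaled_stability=rW,
        waasby=y,
        quadrant=q,
    )
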