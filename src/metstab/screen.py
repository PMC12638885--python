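"""Pearson correlation among trait genotype-means and yield-trait screening.

Correlations are computed on genotype means across all environments —
one value per genotype per trait — which is the operative scale for
deciding which traits travel with yield into the stability analyses.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["CorrelationMatrix", "pearson_matrix", "select_yield_traits"]


class DegenerateTraitError(ValueError):
    """A trait has zero variance, so Pearson r is undefined."""


@dataclass(frozen=True)
class CorrelationMatrix:
    traits: tuple[str, ...]
    r: pd.DataFrame
    p: pd.DataFrame
    n: int

    def flagged(self) -> pd.DataFrame:
        """Correlation table with significance stars (* p<0.05, ** p<0.01)."""
        out = self.r.round(2).astype(str)
        for i in self.traits:
            for j in self.traits:
                if i == j:
                    continue
                p = self.p.loc[i, j]
                star = "**" if p < 0.01 else "*" if p < 0.05 else ""
                out.loc[i, j] = f"{self.r.loc[i, j]:.2f}{star}"
        return out


def pearson_matrix(means: pd.DataFrame) -> CorrelationMatrix:
    """Pairwise Pearson r and two-sided p-values over a genotype x trait
    table of means.

    p-values come from the exact t transform ``t = r sqrt((n-2)/(1-r^2))``
    with ``n - 2`` degrees of freedom.  Raises
    :class:`DegenerateTraitError` naming any zero-variance trait.
    """
    n = len(means)
    if n < 3:
        raise ValueError("need at least 3 genotypes for a correlation screen")
    traits = tuple(means.columns)
    X = means.to_numpy(dtype=float)
    sd = X.std(axis=0, ddof=1)
    dead = [t for t, s in zip(traits, sd) if s == 0.0]
    if dead:
        raise DegenerateTraitError(f"zero-variance trait(s): {dead}")
    r = np.corrcoef(X, rowvar=False)
    np.fill_diagonal(r, 1.0)
    rr = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore"):
        tstat = rr * np.sqrt((n - 2) / np.maximum(1.0 - rr**2, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(tstat), df=n - 2)
    np.fill_diagonal(p, 0.0)
    return CorrelationMatrix(
        traits=traits,
        r=pd.DataFrame(r, index=traits, columns=traits),
        p=pd.DataFrame(p, index=traits, columns=traits),
        n=n,
    )


def select_yield_traits(
    cm: CorrelationMatrix,
    focal: str = "YD",
    alpha: float = 0.05,
    keep: Sequence[str] = (),
) -> list[str]:
    """Traits with a significant positive correlation with the focal
    trait, plus the focal trait itself and any forced keeps.

    The forced-keep list is explicit configuration: retaining a trait
    with a positive but non-significant yield correlation (e.g. maturity
    duration, for its agronomic relevance) is a judgment call, not a
    rule.  Output preserves the input trait order.
    """
    if focal not in cm.traits:
        raise KeyError(f"focal trait {focal!r} not in correlation matrix")
    unknown = [k for k in keep if k not in cm.traits]
    if unknown:
        raise KeyError(f"forced-keep trait(s) not in matrix: {unknown}")
    chosen = set(keep) | {focal}
    for t in cm.traits:
        if t == focal:
            continue
        if cm.r.loc[t, focal] > 0 and cm.p.loc[t, focal] < alpha:
            chosen.add(t)
    return [t for t in cm.traits if t in chosen]
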