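"""Yield relative to the environmental maximum (YREM).

YREM divides each genotype's yield in an environment by the best yield
any genotype achieved in that environment, ``Y_ij = X_ij / MAX_j``, so
every value lies in (0, 1] and the environmental main effect cancels.
Averaged over environments it measures how much yield a genotype loses
to crossover genotype-by-environment interaction: ``1 - YREM`` is the
crossover loss, and a genotype that wins everywhere scores exactly 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import TraitMatrix

__all__ = ["YREMResult", "yrem_scores", "rank_by_yrem"]


@dataclass(frozen=True)
class YREMResult:
    per_environment: pd.DataFrame  # genotype x environment, values in (0, 1]
    average: pd.Series  # per-genotype mean over environments
    loss: pd.Series  # 1 - average
    mean_yield: pd.Series  # per-genotype mean yield (tie-break key)

    def to_frame(self) -> pd.DataFrame:
        out = self.per_environment.copy()
        out["average_yrem"] = self.average
        out["crossover_loss"] = self.loss
        out["rank"] = rank_series(self)
        return out


def yrem_scores(yields: TraitMatrix) -> YREMResult:
    """Cell-wise division by each environment's maximum, averaged over
    environments.  All yields must be strictly positive."""
    M = yields.values
    bad = M.stack()[M.stack() <= 0]
    if len(bad):
        cell = bad.index[0]
        raise ValueError(
            f"YREM requires positive yields; cell {cell} = {bad.iloc[0]}"
        )
    per_env = M / M.max(axis=0)
    avg = per_env.mean(axis=1)
    return YREMResult(
        per_environment=per_env,
        average=avg,
        loss=1.0 - avg,
        mean_yield=M.mean(axis=1),
    )


def rank_series(res: YREMResult) -> pd.Series:
    """1-based ranks, descending by average YREM; ties broken by mean
    yield (higher first), then label order."""
    order = _ordered_index(res)
    ranks = pd.Series(np.arange(1, len(order) + 1), index=order)
    return ranks.reindex(res.average.index)


def rank_by_yrem(res: YREMResult) -> list[str]:
    """Genotype labels from most to least stable-and-superior."""
    return list(_ordered_index(res))


def _ordered_index(res: YREMResult) -> pd.Index:
    df = pd.DataFrame(
        {"avg": res.average, "yld": res.mean_yield, "label": res.average.index}
    )
    df = df.sort_values(
        by=["avg", "yld", "label"], ascending=[False, False, True]
    )
    return df.index
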