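"""Joint ANOVA and the AMMI decomposition.

The additive main effects and multiplicative interaction (AMMI) model

    y_ij = mu + g_i + e_j + sum_k lambda_k alpha_ik gamma_jk + theta_ij

fits genotype and environment main effects by ANOVA and decomposes the
double-centred interaction residual d_ij = ybar_ij - ybar_i. - ybar_.j
+ ybar_.. by singular value decomposition.  Axis significance uses the
Gollob test: axis k carries G + E - 1 - 2k degrees of freedom and sum
of squares R * lambda_k^2 on the plot basis, tested against the pooled
error mean square from the joint ANOVA.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data import ENV_COL, GEN_COL, REP_COL, METDataset, TraitMatrix, require_balanced

__all__ = ["JointAnova", "AMMIDecomposition", "joint_anova", "ammi_decompose",
           "ipca_significance"]


@dataclass(frozen=True)
class JointAnova:
    """Two-way G x E ANOVA with replicates nested in environments."""

    table: pd.DataFrame  # index: source; columns: df, SS, MS, F, p, pct_SS

    @property
    def residual_ms(self) -> float:
        return float(self.table.loc["residual", "MS"])

    @property
    def residual_df(self) -> float:
        return float(self.table.loc["residual", "df"])

    @property
    def ss_gei(self) -> float:
        return float(self.table.loc["genotype:environment", "SS"])


@dataclass(frozen=True)
class AMMIDecomposition:
    """SVD of the double-centred interaction residual (cell-mean basis).

    ``genotype_scores``/``environment_scores`` hold the symmetric
    scaling alpha_ik sqrt(lambda_k) and gamma_jk sqrt(lambda_k); the raw
    orthonormal singular vectors are kept alongside for reconstruction.
    """

    singular_values: np.ndarray  # lambda_k, non-increasing, length K
    genotype_scores: pd.DataFrame  # G x K, symmetric scaling
    environment_scores: pd.DataFrame  # E x K, symmetric scaling
    alpha: np.ndarray  # G x K orthonormal
    gamma: np.ndarray  # E x K orthonormal
    proportion: np.ndarray  # EP_k = lambda_k^2 / sum lambda^2 (zeros if none)
    grand_mean: float
    genotype_means: pd.Series
    environment_means: pd.Series

    @property
    def n_axes(self) -> int:
        return len(self.singular_values)

    def reconstruct(self, k: int | None = None) -> np.ndarray:
        """Cell means from main effects plus the first ``k`` axes
        (all axes when ``k`` is None)."""
        k = self.n_axes if k is None else k
        additive = (
            self.genotype_means.to_numpy()[:, None]
            + self.environment_means.to_numpy()[None, :]
            - self.grand_mean
        )
        L = self.singular_values[:k]
        return additive + (self.alpha[:, :k] * L) @ self.gamma[:, :k].T


def joint_anova(data: METDataset, trait: str) -> JointAnova:
    """Balanced joint ANOVA: environment tested against the
    replicate-within-environment stratum, genotype and interaction
    against the pooled plot residual."""
    require_balanced(data)
    if trait not in data.traits:
        raise KeyError(f"unknown trait {trait!r}")
    df = data.table
    G, E, R = data.design
    y = df[trait].to_numpy(dtype=float)
    grand = y.mean()
    ss_total = float(((y - grand) ** 2).sum())

    env_means = df.groupby(ENV_COL)[trait].mean()
    gen_means = df.groupby(GEN_COL)[trait].mean()
    rep_in_env = df.groupby([ENV_COL, REP_COL])[trait].mean()
    cell = df.groupby([GEN_COL, ENV_COL])[trait].mean()

    ss_env = G * R * float(((env_means - grand) ** 2).sum())
    ss_rep = G * float(
        ((rep_in_env - env_means.reindex(
            rep_in_env.index.get_level_values(0)).to_numpy()) ** 2).sum()
    )
    ss_gen = E * R * float(((gen_means - grand) ** 2).sum())
    d = (
        cell
        - gen_means.reindex(cell.index.get_level_values(0)).to_numpy()
        - env_means.reindex(cell.index.get_level_values(1)).to_numpy()
        + grand
    )
    ss_gei = R * float((d**2).sum())
    ss_res = ss_total - ss_env - ss_rep - ss_gen - ss_gei

    rows = {
        "environment": (E - 1, ss_env),
        "replicate(environment)": (E * (R - 1), ss_rep),
        "genotype": (G - 1, ss_gen),
        "genotype:environment": ((G - 1) * (E - 1), ss_gei),
        "residual": ((G - 1) * E * (R - 1), ss_res),
    }
    tab = pd.DataFrame(
        {"df": [v[0] for v in rows.values()], "SS": [v[1] for v in rows.values()]},
        index=list(rows),
    )
    tab["MS"] = tab["SS"] / tab["df"]
    ms_res = tab.loc["residual", "MS"]
    ms_rep = tab.loc["replicate(environment)", "MS"]

    tab["F"] = np.nan
    tab["p"] = np.nan
    for source, denom_ms, denom_df in (
        ("environment", ms_rep, rows["replicate(environment)"][0]),
        ("genotype", ms_res, rows["residual"][0]),
        ("genotype:environment", ms_res, rows["residual"][0]),
    ):
        if denom_ms > 0:
            f = tab.loc[source, "MS"] / denom_ms
            tab.loc[source, "F"] = f
            tab.loc[source, "p"] = stats.f.sf(f, tab.loc[source, "df"], denom_df)

    main = ss_env + ss_gen + ss_gei
    tab["pct_SS"] = np.nan
    if main > 0:
        for source in ("environment", "genotype", "genotype:environment"):
            tab.loc[source, "pct_SS"] = 100.0 * tab.loc[source, "SS"] / main
    return JointAnova(table=tab)


def ammi_decompose(means: TraitMatrix, n_reps: int | None = None) -> AMMIDecomposition:
    """SVD of the double-centred cell-mean residual.

    All K = min(G, E) - 1 axes are returned; a rank-deficient (even
    fully additive) interaction simply yields trailing zero singular
    values.  ``n_reps`` is carried by the caller to put axis sums of
    squares on the plot basis (SS_k = R * lambda_k^2); it does not
    affect the decomposition itself.
    """
    M = means.values
    G, E = M.shape
    if G < 2 or E < 2:
        raise ValueError("need at least 2 genotypes and 2 environments")
    if M.isna().any().any():
        raise ValueError("cell-mean matrix has missing values")
    X = M.to_numpy(dtype=float)
    grand = X.mean()
    gmeans = X.mean(axis=1)
    emeans = X.mean(axis=0)
    D = X - gmeans[:, None] - emeans[None, :] + grand

    K = min(G, E) - 1
    U, s, Vt = np.linalg.svd(D, full_matrices=False)
    lam = s[:K]
    alpha = U[:, :K]
    gamma = Vt[:K].T
    total = float((lam**2).sum())
    prop = lam**2 / total if total > 0 else np.zeros(K)
    root = np.sqrt(lam)
    return AMMIDecomposition(
        singular_values=lam,
        genotype_scores=pd.DataFrame(
            alpha * root, index=M.index, columns=[f"IPCA{k+1}" for k in range(K)]
        ),
        environment_scores=pd.DataFrame(
            gamma * root, index=M.columns, columns=[f"IPCA{k+1}" for k in range(K)]
        ),
        alpha=alpha,
        gamma=gamma,
        proportion=prop,
        grand_mean=float(grand),
        genotype_means=pd.Series(gmeans, index=M.index),
        environment_means=pd.Series(emeans, index=M.columns),
    )


def ipca_significance(
    dec: AMMIDecomposition,
    residual_ms: float,
    residual_df: float,
    n_reps: int,
) -> pd.DataFrame:
    """Gollob F-test per interaction axis.

    Axis k (1-based) has df_k = G + E - 1 - 2k and plot-basis
    SS_k = R * lambda_k^2; F_k = (SS_k / df_k) / pooled-error MS.
    """
    if residual_ms <= 0:
        raise ValueError("pooled residual MS must be positive")
    G = dec.alpha.shape[0]
    E = dec.gamma.shape[0]
    rows = []
    for k in range(dec.n_axes):
        df_k = G + E - 1 - 2 * (k + 1)
        ss_k = n_reps * dec.singular_values[k] ** 2
        ms_k = ss_k / df_k
        f = ms_k / residual_ms
        rows.append(
            {
                "axis": f"IPCA{k+1}",
                "df": df_k,
                "SS": ss_k,
                "MS": ms_k,
                "F": f,
                "p": stats.f.sf(f, df_k, residual_df),
                "proportion": dec.proportion[k],
            }
        )
    return pd.DataFrame(rows).set_index("axis")


def scores_long(dec: AMMIDecomposition) -> pd.DataFrame:
    """Scores in long form (entity, type in {GEN, ENV}, axis, score),
    the export dialect for external biplotting."""
    gs = dec.genotype_scores.stack().reset_index()
    gs.columns = ["entity", "axis", "score"]
    gs["type"] = "GEN"
    es = dec.environment_scores.stack().reset_index()
    es.columns = ["entity", "axis", "score"]
    es["type"] = "ENV"
    return pd.concat([gs, es], ignore_index=True)[["entity", "type", "axis", "score"]]
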