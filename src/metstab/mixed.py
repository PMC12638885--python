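"""REML variance components, BLUPs and genetic-parameter summaries.

The linear mixed model treats environment and replicate-within-
environment as fixed and genotype and genotype-by-environment
interaction as random:

    y_ijr = mu + e_j + b_r(j) + g_i + (ge)_ij + eps_ijr,
    g ~ N(0, sigma2_g),  (ge) ~ N(0, sigma2_gei),  eps ~ N(0, sigma2_e).

For a balanced design the restricted likelihood factors over three
orthogonal contrast strata (genotype; interaction; plot residual) whose
expected mean squares are

    E[MS_G]   = sigma2_e + R sigma2_gei + E R sigma2_g
    E[MS_GEI] = sigma2_e + R sigma2_gei
    E[MS_res] = sigma2_e,

so the REML log-likelihood is, up to an additive constant,

    ll = -1/2 sum_s [ df_s log gamma_s + SS_s / gamma_s ],

with gamma_s the stratum expectation above.  Maximizing it (bounded
quasi-Newton on log-variances, method-of-moments start) reproduces the
expected-mean-square closed forms whenever those are interior, and
stays well-defined at the zero boundary.

Genotype BLUPs use the balanced shrinkage identity
ghat_i = h2_mean (ybar_i - ybar..) with h2_mean the heritability of
genotype means; interaction BLUPs shrink the double-centred cell
residual by R sigma2_gei / (R sigma2_gei + sigma2_e).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .data import ENV_COL, GEN_COL, METDataset, require_balanced
from .ammi import joint_anova

__all__ = [
    "VarianceComponents",
    "GVCSummary",
    "MixedModelFit",
    "LRTResult",
    "ems_variance_components",
    "fit_mixed_model",
    "genotype_blups",
    "ge_interaction_blups",
    "genetic_parameters",
    "lrt_random_terms",
]


@dataclass(frozen=True)
class VarianceComponents:
    sigma2_g: float
    sigma2_gei: float
    sigma2_e: float
    n_environments: int
    n_replicates: int
    truncated: bool = False  # a negative moment estimate was clipped to 0


@dataclass(frozen=True)
class GVCSummary:
    """Genetic-parameter summaries derived from the variance components.

    h2_mean is the heritability of genotype means,
    sigma2_g / (sigma2_g + sigma2_gei/E + sigma2_e/(E R)); the selection
    accuracy As is its square root.  r_ge is the within-environment
    genotype-environment correlation sigma2_gei / (sigma2_gei +
    sigma2_e); H2_broad and r2_gei are plot-basis variance shares.
    """

    r2_gei: float
    accuracy_As: float
    r_ge: float
    H2_broad: float
    h2_mean: float


@dataclass(frozen=True)
class LRTResult:
    term: str
    loglik_full: float
    loglik_reduced: float
    statistic: float
    p_value: float


@dataclass
class MixedModelFit:
    trait: str
    components: VarianceComponents
    loglik: float
    grand_mean: float
    environment_effects: pd.Series
    replicate_effects: pd.Series  # (env, rep) -> effect
    genotype_means: pd.Series  # raw means over E*R plots
    cell_means: pd.DataFrame  # G x E
    converged: bool = True

    @property
    def h2_mean(self) -> float:
        return genetic_parameters(self.components).h2_mean


# ---------------------------------------------------------------------------


def _strata(data: METDataset, trait: str):
    """(df, SS) per stratum plus design constants, from the joint ANOVA."""
    an = joint_anova(data, trait).table
    G, E, R = data.design
    out = {
        "G": (an.loc["genotype", "df"], an.loc["genotype", "SS"]),
        "GEI": (
            an.loc["genotype:environment", "df"],
            an.loc["genotype:environment", "SS"],
        ),
        "res": (an.loc["residual", "df"], an.loc["residual", "SS"]),
    }
    return out, G, E, R


def ems_variance_components(data: METDataset, trait: str) -> VarianceComponents:
    """Method-of-moments estimates from the expected mean squares.

    Negative solutions are truncated to zero and flagged.  On balanced
    data with an interior optimum these equal the REML estimates.
    """
    strata, G, E, R = _strata(data, trait)
    ms = {k: ss / df for k, (df, ss) in strata.items()}
    s2e = ms["res"]
    s2gei = (ms["GEI"] - ms["res"]) / R
    s2g = (ms["G"] - ms["GEI"]) / (E * R)
    truncated = s2gei < 0 or s2g < 0
    return VarianceComponents(
        sigma2_g=max(s2g, 0.0),
        sigma2_gei=max(s2gei, 0.0),
        sigma2_e=max(s2e, 0.0),
        n_environments=E,
        n_replicates=R,
        truncated=bool(truncated),
    )


def _reml_loglik(s2g: float, s2gei: float, s2e: float, strata, E: int, R: int) -> float:
    """Balanced-stratum restricted log-likelihood, constant dropped."""
    gammas = {
        "G": s2e + R * s2gei + E * R * s2g,
        "GEI": s2e + R * s2gei,
        "res": s2e,
    }
    ll = 0.0
    for key, (df, ss) in strata.items():
        gam = gammas[key]
        if gam <= 0:
            return -np.inf
        ll -= 0.5 * (df * np.log(gam) + ss / gam)
    return ll


def _maximize_reml(strata, E: int, R: int, free: tuple[str, ...]):
    """Maximize the restricted likelihood over the named free variances
    (others pinned at 0).  Returns (components dict, loglik, converged)."""
    ems = {}
    ms = {k: ss / df for k, (df, ss) in strata.items()}
    ems["sigma2_e"] = max(ms["res"], 1e-12)
    ems["sigma2_gei"] = max((ms["GEI"] - ms["res"]) / R, 0.0)
    ems["sigma2_g"] = max((ms["G"] - ms["GEI"]) / (E * R), 0.0)
    scale = max(ems["sigma2_e"] + ems["sigma2_gei"] + ems["sigma2_g"], 1e-10)
    floor = np.log(scale) - 40.0

    def unpack(theta):
        vals = {"sigma2_g": 0.0, "sigma2_gei": 0.0, "sigma2_e": 0.0}
        for name, t in zip(free, theta):
            vals[name] = np.exp(t)
        return vals

    def neg(theta):
        v = unpack(theta)
        return -_reml_loglik(v["sigma2_g"], v["sigma2_gei"], v["sigma2_e"],
                             strata, E, R)

    x0 = [np.log(max(ems[name], scale * 1e-8)) for name in free]
    res = optimize.minimize(
        neg,
        x0=x0,
        method="L-BFGS-B",
        bounds=[(floor, np.log(scale) + 10.0)] * len(free),
        options={"maxiter": 500, "ftol": 1e-14, "gtol": 1e-10},
    )
    ok = bool(res.success)
    if not ok:
        # the moment start is often the exact interior optimum, where the
        # line search aborts without a step; accept stationary points
        grad = optimize.approx_fprime(res.x, neg, 1e-7)
        ok = float(np.abs(grad).max()) < 1e-4 * (1.0 + abs(res.fun))
    v = unpack(res.x)
    # snap effectively-zero boundary solutions to exact zero
    for name in free:
        if v[name] < scale * 1e-12:
            v[name] = 0.0
    ll = _reml_loglik(v["sigma2_g"], v["sigma2_gei"], v["sigma2_e"], strata, E, R)
    return v, ll, ok


def fit_mixed_model(data: METDataset, trait: str) -> MixedModelFit:
    """REML fit of the two-random-component model on balanced data."""
    require_balanced(data)
    strata, G, E, R = _strata(data, trait)
    v, ll, ok = _maximize_reml(strata, E, R, ("sigma2_g", "sigma2_gei", "sigma2_e"))
    if not ok:
        raise RuntimeError(f"REML did not converge for trait {trait!r}")
    comps = VarianceComponents(
        sigma2_g=v["sigma2_g"],
        sigma2_gei=v["sigma2_gei"],
        sigma2_e=v["sigma2_e"],
        n_environments=E,
        n_replicates=R,
    )
    df = data.table
    grand = float(df[trait].mean())
    env_eff = df.groupby(ENV_COL)[trait].mean() - grand
    rep_eff = (
        df.groupby([ENV_COL, "REP"])[trait].mean()
        - df.groupby(ENV_COL)[trait].mean().reindex(
            df.groupby([ENV_COL, "REP"])[trait].mean().index.get_level_values(0)
        ).to_numpy()
    )
    gen_means = df.groupby(GEN_COL)[trait].mean()
    cells = df.groupby([GEN_COL, ENV_COL])[trait].mean().unstack(ENV_COL)
    return MixedModelFit(
        trait=trait,
        components=comps,
        loglik=ll,
        grand_mean=grand,
        environment_effects=env_eff,
        replicate_effects=rep_eff,
        genotype_means=gen_means,
        cell_means=cells,
        converged=ok,
    )


def genotype_blups(fit: MixedModelFit) -> pd.DataFrame:
    """Shrunken genotype effects and predicted means.

    ghat_i = h2_mean * (ybar_i - ybar..); predicted mean = mu + ghat_i.
    The ``above_average`` flag marks genotypes predicted above the grand
    mean (the shortlisting rule used on predicted-mean plots).
    """
    h2 = fit.h2_mean
    g_hat = h2 * (fit.genotype_means - fit.grand_mean)
    pred = fit.grand_mean + g_hat
    return pd.DataFrame(
        {
            "raw_mean": fit.genotype_means,
            "blup_effect": g_hat,
            "predicted_mean": pred,
            "above_average": pred > fit.grand_mean,
        }
    )


def ge_interaction_blups(fit: MixedModelFit) -> pd.DataFrame:
    """BLUP matrix of the interaction effects (G x E, double-centred).

    Each double-centred cell residual d_ij = ybar_ij - ybar_i. - ybar_.j
    + ybar_.. is shrunk by c = R sigma2_gei / (R sigma2_gei + sigma2_e),
    the balanced-design shrinkage of the interaction contrast stratum.
    """
    cells = fit.cell_means
    gmeans = cells.mean(axis=1)
    emeans = cells.mean(axis=0)
    D = cells.sub(gmeans, axis=0).sub(emeans, axis=1) + fit.grand_mean
    vc = fit.components
    denom = vc.n_replicates * vc.sigma2_gei + vc.sigma2_e
    c = 0.0 if denom == 0 else vc.n_replicates * vc.sigma2_gei / denom
    return D * c


def genetic_parameters(vc: VarianceComponents) -> GVCSummary:
    """Genetic-parameter summaries from the variance components."""
    total = vc.sigma2_g + vc.sigma2_gei + vc.sigma2_e
    if total <= 0:
        raise ValueError("all variance components are zero")
    E, R = vc.n_environments, vc.n_replicates
    denom_mean = vc.sigma2_g + vc.sigma2_gei / E + vc.sigma2_e / (E * R)
    h2_mean = vc.sigma2_g / denom_mean if denom_mean > 0 else 0.0
    ge_denom = vc.sigma2_gei + vc.sigma2_e
    return GVCSummary(
        r2_gei=vc.sigma2_gei / total,
        accuracy_As=float(np.sqrt(h2_mean)),
        r_ge=vc.sigma2_gei / ge_denom if ge_denom > 0 else 0.0,
        H2_broad=vc.sigma2_g / total,
        h2_mean=h2_mean,
    )


def lrt_random_terms(data: METDataset, trait: str) -> dict[str, LRTResult]:
    """Likelihood-ratio tests for each random term.

    Each reduced model pins one variance at zero and re-maximizes the
    same restricted likelihood (fixed effects unchanged).  The statistic
    is referred to chi-square with 1 df; at the boundary this is
    conservative relative to the 50:50 mixture reference.
    """
    require_balanced(data)
    strata, G, E, R = _strata(data, trait)
    _, ll_full, ok = _maximize_reml(
        strata, E, R, ("sigma2_g", "sigma2_gei", "sigma2_e")
    )
    if not ok:
        raise RuntimeError(f"full-model REML did not converge for {trait!r}")
    out: dict[str, LRTResult] = {}
    reduced_specs = {
        "genotype": ("sigma2_gei", "sigma2_e"),
        "genotype:environment": ("sigma2_g", "sigma2_e"),
    }
    for term, free in reduced_specs.items():
        _, ll_red, ok = _maximize_reml(strata, E, R, free)
        if not ok:
            raise RuntimeError(f"reduced-model REML failed for term {term!r}")
        stat = max(2.0 * (ll_full - ll_red), 0.0)
        out[term] = LRTResult(
            term=term,
            loglik_full=ll_full,
            loglik_reduced=ll_red,
            statistic=stat,
            p_value=float(stats.chi2.sf(stat, df=1)),
        )
    return out
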