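"""REML variance components, BLUPs, genetic parameters and LRT."""

import numpy as np
import pandas as pd
import pytest

from metstab.data import METDataset
from metstab.datasets import load_variance_components
from metstab.mixed import (
    VarianceComponents,
    ems_variance_components,
    fit_mixed_model,
    ge_interaction_blups,
    genetic_parameters,
    genotype_blups,
    lrt_random_terms,
)
from metstab.mixed import _maximize_reml, _reml_loglik, _strata
from metstab.synth import SynthConfig, generate_met


# ----------------------------------------------------- dense-matrix oracles


def _design_matrices(data: METDataset):
    """Full-rank fixed design (intercept, env, rep-in-env) and random
    incidence matrices for genotype and interaction."""
    df = data.table
    n = len(df)
    envs, gens, reps = data.environments, data.genotypes, data.replicates
    X_cols = [np.ones(n)]
    for e in envs[1:]:
        X_cols.append((df["ENV"] == e).to_numpy(float))
    for e in envs:
        for r in reps[1:]:
            X_cols.append(((df["ENV"] == e) & (df["REP"] == r)).to_numpy(float))
    X = np.column_stack(X_cols)
    Zg = np.column_stack([(df["GEN"] == g).to_numpy(float) for g in gens])
    Zu = np.column_stack(
        [
            ((df["GEN"] == g) & (df["ENV"] == e)).to_numpy(float)
            for g in gens
            for e in envs
        ]
    )
    return X, Zg, Zu


def _dense_restricted_loglik(y, X, Zg, Zu, s2g, s2u, s2e):
    V = s2g * Zg @ Zg.T + s2u * Zu @ Zu.T + s2e * np.eye(len(y))
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    beta = np.linalg.solve(XtViX, X.T @ Vi @ y)
    r = y - X @ beta
    _, ld_V = np.linalg.slogdet(V)
    _, ld_X = np.linalg.slogdet(XtViX)
    return -0.5 * (ld_V + ld_X + r @ Vi @ r)


def _henderson_solution(y, X, Zg, Zu, s2g, s2u, s2e):
    lam_g, lam_u = s2e / s2g, s2e / s2u
    W = np.hstack([X, Zg, Zu])
    C = W.T @ W
    p, qg = X.shape[1], Zg.shape[1]
    C[p : p + qg, p : p + qg] += lam_g * np.eye(qg)
    C[p + qg :, p + qg :] += lam_u * np.eye(Zu.shape[1])
    sol = np.linalg.solve(C, W.T @ y)
    return sol[p : p + qg], sol[p + qg :]


def test_reml_loglik_matches_dense_matrix_oracle():
    """Stratum-factorized restricted likelihood differences equal the
    brute-force log|V| + log|X'V^-1 X| + y'Py evaluation."""
    cfg = SynthConfig(G=4, E=3, R=2, mu=10.0, sigma2_g=4.0, sigma2_gei=2.0,
                      sigma2_e=1.0, sigma2_env=1.0, sigma2_block=0.5,
                      gei_rank=2, seed=13)
    data, _ = generate_met(cfg)
    y = data.table[data.traits[0]].to_numpy()
    X, Zg, Zu = _design_matrices(data)
    strata, G, E, R = _strata(data, data.traits[0])
    points = [(4.0, 2.0, 1.0), (1.0, 5.0, 2.0), (0.5, 0.1, 3.0)]
    dense = [_dense_restricted_loglik(y, X, Zg, Zu, *p) for p in points]
    ours = [_reml_loglik(*p, strata, E, R) for p in points]
    for i in range(1, len(points)):
        assert ours[i] - ours[0] == pytest.approx(dense[i] - dense[0], abs=1e-6)


def test_blups_match_henderson_mme(toy_met):
    """Closed-form genotype BLUPs equal the Henderson mixed-model-equation
    solution; the interaction BLUP matrix equals the double-centred
    projection of the MME interaction solution."""
    _, data, _ = toy_met
    trait = data.traits[0]
    fit = fit_mixed_model(data, trait)
    vc = fit.components
    y = data.table[trait].to_numpy()
    X, Zg, Zu = _design_matrices(data)
    g_hat, u_hat = _henderson_solution(
        y, X, Zg, Zu, vc.sigma2_g, vc.sigma2_gei, vc.sigma2_e
    )
    ours = genotype_blups(fit)["blup_effect"].reindex(data.genotypes).to_numpy()
    np.testing.assert_allclose(ours, g_hat, atol=1e-8)

    U = u_hat.reshape(len(data.genotypes), len(data.environments))
    U_cc = U - U.mean(axis=1, keepdims=True) - U.mean(axis=0, keepdims=True) + U.mean()
    ours_u = ge_interaction_blups(fit)
    ours_u = ours_u.loc[data.genotypes, data.environments].to_numpy()
    np.testing.assert_allclose(ours_u, U_cc, atol=1e-8)


# ------------------------------------------------------------- EMS and REML


def test_ems_matches_brute_force_mean_squares(toy_met):
    _, data, _ = toy_met
    trait = data.traits[0]
    vc = ems_variance_components(data, trait)
    G, E, R = data.design
    cell = data.table.groupby(["GEN", "ENV"])[trait].mean().unstack()
    gm = cell.mean(axis=1)
    em = cell.mean(axis=0)
    grand = data.table[trait].mean()
    d = cell.sub(gm, axis=0).sub(em, axis=1) + grand
    ms_gei = R * (d.to_numpy() ** 2).sum() / ((G - 1) * (E - 1))
    ms_g = E * R * ((gm - grand) ** 2).sum() / (G - 1)
    # residual MS enters through sigma2_e, checked against statsmodels in
    # the ANOVA tests; verify the two genetic components here.
    assert vc.sigma2_gei == pytest.approx(
        max((ms_gei - vc.sigma2_e) / R, 0.0), rel=1e-10
    )
    assert vc.sigma2_g == pytest.approx(
        max((ms_g - ms_gei) / (E * R), 0.0), rel=1e-10
    )


def test_ems_truncates_negative_components():
    """When MS_G < MS_GEI the genotype component clips to 0, flagged."""
    rng = np.random.default_rng(5)
    rows = []
    # pure noise with a strong interaction pattern: sigma2_g estimate < 0
    inter = rng.normal(0, 5, size=(4, 3))
    inter -= inter.mean(axis=0)
    inter -= inter.mean(axis=1, keepdims=True)
    for gi, g in enumerate("ABCD"):
        for ei, e in enumerate(["E1", "E2", "E3"]):
            for r in ["R1", "R2"]:
                rows.append(
                    {"ENV": e, "GEN": g, "REP": r,
                     "T": inter[gi, ei] + rng.normal(0, 0.5)}
                )
    data = METDataset(pd.DataFrame(rows))
    vc = ems_variance_components(data, "T")
    assert vc.sigma2_g == 0.0
    assert vc.truncated


def test_reml_equals_ems_at_interior_optimum(paper_scale_met):
    _, data, _ = paper_scale_met
    trait = data.traits[0]
    ems = ems_variance_components(data, trait)
    assert not ems.truncated
    fit = fit_mixed_model(data, trait)
    assert fit.components.sigma2_g == pytest.approx(ems.sigma2_g, rel=1e-6)
    assert fit.components.sigma2_gei == pytest.approx(ems.sigma2_gei, rel=1e-6)
    assert fit.components.sigma2_e == pytest.approx(ems.sigma2_e, rel=1e-6)


def test_boundary_estimate_when_no_genotype_variance():
    cfg = SynthConfig(G=10, E=4, R=3, mu=50.0, sigma2_g=0.0, sigma2_gei=1.0,
                      sigma2_e=4.0, sigma2_env=1.0, sigma2_block=0.2,
                      gei_rank=2, seed=17)
    data, _ = generate_met(cfg)
    fit = fit_mixed_model(data, data.traits[0])
    ems = ems_variance_components(data, data.traits[0])
    # REML stays at (or within noise of) the zero boundary
    assert fit.components.sigma2_g <= max(ems.sigma2_g, 1e-6) + 1e-6


# ------------------------------------------------------------------- BLUPs


def test_blup_shrinkage_bounds(paper_scale_met):
    _, data, _ = paper_scale_met
    fit = fit_mixed_model(data, data.traits[0])
    b = genotype_blups(fit)
    raw_dev = fit.genotype_means - fit.grand_mean
    assert np.all(np.abs(b["blup_effect"]) <= np.abs(raw_dev) + 1e-12)
    assert b["blup_effect"].sum() == pytest.approx(0.0, abs=1e-8)


def test_blup_limits_via_synthetic_components(toy_met):
    _, data, _ = toy_met
    from dataclasses import replace

    fit = fit_mixed_model(data, data.traits[0])
    # h2 -> 1 limit: no interaction or error variance
    fit1 = replace(fit)
    fit1.components = VarianceComponents(10.0, 0.0, 0.0, 3, 2)
    b1 = genotype_blups(fit1)
    np.testing.assert_allclose(
        b1["predicted_mean"], fit.genotype_means, atol=1e-10
    )
    fit0 = replace(fit)
    fit0.components = VarianceComponents(0.0, 1.0, 1.0, 3, 2)
    b0 = genotype_blups(fit0)
    np.testing.assert_allclose(b0["predicted_mean"], fit.grand_mean, atol=1e-10)


def test_interaction_blups_structure(paper_scale_met):
    _, data, _ = paper_scale_met
    fit = fit_mixed_model(data, data.traits[0])
    U = ge_interaction_blups(fit)
    np.testing.assert_allclose(U.sum(axis=0), 0.0, atol=1e-8)
    np.testing.assert_allclose(U.sum(axis=1), 0.0, atol=1e-8)
    # zero interaction variance -> zero matrix
    from dataclasses import replace

    fit0 = replace(fit)
    fit0.components = VarianceComponents(10.0, 0.0, 5.0, 6, 6)
    assert (ge_interaction_blups(fit0).to_numpy() == 0).all()


# --------------------------------------------------------- genetic parameters


@pytest.mark.parametrize(
    "trait,h2,As,rge,r2",
    [
        ("YD", 0.863, 0.993, 0.412, 0.056),
        ("NC", 0.771, 0.981, 0.758, 0.173),
        ("DM", 0.068, 0.785, 0.127, 0.118),
    ],
)
def test_published_gvc_values(trait, h2, As, rge, r2):
    """Published variance components reproduce the printed heritability,
    selection accuracy, GE correlation and GEI share (3 dp; the printed
    components themselves carry 3-significant-figure rounding)."""
    row = load_variance_components().loc[trait]
    vc = VarianceComponents(row.sigma2_g, row.sigma2_gei, row.sigma2_e, 6, 6)
    p = genetic_parameters(vc)
    assert p.H2_broad == pytest.approx(h2, abs=0.002)
    assert p.accuracy_As == pytest.approx(As, abs=0.002)
    assert p.r_ge == pytest.approx(rge, abs=0.002)
    assert p.r2_gei == pytest.approx(r2, abs=0.002)


def test_gvc_degenerate_and_limit_cases():
    p = genetic_parameters(VarianceComponents(10.0, 0.0, 0.0, 6, 6))
    assert p.H2_broad == 1.0 and p.r2_gei == 0.0 and p.accuracy_As == 1.0
    with pytest.raises(ValueError):
        genetic_parameters(VarianceComponents(0.0, 0.0, 0.0, 6, 6))


def test_accuracy_is_sqrt_of_h2_mean_and_bounds():
    rng = np.random.default_rng(2)
    for _ in range(20):
        vc = VarianceComponents(*rng.uniform(0.01, 10.0, 3), 5, 4)
        p = genetic_parameters(vc)
        assert p.accuracy_As**2 == pytest.approx(p.h2_mean, rel=1e-12)
        for v in (p.r2_gei, p.accuracy_As, p.r_ge, p.H2_broad, p.h2_mean):
            assert 0.0 <= v <= 1.0


def test_h2_mean_decreases_with_error_variance():
    vals = [
        genetic_parameters(VarianceComponents(10.0, 2.0, s2e, 6, 6)).h2_mean
        for s2e in (0.5, 1.0, 5.0, 20.0)
    ]
    assert all(a > b for a, b in zip(vals, vals[1:]))


# ----------------------------------------------------------------------- LRT


def test_lrt_strong_signal_significant(paper_scale_met):
    _, data, _ = paper_scale_met
    res = lrt_random_terms(data, data.traits[0])
    assert res["genotype"].statistic > 0
    assert res["genotype"].p_value < 0.01
    assert res["genotype:environment"].statistic >= 0


def test_lrt_null_statistic_near_zero():
    cfg = SynthConfig(G=12, E=4, R=3, mu=20.0, sigma2_g=0.0, sigma2_gei=1.0,
                      sigma2_e=4.0, sigma2_env=1.0, sigma2_block=0.1,
                      gei_rank=2, seed=23)
    data, _ = generate_met(cfg)
    res = lrt_random_terms(data, data.traits[0])
    assert res["genotype"].statistic < 4.0  # not significant at 5%
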