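"""Synthetic balanced MET generator with a known ground truth.

Simulates plot records under the same generative form the downstream
models assume,

    y_ijr = mu + g_i + e_j + (ge)_ij + b_r(j) + eps_ijr,

with Gaussian genotype effects ``g ~ N(0, sigma2_g)``, environment
effects ``e ~ N(0, sigma2_env)``, blocks nested in environments
``b ~ N(0, sigma2_block)``, plot error ``eps ~ N(0, sigma2_e)`` and a
low-rank double-centred interaction matrix whose empirical variance is
scaled to ``sigma2_gei`` — so AMMI can recover its rank and REML its
variance, and every downstream stage is testable without field data.

A single integer seed drives named sub-streams (genotype, environment,
interaction, block, error, one set per trait), so one component's draw
never shifts another's.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .data import ENV_COL, GEN_COL, REP_COL, METDataset

__all__ = ["SynthConfig", "TruthLedger", "generate_met", "generate_multitrait_met"]

_STREAMS = ("genotype", "environment", "interaction", "block", "error")


@dataclass(frozen=True)
class SynthConfig:
    """Ground-truth configuration of a simulated balanced MET.

    Defaults reproduce the design and seed-yield variance components of
    the horse gram trials the package was built around: 30 genotypes x
    6 environments x 6 replicates with sigma2_g = 25425, sigma2_gei =
    1663, sigma2_e = 2374 (kg/ha)^2 and grand mean 938 kg/ha.
    Environment and block variances are nuisance scales (both enter the
    model as fixed/nuisance terms downstream) set to values typical of
    a rainfed legume MET at this yield scale.
    """

    G: int = 30
    E: int = 6
    R: int = 6
    mu: float = 938.0
    sigma2_g: float = 25425.0
    sigma2_gei: float = 1663.0
    sigma2_e: float = 2374.0
    sigma2_env: float = 1500.0
    sigma2_block: float = 200.0
    gei_rank: int = 2
    n_traits: int = 1
    trait_cor: np.ndarray | None = None
    trait_names: tuple[str, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.G, self.E, self.R) < 2:
            raise ValueError("G, E, R must all be >= 2")
        for name in ("sigma2_g", "sigma2_gei", "sigma2_e", "sigma2_env", "sigma2_block"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.gei_rank <= min(self.G, self.E) - 1:
            raise ValueError("gei_rank must be in [0, min(G, E) - 1]")
        if self.n_traits < 1:
            raise ValueError("n_traits must be >= 1")
        if self.trait_cor is not None:
            C = np.asarray(self.trait_cor, dtype=float)
            if C.shape != (self.n_traits, self.n_traits):
                raise ValueError("trait_cor must be n_traits x n_traits")
            if not np.allclose(C, C.T, atol=1e-10) or not np.allclose(
                np.diag(C), 1.0, atol=1e-10
            ):
                raise ValueError("trait_cor must be symmetric with unit diagonal")
            if np.linalg.eigvalsh(C).min() <= 1e-12:
                raise ValueError("trait_cor must be positive definite")

    @property
    def traits(self) -> tuple[str, ...]:
        if self.trait_names is not None:
            if len(self.trait_names) != self.n_traits:
                raise ValueError("trait_names length must equal n_traits")
            return tuple(self.trait_names)
        return tuple(f"T{k + 1}" for k in range(self.n_traits))


@dataclass
class TruthLedger:
    """Realized effects behind a simulated dataset (per trait)."""

    config: SynthConfig
    genotype_effects: dict[str, np.ndarray] = field(default_factory=dict)
    environment_effects: dict[str, np.ndarray] = field(default_factory=dict)
    interaction: dict[str, np.ndarray] = field(default_factory=dict)  # G x E
    block_effects: dict[str, np.ndarray] = field(default_factory=dict)  # E x R

    def to_json(self) -> str:
        cfg = {
            k: (v.tolist() if isinstance(v, np.ndarray) else v)
            for k, v in vars(self.config).items()
        }
        payload = {
            "config": cfg,
            "genotype_effects": {t: v.tolist() for t, v in self.genotype_effects.items()},
            "environment_effects": {
                t: v.tolist() for t, v in self.environment_effects.items()
            },
            "interaction": {t: v.tolist() for t, v in self.interaction.items()},
            "block_effects": {t: v.tolist() for t, v in self.block_effects.items()},
        }
        return json.dumps(payload, indent=1)


def _labels(prefix: str, n: int) -> list[str]:
    width = len(str(n))
    return [f"{prefix}{i + 1:0{width}d}" for i in range(n)]


def _interaction_matrix(rng: np.random.Generator, G: int, E: int, rank: int,
                        sigma2: float) -> np.ndarray:
    """Rank-``rank`` double-centred G x E matrix with realized variance
    ``sigma2`` on the interaction degrees of freedom:
    sum(M**2) = (G-1)(E-1) * sigma2.

    A double-centred matrix lives in a (G-1)(E-1)-dimensional space, so
    this is the scaling under which the expected-mean-square (and REML)
    estimate of sigma2_gei is unbiased for the configured value; scaling
    by the raw mean square over G*E entries would inflate recovered
    components by GE / ((G-1)(E-1))."""
    if rank == 0 or sigma2 == 0.0:
        return np.zeros((G, E))
    # Draw scores, double-centre, then orthonormalize so the realized
    # matrix has exactly the requested rank with probability 1.
    A = rng.standard_normal((G, rank))
    B = rng.standard_normal((E, rank))
    A = A - A.mean(axis=0)
    B = B - B.mean(axis=0)
    A, _ = np.linalg.qr(A)
    B, _ = np.linalg.qr(B)
    weights = rng.uniform(0.5, 1.5, size=rank)
    M = (A * weights) @ B.T
    # QR after centring keeps columns in the centred subspace, so M is
    # double-centred already; rescale to the target stratum variance.
    scale = np.sqrt((G - 1) * (E - 1) * sigma2 / np.sum(M**2))
    return M * scale


def generate_multitrait_met(config: SynthConfig) -> tuple[METDataset, TruthLedger]:
    """Simulate a balanced MET with ``config.n_traits`` traits.

    Genotype effects are drawn jointly across traits with correlation
    ``trait_cor`` (identity when omitted); environment, interaction,
    block and error draws are independent between traits, each from its
    own named sub-stream of the seed.
    """
    cfg = config
    G, E, R, T = cfg.G, cfg.E, cfg.R, cfg.n_traits
    traits = cfg.traits
    root = np.random.SeedSequence(cfg.seed)
    # one child stream per (trait, component); genotype effects use a
    # single shared stream so the cross-trait correlation is exact
    children = root.spawn(1 + T * (len(_STREAMS) - 1))
    rng_g = np.random.default_rng(children[0])

    C = (
        np.asarray(cfg.trait_cor, dtype=float)
        if cfg.trait_cor is not None
        else np.eye(T)
    )
    L = np.linalg.cholesky(C)
    Z = rng_g.standard_normal((G, T))
    g_all = np.sqrt(cfg.sigma2_g) * (Z @ L.T)  # G x T, rows iid N(0, sigma2_g * C)

    ledger = TruthLedger(config=cfg)
    genotypes = _labels("G", G)
    envs = _labels("E", E)
    reps = _labels("R", R)

    frames: list[pd.DataFrame] = []
    gi, ei, ri = np.meshgrid(
        np.arange(G), np.arange(E), np.arange(R), indexing="ij"
    )
    base = pd.DataFrame(
        {
            ENV_COL: np.array(envs)[ei.ravel()],
            GEN_COL: np.array(genotypes)[gi.ravel()],
            REP_COL: np.array(reps)[ri.ravel()],
        }
    )
    for t_idx, trait in enumerate(traits):
        off = 1 + t_idx * (len(_STREAMS) - 1)
        rng_e = np.random.default_rng(children[off])
        rng_i = np.random.default_rng(children[off + 1])
        rng_b = np.random.default_rng(children[off + 2])
        rng_eps = np.random.default_rng(children[off + 3])

        g = g_all[:, t_idx]
        e = rng_e.normal(0.0, np.sqrt(cfg.sigma2_env), size=E)
        ge = _interaction_matrix(rng_i, G, E, cfg.gei_rank, cfg.sigma2_gei)
        b = rng_b.normal(0.0, np.sqrt(cfg.sigma2_block), size=(E, R))
        eps = rng_eps.normal(0.0, np.sqrt(cfg.sigma2_e), size=(G, E, R))

        y = (
            cfg.mu
            + g[:, None, None]
            + e[None, :, None]
            + ge[:, :, None]
            + b[None, :, :]
            + eps
        )
        base[trait] = y.ravel()
        ledger.genotype_effects[trait] = g
        ledger.environment_effects[trait] = e
        ledger.interaction[trait] = ge
        ledger.block_effects[trait] = b

    dataset = METDataset(base.copy(), traits=traits)
    return dataset, ledger


def generate_met(config: SynthConfig) -> tuple[METDataset, TruthLedger]:
    """Simulate a single-trait balanced MET (``n_traits`` forced to 1)."""
    if config.n_traits != 1:
        config = SynthConfig(**{**vars(config), "n_traits": 1, "trait_cor": None,
                                "trait_names": (config.traits[0],)})
    return generate_multitrait_met(config)


def config_from_dict(d: dict) -> SynthConfig:
    """Build a config from a plain mapping (YAML/JSON round-trip)."""
    d = dict(d)
    if "trait_cor" in d and d["trait_cor"] is not None:
        d["trait_cor"] = np.asarray(d["trait_cor"], dtype=float)
    if "trait_names" in d and d["trait_names"] is not None:
        d["trait_names"] = tuple(d["trait_names"])
    return SynthConfig(**d)
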