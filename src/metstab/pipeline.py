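"""End-to-end orchestration of the MET stability analysis.

Runs the full sequence — trait screen, YREM, joint ANOVA + AMMI,
REML/BLUP with genetic-parameter summaries, WAASB/WAASBY, and MTSI
selection with differential and gain — over one balanced MET, writing
every stage table as CSV plus a JSON run manifest.  Deterministic given
the input (or synthesis seed) and configuration.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .ammi import ammi_decompose, ipca_significance, joint_anova
from .data import METDataset, ge_means, read_met_csv
from .mixed import (
    fit_mixed_model,
    ge_interaction_blups,
    genetic_parameters,
    genotype_blups,
    lrt_random_terms,
)
from .mtsi import (
    build_waasby_table,
    factor_contributions,
    fit_factor_model,
    mtsi_scores,
    select_genotypes,
    selection_response,
)
from .screen import pearson_matrix, select_yield_traits
from .stability import stability_table
from .synth import SynthConfig, generate_multitrait_met
from .yrem import yrem_scores

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass(frozen=True)
class PipelineConfig:
    input_csv: str | None = None  # long-format MET CSV; None -> synthesize
    synth: SynthConfig | None = None
    traits: tuple[str, ...] | None = None  # None -> all trait columns
    focal: str = "YD"
    alpha: float = 0.05
    keep: tuple[str, ...] = ()
    theta_y: float = 65.0
    theta_s: float = 35.0
    intensity: float = 0.15
    out_dir: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.theta_y < 0 or self.theta_s < 0 or self.theta_y + self.theta_s == 0:
            raise ValueError("weights must be >= 0 with a positive sum")
        if not 0 < self.intensity <= 1:
            raise ValueError("intensity must be in (0, 1]")


@dataclass
class PipelineResult:
    data: METDataset
    correlation: pd.DataFrame
    selected_traits: list[str]
    yrem: pd.DataFrame
    anova: dict[str, pd.DataFrame]
    ipca: dict[str, pd.DataFrame]
    gvc: pd.DataFrame
    blups: dict[str, pd.DataFrame]
    stability: dict[str, pd.DataFrame]
    eigenvalues: pd.DataFrame | None
    mtsi: pd.DataFrame | None
    selection: list[str]
    response: pd.DataFrame | None
    contributions: pd.DataFrame | None
    manifest: dict = field(default_factory=dict)


def _load(cfg: PipelineConfig) -> METDataset:
    if cfg.input_csv is not None:
        return read_met_csv(cfg.input_csv, traits=cfg.traits)
    synth = cfg.synth or SynthConfig(seed=cfg.seed)
    if synth.seed != cfg.seed:
        synth = dataclasses.replace(synth, seed=cfg.seed)
    data, _ = generate_multitrait_met(synth)
    return data


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """Execute every stage and (optionally) write the report bundle."""
    data = _load(cfg)
    traits = list(cfg.traits or data.traits)

    # 1. trait screen on genotype means across environments
    means = pd.DataFrame(
        {t: ge_means(data, t).values.mean(axis=1) for t in traits}
    )
    cm = pearson_matrix(means)
    selected_traits = select_yield_traits(
        cm, focal=cfg.focal, alpha=cfg.alpha, keep=cfg.keep
    )

    # 2. YREM on the focal (yield) trait
    yrem = yrem_scores(ge_means(data, cfg.focal)).to_frame()

    # 3-5. per selected trait: joint ANOVA + AMMI axes, REML/BLUP, GVC
    anova, ipca, blups, stab = {}, {}, {}, {}
    gvc_rows = []
    h2_map: dict[str, float] = {}
    for trait in selected_traits:
        an = joint_anova(data, trait)
        anova[trait] = an.table
        dec = ammi_decompose(ge_means(data, trait))
        _, _, R = data.design
        ipca[trait] = ipca_significance(dec, an.residual_ms, an.residual_df, R)

        fit = fit_mixed_model(data, trait)
        params = genetic_parameters(fit.components)
        lrt = lrt_random_terms(data, trait)
        blups[trait] = genotype_blups(fit)
        gvc_rows.append(
            {
                "trait": trait,
                "sigma2_g": fit.components.sigma2_g,
                "sigma2_gei": fit.components.sigma2_gei,
                "sigma2_e": fit.components.sigma2_e,
                "H2_broad": params.H2_broad,
                "h2_mean": params.h2_mean,
                "accuracy_As": params.accuracy_As,
                "r_ge": params.r_ge,
                "r2_gei": params.r2_gei,
                "lrt_gen": lrt["genotype"].statistic,
                "lrt_gen_p": lrt["genotype"].p_value,
                "lrt_gei": lrt["genotype:environment"].statistic,
                "lrt_gei_p": lrt["genotype:environment"].p_value,
            }
        )
        h2_map[trait] = params.h2_mean

        # 6. stability (WAASB on the interaction BLUP matrix)
        scores = stability_table(
            trait,
            fit.genotype_means,
            ge_interaction_blups(fit),
            theta_y=cfg.theta_y,
            theta_s=cfg.theta_s,
        )
        stab[trait] = scores
    gvc = pd.DataFrame(gvc_rows).set_index("trait")

    # 7. MTSI over the WAASBY table (needs >= 3 traits)
    eig = mtsi_frame = response = contrib = None
    selection: list[str] = []
    if len(selected_traits) >= 3:
        table = build_waasby_table({t: stab[t] for t in selected_traits})
        model = fit_factor_model(table)
        eig = model.explained_variance()
        result = mtsi_scores(model)
        selection = select_genotypes(result, cfg.intensity)
        mtsi_frame = pd.DataFrame({"mtsi": result.mtsi, "rank": result.ranks})
        mtsi_frame["selected"] = mtsi_frame.index.isin(selection)
        response = selection_response(
            means[selected_traits], selection, h2_map
        )
        contrib = factor_contributions(model, result, selection)

    manifest = {
        "metstab_version": __version__,
        # out_dir is a run location, not an analysis decision; leaving it
        # out keeps the bundle byte-identical across reruns elsewhere
        "config": _jsonable(
            {k: v for k, v in dataclasses.asdict(cfg).items() if k != "out_dir"}
        ),
        "design": data.design,
        "traits": traits,
        "selected_traits": selected_traits,
        "selection": selection,
        "decisions": {
            "alpha": cfg.alpha,
            "waasby_weights": [cfg.theta_y, cfg.theta_s],
            "intensity": cfg.intensity,
            "factor_retention": "Kaiser (eigenvalue > 1)",
            "factor_scores": "regression (Thomson) on varimax-rotated loadings",
            "quadrant_splits": "x: grand mean; y: mean WAASB",
        },
    }
    result = PipelineResult(
        data=data,
        correlation=cm.r,
        selected_traits=selected_traits,
        yrem=yrem,
        anova=anova,
        ipca=ipca,
        gvc=gvc,
        blups=blups,
        stability={t: s.to_frame() for t, s in stab.items()},
        eigenvalues=eig,
        mtsi=mtsi_frame,
        selection=selection,
        response=response,
        contributions=contrib,
        manifest=manifest,
    )
    if cfg.out_dir is not None:
        write_bundle(result, cfg.out_dir)
    return result


def write_bundle(result: PipelineResult, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.correlation.to_csv(out / "correlation.csv")
    result.yrem.to_csv(out / "yrem.csv")
    for trait in result.selected_traits:
        result.anova[trait].to_csv(out / f"anova_{trait}.csv")
        result.ipca[trait].to_csv(out / f"ipca_{trait}.csv")
        result.blups[trait].to_csv(out / f"blup_{trait}.csv")
        result.stability[trait].to_csv(out / f"stability_{trait}.csv")
    result.gvc.to_csv(out / "gvc.csv")
    if result.mtsi is not None:
        result.eigenvalues.to_csv(out / "mtsi_eigenvalues.csv")
        result.mtsi.to_csv(out / "mtsi.csv")
        result.response.to_csv(out / "selection_response.csv")
        result.contributions.to_csv(out / "factor_contributions.csv")
    (out / "manifest.json").write_text(
        json.dumps(result.manifest, indent=1, sort_keys=True)
    )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj
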