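"""REML variance components, LRT, BLUPs and genetic parameters.

Fits the mixed model (genotype and GEI random; environment and
replicate-within-environment fixed) per trait, tests the random terms,
and summarizes heritability, selection accuracy and the GE correlation.
"""

from pathlib import Path

import pandas as pd

from metstab.data import read_met_csv
from metstab.mixed import (
    fit_mixed_model,
    genetic_parameters,
    genotype_blups,
    lrt_random_terms,
)

OUT = Path(__file__).resolve().parents[1] / "results"

if __name__ == "__main__":
    data = read_met_csv(str(OUT / "met.csv"))
    rows = []
    for trait in data.traits:
        fit = fit_mixed_model(data, trait)
        p = genetic_parameters(fit.components)
        lrt = lrt_random_terms(data, trait)
        genotype_blups(fit).to_csv(OUT / f"blup_{trait}.csv")
        rows.append(
            {
                "trait": trait,
                "sigma2_g": fit.components.sigma2_g,
                "sigma2_gei": fit.components.sigma2_gei,
                "sigma2_e": fit.components.sigma2_e,
                "H2_broad": p.H2_broad,
                "accuracy_As": p.accuracy_As,
                "r_ge": p.r_ge,
                "r2_gei": p.r2_gei,
                "h2_mean": p.h2_mean,
                "lrt_gen_p": lrt["genotype"].p_value,
                "lrt_gei_p": lrt["genotype:environment"].p_value,
            }
        )
    gvc = pd.DataFrame(rows).set_index("trait")
    gvc.to_csv(OUT / "gvc.csv")
    print(gvc.round(3).to_string())
    print(f"\nwrote gvc.csv and blup_*.csv to {OUT}")
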