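"""Joint ANOVA and AMMI interaction axes for every selected trait.

Partitions plot variance into environment, replicate-within-environment,
genotype, GEI and residual, then decomposes the interaction into IPCA
axes with Gollob F-tests.
"""

from pathlib import Path

from metstab.ammi import ammi_decompose, ipca_significance, joint_anova
from metstab.data import ge_means, read_met_csv

OUT = Path(__file__).resolve().parents[1] / "results"

if __name__ == "__main__":
    data = read_met_csv(str(OUT / "met.csv"))
    _, _, R = data.design
    for trait in data.traits:
        an = joint_anova(data, trait)
        an.table.to_csv(OUT / f"anova_{trait}.csv")
        dec = ammi_decompose(ge_means(data, trait))
        tab = ipca_significance(dec, an.residual_ms, an.residual_df, R)
        tab.to_csv(OUT / f"ipca_{trait}.csv")
        sig = (tab["p"] < 0.01).sum()
        pct = an.table["pct_SS"]
        print(
            f"{trait}: G {pct['genotype']:.1f}% / E {pct['environment']:.1f}% / "
            f"GEI {pct['genotype:environment']:.1f}% of main+interaction SS; "
            f"{sig}/{len(tab)} IPCA axes significant at 1%"
        )
    print(f"wrote anova_*.csv and ipca_*.csv to {OUT}")
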