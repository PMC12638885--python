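"""WAASB stability, WAASBY superiority and quadrant classification.

The interaction BLUP matrix of each trait is decomposed by SVD; WAASB
averages the absolute axis scores weighted by explained interaction
variance.  WAASBY blends rescaled performance and stability 65:35.
"""

from pathlib import Path

from metstab.data import read_met_csv
from metstab.mixed import fit_mixed_model, ge_interaction_blups
from metstab.stability import stability_table

OUT = Path(__file__).resolve().parents[1] / "results"

if __name__ == "__main__":
    data = read_met_csv(str(OUT / "met.csv"))
    for trait in data.traits:
        fit = fit_mixed_model(data, trait)
        tab = stability_table(trait, fit.genotype_means, ge_interaction_blups(fit))
        tab.to_frame().to_csv(OUT / f"stability_{trait}.csv")
        q4 = tab.quadrant[tab.quadrant == "IV"].index.tolist()
        print(f"{trait}: stable high performers (quadrant IV): {', '.join(q4)}")
    print(f"wrote stability_*.csv to {OUT}")
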