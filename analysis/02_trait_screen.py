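"""Pearson screen over genotype means: which traits travel with yield.

Reads the simulated MET, correlates genotype means across environments,
and keeps traits with a significant positive yield correlation (DM is
force-kept, mirroring the agronomic judgment call for maturity).
"""

from pathlib import Path

import pandas as pd

from metstab.data import ge_means, read_met_csv
from metstab.screen import pearson_matrix, select_yield_traits

OUT = Path(__file__).resolve().parents[1] / "results"

if __name__ == "__main__":
    data = read_met_csv(str(OUT / "met.csv"))
    means = pd.DataFrame(
        {t: ge_means(data, t).values.mean(axis=1) for t in data.traits}
    )
    cm = pearson_matrix(means)
    cm.flagged().to_csv(OUT / "correlation.csv")
    chosen = select_yield_traits(cm, focal="YD", keep=("DM",))
    print("yield correlations:",
          ", ".join(f"{t} {cm.r.loc[t, 'YD']:.2f}" for t in data.traits if t != "YD"))
    print(f"selected for stability analysis: {', '.join(chosen)}")
    print(f"wrote flagged correlation matrix to {OUT / 'correlation.csv'}")
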