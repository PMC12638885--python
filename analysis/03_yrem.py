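"""Yield relative to the environmental maximum: crossover-GEI losses.

Each genotype's cell-mean yield is divided by the best yield in its
environment; 1 - (average YREM) is the yield share lost to crossover
interaction.
"""

from pathlib import Path

from metstab.data import ge_means, read_met_csv
from metstab.yrem import rank_by_yrem, yrem_scores

OUT = Path(__file__).resolve().parents[1] / "results"

if __name__ == "__main__":
    data = read_met_csv(str(OUT / "met.csv"))
    res = yrem_scores(ge_means(data, "YD"))
    res.to_frame().to_csv(OUT / "yrem.csv")
    top = rank_by_yrem(res)[:5]
    print("top genotypes by average YREM:")
    for g in top:
        print(f"  {g}: YREM {res.average[g]:.2f}, crossover loss {res.loss[g]:.0%}")
    print(f"wrote per-environment YREM table to {OUT / 'yrem.csv'}")
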