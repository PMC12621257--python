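#!/usr/bin/env python
"""Stage 4: aggregate per-compound metrics into method rankings.

Builds compound x method tables for bond MUE, superposition RMSE,
absolute shift and similarity; reports per-method average and median side
by side (they can and do rank methods differently), box-plot statistics,
and a subgroup contrast between the first and second half of the compound
set. Figures go next to the tables.
"""

from pathlib import Path

import pandas as pd

from benchkit import BenchmarkTable, aggregate, boxplot_stats, subgroup
from benchkit.ranking import _save_boxplot

ROOT = Path(__file__).resolve().parent.parent
OUT = ROOT / "results"


def main() -> None:
    struct = pd.read_csv(OUT / "02_structure_errors.csv")
    sim = pd.read_csv(OUT / "03_similarity.csv")

    frames = []
    for metric, df, absolute in (
        ("mue", struct, False),
        ("rmse", struct, False),
        ("abs_shift", sim.rename(columns={"delta_opt": "abs_shift"}), True),
        ("s_max", sim, False),
    ):
        pivot = df.pivot(index="compound", columns="method", values=metric)
        table = BenchmarkTable(pivot, metric_name=metric)
        agg = aggregate(table, absolute=absolute).assign(metric=metric)
        frames.append(agg.reset_index())
        vals = pivot.abs() if absolute else pivot
        _save_boxplot(vals, metric, OUT / f"04_boxplot_{metric}.png")

        if metric == "mue":
            compounds = sorted(pivot.index)
            half = len(compounds) // 2
            groups = {"groupA": compounds[:half], "groupB": compounds[half:]}
            for gname, stats in subgroup(table, groups).items():
                med = {m: round(s.median, 4) for m, s in stats.items()}
                print(f"MUE medians within {gname} ({len(groups[gname])} compounds): {med}")

    agg_df = pd.concat(frames, ignore_index=True)
    agg_df.to_csv(OUT / "04_aggregates.csv", index=False, float_format="%.6f")
    print(f"\nwrote {OUT / '04_aggregates.csv'}")

    print("\nmethod ranking by average bond MUE (A, best first):")
    print(agg_df[agg_df.metric == "mue"].sort_values("average")
          [["method", "average", "median"]].round(4).to_string(index=False))
    print("\nmethod ranking by average absolute shift (eV, best first):")
    print(agg_df[agg_df.metric == "abs_shift"].sort_values("average")
          [["method", "average", "median"]].round(3).to_string(index=False))
    print("\nmethod ranking by average similarity (higher is better):")
    smax = agg_df[agg_df.metric == "s_max"].sort_values("average", ascending=False)
    print((smax.assign(average=100 * smax["average"], median=100 * smax["median"]))
          [["method", "average", "median"]].round(1).to_string(index=False))


if __name__ == "__main__":
    main()
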