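#!/usr/bin/env python
"""Stage 2: score every computed geometry against its reference.

For each compound x method pair: optimal-superposition RMSE over the heavy
atoms, and MUE/MSE over the metal-ligand bonds of the coordination sphere.
Compares the recovered MUE/MSE against the generator's ground truth and
reports how closely the per-method mean signed error tracks the injected
bond-length bias.
"""

from pathlib import Path

import pandas as pd
import yaml

from benchkit import compare_structures, read_xyz

ROOT = Path(__file__).resolve().parent.parent
DATA = ROOT / "results" / "simulated"
OUT = ROOT / "results"


def main() -> None:
    cfg = yaml.safe_load(open(DATA / "manifest.yaml"))
    compounds = {c["id"]: c for c in cfg["compounds"]}
    rows = []
    for method in cfg["methods"]:
        for cid, files in sorted(method["data"].items()):
            ref = read_xyz(DATA / compounds[cid]["reference_structure"])
            comp = read_xyz(DATA / files["structure"])
            errs = compare_structures(comp, ref, tolerance=cfg.get("bond_tolerance", 1.3))
            rows.append(
                dict(compound=cid, method=method["id"], rmse=errs.rmse,
                     n_bonds=len(errs.per_bond), mue=errs.mue, mse=errs.mse)
            )
    df = pd.DataFrame(rows).sort_values(["compound", "method"])
    out = OUT / "02_structure_errors.csv"
    df.to_csv(out, index=False, float_format="%.6f")

    truth = pd.read_csv(DATA / "ground_truth.csv")
    merged = df.merge(truth, on=["compound", "method"])
    mue_gap = (merged.mue - merged.mue_true).abs().max()
    by_method = merged.groupby("method")[["mse", "mse_true"]].mean()
    print(f"wrote {out} ({len(df)} comparisons)")
    print(f"largest |MUE - truth| across cells: {mue_gap:.4f} A "
          "(residual from the 0.01 A jitter on non-bonded atoms)")
    print("per-method mean MSE vs injected bond bias (A):")
    print(by_method.rename(columns={"mse": "recovered", "mse_true": "injected"})
          .round(4).to_string())


if __name__ == "__main__":
    main()
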