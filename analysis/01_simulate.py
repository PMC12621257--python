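#!/usr/bin/env python
"""Stage 1: generate the simulated benchmark inputs.

Emits a complete benchmark — pseudo-experimental spectra, per-method stick
spectra with known systematic energy biases, reference and per-method XYZ
structures with known bond-length biases — plus a ground-truth sidecar, so
the later stages can be validated closed-loop. Eight compounds x five
methods keeps every downstream stage fast while leaving enough compounds
for meaningful medians and box plots.
"""

from pathlib import Path

from benchkit.synthetic import simulate_benchmark

ROOT = Path(__file__).resolve().parent.parent
DATA = ROOT / "results" / "simulated"
SEED = 20260927


def main() -> None:
    manifest = simulate_benchmark(
        DATA, n_compounds=8, n_methods=5, seed=SEED, noise_level=0.03
    )
    print(f"simulated benchmark written under {DATA}")
    print(f"manifest: {manifest}")
    print(f"ground truth: {DATA / 'ground_truth.csv'}")


if __name__ == "__main__":
    main()
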