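# benchkit

Benchmarking how well quantum-chemistry methods reproduce the UV–vis
spectra and coordination geometries of mononuclear transition-metal (in
particular iron) complexes.

Excited-state calculations emit *stick spectra* — vertical transition
energies `E_i` (eV) with oscillator strengths `f_i` — which cannot be
compared directly with a measured absorption curve. benchkit builds a
continuous spectrum by shifted Gaussian broadening,

    I_comp(E; δ, σ) = N · Σ_i f_i · exp(−(E − E_i + δ)² / (2σ²)),

where `N` normalizes the maximum to one, `σ` is the band width (FWHM =
2√(2 ln 2)·σ ≈ 2.355 σ) and `δ` is a uniform energy shift (positive `δ`
moves the bands to lower energy). It then scores the broadened spectrum
against the experimental one on a shared energy window [E1, E2] with a
cosine similarity,

    S(δ, σ) = ∫ I_exp·I_comp dE / √(∫ I_exp² dE · ∫ I_comp² dE),

integrated by composite Simpson quadrature, and maximizes S over (δ, σ)
with a multi-start Nelder–Mead simplex inside the box δ ∈ [−1.5, 1.5] eV,
σ ∈ (0, 0.5] eV. The maximized similarity `S_max` scores the spectral
*shape*; the magnitude of the optimal shift `|δ|` proxies the method's
systematic error in excitation energies.

Geometries are scored twice: by the root-mean-square Cartesian deviation
after optimal rigid-body superposition (Kabsch alignment, proper rotations
only, hydrogens excluded), and by the mean unsigned / mean signed error
(MUE/MSE) of the metal–ligand bond lengths of the coordination sphere —
the atoms directly bonded to the metal, found by a covalent-radius
distance cutoff. Per-compound metrics are aggregated per method into
averages, medians and box-plot statistics.

Because real benchmark inputs (digitized spectra, excited-state tables,
crystal structures) carry no ground truth, the package ships a synthetic
generator that emulates all three input kinds with known true parameters,
so every stage is validated closed-loop.

## Worked example

```sh
benchkit simulate --out-dir demo/data --seed 11 --n-compounds 2 --n-methods 2
benchkit run --manifest demo/data/manifest.yaml --out-dir demo/out --no-plots
```

prints (abridged):

```
method   average    median  n    metric
    M1  0.017133  0.017133  2       mue
    M2  0.017198  0.017198  2       mue
    M1  0.238891  0.238891  2 abs_shift
    M2  0.099443  0.099443  2 abs_shift
    M1  0.994687  0.994687  2     s_max
    M2  0.995649  0.995649  2     s_max
```

The simulator injected a systematic excitation-energy bias of −0.25 eV
into method M1 and +0.10 eV into M2 (see `demo/data/ground_truth.csv`),
and the pipeline recovers absolute shifts of 0.239 and 0.099 eV; bond MUE
around 0.017 Å reflects the injected ±0.02 Å bond biases plus the 0.01 Å
jitter; similarities above 99% say the band shapes themselves are
reproduced almost exactly. `demo/out/similarity.csv` and
`structure_errors.csv` hold the per-compound values, `aggregates.csv` and
`boxplot_*.csv` the summaries.

The numbered scripts under `analysis/` run the same pipeline as a
narrative study (8 compounds × 5 methods): `01_simulate.py` generates the
inputs, `02_structures.py` and `03_spectra.py` score geometries and
spectra against the generator's ground truth, `04_rank.py` ranks the
methods. Outputs land under `results/`.

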