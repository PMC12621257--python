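# Methods

## Spectral model

A computed UV–vis spectrum is modelled as a sum of Gaussians, one per
vertical transition, with a single width σ and a single shift δ shared by
all transitions:

    I_comp(E; {f_i, E_i}, δ, σ) = N · Σ_i f_i · exp(−(E − E_i + δ)² / (2σ²)).

N renormalizes the maximum to one and is recomputed for every (δ, σ) —
it depends on both parameters, so it is never cached across optimizer
steps. The sign convention puts each band's peak at `E_i − δ`: a positive
δ moves the computed spectrum to lower energy. Because this convention is
easy to misread, results also expose the *apparent* band displacement
`−δ`. The model deliberately omits Lorentzian/Voigt profiles,
energy-dependent widths and vibronic structure: a single (δ, σ) pair per
spectrum is what makes |δ| interpretable as a method's systematic
excitation-energy error.

The shared-width assumption means S_max saturates only when all bands in
the window are reproduced with roughly the right relative intensities; a
single inverted band ratio (e.g. a charge-transfer band predicted too
strong) drags S_max down even when each band position is fixable by δ.

## Experimental-spectrum conditioning

Digitized spectra arrive as wavelength–intensity pairs. Conversion to the
energy domain uses `E = hc/λ` with hc pinned at 1239.841984 eV·nm (the
single source of truth for all conversions), and rescales the intensity
by the Jacobian factor `λ²/hc` so integrated band areas are preserved
(`dλ = (λ²/hc) dE`). The spectrum is then smoothed, interpolated to a
uniform grid with a 100 cm⁻¹ (≈ 0.0124 eV) default spacing, clipped at
zero and max-normalized, restricted to a per-compound window [E1, E2]
chosen to avoid the noisiest digitized regions.

Choices where several defensible options existed:

* **Smoothing** — a Savitzky–Golay moving-window polynomial filter
  (window 9 points, order 3) by default. It is standard,
  order-preserving, and pluggable: any callable on the intensity array
  can replace it, and `None` disables it. The window auto-shrinks on
  short spectra.
* **Interpolation** — piecewise linear by default (monotone, no
  ringing); cubic splines optional.
* **Negative intensities** (a digitization artifact) are clipped to zero
  before normalization, as the cosine similarity assumes non-negative
  signals.
* Duplicate abscissa values in a digitized file are averaged; rows are
  sorted to a strictly monotone abscissa.

Max-normalization has no effect on S (cosine similarity is
scale-invariant); it only standardizes plots and the stored carriers.

## Similarity and its maximization

All integrals use composite Simpson quadrature on the shared uniform
grid. Simpson's rule needs an even interval count; when the window gives
an odd one, the final interval is integrated by the trapezoid rule — a
single-interval O(Δ³) correction, tested against dense-grid references.
The computed spectrum is evaluated directly on the experimental grid
restricted to the window, so the integrand is pointwise aligned and no
second interpolation is introduced. Transitions whose shifted centres lie
outside the window still contribute their tails.

The optimizer is Nelder–Mead with:

* **Box constraints** δ ∈ [−1.5, 1.5] eV, σ ∈ [0.005, 0.5] eV. The
  classic simplex is unconstrained, so the objective evaluates at the
  clipped point and adds a quadratic penalty (weight 10) on the
  excursion; the simplex can approach the boundary without collapsing.
  The σ lower bound is numerical safety — zero width is singular in the
  band model; 0.005 eV is below half the default grid spacing, so no
  physically meaningful optimum is excluded.
* **Multi-start** — a deterministic 3×3 grid of interior starting points
  at fractions 1/4, 1/2, 3/4 of each box edge. No randomness anywhere in
  the optimizer. The returned point is the best over all restarts *and*
  their starting values, so the result can never be worse than any
  restart's outcome.
* **Tolerances** 1e-6 on simplex size and function value; ties between
  restarts broken by higher S, then smaller |δ|, then smaller σ (a
  1e-9 tie window).
* Non-convergence of every restart is reported via a `converged` flag on
  the result, never as an exception.

An exhaustive grid scan (0.01 eV × 0.005 eV) is kept as a brute-force
oracle; tests and the acceptance script verify the simplex result never
falls more than 1e-4 below it.

## Geometry metrics

Superposition RMSE is `sqrt((1/N) Σ_i |r_i^comp − r_i^ref|²)` after
centroid alignment and the optimal proper rotation (Kabsch via SVD, with
the determinant sign fixed to exclude reflections — mirror images are not
the same conformer). Hydrogens are excluded: X-ray positions for H are
unreliable next to heavy elements. Atom correspondence is positional
(index by index after H filtering) and guarded by a strict
element-sequence check; no graph matching is attempted, so misordered
files fail loudly instead of being silently re-paired. Structures with
fewer than three non-collinear atoms are rejected as ill-posed.

The coordination sphere is detected on the *reference* structure: every
non-hydrogen atom within `tolerance × (r_cov(M) + r_cov(X))` of the
metal, with tolerance 1.3 by default and radii pinned to the Cordero 2008
single-bond set (high-spin values for Mn/Fe/Co; unknown elements fall
back to 1.5 Å). The same index pairs are then measured in the computed
structure, and an explicit per-compound bond list in the manifest
overrides detection entirely. Per-bond signed errors
`R^comp − R^ref` give MUE (mean absolute) and MSE (mean signed);
MUE ≥ |MSE| always, with equality iff all signed errors share one sign.
Bond metrics use distances only, hence are independent of any
superposition.

## Aggregation

Per-method aggregates report the arithmetic mean and the median side by
side and never collapse them into one score — methods genuinely rank
differently under the two, and the disagreement (mean dragged by a few
pathological compounds, median not) is informative. Energy shifts are
aggregated as |δ|. Box-plot statistics use linear-interpolation quartiles
(numpy's default percentile convention), the conventional 1.5×IQR outlier
rule, and whiskers at the extreme non-outlier points. Missing cells
(failed or absent calculations) are excluded from aggregates and never
affect other cells. All result tables are written with fixed float
formatting, so reruns are byte-identical.

## Synthetic benchmark generator

Every generator is a pure function of its seed and parameters.

* **Stick spectra** — energies uniform over the requested window
  (default extremes 1.4–6.2 eV, matching typical visible–UV comparison
  windows for iron complexes; 40 transitions by default, a typical
  excited-state count for this system size); strengths log-uniform over
  two decades, so a few transitions dominate as in real spectra.
* **Pseudo-experimental spectra** — broadened truth (δ*, σ*) times
  multiplicative noise `1 + ε·u`, u uniform on [−1, 1], default
  ε = 3%: digitization and baseline error scale with the signal. Clipped
  and renormalized.
* **Structure pairs** — an ideal coordination polyhedron (tetrahedron,
  trigonal bipyramid or octahedron; Fe–N ≈ 2 Å) with each metal–ligand
  bond stretched along its bond vector by a prescribed per-bond delta,
  Gaussian jitter (default 0.01 Å) on atoms outside the coordination
  sphere, and a seeded rigid motion. With zero jitter the ground-truth
  MUE/MSE equal the mean |delta| and mean delta exactly.
* **Full simulated benchmark** — each simulated "method" carries a fixed
  systematic excitation-energy bias (±0.05…0.9 eV, spanning the range
  where methods differ meaningfully) plus 0.03 eV per-transition scatter
  and 10% log-normal strength jitter, and a systematic bond-length bias
  (±0.015…0.05 Å, bracketing the accuracy of common functionals) plus
  0.01 Å per-bond scatter. A ground-truth sidecar records every true
  parameter.

What passing closed-loop tests does and does not show: recovery of known
(δ*, σ*, bond deltas) validates the conditioning, broadening, quadrature,
optimization and error metrics as computations. It does not certify
behaviour on real data, whose band shapes are not sums of a few
Gaussians, whose noise is correlated, and whose structures differ by
conformational rearrangements rather than clean bond stretches — the
failure modes the RMSE caveats above are about.

## Problem sizes and determinism

Default study sizes: the analysis drivers use 8 compounds × 5 methods;
recovery studies use 50 seeded scenarios of 40 transitions; the
brute-force superposition cross-check uses 20 random 5–10 atom toys; bond
identities are checked over 1000 random perturbation scenarios. These
sizes give stable statistics while keeping any single stage at the scale
of a coffee break on one core. Every random draw flows from an explicit
seed; the CLI defaults to seed 0.

## Known limitations

* Single global (δ, σ): no per-band shifts, no wavelength-scaling
  corrections, no oscillator-strength rescaling.
* Positional atom correspondence cannot handle reordered atom lists or
  symmetry-equivalent permutations; such inputs are rejected, not
  repaired.
* Bond detection assumes a sensible reference geometry; grossly
  distorted references need the explicit bond-list override.
* The box-plot outlier rule and quantile convention are fixed choices;
  other conventions shift quartiles slightly for small n.
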