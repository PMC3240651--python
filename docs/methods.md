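# Methods

## The statistic and the regression model

Raw steady-state ¹H-¹⁵N NOE values are heteroscedastic across their range
and unbounded below; the NHNOE\* transform, `star_i = b^{x_i} / max_j
b^{x_j}`, maps a protein's profile onto (0, 1] so it can share an axis with
disorder probabilities.  The transform is order-preserving for any base
b > 1 and exactly invariant to adding a constant to every raw value (the
ratio cancels it), so the choice of b affects only the curvature of the
scale.  We take b = 10, the common-log reading of "antilog", and expose it
in `TransformConfig`; it is computed as `b^(x − max x)` to avoid overflow.

The concordance model is ordinary least squares of NHNOE\* (response) on
one predictor's probabilities (covariate), per protein.  Pairs form only
on residues where both values exist: prolines (no amide hydrogen) and
unassigned residues drop out listwise, which is why sample sizes sit below
sequence lengths.  The association is negative — rigid residues have high
NHNOE\* and low disorder probability — but correlation strength is
conventionally tabulated as a magnitude, so `RegressionResult` stores
r ∈ [0, 1] plus a separate sign.  Significance is the exact null
transform t = r√(n−2)/√(1−r²) against Student's t with n−2 degrees of
freedom (two-tailed), implemented on scipy's t distribution and
cross-checked in the tests against direct numerical quadrature of the t
density.  r = 1 returns p = 0 as the documented limit.

When verifying a published p against a published (r, n) pair, exact
agreement is impossible in principle because r is printed at two decimals.
The checker therefore applies two rules: (i) the direct rule — the
recomputed p reproduces the printed string at its own precision, or
deviates by ≤ 10% relative; (ii) the rounding-interval rule — some
correlation within ±0.005 of the printed r yields the printed p.  Printed
bounds "<x" (including the degenerate "<0.000000", read as vanishing at
the printed precision) are checked as p ≤ bound.  On the packaged
18-row table, 16 rows satisfy the direct rule and all 18 the interval
rule.

## The ≥ kσ misprediction rule

σ is the regression residual standard error, √(SSE/(n−2)) — the spread
around the *conditional* mean, the natural yardstick once "the mean value
estimated from the regression" is the reference.  A residue is flagged
when |observed − fitted| ≥ k·σ (default k = 1, a deliberately strict
bar: for Gaussian residuals it flags the 2Φ(−1) ≈ 31.7% tails; 2σ is the
conventional outlier cutoff and is reported alongside).  Direction is
meaningful only through the negative association: a positive residual
(measured NHNOE\* above the line) means the predictor overcalled
disorder, labelled ABOVE; the labels swap if a fit comes out
positive-sloped.  If σ = 0 (degenerate perfect fit) any nonzero residual
is flagged, with an infinite σ-multiple recorded.

Flags are made per (protein, predictor) pair with that pair's own
regression, then pooled: the per-type numerator counts flag *events*
(a residue flagged by three predictors counts three times) and the
denominator is the type's occurrence count in the sequence set, so
percentages can exceed 100 and measure flags per residue of that type.
Types absent from the sequences are undefined (NaN), never 0.  Proline is
reported as 0 with a NOT_MEASURABLE annotation and is excluded from the
mean ± sd summary by default (`include_not_measurable=True` restores it):
its zero is a data limitation, not predictor accuracy.  The summary also
excludes types not occurring at least once per homologue
(`min_per_homologue`), and uses the sample (n−1) standard deviation.

Composition enrichment is `100·(observed/reference − 1)` per type, pooled
over the sequence set.  The shipped reference composition
(`data/reference_composition_synthetic.yaml`) is a synthetic stand-in
shaped like a disordered-protein database (hydrophobics rare, E/K/S/P/G
common); real comparisons should supply the actual database table.

## The synthetic generator

The generator emulates what a 600 MHz triplicate NOE experiment on an
IDP-like chain would produce, and what a well-behaved predictor of it
would look like.  It does **not** emulate: chemical-shift overlap and
assignment gaps (beyond prolines), two-timescale (Lipari–Szabo)
internal motion, conformational exchange, field-dependent noise, or any
sequence-dependence of the dynamics — τ profiles are positional, not
compositional.  Passing tests therefore demonstrate the statistical
machinery under the assumed model, not predictor accuracy on real
proteins.

* **τ profile** — baseline 3·10⁻¹⁰ s (mid-range for IDP residues, which
  run ≈ 100 ps–1 ns), decaying exponentially toward 1·10⁻¹⁰ s at each
  terminus over 5 residues (the polymer end effect); Gaussian bumps
  (center, width, τ_peak) model transient-helix rigidification at binding
  regions — the p53TAD-like preset places them at residues 15–30 and
  40–60 with peaks of 8·10⁻¹⁰ and 5·10⁻¹⁰ s.  Bumps combine with the
  baseline by maximum so overlaps never exceed the larger peak.  Setting
  `terminal_decay_length = 0` disables the end effect.  All τ are clipped
  to [10⁻¹¹, 10⁻⁷] s.
* **NOE physics** — single-Lorentzian spectral density
  J(ω) = (2/5)·τ/(1+(ωτ)²); dipolar constant from γH, γN, r_NH = 1.02 Å;
  ¹⁵N CSA −160 ppm (on by default, off for closed-form limit tests);
  NOE = 1 + (γH/γN)·σ_NH/R1 with σ_NH = (d²/4)(6J(ωH+ωN) − J(ωH−ωN)) and
  R1 = (d²/4)(J(ωH−ωN) + 3J(ωN) + 6J(ωH+ωN)) + c²J(ωN).  Dipolar-only,
  the extreme-narrowing limit is 1 + (γH/γN)/2 ≈ −3.93; the function is
  monotone in τ through the whole range, with the rigid plateau ≈ 0.82
  at 600 MHz.  Note 100 ps already gives ≈ −3.4 at 600 MHz, so terminal
  residues sit below −3 while interior residues stay above it.
* **Measurement** — each residue's raw NOE is the mean of 3 replicates
  with Gaussian noise (sd 0.05 by default — a config placeholder, not a
  measured figure), mirroring triplicate averaging; prolines are missing.
* **Planted association** — probabilities are
  clip₀₁(a − b·star + ε), ε ~ N(0, noise_sd).  b is calibrated from the
  star profile's sample sd so the expected correlation magnitude equals
  `planted_rho` at the given noise (b = ρ·σ_ε/(s_star·√(1−ρ²)));
  a centers the line at probability 0.5.  Clipping can attenuate the
  association, so the realized noise-free correlation is reported in the
  profile metadata next to the target.  noise_sd defaults to 0.10, a
  probability-scale scatter that keeps clipping essentially inactive for
  mid-range lines.  With noise_sd = 0 the mapping is exact and |r| = 1.

Determinism: all randomness flows from `SyntheticSpec.seed` through
`numpy.random.default_rng`; identical spec and seed give bit-identical
profiles.

A note on statistical power at this design: with a true association of
0.55 over n = 58 pairs, the sampling spread of the fitted r (≈ 0.08–0.09)
leaves roughly 5% of replicates below the r ≈ 0.40 needed for p < 0.002,
so about 95% — not essentially all — of replicates clear that bar; the
per-replicate mean of r recovers the planted value to well within 0.03.
`scripts/acceptance.py` reports both numbers as computed.

## Sequence fixtures

Only the human p53TAD anchor (residues 1–73 of human p53) is a real
sequence.  `noestar.fixtures.synthetic_family` derives five synthetic
"homologues" by seeded proline-neutral substitution at graded divergence
(6 substitutions ≈ 92% identity for the macaque-like partner, up to 28
for the mouse-like one), preserving the proline pattern and the E/L/P/S
composition skew.  Percent identity counts matches over columns where
neither sequence is gapped, with that column count as denominator —
singly- and doubly-gapped columns are excluded; cross-homologue residue
statements travel through alignment position maps, never raw indices.

## Numerical and interface choices

* Missing is NaN in memory and the literal `NA` on disk, never 0.
* Smoothing windows truncate at the termini (no padding invented) and
  skip missing neighbours; an output is missing only if its whole window
  is.  Smoothing is display-only by default; `smooth_before_regression`
  feeds smoothed, re-normalized NHNOE\* into the fits for sensitivity
  checks.
* Report TSVs carry `# noestar <version>`, a config hash and the seed;
  floats are written at 6 significant digits, which round-trips the
  analysis bit-stably at that precision.
* Problem sizes in the test-suite simulations (10⁵ residuals for the
  Gaussian-tail check, 500 replicates for recovery studies, 70–73-residue
  chains) were chosen as the smallest sizes at which the targeted
  tolerances are comfortably resolved.

## Known limitations

* The stand-in predictor is a windowed propensity average with min-max
  calibration — adequate for exercising the pipeline and for qualitative
  order/disorder asymmetries, with no claim of equivalence to trained
  predictors.
* No multiple-testing correction is applied across regressions (none is
  part of the analysis this reproduces); no nonlinear fits.
* The NOE model is single-Lorentzian per residue; real IDPs need at
  least a two-timescale treatment for quantitative τ inference, which is
  out of scope (the generator is a forward model only).
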