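# Methods

`dectmd` models a desk-scale version of a clinical dual-energy CT (DECT)
workflow for pancreatic ductal adenocarcinoma (PDAC): find the two-material
decomposition basis that best separates normal pancreas from tumor, then
quantify what a better image dataset buys in a multi-reader study. This
note records the models, the numerical choices, and what the synthetic
data do and do not establish.

## Attenuation model and effective energies

A rapid kV-switching scanner acquires projections at 80/140 kVp. The
package reduces each polychromatic spectrum to one effective monoenergy —
defaults 52 keV (low) and 75 keV (high), configurable through
`EnergyPair` — and works entirely in the image domain: each region of
interest (ROI) is a pair of linear attenuation values (mu_low, mu_high) in
1/cm. This is a documented approximation of the vendor's projection-space
pipeline; beam hardening, spectra and scanner geometry are out of scope.

Material curves are mass attenuation coefficients (cm^2/g) tabulated
against energy (keV) and interpolated log-log linearly, exact at the
knots, with no silent extrapolation. No candidate material has a K-edge
inside the 40-150 keV working range, so piecewise log-log interpolation is
adequate. Vendor tables are proprietary, so the bundled 27-material
library is generated by a two-term parametric model — a photoelectric term
proportional to Z_eff^3.8 / E^3.2 plus a Klein-Nishina Compton term —
with per-material (Z_eff, density) presets. The photoelectric constant is
calibrated so a water-like material gives ~0.268 1/cm at 40 keV (and
~0.19 1/cm at 70 keV). These synthetic curves are plausible in shape and
ordering but are *not* measured data; users can substitute a measured
table in the same CSV dialect (`material,energy_kev,mu_over_rho`).

## Two-material decomposition

Measured attenuation is written as a linear combination of two basis
materials,

    mu(E) = d_a * (mu/rho)_a(E) + d_b * (mu/rho)_b(E),

and evaluated at the two effective energies, giving a 2x2 system for the
density coefficients (d_a, d_b). Solving it is a coordinate transformation
from attenuation space into basis-material space; the "A/B image" displays
d_a. Densities are kept signed — the decomposition is algebraic, and large
negative mean contrasts are meaningful. A pair whose basis matrix has
condition number above 1e8 is flagged degenerate and skipped by the scan
rather than raising, so the exhaustive enumeration always completes.
Virtual monoenergetic values re-synthesize mu at any in-range energy from
the solved densities and convert to HU against water; at a measured energy
this reproduces the input exactly for any non-degenerate basis.

`noise_amplification` is the Euclidean norm of the first row of the
inverted basis matrix: the gain from isotropic attenuation noise into the
displayed component. It is expressed in the display material's density
units, so its magnitude is comparable only within a display material — see
the selection-screen caveat below.

## The pair search and its geometry

For each ordered pair, each patient contributes

    contrast % = 100 * (d_a[normal] - d_a[tumor]) / d_a[normal],

a scale-invariant ratio (HU-based and density-based contrasts agree
whenever values are proportional; whether the vendor reports density or
concentration therefore does not matter downstream). A patient is excluded
from a pair when |d_a[normal]| falls below 1e-6 times the cohort median
for that pair — the ratio is numerically meaningless near zero. Pairs are
ranked by the absolute mean contrast across patients (sample SD, n-1);
among the top k (default 3) the winner is the largest |z| = |mean/SD|
surviving a noise screen.

Two structural properties of exact image-domain decomposition are worth
stating because they shape every scan result:

1. **The contrast ratio depends only on the partner material.** The
   functional extracting d_a is, up to the basis determinant, fixed by
   material B's column; the determinant cancels in the ratio. All 26
   ordered pairs sharing a partner therefore tie exactly, and tie-breaking
   is by pair id on keys quantized to 1e-6 so it never rides on solver
   round-off.
2. **The top of the ranking is "blow-up" families.** |mean contrast| is
   maximized when the reference density d_a[normal] sits near zero, which
   simultaneously inflates the SD — huge means with |z| well under 1,
   which is exactly the signature the z screen is designed to demote, and
   matches the behavior of an aligned, stable display such as the iodine
   map: modest mean contrast (tens of percent) with |z| an order of
   magnitude higher.

A corollary: the axis-alignment diagnostic (angle between the
tissue-contrast direction and the display axis) describes how the tissue
*difference* splits between the two components — zero degrees puts all of
it in d_a — but it cannot predict the contrast *ratio* across ordered
pairs, because the angle is a function of material A while the ratio is a
function of material B.

The noise screen defaults to 25x the noise amplification of Iodine/Water
at the same energies, a quantitative stand-in for a subjective
image-quality read. Because raw noise amplification is scale-dependent
across display materials (the iodine map's value is ~400x smaller than a
tissue-like display's), this default screens out every top-contrast pair
on the bundled library and the selection falls back, with a warning, to
the lowest-noise member of the top k. The cap is configurable, and the
report always carries both the screened selection and the full unscreened
ranking.

## Reader-study statistics

Ratings are 1-5 confidence scores; 3-5 is a positive call. Accuracy
metrics keep their numerator/denominator so the printed
`percent (num/den)` form is exact; pooling across readers is a
componentwise sum of 2x2 counts.

Dataset comparisons use a binomial GEE (logit link) with an exchangeable
working correlation clustered on patient and robust sandwich Wald tests
(max 100 iterations, relative tolerance 1e-8; non-convergence is reported
as not-calculable rather than silently downgraded). Each metric is fitted
on its own subset: truth-positives for sensitivity, truth-negatives for
specificity, all readings for accuracy, and — a documented choice, since
conditioning on calls makes clustering subtle — called-positives for PPV
and called-negatives for NPV, with clustering kept at the patient level.
A comparison is not-calculable when the outcomes are identical across
datasets or either dataset sits at 100%, mirroring standard practice for
paired designs. With single-observation clusters and an independence
working correlation the fit reduces to ordinary logistic regression, and
on independent data the Wald p agrees with a two-proportion z-test; both
are test-enforced.

Confidence-rating shifts use a proportional-odds model on the 1-5 scale
with a dataset indicator, stratified by truth, with a patient-level
Huber-White cluster sandwich (assembled from the per-observation scores,
with a G/(G-1) small-sample factor). Agreement uses unweighted Cohen kappa
(large-sample variance per the classic two-rater asymptotics) and Fleiss
kappa for all readers (Fleiss 1971 large-sample SE), compared by a normal
z-test. Kappas are computed on the binarized calls, not the 5-point scale
— an assumption, since published agreement values are typically reported
for the dichotomized diagnosis.

## Sample-size simulation

Each patient without disease yields 2 x readers correlated binary
"correct negative" outcomes (marginals p0 = 0.80 conventional, p1 = 0.90
optimal, four readers) with one common pairwise within-patient
correlation rho. Sampling thresholds a latent Gaussian whose pairwise
correlations are calibrated Emrich-Piedmonte style: solve
Phi2(z_i, z_j; r) = p_i p_j + rho*sqrt(p_i q_i p_j q_j) for each of the
three pair types (conv-conv, conv-opt, opt-opt), assemble the 2m x 2m
latent matrix, and reject infeasible (p, rho) combinations (Frechet bound
or non-positive-definite latent matrix) before sampling. Calibration is
test-verified at 1e5 patients (marginals within 0.004, pairwise
correlation within 0.01).

Each replicate is tested with the same clustered GEE Wald test at
two-sided alpha 0.05; empirical power is the rejection fraction over 1000
iterations (non-convergent replicates count as non-rejections and are
rare). Replicate r is seeded deterministically from (seed, n, rho, r), so
any replicate is reproducible in isolation. The minimum sample size is
found by coarse doubling at a reduced iteration count to bracket the
crossing, then an upward unit-step scan at full iterations.

Because both datasets are read on the *same* patients, power increases
with rho: higher within-patient correlation shrinks the variance of the
paired difference. The assumed range 0.01-0.5 therefore spans minimum
sample sizes from roughly 68 (rho = 0.01) down to roughly 34 (rho = 0.5)
under this design. The headline number is reported at a representative
mid-range correlation of 0.3 — moderate within-patient agreement, the
package's own choice — giving a minimum of 43-47 patients without disease
across seeds at 1000 iterations; the full (n, rho) surface is available
via `power_surface` and `minimum_sample_size(..., per_rho=True)`. The
test's empirical size is 0.05-0.06 at moderate cluster counts (the
robust sandwich is mildly anti-conservative below ~50 clusters, a known
small-sample property).

## Synthetic data: what it shows and what it does not

The cohort generator models tissue as water plus iodine only: normal
pancreas at 3.0 mg/mL iodine, tumor at 1.5 mg/mL (hypo-enhancing, as in
the pancreatic phase), a shared lognormal per-patient enhancement factor
(sigma 0.15), and 1% relative Gaussian measurement noise per attenuation
value; 67 tumor-bearing patients contribute ROI pairs and 43 without
disease fill out the truth labels, matching the modeled study's shape.
True iodine concentrations for these tissues are not published; the
defaults are documented placeholders that no headline quantity depends
on. The ratings generator draws a patient-shared latent Gaussian (weight
sqrt(rho)) plus reading noise, shifted so the binarized calls hit the
configured sensitivity/specificity per dataset; rho is a latent-scale
correlation, so the induced binary correlation is somewhat smaller.

All generators are pure functions of (config, seed). Passing tests on
these data establish internal consistency — decomposition recovers the
configured concentrations to <2% at zero noise, the configured
specificity gap reappears in pooled calls, the study-scale pipeline
rejects in the expected power regime — not fidelity to real tissue
composition (no fat/calcium compartments, no lesion geometry, no texture,
no reader drift). Published rating-level results (per-reader p values,
kappa magnitudes) are not reproducible from counts alone and are not
claimed.

## Problem sizes

Default problem sizes were chosen so a full run is desk-scale: the 702-pair
scan over 67 patients takes well under a second; the full-precision
sample-size search (1000 iterations per candidate n) runs in about one to
two minutes on one CPU; unit tests use reduced iteration counts where the
assertion is qualitative.
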