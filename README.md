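# dectmd

Basis-pair optimization for dual-energy CT material decomposition, with
the reader-study statistics that turn a better image into a clinical
claim.

## The problem

Dual-energy CT measures linear attenuation at two effective energies, so
any region of interest (ROI) can be decomposed into densities of two basis
materials by solving

    [ (mu/rho)_a(E_lo)  (mu/rho)_b(E_lo) ] [ d_a ]   [ mu_lo ]
    [ (mu/rho)_a(E_hi)  (mu/rho)_b(E_hi) ] [ d_b ] = [ mu_hi ].

The displayed "A/B image" is the d_a map. Pancreatic ductal adenocarcinoma
(PDAC) hypo-enhances relative to normal pancreas in the pancreatic phase,
and the right basis pair can amplify that difference far beyond the
conventional iodine map. `dectmd` scores **every ordered pair** from a
material library by the per-patient contrast-difference statistic

    contrast % = 100 * (value_normal - value_tumor) / value_normal,

ranks pairs by |mean contrast| across the cohort, and selects among the
top three by the stability-adjusted z value (mean/SD) under a noise
screen. Around that core it provides:

- virtual monoenergetic synthesis (HU at any in-range keV) and an
  axis-alignment diagnostic for the geometry of a basis pair;
- multi-reader diagnostic accuracy (sensitivity/specificity/PPV/NPV/
  accuracy as exact `percent (num/den)` values) compared between image
  datasets with patient-clustered binomial GEE, proportional-odds
  confidence-shift tests with cluster-robust variance, and Cohen/Fleiss
  kappa agreement;
- a correlated-Bernoulli Monte Carlo sample-size simulation (Gaussian
  copula with Emrich-Piedmonte calibration, GEE Wald testing) for a
  clustered specificity comparison;
- synthetic-data generators (material library, dual-energy ROI cohort,
  reader ratings) so the whole pipeline runs without any proprietary
  input.

## Worked example

```python
from dectmd import DEFAULT_ENERGIES, scan_all_pairs
from dectmd.synthetic import (CohortConfig, cohort_from_frame,
                              generate_attenuation_fixture, generate_cohort)

table = generate_attenuation_fixture(seed=0)          # 27-material library
cohort = cohort_from_frame(
    generate_cohort(CohortConfig(seed=7), table, DEFAULT_ENERGIES)
)
report = scan_all_pairs(cohort, table, DEFAULT_ENERGIES, k=3)
for s in report.top_k:
    print(f"{s.pair_id:<45} mean {s.mean_contrast:9.1f}%  "
          f"SD {s.sd_contrast:9.1f}%  z {s.z:+.2f}  noise x{s.noise_amp:.1f}")
```

prints (67 synthetic patients, 702 ordered pairs):

```
Bilirubin/Calcium oxalate mono-hydrate (CaOxMono) mean    1345.6%  SD   12885.5%  z +0.10  noise x23.9
Blood/Calcium oxalate mono-hydrate (CaOxMono) mean    1345.6%  SD   12885.5%  z +0.10  noise x25.7
Bone/Calcium oxalate mono-hydrate (CaOxMono)  mean    1345.6%  SD   12885.5%  z +0.10  noise x81.0
```

while the clinical-reference iodine map (see
`examples/pair_search_demo.py`) scores

```
reference Iodine/Water:        mean      50.1%  SD       4.5%  z +11.12  noise x0.052
```

The numbers illustrate the core trade-off the z value arbitrates: the
top-ranked pairs divide by a reference density near zero, so their mean
contrast is enormous but unstable (SD ten times the mean, |z| ~ 0.1),
whereas the iodine display is modest but extremely stable. See
`examples/` for one narrative script per capability (decomposition + VMI,
pair search, reader statistics, power simulation); each prints its
numbers with a line on what they mean.

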