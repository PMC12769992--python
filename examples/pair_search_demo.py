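"""Exhaustive basis-pair search on a synthetic dual-energy cohort.

Builds the 27-material attenuation library and a 67-patient cohort whose
only tissue difference is iodine uptake (normal pancreas 3.0 mg/mL, tumor
1.5 mg/mL), scores all 702 ordered basis pairs by the per-patient
contrast-difference statistic, and prints the top-3 ranking and the
selected pair.
"""

from dectmd import DEFAULT_ENERGIES, scan_all_pairs
from dectmd.pair_search import score_pair
from dectmd.decomposition import build_basis_pair
from dectmd.synthetic import (
    CohortConfig,
    cohort_from_frame,
    generate_attenuation_fixture,
    generate_cohort,
)

table = generate_attenuation_fixture(seed=0)
cohort = cohort_from_frame(
    generate_cohort(CohortConfig(seed=7), table, DEFAULT_ENERGIES)
)

report = scan_all_pairs(cohort, table, DEFAULT_ENERGIES, k=3)
print(f"scored {len(report.scores)} ordered pairs over {len(cohort)} patients\n")
print("top 3 by |mean contrast| (percent; z = mean/SD across patients):")
for s in report.top_k:
    print(
        f"  {s.pair_id:<30} mean {s.mean_contrast:9.1f}%  "
        f"SD {s.sd_contrast:9.1f}%  z {s.z:+.2f}  noise x{s.noise_amp:.1f}"
    )
print(f"\nselected pair (z and noise screen): {report.optimal}")

# The clinical-reference iodine map for comparison: a modest mean contrast
# but a far more stable (high |z|) one, because the top-ranked pairs divide
# by a reference density that sits near zero.
iw = score_pair(cohort, build_basis_pair(table, "Iodine", "Water", DEFAULT_ENERGIES))
print(
    f"reference Iodine/Water:        mean {iw.mean_contrast:9.1f}%  "
    f"SD {iw.sd_contrast:9.1f}%  z {iw.z:+.2f}  noise x{iw.noise_amp:.3f}"
)
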