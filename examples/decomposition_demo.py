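"""Two-material decomposition and virtual monoenergetic synthesis.

Takes one region of interest measured at the two effective energies,
solves the 2x2 basis system for the Iodine/Water density pair, and
re-synthesizes virtual monoenergetic values across 45-140 keV.
"""

from dectmd import DEFAULT_ENERGIES, build_basis_pair, decompose, synthesize_vmi
from dectmd.decomposition import DualEnergyROI, Tissue, axis_alignment
from dectmd.synthetic import generate_attenuation_fixture

table = generate_attenuation_fixture(seed=0)
pair = build_basis_pair(table, "Iodine", "Water", DEFAULT_ENERGIES)

# An enhancing normal-pancreas ROI: water plus ~3 mg/mL iodine.
roi = DualEnergyROI("P001", Tissue.NORMAL_PANCREAS, mu_low=0.3635, mu_high=0.2318)
densities = decompose(roi, pair)
print(f"ROI (mu_low, mu_high) = ({roi.mu_low}, {roi.mu_high}) 1/cm")
print(
    f"decomposed in {pair.pair_id}: iodine {densities.d_a * 1e3:.2f} mg/mL, "
    f"water {densities.d_b:.3f} g/cm^3"
)

print("\nvirtual monoenergetic values (HU vs water at each energy):")
for e in (45, 50, 52, 60, 70, 75, 100, 140):
    print(f"  {e:>3} keV: {synthesize_vmi(densities, pair, table, float(e)):8.1f} HU")
print("low keV boosts iodine conspicuity; the curve flattens toward water at high keV")

tumor = DualEnergyROI("P001", Tissue.PDAC, mu_low=0.292, mu_high=0.207)
angle = axis_alignment(pair, roi, tumor)
print(
    f"\nangle between the tissue-contrast direction and the iodine axis: "
    f"{angle:.2f} deg (small: the contrast lives in the iodine component)"
)
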