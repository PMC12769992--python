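"""Synthetic inputs with the statistical structure the analysis assumes.

Three generators, all pure functions of (config, seed):

* a material attenuation table (the 27-name basis library) built from the
  parametric attenuation model with fixed per-material (Z_eff, density)
  presets — synthetic stand-in curves, since vendor tables are proprietary;
* a dual-energy ROI cohort emulating pancreatic-phase enhancement, where
  tissue is water plus iodine and the tumor carries less iodine than
  normal parenchyma (hypo-enhancing lesion);
* multi-reader 5-point confidence ratings from a patient-shared latent
  Gaussian, calibrated so the binarized calls hit configured
  sensitivity/specificity operating points with within-patient correlation
  rho on the latent scale.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .attenuation import (
    AttenuationTable,
    EnergyPair,
    MaterialSpec,
    load_attenuation_table,
    parametric_attenuation,
)
from .decomposition import DualEnergyROI, Tissue

__all__ = [
    "MATERIAL_PRESETS",
    "CohortConfig",
    "RatingsConfig",
    "generate_attenuation_fixture",
    "generate_cohort",
    "cohort_from_frame",
    "generate_truth",
    "generate_ratings",
]

#: Effective atomic number and bulk density (g/cm^3) presets for the
#: 27-material basis library (synthetic curve parameters; the names are
#: the library, the numbers are plausible stand-ins).
MATERIAL_PRESETS: dict[str, tuple[float, float]] = {
    "Octacalcium phosphate (OCP)": (13.6, 2.61),
    "Brushite": (12.35, 2.33),
    "Silicon": (14.0, 2.33),
    "Calcium": (20.0, 1.55),
    "Phosphorus": (15.0, 1.82),
    "Struvite": (10.0, 1.71),
    "Water": (7.42, 1.00),
    "Monosodium urate": (8.9, 1.89),
    "Calc measured": (12.9, 1.90),
    "Muscle": (7.45, 1.05),
    "Cystine": (10.2, 1.68),
    "Iodine": (53.0, 4.93),
    "Cortical bone": (13.8, 1.92),
    "Bilirubin": (6.9, 1.31),
    "Calcium pyrophosphate dehydrate deposition (CPPD)": (13.1, 2.56),
    "Fat": (6.3, 0.92),
    "Hydroxyapatite (HAP)": (15.9, 3.16),
    "Uric acid": (7.1, 1.87),
    "Tricresyl phosphate (TCP)": (9.2, 1.16),
    "Bone": (12.3, 1.65),
    "Calcium oxalate mono-hydrate (CaOxMono)": (11.6, 2.20),
    "Calcium chloride (CaCl2)": (16.3, 2.15),
    "Blood": (7.55, 1.06),
    "Calcium phosphate": (15.7, 3.14),
    "Natrium": (11.0, 0.97),
    "Sodium chloride (NaCl)": (15.3, 2.17),
    "Calc bone": (12.6, 1.85),
}

FIXTURE_ENERGIES_KEV = np.arange(40.0, 151.0, 5.0)


@dataclass(frozen=True)
class CohortConfig:
    """Dual-energy ROI cohort conditions.

    67 patients with tumors (each contributing a normal-pancreas and a
    tumor ROI) and 43 without, iodine uptake 3.0 vs 1.5 mg/mL (normal vs
    tumor, pancreatic-phase hypo-enhancement), lognormal between-patient
    enhancement variability (sigma 0.15) and 1% relative Gaussian
    measurement noise on each attenuation value.
    """

    n_pdac: int = 67
    n_no_pdac: int = 43
    iodine_normal_mg_ml: float = 3.0
    iodine_pdac_mg_ml: float = 1.5
    between_patient_sigma: float = 0.15
    noise_rel_sd: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pdac <= 0 or self.n_no_pdac <= 0:
            raise ValueError("cohort sizes must be positive")
        if self.iodine_normal_mg_ml < 0 or self.iodine_pdac_mg_ml < 0:
            raise ValueError("iodine concentrations must be nonnegative")
        if self.iodine_pdac_mg_ml >= self.iodine_normal_mg_ml:
            raise ValueError("tumor must enhance less than normal pancreas")


@dataclass(frozen=True)
class RatingsConfig:
    """Reader-rating generator conditions.

    Operating points default to the planning assumptions of the modeled
    study (specificity 0.80 conventional vs 0.90 optimal; sensitivity
    ~0.99/0.98); rho is the patient-level latent correlation; cuts are the
    strictly increasing thresholds mapping the latent score to ratings
    1-5 (a score above ``cuts[1]`` binarizes positive).
    """

    sens_conventional: float = 0.99
    spec_conventional: float = 0.80
    sens_optimal: float = 0.98
    spec_optimal: float = 0.90
    rho: float = 0.3
    readers: int = 4
    groups: tuple[str, ...] = ("expert", "expert", "trainee", "trainee")
    cuts: tuple[float, ...] = (-1.8, -0.6, 0.6, 1.8)
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.sens_conventional, self.spec_conventional,
                  self.sens_optimal, self.spec_optimal):
            if not 0 < p < 1:
                raise ValueError("operating points must lie in (0, 1)")
        if not 0 <= self.rho < 1:
            raise ValueError("rho must lie in [0, 1)")
        if len(self.groups) != self.readers:
            raise ValueError("need one group label per reader")
        if any(b <= a for a, b in zip(self.cuts, self.cuts[1:])):
            raise ValueError("cuts must be strictly increasing")


def generate_attenuation_fixture(
    path=None, materials: dict[str, tuple[float, float]] | None = None, seed: int = 0
) -> AttenuationTable:
    """Deterministic fixture attenuation table (CSV) for the basis library.

    Curves cover 40-150 keV at 5-keV steps from the parametric model with
    the per-material presets; a seed-driven 0.5% lognormal density jitter
    distinguishes seeds while keeping identical seeds byte-identical. When
    ``path`` is given the CSV is written there; the parsed table is
    returned either way.
    """
    presets = MATERIAL_PRESETS if materials is None else materials
    rng = np.random.default_rng(seed)
    rows = []
    for name in presets:  # insertion order: deterministic
        z_eff, density = presets[name]
        # Mass attenuation is per-gram, so only the (lightly seed-jittered)
        # effective Z shapes the curve.
        z_eff = z_eff * float(np.exp(rng.normal(0.0, 0.002)))
        for e in FIXTURE_ENERGIES_KEV:
            mu_over_rho = parametric_attenuation(z_eff, density, e) / density
            rows.append((name, e, mu_over_rho))
    df = pd.DataFrame(rows, columns=["material", "energy_kev", "mu_over_rho"])
    csv_text = df.to_csv(index=False, float_format="%.8g")
    if path is not None:
        with open(path, "w", newline="") as fh:
            fh.write(csv_text)
    return load_attenuation_table(io.StringIO(csv_text))


def generate_cohort(
    config: CohortConfig,
    table: AttenuationTable,
    energies: EnergyPair,
) -> pd.DataFrame:
    """Dual-energy ROI table for the tumor-bearing patients.

    One normal-pancreas and one tumor ROI per patient with
    ``mu(E) = mu_water(E) + c_iodine * (mu/rho)_iodine(E)`` (iodine in
    g/cm^3), a shared lognormal patient enhancement factor on the iodine
    concentration, and relative Gaussian measurement noise on each mu.
    Columns: ``patient_id, tissue, mu_low, mu_high``.
    """
    if "Water" not in table or "Iodine" not in table:
        raise ValueError("cohort generation needs Water and Iodine in the table")
    rng = np.random.default_rng(config.seed)
    mu_w = np.array([table.mu_water(energies.e_low), table.mu_water(energies.e_high)])
    mr_iod = np.array(
        [table["Iodine"](energies.e_low), table["Iodine"](energies.e_high)]
    )
    rows = []
    for i in range(config.n_pdac):
        pid = f"P{i + 1:03d}"
        enhancement = float(np.exp(rng.normal(0.0, config.between_patient_sigma)))
        for tissue, c_mg_ml in (
            (Tissue.NORMAL_PANCREAS, config.iodine_normal_mg_ml),
            (Tissue.PDAC, config.iodine_pdac_mg_ml),
        ):
            c = c_mg_ml * enhancement * 1e-3  # mg/mL -> g/cm^3
            mu = mu_w + c * mr_iod
            mu = mu * (1.0 + config.noise_rel_sd * rng.standard_normal(2))
            rows.append((pid, tissue.value, mu[0], mu[1]))
    return pd.DataFrame(rows, columns=["patient_id", "tissue", "mu_low", "mu_high"])


def cohort_from_frame(df: pd.DataFrame) -> list[tuple[DualEnergyROI, DualEnergyROI]]:
    """Convert an ROI table into the (roi_normal, roi_pdac) pair list."""
    cohort = []
    for pid, grp in df.groupby("patient_id", sort=True):
        by_tissue = {t: g for t, g in grp.groupby("tissue")}
        rois = {}
        for tissue in (Tissue.NORMAL_PANCREAS, Tissue.PDAC):
            row = by_tissue[tissue.value].iloc[0]
            rois[tissue] = DualEnergyROI(
                patient_id=str(pid), tissue=tissue,
                mu_low=float(row["mu_low"]), mu_high=float(row["mu_high"]),
            )
        cohort.append((rois[Tissue.NORMAL_PANCREAS], rois[Tissue.PDAC]))
    return cohort


def generate_truth(config: CohortConfig) -> pd.DataFrame:
    """Truth labels: n_pdac tumor patients then n_no_pdac without."""
    rows = [(f"P{i + 1:03d}", "pdac") for i in range(config.n_pdac)]
    rows += [(f"N{i + 1:03d}", "no_pdac") for i in range(config.n_no_pdac)]
    return pd.DataFrame(rows, columns=["patient_id", "truth"])


def generate_ratings(config: RatingsConfig, truth: pd.DataFrame) -> pd.DataFrame:
    """Reader x patient x dataset 5-point ratings from a latent Gaussian.

    Each patient carries one latent factor shared by all readers and both
    datasets (weight sqrt(rho)), each reading adds independent noise
    (weight sqrt(1-rho)); the dataset/truth-specific shift places the
    probability of a positive call (score above ``cuts[1]``) at the
    configured operating point. Columns follow the ratings-table contract.
    """
    rng = np.random.default_rng(config.seed)
    operating = {
        ("conventional", "pdac"): config.sens_conventional,
        ("conventional", "no_pdac"): 1.0 - config.spec_conventional,
        ("optimal", "pdac"): config.sens_optimal,
        ("optimal", "no_pdac"): 1.0 - config.spec_optimal,
    }
    c_pos = config.cuts[1]
    sqrt_rho = np.sqrt(config.rho)
    sqrt_res = np.sqrt(1.0 - config.rho)
    cuts = np.asarray(config.cuts)
    rows = []
    for _, patient in truth.iterrows():
        u = rng.standard_normal()
        for reader_idx in range(config.readers):
            for dataset in ("conventional", "optimal"):
                p = operating[(dataset, patient["truth"])]
                shift = c_pos + stats.norm.ppf(p)
                score = shift + sqrt_rho * u + sqrt_res * rng.standard_normal()
                rating = int(np.searchsorted(cuts, score)) + 1
                rows.append(
                    (
                        f"R{reader_idx + 1}",
                        config.groups[reader_idx],
                        patient["patient_id"],
                        dataset,
                        rating,
                        patient["truth"],
                    )
                )
    return pd.DataFrame(
        rows, columns=["reader_id", "group", "patient_id", "dataset", "rating", "truth"]
    )
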