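"""Two-material basis decomposition of dual-energy ROI measurements.

A dual-energy acquisition yields, per region of interest, two linear
attenuation values (mu_low, mu_high) at the effective low/high energies.
Writing the measured attenuation as a linear combination of two basis
materials' mass attenuation curves,

    mu(E) = d_a * (mu/rho)_a(E) + d_b * (mu/rho)_b(E),

and evaluating at the two energies gives a 2x2 linear system for the
density coefficients (d_a, d_b). Solving it is a coordinate transformation
from attenuation space to basis-material space; the first material's
density map is the displayed "A/B image". Densities may be negative: the
decomposition is algebraic, not physical.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .attenuation import AttenuationTable, EnergyPair, hu_from_mu

__all__ = [
    "Tissue",
    "DualEnergyROI",
    "BasisPair",
    "DensityPair",
    "DegeneratePairError",
    "DEGENERACY_THRESHOLD",
    "build_basis_pair",
    "decompose",
    "synthesize_vmi",
    "noise_amplification",
    "axis_alignment",
]

#: A basis pair is unusable when the 2x2 condition number exceeds this.
DEGENERACY_THRESHOLD = 1e8


class Tissue(str, Enum):
    NORMAL_PANCREAS = "normal_pancreas"
    PDAC = "pdac"


class DegeneratePairError(ValueError):
    """Raised when an operation requires a non-degenerate basis pair."""


@dataclass(frozen=True)
class DualEnergyROI:
    """Per-patient linear attenuation pair for one tissue class (1/cm)."""

    patient_id: str
    tissue: Tissue
    mu_low: float
    mu_high: float

    def __post_init__(self) -> None:
        if not self.patient_id:
            raise ValueError("patient_id must be nonempty")
        if not (np.isfinite(self.mu_low) and np.isfinite(self.mu_high)):
            raise ValueError(f"{self.patient_id}: attenuation values must be finite")

    @property
    def vector(self) -> np.ndarray:
        return np.array([self.mu_low, self.mu_high], dtype=float)


@dataclass(frozen=True)
class BasisPair:
    """An ordered basis pair (A, B) with its 2x2 basis matrix.

    ``basis_matrix`` rows correspond to (e_low, e_high) and columns to
    (material_a, material_b); entries are mass attenuation in cm^2/g.
    """

    material_a: str
    material_b: str
    basis_matrix: np.ndarray
    condition_number: float

    @property
    def pair_id(self) -> str:
        return f"{self.material_a}/{self.material_b}"

    @property
    def degenerate(self) -> bool:
        return not np.isfinite(self.condition_number) or (
            self.condition_number > DEGENERACY_THRESHOLD
        )


@dataclass(frozen=True)
class DensityPair:
    """Solved density coefficients (g/cm^3); may be negative."""

    d_a: float
    d_b: float


def build_basis_pair(
    table: AttenuationTable,
    a: str,
    b: str,
    energies: EnergyPair,
    degeneracy_threshold: float = DEGENERACY_THRESHOLD,
) -> BasisPair:
    """Assemble the 2x2 basis matrix for materials ``a`` and ``b``.

    A singular or near-singular matrix (condition number above the
    threshold) yields a pair flagged degenerate rather than an exception,
    so an exhaustive scan can skip it.
    """
    if a == b:
        raise ValueError(f"basis materials must differ, got {a!r} twice")
    spec_a, spec_b = table[a], table[b]
    m = np.array(
        [
            [spec_a(energies.e_low), spec_b(energies.e_low)],
            [spec_a(energies.e_high), spec_b(energies.e_high)],
        ]
    )
    det = m[0, 0] * m[1, 1] - m[0, 1] * m[1, 0]
    cond = np.inf if det == 0.0 else float(np.linalg.cond(m))
    if cond > degeneracy_threshold:
        cond = np.inf if not np.isfinite(cond) else cond
    return BasisPair(material_a=a, material_b=b, basis_matrix=m, condition_number=cond)


def decompose(roi: DualEnergyROI, pair: BasisPair) -> DensityPair:
    """Solve the 2x2 system ``basis_matrix @ (d_a, d_b) = (mu_low, mu_high)``."""
    if pair.degenerate:
        raise DegeneratePairError(f"pair {pair.pair_id} is degenerate")
    d = np.linalg.solve(pair.basis_matrix, roi.vector)
    return DensityPair(d_a=float(d[0]), d_b=float(d[1]))


def decompose_many(mu: np.ndarray, pair: BasisPair) -> np.ndarray:
    """Vectorized decomposition of an ``(n, 2)`` array of (mu_low, mu_high).

    Returns an ``(n, 2)`` array of (d_a, d_b). Used by the pair scan.
    """
    if pair.degenerate:
        raise DegeneratePairError(f"pair {pair.pair_id} is degenerate")
    return np.linalg.solve(pair.basis_matrix, np.asarray(mu, dtype=float).T).T


def synthesize_vmi(
    densities: DensityPair,
    pair: BasisPair,
    table: AttenuationTable,
    energy_kev: float,
) -> float:
    """Virtual monoenergetic value (HU) at ``energy_kev`` from solved densities.

    Reconstructs ``mu(E) = d_a*(mu/rho)_a(E) + d_b*(mu/rho)_b(E)`` and
    converts to HU against water at the same energy. At a measured energy
    this reproduces the input attenuation for any non-degenerate basis.
    """
    mu = densities.d_a * table[pair.material_a](energy_kev) + densities.d_b * table[
        pair.material_b
    ](energy_kev)
    return float(hu_from_mu(mu, table.mu_water(energy_kev)))


def noise_amplification(pair: BasisPair) -> float:
    """Error gain from attenuation noise into the displayed component d_a.

    The Euclidean norm of the first row of the inverted basis matrix: the
    factor by which isotropic measurement noise on (mu_low, mu_high)
    propagates into d_a. Scale-free; meaningful for comparisons only.
    """
    if pair.degenerate:
        raise DegeneratePairError(f"pair {pair.pair_id} is degenerate")
    inv = np.linalg.inv(pair.basis_matrix)
    return float(np.linalg.norm(inv[0]))


def axis_alignment(
    pair: BasisPair, roi_normal: DualEnergyROI, roi_pdac: DualEnergyROI
) -> float:
    """Angle (degrees, in [0, 90]) between the tissue-contrast direction and axis A.

    The contrast direction is the vector between the two ROIs in
    (mu_low, mu_high) space; axis A is the material_a column of the basis
    matrix. A small angle means the tissue difference projects almost
    entirely onto the displayed component d_a.
    """
    delta = roi_normal.vector - roi_pdac.vector
    norm_delta = np.linalg.norm(delta)
    if norm_delta == 0.0:
        raise ValueError("identical ROIs: contrast direction undefined")
    col_a = pair.basis_matrix[:, 0]
    cosine = abs(float(delta @ col_a)) / (norm_delta * np.linalg.norm(col_a))
    return float(np.degrees(np.arccos(np.clip(cosine, 0.0, 1.0))))
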