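"""Exhaustive basis-pair search by the contrast-difference statistic.

For every ordered pair (A, B) of library materials, each patient's two
tissue ROIs (normal pancreas, tumor) are decomposed and the per-patient
contrast difference of the displayed component d_a is computed:

    contrast % = 100 * (value_normal - value_pdac) / value_normal.

Pairs are ranked by the absolute mean contrast across patients; among the
top k, the optimal pair is chosen by the z value (mean / sample SD of the
per-patient contrasts) subject to a noise-amplification screen standing in
for a subjective image-quality read.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import permutations

import numpy as np
import pandas as pd

from .attenuation import AttenuationTable, EnergyPair
from .decomposition import (
    BasisPair,
    DualEnergyROI,
    build_basis_pair,
    decompose_many,
    noise_amplification,
)

__all__ = [
    "UndefinedContrastError",
    "PairScore",
    "PairSearchReport",
    "contrast_difference",
    "z_value",
    "enumerate_ordered_pairs",
    "score_pair",
    "rank_and_select",
    "scan_all_pairs",
    "DEFAULT_ENERGIES",
]

logger = logging.getLogger(__name__)

#: Effective monoenergies standing in for the 80/140 kVp spectra, keV.
DEFAULT_ENERGIES = EnergyPair(e_low=52.0, e_high=75.0)

#: A patient's contrast is undefined when |value_normal| falls below this
#: fraction of the cohort median |value_normal| for the same pair.
RELATIVE_EPSILON = 1e-6

#: Report columns (kept stable as the CSV-facing contract).
REPORT_COLUMNS = [
    "material_a",
    "material_b",
    "n",
    "mean_contrast_pct",
    "sd_contrast_pct",
    "z_value",
    "noise_amplification",
    "degenerate",
    "rank",
]


class UndefinedContrastError(ValueError):
    """Raised when the reference (normal-tissue) value is numerically zero."""


def contrast_difference(value_normal: float, value_pdac: float, eps: float = 0.0) -> float:
    """Percent contrast difference, ``100 * (normal - pdac) / normal``.

    Scale-invariant: rescaling both inputs by any nonzero constant leaves
    the result unchanged, so HU-based and density-based contrasts agree
    whenever the two are proportional. Raises
    :class:`UndefinedContrastError` when ``|value_normal| <= eps``.
    """
    if abs(value_normal) <= eps or value_normal == 0.0:
        raise UndefinedContrastError(
            f"normal-tissue value {value_normal} too close to zero for a contrast ratio"
        )
    return 100.0 * (value_normal - value_pdac) / value_normal


def z_value(mean: float, sd: float) -> float:
    """Stability-adjusted effect size: mean contrast over its SD."""
    if sd == 0.0 or not np.isfinite(sd):
        raise ValueError("z value undefined for zero or non-finite SD")
    return mean / sd


@dataclass(frozen=True)
class PairScore:
    """Cohort-level summary of one ordered basis pair."""

    pair_id: str
    material_a: str
    material_b: str
    n_patients: int = 0
    mean_contrast: float = np.nan
    sd_contrast: float = np.nan
    z: float | None = None
    noise_amp: float = np.nan
    degenerate: bool = False
    n_excluded: int = 0

    @property
    def z_defined(self) -> bool:
        return self.z is not None and np.isfinite(self.z)


def enumerate_ordered_pairs(materials: list[str]) -> list[tuple[str, str]]:
    """All ordered pairs (a, b), a != b, in lexicographic order.

    With n unique names this yields n*(n-1) pairs — 702 for a 27-material
    library.
    """
    names = list(materials)
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate material names {dupes}")
    return sorted(permutations(names, 2))


def _per_patient_contrasts(
    cohort: list[tuple[DualEnergyROI, DualEnergyROI]], pair: BasisPair
) -> tuple[np.ndarray, int]:
    """Per-patient contrast of component d_a; returns (contrasts, n_excluded)."""
    mu = np.array(
        [[r.mu_low, r.mu_high] for pair_rois in cohort for r in pair_rois]
    )  # (2n, 2): normal, pdac interleaved
    d = decompose_many(mu, pair)[:, 0].reshape(-1, 2)
    d_normal, d_pdac = d[:, 0], d[:, 1]
    eps = RELATIVE_EPSILON * np.median(np.abs(d_normal))
    ok = np.abs(d_normal) > eps
    contrasts = 100.0 * (d_normal[ok] - d_pdac[ok]) / d_normal[ok]
    return contrasts, int((~ok).sum())


def score_pair(
    cohort: list[tuple[DualEnergyROI, DualEnergyROI]], pair: BasisPair
) -> PairScore:
    """Mean, sample SD and z of per-patient contrast differences of d_a.

    The cohort is a list of (roi_normal, roi_pdac) per patient. A
    degenerate pair returns a flagged score with no statistics; the z value
    is left undefined when the SD is zero or fewer than 2 patients remain.
    """
    base = dict(
        pair_id=f"{pair.material_a}/{pair.material_b}",
        material_a=pair.material_a,
        material_b=pair.material_b,
    )
    if pair.degenerate:
        return PairScore(degenerate=True, **base)
    contrasts, n_excl = _per_patient_contrasts(cohort, pair)
    n = contrasts.size
    if n < 2:
        return PairScore(n_patients=n, n_excluded=n_excl,
                         noise_amp=noise_amplification(pair), **base)
    mean = float(contrasts.mean())
    sd = float(contrasts.std(ddof=1))
    # SD at floating-point noise relative to the mean counts as zero.
    z = mean / sd if sd > 1e-12 * abs(mean) and sd > 0 else None
    return PairScore(
        n_patients=n,
        mean_contrast=mean,
        sd_contrast=sd,
        z=z,
        noise_amp=noise_amplification(pair),
        n_excluded=n_excl,
        **base,
    )


def rank_and_select(
    scores: list[PairScore], k: int = 3, noise_cap: float = np.inf
) -> tuple[list[PairScore], str]:
    """Rank by |mean contrast| and pick the optimal pair among the top k.

    Ranking uses the absolute mean contrast (large negative contrasts are
    as informative as large positive ones), ties broken lexicographically
    by pair id. Keys are quantized to 1e-6 before comparison: pairs sharing
    a partner material tie exactly in infinite precision, and without
    quantization the tie-break would ride on solver round-off. Within the
    top k, members with noise amplification above ``noise_cap`` are
    screened out and the largest |z| among the survivors wins; if nothing
    survives the screen, the lowest-noise member of the top k is returned
    with a warning.
    """
    usable = [s for s in scores if not s.degenerate and np.isfinite(s.mean_contrast)]
    if len(usable) < k:
        raise ValueError(f"need at least k={k} non-degenerate pair scores, have {len(usable)}")
    ranked = sorted(usable, key=lambda s: (-round(abs(s.mean_contrast), 6), s.pair_id))
    top_k = ranked[:k]
    passing = [s for s in top_k if s.noise_amp <= noise_cap]
    if passing:
        optimal = sorted(
            passing,
            key=lambda s: (-(round(abs(s.z), 6) if s.z_defined else -np.inf), s.pair_id),
        )[0]
    else:
        optimal = min(top_k, key=lambda s: (s.noise_amp, s.pair_id))
        logger.warning(
            "no top-%d pair passes noise cap %.3g; falling back to lowest-noise %s",
            k, noise_cap, optimal.pair_id,
        )
    return top_k, optimal.pair_id


@dataclass
class PairSearchReport:
    """Full output of an exhaustive ordered-pair scan."""

    scores: pd.DataFrame
    top_k: list[PairScore]
    optimal: str
    noise_cap: float
    energies: EnergyPair
    exclusions: dict[str, int] = field(default_factory=dict)


def default_noise_cap(table: AttenuationTable, energies: EnergyPair) -> float:
    """25x the noise amplification of the Iodine/Water pair (if available).

    A quantitative stand-in for the radiologists' subjective screen for
    unacceptable image noise; pairs noisier than 25x the clinical-reference
    iodine map are screened out of the optimal-pair selection.
    """
    if "Iodine" in table and "Water" in table:
        ref = build_basis_pair(table, "Iodine", "Water", energies)
        if not ref.degenerate:
            return 25.0 * noise_amplification(ref)
    return np.inf


def scan_all_pairs(
    cohort: list[tuple[DualEnergyROI, DualEnergyROI]],
    table: AttenuationTable,
    energies: EnergyPair = DEFAULT_ENERGIES,
    k: int = 3,
    noise_cap: float | None = None,
) -> PairSearchReport:
    """Score every ordered material pair and select the optimal one.

    Returns a report whose ``scores`` DataFrame has one row per ordered
    pair — n*(n-1) rows always — ranked by |mean contrast| (rank 1 =
    largest; degenerate pairs unranked), plus the top-k list and the
    selected optimal pair id. Deterministic given inputs.
    """
    if noise_cap is None:
        noise_cap = default_noise_cap(table, energies)
    pairs = enumerate_ordered_pairs(table.names)
    scores: list[PairScore] = []
    exclusions: dict[str, int] = {}
    for a, b in pairs:
        bp = build_basis_pair(table, a, b, energies)
        s = score_pair(cohort, bp)
        if s.degenerate:
            logger.info("pair %s/%s degenerate (cond=%.3g), skipped", a, b, bp.condition_number)
        if s.n_excluded:
            exclusions[s.pair_id] = s.n_excluded
        scores.append(s)
    top_k, optimal = rank_and_select(scores, k=k, noise_cap=noise_cap)

    df = pd.DataFrame(
        {
            "material_a": [s.material_a for s in scores],
            "material_b": [s.material_b for s in scores],
            "n": [s.n_patients for s in scores],
            "mean_contrast_pct": [s.mean_contrast for s in scores],
            "sd_contrast_pct": [s.sd_contrast for s in scores],
            "z_value": [s.z if s.z_defined else np.nan for s in scores],
            "noise_amplification": [s.noise_amp for s in scores],
            "degenerate": [s.degenerate for s in scores],
        }
    )
    order = (-df["mean_contrast_pct"].abs().round(6)).to_numpy()
    rank = np.full(len(df), np.nan)
    valid = ~df["degenerate"] & np.isfinite(df["mean_contrast_pct"])
    idx = df.index[valid].to_numpy()
    idx = idx[np.lexsort((df.loc[valid, "material_b"], df.loc[valid, "material_a"],
                          order[valid]))]
    rank[idx] = np.arange(1, len(idx) + 1)
    df["rank"] = rank
    df = df[REPORT_COLUMNS]
    return PairSearchReport(
        scores=df, top_k=top_k, optimal=optimal, noise_cap=noise_cap,
        energies=energies, exclusions=exclusions,
    )
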