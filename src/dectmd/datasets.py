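"""Bundled example data: pooled per-reader counts from a published four-reader
evaluation of pancreatic-phase dual-energy CT image datasets.

110 patients (67 with pancreatic ductal adenocarcinoma, 43 without) were
each read on a conventional image dataset (iodine map + low-keV VMI) and an
optimal two-material image dataset by two experts and two trainees. Only
the per-reader 2x2 confusion counts are public; raw ratings are not, so
rating-level analyses use the synthetic generator instead.
"""

from __future__ import annotations

import pandas as pd

from .reader_stats import ConfusionCounts

__all__ = ["example_reader_counts", "READER_GROUPS"]

READER_GROUPS = {
    "R1": "expert",
    "R2": "expert",
    "R3": "trainee",
    "R4": "trainee",
}

# (reader, dataset) -> (tp, fp, tn, fn); every reader saw 67 diseased and
# 43 non-diseased patients.
_COUNTS: dict[tuple[str, str], tuple[int, int, int, int]] = {
    ("R1", "conventional"): (66, 3, 40, 1),
    ("R1", "optimal"): (66, 3, 40, 1),
    ("R2", "conventional"): (66, 6, 37, 1),
    ("R2", "optimal"): (66, 6, 37, 1),
    ("R3", "conventional"): (65, 9, 34, 2),
    ("R3", "optimal"): (64, 5, 38, 3),
    ("R4", "conventional"): (67, 15, 28, 0),
    ("R4", "optimal"): (67, 6, 37, 0),
}


def example_reader_counts() -> pd.DataFrame:
    """Per-reader confusion counts, one row per (reader, dataset).

    Columns: ``reader_id, group, dataset, tp, fp, tn, fn``.
    """
    rows = [
        (reader, READER_GROUPS[reader], dataset, *counts)
        for (reader, dataset), counts in _COUNTS.items()
    ]
    return pd.DataFrame(
        rows, columns=["reader_id", "group", "dataset", "tp", "fp", "tn", "fn"]
    )


def counts_for(df: pd.DataFrame, dataset: str, group: str | None = None) -> list[ConfusionCounts]:
    """Per-reader :class:`ConfusionCounts` for one dataset (optionally one group)."""
    sub = df[df["dataset"] == dataset]
    if group is not None:
        sub = sub[sub["group"] == group]
    return [
        ConfusionCounts(tp=int(r.tp), fp=int(r.fp), tn=int(r.tn), fn=int(r.fn))
        for r in sub.itertuples()
    ]
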