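"""Aggregation of per-breed ROH length-class counts into cohort tables.

The aggregator takes a breeds x length-classes count matrix plus a
breed -> group map and produces class totals, group totals, the percentage
of all segments per class, and each group's share within every class.  It
is used both by the pipeline reporting stage and directly on externally
tabulated counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

#: Canonical length-class labels (Mb, half-open, last class open-ended).
CLASS_LABELS: tuple[str, ...] = ("1-5", "5-10", "10-20", "20-40", ">40")


@dataclass
class ClassCountSummary:
    """Totals and shares derived from a breeds x classes count matrix."""

    counts: pd.DataFrame                 # breeds x classes
    group_of: dict[str, str]
    class_totals: pd.Series              # per class, summed over breeds
    grand_total: int
    group_totals: pd.Series              # per group, summed over classes
    group_class_counts: pd.DataFrame     # groups x classes
    class_share_pct: pd.Series           # 100 * class_total / grand_total
    group_class_share_pct: pd.DataFrame  # 100 * group count / class total

    def to_frames(self) -> dict[str, pd.DataFrame]:
        return {
            "class_counts": self.counts,
            "group_class_counts": self.group_class_counts,
            "class_share_pct": self.class_share_pct.to_frame("share_pct"),
            "group_class_share_pct": self.group_class_share_pct,
        }


def aggregate_class_counts(
    counts: pd.DataFrame, group_of: Mapping[str, str]
) -> ClassCountSummary:
    """Aggregate per-breed length-class counts.

    Parameters
    ----------
    counts:
        Integer matrix indexed by breed with one column per length class.
    group_of:
        Breed -> group label; every breed in ``counts`` must be mapped.

    Shares within a class sum to 100% across groups (classes with a zero
    total get NaN shares).
    """
    counts = counts.copy()
    if counts.isna().any().any():
        raise ValueError("class counts must not contain missing values")
    arr = counts.to_numpy()
    if (arr < 0).any():
        raise ValueError("class counts must be non-negative")
    missing = [b for b in counts.index if b not in group_of]
    if missing:
        raise KeyError(f"breeds without a group mapping: {missing}")

    groups = pd.Series({b: group_of[b] for b in counts.index}, name="group")
    class_totals = counts.sum(axis=0)
    grand_total = int(class_totals.sum())
    group_class_counts = counts.groupby(groups).sum()
    group_totals = group_class_counts.sum(axis=1)

    with np.errstate(invalid="ignore", divide="ignore"):
        class_share = 100.0 * class_totals / grand_total if grand_total else class_totals * np.nan
        denom = class_totals.replace(0, np.nan)
        group_class_share = 100.0 * group_class_counts.div(denom, axis=1)

    return ClassCountSummary(
        counts=counts,
        group_of=dict(group_of),
        class_totals=class_totals,
        grand_total=grand_total,
        group_totals=group_totals,
        group_class_counts=group_class_counts,
        class_share_pct=class_share,
        group_class_share_pct=group_class_share,
    )


def read_class_counts_tsv(path: str | Path) -> tuple[pd.DataFrame, dict[str, str]]:
    """Read a per-breed class-count table.

    Expected columns: ``breed``, ``group``, then one column per length class
    (any subset/ordering of :data:`CLASS_LABELS` is accepted as long as the
    names match).
    """
    frame = pd.read_csv(path, sep="\t", dtype={"breed": str, "group": str})
    for col in ("breed", "group"):
        if col not in frame.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    class_cols = [c for c in frame.columns if c in CLASS_LABELS]
    if not class_cols:
        raise ValueError(f"{path}: no length-class columns found")
    counts = frame.set_index("breed")[class_cols].astype(int)
    group_of = dict(zip(frame["breed"], frame["group"]))
    return counts, group_of


def write_summary_tsvs(summary: ClassCountSummary, out_dir: str | Path) -> list[Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, frame in summary.to_frames().items():
        path = out_dir / f"{name}.tsv"
        frame.to_csv(path, sep="\t")
        written.append(path)
    return written
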