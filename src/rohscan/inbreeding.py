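"""Genomic inbreeding coefficients from excess homozygosity and from ROHs.

F_HOM = (O - E) / (L - E) with O the observed and E the chance-expected
homozygote count over an individual's genotyped autosomal SNPs; E uses the
cohort allele frequencies with an optional small-sample correction factor
n/(n-1) on the heterozygosity term (n = non-missing haploid count at the
variant).

F_ROH = sum of an individual's ROH lengths divided by L_auto, the autosomal
span covered by the SNP map (per-chromosome last minus first SNP position,
summed).  Per-length-class components bin each segment wholly into its
class.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeDataset, allele_stats
from .roh import (
    DEFAULT_CLASS_EDGES_MB,
    ROHSegment,
    ROHSet,
    class_labels_for_edges,
    classify_lengths_mb,
)

logger = logging.getLogger(__name__)


def _per_variant_hom_expectation(
    dataset: GenotypeDataset, small_sample_correction: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Per-variant expected homozygote probability and a usability mask.

    Variants with fewer than two observed alleles carry no information and
    are masked out (with a warning).
    """
    stats = allele_stats(dataset)
    p = stats.p
    n_hap = 2 * stats.frame["n_obs"].to_numpy()
    usable = n_hap >= 2
    if (~usable).any():
        warnings.warn(
            f"{int((~usable).sum())} variant(s) with <2 observed alleles skipped in E",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        het_exp = 2.0 * p * (1.0 - p)
        if small_sample_correction:
            het_exp = het_exp * n_hap / np.maximum(n_hap - 1, 1)
    contrib = 1.0 - het_exp
    contrib[~usable] = 0.0
    return contrib, usable


def expected_homozygotes(
    dataset: GenotypeDataset, sample_id: str, small_sample_correction: bool = True
) -> float:
    """E: homozygotes expected by chance over the sample's non-missing variants."""
    i = dataset.sample_index(sample_id)
    contrib, usable = _per_variant_hom_expectation(dataset, small_sample_correction)
    observed = (dataset.calls[i] != MISSING) & usable
    return float(contrib[observed].sum())


def observed_homozygotes(dataset: GenotypeDataset, sample_id: str) -> tuple[int, int]:
    """(O, L): observed homozygote count and genotyped SNP count for a sample."""
    i = dataset.sample_index(sample_id)
    calls = dataset.calls[i]
    non_missing = calls != MISSING
    o = int(((calls == 0) | (calls == 2)).sum())
    return o, int(non_missing.sum())


def f_hom(o: float, e: float, l: float) -> float:
    """Excess-homozygosity inbreeding coefficient (O - E) / (L - E)."""
    if l <= e:
        raise ValueError(f"degenerate input: L={l} must exceed E={e}")
    return (o - e) / (l - e)


def autosome_length(dataset: GenotypeDataset) -> int:
    """L_auto: summed per-chromosome SNP span (last - first position + 1).

    Chromosomes with fewer than two SNPs are excluded with a warning.
    """
    total = 0
    for chrom, sl in dataset.chrom_slices().items():
        n = sl.stop - sl.start
        if n < 2:
            warnings.warn(f"chromosome {chrom} has <2 SNPs; excluded from L_auto", stacklevel=2)
            continue
        first, last = dataset.positions[sl.start], dataset.positions[sl.stop - 1]
        total += int(last - first + 1)
    return total


def _check_non_overlapping(segments: Sequence[ROHSegment]) -> None:
    by_chrom: dict[int, list[ROHSegment]] = {}
    for seg in segments:
        by_chrom.setdefault(seg.chrom, []).append(seg)
    for segs in by_chrom.values():
        segs = sorted(segs, key=lambda s: s.start_bp)
        for a, b in zip(segs, segs[1:]):
            if b.start_bp <= a.end_bp:
                raise ValueError(
                    f"overlapping segments for one sample on chrom {a.chrom}: "
                    f"[{a.start_bp}, {a.end_bp}] and [{b.start_bp}, {b.end_bp}]"
                )


def f_roh(
    sample_segments: Sequence[ROHSegment],
    l_auto: int,
    class_range_mb: tuple[float, float | None] | None = None,
) -> float:
    """Fraction of the SNP-covered autosome inside the sample's ROHs.

    ``class_range_mb`` restricts the sum to segments whose length falls in
    ``[lo, hi)`` Mb (``hi=None`` means unbounded above).
    """
    if l_auto <= 0:
        raise ValueError("l_auto must be positive")
    ids = {s.sample_id for s in sample_segments}
    if len(ids) > 1:
        raise ValueError(f"segments belong to more than one sample: {sorted(ids)}")
    _check_non_overlapping(sample_segments)
    total = 0
    for seg in sample_segments:
        if class_range_mb is not None:
            lo, hi = class_range_mb
            if seg.length_mb < lo or (hi is not None and seg.length_mb >= hi):
                continue
        total += seg.length_bp
    return total / l_auto


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson product-moment correlation coefficient."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if (x == x[0]).all() or (y == y[0]).all():
        raise ValueError("undefined correlation: zero variance")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = math.sqrt(float(xc @ xc) * float(yc @ yc))
    if denom == 0.0:
        raise ValueError("undefined correlation: zero variance")
    return float(np.clip((xc @ yc) / denom, -1.0, 1.0))


# ---------------------------------------------------------------------------
# per-individual records and per-breed summaries
# ---------------------------------------------------------------------------


def _class_columns(class_edges_mb: Sequence[float]) -> list[str]:
    return [f"f_roh_{lab}" for lab in class_labels_for_edges(class_edges_mb)]


def inbreeding_records(
    dataset: GenotypeDataset,
    rohset: ROHSet,
    class_edges_mb: Sequence[float] = DEFAULT_CLASS_EDGES_MB,
    small_sample_correction: bool = True,
) -> pd.DataFrame:
    """One row per individual: O, E, L, F_HOM, per-class and total F_ROH."""
    contrib, usable = _per_variant_hom_expectation(dataset, small_sample_correction)
    l_auto = autosome_length(dataset)
    labels = class_labels_for_edges(class_edges_mb)
    edges = list(class_edges_mb)
    ranges: list[tuple[float, float | None]] = [
        (a, b) for a, b in zip(edges, edges[1:])
    ] + [(edges[-1], None)]
    by_sample = rohset.by_sample()

    calls = dataset.calls
    non_missing = calls != MISSING
    o_vec = ((calls == 0) | (calls == 2)).sum(axis=1)
    l_vec = non_missing.sum(axis=1)
    e_vec = (non_missing & usable) @ contrib

    rows = []
    for i, s in enumerate(dataset.samples):
        segs = by_sample.get(s.sample_id, [])
        row: dict[str, object] = {
            "sample_id": s.sample_id,
            "breed": s.breed,
            "group": s.group,
            "O": int(o_vec[i]),
            "E": float(e_vec[i]),
            "L": int(l_vec[i]),
            "L_auto": l_auto,
            "f_hom": f_hom(int(o_vec[i]), float(e_vec[i]), int(l_vec[i])),
        }
        for lab, rng in zip(labels, ranges):
            row[f"f_roh_{lab}"] = f_roh(segs, l_auto, class_range_mb=rng)
        row["f_roh_all"] = f_roh(segs, l_auto)
        rows.append(row)
    return pd.DataFrame(rows)


def breed_summaries(
    records: pd.DataFrame,
    class_edges_mb: Sequence[float] = DEFAULT_CLASS_EDGES_MB,
) -> pd.DataFrame:
    """Per-breed mean +/- SE of F_ROH (per class and total), mean +/- SD of
    F_HOM, and the Pearson correlation between total F_ROH and F_HOM.

    The correlation is NaN for breeds with fewer than three individuals or
    with zero variance in either coefficient.
    """
    class_cols = _class_columns(class_edges_mb)
    rows = []
    for breed, grp in records.groupby("breed", sort=True):
        row: dict[str, object] = {"breed": breed, "n": len(grp)}
        for col in class_cols + ["f_roh_all"]:
            vals = grp[col].to_numpy(dtype=float)
            row[f"{col}_mean"] = float(vals.mean())
            row[f"{col}_se"] = (
                float(np.std(vals, ddof=1) / math.sqrt(len(vals))) if len(vals) > 1 else float("nan")
            )
        fh = grp["f_hom"].to_numpy(dtype=float)
        row["f_hom_mean"] = float(fh.mean())
        row["f_hom_sd"] = float(np.std(fh, ddof=1)) if len(fh) > 1 else float("nan")
        try:
            row["r_froh_fhom"] = pearson_r(grp["f_roh_all"], grp["f_hom"])
        except ValueError:
            row["r_froh_fhom"] = float("nan")
        rows.append(row)
    return pd.DataFrame(rows).set_index("breed")
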