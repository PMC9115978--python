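"""ROH incidence tracks, island (hotspot) calling and interval annotation.

A breed's incidence track holds, for every post-QC SNP, the fraction of the
breed's individuals whose called ROHs cover that SNP's position.  Maximal
runs of map-adjacent SNPs whose incidence reaches the hotspot threshold
(default 0.40, inclusive) form islands; runs never span chromosomes and a
single below-threshold SNP splits an island.

Features for annotation are read from BED (0-based half-open) or GFF3
(1-based inclusive) and normalised internally to 1-based inclusive.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genotype_io import GenotypeDataset
from .roh import ROHSet

logger = logging.getLogger(__name__)

DEFAULT_ISLAND_THRESHOLD = 0.40


@dataclass
class IncidenceTrack:
    """Per-SNP ROH incidence for one breed, aligned to the dataset map."""

    breed: str
    n_individuals: int
    values: np.ndarray  # fraction in [0, 1], one entry per SNP

    def to_frame(self, dataset: GenotypeDataset) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": dataset.chromosomes,
                "pos_bp": dataset.positions,
                "snp_id": [v.id for v in dataset.variants],
                "breed": self.breed,
                "incidence": self.values,
            }
        )


@dataclass(frozen=True)
class IslandInterval:
    """A maximal run of above-threshold SNPs on one chromosome."""

    breed: str
    chrom: int
    start_bp: int
    end_bp: int
    n_snps: int
    peak_incidence: float
    snp_ids: tuple[str, ...]

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp + 1


@dataclass(frozen=True)
class AnnotationHit:
    """One (island, feature) overlap of at least 1 bp."""

    island: IslandInterval
    feature_id: str
    feature_chrom: int
    feature_start_bp: int
    feature_end_bp: int
    overlap_bp: int


def snp_incidence(rohset: ROHSet, dataset: GenotypeDataset, breed: str) -> IncidenceTrack:
    """Fraction of a breed's individuals with >= 1 ROH covering each SNP."""
    members = [s.sample_id for s in rohset.samples if s.breed == breed]
    if not members:
        raise KeyError(f"unknown breed {breed!r}")
    pos = dataset.positions
    chroms = dataset.chromosomes
    slices = dataset.chrom_slices()
    counts = np.zeros(dataset.n_s, dtype=np.int64)
    by_sample = rohset.by_sample()
    for m in members:
        covered = np.zeros(dataset.n_s, dtype=bool)
        for seg in by_sample.get(m, []):
            sl = slices.get(seg.chrom)
            if sl is None:
                continue
            cpos = pos[sl]
            lo = int(np.searchsorted(cpos, seg.start_bp, side="left"))
            hi = int(np.searchsorted(cpos, seg.end_bp, side="right"))
            covered[sl.start + lo : sl.start + hi] = True
        counts += covered
    return IncidenceTrack(
        breed=breed, n_individuals=len(members), values=counts / len(members)
    )


def call_islands(
    track: IncidenceTrack,
    dataset: GenotypeDataset,
    threshold: float = DEFAULT_ISLAND_THRESHOLD,
) -> list[IslandInterval]:
    """Maximal runs of map-adjacent same-chromosome SNPs with incidence >=
    ``threshold`` (inclusive)."""
    if not 0.0 < threshold <= 1.0:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    values = track.values
    pos = dataset.positions
    ids = [v.id for v in dataset.variants]
    islands: list[IslandInterval] = []
    for chrom, sl in dataset.chrom_slices().items():
        above = values[sl] >= threshold
        idx = np.flatnonzero(above)
        if idx.size == 0:
            continue
        breaks = np.flatnonzero(np.diff(idx) > 1)
        starts = np.concatenate([[0], breaks + 1])
        stops = np.concatenate([breaks, [idx.size - 1]])
        for a, b in zip(starts, stops):
            lo = sl.start + int(idx[a])
            hi = sl.start + int(idx[b])
            islands.append(
                IslandInterval(
                    breed=track.breed,
                    chrom=chrom,
                    start_bp=int(pos[lo]),
                    end_bp=int(pos[hi]),
                    n_snps=hi - lo + 1,
                    peak_incidence=float(values[lo : hi + 1].max()),
                    snp_ids=tuple(ids[lo : hi + 1]),
                )
            )
    return islands


def compare_group_islands(
    tracks_by_breed: Mapping[str, IncidenceTrack],
    dataset: GenotypeDataset,
    group_of: Mapping[str, str],
    threshold: float = DEFAULT_ISLAND_THRESHOLD,
) -> dict[str, object]:
    """Island SNP sets per group (union over the group's breeds) and their
    unique/shared decomposition.

    Returns ``{"groups": (g1, g2), "unique": {g: set}, "shared": set,
    "union": set}``.
    """
    group_snps: dict[str, set[str]] = {}
    for breed, track in tracks_by_breed.items():
        group = group_of.get(breed)
        if group is None:
            raise KeyError(f"breed {breed!r} has no group mapping")
        snps = group_snps.setdefault(group, set())
        for isl in call_islands(track, dataset, threshold):
            snps.update(isl.snp_ids)
    groups = sorted(group_snps)
    if len(groups) != 2:
        raise ValueError(f"expected exactly two groups with breeds, got {groups}")
    g1, g2 = groups
    shared = group_snps[g1] & group_snps[g2]
    return {
        "groups": (g1, g2),
        "unique": {g1: group_snps[g1] - shared, g2: group_snps[g2] - shared},
        "shared": shared,
        "union": group_snps[g1] | group_snps[g2],
    }


# ---------------------------------------------------------------------------
# feature annotation
# ---------------------------------------------------------------------------


def read_features(path: str | Path) -> pd.DataFrame:
    """Read intervals from BED or GFF3 into 1-based inclusive coordinates.

    Columns of the result: ``chrom`` (int), ``start_bp``, ``end_bp``,
    ``feature_id``.  Rows on chromosomes that do not parse as integers are
    skipped with a warning.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".bed":
        frame = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
        chrom = frame[0]
        start = frame[1].astype(int) + 1  # 0-based half-open -> 1-based inclusive
        end = frame[2].astype(int)
        if frame.shape[1] > 3:
            name = frame[3].astype(str)
        else:
            name = pd.Series([f"feature_{i}" for i in range(len(frame))])
    elif suffix in (".gff", ".gff3", ".gtf"):
        frame = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
        if frame.shape[1] < 9:
            raise ValueError(f"{path}: expected 9 GFF3 columns")
        chrom = frame[0]
        start = frame[3].astype(int)
        end = frame[4].astype(int)
        name = frame[8].map(_gff3_feature_id)
        name = pd.Series(
            [n if n else f"feature_{i}" for i, n in enumerate(name)], index=frame.index
        )
    else:
        raise ValueError(f"unsupported feature format: {path.name}")

    chrom_num = pd.to_numeric(chrom, errors="coerce")
    bad = chrom_num.isna()
    if bad.any():
        warnings.warn(
            f"{int(bad.sum())} feature(s) on unknown chromosomes skipped: "
            f"{sorted(set(chrom[bad]))[:5]}",
            stacklevel=2,
        )
    out = pd.DataFrame(
        {
            "chrom": chrom_num[~bad].astype(int),
            "start_bp": start[~bad],
            "end_bp": end[~bad],
            "feature_id": name[~bad],
        }
    ).reset_index(drop=True)
    return out


def _gff3_feature_id(attributes: str) -> str:
    fields = dict(
        kv.split("=", 1) for kv in str(attributes).split(";") if "=" in kv
    )
    return fields.get("Name") or fields.get("ID") or ""


def annotate_islands(
    islands: Sequence[IslandInterval], feature_file: str | Path
) -> list[AnnotationHit]:
    """Every (island, feature) pair overlapping by >= 1 bp, in deterministic
    (chrom, island start, feature id) order."""
    features = read_features(feature_file)
    hits: list[AnnotationHit] = []
    by_chrom = {
        int(chrom): grp.sort_values(["start_bp", "feature_id"]).reset_index(drop=True)
        for chrom, grp in features.groupby("chrom")
    }
    for isl in islands:
        grp = by_chrom.get(isl.chrom)
        if grp is None:
            continue
        starts = grp["start_bp"].to_numpy()
        # candidates: features starting at or before the island end
        n_cand = int(np.searchsorted(starts, isl.end_bp, side="right"))
        for k in range(n_cand):
            f_start = int(grp.at[k, "start_bp"])
            f_end = int(grp.at[k, "end_bp"])
            overlap = min(isl.end_bp, f_end) - max(isl.start_bp, f_start) + 1
            if overlap >= 1:
                hits.append(
                    AnnotationHit(
                        island=isl,
                        feature_id=str(grp.at[k, "feature_id"]),
                        feature_chrom=isl.chrom,
                        feature_start_bp=f_start,
                        feature_end_bp=f_end,
                        overlap_bp=int(overlap),
                    )
                )
    hits.sort(key=lambda h: (h.island.chrom, h.island.start_bp, h.feature_id))
    return hits


def islands_to_frame(islands: Sequence[IslandInterval]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "breed": [i.breed for i in islands],
            "chrom": [i.chrom for i in islands],
            "start_bp": [i.start_bp for i in islands],
            "end_bp": [i.end_bp for i in islands],
            "n_snps": [i.n_snps for i in islands],
            "peak_incidence": [i.peak_incidence for i in islands],
        }
    )


def hits_to_frame(hits: Sequence[AnnotationHit]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "breed": [h.island.breed for h in hits],
            "chrom": [h.island.chrom for h in hits],
            "island_start_bp": [h.island.start_bp for h in hits],
            "island_end_bp": [h.island.end_bp for h in hits],
            "feature_id": [h.feature_id for h in hits],
            "feature_start_bp": [h.feature_start_bp for h in hits],
            "feature_end_bp": [h.feature_end_bp for h in hits],
            "overlap_bp": [h.overlap_bp for h in hits],
        }
    )
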