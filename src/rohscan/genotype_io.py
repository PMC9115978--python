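"""PLINK-format genotype I/O, allele statistics and cohort quality control.

Two classic PLINK 1 dialects are supported: the PED/MAP text pair and the
SNP-major BED/BIM/FAM binary triple (magic bytes ``6C 1B``, mode ``01``).
Genotypes are held in memory as an ``int8`` matrix of counted-allele dosages
``{0, 1, 2}`` with ``-1`` marking a missing call.  Only autosomal variants
are retained; the number of autosomes is configurable (default 18).

The QC entry point :func:`apply_qc` applies, in a fixed order, a
sample-call-rate filter, a variant-call-rate filter, a Hardy-Weinberg exact
test filter and a minor-allele-frequency filter, and reports per-stage
removal tallies.
"""

from __future__ import annotations

import functools
import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Genotype code for a missing call.
MISSING: int = -1

_BED_MAGIC = bytes([0x6C, 0x1B])
_SNP_MAJOR_MODE = 0x01
_VALID_ALLELE_CHARS = frozenset("ACGT12")


class GenotypeIOError(ValueError):
    """A genotype file is malformed or uses an unsupported layout."""


class EmptyDatasetError(ValueError):
    """An operation produced or received a dataset without samples/variants."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class VariantRecord:
    """A single biallelic autosomal marker.

    ``allele_b`` is the counted allele: genotype code 2 means two copies of
    ``allele_b``.  Positions are 1-based inclusive base pairs.
    """

    id: str
    chrom: int
    pos_bp: int
    allele_a: str
    allele_b: str

    def __post_init__(self) -> None:
        if self.pos_bp < 1:
            raise GenotypeIOError(
                f"variant {self.id!r}: pos_bp must be >= 1, got {self.pos_bp}"
            )


@dataclass(frozen=True)
class SampleRecord:
    sample_id: str
    breed: str = "unknown"
    group: str = "other"


@dataclass
class GenotypeDataset:
    """Samples x variants matrix of counted-allele dosages.

    ``calls[i, j]`` holds the genotype of sample ``i`` at variant ``j`` as a
    count of ``allele_b`` copies, or :data:`MISSING`.
    """

    samples: list[SampleRecord]
    variants: list[VariantRecord]
    calls: np.ndarray
    n_dropped_non_autosomal: int = 0

    def __post_init__(self) -> None:
        self.calls = np.ascontiguousarray(self.calls, dtype=np.int8)
        if self.calls.ndim != 2 or self.calls.shape != (
            len(self.samples),
            len(self.variants),
        ):
            raise GenotypeIOError(
                f"calls matrix shape {self.calls.shape} does not match "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        bad = ~np.isin(self.calls, (0, 1, 2, MISSING))
        if bad.any():
            raise GenotypeIOError("calls contain codes outside {0, 1, 2, missing}")
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise GenotypeIOError("duplicate sample ids in dataset")
        keys = [(v.chrom, v.pos_bp) for v in self.variants]
        for a, b in zip(keys, keys[1:]):
            if b <= a:
                raise GenotypeIOError(
                    "variants must be strictly increasing by (chrom, pos_bp)"
                )

    # -- shape ------------------------------------------------------------

    @property
    def n_i(self) -> int:
        """Number of individuals."""
        return len(self.samples)

    @property
    def n_s(self) -> int:
        """Number of variants."""
        return len(self.variants)

    # -- convenience views -------------------------------------------------

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def positions(self) -> np.ndarray:
        return np.array([v.pos_bp for v in self.variants], dtype=np.int64)

    @property
    def chromosomes(self) -> np.ndarray:
        return np.array([v.chrom for v in self.variants], dtype=np.int64)

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise KeyError(f"unknown sample_id {sample_id!r}") from None

    def chrom_slices(self) -> dict[int, slice]:
        """Contiguous column slice per chromosome (variants are sorted)."""
        chroms = self.chromosomes
        out: dict[int, slice] = {}
        if chroms.size == 0:
            return out
        bounds = np.flatnonzero(np.diff(chroms)) + 1
        starts = np.concatenate([[0], bounds])
        stops = np.concatenate([bounds, [chroms.size]])
        for a, b in zip(starts, stops):
            out[int(chroms[a])] = slice(int(a), int(b))
        return out

    def chrom_spans(self) -> dict[int, tuple[int, int]]:
        """First/last SNP position per chromosome."""
        pos = self.positions
        return {
            c: (int(pos[s.start]), int(pos[s.stop - 1]))
            for c, s in self.chrom_slices().items()
        }

    def subset(
        self,
        sample_idx: np.ndarray | Sequence[int] | None = None,
        variant_idx: np.ndarray | Sequence[int] | None = None,
    ) -> "GenotypeDataset":
        si = (
            np.arange(self.n_i)
            if sample_idx is None
            else np.asarray(sample_idx, dtype=np.intp)
        )
        vi = (
            np.arange(self.n_s)
            if variant_idx is None
            else np.asarray(variant_idx, dtype=np.intp)
        )
        return GenotypeDataset(
            samples=[self.samples[int(i)] for i in si],
            variants=[self.variants[int(j)] for j in vi],
            calls=self.calls[np.ix_(si, vi)],
            n_dropped_non_autosomal=self.n_dropped_non_autosomal,
        )

    def equals(self, other: "GenotypeDataset") -> bool:
        return (
            self.samples == other.samples
            and self.variants == other.variants
            and np.array_equal(self.calls, other.calls)
        )

    def variant_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": [v.id for v in self.variants],
                "chrom": self.chromosomes,
                "pos_bp": self.positions,
                "allele_a": [v.allele_a for v in self.variants],
                "allele_b": [v.allele_b for v in self.variants],
            }
        )


def _autosome_set(autosomes: int | Iterable[int]) -> set[int]:
    if isinstance(autosomes, int):
        return set(range(1, autosomes + 1))
    return {int(c) for c in autosomes}


# ---------------------------------------------------------------------------
# PED/MAP text dialect
# ---------------------------------------------------------------------------


def read_plink_text(
    ped_path: str | Path,
    map_path: str | Path,
    autosomes: int | Iterable[int] = 18,
) -> GenotypeDataset:
    """Read a PLINK PED/MAP text pair.

    The counted allele (``allele_b``, code 2) of each variant is assigned to
    the minor allele observed in the file; ties are broken toward the
    lexicographically larger allele so the assignment is deterministic.
    ``0 0`` (or any pair containing ``0``) maps to a missing call.
    Non-autosomal rows and rows with non-positive positions are dropped and
    counted in ``n_dropped_non_autosomal``.
    """
    auto = _autosome_set(autosomes)
    map_path, ped_path = Path(map_path), Path(ped_path)

    map_rows: list[tuple[int, str, int, int]] = []  # (orig_col, id, chrom, pos)
    n_total = 0
    n_dropped = 0
    with open(map_path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            if not raw.strip():
                continue
            parts = raw.split()
            if len(parts) != 4:
                raise GenotypeIOError(
                    f"{map_path}:{lineno}: expected 4 MAP columns, got {len(parts)}"
                )
            chrom_s, snp_id, _cm, pos_s = parts
            col = n_total
            n_total += 1
            try:
                chrom = int(chrom_s)
            except ValueError:
                chrom = -1
            try:
                pos = int(pos_s)
            except ValueError:
                raise GenotypeIOError(
                    f"{map_path}:{lineno}: unparseable position {pos_s!r}"
                ) from None
            if chrom not in auto or pos < 1:
                n_dropped += 1
                continue
            map_rows.append((col, snp_id, chrom, pos))

    samples: list[SampleRecord] = []
    pairs: list[list[tuple[str, str]]] = []  # per sample, per kept variant
    with open(ped_path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            if not raw.strip():
                continue
            parts = raw.split()
            expected = 6 + 2 * n_total
            if len(parts) != expected:
                raise GenotypeIOError(
                    f"{ped_path}:{lineno}: expected {expected} PED columns for "
                    f"{n_total} MAP rows, got {len(parts)}"
                )
            fid, iid = parts[0], parts[1]
            samples.append(SampleRecord(sample_id=iid, breed=fid))
            row: list[tuple[str, str]] = []
            for col, _sid, _c, _p in map_rows:
                a1 = parts[6 + 2 * col]
                a2 = parts[7 + 2 * col]
                for a in (a1, a2):
                    if a != "0" and a not in _VALID_ALLELE_CHARS:
                        raise GenotypeIOError(
                            f"{ped_path}:{lineno}: invalid allele {a!r}"
                        )
                row.append((a1, a2))
            pairs.append(row)

    if not samples:
        raise EmptyDatasetError(f"{ped_path}: no samples")

    order = sorted(range(len(map_rows)), key=lambda k: (map_rows[k][2], map_rows[k][3]))
    variants: list[VariantRecord] = []
    calls = np.full((len(samples), len(map_rows)), MISSING, dtype=np.int8)
    for out_j, k in enumerate(order):
        _col, snp_id, chrom, pos = map_rows[k]
        counts: dict[str, int] = {}
        for row in pairs:
            a1, a2 = row[k]
            if a1 == "0" or a2 == "0":
                continue
            counts[a1] = counts.get(a1, 0) + 1
            counts[a2] = counts.get(a2, 0) + 1
        alleles = sorted(counts)
        if len(alleles) > 2:
            raise GenotypeIOError(
                f"variant {snp_id!r} has more than two alleles: {alleles}"
            )
        if not alleles:
            allele_a, allele_b = "0", "0"
        elif len(alleles) == 1:
            allele_a, allele_b = alleles[0], "0"
        else:
            # counted allele = minor; tie -> lexicographically larger
            x, y = alleles
            if counts[x] < counts[y] or (counts[x] == counts[y] and x > y):
                allele_a, allele_b = y, x
            else:
                allele_a, allele_b = x, y
        variants.append(VariantRecord(snp_id, chrom, pos, allele_a, allele_b))
        for i, row in enumerate(pairs):
            a1, a2 = row[k]
            if a1 == "0" or a2 == "0":
                continue
            calls[i, out_j] = (a1 == allele_b) + (a2 == allele_b)

    ds = GenotypeDataset(samples, variants, calls, n_dropped_non_autosomal=n_dropped)
    if n_dropped:
        logger.info("dropped %d non-autosomal/unknown-position variants", n_dropped)
    return ds


def write_plink_text(dataset: GenotypeDataset, prefix: str | Path) -> tuple[Path, Path]:
    """Write a PED/MAP pair; returns the (ped, map) paths."""
    if dataset.n_i == 0 or dataset.n_s == 0:
        raise EmptyDatasetError("refusing to write an empty dataset")
    prefix = Path(prefix)
    map_path = prefix.with_suffix(".map")
    ped_path = prefix.with_suffix(".ped")
    with open(map_path, "w") as fh:
        for v in dataset.variants:
            fh.write(f"{v.chrom}\t{v.id}\t0\t{v.pos_bp}\n")
    with open(ped_path, "w") as fh:
        for i, s in enumerate(dataset.samples):
            fields = [s.breed, s.sample_id, "0", "0", "0", "-9"]
            for j, v in enumerate(dataset.variants):
                c = int(dataset.calls[i, j])
                if c == MISSING:
                    fields += ["0", "0"]
                elif c == 0:
                    fields += [v.allele_a, v.allele_a]
                elif c == 1:
                    fields += [v.allele_a, v.allele_b]
                else:
                    fields += [v.allele_b, v.allele_b]
            fh.write(" ".join(fields) + "\n")
    return ped_path, map_path


# ---------------------------------------------------------------------------
# BED/BIM/FAM binary dialect (SNP-major)
# ---------------------------------------------------------------------------

# 2-bit field -> genotype code: 00 hom allele_a, 01 missing, 10 het, 11 hom allele_b
_BITS_TO_CODE = np.array([0, MISSING, 1, 2], dtype=np.int8)
_CODE_TO_BITS = {0: 0b00, MISSING: 0b01, 1: 0b10, 2: 0b11}

_DECODE_LUT = np.empty((256, 4), dtype=np.int8)
for _b in range(256):
    for _j in range(4):
        _DECODE_LUT[_b, _j] = _BITS_TO_CODE[(_b >> (2 * _j)) & 0b11]


def read_plink_binary(
    bed_path: str | Path,
    bim_path: str | Path,
    fam_path: str | Path,
    autosomes: int | Iterable[int] = 18,
) -> GenotypeDataset:
    """Read a PLINK 1 SNP-major BED/BIM/FAM triple."""
    auto = _autosome_set(autosomes)
    bim = pd.read_csv(bim_path, sep=r"\s+", header=None, dtype=str)
    if bim.shape[1] != 6:
        raise GenotypeIOError(f"{bim_path}: expected 6 BIM columns, got {bim.shape[1]}")
    fam = pd.read_csv(fam_path, sep=r"\s+", header=None, dtype=str)
    if fam.shape[1] < 2:
        raise GenotypeIOError(f"{fam_path}: expected >= 2 FAM columns")

    n_i = len(fam)
    n_s_total = len(bim)
    raw = Path(bed_path).read_bytes()
    if len(raw) < 3 or raw[:2] != _BED_MAGIC:
        raise GenotypeIOError(f"{bed_path}: missing PLINK BED magic bytes 6C 1B")
    if raw[2] != _SNP_MAJOR_MODE:
        raise GenotypeIOError(
            f"{bed_path}: unsupported mode byte 0x{raw[2]:02X} "
            "(only SNP-major 0x01 is supported)"
        )
    bpv = (n_i + 3) // 4  # bytes per variant
    expected = 3 + bpv * n_s_total
    if len(raw) != expected:
        raise GenotypeIOError(
            f"{bed_path}: expected {expected} bytes for {n_i} samples x "
            f"{n_s_total} variants, got {len(raw)}"
        )

    chrom_num = pd.to_numeric(bim[0], errors="coerce")
    pos_num = pd.to_numeric(bim[3], errors="coerce")
    keep = chrom_num.isin(list(auto)) & (pos_num >= 1)
    n_dropped = int((~keep).sum())

    body = np.frombuffer(raw, dtype=np.uint8, offset=3).reshape(n_s_total, bpv)
    decoded = _DECODE_LUT[body].reshape(n_s_total, bpv * 4)[:, :n_i]

    kept_idx = np.flatnonzero(keep.to_numpy())
    order = kept_idx[
        np.lexsort((pos_num.iloc[kept_idx].to_numpy(), chrom_num.iloc[kept_idx].to_numpy()))
    ]
    variants = [
        VariantRecord(
            id=str(bim.iat[j, 1]),
            chrom=int(chrom_num.iat[j]),
            pos_bp=int(pos_num.iat[j]),
            allele_a=str(bim.iat[j, 4]),
            allele_b=str(bim.iat[j, 5]),
        )
        for j in order
    ]
    calls = decoded[order].T
    samples = [
        SampleRecord(sample_id=str(fam.iat[i, 1]), breed=str(fam.iat[i, 0]))
        for i in range(n_i)
    ]
    ds = GenotypeDataset(samples, variants, calls, n_dropped_non_autosomal=n_dropped)
    if n_dropped:
        logger.info("dropped %d non-autosomal/unknown-position variants", n_dropped)
    return ds


def write_plink_binary(
    dataset: GenotypeDataset, prefix: str | Path
) -> tuple[Path, Path, Path]:
    """Write a SNP-major BED/BIM/FAM triple; returns (bed, bim, fam) paths."""
    if dataset.n_i == 0 or dataset.n_s == 0:
        raise EmptyDatasetError("refusing to write an empty dataset")
    prefix = Path(prefix)
    bed_path = prefix.with_suffix(".bed")
    bim_path = prefix.with_suffix(".bim")
    fam_path = prefix.with_suffix(".fam")

    with open(bim_path, "w") as fh:
        for v in dataset.variants:
            fh.write(f"{v.chrom}\t{v.id}\t0\t{v.pos_bp}\t{v.allele_a}\t{v.allele_b}\n")
    with open(fam_path, "w") as fh:
        for s in dataset.samples:
            fh.write(f"{s.breed}\t{s.sample_id}\t0\t0\t0\t-9\n")

    n_i = dataset.n_i
    bpv = (n_i + 3) // 4
    # map codes to 2-bit fields, pad with 00
    bits = np.zeros((dataset.n_s, bpv * 4), dtype=np.uint8)
    for code, pattern in _CODE_TO_BITS.items():
        bits[:, :n_i][dataset.calls.T == code] = pattern
    packed = (
        bits.reshape(dataset.n_s, bpv, 4)
        << np.array([0, 2, 4, 6], dtype=np.uint8)
    ).sum(axis=2, dtype=np.uint8)
    with open(bed_path, "wb") as fh:
        fh.write(_BED_MAGIC + bytes([_SNP_MAJOR_MODE]))
        fh.write(packed.tobytes())
    return bed_path, bim_path, fam_path


# ---------------------------------------------------------------------------
# allele statistics
# ---------------------------------------------------------------------------


@dataclass
class AlleleStats:
    """Per-variant allele frequency table plus cohort mean heterozygosity."""

    frame: pd.DataFrame  # columns: id, chrom, pos_bp, p, n_obs, het_obs, undefined
    het: float

    @property
    def p(self) -> np.ndarray:
        return self.frame["p"].to_numpy()


def allele_stats(dataset: GenotypeDataset) -> AlleleStats:
    """Counted-allele frequency, observed-genotype count and heterozygote
    fraction per variant, and the cohort mean observed heterozygosity.

    Frequencies use non-missing calls only.  Variants with zero non-missing
    calls are flagged ``undefined`` (``p`` is NaN) and excluded from the
    cohort ``het`` mean.
    """
    calls = dataset.calls
    obs = calls != MISSING
    n_obs = obs.sum(axis=0)
    dose = np.where(obs, calls, 0).sum(axis=0, dtype=np.int64)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(n_obs > 0, dose / np.maximum(2 * n_obs, 1), np.nan)
        het_obs = np.where(n_obs > 0, (calls == 1).sum(axis=0) / np.maximum(n_obs, 1), np.nan)
    undefined = n_obs == 0
    het = float(np.nanmean(het_obs)) if (~undefined).any() else float("nan")
    frame = dataset.variant_frame()[["id", "chrom", "pos_bp"]].copy()
    frame["p"] = p
    frame["n_obs"] = n_obs
    frame["het_obs"] = het_obs
    frame["undefined"] = undefined
    return AlleleStats(frame=frame, het=het)


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------


@functools.lru_cache(maxsize=None)
def _hwe_pvalues(n_genotypes: int, n_rare: int) -> dict[int, float]:
    """Exact two-sided p-value for every attainable heterozygote count,
    conditional on ``n_rare`` copies of the rarer allele among
    ``2 * n_genotypes`` alleles.

    Probabilities are built with the stable ratio recurrence of the
    conditional distribution and normalised; the p-value for an observed
    heterozygote count is the total probability of all counts whose
    probability does not exceed the observed one.
    """
    n2 = 2 * n_genotypes
    hets = list(range(n_rare % 2, n_rare + 1, 2))
    mid = int(n_rare * (n2 - n_rare) / n2)
    if mid % 2 != n_rare % 2:
        mid += 1 if mid < n_rare else -1
    probs = {mid: 1.0}
    h = mid
    while h + 2 <= n_rare:
        probs[h + 2] = probs[h] * (n_rare - h) * (n2 - n_rare - h) / (
            (h + 2.0) * (h + 1.0)
        )
        h += 2
    h = mid
    while h - 2 >= 0:
        probs[h - 2] = probs[h] * h * (h - 1) / (
            (n_rare - h + 2.0) * (n2 - n_rare - h + 2.0)
        )
        h -= 2
    total = sum(probs.values())
    dist = np.array([probs[h] / total for h in hets])
    out: dict[int, float] = {}
    for h, ph in zip(hets, dist):
        out[h] = float(min(1.0, dist[dist <= ph * (1.0 + 1e-12)].sum()))
    return out


def hwe_exact_test(n_hom_a: int, n_het: int, n_hom_b: int) -> float:
    """Two-sided Hardy-Weinberg exact test p-value.

    Sums the conditional probabilities of all heterozygote counts that are
    no more likely than the observed one, given the observed allele counts.
    """
    counts = (n_hom_a, n_het, n_hom_b)
    for c in counts:
        if int(c) != c or c < 0:
            raise ValueError(f"genotype counts must be non-negative integers: {counts}")
    n_hom_a, n_het, n_hom_b = (int(c) for c in counts)
    n = n_hom_a + n_het + n_hom_b
    if n < 1:
        raise ValueError("total genotype count must be >= 1")
    n_rare = 2 * min(n_hom_a, n_hom_b) + n_het
    return _hwe_pvalues(n, n_rare)[n_het]


# ---------------------------------------------------------------------------
# quality control
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class QCThresholds:
    """The four filtering thresholds (all fractions/probabilities in [0, 1])."""

    max_variant_missing: float = 0.05
    min_maf: float = 0.05
    max_sample_missing: float = 0.10
    hwe_p_floor: float = 1e-6

    def __post_init__(self) -> None:
        for name in (
            "max_variant_missing",
            "min_maf",
            "max_sample_missing",
            "hwe_p_floor",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclass
class QCReport:
    """Per-stage removal tallies for one :func:`apply_qc` pass."""

    stage_order: tuple[str, ...]
    n_removed_mind: int
    n_removed_geno: int
    n_removed_hwe: int
    n_removed_maf: int
    n_samples_kept: int
    n_variants_kept: int
    removed_samples_mind: list[str]
    removed_variants_geno: list[str]
    removed_variants_hwe: list[str]
    removed_variants_maf: list[str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "stage": ["mind", "geno", "hwe", "maf", "kept"],
                "n_samples_removed": [self.n_removed_mind, 0, 0, 0, self.n_samples_kept],
                "n_variants_removed": [
                    0,
                    self.n_removed_geno,
                    self.n_removed_hwe,
                    self.n_removed_maf,
                    self.n_variants_kept,
                ],
            }
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def apply_qc(
    dataset: GenotypeDataset, thresholds: QCThresholds
) -> tuple[GenotypeDataset, QCReport]:
    """Single ordered QC pass: mind -> geno -> hwe -> maf.

    Sample filtering precedes variant filtering; variant statistics (missing
    fraction, HWE, MAF) are computed on the post-mind sample set from
    non-missing calls only.
    """
    if dataset.n_i == 0 or dataset.n_s == 0:
        raise EmptyDatasetError("cannot QC an empty dataset")

    miss = dataset.calls == MISSING
    sample_missing = miss.mean(axis=1)
    keep_samples = sample_missing <= thresholds.max_sample_missing
    removed_mind = [
        s.sample_id for s, k in zip(dataset.samples, keep_samples) if not k
    ]
    if not keep_samples.any():
        raise EmptyDatasetError("QC removed every sample at the mind stage")
    ds = dataset.subset(sample_idx=np.flatnonzero(keep_samples))

    variant_missing = (ds.calls == MISSING).mean(axis=0)
    keep_geno = variant_missing <= thresholds.max_variant_missing
    removed_geno = [v.id for v, k in zip(ds.variants, keep_geno) if not k]
    ds = ds.subset(variant_idx=np.flatnonzero(keep_geno))

    calls = ds.calls
    n0 = (calls == 0).sum(axis=0)
    n1 = (calls == 1).sum(axis=0)
    n2 = (calls == 2).sum(axis=0)
    keep_hwe = np.ones(ds.n_s, dtype=bool)
    for j in range(ds.n_s):
        tot = int(n0[j] + n1[j] + n2[j])
        if tot == 0:
            continue  # undefined; geno stage owns missingness
        p_val = hwe_exact_test(int(n0[j]), int(n1[j]), int(n2[j]))
        if p_val < thresholds.hwe_p_floor:
            keep_hwe[j] = False
    removed_hwe = [v.id for v, k in zip(ds.variants, keep_hwe) if not k]
    ds = ds.subset(variant_idx=np.flatnonzero(keep_hwe))

    stats = allele_stats(ds)
    p = stats.p
    with np.errstate(invalid="ignore"):
        maf = np.minimum(p, 1.0 - p)
    drop_maf = maf < thresholds.min_maf  # NaN compares False -> kept
    removed_maf = [v.id for v, d in zip(ds.variants, drop_maf) if d]
    if drop_maf.all() and ds.n_s > 0:
        raise EmptyDatasetError("QC removed every variant")
    ds = ds.subset(variant_idx=np.flatnonzero(~drop_maf))
    if ds.n_s == 0:
        raise EmptyDatasetError("QC removed every variant")

    report = QCReport(
        stage_order=("mind", "geno", "hwe", "maf"),
        n_removed_mind=len(removed_mind),
        n_removed_geno=len(removed_geno),
        n_removed_hwe=len(removed_hwe),
        n_removed_maf=len(removed_maf),
        n_samples_kept=ds.n_i,
        n_variants_kept=ds.n_s,
        removed_samples_mind=removed_mind,
        removed_variants_geno=removed_geno,
        removed_variants_hwe=removed_hwe,
        removed_variants_maf=removed_maf,
    )
    logger.info(
        "QC (mind->geno->hwe->maf): removed %d samples, %d/%d/%d variants; kept %d x %d",
        report.n_removed_mind,
        report.n_removed_geno,
        report.n_removed_hwe,
        report.n_removed_maf,
        report.n_samples_kept,
        report.n_variants_kept,
    )
    return ds, report


# ---------------------------------------------------------------------------
# breed -> group map
# ---------------------------------------------------------------------------


def read_breed_group_map(path: str | Path) -> dict[str, str]:
    """Two-column TSV (breed, group) -> mapping; a header row is optional."""
    frame = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if frame.shape[1] < 2:
        raise GenotypeIOError(f"{path}: expected two tab-separated columns")
    rows = frame.iloc[:, :2].itertuples(index=False)
    mapping = {str(b): str(g) for b, g in rows}
    mapping.pop("breed", None)  # tolerate a header line
    return mapping


def apply_breed_groups(
    dataset: GenotypeDataset, mapping: Mapping[str, str], default: str = "other"
) -> GenotypeDataset:
    """Return a dataset whose sample groups follow a breed -> group map."""
    samples = [
        SampleRecord(s.sample_id, s.breed, mapping.get(s.breed, default))
        for s in dataset.samples
    ]
    return GenotypeDataset(
        samples,
        dataset.variants,
        dataset.calls.copy(),
        n_dropped_non_autosomal=dataset.n_dropped_non_autosomal,
    )
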