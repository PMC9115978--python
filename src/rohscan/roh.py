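"""Sliding-window run-of-homozygosity (ROH) scanner and summaries.

The scanner follows the classic SNP-array recipe: slide a fixed-size window
one SNP at a time along each chromosome, call a window homozygous when it
carries at most ``window_max_het`` heterozygous and ``window_max_missing``
missing calls, qualify a SNP when the fraction of homozygous windows among
the windows containing it reaches ``window_threshold``, and emit maximal
runs of qualifying SNPs that survive gap-splitting plus minimum-SNP,
minimum-length and density constraints.

``min_roh_snps`` computes the minimum run length l from the false-positive
bound l = ln(alpha / (n_s * n_i)) / ln(1 - het); the pipeline logs the
computed value but calls with the fixed ``min_snps`` parameter.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeDataset, SampleRecord
from .report import CLASS_LABELS, ClassCountSummary, aggregate_class_counts

logger = logging.getLogger(__name__)

DEFAULT_CLASS_EDGES_MB: tuple[float, ...] = (1.0, 5.0, 10.0, 20.0, 40.0)


@dataclass(frozen=True)
class ROHParams:
    """The seven calling criteria plus the false-positive rate alpha."""

    min_length_kb: float = 1000.0
    min_snps: int = 50
    max_gap_kb: float = 1000.0
    min_density_kb_per_snp: float = 100.0
    window_snps: int = 50
    window_max_het: int = 1
    window_max_missing: int = 5
    window_threshold: float = 0.01
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.min_snps < 1 or self.window_snps < 1:
            raise ValueError("min_snps and window_snps must be >= 1")
        if self.window_max_het < 0 or self.window_max_missing < 0:
            raise ValueError("window tolerances must be >= 0")
        if not 0.0 < self.window_threshold <= 1.0:
            raise ValueError("window_threshold must be in (0, 1]")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.min_length_kb <= 0 or self.max_gap_kb <= 0 or self.min_density_kb_per_snp <= 0:
            raise ValueError("length/gap/density parameters must be positive")
        if self.window_snps < self.min_snps:
            warnings.warn(
                "window_snps < min_snps: windows are smaller than the minimum run",
                stacklevel=2,
            )


@dataclass(frozen=True)
class ROHSegment:
    """One called homozygous run (1-based inclusive bp bounds)."""

    sample_id: str
    chrom: int
    start_bp: int
    end_bp: int
    n_snps: int
    breed: str = "unknown"

    def __post_init__(self) -> None:
        if self.start_bp > self.end_bp:
            raise ValueError("start_bp must be <= end_bp")
        if self.n_snps < 1:
            raise ValueError("n_snps must be >= 1")

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp + 1

    @property
    def length_mb(self) -> float:
        return self.length_bp / 1e6


@dataclass
class ROHSet:
    """All segments called in a cohort, plus the cohort's sample metadata.

    ``samples`` lists every scanned individual (including ROH-free ones) so
    that per-breed means are taken over the right denominators.
    """

    segments: list[ROHSegment]
    samples: list[SampleRecord]

    def __post_init__(self) -> None:
        known = {s.sample_id for s in self.samples}
        for seg in self.segments:
            if seg.sample_id not in known:
                raise ValueError(f"segment for unknown sample {seg.sample_id!r}")

    @property
    def breed_of(self) -> dict[str, str]:
        return {s.sample_id: s.breed for s in self.samples}

    @property
    def group_of_breed(self) -> dict[str, str]:
        return {s.breed: s.group for s in self.samples}

    def by_sample(self) -> dict[str, list[ROHSegment]]:
        out: dict[str, list[ROHSegment]] = {s.sample_id: [] for s in self.samples}
        for seg in self.segments:
            out[seg.sample_id].append(seg)
        for segs in out.values():
            segs.sort(key=lambda s: (s.chrom, s.start_bp))
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": [s.sample_id for s in self.segments],
                "breed": [s.breed for s in self.segments],
                "chrom": [s.chrom for s in self.segments],
                "start_bp": [s.start_bp for s in self.segments],
                "end_bp": [s.end_bp for s in self.segments],
                "n_snps": [s.n_snps for s in self.segments],
                "length_mb": [s.length_mb for s in self.segments],
            }
        )

    def validate(self, params: "ROHParams") -> None:
        """Audit every segment against the segment-level constraints."""
        for segs in self.by_sample().values():
            prev_end: dict[int, int] = {}
            for seg in segs:
                if seg.n_snps < params.min_snps:
                    raise AssertionError(f"{seg}: below min_snps")
                if seg.length_bp < params.min_length_kb * 1000.0:
                    raise AssertionError(f"{seg}: below min length")
                if (seg.length_bp / 1000.0) / seg.n_snps > params.min_density_kb_per_snp:
                    raise AssertionError(f"{seg}: too sparse")
                if seg.chrom in prev_end and seg.start_bp <= prev_end[seg.chrom]:
                    raise AssertionError(f"{seg}: overlaps previous segment")
                prev_end[seg.chrom] = seg.end_bp


# ---------------------------------------------------------------------------
# minimum-SNP rule
# ---------------------------------------------------------------------------


def min_roh_snps(alpha: float, n_s: int, n_i: int, het: float) -> int:
    """Minimum number of consecutive SNPs per ROH bounding the expected
    count of chance runs by ``alpha``: ceil(ln(alpha/(n_s*n_i)) / ln(1-het)).
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if n_s < 1 or n_i < 1:
        raise ValueError("n_s and n_i must be >= 1")
    if not 0.0 < het < 1.0:
        raise ValueError(f"het must be in (0, 1), got {het}")
    value = math.log(alpha / (n_s * n_i)) / math.log1p(-het)
    return max(1, math.ceil(value))


# ---------------------------------------------------------------------------
# scanner
# ---------------------------------------------------------------------------


def window_pass_flags(sample_calls: np.ndarray, params: ROHParams) -> np.ndarray:
    """Boolean flag per sliding window (step 1) over one chromosome's calls.

    A window passes when it holds at most ``window_max_het`` heterozygous
    and ``window_max_missing`` missing calls.  Chromosomes shorter than the
    window yield an empty array.
    """
    calls = np.asarray(sample_calls, dtype=np.int8)
    n = calls.size
    w = params.window_snps
    if n < w:
        return np.zeros(0, dtype=bool)
    het = np.concatenate([[0], np.cumsum(calls == 1)])
    mis = np.concatenate([[0], np.cumsum(calls == MISSING)])
    het_w = het[w:] - het[:-w]
    mis_w = mis[w:] - mis[:-w]
    return (het_w <= params.window_max_het) & (mis_w <= params.window_max_missing)


def snp_in_run_flags(
    window_flags: np.ndarray, params: ROHParams, n_snps: int | None = None
) -> np.ndarray:
    """Per-SNP qualification from window flags.

    A SNP qualifies when the fraction of passing windows among the windows
    that actually contain it is at least ``window_threshold`` (chromosome
    edges sit in fewer windows, so the denominator shrinks there).  SNPs in
    zero windows never qualify.
    """
    flags = np.asarray(window_flags, dtype=bool)
    w = params.window_snps
    nw = flags.size
    if n_snps is None:
        n_snps = nw + w - 1 if nw else 0
    if nw == 0:
        return np.zeros(n_snps, dtype=bool)
    cp = np.concatenate([[0], np.cumsum(flags)])
    i = np.arange(n_snps)
    lo = np.maximum(0, i - w + 1)
    hi = np.minimum(i, nw - 1)
    containing = hi - lo + 1
    passing = cp[hi + 1] - cp[lo]
    ok = containing > 0
    frac = np.where(ok, passing / np.maximum(containing, 1), 0.0)
    return ok & (frac >= params.window_threshold)


def _segments_from_qualifying(
    qual: np.ndarray,
    pos: np.ndarray,
    chrom: int,
    sample_id: str,
    breed: str,
    params: ROHParams,
) -> list[ROHSegment]:
    """Turn a per-SNP qualification mask into filtered segments."""
    segments: list[ROHSegment] = []
    idx = np.flatnonzero(qual)
    if idx.size == 0:
        return segments
    max_gap_bp = params.max_gap_kb * 1000.0
    min_len_bp = params.min_length_kb * 1000.0
    run_breaks = np.flatnonzero(np.diff(idx) > 1)
    run_starts = np.concatenate([[0], run_breaks + 1])
    run_stops = np.concatenate([run_breaks, [idx.size - 1]])
    for a, b in zip(run_starts, run_stops):
        lo, hi = int(idx[a]), int(idx[b])
        run_pos = pos[lo : hi + 1]
        # split the run at any inter-SNP gap above the tolerance
        gap_breaks = np.flatnonzero(np.diff(run_pos) > max_gap_bp)
        sub_starts = np.concatenate([[0], gap_breaks + 1])
        sub_stops = np.concatenate([gap_breaks, [run_pos.size - 1]])
        for sa, sb in zip(sub_starts, sub_stops):
            n = int(sb - sa + 1)
            start_bp = int(run_pos[sa])
            end_bp = int(run_pos[sb])
            length_bp = end_bp - start_bp + 1
            if n < params.min_snps:
                continue
            if length_bp < min_len_bp:
                continue
            if (length_bp / 1000.0) / n > params.min_density_kb_per_snp:
                continue
            segments.append(
                ROHSegment(
                    sample_id=sample_id,
                    chrom=chrom,
                    start_bp=start_bp,
                    end_bp=end_bp,
                    n_snps=n,
                    breed=breed,
                )
            )
    return segments


def call_roh_for_sample(
    dataset: GenotypeDataset, sample_id: str, params: ROHParams | None = None
) -> list[ROHSegment]:
    """Call ROH segments for one individual across all chromosomes."""
    params = params or ROHParams()
    i = dataset.sample_index(sample_id)
    breed = dataset.samples[i].breed
    pos = dataset.positions
    segments: list[ROHSegment] = []
    for chrom, sl in dataset.chrom_slices().items():
        calls = dataset.calls[i, sl]
        flags = window_pass_flags(calls, params)
        qual = snp_in_run_flags(flags, params, n_snps=calls.size)
        segments.extend(
            _segments_from_qualifying(qual, pos[sl], chrom, sample_id, breed, params)
        )
    return segments


def detect_roh(dataset: GenotypeDataset, params: ROHParams | None = None) -> ROHSet:
    """Call ROH segments for every individual in the cohort."""
    params = params or ROHParams()
    segments: list[ROHSegment] = []
    for s in dataset.samples:
        segments.extend(call_roh_for_sample(dataset, s.sample_id, params))
    return ROHSet(segments=segments, samples=list(dataset.samples))


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------


def _se(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        return float("nan")
    return float(np.std(x, ddof=1) / math.sqrt(x.size))


def classify_lengths_mb(
    lengths_mb: np.ndarray, class_edges_mb: Sequence[float] = DEFAULT_CLASS_EDGES_MB
) -> np.ndarray:
    """Half-open class index per segment length: [e0,e1), ..., [e_last, inf)."""
    edges = np.asarray(class_edges_mb, dtype=float)
    lengths_mb = np.asarray(lengths_mb, dtype=float)
    if lengths_mb.size and lengths_mb.min() < edges[0]:
        raise ValueError(
            f"segment of {lengths_mb.min():.3f} Mb lies below the first class edge "
            f"{edges[0]} Mb"
        )
    return np.searchsorted(edges, lengths_mb, side="right") - 1


def class_labels_for_edges(class_edges_mb: Sequence[float]) -> tuple[str, ...]:
    edges = list(class_edges_mb)
    labels = [f"{_fmt(a)}-{_fmt(b)}" for a, b in zip(edges, edges[1:])]
    labels.append(f">{_fmt(edges[-1])}")
    return tuple(labels)


def _fmt(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else str(x)


@dataclass
class LengthClassTable:
    """Per-breed length-class counts and descriptive statistics."""

    class_labels: tuple[str, ...]
    class_counts: pd.DataFrame  # breeds x classes
    per_breed: pd.DataFrame     # descriptive stats per breed
    summary: ClassCountSummary  # totals + group shares

    def write_tsvs(self, out_dir: str | Path) -> list[Path]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = []
        for name, frame in [
            ("class_counts", self.class_counts),
            ("per_breed_stats", self.per_breed),
            ("group_class_counts", self.summary.group_class_counts),
            ("group_class_share_pct", self.summary.group_class_share_pct),
        ]:
            p = out_dir / f"{name}.tsv"
            frame.to_csv(p, sep="\t")
            paths.append(p)
        return paths


def length_class_table(
    rohset: ROHSet, class_edges_mb: Sequence[float] = DEFAULT_CLASS_EDGES_MB
) -> LengthClassTable:
    """Per-breed counts per length class plus mean +/- SE of the per-individual
    ROH number and of segment length, with group totals and shares."""
    labels = class_labels_for_edges(class_edges_mb)
    breeds = sorted({s.breed for s in rohset.samples})
    frame = rohset.to_frame()
    if len(frame):
        frame["class"] = [labels[k] for k in classify_lengths_mb(frame["length_mb"].to_numpy(), class_edges_mb)]

    counts = pd.DataFrame(0, index=pd.Index(breeds, name="breed"), columns=list(labels))
    if len(frame):
        tab = frame.groupby(["breed", "class"]).size().unstack(fill_value=0)
        counts = counts.add(tab.reindex(columns=list(labels), fill_value=0), fill_value=0).astype(int)

    rows = []
    by_sample = rohset.by_sample()
    for breed in breeds:
        members = [s.sample_id for s in rohset.samples if s.breed == breed]
        n_per_ind = np.array([len(by_sample[m]) for m in members], dtype=float)
        lengths = np.array(
            [seg.length_mb for m in members for seg in by_sample[m]], dtype=float
        )
        rows.append(
            {
                "breed": breed,
                "n_individuals": len(members),
                "n_roh": int(n_per_ind.sum()),
                "mean_length_mb": float(lengths.mean()) if lengths.size else float("nan"),
                "se_length_mb": _se(lengths),
                "min_length_mb": float(lengths.min()) if lengths.size else float("nan"),
                "max_length_mb": float(lengths.max()) if lengths.size else float("nan"),
                "mean_number": float(n_per_ind.mean()) if n_per_ind.size else float("nan"),
                "se_number": _se(n_per_ind),
                "min_number": int(n_per_ind.min()) if n_per_ind.size else 0,
                "max_number": int(n_per_ind.max()) if n_per_ind.size else 0,
            }
        )
    per_breed = pd.DataFrame(rows).set_index("breed")
    summary = aggregate_class_counts(counts, rohset.group_of_breed)
    return LengthClassTable(
        class_labels=labels, class_counts=counts, per_breed=per_breed, summary=summary
    )


def chromosome_coverage(rohset: ROHSet, dataset: GenotypeDataset) -> pd.DataFrame:
    """Mean fraction of each chromosome's SNP span covered by ROHs, per breed.

    Chromosomes with fewer than two SNPs have no usable span and are NaN.
    """
    spans = dataset.chrom_spans()
    slices = dataset.chrom_slices()
    chroms = sorted(spans)
    breeds = sorted({s.breed for s in rohset.samples})
    by_sample = rohset.by_sample()
    out = pd.DataFrame(index=pd.Index(breeds, name="breed"), columns=chroms, dtype=float)
    for breed in breeds:
        members = [s.sample_id for s in rohset.samples if s.breed == breed]
        for chrom in chroms:
            first, last = spans[chrom]
            n_snps = slices[chrom].stop - slices[chrom].start
            if n_snps < 2:
                out.loc[breed, chrom] = float("nan")
                continue
            span = last - first + 1
            fracs = []
            for m in members:
                covered = sum(
                    seg.length_bp for seg in by_sample[m] if seg.chrom == chrom
                )
                fracs.append(covered / span)
            out.loc[breed, chrom] = float(np.mean(fracs)) if fracs else float("nan")
    return out


# ---------------------------------------------------------------------------
# TSV round trip for pipeline stages
# ---------------------------------------------------------------------------

_SEGMENT_COLUMNS = ["sample_id", "breed", "chrom", "start_bp", "end_bp", "n_snps", "length_mb"]


def write_segments_tsv(rohset: ROHSet, path: str | Path) -> Path:
    path = Path(path)
    frame = rohset.to_frame()[_SEGMENT_COLUMNS]
    frame.to_csv(path, sep="\t", index=False, float_format="%.6f")
    return path


def read_segments_tsv(path: str | Path, samples: Sequence[SampleRecord]) -> ROHSet:
    frame = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "breed": str})
    segments = [
        ROHSegment(
            sample_id=row.sample_id,
            chrom=int(row.chrom),
            start_bp=int(row.start_bp),
            end_bp=int(row.end_bp),
            n_snps=int(row.n_snps),
            breed=row.breed,
        )
        for row in frame.itertuples(index=False)
    ]
    return ROHSet(segments=segments, samples=list(samples))
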