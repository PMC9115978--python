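"""Synthetic SNP-array cohorts with exactly known autozygosity ground truth.

Background genotypes are drawn per SNP from Hardy-Weinberg proportions at
(optionally group-shifted) frequencies.  Autozygosity is planted directly:
each planted tract is a run of homozygous calls whose first and last SNPs
are heterozygous and which is flanked by two heterozygous guard SNPs on
each side.  Under the default scanner parameters (window of 50 SNPs, one
heterozygote allowed per window, per-SNP qualifying threshold 0.01) this
construction pins the called segment to exactly the planted SNP range:

* every SNP of the tract sits in at least one window with a single
  heterozygote, so it qualifies;
* any SNP outside the tract sits only in windows containing at least two
  of the guard/boundary heterozygotes, so it never qualifies.

Tracts shorter than ``window + 1`` SNPs admit no single-het window and are
deliberately left uncallable (they stay in the truth table).

Island loci are shared tracts planted over a fixed interval in a
deterministic carrier subset (the first ``floor(fraction * n)`` individuals
of the breed by index).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genotype_io import (
    MISSING,
    GenotypeDataset,
    SampleRecord,
    VariantRecord,
    write_plink_binary,
)
from .inbreeding import autosome_length
from .roh import DEFAULT_CLASS_EDGES_MB, ROHSet, class_labels_for_edges

logger = logging.getLogger(__name__)

#: index margin kept free around every planted tract (guards + one window)
_TRACT_MARGIN_SNPS = 54


@dataclass(frozen=True)
class IslandSpec:
    """A breed-level island locus: interval plus per-breed carrier fraction."""

    chrom: int
    start_bp: int
    end_bp: int
    carrier_frac: float
    breeds: tuple[str, ...] | None = None  # None -> every breed

    def __post_init__(self) -> None:
        if not 0.0 <= self.carrier_frac <= 1.0:
            raise ValueError("carrier_frac must be in [0, 1]")
        if self.start_bp > self.end_bp:
            raise ValueError("island start_bp must be <= end_bp")


@dataclass(frozen=True)
class SimConfig:
    seed: int = 0
    n_breeds: int = 10
    individuals_per_breed: int = 30
    n_chromosomes: int = 18
    snps_per_chromosome: int = 500
    mean_spacing_kb: float = 16.0
    spacing_jitter: float = 0.5
    maf_low: float = 0.05
    maf_high: float = 0.5
    breed_f: tuple[float, ...] | float = 0.15
    f_jitter: float = 0.5
    class_weights: tuple[float, ...] = (0.7, 0.3, 0.0, 0.0, 0.0)
    class_edges_mb: tuple[float, ...] = DEFAULT_CLASS_EDGES_MB
    islands: tuple[IslandSpec, ...] = ()
    het_error_rate: float = 0.0
    missing_rate: float = 0.01
    group_divergence: float = 0.0
    group_names: tuple[str, str] = ("AHIP", "WECP")

    def __post_init__(self) -> None:
        for name in ("het_error_rate", "missing_rate", "f_jitter", "spacing_jitter"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 < self.maf_low <= self.maf_high < 1.0:
            raise ValueError("need 0 < maf_low <= maf_high < 1")
        if self.mean_spacing_kb <= 0:
            raise ValueError("mean_spacing_kb must be positive")
        if len(self.class_weights) != len(self.class_edges_mb):
            raise ValueError("class_weights must match class_edges_mb in length")
        if any(w < 0 for w in self.class_weights) or sum(self.class_weights) <= 0:
            raise ValueError("class_weights must be non-negative and sum > 0")
        if isinstance(self.breed_f, (tuple, list)):
            if len(self.breed_f) != self.n_breeds:
                raise ValueError("breed_f sequence must have n_breeds entries")

    # -- cohort layout ----------------------------------------------------

    @property
    def breed_names(self) -> list[str]:
        return [f"BR{i + 1:02d}" for i in range(self.n_breeds)]

    @property
    def breed_groups(self) -> dict[str, str]:
        names = self.breed_names
        half = (self.n_breeds + 1) // 2
        return {
            b: (self.group_names[0] if i < half else self.group_names[1])
            for i, b in enumerate(names)
        }

    def breed_f_of(self, breed_index: int) -> float:
        if isinstance(self.breed_f, (tuple, list)):
            return float(self.breed_f[breed_index])
        return float(self.breed_f)


@dataclass
class SimTruth:
    """Exact ground truth for one simulated cohort."""

    tracts: pd.DataFrame        # sample_id, breed, chrom, start/end_bp, ...
    f_star: pd.Series           # per-sample planted autozygous fraction
    islands: list[tuple[IslandSpec, list[str]]]
    allele_freqs: pd.DataFrame  # per-SNP generating frequency per group
    l_auto: int


class InfeasibleClassError(ValueError):
    """Requested tract length classes exceed what the map can host."""


def _class_ranges(config: SimConfig) -> list[tuple[float, float]]:
    edges = list(config.class_edges_mb)
    out = [(a, b) for a, b in zip(edges, edges[1:])]
    out.append((edges[-1], edges[-1] * 2.0))  # open class capped at 2x its edge
    return out


def _check_class_feasibility(config: SimConfig, chrom_span_bp: float) -> None:
    labels = class_labels_for_edges(config.class_edges_mb)
    infeasible = [
        labels[k]
        for k, (lo, _hi) in enumerate(_class_ranges(config))
        if config.class_weights[k] > 0 and lo * 1e6 >= 0.9 * chrom_span_bp
    ]
    if infeasible:
        raise InfeasibleClassError(
            f"tract classes {infeasible} (Mb) do not fit on chromosomes spanning "
            f"~{chrom_span_bp / 1e6:.1f} Mb; reduce their weights or enlarge the map"
        )


def simulate_cohort(config: SimConfig) -> tuple[GenotypeDataset, SimTruth]:
    """Generate a cohort and its exact truth tables, reproducibly from the seed."""
    rng = np.random.default_rng(config.seed)
    n_chrom = config.n_chromosomes
    n_per_chrom = config.snps_per_chromosome
    n_s = n_chrom * n_per_chrom

    # --- SNP map ---------------------------------------------------------
    chroms = np.repeat(np.arange(1, n_chrom + 1), n_per_chrom)
    positions = np.empty(n_s, dtype=np.int64)
    spacing_bp = config.mean_spacing_kb * 1000.0
    for c in range(n_chrom):
        gaps = spacing_bp * (
            1.0 + config.spacing_jitter * rng.uniform(-1.0, 1.0, n_per_chrom - 1)
        )
        pos = 100_000 + np.concatenate([[0.0], np.cumsum(gaps)])
        positions[c * n_per_chrom : (c + 1) * n_per_chrom] = np.round(pos).astype(np.int64)
    chrom_span = float(positions[n_per_chrom - 1] - positions[0])
    any_planting = any(
        config.breed_f_of(b) > 0 for b in range(config.n_breeds)
    )
    if any_planting:
        _check_class_feasibility(config, chrom_span)

    variants = [
        VariantRecord(
            id=f"snp_{chroms[j]}_{j % n_per_chrom + 1:05d}",
            chrom=int(chroms[j]),
            pos_bp=int(positions[j]),
            allele_a="A",
            allele_b="G",
        )
        for j in range(n_s)
    ]

    # --- allele frequencies ---------------------------------------------
    base_p = rng.uniform(config.maf_low, config.maf_high, n_s)
    shift_sign = rng.choice([-1.0, 1.0], size=n_s)
    d = config.group_divergence / 2.0
    p_by_group = {
        config.group_names[0]: np.clip(base_p + shift_sign * d, 0.01, 0.99),
        config.group_names[1]: np.clip(base_p - shift_sign * d, 0.01, 0.99),
    }

    # --- samples and background genotypes --------------------------------
    breeds = config.breed_names
    groups = config.breed_groups
    samples: list[SampleRecord] = []
    calls = np.empty((config.n_breeds * config.individuals_per_breed, n_s), dtype=np.int8)
    for bi, breed in enumerate(breeds):
        p = p_by_group[groups[breed]]
        lo = bi * config.individuals_per_breed
        hi = lo + config.individuals_per_breed
        calls[lo:hi] = rng.binomial(2, p, size=(config.individuals_per_breed, n_s)).astype(np.int8)
        samples.extend(
            SampleRecord(
                sample_id=f"{breed}_{i + 1:03d}", breed=breed, group=groups[breed]
            )
            for i in range(config.individuals_per_breed)
        )
    sample_ids = [s.sample_id for s in samples]

    chrom_offsets = {c + 1: c * n_per_chrom for c in range(n_chrom)}
    l_auto = int(
        sum(
            positions[off + n_per_chrom - 1] - positions[off] + 1
            for off in chrom_offsets.values()
        )
    )

    # occupancy bookkeeping: per sample -> per chrom -> list of (lo, hi) SNP
    # index ranges already used (expanded by the margin); island zones are
    # globally reserved so random tracts never contaminate island incidence.
    occupied: dict[str, dict[int, list[tuple[int, int]]]] = {
        sid: {} for sid in sample_ids
    }
    global_zones: dict[int, list[tuple[int, int]]] = {}

    tract_rows: list[dict[str, object]] = []
    planted_bp = {sid: 0 for sid in sample_ids}
    labels = class_labels_for_edges(config.class_edges_mb)

    def plant(sample_idx: int, chrom: int, i0: int, i1: int, kind: str, label: str) -> None:
        """Write a homozygous tract with het endpoints and het double guards."""
        off = chrom_offsets[chrom]
        j0, j1 = off + i0, off + i1
        p = p_by_group[groups[samples[sample_idx].breed]]
        interior = slice(j0 + 1, j1)
        hap = rng.random(j1 - j0 - 1) < p[interior]
        calls[sample_idx, interior] = np.where(hap, 2, 0).astype(np.int8)
        if config.het_error_rate > 0:
            flips = rng.random(j1 - j0 - 1) < config.het_error_rate
            calls[sample_idx, interior][flips] = 1
        calls[sample_idx, j0] = 1
        calls[sample_idx, j1] = 1
        calls[sample_idx, [j0 - 2, j0 - 1, j1 + 1, j1 + 2]] = 1
        sid = sample_ids[sample_idx]
        start_bp = int(positions[j0])
        end_bp = int(positions[j1])
        length_bp = end_bp - start_bp + 1
        tract_rows.append(
            {
                "sample_id": sid,
                "breed": samples[sample_idx].breed,
                "chrom": chrom,
                "start_bp": start_bp,
                "end_bp": end_bp,
                "n_snps": i1 - i0 + 1,
                "length_bp": length_bp,
                "length_class": label,
                "kind": kind,
            }
        )
        planted_bp[sid] += length_bp
        occupied[sid].setdefault(chrom, []).append(
            (i0 - _TRACT_MARGIN_SNPS, i1 + _TRACT_MARGIN_SNPS)
        )

    def is_free(sid: str, chrom: int, i0: int, i1: int) -> bool:
        for zlo, zhi in global_zones.get(chrom, []):
            if i0 <= zhi and i1 >= zlo:
                return False
        for zlo, zhi in occupied[sid].get(chrom, []):
            if i0 <= zhi and i1 >= zlo:
                return False
        return True

    # --- islands (planted first; their zones are reserved globally) ------
    islands_truth: list[tuple[IslandSpec, list[str]]] = []
    for spec in config.islands:
        if spec.chrom not in chrom_offsets:
            raise ValueError(f"island on unknown chromosome {spec.chrom}")
        off = chrom_offsets[spec.chrom]
        cpos = positions[off : off + n_per_chrom]
        i0 = int(np.searchsorted(cpos, spec.start_bp, side="left"))
        i1 = int(np.searchsorted(cpos, spec.end_bp, side="right")) - 1
        if i1 - i0 + 1 < 3:
            raise ValueError(f"island {spec} covers fewer than 3 SNPs")
        if i0 < 2 or i1 > n_per_chrom - 3:
            raise ValueError(f"island {spec} leaves no room for flank guards")
        target_breeds = spec.breeds if spec.breeds is not None else tuple(breeds)
        carriers: list[str] = []
        length_mb = (positions[off + i1] - positions[off + i0] + 1) / 1e6
        label_idx = max(
            0, int(np.searchsorted(config.class_edges_mb, length_mb, side="right")) - 1
        )
        for breed in target_breeds:
            bi = breeds.index(breed)
            n_carriers = math.floor(spec.carrier_frac * config.individuals_per_breed)
            for i in range(n_carriers):
                sample_idx = bi * config.individuals_per_breed + i
                plant(sample_idx, spec.chrom, i0, i1, "island", labels[label_idx])
                carriers.append(sample_ids[sample_idx])
        global_zones.setdefault(spec.chrom, []).append(
            (i0 - _TRACT_MARGIN_SNPS, i1 + _TRACT_MARGIN_SNPS)
        )
        islands_truth.append((spec, carriers))

    # --- random autozygous tracts ----------------------------------------
    weights = np.asarray(config.class_weights, dtype=float)
    weights = weights / weights.sum()
    ranges = _class_ranges(config)
    for bi, breed in enumerate(breeds):
        f_breed = config.breed_f_of(bi)
        for i in range(config.individuals_per_breed):
            sample_idx = bi * config.individuals_per_breed + i
            sid = sample_ids[sample_idx]
            f_target = f_breed * (1.0 + config.f_jitter * rng.uniform(-1.0, 1.0))
            target_bp = f_target * l_auto
            attempts = 0
            while planted_bp[sid] < target_bp and attempts < 200:
                attempts += 1
                k = int(rng.choice(len(weights), p=weights))
                lo_mb, hi_mb = ranges[k]
                length_bp = rng.uniform(lo_mb, min(hi_mb, 0.9 * chrom_span / 1e6)) * 1e6
                chrom = int(rng.integers(1, n_chrom + 1))
                off = chrom_offsets[chrom]
                cpos = positions[off : off + n_per_chrom]
                # random left endpoint with room for guards on both sides
                max_i0 = int(np.searchsorted(cpos, cpos[-1] - length_bp)) - 1
                if max_i0 < 2:
                    continue
                i0 = int(rng.integers(2, max_i0 + 1))
                i1 = int(np.searchsorted(cpos, cpos[i0] + length_bp - 1, side="right")) - 1
                if i1 > n_per_chrom - 3 or i1 - i0 + 1 < 3:
                    continue
                if not is_free(sid, chrom, i0, i1):
                    continue
                plant(sample_idx, chrom, i0, i1, "random", labels[k])

    # --- missingness ------------------------------------------------------
    if config.missing_rate > 0:
        mask = rng.random(calls.shape) < config.missing_rate
        calls[mask] = MISSING

    tracts = pd.DataFrame(
        tract_rows,
        columns=[
            "sample_id",
            "breed",
            "chrom",
            "start_bp",
            "end_bp",
            "n_snps",
            "length_bp",
            "length_class",
            "kind",
        ],
    )
    f_star = pd.Series(
        {sid: planted_bp[sid] / l_auto for sid in sample_ids}, name="f_star"
    )
    freqs = pd.DataFrame(p_by_group)
    freqs.insert(0, "snp_id", [v.id for v in variants])
    dataset = GenotypeDataset(samples, variants, calls)
    truth = SimTruth(
        tracts=tracts,
        f_star=f_star,
        islands=islands_truth,
        allele_freqs=freqs,
        l_auto=l_auto,
    )
    return dataset, truth


# ---------------------------------------------------------------------------
# file emission
# ---------------------------------------------------------------------------


def write_cohort(
    dataset: GenotypeDataset, truth: SimTruth, out_dir: str | Path, prefix: str = "cohort"
) -> dict[str, Path]:
    """Emit BED/BIM/FAM, the breed -> group map and the truth tables."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    bed, bim, fam = write_plink_binary(dataset, out_dir / prefix)

    breed_map_path = out_dir / "breeds.tsv"
    pairs = sorted({(s.breed, s.group) for s in dataset.samples})
    with open(breed_map_path, "w") as fh:
        for breed, group in pairs:
            fh.write(f"{breed}\t{group}\n")

    tracts_path = out_dir / "truth_tracts.tsv"
    truth.tracts.to_csv(tracts_path, sep="\t", index=False)
    f_path = out_dir / "truth_f.tsv"
    truth.f_star.rename_axis("sample_id").to_csv(f_path, sep="\t")
    islands_path = out_dir / "truth_islands.tsv"
    rows = [
        {
            "chrom": spec.chrom,
            "start_bp": spec.start_bp,
            "end_bp": spec.end_bp,
            "carrier_frac": spec.carrier_frac,
            "carriers": ",".join(carriers),
        }
        for spec, carriers in truth.islands
    ]
    pd.DataFrame(rows, columns=["chrom", "start_bp", "end_bp", "carrier_frac", "carriers"]).to_csv(
        islands_path, sep="\t", index=False
    )
    freqs_path = out_dir / "truth_freqs.tsv"
    truth.allele_freqs.to_csv(freqs_path, sep="\t", index=False)
    return {
        "bed": bed,
        "bim": bim,
        "fam": fam,
        "breed_map": breed_map_path,
        "truth_tracts": tracts_path,
        "truth_f": f_path,
        "truth_islands": islands_path,
        "truth_freqs": freqs_path,
    }


# ---------------------------------------------------------------------------
# truth comparison
# ---------------------------------------------------------------------------


@dataclass
class TruthComparison:
    sensitivity: float
    precision: float
    boundary_error_snps: float
    f_roh_bias: float
    f_roh_corr: float
    n_eligible_tracts: int
    n_called_segments: int


def _reciprocal_overlap(a0: int, a1: int, b0: int, b1: int, frac: float = 0.8) -> bool:
    ov = min(a1, b1) - max(a0, b0) + 1
    if ov < 1:
        return False
    return ov >= frac * (a1 - a0 + 1) and ov >= frac * (b1 - b0 + 1)


def truth_compare(
    rohset: ROHSet,
    truth: SimTruth,
    dataset: GenotypeDataset,
    tolerance_snps: int = 1,
    min_snps: int = 50,
    min_length_bp: int = 1_000_000,
) -> TruthComparison:
    """Score a called ROH set against the planted truth.

    A tract counts as recovered when some called segment of the same sample
    and chromosome overlaps it reciprocally by at least 80%.  Sensitivity is
    measured over "eligible" tracts (at least ``min_snps`` SNPs and
    ``min_length_bp`` long); precision over all called segments.  Boundary
    error is the mean SNP-index offset of the recovered tracts' endpoints.
    """
    truth_samples = set(truth.f_star.index)
    called_samples = {s.sample_id for s in rohset.samples}
    if not truth_samples <= called_samples:
        raise ValueError("truth and ROH set refer to different cohorts")

    slices = dataset.chrom_slices()
    pos = dataset.positions

    def snp_index(chrom: int, bp: int) -> int:
        sl = slices[chrom]
        return int(np.searchsorted(pos[sl.start : sl.stop], bp, side="left"))

    by_key: dict[tuple[str, int], list] = {}
    for seg in rohset.segments:
        by_key.setdefault((seg.sample_id, seg.chrom), []).append(seg)

    eligible = 0
    recovered = 0
    boundary_errors: list[float] = []
    matched_segments: set[int] = set()
    for row in truth.tracts.itertuples(index=False):
        is_eligible = row.n_snps >= min_snps and row.length_bp >= min_length_bp
        if is_eligible:
            eligible += 1
        for seg in by_key.get((row.sample_id, row.chrom), []):
            if _reciprocal_overlap(row.start_bp, row.end_bp, seg.start_bp, seg.end_bp):
                matched_segments.add(id(seg))
                if is_eligible:
                    recovered += 1
                    err = (
                        abs(snp_index(row.chrom, seg.start_bp) - snp_index(row.chrom, row.start_bp))
                        + abs(snp_index(row.chrom, seg.end_bp) - snp_index(row.chrom, row.end_bp))
                    ) / 2.0
                    boundary_errors.append(err)
                break

    n_called = len(rohset.segments)
    n_matched_called = sum(1 for seg in rohset.segments if id(seg) in matched_segments)

    l_auto = autosome_length(dataset)
    by_sample = rohset.by_sample()
    f_roh_vals = []
    f_star_vals = []
    for sid in truth.f_star.index:
        covered = sum(seg.length_bp for seg in by_sample.get(sid, []))
        f_roh_vals.append(covered / l_auto)
        f_star_vals.append(float(truth.f_star[sid]))
    f_roh_arr = np.asarray(f_roh_vals)
    f_star_arr = np.asarray(f_star_vals)
    if f_star_arr.std() > 0 and f_roh_arr.std() > 0:
        corr = float(np.corrcoef(f_roh_arr, f_star_arr)[0, 1])
    else:
        corr = float("nan")

    return TruthComparison(
        sensitivity=recovered / eligible if eligible else float("nan"),
        precision=n_matched_called / n_called if n_called else float("nan"),
        boundary_error_snps=float(np.mean(boundary_errors)) if boundary_errors else float("nan"),
        f_roh_bias=float(np.mean(f_roh_arr - f_star_arr)),
        f_roh_corr=corr,
        n_eligible_tracts=eligible,
        n_called_segments=n_called,
    )
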