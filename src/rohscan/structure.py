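"""Genomic relationship matrix and principal component analysis.

The GRM follows the per-SNP variance-standardised estimator
``A_jk = (1/N_jk) * sum_i (x_ij - 2 p_i) (x_ik - 2 p_i) / (2 p_i (1 - p_i))``
with SNPs missing in either member of a pair excluded pairwise (``N_jk`` is
the per-pair count of usable SNPs).  Monomorphic or undefined-frequency
SNPs are excluded globally.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeDataset, allele_stats

logger = logging.getLogger(__name__)


@dataclass
class GRM:
    values: np.ndarray       # n_i x n_i symmetric
    n_snps_used: np.ndarray  # per-pair usable SNP count
    sample_ids: list[str]

    @property
    def n_i(self) -> int:
        return len(self.sample_ids)


def build_grm(dataset: GenotypeDataset) -> GRM:
    """Variance-standardised genomic relationship matrix."""
    stats = allele_stats(dataset)
    p = stats.p
    with np.errstate(invalid="ignore"):
        usable = (~stats.frame["undefined"].to_numpy()) & (p > 0.0) & (p < 1.0)
    n_excluded = int((~usable).sum())
    if n_excluded:
        logger.info("GRM: excluded %d monomorphic/undefined SNPs", n_excluded)
    if not usable.any():
        raise ValueError("no usable SNPs for GRM (all monomorphic or undefined)")

    calls = dataset.calls[:, usable].astype(float)
    p = p[usable]
    mask = dataset.calls[:, usable] != MISSING
    z = (calls - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))
    z[~mask] = 0.0
    numer = z @ z.T
    counts = mask.astype(np.int64) @ mask.astype(np.int64).T
    if (counts == 0).any():
        raise ValueError("sample pair with zero jointly genotyped SNPs")
    values = numer / counts
    return GRM(values=values, n_snps_used=counts, sample_ids=dataset.sample_ids)


def pca(grm: GRM, k: int = 3) -> tuple[np.ndarray, np.ndarray]:
    """Top-k eigenpairs of the GRM.

    Returns ``(eigenvalues, scores)`` with eigenvalues non-increasing and
    scores the eigenvectors scaled by the square root of their (clipped at
    zero) eigenvalues.  The sign of each component is fixed so that its
    largest-magnitude loading is positive.
    """
    if not np.isfinite(grm.values).all():
        raise ValueError("GRM contains non-finite entries")
    if k >= grm.n_i:
        raise ValueError(f"k={k} must be < n_i={grm.n_i}")
    sym = (grm.values + grm.values.T) / 2.0
    evals, evecs = np.linalg.eigh(sym)
    order = np.argsort(evals)[::-1][:k]
    evals = evals[order]
    evecs = evecs[:, order]
    for j in range(k):
        i_max = int(np.argmax(np.abs(evecs[:, j])))
        if evecs[i_max, j] < 0:
            evecs[:, j] = -evecs[:, j]
    scores = evecs * np.sqrt(np.clip(evals, 0.0, None))
    return evals, scores


def write_grm_text(grm: GRM, prefix: str | Path) -> tuple[Path, Path]:
    """GCTA-style plain-text triplets (1-based lower triangle) plus id list."""
    prefix = Path(prefix)
    grm_path = prefix.with_suffix(".grm.txt")
    id_path = prefix.with_suffix(".grm.id")
    with open(grm_path, "w") as fh:
        for j in range(grm.n_i):
            for k in range(j + 1):
                fh.write(
                    f"{j + 1}\t{k + 1}\t{int(grm.n_snps_used[j, k])}\t"
                    f"{grm.values[j, k]:.10g}\n"
                )
    with open(id_path, "w") as fh:
        for sid in grm.sample_ids:
            fh.write(f"{sid}\t{sid}\n")
    return grm_path, id_path


def scores_frame(
    grm: GRM, scores: np.ndarray, breeds: dict[str, str] | None = None
) -> pd.DataFrame:
    frame = pd.DataFrame(
        scores, columns=[f"PC{i + 1}" for i in range(scores.shape[1])]
    )
    frame.insert(0, "sample_id", grm.sample_ids)
    if breeds is not None:
        frame.insert(1, "breed", [breeds.get(s, "unknown") for s in grm.sample_ids])
    return frame
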