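"""Genotype-matrix PCA and nearest-centroid population assignment.

Biallelic SNVs are coded as alt-allele dosages in {0, 1, 2}; columns are
mean-centered and, by default, scaled by sqrt(2 p (1-p)) with p the sample
allele frequency (the scaling PLINK/EIGENSTRAT apply), then decomposed by
SVD. The case sample is assigned to the panel population whose centroid in
the top-k score space is nearest in Euclidean distance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .variant_io import VariantSite

__all__ = [
    "GenotypeMatrix",
    "PCAResult",
    "AmbiguousAssignmentError",
    "build_genotype_matrix",
    "run_pca",
    "assign_population",
    "write_scores",
    "plot_pca",
]


class AmbiguousAssignmentError(ValueError):
    """Raised when two population centroids are equidistant from the case."""


@dataclass
class GenotypeMatrix:
    """Samples x sites alt-dosage matrix (missing entries mean-imputed)."""

    samples: List[str]
    sites: List[Tuple[str, int]]
    dosages: np.ndarray  # float array, shape (n_samples, n_sites)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.samples), len(self.sites)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} != "
                f"({len(self.samples)}, {len(self.sites)})"
            )


@dataclass
class PCAResult:
    """Top-k PCA scores and per-component variance fractions (percent)."""

    samples: List[str]
    coordinates: np.ndarray  # (n_samples, k)
    variance_explained: np.ndarray  # (k,), percent of total variance

    @property
    def k(self) -> int:
        return self.coordinates.shape[1]

    def coords_of(self, sample_id: str) -> np.ndarray:
        return self.coordinates[self.samples.index(sample_id)]


def build_genotype_matrix(
    sites: Iterable[VariantSite],
    samples: Sequence[str],
    max_missing: float = 0.1,
) -> GenotypeMatrix:
    """Assemble the dosage matrix from biallelic SNVs.

    Sites that are not biallelic SNVs are skipped; sites whose missing-call
    fraction exceeds ``max_missing`` are dropped; remaining missing entries
    are imputed to the site mean dosage.
    """
    samples = list(samples)
    index = {s: i for i, s in enumerate(samples)}
    columns: List[np.ndarray] = []
    keys: List[Tuple[str, int]] = []
    for site in sites:
        if not site.is_biallelic_snv:
            continue
        col = np.full(len(samples), np.nan)
        for gt in site.genotypes:
            if gt.allele_indices is not None:
                col[index[gt.sample_id]] = sum(
                    1 for a in gt.allele_indices if a == 1
                )
        n_missing = int(np.isnan(col).sum())
        if n_missing / len(samples) > max_missing:
            continue
        if n_missing:
            col = np.where(np.isnan(col), np.nanmean(col), col)
        columns.append(col)
        keys.append((site.chrom, site.pos))
    if not columns:
        raise ValueError("no usable biallelic SNV sites for the genotype matrix")
    return GenotypeMatrix(
        samples=samples, sites=keys, dosages=np.column_stack(columns)
    )


def run_pca(
    matrix: GenotypeMatrix, k: int = 3, standardize: bool = True
) -> PCAResult:
    """PCA of the dosage matrix.

    Columns are mean-centered; with ``standardize`` (default) they are also
    divided by sqrt(2 p (1-p)), p = mean dosage / 2 (monomorphic columns are
    left unscaled). Scores are the projections onto the top-k right singular
    vectors; variance fractions are eigenvalue shares over all nonzero
    eigenvalues. Each component's sign is fixed so its loading vector sums
    to a non-negative value. ``k`` beyond the matrix rank is truncated.
    """
    X = matrix.dosages.copy()
    n, m = X.shape
    if n < 2:
        raise ValueError("need at least 2 samples for PCA")
    mean = X.mean(axis=0)
    X -= mean
    if standardize:
        p = mean / 2.0
        scale = np.sqrt(2.0 * p * (1.0 - p))
        scale[scale == 0] = 1.0
        X /= scale
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    eigvals = s**2
    tol = max(n, m) * np.finfo(float).eps * (s[0] if s.size else 0.0)
    rank = int(np.sum(s > tol))
    if k > rank:
        import warnings

        warnings.warn(
            f"k={k} exceeds matrix rank {rank}; truncating", stacklevel=2
        )
        k = rank
    if k < 1:
        raise ValueError("matrix has rank 0; no informative sites")
    # Deterministic sign: loading vector (row of Vt) sums non-negative.
    signs = np.where(Vt[:k].sum(axis=1) < 0, -1.0, 1.0)
    scores = U[:, :k] * s[:k] * signs
    total = eigvals[eigvals > tol**2].sum() if eigvals.size else 1.0
    var_pct = 100.0 * eigvals[:k] / total
    return PCAResult(
        samples=list(matrix.samples),
        coordinates=scores,
        variance_explained=var_pct,
    )


def assign_population(
    result: PCAResult,
    labels: Dict[str, str],
    case_id: str,
    tie_tol: float = 1e-9,
) -> Tuple[str, Dict[str, float]]:
    """Nearest-centroid population assignment of the case.

    ``labels`` maps panel sample -> population (the case must be absent).
    Returns the winning population and the case-to-centroid distance for
    every population; raises :class:`AmbiguousAssignmentError` on a tie
    within ``tie_tol``.
    """
    if case_id in labels:
        raise ValueError(f"case {case_id!r} must not appear in the panel labels")
    if case_id not in result.samples:
        raise ValueError(f"case {case_id!r} has no PCA coordinates")
    populations: Dict[str, List[np.ndarray]] = {}
    for sample, pop in labels.items():
        if sample not in result.samples:
            raise ValueError(f"labeled sample {sample!r} has no PCA coordinates")
        populations.setdefault(pop, []).append(result.coords_of(sample))
    if not populations:
        raise ValueError("no labeled panel samples")
    case = result.coords_of(case_id)
    distances = {
        pop: float(np.linalg.norm(case - np.mean(coords, axis=0)))
        for pop, coords in populations.items()
    }
    ordered = sorted(distances.items(), key=lambda kv: kv[1])
    if len(ordered) > 1 and ordered[1][1] - ordered[0][1] <= tie_tol:
        raise AmbiguousAssignmentError(
            f"populations {ordered[0][0]!r} and {ordered[1][0]!r} are "
            f"equidistant from {case_id!r} ({ordered[0][1]:.3g})"
        )
    return ordered[0][0], distances


def write_scores(
    result: PCAResult, labels: Dict[str, str], path, case_id: Optional[str] = None
) -> None:
    """Export scores as TSV: sample, population, PC1..PCk."""
    rows = []
    for i, sample in enumerate(result.samples):
        pop = labels.get(sample, "case" if sample == case_id else ".")
        row = {"sample": sample, "population": pop}
        for j in range(result.k):
            row[f"PC{j + 1}"] = result.coordinates[i, j]
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.6g")


def plot_pca(
    result: PCAResult,
    labels: Dict[str, str],
    out_dir,
    case_id: Optional[str] = None,
) -> List[str]:
    """Scatter plots of PC1 x PC2 and PC2 x PC3 (when k >= 3), one point per
    sample colored by population, the case highlighted. Returns paths."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pairs = [(0, 1)]
    if result.k >= 3:
        pairs.append((1, 2))
    pops = sorted({labels.get(s) for s in result.samples if s in labels})
    cmap = plt.get_cmap("tab10")
    paths: List[str] = []
    for a, b in pairs:
        fig, ax = plt.subplots(figsize=(5, 4))
        for i, pop in enumerate(pops):
            idx = [j for j, s in enumerate(result.samples) if labels.get(s) == pop]
            ax.scatter(
                result.coordinates[idx, a],
                result.coordinates[idx, b],
                s=25,
                color=cmap(i % 10),
                label=pop,
            )
        if case_id is not None and case_id in result.samples:
            c = result.coords_of(case_id)
            ax.scatter([c[a]], [c[b]], marker="*", s=140, color="black", label=case_id)
        ax.set_xlabel(f"PC{a + 1} ({result.variance_explained[a]:.2f}% of variance)")
        ax.set_ylabel(f"PC{b + 1} ({result.variance_explained[b]:.2f}%)")
        ax.legend(fontsize=7)
        fig.tight_layout()
        path = out_dir / f"pca_pc{a + 1}_pc{b + 1}.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        paths.append(str(path))
    return paths
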