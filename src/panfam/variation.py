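"""Genotype-level sequence variation via k-mer frequency PCA.

Protein sequences are grouped by genotype, overlapping amino-acid k-mers
(k = 3 by default) are counted over each genotype's full protein complement,
rows are normalized by the genotype's total k-mer count (so partial
deletions, presence/absence and copy-number differences all move the
profile), and a PCA of the genotype x k-mer matrix places genotypes in a
low-dimensional space.  Per-genotype cos-squared values quantify how much of
each genotype's displacement each dimension explains.  A leave-family-out
rerun and a centroid-distance driver ranking localize which family carries a
between-group separation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA as _SKPCA

from .domains import AMINO_ACIDS

__all__ = [
    "KmerMatrix",
    "PCAResult",
    "kmer_counts",
    "kmer_profile",
    "pca",
    "leave_family_out",
    "rank_driver_genes",
]

_VALID = set(AMINO_ACIDS)


@dataclass
class KmerMatrix:
    """Genotype x k-mer normalized frequency matrix.

    Rows of genotypes with at least one countable k-mer sum to 1; genotypes
    contributing no sequence yield all-zero rows and are flagged.
    """

    frequencies: pd.DataFrame
    k: int
    empty_genotypes: List[str] = field(default_factory=list)

    @property
    def genotypes(self) -> List[str]:
        return list(self.frequencies.index)


def kmer_counts(sequences: Iterable[str], k: int) -> Dict[str, int]:
    """Overlapping k-mer counts; k-mers containing residues outside the 20
    standard amino acids (X, *, gaps) are skipped."""
    counts: Dict[str, int] = {}
    for seq in sequences:
        seq = seq.upper()
        for i in range(len(seq) - k + 1):
            kmer = seq[i:i + k]
            if all(c in _VALID for c in kmer):
                counts[kmer] = counts.get(kmer, 0) + 1
    return counts


def kmer_profile(proteins: pd.DataFrame, k: int = 3) -> KmerMatrix:
    """Build the normalized k-mer matrix from a frame with columns
    ``genotype``, ``family``, ``sequence``; columns are the union of observed
    k-mers across genotypes."""
    if k < 1:
        raise ValueError("k must be >= 1")
    per_genotype: Dict[str, Dict[str, int]] = {}
    for genotype, group in proteins.groupby("genotype", sort=True):
        per_genotype[genotype] = kmer_counts(group["sequence"], k)
    all_kmers = sorted(set().union(*per_genotype.values())) if per_genotype else []
    rows = []
    empty = []
    for genotype, counts in per_genotype.items():
        total = sum(counts.values())
        if total == 0:
            empty.append(genotype)
            rows.append([0.0] * len(all_kmers))
        else:
            rows.append([counts.get(km, 0) / total for km in all_kmers])
    freq = pd.DataFrame(rows, index=list(per_genotype), columns=all_kmers)
    return KmerMatrix(freq, k, empty)


@dataclass
class PCAResult:
    """Genotype coordinates with explained-variance percentages and
    cos-squared contributions.

    ``cos2[i, d] = coord[i, d]**2 / sum_d' coord[i, d']**2`` over all retained
    dimensions, so each off-centroid genotype's cos2 sums to 1; ``cos2_12``
    (the sum over dimensions 1-2, the plotted plane) is the quantity used for
    point coloring.
    """

    coordinates: pd.DataFrame          # genotypes x Dim1..DimD
    explained_variance: np.ndarray     # percentages, non-increasing
    cos2: pd.DataFrame
    cos2_12: pd.Series
    degenerate: bool = False
    excluded_family: Optional[str] = None

    def dim(self, d: int) -> pd.Series:
        return self.coordinates[f"Dim{d}"]


def pca(matrix: KmerMatrix, center: bool = True, scale: bool = False) -> PCAResult:
    """PCA of the k-mer matrix.

    Zero-variance columns are dropped before optional unit-variance scaling.
    All non-trivial dimensions are retained so the per-genotype cos2 values
    sum to 1.  When every row is identical the result is degenerate: all
    coordinates and cos2 are 0 and the flag is set.
    """
    X = matrix.frequencies.to_numpy(dtype=float)
    n, p = X.shape
    if n < 2:
        raise ValueError("need >= 2 genotypes")
    keep = X.std(axis=0) > 0
    Xk = X[:, keep]
    if scale and Xk.shape[1]:
        Xk = (Xk - Xk.mean(axis=0)) / Xk.std(axis=0)
    genotypes = matrix.genotypes
    n_comp = min(n - 1, Xk.shape[1])
    if n_comp == 0:
        dims = ["Dim1", "Dim2"]
        zero = pd.DataFrame(0.0, index=genotypes, columns=dims)
        return PCAResult(
            coordinates=zero,
            explained_variance=np.zeros(len(dims)),
            cos2=zero.copy(),
            cos2_12=pd.Series(0.0, index=genotypes),
            degenerate=True,
        )
    model = _SKPCA(n_components=n_comp)
    if not center:
        mean = Xk.mean(axis=0)
        scores = model.fit_transform(Xk)  # sklearn always centers;
        # add back the projected mean so coordinates are uncentered scores
        scores = scores + mean @ model.components_.T
    else:
        scores = model.fit_transform(Xk)
    dims = [f"Dim{d + 1}" for d in range(n_comp)]
    coords = pd.DataFrame(scores, index=genotypes, columns=dims)
    explained = model.explained_variance_ratio_ * 100.0
    sq = scores ** 2
    row_norm = sq.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cos2_values = np.where(row_norm[:, None] > 0, sq / row_norm[:, None], 0.0)
    cos2 = pd.DataFrame(cos2_values, index=genotypes, columns=dims)
    cos2_12 = cos2[dims[:2]].sum(axis=1) if len(dims) >= 2 else cos2[dims[0]]
    degenerate = bool(np.allclose(model.explained_variance_, 0))
    return PCAResult(coords, explained, cos2, cos2_12, degenerate)


def leave_family_out(
    proteins: pd.DataFrame,
    family: str,
    k: int = 3,
    center: bool = True,
    scale: bool = False,
) -> PCAResult:
    """Rebuild the k-mer matrix from all proteins except the named family's
    and rerun the PCA (the exclusion rerun used to localize a separation)."""
    if family not in set(proteins["family"]):
        kept = proteins
    else:
        kept = proteins[proteins["family"] != family]
    if kept.empty:
        raise ValueError("excluding this family removes every sequence")
    result = pca(kmer_profile(kept, k), center=center, scale=scale)
    result.excluded_family = family
    return result


def rank_driver_genes(
    proteins: pd.DataFrame,
    group_a: Sequence[str],
    group_b: Sequence[str],
    k: int = 3,
) -> pd.DataFrame:
    """Rank families by between-group k-mer divergence.

    For each family, each group's centroid k-mer profile is computed from
    that family's sequences only (per-genotype normalized, then averaged) and
    the divergence is the Euclidean distance between the two centroids.
    Families absent from an entire group are scored against the zero profile
    and flagged.  Ties break alphabetically.
    """
    set_a, set_b = set(group_a), set(group_b)
    if not set_a or not set_b:
        raise ValueError("both groups must be non-empty")
    if set_a & set_b:
        raise ValueError("groups must be disjoint")
    rows = []
    for family, fam_df in proteins.groupby("family", sort=True):
        profiles: Dict[str, Dict[str, float]] = {}
        for genotype, g_df in fam_df.groupby("genotype"):
            counts = kmer_counts(g_df["sequence"], k)
            total = sum(counts.values())
            if total:
                profiles[genotype] = {km: c / total for km, c in counts.items()}
        def centroid(members: set) -> Tuple[Dict[str, float], bool]:
            present = [profiles[g] for g in members if g in profiles]
            if not present:
                return {}, True
            keys = set().union(*present)
            return (
                {km: sum(p.get(km, 0.0) for p in present) / len(present)
                 for km in keys},
                False,
            )
        ca, missing_a = centroid(set_a)
        cb, missing_b = centroid(set_b)
        keys = set(ca) | set(cb)
        div = float(np.sqrt(sum((ca.get(km, 0.0) - cb.get(km, 0.0)) ** 2
                                for km in keys)))
        rows.append({"family": family, "divergence": div,
                     "absent_in_group": missing_a or missing_b})
    out = pd.DataFrame(rows).sort_values(
        ["divergence", "family"], ascending=[False, True]
    ).reset_index(drop=True)
    return out
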