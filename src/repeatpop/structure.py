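"""Population structure from repeat abundances vs SNP genotypes via PCA.

Abundances are min/max-scaled per cluster; genotype calls are encoded 1
(homozygous major) / 0 (homozygous minor) with heterozygous calls masked
and, by default, imputed with the column mean of unmasked entries before
PCA. Group separation in 2-D score space is quantified with the mean
silhouette coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import silhouette_score


@dataclass
class PCAResult:
    scores: pd.DataFrame  # individuals x components
    explained_variance_ratio: np.ndarray
    loadings: np.ndarray  # components x features

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]


def minmax_scale_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-column (x - min)/(max - min); constant columns become zeros."""
    if len(matrix) < 2:
        raise ValueError("need >= 2 individuals")
    data = matrix.astype(float)
    lo = data.min(axis=0)
    hi = data.max(axis=0)
    span = (hi - lo).replace(0, np.nan)
    out = (data - lo) / span
    return out.fillna(0.0)


def encode_genotypes(
    calls: pd.DataFrame, impute: bool = True, drop_masked: bool = False
) -> pd.DataFrame:
    """Encode allele-pair calls as 1 (major hom) / 0 (minor hom), masking hets.

    The major allele per marker is the more frequent allele among
    homozygous calls (ties go to the lexicographically smaller allele).
    Masked (heterozygous) entries are imputed with the column mean of
    unmasked entries by default; drop_masked=True instead drops markers
    with any masked call. More than two alleles at a marker is an error.
    """
    encoded = pd.DataFrame(index=calls.index, columns=calls.columns, dtype=float)
    for marker in calls.columns:
        col = calls[marker].astype(str)
        alleles: dict[str, int] = {}
        for call in col:
            if len(call) != 2:
                raise ValueError(f"marker {marker}: bad call {call!r}")
            for a in call:
                alleles.setdefault(a, 0)
        if len(alleles) > 2:
            raise ValueError(
                f"marker {marker} has more than two alleles: {sorted(alleles)}"
            )
        hom = col[col.str[0] == col.str[1]]
        counts: dict[str, int] = {}
        for call in hom:
            counts[call[0]] = counts.get(call[0], 0) + 2
        if counts:
            major = sorted(counts, key=lambda a: (-counts[a], a))[0]
        else:
            major = sorted(alleles)[0]
        is_hom = col.str[0] == col.str[1]
        encoded[marker] = np.where(
            ~is_hom, np.nan, np.where(col.str[0] == major, 1.0, 0.0)
        )
    if drop_masked:
        encoded = encoded.dropna(axis=1)
    elif impute:
        encoded = impute_masked(encoded)
    return encoded


def impute_masked(encoded: pd.DataFrame) -> pd.DataFrame:
    """Replace masked (NaN) entries with the column mean of unmasked entries."""
    means = encoded.mean(axis=0)
    return encoded.fillna(means.fillna(0.0))


def pca(matrix: pd.DataFrame, n_components: int = 2) -> PCAResult:
    """Column-mean-centered PCA via SVD with a fixed sign convention.

    The sign of each component is chosen so its largest-magnitude loading
    is positive, making scores reproducible run to run.
    """
    X = np.asarray(matrix, dtype=float)
    n, m = X.shape
    if n_components > min(n, m):
        raise ValueError(
            f"n_components={n_components} exceeds min(rows, cols)={min(n, m)}"
        )
    if np.isnan(X).any():
        raise ValueError("matrix contains unimputed masked entries")
    Xc = X - X.mean(axis=0, keepdims=True)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    total_var = (s**2).sum()
    ratios = (s[:n_components] ** 2) / total_var if total_var > 0 else np.zeros(n_components)
    loadings = Vt[:n_components]
    scores = U[:, :n_components] * s[:n_components]
    for comp in range(n_components):
        j = np.argmax(np.abs(loadings[comp]))
        if loadings[comp, j] < 0:
            loadings[comp] *= -1
            scores[:, comp] *= -1
    score_df = pd.DataFrame(
        scores,
        index=matrix.index,
        columns=[f"PC{i+1}" for i in range(n_components)],
    )
    return PCAResult(score_df, ratios, loadings)


def separation_score(scores: pd.DataFrame, labels: pd.Series) -> float:
    """Mean silhouette of the two populations in Euclidean score space.

    Degenerate inputs (all points identical) yield 0.0.
    """
    labels = labels.loc[scores.index]
    groups = labels.value_counts()
    if len(groups) != 2:
        raise ValueError(f"expected exactly 2 labels, got {list(groups.index)}")
    if (groups < 2).any():
        raise ValueError("each label needs >= 2 members")
    X = np.asarray(scores, dtype=float)
    if np.allclose(X, X[0]):
        return 0.0
    return float(silhouette_score(X, labels.values, metric="euclidean"))


@dataclass
class StructureContrast:
    repeat_pca: PCAResult
    snp_pca: PCAResult
    repeat_silhouette: float
    snp_silhouette: float
    labels: pd.Series


def structure_contrast(
    abundance: pd.DataFrame,
    genotype_calls: pd.DataFrame,
    labels: pd.Series,
    n_components: int = 2,
    impute: bool = True,
) -> StructureContrast:
    """Run identical PCA machinery on repeat abundances and SNP genotypes.

    Both matrices must cover the same individuals in the same order; a
    mismatch is an error listing the difference.
    """
    if list(abundance.index) != list(genotype_calls.index):
        only_a = sorted(set(abundance.index) - set(genotype_calls.index))
        only_g = sorted(set(genotype_calls.index) - set(abundance.index))
        raise ValueError(
            "individual sets differ between matrices: "
            f"abundance-only={only_a}, genotype-only={only_g} "
            "(or ordering differs)"
        )
    repeat_scaled = minmax_scale_matrix(abundance)
    snp_encoded = encode_genotypes(genotype_calls, impute=impute)
    rp = pca(repeat_scaled, n_components)
    sp = pca(snp_encoded, n_components)
    return StructureContrast(
        repeat_pca=rp,
        snp_pca=sp,
        repeat_silhouette=separation_score(rp.scores, labels),
        snp_silhouette=separation_score(sp.scores, labels),
        labels=labels.loc[abundance.index],
    )
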