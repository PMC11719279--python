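"""SmartPCA-style PCA on standardized genotype matrices via the SVD.

Each sample row g_i is centered by its own mean and scaled by its sample
standard deviation (n-1 denominator), so that C = Z Z^T / (n-1) is exactly
the m x m matrix of pairwise Pearson correlations between samples.  The
thin SVD Z = U S V^T then yields eigenvalues lambda_j = S_j^2 / (n-1) of C,
principal components P = U^T Z, and the key identity that the loadings
matrix M -- the matrix-normalized correlation between sample rows and
component rows,

    M = [cov(Z, Z^T)]^{-1/2} cov(Z, P^T) [cov(P, P^T)]^{-1/2}

-- equals U.  Because U's entries are correlations in [-1, 1], they can be
rescaled entrywise into mutual-information units downstream.

Note the per-row centering differs from the per-SNP (column) normalization
of some population-genetics pipelines; a ``center_mode='snp'`` variant is
provided for comparison, but the M = U identity and the unit-diagonal C are
guaranteed only in row mode.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "StandardizedMatrix",
    "PCADecomposition",
    "standardize",
    "correlation_matrix",
    "decompose",
    "correlation_loadings",
    "conventional_coordinates",
    "explained_variance_table",
]

#: eigenvalues below this fraction of the leading one are treated as null
NULL_EIGENVALUE_REL_TOL = 1e-12


@dataclass
class StandardizedMatrix:
    """Row-centered, row-scaled matrix Z with the dropped-row bookkeeping."""

    Z: np.ndarray
    row_means: np.ndarray
    row_sds: np.ndarray
    sample_ids: list[str]
    dropped_rows: list[str] = field(default_factory=list)
    center_mode: str = "row"

    @property
    def n_samples(self) -> int:
        return self.Z.shape[0]

    @property
    def n_loci(self) -> int:
        return self.Z.shape[1]


@dataclass
class PCADecomposition:
    """Thin SVD of Z with the derived correlation-matrix eigenstructure.

    ``U`` columns are orthonormal sample loadings, ``eigenvalues`` are
    lambda_j = S_j^2/(n-1) (descending), and ``null_components`` flags
    components with lambda below ``NULL_EIGENVALUE_REL_TOL`` times the
    leading eigenvalue, whose loadings are not meaningful correlations.
    """

    U: np.ndarray
    singular_values: np.ndarray
    Vt: np.ndarray
    eigenvalues: np.ndarray
    n_samples: int
    n_loci: int
    sample_ids: list[str]

    @property
    def rank(self) -> int:
        return self.U.shape[1]

    @property
    def null_components(self) -> np.ndarray:
        lead = self.eigenvalues[0] if self.eigenvalues.size else 0.0
        return self.eigenvalues < NULL_EIGENVALUE_REL_TOL * max(lead, 0.0)

    def components(self, Z: np.ndarray) -> np.ndarray:
        """Principal components P = U^T Z (rows are the pi_j score vectors)."""
        return self.U.T @ Z


def standardize(gm, center_mode: str = "row", *, strict: bool = False) -> StandardizedMatrix:
    """Standardize an imputed genotype matrix.

    ``row`` mode (default): subtract each sample row's mean and divide by its
    sample standard deviation (n-1 denominator), so retained rows have mean 0
    and sd 1 exactly.  ``snp`` mode standardizes columns instead.  Rows (or
    columns) with zero variance are dropped, or raise in strict mode.
    """
    from .genio import GenotypeMatrix  # avoid import cycle at module load

    if isinstance(gm, GenotypeMatrix):
        if np.any(gm.missing_mask) and not gm.imputed:
            raise ValueError("matrix has missing entries: impute_missing first")
        X = np.asarray(gm.values, dtype=float)
        sample_ids = list(gm.sample_ids)
    else:
        X = np.asarray(gm, dtype=float)
        sample_ids = [f"s{i}" for i in range(X.shape[0])]
    if center_mode not in ("row", "snp"):
        raise ValueError("center_mode must be 'row' or 'snp'")

    if center_mode == "snp":
        means = X.mean(axis=0)
        sds = X.std(axis=0, ddof=1)
        keep_cols = sds > 0
        Z = (X[:, keep_cols] - means[keep_cols]) / sds[keep_cols]
        return StandardizedMatrix(
            Z=Z,
            row_means=means,
            row_sds=sds,
            sample_ids=sample_ids,
            dropped_rows=[],
            center_mode="snp",
        )

    means = X.mean(axis=1)
    sds = X.std(axis=1, ddof=1)
    zero = sds == 0
    if np.any(zero):
        dropped = [sid for sid, z in zip(sample_ids, zero) if z]
        if strict:
            raise ValueError(f"zero-variance sample rows: {dropped}")
        warnings.warn(f"dropping zero-variance sample rows: {dropped}", UserWarning)
    else:
        dropped = []
    keep = ~zero
    Z = (X[keep] - means[keep, None]) / sds[keep, None]
    return StandardizedMatrix(
        Z=Z,
        row_means=means[keep],
        row_sds=sds[keep],
        sample_ids=[sid for sid, k in zip(sample_ids, keep) if k],
        dropped_rows=dropped,
    )


def correlation_matrix(sm: StandardizedMatrix) -> np.ndarray:
    """C = Z Z^T / (n-1): the pairwise sample correlation matrix (row mode)."""
    Z = sm.Z
    n = Z.shape[1]
    return (Z @ Z.T) / (n - 1)


def _fix_signs(U: np.ndarray, Vt: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # deterministic orientation: largest-|entry| of each U column positive
    idx = np.argmax(np.abs(U), axis=0)
    signs = np.sign(U[idx, np.arange(U.shape[1])])
    signs[signs == 0] = 1.0
    return U * signs, Vt * signs[:, None]


def decompose(sm: StandardizedMatrix, k: int | str = "full") -> PCADecomposition:
    """Thin SVD Z = U S V^T, truncated to ``k`` components.

    Eigenvalues of C are lambda_j = S_j^2/(n-1), sorted descending (numpy's
    SVD returns them so; ties keep the returned order).  A deterministic
    sign convention orients each loading column.
    """
    Z = sm.Z
    m, n = Z.shape
    rmax = min(m, n)
    if k == "full":
        k = rmax
    k = int(k)
    if not 1 <= k <= rmax:
        raise ValueError(f"k must be in [1, {rmax}], got {k}")
    U, S, Vt = np.linalg.svd(Z, full_matrices=False)
    U, S, Vt = U[:, :k], S[:k], Vt[:k]
    U, Vt = _fix_signs(U, Vt)
    return PCADecomposition(
        U=U,
        singular_values=S,
        Vt=Vt,
        eigenvalues=S * S / (n - 1),
        n_samples=m,
        n_loci=n,
        sample_ids=list(sm.sample_ids),
    )


def _inv_sqrt_psd(A: np.ndarray, rel_tol: float = 1e-12) -> np.ndarray:
    w, Q = np.linalg.eigh(A)
    lead = w.max() if w.size else 0.0
    inv = np.where(w > rel_tol * max(lead, 0.0), 1.0 / np.sqrt(np.clip(w, 1e-300, None)), 0.0)
    return (Q * inv) @ Q.T


def correlation_loadings(
    decomp: PCADecomposition, sm: StandardizedMatrix, *, tol: float = 1e-8
) -> np.ndarray:
    """Loadings M = cor(Z, P^T), computed directly and verified to equal U.

    The correlation is the matrix-normalized one used in the M = U identity:
    cov(Z,Z^T)^{-1/2} cov(Z,P^T) cov(P,P^T)^{-1/2}, with the covariances
    estimated with the n-1 denominator.  (The entrywise Pearson correlation
    of row z_i with component pi_j is sqrt(lambda_j) * U_ij instead; the
    matrix whitening is what removes the sqrt(lambda) factor.)  Entries lie
    in [-1, 1] and feed the MI rescaling.  Columns with a null eigenvalue
    have no defined correlation and are set to 0.
    """
    Z = sm.Z
    n = Z.shape[1]
    P = decomp.components(Z)
    covZZ = (Z @ Z.T) / (n - 1)
    covZP = (Z @ P.T) / (n - 1)
    covPP = (P @ P.T) / (n - 1)
    null = decomp.null_components
    d = np.diag(covPP).copy()
    d[null] = 1.0  # keep the whitening finite; zero the columns below
    M = _inv_sqrt_psd(covZZ) @ covZP @ np.diag(1.0 / np.sqrt(d))
    M[:, null] = 0.0
    U = decomp.U.copy()
    U[:, null] = 0.0
    err = float(np.max(np.abs(M - U))) if M.size else 0.0
    if err > tol:
        raise RuntimeError(
            f"internal consistency failure: max|cor(Z,P^T) - U| = {err:.3e} > {tol:g}; "
            "this signals a normalization bug"
        )
    return U


def conventional_coordinates(
    decomp: PCADecomposition, axes: tuple[int, ...] | list[int], *, scale: str = "sqrt_eigenvalue"
) -> np.ndarray:
    """Map coordinates U_ij * sqrt(lambda_j) on the requested components.

    ``axes`` are 1-based component indices.  ``scale='singular'`` gives the
    S-scaled scores U_ij * S_j = U_ij * sqrt((n-1) lambda_j) instead, which
    some pipelines report.
    """
    axes = list(axes)
    if len(set(axes)) != len(axes):
        raise ValueError("duplicate axis indices")
    for a in axes:
        if not 1 <= a <= decomp.rank:
            raise ValueError(f"axis {a} out of range 1..{decomp.rank}")
    j = np.array(axes, dtype=int) - 1
    if scale == "sqrt_eigenvalue":
        w = np.sqrt(decomp.eigenvalues[j])
    elif scale == "singular":
        w = decomp.singular_values[j]
    else:
        raise ValueError("scale must be 'sqrt_eigenvalue' or 'singular'")
    return decomp.U[:, j] * w[None, :]


def explained_variance_table(decomp: PCADecomposition) -> pd.DataFrame:
    """Eigenvalue report: component, lambda, proportion of trace, cumulative."""
    lam = decomp.eigenvalues
    total = decomp.n_samples  # trace(C) = m for a correlation matrix
    prop = lam / total
    return pd.DataFrame(
        {
            "component": np.arange(1, lam.size + 1),
            "eigenvalue": lam,
            "proportion": prop,
            "cumulative": np.cumsum(prop),
        }
    )
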