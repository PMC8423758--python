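"""Centering, covariance eigendecomposition, projections, and SVD loadings.

For a loci x subjects genotype matrix X, rows are centered (X̃ = X - X̄),
the unscaled subject covariance C = X̃ᵀX̃ is eigendecomposed CE = ΛE, and
projections P = EΛ.  Writing X̃ = UΣVᵀ gives V = E, ΣᵀΣ = Λ, per-locus SVD
loadings Γ = UΣ = X̃V, and the equivalent projection route P = X̃ᵀΓ, whose
restriction to a locus subset is the partial projection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .vcfio import GenotypeMatrix

__all__ = [
    "CenteredGenotypeMatrix",
    "EigenSystem",
    "LoadingsMatrix",
    "center_matrix",
    "eigen_decompose",
    "compute_loadings",
    "project",
    "partial_projection",
]


@dataclass
class CenteredGenotypeMatrix:
    """Row-centered genotype matrix with stored row means (for reuse on
    external or haploid data)."""

    values: np.ndarray  # (n, m) float64, rows zero-mean
    row_means: np.ndarray  # (n,)

    @property
    def n_loci(self) -> int:
        return self.values.shape[0]

    @property
    def n_subjects(self) -> int:
        return self.values.shape[1]


@dataclass
class EigenSystem:
    """Eigenvalues (non-increasing) and orthonormal eigenvectors of C = X̃ᵀX̃,
    truncated to numerical rank."""

    eigenvalues: np.ndarray  # (r,)
    eigenvectors: np.ndarray  # (m, r), sign-oriented
    rank: int


@dataclass
class LoadingsMatrix:
    """Per-locus SVD loadings Γ = X̃V = UΣ; column k has squared norm Λ_k."""

    values: np.ndarray  # (n, r)
    eigenvalues: np.ndarray  # (r,)


def center_matrix(gm: GenotypeMatrix | np.ndarray) -> CenteredGenotypeMatrix:
    """Subtract each row's mean; means are kept for projecting new data."""
    x = gm.values if isinstance(gm, GenotypeMatrix) else np.asarray(gm, dtype=np.float64)
    if x.ndim != 2 or x.shape[0] < 1 or x.shape[1] < 1:
        raise ValueError("genotype matrix must be 2-D and nonempty")
    means = x.mean(axis=1)
    return CenteredGenotypeMatrix(values=x - means[:, None], row_means=means)


def covariance(cgm: CenteredGenotypeMatrix, block: int = 100_000) -> np.ndarray:
    """Unscaled covariance C = X̃ᵀX̃ accumulated in locus blocks, so the full
    matrix need not be resident for very large n."""
    m = cgm.n_subjects
    c = np.zeros((m, m))
    for start in range(0, cgm.n_loci, block):
        chunk = cgm.values[start:start + block]
        c += chunk.T @ chunk
    return c


def _orient_signs(vectors: np.ndarray) -> np.ndarray:
    """Deterministic sign convention: make each eigenvector's largest-|entry|
    coordinate positive."""
    idx = np.argmax(np.abs(vectors), axis=0)
    signs = np.sign(vectors[idx, np.arange(vectors.shape[1])])
    signs[signs == 0] = 1.0
    return vectors * signs


def eigen_decompose(cgm: CenteredGenotypeMatrix, tol_ratio: float = 1e-9,
                    block: int = 100_000) -> EigenSystem:
    """Eigendecompose C = X̃ᵀX̃, sort by decreasing eigenvalue, truncate the
    null space (eigenvalues < tol_ratio x max), and orient signs."""
    if cgm.n_subjects < 2:
        raise ValueError("need at least two subjects")
    if not np.all(np.isfinite(cgm.values)):
        raise ValueError("non-finite entries in centered matrix")
    c = covariance(cgm, block=block)
    evals, evecs = np.linalg.eigh(c)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    top = max(evals[0], 0.0)
    tol = tol_ratio * top
    if evals.size and evals[-1] < -max(tol, 1e-8 * max(top, 1.0)):
        raise ValueError("covariance matrix is not positive semi-definite")
    r = int(np.sum(evals > tol))
    evals = np.clip(evals[:r], 0.0, None)
    return EigenSystem(eigenvalues=evals, eigenvectors=_orient_signs(evecs[:, :r]),
                       rank=r)


def compute_loadings(cgm: CenteredGenotypeMatrix, eig: EigenSystem) -> LoadingsMatrix:
    """Γ = X̃V (equals UΣ of the SVD of X̃ up to the shared sign convention)."""
    return LoadingsMatrix(values=cgm.values @ eig.eigenvectors,
                          eigenvalues=eig.eigenvalues.copy())


def project(cgm: CenteredGenotypeMatrix,
            system: EigenSystem | LoadingsMatrix,
            route: str = "eigen") -> np.ndarray:
    """Projection matrix P (subjects x PCs) via either route.

    ``route="eigen"`` evaluates P = EΛ; ``route="loadings"`` evaluates
    P = X̃ᵀΓ.  The two agree to numerical tolerance.
    """
    if route == "eigen":
        eig = system if isinstance(system, EigenSystem) else None
        if eig is None:
            raise ValueError("eigen route needs an EigenSystem")
        return eig.eigenvectors * eig.eigenvalues[None, :]
    if route == "loadings":
        gamma = system.values if isinstance(system, LoadingsMatrix) else system.eigenvectors
        if isinstance(system, EigenSystem):
            gamma = cgm.values @ system.eigenvectors
        if gamma.shape[0] != cgm.n_loci:
            raise ValueError("loadings/matrix dimension mismatch")
        return cgm.values.T @ gamma
    raise ValueError(f"unknown route {route!r}")


def partial_projection(cgm: CenteredGenotypeMatrix, loadings: LoadingsMatrix,
                       locus_subset, k: int) -> np.ndarray:
    """Projection sum restricted to a locus subset S on PC k:
    sum_{j in S} γ_jk X̃_ji.  Linear in S; empty S gives zeros."""
    s = np.asarray(locus_subset, dtype=np.intp)
    if s.size == 0:
        return np.zeros(cgm.n_subjects)
    return cgm.values[s].T @ loadings.values[s, k]
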