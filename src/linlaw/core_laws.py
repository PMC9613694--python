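"""Time-delay embedding, Gram matrices and linear-law extraction.

The *linear law* of a scalar series ``z_1..z_k`` at embedding order ``l`` is the
unit vector ``v`` minimising ``||A v||^2``, where ``A`` is the Hankel trajectory
matrix whose rows are the ``k - l + 1`` overlapping length-``l`` windows of the
series.  Minimising the quadratic form is an eigenproblem of the Gram matrix
``S = A.T @ A``: ``v`` is the eigenvector of the smallest eigenvalue, and that
eigenvalue (the *residual*) equals ``||A v||^2``.  A residual of zero means the
series exactly satisfies the length-``l`` linear recurrence with coefficients
``v``; small residuals mean the recurrence holds approximately.

The construction is deliberately the mirror image of PCA on the embedded
windows: PCA keeps directions of greatest variation, a law is the direction of
least variation — an (approximately) conserved linear relation among ``l``
consecutive samples.

Laws are invariant to amplitude scaling of the series (``S`` scales by ``a**2``,
its eigenvectors do not move), and any law with zero weight on the constant
vector's complement — e.g. a second-difference law — is additionally insensitive
to offsets and linear drift.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .exceptions import DataError, NumericalError, ParameterError

__all__ = ["LinearLaw", "embed", "gram", "extract_law", "law_of_series"]

#: relative tolerance used when checking that a Gram matrix is symmetric
_SYM_RTOL = 1e-10


@dataclass(frozen=True)
class LinearLaw:
    """A unit-norm recurrence coefficient vector and its residual eigenvalue.

    Attributes
    ----------
    coefficients:
        Unit Euclidean-norm vector of length ``l``.  Sign convention: the
        entry of largest absolute value is positive (ties broken by lowest
        index), so equal series always yield bit-identical laws.
    residual:
        Smallest eigenvalue of the source Gram matrix, clipped at zero.
        Equals ``||A v||^2`` for the embedding ``A`` the Gram matrix came from.
    """

    coefficients: np.ndarray
    residual: float

    @property
    def order(self) -> int:
        return self.coefficients.shape[0]


def _as_series(values) -> np.ndarray:
    z = np.asarray(values, dtype=float)
    if z.ndim != 1:
        raise DataError(f"series must be one-dimensional, got shape {z.shape}")
    if z.shape[0] < 2:
        raise DataError(f"series must have length >= 2, got {z.shape[0]}")
    bad = np.flatnonzero(~np.isfinite(z))
    if bad.size:
        raise DataError(f"series contains non-finite value at index {bad[0]}")
    return z


def embed(series, order: int) -> np.ndarray:
    """Order-``l`` time-delay embedding (Hankel trajectory matrix).

    Returns the ``(k - l + 1) x l`` matrix whose row ``r`` (0-based) is
    ``(z[r], z[r+1], ..., z[r+l-1])``; entries are constant along
    anti-diagonals.

    Parameters
    ----------
    series:
        One-dimensional sequence of ``k`` finite values.
    order:
        Embedding order ``l`` with ``2 <= l < k``.
    """
    z = _as_series(series)
    k = z.shape[0]
    order = int(order)
    if not 2 <= order < k:
        raise ParameterError(
            f"embedding order must lie in [2, {k - 1}] for a series of "
            f"length {k}, got {order}"
        )
    windows = np.lib.stride_tricks.sliding_window_view(z, order)
    return np.ascontiguousarray(windows, dtype=float)


def gram(A: np.ndarray) -> np.ndarray:
    """Gram matrix ``S = A.T @ A`` of an embedding, symmetrised exactly.

    ``S`` is symmetric positive semidefinite; its spectrum encodes the
    directions of most/least variation of the embedded windows.
    """
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.size == 0:
        raise DataError(f"embedding must be a nonempty 2-D matrix, got shape {A.shape}")
    S = A.T @ A
    return (S + S.T) / 2.0


def _check_gram(S: np.ndarray) -> np.ndarray:
    S = np.asarray(S, dtype=float)
    if S.ndim != 2 or S.shape[0] != S.shape[1] or S.shape[0] < 2:
        raise DataError(f"Gram matrix must be square with size >= 2, got shape {S.shape}")
    if not np.all(np.isfinite(S)):
        raise DataError("Gram matrix contains non-finite entries")
    scale = np.abs(S).max()
    if scale > 0 and np.abs(S - S.T).max() > _SYM_RTOL * scale:
        raise DataError("Gram matrix is not symmetric within tolerance")
    return (S + S.T) / 2.0


def _apply_sign_convention(v: np.ndarray) -> np.ndarray:
    # largest-|component| entry made positive; ties resolved by lowest index
    pivot = int(np.flatnonzero(np.abs(v) == np.abs(v).max())[0])
    if v[pivot] < 0:
        v = -v
    return v


def extract_law(S: np.ndarray) -> LinearLaw:
    """Extract the linear law of a Gram matrix.

    Performs a symmetric eigendecomposition and returns the eigenvector of the
    smallest eigenvalue (ascending order; for a degenerate smallest eigenspace
    the solver's first basis vector is used, which is deterministic across
    runs).  The sign convention makes the largest-magnitude coefficient
    positive.  Tiny negative eigenvalues from floating point are clipped to 0.
    """
    S = _check_gram(S)
    try:
        eigvals, eigvecs = scipy.linalg.eigh(S)
    except scipy.linalg.LinAlgError as exc:  # pragma: no cover - rare
        raise NumericalError(
            f"eigendecomposition failed (cond estimate "
            f"{np.linalg.cond(S):.3e}): {exc}"
        ) from exc
    v = _apply_sign_convention(eigvecs[:, 0].copy())
    v /= np.linalg.norm(v)
    residual = float(max(eigvals[0], 0.0))
    return LinearLaw(coefficients=v, residual=residual)


def law_of_series(series, order: int, zscore: bool = False) -> LinearLaw:
    """Linear law of a series: ``extract_law(gram(embed(series, order)))``.

    Parameters
    ----------
    series, order:
        As for :func:`embed`.
    zscore:
        Optionally standardise the series (zero mean, unit variance) before
        embedding.  Off by default: the transform is defined on raw values and
        laws are amplitude-invariant anyway.
    """
    z = _as_series(series)
    if zscore:
        sd = z.std()
        z = (z - z.mean()) / (sd if sd > 0 else 1.0)
    return extract_law(gram(embed(z, order)))
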