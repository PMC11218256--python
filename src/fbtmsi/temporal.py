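"""Temporally local covariance estimation and the TMSI index.

EEG is non-stationary on the second scale, so a plain sample covariance
mixes statistics across the whole window.  The temporally local variant
weights pairs of time points by a kernel that decays with their distance,

    C' = (1/2M) Σ_ij W_ij (z_i − z_j)(z_i − z_j)ᵀ = (1/M) Z L Zᵀ,

where W is a symmetric adjacency over time points, D the degree matrix and
L = D − W the graph Laplacian.  The two forms above are algebraically equal
for any symmetric W (the cross terms pair up), which the test suite checks
directly.  The adjacency here is Tukey's tricube kernel with locality
parameter τ (in samples): W_ij = (1 − |i−j|³/τ³)³ for |i−j| < τ, else 0.

Whitening cancels any uniform scaling of the joint covariance, so TMSI with
an all-ones adjacency collapses to plain MSI — a useful correctness check.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property

import numpy as np

from functools import lru_cache

from .msi import JointCovariance, _inv_sqrt, _sync_from_blocks, sync_index, whiten
from .reference import HarmonicReference, ReferenceBank, standardize

__all__ = [
    "TemporalKernel",
    "tricube_adjacency",
    "uniform_kernel",
    "tl_joint_covariance",
    "tmsi",
    "tmsi_profile",
]


@dataclass(eq=False)
class TemporalKernel:
    """Adjacency W, degrees D (stored as a vector) and Laplacian L = D − W."""

    adjacency: np.ndarray = field(repr=False)
    tau: float | None = None

    @property
    def n_samples(self) -> int:
        return self.adjacency.shape[0]

    @property
    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1)

    @cached_property
    def laplacian(self) -> np.ndarray:
        w = self.adjacency
        return np.diag(self.degrees) - w


def tricube_adjacency(n_samples: int, tau: float) -> TemporalKernel:
    """Tricube temporal adjacency: W_ij = (1 − |i−j|³/τ³)³ on |i−j| < τ.

    τ is measured in samples; at 250 Hz, τ = 15 spans 60 ms.  W has unit
    diagonal, is symmetric, banded with bandwidth τ, and its Laplacian is
    positive semidefinite.
    """
    if n_samples < 2:
        raise ValueError(f"n_samples must be >= 2, got {n_samples}")
    if tau <= 0:
        raise ValueError(f"tau must be positive, got {tau}")
    idx = np.arange(n_samples)
    d = np.abs(idx[:, None] - idx[None, :]) / float(tau)
    w = np.where(d < 1.0, (1.0 - d**3) ** 3, 0.0)
    return TemporalKernel(adjacency=w, tau=float(tau))


@lru_cache(maxsize=64)
def _tricube_cached(n_samples: int, tau: float) -> TemporalKernel:
    return tricube_adjacency(n_samples, tau)


def uniform_kernel(n_samples: int) -> TemporalKernel:
    """All-ones adjacency; with zero-mean rows the local covariance reduces
    to M times the ordinary one, so any index built on whitening is
    unchanged.  Used for equivalence testing."""
    if n_samples < 2:
        raise ValueError(f"n_samples must be >= 2, got {n_samples}")
    return TemporalKernel(adjacency=np.ones((n_samples, n_samples)), tau=None)


def tl_joint_covariance(
    X: np.ndarray, Y: np.ndarray, kernel: TemporalKernel
) -> JointCovariance:
    """Temporally local joint covariance: blocks Z L Zᵀ / M on the stacked
    signal, split back into the X/Y block structure."""
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    m = X.shape[1]
    if Y.shape[1] != m or kernel.n_samples != m:
        raise ValueError(
            f"sample-count mismatch: X has {m}, Y has {Y.shape[1]}, "
            f"kernel has {kernel.n_samples}"
        )
    lap = kernel.laplacian
    xl = X @ lap
    yl = Y @ lap
    return JointCovariance(
        c11=(xl @ X.T) / m,
        c12=(xl @ Y.T) / m,
        c22=(yl @ Y.T) / m,
    )


def tmsi(
    X: np.ndarray,
    Y,
    tau: float | None = None,
    kernel: TemporalKernel | None = None,
) -> float:
    """Temporally local MSI between an epoch and a reference.

    Either ``tau`` (builds a tricube kernel) or an explicit ``kernel`` must
    be given.  The pipeline is standardize → temporally local joint
    covariance → whiten → entropy index, identical to MSI except for the
    covariance estimator.
    """
    ym = Y.matrix if isinstance(Y, HarmonicReference) else np.asarray(Y, dtype=float)
    xs = standardize(X)
    ys = standardize(ym)
    if kernel is None:
        if tau is None:
            raise ValueError("provide tau or an explicit kernel")
        kernel = tricube_adjacency(xs.shape[1], tau)
    cov = tl_joint_covariance(xs, ys, kernel)
    return sync_index(whiten(cov))


def _bank_tmsi_cache(bank: ReferenceBank, kernel: TemporalKernel, key):
    """Per-reference (Ys·L, C'22^{-1/2}, R22) cached on the bank."""
    if key not in bank.cache:
        m = bank.n_samples
        lap = kernel.laplacian
        entries = []
        for ref in bank:
            ys = ref.standardized
            yl = ys @ lap
            c22 = 0.5 * ((yl @ ys.T) / m + ((yl @ ys.T) / m).T)
            q2 = _inv_sqrt(c22, "C22")
            entries.append((ys, q2, q2 @ c22 @ q2))
        bank.cache[key] = entries
    return bank.cache[key]


def tmsi_profile(
    X: np.ndarray,
    bank: ReferenceBank,
    tau: float | None = None,
    kernel: TemporalKernel | None = None,
) -> np.ndarray:
    """TMSI of one epoch against every reference in the bank.

    X·L and the epoch-side whitening are computed once per epoch; the
    reference-side blocks depend only on (bank, kernel) and are cached.
    """
    xs = standardize(X)
    m = xs.shape[1]
    if m != bank.n_samples:
        raise ValueError(
            f"epoch has {m} samples but bank references have {bank.n_samples}"
        )
    if kernel is None:
        if tau is None:
            raise ValueError("provide tau or an explicit kernel")
        kernel = _tricube_cached(m, float(tau))
        cache_key = ("tmsi", "tricube", float(tau), m)
    else:
        cache_key = ("tmsi", "custom", id(kernel), m)
    lap = kernel.laplacian
    xl = xs @ lap
    c11 = (xl @ xs.T) / m
    c11 = 0.5 * (c11 + c11.T)
    q1 = _inv_sqrt(c11, "C11")
    r11 = q1 @ c11 @ q1
    out = np.empty(len(bank))
    for i, (ys, q2, r22) in enumerate(_bank_tmsi_cache(bank, kernel, cache_key)):
        c12 = (xl @ ys.T) / m
        r12 = q1 @ c12 @ q2
        out[i] = _sync_from_blocks(r11, r12, r22)
    return out
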