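"""Multivariate synchronization index (MSI) between an EEG epoch and a
harmonic reference.

The index is one minus the normalized eigenvalue entropy of the whitened
joint correlation matrix of the two signal sets:

    C  = [[XXᵀ, XYᵀ], [YXᵀ, YYᵀ]] / M         (signals standardized)
    R  = Q C Qᵀ,  Q = blockdiag(C11^{-1/2}, C22^{-1/2})
    S  = 1 + Σ λ'_i log λ'_i / log P,  λ'_i = λ_i / tr(R),  P = N_c + 2·N_h

S = 0 when the epoch and reference are independent (R = I, maximal entropy)
and S = 1 when they are perfectly synchronized (rank-one R).  The target
frequency is the bank member attaining the maximum index.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import eigh, eigvalsh

from .reference import HarmonicReference, ReferenceBank, standardize

__all__ = [
    "JointCovariance",
    "SyncProfile",
    "DetectionResult",
    "joint_covariance",
    "whiten",
    "sync_index",
    "msi",
    "msi_profile",
    "classify",
]

# Eigenvalue floor for the inverse square roots, relative to the largest
# eigenvalue of the block.  Short windows make C11 near-singular (and a
# noiseless rank-one epoch makes it exactly singular); the floor keeps the
# whitening bounded while leaving well-conditioned blocks untouched.
EIG_FLOOR_REL = 1e-10


@dataclass(eq=False)
class JointCovariance:
    """Block joint covariance of a (standardized) epoch and reference."""

    c11: np.ndarray = field(repr=False)
    c12: np.ndarray = field(repr=False)
    c22: np.ndarray = field(repr=False)

    @property
    def c21(self) -> np.ndarray:
        return self.c12.T

    @property
    def p(self) -> int:
        return self.c11.shape[0] + self.c22.shape[0]

    @property
    def matrix(self) -> np.ndarray:
        return np.block([[self.c11, self.c12], [self.c21, self.c22]])


@dataclass(eq=False)
class SyncProfile:
    """Synchronization indices over a reference bank, plus provenance."""

    indices: np.ndarray
    frequencies: np.ndarray
    method: str
    params: dict = field(default_factory=dict)


@dataclass(eq=False)
class DetectionResult:
    """Outcome of argmax classification over a bank."""

    frequency: float
    index: int  # 0-based position in the bank
    profile: SyncProfile

    @property
    def n(self) -> int:
        """1-based candidate index, the convention used in reports."""
        return self.index + 1


def joint_covariance(X: np.ndarray, Y: np.ndarray) -> JointCovariance:
    """Joint covariance blocks C11 = XXᵀ/M, C12 = XYᵀ/M, C22 = YYᵀ/M.

    Inputs are expected to be standardized (zero-mean, unit-variance rows);
    the diagonal of C11 and C22 is then all ones.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.ndim != 2 or Y.ndim != 2:
        raise ValueError("X and Y must be 2-D (rows x samples)")
    if X.shape[1] != Y.shape[1]:
        raise ValueError(
            f"sample-count mismatch: X has {X.shape[1]} samples, Y has {Y.shape[1]}"
        )
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(Y))):
        raise ValueError("inputs contain non-finite values")
    m = X.shape[1]
    return JointCovariance(
        c11=(X @ X.T) / m,
        c12=(X @ Y.T) / m,
        c22=(Y @ Y.T) / m,
    )


def _inv_sqrt(block: np.ndarray, name: str) -> np.ndarray:
    """Symmetric inverse square root with a relative eigenvalue floor."""
    block = 0.5 * (block + block.T)
    w, v = eigh(block)
    w_max = w[-1]
    if not np.isfinite(w_max) or w_max <= 0:
        raise np.linalg.LinAlgError(
            f"covariance block {name} is not positive (max eigenvalue {w_max}); "
            "cannot whiten"
        )
    w = np.maximum(w, EIG_FLOOR_REL * w_max)
    return (v * (1.0 / np.sqrt(w))) @ v.T


def whiten(cov: JointCovariance) -> np.ndarray:
    """Whitened joint correlation matrix R = Q C Qᵀ.

    Q is block-diagonal with the inverse square roots of C11 and C22, so
    the diagonal blocks of R are identity up to the regularization floor and
    only the cross-correlation structure survives.
    """
    q1 = _inv_sqrt(cov.c11, "C11")
    q2 = _inv_sqrt(cov.c22, "C22")
    r11 = q1 @ cov.c11 @ q1
    r22 = q2 @ cov.c22 @ q2
    r12 = q1 @ cov.c12 @ q2
    r = np.block([[r11, r12], [r12.T, r22]])
    return 0.5 * (r + r.T)


def sync_index(R: np.ndarray, p: int | None = None) -> float:
    """Normalized-entropy synchronization index of a whitened matrix.

    Eigenvalues are clamped at zero (tiny negatives are float noise from the
    symmetric eigensolver), normalized by their sum, and fed through
    S = 1 + Σ λ' log λ' / log P with the convention 0·log 0 = 0.  The
    entropy term is evaluated as Σ λ'_i log λ_i − log tr(R), which is
    algebraically identical (Σ λ' = 1) but hits the two extreme cases
    exactly: R = I gives S = 0 and a rank-one R gives S = 1.
    The log base cancels in the ratio; natural log is used.
    """
    R = np.asarray(R, dtype=float)
    if R.ndim != 2 or R.shape[0] != R.shape[1]:
        raise ValueError("R must be square")
    if not np.allclose(R, R.T, atol=1e-8):
        raise ValueError("R must be symmetric")
    if p is None:
        p = R.shape[0]
    if p < 2:
        raise ValueError("need P >= 2 signals for a meaningful index")
    lam = _clean_eigenvalues(eigvalsh(0.5 * (R + R.T)))
    total = lam.sum()
    if not np.isfinite(total) or total <= 0:
        raise ValueError(f"trace of R must be positive, got {total}")
    pos = lam > 0
    lam_pos = lam[pos]
    s = float(np.sum((lam_pos / total) * np.log(lam_pos)))
    value = 1.0 + (s - np.log(total)) / np.log(p)
    return float(min(max(value, 0.0), 1.0))


def _clean_eigenvalues(lam: np.ndarray) -> np.ndarray:
    """Clamp negatives and zero out eigenvalues at the eigensolver's noise
    floor (relative machine precision), so exactly-degenerate inputs — a
    rank-one matrix in particular — are treated as such."""
    lam = np.maximum(lam, 0.0)
    top = lam[-1] if lam.size else 0.0
    if top > 0:
        lam[lam < lam.size * np.finfo(float).eps * top] = 0.0
    return lam


def _sync_from_blocks(r11: np.ndarray, r12: np.ndarray, r22: np.ndarray) -> float:
    """Entropy index from pre-whitened blocks, skipping the validation of
    :func:`sync_index` (the blocks are symmetric by construction).  Hot
    path for bank scans."""
    n1, n2 = r11.shape[0], r22.shape[0]
    p = n1 + n2
    r = np.empty((p, p))
    r[:n1, :n1] = r11
    r[:n1, n1:] = r12
    r[n1:, :n1] = r12.T
    r[n1:, n1:] = r22
    lam = _clean_eigenvalues(np.linalg.eigvalsh(r))
    total = lam.sum()
    if total <= 0:
        raise ValueError(f"trace of R must be positive, got {total}")
    pos = lam > 0
    lam_pos = lam[pos]
    s = float(np.sum((lam_pos / total) * np.log(lam_pos)))
    value = 1.0 + (s - np.log(total)) / np.log(p)
    return float(min(max(value, 0.0), 1.0))


def msi(X: np.ndarray, Y) -> float:
    """Standard MSI between a raw epoch X and a reference Y.

    Both inputs are standardized, the joint covariance assembled, whitened,
    and reduced to the entropy index.  ``Y`` may be a raw matrix or a
    :class:`HarmonicReference`.
    """
    ym = Y.matrix if isinstance(Y, HarmonicReference) else np.asarray(Y, dtype=float)
    xs = standardize(X)
    ys = standardize(ym)
    return sync_index(whiten(joint_covariance(xs, ys)))


def _bank_msi_cache(bank: ReferenceBank) -> list[tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Per-reference (Ys, C22^{-1/2}, R22) cached on the bank."""
    key = "msi"
    if key not in bank.cache:
        entries = []
        m = bank.n_samples
        for ref in bank:
            ys = ref.standardized
            c22 = (ys @ ys.T) / m
            q2 = _inv_sqrt(c22, "C22")
            entries.append((ys, q2, q2 @ c22 @ q2))
        bank.cache[key] = entries
    return bank.cache[key]


def msi_profile(X: np.ndarray, bank: ReferenceBank) -> np.ndarray:
    """MSI of one epoch against every reference in the bank.

    The epoch-side whitening block is computed once and the reference-side
    blocks are cached on the bank, so scanning 40 candidates costs little
    more than 40 small eigendecompositions.
    """
    xs = standardize(X)
    m = xs.shape[1]
    if m != bank.n_samples:
        raise ValueError(
            f"epoch has {m} samples but bank references have {bank.n_samples}"
        )
    c11 = (xs @ xs.T) / m
    q1 = _inv_sqrt(c11, "C11")
    r11 = q1 @ c11 @ q1
    out = np.empty(len(bank))
    for i, (ys, q2, r22) in enumerate(_bank_msi_cache(bank)):
        c12 = (xs @ ys.T) / m
        r12 = q1 @ c12 @ q2
        out[i] = _sync_from_blocks(r11, r12, r22)
    return out


def classify(
    X: np.ndarray,
    bank: ReferenceBank,
    method: str = "fbtmsi",
    **params,
) -> DetectionResult:
    """Argmax frequency detection over a reference bank.

    ``method`` is one of ``msi``, ``tmsi``, ``fbmsi``, ``fbtmsi``; extra
    keyword arguments (``tau``, ``scheme``, ``rule``, ``sample_rate``) are
    forwarded to the index.  Ties are broken toward the lower frequency
    (first argmax), which makes the rule deterministic.
    """
    method = method.lower()
    if method == "msi":
        indices = msi_profile(X, bank)
    elif method == "tmsi":
        from .temporal import tmsi_profile

        indices = tmsi_profile(X, bank, **params)
    elif method in ("fbmsi", "fbtmsi"):
        from .filterbank import fb_profile

        base = "msi" if method == "fbmsi" else "tmsi"
        indices = fb_profile(X, bank, base=base, **params)
    else:
        raise ValueError(f"unknown method {method!r}; expected msi|tmsi|fbmsi|fbtmsi")
    if np.all(np.isnan(indices)):
        raise ValueError("all synchronization indices are NaN; cannot classify")
    best = int(np.nanargmax(indices))
    profile = SyncProfile(
        indices=indices,
        frequencies=bank.frequencies,
        method=method,
        params=dict(params),
    )
    return DetectionResult(
        frequency=float(bank.frequencies[best]), index=best, profile=profile
    )
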