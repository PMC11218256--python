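"""Harmonic reference signals for SSVEP frequency recognition.

Each candidate stimulus frequency f is represented by a bank of sine/cosine
pairs at its harmonics k·f, k = 1..N_h.  The reference matrix has 2·N_h rows
and M columns, evaluated on the time grid t = 1/F_s, 2/F_s, ..., M/F_s.  The
grid deliberately starts at 1/F_s rather than 0; at short windows an
off-by-one shift changes every sample index, so the convention is fixed here
once and reused everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property

import numpy as np

__all__ = [
    "HarmonicReference",
    "ReferenceBank",
    "build_reference",
    "build_reference_bank",
    "standardize",
    "default_frequency_grid",
]


def default_frequency_grid() -> np.ndarray:
    """The 40-target speller grid: 8 to 15.8 Hz in 0.2 Hz steps."""
    return np.round(np.arange(8.0, 15.8 + 1e-9, 0.2), 10)


def standardize(matrix: np.ndarray) -> np.ndarray:
    """Normalize every row to zero mean and unit variance.

    Uses the population convention (divisor M), matching the 1/M factor in
    the joint covariance.  A constant row has no scale and is rejected.

    Parameters
    ----------
    matrix : ndarray, shape (n_rows, n_samples)

    Returns
    -------
    ndarray of the same shape with row means 0 and row variances 1.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2:
        raise ValueError(f"expected a 2-D (rows x samples) array, got ndim={matrix.ndim}")
    if not np.all(np.isfinite(matrix)):
        raise ValueError("matrix contains non-finite values")
    mean = matrix.mean(axis=1, keepdims=True)
    sd = matrix.std(axis=1, ddof=0, keepdims=True)
    dead = np.flatnonzero(sd[:, 0] == 0.0)
    if dead.size:
        raise ValueError(f"row {dead[0]} has zero variance; cannot standardize a constant row")
    return (matrix - mean) / sd


@dataclass(eq=False)
class HarmonicReference:
    """Sin/cos harmonic matrix for one candidate stimulus frequency.

    ``matrix`` holds the raw (unit-amplitude) sinusoids; rows alternate
    sin(2π·k·f·t), cos(2π·k·f·t) for k = 1..n_harmonics.  ``standardized``
    caches the zero-mean/unit-variance version used by the synchronization
    indices.
    """

    frequency: float
    n_harmonics: int
    sample_rate: float
    matrix: np.ndarray = field(repr=False)

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[1]

    @cached_property
    def standardized(self) -> np.ndarray:
        return standardize(self.matrix)


def build_reference(
    frequency: float,
    n_harmonics: int,
    n_samples: int,
    sample_rate: float,
) -> HarmonicReference:
    """Build the 2·N_h × M harmonic reference for one frequency.

    Row 2k−1 (1-based) is sin(2π·k·f·t), row 2k is cos(2π·k·f·t), with
    t = 1/F_s, ..., M/F_s.  Harmonics at or above Nyquist are rejected:
    an aliased reference row would silently match the wrong frequency.
    """
    if frequency <= 0:
        raise ValueError(f"frequency must be positive, got {frequency}")
    if n_harmonics < 1:
        raise ValueError(f"n_harmonics must be >= 1, got {n_harmonics}")
    if sample_rate <= 0:
        raise ValueError(f"sample_rate must be positive, got {sample_rate}")
    if n_samples < 2:
        raise ValueError(f"n_samples must be >= 2, got {n_samples}")
    nyquist = sample_rate / 2.0
    if n_harmonics * frequency >= nyquist:
        raise ValueError(
            f"harmonic {n_harmonics}*{frequency}={n_harmonics * frequency:g} Hz "
            f">= Nyquist {nyquist:g} Hz; reduce n_harmonics or frequency"
        )
    t = np.arange(1, n_samples + 1) / sample_rate
    rows = np.empty((2 * n_harmonics, n_samples))
    for k in range(1, n_harmonics + 1):
        phase = 2.0 * np.pi * k * frequency * t
        rows[2 * k - 2] = np.sin(phase)
        rows[2 * k - 1] = np.cos(phase)
    return HarmonicReference(
        frequency=float(frequency),
        n_harmonics=int(n_harmonics),
        sample_rate=float(sample_rate),
        matrix=rows,
    )


class ReferenceBank:
    """Ordered collection of harmonic references sharing (N_h, M, F_s).

    The bank is rebuilt deterministically from its parameters; downstream
    code caches per-bank quantities (reference Gram matrices, whitening
    blocks) on :attr:`cache`, keyed by method and kernel parameters.
    """

    def __init__(self, references: list[HarmonicReference]):
        if not references:
            raise ValueError("reference bank cannot be empty")
        freqs = np.array([r.frequency for r in references])
        if np.any(np.diff(freqs) <= 0):
            raise ValueError("bank frequencies must be strictly increasing")
        first = references[0]
        for r in references[1:]:
            if (
                r.n_harmonics != first.n_harmonics
                or r.n_samples != first.n_samples
                or r.sample_rate != first.sample_rate
            ):
                raise ValueError("all references in a bank must share N_h, M and F_s")
        self.references = references
        self.frequencies = freqs
        self.cache: dict = {}

    @property
    def n_harmonics(self) -> int:
        return self.references[0].n_harmonics

    @property
    def n_samples(self) -> int:
        return self.references[0].n_samples

    @property
    def sample_rate(self) -> float:
        return self.references[0].sample_rate

    def __len__(self) -> int:
        return len(self.references)

    def __iter__(self):
        return iter(self.references)

    def __getitem__(self, i: int) -> HarmonicReference:
        return self.references[i]


def build_reference_bank(
    frequencies,
    n_harmonics: int,
    n_samples: int,
    sample_rate: float,
) -> ReferenceBank:
    """Build one :class:`HarmonicReference` per candidate frequency."""
    frequencies = np.asarray(frequencies, dtype=float)
    if frequencies.ndim != 1 or frequencies.size == 0:
        raise ValueError("frequencies must be a non-empty 1-D sequence")
    if np.any(np.diff(frequencies) <= 0):
        raise ValueError("frequencies must be strictly increasing (no duplicates)")
    refs = [
        build_reference(f, n_harmonics, n_samples, sample_rate) for f in frequencies
    ]
    return ReferenceBank(refs)
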