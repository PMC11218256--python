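"""Filter-bank subband decomposition and the fused FBMSI/FBTMSI indices.

SSVEP responses carry energy at the stimulus frequency and its harmonics up
to roughly 90 Hz.  The filter bank splits the EEG into N_sb subbands so the
synchronization index can exploit harmonic content explicitly; the per-
subband indices are fused by a weighted sum with weights ω_l = l^(−a) + b
that decay with subband order, reflecting the falling SNR of higher
harmonics.  Only the EEG is decomposed — the full harmonic reference is
reused in every subband.

Four subband layouts are provided (bandwidth unit 8 Hz, the width of the
stimulus grid; global band [8, 88] Hz):

    a: [8l, 8l+8]                 — disjoint equal-width bands
    b: [8l, min(16l+32, 88)]      — three-bandwidth bands
    c: [8, 8(12−l)]               — common lower edge, shrinking top
    d: [8l, 88]                   — common upper edge (the default)

Subbands are extracted with zero-phase (forward–backward) Chebyshev type-I
IIR bandpass filters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy import signal as sps

from .msi import msi, msi_profile
from .reference import HarmonicReference, ReferenceBank
from .temporal import tmsi, tmsi_profile

__all__ = [
    "SubbandScheme",
    "WeightRule",
    "FilterSpec",
    "subband_edges",
    "subband_weights",
    "design_filter",
    "apply_zero_phase",
    "fb_index",
    "fb_profile",
]

#: Default filter-design margins (adopted from the filter-bank convention
#: common in SSVEP decoding): 2 Hz transition bands, 0.5 dB passband
#: ripple, 40 dB stopband attenuation, minimal order meeting the spec.
TRANSITION_HZ = 2.0
RIPPLE_DB = 0.5
ATTEN_DB = 40.0


@dataclass(frozen=True)
class SubbandScheme:
    """Ordered list of subband passbands for one design scheme."""

    scheme: str
    n_subbands: int
    bands: tuple[tuple[float, float], ...]
    unit: float = 8.0
    f_high: float = 88.0


@dataclass(frozen=True)
class WeightRule:
    """Subband fusion weights ω_l = l^(−a) + b."""

    a: float = 1.0
    b: float = 0.0

    def weights(self, n_subbands: int) -> np.ndarray:
        return subband_weights(n_subbands, self.a, self.b)


@dataclass(frozen=True)
class FilterSpec:
    """Declarative bandpass design; coefficients are regenerated on demand
    (never stored), so a spec in a run config reproduces the filter
    exactly."""

    band: tuple[float, float]
    sample_rate: float
    transition_hz: float = TRANSITION_HZ
    ripple_db: float = RIPPLE_DB
    attenuation_db: float = ATTEN_DB

    @property
    def order(self) -> int:
        return _design(self.band, self.sample_rate, self.transition_hz,
                       self.ripple_db, self.attenuation_db)[0]

    @property
    def sos(self) -> np.ndarray:
        return _design(self.band, self.sample_rate, self.transition_hz,
                       self.ripple_db, self.attenuation_db)[1]

    def frequency_response(self, freqs_hz: np.ndarray) -> np.ndarray:
        """Complex single-pass response at the given frequencies (Hz)."""
        _, h = sps.sosfreqz(self.sos, worN=np.asarray(freqs_hz, dtype=float),
                            fs=self.sample_rate)
        return h


def subband_weights(n_subbands: int, a: float, b: float) -> np.ndarray:
    """ω_l = l^(−a) + b for l = 1..N_sb."""
    if n_subbands < 1:
        raise ValueError(f"n_subbands must be >= 1, got {n_subbands}")
    l = np.arange(1, n_subbands + 1, dtype=float)
    return l ** (-float(a)) + float(b)


def subband_edges(
    scheme: str,
    n_subbands: int,
    unit: float = 8.0,
    f_high: float = 88.0,
) -> SubbandScheme:
    """Passband edges for scheme a|b|c|d (see module docstring)."""
    scheme = scheme.lower()
    if scheme not in "abcd" or len(scheme) != 1:
        raise ValueError(f"scheme must be one of a|b|c|d, got {scheme!r}")
    if n_subbands < 1:
        raise ValueError(f"n_subbands must be >= 1, got {n_subbands}")
    if unit <= 0 or f_high <= unit:
        raise ValueError("need 0 < unit < f_high")
    bands = []
    for l in range(1, n_subbands + 1):
        if scheme == "a":
            low, high = unit * l, unit * (l + 1)
        elif scheme == "b":
            low, high = unit * l, min(2 * unit * l + 4 * unit, f_high)
        elif scheme == "c":
            low, high = unit, f_high - unit * (l - 1)
        else:  # d
            low, high = unit * l, f_high
        if not low < high:
            raise ValueError(
                f"scheme {scheme!r} with n_subbands={n_subbands} yields an "
                f"empty band [{low}, {high}] Hz at l={l}"
            )
        bands.append((float(low), float(high)))
    return SubbandScheme(
        scheme=scheme, n_subbands=n_subbands, bands=tuple(bands),
        unit=float(unit), f_high=float(f_high),
    )


@lru_cache(maxsize=256)
def _design(band, sample_rate, transition, ripple, atten):
    low, high = band
    nyq = sample_rate / 2.0
    if not 0 < low < high < nyq:
        raise ValueError(
            f"passband [{low}, {high}] Hz invalid for Nyquist {nyq:g} Hz"
        )
    ws_low = max(low - transition, 0.5)
    ws_high = high + transition
    if ws_high >= nyq:
        raise ValueError(
            f"stopband edge {ws_high:g} Hz >= Nyquist {nyq:g} Hz; "
            "spec unmeetable at this sample rate"
        )
    order, wn = sps.cheb1ord(
        wp=[low, high], ws=[ws_low, ws_high], gpass=ripple, gstop=atten,
        fs=sample_rate,
    )
    sos = sps.cheby1(order, ripple, wn, btype="bandpass", output="sos",
                     fs=sample_rate)
    return order, sos


def design_filter(
    band: tuple[float, float],
    sample_rate: float,
    transition_hz: float = TRANSITION_HZ,
    ripple_db: float = RIPPLE_DB,
    attenuation_db: float = ATTEN_DB,
) -> FilterSpec:
    """Minimal-order Chebyshev type-I bandpass meeting the ripple and
    attenuation spec, with stopband edges ``transition_hz`` outside the
    passband (lower edge floored at 0.5 Hz)."""
    spec = FilterSpec(
        band=(float(band[0]), float(band[1])),
        sample_rate=float(sample_rate),
        transition_hz=float(transition_hz),
        ripple_db=float(ripple_db),
        attenuation_db=float(attenuation_db),
    )
    spec.sos  # design now so invalid specs fail at construction
    return spec


def _padlen(sos: np.ndarray) -> int:
    # mirror scipy.signal.sosfiltfilt's default edge padding
    n_sections = sos.shape[0]
    ntaps = 2 * n_sections + 1
    ntaps -= min((sos[:, 2] == 0).sum(), (sos[:, 5] == 0).sum())
    return 3 * ntaps


def apply_zero_phase(X: np.ndarray, spec: FilterSpec) -> np.ndarray:
    """Forward–backward (zero-phase) filtering along the sample axis.

    The double pass squares the magnitude response and cancels the phase,
    so an in-band sinusoid comes back with no lag.  The epoch must be long
    enough for the edge padding of the realized order.
    """
    X = np.asarray(X, dtype=float)
    sos = spec.sos
    pad = _padlen(sos)
    if X.shape[-1] <= pad:
        raise ValueError(
            f"epoch of {X.shape[-1]} samples too short for zero-phase "
            f"filtering with realized order {spec.order} (needs > {pad})"
        )
    return sps.sosfiltfilt(sos, X, axis=-1)


def fb_index(
    X: np.ndarray,
    Y,
    scheme: SubbandScheme,
    rule: WeightRule,
    base: str = "tmsi",
    tau: float | None = None,
    sample_rate: float | None = None,
) -> float:
    """Fused filter-bank index S = Σ_l ω_l S^l for one epoch/reference pair.

    S^l is the base index (``msi`` → FBMSI, ``tmsi`` → FBTMSI) between the
    l-th subband-filtered epoch and the *unfiltered* reference.
    """
    if sample_rate is None:
        if isinstance(Y, HarmonicReference):
            sample_rate = Y.sample_rate
        else:
            raise ValueError("sample_rate required when Y is a raw matrix")
    if base == "tmsi" and tau is None:
        raise ValueError("tau is required for the tmsi base")
    w = rule.weights(scheme.n_subbands)
    total = 0.0
    for wl, band in zip(w, scheme.bands):
        if wl == 0.0:
            continue
        xf = apply_zero_phase(X, design_filter(band, sample_rate))
        s = tmsi(xf, Y, tau=tau) if base == "tmsi" else msi(xf, Y)
        total += wl * s
    return float(total)


def fb_profile(
    X: np.ndarray,
    bank: ReferenceBank,
    scheme: SubbandScheme | None = None,
    rule: WeightRule | None = None,
    base: str = "tmsi",
    tau: float | None = None,
    sample_rate: float | None = None,
) -> np.ndarray:
    """Fused filter-bank indices of one epoch against the whole bank.

    Defaults to the optimized operating point: scheme d with N_sb = 7 and
    (a, b) = (1, 0); ``tau`` defaults to 15 samples for the tmsi base.
    Each subband is filtered once and scanned against all references.
    """
    if sample_rate is None:
        sample_rate = bank.sample_rate
    if scheme is None:
        scheme = subband_edges("d", 7)
    if rule is None:
        rule = WeightRule(1.0, 0.0)
    if base == "tmsi" and tau is None:
        tau = 15.0
    if base not in ("msi", "tmsi"):
        raise ValueError(f"base must be msi or tmsi, got {base!r}")
    w = rule.weights(scheme.n_subbands)
    out = np.zeros(len(bank))
    for wl, band in zip(w, scheme.bands):
        if wl == 0.0:
            continue
        xf = apply_zero_phase(X, design_filter(band, sample_rate))
        if base == "tmsi":
            out += wl * tmsi_profile(xf, bank, tau=tau)
        else:
            out += wl * msi_profile(xf, bank)
    return out
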