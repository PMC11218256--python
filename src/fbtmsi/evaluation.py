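"""Evaluation protocol: accuracy, information transfer rate, SSVEP SNR,
leave-subjects-out cross-validation and parameter grid search.

Accuracy is the fraction of trials whose argmax frequency equals the true
stimulus.  ITR uses the Wolpaw formula with a selection time of
TW + 0.5 s gaze shift + 0.14 s visual latency.  Cross-validation leaves
whole subjects out (default 5 folds), optimizing parameters only on the
training subjects of each fold so no test subject influences the choice.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .filterbank import WeightRule, subband_edges
from .msi import classify
from .reference import ReferenceBank, build_reference_bank
from .simulate import Epoch

__all__ = [
    "accuracy",
    "itr",
    "selection_time",
    "power_spectrum",
    "ssvep_snr",
    "GridSpec",
    "GridSearchResult",
    "EvalReport",
    "grid_search",
    "cross_validate",
    "predict_epochs",
]

GAZE_SHIFT_S = 0.5
VISUAL_LATENCY_S = 0.14


def accuracy(predictions, truths) -> float:
    """Fraction of correct identifications: N_correct / N_total."""
    predictions = np.asarray(predictions, dtype=float)
    truths = np.asarray(truths, dtype=float)
    if predictions.size == 0:
        raise ValueError("cannot compute accuracy of zero trials")
    if predictions.shape != truths.shape:
        raise ValueError("predictions and truths must have equal length")
    return float(np.mean(np.isclose(predictions, truths, atol=1e-9)))


def selection_time(tw: float, gaze_shift: float = GAZE_SHIFT_S,
                   latency: float = VISUAL_LATENCY_S) -> float:
    """Seconds per selection: analysis window plus gaze-shift and latency
    overheads."""
    return tw + gaze_shift + latency


def itr(p: float, n_targets: int, t_select: float) -> float:
    """Wolpaw information transfer rate in bits/min.

    ITR = [log2 N + P log2 P + (1−P) log2((1−P)/(N−1))] · 60 / T, with
    0·log 0 := 0.  Sub-chance accuracy (P < 1/N) is clamped to 0 bits/min
    rather than returning the symmetric positive value — conservative, and
    the regime carries no usable information anyway.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"accuracy must be in [0, 1], got {p}")
    if n_targets < 2:
        raise ValueError(f"need at least 2 targets, got {n_targets}")
    if t_select <= 0:
        raise ValueError(f"selection time must be positive, got {t_select}")
    if p < 1.0 / n_targets:
        return 0.0
    bits = np.log2(n_targets)
    if p > 0:
        bits += p * np.log2(p)
    if p < 1:
        bits += (1.0 - p) * np.log2((1.0 - p) / (n_targets - 1))
    return float(max(bits, 0.0) * 60.0 / t_select)


def power_spectrum(x: np.ndarray, sample_rate: float,
                   delta_f: float = 0.2) -> tuple[np.ndarray, np.ndarray]:
    """Periodogram on a Δf grid (zero-padded as needed).

    Returns (frequencies, power).  Multichannel input is averaged over
    channels after the per-channel periodogram.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    nfft = max(int(round(sample_rate / delta_f)), x.shape[1])
    freqs, pxx = sps.periodogram(x, fs=sample_rate, nfft=nfft, axis=-1)
    return freqs, pxx.mean(axis=0)


def ssvep_snr(freqs: np.ndarray, power: np.ndarray, f_n: float,
              m: int = 10) -> float:
    """SNR at f_n: P(f_n) over the mean power of the m surrounding bins.

    The m neighbors are the grid points f_{n±q}, q = 1..m/2 on each side,
    excluding the target bin itself.
    """
    freqs = np.asarray(freqs, dtype=float)
    power = np.asarray(power, dtype=float)
    if m < 2 or m % 2:
        raise ValueError(f"m must be even and >= 2, got {m}")
    i = int(np.argmin(np.abs(freqs - f_n)))
    if abs(freqs[i] - f_n) > 0.5 * np.median(np.diff(freqs)):
        raise ValueError(f"target frequency {f_n} Hz not on the spectrum grid")
    half = m // 2
    if i - half < 0 or i + half >= freqs.size:
        raise ValueError("spectrum does not cover the m neighboring bins")
    idx = np.r_[i - half : i, i + 1 : i + half + 1]
    floor = power[idx].mean()
    if floor <= 0:
        raise ValueError("neighboring power is zero; SNR undefined")
    return float(power[i] / floor)


# ---------------------------------------------------------------------------
# classification over epoch collections

_BANK_CACHE: dict = {}


def _bank_for(frequencies, n_harmonics: int, n_samples: int,
              sample_rate: float) -> ReferenceBank:
    key = (tuple(np.round(frequencies, 10)), n_harmonics, n_samples, sample_rate)
    if key not in _BANK_CACHE:
        _BANK_CACHE[key] = build_reference_bank(
            frequencies, n_harmonics, n_samples, sample_rate
        )
    return _BANK_CACHE[key]


def _method_kwargs(method: str, params: dict) -> dict:
    """Forward only the parameters the method consumes."""
    method = method.lower()
    kw: dict = {}
    if method == "tmsi":
        kw["tau"] = params.get("tau", 15.0)
    elif method in ("fbmsi", "fbtmsi"):
        kw["scheme"] = subband_edges(
            params.get("scheme", "d"), params.get("n_subbands", 7)
        )
        kw["rule"] = WeightRule(params.get("a", 1.0), params.get("b", 0.0))
        if method == "fbtmsi":
            kw["tau"] = params.get("tau", 15.0)
    return kw


def predict_epochs(
    epochs: list[Epoch],
    method: str,
    tw: float,
    frequencies=None,
    n_harmonics: int = 4,
    latency: float = VISUAL_LATENCY_S,
    **params,
) -> np.ndarray:
    """Predicted stimulus frequency for every epoch.

    Each epoch is cropped to the TW-second window starting after the visual
    latency and classified against a bank built for that window length.
    """
    if not epochs:
        raise ValueError("no epochs to classify")
    fs = epochs[0].sample_rate
    if frequencies is None:
        labels = sorted({e.frequency for e in epochs if e.frequency is not None})
        if not labels:
            raise ValueError("epochs carry no frequency labels; pass frequencies=")
        frequencies = labels
    n = int(round(tw * fs))
    bank = _bank_for(frequencies, n_harmonics, n, fs)
    kw = _method_kwargs(method, params)
    preds = np.empty(len(epochs))
    for i, ep in enumerate(epochs):
        x = ep.window(tw, offset=latency)
        preds[i] = classify(x, bank, method=method, **kw).frequency
    return preds


# ---------------------------------------------------------------------------
# grid search

@dataclass(frozen=True)
class GridSpec:
    """Candidate grids for the tunable parameters.  Defaults are the
    canonical search ranges: τ ∈ [2:1:19], a ∈ [0.25:0.25:2.5],
    b ∈ [0:0.25:1]; N_h and N_sb pinned at the operating point unless a
    wider sweep is requested."""

    tau: tuple[float, ...] = tuple(range(2, 20))
    a: tuple[float, ...] = tuple(np.round(np.arange(0.25, 2.5 + 1e-9, 0.25), 10))
    b: tuple[float, ...] = tuple(np.round(np.arange(0.0, 1.0 + 1e-9, 0.25), 10))
    n_harmonics: tuple[int, ...] = (4,)
    n_subbands: tuple[int, ...] = (7,)


#: Which grid axes each method actually consumes, in tie-break order.
_METHOD_AXES = {
    "msi": ("n_harmonics",),
    "tmsi": ("n_harmonics", "tau"),
    "fbmsi": ("n_harmonics", "n_subbands", "a", "b"),
    "fbtmsi": ("n_harmonics", "n_subbands", "tau", "a", "b"),
}


@dataclass(eq=False)
class GridSearchResult:
    best_params: dict
    best_score: float
    surface: pd.DataFrame  # one row per grid point: params + accuracy


def grid_search(
    epochs: list[Epoch],
    method: str,
    grids: GridSpec,
    tw: float,
    frequencies=None,
    latency: float = VISUAL_LATENCY_S,
    scheme: str = "d",
) -> GridSearchResult:
    """Exhaustive search of mean accuracy over the method's parameter grid.

    Iteration (and hence tie-breaking toward the first maximum) runs in
    ascending order over (N_h, N_sb, τ, a, b) restricted to the axes the
    method uses.  The full score surface is returned for inspection.
    """
    method = method.lower()
    if method not in _METHOD_AXES:
        raise ValueError(f"unknown method {method!r}")
    if not epochs:
        raise ValueError("empty training set")
    axes = _METHOD_AXES[method]
    grids_d = {
        "tau": grids.tau, "a": grids.a, "b": grids.b,
        "n_harmonics": grids.n_harmonics, "n_subbands": grids.n_subbands,
    }
    for name in axes:
        if not len(grids_d[name]):
            raise ValueError(f"grid for {name!r} is empty")
    truths = np.array([e.frequency for e in epochs], dtype=float)
    rows = []
    best = None
    for combo in itertools.product(*(grids_d[name] for name in axes)):
        params = dict(zip(axes, combo))
        nh = int(params.pop("n_harmonics", 4))
        preds = predict_epochs(
            epochs, method, tw, frequencies=frequencies, n_harmonics=nh,
            latency=latency, scheme=scheme, **params,
        )
        score = accuracy(preds, truths)
        full = {"n_harmonics": nh, **params}
        rows.append({**full, "accuracy": score})
        if best is None or score > best[1]:
            best = (full, score)
    return GridSearchResult(
        best_params=best[0], best_score=best[1], surface=pd.DataFrame(rows)
    )


# ---------------------------------------------------------------------------
# cross-validation

@dataclass(eq=False)
class EvalReport:
    """Long-format results table plus fold bookkeeping.

    ``table`` has one row per (method, tw, fold, subject) with accuracy,
    ITR and the parameters chosen on that fold's training subjects;
    ``folds`` records the exact train/test subject partition for audit.
    """

    table: pd.DataFrame
    folds: list[dict] = field(default_factory=list)

    def summary(self) -> pd.DataFrame:
        g = self.table.groupby(["method", "tw"])
        out = g.agg(
            accuracy_mean=("accuracy", "mean"),
            accuracy_sd=("accuracy", "std"),
            itr_mean=("itr", "mean"),
            itr_sd=("itr", "std"),
        ).reset_index()
        return out

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def to_json_summary(self) -> dict:
        return {
            f"{row.method}_tw{row.tw:g}": {
                "accuracy_mean": row.accuracy_mean,
                "accuracy_sd": row.accuracy_sd,
                "itr_mean": row.itr_mean,
                "itr_sd": row.itr_sd,
            }
            for row in self.summary().itertuples()
        }


def cross_validate(
    epochs: list[Epoch],
    methods,
    tw_list,
    grids: GridSpec | None = None,
    n_folds: int = 5,
    latency: float = VISUAL_LATENCY_S,
    global_search: bool = False,
    scheme: str = "d",
) -> EvalReport:
    """Leave-subjects-out cross-validation with per-fold grid search.

    Subjects are split into ``n_folds`` equal folds (error if not
    divisible).  For each fold, method and TW, parameters maximizing mean
    accuracy on the training subjects are found by :func:`grid_search`
    and then applied to the held-out subjects, so every subject is tested
    exactly once and never influences its own parameter choice.  With
    ``global_search=True`` a single pooled search over all subjects is run
    instead (optimistic; kept for reproducing pooled-optimum analyses).
    """
    if grids is None:
        grids = GridSpec()
    if isinstance(methods, str):
        methods = [methods]
    subjects = sorted({e.subject for e in epochs})
    if None in subjects:
        raise ValueError("all epochs need a subject id for cross-validation")
    if len(subjects) % n_folds:
        raise ValueError(
            f"{len(subjects)} subjects cannot be split into {n_folds} equal folds"
        )
    per = len(subjects) // n_folds
    fold_subjects = [subjects[i * per : (i + 1) * per] for i in range(n_folds)]
    by_subject: dict = {s: [] for s in subjects}
    for e in epochs:
        by_subject[e.subject].append(e)
    n_targets = len({e.frequency for e in epochs})

    rows = []
    folds_meta = []
    pooled: dict = {}
    for k, test_subjects in enumerate(fold_subjects):
        train_subjects = [s for s in subjects if s not in test_subjects]
        train = [e for s in train_subjects for e in by_subject[s]]
        folds_meta.append(
            {"fold": k, "train_subjects": list(train_subjects),
             "test_subjects": list(test_subjects)}
        )
        for method in methods:
            for tw in tw_list:
                if global_search:
                    key = (method, tw)
                    if key not in pooled:
                        pooled[key] = grid_search(
                            epochs, method, grids, tw, latency=latency,
                            scheme=scheme,
                        ).best_params
                    params = dict(pooled[key])
                else:
                    params = dict(
                        grid_search(
                            train, method, grids, tw, latency=latency,
                            scheme=scheme,
                        ).best_params
                    )
                nh = int(params.pop("n_harmonics", 4))
                t_sel = selection_time(tw, latency=latency)
                for s in test_subjects:
                    eps = by_subject[s]
                    preds = predict_epochs(
                        eps, method, tw, n_harmonics=nh, latency=latency,
                        scheme=scheme, **params,
                    )
                    truths = np.array([e.frequency for e in eps])
                    acc = accuracy(preds, truths)
                    rows.append(
                        {
                            "method": method, "tw": tw, "fold": k,
                            "subject": s, "accuracy": acc,
                            "itr": itr(acc, n_targets, t_sel),
                            "n_trials": len(eps),
                            "params": {"n_harmonics": nh, **params},
                        }
                    )
    return EvalReport(table=pd.DataFrame(rows), folds=folds_meta)
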