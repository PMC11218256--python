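"""Epoch container I/O: HDF5 primary format, CSV-directory fallback, and a
best-effort reader for the public benchmark MAT layout.

HDF5 layout (documented in the README):
    /data   float64, shape (subject, block, target, channel, sample)
    attrs   sample_rate, channels, frequencies, subjects, blocks,
            provenance (JSON string, includes the simulator seed)

The CSV fallback writes one file per epoch (samples × channels, header row
of channel labels) plus a ``metadata.json`` with the shared attributes, so
a container can be inspected with nothing but a text editor.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .simulate import OCC3, OCC6, OCC9, Epoch, SimConfig

__all__ = ["EpochContainer", "CHANNEL_PRESETS", "read_epochs"]

#: Named montage presets (3/6/9 parieto-occipital channels).
CHANNEL_PRESETS = {"occ3": OCC3, "occ6": OCC6, "occ9": OCC9}

#: Position (0-based) of the nine parieto-occipital channels in the
#: 64-channel benchmark cap layout.  Best-effort: verify against the
#: dataset's own channel file when using real recordings.
_BENCHMARK_9CH = {
    "Pz": 47, "PO5": 53, "PO3": 54, "POz": 55, "PO4": 56, "PO6": 57,
    "O1": 60, "Oz": 61, "O2": 62,
}


class EpochContainer:
    """A labeled collection of epochs sharing geometry and sampling rate."""

    def __init__(self, epochs: list[Epoch], provenance: dict | None = None):
        if not epochs:
            raise ValueError("container cannot be empty")
        first = epochs[0]
        for i, e in enumerate(epochs):
            if e.sample_rate != first.sample_rate:
                raise ValueError(f"epoch {i}: sample_rate differs from the first epoch")
            if e.data.shape != first.data.shape:
                raise ValueError(f"epoch {i}: data shape differs from the first epoch")
            if not np.all(np.isfinite(e.data)):
                raise ValueError(f"epoch {i}: data contains non-finite values")
        self.epochs = list(epochs)
        self.provenance = dict(provenance or {})

    # -- basic views --------------------------------------------------------

    @property
    def sample_rate(self) -> float:
        return self.epochs[0].sample_rate

    @property
    def channels(self):
        return self.epochs[0].channels

    @property
    def frequencies(self) -> list[float]:
        return sorted({e.frequency for e in self.epochs if e.frequency is not None})

    @property
    def subjects(self) -> list:
        return sorted({e.subject for e in self.epochs if e.subject is not None})

    def __len__(self) -> int:
        return len(self.epochs)

    def __iter__(self):
        return iter(self.epochs)

    @classmethod
    def simulate(cls, config: SimConfig) -> "EpochContainer":
        from .simulate import simulate_dataset

        return cls(
            simulate_dataset(config),
            provenance={"simulator": "fbtmsi.simulate", "seed": config.seed,
                        "noise_sigma": config.noise_sigma,
                        "duration": config.duration},
        )

    # -- HDF5 ---------------------------------------------------------------

    def to_hdf5(self, path) -> None:
        """Write the 5-D layout; requires a complete subject×block×target
        grid (which every simulated dataset has)."""
        subjects = self.subjects
        blocks = sorted({e.block for e in self.epochs})
        freqs = self.frequencies
        index = {}
        for e in self.epochs:
            key = (e.subject, e.block, e.frequency)
            if key in index:
                raise ValueError(f"duplicate epoch for (subject, block, target) {key}")
            index[key] = e
        if len(index) != len(subjects) * len(blocks) * len(freqs):
            raise ValueError(
                "HDF5 layout needs a complete subject x block x target grid; "
                "use to_csv_dir for irregular collections"
            )
        shape = (len(subjects), len(blocks), len(freqs),
                 self.epochs[0].n_channels, self.epochs[0].n_samples)
        data = np.empty(shape)
        for (s, b, f), e in index.items():
            data[subjects.index(s), blocks.index(b), freqs.index(f)] = e.data
        with h5py.File(path, "w") as h5:
            h5.create_dataset("data", data=data)
            h5.attrs["sample_rate"] = self.sample_rate
            h5.attrs["channels"] = json.dumps(list(self.channels or []))
            h5.attrs["frequencies"] = np.asarray(freqs)
            h5.attrs["subjects"] = np.asarray(subjects)
            h5.attrs["blocks"] = np.asarray(blocks)
            h5.attrs["provenance"] = json.dumps(self.provenance)

    @classmethod
    def from_hdf5(cls, path) -> "EpochContainer":
        with h5py.File(path, "r") as h5:
            for attr in ("sample_rate", "frequencies", "subjects", "blocks"):
                if attr not in h5.attrs:
                    raise ValueError(f"invalid container: missing attribute {attr!r}")
            if "data" not in h5:
                raise ValueError("invalid container: missing dataset 'data'")
            data = h5["data"][()]
            fs = float(h5.attrs["sample_rate"])
            channels = tuple(json.loads(h5.attrs.get("channels", "[]"))) or None
            freqs = np.asarray(h5.attrs["frequencies"])
            subjects = np.asarray(h5.attrs["subjects"])
            blocks = np.asarray(h5.attrs["blocks"])
            provenance = json.loads(h5.attrs.get("provenance", "{}"))
        if data.ndim != 5:
            raise ValueError(f"invalid container: data must be 5-D, got {data.ndim}-D")
        epochs = []
        for si, s in enumerate(subjects):
            for bi, b in enumerate(blocks):
                for fi, f in enumerate(freqs):
                    epochs.append(
                        Epoch(data=data[si, bi, fi], sample_rate=fs,
                              frequency=float(f), channels=channels,
                              subject=int(s), block=int(b))
                    )
        return cls(epochs, provenance=provenance)

    # -- CSV directory ------------------------------------------------------

    def to_csv_dir(self, path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        meta = {"sample_rate": self.sample_rate, "provenance": self.provenance,
                "epochs": {}}
        for i, e in enumerate(self.epochs):
            name = f"epoch_{i:05d}.csv"
            header = ",".join(e.channels or [f"ch{c}" for c in range(e.n_channels)])
            np.savetxt(path / name, e.data.T, delimiter=",", header=header,
                       comments="", fmt="%.17g")
            meta["epochs"][name] = {
                "frequency": e.frequency, "subject": e.subject, "block": e.block,
            }
        (path / "metadata.json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def from_csv_dir(cls, path) -> "EpochContainer":
        path = Path(path)
        meta_path = path / "metadata.json"
        if not meta_path.exists():
            raise ValueError(f"invalid csv-dir container: missing {meta_path}")
        meta = json.loads(meta_path.read_text())
        if "sample_rate" not in meta:
            raise ValueError("invalid csv-dir container: metadata lacks 'sample_rate'")
        epochs = []
        for name in sorted(meta.get("epochs", {})):
            info = meta["epochs"][name]
            fpath = path / name
            if not fpath.exists():
                raise ValueError(f"invalid csv-dir container: missing file {name}")
            with open(fpath) as fh:
                channels = tuple(fh.readline().strip().split(","))
            data = np.loadtxt(fpath, delimiter=",", skiprows=1, ndmin=2).T
            epochs.append(
                Epoch(data=data, sample_rate=float(meta["sample_rate"]),
                      frequency=info.get("frequency"), channels=channels,
                      subject=info.get("subject"), block=info.get("block"))
            )
        return cls(epochs, provenance=meta.get("provenance", {}))

    # -- benchmark MAT (optional, best-effort) ------------------------------

    @classmethod
    def from_benchmark_mat(cls, path, subject: int = 0, crop: bool = False,
                           tw: float | None = None) -> "EpochContainer":
        """Read one subject file of the public 40-target benchmark layout
        (64 ch × 1500 samples × 40 targets × 6 blocks at 250 Hz), keeping
        the nine parieto-occipital channels.

        ``crop=True`` drops the 0.5 s cue plus 0.14 s latency before the
        window (and keeps ``tw`` seconds if given).  Best-effort: raises a
        clear error when the file does not match the expected layout.
        """
        try:
            from scipy.io import loadmat
        except ImportError as exc:  # pragma: no cover
            raise RuntimeError("scipy is required for MAT reading") from exc
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"benchmark file not found: {path}")
        mat = loadmat(path)
        if "data" not in mat:
            raise ValueError("not a benchmark subject file: no 'data' variable")
        data = mat["data"]
        if data.ndim != 4 or data.shape[0] < 64:
            raise ValueError(
                f"unexpected benchmark layout {data.shape}; "
                "expected (64, samples, 40, 6)"
            )
        fs = 250.0
        labels = tuple(_BENCHMARK_9CH)
        rows = [_BENCHMARK_9CH[c] for c in labels]
        grid = np.round(np.arange(8.0, 15.8 + 1e-9, 0.2), 10)
        epochs = []
        for b in range(data.shape[3]):
            for t in range(data.shape[2]):
                x = np.asarray(data[rows, :, t, b], dtype=float)
                if crop:
                    i0 = int(round((0.5 + 0.14) * fs))
                    i1 = i0 + int(round(tw * fs)) if tw else x.shape[1]
                    x = x[:, i0:i1]
                epochs.append(
                    Epoch(data=x, sample_rate=fs, frequency=float(grid[t]),
                          channels=labels, subject=subject, block=b)
                )
        return cls(epochs, provenance={"source": str(path), "reader": "benchmark-mat"})


def read_epochs(path, format: str = "hdf5") -> EpochContainer:
    """Dispatch on container format: ``hdf5``, ``csv-dir`` or
    ``benchmark-mat``."""
    if format == "hdf5":
        return EpochContainer.from_hdf5(path)
    if format == "csv-dir":
        return EpochContainer.from_csv_dir(path)
    if format == "benchmark-mat":
        return EpochContainer.from_benchmark_mat(path)
    raise ValueError(f"unknown format {format!r}")
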