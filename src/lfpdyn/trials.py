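"""Core data model for multi-trial LFP recordings and file I/O.

A recording session is a :class:`TrialSet`: a stack of equally long,
equally sampled sweeps (:class:`Trial`), each tagged with a condition label
(``control`` or ``treated``) and an animal id.  Two on-disk layouts are
supported:

* **CSV (wide)** — one column per trial, one sample per row.  Four metadata
  rows precede the data block; the first cell of each names the field::

      trial_id,1,2,3
      condition,control,control,control
      animal_id,1,1,1
      dt,0.0001,0.0001,0.0001
      -0.123,0.456,...

* **HDF5** — one 2-D dataset ``lfp`` of shape (samples, trials) with file
  attribute ``dt`` and per-trial attribute arrays ``trial_id``,
  ``condition``, ``animal_id``.

Floats round-trip bit-exactly through both formats (CSV uses ``repr``
precision).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import h5py
import numpy as np

from .exceptions import EmptyWindowError, MalformedInputError, ParseError

CONDITIONS = ("control", "treated")


@dataclass(frozen=True)
class Trial:
    """One sampled LFP sweep.

    Parameters
    ----------
    samples : array-like
        Voltage samples (microvolts by convention; units are not enforced).
    dt : float
        Sampling step in seconds (1e-4 s for 10 kHz recordings).
    trial_id : int
        Identifier, unique within a condition.
    condition : str
        ``"control"`` or ``"treated"``.
    animal_id : int
        Subject identifier.
    """

    samples: np.ndarray
    dt: float
    trial_id: int = 0
    condition: str = "control"
    animal_id: int = 1

    def __post_init__(self):
        samples = np.asarray(self.samples, dtype=float)
        if samples.ndim != 1 or samples.size < 2:
            raise MalformedInputError("a trial needs a 1-D series of length >= 2")
        if not np.all(np.isfinite(samples)):
            raise MalformedInputError("trial samples must all be finite")
        if not (self.dt > 0):
            raise MalformedInputError(f"dt must be positive, got {self.dt}")
        if self.condition not in CONDITIONS:
            raise MalformedInputError(
                f"condition must be one of {CONDITIONS}, got {self.condition!r}"
            )
        object.__setattr__(self, "samples", samples)

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        return self.samples.size * self.dt

    def with_samples(self, samples: np.ndarray) -> "Trial":
        return replace(self, samples=np.asarray(samples, dtype=float))


@dataclass(frozen=True)
class TrialSet:
    """A list of trials sharing dt and length."""

    trials: tuple[Trial, ...]

    def __post_init__(self):
        trials = tuple(self.trials)
        if not trials:
            raise MalformedInputError("empty trial set")
        dt0, n0 = trials[0].dt, len(trials[0])
        seen: set[tuple[str, int]] = set()
        for t in trials:
            if t.dt != dt0:
                raise MalformedInputError("all trials must share dt")
            if len(t) != n0:
                raise MalformedInputError("all trials must share length")
            key = (t.condition, t.trial_id)
            if key in seen:
                raise MalformedInputError(
                    f"duplicate trial_id {t.trial_id} within condition {t.condition!r}"
                )
            seen.add(key)
        object.__setattr__(self, "trials", trials)

    def __len__(self) -> int:
        return len(self.trials)

    def __iter__(self):
        return iter(self.trials)

    def __getitem__(self, i: int) -> Trial:
        return self.trials[i]

    @property
    def dt(self) -> float:
        return self.trials[0].dt

    @property
    def n_samples(self) -> int:
        return len(self.trials[0])

    def to_array(self) -> np.ndarray:
        """Samples as a (n_samples, n_trials) array, column per trial."""
        return np.column_stack([t.samples for t in self.trials])

    def conditions(self) -> list[str]:
        return [t.condition for t in self.trials]

    def map_samples(self, fn) -> "TrialSet":
        return TrialSet(tuple(t.with_samples(fn(t.samples)) for t in self.trials))


def concat_trialsets(a: TrialSet, b: TrialSet) -> TrialSet:
    """Concatenate two compatible trial sets (e.g. control + treated)."""
    if a.dt != b.dt or a.n_samples != b.n_samples:
        raise MalformedInputError("trial sets differ in dt or length")
    return TrialSet(tuple(a.trials) + tuple(b.trials))


def steady_window(trial: Trial, discard: float = 0.5) -> Trial:
    """Drop the initial stimulus-locked transient and keep the steady tail.

    The first ``discard`` seconds (default 0.5 s) are removed: the output is
    the suffix starting at the first sample index >= discard/dt.  For a 2 s
    sweep at 10 kHz and the default discard this keeps the last 15,000
    samples (1.5 s of steady oscillatory activity).
    """
    if discard < 0:
        raise ValueError("discard must be nonnegative")
    start = math.ceil(discard / trial.dt - 1e-12)
    if start >= len(trial):
        raise EmptyWindowError(
            f"discard {discard}s >= trial duration {trial.duration}s"
        )
    if start == 0:
        return trial
    return trial.with_samples(trial.samples[start:])


def steady_window_set(tset: TrialSet, discard: float = 0.5) -> TrialSet:
    return TrialSet(tuple(steady_window(t, discard) for t in tset))


# ---------------------------------------------------------------------------
# I/O

_META_ROWS = ("trial_id", "condition", "animal_id", "dt")


def write_trialset(tset: TrialSet, path, format: str | None = None) -> None:
    """Write a trial set to CSV (wide) or HDF5; format inferred from suffix."""
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "csv":
        _write_csv(tset, path)
    elif fmt == "hdf5":
        _write_hdf5(tset, path)
    else:
        raise ValueError(f"unknown format {fmt!r}")


def read_trialset(path, format: str | None = None) -> TrialSet:
    """Read a trial set written by :func:`write_trialset`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or _infer_format(path)
    if fmt == "csv":
        return _read_csv(path)
    if fmt == "hdf5":
        return _read_hdf5(path)
    raise ValueError(f"unknown format {fmt!r}")


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in (".h5", ".hdf5", ".hdf"):
        return "hdf5"
    return "csv"


def _write_csv(tset: TrialSet, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("trial_id," + ",".join(str(t.trial_id) for t in tset) + "\n")
        fh.write("condition," + ",".join(t.condition for t in tset) + "\n")
        fh.write("animal_id," + ",".join(str(t.animal_id) for t in tset) + "\n")
        fh.write("dt," + ",".join(repr(float(tset.dt)) for _ in tset) + "\n")
        arr = tset.to_array()
        for row in arr:
            fh.write(",".join(repr(float(v)) for v in row) + "\n")


def _read_csv(path: Path) -> TrialSet:
    with open(path) as fh:
        raw = [line.rstrip("\n") for line in fh if line.strip()]
    meta: dict[str, list[str]] = {}
    data_lines: list[list[str]] = []
    for i, line in enumerate(raw):
        cells = line.split(",")
        if cells[0] in _META_ROWS:
            meta[cells[0]] = cells[1:]
        else:
            data_lines.append(cells)
    missing = [m for m in _META_ROWS if m not in meta]
    if missing:
        raise MalformedInputError(f"missing metadata rows: {missing}")
    n_trials = len(meta["trial_id"])
    for name, vals in meta.items():
        if len(vals) != n_trials:
            raise MalformedInputError(
                f"metadata row {name!r} has {len(vals)} cells, expected {n_trials}"
            )
    columns: list[list[float]] = [[] for _ in range(n_trials)]
    for r, cells in enumerate(data_lines):
        if len(cells) != n_trials:
            raise MalformedInputError(
                f"data row {r} has {len(cells)} cells, expected {n_trials} "
                "(unequal column lengths)"
            )
        for c, cell in enumerate(cells):
            try:
                columns[c].append(float(cell))
            except ValueError as exc:
                raise ParseError(
                    f"non-numeric cell at data row {r}, column {c}: {cell!r}"
                ) from exc
    try:
        dt = float(meta["dt"][0])
        trial_ids = [int(v) for v in meta["trial_id"]]
        animal_ids = [int(v) for v in meta["animal_id"]]
    except ValueError as exc:
        raise ParseError(f"bad metadata value: {exc}") from exc
    trials = [
        Trial(
            samples=np.asarray(columns[c]),
            dt=dt,
            trial_id=trial_ids[c],
            condition=meta["condition"][c],
            animal_id=animal_ids[c],
        )
        for c in range(n_trials)
    ]
    return TrialSet(tuple(trials))


def _write_hdf5(tset: TrialSet, path: Path) -> None:
    with h5py.File(path, "w") as fh:
        dset = fh.create_dataset("lfp", data=tset.to_array())
        dset.attrs["dt"] = tset.dt
        dset.attrs["trial_id"] = np.asarray([t.trial_id for t in tset])
        dset.attrs["condition"] = np.asarray(
            [t.condition for t in tset], dtype=h5py.string_dtype()
        )
        dset.attrs["animal_id"] = np.asarray([t.animal_id for t in tset])


def _read_hdf5(path: Path) -> TrialSet:
    with h5py.File(path, "r") as fh:
        if "lfp" not in fh:
            raise MalformedInputError("HDF5 file lacks an 'lfp' dataset")
        dset = fh["lfp"]
        arr = dset[...]
        dt = float(dset.attrs["dt"])
        trial_ids = [int(v) for v in dset.attrs["trial_id"]]
        conditions = [
            v.decode() if isinstance(v, bytes) else str(v)
            for v in dset.attrs["condition"]
        ]
        animal_ids = [int(v) for v in dset.attrs["animal_id"]]
    trials = [
        Trial(arr[:, c], dt=dt, trial_id=trial_ids[c], condition=conditions[c],
              animal_id=animal_ids[c])
        for c in range(arr.shape[1])
    ]
    return TrialSet(tuple(trials))
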