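"""Core data model and HDF5 I/O for multielectrode-array spike recordings.

A recording is stored as a single HDF5 file with the layout used by
open MEA spike repositories:

``/spikes``
    all spike times on the array, concatenated electrode by electrode
    (float64, seconds);
``/sCount``
    number of spikes per electrode (int), summing to ``len(/spikes)``;
``/epos``
    N x 2 electrode positions in micrometres;
``/names``
    electrode labels (strings);
``/array``
    array model identifier (string);
``/meta/region``
    tissue-of-origin label, the string ``"CTX"`` or ``"HPC"``;
``/meta/age``
    culture age in days in vitro (int).

``/t_start`` and ``/t_stop`` record the recording interval; files
lacking them are assumed to start at 0 s and span at least 900 s
(the standard 15-minute recording).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import h5py
import numpy as np

__all__ = [
    "SpikeTrain",
    "Recording",
    "RecordingFormatError",
    "MetadataError",
    "SpikeDataError",
    "REGIONS",
    "DEFAULT_DURATION",
    "default_positions",
    "read_recording",
    "write_recording",
    "validate_recording",
]

REGIONS = ("CTX", "HPC")

#: Default recording interval length (15 minutes), seconds.
DEFAULT_DURATION = 900.0

#: Inter-electrode pitch of the default 60MEA200/30 geometry, micrometres.
MEA_PITCH_UM = 200.0


class RecordingFormatError(ValueError):
    """File does not conform to the expected HDF5 layout."""


class MetadataError(ValueError):
    """Recording metadata is present but invalid (e.g. unknown region)."""


class SpikeDataError(ValueError):
    """Spike data violates basic constraints (e.g. unsorted times)."""


@dataclass(eq=False)
class SpikeTrain:
    """Sorted spike times of one electrode over a known interval.

    Parameters
    ----------
    times
        Spike times in seconds, strictly increasing.
    t_start, t_stop
        Recording interval; every spike time must fall inside it.
    """

    times: np.ndarray
    t_start: float = 0.0
    t_stop: float = DEFAULT_DURATION

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=np.float64)
        self.t_start = float(self.t_start)
        self.t_stop = float(self.t_stop)

    @property
    def n_spikes(self) -> int:
        return int(self.times.size)

    @property
    def duration(self) -> float:
        return self.t_stop - self.t_start

    @property
    def firing_rate(self) -> float:
        """Mean firing rate over the recording interval, Hz."""
        return self.n_spikes / self.duration

    def isi(self) -> np.ndarray:
        """Interspike intervals, seconds (length ``n_spikes - 1``)."""
        return np.diff(self.times)

    def violations(self) -> list[str]:
        out: list[str] = []
        if not self.t_stop > self.t_start:
            out.append(f"t_stop ({self.t_stop}) must exceed t_start ({self.t_start})")
        if self.times.size:
            if self.times[0] < self.t_start or self.times[-1] > self.t_stop:
                out.append("spike times outside [t_start, t_stop]")
            if np.any(np.diff(self.times) <= 0):
                out.append("spike times not strictly increasing")
        return out

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SpikeTrain):
            return NotImplemented
        return (
            self.t_start == other.t_start
            and self.t_stop == other.t_stop
            and np.array_equal(self.times, other.times)
        )


@dataclass(eq=False)
class Recording:
    """One multielectrode-array recording: spike trains plus metadata."""

    trains: list[SpikeTrain]
    positions: np.ndarray
    labels: list[str]
    region: str
    age_div: int
    array_id: str = ""

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.float64).reshape(-1, 2)
        self.labels = [str(x) for x in self.labels]

    @property
    def n_electrodes(self) -> int:
        return len(self.trains)

    @property
    def t_start(self) -> float:
        return self.trains[0].t_start

    @property
    def t_stop(self) -> float:
        return self.trains[0].t_stop

    @property
    def duration(self) -> float:
        return self.t_stop - self.t_start

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Recording):
            return NotImplemented
        return (
            self.trains == other.trains
            and np.array_equal(self.positions, other.positions)
            and self.labels == other.labels
            and self.region == other.region
            and self.age_div == other.age_div
            and self.array_id == other.array_id
        )


def default_positions(n: int) -> np.ndarray:
    """Electrode positions (µm) of the default 8x8-minus-corners grid.

    The 60MEA200/30 layout: an 8x8 grid at 200 µm pitch with the four
    corner sites absent.  The first ``n`` sites are returned in
    column-major order; for ``n > 60`` the grid is extended to a larger
    square of the same pitch.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if n <= 60:
        coords = [
            (c * MEA_PITCH_UM, r * MEA_PITCH_UM)
            for c in range(8)
            for r in range(8)
            if (c, r) not in {(0, 0), (0, 7), (7, 0), (7, 7)}
        ]
        return np.asarray(coords[:n], dtype=np.float64)
    side = int(np.ceil(np.sqrt(n)))
    coords = [(c * MEA_PITCH_UM, r * MEA_PITCH_UM) for c in range(side) for r in range(side)]
    return np.asarray(coords[:n], dtype=np.float64)


def _decode(value) -> str:
    if isinstance(value, bytes):
        return value.decode("utf-8")
    if isinstance(value, np.ndarray):
        return _decode(value.reshape(-1)[0])
    return str(value)


def read_recording(path: str | os.PathLike, units: str = "seconds", sample_rate: float = 25000.0) -> Recording:
    """Read a recording from an HDF5 file.

    Parameters
    ----------
    path
        HDF5 file following the layout in the module docstring.
    units
        ``"seconds"`` (default) if ``/spikes`` holds seconds, or
        ``"samples"`` if it holds integer sample counts to be divided
        by ``sample_rate``.
    sample_rate
        Sampling rate in Hz, used only when ``units == "samples"``.

    Raises
    ------
    RecordingFormatError
        A required dataset is missing or the per-electrode counts do
        not sum to the total spike count.
    MetadataError
        The region label is not ``"CTX"`` or ``"HPC"``.
    SpikeDataError
        Per-electrode spike times are not strictly increasing.
    """
    if units not in ("seconds", "samples"):
        raise ValueError(f"unknown units {units!r}")
    with h5py.File(path, "r") as f:
        for name in ("spikes", "sCount", "epos", "names", "meta/region", "meta/age"):
            if name not in f:
                raise RecordingFormatError(f"missing required dataset /{name}")
        spikes = np.asarray(f["spikes"], dtype=np.float64).reshape(-1)
        counts = np.asarray(f["sCount"], dtype=np.int64).reshape(-1)
        epos = np.asarray(f["epos"], dtype=np.float64)
        names = [_decode(x) for x in np.asarray(f["names"]).reshape(-1)]
        region = _decode(f["meta/region"][()])
        age = int(np.asarray(f["meta/age"][()]).reshape(-1)[0])
        array_id = _decode(f["array"][()]) if "array" in f else ""
        t_start = float(np.asarray(f["t_start"][()]).reshape(-1)[0]) if "t_start" in f else 0.0
        if "t_stop" in f:
            t_stop = float(np.asarray(f["t_stop"][()]).reshape(-1)[0])
        else:
            top = float(spikes.max()) if spikes.size else 0.0
            t_stop = max(t_start + DEFAULT_DURATION, top)

    if units == "samples":
        spikes = spikes / float(sample_rate)
    if counts.sum() != spikes.size:
        raise RecordingFormatError(
            f"/sCount sums to {counts.sum()} but /spikes holds {spikes.size} times"
        )
    if np.any(counts < 0):
        raise RecordingFormatError("/sCount contains negative counts")
    if epos.ndim != 2 or epos.shape[1] != 2 or epos.shape[0] != counts.size:
        raise RecordingFormatError("/epos must be N x 2 with one row per electrode")
    if len(names) != counts.size:
        raise RecordingFormatError("/names length does not match /sCount")
    if region not in REGIONS:
        raise MetadataError(f"region {region!r} not in {REGIONS}")

    bounds = np.concatenate([[0], np.cumsum(counts)])
    trains = []
    for i, label in enumerate(names):
        t = spikes[bounds[i] : bounds[i + 1]]
        if t.size and np.any(np.diff(t) <= 0):
            raise SpikeDataError(f"electrode {label}: spike times not strictly increasing")
        trains.append(SpikeTrain(t, t_start=t_start, t_stop=t_stop))
    return Recording(trains, epos, names, region, age, array_id)


def write_recording(rec: Recording, path: str | os.PathLike) -> str:
    """Write ``rec`` to ``path`` in the HDF5 layout; returns ``path``."""
    problems = validate_recording(rec)
    if problems:
        raise ValueError("invalid recording: " + "; ".join(problems))
    spikes = (
        np.concatenate([t.times for t in rec.trains])
        if rec.trains
        else np.empty(0, dtype=np.float64)
    )
    counts = np.asarray([t.n_spikes for t in rec.trains], dtype=np.int64)
    str_dt = h5py.string_dtype(encoding="utf-8")
    with h5py.File(path, "w") as f:
        f.create_dataset("spikes", data=spikes, dtype=np.float64)
        f.create_dataset("sCount", data=counts)
        f.create_dataset("epos", data=rec.positions, dtype=np.float64)
        f.create_dataset("names", data=np.asarray(rec.labels, dtype=object), dtype=str_dt)
        f.create_dataset("array", data=rec.array_id, dtype=str_dt)
        f.create_dataset("t_start", data=rec.t_start)
        f.create_dataset("t_stop", data=rec.t_stop)
        meta = f.create_group("meta")
        meta.create_dataset("region", data=rec.region, dtype=str_dt)
        meta.create_dataset("age", data=int(rec.age_div))
    return os.fspath(path)


def validate_recording(rec: Recording) -> list[str]:
    """Return a list of invariant violations (empty when valid).

    Never raises on invalid data; each entry is a human-readable
    description naming the offending electrode where applicable.
    """
    out: list[str] = []
    n = len(rec.trains)
    if n == 0:
        out.append("recording has no electrodes")
        return out
    if rec.positions.shape[0] != n:
        out.append(f"{rec.positions.shape[0]} positions for {n} trains")
    if len(rec.labels) != n:
        out.append(f"{len(rec.labels)} labels for {n} trains")
    if rec.region not in REGIONS:
        out.append(f"region {rec.region!r} not in {REGIONS}")
    starts = {t.t_start for t in rec.trains}
    stops = {t.t_stop for t in rec.trains}
    if len(starts) > 1 or len(stops) > 1:
        out.append("trains do not share a common recording interval")
    for i, train in enumerate(rec.trains):
        label = rec.labels[i] if i < len(rec.labels) else f"#{i}"
        for v in train.violations():
            out.append(f"electrode {label}: {v}")
    return out


def filter_min_spikes(rec: Recording, min_spikes: int) -> Recording:
    """Drop electrodes with fewer than ``min_spikes`` spikes.

    Off by default throughout the pipeline: silent electrodes are kept
    because they enter denominators such as the theta fraction.
    """
    keep = [i for i, t in enumerate(rec.trains) if t.n_spikes >= min_spikes]
    return replace(
        rec,
        trains=[rec.trains[i] for i in keep],
        positions=rec.positions[keep],
        labels=[rec.labels[i] for i in keep],
    )
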