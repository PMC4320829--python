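"""Array-wide population activity: active-electrode counts and network spikes.

Time is divided into small bins (3 ms by default) and the number of
electrodes with at least one spike in each bin is counted.  A network
spike is a maximal run of consecutive bins whose count strictly
exceeds a threshold (10 electrodes by default); its duration is the
run length times the bin width and its peak is the maximum count in
the run.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from meadev.spike_io import Recording

__all__ = [
    "ActivityCounts",
    "NetworkSpike",
    "NetworkSpikeSet",
    "count_active",
    "detect_network_spikes",
    "network_spike_summary",
]

DEFAULT_BIN_WIDTH = 0.003
DEFAULT_THRESHOLD = 10


@dataclass(frozen=True)
class ActivityCounts:
    """Number of active electrodes per time bin."""

    bin_width: float
    counts: np.ndarray
    t_start: float

    @property
    def n_bins(self) -> int:
        return int(self.counts.size)


class NetworkSpike(NamedTuple):
    onset: float
    offset: float
    peak: int

    @property
    def duration(self) -> float:
        return self.offset - self.onset


@dataclass(frozen=True)
class NetworkSpikeSet:
    events: tuple[NetworkSpike, ...]
    threshold: int
    bin_width: float

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)


def count_active(rec: Recording, bin_width: float = DEFAULT_BIN_WIDTH) -> ActivityCounts:
    """Count electrodes active in each bin of width ``bin_width`` seconds.

    An electrode contributes at most 1 to a bin however many spikes it
    fires there.  A trailing partial bin is dropped so all bins have
    equal width.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    t0 = rec.t_start
    n_bins = int(math.floor(rec.duration / bin_width))
    counts = np.zeros(n_bins, dtype=np.int64)
    for train in rec.trains:
        if train.n_spikes == 0:
            continue
        idx = np.floor((train.times - t0) / bin_width).astype(np.int64)
        idx = np.unique(idx[(idx >= 0) & (idx < n_bins)])
        counts[idx] += 1
    return ActivityCounts(bin_width=bin_width, counts=counts, t_start=t0)


def detect_network_spikes(ac: ActivityCounts, threshold: int = DEFAULT_THRESHOLD) -> NetworkSpikeSet:
    """Find maximal runs of bins with count strictly above ``threshold``.

    "More than a threshold number of electrodes" is read strictly:
    a bin belongs to an event iff ``count > threshold``.  Events
    separated by a single sub-threshold bin are not merged.
    """
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    above = ac.counts > threshold
    events: list[NetworkSpike] = []
    if above.any():
        padded = np.concatenate([[False], above, [False]])
        edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
        starts, stops = edges[::2], edges[1::2]  # stop is one past the last bin
        for s, e in zip(starts, stops):
            events.append(
                NetworkSpike(
                    onset=ac.t_start + s * ac.bin_width,
                    offset=ac.t_start + e * ac.bin_width,
                    peak=int(ac.counts[s:e].max()),
                )
            )
    return NetworkSpikeSet(tuple(events), threshold=threshold, bin_width=ac.bin_width)


def network_spike_summary(ns: NetworkSpikeSet, duration: float) -> dict[str, float]:
    """Array-level network-spike statistics (features 7-9).

    ``ns_rate`` is events per minute; ``ns_peak`` and ``ns_duration``
    are medians over events and NaN when there are no events.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    out = {
        "ns_rate": len(ns) / (duration / 60.0),
        "ns_peak": math.nan,
        "ns_duration": math.nan,
    }
    if len(ns):
        out["ns_peak"] = float(np.median([e.peak for e in ns]))
        out["ns_duration"] = float(np.median([e.duration for e in ns]))
    return out
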