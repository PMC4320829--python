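"""Pairwise spike-time tiling coefficient (STTC) and the array mean.

For trains A and B on a common interval, with coincidence window dt:

* ``T_A`` — fraction of the interval covered by the union of
  ``[t - dt, t + dt]`` windows around A's spikes (clipped to the
  interval);
* ``P_A`` — fraction of A's spikes lying within dt of some spike of B
  (closed interval: ``|ta - tb| <= dt`` counts);

and symmetrically for B.  The coefficient is

    0.5 * ((P_A - T_B) / (1 - P_A * T_B) + (P_B - T_A) / (1 - P_B * T_A)).

A degenerate denominator can only arise with ``P = T = 1``, where the
term is 0/0 and taken as 0.  Pairs involving an empty train are
undefined (NaN) and excluded from the array mean.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from meadev.spike_io import Recording, SpikeTrain

__all__ = ["PairCorrelation", "sttc", "pairwise_correlations", "mean_correlation"]

DEFAULT_DT = 0.005


@dataclass(frozen=True)
class PairCorrelation:
    electrode_i: str
    electrode_j: str
    distance: float
    sttc: float

    @property
    def defined(self) -> bool:
        return not math.isnan(self.sttc)


def _tiled_fraction(times: np.ndarray, dt: float, t_start: float, t_stop: float) -> float:
    """Fraction of [t_start, t_stop] covered by the union of +/-dt tiles."""
    starts = np.maximum(times - dt, t_start)
    ends = np.minimum(times + dt, t_stop)
    covered = float(np.sum(ends - starts))
    if times.size > 1:
        overlap = np.clip(ends[:-1] - starts[1:], 0.0, None)
        covered -= float(np.sum(overlap))
    return covered / (t_stop - t_start)


def _proportion_coincident(a: np.ndarray, b: np.ndarray, dt: float) -> float:
    """Fraction of spikes in ``a`` within dt (inclusive) of a spike in ``b``."""
    idx = np.searchsorted(b, a)
    near = np.full(a.size, np.inf)
    left = idx > 0
    near[left] = a[left] - b[idx[left] - 1]
    right = idx < b.size
    near[right] = np.minimum(near[right], b[idx[right]] - a[right])
    return float(np.mean(near <= dt))


def sttc(a: SpikeTrain, b: SpikeTrain, dt: float = DEFAULT_DT) -> float:
    """Spike-time tiling coefficient of two trains; NaN if either is empty."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    if (a.t_start, a.t_stop) != (b.t_start, b.t_stop):
        raise ValueError("trains must share the recording interval")
    if a.n_spikes == 0 or b.n_spikes == 0:
        return math.nan
    t_a = _tiled_fraction(a.times, dt, a.t_start, a.t_stop)
    t_b = _tiled_fraction(b.times, dt, b.t_start, b.t_stop)
    p_a = _proportion_coincident(a.times, b.times, dt)
    p_b = _proportion_coincident(b.times, a.times, dt)

    def term(p: float, t: float) -> float:
        denom = 1.0 - p * t
        if denom == 0.0:
            return 0.0  # only reachable with p == t == 1 (0/0)
        return (p - t) / denom

    return 0.5 * (term(p_a, t_b) + term(p_b, t_a))


def pairwise_correlations(rec: Recording, dt: float = DEFAULT_DT) -> list[PairCorrelation]:
    """STTC for every unordered electrode pair (N(N-1)/2 entries).

    Distances are Euclidean, from the recording's electrode positions
    (micrometres).  Pairs with an empty train carry ``sttc = NaN``.
    """
    n = rec.n_electrodes
    if n < 2:
        raise ValueError("need at least two electrodes")
    out: list[PairCorrelation] = []
    for i in range(n):
        for j in range(i + 1, n):
            d = float(np.linalg.norm(rec.positions[i] - rec.positions[j]))
            out.append(
                PairCorrelation(
                    electrode_i=rec.labels[i],
                    electrode_j=rec.labels[j],
                    distance=d,
                    sttc=sttc(rec.trains[i], rec.trains[j], dt),
                )
            )
    return out


def mean_correlation(pairs: list[PairCorrelation]) -> float:
    """Arithmetic mean of defined pair coefficients; NaN if none defined."""
    vals = [p.sttc for p in pairs if p.defined]
    if not vals:
        return math.nan
    return float(np.mean(vals))


def distance_profile(pairs: list[PairCorrelation], bin_width: float = 200.0) -> "np.ndarray":
    """Mean STTC binned by inter-electrode distance.

    Returns an array with columns (bin centre µm, mean STTC, n pairs);
    diagnostic output for distance-dependence plots.
    """
    defined = [p for p in pairs if p.defined]
    if not defined:
        return np.empty((0, 3))
    d = np.asarray([p.distance for p in defined])
    v = np.asarray([p.sttc for p in defined])
    idx = np.floor(d / bin_width).astype(int)
    rows = []
    for k in np.unique(idx):
        sel = idx == k
        rows.append(((k + 0.5) * bin_width, float(v[sel].mean()), int(sel.sum())))
    return np.asarray(rows)
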