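"""Assembly of the 11-feature description of a recording.

Feature order and electrode-to-array summarisation rules:

1.  ``firing_rate`` — median over *all* electrodes of spikes/duration
    (silent electrodes contribute 0 Hz);
2.  ``within_burst_rate`` — median over bursting electrodes of the mean
    within-burst firing rate;
3.  ``burst_rate`` — median over bursting electrodes, bursts/min;
4.  ``burst_duration`` — median over bursting electrodes, s;
5.  ``fraction_in_bursts`` — median over bursting electrodes;
6.  ``cv_ibi`` — median over electrodes with >= 2 interburst intervals;
7.  ``ns_rate`` — network spikes per minute;
8.  ``ns_peak`` — median network-spike peak electrode count;
9.  ``ns_duration`` — median network-spike duration, s;
10. ``mean_correlation`` — mean pairwise STTC over defined pairs;
11. ``theta_fraction`` — fraction of electrodes classed theta bursting.

Electrodes where a statistic is undefined (e.g. no bursts detected)
are excluded from medians; an array value with no defined electrode is
NaN, never silently 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from meadev import bursts as _bursts
from meadev import correlation as _correlation
from meadev import network_spikes as _ns
from meadev import theta as _theta
from meadev.spike_io import Recording

__all__ = [
    "FEATURE_NAMES",
    "AnalysisConfig",
    "FeatureVector",
    "summarise_electrodes",
    "feature_vector",
    "features_table",
]

FEATURE_NAMES = (
    "firing_rate",
    "within_burst_rate",
    "burst_rate",
    "burst_duration",
    "fraction_in_bursts",
    "cv_ibi",
    "ns_rate",
    "ns_peak",
    "ns_duration",
    "mean_correlation",
    "theta_fraction",
)

METADATA_COLUMNS = ("region", "age_div", "array_id")


@dataclass(frozen=True)
class AnalysisConfig:
    """All thresholds of the feature pipeline, with the standard defaults."""

    burst_params: _bursts.BurstParams = field(default_factory=_bursts.BurstParams)
    ibi_mode: str = "gap"
    merge_before_filter: bool = True
    bin_width: float = _ns.DEFAULT_BIN_WIDTH
    ns_threshold: int = _ns.DEFAULT_THRESHOLD
    sttc_dt: float = _correlation.DEFAULT_DT
    theta_band: tuple[float, float] = _theta.THETA_BAND
    min_isi: int = _theta.MIN_ISI


@dataclass(frozen=True)
class FeatureVector:
    """The 11 array-level features of one recording, plus metadata."""

    firing_rate: float
    within_burst_rate: float
    burst_rate: float
    burst_duration: float
    fraction_in_bursts: float
    cv_ibi: float
    ns_rate: float
    ns_peak: float
    ns_duration: float
    mean_correlation: float
    theta_fraction: float
    region: str = ""
    age_div: int = 0
    array_id: str = ""

    def values(self) -> np.ndarray:
        return np.asarray([getattr(self, k) for k in FEATURE_NAMES], dtype=float)

    def to_dict(self) -> dict:
        return asdict(self)


def summarise_electrodes(values, rule: str = "median") -> float:
    """Collapse per-electrode values to one array value.

    NaN entries (undefined electrodes) are dropped first; the summary
    of an all-undefined set is NaN.
    """
    if rule not in ("median", "mean"):
        raise ValueError(f"unknown rule {rule!r}")
    v = np.asarray(list(values), dtype=float)
    v = v[~np.isnan(v)]
    if v.size == 0:
        return math.nan
    return float(np.median(v) if rule == "median" else np.mean(v))


def feature_vector(rec: Recording, config: AnalysisConfig | None = None) -> FeatureVector:
    """Compute the 11-feature vector of one recording.

    Pure function of (recording, config): recomputation is
    bit-identical.  Undefined features propagate as NaN without failing
    the rest of the vector.
    """
    if config is None:
        config = AnalysisConfig()

    rates = [t.firing_rate for t in rec.trains]

    per_electrode = []
    for train in rec.trains:
        bs = _bursts.detect_bursts(train, config.burst_params, config.merge_before_filter)
        per_electrode.append(_bursts.burst_statistics(train, bs, ibi_mode=config.ibi_mode))

    ac = _ns.count_active(rec, config.bin_width)
    ns_set = _ns.detect_network_spikes(ac, config.ns_threshold)
    ns = _ns.network_spike_summary(ns_set, rec.duration)

    if rec.n_electrodes >= 2:
        pairs = _correlation.pairwise_correlations(rec, config.sttc_dt)
        mean_corr = _correlation.mean_correlation(pairs)
    else:
        mean_corr = math.nan

    frac_theta = _theta.theta_fraction(rec, band=config.theta_band, min_isi=config.min_isi)

    return FeatureVector(
        firing_rate=summarise_electrodes(rates),
        within_burst_rate=summarise_electrodes(s["within_burst_rate"] for s in per_electrode),
        burst_rate=summarise_electrodes(s["burst_rate"] for s in per_electrode),
        burst_duration=summarise_electrodes(s["mean_duration"] for s in per_electrode),
        fraction_in_bursts=summarise_electrodes(s["fraction_in_bursts"] for s in per_electrode),
        cv_ibi=summarise_electrodes(s["cv_ibi"] for s in per_electrode),
        ns_rate=ns["ns_rate"],
        ns_peak=ns["ns_peak"],
        ns_duration=ns["ns_duration"],
        mean_correlation=mean_corr,
        theta_fraction=frac_theta,
        region=rec.region,
        age_div=rec.age_div,
        array_id=rec.array_id,
    )


def features_table(recordings, config: AnalysisConfig | None = None) -> pd.DataFrame:
    """Tidy table: one row per recording, 11 feature columns + metadata.

    This is the interchange format consumed by the group-comparison and
    classification stages.
    """
    rows = [feature_vector(r, config).to_dict() for r in recordings]
    df = pd.DataFrame(rows)
    return df[list(FEATURE_NAMES) + list(METADATA_COLUMNS)]
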