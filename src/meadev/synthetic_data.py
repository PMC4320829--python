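"""Synthetic MEA recordings with controllable burst, theta and network structure.

Spike trains are built from three superposed sources:

* tonic background firing (homogeneous Poisson);
* burst events whose onsets follow a renewal process with
  gamma-distributed intervals (mean ``60 / burst_rate`` s, coefficient
  of variation ``ibi_cv``), each emitting a Poisson-distributed number
  of spikes with exponential within-burst intervals — or, for
  theta-modulated trains, lognormal intervals whose log-ISI density
  peaks near 0.15 s;
* for recordings, a master burst schedule shared across electrodes:
  each electrode moves a fraction of its own bursts onto the nearest
  master onset (plus jitter), which yields network spikes and
  distance-independent pairwise correlations while preserving the
  planted burst count and interval regularity.

Theta-modulated trains emit their burst spikes as short fast packets
separated by theta-band gaps (lognormal, median 0.15 s), so the
log-ISI density develops a peak inside 0.1-0.25 s while bursts remain
detectable by a max-interval detector.

Per-electrode random streams are split deterministically from the
master seed (``SeedSequence(seed, spawn_key=(electrode + 1,))``), so
changing the electrode count never reshuffles other electrodes.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from meadev.spike_io import Recording, SpikeTrain, default_positions

__all__ = [
    "TrainParams",
    "NetworkParams",
    "generate_train",
    "generate_recording",
    "preset_profile",
    "simulate_recording",
]

#: Median theta-band gap between spike packets, seconds.
THETA_MEDIAN_ISI = 0.15
#: Lognormal sigma (natural-log scale) keeping the log-ISI peak in 0.1-0.25 s.
THETA_SIGMA = 0.15
#: Probability that a within-burst interval of a theta train is a theta gap
#: (the rest are fast packet intervals at ``within_burst_rate``).
THETA_GAP_P = 0.5


@dataclass(frozen=True)
class TrainParams:
    """Statistical knobs of one synthetic spike train."""

    background_rate: float = 0.25  # Hz, tonic Poisson firing
    burst_rate: float = 10.0  # bursts per minute
    ibi_cv: float = 0.5  # CV of interburst (onset-to-onset) intervals
    spikes_per_burst: float = 8.0  # mean spikes per burst event
    within_burst_rate: float = 60.0  # Hz inside a burst (non-theta trains)
    theta: bool = False  # theta-band within-burst ISIs when True
    jitter_sd: float = 0.005  # s, jitter applied to shared master bursts

    def __post_init__(self) -> None:
        for name in ("background_rate", "burst_rate", "spikes_per_burst", "jitter_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.burst_rate > 0 and self.ibi_cv < 0:
            raise ValueError("ibi_cv must be >= 0")
        if self.within_burst_rate <= 0:
            raise ValueError("within_burst_rate must be positive")


@dataclass(frozen=True)
class NetworkParams:
    """Array-level knobs of a synthetic recording."""

    n_electrodes: int = 59
    duration: float = 900.0  # seconds
    participation_p: float = 1.0  # probability an electrode joins a master burst
    shared_fraction: float = 0.0  # fraction of bursts drawn from the master process
    theta_fraction: float | None = None  # None: use TrainParams.theta everywhere
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_electrodes < 1:
            raise ValueError("n_electrodes must be >= 1")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        for name in ("participation_p", "shared_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.theta_fraction is not None and not 0.0 <= self.theta_fraction <= 1.0:
            raise ValueError("theta_fraction must lie in [0, 1]")


def _renewal_times(rng: np.random.Generator, rate_per_s: float, cv: float, duration: float) -> np.ndarray:
    """Event times of a gamma-renewal process on [0, duration]."""
    if rate_per_s <= 0:
        return np.empty(0)
    mean = 1.0 / rate_per_s
    out: list[float] = []
    t = 0.0
    while True:
        if cv == 0.0:
            iv = mean
        else:
            shape = 1.0 / (cv * cv)
            iv = float(rng.gamma(shape, mean / shape))
        t += iv
        if t > duration:
            break
        out.append(t)
    return np.asarray(out)


def _burst_spikes(rng: np.random.Generator, onset: float, p: TrainParams) -> np.ndarray:
    n = int(rng.poisson(p.spikes_per_burst))
    if n <= 0:
        return np.empty(0)
    if n == 1:
        return np.asarray([onset])
    if p.theta:
        # fast packets separated by theta-band gaps: the concentrated
        # lognormal gap component dominates the log-ISI density peak
        fast = rng.exponential(1.0 / p.within_burst_rate, n - 1)
        slow = rng.lognormal(np.log(THETA_MEDIAN_ISI), THETA_SIGMA, n - 1)
        isis = np.where(rng.random(n - 1) < THETA_GAP_P, slow, fast)
    else:
        isis = rng.exponential(1.0 / p.within_burst_rate, n - 1)
    return onset + np.concatenate([[0.0], np.cumsum(isis)])


def _assemble(parts: list[np.ndarray], duration: float) -> SpikeTrain:
    if parts:
        times = np.concatenate(parts)
        times = times[(times >= 0.0) & (times <= duration)]
        times = np.unique(times)
    else:
        times = np.empty(0)
    return SpikeTrain(times, t_start=0.0, t_stop=duration)


def generate_train(p: TrainParams, duration: float, seed) -> SpikeTrain:
    """One synthetic spike train on [0, duration]; bit-reproducible per seed."""
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(seed)
    parts: list[np.ndarray] = []
    for onset in _renewal_times(rng, p.burst_rate / 60.0, p.ibi_cv, duration):
        parts.append(_burst_spikes(rng, onset, p))
    if p.background_rate > 0:
        n_bg = int(rng.poisson(p.background_rate * duration))
        parts.append(rng.uniform(0.0, duration, n_bg))
    return _assemble(parts, duration)


def generate_recording(
    tp: TrainParams,
    net: NetworkParams,
    region: str = "CTX",
    age_div: int = 14,
    array_id: str = "synthetic",
) -> Recording:
    """Synthetic recording with a shared master burst schedule.

    Each electrode draws its own renewal burst schedule; every burst
    is then, with probability ``shared_fraction * participation_p``,
    moved onto the nearest master onset plus Gaussian jitter
    (``jitter_sd``).  Moving rather than superposing keeps the planted
    burst rate and interval regularity while aligning bursts across
    electrodes.  When ``theta_fraction`` is set, the first
    ``round(theta_fraction * n)`` electrodes emit theta-modulated
    bursts and the rest do not, overriding ``tp.theta``.
    """
    if net.n_electrodes < 2:
        raise ValueError("need at least two electrodes for a recording")
    master_rng = np.random.default_rng(np.random.SeedSequence(net.seed, spawn_key=(0,)))
    master = _renewal_times(master_rng, tp.burst_rate / 60.0, tp.ibi_cv, net.duration)

    if net.theta_fraction is None:
        n_theta = net.n_electrodes if tp.theta else 0
    else:
        n_theta = int(round(net.theta_fraction * net.n_electrodes))

    trains: list[SpikeTrain] = []
    for e in range(net.n_electrodes):
        rng = np.random.default_rng(np.random.SeedSequence(net.seed, spawn_key=(e + 1,)))
        pe = replace(tp, theta=e < n_theta)
        onsets = _renewal_times(rng, pe.burst_rate / 60.0, pe.ibi_cv, net.duration)
        if master.size and onsets.size:
            move = rng.random(onsets.size) < net.shared_fraction * net.participation_p
            if move.any():
                idx = np.clip(np.searchsorted(master, onsets[move]), 0, master.size - 1)
                left = np.maximum(idx - 1, 0)
                nearest = np.where(
                    np.abs(master[left] - onsets[move]) <= np.abs(master[idx] - onsets[move]),
                    master[left],
                    master[idx],
                )
                onsets = onsets.copy()
                onsets[move] = nearest + rng.normal(0.0, pe.jitter_sd, int(move.sum()))
                onsets = np.sort(onsets)
        parts = [_burst_spikes(rng, onset, pe) for onset in onsets]
        if pe.background_rate > 0:
            n_bg = int(rng.poisson(pe.background_rate * net.duration))
            parts.append(rng.uniform(0.0, net.duration, n_bg))
        trains.append(_assemble(parts, net.duration))

    labels = [f"E{e + 1:02d}" for e in range(net.n_electrodes)]
    return Recording(
        trains=trains,
        positions=default_positions(net.n_electrodes),
        labels=labels,
        region=region,
        age_div=age_div,
        array_id=array_id,
    )


def preset_profile(region: str, age_div: int) -> tuple[TrainParams, NetworkParams]:
    """Parameter presets emulating HPC-like and CTX-like cultures by age.

    The presets encode only ordinal structure: relative to CTX at the
    same age, HPC presets have lower interburst-interval CV, a majority
    of theta-modulated electrodes at maturity, and a larger shared-burst
    fraction (hence higher correlations and more network spikes); burst
    rate and sharing ramp up from 7 to 14 days in vitro and then
    plateau.  Absolute magnitudes are conventions of this module, not
    measurements.
    """
    if region not in ("CTX", "HPC"):
        raise ValueError(f"unknown region {region!r}")
    if not 7 <= age_div <= 28:
        raise ValueError("age_div must lie in 7..28")
    ramp = min(1.0, max(0.0, (age_div - 7) / 7.0))
    if region == "CTX":
        tp = TrainParams(
            background_rate=0.25,
            burst_rate=4.0 + 8.0 * ramp,
            ibi_cv=0.9,
            spikes_per_burst=8.0,
            within_burst_rate=60.0,
            theta=False,
            jitter_sd=0.008,
        )
        net = NetworkParams(
            n_electrodes=59,
            duration=900.0,
            participation_p=0.8,
            shared_fraction=0.10 + 0.15 * ramp,
            theta_fraction=0.08,
            seed=0,
        )
    else:
        tp = TrainParams(
            background_rate=0.25,
            burst_rate=5.0 + 10.0 * ramp,
            ibi_cv=0.45,
            spikes_per_burst=10.0,
            within_burst_rate=80.0,
            theta=False,
            jitter_sd=0.003,
        )
        net = NetworkParams(
            n_electrodes=59,
            duration=900.0,
            participation_p=0.9,
            shared_fraction=0.30 + 0.30 * ramp,
            theta_fraction=0.10 + 0.50 * ramp,
            seed=0,
        )
    return tp, net


def simulate_recording(
    region: str,
    age_div: int,
    n_electrodes: int | None = None,
    duration: float | None = None,
    seed: int = 0,
    array_id: str | None = None,
) -> Recording:
    """Preset-driven recording generation (the CLI ``simulate`` backend)."""
    tp, net = preset_profile(region, age_div)
    overrides: dict = {"seed": seed}
    if n_electrodes is not None:
        overrides["n_electrodes"] = n_electrodes
    if duration is not None:
        overrides["duration"] = duration
    net = replace(net, **overrides)
    if array_id is None:
        array_id = f"sim-{region}-{age_div}div-{seed}"
    return generate_recording(tp, net, region=region, age_div=age_div, array_id=array_id)
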