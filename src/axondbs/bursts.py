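"""Synthetic intrinsic activity: thalamic burst trains and fixture trains.

The intrinsic drive emulates pathological thalamic bursting recorded in
tremor patients: bursts of a few spikes at a fast intra-burst rate
(243.40 +- 89.09 Hz) recurring at a slow inter-burst rhythm
(4.33 +- 0.06 Hz). The +- values are treated as across-fiber
variability: each fiber draws its inter-burst rate and its intra-burst rate
once, so within a fiber bursts are stereotyped, as produced by a
thalamocortical relay neuron in bursting mode. The number of spikes per
burst is drawn per burst; the default range (uniform 3..8) is calibrated so
the drive's firing-pattern entropy matches the ~1.49 bits/spike of the
emulated intrinsic activity.

Fixture trains (periodic, Poisson, alternating, two-state bursting) have
closed-form ISI-pair structure and serve as oracles for the entropy
estimator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .fiber import FiberGeometry

__all__ = [
    "BurstModelParams",
    "InjectionSchedule",
    "generate_burst_train",
    "burst_rate",
    "schedule_injection",
    "fixture_trains",
]

IntraBurstDraw = Literal["per_fiber", "per_burst", "per_isi"]


@dataclass(frozen=True)
class BurstModelParams:
    """Statistics of the intrinsic bursting pattern.

    Rates are in Hz (mean, sd). ``intraburst_draw`` controls where the
    intra-burst variability lives: across fibers (default), across bursts,
    or across individual ISIs.
    """

    interburst_rate_hz: tuple[float, float] = (4.33, 0.06)
    intraburst_rate_hz: tuple[float, float] = (243.40, 89.09)
    spikes_per_burst: tuple[int, int] = (3, 8)
    intraburst_draw: IntraBurstDraw = "per_fiber"
    epoch_ms: float = 1000.0
    seed: int | None = None

    def __post_init__(self):
        if self.interburst_rate_hz[0] <= 0 or self.intraburst_rate_hz[0] <= 0:
            raise ValueError("mean rates must be positive")
        if self.interburst_rate_hz[1] < 0 or self.intraburst_rate_hz[1] < 0:
            raise ValueError("rate sds must be >= 0")
        if self.spikes_per_burst[0] < 2:
            raise ValueError("bursts need >= 2 spikes")


def _truncated_normal(rng, mean, sd, floor, max_tries=1000):
    """Normal(mean, sd) resampled until > floor."""
    for _ in range(max_tries):
        x = rng.normal(mean, sd)
        if x > floor:
            return x
    raise RuntimeError("truncated normal draw exhausted; degenerate params")


def generate_burst_train(params: BurstModelParams,
                         rng: np.random.Generator | None = None) -> np.ndarray:
    """Spike times (ms, strictly increasing) of one intrinsic burst train.

    Burst onsets form a regular renewal process at a per-fiber rate drawn
    from Normal(4.33, 0.06) Hz; each burst contains spikes at a constant
    intra-burst ISI set by the fiber's (or burst's) intra-burst rate draw.
    The first burst onset is uniform within one inter-burst period so that
    trains from different fibers are desynchronized.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    if params.epoch_ms <= 0:
        return np.empty(0)

    f_inter = _truncated_normal(rng, *params.interburst_rate_hz, floor=0.1)
    period_ms = 1000.0 / f_inter
    # intra-burst rates below ~2x the inter-burst rhythm would be degenerate
    rate_floor = 20.0
    f_intra_fiber = _truncated_normal(rng, *params.intraburst_rate_hz,
                                      floor=rate_floor)
    lo, hi = params.spikes_per_burst

    times: list[float] = []
    onset = rng.uniform(0.0, period_ms)
    while onset < params.epoch_ms:
        if params.intraburst_draw == "per_fiber":
            f_intra = f_intra_fiber
        else:
            f_intra = _truncated_normal(rng, *params.intraburst_rate_hz,
                                        floor=rate_floor)
        n_spikes = int(rng.integers(lo, hi + 1))
        t = onset
        next_onset = onset + period_ms
        for k in range(n_spikes):
            # slow intra-burst draws must not run into the next burst
            if t >= params.epoch_ms or t >= next_onset - 1.0:
                break
            times.append(t)
            if params.intraburst_draw == "per_isi":
                f_intra = _truncated_normal(rng, *params.intraburst_rate_hz,
                                            floor=rate_floor)
            t += 1000.0 / f_intra
        onset += period_ms
    return np.asarray(times)


def burst_rate(spike_times_ms: np.ndarray, epoch_ms: float,
               gap_threshold_ms: float = 50.0) -> float:
    """Empirical burst rate (Hz): bursts delimited by ISI gaps > threshold.

    The 50 ms default sits between the intra-burst (~4 ms) and inter-burst
    (~230 ms) timescales.
    """
    t = np.asarray(spike_times_ms)
    if t.size == 0 or epoch_ms <= 0:
        return 0.0
    n_bursts = 1 + int(np.sum(np.diff(t) > gap_threshold_ms))
    return n_bursts / (epoch_ms * 1e-3)


@dataclass
class InjectionSchedule:
    """Intracellular pulse program initiating one spike per intended time.

    ``pulse_amplitude_na`` of None means "resolve at simulation time to
    2x the intracellular rheobase of the target fiber"; an array gives one
    amplitude per pulse.
    """

    spike_times_ms: np.ndarray
    pulse_amplitude_na: float | np.ndarray | None = None
    pulse_width_ms: float = 0.1
    injection_node: int = 0  # proximal end

    def __post_init__(self):
        t = np.asarray(self.spike_times_ms, dtype=float)
        if np.any(np.diff(t) <= 0):
            raise ValueError("spike times must be strictly increasing")
        self.spike_times_ms = t


def schedule_injection(spike_times_ms: np.ndarray, geom: FiberGeometry,
                       pulse_amplitude_na: float | None = None,
                       pulse_width_ms: float = 0.1,
                       refractory_ms: float = 1.0) -> InjectionSchedule:
    """Build the intracellular injection schedule for intended spike times."""
    t = np.asarray(spike_times_ms, dtype=float)
    if t.size and np.any(np.diff(t) < refractory_ms + pulse_width_ms):
        warnings.warn("inter-spike gaps shorter than refractory + pulse "
                      "width; some injected spikes may fail", stacklevel=2)
    return InjectionSchedule(t, pulse_amplitude_na, pulse_width_ms,
                             injection_node=0)


def fixture_trains(kind: str, params: dict | None = None,
                   seed: int | None = None) -> np.ndarray:
    """Analytic spike trains with known ISI-pair structure.

    kinds: 'periodic' (rate_hz, epoch_ms), 'poisson' (rate_hz, epoch_ms),
    'alternating' (isi_short_ms, isi_long_ms, n_spikes),
    'bursty_two_state' (isi_short_ms, isi_long_ms, spikes_per_burst,
    n_bursts): deterministic bursts, a two-state ISI alternation oracle.
    """
    p = dict(params or {})
    rng = np.random.default_rng(seed)
    if kind == "periodic":
        rate, epoch = p.get("rate_hz", 100.0), p.get("epoch_ms", 1000.0)
        if rate <= 0:
            raise ValueError("rate must be positive")
        period = 1000.0 / rate
        return np.arange(0.0, epoch, period)
    if kind == "poisson":
        rate, epoch = p.get("rate_hz", 100.0), p.get("epoch_ms", 1000.0)
        if rate <= 0:
            raise ValueError("rate must be positive")
        n = rng.poisson(rate * epoch * 1e-3)
        return np.sort(rng.uniform(0.0, epoch, size=n))
    if kind == "alternating":
        s, l = p.get("isi_short_ms", 5.0), p.get("isi_long_ms", 50.0)
        n = p.get("n_spikes", 101)
        isis = np.tile([s, l], n)[:n - 1]
        return np.concatenate([[0.0], np.cumsum(isis)])
    if kind == "bursty_two_state":
        s, l = p.get("isi_short_ms", 4.0), p.get("isi_long_ms", 220.0)
        k, nb = p.get("spikes_per_burst", 5), p.get("n_bursts", 20)
        isis = np.tile([s] * (k - 1) + [l], nb)[:-1]
        return np.concatenate([[0.0], np.cumsum(isis)])
    raise ValueError(f"unknown fixture kind {kind!r}")
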