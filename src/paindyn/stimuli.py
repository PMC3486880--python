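"""Thermal stimulation protocols.

Generators for the contact-thermode protocols the models are exercised on:
a pseudo-randomized *simple* train of nine rectangular heat pulses, a fixed
*complex* three-pulse pattern with small superimposed temperature kinks, and
two offset-analgesia series (variable fall rates; constant / +1 °C-offset /
return-to-baseline triples).  All traces are piecewise-linear temperature
profiles sampled on a uniform grid, with every transition ramped at the
thermode slew rate (about 8 °C/s).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .traces import StimulusTrace

__all__ = [
    "ProtocolSpec",
    "simple_stimulus",
    "complex_stimulus",
    "offset_rate_series",
    "offset_perturbation_series",
    "supra_threshold_intervals",
]


@dataclass(frozen=True)
class ProtocolSpec:
    """Shared protocol constants.

    baseline_C: skin-adaptation baseline temperature (°C).
    ramp_rate_C_per_s: thermode rise/fall slew rate (°C/s).
    dt: sample spacing of the generated trace (s); 0.1 s resolves an
        8 °C/s ramp over a 10 °C excursion with >10 samples.
    seed: RNG seed for pseudo-randomized protocols.
    """

    baseline_C: float = 35.0
    ramp_rate_C_per_s: float = 8.0
    dt: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.ramp_rate_C_per_s <= 0:
            raise ValueError("ramp_rate must be positive")
        if self.dt <= 0:
            raise ValueError("dt must be positive")


def _snap(duration: float, dt: float, up: bool = False) -> float:
    """Snap a duration to the sample grid (ceil for ramps so the slew rate
    is never exceeded; round for holds)."""
    k = duration / dt
    k = math.ceil(k - 1e-9) if up else round(k)
    return max(1, k) * dt


class _Profile:
    """Piecewise-linear keypoint builder with rate-limited transitions."""

    def __init__(self, spec: ProtocolSpec):
        self.spec = spec
        self.t = [0.0]
        self.T = [spec.baseline_C]

    def hold(self, duration: float):
        d = _snap(duration, self.spec.dt)
        self.t.append(self.t[-1] + d)
        self.T.append(self.T[-1])
        return self

    def ramp_to(self, level: float, rate: float | None = None):
        rate = self.spec.ramp_rate_C_per_s if rate is None else rate
        jump = abs(level - self.T[-1])
        if jump > 0:
            d = _snap(jump / rate, self.spec.dt, up=True)
            self.t.append(self.t[-1] + d)
            self.T.append(level)
        return self

    def pulse(self, peak: float, duration: float):
        return self.ramp_to(peak).hold(duration).ramp_to(self.spec.baseline_C)

    def build(self) -> StimulusTrace:
        dt = self.spec.dt
        n = int(round(self.t[-1] / dt)) + 1
        grid = dt * np.arange(n)
        return StimulusTrace(grid, np.interp(grid, self.t, self.T))


#: peak temperatures of the simple protocol (°C), three pulses each
SIMPLE_PEAKS_C = (45.0, 47.0, 49.0)
#: pulse plateau duration range of the simple protocol (s)
SIMPLE_DURATION_RANGE_S = (10.0, 40.0)
#: inter-stimulus interval range (s); the protocol description says only
#: "pseudo-randomized", this range keeps run length near the published traces
SIMPLE_ISI_RANGE_S = (20.0, 40.0)


def simple_stimulus(spec: ProtocolSpec = ProtocolSpec()) -> StimulusTrace:
    """Pseudo-randomized simple protocol: nine rectangular heat pulses.

    From a 35 °C baseline, nine supra-threshold pulses with peak temperatures
    45, 47 and 49 °C (three pulses each, order shuffled), plateau durations
    uniform on [10, 40] s and inter-stimulus intervals uniform on [20, 40] s,
    all drawn from ``spec.seed``.  Transitions are ramped at the slew rate.
    """
    rng = np.random.default_rng(spec.seed)
    peaks = np.repeat(SIMPLE_PEAKS_C, 3)
    rng.shuffle(peaks)
    durations = rng.uniform(*SIMPLE_DURATION_RANGE_S, size=9)
    isis = rng.uniform(*SIMPLE_ISI_RANGE_S, size=8)

    prof = _Profile(spec)
    prof.hold(20.0)  # lead-in baseline
    for i, (peak, dur) in enumerate(zip(peaks, durations)):
        prof.pulse(peak, dur)
        if i < 8:
            prof.hold(isis[i])
    prof.hold(20.0)  # tail baseline
    return prof.build()


def complex_stimulus(spec: ProtocolSpec = ProtocolSpec()) -> StimulusTrace:
    """Deterministic complex protocol: three pulses with 1 °C kinks.

    35 °C baseline for 30 s; pulse 1: 47 °C for 5 s, +1 °C to 48 °C for 5 s,
    back to 47 °C for 20 s; 50 s baseline; pulse 2: 47 °C for 35 s; 60 s
    baseline; pulse 3: 47 °C for 5 s then 48 °C for 5 s; return to baseline.
    """
    b = spec.baseline_C
    prof = _Profile(spec)
    prof.hold(30.0)
    prof.ramp_to(47.0).hold(5.0).ramp_to(48.0).hold(5.0).ramp_to(47.0).hold(20.0)
    prof.ramp_to(b).hold(50.0)
    prof.ramp_to(47.0).hold(35.0)
    prof.ramp_to(b).hold(60.0)
    prof.ramp_to(47.0).hold(5.0).ramp_to(48.0).hold(5.0)
    prof.ramp_to(b).hold(30.0)
    return prof.build()


def offset_rate_series(
    fall_rates,
    spec: ProtocolSpec = ProtocolSpec(),
    plateau_C: float = 47.0,
    plateau_s: float = 20.0,
) -> list[StimulusTrace]:
    """One trace per fall rate: common rise and plateau, variable descent.

    Each trace rises at the protocol slew rate from baseline to ``plateau_C``,
    holds for ``plateau_s``, then falls back to baseline at the given rate
    (°C/s).  Used to probe offset-analgesia insensitivity to slow falls.
    """
    fall_rates = list(fall_rates)
    if any(r <= 0 for r in fall_rates):
        raise ValueError("fall rates must be positive")
    out = []
    for rate in fall_rates:
        prof = _Profile(spec)
        prof.hold(10.0)
        prof.ramp_to(plateau_C).hold(plateau_s)
        prof.ramp_to(spec.baseline_C, rate=rate)
        prof.hold(20.0)
        out.append(prof.build())
    return out


def offset_perturbation_series(
    plateaus,
    spec: ProtocolSpec = ProtocolSpec(),
    window_s: float = 30.0,
    excursion_onset_s: float = 15.0,
    excursion_s: float = 5.0,
) -> list[tuple[StimulusTrace, StimulusTrace, StimulusTrace]]:
    """Constant / offset / return-to-baseline triples per plateau level.

    For each plateau temperature ``X`` (> baseline) three traces are built
    over the same window: (a) constant ``X`` for the full window; (b) ``X``
    with a +1 °C excursion of ``excursion_s`` starting at
    ``excursion_onset_s``; (c) ``X`` held until ``excursion_onset_s`` then an
    early return to baseline.  Window timings are reconstruction defaults and
    fully overridable.
    """
    plateaus = list(plateaus)
    if any(x <= spec.baseline_C for x in plateaus):
        raise ValueError("plateau temperatures must exceed the baseline")
    triples = []
    for x in plateaus:
        const = _Profile(spec)
        const.hold(10.0).ramp_to(x).hold(window_s).ramp_to(spec.baseline_C).hold(15.0)

        offset = _Profile(spec)
        offset.hold(10.0).ramp_to(x).hold(excursion_onset_s)
        offset.ramp_to(x + 1.0).hold(excursion_s).ramp_to(x)
        offset.hold(window_s - excursion_onset_s - excursion_s)
        offset.ramp_to(spec.baseline_C).hold(15.0)

        early = _Profile(spec)
        early.hold(10.0).ramp_to(x).hold(excursion_onset_s)
        early.ramp_to(spec.baseline_C).hold(15.0 + (window_s - excursion_onset_s))

        triples.append((const.build(), offset.build(), early.build()))
    return triples


def supra_threshold_intervals(trace: StimulusTrace, threshold_C: float = 44.0):
    """Maximal intervals where T ≥ threshold, as (t_on, t_off) pairs.

    Convenience for counting pulses and measuring plateau durations.
    """
    above = trace.T >= threshold_C
    edges = np.diff(above.astype(int))
    starts = list(np.nonzero(edges == 1)[0] + 1)
    stops = list(np.nonzero(edges == -1)[0] + 1)
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        stops.append(len(trace))
    return [(trace.t[i], trace.t[j - 1]) for i, j in zip(starts, stops)]
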