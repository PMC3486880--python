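"""Forward simulation of the perception models.

The core model treats the perceived pain magnitude P(t) as the state of a
second-order dynamical system driven by the skin temperature T(t):

    d²P/dt² = k1·max(0, T − T0) − γ·dP/dt + k2·(dT/dt − Tc)·P,   P ≥ 0.

The three right-hand-side terms are (i) a thresholded temperature forcing (a
ramp in T taking effect above the pain threshold T0), (ii) a "forgetting"
decay with rate γ, and (iii) a rate-dependent restoring/driving force: when
the temperature falls quickly the term pushes perception down faster than
decay alone would (the substrate of offset analgesia), while fast rises
accelerate it.  Non-negativity is enforced with a reflecting clamp.

Dropping the acceleration term and neglecting fast temperature changes
reduces this to a leaky integrator,

    dP/dt = A·max(0, T − T0) − P/τ,

with a single time constant for rise and fall.  A power-law variant raises
the supra-threshold drive to an exponent δ, and a two-time-constant variant
sums a fast and a slow leaky process (myelinated/unmyelinated afferents).
Two null predictors — perception proportional to temperature, and to
temperature above a threshold — complete the model set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields

import numpy as np

from . import _integrators as _ker
from .traces import RatingTrace, StimulusTrace, TraceError, derivative

__all__ = [
    "SecondOrderParams",
    "FirstOrderParams",
    "PowerLawParams",
    "TwoTauParams",
    "SimState",
    "ramp_forcing",
    "simulate_second_order",
    "simulate_first_order",
    "simulate_power_law",
    "simulate_two_tau",
    "simulate",
    "predict_linear",
    "predict_threshold_linear",
    "MODEL_KINDS",
    "DEFAULT_MAX_STEP",
]

#: default ceiling on the effective RK4 step (seconds)
DEFAULT_MAX_STEP = 0.05


def _check_finite(obj):
    for f in fields(obj):
        v = getattr(obj, f.name)
        if not math.isfinite(v):
            raise ValueError(f"{type(obj).__name__}.{f.name} must be finite")


@dataclass(frozen=True)
class SecondOrderParams:
    """Constants of the second-order model.

    k1 : forcing gain (rating·s⁻²·°C⁻¹), ≥ 0
    gamma : decay ("forgetting") rate (s⁻¹), ≥ 0
    k2 : restoring/driving gain (°C⁻¹·s⁻¹), applied as k2·(dT/dt − Tc)·P, ≥ 0
    T0 : temperature threshold (°C), within [30, 55]
    Tc : temperature-rate threshold (°C/s) above which changes are alarming
    """

    k1: float
    gamma: float
    k2: float
    T0: float
    Tc: float

    def __post_init__(self):
        _check_finite(self)
        if self.k1 < 0 or self.gamma < 0 or self.k2 < 0:
            raise ValueError("k1, gamma and k2 must be non-negative")
        if not 30.0 <= self.T0 <= 55.0:
            raise ValueError("T0 must lie within [30, 55] °C")


@dataclass(frozen=True)
class FirstOrderParams:
    """Constants of the first-order (leaky-integrator) reduction.

    A : forcing gain (rating·s⁻¹·°C⁻¹), ≥ 0
    tau : time constant (s), > 0 — shared by rise and fall
    T0 : temperature threshold (°C)
    """

    A: float
    tau: float
    T0: float

    def __post_init__(self):
        _check_finite(self)
        if self.A < 0:
            raise ValueError("A must be non-negative")
        if self.tau <= 0:
            raise ValueError("tau must be positive")


@dataclass(frozen=True)
class PowerLawParams:
    """First-order model with the supra-threshold drive raised to ``delta``."""

    A: float
    tau: float
    T0: float
    delta: float

    def __post_init__(self):
        _check_finite(self)
        if self.tau <= 0:
            raise ValueError("tau must be positive")


@dataclass(frozen=True)
class TwoTauParams:
    """Fast + slow leaky processes sharing one threshold; P = P_fast + P_slow."""

    A_fast: float
    tau_fast: float
    A_slow: float
    tau_slow: float
    T0: float

    def __post_init__(self):
        _check_finite(self)
        if not 0 < self.tau_fast < self.tau_slow:
            raise ValueError("need 0 < tau_fast < tau_slow (strictly)")


@dataclass(frozen=True)
class SimState:
    """Initial state of the second-order integrator."""

    P: float = 0.0
    dP: float = 0.0

    def __post_init__(self):
        if self.P < 0:
            raise ValueError("initial P must be non-negative")


# demonstration defaults for tests/demos (not estimates from any dataset)
DEFAULT_SECOND = SecondOrderParams(k1=0.4, gamma=0.8, k2=0.08, T0=45.0, Tc=0.5)
DEFAULT_FIRST = FirstOrderParams(A=1.2, tau=5.0, T0=45.0)

MODEL_KINDS = ("second", "first", "power", "twotau", "linear", "threshlin")


def ramp_forcing(T, T0):
    """Supra-threshold drive max(0, T − T0): zero below threshold, linear above."""
    return np.maximum(0.0, np.asarray(T, dtype=float) - T0)


# ---------------------------------------------------------------------------
# grid preparation
# ---------------------------------------------------------------------------

def _fine_grid(stim: StimulusTrace, max_step: float):
    """Subdivide the stimulus grid so the RK4 step is ≤ max_step.

    Returns (Tf, dTf, n_sub, h): temperature and its central-difference
    derivative linearly interpolated onto the fine grid.
    """
    dt = stim.dt
    n_sub = max(1, int(math.ceil(dt / max_step - 1e-12)))
    h = dt / n_sub
    nf = (len(stim) - 1) * n_sub + 1
    tf = stim.t[0] + h * np.arange(nf)
    Tf = np.interp(tf, stim.t, stim.T)
    dT = derivative(stim)
    dTf = np.interp(tf, stim.t, dT)
    return Tf, dTf, n_sub, h


def _midpoints(stim: StimulusTrace) -> np.ndarray:
    return 0.5 * (stim.T[:-1] + stim.T[1:])


# ---------------------------------------------------------------------------
# simulators
# ---------------------------------------------------------------------------

def simulate_second_order(
    params: SecondOrderParams,
    stim: StimulusTrace,
    init: SimState = SimState(),
    max_step: float = DEFAULT_MAX_STEP,
) -> RatingTrace:
    """Integrate the second-order model on the stimulus grid.

    Classical fixed-step RK4 with automatic substepping (effective step
    ≤ ``max_step``); the non-negativity clamp is applied after every substep.
    dT/dt is the central-difference derivative of the supplied stimulus, so
    measured and generated stimuli are treated identically.
    """
    Tf, dTf, n_sub, h = _fine_grid(stim, max_step)
    P = _ker.rk4_second_traj(
        params.k1, params.gamma, params.k2, params.T0, params.Tc,
        Tf, dTf, n_sub, h, float(init.P), float(init.dP),
    )
    return RatingTrace(stim.t, P)


def simulate_first_order(
    params: FirstOrderParams, stim: StimulusTrace, P0: float = 0.0
) -> RatingTrace:
    """Integrate dP/dt = A·max(0, T−T0) − P/τ.

    Exact exponential-integrator update per step with the temperature held
    at the step-midpoint value, so constant-drive segments are reproduced to
    machine precision.
    """
    if P0 < 0:
        raise ValueError("P0 must be non-negative")
    P = _ker.leaky_traj(params.A, params.tau, params.T0, 1.0,
                        _midpoints(stim), stim.dt, float(P0))
    return RatingTrace(stim.t, P)


def simulate_power_law(
    params: PowerLawParams, stim: StimulusTrace, P0: float = 0.0
) -> RatingTrace:
    """Integrate dP/dt = A·max(0, T−T0)^δ − P/τ.

    δ = 1 reduces exactly to :func:`simulate_first_order`; the drive at
    exactly T = T0 is defined as 0 (limit from below), so negative exponents
    never hit 0^δ.
    """
    if P0 < 0:
        raise ValueError("P0 must be non-negative")
    P = _ker.leaky_traj(params.A, params.tau, params.T0, params.delta,
                        _midpoints(stim), stim.dt, float(P0))
    return RatingTrace(stim.t, P)


def simulate_two_tau(
    params: TwoTauParams, stim: StimulusTrace,
    P0_fast: float = 0.0, P0_slow: float = 0.0,
) -> RatingTrace:
    """Two independent leaky processes sharing T0; output is their sum."""
    if P0_fast < 0 or P0_slow < 0:
        raise ValueError("initial states must be non-negative")
    mids = _midpoints(stim)
    Pf = _ker.leaky_traj(params.A_fast, params.tau_fast, params.T0, 1.0,
                         mids, stim.dt, float(P0_fast))
    Ps = _ker.leaky_traj(params.A_slow, params.tau_slow, params.T0, 1.0,
                         mids, stim.dt, float(P0_slow))
    return RatingTrace(stim.t, Pf + Ps)


def predict_linear(stim: StimulusTrace) -> RatingTrace:
    """Null predictor: perception follows temperature, P̂(t) = T(t).

    Scale-free under Pearson r; SSE evaluation applies a fitted gain in the
    fitting module.
    """
    return RatingTrace(stim.t, stim.T.copy())


def predict_threshold_linear(stim: StimulusTrace, T0: float) -> RatingTrace:
    """Null predictor: perception follows temperature above a threshold."""
    return RatingTrace(stim.t, ramp_forcing(stim.T, T0))


def simulate(kind: str, params, stim: StimulusTrace, **kw) -> RatingTrace:
    """Dispatch a forward simulation by model kind."""
    if kind == "second":
        return simulate_second_order(params, stim, **kw)
    if kind == "first":
        return simulate_first_order(params, stim, **kw)
    if kind == "power":
        return simulate_power_law(params, stim, **kw)
    if kind == "twotau":
        return simulate_two_tau(params, stim, **kw)
    if kind == "linear":
        return predict_linear(stim)
    if kind == "threshlin":
        return predict_threshold_linear(stim, params.T0 if hasattr(params, "T0") else float(params))
    raise ValueError(f"unknown model kind {kind!r}; expected one of {MODEL_KINDS}")
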