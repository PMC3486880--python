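"""Parameter estimation and model comparison.

Estimation follows the study's procedure: least-squares fitting of the ODE
models to continuous pain ratings by a seeded uniform random search over a
bounded parameter box (default 20,000 draws), optionally polished with a
derivative-free Nelder-Mead local search from the best draw.  Fit adequacy
is the zero-lag Pearson correlation between model output and ratings, with
the residual sum of squares feeding AIC-based model comparison:

    AIC = n·ln(SS/n) + 2k          (dataset constant dropped)
    Akaike gain(m, c) = (AIC_c − AIC_m) / n

A positive gain means the candidate model m is preferred over the contrast c
even after the free-parameter penalty.  The null predictors carry the
published parameter accounting (k = 0 for the linear null, k = 1 for the
threshold-linear null) although a scalar gain is least-squares-fitted before
the SS is computed — a correlation-based measure needs no scale, an SS does.

The public surface is statsmodels-shaped: build a :class:`PerceptionModel`
from a (stimulus, rating) pair, call :meth:`~PerceptionModel.fit`, and get a
:class:`PerceptionFit` carrying estimates, adequacy metrics and prediction
methods.  ``fit_model`` / ``cross_predict`` / ``group_average_fit`` are thin
functional wrappers.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import optimize

from . import _integrators as _ker
from . import dynamics
from .dynamics import (
    FirstOrderParams,
    PowerLawParams,
    SecondOrderParams,
    TwoTauParams,
)
from .traces import PairedSeries, RatingTrace, StimulusTrace, TraceError, align, derivative

__all__ = [
    "FitConfig",
    "FitError",
    "PerceptionModel",
    "PerceptionFit",
    "DEFAULT_BOUNDS",
    "PARAM_COUNT",
    "sse",
    "pearson_r",
    "derivative_r",
    "aic",
    "akaike_gain",
    "fit_model",
    "cross_predict",
    "group_average_fit",
]


class FitError(RuntimeError):
    """Estimation failed (degenerate data or no valid candidate)."""


# free-parameter counts as published: 5 for the second-order model, 3 for the
# first-order, 4 for the power-law, 5 for the two-time-constant variant,
# 0 and 1 for the linear and threshold-linear nulls
PARAM_COUNT = {
    "linear": 0,
    "threshlin": 1,
    "first": 3,
    "power": 4,
    "second": 5,
    "twotau": 5,
}

_PARAM_NAMES = {
    "first": ("A", "tau", "T0"),
    "power": ("A", "tau", "T0", "delta"),
    "second": ("k1", "gamma", "k2", "T0", "Tc"),
    "twotau": ("A_fast", "tau_fast", "A_slow", "tau_slow", "T0"),
    "threshlin": ("T0",),
    "linear": (),
}

_PARAM_CLASS = {
    "first": FirstOrderParams,
    "power": PowerLawParams,
    "second": SecondOrderParams,
    "twotau": TwoTauParams,
}

# default search box; wide enough to cover published fitted ranges
# (e.g. the power exponent spanned roughly -0.3 to 3)
DEFAULT_BOUNDS = {
    "T0": (40.0, 50.0),
    "tau": (0.5, 60.0),
    "A": (0.0, 10.0),
    "k1": (0.0, 5.0),
    "gamma": (0.0, 5.0),
    "k2": (0.0, 1.0),
    "Tc": (-2.0, 5.0),
    "delta": (-0.5, 3.0),
    "A_fast": (0.0, 10.0),
    "A_slow": (0.0, 10.0),
    "tau_fast": (0.5, 60.0),
    "tau_slow": (0.5, 60.0),
}


@dataclass(frozen=True)
class FitConfig:
    """Random-search configuration.

    bounds : per-parameter closed intervals; ``None`` entries fall back to
        :data:`DEFAULT_BOUNDS`.
    n_draws : number of uniform random draws (≥ 1).
    seed : RNG seed; identical (seed, config, data) gives identical results.
    polish : refine the best draw with Nelder-Mead (bounded by penalty).
    dt_sim : ceiling on the effective integration substep (s).
    """

    bounds: dict | None = None
    n_draws: int = 20000
    seed: int = 0
    polish: bool = True
    dt_sim: float = dynamics.DEFAULT_MAX_STEP

    def __post_init__(self):
        if self.n_draws < 1:
            raise ValueError("n_draws must be >= 1")
        if self.dt_sim <= 0:
            raise ValueError("dt_sim must be positive")
        for name, (lo, hi) in (self.bounds or {}).items():
            if not (math.isfinite(lo) and math.isfinite(hi) and lo < hi):
                raise ValueError(f"bounds for {name!r} must be finite and ordered")

    def bound(self, name: str):
        if self.bounds and name in self.bounds:
            return self.bounds[name]
        return DEFAULT_BOUNDS[name]


# ---------------------------------------------------------------------------
# adequacy metrics
# ---------------------------------------------------------------------------

def _values(x) -> np.ndarray:
    return x.values if hasattr(x, "values") else np.asarray(x, dtype=float)


def _check_same_grid(a, b):
    if hasattr(a, "t") and hasattr(b, "t"):
        if len(a.t) != len(b.t) or not np.allclose(a.t, b.t, atol=1e-9):
            raise TraceError("traces are not on a common grid")
    elif _values(a).shape != _values(b).shape:
        raise TraceError("series lengths differ")


def sse(pred, obs) -> float:
    """Residual sum of squares Σ(pred − obs)² on a common grid."""
    _check_same_grid(pred, obs)
    d = _values(pred) - _values(obs)
    return float(d @ d)


def pearson_r(pred, obs) -> float:
    """Zero-lag Pearson correlation between two series on a common grid."""
    _check_same_grid(pred, obs)
    x = _values(pred)
    y = _values(obs)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise FitError("correlation undefined: zero-variance input")
    return float(np.corrcoef(x, y)[0, 1])


def derivative_r(pred: RatingTrace, obs: RatingTrace) -> float:
    """Pearson correlation between the time derivatives of two traces."""
    _check_same_grid(pred, obs)
    dx = np.gradient(_values(pred), pred.dt if hasattr(pred, "dt") else 1.0, edge_order=1)
    dy = np.gradient(_values(obs), obs.dt if hasattr(obs, "dt") else 1.0, edge_order=1)
    if np.ptp(dx) == 0 or np.ptp(dy) == 0:
        raise FitError("correlation undefined: constant derivative")
    return float(np.corrcoef(dx, dy)[0, 1])


def aic(ss: float, n: int, k: int) -> float:
    """AIC = n·ln(SS/n) + 2k, dataset constant dropped."""
    if n <= 0:
        raise ValueError("n must be positive")
    if ss < 0:
        raise ValueError("SS must be non-negative")
    if ss == 0:
        warnings.warn("SS = 0: AIC is -inf", RuntimeWarning, stacklevel=2)
        return float("-inf")
    return n * math.log(ss / n) + 2 * k


def akaike_gain(aic_model: float, aic_contrast: float, n: int) -> float:
    """Normalized AIC difference (AIC_contrast − AIC_model)/n.

    Positive values favour the model: its accuracy gain cannot be explained
    by the extra parameters alone.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    return (aic_contrast - aic_model) / n


# ---------------------------------------------------------------------------
# results object
# ---------------------------------------------------------------------------

@dataclass
class PerceptionFit:
    """Fitted perception model: estimates, adequacy metrics, predictions.

    Attributes
    ----------
    kind : model identifier ("second", "first", "power", "twotau",
        "linear", "threshlin").
    params : parameter bundle (a dynamics dataclass for the ODE models; for
        the nulls, ``None`` / a float threshold — see ``gain``).
    gain : scalar output gain (null models only; 1.0 for ODE models).
    r : zero-lag Pearson correlation between fit and ratings.
    sse : residual sum of squares.
    n, k : sample and free-parameter counts entering the AIC.
    aic : n·ln(SS/n) + 2k.
    fitted : the training-data prediction trace.
    """

    kind: str
    params: object
    gain: float
    r: float
    sse: float
    n: int
    k: int
    aic: float
    fitted: RatingTrace
    config: FitConfig | None = None

    # -- prediction ---------------------------------------------------------
    def predict(self, stim: StimulusTrace) -> RatingTrace:
        """Simulate the fitted model on a (new) stimulus."""
        if self.kind == "linear":
            return RatingTrace(stim.t, np.maximum(0.0, self.gain * stim.T))
        if self.kind == "threshlin":
            base = dynamics.ramp_forcing(stim.T, self.params)
            return RatingTrace(stim.t, np.maximum(0.0, self.gain * base))
        return dynamics.simulate(self.kind, self.params, stim)

    def cross_predict(self, new_pair: PairedSeries):
        """Predict a held-out (stimulus, rating) pair with frozen parameters.

        Returns (prediction trace, test Pearson r).
        """
        pred = self.predict(new_pair.stimulus)
        return pred, pearson_r(pred, new_pair.rating)

    def derivative_r(self, obs: RatingTrace) -> float:
        return derivative_r(self.fitted, obs)

    # -- reporting ----------------------------------------------------------
    def params_dict(self) -> dict:
        if self.kind == "linear":
            d = {}
        elif self.kind == "threshlin":
            d = {"T0": float(self.params)}
        else:
            d = {name: float(v) for name, v in asdict(self.params).items()}
        if self.kind in ("linear", "threshlin"):
            d["gain"] = self.gain
        return d

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "params": self.params_dict(),
            "r": self.r,
            "sse": self.sse,
            "n": self.n,
            "k": self.k,
            "aic": self.aic,
        }

    def summary(self) -> str:
        lines = [
            "Perception model fit",
            "=" * 46,
            f"{'model kind:':<22}{self.kind}",
            f"{'n samples:':<22}{self.n}",
            f"{'free parameters k:':<22}{self.k}",
            f"{'Pearson r:':<22}{self.r:.4f}",
            f"{'SSE:':<22}{self.sse:.4g}",
            f"{'AIC:':<22}{self.aic:.4g}",
            "-" * 46,
        ]
        for name, v in self.params_dict().items():
            lines.append(f"{name:<22}{v:.6g}")
        lines.append("=" * 46)
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# the model object
# ---------------------------------------------------------------------------

class PerceptionModel:
    """A perception model bound to one (stimulus, rating) pair.

    Parameters
    ----------
    pair : PairedSeries
        Stimulus and rating on one uniform grid (see :func:`traces.align`).
    kind : str
        One of ``"second"``, ``"first"``, ``"power"``, ``"twotau"``,
        ``"linear"``, ``"threshlin"``.
    """

    def __init__(self, pair: PairedSeries, kind: str = "second"):
        if kind not in PARAM_COUNT:
            raise ValueError(f"unknown model kind {kind!r}")
        self.pair = pair
        self.kind = kind

    @classmethod
    def from_traces(cls, stim: StimulusTrace, rating: RatingTrace,
                    dt: float | None = None, kind: str = "second"):
        dt = stim.dt if dt is None else dt
        return cls(align(stim, rating, dt), kind=kind)

    # -- internals ----------------------------------------------------------
    def _draw(self, rng, n_draws: int, cfg: FitConfig) -> np.ndarray:
        names = _PARAM_NAMES[self.kind]
        lo = np.array([cfg.bound(p)[0] for p in names])
        hi = np.array([cfg.bound(p)[1] for p in names])
        theta = rng.uniform(lo, hi, size=(n_draws, len(names)))
        if self.kind == "twotau":
            # enforce tau_fast < tau_slow by ordering the two tau draws
            taus = np.sort(theta[:, [1, 3]], axis=1)
            theta[:, 1] = taus[:, 0]
            theta[:, 3] = taus[:, 1]
        return theta

    def _sse_batch(self, theta: np.ndarray, cfg: FitConfig) -> np.ndarray:
        pair = self.pair
        obs = pair.P
        if self.kind == "second":
            Tf, dTf, n_sub, h = dynamics._fine_grid(pair.stimulus, cfg.dt_sim)
            return _ker.rk4_second_sse_batch(theta, Tf, dTf, n_sub, h, obs)
        mids = 0.5 * (pair.T[:-1] + pair.T[1:])
        if self.kind == "first":
            full = np.column_stack([theta, np.ones(len(theta))])
            return _ker.leaky_sse_batch(full, mids, pair.dt, obs)
        if self.kind == "power":
            return _ker.leaky_sse_batch(theta, mids, pair.dt, obs)
        if self.kind == "twotau":
            return _ker.twotau_sse_batch(theta, mids, pair.dt, obs)
        raise AssertionError(self.kind)

    def _penalized_objective(self, cfg: FitConfig):
        names = _PARAM_NAMES[self.kind]
        lo = np.array([cfg.bound(p)[0] for p in names])
        hi = np.array([cfg.bound(p)[1] for p in names])

        def obj(x):
            if np.any(x < lo) or np.any(x > hi):
                return float("inf")
            if self.kind == "twotau" and x[1] >= x[3]:
                return float("inf")
            val = self._sse_batch(np.asarray(x, dtype=float)[None, :], cfg)[0]
            return val if math.isfinite(val) else float("inf")

        return obj

    def _to_params(self, x: np.ndarray):
        return _PARAM_CLASS[self.kind](*[float(v) for v in x])

    def _fit_ode(self, cfg: FitConfig) -> PerceptionFit:
        rng = np.random.default_rng(cfg.seed)
        best_sse = float("inf")
        best_x = None
        chunk = 5000
        remaining = cfg.n_draws
        while remaining > 0:
            m = min(chunk, remaining)
            theta = self._draw(rng, m, cfg)
            vals = self._sse_batch(theta, cfg)
            vals = np.where(np.isfinite(vals), vals, np.inf)
            j = int(np.argmin(vals))
            # ties broken by first-encountered minimum (deterministic)
            if vals[j] < best_sse:
                best_sse = float(vals[j])
                best_x = theta[j].copy()
            remaining -= m
        if best_x is None or not math.isfinite(best_sse):
            raise FitError("all candidate simulations were invalid")
        if cfg.polish:
            res = optimize.minimize(self._penalized_objective(cfg), best_x,
                                    method="Nelder-Mead",
                                    options={"xatol": 1e-5, "fatol": 1e-8})
            if math.isfinite(res.fun) and res.fun < best_sse:
                best_sse = float(res.fun)
                best_x = np.asarray(res.x, dtype=float)
        params = self._to_params(best_x)
        pred = dynamics.simulate(self.kind, params, self.pair.stimulus)
        return self._package(params, 1.0, pred, cfg)

    def _fit_linear(self, cfg: FitConfig) -> PerceptionFit:
        T = self.pair.T
        P = self.pair.P
        denom = float(T @ T)
        if denom == 0:
            raise FitError("degenerate stimulus (all-zero temperature)")
        gain = float(T @ P) / denom
        pred = RatingTrace(self.pair.t, np.maximum(0.0, gain * T))
        return self._package(None, gain, pred, cfg, pred_raw=gain * T)

    def _fit_threshlin(self, cfg: FitConfig) -> PerceptionFit:
        T = self.pair.T
        P = self.pair.P
        lo, hi = cfg.bound("T0")
        rng = np.random.default_rng(cfg.seed)
        cand = rng.uniform(lo, hi, size=cfg.n_draws)

        def sse_of(t0s):
            # gain-fitted SSE in closed form, vectorized over thresholds
            u = np.maximum(0.0, T[None, :] - np.asarray(t0s)[:, None])
            uu = np.einsum("ij,ij->i", u, u)
            up = u @ P
            pp = float(P @ P)
            with np.errstate(divide="ignore", invalid="ignore"):
                out = pp - np.where(uu > 0, up**2 / np.where(uu > 0, uu, 1.0), 0.0)
            return out

        vals = np.concatenate([sse_of(cand[i:i + 2000])
                               for i in range(0, len(cand), 2000)])
        j = int(np.argmin(vals))
        best_t0, best_sse = float(cand[j]), float(vals[j])
        if cfg.polish:
            res = optimize.minimize_scalar(lambda x: float(sse_of([x])[0]),
                                           bounds=(lo, hi), method="bounded")
            if res.fun < best_sse:
                best_t0 = float(res.x)
        u = np.maximum(0.0, T - best_t0)
        uu = float(u @ u)
        if uu == 0:
            raise FitError("threshold above all temperatures: degenerate fit")
        gain = float(u @ P) / uu
        pred = RatingTrace(self.pair.t, np.maximum(0.0, gain * u))
        return self._package(best_t0, gain, pred, cfg, pred_raw=gain * u)

    def _package(self, params, gain, pred, cfg, pred_raw=None) -> PerceptionFit:
        P = self.pair.P
        resid = (pred.P if pred_raw is None else pred_raw) - P
        ss = float(resid @ resid)
        n = len(self.pair)
        k = PARAM_COUNT[self.kind]
        if np.ptp(pred.P) == 0:
            raise FitError("fit produced a constant prediction; correlation undefined")
        r = pearson_r(pred, self.pair.rating)
        return PerceptionFit(kind=self.kind, params=params, gain=gain, r=r,
                             sse=ss, n=n, k=k, aic=aic(ss, n, k),
                             fitted=pred, config=cfg)

    # -- public -------------------------------------------------------------
    def fit(self, config: FitConfig | None = None) -> PerceptionFit:
        """Estimate parameters by seeded random search (+ optional polish)."""
        cfg = config or FitConfig()
        if self.kind == "linear":
            return self._fit_linear(cfg)
        if self.kind == "threshlin":
            return self._fit_threshlin(cfg)
        return self._fit_ode(cfg)


# ---------------------------------------------------------------------------
# functional wrappers
# ---------------------------------------------------------------------------

def fit_model(kind: str, pair: PairedSeries, cfg: FitConfig | None = None) -> PerceptionFit:
    """Fit a model kind to a paired series (see :class:`PerceptionModel`)."""
    return PerceptionModel(pair, kind=kind).fit(cfg)


def cross_predict(fit: PerceptionFit, new_pair: PairedSeries):
    """Simulate a fitted model on held-out data; returns (prediction, r)."""
    return fit.cross_predict(new_pair)


def group_average_fit(pairs, kind: str, cfg: FitConfig | None = None) -> PerceptionFit:
    """Fit one model to the pointwise-average rating of several pairs.

    All pairs must share the stimulus protocol and the grid.
    """
    pairs = list(pairs)
    if not pairs:
        raise ValueError("need at least one pair")
    ref = pairs[0]
    for p in pairs[1:]:
        if len(p) != len(ref) or not np.allclose(p.t, ref.t, atol=1e-9):
            raise TraceError("pairs are not on a common grid")
        if not np.allclose(p.T, ref.T, atol=1e-6):
            raise TraceError("pairs do not share one stimulus protocol")
    mean_P = np.mean([p.P for p in pairs], axis=0)
    avg = PairedSeries(ref.t, ref.T, mean_P)
    return fit_model(kind, avg, cfg)
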