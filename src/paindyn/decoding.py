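"""Predicting pain ratings from voxel activity.

Four TR-wise decoders, treating voxels as predictors and TRs as independent
samples: ordinary least squares (OLS); the Elastic Net (EN), whose sparsity
is parameterized directly as the desired number of selected predictors and
whose squared-2-norm term groups correlated voxels; EN on a time-lagged
design (every voxel at lags 0..7 TRs, prescreened by correlation with the
target); and a Combined decoder that mixes the direct fMRI→pain EN with an
fMRI→temperature EN whose output is passed through the fitted analytic
temperature→pain ODE model.  Training uses the first 120 TRs by default and
accuracy is the Pearson correlation between prediction and rating on the
held-out TRs.

The EN optimum is solved by coordinate descent at a fixed grouping
parameter λ₂, with the sparsity penalty λ₁ located by bisection so that the
active set is the largest one not exceeding the requested predictor count —
the same path semantics as LARS-EN, but robust to exactly collinear voxels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import warnings

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import ElasticNet as _SkElasticNet

from . import dynamics
from .fitting import FitConfig, PerceptionFit, fit_model, pearson_r
from .synthdata import DecodingDataset
from .traces import PairedSeries, RatingTrace, StimulusTrace, resample

__all__ = [
    "LinearDecoder",
    "CombinedDecoder",
    "SplitSpec",
    "EmptyDesignError",
    "fit_ols",
    "fit_en",
    "build_lagged_design",
    "lagged_columns",
    "fit_combined",
    "predict",
    "evaluate_decoders",
]


class EmptyDesignError(ValueError):
    """No predictor column survived screening."""


@dataclass(frozen=True)
class SplitSpec:
    """Train/test split: the first ``n_train_tr`` TRs train, the rest test."""

    n_train_tr: int = 120

    def __post_init__(self):
        if self.n_train_tr <= 0:
            raise ValueError("n_train_tr must be positive")


@dataclass
class LinearDecoder:
    """A linear map from predictor columns to the target.

    ``coef`` holds one weight per column (sparse for the EN variants),
    ``meta`` records the kind and hyper-parameters (plus the lag map for the
    lagged variant).
    """

    coef: np.ndarray
    intercept: float
    meta: dict = field(default_factory=dict)

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.coef.shape[0]:
            raise ValueError(
                f"column mismatch: decoder expects {self.coef.shape[0]}, got {X.shape[1]}")
        return X @ self.coef + self.intercept


def fit_ols(X: np.ndarray, y: np.ndarray) -> LinearDecoder:
    """Ordinary least squares, β = inv(XᵀX)Xᵀy when X has full column rank.

    Rank-deficient (or wide, n_voxels > n_TR) designs get the minimum-norm
    least-squares solution via the pseudo-inverse; no intercept is fitted
    (voxel time courses are assumed mean-subtracted upstream).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.size == 0:
        raise ValueError("empty design matrix")
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    return LinearDecoder(coef=coef, intercept=0.0, meta={"kind": "ols"})


def _en_optimum(Xs: np.ndarray, yc: np.ndarray, lambda1: float,
                lambda2: float) -> np.ndarray:
    """Coordinate-descent solution of ‖y − Xβ‖² + λ₂‖β‖² + λ₁‖β‖₁."""
    n = Xs.shape[0]
    if lambda1 <= 0 and lambda2 <= 0:
        beta, *_ = np.linalg.lstsq(Xs, yc, rcond=None)
        return beta
    alpha = lambda1 / (2 * n) + lambda2 / n
    l1_ratio = (lambda1 / (2 * n)) / alpha
    model = _SkElasticNet(alpha=alpha, l1_ratio=l1_ratio, fit_intercept=False,
                          max_iter=50000, tol=1e-8)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        model.fit(Xs, yc)
    return model.coef_.copy()


def fit_en(X: np.ndarray, y: np.ndarray, lambda2: float = 1.0,
           n_select: int = 100) -> LinearDecoder:
    """Elastic Net with sparsity given as a predictor count.

    Solves min ‖y − Xβ‖² + λ₂‖β‖² + λ₁‖β‖₁ along the λ₁ path (coordinate
    descent with a bisection search on λ₁) and returns the solution with the
    largest active set not exceeding ``n_select``.  Predictors are
    standardized internally; coefficients come back on the original scale
    with an intercept.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n_select <= 0:
        raise ValueError("n_select must be positive")
    if n_select > p:
        raise ValueError("n_select exceeds the number of predictors")
    if lambda2 < 0:
        raise ValueError("lambda2 must be non-negative")

    mu_x = X.mean(axis=0)
    sd_x = X.std(axis=0)
    sd_x = np.where(sd_x > 0, sd_x, 1.0)
    Xs = (X - mu_x) / sd_x
    mu_y = y.mean()
    yc = y - mu_y

    beta = _en_optimum(Xs, yc, 0.0, lambda2)
    if np.count_nonzero(beta) > n_select:
        # bisection: largest active set not exceeding n_select
        lo, hi = 0.0, 2.0 * np.abs(Xs.T @ yc).max()
        beta = np.zeros(p)
        for _ in range(40):
            mid = 0.5 * (lo + hi)
            cand = _en_optimum(Xs, yc, mid, lambda2)
            if np.count_nonzero(cand) <= n_select:
                beta, hi = cand, mid
            else:
                lo = mid
            if hi - lo < 1e-10 * (1.0 + hi):
                break

    coef = beta / sd_x
    intercept = float(mu_y - mu_x @ coef)
    return LinearDecoder(coef=coef, intercept=intercept,
                         meta={"kind": "en", "lambda2": lambda2,
                               "n_select": n_select})


# ---------------------------------------------------------------------------
# lagged design
# ---------------------------------------------------------------------------

def lagged_columns(X: np.ndarray, lag_map, max_lag: int) -> np.ndarray:
    """Assemble the kept (voxel, lag) columns; rows start at index max_lag."""
    X = np.asarray(X, dtype=float)
    m = X.shape[0]
    cols = [X[max_lag - lag:m - lag, vox] for vox, lag in lag_map]
    return np.column_stack(cols)


def build_lagged_design(X: np.ndarray, y: np.ndarray, max_lag: int = 7,
                        screen_r: float = 0.2, n_train: int | None = None):
    """Time-lagged, correlation-screened design for the EN-with-lags decoder.

    Candidate columns are every (voxel, lag 0..max_lag) pair with the lagged
    series shifted forward so row i of the design aligns with target row
    ``i + max_lag`` (the first ``max_lag`` rows are dropped to avoid
    undefined leading values).  Only columns whose |correlation| with the
    target exceeds ``screen_r`` on the screening rows are kept — the first
    ``n_train − max_lag`` design rows when ``n_train`` is given (preventing
    test-set leakage), otherwise all rows.

    Returns (design matrix, lag_map) with lag_map a list of (voxel, lag).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    m, p = X.shape
    if m <= max_lag:
        raise ValueError("need more rows than max_lag")
    y_trim = y[max_lag:]
    n_screen = len(y_trim) if n_train is None else n_train - max_lag
    if n_screen <= 2:
        raise ValueError("too few screening rows")

    ys = y_trim[:n_screen]
    ys_c = ys - ys.mean()
    ys_n = np.sqrt(ys_c @ ys_c)
    kept_cols = []
    lag_map = []
    for lag in range(max_lag + 1):
        block = X[max_lag - lag:m - lag, :]
        B = block[:n_screen]
        Bc = B - B.mean(axis=0)
        denom = np.sqrt((Bc * Bc).sum(axis=0)) * ys_n
        with np.errstate(divide="ignore", invalid="ignore"):
            corr = np.where(denom > 0, (Bc.T @ ys_c) / np.where(denom > 0, denom, 1.0), 0.0)
        for vox in np.nonzero(np.abs(corr) > screen_r)[0]:
            kept_cols.append(block[:, vox])
            lag_map.append((int(vox), lag))
    if not kept_cols:
        raise EmptyDesignError("no (voxel, lag) column passed screening")
    return np.column_stack(kept_cols), lag_map


# ---------------------------------------------------------------------------
# combined decoder
# ---------------------------------------------------------------------------

#: default random-search budget for the analytic pathway inside the decoder
DEFAULT_COMBINED_FIT = FitConfig(n_draws=5000, seed=0, polish=True)

#: default EN hyper-parameters: the grouping weight and an active set sized
#: for ~120 training TRs (a 100-predictor set on 120 samples overfits badly)
DEFAULT_EN_CFG = {"lambda2": 1.0, "n_select": 25}


def _analytic_on_temperature(analytic: PerceptionFit, temp_tr: np.ndarray,
                             tr_s: float, dt_sim: float) -> np.ndarray:
    """Run the fitted ODE on a TR-grid temperature series.

    The series is linearly upsampled to ``dt_sim`` for integration, then
    decimated back to the TR grid.
    """
    t = tr_s * np.arange(len(temp_tr))
    stim = resample(StimulusTrace(t, temp_tr), dt_sim)
    pred = analytic.predict(stim)
    k = int(round(tr_s / dt_sim))
    return pred.P[::k]


@dataclass
class CombinedDecoder:
    """Analytic-model-constrained decoder (direct EN + EN∘temperature∘ODE).

    Prediction runs the fMRI→temperature EN, simulates the analytic
    temperature→pain model on that series, and mixes the result with the
    direct fMRI→pain EN through least-squares weights (w0, w_en, w_model).
    """

    en_pain: LinearDecoder
    en_temp: LinearDecoder
    analytic: PerceptionFit
    mix: np.ndarray
    tr_s: float = 2.5
    dt_sim: float = 0.1

    def pathway_predictions(self, X: np.ndarray):
        p_en = self.en_pain.predict(X)
        temp_hat = self.en_temp.predict(X)
        p_an = _analytic_on_temperature(self.analytic, temp_hat, self.tr_s, self.dt_sim)
        return p_en, p_an

    def predict(self, X: np.ndarray) -> np.ndarray:
        p_en, p_an = self.pathway_predictions(X)
        w0, w_en, w_model = self.mix
        return w0 + w_en * p_en + w_model * p_an


def _mix_weights(p_en, p_an, y):
    A = np.column_stack([np.ones_like(p_en), p_en, p_an])
    w, *_ = np.linalg.lstsq(A, y, rcond=None)
    return w


def fit_combined(X: np.ndarray, y_pain: np.ndarray, y_temp: np.ndarray,
                 en_cfg: dict | None = None, analytic_kind: str = "second",
                 fit_cfg: FitConfig = DEFAULT_COMBINED_FIT,
                 tr_s: float = 2.5, dt_sim: float = 0.1,
                 validate_mix: bool = True) -> CombinedDecoder:
    """Train the Combined decoder on aligned TR-wise training arrays.

    Steps: (1) EN for fMRI→temperature; (2) fit the analytic model on the
    actual (temperature, rating) training series upsampled to ``dt_sim``;
    (3) EN for fMRI→pain; (4) least-squares mixing weights (with intercept)
    regressing the rating on the two pathway predictions over training rows.

    The analytic pathway runs the ODE on a regression estimate of the
    temperature, so its output scale hinges on how often that estimate
    crosses the fitted pain threshold — on unlucky runs the pathway
    degenerates and an unconstrained stack then hurts out-of-sample.  With
    ``validate_mix`` the mixing weights are therefore accepted only if they
    beat the pure EN pathway on a held-out tail (last quarter) of the
    training rows; otherwise the decoder falls back to the EN-only mix.
    """
    en_cfg = dict(en_cfg or DEFAULT_EN_CFG)
    en_cfg.setdefault("lambda2", DEFAULT_EN_CFG["lambda2"])
    en_cfg.setdefault("n_select", min(DEFAULT_EN_CFG["n_select"], X.shape[1]))

    en_temp = fit_en(X, y_temp, **en_cfg)
    en_pain = fit_en(X, y_pain, **en_cfg)

    t = tr_s * np.arange(len(y_temp))
    stim = resample(StimulusTrace(t, y_temp), dt_sim)
    rating = resample(RatingTrace(t, np.maximum(0.0, y_pain)), dt_sim)
    pair = PairedSeries(stim.t, stim.T, rating.P)
    analytic = fit_model(analytic_kind, pair, fit_cfg)

    dec = CombinedDecoder(en_pain=en_pain, en_temp=en_temp, analytic=analytic,
                          mix=np.array([0.0, 1.0, 0.0]), tr_s=tr_s, dt_sim=dt_sim)
    p_en, p_an = dec.pathway_predictions(X)
    mix = _mix_weights(p_en, p_an, y_pain)
    if validate_mix:
        # contiguous-block CV over the training rows: refit the 3-parameter
        # mix with each block held out and compare the stack with the pure
        # EN pathway on the held-out blocks
        n = len(y_pain)
        err_mixed = err_en = 0.0
        for edges in np.array_split(np.arange(n), 4):
            rest = np.setdiff1d(np.arange(n), edges)
            w = _mix_weights(p_en[rest], p_an[rest], y_pain[rest])
            held = w[0] + w[1] * p_en[edges] + w[2] * p_an[edges]
            err_mixed += np.sum((held - y_pain[edges]) ** 2)
            err_en += np.sum((p_en[edges] - y_pain[edges]) ** 2)
        if err_mixed >= err_en:
            mix = np.array([0.0, 1.0, 0.0])
    dec.mix = mix
    return dec


def predict(decoder, X: np.ndarray) -> np.ndarray:
    """Deterministic per-TR prediction for any decoder.

    For the lagged EN decoder ``X`` is the raw TR×voxel matrix including the
    ``max_lag`` leading context rows; the output aligns with rows
    ``max_lag:`` of ``X``.
    """
    if isinstance(decoder, CombinedDecoder):
        return decoder.predict(X)
    if decoder.meta.get("lag_map") is not None:
        cols = lagged_columns(X, decoder.meta["lag_map"], decoder.meta["max_lag"])
        return LinearDecoder.predict(decoder, cols)
    return decoder.predict(X)


# ---------------------------------------------------------------------------
# evaluation protocol
# ---------------------------------------------------------------------------

def evaluate_decoders(ds: DecodingDataset, split: SplitSpec = SplitSpec(),
                      cfgs: dict | None = None) -> pd.DataFrame:
    """Fit OLS, EN, EN w/lags and Combined; report train/test Pearson r.

    The first ``split.n_train_tr`` TRs train every decoder; the remaining
    TRs are the test set.  Deterministic given the dataset and configs.
    """
    cfgs = cfgs or {}
    n_train = split.n_train_tr
    if ds.n_tr <= n_train:
        raise ValueError("dataset has no test rows under this split")
    X, y = ds.X, ds.y_pain
    Xtr, ytr = X[:n_train], y[:n_train]
    Xte, yte = X[n_train:], y[n_train:]

    en_cfg = dict(cfgs.get("en", {}))
    en_cfg.setdefault("lambda2", DEFAULT_EN_CFG["lambda2"])
    en_cfg.setdefault("n_select", min(DEFAULT_EN_CFG["n_select"], ds.n_voxels))
    lag_cfg = dict(cfgs.get("lags", {}))
    max_lag = lag_cfg.get("max_lag", 7)
    screen_r = lag_cfg.get("screen_r", 0.2)
    comb_cfg = dict(cfgs.get("combined", {}))

    rows = []

    def score(name, pred_tr, pred_te, ytr_, yte_):
        rows.append({"model": name,
                     "train_r": pearson_r(pred_tr, ytr_),
                     "test_r": pearson_r(pred_te, yte_)})

    ols = fit_ols(Xtr, ytr)
    score("ols", ols.predict(Xtr), ols.predict(Xte), ytr, yte)

    en = fit_en(Xtr, ytr, **en_cfg)
    score("en", en.predict(Xtr), en.predict(Xte), ytr, yte)

    # lagged design built over the full run; screening restricted to train rows
    D, lag_map = build_lagged_design(X, y, max_lag=max_lag, screen_r=screen_r,
                                     n_train=n_train)
    y_trim = y[max_lag:]
    n_tr_d = n_train - max_lag
    en_lag_cfg = dict(en_cfg)
    en_lag_cfg["n_select"] = min(en_lag_cfg["n_select"], D.shape[1])
    enlags = fit_en(D[:n_tr_d], y_trim[:n_tr_d], **en_lag_cfg)
    enlags.meta.update({"kind": "enlags", "lag_map": lag_map, "max_lag": max_lag,
                        "screen_r": screen_r})
    score("enlags", enlags.predict(D[:n_tr_d]), enlags.predict(D[n_tr_d:]),
          y_trim[:n_tr_d], y_trim[n_tr_d:])

    comb = fit_combined(Xtr, ytr, ds.y_temp[:n_train], en_cfg=en_cfg,
                        tr_s=ds.tr_s, **comb_cfg)
    score("combined", comb.predict(Xtr), comb.predict(Xte), ytr, yte)

    return pd.DataFrame(rows).set_index("model")
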