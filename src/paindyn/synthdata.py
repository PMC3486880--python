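"""Synthetic data generators.

Two emulators make every downstream stage testable without any recorded
data: (i) noisy continuous pain ratings produced by any perception model in
response to a thermal protocol (standing in for finger-span ratings on the
0-100 scale), and (ii) BOLD-like TR×voxel matrices whose informative voxels
are noisy, hemodynamically smoothed encodings of the temperature or of the
pain rating, sampled at the scanner repetition time (TR = 2.5 s).

The BOLD emulator reproduces only the statistical structure the decoders
assume — linear voxel encodings under a canonical double-gamma hemodynamic
response, autocorrelated Gaussian noise — with no spatial structure, head
motion or physiological confounds.  Pain-coding voxels encode the *rating*
(not the stimulus), so the fMRI→pain map inherits the perception model's
nonlinearity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from . import dynamics
from .traces import RatingTrace, StimulusTrace, TraceError, align, resample

__all__ = [
    "RatingNoiseSpec",
    "BoldSpec",
    "DecodingDataset",
    "synth_rating",
    "synth_bold",
    "double_gamma_hrf",
    "make_decoding_dataset",
]


@dataclass(frozen=True)
class RatingNoiseSpec:
    """Noise model for synthetic ratings.

    noise_sd : i.i.d. Gaussian noise, rating units.
    smooth_tau : first-order (motor-lag) smoothing time constant in s;
        0 disables.
    clamp : reporting range of the rating device.
    """

    noise_sd: float = 5.0
    smooth_tau: float = 0.0
    clamp: tuple = (0.0, 100.0)
    seed: int = 0

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.smooth_tau < 0:
            raise ValueError("smooth_tau must be non-negative")


def synth_rating(kind: str, params, stim: StimulusTrace,
                 spec: RatingNoiseSpec = RatingNoiseSpec()) -> RatingTrace:
    """Simulate a model, smooth, add noise, clamp to the rating range."""
    clean = dynamics.simulate(kind, params, stim)
    P = clean.P.copy()
    if spec.smooth_tau > 0:
        e = np.exp(-stim.dt / spec.smooth_tau)
        for i in range(1, len(P)):
            P[i] = e * P[i - 1] + (1.0 - e) * P[i]
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        P = P + rng.normal(0.0, spec.noise_sd, size=P.shape)
    P = np.clip(P, *spec.clamp)
    return RatingTrace(stim.t, P)


# ---------------------------------------------------------------------------
# BOLD-like decoding datasets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BoldSpec:
    """Statistical structure of the synthetic TR×voxel matrix.

    n_voxels : total voxel count.
    frac_temp_coding / frac_pain_coding : fraction of voxels encoding the
        hemodynamically smoothed temperature / pain rating (sum ≤ 1).
    snr : per-voxel ratio of (unit) signal sd to noise sd.
    ar1_rho : lag-1 autocorrelation of the voxel noise.
    hrf_peak_s, hrf_undershoot_s, hrf_ratio : canonical double-gamma
        hemodynamic response (peak 6 s, undershoot 16 s, ratio 1/6).
    tr_s : repetition time, 2.5 s.
    """

    n_voxels: int = 500
    frac_temp_coding: float = 0.05
    frac_pain_coding: float = 0.05
    snr: float = 1.0
    ar1_rho: float = 0.3
    hrf_peak_s: float = 6.0
    hrf_undershoot_s: float = 16.0
    hrf_ratio: float = 1.0 / 6.0
    tr_s: float = 2.5
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.frac_temp_coding <= 1 and 0 <= self.frac_pain_coding <= 1
                and self.frac_temp_coding + self.frac_pain_coding <= 1):
            raise ValueError("coding fractions must lie in [0,1] and sum to <= 1")
        if self.snr <= 0:
            raise ValueError("snr must be positive")
        if not abs(self.ar1_rho) < 1:
            raise ValueError("|ar1_rho| must be < 1")
        if self.tr_s <= 0:
            raise ValueError("tr_s must be positive")


@dataclass
class DecodingDataset:
    """TR-wise decoding data: voxel matrix plus aligned targets.

    X : (n_tr, n_voxels) response matrix, arbitrary signal units.
    y_pain : rating per TR (0-100 scale).
    y_temp : temperature per TR (°C).
    tr_s : repetition time (s).
    voxel_roles : ground-truth label per voxel ("temp", "pain", "noise");
        empty for imported real data.
    """

    X: np.ndarray
    y_pain: np.ndarray
    y_temp: np.ndarray
    tr_s: float = 2.5
    voxel_roles: np.ndarray = field(default_factory=lambda: np.array([]))

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.y_pain = np.asarray(self.y_pain, dtype=float)
        self.y_temp = np.asarray(self.y_temp, dtype=float)
        n = self.X.shape[0]
        if self.y_pain.shape[0] != n or self.y_temp.shape[0] != n:
            raise ValueError("X, y_pain and y_temp must have equal row counts")
        if self.tr_s <= 0:
            raise ValueError("tr_s must be positive")

    @property
    def n_tr(self) -> int:
        return self.X.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.X.shape[1]

    # -- delimited-file round trip -----------------------------------------
    def write(self, matrix_path, targets_path, labels_path=None,
              delimiter: str = "\t") -> None:
        np.savetxt(matrix_path, self.X, delimiter=delimiter, fmt="%.8g")
        hdr = "tr_index\ty_pain\ty_temp"
        tgt = np.column_stack([np.arange(self.n_tr), self.y_pain, self.y_temp])
        np.savetxt(targets_path, tgt, delimiter=delimiter, fmt="%.8g",
                   header=hdr, comments="# ")
        if labels_path is not None:
            with open(labels_path, "w", encoding="utf-8") as fh:
                json.dump({"tr_s": self.tr_s,
                           "voxel_roles": [str(v) for v in self.voxel_roles]}, fh)

    @classmethod
    def read(cls, matrix_path, targets_path, labels_path=None) -> "DecodingDataset":
        X = np.loadtxt(matrix_path, delimiter=None)
        tgt = np.loadtxt(targets_path, delimiter=None)
        tr_s, roles = 2.5, np.array([])
        if labels_path is not None:
            with open(labels_path, "r", encoding="utf-8") as fh:
                meta = json.load(fh)
            tr_s = float(meta.get("tr_s", 2.5))
            roles = np.array(meta.get("voxel_roles", []))
        return cls(X=X, y_pain=tgt[:, 1], y_temp=tgt[:, 2], tr_s=tr_s,
                   voxel_roles=roles)


def double_gamma_hrf(t: np.ndarray, peak_s: float = 6.0,
                     undershoot_s: float = 16.0, ratio: float = 1.0 / 6.0) -> np.ndarray:
    """Canonical double-gamma hemodynamic response, peak normalized to 1."""
    t = np.asarray(t, dtype=float)
    h = stats.gamma.pdf(t, peak_s) - ratio * stats.gamma.pdf(t, undershoot_s)
    m = np.max(np.abs(h))
    return h / m if m > 0 else h


def _ar1_noise(rng, rho: float, shape) -> np.ndarray:
    """AR(1) noise with unit marginal sd, independent per column."""
    n, p = shape
    e = rng.normal(size=(n, p))
    if rho == 0:
        return e
    out = np.empty_like(e)
    out[0] = e[0]
    s = np.sqrt(1.0 - rho * rho)
    for i in range(1, n):
        out[i] = rho * out[i - 1] + s * e[i]
    return out


def synth_bold(stim: StimulusTrace, rating: RatingTrace,
               spec: BoldSpec = BoldSpec()) -> DecodingDataset:
    """Generate a BOLD-like TR×voxel matrix from a paired series.

    Temperature and rating are resampled to the TR grid and convolved with
    the hemodynamic response; informative voxels receive the standardized
    convolved signal scaled by a log-normal gain, and every voxel receives
    AR(1) Gaussian noise with sd 1/snr.  Targets stay unconvolved.
    """
    pair = align(stim, rating, spec.tr_s)
    # half-open TR convention: a 600 s series at TR 2.5 s gives 240 volumes
    span = pair.t[-1] - pair.t[0]
    n_tr = len(pair) - 1 if abs(span / spec.tr_s - round(span / spec.tr_s)) < 1e-9 else len(pair)
    T_tr = pair.T[:n_tr]
    P_tr = pair.P[:n_tr]
    hrf_support = np.arange(0.0, 32.0 + spec.tr_s / 2, spec.tr_s)
    if n_tr <= len(hrf_support):
        raise TraceError("paired series shorter than the HRF support")
    h = double_gamma_hrf(hrf_support, spec.hrf_peak_s, spec.hrf_undershoot_s,
                         spec.hrf_ratio)

    def encode(y):
        sig = np.convolve(y - y.min(), h)[:n_tr]
        sd = sig.std()
        if sd == 0:
            raise TraceError("constant target cannot be encoded")
        return (sig - sig.mean()) / sd

    sig_temp = encode(T_tr)
    sig_pain = encode(P_tr)

    rng = np.random.default_rng(spec.seed)
    n_temp = int(round(spec.frac_temp_coding * spec.n_voxels))
    n_pain = int(round(spec.frac_pain_coding * spec.n_voxels))
    roles = np.array(["temp"] * n_temp + ["pain"] * n_pain
                     + ["noise"] * (spec.n_voxels - n_temp - n_pain))
    rng.shuffle(roles)

    X = _ar1_noise(rng, spec.ar1_rho, (n_tr, spec.n_voxels)) / spec.snr
    gains = rng.lognormal(mean=0.0, sigma=0.5, size=spec.n_voxels)
    signs = rng.choice([-1.0, 1.0], size=spec.n_voxels)
    for j in range(spec.n_voxels):
        if roles[j] == "temp":
            X[:, j] += signs[j] * gains[j] * sig_temp
        elif roles[j] == "pain":
            X[:, j] += signs[j] * gains[j] * sig_pain

    return DecodingDataset(X=X, y_pain=P_tr, y_temp=T_tr, tr_s=spec.tr_s,
                           voxel_roles=roles)


def make_decoding_dataset(seed: int = 0, duration_s: float = 600.0,
                          bold_spec: BoldSpec | None = None,
                          noise_sd: float = 5.0) -> DecodingDataset:
    """Default end-to-end decoding fixture.

    A simple nine-pulse protocol padded/truncated to ``duration_s`` drives
    the default second-order model; the noisy rating and the stimulus are
    then encoded into a synthetic BOLD matrix.  One seed controls protocol
    randomization, rating noise and voxel noise.
    """
    from .stimuli import ProtocolSpec, simple_stimulus

    stim = simple_stimulus(ProtocolSpec(seed=seed))
    dt = stim.dt
    n_target = int(round(duration_s / dt)) + 1
    T = stim.T
    if len(T) >= n_target:
        T = T[:n_target]
    else:
        T = np.concatenate([T, np.full(n_target - len(T), 35.0)])
    stim = StimulusTrace(dt * np.arange(n_target), T)

    rating = synth_rating(
        "second", dynamics.DEFAULT_SECOND, stim,
        RatingNoiseSpec(noise_sd=noise_sd, smooth_tau=1.0, seed=seed + 1),
    )
    spec = bold_spec or BoldSpec(seed=seed + 2)
    if bold_spec is not None and bold_spec.seed == 0:
        spec = BoldSpec(**{**bold_spec.__dict__, "seed": seed + 2})
    return synth_bold(stim, rating, spec)
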