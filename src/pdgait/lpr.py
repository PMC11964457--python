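"""Linear-prediction-residual (LPR) preprocessing.

Each sensor channel is mean-filtered, min–max normalised, decimated by a
factor of 4, 2 or 1 (effective 25 / 50 / 100 Hz, hence the tags ``lp_25``,
``lp_50``, ``lp_100``), fitted with a per-channel linear predictor

    x_hat(n) = sum_{k=1..p} a_k x(n - k)

and replaced by its prediction residual e(n) = x(n) - x_hat(n).  The
residual strips the predictable quasi-periodic bulk of the force signal and
keeps the less predictable fine structure; heavier decimation leaves more
unpredictable variation, so the residual range grows with the decimation
factor.

Coefficients are estimated by least squares per channel per walk.  The
predictor order ``p`` defaults to 10.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace as dc_replace

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.signal import lfilter

from .errors import DegenerateInputWarning
from .io import WalkRecord

RATE_TAGS = {4: "lp_25", 2: "lp_50", 1: "lp_100"}


@dataclass(frozen=True)
class LPRConfig:
    smoothing_window: int = 3  # samples, centred mean filter
    decimation_rate: int = 1  # in {1, 2, 4}
    order_p: int = 10  # past samples in the predictor
    normalize: bool = True

    def __post_init__(self) -> None:
        if self.decimation_rate not in RATE_TAGS:
            raise ValueError("decimation_rate must be one of {1, 2, 4}")
        if self.order_p < 1:
            raise ValueError("order_p must be >= 1")
        if self.smoothing_window < 1:
            raise ValueError("smoothing_window must be >= 1")

    @property
    def tag(self) -> str:
        return RATE_TAGS[self.decimation_rate]


def smooth_and_normalize(x: np.ndarray, config: LPRConfig) -> np.ndarray:
    """Centred moving average of the configured window, then min–max
    normalisation to [0, 1] (a constant series maps to all zeros)."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("empty series")
    if x.size < config.smoothing_window:
        raise ValueError(
            f"series of length {x.size} shorter than smoothing window "
            f"{config.smoothing_window}"
        )
    y = x if config.smoothing_window == 1 else uniform_filter1d(
        x, config.smoothing_window, mode="nearest"
    )
    if not config.normalize:
        return y.copy() if y is x else y
    lo, hi = float(y.min()), float(y.max())
    if hi == lo:
        return np.zeros_like(y)
    return (y - lo) / (hi - lo)


def decimate(x: np.ndarray, rate: int) -> np.ndarray:
    """Keep every ``rate``-th sample starting at index 0 (length ceil(T/rate))."""
    if rate not in RATE_TAGS:
        raise ValueError("rate must be one of {1, 2, 4}")
    return np.asarray(x, dtype=float)[::rate].copy()


def _lag_matrix(x: np.ndarray, p: int) -> tuple[np.ndarray, np.ndarray]:
    """Design matrix A[n-p, k-1] = x(n-k) and target y[n-p] = x(n), n = p..T-1."""
    T = x.size
    A = np.column_stack([x[p - k : T - k] for k in range(1, p + 1)])
    return A, x[p:]


def estimate_lp_coeffs(x: np.ndarray, p: int) -> np.ndarray:
    """Least-squares linear-prediction coefficients a_1..a_p.

    Minimises sum_n (x(n) - sum_k a_k x(n-k))^2 over n = p..T-1.  A
    rank-deficient design (e.g. an all-zero signal) falls back to a lightly
    ridge-regularised solve with a warning.
    """
    x = np.asarray(x, dtype=float)
    if x.size <= 2 * p:
        raise ValueError(f"need length > 2p = {2 * p}, got {x.size}")
    A, y = _lag_matrix(x, p)
    a, _, rank, _ = np.linalg.lstsq(A, y, rcond=None)
    if rank < p:
        warnings.warn(
            f"rank-deficient lag design (rank {rank} < p={p}); using ridge solve",
            DegenerateInputWarning,
            stacklevel=2,
        )
        lam = 1e-8 * max(float(np.trace(A.T @ A)) / p, 1.0)
        a = np.linalg.solve(A.T @ A + lam * np.eye(p), A.T @ y)
    return a


def predict_lp(x: np.ndarray, a: np.ndarray) -> np.ndarray:
    """One-step prediction x_hat(n) = sum_k a_k x(n-k); first p samples are 0."""
    x = np.asarray(x, dtype=float)
    a = np.asarray(a, dtype=float)
    xhat = lfilter(np.concatenate(([0.0], a)), [1.0], x)
    xhat[: a.size] = 0.0
    return xhat


def residual(x: np.ndarray, a: np.ndarray) -> np.ndarray:
    """Prediction residual e(n) = x(n) - x_hat(n) for n >= p; the p warmup
    samples are emitted as zeros to preserve alignment for windowing."""
    x = np.asarray(x, dtype=float)
    a = np.asarray(a, dtype=float)
    if x.size <= a.size:
        raise ValueError("series shorter than predictor order")
    e = x - predict_lp(x, a)
    e[: a.size] = 0.0
    return e


def lpr_transform(record: WalkRecord, config: LPRConfig) -> WalkRecord:
    """Apply the full LPR pipeline to every channel of a walk.

    Returns a record at the decimated rate whose force matrix holds the
    per-channel prediction residuals, tagged lp_25 / lp_50 / lp_100 for
    decimation rate 4 / 2 / 1.  The totals-as-sums invariant intentionally
    does not survive this transform.
    """
    T, C = record.forces.shape
    rate = config.decimation_rate
    out_len = int(np.ceil(T / rate))
    if out_len <= 2 * config.order_p:
        raise ValueError(
            f"decimated length {out_len} too short for order p={config.order_p}"
        )
    res = np.empty((out_len, C))
    for c in range(C):
        x = smooth_and_normalize(record.forces[:, c], config)
        x = decimate(x, rate)
        a = estimate_lp_coeffs(x, config.order_p)
        res[:, c] = residual(x, a)
    return dc_replace(
        record,
        forces=res,
        time=record.time[::rate].copy(),
        sampling_rate=record.sampling_rate / rate,
        tag=config.tag,
    )
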