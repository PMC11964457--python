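"""Seven composable time-series augmentation operators for wearable-sensor data.

All operators map a T×C force matrix to a new T×C matrix (shape preserved,
input never mutated) and are meant to be applied to *full-length walks of
the training folds only*, before windowing: permutation's minimum segment
length equals the window length, and validation data must stay pristine.

Operators and default strengths:

==================  =========================================  ==============
operator            mechanism                                  defaults
==================  =========================================  ==============
jitter              add i.i.d. Gaussian noise                  sigma = 2
scale               one Gaussian factor per channel            sigma = 0.1
rotate              Rodrigues rotation of channel triples      angle ~ U(-pi, pi]
magnitude_warp      multiply by a smooth random spline curve   sigma = 0.2, knot = 4
permute             shuffle contiguous blocks                  n_perm = 4, min_seg_length = 100
time_warp           re-sample along a warped time axis         sigma = 0.2, knot = 4
random_sample       keep random time points, re-interpolate    n_sample = 1000
==================  =========================================  ==============

They can be freely combined via :func:`compose`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace as dc_replace
import numpy as np
from scipy.interpolate import CubicSpline

from .errors import DegenerateInputWarning
from .io import WalkRecord

OPERATOR_NAMES = (
    "jitter",
    "scale",
    "rotate",
    "magnitude_warp",
    "permute",
    "time_warp",
    "random_sample",
)


@dataclass(frozen=True)
class AugmentationConfig:
    """Operator selection and strengths; an empty operator list is the identity."""

    operators: tuple[str, ...] = ()
    sigma_jitter: float = 2.0
    sigma_scale: float = 0.1
    sigma_magnitude_warp: float = 0.2  # strength unstated for this operator; mirrors time_warp
    sigma_timewarp: float = 0.2
    knot: int = 4
    n_perm: int = 4
    min_seg_length: int = 100
    n_sample: int = 1000
    max_angle: float = float(np.pi)
    rotation_group_size: int = 3
    copies: int = 1  # augmented copies appended per original walk
    seed: int | None = None

    def __post_init__(self) -> None:
        for s in (self.sigma_jitter, self.sigma_scale, self.sigma_magnitude_warp,
                  self.sigma_timewarp):
            if s < 0:
                raise ValueError("sigma parameters must be >= 0")
        if self.n_perm < 1 or self.min_seg_length < 1:
            raise ValueError("n_perm and min_seg_length must be >= 1")
        unknown = [op for op in self.operators if op not in OPERATOR_NAMES]
        if unknown:
            raise ValueError(f"unknown operator(s) {unknown}; known: {OPERATOR_NAMES}")

    @property
    def recipe(self) -> str:
        return "+".join(self.operators) if self.operators else "none"


def _check(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError(f"expected a T×C matrix, got shape {X.shape}")
    return X


def jitter(X: np.ndarray, sigma: float = 2.0, rng: np.random.Generator | None = None) -> np.ndarray:
    """Add zero-mean Gaussian noise of standard deviation ``sigma`` per element."""
    X = _check(X)
    rng = rng or np.random.default_rng()
    if sigma == 0:
        return X.copy()
    return X + rng.normal(0.0, sigma, X.shape)


def scale(X: np.ndarray, sigma: float = 0.1, rng: np.random.Generator | None = None) -> np.ndarray:
    """Multiply each channel by one factor drawn from N(1, sigma^2)."""
    X = _check(X)
    rng = rng or np.random.default_rng()
    if sigma == 0:
        return X.copy()
    factors = rng.normal(1.0, sigma, X.shape[1])
    return X * factors


def _rodrigues(axis: np.ndarray, angle: float) -> np.ndarray:
    a = axis / np.linalg.norm(axis)
    K = np.array([[0, -a[2], a[1]], [a[2], 0, -a[0]], [-a[1], a[0], 0]])
    return np.eye(3) * np.cos(angle) + np.sin(angle) * K + (1 - np.cos(angle)) * np.outer(a, a)


def rotate(
    X: np.ndarray,
    rng: np.random.Generator | None = None,
    max_angle: float = float(np.pi),
    group_size: int = 3,
) -> np.ndarray:
    """Rotate consecutive channel groups rigidly around their mean direction.

    Channels are partitioned into consecutive groups of ``group_size`` (any
    remainder passes through unchanged).  Per group the time-mean vector,
    normalised to unit length, is the rotation axis; the angle is drawn
    uniformly from (-max_angle, max_angle].  The rotation is orthogonal, so
    each time-sample's group norm is preserved.  A zero-mean group falls
    back to a fixed unit axis with a warning.
    """
    X = _check(X)
    rng = rng or np.random.default_rng()
    out = X.copy()
    C = X.shape[1]
    for g0 in range(0, C - group_size + 1, group_size):
        block = X[:, g0 : g0 + group_size]
        axis = block.mean(axis=0)
        if np.linalg.norm(axis) == 0:
            warnings.warn(
                f"rotation group at channel {g0} has zero mean; using fixed axis",
                DegenerateInputWarning,
                stacklevel=2,
            )
            axis = np.zeros(group_size)
            axis[0] = 1.0
        angle = rng.uniform(-max_angle, max_angle)
        if group_size == 3:
            R = _rodrigues(axis, angle)
        else:  # planar rotation in the plane of the first two coordinates
            R = np.eye(group_size)
            R[0, 0] = R[1, 1] = np.cos(angle)
            R[0, 1], R[1, 0] = -np.sin(angle), np.sin(angle)
        out[:, g0 : g0 + group_size] = block @ R.T
    return out


def _random_curves(
    T: int, C: int, sigma: float, knot: int, rng: np.random.Generator
) -> np.ndarray:
    """Smooth (T, C) curves through knot+2 control values ~ N(1, sigma^2)."""
    xs = np.linspace(0.0, T - 1.0, knot + 2)
    ys = rng.normal(1.0, sigma, (knot + 2, C))
    return CubicSpline(xs, ys, axis=0)(np.arange(T))


def magnitude_warp(
    X: np.ndarray,
    sigma: float = 0.2,
    knot: int = 4,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Multiply each channel by a smooth random curve (cubic spline through
    ``knot + 2`` control points drawn from N(1, sigma^2))."""
    X = _check(X)
    rng = rng or np.random.default_rng()
    if sigma == 0:
        return X.copy()
    if X.shape[0] < 2:
        raise ValueError("magnitude_warp needs T >= 2")
    return X * _random_curves(X.shape[0], X.shape[1], sigma, knot, rng)


def permute(
    X: np.ndarray,
    n_perm: int = 4,
    min_seg_length: int = 100,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Split the walk into ``n_perm`` contiguous blocks (each at least
    ``min_seg_length`` samples, cut points random) and concatenate them in a
    random order.  All channels share the block order, so the multiset of
    rows is preserved exactly."""
    X = _check(X)
    rng = rng or np.random.default_rng()
    T = X.shape[0]
    if T < n_perm * min_seg_length:
        raise ValueError(
            f"T={T} too short for {n_perm} blocks of >= {min_seg_length} samples; "
            "apply permutation to full walks, not windows"
        )
    if n_perm == 1:
        return X.copy()
    spare = T - n_perm * min_seg_length
    cuts = np.sort(rng.integers(0, spare + 1, size=n_perm - 1))
    extras = np.diff(np.concatenate(([0], cuts, [spare])))
    lengths = min_seg_length + extras
    bounds = np.concatenate(([0], np.cumsum(lengths)))
    order = rng.permutation(n_perm)
    return np.concatenate([X[bounds[i] : bounds[i + 1]] for i in order], axis=0)


_RATE_FLOOR = 1e-3  # keeps the warped time axis strictly increasing


def time_warp(
    X: np.ndarray,
    sigma: float = 0.2,
    knot: int = 4,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Distort the time axis per channel: a smooth positive rate curve is
    cumulatively summed into a warped time axis (rescaled to [0, T-1]) and
    the signal is linearly re-interpolated at the warped times."""
    X = _check(X)
    rng = rng or np.random.default_rng()
    T, C = X.shape
    rates = np.clip(_random_curves(T, C, sigma, knot, rng), _RATE_FLOOR, None)
    cum = np.cumsum(rates, axis=0)
    out = np.empty_like(X)
    grid = np.arange(T, dtype=float)
    for c in range(C):
        warped = (cum[:, c] - cum[0, c]) / (cum[-1, c] - cum[0, c]) * (T - 1)
        out[:, c] = np.interp(warped, grid, X[:, c])
    return out


def random_sample(
    X: np.ndarray, n_sample: int = 1000, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Keep ``n_sample`` random distinct time points per channel (endpoints
    always kept) and linearly re-interpolate back onto the full grid."""
    X = _check(X)
    rng = rng or np.random.default_rng()
    T, C = X.shape
    if n_sample < 2:
        raise ValueError("n_sample must be >= 2")
    out = np.empty_like(X)
    grid = np.arange(T, dtype=float)
    n_inner = min(n_sample, T) - 2
    for c in range(C):
        inner = rng.choice(np.arange(1, T - 1), size=n_inner, replace=False)
        idx = np.sort(np.concatenate(([0], inner, [T - 1])))
        out[:, c] = np.interp(grid, idx.astype(float), X[idx, c])
    return out


def _apply_operator(name: str, X: np.ndarray, cfg: AugmentationConfig,
                    rng: np.random.Generator) -> np.ndarray:
    if name == "jitter":
        return jitter(X, cfg.sigma_jitter, rng)
    if name == "scale":
        return scale(X, cfg.sigma_scale, rng)
    if name == "rotate":
        return rotate(X, rng, cfg.max_angle, cfg.rotation_group_size)
    if name == "magnitude_warp":
        return magnitude_warp(X, cfg.sigma_magnitude_warp, cfg.knot, rng)
    if name == "permute":
        return permute(X, cfg.n_perm, cfg.min_seg_length, rng)
    if name == "time_warp":
        return time_warp(X, cfg.sigma_timewarp, cfg.knot, rng)
    if name == "random_sample":
        return random_sample(X, cfg.n_sample, rng)
    raise ValueError(f"unknown operator {name!r}")


def compose(
    X: np.ndarray, config: AugmentationConfig, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Apply the configured operators in listed order; empty list = identity."""
    X = _check(X)
    if rng is None:
        rng = np.random.default_rng(config.seed)
    out = X.copy()
    for name in config.operators:
        out = _apply_operator(name, out, config, rng)
    return out


def augment_walk(
    record: WalkRecord, config: AugmentationConfig, rng: np.random.Generator | None = None
) -> WalkRecord:
    """Return a new record whose forces went through the configured recipe,
    tagged with the recipe name."""
    forces = compose(record.forces, config, rng)
    return dc_replace(record, forces=forces, tag=config.recipe)
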