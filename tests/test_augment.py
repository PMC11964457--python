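import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.interpolate import CubicSpline

import pdgait.augment as aug
from pdgait.augment import (
    AugmentationConfig,
    compose,
    jitter,
    magnitude_warp,
    permute,
    random_sample,
    rotate,
    scale,
    time_warp,
)
from pdgait.errors import DegenerateInputWarning

ZERO_STRENGTH = {
    "jitter": lambda X, rng: jitter(X, sigma=0.0, rng=rng),
    "scale": lambda X, rng: scale(X, sigma=0.0, rng=rng),
    "rotate": lambda X, rng: rotate(X, rng=rng, max_angle=0.0),
    "magnitude_warp": lambda X, rng: magnitude_warp(X, sigma=0.0, rng=rng),
    "permute": lambda X, rng: permute(X, n_perm=1, min_seg_length=1, rng=rng),
    "time_warp": lambda X, rng: time_warp(X, sigma=0.0, rng=rng),
    "random_sample": lambda X, rng: random_sample(X, n_sample=10**6, rng=rng),
}


@pytest.mark.parametrize("name", sorted(ZERO_STRENGTH))
def test_zero_strength_is_identity(name, rng):
    X = rng.normal(0, 1, (300, 6))
    out = ZERO_STRENGTH[name](X, rng)
    assert out.shape == X.shape
    assert np.allclose(out, X, atol=1e-9)


@pytest.mark.parametrize(
    "op",
    [
        lambda X, rng: jitter(X, 2.0, rng),
        lambda X, rng: scale(X, 0.1, rng),
        lambda X, rng: rotate(X, rng),
        lambda X, rng: magnitude_warp(X, 0.2, 4, rng),
        lambda X, rng: permute(X, 4, 50, rng),
        lambda X, rng: time_warp(X, 0.2, 4, rng),
        lambda X, rng: random_sample(X, 100, rng),
    ],
    ids=["jitter", "scale", "rotate", "magnitude_warp", "permute", "time_warp", "random_sample"],
)
def test_shape_preserved_and_input_not_mutated(op, rng):
    X = rng.normal(0, 5, (400, 6))
    before = X.copy()
    out = op(X, rng)
    assert out.shape == X.shape
    assert np.array_equal(X, before)


def test_jitter_noise_moments(rng):
    X = np.zeros((10_000, 1))
    out = jitter(X, sigma=2.0, rng=rng)
    assert 1.94 <= out.std() <= 2.06
    assert -0.07 <= out.mean() <= 0.07


def test_scale_factor_constant_per_channel(rng):
    X = rng.normal(0, 1, (500, 4)) + 5.0
    out = scale(X, 0.1, rng)
    ratios = out / X
    assert np.allclose(ratios.std(axis=0), 0.0, atol=1e-12)


def test_scale_factor_spread_matches_sigma(rng):
    factors = []
    X = np.ones((2, 1))
    for _ in range(2000):
        factors.append(scale(X, 0.1, rng)[0, 0])
    sd = np.std(factors)
    assert abs(sd - 0.1) < 0.01


def test_rotate_preserves_triple_norms(rng):
    X = rng.normal(0, 3, (200, 6)) + 2.0
    out = rotate(X, rng)
    for g in (0, 3):
        n_in = np.linalg.norm(X[:, g : g + 3], axis=1)
        n_out = np.linalg.norm(out[:, g : g + 3], axis=1)
        assert np.allclose(n_in, n_out, atol=1e-9)


def test_rotate_zero_mean_group_warns(rng):
    X = np.zeros((50, 3))
    X[::2, 0] = 1.0
    X[1::2, 0] = -1.0  # exactly zero time-mean in the triple
    with pytest.warns(DegenerateInputWarning):
        rotate(X, rng)


def test_magnitude_warp_ratio_is_the_generated_spline(rng):
    T, C, sigma, knot = 400, 3, 0.2, 4
    seed_state = rng.bit_generator.state
    X = np.full((T, C), 2.0)
    out = magnitude_warp(X, sigma, knot, rng)
    # reconstruct the curve from an identically seeded generator
    rng2 = np.random.default_rng()
    rng2.bit_generator.state = seed_state
    xs = np.linspace(0.0, T - 1.0, knot + 2)
    ys = rng2.normal(1.0, sigma, (knot + 2, C))  # knot+2 = 6 control points
    curve = CubicSpline(xs, ys, axis=0)(np.arange(T))
    assert np.allclose(out / X, curve, atol=1e-12)


def test_permute_preserves_row_multiset(rng):
    X = rng.normal(0, 1, (500, 4))
    out = permute(X, 4, 100, rng)
    key = np.lexsort(X.T)
    key_out = np.lexsort(out.T)
    assert np.allclose(X[key], out[key_out])


def test_permute_block_lengths_respect_minimum(rng):
    # replicate the internal cut construction from the same generator state
    T, n_perm, min_seg = 500, 4, 100
    state = rng.bit_generator.state
    permute(rng.normal(0, 1, (T, 2)), n_perm, min_seg, rng)
    rng2 = np.random.default_rng()
    rng2.bit_generator.state = state
    rng2.normal(0, 1, (T, 2))  # consume the X draw
    spare = T - n_perm * min_seg
    cuts = np.sort(rng2.integers(0, spare + 1, size=n_perm - 1))
    lengths = min_seg + np.diff(np.concatenate(([0], cuts, [spare])))
    assert lengths.sum() == T and np.all(lengths >= min_seg)


def test_permute_too_short_input_rejected(rng):
    with pytest.raises(ValueError):
        permute(np.zeros((100, 2)), 4, 100, rng)


def test_time_warp_axis_strictly_increasing(rng):
    from pdgait.augment import _RATE_FLOOR, _random_curves

    T, C = 300, 2
    state = rng.bit_generator.state
    X = np.linspace(0, 1, T)[:, None] * np.ones((1, C))
    time_warp(X, 0.5, 4, rng)
    rng2 = np.random.default_rng()
    rng2.bit_generator.state = state
    rates = np.clip(_random_curves(T, C, 0.5, 4, rng2), _RATE_FLOOR, None)
    cum = np.cumsum(rates, axis=0)
    for c in range(C):
        warped = (cum[:, c] - cum[0, c]) / (cum[-1, c] - cum[0, c]) * (T - 1)
        assert np.all(np.diff(warped) > 0)


def test_random_sample_preserves_endpoints_and_linear_ramps(rng):
    T = 500
    ramp = np.linspace(-3.0, 7.0, T)[:, None]
    out = random_sample(ramp, 20, rng)
    assert out[0, 0] == ramp[0, 0] and out[-1, 0] == ramp[-1, 0]
    assert np.allclose(out, ramp, atol=1e-9)  # linear interp of a line is exact


def test_compose_empty_and_zero_strength_are_identity(rng):
    X = rng.normal(0, 1, (300, 6))
    assert np.array_equal(compose(X, AugmentationConfig(operators=()), rng), X)
    cfg = AugmentationConfig(operators=("jitter", "scale"), sigma_jitter=0.0, sigma_scale=0.0)
    assert np.allclose(compose(X, cfg, rng), X)


def test_compose_reproducible_under_fixed_seed(rng):
    X = rng.normal(0, 1, (600, 6))
    cfg = AugmentationConfig(operators=("jitter", "permute", "time_warp"),
                             min_seg_length=100, seed=77)
    a = compose(X, cfg)
    b = compose(X, cfg)
    assert np.array_equal(a, b)


def test_unknown_operator_rejected():
    with pytest.raises(ValueError):
        AugmentationConfig(operators=("flip",))


@given(st.integers(2, 50), st.integers(1, 5))
def test_jitter_scale_shapes_property(T, C):
    rng = np.random.default_rng(0)
    X = rng.normal(0, 1, (T, C))
    assert jitter(X, 1.0, rng).shape == (T, C)
    assert scale(X, 0.2, rng).shape == (T, C)


def test_label_statistic_stable_under_jitter_and_scale(small_cohort, rng):
    """Jitter/scale at default strength must not move the class-separating
    statistic (stance fraction) appreciably — the label stays meaningful."""
    from pdgait.augment import augment_walk
    from pdgait.simulate import estimate_stance_fraction

    for w in small_cohort.walks[:4]:
        base = estimate_stance_fraction(w)
        for ops in (("jitter",), ("scale",)):
            out = augment_walk(w, AugmentationConfig(operators=ops), rng)
            assert abs(estimate_stance_fraction(out) - base) < 0.05
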