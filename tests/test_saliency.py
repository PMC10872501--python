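"""Attribution, effect-size and atlas-matching checks."""

import numpy as np
import pytest
from scipy import ndimage, stats

from neurofuse.networks import EncoderConfig, build_encoder
from neurofuse.nn.autograd import Tensor
from neurofuse.saliency import (AtlasDef, AttributionMap, RBCMap,
                                attribution_maps, atlas_peak_match, fdr_bh,
                                integrated_gradients_dim, postprocess_map,
                                rbc_from_u, voxelwise_group_test)


class _LinearEncoder:
    """z = W @ flatten(x): IG has the closed form W[dim] * x."""

    def __init__(self, W, shape):
        self.W, self.shape = W, shape

    def __call__(self, x):
        n = x.shape[0]
        return x.reshape(n, int(np.prod(self.shape))) @ Tensor(self.W.T)


def test_ig_linear_encoder_closed_form(rng):
    shape = (4, 4, 4)
    W = rng.normal(size=(3, 64))
    enc = _LinearEncoder(W, shape)
    x = rng.normal(size=shape)
    a = integrated_gradients_dim(enc, x, dim=1, steps=8)
    expect = (W[1].reshape(shape)) * x
    assert np.allclose(a.values, expect, atol=1e-10)


def test_ig_baseline_equals_input_gives_zero(rng):
    shape = (4, 4, 4)
    enc = _LinearEncoder(rng.normal(size=(2, 64)), shape)
    x = rng.normal(size=shape)
    a = integrated_gradients_dim(enc, x, dim=0, baseline=x, steps=4)
    assert np.allclose(a.values, 0)


def test_ig_rejects_out_of_range_dimension(rng):
    enc = _LinearEncoder(rng.normal(size=(2, 64)), (4, 4, 4))
    with pytest.raises(ValueError):
        integrated_gradients_dim(enc, rng.normal(size=(4, 4, 4)), dim=5)


def test_ig_completeness_on_conv_encoder():
    """Σ_v attribution_v ≈ z_dim(x) − z_dim(0) on the desk-scale encoder."""
    cfg = EncoderConfig.desk()
    enc = build_encoder(cfg, 0)
    x = np.random.default_rng(1).random((16, 16, 16))
    a = attribution_maps(enc, x[None], dim=3, steps=512)
    z_x = enc(Tensor(x[None, None])).numpy()[0, 3]
    z_0 = enc(Tensor(np.zeros((1, 1, 16, 16, 16)))).numpy()[0, 3]
    total = a.values.sum()
    assert abs(total - (z_x - z_0)) <= 0.005 * abs(z_x - z_0)


def test_postprocess_zero_sigma_is_masked_identity(rng):
    vals = rng.normal(size=(6, 6, 6))
    mask = np.zeros((6, 6, 6))
    mask[2:4] = 1
    out = postprocess_map(AttributionMap(vals, 0), mask, sigma=0)
    assert np.array_equal(out.values, vals * mask)


def test_postprocess_constant_map_unchanged_in_interior():
    vals = np.full((8, 8, 8), 3.0)
    out = postprocess_map(AttributionMap(vals, 0), np.ones((8, 8, 8)), sigma=1.5)
    assert np.allclose(out.values, 3.0, atol=1e-10)


def test_postprocess_impulse_matches_discrete_kernel():
    vals = np.zeros((9, 9, 9))
    vals[4, 4, 4] = 1.0
    out = postprocess_map(AttributionMap(vals, 0), np.ones((9, 9, 9)), sigma=1.0)
    expect = ndimage.gaussian_filter(vals, sigma=1.0, mode="reflect")
    assert np.allclose(out.values, expect)
    assert out.values.sum() == pytest.approx(1.0, abs=1e-6)


def test_postprocess_rejects_non_binary_mask(rng):
    with pytest.raises(ValueError):
        postprocess_map(AttributionMap(np.zeros((4, 4, 4)), 0),
                        rng.random((4, 4, 4)))


# ----------------------------------------------------------------------- RBC

def test_rbc_complete_separation_and_interleaving():
    assert rbc_from_u(12.0, 3, 4) == 1.0       # all case > control
    assert rbc_from_u(6.0, 3, 4) == 0.0
    assert rbc_from_u(0.0, 3, 4) == -1.0
    with pytest.raises(ValueError):
        rbc_from_u(13.0, 3, 4)


def _rbc_pair_oracle(a, b):
    """Exhaustive all-pairs count with half-credit ties."""
    u = sum(1.0 if x > y else 0.5 if x == y else 0.0 for x in a for y in b)
    return 2.0 * u / (len(a) * len(b)) - 1.0


@pytest.mark.parametrize("seed", range(6))
def test_voxelwise_rbc_matches_exhaustive_pair_count(seed):
    r = np.random.default_rng(seed)
    n1, n2 = int(r.integers(3, 12)), int(r.integers(3, 12))
    a = np.round(r.normal(size=(n1, 2, 2, 2)), 1)  # rounding forces ties
    b = np.round(r.normal(size=(n2, 2, 2, 2)), 1)
    _, rbc = voxelwise_group_test(a, b)
    for idx in np.ndindex(2, 2, 2):
        expect = _rbc_pair_oracle(a[(slice(None),) + idx], b[(slice(None),) + idx])
        assert rbc[idx] == pytest.approx(expect, abs=1e-12)


def test_group_test_detects_planted_shift():
    r = np.random.default_rng(3)
    g1 = r.normal(size=(20, 3, 3, 3))
    g2 = r.normal(size=(20, 3, 3, 3))
    g2[:, 1, 1, 1] += 5.0
    p, rbc = voxelwise_group_test(g1, g2)
    assert p[1, 1, 1] < 1e-3
    assert rbc[1, 1, 1] < -0.9  # group 2 larger -> group-1-vs-2 RBC near -1


def test_group_test_antisymmetric_under_group_swap():
    r = np.random.default_rng(4)
    g1, g2 = r.normal(size=(8, 2, 2, 2)), r.normal(size=(9, 2, 2, 2))
    p_a, rbc_a = voxelwise_group_test(g1, g2)
    p_b, rbc_b = voxelwise_group_test(g2, g1)
    assert np.allclose(p_a, p_b, atol=1e-12)
    assert np.allclose(rbc_a, -rbc_b, atol=1e-12)


def test_group_test_constant_voxels_declared_null():
    g1 = np.zeros((5, 2, 2, 2))
    g2 = np.zeros((6, 2, 2, 2))
    g2[:, 0, 0, 0] = 1.0
    p, rbc = voxelwise_group_test(g1, g2)
    assert p[1, 1, 1] == 1.0 and rbc[1, 1, 1] == 0.0
    assert p[0, 0, 0] < 0.01


def test_group_test_requires_three_per_group(rng):
    with pytest.raises(ValueError):
        voxelwise_group_test(rng.normal(size=(2, 2, 2, 2)),
                             rng.normal(size=(5, 2, 2, 2)))


# ----------------------------------------------------------------------- FDR

def test_fdr_bh_hand_worked_example():
    mask = fdr_bh(np.array([0.01, 0.02, 0.30, 0.90]), alpha=0.05)
    assert mask.tolist() == [True, True, False, False]


def test_fdr_bh_degenerate_vectors():
    assert not fdr_bh(np.ones(5)).any()
    assert fdr_bh(np.zeros(5)).all()
    assert fdr_bh(np.array([])).size == 0
    with pytest.raises(ValueError):
        fdr_bh(np.array([1.5]))


def _bh_step_up_oracle(p, alpha):
    order = np.argsort(p)
    m = len(p)
    passed = [i for i in range(m) if p[order[i]] <= alpha * (i + 1) / m]
    k = (max(passed) + 1) if passed else 0
    mask = np.zeros(m, dtype=bool)
    mask[order[:k]] = True
    return mask


@pytest.mark.parametrize("seed", range(5))
def test_fdr_bh_matches_step_up_oracle(seed):
    p = np.random.default_rng(seed).random(40) ** 2
    assert np.array_equal(fdr_bh(p, 0.05), _bh_step_up_oracle(p, 0.05))


def test_fdr_null_rejection_rate_bounded():
    rates = []
    for seed in range(50):
        r = np.random.default_rng(seed)
        p = stats.norm.sf(np.abs(r.normal(size=1000))) * 2
        rates.append(fdr_bh(p, 0.05).mean())
    assert np.mean(rates) <= 0.05


# --------------------------------------------------------------- atlas match

def _toy_atlas():
    labels = np.zeros((4, 4, 4), dtype=int)
    labels[0, :2, :2] = 1
    labels[2:, 2:, 2:] = 2
    return AtlasDef(labels, {1: "left", 2: "right"})


def test_atlas_peak_keeps_sign_of_max_abs():
    atlas = _toy_atlas()
    rbc = np.zeros((4, 4, 4))
    rbc[0, 0, 0], rbc[0, 1, 1] = 0.2, -0.5
    sig = np.zeros((4, 4, 4), dtype=bool)
    sig[0, 0, 0] = sig[0, 1, 1] = True
    table = atlas_peak_match(RBCMap(rbc, np.zeros_like(rbc), sig, 0), atlas)
    assert len(table) == 1
    assert table.iloc[0]["peak_rbc"] == -0.5
    assert table.iloc[0]["roi_name"] == "left"


def test_atlas_roi_without_significant_voxels_is_absent():
    atlas = _toy_atlas()
    rbc = np.random.default_rng(0).normal(size=(4, 4, 4))
    sig = np.zeros((4, 4, 4), dtype=bool)
    table = atlas_peak_match(RBCMap(rbc, np.ones_like(rbc), sig, 0), atlas)
    assert len(table) == 0


@pytest.mark.parametrize("seed", range(4))
def test_atlas_peak_matches_voxel_loop_oracle(seed):
    r = np.random.default_rng(seed)
    atlas = _toy_atlas()
    rbc = r.normal(size=(4, 4, 4))
    sig = r.random((4, 4, 4)) > 0.5
    table = atlas_peak_match(RBCMap(rbc, np.zeros_like(rbc), sig, 0), atlas)
    for roi_id, name in atlas.roi_names.items():
        vals = [rbc[i] for i in np.ndindex(4, 4, 4)
                if atlas.labels[i] == roi_id and sig[i]]
        rows = table[table["roi_id"] == roi_id]
        if not vals:
            assert len(rows) == 0
        else:
            expect = max(vals, key=abs)
            assert rows.iloc[0]["peak_rbc"] == pytest.approx(expect, abs=1e-12)
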