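"""Contrastive-objective tests against independent brute-force oracles.

The oracles below recompute every loss with explicit Python loops over
samples and locations, straight from the written formulas; the implementation
under test is vectorized and graph-building, so agreement is meaningful.
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from neurofuse.losses import (LossBreakdown, ObjectiveSpec, ScoreMatrix,
                              compose_objective, critic_scores, infonce,
                              loss_cc, loss_cca, loss_cr, loss_reconstruction,
                              loss_rr, loss_xx)
from neurofuse.networks import FeatureBundle
from neurofuse.losses import LocalFeatureMap, RepresentationSet
from neurofuse.nn.autograd import Tensor

from conftest import finite_difference_grad


# ----------------------------------------------------------------- oracles

def o_scores(X, Y, spec):
    n, d = X.shape
    div = np.sqrt(d) if spec.critic_scale == "sqrt_d" else float(d)
    S = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            S[i, j] = float(np.dot(X[i], Y[j])) / div
    return S


def o_infonce(S, exclude_positive):
    n = len(S)
    total = 0.0
    for i in range(n):
        denom = 0.0
        for j in range(n):
            if exclude_positive and j == i:
                continue
            denom += np.exp(S[i, j])
        total += S[i, i] - np.log(denom / n)
    return total / n


def o_nce(X, Y, spec):
    raw = o_scores(X, Y, spec)
    pen = spec.score_lambda * np.mean(raw**2)
    s = spec.score_clip * np.tanh(raw / spec.score_clip) if spec.score_clip else raw
    return -o_infonce(s, spec.exclude_positive), pen


def o_local_global(L, G, spec):
    # L: (n, d, S); each location contrasted against G, averaged
    losses, pens = zip(*(o_nce(L[:, :, s], G, spec) for s in range(L.shape[2])))
    return float(np.mean(losses)), float(np.mean(pens))


def o_cc(Lm, Lk, spec, rng):
    T = Lk.shape[2]
    vals, pens = [], []
    for _ in range(spec.cc_samples):
        t = int(rng.integers(T))
        v, p = o_local_global(Lm, Lk[:, :, t], spec)
        vals.append(v)
        pens.append(p)
    return float(np.mean(vals)), float(np.mean(pens))


def _rand(shape, seed):
    return np.random.default_rng(seed).normal(size=shape)


# ------------------------------------------------------------ critic scores

def test_critic_score_forced_arithmetic():
    spec = ObjectiveSpec()
    x = np.ones((2, 4))
    s = critic_scores(x, x, spec).scores.numpy()
    assert s[0, 0] == pytest.approx(2.0)  # 4 / sqrt(4)


def test_critic_score_orthogonal_vectors():
    X = np.array([[1.0, 0.0], [0.0, 2.0]])
    Y = np.array([[0.0, 3.0], [4.0, 0.0]])
    s = critic_scores(X, Y).scores.numpy()
    assert s[0, 0] == 0.0 and s[1, 1] == 0.0


@pytest.mark.parametrize("scale", ["sqrt_d", "d"])
def test_critic_scores_match_loop_oracle(scale):
    spec = ObjectiveSpec(critic_scale=scale)
    X, Y = _rand((5, 8), 0), _rand((5, 8), 1)
    got = critic_scores(X, Y, spec).scores.numpy()
    assert np.max(np.abs(got - o_scores(X, Y, spec))) < 1e-12


def test_critic_scores_transpose_symmetry():
    X, Y = _rand((4, 3), 2), _rand((4, 3), 3)
    a = critic_scores(X, Y).scores.numpy()
    b = critic_scores(Y, X).scores.numpy()
    assert np.allclose(a, b.T, atol=1e-12)


def test_critic_scores_rejects_bad_input():
    with pytest.raises(ValueError):
        critic_scores(_rand((3, 4), 0), _rand((3, 5), 1))
    bad = _rand((3, 4), 0)
    bad[0, 0] = np.nan
    with pytest.raises(ValueError):
        critic_scores(bad, _rand((3, 4), 1))


# ------------------------------------------------------------ regularization

def test_regularize_scores_clip_and_penalty():
    from neurofuse.losses import regularize_scores
    out = regularize_scores(ScoreMatrix(scores=Tensor(np.zeros((3, 3)))))
    assert np.allclose(out.scores.numpy(), 0) and out.penalty.item() == 0
    out1 = regularize_scores(ScoreMatrix(scores=Tensor(np.array([[1.0]]))),
                             lambda_=0.04)
    assert out1.penalty.item() == pytest.approx(0.04)
    big = regularize_scores(ScoreMatrix(scores=Tensor(np.array([[1e6]]))), c=20)
    assert big.scores.numpy()[0, 0] == pytest.approx(20.0, abs=1e-9)
    assert big.clipped


def test_regularize_scores_validation():
    from neurofuse.losses import regularize_scores
    S = ScoreMatrix(scores=Tensor(np.zeros((2, 2))))
    with pytest.raises(ValueError):
        regularize_scores(S, c=0)
    with pytest.raises(ValueError):
        regularize_scores(S, lambda_=-1)
    clipped = regularize_scores(S)
    with pytest.raises(ValueError):
        regularize_scores(clipped)


def test_clipped_scores_bounded_by_c():
    from neurofuse.losses import regularize_scores
    raw = _rand((6, 6), 4) * 100
    out = regularize_scores(ScoreMatrix(scores=Tensor(raw)), c=20)
    assert np.all(np.abs(out.scores.numpy()) <= 20.0)


# ----------------------------------------------------------------- InfoNCE

def test_infonce_equal_scores_forced_value():
    S = np.full((4, 4), 1.7)
    assert infonce(S, exclude_positive=True).item() == pytest.approx(np.log(4 / 3))


def test_infonce_diagonal_example():
    S = np.array([[10.0, 0.0], [0.0, 10.0]])
    assert infonce(S, True).item() == pytest.approx(10 + np.log(2))


@pytest.mark.parametrize("exclude", [True, False])
@pytest.mark.parametrize("n", [2, 3, 4, 6])
def test_infonce_matches_direct_summation(n, exclude):
    S = _rand((n, n), n) * 3
    assert infonce(S, exclude).item() == pytest.approx(
        o_infonce(S, exclude), abs=1e-10)


def test_infonce_rejects_tiny_batch():
    with pytest.raises(ValueError):
        infonce(np.zeros((1, 1)), True)


@settings(max_examples=80, derandomize=True, deadline=None)
@given(st.integers(2, 8), st.integers(0, 10**6))
def test_infonce_include_positive_bounded_by_log_n(n, seed):
    S = np.random.default_rng(seed).normal(size=(n, n)) * 5
    assert infonce(S, exclude_positive=False).item() <= np.log(n) + 1e-9


# ------------------------------------------------------------ loss oracles

SPEC = ObjectiveSpec(terms={"CR", "XX", "RR", "CC"})


def test_loss_cr_matches_location_oracle():
    L, G = _rand((3, 4, 2), 5), _rand((3, 4), 6)
    expect, _ = o_local_global(L, G, SPEC)
    assert loss_cr(L, G, SPEC).item() == pytest.approx(expect, abs=1e-8)


def test_loss_cr_perfect_alignment_attains_bound():
    # a single location identical to the globals with large scale drives the
    # loss to its minimum: -(bound); with distinct scaled rows the diagonal
    # dominates and the bound approaches its max
    G = np.eye(3, 4) * 50
    L = G[:, :, None]
    spec = ObjectiveSpec(score_clip=None, score_lambda=0.0)
    val = loss_cr(L, G, spec)
    # InfoNCE cannot exceed its saturation; near-saturated here
    assert val.item() < -3.0


def test_loss_cr_permutation_invariance():
    L, G = _rand((4, 3, 2), 7), _rand((4, 3), 8)
    perm = [2, 0, 3, 1]
    a = loss_cr(L, G, SPEC).item()
    b = loss_cr(L[perm], G[perm], SPEC).item()
    assert a == pytest.approx(b, abs=1e-12)


def test_loss_xx_matches_oracle_and_reduces_to_cr():
    L, G = _rand((3, 4, 2), 9), _rand((3, 4), 10)
    expect, _ = o_local_global(L, G, SPEC)
    lm = LocalFeatureMap(L, 3, modality_id=1)
    gk = RepresentationSet(G, "global", modality_id=2)
    assert loss_xx(lm, gk, SPEC).item() == pytest.approx(expect, abs=1e-8)
    # same-content degenerate case equals the CR computation
    assert loss_xx(lm, gk, SPEC).item() == pytest.approx(
        loss_cr(L, G, SPEC).item(), abs=1e-10)


def test_loss_xx_rejects_same_modality():
    lm = LocalFeatureMap(_rand((3, 4, 2), 11), 3, modality_id=1)
    g = RepresentationSet(_rand((3, 4), 12), "global", modality_id=1)
    with pytest.raises(ValueError):
        loss_xx(lm, g, SPEC)


def test_loss_xx_true_pairing_beats_shuffled_on_correlated_features():
    """Breaking subject pairing must increase the cross-modal loss."""
    wins = 0
    for seed in range(20):
        r = np.random.default_rng(seed)
        latent = r.normal(size=(8, 4))
        L = (latent + 0.1 * r.normal(size=(8, 4)))[:, :, None]
        G = latent + 0.1 * r.normal(size=(8, 4))
        paired = loss_xx(L, G, SPEC).item()
        perm = r.permutation(8)
        while np.all(perm == np.arange(8)):
            perm = r.permutation(8)
        shuffled = loss_xx(L, G[perm], SPEC).item()
        wins += shuffled > paired
    assert wins == 20


def test_loss_rr_matches_direct_oracle():
    Zm, Zk = _rand((4, 5), 13), _rand((4, 5), 14)
    spec = ObjectiveSpec(symmetric=False)
    v, _ = o_nce(Zm, Zk, spec)
    assert loss_rr(Zm, Zk, spec).item() == pytest.approx(v, abs=1e-10)
    sym = ObjectiveSpec(symmetric=True)
    v2 = o_nce(Zm, Zk, sym)[0] + o_nce(Zk, Zm, sym)[0]
    assert loss_rr(Zm, Zk, sym).item() == pytest.approx(v2, abs=1e-10)


def test_loss_rr_symmetric_order_invariance():
    Zm, Zk = _rand((5, 3), 15), _rand((5, 3), 16)
    sym = ObjectiveSpec(symmetric=True)
    assert loss_rr(Zm, Zk, sym).item() == pytest.approx(
        loss_rr(Zk, Zm, sym).item(), abs=1e-12)


def test_loss_rr_identical_representations_minimize():
    Z = np.eye(4, 6) * 40
    spec = ObjectiveSpec(symmetric=False, score_clip=None, score_lambda=0)
    assert loss_rr(Z, Z, spec).item() < -3.0


def test_loss_cc_single_location_equals_xx():
    Lm, Lk = _rand((3, 4, 2), 17), _rand((3, 4, 1), 18)
    spec = ObjectiveSpec(cc_samples=1)
    got = loss_cc(Lm, Lk, spec, np.random.default_rng(0)).item()
    expect = loss_xx(Lm, Lk[:, :, 0], spec).item()
    assert got == pytest.approx(expect, abs=1e-12)


def test_loss_cc_seeded_determinism():
    Lm, Lk = _rand((3, 4, 3), 19), _rand((3, 4, 4), 20)
    spec = ObjectiveSpec(cc_samples=2)
    a = loss_cc(Lm, Lk, spec, np.random.default_rng(5)).item()
    b = loss_cc(Lm, Lk, spec, np.random.default_rng(5)).item()
    assert a == b


def test_loss_cc_many_samples_converge_to_exhaustive_average():
    Lm, Lk = _rand((4, 3, 2), 21), _rand((4, 3, 4), 22)
    exhaustive = np.array([
        o_local_global(Lm, Lk[:, :, t], SPEC)[0] for t in range(4)
    ])
    draws = np.array([
        o_local_global(Lm, Lk[:, :, int(t)], SPEC)[0]
        for t in np.random.default_rng(9).integers(4, size=64)
    ])
    spec64 = ObjectiveSpec(cc_samples=64)
    got = loss_cc(Lm, Lk, spec64, np.random.default_rng(9)).item()
    se = exhaustive.std() / np.sqrt(64)
    assert got == pytest.approx(draws.mean(), abs=1e-8)
    assert abs(got - exhaustive.mean()) <= 3 * se + 1e-12


def test_loss_cc_matches_oracle_with_mirrored_rng():
    Lm, Lk = _rand((4, 5, 3), 23), _rand((4, 5, 3), 24)
    spec = ObjectiveSpec(cc_samples=3)
    expect, _ = o_cc(Lm, Lk, spec, np.random.default_rng(2))
    got = loss_cc(Lm, Lk, spec, np.random.default_rng(2)).item()
    assert got == pytest.approx(expect, abs=1e-8)


# ------------------------------------------------------------------ CCA, AE

def test_loss_cca_perfect_correlation_approaches_minus_d():
    Z = _rand((500, 3), 25)
    v = loss_cca(Z, Z.copy(), reg=1e-8).item()
    assert v == pytest.approx(-3.0, abs=1e-3)


def test_loss_cca_independent_sets_near_zero():
    vals = [loss_cca(_rand((2000, 4), 100 + s), _rand((2000, 4), 200 + s),
                     reg=1e-3).item() for s in range(20)]
    assert all(-0.35 <= v <= 0 for v in vals)


def test_loss_cca_d1_equals_negative_absolute_pearson():
    x, y = _rand((200, 1), 26), _rand((200, 1), 27)
    y = 0.6 * x + 0.8 * y
    r = np.corrcoef(x[:, 0], y[:, 0])[0, 1]
    assert loss_cca(x, y, reg=1e-9).item() == pytest.approx(-abs(r), abs=1e-6)


def test_loss_cca_validation():
    with pytest.raises(ValueError):
        loss_cca(_rand((10, 2), 0), _rand((10, 2), 1), reg=0.0)


def test_reconstruction_loss_examples_and_oracle():
    x = _rand((3, 4, 4, 4), 28)
    assert loss_reconstruction(x, x.copy()).item() == 0
    ones = np.ones((2, 3, 3, 3))
    assert loss_reconstruction(ones, np.zeros_like(ones)).item() == pytest.approx(27)
    xh = _rand((3, 4, 4, 4), 29)
    expect = np.mean([np.sum((x[i] - xh[i]) ** 2) for i in range(3)])
    assert loss_reconstruction(x, xh).item() == pytest.approx(expect, abs=1e-10)
    with pytest.raises(ValueError):
        loss_reconstruction(x, xh[:2])


# --------------------------------------------------------------- composition

def _bundles(seed, n=4, d=4, S=2):
    r = np.random.default_rng(seed)
    out = {}
    for m in (1, 2):
        local = r.normal(size=(n, d, S))
        z = r.normal(size=(n, d))
        out[m] = FeatureBundle(
            local=LocalFeatureMap(local, 3, m),
            local_projected=LocalFeatureMap(local, 3, m),
            global_raw=RepresentationSet(z, "global", m),
            global_projected=RepresentationSet(z, "global", m),
        )
    return out


def test_compose_single_rr_equals_symmetric_loss_plus_regularizer():
    b = _bundles(0)
    spec = ObjectiveSpec(terms={"RR"})
    bd = compose_objective(spec, b, np.random.default_rng(0))
    direct = loss_rr(b[1].global_projected, b[2].global_projected, spec).item()
    assert bd.total == pytest.approx(direct + bd.regularizer, abs=1e-10)


def test_compose_xx_cc_equals_sum_of_orderings():
    b = _bundles(1)
    spec = ObjectiveSpec(terms={"XX", "CC"})
    rng = np.random.default_rng(3)
    bd = compose_objective(spec, b, rng)
    mirror = np.random.default_rng(3)
    expect = (
        o_local_global(b[1].local_projected.values.numpy(),
                       b[2].global_projected.vectors.numpy(), spec)[0]
        + o_local_global(b[2].local_projected.values.numpy(),
                         b[1].global_projected.vectors.numpy(), spec)[0]
        + o_cc(b[1].local_projected.values.numpy(),
               b[2].local_projected.values.numpy(), spec, mirror)[0]
        + o_cc(b[2].local_projected.values.numpy(),
               b[1].local_projected.values.numpy(), spec, mirror)[0]
    )
    assert bd.total - bd.regularizer == pytest.approx(expect, abs=1e-8)


def test_compose_rr_xx_cc_term_count():
    bd = compose_objective(ObjectiveSpec(terms={"RR", "XX", "CC"}),
                           _bundles(2), np.random.default_rng(0))
    assert len(bd.per_term) == 6  # 3 terms x 2 orderings


def test_compose_breakdown_total_is_consistent():
    spec = ObjectiveSpec(terms={"CR", "RR"}, weights={"RR": 2.0})
    bd = compose_objective(spec, _bundles(3), np.random.default_rng(0))
    expect = sum(spec.weight(t) * v for (t, _), v in bd.per_term.items())
    assert bd.total == pytest.approx(expect + bd.regularizer, rel=1e-6)


def test_compose_additivity_modulo_regularizer():
    b = _bundles(4)
    rng = lambda: np.random.default_rng(11)
    both = compose_objective(ObjectiveSpec(terms={"RR", "CR"}), b, rng())
    only_rr = compose_objective(ObjectiveSpec(terms={"RR"}), b, rng())
    only_cr = compose_objective(ObjectiveSpec(terms={"CR"}), b, rng())
    lhs = both.total - both.regularizer
    rhs = (only_rr.total - only_rr.regularizer) + (only_cr.total - only_cr.regularizer)
    assert lhs == pytest.approx(rhs, abs=1e-10)


def test_compose_ae_requires_decoder_reconstructions():
    with pytest.raises(ValueError):
        compose_objective(ObjectiveSpec(terms={"RR", "AE"}), _bundles(5),
                          np.random.default_rng(0))


def test_objective_spec_taxonomy_names():
    assert ObjectiveSpec.from_name("RR-XX-CC").terms == {"RR", "XX", "CC"}
    assert ObjectiveSpec.from_name("CR-CCA").terms == {"CR", "CCA"}
    assert ObjectiveSpec.from_name("RR-AE").terms == {"RR", "AE"}
    with pytest.raises(ValueError):
        ObjectiveSpec(terms=set())
    with pytest.raises(ValueError):
        ObjectiveSpec.from_name("RR-BOGUS")


# ------------------------------------------------------------ gradient sanity

def _fd_check(loss_fn, arrays, tol=1e-4):
    ts = [Tensor(a.copy(), requires_grad=True) for a in arrays]
    loss_fn(*ts).backward()
    for k, t in enumerate(ts):
        def scalar(x, _k=k):
            args = [a.copy() for a in arrays]
            args[_k] = x
            return loss_fn(*[Tensor(a) for a in args]).item()

        num = finite_difference_grad(scalar, arrays[k].copy())
        err = np.max(np.abs(t.grad - num) / (np.abs(num) + 1e-3))
        assert err < tol, f"arg {k}: rel err {err}"


@pytest.mark.parametrize("name", ["CR", "XX", "RR", "CC", "CCA", "AE"])
def test_loss_gradients_match_finite_differences(name):
    r = np.random.default_rng(42)
    spec = ObjectiveSpec(terms={name} if name != "AE" else {"AE"})
    if name in ("CR", "XX"):
        L, G = r.normal(size=(3, 4, 2)), r.normal(size=(3, 4))
        fn = loss_cr if name == "CR" else loss_xx
        _fd_check(lambda a, b: fn(a, b, spec), [L, G])
    elif name == "RR":
        _fd_check(lambda a, b: loss_rr(a, b, spec),
                  [r.normal(size=(3, 4)), r.normal(size=(3, 4))])
    elif name == "CC":
        Lm, Lk = r.normal(size=(3, 4, 2)), r.normal(size=(3, 4, 2))
        _fd_check(lambda a, b: loss_cc(a, b, spec, np.random.default_rng(1)),
                  [Lm, Lk])
    elif name == "CCA":
        _fd_check(lambda a, b: loss_cca(a, b, reg=1e-2),
                  [r.normal(size=(12, 4)), r.normal(size=(12, 4))])
    else:
        _fd_check(loss_reconstruction,
                  [r.normal(size=(3, 2, 2, 2)), r.normal(size=(3, 2, 2, 2))])
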