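"""Contrastive objectives for multi-scale coordinated multimodal learning.

The estimator of mutual information is InfoNCE: classify the true pairing of
two representation sets against in-batch negatives through a softmax over
critic scores.  The critic is a scaled dot product.  Four principal
objectives arise from contrasting local (intermediate convolutional) and
global (final) representations within and across modalities:

* CR — intra-modal local-to-global ("deep infomax" style),
* XX — cross-modal local-to-global,
* RR — cross-modal global-to-global,
* CC — cross-modal local-to-local (with location subsampling).

Any non-empty subset of these (plus a CCA term and an autoencoding
reconstruction term for the hybrid baselines) composes into a training
objective; score clipping and a squared-score penalty regularize every
InfoNCE term.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn.autograd import Tensor, as_tensor

TAXONOMY_TERMS = ("CR", "XX", "RR", "CC", "CCA", "AE")

__all__ = [
    "RepresentationSet", "LocalFeatureMap", "ScoreMatrix", "ObjectiveSpec",
    "LossBreakdown", "critic_scores", "regularize_scores", "infonce",
    "loss_cr", "loss_xx", "loss_rr", "loss_cc", "loss_cca",
    "loss_reconstruction", "compose_objective", "TAXONOMY_TERMS",
]


# --------------------------------------------------------------------- types

@dataclass
class RepresentationSet:
    """n paired representation vectors (rows = samples, columns = dims)."""

    vectors: object  # (n, d) array or Tensor
    source: str = "global"
    modality_id: int = 1

    def __post_init__(self):
        t = as_tensor(self.vectors)
        if t.ndim != 2:
            raise ValueError("vectors must be an n×d matrix")
        if not np.all(np.isfinite(t.data)):
            raise ValueError("non-finite representation vectors")
        self.vectors = t

    @property
    def n(self):
        return self.vectors.shape[0]

    @property
    def d(self):
        return self.vectors.shape[1]


@dataclass
class LocalFeatureMap:
    """Intermediate convolutional features: (n, C, S) with S = s³ locations."""

    values: object  # (n, C, S) array or Tensor
    layer_index: int = 3
    modality_id: int = 1

    def __post_init__(self):
        t = as_tensor(self.values)
        if t.ndim != 3:
            raise ValueError("values must be an n×C×S array")
        if not np.all(np.isfinite(t.data)):
            raise ValueError("non-finite local features")
        self.values = t

    @property
    def n(self):
        return self.values.shape[0]

    @property
    def channels(self):
        return self.values.shape[1]

    @property
    def n_locations(self):
        return self.values.shape[2]

    def location(self, s: int) -> Tensor:
        return self.values[:, :, s]


@dataclass
class ScoreMatrix:
    """n×n critic scores; entry (i,j) = f(x_i, y_j)."""

    scores: Tensor
    clipped: bool = False
    penalty: Tensor = field(default_factory=lambda: Tensor(0.0))


@dataclass
class ObjectiveSpec:
    """One node of the objective taxonomy: which terms are summed and how."""

    terms: frozenset = frozenset({"RR"})
    weights: dict = field(default_factory=dict)
    symmetric: bool = True
    cc_samples: int = 1
    critic_scale: str = "sqrt_d"  # or "d"
    score_lambda: float = 4e-2
    score_clip: float | None = 20.0
    exclude_positive: bool = True  # positive excluded from the denominator
    penalty_on_raw: bool = True    # squared-score penalty uses pre-clip scores
    cca_reg: float = 1e-3

    def __post_init__(self):
        self.terms = frozenset(self.terms)
        if not self.terms:
            raise ValueError("ObjectiveSpec.terms must be non-empty")
        unknown = self.terms - set(TAXONOMY_TERMS)
        if unknown:
            raise ValueError(f"unknown objective terms: {sorted(unknown)}")
        if self.cc_samples < 1:
            raise ValueError("cc_samples must be >= 1")
        if self.critic_scale not in ("sqrt_d", "d"):
            raise ValueError("critic_scale must be 'sqrt_d' or 'd'")

    @classmethod
    def from_name(cls, name: str, **kw) -> "ObjectiveSpec":
        """Parse taxonomy names like 'RR-XX-CC', 'CR-CCA', 'RR-AE', 'AE'."""
        terms = frozenset(part.upper() for part in name.split("-"))
        return cls(terms=terms, **kw)

    @property
    def name(self) -> str:
        order = {t: i for i, t in enumerate(TAXONOMY_TERMS)}
        return "-".join(sorted(self.terms, key=order.get))

    def weight(self, term: str) -> float:
        return float(self.weights.get(term, 1.0))


@dataclass
class LossBreakdown:
    total: float
    per_term: dict           # (term, (m, k)) -> float
    regularizer: float
    total_tensor: Tensor | None = None


# ---------------------------------------------------------------- operations

def _vec(x) -> Tensor:
    if isinstance(x, RepresentationSet):
        return x.vectors
    return as_tensor(x)


def _loc(x) -> Tensor:
    if isinstance(x, LocalFeatureMap):
        return x.values
    return as_tensor(x)


def critic_scores(X, Y, spec: ObjectiveSpec | None = None) -> ScoreMatrix:
    """Scaled dot-product critic: scores[i, j] = x_iᵀ y_j / divisor."""
    spec = spec or ObjectiveSpec()
    Xt, Yt = _vec(X), _vec(Y)
    if Xt.shape != Yt.shape:
        raise ValueError(f"shape mismatch {Xt.shape} vs {Yt.shape}")
    if not (np.all(np.isfinite(Xt.data)) and np.all(np.isfinite(Yt.data))):
        raise ValueError("non-finite inputs to critic")
    d = Xt.shape[1]
    divisor = float(np.sqrt(d)) if spec.critic_scale == "sqrt_d" else float(d)
    return ScoreMatrix(scores=(Xt @ Yt.T) / divisor, clipped=False)


def regularize_scores(S: ScoreMatrix, lambda_: float = 4e-2,
                      c: float = 20.0) -> ScoreMatrix:
    """Clip scores to c·tanh(s/c) and record the λ·mean(s²) penalty.

    The penalty is computed on the raw (pre-clip) scores.
    """
    if S.clipped:
        raise ValueError("scores already clipped")
    if c <= 0:
        raise ValueError("clip constant c must be positive")
    if lambda_ < 0:
        raise ValueError("lambda must be non-negative")
    raw = S.scores
    penalty = lambda_ * (raw**2).mean()
    clipped = (raw / c).tanh() * c
    return ScoreMatrix(scores=clipped, clipped=True, penalty=penalty)


def infonce(S, exclude_positive: bool = True) -> Tensor:
    """InfoNCE lower bound on mutual information from an n×n score matrix.

    (1/N) Σ_i [s_ii − log((1/N) Σ_j e^{s_ij})], with j ≠ i excluded from the
    denominator sum when ``exclude_positive`` (the default, following the
    printed indicator); with the positive included the bound is ≤ log N.
    """
    scores = S.scores if isinstance(S, ScoreMatrix) else as_tensor(S)
    n = scores.shape[0]
    if scores.ndim != 2 or scores.shape[1] != n:
        raise ValueError("score matrix must be square")
    if n < 2:
        raise ValueError("InfoNCE needs n >= 2 (no negatives otherwise)")
    mask = None if not exclude_positive else ~np.eye(n, dtype=bool)
    lse = scores.logsumexp(1, mask)          # log Σ_j e^{s_ij}
    diag = scores[np.arange(n), np.arange(n)]
    return (diag - lse).mean() + float(np.log(n))


def _nce_term(X: Tensor, Y: Tensor, spec: ObjectiveSpec):
    """Regularized negative InfoNCE between two (n, d) sets.

    Returns (loss, penalty): the minimizable loss and the squared-score
    penalty contribution.
    """
    S = critic_scores(X, Y, spec)
    if spec.score_clip is not None:
        S = regularize_scores(S, spec.score_lambda, spec.score_clip)
    elif spec.score_lambda:
        S = ScoreMatrix(scores=S.scores, clipped=False,
                        penalty=spec.score_lambda * (S.scores**2).mean())
    return -infonce(S, spec.exclude_positive), S.penalty


def _location_scores(local: Tensor, glob: Tensor) -> Tensor:
    """Batched critic numerators: (n,d,S),(n,d) -> (S,n,n) dot products."""
    out_data = np.einsum("nds,md->snm", local.data, glob.data, optimize=True)

    def bw(g):
        if local.requires_grad:
            Tensor._accum(local, np.einsum("snm,md->nds", g, glob.data, optimize=True))
        if glob.requires_grad:
            Tensor._accum(glob, np.einsum("snm,nds->md", g, local.data, optimize=True))

    out = Tensor(out_data)
    if local.requires_grad or glob.requires_grad:
        out.requires_grad = True
        out._parents = (local, glob)
        out._backward = bw
    return out


def _local_vs_global(local: Tensor, glob: Tensor, spec: ObjectiveSpec):
    """Mean regularized negative InfoNCE of every location against a global set.

    Each of the S locations contributes its own n-sample contrastive term
    (positives on the diagonal); the S terms are averaged.  Vectorized over
    locations via an (S, n, n) score tensor.
    """
    if local.shape[0] != glob.shape[0]:
        raise ValueError("batch size mismatch between local and global inputs")
    if local.shape[1] != glob.shape[1]:
        raise ValueError("projected local channels must equal global dimension")
    n = glob.shape[0]
    if n < 2:
        raise ValueError("InfoNCE needs n >= 2")
    d = glob.shape[1]
    divisor = float(np.sqrt(d)) if spec.critic_scale == "sqrt_d" else float(d)
    raw = _location_scores(local, glob) / divisor
    pen = spec.score_lambda * (raw**2).mean()
    s = (raw / spec.score_clip).tanh() * spec.score_clip if spec.score_clip else raw
    mask = ~np.eye(n, dtype=bool) if spec.exclude_positive else None
    lse = s.logsumexp(2, mask)                       # (S, n)
    idx = np.arange(n)
    diag = s[:, idx, idx]                            # (S, n)
    loss = -((diag - lse).mean() + float(np.log(n)))
    return loss, pen


def loss_cr(local, global_rep, spec: ObjectiveSpec | None = None) -> Tensor:
    """Intra-modal local-to-global objective for one modality."""
    spec = spec or ObjectiveSpec(terms={"CR"})
    if isinstance(local, LocalFeatureMap) and isinstance(global_rep, RepresentationSet):
        if local.modality_id != global_rep.modality_id:
            raise ValueError("CR is intra-modal: modality ids must match")
    loss, _ = _local_vs_global(_loc(local), _vec(global_rep), spec)
    return loss


def loss_xx(local_m, global_k, spec: ObjectiveSpec | None = None) -> Tensor:
    """Cross-modal local-to-global objective, one ordering (m, k)."""
    spec = spec or ObjectiveSpec(terms={"XX"})
    if isinstance(local_m, LocalFeatureMap) and isinstance(global_k, RepresentationSet):
        if local_m.modality_id == global_k.modality_id:
            raise ValueError("XX is cross-modal: modality ids must differ")
    loss, _ = _local_vs_global(_loc(local_m), _vec(global_k), spec)
    return loss


def loss_rr(global_m, global_k, spec: ObjectiveSpec | None = None) -> Tensor:
    """Cross-modal global-to-global objective.

    With ``spec.symmetric`` both modality orderings are computed and summed.
    """
    spec = spec or ObjectiveSpec(terms={"RR"})
    Zm, Zk = _vec(global_m), _vec(global_k)
    if Zm.shape != Zk.shape:
        raise ValueError("global sets must share n and d")
    if Zm.shape[0] < 2:
        raise ValueError("InfoNCE needs n >= 2")
    loss, _ = _nce_term(Zm, Zk, spec)
    if spec.symmetric:
        loss2, _ = _nce_term(Zk, Zm, spec)
        loss = loss + loss2
    return loss


def loss_cc(local_m, local_k, spec: ObjectiveSpec | None = None,
            rng: np.random.Generator | None = None) -> Tensor:
    """Cross-modal local-to-local objective, one ordering (m, k).

    One location of modality k's map is sampled uniformly per draw and
    treated as the global set; averaged over ``spec.cc_samples`` draws.
    """
    spec = spec or ObjectiveSpec(terms={"CC"})
    rng = rng if rng is not None else np.random.default_rng(0)
    Lm, Lk = _loc(local_m), _loc(local_k)
    if isinstance(local_m, LocalFeatureMap) and isinstance(local_k, LocalFeatureMap):
        if local_m.modality_id == local_k.modality_id:
            raise ValueError("CC is cross-modal: modality ids must differ")
    T = Lk.shape[2]
    if T == 0:
        raise ValueError("modality k has no locations to sample")
    total = None
    for _ in range(spec.cc_samples):
        t = int(rng.integers(T))
        draw, _ = _local_vs_global(Lm, Lk[:, :, t], spec)
        total = draw if total is None else total + draw
    return total / spec.cc_samples


def _cc_term(Lm: Tensor, Lk: Tensor, spec: ObjectiveSpec, rng):
    T = Lk.shape[2]
    loss = pen = None
    for _ in range(spec.cc_samples):
        t = int(rng.integers(T))
        l, p = _local_vs_global(Lm, Lk[:, :, t], spec)
        loss = l if loss is None else loss + l
        pen = p if pen is None else pen + p
    return loss / spec.cc_samples, pen / spec.cc_samples


# ------------------------------------------------------------------ CCA / AE

def loss_cca(Zm, Zk, reg: float = 1e-3) -> Tensor:
    """Negative sum of canonical correlations of two column-centered sets.

    Computed as the trace (nuclear) norm of the whitened cross-covariance
    T = Σ₁₁^{-1/2} Σ₁₂ Σ₂₂^{-1/2} with ridge ``reg`` on both covariance
    diagonals; value in [−d, 0].  The gradient is implemented analytically
    through the eigendecompositions of the covariances.
    """
    Zm, Zk = _vec(Zm), _vec(Zk)
    if Zm.shape[0] != Zk.shape[0]:
        raise ValueError("sample counts must match")
    if reg <= 0:
        raise ValueError("reg must be positive")
    n = Zm.shape[0]
    Hm = Zm.data - Zm.data.mean(axis=0)
    Hk = Zk.data - Zk.data.mean(axis=0)
    denom = max(n - 1, 1)
    S11 = Hm.T @ Hm / denom + reg * np.eye(Hm.shape[1])
    S22 = Hk.T @ Hk / denom + reg * np.eye(Hk.shape[1])
    S12 = Hm.T @ Hk / denom

    lam1, Q1 = np.linalg.eigh(S11)
    lam2, Q2 = np.linalg.eigh(S22)
    if lam1.min() < 1e-12 or lam2.min() < 1e-12:
        raise np.linalg.LinAlgError(
            f"regularized covariance is singular; increase reg (reg={reg})")
    A = (Q1 * lam1**-0.5) @ Q1.T
    B = (Q2 * lam2**-0.5) @ Q2.T
    Tmat = A @ S12 @ B
    U, sig, Vt = np.linalg.svd(Tmat)
    value = -float(sig.sum())

    def _invsqrt_vjp(G, lam, Q):
        """Adjoint of S -> S^{-1/2} at symmetric S = Q diag(lam) Qᵀ."""
        Gs = 0.5 * (G + G.T)
        h = lam**-0.5
        diff = lam[:, None] - lam[None, :]
        K = np.where(np.abs(diff) > 1e-12,
                     (h[:, None] - h[None, :]) / np.where(diff == 0, 1, diff),
                     -0.5 * lam[:, None]**-1.5)
        return Q @ ((Q.T @ Gs @ Q) * K) @ Q.T

    def bw(g):
        g = float(g)
        GT = -g * (U @ Vt)                    # d(loss)/dT
        G12 = A @ GT @ B
        GA = GT @ B @ S12.T
        GB = S12.T @ A @ GT
        G11 = _invsqrt_vjp(GA, lam1, Q1)
        G22 = _invsqrt_vjp(GB, lam2, Q2)
        gHm = (Hm @ (G11 + G11.T) + Hk @ G12.T) / denom
        gHk = (Hk @ (G22 + G22.T) + Hm @ G12) / denom
        gZm = gHm - gHm.mean(axis=0)
        gZk = gHk - gHk.mean(axis=0)
        Tensor._accum(Zm, gZm)
        Tensor._accum(Zk, gZk)

    out = Tensor(value)
    if Zm.requires_grad or Zk.requires_grad:
        out.requires_grad = True
        out._parents = (Zm, Zk)
        out._backward = bw
    return out


def loss_reconstruction(x, x_hat) -> Tensor:
    """Mean over the batch of the per-sample squared Euclidean norm of x − x̂."""
    xt, ht = as_tensor(x), as_tensor(x_hat)
    if xt.shape != ht.shape:
        raise ValueError(f"shape mismatch {xt.shape} vs {ht.shape}")
    n = xt.shape[0]
    diff = xt - ht
    return (diff**2).sum() / float(n)


# ------------------------------------------------------------- composition

def compose_objective(spec: ObjectiveSpec, bundles: dict,
                      rng: np.random.Generator | None = None,
                      recons: dict | None = None) -> LossBreakdown:
    """Sum the requested taxonomy terms over a pair of modality bundles.

    ``bundles`` maps modality id -> FeatureBundle (see networks module);
    ``recons`` maps modality id -> (input volume batch, reconstruction) and
    is required when the AE term is present.  Both modality orderings are
    computed for the cross-modal InfoNCE terms when ``spec.symmetric``.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    mods = sorted(bundles)
    if len(mods) != 2:
        raise ValueError("compositions are defined pairwise (exactly 2 modalities)")
    m, k = mods
    per_term: dict = {}
    tensors: dict = {}
    penalty = None

    def add(term, pair, loss, pen=None):
        nonlocal penalty
        tensors[(term, pair)] = loss
        per_term[(term, pair)] = loss.item()
        if pen is not None:
            penalty = pen if penalty is None else penalty + pen

    orderings = [(m, k), (k, m)] if spec.symmetric else [(m, k)]

    if "CR" in spec.terms:
        for mod in mods:
            b = bundles[mod]
            l, p = _local_vs_global(_loc(b.local_projected), _vec(b.global_projected), spec)
            add("CR", (mod, mod), l, p)
    if "XX" in spec.terms:
        for a, b_ in orderings:
            l, p = _local_vs_global(_loc(bundles[a].local_projected),
                                    _vec(bundles[b_].global_projected), spec)
            add("XX", (a, b_), l, p)
    if "RR" in spec.terms:
        for a, b_ in orderings:
            l, p = _nce_term(_vec(bundles[a].global_projected),
                             _vec(bundles[b_].global_projected), spec)
            add("RR", (a, b_), l, p)
    if "CC" in spec.terms:
        for a, b_ in orderings:
            l, p = _cc_term(_loc(bundles[a].local_projected),
                            _loc(bundles[b_].local_projected), spec, rng)
            add("CC", (a, b_), l, p)
    if "CCA" in spec.terms:
        add("CCA", (m, k), loss_cca(bundles[m].global_projected,
                                    bundles[k].global_projected, spec.cca_reg))
    if "AE" in spec.terms:
        if not recons:
            raise ValueError("AE term requires decoder reconstructions")
        for mod in mods:
            x, x_hat = recons[mod]
            add("AE", (mod, mod), loss_reconstruction(x, x_hat))

    total = None
    for (term, pair), t in tensors.items():
        wt = spec.weight(term) * t
        total = wt if total is None else total + wt
    if penalty is not None:
        total = total + penalty
    reg_val = penalty.item() if penalty is not None else 0.0
    return LossBreakdown(total=total.item(), per_term=per_term,
                         regularizer=reg_val, total_tensor=total)
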