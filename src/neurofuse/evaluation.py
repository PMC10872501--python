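"""Frozen-encoder evaluation: linear probing with a seeded hyperparameter
search, CKA alignment between modalities, checkpoint selection, and the
label-efficiency protocol."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import permutations

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.preprocessing import StandardScaler

__all__ = ["ProbeSearchSpace", "ProbeResult", "CKAResult", "linear_probe",
           "roc_auc_ovo_macro", "cka", "cka_gram", "select_checkpoint",
           "label_efficiency", "extract_representations"]


@dataclass
class ProbeSearchSpace:
    """Elastic-net logistic regression search space (SAGA solver).

    C is sampled log-uniformly on [c_low, c_high]; the elastic-net mixing
    parameter uniformly on [0, 1]; ``budget`` seeded random-search trials.
    """

    c_low: float = 1e-6
    c_high: float = 1e3
    budget: int = 500
    max_iter: int = 2000
    standardize: bool = True

    def __post_init__(self):
        if self.budget < 1:
            raise ValueError("budget must be >= 1")


@dataclass
class ProbeResult:
    metric_value: float
    betas: np.ndarray
    chosen_hparams: dict
    fold_id: int = 0
    modality_id: int = 0
    model: object = field(default=None, repr=False)


@dataclass
class CKAResult:
    value: float
    n: int
    centered: bool = True


def roc_auc_ovo_macro(y, scores) -> float:
    """Macro one-vs-one ROC-AUC: mean pairwise AUC over ordered class pairs.

    For K = 2 this reduces to the plain ROC-AUC.  ``scores`` is (n, K) with
    columns in sorted class order (or (n,) for binary positive-class scores).
    """
    y = np.asarray(y)
    scores = np.asarray(scores, dtype=np.float64)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("need at least two classes")
    if scores.ndim == 1:
        if len(classes) != 2:
            raise ValueError("1-D scores only valid for binary labels")
        return float(roc_auc_score(y == classes[1], scores))
    if scores.shape[1] != len(classes):
        raise ValueError("score matrix must have one column per class")
    if len(classes) == 2:
        return float(roc_auc_score(y == classes[1], scores[:, 1]))
    col = {c: i for i, c in enumerate(classes)}
    aucs = []
    for a, b in permutations(classes, 2):
        sel = np.isin(y, (a, b))
        aucs.append(roc_auc_score(y[sel] == a, scores[sel, col[a]]))
    return float(np.mean(aucs))


def _score(model, Z, y) -> float:
    classes = np.unique(y)
    prob = model.predict_proba(Z)
    if len(classes) == 2:
        return float(roc_auc_score(y == model.classes_[1], prob[:, 1]))
    # align probability columns with sorted label order
    order = np.argsort(model.classes_)
    return roc_auc_ovo_macro(y, prob[:, order])


def linear_probe(Z_train, y_train, Z_val, y_val,
                 space: ProbeSearchSpace | None = None, seed: int = 0,
                 fold_id: int = 0, modality_id: int = 0) -> ProbeResult:
    """Elastic-net logistic probe on frozen representations.

    Random-search over (C, l1_ratio) with ``space.budget`` trials; the
    configuration with the best validation ROC-AUC (macro OVO ROC-AUC for
    three or more classes) is returned with its coefficients.
    """
    space = space or ProbeSearchSpace()
    y_train, y_val = np.asarray(y_train), np.asarray(y_val)
    if len(np.unique(y_train)) < 2 or len(np.unique(y_val)) < 2:
        raise ValueError("both splits must contain at least two classes")
    rng = np.random.default_rng(seed)
    scaler = None
    if space.standardize:
        scaler = StandardScaler().fit(Z_train)
        Z_train, Z_val = scaler.transform(Z_train), scaler.transform(Z_val)
    best = None
    for _ in range(space.budget):
        C = float(np.exp(rng.uniform(np.log(space.c_low), np.log(space.c_high))))
        l1 = float(rng.uniform(0.0, 1.0))
        clf = LogisticRegression(penalty="elasticnet", solver="saga", C=C,
                                 l1_ratio=l1, max_iter=space.max_iter, tol=1e-4)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            clf.fit(Z_train, y_train)
        metric = _score(clf, Z_val, y_val)
        if best is None or metric > best[0]:
            best = (metric, clf, {"C": C, "l1_ratio": l1})
    metric, clf, hparams = best
    return ProbeResult(metric_value=metric, betas=clf.coef_.copy(),
                       chosen_hparams=hparams, fold_id=fold_id,
                       modality_id=modality_id, model=(clf, scaler))


def cka(Zm, Zk, center: bool = True) -> CKAResult:
    """Linear centered kernel alignment between two representation matrices.

    ‖Z_kᵀZ_m‖²_F / (‖Z_mᵀZ_m‖_F · ‖Z_kᵀZ_k‖_F) after column centering;
    invariant to orthogonal transforms and isotropic scaling, in [0, 1].
    """
    Zm = np.asarray(Zm, dtype=np.float64)
    Zk = np.asarray(Zk, dtype=np.float64)
    if Zm.shape[0] != Zk.shape[0] or Zm.shape[0] < 2:
        raise ValueError("need matching sample counts with n >= 2")
    if center:
        Zm = Zm - Zm.mean(axis=0)
        Zk = Zk - Zk.mean(axis=0)
    denom = np.linalg.norm(Zm.T @ Zm) * np.linalg.norm(Zk.T @ Zk)
    if denom == 0:
        raise ValueError("zero-variance input: CKA undefined")
    value = np.linalg.norm(Zk.T @ Zm) ** 2 / denom
    return CKAResult(value=float(value), n=Zm.shape[0], centered=center)


def cka_gram(Zm, Zk) -> float:
    """HSIC-ratio formulation via n×n centered Gram matrices (O(n²) memory).

    Mathematically identical to :func:`cka`; kept as an independent route for
    cross-checking.
    """
    Zm = np.asarray(Zm, dtype=np.float64)
    Zk = np.asarray(Zk, dtype=np.float64)
    n = Zm.shape[0]
    H = np.eye(n) - np.ones((n, n)) / n
    Km = H @ (Zm @ Zm.T) @ H
    Kk = H @ (Zk @ Zk.T) @ H
    hsic = float(np.sum(Km * Kk))
    return hsic / np.sqrt(np.sum(Km * Km) * np.sum(Kk * Kk))


def select_checkpoint(per_checkpoint_metrics) -> object:
    """Argmax over checkpoints of the cross-modality mean metric.

    Accepts a DataFrame (rows = checkpoints, columns = modalities) or a dict
    {checkpoint: {modality: metric}}.  Ties break toward the later checkpoint
    (larger row label).
    """
    if isinstance(per_checkpoint_metrics, dict):
        table = pd.DataFrame(per_checkpoint_metrics).T
    else:
        table = pd.DataFrame(per_checkpoint_metrics)
    if table.empty:
        raise ValueError("empty metric table")
    means = table.mean(axis=1)
    best = means.max()
    winners = means.index[means == best]
    return max(winners)


def label_efficiency(Z_train, y_train, Z_val, y_val,
                     fractions=(0.10, 0.25, 0.50, 0.75, 1.00),
                     space: ProbeSearchSpace | None = None,
                     seed: int = 0) -> pd.DataFrame:
    """Probe metric as a function of the labeled-training fraction.

    The encoder (hence Z) is fixed; only the probe sees fewer labels.
    Subsets are stratified and nested under a fixed seed.  Fractions leaving a
    class empty are skipped with a warning.
    """
    y_train = np.asarray(y_train)
    rng = np.random.default_rng(seed)
    order_per_class = {c: rng.permutation(np.flatnonzero(y_train == c))
                       for c in np.unique(y_train)}
    rows = []
    for frac in fractions:
        idx = np.concatenate([
            order[:int(np.ceil(frac * len(order)))]
            for order in order_per_class.values()
        ])
        sub_y = y_train[idx]
        if len(np.unique(sub_y)) < 2:
            warnings.warn(f"fraction {frac} leaves a class empty; skipped")
            continue
        res = linear_probe(np.asarray(Z_train)[idx], sub_y, Z_val, y_val,
                           space, seed=seed)
        rows.append({"fraction": frac, "n_labeled": len(idx),
                     "metric": res.metric_value})
    return pd.DataFrame(rows, columns=["fraction", "n_labeled", "metric"])


def extract_representations(model, volumes: np.ndarray,
                            batch_size: int = 64,
                            rescale: bool = True) -> np.ndarray:
    """Frozen-encoder global representations z for a stack of volumes."""
    from .nn.autograd import Tensor, no_grad
    from .training import minmax_rescale

    model.eval()
    out = []
    with no_grad():
        for start in range(0, len(volumes), batch_size):
            vb = volumes[start:start + batch_size]
            if rescale:
                vb = np.stack([minmax_rescale(v) for v in vb])
            xb = np.ascontiguousarray(vb[:, None], dtype=model.dtype)
            out.append(model.encode(Tensor(xb)).numpy().astype(np.float64))
    model.train()
    return np.concatenate(out)
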