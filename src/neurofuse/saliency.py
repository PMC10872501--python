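"""Voxel-space interpretability: per-dimension integrated gradients, voxel-wise
group testing with rank-biserial effect sizes, FDR control, and atlas peak
matching.

The pipeline for one representation dimension:

1. integrated gradients of z_dim with respect to the input volume, per subject
   (signed attributions are kept);
2. brain masking and Gaussian smoothing of each attribution map;
3. per voxel, a two-sided Mann–Whitney U test between the two groups' maps,
   with the rank-biserial correlation RBC = 2U/(n₁n₂) − 1 as effect size
   (positive ⇒ the network is more sensitive there in the case group);
4. Benjamini–Hochberg FDR at α across voxels;
5. for each atlas ROI, the significant-voxel RBC of maximal absolute value
   (sign retained).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from statsmodels.stats.multitest import multipletests

from .nn.autograd import Tensor

__all__ = [
    "AttributionMap", "RBCMap", "AtlasDef", "integrated_gradients_dim",
    "attribution_maps", "postprocess_map", "rbc_from_u", "voxelwise_group_test",
    "fdr_bh", "atlas_peak_match", "rbc_pipeline",
]


@dataclass
class AttributionMap:
    values: np.ndarray              # (..., s, s, s) signed attributions
    dimension: int
    steps: int = 50
    baseline: str = "zero"


@dataclass
class RBCMap:
    rbc: np.ndarray
    pvals: np.ndarray
    significant: np.ndarray
    dimension: int


@dataclass
class AtlasDef:
    """Integer-labeled volume (0 = background) with ROI names."""

    labels: np.ndarray
    roi_names: dict = field(default_factory=dict)

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if not self.roi_names:
            ids = np.unique(self.labels)
            self.roi_names = {int(i): f"ROI {int(i)}" for i in ids if i != 0}

    @property
    def roi_ids(self):
        return sorted(self.roi_names)

    def mask(self, roi_id: int) -> np.ndarray:
        return self.labels == roi_id


# ------------------------------------------------------------------ IG

def integrated_gradients_dim(encoder, x: np.ndarray, dim: int,
                             baseline: np.ndarray | None = None,
                             steps: int = 50) -> AttributionMap:
    """Integrated gradients of one representation dimension for one volume.

    ``encoder`` is any callable mapping a Tensor (N,1,s,s,s) to (N,d); the
    straight path from ``baseline`` (default all-zero) to ``x`` is discretized
    at midpoints of ``steps`` equal intervals (a midpoint Riemann sum, which
    converges to the completeness identity as steps grow).
    """
    maps = attribution_maps(encoder, x[None], dim, baseline=baseline, steps=steps)
    return AttributionMap(maps.values[0], dim, steps, maps.baseline)


def attribution_maps(encoder, x: np.ndarray, dim: int,
                     baseline: np.ndarray | None = None,
                     steps: int = 50) -> AttributionMap:
    """Batched integrated gradients: x is (N, s, s, s) -> values (N, s, s, s)."""
    x = np.asarray(x, dtype=np.float64)
    n = x.shape[0]
    b = np.zeros_like(x) if baseline is None else np.broadcast_to(
        np.asarray(baseline, dtype=np.float64), x.shape)
    d_probe = encoder(Tensor(x[:1, None])).shape[1]
    if not 0 <= dim < d_probe:
        raise ValueError(f"dimension {dim} out of range for d={d_probe}")
    diff = x - b
    grad_sum = np.zeros_like(x)
    for s in range(steps):
        alpha = (s + 0.5) / steps
        xt = Tensor(b + alpha * diff, requires_grad=True)
        z = encoder(xt.reshape(n, 1, *x.shape[1:]))
        z[:, dim].sum().backward()
        grad_sum += xt.grad
    values = diff * grad_sum / steps
    return AttributionMap(values, dim, steps, "zero" if baseline is None else "custom")


# --------------------------------------------------------------- processing

def postprocess_map(a: AttributionMap, mask: np.ndarray,
                    sigma: float = 1.5) -> AttributionMap:
    """Gaussian-smooth (σ in voxels, reflect boundaries) then apply the mask."""
    mask = np.asarray(mask)
    if not np.isin(mask, (0, 1)).all():
        raise ValueError("mask must be binary")
    if mask.shape != a.values.shape[-3:]:
        raise ValueError("mask grid must match the attribution grid")
    vals = a.values
    if sigma > 0:
        axes = tuple(range(vals.ndim - 3, vals.ndim))
        vals = ndimage.gaussian_filter(vals, sigma=sigma, mode="reflect", axes=axes)
    vals = vals * mask
    return AttributionMap(vals, a.dimension, a.steps, a.baseline)


def rbc_from_u(U: float, n1: int, n2: int) -> float:
    """Rank-biserial correlation 2U/(n₁n₂) − 1.

    U counts (group-1, group-2) pairs where the group-1 value is greater
    (ties count ½); positive RBC ⇒ group 1 stochastically larger.
    """
    if not 0 <= U <= n1 * n2:
        raise ValueError("U out of range [0, n1*n2]")
    return 2.0 * U / (n1 * n2) - 1.0


def voxelwise_group_test(maps_group1: np.ndarray,
                         maps_group2: np.ndarray) -> tuple:
    """Per-voxel two-sided Mann–Whitney U tests between two map stacks.

    Inputs are (n₁, …grid) and (n₂, …grid); returns (pvals, rbc) on the grid.
    The normal approximation with tie correction and continuity correction is
    used.  Voxels constant across both groups get p = 1, rbc = 0.
    """
    g1 = np.asarray(maps_group1, dtype=np.float64)
    g2 = np.asarray(maps_group2, dtype=np.float64)
    n1, n2 = g1.shape[0], g2.shape[0]
    if n1 < 3 or n2 < 3:
        raise ValueError("need at least 3 subjects per group")
    grid = g1.shape[1:]
    flat1 = g1.reshape(n1, -1)
    flat2 = g2.reshape(n2, -1)
    const = (np.ptp(flat1, axis=0) == 0) & (np.ptp(flat2, axis=0) == 0) & (
        np.abs(flat1[0] - flat2[0]) == 0)
    res = stats.mannwhitneyu(flat1, flat2, axis=0, method="asymptotic",
                             alternative="two-sided")
    pvals = np.asarray(res.pvalue, dtype=np.float64)
    rbc = 2.0 * np.asarray(res.statistic) / (n1 * n2) - 1.0
    pvals[const] = 1.0
    rbc[const] = 0.0
    return pvals.reshape(grid), rbc.reshape(grid)


def fdr_bh(pvals: np.ndarray, alpha: float = 0.05) -> np.ndarray:
    """Benjamini–Hochberg step-up rejection mask at level alpha."""
    p = np.asarray(pvals, dtype=np.float64)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject = multipletests(p.ravel(), alpha=alpha, method="fdr_bh")[0]
    return reject.reshape(p.shape)


def atlas_peak_match(r: RBCMap, atlas: AtlasDef) -> pd.DataFrame:
    """Per-ROI peak effect: sign(max(abs)) over the ROI's significant voxels.

    ROIs without significant voxels are omitted.  Returns columns
    roi_id, roi_name, dimension, peak_rbc, n_sig_voxels.
    """
    if atlas.labels.shape != r.rbc.shape:
        raise ValueError("atlas grid must match the map grid")
    rows = []
    for roi_id in atlas.roi_ids:
        m = atlas.mask(roi_id)
        if not m.any():
            continue  # label absent from the grid
        sel = m & r.significant
        if not sel.any():
            continue
        vals = r.rbc[sel]
        peak = vals[np.argmax(np.abs(vals))]
        rows.append({"roi_id": roi_id, "roi_name": atlas.roi_names[roi_id],
                     "dimension": r.dimension, "peak_rbc": float(peak),
                     "n_sig_voxels": int(sel.sum())})
    return pd.DataFrame(rows, columns=["roi_id", "roi_name", "dimension",
                                       "peak_rbc", "n_sig_voxels"])


# ----------------------------------------------------------------- pipeline

def rbc_pipeline(encoder, volumes: np.ndarray, groups: np.ndarray,
                 dims, mask: np.ndarray | None = None,
                 atlas: AtlasDef | None = None, sigma: float = 1.5,
                 steps: int = 50, alpha: float = 0.05,
                 baseline="zero", case_label="AD", control_label="HC") -> tuple:
    """Attribution → smoothing → group test → FDR → atlas matching.

    ``groups`` holds per-subject labels; the RBC sign is positive where the
    case group's attributions are stochastically larger.  ``baseline`` is the
    IG reference: "zero", "cohort-mean" (the voxel-wise mean over the
    analysis subjects, which cancels attribution mass shared by everyone and
    sharpens group localization), or an explicit volume.  Returns
    (list of RBCMap, concatenated ROI table).
    """
    groups = np.asarray(groups)
    volumes = np.asarray(volumes, dtype=np.float64)
    if mask is None:
        mask = np.ones(volumes.shape[1:], dtype=np.float64)
    if isinstance(baseline, str):
        if baseline == "zero":
            base = None
        elif baseline == "cohort-mean":
            base = volumes.mean(axis=0)
        else:
            raise ValueError(f"unknown baseline {baseline!r}")
    else:
        base = np.asarray(baseline, dtype=np.float64)
    case = volumes[groups == case_label]
    ctrl = volumes[groups == control_label]
    maps_out, tables = [], []
    for dim in dims:
        a_case = postprocess_map(
            attribution_maps(encoder, case, dim, baseline=base, steps=steps),
            mask, sigma)
        a_ctrl = postprocess_map(
            attribution_maps(encoder, ctrl, dim, baseline=base, steps=steps),
            mask, sigma)
        pvals, rbc = voxelwise_group_test(a_case.values, a_ctrl.values)
        sig = fdr_bh(pvals, alpha) & (mask > 0)
        rmap = RBCMap(rbc=rbc, pvals=pvals, significant=sig, dimension=dim)
        maps_out.append(rmap)
        if atlas is not None:
            tables.append(atlas_peak_match(rmap, atlas))
    tables = [t for t in tables if len(t)]
    table = (pd.concat(tables, ignore_index=True) if tables
             else pd.DataFrame(columns=["roi_id", "roi_name", "dimension",
                                        "peak_rbc", "n_sig_voxels"]))
    return maps_out, table
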