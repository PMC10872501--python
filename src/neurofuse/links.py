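"""Group-wise cross-modal latent correlation analysis and ROI link graphs.

For each group (controls and cases) a d×d Spearman correlation matrix is
computed between the latent dimensions of the two modalities across subjects.
Within-group significance is controlled by Benjamini–Hochberg FDR; a Fisher
z-test on the transformed correlations then flags group-discriminative
entries.  Dimensions are paired by their strongest significant positive and
negative correlations, mapped to atlas ROIs via their peak-RBC assignment,
and assembled into a weighted link graph.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .saliency import fdr_bh

__all__ = ["CorrMatrixPair", "LinkEdge", "spearman_matrix", "fisher_group_ztest",
           "select_group_discriminative", "pair_dimensions", "build_link_graph",
           "count_significant_links", "top_roi_per_dimension", "link_pipeline"]


@dataclass
class CorrMatrixPair:
    r_hc: np.ndarray
    r_ad: np.ndarray
    p_hc: np.ndarray
    p_ad: np.ndarray
    n_hc: int
    n_ad: int

    def __post_init__(self):
        if self.n_hc < 4 or self.n_ad < 4:
            raise ValueError("need at least 4 subjects per group")


@dataclass
class LinkEdge:
    dim_1: int
    dim_2: int
    weight: float
    group: str
    roi_1: str
    roi_2: str
    z: float = np.nan


def spearman_matrix(Zm, Zk) -> tuple:
    """Cross-block Spearman rho and two-sided p for all dimension pairs.

    Entry (a, b) correlates column a of Zm with column b of Zk across
    subjects.  Constant columns yield rho 0 with p 1.
    """
    Zm = np.asarray(Zm, dtype=np.float64)
    Zk = np.asarray(Zk, dtype=np.float64)
    if Zm.shape[0] != Zk.shape[0] or Zm.shape[0] < 4:
        raise ValueError("need matching sample counts with n >= 4")
    d1, d2 = Zm.shape[1], Zk.shape[1]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho, p = stats.spearmanr(np.hstack([Zm, Zk]))
    if np.ndim(rho) == 0:  # scipy collapses the 2-column case to a scalar
        rho = np.array([[1.0, rho], [rho, 1.0]])
        p = np.array([[0.0, p], [p, 0.0]])
    rho = np.asarray(rho)[:d1, d1:]
    p = np.asarray(p)[:d1, d1:]
    bad = ~np.isfinite(rho)
    rho = np.where(bad, 0.0, rho)
    p = np.where(bad | ~np.isfinite(p), 1.0, p)
    return rho, p


def fisher_group_ztest(r1, n1: int, r2, n2: int) -> tuple:
    """z-test on Fisher-transformed correlations of two independent groups.

    z = (atanh r₁ − atanh r₂) / √(1/(n₁−3) + 1/(n₂−3)), two-sided normal p.
    Correlations at ±1 are clamped to ±(1 − 1e−7) with a warning.
    """
    r1 = np.asarray(r1, dtype=np.float64)
    r2 = np.asarray(r2, dtype=np.float64)
    if n1 < 4 or n2 < 4:
        raise ValueError("need n >= 4 in each group")
    if np.any(np.abs(r1) >= 1) or np.any(np.abs(r2) >= 1):
        warnings.warn("correlation at |r| = 1 clamped for the z-test")
        r1 = np.clip(r1, -1 + 1e-7, 1 - 1e-7)
        r2 = np.clip(r2, -1 + 1e-7, 1 - 1e-7)
    se = np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    z = (np.arctanh(r1) - np.arctanh(r2)) / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    return z, p


def select_group_discriminative(pair: CorrMatrixPair, alpha: float = 0.05) -> tuple:
    """Two-stage selection of group-discriminative correlation entries.

    Stage 1: BH-FDR at ``alpha`` within each group's p matrix (masks kept as
    metadata).  Stage 2: Fisher z-test over all entries; the returned mask is
    z-test p < alpha (uncorrected, as the link-counting protocol specifies).
    """
    sig_hc = fdr_bh(pair.p_hc, alpha)
    sig_ad = fdr_bh(pair.p_ad, alpha)
    z, pz = fisher_group_ztest(pair.r_hc, pair.n_hc, pair.r_ad, pair.n_ad)
    mask = pz < alpha
    meta = {"stage1_hc": sig_hc, "stage1_ad": sig_ad, "p_z": pz}
    return mask, z, meta


def pair_dimensions(mask, r_group, mode: str) -> list:
    """Per row dimension, the column with the extreme significant correlation.

    ``mode='positive'`` takes the maximal significant positive r per row,
    ``'negative'`` the minimal significant negative r.  Rows with no
    qualifying entries are skipped.  Returns [(row_dim, col_dim), ...].
    """
    mask = np.asarray(mask, dtype=bool)
    r = np.asarray(r_group, dtype=np.float64)
    if mode not in ("positive", "negative"):
        raise ValueError("mode must be 'positive' or 'negative'")
    pairs = []
    for i in range(mask.shape[0]):
        cols = np.flatnonzero(mask[i])
        if len(cols) == 0:
            continue
        vals = r[i, cols]
        if mode == "positive":
            if vals.max() <= 0:
                continue
            j = cols[np.argmax(vals)]
        else:
            if vals.min() >= 0:
                continue
            j = cols[np.argmin(vals)]
        pairs.append((i, int(j)))
    return pairs


def top_roi_per_dimension(roi_table: pd.DataFrame) -> dict:
    """dimension -> ROI name with the largest |peak_rbc| in a saliency table."""
    out = {}
    for dim, grp in roi_table.groupby("dimension"):
        row = grp.loc[grp["peak_rbc"].abs().idxmax()]
        out[int(dim)] = str(row["roi_name"])
    return out


def build_link_graph(pairs, roi_tables: dict, r_group, group: str = "HC",
                     z_matrix=None, top_k: int = 64) -> list:
    """ROI-level link edges from dimension pairs.

    ``roi_tables`` maps modality id (1, 2) to a saliency ROI table; each
    paired dimension is represented by its top-|peak RBC| ROI.  Pairs whose
    dimension has no ROI assignment are dropped with a warning.  Edges are
    sorted by |weight| descending (ties by (dim_1, dim_2)) and truncated to
    ``top_k``.
    """
    if not roi_tables or 1 not in roi_tables or 2 not in roi_tables:
        raise ValueError("roi_tables must map both modalities")
    r = np.asarray(r_group, dtype=np.float64)
    top1 = top_roi_per_dimension(roi_tables[1])
    top2 = top_roi_per_dimension(roi_tables[2])
    edges = []
    for d1, d2 in pairs:
        if d1 not in top1 or d2 not in top2:
            warnings.warn(f"dimension pair ({d1},{d2}) lacks an ROI assignment; dropped")
            continue
        zval = float(np.asarray(z_matrix)[d1, d2]) if z_matrix is not None else np.nan
        edges.append(LinkEdge(dim_1=d1, dim_2=d2, weight=float(r[d1, d2]),
                              group=group, roi_1=top1[d1], roi_2=top2[d2], z=zval))
    edges.sort(key=lambda e: (-abs(e.weight), e.dim_1, e.dim_2))
    return edges[:top_k]


def count_significant_links(mask) -> int:
    """Number of group-discriminative entries in the z-test mask."""
    return int(np.asarray(mask, dtype=bool).sum())


def link_pipeline(Z1_by_group: dict, Z2_by_group: dict, roi_tables: dict,
                  group: str = "HC", alpha: float = 0.05,
                  top_k: int = 64) -> dict:
    """Full Spearman → FDR → z-test → pairing → ROI-graph pipeline.

    ``Z*_by_group`` map group label ("HC"/"AD") to (n_g, d) representation
    matrices of modality 1 and 2.  Pairing requires stage-1 significance in
    the diagrammed ``group`` in addition to the z-test.
    """
    r_hc, p_hc = spearman_matrix(Z1_by_group["HC"], Z2_by_group["HC"])
    r_ad, p_ad = spearman_matrix(Z1_by_group["AD"], Z2_by_group["AD"])
    pair = CorrMatrixPair(r_hc=r_hc, r_ad=r_ad, p_hc=p_hc, p_ad=p_ad,
                          n_hc=len(Z1_by_group["HC"]), n_ad=len(Z1_by_group["AD"]))
    mask, z, meta = select_group_discriminative(pair, alpha)
    stage1 = meta["stage1_hc"] if group == "HC" else meta["stage1_ad"]
    eff = mask & stage1
    r_g = r_hc if group == "HC" else r_ad
    pairs = pair_dimensions(eff, r_g, "positive") + pair_dimensions(eff, r_g, "negative")
    # transposed direction: rows of modality 2 against columns of modality 1
    pairs_t = (pair_dimensions(eff.T, r_g.T, "positive")
               + pair_dimensions(eff.T, r_g.T, "negative"))
    pairs += [(d1, d2) for (d2, d1) in pairs_t]
    pairs = sorted(set(pairs))
    edges = build_link_graph(pairs, roi_tables, r_g, group, z, top_k)
    summary = {
        "n_significant_links": count_significant_links(mask),
        "max_positive_r": float(r_g.max()),
        "max_negative_r": float(r_g.min()),
    }
    return {"edges": edges, "summary": summary, "corr": pair, "mask": mask,
            "z": z, "meta": meta}
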