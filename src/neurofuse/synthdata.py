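"""Synthetic paired multimodal volumes with planted latent structure.

The generator emulates the structure the framework assumes in real data:

* shared cross-modal factors u ~ N(0,1) loading smooth Gaussian-blob patterns
  in both modalities (the joint information contrastive objectives should
  capture),
* modality-unique factors v_m ~ N(0,1) loading one modality only,
* a group effect: a case ("AD") mean shift of known amplitude, localized to
  designated atlas ROIs per modality (calibrated so the ROI-mean group
  difference equals the amplitude, in units of the voxel noise SD),
* an optional cross-modal link: a factor loading ROI r₁ of modality 1 and ROI
  r₂ of modality 2 whose modality-1 loading flips sign in the case group, so
  the within-group latent correlation is +r for controls and −r for cases
  (group-discriminative by construction),
* i.i.d. Gaussian voxel noise on a fixed smooth anatomical background.

Everything is driven by one seed and is bitwise reproducible.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .saliency import AtlasDef

__all__ = ["GeneratorConfig", "SyntheticDataset", "make_toy_atlas",
           "generate_dataset", "write_fixtures", "load_fixtures"]


@dataclass
class GeneratorConfig:
    n_subjects: int = 200
    shape: tuple = (16, 16, 16)
    n_shared: int = 2
    n_unique: int = 2
    n_rois: int = 8
    group_effect_amplitude: float = 2.0        # in units of noise_sd
    group_effect_rois: dict = field(default_factory=lambda: {1: [1], 2: [2]})
    crossmodal_link: tuple | None = None       # (roi_1, roi_2, target_r)
    link_strength: float = 1.5                 # link loading scale (noise-SD units, matches factor_strength)
    factor_strength: float = 1.5               # loading scale of u and v_m
    noise_sd: float = 1.0
    group_fractions: dict = field(default_factory=lambda: {"HC": 0.7, "AD": 0.3})
    seed: int = 0

    def __post_init__(self):
        total = sum(self.group_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("group fractions must sum to 1")


@dataclass
class SyntheticDataset:
    volumes: dict                   # modality id -> (n, s, s, s) float array
    labels: np.ndarray              # (n,) strings
    latents: dict                   # ground-truth factors for recovery tests
    atlas: AtlasDef
    manifest: pd.DataFrame
    config: GeneratorConfig

    @property
    def n(self):
        return len(self.labels)

    def split_indices(self, split: str, fold: int | None = None):
        """Train/validation/test indices per the manifest's fold scheme."""
        m = self.manifest
        if split == "holdout":
            return np.flatnonzero(m["split"] == "holdout")
        dev = m["split"] == "dev"
        fold = 0 if fold is None else fold
        if split == "train":
            return np.flatnonzero(dev & (m["fold"] != fold))
        if split == "val":
            return np.flatnonzero(dev & (m["fold"] == fold))
        raise ValueError(f"unknown split {split!r}")


def make_toy_atlas(shape: tuple, n_rois: int, rng: np.random.Generator) -> AtlasDef:
    """n_rois disjoint axis-aligned boxes with ≥1-voxel gaps on a cubic grid."""
    edge = shape[0]
    g = 1
    while g**3 < n_rois:
        g += 1
    cell = edge // g
    if cell < 3:
        raise ValueError(f"cannot place {n_rois} ROIs in shape {shape}")
    b = max(1, cell // 2)
    labels = np.zeros(shape, dtype=np.int32)
    cells = [(i, j, k) for i in range(g) for j in range(g) for k in range(g)]
    order = rng.permutation(len(cells))[:n_rois]
    for label, ci in enumerate(order, start=1):
        i, j, k = cells[ci]
        s0 = [c * cell + (cell - b) // 2 for c in (i, j, k)]
        labels[s0[0]:s0[0] + b, s0[1]:s0[1] + b, s0[2]:s0[2] + b] = label
    return AtlasDef(labels, {i: f"ROI {i}" for i in range(1, n_rois + 1)})


def _blob(shape, center, sigma) -> np.ndarray:
    grids = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    d2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    return np.exp(-d2 / (2.0 * sigma**2))


def _roi_blob(atlas: AtlasDef, roi_id: int) -> np.ndarray:
    """Gaussian blob centered in the ROI, normalized to ROI-mean 1."""
    m = atlas.mask(roi_id)
    if not m.any():
        raise ValueError(f"ROI {roi_id} absent from atlas")
    center = [c.mean() for c in np.nonzero(m)]
    extent = max(c.max() - c.min() + 1 for c in np.nonzero(m))
    blob = _blob(atlas.labels.shape, center, sigma=extent / 2.5)
    return blob / blob[m].mean()


def _background_center(atlas, rng, margin=2):
    """A voxel at least ``margin`` from every ROI and off the bright core."""
    from scipy import ndimage
    shape = atlas.labels.shape
    occupied = ndimage.binary_dilation(atlas.labels > 0, iterations=margin)
    grids = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    d2 = sum((g - (s / 2 - 0.5)) ** 2 for g, s in zip(grids, shape))
    occupied |= d2 < (shape[0] / 4) ** 2
    free = np.argwhere(~occupied)
    if len(free) == 0:
        free = np.argwhere(atlas.labels == 0)
    return free[rng.integers(len(free))]


def generate_dataset(cfg: GeneratorConfig) -> SyntheticDataset:
    rng = np.random.default_rng(cfg.seed)
    shape = tuple(cfg.shape)
    atlas = make_toy_atlas(shape, cfg.n_rois, rng)
    for mod, rois in cfg.group_effect_rois.items():
        for r in rois:
            if r not in atlas.roi_names:
                raise ValueError(f"group-effect ROI {r} not in atlas")
    n = cfg.n_subjects

    # labels, stratified deterministic order then shuffled
    labels = []
    for lab, frac in sorted(cfg.group_fractions.items()):
        labels += [lab] * int(round(frac * n))
    while len(labels) < n:
        labels.append(sorted(cfg.group_fractions)[0])
    labels = np.array(labels[:n])
    rng.shuffle(labels)
    is_case = labels == "AD"

    # latent draws
    u = rng.standard_normal((n, cfg.n_shared))
    v = {m: rng.standard_normal((n, cfg.n_unique)) for m in (1, 2)}
    w = rng.standard_normal(n)  # cross-modal link factor

    # fixed smooth loading patterns (blobs in background so ROI means stay
    # interpretable)
    blob_sigma = max(1.5, shape[0] / 10)
    loadings_shared = {m: [cfg.factor_strength *
                           _blob(shape, _background_center(atlas, rng), blob_sigma)
                           for _ in range(cfg.n_shared)] for m in (1, 2)}
    loadings_unique = {m: [cfg.factor_strength *
                           _blob(shape, _background_center(atlas, rng), blob_sigma)
                           for _ in range(cfg.n_unique)] for m in (1, 2)}

    # anatomical background common to all subjects: a central structure kept
    # compact so its bulk stays clear of the atlas ROIs (attribution analyses
    # see smaller baseline intensities inside ROIs that way)
    base = 2.0 * cfg.noise_sd * _blob(shape, [s / 2 - 0.5 for s in shape],
                                      shape[0] / 8)

    # group-effect patterns, ROI-mean-normalized so the planted ROI-mean
    # difference equals the amplitude
    group_patterns = {m: sum(_roi_blob(atlas, r) for r in cfg.group_effect_rois.get(m, []))
                      if cfg.group_effect_rois.get(m) else np.zeros(shape)
                      for m in (1, 2)}

    # cross-modal link loadings: each modality carries a strong (voxel-scale
    # visible) factor w_m in its link ROI; the target ROI-mean correlation is
    # met by decorrelating w_1 and w_2, after accounting for the attenuation
    # from the ROI noise mean
    link_patterns = {1: np.zeros(shape), 2: np.zeros(shape)}
    link_factors = {1: w, 2: w}
    link_sign = np.ones(n)
    if cfg.crossmodal_link is not None:
        roi_1, roi_2, target_r = cfg.crossmodal_link
        if not 0 < target_r < 1:
            raise ValueError("link target correlation must be in (0, 1)")
        a = cfg.link_strength * cfg.noise_sd
        lam = {}
        for mod, roi in ((1, roi_1), (2, roi_2)):
            v_roi = int(atlas.mask(roi).sum())
            s_mean = cfg.noise_sd / np.sqrt(v_roi)   # SD of the ROI noise mean
            lam[mod] = a / np.sqrt(a**2 + s_mean**2)
            link_patterns[mod] = a * _roi_blob(atlas, roi)
        rho = target_r / (lam[1] * lam[2])
        if rho > 1:
            raise ValueError("link target correlation unreachable; raise link_strength")
        xi = rng.standard_normal(n)
        link_factors = {1: w, 2: rho * w + np.sqrt(1.0 - rho**2) * xi}
        link_sign = np.where(is_case, -1.0, 1.0)     # modality-1 loading flips

    amp = cfg.group_effect_amplitude * cfg.noise_sd
    volumes = {}
    for m in (1, 2):
        vol = np.broadcast_to(base, (n,) + shape).copy()
        for i in range(cfg.n_shared):
            vol += u[:, i, None, None, None] * loadings_shared[m][i]
        for i in range(cfg.n_unique):
            vol += v[m][:, i, None, None, None] * loadings_unique[m][i]
        vol += amp * is_case[:, None, None, None] * group_patterns[m]
        if cfg.crossmodal_link is not None:
            sign = link_sign if m == 1 else np.ones(n)
            vol += (sign * link_factors[m])[:, None, None, None] * link_patterns[m]
        if "MIX" in cfg.group_fractions:
            mix = labels == "MIX"
            roi_ids = np.array(atlas.roi_ids)
            choice = rng.integers(len(roi_ids), size=n)
            for idx in np.flatnonzero(mix):
                vol[idx] += 0.5 * amp * _roi_blob(atlas, int(roi_ids[choice[idx]]))
        vol += cfg.noise_sd * rng.standard_normal((n,) + shape)
        # constant intensity reference anchors (a dark corner and a bright
        # core, emulating the stable extreme-intensity structures of real
        # preprocessed anatomy) pin each volume's min and max, so per-volume
        # min-max rescaling is the same affine map for every subject instead
        # of a noisy, potentially group-coupled one
        c = shape[0] // 2
        vol[:, :2, :2, :2] = -4.5 * cfg.noise_sd
        vol[:, c - 1:c + 1, c - 1:c + 1, c - 1:c + 1] = 9.0 * cfg.noise_sd
        volumes[m] = vol

    manifest = _make_manifest(labels, rng)
    latents = {"shared": u, "unique": v, "link": link_factors,
               "link_sign": link_sign}
    return SyntheticDataset(volumes=volumes, labels=labels, latents=latents,
                            atlas=atlas, manifest=manifest, config=cfg)


def _make_manifest(labels: np.ndarray, rng: np.random.Generator,
                   n_folds: int = 5, holdout_frac: float = 1 / 6) -> pd.DataFrame:
    """Stratified n-fold + holdout assignment (one row per subject)."""
    n = len(labels)
    split = np.full(n, "dev", dtype=object)
    fold = np.full(n, -1)
    for lab in np.unique(labels):
        idx = np.flatnonzero(labels == lab)
        idx = idx[rng.permutation(len(idx))]
        n_hold = int(round(holdout_frac * len(idx)))
        split[idx[:n_hold]] = "holdout"
        dev_idx = idx[n_hold:]
        for i, subject in enumerate(dev_idx):
            fold[subject] = i % n_folds
    return pd.DataFrame({
        "subject_id": [f"sub-{i:04d}" for i in range(n)],
        "label": labels, "fold": fold, "split": split,
    })


# ------------------------------------------------------------------ fixtures

def write_fixtures(ds: SyntheticDataset, out_dir: str) -> str:
    """One NIfTI per subject per modality, atlas + mask NIfTIs, CSV manifest."""
    import nibabel as nib

    os.makedirs(out_dir, exist_ok=True)
    affine = np.eye(4)
    rows = ds.manifest.copy()
    paths = {1: [], 2: []}
    for i, sub in enumerate(rows["subject_id"]):
        for m in (1, 2):
            p = os.path.join(out_dir, f"{sub}_mod{m}.nii.gz")
            nib.save(nib.Nifti1Image(ds.volumes[m][i], affine), p)
            paths[m].append(p)
    rows.insert(1, "path_mod1", paths[1])
    rows.insert(2, "path_mod2", paths[2])
    nib.save(nib.Nifti1Image(ds.atlas.labels.astype(np.int16), affine),
             os.path.join(out_dir, "atlas.nii.gz"))
    nib.save(nib.Nifti1Image(np.ones(ds.config.shape, dtype=np.uint8), affine),
             os.path.join(out_dir, "mask.nii.gz"))
    manifest_path = os.path.join(out_dir, "manifest.csv")
    rows.to_csv(manifest_path, index=False)
    return manifest_path


def load_fixtures(manifest_path: str) -> tuple:
    """Read a fixtures manifest back into (volumes dict, manifest frame)."""
    import nibabel as nib

    manifest = pd.read_csv(manifest_path)
    volumes = {}
    for m in (1, 2):
        volumes[m] = np.stack([
            np.asarray(nib.load(p).dataobj, dtype=np.float64)
            for p in manifest[f"path_mod{m}"]
        ])
    return volumes, manifest
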