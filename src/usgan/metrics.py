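"""Quantitative image-quality evaluation suite.

Implements the metrics used to compare enhancement methods on grey-scale
ultrasound: contrast ratio (CR) and contrast-to-noise ratio (CNR) over
foreground/background regions, patch-wise SSIM for structure preservation,
first-order intensity statistics (mean, std, skewness, entropy), grey-level
co-occurrence matrix (GLCM) texture features, and the Fréchet distance
between feature distributions of two image sets (FID with a pluggable
feature extractor).

Conventions (documented because the quantities are scale-sensitive):

* CR is the absolute foreground/background mean difference expressed on the
  0–255 intensity scale;
* CNR is |mean difference| / sqrt(var_fg + var_bg) with population variances
  (scale-invariant);
* first-order statistics are reported on the [0, 1] scale, entropy in bits
  over a 256-bin histogram;
* GLCM features default to 64 grey levels, offset (0, 1), symmetric;
* SSIM uses sample (ddof = 1) variances/covariance and the conventional
  stabilizers C1 = (0.01 L)^2, C2 = (0.03 L)^2 on data range L = 1;
* skewness of a zero-variance image is 0 by convention, and GLCM correlation
  of a constant image is 1 by convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import linalg

from .images import as_array, load_image


class ROIError(ValueError):
    """Raised for empty, overlapping, or missing regions of interest."""


@dataclass
class ROIPair:
    """Foreground/background masks for region-based contrast metrics."""

    fg_mask: np.ndarray
    bg_mask: np.ndarray

    def __post_init__(self):
        self.fg_mask = np.asarray(self.fg_mask, dtype=bool)
        self.bg_mask = np.asarray(self.bg_mask, dtype=bool)
        if self.fg_mask.shape != self.bg_mask.shape:
            raise ROIError("fg and bg masks must have the same shape")
        if not self.fg_mask.any() or not self.bg_mask.any():
            raise ROIError("ROI masks must be non-empty")
        if (self.fg_mask & self.bg_mask).any():
            raise ROIError("ROI masks must be disjoint")

    def check_shape(self, img: np.ndarray) -> None:
        if self.fg_mask.shape != img.shape:
            raise ROIError(
                f"mask shape {self.fg_mask.shape} does not match image "
                f"shape {img.shape}")


def auto_roi(shape: tuple[int, int]) -> ROIPair:
    """Geometric fallback ROI: a central disc as foreground and a border
    ring as background. Used only when no ground-truth or user mask exists;
    region-based metrics are then relative, not anatomical."""
    h, w = shape
    rr, cc = np.mgrid[0:h, 0:w]
    d2 = (rr - h / 2) ** 2 + (cc - w / 2) ** 2
    fg = d2 <= (min(h, w) / 4) ** 2
    ring_in, ring_out = min(h, w) / 2.6, min(h, w) / 2.1
    bg = (d2 >= ring_in**2) & (d2 <= ring_out**2)
    return ROIPair(fg, bg)


# ---------------------------------------------------------------------------
# region contrast metrics


def contrast_ratio(img, roi: ROIPair) -> float:
    """|mean(fg) - mean(bg)|, intensities expressed on the 0-255 scale."""
    arr = as_array(img)
    roi.check_shape(arr)
    return float(abs(arr[roi.fg_mask].mean() - arr[roi.bg_mask].mean()) * 255.0)


def contrast_to_noise(img, roi: ROIPair) -> float:
    """|mean(fg) - mean(bg)| / sqrt(var(fg) + var(bg)), population variances."""
    arr = as_array(img)
    roi.check_shape(arr)
    if roi.fg_mask.sum() < 2 or roi.bg_mask.sum() < 2:
        raise ROIError("CNR needs at least 2 pixels per region")
    fg, bg = arr[roi.fg_mask], arr[roi.bg_mask]
    pooled = fg.var() + bg.var()
    if pooled == 0.0:
        raise ROIError("undefined CNR: both regions have zero variance")
    return float(abs(fg.mean() - bg.mean()) / np.sqrt(pooled))


# ---------------------------------------------------------------------------
# structural similarity


def _ssim_patch(a: np.ndarray, b: np.ndarray, data_range: float = 1.0) -> float:
    """Single-window SSIM of two equally shaped patches (sample statistics)."""
    c1 = (0.01 * data_range) ** 2
    c2 = (0.03 * data_range) ** 2
    a = a.ravel().astype(np.float64)
    b = b.ravel().astype(np.float64)
    n = a.size
    mu_a, mu_b = a.mean(), b.mean()
    ddof = 1 if n > 1 else 0
    var_a, var_b = a.var(ddof=ddof), b.var(ddof=ddof)
    cov = ((a - mu_a) * (b - mu_b)).sum() / max(n - 1, 1)
    return float(((2 * mu_a * mu_b + c1) * (2 * cov + c2))
                 / ((mu_a**2 + mu_b**2 + c1) * (var_a + var_b + c2)))


def patchwise_ssim(a, b, patch: int = 32, stride: int | None = None) -> float:
    """Mean single-window SSIM over a stride grid of patches.

    With ``patch`` equal to the full image size this reduces to the global
    (single-window) SSIM. Identical images score exactly 1; structurally
    anti-correlated patches score negatively.
    """
    arr_a, arr_b = as_array(a), as_array(b)
    if arr_a.shape != arr_b.shape:
        raise ValueError(f"shape mismatch: {arr_a.shape} vs {arr_b.shape}")
    h, w = arr_a.shape
    if patch > min(h, w):
        raise ValueError(f"patch ({patch}) exceeds min image dimension {min(h, w)}")
    stride = stride if stride is not None else patch
    scores = []
    for r0 in range(0, h - patch + 1, stride):
        for c0 in range(0, w - patch + 1, stride):
            scores.append(_ssim_patch(arr_a[r0:r0 + patch, c0:c0 + patch],
                                      arr_b[r0:r0 + patch, c0:c0 + patch]))
    return float(np.mean(scores))


# ---------------------------------------------------------------------------
# first-order statistics


def first_order_stats(img) -> tuple[float, float, float, float]:
    """(mean, population std, skewness, entropy in bits over 256 bins).

    All on the [0, 1] intensity scale. Skewness of a constant image is 0 by
    convention; empty histogram bins contribute nothing to the entropy.
    """
    arr = as_array(img)
    if arr.size == 0:
        raise ValueError("empty image")
    mu = float(arr.mean())
    sigma = float(arr.std())
    if sigma == 0.0:
        skew = 0.0
    else:
        skew = float(((arr - mu) ** 3).mean() / sigma**3)
    counts, _ = np.histogram(arr, bins=256, range=(0.0, 1.0))
    p = counts[counts > 0] / arr.size
    entropy = float(-(p * np.log2(p)).sum())
    return mu, sigma, skew, entropy


# ---------------------------------------------------------------------------
# grey-level co-occurrence matrix


@dataclass
class GLCMatrix:
    """Normalized co-occurrence probabilities at one spatial offset."""

    counts: np.ndarray
    levels: int
    offset: tuple[int, int]
    symmetric: bool

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.float64)
        total = self.counts.sum()
        if total <= 0:
            raise ValueError("empty co-occurrence matrix")
        self.counts = self.counts / total


def quantize(img, levels: int) -> np.ndarray:
    """Equal-width quantization of a [0,1] image into ``levels`` bins."""
    arr = as_array(img)
    return np.minimum((arr * levels).astype(np.int64), levels - 1)


def glcm(img, levels: int = 64, offset: tuple[int, int] = (0, 1),
         symmetric: bool = True) -> GLCMatrix:
    """Co-occurrence matrix of grey-level pairs at the given (row, col) offset."""
    if levels < 2:
        raise ValueError("levels must be >= 2")
    q = quantize(img, levels)
    h, w = q.shape
    dr, dc = offset
    if abs(dr) >= h or abs(dc) >= w:
        raise ValueError(f"offset {offset} does not fit inside image {q.shape}")
    rs = slice(max(0, -dr), h - max(0, dr))
    cs = slice(max(0, -dc), w - max(0, dc))
    rt = slice(max(0, dr), h + min(0, dr))
    ct = slice(max(0, dc), w + min(0, dc))
    a = q[rs, cs].ravel()
    b = q[rt, ct].ravel()
    counts = np.bincount(a * levels + b, minlength=levels * levels)
    counts = counts.reshape(levels, levels).astype(np.float64)
    if symmetric:
        counts = counts + counts.T
    return GLCMatrix(counts, levels, (dr, dc), symmetric)


def glcm_features(g: GLCMatrix) -> tuple[float, float, float, float]:
    """(contrast, correlation, energy, homogeneity) of a normalized GLCM.

    contrast    = sum P(i,j) (i-j)^2
    correlation = sum P(i,j) (i-mu_i)(j-mu_j) / (sigma_i sigma_j)
    energy      = sum P(i,j)^2
    homogeneity = sum P(i,j) / (1 + (i-j)^2)

    A constant image (sigma_i sigma_j = 0) reports correlation 1 by
    convention.
    """
    p = g.counts
    idx = np.arange(g.levels, dtype=np.float64)
    i = idx[:, None]
    j = idx[None, :]
    contrast = float((p * (i - j) ** 2).sum())
    energy = float((p * p).sum())
    homogeneity = float((p / (1.0 + (i - j) ** 2)).sum())
    pi = p.sum(axis=1)
    pj = p.sum(axis=0)
    mu_i = float((idx * pi).sum())
    mu_j = float((idx * pj).sum())
    sigma_i = float(np.sqrt(((idx - mu_i) ** 2 * pi).sum()))
    sigma_j = float(np.sqrt(((idx - mu_j) ** 2 * pj).sum()))
    if sigma_i * sigma_j == 0.0:
        correlation = 1.0
    else:
        correlation = float((p * (i - mu_i) * (j - mu_j)).sum() / (sigma_i * sigma_j))
    return contrast, correlation, energy, homogeneity


# ---------------------------------------------------------------------------
# Fréchet distance / FID


def frechet_distance(features_a, features_b) -> float:
    """Fréchet distance between Gaussian fits of two feature sets.

    ||mu_A - mu_B||^2 + tr(S_A + S_B - 2 (S_A S_B)^{1/2}) with population
    (ddof = 0) covariances, a symmetrized real matrix square root, and a
    small-jitter retry for near-singular products. In one dimension this is
    exactly (mu_A - mu_B)^2 + (sigma_A - sigma_B)^2.
    """
    fa = np.atleast_2d(np.asarray(features_a, dtype=np.float64))
    fb = np.atleast_2d(np.asarray(features_b, dtype=np.float64))
    if fa.ndim != 2 or fb.ndim != 2 or fa.shape[1] != fb.shape[1]:
        raise ValueError(f"feature shapes {fa.shape} and {fb.shape} do not match")
    if fa.shape[0] < 2 or fb.shape[0] < 2:
        raise ValueError("need at least 2 feature vectors per set")
    mu_a, mu_b = fa.mean(axis=0), fb.mean(axis=0)
    cov_a = np.cov(fa, rowvar=False, ddof=0)
    cov_b = np.cov(fb, rowvar=False, ddof=0)
    cov_a = np.atleast_2d(cov_a)
    cov_b = np.atleast_2d(cov_b)
    diff = mu_a - mu_b

    import warnings

    with warnings.catch_warnings():
        # singular products are expected for degenerate (e.g. constant) sets;
        # the symmetrized real part below is the standard resolution
        warnings.simplefilter("ignore", linalg.LinAlgWarning)
        covmean = linalg.sqrtm(cov_a @ cov_b)
        if not np.all(np.isfinite(covmean)):
            jitter = 1e-9 * np.eye(cov_a.shape[0])
            covmean = linalg.sqrtm((cov_a + jitter) @ (cov_b + jitter))
    if np.iscomplexobj(covmean):
        covmean = covmean.real
    covmean = (covmean + covmean.T) / 2.0
    value = float(diff @ diff + np.trace(cov_a) + np.trace(cov_b)
                  - 2.0 * np.trace(covmean))
    return max(value, 0.0) if abs(value) < 1e-10 else value


class RandomConvFeatures:
    """Seeded random-convolution feature extractor (the default FID basis).

    Resizes an image to a fixed grid, applies a bank of fixed random
    convolution kernels with a ReLU, and summarizes each channel by its
    spatial mean and standard deviation. Deterministic given the seed.
    A user may substitute any callable mapping an image to a fixed-length
    vector (e.g. features of a pretrained network) to approximate the
    natural-image FID protocol.
    """

    def __init__(self, n_kernels: int = 8, kernel: int = 7, grid: int = 64,
                 seed: int = 0):
        from . import nn

        rng = np.random.default_rng(np.random.SeedSequence([seed, 77]))
        self.grid = grid
        self.conv = nn.Conv2d(1, n_kernels, kernel, stride=4, rng=rng,
                              init_std=0.5, dtype=np.float64)

    def __call__(self, img) -> np.ndarray:
        from skimage.transform import resize

        arr = as_array(img)
        if arr.shape != (self.grid, self.grid):
            arr = resize(arr, (self.grid, self.grid), anti_aliasing=True)
        out, _ = self.conv.forward(arr[None, None].astype(np.float64))
        act = np.maximum(out[0], 0.0)
        means = act.mean(axis=(1, 2))
        stds = act.std(axis=(1, 2))
        return np.concatenate([means, stds])


def fid_score(images_a, images_b, extractor=None) -> float:
    """Fréchet distance between extracted feature distributions of two
    image sets. Identical sets score 0; the result does not depend on the
    order of images within a set."""
    if extractor is None:
        extractor = RandomConvFeatures()
    list_a = list(images_a)
    list_b = list(images_b)
    if not list_a or not list_b:
        raise ValueError("image sets must be non-empty")
    feats_a = np.stack([extractor(img) for img in list_a])
    feats_b = np.stack([extractor(img) for img in list_b])
    return frechet_distance(feats_a, feats_b)


# ---------------------------------------------------------------------------
# per-image report and set evaluation


@dataclass
class MetricReport:
    """All per-image quality metrics in one record."""

    file: str = ""
    cr: float = np.nan
    cnr: float = np.nan
    patch_ssim: float = np.nan
    mean_intensity: float = np.nan
    std: float = np.nan
    skewness: float = np.nan
    entropy: float = np.nan
    glcm_contrast: float = np.nan
    glcm_correlation: float = np.nan
    glcm_energy: float = np.nan
    glcm_homogeneity: float = np.nan


REPORT_COLUMNS = ["file", "cr", "cnr", "patch_ssim", "mean_intensity", "std",
                  "skewness", "entropy", "glcm_contrast", "glcm_correlation",
                  "glcm_energy", "glcm_homogeneity"]


def compute_report(img, roi: ROIPair | None = None, ref=None,
                   glcm_levels: int = 64, patch: int = 32,
                   stride: int | None = None, name: str = "") -> MetricReport:
    """Compute every per-image metric; patch-wise SSIM against ``ref``."""
    arr = as_array(img)
    rep = MetricReport(file=name)
    if roi is not None:
        rep.cr = contrast_ratio(arr, roi)
        try:
            rep.cnr = contrast_to_noise(arr, roi)
        except ROIError:
            rep.cnr = np.nan
    rep.mean_intensity, rep.std, rep.skewness, rep.entropy = first_order_stats(arr)
    g = glcm(arr, levels=glcm_levels)
    (rep.glcm_contrast, rep.glcm_correlation,
     rep.glcm_energy, rep.glcm_homogeneity) = glcm_features(g)
    if ref is not None:
        p = min(patch, min(arr.shape))
        rep.patch_ssim = patchwise_ssim(arr, ref, patch=p,
                                        stride=stride if stride else max(p // 2, 1))
    return rep


def _find_masks(img_path: Path, masks_dir: Path) -> ROIPair | None:
    stem = img_path.stem
    domain = img_path.parent.name
    for prefix in (stem, f"{domain}_{stem}"):
        fg = masks_dir / f"{prefix}_fg.png"
        bg = masks_dir / f"{prefix}_bg.png"
        if fg.exists() and bg.exists():
            return ROIPair(load_image(fg).values > 0.5,
                           load_image(bg).values > 0.5)
    return None


def evaluate_set(img_dir, ref_dir=None, roi_source=None, out_csv=None,
                 glcm_levels: int = 64, patch: int = 32,
                 fid_against=None, extractor=None,
                 allow_auto_roi: bool = False) -> pd.DataFrame:
    """Per-image MetricReport rows plus a set-mean row, optionally written
    to CSV.

    ``roi_source`` may be a directory of ``<image>_fg.png`` / ``<image>_bg.png``
    mask pairs (0/255 PNG), a single :class:`ROIPair` applied to every image,
    or None. With no masks and ``allow_auto_roi`` unset, region metrics raise
    an :class:`ROIError` unless omitted entirely; ``allow_auto_roi=True``
    enables the documented geometric fallback. ``ref_dir`` supplies paired
    pre-enhancement images (matched by filename) for patch-wise SSIM.
    ``fid_against`` adds a set-level FID against another image folder,
    reported on the mean row.
    """
    img_dir = Path(img_dir)
    paths = sorted(p for p in img_dir.iterdir() if p.suffix.lower() == ".png")
    if not paths:
        raise ValueError(f"no images in {img_dir}")
    rows = []
    arrays = []
    for path in paths:
        arr = load_image(path).values
        arrays.append(arr)
        if isinstance(roi_source, ROIPair):
            roi = roi_source
        elif roi_source is not None:
            roi = _find_masks(path, Path(roi_source))
            if roi is None:
                if not allow_auto_roi:
                    raise ROIError(f"no mask pair found for {path.name} in {roi_source}")
                roi = auto_roi(arr.shape)
        elif allow_auto_roi:
            roi = auto_roi(arr.shape)
        else:
            roi = None
        ref = None
        if ref_dir is not None:
            ref_path = Path(ref_dir) / path.name
            if ref_path.exists():
                ref = load_image(ref_path).values
        rep = compute_report(arr, roi=roi, ref=ref, glcm_levels=glcm_levels,
                             patch=patch, name=path.name)
        rows.append(rep.__dict__)
    df = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    mean_row = df.drop(columns=["file"]).mean(numeric_only=True).to_dict()
    mean_row["file"] = "mean"
    if fid_against is not None:
        other_dir = Path(fid_against)
        others = [load_image(p).values
                  for p in sorted(other_dir.iterdir()) if p.suffix.lower() == ".png"]
        mean_row["fid"] = fid_score(arrays, others, extractor=extractor)
    df = pd.concat([df, pd.DataFrame([mean_row])], ignore_index=True)
    if out_csv is not None:
        df.to_csv(out_csv, index=False)
    return df
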