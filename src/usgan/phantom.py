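"""Seeded synthetic B-mode phantom generator.

Renders grey-scale speckle images in two unpaired quality domains so that
training and every metric in the package are exercisable without clinical
data. The high-quality domain Y is a clean render (moderate speckle, mild
point-spread blur); the low-quality domain X is a degraded render emulating
an aging scanner: compressed parenchymal contrast, reduced brightness,
heavier speckle, extra blur, and near-field reverberation bands.

The speckle model is multiplicative gamma noise with unit mean and shape
equal to the number of "looks" (a standard approximation to multi-look
envelope statistics): fewer looks, grainier texture, and the expected pixel
value always equals the underlying echogenicity.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml
from scipy.ndimage import gaussian_filter

from .images import save_image

# Default rendering / degradation parameters: the package's fixed synthetic
# study conditions (the clinical degradation is described only qualitatively,
# so these are calibration choices documented in docs/methods.md).
HQ_SPECKLE_LOOKS = 12
HQ_PSF_SIGMA = 1.0


@dataclass(frozen=True)
class Lesion:
    center_row: int
    center_col: int
    radius_px: int
    echogenicity: float


@dataclass(frozen=True)
class Vessel:
    start: tuple[int, int]
    end: tuple[int, int]
    width_px: int


@dataclass
class PhantomScene:
    """Geometric ground truth from which a B-mode image is rendered.

    ``fg_mask`` marks the metric foreground (lesion interiors, or a central
    parenchyma disc when the scene has no lesions); ``bg_mask`` marks clean
    parenchyma away from any structure. The two are disjoint and non-empty
    by construction.
    """

    height: int
    width: int
    parenchyma_echogenicity: float
    lesions: list[Lesion]
    vessels: list[Vessel]
    fg_mask: np.ndarray
    bg_mask: np.ndarray
    seed: int

    def echo_map(self) -> np.ndarray:
        """Noise-free echogenicity map in [0, 1]."""
        emap = np.full((self.height, self.width), self.parenchyma_echogenicity)
        rr, cc = np.mgrid[0:self.height, 0:self.width]
        for les in self.lesions:
            d2 = (rr - les.center_row) ** 2 + (cc - les.center_col) ** 2
            emap[d2 <= les.radius_px**2] = les.echogenicity
        for ves in self.vessels:
            emap[_line_mask(self.height, self.width, ves)] = 0.05
        return np.clip(emap, 0.0, 1.0)


@dataclass(frozen=True)
class DegradeParams:
    """Degradation recipe turning a clean render into the low-quality domain.

    The identity setting (contrast_gain=1, brightness_offset=0,
    speckle_looks=None, blur_sigma_px=0, reverb_band_count=0) leaves the
    image bit-identical.
    """

    contrast_gain: float = 0.55      # multiplies deviation from mid-grey
    brightness_offset: float = -0.08
    speckle_looks: int | None = 3    # None means no extra speckle (infinite looks)
    blur_sigma_px: float = 1.0
    reverb_band_count: int = 3
    reverb_amplitude: float = 0.25
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.contrast_gain <= 1.0):
            raise ValueError("contrast_gain must be in (0, 1]")
        if not (-0.5 <= self.brightness_offset <= 0.0):
            raise ValueError("brightness_offset must be in [-0.5, 0]")
        if self.speckle_looks is not None and self.speckle_looks < 1:
            raise ValueError("speckle_looks must be a positive integer or None")
        if self.blur_sigma_px < 0:
            raise ValueError("blur_sigma_px must be non-negative")
        if self.reverb_band_count < 0:
            raise ValueError("reverb_band_count must be non-negative")
        if not (0.0 <= self.reverb_amplitude <= 1.0):
            raise ValueError("reverb_amplitude must be in [0, 1]")


def _line_mask(h: int, w: int, ves: Vessel) -> np.ndarray:
    """Boolean mask of a thick line segment (the vessel lumen)."""
    rr, cc = np.mgrid[0:h, 0:w].astype(np.float64)
    (r0, c0), (r1, c1) = ves.start, ves.end
    dr, dc = r1 - r0, c1 - c0
    norm2 = dr * dr + dc * dc
    if norm2 == 0:
        d2 = (rr - r0) ** 2 + (cc - c0) ** 2
        return d2 <= (ves.width_px / 2) ** 2
    t = np.clip(((rr - r0) * dr + (cc - c0) * dc) / norm2, 0.0, 1.0)
    d2 = (rr - (r0 + t * dr)) ** 2 + (cc - (c0 + t * dc)) ** 2
    return d2 <= (ves.width_px / 2) ** 2


def make_scene(height: int, width: int, n_lesions: int, n_vessels: int,
               seed: int) -> PhantomScene:
    """Draw a seeded random phantom scene.

    Lesions are hypoechoic discs placed with a margin from the borders;
    vessels are thin dark segments. Identical arguments give a bit-identical
    scene. Foreground/background masks are disjoint: foreground covers
    slightly eroded lesion interiors (or a central disc for a lesion-free
    scene), background covers parenchyma at least 4 px away from every
    structure.
    """
    if height < 64 or width < 64:
        raise ValueError(f"image must be at least 64x64, got {height}x{width}")
    if n_lesions < 0 or n_vessels < 0:
        raise ValueError("counts must be non-negative")
    rng = np.random.default_rng(seed)
    parenchyma = float(rng.uniform(0.50, 0.62))
    margin = max(8, min(height, width) // 8)
    max_radius = max(6, min(height, width) // 8)

    lesions: list[Lesion] = []
    for _ in range(n_lesions):
        radius = int(rng.integers(5, max_radius + 1))
        row = int(rng.integers(margin + radius, height - margin - radius))
        col = int(rng.integers(margin + radius, width - margin - radius))
        echo = float(rng.uniform(0.12, 0.30))
        lesions.append(Lesion(row, col, radius, echo))

    vessels: list[Vessel] = []
    for _ in range(n_vessels):
        r0 = int(rng.integers(margin, height - margin))
        c0 = int(rng.integers(margin, width - margin))
        r1 = int(np.clip(r0 + rng.integers(-height // 4, height // 4), 1, height - 2))
        c1 = int(np.clip(c0 + rng.integers(-width // 4, width // 4), 1, width - 2))
        width_px = int(rng.integers(2, 5))
        vessels.append(Vessel((r0, c0), (r1, c1), width_px))

    rr, cc = np.mgrid[0:height, 0:width]
    fg = np.zeros((height, width), dtype=bool)
    exclusion = np.zeros((height, width), dtype=bool)
    for les in lesions:
        d2 = (rr - les.center_row) ** 2 + (cc - les.center_col) ** 2
        fg |= d2 <= max(les.radius_px - 2, 1) ** 2
        exclusion |= d2 <= (les.radius_px + 4) ** 2
    for ves in vessels:
        exclusion |= _line_mask(height, width, Vessel(ves.start, ves.end, ves.width_px + 8))
    if n_lesions == 0:
        d2 = (rr - height // 2) ** 2 + (cc - width // 2) ** 2
        fg = d2 <= (min(height, width) // 6) ** 2
        exclusion |= d2 <= (min(height, width) // 6 + 4) ** 2
    interior = ((rr >= 4) & (rr < height - 4) & (cc >= 4) & (cc < width - 4))
    bg = interior & ~exclusion & ~fg
    return PhantomScene(height, width, parenchyma, lesions, vessels, fg, bg, seed)


def render_bmode(scene: PhantomScene, speckle_looks: int = HQ_SPECKLE_LOOKS,
                 psf_sigma_px: float = HQ_PSF_SIGMA, seed: int = 0) -> np.ndarray:
    """Render the scene as a speckled B-mode image in [0, 1].

    The echogenicity map is multiplied by unit-mean gamma speckle
    (shape = ``speckle_looks``), blurred by a Gaussian point-spread of
    ``psf_sigma_px``, and clipped to [0, 1]. Away from the clipping
    boundary the per-pixel expectation equals the echogenicity.
    """
    if speckle_looks < 1:
        raise ValueError("speckle_looks must be >= 1")
    rng = np.random.default_rng(seed)
    emap = scene.echo_map()
    speckle = rng.gamma(shape=float(speckle_looks),
                        scale=1.0 / float(speckle_looks), size=emap.shape)
    img = emap * speckle
    if psf_sigma_px > 0:
        img = gaussian_filter(img, psf_sigma_px, mode="mirror")
    return np.clip(img, 0.0, 1.0)


def degrade(img: np.ndarray, params: DegradeParams) -> np.ndarray:
    """Apply the low-quality-domain degradation, in order: contrast
    compression about mid-grey, brightness offset, extra multiplicative
    speckle, Gaussian blur, additive near-field reverberation bands,
    final clip to [0, 1]."""
    out = np.asarray(img, dtype=np.float64)
    out = 0.5 + params.contrast_gain * (out - 0.5)
    out = out + params.brightness_offset
    if params.speckle_looks is not None:
        rng = np.random.default_rng(params.seed)
        out = out * rng.gamma(shape=float(params.speckle_looks),
                              scale=1.0 / float(params.speckle_looks),
                              size=out.shape)
    if params.blur_sigma_px > 0:
        out = gaussian_filter(out, params.blur_sigma_px, mode="mirror")
    if params.reverb_band_count > 0:
        h, w = out.shape
        quarter = max(h // 4, 1)
        band = np.zeros((h, w))
        # equally spaced bright bands within the top quarter, ~2 px thick
        for i in range(params.reverb_band_count):
            r = int(round((i + 1) * quarter / (params.reverb_band_count + 1)))
            band[max(r - 1, 0):r + 1, :] = params.reverb_amplitude
        out = out + band
    return np.clip(out, 0.0, 1.0)


def generate_dataset(n_per_domain: int, out_dir, seed: int,
                     height: int = 128, width: int = 128,
                     n_lesions: int = 2, n_vessels: int = 1,
                     degrade_params: DegradeParams | None = None,
                     paired: bool = False) -> dict:
    """Write an unpaired two-domain synthetic dataset.

    ``Y/`` receives clean high-quality renders; ``X/`` receives degraded
    renders of *different* scenes (independently seeded), so the folders
    are unpaired by construction — matching the two-device acquisition
    setting the package targets. ``paired=True`` is a debug mode rendering
    both domains from the same scenes (for oracle tests only).

    Per-image foreground/background masks are written as 0/255 PNGs next
    to a YAML manifest listing files, seeds and parameters. Reruns with
    identical arguments produce a byte-identical manifest.
    """
    if n_per_domain < 1:
        raise ValueError("n_per_domain must be >= 1")
    out_dir = Path(out_dir)
    dp = degrade_params if degrade_params is not None else DegradeParams()
    for sub in ("X", "Y", "masks"):
        (out_dir / sub).mkdir(parents=True, exist_ok=True)

    entries = []
    for domain_idx, domain in enumerate(("X", "Y")):
        for i in range(n_per_domain):
            if paired:
                scene_seed = int(np.random.SeedSequence([seed, 2, i]).generate_state(1)[0] % 2**31)
            else:
                scene_seed = int(np.random.SeedSequence([seed, domain_idx, i]).generate_state(1)[0] % 2**31)
            render_seed = scene_seed + 1
            scene = make_scene(height, width, n_lesions, n_vessels, scene_seed)
            img = render_bmode(scene, HQ_SPECKLE_LOOKS, HQ_PSF_SIGMA, render_seed)
            params: dict = {"speckle_looks": HQ_SPECKLE_LOOKS, "psf_sigma_px": HQ_PSF_SIGMA}
            if domain == "X":
                dpi = DegradeParams(dp.contrast_gain, dp.brightness_offset,
                                    dp.speckle_looks, dp.blur_sigma_px,
                                    dp.reverb_band_count, dp.reverb_amplitude,
                                    seed=render_seed + 1)
                img = degrade(img, dpi)
                params.update({
                    "contrast_gain": dpi.contrast_gain,
                    "brightness_offset": dpi.brightness_offset,
                    "degrade_speckle_looks": dpi.speckle_looks,
                    "blur_sigma_px": dpi.blur_sigma_px,
                    "reverb_band_count": dpi.reverb_band_count,
                    "reverb_amplitude": dpi.reverb_amplitude,
                })
            name = f"img_{i:04d}.png"
            save_image(img, out_dir / domain / name)
            save_image(scene.fg_mask.astype(np.float64),
                       out_dir / "masks" / f"{domain}_{name[:-4]}_fg.png")
            save_image(scene.bg_mask.astype(np.float64),
                       out_dir / "masks" / f"{domain}_{name[:-4]}_bg.png")
            entries.append({
                "domain": domain,
                "file": f"{domain}/{name}",
                "fg_mask": f"masks/{domain}_{name[:-4]}_fg.png",
                "bg_mask": f"masks/{domain}_{name[:-4]}_bg.png",
                "seed": scene_seed,
                "params": params,
            })
    manifest = {
        "seed": seed,
        "n_per_domain": n_per_domain,
        "height": height,
        "width": width,
        "paired": paired,
        "images": entries,
    }
    with open(out_dir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return manifest
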