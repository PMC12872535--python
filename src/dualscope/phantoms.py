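"""Synthetic organ-like phantoms and clinical-artifact corruptions.

The generator emulates the difficulty profile of pelvic/abdominal CT
contouring without any clinical data: a large, well-contrasted structure
(bladder-like), an adjacent low-contrast structure sharing an ambiguous
boundary (rectum-like), and optional small rare structures (node-like) that
appear only in a fraction of images.  Intensities are piecewise constant plus
Gaussian noise — the simplest model that exhibits the low-contrast-boundary
failure mode the architecture targets.

Everything is a pure function of ``(spec, seed)``: identical inputs yield
byte-identical images and masks.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage


class SizingError(ValueError):
    """A structure cannot fit on the requested grid."""


# ---------------------------------------------------------------------------
# specifications
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StructureSpec:
    """One foreground class.

    ``size_range`` is the characteristic radius range in pixels (semi-major
    axis for ellipses, half-length for capsules, mean radius for blobs).
    ``contrast`` optionally overrides ``intensity`` relative to the adjacent
    neighbour (class 1): rendered intensity = neighbour intensity − contrast.
    ``occurrence`` is the probability that the structure appears in an image;
    class 1 is always present.
    """

    shape: str = "ellipse"  # ellipse | capsule | blob
    size_range: tuple[float, float] = (8.0, 14.0)
    intensity: float = 0.7
    contrast: float | None = None
    occurrence: float = 1.0

    def __post_init__(self):
        if self.shape not in ("ellipse", "capsule", "blob"):
            raise ValueError(f"unknown shape family {self.shape!r}")
        if not (0.0 <= self.intensity <= 1.0):
            raise ValueError("intensity must be in [0, 1]")
        if not (0.0 <= self.occurrence <= 1.0):
            raise ValueError("occurrence must be in [0, 1]")
        if self.size_range[0] <= 0 or self.size_range[1] < self.size_range[0]:
            raise ValueError("size_range must be positive and ordered")


@dataclass(frozen=True)
class PhantomSpec:
    height: int = 64
    width: int = 64
    n_classes: int = 3
    structures: tuple[StructureSpec, ...] = (
        StructureSpec("ellipse", (12.0, 18.0), 0.70),
        StructureSpec("ellipse", (7.0, 11.0), 0.55),
    )
    adjacency: bool = True
    background_intensity: float = 0.25
    noise_sigma: float = 0.05
    pixel_size_mm: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.n_classes < 2:
            raise ValueError("need at least background + one structure class")
        if len(self.structures) != self.n_classes - 1:
            raise ValueError(
                f"{self.n_classes - 1} structures required, got {len(self.structures)}"
            )
        if not (0.0 <= self.background_intensity <= 1.0):
            raise ValueError("background intensity must be in [0, 1]")
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be >= 0")
        for s in self.structures:
            if 2.0 * s.size_range[1] >= min(self.height, self.width) - 2:
                raise SizingError(
                    f"structure size {s.size_range[1]} px does not fit a "
                    f"{self.height}x{self.width} grid"
                )


@dataclass(frozen=True)
class ArtifactConfig:
    """Clinical corruption model: multiplicative intensity scaling, 1-D
    uniform motion blur along one axis, then additive Gaussian noise."""

    noise_sigma: float = 0.0
    scale_range: tuple[float, float] = (1.0, 1.0)
    blur_length: int = 1
    blur_axis: str = "row"  # kernel spans rows ("row", vertical smear) or columns
    seed: int = 0

    def __post_init__(self):
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be >= 0")
        if self.scale_range[0] <= 0 or self.scale_range[1] < self.scale_range[0]:
            raise ValueError("scale range must be positive and ordered")
        if self.blur_length < 1:
            raise ValueError("blur length must be >= 1 (1 = identity)")
        if self.blur_axis not in ("row", "col"):
            raise ValueError("blur axis must be 'row' or 'col'")


@dataclass(frozen=True)
class AugmentConfig:
    """Training augmentation ranges.  Zero/False everywhere is the identity."""

    flip_h: bool = True
    flip_v: bool = True
    rotate_deg: float = 15.0
    scale_frac: float = 0.10
    elastic_alpha: float = 2.0
    elastic_spacing: int = 16
    jitter_brightness: float = 0.05
    jitter_contrast: float = 0.05

    @staticmethod
    def none() -> "AugmentConfig":
        return AugmentConfig(False, False, 0.0, 0.0, 0.0, 16, 0.0, 0.0)


@dataclass
class LabeledImage:
    image: np.ndarray  # (H, W) float32 in [0, 1]
    mask: np.ndarray  # (H, W) uint8, values < n_classes
    pixel_size_mm: float = 1.0
    ident: str = ""

    def __post_init__(self):
        self.image = np.asarray(self.image, dtype=np.float32)
        self.mask = np.asarray(self.mask, dtype=np.uint8)
        if self.image.shape != self.mask.shape:
            raise ValueError("image and mask shapes differ")
        if not np.all(np.isfinite(self.image)):
            raise ValueError("image contains non-finite values")


# ---------------------------------------------------------------------------
# rasterization
# ---------------------------------------------------------------------------

def _grid(h: int, w: int):
    return np.meshgrid(np.arange(h, dtype=np.float64),
                       np.arange(w, dtype=np.float64), indexing="ij")


def _ellipse(h, w, cy, cx, a, b, angle):
    yy, xx = _grid(h, w)
    ca, sa = np.cos(angle), np.sin(angle)
    u = (yy - cy) * ca + (xx - cx) * sa
    v = -(yy - cy) * sa + (xx - cx) * ca
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def _capsule(h, w, cy, cx, half_len, radius, angle):
    yy, xx = _grid(h, w)
    dy, dx = np.cos(angle), np.sin(angle)
    py, px = yy - cy, xx - cx
    t = np.clip(py * dy + px * dx, -half_len, half_len)
    dist2 = (py - t * dy) ** 2 + (px - t * dx) ** 2
    return dist2 <= radius**2


def _blob(h, w, cy, cx, radius, rng):
    yy, xx = _grid(h, w)
    theta = np.arctan2(yy - cy, xx - cx)
    r = np.hypot(yy - cy, xx - cx)
    bound = np.full_like(theta, float(radius))
    for k in range(2, 5):  # low-order radial harmonics -> smooth lobed outline
        amp = rng.uniform(0.05, 0.18) * radius
        phase = rng.uniform(0, 2 * np.pi)
        bound += amp * np.cos(k * theta + phase)
    return r <= bound


def _raster(struct: StructureSpec, h, w, cy, cx, size, angle, rng):
    if struct.shape == "ellipse":
        return _ellipse(h, w, cy, cx, size, size * rng.uniform(0.6, 0.9), angle)
    if struct.shape == "capsule":
        return _capsule(h, w, cy, cx, size, size * rng.uniform(0.35, 0.5), angle)
    return _blob(h, w, cy, cx, size, rng)


_FOUR_CONN = ndimage.generate_binary_structure(2, 1)


def _touches(a: np.ndarray, b: np.ndarray) -> bool:
    return bool(np.any(ndimage.binary_dilation(a, _FOUR_CONN) & b))


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def generate_phantom(spec: PhantomSpec, rng: np.random.Generator,
                     ident: str = "") -> LabeledImage:
    """Rasterize one phantom from the supplied RNG stream."""
    h, w = spec.height, spec.width
    mask = np.zeros((h, w), dtype=np.uint8)

    regions: dict[int, np.ndarray] = {}
    for c, struct in enumerate(spec.structures, start=1):
        present = True if c == 1 else bool(rng.random() < struct.occurrence)
        if not present:
            continue
        size = rng.uniform(*struct.size_range)
        for attempt in range(20):
            angle = rng.uniform(0, np.pi)
            if c == 2 and spec.adjacency and 1 in regions:
                # place overlapping class 1, then carve: guarantees a shared
                # boundary along the carved rim
                cy1, cx1 = ndimage.center_of_mass(regions[1])
                d = rng.uniform(0.4, 0.9) * spec.structures[0].size_range[1]
                phi = rng.uniform(0, 2 * np.pi)
                cy = np.clip(cy1 + (d + size * 0.5) * np.sin(phi), size, h - 1 - size)
                cx = np.clip(cx1 + (d + size * 0.5) * np.cos(phi), size, w - 1 - size)
            else:
                cy = rng.uniform(size, h - 1 - size)
                cx = rng.uniform(size, w - 1 - size)
            region = _raster(struct, h, w, cy, cx, size, angle, rng)
            region &= mask == 0  # earlier classes take precedence
            if not region.any():
                continue
            if c == 2 and spec.adjacency and 1 in regions:
                if not _touches(region, regions[1]):
                    continue
            regions[c] = region
            mask[region] = c
            break

    image = np.full((h, w), spec.background_intensity, dtype=np.float64)
    for c, struct in enumerate(spec.structures, start=1):
        if c not in regions:
            continue
        level = struct.intensity
        if struct.contrast is not None and 1 in regions and c != 1:
            level = float(np.clip(spec.structures[0].intensity - struct.contrast, 0, 1))
        image[regions[c]] = level
    if spec.noise_sigma > 0:
        image = image + rng.normal(0.0, spec.noise_sigma, size=image.shape)
        image = np.clip(image, 0.0, 1.0)
    return LabeledImage(image.astype(np.float32), mask,
                        pixel_size_mm=spec.pixel_size_mm, ident=ident)


def generate_dataset(spec: PhantomSpec, n: int) -> list[LabeledImage]:
    """Generate ``n`` phantoms; deterministic under ``(spec, spec.seed)``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(spec.seed)
    return [generate_phantom(spec, rng, ident=f"phantom-{spec.seed}-{i:05d}")
            for i in range(n)]


# ---------------------------------------------------------------------------
# artifacts
# ---------------------------------------------------------------------------

def apply_artifacts(img: LabeledImage, cfg: ArtifactConfig,
                    rng: np.random.Generator | None = None) -> LabeledImage:
    """Corrupt intensities (scale -> blur -> noise, then clip); mask untouched."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    out = img.image.astype(np.float64)
    touched = False
    if cfg.scale_range != (1.0, 1.0):
        out = out * rng.uniform(*cfg.scale_range)
        touched = True
    if cfg.blur_length > 1:
        kernel = np.full(cfg.blur_length, 1.0 / cfg.blur_length)
        axis = 0 if cfg.blur_axis == "row" else 1
        out = ndimage.correlate1d(out, kernel, axis=axis, mode="reflect")
        touched = True
    if cfg.noise_sigma > 0:
        out = out + rng.normal(0.0, cfg.noise_sigma, size=out.shape)
        touched = True
    if touched:
        out = np.clip(out, 0.0, 1.0)
    else:
        out = img.image  # zero-strength config: bit-identical passthrough
    return LabeledImage(out.astype(np.float32), img.mask.copy(),
                        pixel_size_mm=img.pixel_size_mm, ident=img.ident)


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

def _warp_pair(image, mask, coords):
    warped_img = ndimage.map_coordinates(image, coords, order=1, mode="nearest")
    warped_mask = ndimage.map_coordinates(mask, coords, order=0, mode="nearest")
    return warped_img, warped_mask


def augment(img: LabeledImage, aug: AugmentConfig,
            seed: int | np.random.Generator = 0) -> LabeledImage:
    """Random flips, rotation, scaling, elastic deformation, intensity jitter.

    One geometric transform is composed and applied to image (bilinear) and
    mask (nearest neighbour) alike; intensity jitter touches the image only.
    The label set can only shrink, never grow.
    """
    rng = np.random.default_rng(seed) if isinstance(seed, (int, np.integer)) else seed
    image = img.image.astype(np.float64)
    mask = img.mask.copy()
    h, w = image.shape

    if aug.flip_h and rng.random() < 0.5:
        image, mask = image[:, ::-1].copy(), mask[:, ::-1].copy()
    if aug.flip_v and rng.random() < 0.5:
        image, mask = image[::-1, :].copy(), mask[::-1, :].copy()

    angle = np.deg2rad(rng.uniform(-aug.rotate_deg, aug.rotate_deg)) if aug.rotate_deg else 0.0
    scale = 1.0 + (rng.uniform(-aug.scale_frac, aug.scale_frac) if aug.scale_frac else 0.0)

    need_affine = angle != 0.0 or scale != 1.0
    need_elastic = aug.elastic_alpha > 0

    if need_affine or need_elastic:
        yy, xx = np.meshgrid(np.arange(h, dtype=np.float64),
                             np.arange(w, dtype=np.float64), indexing="ij")
        cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
        py, px = yy - cy, xx - cx
        if need_affine:
            # inverse map: output pixel -> source location
            ca, sa = np.cos(angle), np.sin(angle)
            sy = (ca * py - sa * px) / scale + cy
            sx = (sa * py + ca * px) / scale + cx
        else:
            sy, sx = yy, xx
        if need_elastic:
            gh = max(h // aug.elastic_spacing, 2)
            gw = max(w // aug.elastic_spacing, 2)
            coarse = rng.normal(0.0, aug.elastic_alpha, size=(2, gh, gw))
            dy = ndimage.zoom(coarse[0], (h / gh, w / gw), order=3)[:h, :w]
            dx = ndimage.zoom(coarse[1], (h / gh, w / gw), order=3)[:h, :w]
            sy, sx = sy + dy, sx + dx
        image, mask = _warp_pair(image, mask, np.stack([sy, sx]))

    if aug.jitter_brightness or aug.jitter_contrast:
        off = rng.uniform(-aug.jitter_brightness, aug.jitter_brightness)
        fac = 1.0 + rng.uniform(-aug.jitter_contrast, aug.jitter_contrast)
        m = image.mean()
        image = np.clip((image - m) * fac + m + off, 0.0, 1.0)

    return LabeledImage(image.astype(np.float32), mask,
                        pixel_size_mm=img.pixel_size_mm, ident=img.ident)


# ---------------------------------------------------------------------------
# CSI unit-test fixtures
# ---------------------------------------------------------------------------

def make_csi_fixture(h: int, w: int, n_classes: int, embed_dim: int, seed: int,
                     separation: float = 4.0, logit_gain: float = 3.0):
    """Logit/embedding/saliency arrays with class-conditional Gaussian
    embeddings.

    Class means sit on a circle in the first two embedding dimensions with
    adjacent chord length ``separation`` (so separation 0 collapses all
    means).  Returns ``(logits (C,h,w), embeddings (D,h,w), saliency (h,w),
    labels (h,w))``, all deterministic under ``seed``.
    """
    if embed_dim < 1:
        raise ValueError("embed_dim must be >= 1")
    rng = np.random.default_rng(seed)
    # spatially blocky labels (coarse grid upsampled) so refinement has context
    gh, gw = max(h // 4, 1), max(w // 4, 1)
    coarse = rng.integers(0, n_classes, size=(gh, gw))
    labels = np.kron(coarse, np.ones((-(-h // gh), -(-w // gw)), dtype=int))[:h, :w]

    means = np.zeros((n_classes, embed_dim))
    if n_classes > 1 and embed_dim >= 2:
        radius = separation / (2.0 * np.sin(np.pi / n_classes))
        ang = 2 * np.pi * np.arange(n_classes) / n_classes
        means[:, 0] = radius * np.cos(ang)
        means[:, 1] = radius * np.sin(ang)
    elif n_classes > 1:
        means[:, 0] = separation * np.arange(n_classes)

    emb = means[labels] + rng.standard_normal((h, w, embed_dim))
    onehot = np.eye(n_classes)[labels]
    logits = logit_gain * onehot + 0.5 * rng.standard_normal((h, w, n_classes))
    saliency = rng.uniform(0.0, 1.0, size=(h, w))
    return (
        logits.transpose(2, 0, 1).astype(np.float32),
        emb.transpose(2, 0, 1).astype(np.float32),
        saliency.astype(np.float32),
        labels.astype(np.int64),
    )
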