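"""Synthetic attenuation phantoms: ellipse composites with metal inserts.

Phantoms are additive ellipse composites (Shepp–Logan style): a body made of
soft-tissue ellipses whose attenuation deltas sum where they overlap, plus a
set of high-attenuation "metal" inserts.  Ellipses are specified in
image-fraction coordinates on [-1, 1] with the origin at the image center,
x rightward and y upward; every ellipse must fit inside the unit disk so that
parallel-beam projections are untruncated and the projection-moment
consistency conditions hold exactly.

Rendering uses pixel-center point sampling (no anti-aliasing), which keeps a
brute-force membership count an exact oracle for the rendered image.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import tifffile

__all__ = [
    "EllipseSpec",
    "PhantomSpec",
    "AttenuationImage",
    "GenerationConfig",
    "render_phantom",
    "sample_random_phantom",
    "save_image",
    "load_image",
    "save_phantom_spec",
    "load_phantom_spec",
    "save_preview",
]


@dataclass(frozen=True)
class EllipseSpec:
    """One additive ellipse in image-fraction coordinates.

    ``attenuation_delta`` is the additive attenuation contribution (arbitrary
    units per reciprocal pixel); overlapping ellipses sum.
    """

    center_x: float
    center_y: float
    semi_axis_a: float
    semi_axis_b: float
    rotation_deg: float = 0.0
    attenuation_delta: float = 1.0

    def validate(self) -> None:
        if self.semi_axis_a <= 0 or self.semi_axis_b <= 0:
            raise ValueError(f"semi-axes must be strictly positive, got "
                             f"({self.semi_axis_a}, {self.semi_axis_b})")
        # Sufficient (conservative) bound: farthest support point from origin
        # is at most |center| + max(a, b).
        reach = np.hypot(self.center_x, self.center_y) + max(
            self.semi_axis_a, self.semi_axis_b
        )
        if reach > 1.0:
            raise ValueError(
                f"ellipse support may extend outside the unit disk "
                f"(center=({self.center_x:.3f},{self.center_y:.3f}), "
                f"axes=({self.semi_axis_a:.3f},{self.semi_axis_b:.3f}), "
                f"reach={reach:.3f} > 1)"
            )

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Vectorized membership test for points in image-fraction coords."""
        phi = np.deg2rad(self.rotation_deg)
        dx, dy = x - self.center_x, y - self.center_y
        u = dx * np.cos(phi) + dy * np.sin(phi)
        v = -dx * np.sin(phi) + dy * np.cos(phi)
        return (u / self.semi_axis_a) ** 2 + (v / self.semi_axis_b) ** 2 <= 1.0


@dataclass(frozen=True)
class PhantomSpec:
    """A full phantom: body ellipses plus metal inserts.

    Metal inserts are ellipses whose attenuation exceeds every non-metal pixel
    by a margin, so threshold segmentation is well posed.
    """

    ellipses: tuple[EllipseSpec, ...]
    metal_inserts: tuple[EllipseSpec, ...] = ()
    image_size: int = 256
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "ellipses", tuple(self.ellipses))
        object.__setattr__(self, "metal_inserts", tuple(self.metal_inserts))
        if self.image_size < 16:
            raise ValueError(f"image_size must be >= 16, got {self.image_size}")

    def all_ellipses(self) -> tuple[EllipseSpec, ...]:
        return self.ellipses + self.metal_inserts


@dataclass
class AttenuationImage:
    """Square 2-D map of linear attenuation coefficients.

    ``values[r, c]`` lives at physical point ``x = c - N//2``,
    ``y = N//2 - r`` (pixel units, y upward) in the frame shared with the
    projector.
    """

    values: np.ndarray
    pixel_spacing: float = 1.0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError(f"attenuation image must be square 2-D, "
                             f"got shape {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("attenuation image contains non-finite values")

    @property
    def size(self) -> int:
        return self.values.shape[0]


def _pixel_center_grid(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Image-fraction coordinates of pixel centers, y-up.

    The fraction origin sits on pixel index ``n//2`` — the same array index
    the projector rotates about — so a phantom centered at fraction (0, 0)
    is centered in the projection frame.
    """
    half = n / 2.0
    cols = (np.arange(n) - n // 2) / half
    rows = (n // 2 - np.arange(n)) / half
    x, y = np.meshgrid(cols, rows)  # x varies along columns, y along rows
    return x, y


def render_phantom(spec: PhantomSpec) -> AttenuationImage:
    """Rasterize a phantom: each pixel is the sum of the attenuation deltas of
    the ellipses whose support contains the pixel center.

    Deterministic and pure.  Raises if any ellipse may leave the unit disk.
    """
    for i, ell in enumerate(spec.all_ellipses()):
        try:
            ell.validate()
        except ValueError as exc:
            raise ValueError(f"ellipse {i}: {exc}") from exc
    x, y = _pixel_center_grid(spec.image_size)
    img = np.zeros((spec.image_size, spec.image_size), dtype=np.float64)
    for ell in spec.all_ellipses():
        img[ell.contains(x, y)] += ell.attenuation_delta
    return AttenuationImage(img)


def render_metal_map(spec: PhantomSpec) -> np.ndarray:
    """Binary map (uint8) of pixels inside any metal insert."""
    x, y = _pixel_center_grid(spec.image_size)
    m = np.zeros((spec.image_size, spec.image_size), dtype=bool)
    for ell in spec.metal_inserts:
        ell.validate()
        m |= ell.contains(x, y)
    return m.astype(np.uint8)


@dataclass(frozen=True)
class GenerationConfig:
    """Ranges for random phantom sampling.

    Defaults give one large body ellipse, a few internal soft-tissue ellipses
    with deltas in [0.2, 1.0], and metal discs with deltas in [5.0, 8.0] —
    arbitrary attenuation units chosen so metal exceeds any body pixel by a
    comfortable margin (threshold segmentation is unambiguous).
    """

    image_size: int = 256
    body_radius_range: tuple[float, float] = (0.55, 0.75)
    body_attenuation_range: tuple[float, float] = (0.2, 0.6)
    n_internal_range: tuple[int, int] = (2, 5)
    internal_axis_range: tuple[float, float] = (0.05, 0.3)
    internal_attenuation_range: tuple[float, float] = (0.2, 1.0)
    metal_count_range: tuple[int, int] = (1, 3)
    metal_radius_range: tuple[float, float] = (0.02, 0.08)
    metal_attenuation_range: tuple[float, float] = (5.0, 8.0)
    separability_margin: float = 2.0
    max_retries: int = 50

    def validate(self) -> None:
        for name in ("body_radius_range", "internal_axis_range",
                     "metal_radius_range"):
            lo, hi = getattr(self, name)
            if lo <= 0 or hi < lo:
                raise ValueError(f"{name} must be positive and ordered, "
                                 f"got ({lo}, {hi})")
        if self.n_internal_range[0] < 0 or self.metal_count_range[0] < 0:
            raise ValueError("counts must be >= 0")
        if self.max_retries < 1:
            raise ValueError("max_retries must be >= 1")


def sample_random_phantom(seed: int, config: GenerationConfig | None = None
                          ) -> PhantomSpec:
    """Draw a random phantom spec; deterministic for a fixed seed.

    The body is one large centered ellipse plus a few internal ellipses; metal
    inserts are small discs placed well inside the body.  Placement retries a
    bounded number of times and raises if the ranges are infeasible.
    """
    cfg = config or GenerationConfig()
    cfg.validate()
    rng = np.random.default_rng(seed)

    lo, hi = cfg.body_radius_range
    body_a = rng.uniform(lo, hi)
    body_b = rng.uniform(lo, hi)
    body = EllipseSpec(0.0, 0.0, body_a, body_b,
                       rotation_deg=rng.uniform(0, 180),
                       attenuation_delta=rng.uniform(*cfg.body_attenuation_range))

    ellipses = [body]
    inner = 0.8 * min(body_a, body_b)  # internal structures stay off the rim
    n_internal = int(rng.integers(cfg.n_internal_range[0],
                                  cfg.n_internal_range[1] + 1))
    for _ in range(n_internal):
        for _ in range(cfg.max_retries):
            a = rng.uniform(*cfg.internal_axis_range)
            b = rng.uniform(*cfg.internal_axis_range)
            r_pos = rng.uniform(0, max(inner - max(a, b), 0.0))
            ang = rng.uniform(0, 2 * np.pi)
            cand = EllipseSpec(r_pos * np.cos(ang), r_pos * np.sin(ang), a, b,
                               rotation_deg=rng.uniform(0, 180),
                               attenuation_delta=rng.uniform(
                                   *cfg.internal_attenuation_range))
            if np.hypot(cand.center_x, cand.center_y) + max(a, b) <= 1.0:
                ellipses.append(cand)
                break
        else:
            raise RuntimeError("could not place an internal ellipse within "
                               f"{cfg.max_retries} retries; ranges infeasible")

    metals: list[EllipseSpec] = []
    n_metal = int(rng.integers(cfg.metal_count_range[0],
                               cfg.metal_count_range[1] + 1))
    for _ in range(n_metal):
        for _ in range(cfg.max_retries):
            r = rng.uniform(*cfg.metal_radius_range)
            r_pos = rng.uniform(0, max(inner - r, 0.0))
            ang = rng.uniform(0, 2 * np.pi)
            cand = EllipseSpec(r_pos * np.cos(ang), r_pos * np.sin(ang), r, r,
                               attenuation_delta=rng.uniform(
                                   *cfg.metal_attenuation_range))
            # keep metals pairwise disjoint so trace intervals stay compact
            ok = all(np.hypot(cand.center_x - m.center_x,
                              cand.center_y - m.center_y)
                     > cand.semi_axis_a + m.semi_axis_a + 0.02
                     for m in metals)
            if ok:
                metals.append(cand)
                break
        else:
            raise RuntimeError("could not place a metal insert within "
                               f"{cfg.max_retries} retries; ranges infeasible")

    return PhantomSpec(tuple(ellipses), tuple(metals),
                       image_size=cfg.image_size, seed=seed)


# ---------------------------------------------------------------------------
# I/O

def save_image(image: AttenuationImage, path: str | Path) -> None:
    """Write as NPY (``.npy``) or single-channel float TIFF (``.tif``)."""
    path = Path(path)
    if path.suffix == ".npy":
        np.save(path, image.values)
    elif path.suffix in (".tif", ".tiff"):
        tifffile.imwrite(path, image.values.astype(np.float32))
    else:
        raise ValueError(f"unsupported image format: {path.suffix}")


def load_image(path: str | Path) -> AttenuationImage:
    path = Path(path)
    if path.suffix == ".npy":
        return AttenuationImage(np.load(path))
    if path.suffix in (".tif", ".tiff"):
        return AttenuationImage(np.asarray(tifffile.imread(path), dtype=np.float64))
    raise ValueError(f"unsupported image format: {path.suffix}")


def save_phantom_spec(spec: PhantomSpec, path: str | Path) -> None:
    payload = {
        "image_size": spec.image_size,
        "seed": spec.seed,
        "ellipses": [asdict(e) for e in spec.ellipses],
        "metal_inserts": [asdict(e) for e in spec.metal_inserts],
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def load_phantom_spec(path: str | Path) -> PhantomSpec:
    payload = json.loads(Path(path).read_text())
    return PhantomSpec(
        tuple(EllipseSpec(**e) for e in payload["ellipses"]),
        tuple(EllipseSpec(**e) for e in payload["metal_inserts"]),
        image_size=payload["image_size"],
        seed=payload["seed"],
    )


def save_preview(image: AttenuationImage, path: str | Path,
                 window: tuple[float, float] = (0.0, 1.0)) -> None:
    """PNG preview with a stated display window (values clipped to window)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    ax.imshow(image.values, cmap="gray", vmin=window[0], vmax=window[1])
    ax.set_title(f"window {window}")
    ax.axis("off")
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
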