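"""Parallel-beam projection, FBP reconstruction, and projection-moment
consistency conditions.

The physical frame is shared with :mod:`sinomar.phantoms`: pixel ``(r, c)``
of an ``N x N`` image sits at ``x = c - N//2``, ``y = N//2 - r`` in pixel
units, y upward (the rotate-and-sum projector rotates about array index
``N//2``).  The projection of an object ``f(x, y)`` at angle ``theta`` is
``g(theta, l)``, the line integral along the ray with signed detector offset
``l = x cos(theta) + y sin(theta)``.  Detector bin ``d`` of a sinogram sits
at ``l(d) = (d - n_detectors//2) * detector_spacing``.

Sinogram arrays are indexed ``(detector, angle)`` throughout.

The Helgason–Ludwig consistency conditions relate the detector moments of the
projections to the geometric moments of the image:

    V_k(theta) = int l^k g(theta, l) dl
    m_ij       = int int x^i y^j f(x, y) dx dy
    V_k(theta) = sum_{r=0..k} C(k, r) m_{r, k-r} cos^r(theta) sin^{k-r}(theta)

For k = 0 this says the total projection mass is the same at every angle —
the invariant that metal-trace deletion visibly breaks.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from math import comb
from pathlib import Path

import numpy as np
import tifffile
from skimage.transform import radon, iradon

from .phantoms import AttenuationImage

__all__ = [
    "ScanGeometry",
    "Sinogram",
    "MomentSeries",
    "ImageMoments",
    "forward_project",
    "fbp_reconstruct",
    "projection_moment",
    "image_moments",
    "hlcc_residual",
    "v0_consistency",
    "save_sinogram",
    "load_sinogram",
]

TRUNCATION_TOL = 1e-6  # relative mass at outermost bins that flags truncation


@dataclass(frozen=True)
class ScanGeometry:
    """Parallel-beam scan geometry.

    Detector array of ``n_detectors`` bins with unit spacing, centered on the
    rotation axis; one projection per entry of ``angles_deg``.
    """

    n_detectors: int = 512
    angles_deg: tuple[float, ...] = ()
    detector_spacing: float = 1.0

    def __post_init__(self):
        object.__setattr__(self, "angles_deg", tuple(self.angles_deg))
        if self.n_detectors < 2:
            raise ValueError("need at least 2 detector bins")
        a = np.asarray(self.angles_deg, dtype=np.float64)
        if a.size == 0:
            raise ValueError("angle list is empty")
        if a.size > 1 and not np.all(np.diff(a) > 0):
            raise ValueError("angles must be strictly increasing")
        if a[-1] - a[0] >= 360.0:
            raise ValueError("angles must lie within one period")

    @classmethod
    def uniform(cls, n_detectors: int = 512, n_angles: int = 360,
                full_circle: bool = True, detector_spacing: float = 1.0
                ) -> "ScanGeometry":
        span = 360.0 if full_circle else 180.0
        angles = tuple(np.arange(n_angles) * span / n_angles)
        return cls(n_detectors, angles, detector_spacing)

    @property
    def n_angles(self) -> int:
        return len(self.angles_deg)

    @property
    def angles_rad(self) -> np.ndarray:
        return np.deg2rad(np.asarray(self.angles_deg))

    def detector_offsets(self) -> np.ndarray:
        """Signed detector coordinates l(d), one per bin.

        The rotation axis projects onto bin index ``n_detectors // 2`` (the
        rotate-and-sum projector rotates about that array index).
        """
        d = np.arange(self.n_detectors, dtype=np.float64)
        return (d - self.n_detectors // 2) * self.detector_spacing


@dataclass
class Sinogram:
    """Projection data, shape ``(n_detectors, n_angles)``.

    ``scale`` is a recorded normalization factor (the completion network
    trains on ``values / scale``); ``values`` themselves are always physical.
    """

    values: np.ndarray
    geometry: ScanGeometry
    scale: float = 1.0
    truncated: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        expected = (self.geometry.n_detectors, self.geometry.n_angles)
        if self.values.shape != expected:
            raise ValueError(f"sinogram shape {self.values.shape} does not "
                             f"match geometry {expected}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("sinogram contains non-finite values")


@dataclass
class MomentSeries:
    """Per-angle detector moment V_k(theta) of a sinogram."""

    k: int
    values: np.ndarray  # one entry per geometry angle
    angles_deg: tuple[float, ...]


@dataclass
class ImageMoments:
    """Geometric moments m_ij of an attenuation image, i + j <= k_max."""

    k_max: int
    moments: dict  # {(i, j): float}

    def __getitem__(self, key: tuple[int, int]) -> float:
        return self.moments[key]


def _embed_centered(image: AttenuationImage, n: int) -> np.ndarray:
    """Place the image at the center of an n x n canvas (shared frame)."""
    m = image.size
    if m > n:
        raise ValueError(f"image side {m} exceeds detector count {n}; "
                         "support would be truncated")
    canvas = np.zeros((n, n), dtype=np.float64)
    off = (n - m) // 2  # odd leftover costs half a pixel; warned by caller
    canvas[off:off + m, off:off + m] = image.values
    return canvas


def forward_project(image: AttenuationImage, geometry: ScanGeometry) -> Sinogram:
    """Parallel-beam Radon transform of an attenuation image.

    Entry ``(d, j)`` approximates the line integral of the image along the ray
    at angle ``angles_deg[j]`` and offset ``l(d)``.  The image is embedded
    centered on the detector span; support reaching the two outermost bins
    sets the ``truncated`` flag and emits a warning.
    """
    if (geometry.n_detectors - image.size) % 2:
        warnings.warn("detector count and image side differ by an odd number "
                      "of pixels; centering is off by half a pixel")
    canvas = _embed_centered(image, geometry.n_detectors)
    with warnings.catch_warnings():
        # skimage warns about mass outside the inscribed circle; we detect
        # truncation ourselves from the outermost bins
        warnings.simplefilter("ignore")
        sino = radon(canvas, theta=np.asarray(geometry.angles_deg),
                     circle=True)
    sino = np.ascontiguousarray(sino, dtype=np.float64)
    # interpolation can produce tiny negatives from a non-negative image
    total = np.abs(sino).sum()
    truncated = False
    if total > 0:
        edge_mass = np.abs(sino[0, :]).max() + np.abs(sino[-1, :]).max()
        if edge_mass / max(np.abs(sino).max(), 1e-300) > TRUNCATION_TOL:
            truncated = True
            warnings.warn("projection support reaches the outermost detector "
                          "bins; sinogram flagged as truncated")
    return Sinogram(sino, geometry, truncated=truncated)


def fbp_reconstruct(sino: Sinogram, output_size: int | None = None
                    ) -> AttenuationImage:
    """Filtered back projection with a ramp (Ram-Lak) filter.

    Reconstructs on the sinogram's own geometry; the output is square with
    side ``n_detectors`` unless ``output_size`` requests a centered crop or
    zero-pad.  Full-circle data are handled by averaging conjugate rays
    (the backprojection sums all views and normalizes by their number).
    """
    if sino.geometry.n_angles < 2:
        raise ValueError("FBP needs at least 2 projection angles")
    theta = np.asarray(sino.geometry.angles_deg)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rec = iradon(sino.values, theta=theta, filter_name="ramp",
                     interpolation="linear", circle=True)
    rec = np.asarray(rec, dtype=np.float64)
    n = rec.shape[0]
    if output_size is not None and output_size != n:
        if output_size < n:
            off = (n - output_size) // 2
            rec = rec[off:off + output_size, off:off + output_size]
        else:
            pad = output_size - n
            lo = pad // 2
            rec = np.pad(rec, ((lo, pad - lo), (lo, pad - lo)))
    return AttenuationImage(rec)


def projection_moment(sino: Sinogram, k: int) -> MomentSeries:
    """k-th detector moment of each projection: V_k(theta) = sum_d l(d)^k g."""
    if k < 0:
        raise ValueError(f"moment order must be >= 0, got {k}")
    l = sino.geometry.detector_offsets()
    vk = (l[:, None] ** k * sino.values).sum(axis=0) * \
        sino.geometry.detector_spacing
    return MomentSeries(k, vk, sino.geometry.angles_deg)


def image_moments(image: AttenuationImage, k_max: int) -> ImageMoments:
    """Geometric moments m_ij for all i + j <= k_max (centered y-up frame)."""
    if k_max < 0:
        raise ValueError(f"k_max must be >= 0, got {k_max}")
    n = image.size
    s = image.pixel_spacing
    x = (np.arange(n) - n // 2) * s
    y = (n // 2 - np.arange(n)) * s
    area = s * s
    moments = {}
    for i in range(k_max + 1):
        for j in range(k_max + 1 - i):
            moments[(i, j)] = float(
                ((x ** i)[None, :] * (y ** j)[:, None] * image.values).sum()
                * area
            )
    return ImageMoments(k_max, moments)


def hlcc_residual(sino: Sinogram, image: AttenuationImage, k: int
                  ) -> np.ndarray:
    """Per-angle residual V_k(theta) - M_k(theta) of the order-k consistency
    condition, with M_k built from the image's geometric moments.

    The sinogram must have been generated in the same frame as the image
    (same detector spacing as pixel spacing).
    """
    if sino.geometry.detector_spacing != image.pixel_spacing:
        raise ValueError("sinogram and image use different spacings; "
                         "moments are not comparable")
    vk = projection_moment(sino, k).values
    m = image_moments(image, k)
    th = sino.geometry.angles_rad
    mk = np.zeros_like(th)
    for r in range(k + 1):
        mk += comb(k, r) * m[(r, k - r)] * np.cos(th) ** r * \
            np.sin(th) ** (k - r)
    return vk - mk


def v0_consistency(sino: Sinogram) -> float:
    """Sinogram-only order-0 consistency score: coefficient of variation of
    the per-angle projection mass.  Zero for perfectly consistent data;
    strictly positive when angle-dependent mass (e.g. a zeroed metal trace)
    breaks the invariant."""
    v0 = projection_moment(sino, 0).values
    mean = v0.mean()
    if mean == 0:
        return 0.0
    return float(v0.std() / abs(mean))


# ---------------------------------------------------------------------------
# I/O — array plus a JSON sidecar recording the geometry and axis order

def save_sinogram(sino: Sinogram, path: str | Path) -> None:
    path = Path(path)
    if path.suffix == ".npy":
        np.save(path, sino.values)
    elif path.suffix in (".tif", ".tiff"):
        tifffile.imwrite(path, sino.values.astype(np.float32))
    else:
        raise ValueError(f"unsupported sinogram format: {path.suffix}")
    meta = {
        "axis_order": "(detector, angle)",
        "n_detectors": sino.geometry.n_detectors,
        "angles_deg": list(sino.geometry.angles_deg),
        "detector_spacing": sino.geometry.detector_spacing,
        "scale": sino.scale,
        "truncated": sino.truncated,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta))


def load_sinogram(path: str | Path) -> Sinogram:
    path = Path(path)
    if path.suffix == ".npy":
        values = np.load(path)
    elif path.suffix in (".tif", ".tiff"):
        values = np.asarray(tifffile.imread(path), dtype=np.float64)
    else:
        raise ValueError(f"unsupported sinogram format: {path.suffix}")
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    geom = ScanGeometry(meta["n_detectors"], tuple(meta["angles_deg"]),
                        meta["detector_spacing"])
    return Sinogram(values, geom, scale=meta["scale"],
                    truncated=meta["truncated"])
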