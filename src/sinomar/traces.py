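"""Metal segmentation, trace-mask construction, trace zeroing, and composite
assembly.

The training/evaluation unit is a :class:`SinogramPair`: a complete ("label")
sinogram, the binary trace mask marking the detector/angle entries whose rays
pass through metal, and the corrupted sinogram obtained by zeroing exactly
those entries.  Only the metal-damaged traces are zeroed; every other entry of
the corrupted sinogram is bit-identical to the label, which is what makes the
pairing valid supervision for completion.

Two routes produce a trace mask and share one implementation:

* simulation time — the metal map is known exactly from the phantom spec;
* test time — reconstruct the corrupted scan with FBP, threshold-segment the
  metal, and reproject (``trace_mask_from_scan``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .phantoms import (AttenuationImage, PhantomSpec, render_phantom,
                       render_metal_map)
from .projection import (ScanGeometry, Sinogram, forward_project,
                         fbp_reconstruct)

__all__ = [
    "TraceMask",
    "SinogramPair",
    "segment_metal",
    "trace_mask",
    "trace_mask_from_scan",
    "corrupt",
    "composite",
    "make_pair",
    "save_pairs",
    "load_pairs",
]

# reprojected binary metal shorter than this path length (in detector-bin
# units) does not count as a trace: suppresses interpolation dust
TRACE_CUTOFF = 0.5

DEFAULT_METAL_THRESHOLD = 4.0
DEFAULT_DILATION_PX = 2


@dataclass
class TraceMask:
    """Binary mask congruent with a sinogram; 1 = metal-damaged trace."""

    values: np.ndarray
    dilation_px: int = 0

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("trace mask must be binary")
        self.values = self.values.astype(np.uint8)
        if self.dilation_px < 0:
            raise ValueError("dilation_px must be >= 0")


@dataclass
class SinogramPair:
    """(corrupted, mask, label) triple satisfying the pairing invariants:
    corrupted == label off the trace (bit-exact) and == 0 on it."""

    corrupted: Sinogram
    mask: TraceMask
    label: Sinogram

    def __post_init__(self):
        if not (self.corrupted.values.shape == self.mask.values.shape
                == self.label.values.shape):
            raise ValueError("pair members have mismatched shapes")
        m = self.mask.values.astype(bool)
        if not np.array_equal(self.corrupted.values[~m],
                              self.label.values[~m]):
            raise ValueError("corrupted sinogram differs from label off the "
                             "trace mask")
        if np.any(self.corrupted.values[m] != 0):
            raise ValueError("corrupted sinogram is nonzero on the trace")


def segment_metal(image: AttenuationImage, threshold: float) -> np.ndarray:
    """Threshold segmentation of metal: binary map of pixels with value >=
    threshold (inclusive)."""
    if threshold <= 0:
        raise ValueError(f"threshold must be > 0, got {threshold}")
    return (image.values >= threshold).astype(np.uint8)


def trace_mask(metal: np.ndarray, geometry: ScanGeometry,
               dilation_px: int = DEFAULT_DILATION_PX) -> TraceMask:
    """Metal trace by reprojection: forward-project the binary metal map,
    binarize where the intersection path length exceeds half a detector bin,
    then dilate along the detector axis by ``dilation_px`` bins per side.
    """
    metal = np.asarray(metal)
    if not np.isin(metal, (0, 1)).all():
        raise ValueError("metal map must be binary")
    if dilation_px < 0:
        raise ValueError("dilation_px must be >= 0")
    shadow = forward_project(AttenuationImage(metal.astype(np.float64)),
                             geometry)
    if shadow.truncated:
        raise ValueError("metal support extends outside the detector span")
    mask = shadow.values > TRACE_CUTOFF
    if dilation_px > 0:
        structure = np.ones((2 * dilation_px + 1, 1), dtype=bool)
        mask = ndimage.binary_dilation(mask, structure=structure)
    return TraceMask(mask.astype(np.uint8), dilation_px=dilation_px)


def trace_mask_from_scan(sino: Sinogram, threshold: float,
                         dilation_px: int = DEFAULT_DILATION_PX) -> TraceMask:
    """Test-time trace recovery: FBP-reconstruct the (metal-bearing) scan,
    threshold-segment the metal, and reproject to the trace."""
    recon = fbp_reconstruct(sino)
    metal = segment_metal(recon, threshold)
    return trace_mask(metal, sino.geometry, dilation_px)


def corrupt(label: Sinogram, mask: TraceMask) -> Sinogram:
    """Zero the metal-damaged trace; leave every other entry bit-exact."""
    if label.values.shape != mask.values.shape:
        raise ValueError(f"shape mismatch: sinogram {label.values.shape} vs "
                         f"mask {mask.values.shape}")
    out = np.where(mask.values.astype(bool), 0.0, label.values)
    return Sinogram(out, label.geometry, scale=label.scale)


def composite(completed: Sinogram, original: Sinogram, mask: TraceMask
              ) -> Sinogram:
    """Keep completed values on the trace, original values elsewhere
    (bit-exact preservation of the unaffected data)."""
    if not (completed.values.shape == original.values.shape
            == mask.values.shape):
        raise ValueError("composite inputs have mismatched shapes")
    out = np.where(mask.values.astype(bool), completed.values,
                   original.values)
    return Sinogram(out, original.geometry, scale=original.scale)


def make_pair(phantom: PhantomSpec, geometry: ScanGeometry,
              threshold: float = DEFAULT_METAL_THRESHOLD,
              dilation_px: int = DEFAULT_DILATION_PX,
              label_mode: str = "full") -> SinogramPair:
    """Build one training/evaluation pair from a phantom spec.

    The label is the forward projection of the full object (body + metal) by
    default; ``label_mode="body_only"`` projects the body alone instead.  The
    trace mask comes from the phantom's exact metal map (no segmentation step
    at simulation time); the corrupted sinogram zeroes the trace.
    """
    if label_mode not in ("full", "body_only"):
        raise ValueError(f"unknown label_mode: {label_mode!r}")
    if label_mode == "full":
        label_img = render_phantom(phantom)
    else:
        label_img = render_phantom(
            PhantomSpec(phantom.ellipses, (), phantom.image_size,
                        phantom.seed))
    label = forward_project(label_img, geometry)
    metal = render_metal_map(phantom)
    if metal.any():
        mask = trace_mask(metal, geometry, dilation_px)
    else:
        mask = TraceMask(np.zeros(label.values.shape, dtype=np.uint8),
                         dilation_px=dilation_px)
    corrupted = corrupt(label, mask)
    return SinogramPair(corrupted, mask, label)


# ---------------------------------------------------------------------------
# Dataset container: one NPZ per dataset plus a JSON manifest

def save_pairs(pairs: list[SinogramPair], path: str | Path,
               manifest: dict | None = None) -> None:
    """Write a dataset as NPZ (stacked corrupted/mask/label arrays) with a
    JSON manifest sidecar recording geometry and provenance."""
    path = Path(path)
    if not pairs:
        np.savez(path, corrupted=np.zeros((0, 0, 0)),
                 mask=np.zeros((0, 0, 0), dtype=np.uint8),
                 label=np.zeros((0, 0, 0)))
        geom_meta = {}
    else:
        g = pairs[0].label.geometry
        np.savez(
            path,
            corrupted=np.stack([p.corrupted.values for p in pairs]),
            mask=np.stack([p.mask.values for p in pairs]),
            label=np.stack([p.label.values for p in pairs]),
        )
        geom_meta = {
            "n_detectors": g.n_detectors,
            "angles_deg": list(g.angles_deg),
            "detector_spacing": g.detector_spacing,
            "dilation_px": pairs[0].mask.dilation_px,
        }
    meta = {"n_pairs": len(pairs), "axis_order": "(pair, detector, angle)",
            "geometry": geom_meta}
    meta.update(manifest or {})
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2,
                                                    sort_keys=True))


def load_pairs(path: str | Path) -> tuple[list[SinogramPair], dict]:
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(".npz")
    data = np.load(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    pairs: list[SinogramPair] = []
    if meta["n_pairs"]:
        g = meta["geometry"]
        geom = ScanGeometry(g["n_detectors"], tuple(g["angles_deg"]),
                            g["detector_spacing"])
        dil = g.get("dilation_px", 0)
        for c, m, l in zip(data["corrupted"], data["mask"], data["label"]):
            pairs.append(SinogramPair(
                Sinogram(c, geom), TraceMask(m, dilation_px=dil),
                Sinogram(l, geom)))
    return pairs, meta
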