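"""Evaluation metrics and method comparison tables.

Sinogram-domain completion quality is scored by mean absolute error (MAE),
either over the full array or restricted to the metal trace (the trace is
where completion happens; full-array MAE additionally penalizes methods that
perturb unaffected data).  Image-domain quality after FBP reconstruction is
scored by root-mean-square error (RMSE) and normalized mean absolute distance
(NMAD), on the full image or a rectangular region of interest:

    MAE  = sum_i |fhat_i - f_i| / N
    RMSE = sqrt( sum_i (ref_i - rec_i)^2 / N )
    NMAD = sum_i |ref_i - rec_i| / sum_i |ref_i|

The reference image for RMSE/NMAD is the FBP reconstruction of the label
sinogram (not the phantom itself), so the scores isolate completion error
from FBP discretization error.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

from .phantoms import AttenuationImage
from .projection import Sinogram, fbp_reconstruct
from .traces import SinogramPair, TraceMask

__all__ = ["ROISpec", "mae", "rmse", "nmad", "compare_methods"]


@dataclass(frozen=True)
class ROISpec:
    """Rectangular region of interest: half-open extents in image coords."""

    row_start: int
    col_start: int
    n_rows: int
    n_cols: int

    def validate(self, shape: tuple[int, int]) -> None:
        if self.n_rows <= 0 or self.n_cols <= 0:
            raise ValueError("ROI extents must be positive")
        if (self.row_start < 0 or self.col_start < 0
                or self.row_start + self.n_rows > shape[0]
                or self.col_start + self.n_cols > shape[1]):
            raise ValueError(f"ROI {self} outside image bounds {shape}")

    def slice(self) -> tuple[slice, slice]:
        return (slice(self.row_start, self.row_start + self.n_rows),
                slice(self.col_start, self.col_start + self.n_cols))


def _values(a) -> np.ndarray:
    if isinstance(a, (Sinogram, AttenuationImage)):
        return a.values
    return np.asarray(a, dtype=np.float64)


def mae(output, label, region: TraceMask | np.ndarray | None = None) -> float:
    """Mean absolute error, full-array or restricted to a binary region."""
    out, lab = _values(output), _values(label)
    if out.shape != lab.shape:
        raise ValueError(f"shape mismatch: {out.shape} vs {lab.shape}")
    diff = np.abs(out - lab)
    if region is None:
        return float(diff.mean())
    reg = region.values.astype(bool) if isinstance(region, TraceMask) \
        else np.asarray(region).astype(bool)
    if reg.shape != out.shape:
        raise ValueError("region shape mismatch")
    n = reg.sum()
    if n == 0:
        raise ValueError("empty evaluation region")
    return float(diff[reg].sum() / n)


def rmse(recon, ref, roi: ROISpec | None = None) -> float:
    """Root-mean-square error over the full image or a rectangular ROI."""
    rec, r = _values(recon), _values(ref)
    if rec.shape != r.shape:
        raise ValueError(f"shape mismatch: {rec.shape} vs {r.shape}")
    if roi is not None:
        roi.validate(rec.shape)
        sl = roi.slice()
        rec, r = rec[sl], r[sl]
    return float(np.sqrt(np.mean((r - rec) ** 2)))


def nmad(recon, ref, roi: ROISpec | None = None) -> float:
    """Normalized mean absolute distance; scale-free (invariant to scaling
    both images by the same positive factor)."""
    rec, r = _values(recon), _values(ref)
    if rec.shape != r.shape:
        raise ValueError(f"shape mismatch: {rec.shape} vs {r.shape}")
    if roi is not None:
        roi.validate(rec.shape)
        sl = roi.slice()
        rec, r = rec[sl], r[sl]
    denom = np.abs(r).sum()
    if denom == 0:
        raise ValueError("reference image has zero absolute sum on the "
                         "evaluated region")
    return float(np.abs(r - rec).sum() / denom)


def compare_methods(pair: SinogramPair,
                    methods: dict[str, Callable[[Sinogram, TraceMask],
                                                Sinogram]],
                    roi: ROISpec | None = None) -> pd.DataFrame:
    """Score completion methods on one pair.

    Each method maps (corrupted sinogram, trace mask) -> completed sinogram.
    Per method the table reports sinogram MAE (full array and trace-restricted
    when the trace is nonempty), then FBP-reconstructs and reports image
    RMSE/NMAD against the FBP reconstruction of the label, plus ROI-restricted
    variants when an ROI is given.
    """
    ref = fbp_reconstruct(pair.label)
    has_trace = bool(pair.mask.values.any())
    rows = []
    for name, method in methods.items():
        completed = method(pair.corrupted, pair.mask)
        rec = fbp_reconstruct(completed)
        row = {
            "method": name,
            "sino_mae": mae(completed, pair.label),
            "trace_mae": (mae(completed, pair.label, region=pair.mask)
                          if has_trace else 0.0),
            "rmse": rmse(rec, ref),
            "nmad": nmad(rec, ref),
        }
        if roi is not None:
            row["roi_rmse"] = rmse(rec, ref, roi=roi)
            row["roi_nmad"] = nmad(rec, ref, roi=roi)
        rows.append(row)
    return pd.DataFrame(rows).set_index("method")
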