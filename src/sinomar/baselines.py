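"""Linear-interpolation metal artifact reduction (LI-MAR).

The classical comparison method: within each projection angle, every maximal
run of trace-masked detector bins is replaced by the 1-D linear interpolant
between the nearest unmasked values on either side (Kalender's method).
Unmasked entries are preserved bit-exact.  A gap touching a detector boundary
is filled by constant extrapolation from its single anchor; a fully masked
angle has no anchors at all and is filled with zeros and flagged.
"""

from __future__ import annotations

import warnings

import numpy as np

from .projection import Sinogram
from .traces import TraceMask

__all__ = ["li_mar"]


def li_mar(sino: Sinogram, mask: TraceMask) -> Sinogram:
    if sino.values.shape != mask.values.shape:
        raise ValueError(f"shape mismatch: sinogram {sino.values.shape} vs "
                         f"mask {mask.values.shape}")
    out = sino.values.copy()
    m = mask.values.astype(bool)
    n_det = out.shape[0]
    idx = np.arange(n_det)
    dead_columns = 0
    for j in range(out.shape[1]):
        col_mask = m[:, j]
        if not col_mask.any():
            continue
        anchors = idx[~col_mask]
        if anchors.size == 0:
            out[:, j] = 0.0
            dead_columns += 1
            continue
        # np.interp: linear between anchors, constant beyond the outermost
        out[col_mask, j] = np.interp(idx[col_mask], anchors,
                                     out[anchors, j])
    if dead_columns:
        warnings.warn(f"{dead_columns} fully masked angle(s) had no anchors; "
                      "filled with zeros")
    return Sinogram(out, sino.geometry, scale=sino.scale,
                    truncated=sino.truncated)
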