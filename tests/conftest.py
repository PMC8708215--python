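"""Shared fixtures: small deterministic phantoms, geometries, and pairs."""

import numpy as np
import pytest

import sinomar as sm


@pytest.fixture(scope="session")
def small_geometry():
    """64-detector, 48-angle full-circle parallel-beam geometry."""
    return sm.ScanGeometry.uniform(n_detectors=64, n_angles=48)


@pytest.fixture(scope="session")
def disk_spec():
    """Centered disk, radius 0.5 image-fraction (16 px at size 64)."""
    return sm.PhantomSpec(
        (sm.EllipseSpec(0.0, 0.0, 0.5, 0.5, 0.0, 1.0),), (), image_size=64)


@pytest.fixture(scope="session")
def disk_image(disk_spec):
    return sm.render_phantom(disk_spec)


@pytest.fixture(scope="session")
def offcenter_spec():
    """Asymmetric two-ellipse body (all moments nonzero)."""
    return sm.PhantomSpec(
        (sm.EllipseSpec(0.3, -0.2, 0.2, 0.3, 30.0, 1.0),
         sm.EllipseSpec(-0.25, 0.3, 0.15, 0.1, 75.0, 0.5)),
        (), image_size=64)


@pytest.fixture(scope="session")
def offcenter_image(offcenter_spec):
    return sm.render_phantom(offcenter_spec)


@pytest.fixture(scope="session")
def metal_phantom_spec():
    """Body ellipse plus a single off-center metal disc."""
    return sm.PhantomSpec(
        (sm.EllipseSpec(0.0, 0.0, 0.7, 0.6, 0.0, 0.5),
         sm.EllipseSpec(0.2, 0.1, 0.25, 0.2, 10.0, 0.5)),
        (sm.EllipseSpec(-0.2, 0.15, 0.1, 0.1, 0.0, 6.0),),
        image_size=48)


@pytest.fixture(scope="session")
def metal_pair(metal_phantom_spec, small_geometry):
    return sm.make_pair(metal_phantom_spec, small_geometry, dilation_px=1)


def brute_force_project(image: np.ndarray, angles_deg, offsets,
                        step: float = 0.25) -> np.ndarray:
    """Independent line-integral oracle: sample each ray densely with
    bilinear interpolation and sum.  Slow; for small fixtures only.

    Shares only the frame convention with the implementation under test:
    pixel (r, c) at x = c - n//2, y = n//2 - r; ray at angle theta, offset l
    is {l*(cos t, sin t) + s*(-sin t, cos t)}.
    """
    n = image.shape[0]
    c0 = n // 2
    out = np.zeros((len(offsets), len(angles_deg)))
    smax = n / np.sqrt(2.0) + 2
    s = np.arange(-smax, smax, step)
    for j, ang in enumerate(np.deg2rad(np.asarray(angles_deg))):
        ct, st = np.cos(ang), np.sin(ang)
        for i, l in enumerate(offsets):
            x = l * ct - s * st
            y = l * st + s * ct
            col = x + c0
            row = c0 - y
            r0 = np.floor(row).astype(int)
            c1 = np.floor(col).astype(int)
            fr = row - r0
            fc = col - c1
            acc = np.zeros_like(s)
            for dr, dc, w in ((0, 0, (1 - fr) * (1 - fc)),
                              (0, 1, (1 - fr) * fc),
                              (1, 0, fr * (1 - fc)),
                              (1, 1, fr * fc)):
                rr = r0 + dr
                cc = c1 + dc
                ok = (rr >= 0) & (rr < n) & (cc >= 0) & (cc < n)
                acc[ok] += w[ok] * image[rr[ok], cc[ok]]
            out[i, j] = acc.sum() * step
    return out
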