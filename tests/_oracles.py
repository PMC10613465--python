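"""Independent oracles used by the test suite.

These deliberately avoid the package's own code paths: the focused-bowl
axial field comes from direct numerical quadrature of the Rayleigh
integral (the classical O'Neil focused-radiator solution), and the RP
candidate screen is a literal re-implementation of the screening rules
using different library primitives (component labelling + KD-tree) than
the implementation (flood fill + distance transform).
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from scipy.integrate import quad
from scipy.spatial import cKDTree


def oneil_axial_pressure(z_m, roc_m: float, aperture_m: float, f: float,
                         c: float = 1482.0) -> np.ndarray:
    """|p| on the bowl axis by Rayleigh ring quadrature (arbitrary units).

    ``z_m`` is axial distance from the cap apex (m); the centre of
    curvature (geometric focus) sits at ``z = roc_m``.
    """
    k = 2 * np.pi * f / c
    a = aperture_m / 2
    th_max = np.arcsin(a / roc_m)
    out = np.empty(np.shape(z_m))
    for i, z in enumerate(np.atleast_1d(z_m)):
        def ire(th):
            zs = roc_m * (1 - np.cos(th))
            rs = roc_m * np.sin(th)
            r = np.sqrt((z - zs) ** 2 + rs**2)
            return np.cos(k * r) / r * roc_m**2 * np.sin(th)

        def iim(th):
            zs = roc_m * (1 - np.cos(th))
            rs = roc_m * np.sin(th)
            r = np.sqrt((z - zs) ** 2 + rs**2)
            return -np.sin(k * r) / r * roc_m**2 * np.sin(th)

        re = quad(ire, 0, th_max, limit=200)[0]
        im = quad(iim, 0, th_max, limit=200)[0]
        out.flat[i] = abs(re + 1j * im)
    return out


def rp_candidates_bruteforce(mask_data, spacing, origin, target_w, roc,
                             clearance, ball_margin=0.0):
    """Literal application of the RP screening rules, voxel by voxel.

    Returns the sorted (n, 3) world-mm candidate array.  Exterior voxels
    are found by labelling the non-skull complement and keeping the
    component touching the domain corner; clearance uses a KD-tree over
    skull voxel centres.
    """
    mask_data = np.asarray(mask_data, dtype=bool)
    spacing = np.asarray(spacing, dtype=float)
    origin = np.asarray(origin, dtype=float)
    target_w = np.asarray(target_w, dtype=float)
    shape = mask_data.shape
    ball_r = roc + ball_margin

    # model centre: midpoint of occupied extent per axis, world mm
    occ = np.nonzero(mask_data)
    mc = np.array([
        origin[a] + spacing[a] * (occ[a].min() + occ[a].max()) / 2.0
        for a in range(3)
    ])

    idx = np.indices(shape, dtype=float)
    world = [origin[a] + idx[a] * spacing[a] for a in range(3)]
    d_t = np.sqrt(sum((world[a] - target_w[a]) ** 2 for a in range(3)))
    d_c = np.sqrt(sum((world[a] - mc[a]) ** 2 for a in range(3)))
    in_ball = d_t <= ball_r

    shell_hits = in_ball & mask_data
    assert shell_hits.any(), "oracle: target unreachable"
    mean_d = d_c[shell_hits].mean()

    labels, _ = ndimage.label(~mask_data)
    exterior = labels == labels[0, 0, 0]

    skull_pts = np.stack([world[a][mask_data] for a in range(3)], axis=1)
    tree = cKDTree(skull_pts)

    cand = in_ball & exterior & (d_c > mean_d)
    ci = np.nonzero(cand)
    pts = np.stack([world[a][ci] for a in range(3)], axis=1)
    dmin, _ = tree.query(pts)
    keep = dmin >= clearance
    pts = pts[keep]
    order = np.lexsort((ci[2][keep], ci[1][keep], ci[0][keep]))
    return pts[order]


def heat_kernel_gaussian(r2, sigma0, diffusivity, t, amplitude, ndim):
    """Spreading-Gaussian closed form of the heat equation: an initial
    perturbation ``A exp(-r^2 / 2 sigma0^2)`` in an infinite homogeneous
    medium evolves to ``A (sigma0^2/sigma^2)^{ndim/2} exp(-r^2/2 sigma^2)``
    with ``sigma^2 = sigma0^2 + 2 D t``."""
    sig2 = sigma0**2 + 2 * diffusivity * t
    return amplitude * (sigma0**2 / sig2) ** (ndim / 2) * np.exp(-r2 / (2 * sig2))
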