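"""Panoramic (cylindrical-projection) descriptor of a surface mesh.

The mesh is centered on its centroid and projected onto three cylinders,
one per principal axis of the vertex covariance (descending eigenvalue,
signs fixed by requiring positive skewness of the projected coordinates,
lexicographic tie-break for near-degenerate axes).  Each cylinder of
radius twice the maximal radial extent samples a depth map D(h, phi):
the distance from the cylinder wall inward to the outermost surface
point in that (height, azimuth) cell.  The surface is represented by a
dense area-weighted point sample so the cell grid is well covered
regardless of tessellation density; cells no surface point falls in are
misses and record depth 0; bent surfaces are legitimately invisible from
much of the cylinder, so only an extreme miss fraction (configurable,
default 90%) aborts.

Features per map: the magnitudes of the lowest 16 x 16 block of the 2D
discrete Fourier transform (invariant to circular shifts in phi, i.e.
to rotation about the cylinder axis) and the sub-band energies of a
2-level 2D Haar wavelet decomposition.  The descriptor concatenates the
three maps' features.
"""

from __future__ import annotations

import logging

import numpy as np
import pywt

from ..mesh import TriangleMesh
from .base import ShapeDescriptor

logger = logging.getLogger(__name__)

__all__ = ["panorama_descriptor", "depth_map"]


class ProjectionError(ValueError):
    """Cylindrical projection failed (too many empty cells)."""


def principal_axes(vertices: np.ndarray) -> np.ndarray:
    """Rows = principal axes, descending variance, deterministic signs."""
    centered = vertices - vertices.mean(axis=0)
    cov = np.cov(centered.T)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    axes = evecs[:, order].T
    # near-degenerate spectra: fall back to a lexicographic convention
    if np.min(np.abs(np.diff(evals[order]))) < 1e-9 * max(evals.max(), 1e-30):
        logger.warning("near-degenerate principal axes; lexicographic tie-break")
        ranking = np.lexsort(axes.T[::-1])
        axes = axes[ranking[::-1]]
    for i in range(3):
        proj = centered @ axes[i]
        skew = np.mean(proj ** 3)
        if skew < 0:
            axes[i] = -axes[i]
    # right-handed frame
    if np.dot(np.cross(axes[0], axes[1]), axes[2]) < 0:
        axes[2] = -axes[2]
    return axes


def depth_map(vertices: np.ndarray, axis: np.ndarray, e1: np.ndarray,
              e2: np.ndarray, h_samples: int, angle_samples: int
              ) -> tuple[np.ndarray, float]:
    """Rasterize the outermost radial extent into an (h, phi) grid.

    Returns (depth map, miss fraction): depth = R_cyl - max radial
    distance of the surface in the cell, R_cyl = 2 x max radial extent.
    """
    h = vertices @ axis
    x = vertices @ e1
    y = vertices @ e2
    rho = np.hypot(x, y)
    phi = np.arctan2(y, x)
    r_cyl = 2.0 * rho.max()
    # central 99% of the height distribution: thin off-axis spikes would
    # otherwise stretch the map into mostly-empty rows
    h_lo, h_hi = np.percentile(h, [0.5, 99.5])
    span = max(h_hi - h_lo, 1e-12)
    hi_idx = np.clip(((h - h_lo) / span * h_samples).astype(int), 0, h_samples - 1)
    pi_idx = np.clip(((phi + np.pi) / (2 * np.pi) * angle_samples).astype(int),
                     0, angle_samples - 1)
    outer = np.zeros((h_samples, angle_samples))
    np.maximum.at(outer, (hi_idx, pi_idx), rho)
    hit = outer > 0
    depth = np.where(hit, r_cyl - outer, 0.0)
    miss_fraction = 1.0 - hit.mean()
    return depth, miss_fraction


def _map_features(depth: np.ndarray, fourier_block: int) -> np.ndarray:
    spectrum = np.abs(np.fft.fft2(depth))[:fourier_block, :fourier_block]
    coeffs = pywt.wavedec2(depth, "haar", level=2)
    energies = [float(np.sum(coeffs[0] ** 2))]
    for detail in coeffs[1:]:
        energies.extend(float(np.sum(d ** 2)) for d in detail)
    return np.concatenate([spectrum.ravel(), np.asarray(energies)])


def panorama_descriptor(mesh: TriangleMesh, cyl_height_samples: int = 64,
                        cyl_angle_samples: int = 128,
                        fourier_block: int = 16,
                        n_surface_samples: int = 60000,
                        max_miss_fraction: float = 0.9) -> ShapeDescriptor:
    """Concatenated Fourier + Haar features of the three principal-axis
    panoramic depth maps (length 3 x (16*16 + 7) = 789 by default)."""
    from .zernike import sample_surface_points

    points = sample_surface_points(mesh, n_surface_samples, seed=0)
    centered = points - points.mean(axis=0)
    axes = principal_axes(points)
    features = []
    for i in range(3):
        axis = axes[i]
        e1 = axes[(i + 1) % 3]
        e2 = axes[(i + 2) % 3]
        depth, miss = depth_map(centered, axis, e1, e2,
                                cyl_height_samples, cyl_angle_samples)
        if miss > max_miss_fraction:
            raise ProjectionError(
                f"{miss:.0%} of projection cells empty along axis {i}")
        if miss > 0:
            logger.debug("axis %d: %.1f%% projection cells empty", i, 100 * miss)
        features.append(_map_features(depth, fourier_block))
    values = np.concatenate(features)
    return ShapeDescriptor(method="panorama", values=values,
                           params={"cyl_height_samples": cyl_height_samples,
                                   "cyl_angle_samples": cyl_angle_samples,
                                   "fourier_block": fourier_block,
                                   "n_surface_samples": n_surface_samples})
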