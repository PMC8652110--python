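"""Surface-shape descriptors and the distances between them.

Four descriptor families are implemented, each mapping a closed triangle
mesh to a fixed-length real vector:

* ``shape_dna`` — leading eigenvalues of the Laplace-Beltrami operator,
  area-normalized (isometry- and scale-invariant);
* ``zernike3d`` — rotation-invariant norms of 3D Zernike moments of the
  voxelized surface inside the unit ball;
* ``vfh`` — viewpoint feature histogram of normal/direction angles,
  viewed from the surface centroid;
* ``panorama`` — Fourier and Haar-wavelet features of cylindrical
  depth-map projections along the principal axes.
"""

from .base import ShapeDescriptor, descriptor_distance, DescriptorContractError
from .spectral import SpectralDescriptor, laplace_beltrami_spectrum, shape_dna_descriptor
from .zernike import zernike3d_descriptor, zernike_invariant_count
from .vfh import vfh_descriptor
from .panorama import panorama_descriptor

METHODS = ("shape_dna", "zernike3d", "vfh", "panorama")

#: the dissimilarity metric used for each method's matrix
DEFAULT_METRICS = {
    "shape_dna": "euclidean",
    "zernike3d": "euclidean",
    "vfh": "euclidean",
    "panorama": "panorama_composite",
}

__all__ = [
    "ShapeDescriptor", "SpectralDescriptor", "DescriptorContractError",
    "descriptor_distance", "laplace_beltrami_spectrum", "shape_dna_descriptor",
    "zernike3d_descriptor", "zernike_invariant_count", "vfh_descriptor",
    "panorama_descriptor", "METHODS", "DEFAULT_METRICS", "compute_descriptor",
]


def compute_descriptor(mesh, method: str, **params) -> ShapeDescriptor:
    """Dispatch to the descriptor implementation named ``method``."""
    if method == "shape_dna":
        return shape_dna_descriptor(mesh, **params)
    if method == "zernike3d":
        return zernike3d_descriptor(mesh, **params)
    if method == "vfh":
        return vfh_descriptor(mesh, **params)
    if method == "panorama":
        return panorama_descriptor(mesh, **params)
    raise ValueError(f"unknown descriptor method {method!r}")
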