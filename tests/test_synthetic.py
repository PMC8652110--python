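"""Synthetic benchmark generator: determinism, hierarchy, hinge geometry."""

import numpy as np
import pytest

from surfshape import (blobby_surface, generate_hierarchy_benchmark,
                       generate_pseudo_structure, mesh_geometry)
from surfshape.homologs import pairwise_sequence_identity
from surfshape.synthetic import EmptySurfaceError


def test_pseudo_structure_determinism_and_contract():
    a = generate_pseudo_structure(10, seed=1)
    b = generate_pseudo_structure(10, seed=1)
    np.testing.assert_array_equal(a.centers, b.centers)
    assert a.sequence == b.sequence
    assert len(a.sequence) == 30
    c = generate_pseudo_structure(10, seed=2)
    assert not np.array_equal(a.centers, c.centers)
    with pytest.raises(ValueError):
        generate_pseudo_structure(4, seed=0)


def test_pseudo_structure_connectivity():
    s = generate_pseudo_structure(20, seed=7)
    d = np.linalg.norm(s.centers[:, None] - s.centers[None], axis=2)
    np.fill_diagonal(d, np.inf)
    thresh = 2 * (s.radii[:, None] + s.radii[None])
    assert (d <= thresh).any(axis=1).all()


def test_single_blob_surface_is_a_sphere():
    """At iso e^-1 the single-blob level set is exactly the r=2 sphere."""
    s = generate_pseudo_structure(5, seed=0)
    one = type(s)(centers=np.zeros((1, 3)), radii=np.array([2.0]),
                  sequence="A" * 20)
    mesh = blobby_surface(one, grid_resolution=96)
    area = mesh_geometry(mesh).area
    assert area == pytest.approx(16 * np.pi, rel=0.05)


def test_grid_refinement_convergence():
    s = generate_pseudo_structure(8, seed=5)
    v64 = mesh_geometry(blobby_surface(s, 64)).volume
    v128 = mesh_geometry(blobby_surface(s, 128)).volume
    assert abs(v64 - v128) / v128 < 0.02


def test_bad_iso_level_rejected():
    s = generate_pseudo_structure(5, seed=0)
    with pytest.raises(EmptySurfaceError):
        blobby_surface(s, 32, iso_level=1e9)


def test_benchmark_counts_and_determinism(tiny_benchmark):
    b = tiny_benchmark
    assert len(b.ids) == 18
    for level, expected in (("protein", 3), ("species", 6), ("domain", 6)):
        assert len(set(b.hierarchy.levels[level].values())) == expected
    again = generate_hierarchy_benchmark(3, 2, 3, deformation_scales=(1.0, 0.1),
                                         seed=4, grid_resolution=40, n_blobs=10)
    for mesh_id in b.ids:
        np.testing.assert_allclose(again.meshes[mesh_id].vertices,
                                   b.meshes[mesh_id].vertices, atol=1e-12)
    assert again.sequences == b.sequences


def test_no_hinge_classes_when_fraction_zero(tiny_benchmark):
    assert tiny_benchmark.hinge_classes == []


def test_dissimilarity_ordering_species_class_between(tiny_benchmark):
    """Conformer < species < class separation in mean descriptor distance."""
    from surfshape import vfh_descriptor, descriptor_distance

    b = tiny_benchmark
    descs = {i: vfh_descriptor(b.meshes[i]) for i in b.ids}
    within_species, within_class, between = [], [], []
    for i in b.ids:
        for j in b.ids:
            if j <= i:
                continue
            d = descriptor_distance(descs[i], descs[j])
            if b.hierarchy.levels["species"][i] == b.hierarchy.levels["species"][j]:
                within_species.append(d)
            elif b.hierarchy.levels["protein"][i] == b.hierarchy.levels["protein"][j]:
                within_class.append(d)
            else:
                between.append(d)
    assert np.mean(within_species) < np.mean(within_class) < np.mean(between)


def test_sequence_identity_contract(tiny_benchmark):
    b = tiny_benchmark
    H = pairwise_sequence_identity(b.sequences)
    idx = {i: k for k, i in enumerate(H.ids)}
    within, between = [], []
    for i in b.ids:
        for j in b.ids:
            if j <= i:
                continue
            v = H.values[idx[i], idx[j]]
            if b.hierarchy.levels["protein"][i] == b.hierarchy.levels["protein"][j]:
                within.append(v)
            else:
                between.append(v)
    assert np.mean(within) - np.mean(between) > 0.3


@pytest.fixture(scope="module")
def hinge_entry():
    bench = generate_hierarchy_benchmark(
        2, 2, 6, deformation_scales=(1.0, 0.1), hinge_fraction=0.5, seed=9,
        grid_resolution=40, n_blobs=12)
    cls = bench.hinge_classes[0]
    members = [i for i in bench.ids
               if bench.hierarchy.levels["species"][i] == f"{cls}.S00"]
    return bench, members


def test_hinge_conformers_preserve_volume(hinge_entry):
    bench, members = hinge_entry
    vols = [mesh_geometry(bench.meshes[i]).volume for i in members]
    assert (max(vols) - min(vols)) / np.mean(vols) < 0.10


def test_hinge_conformers_move_far(hinge_entry):
    bench, members = hinge_entry
    structs = [bench.structures[i] for i in members]
    rmsd = max(np.sqrt(((a.centers - b.centers) ** 2).sum(axis=1).mean())
               for a in structs for b in structs)
    assert rmsd > 10.0


def test_invalid_benchmark_parameters():
    with pytest.raises(ValueError):
        generate_hierarchy_benchmark(2, 2, 2, deformation_scales=(0.0, 0.1))
    with pytest.raises(ValueError):
        generate_hierarchy_benchmark(1, 2, 2)
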