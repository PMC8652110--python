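"""PDB parsing and the superposition-free lDDT score."""

import numpy as np
import pytest

from surfshape.structure import (AtomModel, PDBFormatError, lddt,
                                 parse_pdb_models)

from conftest import random_rotation


def _pdb_atom(serial, name, resname, chain, resi, x, y, z, element):
    return (f"ATOM  {serial:5d} {name:<4s}{resname:>4s}{chain}{resi:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          {element:>2s}\n")


def _toy_pdb(tmp_path, two_chains=False, n_models=2):
    lines = []
    for m in range(1, n_models + 1):
        lines.append(f"MODEL     {m:4d}\n")
        shift = 0.5 * (m - 1)
        serial = 1
        for resi in range(1, 4):
            for j, name in enumerate(("N", "CA", "C")):
                lines.append(_pdb_atom(serial, name, "ALA", "A", resi,
                                       4.0 * resi + shift, 1.0 * j, 0.0, name[0]))
                serial += 1
            lines.append(_pdb_atom(serial, "H", "ALA", "A", resi,
                                   4.0 * resi, -1.0, 0.0, "H"))
            serial += 1
        if two_chains:
            lines.append(_pdb_atom(serial, "CA", "GLY", "B", 1,
                                   20.0, 20.0, 20.0 + shift, "C"))
        lines.append("ENDMDL\n")
    lines.append("END\n")
    path = tmp_path / "toy.pdb"
    path.write_text("".join(lines))
    return path


def test_multi_model_parsing(tmp_path):
    models = parse_pdb_models(_toy_pdb(tmp_path))
    assert len(models) == 2
    assert set(models[0].atom_keys()) == set(models[1].atom_keys())
    # hydrogens dropped by default
    assert not any(n == "H" for n in models[0].atom_names)
    with_h = parse_pdb_models(_toy_pdb(tmp_path), include_hydrogens=True)
    assert any(n == "H" for n in with_h[0].atom_names)


def test_chain_filter(tmp_path):
    path = _toy_pdb(tmp_path, two_chains=True)
    models = parse_pdb_models(path, chain="A")
    assert set(models[0].chains) == {"A"}
    both = parse_pdb_models(path)
    assert set(both[0].chains) == {"A", "B"}


def test_malformed_coordinate_reports_line(tmp_path):
    good = _toy_pdb(tmp_path).read_text().splitlines(keepends=True)
    bad = good[:]
    bad[2] = bad[2][:34] + "xxxx" + bad[2][38:]
    p = tmp_path / "bad.pdb"
    p.write_text("".join(bad))
    with pytest.raises(PDBFormatError, match="line 3"):
        parse_pdb_models(p)


def test_no_atoms_rejected(tmp_path):
    p = tmp_path / "empty.pdb"
    p.write_text("HEADER    NOTHING\nEND\n")
    with pytest.raises(PDBFormatError):
        parse_pdb_models(p)


def _chain_model(xs, model_index=1):
    n = len(xs)
    return AtomModel(chains=np.array(["A"] * n),
                     res_indices=np.arange(1, n + 1),
                     res_names=np.array(["GLY"] * n),
                     atom_names=np.array(["CA"] * n),
                     coords=np.column_stack([xs, np.zeros(n), np.zeros(n)]),
                     model_index=model_index)


def test_lddt_self_is_one(tmp_path):
    models = parse_pdb_models(_toy_pdb(tmp_path))
    assert lddt(models[0], models[0]) == 1.0


def test_lddt_three_residue_hand_example():
    """Reference at 0/4/8, model at 0/4.7/8: deviations (0.7, 0.7, 0).

    f_0.5 = 1/3 and the other three fractions are 1, so the score is
    (1/3 + 3) / 4 = 5/6.
    """
    ref = _chain_model([0.0, 4.0, 8.0])
    mod = _chain_model([0.0, 4.7, 8.0])
    score, fractions = lddt(ref, mod, return_fractions=True)
    assert fractions == pytest.approx([1 / 3, 1.0, 1.0, 1.0])
    assert score == pytest.approx(0.833333333, abs=1e-9)


def test_lddt_rigid_motion_invariance(tmp_path):
    models = parse_pdb_models(_toy_pdb(tmp_path))
    ref, mod = models[0], models[1]
    base = lddt(ref, mod)
    R = random_rotation(3)
    moved = mod.transformed(R, np.array([5.0, -2.0, 9.0]))
    assert lddt(ref, moved) == pytest.approx(base, abs=1e-9)
    ref_moved = ref.transformed(random_rotation(4), np.array([1.0, 1.0, 1.0]))
    assert lddt(ref_moved, mod) == pytest.approx(base, abs=1e-9)


def test_lddt_fraction_monotonicity_and_oracle():
    rng = np.random.default_rng(0)
    n = 40
    ref_xyz = rng.uniform(0, 20, size=(n, 3))
    mod_xyz = ref_xyz + rng.normal(scale=1.0, size=(n, 3))

    def model(xyz):
        return AtomModel(chains=np.array(["A"] * n),
                         res_indices=np.arange(n),
                         res_names=np.array(["GLY"] * n),
                         atom_names=np.array(["CA"] * n),
                         coords=xyz)

    score, fr = lddt(model(ref_xyz), model(mod_xyz), return_fractions=True)
    assert fr[0] <= fr[1] <= fr[2] <= fr[3]

    # naive double-loop oracle
    tol = (0.5, 1.0, 2.0, 4.0)
    conserved = [0] * 4
    total = 0
    for i in range(n):
        for j in range(i + 1, n):
            dref = np.linalg.norm(ref_xyz[i] - ref_xyz[j])
            if dref <= 15.0:
                total += 1
                dev = abs(np.linalg.norm(mod_xyz[i] - mod_xyz[j]) - dref)
                for t in range(4):
                    conserved[t] += dev <= tol[t]
    expected = sum(c / total for c in conserved) / 4
    assert score == pytest.approx(expected, abs=1e-12)


def test_lddt_only_shared_atoms_scored():
    ref = _chain_model([0.0, 4.0, 8.0, 12.0])
    mod = _chain_model([0.0, 4.0, 8.0])
    assert lddt(ref, mod) == 1.0


def test_lddt_asymmetric_in_arguments():
    # reference defines the pair set: a compressed model changes it
    ref = _chain_model([0.0, 7.0, 14.0, 30.0])
    mod = _chain_model([0.0, 7.0, 16.0, 23.0])
    assert lddt(ref, mod) != lddt(mod, ref)


def test_lddt_empty_pair_set_rejected():
    ref = _chain_model([0.0, 100.0])
    mod = _chain_model([0.0, 100.0])
    with pytest.raises(ValueError):
        lddt(ref, mod)
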