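"""Multi-model PDB parsing and the lDDT structure-comparison score.

lDDT (local Distance Difference Test) is superposition-free: it scores a
model against a reference by the fraction of reference interatomic
distances (atom pairs from different residues, within an inclusion
radius of 15 A in the reference) that the model conserves within
tolerances of 0.5, 1, 2 and 4 A, averaged over the four tolerances.
Because only distances enter, the score is invariant to rigid motion of
either structure and is asymmetric in (reference, model) by
construction.  It is the natural reference for conformer retrieval: two
conformers of one protein keep most short-range distances even under
large hinge motions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

__all__ = ["AtomModel", "parse_pdb_models", "lddt", "PDBFormatError"]


class PDBFormatError(ValueError):
    """The coordinate file violates the PDB contract."""


@dataclass
class AtomModel:
    """Atom records of one conformer: parallel arrays plus the model index."""

    chains: np.ndarray      # str
    res_indices: np.ndarray  # int
    res_names: np.ndarray   # str
    atom_names: np.ndarray  # str
    coords: np.ndarray      # (n, 3) float A
    model_index: int = 1

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if not np.all(np.isfinite(self.coords)):
            raise PDBFormatError("non-finite coordinates")
        keys = self.atom_keys()
        if len(set(keys)) != len(keys):
            raise PDBFormatError("duplicate (chain, residue, atom) key in model")

    def atom_keys(self) -> list[tuple[str, int, str]]:
        return list(zip(self.chains.tolist(), self.res_indices.tolist(),
                        self.atom_names.tolist()))

    @property
    def n_atoms(self) -> int:
        return len(self.coords)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray
                    ) -> "AtomModel":
        return AtomModel(self.chains, self.res_indices, self.res_names,
                         self.atom_names,
                         self.coords @ np.asarray(rotation).T + translation,
                         self.model_index)


def _validate_coordinate_fields(path) -> None:
    with open(path, "r", errors="replace") as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(("ATOM  ", "HETATM")) and len(line) >= 54:
                for lo, hi in ((30, 38), (38, 46), (46, 54)):
                    try:
                        float(line[lo:hi])
                    except ValueError:
                        raise PDBFormatError(
                            f"malformed coordinate field at line {lineno}: "
                            f"{line.rstrip()!r}") from None


def parse_pdb_models(path, chain: str | None = None,
                     include_hydrogens: bool = False) -> list[AtomModel]:
    """Parse a (possibly multi-model) PDB file into one AtomModel per MODEL.

    Hydrogens (and deuterium) are dropped unless ``include_hydrogens``;
    alternate-location records other than '' or 'A' are dropped; a chain
    filter keeps only that chain.  Files with no ATOM records raise
    :class:`PDBFormatError`.
    """
    import gemmi

    _validate_coordinate_fields(path)
    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:
        raise PDBFormatError(f"cannot parse PDB file {path}: {exc}") from exc

    models: list[AtomModel] = []
    for model in st:
        chains, resi, resn, atn, xyz = [], [], [], [], []
        for ch in model:
            if chain is not None and ch.name != chain:
                continue
            for res in ch:
                for atom in res:
                    if atom.altloc not in ("", "\0", "A"):
                        continue
                    if not include_hydrogens and atom.element.is_hydrogen:
                        continue
                    chains.append(ch.name)
                    resi.append(res.seqid.num)
                    resn.append(res.name)
                    atn.append(atom.name)
                    xyz.append([atom.pos.x, atom.pos.y, atom.pos.z])
        if xyz:
            num = int(model.num)
            models.append(AtomModel(
                chains=np.asarray(chains), res_indices=np.asarray(resi),
                res_names=np.asarray(resn), atom_names=np.asarray(atn),
                coords=np.asarray(xyz), model_index=num))
    if not models:
        raise PDBFormatError(f"no ATOM records in {path}"
                             + (f" for chain {chain!r}" if chain else ""))
    return models


def lddt(reference: AtomModel, model: AtomModel,
         inclusion_radius: float = 15.0,
         tolerances: tuple[float, ...] = (0.5, 1.0, 2.0, 4.0),
         return_fractions: bool = False):
    """lDDT of ``model`` against ``reference`` on their shared atoms.

    Only atoms present (by chain, residue index and atom name) in both
    structures are scored.  The reference pair set collects atom pairs
    from different residues within ``inclusion_radius``; the score is the
    mean over ``tolerances`` of the fraction of pairs whose model
    distance deviates by at most that tolerance.
    """
    ref_keys = {k: i for i, k in enumerate(reference.atom_keys())}
    mod_keys = {k: i for i, k in enumerate(model.atom_keys())}
    shared = [k for k in reference.atom_keys() if k in mod_keys]
    if not shared:
        raise ValueError("no shared atoms between reference and model")
    ref_idx = np.asarray([ref_keys[k] for k in shared])
    mod_idx = np.asarray([mod_keys[k] for k in shared])
    ref_xyz = reference.coords[ref_idx]
    mod_xyz = model.coords[mod_idx]
    residue = np.asarray([(k[0], k[1]) for k in shared], dtype=object)

    tree = cKDTree(ref_xyz)
    pairs = tree.query_pairs(r=inclusion_radius, output_type="ndarray")
    if len(pairs):
        same_res = np.array([tuple(residue[a]) == tuple(residue[b])
                             for a, b in pairs])
        pairs = pairs[~same_res]
    if len(pairs) == 0:
        raise ValueError("empty reference pair set; nothing to score")
    d_ref = np.linalg.norm(ref_xyz[pairs[:, 0]] - ref_xyz[pairs[:, 1]], axis=1)
    d_mod = np.linalg.norm(mod_xyz[pairs[:, 0]] - mod_xyz[pairs[:, 1]], axis=1)
    dev = np.abs(d_mod - d_ref)
    fractions = [float((dev <= t).mean()) for t in tolerances]
    score = float(np.mean(fractions))
    if return_fractions:
        return score, fractions
    return score
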