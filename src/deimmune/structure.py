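"""Backbone structure container and PDB round-trip.

A :class:`BackboneStructure` holds, per residue, the four backbone atom
coordinates (N, CA, C, O, in Å) that condition fixed-backbone sequence
design, plus optional chain ids, residue numbers, and the template ("native")
sequence.  Reading and writing goes through biotite's PDB support; only the
first model and first altloc are used, and residues missing any of the four
backbone atoms are dropped.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import biotite.structure as struc
from biotite.sequence import ProteinSequence
from biotite.structure.io.pdb import PDBFile

__all__ = ["BACKBONE_ATOMS", "BackboneStructure"]

#: Backbone atom names in storage order.
BACKBONE_ATOMS: tuple[str, ...] = ("N", "CA", "C", "O")


@dataclass
class BackboneStructure:
    """Per-residue backbone coordinates: the conditioning prompt for design.

    Attributes
    ----------
    coords
        Array of shape ``(n_residues, 4, 3)`` in N/CA/C/O order, Å.
    chain_ids
        Per-residue chain identifier (default: single chain ``"A"``).
    residue_indices
        Per-residue author numbering, strictly increasing within a chain.
    sequence
        Optional native amino-acid sequence of the template.
    """

    coords: np.ndarray
    chain_ids: np.ndarray | None = None
    residue_indices: np.ndarray | None = None
    sequence: str | None = None
    name: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[1:] != (4, 3):
            raise ValueError("coords must have shape (n_residues, 4, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("backbone coordinates must be finite")
        n = len(self.coords)
        if self.chain_ids is None:
            self.chain_ids = np.full(n, "A", dtype="U4")
        else:
            self.chain_ids = np.asarray(self.chain_ids, dtype="U4")
        if self.residue_indices is None:
            self.residue_indices = np.arange(1, n + 1, dtype=np.int64)
        else:
            self.residue_indices = np.asarray(self.residue_indices, dtype=np.int64)
        if len(self.chain_ids) != n or len(self.residue_indices) != n:
            raise ValueError("per-residue annotations must match coords length")
        for chain in np.unique(self.chain_ids):
            idx = self.residue_indices[self.chain_ids == chain]
            if np.any(np.diff(idx) <= 0):
                raise ValueError(
                    f"residue indices must be strictly increasing within chain {chain}"
                )
        if self.sequence is not None and len(self.sequence) != n:
            raise ValueError("sequence length must match the number of residues")

    def __len__(self) -> int:
        return len(self.coords)

    @property
    def ca(self) -> np.ndarray:
        """CA coordinates, shape ``(n_residues, 3)``."""
        return self.coords[:, 1, :]

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "BackboneStructure":
        """Return a rigidly moved copy (coords @ R.T + t)."""
        moved = self.coords @ np.asarray(rotation, float).T + np.asarray(translation, float)
        return BackboneStructure(
            coords=moved,
            chain_ids=self.chain_ids.copy(),
            residue_indices=self.residue_indices.copy(),
            sequence=self.sequence,
            name=self.name,
        )

    # ------------------------------------------------------------------- io
    @classmethod
    def from_pdb(cls, path: str | Path, model: int = 1) -> "BackboneStructure":
        """Read backbone atoms from a PDB file (first model, first altloc)."""
        pdb = PDBFile.read(str(path))
        array = pdb.get_structure(model=model, altloc="first")
        array = array[struc.filter_amino_acids(array)]
        coords, chains, res_ids, letters = [], [], [], []
        for res in struc.residue_iter(array):
            atom_map = {}
            for atom in res:
                if atom.atom_name in BACKBONE_ATOMS and atom.atom_name not in atom_map:
                    atom_map[atom.atom_name] = atom.coord
            if any(a not in atom_map for a in BACKBONE_ATOMS):
                continue  # incomplete backbone: skip residue
            coords.append([atom_map[a] for a in BACKBONE_ATOMS])
            chains.append(res.chain_id[0])
            res_ids.append(int(res.res_id[0]))
            try:
                letters.append(ProteinSequence.convert_letter_3to1(res.res_name[0]))
            except Exception:
                letters.append("X")
        if not coords:
            raise ValueError(f"no complete backbone residues found in {path}")
        return cls(
            coords=np.array(coords, dtype=float),
            chain_ids=np.array(chains, dtype="U4"),
            residue_indices=np.array(res_ids, dtype=np.int64),
            sequence="".join(letters),
            name=Path(path).stem,
        )

    def to_pdb(self, path: str | Path, sequence: str | None = None) -> None:
        """Write the backbone as a PDB file.

        *sequence* overrides the stored native sequence for residue naming
        (useful for writing designed sequences onto the template backbone);
        unknown letters are written as UNK glycine-less placeholders.
        """
        seq = sequence if sequence is not None else self.sequence
        n = len(self)
        array = struc.AtomArray(n * 4)
        elements = {"N": "N", "CA": "C", "C": "C", "O": "O"}
        k = 0
        for i in range(n):
            if seq is not None and seq[i] != "X":
                res_name = ProteinSequence.convert_letter_1to3(seq[i])
            else:
                res_name = "UNK"
            for a_i, atom_name in enumerate(BACKBONE_ATOMS):
                array.coord[k] = self.coords[i, a_i]
                array.chain_id[k] = self.chain_ids[i]
                array.res_id[k] = self.residue_indices[i]
                array.res_name[k] = res_name
                array.atom_name[k] = atom_name
                array.element[k] = elements[atom_name]
                array.hetero[k] = False
                k += 1
        pdb = PDBFile()
        pdb.set_structure(array)
        pdb.write(str(path))
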