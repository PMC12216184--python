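"""PDB structure input/output.

A :class:`CoordinateModel` is the light in-memory carrier used by the
restraint and annealing machinery: parallel arrays of chain id, residue
index, residue name, atom name and Cartesian coordinates (Å).  Parsing and
serialisation go through biotite, which handles the fixed-column PDB layout
and MODEL/ENDMDL blocks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile


class EmptyStructureError(ValueError):
    """A PDB file contained no ATOM records."""


@dataclass
class CoordinateModel:
    """One structural model: parallel per-atom arrays plus a model id."""

    chain_id: np.ndarray      # (n,) str
    residue_index: np.ndarray  # (n,) int
    residue_name: np.ndarray  # (n,) str, 3-letter
    atom_name: np.ndarray     # (n,) str
    coords: np.ndarray        # (n, 3) float, Å
    model_id: int = 0

    def __post_init__(self):
        self.chain_id = np.asarray(self.chain_id, dtype="U4")
        self.residue_index = np.asarray(self.residue_index, dtype=int)
        self.residue_name = np.asarray(self.residue_name, dtype="U4")
        self.atom_name = np.asarray(self.atom_name, dtype="U5")
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (len(self.chain_id), 3):
            raise ValueError("coords must be (n_atoms, 3)")
        if not np.isfinite(self.coords).all():
            raise ValueError("non-finite coordinates")
        keys = list(zip(self.chain_id, self.residue_index, self.atom_name))
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (chain, residue, atom) keys")

    def __len__(self) -> int:
        return len(self.chain_id)

    def copy(self) -> "CoordinateModel":
        return CoordinateModel(
            self.chain_id.copy(), self.residue_index.copy(),
            self.residue_name.copy(), self.atom_name.copy(),
            self.coords.copy(), self.model_id,
        )

    def atom_index(self, chain: str, residue: int, atom: str) -> int:
        """Index of one atom; raises KeyError if absent or ambiguous."""
        mask = (
            (self.chain_id == chain)
            & (self.residue_index == residue)
            & (self.atom_name == atom)
        )
        idx = np.flatnonzero(mask)
        if len(idx) != 1:
            raise KeyError(f"atom {chain}/{residue}/{atom} not found")
        return int(idx[0])

    def select(self, chain: str | None = None, atom_names: Sequence[str] | None = None,
               residues: Sequence[int] | None = None) -> np.ndarray:
        """Boolean mask over atoms."""
        mask = np.ones(len(self), dtype=bool)
        if chain is not None:
            mask &= self.chain_id == chain
        if atom_names is not None:
            mask &= np.isin(self.atom_name, list(atom_names))
        if residues is not None:
            mask &= np.isin(self.residue_index, list(residues))
        return mask

    def to_atom_array(self) -> struc.AtomArray:
        arr = struc.AtomArray(len(self))
        arr.chain_id = self.chain_id
        arr.res_id = self.residue_index
        arr.res_name = self.residue_name
        arr.atom_name = self.atom_name
        arr.element = np.array([n[:1] for n in self.atom_name], dtype="U2")
        arr.coord = self.coords
        return arr


def _from_atom_array(arr: struc.AtomArray, model_id: int = 0) -> CoordinateModel:
    return CoordinateModel(
        chain_id=np.asarray(arr.chain_id),
        residue_index=np.asarray(arr.res_id),
        residue_name=np.asarray(arr.res_name),
        atom_name=np.asarray(arr.atom_name),
        coords=np.asarray(arr.coord, dtype=float),
        model_id=model_id,
    )


def read_pdb(path: str | Path) -> list[CoordinateModel]:
    """Read a PDB file; returns one CoordinateModel per MODEL block.

    Single-structure files yield a one-element list.
    """
    pdb = PDBFile.read(str(path))
    n_models = pdb.get_model_count()
    if n_models == 0:
        raise EmptyStructureError(f"{path}: no ATOM records")
    models = []
    for m in range(1, n_models + 1):
        arr = pdb.get_structure(model=m)
        if arr.array_length() == 0:
            raise EmptyStructureError(f"{path}: empty MODEL {m}")
        models.append(_from_atom_array(arr, model_id=m - 1))
    return models


def write_pdb(models: CoordinateModel | Sequence[CoordinateModel],
              path: str | Path) -> None:
    """Write one or several models; several become MODEL/ENDMDL blocks."""
    if isinstance(models, CoordinateModel):
        models = [models]
    if len(models) == 0:
        raise ValueError("nothing to write")
    pdb = PDBFile()
    if len(models) == 1:
        pdb.set_structure(models[0].to_atom_array())
    else:
        stack = struc.stack([m.to_atom_array() for m in models])
        pdb.set_structure(stack)
    pdb.write(str(path))
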