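"""PDB and FASTA I/O for the reduced backbone representation."""

from __future__ import annotations

import warnings
from typing import Optional, Tuple

import numpy as np
from Bio import SeqIO
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from .chain import (BACKBONE_ATOMS, Conformation, CoordinateSet, ONE_LETTER,
                    Sequence, THREE_LETTER)


def read_fasta(path) -> Sequence:
    """First record of a FASTA file; extra records trigger a warning."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: no FASTA records")
    if len(records) > 1:
        warnings.warn(
            f"{path}: {len(records)} FASTA records, using the first "
            f"({records[0].id})", stacklevel=2,
        )
    return Sequence(str(records[0].seq).upper())


def _to_atom_array(coords: CoordinateSet, sequence: Optional[Sequence]) -> struc.AtomArray:
    atoms = list(coords.iter_atoms())
    arr = struc.AtomArray(len(atoms))
    for k, (res_idx, name, pos) in enumerate(atoms):
        arr.coord[k] = pos
        arr.chain_id[k] = "A"
        arr.res_id[k] = res_idx + 1
        code = sequence.residues[res_idx] if sequence is not None else "A"
        arr.res_name[k] = THREE_LETTER[code]
        # centroid pseudo-atoms are written as CB so standard tools read them
        arr.atom_name[k] = "CB" if name == "CEN" else name
        arr.element[k] = arr.atom_name[k][0]
        arr.hetero[k] = False
    return arr


def write_pdb(path, conf_or_coords, sequence: Optional[Sequence] = None) -> None:
    """Write backbone + CB/centroid ATOM records (chain A, 1-based residues)."""
    if isinstance(conf_or_coords, Conformation):
        coords = conf_or_coords.coords
        sequence = conf_or_coords.sequence
    else:
        coords = conf_or_coords
    pdb = PDBFile()
    pdb.set_structure(_to_atom_array(coords, sequence))
    pdb.write(str(path))


def read_pdb_backbone(path) -> Tuple[Optional[Sequence], CoordinateSet]:
    """Read backbone N, CA, C, O (+CB) coordinates from a PDB file.

    Missing atoms — e.g. no O on the final residue — are tolerated and
    stored as NaN; lRMSD computations mask them out.  Returns the one-letter
    sequence when all residue names are standard, else None.
    """
    pdb = PDBFile.read(str(path))
    arr = pdb.get_structure(model=1)
    arr = arr[~arr.hetero]
    res_ids = np.unique(arr.res_id)
    L = len(res_ids)
    if L < 3:
        raise ValueError(f"{path}: fewer than 3 residues")
    backbone = np.full((L, 4, 3), np.nan)
    side = np.full((L, 3), np.nan)
    letters = []
    id_to_row = {rid: i for i, rid in enumerate(sorted(res_ids))}
    for k in range(arr.array_length()):
        i = id_to_row[arr.res_id[k]]
        name = arr.atom_name[k]
        if name in BACKBONE_ATOMS:
            backbone[i, BACKBONE_ATOMS.index(name)] = arr.coord[k]
        elif name == "CB":
            side[i] = arr.coord[k]
    for rid in sorted(res_ids):
        sel = arr.res_name[arr.res_id == rid]
        letters.append(ONE_LETTER.get(sel[0], None))
    seq = Sequence("".join(letters)) if all(x is not None for x in letters) else None
    core = backbone[:, :3]  # N, CA, C must be present everywhere
    if not np.isfinite(core).all():
        missing = np.flatnonzero(~np.isfinite(core).all(axis=(1, 2))) + 1
        raise ValueError(f"{path}: missing N/CA/C atoms at residues {missing.tolist()}")
    return seq, CoordinateSet(backbone=backbone, side=side, mode="cb")
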