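"""Per-residue coordinate models extracted from PDB files.

A protein chain is reduced to one representative point per residue — the
C-alpha atom, or the centroid of heavy atoms when C-alpha is absent. These
points are the sampling universe of the 3D permutation test: every residue
with a coordinate is an equally likely position for a random mutation under
the null hypothesis of spatially uniform mutation placement.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import gemmi
import numpy as np

__all__ = ["ResiduePoint", "ProteinStructure", "read_structure", "chain_sequence"]

#: 3-letter -> 1-letter codes for the 20 standard amino acids plus the
#: selenomethionine convention (MSE -> M). Anything else becomes 'X'.
_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    "MSE": "M",
}


@dataclass(frozen=True)
class ResiduePoint:
    """One residue reduced to a representative coordinate.

    Attributes
    ----------
    chain_id : str
        PDB chain identifier.
    residue_seq_index : int
        0-based ordinal of the residue within the chain (file order).
    residue_label : str
        PDB residue number plus insertion code, e.g. ``"100"`` or ``"100A"``.
    amino_acid : str
        1-letter code; one of the 20 standard codes or ``'X'``.
    coord : tuple of float, optional
        ``(x, y, z)`` in Angstroms, or ``None`` when no atoms carry
        coordinates for this residue.
    has_coord : bool
        ``False`` means the residue is excluded from distance computation
        and from null sampling, but still contributes to the chain sequence.
    """

    chain_id: str
    residue_seq_index: int
    residue_label: str
    amino_acid: str
    coord: Optional[tuple[float, float, float]]
    has_coord: bool

    def __post_init__(self):
        if self.has_coord != (self.coord is not None):
            raise ValueError("has_coord flag inconsistent with coord")


@dataclass
class ProteinStructure:
    """An ordered list of residue points for one chain.

    ``structure_id`` follows the ``PDBID_CHAIN`` convention used in all
    outputs of the pipeline.
    """

    structure_id: str
    residues: list[ResiduePoint] = field(default_factory=list)

    @property
    def sequence(self) -> str:
        return "".join(r.amino_acid for r in self.residues)

    def __len__(self) -> int:
        return len(self.residues)

    def coordinates(self) -> np.ndarray:
        """(k, 3) array of coordinates for residues that have one."""
        return np.array(
            [r.coord for r in self.residues if r.has_coord], dtype=float
        ).reshape(-1, 3)

    def coordinate_indices(self) -> np.ndarray:
        """Residue indices (0-based) of the residues with coordinates."""
        return np.array(
            [r.residue_seq_index for r in self.residues if r.has_coord], dtype=int
        )

    def coord_of(self, residue_seq_index: int) -> np.ndarray:
        res = self.residues[residue_seq_index]
        if not res.has_coord:
            raise ValueError(f"residue {residue_seq_index} has no coordinates")
        return np.asarray(res.coord, dtype=float)


def _pick_altloc(atoms: Sequence[gemmi.Atom]) -> gemmi.Atom:
    """Highest occupancy wins; ties broken by file order."""
    best = atoms[0]
    for a in atoms[1:]:
        if a.occ > best.occ:
            best = a
    return best


def _representative_coord(res: gemmi.Residue) -> Optional[tuple[float, float, float]]:
    """C-alpha coordinate, else centroid of heavy atoms, else None."""
    ca = [a for a in res if a.name == "CA" and a.element.name != "H"]
    if ca:
        p = _pick_altloc(ca).pos
        return (p.x, p.y, p.z)
    heavy: dict[str, list[gemmi.Atom]] = {}
    for a in res:
        if a.is_hydrogen():
            continue
        heavy.setdefault(a.name, []).append(a)
    if not heavy:
        return None
    pts = np.array(
        [[p.x, p.y, p.z] for p in (_pick_altloc(v).pos for v in heavy.values())]
    )
    return tuple(pts.mean(axis=0))


def _is_amino_acid(res: gemmi.Residue) -> bool:
    if res.name in _THREE_TO_ONE:
        return True
    info = gemmi.find_tabulated_residue(res.name)
    return info is not None and info.is_amino_acid()


def read_structure(
    pdb_source: Union[str, Path, io.TextIOBase], chain_id: str,
    structure_id: Optional[str] = None,
) -> ProteinStructure:
    """Parse one chain of a PDB file into a :class:`ProteinStructure`.

    Conventions (the source format does not force them, so they are fixed
    here for reproducibility): only the first model of a multi-model entry
    is read; alternate locations are resolved by highest occupancy with
    ties going to the first atom seen; waters and non-amino-acid HETATM
    records are ignored; amino-acid HETATM residues such as MSE stay in the
    chain (MSE maps to ``M``, other nonstandard residues to ``'X'``).

    Parameters
    ----------
    pdb_source
        Path to a PDB file, PDB-format text, or an open text stream.
    chain_id
        Chain to extract.
    structure_id
        Identifier for outputs; defaults to ``"<pdb-name>_<chain>"``.

    Raises
    ------
    ValueError
        If the chain is missing or no residue carries coordinates.
    """
    if isinstance(pdb_source, io.TextIOBase):
        text = pdb_source.read()
        name = "structure"
    else:
        p = Path(str(pdb_source))
        looks_like_path = "\n" not in str(pdb_source) and p.is_file()
        if looks_like_path:
            text = p.read_text()
            name = p.stem
        else:
            text = str(pdb_source)
            name = "structure"

    st = gemmi.read_pdb_string(text)
    st.setup_entities()
    if len(st) == 0:
        raise ValueError("empty structure: no models in input")
    model = st[0]  # first model only (NMR ensembles)

    chain = None
    for ch in model:
        if ch.name == chain_id:
            chain = ch
            break
    if chain is None:
        raise ValueError(f"chain not found: {chain_id!r}")

    if structure_id is None:
        sid = st.name.strip() or name
        structure_id = f"{sid}_{chain_id}"

    residues: list[ResiduePoint] = []
    for res in chain:
        if res.is_water() or not _is_amino_acid(res):
            continue
        aa = _THREE_TO_ONE.get(res.name, "X")
        # 'X' residues stay in the sequence but are barred from distance
        # computation and null sampling, so no coordinate is kept for them.
        coord = _representative_coord(res) if aa != "X" else None
        label = f"{res.seqid.num}{res.seqid.icode}".strip()
        residues.append(
            ResiduePoint(
                chain_id=chain_id,
                residue_seq_index=len(residues),
                residue_label=label,
                amino_acid=aa,
                coord=coord,
                has_coord=coord is not None,
            )
        )

    if not any(r.has_coord for r in residues):
        raise ValueError(f"empty structure: chain {chain_id!r} has no coordinates")
    return ProteinStructure(structure_id=structure_id, residues=residues)


def chain_sequence(structure: ProteinStructure) -> str:
    """1-letter sequence of the chain, in file order.

    Residues without coordinates are included: the sequence is what gets
    aligned to the reference protein, and alignment uses the full chain.
    """
    if len(structure) == 0:
        raise ValueError("empty structure")
    return structure.sequence
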