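"""Sequence alignment between structure chains and reference proteins.

Structure chains rarely cover a full coding sequence and are not always
human in origin, so mutation codon positions cannot be used as residue
indices directly. Each chain sequence is globally aligned to the reference
protein, the alignment is quality-controlled (gap fraction and structure
coverage), and mutation codons are transferred through the aligned pairs.

Only two sequences are ever compared, so pairwise global alignment
(Needleman–Wunsch with BLOSUM62, affine gaps: open 10, extend 1) is used.
For the dominant case — a chain that is a near-exact fragment of the
reference — this is equivalent to running a multiple aligner on the pair,
and it is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

from Bio import Align
from Bio.Align import substitution_matrices

from .maf import MutationRecord
from .structures import ProteinStructure

__all__ = [
    "StructureAlignment",
    "AlignmentQC",
    "MappedMutationSet",
    "align_global",
    "alignment_qc",
    "map_mutations",
]


@dataclass
class StructureAlignment:
    """A global pairwise alignment of reference protein vs chain sequence.

    ``aligned_pairs`` holds (ref_pos 1-based, struct_residue_index 0-based)
    for every aligned column, mismatches included; both coordinates are
    strictly increasing.
    """

    gene: str
    structure_id: str
    aligned_pairs: list[tuple[int, int]]
    alignment_length: int
    gap_count: int
    aligned_struct_residues: int
    struct_length: int
    ref_length: int = 0
    score: float = 0.0


@dataclass
class AlignmentQC:
    passed: bool
    gap_ratio: float
    coverage: float
    reason: str = ""


@dataclass
class MappedMutationSet:
    """A gene's missense mutations placed on a structure and on the CDS.

    ``struct_positions`` is a multiset (list) of 0-based residue indices,
    one entry per mutation record, so a codon hit k times contributes k
    entries. ``cds_positions`` carries the codon index of every missense
    record within the reference length, independent of structural
    coverage — this is the input to the 1D test over the whole coding
    region.
    """

    gene: str
    structure_id: str
    struct_positions: list[int] = field(default_factory=list)
    cds_positions: list[int] = field(default_factory=list)
    n_unmapped: int = 0

    @property
    def n_mapped(self) -> int:
        return len(self.struct_positions)


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -1.0
    return aligner


def align_global(
    ref_seq: str, struct_seq: str, gene: str = "", structure_id: str = ""
) -> StructureAlignment:
    """Needleman–Wunsch global alignment of reference vs chain sequence.

    Ties among optimal alignments are broken deterministically by taking
    the aligner's first reported optimum.
    """
    if not ref_seq or not struct_seq:
        raise ValueError("both sequences must be non-empty")
    aln = _make_aligner().align(ref_seq, struct_seq)[0]

    pairs: list[tuple[int, int]] = []
    for (rs, re_), (ss, se) in zip(*aln.aligned):
        pairs.extend((r + 1, s) for r, s in zip(range(rs, re_), range(ss, se)))

    length = aln.length
    n_aligned = len(pairs)
    return StructureAlignment(
        gene=gene,
        structure_id=structure_id,
        aligned_pairs=pairs,
        alignment_length=length,
        gap_count=length - n_aligned,
        aligned_struct_residues=n_aligned,
        struct_length=len(struct_seq),
        ref_length=len(ref_seq),
        score=float(aln.score),
    )


def alignment_qc(
    a: StructureAlignment,
    max_gap_ratio: float = 0.5,
    min_coverage: float = 0.5,
) -> AlignmentQC:
    """Gap-fraction and coverage QC for a structure alignment.

    Pass requires gap_count / alignment_length strictly below
    ``max_gap_ratio`` AND aligned structure residues / chain length at
    least ``min_coverage`` (inclusive). The strict/inclusive boundaries
    are deliberate and tested.
    """
    if a.alignment_length == 0:
        return AlignmentQC(False, 1.0, 0.0, reason="empty alignment")
    gap_ratio = a.gap_count / a.alignment_length
    coverage = a.aligned_struct_residues / a.struct_length if a.struct_length else 0.0
    if not gap_ratio < max_gap_ratio:
        return AlignmentQC(False, gap_ratio, coverage, reason="gap ratio too high")
    if not coverage >= min_coverage:
        return AlignmentQC(False, gap_ratio, coverage, reason="coverage too low")
    return AlignmentQC(True, gap_ratio, coverage)


def map_mutations(
    a: StructureAlignment,
    records: Iterable[MutationRecord],
    structure: ProteinStructure,
) -> MappedMutationSet:
    """Transfer mutation codon positions onto structure residue indices.

    A record maps when its codon is an aligned (non-gap) column AND the
    target residue carries a coordinate; otherwise it counts as unmapped.
    Records whose codon falls outside the reference protein are ignored
    entirely (they cannot enter the 1D universe either). Multiplicity is
    preserved: recurrent codons yield repeated indices.
    """
    ref_to_struct = dict(a.aligned_pairs)
    out = MappedMutationSet(gene=a.gene, structure_id=a.structure_id)
    for r in records:
        pos = r.protein_pos
        if pos is None or pos < 1 or (a.ref_length and pos > a.ref_length):
            continue
        out.cds_positions.append(pos)
        idx = ref_to_struct.get(pos)
        if idx is not None and structure.residues[idx].has_coord:
            out.struct_positions.append(idx)
        else:
            out.n_unmapped += 1
    return out
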