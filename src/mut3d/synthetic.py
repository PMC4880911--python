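"""Synthetic cohorts with known ground truth.

Everything the analysis pipeline consumes — PDB structures, reference
protein FASTA, MAF-style mutation tables, germline blacklists, gene
annotations — can be generated at toy scale with planted signal, so the
whole pipeline is testable end to end without any external download.

Structure geometries:

- ``ideal_helix``: canonical alpha-helix C-alpha trace (rise 1.5 A,
  100 degrees per residue, helix radius 2.3 A), giving the textbook
  ~3.8 A consecutive C-alpha spacing.
- ``random_coil``: fixed 3.8 A bond-length random walk that rejects steps
  landing within 3.0 A of any previous residue (self-avoiding-ish).
- ``lattice``: residues on an integer grid, unit spacing — handy for
  exact enumeration oracles.
- ``helix_hairpin``: two antiparallel helices side by side, so residues
  far apart in sequence sit close in space; the geometry that separates
  the 3D test from its 1D control.

Per-gene mutation models: ``uniform`` (null), ``clustered`` (k codons
whose residues lie inside a sphere of the stated radius, the driver-like
signal), ``hotspot`` (one codon hit k times).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .structures import ProteinStructure, ResiduePoint

__all__ = [
    "GeneMutationModel",
    "SyntheticScenario",
    "CohortPaths",
    "make_structure",
    "structure_to_pdb",
    "plant_mutations",
    "make_cohort",
]

_AA20 = "ACDEFGHIKLMNPQRSTVWY"
_AA_1TO3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}
_BASES = "ACGT"

MAF_HEADER = [
    "Hugo_Symbol", "Tumor_Sample_Barcode", "Chromosome", "Start_Position",
    "Reference_Allele", "Tumor_Seq_Allele2", "Variant_Classification",
    "Protein_Change", "Cancer_Type",
]


@dataclass(frozen=True)
class GeneMutationModel:
    """How mutations are planted on one gene.

    kind: ``uniform`` | ``clustered`` | ``hotspot``.
    n_mutations: total rows drawn for uniform; for clustered it is the
    cluster size k plus ``background`` uniform rows; for hotspot the
    recurrence count k.
    """

    kind: str
    n_mutations: int
    radius: float = 6.0
    center: Optional[int] = None  # residue index; random when None
    codon: Optional[int] = None  # hotspot codon (1-based ref position)
    background: int = 0

    def __post_init__(self):
        if self.kind not in ("uniform", "clustered", "hotspot"):
            raise ValueError(f"unknown model kind: {self.kind!r}")
        if self.kind in ("clustered", "hotspot") and self.n_mutations < 2:
            raise ValueError("clustered/hotspot models need k >= 2")
        if self.kind == "clustered" and self.radius <= 0:
            raise ValueError("cluster radius must be positive")


@dataclass
class SyntheticScenario:
    """Parameters of a generated cohort.

    Defaults describe the standard benchmark: 1,000 genes on 200-residue
    random coils, 10% driver-like genes carrying a 6-mutation cluster
    inside a 6 A sphere, null genes carrying 6 uniformly placed mutations,
    100 tumor samples. ``flank`` residues of extra reference sequence on
    each side of the chain make the structure a proper substring of the
    reference protein; ``hard_alignment`` degrades half the genes with a
    wrong-isoform (unrelated, 3x-length) reference and the rest with
    chain mismatches, to exercise alignment QC failure paths.
    """

    n_genes: int = 1000
    driver_fraction: float = 0.1
    n_residues: int = 200
    geometry: str = "random_coil"
    n_samples: int = 100
    cluster_k: int = 6
    cluster_radius: float = 6.0
    null_mutations: int = 6
    flank: int = 10
    seed: int = 0
    cancer_type: str = "SYN"
    n_germline: int = 5
    n_silent: int = 10
    n_duplicates: int = 5
    hard_alignment: bool = False
    mismatch_rate: float = 0.3  # only used when hard_alignment


@dataclass
class CohortPaths:
    root: Path
    maf: Path
    pdb_dir: Path
    fasta: Path
    structure_map: Path
    blacklist: Path
    annotations: Path
    truth: Path


def _helix(n: int, radius: float = 2.3, rise: float = 1.5,
           twist_deg: float = 100.0, x0: float = 0.0, reverse: bool = False,
           phase_deg: float = 0.0) -> np.ndarray:
    i = np.arange(n)
    theta = np.deg2rad(twist_deg * i + phase_deg)
    z = rise * i
    if reverse:
        z = z[::-1]
    return np.column_stack([x0 + radius * np.cos(theta),
                            radius * np.sin(theta), z])


def _random_coil(n: int, rng: np.random.Generator, bond: float = 3.8,
                 clash: float = 3.0, max_tries: int = 50) -> np.ndarray:
    pts = np.zeros((n, 3))
    for i in range(1, n):
        for _ in range(max_tries):
            v = rng.normal(size=3)
            step = v / np.linalg.norm(v) * bond
            cand = pts[i - 1] + step
            d = np.linalg.norm(pts[:i] - cand, axis=1)
            if d.min() >= clash:
                break
        pts[i] = cand
    return pts


def _lattice(n: int) -> np.ndarray:
    side = math.ceil(n ** (1 / 3) - 1e-9)
    grid = [(x, y, z) for x in range(side) for y in range(side) for z in range(side)]
    while len(grid) < n:  # n between cubes: extend one layer
        side += 1
        grid = [(x, y, z) for x in range(side) for y in range(side) for z in range(side)]
    return np.array(grid[:n], dtype=float)


def _helix_hairpin(n: int, separation: float = 5.4) -> np.ndarray:
    """Two antiparallel helices joined end to end.

    Residue i of the first arm and residue (n - 1 - i) of the second lie
    at similar height on axes ``separation`` Angstroms apart: spatial
    neighbours, sequence strangers.
    """
    half = n // 2
    arm1 = _helix(half)
    arm2 = _helix(n - half, x0=separation, phase_deg=180.0, reverse=True)
    return np.vstack([arm1, arm2])


def make_structure(
    geometry: str,
    n_residues: int,
    seed: int = 0,
    structure_id: str = "SYN0001_A",
    chain_id: str = "A",
    sequence: Optional[str] = None,
) -> tuple[ProteinStructure, str]:
    """Build a toy structure and its PDB text.

    Returns the in-memory :class:`ProteinStructure` and a valid PDB string
    (C-alpha trace only) that round-trips through the PDB reader to within
    the format's 1e-3 A coordinate precision.
    """
    if n_residues < 3:
        raise ValueError("need at least 3 residues")
    rng = np.random.default_rng(seed)
    if geometry == "ideal_helix":
        coords = _helix(n_residues)
    elif geometry == "random_coil":
        coords = _random_coil(n_residues, rng)
    elif geometry == "lattice":
        coords = _lattice(n_residues)
    elif geometry == "helix_hairpin":
        coords = _helix_hairpin(n_residues)
    else:
        raise ValueError(f"unknown geometry: {geometry!r}")
    if sequence is None:
        sequence = "".join(rng.choice(list(_AA20), size=n_residues))
    if len(sequence) != n_residues:
        raise ValueError("sequence length must match n_residues")

    residues = [
        ResiduePoint(
            chain_id=chain_id,
            residue_seq_index=i,
            residue_label=str(i + 1),
            amino_acid=sequence[i],
            coord=tuple(np.round(coords[i], 3)),
            has_coord=True,
        )
        for i in range(n_residues)
    ]
    structure = ProteinStructure(structure_id=structure_id, residues=residues)
    return structure, structure_to_pdb(structure)


def structure_to_pdb(structure: ProteinStructure) -> str:
    """Serialize a C-alpha-trace structure as PDB-format text."""
    lines = ["HEADER    SYNTHETIC STRUCTURE"]
    serial = 0
    for r in structure.residues:
        if not r.has_coord:
            continue
        serial += 1
        x, y, z = r.coord
        resname = _AA_1TO3.get(r.amino_acid, "UNK")
        lines.append(
            f"ATOM  {serial:>5d}  CA  {resname:>3s} {r.chain_id:1s}"
            f"{r.residue_seq_index + 1:>4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
            f" C"
        )
    lines.append("TER")
    lines.append("END")
    return "\n".join(lines) + "\n"


def plant_mutations(
    model: GeneMutationModel,
    structure: ProteinStructure,
    gene: str,
    rng: np.random.Generator,
    ref_seq: str,
    struct_offset: int = 0,
    cancer_type: str = "SYN",
    n_samples: int = 100,
    chrom: str = "1",
    gene_genomic_start: int = 1_000_000,
) -> tuple[list[dict], str]:
    """Draw MAF rows for one gene under its mutation model.

    Returns (rows, label) where label is ``"driver"`` for clustered and
    hotspot models and ``"null"`` for uniform. Residue index i of the
    chain corresponds to reference codon ``struct_offset + i + 1``. Each
    mutation gets its own synthetic sample id (distinct within the gene,
    drawn from a pool of ``n_samples``).
    """
    L = len(ref_seq)
    codons: list[int] = []
    if model.kind == "uniform":
        codons = list(rng.integers(1, L + 1, size=model.n_mutations))
        label = "null"
    elif model.kind == "hotspot":
        codon = model.codon if model.codon is not None else int(rng.integers(1, L + 1))
        codons = [codon] * model.n_mutations
        label = "driver"
    else:  # clustered
        label = "driver"
        coords = structure.coordinates()
        idx_with = structure.coordinate_indices()
        if model.center is not None:
            center_i = model.center
        else:
            center_i = int(rng.choice(idx_with))
        center = structure.coord_of(center_i)
        d = np.linalg.norm(coords - center, axis=1)
        candidates = idx_with[d <= model.radius]
        k = model.n_mutations
        if len(candidates) < 2:
            # impossible cluster: degrade to a hotspot at the center codon
            codons = [struct_offset + center_i + 1] * k
        else:
            if len(candidates) >= k:
                chosen = rng.choice(candidates, size=k, replace=False)
            else:
                chosen = rng.choice(candidates, size=k, replace=True)
            codons = [struct_offset + int(i) + 1 for i in chosen]
        codons += list(rng.integers(1, L + 1, size=model.background))

    samples = rng.choice(n_samples, size=len(codons), replace=len(codons) > n_samples)
    rows = []
    for codon, s in zip(codons, samples):
        codon = int(codon)
        ref_aa = ref_seq[codon - 1]
        alt_aa = _AA20[(int(_AA20.index(ref_aa)) + 1 + int(rng.integers(0, 18))) % 20]
        ref_b = _BASES[int(rng.integers(0, 4))]
        alt_b = _BASES[(int(_BASES.index(ref_b)) + 1 + int(rng.integers(0, 3))) % 4]
        rows.append({
            "Hugo_Symbol": gene,
            "Tumor_Sample_Barcode": f"SYN-{int(s):04d}",
            "Chromosome": chrom,
            "Start_Position": gene_genomic_start + codon * 3,
            "Reference_Allele": ref_b,
            "Tumor_Seq_Allele2": alt_b,
            "Variant_Classification": "Missense_Mutation",
            "Protein_Change": f"p.{ref_aa}{codon}{alt_aa}",
            "Cancer_Type": cancer_type,
        })
    return rows, label


def _mutate_chain(seq: str, rate: float, rng: np.random.Generator) -> str:
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < rate:
            out[i] = _AA20[int(rng.integers(0, 20))]
    return "".join(out)


def make_cohort(scenario: SyntheticScenario, outdir) -> CohortPaths:
    """Write a complete, self-consistent toy cohort to ``outdir``.

    Produces a MAF table, one PDB per gene, a reference FASTA (chains are
    exact substrings of the references unless ``hard_alignment``), a
    gene-to-structure map, a germline blacklist whose entries are planted
    in the MAF, annotation and ground-truth TSVs. Deterministic: the same
    scenario and seed yield byte-identical files.
    """
    root = Path(outdir)
    pdb_dir = root / "pdb"
    pdb_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(scenario.seed)

    n_drivers = round(scenario.n_genes * scenario.driver_fraction)
    maf_rows: list[dict] = []
    truth_rows: list[str] = []
    map_rows: list[str] = []
    fasta_chunks: list[str] = []
    anno_rows: list[str] = []
    flank = scenario.flank

    for g in range(scenario.n_genes):
        gene = f"G{g + 1:04d}"
        sid = f"SYN{g + 1:04d}_A"
        structure, pdb_text = make_structure(
            scenario.geometry, scenario.n_residues,
            seed=int(rng.integers(0, 2**31)), structure_id=sid,
        )
        (pdb_dir / f"{sid}.pdb").write_text(pdb_text)
        chain_seq = structure.sequence
        pre = "".join(rng.choice(list(_AA20), size=flank))
        post = "".join(rng.choice(list(_AA20), size=flank))
        ref_seq = pre + chain_seq + post
        if scenario.hard_alignment:
            if rng.random() < 0.5:
                # wrong-isoform reference: unrelated and 3x the chain, so
                # the gap fraction of any global alignment exceeds 1/2 and
                # the QC gate has genuine failures to catch
                ref_seq = "".join(
                    rng.choice(list(_AA20), size=3 * scenario.n_residues))
            else:
                mutated = _mutate_chain(chain_seq, scenario.mismatch_rate, rng)
                structure = ProteinStructure(
                    structure_id=sid,
                    residues=[
                        ResiduePoint(r.chain_id, r.residue_seq_index,
                                     r.residue_label, mutated[i], r.coord,
                                     r.has_coord)
                        for i, r in enumerate(structure.residues)
                    ],
                )
                (pdb_dir / f"{sid}.pdb").write_text(structure_to_pdb(structure))
        fasta_chunks.append(f">{gene}\n{ref_seq}\n")
        map_rows.append(f"{gene}\t{sid}\tpdb/{sid}.pdb\tA")

        is_driver = g < n_drivers
        if is_driver:
            model = GeneMutationModel(
                kind="clustered", n_mutations=scenario.cluster_k,
                radius=scenario.cluster_radius,
            )
            anno_rows.append(f"{gene}\toncogene")
        else:
            model = GeneMutationModel(kind="uniform",
                                      n_mutations=scenario.null_mutations)
        rows, label = plant_mutations(
            model, structure, gene, rng, ref_seq, struct_offset=flank,
            cancer_type=scenario.cancer_type, n_samples=scenario.n_samples,
            chrom=str(g % 22 + 1), gene_genomic_start=(g + 1) * 100_000,
        )
        maf_rows.extend(rows)
        truth_rows.append(f"{gene}\t{label}\t{model.kind}")

    # planted germline contaminants: present in the MAF AND in the blacklist
    blacklist_rows = []
    for j in range(scenario.n_germline):
        g = int(rng.integers(0, scenario.n_genes))
        gene = f"G{g + 1:04d}"
        pos = (g + 1) * 100_000 + 99_000 + j
        row = {
            "Hugo_Symbol": gene,
            "Tumor_Sample_Barcode": f"SYN-{int(rng.integers(0, scenario.n_samples)):04d}",
            "Chromosome": str(g % 22 + 1),
            "Start_Position": pos,
            "Reference_Allele": "A",
            "Tumor_Seq_Allele2": "G",
            "Variant_Classification": "Missense_Mutation",
            "Protein_Change": f"p.A{int(rng.integers(1, flank))}V",
            "Cancer_Type": scenario.cancer_type,
        }
        maf_rows.append(row)
        blacklist_rows.append(f"{row['Chromosome']}\t{pos}\tG")

    for j in range(scenario.n_silent):
        g = int(rng.integers(0, scenario.n_genes))
        maf_rows.append({
            "Hugo_Symbol": f"G{g + 1:04d}",
            "Tumor_Sample_Barcode": f"SYN-{int(rng.integers(0, scenario.n_samples)):04d}",
            "Chromosome": str(g % 22 + 1),
            "Start_Position": (g + 1) * 100_000 + 98_000 + j,
            "Reference_Allele": "C",
            "Tumor_Seq_Allele2": "T",
            "Variant_Classification": "Silent",
            "Protein_Change": "",
            "Cancer_Type": scenario.cancer_type,
        })

    # redundant rows: exact copies of existing calls, removed by dedup
    for j in range(min(scenario.n_duplicates, len(maf_rows))):
        maf_rows.append(dict(maf_rows[j]))

    paths = CohortPaths(
        root=root,
        maf=root / "mutations.maf.tsv",
        pdb_dir=pdb_dir,
        fasta=root / "reference.fasta",
        structure_map=root / "gene_structure_map.tsv",
        blacklist=root / "blacklist.tsv",
        annotations=root / "annotations.tsv",
        truth=root / "truth.tsv",
    )
    maf_lines = ["\t".join(MAF_HEADER)]
    maf_lines += ["\t".join(str(r[c]) for c in MAF_HEADER) for r in maf_rows]
    paths.maf.write_text("\n".join(maf_lines) + "\n")
    paths.fasta.write_text("".join(fasta_chunks))
    paths.structure_map.write_text(
        "gene\tstructure_id\tpdb_path\tchain\n" + "\n".join(map_rows) + "\n"
    )
    paths.blacklist.write_text(
        "chrom\tpos\talt\n" + ("\n".join(blacklist_rows) + "\n" if blacklist_rows else "")
    )
    paths.annotations.write_text(
        "gene\tclass\n" + ("\n".join(anno_rows) + "\n" if anno_rows else "")
    )
    paths.truth.write_text(
        "gene\tlabel\tmodel\n" + "\n".join(truth_rows) + "\n"
    )
    return paths
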