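import numpy as np
import pytest

from mut3d import make_structure


@pytest.fixture
def collinear3():
    """Three residues on a line at x = 0, 1, 2."""
    return np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0]])


@pytest.fixture
def unit_square():
    """Four residues at the corners of a unit square."""
    return np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0]])


@pytest.fixture(scope="session")
def coil200():
    """A 200-residue random-coil structure shared across tests."""
    structure, _ = make_structure("random_coil", 200, seed=42)
    return structure


@pytest.fixture(scope="session")
def lattice27():
    structure, pdb_text = make_structure("lattice", 27, seed=0)
    return structure, pdb_text


TOY_MAF_HEADER = (
    "Hugo_Symbol\tTumor_Sample_Barcode\tChromosome\tStart_Position\t"
    "Reference_Allele\tTumor_Seq_Allele2\tVariant_Classification\t"
    "Protein_Change\tCancer_Type"
)


def maf_line(gene="TP53", sample="S1", chrom="17", pos=1000, ref="C", alt="T",
             vc="Missense_Mutation", pchange="p.R175H", ct="TST"):
    return f"{gene}\t{sample}\t{chrom}\t{pos}\t{ref}\t{alt}\t{vc}\t{pchange}\t{ct}"


@pytest.fixture
def write_maf(tmp_path):
    """Write MAF lines to a temp file and return its path."""

    def _write(lines, name="toy.maf.tsv"):
        path = tmp_path / name
        path.write_text(TOY_MAF_HEADER + "\n" + "\n".join(lines) + "\n")
        return path

    return _write
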