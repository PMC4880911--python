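"""MAF-style somatic mutation tables: parsing and cleaning filters.

The cleaning pipeline mirrors standard practice for TCGA-derived exome
calls: drop redundant SNV rows within a sample, remove candidate somatic
variants that match a germline blacklist (a 1000 Genomes common-SNV set,
or a validated-dbSNP set — the latter is more conservative but is known to
remove genuine cancer hotspots), then keep missense SNVs with a parseable
protein position.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Union

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "MutationRecord",
    "GermlineBlacklist",
    "DEFAULT_COLUMNS",
    "read_maf",
    "read_blacklist",
    "remove_redundant",
    "apply_germline_filter",
    "select_missense",
    "sample_frequency",
]

#: Default MAF column mapping (TCGA conventions).
DEFAULT_COLUMNS = {
    "gene_symbol": "Hugo_Symbol",
    "sample_id": "Tumor_Sample_Barcode",
    "chrom": "Chromosome",
    "genomic_pos": "Start_Position",
    "ref_allele": "Reference_Allele",
    "alt_allele": "Tumor_Seq_Allele2",
    "variant_classification": "Variant_Classification",
    "aa_change": "Protein_Change",
    "cancer_type": "Cancer_Type",  # optional
}

_MANDATORY = ("gene_symbol", "sample_id", "genomic_pos", "variant_classification")

_AA_CHANGE_RE = re.compile(r"^p\.(?:[A-Za-z*]{1,3}?)(\d+)")


@dataclass(frozen=True)
class MutationRecord:
    """One somatic SNV call from a MAF row."""

    gene_symbol: str
    sample_id: str
    chrom: str
    genomic_pos: int
    ref_allele: str
    alt_allele: str
    variant_classification: str
    cancer_type: str = ""
    protein_pos: Optional[int] = None  # 1-based codon in the reference protein
    aa_change: str = ""


@dataclass
class GermlineBlacklist:
    """Exact-match (chrom, pos, alt) lookup of putative germline variants.

    ``mode`` records which population resource the entries emulate:
    ``"filter1"`` for a 1000 Genomes common-SNV style set, ``"filter2"``
    for a validated-dbSNP style set.
    """

    mode: str = "filter1"
    entries: set[tuple[str, int, str]] = field(default_factory=set)

    def __contains__(self, key: tuple[str, int, str]) -> bool:
        chrom, pos, alt = key
        return (str(chrom), int(pos), str(alt)) in self.entries

    def __len__(self) -> int:
        return len(self.entries)


def parse_protein_pos(aa_change: str) -> Optional[int]:
    """Extract the codon index from an HGVS-style change like ``p.V600E``."""
    if not aa_change:
        return None
    m = _AA_CHANGE_RE.match(aa_change.strip())
    return int(m.group(1)) if m else None


def read_maf(
    source: Union[str, Path],
    columns: Optional[dict] = None,
    cancer_type: str = "",
) -> list[MutationRecord]:
    """Read a tab-delimited MAF-style table into mutation records.

    ``columns`` overrides entries of :data:`DEFAULT_COLUMNS` to accommodate
    center-specific headers. Rows whose mandatory fields cannot be parsed
    are skipped and counted in a log message. ``protein_pos`` is parsed
    from the amino-acid change string when it looks like ``p.G12D``.

    Raises
    ------
    ValueError
        If a mandatory column is absent from the header.
    """
    colmap = dict(DEFAULT_COLUMNS)
    if columns:
        colmap.update(columns)

    df = pd.read_csv(source, sep="\t", dtype=str, comment="#").fillna("")
    missing = [colmap[k] for k in _MANDATORY if colmap[k] not in df.columns]
    if missing:
        raise ValueError(f"malformed MAF header: missing column(s) {missing}")

    def col(key: str) -> pd.Series:
        name = colmap[key]
        return df[name] if name in df.columns else pd.Series([""] * len(df))

    records: list[MutationRecord] = []
    skipped = 0
    rows = zip(
        col("gene_symbol"), col("sample_id"), col("chrom"), col("genomic_pos"),
        col("ref_allele"), col("alt_allele"), col("variant_classification"),
        col("aa_change"), col("cancer_type"),
    )
    for gene, sample, chrom, pos, ref, alt, vc, aach, ctype in rows:
        try:
            pos_i = int(float(pos))
            if not gene or not sample or not vc or pos_i < 1:
                raise ValueError
        except (ValueError, TypeError):
            skipped += 1
            continue
        records.append(
            MutationRecord(
                gene_symbol=gene,
                sample_id=sample,
                chrom=str(chrom),
                genomic_pos=pos_i,
                ref_allele=ref,
                alt_allele=alt,
                variant_classification=vc,
                cancer_type=ctype or cancer_type,
                protein_pos=parse_protein_pos(aach),
                aa_change=aach,
            )
        )
    if skipped:
        logger.warning("read_maf: skipped %d row(s) with unparseable fields", skipped)
    return records


def read_blacklist(source: Union[str, Path], mode: str = "filter1") -> GermlineBlacklist:
    """Read a (chrom, pos, alt) TSV into a :class:`GermlineBlacklist`."""
    df = pd.read_csv(source, sep="\t", dtype=str)
    cols = [c.lower() for c in df.columns]
    df.columns = cols
    entries = {
        (str(c), int(p), str(a))
        for c, p, a in zip(df["chrom"], df["pos"], df["alt"])
    }
    return GermlineBlacklist(mode=mode, entries=entries)


def remove_redundant(records: Iterable[MutationRecord]) -> list[MutationRecord]:
    """Drop duplicate SNV calls within a sample.

    The dedup key is (sample, chrom, genomic position, alt allele): the alt
    allele is part of the key so two genuinely different substitutions at
    one site both survive. First occurrence wins.
    """
    seen: set[tuple] = set()
    out = []
    for r in records:
        key = (r.sample_id, r.chrom, r.genomic_pos, r.alt_allele)
        if key in seen:
            continue
        seen.add(key)
        out.append(r)
    logger.info("remove_redundant: kept %d unique record(s)", len(out))
    return out


def apply_germline_filter(
    records: Iterable[MutationRecord], blacklist: GermlineBlacklist
) -> list[MutationRecord]:
    """Remove records whose (chrom, pos, alt) matches the blacklist."""
    out, removed_per_gene = [], {}
    for r in records:
        if (r.chrom, r.genomic_pos, r.alt_allele) in blacklist:
            removed_per_gene[r.gene_symbol] = removed_per_gene.get(r.gene_symbol, 0) + 1
        else:
            out.append(r)
    if removed_per_gene:
        logger.info(
            "apply_germline_filter(%s): removed %d record(s) across %d gene(s): %s",
            blacklist.mode,
            sum(removed_per_gene.values()),
            len(removed_per_gene),
            removed_per_gene,
        )
    return out


def select_missense(records: Iterable[MutationRecord]) -> list[MutationRecord]:
    """Keep missense SNVs that carry a protein position.

    Missense records lacking a parseable codon index cannot be placed on
    either the primary sequence or the structure and are dropped with a
    warning.
    """
    out, dropped = [], 0
    for r in records:
        if r.variant_classification != "Missense_Mutation":
            continue
        if r.protein_pos is None:
            dropped += 1
            continue
        out.append(r)
    if dropped:
        logger.warning(
            "select_missense: dropped %d missense record(s) without protein_pos",
            dropped,
        )
    return out


def sample_frequency(
    records: Iterable[MutationRecord], gene: str, n_samples_total: int
) -> float:
    """Fraction of cohort samples carrying >=1 record in ``gene``."""
    if n_samples_total < 1:
        raise ValueError("n_samples_total must be >= 1")
    samples = {r.sample_id for r in records if r.gene_symbol == gene}
    return len(samples) / n_samples_total
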