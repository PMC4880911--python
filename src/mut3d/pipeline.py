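"""End-to-end analysis: mutation table + structures -> FDR-corrected calls.

``run_analysis`` wires the stages together per cancer type: MAF cleaning,
chain-to-reference alignment with QC, mutation mapping, the adaptive
permutation test (3D on each candidate structure with lowest-p structure
selection, optionally the 1D control over the whole coding region),
Benjamini-Hochberg correction over the tested genes, and significance
calling. ``run_benchmark`` runs the same machinery on a synthetic cohort
with known ground truth and reports rejection rates, ranking performance
and empirical FDR.

Genes are independent work units: every (cancer type, gene, structure,
dimension, stage) combination draws from its own deterministically derived
random stream, so results do not depend on processing order.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
from Bio import SeqIO

from . import maf as maf_mod
from .maf import (
    MutationRecord, read_maf, read_blacklist, remove_redundant,
    apply_germline_filter, select_missense, sample_frequency,
)
from .mapping import align_global, alignment_qc, map_mutations
from .permtest import (
    DistanceObservation, PermutationResult, adaptive_pvalue,
    avg_pairwise_distance_1d, avg_pairwise_distance_3d, call_genes,
    select_best_structure,
)
from .structures import read_structure
from .synthetic import SyntheticScenario, make_cohort

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "RunResult", "run_analysis", "run_benchmark"]


@dataclass
class RunConfig:
    """Inputs, thresholds and run parameters of one analysis.

    Threshold defaults are the standard operating point of the method:
    genes enter the test with >= 3 mutations mapped onto the structure,
    alignments must have a gap fraction strictly below 0.5 and cover at
    least half the chain, stage-1 p-values <= 0.01 escalate from 10^4 to
    10^6 permutations, and a gene is called significant when its BH
    q-value is <= 0.1 and more than 3% of cohort samples carry a missense
    mutation in it.
    """

    maf: Union[str, Path]
    pdb_dir: Union[str, Path]
    fasta: Union[str, Path]
    structure_map: Union[str, Path]
    outdir: Union[str, Path]
    blacklist: Optional[Union[str, Path]] = None
    annotations: Optional[Union[str, Path]] = None
    min_n: int = 3
    q_threshold: float = 0.1
    freq_threshold: float = 0.03
    max_gap_ratio: float = 0.5
    min_coverage: float = 0.5
    m1: int = 10_000
    m2: int = 1_000_000
    p_escalate: float = 0.01
    seed: int = 0
    filter_mode: str = "filter1"  # filter1 | filter2 | none
    replacement: bool = True
    dimension: str = "3D"  # 3D | 1D | both
    n_samples_total: Optional[int] = None
    column_map: Optional[dict] = None


@dataclass
class RunResult:
    results: pd.DataFrame  # one row per (cancer_type, gene, dimension)
    manifest: dict
    untestable: list = field(default_factory=list)


def _load_structure_map(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    needed = {"gene", "structure_id", "pdb_path", "chain"}
    if not needed <= set(df.columns):
        raise ValueError(f"structure map must have columns {sorted(needed)}")
    return df


def _result_row(res: PermutationResult, cancer_type: str) -> dict:
    o = res.observation
    return {
        "cancer_type": cancer_type,
        "gene": o.gene,
        "structure_id": o.structure_id,
        "dimension": o.dimension,
        "n": o.n,
        "observed_distance": o.observed_avg_distance,
        "m": res.m,
        "k": res.k,
        "p_value": res.p_value,
        "stage": res.stage,
        "stage1_p": res.stage1_p if res.stage1_p is not None else res.p_value,
    }


def run_analysis(config: RunConfig) -> RunResult:
    """Execute the full pipeline and write results + manifest to outdir."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts: dict = {}

    records = read_maf(config.maf, columns=config.column_map)
    counts["rows_read"] = len(records)
    records = remove_redundant(records)
    counts["after_dedup"] = len(records)
    if config.filter_mode != "none" and config.blacklist is not None:
        bl = read_blacklist(config.blacklist, mode=config.filter_mode)
        records = apply_germline_filter(records, bl)
    counts["after_germline"] = len(records)
    missense = select_missense(records)
    counts["missense"] = len(missense)

    refs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(config.fasta), "fasta")}
    smap = _load_structure_map(config.structure_map)
    pdb_dir = Path(config.pdb_dir)

    dims = ["3D", "1D"] if config.dimension == "both" else [config.dimension]
    rows: list[dict] = []
    audit_rows: list[dict] = []
    untestable: list[dict] = []
    gene_log: list[dict] = []

    cancer_types = sorted({r.cancer_type or "NA" for r in missense})
    structure_cache: dict[str, object] = {}

    for ct in cancer_types:
        ct_records = [r for r in records if (r.cancer_type or "NA") == ct]
        ct_missense = [r for r in missense if (r.cancer_type or "NA") == ct]
        n_samples = config.n_samples_total or len({r.sample_id for r in ct_records})
        by_gene: dict[str, list[MutationRecord]] = {}
        for r in ct_missense:
            by_gene.setdefault(r.gene_symbol, []).append(r)

        ct_best_3d: list[PermutationResult] = []
        ct_1d: list[PermutationResult] = []
        freqs: dict[str, float] = {}

        for gene in sorted(by_gene):
            gene_records = by_gene[gene]
            ref_seq = refs.get(gene)
            if ref_seq is None:
                untestable.append({"cancer_type": ct, "gene": gene,
                                   "reason": "no reference sequence"})
                continue
            freqs[gene] = sample_frequency(gene_records, gene, n_samples)

            per_structure: list[PermutationResult] = []
            gene_structs = smap[smap["gene"] == gene]
            if "3D" in dims:
                for _, srow in gene_structs.iterrows():
                    sid = srow["structure_id"]
                    if sid not in structure_cache:
                        pdb_path = pdb_dir / Path(srow["pdb_path"]).name
                        if not pdb_path.exists():
                            pdb_path = Path(srow["pdb_path"])
                        try:
                            structure_cache[sid] = read_structure(
                                pdb_path, srow["chain"], structure_id=sid)
                        except (ValueError, OSError) as exc:
                            structure_cache[sid] = exc
                    structure = structure_cache[sid]
                    if isinstance(structure, Exception):
                        audit_rows.append({"gene": gene, "structure_id": sid,
                                           "gap_ratio": "", "coverage": "",
                                           "passed": False,
                                           "reason": str(structure)})
                        continue
                    aln = align_global(ref_seq, structure.sequence,
                                       gene=gene, structure_id=sid)
                    qc = alignment_qc(aln, config.max_gap_ratio, config.min_coverage)
                    audit_rows.append({"gene": gene, "structure_id": sid,
                                       "gap_ratio": round(qc.gap_ratio, 6),
                                       "coverage": round(qc.coverage, 6),
                                       "passed": qc.passed, "reason": qc.reason})
                    if not qc.passed:
                        continue
                    mapped = map_mutations(aln, gene_records, structure)
                    if mapped.n_mapped < config.min_n:
                        continue
                    coords = np.array([structure.coord_of(i)
                                       for i in mapped.struct_positions])
                    observed = avg_pairwise_distance_3d(coords)
                    res = adaptive_pvalue(
                        structure, mapped.n_mapped, observed, config.seed,
                        dimension="3D", m1=config.m1, m2=config.m2,
                        escalate_p=config.p_escalate,
                        replacement=config.replacement,
                        gene=gene, structure_id=sid, cancer_type=ct)
                    per_structure.append(res)
                    gene_log.append({"cancer_type": ct, "gene": gene,
                                     "structure_id": sid, "dimension": "3D",
                                     "n": mapped.n_mapped,
                                     "stage1_p": res.stage1_p or res.p_value,
                                     "stage": res.stage,
                                     "escalated": res.stage == 2})
                if per_structure:
                    ct_best_3d.append(select_best_structure(per_structure))
                elif not gene_structs.empty:
                    untestable.append({"cancer_type": ct, "gene": gene,
                                       "reason": "no QC-passing structure with "
                                                 f">={config.min_n} mapped mutations"})

            if "1D" in dims:
                cds_pos = [r.protein_pos for r in gene_records
                           if r.protein_pos is not None
                           and 1 <= r.protein_pos <= len(ref_seq)]
                if len(cds_pos) >= config.min_n:
                    observed = avg_pairwise_distance_1d(cds_pos)
                    res = adaptive_pvalue(
                        len(ref_seq), len(cds_pos), observed, config.seed,
                        dimension="1D", m1=config.m1, m2=config.m2,
                        escalate_p=config.p_escalate,
                        replacement=config.replacement,
                        gene=gene, structure_id="CDS", cancer_type=ct)
                    ct_1d.append(res)
                    gene_log.append({"cancer_type": ct, "gene": gene,
                                     "structure_id": "CDS", "dimension": "1D",
                                     "n": len(cds_pos),
                                     "stage1_p": res.stage1_p or res.p_value,
                                     "stage": res.stage,
                                     "escalated": res.stage == 2})

        for dim, ct_results in (("3D", ct_best_3d), ("1D", ct_1d)):
            if not ct_results:
                continue
            calls = call_genes(ct_results, freqs, cancer_type=ct,
                               q_threshold=config.q_threshold,
                               freq_threshold=config.freq_threshold,
                               min_n=config.min_n)
            by_gene_res = {r.observation.gene: r for r in ct_results}
            for call in calls:
                row = _result_row(by_gene_res[call.gene], ct)
                row.update(q_value=call.q_value, sample_freq=call.sample_freq,
                           significant=call.significant)
                rows.append(row)

    cols = ["cancer_type", "gene", "structure_id", "dimension", "n",
            "observed_distance", "m", "k", "p_value", "q_value",
            "sample_freq", "significant", "stage", "stage1_p"]
    results = pd.DataFrame(rows, columns=cols).sort_values(
        ["cancer_type", "dimension", "gene"]).reset_index(drop=True)

    manifest = {
        "seed": config.seed,
        "thresholds": {
            "min_n": config.min_n, "q_threshold": config.q_threshold,
            "freq_threshold": config.freq_threshold,
            "max_gap_ratio": config.max_gap_ratio,
            "min_coverage": config.min_coverage,
            "m1": config.m1, "m2": config.m2,
            "p_escalate": config.p_escalate,
            "filter_mode": config.filter_mode,
            "replacement": config.replacement,
            "dimension": config.dimension,
        },
        "counts": counts,
        "genes": gene_log,
        "untestable": untestable,
    }

    results.to_csv(outdir / "results.tsv", sep="\t", index=False)
    pd.DataFrame(audit_rows).to_csv(outdir / "alignment_audit.tsv",
                                    sep="\t", index=False)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                     default=str))
    logger.info("run_analysis: %d result row(s), %d untestable gene(s)",
                len(results), len(untestable))
    return RunResult(results=results, manifest=manifest, untestable=untestable)


def run_benchmark(
    scenario: SyntheticScenario,
    workdir: Union[str, Path],
    alphas: tuple = (0.01, 0.05),
    **config_overrides,
) -> dict:
    """Generate a cohort with known truth, run both tests, score them.

    Returns (and writes to ``workdir/benchmark_report.json``) rejection
    rates per ground-truth class and test dimension at the requested alpha
    levels, driver-vs-null ranking AUROC for the 3D test, and the
    empirical FDR of the significant call set.
    """
    from sklearn.metrics import roc_auc_score

    workdir = Path(workdir)
    cohort_dir = workdir / "cohort"
    paths = make_cohort(scenario, cohort_dir)
    config = RunConfig(
        maf=paths.maf, pdb_dir=paths.pdb_dir, fasta=paths.fasta,
        structure_map=paths.structure_map, blacklist=paths.blacklist,
        annotations=paths.annotations, outdir=workdir / "analysis",
        dimension="both", seed=scenario.seed,
        n_samples_total=scenario.n_samples,
    )
    for k, v in config_overrides.items():
        setattr(config, k, v)
    run = run_analysis(config)

    # keep_default_na: the ground-truth label "null" is a real value here
    truth = pd.read_csv(paths.truth, sep="\t", keep_default_na=False)
    merged = run.results.merge(truth, on="gene", how="left")
    report: dict = {
        "scenario": asdict(scenario),
        "n_tested": {dim: int((merged["dimension"] == dim).sum())
                     for dim in merged["dimension"].unique()},
        "rejection_rates": {},
    }
    for dim in sorted(merged["dimension"].unique()):
        sub = merged[merged["dimension"] == dim]
        for label in sorted(sub["label"].dropna().unique()):
            grp = sub[sub["label"] == label]
            report["rejection_rates"][f"{dim}/{label}"] = {
                f"alpha_{a}": float((grp["p_value"] <= a).mean())
                for a in alphas
            } | {"n_genes": int(len(grp))}

    m3 = merged[merged["dimension"] == "3D"]
    if m3["label"].nunique() == 2:
        y = (m3["label"] == "driver").astype(int)
        report["auroc_3d"] = float(roc_auc_score(y, -m3["p_value"]))
        called = m3[m3["significant"]]
        if len(called):
            report["empirical_fdr_3d"] = float((called["label"] != "driver").mean())
            report["n_significant_3d"] = int(len(called))
        else:
            report["empirical_fdr_3d"] = 0.0
            report["n_significant_3d"] = 0

    (workdir / "benchmark_report.json").write_text(
        json.dumps(report, indent=2, default=str))
    return report
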