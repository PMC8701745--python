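"""End-to-end orchestration: both workflows plus the reproducibility manifest.

``run_full`` executes the classic differential-expression workflow
(filter -> normalize -> batch-correct -> Welch t -> BH -> DEG tiers) and
the machine-learning workflow (per-fold selection cascade -> stable
decision trees -> census) on the same inputs, then clinical association
on the discovered panel and, when a gene-set file or edge list is
supplied, over-representation and subnetwork extraction.  Every output
file is listed in a manifest with a SHA-256 checksum; two runs with the
same inputs, config and seed produce byte-identical files.
"""
from __future__ import annotations

import hashlib
import logging
from pathlib import Path

from . import __version__
from .clinical import correlate_panel, significant_pairs
from .config import PipelineConfig
from .containers import CountsMatrix, SampleMetadata
from .diffexp import de_test, filter_degs, filter_top_degs
from .enrichment import hypergeom_ora, subnetwork
from .io import (
    read_counts,
    read_edge_list,
    read_gene_sets,
    read_metadata,
    write_expression,
    write_json,
)
from .loocv import run_loocv
from .preprocess import batch_correct, cpm_log2, filter_low_expression

logger = logging.getLogger(__name__)


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as handle:
        for chunk in iter(lambda: handle.read(65536), b""):
            digest.update(chunk)
    return digest.hexdigest()


def preprocess_all(
    counts: CountsMatrix, metadata: SampleMetadata, config: PipelineConfig
):
    """Whole-cohort preprocessing for the differential-expression arm."""
    filtered = filter_low_expression(
        counts, config.filter_min_count, config.filter_min_fraction
    )
    # library sizes are total reads per sample (pre-filter)
    expr = cpm_log2(counts, pseudocount=config.pseudocount).subset_genes(
        filtered.gene_ids
    )
    batches = metadata.batches
    if batches.nunique() > 1:
        expr = batch_correct(expr, batches)
    return expr


def run_full(
    counts_path,
    metadata_path,
    out_dir,
    config: PipelineConfig | None = None,
    gmt_path=None,
    edges_path=None,
) -> dict:
    """Run everything; returns the manifest dictionary."""
    config = config or PipelineConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    counts = read_counts(counts_path)
    metadata = read_metadata(metadata_path).aligned_to(counts.sample_ids)

    written: list[Path] = []

    def emit(path: Path) -> None:
        written.append(path)

    # red workflow: classic differential expression
    expr = preprocess_all(counts, metadata, config)
    write_expression(expr, out / "expression.tsv")
    emit(out / "expression.tsv")

    de = de_test(expr, metadata.groups)
    de.to_tsv(out / "de_results.tsv")
    emit(out / "de_results.tsv")

    degs = filter_degs(de, config.diffexp_p_max)
    (out / "degs.txt").write_text("".join(g + "\n" for g in degs))
    emit(out / "degs.txt")

    top = filter_top_degs(de, config.diffexp_fdr_max, config.diffexp_lfc_min)
    (out / "top_degs.txt").write_text(
        "".join(g + "\n" for g in top.genes)
    )
    emit(out / "top_degs.txt")

    # blue workflow: LOO feature selection + stable trees
    loo = run_loocv(counts, metadata, config)
    write_json(loo.to_dict(), out / "loocv_result.json")
    emit(out / "loocv_result.json")

    freq_lines = ["gene\tfrequency\n"] + [
        f"{g}\t{loo.frequency_table.frequency(g):.6f}\n"
        for g in sorted(loo.frequency_table.counts)
    ]
    (out / "frequency_table.tsv").write_text("".join(freq_lines))
    emit(out / "frequency_table.tsv")

    (out / "panel.txt").write_text("".join(g + "\n" for g in loo.panel.panel))
    emit(out / "panel.txt")

    # clinical association on the discovered panel
    if loo.panel.panel and metadata.clinical_columns:
        corr = correlate_panel(
            expr,
            [g for g in loo.panel.panel if g in expr.frame.index],
            metadata,
            stratum=config.clinical_stratum,
            rho_min=config.clinical_rho_min,
            p_max=config.clinical_p_max,
        )
        corr.to_tsv(out / "correlations.tsv")
        emit(out / "correlations.tsv")
        significant_pairs(corr).to_csv(out / "significant_pairs.tsv", sep="\t", index=False)
        emit(out / "significant_pairs.tsv")

    # optional stages
    if gmt_path is not None:
        sets = read_gene_sets(gmt_path)
        universe = list(expr.gene_ids)
        query = [g for g in degs if g in set(universe)]
        enr = hypergeom_ora(query, universe, sets)
        enr.to_tsv(out / "enrichment.tsv")
        emit(out / "enrichment.tsv")
    else:
        logger.info("no gene-set file supplied; enrichment stage skipped")

    if edges_path is not None:
        edges = read_edge_list(edges_path)
        sub = subnetwork(
            edges,
            seeds=list(loo.panel.panel),
            score_min=config.network_score_min,
            channels=config.network_channels,
        )
        sub.edges.to_csv(out / "subnetwork.tsv", sep="\t", index=False)
        emit(out / "subnetwork.tsv")
    else:
        logger.info("no edge list supplied; subnetwork stage skipped")

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": config.to_mapping(),
        "files": {p.name: _sha256(p) for p in sorted(written)},
    }
    write_json(manifest, out / "manifest.json")
    return manifest
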