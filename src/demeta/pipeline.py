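"""End-to-end orchestration: preprocess -> per-study DE -> similarity -> common genes -> meta.

Every stage's table can be persisted as plain TSV so intermediate results are
independently auditable; a run report records the configuration, the filter
counts and the paths of all written outputs.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import __version__
from .common_genes import FDR, TOP_K, find_common_genes
from .diffexpr import de_analysis
from .io import ExpressionDataset, StudyManifest, load_expression_matrix, load_probe_map
from .meta import DEFAULT_P_FLOOR, run_meta
from .preprocess import FilterReport, collapse_probes_iqr, intersect_genes, rank_sum_filter
from .similarity import (
    CorrelationMatrix,
    Dendrogram,
    cluster_studies,
    correlation_matrix,
    to_newick,
    variation_profile,
)

log = logging.getLogger("demeta")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineParams:
    frac_mean: float = 0.30
    frac_sd: float = 0.30
    top_k: int = 100
    alpha: float = 0.01
    min_diseases: int = 3
    corr_methods: tuple[str, ...] = ("kendall", "spearman")
    p_floor: float = DEFAULT_P_FLOOR
    meta_methods: tuple[str, ...] = ("fisher", "maxp")


@dataclass
class PipelineResult:
    filter_report: FilterReport
    filtered: dict[str, ExpressionDataset]
    de: dict[str, pd.DataFrame]
    correlations: dict[str, CorrelationMatrix]
    dendrograms: dict[str, Dendrogram]
    common: pd.DataFrame
    meta: pd.DataFrame


@dataclass
class RunReport:
    params: dict
    seed: int | None
    version: str
    filter_report: dict
    n_significant: dict[str, dict[str, int]]
    outputs: dict[str, str] = field(default_factory=dict)


def _stage(name: str):
    log.info("stage=%s start t=%s", name, time.strftime("%H:%M:%S"))


def analyze_collection(
    datasets: Mapping[str, ExpressionDataset],
    probe_maps: Mapping[str, pd.DataFrame],
    study_to_disease: Mapping[str, str],
    params: PipelineParams | None = None,
) -> PipelineResult:
    """Run the full analysis on in-memory probe-level datasets.

    ``probe_maps`` maps study_id -> probe annotation table for that study's
    platform.  Stages run in order; any failure is re-raised as a
    :class:`StageError` naming the stage.
    """
    params = params or PipelineParams()
    try:
        _stage("collapse")
        gene_level = [
            collapse_probes_iqr(ds, probe_maps[sid]) for sid, ds in datasets.items()
        ]
        n_union = len(set().union(*(set(ds.features) for ds in gene_level)))
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001 - stage boundary
        raise StageError("collapse", str(exc)) from exc
    try:
        _stage("intersect+filter")
        merged = intersect_genes(gene_level)
        filtered, report = rank_sum_filter(
            merged, params.frac_mean, params.frac_sd, n_input_genes=n_union
        )
    except Exception as exc:
        raise StageError("preprocess", str(exc)) from exc
    try:
        _stage("diffexpr")
        de = {ds.study_id: de_analysis(ds) for ds in filtered}
    except Exception as exc:
        raise StageError("diffexpr", str(exc)) from exc
    try:
        _stage("similarity")
        profiles = [
            variation_profile(table, sid, floor=params.p_floor)
            for sid, table in de.items()
        ]
        correlations = {
            m: correlation_matrix(profiles, m) for m in params.corr_methods
        }
        dendrograms = {m: cluster_studies(c) for m, c in correlations.items()}
    except Exception as exc:
        raise StageError("similarity", str(exc)) from exc
    try:
        _stage("common_genes")
        common = find_common_genes(
            de,
            study_to_disease,
            k=params.top_k,
            alpha=params.alpha,
            min_diseases=params.min_diseases,
        )
    except Exception as exc:
        raise StageError("common_genes", str(exc)) from exc
    try:
        _stage("meta")
        meta = run_meta(de, methods=params.meta_methods, floor=params.p_floor)
    except Exception as exc:
        raise StageError("meta", str(exc)) from exc
    return PipelineResult(
        filter_report=report,
        filtered={ds.study_id: ds for ds in filtered},
        de=de,
        correlations=correlations,
        dendrograms=dendrograms,
        common=common,
        meta=meta,
    )


def load_collection_from_manifest(
    manifest: StudyManifest,
) -> tuple[dict[str, ExpressionDataset], dict[str, pd.DataFrame]]:
    """Read every study's expression matrix and probe annotation."""
    datasets, probe_maps = {}, {}
    for entry in manifest.entries:
        datasets[entry.study_id] = load_expression_matrix(
            entry.expression_path,
            entry.case_ids,
            entry.control_ids,
            study_id=entry.study_id,
            disease=entry.disease,
        )
        if entry.annotation_path is None:
            raise StageError("load", f"{entry.study_id}: no probe annotation path")
        probe_maps[entry.study_id] = load_probe_map(entry.annotation_path)
    return datasets, probe_maps


def write_result(
    result: PipelineResult,
    out_dir: str | Path,
    params: PipelineParams,
    seed: int | None = None,
) -> RunReport:
    """Persist every stage table under ``out_dir`` and return the run report."""
    out = Path(out_dir)
    (out / "filtered").mkdir(parents=True, exist_ok=True)
    (out / "de").mkdir(exist_ok=True)
    (out / "similarity").mkdir(exist_ok=True)
    outputs: dict[str, str] = {}

    for sid, ds in result.filtered.items():
        path = out / "filtered" / f"{sid}.tsv"
        ds.to_tsv(path)
        outputs[f"filtered/{sid}"] = str(path)
    report_path = out / "filter_report.tsv"
    pd.DataFrame([asdict(result.filter_report)]).to_csv(report_path, sep="\t", index=False)
    outputs["filter_report"] = str(report_path)

    for sid, table in result.de.items():
        path = out / "de" / f"{sid}.tsv"
        table.rename_axis("gene").to_csv(path, sep="\t")
        outputs[f"de/{sid}"] = str(path)

    for method, corr in result.correlations.items():
        path = out / "similarity" / f"correlation_{method}.tsv"
        corr.values.rename_axis("study").to_csv(path, sep="\t")
        outputs[f"correlation_{method}"] = str(path)
        dend = result.dendrograms[method]
        nwk = out / "similarity" / f"dendrogram_{method}.nwk"
        nwk.write_text(to_newick(dend) + "\n")
        outputs[f"dendrogram_{method}"] = str(nwk)

    common_path = out / "common_genes.tsv"
    result.common.to_csv(common_path, sep="\t")
    outputs["common_genes"] = str(common_path)
    meta_path = out / "meta_results.tsv"
    result.meta.to_csv(meta_path, sep="\t")
    outputs["meta_results"] = str(meta_path)

    n_sig = {
        sid: {
            TOP_K: int((table["rank"] <= params.top_k).sum()),
            FDR: int((table["p_adj"] < params.alpha).sum()),
        }
        for sid, table in result.de.items()
    }
    report = RunReport(
        params=asdict(params),
        seed=seed,
        version=__version__,
        filter_report=asdict(result.filter_report),
        n_significant=n_sig,
        outputs=outputs,
    )
    with open(out / "run_report.json", "w") as fh:
        json.dump(asdict(report), fh, indent=2)
    return report


def run_all(
    manifest: StudyManifest,
    out_dir: str | Path,
    params: PipelineParams | None = None,
    seed: int | None = None,
    gene_sets_path: str | Path | None = None,
) -> RunReport:
    """Load a manifest, run every stage and persist all outputs.

    When ``gene_sets_path`` (GMT) is given, the common-gene union is also
    tested for over-representation against the post-filter universe.
    """
    params = params or PipelineParams()
    try:
        _stage("load")
        datasets, probe_maps = load_collection_from_manifest(manifest)
    except StageError:
        raise
    except Exception as exc:
        raise StageError("load", str(exc)) from exc
    result = analyze_collection(datasets, probe_maps, manifest.study_to_disease, params)
    report = write_result(result, out_dir, params, seed=seed)
    if gene_sets_path is not None:
        try:
            _stage("enrichment")
            from .enrichment import enrich
            from .io import load_gene_sets

            universe = result.filtered[next(iter(result.filtered))].features
            table = enrich(list(result.common.index), load_gene_sets(gene_sets_path), universe)
            path = Path(out_dir) / "enrichment.tsv"
            table.to_csv(path, sep="\t", index=False)
            report.outputs["enrichment"] = str(path)
        except Exception as exc:
            raise StageError("enrichment", str(exc)) from exc
    return report
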