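"""Multi-study preprocessing: probe collapse, gene-panel intersection, expression filtering.

The three steps mirror the standard merge-and-filter protocol for integrative
microarray analysis: (1) when several probes map to one gene, keep the probe
with the largest interquartile range of expression across all samples; (2)
restrict every study to the commonly profiled genes; (3) sequentially drop
un-expressed genes (smallest cross-study rank sum of mean intensity) and
un-informative genes (smallest cross-study rank sum of standard deviation).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io import ExpressionDataset


@dataclass
class FilterReport:
    n_input_genes: int
    n_after_intersection: int
    n_removed_unexpressed: int
    n_removed_uninformative: int
    n_retained: int

    def __post_init__(self) -> None:
        if self.n_retained != (
            self.n_after_intersection
            - self.n_removed_unexpressed
            - self.n_removed_uninformative
        ):
            raise ValueError("inconsistent filter counts")
        if min(
            self.n_input_genes,
            self.n_after_intersection,
            self.n_removed_unexpressed,
            self.n_removed_uninformative,
            self.n_retained,
        ) < 0:
            raise ValueError("filter counts must be non-negative")


def _iqr(row: np.ndarray) -> float:
    # linear-interpolation ("type 7") quartiles
    q75, q25 = np.percentile(row, [75, 25])
    return float(q75 - q25)


def collapse_probes_iqr(
    dataset: ExpressionDataset, probe_map: pd.DataFrame
) -> ExpressionDataset:
    """Collapse a probe-level dataset to gene level by largest IQR.

    For each gene the retained row is, element-wise, the row of the annotated
    probe with the largest interquartile range across all samples of the
    study; ties keep the probe appearing first in file order.  Unannotated
    probes (empty symbol) are dropped.  Output genes are in lexicographic
    order.
    """
    symbols = dict(
        zip(probe_map["probe_id"].astype(str), probe_map["gene_symbol"].astype(str))
    )
    chosen: dict[str, tuple[float, int, str]] = {}  # gene -> (iqr, position, probe)
    mat = dataset.values.to_numpy()
    for pos, probe in enumerate(dataset.values.index):
        gene = symbols.get(str(probe), "")
        if not gene:
            continue
        iqr = _iqr(mat[pos])
        best = chosen.get(gene)
        if best is None or iqr > best[0]:
            chosen[gene] = (iqr, pos, str(probe))
    if not chosen:
        raise ValueError(f"{dataset.study_id}: no annotated probes to collapse")
    genes = sorted(chosen)
    rows = mat[[chosen[g][1] for g in genes]]
    values = pd.DataFrame(rows, index=genes, columns=dataset.values.columns)
    return ExpressionDataset(dataset.study_id, dataset.disease, values, dataset.groups)


def intersect_genes(datasets: Sequence[ExpressionDataset]) -> list[ExpressionDataset]:
    """Restrict every dataset to the shared gene panel, in lexicographic order."""
    if not datasets:
        raise ValueError("no datasets to intersect")
    common = set(datasets[0].features)
    for ds in datasets[1:]:
        common &= set(ds.features)
    if not common:
        raise ValueError("gene panels have an empty intersection")
    order = sorted(common)
    return [ds.subset_features(order) for ds in datasets]


def _stage_removal(
    datasets: Sequence[ExpressionDataset], stat: str, frac: float
) -> list[str]:
    """Genes to drop: smallest cross-study rank sum of per-study mean or SD."""
    genes = datasets[0].features
    rank_sum = np.zeros(len(genes))
    for ds in datasets:
        mat = ds.values.to_numpy()
        values = mat.mean(axis=1) if stat == "mean" else mat.std(axis=1, ddof=1)
        rank_sum += rankdata(values, method="average")  # rank 1 = smallest
    n_remove = int(np.floor(frac * len(genes)))
    order = np.lexsort((np.asarray(genes, dtype=object), rank_sum))
    return [genes[i] for i in order[:n_remove]]


def rank_sum_filter(
    datasets: Sequence[ExpressionDataset],
    frac_mean: float = 0.30,
    frac_sd: float = 0.30,
    n_input_genes: int | None = None,
) -> tuple[list[ExpressionDataset], FilterReport]:
    """Two-stage removal of un-expressed and un-informative genes.

    Stage 1 ranks each gene's mean intensity within each study (rank 1 =
    smallest, ties averaged), sums ranks across studies, and removes the
    ``floor(frac_mean * G)`` genes with the smallest rank sums.  Stage 2
    repeats with standard deviations on the survivors, removing
    ``floor(frac_sd * G')`` genes.  Rank-sum ties break lexicographically on
    the gene symbol.  ``n_input_genes`` optionally records the pre-
    intersection gene count for the report.
    """
    if not (0 <= frac_mean < 1 and 0 <= frac_sd < 1):
        raise ValueError("filter fractions must lie in [0, 1)")
    gene_list = datasets[0].features
    for ds in datasets[1:]:
        if ds.features != gene_list:
            raise ValueError(
                f"{ds.study_id}: gene list differs; run intersect_genes first"
            )
    n0 = len(gene_list)

    drop1 = set(_stage_removal(datasets, "mean", frac_mean))
    kept1 = [g for g in gene_list if g not in drop1]
    stage1 = [ds.subset_features(kept1) for ds in datasets]

    drop2 = set(_stage_removal(stage1, "sd", frac_sd))
    kept2 = [g for g in kept1 if g not in drop2]
    if not kept2:
        raise ValueError("rank-sum filtering removed every gene")
    out = [ds.subset_features(kept2) for ds in stage1]

    report = FilterReport(
        n_input_genes=n0 if n_input_genes is None else n_input_genes,
        n_after_intersection=n0,
        n_removed_unexpressed=len(drop1),
        n_removed_uninformative=len(drop2),
        n_retained=len(kept2),
    )
    return out, report
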