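"""Cross-disease common-gene detection.

A gene is called significant in a study either by the top-K criterion
(rank <= K, K = 100 by default) or by the FDR criterion (BH-adjusted
p < alpha, alpha = 0.01, strict).  Calls are aggregated to the disease level
(a disease is "hit" when the gene is significant in at least one of its
studies), genes hitting at least ``min_diseases`` (default 3) diseases are
selected per criterion, and the two criteria's selections are united with
per-gene provenance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import pandas as pd

TOP_K = "top_k"
FDR = "fdr"


@dataclass
class CommonGeneRecord:
    gene: str
    criterion: str
    diseases_hit: frozenset[str]

    @property
    def n_diseases_hit(self) -> int:
        return len(self.diseases_hit)


def make_calls(
    results: Mapping[str, pd.DataFrame],
    criterion: str,
    k: int = 100,
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Per-(gene, study) significance calls under one criterion.

    ``top_k``: significant iff rank <= k (boundary inclusive).  ``fdr``:
    significant iff BH-adjusted p is strictly below alpha.
    """
    if criterion not in (TOP_K, FDR):
        raise ValueError(f"criterion must be '{TOP_K}' or '{FDR}'")
    if criterion == TOP_K and k <= 0:
        raise ValueError("k must be positive")
    if criterion == FDR and not (0 < alpha < 1):
        raise ValueError("alpha must lie in (0, 1)")
    rows = []
    for study_id, table in results.items():
        if criterion == TOP_K:
            sig = table["rank"] <= k
        else:
            sig = table["p_adj"] < alpha
        rows.append(
            pd.DataFrame(
                {
                    "gene": table.index,
                    "study_id": study_id,
                    "criterion": criterion,
                    "significant": sig.to_numpy(),
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def aggregate_to_disease(
    calls: pd.DataFrame, study_to_disease: Mapping[str, str]
) -> dict[str, frozenset[str]]:
    """Map gene -> set of diseases with >=1 significant study for that gene."""
    unknown = set(calls["study_id"]) - set(study_to_disease)
    if unknown:
        raise ValueError(f"studies absent from manifest: {sorted(unknown)}")
    hits: dict[str, set[str]] = {}
    sig = calls[calls["significant"]]
    for gene, study_id in zip(sig["gene"], sig["study_id"]):
        hits.setdefault(gene, set()).add(study_to_disease[study_id])
    return {g: frozenset(d) for g, d in hits.items()}


def select_common(
    hits: Mapping[str, frozenset[str]],
    min_diseases: int = 3,
    criterion: str = "",
) -> list[CommonGeneRecord]:
    """Genes hitting >= min_diseases diseases, sorted by count (desc) then symbol."""
    records = [
        CommonGeneRecord(gene, criterion, frozenset(diseases))
        for gene, diseases in hits.items()
        if len(diseases) >= min_diseases
    ]
    records.sort(key=lambda r: (-r.n_diseases_hit, r.gene))
    return records


def union_criteria(
    top_k_records: list[CommonGeneRecord],
    fdr_records: list[CommonGeneRecord],
) -> pd.DataFrame:
    """Union of the two criteria's selections with per-gene provenance.

    Returns a gene-indexed DataFrame with boolean columns ``in_top_k`` and
    ``in_fdr``, a ``criteria`` label (``top_k``/``fdr``/``both``) and the
    union of diseases hit.
    """
    genes: dict[str, dict] = {}
    for records, col in ((top_k_records, "in_top_k"), (fdr_records, "in_fdr")):
        for rec in records:
            entry = genes.setdefault(
                rec.gene,
                {"in_top_k": False, "in_fdr": False, "diseases_hit": frozenset()},
            )
            entry[col] = True
            entry["diseases_hit"] = entry["diseases_hit"] | rec.diseases_hit
    rows = []
    for gene in sorted(genes):
        e = genes[gene]
        crit = "both" if e["in_top_k"] and e["in_fdr"] else (
            TOP_K if e["in_top_k"] else FDR
        )
        rows.append(
            {
                "gene": gene,
                "in_top_k": e["in_top_k"],
                "in_fdr": e["in_fdr"],
                "criteria": crit,
                "diseases_hit": ",".join(sorted(e["diseases_hit"])),
                "n_diseases_hit": len(e["diseases_hit"]),
            }
        )
    return pd.DataFrame(rows).set_index("gene") if rows else pd.DataFrame(
        columns=["in_top_k", "in_fdr", "criteria", "diseases_hit", "n_diseases_hit"]
    )


def find_common_genes(
    results: Mapping[str, pd.DataFrame],
    study_to_disease: Mapping[str, str],
    k: int = 100,
    alpha: float = 0.01,
    min_diseases: int = 3,
) -> pd.DataFrame:
    """Convenience wrapper: calls -> disease aggregation -> selection -> union."""
    selections = {}
    for criterion in (TOP_K, FDR):
        calls = make_calls(results, criterion, k=k, alpha=alpha)
        hits = aggregate_to_disease(calls, study_to_disease)
        selections[criterion] = select_common(hits, min_diseases, criterion)
    return union_criteria(selections[TOP_K], selections[FDR])
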