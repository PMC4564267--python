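"""Bundled example: a published cross-study significance pattern for four rheumatic diseases.

Eight immune genes were reported as differentially expressed in at least three
of four rheumatic diseases (rheumatoid arthritis RA, systemic lupus
erythematosus SLE, osteoarthritis OA, ankylosing spondylitis AS) across six
blood gene-expression studies.  Five genes came from the top-100-rank
criterion and five from the adjusted-p < 0.01 criterion, with TXN and CX3CR1
selected by both.  The tables below encode that pattern so the common-gene
logic can be exercised without any expression data.
"""

from __future__ import annotations

import pandas as pd

STUDY_TO_DISEASE = {
    "RA1": "RA",
    "RA2": "RA",
    "SLE1": "SLE",
    "SLE2": "SLE",
    "OA": "OA",
    "AS": "AS",
}

STUDIES = tuple(STUDY_TO_DISEASE)

#: Studies in which each top-100-criterion gene appeared among the 100
#: smallest moderated p-values.
TOP100_HITS: dict[str, tuple[str, ...]] = {
    "TNFSF10": ("RA1", "RA2", "SLE1", "SLE2", "AS"),
    "LY96": ("RA1", "SLE2", "AS"),
    "PRKCH": ("RA1", "OA", "AS"),
    "TXN": ("RA1", "SLE2", "AS"),
    "CX3CR1": ("RA2", "OA", "AS"),
}

#: Raw moderated p-values reported for the top-100-criterion genes.
TOP100_RAW_P: dict[str, dict[str, float]] = {
    "TNFSF10": {"RA1": 1.80e-4, "RA2": 6.00e-4, "SLE1": 9.00e-4,
                "SLE2": 1.00e-20, "OA": 5.66e-1, "AS": 1.50e-3},
    "LY96": {"RA1": 1.20e-4, "RA2": 2.44e-2, "SLE1": 4.49e-2,
             "SLE2": 1.00e-20, "OA": 1.90e-2, "AS": 7.95e-5},
    "PRKCH": {"RA1": 5.13e-6, "RA2": 7.25e-2, "SLE1": 2.52e-1,
              "SLE2": 5.86e-2, "OA": 3.21e-5, "AS": 5.10e-4},
    "TXN": {"RA1": 1.00e-20, "RA2": 1.80e-2, "SLE1": 1.79e-1,
            "SLE2": 1.00e-20, "OA": 6.51e-1, "AS": 1.28e-5},
    "CX3CR1": {"RA1": 7.07e-2, "RA2": 2.00e-4, "SLE1": 3.90e-2,
               "SLE2": 1.52e-2, "OA": 1.00e-20, "AS": 3.46e-5},
}

#: BH-adjusted p-values reported for the FDR-criterion genes; the selection
#: rule is strict (< 0.01).
FDR_ADJUSTED_P: dict[str, dict[str, float]] = {
    "TXN": {"RA1": 1.63e-18, "RA2": 5.83e-2, "SLE1": 7.20e-1,
            "SLE2": 1.61e-19, "OA": 7.79e-1, "AS": 7.33e-3},
    "CX3CR1": {"RA1": 2.58e-1, "RA2": 6.76e-3, "SLE1": 5.83e-1,
               "SLE2": 4.68e-2, "OA": 2.00e-18, "AS": 8.18e-3},
    "TLR5": {"RA1": 4.34e-2, "RA2": 6.76e-3, "SLE1": 3.77e-1,
             "SLE2": 6.94e-5, "OA": 5.49e-3, "AS": 4.05e-1},
    "TIA1": {"RA1": 3.49e-1, "RA2": 6.76e-3, "SLE1": 7.36e-1,
             "SLE2": 1.09e-3, "OA": 6.66e-3, "AS": 5.33e-1},
    "PRF1": {"RA1": 6.26e-2, "RA2": 8.82e-3, "SLE1": 7.08e-1,
             "SLE2": 6.60e-4, "OA": 1.88e-3, "AS": 6.43e-2},
}

#: Reported meta-analysis p-values for the eight genes.
META_FISHER_P = dict.fromkeys(
    ("TNFSF10", "LY96", "PRKCH", "TXN", "CX3CR1", "TLR5", "TIA1", "PRF1"), 1.07e-19
)
META_MAXP_P = {
    "TNFSF10": 1.65e-1,
    "LY96": 2.74e-18,
    "PRKCH": 1.01e-2,
    "TXN": 2.71e-1,
    "CX3CR1": 2.74e-18,
    "TLR5": 2.28e-3,
    "TIA1": 1.58e-2,
    "PRF1": 4.76e-4,
}

EIGHT_GENES = tuple(META_MAXP_P)


def example_de_tables() -> dict[str, pd.DataFrame]:
    """Per-study DE-shaped tables encoding the published significance pattern.

    Top-100 membership is encoded through the ``rank`` column (a distinct rank
    <= 100 for each reported hit, > 100 otherwise) and the FDR criterion
    through the reported adjusted p-values (genes absent from the FDR table
    get p_adj = 1).  The ``p`` column carries the reported raw p where
    available and 1 otherwise; ``t`` is a positive placeholder since only
    significance, not direction, was reported per cell.
    """
    genes = sorted(EIGHT_GENES)
    tables: dict[str, pd.DataFrame] = {}
    for study in STUDIES:
        rows = []
        next_top_rank = 1
        for i, gene in enumerate(genes):
            in_top = study in TOP100_HITS.get(gene, ())
            if in_top:
                rank = next_top_rank
                next_top_rank += 1
            else:
                rank = 101 + i
            p_adj = FDR_ADJUSTED_P.get(gene, {}).get(study, 1.0)
            p_raw = TOP100_RAW_P.get(gene, {}).get(study, 1.0)
            rows.append({"gene": gene, "t": 1.0, "df": 10.0, "p": p_raw,
                         "p_adj": p_adj, "rank": rank})
        tables[study] = pd.DataFrame(rows).set_index("gene")
    return tables
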