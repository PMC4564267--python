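"""Over-representation analysis of a gene list against gene sets (hypergeometric tail).

For a universe of N genes, a set with K universe members, and a selected list
of n genes overlapping the set in k genes, the enrichment p-value is the
hypergeometric upper tail P(X >= k).  The universe defaults to the post-filter
gene list from which the selection was made; sets are restricted to universe
members before testing.  BH adjustment is applied across the tested sets.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import pandas as pd
from scipy.stats import hypergeom

from .diffexpr import bh_adjust
from .io import GeneSet


def hypergeom_tail(N: int, K: int, n: int, k: int) -> float:
    """Upper-tail probability P(X >= k) for X ~ Hypergeometric(N, K, n)."""
    if not (0 <= K <= N and 0 <= n <= N and 0 <= k <= min(K, n)):
        raise ValueError(f"invalid hypergeometric bounds N={N} K={K} n={n} k={k}")
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def enrich(
    selected_genes: Iterable[str],
    gene_sets: Sequence[GeneSet],
    universe: Iterable[str],
) -> pd.DataFrame:
    """One enrichment row per gene set with >=1 universe member, BH-adjusted, sorted by p."""
    universe_set = {g.upper() for g in universe}
    selected = {g.upper() for g in selected_genes}
    outside = selected - universe_set
    if outside:
        raise ValueError(f"selected gene(s) outside the universe: {sorted(outside)[:5]}")
    N, n = len(universe_set), len(selected)
    rows = []
    for gs in gene_sets:
        members = {g.upper() for g in gs.genes} & universe_set
        if not members:
            continue
        overlap = sorted(selected & members)
        rows.append(
            {
                "set_name": gs.name,
                "description": gs.description,
                "N": N,
                "K": len(members),
                "n": n,
                "k": len(overlap),
                "p_value": hypergeom_tail(N, len(members), n, len(overlap)),
                "overlap_genes": ",".join(overlap),
            }
        )
    if not rows:
        return pd.DataFrame(
            columns=["set_name", "description", "N", "K", "n", "k",
                     "p_value", "p_adjusted", "overlap_genes"]
        )
    out = pd.DataFrame(rows)
    out["p_adjusted"] = bh_adjust(out["p_value"].to_numpy())
    out = out.sort_values(["p_value", "set_name"], kind="stable").reset_index(drop=True)
    return out[["set_name", "description", "N", "K", "n", "k",
                "p_value", "p_adjusted", "overlap_genes"]]
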