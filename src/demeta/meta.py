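"""Gene-level p-value combination across studies: Fisher's method and maximum-P.

Fisher's statistic X = -2 * sum(ln p_i) is referred to a chi-square
distribution with 2k df; it rewards one extremely small study p-value.  The
maximum-P statistic max_i p_i is referred to its Beta(k, 1) null, giving
meta-p = (max p)^k; it requires small p-values in every study.  Per-study
p-values are floored (default 1e-20) before taking logs, and the combined
p-values are Benjamini-Hochberg adjusted across genes separately per method.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .diffexpr import bh_adjust

DEFAULT_P_FLOOR = 1e-20


def clamp_p(p, floor: float = DEFAULT_P_FLOOR):
    """Clamp p-values into [floor, 1]."""
    arr = np.asarray(p, dtype=float)
    if np.any(arr < 0):
        raise ValueError("p-values must be non-negative")
    out = np.minimum(np.maximum(arr, floor), 1.0)
    return float(out) if np.isscalar(p) or arr.ndim == 0 else out


def fisher_combine(p_per_study: Sequence[float]) -> tuple[float, float]:
    """Fisher combination: returns (X, meta_p) with X = -2 sum ln p_i."""
    p = np.asarray(p_per_study, dtype=float)
    if p.size == 0:
        raise ValueError("need at least one study p-value")
    stat = float(-2.0 * np.log(p).sum())
    return stat, float(chi2.sf(stat, 2 * p.size))


def maxp_combine(p_per_study: Sequence[float]) -> tuple[float, float]:
    """Maximum-P combination: returns (max p, (max p)^k)."""
    p = np.asarray(p_per_study, dtype=float)
    if p.size == 0:
        raise ValueError("need at least one study p-value")
    stat = float(p.max())
    return stat, float(stat ** p.size)


def run_meta(
    results: Mapping[str, pd.DataFrame],
    methods: Iterable[str] = ("fisher", "maxp"),
    floor: float = DEFAULT_P_FLOOR,
) -> pd.DataFrame:
    """Combine per-study raw moderated-t p-values gene-wise across all studies.

    ``results`` maps study_id -> DE table (gene-indexed, with a ``p`` column);
    all studies must share the same gene universe.  Raw (not BH-adjusted)
    per-study p-values are clamped and combined; BH adjustment is then applied
    once per method across genes.
    """
    methods = list(methods)
    unknown = set(methods) - {"fisher", "maxp"}
    if unknown:
        raise ValueError(f"unknown combination method(s): {sorted(unknown)}")
    study_ids = list(results)
    if not study_ids:
        raise ValueError("no studies to combine")
    genes = sorted(results[study_ids[0]].index)
    for sid in study_ids[1:]:
        if sorted(results[sid].index) != genes:
            raise ValueError(f"{sid}: gene universe differs across studies")
    k = len(study_ids)
    pmat = np.column_stack(
        [clamp_p(results[sid].loc[genes, "p"].to_numpy(), floor) for sid in study_ids]
    )
    out = pd.DataFrame(index=pd.Index(genes, name="gene"))
    out["k"] = k
    if "fisher" in methods:
        stat = -2.0 * np.log(pmat).sum(axis=1)
        out["fisher_stat"] = stat
        out["fisher_p"] = chi2.sf(stat, 2 * k)
        out["fisher_p_adj"] = bh_adjust(np.clip(out["fisher_p"], 1e-300, 1.0))
    if "maxp" in methods:
        stat = pmat.max(axis=1)
        out["maxp_stat"] = stat
        out["maxp_p"] = stat ** k
        out["maxp_p_adj"] = bh_adjust(np.clip(out["maxp_p"], 1e-300, 1.0))
    return out
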