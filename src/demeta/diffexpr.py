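"""Per-study differential expression with the empirical-Bayes moderated t-statistic.

The gene-wise pooled variance s_g^2 (d_g residual df) is shrunk toward a prior
s0^2 with prior df d0 estimated by moment matching on the log variances:
with z_g = ln s_g^2 and e_g = z_g - psi(d_g/2) + ln(d_g/2),

    psi'(d0/2) = max( var(e_g) - mean psi'(d_g/2), 0 )
    s0^2       = exp( mean(e_g) + psi(d0/2) - ln(d0/2) )

where psi is the digamma function and the trigamma equation is solved by a
monotone Newton iteration.  The moderated statistic is

    t_g = M_g / sqrt( s~_g^2 * v ),   s~_g^2 = (d0 s0^2 + d_g s_g^2)/(d0 + d_g)

with M_g the case-minus-control mean difference and v = 1/n1 + 1/n2, referred
to a t distribution on d0 + d_g df (standard normal when d0 is infinite).
Two-sided p-values are adjusted by Benjamini-Hochberg.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import digamma, polygamma
from statsmodels.stats.multitest import multipletests

from .io import ExpressionDataset

_P_MIN = 1e-300  # keeps two-sided p strictly positive for extreme statistics
_D0_INF_TOL = 1e-8


@dataclass
class EBHyperparams:
    """Prior df d0 (possibly infinite) and prior variance s0^2."""

    d0: float
    s02: float

    def __post_init__(self) -> None:
        if not (self.d0 > 0):
            raise ValueError("prior df d0 must be positive")
        if not (self.s02 > 0):
            raise ValueError("prior variance s0^2 must be positive")


def summarize_genes(dataset: ExpressionDataset) -> pd.DataFrame:
    """Per-gene two-group summaries: mean difference, pooled variance, df, design factor.

    Returns a DataFrame indexed by gene with columns ``mean_diff`` (case mean
    minus control mean), ``s2`` (pooled within-group variance on
    ``df`` = n1+n2-2 degrees of freedom) and ``v`` = 1/n1 + 1/n2.
    """
    cases = dataset.values[dataset.case_ids].to_numpy()
    controls = dataset.values[dataset.control_ids].to_numpy()
    n1, n2 = cases.shape[1], controls.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError(
            f"{dataset.study_id}: need >=2 samples per group (got {n1} cases, {n2} controls)"
        )
    mean_diff = cases.mean(axis=1) - controls.mean(axis=1)
    ss = cases.var(axis=1, ddof=1) * (n1 - 1) + controls.var(axis=1, ddof=1) * (n2 - 1)
    df = n1 + n2 - 2
    return pd.DataFrame(
        {
            "mean_diff": mean_diff,
            "s2": ss / df,
            "df": float(df),
            "v": 1.0 / n1 + 1.0 / n2,
        },
        index=dataset.values.index,
    )


def trigamma_inverse(y: float, tol: float = 1e-12, max_iter: int = 75) -> float:
    """Solve psi'(x) = y for x > 0 by Newton iteration (psi' is monotone)."""
    if not (y > 0):
        raise ValueError("trigamma_inverse requires y > 0")
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = float(polygamma(1, x))
        step = tri * (1.0 - tri / y) / float(polygamma(2, x))
        x += step
        if abs(step) < tol * x:
            break
    return x


def estimate_hyperparams(summaries: pd.DataFrame) -> EBHyperparams:
    """Moment estimation of (d0, s0^2) from gene-wise pooled variances.

    Genes with zero pooled variance are excluded from estimation (they still
    receive moderated statistics downstream); at least 10 usable genes are
    required.  If the excess spread of the log variances is at or below
    tolerance, d0 is infinite and s0^2 = exp(mean e_g).
    """
    usable = summaries[summaries["s2"] > 0]
    if len(usable) < 10:
        raise ValueError(
            f"need >=10 genes with positive variance for estimation, got {len(usable)}"
        )
    half_df = usable["df"].to_numpy() / 2.0
    e = np.log(usable["s2"].to_numpy()) - digamma(half_df) + np.log(half_df)
    e_mean = float(e.mean())
    e_var = float(((e - e_mean) ** 2).sum() / (len(e) - 1))
    rhs = e_var - float(polygamma(1, half_df).mean())
    if rhs <= _D0_INF_TOL:
        return EBHyperparams(d0=math.inf, s02=math.exp(e_mean))
    d0 = 2.0 * trigamma_inverse(rhs)
    s02 = math.exp(e_mean + float(digamma(d0 / 2.0)) - math.log(d0 / 2.0))
    return EBHyperparams(d0=d0, s02=s02)


def moderated_t(
    summaries: pd.DataFrame, hyper: EBHyperparams | None
) -> pd.DataFrame:
    """Moderated t, total df and two-sided p per gene.

    ``hyper=None`` (or d0=0, used by tests) disables moderation, reducing the
    statistic to the ordinary pooled two-sample t.
    """
    s2 = summaries["s2"].to_numpy()
    df = summaries["df"].to_numpy()
    v = summaries["v"].to_numpy()
    m = summaries["mean_diff"].to_numpy()

    if hyper is None:
        d0, s02 = 0.0, 1.0
    else:
        d0, s02 = hyper.d0, hyper.s02

    if math.isinf(d0):
        s2_post = np.full_like(s2, s02)
        df_total = np.full_like(s2, math.inf)
    else:
        s2_post = (d0 * s02 + df * s2) / (d0 + df)
        df_total = d0 + df

    with np.errstate(divide="ignore", invalid="ignore"):
        t = m / np.sqrt(s2_post * v)
    t = np.where(np.isnan(t), 0.0, t)  # 0/0 -> no evidence

    if math.isinf(d0):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p = np.clip(p, _P_MIN, 1.0)
    return pd.DataFrame(
        {"t": t, "df": df_total, "p": p}, index=summaries.index
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("expected a non-empty 1-d array of p-values")
    if np.any((p <= 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def rank_by_p(p: np.ndarray, genes) -> np.ndarray:
    """Ranks 1..G by ascending p, ties broken lexicographically on the symbol."""
    order = np.lexsort((np.asarray(genes, dtype=object), np.asarray(p)))
    ranks = np.empty(len(p), dtype=int)
    ranks[order] = np.arange(1, len(p) + 1)
    return ranks


def de_analysis(
    dataset: ExpressionDataset, hyper: EBHyperparams | None = None
) -> pd.DataFrame:
    """Full per-study DE table: gene-indexed t, df, p, BH-adjusted p and rank.

    Hyperparameters are estimated from the study itself when not supplied.
    """
    summaries = summarize_genes(dataset)
    if hyper is None:
        hyper = estimate_hyperparams(summaries)
    res = moderated_t(summaries, hyper)
    res["p_adj"] = bh_adjust(res["p"].to_numpy())
    res["rank"] = rank_by_p(res["p"].to_numpy(), res.index)
    return res
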